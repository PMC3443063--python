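"""Gene-Protein-Reaction (GPR) boolean formulas.

A GPR states which combinations of genes enable a reaction: AND joins
subunits of a complex, OR joins isozymes.  This module parses the COBRA
notes dialect (identifiers, case-insensitive ``and``/``or``, parentheses),
normalizes formulas to *minimal gene sets* (the alternative complete gene
combinations that each suffice for the reaction), evaluates them against a
gene-presence set, and rewrites them through a scaffold-to-target homolog
map, classifying each rewrite into the evolutionary cases M1-M7:

=====  =============================================================
M1     gene loss: the formula has no surviving complete gene set
M2     gene gain: a target-only association (produced by insertion of
       species-specific reactions, never by rewriting)
M3     one-to-one ortholog substitution
M4     duplication in the scaffold: two scaffold genes collapse onto
       one target gene
M5     family contraction: three or more scaffold genes collapse onto
       one target gene
M6     duplication in the target: one scaffold gene expands to an OR
       of two target genes
M7     family expansion: one scaffold gene expands to an OR of three
       or more target genes
=====  =============================================================

A formula combining several non-trivial cases is labelled ``mixed``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

__all__ = [
    "Gene",
    "And",
    "Or",
    "GeneAssociation",
    "GPRParseError",
    "RewriteResult",
    "parse_gpr",
    "to_string",
    "genes_of",
    "evaluate",
    "minimal_gene_sets",
    "from_gene_sets",
    "rewrite",
    "CASE_LOSS",
    "CASE_GAIN",
    "CASE_ONE_TO_ONE",
    "CASE_DUP_IN_SCAFFOLD",
    "CASE_EXPANSION_IN_SCAFFOLD",
    "CASE_DUP_IN_TARGET",
    "CASE_EXPANSION_IN_TARGET",
    "CASE_MIXED",
]

CASE_LOSS = "M1"
CASE_GAIN = "M2"
CASE_ONE_TO_ONE = "M3"
CASE_DUP_IN_SCAFFOLD = "M4"
CASE_EXPANSION_IN_SCAFFOLD = "M5"
CASE_DUP_IN_TARGET = "M6"
CASE_EXPANSION_IN_TARGET = "M7"
CASE_MIXED = "mixed"


@dataclass(frozen=True)
class Gene:
    """Leaf node: a single gene identifier."""

    gene: str

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene identifier must be non-empty")


@dataclass(frozen=True)
class And:
    children: tuple["GeneAssociation", ...]

    def __post_init__(self) -> None:
        if not self.children:
            raise ValueError("AND node must have at least one child")


@dataclass(frozen=True)
class Or:
    children: tuple["GeneAssociation", ...]

    def __post_init__(self) -> None:
        if not self.children:
            raise ValueError("OR node must have at least one child")


GeneAssociation = Union[Gene, And, Or]


class GPRParseError(ValueError):
    """Raised for malformed GPR strings; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# ---------------------------------------------------------------------------
# parsing

_IDENT_CHARS = frozenset(
    "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_.:-'"
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
        elif c == "(":
            tokens.append(("LPAREN", c, i))
            i += 1
        elif c == ")":
            tokens.append(("RPAREN", c, i))
            i += 1
        elif c in _IDENT_CHARS:
            j = i
            while j < n and text[j] in _IDENT_CHARS:
                j += 1
            word = text[i:j]
            low = word.lower()
            if low == "and":
                tokens.append(("AND", word, i))
            elif low == "or":
                tokens.append(("OR", word, i))
            else:
                tokens.append(("IDENT", word, i))
            i = j
        else:
            raise GPRParseError(f"unexpected character {c!r}", i)
    return tokens


def parse_gpr(text: str) -> GeneAssociation:
    """Parse a GPR string into an association tree.

    Grammar: ``expr := term ('or' term)*``, ``term := factor ('and'
    factor)*``, ``factor := '(' expr ')' | identifier``.  Operators are
    case-insensitive; the tree evaluates identically to the source
    expression under every truth assignment.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise GPRParseError("empty GPR string", 0)
    pos = 0

    def peek() -> Optional[tuple[str, str, int]]:
        return tokens[pos] if pos < len(tokens) else None

    def expect_end_pos() -> int:
        return tokens[pos][2] if pos < len(tokens) else len(text)

    def parse_expr() -> GeneAssociation:
        nonlocal pos
        terms = [parse_term()]
        while peek() and peek()[0] == "OR":
            pos += 1
            terms.append(parse_term())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_term() -> GeneAssociation:
        nonlocal pos
        factors = [parse_factor()]
        while peek() and peek()[0] == "AND":
            pos += 1
            factors.append(parse_factor())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def parse_factor() -> GeneAssociation:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise GPRParseError("dangling operator or empty group", len(text))
        kind, word, at = tok
        if kind == "LPAREN":
            pos += 1
            inner = parse_expr()
            closing = peek()
            if closing is None or closing[0] != "RPAREN":
                raise GPRParseError("unbalanced parentheses", at)
            pos += 1
            return inner
        if kind == "IDENT":
            pos += 1
            return Gene(word)
        raise GPRParseError(f"unexpected token {word!r}", at)

    tree = parse_expr()
    if pos != len(tokens):
        raise GPRParseError(
            f"unexpected trailing token {tokens[pos][1]!r}", tokens[pos][2]
        )
    return tree


def to_string(assoc: GeneAssociation) -> str:
    """Render a tree back to the COBRA notes dialect."""
    if isinstance(assoc, Gene):
        return assoc.gene
    if isinstance(assoc, And):
        parts = (
            f"({to_string(c)})" if isinstance(c, Or) else to_string(c)
            for c in assoc.children
        )
        return " and ".join(parts)
    parts = (
        f"({to_string(c)})" if isinstance(c, And) else to_string(c)
        for c in assoc.children
    )
    return " or ".join(parts)


# ---------------------------------------------------------------------------
# semantics

def genes_of(assoc: GeneAssociation) -> frozenset[str]:
    if isinstance(assoc, Gene):
        return frozenset((assoc.gene,))
    out: set[str] = set()
    for child in assoc.children:
        out |= genes_of(child)
    return frozenset(out)


def evaluate(assoc: GeneAssociation, present_genes: Iterable[str]) -> bool:
    """Standard boolean semantics: a leaf is true iff its gene is present."""
    present = (
        present_genes if isinstance(present_genes, (set, frozenset)) else set(present_genes)
    )

    def rec(node: GeneAssociation) -> bool:
        if isinstance(node, Gene):
            return node.gene in present
        if isinstance(node, And):
            return all(rec(c) for c in node.children)
        return any(rec(c) for c in node.children)

    return rec(assoc)


def _prune_supersets(sets: Iterable[frozenset[str]]) -> list[frozenset[str]]:
    unique = sorted(set(sets), key=len)
    kept: list[frozenset[str]] = []
    for s in unique:
        if not any(k <= s for k in kept):
            kept.append(s)
    return kept


def minimal_gene_sets(assoc: GeneAssociation) -> list[frozenset[str]]:
    """Canonical normal form: the minimal alternative complete gene sets.

    The reaction is available iff all genes of at least one returned set
    are present.  No set is a superset of another (absorption applied);
    the list is in lexicographic order for reproducibility.
    """

    def rec(node: GeneAssociation) -> list[frozenset[str]]:
        if isinstance(node, Gene):
            return [frozenset((node.gene,))]
        if isinstance(node, Or):
            out: list[frozenset[str]] = []
            for child in node.children:
                out.extend(rec(child))
            return _prune_supersets(out)
        # And: cross product of the children's alternatives
        combos = [frozenset()]
        for child in node.children:
            child_sets = rec(child)
            combos = [a | b for a, b in itertools.product(combos, child_sets)]
            combos = _prune_supersets(combos)
        return combos

    sets = _prune_supersets(rec(assoc))
    return sorted(sets, key=lambda s: tuple(sorted(s)))


def from_gene_sets(sets: Sequence[frozenset[str]]) -> GeneAssociation:
    """Rebuild a canonical OR-of-ANDs tree from minimal gene sets."""
    if not sets:
        raise ValueError("cannot build an association from zero gene sets")
    terms: list[GeneAssociation] = []
    for s in sorted(sets, key=lambda s: tuple(sorted(s))):
        genes = [Gene(g) for g in sorted(s)]
        terms.append(genes[0] if len(genes) == 1 else And(tuple(genes)))
    return terms[0] if len(terms) == 1 else Or(tuple(terms))


# ---------------------------------------------------------------------------
# rewriting through a homolog map

@dataclass
class RewriteResult:
    """Outcome of projecting one GPR through a scaffold→target homolog map.

    ``new_association`` is absent when no complete gene set survives the
    mapping (case M1); ``unresolved_genes`` lists scaffold genes with no
    target candidates, reported for manual curation as possible losses of
    function.
    """

    new_association: Optional[GeneAssociation]
    case_label: str
    unresolved_genes: frozenset[str] = field(default_factory=frozenset)


# internal marker for a leaf-level partial loss inside a surviving formula
_PARTIAL_LOSS = "partial-loss"


def _leaf_cases(
    leaves: Sequence[str], targets: Mapping[str, frozenset[str]]
) -> dict[str, str]:
    """Assign each scaffold leaf its rewrite case.

    Single-target leaves sharing the same target gene collapse (M4 for a
    pair, M5 for a larger family); multi-target leaves expand (M6 for a
    pair, M7 for a larger family).
    """
    cases: dict[str, str] = {}
    by_single_target: dict[str, list[str]] = {}
    for leaf in leaves:
        tgt = targets.get(leaf, frozenset())
        if not tgt:
            cases[leaf] = _PARTIAL_LOSS
        elif len(tgt) == 1:
            by_single_target.setdefault(next(iter(tgt)), []).append(leaf)
        elif len(tgt) == 2:
            cases[leaf] = CASE_DUP_IN_TARGET
        else:
            cases[leaf] = CASE_EXPANSION_IN_TARGET
    for _tgt, group in by_single_target.items():
        if len(group) == 1:
            label = CASE_ONE_TO_ONE
        elif len(group) == 2:
            label = CASE_DUP_IN_SCAFFOLD
        else:
            label = CASE_EXPANSION_IN_SCAFFOLD
        for leaf in group:
            cases[leaf] = label
    return cases


def rewrite(
    assoc: GeneAssociation, homolog_map: Mapping[str, frozenset[str]] | "object"
) -> RewriteResult:
    """Rewrite a scaffold GPR in terms of target-genome genes.

    ``homolog_map`` is either a plain mapping of scaffold gene id to a
    frozenset of target gene ids, or any object with a ``targets_of(gene)``
    method returning such a frozenset (e.g. a consensus homolog map).

    Each leaf is replaced by the OR over its target candidates.  A leaf
    with no candidates is dropped from an OR (another isozyme may still
    carry the reaction) but poisons an AND (the complex is incomplete).
    If no complete gene set survives, the result is case M1 with no
    association.  The surviving formula is normalized to canonical minimal
    gene sets, merging duplicate leaves and applying absorption.
    """
    if hasattr(homolog_map, "targets_of"):
        lookup = homolog_map.targets_of  # type: ignore[union-attr]
    else:
        mapping = homolog_map

        def lookup(g: str) -> frozenset[str]:
            return frozenset(mapping.get(g, frozenset()))

    leaves = sorted(genes_of(assoc))
    targets = {leaf: frozenset(lookup(leaf)) for leaf in leaves}
    unresolved = frozenset(leaf for leaf, t in targets.items() if not t)

    def substitute(node: GeneAssociation) -> Optional[GeneAssociation]:
        if isinstance(node, Gene):
            tgt = sorted(targets[node.gene])
            if not tgt:
                return None
            if len(tgt) == 1:
                return Gene(tgt[0])
            return Or(tuple(Gene(g) for g in tgt))
        if isinstance(node, And):
            subbed = [substitute(c) for c in node.children]
            if any(s is None for s in subbed):
                return None
            return And(tuple(s for s in subbed if s is not None))
        subbed = [substitute(c) for c in node.children]
        alive = [s for s in subbed if s is not None]
        if not alive:
            return None
        return alive[0] if len(alive) == 1 else Or(tuple(alive))

    new_tree = substitute(assoc)
    if new_tree is None:
        return RewriteResult(None, CASE_LOSS, unresolved)

    canonical = from_gene_sets(minimal_gene_sets(new_tree))
    cases = _leaf_cases(leaves, targets)
    nontrivial = {c for c in cases.values() if c != CASE_ONE_TO_ONE}
    if not nontrivial:
        label = CASE_ONE_TO_ONE
    elif len(nontrivial) == 1 and _PARTIAL_LOSS not in nontrivial:
        label = next(iter(nontrivial))
    else:
        label = CASE_MIXED
    return RewriteResult(canonical, label, unresolved)
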