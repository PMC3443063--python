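"""GPR parsing, normalization, evaluation, and rewrite-case classification."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from gemproject import gpr as G
from oracles import (
    eval_gene_sets,
    eval_tree_directly,
    substitute_and_evaluate,
    truth_table,
)


# ---------------------------------------------------------------------------
# parsing

@pytest.mark.parametrize(
    "text,expected",
    [
        ("G1", G.Gene("G1")),
        ("(YGR032W or YLR342W)", G.Or((G.Gene("YGR032W"), G.Gene("YLR342W")))),
        (
            "A and (B or C)",
            G.And((G.Gene("A"), G.Or((G.Gene("B"), G.Gene("C"))))),
        ),
        ("a AND b Or c", G.Or((G.And((G.Gene("a"), G.Gene("b"))), G.Gene("c")))),
        ("((A))", G.Gene("A")),
    ],
)
def test_parse_structures(text, expected):
    assert G.parse_gpr(text) == expected


@pytest.mark.parametrize("bad", ["", "(A or B", "A or", "and A", "A B", "A ) or B"])
def test_parse_errors_carry_position(bad):
    with pytest.raises(G.GPRParseError) as err:
        G.parse_gpr(bad)
    assert err.value.position >= 0


def test_parse_roundtrips_through_to_string():
    text = "A and (B or C and D) or E"
    tree = G.parse_gpr(text)
    again = G.parse_gpr(G.to_string(tree))
    genes = G.genes_of(tree)
    assert truth_table(lambda p: G.evaluate(tree, p), genes) == truth_table(
        lambda p: G.evaluate(again, p), genes
    )


# ---------------------------------------------------------------------------
# evaluation and normalization vs the truth-table oracle

@pytest.mark.parametrize(
    "text",
    [
        "A",
        "A or B",
        "A and B",
        "A and (B or C)",
        "(A or B) and (C or D)",
        "(A and B) or (A and B and C)",  # absorption
        "A or (A and B)",
        "(A or B or C) and D and (E or F)",
        "YALI0F08195g and (YALI0F01496g or YALI0E23540g)",
        "(A or B) and (B or C) and (C or A)",
    ],
)
def test_minimal_gene_sets_match_truth_table(text):
    tree = G.parse_gpr(text)
    genes = G.genes_of(tree)
    sets = G.minimal_gene_sets(tree)
    # no redundant supersets
    for a, b in itertools.permutations(sets, 2):
        assert not a < b
    direct = truth_table(lambda p: eval_tree_directly(tree, p), genes)
    via_sets = truth_table(lambda p: eval_gene_sets(sets, frozenset(p)), genes)
    assert direct == via_sets
    # rebuilding from sets preserves semantics too
    rebuilt = G.from_gene_sets(sets)
    assert truth_table(lambda p: G.evaluate(rebuilt, p), genes) == direct


def test_minimal_gene_sets_examples():
    tree = G.parse_gpr("A and (B or C)")
    assert G.minimal_gene_sets(tree) == [frozenset("AB"), frozenset("AC")]
    assert G.minimal_gene_sets(G.Gene("A")) == [frozenset("A")]
    tree = G.parse_gpr("YALI0F08195g and (YALI0F01496g or YALI0E23540g)")
    assert G.minimal_gene_sets(tree) == sorted(
        [
            frozenset({"YALI0F08195g", "YALI0F01496g"}),
            frozenset({"YALI0F08195g", "YALI0E23540g"}),
        ],
        key=lambda s: tuple(sorted(s)),
    )


@st.composite
def random_trees(draw, max_depth=4):
    genes = [f"g{i}" for i in range(8)]
    def node(depth):
        if depth >= max_depth or draw(st.booleans()):
            return G.Gene(draw(st.sampled_from(genes)))
        kind = draw(st.sampled_from([G.And, G.Or]))
        n = draw(st.integers(2, 3))
        return kind(tuple(node(depth + 1) for _ in range(n)))
    return node(0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(random_trees())
def test_evaluate_agrees_with_oracle_on_random_trees(tree):
    genes = G.genes_of(tree)
    assert truth_table(lambda p: G.evaluate(tree, p), genes) == truth_table(
        lambda p: eval_tree_directly(tree, p), genes
    )
    sets = G.minimal_gene_sets(tree)
    assert truth_table(lambda p: eval_gene_sets(sets, frozenset(p)), genes) == (
        truth_table(lambda p: eval_tree_directly(tree, p), genes)
    )


def test_evaluate_examples():
    tree = G.parse_gpr("YGR032W or YLR342W")
    assert G.evaluate(tree, {"YLR342W"})
    assert not G.evaluate(G.parse_gpr("A and B"), {"A"})


# ---------------------------------------------------------------------------
# rewriting: the seven evolutionary cases

def test_rewrite_one_to_one():
    res = G.rewrite(G.Gene("YPL104W"), {"YPL104W": frozenset({"YALI0F26433g"})})
    assert res.new_association == G.Gene("YALI0F26433g")
    assert res.case_label == G.CASE_ONE_TO_ONE
    assert not res.unresolved_genes


def test_rewrite_duplication_in_scaffold_collapses():
    tree = G.parse_gpr("YEL006W or YIL006W")
    res = G.rewrite(
        tree,
        {"YEL006W": frozenset({"YALI0E16478g"}), "YIL006W": frozenset({"YALI0E16478g"})},
    )
    assert res.new_association == G.Gene("YALI0E16478g")
    assert res.case_label == G.CASE_DUP_IN_SCAFFOLD


def test_rewrite_scaffold_family_contraction():
    tree = G.parse_gpr("YIL009W or YMR246W or YOR317W")
    res = G.rewrite(tree, {g: frozenset({"YALI0D17864g"}) for g in G.genes_of(tree)})
    assert res.new_association == G.Gene("YALI0D17864g")
    assert res.case_label == G.CASE_EXPANSION_IN_SCAFFOLD


def test_rewrite_duplication_in_target():
    tree = G.parse_gpr("YBL064C and YCR083W")
    res = G.rewrite(
        tree,
        {
            "YCR083W": frozenset({"YALI0F01496g", "YALI0E23540g"}),
            "YBL064C": frozenset({"YALI0F08195g"}),
        },
    )
    expected = G.parse_gpr("YALI0F08195g and (YALI0F01496g or YALI0E23540g)")
    assert G.minimal_gene_sets(res.new_association) == G.minimal_gene_sets(expected)
    assert res.case_label == G.CASE_DUP_IN_TARGET


def test_rewrite_target_family_expansion_unions_six_ways():
    family = frozenset(f"T{i}" for i in range(6))
    res = G.rewrite(G.Gene("S1"), {"S1": family})
    assert res.case_label == G.CASE_EXPANSION_IN_TARGET
    assert G.minimal_gene_sets(res.new_association) == [
        frozenset({t}) for t in sorted(family)
    ]


def test_rewrite_loss_when_unmapped():
    res = G.rewrite(G.Gene("YJR051W"), {})
    assert res.new_association is None
    assert res.case_label == G.CASE_LOSS
    assert res.unresolved_genes == {"YJR051W"}


def test_unmapped_leaf_poisons_and_but_not_or():
    mapping = {"A": frozenset({"tA"})}
    res_and = G.rewrite(G.parse_gpr("A and B"), mapping)
    assert res_and.new_association is None and res_and.case_label == G.CASE_LOSS
    res_or = G.rewrite(G.parse_gpr("A or B"), mapping)
    assert res_or.new_association == G.Gene("tA")
    assert res_or.case_label == G.CASE_MIXED  # partial loss is never a clean case
    assert res_or.unresolved_genes == {"B"}


def test_rewrite_mixed_label_for_combined_cases():
    res = G.rewrite(
        G.parse_gpr("(A or B) and C"),
        {
            "A": frozenset({"t1"}),
            "B": frozenset({"t1"}),  # M4 pair...
            "C": frozenset({"t2", "t3"}),  # ...plus an M6 expansion
        },
    )
    assert res.case_label == G.CASE_MIXED


@settings(max_examples=40, deadline=None, derandomize=True)
@given(random_trees(), st.data())
def test_rewrite_semantics_match_substitution_oracle(tree, data):
    """The rewritten formula's truth table over target genes must equal
    substituting each scaffold leaf with the OR of its candidates."""
    genes = sorted(G.genes_of(tree))
    mapping = {}
    targets = []
    for i, g in enumerate(genes):
        k = data.draw(st.integers(0, 2))
        tgt = frozenset(f"t{i}_{j}" for j in range(k))
        mapping[g] = tgt
        targets.extend(tgt)
    res = G.rewrite(tree, mapping)
    if res.new_association is None:
        # oracle must be identically false
        assert not any(
            substitute_and_evaluate(tree, mapping, set(combo))
            for r in range(len(targets) + 1)
            for combo in itertools.combinations(targets, r)
        )
    else:
        table_impl = truth_table(
            lambda p: G.evaluate(res.new_association, p), targets
        )
        table_oracle = truth_table(
            lambda p: substitute_and_evaluate(tree, mapping, set(p)), targets
        )
        assert table_impl == table_oracle


def test_rewrite_monotone_in_the_map():
    """Adding a mapping for an unresolved gene never removes a gene set."""
    tree = G.parse_gpr("(A or B) and C")
    base = {"A": frozenset({"tA"}), "C": frozenset({"tC"})}
    before = G.rewrite(tree, base)
    richer = dict(base, B=frozenset({"tB"}))
    after = G.rewrite(tree, richer)
    assert set(G.minimal_gene_sets(before.new_association)) <= set(
        G.minimal_gene_sets(after.new_association)
    )


def test_identity_rewrite_preserves_truth_table():
    tree = G.parse_gpr("(A or B) and (C or D)")
    identity = {g: frozenset({g}) for g in G.genes_of(tree)}
    res = G.rewrite(tree, identity)
    assert res.case_label == G.CASE_ONE_TO_ONE
    assert G.minimal_gene_sets(res.new_association) == G.minimal_gene_sets(tree)
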