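"""Compartmentalized metabolic network model and SBML round-trip I/O.

The central object is :class:`MetabolicModel`: reactions with signed
stoichiometry over compartmentalized metabolites, flux bounds in
mmol·gDW⁻¹·h⁻¹, optional boolean gene associations, and a biomass
objective.  SBML is written as Level 2 Version 4 with COBRA-style notes
(``GENE_ASSOCIATION`` strings and ``LOWER_BOUND``/``UPPER_BOUND`` kinetic
law parameters); both that dialect and fbc-v2 are accepted on read.

``census`` partitions the reactions into the five reporting categories
(transport with/without a gene association, exchange, enzymatic
with/without) and computes their shares of the total.
"""

from __future__ import annotations

import json
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import gpr as gprmod
from .gpr import GeneAssociation, GPRParseError

__all__ = [
    "Compartment",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelCensus",
    "ModelValidationError",
    "SBMLReadError",
    "read_sbml",
    "write_sbml",
    "census",
    "models_isomorphic",
    "ENZYMATIC",
    "TRANSPORT",
    "EXCHANGE",
]

ENZYMATIC = "enzymatic"
TRANSPORT = "transport"
EXCHANGE = "exchange"

DEFAULT_BOUND = 1000.0  # COBRA-convention default flux magnitude


class ModelValidationError(ValueError):
    pass


class SBMLReadError(ValueError):
    pass


@dataclass
class Compartment:
    id: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("compartment id must be non-empty")


@dataclass
class Metabolite:
    id: str
    compartment: str
    name: str = ""
    boundary: bool = False

    def species_key(self) -> str:
        """Compartment-independent identity used to recognise transports.

        The name wins when set; otherwise a trailing ``_<compartment>``
        suffix is stripped from the id.
        """
        if self.name:
            return self.name
        suffix = "_" + self.compartment
        if self.id.endswith(suffix):
            return self.id[: -len(suffix)]
        return self.id


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: Optional[GeneAssociation] = None
    category: Optional[str] = None  # enzymatic | transport | exchange, or inferred
    ec_code: Optional[str] = None

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id}: empty stoichiometry")

    @property
    def genes(self) -> frozenset[str]:
        return gprmod.genes_of(self.gpr) if self.gpr is not None else frozenset()

    def gpr_string(self) -> str:
        return gprmod.to_string(self.gpr) if self.gpr is not None else ""


@dataclass
class MetabolicModel:
    id: str
    compartments: dict[str, Compartment] = field(default_factory=dict)
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    biomass_reaction: Optional[str] = None
    name: str = ""
    diagnostics: list[str] = field(default_factory=list)

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        for met in self.metabolites.values():
            if met.compartment not in self.compartments:
                raise ModelValidationError(
                    f"metabolite {met.id} references unknown compartment "
                    f"{met.compartment}"
                )
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {rxn.id} references unknown metabolite {met_id}"
                    )
        if self.biomass_reaction is not None and (
            self.biomass_reaction not in self.reactions
        ):
            raise ModelValidationError(
                f"biomass reaction {self.biomass_reaction} not in model"
            )

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.genes
        return frozenset(out)

    # -- classification -----------------------------------------------------
    def classify(self, rxn: Reaction) -> str:
        """Reaction category; explicit annotation wins, else structural.

        Exchange: touches a boundary metabolite or has one-sided
        stoichiometry.  Transport: the same molecular species appears in
        two different compartments.  Otherwise enzymatic.
        """
        if rxn.category in (ENZYMATIC, TRANSPORT, EXCHANGE):
            return rxn.category
        mets = [self.metabolites[m] for m in rxn.stoichiometry]
        signs = {math.copysign(1, c) for c in rxn.stoichiometry.values() if c != 0}
        if any(m.boundary for m in mets) or len(signs) < 2:
            return EXCHANGE
        by_key: dict[str, set[str]] = {}
        for m in mets:
            by_key.setdefault(m.species_key(), set()).add(m.compartment)
        if any(len(comps) >= 2 for comps in by_key.values()):
            return TRANSPORT
        return ENZYMATIC

    def copy(self) -> "MetabolicModel":
        import copy as _copy

        return _copy.deepcopy(self)


# ---------------------------------------------------------------------------
# census

@dataclass
class ModelCensus:
    n_reactions: int
    n_metabolites: int
    n_genes: int
    n_compartments: int
    transport_with_gpr: int
    transport_without_gpr: int
    exchange: int
    enzymatic_with_gpr: int
    enzymatic_without_gpr: int

    _CATEGORIES = (
        "transport_with_gpr",
        "transport_without_gpr",
        "exchange",
        "enzymatic_with_gpr",
        "enzymatic_without_gpr",
    )

    def counts(self) -> dict[str, int]:
        return {c: getattr(self, c) for c in self._CATEGORIES}

    def percentages(self) -> dict[str, float]:
        """Category shares of total reactions, one decimal."""
        total = self.n_reactions
        if total == 0:
            return {c: 0.0 for c in self._CATEGORIES}
        return {
            c: round(getattr(self, c) / total * 100.0, 1) for c in self._CATEGORIES
        }

    def __post_init__(self) -> None:
        if sum(self.counts().values()) != self.n_reactions:
            raise ModelValidationError(
                "census category counts do not partition the reactions"
            )

    @classmethod
    def from_counts(
        cls,
        transport_with_gpr: int,
        transport_without_gpr: int,
        exchange: int,
        enzymatic_with_gpr: int,
        enzymatic_without_gpr: int,
        n_metabolites: int = 0,
        n_genes: int = 0,
        n_compartments: int = 0,
    ) -> "ModelCensus":
        total = (
            transport_with_gpr
            + transport_without_gpr
            + exchange
            + enzymatic_with_gpr
            + enzymatic_without_gpr
        )
        return cls(
            n_reactions=total,
            n_metabolites=n_metabolites,
            n_genes=n_genes,
            n_compartments=n_compartments,
            transport_with_gpr=transport_with_gpr,
            transport_without_gpr=transport_without_gpr,
            exchange=exchange,
            enzymatic_with_gpr=enzymatic_with_gpr,
            enzymatic_without_gpr=enzymatic_without_gpr,
        )

    # -- reports ------------------------------------------------------------
    @staticmethod
    def _format_pct(value: float) -> str:
        # human report prints whole percentages >= 5 without the trailing .0
        if value >= 5.0 and value == int(value):
            return f"{int(value)}%"
        return f"{value:.1f}%"

    def human_report(self) -> str:
        pct = self.percentages()
        lines = [
            f"reactions: {self.n_reactions}",
            f"metabolites: {self.n_metabolites}",
            f"genes: {self.n_genes}",
            f"compartments: {self.n_compartments}",
        ]
        for cat in self._CATEGORIES:
            lines.append(
                f"{cat.replace('_', ' ')}: {getattr(self, cat)} "
                f"({self._format_pct(pct[cat])})"
            )
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "n_reactions": self.n_reactions,
            "n_metabolites": self.n_metabolites,
            "n_genes": self.n_genes,
            "n_compartments": self.n_compartments,
            "counts": self.counts(),
            "percentages": self.percentages(),
        }
        return json.dumps(payload, indent=2)

    def to_tsv(self) -> str:
        pct = self.percentages()
        rows = ["category\tcount\tpercent"]
        for cat in self._CATEGORIES:
            rows.append(f"{cat}\t{getattr(self, cat)}\t{pct[cat]}")
        return "\n".join(rows) + "\n"


def census(model: MetabolicModel) -> ModelCensus:
    """Partition reactions by (category × has-gene-association)."""
    counts = dict.fromkeys(ModelCensus._CATEGORIES, 0)
    for rxn in model.reactions.values():
        cat = model.classify(rxn)
        if cat == EXCHANGE:
            counts["exchange"] += 1
        elif cat == TRANSPORT:
            key = "transport_with_gpr" if rxn.gpr is not None else "transport_without_gpr"
            counts[key] += 1
        else:
            key = "enzymatic_with_gpr" if rxn.gpr is not None else "enzymatic_without_gpr"
            counts[key] += 1
    return ModelCensus(
        n_reactions=len(model.reactions),
        n_metabolites=len(model.metabolites),
        n_genes=len(model.genes),
        n_compartments=len(model.compartments),
        **counts,
    )


# ---------------------------------------------------------------------------
# SBML I/O (Level 2 Version 4 with COBRA notes on write; + fbc-v2 on read)

_GA_NOTE_RE = re.compile(r"GENE[ _]ASSOCIATION:\s*([^<\n]*)", re.IGNORECASE)
_EC_NOTE_RE = re.compile(r"(?:EC Number|PROTEIN_CLASS):\s*([^<\n]*)", re.IGNORECASE)
_CATEGORY_NOTE_RE = re.compile(r"CATEGORY:\s*([^<\n]*)", re.IGNORECASE)


def _require_libsbml():
    import libsbml

    return libsbml


def write_sbml(model: MetabolicModel, path: str | Path) -> Path:
    """Serialize to SBML L2V4 with COBRA-style notes and bound parameters."""
    libsbml = _require_libsbml()
    model.validate()
    doc = libsbml.SBMLDocument(2, 4)
    sm = doc.createModel()
    sm.setId(model.id)
    if model.name:
        sm.setName(model.name)

    for comp in model.compartments.values():
        c = sm.createCompartment()
        c.setId(comp.id)
        if comp.name:
            c.setName(comp.name)
        c.setSize(1.0)

    for met in model.metabolites.values():
        s = sm.createSpecies()
        s.setId(met.id)
        if met.name:
            s.setName(met.name)
        s.setCompartment(met.compartment)
        s.setBoundaryCondition(bool(met.boundary))
        s.setInitialAmount(0.0)

    for rxn in model.reactions.values():
        r = sm.createReaction()
        r.setId(rxn.id)
        if rxn.name:
            r.setName(rxn.name)
        r.setReversible(rxn.lower_bound < 0)
        for met_id, coef in sorted(rxn.stoichiometry.items()):
            if coef < 0:
                ref = r.createReactant()
            elif coef > 0:
                ref = r.createProduct()
            else:
                continue
            ref.setSpecies(met_id)
            ref.setStoichiometry(abs(coef))
        notes = []
        if rxn.gpr is not None:
            notes.append(f"GENE_ASSOCIATION: {rxn.gpr_string()}")
        if rxn.ec_code:
            notes.append(f"EC Number: {rxn.ec_code}")
        if rxn.category:
            notes.append(f"CATEGORY: {rxn.category}")
        if notes:
            body = "".join(f"<p>{n}</p>" for n in notes)
            r.setNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'
            )
        kl = r.createKineticLaw()
        kl.setFormula("FLUX_VALUE")
        for pname, pval in (
            ("LOWER_BOUND", rxn.lower_bound),
            ("UPPER_BOUND", rxn.upper_bound),
            (
                "OBJECTIVE_COEFFICIENT",
                1.0 if rxn.id == model.biomass_reaction else 0.0,
            ),
        ):
            p = kl.createParameter()
            p.setId(pname)
            p.setValue(pval)

    path = Path(path)
    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")
    return path


def _parse_notes_gpr(
    notes: str, rxn_id: str, diagnostics: list[str]
) -> Optional[GeneAssociation]:
    m = _GA_NOTE_RE.search(notes)
    if not m:
        return None
    text = m.group(1).strip()
    if not text or text in {"-", "--", "N/A", "NA", "none", "None"}:
        return None
    try:
        return gprmod.parse_gpr(text)
    except GPRParseError as exc:
        msg = f"reaction {rxn_id}: unparseable GENE_ASSOCIATION {text!r}: {exc}"
        diagnostics.append(msg)
        warnings.warn(msg, stacklevel=2)
        return None


def _fbc_association_to_tree(assoc) -> Optional[GeneAssociation]:
    import libsbml

    if assoc is None:
        return None
    if isinstance(assoc, libsbml.GeneProductRef):
        return gprmod.Gene(assoc.getGeneProduct())
    children = [
        _fbc_association_to_tree(assoc.getAssociation(i))
        for i in range(assoc.getNumAssociations())
    ]
    children = [c for c in children if c is not None]
    if not children:
        return None
    if isinstance(assoc, libsbml.FbcAnd):
        return children[0] if len(children) == 1 else gprmod.And(tuple(children))
    return children[0] if len(children) == 1 else gprmod.Or(tuple(children))


def read_sbml(path: str | Path) -> MetabolicModel:
    """Parse an SBML file into a :class:`MetabolicModel`.

    Strict on structure (malformed XML raises :class:`SBMLReadError`
    naming the line) but lenient on GPR text: an unparseable gene
    association is recorded as a diagnostic and the reaction keeps no
    association rather than the whole model being rejected.
    """
    libsbml = _require_libsbml()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromFile(str(path))
    n_fatal = doc.getNumErrors(libsbml.LIBSBML_SEV_FATAL) + doc.getNumErrors(
        libsbml.LIBSBML_SEV_ERROR
    )
    if doc.getModel() is None or n_fatal:
        err = doc.getError(0)
        line = err.getLine() if err is not None else "?"
        msg = err.getMessage() if err is not None else "no model element"
        raise SBMLReadError(f"malformed SBML at line {line}: {msg}")
    sm = doc.getModel()

    model = MetabolicModel(id=sm.getId() or path.stem, name=sm.getName() or "")

    for i in range(sm.getNumCompartments()):
        c = sm.getCompartment(i)
        model.compartments[c.getId()] = Compartment(c.getId(), c.getName() or "")

    for i in range(sm.getNumSpecies()):
        s = sm.getSpecies(i)
        model.metabolites[s.getId()] = Metabolite(
            id=s.getId(),
            compartment=s.getCompartment(),
            name=s.getName() or "",
            boundary=bool(s.getBoundaryCondition()),
        )

    fbc_objective_reaction: Optional[str] = None
    mplug = sm.getPlugin("fbc")
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getObjective(mplug.getActiveObjectiveId()) or mplug.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            fbc_objective_reaction = obj.getFluxObjective(0).getReaction()

    note_objective_reaction: Optional[str] = None
    for i in range(sm.getNumReactions()):
        r = sm.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()

        lb = ub = None
        obj_coef = 0.0
        kl = r.getKineticLaw()
        if kl is not None:
            for j in range(kl.getNumParameters()):
                p = kl.getParameter(j)
                if p.getId() == "LOWER_BOUND":
                    lb = p.getValue()
                elif p.getId() == "UPPER_BOUND":
                    ub = p.getValue()
                elif p.getId() == "OBJECTIVE_COEFFICIENT":
                    obj_coef = p.getValue()

        rplug = r.getPlugin("fbc")
        if rplug is not None:
            for getter, setter in (
                (rplug.getLowerFluxBound, "lb"),
                (rplug.getUpperFluxBound, "ub"),
            ):
                pid = getter()
                if pid:
                    param = sm.getParameter(pid)
                    if param is not None:
                        if setter == "lb":
                            lb = param.getValue()
                        else:
                            ub = param.getValue()

        reversible = r.getReversible()
        if lb is None:
            lb = -DEFAULT_BOUND if reversible else 0.0
        if ub is None:
            ub = DEFAULT_BOUND

        notes = r.getNotesString() if r.isSetNotes() else ""
        assoc = _parse_notes_gpr(notes, r.getId(), model.diagnostics)
        if assoc is None and rplug is not None:
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None:
                assoc = _fbc_association_to_tree(gpa.getAssociation())

        category = None
        mcat = _CATEGORY_NOTE_RE.search(notes)
        if mcat and mcat.group(1).strip() in (ENZYMATIC, TRANSPORT, EXCHANGE):
            category = mcat.group(1).strip()
        ec = None
        mec = _EC_NOTE_RE.search(notes)
        if mec and mec.group(1).strip():
            ec = mec.group(1).strip()

        model.reactions[r.getId()] = Reaction(
            id=r.getId(),
            name=r.getName() or "",
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            gpr=assoc,
            category=category,
            ec_code=ec,
        )
        if obj_coef:
            note_objective_reaction = r.getId()

    model.biomass_reaction = fbc_objective_reaction or note_objective_reaction
    if model.biomass_reaction is None:
        for rid in model.reactions:
            if "biomass" in rid.lower():
                model.biomass_reaction = rid
                break
    model.validate()
    return model


# ---------------------------------------------------------------------------
# comparison

def models_isomorphic(a: MetabolicModel, b: MetabolicModel) -> bool:
    """Equality up to representation: ids, stoichiometry, bounds, and GPR
    truth tables (via canonical minimal gene sets) must all match."""
    if set(a.compartments) != set(b.compartments):
        return False
    if set(a.metabolites) != set(b.metabolites):
        return False
    if set(a.reactions) != set(b.reactions):
        return False
    for mid, ma in a.metabolites.items():
        mb = b.metabolites[mid]
        if (ma.compartment, ma.boundary) != (mb.compartment, mb.boundary):
            return False
    for rid, ra in a.reactions.items():
        rb = b.reactions[rid]
        if set(ra.stoichiometry) != set(rb.stoichiometry):
            return False
        for met, coef in ra.stoichiometry.items():
            if abs(coef - rb.stoichiometry[met]) > 1e-9:
                return False
        if (
            abs(ra.lower_bound - rb.lower_bound) > 1e-9
            or abs(ra.upper_bound - rb.upper_bound) > 1e-9
        ):
            return False
        ga = gprmod.minimal_gene_sets(ra.gpr) if ra.gpr is not None else None
        gb = gprmod.minimal_gene_sets(rb.gpr) if rb.gpr is not None else None
        if ga != gb:
            return False
    return a.biomass_reaction == b.biomass_reaction
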