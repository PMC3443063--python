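"""Scaffold→target model projection.

Given a curated scaffold model and a consensus homolog map, every
GPR-bearing scaffold reaction is either *conserved* (its rewritten gene
association retains at least one complete gene set in the target genome)
or *lost* (reported for manual review, never silently dropped).
Compartments, exchanges and spontaneous/non-enzymatic transports are
carried over verbatim, species-specific reactions can be inserted, and
the biomass DNA precursor coefficients are re-balanced for the target
genome's GC content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from . import gpr as gprmod
from .gpr import CASE_GAIN, CASE_LOSS, RewriteResult
from .model import (
    EXCHANGE,
    Metabolite,
    MetabolicModel,
    ModelValidationError,
    Reaction,
)
from .orthology import ConsensusHomologMap

__all__ = [
    "ProjectionOptions",
    "BiomassAdjustment",
    "ProjectionReport",
    "project",
    "add_species_specific",
    "adjust_biomass",
    "load_curation",
]

RULE_COMPLETE_SET = "any-complete-gene-set"
RULE_ANY_LEAF = "any-mapped-leaf"

#: default ids of the DNA precursor metabolite stems in biomass
DNA_PRECURSORS = ("dATP", "dCTP", "dGTP", "dTTP")


@dataclass
class BiomassAdjustment:
    """Target-genome parameters used to re-balance the DNA term of biomass.

    ``gc_content`` is the genomic G+C fraction; ``genome_length`` in base
    pairs; ``dna_mass_fraction`` (g·gDW⁻¹) replaces the scaffold's summed
    DNA precursor mass when given, otherwise that mass is conserved.
    """

    gc_content: float
    genome_length: int
    dna_mass_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie strictly between 0 and 1")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")


@dataclass
class ProjectionOptions:
    keep_spontaneous: bool = True
    keep_exchanges: bool = True
    conservation_rule: str = RULE_COMPLETE_SET
    biomass: Optional[BiomassAdjustment] = None

    def __post_init__(self) -> None:
        if self.conservation_rule not in (RULE_COMPLETE_SET, RULE_ANY_LEAF):
            raise ValueError(
                f"unknown conservation rule {self.conservation_rule!r}"
            )


@dataclass
class ProjectionReport:
    """Audit trail of a projection: what survived, what did not, and why."""

    conserved: dict[str, RewriteResult] = field(default_factory=dict)
    lost: list[str] = field(default_factory=list)
    gained: list[str] = field(default_factory=list)
    dropped_by_option: list[str] = field(default_factory=list)
    unresolved_genes: set[str] = field(default_factory=set)
    forced_retained: list[str] = field(default_factory=list)

    def case_labels(self) -> dict[str, str]:
        labels = {rid: res.case_label for rid, res in self.conserved.items()}
        labels.update({rid: CASE_LOSS for rid in self.lost})
        labels.update({rid: CASE_GAIN for rid in self.gained})
        return labels

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w") as fh:
            fh.write("reaction_id\tstatus\tcase\tnew_gpr\tunresolved_genes\n")
            for rid in sorted(self.conserved):
                res = self.conserved[rid]
                new = gprmod.to_string(res.new_association) if res.new_association else ""
                fh.write(
                    f"{rid}\tconserved\t{res.case_label}\t{new}\t"
                    f"{';'.join(sorted(res.unresolved_genes))}\n"
                )
            for rid in sorted(self.lost):
                fh.write(f"{rid}\tlost\t{CASE_LOSS}\t\t\n")
            for rid in sorted(self.gained):
                fh.write(f"{rid}\tgained\t{CASE_GAIN}\t\t\n")
            for rid in sorted(self.dropped_by_option):
                fh.write(f"{rid}\tdropped-by-option\t\t\t\n")
        return path

    def to_dict(self) -> dict:
        return {
            "conserved": {
                rid: {
                    "case": res.case_label,
                    "gpr": gprmod.to_string(res.new_association)
                    if res.new_association
                    else None,
                    "unresolved": sorted(res.unresolved_genes),
                }
                for rid, res in self.conserved.items()
            },
            "lost": sorted(self.lost),
            "gained": sorted(self.gained),
            "dropped_by_option": sorted(self.dropped_by_option),
            "unresolved_genes": sorted(self.unresolved_genes),
            "forced_retained": sorted(self.forced_retained),
        }


def load_curation(path: str | Path, sep: str = "\t") -> dict[str, str]:
    """Read a curation override table (reaction_id, Lost|Retained[, note])."""
    verdicts: dict[str, str] = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("reaction_id"):
                continue
            cols = line.split(sep)
            if len(cols) < 2 or cols[1].strip() not in ("Lost", "Retained"):
                raise ValueError(
                    f"{path}:{lineno}: expected (reaction_id, Lost|Retained), got {line!r}"
                )
            verdicts[cols[0].strip()] = cols[1].strip()
    return verdicts


def project(
    scaffold: MetabolicModel,
    homolog_map: ConsensusHomologMap | Mapping[str, frozenset[str]],
    opts: Optional[ProjectionOptions] = None,
    curation: Optional[Mapping[str, str]] = None,
    target_id: Optional[str] = None,
) -> tuple[MetabolicModel, ProjectionReport]:
    """Project the scaffold model onto the target genome.

    Every GPR-bearing reaction is rewritten through the homolog map and
    conserved when the rule is met (default: at least one minimal gene
    set fully mapped).  GPR-less reactions — spontaneous, transport,
    exchange — are copied verbatim under the corresponding options, as
    are all compartments.  Metabolites are restricted to those referenced
    by surviving reactions.  A curation table may force individual
    verdicts: ``Retained`` keeps a lost reaction without a gene
    association, ``Lost`` discards a conserved one.
    """
    opts = opts or ProjectionOptions()
    curation = dict(curation or {})
    scaffold.validate()
    if scaffold.biomass_reaction is None:
        raise ModelValidationError(
            "scaffold has no biomass reaction; cannot project a functional model"
        )

    target = MetabolicModel(
        id=target_id or f"{scaffold.id}_projected",
        name=scaffold.name,
    )
    target.compartments = {
        cid: type(c)(c.id, c.name) for cid, c in scaffold.compartments.items()
    }
    report = ProjectionReport()

    def keep(rxn: Reaction, new_gpr) -> None:
        target.reactions[rxn.id] = Reaction(
            id=rxn.id,
            name=rxn.name,
            stoichiometry=dict(rxn.stoichiometry),
            lower_bound=rxn.lower_bound,
            upper_bound=rxn.upper_bound,
            gpr=new_gpr,
            category=rxn.category,
            ec_code=rxn.ec_code,
        )

    for rid, rxn in scaffold.reactions.items():
        verdict = curation.get(rid)
        if rxn.gpr is None:
            cat = scaffold.classify(rxn)
            wanted = (
                opts.keep_exchanges
                if cat == EXCHANGE
                else opts.keep_spontaneous or rid == scaffold.biomass_reaction
            )
            if verdict == "Lost" or (not wanted and verdict != "Retained"):
                report.dropped_by_option.append(rid)
            else:
                keep(rxn, None)
            continue

        res = gprmod.rewrite(rxn.gpr, homolog_map)
        report.unresolved_genes |= res.unresolved_genes
        if opts.conservation_rule == RULE_COMPLETE_SET:
            conserved = res.new_association is not None
        else:  # any-mapped-leaf
            conserved = any(
                homolog_targets(homolog_map, g) for g in gprmod.genes_of(rxn.gpr)
            )
        if verdict == "Lost":
            conserved = False
        elif verdict == "Retained" and not conserved:
            # empirical evidence overrides orthology: keep without a GPR
            keep(rxn, None)
            report.forced_retained.append(rid)
            report.conserved[rid] = RewriteResult(None, res.case_label, res.unresolved_genes)
            continue
        if conserved:
            keep(rxn, res.new_association)
            report.conserved[rid] = res
        else:
            report.lost.append(rid)

    # metabolites referenced by surviving reactions (biomass included above)
    referenced = {m for r in target.reactions.values() for m in r.stoichiometry}
    target.metabolites = {
        mid: Metabolite(met.id, met.compartment, met.name, met.boundary)
        for mid, met in scaffold.metabolites.items()
        if mid in referenced
    }
    target.biomass_reaction = scaffold.biomass_reaction
    if opts.biomass is not None:
        target = adjust_biomass(target, opts.biomass)
    target.validate()
    return target, report


def homolog_targets(homolog_map, gene: str) -> frozenset[str]:
    if hasattr(homolog_map, "targets_of"):
        return homolog_map.targets_of(gene)
    return frozenset(homolog_map.get(gene, frozenset()))


def add_species_specific(
    model: MetabolicModel,
    reactions: Sequence[Reaction],
    metabolite_compartments: Optional[Mapping[str, str]] = None,
    report: Optional[ProjectionReport] = None,
) -> MetabolicModel:
    """Insert species-specific reactions (case M2 gains) into a model.

    New metabolites referenced by the inserted reactions are created in
    their declared compartment; a metabolite id ending in
    ``_<compartment>`` declares its own.  Duplicated reaction ids are an
    error.
    """
    metabolite_compartments = dict(metabolite_compartments or {})
    out = model.copy()
    for rxn in reactions:
        if rxn.id in out.reactions:
            raise ValueError(f"reaction id collision: {rxn.id!r} already in model")
        for met_id in rxn.stoichiometry:
            if met_id in out.metabolites:
                continue
            comp = metabolite_compartments.get(met_id)
            if comp is None:
                for cid in out.compartments:
                    if met_id.endswith("_" + cid):
                        comp = cid
                        break
            if comp is None or comp not in out.compartments:
                raise ModelValidationError(
                    f"cannot place new metabolite {met_id!r}: no declared compartment"
                )
            out.metabolites[met_id] = Metabolite(met_id, comp)
        out.reactions[rxn.id] = Reaction(
            id=rxn.id,
            name=rxn.name,
            stoichiometry=dict(rxn.stoichiometry),
            lower_bound=rxn.lower_bound,
            upper_bound=rxn.upper_bound,
            gpr=rxn.gpr,
            category=rxn.category,
            ec_code=rxn.ec_code,
        )
        if report is not None:
            report.gained.append(rxn.id)
    out.validate()
    return out


def adjust_biomass(
    model: MetabolicModel,
    adj: BiomassAdjustment,
    precursor_ids: Optional[Mapping[str, str]] = None,
    precursor_weights: Optional[Mapping[str, float]] = None,
) -> MetabolicModel:
    """Re-balance the DNA precursor coefficients of the biomass reaction.

    The four deoxynucleotides are consumed in GC-determined proportions —
    dGTP and dCTP each proportional to gc/2, dATP and dTTP to (1−gc)/2 —
    scaled so the summed precursor mass equals ``adj.dna_mass_fraction``,
    or the scaffold's original summed mass when absent.  All other
    biomass coefficients pass through unchanged.

    ``precursor_ids`` maps the stems dATP/dCTP/dGTP/dTTP to metabolite
    ids in the model (default: a biomass substrate whose id starts with
    the stem); ``precursor_weights`` gives molar masses in g·mmol⁻¹
    (default 1 for each, i.e. coefficients are treated as mass units).
    """
    out = model.copy()
    if out.biomass_reaction is None:
        raise ModelValidationError("model has no biomass reaction")
    biomass = out.reactions[out.biomass_reaction]

    ids: dict[str, str] = dict(precursor_ids or {})
    missing = []
    for stem in DNA_PRECURSORS:
        if stem in ids:
            if ids[stem] not in biomass.stoichiometry:
                missing.append(ids[stem])
            continue
        found = [
            m
            for m, coef in biomass.stoichiometry.items()
            if coef < 0 and m.lower().startswith(stem.lower())
        ]
        if not found:
            missing.append(stem)
        else:
            ids[stem] = sorted(found)[0]
    if missing:
        raise ModelValidationError(
            f"biomass reaction lacks DNA precursors: {sorted(missing)}"
        )

    weights = {s: float((precursor_weights or {}).get(s, 1.0)) for s in DNA_PRECURSORS}
    original_mass = sum(
        -biomass.stoichiometry[ids[s]] * weights[s] for s in DNA_PRECURSORS
    )
    total_mass = (
        adj.dna_mass_fraction if adj.dna_mass_fraction is not None else original_mass
    )
    fractions = {
        "dGTP": adj.gc_content / 2.0,
        "dCTP": adj.gc_content / 2.0,
        "dATP": (1.0 - adj.gc_content) / 2.0,
        "dTTP": (1.0 - adj.gc_content) / 2.0,
    }
    for stem in DNA_PRECURSORS:
        coef = total_mass * fractions[stem] / weights[stem]
        biomass.stoichiometry[ids[stem]] = -coef
    return out
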