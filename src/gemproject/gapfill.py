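"""Network gap detection and EC-based fix candidates.

Automatic projection can leave *gaps*: dead-end metabolites (only ever
produced or only ever consumed), reactions that can never carry flux
under the medium, and biomass precursors unreachable from the available
nutrients.  These gaps are detected (structurally and by flux
variability) and, from a table of EC-annotated target genes plus a table
of EC reaction templates, ranked candidate reactions are proposed; the
candidates feed manual curation rather than an automated network edit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

from .model import MetabolicModel, Reaction
from .simulate import MediaCondition, apply_media, build_lp, optimize_flux

__all__ = [
    "GapReport",
    "GapCandidate",
    "ReactionTemplate",
    "find_gaps",
    "suggest_candidates",
    "parse_equation",
    "load_annotations",
    "load_templates",
]

FVA_ZERO_TOL = 1e-9

NEVER_PRODUCED = "never-produced"
NEVER_CONSUMED = "never-consumed"


@dataclass
class GapReport:
    dead_end_metabolites: dict[str, str] = field(default_factory=dict)  # id -> role
    blocked_reactions: list[str] = field(default_factory=list)
    disconnected_biomass_precursors: list[str] = field(default_factory=list)
    infeasible: bool = False

    def is_empty(self) -> bool:
        return not (
            self.dead_end_metabolites
            or self.blocked_reactions
            or self.disconnected_biomass_precursors
        )

    def to_dict(self) -> dict:
        return {
            "dead_end_metabolites": dict(sorted(self.dead_end_metabolites.items())),
            "blocked_reactions": sorted(self.blocked_reactions),
            "disconnected_biomass_precursors": sorted(
                self.disconnected_biomass_precursors
            ),
            "infeasible": self.infeasible,
        }


def structural_dead_ends(model: MetabolicModel) -> dict[str, str]:
    """Metabolites with only producers or only consumers (boundary excluded).

    Reversibility counts: a reversible reaction both produces and
    consumes each of its participants.
    """
    produced: set[str] = set()
    consumed: set[str] = set()
    for rxn in model.reactions.values():
        for met, coef in rxn.stoichiometry.items():
            if coef < 0:
                if rxn.upper_bound > 0:
                    consumed.add(met)
                if rxn.lower_bound < 0:
                    produced.add(met)
            elif coef > 0:
                if rxn.upper_bound > 0:
                    produced.add(met)
                if rxn.lower_bound < 0:
                    consumed.add(met)
    out: dict[str, str] = {}
    for mid, met in model.metabolites.items():
        if met.boundary:
            continue
        is_p, is_c = mid in produced, mid in consumed
        if is_p and not is_c:
            out[mid] = NEVER_CONSUMED
        elif is_c and not is_p:
            out[mid] = NEVER_PRODUCED
    return out


def find_gaps(
    model: MetabolicModel,
    media: Optional[MediaCondition] = None,
    base_bounds: Optional[Mapping[str, tuple[float, float]]] = None,
) -> GapReport:
    """Detect dead ends, blocked reactions, and unreachable biomass precursors.

    Dead ends are structural; blocked reactions have zero flux range
    under the medium (flux variability, |flux|max < 1e-9); a biomass
    precursor is disconnected when its maximal production flux through a
    temporary demand is zero.  An infeasible LP is reported as
    all-blocked with the ``infeasible`` flag set.
    """
    constrained = apply_media(model, media, base_bounds) if media is not None else model
    report = GapReport(dead_end_metabolites=structural_dead_ends(model))

    lp = build_lp(constrained)
    _, _, rxn_ids = lp
    feasible = optimize_flux(constrained, {}, maximize=True, _lp=lp)
    if feasible.status != "optimal":
        report.infeasible = True
        report.blocked_reactions = sorted(rxn_ids)
        return report

    for rid in rxn_ids:
        vmax = optimize_flux(constrained, {rid: 1.0}, maximize=True, _lp=lp).objective
        if vmax > FVA_ZERO_TOL:
            continue
        vmin = optimize_flux(constrained, {rid: 1.0}, maximize=False, _lp=lp).objective
        if abs(vmin) <= FVA_ZERO_TOL:
            report.blocked_reactions.append(rid)
    report.blocked_reactions.sort()

    if constrained.biomass_reaction is not None:
        biomass = constrained.reactions[constrained.biomass_reaction]
        precursors = sorted(m for m, c in biomass.stoichiometry.items() if c < 0)
        for met in precursors:
            probe = constrained.copy()
            # temporary demand: maximise net production of the precursor
            probe.reactions[probe.biomass_reaction].lower_bound = 0.0
            probe.reactions[probe.biomass_reaction].upper_bound = 0.0
            probe.reactions["__demand__"] = Reaction(
                id="__demand__", stoichiometry={met: -1.0}, lower_bound=0.0,
                upper_bound=1e6, category="exchange",
            )
            sol = optimize_flux(probe, {"__demand__": 1.0}, maximize=True)
            if sol.status != "optimal" or sol.objective <= FVA_ZERO_TOL:
                report.disconnected_biomass_precursors.append(met)
    return report


# ---------------------------------------------------------------------------
# candidates

@dataclass
class ReactionTemplate:
    ec: str
    stoichiometry: Optional[dict[str, float]]  # None when unknown
    reversible: bool = False


@dataclass
class GapCandidate:
    """A proposed reaction addition, backed by EC-annotated target genes."""

    ec: str
    supporting_genes: tuple[str, ...]
    template: Optional[ReactionTemplate]
    closes: tuple[str, ...] = ()  # gap ids (metabolite or precursor ids)

    def to_dict(self) -> dict:
        return {
            "ec": self.ec,
            "supporting_genes": list(self.supporting_genes),
            "stoichiometry": self.template.stoichiometry if self.template else None,
            "closes": list(self.closes),
        }


def parse_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse ``2 A + B -> C`` / ``A <-> B`` into signed coefficients."""
    for arrow, reversible in (("<->", True), ("<=>", True), ("->", False), ("=>", False)):
        if arrow in text:
            left, right = text.split(arrow, 1)
            break
    else:
        raise ValueError(f"no reaction arrow in equation {text!r}")

    def side(chunk: str, sign: float, acc: dict[str, float]) -> None:
        for term in chunk.split("+"):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 2:
                coef, met = float(parts[0]), parts[1]
            else:
                coef, met = 1.0, parts[0]
            acc[met] = acc.get(met, 0.0) + sign * coef

    stoich: dict[str, float] = {}
    side(left, -1.0, stoich)
    side(right, +1.0, stoich)
    return stoich, reversible


def load_annotations(path: str | Path, sep: str = "\t") -> dict[str, set[str]]:
    """Gene→EC table (gene_id, EC); returns EC → supporting genes."""
    by_ec: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("gene_id"):
                continue
            cols = line.split(sep)
            if len(cols) < 2:
                raise ValueError(f"annotation row needs (gene_id, EC): {line!r}")
            by_ec.setdefault(cols[1].strip(), set()).add(cols[0].strip())
    return by_ec


def load_templates(path: str | Path, sep: str = "\t") -> dict[str, ReactionTemplate]:
    """EC→template table (EC, equation, reversible yes/no)."""
    out: dict[str, ReactionTemplate] = {}
    with Path(path).open() as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("EC"):
                continue
            cols = line.split(sep)
            ec = cols[0].strip()
            stoich, rev = (None, False)
            if len(cols) >= 2 and cols[1].strip():
                stoich, rev = parse_equation(cols[1].strip())
            if len(cols) >= 3:
                rev = cols[2].strip().lower() in ("yes", "true", "1", "reversible")
            out[ec] = ReactionTemplate(ec, stoich, rev)
    return out


def suggest_candidates(
    report: GapReport,
    annotations: Mapping[str, set[str]],
    templates: Mapping[str, ReactionTemplate],
    model: MetabolicModel,
) -> list[GapCandidate]:
    """Rank candidate reactions from ECs annotated in the target genome.

    Every EC present in the annotations but absent from the draft model
    yields one candidate; candidates whose template would close a listed
    gap (produce a never-produced metabolite or disconnected precursor,
    consume a never-consumed one) rank first, then candidates with a
    known stoichiometry, then ECs with no template.
    """
    draft_ecs = {r.ec_code for r in model.reactions.values() if r.ec_code}
    draft_genes = model.genes

    gaps_need_producer = {
        m for m, role in report.dead_end_metabolites.items() if role == NEVER_PRODUCED
    } | set(report.disconnected_biomass_precursors)
    gaps_need_consumer = {
        m for m, role in report.dead_end_metabolites.items() if role == NEVER_CONSUMED
    }

    candidates: list[GapCandidate] = []
    for ec in sorted(set(annotations) - draft_ecs):
        genes = tuple(sorted(set(annotations[ec]) - set(draft_genes)))
        if not genes:
            continue  # supporting genes must be absent from the draft's GPRs
        template = templates.get(ec)
        closes: list[str] = []
        if template is not None and template.stoichiometry:
            for met, coef in template.stoichiometry.items():
                if coef > 0 and met in gaps_need_producer:
                    closes.append(met)
                if coef < 0 and met in gaps_need_consumer:
                    closes.append(met)
                if template.reversible:
                    if coef < 0 and met in gaps_need_producer:
                        closes.append(met)
                    if coef > 0 and met in gaps_need_consumer:
                        closes.append(met)
        candidates.append(GapCandidate(ec, genes, template, tuple(sorted(set(closes)))))

    def rank_key(c: GapCandidate):
        return (
            0 if c.closes else 1,
            -len(c.closes),
            0 if (c.template and c.template.stoichiometry) else 1,
            c.ec,
        )

    return sorted(candidates, key=rank_key)
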