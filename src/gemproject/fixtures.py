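"""Deterministic synthetic fixtures for the projection pipeline.

The generator emits everything the pipeline consumes — a functional
scaffold model (SBML-serializable), per-method ortholog maps with
*planted* evolutionary events (ground truth returned for recovery
testing), media presets, and experiment tables with controlled numbers
of planted false positives/negatives — at toy scale and with no
biochemical pretension: fixtures are topological and logical, not
chemical.

Scaffold layout.  ``n_linear_pathways`` carbon sources each feed a
linear enzymatic chain of ``pathway_length`` steps converging on one
central carbon currency metabolite consumed by biomass, so any single
open carbon source supports growth and a knockout in pathway *i* is
lethal exactly on medium *i*.  Biomass additionally consumes the four
DNA precursors (synthesized from the nitrogen source) in GC-determined
proportions.  Chains are routed through extra compartments to create
transport reactions; dispensable secreted side-branches provide
reactions whose loss does not compromise growth (the only reactions on
which gene-loss events are planted, so the projected target stays
functional).  Gene ids follow ``SC_G####`` (scaffold) / ``TG_G####``
(target) to keep rewrite provenance legible in diffs.

Every stage draws from its own seeded random stream, so adding stages
never perturbs earlier outputs and identical specs yield byte-identical
artifacts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import gpr as gprmod
from .gpr import And, Gene, Or
from .model import MetabolicModel, Compartment, Metabolite, Reaction
from .orthology import OrthologMap
from .simulate import MediaCondition, MediaConfig, apply_media, fba, knockout
from .validate import ExperimentRecord

__all__ = [
    "FixtureSpec",
    "FixtureGroundTruth",
    "make_scaffold",
    "make_ortholog_maps",
    "make_media_config",
    "make_experiments",
]

# per-stage stream tags (seeded together with the user seed)
_STREAM_EVENTS = 1
_STREAM_NOISE = 2
_STREAM_EXPERIMENTS = 3

EVENT_CASE = {
    "loss": gprmod.CASE_LOSS,
    "one_to_one": gprmod.CASE_ONE_TO_ONE,
    "dup_in_scaffold": gprmod.CASE_DUP_IN_SCAFFOLD,
    "expansion_in_scaffold": gprmod.CASE_EXPANSION_IN_SCAFFOLD,
    "dup_in_target": gprmod.CASE_DUP_IN_TARGET,
    "expansion_in_target": gprmod.CASE_EXPANSION_IN_TARGET,
}

_DEFAULT_EVENT_MIX = {
    "loss": 0.08,
    "one_to_one": 0.42,
    "dup_in_scaffold": 0.10,
    "expansion_in_scaffold": 0.10,
    "dup_in_target": 0.15,
    "expansion_in_target": 0.15,
}

SCAFFOLD_GC = 0.38  # S. cerevisiae-like genomic G+C of the scaffold biomass
DNA_MASS = 0.2  # summed DNA precursor coefficient mass in biomass
CARBON_COEF = 5.0  # central carbon units per unit biomass


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study; same spec → byte-identical files."""

    seed: int = 1
    n_linear_pathways: int = 6
    pathway_length: int = 5
    n_compartments: int = 3
    event_mix: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_EVENT_MIX)
    )
    n_isozyme_reactions: int = 8
    n_complex_reactions: int = 6
    n_dispensable: int = 8
    max_family_size: int = 6
    n_methods: int = 3
    noise: float = 0.0
    n_experiments: int = 152
    fraction_observed: float = 98 / 152
    observed_growth_fraction: float = 55 / 98
    flip_false_positives: int = 16
    flip_false_negatives: int = 18

    def __post_init__(self) -> None:
        if self.n_linear_pathways < 1 or self.pathway_length < 2:
            raise ValueError(
                "need at least one pathway of length >= 2 to build a scaffold"
            )
        if self.n_compartments < 2:
            raise ValueError("need at least extracellular + cytosol compartments")
        if abs(sum(self.event_mix.values()) - 1.0) > 1e-9:
            raise ValueError("event_mix probabilities must sum to 1")
        if set(self.event_mix) - set(EVENT_CASE):
            raise ValueError(f"unknown events: {set(self.event_mix) - set(EVENT_CASE)}")
        n_chain = self.n_linear_pathways * self.pathway_length
        if self.n_isozyme_reactions + self.n_complex_reactions > n_chain:
            raise ValueError("more isozyme/complex reactions than chain steps")
        if not 0.0 <= self.fraction_observed <= 1.0:
            raise ValueError("fraction_observed must be a fraction")
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise must be a fraction")

    def n_observed(self) -> int:
        return round(self.n_experiments * self.fraction_observed)


@dataclass
class FixtureGroundTruth:
    """What was planted: the answer key for recovery tests."""

    reaction_cases: dict[str, str] = field(default_factory=dict)  # rid -> M1..M7
    reaction_events: dict[str, str] = field(default_factory=dict)
    gene_targets: dict[str, tuple[str, ...]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# scaffold

def make_scaffold(spec: FixtureSpec) -> MetabolicModel:
    """Build the functional scaffold model (growth > 0 on its reference
    medium); fully deterministic in the spec, no randomness needed."""
    m = MetabolicModel(id="fixture_scaffold")
    m.compartments["e"] = Compartment("e", "extracellular")
    m.compartments["c"] = Compartment("c", "cytosol")
    extra = [f"p{k}" for k in range(spec.n_compartments - 2)]
    for cid in extra:
        m.compartments[cid] = Compartment(cid, f"organelle {cid}")

    gene_counter = itertools.count(1)

    def new_gene() -> str:
        return f"SC_G{next(gene_counter):04d}"

    def met(stem: str, comp: str) -> str:
        mid = f"{stem}_{comp}"
        if mid not in m.metabolites:
            m.metabolites[mid] = Metabolite(mid, comp)
        return mid

    def add(rid: str, stoich: dict[str, float], lb: float, ub: float, gpr=None) -> None:
        m.reactions[rid] = Reaction(
            id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub, gpr=gpr
        )

    # GPR shape schedule for the enzymatic chain steps
    n_chain = spec.n_linear_pathways * spec.pathway_length
    shapes = []
    for k in range(n_chain):
        if k < spec.n_isozyme_reactions:
            shapes.append(("or", 2 + k % 2))  # isozyme pairs and triples
        elif k < spec.n_isozyme_reactions + spec.n_complex_reactions:
            shapes.append(("and", 2))
        else:
            shapes.append(("single", 1))

    def make_gpr(shape) -> gprmod.GeneAssociation:
        kind, k = shape
        genes = tuple(Gene(new_gene()) for _ in range(k))
        if kind == "or":
            return Or(genes)
        if kind == "and":
            return And(genes)
        return genes[0]

    step = 0
    mid_step = spec.pathway_length // 2
    for i in range(spec.n_linear_pathways):
        add(f"EX_carb{i}", {met(f"carb{i}", "e"): -1.0}, 0.0, 1000.0)
        t_gpr = Gene(new_gene()) if i % 2 == 1 else None  # odd: gene-associated
        add(
            f"T_carb{i}",
            {met(f"carb{i}", "e"): -1.0, met(f"carb{i}", "c"): 1.0},
            -1000.0,
            1000.0,
            gpr=t_gpr,
        )
        route_comp = extra[i % len(extra)] if extra else None
        prev = met(f"carb{i}", "c")
        for j in range(spec.pathway_length):
            last = j == spec.pathway_length - 1
            nxt = met("cmet", "c") if last else met(f"m{i}_{j + 1}", "c")
            if route_comp is not None and j == mid_step and not last:
                # detour through an organelle: transport the substrate in,
                # convert there, transport the product back out
                prev_p = met(f"m{i}_{j}", route_comp)
                out_p = met(f"m{i}_{j + 1}", route_comp)
                add(f"TIN_{i}", {prev: -1.0, prev_p: 1.0}, -1000.0, 1000.0)
                add(
                    f"R_{i}_{j}",
                    {prev_p: -1.0, out_p: 1.0},
                    0.0,
                    1000.0,
                    gpr=make_gpr(shapes[step]),
                )
                add(f"TOUT_{i}", {out_p: -1.0, nxt: 1.0}, -1000.0, 1000.0)
            else:
                add(
                    f"R_{i}_{j}",
                    {prev: -1.0, nxt: 1.0},
                    0.0,
                    1000.0,
                    gpr=make_gpr(shapes[step]),
                )
            step += 1
            prev = nxt

    # nitrogen source and DNA precursor synthesis
    add("EX_nh4", {met("nh4", "e"): -1.0}, 0.0, 1000.0)
    add("T_nh4", {met("nh4", "e"): -1.0, met("nh4", "c"): 1.0}, -1000.0, 1000.0)
    for stem in ("dATP", "dCTP", "dGTP", "dTTP"):
        add(
            f"R_DNA_{stem}",
            {met("nh4", "c"): -1.0, met(stem, "c"): 1.0},
            0.0,
            1000.0,
            gpr=Gene(new_gene()),
        )

    # dispensable secreted side branches: safe to lose in projection
    for k in range(spec.n_dispensable):
        src = met(f"m{k % spec.n_linear_pathways}_1", "c")
        w = met(f"w{k}", "c")
        side_gpr = (
            And((Gene(new_gene()), Gene(new_gene()))) if k % 2 == 0 else Gene(new_gene())
        )
        add(f"R_SIDE_{k}", {src: -1.0, w: 1.0}, 0.0, 1000.0, gpr=side_gpr)
        add(f"T_SIDE_{k}", {w: -1.0, met(f"w{k}", "e"): 1.0}, 0.0, 1000.0)
        add(f"EX_w{k}", {met(f"w{k}", "e"): -1.0}, 0.0, 1000.0)

    # biomass: central carbon + GC-proportioned DNA precursors
    gc = SCAFFOLD_GC
    add(
        "BIOMASS",
        {
            met("cmet", "c"): -CARBON_COEF,
            met("dGTP", "c"): -DNA_MASS * gc / 2,
            met("dCTP", "c"): -DNA_MASS * gc / 2,
            met("dATP", "c"): -DNA_MASS * (1 - gc) / 2,
            met("dTTP", "c"): -DNA_MASS * (1 - gc) / 2,
            met("biomass", "c"): 1.0,
        },
        0.0,
        1000.0,
    )
    add("EX_biomass", {met("biomass", "c"): -1.0}, 0.0, 1000.0)
    m.biomass_reaction = "BIOMASS"
    m.validate()
    return m


def make_media_config(spec: FixtureSpec) -> MediaConfig:
    """Base (nitrogen) nutrients plus one minimal medium per carbon source.

    ``MED0`` is the reference medium (glucose-like first carbon source);
    carbon uptake is capped at the conventional 10 mmol·gDW⁻¹·h⁻¹.
    """
    cfg = MediaConfig(base_bounds={"EX_nh4": (-1000.0, 1000.0)})
    for i in range(spec.n_linear_pathways):
        name = f"MED{i}"
        cfg.presets[name] = MediaCondition(
            name, {f"EX_carb{i}": (-10.0, 1000.0)}
        )
    return cfg


# ---------------------------------------------------------------------------
# ortholog maps with planted events

def _compatible_events(rxn: Reaction, spec: FixtureSpec) -> list[str]:
    tree = rxn.gpr
    events = ["one_to_one", "dup_in_target", "expansion_in_target"]
    if isinstance(tree, Or):
        if len(tree.children) == 2:
            events.append("dup_in_scaffold")
        else:
            events.append("expansion_in_scaffold")
    if rxn.id.startswith("R_SIDE_"):
        events.append("loss")
    return [e for e in events if spec.event_mix.get(e, 0.0) > 0.0]


def make_ortholog_maps(
    scaffold: MetabolicModel,
    spec: FixtureSpec,
    n_methods: Optional[int] = None,
) -> tuple[list[OrthologMap], FixtureGroundTruth]:
    """Plant one evolutionary event per GPR-bearing reaction and emit noisy
    per-method views of the resulting scaffold→target gene map.

    Gene-loss events are planted only on dispensable side-branch
    reactions so the projected model remains functional.  Multi-target
    families carry a shared paralog-group label in the map files.  With
    zero noise every method reports the ground truth exactly.
    """
    n_methods = n_methods if n_methods is not None else spec.n_methods
    rng = np.random.default_rng([spec.seed, _STREAM_EVENTS])
    noise_rng = np.random.default_rng([spec.seed, _STREAM_NOISE])
    truth = FixtureGroundTruth()
    tg_counter = itertools.count(1)

    def new_targets(k: int) -> tuple[str, ...]:
        return tuple(f"TG_G{next(tg_counter):04d}" for _ in range(k))

    gpr_rids = [r for r in sorted(scaffold.reactions) if scaffold.reactions[r].gpr]
    compat = {r: _compatible_events(scaffold.reactions[r], spec) for r in gpr_rids}

    # coverage-first: every event with positive probability is planted at
    # least once on some compatible reaction (recovery tests need each
    # case represented), the rest are drawn from the mix
    assigned: dict[str, str] = {}
    for event in sorted(spec.event_mix):
        if spec.event_mix[event] <= 0:
            continue
        hosts = [r for r in gpr_rids if r not in assigned and event in compat[r]]
        if hosts:
            assigned[hosts[int(rng.integers(len(hosts)))]] = event

    for rid in gpr_rids:
        rxn = scaffold.reactions[rid]
        if rid in assigned:
            event = assigned[rid]
        else:
            compatible = compat[rid]
            probs = np.array([spec.event_mix[e] for e in compatible])
            event = str(rng.choice(compatible, p=probs / probs.sum()))
        leaves = sorted(gprmod.genes_of(rxn.gpr))
        truth.reaction_events[rid] = event
        truth.reaction_cases[rid] = EVENT_CASE[event]

        if event == "loss":
            # an OR survives any single unmapped leaf, so lose them all;
            # an AND (or single leaf) is poisoned by its first
            lost = set(leaves if isinstance(rxn.gpr, Or) else leaves[:1])
            for g in leaves:
                truth.gene_targets[g] = () if g in lost else new_targets(1)
        elif event in ("dup_in_scaffold", "expansion_in_scaffold"):
            shared = new_targets(1)
            for g in leaves:
                truth.gene_targets[g] = shared
        elif event == "dup_in_target":
            truth.gene_targets[leaves[0]] = new_targets(2)
            for g in leaves[1:]:
                truth.gene_targets[g] = new_targets(1)
        elif event == "expansion_in_target":
            k = int(rng.integers(3, spec.max_family_size + 1))
            truth.gene_targets[leaves[0]] = new_targets(k)
            for g in leaves[1:]:
                truth.gene_targets[g] = new_targets(1)
        else:  # one_to_one
            for g in leaves:
                truth.gene_targets[g] = new_targets(1)

    maps: list[OrthologMap] = []
    for midx in range(n_methods):
        omap = OrthologMap(method_name=f"method{midx}")
        for sgene in sorted(truth.gene_targets):
            targets = truth.gene_targets[sgene]
            if not targets:
                continue
            if spec.noise > 0 and noise_rng.random() < spec.noise:
                if noise_rng.random() < 0.5:
                    continue  # this method misses the gene entirely
                # or proposes one spurious extra candidate
                spur = f"TG_SPUR_{midx}_{sgene}"
                omap.add(sgene, spur, None)
            label = f"FAM_{sgene}" if len(targets) > 1 else None
            for t in targets:
                omap.add(sgene, t, label)
        maps.append(omap)
    return maps, truth


# ---------------------------------------------------------------------------
# experiments

def make_experiments(
    target: MetabolicModel,
    spec: FixtureSpec,
    media_config: Optional[MediaConfig] = None,
) -> list[ExperimentRecord]:
    """Generate an experiment table with planted observation flips.

    Ground-truth growth for each candidate (medium, knockout) condition
    is computed by simulation on the uncorrupted target model; observed
    values start as the truth, then ``flip_false_positives`` growth
    observations are flipped to "no" and ``flip_false_negatives``
    no-growth observations to "yes", creating a known confusion-matrix
    shape when the same model is validated against the table.  Only
    ``fraction_observed`` of the rows carry observations; the rest are
    simulated but unscored.
    """
    media_config = media_config or make_media_config(spec)
    rng = np.random.default_rng([spec.seed, _STREAM_EXPERIMENTS])
    target.validate()

    media_names = sorted(media_config.presets)
    genes = sorted(target.genes)
    pool: list[tuple[str, frozenset[str]]] = []
    for name in media_names:
        pool.append((name, frozenset()))
    for name in media_names:
        for g in genes:
            pool.append((name, frozenset((g,))))
    for _ in range(4 * spec.n_experiments):
        name = media_names[int(rng.integers(len(media_names)))]
        pair = rng.choice(len(genes), size=2, replace=False)
        pool.append((name, frozenset(genes[int(i)] for i in pair)))
    order = rng.permutation(len(pool))

    n_obs = spec.n_observed()
    n_obs_growth = round(n_obs * spec.observed_growth_fraction)
    n_obs_nogrow = n_obs - n_obs_growth
    n_unobs = spec.n_experiments - n_obs
    if spec.flip_false_positives > n_obs_growth or spec.flip_false_negatives > n_obs_nogrow:
        raise ValueError("more planted flips than observations of that class")

    grown: list[tuple[str, frozenset[str], bool]] = []
    stalled: list[tuple[str, frozenset[str], bool]] = []
    unobserved: list[tuple[str, frozenset[str], bool]] = []
    for idx in order:
        name, kos = pool[int(idx)]
        constrained = apply_media(target, media_config.get(name), media_config.base_bounds)
        if kos:
            constrained = knockout(constrained, kos)
        sol = fba(constrained)
        grows = sol.status == "optimal" and sol.objective > 1e-6
        if grows and len(grown) < n_obs_growth:
            grown.append((name, kos, True))
        elif not grows and len(stalled) < n_obs_nogrow:
            stalled.append((name, kos, False))
        elif len(unobserved) < n_unobs:
            unobserved.append((name, kos, grows))
        if (
            len(grown) == n_obs_growth
            and len(stalled) == n_obs_nogrow
            and len(unobserved) == n_unobs
        ):
            break
    else:
        raise RuntimeError(
            "candidate pool exhausted before experiment quotas were met; "
            "increase pathways or reduce n_experiments"
        )

    flip_pos = set(rng.choice(len(grown), size=spec.flip_false_positives, replace=False))
    flip_neg = set(rng.choice(len(stalled), size=spec.flip_false_negatives, replace=False))

    records: list[ExperimentRecord] = []
    for i, (name, kos, truth_grows) in enumerate(grown):
        observed = not truth_grows if i in flip_pos else truth_grows
        records.append(
            ExperimentRecord(
                id="", media=name, deleted_genes=kos,
                observed_growth=observed, source="synthetic",
            )
        )
    for i, (name, kos, truth_grows) in enumerate(stalled):
        observed = not truth_grows if i in flip_neg else truth_grows
        records.append(
            ExperimentRecord(
                id="", media=name, deleted_genes=kos,
                observed_growth=observed, source="synthetic",
            )
        )
    for name, kos, _truth in unobserved:
        records.append(
            ExperimentRecord(
                id="", media=name, deleted_genes=kos,
                observed_growth=None, source="synthetic",
            )
        )

    final_order = rng.permutation(len(records))
    out = []
    for n, idx in enumerate(final_order, start=1):
        rec = records[int(idx)]
        rec.id = f"EXP{n:04d}"
        out.append(rec)
    return out
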