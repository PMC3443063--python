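"""Constraint-based growth simulation.

Flux balance analysis (FBA) maximizes the biomass flux v_biomass subject
to steady-state mass balance S·v = 0 and per-reaction flux bounds; the
optimum is the predicted growth rate (h⁻¹).  Media are encoded as bounds
on exchange reactions (uptake = negative flux): applying a medium first
closes every uptake, then opens the configurable non-carbon base
nutrients (ammonium, oxygen, ...), then applies the medium's own bounds.
Gene knockouts propagate through the GPR formulas: a reaction whose
association evaluates false with the deleted genes absent is constrained
to zero flux.  Quantitative growth rates and experimental OD curves are
both binarized so predictions and observations can be compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import lil_matrix

from . import gpr as gprmod
from .model import EXCHANGE, MetabolicModel

__all__ = [
    "MediaCondition",
    "MediaConfig",
    "FluxSolution",
    "load_media_config",
    "apply_media",
    "knockout",
    "fba",
    "binarize_growth",
    "binarize_experiment",
    "build_lp",
    "optimize_flux",
]

MASS_BALANCE_TOL = 1e-6
DEFAULT_GROWTH_THRESHOLD = 1e-6  # h^-1
DEFAULT_CARBON_UPTAKE = 10.0  # mmol gDW^-1 h^-1
DEFAULT_BASE_UPTAKE = 1000.0  # non-carbon nutrients are not limiting


@dataclass
class MediaCondition:
    """Named growth medium: bounds for specific exchange reactions."""

    name: str
    exchange_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ex, (lb, ub) in self.exchange_bounds.items():
            if lb > ub:
                raise ValueError(f"medium {self.name}: {ex} lower bound > upper bound")


@dataclass
class MediaConfig:
    """Base (non-carbon) nutrient exchanges plus named media presets."""

    base_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    presets: dict[str, MediaCondition] = field(default_factory=dict)

    def get(self, name: str) -> MediaCondition:
        if name not in self.presets:
            raise KeyError(f"unknown medium {name!r}")
        return self.presets[name]


def load_media_config(path: str | Path, sep: str = "\t") -> MediaConfig:
    """Read a media table: rows of (medium name, exchange id, lower, upper).

    Rows whose medium name is ``base`` define the non-carbon base
    nutrients shared by every condition.
    """
    cfg = MediaConfig()
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("medium"):
                continue
            cols = line.split(sep)
            if len(cols) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {line!r}")
            name, ex, lb, ub = cols[0].strip(), cols[1].strip(), float(cols[2]), float(cols[3])
            if name == "base":
                cfg.base_bounds[ex] = (lb, ub)
            else:
                cfg.presets.setdefault(name, MediaCondition(name)).exchange_bounds[ex] = (lb, ub)
    return cfg


def apply_media(
    model: MetabolicModel,
    media: MediaCondition,
    base_bounds: Optional[Mapping[str, tuple[float, float]]] = None,
) -> MetabolicModel:
    """Return a copy of the model constrained to the given medium.

    Order of application: close all exchange uptakes (lower bound 0),
    open base nutrients, then the medium's own exchange bounds last so a
    medium may override the base.
    """
    out = model.copy()
    for rxn in out.reactions.values():
        if out.classify(rxn) == EXCHANGE:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
    for source in (base_bounds or {}), media.exchange_bounds:
        for ex, (lb, ub) in source.items():
            if ex not in out.reactions:
                raise KeyError(f"medium {media.name}: unknown exchange reaction {ex!r}")
            out.reactions[ex].lower_bound = lb
            out.reactions[ex].upper_bound = ub
    return out


def knockout(model: MetabolicModel, deleted_genes: Iterable[str]) -> MetabolicModel:
    """Propagate gene deletions through the GPRs.

    Reactions whose association evaluates false with the deleted genes
    absent get zero bounds; reactions without an association are never
    touched.  Unknown gene ids are allowed (recorded as diagnostics).
    """
    deleted = set(deleted_genes)
    out = model.copy()
    unknown = deleted - set(model.genes)
    if unknown:
        out.diagnostics.append(f"knockout of unknown genes: {sorted(unknown)}")
    present = set(model.genes) - deleted
    for rxn in out.reactions.values():
        if rxn.gpr is not None and not gprmod.evaluate(rxn.gpr, present):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective: float
    fluxes: dict[str, float] = field(default_factory=dict)


def build_lp(model: MetabolicModel):
    """Assemble the steady-state LP data: (S, bounds, reaction index).

    Rows of S are non-boundary metabolites; boundary metabolites are
    unconstrained pools by definition and drop out of mass balance.
    """
    rxn_ids = sorted(model.reactions)
    met_ids = sorted(m for m, met in model.metabolites.items() if not met.boundary)
    met_index = {m: i for i, m in enumerate(met_ids)}
    S = lil_matrix((len(met_ids), len(rxn_ids)))
    bounds = []
    for j, rid in enumerate(rxn_ids):
        rxn = model.reactions[rid]
        for met, coef in rxn.stoichiometry.items():
            if met in met_index:
                S[met_index[met], j] = coef
        bounds.append((rxn.lower_bound, rxn.upper_bound))
    return S.tocsr(), bounds, rxn_ids


def optimize_flux(
    model: MetabolicModel,
    objective_coeffs: Mapping[str, float],
    maximize: bool = True,
    _lp=None,
) -> FluxSolution:
    """Solve max (or min) c·v subject to S·v = 0 and the flux bounds."""
    S, bounds, rxn_ids = _lp if _lp is not None else build_lp(model)
    c = np.zeros(len(rxn_ids))
    for rid, coef in objective_coeffs.items():
        if rid not in model.reactions:
            raise KeyError(f"objective reaction {rid!r} not in model")
        c[rxn_ids.index(rid)] = coef
    sign = -1.0 if maximize else 1.0
    res = linprog(
        sign * c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
    )
    if res.status == 0:
        fluxes = dict(zip(rxn_ids, res.x))
        residual = np.abs(S @ res.x)
        if residual.size and residual.max() > MASS_BALANCE_TOL:
            raise RuntimeError(
                f"solver returned a mass-imbalanced solution "
                f"(max residual {residual.max():.3g})"
            )
        return FluxSolution("optimal", float(c @ res.x), fluxes)
    if res.status == 3:
        return FluxSolution("unbounded", float("inf") if maximize else float("-inf"))
    return FluxSolution("infeasible", 0.0)


def fba(model: MetabolicModel, objective: Optional[str] = None) -> FluxSolution:
    """Flux balance analysis: maximize the objective (default biomass) flux."""
    objective = objective or model.biomass_reaction
    if objective is None:
        raise ValueError("no objective reaction: model has no biomass reaction")
    if objective not in model.reactions:
        raise KeyError(f"objective reaction {objective!r} not in model")
    return optimize_flux(model, {objective: 1.0}, maximize=True)


def binarize_growth(
    rate: float,
    threshold: float = DEFAULT_GROWTH_THRESHOLD,
    reference_rate: Optional[float] = None,
) -> bool:
    """Growth call from a simulated rate: true iff rate > threshold.

    With ``reference_rate`` the threshold is interpreted as a fraction of
    the wild-type rate on the reference medium; the inequality is strict,
    so a rate exactly at threshold is no-growth.
    """
    if rate < -1e-6:
        raise ValueError(f"negative growth rate {rate}")
    cut = threshold * reference_rate if reference_rate is not None else threshold
    return rate > cut


def binarize_experiment(
    od_curve: Sequence[float], cohort_curves: Sequence[Sequence[float]]
) -> bool:
    """Growth call from an OD time series.

    True iff the curve's mean OD exceeds one third of the mean OD across
    the whole cohort of curves measured together.
    """
    if not len(od_curve):
        raise ValueError("empty OD curve")
    if not cohort_curves or any(not len(c) for c in cohort_curves):
        raise ValueError("cohort must contain non-empty OD curves")
    pooled = np.concatenate([np.asarray(c, dtype=float) for c in cohort_curves])
    threshold = pooled.mean() / 3.0
    return bool(float(np.mean(od_curve)) > threshold)
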