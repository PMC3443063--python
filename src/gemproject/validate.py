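"""Growth-phenotype validation against experiment tables.

Each experiment names a medium, a (possibly empty) set of knocked-out
genes, and an observed growth call extracted from the literature.  Every
experiment is simulated (apply medium → propagate knockouts → FBA →
binarize) and the predictions are scored against the observations as a
confusion matrix, summarized by the geometric mean of sensitivity and
specificity — the standard figure of merit when growth and no-growth
classes are imbalanced.  Observed growth is the positive class: a false
positive is a predicted-growth / observed-no-growth pair (an
over-optimistic simulation), a false negative the converse (a reaction
or annotation missing from the model).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .model import MetabolicModel
from .simulate import (
    DEFAULT_GROWTH_THRESHOLD,
    MediaConfig,
    apply_media,
    binarize_growth,
    fba,
    knockout,
)

__all__ = [
    "ExperimentRecord",
    "ExperimentOutcome",
    "ConfusionMatrix",
    "load_experiments",
    "write_experiments",
    "run_experiments",
    "score",
    "report",
]


@dataclass
class ExperimentRecord:
    id: str
    media: str
    deleted_genes: frozenset[str] = field(default_factory=frozenset)
    observed_growth: Optional[bool] = None  # None: unpaired, simulated but unscored
    source: str = ""


@dataclass
class ExperimentOutcome:
    record: ExperimentRecord
    predicted: Optional[bool]
    growth_rate: Optional[float] = None
    error: Optional[str] = None

    @property
    def scored(self) -> bool:
        return self.error is None and self.record.observed_growth is not None


_BOOL = {"yes": True, "y": True, "true": True, "1": True,
         "no": False, "n": False, "false": False, "0": False}


def load_experiments(path: str | Path, sep: str = "\t") -> list[ExperimentRecord]:
    """Read an experiment table: id, media, KO genes (semicolon-separated),
    observed growth (yes/no, empty = unobserved), source citation."""
    out: list[ExperimentRecord] = []
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("id\t"):
                continue
            cols = (line.split(sep) + [""] * 5)[:5]
            exp_id, media, genes, observed, source = (c.strip() for c in cols)
            if not exp_id or not media:
                raise ValueError(f"{path}:{lineno}: id and media are required")
            obs = _BOOL.get(observed.lower()) if observed else None
            if observed and obs is None:
                raise ValueError(f"{path}:{lineno}: bad observed value {observed!r}")
            out.append(
                ExperimentRecord(
                    id=exp_id,
                    media=media,
                    deleted_genes=frozenset(g for g in genes.split(";") if g),
                    observed_growth=obs,
                    source=source,
                )
            )
    return out


def write_experiments(records: Sequence[ExperimentRecord], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("id\tmedia\tko_genes\tobserved_growth\tsource\n")
        for r in records:
            obs = "" if r.observed_growth is None else ("yes" if r.observed_growth else "no")
            fh.write(
                f"{r.id}\t{r.media}\t{';'.join(sorted(r.deleted_genes))}\t{obs}\t{r.source}\n"
            )
    return path


def run_experiments(
    model: MetabolicModel,
    experiments: Sequence[ExperimentRecord],
    media_config: MediaConfig,
    threshold: float = DEFAULT_GROWTH_THRESHOLD,
) -> list[ExperimentOutcome]:
    """Simulate every experiment: apply_media → knockout → FBA → binarize.

    Experiments whose medium cannot be resolved are marked errored and
    excluded from scoring rather than aborting the run; experiments
    without an observation are simulated but unscored.
    """
    outcomes: list[ExperimentOutcome] = []
    for rec in experiments:
        try:
            medium = media_config.get(rec.media)
            constrained = apply_media(model, medium, media_config.base_bounds)
            if rec.deleted_genes:
                constrained = knockout(constrained, rec.deleted_genes)
            sol = fba(constrained)
            rate = sol.objective if sol.status == "optimal" else 0.0
            outcomes.append(
                ExperimentOutcome(rec, binarize_growth(rate, threshold), rate)
            )
        except (KeyError, ValueError) as exc:
            outcomes.append(ExperimentOutcome(rec, None, None, error=str(exc)))
    return outcomes


@dataclass
class ConfusionMatrix:
    """Growth-prediction confusion counts with derived accuracy metrics.

    When one class is absent the corresponding rate is undefined; the
    geometric mean then falls back to the defined rate alone and the
    ``partial`` flag is set.
    """

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def exact_agreements(self) -> int:
        return self.tp + self.tn

    @property
    def sensitivity(self) -> Optional[float]:
        pos = self.tp + self.fn
        return self.tp / pos if pos else None

    @property
    def specificity(self) -> Optional[float]:
        neg = self.tn + self.fp
        return self.tn / neg if neg else None

    @property
    def partial(self) -> bool:
        return self.sensitivity is None or self.specificity is None

    @property
    def gmean_accuracy(self) -> float:
        se, sp = self.sensitivity, self.specificity
        if se is None and sp is None:
            raise ValueError("no scored pairs in either class")
        if se is None:
            return sp  # type: ignore[return-value]
        if sp is None:
            return se
        return math.sqrt(se * sp)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "total": self.total,
            "exact_agreements": self.exact_agreements,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "gmean_accuracy": self.gmean_accuracy,
            "partial": self.partial,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ConfusionMatrix":
        return cls(tp=d["tp"], tn=d["tn"], fp=d["fp"], fn=d["fn"])


def score(
    pairs: Iterable[tuple[bool, bool] | ExperimentOutcome],
) -> ConfusionMatrix:
    """Confusion matrix over (observed, predicted) pairs.

    Accepts raw boolean pairs or :class:`ExperimentOutcome` objects, in
    which case unscored outcomes (no observation, or errored) are
    dropped.  Order of pairs never matters.
    """
    tp = tn = fp = fn = 0
    n = 0
    for item in pairs:
        if isinstance(item, ExperimentOutcome):
            if not item.scored:
                continue
            observed, predicted = item.record.observed_growth, item.predicted
        else:
            observed, predicted = item
        if not isinstance(observed, bool) or not isinstance(predicted, bool):
            raise ValueError(f"non-boolean pair: {(observed, predicted)!r}")
        n += 1
        if observed and predicted:
            tp += 1
        elif observed and not predicted:
            fn += 1
        elif predicted:
            fp += 1
        else:
            tn += 1
    if n == 0:
        raise ValueError("cannot score an empty set of pairs")
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def report(
    cm: ConfusionMatrix,
    outcomes: Sequence[ExperimentOutcome],
    out_prefix: str | Path,
) -> tuple[Path, Path]:
    """Write the human-readable TSV verdicts and the machine JSON summary.

    The TSV lists one verdict per experiment (TP/TN/FP/FN/unscored);
    false positives and negatives are the cases worth taking back to
    gene annotation.  The JSON carries the full-precision metrics; the
    human summary prints accuracy to two decimals.
    """
    out_prefix = Path(out_prefix)
    tsv_path = out_prefix.with_suffix(".tsv")
    json_path = out_prefix.with_suffix(".json")

    def verdict(o: ExperimentOutcome) -> str:
        if not o.scored:
            return "error" if o.error else "unscored"
        obs, pred = o.record.observed_growth, o.predicted
        if obs and pred:
            return "TP"
        if obs:
            return "FN"
        return "FP" if pred else "TN"

    with tsv_path.open("w") as fh:
        fh.write("id\tmedia\tko_genes\tobserved\tpredicted\tgrowth_rate\tverdict\n")
        for o in outcomes:
            obs = "" if o.record.observed_growth is None else str(o.record.observed_growth)
            pred = "" if o.predicted is None else str(o.predicted)
            rate = "" if o.growth_rate is None else f"{o.growth_rate:.6g}"
            fh.write(
                f"{o.record.id}\t{o.record.media}\t"
                f"{';'.join(sorted(o.record.deleted_genes))}\t{obs}\t{pred}\t{rate}\t"
                f"{verdict(o)}\n"
            )
        fh.write(
            f"# total scored: {cm.total}; exact agreements: {cm.exact_agreements}; "
            f"gmean accuracy: {cm.gmean_accuracy:.2f}\n"
        )

    with json_path.open("w") as fh:
        json.dump(cm.to_dict(), fh, indent=2)
        fh.write("\n")
    return tsv_path, json_path
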