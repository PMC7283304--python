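"""Full-range threshold sweeps with voxel-wise ROC, Dice and Youden
evaluation against a reference infarct mask.

For every parametric map a grid of thresholds is applied; each threshold
produces a binary prediction (1 where the value exceeds — or, for
flow/volume parameters, falls below — the threshold), which is scored
voxel-wise against the reference mask inside the evaluable region.  Each
threshold contributes one (1-specificity, sensitivity) point of the ROC
curve; the area under the curve is the trapezoidal area after appending
the (0,0) and (1,1) corners.  "Optimal" thresholds maximise either the
Youden index (sensitivity + specificity - 1) or Dice's coefficient,
pooled over subjects or per subject.

The default grids cover the published full sweep ranges: Tmax 1–16 s in
0.5 s steps (31 binary maps), MTT 1–20 s / 0.5 s, CBF 1–90 / 1,
CBV 1–10 / 0.1, and the contralateral-relative variants in 0.05 steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "ThresholdGrid", "ConfusionCounts", "ROCResult", "OptimalThreshold",
    "AtsDefaultRule", "TABLE_GRIDS", "make_threshold_grid", "binarize",
    "confusion", "dice", "youden", "sweep_counts", "counts_to_scores",
    "roc_curve", "pooled_roc", "optimal_threshold",
    "pooled_optimal_threshold", "per_subject_distribution",
    "ats_default_prediction",
]

Direction = Literal["above", "below"]
Criterion = Literal["youden", "dice"]

#: Lesion direction per parameter: ischemic tissue has prolonged time
#: parameters (threshold from above) and reduced flow/volume (from below).
PARAMETER_DIRECTIONS: dict[str, Direction] = {
    "tmax": "above", "mtt": "above", "ttp": "above",
    "tmax_rel": "above", "mtt_rel": "above", "ttp_rel": "above",
    "cbf": "below", "cbv": "below", "cbf_rel": "below", "cbv_rel": "below",
}


class InvalidGridError(ValueError):
    """Raised for ill-formed threshold grids."""


@dataclass(frozen=True)
class ThresholdGrid:
    """Inclusive arithmetic threshold sequence for one parameter.

    Values are generated by integer step index (minimum + k·increment)
    with a half-increment endpoint tolerance, so the maximum is always
    included and the count is exactly floor((max-min)/inc) + 1 —
    immune to floating-point drift from repeated addition.
    """

    parameter: str
    minimum: float
    maximum: float
    increment: float
    direction: Direction

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETER_DIRECTIONS:
            raise InvalidGridError(
                f"unknown parameter {self.parameter!r}; valid: "
                + ", ".join(sorted(PARAMETER_DIRECTIONS))
            )
        if self.minimum >= self.maximum:
            raise InvalidGridError("grid needs minimum < maximum")
        if self.increment <= 0:
            raise InvalidGridError("grid increment must be positive")
        if self.direction not in ("above", "below"):
            raise InvalidGridError(f"bad direction {self.direction!r}")

    @property
    def values(self) -> np.ndarray:
        n = int(np.floor((self.maximum - self.minimum) / self.increment + 0.5)) + 1
        vals = self.minimum + self.increment * np.arange(n)
        return vals[vals <= self.maximum + 0.5 * self.increment]

    def __len__(self) -> int:
        return self.values.size


def make_threshold_grid(parameter: str, minimum: float, maximum: float,
                        increment: float, direction: Direction | None = None
                        ) -> ThresholdGrid:
    """Build a grid, defaulting the direction to the parameter's lesion side."""
    if direction is None:
        direction = PARAMETER_DIRECTIONS.get(parameter)
        if direction is None:
            raise InvalidGridError(
                f"unknown parameter {parameter!r}; valid: "
                + ", ".join(sorted(PARAMETER_DIRECTIONS))
            )
    return ThresholdGrid(parameter, minimum, maximum, increment, direction)


def _published_grids() -> dict[str, ThresholdGrid]:
    g = make_threshold_grid
    return {
        "cbv": g("cbv", 1.0, 10.0, 0.1),
        "mtt": g("mtt", 1.0, 20.0, 0.5),
        "cbf": g("cbf", 1.0, 90.0, 1.0),
        "tmax": g("tmax", 1.0, 16.0, 0.5),
        "cbv_rel": g("cbv_rel", 0.05, 3.5, 0.05),
        "mtt_rel": g("mtt_rel", 0.05, 3.0, 0.05),
        "cbf_rel": g("cbf_rel", 0.05, 3.0, 0.05),
        "tmax_rel": g("tmax_rel", 0.05, 4.0, 0.05),
        # TTP has no published sweep range; it shares Tmax's units and
        # physiological span, so the Tmax bounds are reused.
        "ttp": g("ttp", 1.0, 16.0, 0.5),
        "ttp_rel": g("ttp_rel", 0.05, 4.0, 0.05),
    }


#: The default full-sweep grids, keyed by parameter name.
TABLE_GRIDS: dict[str, ThresholdGrid] = _published_grids()


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel-wise confusion counts over the evaluable region."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass
class ROCResult:
    """One ROC curve: one point per grid threshold, plus its AUC."""

    parameter: str
    thresholds: np.ndarray
    fpr: np.ndarray          # 1 - specificity, per threshold
    tpr: np.ndarray          # sensitivity, per threshold
    auc: float


@dataclass(frozen=True)
class OptimalThreshold:
    criterion: Criterion
    threshold: float
    score: float


@dataclass(frozen=True)
class AtsDefaultRule:
    """Vendor factory thresholds for the arrival-time-sensitive maps:
    hypoperfusion where relative MTT > 150%, core additionally CBV < 2
    ml/100 g."""

    mtt_rel_cutoff: float = 1.5
    cbv_cutoff: float = 2.0   # ml/100 g


def binarize(volume: np.ndarray, threshold: float, direction: Direction,
             eval_mask: np.ndarray) -> np.ndarray:
    """Binary prediction map: 1 where the value crosses the threshold.

    ``direction='above'`` marks values strictly exceeding the threshold
    (the published rule for Tmax); ``'below'`` marks values strictly
    under it.  Voxels outside the evaluable region are 0.
    """
    if direction == "above":
        pred = volume > threshold
    elif direction == "below":
        pred = volume < threshold
    else:
        raise InvalidGridError(f"bad direction {direction!r}")
    return pred & eval_mask.astype(bool)


def confusion(pred: np.ndarray, ref: np.ndarray,
              eval_mask: np.ndarray) -> ConfusionCounts:
    """Confusion counts restricted to the evaluable region."""
    if pred.shape != ref.shape or pred.shape != eval_mask.shape:
        raise ValueError("shape mismatch between prediction, reference, mask")
    m = eval_mask.astype(bool)
    p = pred.astype(bool)[m]
    r = ref.astype(bool)[m]
    tp = int(np.count_nonzero(p & r))
    fp = int(np.count_nonzero(p & ~r))
    fn = int(np.count_nonzero(~p & r))
    tn = int(m.sum() - tp - fp - fn)
    return ConfusionCounts(tp, fp, tn, fn)


def dice(pred: np.ndarray, ref: np.ndarray, eval_mask: np.ndarray) -> float:
    """Dice overlap 2|P∩R| / (|P|+|R|) over the evaluable region.

    NaN when both sets are empty (the 0/0 limit is undefined; callers
    exclude such cases rather than scoring them).
    """
    m = eval_mask.astype(bool)
    p = pred.astype(bool)[m]
    r = ref.astype(bool)[m]
    denom = int(p.sum()) + int(r.sum())
    if denom == 0:
        return float("nan")
    return 2.0 * int(np.count_nonzero(p & r)) / denom


def youden(counts: ConfusionCounts) -> float:
    """Youden index: sensitivity + specificity - 1 (NaN if undefined)."""
    return counts.sensitivity + counts.specificity - 1.0


# ---------------------------------------------------------------------------
# Vectorised sweeps


def sweep_counts(volume: np.ndarray, grid: ThresholdGrid, ref: np.ndarray,
                 eval_mask: np.ndarray) -> dict[str, np.ndarray]:
    """tp/fp/tn/fn for every grid threshold at once.

    Sorting the lesion and background values once and counting threshold
    crossings by binary search is equivalent to binarising per threshold
    but O((V + T) log V) instead of O(V·T).
    """
    m = eval_mask.astype(bool)
    vals = np.asarray(volume)[m]
    labels = np.asarray(ref).astype(bool)[m]
    pos = np.sort(vals[labels])
    neg = np.sort(vals[~labels])
    thr = grid.values
    if grid.direction == "above":
        tp = pos.size - np.searchsorted(pos, thr, side="right")
        fp = neg.size - np.searchsorted(neg, thr, side="right")
    else:
        tp = np.searchsorted(pos, thr, side="left")
        fp = np.searchsorted(neg, thr, side="left")
    fn = pos.size - tp
    tn = neg.size - fp
    return {
        "threshold": thr,
        "tp": tp.astype(np.int64), "fp": fp.astype(np.int64),
        "tn": tn.astype(np.int64), "fn": fn.astype(np.int64),
    }


def counts_to_scores(counts: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Sensitivity, specificity, Dice and Youden per threshold."""
    tp, fp = counts["tp"].astype(float), counts["fp"].astype(float)
    tn, fn = counts["tn"].astype(float), counts["fn"].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        sens = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        spec = np.where(tn + fp > 0, tn / (tn + fp), np.nan)
        denom = 2 * tp + fp + fn
        dice_v = np.where(denom > 0, 2 * tp / np.where(denom > 0, denom, 1), np.nan)
    return {**counts, "sensitivity": sens, "specificity": spec,
            "dice": dice_v, "youden": sens + spec - 1.0}


def _auc_from_points(fpr: np.ndarray, tpr: np.ndarray) -> float:
    """Trapezoidal AUC over points sorted by FPR, corners appended."""
    ok = np.isfinite(fpr) & np.isfinite(tpr)
    x = np.concatenate([[0.0], fpr[ok], [1.0]])
    y = np.concatenate([[0.0], tpr[ok], [1.0]])
    order = np.lexsort((y, x))
    return float(np.trapezoid(y[order], x[order]))


def _roc_from_counts(parameter: str, counts: dict[str, np.ndarray]) -> ROCResult:
    scores = counts_to_scores(counts)
    fpr = 1.0 - scores["specificity"]
    tpr = scores["sensitivity"]
    if np.all((counts["tp"] + counts["fp"]) == 0):
        warnings.warn(
            f"{parameter}: every threshold produced an empty prediction; "
            "ROC is degenerate", stacklevel=3,
        )
    return ROCResult(parameter, counts["threshold"], fpr, tpr,
                     _auc_from_points(fpr, tpr))


def roc_curve(volume: np.ndarray, grid: ThresholdGrid, ref: np.ndarray,
              eval_mask: np.ndarray) -> ROCResult:
    """Single-subject ROC over the threshold grid."""
    return _roc_from_counts(grid.parameter,
                            sweep_counts(volume, grid, ref, eval_mask))


def _pool(subjects: Iterable[tuple[np.ndarray, np.ndarray, np.ndarray]],
          grid: ThresholdGrid) -> dict[str, np.ndarray]:
    """Sum confusion counts across subjects before computing rates."""
    total: dict[str, np.ndarray] | None = None
    for volume, ref, eval_mask in subjects:
        c = sweep_counts(volume, grid, ref, eval_mask)
        if total is None:
            total = c
        else:
            for k in ("tp", "fp", "tn", "fn"):
                total[k] = total[k] + c[k]
    if total is None:
        raise ValueError("no subjects supplied")
    return total


def pooled_roc(subjects: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]],
               grid: ThresholdGrid) -> ROCResult:
    """ROC on voxel counts pooled over subjects (one point per threshold)."""
    return _roc_from_counts(grid.parameter, _pool(subjects, grid))


def _best_index(scores: dict[str, np.ndarray], criterion: Criterion,
                direction: Direction) -> int:
    crit = scores[criterion]
    if np.all(~np.isfinite(crit)):
        raise ValueError(f"criterion {criterion!r} undefined at every threshold")
    best = np.nanmax(crit)
    ties = np.flatnonzero(crit == best)
    # Among ties take the most specific prediction: the threshold closest
    # to the lesion-side values (largest for 'above', smallest for 'below').
    return int(ties[-1] if direction == "above" else ties[0])


def optimal_threshold(volume: np.ndarray, grid: ThresholdGrid, ref: np.ndarray,
                      eval_mask: np.ndarray,
                      criterion: Criterion) -> OptimalThreshold:
    """Grid threshold maximising Youden or Dice for one subject."""
    scores = counts_to_scores(sweep_counts(volume, grid, ref, eval_mask))
    i = _best_index(scores, criterion, grid.direction)
    return OptimalThreshold(criterion, float(scores["threshold"][i]),
                            float(scores[criterion][i]))


def pooled_optimal_threshold(
    subjects: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]],
    grid: ThresholdGrid, criterion: Criterion,
) -> OptimalThreshold:
    """Criterion optimum on counts pooled over subjects."""
    scores = counts_to_scores(_pool(subjects, grid))
    i = _best_index(scores, criterion, grid.direction)
    return OptimalThreshold(criterion, float(scores["threshold"][i]),
                            float(scores[criterion][i]))


def per_subject_distribution(
    subjects: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]],
    grid: ThresholdGrid, criterion: Criterion,
) -> list[OptimalThreshold]:
    """One criterion optimum per subject (the optimal-threshold spread).

    Subjects whose reference mask does not intersect the evaluable region
    have no defined sensitivity and are excluded with a warning.
    """
    if len(subjects) < 1:
        raise ValueError("need at least one subject")
    out = []
    for i, (volume, ref, eval_mask) in enumerate(subjects):
        if not np.count_nonzero(np.asarray(ref).astype(bool)
                                & eval_mask.astype(bool)):
            warnings.warn(f"subject index {i}: reference mask empty inside "
                          "the evaluable region; excluded", stacklevel=2)
            continue
        out.append(optimal_threshold(volume, grid, ref, eval_mask, criterion))
    return out


def ats_default_prediction(map_set, rule: AtsDefaultRule | None = None,
                           target: str = "hypoperfused") -> np.ndarray:
    """Apply the vendor factory rule to an ATS map set.

    hypoperfused = {relative MTT > 1.5}; core = hypoperfused ∧
    {CBV < 2 ml/100 g}; penumbra = hypoperfused ∖ core.  Group-A subjects
    are evaluated against the hypoperfused prediction, group-B subjects
    against the core prediction.
    """
    rule = rule or AtsDefaultRule()
    try:
        mtt_rel = map_set["mtt_rel"]
    except KeyError as e:
        raise ValueError("ATS default rule needs relative maps") from e
    valid = map_set.validity("mtt_rel")
    with np.errstate(invalid="ignore"):
        hypo = (mtt_rel > rule.mtt_rel_cutoff) & valid
        core = hypo & (map_set["cbv"] < rule.cbv_cutoff)
    if target == "hypoperfused":
        return hypo
    if target == "core":
        return core
    if target == "penumbra":
        return hypo & ~core
    raise ValueError(f"unknown target {target!r}")
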