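"""Volume-level cohort statistics.

Predicted lesion volumes (voxel count × voxel volume) are correlated with
the reference final-infarct volume using Pearson's r, per group and per
(algorithm, parameter, threshold) configuration.  Group characteristics
are compared with two-sided Wilcoxon rank-sum tests — exact enumeration
of the rank-sum distribution for small samples, a tie-corrected normal
approximation otherwise.  Competing dependent correlations (two
predictors against the same reference, on the same subjects) are compared
with a Steiger-type z test.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "mask_volume", "correlate_volumes", "compare_groups",
    "wilcoxon_rank_sum", "steiger_z", "build_report",
]

SIGNIFICANCE_LEVEL = 0.05
EXACT_ENUMERATION_MAX_N = 20


def mask_volume(mask: np.ndarray, voxel_size: tuple[float, float, float]) -> float:
    """Volume of a binary mask in ml (voxel sizes in mm)."""
    voxel_mm3 = float(np.prod(voxel_size))
    return float(np.count_nonzero(mask)) * voxel_mm3 / 1000.0


def correlate_volumes(predicted: np.ndarray, reference: np.ndarray) -> float:
    """Sample Pearson correlation between predicted and reference volumes.

    NaN (flagged undefined) when either vector has zero variance.
    Requires at least 3 subjects.
    """
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.shape != reference.shape or predicted.size < 3:
        raise ValueError("need >= 3 paired volumes")
    if np.std(predicted) == 0 or np.std(reference) == 0:
        return float("nan")
    return float(np.corrcoef(predicted, reference)[0, 1])


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact: for combined n <= 20 the rank-sum null distribution is
    enumerated over all group assignments (ties handled through midranks),
    and p = min(1, 2·min(lower tail, upper tail)).  Larger samples use
    the tie-corrected normal approximation.  All values tied across both
    groups gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    n = pooled.size
    if n <= EXACT_ENUMERATION_MAX_N:
        ranks = stats.rankdata(pooled)
        w_obs = ranks[: x.size].sum()
        sums = np.fromiter(
            (ranks[list(idx)].sum() for idx in combinations(range(n), x.size)),
            dtype=float, count=comb(n, x.size),
        )
        tol = 1e-9
        lower = np.count_nonzero(sums <= w_obs + tol) / sums.size
        upper = np.count_nonzero(sums >= w_obs - tol) / sums.size
        return min(1.0, 2.0 * min(lower, upper))
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def compare_groups(records: pd.DataFrame, characteristic: str,
                   group_col: str = "group") -> dict:
    """Wilcoxon rank-sum comparison of one characteristic between groups A/B."""
    a = records.loc[records[group_col] == "A", characteristic].to_numpy(float)
    b = records.loc[records[group_col] == "B", characteristic].to_numpy(float)
    p = wilcoxon_rank_sum(a, b)
    return {
        "characteristic": characteristic,
        "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)) if a.size > 1 else 0.0,
        "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1)) if b.size > 1 else 0.0,
        "p_value": p,
        "significant": bool(p < SIGNIFICANCE_LEVEL),
    }


def steiger_z(r12: float, r13: float, r23: float, n: int) -> tuple[float, float]:
    """Two-sided test comparing dependent overlapping correlations.

    Tests r12 == r13 where variable 1 (the reference volume) is shared by
    both predictors (2, 3), which are themselves correlated r23 on the
    same n subjects.  Returns (z, p).  Uses Fisher z-transforms with
    Steiger's (1980) covariance for overlapping correlations.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    for r in (r12, r13, r23):
        if not -1.0 < r < 1.0:
            raise ValueError("correlations must be in (-1, 1)")
    z12 = np.arctanh(r12)
    z13 = np.arctanh(r13)
    rbar = (r12 + r13) / 2.0
    psi = (
        r23 * (1.0 - 2.0 * rbar**2)
        - 0.5 * rbar**2 * (1.0 - 2.0 * rbar**2 - r23**2)
    )
    cov = psi / ((1.0 - rbar**2) ** 2)
    z = (z12 - z13) * np.sqrt((n - 3.0) / (2.0 * (1.0 - cov)))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def build_report(
    subject_table: pd.DataFrame,
    auc_table: pd.DataFrame,
    optima_table: pd.DataFrame,
    correlation_table: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Assemble the cohort summary tables.

    * ``subjects`` — one row per subject with group, reference and
      predicted volumes (missing predictions stay as NaN markers);
    * ``group_characteristics`` — per-group means/SDs and Wilcoxon p for
      each numeric subject characteristic;
    * ``auc`` — pooled AUC per (group, algorithm, parameter);
    * ``optimal_thresholds`` and ``correlations`` — passed through sorted,
      so reruns with identical inputs serialise byte-identically.
    """
    if subject_table.empty:
        raise ValueError("empty cohort: no subjects to report")
    characteristics = [
        c for c in subject_table.columns
        if c not in ("subject_id", "group")
        and pd.api.types.is_numeric_dtype(subject_table[c])
    ]
    rows = []
    for c in characteristics:
        sub = subject_table.dropna(subset=[c])
        if (sub["group"] == "A").any() and (sub["group"] == "B").any():
            rows.append(compare_groups(sub, c))
    group_chars = pd.DataFrame(rows)
    report = {
        "subjects": subject_table.sort_values("subject_id").reset_index(drop=True),
        "group_characteristics": group_chars,
        "auc": auc_table.sort_values(list(auc_table.columns[:3])).reset_index(drop=True),
        "optimal_thresholds": optima_table.reset_index(drop=True),
        "correlations": correlation_table.reset_index(drop=True),
    }
    return report
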