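"""Interobserver variability of malignancy-potential scores.

For each case and modality the spread of the r reader scores is summarised
by the sample standard deviation (divisor r - 1, score units on the 0-100
scale); per-case SDs are averaged over all cases and per truth class, and
the two reading modalities are compared case-pairwise.  Class-conditional
mean scores with a paired modality comparison are also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rating_data import RatingSet

__all__ = [
    "PairedComparison",
    "per_case_sd",
    "compare_modalities_sd",
    "mean_score_by_class",
    "variability_tables",
]

_SUBSETS = ("all", "benign", "malignant")


@dataclass(frozen=True)
class PairedComparison:
    """Paired two-modality contrast: mean difference, 95% CI, p-value."""

    mean_first: float
    mean_second: float
    difference: float  # first - second
    ci: tuple[float, float]
    p: float
    test: str
    degenerate: bool = False  # True when the difference had zero variance


def _case_mask(rs: RatingSet, subset: str) -> np.ndarray:
    if subset == "all":
        return np.ones(rs.n_cases, dtype=bool)
    if subset == "benign":
        return rs.truth == 0
    if subset == "malignant":
        return rs.truth == 1
    raise ValueError(f"subset must be one of {_SUBSETS}, got {subset!r}")


def _paired_test(x: np.ndarray, y: np.ndarray, test: str, alpha: float = 0.05,
                 label: str = "paired t") -> PairedComparison:
    d = x - y
    n = d.size
    mean_d = float(d.mean())
    if np.allclose(d.std(ddof=1) if n > 1 else 0.0, 0.0):
        return PairedComparison(float(x.mean()), float(y.mean()), mean_d,
                                (mean_d, mean_d), 1.0, label, degenerate=True)
    se = d.std(ddof=1) / np.sqrt(n)
    tq = stats.t.ppf(1 - alpha / 2, n - 1)
    ci = (mean_d - tq * se, mean_d + tq * se)
    if test == "t":
        _, p = stats.ttest_rel(x, y)
    elif test == "wilcoxon":
        _, p = stats.wilcoxon(x, y)
    else:
        raise ValueError(f"unknown test {test!r}")
    return PairedComparison(float(x.mean()), float(y.mean()), mean_d,
                            (float(ci[0]), float(ci[1])), float(p), label)


def per_case_sd(rs: RatingSet, modality: str) -> np.ndarray:
    """Sample SD (divisor r - 1) of the r reader scores for each case."""
    if rs.n_readers < 2:
        raise ValueError("per-case SD requires at least 2 readers")
    i = rs.modalities.index(modality)
    return rs.scores[i].std(axis=0, ddof=1)


def compare_modalities_sd(
    rs: RatingSet, subset: str = "all", test: str = "t"
) -> PairedComparison:
    """Paired comparison of per-case reader SDs between the two modalities.

    Difference is first modality minus second (the study convention:
    without CAD minus with CAD, positive = variability reduced).  ``test``
    is ``"t"`` (paired t over cases, default) or ``"wilcoxon"``
    (signed-rank).
    """
    if rs.n_modalities != 2:
        raise ValueError("modality SD comparison requires exactly 2 modalities")
    mask = _case_mask(rs, subset)
    sd1 = per_case_sd(rs, rs.modalities[0])[mask]
    sd2 = per_case_sd(rs, rs.modalities[1])[mask]
    label = "paired t over cases" if test == "t" else "Wilcoxon signed-rank"
    return _paired_test(sd1, sd2, test, label=label)


def mean_score_by_class(
    rs: RatingSet, test: str = "t"
) -> dict[str, dict[str, float | PairedComparison]]:
    """Mean score per (truth class, modality) plus paired modality contrast.

    The paired test operates on per-case reader-mean scores within each
    class.  Returns ``{class: {modality: mean, ..., 'comparison': ...}}``.
    """
    if rs.n_modalities != 2:
        raise ValueError("class-mean comparison requires exactly 2 modalities")
    out: dict[str, dict] = {}
    for subset in ("benign", "malignant"):
        mask = _case_mask(rs, subset)
        case_means = rs.scores[:, :, mask].mean(axis=1)  # (t, n_subset)
        entry: dict[str, float | PairedComparison] = {
            m: float(case_means[i].mean()) for i, m in enumerate(rs.modalities)
        }
        entry["comparison"] = _paired_test(
            case_means[0], case_means[1], test,
            label="paired t over cases" if test == "t" else "Wilcoxon signed-rank",
        )
        out[subset] = entry
    return out


def variability_tables(rs: RatingSet, test: str = "t") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summary tables of SD-of-scores and class-mean-score comparisons.

    Returns ``(sd_table, mean_table)``: the first has one row per case
    subset (all / benign / malignant) with the average per-case SD under
    each modality, their paired difference, CI and p; the second has one
    row per truth class with mean scores and the paired comparison.
    """
    m1, m2 = rs.modalities[:2]
    sd_rows = []
    for subset in _SUBSETS:
        cmp_ = compare_modalities_sd(rs, subset, test=test)
        sd_rows.append(
            {
                "cases": subset,
                m1: cmp_.mean_first,
                m2: cmp_.mean_second,
                "difference": cmp_.difference,
                "ci_low": cmp_.ci[0],
                "ci_high": cmp_.ci[1],
                "p": cmp_.p,
            }
        )
    means = mean_score_by_class(rs, test=test)
    mean_rows = []
    for subset in ("benign", "malignant"):
        cmp_ = means[subset]["comparison"]
        mean_rows.append(
            {
                "cases": subset,
                m1: means[subset][m1],
                m2: means[subset][m2],
                "difference": cmp_.difference,
                "ci_low": cmp_.ci[0],
                "ci_high": cmp_.ci[1],
                "p": cmp_.p,
            }
        )
    return pd.DataFrame(sd_rows), pd.DataFrame(mean_rows)
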