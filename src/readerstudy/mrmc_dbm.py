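"""Dorfman-Berbaum-Metz (DBM) multi-reader multi-case modality comparison.

The DBM procedure converts a per-(modality, reader) accuracy metric into
jackknife pseudovalues over cases,

    Y[i, j, k] = c * theta_ij - (c - 1) * theta_ij(k),

where theta_ij(k) is the metric recomputed with case k deleted, then treats
the pseudovalues as observations in a fully crossed three-way mixed ANOVA
(modality fixed; reader and case random).  The modality F test uses the
Hillis-corrected denominator

    D = MS(TR) + max(MS(TC) - MS(TRC), 0)

with numerator df t-1 and Hillis denominator df
ddf = D**2 / (MS(TR)**2 / ((t-1)(r-1))).  The original DBM denominator
(no truncation, ddf = (t-1)(r-1)(c-1)) is available behind ``hillis=False``.

For the Wilcoxon AUC metric the pseudovalue case-mean reproduces the
full-sample AUC exactly (U-statistic identity), which the test suite uses
as an internal oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .rating_data import RatingSet
from .roc_core import wilcoxon_auc

__all__ = [
    "PseudovalueCube",
    "DBMResult",
    "SubgroupComparison",
    "jackknife_pseudovalues",
    "dbm_anova",
    "dbm_test",
    "dbm_analysis",
    "per_reader_test",
    "subgroup_analysis",
    "estimate_power",
]

Metric = Callable[[np.ndarray, np.ndarray], float]


@dataclass(frozen=True)
class PseudovalueCube:
    """Jackknife pseudovalues Y[i, j, k] with the full-sample metric theta."""

    Y: np.ndarray  # (t, r, c)
    theta: np.ndarray  # (t, r)
    metric_name: str
    modalities: tuple[str, ...]
    readers: tuple[str, ...]
    cases: tuple[str, ...]


@dataclass
class DBMResult:
    """Mean squares, F test, and interval estimates of a DBM analysis."""

    ms: dict[str, float]
    dims: tuple[int, int, int]  # (t, r, c)
    modalities: tuple[str, ...]
    metric_name: str
    per_modality: np.ndarray  # pseudovalue modality means = averaged metric
    per_modality_ci: np.ndarray | None = None  # (t, 2)
    F: float | None = None
    ndf: float | None = None
    ddf: float | None = None
    p: float | None = None
    diff: float | None = None
    diff_ci: tuple[float, float] | None = None
    alpha: float = 0.05
    hillis: bool = True
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric_name,
            "dims": {"modalities": self.dims[0], "readers": self.dims[1],
                     "cases": self.dims[2]},
            "mean_squares": self.ms,
            "per_modality": {
                m: {"estimate": float(self.per_modality[i]),
                    "ci": None if self.per_modality_ci is None
                    else [float(x) for x in self.per_modality_ci[i]]}
                for i, m in enumerate(self.modalities)
            },
            "F": self.F, "ndf": self.ndf, "ddf": self.ddf, "p": self.p,
            "difference": self.diff,
            "difference_ci": None if self.diff_ci is None
            else [float(x) for x in self.diff_ci],
            "alpha": self.alpha, "hillis": self.hillis, "flags": self.flags,
        }


def _wilcoxon_pseudovalues(scores: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised leave-one-case-out Wilcoxon AUC pseudovalues.

    ``scores`` is (t, r, c).  Removing benign case k only drops its row of
    the pairwise win matrix, so every leave-one-out AUC comes from row/column
    sums of one (n1, n0) comparison per reader and modality.
    """
    ben = scores[:, :, truth == 0]  # (t, r, n0)
    mal = scores[:, :, truth == 1]  # (t, r, n1)
    n0, n1 = ben.shape[-1], mal.shape[-1]
    if n0 < 2 or n1 < 2:
        raise ValueError("insufficient cases for jackknife: need >= 2 per class")
    w = (mal[:, :, :, None] > ben[:, :, None, :]).astype(float)
    w += 0.5 * (mal[:, :, :, None] == ben[:, :, None, :])
    u = w.sum(axis=(2, 3))  # (t, r)
    theta = u / (n0 * n1)
    s_ben = w.sum(axis=2)  # (t, r, n0): wins involving each benign case
    s_mal = w.sum(axis=3)  # (t, r, n1)
    theta_del_ben = (u[:, :, None] - s_ben) / ((n0 - 1) * n1)
    theta_del_mal = (u[:, :, None] - s_mal) / (n0 * (n1 - 1))
    c = n0 + n1
    Y = np.empty_like(scores)
    Y[:, :, truth == 0] = c * theta[:, :, None] - (c - 1) * theta_del_ben
    Y[:, :, truth == 1] = c * theta[:, :, None] - (c - 1) * theta_del_mal
    return Y, theta


def jackknife_pseudovalues(rs: RatingSet, metric: Metric = wilcoxon_auc) -> PseudovalueCube:
    """Leave-one-case-out jackknife pseudovalues of ``metric`` per (modality, reader)."""
    if rs.n_benign < 2 or rs.n_malignant < 2:
        raise ValueError("insufficient cases for jackknife: need >= 2 per class")
    if metric is wilcoxon_auc:
        Y, theta = _wilcoxon_pseudovalues(rs.scores, rs.truth)
        name = "wilcoxon_auc"
    else:
        t, r, c = rs.scores.shape
        theta = np.empty((t, r))
        Y = np.empty((t, r, c))
        for i in range(t):
            for j in range(r):
                row = rs.scores[i, j]
                theta[i, j] = metric(row[rs.truth == 0], row[rs.truth == 1])
                for k in range(c):
                    keep = np.arange(c) != k
                    tk = metric(
                        row[keep][rs.truth[keep] == 0],
                        row[keep][rs.truth[keep] == 1],
                    )
                    Y[i, j, k] = c * theta[i, j] - (c - 1) * tk
        name = getattr(metric, "__name__", "metric")
    return PseudovalueCube(Y, theta, name, rs.modalities, rs.readers, rs.cases)


def dbm_anova(pv: PseudovalueCube) -> DBMResult:
    """Three-way crossed ANOVA decomposition of the pseudovalue cube."""
    Y = pv.Y
    t, r, c = Y.shape
    if t < 2 or r < 2 or c < 2:
        raise ValueError(
            "full DBM ANOVA needs >= 2 levels of every factor; "
            f"got (t, r, c) = {(t, r, c)}"
        )
    m = Y.mean()
    A = Y.mean(axis=(1, 2))  # modality means
    B = Y.mean(axis=(0, 2))  # reader means
    C = Y.mean(axis=(0, 1))  # case means
    AB = Y.mean(axis=2)
    AC = Y.mean(axis=1)
    BC = Y.mean(axis=0)
    ms = {
        "T": r * c * np.sum((A - m) ** 2) / (t - 1),
        "R": t * c * np.sum((B - m) ** 2) / (r - 1),
        "C": t * r * np.sum((C - m) ** 2) / (c - 1),
        "TR": c * np.sum((AB - A[:, None] - B[None, :] + m) ** 2)
        / ((t - 1) * (r - 1)),
        "TC": r * np.sum((AC - A[:, None] - C[None, :] + m) ** 2)
        / ((t - 1) * (c - 1)),
        "RC": t * np.sum((BC - B[:, None] - C[None, :] + m) ** 2)
        / ((r - 1) * (c - 1)),
        "TRC": np.sum(
            (
                Y
                - AB[:, :, None]
                - AC[:, None, :]
                - BC[None, :, :]
                + A[:, None, None]
                + B[None, :, None]
                + C[None, None, :]
                - m
            )
            ** 2
        )
        / ((t - 1) * (r - 1) * (c - 1)),
    }
    ms = {k: float(v) for k, v in ms.items()}
    return DBMResult(
        ms=ms,
        dims=(t, r, c),
        modalities=pv.modalities,
        metric_name=pv.metric_name,
        per_modality=A.copy(),
    )


def _single_modality_ci(Yi: np.ndarray, alpha: float) -> tuple[float, float]:
    """Hillis single-treatment CI from the within-modality (r x c) ANOVA."""
    r, c = Yi.shape
    m = Yi.mean()
    br = Yi.mean(axis=1)
    bc = Yi.mean(axis=0)
    ms_r = c * np.sum((br - m) ** 2) / (r - 1)
    ms_c = r * np.sum((bc - m) ** 2) / (c - 1)
    ms_rc = np.sum((Yi - br[:, None] - bc[None, :] + m) ** 2) / ((r - 1) * (c - 1))
    denom = ms_r + max(ms_c - ms_rc, 0.0)
    if denom <= 0:
        return (m, m)
    var = denom / (r * c)
    ddf = denom**2 / (ms_r**2 / (r - 1)) if ms_r > 0 else np.inf
    tq = stats.t.ppf(1 - alpha / 2, ddf)
    return (m - tq * np.sqrt(var), m + tq * np.sqrt(var))


def dbm_test(result: DBMResult, alpha: float = 0.05, hillis: bool = True,
             pv: PseudovalueCube | None = None) -> DBMResult:
    """Populate the modality F test, p-value, and interval estimates.

    With ``hillis=True`` (default) the denominator is truncated at MS(TR)
    and the Hillis denominator df is used; ``hillis=False`` gives the
    original DBM test with ddf = (t-1)(r-1)(c-1).  ``pv`` is only needed
    for the per-modality CIs.
    """
    ms = result.ms
    t, r, c = result.dims
    result.alpha = alpha
    result.hillis = hillis
    result.ndf = float(t - 1)
    if hillis:
        D = ms["TR"] + max(ms["TC"] - ms["TRC"], 0.0)
        if D > 0 and ms["TR"] > 0:
            result.ddf = float(D**2 / (ms["TR"] ** 2 / ((t - 1) * (r - 1))))
        else:
            result.ddf = float((t - 1) * (r - 1))
    else:
        D = ms["TR"] + ms["TC"] - ms["TRC"]
        result.ddf = float((t - 1) * (r - 1) * (c - 1))
    if D <= 0:
        result.F = 0.0 if ms["T"] == 0 else np.inf
        result.p = 1.0
        result.flags.append("no variability: zero denominator mean square")
    else:
        result.F = float(ms["T"] / D)
        result.p = float(stats.f.sf(result.F, result.ndf, result.ddf))
    if t == 2:
        result.diff = float(result.per_modality[0] - result.per_modality[1])
        if D > 0:
            se = np.sqrt(2.0 * D / (r * c))
            tq = stats.t.ppf(1 - alpha / 2, result.ddf)
            result.diff_ci = (result.diff - tq * se, result.diff + tq * se)
        else:
            result.diff_ci = (result.diff, result.diff)
    if pv is not None:
        result.per_modality_ci = np.array(
            [_single_modality_ci(pv.Y[i], alpha) for i in range(t)]
        )
    return result


def dbm_analysis(rs: RatingSet, metric: Metric = wilcoxon_auc,
                 alpha: float = 0.05, hillis: bool = True) -> DBMResult:
    """Full pipeline: pseudovalues -> ANOVA -> Hillis-corrected F test."""
    pv = jackknife_pseudovalues(rs, metric)
    return dbm_test(dbm_anova(pv), alpha=alpha, hillis=hillis, pv=pv)


def per_reader_test(
    rs: RatingSet, reader: str, metric: Metric = wilcoxon_auc
) -> tuple[np.ndarray, float]:
    """Single-reader paired modality test on jackknife pseudovalues.

    Computes per-case pseudovalue differences d_k between the two modalities
    for one reader and applies a two-sided one-sample t test of mean(d) = 0
    with c - 1 degrees of freedom.  Returns (theta per modality, p).
    """
    if rs.n_modalities != 2:
        raise ValueError("per-reader paired test requires exactly 2 modalities")
    sub = rs.select_readers([reader])
    pv = jackknife_pseudovalues(sub, metric)
    d = pv.Y[0, 0] - pv.Y[1, 0]
    theta = pv.theta[:, 0]
    if np.allclose(d.std(ddof=1), 0.0):
        return theta, 1.0
    t_stat, p = stats.ttest_1samp(d, 0.0)
    return theta, float(p)


@dataclass
class SubgroupComparison:
    """Per-group DBM results plus a between-group improvement contrast."""

    groups: dict[str, DBMResult]
    improvements: dict[str, np.ndarray]  # per-reader modality-1 minus modality-2
    between_p: float | None
    between_diff: float | None

    def to_dict(self) -> dict:
        return {
            "groups": {g: res.to_dict() for g, res in self.groups.items()},
            "between_group_improvement_difference": self.between_diff,
            "between_group_p": self.between_p,
        }


def subgroup_analysis(
    rs: RatingSet,
    groups: dict[str, Sequence[str]],
    metric: Metric = wilcoxon_auc,
    alpha: float = 0.05,
) -> SubgroupComparison:
    """DBM pipeline per reader group + Welch t test on per-reader improvements.

    ``groups`` maps group label -> reader ids; groups must partition (a
    subset of) the readers with at least 2 readers each.  The between-group
    test compares the group means of per-reader modality improvements
    (theta[modality 0] - theta[modality 1]) by Welch's two-sample t test and
    is reported only for exactly two groups.
    """
    results: dict[str, DBMResult] = {}
    improvements: dict[str, np.ndarray] = {}
    for name, ids in groups.items():
        if len(ids) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 readers")
        sub = rs.select_readers(list(ids))
        pv = jackknife_pseudovalues(sub, metric)
        results[name] = dbm_test(dbm_anova(pv), alpha=alpha, pv=pv)
        improvements[name] = pv.theta[0] - pv.theta[1] if sub.n_modalities == 2 \
            else np.full(sub.n_readers, np.nan)
    between_p = between_diff = None
    if len(groups) == 2 and rs.n_modalities == 2:
        g1, g2 = list(groups)
        d1, d2 = improvements[g1], improvements[g2]
        between_diff = float(d1.mean() - d2.mean())
        if np.allclose(np.concatenate([d1 - d1.mean(), d2 - d2.mean()]), 0.0):
            between_p = 1.0
        else:
            _, between_p = stats.ttest_ind(d1, d2, equal_var=False)
            between_p = float(between_p)
    return SubgroupComparison(results, improvements, between_p, between_diff)


def estimate_power(
    cfg,
    alpha: float = 0.05,
    nsim: int = 500,
    seed: int = 0,
    hillis: bool = True,
) -> tuple[float, float]:
    """Monte-Carlo power of the DBM test under a simulator configuration.

    Simulates ``nsim`` independent studies from ``cfg`` (reseeded from
    ``seed``), runs the DBM modality test on each, and returns the rejection
    fraction with its binomial standard error.  With equal modality
    separations this estimates the type-I error rate.
    """
    from dataclasses import replace

    from .synthetic_data import simulate_ratings

    if nsim < 100:
        raise ValueError("nsim must be at least 100 for a stable estimate")
    child_seeds = np.random.SeedSequence(seed).generate_state(nsim) & 0x7FFFFFFF
    reject = 0
    for s in child_seeds:
        rs = simulate_ratings(replace(cfg, seed=int(s)))
        res = dbm_analysis(rs, hillis=hillis, alpha=alpha)
        if res.p < alpha:
            reject += 1
    power = reject / nsim
    se = float(np.sqrt(power * (1.0 - power) / nsim))
    return float(power), se
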