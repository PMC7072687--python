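"""Single-reader ROC machinery.

Empirical operating points and the trapezoidal (Wilcoxon) AUC; maximum
likelihood fitting of the binormal ROC model TPF = Phi(a + b * Phi^-1(FPF))
from ordered rating categories (Dorfman-Alf); and curve-shape summaries
derived from a fit: partial AUC over an FPF interval, sensitivity at fixed
specificity, and specificity at fixed sensitivity.

The binormal parameterisation places the benign latent decision variable at
N(0, 1) and the malignant one at N(a/b, 1/b**2), so a is the class
separation in malignant-SD units and b the ratio of benign to malignant
latent SDs.  The ROC curve is proper (concave) only when b = 1; the fitted
curve may exhibit the usual binormal "hook" near the corners when b != 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, stats
from scipy.special import ndtr, ndtri

__all__ = [
    "EmpiricalROC",
    "BinormalFit",
    "empirical_roc",
    "wilcoxon_auc",
    "fit_binormal",
    "binormal_auc",
    "binormal_curve",
    "pauc",
    "sens_at_spec",
    "spec_at_sens",
]


@dataclass(frozen=True)
class EmpiricalROC:
    """Empirical ROC operating points, including (0,0) and (1,1).

    ``points[k] = (FPF, TPF)`` at ``thresholds[k]`` under the convention
    "positive if score >= threshold"; ``thresholds[0]`` is +inf for (0, 0).
    """

    points: np.ndarray  # (n, 2) of (FPF, TPF), nondecreasing
    thresholds: np.ndarray  # (n,)

    @property
    def auc(self) -> float:
        """Trapezoidal area under the operating points."""
        return float(np.trapezoid(self.points[:, 1], self.points[:, 0]))


@dataclass(frozen=True)
class BinormalFit:
    """Fitted binormal ROC curve TPF = Phi(a + b * Phi^-1(FPF))."""

    a: float
    b: float
    loglik: float
    n_bins: int
    converged: bool
    fallback: str | None = None  # 'continuity_correction' | 'empirical_b1'

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError(f"slope parameter b must be positive, got {self.b}")

    @property
    def auc(self) -> float:
        return binormal_auc(self.a, self.b)

    def tpf(self, fpf):
        """TPF of the fitted curve at the given FPF value(s)."""
        fpf = np.asarray(fpf, dtype=float)
        with np.errstate(divide="ignore"):
            return ndtr(self.a + self.b * ndtri(fpf))


def _check_classes(scores_benign, scores_malignant) -> tuple[np.ndarray, np.ndarray]:
    ben = np.asarray(scores_benign, dtype=float).ravel()
    mal = np.asarray(scores_malignant, dtype=float).ravel()
    if ben.size == 0 or mal.size == 0:
        raise ValueError("both classes must be nonempty")
    return ben, mal


def empirical_roc(scores_benign, scores_malignant) -> EmpiricalROC:
    """Empirical ROC points, one per distinct threshold, plus the endpoints."""
    ben, mal = _check_classes(scores_benign, scores_malignant)
    thr = np.unique(np.concatenate([ben, mal]))[::-1]
    fpf = (ben[None, :] >= thr[:, None]).mean(axis=1)
    tpf = (mal[None, :] >= thr[:, None]).mean(axis=1)
    points = np.column_stack(
        [np.concatenate([[0.0], fpf]), np.concatenate([[0.0], tpf])]
    )
    thresholds = np.concatenate([[np.inf], thr])
    if points[-1, 0] != 1.0 or points[-1, 1] != 1.0:  # all scores above min
        points = np.vstack([points, [1.0, 1.0]])
        thresholds = np.concatenate([thresholds, [-np.inf]])
    return EmpiricalROC(points, thresholds)


def wilcoxon_auc(scores_benign, scores_malignant) -> float:
    """Wilcoxon (trapezoidal) AUC: P(malignant > benign) + 0.5 P(tie).

    Computed from midranks in O(n log n); exactly equals the trapezoidal
    area under :func:`empirical_roc` and the normalised Mann-Whitney U.
    """
    ben, mal = _check_classes(scores_benign, scores_malignant)
    n0, n1 = ben.size, mal.size
    ranks = stats.rankdata(np.concatenate([ben, mal]))
    u = ranks[n0:].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


def binormal_auc(a: float, b: float) -> float:
    """AUC of the binormal curve: Phi(a / sqrt(1 + b**2))."""
    if b <= 0:
        raise ValueError(f"slope parameter b must be positive, got {b}")
    return float(ndtr(a / np.hypot(1.0, b)))


# ---------------------------------------------------------------------------
# Dorfman-Alf categorical ML fit
# ---------------------------------------------------------------------------


def _bin_counts(
    ben: np.ndarray, mal: np.ndarray, max_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Reduce ratings to ordered categories; return per-class counts."""
    pooled = np.concatenate([ben, mal])
    values = np.unique(pooled)
    if values.size > max_bins:
        qs = np.quantile(pooled, np.linspace(0, 1, max_bins + 1)[1:-1])
        edges = np.unique(qs)
        ben_cat = np.searchsorted(edges, ben, side="right")
        mal_cat = np.searchsorted(edges, mal, side="right")
        k = edges.size + 1
    else:
        ben_cat = np.searchsorted(values, ben)
        mal_cat = np.searchsorted(values, mal)
        k = values.size
    n0 = np.bincount(ben_cat, minlength=k).astype(float)
    n1 = np.bincount(mal_cat, minlength=k).astype(float)
    keep = (n0 + n1) > 0
    return n0[keep], n1[keep]


def _nll(params: np.ndarray, n0: np.ndarray, n1: np.ndarray) -> float:
    """Negative log-likelihood of category counts under the binormal model.

    params = [a, log b, c_1, log(c_2 - c_1), ...]; cutpoints live on the
    benign latent scale.
    """
    a, logb = params[0], params[1]
    b = np.exp(logb)
    cuts = np.concatenate([[params[2]], params[2] + np.cumsum(np.exp(params[3:]))])
    zb = np.concatenate([[-np.inf], cuts, [np.inf]])
    p0 = np.diff(ndtr(zb))
    p1 = np.diff(ndtr(b * zb - a))
    eps = 1e-300
    return -float(n0 @ np.log(np.maximum(p0, eps)) + n1 @ np.log(np.maximum(p1, eps)))


def _initial_cuts(n0: np.ndarray, n1: np.ndarray) -> np.ndarray:
    cum = np.cumsum(n0 + n1)[:-1] / (n0.sum() + n1.sum())
    return ndtri(np.clip(cum, 1e-4, 1 - 1e-4))


def _ml_fit(n0: np.ndarray, n1: np.ndarray, auc0: float) -> optimize.OptimizeResult:
    cuts0 = _initial_cuts(n0, n1)
    # strictly increasing start for the log-increment transform
    incr = np.maximum(np.diff(cuts0), 1e-3)
    best = None
    for b0 in (0.5, 1.0, 2.0):
        a0 = np.hypot(1.0, b0) * ndtri(np.clip(auc0, 1e-4, 1 - 1e-4))
        x0 = np.concatenate([[a0, np.log(b0), cuts0[0]], np.log(incr)])
        res = optimize.minimize(
            _nll,
            x0,
            args=(n0, n1),
            method="L-BFGS-B",
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best


def fit_binormal(scores_benign, scores_malignant, max_bins: int = 20) -> BinormalFit:
    """Fit the binormal ROC model by categorical maximum likelihood.

    Ratings are reduced to at most ``max_bins`` ordered categories (quantile
    binning of the pooled scores when there are more distinct values); the
    Dorfman-Alf likelihood over category counts is maximised with multiple
    slope starts (b in {0.5, 1, 2}).

    Degenerate data are handled in two stages: on perfect class separation
    or optimiser failure, a half-count continuity correction is added to the
    extreme category cells and the model refit; if that also fails, the
    returned curve has b = 1 and a = sqrt(2) * Phi^-1(Wilcoxon AUC).  Either
    remedy reports ``converged=False`` and names itself in ``fallback``.
    """
    ben, mal = _check_classes(scores_benign, scores_malignant)
    if np.unique(np.concatenate([ben, mal])).size < 2:
        raise ValueError("no discrimination information: single distinct score value")
    n0, n1 = _bin_counts(ben, mal, max_bins)
    auc0 = wilcoxon_auc(ben, mal)

    separated = ben.max() < mal.min() or mal.max() < ben.min()
    fallback: str | None = None
    res = None
    if not separated:
        res = _ml_fit(n0, n1, auc0)
    if separated or not res.success:
        # half-count continuity correction in the four corner cells
        n0c, n1c = n0.copy(), n1.copy()
        n0c[[0, -1]] += 0.5
        n1c[[0, -1]] += 0.5
        res = _ml_fit(n0c, n1c, auc0)
        fallback = "continuity_correction"
        if not res.success or not np.isfinite(res.fun):
            a = float(np.sqrt(2.0) * ndtri(np.clip(auc0, 1e-12, 1 - 1e-12)))
            return BinormalFit(
                a=a, b=1.0, loglik=np.nan, n_bins=len(n0),
                converged=False, fallback="empirical_b1",
            )
    a = float(res.x[0])
    b = float(np.exp(res.x[1]))
    return BinormalFit(
        a=a,
        b=b,
        loglik=-float(res.fun),
        n_bins=len(n0),
        converged=bool(res.success) and fallback is None,
        fallback=fallback,
    )


# ---------------------------------------------------------------------------
# curve-shape summaries
# ---------------------------------------------------------------------------


def pauc(fit: BinormalFit, fpf_lo: float = 0.0, fpf_hi: float = 0.3) -> float:
    """Partial AUC: integral of the fitted TPF over [fpf_lo, fpf_hi]."""
    if not (0.0 <= fpf_lo < fpf_hi <= 1.0):
        raise ValueError(f"invalid FPF interval [{fpf_lo}, {fpf_hi}]")
    val, _ = integrate.quad(
        lambda x: ndtr(fit.a + fit.b * ndtri(x)), fpf_lo, fpf_hi,
        epsabs=1e-10, epsrel=1e-10, limit=200,
    )
    return float(val)


def sens_at_spec(fit: BinormalFit, spec: float = 0.95) -> float:
    """Sensitivity (TPF) of the fitted curve at the given specificity."""
    if not 0.0 < spec < 1.0:
        raise ValueError(f"specificity must be in (0, 1), got {spec}")
    return float(ndtr(fit.a + fit.b * ndtri(1.0 - spec)))


def spec_at_sens(fit: BinormalFit, sens: float = 0.95) -> float:
    """Specificity (1 - FPF) of the fitted curve at the given sensitivity."""
    if not 0.0 < sens < 1.0:
        raise ValueError(f"sensitivity must be in (0, 1), got {sens}")
    return float(1.0 - ndtr((ndtri(sens) - fit.a) / fit.b))


def binormal_curve(fit: BinormalFit, n: int = 1001) -> np.ndarray:
    """Sample the fitted curve at ``n`` evenly spaced FPF values (for export)."""
    fpf = np.linspace(0.0, 1.0, n)
    tpf = np.empty_like(fpf)
    tpf[0], tpf[-1] = 0.0, 1.0
    tpf[1:-1] = fit.tpf(fpf[1:-1])
    return np.column_stack([fpf, tpf])
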