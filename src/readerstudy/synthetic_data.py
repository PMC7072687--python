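"""Synthetic reader-study data: latent-variable ratings and contour pairs.

The rating simulator is a simplified Roe-Metz latent Gaussian model for a
paired two-(or more-)modality MRMC design.  For modality i, reader j and
case k with truth s_k in {0 benign, 1 malignant},

    Z_ijk = (delta_i + tauR_ij) * s_k + C_k + RC_jk + eps_ijk

with tauR_ij ~ N(0, var_reader_skill) a reader-specific discriminability
perturbation, C_k ~ N(0, var_case) and RC_jk ~ N(0, var_reader_case) shared
across modalities (inducing the positive within-case correlation of the
paired design), and modality-specific noise eps_ijk ~ N(0, var_error).  The
within-class latent variance is normalised to one
(var_case + var_reader_case + var_error = 1), so the expected
reader-averaged Wilcoxon AUC of modality i has the closed form

    E[AUC_i] = Phi(delta_i / sqrt(2 + var_reader_skill))

up to the distortion of the score map, which discretises the latent value
to the bounded 0-100 rating scale: score = clamp(round(50 + slope * Z)).

The contour generator emulates nodule locus pairs: the physician contour is
a circle; the software contour perturbs its radius with smoothed Gaussian
noise plus a constant systematic offset, remaining a simple closed polyline.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri

from .rating_data import RatingSet
from .segmentation_match import Contour

__all__ = [
    "RoeMetzConfig",
    "ContourSimConfig",
    "simulate_ratings",
    "default_study_config",
    "separations_for_auc",
    "expected_auc",
    "simulate_contour_pairs",
]


@dataclass(frozen=True)
class RoeMetzConfig:
    """Configuration of the latent-variable rating simulator.

    ``separations`` holds one latent-scale class separation delta_i per
    modality; the three within-class variance components must sum to one.
    ``score_slope`` is the affine score map's gain in rating points per
    latent unit.
    """

    n_readers: int = 19
    n_benign: int = 165
    n_malignant: int = 100
    separations: tuple[float, ...] = (1.0, 1.0)
    var_reader_skill: float = 0.04
    var_case: float = 0.6
    var_reader_case: float = 0.2
    var_error: float = 0.2
    score_slope: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "separations", tuple(float(d) for d in self.separations))
        if self.n_readers < 1:
            raise ValueError("need at least one reader")
        if self.n_benign < 2 or self.n_malignant < 2:
            raise ValueError("need at least 2 cases per truth class")
        if not self.separations:
            raise ValueError("need at least one modality separation")
        if any(d < 0 for d in self.separations):
            raise ValueError("separations must be nonnegative")
        for name in ("var_reader_skill", "var_case", "var_reader_case", "var_error"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        total = self.var_case + self.var_reader_case + self.var_error
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                "within-class latent variance must be normalised: "
                f"var_case + var_reader_case + var_error = {total}, expected 1"
            )
        if self.score_slope <= 0:
            raise ValueError("score_slope must be positive")

    @property
    def n_modalities(self) -> int:
        return len(self.separations)

    @property
    def n_cases(self) -> int:
        return self.n_benign + self.n_malignant

    def expected_aucs(self) -> tuple[float, ...]:
        """Closed-form expected reader-averaged AUC per modality."""
        return tuple(expected_auc(d, self.var_reader_skill) for d in self.separations)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "RoeMetzConfig":
        d = dict(d)
        if "separations" in d:
            d["separations"] = tuple(d["separations"])
        return cls(**d)


def expected_auc(delta: float, var_reader_skill: float) -> float:
    """E[AUC] = Phi(delta / sqrt(2 + var_reader_skill)) under the latent model."""
    return float(ndtr(delta / np.sqrt(2.0 + var_reader_skill)))


def separations_for_auc(aucs, var_reader_skill: float = 0.04) -> tuple[float, ...]:
    """Invert the expected-AUC formula: delta = Phi^-1(AUC) * sqrt(2 + var)."""
    return tuple(
        float(ndtri(a) * np.sqrt(2.0 + var_reader_skill)) for a in np.atleast_1d(aucs)
    )


def default_study_config(seed: int = 20200206) -> RoeMetzConfig:
    """Study-shaped defaults: 19 readers, 165 benign + 100 malignant cases,
    two paired modalities with separations calibrated so the expected mean
    AUCs are 0.728 (first modality) and 0.792 (second)."""
    return RoeMetzConfig(
        n_readers=19,
        n_benign=165,
        n_malignant=100,
        separations=separations_for_auc((0.728, 0.792), 0.04),
        var_reader_skill=0.04,
        var_case=0.6,
        var_reader_case=0.2,
        var_error=0.2,
        score_slope=20.0,
        seed=seed,
    )


def _modality_labels(t: int) -> tuple[str, ...]:
    if t == 2:
        return ("mod1_without_CAD", "mod2_with_CAD")
    return tuple(f"mod{i + 1}" for i in range(t))


def simulate_ratings(cfg: RoeMetzConfig) -> RatingSet:
    """Draw one fully crossed rating study from the latent model.

    Deterministic given ``cfg.seed``; all draws flow from a single
    ``numpy.random.default_rng`` generator in a fixed order.
    """
    rng = np.random.default_rng(cfg.seed)
    t, r, c = cfg.n_modalities, cfg.n_readers, cfg.n_cases
    truth = np.concatenate(
        [np.zeros(cfg.n_benign, dtype=int), np.ones(cfg.n_malignant, dtype=int)]
    )
    delta = np.asarray(cfg.separations)
    tau = rng.normal(0.0, np.sqrt(cfg.var_reader_skill), size=(t, r))
    case = rng.normal(0.0, np.sqrt(cfg.var_case), size=c)
    reader_case = rng.normal(0.0, np.sqrt(cfg.var_reader_case), size=(r, c))
    eps = rng.normal(0.0, np.sqrt(cfg.var_error), size=(t, r, c))
    z = (
        (delta[:, None, None] + tau[:, :, None]) * truth[None, None, :]
        + case[None, None, :]
        + reader_case[None, :, :]
        + eps
    )
    scores = np.clip(np.rint(50.0 + cfg.score_slope * z), 0.0, 100.0)
    width = len(str(c))
    cases = tuple(f"case{k + 1:0{width}d}" for k in range(c))
    readers = tuple(f"reader{j + 1:02d}" for j in range(r))
    return RatingSet(scores, truth, readers, cases, _modality_labels(t))


# ---------------------------------------------------------------------------
# contour pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContourSimConfig:
    """Configuration of the nodule contour-pair generator.

    The physician contour is a circle of ``base_radius_mm`` sampled at
    ``n_vertices``; the software contour adds smoothed per-vertex radial
    Gaussian noise (``radial_noise_sd_mm``) and a constant radial
    ``systematic_offset_mm``.
    """

    n_pairs: int = 265
    base_radius_mm: float = 10.0
    radial_noise_sd_mm: float = 0.4
    systematic_offset_mm: float = 0.0
    n_vertices: int = 180
    seed: int = 0
    malignant_fraction: float = 100.0 / 265.0

    def __post_init__(self) -> None:
        if self.base_radius_mm <= 0:
            raise ValueError("base_radius_mm must be positive")
        if self.n_vertices < 16:
            raise ValueError("need at least 16 vertices per contour")
        if self.n_pairs < 1:
            raise ValueError("need at least one contour pair")
        if self.radial_noise_sd_mm < 0:
            raise ValueError("radial_noise_sd_mm must be nonnegative")
        if not 0.0 <= self.malignant_fraction <= 1.0:
            raise ValueError("malignant_fraction must be in [0, 1]")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "ContourSimConfig":
        return cls(**dict(d))


def _circle(radius: float | np.ndarray, n: int) -> np.ndarray:
    angles = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([radius * np.cos(angles), radius * np.sin(angles)])


def _smooth_circular(x: np.ndarray, window: int = 5) -> np.ndarray:
    """Circular moving average, rescaled to keep the input SD."""
    kernel = np.ones(window) / window
    padded = np.concatenate([x[-(window // 2):], x, x[: window // 2]])
    smoothed = np.convolve(padded, kernel, mode="valid")
    sd_in, sd_out = x.std(), smoothed.std()
    if sd_out > 0 and sd_in > 0:
        smoothed = smoothed * (sd_in / sd_out)
    return smoothed


def simulate_contour_pairs(
    cfg: ContourSimConfig, max_retries: int = 10
) -> list[tuple[Contour, Contour, int]]:
    """Generate (physician, software, truth) contour triples.

    The software contour's radius is resampled (up to ``max_retries``)
    whenever the perturbation produces a non-positive radius or a
    self-intersecting polyline; a pair that cannot be repaired raises.
    Truth labels are Bernoulli draws at ``cfg.malignant_fraction``.
    """
    rng = np.random.default_rng(cfg.seed)
    pairs = []
    for _ in range(cfg.n_pairs):
        truth = int(rng.random() < cfg.malignant_fraction)
        physician = Contour(_circle(cfg.base_radius_mm, cfg.n_vertices))
        software = None
        for _attempt in range(max_retries):
            noise = (
                _smooth_circular(rng.normal(0.0, cfg.radial_noise_sd_mm, cfg.n_vertices))
                if cfg.radial_noise_sd_mm > 0
                else np.zeros(cfg.n_vertices)
            )
            radii = cfg.base_radius_mm + cfg.systematic_offset_mm + noise
            if radii.min() <= 0.05 * cfg.base_radius_mm:
                continue
            candidate = Contour(_circle(radii, cfg.n_vertices))
            if candidate.is_simple():
                software = candidate
                break
        if software is None:
            raise RuntimeError(
                "could not generate a simple software contour after "
                f"{max_retries} retries; reduce radial_noise_sd_mm"
            )
        pairs.append((physician, software, truth))
    return pairs
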