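"""Contour agreement between software-defined and physician-adjusted loci.

A nodule contour is a closed 2D polyline in millimetres.  Agreement is
measured directionally: every vertex of the physician-adjusted contour is
projected onto the software-defined locus, and a vertex counts as matched
when its nearest distance is at most a tolerance (default 1 mm).  The match
ratio — matched vertices over total vertices — is classified as

* excellent:    ratio = 100% (within 1e-12),
* satisfactory: 70% <= ratio < 100%,
* poor:         ratio < 70%,

with excellent + satisfactory together regarded as successful segmentation.
Because only the physician contour's vertices are evaluated, the metric is
not symmetric in its arguments, and the ratio depends on the vertex
sampling density; reports therefore record vertex counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats

__all__ = [
    "Contour",
    "MatchResult",
    "MatchSummary",
    "nearest_distance",
    "match_ratio",
    "classify_match",
    "summarize_matches",
    "read_contours",
    "write_contours",
]

CATEGORIES = ("excellent", "satisfactory", "poor")
_EXCELLENT_TOL = 1e-12


@dataclass(frozen=True)
class Contour:
    """Closed polyline contour with vertices in millimetres."""

    vertices: np.ndarray  # (n, 2)
    closed: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        object.__setattr__(self, "vertices", v)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("contour needs an (n >= 3, 2) vertex array")
        if not np.all(np.isfinite(v)):
            raise ValueError("contour vertices must be finite")
        consecutive = np.vstack([np.diff(v, axis=0), v[0] - v[-1]])
        if self.closed and np.any(np.all(consecutive == 0.0, axis=1)):
            raise ValueError("two consecutive contour vertices coincide")
        if not self.closed and np.any(np.all(np.diff(v, axis=0) == 0.0, axis=1)):
            raise ValueError("two consecutive contour vertices coincide")
        v.setflags(write=False)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def ring(self) -> shapely.LinearRing:
        if not self.closed:
            raise ValueError("open contours are rejected; close the polyline")
        return shapely.LinearRing(self.vertices)

    def is_simple(self) -> bool:
        return bool(self.ring().is_simple)

    def translated(self, dx: float, dy: float) -> "Contour":
        return Contour(self.vertices + np.array([dx, dy]), self.closed)


@dataclass(frozen=True)
class MatchResult:
    """Per-vertex nearest distances (mm), match ratio, and category."""

    distances: np.ndarray
    ratio: float
    category: str
    tolerance_mm: float
    n_vertices: int


def nearest_distance(p, target: Contour, mode: str = "segment") -> float:
    """Nearest distance (mm) from point ``p`` to a contour.

    ``mode="segment"`` measures to the continuous closed polyline (any
    point on any edge); ``mode="vertex"`` only to the vertices, so it is
    always >= the segment distance.
    """
    p = np.asarray(p, dtype=float)
    if mode == "segment":
        return float(shapely.distance(shapely.Point(p), target.ring()))
    if mode == "vertex":
        return float(np.min(np.hypot(*(target.vertices - p).T)))
    raise ValueError(f"mode must be 'segment' or 'vertex', got {mode!r}")


def match_ratio(
    physician: Contour,
    software: Contour,
    tolerance_mm: float = 1.0,
    mode: str = "segment",
) -> MatchResult:
    """Directional match ratio of physician vertices against the software locus.

    Every vertex of ``physician`` is tested against the software contour;
    a vertex within ``tolerance_mm`` is matched.  Swapping the arguments
    generally changes the result.
    """
    if tolerance_mm <= 0:
        raise ValueError(f"tolerance must be positive, got {tolerance_mm}")
    if not physician.closed or not software.closed:
        raise ValueError("open contours are rejected; close the polyline")
    if mode == "segment":
        ring = software.ring()
        pts = shapely.points(physician.vertices)
        distances = shapely.distance(pts, ring)
    elif mode == "vertex":
        diff = physician.vertices[:, None, :] - software.vertices[None, :, :]
        distances = np.sqrt((diff**2).sum(axis=2)).min(axis=1)
    else:
        raise ValueError(f"mode must be 'segment' or 'vertex', got {mode!r}")
    distances = np.asarray(distances, dtype=float)
    ratio = float((distances <= tolerance_mm).mean())
    return MatchResult(
        distances=distances,
        ratio=ratio,
        category=classify_match(ratio),
        tolerance_mm=tolerance_mm,
        n_vertices=physician.n_vertices,
    )


def classify_match(ratio: float) -> str:
    """Excellent (ratio = 1), satisfactory (0.7 <= ratio < 1) or poor (< 0.7).

    A ratio of exactly 0.7 is satisfactory (closed lower bound).
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"match ratio must be in [0, 1], got {ratio}")
    if ratio >= 1.0 - _EXCELLENT_TOL:
        return "excellent"
    if ratio >= 0.7:
        return "satisfactory"
    return "poor"


@dataclass(frozen=True)
class MatchSummary:
    """Cross-tab of match categories by truth class with a two-proportion test."""

    counts: pd.DataFrame  # rows all/benign/malignant, columns categories
    percentages: pd.DataFrame
    successful_fraction: dict[str, float]
    chi2: float
    p: float
    test: str

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy().astype(object)
        for row in out.index:
            for col in out.columns:
                out.loc[row, col] = (
                    f"{self.counts.loc[row, col]} "
                    f"({self.percentages.loc[row, col]:.1f}%)"
                )
        return out


def summarize_matches(
    records: list[tuple[str, int]], yates: bool = False
) -> MatchSummary:
    """Cross-tabulate (category, truth) records and test class proportions.

    ``records`` holds one ``(category, truth)`` pair per nodule, truth
    0 = benign / 1 = malignant.  Row percentages are computed for
    all/benign/malignant, and a Pearson chi-square two-proportion test
    (without continuity correction unless ``yates=True``) compares the
    successful (excellent + satisfactory) fraction between classes.
    """
    if not records:
        raise ValueError("no match records to summarise")
    cats = [c for c, _ in records]
    bad = set(cats) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown match category label(s): {sorted(bad)}")
    truth = np.array([t for _, t in records], dtype=int)
    cat_arr = np.array(cats)
    rows = {}
    for name, mask in (
        ("all", np.ones(len(records), dtype=bool)),
        ("benign", truth == 0),
        ("malignant", truth == 1),
    ):
        rows[name] = [int(((cat_arr == c) & mask).sum()) for c in CATEGORIES]
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=list(CATEGORIES))
    totals = counts.sum(axis=1)
    percentages = counts.div(totals.replace(0, np.nan), axis=0) * 100.0
    successful = {
        name: float(
            (counts.loc[name, "excellent"] + counts.loc[name, "satisfactory"])
            / totals[name]
        )
        if totals[name]
        else np.nan
        for name in counts.index
    }
    succ_b = counts.loc["benign", "excellent"] + counts.loc["benign", "satisfactory"]
    succ_m = (
        counts.loc["malignant", "excellent"] + counts.loc["malignant", "satisfactory"]
    )
    fail_b = counts.loc["benign", "poor"]
    fail_m = counts.loc["malignant", "poor"]
    table = np.array([[succ_b, fail_b], [succ_m, fail_m]], dtype=float)
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return MatchSummary(
        counts=counts,
        percentages=percentages,
        successful_fraction=successful,
        chi2=float(chi2),
        p=float(p),
        test="Pearson chi-square" + (" (Yates)" if yates else ""),
    )


# ---------------------------------------------------------------------------
# CSV I/O: case_id,role(software|physician),vertex_index,x_mm,y_mm
# ---------------------------------------------------------------------------


def write_contours(pairs: list[tuple[str, Contour, Contour]], path) -> None:
    """Write (case_id, physician, software) contour pairs as long CSV."""
    rows = []
    for case_id, physician, software in pairs:
        for role, contour in (("physician", physician), ("software", software)):
            for idx, (x, y) in enumerate(contour.vertices):
                rows.append((case_id, role, idx, x, y))
    pd.DataFrame(
        rows, columns=["case_id", "role", "vertex_index", "x_mm", "y_mm"]
    ).to_csv(path, index=False)


def read_contours(path) -> list[tuple[str, Contour, Contour]]:
    """Read contour pairs written by :func:`write_contours`."""
    df = pd.read_csv(path, dtype={"case_id": str})
    pairs = []
    for case_id, grp in df.groupby("case_id", sort=True):
        contours = {}
        for role, sub in grp.groupby("role"):
            sub = sub.sort_values("vertex_index")
            contours[role] = Contour(sub[["x_mm", "y_mm"]].to_numpy())
        if set(contours) != {"physician", "software"}:
            raise ValueError(
                f"case {case_id!r} must have exactly physician and software contours"
            )
        pairs.append((case_id, contours["physician"], contours["software"]))
    return pairs
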