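"""Data model and I/O for fully crossed reader-rating studies.

A rating study assigns one malignancy-potential score (0-100) per
(reader, case, modality) cell, with per-case binary pathology truth
(0 = benign, 1 = malignant).  The design is fully crossed: every reader
rates every case under every modality, so the scores form a dense
``(modality, reader, case)`` array with no missing cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RatingSet",
    "ReaderInfo",
    "IncompleteDesignError",
    "ScoreRangeError",
    "TruthConsistencyError",
    "read_ratings",
    "write_ratings",
    "read_reader_info",
    "write_reader_info",
    "split_by_experience",
]

RATING_COLUMNS = ["reader_id", "case_id", "modality", "score", "truth"]


class IncompleteDesignError(ValueError):
    """A (reader, case, modality) cell is missing from the crossed design."""


class ScoreRangeError(ValueError):
    """A score lies outside the 0-100 rating scale."""


class TruthConsistencyError(ValueError):
    """A case carries two distinct truth labels."""


@dataclass(frozen=True)
class ReaderInfo:
    """Reader metadata: identifier plus years of experience."""

    reader_id: str
    experience_years: float

    def __post_init__(self) -> None:
        if self.experience_years < 0:
            raise ValueError(
                f"experience_years must be >= 0, got {self.experience_years}"
            )


@dataclass(frozen=True)
class RatingSet:
    """Scores of a fully crossed reader study.

    Parameters
    ----------
    scores
        Array of shape ``(t, r, c)`` — modality x reader x case — with
        values in [0, 100].
    truth
        Length-``c`` integer array, 0 = benign, 1 = malignant.
    readers, cases, modalities
        Ordered axis labels.
    """

    scores: np.ndarray
    truth: np.ndarray
    readers: tuple[str, ...]
    cases: tuple[str, ...]
    modalities: tuple[str, ...]

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        truth = np.asarray(self.truth, dtype=int)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "truth", truth)
        object.__setattr__(self, "readers", tuple(str(x) for x in self.readers))
        object.__setattr__(self, "cases", tuple(str(x) for x in self.cases))
        object.__setattr__(
            self, "modalities", tuple(str(x) for x in self.modalities)
        )
        self._validate()
        scores.setflags(write=False)
        truth.setflags(write=False)

    def _validate(self) -> None:
        t, r, c = len(self.modalities), len(self.readers), len(self.cases)
        if t < 1:
            raise ValueError("at least one modality is required")
        if r < 1 or c < 1:
            raise ValueError("at least one reader and one case are required")
        for name, labels in (
            ("reader", self.readers),
            ("case", self.cases),
            ("modality", self.modalities),
        ):
            if len(set(labels)) != len(labels):
                raise ValueError(f"duplicate {name} identifiers")
        if self.scores.shape != (t, r, c):
            raise IncompleteDesignError(
                f"scores shape {self.scores.shape} does not match "
                f"(modalities, readers, cases) = {(t, r, c)}"
            )
        if not np.all(np.isfinite(self.scores)):
            raise ScoreRangeError("scores contain non-finite values")
        if self.scores.min() < 0 or self.scores.max() > 100:
            bad = self.scores[(self.scores < 0) | (self.scores > 100)][0]
            raise ScoreRangeError(f"score {bad} outside [0, 100]")
        if self.truth.shape != (c,):
            raise ValueError("truth must have one label per case")
        if not np.isin(self.truth, [0, 1]).all():
            raise TruthConsistencyError("truth labels must be 0 or 1")
        if (self.truth == 0).sum() < 2 or (self.truth == 1).sum() < 2:
            raise ValueError("need at least 2 cases of each truth class")

    # -- basic dimensions ------------------------------------------------
    @property
    def n_modalities(self) -> int:
        return len(self.modalities)

    @property
    def n_readers(self) -> int:
        return len(self.readers)

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    @property
    def n_benign(self) -> int:
        return int((self.truth == 0).sum())

    @property
    def n_malignant(self) -> int:
        return int((self.truth == 1).sum())

    # -- views -----------------------------------------------------------
    def class_scores(self, modality: str, reader: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (benign, malignant) score vectors for one reader/modality."""
        i = self.modalities.index(modality)
        j = self.readers.index(reader)
        row = self.scores[i, j]
        return row[self.truth == 0], row[self.truth == 1]

    def select_readers(self, reader_ids: list[str] | tuple[str, ...]) -> "RatingSet":
        """Sub-study restricted to the given readers (order preserved)."""
        idx = [self.readers.index(r) for r in reader_ids]
        return RatingSet(
            scores=self.scores[:, idx, :].copy(),
            truth=self.truth.copy(),
            readers=tuple(reader_ids),
            cases=self.cases,
            modalities=self.modalities,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, rows sorted by (reader, case, modality)."""
        t, r, c = self.scores.shape
        df = pd.DataFrame(
            {
                "reader_id": np.repeat(self.readers, c * t),
                "case_id": np.tile(np.repeat(self.cases, t), r),
                "modality": np.tile(self.modalities, r * c),
                "score": np.transpose(self.scores, (1, 2, 0)).ravel(),
                "truth": np.tile(np.repeat(self.truth, t), r),
            }
        )
        return df.sort_values(
            ["reader_id", "case_id", "modality"], kind="stable"
        ).reset_index(drop=True)

    def equals(self, other: "RatingSet") -> bool:
        """Equality as a mapping cell -> score, ignoring axis order."""
        if (
            sorted(self.readers) != sorted(other.readers)
            or sorted(self.cases) != sorted(other.cases)
            or sorted(self.modalities) != sorted(other.modalities)
        ):
            return False
        mi = [other.modalities.index(m) for m in self.modalities]
        ri = [other.readers.index(r) for r in self.readers]
        ci = [other.cases.index(k) for k in self.cases]
        aligned = other.scores[np.ix_(mi, ri, ci)]
        return bool(
            np.array_equal(self.scores, aligned)
            and np.array_equal(self.truth, other.truth[ci])
        )


def _from_frame(df: pd.DataFrame) -> RatingSet:
    missing_cols = [c for c in RATING_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing required columns: {missing_cols}")
    df = df.copy()
    for col in ("reader_id", "case_id", "modality"):
        df[col] = df[col].astype(str)

    truth_per_case = df.groupby("case_id")["truth"].nunique()
    bad = truth_per_case[truth_per_case > 1]
    if len(bad):
        raise TruthConsistencyError(
            f"case {bad.index[0]!r} has {bad.iloc[0]} distinct truth values"
        )
    scores = df["score"].to_numpy(dtype=float)
    if not np.all(np.isfinite(scores)) or scores.min() < 0 or scores.max() > 100:
        raise ScoreRangeError("score outside [0, 100] in input table")

    readers = tuple(sorted(df["reader_id"].unique()))
    cases = tuple(sorted(df["case_id"].unique()))
    modalities = tuple(sorted(df["modality"].unique()))
    t, r, c = len(modalities), len(readers), len(cases)
    if len(df) != t * r * c or df.duplicated(
        ["reader_id", "case_id", "modality"]
    ).any():
        # locate the first missing cell in (reader, case, modality) order
        have = set(zip(df["reader_id"], df["case_id"], df["modality"]))
        for rd in readers:
            for cs in cases:
                for md in modalities:
                    if (rd, cs, md) not in have:
                        raise IncompleteDesignError(
                            "incomplete design: missing cell "
                            f"(reader={rd!r}, case={cs!r}, modality={md!r})"
                        )
        raise IncompleteDesignError("duplicate (reader, case, modality) rows")

    cube = np.empty((t, r, c), dtype=float)
    ridx = {v: i for i, v in enumerate(readers)}
    cidx = {v: i for i, v in enumerate(cases)}
    midx = {v: i for i, v in enumerate(modalities)}
    cube[
        df["modality"].map(midx).to_numpy(),
        df["reader_id"].map(ridx).to_numpy(),
        df["case_id"].map(cidx).to_numpy(),
    ] = scores
    truth = np.empty(c, dtype=int)
    truth[df["case_id"].map(cidx).to_numpy()] = df["truth"].to_numpy(dtype=int)
    return RatingSet(cube, truth, readers, cases, modalities)


def read_ratings(path) -> RatingSet:
    """Read a long-format ratings CSV into a validated :class:`RatingSet`.

    The file must have columns ``reader_id,case_id,modality,score,truth``.
    Row order does not affect the result: axis labels are ordered
    lexicographically.
    """
    return _from_frame(pd.read_csv(path, dtype={"reader_id": str, "case_id": str}))


def write_ratings(rs: RatingSet, path) -> None:
    """Write ``rs`` as long CSV with deterministic lexicographic row order."""
    rs.to_frame().to_csv(path, index=False, columns=RATING_COLUMNS)


def read_reader_info(path) -> list[ReaderInfo]:
    """Read the companion readers CSV (``reader_id,experience_years``)."""
    df = pd.read_csv(path, dtype={"reader_id": str})
    return [
        ReaderInfo(row.reader_id, float(row.experience_years))
        for row in df.itertuples()
    ]


def write_reader_info(info: list[ReaderInfo], path) -> None:
    pd.DataFrame(
        {
            "reader_id": [x.reader_id for x in info],
            "experience_years": [x.experience_years for x in info],
        }
    ).to_csv(path, index=False)


def split_by_experience(
    rs: RatingSet,
    info: list[ReaderInfo],
    threshold_years: float = 10.0,
) -> tuple[RatingSet | None, RatingSet | None]:
    """Partition readers into junior (< threshold) and senior (>= threshold).

    Cases and modalities are unchanged.  A subgroup with fewer than two
    readers triggers a warning (its reader-variance estimate is weak) and is
    returned as ``None`` if empty.
    """
    by_id = {x.reader_id: x for x in info}
    if len(by_id) != len(info):
        raise ValueError("duplicate reader_id in reader info")
    missing = [r for r in rs.readers if r not in by_id]
    if missing:
        raise ValueError(f"no experience record for reader(s) {missing}")
    junior_ids = [r for r in rs.readers if by_id[r].experience_years < threshold_years]
    senior_ids = [r for r in rs.readers if by_id[r].experience_years >= threshold_years]
    for name, ids in (("junior", junior_ids), ("senior", senior_ids)):
        if len(ids) < 2:
            warnings.warn(
                f"{name} group has {len(ids)} reader(s); "
                "reader-variance estimates will be weak or undefined",
                stacklevel=2,
            )
    junior = rs.select_readers(junior_ids) if junior_ids else None
    senior = rs.select_readers(senior_ids) if senior_ids else None
    return junior, senior
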