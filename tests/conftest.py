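import numpy as np
import pytest

from readerstudy import RatingSet


@pytest.fixture
def toy_ratings() -> RatingSet:
    """Small deterministic 2-modality, 3-reader, 6-case study."""
    rng = np.random.default_rng(1234)
    scores = rng.integers(0, 101, size=(2, 3, 6)).astype(float)
    truth = np.array([0, 0, 0, 1, 1, 1])
    return RatingSet(
        scores=scores,
        truth=truth,
        readers=("r1", "r2", "r3"),
        cases=("c1", "c2", "c3", "c4", "c5", "c6"),
        modalities=("without", "with"),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20200206)


def random_rating_set(rng: np.random.Generator, t=2, r=3, n0=4, n1=3) -> RatingSet:
    c = n0 + n1
    scores = rng.integers(0, 101, size=(t, r, c)).astype(float)
    truth = np.r_[np.zeros(n0, int), np.ones(n1, int)]
    return RatingSet(
        scores,
        truth,
        tuple(f"r{j}" for j in range(r)),
        tuple(f"c{k}" for k in range(c)),
        tuple(f"m{i}" for i in range(t)),
    )
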