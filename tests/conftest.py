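import numpy as np
import pytest

from driftfa import GenotypeMatrix, SampleMetadata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dosage_matrix(rng):
    """Random 10 x 50 dosage matrix with ~8% missing cells."""
    vals = rng.integers(0, 3, size=(10, 50)).astype(float)
    mask = rng.random((10, 50)) < 0.08
    vals[mask] = np.nan
    return GenotypeMatrix(
        vals,
        [f"s{i}" for i in range(10)],
        [f"m{j}" for j in range(50)],
        mask,
    )


@pytest.fixture
def centered_matrix(rng):
    """Row-centered continuous 12 x 40 matrix."""
    vals = rng.standard_normal((12, 40))
    vals -= vals.mean(axis=1, keepdims=True)
    return GenotypeMatrix(
        vals,
        [f"s{i}" for i in range(12)],
        [f"m{j}" for j in range(40)],
        np.zeros((12, 40), bool),
        centered=True,
    )


def make_metadata(ids, ages=None, coverages=None, populations=None):
    n = len(ids)
    ages = ages if ages is not None else np.linspace(4000, 0, n)
    out = []
    for i, s in enumerate(ids):
        out.append(
            SampleMetadata(
                sample_id=s,
                age=float(ages[i]),
                coverage=None if coverages is None else float(coverages[i]),
                population=None if populations is None else populations[i],
            )
        )
    return out
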