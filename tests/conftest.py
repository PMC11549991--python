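import numpy as np
import pytest

from connstats import Atlas, Connectome, SyntheticSpec, generate_cohort


def small_atlas(n: int) -> Atlas:
    return Atlas(
        labels=tuple(f"L.N{i:02d}" for i in range(n)),
        hemisphere=("L",) * n,
    )


def connectome_from(weights, subject_id="test") -> Connectome:
    w = np.asarray(weights, dtype=float)
    return Connectome(w, small_atlas(w.shape[0]), subject_id)


@pytest.fixture
def make_connectome():
    return connectome_from


@pytest.fixture
def random_connectome():
    """Dense random-weight connectome factory (symmetric, positive)."""

    def _make(n: int, seed: int = 0) -> Connectome:
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.1, 1.0, size=(n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        return connectome_from(w)

    return _make


@pytest.fixture(scope="session")
def small_cohort():
    """Planted-effect cohort small enough for fast tests."""
    spec = SyntheticSpec()
    return generate_cohort(spec, (8, 8, 8), seed=42)


@pytest.fixture(scope="session")
def null_cohort():
    spec = SyntheticSpec(effect_size=0.0)
    return generate_cohort(spec, (8, 8, 8), seed=43)
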