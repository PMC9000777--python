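import numpy as np
import pytest

from aquarocket.dataset import SampleMeta, SpectralDataset


def make_dataset(values, wavelengths=None, mode="absorbance", meta=None):
    """Build a small SpectralDataset with auto-filled metadata."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, p = values.shape
    if wavelengths is None:
        wavelengths = np.linspace(1300.0, 1600.0, p)
    if meta is None:
        meta = [
            SampleMeta("A", 0, bag=str(i // 2 + 1), side="front" if i % 2 == 0 else "back",
                       replicate=i + 1)
            for i in range(n)
        ]
    return SpectralDataset(np.asarray(wavelengths, float), values, mode, meta)


@pytest.fixture
def small_scenario():
    """Reduced replication for fast unit tests (not the study conditions)."""
    from aquarocket.synthetic_data import SpectralScenario

    return SpectralScenario(n_reps=2, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
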