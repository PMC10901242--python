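import numpy as np
import pytest

from nirsmap import preprocess, synthetic
from nirsmap.types import GRID, RelativeSpectrum


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def optics():
    return synthetic.TissueOpticsParams()


@pytest.fixture
def calibration(optics):
    return synthetic.simulate_calibration(optics, np.random.default_rng(0))


def make_conditioned(rng, n=1, state="nonlesion", optics=None):
    """Conditioned spectra straight from the forward model."""
    optics = optics or synthetic.TissueOpticsParams()
    cal = synthetic.simulate_calibration(optics, rng)
    counts, _ = synthetic.simulate_spectra_batch(
        np.full(n, state == "lesion"),
        np.ones(n, bool),
        np.zeros(n),
        "PBS",
        optics,
        rng,
    )
    rel = optics.phantom_factor * counts / cal.standard.counts[None, :]
    return preprocess.condition_batch(synthetic.RAW_WL, rel)


@pytest.fixture
def conditioned_spectrum(rng):
    return RelativeSpectrum(make_conditioned(rng)[0])


@pytest.fixture
def smooth_rrel():
    """A hand-built smooth conditioned-like spectrum on the standard grid."""
    rrel = 1.0 + 0.3 * np.sin(2 * np.pi * (GRID - 600) / 800.0)
    rrel /= rrel[0]
    return RelativeSpectrum(rrel)


@pytest.fixture(scope="session")
def small_session():
    cfg = synthetic.SessionConfig(n_hearts=2, points_per_heart=60, seed=7)
    return synthetic.simulate_session(cfg)
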