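import numpy as np
import pytest

from pfasbind import SimulationConfig, simulate_titration


@pytest.fixture
def noshift_config():
    """Simulator config whose band does not shift, so the intensity read at
    the reference wavelength equals the quenching model F(Q) exactly."""

    def make(**kwargs):
        kwargs.setdefault("kb_true", 1e5)
        kwargs.setdefault("peak_free_nm", 337.0)
        kwargs.setdefault("peak_bound_nm", 337.0)
        return SimulationConfig(**kwargs)

    return make


@pytest.fixture
def gaussian_spectrum():
    """Factory for a Gaussian emission band on the standard 275-500 nm grid."""

    def make(centre_nm=337.0, height=1000.0, sigma_nm=25.0, step_nm=1.0):
        from pfasbind import EmissionSpectrum

        wl = np.arange(275.0, 500.0 + step_nm / 2, step_nm)
        return EmissionSpectrum(wl, height * np.exp(-0.5 * ((wl - centre_nm) / sigma_nm) ** 2))

    return make


@pytest.fixture
def simulated_series(noshift_config):
    series, truth = simulate_titration(noshift_config())
    return series, truth
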