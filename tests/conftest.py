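import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from leafspec import SyntheticConfig, simulate_study
from leafspec.validation import build_dataset

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic dry-down study (12 trees x 7 dates, seeded)."""
    return simulate_study(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_dataset(default_study):
    """Mean spectra + gas-exchange-fitted traits for the default study."""
    return build_dataset(default_study, trait_source="fitted")


@pytest.fixture(scope="session")
def small_noise_free_study():
    """A small all-noise-off study: the injective spectra->trait limit."""
    cfg = SyntheticConfig(n_trees=6, n_dates=5, seed=3, tree_sd=4.0,
                          psi_sd=0.0, aci_noise_sd=0.0,
                          spectral_noise_sd=0.0, jmax_cv=0.0,
                          n_replicate_spectra=2, stress_peak_date_index=2)
    return simulate_study(cfg)


def flat_spectrum(value=0.3, lo=350, hi=2500):
    from leafspec import Spectrum
    wl = np.arange(lo, hi + 1, dtype=float)
    return Spectrum(wl, np.full(wl.size, float(value)))


@pytest.fixture
def make_flat_spectrum():
    return flat_spectrum


# Second, independent transcription of the published index formulas, written
# directly from the printed comparison table (guards the registry against
# transcription typos). r is a dict wavelength -> raw reflectance.
INDEX_TRANSCRIPTION = {
    "SR1": lambda r: r[750] / r[700],
    "DoubleDifference": lambda r: (r[749] - r[720]) - (r[701] - r[672]),
    "Vogelmann1": lambda r: r[740] / r[720],
    "mSR705": lambda r: (r[750] - r[445]) / (r[705] - r[445]),
    "SRCarter": lambda r: r[760] / r[695],
    "Maccioni": lambda r: (r[780] - r[710]) / (r[780] - r[680]),
    "SR3": lambda r: r[750] / r[550],
    "Gitelson": lambda r: 1.0 / r[700],
    "Datt4": lambda r: r[672] / (r[550] * r[708]),
    "SR4": lambda r: r[700] / r[670],
    "SR2": lambda r: r[752] / r[690],
    "NDVI": lambda r: (r[860] - r[690]) / (r[860] + r[690]),
    "Vogelmann2": lambda r: (r[734] - r[747]) - (r[715] + r[726]),
    "mNDVI": lambda r: (r[800] - r[680]) / (r[800] + r[680] - 2 * r[445]),
    "NDWI": lambda r: (r[860] - r[1240]) / (r[860] + r[1240]),
    "SIPI": lambda r: r[800] - r[445],
    "PRI": lambda r: (r[531] - r[570]) / (r[531] + r[570]),
    "mSRCHL": lambda r: (r[800] - r[445]) / (r[680] - r[445]),
}


@pytest.fixture(scope="session")
def index_transcription():
    return INDEX_TRANSCRIPTION
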