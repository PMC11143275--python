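import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fiberfold import ftir, synthdata, waxs

settings.register_profile(
    "deterministic", derandomize=True, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("deterministic")

#: canonical 7-band construction used across FTIR tests (areas chosen to give
#: beta 0.42 / alpha 0.40 / other 0.18)
SEVEN_BANDS = [
    ftir.Band(1696.0, 25.0, 0.05, 0.7),
    ftir.Band(1682.0, 25.0, 0.08, 0.7),
    ftir.Band(1660.0, 25.0, 0.10, 0.7),
    ftir.Band(1650.0, 25.0, 0.40, 0.7),
    ftir.Band(1632.0, 25.0, 0.15, 0.7),
    ftir.Band(1624.0, 25.0, 0.17, 0.7),
    ftir.Band(1615.0, 25.0, 0.05, 0.7),
]


@pytest.fixture(scope="session")
def seven_band_spectrum():
    spec, truth = synthdata.synth_amide_spectrum(SEVEN_BANDS)
    return spec, truth


@pytest.fixture(scope="session")
def synchrotron_geometry():
    """Microfocus beamline geometry: 0.9996 A at 76.3 mm, binned 102 um pixels."""
    return waxs.DetectorGeometry(wavelength=0.9996, distance_mm=76.3,
                                 pixel_um=102.0, beam_center=(256.0, 256.0))


@pytest.fixture(scope="session")
def cuka_geometry():
    """Cu K-alpha geometry: 1.5418 A at 110.8 mm (coarse 204 um pixels so the
    pattern fits a 512x512 frame)."""
    return waxs.DetectorGeometry(wavelength=1.5418, distance_mm=110.8,
                                 pixel_um=204.0, beam_center=(256.0, 256.0))


def make_index_spectrum(ratio: float, sigma: float = 0.0, seed: int = 0):
    """Amide spectrum built from Lorentzian bands whose 1695/1624 heights
    stand in the given ratio (the organizational-index construction)."""
    h = ftir.band_height(1.0, 20.0, 0.0)
    bands = [ftir.Band(1624.0, 20.0, 1.0 / h, 0.0),
             ftir.Band(1650.0, 20.0, 0.8 / h, 0.0),
             ftir.Band(1660.0, 20.0, 0.5 / h, 0.0)]
    if ratio > 0:
        bands.append(ftir.Band(1695.0, 20.0, ratio / h, 0.0))
    spec, truth = synthdata.synth_amide_spectrum(
        bands, noise=synthdata.NoiseModel(sigma=sigma), seed=seed)
    return spec, truth


def random_band_model(rng: np.random.Generator, n_bands: int | None = None):
    """A random physically plausible amide I band table."""
    n = n_bands or int(rng.integers(3, 9))
    centers = rng.uniform(1595.0, 1705.0, size=n)
    return [ftir.Band(float(c), float(rng.uniform(10.0, 35.0)),
                      float(rng.uniform(0.05, 1.0)), float(rng.uniform(0.0, 1.0)))
            for c in centers]
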