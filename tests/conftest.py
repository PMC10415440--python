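import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import wfsep as w

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spectrum():
    return w.default_liver_spectrum(1.5)


@pytest.fixture(scope="session")
def acq3():
    return w.AcquisitionParams.from_ms(1.29, 2.1, 3)


@pytest.fixture(scope="session")
def acq6():
    return w.AcquisitionParams.from_ms(1.29, 2.1, 6)


@pytest.fixture()
def small_maps():
    """16x16 phantom with moderate parameter ranges."""
    return w.generate_phantom(
        w.PhantomConfig(image_size=16, n_regions=2, seed=7, noise_snr=None)
    )


def random_maps(seed: int, size: int = 8) -> w.ParameterMaps:
    """Fully random in-mask parameter maps for oracle comparisons."""
    rng = np.random.default_rng(seed)
    mask = rng.random((size, size)) > 0.2
    phase = np.exp(1j * rng.uniform(-np.pi, np.pi, (size, size)))
    water = rng.uniform(0, 1, (size, size)) * phase
    fat = rng.uniform(0, 1, (size, size)) * phase
    r2 = rng.uniform(0, 200, (size, size))
    fm = rng.uniform(-400, 400, (size, size))
    for arr in (water, fat, r2, fm):
        arr[~mask] = 0
    return w.ParameterMaps(
        water=water, fat=fat, r2star_per_s=r2, fieldmap_hz=fm, mask=mask
    )
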