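import numpy as np
import pytest

from lipidqy import ReferenceStandard, StrainProfile, default_campaign_configs, generate_campaign


@pytest.fixture
def gaussian_spectrum():
    """Gaussian band, amplitude 1000 at 570 nm, sigma 15 nm, 1 nm grid."""
    from lipidqy import validate_spectrum
    wl = np.arange(500.0, 700.0 + 1e-9, 1.0)
    it = 1000.0 * np.exp(-0.5 * ((wl - 570.0) / 15.0) ** 2)
    return validate_spectrum(wl, it, 488.0)


@pytest.fixture
def standard():
    return ReferenceStandard(od_488_s=0.3, a_e_s=50_000.0)


@pytest.fixture
def profile():
    return StrainProfile()


@pytest.fixture
def noisy_campaign():
    m1, m7 = default_campaign_configs(seed=11)
    return generate_campaign(m1, m7)


@pytest.fixture
def noiseless_campaign():
    m1, m7 = default_campaign_configs(seed=11, noise_cv=0.0)
    return generate_campaign(m1, m7)
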