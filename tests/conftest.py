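import numpy as np
import pytest

from modenc import auditory, encoding, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def roi_features():
    """Small raw surrogate feature matrix on the ROI grid (4 runs x 40)."""
    return synthetic.surrogate_feature_matrix(4, 40, "roi_decoding", seed=11)


@pytest.fixture(scope="session")
def roi_features_convolved(roi_features):
    return auditory.hrf_convolve(roi_features)


@pytest.fixture(scope="session")
def roi_features_standardized(roi_features_convolved):
    return encoding.zscore_feature_matrix(roi_features_convolved)


@pytest.fixture(scope="session")
def ripple_grid():
    """Modulation-energy grid of a (4 Hz, 0.4 cyc/oct) moving ripple."""
    rip = synthetic.make_ripple(
        2.0, 16000.0, rate_hz=4.0, scale_cyc_per_oct=0.4, depth=1.0, seed=1
    )
    spec = auditory.auditory_spectrogram(rip.waveform, 16000.0)
    return auditory.modulation_energy(spec, "encoding")
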