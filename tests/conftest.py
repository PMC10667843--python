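import numpy as np
import pytest

from spindec.features import FeatureParams, MinMaxNormalizer
from spindec.pipeline import run_pipeline
from spindec.synthetic import SimConfig


@pytest.fixture(scope="session")
def session30():
    """A 30 s default session through the full pipeline (≈60 step cycles)."""
    return run_pipeline(SimConfig(seed=7, duration_s=30.0))


@pytest.fixture(scope="session")
def snr10_session():
    """A session whose units sit near SNR 10 (10 µV noise, ~150 µV units)."""
    cfg = SimConfig(seed=5, duration_s=10.0, noise_rms_uv=10.0)
    return cfg, run_pipeline(cfg, with_trajectory=False)


@pytest.fixture(scope="session")
def decoding_session():
    """A continuously-moving 1000-frame session with aligned features/targets."""
    cfg = SimConfig(seed=11, duration_s=17.5, moving_fraction=1.0)
    res = run_pipeline(cfg, with_trajectory=False)
    valid = res.features.valid
    X = res.features.data.astype(float)[valid][:1000]
    Y = MinMaxNormalizer().fit_transform(res.kinematics.coordinate_matrix())[valid][:1000]
    assert len(X) == 1000
    return X, Y, res


@pytest.fixture
def feature_params():
    return FeatureParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
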