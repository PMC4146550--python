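import numpy as np
import pytest

from hybridbci import (
    HybridPipeline,
    PipelineConfig,
    SyntheticConfig,
    generate_recording,
)


@pytest.fixture(scope="session")
def synth_session():
    """One moderate-SNR labeled session: 50 trials/class, 16 channels."""
    cfg = SyntheticConfig(seed=7, n_trials_per_class=50, snr=1.0)
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def _fitted_pipeline_master(synth_session):
    rec, _ = synth_session
    return HybridPipeline(PipelineConfig()).fit(rec)


@pytest.fixture
def pipeline_factory(_fitted_pipeline_master):
    """Fresh, independently mutable copy of the fitted pipeline."""

    def make():
        return HybridPipeline.from_json(_fitted_pipeline_master.to_json())

    return make


@pytest.fixture
def toy_csp_data():
    """Two 2-channel classes with covariances diag(4,1) and diag(1,4)."""
    rng = np.random.default_rng(0)
    X1 = rng.standard_normal((200, 2, 500)) * np.array([2.0, 1.0])[:, None]
    X2 = rng.standard_normal((200, 2, 500)) * np.array([1.0, 2.0])[:, None]
    X = np.concatenate([X1, X2])
    y = np.r_[np.ones(200, dtype=int), np.full(200, 2, dtype=int)]
    return X, y
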