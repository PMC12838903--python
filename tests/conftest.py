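import numpy as np
import pytest

import sparseeg as s


@pytest.fixture
def tiny_config():
    """Small but structurally complete network for fast unit tests (valid at
    100-sample windows)."""
    return s.NetworkConfig(
        n_channels=4,
        window_len=100,
        temporal_filters=8,
        spatial_filters=5,
        fusion_channels=(5, 6, 7),
        fusion_pool=(4, 2, 2),
        hidden=(10, 6),
        dropout=0.5,
    )


def make_windowed(
    n_subjects=3,
    n_trials=8,
    duration_s=6.0,
    baseline_s=1.0,
    rate_hz=100.0,
    shift_scale=0.0,
    effect_size=1.0,
    seed=7,
    mode="binary_valence",
):
    """Small preprocessed dataset straight from the generator."""
    raw = s.simulate_dataset(
        n_subjects=n_subjects,
        n_trials=n_trials,
        duration_s=duration_s,
        baseline_s=baseline_s,
        rate_hz=rate_hz,
        shift_scale=shift_scale,
        effect_size=effect_size,
        seed=seed,
    )
    profile = s.preprocess.Profile("custom", rate_hz, n_trials, duration_s, baseline_s)
    return s.run_pipeline(raw, profile=profile, scheme=s.LabelScheme(mode))


@pytest.fixture
def micro_dataset():
    """3 subjects × 40 windows of 4 × 100, identical-distribution subjects."""
    return make_windowed()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
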