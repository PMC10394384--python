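"""Shared fixtures: tiny phantom cohorts and micro network configurations."""

from __future__ import annotations

import numpy as np
import pytest

from neurofactor.network import NetworkConfig, TrainingConfig
from neurofactor.sampling import SamplingConfig
from neurofactor.synthetic import CohortConfig, generate_atlas, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def micro_network_config() -> NetworkConfig:
    """Smallest useful 12-convolution layout for unit tests."""
    return NetworkConfig(stem_channels=2, channel_schedule=(2, 4, 4, 8, 8),
                         stem_stride=2, downsample_strides=(2, 2, 2, 1, 1))


@pytest.fixture
def micro_net_config():
    return micro_network_config()


@pytest.fixture(scope="session")
def tiny_cohort_config() -> CohortConfig:
    """12 subjects, 48-cube volumes, 3 ellipsoidal ROIs, one strong effect."""
    from neurofactor.synthetic import EffectSpec

    return CohortConfig(
        n_subjects=12,
        volume_shape=(48, 48, 48),
        n_rois=3,
        n_groups=3,
        roi_radius_range=(4.0, 6.0),
        noise_sd=1.0,
        effects=(EffectSpec("R01", "Anxiety", 2.0),),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cohort_config):
    """(atlas, volumes dict, scores table, manifest) kept in memory."""
    return generate_cohort(tiny_cohort_config)


@pytest.fixture(scope="session")
def tiny_atlas(tiny_cohort):
    return tiny_cohort[0]


@pytest.fixture
def tiny_sampling_config() -> SamplingConfig:
    return SamplingConfig(patch_size=12, patches_per_roi=2, max_attempts=500, seed=0)


@pytest.fixture
def fast_training_config() -> TrainingConfig:
    return TrainingConfig(batch_size=32, learning_rate=3e-3, epochs=3, seed=0)
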