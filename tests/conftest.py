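import numpy as np
import pytest

from nirsfc.config import PipelineConfig
from nirsfc.montage import build_default_montage
from nirsfc.synth import (
    SimParams,
    plan_ground_truth,
    sample_cohort,
    simulate_recording,
)

QUIET = dict(
    resp_amp=0.0, mayer_amp=0.0, drift_amp=0.0, noise_sd=0.0,
    motion_epoch_rate=0.0, spike_rate=0.0, dead_channel_prob=0.0,
    hbr_noise=0.0,
)


@pytest.fixture(scope="session")
def montage():
    return build_default_montage()


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def clean_recording(montage):
    """600-s recording with cardiac pulsation but no noise, physiology
    confounds, motion, or dead channels."""
    params = SimParams(n_subjects=1, duration_range=(600.0, 600.0), **QUIET)
    meta = sample_cohort(params, 1)[0]
    truth = plan_ground_truth(meta, params, 17, montage=montage)
    rec = simulate_recording(meta, truth, params, 17, montage)
    return rec, truth, params


@pytest.fixture(scope="session")
def default_recording(montage):
    """400-s recording under the generator's default (noisy) conditions."""
    params = SimParams(n_subjects=1, duration_range=(400.0, 400.0))
    meta = sample_cohort(params, 2)[0]
    truth = plan_ground_truth(meta, params, 23, montage=montage)
    rec = simulate_recording(meta, truth, params, 23, montage)
    return rec, truth, params
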