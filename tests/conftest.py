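import numpy as np
import pytest

from catchup_saccades import ModelParams, StepRampSpec, build_trial
from catchup_saccades.synthesis import DatasetConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_spec():
    """A foveofugal second step-ramp: 8 deg step, +20 deg/s velocity step."""
    return StepRampSpec(
        fixation_x=-20.0, ps1=-4.0, vs1=20.0, steady_dur=600.0,
        ps2=8.0, vs2=20.0, blur=False, trial_id=1,
    )


@pytest.fixture
def simple_traj(simple_spec):
    return build_trial(simple_spec)


@pytest.fixture(scope="session")
def model_metrics():
    """A moderate model-mode dataset analyzed once and shared across tests."""
    from catchup_saccades.trace_analysis import analyze_dataset

    cfg = DatasetConfig(
        n_participants=4, n_sessions=2, blocks_per_session=2, trials_per_block=25
    )
    ds = generate_dataset(
        cfg, mode="model", rng=np.random.default_rng(777), model_params=ModelParams()
    )
    return analyze_dataset(ds.traces)
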