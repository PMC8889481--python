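import pytest

from oxival.session_model import MOVEMENT_TASKS
from oxival.synthetic_data import DeviceModel, ProtocolConfig

FAST_PROTOCOL_KWARGS = dict(
    task_durations=tuple((label, 60.0) for label in MOVEMENT_TASKS),
    inter_task_gap_s=10.0,
    plateau_duration_s=80.0,
    transition_duration_s=20.0,
    transition_tau_s=3.0,
    phase_gap_s=30.0,
    tail_s=10.0,
)


@pytest.fixture(scope="session")
def fast_config():
    """Shortened protocol (same structure, ~20 min -> ~20 s of session time)."""
    return ProtocolConfig(**FAST_PROTOCOL_KWARGS)


@pytest.fixture(scope="session")
def noise_free_config():
    """Fast protocol with every stochastic component switched off."""
    return ProtocolConfig(
        **FAST_PROTOCOL_KWARGS,
        baseline_sao2_sd=0.0,
        sts_dip_mean=0.0,
        sts_dip_sd=0.0,
        plateau_noise_sd=0.0,
        abg_analyzer_sd=0.0,
    )


@pytest.fixture
def clean_device():
    return DeviceModel(device_id="clean")


@pytest.fixture
def wristox_like():
    """Finger-probe-like error model: bias -1.9%, scatter 2.7%."""
    return DeviceModel(device_id="wx", systematic_bias=-1.9, scatter_sd=2.7)
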