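import math

import numpy as np
import pytest

from oxival.errors import ConfigError
from oxival.session_model import write_study
from oxival.synthetic_data import (
    DeviceModel,
    ProtocolConfig,
    predicted_hypoxia_residual_sd,
    session_layout,
    simulate_device_stream,
    simulate_sao2_trajectory,
    simulate_session,
    simulate_study,
)
from oxival.windowing import match_study
from oxival.accuracy_metrics import mean_bias, pair_arrays, rmse
from tests.conftest import FAST_PROTOCOL_KWARGS


class TestTrajectory:
    def test_noise_free_movement_phase_is_constant_baseline(self, noise_free_config):
        t, sao2 = simulate_sao2_trajectory(noise_free_config, seed=0)
        layout = session_layout(noise_free_config)
        movement = sao2[t <= layout.movement_end]
        assert np.all(movement == noise_free_config.baseline_sao2_mean)

    @pytest.mark.parametrize("seed", [0, 7])
    def test_plateau_means_near_targets(self, seed):
        config = ProtocolConfig()
        t, sao2 = simulate_sao2_trajectory(config, seed=seed)
        for plateau in session_layout(config).plateaus:
            mask = (t >= plateau.start) & (t < plateau.stop)
            assert abs(sao2[mask].mean() - plateau.target) < 0.5

    def test_custom_targets_produce_expected_plateaus(self):
        config = ProtocolConfig(
            **FAST_PROTOCOL_KWARGS | {"plateau_duration_s": 60.0},
            hypoxia_targets=(100.0, 95.0, 90.0),
            baseline_sao2_sd=0.0,
            plateau_noise_sd=0.0,
            sts_dip_mean=0.0,
            sts_dip_sd=0.0,
        )
        t, sao2 = simulate_sao2_trajectory(config, seed=1)
        layout = session_layout(config)
        assert len(t) == int(layout.duration) + 1
        assert len(layout.plateaus) == 3
        for plateau in layout.plateaus:
            mask = (t >= plateau.start) & (t < plateau.stop)
            assert np.all(sao2[mask] == plateau.target)

    def test_sts_dip_lowers_midpoint(self, fast_config):
        config = ProtocolConfig(
            **FAST_PROTOCOL_KWARGS,
            baseline_sao2_sd=0.0,
            plateau_noise_sd=0.0,
            sts_dip_mean=2.0,
            sts_dip_sd=0.0,
        )
        t, sao2 = simulate_sao2_trajectory(config, seed=0)
        sts = next(a for a in session_layout(config).annotations if a.label == "STS")
        mid_value = sao2[int((sts.start + sts.stop) / 2)]
        end_value = sao2[int(sts.stop)]
        assert mid_value == pytest.approx(config.baseline_sao2_mean - 2.0, abs=0.05)
        assert end_value == pytest.approx(config.baseline_sao2_mean, abs=0.05)

    def test_bounded_in_70_100(self):
        config = ProtocolConfig(plateau_noise_sd=5.0)
        _, sao2 = simulate_sao2_trajectory(config, seed=2)
        assert sao2.min() >= 70.0 and sao2.max() <= 100.0

    def test_plateau_shorter_than_window_rejected(self):
        with pytest.raises(ConfigError, match="plateau"):
            ProtocolConfig(plateau_duration_s=30.0)

    def test_non_decreasing_targets_rejected(self):
        with pytest.raises(ConfigError, match="decreasing"):
            ProtocolConfig(hypoxia_targets=(95.0, 100.0))


class TestDeviceStream:
    def test_zero_noise_stream_equals_trajectory(self, noise_free_config, clean_device):
        t, sao2 = simulate_sao2_trajectory(noise_free_config, seed=0)
        layout = session_layout(noise_free_config)
        stream = simulate_device_stream(t, sao2, clean_device, layout.annotations, seed=0)
        values = np.array([v for _, v in stream.samples])
        np.testing.assert_array_equal(values, sao2)

    def test_pure_systematic_bias_is_exact_offset(self, noise_free_config):
        device = DeviceModel(device_id="wx", systematic_bias=-1.92)
        t, sao2 = simulate_sao2_trajectory(noise_free_config, seed=0)
        layout = session_layout(noise_free_config)
        stream = simulate_device_stream(t, sao2, device, layout.annotations, seed=0)
        values = np.array([v for _, v in stream.samples])
        np.testing.assert_allclose(values, sao2 - 1.92, atol=1e-12)

    def test_full_dropout_empties_task_window(self, fast_config):
        device = DeviceModel(device_id="d", dropout_prob_by_task={"rubbing": 1.0})
        t, sao2 = simulate_sao2_trajectory(fast_config, seed=0)
        layout = session_layout(fast_config)
        stream = simulate_device_stream(t, sao2, device, layout.annotations, seed=0)
        rubbing = next(a for a in layout.annotations if a.label == "rubbing")
        in_window = [v for tt, v in stream.samples if rubbing.start <= tt < rubbing.stop]
        assert in_window and all(v is None for v in in_window)

    def test_smoothing_window_attenuates_scatter(self, noise_free_config):
        t, sao2 = simulate_sao2_trajectory(noise_free_config, seed=0)
        layout = session_layout(noise_free_config)
        raw = DeviceModel(device_id="a", scatter_sd=0.0, smoothing_window=1.0)
        smoothed = DeviceModel(device_id="b", scatter_sd=0.0, smoothing_window=10.0)
        va = np.array([v for _, v in simulate_device_stream(t, sao2, raw, layout.annotations, 0).samples])
        vb = np.array([v for _, v in simulate_device_stream(t, sao2, smoothed, layout.annotations, 0).samples])
        # noise-free trajectory is piecewise smooth; smoothing lags transitions
        assert np.var(np.diff(vb)) <= np.var(np.diff(va))

    def test_invalid_device_params_rejected(self):
        with pytest.raises(ConfigError):
            DeviceModel(device_id="d", scatter_sd=-1.0)
        with pytest.raises(ConfigError):
            DeviceModel(device_id="d", dropout_prob_by_task={"tapping": 1.5})
        with pytest.raises(ConfigError):
            DeviceModel(device_id="d", artifact_bias_by_task={"jogging": -1.0})


class TestSession:
    def test_default_session_reference_counts(self, fast_config, clean_device):
        session = simulate_session(fast_config, [clean_device], seed=0)
        movement = [r for r in session.references if r.phase == "movement"]
        hypoxia = [r for r in session.references if r.phase == "hypoxia"]
        assert len(movement) == 7 and len(hypoxia) == 7
        assert {r.label for r in hypoxia} == {"100", "95", "90", "87", "85", "83", "80"}

    def test_sts_midpoint_adds_one_reference(self, clean_device):
        config = ProtocolConfig(**FAST_PROTOCOL_KWARGS, include_sts_midpoint=True)
        session = simulate_session(config, [clean_device], seed=0)
        mids = [r for r in session.references if r.kind == "mid-task"]
        assert len(mids) == 1 and mids[0].label == "STS"
        assert len([r for r in session.references if r.phase == "movement"]) == 8

    def test_noise_free_session_has_zero_downstream_rmse(self, noise_free_config, clean_device):
        from oxival.session_model import StudyDataset

        session = simulate_session(noise_free_config, [clean_device], seed=0)
        dataset = StudyDataset(sessions=(session,), devices=("clean",))
        for phase in ("movement", "hypoxia"):
            spo2, sao2 = pair_arrays(match_study(dataset, phase).pairs)
            assert rmse(spo2, sao2) == 0.0


class TestStudy:
    def test_study_is_deterministic(self, fast_config, wristox_like, tmp_path):
        a = simulate_study(fast_config, [wristox_like], 3, seed=9)
        b = simulate_study(fast_config, [wristox_like], 3, seed=9)
        assert a == b
        write_study(a, tmp_path / "a")
        write_study(b, tmp_path / "b")
        for fa in sorted((tmp_path / "a").rglob("*")):
            if fa.is_file():
                fb = tmp_path / "b" / fa.relative_to(tmp_path / "a")
                assert fa.read_bytes() == fb.read_bytes()

    def test_33_sessions_yield_231_hypoxia_references(self, fast_config, clean_device):
        dataset = simulate_study(fast_config, [clean_device], 33, seed=0)
        n_refs = sum(1 for s in dataset.sessions for r in s.references if r.phase == "hypoxia")
        assert n_refs == 33 * 7 == 231

    def test_parameter_recovery(self, fast_config, wristox_like):
        # no-motion device, >= 500 hypoxia pairs
        dataset = simulate_study(fast_config, [wristox_like], 75, seed=11)
        spo2, sao2 = pair_arrays(match_study(dataset, "hypoxia").pairs)
        assert len(spo2) == 525
        sd_eff = predicted_hypoxia_residual_sd(wristox_like, fast_config)
        se = sd_eff / math.sqrt(len(spo2))
        assert abs(mean_bias(spo2, sao2) - (-1.9)) < 3 * se
        expected_rmse = math.sqrt(1.9**2 + sd_eff**2)
        assert rmse(spo2, sao2) == pytest.approx(expected_rmse, rel=0.05)

    def test_motion_artifact_bias_is_more_negative_than_rest(self, fast_config):
        device = DeviceModel(
            device_id="d",
            scatter_sd=1.0,
            artifact_bias_by_task={"tapping": -6.0, "rubbing": -8.0},
            artifact_sd_by_task={"tapping": 3.0, "rubbing": 4.0},
        )
        dataset = simulate_study(fast_config, [device], 10, seed=4)
        pairs = match_study(dataset, "movement").pairs
        def stratum_bias(name):
            sel = [p for p in pairs if p.stratum == name]
            return mean_bias(*pair_arrays(sel))
        rest = stratum_bias("at-rest")
        assert stratum_bias("tapping") < rest
        assert stratum_bias("rubbing") < rest
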