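"""Study-session simulator with known ground truth.

Generates the data the downstream analysis assumes: a movement phase at a
near-100% participant baseline (with a transient desaturation dip during the
sit-to-stand task), a hypoxia phase stepping through stable plateaus at a
decreasing sequence of target levels, per-device systematic bias and Gaussian
scatter on top of a vendor-style moving average, task-specific artifact noise
with negative mean bias, stream dropouts, and arterial-blood reference samples
at task ends and plateau midpoints.

Everything is deterministic given ``(config, devices, seed)``; per-session and
per-device randomness is split off a single :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .session_model import (
    MOVEMENT_TASKS,
    ReferenceSample,
    Session,
    SpO2Stream,
    StudyDataset,
    TaskAnnotation,
)

#: Length of the downstream alignment window (seconds); plateaus must be at
#: least this long so that windowed medians are well defined.
ALIGNMENT_WINDOW_S = 40.0


@dataclass(frozen=True)
class DeviceModel:
    """Statistical error model for one simulated pulse oximeter.

    ``systematic_bias`` is additive; ``bias_slope`` adds a component linear in
    the (smoothed) true saturation, anchored at 90% so that the nominal bias
    is realized near the hypoxemia threshold.  Task-keyed maps model motion
    artifacts (negative means = underestimation) and stream dropout.
    """

    device_id: str
    systematic_bias: float = 0.0
    bias_slope: float = 0.0
    scatter_sd: float = 0.0
    smoothing_window: float = 1.0
    artifact_bias_by_task: Mapping[str, float] = field(default_factory=dict)
    artifact_sd_by_task: Mapping[str, float] = field(default_factory=dict)
    dropout_prob_by_task: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "artifact_bias_by_task", dict(self.artifact_bias_by_task))
        object.__setattr__(self, "artifact_sd_by_task", dict(self.artifact_sd_by_task))
        object.__setattr__(self, "dropout_prob_by_task", dict(self.dropout_prob_by_task))
        if self.scatter_sd < 0:
            raise ConfigError(f"device {self.device_id!r}: scatter_sd must be >= 0")
        if self.smoothing_window < 1.0:
            raise ConfigError(f"device {self.device_id!r}: smoothing_window must be >= 1 s")
        for name, table in (
            ("artifact_bias_by_task", self.artifact_bias_by_task),
            ("artifact_sd_by_task", self.artifact_sd_by_task),
            ("dropout_prob_by_task", self.dropout_prob_by_task),
        ):
            for task in table:
                if task not in MOVEMENT_TASKS:
                    raise ConfigError(f"device {self.device_id!r}: {name} key {task!r} is not a known task")
        for task, sd in self.artifact_sd_by_task.items():
            if sd < 0:
                raise ConfigError(f"device {self.device_id!r}: artifact sd for {task!r} must be >= 0")
        for task, p in self.dropout_prob_by_task.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"device {self.device_id!r}: dropout prob for {task!r} must be in [0, 1]")


@dataclass(frozen=True)
class ProtocolConfig:
    """Timing and noise parameters of one simulated study session.

    Defaults mirror the study protocol: six motion tasks after an at-rest
    window, then a hypoxia phase descending through plateaus at
    100/95/90/87/85/83/80%.  The sit-to-stand desaturation dip defaults to
    mean 1.87% (SD 0.87%).  Within-plateau SaO2 variability (default 0.3% SD)
    and blood-gas analyzer noise (default 0.2% SD) are modeling choices, both
    configurable.
    """

    task_durations: tuple[tuple[str, float], ...] = (
        ("at-rest", 240.0),
        ("STS", 180.0),       # 20 repetitions
        ("tapping", 120.0),   # 2 min at 2 Hz
        ("rubbing", 120.0),   # 2 min at 2 Hz
        ("drinking", 150.0),  # 20 sips
        ("turning-pages", 150.0),  # 50 pages
        ("tablet", 180.0),
    )
    inter_task_gap_s: float = 30.0
    hypoxia_targets: tuple[float, ...] = (100.0, 95.0, 90.0, 87.0, 85.0, 83.0, 80.0)
    plateau_duration_s: float = 90.0
    transition_duration_s: float = 40.0
    transition_tau_s: float = 5.0
    phase_gap_s: float = 120.0
    tail_s: float = 30.0
    baseline_sao2_mean: float = 99.8
    baseline_sao2_sd: float = 0.3
    sts_dip_mean: float = 1.87
    sts_dip_sd: float = 0.87
    plateau_noise_sd: float = 0.3
    abg_analyzer_sd: float = 0.2
    include_sts_midpoint: bool = False

    def __post_init__(self) -> None:
        labels = [label for label, _ in self.task_durations]
        for label, duration in self.task_durations:
            if label not in MOVEMENT_TASKS:
                raise ConfigError(f"unknown task label {label!r}")
            if duration <= 0:
                raise ConfigError(f"task {label!r}: duration must be > 0")
        if len(set(labels)) != len(labels):
            raise ConfigError("duplicate task labels in protocol")
        if len(self.hypoxia_targets) < 1:
            raise ConfigError("at least one hypoxia target required")
        diffs = np.diff(self.hypoxia_targets)
        if len(diffs) and not np.all(diffs < 0):
            raise ConfigError(f"hypoxia targets must be strictly decreasing, got {self.hypoxia_targets}")
        for level in self.hypoxia_targets:
            if not 70.0 <= level <= 100.0:
                raise ConfigError(f"hypoxia target {level} outside [70, 100]")
        if self.plateau_duration_s < ALIGNMENT_WINDOW_S:
            raise ConfigError(
                f"plateau duration {self.plateau_duration_s} s shorter than the "
                f"{ALIGNMENT_WINDOW_S} s alignment window"
            )
        for name in ("baseline_sao2_sd", "sts_dip_sd", "plateau_noise_sd", "abg_analyzer_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass(frozen=True)
class _Plateau:
    label: str
    target: float
    start: float
    stop: float

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.stop)


@dataclass(frozen=True)
class SessionLayout:
    """Deterministic timing skeleton derived from a :class:`ProtocolConfig`."""

    annotations: tuple[TaskAnnotation, ...]
    plateaus: tuple[_Plateau, ...]
    movement_end: float
    hypoxia_start: float
    duration: float


def _format_target(level: float) -> str:
    return str(int(level)) if float(level).is_integer() else repr(float(level))


def session_layout(config: ProtocolConfig) -> SessionLayout:
    """Lay out task and plateau intervals on the session clock."""
    annotations = []
    cursor = 0.0
    for label, duration in config.task_durations:
        annotations.append(TaskAnnotation(label=label, start=cursor, stop=cursor + duration))
        cursor += duration + config.inter_task_gap_s
    movement_end = annotations[-1].stop
    hypoxia_start = movement_end + config.phase_gap_s

    plateaus = []
    cursor = hypoxia_start
    for target in config.hypoxia_targets:
        start = cursor + config.transition_duration_s
        stop = start + config.plateau_duration_s
        plateaus.append(_Plateau(label=_format_target(target), target=float(target), start=start, stop=stop))
        cursor = stop
    duration = cursor + config.tail_s
    return SessionLayout(
        annotations=tuple(annotations),
        plateaus=tuple(plateaus),
        movement_end=movement_end,
        hypoxia_start=hypoxia_start,
        duration=duration,
    )


def simulate_sao2_trajectory(
    config: ProtocolConfig, seed: int | np.random.SeedSequence | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the dense 1 Hz true-saturation curve for one session.

    The movement phase sits at a participant baseline drawn from
    ``N(baseline_sao2_mean, baseline_sao2_sd)`` with a Gaussian-shaped dip of
    amplitude ``N(sts_dip_mean, sts_dip_sd)`` centered on the sit-to-stand
    task.  The hypoxia phase descends through the configured targets with
    logistic transitions and holds each plateau at its target.  Within-plateau
    (and within-baseline) noise is i.i.d. Gaussian with SD
    ``plateau_noise_sd``; the final curve is clipped to [70, 100].

    Returns ``(t, sao2)`` arrays on a 1 s grid.
    """
    rng = np.random.default_rng(seed)
    layout = session_layout(config)
    n = int(math.floor(layout.duration)) + 1
    t = np.arange(n, dtype=float)

    baseline = float(np.clip(rng.normal(config.baseline_sao2_mean, config.baseline_sao2_sd), 90.0, 100.0))
    level = np.full(n, baseline)

    prev = baseline
    for plateau in layout.plateaus:
        trans_start = plateau.start - config.transition_duration_s
        mask = (t >= trans_start) & (t < plateau.start)
        mid = 0.5 * (trans_start + plateau.start)
        level[mask] = prev + (plateau.target - prev) / (
            1.0 + np.exp(-(t[mask] - mid) / config.transition_tau_s)
        )
        level[t >= plateau.start] = plateau.target
        prev = plateau.target

    # Sit-to-stand dip: returns to baseline by the task stop, where the
    # end-of-task reference is drawn.
    dip_amplitude = max(0.0, rng.normal(config.sts_dip_mean, config.sts_dip_sd))
    for ann in layout.annotations:
        if ann.label == "STS":
            mid = 0.5 * (ann.start + ann.stop)
            width = 0.25 * (ann.stop - ann.start)
            level = level - dip_amplitude * np.exp(-(((t - mid) / width) ** 2))
            break

    noise = rng.normal(0.0, config.plateau_noise_sd, n) if config.plateau_noise_sd > 0 else 0.0
    return t, np.clip(level + noise, 70.0, 100.0)


def _trailing_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Trailing moving average over ``window`` samples (shorter at the left edge)."""
    if window <= 1:
        return x.astype(float, copy=True)
    c = np.concatenate(([0.0], np.cumsum(x, dtype=float)))
    idx = np.arange(len(x))
    lo = np.maximum(0, idx - window + 1)
    return (c[idx + 1] - c[lo]) / (idx + 1 - lo)


def simulate_device_stream(
    t: np.ndarray,
    sao2: np.ndarray,
    device: DeviceModel,
    annotations: Sequence[TaskAnnotation],
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> SpO2Stream:
    """Apply one device's error model to a true-saturation trajectory.

    The stream equals a trailing moving average of the trajectory plus the
    systematic bias (optionally sloped in saturation) plus i.i.d. Gaussian
    scatter; samples inside annotated task windows receive an extra Gaussian
    artifact perturbation and are dropped (value set missing) with the task's
    dropout probability.  Values are clipped to [0, 100].
    """
    rng = np.random.default_rng(seed)
    n = len(t)
    smoothed = _trailing_mean(np.asarray(sao2, dtype=float), int(round(device.smoothing_window)))
    values = smoothed + device.systematic_bias + device.bias_slope * (smoothed - 90.0)
    values = values + rng.normal(0.0, device.scatter_sd, n)

    dropped = np.zeros(n, dtype=bool)
    for ann in annotations:
        mask = (t >= ann.start) & (t < ann.stop)
        if not mask.any():
            continue
        bias = device.artifact_bias_by_task.get(ann.label, 0.0)
        sd = device.artifact_sd_by_task.get(ann.label, 0.0)
        if bias != 0.0 or sd != 0.0:
            values[mask] += rng.normal(bias, sd, int(mask.sum()))
        p = device.dropout_prob_by_task.get(ann.label, 0.0)
        if p > 0.0:
            dropped |= mask & (rng.random(n) < p)

    values = np.clip(values, 0.0, 100.0)
    samples = tuple(
        (float(ti), None if drop else float(vi)) for ti, vi, drop in zip(t, values, dropped)
    )
    return SpO2Stream(device_id=device.device_id, samples=samples)


def _sample_demographics(rng: np.random.Generator, baseline_sao2: float) -> dict:
    """Pass-through participant descriptors; not used by any metric."""
    sex = str(rng.choice(["female", "male"]))
    height = round(float(rng.normal(1.64 if sex == "female" else 1.77, 0.06)), 2)
    weight = round(float(rng.normal(63.0 if sex == "female" else 78.0, 9.0)), 1)
    return {
        "age": int(rng.integers(20, 61)),
        "sex": sex,
        "height_m": height,
        "weight_kg": weight,
        "skin_type": int(rng.integers(1, 5)),  # Fitzpatrick 1-4
        "baseline_heart_rate": round(float(rng.normal(71.0, 8.0)), 1),
        "baseline_resp_rate": round(float(rng.normal(15.0, 2.0)), 1),
        "baseline_sao2": round(baseline_sao2, 1),
        "systolic_bp": round(float(rng.normal(130.0, 10.0)), 1),
        "diastolic_bp": round(float(rng.normal(75.0, 8.0)), 1),
    }


def simulate_session(
    config: ProtocolConfig,
    devices: Sequence[DeviceModel],
    seed: int | np.random.SeedSequence,
    session_id: str = "S001",
) -> Session:
    """Simulate one complete session for all devices.

    References are placed at each task stop (end-of-task, including the
    at-rest window), optionally at the sit-to-stand midpoint, and at each
    plateau midpoint; each reference value is the trajectory at that instant
    plus analyzer noise ``N(0, abg_analyzer_sd)``.
    """
    if not devices:
        raise ConfigError("at least one device model required")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    traj_seed, ref_seed, demo_seed, *dev_seeds = ss.spawn(3 + len(devices))

    layout = session_layout(config)
    t, sao2 = simulate_sao2_trajectory(config, traj_seed)

    ref_rng = np.random.default_rng(ref_seed)

    def reference_at(when: float, phase: str, label: str, kind: str) -> ReferenceSample:
        value = float(sao2[int(round(when))]) + float(ref_rng.normal(0.0, config.abg_analyzer_sd))
        return ReferenceSample(t=float(when), sao2=float(np.clip(value, 0.0, 100.0)), phase=phase, label=label, kind=kind)

    references = []
    for ann in layout.annotations:
        if config.include_sts_midpoint and ann.label == "STS":
            references.append(
                reference_at(0.5 * (ann.start + ann.stop), "movement", "STS", "mid-task")
            )
        references.append(reference_at(ann.stop, "movement", ann.label, "end-of-task"))
    for plateau in layout.plateaus:
        references.append(reference_at(plateau.midpoint, "hypoxia", plateau.label, "plateau"))
    references.sort(key=lambda r: r.t)

    streams = {
        device.device_id: simulate_device_stream(t, sao2, device, layout.annotations, dev_seed)
        for device, dev_seed in zip(devices, dev_seeds)
    }

    baseline = float(sao2[: int(layout.annotations[0].stop)].mean())
    demographics = _sample_demographics(np.random.default_rng(demo_seed), baseline)

    return Session(
        session_id=session_id,
        demographics=demographics,
        streams=streams,
        annotations=layout.annotations,
        references=tuple(references),
    )


def simulate_study(
    config: ProtocolConfig,
    devices: Sequence[DeviceModel],
    n_participants: int,
    seed: int | np.random.SeedSequence,
) -> StudyDataset:
    """Simulate ``n_participants`` independent sessions; deterministic given seed."""
    if n_participants < 1:
        raise ConfigError("n_participants must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    sessions = tuple(
        simulate_session(config, devices, child, session_id=f"S{i + 1:03d}")
        for i, child in enumerate(ss.spawn(n_participants))
    )
    return StudyDataset(sessions=sessions, devices=tuple(d.device_id for d in devices))


def predicted_hypoxia_residual_sd(device: DeviceModel, config: ProtocolConfig) -> float:
    """Closed-form effective SD of (windowed-median SpO2 - reference SaO2).

    The 40-sample windowed median attenuates the device scatter by roughly
    ``sqrt(pi / (2 n))`` (the asymptotic efficiency of the median of i.i.d.
    Gaussians); plateau noise at the reference instant and analyzer noise pass
    through unattenuated.  Validated empirically against the simulator.
    """
    n_window = int(ALIGNMENT_WINDOW_S)
    w = max(1, int(round(device.smoothing_window)))
    var_median = (math.pi / 2.0) * (device.scatter_sd**2 + config.plateau_noise_sd**2 / w) / n_window
    return math.sqrt(var_median + config.plateau_noise_sd**2 + config.abg_analyzer_sd**2)
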