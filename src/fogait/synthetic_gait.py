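"""Synthetic single-foot IMU recordings with ground-truth gait events.

The generator builds analytic foot trajectories (pitch from two raised-cosine
lobes — a positive heel-off peak followed by a negative pre-contact trough —
and a minimum-jerk horizontal displacement), adds a short high-jerk contact
transient, rotates everything into the sensor frame, adds gravity and noise,
and keeps the analytic kinematics as ground truth. FoG subtypes are emulated
by mode-specific deformations: shuffling (scaled-down pitch and stride),
festination (short fast steps without inter-step rest), shank trembling
(3-8 Hz oscillation without displacement) and akinesia (no motion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_io import AnnotatedEpisode, FogaitError, ImuSeries
from .feature_extraction import FEATURE_NAMES
from .orientation import GRAVITY

__all__ = [
    "GaitProfile",
    "FogScenario",
    "StepRecord",
    "GroundTruth",
    "SimulatedSegment",
    "simulate_step",
    "simulate_recording",
    "simulate_cohort",
]

FOG_MODES = ("shuffling", "festination", "trembling", "akinesia")
ALL_MODES = ("normal", "rest", "turn") + FOG_MODES


@dataclass(frozen=True)
class GaitProfile:
    """Morphology of one simulated step and the sensor noise level."""

    stride_length: float = 0.6      # m
    swing_duration: float = 0.7     # s, toe-off to initial contact
    heel_off_lead: float = 0.15     # s, pitch rise before toe-off
    contact_recovery: float = 0.08  # s, pitch return to flat after contact
    rest_gap: float = 0.5           # s, stillness between steps
    cadence: float | None = None    # steps/min; overrides rest_gap when set
    pitch_amplitude_deg: float = 20.0
    pitch_trough_frac: float = 0.5  # trough depth relative to the peak
    lift_height: float = 0.05       # m, vertical swing clearance
    contact_spike: float = 40.0     # m/s^2, full-sine vertical transient
    contact_spike_duration: float = 0.03  # s
    noise_sd_acc: float = 0.05      # m/s^2
    noise_sd_gyro: float = 0.005    # rad/s

    def __post_init__(self) -> None:
        for name in ("stride_length", "swing_duration", "heel_off_lead",
                     "contact_recovery", "pitch_amplitude_deg"):
            if getattr(self, name) <= 0:
                raise FogaitError(f"{name} must be positive")
        if self.rest_gap < 0 or self.noise_sd_acc < 0 or self.noise_sd_gyro < 0:
            raise FogaitError("rest_gap and noise levels must be non-negative")
        if self.cadence is not None:
            period = 60.0 / self.cadence
            busy = self.heel_off_lead + self.swing_duration + self.contact_recovery
            if period <= busy:
                raise FogaitError(
                    f"cadence {self.cadence}/min infeasible: step period {period:.3f}s "
                    f"shorter than the active phase {busy:.3f}s"
                )
            object.__setattr__(self, "rest_gap", period - busy)

    @property
    def step_period(self) -> float:
        return (self.heel_off_lead + self.swing_duration
                + self.contact_recovery + self.rest_gap)


#: Per-mode profile deformations (applied on top of the caller's profile).
_MODE_SCALES = {
    "shuffling": {"pitch": 0.25, "stride": 0.4, "lift": 0.3},
    "festination": {"pitch": 0.4, "stride": 0.3, "lift": 0.5},
}
# heel-off lead exceeds the unrest debounce (n_r/fs) so even the first fast
# step presents its pitch peak after the unrest transition; period 0.40 s
_FESTINATION_TIMING = dict(heel_off_lead=0.08, swing_duration=0.16,
                           contact_recovery=0.04, rest_gap=0.12, cadence=None)


@dataclass(frozen=True)
class FogScenario:
    """One protocol segment: a walking bout, a FoG episode, a turn or rest."""

    mode: str
    n_steps: int | None = None     # for stepping modes
    duration: float | None = None  # for trembling/akinesia/rest/turn
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ALL_MODES:
            raise FogaitError(f"unknown mode {self.mode!r}; expected one of {ALL_MODES}")
        if self.mode in ("normal", "shuffling", "festination"):
            if not self.n_steps or self.n_steps < 1:
                raise FogaitError(f"mode {self.mode!r} requires n_steps >= 1")
        elif self.duration is None or self.duration <= 0:
            raise FogaitError(f"mode {self.mode!r} requires a positive duration")
        freq = self.params.get("tremble_freq")
        if freq is not None and not (3.0 <= freq <= 8.0):
            raise FogaitError("tremble_freq must lie in [3, 8] Hz")


@dataclass(frozen=True)
class StepRecord:
    """Ground-truth boundary events and geometry of one simulated step."""

    toe_off: float          # s, pitch-maximum time
    initial_contact: float  # s, contact-transient time
    stride_length: float    # m
    swing_duration: float   # s
    mode: str
    fog: bool

    def __post_init__(self) -> None:
        if not self.initial_contact > self.toe_off:
            raise FogaitError("initial contact must follow toe-off")


@dataclass
class GroundTruth:
    steps: list[StepRecord] = field(default_factory=list)
    episodes: list[AnnotatedEpisode] = field(default_factory=list)  # rater="truth"
    turn_angles: list[float] = field(default_factory=list)


@dataclass
class SimulatedSegment:
    """Sensor-frame signals of one segment plus the analytic ground truth."""

    acc: np.ndarray          # (n, 3), sensor frame, gravity + noise included
    gyro: np.ndarray         # (n, 3), sensor frame
    pos_true: np.ndarray     # (n, 3), analytic global position (smooth part)
    vel_true: np.ndarray     # (n, 3)
    acc_lin_true: np.ndarray  # (n, 3), analytic global linear acceleration
    pitch_true: np.ndarray   # (n,), rad
    yaw_true: np.ndarray     # (n,), rad
    step: StepRecord | None  # segment-relative event times
    fog: bool

    @property
    def n(self) -> int:
        return int(self.acc.shape[0])


def _minimum_jerk(tau: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Position, velocity and acceleration shape functions on [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    ds = 30 * tau**2 - 60 * tau**3 + 30 * tau**4
    dds = 60 * tau - 180 * tau**2 + 120 * tau**3
    return s, ds, dds


def _raised_cos(t: np.ndarray, t0: float, t1: float, y0: float, y1: float):
    """Smooth monotone transition y0 -> y1 on [t0, t1]; zero slope at both ends."""
    tau = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
    y = y0 + (y1 - y0) * 0.5 * (1.0 - np.cos(np.pi * tau))
    dy = (y1 - y0) * 0.5 * np.pi / (t1 - t0) * np.sin(np.pi * tau)
    active = (t >= t0) & (t <= t1)
    return np.where(active | (t > t1), y, y0), np.where(active, dy, 0.0)


def _to_sensor_frame(a_global_total: np.ndarray, pitch: np.ndarray,
                     pitch_rate: np.ndarray, yaw: np.ndarray,
                     yaw_rate: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotate global signals into a sensor frame with orientation Rz(yaw)Rx(pitch)."""
    c, s = np.cos(pitch), np.sin(pitch)
    cy, sy = np.cos(yaw), np.sin(yaw)
    # undo yaw, then undo pitch
    ax = cy * a_global_total[:, 0] + sy * a_global_total[:, 1]
    ay = -sy * a_global_total[:, 0] + cy * a_global_total[:, 1]
    az = a_global_total[:, 2]
    acc_sensor = np.column_stack([ax, c * ay + s * az, -s * ay + c * az])
    # body rates of Rz(yaw)Rx(pitch): omega_b = pitch'*ex + Rx^T(yaw'*ez)
    gyro_sensor = np.column_stack([pitch_rate, yaw_rate * s, yaw_rate * c])
    return acc_sensor, gyro_sensor


def simulate_step(
    profile: GaitProfile,
    mode: str = "normal",
    rng: np.random.Generator | None = None,
    fs: float = 200.0,
) -> SimulatedSegment:
    """Simulate one step (or one second of a non-stepping mode) analytically.

    Stepping modes produce a pitch trace with a heel-off maximum at toe-off
    and a pre-contact trough, a minimum-jerk horizontal displacement of the
    true stride length ending at zero velocity, and a zero-net-impulse
    vertical contact transient. Trembling produces a 3-8 Hz oscillation;
    akinesia near-silence.
    """
    rng = rng or np.random.default_rng(0)
    prof = profile
    if mode == "festination":
        prof = replace(prof, **_FESTINATION_TIMING)
    scales = _MODE_SCALES.get(mode, {})
    amp = math.radians(prof.pitch_amplitude_deg) * scales.get("pitch", 1.0)
    stride = prof.stride_length * scales.get("stride", 1.0)
    lift = prof.lift_height * scales.get("lift", 1.0)

    if mode in ("normal", "shuffling", "festination"):
        total = prof.step_period
        n = int(round(total * fs))
        t = np.arange(n) / fs
        lead, swing = prof.heel_off_lead, prof.swing_duration
        t_to = lead                  # toe-off = pitch maximum
        t_ic = lead + swing          # initial contact
        trough = -prof.pitch_trough_frac * amp

        up, dup = _raised_cos(t, 0.0, t_to, 0.0, amp)
        down, ddown = _raised_cos(t, t_to, t_ic, 0.0, trough - amp)
        rec, drec = _raised_cos(t, t_ic, t_ic + prof.contact_recovery, 0.0, -trough)
        pitch = up + down + rec
        pitch_rate = dup + ddown + drec

        tau = (t - t_to) / swing
        s, ds, dds = _minimum_jerk(tau)
        in_swing = (t >= t_to) & (t <= t_ic)
        pos = np.zeros((n, 3))
        vel = np.zeros((n, 3))
        acc_lin = np.zeros((n, 3))
        pos[:, 1] = -stride * s
        vel[:, 1] = np.where(in_swing, -stride * ds / swing, 0.0)
        acc_lin[:, 1] = np.where(in_swing, -stride * dds / swing**2, 0.0)
        # sin^4 lift: acceleration is continuous at the swing boundaries, so
        # double integration of the generated signal is trapezoid-exact
        u = np.pi * np.clip(tau, 0.0, 1.0)
        su, cu = np.sin(u), np.cos(u)
        pos[:, 2] = lift * su**4
        vel[:, 2] = np.where(in_swing, lift * 4 * np.pi / swing * su**3 * cu, 0.0)
        acc_lin[:, 2] = np.where(
            in_swing,
            lift * (np.pi / swing) ** 2 * (12.0 * su**2 * cu**2 - 4.0 * su**4),
            0.0,
        )

        acc_signal = acc_lin.copy()
        # initial-contact transient: one full sine on z, zero net impulse
        d = prof.contact_spike_duration
        in_spike = (t >= t_ic) & (t < t_ic + d)
        acc_signal[:, 2] += np.where(
            in_spike, prof.contact_spike * np.sin(2 * np.pi * (t - t_ic) / d), 0.0
        )
        if mode == "festination":
            # low-amplitude stance vibration keeps the inter-step interval
            # above the rest thresholds without mimicking a new step
            in_stance = t > t_ic + prof.contact_recovery
            acc_signal[:, 2] += np.where(in_stance, 0.8 * np.sin(2 * np.pi * 25.0 * t), 0.0)
        step = StepRecord(
            toe_off=t_to, initial_contact=t_ic, stride_length=stride,
            swing_duration=swing, mode=mode, fog=mode in FOG_MODES,
        )
        fog = mode in FOG_MODES
    elif mode == "trembling":
        total = 1.0
        n = int(round(total * fs))
        t = np.arange(n) / fs
        freq = 5.0
        tremble_amp = math.radians(3.0)
        envelope = np.sin(np.pi * t / total) ** 2  # fades in and out
        pitch = tremble_amp * envelope * np.sin(2 * np.pi * freq * t)
        pitch_rate = np.gradient(pitch, 1.0 / fs)
        pos = np.zeros((n, 3))
        vel = np.zeros((n, 3))
        acc_lin = np.zeros((n, 3))
        acc_lin[:, 2] = 1.5 * envelope * np.sin(2 * np.pi * freq * t)
        acc_signal = acc_lin.copy()
        step, fog = None, True
    elif mode == "akinesia":
        total = 1.0
        n = int(round(total * fs))
        t = np.arange(n) / fs
        pitch = np.zeros(n)
        pitch_rate = np.zeros(n)
        pos = np.zeros((n, 3))
        vel = np.zeros((n, 3))
        acc_lin = np.zeros((n, 3))
        acc_signal = acc_lin.copy()
        step, fog = None, True
    else:
        raise FogaitError(f"simulate_step does not handle mode {mode!r}")

    yaw = np.zeros_like(pitch)
    yaw_rate = np.zeros_like(pitch)
    gravity = np.zeros_like(acc_signal)
    gravity[:, 2] = GRAVITY
    acc_sensor, gyro_sensor = _to_sensor_frame(
        acc_signal + gravity, pitch, pitch_rate, yaw, yaw_rate
    )
    if prof.noise_sd_acc > 0:
        acc_sensor = acc_sensor + rng.normal(0.0, prof.noise_sd_acc, acc_sensor.shape)
    if prof.noise_sd_gyro > 0:
        gyro_sensor = gyro_sensor + rng.normal(0.0, prof.noise_sd_gyro, gyro_sensor.shape)
    return SimulatedSegment(
        acc=acc_sensor, gyro=gyro_sensor, pos_true=pos, vel_true=vel,
        acc_lin_true=acc_lin, pitch_true=pitch, yaw_true=yaw, step=step, fog=fog,
    )


def _still_segment(duration: float, profile: GaitProfile,
                   rng: np.random.Generator, fs: float) -> SimulatedSegment:
    n = int(round(duration * fs))
    zeros3 = np.zeros((n, 3))
    acc = np.tile([0.0, 0.0, GRAVITY], (n, 1))
    gyro = np.zeros((n, 3))
    if profile.noise_sd_acc > 0:
        acc = acc + rng.normal(0.0, profile.noise_sd_acc, acc.shape)
    if profile.noise_sd_gyro > 0:
        gyro = gyro + rng.normal(0.0, profile.noise_sd_gyro, gyro.shape)
    flat = np.zeros(n)
    return SimulatedSegment(acc=acc, gyro=gyro, pos_true=zeros3.copy(),
                            vel_true=zeros3.copy(), acc_lin_true=zeros3.copy(),
                            pitch_true=flat, yaw_true=flat.copy(), step=None, fog=False)


def _turn_segment(duration: float, angle: float, profile: GaitProfile,
                  rng: np.random.Generator, fs: float) -> SimulatedSegment:
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    s, ds, _ = _minimum_jerk(t / duration)
    yaw = angle * s
    yaw_rate = angle * ds / duration
    pitch = np.zeros(n)
    acc_total = np.tile([0.0, 0.0, GRAVITY], (n, 1))
    acc, gyro = _to_sensor_frame(acc_total, pitch, np.zeros(n), yaw, yaw_rate)
    if profile.noise_sd_acc > 0:
        acc = acc + rng.normal(0.0, profile.noise_sd_acc, acc.shape)
    if profile.noise_sd_gyro > 0:
        gyro = gyro + rng.normal(0.0, profile.noise_sd_gyro, gyro.shape)
    zeros3 = np.zeros((n, 3))
    return SimulatedSegment(acc=acc, gyro=gyro, pos_true=zeros3.copy(),
                            vel_true=zeros3.copy(), acc_lin_true=zeros3.copy(),
                            pitch_true=pitch, yaw_true=yaw, step=None, fog=False)


def simulate_recording(
    scenarios: list[FogScenario],
    profile: GaitProfile | None = None,
    seed: int = 1,
    fs: float = 200.0,
    foot: str = "left",
    subject_id: str = "S0",
    lead_in_rest: float = 2.0,
    rater_jitter_sd: float = 0.1,
) -> tuple[ImuSeries, GroundTruth, list[AnnotatedEpisode]]:
    """Concatenate scenario segments into one recording with ground truth.

    The recording opens with ``lead_in_rest`` seconds of stillness so rest
    offsets can settle. Two simulated raters are derived from the true FoG
    episodes by jittering the boundaries with Gaussian noise of
    ``rater_jitter_sd`` seconds. Deterministic for a fixed seed.
    """
    profile = profile or GaitProfile()
    rng = np.random.default_rng(seed)
    segments: list[SimulatedSegment] = []
    truth = GroundTruth()
    t_cursor = 0.0

    def _append(seg: SimulatedSegment) -> None:
        nonlocal t_cursor
        if seg.step is not None:
            truth.steps.append(
                replace(seg.step,
                        toe_off=seg.step.toe_off + t_cursor,
                        initial_contact=seg.step.initial_contact + t_cursor)
            )
        segments.append(seg)
        t_cursor += seg.n / fs

    if lead_in_rest > 0:
        _append(_still_segment(lead_in_rest, profile, rng, fs))

    for scenario in scenarios:
        seg_start = t_cursor
        if scenario.mode in ("normal", "shuffling", "festination"):
            for _ in range(scenario.n_steps):
                _append(simulate_step(profile, scenario.mode, rng, fs))
        elif scenario.mode in ("trembling", "akinesia"):
            remaining = scenario.duration
            while remaining > 1e-9:
                chunk = simulate_step(profile, scenario.mode, rng, fs)
                _append(chunk)
                remaining -= chunk.n / fs
        elif scenario.mode == "turn":
            angle = scenario.params.get("angle", 2.0 * math.pi)
            seg = _turn_segment(scenario.duration, angle, profile, rng, fs)
            _append(seg)
            truth.turn_angles.append(angle)
        elif scenario.mode == "rest":
            _append(_still_segment(scenario.duration, profile, rng, fs))
        if scenario.mode in FOG_MODES:
            truth.episodes.append(
                AnnotatedEpisode(start=seg_start, end=t_cursor,
                                 subtype=scenario.mode, rater="truth")
            )

    acc = np.vstack([s.acc for s in segments])
    gyro = np.vstack([s.gyro for s in segments])
    n = acc.shape[0]
    series = ImuSeries(t=np.arange(n) / fs, acc=acc, gyro=gyro, fs=fs,
                       foot=foot, subject_id=subject_id)

    rater_episodes: list[AnnotatedEpisode] = []
    for rater in ("expert1", "expert2"):
        for e in truth.episodes:
            start = max(0.0, e.start + rng.normal(0.0, rater_jitter_sd))
            end = max(start + 0.05, e.end + rng.normal(0.0, rater_jitter_sd))
            rater_episodes.append(
                AnnotatedEpisode(start=start, end=end, subtype=e.subtype, rater=rater)
            )
    return series, truth, rater_episodes


# ---------------------------------------------------------------------------
# Feature-level cohorts for classifier evaluation
# ---------------------------------------------------------------------------

#: Plausible population mean and spread of each feature in the normal class.
_FEATURE_POPULATION = {
    "max_acc_norm": (8.0, 1.5),
    "max_pitch": (0.35, 0.05),
    "min_pitch": (-0.17, 0.04),
    "stride_length": (0.6, 0.1),
    "max_velocity": (1.2, 0.2),
    "turning_angle": (0.0, 0.3),
    "turned_flag": (0.2, None),   # Bernoulli rate
    "max_turn_rate": (1.0, 0.3),
    "mean_turn_rate": (0.4, 0.15),
    "step_duration": (0.7, 0.1),
}

#: Features depressed in FoG phases (shorter, slower, flatter steps).
_FOG_AFFECTED = ("max_velocity", "stride_length", "step_duration", "max_pitch")


def simulate_cohort(
    n_subjects: int = 16,
    fog_prevalence: float = 0.65,
    effect_size: float = 2.0,
    seed: int = 0,
    n_phases: int = 40,
    label_persistence: float = 0.7,
) -> pd.DataFrame:
    """Feature-level cohort: per-phase feature rows with FoG labels.

    Each subject gets a random gait profile (between-subject variation on
    every feature mean) and two feet with ``n_phases`` motion phases each.
    Labels follow a two-state Markov chain with the requested stationary
    prevalence and persistence; FoG phases shift the affected feature means
    down by ``effect_size`` population standard deviations. With
    ``effect_size=0`` the labels carry no feature signal.
    """
    if n_subjects < 2:
        raise FogaitError("need at least 2 subjects")
    if not 0.0 < fog_prevalence < 1.0:
        raise FogaitError("fog_prevalence must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    p_stay = label_persistence + (1 - label_persistence) * fog_prevalence
    p_enter = (1 - label_persistence) * fog_prevalence

    rows = []
    for si in range(n_subjects):
        subject = f"P{si + 1:02d}"
        subject_shift = {
            name: rng.normal(0.0, 0.3 * sd) if sd is not None else 0.0
            for name, (_, sd) in _FEATURE_POPULATION.items()
        }
        for foot in ("left", "right"):
            label = int(rng.random() < fog_prevalence)
            for k in range(n_phases):
                if k > 0:
                    p = p_stay if label == 1 else p_enter
                    label = int(rng.random() < p)
                row = {}
                for name, (mu, sd) in _FEATURE_POPULATION.items():
                    if sd is None:
                        row[name] = int(rng.random() < mu)
                        continue
                    value = mu + subject_shift[name] + rng.normal(0.0, sd)
                    if label and name in _FOG_AFFECTED:
                        value -= effect_size * sd
                    row[name] = value
                row["stride_length"] = max(row["stride_length"], 0.0)
                row["step_duration"] = max(row["step_duration"], 0.05)
                row["max_velocity"] = max(row["max_velocity"], 0.0)
                row.update(subject_id=subject, foot=foot, label=label,
                           t_end=float(k) + (0.0 if foot == "left" else 0.5))
                rows.append(row)
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES)
                        + ["subject_id", "foot", "label", "t_end"])
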