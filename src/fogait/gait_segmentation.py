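"""Causal rest/unrest/motion gait-phase state machine for a single foot IMU.

The machine partitions a recording into rest and unrest intervals and, inside
unrest, locates motion phases (toe-off to initial contact in healthy gait).
A control flag Z gates the search for a new motion phase inside an ongoing
unrest interval so that step sequences without intermediate rest (festination,
trembling) still yield one motion phase per step.

Condition letters used throughout:

A  rest/unrest transition by debounced thresholds on the detrended norms
B  motion start: pitch local maximum above a bound, or a roll maximum
   correlated in time with a filtered acceleration-norm maximum
D1 initial-contact jerk spike relative to the running jerk maximum
D2 horizontal velocities decayed below a fraction of their running maxima
E  pitch local minimum with bounded roll and bounded |pitch|
F  angular stillness (pitch/roll rates, or angles, below p1)
G  low variance of the acceleration norm
H  pitch local maximum above phi_thres (immediate Z reactivation)
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import FogaitError, GpdParams, ImuSeries
from .orientation import (
    GRAVITY,
    OrientationFilter,
    RestOffsetTracker,
    compute_jerk,
    transform_and_detrend,
)

__all__ = [
    "MotionPhase",
    "PhaseInterval",
    "PhaseSequence",
    "KinematicsTrack",
    "PeakDetector",
    "RestUnrestCondition",
    "MotionStartSearch",
    "MotionPhaseTracker",
    "ZReactivationMonitor",
    "GaitPhaseDetector",
    "segment_recording",
    "phase_sequence_to_json",
    "phase_sequence_from_json",
]

REST = "rest"
UNREST = "unrest"


# ---------------------------------------------------------------------------
# Small causal building blocks
# ---------------------------------------------------------------------------

class PeakDetector:
    """Streaming local-extremum detector.

    An extremum is a sign change of the first difference, confirmed one
    sample later; on plateaus the earliest plateau sample wins. ``update``
    returns ``(t_peak, value)`` on the confirming sample, else ``None``.
    """

    def __init__(self, mode: str = "max"):
        if mode not in ("max", "min"):
            raise ValueError("mode must be 'max' or 'min'")
        self._sign = 1.0 if mode == "max" else -1.0
        self._prev: float | None = None
        self._cand_t: float | None = None
        self._cand_v: float | None = None
        self._rising = False

    def update(self, t: float, value: float) -> tuple[float, float] | None:
        v = self._sign * value
        out = None
        if self._prev is not None:
            if v > self._prev:
                self._rising = True
                self._cand_t, self._cand_v = t, value
            elif v < self._prev:
                if self._rising and self._cand_t is not None:
                    out = (self._cand_t, self._cand_v)
                self._rising = False
                self._cand_t = self._cand_v = None
            # equal: keep the earlier candidate
        else:
            self._cand_t, self._cand_v = t, value
        self._prev = v
        return out


class _MovingStats:
    """Mean/variance over a trailing window (population variance)."""

    def __init__(self, window: int):
        self._buf: deque = deque(maxlen=window)
        self.window = window

    def update(self, value: float) -> None:
        self._buf.append(float(value))

    @property
    def mean(self) -> float:
        return float(np.mean(self._buf)) if self._buf else 0.0

    @property
    def var(self) -> float | None:
        """Variance, or None until the window is full."""
        if len(self._buf) < self.window:
            return None
        return float(np.var(self._buf))


class RestUnrestCondition:
    """Condition A: debounced threshold test on the detrended signal norms.

    Requires ``n_r`` consecutive samples with both norms strictly below
    their bounds for rest, or with either norm at/above its bound for
    unrest (the unrest direction mirrors the rest debounce).
    """

    def __init__(self, params: GpdParams):
        self.params = params
        self.rest_count = 0
        self.unrest_count = 0

    def update(self, a_norm: float, w_norm: float) -> str | None:
        p = self.params
        if a_norm < p.a_rest and w_norm < p.w_rest:
            self.rest_count += 1
            self.unrest_count = 0
        else:
            self.unrest_count += 1
            self.rest_count = 0
        if self.rest_count >= p.n_r:
            return REST
        if self.unrest_count >= p.n_r:
            return UNREST
        return None


@dataclass(frozen=True)
class StartEvent:
    t0: float
    rule: str          # "pitch_max" | "roll_acc_corr"
    pitch_peak: float  # pitch value at the start (rad); NaN for the roll route


class MotionStartSearch:
    """Condition B: locate the start of a motion phase.

    Route (i): a local pitch maximum exceeding ``phi_p``.
    Route (ii): a local roll maximum and a local maximum of the
    ``n_a``-sample moving-average acceleration norm above ``a_s``,
    at most ``delta`` seconds apart.
    """

    def __init__(self, params: GpdParams):
        self.params = params
        self._pitch_peaks = PeakDetector("max")
        self._roll_ma = _MovingStats(params.n_a)  # same smoothing as the acc norm
        self._roll_peaks = PeakDetector("max")
        self._acc_ma = _MovingStats(params.n_a)
        self._acc_peaks = PeakDetector("max")
        self._last_roll_t: float | None = None
        self._last_acc_t: float | None = None

    def clear_pairs(self) -> None:
        """Forget stored roll/acc peaks, e.g. when a motion phase closes."""
        self._last_roll_t = None
        self._last_acc_t = None

    def update(self, t: float, pitch: float, roll: float, acc_norm: float) -> StartEvent | None:
        p = self.params
        event: StartEvent | None = None

        peak = self._pitch_peaks.update(t, pitch)
        if peak is not None and peak[1] > p.phi_p_rad:
            event = StartEvent(t0=peak[0], rule="pitch_max", pitch_peak=peak[1])

        self._acc_ma.update(acc_norm)
        self._roll_ma.update(roll)
        roll_peak = self._roll_peaks.update(t, self._roll_ma.mean)
        acc_peak = self._acc_peaks.update(t, self._acc_ma.mean)
        if roll_peak is not None:
            self._last_roll_t = roll_peak[0]
        if acc_peak is not None and acc_peak[1] > p.a_s:
            self._last_acc_t = acc_peak[0]
        if event is None and self._last_roll_t is not None and self._last_acc_t is not None:
            if abs(self._last_roll_t - self._last_acc_t) <= p.delta:
                t0 = max(self._last_roll_t, self._last_acc_t)
                event = StartEvent(t0=t0, rule="roll_acc_corr", pitch_peak=float("nan"))
                self.clear_pairs()
        return event


@dataclass(frozen=True)
class EndEvent:
    t_end: float
    rule: str  # "jerk_velocity" | "pitch_min"


class MotionPhaseTracker:
    """Per-motion-phase state: strap-down velocity, running maxima, end rules.

    D1 compares the current jerk against ``alpha`` times the maximum jerk
    registered strictly before the current sample; D2 compares the current
    horizontal velocity components against ``beta`` times their running
    maxima (current sample included). Rule E fires on a local pitch minimum
    with bounded roll and |pitch| below ``kappa`` times the running pitch
    maximum of the phase. End checks start only once ``t > t0 + t_mot``.
    """

    def __init__(self, t0: float, pitch0: float, params: GpdParams, fs: float):
        self.t0 = t0
        self.params = params
        self.dt = 1.0 / fs
        self.v = np.zeros(3)
        self.vmax_x = 0.0
        self.vmax_y = 0.0
        self.max_jerk_before = 0.0
        self.pitch_max = pitch0 if math.isfinite(pitch0) else 0.0
        self._pitch_min = PeakDetector("min")
        self._prev_a: np.ndarray | None = None

    def update(self, t: float, a_dg: np.ndarray, jerk: float, pitch: float,
               roll: float) -> EndEvent | None:
        p = self.params
        if self._prev_a is not None:
            self.v = self.v + 0.5 * (self._prev_a + a_dg) * self.dt
        self._prev_a = np.asarray(a_dg, dtype=float)
        self.pitch_max = max(self.pitch_max, pitch)
        self.vmax_x = max(self.vmax_x, abs(float(self.v[0])))
        self.vmax_y = max(self.vmax_y, abs(float(self.v[1])))
        pitch_min = self._pitch_min.update(t, pitch)

        event: EndEvent | None = None
        if t > self.t0 + p.t_mot:
            d1 = jerk > p.alpha * self.max_jerk_before and self.max_jerk_before > 0.0
            d2 = (
                abs(float(self.v[0])) < p.beta * self.vmax_x
                and abs(float(self.v[1])) < p.beta * self.vmax_y
            )
            if d1 and d2:
                event = EndEvent(t_end=t, rule="jerk_velocity")
            elif (
                pitch_min is not None
                and abs(roll) < p.phi_r_rad
                and abs(pitch_min[1]) < p.kappa * self.pitch_max
            ):
                event = EndEvent(t_end=pitch_min[0], rule="pitch_min")
        self.max_jerk_before = max(self.max_jerk_before, jerk)
        return event


@dataclass(frozen=True)
class ZEvent:
    rule: str                  # "F" | "G" | "H"
    t_peak: float | None       # pitch-peak time for rule H
    peak_value: float | None   # pitch-peak value for rule H


class ZReactivationMonitor:
    """Conditions F/G/H re-enabling the motion-phase search.

    Armed after each motion-phase end; F and G must hold for ``n_r``
    consecutive samples starting no earlier than ``t_x`` after the motion
    end, H (pitch maximum above ``phi_thres``) fires immediately.
    F compares angular rates (default) or angles against ``p1`` depending
    on ``params.f_mode``.
    """

    def __init__(self, params: GpdParams, fs: float):
        self.params = params
        self.fs = fs
        self._pitch_peaks = PeakDetector("max")
        self._acc_stats = _MovingStats(params.n_r)
        self._prev_pitch: float | None = None
        self._prev_roll: float | None = None
        self._armed_since: float | None = None
        self._count_f = 0
        self._count_g = 0

    def arm(self, t_end: float) -> None:
        self._armed_since = t_end
        self._count_f = 0
        self._count_g = 0

    def disarm(self) -> None:
        self._armed_since = None

    def update(self, t: float, pitch: float, roll: float, acc_norm: float) -> ZEvent | None:
        p = self.params
        pitch_rate = (pitch - self._prev_pitch) * self.fs if self._prev_pitch is not None else 0.0
        roll_rate = (roll - self._prev_roll) * self.fs if self._prev_roll is not None else 0.0
        self._prev_pitch, self._prev_roll = pitch, roll
        self._acc_stats.update(acc_norm)
        peak = self._pitch_peaks.update(t, pitch)

        if self._armed_since is None or t < self._armed_since + p.t_x:
            return None

        if peak is not None and peak[1] > p.phi_thres_rad:
            return ZEvent(rule="H", t_peak=peak[0], peak_value=peak[1])

        if p.f_mode == "rate":
            f_holds = abs(pitch_rate) < p.p1_rad and abs(roll_rate) < p.p1_rad
        else:
            f_holds = abs(pitch) < math.radians(p.p1) and abs(roll) < math.radians(p.p1)
        self._count_f = self._count_f + 1 if f_holds else 0

        var = self._acc_stats.var
        g_holds = var is not None and var < p.p2
        self._count_g = self._count_g + 1 if g_holds else 0

        if self._count_f >= p.n_r:
            return ZEvent(rule="F", t_peak=None, peak_value=None)
        if self._count_g >= p.n_r:
            return ZEvent(rule="G", t_peak=None, peak_value=None)
        return None


# ---------------------------------------------------------------------------
# Output types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotionPhase:
    """One motion phase: half-open interval inside an unrest interval."""

    t_start: float
    t_end: float
    start_rule: str   # "pitch_max" | "roll_acc_corr"
    end_rule: str     # "jerk_velocity" | "pitch_min" | "truncated"

    def __post_init__(self) -> None:
        if self.t_end < self.t_start:
            raise FogaitError(
                f"motion phase end {self.t_end} precedes start {self.t_start}"
            )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class PhaseInterval:
    phase: str        # "rest" | "unrest"
    t_start: float
    t_end: float
    motion_phases: list[MotionPhase] = field(default_factory=list)
    z_reactivations: int = 0


@dataclass
class PhaseSequence:
    """Segmentation result: rest/unrest tiling plus nested motion phases."""

    intervals: list[PhaseInterval]
    fs: float
    n_samples: int
    z_trace: np.ndarray  # bool per sample: Z active

    @property
    def motion_phases(self) -> list[MotionPhase]:
        return [m for iv in self.intervals for m in iv.motion_phases]

    def sample_labels(self) -> np.ndarray:
        """Per-sample phase label array (values "rest"/"unrest")."""
        labels = np.empty(self.n_samples, dtype=object)
        dt = 1.0 / self.fs
        for iv in self.intervals:
            lo = int(round(iv.t_start / dt))
            hi = int(round(iv.t_end / dt))
            labels[lo:hi] = iv.phase
        return labels

    def rest_duration(self) -> float:
        return sum(iv.t_end - iv.t_start for iv in self.intervals if iv.phase == REST)


@dataclass
class KinematicsTrack:
    """Per-sample kinematics retained for feature extraction."""

    t: np.ndarray
    euler_d: np.ndarray   # (n, 3): roll, pitch, yaw, rad
    a_dg: np.ndarray      # (n, 3)
    w_dg: np.ndarray      # (n, 3)
    jerk: np.ndarray      # (n,)

    def segment(self, t_start: float, t_end: float) -> "KinematicsTrack":
        mask = (self.t >= t_start - 1e-12) & (self.t <= t_end + 1e-12)
        return KinematicsTrack(
            t=self.t[mask],
            euler_d=self.euler_d[mask],
            a_dg=self.a_dg[mask],
            w_dg=self.w_dg[mask],
            jerk=self.jerk[mask],
        )


# ---------------------------------------------------------------------------
# The state machine
# ---------------------------------------------------------------------------

class GaitPhaseDetector:
    """Single-pass causal detector; feed samples via :meth:`step`.

    The orientation filter, rest-offset estimation and jerk computation run
    inline, so the detector consumes raw sensor-frame samples.
    """

    def __init__(self, params: GpdParams, fs: float, z_reactivation: bool = True):
        self.params = params
        self.fs = fs
        self.dt = 1.0 / fs
        self.z_reactivation = z_reactivation

        self._filter = OrientationFilter()
        self._offset_tracker = RestOffsetTracker(params.n_d)
        self._cond_a = RestUnrestCondition(params)
        self._search = MotionStartSearch(params)
        self._zmon = ZReactivationMonitor(params, fs)
        self._tracker: MotionPhaseTracker | None = None

        self.phase = REST
        self.z_active = False
        self._k = 0
        self._prev_a_dg: np.ndarray | None = None
        self._interval_start = 0.0
        self._interval_motions: list[MotionPhase] = []
        self._interval_z_count = 0
        self.intervals: list[PhaseInterval] = []
        self._z_trace: list[bool] = []
        self._kin_rows: list[tuple] = []

    # -- internal helpers ---------------------------------------------------

    def _close_interval(self, t: float) -> None:
        if t > self._interval_start:
            self.intervals.append(
                PhaseInterval(
                    phase=self.phase,
                    t_start=self._interval_start,
                    t_end=t,
                    motion_phases=self._interval_motions,
                    z_reactivations=self._interval_z_count,
                )
            )
        self._interval_start = t
        self._interval_motions = []
        self._interval_z_count = 0

    def _start_motion(self, event: StartEvent) -> None:
        t0 = max(event.t0, self._interval_start)
        self._tracker = MotionPhaseTracker(t0, event.pitch_peak, self.params, self.fs)
        self._start_rule = event.rule
        self._zmon.disarm()

    def _end_motion(self, event: EndEvent) -> None:
        assert self._tracker is not None
        self._interval_motions.append(
            MotionPhase(
                t_start=self._tracker.t0,
                t_end=event.t_end,
                start_rule=self._start_rule,
                end_rule=event.rule,
            )
        )
        self._tracker = None
        self.z_active = False
        self._search.clear_pairs()
        self._zmon.arm(event.t_end)

    # -- public API ---------------------------------------------------------

    @property
    def in_motion(self) -> bool:
        return self._tracker is not None

    def step(self, acc: np.ndarray, gyro: np.ndarray) -> None:
        t = self._k * self.dt
        q = self._filter.update(acc, gyro, self.dt)
        kin = transform_and_detrend(acc, gyro, q, self._offset_tracker.offsets)
        jerk = (
            compute_jerk(self._prev_a_dg, kin.a_dg, self.dt)
            if self._prev_a_dg is not None
            else 0.0
        )
        self._prev_a_dg = kin.a_dg
        a_norm = float(np.linalg.norm(kin.a_dg))
        w_norm = float(np.linalg.norm(kin.w_dg))

        transition = self._cond_a.update(a_norm, w_norm)
        if transition == UNREST and self.phase == REST:
            self._close_interval(t)
            self.phase = UNREST
            self.z_active = True
            self._search = MotionStartSearch(self.params)
            self._zmon = ZReactivationMonitor(self.params, self.fs)
        elif transition == REST and self.phase == UNREST and not self.in_motion:
            self._close_interval(t)
            self.phase = REST
            self.z_active = False

        # offsets learned only in rest; gravity removed before averaging.
        # samples already above the rest bounds are excluded so that the
        # trailing window does not ingest movement onset during the debounce
        a_lin = kin.a_g - np.array([0.0, 0.0, GRAVITY])
        quiet = a_norm < self.params.a_rest and w_norm < self.params.w_rest
        self._offset_tracker.update(a_lin, kin.w_g, kin.euler,
                                    self.phase == REST and quiet)

        pitch, roll = kin.pitch_d, kin.roll_d
        if self.phase == UNREST:
            start_event = self._search.update(t, pitch, roll, a_norm)
            z_event = self._zmon.update(t, pitch, roll, a_norm) if self.z_reactivation else None
            if self.in_motion:
                end_event = self._tracker.update(t, kin.a_dg, jerk, pitch, roll)
                if end_event is not None:
                    self._end_motion(end_event)
            elif self.z_active:
                if start_event is not None:
                    self._start_motion(start_event)
            elif z_event is not None:
                self.z_active = True
                self._interval_z_count += 1
                self._search.clear_pairs()  # the new search starts fresh
                if z_event.rule == "H":
                    # the reactivating pitch peak itself marks the next start
                    self._start_motion(
                        StartEvent(t0=z_event.t_peak, rule="pitch_max",
                                   pitch_peak=z_event.peak_value)
                    )

        self._z_trace.append(self.z_active)
        self._kin_rows.append((t, kin.euler_d, kin.a_dg, kin.w_dg, jerk))
        self._k += 1

    def finalize(self) -> tuple[PhaseSequence, KinematicsTrack]:
        if self._k == 0:
            raise FogaitError("no samples processed")
        t_end = self._k * self.dt
        if self.in_motion:
            assert self._tracker is not None
            self._interval_motions.append(
                MotionPhase(
                    t_start=self._tracker.t0,
                    t_end=t_end - self.dt,
                    start_rule=self._start_rule,
                    end_rule="truncated",
                )
            )
            self._tracker = None
        self._close_interval(t_end)
        seq = PhaseSequence(
            intervals=self.intervals,
            fs=self.fs,
            n_samples=self._k,
            z_trace=np.array(self._z_trace, dtype=bool),
        )
        track = KinematicsTrack(
            t=np.array([r[0] for r in self._kin_rows]),
            euler_d=np.array([r[1] for r in self._kin_rows]),
            a_dg=np.array([r[2] for r in self._kin_rows]),
            w_dg=np.array([r[3] for r in self._kin_rows]),
            jerk=np.array([r[4] for r in self._kin_rows]),
        )
        return seq, track


def segment_recording(
    series: ImuSeries,
    params: GpdParams | None = None,
    z_reactivation: bool = True,
    return_kinematics: bool = False,
):
    """Segment a recording into rest/unrest intervals and motion phases.

    Deterministic, causal, single pass. Raises on recordings shorter than
    ``n_r`` samples.
    """
    params = params or GpdParams()
    if len(series) < params.n_r:
        raise FogaitError(
            f"recording of {len(series)} samples is shorter than n_r={params.n_r}"
        )
    detector = GaitPhaseDetector(params, series.fs, z_reactivation=z_reactivation)
    for k in range(len(series)):
        detector.step(series.acc[k], series.gyro[k])
    seq, track = detector.finalize()
    return (seq, track) if return_kinematics else seq


# ---------------------------------------------------------------------------
# JSON export
# ---------------------------------------------------------------------------

def phase_sequence_to_json(seq: PhaseSequence, path: str | Path | None = None) -> str:
    payload = {
        "fs": seq.fs,
        "n_samples": seq.n_samples,
        "intervals": [
            {
                "phase": iv.phase,
                "t_start": iv.t_start,
                "t_end": iv.t_end,
                "z_reactivations": iv.z_reactivations,
                "motion_phases": [
                    {
                        "t_start": m.t_start,
                        "t_end": m.t_end,
                        "start_rule": m.start_rule,
                        "end_rule": m.end_rule,
                    }
                    for m in iv.motion_phases
                ],
            }
            for iv in seq.intervals
        ],
        "z_trace": [bool(z) for z in seq.z_trace],
    }
    text = json.dumps(payload, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def phase_sequence_from_json(source: str | Path) -> PhaseSequence:
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = source
    payload = json.loads(text)
    intervals = [
        PhaseInterval(
            phase=iv["phase"],
            t_start=iv["t_start"],
            t_end=iv["t_end"],
            z_reactivations=iv.get("z_reactivations", 0),
            motion_phases=[MotionPhase(**m) for m in iv["motion_phases"]],
        )
        for iv in payload["intervals"]
    ]
    return PhaseSequence(
        intervals=intervals,
        fs=payload["fs"],
        n_samples=payload["n_samples"],
        z_trace=np.array(payload["z_trace"], dtype=bool),
    )
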