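"""Spatio-temporal features of completed motion phases.

Ten features per phase, in fixed order: maximum acceleration norm, maximum
and minimum pitch, stride length, maximum horizontal gait velocity, turning
angle, turned flag, maximum and average turn rate, and step duration.
Stride and velocity come from strap-down integration of the detrended
global acceleration with a zero-end-velocity drift correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import cumulative_trapezoid

from .data_io import FogaitError
from .gait_segmentation import KinematicsTrack, MotionPhase

__all__ = [
    "FEATURE_NAMES",
    "VARIANT_LAGS",
    "RELEVANCE_THRESHOLD",
    "FeatureRow",
    "integrate_motion_velocity",
    "correct_velocity_drift",
    "detect_turning",
    "extract_features",
    "extract_feature_table",
    "importance_from_p",
    "rank_features",
    "build_design_matrix",
]

#: Canonical feature order; every table and matrix uses this ordering.
FEATURE_NAMES = (
    "max_acc_norm",
    "max_pitch",
    "min_pitch",
    "stride_length",
    "max_velocity",
    "turning_angle",
    "turned_flag",
    "max_turn_rate",
    "mean_turn_rate",
    "step_duration",
)

#: Lag structure of the classifier input variants. Lag 0 is the phase being
#: labeled; negative lags are preceding phases of the same subject and foot.
VARIANT_LAGS = {"C0": (0,), "C210": (0, -1, -2), "C21": (-1, -2)}

#: Importance above this marks a feature as relevant (p < 0.05).
RELEVANCE_THRESHOLD = -math.log10(0.05)


@dataclass(frozen=True)
class FeatureRow:
    max_acc_norm: float
    max_pitch: float
    min_pitch: float
    stride_length: float
    max_velocity: float
    turning_angle: float
    turned_flag: int
    max_turn_rate: float
    mean_turn_rate: float
    step_duration: float
    subject_id: str = "S0"
    foot: str = "left"
    t_end: float = 0.0

    def __post_init__(self) -> None:
        if self.step_duration <= 0:
            raise FogaitError("step_duration must be positive")
        if self.turned_flag not in (0, 1):
            raise FogaitError("turned_flag must be 0 or 1")
        if self.stride_length < 0:
            raise FogaitError("stride_length must be non-negative")
        if self.max_pitch < self.min_pitch:
            raise FogaitError("max_pitch must be >= min_pitch")

    def values(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    def to_dict(self) -> dict:
        out = {n: getattr(self, n) for n in FEATURE_NAMES}
        out.update(subject_id=self.subject_id, foot=self.foot, t_end=self.t_end)
        return out


def integrate_motion_velocity(a_dg: np.ndarray, dt: float) -> np.ndarray:
    """Strap-down velocity: cumulative trapezoidal integral with v(t0) = 0."""
    a_dg = np.asarray(a_dg, dtype=float)
    if a_dg.ndim != 2 or a_dg.shape[0] == 0:
        raise FogaitError("expected a non-empty (n, 3) acceleration segment")
    if dt <= 0:
        raise FogaitError("dt must be positive")
    return cumulative_trapezoid(a_dg, dx=dt, axis=0, initial=0.0)


def correct_velocity_drift(v: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Enforce zero end velocity by subtracting a per-axis linear ramp.

    Returns the corrected velocity series and the stride vector (x, y): the
    integral of the corrected horizontal velocity over the phase. The ramp's
    own integral is thereby excluded from the stride.
    """
    v = np.asarray(v, dtype=float)
    n = v.shape[0]
    if n < 2:
        return v.copy(), np.zeros(2)
    ramp = np.linspace(0.0, 1.0, n)[:, None] * v[-1][None, :]
    v_corr = v - ramp
    displacement = np.trapezoid(v_corr, dx=dt, axis=0)
    return v_corr, displacement[:2]


def detect_turning(
    yaw: np.ndarray,
    eps_yaw: float = math.radians(1.0),
    smooth_window: int = 5,
) -> tuple[int, float]:
    """Classify a motion phase as turning from its yaw trace.

    The yaw series is referenced to the phase start and unwrapped. The phase
    counts as a turn when the (lightly smoothed) yaw evolves monotonically —
    drawdown from the running extreme stays below ``eps_yaw`` — and never
    re-crosses zero after leaving the ``eps_yaw`` band. The turning angle,
    the net yaw at the phase end, is always reported.
    """
    yaw = np.unwrap(np.asarray(yaw, dtype=float))
    yaw = yaw - yaw[0]
    angle = float(yaw[-1])
    if yaw.size < 3:
        return 0, angle
    if smooth_window > 1 and yaw.size > smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        smooth = np.convolve(yaw, kernel, mode="valid")
    else:
        smooth = yaw
    direction = 1.0 if angle >= 0 else -1.0
    signed = direction * smooth
    drawdown = float(np.max(np.maximum.accumulate(signed) - signed))
    monotone = drawdown <= eps_yaw
    left_band = np.nonzero(np.abs(smooth) > eps_yaw)[0]
    recrossed = False
    if left_band.size:
        after = signed[left_band[0]:]
        recrossed = bool(np.any(after < -eps_yaw))
    turned = int(monotone and not recrossed and abs(angle) > eps_yaw)
    return turned, angle


def extract_features(
    track: KinematicsTrack,
    phase: MotionPhase,
    subject_id: str = "S0",
    foot: str = "left",
) -> FeatureRow:
    """Compute the 10 features of one completed motion phase.

    ``track`` may span the whole recording; it is sliced to the phase.
    """
    seg = track.segment(phase.t_start, phase.t_end)
    if seg.t.size < 2:
        raise FogaitError(
            f"motion phase [{phase.t_start}, {phase.t_end}] has fewer than 2 samples"
        )
    dt = float(np.median(np.diff(seg.t)))
    acc_norm = np.linalg.norm(seg.a_dg, axis=1)
    pitch = seg.euler_d[:, 1]
    yaw = np.unwrap(seg.euler_d[:, 2])

    v = integrate_motion_velocity(seg.a_dg, dt)
    v_corr, stride_vec = correct_velocity_drift(v, dt)
    horizontal_speed = np.linalg.norm(v_corr[:, :2], axis=1)

    turned, turning_angle = detect_turning(yaw)
    yaw_rate = np.abs(np.gradient(yaw, dt))

    return FeatureRow(
        max_acc_norm=float(np.max(acc_norm)),
        max_pitch=float(np.max(pitch)),
        min_pitch=float(np.min(pitch)),
        stride_length=float(np.linalg.norm(stride_vec)),
        max_velocity=float(np.max(horizontal_speed)),
        turning_angle=turning_angle,
        turned_flag=turned,
        max_turn_rate=float(np.max(yaw_rate)),
        mean_turn_rate=float(np.mean(yaw_rate)),
        step_duration=float(phase.t_end - phase.t_start),
        subject_id=subject_id,
        foot=foot,
        t_end=float(phase.t_end),
    )


def extract_feature_table(track, phases, subject_id="S0", foot="left") -> pd.DataFrame:
    """One row per motion phase, ordered by phase end time."""
    rows = [extract_features(track, ph, subject_id, foot).to_dict() for ph in phases]
    frame = pd.DataFrame(rows, columns=list(FEATURE_NAMES) + ["subject_id", "foot", "t_end"])
    return frame.sort_values("t_end", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Chi-square feature ranking
# ---------------------------------------------------------------------------

def importance_from_p(p: float) -> float:
    """Importance score of a p-value: -log10(p), floored at 0 for p >= 1."""
    p = max(float(p), 5e-324)
    return max(-math.log10(p), 0.0)


def rank_features(
    frame: pd.DataFrame,
    labels: np.ndarray,
    n_bins: int = 10,
    feature_names=FEATURE_NAMES,
) -> pd.DataFrame:
    """Univariate chi-square ranking of features against a binary label.

    Continuous features are discretized into ``n_bins`` quantile bins; a
    chi-square test of independence on the bin-by-label contingency table
    gives the p-value and importance = -log10(p). Features above
    :data:`RELEVANCE_THRESHOLD` are marked relevant. Returns a table sorted
    by descending importance.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2 or min(np.bincount(labels.astype(int))) < 2:
        raise FogaitError("need at least 2 samples per class for ranking")
    records = []
    for name in feature_names:
        x = np.asarray(frame[name], dtype=float)
        if np.all(x == x[0]):
            warnings.warn(f"feature {name!r} is constant; importance set to 0")
            records.append((name, 0.0, 1.0, 0.0, False))
            continue
        if len(np.unique(x)) <= n_bins:
            bins = x  # already discrete (e.g. a flag)
        else:
            bins = pd.qcut(x, q=n_bins, labels=False, duplicates="drop")
        table = pd.crosstab(bins, labels)
        if table.shape[0] < 2:
            warnings.warn(f"feature {name!r} collapsed to one bin; importance set to 0")
            records.append((name, 0.0, 1.0, 0.0, False))
            continue
        chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
        imp = importance_from_p(p)
        records.append((name, float(chi2), float(p), imp, imp > RELEVANCE_THRESHOLD))
    out = pd.DataFrame(records, columns=["feature", "chi2", "p_value", "importance", "relevant"])
    return out.sort_values("importance", ascending=False, kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Design matrices with lagged phases
# ---------------------------------------------------------------------------

def build_design_matrix(
    frame: pd.DataFrame,
    variant: str,
    label_column: str = "label",
    feature_names=FEATURE_NAMES,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Stack lagged feature rows per (subject, foot) sequence.

    Rows are ordered by phase end time within each subject/foot group; lag
    stacking never crosses a group boundary, and rows lacking the required
    predecessors are dropped. The label is always taken from the lag-0
    phase, so the ``C21`` variant predicts a phase from its two
    predecessors only.

    Returns ``(X, y, meta)`` where meta holds subject_id, foot and t_end of
    each lag-0 phase.
    """
    if variant not in VARIANT_LAGS:
        raise FogaitError(f"unknown variant {variant!r}; expected one of {list(VARIANT_LAGS)}")
    lags = VARIANT_LAGS[variant]
    max_back = -min(min(lags), 0)
    X_rows, y_rows, meta_rows = [], [], []
    for (subject, foot), group in frame.groupby(["subject_id", "foot"], sort=True):
        group = group.sort_values("t_end", kind="stable").reset_index(drop=True)
        values = group[list(feature_names)].to_numpy(dtype=float)
        for i in range(max_back, len(group)):
            X_rows.append(np.concatenate([values[i + lag] for lag in lags]))
            y_rows.append(group[label_column].iloc[i])
            meta_rows.append((subject, foot, float(group["t_end"].iloc[i])))
    if not X_rows:
        warnings.warn(f"variant {variant}: no rows have the required predecessors")
        n_cols = len(lags) * len(feature_names)
        return (np.empty((0, n_cols)), np.empty((0,), dtype=int),
                pd.DataFrame(columns=["subject_id", "foot", "t_end"]))
    meta = pd.DataFrame(meta_rows, columns=["subject_id", "foot", "t_end"])
    return np.vstack(X_rows), np.asarray(y_rows, dtype=int), meta


def design_column_names(variant: str, feature_names=FEATURE_NAMES) -> list[str]:
    """Column labels matching :func:`build_design_matrix` output order."""
    return [
        name if lag == 0 else f"{name}_lag{lag}"
        for lag in VARIANT_LAGS[variant]
        for name in feature_names
    ]
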