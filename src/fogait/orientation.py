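"""Foot-orientation estimation and global-frame kinematics.

Conventions
-----------
Sensor at rest is aligned with the global frame: z up, y pointing opposite
to the walking direction, x mediolateral (right-handed). Euler angles are
intrinsic z-y'-x'': yaw about z, roll about the foot's longitudinal y axis,
pitch about the mediolateral x axis. Pitch is positive when the heel is
above the toes.

Quaternions are unit, scalar-first ``(w, x, y, z)`` and map sensor-frame
vectors into the global frame.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .data_io import FogaitError

__all__ = [
    "GRAVITY",
    "KinematicsSample",
    "RestOffsets",
    "RestOffsetTracker",
    "OrientationFilter",
    "quat_multiply",
    "quat_rotate",
    "quat_from_rotvec",
    "quat_to_euler",
    "update_orientation",
    "transform_and_detrend",
    "update_rest_offsets",
    "compute_jerk",
]

GRAVITY = 9.81  # m/s^2

_IDENTITY_Q = np.array([1.0, 0.0, 0.0, 0.0])


def quat_multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Hamilton product p ∘ q (scalar-first)."""
    pw, px, py, pz = p
    qw, qx, qy, qz = q
    return np.array(
        [
            pw * qw - px * qx - py * qy - pz * qz,
            pw * qx + px * qw + py * qz - pz * qy,
            pw * qy - px * qz + py * qw + pz * qx,
            pw * qz + px * qy - py * qx + pz * qw,
        ]
    )


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector v by quaternion q (sensor -> global for the state q)."""
    w, x, y, z = q
    u = np.array([x, y, z])
    return v + 2.0 * np.cross(u, np.cross(u, v) + w * v)


def quat_from_rotvec(rv: np.ndarray) -> np.ndarray:
    """Quaternion of a rotation vector (axis * angle, rad)."""
    angle = float(np.linalg.norm(rv))
    if angle < 1e-12:
        # second-order small-angle expansion keeps unit norm to ~1e-24
        half = 0.5 * np.asarray(rv, dtype=float)
        return _normalize(np.concatenate(([1.0 - 0.5 * (angle * 0.5) ** 2], half)))
    axis = np.asarray(rv, dtype=float) / angle
    half = 0.5 * angle
    return np.concatenate(([np.cos(half)], np.sin(half) * axis))


def _normalize(q: np.ndarray) -> np.ndarray:
    norm = float(np.linalg.norm(q))
    if norm < 1e-12:
        raise FogaitError("quaternion collapsed to zero norm")
    return q / norm


def quat_to_euler(q: np.ndarray) -> np.ndarray:
    """Euler angles ``(roll, pitch, yaw)`` of q under the z-y'-x'' convention.

    Returned order matches :class:`KinematicsSample.euler`: roll about y
    (longitudinal), pitch about x (mediolateral), yaw about z.
    """
    w, x, y, z = q
    # rotation-matrix elements needed for the ZYX factorization
    r00 = 1.0 - 2.0 * (y * y + z * z)
    r10 = 2.0 * (x * y + w * z)
    r20 = 2.0 * (x * z - w * y)
    r21 = 2.0 * (y * z + w * x)
    r22 = 1.0 - 2.0 * (x * x + y * y)
    yaw = np.arctan2(r10, r00)
    roll = -np.arcsin(np.clip(r20, -1.0, 1.0))
    pitch = np.arctan2(r21, r22)
    return np.array([roll, pitch, yaw])


@dataclass
class KinematicsSample:
    """Per-sample derived state in the global frame."""

    q: np.ndarray
    euler: np.ndarray          # (roll, pitch, yaw), rad
    a_g: np.ndarray            # global acceleration, gravity included, m/s^2
    w_g: np.ndarray            # global angular rate, rad/s
    a_dg: np.ndarray           # detrended gravity-free global acceleration
    w_dg: np.ndarray           # detrended global angular rate
    euler_d: np.ndarray        # detrended Euler angles, rad
    jerk: float = 0.0          # ||d a_dg / dt||, m/s^3
    v: np.ndarray | None = None  # strap-down velocity, valid inside motion only

    @property
    def pitch_d(self) -> float:
        return float(self.euler_d[1])

    @property
    def roll_d(self) -> float:
        return float(self.euler_d[0])

    @property
    def yaw_d(self) -> float:
        return float(self.euler_d[2])


@dataclass(frozen=True)
class RestOffsets:
    """Rest-phase offsets; frozen while the machine is outside rest."""

    acc_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gyro_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    euler_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    window: int = 10


class OrientationFilter:
    """Gyro strap-down with complementary accelerometer inclination correction.

    The correction rotates the estimate about a horizontal axis toward the
    measured gravity direction, so heading (yaw) stays unconstrained. The
    time constant ``tau`` sets static convergence (~2 s at the default);
    the correction is soft-gated off when the accelerometer norm departs
    from gravity, i.e. during dynamic motion.
    """

    def __init__(self, tau: float = 0.5, accel_weight: float = 1.0,
                 gate_width: float = 1.0, rate_gate: float = 0.3,
                 q0: np.ndarray | None = None):
        if tau <= 0:
            raise ValueError("tau must be positive")
        self.tau = tau
        self.accel_weight = accel_weight
        self.gate_width = gate_width
        self.rate_gate = rate_gate
        self.q = _normalize(np.array(q0, dtype=float)) if q0 is not None else _IDENTITY_Q.copy()

    def update(self, acc: np.ndarray, gyro: np.ndarray, dt: float) -> np.ndarray:
        self.q = update_orientation(
            self.q, acc, gyro, dt,
            tau=self.tau, accel_weight=self.accel_weight,
            gate_width=self.gate_width, rate_gate=self.rate_gate,
        )
        return self.q


def update_orientation(
    prev_q: np.ndarray,
    acc: np.ndarray,
    gyro: np.ndarray,
    dt: float,
    tau: float = 0.5,
    accel_weight: float = 1.0,
    gate_width: float = 1.0,
    rate_gate: float = 0.3,
) -> np.ndarray:
    """One fusion step: integrate the gyro, then tilt-correct toward gravity.

    Parameters
    ----------
    prev_q : unit quaternion (sensor -> global).
    acc, gyro : sensor-frame specific force (m/s^2) and rate (rad/s).
    dt : time step, s (> 0).
    tau : complementary time constant, s.
    accel_weight : scale on the correction; 0 gives pure gyro integration.
    gate_width : m/s^2 scale over which the correction fades when
        ``| ||acc|| - g |`` grows.
    rate_gate : rad/s scale over which the correction fades at high angular
        rate, leaving fast motion to the gyro alone.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    gyro = np.asarray(gyro, dtype=float)
    acc = np.asarray(acc, dtype=float)
    q = quat_multiply(np.asarray(prev_q, dtype=float), quat_from_rotvec(gyro * dt))
    acc_norm = float(np.linalg.norm(acc))
    if accel_weight > 0.0 and acc_norm > 1e-9:
        # gravity direction predicted vs measured, compared in the global frame
        g_est = quat_rotate(q, acc / acc_norm)
        axis = np.cross(g_est, np.array([0.0, 0.0, 1.0]))  # horizontal axis
        sin_err = float(np.linalg.norm(axis))
        if sin_err > 1e-12:
            angle = float(np.arctan2(sin_err, float(g_est[2])))
            gate = float(np.exp(-((acc_norm - GRAVITY) / gate_width) ** 2))
            gate *= float(np.exp(-(float(np.linalg.norm(gyro)) / rate_gate) ** 2))
            gain = accel_weight * gate * min(dt / tau, 1.0)
            corr = quat_from_rotvec(axis / sin_err * (gain * angle))
            q = quat_multiply(corr, q)  # left-multiply: global-frame correction
    return _normalize(q)


def transform_and_detrend(
    acc: np.ndarray,
    gyro: np.ndarray,
    q: np.ndarray,
    offsets: RestOffsets,
    remove_gravity: bool = True,
) -> KinematicsSample:
    """Rotate sensor signals into the global frame and subtract rest offsets.

    Gravity (0, 0, g) is removed from the rotated acceleration before the
    offset subtraction when ``remove_gravity`` is set, so ``a_dg`` is a
    gravity-free linear acceleration suitable for strap-down integration.
    """
    acc = np.asarray(acc, dtype=float)
    gyro = np.asarray(gyro, dtype=float)
    a_g = quat_rotate(q, acc)
    w_g = quat_rotate(q, gyro)
    euler = quat_to_euler(q)
    a_lin = a_g - np.array([0.0, 0.0, GRAVITY]) if remove_gravity else a_g
    return KinematicsSample(
        q=np.array(q, dtype=float),
        euler=euler,
        a_g=a_g,
        w_g=w_g,
        a_dg=a_lin - offsets.acc_offset,
        w_dg=w_g - offsets.gyro_offset,
        euler_d=euler - offsets.euler_offset,
    )


class RestOffsetTracker:
    """Moving-average offset estimator fed only while the machine rests."""

    def __init__(self, window: int):
        if window < 1:
            raise ValueError("window must be >= 1")
        self.window = window
        self._acc: deque = deque(maxlen=window)
        self._gyro: deque = deque(maxlen=window)
        self._euler: deque = deque(maxlen=window)
        self.offsets = RestOffsets(window=window)

    def update(self, a_lin_g: np.ndarray, w_g: np.ndarray, euler: np.ndarray,
               in_rest: bool) -> RestOffsets:
        """Push one global-frame sample; the mean refreshes only in rest."""
        if in_rest:
            self._acc.append(np.asarray(a_lin_g, dtype=float))
            self._gyro.append(np.asarray(w_g, dtype=float))
            self._euler.append(np.asarray(euler, dtype=float))
            self.offsets = RestOffsets(
                acc_offset=np.mean(self._acc, axis=0),
                gyro_offset=np.mean(self._gyro, axis=0),
                euler_offset=np.mean(self._euler, axis=0),
                window=self.window,
            )
        return self.offsets


def update_rest_offsets(tracker: RestOffsetTracker, a_lin_g, w_g, euler,
                        in_rest: bool) -> RestOffsets:
    """Functional wrapper around :meth:`RestOffsetTracker.update`."""
    return tracker.update(a_lin_g, w_g, euler, in_rest)


def compute_jerk(a_dg_prev: np.ndarray, a_dg_curr: np.ndarray, dt: float) -> float:
    """Jerk norm by first-order backward difference of the detrended acceleration."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    diff = np.asarray(a_dg_curr, dtype=float) - np.asarray(a_dg_prev, dtype=float)
    return float(np.linalg.norm(diff) / dt)
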