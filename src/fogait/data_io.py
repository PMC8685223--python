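"""Reading and writing of IMU recordings, annotations, parameters and feature tables.

All on-disk formats are plain text: CSV for signals/annotations/features,
YAML or JSON for parameter overrides. Angles in configuration files are
degrees; everything internal is radians.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FogaitError",
    "ParseError",
    "SamplingError",
    "ValidationError",
    "ImuSeries",
    "AnnotatedEpisode",
    "GpdParams",
    "FOG_SUBTYPES",
    "read_imu_recording",
    "write_imu_recording",
    "read_annotations",
    "write_annotations",
    "load_gpd_params",
    "read_feature_table",
    "write_feature_table",
]

#: Expert-annotated freezing-of-gait subtypes.
FOG_SUBTYPES = ("festination", "shuffling", "trembling", "akinesia")

#: Sampling-grid uniformity tolerance in seconds.
_T_TOL = 1e-6

_IMU_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")


class FogaitError(Exception):
    """Base class for all package errors."""


class ParseError(FogaitError):
    """Malformed file content; carries a line number where possible."""


class SamplingError(FogaitError):
    """Timestamps violate the uniform-sampling contract."""


class ValidationError(FogaitError):
    """A value violates a domain-type invariant."""


@dataclass(frozen=True)
class ImuSeries:
    """Uniformly sampled 6-channel inertial recording of one foot.

    Attributes
    ----------
    t : ndarray, shape (n,)
        Seconds from recording start, strictly increasing on a constant grid.
    acc : ndarray, shape (n, 3)
        Linear acceleration in the sensor frame, m/s^2, gravity included.
    gyro : ndarray, shape (n, 3)
        Angular rate in the sensor frame, rad/s.
    fs : float
        Sampling rate in Hz.
    foot : str
        ``"left"`` or ``"right"``.
    subject_id : str
        Opaque subject identifier.
    """

    t: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    fs: float
    foot: str = "left"
    subject_id: str = "S0"

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        acc = np.asarray(self.acc, dtype=float)
        gyro = np.asarray(self.gyro, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "acc", acc)
        object.__setattr__(self, "gyro", gyro)
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if acc.shape != (t.size, 3) or gyro.shape != (t.size, 3):
            raise ValidationError(
                f"acc/gyro shapes {acc.shape}/{gyro.shape} do not match t ({t.size},)"
            )
        if self.foot not in ("left", "right"):
            raise ValidationError(f"foot must be 'left' or 'right', got {self.foot!r}")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                k = int(np.argmax(dt <= 0))
                raise SamplingError(
                    f"timestamps not strictly increasing at sample {k + 1} (t={t[k + 1]!r})"
                )
            if np.any(np.abs(dt - 1.0 / self.fs) > _T_TOL):
                k = int(np.argmax(np.abs(dt - 1.0 / self.fs) > _T_TOL))
                raise SamplingError(
                    f"non-uniform sampling at sample {k + 1}: dt={dt[k]:.9f}, "
                    f"expected {1.0 / self.fs:.9f}"
                )

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0


@dataclass(frozen=True)
class AnnotatedEpisode:
    """One expert-annotated FoG episode: half-open interval ``[start, end)``."""

    start: float
    end: float
    subtype: str
    rater: str = "expert1"

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValidationError(
                f"episode end ({self.end}) must exceed start ({self.start})"
            )
        if self.subtype not in FOG_SUBTYPES:
            raise ValidationError(
                f"unknown subtype {self.subtype!r}; expected one of {FOG_SUBTYPES}"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, time: float) -> bool:
        """Half-open containment test: ``start <= time < end``."""
        return self.start <= time < self.end


@dataclass(frozen=True)
class GpdParams:
    """Thresholds and counters of the gait-phase-detection state machine.

    Angle-valued thresholds (``phi_p``, ``phi_r``, ``phi_thres``) and the
    stillness bound ``p1`` are stored in degrees (resp. deg/s) as configured;
    use the ``*_rad`` properties inside the pipeline.
    """

    a_rest: float = 0.5        # m/s^2, rest bound on ||a_dg||
    w_rest: float = 0.11       # rad/s, rest bound on ||w_dg||
    delta: float = 0.25        # s, max lag between roll and acc-norm peaks
    n_r: int = 10              # samples, debounce count
    phi_p: float = 1.0         # deg, min pitch-peak height for motion start
    phi_r: float = 5.0         # deg, roll bound in the pitch-minimum end rule
    a_s: float = 2.0           # m/s^2, min filtered acc-norm peak height
    t_x: float = 0.1           # s, no-rest window after a motion end
    n_a: int = 7               # samples, acc-norm moving-average width
    alpha: float = 1.2         # jerk-spike factor over the running maximum
    beta: float = 0.6          # velocity fraction at initial contact
    kappa: float = 0.8         # pitch-minimum bound relative to the pitch max
    p1: float = 0.75           # deg/s (or deg, see f_mode), stillness bound
    p2: float = 1.5            # variance bound on the acceleration norm
    phi_thres: float = 15.0    # deg, pitch-peak height re-activating Z
    t_mot: float = 0.075       # s, min motion-phase duration before end checks
    n_d: int = 10              # samples, rest-offset moving-average width
    f_mode: str = "rate"       # stillness check compares angular rates ("rate")
                               # or angles ("angle") against p1

    def __post_init__(self) -> None:
        for name in (
            "a_rest", "w_rest", "delta", "phi_p", "phi_r", "a_s", "t_x",
            "alpha", "beta", "kappa", "p1", "p2", "phi_thres", "t_mot",
        ):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise ValidationError(f"{name} must be a positive finite number, got {value!r}")
        for name in ("n_r", "n_a", "n_d"):
            value = getattr(self, name)
            if not (isinstance(value, int) and value > 0):
                raise ValidationError(f"{name} must be a positive integer, got {value!r}")
        if not self.alpha > 1:
            raise ValidationError(f"alpha must exceed 1, got {self.alpha}")
        if not self.beta < 1:
            raise ValidationError(f"beta must lie in (0, 1), got {self.beta}")
        if not self.kappa <= 1:
            raise ValidationError(f"kappa must lie in (0, 1], got {self.kappa}")
        if self.f_mode not in ("rate", "angle"):
            raise ValidationError(f"f_mode must be 'rate' or 'angle', got {self.f_mode!r}")

    @property
    def phi_p_rad(self) -> float:
        return math.radians(self.phi_p)

    @property
    def phi_r_rad(self) -> float:
        return math.radians(self.phi_r)

    @property
    def phi_thres_rad(self) -> float:
        return math.radians(self.phi_thres)

    @property
    def p1_rad(self) -> float:
        """p1 converted from degrees (per second) to radians (per second)."""
        return math.radians(self.p1)

    def replace(self, **overrides) -> "GpdParams":
        return dataclasses.replace(self, **overrides)


# ---------------------------------------------------------------------------
# IMU recording CSV
# ---------------------------------------------------------------------------

def _parse_header(line: str) -> tuple[float, float]:
    """Return (acc_scale, gyro_scale) implied by a units header line.

    The header carries units in square brackets, e.g.
    ``t[s],ax[m/s^2],...,gx[rad/s],...``. A gyro unit of ``deg/s`` triggers
    conversion to rad/s on read.
    """
    names = [c.split("[")[0].strip() for c in line.strip().split(",")]
    if tuple(names) != _IMU_COLUMNS:
        raise ParseError(
            f"line 1: expected columns {','.join(_IMU_COLUMNS)}, got {line.strip()!r}"
        )
    gyro_scale = 1.0
    cells = line.strip().split(",")
    for cell in cells[4:7]:
        if "[" in cell:
            unit = cell.split("[", 1)[1].rstrip("]").strip().lower()
            if unit in ("deg/s", "°/s"):
                gyro_scale = math.pi / 180.0
            elif unit not in ("rad/s", ""):
                raise ParseError(f"line 1: unsupported gyro unit {unit!r}")
    return 1.0, gyro_scale


def read_imu_recording(
    path: str | Path,
    fs_expected: float | None = None,
    foot: str = "left",
    subject_id: str = "S0",
) -> ImuSeries:
    """Read a 7-column CSV (t, ax, ay, az, gx, gy, gz) with one units header line.

    Gyro columns declared in deg/s are converted to rad/s. The sampling rate
    is inferred from the time grid unless ``fs_expected`` is given, in which
    case the grid must match it within 1e-6 s per step.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header:
            raise ParseError(f"{path}: empty file")
        _, gyro_scale = _parse_header(header)
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            cells = line.split(",")
            if len(cells) != 7:
                raise ParseError(f"{path}: line {lineno}: expected 7 fields, got {len(cells)}")
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    if not rows:
        raise ParseError(f"{path}: no data rows")
    data = np.asarray(rows, dtype=float)
    t = data[:, 0]
    if fs_expected is not None:
        fs = float(fs_expected)
    elif t.size >= 2:
        fs = 1.0 / float(np.median(np.diff(t)))
    else:
        raise SamplingError(f"{path}: cannot infer fs from a single sample")
    return ImuSeries(
        t=t,
        acc=data[:, 1:4],
        gyro=data[:, 4:7] * gyro_scale,
        fs=fs,
        foot=foot,
        subject_id=subject_id,
    )


def write_imu_recording(series: ImuSeries, path: str | Path) -> None:
    """Write an :class:`ImuSeries` as CSV; round-trips through
    :func:`read_imu_recording` to better than 1e-9 relative error."""
    path = Path(path)
    header = "t[s],ax[m/s^2],ay[m/s^2],az[m/s^2],gx[rad/s],gy[rad/s],gz[rad/s]"
    data = np.column_stack([series.t, series.acc, series.gyro])
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for row in data:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> list[AnnotatedEpisode]:
    """Read FoG episode annotations (CSV: start,end,subtype,rater), sorted by start."""
    frame = pd.read_csv(path, dtype={"subtype": str, "rater": str})
    required = {"start", "end", "subtype", "rater"}
    if not required.issubset(frame.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(frame.columns))}")
    episodes = [
        AnnotatedEpisode(
            start=float(row.start),
            end=float(row.end),
            subtype=str(row.subtype),
            rater=str(row.rater),
        )
        for row in frame.itertuples(index=False)
    ]
    return sorted(episodes, key=lambda e: (e.start, e.end))


def write_annotations(episodes: Sequence[AnnotatedEpisode], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(e.start, e.end, e.subtype, e.rater) for e in episodes],
        columns=["start", "end", "subtype", "rater"],
    )
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

def load_gpd_params(path: str | Path | None = None) -> GpdParams:
    """Return defaults, optionally overridden by a YAML/JSON mapping of fields."""
    if path is None:
        return GpdParams()
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        overrides = json.loads(text)
    else:
        overrides = yaml.safe_load(text)
    if overrides is None:
        return GpdParams()
    if not isinstance(overrides, dict):
        raise ParseError(f"{path}: expected a mapping of parameter overrides")
    valid = {f.name for f in dataclasses.fields(GpdParams)}
    unknown = set(overrides) - valid
    if unknown:
        raise ValidationError(f"{path}: unknown parameters {sorted(unknown)}")
    for name in ("n_r", "n_a", "n_d"):
        if name in overrides:
            overrides[name] = int(overrides[name])
    return GpdParams(**overrides)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def write_feature_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
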