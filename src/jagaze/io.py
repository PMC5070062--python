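"""Reading and writing gaze logs, task configuration and participant metadata.

Coordinate convention (used everywhere in the package): screen pixels with the
origin at the top-left corner, x increasing rightward, y increasing downward,
half-open screen bounds ``[0, width_px) x [0, height_px)``.

Canonical gaze CSV dialect: comma-separated UTF-8 with header
``t_ms,x_px,y_px,valid_l,valid_r``; one row per 120 Hz sample.  Invalid samples
(neither eye tracked, blinks, off-screen gaze) carry sentinel coordinates that
must never enter event detection; they are identified by the validity flags.
"""

from __future__ import annotations

import io as _stdio
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, FormatError

CANONICAL_COLUMNS = ("t_ms", "x_px", "y_px", "valid_l", "valid_r")

#: per-component calibration criterion, degrees of visual angle
CALIBRATION_MAX_DEV_DEG = 2.0


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical screen layout needed for pixel <-> visual-angle conversion.

    The visual angle subtended by a physical extent ``s`` (cm) at viewing
    distance ``d`` (cm) is ``2*atan(s / (2*d))``.
    """

    width_px: int
    height_px: int
    width_cm: float
    height_cm: float
    viewing_distance_cm: float

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_cm", "height_cm",
                     "viewing_distance_cm"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"ScreenGeometry.{name} must be positive")

    @property
    def cm_per_px_x(self) -> float:
        return self.width_cm / self.width_px

    @property
    def cm_per_px_y(self) -> float:
        return self.height_cm / self.height_px

    def extent_deg_x(self, extent_px: float) -> float:
        """Visual angle (degrees) of a horizontal pixel extent."""
        cm = extent_px * self.cm_per_px_x
        return math.degrees(2.0 * math.atan2(cm, 2.0 * self.viewing_distance_cm))

    def extent_deg_y(self, extent_px: float) -> float:
        cm = extent_px * self.cm_per_px_y
        return math.degrees(2.0 * math.atan2(cm, 2.0 * self.viewing_distance_cm))


#: 22-inch 16:10 monitor at 50 cm, the geometry the packaged task layout assumes
DEFAULT_GEOMETRY = ScreenGeometry(
    width_px=1680, height_px=1050, width_cm=47.4, height_cm=29.6,
    viewing_distance_cm=50.0,
)


@dataclass(frozen=True)
class GazeSample:
    """A single gaze sample. Bulk data is held as a DataFrame; this type exists
    for clarity at API boundaries and in tests."""

    t_ms: float
    x_px: float
    y_px: float
    valid_l: bool
    valid_r: bool

    @property
    def valid(self) -> bool:
        return self.valid_l or self.valid_r


@dataclass
class GazeRecording:
    """A participant's gaze stream plus the context needed to analyse it.

    ``samples`` is a DataFrame with the canonical columns.  Timestamps are
    milliseconds since recording start and strictly increasing.
    """

    participant_id: str
    group: str  # "ASD" | "TD"
    covariate: float  # nonverbal developmental score used as ANCOVA covariate
    samples: pd.DataFrame
    geometry: ScreenGeometry
    sample_rate_hz: float = 120.0

    def __post_init__(self) -> None:
        if self.group not in ("ASD", "TD"):
            raise DataError(f"unknown group {self.group!r}")
        if not np.isfinite(self.covariate):
            raise DataError("covariate must be finite")
        if len(self.samples) < 1:
            raise DataError("recording must contain at least one sample")
        t = self.samples["t_ms"].to_numpy()
        if np.any(np.diff(t) <= 0):
            row = int(np.argmax(np.diff(t) <= 0)) + 1
            raise DataError(f"timestamps not strictly increasing at row {row}")


@dataclass(frozen=True)
class CalibrationResult:
    rms_deg: float
    passed: bool

    def __post_init__(self) -> None:
        if self.rms_deg < 0:
            raise DataError("rms_deg must be non-negative")


def compute_calibration_rms(
    deviations: Sequence[tuple[float, float]],
    max_dev_deg: float = CALIBRATION_MAX_DEV_DEG,
) -> CalibrationResult:
    """Calibration quality from per-point (dx, dy) deviations in degrees.

    The RMS pools the x and y components of every calibration point:
    ``sqrt(mean(dx_i^2 and dy_i^2))``.  The pass criterion is per-component:
    every ``|dx|`` and ``|dy|`` must be below ``max_dev_deg``.
    """
    arr = np.asarray(deviations, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one deviation pair")
    if arr.ndim != 2 or arr.shape[1] != 2 or not np.all(np.isfinite(arr)):
        raise ValueError("deviations must be finite (dx, dy) pairs")
    rms = float(np.sqrt(np.mean(arr**2)))
    passed = bool(np.max(np.abs(arr)) < max_dev_deg)
    return CalibrationResult(rms_deg=rms, passed=passed)


# ---------------------------------------------------------------------------
# canonical gaze CSV


def _format_gaze_frame(df: pd.DataFrame) -> str:
    buf = _stdio.StringIO()
    buf.write(",".join(CANONICAL_COLUMNS) + "\n")
    t = df["t_ms"].to_numpy(float)
    x = df["x_px"].to_numpy(float)
    y = df["y_px"].to_numpy(float)
    vl = df["valid_l"].to_numpy(int)
    vr = df["valid_r"].to_numpy(int)
    for i in range(len(df)):
        buf.write(f"{t[i]:.4f},{x[i]:.2f},{y[i]:.2f},{vl[i]:d},{vr[i]:d}\n")
    return buf.getvalue()


def write_gaze_csv(rec: GazeRecording, path: str | Path) -> None:
    """Write the samples of a recording in the canonical dialect."""
    Path(path).write_text(_format_gaze_frame(rec.samples), encoding="utf-8")


def read_gaze_csv(
    path: str | Path,
    geometry: ScreenGeometry,
    *,
    participant_id: str = "",
    group: str = "TD",
    covariate: float = 0.0,
    sample_rate_hz: float = 120.0,
) -> GazeRecording:
    """Read a canonical gaze CSV into a :class:`GazeRecording`.

    Malformed rows raise :class:`FormatError` (missing columns) or
    :class:`DataError` (unparseable values, non-monotone timestamps) naming the
    first offending data row (1-based, excluding the header).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df[list(CANONICAL_COLUMNS)]
    out = {}
    for col in CANONICAL_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 1
            raise DataError(f"{path}: malformed value in column {col!r} at row {row}")
        out[col] = vals.to_numpy(float)
    t = out["t_ms"]
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 2
        raise DataError(f"{path}: non-monotone timestamp at row {row}")
    frame = pd.DataFrame(
        {
            "t_ms": t,
            "x_px": out["x_px"],
            "y_px": out["y_px"],
            "valid_l": out["valid_l"].astype(int),
            "valid_r": out["valid_r"].astype(int),
        }
    )
    return GazeRecording(
        participant_id=participant_id or path.stem,
        group=group,
        covariate=covariate,
        samples=frame,
        geometry=geometry,
        sample_rate_hz=sample_rate_hz,
    )


# ---------------------------------------------------------------------------
# SMI-like raw export shim

_SMI_COLUMNS = {
    "time": "Time",
    "lx": "L POR X [px]",
    "ly": "L POR Y [px]",
    "rx": "R POR X [px]",
    "ry": "R POR Y [px]",
    "lval": "L Validity",
    "rval": "R Validity",
}


def read_smi_txt(
    path: str | Path,
    geometry: ScreenGeometry,
    **kwargs,
) -> GazeRecording:
    """Read a tab-separated SMI-style raw export and map it onto the canonical
    dialect.

    Binocular combination: average the two points of regard when both eyes are
    valid, use the valid eye when only one is, and mark the sample invalid when
    neither is.  SMI times are microseconds; they are rebased to ms from the
    first sample.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [v for v in _SMI_COLUMNS.values() if v not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    t_us = df[_SMI_COLUMNS["time"]].to_numpy(float)
    t_ms = (t_us - t_us[0]) / 1000.0
    lx = df[_SMI_COLUMNS["lx"]].to_numpy(float)
    ly = df[_SMI_COLUMNS["ly"]].to_numpy(float)
    rx = df[_SMI_COLUMNS["rx"]].to_numpy(float)
    ry = df[_SMI_COLUMNS["ry"]].to_numpy(float)
    lv = df[_SMI_COLUMNS["lval"]].to_numpy(float) > 0
    rv = df[_SMI_COLUMNS["rval"]].to_numpy(float) > 0
    x = np.zeros(len(df))
    y = np.zeros(len(df))
    both = lv & rv
    x[both] = (lx[both] + rx[both]) / 2.0
    y[both] = (ly[both] + ry[both]) / 2.0
    only_l = lv & ~rv
    x[only_l], y[only_l] = lx[only_l], ly[only_l]
    only_r = rv & ~lv
    x[only_r], y[only_r] = rx[only_r], ry[only_r]
    frame = pd.DataFrame(
        {
            "t_ms": t_ms,
            "x_px": x,
            "y_px": y,
            "valid_l": lv.astype(int),
            "valid_r": rv.astype(int),
        }
    )
    geometry_kwargs = dict(kwargs)
    return GazeRecording(
        participant_id=geometry_kwargs.pop("participant_id", path.stem),
        group=geometry_kwargs.pop("group", "TD"),
        covariate=geometry_kwargs.pop("covariate", 0.0),
        samples=frame,
        geometry=geometry,
        **geometry_kwargs,
    )


# ---------------------------------------------------------------------------
# participant metadata

METADATA_COLUMNS = ("participant_id", "group", "covariate")


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    """Read the participant metadata table (``participant_id,group,covariate``)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    bad_groups = set(df["group"]) - {"ASD", "TD"}
    if bad_groups:
        raise DataError(f"{path}: unknown group labels {sorted(bad_groups)}")
    if not np.all(np.isfinite(df["covariate"].to_numpy(float))):
        raise DataError(f"{path}: non-finite covariate")
    return df[list(METADATA_COLUMNS)]


def write_metadata_csv(df: pd.DataFrame, path: str | Path) -> None:
    df[list(METADATA_COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# task / AOI configuration


def load_task_config(path: str | Path):
    """Load and validate a study task configuration (JSON).

    Returns a :class:`jagaze.trials.StudyDesign`.  Schema violations raise
    :class:`ConfigError` listing the offending paths.
    """
    from .trials import StudyDesign, study_design_from_dict

    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: invalid JSON: {exc}") from exc
    return study_design_from_dict(payload, source=str(path))


def default_task_config_path() -> Path:
    """Path of the packaged default task configuration."""
    return Path(__file__).parent / "data" / "default_tasks.json"


def load_default_design():
    return load_task_config(default_task_config_path())
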