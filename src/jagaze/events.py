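"""Fixation detection (dispersion-based), AOI assignment and transition extraction.

Fixations are detected with I-DT semantics: a fixation is a maximal, greedily
grown window of valid on-screen samples whose bounding-box dispersion (the sum
of the horizontal and vertical visual-angle extents) stays within a ceiling,
and whose time span (last minus first sample time) reaches the minimum
duration.  Runs of invalid samples up to 75 ms inside a window are bridged;
longer gaps terminate it.  The scan is left-to-right: from each start index the
window is extended as far as dispersion and gap constraints allow; if the
resulting span is long enough a fixation is emitted and the scan resumes after
it, otherwise the start advances by one sample.  This greedy-maximal rule is
deterministic and is checked against an exhaustive brute-force oracle in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import GazeRecording, ScreenGeometry

AOI_NAMES = ("face", "target", "non_target")

DEFAULT_DISPERSION_MAX_DEG = 1.0
DEFAULT_MIN_DURATION_MS = 60.0
DEFAULT_MAX_GAP_MS = 75.0


@dataclass(frozen=True)
class Fixation:
    onset_ms: float
    offset_ms: float
    cx_px: float
    cy_px: float
    aoi: str = "none"  # face | target | non_target | none

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class AOI:
    """A named half-open screen rectangle [x0, x1) x [y0, y1)."""

    name: str
    rect: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.rect
        if not (x0 < x1 and y0 < y1):
            raise ConfigError(f"AOI {self.name!r}: degenerate rect {self.rect}")

    def contains(self, x: float, y: float) -> bool:
        x0, y0, x1, y1 = self.rect
        return (x0 <= x < x1) and (y0 <= y < y1)

    @property
    def center(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.rect
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)


class AOISet:
    """The AOIs of one trial; rectangles must be pairwise disjoint and names unique."""

    def __init__(self, aois: Iterable[AOI]):
        self.aois = tuple(aois)
        names = [a.name for a in self.aois]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate AOI names: {names}")
        for a in self.aois:
            if a.name not in AOI_NAMES:
                raise ConfigError(f"unknown AOI name {a.name!r}")
        for i, a in enumerate(self.aois):
            for b in self.aois[i + 1:]:
                if _rects_overlap(a.rect, b.rect):
                    raise ConfigError(
                        f"AOIs {a.name!r} and {b.name!r} overlap: {a.rect} / {b.rect}"
                    )

    def __iter__(self):
        return iter(self.aois)

    def __getitem__(self, name: str) -> AOI:
        for a in self.aois:
            if a.name == name:
                return a
        raise KeyError(name)

    def label(self, x: float, y: float) -> str:
        for a in self.aois:
            if a.contains(x, y):
                return a.name
        return "none"


def _rects_overlap(r1, r2) -> bool:
    ax0, ay0, ax1, ay1 = r1
    bx0, by0, bx1, by1 = r2
    return (ax0 < bx1 and bx0 < ax1) and (ay0 < by1 and by0 < ay1)


@dataclass(frozen=True)
class Transition:
    """An ordered move between two distinct AOIs; ``t_ms`` is the onset of the
    destination fixation."""

    from_aoi: str
    to_aoi: str
    t_ms: float

    def __post_init__(self) -> None:
        if self.from_aoi == self.to_aoi:
            raise ValueError("transition endpoints must differ")
        if "none" in (self.from_aoi, self.to_aoi):
            raise ValueError("transitions connect real AOIs only")


# ---------------------------------------------------------------------------
# detection


def _valid_arrays(samples: pd.DataFrame, geometry: ScreenGeometry):
    t = samples["t_ms"].to_numpy(float)
    x = samples["x_px"].to_numpy(float)
    y = samples["y_px"].to_numpy(float)
    valid = (samples["valid_l"].to_numpy() != 0) | (samples["valid_r"].to_numpy() != 0)
    onscreen = (
        (x >= 0) & (x < geometry.width_px) & (y >= 0) & (y < geometry.height_px)
    )
    keep = valid & onscreen
    return t[keep], x[keep], y[keep]


def detect_fixations(
    samples: pd.DataFrame | GazeRecording,
    geometry: ScreenGeometry | None = None,
    dispersion_max_deg: float = DEFAULT_DISPERSION_MAX_DEG,
    min_duration_ms: float = DEFAULT_MIN_DURATION_MS,
    max_gap_ms: float = DEFAULT_MAX_GAP_MS,
) -> list[Fixation]:
    """Detect fixations in a time-ordered sample stream.

    ``samples`` may be a recording (geometry taken from it) or a canonical
    sample DataFrame plus an explicit geometry.  Invalid or off-screen samples
    never enter dispersion or centroid computations; they only matter through
    the gap rule.  An empty stream yields an empty list.
    """
    if isinstance(samples, GazeRecording):
        geometry = samples.geometry
        samples = samples.samples
    if geometry is None:
        raise ValueError("geometry required when passing a bare sample frame")
    t, x, y = _valid_arrays(samples, geometry)
    n = len(t)
    if n == 0:
        return []

    # dispersion(dx_px, dy_px) <= ceiling, in degrees; atan is monotone so we
    # evaluate it per candidate extension (cheap: two atans per step).
    ext_x = geometry.extent_deg_x
    ext_y = geometry.extent_deg_y

    fixations: list[Fixation] = []
    i = 0
    while i < n:
        j = i
        minx = maxx = x[i]
        miny = maxy = y[i]
        while j + 1 < n and (t[j + 1] - t[j]) <= max_gap_ms:
            nminx = min(minx, x[j + 1])
            nmaxx = max(maxx, x[j + 1])
            nminy = min(miny, y[j + 1])
            nmaxy = max(maxy, y[j + 1])
            if ext_x(nmaxx - nminx) + ext_y(nmaxy - nminy) > dispersion_max_deg:
                break
            minx, maxx, miny, maxy = nminx, nmaxx, nminy, nmaxy
            j += 1
        if t[j] - t[i] >= min_duration_ms:
            fixations.append(
                Fixation(
                    onset_ms=float(t[i]),
                    offset_ms=float(t[j]),
                    cx_px=float(np.mean(x[i:j + 1])),
                    cy_px=float(np.mean(y[i:j + 1])),
                )
            )
            i = j + 1
        else:
            i += 1
    return fixations


def assign_aoi(fix: Fixation, aois: AOISet) -> Fixation:
    """Label a fixation with the AOI containing its centroid (half-open bounds)."""
    return replace(fix, aoi=aois.label(fix.cx_px, fix.cy_px))


def assign_aois(fixations: Sequence[Fixation], aois: AOISet) -> list[Fixation]:
    return [assign_aoi(f, aois) for f in fixations]


def extract_transitions(fixations: Sequence[Fixation]) -> list[Transition]:
    """Ordered AOI-to-AOI moves between consecutive AOI-labelled fixations.

    Fixations labelled ``none`` are transparent: they are skipped rather than
    breaking the chain.  Consecutive fixations on the same AOI emit nothing.
    """
    labelled = [f for f in fixations if f.aoi != "none"]
    out: list[Transition] = []
    for prev, cur in zip(labelled, labelled[1:]):
        if prev.aoi != cur.aoi:
            out.append(Transition(prev.aoi, cur.aoi, cur.onset_ms))
    return out


def first_look(fixations: Sequence[Fixation]) -> str:
    """AOI of the first fixation landing on either object; face looks before it
    are ignored.  Returns ``'target'``, ``'non_target'`` or ``'neither'``."""
    for f in fixations:
        if f.aoi in ("target", "non_target"):
            return f.aoi
    return "neither"
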