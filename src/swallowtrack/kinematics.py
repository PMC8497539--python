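"""From pixel tracks to a per-session marker distance in millimeters.

The session statistic is built in four steps: (1) calibrate mm per pixel
from the known sticker diameter (5 mm) as it appears in the first frame;
(2) average the y coordinate of the recognized markers in each frame —
unrecognized markers are simply excluded, which makes the trajectory
robust to dropout; (3) cut the trajectory into the three guided swallows
(fixed guide-voice schedule, or automatic pulse detection); (4) each
swallow's excursion is max - min of the mean trajectory in mm, and the
session distance is the median of the three excursions (the median, not
the mean, so one corrupted swallow cannot dominate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .vision import MarkerTrack

#: guide-voice swallow windows (seconds) for the 36 s protocol
DEFAULT_SCHEDULE = ((8.0, 14.0), (18.0, 24.0), (28.0, 34.0))


@dataclass(frozen=True)
class CalibrationScale:
    """Pixel-to-mm conversion from an object of known physical size."""

    mm_per_px: float
    source_diameter_mm: float
    source_diameter_px: float

    def __post_init__(self):
        if self.source_diameter_px <= 0:
            raise ValueError("source diameter in px must be positive")
        expected = self.source_diameter_mm / self.source_diameter_px
        if not np.isclose(self.mm_per_px, expected, rtol=1e-9):
            raise ValueError("mm_per_px inconsistent with source diameters")


@dataclass(frozen=True)
class SwallowSegment:
    """Half-open frame range [start, end) of one guided swallow."""

    index: int
    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.index <= 3):
            raise ValueError("swallow index must be 1..3")
        if self.end <= self.start or self.start < 0:
            raise ValueError(f"invalid frame range [{self.start}, {self.end})")


@dataclass
class SessionDistance:
    """One subject-session scalar: median over swallows of the excursion."""

    subject: str
    timepoint: str
    excursions_mm: tuple[float, float, float]
    distance_mm: float
    scale_mm_per_px: float
    gap_fraction: float = 0.0


def estimate_scale(tracks: Sequence[MarkerTrack],
                   marker_diameter_mm: float = 5.0) -> CalibrationScale:
    """Calibrate mm/px from first-frame marker diameters.

    The sticker diameter is known in mm; its apparent diameter in pixels is
    taken as the mean equivalent diameter over markers recognized in the
    first frame (averaging damps single-marker segmentation error).
    """
    if marker_diameter_mm <= 0:
        raise ValueError("marker_diameter_mm must be positive")
    diams = [t.diameter_px[0] for t in tracks
             if t.recognized[0] and t.diameter_px[0] > 0]
    if not diams:
        raise ValueError("no marker recognized in the first frame; "
                         "cannot calibrate scale")
    d_px = float(np.mean(diams))
    return CalibrationScale(mm_per_px=marker_diameter_mm / d_px,
                            source_diameter_mm=marker_diameter_mm,
                            source_diameter_px=d_px)


def mean_trajectory(tracks: Sequence[MarkerTrack],
                    center: bool = True) -> tuple[np.ndarray, float]:
    """Dropout-robust mean y trajectory (px) and the gap fraction.

    Per frame, the arithmetic mean of y over recognized markers only
    (unrecognized markers are excluded, not imputed).  With ``center=True``
    (default) each marker's y is first referenced to its own session rest
    position (median of its recognized y), so what is averaged is each
    marker's *motion*; the mean rest position is added back so the result
    stays in image coordinates.  Centering matters under dropout: markers
    sit at different grid heights, and averaging raw coordinates would make
    the mean trajectory jump by (offset / n recognized) every time one
    drops out, inflating the excursion.  ``center=False`` averages the raw
    coordinates.

    Frames where no marker is recognized are gaps, filled by linear
    interpolation between the nearest non-gap frames (leading/trailing
    gaps held at the nearest value).
    """
    if not tracks:
        raise ValueError("need at least one track")
    y = np.stack([t.y_px for t in tracks])          # (n_markers, n_frames)
    rec = np.stack([t.recognized for t in tracks])
    if center:
        ever = rec.any(axis=1)
        base = np.array([np.median(yi[ri]) if ri.any() else np.nan
                         for yi, ri in zip(y, rec)])
        y = y - base[:, None] + np.nanmean(base[ever])
    counts = rec.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_y = np.where(counts > 0,
                          np.nansum(np.where(rec, y, 0.0), axis=0)
                          / np.maximum(counts, 1),
                          np.nan)
    gaps = counts == 0
    gap_fraction = float(gaps.mean())
    if gaps.all():
        raise ValueError("every frame is a gap: no marker ever recognized")
    if gaps.any():
        idx = np.arange(len(mean_y))
        mean_y = np.interp(idx, idx[~gaps], mean_y[~gaps])
    return mean_y, gap_fraction


def per_marker_trajectories(tracks: Sequence[MarkerTrack]) -> np.ndarray:
    """(n_markers, n_frames) y with per-track gap interpolation (NaN if never seen)."""
    out = []
    for t in tracks:
        y = t.y_px.copy()
        rec = t.recognized
        if rec.any():
            idx = np.arange(len(y))
            y = np.interp(idx, idx[rec], y[rec])
        out.append(y)
    return np.stack(out)


def segment_swallows(n_frames: int, fps: float,
                     schedule: Sequence[tuple[float, float]] | None = DEFAULT_SCHEDULE,
                     trajectory: np.ndarray | None = None,
                     auto_half_width_s: float = 3.0) -> list[SwallowSegment]:
    """Locate the three swallow windows as frame ranges.

    Schedule mode (default) converts the configured guide-voice windows
    (seconds) to frame ranges.  Auto mode (``schedule=None``) finds the
    three highest-prominence excursion pulses of the mean trajectory and
    widens each to ``auto_half_width_s`` on both sides, truncating at
    midpoints so windows never overlap.
    """
    if n_frames < 3:
        raise ValueError("need at least 3 frames")
    if fps <= 0:
        raise ValueError("fps must be positive")
    if schedule is not None:
        if len(schedule) != 3:
            raise ValueError("schedule must contain exactly 3 windows")
        segs = []
        for i, (t0, t1) in enumerate(sorted(schedule)):
            a = max(int(round(t0 * fps)), 0)
            b = min(int(round(t1 * fps)), n_frames)
            segs.append(SwallowSegment(i + 1, a, b))
        for s1, s2 in zip(segs, segs[1:]):
            if s2.start < s1.end:
                raise ValueError("schedule windows overlap")
        return segs
    if trajectory is None:
        raise ValueError("auto mode requires the mean trajectory")
    # excursion pulses point upward in the neck = decreasing y
    signal = np.median(trajectory) - trajectory
    span = signal.max() - signal.min()
    if span == 0:
        raise ValueError("flat trajectory: no swallow pulses; use schedule mode")
    peaks, props = find_peaks(signal, prominence=0.1 * span)
    if len(peaks) < 3:
        raise ValueError(f"auto segmentation found only {len(peaks)} pulses; "
                         "use schedule mode")
    top3 = np.sort(peaks[np.argsort(props["prominences"])[-3:]])
    half = int(round(auto_half_width_s * fps))
    segs = []
    for i, p in enumerate(top3):
        a, b = max(p - half, 0), min(p + half, n_frames)
        if i > 0:
            a = max(a, (top3[i - 1] + p) // 2)
        if i < 2:
            b = min(b, (p + top3[i + 1]) // 2)
        segs.append(SwallowSegment(i + 1, int(a), int(max(b, a + 1))))
    return segs


def swallow_excursion(mean_y_px: np.ndarray, segment: SwallowSegment,
                      scale: CalibrationScale) -> float:
    """Excursion of one swallow: (max - min of y over the window) in mm."""
    if segment.end > len(mean_y_px):
        raise ValueError("segment extends past the trajectory")
    seg = mean_y_px[segment.start:segment.end]
    if len(seg) == 0:
        raise ValueError("empty swallow segment")
    return float((seg.max() - seg.min()) * scale.mm_per_px)


def session_distance(excursions: Sequence[float]) -> float:
    """Median of the three per-swallow excursions.

    The median (not the mean) absorbs one aberrant swallow — a marker that
    moved much more or less than usual.
    """
    if len(excursions) != 3:
        raise ValueError(f"expected exactly 3 excursions, got {len(excursions)}")
    return float(np.median(excursions))


def analyze_session(tracks: Sequence[MarkerTrack], fps: float,
                    marker_diameter_mm: float = 5.0,
                    schedule: Sequence[tuple[float, float]] | None = DEFAULT_SCHEDULE,
                    subject: str = "unknown", timepoint: str = "pre",
                    excursion_order: str = "average_first") -> SessionDistance:
    """Tracks -> calibrated session distance (the full per-session pipeline).

    ``excursion_order`` selects between averaging recognized marker
    coordinates per frame and then taking the excursion of the mean
    trajectory (``"average_first"``, the default, consistent with the
    dropout rule) and computing per-marker excursions first and averaging
    those (``"excursion_first"``).
    """
    if excursion_order not in ("average_first", "excursion_first"):
        raise ValueError(f"unknown excursion_order {excursion_order!r}")
    scale = estimate_scale(tracks, marker_diameter_mm)
    mean_y, gap_fraction = mean_trajectory(tracks)
    n = len(mean_y)
    segments = segment_swallows(n, fps, schedule,
                                trajectory=mean_y if schedule is None else None)
    if excursion_order == "average_first":
        exc = [swallow_excursion(mean_y, s, scale) for s in segments]
    else:
        per = per_marker_trajectories(tracks)
        exc = []
        for s in segments:
            seg = per[:, s.start:s.end]
            rng = np.nanmax(seg, axis=1) - np.nanmin(seg, axis=1)
            exc.append(float(np.nanmean(rng) * scale.mm_per_px))
    return SessionDistance(subject=subject, timepoint=timepoint,
                           excursions_mm=tuple(exc),
                           distance_mm=session_distance(exc),
                           scale_mm_per_px=scale.mm_per_px,
                           gap_fraction=gap_fraction)
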