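"""Colored-marker detection and 3x3 grid labeling in video frames.

Each frame is converted from RGB to HSV and thresholded into four hue
bands (blue, orange, green, yellow); connected components above a minimum
area become candidate marker blobs.  Blobs are then placed on the H/M/L x
1/2/3 grid by geometry alone — rows by vertical position (top row = H),
columns left to right — because the protocol does not fix which color sits
at which grid position.  A region of interest from the first frame bounds
the search, and implausible per-frame jumps are rejected as misdetections.

Coordinates: pixel centers at integer coordinates, origin top-left, y
increasing downward.  Excursions downstream use max - min of y, so the
sign convention never affects results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from skimage import color as skcolor
from skimage import measure

log = logging.getLogger(__name__)

GRID_LABELS = ("H1", "H2", "H3", "M1", "M2", "M3", "L1", "L2", "L3")


@dataclass(frozen=True)
class ColorSpec:
    """HSV threshold band for one marker color.

    ``hue_range`` is in degrees and wrap-aware (lo > hi wraps through 0);
    a pixel matches when its hue falls in the band and saturation/value
    exceed the floors (illumination changes mostly move value, so the
    hue/saturation gate is lighting-tolerant).
    """

    name: str
    hue_range: tuple[float, float]
    sat_min: float = 0.4
    val_min: float = 0.3

    def mask(self, hsv: np.ndarray) -> np.ndarray:
        h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
        lo, hi = self.hue_range
        if lo <= hi:
            in_hue = (h >= lo) & (h <= hi)
        else:
            in_hue = (h >= lo) | (h <= hi)
        return in_hue & (s >= self.sat_min) & (v >= self.val_min)


def default_color_specs() -> tuple[ColorSpec, ...]:
    """Disjoint hue bands for the four sticker colors."""
    return (
        ColorSpec("blue", (200.0, 260.0)),
        ColorSpec("orange", (15.0, 40.0)),
        ColorSpec("green", (90.0, 150.0)),
        ColorSpec("yellow", (45.0, 70.0)),
    )


class MarkerLayout:
    """The nine grid identifiers: rows H (top), M, L; columns 1-3 left to right."""

    labels = GRID_LABELS

    @staticmethod
    def row(label: str) -> int:
        return "HML".index(label[0])

    @staticmethod
    def col(label: str) -> int:
        return int(label[1]) - 1


class Blob(NamedTuple):
    """One detected color region."""

    color: str
    x: float
    y: float
    area: int
    equiv_diameter: float


Rect = tuple[int, int, int, int]  # (x0, y0, x1, y1), half-open


@dataclass
class MarkerTrack:
    """Per-frame centroid track of one labeled marker.

    ``x_px``/``y_px``/``diameter_px`` are NaN wherever ``recognized`` is
    False; a centroid is present iff the marker was recognized there.
    """

    label: str
    x_px: np.ndarray
    y_px: np.ndarray
    diameter_px: np.ndarray
    recognized: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.recognized)


def rgb_to_hsv(pixel: Sequence[float]) -> tuple[float, float, float]:
    """Standard hexcone RGB -> HSV for one pixel.

    Channels must lie in [0, 1]; returns hue in degrees [0, 360) and
    saturation/value in [0, 1].  Hue of an achromatic pixel is 0 by
    convention.
    """
    r, g, b = (float(c) for c in pixel)
    for c in (r, g, b):
        if not (0.0 <= c <= 1.0):
            raise ValueError(f"RGB channels must be in [0, 1], got {pixel}")
    v = max(r, g, b)
    delta = v - min(r, g, b)
    s = 0.0 if v == 0 else delta / v
    if delta == 0:
        h = 0.0
    elif v == r:
        h = 60.0 * (((g - b) / delta) % 6)
    elif v == g:
        h = 60.0 * ((b - r) / delta + 2)
    else:
        h = 60.0 * ((r - g) / delta + 4)
    return h % 360.0, s, v


def frame_to_hsv(frame: np.ndarray) -> np.ndarray:
    """Vectorized RGB(A) frame -> HSV with hue in degrees."""
    img = np.asarray(frame)
    if img.dtype == np.uint8:
        img = img.astype(np.float64) / 255.0
    if img.shape[-1] == 4:
        img = img[..., :3]
    hsv = skcolor.rgb2hsv(img)
    hsv[..., 0] *= 360.0
    return hsv


def clip_rect(roi: Rect, image_shape: tuple[int, int]) -> Rect:
    h, w = image_shape[:2]
    x0, y0, x1, y1 = roi
    x0c, y0c = max(int(x0), 0), max(int(y0), 0)
    x1c, y1c = min(int(x1), w), min(int(y1), h)
    if x1c <= x0c or y1c <= y0c:
        raise ValueError(f"ROI {roi} has no area inside the {w}x{h} image")
    return (x0c, y0c, x1c, y1c)


def segment_colors(frame: np.ndarray, roi: Rect | None,
                   colors: Iterable[ColorSpec] | None = None,
                   min_area_px: int = 20) -> list[Blob]:
    """Detect colored blobs: per-color HSV masks -> connected components.

    Components with area >= ``min_area_px`` inside ``roi`` become blobs
    with intensity-unweighted centroids (image coords) and area-equivalent
    diameters.  The result is sorted by (-area, y, x) so it does not depend
    on the order of the color list.
    """
    colors = tuple(colors) if colors is not None else default_color_specs()
    if not colors:
        raise ValueError("need at least one ColorSpec")
    if roi is None:
        roi = (0, 0, frame.shape[1], frame.shape[0])
    x0, y0, x1, y1 = clip_rect(roi, frame.shape)
    hsv = frame_to_hsv(frame[y0:y1, x0:x1])
    blobs: list[Blob] = []
    for spec in colors:
        lab = measure.label(spec.mask(hsv), connectivity=2)
        for region in measure.regionprops(lab):
            if region.area < min_area_px:
                continue
            cy, cx = region.centroid
            blobs.append(Blob(spec.name, cx + x0, cy + y0, int(region.area),
                              float(region.equivalent_diameter_area)))
    blobs.sort(key=lambda b: (-b.area, b.y, b.x))
    return blobs


def init_roi(first_frame: np.ndarray, roi: Rect | None = None,
             colors: Iterable[ColorSpec] | None = None,
             min_area_px: int = 20, margin_px: int = 25) -> Rect:
    """Region of interest from the first frame.

    A supplied rectangle is returned clipped to the image; otherwise the
    bounding box of all detected color blobs, dilated by ``margin_px``
    (generous enough to contain the markers throughout their excursion).
    """
    if roi is not None:
        return clip_rect(roi, first_frame.shape)
    blobs = segment_colors(first_frame, None, colors, min_area_px)
    if not blobs:
        raise ValueError("no color blobs found in the first frame; "
                         "supply an explicit ROI")
    xs = np.array([b.x for b in blobs])
    ys = np.array([b.y for b in blobs])
    d = max(b.equiv_diameter for b in blobs)
    pad = margin_px + d
    return clip_rect((int(xs.min() - pad), int(ys.min() - pad),
                      int(np.ceil(xs.max() + pad)), int(np.ceil(ys.max() + pad))),
                     first_frame.shape)


def _template_from_blobs(blobs: Sequence[Blob]) -> dict[str, tuple[float, float]]:
    """Expected 3x3 lattice spanning the blob extent (first-frame fallback)."""
    xs = np.array([b.x for b in blobs])
    ys = np.array([b.y for b in blobs])
    gx = np.linspace(xs.min(), xs.max(), 3)
    gy = np.linspace(ys.min(), ys.max(), 3)
    return {f"{row}{c + 1}": (gx[c], gy[r])
            for r, row in enumerate("HML") for c in range(3)}


def assign_grid(blobs: Sequence[Blob],
                reference: dict[str, tuple[float, float]] | None = None
                ) -> dict[str, Blob]:
    """Label blobs on the H/M/L x 1/2/3 grid.

    With nine blobs the labeling is canonical: sort by y, split into three
    rows of three (smallest y = row H), then order each row by ascending x
    (ties broken by ascending area).  With fewer, the assignment minimizes
    total Euclidean distance to ``reference`` positions (the previous
    frame's labeled centroids, or a lattice spanning the blobs on the first
    frame).  More than nine plausible blobs: the nine largest are kept with
    a warning.  Unassigned labels are simply absent from the result.
    """
    blobs = list(blobs)
    if len(blobs) > 9:
        log.warning("%d blobs detected; keeping the 9 largest", len(blobs))
        blobs = sorted(blobs, key=lambda b: (-b.area, b.y, b.x))[:9]
    if not blobs:
        return {}
    if len(blobs) == 9:
        by_y = sorted(blobs, key=lambda b: (b.y, b.x, b.area))
        out: dict[str, Blob] = {}
        for r, row in enumerate("HML"):
            row_blobs = sorted(by_y[3 * r:3 * r + 3],
                               key=lambda b: (b.x, b.area))
            for c, blob in enumerate(row_blobs):
                out[f"{row}{c + 1}"] = blob
        return out
    ref = reference if reference else _template_from_blobs(blobs)
    labels = [lab for lab in GRID_LABELS if lab in ref]
    cost = np.array([[np.hypot(b.x - ref[lab][0], b.y - ref[lab][1])
                      for lab in labels] for b in blobs])
    rows, cols = linear_sum_assignment(cost)
    return {labels[c]: blobs[r] for r, c in zip(rows, cols)}


@dataclass
class TrackingConfig:
    """Detection and tracking parameters."""

    colors: tuple[ColorSpec, ...] = field(default_factory=default_color_specs)
    min_area_px: int = 20
    max_jump_diameters: float = 3.0   # per-frame jump cap, in marker diameters
    roi: Rect | None = None
    roi_margin_px: int = 25


def track_markers(frames: Iterable[np.ndarray],
                  config: TrackingConfig | None = None) -> list[MarkerTrack]:
    """Track the nine markers through a frame sequence.

    Applies :func:`init_roi` to the first frame, then per frame
    :func:`segment_colors` + :func:`assign_grid` (referenced to the last
    recognized positions).  A frame-label whose centroid would jump more
    than ``max_jump_diameters`` marker diameters from its last recognized
    position is rejected as a flicker misdetection and marked unrecognized.
    """
    cfg = config or TrackingConfig()
    frame_iter = iter(frames)
    frame_list = list(frame_iter)
    if len(frame_list) == 0:
        raise ValueError("no frames to track")
    if len(frame_list) < 2:
        raise ValueError("need at least 2 frames")
    roi = init_roi(frame_list[0], cfg.roi, cfg.colors, cfg.min_area_px,
                   cfg.roi_margin_px)
    n = len(frame_list)
    data = {lab: dict(x=np.full(n, np.nan), y=np.full(n, np.nan),
                      d=np.full(n, np.nan), rec=np.zeros(n, dtype=bool))
            for lab in GRID_LABELS}
    last_pos: dict[str, tuple[float, float]] = {}
    max_jump_px: float | None = None
    for f, frame in enumerate(frame_list):
        blobs = segment_colors(frame, roi, cfg.colors, cfg.min_area_px)
        assigned = assign_grid(blobs, last_pos if last_pos else None)
        if max_jump_px is None and assigned:
            med_d = float(np.median([b.equiv_diameter for b in assigned.values()]))
            max_jump_px = cfg.max_jump_diameters * med_d
        for lab, blob in assigned.items():
            if lab in last_pos and max_jump_px is not None:
                jump = np.hypot(blob.x - last_pos[lab][0],
                                blob.y - last_pos[lab][1])
                if jump > max_jump_px:
                    log.debug("frame %d: %s jump %.1f px rejected", f, lab, jump)
                    continue
            data[lab]["x"][f] = blob.x
            data[lab]["y"][f] = blob.y
            data[lab]["d"][f] = blob.equiv_diameter
            data[lab]["rec"][f] = True
            last_pos[lab] = (blob.x, blob.y)
    return [MarkerTrack(lab, data[lab]["x"], data[lab]["y"], data[lab]["d"],
                        data[lab]["rec"]) for lab in GRID_LABELS]
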