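"""Synthetic swallow-session generator with ground truth.

Emulates the recording protocol behind the marker-tracking pipeline: a
front-facing camera films a neck bearing nine colored circular stickers in
a 3x3 grid (rows H/M/L around the incision line, columns 1-3 left to
right) while the subject swallows water three times over ~36 s at 30 fps,
guided by a recorded voice so swallow timing is reproducible.  Each
swallow displaces the skin vertically; rows may respond with different
gains (an adhesion-like reduction of excursion).  Frames are rendered as
anti-aliased colored disks over a textured skin-tone background with
optional brightness drift, pixel noise, and per-marker dropout, and every
session carries its exact ground-truth trajectories and excursions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .trial import TrialTable, TRIAL_COLUMNS, FOLLOWUPS

GRID_LABELS = ("H1", "H2", "H3", "M1", "M2", "M3", "L1", "L2", "L3")
MARKER_COLORS = ("blue", "orange", "green", "yellow")

#: rendered sticker colors (RGB in [0,1]); hues fall centrally inside the
#: default detection bands (blue 228deg, orange 30, green 135, yellow 60)
COLOR_RGB = {
    "blue": (0.10, 0.25, 0.95),
    "orange": (0.98, 0.55, 0.08),
    "green": (0.10, 0.80, 0.35),
    "yellow": (0.95, 0.90, 0.10),
}

SKIN_RGB = (0.82, 0.68, 0.58)


@dataclass(frozen=True)
class SwallowWaveform:
    """Vertical skin displacement of one guided swallow.

    Displacement is zero outside [onset, onset + duration] and peaks at
    ``peak_displacement_mm`` mid-swallow.  ``raised_cosine`` is smooth
    (continuous at the window edges); ``triangular`` ramps linearly.
    """

    peak_displacement_mm: float
    onset_s: float
    duration_s: float
    shape: str = "raised_cosine"

    def __post_init__(self):
        if self.peak_displacement_mm < 0:
            raise ValueError("peak_displacement_mm must be >= 0")
        if self.onset_s < 0:
            raise ValueError("onset_s must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.shape not in ("raised_cosine", "triangular"):
            raise ValueError(f"unknown shape {self.shape!r}")

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s

    def displacement_mm(self, t_s: np.ndarray) -> np.ndarray:
        """Displacement (mm, upward-positive) at times ``t_s`` (seconds)."""
        t = np.asarray(t_s, dtype=float)
        u = (t - self.onset_s) / self.duration_s
        inside = (u >= 0) & (u <= 1)
        if self.shape == "raised_cosine":
            w = 0.5 * (1 - np.cos(2 * np.pi * u))
        else:
            w = 1 - np.abs(2 * u - 1)
        return np.where(inside, self.peak_displacement_mm * w, 0.0)


def default_waveforms(duration_s: float = 36.0,
                      peaks_mm: tuple[float, float, float] = (6.0, 6.0, 6.0),
                      swallow_duration_s: float | None = None
                      ) -> tuple[SwallowWaveform, ...]:
    """Three evenly spaced swallows; onsets 8/18/28 s for the 36 s protocol.

    For other session lengths the onsets scale proportionally, keeping the
    same quiet lead-in and spacing structure.  ``swallow_duration_s``
    defaults to 4 s scaled likewise; an explicit value is used as given.
    """
    scale = duration_s / 36.0
    onsets = (8.0 * scale, 18.0 * scale, 28.0 * scale)
    dur = 4.0 * scale if swallow_duration_s is None else swallow_duration_s
    return tuple(SwallowWaveform(p, o, dur)
                 for p, o in zip(peaks_mm, onsets))


def default_grid_centers(image_size_px: tuple[int, int], scale_mm_per_px: float,
                         col_spacing_mm: float = 15.0,
                         row_spacing_mm: float = 10.0) -> dict[str, tuple[float, float]]:
    """3x3 grid of marker centers (mm, image coords) centered in the frame.

    Rows H/M/L are 1 cm apart (stickers sit 1 cm above / on / 1 cm below
    the incision line); lateral spacing is a free protocol parameter.
    """
    w, h = image_size_px
    cx, cy = w * scale_mm_per_px / 2, h * scale_mm_per_px / 2
    centers = {}
    for ri, row in enumerate("HML"):
        for ci in range(3):
            centers[f"{row}{ci + 1}"] = (
                cx + (ci - 1) * col_spacing_mm,
                cy + (ri - 1) * row_spacing_mm,
            )
    return centers


def default_color_assignment() -> dict[str, str]:
    """Fixed repeating color assignment over the grid (row-major)."""
    return {lab: MARKER_COLORS[i % 4] for i, lab in enumerate(GRID_LABELS)}


@dataclass
class SessionSpec:
    """Full description of one synthetic recording session."""

    image_size_px: tuple[int, int] = (960, 540)
    scale_mm_per_px: float = 0.1
    marker_diameter_mm: float = 5.0
    fps: float = 30.0
    duration_s: float = 36.0
    grid_centers_mm: dict[str, tuple[float, float]] | None = None
    color_assignment: dict[str, str] = field(default_factory=default_color_assignment)
    waveforms: tuple[SwallowWaveform, ...] | None = None
    row_gain: dict[str, float] = field(
        default_factory=lambda: {"H": 1.0, "M": 1.0, "L": 1.0})
    dropout_prob: float | dict[str, float] = 0.0
    illumination_drift: float = 0.0
    noise_sd: float = 0.0
    x_jitter_mm: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.grid_centers_mm is None:
            self.grid_centers_mm = default_grid_centers(
                self.image_size_px, self.scale_mm_per_px)
        if self.waveforms is None:
            self.waveforms = default_waveforms(self.duration_s)
        self.validate()

    def validate(self) -> None:
        if self.scale_mm_per_px <= 0 or self.marker_diameter_mm <= 0:
            raise ValueError("scale and marker diameter must be positive")
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValueError("fps and duration must be positive")
        if set(self.grid_centers_mm) != set(GRID_LABELS):
            raise ValueError(f"grid labels must be exactly {GRID_LABELS}")
        bad = set(self.color_assignment.values()) - set(MARKER_COLORS)
        if bad:
            raise ValueError(f"colors must come from {MARKER_COLORS}, got {bad}")
        if set(self.color_assignment) != set(GRID_LABELS):
            raise ValueError("color_assignment must cover all nine labels")
        if len(self.waveforms) != 3:
            raise ValueError("exactly 3 swallow waveforms required")
        windows = sorted((w.onset_s, w.offset_s) for w in self.waveforms)
        for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
            if b0 < a1:
                raise ValueError(
                    f"swallow windows overlap: [{a0},{a1}) and [{b0},{b1})")
        for p in np.atleast_1d(self.dropout_vector()):
            if not (0 <= p <= 1):
                raise ValueError("dropout_prob must be in [0, 1]")
        if set(self.row_gain) != {"H", "M", "L"}:
            raise ValueError("row_gain needs keys H, M, L")
        for g in self.row_gain.values():
            if not (0 <= g <= 1):
                raise ValueError("row gains must be in [0, 1]")

    def dropout_vector(self) -> np.ndarray:
        """Per-label dropout probabilities in GRID_LABELS order."""
        if isinstance(self.dropout_prob, dict):
            return np.array([float(self.dropout_prob.get(lab, 0.0))
                             for lab in GRID_LABELS])
        return np.full(9, float(self.dropout_prob))

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def marker_diameter_px(self) -> float:
        return self.marker_diameter_mm / self.scale_mm_per_px

    def schedule(self) -> list[tuple[float, float]]:
        """Guide-voice swallow windows (s), sorted by onset."""
        return sorted((w.onset_s, w.offset_s) for w in self.waveforms)


@dataclass
class FrameSequence:
    """Ordered frames plus the session metadata needed to analyze them."""

    frames: list[np.ndarray]
    fps: float
    subject: str = "synthetic"
    timepoint: str = "pre"
    marker_diameter_mm: float = 5.0

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def manifest(self) -> dict:
        return {"subject": self.subject, "timepoint": self.timepoint,
                "fps": self.fps, "marker_diameter_mm": self.marker_diameter_mm,
                "n_frames": len(self.frames), "labels": list(GRID_LABELS)}


@dataclass
class GroundTruth:
    """Exact trajectories and excursions underlying a synthetic session."""

    labels: tuple[str, ...]
    centroids_px: np.ndarray      # (n_frames, 9, 2) float, (x, y)
    recognized: np.ndarray        # (n_frames, 9) bool
    mean_y_px: np.ndarray         # (n_frames,) mean over all 9 true tracks
    excursions_mm: np.ndarray     # (3,) per-swallow excursion of mean trajectory
    session_distance_mm: float    # median of the three excursions
    scale_mm_per_px: float

    def to_frame(self) -> pd.DataFrame:
        n, m, _ = self.centroids_px.shape
        rows = []
        for f in range(n):
            for j, lab in enumerate(self.labels):
                rows.append((f, lab, self.centroids_px[f, j, 0],
                             self.centroids_px[f, j, 1],
                             bool(self.recognized[f, j])))
        return pd.DataFrame(rows, columns=["frame", "label", "x_px", "y_px",
                                           "recognized"])


def _true_trajectories(spec: SessionSpec, rng: np.random.Generator
                       ) -> tuple[np.ndarray, np.ndarray]:
    """(n_frames, 9, 2) true centroids in px and (n_frames,) total disp (mm)."""
    t = np.arange(spec.n_frames) / spec.fps
    disp_mm = np.zeros_like(t)
    for w in spec.waveforms:
        disp_mm = disp_mm + w.displacement_mm(t)
    centers = np.array([spec.grid_centers_mm[lab] for lab in GRID_LABELS])
    gains = np.array([spec.row_gain[lab[0]] for lab in GRID_LABELS])
    xy = np.empty((spec.n_frames, 9, 2))
    xy[:, :, 0] = centers[None, :, 0] / spec.scale_mm_per_px
    # swallowing lifts the skin: displacement moves markers up (-y in image)
    xy[:, :, 1] = (centers[None, :, 1]
                   - gains[None, :] * disp_mm[:, None]) / spec.scale_mm_per_px
    if spec.x_jitter_mm > 0:
        xy[:, :, 0] += rng.normal(0, spec.x_jitter_mm / spec.scale_mm_per_px,
                                  (spec.n_frames, 9))
    return xy, disp_mm


def _background(spec: SessionSpec, rng: np.random.Generator) -> np.ndarray:
    """Textured skin-tone background, fixed for the session.

    Gradient and texture modulate brightness multiplicatively (shading),
    which leaves hue and saturation untouched, as shading on real skin
    largely does.
    """
    w, h = spec.image_size_px
    shade = 1.0 + np.linspace(-0.06, 0.06, h)[:, None]
    # low-frequency texture: smooth random brightness field
    coarse = rng.normal(0, 1.0, (max(h // 40, 2), max(w // 40, 2)))
    from scipy.ndimage import zoom
    tex = zoom(coarse, (h / coarse.shape[0], w / coarse.shape[1]), order=1)
    shade = shade + 0.03 * tex
    return np.clip(np.asarray(SKIN_RGB)[None, None, :] * shade[:, :, None], 0, 1)


def _paint_disk(img: np.ndarray, cx: float, cy: float, radius_px: float,
                rgb: tuple[float, float, float]) -> None:
    """Alpha-composite an anti-aliased disk onto ``img`` in place."""
    h, w, _ = img.shape
    x0 = max(int(math.floor(cx - radius_px - 1)), 0)
    x1 = min(int(math.ceil(cx + radius_px + 2)), w)
    y0 = max(int(math.floor(cy - radius_px - 1)), 0)
    y1 = min(int(math.ceil(cy + radius_px + 2)), h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - cx, yy - cy)
    alpha = np.clip(radius_px + 0.5 - dist, 0.0, 1.0)[:, :, None]
    img[y0:y1, x0:x1] = (1 - alpha) * img[y0:y1, x0:x1] + alpha * np.asarray(rgb)


def _ground_truth_from_trajectories(spec: SessionSpec, xy: np.ndarray,
                                    recognized: np.ndarray) -> GroundTruth:
    mean_y = xy[:, :, 1].mean(axis=1)
    fps = spec.fps
    excursions = []
    for (on, off) in spec.schedule():
        a, b = int(round(on * fps)), int(round(off * fps))
        seg = mean_y[a:max(b, a + 1)]
        excursions.append((seg.max() - seg.min()) * spec.scale_mm_per_px)
    excursions = np.array(excursions)
    return GroundTruth(
        labels=GRID_LABELS, centroids_px=xy, recognized=recognized,
        mean_y_px=mean_y, excursions_mm=excursions,
        session_distance_mm=float(np.median(excursions)),
        scale_mm_per_px=spec.scale_mm_per_px)


def iter_frames(spec: SessionSpec) -> Iterator[np.ndarray]:
    """Yield rendered uint8 frames one at a time (memory-light)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    recognized = rng.random((spec.n_frames, 9)) >= spec.dropout_vector()[None, :]
    xy, _ = _true_trajectories(spec, rng)
    bg = _background(spec, rng)
    radius = spec.marker_diameter_px / 2
    t = np.arange(spec.n_frames) / spec.fps
    brightness = 1.0 + spec.illumination_drift * np.sin(
        2 * np.pi * t / spec.duration_s)
    for f in range(spec.n_frames):
        img = bg.copy()
        for j, lab in enumerate(GRID_LABELS):
            if not recognized[f, j]:
                continue
            _paint_disk(img, xy[f, j, 0], xy[f, j, 1], radius,
                        COLOR_RGB[spec.color_assignment[lab]])
        img = img * brightness[f]
        if spec.noise_sd > 0:
            img = img + rng.normal(0, spec.noise_sd, img.shape)
        yield (np.clip(img, 0, 1) * 255).round().astype(np.uint8)


def generate_session(spec: SessionSpec, subject: str = "synthetic",
                     timepoint: str = "pre") -> tuple[FrameSequence, GroundTruth]:
    """Render a full session and return frames plus exact ground truth.

    Deterministic given ``spec.seed``: the same spec yields bit-identical
    frames and ground truth on every call.
    """
    spec.validate()
    # recreate the identical RNG stream used by iter_frames for the truth
    rng = np.random.default_rng(spec.seed)
    recognized = rng.random((spec.n_frames, 9)) >= spec.dropout_vector()[None, :]
    xy, _ = _true_trajectories(spec, rng)
    truth = _ground_truth_from_trajectories(spec, xy, recognized)
    frames = list(iter_frames(spec))
    seq = FrameSequence(frames=frames, fps=spec.fps, subject=subject,
                        timepoint=timepoint,
                        marker_diameter_mm=spec.marker_diameter_mm)
    return seq, truth


def ground_truth_only(spec: SessionSpec) -> GroundTruth:
    """Ground truth without rendering (for large parameter sweeps)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    recognized = rng.random((spec.n_frames, 9)) >= spec.dropout_vector()[None, :]
    xy, _ = _true_trajectories(spec, rng)
    return _ground_truth_from_trajectories(spec, xy, recognized)


# ---------------------------------------------------------------------------
# synthetic randomized trial


@dataclass
class ArmEffect:
    """Normal distributions generating one arm's distances (mm).

    ``pre`` is (mean, sd) of the baseline session distance; ``change``
    maps each follow-up to (mean, sd) of the baseline-subtracted change,
    so distance(t) = pre + change(t) per subject.
    """

    pre: tuple[float, float]
    change: dict[str, tuple[float, float]]

    def validate(self) -> None:
        if self.pre[1] < 0:
            raise ValueError("pre sd must be >= 0")
        if set(self.change) != set(FOLLOWUPS):
            raise ValueError(f"change must cover {FOLLOWUPS}")
        for m, s in self.change.values():
            if s < 0:
                raise ValueError("change sd must be >= 0")


def reported_arm_effects() -> dict[str, ArmEffect]:
    """Arm distributions matching the reported trial summaries.

    Treated arm (AA+): baseline 3.92 +/- 1.19 mm, changes 2.96 +/- 2.1,
    1.8 +/- 1.52, 1.45 +/- 1.66 mm at 2 wk / 3 mo / 9 mo; control arm
    (AA-): baseline 4.1 +/- 1.38 mm, changes 2.04 +/- 1.85, 1.1 +/- 1.55,
    0.58 +/- 1.5 mm.
    """
    return {
        "AA+": ArmEffect(pre=(3.92, 1.19),
                         change={"2wk": (2.96, 2.1), "3mo": (1.8, 1.52),
                                 "9mo": (1.45, 1.66)}),
        "AA-": ArmEffect(pre=(4.1, 1.38),
                         change={"2wk": (2.04, 1.85), "3mo": (1.1, 1.55),
                                 "9mo": (0.58, 1.5)}),
    }


def generate_trial(n_per_arm: int = 44,
                   effect: dict[str, ArmEffect] | None = None,
                   seed: int = 0) -> TrialTable:
    """Simulate a two-arm trial table of session distances.

    Each subject draws a baseline distance and three follow-up changes from
    the arm's normal distributions (defaults: the reported trial
    summaries); covariates are sampled from the eligible population (age
    20-65, ~36% male, height ~N(160, 7) cm).  Distances are floored at 0.
    """
    if n_per_arm < 2:
        raise ValueError("n_per_arm must be >= 2")
    effects = effect or reported_arm_effects()
    for e in effects.values():
        e.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for arm, eff in sorted(effects.items()):
        for i in range(n_per_arm):
            pre = max(0.0, rng.normal(*eff.pre))
            row = {
                "id": f"{arm}{i + 1:03d}",
                "arm": arm,
                "sex": "M" if rng.random() < 0.36 else "F",
                "age_years": int(rng.integers(20, 66)),
                "height_cm": float(np.clip(rng.normal(160, 7), 140, 190)),
                "distance_pre": pre,
            }
            for tp in FOLLOWUPS:
                row[f"distance_{tp}"] = max(0.0, pre + rng.normal(*eff.change[tp]))
            rows.append(row)
    return TrialTable(pd.DataFrame(rows, columns=TRIAL_COLUMNS))
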