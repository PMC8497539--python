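"""Reading and writing the pipeline's on-disk artifacts.

Sessions live on disk as a directory of zero-padded numbered PNG frames
(``frame_000000.png`` ...) plus a ``manifest.json`` (subject, timepoint,
fps, marker diameter).  Tracks are long-format CSV (frame, label,
recognized, x_px, y_px, diameter_px); per-session results are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .synth import FrameSequence, GroundTruth
from .vision import GRID_LABELS, MarkerTrack

FRAME_PATTERN = "frame_{:06d}.png"


def write_session(out_dir: str | Path, frames: Iterable[np.ndarray],
                  manifest: dict, truth: GroundTruth | None = None) -> Path:
    """Write frames + manifest (and optional ground truth) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = 0
    for i, frame in enumerate(frames):
        iio.imwrite(out / FRAME_PATTERN.format(i), frame)
        n += 1
    manifest = dict(manifest, n_frames=n)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    if truth is not None:
        truth.to_frame().to_csv(out / "ground_truth.csv", index=False)
        summary = {
            "excursions_mm": [float(e) for e in truth.excursions_mm],
            "session_distance_mm": truth.session_distance_mm,
            "scale_mm_per_px": truth.scale_mm_per_px,
        }
        (out / "ground_truth.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True))
    return out


def read_manifest(session_dir: str | Path) -> dict:
    path = Path(session_dir) / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(f"no manifest.json in {session_dir}")
    return json.loads(path.read_text())


def iter_session_frames(session_dir: str | Path) -> Iterator[np.ndarray]:
    """Yield frames of a session directory in index order."""
    paths = sorted(Path(session_dir).glob("frame_*.png"))
    if not paths:
        raise FileNotFoundError(f"no frame_*.png files in {session_dir}")
    for p in paths:
        yield iio.imread(p)


def read_session(session_dir: str | Path) -> FrameSequence:
    """Load a frame directory + manifest into a FrameSequence."""
    manifest = read_manifest(session_dir)
    frames = list(iter_session_frames(session_dir))
    return FrameSequence(frames=frames, fps=float(manifest["fps"]),
                         subject=str(manifest.get("subject", "unknown")),
                         timepoint=str(manifest.get("timepoint", "pre")),
                         marker_diameter_mm=float(
                             manifest.get("marker_diameter_mm", 5.0)))


def tracks_to_frame(tracks: list[MarkerTrack]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for f in range(t.n_frames):
            rows.append((f, t.label, bool(t.recognized[f]),
                         t.x_px[f], t.y_px[f], t.diameter_px[f]))
    df = pd.DataFrame(rows, columns=["frame", "label", "recognized",
                                     "x_px", "y_px", "diameter_px"])
    return df.sort_values(["frame", "label"]).reset_index(drop=True)


def write_tracks(path: str | Path, tracks: list[MarkerTrack]) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False)


def read_tracks(path: str | Path) -> list[MarkerTrack]:
    df = pd.read_csv(path)
    n = int(df["frame"].max()) + 1
    out = []
    for lab in GRID_LABELS:
        sub = df[df["label"] == lab].set_index("frame")
        x = np.full(n, np.nan)
        y = np.full(n, np.nan)
        d = np.full(n, np.nan)
        rec = np.zeros(n, dtype=bool)
        idx = sub.index.to_numpy()
        rec[idx] = sub["recognized"].to_numpy(dtype=bool)
        x[idx] = sub["x_px"].to_numpy(dtype=float)
        y[idx] = sub["y_px"].to_numpy(dtype=float)
        d[idx] = sub["diameter_px"].to_numpy(dtype=float)
        x[~rec] = np.nan
        y[~rec] = np.nan
        d[~rec] = np.nan
        out.append(MarkerTrack(lab, x, y, d, rec))
    return out


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
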