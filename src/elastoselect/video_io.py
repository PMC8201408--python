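"""Frame-sequence, ROI-mask and metadata I/O.

The canonical in-memory representation of an elastography recording is a
:class:`VideoSequence`: an ordered list of 8-bit RGB :class:`Frame` objects
with 0-based contiguous indices.  A lesion may pool frames from one or two
source videos (two 20-second clips are recorded per lesion); pooling
preserves each video's internal order.  Channel order is RGB everywhere;
any BGR-native decoder output must be converted at this boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

IMAGE_SUFFIXES = {".png", ".bmp", ".jpg", ".jpeg", ".tif", ".tiff"}
VIDEO_SUFFIXES = {".mp4", ".avi", ".mov", ".mkv"}


@dataclass
class Frame:
    """A single 8-bit RGB frame.

    ``index`` is the 0-based position in the pooled per-lesion sequence;
    ``source_video`` records which recording the frame came from.
    """

    index: int
    source_video: str
    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"frame pixels must be H×W×3, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("frame must have at least one pixel")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class VideoSequence:
    """Ordered frame stack for one lesion, possibly pooled from two videos."""

    lesion_id: str
    frames: list[Frame] = field(default_factory=list)
    fps: float = 10.0  # metadata only; no time-based resampling is done

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.frames:
            shape = self.frames[0].shape
            for f in self.frames:
                if f.shape != shape:
                    raise ValueError(
                        f"inconsistent frame size in lesion {self.lesion_id}: "
                        f"{f.shape} vs {shape}"
                    )
            indices = [f.index for f in self.frames]
            if indices != list(range(len(self.frames))):
                raise ValueError("frame indices must be 0-based and contiguous")

    def __len__(self) -> int:
        return len(self.frames)

    def stack(self) -> np.ndarray:
        """All frames as one (n, H, W, 3) uint8 array."""
        return np.stack([f.pixels for f in self.frames])


@dataclass
class ROIMask:
    """Binary region-of-interest mask outlining the lesion."""

    mask: np.ndarray
    lesion_id: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        m = m.astype(bool)
        if not m.any():
            raise ValueError("ROI mask has no true pixels")
        self.mask = m

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def _read_frame_file(path: Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 2:  # grayscale promoted to RGB
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    return np.ascontiguousarray(arr, dtype=np.uint8)


def _frames_from_dir(path: Path, source: str, start_index: int) -> list[Frame]:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)
    if not files:
        raise ValueError(f"no image files found in {path}")
    frames: list[Frame] = []
    shape: tuple[int, int] | None = None
    for i, f in enumerate(files):
        try:
            px = _read_frame_file(f)
        except Exception as exc:  # pragma: no cover - decoder specific
            raise ValueError(f"unreadable frame {f}: {exc}") from exc
        if shape is None:
            shape = px.shape[:2]
        elif px.shape[:2] != shape:
            raise ValueError(
                f"frame {f} has size {px.shape[:2]}, expected {shape}"
            )
        frames.append(Frame(index=start_index + i, source_video=source, pixels=px))
    return frames


def _frames_from_container(path: Path, source: str, start_index: int) -> list[Frame]:
    try:
        stack = iio.imread(path, plugin="pyav")
    except Exception:
        stack = iio.imread(path)
    frames = []
    for i, px in enumerate(np.asarray(stack)):
        if px.ndim == 2:
            px = np.stack([px] * 3, axis=-1)
        frames.append(
            Frame(
                index=start_index + i,
                source_video=source,
                pixels=np.ascontiguousarray(px[..., :3], dtype=np.uint8),
            )
        )
    if not frames:
        raise ValueError(f"no frames decoded from {path}")
    return frames


def read_video(
    path: str | Path | Sequence[str | Path],
    lesion_id: str,
    fps: float = 10.0,
) -> VideoSequence:
    """Read one or two frame sources into a pooled :class:`VideoSequence`.

    ``path`` may be a directory of lexicographically ordered image files, a
    decodable video container, or a sequence of such paths (the two videos
    of one lesion); pooled frames get contiguous 0-based indices and record
    their source path's name as ``source_video``.
    """
    paths = [Path(path)] if isinstance(path, (str, Path)) else [Path(p) for p in path]
    frames: list[Frame] = []
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(f"video source not found: {p}")
        if p.is_dir():
            frames.extend(_frames_from_dir(p, source=p.name, start_index=len(frames)))
        elif p.suffix.lower() in VIDEO_SUFFIXES:
            frames.extend(_frames_from_container(p, source=p.name, start_index=len(frames)))
        else:
            raise ValueError(f"unsupported video source: {p}")
    return VideoSequence(lesion_id=lesion_id, frames=frames, fps=fps)


def write_video(video: VideoSequence, out_dir: str | Path) -> list[Path]:
    """Write frames as zero-padded PNGs (round-trips bitwise with read_video)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for f in video.frames:
        p = out / f"frame_{f.index:05d}.png"
        iio.imwrite(p, f.pixels)
        written.append(p)
    return written


def read_mask(path: str | Path, lesion_id: str = "") -> ROIMask:
    """Read an image file as a binary ROI mask (any nonzero pixel is inside)."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"mask not found: {p}")
    arr = iio.imread(p)
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=-1)
    return ROIMask(mask=arr > 0, lesion_id=lesion_id or p.stem)


def write_mask(mask: ROIMask, path: str | Path) -> None:
    iio.imwrite(Path(path), (mask.mask.astype(np.uint8) * 255))


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-lesion metadata CSV (lesion_id, label, group, ...)."""
    df = pd.read_csv(path, dtype={"lesion_id": str})
    missing = {"lesion_id", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"metadata CSV missing columns: {sorted(missing)}")
    bad = set(df["label"].unique()) - {"benign", "malignant"}
    if bad:
        raise ValueError(f"unknown labels in metadata: {sorted(bad)}")
    return df


def write_selection(selection, video: VideoSequence, out_dir: str | Path) -> dict:
    """Write the selected representative frames and a JSON sidecar.

    Frames are written as ``<lesion_id>_rep{1,2,3}.png`` ordered by ascending
    distance to the representative-pattern center (ties: lower frame index
    first, which :class:`~elastoselect.selector.Selection` already enforces).
    """
    if not selection.frame_indices:
        raise ValueError(f"empty selection for lesion {selection.lesion_id}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame_by_index = {f.index: f for f in video.frames}
    record = {
        "lesion_id": selection.lesion_id,
        "representative_pattern": int(selection.representative_pattern),
        "short": bool(selection.short),
        "frames": [],
    }
    for rank, (idx, dist) in enumerate(zip(selection.frame_indices, selection.distances), 1):
        if idx not in frame_by_index:
            raise ValueError(f"selected frame {idx} not present in video {video.lesion_id}")
        name = f"{selection.lesion_id}_rep{rank}.png"
        iio.imwrite(out / name, frame_by_index[idx].pixels)
        record["frames"].append({"rank": rank, "index": int(idx), "distance": float(dist), "file": name})
    sidecar = out / f"{selection.lesion_id}_selection.json"
    sidecar.write_text(json.dumps(record, indent=2, sort_keys=True))
    return record


def pool_videos(lesion_id: str, videos: Iterable[VideoSequence], fps: float = 10.0) -> VideoSequence:
    """Pool the frames of several videos of one lesion, re-indexing contiguously."""
    frames: list[Frame] = []
    for v in videos:
        for f in v.frames:
            frames.append(Frame(index=len(frames), source_video=f.source_video, pixels=f.pixels))
    return VideoSequence(lesion_id=lesion_id, frames=frames, fps=fps)
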