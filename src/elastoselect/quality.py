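"""Frame quality gating and thinning.

A strain-elastography frame is useful only when the elastogram overlay is
actually present (enough colored pixels) and the exposure is typical for the
recording (relative intensity near 1).  Frames passing both gates are
*qualified*; adjacent qualified frames are then thinned with a greedy walk so
that near-duplicate consecutive frames do not overwhelm the clustering stage.

The two gate quantities are

* colored-pixel proportion: fraction of pixels with HSV saturation
  (0–255 scale) at or above ``s_min``;
* relative intensity: the frame's mean HSV value channel divided by the
  median of that mean over the whole video (median, so a handful of dark
  dropout frames cannot drag the normalizer down).

Threshold comparisons are closed: a frame exactly at ``p_min`` or at a band
edge qualifies.  The published defaults for these thresholds are not public;
the values here are plausible settings and every one is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from elastoselect._color import sat_val255
from elastoselect.video_io import Frame, VideoSequence


@dataclass(frozen=True)
class QualityConfig:
    """Gate thresholds and thinning gap.

    s_min: minimum saturation (0–255) for a pixel to count as colored.
    p_min: minimum colored-pixel proportion for a frame to qualify.
    i_lo, i_hi: allowed relative-intensity band (i_lo < 1 < i_hi).
    gap: number of subsequent qualified frames dropped after each kept frame;
         gap=2 drops the adjacent two frames.
    """

    s_min: float = 40.0
    p_min: float = 0.15
    i_lo: float = 0.6
    i_hi: float = 1.4
    gap: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.s_min <= 255:
            raise ValueError("s_min must lie in [0, 255]")
        if not 0 <= self.p_min <= 1:
            raise ValueError("p_min must lie in [0, 1]")
        if not 0 < self.i_lo < self.i_hi:
            raise ValueError("require 0 < i_lo < i_hi")
        if self.gap < 0:
            raise ValueError("gap must be non-negative")


@dataclass
class QualityReport:
    """Per-frame gate quantities and flags; ``kept`` implies ``qualified``."""

    lesion_id: str
    frame: pd.DataFrame  # columns: index, colored_proportion, relative_intensity, qualified, kept

    @property
    def kept_indices(self) -> list[int]:
        return self.frame.loc[self.frame["kept"], "index"].tolist()

    @property
    def qualified_indices(self) -> list[int]:
        return self.frame.loc[self.frame["qualified"], "index"].tolist()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def colored_proportion(frame: Frame | np.ndarray, s_min: float) -> float:
    """Fraction of pixels whose HSV saturation (0–255) is >= s_min."""
    px = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    sat, _ = sat_val255(px)
    return float(np.mean(sat >= s_min))


def _mean_value(px: np.ndarray) -> float:
    return float(sat_val255(px)[1].mean())


def relative_intensity(frame: Frame, video: VideoSequence) -> float:
    """Frame mean HSV value over the video-median of per-frame mean values."""
    if len(video) == 0:
        raise ValueError("empty video")
    norm = float(np.median([_mean_value(f.pixels) for f in video.frames]))
    if norm <= 0:
        raise ValueError("all-black video: relative intensity undefined")
    return _mean_value(frame.pixels) / norm


def thin_adjacent(qualified_indices: list[int], gap: int) -> list[int]:
    """Greedy left-to-right thinning of a sorted index list.

    Keep the first index; drop any subsequent index within ``gap`` of the
    last kept one; repeat.  gap=0 is the identity.
    """
    if gap < 0:
        raise ValueError("gap must be non-negative")
    if any(b <= a for a, b in zip(qualified_indices, qualified_indices[1:])):
        raise ValueError("qualified_indices must be strictly increasing")
    kept: list[int] = []
    for idx in qualified_indices:
        if not kept or idx - kept[-1] > gap:
            kept.append(idx)
    return kept


def evaluate_quality(video: VideoSequence, config: QualityConfig = QualityConfig()) -> QualityReport:
    """Gate every frame of ``video`` and thin the qualified ones.

    A frame qualifies iff colored_proportion >= p_min and its relative
    intensity lies in the closed band [i_lo, i_hi].
    """
    if len(video) == 0:
        raise ValueError(f"empty video for lesion {video.lesion_id}")
    # one HSV pass per frame serves both gates
    prop_list, mean_list = [], []
    for f in video.frames:
        sat, val = sat_val255(f.pixels)
        prop_list.append(float(np.mean(sat >= config.s_min)))
        mean_list.append(float(val.mean()))
    mean_values = np.array(mean_list)
    norm = float(np.median(mean_values))
    if norm <= 0:
        raise ValueError("all-black video: relative intensity undefined")
    rel = mean_values / norm
    prop = np.array(prop_list)
    qualified = (prop >= config.p_min) & (rel >= config.i_lo) & (rel <= config.i_hi)
    indices = np.array([f.index for f in video.frames])
    kept_set = set(thin_adjacent(indices[qualified].tolist(), config.gap))
    df = pd.DataFrame(
        {
            "index": indices,
            "colored_proportion": prop,
            "relative_intensity": rel,
            "qualified": qualified,
            "kept": [bool(q) and (i in kept_set) for i, q in zip(indices, qualified)],
        }
    )
    return QualityReport(lesion_id=video.lesion_id, frame=df)
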