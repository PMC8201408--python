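"""Quantitative elastography metrics over a region of interest.

Given an elastography image and an expert-drawn lesion ROI, six numbers are
computed:

* SAR (stiff area ratio): fraction of ROI pixels classified as blue — the
  stiff end of the elastographic color scale.
* B/G, B/R, G/R: ratios of summed 8-bit channel intensities over the ROI.
* mean hue: arithmetic mean of the HSV hue channel (0–255 full-range scale)
  over the ROI; achromatic pixels contribute hue 0.
* mean gray: mean BT.601 luma (0.299 R + 0.587 G + 0.114 B), on [0, 255].

Pixel color classification uses configurable hue windows centered on the
canonical hues (red 0, yellow ~43, green 85, blue 170 on the 0–255 circle);
pixels failing a chroma gate (low saturation or low value) are unclassified.
Ratios with a zero denominator are flagged undefined rather than infinite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from elastoselect._color import hsv255
from elastoselect.video_io import Frame, ROIMask

CLASSES = ("red", "yellow", "green", "blue", "unclassified")


@dataclass(frozen=True)
class HueClassConfig:
    """Hue windows (0–255 scale) and chroma gate for pixel classification.

    Windows: red = [0, red_hi] ∪ [red_lo_wrap, 255], yellow = (red_hi,
    yellow_hi], green = (yellow_hi, green_hi], blue = (green_hi, blue_hi];
    hues in (blue_hi, red_lo_wrap) and chroma-gated pixels are unclassified.
    """

    red_hi: float = 21.0
    yellow_hi: float = 64.0
    green_hi: float = 128.0
    blue_hi: float = 184.0
    red_lo_wrap: float = 234.0
    s_color: float = 40.0  # minimum saturation for a pixel to be classifiable
    v_min: float = 32.0  # minimum value (brightness)

    def __post_init__(self) -> None:
        if not 0 < self.red_hi < self.yellow_hi < self.green_hi < self.blue_hi < self.red_lo_wrap <= 255:
            raise ValueError("hue window edges must be strictly increasing within [0, 255]")


@dataclass
class QuantResult:
    """The six ROI metrics for one image; undefined ratios are None."""

    sar: float
    b_g: Optional[float]
    b_r: Optional[float]
    g_r: Optional[float]
    mean_hue: float
    mean_gray: float
    n_roi: int
    counts: dict

    def as_dict(self) -> dict:
        return {
            "sar": self.sar,
            "b_g": self.b_g,
            "b_r": self.b_r,
            "g_r": self.g_r,
            "mean_hue": self.mean_hue,
            "mean_gray": self.mean_gray,
            "n_roi": self.n_roi,
        }


def _roi_pixels(frame: Frame | np.ndarray, roi: ROIMask) -> np.ndarray:
    px = frame.pixels if isinstance(frame, Frame) else np.asarray(frame, dtype=np.uint8)
    if roi.mask.shape != px.shape[:2]:
        raise ValueError(f"ROI mask shape {roi.mask.shape} does not match frame {px.shape[:2]}")
    out = px[roi.mask]
    if out.size == 0:
        raise ValueError("empty ROI")
    return out


def classify_pixels(frame: Frame | np.ndarray, roi: ROIMask, config: HueClassConfig = HueClassConfig()) -> dict:
    """Count ROI pixels per color class; counts partition the ROI exactly."""
    px = _roi_pixels(frame, roi)
    hsv = hsv255(px[None, :, :])[0]
    hue, sat, val = hsv[:, 0], hsv[:, 1], hsv[:, 2]
    classifiable = (sat >= config.s_color) & (val >= config.v_min)
    counts = dict.fromkeys(CLASSES, 0)
    red = (hue <= config.red_hi) | (hue >= config.red_lo_wrap)
    yellow = (hue > config.red_hi) & (hue <= config.yellow_hi)
    green = (hue > config.yellow_hi) & (hue <= config.green_hi)
    blue = (hue > config.green_hi) & (hue <= config.blue_hi)
    for name, mask in (("red", red), ("yellow", yellow), ("green", green), ("blue", blue)):
        counts[name] = int((mask & classifiable).sum())
    counts["unclassified"] = int(len(px) - sum(counts.values()))
    return counts


def stiff_area_ratio(counts: dict, n_roi: int) -> float:
    """Blue (stiff) pixel count over the whole-lesion pixel count."""
    if n_roi < 1:
        raise ValueError("empty ROI")
    return counts["blue"] / n_roi


def channel_ratios(frame: Frame | np.ndarray, roi: ROIMask) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """(B/G, B/R, G/R) as ratios of summed channel intensities over the ROI.

    A zero-sum denominator channel makes the corresponding ratio None.
    """
    px = _roi_pixels(frame, roi).astype(np.float64)
    r, g, b = px[:, 0].sum(), px[:, 1].sum(), px[:, 2].sum()
    b_g = b / g if g > 0 else None
    b_r = b / r if r > 0 else None
    g_r = g / r if r > 0 else None
    return b_g, b_r, g_r


def mean_hue(frame: Frame | np.ndarray, roi: ROIMask) -> float:
    """Mean HSV hue (0–255 full-range) over the ROI; achromatic pixels count as hue 0."""
    px = _roi_pixels(frame, roi)
    return float(hsv255(px[None, :, :])[0][:, 0].mean())


def mean_gray(frame: Frame | np.ndarray, roi: ROIMask) -> float:
    """Mean BT.601 luma over the ROI, on [0, 255]."""
    px = _roi_pixels(frame, roi).astype(np.float64)
    return float((0.299 * px[:, 0] + 0.587 * px[:, 1] + 0.114 * px[:, 2]).mean())


def quantify(frame: Frame | np.ndarray, roi: ROIMask, config: HueClassConfig = HueClassConfig()) -> QuantResult:
    """All six metrics for one image + ROI."""
    counts = classify_pixels(frame, roi, config)
    n_roi = roi.n_pixels
    b_g, b_r, g_r = channel_ratios(frame, roi)
    return QuantResult(
        sar=stiff_area_ratio(counts, n_roi),
        b_g=b_g,
        b_r=b_r,
        g_r=g_r,
        mean_hue=mean_hue(frame, roi),
        mean_gray=mean_gray(frame, roi),
        n_roi=n_roi,
        counts=counts,
    )
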