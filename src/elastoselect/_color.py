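"""Shared color-space helpers.

Hue, saturation and value are reported on the full 0–255 scale throughout the
package (matching 8-bit channel data); scikit-image's [0, 1] HSV output is
rescaled at this boundary.
"""

from __future__ import annotations

import numpy as np
from skimage.color import hsv2rgb, rgb2hsv


def hsv255(pixels: np.ndarray) -> np.ndarray:
    """HSV of an 8-bit RGB array, each channel on the 0–255 scale.

    Achromatic pixels (R=G=B) get hue 0 and saturation 0.
    """
    return rgb2hsv(pixels) * 255.0


def sat_val255(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """HSV saturation and value channels on the 0–255 scale, without hue.

    S = (max − min)/max (0 where max = 0), V = max — identical to the full
    HSV conversion but cheap enough for per-frame gating of long videos.
    """
    px = np.asarray(pixels, dtype=np.float64)
    mx = px.max(axis=-1)
    mn = px.min(axis=-1)
    sat = np.zeros_like(mx)
    nz = mx > 0
    sat[nz] = (mx[nz] - mn[nz]) / mx[nz] * 255.0
    return sat, mx


def rgb_from_hsv255(h: np.ndarray, s: np.ndarray, v: np.ndarray) -> np.ndarray:
    """8-bit RGB from HSV channels on the 0–255 scale (rounded)."""
    hsv = np.stack([np.asarray(h), np.asarray(s), np.asarray(v)], axis=-1) / 255.0
    return np.round(hsv2rgb(hsv) * 255.0).astype(np.uint8)
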