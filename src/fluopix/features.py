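"""Per-pixel feature extraction.

A single RGB pixel is expanded to a 10-dimensional feature vector before
anomaly detection and quantification:

====  =========================================================
R     red intensity, rescaled to [0, 1]
G     green intensity, rescaled to [0, 1]
B     blue intensity, rescaled to [0, 1]
pR    proportional red,   r / (r + g + b)
pG    proportional green, g / (r + g + b)
pB    proportional blue,  b / (r + g + b)
H     HSV hue in [0, 1] (0 for achromatic pixels)
S     HSV saturation
V     HSV value, max(R, G, B)
E     red excess (r - (g + b) / 2) / 255, affinely mapped to [0, 1]
      (anti-red pixels clip at 0)
====  =========================================================

All features use only the pixel's own channel values — no neighbourhood or
image context.  PPIX emission under blue-light excitation raises the red
channel, so the red-weighted features (R, pR, E) carry most of the signal;
the chromatic features separate fluorescence from bright achromatic
reflections.  For black pixels the channel proportions are undefined and
default to 1/3 each.

The feature list is configurable: pass a ``names`` subset to the extractors
to work with an alternative set without touching downstream code.
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2hsv

from .frame import as_frame

FEATURE_NAMES = ("R", "G", "B", "pR", "pG", "pB", "H", "S", "V", "E")


def extract_features_frame(frame: np.ndarray, names=FEATURE_NAMES) -> np.ndarray:
    """Feature planes for a whole frame, shape (H, W, len(names))."""
    frame = as_frame(frame)
    rgb = frame.astype(np.float64) / 255.0
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]

    total = r + g + b
    safe = np.where(total > 0, total, 1.0)
    props = np.where(total[..., None] > 0, rgb / safe[..., None], 1.0 / 3.0)

    hsv = rgb2hsv(rgb)
    # red excess, affinely mapped from [-0.5, 1] onto [0, 1]; pixels with
    # (g + b)/2 exceeding r + 0.5 (strongly anti-red) clip at 0
    e = np.clip(((r - (g + b) / 2.0) + 0.5) / 1.5, 0.0, 1.0)

    planes = {
        "R": r,
        "G": g,
        "B": b,
        "pR": props[..., 0],
        "pG": props[..., 1],
        "pB": props[..., 2],
        "H": hsv[..., 0],
        "S": hsv[..., 1],
        "V": hsv[..., 2],
        "E": e,
    }
    return np.stack([planes[n] for n in names], axis=-1)


def extract_features(r: float, g: float, b: float, names=FEATURE_NAMES) -> np.ndarray:
    """Feature vector of a single pixel with channels in [0, 255]."""
    for v in (r, g, b):
        if not 0 <= v <= 255:
            raise ValueError(f"channel values must lie in [0, 255], got {(r, g, b)}")
    px = np.array([[[r, g, b]]], dtype=np.uint8)
    return extract_features_frame(px, names=names)[0, 0]


def extract_features_pixels(rgb: np.ndarray, names=FEATURE_NAMES) -> np.ndarray:
    """Vectorized extraction for an (n, 3) array of pixels in [0, 255]."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 2 or rgb.shape[1] != 3:
        raise ValueError("expected an (n, 3) pixel array")
    return extract_features_frame(rgb.reshape(-1, 1, 3), names=names).reshape(
        rgb.shape[0], len(names)
    )
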