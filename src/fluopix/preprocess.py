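"""Removal of JPEG quantization artifacts from dark image regions.

Surgical-microscope video frames are stored as JPEG, and in the nearly black
background of fluorescence-mode images the compressor collapses 8x8 blocks
onto a handful of intensity levels.  Those levels show up as isolated spikes
in the per-channel intensity histogram.  The pipeline here:

1. build the intensity histogram of a channel;
2. approximate its density with a moving average and flag every level whose
   frequency exceeds that local density by more than a factor (default 1.5);
3. zero the flagged pixels in the offending channel and re-interpolate them
   with a 9x9 median filter over the zeroed channel.

Each channel is processed independently and the three planes are then
reassembled into an RGB frame.
"""

from __future__ import annotations

import numpy as np

from .frame import as_frame, channel_index

DEFAULT_WINDOW = 5
DEFAULT_FACTOR = 1.5
_MEDIAN_HALF = 4  # 9x9 interpolation window


def build_channel_histogram(frame: np.ndarray, channel: int | str) -> np.ndarray:
    """256-bin intensity histogram of one channel; counts sum to H*W."""
    frame = as_frame(frame)
    c = channel_index(channel)
    return np.bincount(frame[:, :, c].ravel(), minlength=256).astype(np.int64)


def moving_average(counts: np.ndarray, window: int) -> np.ndarray:
    """Moving average with edge windows truncated to the in-range portion.

    No padding is used: at level 0 the average runs over levels
    0..window//2 only, so no counts are fabricated beyond the 0/255 ends.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    counts = np.asarray(counts, dtype=float)
    kernel = np.ones(window)
    sums = np.convolve(counts, kernel, mode="same")
    sizes = np.convolve(np.ones_like(counts), kernel, mode="same")
    return sums / sizes


def detect_artifact_levels(
    hist: np.ndarray, window: int = DEFAULT_WINDOW, factor: float = DEFAULT_FACTOR
) -> np.ndarray:
    """Intensity levels whose frequency exceeds ``factor`` x the local density.

    Returns a sorted integer array of flagged levels (possibly empty).
    """
    if not factor > 1:
        raise ValueError(f"factor must exceed 1, got {factor}")
    hist = np.asarray(hist, dtype=float)
    if hist.ndim != 1 or hist.size < window:
        raise ValueError("histogram must be 1-D with at least `window` bins")
    density = moving_average(hist, window)
    return np.flatnonzero(hist > factor * density)


def _truncated_median(plane: np.ndarray, i: int, j: int) -> int:
    """Median of the 9x9 window around (i, j), truncated at image borders.

    For an even-count window the lower middle order statistic is returned,
    so the result is always an existing 8-bit value.
    """
    h, w = plane.shape
    block = plane[
        max(0, i - _MEDIAN_HALF) : min(h, i + _MEDIAN_HALF + 1),
        max(0, j - _MEDIAN_HALF) : min(w, j + _MEDIAN_HALF + 1),
    ].ravel()
    return int(np.partition(block, (block.size - 1) // 2)[(block.size - 1) // 2])


def suppress_and_interpolate(frame: np.ndarray, levels) -> np.ndarray:
    """Zero flagged levels per channel, then median-interpolate those pixels.

    ``levels`` is a sequence of three level arrays (red, green, blue).  Only
    the offending channel of a flagged pixel is touched; the median is taken
    over the post-zeroing 9x9 neighbourhood of that channel, truncated to
    the in-image intersection at borders.
    """
    frame = as_frame(frame)
    out = frame.copy()
    for c in range(3):
        lv = np.asarray(levels[c], dtype=np.int64)
        if lv.size == 0:
            continue
        if np.any((lv < 0) | (lv > 255)):
            raise ValueError("artifact levels must lie in [0, 255]")
        plane = out[:, :, c]
        flagged = np.isin(plane, lv)
        if not flagged.any():
            continue
        zeroed = plane.copy()
        zeroed[flagged] = 0
        rows, cols = np.nonzero(flagged)
        filled = zeroed.copy()
        for i, j in zip(rows.tolist(), cols.tolist()):
            filled[i, j] = _truncated_median(zeroed, i, j)
        out[:, :, c] = filled
    return out


def preprocess_frame(
    frame: np.ndarray, window: int = DEFAULT_WINDOW, factor: float = DEFAULT_FACTOR
) -> np.ndarray:
    """Full artifact-removal pass: detect levels per channel, zero, interpolate."""
    frame = as_frame(frame)
    levels = [
        detect_artifact_levels(build_channel_histogram(frame, c), window, factor)
        for c in range(3)
    ]
    return suppress_and_interpolate(frame, levels)
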