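"""Frame container conventions.

An RGB frame is a ``numpy.ndarray`` of shape ``(height, width, 3)`` and dtype
``uint8``, row-major, channels ordered red, green, blue.  All image-level
operations in this package accept and return frames in this layout; this
module provides the validation helpers they share.
"""

from __future__ import annotations

import numpy as np

CHANNELS = ("red", "green", "blue")


def as_frame(arr: np.ndarray) -> np.ndarray:
    """Validate ``arr`` as an 8-bit RGB frame and return it as ``uint8``.

    Raises
    ------
    ValueError
        If the array is not H x W x 3 with H, W >= 1, or holds values
        outside [0, 255].
    """
    a = np.asarray(arr)
    if a.ndim != 3 or a.shape[2] != 3 or a.shape[0] < 1 or a.shape[1] < 1:
        raise ValueError(f"expected an (H, W, 3) RGB frame, got shape {a.shape}")
    if a.dtype != np.uint8:
        if np.any((a < 0) | (a > 255)):
            raise ValueError("frame intensities must lie in [0, 255]")
        a = a.astype(np.uint8)
    return a


def channel_index(channel: int | str) -> int:
    """Map a channel id (0/1/2 or 'red'/'green'/'blue') to a plane index."""
    if isinstance(channel, str):
        try:
            return CHANNELS.index(channel.lower())
        except ValueError:
            raise ValueError(f"unknown channel {channel!r}; use one of {CHANNELS}") from None
    c = int(channel)
    if c not in (0, 1, 2):
        raise ValueError(f"channel index must be 0, 1 or 2, got {c}")
    return c


def black_mask(frame: np.ndarray) -> np.ndarray:
    """Boolean plane marking exactly-(0, 0, 0) pixels.

    Black pixels carry no colour information (typically the area outside the
    microscope's circular optical field) and are excluded from specificity
    accounting; by convention they can never be detected as fluorescent.
    """
    frame = as_frame(frame)
    return (frame == 0).all(axis=2)
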