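"""Pixel extraction from ROI masks and training-set assembly.

Training data are individual pixels drawn from region-of-interest masks:
the positive class holds pixels with clearly visible fluorescence, the
negative class holds reference-sample and background pixels.  Two set
compositions are supported:

* a **balanced** set (equal pixels per class) for the traditional
  classifiers, and
* an **anomaly** set for the contrastive VAE: a large pool of normal
  (negative) pixels plus normal-anomaly pairs for the contrastive term.

All sampling is without replacement and fully determined by an integer
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, extract_features_pixels
from .frame import as_frame

POSITIVE, NEGATIVE = 1, 0


@dataclass
class PixelSet:
    """A labeled set of pixels.

    rgb      : (n, 3) raw channel values in [0, 255]
    label    : (n,) class labels, 1 = positive (fluorescent), 0 = negative
    conc     : (n,) PPIX concentration in ug/mL (NaN where unknown)
    coords   : (n, 2) source (row, col), -1 where not applicable
    frame_id : (n,) integer source-frame id, -1 where not applicable
    """

    rgb: np.ndarray
    label: np.ndarray
    conc: np.ndarray = field(default=None)
    coords: np.ndarray = field(default=None)
    frame_id: np.ndarray = field(default=None)

    def __post_init__(self):
        self.rgb = np.asarray(self.rgb, dtype=np.float64).reshape(-1, 3)
        n = len(self.rgb)
        self.label = np.asarray(self.label, dtype=np.int8).reshape(n)
        if not np.isin(self.label, [POSITIVE, NEGATIVE]).all():
            raise ValueError("labels must be binary (0 = negative, 1 = positive)")
        if self.conc is None:
            self.conc = np.full(n, np.nan)
        self.conc = np.asarray(self.conc, dtype=np.float64).reshape(n)
        if np.any(self.conc[np.isfinite(self.conc)] < 0):
            raise ValueError("concentrations must be >= 0")
        if self.coords is None:
            self.coords = np.full((n, 2), -1, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(n, 2)
        if self.frame_id is None:
            self.frame_id = np.full(n, -1, dtype=np.int64)
        self.frame_id = np.asarray(self.frame_id, dtype=np.int64).reshape(n)

    def __len__(self) -> int:
        return len(self.rgb)

    def features(self, names=FEATURE_NAMES) -> np.ndarray:
        """The per-pixel feature matrix (n, len(names))."""
        return extract_features_pixels(self.rgb, names=names)

    def take(self, idx: np.ndarray) -> "PixelSet":
        idx = np.asarray(idx)
        return PixelSet(
            self.rgb[idx], self.label[idx], self.conc[idx],
            self.coords[idx], self.frame_id[idx],
        )

    @staticmethod
    def concat(sets) -> "PixelSet":
        sets = list(sets)
        return PixelSet(
            np.concatenate([s.rgb for s in sets]),
            np.concatenate([s.label for s in sets]),
            np.concatenate([s.conc for s in sets]),
            np.concatenate([s.coords for s in sets]),
            np.concatenate([s.frame_id for s in sets]),
        )

    def to_frame(self) -> pd.DataFrame:
        """CSV-ready table: the 10 features plus label and concentration."""
        df = pd.DataFrame(self.features(), columns=list(FEATURE_NAMES))
        df["label"] = self.label
        df["concentration"] = self.conc
        return df


@dataclass
class ContrastivePairSet:
    """Normal-anomaly pixel pairs for the contrastive loss term."""

    normal: PixelSet
    anomaly: PixelSet

    def __post_init__(self):
        if len(self.normal) != len(self.anomaly):
            raise ValueError("pair sets must have equal length")
        if not (self.normal.label == NEGATIVE).all():
            raise ValueError("normal pair members must all be class negative")
        if not (self.anomaly.label == POSITIVE).all():
            raise ValueError("anomaly pair members must all be class positive")

    def __len__(self) -> int:
        return len(self.normal)


def extract_roi_pixels(
    frame: np.ndarray,
    mask: np.ndarray,
    label: int,
    concentration: float | None = None,
    frame_id: int = -1,
) -> PixelSet:
    """One record per true mask element, carrying the frame's RGB there."""
    frame = as_frame(frame)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frame.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match frame {frame.shape[:2]}"
        )
    rows, cols = np.nonzero(mask)
    n = len(rows)
    conc = np.full(n, np.nan if concentration is None else float(concentration))
    return PixelSet(
        rgb=frame[rows, cols].astype(np.float64),
        label=np.full(n, label, dtype=np.int8),
        conc=conc,
        coords=np.stack([rows, cols], axis=1),
        frame_id=np.full(n, frame_id, dtype=np.int64),
    )


def build_balanced_training_set(
    positives: PixelSet, negatives: PixelSet, n_per_class: int, seed: int
) -> PixelSet:
    """Equal-size random subsets of each class, without replacement."""
    for name, pool in (("positive", positives), ("negative", negatives)):
        if len(pool) < n_per_class:
            raise ValueError(
                f"{name} pool holds {len(pool)} pixels, fewer than the "
                f"requested {n_per_class} per class"
            )
    rng = np.random.default_rng(seed)
    pos = positives.take(rng.choice(len(positives), n_per_class, replace=False))
    neg = negatives.take(rng.choice(len(negatives), n_per_class, replace=False))
    return PixelSet.concat([pos, neg])


def build_anomaly_training_set(
    normal_pool: PixelSet,
    anomaly_pool: PixelSet,
    n_normal: int,
    n_pairs: int,
    seed: int,
) -> tuple[PixelSet, ContrastivePairSet]:
    """Normal training set plus contrastive pairs.

    ``n_normal`` pixels are drawn from the normal pool without replacement;
    ``n_pairs`` of those are paired with ``n_pairs`` anomaly pixels drawn
    without replacement from the anomaly pool.
    """
    if len(normal_pool) < n_normal:
        raise ValueError(
            f"normal pool holds {len(normal_pool)} pixels, fewer than {n_normal}"
        )
    if n_pairs > n_normal:
        raise ValueError("n_pairs cannot exceed n_normal")
    if len(anomaly_pool) < n_pairs:
        raise ValueError(
            f"anomaly pool holds {len(anomaly_pool)} pixels, fewer than {n_pairs}"
        )
    if not (normal_pool.label == NEGATIVE).all():
        raise ValueError("normal pool must contain only negative-class pixels")
    rng = np.random.default_rng(seed)
    normal = normal_pool.take(rng.choice(len(normal_pool), n_normal, replace=False))
    pair_normal = normal.take(rng.choice(n_normal, n_pairs, replace=False))
    pair_anom = anomaly_pool.take(
        rng.choice(len(anomaly_pool), n_pairs, replace=False)
    )
    return normal, ContrastivePairSet(pair_normal, pair_anom)
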