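"""Evaluation protocol: ROC analysis, fixed-specificity detection rates,
negative-frame specificity and annotation overlap.

Conventions used throughout:

* the detection rule is "flag iff score > threshold";
* exactly-black (0, 0, 0) pixels can never be detected — their scores are
  forced below every threshold before masks are built — which also makes
  the black-pixel-excluded specificity well defined;
* the "optimal operating point" of a ROC curve maximizes Youden's
  J = sensitivity + specificity - 1, with ties broken toward the higher
  specificity (the conservative choice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

from .frame import as_frame, black_mask
from .sampling import PixelSet


@dataclass
class RocCurve:
    """ROC curve over all distinct score thresholds."""

    thresholds: np.ndarray
    sensitivity: np.ndarray   # TPR per threshold
    specificity: np.ndarray   # 1 - FPR per threshold
    auc: float
    n_pos: int | None = None
    n_neg: int | None = None

    def __post_init__(self):
        if not 0 <= self.auc <= 1:
            raise ValueError("AUC must lie in [0, 1]")


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float


@dataclass
class SpecificityReport:
    """Per-frame and pooled specificity on negative (non-FGS) frames."""

    fp_counts: np.ndarray            # false-positive pixels per frame
    totals: np.ndarray               # pixels per frame
    black_counts: np.ndarray         # exactly-black pixels per frame
    specificity_all: np.ndarray      # 1 - FP / total
    specificity_excl_black: np.ndarray
    pooled: float                    # 1 - sum(FP) / sum(total)
    pooled_excl_black: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(1, len(self.fp_counts) + 1),
            "fp_pixels": self.fp_counts,
            "total_pixels": self.totals,
            "black_pixels": self.black_counts,
            "specificity": np.round(self.specificity_all, 4),
            "specificity_excl_black": np.round(self.specificity_excl_black, 4),
        })


@dataclass
class OverlapReport:
    """Comparison of a model detection mask with an annotation mask."""

    model_area: int
    annotated_area: int
    area_ratio: float | None      # model / annotated; None if annotated = 0
    coverage: float | None        # |model & annot| / annotated


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC over all distinct thresholds; AUC equals the tie-adjusted
    probability that a random positive outscores a random negative."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels lengths differ")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return RocCurve(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=float(roc_auc_score(labels, scores)),
        n_pos=int((labels == classes.max()).sum()),
        n_neg=int((labels == classes.min()).sum()),
    )


def optimal_operating_point(curve: RocCurve) -> OperatingPoint:
    """Threshold maximizing Youden's J; ties go to the higher specificity."""
    j = curve.sensitivity + curve.specificity - 1.0
    best = np.flatnonzero(j == j.max())
    pick = best[np.argmax(curve.specificity[best])]
    sens = float(curve.sensitivity[pick])
    spec = float(curve.specificity[pick])
    if curve.n_pos is not None and curve.n_neg is not None:
        acc = (sens * curve.n_pos + spec * curve.n_neg) / (
            curve.n_pos + curve.n_neg
        )
    else:
        acc = (sens + spec) / 2.0  # balanced accuracy when counts unknown
    return OperatingPoint(float(curve.thresholds[pick]), sens, spec, float(acc))


def detection_rate_table(
    scores: np.ndarray, concentrations: np.ndarray, tau: float
) -> pd.DataFrame:
    """Percentage of pixels scored above tau, per distinct concentration.

    Returned table has columns ``concentration``, ``n_pixels``,
    ``detection_rate`` (percent, descending concentration order).
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    conc = np.asarray(concentrations, dtype=np.float64).ravel()
    if scores.shape != conc.shape:
        raise ValueError("scores and concentrations lengths differ")
    if scores.size == 0:
        raise ValueError("empty input")
    rows = []
    for c in sorted(np.unique(conc), reverse=True):
        sel = conc == c
        rows.append({
            "concentration": c,
            "n_pixels": int(sel.sum()),
            "detection_rate": 100.0 * float((scores[sel] > tau).mean()),
        })
    return pd.DataFrame(rows)


def detection_mask(
    score_plane: np.ndarray, frame: np.ndarray, tau: float
) -> np.ndarray:
    """Thresholded detection mask; exactly-black pixels are never flagged."""
    score_plane = np.asarray(score_plane, dtype=np.float64)
    frame = as_frame(frame)
    if score_plane.shape != frame.shape[:2]:
        raise ValueError("score plane does not match the frame")
    return (score_plane > tau) & ~black_mask(frame)


def negative_frame_specificity(masks, frames) -> SpecificityReport:
    """Specificity accounting on frames known to contain no fluorescence.

    Every detection is a false positive.  Per frame the specificity is
    reported over all pixels and, in parallel, excluding exactly-(0, 0, 0)
    pixels (detections on black pixels are impossible by convention, see
    :func:`detection_mask`).
    """
    masks = [np.asarray(m, dtype=bool) for m in masks]
    frames = [as_frame(f) for f in frames]
    if len(masks) != len(frames):
        raise ValueError("need one mask per frame")
    fp, tot, blk = [], [], []
    for m, f in zip(masks, frames):
        if m.shape != f.shape[:2]:
            raise ValueError("mask does not match its frame")
        fp.append(int(m.sum()))
        tot.append(m.size)
        blk.append(int(black_mask(f).sum()))
    fp, tot, blk = np.array(fp), np.array(tot), np.array(blk)
    if np.any(tot - blk == 0):
        raise ZeroDivisionError(
            "a frame is entirely black; black-pixel-excluded specificity "
            "is undefined"
        )
    return SpecificityReport(
        fp_counts=fp,
        totals=tot,
        black_counts=blk,
        specificity_all=1.0 - fp / tot,
        specificity_excl_black=1.0 - fp / (tot - blk),
        pooled=1.0 - fp.sum() / tot.sum(),
        pooled_excl_black=1.0 - fp.sum() / (tot.sum() - blk.sum()),
    )


def annotation_overlap(model_mask: np.ndarray, annot_mask: np.ndarray) -> OverlapReport:
    """Area comparison between a model detection mask and an annotation."""
    model_mask = np.asarray(model_mask, dtype=bool)
    annot_mask = np.asarray(annot_mask, dtype=bool)
    if model_mask.shape != annot_mask.shape:
        raise ValueError("mask dimensions differ")
    ma = int(model_mask.sum())
    aa = int(annot_mask.sum())
    if aa == 0:
        return OverlapReport(ma, 0, None, None)
    return OverlapReport(
        model_area=ma,
        annotated_area=aa,
        area_ratio=ma / aa,
        coverage=int((model_mask & annot_mask).sum()) / aa,
    )


def embed_qualitative(
    pixels: PixelSet | np.ndarray,
    perplexity: float = 200.0,
    metric_order: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """2-D stochastic-neighbour embedding for qualitative separability plots.

    Runs t-SNE with the given perplexity under a Minkowski distance of the
    given order; deterministic for a fixed seed.  Intended purely for
    visual inspection of class structure, never for quantitative claims.
    """
    X = pixels.features() if isinstance(pixels, PixelSet) else np.asarray(
        pixels, dtype=np.float64
    )
    if len(X) < 3 * perplexity:
        raise ValueError(
            f"need at least 3 x perplexity = {3 * perplexity:.0f} points, "
            f"got {len(X)}"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        metric="minkowski",
        metric_params={"p": metric_order},
        random_state=seed,
        init="pca",
    )
    return tsne.fit_transform(X)
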