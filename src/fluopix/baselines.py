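"""Traditional pixel classifiers used as comparison baselines.

Three classifiers operate directly on raw RGB triplets in [0, 255]:

* ``svm`` — soft-margin SVM with RBF kernel k(u, v) = exp(-||u-v||^2 / s^2),
  kernel scale s = 5 (cost C = 1); scores are signed decision values;
* ``nb``  — Gaussian naive Bayes with class priors estimated from the data;
  scores are positive-class posteriors;
* ``nn``  — a single fully connected hidden layer of 10 ReLU units with a
  softmax output, trained by cross-entropy with an adaptive-moment
  optimizer (step 1e-3, 200 epochs, mini-batches of 256); scores are
  positive-class posteriors.

All three are trained on a balanced set of strongly fluorescent versus
non-fluorescent pixels; weaker concentrations are only ever seen at test
time.  Higher score always means "more fluorescent".
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .sampling import POSITIVE, PixelSet

KINDS = ("svm", "nb", "nn")


@dataclass
class BaselineSpec:
    kind: str = "svm"
    svm_kernel_scale: float = 5.0
    svm_cost: float = 1.0
    nn_hidden_units: int = 10
    nn_learning_rate: float = 1e-3
    nn_epochs: int = 200
    nn_batch_size: int = 256
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.svm_kernel_scale <= 0:
            raise ValueError("SVM kernel scale must be > 0")
        if self.nn_hidden_units < 1:
            raise ValueError("NN needs at least one hidden unit")


@dataclass
class TrainedBaseline:
    spec: BaselineSpec
    estimator: object
    representation: str = "raw-RGB"

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.with_suffix(".json").write_text(
            json.dumps({"kind": self.spec.kind, "representation": self.representation})
        )
        joblib.dump({"spec": self.spec, "estimator": self.estimator},
                    path.with_suffix(".joblib"))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedBaseline":
        blob = joblib.load(Path(path).with_suffix(".joblib"))
        return cls(spec=blob["spec"], estimator=blob["estimator"])


def _make_estimator(spec: BaselineSpec):
    if spec.kind == "svm":
        # gamma = 1 / s^2 gives k(u, v) = exp(-||u-v||^2 / s^2)
        return SVC(C=spec.svm_cost, kernel="rbf",
                   gamma=1.0 / spec.svm_kernel_scale**2)
    if spec.kind == "nb":
        return GaussianNB()
    return MLPClassifier(
        hidden_layer_sizes=(spec.nn_hidden_units,),
        activation="relu",
        solver="adam",
        learning_rate_init=spec.nn_learning_rate,
        max_iter=spec.nn_epochs,
        batch_size=spec.nn_batch_size,
        random_state=spec.seed,
        n_iter_no_change=spec.nn_epochs,  # run the full epoch budget
    )


def train_baseline(spec: BaselineSpec, data: PixelSet) -> TrainedBaseline:
    """Fit one baseline on raw RGB pixel values."""
    y = data.label
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    est = _make_estimator(spec)
    est.fit(data.rgb, y)
    return TrainedBaseline(spec=spec, estimator=est)


def score_pixels(model: TrainedBaseline, pixels: PixelSet | np.ndarray) -> np.ndarray:
    """Continuous fluorescence score per pixel (higher = more fluorescent)."""
    X = pixels.rgb if isinstance(pixels, PixelSet) else np.asarray(pixels, float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("baselines score raw (n, 3) RGB pixels")
    est = model.estimator
    if model.spec.kind == "svm":
        s = est.decision_function(X)
        # decision_function is oriented toward classes_[1]
        return s if est.classes_[1] == POSITIVE else -s
    proba = est.predict_proba(X)
    col = int(np.flatnonzero(est.classes_ == POSITIVE)[0])
    return proba[:, col]


def score_frame(model: TrainedBaseline, frame: np.ndarray) -> np.ndarray:
    """Per-pixel score plane for an RGB frame."""
    frame = np.asarray(frame)
    h, w = frame.shape[:2]
    return score_pixels(model, frame.reshape(-1, 3).astype(float)).reshape(h, w)
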