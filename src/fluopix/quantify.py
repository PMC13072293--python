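"""PPIX concentration quantification from pixel features.

Detected pixels are mapped to a *PPIX-sample-equivalent* concentration —
expressed relative to the calibrated synthetic sample ladder, not an
absolute tissue concentration — through low-order polynomial calibration
models:

* a quadratic in the red intensity R alone,
      f(x) = p1 + p2*x + p3*x^2
* a bivariate polynomial adding the proportional green component pG,
      f(x, y) = p00 + p10*x + p01*y + p20*x^2 + p11*x*y

Both are ordinary-least-squares fits.  Which predictors matter is assessed
beforehand with a regression random forest whose out-of-bag (OOB)
permutation importances rank the 10 features without a held-out set.

A reference coefficient set for both model forms ships with the package
(``reference_quadratic`` / ``reference_bivariate``).  The numeric scale its
coefficients assume is not recorded, so it is tagged ``scale="reference"``
and intended for evaluation-at-a-point and serialization checks rather
than extrapolation; freshly fitted models carry ``scale="unit"`` (R, pG in
[0, 1] as produced by the feature extractor).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.tree import DecisionTreeRegressor

from .features import FEATURE_NAMES
from .frame import as_frame

CMAX_DEFAULT = 5.0

#: shipped reference coefficients for the two calibration forms
REFERENCE_QUADRATIC = (2.166, 7.325, -0.02339)
REFERENCE_BIVARIATE = (0.0327, -1.009, 0.6343, 46.99, -93.46)


@dataclass
class QuantModel:
    """Polynomial calibration model mapping features to ug/mL."""

    form: str                       # "quadratic1d" | "poly2d"
    coeffs: tuple                   # (p1,p2,p3) or (p00,p10,p01,p20,p11)
    predictors: tuple = ("R",)      # feature tags, x first (and y second)
    r_squared: float = float("nan")
    scale: str = "unit"
    cmax: float = CMAX_DEFAULT

    def __post_init__(self):
        n_expected = {"quadratic1d": 3, "poly2d": 5}
        if self.form not in n_expected:
            raise ValueError(f"unknown model form {self.form!r}")
        if len(self.coeffs) != n_expected[self.form]:
            raise ValueError(
                f"{self.form} expects {n_expected[self.form]} coefficients"
            )
        self.coeffs = tuple(float(c) for c in self.coeffs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "form": self.form,
            "coeffs": list(self.coeffs),
            "predictors": list(self.predictors),
            "r_squared": self.r_squared,
            "scale": self.scale,
            "cmax": self.cmax,
        }, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "QuantModel":
        d = json.loads(Path(path).read_text())
        return cls(form=d["form"], coeffs=tuple(d["coeffs"]),
                   predictors=tuple(d["predictors"]),
                   r_squared=d["r_squared"], scale=d["scale"], cmax=d["cmax"])


def reference_quadratic() -> QuantModel:
    """The shipped single-predictor (R) reference calibration."""
    return QuantModel(form="quadratic1d", coeffs=REFERENCE_QUADRATIC,
                      predictors=("R",), r_squared=0.72, scale="reference")


def reference_bivariate() -> QuantModel:
    """The shipped two-predictor (R, pG) reference calibration."""
    return QuantModel(form="poly2d", coeffs=REFERENCE_BIVARIATE,
                      predictors=("R", "pG"), r_squared=0.92, scale="reference")


@dataclass
class ImportanceReport:
    """Per-feature OOB permutation importance from a regression forest."""

    feature_names: tuple
    importances: np.ndarray   # mean increase in OOB squared error
    ranks: np.ndarray         # 1 = most important
    oob_r2: float


def _r_squared(y, yhat) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0  # degenerate (constant) response, by convention
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def rank_feature_importance(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: tuple = FEATURE_NAMES,
    n_trees: int = 100,
    seed: int = 0,
) -> ImportanceReport:
    """Rank features by OOB permutation importance of a regression forest.

    The forest is an explicit bagging ensemble of decision trees with
    package-owned bootstrap indices, so each tree's out-of-bag rows are
    known exactly: a feature's importance is the mean over trees of the
    increase in OOB squared error after permuting that feature's values
    among the tree's OOB rows.  ``oob_r2`` is the R^2 of the aggregated
    OOB predictions.  Deterministic for a fixed seed.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, d = X.shape
    if n < 50:
        raise ValueError("need at least 50 rows for a meaningful forest fit")
    if len(np.unique(y)) < 2:
        raise ValueError("response must take at least 2 distinct values")
    rng = np.random.default_rng(seed)
    max_features = max(1, d // 3)

    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n)
    delta = np.zeros((n_trees, d))
    for t in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeRegressor(
            max_features=max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[boot], y[boot])
        if oob.size == 0:
            continue
        pred = tree.predict(X[oob])
        oob_sum[oob] += pred
        oob_cnt[oob] += 1
        base_err = np.mean((pred - y[oob]) ** 2)
        for j in range(d):
            Xp = X[oob].copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            perm_err = np.mean((tree.predict(Xp) - y[oob]) ** 2)
            delta[t, j] = perm_err - base_err

    importances = delta.mean(axis=0)
    order = np.argsort(-importances)
    ranks = np.empty(d, dtype=int)
    ranks[order] = np.arange(1, d + 1)
    seen = oob_cnt > 0
    oob_r2 = _r_squared(y[seen], oob_sum[seen] / oob_cnt[seen])
    return ImportanceReport(tuple(feature_names), importances, ranks, oob_r2)


def _ols(design: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, rank, _ = np.linalg.lstsq(design, c, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient design; predictors are degenerate")
    return coef, _r_squared(c, design @ coef)


def fit_quadratic_1d(x: np.ndarray, c: np.ndarray) -> QuantModel:
    """OLS fit of concentration on {1, x, x^2}; x is the red intensity R."""
    x = np.asarray(x, dtype=np.float64).ravel()
    c = np.asarray(c, dtype=np.float64).ravel()
    if len(x) != len(c):
        raise ValueError("x and c lengths differ")
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct x values")
    if np.ptp(c) == 0.0:
        # constant response: exact flat fit, R^2 reported as 0 by convention
        return QuantModel("quadratic1d", (float(c[0]), 0.0, 0.0),
                          predictors=("R",), r_squared=0.0)
    design = np.column_stack([np.ones_like(x), x, x**2])
    coef, r2 = _ols(design, c)
    return QuantModel("quadratic1d", tuple(coef), predictors=("R",), r_squared=r2)


def fit_poly_2d(x: np.ndarray, y: np.ndarray, c: np.ndarray) -> QuantModel:
    """OLS fit of concentration on {1, x, y, x^2, x*y}; (x, y) = (R, pG)."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    c = np.asarray(c, dtype=np.float64).ravel()
    if not len(x) == len(y) == len(c):
        raise ValueError("x, y and c lengths differ")
    if len(x) < 5:
        raise ValueError("need at least 5 points for the bivariate fit")
    design = np.column_stack([np.ones_like(x), x, y, x**2, x * y])
    coef, r2 = _ols(design, c)
    if np.ptp(c) == 0.0:
        r2 = 0.0
    return QuantModel("poly2d", tuple(coef), predictors=("R", "pG"), r_squared=r2)


def predict_concentration(model: QuantModel, x, y=None) -> np.ndarray:
    """Evaluate the calibration polynomial; result clamped to [0, cmax].

    ``x`` is the first predictor (R); ``y`` the second (pG), required for
    the bivariate form.
    """
    x = np.asarray(x, dtype=np.float64)
    if model.form == "quadratic1d":
        p1, p2, p3 = model.coeffs
        raw = p1 + p2 * x + p3 * x**2
    else:
        if y is None:
            raise ValueError("the bivariate model needs both predictors")
        y = np.asarray(y, dtype=np.float64)
        p00, p10, p01, p20, p11 = model.coeffs
        raw = p00 + p10 * x + p01 * y + p20 * x**2 + p11 * x * y
    return np.clip(raw, 0.0, model.cmax)


def render_concentration_map(
    frame: np.ndarray,
    model: QuantModel,
    detection_mask: np.ndarray,
    alpha: float = 0.55,
    colormap: str = "inferno",
) -> tuple[np.ndarray, np.ndarray]:
    """Concentration map over detected pixels plus a colour overlay image.

    Returns ``(conc_map, overlay)``: the map holds the clamped predicted
    concentration at detected pixels and 0 elsewhere; the overlay blends
    the frame with a perceptually ordered colormap of the map.
    """
    from matplotlib import colormaps

    frame = as_frame(frame)
    detection_mask = np.asarray(detection_mask, dtype=bool)
    if detection_mask.shape != frame.shape[:2]:
        raise ValueError("detection mask does not match the frame")
    from .features import extract_features_frame

    conc = np.zeros(frame.shape[:2], dtype=np.float64)
    if detection_mask.any():
        feats = extract_features_frame(frame, names=("R", "pG"))
        r = feats[..., 0][detection_mask]
        pg = feats[..., 1][detection_mask]
        if model.form == "quadratic1d":
            conc[detection_mask] = predict_concentration(model, r)
        else:
            conc[detection_mask] = predict_concentration(model, r, pg)

    cmap = colormaps[colormap]
    colours = (cmap(conc / model.cmax)[..., :3] * 255).astype(np.float64)
    overlay = frame.astype(np.float64)
    m = detection_mask
    overlay[m] = (1 - alpha) * overlay[m] + alpha * colours[m]
    return conc, np.clip(np.rint(overlay), 0, 255).astype(np.uint8)
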