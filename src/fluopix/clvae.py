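"""Contrastive-loss variational autoencoder for pixel-wise anomaly scoring.

The detector learns the *normal* (non-fluorescent) pixel class only: a VAE
with a 10-dimensional input, a 3-dimensional diagonal-Gaussian latent and a
10-dimensional sigmoid output is trained to reconstruct normal pixels under
a KL penalty toward the standard-normal prior.  Fluorescent pixels then
stand out because their encoder posterior is pushed away from the prior;
the closed-form KL divergence

    KL(q || N(0, I)) = 1/2 * sum_j (mu_j^2 + sigma_j^2 - ln sigma_j^2 - 1)

serves directly as the per-pixel anomaly score.

Three refinements over a plain VAE:

* **cyclic beta-annealing** — the KL weight beta rises from 0 to its
  maximum along a normalized sigmoidal ramp during the first half of each
  of 20 cycles and stays at the maximum for the second half;
* **exponential learning-rate decay** from 1e-3 to 1e-4 across training;
* a **contrastive term**: normal-anomaly pixel pairs are pushed apart in
  latent-mean space through a squared hinge max(0, m - ||mu_n - mu_a||)^2.
  Anomaly pixels influence training only through this term — they are never
  reconstructed, preserving the learn-the-normal-class premise.

The model is small enough that training runs on plain numpy with
analytically derived gradients and an in-package Adam optimizer; everything
is bit-deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .features import FEATURE_NAMES, extract_features_frame
from .sampling import ContrastivePairSet, PixelSet


@dataclass
class VaeConfig:
    input_dim: int = 10
    latent_dim: int = 3
    output_dim: int = 10
    epochs: int = 1000
    batch_size: int = 256
    lr_start: float = 1e-3
    lr_end: float = 1e-4
    beta_max: float = 1.0
    cycles: int = 20
    margin: float = 1.0              # contrastive hinge margin, latent units
    contrastive_weight: float = 1.0  # lambda
    hidden_dim: int = 0              # 0 = the plain 10-3-10 stack
    seed: int = 0

    def __post_init__(self):
        if self.epochs % self.cycles != 0:
            raise ValueError("epochs must be divisible by the cycle count")
        L = self.epochs // self.cycles
        if L < 4 or L % 2 != 0:
            raise ValueError("cycle length (epochs / cycles) must be even and >= 4")
        if not self.lr_start > self.lr_end > 0:
            raise ValueError("require lr_start > lr_end > 0")
        if self.beta_max <= 0:
            raise ValueError("beta_max must be > 0")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


def beta_at(config: VaeConfig, epoch: int) -> float:
    """KL weight at a 0-based epoch under two-phase cyclic annealing.

    With cycle length L and in-cycle position t: for t < L/2 the weight
    follows a sigmoidal ramp normalized to start at exactly 0 and reach
    exactly beta_max at the half-cycle's last ramp epoch; for t >= L/2 it
    stays at beta_max.
    """
    if not 0 <= epoch < config.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs})")
    L = config.epochs // config.cycles
    half = L // 2
    t = epoch % L
    if t >= half:
        return float(config.beta_max)
    u = t / (half - 1) if half > 1 else 0.0
    lo, hi = _sigmoid(-6.0), _sigmoid(6.0)
    s = (_sigmoid(12.0 * u - 6.0) - lo) / (hi - lo)
    return float(config.beta_max * s)


def lr_at(config: VaeConfig, epoch: int) -> float:
    """Exponentially decayed learning rate; hits lr_start and lr_end exactly."""
    if not 0 <= epoch < config.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs})")
    frac = epoch / (config.epochs - 1) if config.epochs > 1 else 0.0
    return float(config.lr_start * (config.lr_end / config.lr_start) ** frac)


def kl_anomaly_score(mu: np.ndarray, log_var: np.ndarray) -> np.ndarray:
    """Closed-form KL divergence of N(mu, diag(exp(log_var))) from N(0, I).

    Accepts (..., d) arrays and returns scores of shape (...).  Always >= 0;
    exactly 0 when the posterior equals the prior.
    """
    mu = np.asarray(mu, dtype=np.float64)
    log_var = np.asarray(log_var, dtype=np.float64)
    if not (np.isfinite(mu).all() and np.isfinite(log_var).all()):
        raise ValueError("posterior parameters must be finite")
    return 0.5 * np.sum(mu**2 + np.exp(log_var) - log_var - 1.0, axis=-1)


def _relu(x):
    return np.maximum(x, 0.0)


class _Adam:
    """Adaptive-moment optimizer over a dict of numpy parameters."""

    def __init__(self, params, b1=0.9, b2=0.999, eps=1e-8):
        self.b1, self.b2, self.eps = b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads, lr):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainedClvae:
    """Fitted encoder/decoder parameters plus the training configuration."""

    params: dict
    config: VaeConfig
    loss_trace: np.ndarray = field(default=None)
    feature_names: tuple = FEATURE_NAMES

    def encode(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior (mu, log_var) for an (n, input_dim) feature matrix."""
        x = np.asarray(x, dtype=np.float64)
        p = self.params
        h = _relu(x @ p["W_he"] + p["b_he"]) if "W_he" in p else x
        return h @ p["W_mu"] + p["b_mu"], h @ p["W_lv"] + p["b_lv"]

    def decode(self, z: np.ndarray) -> np.ndarray:
        p = self.params
        h = _relu(z @ p["W_hd"] + p["b_hd"]) if "W_hd" in p else z
        return _sigmoid(h @ p["W_o"] + p["b_o"])

    def score(self, x: np.ndarray) -> np.ndarray:
        """KL anomaly score per row of an (n, input_dim) feature matrix."""
        mu, lv = self.encode(x)
        return kl_anomaly_score(mu, lv)

    def score_frame(self, frame: np.ndarray, chunk_rows: int = 128) -> np.ndarray:
        """Per-pixel anomaly-score plane for an RGB frame."""
        planes = extract_features_frame(frame, names=self.feature_names)
        h, w, d = planes.shape
        out = np.empty((h, w), dtype=np.float64)
        for i in range(0, h, chunk_rows):
            block = planes[i : i + chunk_rows].reshape(-1, d)
            out[i : i + chunk_rows] = self.score(block).reshape(-1, w)
        return out

    def save(self, path: str | Path) -> None:
        """Write a checkpoint: JSON config/metadata next to an .npz of arrays."""
        path = Path(path)
        meta = {
            "config": asdict(self.config),
            "feature_names": list(self.feature_names),
            "params": sorted(self.params),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
        np.savez(
            path.with_suffix(".npz"),
            loss_trace=self.loss_trace,
            **self.params,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClvae":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        with np.load(path.with_suffix(".npz")) as z:
            arrays = {k: z[k] for k in z.files}
        trace = arrays.pop("loss_trace", None)
        return cls(
            params=arrays,
            config=VaeConfig(**meta["config"]),
            loss_trace=trace,
            feature_names=tuple(meta["feature_names"]),
        )


def _init_params(config: VaeConfig, rng: np.random.Generator) -> dict:
    d_in, d_z, d_out = config.input_dim, config.latent_dim, config.output_dim

    def w(shape):
        return rng.normal(0.0, 1.0 / np.sqrt(shape[0]), size=shape)

    params = {}
    enc_in = d_in
    if config.hidden_dim > 0:
        params["W_he"] = w((d_in, config.hidden_dim))
        params["b_he"] = np.zeros(config.hidden_dim)
        enc_in = config.hidden_dim
    params["W_mu"] = w((enc_in, d_z))
    params["b_mu"] = np.zeros(d_z)
    params["W_lv"] = w((enc_in, d_z))
    params["b_lv"] = np.zeros(d_z)
    dec_in = d_z
    if config.hidden_dim > 0:
        params["W_hd"] = w((d_z, config.hidden_dim))
        params["b_hd"] = np.zeros(config.hidden_dim)
        dec_in = config.hidden_dim
    params["W_o"] = w((dec_in, d_out))
    params["b_o"] = np.zeros(d_out)
    return params


def _encode_with_cache(params, x):
    if "W_he" in params:
        pre = x @ params["W_he"] + params["b_he"]
        h = _relu(pre)
    else:
        pre, h = None, x
    mu = h @ params["W_mu"] + params["b_mu"]
    lv = h @ params["W_lv"] + params["b_lv"]
    return mu, lv, h, pre


def _encoder_backward(params, grads, x, h, pre, dmu, dlv=None):
    """Accumulate encoder gradients given upstream dL/dmu (and dL/dlv)."""
    grads["W_mu"] += h.T @ dmu
    grads["b_mu"] += dmu.sum(0)
    dh = dmu @ params["W_mu"].T
    if dlv is not None:
        grads["W_lv"] += h.T @ dlv
        grads["b_lv"] += dlv.sum(0)
        dh = dh + dlv @ params["W_lv"].T
    if "W_he" in params:
        dpre = dh * (pre > 0)
        grads["W_he"] += x.T @ dpre
        grads["b_he"] += dpre.sum(0)


def train_clvae(
    normal: PixelSet | np.ndarray,
    pairs: ContrastivePairSet | None,
    config: VaeConfig,
    feature_names: tuple = FEATURE_NAMES,
) -> TrainedClvae:
    """Train the detector on normal pixels (plus optional contrastive pairs).

    ``normal`` may be a :class:`PixelSet` (features are extracted with
    ``feature_names``) or a ready-made (n, input_dim) feature matrix.  With
    ``pairs`` empty or None the contrastive term is omitted and the model is
    a plain beta-VAE.  Per epoch the normal set is swept in seeded
    mini-batches minimizing

        MSE(reconstruction) + beta(epoch) * KL + lambda * contrastive.

    Returns the trained model with its per-epoch loss trace.
    """
    X = normal.features(feature_names) if isinstance(normal, PixelSet) else np.asarray(
        normal, dtype=np.float64
    )
    if X.ndim != 2 or X.shape[1] != config.input_dim:
        raise ValueError(
            f"normal data must be (n, {config.input_dim}), got {X.shape}"
        )
    n = len(X)
    if n == 0:
        raise ValueError("normal set is empty")

    use_pairs = pairs is not None and len(pairs) > 0
    if use_pairs:
        Xn = pairs.normal.features(feature_names)
        Xa = pairs.anomaly.features(feature_names)
        if Xn.shape[1] != config.input_dim:
            raise ValueError("pair features do not match the input dimension")

    rng = np.random.default_rng(config.seed)
    params = _init_params(config, rng)
    opt = _Adam(params)
    d_out = config.output_dim
    trace = np.empty(config.epochs)

    for epoch in range(config.epochs):
        lr = lr_at(config, epoch)
        beta = beta_at(config, epoch)
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0

        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = X[idx]
            B = len(xb)
            grads = {k: np.zeros_like(v) for k, v in params.items()}

            # forward: reconstruction + KL on the normal batch
            mu, lv, h_enc, pre_enc = _encode_with_cache(params, xb)
            sigma = np.exp(0.5 * lv)
            eps = rng.standard_normal(mu.shape)
            z = mu + sigma * eps
            if "W_hd" in params:
                pre_dec = z @ params["W_hd"] + params["b_hd"]
                h_dec = _relu(pre_dec)
            else:
                pre_dec, h_dec = None, z
            logits = h_dec @ params["W_o"] + params["b_o"]
            xhat = _sigmoid(logits)

            rec = np.mean((xhat - xb) ** 2)
            kl = float(np.mean(kl_anomaly_score(mu, lv)))

            # backward: reconstruction
            dxhat = 2.0 * (xhat - xb) / (B * d_out)
            dlogits = dxhat * xhat * (1.0 - xhat)
            grads["W_o"] += h_dec.T @ dlogits
            grads["b_o"] += dlogits.sum(0)
            dh_dec = dlogits @ params["W_o"].T
            if "W_hd" in params:
                dpre = dh_dec * (pre_dec > 0)
                grads["W_hd"] += z.T @ dpre
                grads["b_hd"] += dpre.sum(0)
                dz = dpre @ params["W_hd"].T
            else:
                dz = dh_dec
            dmu = dz.copy()
            dlv = dz * eps * sigma * 0.5

            # backward: KL (mean over batch of the closed form)
            dmu += beta * mu / B
            dlv += beta * 0.5 * (sigma**2 - 1.0) / B
            _encoder_backward(params, grads, xb, h_enc, pre_enc, dmu, dlv)

            # contrastive term on a same-size batch of pairs
            con = 0.0
            if use_pairs:
                pidx = rng.integers(0, len(Xn), size=B)
                xn, xa = Xn[pidx], Xa[pidx]
                mu_n, _, h_n, pre_n = _encode_with_cache(params, xn)
                mu_a, _, h_a, pre_a = _encode_with_cache(params, xa)
                diff = mu_n - mu_a
                dist = np.sqrt((diff**2).sum(1) + 1e-12)
                gap = np.maximum(0.0, config.margin - dist)
                con = float(np.mean(gap**2))
                coeff = (
                    config.contrastive_weight * (-2.0) * gap / (dist * B)
                )[:, None]
                dmu_n = coeff * diff
                _encoder_backward(params, grads, xn, h_n, pre_n, dmu_n)
                _encoder_backward(params, grads, xa, h_a, pre_a, -dmu_n)

            opt.step(params, grads, lr)
            epoch_loss += rec + beta * kl + config.contrastive_weight * con
            n_batches += 1

        trace[epoch] = epoch_loss / n_batches
        if not np.isfinite(trace[epoch]):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")

    return TrainedClvae(params=params, config=config, loss_trace=trace,
                        feature_names=tuple(feature_names))


def calibrate_threshold(neg_scores: np.ndarray, target_specificity: float) -> float:
    """Threshold achieving at least the target specificity on negatives.

    Returns the ceil(target * n)-th ascending order statistic of the
    negative scores; with the decision rule "flag iff score > threshold"
    the achieved specificity on these scores is always >= the target.
    """
    s = np.asarray(neg_scores, dtype=np.float64).ravel()
    if s.size == 0:
        raise ValueError("need at least one negative score")
    if not 0 < target_specificity <= 1:
        raise ValueError("target specificity must lie in (0, 1]")
    k = int(np.ceil(target_specificity * s.size))
    return float(np.partition(s, k - 1)[k - 1])
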