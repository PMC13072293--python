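# Methods

This note documents the models, numerical choices and limitations of
`fluopix` in one place.  Everything stated here is computed by the package
itself (tests, examples or `scripts/acceptance.py`).

## Problem setting

A surgical microscope in blue-light mode delivers 8-bit RGB frames.  PPIX
fluorescence raises the red channel (and, weakly, green) of affected
pixels.  The task is pixel-wise: decide for every pixel whether it carries
fluorescence, at a fixed, conservative specificity, and map detected
pixels to a PPIX-sample-equivalent concentration.  Only single-pixel
information is used — no neighbourhood or image context.

## Preprocessing (module `preprocess`)

JPEG compression collapses dark 8×8 blocks onto few intensity levels,
producing isolated spikes in the per-channel intensity histogram.  For
each channel independently:

1. the 256-bin histogram is smoothed with a moving average (default
   window 5 bins; at the 0/255 edges the window truncates to its in-range
   part so no counts are fabricated);
2. levels whose count exceeds the smoothed density by more than a factor
   (default 1.5) are flagged;
3. flagged pixels are set to 0 in that channel only, then replaced by the
   median of their 9×9 neighbourhood computed on the zeroed channel
   (truncated at image borders; even-sized windows take the lower middle
   order statistic so the result is an existing 8-bit value).

The procedure is intentionally not idempotent — flagging is
data-dependent — but a second pass never changes more pixels than the
first.  In histogram tails (counts of a few) the spike test can fire
spuriously; the effect is a handful of re-interpolated pixels per frame.
For this reason the synthetic benchmark samples well ROIs eroded 5 px
inside each well, so a boundary pixel re-interpolated from background
neighbours cannot enter an evaluation pool — mirroring how regions of
interest are drawn inside samples in practice.

## Pixel features (module `features`)

The 10 features are {R, G, B, pR, pG, pB, H, S, V, E}: channel
intensities rescaled to [0, 1]; channel proportions c/(r+g+b) (1/3 each
for exactly black pixels, where proportions are undefined); HSV hue
(0 for achromatic pixels), saturation and value; and red excess
E = ((r − (g+b)/2)/255 + 0.5)/1.5, the affine map of the raw range
[−0.5, 1] onto [0, 1].  The list is configurable; two of the features
(R, pG) are also the quantification predictors.

## Anomaly detector (module `clvae`)

Architecture: linear encoder 10 → (mu, log sigma²) ∈ R³ ⊕ R³, linear
decoder 3 → 10 with sigmoid output (features live in [0, 1], so the
reconstruction loss is mean squared error).  A single ReLU hidden layer
can be toggled on both sides via `hidden_dim`; the default is the plain
10–3–10 stack.  Training is plain numpy with analytically derived
gradients and an in-package Adam optimizer — the model is far too small
to warrant a deep-learning framework — and is bit-reproducible for a
fixed seed.

Loss per mini-batch (size 256, 1000 epochs by default):

    MSE(x̂, x) + beta(t)·KL(q‖N(0,I)) + lambda·mean max(0, m − ‖mu_n − mu_a‖₂)²

* **beta schedule**: two-phase cyclic annealing over 20 cycles.  Within a
  cycle of length L, the first half follows a sigmoidal ramp normalized to
  start at exactly 0 and reach exactly beta_max at the last ramp epoch
  (s(u) = (σ(12u−6) − σ(−6))/(σ(6) − σ(−6))); the second half holds
  beta_max.  Cycle length must be even and ≥ 4.
* **learning rate**: lr(e) = 1e-3 · (0.1)^(e/(epochs−1)), hitting 1e-3
  and 1e-4 exactly at the ends.
* **contrastive term**: squared hinge on the Euclidean distance between
  the latent means of normal/anomaly pairs, margin m = 1, weight
  lambda = 1.  Anomaly pixels receive gradients only through this term —
  they are never reconstructed and contribute no KL — preserving the
  learn-the-normal-class premise.  With an empty pair set the model is a
  plain beta-VAE.

The anomaly score is the closed-form posterior divergence
½ Σ (mu² + sigma² − ln sigma² − 1), not a stochastic estimate: it is
deterministic, non-negative and exactly 0 when the posterior equals the
prior.

**Threshold calibration**: tau = the ⌈s·n⌉-th ascending order statistic of
n negative scores for target specificity s; with the rule "flag iff
score > tau" the achieved specificity on the calibration scores is
guaranteed ≥ s.  Exactly-black pixels are defined undetectable (their
scores are forced below any threshold), which also makes the
black-pixel-excluded specificity well defined.

## Baselines (module `baselines`)

SVM (RBF kernel k(u,v) = exp(−‖u−v‖²/s²), scale s = 5, cost C = 1),
Gaussian naive Bayes, and a 3→10 (ReLU) →2 (softmax) network trained by
cross-entropy (Adam, step 1e-3, 200 epochs, batch 256), all via
scikit-learn.  The baselines consume raw RGB in [0, 255]: feature
extraction was introduced specifically for the anomaly detector, and the
balanced 2-class training set is the baselines' native regime.  Scores are
signed decision values (SVM) or positive-class posteriors (NB, NN).

## Quantification (module `quantify`)

Predictor choice is justified by a regression random forest ranked by
out-of-bag permutation importance.  The forest is an explicit bagging
ensemble over scikit-learn decision trees with package-owned bootstrap
indices, so each tree's OOB rows are known exactly: a feature's
importance is the mean over trees of the increase in OOB squared error
after permuting the feature within the OOB rows (Breiman's estimator);
OOB R² comes from the aggregated OOB predictions.  Defaults: 100 trees,
⌊d/3⌋ features per split, unlimited depth.

Calibration models are ordinary least squares on polynomial bases:
f(x) = p1 + p2·x + p3·x² in R, and
f(x, y) = p00 + p10·x + p01·y + p20·x² + p11·x·y in (R, pG).
Predictions are clamped to [0, 5] µg/mL (the ladder maximum).  A
degenerate constant response reports R² = 0 by convention.  A reference
coefficient set for both forms ships with the package
(p1 = 2.166, p2 = 7.325, p3 = −0.02339; p00 = 0.0327, p10 = −1.009,
p01 = 0.6343, p20 = 46.99, p11 = −93.46); the numeric scale those
coefficients assume is not recorded, so the reference models are tagged
`scale="reference"` and used for evaluation-at-a-point and serialization
checks, not extrapolation.  Freshly fitted models are tagged
`scale="unit"` (predictors in [0, 1]).

## Evaluation (module `evaluate`)

ROC curves over all distinct thresholds with trapezoidal AUC (equal to
the tie-adjusted pairwise-comparison probability; the test suite checks
this against an exhaustive O(n²) oracle).  The "optimal operating point"
maximizes Youden's J = sensitivity + specificity − 1 with ties broken
toward higher specificity.  Detection-rate tables report, per distinct
concentration, the percentage of pixels scored above the calibrated
threshold; the rates are invariant under any jointly monotone transform
of scores and threshold.  Negative-frame specificity is reported per
frame and pooled, both over all pixels and excluding exactly-(0,0,0)
pixels.  The qualitative 2-D embedding wraps t-SNE (default perplexity
200, Minkowski distance of order 2 — the order is a package choice) and
is for visual inspection only.

## Synthetic scenes (module `synth`)

The generator supplies the ground truth that intraoperative data lacks.

**Sample scenes**: circular wells on a dark blue-cast background
(mean RGB (8, 10, 26), i.i.d. Gaussian noise sd 3, clipped and rounded to
8 bits), one well per ladder concentration plus a PPIX-free reference.
Concentration maps to mean red elevation through a saturating Hill
response A·c^h/(c^h + K^h) with defaults A = 175, K = 0.9 µg/mL,
h = 1.7 (h = 1 recovers a plain hyperbola).  These constants place the
ladder's visibility boundary between 0.5 and 0.2 µg/mL: elevations are
≈ 0.4 noise sd at 0.05 µg/mL, ≈ 1.4 sd at 0.1, ≈ 4 sd at 0.2 and ≥ 16 sd
at 0.5 — so concentrations ≥ 0.5 are unambiguous, 0.2/0.1 fall in the
detection transition zone and ≤ 0.05 is sub-noise.  A plain hyperbola
cannot realize all three anchors at once (its f(0.5)/f(0.2) ratio is
bounded by 2.5 below saturation), which is why the steeper Hill form is
the default.  Green rises at 0.15× the red response; blue is unaffected.
Well ROIs are eroded 5 px (see Preprocessing); the background ROI keeps
the same margin from well boundaries.

**Surgical frames** (default 1920×1080): low-frequency tissue texture in
dark violet tones inside a circular optical field (outside is exactly
black); Gaussian-profile fluorescent blobs whose per-pixel concentration
drives the same Hill response (tails below 0.005 µg/mL are truncated to
zero so the fluorescence mask is finite); near-saturated specular
reflection discs carrying zero concentration; an 8-px-grid-aligned dark
shadow rectangle that occludes fluorescence; and optional JPEG-like
artifacts — 8×8 blocks inside the dark region quantized per channel
(red/blue) to a single level on a 4-level grid, recorded in the artifact
mask.

**What the generator does not model**: optics, illumination gradients,
working distance, photobleaching, tissue texture statistics of real
cavities, chroma-subsampled JPEG blocking, or inter-patient variability.
Passing tests on these scenes demonstrates the *machinery* — set
assembly, training dynamics, threshold calibration, the structural
detection-rate pattern — not clinical performance.

## Default problem sizes

Study-scale defaults: balanced sets of 10,000 pixels per class; 60,000
normal pixels and 10,000 contrastive pairs for the benchmark clVAE
(500,000 / 50,000 for the transfer protocol); 1000 epochs.  The test
suite and examples run the same pipeline at reduced sizes chosen so the
pattern of interest is stable across seeds — typically 2 scenes per
split, ~3,000 pixels per class, 15,000 normals, 400 epochs (the 20-cycle
annealing structure is preserved; epochs must stay divisible by the
cycle count) — and the structural ladder test averages 5 seeds and allows
adjacent-rate increases only within 3 standard errors of the rate
difference, since rates at the bottom of the ladder sit at the
false-positive floor where strict per-seed monotonicity is not a
statistically meaningful expectation.

## Known limitations

* The anomaly detector relies on single-pixel features; specular
  reflections are its dominant false-positive source (they are the
  dominant deviation from dark normal tissue), exactly as the
  negative-frame evaluation shows.
* PPIX-sample-equivalent concentrations are relative to the calibration
  ladder, not absolute tissue concentrations; no illumination or
  distance correction is applied.
* The shipped reference polynomial extrapolates outside the 0–5 µg/mL
  ladder for parts of the unit square; predictions are clamped, and
  refitting on one's own calibration data is preferred.
* SVM training does not scale well beyond a few 10⁴ pixels (kernel
  matrix growth); the defaults keep it at 20,000.
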