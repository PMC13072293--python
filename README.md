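# fluopix

Pixel-wise detection and quantification of protoporphyrin-IX (PPIX)
fluorescence in conventional RGB images from neurosurgical microscopes.

## The problem

During 5-ALA fluorescence-guided glioblastoma resection, tumour tissue
accumulates PPIX and glows pinkish-red (~635 nm) under the microscope's
blue-light mode.  At infiltrative tumour margins the signal fades below the
threshold of visual perception, so residual tumour is routinely left behind.
`fluopix` implements a machine-learning pipeline that pushes fluorescence
detection below the visual threshold using nothing but the standard RGB
camera stream: it classifies every pixel as fluorescent or not, calibrates
its decision threshold to a fixed 99% specificity, and converts detected
signal into a *PPIX-sample-equivalent* concentration map for display.

It is a library first (importable modules plus `examples/`), with a thin
`fluopix` CLI for the common end-to-end runs.

## The method

The core detector is a **contrastive-loss variational autoencoder (clVAE)**
used for anomaly detection.  Each pixel is expanded to a 10-dimensional
feature vector

x = (R, G, B, pR, pG, pB, H, S, V, E),

channel intensities, channel proportions, HSV coordinates and a red-excess
term, all in [0, 1].  A VAE with a 3-dimensional diagonal-Gaussian latent
q(z|x) = N(mu(x), diag(sigma²(x))) is trained **only on non-fluorescent
("normal") pixels**, minimizing

L = MSE(x̂, x) + beta(t) · KL(q(z|x) ‖ N(0, I)) + lambda · max(0, m − ‖mu_n − mu_a‖)²,

where the last term pushes normal/anomaly pixel pairs apart in latent-mean
space (anomaly pixels are never reconstructed).  The KL weight beta follows
a two-phase cyclic annealing schedule (sigmoidal ramp to beta_max, then a
plateau, over 20 cycles of 1000 epochs), and the learning rate decays
exponentially from 1e-3 to 1e-4.  At test time the per-pixel anomaly score
is the closed-form divergence

KL = ½ Σ_j (mu_j² + sigma_j² − ln sigma_j² − 1),

large whenever a pixel does not resemble the learned normal class.  The
decision threshold tau is the order statistic of negative-pixel scores that
guarantees a chosen specificity (default 99%).

Around the detector the package provides: JPEG artifact removal
(histogram-spike detection + 9×9 median interpolation), three classical
baselines (RBF-SVM with kernel scale 5, Gaussian naive Bayes, a 10-unit
ReLU network), ROC/operating-point/detection-rate evaluation, random-forest
OOB permutation feature ranking, polynomial concentration calibration
(quadratic in R; bivariate in R and pG), and a seeded synthetic scene
generator — sample ladders over the dilution series
{5, 2, 1, 0.5, 0.2, 0.1, 0.05, 0.025, 0.01, 0} µg/mL and surgical frames
with fluorescent blobs, specular reflections and ground-truth masks — so
the entire pipeline is testable without clinical data.

## Worked example

`examples/03_detection_rate_benchmark.py` renders train/test sample
scenes, trains all six models and prints the detection-rate table at 99%
specificity (scaled-down sizes, seed 1):

```
detection rate (%) at 99% specificity:
   model   c=5   c=2   c=1  c=0.5  c=0.2  c=0.1  c=0.05  c=0.025  c=0.01
     svm 100.0 100.0 100.0  100.0  88.47   6.43    1.98     0.85    1.51
      nb 100.0 100.0 100.0  100.0  80.25   5.10    1.61     0.66    1.51
      nn 100.0 100.0 100.0  100.0  44.90   6.05    2.08     0.76    1.61
clvae-b1 100.0 100.0 100.0  100.0  95.65  11.72    2.17     0.95    1.80
clvae-b2 100.0 100.0 100.0  100.0  91.49   8.98    1.61     0.85    1.51
clvae-b3 100.0 100.0 100.0  100.0  94.90   9.64    1.98     0.76    1.13
```

Reading the table: every model detects all pixels down to 0.5 µg/mL (the
faintest visually perceptible level in the synthetic calibration), and the
clVAE variants detect clearly more pixels than the SVM and the neural
network at the *non-visible* concentrations 0.2 and 0.1 µg/mL — the
anomaly-detection advantage the pipeline exists for.  Rates at and below
0.05 µg/mL sit at the ~1% false-positive floor implied by the 99%
specificity threshold.

The other examples cover artifact preprocessing, training and scoring the
clVAE directly, feature ranking + concentration calibration, and the
transfer protocol on surgical frames (negative-frame specificity and
annotation overlap).

## Command line

```bash
fluopix synth --kind sample --seed 1 --out scene/
fluopix train --model clvae --beta 1 --data scene/ --out ckpt
fluopix detect --ckpt ckpt --image scene/frame.png --spec 0.99 --out det
fluopix bench --seed 1 --out bench_out/
fluopix transfer --seed 1 --out transfer_out/
```

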