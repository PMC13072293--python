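"""Train the contrastive-loss VAE and score a held-out dilution ladder.

Normal (non-fluorescent) pixels come from the reference well and the dark
background; anomaly pairs use pixels from the clearly fluorescent wells
(5, 2, 1 ug/mL).  The held-out scene's per-well mean KL anomaly score
should fall monotonically with concentration and approach the background
level below ~0.05 ug/mL.
"""

import fluopix as fp
from fluopix.sampling import NEGATIVE, POSITIVE, PixelSet, extract_roi_pixels

spec = fp.SampleSceneSpec(well_radius=18)
train_frame, train_truth = fp.render_sample_scene(spec, seed=0)
test_frame, test_truth = fp.render_sample_scene(spec, seed=1)

positives = PixelSet.concat([
    extract_roi_pixels(train_frame, train_truth.roi_masks[c], POSITIVE, c)
    for c in (5.0, 2.0, 1.0)
])
negatives = PixelSet.concat([
    extract_roi_pixels(train_frame, train_truth.roi_masks[0.0], NEGATIVE, 0.0),
    extract_roi_pixels(train_frame, train_truth.background_mask, NEGATIVE, 0.0),
])
normal, pairs = fp.build_anomaly_training_set(
    negatives, positives, n_normal=15_000, n_pairs=1_500, seed=0
)

model = fp.train_clvae(normal, pairs,
                       fp.VaeConfig(beta_max=1.0, epochs=400, cycles=20, seed=0))

print("held-out mean KL anomaly score per well:")
for c in (5.0, 2.0, 1.0, 0.5, 0.2, 0.1, 0.05, 0.025, 0.01, 0.0):
    px = extract_roi_pixels(test_frame, test_truth.roi_masks[c], POSITIVE
                            if c > 0 else NEGATIVE, c)
    print(f"  c = {c:>6g} ug/mL : {model.score(px.features()).mean():10.3e}")
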