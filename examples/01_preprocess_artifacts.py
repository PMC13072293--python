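"""Remove JPEG block artifacts from a dark surgical frame.

Renders a negative surgical frame with injected 8x8 block-quantization
artifacts, runs the histogram-spike detector and median interpolation, and
reports how precisely the repair was targeted.
"""

import fluopix as fp

spec = fp.SurgicalSceneSpec(
    image_size=(270, 480), n_blobs=0, n_reflections=3, inject_artifacts=True
)
frame, truth = fp.render_surgical_scene(spec, seed=4)

clean = fp.preprocess_frame(frame, window=5, factor=1.5)
changed = (clean != frame).any(axis=2)

print(f"injected artifact pixels : {truth.artifact_mask.sum()}")
print(f"repaired artifact pixels : {changed[truth.artifact_mask].sum()}")
print(f"collateral changed pixels: {changed[~truth.artifact_mask].sum()} "
      f"({100 * changed[~truth.artifact_mask].mean():.2f}% of clean pixels)")
# A good pass repairs essentially all injected block pixels while leaving
# well over 99% of untouched pixels bit-identical.
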