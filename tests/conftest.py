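import pytest

from fluopix import (
    SampleSceneSpec,
    SurgicalSceneSpec,
    VaeConfig,
    render_sample_scene,
    render_surgical_scene,
    train_clvae,
)
from fluopix.sampling import (
    NEGATIVE,
    POSITIVE,
    PixelSet,
    build_anomaly_training_set,
    extract_roi_pixels,
)


@pytest.fixture(scope="session")
def sample_scene():
    """A small rendered sample-ladder scene with ground truth."""
    spec = SampleSceneSpec(well_radius=14)
    return render_sample_scene(spec, seed=7)


@pytest.fixture(scope="session")
def surgical_scene():
    spec = SurgicalSceneSpec(
        image_size=(270, 480), n_blobs=2, n_reflections=3, inject_artifacts=True
    )
    return render_surgical_scene(spec, seed=11)


def ladder_pools(frame, gt):
    """Positive (c in {5,2,1}) and negative (reference + background) pools."""
    pos = PixelSet.concat(
        [extract_roi_pixels(frame, gt.roi_masks[c], POSITIVE, c)
         for c in (5.0, 2.0, 1.0)]
    )
    neg = PixelSet.concat([
        extract_roi_pixels(frame, gt.roi_masks[0.0], NEGATIVE, 0.0),
        extract_roi_pixels(frame, gt.background_mask, NEGATIVE, 0.0),
    ])
    return pos, neg


@pytest.fixture(scope="session")
def tiny_clvae(sample_scene):
    """A quickly trained clVAE used by scoring/IO tests."""
    frame, gt = sample_scene
    pos, neg = ladder_pools(frame, gt)
    normal, pairs = build_anomaly_training_set(neg, pos, 4000, 600, seed=0)
    cfg = VaeConfig(epochs=80, cycles=20, seed=0)
    return train_clvae(normal, pairs, cfg)
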