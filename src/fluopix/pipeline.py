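"""End-to-end experiment orchestration.

Two experiments are wired together here, both driven entirely by synthetic
scenes (or user-supplied frames) and a single seeded configuration:

* :func:`run_synthetic_benchmark` — the sample-ladder benchmark: render
  train/test sample scenes, preprocess, assemble the training compositions,
  train the full model roster (SVM, NB, NN, clVAE at beta = 1, 2, 3) and
  report ROC/AUC, the optimal operating point and the per-concentration
  detection-rate table at a fixed-specificity threshold.
* :func:`run_transfer_evaluation` — the intraoperative transfer protocol:
  train a beta = 1 clVAE on pixels from negative (non-fluorescence-guided)
  frames, calibrate the threshold on negative-frame scores, then report
  negative-frame specificity, annotation overlap on fluorescence-guided
  frames and quantified concentration overlays.

Every random draw descends from the config's seed through a spawned seed
tree, so reports are byte-identical across re-runs of the same config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import baselines as bl
from .clvae import TrainedClvae, VaeConfig, calibrate_threshold, train_clvae
from .evaluate import (
    annotation_overlap,
    detection_mask,
    detection_rate_table,
    negative_frame_specificity,
    optimal_operating_point,
    roc_curve,
)
from .frame import black_mask
from .preprocess import preprocess_frame
from .quantify import fit_poly_2d, render_concentration_map
from .sampling import (
    NEGATIVE,
    POSITIVE,
    PixelSet,
    build_anomaly_training_set,
    build_balanced_training_set,
    extract_roi_pixels,
)
from .synth import SampleSceneSpec, SurgicalSceneSpec, render_sample_scene, render_surgical_scene

DEFAULT_ROSTER = ("svm", "nb", "nn", "clvae-b1", "clvae-b2", "clvae-b3")
HIGH_CONCS = (5.0, 2.0, 1.0)  # "clearly fluorescent" training concentrations


@dataclass
class BenchmarkConfig:
    sample_spec: SampleSceneSpec = field(
        default_factory=lambda: SampleSceneSpec(well_radius=36)
    )
    n_train_scenes: int = 3
    n_test_scenes: int = 3
    n_per_class: int = 10_000          # balanced set size per class
    n_normal: int = 60_000             # clVAE normal-pool draw
    n_pairs: int = 10_000              # contrastive pairs
    roster: tuple = DEFAULT_ROSTER
    target_specificity: float = 0.99
    vae: VaeConfig = field(default_factory=VaeConfig)
    preprocess: bool = True
    seed: int = 0
    out_dir: str | None = None


@dataclass
class BenchmarkReport:
    """Per-model ROC summary and detection-rate table, plus run metadata."""

    summary: pd.DataFrame       # one row per model
    rates: pd.DataFrame         # model x concentration detection rates (%)
    metadata: dict

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(out / "benchmark_summary.csv", index=False)
        self.rates.to_csv(out / "benchmark_detection_rates.csv", index=False)
        (out / "benchmark_metadata.json").write_text(
            json.dumps(self.metadata, indent=2, sort_keys=True)
        )


def _config_digest(cfg) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _subseed(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1)[0] % (2**31 - 1))


def _ladder_pools(frames, truths, high_concs):
    """Split scene pixels into positive / negative / per-concentration sets."""
    pos_train, neg, per_conc = [], [], {}
    for fid, (frame, gt) in enumerate(zip(frames, truths)):
        for c, mask in gt.roi_masks.items():
            if c > 0:
                ps = extract_roi_pixels(frame, mask, POSITIVE, c, fid)
                per_conc.setdefault(c, []).append(ps)
                if c in high_concs:
                    pos_train.append(ps)
            else:
                neg.append(extract_roi_pixels(frame, mask, NEGATIVE, 0.0, fid))
        neg.append(
            extract_roi_pixels(frame, gt.background_mask, NEGATIVE, 0.0, fid)
        )
    return (
        PixelSet.concat(pos_train),
        PixelSet.concat(neg),
        {c: PixelSet.concat(v) for c, v in per_conc.items()},
    )


def _train_roster(config, balanced, normal, pairs, seeds):
    models = {}
    for name in config.roster:
        if name.startswith("clvae"):
            beta = float(name.rsplit("b", 1)[-1])
            vcfg = replace(config.vae, beta_max=beta, seed=_subseed(seeds[name]))
            models[name] = train_clvae(normal, pairs, vcfg)
        else:
            spec = bl.BaselineSpec(kind=name, seed=_subseed(seeds[name]))
            models[name] = bl.train_baseline(spec, balanced)
    return models


def _score(model, pixels: PixelSet) -> np.ndarray:
    if isinstance(model, TrainedClvae):
        return model.score(pixels.features(model.feature_names))
    return bl.score_pixels(model, pixels)


def run_synthetic_benchmark(config: BenchmarkConfig) -> BenchmarkReport:
    """Run the full sample-ladder benchmark and assemble the report."""
    root = np.random.SeedSequence(config.seed)
    keys = ["scenes", "balanced", "anomaly"] + list(config.roster)
    seeds = dict(zip(keys, root.spawn(len(keys))))

    scene_seeds = seeds["scenes"].spawn(config.n_train_scenes + config.n_test_scenes)
    frames, truths = [], []
    for s in scene_seeds:
        frame, gt = render_sample_scene(config.sample_spec, _subseed(s))
        if config.preprocess:
            frame = preprocess_frame(frame)
        frames.append(frame)
        truths.append(gt)
    tr = slice(0, config.n_train_scenes)
    te = slice(config.n_train_scenes, None)

    pos_train, neg_train, _ = _ladder_pools(frames[tr], truths[tr], HIGH_CONCS)
    _, neg_test, conc_test = _ladder_pools(frames[te], truths[te], HIGH_CONCS)

    balanced = build_balanced_training_set(
        pos_train, neg_train, config.n_per_class, _subseed(seeds["balanced"])
    )
    normal, pairs = build_anomaly_training_set(
        neg_train, pos_train, config.n_normal, config.n_pairs,
        _subseed(seeds["anomaly"]),
    )
    models = _train_roster(config, balanced, normal, pairs, seeds)

    pos_test = PixelSet.concat([conc_test[c] for c in sorted(conc_test, reverse=True)])
    eval_set = PixelSet.concat([pos_test, neg_test])
    labels = eval_set.label

    summary_rows, rate_rows = [], []
    for name, model in models.items():
        scores = _score(model, eval_set)
        curve = roc_curve(scores, labels)
        op = optimal_operating_point(curve)
        tau = calibrate_threshold(scores[labels == NEGATIVE],
                                  config.target_specificity)
        pos_mask = labels == POSITIVE
        table = detection_rate_table(scores[pos_mask],
                                     eval_set.conc[pos_mask], tau)
        summary_rows.append({
            "model": name,
            "auc": round(curve.auc, 4),
            "accuracy": round(op.accuracy, 4),
            "sensitivity": round(op.sensitivity, 4),
            "specificity": round(op.specificity, 4),
            "threshold_99": tau,
        })
        row = {"model": name}
        for _, r in table.iterrows():
            row[f"c={r['concentration']:g}"] = round(r["detection_rate"], 2)
        rate_rows.append(row)

    metadata = {
        "config_digest": _config_digest(config),
        "seed": config.seed,
        "roster": list(config.roster),
        "n_eval_pixels": int(len(eval_set)),
    }
    report = BenchmarkReport(pd.DataFrame(summary_rows),
                             pd.DataFrame(rate_rows), metadata)
    if config.out_dir:
        report.save(config.out_dir)
    return report


@dataclass
class TransferConfig:
    neg_spec: SurgicalSceneSpec = field(
        default_factory=lambda: SurgicalSceneSpec(n_blobs=0, n_reflections=4)
    )
    fgs_spec: SurgicalSceneSpec = field(
        default_factory=lambda: SurgicalSceneSpec(n_blobs=3, n_reflections=3)
    )
    n_train_neg_frames: int = 2
    n_eval_neg_frames: int = 5
    n_train_fgs_frames: int = 2
    n_eval_fgs_frames: int = 3
    n_normal: int = 500_000
    n_pairs: int = 50_000
    anomaly_min_conc: float = 1.0      # blob pixels this strong feed the pairs
    annotation_min_conc: float = 0.5   # visible-fluorescence annotation proxy
    vae: VaeConfig = field(default_factory=lambda: VaeConfig(beta_max=1.0))
    target_specificity: float = 0.99
    preprocess: bool = True
    seed: int = 0
    out_dir: str | None = None


def _random_pixelset(frame, keep_mask, label, n, seed, frame_id):
    rows, cols = np.nonzero(keep_mask)
    rng = np.random.default_rng(seed)
    if n < len(rows):
        idx = rng.choice(len(rows), n, replace=False)
        rows, cols = rows[idx], cols[idx]
    return PixelSet(
        rgb=frame[rows, cols].astype(float),
        label=np.full(len(rows), label, dtype=np.int8),
        coords=np.stack([rows, cols], axis=1),
        frame_id=np.full(len(rows), frame_id, dtype=np.int64),
    )


def run_transfer_evaluation(config: TransferConfig):
    """Transfer protocol on surgical frames.

    Returns ``(specificity_report, overlap_reports, artifacts)`` where
    ``artifacts`` holds the trained model, threshold, masks, concentration
    maps and (when ``out_dir`` is set) the paths of the written overlays.
    """
    root = np.random.SeedSequence(config.seed)
    s_neg, s_fgs, s_sample, s_anom, s_norm, s_vae = root.spawn(6)

    def render_many(spec, n, seq):
        out = []
        for s in seq.spawn(n):
            frame, gt = render_surgical_scene(spec, _subseed(s))
            if config.preprocess:
                frame = preprocess_frame(frame)
            out.append((frame, gt))
        return out

    train_neg = render_many(config.neg_spec,
                            config.n_train_neg_frames + config.n_eval_neg_frames,
                            s_neg)
    eval_neg = train_neg[config.n_train_neg_frames:]
    train_neg = train_neg[: config.n_train_neg_frames]
    fgs = render_many(config.fgs_spec,
                      config.n_train_fgs_frames + config.n_eval_fgs_frames,
                      s_fgs)
    eval_fgs = fgs[config.n_train_fgs_frames:]
    train_fgs = fgs[: config.n_train_fgs_frames]

    # normal pool: random non-black pixels of the training negative frames
    per_frame = -(-config.n_normal // len(train_neg))
    normal_pool = PixelSet.concat([
        _random_pixelset(f, ~black_mask(f), NEGATIVE, per_frame,
                         _subseed(s), fid)
        for fid, ((f, _), s) in enumerate(
            zip(train_neg, s_norm.spawn(len(train_neg)))
        )
    ])
    # anomaly pool: strongly fluorescent blob pixels of the training frames
    anomaly_pool = PixelSet.concat([
        extract_roi_pixels(f, gt.concentration_map >= config.anomaly_min_conc,
                           POSITIVE, frame_id=fid)
        for fid, (f, gt) in enumerate(train_fgs)
    ])

    normal, pairs = build_anomaly_training_set(
        normal_pool, anomaly_pool,
        min(config.n_normal, len(normal_pool)),
        min(config.n_pairs, len(anomaly_pool)),
        _subseed(s_anom),
    )
    vcfg = replace(config.vae, seed=_subseed(s_vae))
    model = train_clvae(normal, pairs, vcfg)

    # threshold from the calibration (training) negative frames
    cal_scores = np.concatenate([
        model.score_frame(f)[~black_mask(f)] for f, _ in train_neg
    ])
    tau = calibrate_threshold(cal_scores, config.target_specificity)

    neg_masks = [detection_mask(model.score_frame(f), f, tau)
                 for f, _ in eval_neg]
    spec_report = negative_frame_specificity(neg_masks,
                                             [f for f, _ in eval_neg])

    # quantification model calibrated on a sample-ladder scene
    sframe, sgt = render_sample_scene(SampleSceneSpec(), _subseed(s_sample))
    wells = sgt.fluorescence_mask
    from .features import extract_features_frame

    feats = extract_features_frame(sframe, names=("R", "pG"))
    quant = fit_poly_2d(feats[..., 0][wells], feats[..., 1][wells],
                        sgt.concentration_map[wells])

    overlaps, fgs_masks, conc_maps, overlay_paths = [], [], [], []
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    for i, (frame, gt) in enumerate(eval_fgs):
        mask = detection_mask(model.score_frame(frame), frame, tau)
        annot = gt.concentration_map >= config.annotation_min_conc
        overlaps.append(annotation_overlap(mask, annot))
        conc_map, overlay = render_concentration_map(frame, quant, mask)
        fgs_masks.append(mask)
        conc_maps.append(conc_map)
        if out:
            from .io import write_float_map, write_frame, write_mask

            write_frame(out / f"fgs_{i}_original.png", frame)
            write_frame(out / f"fgs_{i}_overlay.png", overlay)
            write_mask(out / f"fgs_{i}_mask.png", mask)
            write_mask(out / f"fgs_{i}_annotation.png", annot)
            write_float_map(out / f"fgs_{i}_concentration.h5", "concentration",
                            conc_map)
            overlay_paths.append(str(out / f"fgs_{i}_overlay.png"))
    if out:
        spec_report.to_frame().to_csv(out / "negative_frame_specificity.csv",
                                      index=False)

    artifacts = {
        "model": model,
        "threshold": tau,
        "quant_model": quant,
        "neg_masks": neg_masks,
        "fgs_masks": fgs_masks,
        "conc_maps": conc_maps,
        "eval_fgs": eval_fgs,
        "overlay_paths": overlay_paths,
        "config_digest": _config_digest(config),
    }
    return spec_report, overlaps, artifacts
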