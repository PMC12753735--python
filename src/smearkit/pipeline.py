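"""End-to-end orchestration: synthesize -> preprocess -> segment ->
extract -> classify -> evaluate.

Each run writes a directory containing the resolved config snapshot,
per-stage outputs (smear dataset, predicted masks, extracted ROI counts,
per-fold classifier metrics) and a ``metrics.json`` summary.  Re-running
with the same config and seed reproduces ``metrics.json`` exactly.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import synthetic
from .classifier import CLASS_NAMES, LWCNNConfig, stratified_kfold, train_classifier
from .config import PipelineConfig, dump_config
from .evaluation import aggregate_folds, multiclass_report, overlap_metrics
from .nn.train import TrainingPolicy
from .preprocessing import augment_batch, clahe_enhance, normalize_unit
from .unet import UNetConfig, build_unet, predict_mask, train_segmenter
from .watershed import separate_cells

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _stage(name):
    logger.info("stage %s", name)
    return time.time()


def _make_smears(cfg: PipelineConfig):
    samples = []
    for i in range(cfg.synth.n_smears):
        spec = synthetic.SmearSpec(
            height=cfg.synth.height, width=cfg.synth.width,
            cells_per_class={n: cfg.synth.cells_per_class for n in CLASS_NAMES},
            overlap_fraction=cfg.synth.overlap_fraction,
            noise_sigma=cfg.synth.noise_sigma,
            illumination_gradient=cfg.synth.illumination_gradient,
            seed=cfg.seed * 100_003 + i,
            attempt_cap=300,
        )
        samples.append(synthetic.generate_smear(spec))
    return samples


def _direct_tiles(samples, roi_size, rng):
    """Fixed-grid tiles labelled by the dominant instance class (the
    no-ROI-segmentation ablation); background-dominated tiles dropped."""
    from .preprocessing import ResizeSpec, resize_bilinear

    xs, ys = [], []
    for s in samples:
        h, w = s.instances.shape
        step = max(h // 3, 24)
        stride = max(step // 2, 12)
        for top in range(0, h - step + 1, stride):
            for left in range(0, w - step + 1, stride):
                tile_inst = s.instances[top : top + step, left : left + step]
                ids, counts = np.unique(tile_inst[tile_inst > 0], return_counts=True)
                if ids.size == 0 or counts.max() < 0.05 * step * step:
                    continue
                name = s.labels[int(ids[counts.argmax()])]
                tile = s.image[top : top + step, left : left + step]
                xs.append(resize_bilinear(tile, ResizeSpec(roi_size, roi_size)))
                ys.append(CLASS_NAMES.index(name))
    return np.stack(xs), np.asarray(ys)


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the configured pipeline on synthetic data; returns the run
    directory (created if needed) containing all stage outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(dump_config(cfg))
    metrics: dict = {"stages": []}
    rng = np.random.default_rng(cfg.seed)

    # 1 — synthesize
    t0 = _stage("synth")
    samples = _make_smears(cfg)
    synthetic.write_smear_dataset(out / "synth", [s.spec for s in samples[:4]])
    metrics["stages"].append("synth")
    metrics["synth"] = {
        "n_smears": len(samples),
        "mean_overlap_fraction": round(float(np.mean([s.achieved_overlap_fraction for s in samples])), 4),
    }

    # 2 — preprocess
    _stage("preprocess")
    images = [clahe_enhance(s.image, cfg.clahe) if cfg.toggles.clahe else s.image for s in samples]
    masks = [(s.instances > 0).astype(np.float32) for s in samples]
    metrics["stages"].append("preprocess")
    metrics["preprocess"] = {"clahe": cfg.toggles.clahe}

    roi_count = 0
    if cfg.toggles.segmentation:
        # 3 — segment
        _stage("segment")
        x = np.stack([normalize_unit(im) for im in images])
        y = np.stack(masks)
        model = build_unet(
            UNetConfig(input_hw=(cfg.synth.height, cfg.synth.width),
                       width_divisor=cfg.unet.width_divisor,
                       activation=cfg.unet.activation, l2=cfg.unet.l2),
            seed=cfg.seed,
        )
        policy = TrainingPolicy(lr=cfg.unet.lr, batch_size=cfg.unet.batch_size,
                                max_epochs=cfg.unet.max_epochs, loss="bce", l2=cfg.unet.l2)
        model, hist = train_segmenter(model, x, y, policy, seed=cfg.seed, stop_iou=0.9)
        ious = []
        pred_masks = []
        for im, m in zip(x, y):
            prob, pred = predict_mask(model, im, tau=cfg.unet.tau)
            pred_masks.append(pred)
            ious.append(overlap_metrics(pred, m > 0.5)[0])
        metrics["stages"].append("segment")
        metrics["segment"] = {"epochs": len(hist), "mean_iou": round(float(np.mean(ious)), 4)}

        # 4 — extract
        _stage("extract")
        ws = cfg.watershed
        for s, pred in zip(samples, pred_masks):
            labels, rois, removed = separate_cells(s.image, pred, ws, cfg.synth.roi_size)
            roi_count += len(rois)
        metrics["stages"].append("extract")
        metrics["extract"] = {"rois_from_predicted_masks": roi_count}

    # 5 — classify (ROI dataset from the generator keeps labels exact)
    _stage("classify")
    if cfg.toggles.segmentation:
        x_roi, y_roi = synthetic.generate_roi_arrays(
            cfg.synth.rois_per_class, roi_size=cfg.synth.roi_size, seed=cfg.seed + 1
        )
    else:
        x_roi, y_roi = _direct_tiles(samples, cfg.synth.roi_size, rng)
        metrics.setdefault("extract", {"rois_from_predicted_masks": 0})
        metrics["stages"].append("extract")
    folds = stratified_kfold(y_roi, k=cfg.lwcnn.folds, seed=cfg.seed)
    lw_cfg = LWCNNConfig(dropout_conv=cfg.lwcnn.dropout_conv,
                         dropout_dense=cfg.lwcnn.dropout_dense,
                         extra_conv_blocks=cfg.toggles.extra_conv_blocks)
    policy = TrainingPolicy(lr=cfg.lwcnn.lr, batch_size=cfg.lwcnn.batch_size,
                            max_epochs=cfg.lwcnn.max_epochs, loss="cce", l2=0.0)
    augment = None
    if cfg.toggles.augmentation:
        def augment(imgs, rng_):
            byte = np.rint(np.clip(imgs, 0, 1) * 255).astype(np.uint8)
            return normalize_unit(augment_batch(byte, rng_))
    results = train_classifier(normalize_unit(x_roi), y_roi, folds, lw_cfg, policy,
                               seed=cfg.seed, augment_fn=augment, stop_accuracy=0.97)
    metrics["stages"].append("classify")

    # 6 — evaluate
    _stage("evaluate")
    fold_rows = []
    for r in results:
        rep = multiclass_report(r.y_true, r.y_pred)
        fold_rows.append({"accuracy": rep["accuracy"], "precision": rep["precision"],
                          "recall": rep["recall"], "f1": rep["f1"]})
    table = aggregate_folds(fold_rows, decimals=4)
    table.to_csv(out / "classification_metrics.csv")
    metrics["stages"].append("evaluate")
    metrics["classification"] = {k: float(table.loc["mean", k]) for k in table.columns}
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    return out
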