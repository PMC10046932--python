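"""End-to-end orchestration: preprocess -> segment -> features -> classify
-> evaluate, with a run log recording every parameter and seed."""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import crnn, evaluation, io as gio, phantom, preprocessing, segmentation, texture
from .config import PipelineConfig

logger = logging.getLogger("gliopipe")


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_manifest(manifest_path: str | Path) -> list[phantom.LabeledImage]:
    """Read images listed in a manifest CSV (filename, label[, ...])."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    items = []
    with open(manifest_path) as fh:
        for row in csv.DictReader(fh):
            path = base / row["filename"]
            try:
                img = gio.read_image(path)
            except (ValueError, OSError) as exc:
                logger.warning("skipping unreadable image %s: %s", path, exc)
                continue
            items.append(phantom.LabeledImage(
                image=img, label=row["label"],
                truth_mask=np.zeros_like(img, dtype=bool),
                spec=phantom.PhantomSpec(height=img.shape[0], width=img.shape[1],
                                         has_tumor=False, tumor_area_fraction=0.0),
            ))
    if not items:
        raise ValueError(f"no readable images listed in {manifest_path}")
    return items


def standard_benchmark(n_train: int = 200, n_test: int = 100, seed: int = 0,
                       size: int = 32, tumor_contrast: float = 0.3,
                       noise_variance: float = 0.002):
    """The standard phantom benchmark: balanced tumor/normal phantoms at the
    stated contrast and noise level, split train/test by generation."""
    base = phantom.PhantomSpec(height=size, width=size,
                               tumor_contrast=tumor_contrast,
                               noise_variance=noise_variance)
    items = phantom.make_dataset(n_train + n_test, 0.5, base, seed=seed)
    train_items, test_items = evaluation.split_dataset(
        items, n_train / (n_train + n_test), seed=seed)
    return train_items, test_items


def run_pipeline(config: PipelineConfig,
                 source: "str | Path | list[phantom.LabeledImage]",
                 out_dir: str | Path | None = None) -> dict:
    """Execute the full workflow on a manifest path or in-memory dataset.

    Returns a report dict with per-image predictions, segmentation stats,
    feature rows, confusion metrics, and the config hash; artifacts (masks,
    feature CSV, predictions CSV, metrics JSON, run log) are written when
    ``out_dir`` is given.
    """
    if isinstance(source, (str, Path)):
        items = load_manifest(source)
    else:
        items = list(source)
    if not items:
        raise ValueError("empty input set")

    out = None
    if out_dir is not None:
        out = Path(out_dir)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out / "run.log")
        handler.setFormatter(logging.Formatter(
            "%(asctime)s %(levelname)s [%(name)s] %(message)s"))
        logger.addHandler(handler)
        if logger.getEffectiveLevel() > logging.INFO:
            logger.setLevel(logging.INFO)
    logger.info("run config hash=%s seed=%d", _config_hash(config), config.seed)
    logger.info("config: %s", json.dumps(config.to_dict(), sort_keys=True))

    pp, seg_cfg, feat_cfg = config.preprocessing, config.segmentation, config.features

    processed, feature_rows, seg_rows = [], [], []
    for i, item in enumerate(items):
        img = preprocessing.denoise(item.image, pp.window_size)
        if pp.sharpen_amount > 0:
            img = preprocessing.sharpen(img, pp.sharpen_amount)
        processed.append(img)

        min_area = max(1, int(round(seg_cfg.min_area_fraction * img.size)))
        mask = segmentation.segment_image(
            img, c=seg_cfg.clusters, m=seg_cfg.fuzziness, eps=seg_cfg.eps,
            max_iter=seg_cfg.max_iter, seed=config.seed, min_area=min_area)
        brain = img > (phantom.BACKGROUND_LEVEL + phantom.BRAIN_LEVEL) / 2.0
        if brain.any():
            percent, count = segmentation.tumor_stats(mask, brain)
        else:
            percent, count = 0.0, int(mask.pixels.sum())
        seg_rows.append({"image_id": i, "affected_percent": percent,
                         "defective_cell_count": count})
        if out is not None:
            gio.write_mask(mask.pixels, out / "masks" / f"mask_{i:05d}.png")

        fmask = mask.pixels if (feat_cfg.masked and mask.pixels.any()) else None
        fv = texture.extract_features(img, feat_cfg.levels, feat_cfg.distance,
                                      feat_cfg.angles, mask=fmask)
        feature_rows.append({"image_id": i, **{name: val for name, val in
                             zip(texture.FEATURE_NAMES, fv.to_array())},
                             "label": item.label})

    labeled = [replace(item, image=img) for item, img in zip(items, processed)]
    train_items, test_items = evaluation.split_dataset(
        labeled, config.train_fraction, seed=config.seed)

    def stack(subset):
        return (np.stack([it.image for it in subset]),
                np.array([it.label for it in subset]))

    x_train, y_train = stack(train_items)
    x_test, y_test = stack(test_items)
    net = crnn.build_network(config.network, seed=config.seed)
    history = crnn.train(net, x_train,
                         (y_train == phantom.LABEL_TUMOR).astype(np.int64),
                         config.training)
    probs = net.predict_proba(crnn.adapt_images(x_test, net.spec.in_channels))
    pred = np.where(probs[:, 1] > probs[:, 0],
                    phantom.LABEL_TUMOR, phantom.LABEL_NORMAL)
    cc = evaluation.confusion(pred, y_test, positive_class=phantom.LABEL_TUMOR)
    metrics = evaluation.metric_report(cc)
    logger.info("test metrics: %s", json.dumps(metrics))

    report = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_images": len(items),
        "segmentation": seg_rows,
        "features": feature_rows,
        "history": history,
        "predictions": [{"image": i, "predicted": p, "truth": t}
                        for i, (p, t) in enumerate(zip(pred, y_test))],
        "metrics": metrics,
    }

    if out is not None:
        with open(out / "features.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(feature_rows[0]))
            writer.writeheader()
            writer.writerows(feature_rows)
        with open(out / "predictions.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["image", "predicted", "truth"])
            writer.writeheader()
            writer.writerows(report["predictions"])
        with open(out / "history.csv", "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["epoch", "lr", "momentum", "loss", "accuracy"])
            writer.writeheader()
            writer.writerows(history)
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2)
        net.save(out / "model.npz")
        logger.removeHandler(handler)
        handler.close()
    return report
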