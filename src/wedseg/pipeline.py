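"""End-to-end pipeline: synth -> augment -> watershed masks -> train -> evaluate.

Each stage writes a fresh directory under the run root and never mutates
its input; a ``manifest.json`` records the configuration, seeds, and a
checksum per stage directory so any stage can be re-run and compared
bit-for-bit (training is reproducible modulo floating-point scheduling).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import numpy as np

from .augment import augment_to_count
from .config import RunConfig
from .estimator import NucleiSegmenter
from .io import (DatasetLayout, load_paired_dataset, read_image, read_mask,
                 write_mask, write_preview)
from .synthetic import generate_dataset, save_dataset
from .train import split_dataset
from .watershed import make_watershed_mask

logger = logging.getLogger("wedseg")

__all__ = ["run_pipeline", "PipelineError", "stage_checksum", "write_watershed_masks"]


class PipelineError(RuntimeError):
    """A stage failure; the message names the failing stage."""


def stage_checksum(directory: Path) -> str:
    """SHA-256 over sorted file names and contents of a stage directory."""
    digest = hashlib.sha256()
    for path in sorted(Path(directory).rglob("*")):
        if path.is_file():
            digest.update(path.relative_to(directory).as_posix().encode())
            digest.update(path.read_bytes())
    return digest.hexdigest()


def _setup_logging(run_dir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers.clear()  # repeated runs must not stack handlers
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr),
                    logging.FileHandler(run_dir / "run.log")):
        handler.setFormatter(fmt)
        logger.addHandler(handler)


def write_watershed_masks(images_dir: Path, out_dir: Path, config,
                          previews: bool = False) -> int:
    """Derive and save a 3-class watershed mask for every image (by stem)."""
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = sorted(Path(images_dir).glob("*.png"))
    if not paths:
        raise PipelineError(f"watershed-masks: no PNG images in {images_dir}")
    for path in paths:
        mask = make_watershed_mask(read_image(path), config)
        write_mask(out_dir / path.name, mask)
        if previews:
            preview_dir = out_dir.parent / f"{out_dir.name}_preview"
            preview_dir.mkdir(exist_ok=True)
            write_preview(preview_dir / path.name, mask)
    return len(paths)


def run_pipeline(config: RunConfig, out_dir: str | Path,
                 source: str | Path | None = None) -> dict:
    """Execute every stage; returns the manifest dictionary.

    Without ``source``, ``n_source_pairs`` synthetic pairs seed the run;
    with it, the PNG dataset under that root (images/ + masks/) is used.
    """
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(run_dir)
    manifest: dict = {"config": _config_dict(config), "stages": {}}
    t0 = time.time()

    def stage(name):
        logger.info("stage %s", name)
        return name

    try:
        name = stage("synth")
        if source is None:
            synth_dir = run_dir / "synthetic"
            pairs = generate_dataset(config.synthetic, config.n_source_pairs,
                                     seed=config.seed)
            save_dataset(pairs, synth_dir)
            manifest["stages"]["synth"] = {
                "n_pairs": len(pairs), "checksum": stage_checksum(synth_dir)}
            source_root = synth_dir
        else:
            source_root = Path(source)
            pairs = load_paired_dataset(DatasetLayout(source_root))
            manifest["stages"]["synth"] = {"n_pairs": len(pairs), "external": True}

        name = stage("augment")
        aug_dir = run_dir / "augmented"
        augmented = augment_to_count(pairs, config.augmentation)
        save_dataset(augmented, aug_dir)
        manifest["stages"]["augment"] = {
            "n_pairs": len(augmented), "checksum": stage_checksum(aug_dir)}

        name = stage("watershed-masks")
        ws_dir = run_dir / "watershed_masks"
        n = write_watershed_masks(aug_dir / "images", ws_dir, config.watershed)
        manifest["stages"]["watershed-masks"] = {
            "n_masks": n, "checksum": stage_checksum(ws_dir)}

        name = stage("train")
        images = np.stack([p.image for p in augmented])
        targets = np.stack([
            read_mask(ws_dir / f"{i:04d}.png") for i in range(len(augmented))])
        split = split_dataset(len(images), config.training.split_fraction,
                              config.seed)
        model = NucleiSegmenter(
            base_width=config.model.base_width, depth=config.model.depth,
            num_classes=config.model.num_classes,
            dropout_rates=config.model.dropout_rates,
            use_batch_norm=config.model.use_batch_norm,
            learning_rate=config.training.learning_rate,
            batch_size=config.training.batch_size,
            epochs=config.training.epochs,
            weight_decay=config.training.weight_decay,
            early_stop_patience=config.training.early_stop_patience,
            plateau_factor=config.training.plateau_factor,
            plateau_patience=config.training.plateau_patience,
            dice_weight=config.training.dice_weight,
            ce_weight=config.training.ce_weight,
            threshold=config.evaluation.threshold,
            random_state=config.seed, verbose=True,
        )
        tr, te = split.train_indices, split.test_indices
        model.fit(images[tr], targets[tr],
                  validation_data=(images[te], targets[te]))
        model.network_.save(run_dir / "checkpoint.npz")
        _write_history(model.history_, run_dir / "history.csv")
        manifest["stages"]["train"] = {
            "n_train": int(len(tr)), "n_test": int(len(te)),
            "split_indices": {"train": tr.tolist(), "test": te.tolist()},
            "n_parameters": int(model.n_parameters_),
            "best_epoch": model.history_.best_epoch,
        }

        name = stage("evaluate")
        report = model.evaluate(images[te], targets[te])
        (run_dir / "metrics.json").write_text(json.dumps(report.as_dict(), indent=2))
        manifest["stages"]["evaluate"] = report.as_dict()
    except Exception as exc:  # noqa: BLE001 - stage name must reach the user
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    manifest["runtime_seconds"] = round(time.time() - t0, 2)
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return clean(d)


def _write_history(history, path: Path) -> None:
    rows = ["epoch,lr,train_loss,val_loss,val_dice,val_iou,val_accuracy"]
    for i in range(len(history.epoch)):
        rows.append(",".join(str(v) for v in (
            history.epoch[i], history.lr[i], history.train_loss[i],
            history.val_loss[i], history.val_dice[i], history.val_iou[i],
            history.val_accuracy[i])))
    path.write_text("\n".join(rows) + "\n")
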