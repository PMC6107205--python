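"""End-to-end runs: synthetic data -> training -> scoring -> maps -> evaluation,
with one root seed, a serialized config and a manifest in every output
directory so each artifact is reconstructible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classifier import TrainConfig, build_model, save_model, train
from .dataset import load_labelled_folders, split_train_val
from .errors import ConfigurationError
from .evaluation import adjacent_confusion_mass, confusion_matrix
from .schemes import get_scheme
from .scoring import render_score_map, score_tile_grid, slide_score, write_tile_scores
from .synthetic import generate_labelled_folders, generate_virtual_slide
from .tiling import SlideImage, slice_tiles

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one end-to-end demonstration run."""

    scheme: str = "fibrosis"
    out_dir: str = "histoscore_run"
    data_root: str | None = None  # labelled folders; generated when None
    backend: str = "small_cnn"
    tile_px: int = 96
    input_px: int = 32
    counts_per_class: int = 20
    slide_tiles: tuple[int, int] = (4, 4)  # (rows, cols) of the demo slide
    n_slides: int = 3
    val_fraction: float = 0.1
    stratified_split: bool = False
    max_epochs: int = 20
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "slide_tiles" in raw:
            raw["slide_tiles"] = tuple(raw["slide_tiles"])
        return cls(**raw)


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministically fan the root seed out to a per-stage seed."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _graded_score_field(rng, scheme, shape, severity: float):
    """Random per-tile ground truth whose class mix shifts with severity in [0,1]."""
    labels = scheme.class_labels
    k = len(labels)
    # triangular-ish weights peaked at the class matching the severity level
    peak = severity * (k - 1)
    w = np.exp(-0.5 * ((np.arange(k) - peak) / 0.8) ** 2)
    w /= w.sum()
    return rng.choice(list(labels), size=shape, p=w)


def run_end_to_end(config: RunConfig) -> Path:
    """Execute synth -> train -> score -> map -> eval and write all artifacts.

    Returns the output directory. Fails fast with a stage-named error; a
    ``manifest.json`` records config, package version, per-stage seeds and
    timings so reruns with the same config reproduce identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = get_scheme(config.scheme)
    manifest: dict = {
        "package_version": __version__,
        "config": asdict(config),
        "stages": {},
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh)

    def _stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    try:
        # -- synthetic training data -------------------------------------
        t0 = _stage("synth")
        if config.data_root is None:
            data_root = out / "tiles"
            generate_labelled_folders(
                data_root,
                config.scheme,
                config.counts_per_class,
                stage_seed(config.seed, "synth"),
                tile_px=config.tile_px,
                overwrite=True,
            )
        else:
            data_root = Path(config.data_root)
            if not data_root.is_dir():
                raise ConfigurationError(f"data root {data_root} does not exist")
        manifest["stages"]["synth"] = {"seconds": time.perf_counter() - t0}

        # -- dataset + training ------------------------------------------
        t0 = _stage("train")
        ds = load_labelled_folders(data_root, scheme.all_labels)
        ds = split_train_val(
            ds,
            config.val_fraction,
            stage_seed(config.seed, "split"),
            stratified=config.stratified_split,
        )
        model = build_model(
            config.backend,
            scheme.all_labels,
            seed=stage_seed(config.seed, "init"),
            input_px=config.input_px,
            scheme_name=scheme.name,
        )
        cfg = TrainConfig.desk_scale(
            max_epochs=config.max_epochs, seed=stage_seed(config.seed, "train")
        )
        model, curve = train(model, ds, cfg)
        save_model(model, out / "model.npz")
        curve.to_dataframe().to_csv(out / "learning_curve.csv", index=False)
        manifest["stages"]["train"] = {
            "seconds": time.perf_counter() - t0,
            "epochs": len(curve),
            "final_val_accuracy": curve.val_accuracy[-1] if len(curve) else None,
        }

        # -- score demo slides + maps -------------------------------------
        t0 = _stage("score")
        rng = np.random.default_rng(stage_seed(config.seed, "slides"))
        rows, cols = config.slide_tiles
        slide_records = []
        for s in range(config.n_slides):
            severity = s / max(config.n_slides - 1, 1)
            field_labels = _graded_score_field(rng, scheme, (rows, cols), severity)
            slide_px, truth = generate_virtual_slide(
                cols,
                rows,
                field_labels,
                stage_seed(config.seed, f"slide{s}"),
                scheme=config.scheme,
                tile_px=config.tile_px,
            )
            grid = slice_tiles(SlideImage(slide_px), config.tile_px)
            smap = score_tile_grid(model, grid, scheme)
            write_tile_scores(smap, out / f"slide{s}_tile_scores.csv")
            render_score_map(smap, out / f"slide{s}_map.png")
            sc = slide_score(smap)
            truth_weights = [
                scheme.weight_of(l) for l in truth.ravel() if l != scheme.ignore_label
            ]
            slide_records.append(
                {
                    "slide": s,
                    "severity": severity,
                    "mean_score": sc.mean,
                    "n_scored": sc.n_scored,
                    "n_ignored": sc.n_ignored,
                    "truth_mean": float(np.mean(truth_weights)) if truth_weights else None,
                }
            )
        with open(out / "slide_scores.json", "w") as fh:
            json.dump(slide_records, fh, indent=2)
        manifest["stages"]["score"] = {"seconds": time.perf_counter() - t0}

        # -- evaluation on the validation split ----------------------------
        t0 = _stage("eval")
        from .classifier import _load_image, predict_proba

        val_items = ds.val_items
        probs = predict_proba(model, [_load_image(it.path) for it in val_items])
        pred = [scheme.all_labels[i] for i in probs.argmax(axis=1)]
        cm = confusion_matrix([it.label for it in val_items], pred, scheme.all_labels)
        cm.to_dataframe().to_csv(out / "confusion.csv")
        adj = adjacent_confusion_mass(cm, scheme)
        with open(out / "eval.json", "w") as fh:
            json.dump(
                {
                    "val_accuracy": accuracy_of(cm),
                    "adjacent_confusion_mass": adj,
                    "n_validation": len(val_items),
                },
                fh,
                indent=2,
            )
        manifest["stages"]["eval"] = {"seconds": time.perf_counter() - t0}
    except Exception as exc:
        manifest["failed"] = f"{type(exc).__name__}: {exc}"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out


def accuracy_of(cm) -> float:
    """Overall accuracy from a confusion matrix's raw counts."""
    total = cm.counts.sum()
    return float(np.trace(cm.counts) / total) if total else 0.0
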