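"""End-to-end orchestration: generate → preprocess → detect → measure → report.

A run is fully reproducible from a :class:`RunConfig` plus its seed: every
stage draws randomness from seeds derived deterministically from the run
seed, and all outputs are plain PNG / YOLO label text / CSV files.  By
default the measurement stage consumes the ground-truth boxes (truth-box
mode), which makes the size-calculation pipeline testable without trained
detector weights; inference mode runs the detector forward pass instead.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import lwc, metrics
from .io import CLASS_NAMES, DetectionBox, ValidationError
from .preprocess import AugmentConfig, ShadowParams, augment, eliminate_shadow
from .synthgen import Scene, build_manifest, generate_scene, save_scene

logger = logging.getLogger("shredkit")


@dataclass
class GenerateConfig:
    n_scenes: int = 1
    n_per_class: dict[str, int] = field(default_factory=lambda: {c: 1 for c in CLASS_NAMES})
    overlap_fraction: float = 0.0
    with_block: bool = True
    shadow_strength: float = 0.3
    canvas: tuple[int, int] = (1280, 1280)
    ppmm: float = 10.0


@dataclass
class LwcConfig:
    strips: int = 50
    block_mm: float = 9.0
    block_px: float | None = None  # None = use the scene-recorded / detected block


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "runs/run0"
    generate: GenerateConfig = field(default_factory=GenerateConfig)
    preprocess: ShadowParams = field(default_factory=ShadowParams)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    lwc: LwcConfig = field(default_factory=LwcConfig)
    apply_preprocess: bool = True
    truth_box_mode: bool = True
    weights: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        cfg = RunConfig()
        plain = {k: v for k, v in d.items() if not isinstance(v, dict)}
        cfg = dataclasses.replace(cfg, **plain)
        if "generate" in d:
            g = dict(d["generate"])
            if "canvas" in g:
                g["canvas"] = tuple(g["canvas"])
            cfg = dataclasses.replace(cfg, generate=GenerateConfig(**g))
        if "preprocess" in d:
            cfg = dataclasses.replace(cfg, preprocess=ShadowParams(**d["preprocess"]))
        if "augment" in d:
            cfg = dataclasses.replace(cfg, augment=AugmentConfig(**d["augment"]))
        if "lwc" in d:
            cfg = dataclasses.replace(cfg, lwc=LwcConfig(**d["lwc"]))
        return cfg

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return RunConfig.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class Report:
    measurements: pd.DataFrame
    aggregates: pd.DataFrame
    detection: pd.DataFrame | None
    provenance: dict


def _derive_seed(seed: int, stage: str, index: int = 0) -> int:
    blob = f"{seed}:{stage}:{index}".encode()
    return int.from_bytes(hashlib.sha256(blob).digest()[:4], "little") % (2**31)


def run(config: RunConfig) -> Report:
    """Execute all stages and write artifacts under ``config.outdir``."""
    if not config.truth_box_mode and not config.weights:
        raise ValidationError("inference mode requires a weights file")
    if not config.generate.with_block and config.lwc.block_px is None:
        raise ValidationError("need a calibration block or an explicit block_px")
    outdir = Path(config.outdir)
    (outdir / "scenes").mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    scenes: list[Scene] = []
    for i in range(config.generate.n_scenes):
        sc = generate_scene(
            n_per_class=config.generate.n_per_class,
            overlap_fraction=config.generate.overlap_fraction,
            with_block=config.generate.with_block,
            shadow_strength=config.generate.shadow_strength,
            seed=_derive_seed(config.seed, "generate", i),
            canvas=config.generate.canvas,
            ppmm=config.generate.ppmm,
        )
        scenes.append(sc)
        save_scene(sc, outdir / "scenes", f"scene_{i:04d}")
    logger.info("generated %d scenes in %.1fs", len(scenes), time.time() - t0)

    all_rows: list[pd.DataFrame] = []
    truths_all: dict[int, tuple[float, float]] = {}
    offset = 0
    for i, sc in enumerate(scenes):
        image = sc.image
        if config.apply_preprocess:
            image = eliminate_shadow(image, config.preprocess).image
        if config.truth_box_mode:
            boxes = sc.boxes
        else:
            boxes = _infer_boxes(image, config)
        if config.lwc.block_px is not None:
            cal = lwc.calibrate(config.lwc.block_px, config.lwc.block_mm)
        elif sc.block_px_length is not None:
            cal = lwc.calibrate(sc.block_px_length, config.lwc.block_mm)
        else:
            cal = lwc.calibrate(lwc.detect_block_px(sc.image), config.lwc.block_mm)
        truths = {oid: (tl, tw) for oid, tl, tw in sc.truths} if config.truth_box_mode else None
        df = lwc.measure_scene(sc.image, boxes, cal, n=config.lwc.strips, truths=truths)
        for bad in df[df["error"].notna()].itertuples():
            logger.warning("scene %d object %d failed: %s", i, bad.object_id, bad.error)
        df["scene"] = i
        df["object_id"] = df["object_id"] + offset
        if truths:
            truths_all.update({oid + offset: v for oid, v in truths.items()})
        offset += len(boxes)
        all_rows.append(df)

    measurements = pd.concat(all_rows, ignore_index=True) if all_rows else pd.DataFrame()
    aggregates = (
        lwc.aggregate_report(measurements, truths_all)
        if len(truths_all)
        else pd.DataFrame(columns=["sample", "n_objects", "rel_err_len_pct", "rel_err_wid_pct"])
    )

    detection = None
    if not config.truth_box_mode:
        preds = {str(i): _infer_boxes(sc.image, config, as_boxes=True) for i, sc in enumerate(scenes)}
        gts = {str(i): sc.boxes for i, sc in enumerate(scenes)}
        detection = metrics.evaluate_detections(preds, gts)

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_scenes": len(scenes),
        "package": "shredkit 0.1.0",
    }
    measurements.to_csv(outdir / "measurements.csv", index=False, float_format="%.4f")
    aggregates.to_csv(outdir / "aggregates.csv", index=False, float_format="%.4f")
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    logger.info("run complete: %d objects measured", len(measurements))
    return Report(measurements=measurements, aggregates=aggregates, detection=detection, provenance=provenance)


def _infer_boxes(image: np.ndarray, config: RunConfig, as_boxes: bool = False):
    from . import model as model_mod

    cfg = model_mod.SMOKE_CONFIG
    net = model_mod.DetectionModel(cfg, seed=config.seed)
    model_mod.load_weights(net, config.weights)
    x = model_mod.Tensor(image.astype(np.float32).transpose(2, 0, 1)[None] / 255.0)
    outputs = net(x)
    dets = model_mod.decode_predictions(outputs, image.shape[:2], cfg.n_classes)
    boxes = [
        DetectionBox.from_xyxy(ci, x0, y0, x1, y1, shape=image.shape[:2], confidence=conf)
        for ci, x0, y0, x1, y1, conf in dets
    ]
    return boxes


def split_dataset(
    manifest_counts: dict[str, int], ratio: tuple[int, int] = (7, 3), seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a dataset manifest into train/test listings at an exact ratio."""
    manifest = build_manifest(manifest_counts, ratio=ratio, seed=seed)
    return (
        manifest[manifest["split"] == "train"].reset_index(drop=True),
        manifest[manifest["split"] == "test"].reset_index(drop=True),
    )
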