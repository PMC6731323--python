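"""End-to-end orchestration: synth -> extract -> train -> infer -> hotspot
-> validate, with a manifest that records the config hash, seeds and every
stage's outputs so any stage can be re-run in isolation."""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np

from . import io as kio
from .annotations import read_imagescope_xml, write_imagescope_xml, rasterise
from .config import RunConfig
from .estimator import PatchCNNClassifier
from .hotspot import (
    band_proliferation,
    centroids,
    extract_dab,
    render_hotspot_overlay,
    score_circles,
    subtractive_cluster,
)
from .inference import ColourBinning, binarise, exclude_infiltrate, infer_slide, render_pseudocolour
from .metrics import confusion, cohort_report, render_confusion_overlay
from .patches import PatchSet, TileGrid, TissueRule, augment, extract_labelled_patches
from .synthetic import demo_slide_spec, generate_pseudo_slide

ALL_STAGES = ("synth", "extract", "train", "infer", "hotspot", "validate")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _train_split(ps: PatchSet, holdout_fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ps))
    n_hold = int(round(holdout_fraction * len(ps)))
    return ps.subset(order[n_hold:]), ps.subset(order[:n_hold])


def run_pipeline(
    cfg: RunConfig, out_dir, stages: tuple[str, ...] = ALL_STAGES
) -> dict:
    """Execute the requested stages; returns the manifest dict.

    Stage inputs either come from the preceding stage in this run or from
    the paths in the config; a missing requirement aborts with the name of
    the config key that would supply it.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": cfg.config_hash(),
        "seeds": cfg.seeds.model_dump(),
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    cfg.to_yaml(out / "config.yaml")

    slide = gt = ann = None
    tumour_patches = infi_patches = None
    model = infi_model = None
    tumour_map = binary_cells = None

    grid = TileGrid(cfg.extract.patch_size, cfg.extract.stride)
    rule = TissueRule(cfg.extract.mi_threshold)

    for stage in stages:
        try:
            if stage == "synth":
                spec = demo_slide_spec(
                    cfg.synth.width,
                    cfg.synth.height,
                    seed=cfg.seeds.synth,
                    tumour_ki67=cfg.synth.tumour_ki67,
                    with_infiltrate=cfg.synth.with_infiltrate,
                )
                slide, gt = generate_pseudo_slide(spec)
                ann = gt.annotation_set
                kio.save_slide(slide, out / "slide.png")
                kio.save_mask(gt.label_mask, out / "label_mask.png")
                kio.save_mask(gt.ki67_positive_mask, out / "ki67_mask.png")
                write_imagescope_xml(ann, out / "annotations.xml")
                manifest["stages"]["synth"] = {
                    "slide": "slide.png",
                    "label_mask": "label_mask.png",
                    "ki67_mask": "ki67_mask.png",
                    "annotations": "annotations.xml",
                }
            elif stage == "extract":
                if slide is None:
                    if cfg.paths.slide is None:
                        raise ValueError("no slide available: set paths.slide")
                    slide = kio.load_slide(cfg.paths.slide)
                    if cfg.paths.annotations is None:
                        raise ValueError("no annotations: set paths.annotations")
                    ann = read_imagescope_xml(cfg.paths.annotations)
                tumour_patches = extract_labelled_patches(
                    slide, ann, grid, cfg.extract.purity, rule, task="tumour"
                )
                if cfg.extract.augmentations:
                    tumour_patches = augment(
                        tumour_patches, cfg.extract.augmentations
                    )
                infi_patches = extract_labelled_patches(
                    slide, ann, grid, cfg.extract.purity, rule, task="infiltrate"
                )
                counts = tumour_patches.class_counts()
                manifest["stages"]["extract"] = {
                    "n_patches": len(tumour_patches),
                    "class_counts": counts.to_dict(),
                    "n_infiltrate_patches": len(infi_patches),
                }
            elif stage == "train":
                if tumour_patches is None:
                    raise ValueError("no patches: run the extract stage first")
                t = cfg.train
                rng = np.random.default_rng(cfg.seeds.train)
                ps = tumour_patches
                if len(ps) > cfg.extract.max_patches:
                    ps = ps.subset(
                        rng.permutation(len(ps))[: cfg.extract.max_patches]
                    )
                tr, hold = _train_split(
                    ps, cfg.extract.holdout_fraction, cfg.seeds.train
                )
                model = PatchCNNClassifier(
                    dropout_rate=t.dropout_rate,
                    learning_rate=t.learning_rate,
                    momentum=t.momentum,
                    epochs=t.epochs,
                    batch_size=t.batch_size,
                    random_state=cfg.seeds.train,
                ).fit(tr.patches, tr.labels)
                holdout_acc = (
                    float(model.score(hold.patches, hold.labels))
                    if len(hold)
                    else float("nan")
                )
                model.save(out / "model.npz")
                model.history_.to_csv(out / "training_log.csv", index=False)
                entry = {
                    "model": "model.npz",
                    "log": "training_log.csv",
                    "holdout_accuracy": holdout_acc,
                    "n_parameters": int(model.n_parameters_),
                }
                if infi_patches is not None and len(
                    np.unique(infi_patches.labels)
                ) == 2:
                    ip = infi_patches
                    if len(ip) > t.infiltrate_max_patches:
                        ip = ip.subset(
                            rng.permutation(len(ip))[: t.infiltrate_max_patches]
                        )
                    infi_model = PatchCNNClassifier(
                        dropout_rate=t.dropout_rate,
                        learning_rate=t.learning_rate,
                        momentum=t.momentum,
                        epochs=t.infiltrate_epochs,
                        batch_size=t.batch_size,
                        random_state=cfg.seeds.infiltrate_train,
                    ).fit(ip.patches, ip.labels)
                    infi_model.save(out / "infiltrate_model.npz")
                    entry["infiltrate_model"] = "infiltrate_model.npz"
                manifest["stages"]["train"] = entry
            elif stage == "infer":
                if model is None:
                    if cfg.paths.model is None:
                        raise ValueError("no trained model: set paths.model")
                    model = PatchCNNClassifier.load(cfg.paths.model)
                if infi_model is None and cfg.paths.infiltrate_model:
                    infi_model = PatchCNNClassifier.load(cfg.paths.infiltrate_model)
                if slide is None:
                    if cfg.paths.slide is None:
                        raise ValueError("no slide available: set paths.slide")
                    slide = kio.load_slide(cfg.paths.slide)
                tumour_map = infer_slide(
                    slide, model, cfg.infer.stride, rule, positive_label="tumour"
                )
                if infi_model is not None:
                    infi_map = infer_slide(
                        slide,
                        infi_model,
                        cfg.infer.stride,
                        rule,
                        positive_label="infiltrate",
                    )
                    tumour_map = exclude_infiltrate(
                        tumour_map, infi_map, cfg.infer.infiltrate_threshold
                    )
                binary_cells = binarise(tumour_map, cfg.infer.binarise_threshold)
                kio.save_probability_map(tumour_map, out / "probability_map.tiff")
                bins = ColourBinning(edges=tuple(cfg.infer.colour_edges))
                overlay = render_pseudocolour(tumour_map, bins, slide)
                kio.save_mask(binary_cells, out / "tumour_cells.png")
                from PIL import Image

                Image.fromarray(overlay).save(out / "pseudocolour.png")
                manifest["stages"]["infer"] = {
                    "probability_map": "probability_map.tiff",
                    "pseudocolour": "pseudocolour.png",
                    "tumour_mask_cells": "tumour_cells.png",
                    "covered_cells": int(tumour_map.covered.sum()),
                }
            elif stage == "hotspot":
                if tumour_map is None or binary_cells is None or slide is None:
                    raise ValueError("no probability map: run the infer stage first")
                hcfg = cfg.hotspot
                h, w = slide.image.shape[:2]
                tumour_full = tumour_map.to_fullres_mask(binary_cells, w, h)
                dab = extract_dab(
                    slide.image,
                    tumour_full,
                    hcfg.od_threshold,
                    hcfg.min_area_px,
                    hcfg.morph_radius,
                )
                pts = centroids(dab)
                centres = subtractive_cluster(pts, ra=hcfg.ra)
                report = score_circles(
                    dab,
                    centres,
                    hcfg.diameter_px,
                    hcfg.ratio_threshold,
                    all_centroids=pts,
                )
                if hcfg.bands:
                    report = band_proliferation(report, tuple(hcfg.bands))
                (out / "hotspots.json").write_text(report.to_json())
                from PIL import Image

                Image.fromarray(render_hotspot_overlay(slide, report)).save(
                    out / "hotspot_overlay.png"
                )
                manifest["stages"]["hotspot"] = {
                    "report": "hotspots.json",
                    "overlay": "hotspot_overlay.png",
                    "n_centroids": len(pts),
                    "n_cluster_centres": len(centres),
                    "n_hotspots": int(report.circles.is_hotspot.sum()),
                }
            elif stage == "validate":
                if binary_cells is None or tumour_map is None:
                    raise ValueError("no prediction: run the infer stage first")
                if gt is None:
                    raise ValueError("no ground truth: run the synth stage first")
                d = cfg.validate_cfg.downsample
                h, w = slide.image.shape[:2]
                pred_full = tumour_map.to_fullres_mask(binary_cells, w, h)
                pred_ds = pred_full[::d, ::d]
                truth = rasterise(gt.annotation_set, d) == 2
                tissue = rasterise(gt.annotation_set, d) > 0
                gh, gw = min(pred_ds.shape[0], truth.shape[0]), min(
                    pred_ds.shape[1], truth.shape[1]
                )
                pred_ds, truth, tissue = (
                    pred_ds[:gh, :gw],
                    truth[:gh, :gw],
                    tissue[:gh, :gw],
                )
                counts = confusion(
                    pred_ds, truth, tissue if cfg.validate_cfg.tissue_only else None
                )
                report = cohort_report([counts])
                report.to_csv(out / "validation.csv")
                overlay = render_confusion_overlay(
                    pred_ds, truth, evaluate_mask=tissue
                )
                from PIL import Image

                Image.fromarray(overlay).save(out / "confusion_overlay.png")
                manifest["stages"]["validate"] = {
                    "report": "validation.csv",
                    "overlay": "confusion_overlay.png",
                    "dice": float(report.loc["slide_0", "dice"]),
                }
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as e:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(stage, e) from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
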