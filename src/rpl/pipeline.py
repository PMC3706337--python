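"""End-to-end orchestration: train -> localize -> evaluate.

Defaults reproduce the published parameter set (v1=0.7, v2=0.4, dv=0.1,
a1=0.6, a2=0.4, g1=0.25, g2=1, dg=0.25, 64 bins, 12 words, 8-px patches,
C=128); everything is overridable through the config file or CLI flags.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from . import contour_refinement as cr
from . import decluster as dc
from . import evaluation as ev
from . import initial_segmentation as iseg
from . import training as tr

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "RunRecord",
    "localize",
    "run_batch",
    "stage_ablation",
    "fit_models",
]


@dataclass(frozen=True)
class PipelineConfig:
    mser: iseg.MserParams = field(default_factory=iseg.MserParams)
    validation: dc.ValidationParams = field(default_factory=dc.ValidationParams)
    contrast: cr.ContrastParams = field(default_factory=cr.ContrastParams)
    seed: int = 0
    verbosity: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs: dict = {}
        if "mser" in raw:
            kwargs["mser"] = iseg.MserParams(**raw["mser"])
        if "validation" in raw:
            kwargs["validation"] = dc.ValidationParams(**raw["validation"])
        if "contrast" in raw:
            kwargs["contrast"] = cr.ContrastParams(**raw["contrast"])
        for key in ("seed", "verbosity"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RunRecord:
    config: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    version: str = "0.1.0"

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        return json.dumps(
            {"config": self.config, "stages": self.stages,
             "timings": self.timings, "version": self.version},
            default=default,
        )


def fit_models(
    images, truths, config: PipelineConfig | None = None, seed: int = 0
) -> tr.TrainedModels:
    """Train all learned components from annotated images.

    Stage-1 detection (without merging) supplies the nested pairs for the
    merge classifier; the pixel classifier and codebook are fit on the
    contrast-enhanced working images so train and test distributions match.
    """
    config = config or PipelineConfig()
    pairs = []
    enhanced_images = []
    for idx, image in enumerate(images):
        try:
            hierarchy, work = iseg.run_initial_segmentation(
                image, config.mser, merge_model=None
            )
        except iseg.NoRegionsFoundError:
            logger.warning("training image %d produced no regions; skipped", idx)
            enhanced_images.append(np.asarray(image))
            continue
        enhanced_images.append(work)
        for lower in hierarchy.lowers():
            kids = hierarchy.children_of(lower.id)
            if kids:
                pairs.append((lower, kids[0], idx))
    merge = tr.train_merge_classifier(pairs, truths)
    pixel = tr.train_pixel_classifier(enhanced_images, truths, seed=seed)
    codebook = tr.build_codebook(
        enhanced_images, patch_size=config.validation.patch_size, seed=seed
    )
    return tr.TrainedModels(
        merge=merge, pixel=pixel, codebook=codebook,
        patch_size=config.validation.patch_size,
    )


def _stage1(image, models, config, record):
    t0 = time.perf_counter()
    s1rec: dict = {}
    hierarchy, work = iseg.run_initial_segmentation(
        image, config.mser, merge_model=models.merge if models else None,
        record=s1rec,
    )
    record.stages["stage1"] = {
        **s1rec,
        "n_regions": len(hierarchy),
        "n_singles": len(hierarchy.singles()),
        "n_clusters": len(
            [r for r in hierarchy.lowers() if hierarchy.children_of(r.id)]
        ),
    }
    record.timings["stage1"] = time.perf_counter() - t0
    return hierarchy, work


def localize(
    image: np.ndarray, models: tr.TrainedModels, config: PipelineConfig
) -> tuple[np.ndarray, RunRecord]:
    """Full three-stage localization of one image."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(
            "expected a single-channel grayscale image; convert RGB inputs "
            "before running the pipeline"
        )
    record = RunRecord(config=config.to_dict())
    try:
        hierarchy, work = _stage1(image, models, config, record)
    except iseg.NoRegionsFoundError:
        logger.info("no interest regions; returning empty mask")
        record.stages["stage1"] = {"n_regions": 0}
        return np.zeros(image.shape, dtype=np.int32), record

    t0 = time.perf_counter()
    s2rec: dict = {}
    detected = dc.decluster_process(
        work, hierarchy, models, config.validation, record=s2rec
    )
    record.stages["stage2"] = {**s2rec, "n_detected": len(detected)}
    record.timings["stage2"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    refined = []
    gammas = []
    for region in detected:
        rrec: dict = {}
        refined.append(
            cr.refine_contour(region.pixels, work, config.contrast, record=rrec)
        )
        gammas.append(rrec.get("gamma_G"))
    refined = _trim_refined(refined, detected, tuple(image.shape))
    mask = cr.assemble_result(refined, tuple(image.shape), image=work)
    record.stages["stage3"] = {
        "gamma_G": gammas,
        "n_instances": int(mask.max()),
    }
    record.timings["stage3"] = time.perf_counter() - t0
    return mask, record


def run_batch(
    images: dict[str, np.ndarray],
    models: tr.TrainedModels,
    config: PipelineConfig,
    truths: dict[str, np.ndarray] | None = None,
):
    """Localize a batch; returns (masks, records, reports, summary)."""
    masks, records, reports = {}, {}, {}
    for name, image in images.items():
        try:
            mask, rec = localize(image, models, config)
        except Exception:
            logger.exception("failed on %s; skipping", name)
            continue
        masks[name] = mask
        records[name] = rec
        if truths is not None and name in truths:
            reports[name] = ev.evaluate(mask, truths[name])
    summary = {}
    if reports:
        for metric in ("R", "P", "A", "dice", "nsd", "hd"):
            summary[metric] = float(
                np.mean([getattr(r, metric) for r in reports.values()])
            )
    return masks, records, reports, summary


def _trim_refined(refined, detected, shape):
    """A refined contour may not claim territory of another stage-2
    detection: each expanded window can reach into a neighboring nucleus,
    and without this trim the assembly would bisect that neighbor."""
    out = []
    for i, pix in enumerate(refined):
        others = [d.pixels for j, d in enumerate(detected) if j != i]
        if others:
            pix = np.setdiff1d(pix, np.concatenate(others))
        # keep connected components still touching the original detection
        m = np.zeros(shape, bool)
        m.ravel()[pix] = True
        comp, _ = ndimage.label(m)
        own = np.zeros(shape, bool)
        own.ravel()[np.intersect1d(pix, detected[i].pixels)] = True
        keep = np.unique(comp[own & (comp > 0)])
        out.append(np.flatnonzero(np.isin(comp, keep[keep > 0]).ravel()))
    return out


def _mask_from_regions(pixel_sets, shape, image):
    return cr.assemble_result(list(pixel_sets), shape, image=image)


def stage_ablation(
    fixtures, models: tr.TrainedModels, config: PipelineConfig
) -> dict[str, dict]:
    """Evaluate after stage 1 only, stages 1-2, and the full pipeline.

    Detection counts are pooled over images; Dice/NSD/HD are averaged.
    """
    per_stage = {s: {"TP": 0, "FN": 0, "FP": 0, "dice": [], "nsd": [], "hd": []}
                 for s in ("S-1", "S-2", "S-3")}
    for fix in fixtures:
        image, truth = fix.image, fix.truth
        record = RunRecord(config=config.to_dict())
        shape = tuple(image.shape)
        try:
            hierarchy, work = _stage1(image, models, config, record)
        except iseg.NoRegionsFoundError:
            masks = {s: np.zeros(shape, np.int32) for s in per_stage}
        else:
            s1_regions = [r.pixels for r in hierarchy.singles()] + [
                r.pixels for r in hierarchy.uppers()
            ]
            s1_mask = _mask_from_regions(s1_regions, shape, work)
            detected = dc.decluster_process(
                work, hierarchy, models, config.validation
            )
            s2_mask = _mask_from_regions(
                [d.pixels for d in detected], shape, work
            )
            refined = [
                cr.refine_contour(d.pixels, work, config.contrast)
                for d in detected
            ]
            refined = _trim_refined(refined, detected, shape)
            s3_mask = cr.assemble_result(refined, shape, image=work)
            masks = {"S-1": s1_mask, "S-2": s2_mask, "S-3": s3_mask}
        for stage, mask in masks.items():
            rep = ev.evaluate(mask, truth)
            acc = per_stage[stage]
            acc["TP"] += rep.match.TP
            acc["FN"] += rep.match.FN
            acc["FP"] += rep.match.FP
            acc["dice"].append(rep.dice)
            acc["nsd"].append(rep.nsd)
            acc["hd"].append(rep.hd)
    out = {}
    for stage, acc in per_stage.items():
        tp, fn, fp = acc["TP"], acc["FN"], acc["FP"]
        out[stage] = {
            "R": tp / (tp + fn) if tp + fn else 0.0,
            "P": tp / (tp + fp) if tp + fp else 0.0,
            "A": tp / (tp + fn + fp) if tp + fn + fp else 0.0,
            "dice": float(np.mean(acc["dice"])),
            "nsd": float(np.mean(acc["nsd"])),
            "hd": float(np.mean(acc["hd"])),
            "TP": tp, "FN": fn, "FP": fp,
        }
    return out
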