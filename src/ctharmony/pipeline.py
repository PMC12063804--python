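"""End-to-end orchestration of the three harmonization sub-experiments.

* ``image``    — train a paired GAN per source group toward the reference
                 group, harmonize images, extract features, evaluate.
* ``feature``  — extract features from the original images, per-ROI
                 reference-batch ComBat, evaluate.
* ``combined`` — GAN-harmonized images feed feature extraction, then
                 per-ROI ComBat, then evaluation (GAN first, ComBat
                 second — never reversed).

Each run emits a manifest (seeds, configs, software versions) sufficient
to regenerate its outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ctharmony import combat as combat_mod
from ctharmony import evaluation as ev
from ctharmony import synthetic
from ctharmony.features import ExtractionConfig, extract_dataset
from ctharmony.gan_harmonize import (
    CriticSpec,
    GeneratorSpec,
    HarmonizerModel,
    LossWeights,
    TrainConfig,
    harmonize_images,
    hu_to_unit,
    train_harmonizer,
    unit_to_hu,
)
from ctharmony.preprocess import clip_intensity
from ctharmony.types import REFERENCE_GROUP, LabeledVolume, default_groups

logger = logging.getLogger(__name__)

SUBEXPERIMENTS = ("image", "feature", "combined")


class UsageError(ValueError):
    pass


@dataclass
class RunConfig:
    """Configuration of one synthetic-study run.

    The defaults describe a small desk-scale study; the full study shape
    is 8 groups x 30 scans.
    """

    seed: int = 0
    group_ids: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    n_scans: int = 30
    shape: tuple[int, int, int] = (64, 64, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    reference_group: int = REFERENCE_GROUP
    clip: tuple[float, float] = (-45.0, 125.0)
    n_slices: int = 8  # central slices per scan used for GAN training
    gan_steps: int = 200
    gan_filters: int = 4
    gan_critic_filters: tuple[int, ...] = (8, 16, 32, 32)
    gan_identity: bool = False  # bypass the GAN (identity image transform)
    bin_width: float = 25.0

    def groups(self):
        by_id = {g.group_id: g for g in default_groups()}
        missing = [g for g in self.group_ids if g not in by_id]
        if missing:
            raise UsageError(f"unknown group ids: {missing}")
        if self.reference_group not in self.group_ids:
            raise UsageError(f"reference group {self.reference_group} not among groups")
        return [by_id[g] for g in self.group_ids]


def _generate_volumes(config: RunConfig) -> dict[tuple[int, int], LabeledVolume]:
    study = synthetic.simulate_study(
        seed=config.seed,
        groups=config.groups(),
        n_scans=config.n_scans,
        shape=config.shape,
        spacing=config.spacing,
    )
    return {k: clip_intensity(v, *config.clip) for k, v in study.items()}


def _central_slices(volume: LabeledVolume, n: int) -> list[np.ndarray]:
    nz = volume.shape[2]
    lo = max(0, nz // 2 - n // 2)
    return [volume.intensities[:, :, z] for z in range(lo, min(nz, lo + n))]


def _train_gans(
    volumes: Mapping[tuple[int, int], LabeledVolume], config: RunConfig
) -> dict[int, HarmonizerModel]:
    models = {}
    sources = [g for g in config.group_ids if g != config.reference_group]
    for gid in sources:
        pairs = []
        for s in range(config.n_scans):
            src_slices = _central_slices(volumes[(gid, s)], config.n_slices)
            tgt_slices = _central_slices(volumes[(config.reference_group, s)], config.n_slices)
            for a, b in zip(src_slices, tgt_slices):
                pairs.append((hu_to_unit(a, config.clip), hu_to_unit(b, config.clip)))
        t0 = time.perf_counter()
        models[gid] = train_harmonizer(
            pairs,
            TrainConfig(steps=config.gan_steps, seed=synthetic._child_seed(config.seed, 77, gid)),
            LossWeights(),
            GeneratorSpec(n_filters=config.gan_filters),
            CriticSpec(filters=config.gan_critic_filters),
            source_group=gid,
            reference_group=config.reference_group,
        )
        logger.info("trained GAN %s->%s in %.1fs", gid, config.reference_group, time.perf_counter() - t0)
    return models


def _apply_gans(
    volumes: Mapping[tuple[int, int], LabeledVolume],
    models: Mapping[int, HarmonizerModel],
    config: RunConfig,
) -> dict[tuple[int, int], LabeledVolume]:
    out = {}
    for (gid, s), vol in volumes.items():
        if gid == config.reference_group or config.gan_identity:
            out[(gid, s)] = vol.copy()
            continue
        unit = hu_to_unit(vol.intensities, config.clip)
        harm = harmonize_images(models[gid], unit)
        out[(gid, s)] = LabeledVolume(unit_to_hu(harm, config.clip), vol.spacing, vol.mask.copy())
    return out


def _evaluate(
    table: pd.DataFrame,
    harmonized: pd.DataFrame | None,
    config: RunConfig,
    quality: ev.ImageQualityReport | None = None,
) -> dict:
    target = harmonized if harmonized is not None else table
    repro = ev.reproducibility_report(
        table, harmonized, reference_group=config.reference_group
    )
    stab = ev.stability_report(target, reference_group=config.reference_group)
    cls = ev.discrimination_report(target, seed=config.seed)
    bundle = {
        "reproducibility": repro.summary(),
        "average_ccc": repro.average_ccc,
        "percent_reproducible": 100.0 * repro.fraction_reproducible,
        "stability": stab.per_roi.to_dict(orient="list"),
        "per_roi_stability": dict(
            zip(stab.per_roi["roi"].tolist(), stab.per_roi["percent_stable"].tolist())
        ),
        "average_percent_stable": stab.average_percent_stable,
        "per_roi_auc": cls.per_class_auc,
        "macro_auc": cls.macro_auc,
        "classification": {
            "macro_auc": cls.macro_auc,
            "n_retained_features": len(cls.retained_features),
            "best_params": cls.best_params,
        },
    }
    if quality is not None:
        bundle["image_quality"] = {
            "nmse": quality.nmse,
            "psnr": quality.psnr,
            "ssim": quality.ssim,
        }
    return bundle


def run_subexperiment(which: str, config: RunConfig) -> dict:
    """Run one sub-experiment on a synthetic study; returns a report bundle."""
    if which not in SUBEXPERIMENTS:
        raise UsageError(f"unknown sub-experiment {which!r}; choose from {SUBEXPERIMENTS}")
    config.groups()  # validates reference group membership

    stages = ["simulate", "clip"]
    volumes = _generate_volumes(config)
    extraction = ExtractionConfig(bin_width=config.bin_width)
    baseline_table = extract_dataset(volumes, extraction)

    quality = None
    if which in ("image", "combined"):
        models = {} if config.gan_identity else _train_gans(volumes, config)
        harmonized_volumes = _apply_gans(volumes, models, config)
        stages.append("gan" if not config.gan_identity else "gan(identity)")
        gen, tgt = [], []
        for gid in config.group_ids:
            if gid == config.reference_group:
                continue
            for s in range(config.n_scans):
                gen.extend(
                    hu_to_unit(x, config.clip)
                    for x in _central_slices(harmonized_volumes[(gid, s)], config.n_slices)
                )
                tgt.extend(
                    hu_to_unit(x, config.clip)
                    for x in _central_slices(volumes[(config.reference_group, s)], config.n_slices)
                )
        quality = ev.image_quality(gen, tgt, data_range=1.0)
        work_table = extract_dataset(harmonized_volumes, extraction)
        stages.append("extract")
    else:
        work_table = baseline_table
        stages.append("extract")

    harmonized_table = None
    if which in ("feature", "combined"):
        harmonized_table = combat_mod.harmonize_per_roi(
            work_table, reference_batch=config.reference_group
        )
        stages.append("combat")
    stages.append("evaluate")

    if which == "feature":
        report = _evaluate(baseline_table, harmonized_table, config)
    elif which == "image":
        report = _evaluate(baseline_table, work_table, config, quality)
    else:
        report = _evaluate(baseline_table, harmonized_table, config, quality)

    return {
        "which": which,
        "provenance": stages,
        "report": report,
        "tables": {
            "baseline": baseline_table,
            "harmonized": harmonized_table if harmonized_table is not None else work_table,
        },
        "manifest": {
            "experiment": which,
            "config": dataclasses.asdict(config),
            "stages": stages,
        },
    }


def run_baseline(config: RunConfig) -> dict:
    """Evaluation of the non-harmonized study (reference for comparisons)."""
    volumes = _generate_volumes(config)
    table = extract_dataset(volumes, ExtractionConfig(bin_width=config.bin_width))
    report = _evaluate(table, None, config)
    return {
        "which": "none",
        "provenance": ["simulate", "clip", "extract", "evaluate"],
        "report": report,
        "tables": {"baseline": table, "harmonized": None},
        "manifest": {"experiment": "none", "config": dataclasses.asdict(config)},
    }


# ------------------------------------------------------- comparisons

REL_CHANGE_FORMULA = (
    "relative_change_pct = 100 * (method_value - baseline_value) / baseline_value, "
    "computed on summary metrics rounded to 2 decimals (macro AUC = mean of "
    "per-ROI AUCs rounded to 2 decimals)"
)

METHOD_ORDER = ("none", "combat", "gan", "gan+combat")


def _extract_metrics(bundle: Mapping) -> dict:
    rep = bundle.get("report", bundle)
    out = {}
    if "average_ccc" in rep:
        out["average_ccc"] = round(float(rep["average_ccc"]), 2)
    if "percent_reproducible" in rep:
        out["percent_reproducible"] = round(float(rep["percent_reproducible"]), 2)
    if "per_roi_stability" in rep:
        vals = list(rep["per_roi_stability"].values())
        out["average_percent_stable"] = round(float(np.mean(vals)), 2)
    elif "average_percent_stable" in rep:
        out["average_percent_stable"] = round(float(rep["average_percent_stable"]), 2)
    if "per_roi_auc" in rep:
        per_roi = {k: float(v) for k, v in rep["per_roi_auc"].items()}
        out.update({f"auc_roi_{k}": v for k, v in per_roi.items()})
        out["macro_auc"] = round(float(np.mean(list(per_roi.values()))), 2)
    elif "macro_auc" in rep:
        out["macro_auc"] = round(float(rep["macro_auc"]), 2)
    return out


class ComparabilityError(ValueError):
    pass


def compare_methods(reports: Mapping[str, Mapping]) -> dict:
    """Summarize evaluation bundles for {none, combat, gan, gan+combat}.

    Emits per-method summary metrics (average CCC, % reproducible,
    average per-ROI stability %, per-ROI and macro AUC) plus relative
    percent changes of each method against the non-harmonized baseline
    under the documented formula.
    """
    if "none" not in reports:
        raise ComparabilityError("baseline bundle 'none' is required")
    manifests = [
        b["manifest"].get("config")
        for b in reports.values()
        if isinstance(b, Mapping) and "manifest" in b and b["manifest"].get("config")
    ]
    if manifests and any(m != manifests[0] for m in manifests[1:]):
        raise ComparabilityError("bundles were not computed on the same inputs")

    metrics = {name: _extract_metrics(b) for name, b in reports.items()}
    base = metrics["none"]
    rows = []
    changes = {}
    for name in list(METHOD_ORDER) + [n for n in reports if n not in METHOD_ORDER]:
        if name not in metrics:
            continue
        m = metrics[name]
        rows.append({"method": name, **m})
        rel = {}
        for key in ("average_ccc", "percent_reproducible", "average_percent_stable", "macro_auc"):
            if key in m and key in base and base[key] != 0:
                rel[key] = round(100.0 * (m[key] - base[key]) / base[key], 2)
        changes[name] = rel
    return {
        "summary": pd.DataFrame(rows).set_index("method"),
        "relative_changes_pct": changes,
        "formula": REL_CHANGE_FORMULA,
    }
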