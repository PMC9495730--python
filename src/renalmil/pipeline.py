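"""End-to-end orchestration: normalize → tile → train → predict → fuse → score.

The in-memory engine functions (``normalize_slides``, ``train_bank``,
``predict_decisions``, ``run_cv``) do the actual work on loaded images; the
file-level entry points (``run_train``, ``run_predict``, ``run_full``) wrap
them with manifest reading, checkpointing and artifact writing for the CLI.

All randomness flows from one top-level seed: per-fold and per-scale
training seeds are derived with ``numpy.random.SeedSequence`` so a rerun with
the same seed reproduces the entire report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifiers, color, evaluation, fusion, tiling
from .io import SlideRecord, read_image, read_manifest, write_image

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "normalize_slides",
    "train_bank",
    "predict_decisions",
    "run_cv",
    "run_train",
    "run_predict",
    "run_full",
]

SCALES = (400, 200, 100)


@dataclass(frozen=True)
class PipelineConfig:
    manifest: str
    out_dir: str = "artifacts"
    reference_slide: str | None = None  # default: first manifest slide
    bins: int = 1024
    norm_method: str = "specification"
    tiling: tiling.TilingConfig = field(default_factory=tiling.TilingConfig)
    training: classifiers.TrainingConfig = field(default_factory=classifiers.TrainingConfig)
    architecture: str = "small_resnet"
    scheme: str = "kfold"  # kfold | loso
    k: int = 2
    seed: int = 0
    single_scale: int | None = None  # bypass fusion, score one scale alone
    cache_normalized: bool = False


def _derived_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def normalize_slides(
    records: list[SlideRecord],
    reference_slide: str | None = None,
    bins: int = 1024,
    method: str = "specification",
    images: dict[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Load (or take) slide images and stain-normalize them against one reference."""
    if images is None:
        missing = [r.path for r in records if not Path(r.path).exists()]
        if missing:
            raise FileNotFoundError(f"missing slide images: {missing}")
        images = {r.slide_id: read_image(r.path) for r in records}
    ref_id = reference_slide or records[0].slide_id
    if ref_id not in images:
        raise ValueError(f"reference slide {ref_id!r} not in manifest")
    profile = color.fit_reference(images[ref_id], bins=bins)
    return {
        sid: color.normalize_image(img, profile, method=method) for sid, img in images.items()
    }


def train_bank(
    images: dict[str, np.ndarray],
    records: list[SlideRecord],
    tiling_config: tiling.TilingConfig,
    training_config: classifiers.TrainingConfig,
    class_order: tuple[str, ...],
    seed: int,
    architecture: str = "small_resnet",
    scales: tuple[int, ...] = SCALES,
) -> dict[int, tuple[classifiers.ScaleModel, list[dict]]]:
    """Train one classifier per scale on weakly-labeled overlapping patches."""
    labels_by_slide = {r.slide_id: r.label for r in records}
    if len({r.label for r in records}) < 2:
        raise ValueError("training requires slides from at least 2 classes")
    bank: dict[int, tuple[classifiers.ScaleModel, list[dict]]] = {}
    for scale in scales:
        patches: list[tiling.Patch] = []
        labels: list[str] = []
        for r in records:
            ps = tiling.extract_training_patches(
                images[r.slide_id], r.slide_id, tiling_config, scales=(scale,)
            )
            patches.extend(ps)
            labels.extend([labels_by_slide[r.slide_id]] * len(ps))
        model_seed = _derived_seed(seed, scale)
        model = classifiers.build_model(
            scale=scale,
            n_classes=len(class_order),
            architecture=architecture,
            seed=model_seed,
            class_order=class_order,
        )
        cfg = dataclasses.replace(training_config, seed=model_seed)
        model, history = classifiers.train(model, patches, labels, cfg)
        logger.info(
            "trained scale-%d model on %d patches (%d epochs)", scale, len(patches), len(history)
        )
        bank[scale] = (model, history)
    return bank


def predict_decisions(
    bank: dict[int, classifiers.ScaleModel],
    images: dict[str, np.ndarray],
    records: list[SlideRecord],
    tiling_config: tiling.TilingConfig,
) -> list[fusion.PatchDecision]:
    """Concentric-set predictions for every test slide, fused per patch."""
    missing = [s for s in SCALES if s not in bank]
    if missing:
        raise ValueError(f"missing scale models: {missing}")
    decisions: list[fusion.PatchDecision] = []
    for r in records:
        sets = tiling.extract_concentric_sets(images[r.slide_id], r.slide_id, tiling_config)
        if not sets:
            logger.warning("slide %s yields no valid concentric sets", r.slide_id)
            continue
        preds_by_scale = {
            400: classifiers.predict_batch(bank[400], [s.large for s in sets]),
            200: classifiers.predict_batch(bank[200], [s.medium for s in sets]),
            100: classifiers.predict_batch(bank[100], [s.small for s in sets]),
        }
        for i, cset in enumerate(sets):
            votes = tuple(preds_by_scale[s][i].label for s in SCALES)
            probs = tuple(preds_by_scale[s][i].probabilities for s in SCALES)
            r0, c0 = cset.small.top_left
            decisions.append(
                fusion.PatchDecision(
                    set_id=f"{r.slide_id}:{r0}:{c0}",
                    slide_id=r.slide_id,
                    votes=votes,
                    outcome=fusion.fuse_patch(votes),
                    probabilities=probs,
                )
            )
    return decisions


def _class_order(records: list[SlideRecord]) -> tuple[str, ...]:
    seen: list[str] = []
    for r in records:
        if r.label not in seen:
            seen.append(r.label)
    return tuple(seen)


def _metrics_block(actual, predicted, classes) -> dict:
    cm = evaluation.confusion_matrix(actual, predicted, classes)
    per_class = evaluation.per_class_metrics(cm)
    block = {
        "confusion": {
            "classes": list(cm.classes),
            "counts": cm.counts.tolist(),
            "n_indeterminate": cm.n_indeterminate.tolist(),
        },
        "per_class": per_class,
        "summary": {},
    }
    for metric in ("accuracy", "sensitivity", "specificity"):
        vals = [
            per_class[c][metric]
            for c in classes
            if per_class[c][metric] is not None and not per_class[c]["flags"]
        ]
        if vals:
            s = evaluation.macro_summary(vals)
            mean_r, sd_r = s.rounded(1)
            block["summary"][metric] = {"mean": s.mean, "sd": s.sd, "display": f"{mean_r} ± {sd_r}"}
    return block


def run_cv(
    records: list[SlideRecord],
    images: dict[str, np.ndarray],
    split: evaluation.CVSplit,
    config: PipelineConfig,
) -> dict:
    """Full cross-validated evaluation: per-fold training and fused scoring.

    Reports per-fold patch-level accuracies for each single scale and for
    the fused decision (the fold-by-fold comparison layout), pooled
    patch-level one-vs-rest metrics, and pooled slide-level predictions and
    per-class accuracies.
    """
    class_order = _class_order(records)
    by_id = {r.slide_id: r for r in records}
    fold_rows: list[dict] = []
    pooled_decisions: list[fusion.PatchDecision] = []
    slide_actual: list[str] = []
    slide_predicted: list[str] = []
    slide_rows: list[dict] = []
    single_scale_slide: dict[int, list[str]] = {s: [] for s in SCALES}

    for fold_idx, (train_ids, test_ids) in enumerate(split):
        train_records = [by_id[i] for i in train_ids]
        test_records = [by_id[i] for i in test_ids]
        if len({r.label for r in train_records}) < 2:
            logger.warning("fold %d training set lacks class diversity; skipped", fold_idx)
            fold_rows.append({"fold": fold_idx, "degenerate": True})
            continue
        fold_seed = _derived_seed(config.seed, fold_idx)
        bank_hist = train_bank(
            images,
            train_records,
            config.tiling,
            config.training,
            class_order,
            fold_seed,
            architecture=config.architecture,
        )
        bank = {s: m for s, (m, _) in bank_hist.items()}
        decisions = predict_decisions(bank, images, test_records, config.tiling)
        pooled_decisions.extend(decisions)

        actual_by_set = [by_id[d.slide_id].label for d in decisions]
        kept = [(d, a) for d, a in zip(decisions, actual_by_set) if d.outcome != fusion.DISCARD]
        fold_acc = {
            "fused": 100.0 * np.mean([d.outcome == a for d, a in kept]) if kept else None,
        }
        for j, scale in enumerate(SCALES):
            fold_acc[f"scale_{scale}"] = (
                100.0 * np.mean([d.votes[j] == a for d, a in zip(decisions, actual_by_set)])
                if decisions
                else None
            )
        fold_rows.append(
            {
                "fold": fold_idx,
                "n_sets": len(decisions),
                "n_discarded": sum(d.outcome == fusion.DISCARD for d in decisions),
                "patch_accuracy": fold_acc,
            }
        )

        # slide-level: fused aggregation, plus each scale's votes alone
        for r in test_records:
            slide_dec = [d for d in decisions if d.slide_id == r.slide_id]
            if not slide_dec:
                continue
            pred = fusion.aggregate_slide(slide_dec, list(class_order))
            slide_actual.append(r.label)
            slide_predicted.append(pred.label)
            slide_rows.append(
                {
                    "fold": fold_idx,
                    "slide_id": r.slide_id,
                    "actual": r.label,
                    "predicted": pred.label,
                    "n_patches": pred.n_patches,
                    "n_discarded": pred.n_discarded,
                    "tie_flag": pred.tie_flag,
                    **{f"frac_{c}": pred.class_fractions[c] for c in class_order},
                }
            )
            for j, scale in enumerate(SCALES):
                sdec = [
                    fusion.PatchDecision(d.set_id, d.slide_id, d.votes, d.votes[j])
                    for d in slide_dec
                ]
                single_scale_slide[scale].append(
                    fusion.aggregate_slide(sdec, list(class_order)).label
                )

    report: dict = {
        "scheme": split.scheme,
        "n_folds": len(split),
        "classes": list(class_order),
        "folds": fold_rows,
        "slides": slide_rows,
    }
    ok_folds = [f for f in fold_rows if not f.get("degenerate")]
    if ok_folds:
        mean_acc = {}
        for key in ok_folds[0]["patch_accuracy"]:
            vals = [f["patch_accuracy"][key] for f in ok_folds if f["patch_accuracy"][key] is not None]
            mean_acc[key] = float(np.mean(vals)) if vals else None
        report["patch_accuracy_fold_mean"] = mean_acc
    if pooled_decisions:
        kept = [d for d in pooled_decisions if d.outcome != fusion.DISCARD]
        report["n_sets"] = len(pooled_decisions)
        report["n_discarded"] = len(pooled_decisions) - len(kept)
        report["patch_level"] = _metrics_block(
            [by_id[d.slide_id].label for d in kept],
            [d.outcome for d in kept],
            list(class_order),
        )
    if slide_actual:
        report["slide_level"] = _metrics_block(slide_actual, slide_predicted, list(class_order))
        report["slide_level"]["overall_accuracy"] = 100.0 * float(
            np.mean([a == p for a, p in zip(slide_actual, slide_predicted)])
        )
        report["slide_level_single_scale"] = {
            f"scale_{s}": 100.0
            * float(np.mean([a == p for a, p in zip(slide_actual, single_scale_slide[s])]))
            for s in SCALES
        }
    return report


# ---- file-level entry points (CLI) -----------------------------------------


def _prepare(config: PipelineConfig):
    records = read_manifest(config.manifest)
    images = normalize_slides(
        records, config.reference_slide, bins=config.bins, method=config.norm_method
    )
    if config.cache_normalized:
        cache = Path(config.out_dir) / "normalized"
        cache.mkdir(parents=True, exist_ok=True)
        for sid, img in images.items():
            write_image(cache / f"{sid}.png", img)
    return records, images


def run_train(config: PipelineConfig) -> dict:
    """Train the three-scale bank on all manifest slides; write checkpoints."""
    records, images = _prepare(config)
    bank = train_bank(
        images,
        records,
        config.tiling,
        config.training,
        _class_order(records),
        config.seed,
        architecture=config.architecture,
    )
    out = Path(config.out_dir)
    report = {"scales": [], "histories": {}}
    for scale, (model, history) in bank.items():
        classifiers.save_model(model, out / f"model_{scale}")
        report["scales"].append(scale)
        report["histories"][str(scale)] = history
    (out / "training_report.json").write_text(json.dumps(report, indent=2))
    return report


def run_predict(config: PipelineConfig, models_dir: str | Path | None = None) -> pd.DataFrame:
    """Predict concentric sets for every manifest slide; write predictions CSV."""
    records, images = _prepare(config)
    models_dir = Path(models_dir or config.out_dir)
    bank = {}
    for scale in SCALES:
        path = models_dir / f"model_{scale}"
        if not path.exists():
            raise ValueError(f"missing checkpoint for scale {scale}: {path}")
        bank[scale] = classifiers.load_model(path)
    decisions = predict_decisions(bank, images, records, config.tiling)
    class_order = bank[400].class_order
    rows = []
    for d in decisions:
        row = {
            "set_id": d.set_id,
            "slide_id": d.slide_id,
            "ypred_400": d.votes[0],
            "ypred_200": d.votes[1],
            "ypred_100": d.votes[2],
            "outcome": d.outcome,
        }
        for j, scale in enumerate(SCALES):
            for ci, cls in enumerate(class_order):
                row[f"p{scale}_{cls}"] = float(d.probabilities[j][ci])
        rows.append(row)
    df = pd.DataFrame(rows)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "predictions.csv", index=False)
    return df


def run_full(config: PipelineConfig) -> dict:
    """The whole chain under the chosen CV scheme; writes metrics JSON."""
    records, images = _prepare(config)
    if config.scheme == "kfold":
        split = evaluation.kfold_split(records, k=config.k, seed=config.seed)
    elif config.scheme == "loso":
        split = evaluation.loso_split(records)
    else:
        raise ValueError(f"unknown CV scheme {config.scheme!r}")
    if config.single_scale is not None:
        report = _run_single_scale(records, images, split, config)
    else:
        report = run_cv(records, images, split, config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "metrics.json").write_text(json.dumps(report, indent=2, default=_json_default))
    if "slides" in report:
        pd.DataFrame(report["slides"]).to_csv(out / "slide_predictions.csv", index=False)
    return report


def _run_single_scale(records, images, split, config: PipelineConfig) -> dict:
    """Single-classifier mode: one scale's votes, no fusion (comparison runs)."""
    scale = config.single_scale
    if scale not in SCALES:
        raise ValueError(f"single_scale must be one of {SCALES}")
    j = SCALES.index(scale)
    class_order = _class_order(records)
    by_id = {r.slide_id: r for r in records}
    slide_actual, slide_predicted = [], []
    fold_rows = []
    for fold_idx, (train_ids, test_ids) in enumerate(split):
        train_records = [by_id[i] for i in train_ids]
        test_records = [by_id[i] for i in test_ids]
        fold_seed = _derived_seed(config.seed, fold_idx)
        bank_hist = train_bank(
            images, train_records, config.tiling, config.training, class_order, fold_seed,
            architecture=config.architecture,
        )
        bank = {s: m for s, (m, _) in bank_hist.items()}
        decisions = predict_decisions(bank, images, test_records, config.tiling)
        acc = (
            100.0 * float(np.mean([d.votes[j] == by_id[d.slide_id].label for d in decisions]))
            if decisions
            else None
        )
        fold_rows.append({"fold": fold_idx, "n_sets": len(decisions), "patch_accuracy": acc})
        for r in test_records:
            slide_dec = [
                fusion.PatchDecision(d.set_id, d.slide_id, d.votes, d.votes[j])
                for d in decisions
                if d.slide_id == r.slide_id
            ]
            if not slide_dec:
                continue
            slide_actual.append(r.label)
            slide_predicted.append(fusion.aggregate_slide(slide_dec, list(class_order)).label)
    report = {"scheme": split.scheme, "single_scale": scale, "folds": fold_rows,
              "classes": list(class_order)}
    if slide_actual:
        report["slide_level"] = _metrics_block(slide_actual, slide_predicted, list(class_order))
        report["slide_level"]["overall_accuracy"] = 100.0 * float(
            np.mean([a == p for a, p in zip(slide_actual, slide_predicted)])
        )
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
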