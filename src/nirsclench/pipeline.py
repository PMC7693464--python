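"""End-to-end orchestration: simulate -> preprocess -> encode -> CV -> report.

One declarative :class:`PipelineConfig` drives every stage; all randomness
derives from its seeds, so a manifest plus the package version is enough
to regenerate every output file bit-identically.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier as clf
from .channel_stats import channel_changes
from .dataset import BalancedSet, FoldPlan, balance_classes, fold_images, make_fold_plan
from .evaluation import (ConfusionCounts, MetricSet, ROCResult, aggregate_folds,
                         confusion_counts, compute_metrics, metrics_report,
                         micro_accuracy, roc_auc, ryan_compare)
from .imaging import MODALITIES, ChannelLayout, GrayscaleScheme, HbImage, build_image_set
from .preprocess import preprocess_recording
from .synth import CohortConfig, generate_cohort


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    cutoff_hz: float = 0.2
    filter_order: int = 4
    mask_n_sd: float = 2.0
    gray_scope: str = "per_subject"
    balance_strategy: str = "per_subject"
    frame_stride: int = 1  # 1 = native 10 Hz frame cadence
    modalities: tuple[str, ...] = MODALITIES
    preset: str = "tiny"  # tiny | full
    train: clf.TrainConfig = field(default_factory=lambda: clf.TrainConfig(epochs=10, batch_size=32))
    n_folds: int = 5
    seed: int = 0

    def network_spec(self) -> clf.NetworkSpec:
        if self.preset == "tiny":
            return clf.NetworkSpec.tiny()
        if self.preset == "full":
            return clf.NetworkSpec()
        raise ValueError(f"unknown preset {self.preset!r}")


def _sub_seed(seed: int, *tags: int) -> int:
    """Deterministic sub-seed below 2**31."""
    ss = np.random.SeedSequence([seed, *tags])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class ModalityResult:
    modality: str
    predictions: clf.PredictionSet
    fold_metrics: list[MetricSet]
    fold_counts: list[ConfusionCounts]
    aggregate: dict[str, tuple[float, float]]
    roc: ROCResult
    report: pd.DataFrame

    @property
    def macro_accuracy(self) -> float:
        return self.aggregate["accuracy"][0]

    @property
    def micro_accuracy(self) -> float:
        return micro_accuracy(self.fold_counts)

    @property
    def pooled_counts(self) -> tuple[int, int]:
        c = sum(x.correct for x in self.fold_counts)
        n = sum(x.total for x in self.fold_counts)
        return c, n


def run_grouped_cv(images: list[HbImage], plan: FoldPlan,
                   spec: clf.NetworkSpec, train_cfg: clf.TrainConfig,
                   modality: str, seed: int) -> ModalityResult:
    """Train/test the CNN once per fold, holding out one subject group."""
    balanced = BalancedSet(images=images,
                           n_rest=sum(im.label == "rest" for im in images),
                           n_clench=sum(im.label == "clench" for im in images))
    x_all = clf.images_to_array(images, spec.input_side)
    y_all = clf.labels_to_array(images)
    subjects = np.array([im.subject_id for im in images])

    preds = []
    fold_metrics = []
    fold_counts = []
    for fold in range(plan.n_folds):
        train_subj, test_subj = plan.split(fold)
        tr = np.isin(subjects, sorted(train_subj))
        te = np.isin(subjects, sorted(test_subj))
        model = clf.build_network(spec, seed=_sub_seed(seed, fold, 1))
        fold_cfg = replace(train_cfg, seed=_sub_seed(seed, fold, 2))
        clf.train(model, [], fold_cfg, x=x_all[tr], y=y_all[tr])
        test_images = [im for im, flag in zip(images, te) if flag]
        p = clf.predict(model, test_images, fold=fold, modality=modality,
                        x=x_all[te])
        preds.append(p)
        counts = confusion_counts(p)
        fold_counts.append(counts)
        fold_metrics.append(compute_metrics(counts))

    pooled = clf.PredictionSet.concat(preds)
    return ModalityResult(
        modality=modality,
        predictions=pooled,
        fold_metrics=fold_metrics,
        fold_counts=fold_counts,
        aggregate=aggregate_folds(fold_metrics),
        roc=roc_auc(pooled),
        report=metrics_report(fold_metrics),
    )


def encode_cohort(config: PipelineConfig) -> tuple[dict[str, list[HbImage]], list]:
    """Stages 1-3: simulate, preprocess, render frames for every modality."""
    cohort = generate_cohort(config.cohort)
    layout = ChannelLayout.default()
    scheme = GrayscaleScheme(scope=config.gray_scope)
    images: dict[str, list[HbImage]] = {m: [] for m in config.modalities}
    for rec in cohort:
        epoch = preprocess_recording(
            rec, cutoff=config.cutoff_hz, filter_order=config.filter_order,
            n_sd=config.mask_n_sd)
        per_subject = build_image_set(epoch, layout, scheme,
                                      modalities=config.modalities,
                                      sample_stride=config.frame_stride)
        for m in config.modalities:
            images[m].extend(per_subject[m])
    return images, cohort


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage and return (and optionally write) the manifest."""
    t0 = time.time()
    manifest: dict = {"seed": config.seed, "preset": config.preset,
                      "frame_stride": config.frame_stride, "stages": {}}

    try:
        images, cohort = encode_cohort(config)
    except Exception as e:  # noqa: BLE001
        raise StageError("encode", e) from e
    manifest["stages"]["encode"] = {
        m: {"n_frames": len(ims),
            "n_rest": sum(im.label == "rest" for im in ims),
            "n_clench": sum(im.label == "clench" for im in ims)}
        for m, ims in images.items()
    }

    try:
        subject_ids = sorted({rec.subject_id for rec in cohort})
        plan = make_fold_plan(subject_ids, seed=_sub_seed(config.seed, 101),
                              n_folds=config.n_folds)
        balanced = {
            m: balance_classes(ims, seed=_sub_seed(config.seed, 102, i),
                               strategy=config.balance_strategy)
            for i, (m, ims) in enumerate(images.items())
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("dataset", e) from e
    manifest["stages"]["dataset"] = {
        m: {"n_rest": b.n_rest, "n_clench": b.n_clench}
        for m, b in balanced.items()
    }
    manifest["fold_plan"] = [list(g) for g in plan.groups]

    results: dict[str, ModalityResult] = {}
    spec = config.network_spec()
    try:
        for mi, m in enumerate(config.modalities):
            results[m] = run_grouped_cv(
                balanced[m].images, plan, spec, config.train, m,
                seed=_sub_seed(config.seed, 103, mi))
    except Exception as e:  # noqa: BLE001
        raise StageError("classifier", e) from e

    try:
        stats_tables = channel_changes(cohort, cutoff=config.cutoff_hz)
    except Exception as e:  # noqa: BLE001
        raise StageError("channel_stats", e) from e

    ryan = None
    if len(results) >= 2:
        ryan = ryan_compare({m: r.pooled_counts for m, r in results.items()})

    manifest["stages"]["evaluation"] = {
        m: {
            "macro_accuracy": r.macro_accuracy,
            "micro_accuracy": r.micro_accuracy,
            "auc": r.roc.auc,
            "auc_ci": [r.roc.ci_low, r.roc.ci_high],
            "auc_p": r.roc.p_value,
            "pooled_correct": r.pooled_counts[0],
            "pooled_total": r.pooled_counts[1],
        }
        for m, r in results.items()
    }
    if ryan is not None:
        manifest["ryan"] = [asdict(d) for d in ryan]
    manifest["wall_clock_s"] = round(time.time() - t0, 2)
    manifest["results"] = results
    manifest["channel_stats"] = stats_tables

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for m, r in results.items():
            r.report.to_csv(out / f"metrics_{m}.csv", index=False)
            r.predictions.frame.to_csv(out / f"predictions_{m}.csv", index=False)
            pd.DataFrame({"fpr": r.roc.fpr, "tpr": r.roc.tpr}).to_csv(
                out / f"roc_{m}.csv", index=False)
        for sp, table in stats_tables.items():
            table.frame.to_csv(out / f"channel_changes_{sp}.csv", index=False)
        slim = {k: v for k, v in manifest.items()
                if k not in ("results", "channel_stats")}
        (out / "manifest.json").write_text(
            json.dumps(slim, indent=2, default=float))
    return manifest
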