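"""Experiment orchestration: hold-out, cross-validation, ablation, baselines,
explanation.

Every runner consumes one :class:`ExperimentConfig`, writes its outputs under
the configured run directory, and drops a ``manifest.json`` (config, seed,
package version, per-stage wall time) sufficient to re-run it.  The default
configuration is desk-scale: the synthetic generator as data source and the
tiny CNN teacher/student pair at 96 px.  The full-scale reference protocol
(ResNet-50 teacher, ResNet-18 student, 224 px) is selected through the same
config fields.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .baselines import FEATURE_MODES, HandcraftedFeatureConfig, run_baseline
from .evaluation import CvSummary, classification_metrics, run_cross_validation
from .explain import explain_batch
from .models import BackboneSpec
from .nkd_core import DistillationConfig
from .preprocessing import PreprocessConfig, preprocess_set
from .synthetic import LabeledImageSet, SyntheticSpec, generate, read_from_disk, stratified_split
from .training import TrainConfig, train_student, train_teacher

__all__ = [
    "ExperimentConfig",
    "ABLATION_ARMS",
    "load_dataset",
    "run_holdout",
    "run_cv",
    "run_ablation",
    "run_baselines",
    "run_explain",
]

#: ablation arm -> (student_mode, DistillationConfig overrides)
ABLATION_ARMS = {
    "ce_only": ("ce_only", {}),
    "neutro_full": ("nkd", {}),
    "neutro_no_weight": ("nkd", {"weighting_enabled": False}),
    "neutro_entropy": ("nkd", {"indeterminacy_mode": "entropy"}),
    "neutro_wmin0": ("nkd", {"weight_min": 0.0}),
    "neutro_fixed_alpha": ("nkd", {"fixed_alpha": True}),
}


@dataclass(frozen=True)
class ExperimentConfig:
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    data_dir: str | None = None
    preprocess: PreprocessConfig = field(default_factory=lambda: PreprocessConfig(target_size=96))
    distill: DistillationConfig = field(default_factory=DistillationConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    teacher_arch: str = "tiny_cnn_large"
    student_arch: str = "tiny_cnn_small"
    test_fraction: float = 0.2
    val_fraction: float = 0.15
    n_folds: int = 5
    output_dir: str = "runs"
    seed: int = 42

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_dataset(cfg: ExperimentConfig) -> LabeledImageSet:
    if cfg.data_dir is not None:
        return read_from_disk(cfg.data_dir)
    return generate(cfg.synthetic)


def _manifest(cfg: ExperimentConfig, out: Path, stages: dict, extra: dict | None = None):
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "package_version": __version__,
        "wall_time_s": stages,
    }
    if extra:
        payload.update(extra)
    with open(out / "manifest.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=str)


def _inner_split(train_set: LabeledImageSet, cfg: ExperimentConfig):
    return stratified_split(train_set, cfg.val_fraction, cfg.seed + 1)


def _student_probs(student, test_set, pre_cfg) -> np.ndarray:
    x = preprocess_set(test_set.images, dataclasses.replace(pre_cfg, augment=False))
    logits = student.logits(x).astype(np.float64)
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _train_pair(fit_set, cfg: ExperimentConfig, mode: str, dcfg: DistillationConfig, teacher=None):
    """Train (teacher if absent) and a student in ``mode`` on ``fit_set``."""
    tr, val = _inner_split(fit_set, cfg)
    if teacher is None:
        teacher, _ = train_teacher(
            tr,
            val,
            BackboneSpec(cfg.teacher_arch, fit_set.n_classes, role="teacher", seed=cfg.seed),
            cfg.train,
            cfg.preprocess,
        )
    tcfg = dataclasses.replace(cfg.train, student_mode=mode)
    student, history = train_student(
        tr,
        val,
        teacher,
        BackboneSpec(cfg.student_arch, fit_set.n_classes, role="student", seed=cfg.seed + 1),
        dcfg,
        tcfg,
        cfg.preprocess,
    )
    return teacher, student, history


def run_holdout(cfg: ExperimentConfig, modes: tuple[str, ...] = ("ce_only", "nkd")) -> dict:
    """Stratified hold-out evaluation of the teacher and selected student modes."""
    out = Path(cfg.output_dir) / "holdout"
    t0 = time.time()
    dataset = load_dataset(cfg)
    fit_set, test_set = stratified_split(dataset, cfg.test_fraction, cfg.seed)
    stages = {"data": time.time() - t0}

    results: dict[str, object] = {}
    teacher = None
    for mode in modes:
        t0 = time.time()
        teacher, student, history = _train_pair(fit_set, cfg, mode, cfg.distill, teacher)
        probs = _student_probs(student, test_set, cfg.preprocess)
        report = classification_metrics(test_set.labels, probs)
        results[mode] = {"report": report, "history": history, "student": student}
        stages[f"student_{mode}"] = time.time() - t0
    if teacher is None:  # teacher-only run
        t0 = time.time()
        tr, val = _inner_split(fit_set, cfg)
        teacher, _ = train_teacher(
            tr,
            val,
            BackboneSpec(cfg.teacher_arch, dataset.n_classes, role="teacher", seed=cfg.seed),
            cfg.train,
            cfg.preprocess,
        )
        stages["teacher"] = time.time() - t0
    teacher_probs = _student_probs(teacher, test_set, cfg.preprocess)
    results["teacher"] = {"report": classification_metrics(test_set.labels, teacher_probs)}
    results["teacher"]["network"] = teacher
    results["test_set"] = test_set

    table = pd.DataFrame(
        {
            name: {
                m: results[name]["report"].metric(m)
                for m in ("accuracy", "sensitivity", "specificity", "precision", "recall", "f1", "auc_macro")
            }
            for name in list(modes) + ["teacher"]
        }
    ).T
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "metrics.csv")
    _manifest(cfg, out, stages)
    results["table"] = table
    return results


def run_cv(cfg: ExperimentConfig, mode: str = "nkd") -> CvSummary:
    """Stratified K-fold CV of the full teacher->student pipeline.

    The teacher is retrained inside every fold on that fold's training split
    only, so no fold's test images ever influence its own teacher.
    """
    out = Path(cfg.output_dir) / f"cv_{mode}"
    dataset = load_dataset(cfg)
    t0 = time.time()

    def fit_predict(train_split, test_split, fold_id):
        _, student, _ = _train_pair(train_split, cfg, mode, cfg.distill)
        return _student_probs(student, test_split, cfg.preprocess)

    summary = run_cross_validation(dataset, fit_predict, n_splits=cfg.n_folds, seed=cfg.seed)
    out.mkdir(parents=True, exist_ok=True)
    rows = pd.DataFrame(
        [{m: r.metric(m) for m in ("accuracy", "sensitivity", "specificity", "precision", "recall", "f1")} for r in summary.per_fold]
    )
    rows.to_csv(out / "metrics.csv", index=False)
    summary.summary.to_csv(out / "aggregate.csv")
    np.savetxt(out / "cumulative_confusion.csv", summary.cumulative_confusion, fmt="%d", delimiter=",")
    _manifest(cfg, out, {"cv": time.time() - t0})
    return summary


def run_ablation(cfg: ExperimentConfig) -> pd.DataFrame:
    """All six ablation arms plus the teacher reference on one fixed split.

    Every arm shares the identical stratified 80/20 split and the identical
    trained teacher; only the distillation configuration differs.
    """
    out = Path(cfg.output_dir) / "ablation"
    dataset = load_dataset(cfg)
    fit_set, test_set = stratified_split(dataset, cfg.test_fraction, cfg.seed)
    split_checksum = hashlib.sha256(
        np.concatenate([fit_set.labels, test_set.labels]).tobytes()
    ).hexdigest()[:16]

    stages: dict[str, float] = {}
    rows = []
    t0 = time.time()
    tr, val = _inner_split(fit_set, cfg)
    teacher, _ = train_teacher(
        tr,
        val,
        BackboneSpec(cfg.teacher_arch, dataset.n_classes, role="teacher", seed=cfg.seed),
        cfg.train,
        cfg.preprocess,
    )
    stages["teacher"] = time.time() - t0
    teacher_probs = _student_probs(teacher, test_set, cfg.preprocess)
    rep = classification_metrics(test_set.labels, teacher_probs)
    rows.append(_ablation_row("teacher", rep, None, None))

    weight_logs: dict[str, np.ndarray] = {}
    for arm, (mode, overrides) in ABLATION_ARMS.items():
        t0 = time.time()
        dcfg = cfg.distill.replace(**overrides)
        tcfg = dataclasses.replace(cfg.train, student_mode=mode)
        student, history = train_student(
            tr,
            val,
            teacher,
            BackboneSpec(cfg.student_arch, dataset.n_classes, role="student", seed=cfg.seed + 1),
            dcfg,
            tcfg,
            cfg.preprocess,
        )
        probs = _student_probs(student, test_set, cfg.preprocess)
        rep = classification_metrics(test_set.labels, probs)
        rows.append(_ablation_row(arm, rep, history, dcfg))
        weight_logs[arm] = history["mean_weight"].to_numpy()
        stages[arm] = time.time() - t0

    table = pd.DataFrame(rows).set_index("method")
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "ablation.csv")
    _manifest(cfg, out, stages, extra={"split_checksum": split_checksum})
    table.attrs["split_checksum"] = split_checksum
    table.attrs["weight_logs"] = weight_logs
    return table


def _ablation_row(name, report, history, dcfg):
    row = {
        "method": name,
        "accuracy": report.accuracy,
        "sensitivity": report.sensitivity,
        "specificity": report.specificity,
        "precision": report.precision,
        "recall": report.recall,
        "f1": report.f1,
        "auc": report.auc_macro,
    }
    if history is not None:
        row["mean_weight"] = float(history["mean_weight"].mean())
        row["alpha_first"] = float(history["alpha"].iloc[0])
        row["alpha_last"] = float(history["alpha"].iloc[-1])
    return row


def run_baselines(
    cfg: ExperimentConfig,
    feature_modes: tuple[str, ...] = FEATURE_MODES,
    kernels: tuple[str, ...] = ("linear", "rbf"),
    feature_config: HandcraftedFeatureConfig | None = None,
) -> pd.DataFrame:
    """Classical feature+SVM baselines under the shared CV protocol."""
    out = Path(cfg.output_dir) / "baselines"
    dataset = load_dataset(cfg)
    base = feature_config or HandcraftedFeatureConfig()
    rows = []
    stages = {}
    for mode in feature_modes:
        for kernel in kernels:
            t0 = time.time()
            fc = dataclasses.replace(base, svm_kernel=kernel)
            summary = run_baseline(
                dataset, mode, fc, cfg.preprocess, n_splits=cfg.n_folds, seed=cfg.seed
            )
            agg = summary.summary
            rows.append(
                {
                    "method": f"{mode}_svm_{kernel}",
                    **{m: agg.loc[m, "mean"] for m in ("accuracy", "specificity", "precision", "recall", "f1")},
                }
            )
            stages[f"{mode}_{kernel}"] = time.time() - t0
    table = pd.DataFrame(rows).set_index("method")
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "metrics.csv")
    _manifest(cfg, out, stages)
    return table


def run_explain(cfg: ExperimentConfig, per_class: int = 2):
    """Train the NKD student on a hold-out split and produce a Grad-CAM++
    gallery with confidence/entropy/indeterminacy annotations."""
    out = Path(cfg.output_dir) / "explain"
    dataset = load_dataset(cfg)
    fit_set, test_set = stratified_split(dataset, cfg.test_fraction, cfg.seed)
    _, student, _ = _train_pair(fit_set, cfg, "nkd", cfg.distill)

    picks = []
    for k in range(dataset.n_classes):
        picks.extend(np.flatnonzero(test_set.labels == k)[:per_class])
    picks = np.asarray(picks)
    subset = test_set.subset(picks)
    x = preprocess_set(subset.images, dataclasses.replace(cfg.preprocess, augment=False))
    records, fig = explain_batch(
        student, x, subset.labels, cfg.distill,
        originals=subset.images, class_names=dataset.class_names,
    )
    out.mkdir(parents=True, exist_ok=True)
    fig.savefig(out / "gallery.png", dpi=120)
    _manifest(cfg, out, {})
    return records, fig
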