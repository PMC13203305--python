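"""Teacher and student trainers sharing one optimization loop.

The teacher is trained with plain cross-entropy.  Students are trained in one
of four modes: ``ce_only`` (no distillation), ``standard_kd`` (temperature-
scaled KL on teacher soft targets), ``fuzzy_kd`` (teacher probabilities
power-transformed before the KL) and ``nkd`` (the neutrosophic
indeterminacy-weighted distillation objective).  The teacher is used in
inference mode only and is never updated — only the student receives
gradients.

Batch-level loss values are computed with the same formulas as
:mod:`neutrokd.nkd_core`; the analytic logit gradients are

    d L_CE / d z_s = (softmax(z_s) - onehot(y)) / N
    d L_KD / d z_s = T * w_i * (softmax(z_s/T) - p_t) / N

so the weighted distillation term's gradient is temperature-invariant in
magnitude (the usual T^2 compensation).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nkd_core as core
from .models import BackboneSpec, Network, build
from .nn import AdamW, ReduceLROnPlateau
from .preprocessing import PreprocessConfig, apply_clahe, augment, standardize
from .synthetic import LabeledImageSet

__all__ = [
    "TrainConfig",
    "train_teacher",
    "train_student",
    "student_batch_loss",
]

STUDENT_MODES = ("ce_only", "standard_kd", "fuzzy_kd", "nkd")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 40
    batch_size: int = 16
    learning_rate: float = 3e-4
    weight_decay: float = 1e-4
    optimizer: str = "adamw"
    scheduler: str = "reduce_on_plateau"
    grad_accumulation_steps: int = 1
    mixed_precision: bool = False
    seed: int = 42
    student_mode: str = "nkd"

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.grad_accumulation_steps < 1:
            raise ValueError("epochs, batch_size and grad_accumulation_steps must be >= 1")
        if self.optimizer != "adamw":
            raise ValueError("only the adamw optimizer is supported")
        if self.scheduler not in ("reduce_on_plateau", "none"):
            raise ValueError("scheduler must be 'reduce_on_plateau' or 'none'")
        if self.student_mode not in STUDENT_MODES:
            raise ValueError(f"student_mode must be one of {STUDENT_MODES}")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _batch_weights(pt: np.ndarray, dcfg: core.DistillationConfig) -> np.ndarray:
    """Vectorized per-sample neutrosophic distillation weights."""
    n = pt.shape[0]
    if not dcfg.weighting_enabled:
        return np.ones(n)
    if dcfg.indeterminacy_mode == "margin":
        top2 = np.partition(pt, -2, axis=1)[:, -2:]
        indet = 1.0 - (top2[:, 1] - top2[:, 0])
    else:
        safe = np.where(pt > 0, pt, 1.0)
        indet = -(pt * np.log(safe)).sum(axis=1) / np.log(pt.shape[1])
    indet = np.clip(indet, 0.0, 1.0)
    margin_conf = 1.0 - indet
    raw = 1.0 / (1.0 + np.exp(-dcfg.steepness_k * (margin_conf - dcfg.margin_threshold_tau)))
    return np.clip(raw, dcfg.weight_min, dcfg.weight_max)


def student_batch_loss(
    teacher_logits: np.ndarray | None,
    student_logits: np.ndarray,
    labels: np.ndarray,
    mode: str,
    dcfg: core.DistillationConfig,
    alpha: float,
):
    """Loss breakdown and analytic logit gradient for one student batch.

    Returns ``(breakdown, dlogits, weights)``; ``dlogits`` is the gradient of
    the combined objective with respect to the student logits.
    """
    zs = np.asarray(student_logits, dtype=np.float64)
    y = np.asarray(labels)
    n, n_classes = zs.shape
    onehot = np.zeros_like(zs)
    onehot[np.arange(n), y] = 1.0

    ps1 = _softmax(zs)
    ce = float(-np.log(np.maximum(ps1[np.arange(n), y], core.LOG_EPS)).mean())
    g_ce = (ps1 - onehot) / n

    if mode == "ce_only":
        breakdown = core.combined_loss(ce, 0.0, 1.0)
        return breakdown, g_ce, np.ones(n)

    if teacher_logits is None:
        raise ValueError(f"student mode {mode!r} requires teacher logits")
    zt = np.asarray(teacher_logits, dtype=np.float64)
    if zt.shape != zs.shape:
        raise ValueError("teacher/student class count or batch size mismatch")

    T = dcfg.temperature
    pt = _softmax(zt / T)
    if mode == "fuzzy_kd":
        pt = pt**dcfg.fuzzy_exponent
        pt = pt / pt.sum(axis=1, keepdims=True)
    psT = _softmax(zs / T)

    if mode == "nkd":
        weights = _batch_weights(pt, dcfg)
    else:  # standard_kd and fuzzy_kd use unweighted soft targets
        weights = np.ones(n)

    safe_ps = np.maximum(psT, core.LOG_EPS)
    kl_per = np.where(pt > 0, pt * np.log(np.where(pt > 0, pt, 1.0) / safe_ps), 0.0).sum(axis=1)
    distill = float(T * T * (weights * kl_per).mean())
    g_kd = T * weights[:, None] * (psT - pt) / n

    breakdown = core.combined_loss(ce, distill, alpha, sample_weights=weights)
    dlogits = alpha * g_ce + (1.0 - alpha) * g_kd
    return breakdown, dlogits, weights


def _prepare_tensors(
    dataset: LabeledImageSet, pre_cfg: PreprocessConfig, dtype
) -> tuple[list[np.ndarray], np.ndarray]:
    """CLAHE once per image; return enhanced uint8 images and eval tensors."""
    enhanced = [apply_clahe(img, pre_cfg) for img in dataset.images]
    tensors = np.stack([standardize(img, pre_cfg) for img in enhanced]).astype(dtype)
    return enhanced, tensors


def _epoch_inputs(enhanced, eval_tensors, pre_cfg, rng, dtype):
    if not pre_cfg.augment or rng is None:
        return eval_tensors
    return np.stack(
        [standardize(augment(img, pre_cfg, rng), pre_cfg) for img in enhanced]
    ).astype(dtype)


def _evaluate(net: Network, tensors: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    logits = net.logits(tensors)
    p = _softmax(logits.astype(np.float64))
    loss = float(-np.log(np.maximum(p[np.arange(len(labels)), labels], core.LOG_EPS)).mean())
    acc = float((p.argmax(axis=1) == labels).mean())
    return loss, acc


def _fit(
    net: Network,
    teacher: Network | None,
    train_set: LabeledImageSet,
    val_set: LabeledImageSet,
    config: TrainConfig,
    dcfg: core.DistillationConfig | None,
    mode: str,
    pre_cfg: PreprocessConfig,
):
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation splits must be non-empty")
    if teacher is not None and teacher.spec.n_classes != net.spec.n_classes:
        raise ValueError("teacher/student class count mismatch")
    dtype = np.float16 if config.mixed_precision else np.float32
    rng = np.random.default_rng(config.seed)
    enhanced, train_eval = _prepare_tensors(train_set, pre_cfg, dtype)
    _, val_tensors = _prepare_tensors(val_set, pre_cfg, dtype)
    y = train_set.labels

    opt = AdamW(
        net.params(), lr=config.learning_rate, weight_decay=config.weight_decay
    )
    sched = (
        ReduceLROnPlateau(opt, factor=0.5, patience=3)
        if config.scheduler == "reduce_on_plateau"
        else None
    )
    dcfg = dcfg or core.DistillationConfig()
    accum = config.grad_accumulation_steps
    history = []
    best = (-1.0, None)

    for epoch in range(config.epochs):
        alpha = 1.0 if mode == "ce_only" else core.alpha_at(epoch, config.epochs, dcfg)
        xs = _epoch_inputs(enhanced, train_eval, pre_cfg, rng, dtype)
        zt_all = teacher.logits(xs) if teacher is not None else None
        order = rng.permutation(len(y))
        tot_loss = tot_ce = tot_kd = tot_w = 0.0
        n_correct = 0
        opt.zero_grad()
        pending = 0
        batches = [order[i : i + config.batch_size] for i in range(0, len(order), config.batch_size)]
        for bi, idx in enumerate(batches):
            logits = net.forward(xs[idx], train=True)
            zt = None if zt_all is None else zt_all[idx]
            breakdown, dlogits, weights = student_batch_loss(
                zt, logits.astype(np.float64), y[idx], mode, dcfg, alpha
            )
            net.backward(dlogits / accum)
            pending += 1
            if pending == accum or bi == len(batches) - 1:
                opt.step()
                opt.zero_grad()
                pending = 0
            tot_loss += breakdown.total * len(idx)
            tot_ce += breakdown.ce_term * len(idx)
            tot_kd += breakdown.distill_term * len(idx)
            tot_w += float(np.sum(weights))
            n_correct += int((logits.argmax(axis=1) == y[idx]).sum())
        n = len(y)
        val_loss, val_acc = _evaluate(net, val_tensors, val_set.labels)
        if sched is not None:
            sched.step(val_loss)
        history.append(
            {
                "epoch": epoch,
                "train_loss": tot_loss / n,
                "train_acc": n_correct / n,
                "ce_term": tot_ce / n,
                "distill_term": tot_kd / n,
                "mean_weight": tot_w / n,
                "alpha": alpha,
                "val_loss": val_loss,
                "val_acc": val_acc,
                "lr": opt.lr,
            }
        )
        if not np.isfinite(tot_loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        if val_acc > best[0]:
            best = (val_acc, copy.deepcopy(net))

    final = best[1] if best[1] is not None else net
    return final, pd.DataFrame(history)


def train_teacher(
    train_set: LabeledImageSet,
    val_set: LabeledImageSet,
    backbone_spec: BackboneSpec,
    config: TrainConfig,
    preprocess_config: PreprocessConfig | None = None,
) -> tuple[Network, pd.DataFrame]:
    """Cross-entropy training of the teacher; returns the best-validation
    checkpoint and the per-epoch history."""
    net = build(backbone_spec)
    pre_cfg = preprocess_config or PreprocessConfig()
    return _fit(net, None, train_set, val_set, config, None, "ce_only", pre_cfg)


def train_student(
    train_set: LabeledImageSet,
    val_set: LabeledImageSet,
    teacher: Network | None,
    backbone_spec: BackboneSpec,
    distill_config: core.DistillationConfig,
    config: TrainConfig,
    preprocess_config: PreprocessConfig | None = None,
) -> tuple[Network, pd.DataFrame]:
    """Train a student in the configured mode; the teacher is never updated."""
    net = build(backbone_spec)
    pre_cfg = preprocess_config or PreprocessConfig()
    return _fit(
        net, teacher if config.student_mode != "ce_only" else None,
        train_set, val_set, config, distill_config, config.student_mode, pre_cfg,
    )
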