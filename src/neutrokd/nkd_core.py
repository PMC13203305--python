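"""Neutrosophic knowledge distillation (NKD) loss mathematics.

Pure NumPy implementation of the distillation objective, independent of any
training loop or network architecture.

The method decomposes the teacher's temperature-softened class distribution
into a neutrosophic triplet (truth ``T``, indeterminacy ``I``, falsity ``F``):
``T`` is the top teacher probability, ``F = 1 - T``, and ``I`` measures how
ambiguous the prediction is — either one minus the margin between the two
largest probabilities (margin mode) or the Shannon entropy normalized by
``log C`` (entropy mode).  Each sample's contribution to the distillation KL
term is scaled by a sigmoid of its margin-based confidence ``M = 1 - I``,

    w = clamp(sigmoid(k * (M - tau)), w_min, w_max),

so confidently-predicted samples transfer teacher knowledge at full strength
while ambiguous ones are down-weighted.  The full student objective mixes this
weighted distillation term with ordinary cross-entropy on the hard labels
using an epoch-wise linearly decayed coefficient alpha.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DistillationConfig",
    "NeutrosophicTriplet",
    "LossBreakdown",
    "soften",
    "kl_divergence",
    "cross_entropy",
    "neutrosophic_triplet",
    "distillation_weight",
    "nkd_loss",
    "fuzzy_transform",
    "alpha_at",
    "combined_loss",
]

#: Floor used inside every logarithm to keep the loss finite.
LOG_EPS = 1e-12


@dataclass(frozen=True)
class DistillationConfig:
    """Hyperparameters of the NKD objective.

    Defaults are the published reference settings: temperature 4.0, sigmoid
    steepness ``k`` 8.0, confidence margin threshold ``tau`` 0.15, weight
    bounds [0.10, 1.00], and a linear epoch-wise alpha decay 0.90 -> 0.70.
    """

    temperature: float = 4.0
    steepness_k: float = 8.0
    margin_threshold_tau: float = 0.15
    weight_min: float = 0.10
    weight_max: float = 1.00
    alpha_start: float = 0.90
    alpha_end: float = 0.70
    indeterminacy_mode: str = "margin"  # "margin" or "entropy"
    weighting_enabled: bool = True
    fuzzy_exponent: float = 2.0
    fixed_alpha: bool = False  # ablation arm: hold alpha at alpha_start

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.steepness_k <= 0:
            raise ValueError("steepness_k must be positive")
        if not 0.0 <= self.margin_threshold_tau <= 1.0:
            raise ValueError("margin_threshold_tau must lie in [0, 1]")
        if not 0.0 <= self.weight_min <= self.weight_max <= 1.0:
            raise ValueError("need 0 <= weight_min <= weight_max <= 1")
        if self.indeterminacy_mode not in ("margin", "entropy"):
            raise ValueError("indeterminacy_mode must be 'margin' or 'entropy'")
        if self.fuzzy_exponent <= 0:
            raise ValueError("fuzzy_exponent must be positive")
        for name in ("alpha_start", "alpha_end"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def replace(self, **kwargs) -> "DistillationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class NeutrosophicTriplet:
    """(truth, indeterminacy, falsity) decomposition of a teacher prediction."""

    truth: float
    indeterminacy: float
    falsity: float


@dataclass(frozen=True)
class LossBreakdown:
    """Terms of the combined student objective ``alpha*CE + (1-alpha)*NKD``."""

    ce_term: float
    distill_term: float
    alpha: float
    total: float
    sample_weights: np.ndarray | None = None


def _as_prob_matrix(p, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        raise ValueError(f"{name} is empty")
    if p.ndim == 1:
        p = p[None, :]
    if p.ndim != 2:
        raise ValueError(f"{name} must be a vector or a matrix of distributions")
    if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
        raise ValueError(f"{name} entries must lie in [0, 1]")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError(f"rows of {name} must sum to 1")
    return np.clip(p, 0.0, 1.0)


def soften(logits, temperature: float) -> np.ndarray:
    """Temperature-scaled softmax ``exp(z_i/T) / sum_j exp(z_j/T)``.

    Stable under large logits: a constant shift of all logits leaves the
    output unchanged (max subtraction).  Accepts a single logit vector or a
    batch (rows are samples); the output has the same leading shape.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    z = np.asarray(logits, dtype=np.float64)
    if z.size == 0:
        raise ValueError("logits are empty")
    if not np.all(np.isfinite(z)):
        raise ValueError("logits must be finite")
    squeeze = z.ndim == 1
    if squeeze:
        z = z[None, :]
    z = z / float(temperature)
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    return p[0] if squeeze else p


def kl_divergence(p_teacher, p_student, temperature: float = 1.0) -> float:
    """Temperature-scaled KL divergence ``T^2 * sum_i p_t[i] log(p_t[i]/p_s[i])``.

    Natural log; zero teacher entries contribute nothing; student entries are
    floored at 1e-12 before the division.
    """
    pt = _as_prob_matrix(p_teacher, "p_teacher")
    ps = _as_prob_matrix(p_student, "p_student")
    if pt.shape != ps.shape:
        raise ValueError("p_teacher and p_student must have the same shape")
    ps = np.maximum(ps, LOG_EPS)
    ratio = np.where(pt > 0, pt / ps, 1.0)
    per_row = np.where(pt > 0, pt * np.log(ratio), 0.0).sum(axis=1)
    return float(temperature) ** 2 * float(per_row.mean() if per_row.size > 1 else per_row[0])


def cross_entropy(p_student, label: int) -> float:
    """Hard-label cross-entropy ``-log p_hat_s[label]`` (temperature-1 probs)."""
    ps = _as_prob_matrix(p_student, "p_student")[0]
    label = int(label)
    if not 0 <= label < ps.shape[0]:
        raise ValueError(f"label {label} out of range for {ps.shape[0]} classes")
    return float(-np.log(max(ps[label], LOG_EPS)))


def neutrosophic_triplet(p_teacher, mode: str = "margin") -> NeutrosophicTriplet:
    """Decompose a teacher distribution into its (T, I, F) triplet.

    truth = max probability; falsity = 1 - truth; indeterminacy is
    ``1 - (p_(1) - p_(2))`` in margin mode (the two largest entries) or the
    entropy normalized by ``log C`` in entropy mode.
    """
    p = _as_prob_matrix(p_teacher, "p_teacher")[0]
    if p.shape[0] < 2:
        raise ValueError("need at least two classes")
    order = np.sort(p)[::-1]
    truth = float(order[0])
    if mode == "margin":
        indet = 1.0 - (order[0] - order[1])
    elif mode == "entropy":
        nz = p[p > 0]
        indet = float(-(nz * np.log(nz)).sum() / np.log(p.shape[0]))
    else:
        raise ValueError("mode must be 'margin' or 'entropy'")
    indet = float(min(max(indet, 0.0), 1.0))
    return NeutrosophicTriplet(truth=truth, indeterminacy=indet, falsity=1.0 - truth)


def distillation_weight(indeterminacy: float, config: DistillationConfig) -> float:
    """Sample weight ``clamp(sigmoid(k*(M - tau)), w_min, w_max)`` with ``M = 1 - I``.

    With weighting disabled (the no-weight ablation arm) the weight is 1.
    """
    if not 0.0 <= indeterminacy <= 1.0:
        raise ValueError("indeterminacy must lie in [0, 1]")
    if not config.weighting_enabled:
        return 1.0
    margin_conf = 1.0 - indeterminacy
    raw = 1.0 / (1.0 + np.exp(-config.steepness_k * (margin_conf - config.margin_threshold_tau)))
    return float(min(max(raw, config.weight_min), config.weight_max))


def nkd_loss(teacher_logits, student_logits, config: DistillationConfig):
    """Weighted distillation term ``(1/N) sum_i w_i KL(p_t^i || p_s^i)``.

    Both inputs are ``(N, C)`` logit batches.  Teacher and student logits are
    softened at the configured temperature, each sample's weight comes from
    the teacher triplet's indeterminacy, and the KL carries the usual ``T^2``
    factor so that with weighting disabled the term reduces exactly to the
    plain mean temperature-scaled KL of standard knowledge distillation.

    Returns ``(distill_term, sample_weights)``.
    """
    zt = np.atleast_2d(np.asarray(teacher_logits, dtype=np.float64))
    zs = np.atleast_2d(np.asarray(student_logits, dtype=np.float64))
    if zt.shape != zs.shape:
        raise ValueError("teacher and student logit batches must have identical shape")
    if zt.shape[0] < 1 or zt.shape[1] < 2:
        raise ValueError("need at least one sample and two classes")
    T = config.temperature
    pt = soften(zt, T)
    ps = np.maximum(soften(zs, T), LOG_EPS)
    kl_per = np.where(pt > 0, pt * np.log(np.where(pt > 0, pt, 1.0) / ps), 0.0).sum(axis=1)
    weights = np.array(
        [
            distillation_weight(
                neutrosophic_triplet(row, config.indeterminacy_mode).indeterminacy, config
            )
            for row in pt
        ]
    )
    distill = float(T * T * (weights * kl_per).mean())
    return distill, weights


def fuzzy_transform(p_teacher, exponent: float) -> np.ndarray:
    """Power-transform a distribution: ``p_i^g / sum_j p_j^g`` (renormalized).

    Exponents above one sharpen the distribution (dominant entries are
    emphasized); exponent one is the identity.
    """
    if exponent <= 0:
        raise ValueError("exponent must be positive")
    p = _as_prob_matrix(p_teacher, "p_teacher")
    powered = p**exponent
    denom = powered.sum(axis=1, keepdims=True)
    if np.any(denom <= 0):
        raise ValueError("power transform annihilated the distribution")
    out = powered / denom
    return out[0] if np.asarray(p_teacher).ndim == 1 else out


def alpha_at(epoch: int, total_epochs: int, config: DistillationConfig) -> float:
    """Cross-entropy mixing coefficient for ``epoch`` under linear decay.

    Interpolates alpha_start -> alpha_end across the run; constant at
    alpha_start when ``fixed_alpha`` is set (ablation) or for a 1-epoch run.
    """
    if total_epochs < 1:
        raise ValueError("total_epochs must be >= 1")
    if not 0 <= epoch < total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {total_epochs})")
    if config.fixed_alpha or total_epochs == 1:
        return config.alpha_start
    frac = epoch / (total_epochs - 1)
    return config.alpha_start + (config.alpha_end - config.alpha_start) * frac


def combined_loss(
    ce_term: float, distill_term: float, alpha: float, sample_weights=None
) -> LossBreakdown:
    """Full student objective ``alpha * L_CE + (1 - alpha) * L_NKD``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    total = alpha * ce_term + (1.0 - alpha) * distill_term
    return LossBreakdown(
        ce_term=float(ce_term),
        distill_term=float(distill_term),
        alpha=float(alpha),
        total=float(total),
        sample_weights=None if sample_weights is None else np.asarray(sample_weights),
    )
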