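"""Loss mathematics: closed-form examples, invariants and a loop-based oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neutrokd import nkd_core as core
from neutrokd.nkd_core import DistillationConfig

from conftest import random_distributions


# ---------------------------------------------------------------- scalar oracle
def oracle_soften(logits, T):
    vals = [math.exp((z - max(logits)) / T) for z in logits]
    s = sum(vals)
    return [v / s for v in vals]


def oracle_kl(pt, ps, T):
    total = 0.0
    for a, b in zip(pt, ps):
        if a > 0:
            total += a * math.log(a / max(b, 1e-12))
    return T * T * total


def oracle_triplet(p, mode):
    srt = sorted(p, reverse=True)
    truth = srt[0]
    if mode == "margin":
        indet = 1.0 - (srt[0] - srt[1])
    else:
        indet = -sum(x * math.log(x) for x in p if x > 0) / math.log(len(p))
    return truth, min(max(indet, 0.0), 1.0), 1.0 - truth


def oracle_weight(indet, cfg):
    if not cfg.weighting_enabled:
        return 1.0
    raw = 1.0 / (1.0 + math.exp(-cfg.steepness_k * ((1.0 - indet) - cfg.margin_threshold_tau)))
    return min(max(raw, cfg.weight_min), cfg.weight_max)


def oracle_nkd_loss(zt_rows, zs_rows, cfg):
    total = 0.0
    for zt, zs in zip(zt_rows, zs_rows):
        pt = oracle_soften(zt, cfg.temperature)
        ps = oracle_soften(zs, cfg.temperature)
        _, indet, _ = oracle_triplet(pt, cfg.indeterminacy_mode)
        total += oracle_weight(indet, cfg) * oracle_kl(pt, ps, cfg.temperature)
    return total / len(zt_rows)


# ------------------------------------------------------------ closed-form cases
@pytest.mark.parametrize(
    "logits,T,expected",
    [
        ([0.0, 0.0], 3.0, [0.5, 0.5]),
        ([2.0, 0.0], 4.0, [0.62245933, 0.37754067]),
    ],
)
def test_soften_examples(logits, T, expected):
    np.testing.assert_allclose(core.soften(logits, T), expected, atol=1e-6)


def test_soften_shift_invariance(rng):
    z = rng.normal(0, 3, 5)
    for c in (-100.0, 7.3, 1e6):
        np.testing.assert_allclose(core.soften(z + c, 2.5), core.soften(z, 2.5), atol=1e-6)


def test_soften_temperature_limits(rng):
    z = rng.normal(0, 2, 6)
    hot = core.soften(z, 100.0)
    assert np.abs(hot - 1 / 6).max() < 0.02
    cold = core.soften(z, 0.01)
    assert cold[np.argmax(z)] > 0.999


@pytest.mark.parametrize(
    "pt,ps,T,expected",
    [
        ([0.5, 0.5], [0.5, 0.5], 3.0, 0.0),
        ([0.5, 0.5], [0.25, 0.75], 1.0, 0.5 * math.log(2) + 0.5 * math.log(2 / 3)),
        ([1.0, 0.0], [0.5, 0.5], 2.0, 4 * math.log(2)),
    ],
)
def test_kl_examples(pt, ps, T, expected):
    assert core.kl_divergence(pt, ps, T) == pytest.approx(expected, abs=1e-6)


def test_kl_nonnegative_and_zero_iff_equal(rng):
    for _ in range(1000):
        c = rng.integers(2, 8)
        pt, ps = random_distributions(rng, 2, c)
        assert core.kl_divergence(pt, ps) >= 0.0
        assert core.kl_divergence(pt, pt) == pytest.approx(0.0, abs=1e-12)
    pt, ps = random_distributions(rng, 2, 5)
    if np.abs(pt - ps).max() > 1e-6:
        assert core.kl_divergence(pt, ps) > 0.0


@pytest.mark.parametrize(
    "probs,label,expected",
    [
        ([1.0, 0.0, 0.0], 0, 0.0),
        ([1 / 7] * 7, 3, math.log(7)),
        ([0.9, 0.1], 1, -math.log(0.1)),
    ],
)
def test_cross_entropy_examples(probs, label, expected):
    assert core.cross_entropy(probs, label) == pytest.approx(expected, abs=1e-6)


def test_cross_entropy_rejects_bad_label():
    with pytest.raises(ValueError):
        core.cross_entropy([0.5, 0.5], 2)


@pytest.mark.parametrize("mode", ["margin", "entropy"])
def test_triplet_onehot_and_uniform(mode):
    t = core.neutrosophic_triplet([1.0, 0.0, 0.0], mode)
    assert (t.truth, t.indeterminacy, t.falsity) == (1.0, 0.0, 0.0)
    u = core.neutrosophic_triplet([1 / 3] * 3, mode)
    assert u.indeterminacy == pytest.approx(1.0, abs=1e-9)


def test_triplet_worked_example():
    t = core.neutrosophic_triplet([0.7, 0.2, 0.1], "margin")
    assert t.indeterminacy == pytest.approx(0.5, abs=1e-9)
    assert t.truth + t.falsity == 1.0
    e = core.neutrosophic_triplet([0.7, 0.2, 0.1], "entropy")
    assert e.indeterminacy == pytest.approx(0.801819 / math.log(3), abs=1e-4)


def test_triplet_consistency_random(rng):
    for _ in range(1000):
        c = rng.integers(2, 11)
        (p,) = random_distributions(rng, 1, c)
        for mode in ("margin", "entropy"):
            t = core.neutrosophic_triplet(p, mode)
            assert t.truth + t.falsity == 1.0  # exact by construction
            assert 0.0 <= t.indeterminacy <= 1.0


def test_weight_examples():
    cfg = DistillationConfig()
    tau = cfg.margin_threshold_tau
    assert core.distillation_weight(1 - tau, cfg) == pytest.approx(0.5, abs=1e-9)
    assert core.distillation_weight(0.0, cfg) == pytest.approx(1 / (1 + math.exp(-6.8)), abs=1e-6)
    hard = DistillationConfig(steepness_k=20.0, margin_threshold_tau=0.5, weight_min=0.10)
    assert core.distillation_weight(1.0, hard) == pytest.approx(0.10, abs=1e-12)


def test_weight_monotone_and_bounded():
    cfg = DistillationConfig()
    grid = np.linspace(0.0, 1.0, 101)
    w = np.array([core.distillation_weight(i, cfg) for i in grid])
    assert np.all(np.diff(w) <= 1e-12)  # nonincreasing in indeterminacy
    unclamped = (w > cfg.weight_min + 1e-9) & (w < cfg.weight_max - 1e-9)
    assert np.all(np.diff(w)[unclamped[:-1] & unclamped[1:]] < 0)
    assert np.all((w >= cfg.weight_min) & (w <= cfg.weight_max))


def test_weight_disabled_returns_one():
    cfg = DistillationConfig(weighting_enabled=False)
    assert core.distillation_weight(1.0, cfg) == 1.0


def test_nkd_loss_zero_when_identical(rng):
    z = rng.normal(0, 2, (4, 5))
    distill, w = core.nkd_loss(z, z, DistillationConfig())
    assert distill == pytest.approx(0.0, abs=1e-9)
    assert w.shape == (4,)


def test_nkd_loss_reduces_to_standard_kd(rng):
    cfg = DistillationConfig(weighting_enabled=False)
    zt = rng.normal(0, 2, (8, 4))
    zs = rng.normal(0, 2, (8, 4))
    distill, w = core.nkd_loss(zt, zs, cfg)
    assert np.all(w == 1.0)
    T = cfg.temperature
    plain = np.mean(
        [core.kl_divergence(core.soften(a, T), core.soften(b, T), T) for a, b in zip(zt, zs)]
    )
    assert distill == pytest.approx(plain, abs=1e-6)


def test_nkd_loss_worked_example():
    # teacher probs [[0.5,0.5],[~1,0]] and student [[0.25,0.75],[0.5,0.5]] at T=1
    cfg = DistillationConfig(temperature=1.0, weighting_enabled=False)
    zt = np.log(np.array([[0.5, 0.5], [1 - 1e-12, 1e-12]]))
    zs = np.log(np.array([[0.25, 0.75], [0.5, 0.5]]))
    distill, _ = core.nkd_loss(zt, zs, cfg)
    assert distill == pytest.approx((0.143841 + math.log(2)) / 2, abs=1e-4)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    st.integers(2, 3),
    st.integers(1, 4),
    st.integers(0, 10_000),
    st.sampled_from(["margin", "entropy"]),
    st.booleans(),
)
def test_nkd_loss_matches_scalar_oracle(c, n, seed, mode, weighted):
    """Vectorized batch loss equals a loop-based scalar reimplementation."""
    rng = np.random.default_rng(seed)
    cfg = DistillationConfig(indeterminacy_mode=mode, weighting_enabled=weighted)
    zt = rng.normal(0, 3, (n, c))
    zs = rng.normal(0, 3, (n, c))
    distill, _ = core.nkd_loss(zt, zs, cfg)
    assert distill == pytest.approx(oracle_nkd_loss(zt.tolist(), zs.tolist(), cfg), abs=1e-6)


@pytest.mark.parametrize(
    "p,g,expected",
    [
        ([0.2, 0.3, 0.5], 1.0, [0.2, 0.3, 0.5]),
        ([0.25] * 4, 3.0, [0.25] * 4),
        ([0.7, 0.2, 0.1], 2.0, [0.49 / 0.54, 0.04 / 0.54, 0.01 / 0.54]),
    ],
)
def test_fuzzy_examples(p, g, expected):
    np.testing.assert_allclose(core.fuzzy_transform(p, g), expected, atol=1e-6)


def test_fuzzy_sharpening_reduces_entropy(rng):
    def entropy(p):
        nz = p[p > 0]
        return float(-(nz * np.log(nz)).sum())

    for _ in range(1000):
        c = rng.integers(2, 8)
        (p,) = random_distributions(rng, 1, c)
        q = core.fuzzy_transform(p, 2.0)
        assert entropy(q) <= entropy(p) + 1e-12
        assert q.max() >= p.max() - 1e-12


@pytest.mark.parametrize(
    "epoch,total,expected",
    [(0, 40, 0.90), (39, 40, 0.70), (13, 40, 0.90 - 0.20 * 13 / 39)],
)
def test_alpha_schedule(epoch, total, expected):
    assert core.alpha_at(epoch, total, DistillationConfig()) == pytest.approx(expected, abs=1e-4)


def test_alpha_fixed_and_edges():
    cfg = DistillationConfig(fixed_alpha=True)
    assert all(core.alpha_at(e, 40, cfg) == 0.90 for e in (0, 20, 39))
    assert core.alpha_at(0, 1, DistillationConfig()) == 0.90
    with pytest.raises(ValueError):
        core.alpha_at(40, 40, DistillationConfig())


@pytest.mark.parametrize(
    "ce,kd,alpha,expected", [(2.0, 0.5, 0.8, 1.7), (3.0, 1.0, 1.0, 3.0), (3.0, 1.0, 0.0, 1.0)]
)
def test_combined_loss(ce, kd, alpha, expected):
    b = core.combined_loss(ce, kd, alpha)
    assert b.total == pytest.approx(expected, abs=1e-9)
    assert b.total == pytest.approx(b.alpha * b.ce_term + (1 - b.alpha) * b.distill_term, abs=1e-6)


def test_config_validation():
    with pytest.raises(ValueError):
        DistillationConfig(temperature=0.0)
    with pytest.raises(ValueError):
        DistillationConfig(weight_min=0.9, weight_max=0.5)
    with pytest.raises(ValueError):
        core.soften([1.0, 2.0], -1.0)
    with pytest.raises(ValueError):
        core.kl_divergence([0.5, 0.5], [0.2, 0.3, 0.5])
    with pytest.raises(ValueError):
        core.neutrosophic_triplet([1.0])
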