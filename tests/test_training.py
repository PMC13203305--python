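"""Trainer contracts: loss equivalences, frozen teacher, determinism."""

import numpy as np
import pytest

from neutrokd import nkd_core as core
from neutrokd.models import BackboneSpec, build, parameter_checksum
from neutrokd.training import TrainConfig, student_batch_loss, train_student, train_teacher


@pytest.fixture(scope="module")
def batch():
    rng = np.random.default_rng(0)
    zt = rng.normal(0, 3, (8, 5))
    zs = rng.normal(0, 3, (8, 5))
    y = rng.integers(0, 5, 8)
    return zt, zs, y


def test_nkd_batch_matches_core(batch):
    """The trainer's vectorized distillation term equals the reference loss."""
    zt, zs, y = batch
    for mode_cfg in (
        core.DistillationConfig(),
        core.DistillationConfig(indeterminacy_mode="entropy"),
        core.DistillationConfig(weighting_enabled=False),
    ):
        breakdown, _, weights = student_batch_loss(zt, zs, y, "nkd", mode_cfg, 0.8)
        ref_distill, ref_w = core.nkd_loss(zt, zs, mode_cfg)
        assert breakdown.distill_term == pytest.approx(ref_distill, abs=1e-6)
        np.testing.assert_allclose(weights, ref_w, atol=1e-9)


def test_no_weight_fixed_alpha_equals_standard_kd(batch):
    """Weighting off + fixed alpha: the NKD arm is exactly standard KD."""
    zt, zs, y = batch
    dcfg = core.DistillationConfig(weighting_enabled=False, fixed_alpha=True)
    nkd_b, nkd_g, _ = student_batch_loss(zt, zs, y, "nkd", dcfg, 0.9)
    std_b, std_g, _ = student_batch_loss(zt, zs, y, "standard_kd", dcfg, 0.9)
    assert nkd_b.total == pytest.approx(std_b.total, abs=1e-6)
    np.testing.assert_allclose(nkd_g, std_g, atol=1e-9)


def test_identical_logits_zero_distill(batch):
    zt, _, y = batch
    b, _, _ = student_batch_loss(zt, zt.copy(), y, "nkd", core.DistillationConfig(), 0.5)
    assert b.distill_term == pytest.approx(0.0, abs=1e-9)


def test_alpha_one_reduces_to_ce(batch):
    zt, zs, y = batch
    b, g, _ = student_batch_loss(zt, zs, y, "nkd", core.DistillationConfig(), 1.0)
    ce_b, ce_g, _ = student_batch_loss(None, zs, y, "ce_only", core.DistillationConfig(), 1.0)
    assert b.total == pytest.approx(ce_b.ce_term, abs=1e-9)
    np.testing.assert_allclose(g, ce_g, atol=1e-9)


def test_fuzzy_mode_uses_power_transformed_targets(batch):
    zt, zs, y = batch
    dcfg = core.DistillationConfig(temperature=1.0, fuzzy_exponent=2.0)
    fuzzy_b, _, _ = student_batch_loss(zt, zs, y, "fuzzy_kd", dcfg, 0.5)
    pt = core.soften(zt, 1.0)
    ps = core.soften(zs, 1.0)
    ref = np.mean(
        [core.kl_divergence(core.fuzzy_transform(a, 2.0), b) for a, b in zip(pt, ps)]
    )
    assert fuzzy_b.distill_term == pytest.approx(ref, abs=1e-6)


def test_batch_shape_mismatch_rejected(batch):
    zt, zs, y = batch
    with pytest.raises(ValueError):
        student_batch_loss(zt[:, :4], zs, y, "nkd", core.DistillationConfig(), 0.5)
    with pytest.raises(ValueError):
        student_batch_loss(None, zs, y, "nkd", core.DistillationConfig(), 0.5)


def test_confident_teacher_gives_full_weights(batch):
    _, zs, y = batch
    zt = np.zeros_like(zs)
    zt[np.arange(8), y] = 60.0  # one-hot-like even after T=4 softening
    _, _, weights = student_batch_loss(zt, zs, y, "nkd", core.DistillationConfig(), 0.8)
    assert np.all(weights > 0.99)


# --------------------------------------------------------- end-to-end (small)
@pytest.fixture(scope="module")
def small_run(small_split_module, pre64_module):
    train, val = small_split_module
    cfg = TrainConfig(epochs=4, batch_size=8, learning_rate=3e-3, seed=5)
    teacher, hist = train_teacher(
        train, val, BackboneSpec("tiny_cnn_large", 7, role="teacher", seed=1), cfg, pre64_module
    )
    return train, val, teacher, hist, cfg


@pytest.fixture(scope="module")
def small_split_module():
    from neutrokd.synthetic import SyntheticSpec, generate, stratified_split

    ds = generate(SyntheticSpec(n_classes=7, images_per_class=6, image_size=64, seed=21))
    return stratified_split(ds, 0.25, seed=2)


@pytest.fixture(scope="module")
def pre64_module():
    from neutrokd.preprocessing import PreprocessConfig

    return PreprocessConfig(target_size=64, augment=False)


def test_teacher_loss_decreases(small_run):
    _, _, _, hist, _ = small_run
    assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]
    assert np.isfinite(hist["train_loss"]).all()


def test_teacher_frozen_during_student_training(small_run, pre64_module):
    train, val, teacher, _, cfg = small_run
    before = parameter_checksum(teacher)
    train_student(
        train,
        val,
        teacher,
        BackboneSpec("tiny_cnn_small", 7, seed=2),
        core.DistillationConfig(),
        cfg,
        pre64_module,
    )
    assert parameter_checksum(teacher) == before


def test_ce_only_student_logs_zero_distill(small_run, pre64_module):
    train, val, teacher, _, _ = small_run
    cfg = TrainConfig(epochs=2, batch_size=8, seed=3, student_mode="ce_only")
    _, hist = train_student(
        train, val, None, BackboneSpec("tiny_cnn_small", 7, seed=2),
        core.DistillationConfig(), cfg, pre64_module,
    )
    assert (hist["distill_term"] == 0.0).all()
    assert (hist["alpha"] == 1.0).all()


def test_zero_learning_rate_leaves_parameters_unchanged(small_run, pre64_module):
    train, val, _, _, _ = small_run
    spec = BackboneSpec("tiny_cnn_small", 7, seed=9)
    cfg = TrainConfig(epochs=2, batch_size=8, learning_rate=0.0, seed=1, student_mode="ce_only")
    net, hist = train_student(
        train, val, None, spec, core.DistillationConfig(), cfg, pre64_module
    )
    fresh = build(spec)
    for p, q in zip(net.params(), fresh.params()):
        np.testing.assert_array_equal(p.data, q.data)
    # loss varies only through batch-norm batch statistics (shuffled batch
    # composition), never through parameter movement
    assert np.ptp(hist["train_loss"].to_numpy()) < 0.01


def test_training_deterministic_under_seed(small_split_module, pre64_module):
    train, val = small_split_module
    cfg = TrainConfig(epochs=2, batch_size=8, learning_rate=3e-3, seed=17)
    spec = BackboneSpec("tiny_cnn_small", 7, seed=4)
    a, _ = train_teacher(train, val, spec, cfg, pre64_module)
    b, _ = train_teacher(train, val, spec, cfg, pre64_module)
    for p, q in zip(a.params(), b.params()):
        np.testing.assert_array_equal(p.data, q.data)


def test_empty_split_rejected(small_split_module, pre64_module):
    train, _ = small_split_module
    empty = train.subset(np.array([], dtype=int))
    with pytest.raises(ValueError):
        train_teacher(
            train, empty, BackboneSpec("tiny_cnn_small", 7, seed=0),
            TrainConfig(epochs=1), pre64_module,
        )
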