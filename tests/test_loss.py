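"""Marginal focal dice loss: scalar oracle, limits, equivalences, gradients."""

import dataclasses
import math

import numpy as np
import pytest

from mfpep.autodiff import Tensor, finite_difference_gradient
from mfpep.loss import (
    ClassStats,
    LossConfigError,
    MFDLConfig,
    compute_class_stats,
    mfdl_loss,
    reference_losses,
)

EPS = 1e-8


def mfdl_scalar_reference(logits, labels, stats, cfg):
    """Independent per-entry/per-class loop implementing the loss from its
    defining formulas; deliberately unvectorized."""
    N, C = labels.shape
    per_class = []
    for c in range(C):
        num_p = den_p = num_n = den_n = 0.0
        n_pos = n_neg = 0
        for i in range(N):
            y = labels[i, c]
            m = stats.margin_pos[c] if y == 1 else stats.margin_neg[c]
            p = 1.0 / (1.0 + math.exp(-(logits[i, c] - m)))
            if y == 1:
                pp = min(p + cfg.clip_pos, 1.0) * p
                num_p += pp
                den_p += pp**cfg.p_pos + 1.0
                n_pos += 1
            else:
                q = 1.0 - p
                pn = min(q + cfg.clip_neg, 1.0) * q
                num_n += pn
                den_n += pn**cfg.p_neg + 1.0
                n_neg += 1
        l_pos = 1.0 - 2.0 * num_p / (den_p + EPS) if n_pos else 0.0
        l_neg = 1.0 - 2.0 * num_n / (den_n + EPS) if n_neg else 0.0
        per_class.append(stats.w_class[c] * (cfg.alpha * l_pos + (1 - cfg.alpha) * l_neg))
    if cfg.reduction == "mean":
        return float(np.mean(per_class))
    if cfg.reduction == "sum":
        return float(np.sum(per_class))
    return np.array(per_class)


def _random_instance(rng, n_max=8, c_max=5):
    n = int(rng.integers(1, n_max + 1))
    c = int(rng.integers(1, c_max + 1))
    logits = rng.normal(scale=2.0, size=(n, c))
    labels = (rng.random((n, c)) < 0.4).astype(int)
    if labels.sum() == 0:
        labels[rng.integers(n), rng.integers(c)] = 1
    return logits, labels


def _random_config(rng):
    return MFDLConfig(
        alpha=float(rng.uniform(0.1, 0.9)),
        m_max=float(rng.uniform(0, 1)),
        p_pos=float(rng.choice([1.0, 2.0, 3.0])),
        p_neg=float(rng.choice([1.0, 2.0, 3.0])),
        clip_pos=float(rng.uniform(0, 0.3)),
        clip_neg=float(rng.uniform(0, 0.3)),
        use_class_weights=bool(rng.random() < 0.5),
        reduction="mean",
    )


class TestClassStats:
    def test_uniform_weights_when_disabled(self):
        Y = np.array([[1, 0], [0, 1], [1, 1]])
        st = compute_class_stats(Y, MFDLConfig(use_class_weights=False))
        assert np.allclose(st.w_class, 1.0)

    def test_inverse_sqrt_scaling(self):
        Y = np.zeros((101, 2), dtype=int)
        Y[:100, 0] = 1
        Y[:1, 1] = 1
        st = compute_class_stats(Y, MFDLConfig(m_max=0.5))
        assert np.allclose(st.w_class, [0.05, 0.5])

    def test_equal_counts_equal_weights_and_margins(self):
        Y = np.zeros((10, 3), dtype=int)
        Y[:4] = 1
        st = compute_class_stats(Y, MFDLConfig(m_max=0.5))
        assert np.allclose(st.w_class, st.w_class[0])
        assert np.allclose(st.margin_pos, st.margin_pos[0])

    def test_minority_side_gets_full_margin(self):
        Y = np.zeros((100, 1), dtype=int)
        Y[:10, 0] = 1  # positives are the minority
        st = compute_class_stats(Y, MFDLConfig(m_max=0.5))
        assert st.margin_pos[0] == pytest.approx(0.5)
        assert st.margin_neg[0] == pytest.approx(0.5 * np.sqrt(10 / 90))
        assert st.margin_neg[0] < st.margin_pos[0]

    def test_counts_partition_n(self):
        Y = (np.random.default_rng(0).random((30, 4)) < 0.3).astype(int)
        Y[0, 0] = 1
        st = compute_class_stats(Y, MFDLConfig())
        assert np.array_equal(st.n_pos + st.n_neg, np.full(4, 30.0))

    def test_empty_class_warns(self):
        Y = np.array([[1, 0], [1, 0]])
        with pytest.warns(UserWarning, match="no positives"):
            compute_class_stats(Y, MFDLConfig())


class TestMFDLOracle:
    def test_hand_worked_example(self):
        cfg = MFDLConfig(alpha=0.5, m_max=0.0, p_pos=1, p_neg=1,
                         clip_pos=0, clip_neg=0, use_class_weights=False)
        Y = np.array([[1, 0]])
        st = compute_class_stats(Y, cfg)
        val = float(mfdl_loss(np.zeros((1, 2)), Y, st, cfg).numpy())
        assert val == pytest.approx(0.3, abs=1e-6)

    def test_vectorized_matches_scalar_loop_on_random_instances(self):
        rng = np.random.default_rng(1234)
        for _ in range(100):
            logits, labels = _random_instance(rng)
            cfg = _random_config(rng)
            st = compute_class_stats(labels, cfg)
            vec = float(mfdl_loss(logits, labels, st, cfg).numpy())
            ref = mfdl_scalar_reference(logits, labels, st, cfg)
            assert abs(vec - ref) < 1e-6

    def test_reduction_modes_are_consistent(self):
        rng = np.random.default_rng(5)
        logits, labels = _random_instance(rng, n_max=6, c_max=4)
        C = labels.shape[1]
        base = MFDLConfig()
        st = compute_class_stats(labels, base)
        mean = float(mfdl_loss(logits, labels, st, base).numpy())
        s = float(mfdl_loss(logits, labels, st,
                            dataclasses.replace(base, reduction="sum")).numpy())
        none = mfdl_loss(logits, labels, st,
                         dataclasses.replace(base, reduction="none")).numpy()
        assert s == pytest.approx(C * mean, rel=1e-12)
        assert none.shape == (C,)
        assert float(none.mean()) == pytest.approx(mean, rel=1e-12)

    def test_non_binary_labels_rejected(self):
        cfg = MFDLConfig()
        st = compute_class_stats(np.array([[1, 0]]), cfg)
        with pytest.raises(LossConfigError):
            mfdl_loss(np.zeros((1, 2)), np.array([[0.5, 0]]), st, cfg)

    def test_unknown_reduction_rejected(self):
        with pytest.raises(LossConfigError):
            MFDLConfig(reduction="median")


class TestMFDLLimits:
    def test_perfect_prediction_drives_loss_to_zero(self):
        cfg = MFDLConfig(m_max=0.0, clip_pos=0, clip_neg=0, p_pos=1, p_neg=1,
                         use_class_weights=False)
        Y = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 0]])
        st = compute_class_stats(Y, cfg)
        logits = np.where(Y == 1, 50.0, -50.0)
        val = float(mfdl_loss(logits, Y, st, cfg).numpy())
        assert val < 1e-6

    def test_inverted_prediction_drives_components_to_one(self):
        cfg = MFDLConfig(m_max=0.0, clip_pos=0, clip_neg=0, p_pos=1, p_neg=1,
                         use_class_weights=False)
        Y = np.array([[1, 0], [0, 1], [1, 1], [0, 0]])
        st = compute_class_stats(Y, cfg)
        logits = np.where(Y == 1, -50.0, 50.0)
        _, comp = mfdl_loss(logits, Y, st, cfg, return_components=True)
        assert np.allclose(comp["l_pos"], 1.0, atol=1e-6)
        assert np.allclose(comp["l_neg"], 1.0, atol=1e-6)

    def test_margin_free_unweighted_equals_mlfdl_comparator(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            logits, labels = _random_instance(rng)
            base = _random_config(rng)
            cfg = dataclasses.replace(base, m_max=0.0, use_class_weights=False)
            st = compute_class_stats(labels, cfg)
            mine = float(mfdl_loss(logits, labels, st, cfg).numpy())
            comp = float(reference_losses(logits, labels, "mlfdl", config=base).numpy())
            assert mine == pytest.approx(comp, abs=1e-12)

    def test_component_bound_and_weighting(self):
        rng = np.random.default_rng(9)
        logits, labels = _random_instance(rng)
        cfg = MFDLConfig(p_pos=1, p_neg=1, clip_pos=0, clip_neg=0)
        st = compute_class_stats(labels, cfg)
        _, comp = mfdl_loss(logits, labels, st, cfg, return_components=True)
        assert (comp["l_pos"] >= -1e-12).all() and (comp["l_pos"] <= 1 + 1e-12).all()
        assert (comp["l_neg"] >= -1e-12).all() and (comp["l_neg"] <= 1 + 1e-12).all()
        total = float(mfdl_loss(logits, labels, st,
                                dataclasses.replace(cfg, reduction="none")).numpy().max())
        assert total <= st.w_class.max() + 1e-12

    def test_increasing_positive_logit_never_increases_loss(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            logits, labels = _random_instance(rng)
            cfg = _random_config(rng)
            st = compute_class_stats(labels, cfg)
            pos = np.argwhere(labels == 1)
            i, c = pos[rng.integers(len(pos))]
            lo = float(mfdl_loss(logits, labels, st, cfg).numpy())
            bumped = logits.copy()
            bumped[i, c] += 1.0
            hi = float(mfdl_loss(bumped, labels, st, cfg).numpy())
            assert hi <= lo + 1e-10


class TestMFDLGradient:
    def test_matches_finite_differences_on_micro_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            logits, labels = _random_instance(rng, n_max=4, c_max=3)
            cfg = _random_config(rng)
            st = compute_class_stats(labels, cfg)
            z = Tensor(logits.copy(), requires_grad=True)
            mfdl_loss(z, labels, st, cfg).backward()
            num = finite_difference_gradient(
                lambda a: float(mfdl_loss(a, labels, st, cfg).numpy()), logits.copy()
            )
            assert np.allclose(z.grad, num, atol=1e-4)


class TestReferenceLosses:
    def test_bce_at_logit_zero_is_ln2(self):
        val = float(reference_losses(np.array([[0.0]]), np.array([[1]]), "bce").numpy())
        assert val == pytest.approx(math.log(2), abs=1e-9)

    def test_bce_matches_closed_form(self):
        rng = np.random.default_rng(6)
        z = rng.normal(size=(4, 3))
        y = (rng.random((4, 3)) < 0.5).astype(float)
        p = 1 / (1 + np.exp(-z))
        expected = float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))
        got = float(reference_losses(z, y, "bce").numpy())
        assert got == pytest.approx(expected, rel=1e-9)

    def test_focal_with_zero_exponent_reduces_to_bce(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=(5, 4))
        y = (rng.random((5, 4)) < 0.5).astype(float)
        f = float(reference_losses(z, y, "focal", focal_gamma=0.0).numpy())
        b = float(reference_losses(z, y, "bce").numpy())
        assert f == pytest.approx(b, rel=1e-6)

    def test_ldam_is_bce_on_margin_adjusted_logits(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=(6, 2))
        y = (rng.random((6, 2)) < 0.5).astype(int)
        y[0] = 1
        cfg = MFDLConfig(m_max=0.4)
        st = compute_class_stats(y, cfg)
        ldam = float(reference_losses(z, y, "ldam_margin", stats=st, config=cfg).numpy())
        m = np.where(y == 1, st.margin_pos, st.margin_neg)
        bce = float(reference_losses(z - m, y, "bce").numpy())
        assert ldam == pytest.approx(bce, rel=1e-9)

    def test_asymmetric_loss_is_finite_and_positive(self):
        rng = np.random.default_rng(9)
        z = rng.normal(size=(6, 3))
        y = (rng.random((6, 3)) < 0.5).astype(float)
        val = float(reference_losses(z, y, "asymmetric").numpy())
        assert np.isfinite(val) and val > 0

    def test_unknown_variant_rejected(self):
        with pytest.raises(LossConfigError):
            reference_losses(np.zeros((1, 1)), np.ones((1, 1)), "hinge")
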