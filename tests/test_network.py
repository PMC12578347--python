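"""Model construction, forward contracts, masking, graph stream, ablation."""

import dataclasses

import numpy as np
import pytest

from mfpep.encoders import build_chain_graph
from mfpep.network import (
    BuildError,
    InferenceError,
    MFTPModel,
    ModelConfig,
    STREAMS,
    predict_labels,
)
from mfpep.sequence_io import PeptideRecord, tokenize
from mfpep.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture(scope="module")
def micro_model():
    cfg = ModelConfig(
        d_model=8, attn_heads=2, lstm_hidden=4, conv_kernels=(3,),
        conv_channels=4, ffn_dim=8, gat_heads=2, dropout=0.0,
        n_classes=3, max_len=12, seed=0,
    )
    return MFTPModel(cfg)


@pytest.fixture(scope="module")
def micro_records():
    recs, _ = generate_dataset(
        SyntheticConfig(n_sequences=6, n_classes=3, length_range=(5, 10), seed=3)
    )
    return recs


class TestBuild:
    def test_same_config_and_seed_give_identical_parameters(self, micro_model):
        other = MFTPModel(micro_model.config)
        for (ka, va), (kb, vb) in zip(
            micro_model.params.items(), other.params.items()
        ):
            assert ka == kb
            assert np.array_equal(va.data, vb.data)

    def test_classifier_width_follows_n_classes(self):
        m = MFTPModel(ModelConfig(d_model=8, attn_heads=2, lstm_hidden=4,
                                  conv_kernels=(3,), conv_channels=4, ffn_dim=8,
                                  n_classes=21, max_len=10, seed=1))
        assert m.params["clf.W2"].shape[1] == 21

    def test_empty_conv_kernels_rejected(self):
        with pytest.raises(BuildError):
            ModelConfig(conv_kernels=())

    def test_unknown_ablation_target_rejected(self):
        with pytest.raises(BuildError):
            ModelConfig(ablate_modules=frozenset({"transformer"}))

    def test_parameter_count_reported(self, micro_model):
        assert micro_model.n_parameters() > 0


class TestForward:
    def test_logit_shape(self, micro_model, micro_records):
        batch = micro_model.encode_records(micro_records)
        logits = micro_model.forward(batch)
        assert logits.shape == (len(micro_records), 3)
        assert np.isfinite(logits.numpy()).all()

    def test_batch_permutation_permutes_logits(self, micro_model, micro_records):
        batch = micro_model.encode_records(micro_records)
        logits = micro_model.forward(batch).numpy()
        perm = [3, 0, 5, 1, 4, 2]
        batch_p = micro_model.encode_records([micro_records[i] for i in perm])
        logits_p = micro_model.forward(batch_p).numpy()
        assert np.allclose(logits_p, logits[perm], atol=1e-10)

    def test_eval_forward_deterministic(self, micro_model, micro_records):
        batch = micro_model.encode_records(micro_records)
        a = micro_model.forward(batch).numpy()
        b = micro_model.forward(batch).numpy()
        assert np.array_equal(a, b)

    def test_masked_positions_do_not_influence_logits(self, micro_model, micro_records):
        batch = micro_model.encode_records(micro_records)
        base = micro_model.forward(batch).numpy()
        rng = np.random.default_rng(0)
        pad = batch.mask == 0
        tampered = dataclasses.replace(
            batch,
            tokens=np.where(pad, rng.integers(1, 21, batch.tokens.shape), batch.tokens),
            bio={
                k: np.where(pad[..., None], rng.normal(size=v.shape) * 10, v)
                for k, v in batch.bio.items()
            },
        )
        out = micro_model.forward(tampered).numpy()
        assert np.abs(out - base).max() < 1e-6

    def test_zeroing_a_stream_changes_logits_without_errors(self, micro_records):
        base_cfg = ModelConfig(d_model=8, attn_heads=2, lstm_hidden=4,
                               conv_kernels=(3,), conv_channels=4, ffn_dim=8,
                               dropout=0.0, n_classes=3, max_len=12, seed=0)
        full = MFTPModel(base_cfg)
        ablated = MFTPModel(dataclasses.replace(base_cfg, ablate_streams=frozenset({"aac"})))
        ablated.params.load_state_dict(full.params.state_dict())
        batch = full.encode_records(micro_records)
        a = full.forward(batch).numpy()
        b = ablated.forward(batch).numpy()
        assert a.shape == b.shape
        assert np.isfinite(b).all()
        assert not np.allclose(a, b)

    def test_end_to_end_gradients_match_finite_differences(self, micro_records):
        from mfpep.loss import MFDLConfig, compute_class_stats, mfdl_loss
        from mfpep.sequence_io import LabelSpace

        cfg = ModelConfig(d_model=8, attn_heads=2, lstm_hidden=4,
                          conv_kernels=(3,), conv_channels=4, ffn_dim=8,
                          dropout=0.0, n_classes=3, max_len=12, seed=0)
        model = MFTPModel(cfg)
        recs = micro_records[:2]
        batch = model.encode_records(recs)
        names = sorted({l for r in micro_records for l in r.labels})[:3]
        names += [f"u{i}" for i in range(3 - len(names))]
        space = LabelSpace(tuple(names))
        Y = np.maximum(space.to_matrix(recs), np.eye(2, 3, dtype=np.int8))
        lcfg = MFDLConfig()
        stats = compute_class_stats(Y, lcfg)

        def loss_value():
            return mfdl_loss(model.forward(batch), Y, stats, lcfg)

        loss_value().backward()
        rng = np.random.default_rng(1)
        for name in ("embedding.W", "gates.G", "attn.Wq", "gat.h0.W",
                     "fuzz.pc6.c", "lstm0.fw.Wx", "conv3.W", "ffn.W1", "clf.W2"):
            p = model.params[name]
            ana = p.grad
            flat = p.data.reshape(-1)
            for i in rng.choice(flat.size, size=3, replace=False):
                orig = flat[i]
                eps = 1e-5
                flat[i] = orig + eps
                lp = float(loss_value().numpy())
                flat[i] = orig - eps
                lm = float(loss_value().numpy())
                flat[i] = orig
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - ana.reshape(-1)[i]) < 1e-3, name


class TestGraphStream:
    def test_attention_coefficients_normalize(self, micro_model):
        g = build_chain_graph(tokenize("ACDEF", max_len=12))
        feats = np.random.default_rng(0).normal(size=(5, 8))
        out, coeffs = micro_model.graph_stream(g, feats, return_attention=True)
        assert out.shape == (12, 8)
        assert (out[5:] == 0).all()  # re-padded
        for alpha in coeffs:  # (L, 3) per head
            sums = alpha[:5].sum(axis=1)
            assert np.allclose(sums, 1.0, atol=1e-8)

    def test_single_node_depends_only_on_own_features(self, micro_model):
        g = build_chain_graph(tokenize("A", max_len=12))
        rng = np.random.default_rng(1)
        f1 = rng.normal(size=(1, 8))
        out1 = micro_model.graph_stream(g, f1)
        out2 = micro_model.graph_stream(g, f1.copy())
        assert np.allclose(out1, out2)
        assert not np.allclose(out1[0], 0)

    def test_identical_features_give_symmetric_attention(self, micro_model):
        g = build_chain_graph(tokenize("AAA", max_len=12))
        feats = np.tile(np.random.default_rng(2).normal(size=(1, 8)), (3, 1))
        _, coeffs = micro_model.graph_stream(g, feats, return_attention=True)
        for alpha in coeffs:
            # middle node of a homogeneous path attends equally left/right
            assert alpha[1, 0] == pytest.approx(alpha[1, 2], abs=1e-10)
            # end nodes mirror one another
            assert alpha[0, 1] == pytest.approx(alpha[2, 1], abs=1e-10)

    def test_empty_graph_rejected(self, micro_model):
        from mfpep.encoders import ChainGraph

        with pytest.raises(InferenceError):
            micro_model.graph_stream(ChainGraph(0, ()), np.zeros((0, 8)))


class TestPredictLabels:
    def test_strict_sign_rule_at_default_threshold(self):
        out = predict_labels(np.array([[2.0, -1.0, 0.0]]))
        assert out == [{0}]

    def test_all_negative_infinite_logits_give_empty_set(self):
        out = predict_labels(np.array([[-np.inf, -np.inf]]))
        assert out == [set()]

    def test_high_threshold_excludes_moderate_logit(self):
        # sigmoid(2.0) ~ 0.881 < 0.9
        assert predict_labels(np.array([[2.0]]), threshold=0.9) == [set()]
        assert predict_labels(np.array([[2.3]]), threshold=0.9) == [{0}]

    def test_names_are_applied(self):
        out = predict_labels(np.array([[1.0, -1.0]]), names=("AMP", "ACP"))
        assert out == [{"AMP"}]

    def test_threshold_bounds(self):
        with pytest.raises(InferenceError):
            predict_labels(np.zeros((1, 2)), threshold=1.0)


def test_checkpoint_round_trip(tmp_path, micro_model, micro_records):
    path = tmp_path / "model.npz"
    micro_model.save(path)
    loaded = MFTPModel.load(path)
    batch = micro_model.encode_records(micro_records)
    assert np.allclose(
        micro_model.forward(batch).numpy(), loaded.forward(batch).numpy()
    )
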