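import numpy as np
import pytest

import readernet as rn
from readernet import nn
from readernet.model import (
    ActivationKind,
    ModelSpec,
    apply_max_norm,
    build_model,
    forward_baseline,
    forward_reader,
    load_model,
    save_model,
)


def small_spec(**over):
    kw = dict(
        backbone="TOY_CNN", n_readers=6, reader_emb_dim=8, toy_channels=(4, 6, 8),
        dropout=0.0, use_reader_embeddings=True,
    )
    kw.update(over)
    return ModelSpec(**kw)


def make_ones_modulation(model):
    """Force the reader branch to the all-ones modulation point."""
    model.projection.params["W"][...] = 0.0
    model.projection.params["b"][...] = 1.0


class TestBuild:
    def test_baseline_needs_no_reader_id(self, rng):
        model = build_model(small_spec(use_reader_embeddings=False), seed=0)
        x = rng.standard_normal((2, 1, 32, 32)).astype(np.float32)
        probs = model.predict_proba(x)
        assert probs.shape == (2, 5)

    def test_embedding_table_shape_for_full_panel(self):
        model = build_model(ModelSpec(backbone="TOY_CNN", n_readers=18, reader_emb_dim=32))
        assert model.embedding.params["table"].shape == (18, 32)

    def test_same_seed_same_parameters(self):
        a = build_model(small_spec(), seed=5)
        b = build_model(small_spec(), seed=5)
        for (_, la), (_, lb) in zip(a.named_layers(), b.named_layers()):
            for k in la.params:
                np.testing.assert_array_equal(la.params[k], lb.params[k])

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(backbone="VGG")

    def test_invalid_spec_values_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(n_readers=0)
        with pytest.raises(ValueError):
            ModelSpec(dropout=1.0)
        with pytest.raises(ValueError):
            ModelSpec(max_norm=0.0)

    def test_resnet_backbone_dimensions(self, rng):
        spec = ModelSpec(backbone="RESNET18", n_readers=4, use_reader_embeddings=False)
        assert spec.embedding_dim == 512
        assert ModelSpec(backbone="RESNET50").embedding_dim == 2048
        model = build_model(spec, seed=0)
        x = rng.standard_normal((1, 3, 64, 64)).astype(np.float32)
        probs = model.predict_proba(x)
        assert probs.shape == (1, 5)
        assert probs.sum() == pytest.approx(1.0, abs=1e-5)


class TestForward:
    def test_reader_output_is_simplex(self, rng):
        model = build_model(small_spec(), seed=1)
        for _ in range(20):
            x = rng.standard_normal((1, 32, 32)).astype(np.float32)
            p = forward_reader(model, x, int(rng.integers(6)))
            assert p.min() >= 0
            assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_reader_id_out_of_range(self, rng):
        model = build_model(small_spec(), seed=1)
        x = rng.standard_normal((1, 32, 32)).astype(np.float32)
        with pytest.raises(IndexError):
            forward_reader(model, x, 6)

    def test_baseline_on_model_without_embeddings_only(self, rng):
        model = build_model(small_spec(use_reader_embeddings=False), seed=1)
        x = rng.standard_normal((1, 32, 32)).astype(np.float32)
        with pytest.raises(ValueError):
            forward_reader(model, x, 0)

    def test_all_ones_modulation_equals_baseline(self, rng):
        """Identity activation + zero projection weights + unit bias makes
        the reader path an exact no-op for every reader."""
        model = build_model(small_spec(activation="IDENTITY"), seed=2)
        make_ones_modulation(model)
        for _ in range(10):
            x = rng.standard_normal((1, 32, 32)).astype(np.float32)
            pb = forward_baseline(model, x)
            for r in range(6):
                pr = forward_reader(model, x, r)
                assert np.abs(pr - pb).max() < 1e-6

    def test_distinct_modulation_changes_output(self, rng):
        model = build_model(small_spec(activation="IDENTITY"), seed=3)
        make_ones_modulation(model)
        # give reader 1 a different modulation in one coordinate
        model.embedding.params["table"][...] = 0.0
        model.embedding.params["table"][1, 0] = 1.0
        model.projection.params["W"][0, 0] = 2.0
        x = np.abs(rng.standard_normal((1, 32, 32))).astype(np.float32)
        p0 = forward_reader(model, x, 0)
        p1 = forward_reader(model, x, 1)
        assert np.abs(p0 - p1).max() > 1e-6

    def test_constant_zero_image_gives_valid_simplex(self):
        model = build_model(small_spec(use_reader_embeddings=False), seed=4)
        p = forward_baseline(model, np.zeros((1, 32, 32), dtype=np.float32))
        assert p.min() >= 0 and p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_eval_mode_deterministic_despite_dropout(self, rng):
        model = build_model(small_spec(dropout=0.5, use_reader_embeddings=False), seed=5)
        x = rng.standard_normal((1, 1, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(model.predict_proba(x), model.predict_proba(x))

    def test_train_mode_dropout_is_stochastic_with_correct_mean(self, rng):
        model = build_model(small_spec(dropout=0.5, use_reader_embeddings=False), seed=5)
        x = rng.standard_normal((1, 1, 32, 32)).astype(np.float32)
        feat = model.backbone.forward(x, train=False)
        h = model.gap.forward(feat)
        eval_logits = model.head.forward(h)
        # dropout sits just before the linear head, so train-mode logits are
        # linear in the mask: single passes differ, the mean does not
        draws = np.stack(
            [model.head.forward(model.dropout.forward(h, train=True)) for _ in range(3000)]
        )
        assert np.std(draws, axis=0).max() > 0
        np.testing.assert_allclose(draws.mean(axis=0), eval_logits, atol=0.15)


class TestActivationGating:
    @pytest.mark.parametrize("act", ["RELU", "SIGMOID"])
    def test_nonnegative_activations_cannot_flip_feature_signs(self, act, rng):
        model = build_model(small_spec(activation=act), seed=6)
        model.embedding.params["table"][...] = rng.standard_normal((6, 8)) * 3
        m = model.modulation(np.arange(6))
        assert m.min() >= 0.0
        # hence each embedding coordinate keeps its sign for every reader
        h = rng.standard_normal(8).astype(np.float32)
        signs = np.sign(h[None, :] * m)
        nonzero = np.abs(h[None, :] * m) > 0
        for j in range(8):
            col = signs[:, j][nonzero[:, j]]
            assert len(set(col.tolist())) <= 1

    @pytest.mark.parametrize("act", ["IDENTITY", "TANH"])
    def test_signed_activations_can_flip(self, act):
        model = build_model(small_spec(activation=act), seed=7)
        model.embedding.params["table"][...] = 0.0
        model.embedding.params["table"][0, 0] = 3.0
        model.embedding.params["table"][1, 0] = -3.0
        model.projection.params["W"][...] = 0.0
        model.projection.params["W"][0, 0] = 1.0
        model.projection.params["b"][...] = 0.0
        m = model.modulation(np.array([0, 1]))
        assert m[0, 0] > 0 > m[1, 0]


class TestMaxNorm:
    def test_long_row_projected_onto_ball(self):
        table = np.zeros((1, 4), dtype=np.float32)
        table[0, 0] = 2.0
        out = apply_max_norm(table, 1.0)
        assert np.linalg.norm(out[0]) == pytest.approx(1.0, abs=1e-6)

    def test_interior_row_untouched(self):
        table = np.full((1, 4), 0.25, dtype=np.float32)  # norm 0.5
        np.testing.assert_array_equal(apply_max_norm(table, 1.0), table)

    def test_mixed_rows_at_norm_four(self, rng):
        rows = []
        for target in (3.9, 4.0, 4.1):
            v = rng.standard_normal(8)
            rows.append(v / np.linalg.norm(v) * target)
        out = apply_max_norm(np.stack(rows).astype(np.float32), 4.0)
        norms = np.linalg.norm(out, axis=1)
        np.testing.assert_allclose(norms, [3.9, 4.0, 4.0], atol=1e-5)

    def test_nonpositive_max_norm_rejected(self):
        with pytest.raises(ValueError):
            apply_max_norm(np.ones((1, 2)), 0.0)


class TestBookkeeping:
    def test_reader_branch_parameter_count(self):
        spec = small_spec(n_readers=18, reader_emb_dim=32, toy_channels=(8, 16, 32))
        model = build_model(spec, seed=0)
        D = spec.embedding_dim
        expected = 18 * 32 + 32 * D + D
        assert model.reader_branch_param_count() == expected
        base = build_model(small_spec(n_readers=18, reader_emb_dim=32,
                                      toy_channels=(8, 16, 32),
                                      use_reader_embeddings=False), seed=0)
        assert model.n_params() - base.n_params() == expected

    def test_summary_reports_branch_count(self):
        model = build_model(small_spec(), seed=0)
        assert str(model.reader_branch_param_count()) in model.summary()


class TestCheckpoint:
    def test_roundtrip_preserves_outputs(self, tmp_path, rng):
        model = build_model(small_spec(dropout=0.2), seed=8)
        x = rng.standard_normal((3, 1, 32, 32)).astype(np.float32)
        rids = np.array([0, 2, 5])
        before = model.predict_proba(x, rids)
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(loaded.predict_proba(x, rids), before)
        assert loaded.spec.dropout == 0.2
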