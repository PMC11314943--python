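import numpy as np
import pytest

import radarposture as rp
from radarposture import nn
from radarposture.mvcnn import BACKBONES, STUB_BACKBONES


def tiny_spec(**kw):
    defaults = dict(backbone="tiny_cnn", n_views=2, n_classes=4, input_size=8, head=(8,))
    defaults.update(kw)
    return rp.ModelSpec(**defaults)


class TestTaxonomy:
    @pytest.mark.parametrize(
        "fine,coarse",
        [("S", "Supine"), ("L.Sto", "Left"), ("R.Pr", "Prone"), ("R.Fet", "Right")],
    )
    def test_examples(self, fine, coarse):
        assert rp.coarse_map(fine) == coarse

    def test_total_and_surjective(self):
        images = {rp.coarse_map(f) for f in rp.FINE_LABELS}
        assert images == set(rp.COARSE_LABELS)

    def test_coarse_class_sizes(self):
        sizes = {c: sum(rp.coarse_map(f) == c for f in rp.FINE_LABELS) for c in rp.COARSE_LABELS}
        assert sizes == {"Supine": 1, "Left": 3, "Right": 3, "Prone": 2}

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError):
            rp.coarse_map("Standing")


class TestModelStructure:
    def test_max_pool_of_duplicated_views_equals_single_view(self):
        rng = np.random.default_rng(0)
        x1 = rng.uniform(size=(3, 1, 8, 8)).astype(np.float64)
        m1 = rp.build_model(tiny_spec(n_views=1), seed=5)
        m4 = rp.build_model(tiny_spec(n_views=4), seed=5)  # same init: same seed
        x4 = np.repeat(x1, 4, axis=1)
        np.testing.assert_allclose(m1.forward(x1), m4.forward(x4), atol=1e-10)

    def test_pooled_dimension_independent_of_view_count(self):
        rng = np.random.default_rng(1)
        for v in (1, 3, 8):
            m = rp.build_model(tiny_spec(n_views=v), seed=2)
            out = m.forward(rng.uniform(size=(2, v, 8, 8)))
            assert out.shape == (2, 4)

    def test_view_permutation_invariance_under_max_pool(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(size=(4, 5, 8, 8))
        m = rp.build_model(tiny_spec(n_views=5), seed=3)
        base = m.forward(x)
        perm = m.forward(x[:, [3, 0, 4, 1, 2]])
        np.testing.assert_allclose(base, perm, atol=1e-10)

    def test_softmax_normalises(self):
        rng = np.random.default_rng(3)
        m = rp.build_model(tiny_spec(), seed=0)
        p = m.predict_proba(rng.uniform(size=(6, 2, 8, 8)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(p >= 0)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError, match="unknown backbone"):
            rp.ModelSpec(backbone="vgg19")

    @pytest.mark.parametrize("name", STUB_BACKBONES)
    def test_stub_backbones_rejected_with_guidance(self, name):
        with pytest.raises(ValueError, match="registry stub"):
            rp.ModelSpec(backbone=name)

    def test_checkpoint_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        x = rng.uniform(size=(3, 2, 8, 8))
        m = rp.build_model(tiny_spec(), seed=9)
        rp.save_checkpoint(m, tmp_path / "m.npz")
        m2 = rp.load_checkpoint(tmp_path / "m.npz")
        np.testing.assert_array_equal(m.forward(x), m2.forward(x))
        assert m2.spec == m.spec


class TestGradients:
    """Analytic backward passes against central finite differences."""

    @pytest.mark.parametrize("backbone", BACKBONES)
    @pytest.mark.parametrize("pooling", ["max", "mean"])
    def test_parameter_gradients(self, backbone, pooling):
        rng = np.random.default_rng(0)
        spec = tiny_spec(backbone=backbone, pooling=pooling)
        model = rp.build_model(spec, seed=1)
        x = rng.uniform(size=(3, 2, 8, 8))
        y = np.array([0, 2, 3])

        def loss_value():
            loss, _ = nn.cross_entropy_with_logits(model.forward(x), y)
            return loss

        loss, dlogits = nn.cross_entropy_with_logits(model.forward(x), y)
        model.backward(dlogits)
        eps = 1e-6
        checked = 0
        for layer, key in model.param_items():
            p = layer.params[key]
            flat_idx = rng.integers(0, p.size, size=min(3, p.size))
            for fi in flat_idx:
                idx = np.unravel_index(fi, p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                up = loss_value()
                p[idx] = orig - eps
                down = loss_value()
                p[idx] = orig
                numeric = (up - down) / (2 * eps)
                analytic = layer.grads[key][idx]
                assert numeric == pytest.approx(analytic, abs=1e-6, rel=1e-4)
                checked += 1
        assert checked > 10


class TestTraining:
    def test_zero_learning_rate_leaves_weights_unchanged(self, small_views):
        x, y, _ = small_views
        m = rp.build_model(rp.ModelSpec(n_views=8, n_classes=4, input_size=32), seed=1)
        before = [layer.params[k].copy() for layer, k in m.param_items()]
        acc_before, _ = rp.evaluate(m, x, y)
        rp.train(m, x, y, rp.TrainConfig(learning_rate=0.0, epochs=1, seed=0))
        for (layer, k), b in zip(m.param_items(), before):
            np.testing.assert_array_equal(layer.params[k], b)
        acc_after, _ = rp.evaluate(m, x, y)
        assert acc_after == acc_before

    def test_same_seed_gives_identical_history(self, small_views):
        x, y, _ = small_views
        histories = []
        for _ in range(2):
            m = rp.build_model(rp.ModelSpec(n_views=8, n_classes=4, input_size=32), seed=3)
            h = rp.train(m, x[:24], y[:24], rp.TrainConfig(epochs=2, seed=3))
            histories.append(h)
        assert histories[0] == histories[1]

    def test_learns_separable_synthetic_set(self):
        # noise-free thin-blanket fixture is separable by construction:
        # training should fit it almost perfectly
        params = rp.SimParams(n_pulses=8, noise_sigma=0.0, blanket_diffuse=0.0)
        records, _ = rp.generate_dataset(6, rp.FINE_LABELS, ("thin",), 1,
                                         params=params, seed=11)
        x, postures, _, _ = rp.views_from_samples(records, input_size=32)
        y = rp.encode_labels(postures, "coarse")
        m = rp.build_model(rp.ModelSpec(n_views=8, n_classes=4, input_size=32), seed=1)
        hist = rp.train(m, x, y, rp.TrainConfig(epochs=30, batch_size=8, seed=1))
        assert len(hist["epoch"]) == 30
        assert max(hist["accuracy"]) >= 0.9
        assert hist["loss"][-1] < hist["loss"][0]

    def test_empty_training_set_rejected(self):
        m = rp.build_model(tiny_spec(), seed=0)
        with pytest.raises(ValueError):
            rp.train(m, np.empty((0, 2, 8, 8)), np.empty(0, dtype=int))

    def test_missing_class_warns(self):
        rng = np.random.default_rng(0)
        m = rp.build_model(tiny_spec(), seed=0)
        x = rng.uniform(size=(8, 2, 8, 8))
        y = np.array([0, 1] * 4)
        with pytest.warns(UserWarning, match="classes present"):
            rp.train(m, x, y, rp.TrainConfig(epochs=1, seed=0))

    def test_single_class_rejected(self):
        m = rp.build_model(tiny_spec(), seed=0)
        with pytest.raises(ValueError):
            rp.train(m, np.zeros((4, 2, 8, 8)), np.zeros(4, dtype=int))


class TestEvaluate:
    def constant_predictor(self, cls=0):
        m = rp.build_model(tiny_spec(), seed=0)
        final = m.head.layers[-1]
        final.params["W"][:] = 0.0
        final.params["b"][:] = 0.0
        final.params["b"][cls] = 10.0
        return m

    def test_constant_predictor_on_balanced_set(self):
        x = np.random.default_rng(0).uniform(size=(16, 2, 8, 8))
        y = np.repeat(np.arange(4), 4)
        acc, cm = rp.evaluate(self.constant_predictor(), x, y)
        assert acc == pytest.approx(0.25)
        assert cm[:, 0].sum() == 16

    def test_confusion_matrix_conservation(self, small_views):
        x, y, _ = small_views
        m = rp.build_model(rp.ModelSpec(n_views=8, n_classes=4, input_size=32), seed=0)
        acc, cm = rp.evaluate(m, x, y)
        assert cm.sum() == len(y)
        np.testing.assert_array_equal(cm.sum(axis=1), np.bincount(y, minlength=4))
        assert acc == pytest.approx(np.trace(cm) / cm.sum())

    def test_perfect_predictions_give_one(self):
        # oracle check via a constant predictor on a single-class set
        x = np.random.default_rng(1).uniform(size=(6, 2, 8, 8))
        y = np.full(6, 2)
        acc, _ = rp.evaluate(self.constant_predictor(cls=2), x, y)
        assert acc == 1.0

    def test_out_of_taxonomy_labels_rejected(self):
        m = rp.build_model(tiny_spec(), seed=0)
        with pytest.raises(ValueError):
            rp.evaluate(m, np.zeros((2, 2, 8, 8)), np.array([0, 7]))

    def test_coarse_accuracy_of_fine_model_dominates(self, small_records, placement, grid):
        # mapping fine predictions and labels to coarse classes can only
        # merge errors into hits, never the reverse
        records, _ = small_records
        x, postures, _, _ = rp.views_from_samples(records[:27], placement=placement,
                                                  grid=grid, input_size=16)
        y_fine = rp.encode_labels(postures, "fine")
        m = rp.build_model(rp.ModelSpec(n_views=8, n_classes=9, input_size=16), seed=2)
        rp.train(m, x, y_fine, rp.TrainConfig(epochs=2, seed=2))
        pred_fine = m.predict(x)
        fine_acc = float(np.mean(pred_fine == y_fine))
        to_coarse = np.array([rp.COARSE_LABELS.index(rp.coarse_map(f)) for f in rp.FINE_LABELS])
        coarse_acc = float(np.mean(to_coarse[pred_fine] == to_coarse[y_fine]))
        assert coarse_acc >= fine_acc
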