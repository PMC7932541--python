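"""The NumPy CNN: architecture, analytic gradients, the staged early-stopping
trainer, metrics and checkpointing."""

import numpy as np
import pytest

from srescan import cnn, encode
from srescan.couples import LabeledSequence


def random_windows(n, rng, label=None):
    out = []
    for i in range(n):
        seq = "".join(rng.choice(list("atcg"), 100))
        lab = int(rng.integers(0, 2)) if label is None else label
        out.append(LabeledSequence(sequence=seq, label=lab, source_id=f"w{i}"))
    return out


SMALL = cnn.ModelConfig(
    n_filters=32, kernel_size=3, batch_size=64,
    epoch_blocks=(2,), patience_per_block=(2,), rng_seed=3,
)


class TestBuildModel:
    def test_output_strictly_in_unit_interval(self, tiny_model):
        rng = np.random.default_rng(0)
        x = encode.encode_batch(["".join(rng.choice(list("atcg"), 100)) for _ in range(8)])
        p = tiny_model.predict_proba(x)
        assert np.all((p > 0) & (p < 1))

    def test_fixed_seed_reproducible_init(self):
        a = cnn.build_model(SMALL)
        b = cnn.build_model(SMALL)
        for name in a.params:
            assert np.array_equal(a.params[name], b.params[name])

    def test_parameter_count_matches_layer_arithmetic(self):
        model = cnn.build_model(cnn.ModelConfig(n_filters=64, kernel_size=6))
        k, f, d = 6, 64, 64
        expected = (k * 5 * f + f) + (k * f * f + f) + (f * d + d) + (d * 1 + 1)
        assert model.n_parameters() == expected

    def test_off_grid_config_warns_not_errors(self):
        with pytest.warns(UserWarning, match="off the usual grid"):
            cnn.ModelConfig(n_filters=17)


class TestGradients:
    def test_backprop_matches_numerical_gradient(self):
        """Finite-difference check of every parameter tensor on a tiny net."""
        cfg = cnn.ModelConfig(n_filters=4, kernel_size=3, dense_units=5,
                              dropout=0.0, rng_seed=1)
        model = cnn.build_model(cfg)
        for name in model.params:
            model.params[name] = model.params[name].astype(np.float64)
        rng = np.random.default_rng(2)
        x = encode.encode_batch(["".join(rng.choice(list("atcg"), 100)) for _ in range(4)]).astype(np.float64)
        y = np.array([1.0, 0.0, 1.0, 0.0])

        def loss_value():
            prob, _ = model._forward(x, train=False)
            p = np.clip(prob[:, 0], 1e-12, 1 - 1e-12)
            return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

        prob, cache = model._forward(x, train=False)
        grads = model._backward(prob, y, cache)
        eps = 1e-6
        rng_idx = np.random.default_rng(3)
        for name, g in grads.items():
            flat = model.params[name].ravel()
            for idx in rng_idx.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_value()
                flat[idx] = orig - eps
                down = loss_value()
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert g.ravel()[idx] == pytest.approx(numeric, rel=1e-3, abs=1e-7), name


class TestTrain:
    def test_empty_or_single_class_sets_rejected(self):
        rng = np.random.default_rng(0)
        data = random_windows(10, rng)
        model = cnn.build_model(SMALL)
        with pytest.raises(ValueError):
            cnn.train(model, [], data)
        ones = random_windows(10, rng, label=1)
        with pytest.raises(ValueError):
            cnn.train(model, ones, data)

    def test_patience_one_with_flat_accuracy_ends_block_after_two_epochs(self):
        """With learning rate 0 validation accuracy never improves after the
        first epoch, so a patience-1 block stops at exactly 2 epochs."""
        rng = np.random.default_rng(1)
        data = random_windows(40, rng)
        cfg = cnn.ModelConfig(n_filters=32, kernel_size=3, batch_size=32,
                              epoch_blocks=(40,), patience_per_block=(1,),
                              learning_rate=0.0, rng_seed=3)
        model = cnn.build_model(cfg)
        history = cnn.train(model, data, data)
        assert len(history.losses) == 2

    def test_epochs_bounded_by_block_schedule(self):
        rng = np.random.default_rng(2)
        data = random_windows(30, rng)
        cfg = cnn.ModelConfig(n_filters=32, kernel_size=3, batch_size=32,
                              epoch_blocks=(2, 1), patience_per_block=(5, 5),
                              rng_seed=3)
        model = cnn.build_model(cfg)
        history = cnn.train(model, data, data[:10])
        assert len(history.losses) <= 3
        assert history.block_ends[-1] == len(history.losses)

    def test_training_is_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(4)
        train_set = random_windows(60, rng)
        val_set = random_windows(20, rng)
        h1 = cnn.train(cnn.build_model(SMALL), train_set, val_set)
        h2 = cnn.train(cnn.build_model(SMALL), train_set, val_set)
        assert h1.losses == h2.losses
        assert h1.val_accuracies == h2.val_accuracies

    def test_best_validation_weights_restored(self):
        rng = np.random.default_rng(5)
        train_set = random_windows(60, rng)
        val_set = random_windows(20, rng)
        model = cnn.build_model(SMALL)
        history = cnn.train(model, train_set, val_set)
        probs = model.predict_proba_sequences([s.sequence for s in val_set])
        acc = np.mean((probs >= 0.5) == np.array([s.label for s in val_set], bool))
        assert acc == pytest.approx(max(history.val_accuracies))


class TestPredict:
    def test_order_preserving_and_matching_single_calls(self, tiny_model):
        rng = np.random.default_rng(6)
        seqs = ["".join(rng.choice(list("atcg"), 100)) for _ in range(5)]
        batch = tiny_model.predict_proba(encode.encode_batch(seqs))
        singles = [tiny_model.predict_proba(encode.encode_window(s))[0] for s in seqs]
        assert np.allclose(batch, singles, atol=1e-6)

    def test_rejects_wrong_geometry(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.predict_proba(np.zeros((3, 100, 5)))


class TestEvaluate:
    def test_hand_counted_confusion(self):
        probs = np.array([0.9] * 9 + [0.1] + [0.8] + [0.2] * 9)
        labels = np.array([1] * 10 + [0] * 10)
        m = cnn.evaluate(probs, labels, threshold=0.5)
        assert (m.tp, m.fn, m.fp, m.tn) == (9, 1, 1, 9)
        assert m.precision == m.recall == m.f1 == m.accuracy == 0.9

    def test_perfect_and_anti_perfect(self):
        labels = np.array([1, 0, 1, 0])
        perfect = cnn.evaluate(np.array([0.9, 0.1, 0.8, 0.2]), labels)
        assert perfect.accuracy == perfect.f1 == 1.0
        anti = cnn.evaluate(np.array([0.1, 0.9, 0.2, 0.8]), labels)
        assert anti.accuracy == 0.0

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(7)
        probs = rng.random(500)
        labels = rng.integers(0, 2, 500)
        m = cnn.evaluate(probs, labels, threshold=0.4)
        tp = sum(1 for p, l in zip(probs, labels) if p >= 0.4 and l == 1)
        tn = sum(1 for p, l in zip(probs, labels) if p < 0.4 and l == 0)
        assert m.tp == tp and m.tn == tn
        assert m.accuracy == pytest.approx((tp + tn) / 500)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cnn.evaluate(np.array([]), np.array([]))


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, tiny_model):
        rng = np.random.default_rng(8)
        seqs = ["".join(rng.choice(list("atcg"), 100)) for _ in range(4)]
        path = tmp_path / "model.npz"
        tiny_model.save(path)
        back = cnn.SREClassifier.load(path)
        assert back.config == tiny_model.config
        assert np.allclose(
            back.predict_proba_sequences(seqs), tiny_model.predict_proba_sequences(seqs)
        )

    def test_unrecognized_format_rejected(self, tmp_path):
        path = tmp_path / "bogus.npz"
        np.savez(path, __format__="something-else", __config__="{}")
        with pytest.raises(ValueError, match="format"):
            cnn.SREClassifier.load(path)
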