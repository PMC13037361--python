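"""The multi-modal classifier: gradients, contracts, learning behaviour."""

import numpy as np
import pytest

from actikoa.model import (
    DiurnalNet,
    ModelConfig,
    SingleClassError,
    TrainedModel,
    expected_num_parameters,
    forward,
    predict,
    train_fold,
)
from actikoa.nn import cross_entropy, softmax
from actikoa.simulate import SyntheticConfig, generate_population, calibrate_attenuation


def _random_batch(rng, n=8):
    return {
        "profile": rng.normal(size=(n, 24)),
        "numeric": rng.normal(size=(n, 2)),
        "month_idx": rng.integers(0, 12, n),
        "sex_idx": rng.integers(0, 2, n),
    }


def _training_arrays(rng, n=200, shift=0.0):
    """Synthetic arrays with a class-0 daytime elevation of `shift`."""
    y = rng.integers(0, 2, n)
    profile = rng.normal(20.0, 5.0, size=(n, 24))
    profile[y == 0, 9:17] += shift
    return {
        "profile": profile,
        "month": rng.integers(1, 13, n),
        "sex": rng.integers(0, 2, n),
        "age": rng.normal(65, 7, n),
        "weight": rng.normal(85, 12, n),
        "y": y,
    }


class TestNetwork:
    def test_gradients_match_finite_differences(self, rng):
        """Analytic backprop vs central differences through the whole net."""
        net = DiurnalNet(ModelConfig(seed=0), np.random.default_rng(0))
        batch = _random_batch(rng, n=6)
        y = rng.integers(0, 2, 6)

        for p in net.parameters():
            p.grad[...] = 0.0
        loss, dlogits = cross_entropy(net.forward(batch, train=True), y)
        net.backward(dlogits)

        eps = 1e-6
        check_rng = np.random.default_rng(7)
        for p in net.parameters():
            flat = p.data.ravel()
            for _ in range(3):
                i = check_rng.integers(flat.size)
                orig = flat[i]
                flat[i] = orig + eps
                lp = cross_entropy(net.forward(batch, train=True), y)[0]
                flat[i] = orig - eps
                lm = cross_entropy(net.forward(batch, train=True), y)[0]
                flat[i] = orig
                numeric = (lp - lm) / (2 * eps)
                analytic = p.grad.ravel()[i]
                assert analytic == pytest.approx(numeric, abs=1e-6, rel=1e-4)

    def test_parameter_count_matches_closed_form(self):
        cfg = ModelConfig()
        net = DiurnalNet(cfg, np.random.default_rng(0))
        assert net.num_parameters() == expected_num_parameters(cfg) == 3374

    def test_probabilities_valid_for_any_input(self, rng):
        net = DiurnalNet(ModelConfig(seed=1), np.random.default_rng(1))
        probs = softmax(net.forward(_random_batch(rng, 32), train=False))
        assert np.all(probs >= 0) and np.all(probs <= 1)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_zeroed_final_layer_gives_coin_flip(self, rng):
        net = DiurnalNet(ModelConfig(seed=2), np.random.default_rng(2))
        net.fc2.weight.data[...] = 0.0
        net.fc2.bias.data[...] = 0.0
        probs = softmax(net.forward(_random_batch(rng, 16), train=False))
        np.testing.assert_allclose(probs, 0.5, atol=1e-12)

    def test_wrong_profile_length_rejected(self, rng):
        net = DiurnalNet(ModelConfig(), np.random.default_rng(0))
        batch = _random_batch(rng, 4)
        batch["profile"] = batch["profile"][:, :20]
        with pytest.raises(ValueError):
            net.forward(batch)

    def test_unknown_category_rejected(self, rng):
        net = DiurnalNet(ModelConfig(), np.random.default_rng(0))
        batch = _random_batch(rng, 4)
        batch["month_idx"] = np.array([0, 3, 12, 1])  # 12 is out of range
        with pytest.raises(ValueError):
            net.forward(batch)


class TestTraining:
    def test_seeded_determinism(self, rng):
        arrays = _training_arrays(np.random.default_rng(0))
        cfg = ModelConfig(epochs=3, seed=5)
        m1 = train_fold(arrays, cfg)
        m2 = train_fold(arrays, cfg)
        _, s1 = predict(m1, arrays)
        _, s2 = predict(m2, arrays)
        np.testing.assert_array_equal(s1, s2)
        for p1, p2 in zip(m1.net.parameters(), m2.net.parameters()):
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_single_class_rejected(self):
        arrays = _training_arrays(np.random.default_rng(0), n=40)
        arrays["y"][:] = 1
        with pytest.raises(SingleClassError):
            train_fold(arrays, ModelConfig(epochs=1))

    def test_separable_data_is_learned(self):
        """Large injected shift: training accuracy clears a logistic-style bound."""
        arrays = _training_arrays(np.random.default_rng(3), n=400, shift=25.0)
        model = train_fold(arrays, ModelConfig(seed=3))
        yhat, _ = predict(model, arrays)
        assert np.mean(yhat == arrays["y"]) > 0.95

    def test_loss_decreases(self):
        arrays = _training_arrays(np.random.default_rng(4), n=300, shift=10.0)
        model = train_fold(arrays, ModelConfig(seed=4))
        assert model.training_log[-1] < model.training_log[0]

    def test_scaler_from_training_fold_only(self):
        arrays = _training_arrays(np.random.default_rng(5), n=120)
        model = train_fold(arrays, ModelConfig(epochs=1, seed=0))
        expected_mean = arrays["profile"].mean()
        assert model.scaler.hour_mean[0] == pytest.approx(expected_mean)
        assert np.all(model.scaler.hour_mean == model.scaler.hour_mean[0])


@pytest.fixture(scope="module")
def trained():
    arrays = _training_arrays(np.random.default_rng(6), n=240, shift=8.0)
    return train_fold(arrays, ModelConfig(epochs=5, seed=6)), arrays


class TestPrediction:

    def test_argmax_labels(self, trained):
        model, arrays = trained
        yhat, scores = predict(model, arrays)
        probs = model.predict_proba(arrays)
        np.testing.assert_array_equal(yhat, probs.argmax(axis=1))
        np.testing.assert_array_equal(scores, probs[:, 1])

    def test_empty_dataset(self, trained):
        model, _ = trained
        empty = {k: np.asarray(v)[:0] for k, v in _training_arrays(np.random.default_rng(0), 4).items()}
        yhat, scores = predict(model, empty)
        assert yhat.size == 0 and scores.size == 0

    def test_batch_equals_one_at_a_time(self, trained):
        """Frozen batch-norm statistics: prediction is batch-size independent."""
        model, arrays = trained
        _, batch_scores = predict(model, arrays)
        single_scores = []
        for i in range(20):
            sub = {k: np.asarray(v)[i : i + 1] for k, v in arrays.items()}
            single_scores.append(predict(model, sub)[1][0])
        np.testing.assert_allclose(batch_scores[:20], single_scores, atol=1e-12)

    def test_single_record_forward_interface(self, trained):
        model, _ = trained
        probs = forward([20.0] * 24, 6, "female", 65.0, 80.0, model)
        assert probs.shape == (2,)
        assert probs.sum() == pytest.approx(1.0)
        with pytest.raises(ValueError):
            forward([20.0] * 23, 6, "female", 65.0, 80.0, model)
        with pytest.raises(ValueError):
            forward([20.0] * 24, 6, "other", 65.0, 80.0, model)

    def test_month_embedding_is_wired_in(self, trained):
        """Permuting months at inference changes scores; identity does not."""
        model, arrays = trained
        _, base = predict(model, arrays)
        shuffled = dict(arrays)
        shuffled["month"] = np.roll(np.asarray(arrays["month"]), 1)
        _, moved = predict(model, shuffled)
        assert not np.allclose(base, moved)
        _, again = predict(model, dict(arrays))
        np.testing.assert_array_equal(base, again)

    def test_checkpoint_roundtrip(self, trained, tmp_path):
        model, arrays = trained
        path = tmp_path / "model.json"
        model.save(path)
        restored = TrainedModel.load(path)
        _, s0 = predict(model, arrays)
        _, s1 = predict(restored, arrays)
        np.testing.assert_allclose(s0, s1, atol=1e-15)


class TestLearningSignal:
    def test_auc_monotone_in_effect_size(self):
        """Held-out AUC rises with injected effect over delta(0.5/0.6/0.7)."""
        from sklearn.metrics import roc_auc_score

        base = SyntheticConfig(n_participants=6000, case_fraction=0.5, seed=31)
        aucs = []
        for target in (None, 0.6, 0.7):
            delta = 0.0 if target is None else calibrate_attenuation(target, base)
            cfg = SyntheticConfig(
                n_participants=6000, case_fraction=0.5,
                daytime_attenuation=delta, seed=31,
            )
            records = generate_population(cfg)
            arrays_y = np.array([r.diagnosis_offset_years is not None for r in records], int)
            arrays = {
                "profile": np.array([r.profile for r in records]),
                "month": np.array([r.month for r in records]),
                "sex": np.array([1 if r.sex == "male" else 0 for r in records]),
                "age": np.array([r.age for r in records]),
                "weight": np.array([r.weight for r in records]),
                "y": arrays_y,
            }
            tr = {k: v[:4500] for k, v in arrays.items()}
            te = {k: v[4500:] for k, v in arrays.items()}
            model = train_fold(tr, ModelConfig(seed=31))
            _, scores = predict(model, te)
            aucs.append(roc_auc_score(te["y"], scores))
        assert aucs[0] < aucs[1] < aucs[2]
        assert abs(aucs[0] - 0.5) < 0.05
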