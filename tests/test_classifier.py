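import numpy as np
import pytest
from sklearn.base import clone

from traminer.classifier import (
    Prediction,
    TrainConfig,
    TwoBranchMLPClassifier,
    build_dcnn_baseline,
    build_two_input_mlp,
    predict_trajectory,
    stratified_validation_split,
    train_model,
)
from traminer.nn import DcnnNet, TwoBranchMLPNet, softmax


class TestSoftmax:
    def test_symmetric_logits_give_uniform(self):
        np.testing.assert_allclose(softmax(np.zeros(3)), np.full(3, 1 / 3))

    def test_shift_invariance(self):
        for c in (-100.0, 0.0, 42.0):
            np.testing.assert_allclose(
                softmax(np.array([c, c + 0.5, c])),
                softmax(np.array([0.0, 0.5, 0.0])),
                atol=1e-12,
            )

    def test_matches_direct_evaluation(self):
        z = np.array([1.0, 2.0, 3.0])
        expected = np.exp(z) / np.exp(z).sum()
        np.testing.assert_allclose(softmax(z), expected, atol=1e-12)

    def test_non_finite_logits_rejected(self):
        with pytest.raises(ValueError):
            softmax(np.array([np.inf, 0, 0]))


class TestArchitectures:
    def test_mlp_branch_input_dimension(self):
        spec = build_two_input_mlp(39_000)
        net = spec.instantiate(np.random.default_rng(0))
        assert net.branch_traj.layers[0].n_in == 39_000
        assert net.head.layers[0].n_out == 3

    def test_mlp_parameter_count_matches_arithmetic(self):
        d, h, c = 120, 32, 3
        spec = build_two_input_mlp(d, hidden=h, n_classes=c)
        expected = 2 * ((d * h + h) + 2 * h + (h * h + h) + 2 * h)
        expected += 2 * h * c + c + 2 * c
        assert spec.n_params == expected
        net = spec.instantiate(np.random.default_rng(0))
        assert net.n_params == expected

    def test_dcnn_filter_counts_and_halving(self):
        spec = build_dcnn_baseline((64, 64, 1))
        conv_params = [n for name, n in spec.layers if name.startswith("conv")]
        assert conv_params == [
            5 * 5 * 1 * 32 + 32,
            5 * 5 * 32 * 128 + 128,
            5 * 5 * 128 * 256 + 256,
        ]
        net = DcnnNet((64, 64, 1), rng=np.random.default_rng(0))
        assert net.post_conv_hw == (8, 8)  # three 2x halvings of 64

    def test_dcnn_pooling_halves_each_time(self):
        net = DcnnNet((16, 24, 1), rng=np.random.default_rng(0))
        x = np.random.default_rng(1).normal(size=(2, 16, 24, 1)).astype(np.float32)
        logits = net.forward_logits((x,))
        assert logits.shape == (2, 3)
        assert net.post_conv_hw == (2, 3)

    def test_dcnn_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            build_dcnn_baseline((4, 4, 1))


def separable_pairs(n_per_class=100, dim=60, seed=0):
    """Three classes marked by disjoint always-on feature blocks in both views."""
    rng = np.random.default_rng(seed)
    X_t, X_s, y = [], [], []
    for k, cls in enumerate(("healthy", "MCI", "PwD")):
        for _ in range(n_per_class):
            xt = (rng.random(dim) < 0.05).astype(np.float32)
            xs = (rng.random(dim) < 0.05).astype(np.float32)
            block = slice(k * (dim // 3), (k + 1) * (dim // 3))
            xt[block] = 1.0
            xs[block] = 1.0
            X_t.append(xt)
            X_s.append(xs)
            y.append(cls)
    return np.array(X_t), np.array(X_s), np.array(y)


class TestTraining:
    def test_same_seed_reproduces_identical_weights(self):
        Xt, Xs, y = separable_pairs(n_per_class=20, dim=30)
        onehot = np.eye(3, dtype=np.float32)[
            [("healthy", "MCI", "PwD").index(v) for v in y]
        ]
        data = ((Xt, Xs), onehot)
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=5, seed=11)
        net1, _ = train_model(build_two_input_mlp(30), data, data, cfg)
        net2, _ = train_model(build_two_input_mlp(30), data, data, cfg)
        for a, b in zip(net1.get_weights(), net2.get_weights()):
            np.testing.assert_array_equal(a, b)

    def test_missing_class_rejected(self):
        Xt, Xs, y = separable_pairs(n_per_class=10, dim=30)
        onehot = np.zeros((len(y), 3), dtype=np.float32)
        onehot[:, 0] = 1.0  # only class 0 present
        with pytest.raises(ValueError, match="absent"):
            train_model(
                build_two_input_mlp(30), ((Xt, Xs), onehot), ((Xt, Xs), onehot)
            )

    def test_early_stopping_halts_on_rising_validation_loss(self):
        rng = np.random.default_rng(0)
        Xt, Xs, y = separable_pairs(n_per_class=30, dim=30)
        onehot = np.eye(3, dtype=np.float32)[
            [("healthy", "MCI", "PwD").index(v) for v in y]
        ]
        # adversarial validation labels: fitting train degrades val loss
        val_onehot = np.roll(onehot, 1, axis=1)
        cfg = TrainConfig(learning_rate=5e-2, max_epochs=100, patience=3, seed=0)
        net, hist = train_model(
            build_two_input_mlp(30), ((Xt, Xs), onehot), ((Xt, Xs), val_onehot), cfg
        )
        assert hist["stopped_epoch"] < 99
        assert len(hist["val_loss"]) == hist["stopped_epoch"] + 1

    def test_restored_weights_match_best_validation_epoch(self):
        Xt, Xs, y = separable_pairs(n_per_class=30, dim=30)
        onehot = np.eye(3, dtype=np.float32)[
            [("healthy", "MCI", "PwD").index(v) for v in y]
        ]
        val_onehot = np.roll(onehot, 1, axis=1)
        cfg = TrainConfig(learning_rate=5e-2, max_epochs=50, patience=4, seed=0)
        net, hist = train_model(
            build_two_input_mlp(30), ((Xt, Xs), onehot), ((Xt, Xs), val_onehot), cfg
        )
        probs = softmax(net.forward_logits((Xt, Xs), training=False))
        from traminer.classifier import _xent

        assert _xent(probs, val_onehot) == pytest.approx(
            hist["val_loss"][hist["best_epoch"]], abs=1e-6
        )

    def test_default_recipe_fits_separable_fixture(self):
        # 3 classes x 100 samples of image-scale feature pairs
        Xt, Xs, y = separable_pairs(n_per_class=100, dim=600)
        clf = TwoBranchMLPClassifier(input_dim=600, random_state=0)
        clf.fit(np.hstack([Xt, Xs]), y)
        acc = (clf.predict(np.hstack([Xt, Xs])) == y).mean()
        assert acc >= 0.9

    def test_loss_decreases_on_separable_fixture(self):
        Xt, Xs, y = separable_pairs(n_per_class=50, dim=60)
        onehot = np.eye(3, dtype=np.float32)[
            [("healthy", "MCI", "PwD").index(v) for v in y]
        ]
        cfg = TrainConfig(learning_rate=1e-2, max_epochs=15, patience=15, seed=1)
        _, hist = train_model(
            build_two_input_mlp(60), ((Xt, Xs), onehot), ((Xt, Xs), onehot), cfg
        )
        assert hist["train_loss"][-1] < hist["train_loss"][0]


class TestInference:
    def _trained(self):
        Xt, Xs, y = separable_pairs(n_per_class=30, dim=30)
        clf = TwoBranchMLPClassifier(
            input_dim=30, learning_rate=1e-2, max_epochs=30, random_state=0
        )
        clf.fit(np.hstack([Xt, Xs]), y)
        return clf, Xt, Xs, y

    def test_probabilities_form_a_simplex(self):
        clf, Xt, Xs, _ = self._trained()
        probs = clf.predict_proba(np.hstack([Xt, Xs]))
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_zeroed_head_predicts_uniform(self):
        net = TwoBranchMLPNet(10, rng=np.random.default_rng(0))
        head = net.head.layers[0]
        head.params["W"][:] = 0
        head.params["b"][:] = 0
        pred = predict_trajectory(net, np.ones(10), np.ones(10))
        for p in pred.probabilities.values():
            assert p == pytest.approx(1 / 3, abs=1e-6)

    def test_hand_set_weights_match_manual_forward_pass(self):
        net = TwoBranchMLPNet(
            2, hidden=2, head_batchnorm=False, rng=np.random.default_rng(0)
        )
        # make both branches the identity up to ReLU, head = sum of features
        for branch in (net.branch_traj, net.branch_speed):
            d1, _, bn1, d2, _, bn2, _ = branch.layers
            d1.params["W"][:] = np.eye(2)
            d1.params["b"][:] = 0
            d2.params["W"][:] = np.eye(2)
            d2.params["b"][:] = 0
            for bn in (bn1, bn2):
                bn.running_mean[:] = 0
                bn.running_var[:] = 1 - bn.eps
        head = net.head.layers[0]
        head.params["W"][:] = 1.0
        head.params["b"][:] = np.array([0.0, 1.0, 2.0])
        xt = np.array([0.25, 0.5], dtype=np.float32)
        xs = np.array([1.0, 0.0], dtype=np.float32)
        logits_expected = np.array([1.75, 2.75, 3.75])
        pred = predict_trajectory(net, xt, xs)
        expected = np.exp(logits_expected) / np.exp(logits_expected).sum()
        np.testing.assert_allclose(
            list(pred.probabilities.values()), expected, atol=1e-5
        )

    def test_frozen_forward_is_batch_size_invariant(self):
        clf, Xt, Xs, _ = self._trained()
        X = np.hstack([Xt, Xs])
        full = clf.predict_proba(X)
        single = np.vstack([clf.predict_proba(X[i : i + 1]) for i in range(8)])
        np.testing.assert_allclose(full[:8], single, atol=1e-6)

    def test_inference_has_no_dropout_noise(self):
        clf, Xt, Xs, _ = self._trained()
        X = np.hstack([Xt, Xs])
        np.testing.assert_array_equal(clf.predict_proba(X), clf.predict_proba(X))

    def test_shape_mismatch_rejected(self):
        clf, *_ = self._trained()
        with pytest.raises(ValueError):
            clf.predict_proba(np.ones((2, 17)))
        net = clf.net_
        with pytest.raises(ValueError):
            predict_trajectory(net, np.ones(5), np.ones(30))

    def test_prediction_validates_simplex(self):
        with pytest.raises(ValueError):
            Prediction(probabilities={"healthy": 0.9, "MCI": 0.9, "PwD": 0.9}, label="healthy")


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        Xt, Xs, y = separable_pairs(n_per_class=20, dim=30)
        X = np.hstack([Xt, Xs])
        clf = TwoBranchMLPClassifier(
            input_dim=30, learning_rate=1e-2, max_epochs=25, random_state=0
        )
        clf.fit(X, y)
        path = tmp_path / "model.npz"
        clf.save(path)
        loaded = TwoBranchMLPClassifier.load(path)
        np.testing.assert_array_equal(loaded.classes_, clf.classes_)
        np.testing.assert_allclose(
            loaded.predict_proba(X), clf.predict_proba(X), atol=1e-7
        )


class TestSklearnCompat:
    def test_get_set_params_and_clone(self):
        clf = TwoBranchMLPClassifier(input_dim=10, max_epochs=3)
        params = clf.get_params()
        assert params["input_dim"] == 10
        cloned = clone(clf)
        assert cloned.get_params() == params

    def test_validation_split_takes_ten_percent_per_class(self):
        y = np.array(["healthy"] * 100 + ["MCI"] * 40)
        train, val = stratified_validation_split(y, 0.1, seed=0)
        assert len(val) == 14
        assert sorted(np.concatenate([train, val])) == list(range(140))
        val_y = y[val]
        assert (val_y == "healthy").sum() == 10
        assert (val_y == "MCI").sum() == 4
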