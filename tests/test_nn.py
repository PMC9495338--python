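import numpy as np
import pytest

from actidep import nn

# Feature-map chain of the published layer table (height, width, channels).
TABLE_SHAPES = [
    ("input", (30, 48, 1)),
    ("conv", (26, 44, 48)),
    ("pool", (13, 22, 48)),
    ("conv", (11, 20, 48)),
    ("pool", (5, 10, 48)),
    ("conv", (3, 8, 48)),
    ("pool", (1, 4, 48)),
    ("flatten", (192,)),
    ("fc", (900,)),
    ("fc", (300,)),
    ("fc", (100,)),
    ("fc", (2,)),
]


class TestRelu:
    def test_scalar_cases(self):
        assert nn.relu(-3) == 0
        assert nn.relu(0) == 0
        assert nn.relu(2.5) == 2.5

    def test_elementwise_on_tensor(self):
        x = np.array([[-1.0, 2.0], [0.0, -0.5]])
        np.testing.assert_array_equal(nn.relu(x), [[0.0, 2.0], [0.0, 0.0]])


class TestReferenceConvolution:
    def test_scalar_kernel(self):
        out = nn.conv2d_reference(np.ones((3, 3)), np.array([[2.0]]))
        np.testing.assert_array_equal(out, np.full((3, 3), 2.0))

    def test_center_delta_kernel_recovers_center(self):
        x = np.arange(9, dtype=float).reshape(3, 3)
        w = np.zeros((3, 3))
        w[1, 1] = 1.0
        out = nn.conv2d_reference(x, w)
        assert out.shape == (1, 1)
        assert out[0, 0] == x[1, 1]

    def test_kernel_larger_than_input_rejected(self):
        with pytest.raises(ValueError):
            nn.conv2d_reference(np.ones((2, 2)), np.ones((3, 3)))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_conv_layer_with_flipped_kernel(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(5, 5))
        w = rng.normal(size=(3, 3))
        ref = nn.conv2d_reference(x, w)
        layer = nn.Conv2D(1, 1, 3)
        layer.params["W"] = w[::-1, ::-1].reshape(1, -1).copy()
        layer.params["b"] = np.zeros(1)
        out = layer.forward(x[None, None])[0, 0]
        assert np.abs(ref - out).max() < 1e-5


class TestArchitecture:
    def test_default_spec_reproduces_published_feature_maps(self):
        model = nn.build_model(seed=0)
        assert model.layer_shapes() == TABLE_SHAPES

    def test_forward_shapes_agree_with_analytic_shapes(self):
        model = nn.build_model(seed=0)
        out = model.forward(np.zeros((2, 1, 30, 48)))
        assert out.shape == (2, 2)

    def test_first_fc_width_900_on_192_features(self):
        model = nn.build_model(seed=0)
        first_fc = next(l for l in model.layers if isinstance(l, nn.Dense))
        assert (first_fc.in_features, first_fc.out_features) == (192, 900)

    def test_literal_mode_builds_and_runs(self):
        model = nn.build_model(nn.ArchitectureSpec(mode="literal"), seed=0)
        assert model.forward(np.zeros((1, 1, 30, 48))).shape == (1, 2)

    def test_collapsing_stack_rejected(self):
        spec = nn.ArchitectureSpec(input_shape=(6, 6))
        with pytest.raises(nn.ArchitectureError):
            nn.build_model(spec, seed=0)

    def test_same_seed_identical_initial_weights(self):
        a = nn.build_model(seed=5)
        b = nn.build_model(seed=5)
        for (_, la), (_, lb) in zip(a.parameters(), b.parameters()):
            for name in la.params:
                np.testing.assert_array_equal(la.params[name], lb.params[name])


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        spec = nn.ArchitectureSpec(
            filters=2, fc_sizes=(5, 2), dropout_p=0.0, input_shape=(30, 48)
        )
        model = nn.build_model(spec, seed=3)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(3, 1, 30, 48))
        y = np.array([0, 1, 1])
        loss, dlogits = nn.bce_with_logits(model.forward(X, train=True), nn.one_hot(y))
        model.backward(dlogits)
        eps = 1e-6
        for layer in model.layers:
            for name, P in layer.params.items():
                analytic = layer.grads[name]
                for _ in range(4):
                    idx = tuple(rng.integers(0, s) for s in P.shape)
                    orig = P[idx]
                    P[idx] = orig + eps
                    lp, _ = nn.bce_with_logits(
                        model.forward(X, train=True), nn.one_hot(y)
                    )
                    P[idx] = orig - eps
                    lm, _ = nn.bce_with_logits(
                        model.forward(X, train=True), nn.one_hot(y)
                    )
                    P[idx] = orig
                    numeric = (lp - lm) / (2 * eps)
                    assert numeric == pytest.approx(analytic[idx], abs=1e-7)


@pytest.fixture(scope="module")
def toy_problem():
    # two linearly separated image classes
    rng = np.random.default_rng(4)
    n = 40
    X = rng.normal(size=(n, 1, 30, 48))
    y = np.array([0, 1] * (n // 2))
    X[y == 1] += 1.5
    return X, y


class TestTraining:

    def test_history_length_equals_epochs(self, toy_problem):
        X, y = toy_problem
        model = nn.build_model(seed=1)
        hist = nn.train(
            model, (X, y), (X, y), nn.TrainingConfig(epochs=3, batch_size=16, seed=0)
        )
        assert len(hist) == 3
        assert len(hist.val_loss) == len(hist.train_acc) == 3

    def test_separable_problem_learned(self, toy_problem):
        X, y = toy_problem
        model = nn.build_model(seed=1)
        hist = nn.train(
            model, (X, y), (X, y), nn.TrainingConfig(epochs=8, batch_size=16, seed=0)
        )
        assert hist.val_acc[-1] > 0.9

    def test_training_deterministic_under_seed(self, toy_problem):
        X, y = toy_problem
        cfg = nn.TrainingConfig(epochs=2, batch_size=16, seed=6)
        h1 = nn.train(nn.build_model(seed=2), (X, y), (X, y), cfg)
        h2 = nn.train(nn.build_model(seed=2), (X, y), (X, y), cfg)
        assert h1.to_dict() == h2.to_dict()

    def test_empty_training_set_rejected(self):
        model = nn.build_model(seed=0)
        empty = (np.zeros((0, 1, 30, 48)), np.zeros(0, int))
        with pytest.raises(ValueError):
            nn.train(model, empty, empty)

    def test_predict_deterministic_dropout_off(self, toy_problem):
        X, _ = toy_problem
        model = nn.build_model(seed=8)
        s1, l1 = nn.predict(model, X[:4])
        s2, l2 = nn.predict(model, X[:4])
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_array_equal(l1, l2)
        assert s1.shape == (4, 2)

    def test_dropout_active_in_training_mode(self, toy_problem):
        X, _ = toy_problem
        model = nn.build_model(seed=8)
        a = model.forward(X[:4], train=True)
        b = model.forward(X[:4], train=True)
        assert not np.array_equal(a, b)

    def test_predict_argmax_labels(self):
        scores = np.array([[0.9, 0.2], [0.4, 0.6]])
        assert scores.argmax(axis=1).tolist() == [0, 1]  # documented convention
        model = nn.build_model(seed=0)
        _, labels = nn.predict(model, np.random.default_rng(0).normal(size=(3, 1, 30, 48)))
        assert set(labels.tolist()) <= {0, 1}

    def test_raw_count_input_warns(self):
        model = nn.build_model(seed=0)
        raw = np.full((1, 1, 30, 48), 300.0)
        with pytest.warns(UserWarning, match="raw activity counts"):
            nn.predict(model, raw)

    def test_checkpoint_round_trip(self, toy_problem, tmp_path):
        X, y = toy_problem
        model = nn.build_model(seed=1)
        cfg = nn.TrainingConfig(epochs=1, batch_size=16, seed=0)
        hist = nn.train(model, (X, y), (X, y), cfg)
        path = nn.save_checkpoint(model, tmp_path / "model.npz", cfg, hist)
        loaded, sidecar = nn.load_checkpoint(path)
        np.testing.assert_array_equal(
            nn.predict(model, X[:5])[0], nn.predict(loaded, X[:5])[0]
        )
        assert sidecar["config"]["epochs"] == 1
        assert len(sidecar["history"]["val_loss"]) == 1


class TestOverfittingCheck:
    def make_history(self, train_loss, val_loss):
        return nn.TrainingHistory(
            train_loss=[train_loss], train_acc=[0.5], val_loss=[val_loss], val_acc=[0.5]
        )

    def test_equal_losses_acceptable(self):
        assert nn.overfitting_check(self.make_history(0.4, 0.4)) == "acceptable"

    def test_val_slightly_above_train_acceptable(self):
        assert nn.overfitting_check(self.make_history(0.4, 0.5)) == "acceptable"

    def test_val_well_below_train_is_underfit(self):
        assert nn.overfitting_check(self.make_history(0.8, 0.3)) == "underfit"

    def test_val_diverging_upward_is_overfit(self):
        assert nn.overfitting_check(self.make_history(0.1, 1.2)) == "overfit"

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            nn.overfitting_check(nn.TrainingHistory())
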