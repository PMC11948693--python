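"""Classifier training: weights, loss, early stopping, prediction, HPO."""

import numpy as np
import pytest

from molaudit.featurization import mol_to_graph
from molaudit.hpo import (
    IntUniform,
    Pruner,
    TPESampler,
    Uniform,
    mlp_search_space,
    optimize_hyperparams,
)
from molaudit.modeling import (
    AdamW,
    EarlyStopper,
    MLPHyperparams,
    MLPNet,
    MPNNHyperparams,
    MPNNNet,
    TrainingConfig,
    batch_graphs,
    class_weights,
    predict_logit,
    predict_proba,
    train_model,
)


class TestClassWeights:
    def test_inverse_frequency_ratio(self):
        labels = [0] * 75 + [1] * 25
        w = class_weights(labels)
        assert w[1] / w[0] == pytest.approx(3.0)
        assert np.mean(w[np.asarray(labels)]) == pytest.approx(1.0)

    def test_balanced_labels_equal_weights(self):
        w = class_weights([0, 1, 0, 1])
        assert w[0] == w[1] == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            class_weights([1, 1, 1])


class TestEarlyStopping:
    def test_patience_arithmetic(self):
        # losses 1.0, 0.9, then ten non-improving epochs -> stop at epoch 12
        stopper = EarlyStopper(patience=10)
        losses = [1.0, 0.9] + [0.95] * 10
        stopped_at = None
        for epoch, loss in enumerate(losses, start=1):
            if stopper.update(epoch, loss):
                stopped_at = epoch
                break
        assert stopped_at == 12
        assert stopper.best_epoch == 2

    def test_snapshot_never_worse_than_any_earlier_epoch(self):
        rng = np.random.default_rng(0)
        losses = rng.random(30)
        stopper = EarlyStopper(patience=5)
        for epoch, loss in enumerate(losses, start=1):
            if stopper.update(epoch, float(loss)):
                break
        assert stopper.best == min(losses[: epoch])


def _toy_separable(n=80, dim=24, seed=0):
    rng = np.random.default_rng(seed)
    X = (rng.random((n, dim)) < 0.3).astype(float)
    y = (X[:, 0] > 0.5).astype(int)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    return X, y


class TestTraining:
    def test_separable_toy_reaches_perfect_validation(self):
        X, y = _toy_separable()
        hp = MLPHyperparams(
            n_layers=1, hidden_dim=32, dropout=0.0, weight_decay=0.0, learning_rate=3e-3
        )
        cfg = TrainingConfig(max_epochs=200, batch_size=16, seed=1, early_stopping=False)
        model = train_model(X[:60], y[:60], X[60:], y[60:], hp, cfg)
        acc = ((predict_proba(model, X[60:]) > 0.5).astype(int) == y[60:]).mean()
        assert acc == 1.0
        assert model.history["train_loss"][-1] < 0.05

    def test_deterministic_loss_curve(self):
        X, y = _toy_separable(seed=3)
        hp = MLPHyperparams(n_layers=2, hidden_dim=16, dropout=0.3)
        cfg = TrainingConfig(max_epochs=5, batch_size=16, seed=7, early_stopping=False)
        h1 = train_model(X, y, X, y, hp, cfg).history
        h2 = train_model(X, y, X, y, hp, cfg).history
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]

    def test_memorizes_random_labels_without_regularization(self):
        # overfitting testbed prerequisite: wd=0, dropout=0 memorises noise
        rng = np.random.default_rng(5)
        X = (rng.random((60, 64)) < 0.3).astype(float)
        y = (rng.random(60) < 0.5).astype(int)
        hp = MLPHyperparams(n_layers=1, hidden_dim=128, dropout=0.0, weight_decay=0.0)
        cfg = TrainingConfig(max_epochs=80, batch_size=16, seed=2, early_stopping=False)
        model = train_model(X, y, None, None, hp, cfg)
        acc = ((predict_proba(model, X) > 0.5).astype(int) == y).mean()
        assert acc >= 0.99

    def test_fixed_epoch_mode_runs_exact_count(self):
        X, y = _toy_separable(seed=4)
        cfg = TrainingConfig(max_epochs=7, batch_size=32, seed=0, early_stopping=False)
        model = train_model(X, y, None, None, MLPHyperparams(), cfg)
        assert len(model.history["train_loss"]) == 7

    def test_mpnn_trains_on_graphs(self, small_library):
        records = small_library.records[:60]
        graphs = [mol_to_graph(r) for r in records]
        y = np.array([r.label for r in records])
        hp = MPNNHyperparams(
            n_layers=1, hidden_dim=16, dropout=0.0, encoder_dim=16, message_steps=2
        )
        cfg = TrainingConfig(max_epochs=4, batch_size=16, seed=0, early_stopping=False)
        model = train_model(graphs, y, None, None, hp, cfg)
        logits = predict_logit(model, graphs)
        assert logits.shape == (60,)
        assert np.isfinite(logits).all()


class TestPrediction:
    def test_logit_zero_gives_half(self):
        from molaudit.modeling import sigmoid

        assert sigmoid(np.array([0.0]))[0] == pytest.approx(0.5)

    def test_proba_in_open_interval_and_batched_consistency(self):
        X, y = _toy_separable(seed=6)
        hp = MLPHyperparams(n_layers=1, hidden_dim=8, dropout=0.0)
        cfg = TrainingConfig(max_epochs=3, batch_size=16, seed=0, early_stopping=False)
        model = train_model(X, y, None, None, hp, cfg)
        p = predict_proba(model, X)
        assert np.all((p > 0) & (p < 1))
        singles = np.concatenate([predict_proba(model, X[i : i + 1]) for i in range(5)])
        assert np.allclose(singles, p[:5])

    def test_scheme_mismatch_rejected(self):
        X, y = _toy_separable(seed=7)
        model = train_model(
            X,
            y,
            None,
            None,
            MLPHyperparams(n_layers=1, hidden_dim=8),
            TrainingConfig(max_epochs=1, seed=0, early_stopping=False),
        )
        with pytest.raises(ValueError, match="mismatch"):
            predict_logit(model, np.zeros((2, X.shape[1] + 1)))


class TestGradients:
    """Analytic gradients match central finite differences."""

    @pytest.mark.parametrize("agg,bias", [("mean", True), ("sum", False)])
    def test_mpnn_gradcheck(self, agg, bias):
        rng = np.random.default_rng(0)
        graphs = [mol_to_graph(s) for s in ["CCO", "c1ccccc1", "CC(=O)NC"]]
        batch = batch_graphs(graphs)
        y = np.array([1.0, 0.0, 1.0])
        sw = np.ones(3)
        hp = MPNNHyperparams(
            n_layers=2,
            hidden_dim=6,
            dropout=0.0,
            encoder_dim=5,
            message_steps=2,
            aggregation=agg,
            encoder_bias=bias,
        )
        net = MPNNNet(hp, rng)
        _, grads = net.loss_and_grads(batch, y, sw, None)
        eps = 1e-6
        for p, g in zip(net.parameters(), grads):
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp, _ = net.loss_and_grads(batch, y, sw, None)
                p[idx] = orig - eps
                lm, _ = net.loss_and_grads(batch, y, sw, None)
                p[idx] = orig
                assert (lp - lm) / (2 * eps) == pytest.approx(g[idx], abs=1e-6)

    def test_mlp_gradcheck(self):
        rng = np.random.default_rng(1)
        net = MLPNet(10, MLPHyperparams(n_layers=2, hidden_dim=6, dropout=0.0), rng)
        X = rng.random((8, 10))
        y = (rng.random(8) > 0.5).astype(float)
        sw = np.ones(8)
        _, grads = net.loss_and_grads(X, y, sw, None)
        eps = 1e-6
        for p, g in zip(net.parameters(), grads):
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp, _ = net.loss_and_grads(X, y, sw, None)
                p[idx] = orig - eps
                lm, _ = net.loss_and_grads(X, y, sw, None)
                p[idx] = orig
                assert (lp - lm) / (2 * eps) == pytest.approx(g[idx], abs=1e-6)


class TestHPO:
    def test_budget_one_returns_single_point_inside_space(self):
        X, y = _toy_separable()
        res = optimize_hyperparams(
            X[:60], y[:60], X[60:], y[60:], budget=1, seed=0, max_epochs=2
        )
        space = mlp_search_space()
        for name, dim in space.items():
            assert dim.contains(getattr(res.best_params, name))

    def test_same_seed_same_selection(self):
        X, y = _toy_separable(seed=9)
        kwargs = dict(budget=4, seed=3, max_epochs=2)
        a = optimize_hyperparams(X[:60], y[:60], X[60:], y[60:], **kwargs)
        b = optimize_hyperparams(X[:60], y[:60], X[60:], y[60:], **kwargs)
        assert a.best_params == b.best_params
        assert a.best_loss == b.best_loss

    def test_tpe_respects_bounds_after_startup(self):
        space = {"x": Uniform(0.0, 1.0), "k": IntUniform(2, 5, log=True)}
        sampler = TPESampler(space, seed=0, n_startup=3)
        history = []
        rng = np.random.default_rng(0)
        for i in range(30):
            params = sampler.suggest(history)
            assert 0.0 <= params["x"] <= 1.0
            assert 2 <= params["k"] <= 5
            history.append((params, (params["x"] - 0.3) ** 2 + rng.random() * 0.01))
        # TPE should concentrate near the optimum once past startup
        late = [p["x"] for p, _ in history[20:]]
        assert abs(np.median(late) - 0.3) < 0.25

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            TPESampler({}, seed=0)

    def test_pruner_two_epoch_stagnation(self):
        cb = Pruner().make_callback()
        assert cb(1, 1.0) is False
        assert cb(2, 0.9) is False
        assert cb(3, 0.95) is False  # one bad epoch
        assert cb(4, 0.92) is True  # two consecutive non-improving

    def test_pruner_median_rule_at_checkpoint(self):
        pruner = Pruner()
        pruner.checkpoint_losses = [0.5, 0.6, 0.7]
        cb = pruner.make_callback()
        for epoch in range(1, 15):
            assert cb(epoch, 1.0 - 0.01 * epoch) is False
        assert cb(15, 0.86) is True  # worse than median 0.6 at epoch 15
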