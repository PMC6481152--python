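"""Architecture arithmetic, closed forms, gradients, and training behavior."""

import numpy as np
import pytest

from mcseg.nn import (
    InvalidConfigError,
    NetworkConfig,
    TrainSchedule,
    build_network,
    crossentropy,
    feature_map_side,
    softmax_posterior,
    train,
)
from mcseg.nn.network import CROSSENTROPY_EPS, make_adam
from mcseg.nn.training import evaluate_loss, make_eval_set
from mcseg.patches import sample_minibatch

TINY_FILTERS = (2, 2, 3, 3, 4, 4)


class TestFeatureMapSide:
    def test_valid_path_49_contracts_to_2(self):
        assert feature_map_side(49, "valid") == 2

    def test_same_path_49_gives_12(self):
        assert feature_map_side(49, "same") == 12

    def test_valid_path_29_underflows(self):
        with pytest.raises(InvalidConfigError, match="conv 5"):
            feature_map_side(29, "valid")

    def test_even_or_small_sides_rejected(self):
        with pytest.raises(ValueError):
            feature_map_side(48, "valid")
        with pytest.raises(ValueError):
            feature_map_side(7, "same")

    @pytest.mark.parametrize("padding", ["same", "valid"])
    def test_agrees_with_instantiated_forward_pass(self, padding):
        """The recurrence equals the spatial shape of a real forward pass."""
        rng = np.random.default_rng(0)
        sides = [9, 13, 21, 29, 35, 49, 61, 75, 99, 121]
        checked = 0
        for n in sides:
            try:
                predicted = feature_map_side(n, padding)
            except InvalidConfigError:
                continue
            cfg = NetworkConfig(patch_side=n, padding_mode=padding, conv_filters=TINY_FILTERS)
            net = build_network(cfg, seed=1)
            out = rng.normal(size=(1, 1, n, n)).astype(np.float32)
            actual = None
            for layer in net.layers:
                out = layer.forward(out, False, None)
                if out.ndim == 4:
                    actual = out.shape[-1]
            assert actual == predicted
            checked += 1
        assert checked >= 5


class TestSoftmax:
    def test_symmetric_scores(self):
        assert np.allclose(softmax_posterior([0.0, 0.0]), [0.5, 0.5])

    def test_closed_form_ln3(self):
        assert np.allclose(softmax_posterior([np.log(3), 0.0]), [0.75, 0.25])

    def test_shift_invariance(self):
        s = np.array([1.3, -0.7])
        for c in (5.0, -300.0, 1e4):
            assert np.allclose(softmax_posterior(s), softmax_posterior(s + c))

    def test_sums_to_one_and_positive(self):
        rng = np.random.default_rng(1)
        s = rng.normal(scale=50, size=(10_000, 2))
        p = softmax_posterior(s)
        assert np.all(p > 0)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            softmax_posterior([np.inf, 0.0])


class TestCrossentropy:
    def test_perfect_prediction_is_zero(self):
        assert crossentropy([1, 0], [1, 0]) == 0.0

    def test_uniform_prediction_is_ln2(self):
        assert np.isclose(crossentropy([1, 0], [0.5, 0.5]), np.log(2))
        assert np.isclose(crossentropy([0, 1], [0.5, 0.5]), np.log(2))

    def test_non_negative(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            p = rng.dirichlet([1, 1])
            assert crossentropy([0, 1], p) >= 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            crossentropy([1, 0, 0], [0.5, 0.5])


class TestBuildNetwork:
    def test_same_seed_identical_weights(self):
        cfg = NetworkConfig(patch_side=9, padding_mode="same", conv_filters=TINY_FILTERS)
        a, b = build_network(cfg, seed=3), build_network(cfg, seed=3)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa, pb)

    def test_flatten_size_valid_49(self):
        cfg = NetworkConfig(patch_side=49, padding_mode="valid", conv_filters=TINY_FILTERS)
        assert cfg.flatten_size == 2 * 2 * TINY_FILTERS[-1]

    def test_zero_patch_forward_is_finite(self):
        cfg = NetworkConfig(patch_side=9, padding_mode="same", conv_filters=TINY_FILTERS)
        net = build_network(cfg, seed=4)
        scores = net.forward(np.zeros((1, 1, 9, 9), dtype=np.float32), train=False)
        assert scores.shape == (1, 2) and np.all(np.isfinite(scores))

    def test_tie_breaks_toward_negative(self):
        cfg = NetworkConfig(patch_side=9, padding_mode="same", conv_filters=TINY_FILTERS)
        net = build_network(cfg, seed=5)
        for layer in net.layers:  # zero every weight => exact posterior tie
            for p in layer.params:
                p[...] = 0
        pred = net.predict(np.ones((3, 1, 9, 9), dtype=np.float32))
        assert np.all(pred == 0)


def test_backprop_matches_numerical_gradient():
    """Central-difference check of every parameter group (float64, no dropout)."""
    cfg = NetworkConfig(
        patch_side=9, padding_mode="same", conv_filters=TINY_FILTERS,
        fc_units=6, dropout_rate=0.0,
    )
    net = build_network(cfg, seed=2, dtype=np.float64)
    rng = np.random.default_rng(3)
    x = rng.normal(size=(4, 1, 9, 9))
    y = np.zeros((4, 2))
    y[np.arange(4), rng.integers(0, 2, 4)] = 1

    def loss_fn():
        p = softmax_posterior(net.forward(x, train=True, rng=None))
        return float(-(y * np.log(np.clip(p, CROSSENTROPY_EPS, None))).sum() / 4)

    net.loss_and_grad(x, y, None)
    grads = [g.copy() for g in net.gradients()]
    eps = 1e-5
    check_rng = np.random.default_rng(5)
    for p, g in zip(net.parameters(), grads):
        flat = p.ravel()
        for i in check_rng.choice(flat.size, size=min(4, flat.size), replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            lp = loss_fn()
            flat[i] = orig - eps
            lm = loss_fn()
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            ana = g.ravel()[i]
            assert abs(num - ana) / max(abs(num), abs(ana), 1e-4) < 1e-5


class TestTraining:
    @pytest.fixture()
    def tiny_setup(self, small_db):
        # shrink N=21 db windows is fixed; use a small net matching N=21
        cfg = NetworkConfig(
            patch_side=21, padding_mode="same", conv_filters=(4, 4, 6, 6, 8, 8),
            dropout_rate=0.0,
        )
        return cfg, small_db

    def test_loss_decreases_over_first_100_steps(self, tiny_setup):
        """Median initial-vs-final loss drop over 5 seeds."""
        cfg, db = tiny_setup
        drops = []
        for seed in range(5):
            schedule = TrainSchedule(batch_size=16, max_steps=100, eval_every=50, seed=seed)
            val = make_eval_set(db, "detector", 64, np.random.default_rng(seed), split="train")
            model = train(cfg, db, "detector", schedule, val)
            loss = model.history["train_loss"]
            drops.append(np.mean(loss[:10]) - np.mean(loss[-10:]))
        assert np.median(drops) > 0

    def test_overfits_32_memorizable_patches(self, small_db):
        """Capacity sanity check: a tiny balanced set is memorized exactly."""
        cfg = NetworkConfig(
            patch_side=21, padding_mode="same", conv_filters=(4, 4, 6, 6, 8, 8),
            dropout_rate=0.0,
        )
        fixed = sample_minibatch(small_db, "detector", 32, np.random.default_rng(0))
        net = build_network(cfg, seed=0)
        adam = make_adam(net, 1e-3)
        acc = 0.0
        for _ in range(500):
            _, acc = net.loss_and_grad(fixed.pixels, fixed.labels, None)
            adam.step(net.gradients())
            if acc == 1.0:
                break
        assert acc == 1.0

    def test_plateau_halves_learning_rate(self, tiny_setup, monkeypatch):
        """Non-improving validation evals halve the lr: 1e-3 -> 5e-4."""
        cfg, db = tiny_setup
        losses = iter([1.0, 1.1, 1.2, 1.3, 1.4, 1.5, 1.6, 1.7, 1.8])
        monkeypatch.setattr(
            "mcseg.nn.training.evaluate_loss", lambda *a, **k: (next(losses), 0.5)
        )
        schedule = TrainSchedule(
            batch_size=8, max_steps=9, eval_every=1, plateau_patience=2,
            early_stop_patience=4, seed=0,
        )
        val = make_eval_set(db, "detector", 8, np.random.default_rng(0), split="train")
        model = train(cfg, db, "detector", schedule, val)
        events = model.history["lr_events"]
        assert events and events[0][1] == pytest.approx(5e-4)
        # early stop after 4 bad evals; best weights predate the rise
        assert model.stopping_step == 1

    def test_early_stop_returns_best_weights(self, tiny_setup):
        cfg, db = tiny_setup
        rng = np.random.default_rng(1)
        val = make_eval_set(db, "segmentator", 64, rng, split="train")
        schedule = TrainSchedule(batch_size=16, max_steps=60, eval_every=10, seed=1)
        model = train(cfg, db, "segmentator", schedule, val)
        loss_now, _ = evaluate_loss(model.network, val.pixels, val.labels)
        assert loss_now == pytest.approx(min(model.history["val_loss"]), abs=1e-6)

    def test_divergence_raises(self, tiny_setup):
        cfg, db = tiny_setup
        net = build_network(cfg, seed=0)
        net.parameters()[0][...] = np.nan
        val = make_eval_set(db, "detector", 8, np.random.default_rng(0), split="train")
        from mcseg.nn import DivergenceError

        with pytest.raises(DivergenceError):
            train(net, db, "detector", TrainSchedule(batch_size=8, max_steps=5), val)


def test_model_roundtrip_through_hdf5(tmp_path, small_db):
    from mcseg.nn import TrainedModel

    cfg = NetworkConfig(patch_side=21, padding_mode="same", conv_filters=TINY_FILTERS)
    net = build_network(cfg, seed=6)
    model = TrainedModel(config=cfg, network=net, role="detector", stopping_step=17)
    path = tmp_path / "m.h5"
    model.save(path)
    loaded = TrainedModel.load(path)
    x = np.random.default_rng(7).normal(size=(4, 1, 21, 21)).astype(np.float32)
    assert np.allclose(model.predict_proba(x), loaded.predict_proba(x))
    assert loaded.role == "detector" and loaded.stopping_step == 17
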