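"""RBM stack, fuzzification, rule evolution, and the quality predictor."""

import numpy as np
import pytest

from nriqa import sdbfn
from nriqa.errors import InvalidArgumentError, InvalidInputError, StateError
from nriqa.sdbfn import (
    INITIAL_SENSITIVITY,
    RbmLayer,
    RuleNode,
    SdbfnConfig,
    SdbfnModel,
    cd1_update,
    evolve_sensitivity,
    forward_stack,
    fuzzy_distance,
    predict,
    predict_scores,
    pretrain_stack,
    rbm_hidden_prob,
    rbm_visible_prob,
    rule_activation,
    saturated_linear,
    train,
    update_rule_weights,
)


def logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


@pytest.fixture
def layer(rng):
    return RbmLayer(
        W=rng.normal(0, 1, (3, 2)),
        hidden_bias=rng.normal(0, 1, 2),
        visible_bias=rng.normal(0, 1, 3),
    )


class TestRbmProbabilities:
    def test_zero_parameters_give_half(self):
        layer = RbmLayer(np.zeros((3, 2)), np.zeros(2), np.zeros(3))
        np.testing.assert_allclose(rbm_hidden_prob(np.ones(3), layer), 0.5)
        np.testing.assert_allclose(rbm_visible_prob(np.ones(2), layer), 0.5)

    def test_large_bias_saturates(self):
        layer = RbmLayer(np.zeros((2, 2)), np.full(2, 20.0), np.zeros(2))
        assert (rbm_hidden_prob(np.zeros(2), layer) > 0.999).all()

    def test_matches_direct_formula(self, layer, rng):
        v = rng.random(3)
        expected = logistic(layer.hidden_bias + v @ layer.W)
        np.testing.assert_allclose(rbm_hidden_prob(v, layer), expected)
        h = rng.random(2)
        expected_v = logistic(layer.visible_bias + layer.W @ h)
        np.testing.assert_allclose(rbm_visible_prob(h, layer), expected_v)

    def test_transpose_symmetry(self, layer, rng):
        """Visible probabilities equal hidden probabilities of the flipped RBM."""
        h = rng.random(2)
        flipped = RbmLayer(layer.W.T.copy(), layer.visible_bias, layer.hidden_bias)
        np.testing.assert_allclose(
            rbm_visible_prob(h, layer), rbm_hidden_prob(h, flipped)
        )

    def test_shape_mismatch_rejected(self, layer):
        with pytest.raises(InvalidInputError):
            rbm_hidden_prob(np.ones(5), layer)


class TestCd1:
    def test_vanishing_learning_rate_limit(self, layer):
        batch = np.array([[1.0, 0.0, 1.0]])
        out = cd1_update(layer, batch, learning_rate=1e-12, seed=0)
        np.testing.assert_allclose(out.W, layer.W, atol=1e-9)

    def test_matches_hand_simulation(self):
        """CD-1 on a 2x2 RBM equals a step-by-step replay of the chain."""
        rng_init = np.random.default_rng(42)
        layer = RbmLayer(
            W=rng_init.normal(0, 0.5, (2, 2)),
            hidden_bias=rng_init.normal(0, 0.5, 2),
            visible_bias=rng_init.normal(0, 0.5, 2),
        )
        batch = np.array([[1, 0], [0, 1], [1, 1], [0, 0]], dtype=float)
        seed = 7
        out = cd1_update(layer, batch, learning_rate=0.5, seed=seed)

        # oracle: replay the sampling chain with the same generator state
        rng = np.random.default_rng(seed)
        ph = logistic(layer.hidden_bias + batch @ layer.W)
        h_sample = (rng.random(ph.shape) < ph).astype(float)
        pv = logistic(layer.visible_bias + h_sample @ layer.W.T)
        ph2 = logistic(layer.hidden_bias + pv @ layer.W)
        B = 4
        dW = np.zeros((2, 2))
        for b in range(B):  # explicit per-sample outer products
            dW += np.outer(batch[b], ph[b]) - np.outer(pv[b], ph2[b])
        dW /= B
        np.testing.assert_allclose(out.W, layer.W + 0.5 * dW, atol=1e-12)
        np.testing.assert_allclose(
            out.hidden_bias, layer.hidden_bias + 0.5 * (ph - ph2).mean(0), atol=1e-12
        )
        np.testing.assert_allclose(
            out.visible_bias, layer.visible_bias + 0.5 * (batch - pv).mean(0),
            atol=1e-12,
        )

    def test_empty_batch_rejected(self, layer):
        with pytest.raises(InvalidInputError):
            cd1_update(layer, np.empty((0, 3)), 0.1, seed=0)


class TestPretrainStack:
    def test_zero_epochs_random_layer_valid_shape(self, rng):
        data = rng.random((10, 6))
        stack = pretrain_stack(data, [6], epochs=0, seed=0)
        assert len(stack) == 1
        assert forward_stack(data, stack).shape == (10, 6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_reconstruction_error_nonincreasing(self, seed):
        """Mean squared reconstruction error drops over training epochs."""
        rng = np.random.default_rng(seed)
        centers = np.array([[0.9, 0.9, 0.1, 0.1], [0.1, 0.1, 0.9, 0.9]])
        data = np.clip(
            centers[rng.integers(0, 2, 40)] + rng.normal(0, 0.05, (40, 4)), 0, 1
        )

        def recon_error(stack):
            h = rbm_hidden_prob(data, stack[0])
            v = rbm_visible_prob(h, stack[0])
            return ((data - v) ** 2).mean()

        first = recon_error(pretrain_stack(data, [8], epochs=1, seed=seed))
        last = recon_error(pretrain_stack(data, [8], epochs=40, seed=seed))
        assert last <= first

    def test_deterministic(self, rng):
        data = rng.random((10, 4))
        a = pretrain_stack(data, [4, 2], epochs=5, seed=3)
        b = pretrain_stack(data, [4, 2], epochs=5, seed=3)
        for la, lb in zip(a, b):
            np.testing.assert_array_equal(la.W, lb.W)


class TestFuzzification:
    def test_exact_exemplar_hit(self):
        rules = [RuleNode(np.zeros(2), 0.5), RuleNode(np.ones(2), 0.5)]
        e = fuzzy_distance(np.zeros(2), rules)
        np.testing.assert_allclose(e, [0.0, 1.0])

    def test_equidistant_halves(self):
        rules = [RuleNode(np.zeros(1), 0.5), RuleNode(np.ones(1), 0.5)]
        e = fuzzy_distance(np.array([0.5]), rules)
        np.testing.assert_allclose(e, [0.5, 0.5])

    def test_distances_sum_to_one(self, rng):
        rules = [RuleNode(rng.random(4), 0.5) for _ in range(5)]
        for _ in range(200):
            e = fuzzy_distance(rng.random(4), rules)
            assert e.sum() == pytest.approx(1.0)
            assert (e >= 0).all() and (e <= 1).all()

    def test_degenerate_all_equal(self):
        x = np.array([0.3, 0.7])
        rules = [RuleNode(x.copy(), 0.5), RuleNode(x.copy(), 0.5)]
        np.testing.assert_allclose(fuzzy_distance(x, rules), [0.5, 0.5])

    def test_activation_complement(self, rng):
        e = fuzzy_distance(
            rng.random(3), [RuleNode(rng.random(3), 0.5) for _ in range(4)]
        )
        np.testing.assert_allclose(rule_activation(e) + e, 1.0)


class TestSensitivityEvolution:
    def test_at_threshold_unchanged(self):
        rule = RuleNode(np.zeros(2), 0.5, 0.3)
        out = evolve_sensitivity(rule, mu=5.0, delta_thr=5.0, x=10.0)
        assert out.sensitivity == 0.3

    def test_fresh_rule_default(self):
        assert RuleNode(np.zeros(2), 0.5).sensitivity == INITIAL_SENSITIVITY == 0.3

    def test_busy_rule_decreases(self):
        rule = RuleNode(np.zeros(2), 0.5, 0.3)
        out = evolve_sensitivity(rule, mu=8.0, delta_thr=5.0, x=10.0)
        assert out.sensitivity == pytest.approx(0.3 * (1 - 0.3))

    def test_idle_rule_increases(self):
        rule = RuleNode(np.zeros(2), 0.5, 0.3)
        out = evolve_sensitivity(rule, mu=2.0, delta_thr=5.0, x=10.0)
        assert out.sensitivity == pytest.approx(0.3 * 1.2)

    def test_large_time_increment_vanishing_update(self):
        rule = RuleNode(np.zeros(2), 0.5, 0.3)
        out = evolve_sensitivity(rule, mu=8.0, delta_thr=5.0, x=1e9)
        assert out.sensitivity == pytest.approx(0.3, abs=1e-8)

    def test_bad_increment_rejected(self):
        with pytest.raises(InvalidArgumentError):
            evolve_sensitivity(RuleNode(np.zeros(2), 0.5), 1.0, 0.5, x=0.0)


class TestSaturatedLinear:
    @pytest.mark.parametrize("v,expected", [(-0.5, 0.0), (1.5, 1.0), (0.4, 0.4)])
    def test_clamping(self, v, expected):
        assert saturated_linear(v) == expected


class TestRuleWeightUpdates:
    def test_exemplar_fixed_at_input(self):
        rule = RuleNode(np.array([0.2, 0.8]), 0.5)
        out = update_rule_weights(rule, rule.exemplar, 1.0, 0.1, 0.1, 0.1)
        np.testing.assert_array_equal(out.exemplar, rule.exemplar)

    def test_geometric_contraction(self):
        """Repeated exemplar updates shrink the gap by (1-kappa1)^t exactly."""
        q = np.array([1.0, 0.0])
        rule = RuleNode(np.array([0.0, 1.0]), 0.5)
        kappa1 = 0.1
        gap0 = np.linalg.norm(rule.exemplar - q)
        for t in range(1, 30):
            rule = update_rule_weights(rule, q, 0.0, 0.0, kappa1, 0.1)
            gap = np.linalg.norm(rule.exemplar - q)
            assert gap == pytest.approx(gap0 * (1 - kappa1) ** t, abs=1e-10)

    def test_consequent_clamped(self):
        rule = RuleNode(np.zeros(1), 0.95)
        out = update_rule_weights(rule, np.zeros(1), 1.0, 10.0, 0.1, 0.5)
        assert out.consequent == 1.0


class TestPredict:
    def test_single_rule_at_exemplar(self):
        model = SdbfnModel(rbm_stack=[], rules=[RuleNode(np.array([0.2, 0.2]), 0.9)])
        score, label = predict(model, np.array([0.2, 0.2]))
        assert score == pytest.approx(0.9)
        assert label == "High"

    def test_two_rules_equidistant_average(self):
        rules = [RuleNode(np.zeros(2), 0.2), RuleNode(np.ones(2), 0.8)]
        model = SdbfnModel(rbm_stack=[], rules=rules)
        score, label = predict(model, np.full(2, 0.5))
        assert score == pytest.approx(0.5)
        assert label == "High"  # threshold tie goes High

    def test_score_bounded_by_consequents(self, rng):
        rules = [RuleNode(rng.random(3), c) for c in (0.2, 0.5, 0.7)]
        model = SdbfnModel(rbm_stack=[], rules=rules)
        for _ in range(100):
            score, _ = predict(model, rng.random(3))
            assert 0.2 - 1e-12 <= score <= 0.7 + 1e-12

    def test_untrained_model_rejected(self):
        with pytest.raises(StateError):
            predict(SdbfnModel(rbm_stack=[], rules=[]), np.zeros(2))


class TestTrain:
    def test_first_sample_creates_rule(self, rng):
        X = rng.random((2, 4))
        model = train(SdbfnConfig(hidden_sizes=(4,)), X, np.array([0.3, 0.7]),
                      epochs=1, seed=0)
        assert len(model.rules) >= 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_two_cluster_recovery(self, seed):
        """Well-separated clusters with scores 0.1/0.9 are learned to 0.15."""
        rng = np.random.default_rng(200 + seed)
        n = 40
        a = rng.normal(0.2, 0.05, (n, 6))
        b = rng.normal(0.8, 0.05, (n, 6))
        X = np.empty((2 * n, 6))
        X[0::2], X[1::2] = a, b
        y = np.empty(2 * n)
        y[0::2], y[1::2] = 0.1, 0.9
        X = np.clip(X, 0, 1)
        model = train(SdbfnConfig(), X, y, epochs=20, seed=seed)
        assert len(model.rules) >= 2
        pred = predict_scores(model, X)
        assert np.abs(pred[0::2] - 0.1).max() <= 0.15
        assert np.abs(pred[1::2] - 0.9).max() <= 0.15

    def test_deterministic(self, rng):
        X = rng.random((20, 5))
        y = np.clip(X[:, 0], 0, 1)
        a = train(SdbfnConfig(), X, y, epochs=5, seed=9)
        b = train(SdbfnConfig(), X, y, epochs=5, seed=9)
        assert len(a.rules) == len(b.rules)
        for ra, rb in zip(a.rules, b.rules):
            np.testing.assert_array_equal(ra.exemplar, rb.exemplar)
            assert ra.consequent == rb.consequent

    def test_targets_outside_unit_interval_rejected(self, rng):
        X = rng.random((5, 3))
        with pytest.raises(InvalidInputError):
            train(SdbfnConfig(), X, np.array([0.1, 0.5, 1.2, 0.3, 0.4]),
                  epochs=1, seed=0)


def test_model_json_roundtrip(tmp_path, rng):
    X = rng.random((15, 4))
    y = np.clip(X[:, 0], 0, 1)
    model = train(SdbfnConfig(), X, y, epochs=3, seed=1)
    path = tmp_path / "model.json"
    sdbfn.save_model(model, path)
    loaded = sdbfn.load_model(path)
    np.testing.assert_allclose(
        predict_scores(loaded, X), predict_scores(model, X), atol=1e-15
    )
    assert loaded.config == model.config
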