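"""Reptile-search optimizer: operators, phases, convergence, wrappers."""

import numpy as np
import pytest

from nriqa import mrsa
from nriqa.errors import InvalidArgumentError, InvalidInputError, OptimizationError
from nriqa.mrsa import (
    MrsaParams,
    evolutionary_ratio,
    hunting_ratio,
    init_population,
    mean_position,
    optimize,
    reduction_function,
    select_features,
    step,
)


def sphere(x):
    return float((x**2).sum())


def make_params(**kw):
    d = kw.pop("dim", 5)
    defaults = dict(
        pop_size=20,
        dim=d,
        lower=-5.0 * np.ones(d),
        upper=5.0 * np.ones(d),
        n_max=200,
        seed=1,
    )
    defaults.update(kw)
    return MrsaParams(**defaults)


class TestInitPopulation:
    def test_within_bounds(self):
        state = init_population(make_params())
        p = make_params()
        assert (state.F >= p.lower).all() and (state.F <= p.upper).all()

    def test_deterministic(self):
        a = init_population(make_params())
        b = init_population(make_params())
        np.testing.assert_array_equal(a.F, b.F)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(InvalidArgumentError):
            make_params(lower=np.zeros(5), upper=np.array([1, 1, 0, 1, 1.0]))


class TestOperators:
    @pytest.mark.parametrize("vec,expected", [([1, 2, 3], 2.0), ([7, 7], 7.0), ([-1, 1], 0.0)])
    def test_mean_position(self, vec, expected):
        assert mean_position(vec) == expected

    def test_mean_position_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            mean_position([])

    def test_evolutionary_ratio_degenerate(self):
        assert evolutionary_ratio(1, 1, 0.73) == 0.0

    def test_evolutionary_ratio_value(self):
        assert evolutionary_ratio(1, 1000, 1.0) == pytest.approx(1.998)

    def test_evolutionary_ratio_bounded(self):
        """|D| never exceeds 2 over a dense (r3, N) grid."""
        worst = max(
            abs(evolutionary_ratio(1, N, r3))
            for N in range(1, 1001)
            for r3 in np.linspace(-1, 1, 201)
        )
        assert worst <= 2.0

    def test_evolutionary_ratio_bad_n(self):
        with pytest.raises(InvalidArgumentError):
            evolutionary_ratio(1, 0, 0.5)

    def test_reduction_function_zero_at_best(self):
        assert reduction_function(1.3, 1.3) == 0.0

    def test_hunting_ratio_alpha_at_mean(self):
        """q reduces to alpha when the coordinate equals the mean position."""
        assert hunting_ratio(2.0, 2.0, 1.5, 4.0, alpha=0.1) == pytest.approx(0.1)


class TestPhases:
    @pytest.mark.parametrize(
        "n,expected", [(25, 1), (26, 2), (50, 2), (51, 3), (75, 3), (76, 4), (100, 4)]
    )
    def test_boundaries_at_nmax_100(self, n, expected):
        assert mrsa._phase(n, 100) == expected

    def test_nmax_4_visits_every_phase_once(self):
        assert [mrsa._phase(n, 4) for n in (1, 2, 3, 4)] == [1, 2, 3, 4]


class TestOptimize:
    def test_sphere_converges(self):
        params = make_params()
        state = init_population(params)
        state.fitness = np.array([sphere(x) for x in state.F])
        initial_best = state.fitness.min()
        _, best_f, _ = optimize(sphere, params)
        assert best_f < 0.01 * initial_best

    def test_history_monotone_and_full_length(self):
        _, _, history = optimize(sphere, make_params(n_max=50))
        assert len(history) == 50
        assert all(a >= b for a, b in zip(history, history[1:]))

    def test_constant_fitness_stable(self):
        _, best_f, history = optimize(lambda x: 1.0, make_params(n_max=20))
        assert best_f == 1.0 and set(history) == {1.0}

    def test_deterministic(self):
        a = optimize(sphere, make_params())
        b = optimize(sphere, make_params())
        assert a[2] == b[2]
        np.testing.assert_array_equal(a[0], b[0])

    def test_positions_stay_in_bounds(self):
        params = make_params(n_max=40)
        state = init_population(params)
        for _ in range(params.n_max):
            step(state, params, sphere)
            assert (state.F >= params.lower).all()
            assert (state.F <= params.upper).all()

    def test_non_finite_fitness_raises(self):
        with pytest.raises(OptimizationError):
            optimize(lambda x: float("nan"), make_params(n_max=5))

    def test_quadratic_minimum_located(self):
        """On a shifted 2-D quadratic the optimum lands in the right grid cell."""
        target = np.array([1.3, -2.1])

        def f(x):
            return float(((x - target) ** 2).sum())

        for seed in (0, 1, 2):
            params = make_params(dim=2, lower=-5 * np.ones(2), upper=5 * np.ones(2), seed=seed)
            best_x, _, _ = optimize(f, params)
            cell = 10.0 / 50  # 50x50 grid over [-5, 5]^2
            assert np.all(np.abs(best_x - target) <= cell)


class TestSelectFeatures:
    def test_recovers_informative_features(self):
        """Features 1-3 drive y linearly; 17 noise columns; 4/5 seeds recover."""
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X = rng.random((120, 20))
            y = 0.5 * X[:, 0] + 0.3 * X[:, 1] + 0.2 * X[:, 2]
            params = MrsaParams(
                pop_size=15, dim=20, lower=np.zeros(20), upper=np.ones(20),
                n_max=60, seed=seed,
            )
            result = select_features(
                X, y, evaluator=mrsa.make_cv_evaluator(seed=seed), params=params
            )
            hits += bool(result.mask[:3].all())
        assert hits >= 4

    def test_empty_mask_never_wins(self):
        rng = np.random.default_rng(0)
        X = rng.random((30, 4))
        y = X[:, 0]
        params = MrsaParams(
            pop_size=5, dim=4, lower=np.zeros(4), upper=np.ones(4), n_max=10, seed=0
        )
        result = select_features(X, y, params=params)
        assert result.mask.any()

    def test_zero_size_weight_reduces_to_error(self):
        rng = np.random.default_rng(0)
        X = rng.random((30, 3))
        y = X[:, 0]
        calls = {}

        def evaluator(Xs, ys):
            calls[Xs.shape[1]] = calls.get(Xs.shape[1], 0) + 1
            return 0.25

        params = MrsaParams(
            pop_size=4, dim=3, lower=np.zeros(3), upper=np.ones(3), n_max=6, seed=0
        )
        result = select_features(X, y, evaluator=evaluator, params=params, w_size=1e-12)
        # all non-empty masks share the same fitness 0.99*0.25 (+ negligible size term)
        non_empty = [f for f, m in result.candidates if m.any()]
        assert np.allclose(non_empty, 0.99 * 0.25, atol=1e-9)

    def test_no_features_rejected(self):
        with pytest.raises(InvalidInputError):
            select_features(np.empty((5, 0)), np.zeros(5))


class TestTuneSdbfn:
    @staticmethod
    def _data(seed=0):
        rng = np.random.default_rng(seed)
        X = rng.random((40, 4))
        y = np.clip(0.8 * X[:, 0] + 0.1, 0, 1)
        return (X[:30], y[:30]), (X[30:], y[30:])

    def test_collapsed_box_returns_point(self):
        train, val = self._data()
        cfg, _ = mrsa.tune_sdbfn(
            {"kappa1": (0.2, 0.2), "kappa2": (0.3, 0.3)}, train, val, epochs=3
        )
        assert cfg["kappa1"] == pytest.approx(0.2)
        assert cfg["kappa2"] == pytest.approx(0.3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_tuning_never_hurts(self, seed):
        """Tuned validation RMSE is at most the default configuration's."""
        from nriqa.evaluate import rmse
        from nriqa.sdbfn import SdbfnConfig, predict_scores, train as sdbfn_train

        train_d, val_d = self._data(seed)
        params = MrsaParams(
            pop_size=4, dim=2, lower=np.array([0.05, 0.05]),
            upper=np.array([0.4, 0.4]), n_max=8, seed=seed,
        )
        _, tuned_f = mrsa.tune_sdbfn(
            {"kappa1": (0.05, 0.4), "kappa2": (0.05, 0.4)},
            train_d, val_d, params=params, epochs=5, seed=seed,
        )
        model = sdbfn_train(SdbfnConfig(), train_d[0], train_d[1], epochs=5, seed=seed)
        default_f = rmse(predict_scores(model, val_d[0]), val_d[1])
        assert tuned_f <= default_f + 1e-12

    def test_deterministic(self):
        train, val = self._data()
        params = MrsaParams(
            pop_size=3, dim=2, lower=np.array([0.05, 0.05]),
            upper=np.array([0.4, 0.4]), n_max=4, seed=7,
        )
        a = mrsa.tune_sdbfn({"kappa1": (0.05, 0.4), "kappa2": (0.05, 0.4)},
                            train, val, params=params, epochs=3)
        b = mrsa.tune_sdbfn({"kappa1": (0.05, 0.4), "kappa2": (0.05, 0.4)},
                            train, val, params=params, epochs=3)
        assert a[1] == b[1] and a[0] == b[0]
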