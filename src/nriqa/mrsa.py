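"""Reptile search metaheuristic with feature-selection and tuning wrappers.

A population of candidate solutions ("crocodiles") explores a box-bounded
search space in four phases over the iteration budget: high walking and
belly walking (global encircling, first half of the iterations) followed
by hunting coordination and cooperation (local exploitation, second
half).  The update rules use a per-dimension hunting operator
``delta = best * q``, a reduction function ``H``, and an evolutionary
ratio ``D``; positions are clamped to the bounds after every update and
the best-so-far solution is tracked greedily, so the recorded best
fitness is monotone non-increasing (minimization convention).

Wrappers map the continuous optimizer onto wrapper feature selection
(threshold positions in [0,1] at 0.5, fitness = weighted classification
or regression error plus subset-size penalty) and onto hyperparameter
search for the fuzzy-network predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import InvalidArgumentError, InvalidInputError, OptimizationError

__all__ = [
    "MrsaParams",
    "OptimizerState",
    "init_population",
    "mean_position",
    "evolutionary_ratio",
    "reduction_function",
    "hunting_ratio",
    "step",
    "optimize",
    "select_features",
    "SelectionResult",
    "make_cv_evaluator",
    "make_sdbfn_cv_evaluator",
    "tune_sdbfn",
]


@dataclass(frozen=True)
class MrsaParams:
    """Population size, dimension, box bounds, and the search constants.

    ``alpha`` controls the hunting-ratio offset and ``beta`` the
    high-walk search precision (both 0.1 by default); ``epsilon`` guards
    divisions by near-zero denominators.
    """

    pop_size: int
    dim: int
    lower: np.ndarray
    upper: np.ndarray
    n_max: int
    alpha: float = 0.1
    beta: float = 0.1
    epsilon: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=float))
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=float))
        if self.pop_size < 1 or self.dim < 1 or self.n_max < 1:
            raise InvalidArgumentError("pop_size, dim and n_max must be positive")
        if self.lower.shape != (self.dim,) or self.upper.shape != (self.dim,):
            raise InvalidArgumentError("bounds must be vectors of length dim")
        if not np.all(self.lower < self.upper):
            raise InvalidArgumentError("lower must be < upper elementwise")
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.beta < 1.0):
            raise InvalidArgumentError("alpha and beta must lie in (0, 1)")
        if self.epsilon <= 0:
            raise InvalidArgumentError("epsilon must be > 0")


@dataclass
class OptimizerState:
    """Population positions, fitness values, best-so-far, and counters."""

    F: np.ndarray
    fitness: np.ndarray | None
    best_x: np.ndarray | None
    best_f: float
    n: int
    history: list = field(default_factory=list)
    rng: np.random.Generator = field(default_factory=np.random.default_rng)


def init_population(params: MrsaParams) -> OptimizerState:
    """Uniform random positions within the box, deterministic given seed."""
    rng = np.random.default_rng(params.seed)
    F = params.lower + rng.random((params.pop_size, params.dim)) * (
        params.upper - params.lower
    )
    return OptimizerState(F=F, fitness=None, best_x=None, best_f=np.inf, n=0, rng=rng)


def mean_position(f_j: Sequence[float]) -> float:
    """Arithmetic mean of one candidate's coordinates."""
    f_j = np.asarray(f_j, dtype=float)
    if f_j.size == 0:
        raise InvalidInputError("position vector must be non-empty")
    return float(f_j.mean())


def evolutionary_ratio(n: int, N: int, r3: float) -> float:
    """Randomly signed declining ratio ``D = 2 * r3 * (1 - 1/N)``.

    Bounded by 2 in magnitude for ``r3`` in [-1, 1]; zero when ``N`` is 1.
    """
    if N < 1:
        raise InvalidArgumentError("N must be >= 1")
    return 2.0 * r3 * (1.0 - 1.0 / N)


def reduction_function(best, x_r2, epsilon: float = 1e-10):
    """Region-shrinking operator ``H = (best - x_r2) / (best + epsilon)``.

    Zero when the sampled neighbor coincides with the best position.
    """
    return (np.asarray(best) - np.asarray(x_r2)) / (np.asarray(best) + epsilon)


def hunting_ratio(x, mean_pos, best, span, alpha: float = 0.1, epsilon: float = 1e-10):
    """Hunting operator ``q = alpha + (x - M(f)) / (best * span + eps)``.

    The ratio separating a candidate's position from its own mean,
    normalized by the best position and the box width.  Equals ``alpha``
    exactly when the candidate coordinate coincides with its mean
    position.
    """
    best = np.asarray(best)
    return alpha + (np.asarray(x) - np.asarray(mean_pos)) / (
        best * np.asarray(span) + epsilon
    )


def _evaluate(
    F: np.ndarray, fitness_fn: Callable[[np.ndarray], float]
) -> np.ndarray:
    vals = np.empty(F.shape[0])
    for i, x in enumerate(F):
        v = float(fitness_fn(x))
        if not np.isfinite(v):
            raise OptimizationError(f"non-finite fitness at position {x}")
        vals[i] = v
    return vals


def _phase(n: int, n_max: int) -> int:
    """Phase index 1-4 for iteration n in 1..n_max (half-open upper bins)."""
    if n <= n_max / 4:
        return 1
    if n <= n_max / 2:
        return 2
    if n <= 3 * n_max / 4:
        return 3
    return 4


def step(
    state: OptimizerState,
    params: MrsaParams,
    fitness_fn: Callable[[np.ndarray], float],
) -> OptimizerState:
    """Advance the population by one iteration of the four-phase schedule."""
    if state.fitness is None:
        state.fitness = _evaluate(state.F, fitness_fn)
        i_best = int(np.argmin(state.fitness))
        state.best_x = state.F[i_best].copy()
        state.best_f = float(state.fitness[i_best])

    rng = state.rng
    M, d = state.F.shape
    n = state.n + 1
    phase = _phase(n, params.n_max)
    best = state.best_x
    span = params.upper - params.lower

    mean_j = state.F.mean(axis=1, keepdims=True)  # M(f_j) per candidate
    q = hunting_ratio(
        state.F, mean_j, best[None, :], span[None, :], params.alpha, params.epsilon
    )
    delta = best[None, :] * q
    r2 = rng.integers(0, M, size=M)  # one neighbor index per crocodile
    H = reduction_function(best[None, :], state.F[r2], params.epsilon)

    if phase == 1:
        r = rng.random((M, d))
        new_F = best[None, :] * (-delta) * params.beta - H * r
    elif phase == 2:
        r = rng.random((M, d))
        r1 = rng.integers(0, M, size=M)
        r3 = rng.uniform(-1.0, 1.0, size=(M, d))
        D = 2.0 * r3 * (1.0 - 1.0 / params.n_max)
        new_F = best[None, :] * state.F[r1] * D * r
    elif phase == 3:
        s = rng.random((M, d))
        new_F = best[None, :] * q * s
    else:
        s = rng.random((M, d))
        new_F = best[None, :] - delta * params.epsilon - H * s

    new_F = np.clip(new_F, params.lower, params.upper)
    new_fit = _evaluate(new_F, fitness_fn)

    # elitist acceptance: a candidate keeps its new position only on improvement
    improved = new_fit < state.fitness
    state.F[improved] = new_F[improved]
    state.fitness[improved] = new_fit[improved]
    i_best = int(np.argmin(state.fitness))
    if state.fitness[i_best] < state.best_f:
        state.best_f = float(state.fitness[i_best])
        state.best_x = state.F[i_best].copy()
    state.n = n
    state.history.append(state.best_f)
    return state


def optimize(
    fitness_fn: Callable[[np.ndarray], float], params: MrsaParams
) -> tuple[np.ndarray, float, list]:
    """Full run: init, evaluate, then ``n_max`` phase-scheduled steps."""
    state = init_population(params)
    state.fitness = _evaluate(state.F, fitness_fn)
    i_best = int(np.argmin(state.fitness))
    state.best_x = state.F[i_best].copy()
    state.best_f = float(state.fitness[i_best])
    for _ in range(params.n_max):
        step(state, params, fitness_fn)
    return state.best_x, state.best_f, state.history


def make_cv_evaluator(n_splits: int = 3, n_neighbors: int = 5, seed: int = 0):
    """k-NN cross-validation evaluator for wrapper feature selection.

    Returns a callable mapping ``(X_subset, y)`` to a mean absolute
    prediction error clipped to [0, 1] (scores live on the unit
    interval).  k-NN is deliberately model-free so the subset quality is
    judged by local geometry rather than a parametric fit.
    """
    from sklearn.model_selection import KFold
    from sklearn.neighbors import KNeighborsRegressor

    def evaluator(X: np.ndarray, y: np.ndarray) -> float:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
        errs = []
        for tr, te in kf.split(X):
            k = min(n_neighbors, len(tr))
            model = KNeighborsRegressor(n_neighbors=k)
            model.fit(X[tr], y[tr])
            errs.append(np.abs(model.predict(X[te]) - y[te]).mean())
        return float(np.clip(np.mean(errs), 0.0, 1.0))

    return evaluator


def make_sdbfn_cv_evaluator(
    n_splits: int = 2, epochs: int = 4, seed: int = 0
):
    """Wrapper evaluator that cross-validates the actual quality predictor.

    Trains a reduced-epoch fuzzy-network model on each fold's training
    part and returns the mean absolute validation error in [0, 1].
    Slower than the k-NN proxy but prices in exactly what the downstream
    predictor can extract from a candidate subset.
    """
    from .sdbfn import SdbfnConfig, predict_scores, train

    def evaluator(X: np.ndarray, y: np.ndarray) -> float:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        idx = np.random.default_rng(seed).permutation(len(y))
        errs = []
        for f in range(n_splits):
            te = idx[f::n_splits]
            tr = np.setdiff1d(idx, te)
            model = train(SdbfnConfig(), X[tr], y[tr], epochs=epochs, seed=seed)
            errs.append(np.abs(predict_scores(model, X[te]) - y[te]).mean())
        return float(np.clip(np.mean(errs), 0.0, 1.0))

    return evaluator


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of a wrapper feature-selection run.

    ``mask`` is the best feature subset found; ``history`` the best-fitness
    trace; ``candidates`` the distinct masks evaluated during the search,
    ordered by fitness (best first) — useful for re-ranking the leading
    subsets on an independent validation partition.
    """

    mask: np.ndarray
    history: list
    candidates: list  # of (fitness, mask) pairs


def select_features(
    X: np.ndarray,
    y: np.ndarray,
    evaluator: Callable[[np.ndarray, np.ndarray], float] | None = None,
    params: MrsaParams | None = None,
    w_err: float = 0.99,
    w_size: float = 0.01,
    local_refine: bool = True,
    max_refine_sweeps: int = 3,
) -> SelectionResult:
    """Wrapper feature selection by reptile search over [0, 1]^d.

    A position is binarized at 0.5 into a feature mask; the fitness is the
    weighted sum ``w_err * error + w_size * |mask| / d`` where ``error``
    is the evaluator's cross-validated prediction error.  The empty mask
    is assigned fitness ``1 + w_size`` so it can never win.  When
    ``local_refine`` is set the global search's best mask is polished by a
    deterministic single-bit hill climb (up to ``max_refine_sweeps``
    passes over the features).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise InvalidInputError("X must be 2-D with at least one column")
    d = X.shape[1]
    evaluator = evaluator or make_cv_evaluator()
    if params is None:
        params = MrsaParams(
            pop_size=15, dim=d, lower=np.zeros(d), upper=np.ones(d), n_max=60
        )
    if params.dim != d:
        raise InvalidArgumentError("params.dim must equal the number of features")

    cache: dict[bytes, tuple[float, np.ndarray]] = {}

    def fitness(pos: np.ndarray) -> float:
        mask = pos > 0.5
        key = np.packbits(mask).tobytes()
        if key not in cache:
            if not mask.any():
                cache[key] = (1.0 + w_size, mask.copy())
            else:
                err = evaluator(X[:, mask], y)
                cache[key] = (w_err * err + w_size * mask.sum() / d, mask.copy())
        return cache[key][0]

    best_x, _, history = optimize(fitness, params)
    best_mask = best_x > 0.5

    def mask_fitness(mask: np.ndarray) -> float:
        key = np.packbits(mask).tobytes()
        if key not in cache:
            if not mask.any():
                cache[key] = (1.0 + w_size, mask.copy())
            else:
                err = evaluator(X[:, mask], y)
                cache[key] = (w_err * err + w_size * mask.sum() / d, mask.copy())
        return cache[key][0]

    if local_refine:
        # memetic finish: deterministic single-bit hill climb from the best
        # mask; the continuous operators rarely propose clean one-feature
        # additions or removals, which is exactly what separates a tight
        # subset from a bloated or starved one
        best_fit = mask_fitness(best_mask)
        for _ in range(max_refine_sweeps):
            improved = False
            for j in range(d):
                cand = best_mask.copy()
                cand[j] = ~cand[j]
                f = mask_fitness(cand)
                if f < best_fit - 1e-12:
                    best_mask, best_fit = cand, f
                    improved = True
            if not improved:
                break

    ranked = sorted(cache.values(), key=lambda fm: fm[0])
    return SelectionResult(best_mask, history, ranked)


def tune_sdbfn(
    space: Mapping[str, tuple[float, float]],
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    params: MrsaParams | None = None,
    epochs: int = 10,
    seed: int = 0,
) -> tuple[dict, float]:
    """Search a hyperparameter box for the fuzzy-network predictor.

    ``space`` maps names (``kappa1``, ``kappa2``, ``p_norm``,
    ``label_threshold``) to (low, high) bounds; the fitness of a point is
    the validation RMSE of a network trained with those settings.
    Returns the best configuration and its validation RMSE.
    """
    names = list(space.keys())
    lower = np.array([space[k][0] for k in names], dtype=float)
    upper = np.array([space[k][1] for k in names], dtype=float)
    degenerate = upper - lower <= 0
    if degenerate.all():
        cfg = dict(zip(names, lower))
        return cfg, _sdbfn_val_rmse(cfg, train_data, val_data, epochs, seed)
    # collapse near-degenerate axes by a tiny widening so bounds stay valid
    upper = np.where(degenerate, lower + 1e-9, upper)
    if params is None:
        params = MrsaParams(
            pop_size=6, dim=len(names), lower=lower, upper=upper, n_max=12, seed=seed
        )

    def fitness(pos: np.ndarray) -> float:
        cfg = dict(zip(names, pos))
        return _sdbfn_val_rmse(cfg, train_data, val_data, epochs, seed)

    best_x, best_f, _ = optimize(fitness, params)
    best_cfg = dict(zip(names, best_x))

    # the untuned defaults (clipped into the box) always compete, so tuning
    # can never return a configuration worse than the default
    from .sdbfn import SdbfnConfig

    defaults = SdbfnConfig()
    default_point = {
        k: float(np.clip(getattr(defaults, k, lower[i]), lower[i], upper[i]))
        for i, k in enumerate(names)
    }
    default_f = _sdbfn_val_rmse(default_point, train_data, val_data, epochs, seed)
    if default_f <= best_f:
        return default_point, default_f
    return best_cfg, best_f


def _sdbfn_val_rmse(cfg: dict, train_data, val_data, epochs: int, seed: int) -> float:
    from .evaluate import rmse
    from .sdbfn import SdbfnConfig, predict_scores, train

    X_tr, y_tr = train_data
    X_val, y_val = val_data
    kwargs = {}
    for key in ("kappa1", "kappa2", "label_threshold"):
        if key in cfg:
            kwargs[key] = float(np.clip(cfg[key], 1e-3, 0.999))
    if "p_norm" in cfg:
        kwargs["p_norm"] = float(max(1.0, cfg["p_norm"]))
    model = train(SdbfnConfig(**kwargs), X_tr, y_tr, epochs=epochs, seed=seed)
    pred = predict_scores(model, X_val)
    return rmse(pred, y_val)
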