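"""Self-evolving deep-belief fuzzy neural network quality predictor.

Five conceptual layers: (1) the input feature vector is passed through a
stack of restricted Boltzmann machines pretrained greedily with one-step
contrastive divergence; (2) the transformed vector is fuzzified by its
normalized p-norm distance to every stored rule exemplar; (3) a dynamic
rule layer holds exemplar/consequent pairs with adaptive sensitivity
thresholds that govern when new rules are spawned; (4) the winning rule's
activation is propagated through a saturated-linear function; (5) the
fuzzy-output layer admits the rules whose distances are comparable to
the winner's (a cutoff gate) and the defuzzified quality score is the
activation-weighted average of their consequents, thresholded into a
High/Low label.

Learning is mixed: unsupervised (exemplars drift toward inputs, CD-1
pretraining) and supervised (the winner's consequent moves by a
learning-rate-scaled error signal).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidArgumentError, InvalidInputError, StateError

__all__ = [
    "RbmLayer",
    "RuleNode",
    "SdbfnConfig",
    "SdbfnModel",
    "rbm_hidden_prob",
    "rbm_visible_prob",
    "cd1_update",
    "pretrain_stack",
    "forward_stack",
    "fuzzy_distance",
    "rule_activation",
    "evolve_sensitivity",
    "saturated_linear",
    "update_rule_weights",
    "predict",
    "predict_scores",
    "train",
    "save_model",
    "load_model",
]

#: Sensitivity assigned to every freshly created rule node.
INITIAL_SENSITIVITY = 0.3


@dataclass
class RbmLayer:
    """One restricted Boltzmann machine: weights plus both bias vectors."""

    W: np.ndarray  # visible x hidden
    hidden_bias: np.ndarray
    visible_bias: np.ndarray

    def __post_init__(self) -> None:
        if self.W.shape != (self.visible_bias.size, self.hidden_bias.size):
            raise InvalidInputError("RBM weight/bias shapes inconsistent")
        if not (
            np.all(np.isfinite(self.W))
            and np.all(np.isfinite(self.hidden_bias))
            and np.all(np.isfinite(self.visible_bias))
        ):
            raise InvalidInputError("RBM parameters must be finite")


@dataclass
class RuleNode:
    """Stored exemplar pattern, consequent quality value, and sensitivity."""

    exemplar: np.ndarray
    consequent: float
    sensitivity: float = INITIAL_SENSITIVITY

    def __post_init__(self) -> None:
        if not 0.0 <= self.consequent <= 1.0:
            raise InvalidArgumentError("consequent must lie in [0, 1]")
        if not 0.0 < self.sensitivity <= 1.0:
            raise InvalidArgumentError("sensitivity must lie in (0, 1]")


@dataclass(frozen=True)
class SdbfnConfig:
    """Network hyperparameters.

    ``hidden_sizes`` are the RBM hidden-layer widths stacked on the input;
    ``kappa1``/``kappa2`` are the fixed exemplar and consequent learning
    rates; ``p_norm`` the fuzzification distance norm; ``time_increment``
    the sensitivity-evolution time constant; scores at or above
    ``label_threshold`` are labelled High.
    """

    hidden_sizes: tuple[int, ...] = (32, 16)
    p_norm: float = 2.0
    kappa1: float = 0.1
    kappa2: float = 0.1
    time_increment: float = 10.0
    label_threshold: float = 0.5
    pretrain_learning_rate: float = 0.1
    activation_gate: float = 0.2
    rule_error_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.kappa1 < 1.0 and 0.0 < self.kappa2 < 1.0):
            raise InvalidArgumentError("kappa1 and kappa2 must lie in (0, 1)")
        if self.p_norm < 1.0:
            raise InvalidArgumentError("p_norm must be >= 1")
        if self.time_increment <= 0:
            raise InvalidArgumentError("time_increment must be > 0")
        if self.activation_gate < 0:
            raise InvalidArgumentError("activation_gate must be >= 0")
        if not 0.0 < self.rule_error_threshold <= 1.0:
            raise InvalidArgumentError("rule_error_threshold must lie in (0, 1]")


@dataclass
class SdbfnModel:
    """Trained predictor: RBM stack plus the evolved rule set."""

    rbm_stack: list
    rules: list
    config: SdbfnConfig = field(default_factory=SdbfnConfig)
    seed: int = 0


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def rbm_hidden_prob(v: np.ndarray, layer: RbmLayer) -> np.ndarray:
    """P(h = 1 | v) = logistic(hidden_bias + v W), per hidden unit."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != layer.W.shape[0]:
        raise InvalidInputError(
            f"visible size {v.shape[-1]} != weight rows {layer.W.shape[0]}"
        )
    return _logistic(layer.hidden_bias + v @ layer.W)


def rbm_visible_prob(h: np.ndarray, layer: RbmLayer) -> np.ndarray:
    """P(v = 1 | h) = logistic(visible_bias + W h): the reconstruction step."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != layer.W.shape[1]:
        raise InvalidInputError(
            f"hidden size {h.shape[-1]} != weight cols {layer.W.shape[1]}"
        )
    return _logistic(layer.visible_bias + h @ layer.W.T)


def cd1_update(
    layer: RbmLayer, batch: np.ndarray, learning_rate: float, seed: int = 0
) -> RbmLayer:
    """One contrastive-divergence (CD-1) step on a batch.

    Positive phase uses the data-driven hidden probabilities; the negative
    phase samples binary hidden states, reconstructs the visibles, and
    recomputes hidden probabilities.  The update is the difference of the
    two correlation statistics (data minus reconstruction), scaled by the
    learning rate and averaged over the batch.  Deterministic given seed.
    """
    if learning_rate <= 0:
        raise InvalidArgumentError("learning_rate must be > 0")
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.size == 0:
        raise InvalidInputError("batch must be non-empty")
    rng = np.random.default_rng(seed)
    ph = rbm_hidden_prob(batch, layer)
    h_sample = (rng.random(ph.shape) < ph).astype(float)
    pv_recon = rbm_visible_prob(h_sample, layer)
    ph_recon = rbm_hidden_prob(pv_recon, layer)
    B = batch.shape[0]
    dW = (batch.T @ ph - pv_recon.T @ ph_recon) / B
    dh = (ph - ph_recon).mean(axis=0)
    dv = (batch - pv_recon).mean(axis=0)
    return RbmLayer(
        W=layer.W + learning_rate * dW,
        hidden_bias=layer.hidden_bias + learning_rate * dh,
        visible_bias=layer.visible_bias + learning_rate * dv,
    )


def pretrain_stack(
    data: np.ndarray,
    layer_sizes: list[int],
    epochs: int,
    learning_rate: float = 0.1,
    seed: int = 0,
) -> list[RbmLayer]:
    """Greedy layer-wise CD-1 pretraining of a stack of RBMs.

    Each machine is trained on the previous machine's hidden
    probabilities; the whole procedure is repeated for ``epochs``
    full-batch updates per layer.  ``layer_sizes`` are the hidden widths.
    """
    if not layer_sizes:
        raise InvalidArgumentError("layer_sizes must be non-empty")
    data = np.atleast_2d(np.asarray(data, dtype=float))
    rng = np.random.default_rng(seed)
    stack: list[RbmLayer] = []
    current = data
    for size in layer_sizes:
        n_vis = current.shape[1]
        # fan-in scaled init keeps hidden probabilities off the 0.5 plateau
        layer = RbmLayer(
            W=rng.normal(0.0, 1.0 / np.sqrt(n_vis), (n_vis, size)),
            hidden_bias=np.zeros(size),
            visible_bias=np.zeros(n_vis),
        )
        for _ in range(epochs):
            layer = cd1_update(
                layer, current, learning_rate, seed=int(rng.integers(0, 2**31 - 1))
            )
        stack.append(layer)
        current = rbm_hidden_prob(current, layer)
    return stack


def forward_stack(x: np.ndarray, stack: list[RbmLayer]) -> np.ndarray:
    """Deterministic forward transform: successive hidden probabilities."""
    out = np.asarray(x, dtype=float)
    for layer in stack:
        out = rbm_hidden_prob(out, layer)
    return out


def fuzzy_distance(q: np.ndarray, rules: list[RuleNode], p: float = 2.0) -> np.ndarray:
    """Normalized p-norm distances from ``q`` to every rule exemplar.

    The distances sum to 1; when ``q`` coincides with every exemplar the
    degenerate convention assigns ``1/count`` to each rule.
    """
    if not rules:
        raise InvalidInputError("at least one rule is required")
    q = np.asarray(q, dtype=float)
    if not np.all(np.isfinite(q)):
        raise InvalidInputError("input vector must be finite")
    dists = np.array(
        [np.linalg.norm(q - r.exemplar, ord=p) for r in rules], dtype=float
    )
    total = dists.sum()
    if total == 0.0:
        return np.full(len(rules), 1.0 / len(rules))
    return dists / total


def rule_activation(e: np.ndarray) -> np.ndarray:
    """Rule-neuron activations ``Y1 = 1 - e``, elementwise in [0, 1]."""
    return 1.0 - np.asarray(e, dtype=float)


def evolve_sensitivity(
    rule: RuleNode, mu: float, delta_thr: float, x: float
) -> RuleNode:
    """Adapt a rule's sensitivity from its win-count statistic.

    A rule winning more often than the threshold (``mu > delta_thr``) has
    its sensitivity decreased by the factor ``1 - (mu - delta_thr)/x``; a
    rarely winning rule (``mu < delta_thr``) has it increased by
    ``1 + mu/x``.  The result is clamped to (0.01, 1]; at the threshold
    the sensitivity is unchanged.  Large time increments ``x`` make both
    updates vanishing.
    """
    if x <= 0:
        raise InvalidArgumentError("time increment x must be > 0")
    s = rule.sensitivity
    if mu > delta_thr:
        s = (1.0 - (mu - delta_thr) / x) * s
    elif mu < delta_thr:
        s = (1.0 + mu / x) * s
    s = float(np.clip(s, 0.01, 1.0))
    return RuleNode(rule.exemplar, rule.consequent, s)


def saturated_linear(v: float) -> float:
    """Clamp to [0, 1]: 0 below, 1 above, identity in between."""
    if not np.isfinite(v):
        raise InvalidInputError("input must be finite")
    return float(np.clip(v, 0.0, 1.0))


def update_rule_weights(
    rule: RuleNode,
    q: np.ndarray,
    y_max: float,
    error: float,
    kappa1: float,
    kappa2: float,
) -> RuleNode:
    """Move the winner's exemplar toward the input and correct its consequent.

    Exemplar: ``D1 <- D1 + kappa1 (q - D1)`` (geometric contraction of the
    exemplar-to-input distance by ``1 - kappa1`` per application).
    Consequent: ``D2 <- clamp(D2 + kappa2 * y_max * error, 0, 1)``.
    """
    if not (0.0 < kappa1 < 1.0 and 0.0 < kappa2 < 1.0):
        raise InvalidArgumentError("kappas must lie in (0, 1)")
    exemplar = rule.exemplar + kappa1 * (np.asarray(q, dtype=float) - rule.exemplar)
    consequent = float(np.clip(rule.consequent + kappa2 * y_max * error, 0.0, 1.0))
    return RuleNode(exemplar, consequent, rule.sensitivity)


def _defuzzify(e: np.ndarray, consequents: np.ndarray, gate: float) -> float:
    """Activation-weighted average of the comparably near (gated) rules.

    Each rule's activation is attenuated by ``exp(-(d/d_min - 1)/gate)``,
    a soft cutoff on the distance ratio to the nearest rule; the score is
    the weighted average of the consequents.  Gating keeps the prediction
    local: without it the normalized distances make every activation
    approach 1 as the rule set grows and the average collapses toward the
    global mean consequent.  Rules at distance zero (exact exemplar hits)
    take all the weight.
    """
    Y1 = 1.0 - e
    e_min = e.min()
    if e_min == 0.0:
        sel = e == 0.0
        total = Y1[sel].sum()
        if total <= 0.0:
            return float(consequents[sel].mean())
        return float((Y1[sel] * consequents[sel]).sum() / total)
    w = Y1 * np.exp(-(e / e_min - 1.0) / gate)
    total = w.sum()
    if total <= 0.0:
        return float(consequents.mean())
    return float((w * consequents).sum() / total)


def predict(model: SdbfnModel, features: np.ndarray) -> tuple[float, str]:
    """Quality score in [0, 1] plus the High/Low label for one vector."""
    if not model.rules:
        raise StateError("model has no rules; train it first")
    z = forward_stack(np.asarray(features, dtype=float), model.rbm_stack)
    e = fuzzy_distance(z, model.rules, model.config.p_norm)
    Y1 = rule_activation(e)
    consequents = np.array([r.consequent for r in model.rules])
    winner = int(np.argmax(Y1))
    _ = saturated_linear(Y1[winner])  # winner propagation (already in [0,1])
    score = _defuzzify(e, consequents, model.config.activation_gate)
    label = "High" if score >= model.config.label_threshold else "Low"
    return score, label


def predict_scores(model: SdbfnModel, X: np.ndarray) -> np.ndarray:
    """Vectorized convenience: scores for each row of ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.array([predict(model, x)[0] for x in X])


def train(
    config: SdbfnConfig,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int = 20,
    seed: int = 0,
) -> SdbfnModel:
    """Pretrain the RBM stack, then evolve the rule layer online.

    Per sample: if there are no rules, the best rule activation falls
    below the winner's sensitivity, or the prediction misses the target
    by more than ``rule_error_threshold``, a new rule is created with the
    transformed input as exemplar, the target as consequent, and the
    default sensitivity 0.3; otherwise the winner is updated with the
    supervised error (target minus defuzzified score) and its win count
    is incremented.  At each epoch's end the sensitivity of the epoch's
    most active rule evolves from its win count relative to the mean win
    count; win counts reset every epoch.  Deterministic given seed.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size or y.size < 2:
        raise InvalidInputError("X rows must match y length >= 2")
    if np.any((y < 0) | (y > 1)):
        raise InvalidInputError("targets must lie in [0, 1]")

    stack = pretrain_stack(
        X,
        list(config.hidden_sizes),
        epochs=epochs,
        learning_rate=config.pretrain_learning_rate,
        seed=seed,
    )
    Z = forward_stack(X, stack)

    rules: list[RuleNode] = []
    for _ in range(epochs):
        wins = np.zeros(len(rules))
        for z_i, y_i in zip(Z, y):
            if not rules:
                rules.append(RuleNode(z_i.copy(), float(y_i)))
                wins = np.zeros(1)
                continue
            e = fuzzy_distance(z_i, rules, config.p_norm)
            Y1 = rule_activation(e)
            winner = int(np.argmax(Y1))
            consequents = np.array([r.consequent for r in rules])
            score = _defuzzify(e, consequents, config.activation_gate)
            error = float(y_i) - score
            if (
                Y1[winner] < rules[winner].sensitivity
                or abs(error) > config.rule_error_threshold
            ):
                rules.append(RuleNode(z_i.copy(), float(y_i)))
                wins = np.append(wins, 0.0)
                continue
            y_max = saturated_linear(Y1[winner])
            rules[winner] = update_rule_weights(
                rules[winner], z_i, y_max, error,
                config.kappa1, config.kappa2,
            )
            wins[winner] += 1.0
        if wins.size == len(rules) and wins.size > 0:
            # the epoch's most active rule becomes less sensitive, so rule
            # creation settles down as the partitioning stabilizes
            epoch_winner = int(np.argmax(wins))
            rules[epoch_winner] = evolve_sensitivity(
                rules[epoch_winner],
                float(wins[epoch_winner]),
                float(wins.mean()),
                config.time_increment,
            )
    return SdbfnModel(rbm_stack=stack, rules=rules, config=config, seed=seed)


def save_model(model: SdbfnModel, path: str | Path) -> None:
    """Serialize a trained model (weights, rules, config, seed) as JSON."""
    payload = {
        "config": {
            "hidden_sizes": list(model.config.hidden_sizes),
            "p_norm": model.config.p_norm,
            "kappa1": model.config.kappa1,
            "kappa2": model.config.kappa2,
            "time_increment": model.config.time_increment,
            "label_threshold": model.config.label_threshold,
            "pretrain_learning_rate": model.config.pretrain_learning_rate,
            "activation_gate": model.config.activation_gate,
            "rule_error_threshold": model.config.rule_error_threshold,
        },
        "seed": model.seed,
        "rbm_stack": [
            {
                "W": layer.W.tolist(),
                "hidden_bias": layer.hidden_bias.tolist(),
                "visible_bias": layer.visible_bias.tolist(),
            }
            for layer in model.rbm_stack
        ],
        "rules": [
            {
                "exemplar": r.exemplar.tolist(),
                "consequent": r.consequent,
                "sensitivity": r.sensitivity,
            }
            for r in model.rules
        ],
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> SdbfnModel:
    """Inverse of :func:`save_model`."""
    payload = json.loads(Path(path).read_text())
    cfg = payload["config"]
    config = SdbfnConfig(
        hidden_sizes=tuple(cfg["hidden_sizes"]),
        p_norm=cfg["p_norm"],
        kappa1=cfg["kappa1"],
        kappa2=cfg["kappa2"],
        time_increment=cfg["time_increment"],
        label_threshold=cfg["label_threshold"],
        pretrain_learning_rate=cfg["pretrain_learning_rate"],
        activation_gate=cfg["activation_gate"],
        rule_error_threshold=cfg["rule_error_threshold"],
    )
    stack = [
        RbmLayer(
            W=np.asarray(layer["W"], dtype=float),
            hidden_bias=np.asarray(layer["hidden_bias"], dtype=float),
            visible_bias=np.asarray(layer["visible_bias"], dtype=float),
        )
        for layer in payload["rbm_stack"]
    ]
    rules = [
        RuleNode(
            np.asarray(r["exemplar"], dtype=float), r["consequent"], r["sensitivity"]
        )
        for r in payload["rules"]
    ]
    return SdbfnModel(rbm_stack=stack, rules=rules, config=config, seed=payload["seed"])
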