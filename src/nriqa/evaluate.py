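"""Quality-prediction evaluation statistics.

PLCC (Pearson linear correlation), SROCC (Spearman rank correlation via
the rank-difference formula with mid-rank ties), KROCC (Kendall tau-a:
concordant minus discordant pairs over all pairs), RMSE and MAE, plus a
JSON-serializable report combining all five.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from .errors import InvalidInputError, UndefinedStatisticError

__all__ = [
    "ScorePairs",
    "plcc",
    "srocc",
    "srocc_pearson_of_ranks",
    "krocc",
    "rmse",
    "mae",
    "evaluate_model",
    "EvaluationReport",
]


def _pairs(p, q) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1 or p.size < 2:
        raise InvalidInputError("inputs must be equal-length 1-D vectors, N >= 2")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise InvalidInputError("inputs must be finite")
    return p, q


@dataclass(frozen=True)
class ScorePairs:
    """A predicted/truth score vector pair of common length N."""

    predicted: np.ndarray
    truth: np.ndarray

    def __post_init__(self) -> None:
        p, q = _pairs(self.predicted, self.truth)
        object.__setattr__(self, "predicted", p)
        object.__setattr__(self, "truth", q)

    @property
    def n(self) -> int:
        return self.predicted.size


def plcc(p, q) -> float:
    """Pearson linear correlation coefficient."""
    p, q = _pairs(p, q)
    dp, dq = p - p.mean(), q - q.mean()
    denom = math.sqrt((dp**2).sum() * (dq**2).sum())
    if denom == 0.0:
        raise UndefinedStatisticError("PLCC undefined for a constant vector")
    return float((dp * dq).sum() / denom)


def srocc(p, q) -> float:
    """Spearman rank correlation by the rank-difference formula.

    Mid-ranks are assigned to ties and the no-ties formula
    ``1 - 6 sum(S^2) / (N (N^2 - 1))`` is applied to the rank
    differences ``S``; without ties this equals the Pearson correlation
    of the ranks exactly, with ties it is an approximation (see
    :func:`srocc_pearson_of_ranks` for the exact variant).
    """
    p, q = _pairs(p, q)
    n = p.size
    s = rankdata(p) - rankdata(q)
    return float(1.0 - 6.0 * (s**2).sum() / (n * (n**2 - 1)))


def srocc_pearson_of_ranks(p, q) -> float:
    """Exact Spearman correlation: Pearson correlation of mid-ranks."""
    p, q = _pairs(p, q)
    return plcc(rankdata(p), rankdata(q))


def krocc(p, q) -> float:
    """Kendall tau-a: (concordant - discordant) / C(N, 2); ties count in neither."""
    p, q = _pairs(p, q)
    n = p.size
    sp = np.sign(p[:, None] - p[None, :])
    sq = np.sign(q[:, None] - q[None, :])
    upper = np.triu_indices(n, k=1)
    net = (sp[upper] * sq[upper]).sum()
    return float(net / (n * (n - 1) / 2))


def rmse(p, q) -> float:
    """Root mean squared error between truth and prediction."""
    p, q = _pairs(p, q)
    return float(np.sqrt(((q - p) ** 2).mean()))


def mae(p, q) -> float:
    """Mean absolute error between truth and prediction."""
    p, q = _pairs(p, q)
    return float(np.abs(q - p).mean())


@dataclass(frozen=True)
class EvaluationReport:
    """All five statistics plus the number of score pairs."""

    plcc: float
    srocc: float
    krocc: float
    rmse: float
    mae: float
    n: int

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "EvaluationReport":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls(**json.loads(text))


def evaluate_model(predicted, truth) -> EvaluationReport:
    """Compute the full report for a predicted/truth score pair."""
    pairs = ScorePairs(np.asarray(predicted, float), np.asarray(truth, float))
    p, q = pairs.predicted, pairs.truth
    return EvaluationReport(
        plcc=plcc(p, q),
        srocc=srocc(p, q),
        krocc=krocc(p, q),
        rmse=rmse(p, q),
        mae=mae(p, q),
        n=pairs.n,
    )
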