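"""Differential-Evolution hyperparameter search for the Bi-LSTM.

Classic DE/rand/1/bin on a box-bounded space: the population is initialized
uniformly between the bounds, each generation builds a mutant
H_i = X_r1 + F (X_r2 - X_r3) from three distinct other members, crosses it
with the parent coordinate-wise at rate CR (one coordinate forced from the
mutant so the trial always differs), and keeps the trial iff its objective
is no worse (greedy selection, minimization).  The objective here is the
validation RMSE between predicted class-1 probabilities and the 0/1 labels
of a held-out fold carved from the training part.

Log-scaled real and integer dimensions are handled at decode time; the
search itself runs in the continuous unit-free space of the bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .bilstm import FittedBiLSTM, TrainConfig, predict, train
from .features import FeatureMatrix
from .io_deap import BinaryLabelSet, TrialSplit, split_trials


@dataclass
class Dimension:
    name: str
    low: float
    high: float
    kind: str = "real"  # "real", "log-real" or "integer"

    def decode(self, x: float) -> float | int:
        x = min(max(x, self.low), self.high)
        if self.kind == "integer":
            return int(round(x))
        if self.kind == "log-real":
            return float(x)
        return float(x)

    def sample_space(self) -> tuple[float, float]:
        if self.kind == "log-real":
            return math.log10(self.low), math.log10(self.high)
        return self.low, self.high


@dataclass
class DEConfig:
    population_size: int = 10
    mutation_factor: float = 0.5  # F
    crossover_rate: float = 0.9   # CR
    generations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("DE mutation needs 3 distinct others: population >= 4")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must lie in [0, 1]")
        if self.mutation_factor <= 0:
            raise ValueError("mutation_factor must be positive")


def default_search_space() -> list[Dimension]:
    """Learning rate (log scale), hidden units, minibatch size."""
    return [
        Dimension("learning_rate", 1e-4, 1e-1, "log-real"),
        Dimension("hidden_units", 32, 256, "integer"),
        Dimension("minibatch_size", 16, 128, "integer"),
    ]


def rmse(y_pred: np.ndarray, y_true: np.ndarray) -> float:
    """Root mean square deviation of predicted probabilities from 0/1 labels."""
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    y_true = np.asarray(y_true, dtype=float).ravel()
    if y_pred.size == 0:
        raise ValueError("empty prediction vector")
    if y_pred.size != y_true.size:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)))


def _decode(space: Sequence[Dimension], x: np.ndarray) -> dict:
    out = {}
    for d, xi in zip(space, x):
        if d.kind == "log-real":
            out[d.name] = d.decode(10.0 ** xi)
        else:
            out[d.name] = d.decode(xi)
    return out


@dataclass
class DEResult:
    best_point: dict
    best_objective: float
    history: pd.DataFrame        # one row per evaluated candidate
    best_trace: np.ndarray       # best objective after each generation


def de_optimize(
    space: Sequence[Dimension],
    objective: Callable[[dict], float],
    cfg: Optional[DEConfig] = None,
    initial_points: Optional[Sequence[dict]] = None,
) -> DEResult:
    """Minimize ``objective`` over the decoded space with DE/rand/1/bin.

    ``initial_points`` (decoded dicts) are injected into the initial
    population, so the search never returns anything worse than the best of
    them.  Every evaluation is recorded once in the history.
    """
    cfg = cfg or DEConfig()
    rng = np.random.default_rng(cfg.seed)
    D = len(space)
    lo = np.array([d.sample_space()[0] for d in space])
    hi = np.array([d.sample_space()[1] for d in space])
    NP = cfg.population_size
    pop = lo + rng.random((NP, D)) * (hi - lo)
    if initial_points:
        for k, pt in enumerate(initial_points[:NP]):
            for j, d in enumerate(space):
                val = pt[d.name]
                pop[k, j] = math.log10(val) if d.kind == "log-real" else float(val)
    pop = np.clip(pop, lo, hi)
    rows = []
    cache: dict[tuple, float] = {}

    def evaluate(x: np.ndarray, gen: int, cand: int) -> float:
        decoded = _decode(space, x)
        key = tuple(sorted(decoded.items()))
        if key not in cache:
            cache[key] = float(objective(decoded))
        rows.append({"generation": gen, "candidate": cand,
                     **decoded, "objective": cache[key]})
        return cache[key]

    fit = np.array([evaluate(pop[i], 0, i) for i in range(NP)])
    best_trace = [float(fit.min())]
    for g in range(1, cfg.generations + 1):
        for i in range(NP):
            others = [j for j in range(NP) if j != i]
            r1, r2, r3 = rng.choice(others, size=3, replace=False)
            mutant = pop[r1] + cfg.mutation_factor * (pop[r2] - pop[r3])
            mutant = np.clip(mutant, lo, hi)
            cross = rng.random(D) <= cfg.crossover_rate
            cross[rng.integers(D)] = True  # guarantee one mutant coordinate
            trial = np.where(cross, mutant, pop[i])
            f_trial = evaluate(trial, g, i)
            if f_trial <= fit[i]:  # greedy selection
                pop[i] = trial
                fit[i] = f_trial
        best_trace.append(float(fit.min()))
    best = int(np.argmin(fit))
    return DEResult(
        best_point=_decode(space, pop[best]),
        best_objective=float(fit[best]),
        history=pd.DataFrame(rows),
        best_trace=np.asarray(best_trace),
    )


def tune_bilstm(
    X: FeatureMatrix | np.ndarray,
    y: BinaryLabelSet | np.ndarray,
    split: Optional[TrialSplit] = None,
    space: Optional[Sequence[Dimension]] = None,
    cfg: Optional[DEConfig] = None,
    base_config: Optional[TrainConfig] = None,
    candidate_epochs: int = 10,
) -> tuple[TrainConfig, DEResult]:
    """DE search over Bi-LSTM hyperparameters minimizing validation RMSE.

    A validation fold (20% of the training part) is held out; each candidate
    trains with a reduced epoch budget and is scored by the RMSE of its
    validation class-1 probabilities.  The defaults of the training recipe
    seed the initial population, so the winner is never worse than them on
    this objective.  Returns the best decoded overrides merged into a full
    ``TrainConfig`` (at the full epoch budget) plus the evaluation history.
    """
    base = base_config or TrainConfig()
    space = list(space) if space is not None else default_search_space()
    cfg = cfg or DEConfig()
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    yv = (y.labels if isinstance(y, BinaryLabelSet) else np.asarray(y)).astype(int)
    if split is None:
        idx = np.arange(Xv.shape[0])
    else:
        idx = split.train_indices
    inner = split_trials(idx.size, 0.8, seed=cfg.seed,
                         stratify_on=BinaryLabelSet("inner", yv[idx]))
    tr, va = idx[inner.train_indices], idx[inner.test_indices]

    def objective(decoded: dict) -> float:
        overrides = {k: v for k, v in decoded.items()}
        cand = replace(base, max_epochs=min(candidate_epochs, base.max_epochs), **overrides)
        try:
            model = train(Xv[tr], yv[tr], cand)
            _, probs = predict(model, Xv[va])
        except (ValueError, FloatingPointError):
            return 1.0  # score failed candidates as worst possible RMSE
        return rmse(probs, yv[va])

    defaults_point = {d.name: getattr(base, d.name) for d in space}
    result = de_optimize(space, objective, cfg, initial_points=[defaults_point])
    tuned = replace(base, **result.best_point)
    return tuned, result
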