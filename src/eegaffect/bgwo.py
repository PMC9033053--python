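"""Binary Grey Wolf Optimizer (BGWO) wrapper feature selection.

Grey wolf optimization moves a pack of candidate solutions in continuous
space, each wolf pulled toward the three best solutions found so far (the
alpha, beta and delta leaders):

    D_i = |C_i * X_leader_i - X|,   X_i = X_leader_i - A_i * D_i
    X(t+1) = (X_1 + X_2 + X_3) / 3

with A_i = 2a*r1 - a and C_i = 2*r2 drawn per dimension, and the control
scalar a decreasing linearly from 2 to 0 over the iterations (exploration
to exploitation).  For feature selection each continuous coordinate in
[0, 1] is mapped to a bit through an S-shaped transfer function; a mask's
fitness is a weighted sum of the stratified cross-validated error of a
k-nearest-neighbour classifier on the masked columns and the fraction of
features kept (minimized).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .features import FeatureMatrix
from .io_deap import BinaryLabelSet


@dataclass
class BGWOConfig:
    n_wolves: int = 10
    max_iter: int = 30
    transfer_slope: float = 10.0
    fitness_alpha: float = 0.99
    a_start: float = 2.0
    a_end: float = 0.0
    binarization: str = "stochastic"  # or "threshold" (deterministic at 0.5)
    knn_k: int = 5
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wolves < 4:
            raise ValueError("need >= 4 wolves (three leaders plus omega)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0.0 <= self.fitness_alpha <= 1.0:
            raise ValueError("fitness_alpha must lie in [0, 1]")


@dataclass
class FeatureMask:
    bits: np.ndarray
    fitness: float
    column_names: Optional[list[str]] = None
    config: Optional[BGWOConfig] = None
    trace: Optional[np.ndarray] = None  # best fitness per iteration

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=int)
        if self.bits.sum() < 1:
            raise ValueError("mask must select at least one feature")

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())

    def selected_names(self) -> list[str]:
        if self.column_names is None:
            return [str(i) for i in np.flatnonzero(self.bits)]
        return [self.column_names[i] for i in np.flatnonzero(self.bits)]

    def to_frame(self) -> pd.DataFrame:
        names = self.column_names or [f"f{i}" for i in range(self.bits.size)]
        return pd.DataFrame({"column_name": names, "selected": self.bits})


def encircle_update(
    position: np.ndarray,
    leaders: tuple[np.ndarray, np.ndarray, np.ndarray],
    a: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One continuous grey-wolf position update toward (alpha, beta, delta).

    Fresh r1, r2 are drawn per leader and per dimension; the result is the
    mean of the three leader-guided moves, clipped to [0, 1].
    """
    if not 0.0 <= a <= 2.0:
        raise ValueError("a must lie in [0, 2]")
    position = np.asarray(position, dtype=float)
    parts = []
    for x_leader in leaders:
        r1 = rng.random(position.size)
        r2 = rng.random(position.size)
        A = 2.0 * a * r1 - a
        C = 2.0 * r2
        D = np.abs(C * x_leader - position)
        parts.append(x_leader - A * D)
    return np.clip((parts[0] + parts[1] + parts[2]) / 3.0, 0.0, 1.0)


def s_transfer(x: np.ndarray, slope: float = 10.0) -> np.ndarray:
    """S-shaped transfer: selection probability 1/(1+exp(-slope*(x-0.5)))."""
    return 1.0 / (1.0 + np.exp(-slope * (np.asarray(x, dtype=float) - 0.5)))


def binarize_position(
    position: np.ndarray,
    rng: np.random.Generator,
    slope: float = 10.0,
    mode: str = "stochastic",
) -> np.ndarray:
    """Map a continuous position in [0,1]^D to a non-empty bit mask."""
    p = s_transfer(position, slope)
    if mode == "stochastic":
        bits = (rng.random(p.size) < p).astype(int)
    elif mode == "threshold":
        bits = (np.asarray(position) > 0.5).astype(int)
    else:
        raise ValueError("mode must be 'stochastic' or 'threshold'")
    if bits.sum() == 0:
        bits[rng.integers(bits.size)] = 1  # repair: force one bit
    return bits


def knn_cv_error(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Stratified k-fold CV error of k-NN with per-fold standardization."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errs = []
    for tr, te in skf.split(X, y):
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        clf = KNeighborsClassifier(n_neighbors=k)
        clf.fit((X[tr] - mu) / sd, y[tr])
        pred = clf.predict((X[te] - mu) / sd)
        errs.append(np.mean(pred != y[te]))
    return float(np.mean(errs))


def fitness(
    mask: np.ndarray,
    X: FeatureMatrix | np.ndarray,
    y: BinaryLabelSet | np.ndarray,
    cfg: Optional[BGWOConfig] = None,
) -> float:
    """alpha * CV-error + (1-alpha) * selected-fraction, to be minimized."""
    cfg = cfg or BGWOConfig()
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 1:
        raise ValueError("mask must select at least one feature")
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    yv = y.labels if isinstance(y, BinaryLabelSet) else np.asarray(y, dtype=int)
    err = knn_cv_error(Xv[:, mask], yv, cfg.knn_k, cfg.cv_folds, cfg.seed)
    return cfg.fitness_alpha * err + (1.0 - cfg.fitness_alpha) * mask.sum() / mask.size


def select_features(
    X: FeatureMatrix | np.ndarray,
    y: BinaryLabelSet | np.ndarray,
    cfg: Optional[BGWOConfig] = None,
    objective: Optional[Callable[[np.ndarray], float]] = None,
) -> FeatureMask:
    """Run the BGWO loop and return the best (alpha) mask ever evaluated.

    Leaders are elitist (best three masks ever seen), so the best-fitness
    trace is monotone non-increasing.  ``objective`` may replace the default
    k-NN wrapper fitness with any callable on a bit mask.
    """
    cfg = cfg or BGWOConfig()
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    yv = y.labels if isinstance(y, BinaryLabelSet) else np.asarray(y, dtype=int)
    D = Xv.shape[1]
    if D == 0:
        raise ValueError("no feature columns")
    if objective is None:
        objective = lambda bits: fitness(bits, Xv, yv, cfg)
    rng = np.random.default_rng(cfg.seed)
    positions = rng.random((cfg.n_wolves, D))
    # leaders: (fitness, bits, position), best first; seeded with +inf sentinels
    leaders: list[tuple[float, np.ndarray, np.ndarray]] = []
    trace = np.empty(cfg.max_iter)
    cache: dict[bytes, float] = {}

    def evaluate(bits: np.ndarray) -> float:
        key = np.packbits(bits).tobytes()
        if key not in cache:
            cache[key] = float(objective(bits))
        return cache[key]

    for t in range(cfg.max_iter):
        for w in range(cfg.n_wolves):
            bits = binarize_position(positions[w], rng, cfg.transfer_slope, cfg.binarization)
            f = evaluate(bits)
            if all(not np.array_equal(bits, lb) for _, lb, _ in leaders) or len(leaders) == 0:
                leaders.append((f, bits.copy(), positions[w].copy()))
                leaders.sort(key=lambda rec: rec[0])
                leaders = leaders[:3]
        trace[t] = leaders[0][0]
        a = cfg.a_start + (cfg.a_end - cfg.a_start) * (
            t / (cfg.max_iter - 1) if cfg.max_iter > 1 else 1.0
        )
        lead_pos = [leaders[min(i, len(leaders) - 1)][2] for i in range(3)]
        for w in range(cfg.n_wolves):
            positions[w] = encircle_update(positions[w], tuple(lead_pos), a, rng)
    best_f, best_bits, _ = leaders[0]
    column_names = X.column_names if isinstance(X, FeatureMatrix) else None
    return FeatureMask(best_bits, best_f, column_names, cfg, trace)
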