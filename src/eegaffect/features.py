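"""Per-trial feature extraction: statistics, wavelet-packet descriptors, Hurst.

The default extractor emits a 68-dimensional vector per trial:

* 8 statistical descriptors (mean, variance, standard deviation, skewness,
  kurtosis, minimum, maximum, median) of the channel-averaged signal;
* 20 wavelet-packet descriptors: a level-2 wavelet packet decomposition of
  the channel-averaged signal yields 4 terminal subbands (in frequency
  order), each summarized by mean |coefficient|, coefficient standard
  deviation, mean power, skewness and kurtosis;
* 40 rescaled-range Hurst exponents, one per channel.

The variance/standard deviation use an unconventional 1/(n+1) normalization
by default (``variance_denominator="n+1"``); the familiar unbiased 1/(n-1)
form is available via configuration.  Skewness and kurtosis are the moment
ratios m3/m2^1.5 and m4/m2^2 (kurtosis is *not* excess-corrected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pywt

from .io_deap import EEGTrialSet, ShapeError, ValidationError


class EstimationError(ValueError):
    """A feature estimator could not run on the given series."""


# ---------------------------------------------------------------------------
# statistical features

STAT_NAMES = ("mean", "variance", "std", "skewness", "kurtosis", "minimum", "maximum", "median")


@dataclass
class StatFeatures:
    mean: float
    variance: float
    std: float
    skewness: float
    kurtosis: float
    minimum: float
    maximum: float
    median: float
    degenerate: bool = False  # constant input: skewness/kurtosis forced to 0

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.mean,
                self.variance,
                self.std,
                self.skewness,
                self.kurtosis,
                self.minimum,
                self.maximum,
                self.median,
            ]
        )


def statistical_features(x: np.ndarray, variance_denominator: str = "n+1") -> StatFeatures:
    """Time-domain summary statistics of a 1-D series.

    ``variance_denominator`` selects the normalization of V (and hence of
    sigma = sqrt(V)): ``"n+1"`` (default) or ``"n-1"``.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise EstimationError("need at least 2 samples")
    mu = float(np.mean(x))
    dev = x - mu
    denom = {"n+1": n + 1, "n-1": n - 1, "n": n}[variance_denominator]
    v = float(np.sum(dev**2) / denom)
    m2 = float(np.mean(dev**2))
    degenerate = m2 == 0.0
    if degenerate:
        skew = kurt = 0.0
    else:
        skew = float(np.mean(dev**3) / m2**1.5)
        kurt = float(np.mean(dev**4) / m2**2)
    return StatFeatures(
        mean=mu,
        variance=v,
        std=float(np.sqrt(v)),
        skewness=skew,
        kurtosis=kurt,
        minimum=float(np.min(x)),
        maximum=float(np.max(x)),
        median=float(np.median(x)),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# wavelet packet decomposition


@dataclass
class WaveletFilterPair:
    """Quadrature-mirror lowpass/highpass analysis pair."""

    lowpass: np.ndarray
    highpass: np.ndarray
    family: str = "custom"

    def __post_init__(self) -> None:
        self.lowpass = np.asarray(self.lowpass, dtype=float)
        self.highpass = np.asarray(self.highpass, dtype=float)
        if self.lowpass.size != self.highpass.size:
            raise ValidationError("lowpass/highpass filters must have equal length")

    @classmethod
    def from_family(cls, family: str = "db4") -> "WaveletFilterPair":
        w = pywt.Wavelet(family)
        return cls(np.asarray(w.dec_lo), np.asarray(w.dec_hi), family)


@dataclass
class WPDTree:
    """Full wavelet-packet tree to a given level.

    ``nodes`` maps binary path strings ('' root, '0' lowpass child, '1'
    highpass child, ...) to coefficient arrays.  Terminal nodes can be
    listed in natural (Paley) or frequency (Gray-code) order.
    """

    level: int
    nodes: dict[str, np.ndarray]
    family: str = "db4"

    def terminal_paths(self, ordering: str = "frequency") -> list[str]:
        paths = [format(i, f"0{self.level}b") for i in range(2**self.level)]
        if ordering == "natural":
            return paths
        if ordering != "frequency":
            raise ValueError("ordering must be 'natural' or 'frequency'")
        # natural (filter-path) order -> frequency order via Gray code:
        # frequency-ordered index g has natural index gray(g)
        def gray(i: int) -> int:
            return i ^ (i >> 1)

        return [format(gray(i), f"0{self.level}b") for i in range(2**self.level)]

    def terminal_nodes(self, ordering: str = "frequency") -> list[np.ndarray]:
        return [self.nodes[p] for p in self.terminal_paths(ordering)]


def wpd_decompose(
    x: np.ndarray,
    filters: WaveletFilterPair | str = "db4",
    level: int = 2,
    mode: str = "periodization",
) -> WPDTree:
    """Recursive two-channel filter-and-decimate wavelet packet analysis.

    Both the approximation (lowpass, child '0') and detail (highpass, child
    '1') branches are split at every level, producing the full binary tree.
    With an orthogonal family and periodization the total terminal energy
    equals the input energy.
    """
    x = np.asarray(x, dtype=float).ravel()
    if isinstance(filters, str):
        filters = WaveletFilterPair.from_family(filters)
    if level < 1:
        raise ValidationError("level must be >= 1")
    wavelet = pywt.Wavelet(
        filters.family if filters.family != "custom" else "custom",
        filter_bank=(
            filters.lowpass.tolist(),
            filters.highpass.tolist(),
            filters.lowpass[::-1].tolist(),
            filters.highpass[::-1].tolist(),
        ),
    ) if filters.family == "custom" else pywt.Wavelet(filters.family)
    nodes: dict[str, np.ndarray] = {"": x}
    frontier = [""]
    for lev in range(level):
        nxt = []
        for path in frontier:
            data = nodes[path]
            if data.size < filters.lowpass.size:
                raise EstimationError(f"series too short for filters at level {lev + 1}")
            lo, hi = pywt.dwt(data, wavelet, mode=mode)
            nodes[path + "0"] = lo
            nodes[path + "1"] = hi
            nxt += [path + "0", path + "1"]
        frontier = nxt
    return WPDTree(level=level, nodes=nodes, family=filters.family)


WPD_DESCRIPTORS = ("mabs", "std", "power", "skewness", "kurtosis")


def wpd_features(tree: WPDTree, ordering: str = "frequency") -> np.ndarray:
    """5 descriptors per terminal subband of a level-2 tree (4 x 5 = 20 values).

    Per node (frequency order): mean absolute coefficient, coefficient
    standard deviation (population), mean power (energy/length), skewness
    and kurtosis of the coefficients.  All-zero nodes yield zeros.
    """
    if tree.level != 2:
        raise ValidationError("wpd_features expects a level-2 tree (4 terminal nodes)")
    out = []
    for coeffs in tree.terminal_nodes(ordering):
        c = np.asarray(coeffs, dtype=float)
        m2 = float(np.mean((c - c.mean()) ** 2))
        if m2 == 0.0:
            skew = kurt = 0.0
        else:
            skew = float(np.mean((c - c.mean()) ** 3) / m2**1.5)
            kurt = float(np.mean((c - c.mean()) ** 4) / m2**2)
        out += [
            float(np.mean(np.abs(c))),
            float(np.sqrt(m2)),
            float(np.mean(c**2)),
            skew,
            kurt,
        ]
    return np.array(out)


# ---------------------------------------------------------------------------
# rescaled-range Hurst estimation

HURST_CLAMP = (0.0, 1.5)


@dataclass
class HurstEstimate:
    H: float
    window_sizes: np.ndarray
    rescaled_ranges: np.ndarray
    intercept: float  # absorbs the proportionality constant of E[R/S] ~ C n^H


def _rs_values(rows: np.ndarray, n: int) -> np.ndarray:
    """Mean R/S over complete length-n blocks, one value per row.

    Zero-dispersion blocks are excluded; rows with no valid block get NaN.
    """
    N = rows.shape[1]
    nb = N // n
    blocks = rows[:, : nb * n].reshape(rows.shape[0], nb, n)
    dev = blocks - blocks.mean(axis=2, keepdims=True)
    cum = np.cumsum(dev, axis=2)
    R = cum.max(axis=2) - cum.min(axis=2)
    S = blocks.std(axis=2)
    valid = S > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rs = np.where(valid, R / np.where(valid, S, 1.0), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(rs, axis=1)


def _window_grid(n_samples: int, min_window: int, n_window_sizes: int) -> np.ndarray:
    grid = np.unique(
        np.round(
            np.geomspace(min_window, n_samples // 2, n_window_sizes)
        ).astype(int)
    )
    return grid[grid >= min_window]


def hurst_many(
    rows: np.ndarray, min_window: int = 8, n_window_sizes: int = 10
) -> np.ndarray:
    """Vectorized R/S Hurst estimate for each row of a 2-D array."""
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2:
        raise ShapeError("expected a 2-D array (series, samples)")
    if min_window < 8:
        raise EstimationError("min_window must be >= 8")
    if rows.shape[1] < 2 * min_window:
        raise EstimationError(
            f"series of length {rows.shape[1]} too short for min_window {min_window}"
        )
    grid = _window_grid(rows.shape[1], min_window, n_window_sizes)
    if grid.size < 2:
        raise EstimationError("fewer than 2 valid window sizes")
    rs = np.column_stack([_rs_values(rows, int(n)) for n in grid])
    logn = np.log(grid)
    H = np.full(rows.shape[0], np.nan)
    for i in range(rows.shape[0]):
        ok = np.isfinite(rs[i]) & (rs[i] > 0)
        if ok.sum() < 2:
            continue
        slope, _ = np.polyfit(logn[ok], np.log(rs[i, ok]), 1)
        H[i] = np.clip(slope, *HURST_CLAMP)
    return H


def hurst_rs(x: np.ndarray, min_window: int = 8, n_window_sizes: int = 10) -> HurstEstimate:
    """Rescaled-range (R/S) Hurst exponent of a 1-D series.

    For each window size n on a geometric grid from ``min_window`` to
    length/2 the series is cut into complete blocks; each block is
    mean-adjusted, cumulated, and contributes R (range of the cumulated
    sums) over S (block standard deviation).  H is the least-squares slope
    of log(mean R/S) against log(n), clamped to [0, 1.5].
    """
    x = np.asarray(x, dtype=float).ravel()
    if min_window < 8:
        raise EstimationError("min_window must be >= 8")
    if x.size < 2 * min_window:
        raise EstimationError(f"series of length {x.size} too short for min_window {min_window}")
    grid = _window_grid(x.size, min_window, n_window_sizes)
    if grid.size < 2:
        raise EstimationError("fewer than 2 valid window sizes")
    rs = np.array([_rs_values(x[None, :], int(n))[0] for n in grid])
    ok = np.isfinite(rs) & (rs > 0)
    if ok.sum() < 2:
        raise EstimationError("fewer than 2 window sizes with valid R/S")
    slope, intercept = np.polyfit(np.log(grid[ok]), np.log(rs[ok]), 1)
    return HurstEstimate(
        H=float(np.clip(slope, *HURST_CLAMP)),
        window_sizes=grid[ok],
        rescaled_ranges=rs[ok],
        intercept=float(intercept),
    )


# ---------------------------------------------------------------------------
# assembly


@dataclass
class FeatureConfig:
    wavelet: str = "db4"
    wpd_level: int = 2
    wpd_mode: str = "periodization"
    variance_denominator: str = "n+1"
    hurst_min_window: int = 8
    hurst_n_window_sizes: int = 10
    eeg_only: bool = False  # restrict the Hurst block to the first 32 channels
    hurst_fill: float = 0.5  # value for channels where estimation fails


@dataclass
class FeatureMatrix:
    values: np.ndarray
    column_names: list[str]
    config: FeatureConfig = field(default_factory=FeatureConfig)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.column_names):
            raise ShapeError("values/column_names mismatch")
        if len(set(self.column_names)) != len(self.column_names):
            raise ValidationError("duplicate column names")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite feature values")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_names)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, config: Optional[FeatureConfig] = None) -> "FeatureMatrix":
        df = pd.read_csv(path)
        return cls(df.to_numpy(float), list(df.columns), config or FeatureConfig())


def feature_names(n_channels: int = 40, cfg: Optional[FeatureConfig] = None) -> list[str]:
    cfg = cfg or FeatureConfig()
    names = [f"stat_{s}" for s in STAT_NAMES]
    for node in range(2**cfg.wpd_level):
        names += [f"wpd_n{node}_{d}" for d in WPD_DESCRIPTORS]
    ch = range(32) if cfg.eeg_only else range(n_channels)
    names += [f"hurst_ch{c:02d}" for c in ch]
    return names


def extract_trial(trial: np.ndarray, cfg: Optional[FeatureConfig] = None) -> np.ndarray:
    """68-vector for one trial shaped (n_channels, n_samples).

    Statistics and wavelet descriptors are computed on the channel-averaged
    signal; the Hurst exponent per channel.  Channels where R/S estimation
    fails receive the configured fill value.
    """
    cfg = cfg or FeatureConfig()
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 2:
        raise ShapeError("trial must be (n_channels, n_samples)")
    avg = trial.mean(axis=0)
    stats = statistical_features(avg, cfg.variance_denominator).as_array()
    tree = wpd_decompose(avg, cfg.wavelet, cfg.wpd_level, cfg.wpd_mode)
    wav = wpd_features(tree)
    rows = trial[:32] if cfg.eeg_only else trial
    try:
        hur = hurst_many(rows, cfg.hurst_min_window, cfg.hurst_n_window_sizes)
    except EstimationError:
        hur = np.full(rows.shape[0], np.nan)
    hur = np.where(np.isfinite(hur), hur, cfg.hurst_fill)
    return np.concatenate([stats, wav, hur])


def extract_matrix(
    dataset: Iterable[EEGTrialSet], cfg: Optional[FeatureConfig] = None
) -> FeatureMatrix:
    """One feature row per trial, participant-major then trial-minor order."""
    cfg = cfg or FeatureConfig()
    rows = []
    n_channels = None
    for tset in dataset:
        if n_channels is None:
            n_channels = tset.n_channels
        elif tset.n_channels != n_channels:
            raise ShapeError("heterogeneous channel counts across participants")
        for tr in range(tset.n_trials):
            rows.append(extract_trial(tset.signals[tr], cfg))
    if not rows:
        raise ValidationError("empty dataset")
    return FeatureMatrix(np.vstack(rows), feature_names(n_channels, cfg), cfg)
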