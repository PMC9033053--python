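"""Synthetic DEAP-shaped EEG datasets and reference stochastic processes.

Two generators live here:

* :func:`generate_dataset` emits per-participant trial sets in the canonical
  DEAP layout (40 trials x 40 channels x 8064 samples at 128 Hz) whose
  class structure is controllable: trials rated "high" on an affect
  dimension receive (a) stronger temporal persistence (larger AR(1)
  coefficient, hence larger Hurst exponents) on a dimension-specific channel
  subset and (b) an additive coherent beta-band (16-30 Hz) oscillation, both
  scaled by ``effect_size``.  Every feature family the pipeline extracts
  (statistics, wavelet-packet subband descriptors, rescaled-range Hurst) is
  therefore informative, so feature selection has genuine work to do.

* :func:`generate_fbm` draws exact-covariance fractional Brownian motion via
  Davies-Harte circulant embedding of the fractional Gaussian noise
  covariance, used to validate the Hurst estimator against a known H.

No physiological realism (electrode geometry, artifacts) is attempted; only
the statistical structure the feature extractor consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .io_deap import (
    CANONICAL_FS,
    CANONICAL_N_CHANNELS,
    CANONICAL_N_SAMPLES,
    CANONICAL_N_TRIALS,
    CLASSIFIED_DIMENSIONS,
    DEFAULT_THRESHOLD,
    EEGTrialSet,
)

# per-dimension signatures: carrier frequency of the coherent burst and the
# slice of channels whose AR(1) persistence is raised for "high" trials
_DIM_FREQ_HZ = {"valence": 18.0, "arousal": 22.0, "liking": 26.0}
_DIM_CHANNEL_BLOCK = {"valence": (0, 12), "arousal": (12, 24), "liking": (24, 36)}

_AR_BASE = 0.3          # baseline AR(1) coefficient of every channel
_AR_GAIN = 0.25         # added per unit effect_size on signature channels (high class)
_OSC_GAIN = 0.35        # oscillation amplitude per unit effect_size, in noise-sd units


@dataclass
class SynthesisConfig:
    """Study-condition knobs for the DEAP-shaped generator."""

    n_participants: int = 32
    n_trials_per_participant: int = CANONICAL_N_TRIALS
    n_channels: int = CANONICAL_N_CHANNELS
    n_samples: int = CANONICAL_N_SAMPLES
    sampling_rate: float = CANONICAL_FS
    effect_size: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_participants", "n_trials_per_participant", "n_channels", "n_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class FBMSpec:
    """Fractional Brownian motion request: Hurst parameter and length."""

    hurst: float
    n_samples: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.hurst < 1.0:
            raise ValueError("hurst must lie in (0, 1)")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")


def _draw_ratings(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform ratings on [1, 9], jittered +-0.25 away from the threshold."""
    r = rng.uniform(1.0, 9.0, size=(n, 4))
    near = np.abs(r - DEFAULT_THRESHOLD) < 0.25
    r = np.where(near, np.where(r >= DEFAULT_THRESHOLD, r + 0.25, r - 0.25), r)
    return np.clip(r, 1.0, 9.0)


def _participant_signals(
    rng: np.random.Generator, cfg: SynthesisConfig, ratings: np.ndarray
) -> np.ndarray:
    n_t, n_c, n_s = cfg.n_trials_per_participant, cfg.n_channels, cfg.n_samples
    t = np.arange(n_s) / cfg.sampling_rate
    signals = np.empty((n_t, n_c, n_s), dtype=np.float32)
    # AR coefficient per trial/channel: raised on signature channels of
    # dimensions the trial is rated high on
    phi = np.full((n_t, n_c), _AR_BASE)
    for d, dim in enumerate(CLASSIFIED_DIMENSIONS):
        lo, hi = _DIM_CHANNEL_BLOCK[dim]
        lo = min(lo, n_c)
        hi = min(hi, n_c)
        high = ratings[:, ("valence", "arousal", "dominance", "liking").index(dim)] >= 5.0
        phi[np.ix_(high, np.arange(lo, hi))] += min(_AR_GAIN * cfg.effect_size, 0.65)
    phi = np.clip(phi, 0.0, 0.97)
    innov = rng.standard_normal((n_t, n_c, n_s)) * cfg.noise_sd
    for tr in range(n_t):
        for coef in np.unique(phi[tr]):
            chs = phi[tr] == coef
            # AR(1): x[k] = coef*x[k-1] + e[k]; unit-variance innovations
            signals[tr, chs] = lfilter([1.0], [1.0, -coef], innov[tr, chs], axis=-1)
    # coherent beta-band burst across all channels for each high-rated dimension
    for dim in CLASSIFIED_DIMENSIONS:
        f0 = _DIM_FREQ_HZ[dim]
        high = ratings[:, ("valence", "arousal", "dominance", "liking").index(dim)] >= 5.0
        if not high.any():
            continue
        phase = rng.uniform(0, 2 * np.pi, size=high.sum())
        osc = np.sin(2 * np.pi * f0 * t[None, :] + phase[:, None])
        amp = _OSC_GAIN * cfg.effect_size * cfg.noise_sd
        signals[high] += (amp * osc)[:, None, :].astype(np.float32)
    return signals


def generate_dataset(cfg: SynthesisConfig) -> list[EEGTrialSet]:
    """Generate ``cfg.n_participants`` DEAP-shaped trial sets.

    Reproducible from ``cfg.seed``; each participant consumes an independent
    substream so subsets of participants are stable under the same seed.
    """
    root = np.random.SeedSequence(cfg.seed)
    sets: list[EEGTrialSet] = []
    for p, child in enumerate(root.spawn(cfg.n_participants)):
        rng = np.random.default_rng(child)
        ratings = _draw_ratings(rng, cfg.n_trials_per_participant)
        signals = _participant_signals(rng, cfg, ratings)
        sets.append(
            EEGTrialSet(
                signals=signals,
                ratings=ratings,
                sampling_rate=cfg.sampling_rate,
                participant_id=f"s{p:02d}",
            )
        )
    return sets


# ---------------------------------------------------------------------------
# fractional Brownian motion


def _fgn_autocov(h: float, n: int) -> np.ndarray:
    k = np.arange(n, dtype=float)
    return 0.5 * (np.abs(k + 1) ** (2 * h) - 2 * np.abs(k) ** (2 * h) + np.abs(k - 1) ** (2 * h))


def generate_fbm(spec: FBMSpec) -> np.ndarray:
    """Exact-covariance fBm path of length ``n_samples`` starting at 0.

    Uses Davies-Harte circulant embedding of the fractional Gaussian noise
    covariance; if the embedding is not positive semi-definite (possible for
    extreme (H, n)), falls back to a Cholesky factorization of the increment
    covariance with a warning.
    """
    n = spec.n_samples
    rng = np.random.default_rng(spec.seed)
    gamma = _fgn_autocov(spec.hurst, n)
    # circulant first row: gamma_0..gamma_{n-1}, gamma_n ≡ edge, mirrored tail
    row = np.concatenate([gamma, [0.0], gamma[-1:0:-1]])
    eig = np.fft.rfft(row).real
    if np.min(eig) < -1e-8 * np.max(eig):
        warnings.warn("circulant embedding not PSD; falling back to Cholesky", RuntimeWarning)
        cov = _fgn_autocov(spec.hurst, n)
        mat = cov[np.abs(np.subtract.outer(np.arange(n), np.arange(n)))]
        chol = np.linalg.cholesky(mat + 1e-12 * np.eye(n))
        fgn = chol @ rng.standard_normal(n)
    else:
        eig = np.clip(eig, 0.0, None)
        m = 2 * n
        # complex Gaussian spectrum with Hermitian symmetry handled by irfft
        z = np.empty(n + 1, dtype=complex)
        z[0] = rng.standard_normal() * np.sqrt(m)
        z[n] = rng.standard_normal() * np.sqrt(m)
        re = rng.standard_normal(n - 1)
        im = rng.standard_normal(n - 1)
        z[1:n] = (re + 1j * im) * np.sqrt(m / 2.0)
        fgn = np.fft.irfft(z * np.sqrt(eig), n=m)[:n]
    return np.concatenate([[0.0], np.cumsum(fgn)])[: n]
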