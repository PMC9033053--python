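# Methods

`eegaffect` implements an affective-computing pipeline that classifies each
EEG trial as *low* or *high* on three self-rated dimensions — valence,
arousal and liking — from engineered signal features. This note documents
the models, the defaults and their rationale, the synthetic study
conditions, and the numerical choices.

## Data model

The pipeline consumes per-participant recordings in the layout of the
preprocessed DEAP release: 40 trials x 40 channels x 8064 samples at
128 Hz per participant, with a 40 x 4 rating matrix (valence, arousal,
dominance, liking), each rating on a continuous 1–9 scale. Ratings are
binarized at 5: *high* iff rating >= 5 (ties go high). Dominance is read
and retained but never classified. Trials are split 70/30 into train and
test by seeded shuffling (no stratification by default); at the canonical
1280-trial scale this yields 896 training and 384 test rows. Optional
stratified splitting keeps class proportions within one trial of the
global proportion in both parts.

Three on-disk containers are supported — the native pickle of the DEAP
release, MATLAB v5, and a plain `.npz` archive. The `.npz` container is
the default everywhere in the test suite so no licensed download is
needed; round-trips through any container are lossless.

## Features (68 per trial)

| block | count | computed on |
|---|---|---|
| statistics | 8 | channel-averaged signal |
| wavelet packet descriptors | 20 | channel-averaged signal |
| rescaled-range Hurst exponent | 40 | each channel |

This allocation — pooled statistics and wavelet descriptors, per-channel
Hurst — is the package's design choice to realize a 68-dimensional vector
on a 40-channel trial (8 + 20 + 40); it is the only simple allocation
consistent with those block totals.

**Statistics.** Mean, variance, standard deviation, skewness, kurtosis,
minimum, maximum, median. The variance is normalized by `n+1` by default
(`variance_denominator="n+1"`), an unconventional estimator retained for
fidelity with the method being reproduced; the standard `n-1` form is one
config switch away. Skewness and kurtosis are the plain moment ratios
m3/m2^1.5 and m4/m2^2 (kurtosis of a Gaussian is 3, not 0). A constant
series returns 0 for both, flagged via `StatFeatures.degenerate`.

**Wavelet packets.** A level-2 wavelet packet decomposition (both the
approximation and detail branches split at each level) with the `db4`
family and periodized extension — db4 being the conventional choice for
EEG, and periodization giving exact energy conservation (Parseval to
1e-8 relative, asserted in tests). The four terminal subbands, taken in
frequency order (at 128 Hz: 0–16, 16–32, 32–48, 48–64 Hz), are each
summarized by five descriptors: mean |coefficient|, coefficient standard
deviation, mean power, skewness and kurtosis. The choice of five
descriptors per node realizes the 20-feature wavelet block and is recorded
in the column registry (`wpd_n{0..3}_{mabs,std,power,skewness,kurtosis}`).
Family, level and extension mode are configurable.

**Hurst exponent.** Classical rescaled-range (R/S) analysis: for each
window size n on a 10-point geometric grid from 8 to N/2, the series is
cut into complete blocks; each block is mean-adjusted, cumulated, and
contributes R (range of the cumulated sums) over S (population standard
deviation). H is the least-squares slope of log mean-R/S against log n,
clamped to [0, 1.5]. Zero-dispersion blocks are excluded; channels where
estimation fails entirely receive a flagged fill of 0.5 (the memoryless
value). R/S estimates on finite samples are biased toward 0.55–0.6 for
white noise; the estimator is validated on exact fractional Brownian
motion rather than against the asymptotic value. An `eeg_only` switch
restricts the Hurst block to the first 32 channels (the EEG electrodes of
the DEAP montage) for users who want to exclude the peripheral channels;
the default uses all 40, which is what produces the 68-feature contract.

## Synthetic study conditions

`generate_dataset` emulates the canonical layout: 32 participants x 40
trials x 40 channels x 8064 samples at 128 Hz, ratings uniform on [1, 9]
jittered ±0.25 away from the threshold so binarization is stable. Class
structure is injected per dimension for trials rated high:

* an AR(1)-persistence increase (baseline coefficient 0.3, +0.25 per unit
  `effect_size`, capped at 0.97) on a dimension-specific block of 12
  channels — this moves per-channel Hurst exponents and variances;
* a phase-coherent beta-band oscillation (valence 18 Hz, arousal 22 Hz,
  liking 26 Hz; amplitude 0.35 x `effect_size` x noise-sd) added across
  channels — this moves the 16–32 Hz wavelet subband descriptors and
  survives channel averaging because the phase is shared across channels.

Both signal families are therefore informative, so feature selection has
genuine work to do. Defaults: `effect_size=1`, `noise_sd=1`. One global
seed fans out to per-participant substreams, so any subset of participants
is reproducible. The generator makes no claim to physiological realism —
no electrode geometry, no artifacts, no 1/f background; passing tests
demonstrate that the pipeline recovers planted statistical structure of
exactly these kinds, not that it reaches any particular accuracy on real
recordings.

`generate_fbm` draws exact-covariance fractional Brownian motion by
Davies–Harte circulant embedding of the fractional-Gaussian-noise
covariance (O(n log n), exact for every (H, n) where the embedding is
positive semi-definite; otherwise it falls back to a Cholesky factor of
the increment covariance with a warning). It is the oracle for the Hurst
estimator: median |Ĥ − H| over 20 seeds at n = 8192 stays within 0.1 for
H in {0.3, 0.5, 0.8}.

## Feature selection: binary grey wolf optimizer

Continuous pack dynamics with the canonical control definitions
A = 2a·r1 − a, C = 2·r2 (fresh draws per leader and dimension) and a
decreasing linearly 2 → 0; each wolf moves to the mean of the three
leader-guided positions, clipped to [0, 1]. Leaders are the best three
masks *ever evaluated* (elitist), which guarantees the monotone
best-fitness trace asserted in tests. Positions are mapped to bits
stochastically through the S-shaped transfer 1/(1+exp(−10(x−0.5)));
deterministic thresholding at 0.5 is available. Empty masks are repaired
to a single uniformly chosen bit.

The fitness is a wrapper criterion: 0.99 x (stratified 5-fold CV error of
a 5-NN classifier on the masked, train-fold-standardized columns) + 0.01 x
(selected fraction), minimized. A k-NN wrapper rather than the downstream
network keeps a full selection run to a few hundred cheap evaluations —
training the recurrent classifier inside every fitness call would be
computationally indefensible — and the objective is a plug-in callable, so
a filter statistic or any other criterion can be swapped in. Defaults: 10
wolves, 30 iterations. Evaluated masks are cached, so repeated visits cost
nothing.

## Classifier: stacked bidirectional LSTM

Implemented from scratch in numpy: gate equations, bidirectional passes,
per-step combination O_t = tanh(W4·h_fwd + W6·h_back) feeding the next
stacked layer, and a dense 2-class softmax on the concatenation of the
last forward state and the first backward state of the top layer. Exact
BPTT gradients are verified against central finite differences (relative
error < 1e-5 with an absolute floor of 1e-4 against finite-difference
roundoff on near-zero entries).

Training recipe (defaults): learning rate 0.01, Adam (0.9 / 0.999 / 1e-8),
35 epochs, minibatch 80, 100 hidden units per direction, 2 stacked
bidirectional layers, gradient clipping at global L2 norm 1, data shuffled
once before training, no dropout. Each trial's selected features are
standardized by training-set statistics and presented as a length-d
sequence of scalars in fixed column order ("sequence" encoding); a
one-step vector encoding is available. Initialization: orthogonal
recurrent blocks, uniform fan-in input blocks, forget-gate bias +1.
Arithmetic is float32 by default (float64 via config, used by the
gradient-check tests). Training is bit-reproducible for a fixed seed on a
fixed platform. The stacking depth of 2 is the minimal reading of
"stacked"; it is configurable.

## Hyperparameter tuning: differential evolution

DE/rand/1/bin: mutation H_i = X_r1 + F(X_r2 − X_r3) with three distinct
others, binomial crossover at rate CR with one forced mutant coordinate
(without which the crossover semantics degenerate), greedy selection,
bounds enforced by clipping, integers rounded at decode, the learning rate
searched on a log10 scale. Defaults NP=10, F=0.5, CR=0.9, 10 generations;
none of these were prescribed by the reproduced method, which states only
that a heuristic random search was used — they are conventional DE
settings surfaced in `DEConfig`. The objective is the validation RMSE of
class-1 probabilities on a 20% stratified holdout carved from the training
part; candidates train under a reduced epoch budget (10) for tractability
and failures score as RMSE 1. The default training recipe seeds the
initial population, so the tuned configuration is never worse than the
defaults on this objective. The full pipeline runs tuning with a reduced
budget (NP=6, 3 generations) when enabled; it is off by default because
the untuned recipe already saturates the synthetic benchmark.

## Evaluation

Confusion counts with *high* as the positive class; accuracy, precision,
recall and F-score as percentages. Because published per-table formatting
differs, the formatting policy is explicit: half-up rounding (default) or
truncation, at a chosen number of decimals; zero-denominator metrics
return 0 and are flagged rather than NaN. ROC and PR curves sweep the
unique scores descending (one point per threshold, ROC anchored at (0,0)
and (1,1)); AUC is the trapezoid rule on the ROC, cross-checked against
scikit-learn in tests.

## Pipeline and problem sizes

Feature extraction runs once and is shared across the three label
dimensions; selection, optional tuning, training and evaluation are
per-dimension. All randomness derives from one global seed through named
substreams (FNV-1a hash of the stage name), so any stage is reproducible
in isolation. Every artifact is written with a JSON sidecar (seed, config,
version) and a finished run directory can re-evaluate a stored model on
stored features and reproduce the stored report exactly.

Problem sizes used by the test suite and the acceptance script are chosen
to keep a full run on one CPU core in minutes: the full synthetic study is
the canonical 1280 trials with `effect_size=2` (a strong, cleanly
separable regime), feature extraction vectorizes the R/S analysis across
channels, BGWO brute-force comparisons use D=8 planted problems with
n=200, and the sphere benchmark for DE uses 4 dimensions. The end-to-end
synthetic benchmark reaches >= 90% test accuracy on all three dimensions
under these conditions.

## Known limitations

* The R/S Hurst estimator carries the classical small-sample bias
  (~ +0.05–0.1 for memoryless series); no Anis–Lloyd correction is
  applied.
* The `n+1` variance normalization is biased; it is the default for
  fidelity, not correctness.
* The synthetic generator plants stationary, Gaussian, artifact-free
  structure; results on it say nothing quantitative about real EEG.
* No GPU path and no attention/GRU variants; binary labels only.
* The optional 5-second segmentation of trials into sub-epochs is not
  implemented; one feature row per trial throughout.
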