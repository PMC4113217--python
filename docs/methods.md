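# Methods

## Decoding model

The decoder operates on per-presentation feature vectors
x ∈ R^(D+1) (D = 372 interval means + 1 bias) and assumes:

- the user attends exactly one of K stimuli for the whole trial, so the
  attended-stimulus hypothesis c determines the target/non-target label
  s(c, j) of every presentation j;
- the one-dimensional projection wᵀx is Gaussian with class-dependent mean
  μ_{s(c,j)} and shared precision λ.  This is weaker than LDA's Gaussianity
  assumption in the full feature space (projections of non-Gaussian data can
  still be Gaussian) and makes inference O(K) per trial;
- w carries a zero-mean isotropic Gaussian prior with precision β, which
  regularizes the 373-dimensional estimate at small sample sizes.

The projection class means are fixed at μ_target = +1, μ_nontarget = −1
(configurable).  With these values the weight update is exactly a ridge
regression onto ±1 labels, which keeps the supervised limit interpretable;
any scaled pair works because w, λ rescale accordingly.

### EM updates

E-step: per trial, log p(c | X_t, w, λ) from the product of the projection
densities plus a uniform prior over c, normalized in log-space with
max-subtraction.  M-step:

- **w** ← (X Xᵀ + (β/λ) I)⁻¹ X ȳ with ȳ_n = q_n μ_t + (1 − q_n) μ_nt,
  where q_n is the posterior probability that epoch n's stimulus is the
  attended one.  Equivalently: the sum of all hard-label ridge classifiers
  weighted by the posterior mass of their labelings (linearity of the solve);
- **λ** ← 1 / max(expected MSE, 10⁻¹⁰), the expected squared distance of
  projections from their class means under the posteriors.  The floor guards
  against infinite precision on degenerate (perfectly fitting) toys; the
  analogous collapse of w is handled by the β cap; nothing caps λ, hence
  the explicit floor;
- **β** ← min((D+1)/‖w‖², 200).  The cap prevents collapse onto w = 0.

β is re-estimated in every one of the 5 inner iterations (the joint update
description admits either reading; per-iteration keeps all three updates one
coordinate sweep).

### What EM ascends — monotonicity

Because the w-update maximizes the *penalized* expected complete-data
objective (the ridge term comes from the prior p(w | β)), the quantity EM
theory guarantees to be non-decreasing is the MAP objective
log p(X | w, λ) + log p(w | β), compared under the β in effect during the
step.  `ClassifierPool.run_em` records these per-step increments
(`last_map_deltas`); on synthetic blocks they are non-negative to ~10⁻¹³.
The data term alone (the marginal likelihood used for classifier selection)
is *not* guaranteed monotone and in practice dips by up to ~4·10⁻³ in a
minority of steps while the penalty term moves — this is structural to a
prior-regularized EM, not a numerical artifact.

### Pool, selection, posthoc

Unsupervised likelihood maximization can converge to the label-swapped
solution (negated w).  Five pairs are drawn with ±w₀, w₀ sampled from the
model's own prior N(0, β₀⁻¹ I) with β₀ = 100 — using the prior as the
initialization law is the one choice consistent with the model itself.
λ starts at 1.  After each trial's 5 EM iterations the classifier with the
highest data log-likelihood (marginalized over the K hypotheses per trial,
summed over all stored trials) predicts; ties break to the lowest pair index.
An alternative selection rule (minimal expected squared error) is available
behind `selection="mse"`.  Each pair then keeps its higher-likelihood member
and re-initializes the other to its negation, copying λ and β (the pair
remains a reflection of one model; only the weight negation is prescribed).
Online predictions are final; `posthoc_reanalysis` re-classifies all stored
trials with the currently best classifier and is cheap enough to run after
every trial.

Reliable selection is a property of the *incremental* regime: running 5 EM
iterations from a cold start on a full block leaves 15–40% of runs on a bad
local optimum, whereas the per-trial schedule with pair re-initialization
ends with a correctly-oriented classifier (labeling AUC > 0.5) in ~100% of
runs at the default settings.  A related consequence of the paradigm
constraint: on decodable data even the very first trial is decoded above
chance (~36% at default SNR), because a single trial's within-trial structure
already identifies the attended stimulus better than guessing; exact
chance-level behavior holds only when the data carry no class information.

A disclosed slip of an earlier implementation of this method (a halved
constant in the Gaussian log-density) can be reproduced with
`loglik_mode="legacy-bug-compat"` for replication studies; it leaves
within-trial posteriors untouched and is off by default.

## Preprocessing

Online chain, strictly causal: Chebyshev type-2 low-pass (order 5, 20 dB
stop-band attenuation, stop edge 40 Hz) applied to continuous data before
epoching; epochs [−200, 700] ms around onsets; per-channel baseline
subtraction over [−200, 0] ms; feature = mean potential per channel in 12
intervals ([100 130] … [600 700] ms), concatenated channel-major → 372
features.  For the unsupervised decoder only: feature-wise z-scoring per
trial (population variance, over the trial's 90 epochs; constant features
are zeroed with a warning) and a constant bias feature of 1.

Outlier rejection (calibration data only): an epoch is removed when its
variance exceeds 2.5 × the 90th percentile of all epoch variances.  The
percentile uses linear interpolation between order statistics, and "variance
within an epoch" pools all channel-sample values into one scalar (a
per-channel-max variant is available) — both points are under-determined
upstream and configurable.  Channel-level rejection exists as an offline
utility only.  The acausal 0.5–20 Hz forward-backward band-pass exists only
on the visualization path (ssAUC maps).

## Synthetic sessions

The generator emits baseline-window epochs directly at 100 Hz / 31 channels
(the acquisition chain — 1 kHz recording, hardware band-pass, 45 Hz low-pass,
downsampling — is treated as upstream; a resampling utility covers imported
data).  Non-target epochs carry a small class-independent exogenous response;
target epochs add a unit-amplitude difference waveform — a fronto-central
negativity (half-sine, 100–200 ms, peak −1 at 150 ms) and a centro-parietal
positivity (250–600 ms, +1) — scaled by `difference_amplitude` (µV).  Noise
is AR(1) in time (coefficient 0.8, marginal std 1 µV) to mimic EEG
autocorrelation, optionally spatially correlated, with optional per-block
drift and high-variance artifact injection for exercising the rejection rule.

**Default amplitude 0.35** realizes the package's "high SNR" study condition:
a pilot sweep over {0.25, 0.30, 0.35, 0.45} (10 seeds each) showed 0.35 is
the smallest value at which a 30-trial online block warms up reliably
(median trials-21–30 accuracy 1.0, posthoc ≥ 80% in all seeds) while leaving
a visible warm-up period; it was frozen once and not tuned further.  Cohort
harnesses draw subject-specific amplitudes uniformly from [0.25, 0.45] to
emulate between-subject variability.

What the generator does *not* emulate: overlap of consecutive stimulus
responses (SOA 175 ms < epoch length; epochs are drawn independently),
latency/amplitude jitter of ERP components, eye/muscle artifacts with
realistic spatio-spectral structure, 1/f background spectra, or
electrode-geometry-consistent field spread.  Passing tests therefore
demonstrate correctness and the qualitative learning dynamics (warm-up,
posthoc recovery, chance behavior, SNR monotonicity) — not performance on
human EEG.

## Baseline

Shrinkage LDA on the un-normalized, bias-free 372-dim features (per-trial
normalization and the bias exist for the unsupervised model; a switch allows
matched preprocessing for ablations).  The pooled within-class covariance is
shrunk toward νI (ν = mean eigenvalue) with the analytic Ledoit–Wolf
intensity; w = C⁻¹(m_t − m_nt), bias centers the decision value between the
class means.  Trial prediction sums the J decision values per stimulus
(equivalent to the mean at equal counts) and takes the argmax, ties to the
lowest stimulus id.  The baseline is trained once on an outlier-rejected
30-trial calibration block and never adapted.

## Evaluation harnesses

- Block protocol: supervised model trained on the calibration block and held
  fixed; the unsupervised pool randomly re-initialized before every
  unsupervised block; posthoc trajectory recorded after each trial.
- Extended simulation: evaluation blocks concatenated chronologically, pool
  initialized once and never reset, posthoc re-analysis at the very end;
  per 10-trial sub-block, two-sided paired t-tests (α = 0.05, no
  multiple-testing correction, as is conventional for this kind of
  sub-block comparison) across
  simulated subjects on matched data.
- Metrics: trial selection accuracy; symbol accuracy (consecutive trial
  pairs, both selections must be correct; the speller shows `°` when both
  failed); time-to-control (first trial of the first run of ≥ 3 consecutive
  correct selections — the probability of guessing that is (1/6)³);
  ssAUC = 2·AUC − 1 per channel/interval, AUC by the Mann–Whitney rank-sum
  with midranks.

## Numerical choices

- Ridge solves go through a cached eigendecomposition of the Gram matrix
  (updated incrementally per appended trial), so the per-classifier,
  per-iteration cost is two matrix-vector products; all ten pool members are
  updated with batched BLAS calls.
- Posteriors and data log-likelihoods are computed from per-trial sufficient
  statistics (per-stimulus projection sums, total sum, sum of squares) in
  log-space with log-sum-exp.
- Argmax ties (prediction and selection) break to the lowest index;
  documented, deterministic.
- Sessions, checkpoints and records serialize to NPZ (format-version tagged,
  bit-exact round-trip) with tidy CSV exports; all randomness flows from one
  seed through named substreams.

## Problem sizes

Defaults everywhere are the study settings (30-trial blocks, 6 evaluation
blocks, 31 channels).  Statistical test suites use what one CPU core handles
comfortably: 20–30 seeded blocks for the monotonicity/chance suites, 10
seeds for warm-up/recovery, a five-subject cohort in the acceptance script.

## Known limitations

- The synthetic generator's realism limits (listed above) mean absolute
  accuracies are not comparable to human data; only the qualitative ordering
  (supervised ≥ posthoc ≥ unsupervised-online ≫ chance) and the pipeline
  arithmetic are meaningful cross-checks.
- The uniform prior over the attended stimulus is a parameter, so language
  models could plug in, but no language model is implemented; cross-subject
  transfer initialization is likewise out of scope.
- `TrialStore` assumes complete trials of exactly K·J epochs; online epoch
  dropout (e.g. rejected artifacts during spelling) is not modeled, matching
  the keep-all-epochs online rule.
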