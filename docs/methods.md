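# Methods

This note documents the model, the estimation and inference procedures, the
synthetic data the package validates itself against, and the numerical and
design choices a user or maintainer should know about.

## Model and estimator

The observation model is linear mixing in feature space: at epoch latency t
and trial n, the D-channel feature vector x_n(t) (here instantaneous band
power, but any per-trial channel feature works) contains some component
whose amplitude co-varies across trials with a continuous behavioral
response y_n.  A spatial filter w reduces the channels to z_n(t) = wᵀx_n(t);
the estimator maximizes the across-trial Pearson correlation between z and
y.  Writing X for the D × N matrix of trials at one latency and R = XXᵀ/N,
the maximizer is the ridge-type closed form

    ŵ ∝ (R + λI)⁻¹ X y.

Two conventions are fixed here and matter for reproducibility:

* **Centering.** Channels and response are mean-centered over the augmented
  columns before the solve and inside the objective.  Pearson correlation
  presumes centered data; skipping this step mixes mean offsets into the
  covariance and changes the solution.
* **Scale.** The objective is invariant to rescaling of w; reported filters
  are unit L2 norm and the closed-form solution always has a nonnegative
  training objective (negating y negates w and leaves it unchanged).

**Temporal augmentation.** For a training window of Δt consecutive samples,
the per-sample trial matrices are concatenated, X̃ = [X^t, …, X^{t+Δt−1}]
(D × NΔt), and the response is replicated per sample, ỹ = 1⊗y.  The
covariance is normalized by the augmented column count NΔt — the point of
the construction is a Δt-fold larger sample for estimating R — and the
block-replicated response makes all window samples contribute to one joint
correlation.

**λ selection.** The grid is logarithmic, spanning 10⁻⁵–10⁻¹ times the mean
covariance eigenvalue (trace(R)/D), five points.  The scale-relative grid
keeps the same code meaningful across bands and feature scalings; the upper
end stops at 10⁻¹ because stronger shrinkage toward the plain
cross-covariance direction measurably costs held-out correlation on
well-conditioned problems (D of tens, thousands of augmented columns) while
never helping in our pilots.  λ is selected inside each outer
cross-validation fold on a 3-fold inner split of that fold's training data
only; the outer held-out trials never influence the choice.

**Degenerate inputs.** A zero-variance projection or response raises an
`UndefinedCorrelationError` rather than returning 0 — a correlation of zero
is a claim, not a fallback.  Per-latency traces mark undefined points as
NaN.  At λ = 0 with singular covariance the solver falls back to the
pseudoinverse with a warning.

## Cross-validated correlation (r_cv)

Each window's merit is a pooled k-fold (default 5) cross-validated
correlation: per fold, the filter is fitted on the other folds, the held-out
trials are projected (component amplitude averaged over the window's Δt
samples), and the pooled held-out (z, y) pairs over all folds give one
Pearson correlation.

Pooling across folds needs care because the solution scale is arbitrary and
varies from fold to fold.  Three conventions were considered: raw pooling
(fold-scale mismatch attenuates the pooled r and inflates its variance),
standardizing held-out projections within each validation fold (the fold
mean/SD are then estimated from only ~N/k held-out values, and that
estimation noise propagates into the variance of r_cv), and unit-norm
filters with the projection rescaled by the training-set scale sqrt(wᵀRw).
The third convention is implemented: the training-derived scale is low-noise
(estimated from (k−1)/k of the trials) and leaves the held-out draws
untouched, so the pooled estimate behaves like a single correlation at the
full sample size — the property the effect-size recovery tests check
(held-out r_cv inside the Fisher 95% band of the planted correlation).

## Permutation inference and τ selection

Significance per window comes from a permutation null: the response vector
is randomly reassigned across trials (default 1000 times), the *entire*
cross-validation — including λ re-selection — is rerun per permutation, and
the add-one estimator p = (1 + #{r_null ≥ r_obs}) / (1 + n_perm) avoids
zero p-values.  Re-selecting λ per permutation is the conservative choice
(the null statistic undergoes exactly the observed statistic's pipeline); a
`reselect_lambda=False` switch freezes the observed λ instead.

The engine vectorizes over permutations: the fold partition is fixed, so
each (fold, λ) covariance factorization is shared and the cross-covariances
of all permuted responses are one matrix product (using the identity
X̃ Ỹc = Δt·T̄ Yc, where T̄ is the window-averaged trial matrix).  This is
what makes 10⁵–10⁶ full cross-validations per scan affordable.

Benjamini–Hochberg step-up (via statsmodels) controls the FDR across the
window grid.  τ is chosen among the significant windows as the largest
local maximum of r_cv taken *along the significant offsets* (neighbors are
adjacent significant windows); plateau ties break toward the earliest
window — the earliest neurophysiological onset — and no significant window
is a valid outcome (τ = none).

## Spectral front end

Complex Morlet kernels φ_f(t) = α·exp(2πift)·exp(−t²/2σ²) with
σ = cycles/(2πf); α sets unit L2 norm so that power is comparable across
frequencies (white noise passes with unit gain at every f; a coherent
sinusoid gains with √σ).  Default 3 cycles: with 60 ms analysis windows the
temporal resolution σ_t ≈ 48 ms at 10 Hz is matched to the window length;
larger values smear latency information the scan is supposed to localize.
The frequency grid is 1 Hz within each closed band.  Convolution is
same-length with zero padding; latencies within ±2σ of the epoch edges are
flagged (not dropped) in `edge_flags`; note that boundary effects ≤ ~5%
extend somewhat beyond the flagged region (the kernel support is ±5σ), so
analyses needing strict stationarity should discard a wider margin.

Band collapse follows max-then-subtract order: per (channel, latency,
trial) the maximum power over the band's grid frequencies, minus the mean
of that collapsed value over a baseline trial set (default: all trials of
the same subject/condition).  Whether the baseline mean is taken before or
after the frequency maximum is ambiguous in principle; the implemented
order (after) makes the baseline trials average to exactly zero per
channel/latency, which is the property downstream code relies on.

## Preprocessing

Deterministic and minimal: zero-phase Butterworth high-pass (default
1.5 Hz) and zero-phase IIR notches (50/100 Hz), common-average re-reference,
epoching at −700..1000 ms around events, baseline amplitude subtraction
over −300..−100 ms.  Epoch sample selection is half-open: samples k with
t0 ≤ 1000·k/fs < t1 (870 samples at 512 Hz for the default window).  Ocular
artifact removal and automatic trial rejection are identity hooks; the
pipeline driver fixes the stage order (filter → ocular hook → re-reference
→ epoch → rejection hook → baseline) so external implementations slot in
without reordering.

## Synthetic ground truth

The generator plants exactly the structure the estimator assumes, so every
recovery claim can be scored against known truth.

* **Source.** A carrier at the band center (10 Hz for α) under a Hann
  envelope with compact support: the planted window (default 240–300 ms)
  widened by 30 ms on each side.  Compact support matters: an envelope with
  smooth infinite tails (a Gaussian) leaks trial-correlated power to
  distant latencies, and at high SNR the scan then finds significant —
  and sometimes maximal — correlations far from the planted window, because
  correlation is amplitude-blind.  The pad keeps the burst longer than one
  carrier cycle so it stays band-limited.  The envelope *shape* is common
  to all trials; only its per-trial scale varies, which makes measured band
  power exactly proportional to planted power (no shape-induced
  distortion of the planted correlation).
* **Effect.** Per-trial log source power and log RT are jointly Gaussian
  (a Gaussian copula over lognormal margins: σ = 0.15 each, RT median
  780 ms).  The requested ρ is the *linear-scale* population correlation
  between window power and RT; the copula parameter is solved from the
  bivariate-lognormal moment formula so that the linear correlation equals
  ρ exactly.  With equal log-σ the whole range ρ ∈ [−1, 1] is attainable;
  an infeasible request is clipped and the attained value recorded in
  `GroundTruth`.  Positive ρ means slower trials carry more power, the
  default direction.
* **Mixing and noise.**  The amplitude topography is a smooth random
  unit-norm vector over the channel index (no head model); 1/f background
  noise enters through six smooth spatial patterns (per-channel SD 0.25)
  plus white sensor noise (SD 0.08).  The source's envelope-peak RMS at its
  strongest channel is 8 by default — a deliberately strong, high-SNR
  induced response.  These values are the package's versioned validation
  conditions: they put the analysis in its near-asymptotic regime, where
  recovery benchmarks (topography cosine, Fisher-band effect-size
  coverage, ±30 ms localization) are properties of the method rather than
  of a particular noise draw.  They were fixed once from engine-level and
  pipeline-level pilot runs on seed ranges disjoint from those used by the
  validation tests.

**What passing tests do and do not show.**  The generator shares the
analysis's feature space (a single oscillatory source, stationary noise
mixed through a few fixed patterns, no artifacts, no non-stationarity, no
subject heterogeneity) and its SNR is generous.  Green tests therefore
demonstrate correctness and calibration of the *procedure* — the estimator
attains its closed-form optimum, held-out correlations are unbiased with
Fisher-rate variance, the permutation test holds its nominal level, the
scan localizes a genuinely confined effect.  They do not predict effect
sizes on real EEG, where attenuation from artifacts, source mixture, and
lower SNR is expected and correlations around 0.2–0.4 are typical.

**Power-space topography.** The analysis operates on band power.  A source
mixed with amplitude topography a produces channel power a_c²·|s|² (plus
zero-mean cross terms), so the recoverable coupling pattern is the
elementwise square of a, not a itself.  `GroundTruth` stores both
(`topography`, `power_topography`); recovery is scored against the latter.

## Numerical choices

* Linear solves via Cholesky factorization of R + λI (never explicit
  inversion); pseudoinverse fallback with warning at λ = 0.
* FFT-based Morlet convolution with one shared forward transform per
  dataset, chunked over trials to bound the working set; verified against
  direct time-domain convolution to 1e−8 relative.
* Fold partitions and permutations come from `numpy.random.Generator`
  seeded per window by spawned `SeedSequence` children: the whole scan is
  bit-for-bit reproducible from (seed, config), and the config hash is
  written into the scan summary.
* Window and epoch sample selection is half-open everywhere; band
  intervals are closed.
* BH step-up is delegated to statsmodels and cross-checked in the test
  suite against a brute-force implementation.

## Known limitations

* No head-model (lead-field) simulation, no artifact synthesis, no
  scalp-surface interpolation: the forward model is a plain channel-value
  vector.
* A single maximizing component per band/window; no multi-component
  extraction.
* The permutation test assumes exchangeability of trials under the null;
  temporally structured RT drifts (fatigue, learning) violate it and would
  need block-aware permutations, which are not implemented.
* EDF/BrainVision readers are thin wrappers over MNE and are exercised
  only lightly by the test suite, since those binary formats cannot be
  written (and thus round-tripped) with the packages available offline.
* The sliding-window scan treats bands separately; no joint correction
  across bands.

## Default problem sizes in the validation suite

The test suite and the acceptance script run the method at reduced but
statistically meaningful scales — e.g. 50-seed recovery studies, 400-dataset
calibration with 200 permutations, effect-size recovery at N = 800 trials —
chosen so the full validation completes on a single CPU in tens of minutes
while keeping Monte-Carlo margins small relative to the tested tolerances.
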