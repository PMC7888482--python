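# Methods

This note documents the models, estimator conventions and design choices
behind `strucdyn`, in the order data flows through the pipeline.

## Synthetic study model

The generator emulates the statistical structure of a high-quality
resting-state fMRI + diffusion connectome study: 34 cortical regions,
100 subjects, 1200 frames at TR = 0.72 s, region volumes spanning 49–4570
voxels, and 34 × 34 nonnegative symmetric connectomes at 25 % edge density.

**Connectomes.** A single random edge support with exactly
round(density · n(n−1)/2) edges is shared by all subjects (a group
consistency structure); base edge weights are log-normal
(μ = 8.5, σ = 1.2, spanning roughly 10²–10⁵ like streamline counts) with
per-subject multiplicative jitter exp(N(0, 0.3)). Node strength is the row
sum of each subject's own matrix.

**Timescales.** Each region's intrinsic timescale is a monotone *rank* map
of its mean strength, τ_i = τ_min + (τ_max − τ_min)(rank(s_i) − 1)/(n − 1)
plus N(0, 0.5 s) noise, clipped to [τ_min, τ_max] = [0.5, 6] s. Ranks (not
raw weights) keep the heavy-tailed weight distribution from destabilizing
τ. Setting `couple_tau_to_strength=False` assigns the same graded τ values
to a random permutation of regions — the decoupled null. The AR(1)
coefficient is the exact Ornstein–Uhlenbeck discretization
φ_i = exp(−TR/τ_i); latent dynamics are a per-region AR(1) with
unit-variance innovations rather than network-coupled dynamics, so the
ground truth the analysis must recover is unambiguous.

**Volume confound.** Each of a region's V voxels carries the latent signal
plus iid N(0, 7²) thermal noise plus a shared global nuisance signal (an
AR(1) with a 4-s timescale, unit sd, amplitude 1). The region series is the
voxel mean, so region noise has sd 7/√V: large regions yield cleaner slow
signal, which is exactly the mechanism by which parcel volume confounds
timescale statistics. By default the voxel mean's distribution is sampled
directly (region noise at sd 7/√V) instead of materializing voxel matrices
— the two are identical in distribution, and a full default study would
need tens of GB of voxel series; `materialize_voxels=True` builds actual
voxel bundles for small configurations, and the voxel-mean identity is
tested. Volumes are log-uniform over [49, 4570] and rank-coupled to mean
strength through a Gaussian copula (ρ = 0.6), reflecting that large regions
also attach more streamlines; without this coupling, volume adjustment
would have nothing to attenuate.

All randomness flows from one integer seed through named
`SeedSequence` substreams (connectome / volumes / timescales / bold /
global), so studies are bit-identical per seed.

**What the generator does not emulate:** hemodynamics, scanner physics,
head motion, spatial autocorrelation between regions, multi-exponential or
oscillatory dynamics. Passing tests therefore demonstrate that the
*analysis* recovers a known coupling under realistic dimensions and noise,
not that real BOLD obeys an AR(1) model.

## Preprocessing

The chain is nuisance regression (against the global signal by default) →
linear detrend → hard-threshold FFT high-pass at 8 × 10⁻³ Hz → z-score
(ddof = 1). Two implementation details matter:

- `preprocess_bold` applies the linear steps as a **single joint OLS
  projection** on [intercept, linear trend, the sine/cosine pairs of every
  FFT bin with 0 < f < cutoff, nuisance regressors]. Residualizing on
  exact-bin sinusoids is identical to zeroing those FFT bins, and a joint
  projection is exactly idempotent — running the chain twice changes
  nothing — whereas sequentially chained partial projections are not (a
  high-passed series regains a small trend estimate through spectral
  leakage of the ramp). The standalone functions (`detrend_linear`,
  `highpass_hard`, `regress_nuisance`) implement the individual sequential
  operations for single series.
- The DC bin is always removed (the intercept); z-scoring cancels in all
  relative-power statistics, so the n−1 convention is immaterial
  downstream. Whether z-scoring happens before or after filtering does not
  affect relative power either.

## Spectral statistics

The spectrum is the plain (untapered, unsmoothed) one-sided periodogram,
renormalized to unit total power; band powers are therefore unitless
fractions. "Lowest 20 % of frequencies" is implemented by bin count,
k ≤ floor(0.2·N/2): at N = 1200, TR = 0.72 s this is bins 0–120 with upper
edge 120/864 = 0.1389 Hz (printing as 0.14 Hz), and the five equal-width
bands close at 0.28 / 0.42 / 0.56 / 0.69 Hz, partitioning total power
exactly. The DC bin belongs to the lowest band (its power is ~0 after mean
removal); bands are half-open [lo, hi) with the Nyquist bin included when a
band closes exactly at Nyquist. Including or excluding the edge bin would
move the RLFP cutoff by one bin (≈ 0.0012 Hz); the bin-count convention is
fixed here because it reproduces the 0.14 Hz edge on the HCP-like grid.

The log–log slope is a least-squares fit of log₁₀ power on log₁₀ frequency
over the middle 50 % of positive-frequency bins by index (the grid
convention for "excluding the lower and upper quarter of frequencies");
zero-power bins inside the window are excluded and counted.

A raw periodogram bin is distributed S(f)·χ²₂/2, so its *binwise* relative
scatter is ~100 % at any series length. Tests of the AR(1) closed form
S(f) ∝ 1/(1 + φ² − 2φ cos 2πf·TR) therefore compare the spectrum *shape*
after coarse-graining into 32 equal-count frequency bands, where sampling
error is ~3 % at T = 2¹⁶.

## Autocorrelation timescales

The ACF uses the biased estimator (nonnegative-definite by construction).
The decay timescale fits ACF(k) ≈ A·(exp(−k·TR/τ) + B) by bounded
nonlinear least squares over lags 1 … min(first_zero − 1, 50): lag 0 is
excluded (noise variance), everything at or past the first zero crossing is
excluded, and the offset B absorbs the fact that finite rs-fMRI ACFs rarely
decay to exactly zero. τ is constrained to the fitted lag window: a decay
constant longer than the window is not identifiable from it, and unbounded
fits on near-white series (ground-truth τ below TR) otherwise return
arbitrary extrapolations; fits pinned at the bound are flagged
`window_limited`, multi-start initialization is used, and non-convergence
is reported honestly (τ absent). The area measure is the rectangular sum
TR·Σ ACF(k) up to (not including) the first lag with ACF ≤ 0 — ties count
as a crossing — with a `no_crossing` flag when the ACF stays positive over
the available lags.

## Feature zoo conventions

- **Motifs.** Binary coding maps positive increments to 'u' and all others
  (including exact zeros) to 'd'; tercile coding ranks the increments
  (average ranks for ties, so constant increments land entirely in the
  middle symbol) and splits at n/3 and 2n/3. Frequencies are counts of
  overlapping words over the number of word positions; single differencing
  only.
- **SampEn(m = 2, r = 0.1).** Chebyshev distance, tolerance r relative to
  the sd of the segment analyzed, template pairs i < j over the first
  N − m positions for both m and m + 1; −ln(A/B), with A = 0 reported as
  +inf. The sliding-window stationarity ratio cuts the series into 10
  equal windows, re-z-scores each, and returns sd(window SampEn)/|SampEn|
  of the full series; on short white-noise windows A = 0 occurs with
  appreciable probability and the ratio is then NaN — a limitation of the
  (2, 0.1) parameterization on unstructured data, not of the
  implementation. Autocorrelated BOLD-like series are unaffected.
- **Automutual information.** Increments are binned into ceil(√(N/5))
  equiprobable bins and MI estimated per lag (a Kraskov k = 4 variant is
  available; the *first-minimum lag* is robust to the estimator). The
  first strict local minimum over k = 1…20 is returned, treating I(0) as
  +∞; note that for oscillatory increments the AMI peaks at the half- and
  full-period lags (anticorrelation is still dependence) and its first
  minimum sits near the quarter-period decorrelation lag.
- **Visibility graph.** Natural visibility (strict inequality: every
  intermediate sample strictly below the chord), computed by an O(N²)
  vectorized running-maximum-of-slopes scan per source node (equivalent to,
  and tested against, the O(N³) definition and networkx). "ol90" is defined
  here as mean(degrees ≥ 90th percentile)/mean(degrees) — a named,
  fixed variant, not claimed identical to any external toolbox's statistic.

Every feature is registered with its parameters and an hctsa-style tag;
all features are invariant to additive shifts, and the motif/visibility
features also to positive rescaling.

## Inference

ρ_V is computed by rank-then-residualize: average ranks of x, y and the
covariate; OLS-residualize the x- and y-ranks on [1, rank(z)]; Pearson
correlation of the residuals. Without ties this equals the classical
partial-correlation recursion; with ties the residual form remains well
defined. p-values use the t approximation (df = n − 2 plain, n − 3
partial); an exact permutation p is available for n ≤ 10. BH-FDR is
applied across features in the group analysis and across subjects in the
individual sweep, both at q = 0.05. Group-level analysis averages each
feature and strength across subjects per region first; the individual
sweep uses each subject's own strengths (subject-specific by default).
Feature ranking orders features by |mean over subjects of ρ_V| descending,
ties broken by name.

Measured calibration: the empirical type-I rate of the partial Spearman at
α = 0.05 over 2000 null datasets of n = 34 is within 0.05 ± 0.02 (the
acceptance script recomputes it per run).

## Problem sizes used in tests and the acceptance script

Unit tests run on small studies (≈ 12 regions × 6 subjects × 240 frames);
the recovery and agreement analyses use the full default study
(34 × 100 × 1200), with the seed sweep at 50 seeds for the coupled model
and 50 for the decoupled null — sizes chosen so the full suite and the
acceptance script each complete in a few minutes on one CPU while keeping
the per-seed analysis identical to the default study conditions.

## Known limitations

- AR(1) latent dynamics cannot probe multi-exponential or oscillatory
  timescale structure; the decay fit and RLFP agree almost perfectly here
  by construction, more than they would on real data.
- Ground-truth τ below TR is only weakly identifiable from the ACF; the
  window bound makes such estimates conservative rather than explosive.
- The published HCP reference values quoted in report annotations (group
  ρ_V ≈ 0.53, RLFP–volume ρ ≈ 0.61, 43 % of individuals significant) come
  from restricted-access data and are reproduced here in *sign and
  mechanism*, not magnitude; synthetic effect sizes are larger because the
  generator's coupling is cleaner than nature's.
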