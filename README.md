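# strucdyn

Regional structure–function analysis of resting-state BOLD dynamics: do
brain areas with stronger structural connectivity show slower intrinsic
timescales of spontaneous activity?

`strucdyn` is a Python library (plus a thin `strucdyn` CLI) for the
region-level version of this question. It takes, per subject, a
region × time BOLD matrix and a weighted undirected structural connectome,
summarizes each region's dynamics with timescale-related time-series
statistics and its connectivity with node strength, and quantifies their
association with partial rank correlations that control for region volume —
the dominant confound, since larger regions average more voxel noise away.
A seeded synthetic-study generator with known ground-truth timescales makes
the whole pipeline testable end to end.

## The statistics at the core

- **RLFP** — relative low-frequency power: the series is detrended,
  z-scored and Fourier transformed; with total power normalized to 1, RLFP
  is the power in the lowest 20 % of frequencies (f < 0.14 Hz at
  TR = 0.72 s, N = 1200). Slow, persistent dynamics ⇒ high RLFP.
- **ACF timescales** — an exponential fit
  ACF(k) ≈ A·(exp(−k·TR/τ) + B) over lags before the first zero crossing,
  and the area under the ACF to its first zero. For AR(1) dynamics with
  coefficient φ these target exactly τ = −TR/ln φ.
- **fALFF** — relative power in 0.01–0.08 Hz, the common fMRI variant.
- **A feature zoo** — hctsa-style high performers: up/down and tercile
  symbolic-motif frequencies on the differenced series, SampEn(2, 0.1) and
  its sliding-window stationarity ratio, the first minimum of the
  automutual information of increments, and a natural-visibility-graph
  degree-outlier ratio.
- **Node strength** — s_i = Σ_j A_ij (weighted degree) per subject, plus a
  group connectome that keeps edges present in > 75 % of subjects and
  averages their nonzero weights.
- **ρ_V** — partial Spearman correlation: ranks of feature and strength are
  residualized on volume ranks and the residuals correlated; p-values via
  the t approximation (df = n − 3), Benjamini–Hochberg FDR across features
  or across subjects.

## Worked example

```python
from strucdyn import SyntheticStudyConfig, StrengthDynamicsModel
from strucdyn.synthetic import generate_study

study = generate_study(SyntheticStudyConfig(n_subjects=25, seed=7))
model = StrengthDynamicsModel.from_study(
    study, feature_names=["rlfp", "band5", "motif2_uduu", "motif3_aabb"]
)
results = model.fit()
print(results.summary())
```

```
Strength-dynamics associations (partial Spearman | volume, q=0.05)
============================================================
  feature   rho_V     p      p_adj   sig frac_indiv_sig rank
------------------------------------------------------------
       rlfp +0.937 1.17e-15 4.66e-15   *           1.00    1
      band5 -0.905 4.84e-13 9.67e-13   *           1.00    2
motif2_uduu -0.311 7.86e-02 7.86e-02               0.00    4
motif3_aabb +0.754 3.95e-07 5.26e-07   *           0.00    3
------------------------------------------------------------
```

The generator coupled each region's ground-truth AR(1) timescale to its
mean node strength, so the fit recovers a strongly positive group-level
ρ_V for RLFP (+0.94 here, after controlling for region volume), with every
individual subject significant. Because total spectral power is normalized,
the association flips sign in the upper frequency bands (band5: −0.91), and
the symbolic motifs behave as expected for slow dynamics: the rapid
"up-down-up-up" motif anticorrelates with strength while the small-movement
"aabb" tercile motif correlates positively. `results.plot_group_scatter()`
and `results.plot_individual_hist()` draw the rank-residual scatter and the
per-subject ρ_V histogram.

The same analysis runs from the shell on plain TSV files:

```bash
strucdyn simulate --seed 1 --out study/
strucdyn preprocess --in study/sub-000_bold.tsv --out clean.tsv
strucdyn features spectral --in clean.tsv --out features.tsv
strucdyn run --config study.yaml --out results/
```

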