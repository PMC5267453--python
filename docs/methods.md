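# Methods

## Model

All inference happens on the arcsine-transformed scale
f(x) = arcsin(2x − 1), which maps beta values in [0, 1] to
[−π/2, π/2], stabilizes the variance of beta-distributed proportions
(so residual variance no longer tracks the mean), and is close enough
to linear that a cell mixture on the beta scale is well approximated
by a linear model on the transformed scale.  The transform is finite
at 0 and 1, so boundary beta values are legal and never clipped.

For CpG site *i*: normal-cell signal X_is ~ N(m_i, σ_i²); pure cancer
signal Y_is = X_is + δ_is with δ_is ~ N(μ_i, τ_i²); observed tumor
signal for a sample with purity λ_s:

    Y′_is = (1 − λ_s) X_is + λ_s Y_is = X_is + λ_s δ_is
          ~ N(m_i + λ_s μ_i, σ′_i²).

The null hypothesis of interest is μ_i = 0.  Because λ_s multiplies
μ_i, the purity is an experimental design factor, not a nuisance
covariate: a test ignoring it conflates purity variation with noise,
and an additive purity covariate mis-specifies the mean structure.
Purities are treated as known constants downstream; uncertainty in λ̂
is not propagated.

## Purity estimation

1. **iDMC selection** (`select_idmcs`).  Per site, a two-sided
   Wilcoxon rank-sum test of tumor vs control beta values (normal
   approximation with tie correction and 0.5 continuity correction —
   identical to the standard asymptotic Mann–Whitney; an exact
   enumeration is used only as a test oracle).  Sites must have tumor
   beta variance > `var_min` (default 0.005, sample variance): a site
   whose tumor values do not vary cannot be responding to varying
   tumor content.  Survivors are ranked by ascending p with a
   deterministic tie-break (larger |z|, then site id) and truncated to
   `n_top` (default 1000).  Direction is hyper when mean tumor beta ≥
   mean control beta, else hypo (exact equality → hyper; measure-zero).
   The variance filter is applied before ranking, as a hard filter.
2. **Transform** (`transform_idmc_betas`).  Hyper iDMC betas pass
   through; hypo betas flip v → 1 − v.  The flip depends only on the
   direction label, never on the value itself.  Sites absent or
   missing for a sample are dropped (error if > 50% drop).
3. **Mode** (`density_mode`).  Gaussian KDE of the pooled transformed
   values, Silverman bandwidth 0.9·min(sd, IQR/1.34)·n^(−1/5) with a
   floor of 0.01 (a point mass then still yields a well-defined
   peak), evaluated on 1001 equispaced grid points spanning [0, 1]
   (resolution ≈ 0.001 purity).  λ̂ is the grid point of global
   maximum density, smallest grid point on exact ties; no boundary
   correction is applied.  Near-tied secondary peaks (within 5% of
   the maximum) are logged as a stability diagnostic — when they
   appear, re-estimating with a different iDMC count is advisable.

Estimation is strictly per sample: λ̂ for one tumor depends only on
its own column and the iDMC list.  Estimates are clamped to [0, 1]
(and floored at 1e−6 so they remain valid purity-table entries).

The estimator carries a small systematic bias: at a hyper iDMC the
observed beta is (1 − λ)x + λy with baseline x slightly above 0 and
pure-cancer y slightly below 1, so the density mode sits at
x + (y − x)λ rather than λ.  With marker-grade sites (x ≈ 0.1,
y ≈ 0.97) this bounds the error at roughly 0.05 near λ = 0.3 and less
elsewhere; the rank ordering of samples is essentially unaffected.

## DM calling with normal controls

Per site, stack the transformed values Z = (X_1..X_n0, Y′_1..Y′_n1)
and build the (n0+n1) × 2 design W with an all-ones first column and
second column (0, …, 0, λ_1, …, λ_n1).  Then:

- β̂ = (WᵀW)⁻¹WᵀZ ≜ HZ, β̂ = (m̂, μ̂);
- residuals ε̂ = Z − Wβ̂; group variances σ̂² = Σ_normals ε̂²/(n0−2)
  and σ̂′² = Σ_tumors ε̂²/(n1−2) (both groups therefore need > 2
  samples);
- var(β̂) = H₁ΣH₁ᵀ + H₂Σ′H₂ᵀ with Σ = σ²I, Σ′ = σ′²I; only the
  [2,2] element is needed, which reduces to q₀σ² + q₁σ′² with scalars
  q₀, q₁ precomputed from H;
- variance shrinkage across sites: σ̃² = exp((1−w)·log σ̂² + w·ḡ)
  with ḡ the mean log variance, applied separately to the normal-pool
  and tumor-pool vectors; default weight w = 0.2.  This preserves each
  pool's geometric mean for every w and stabilizes per-site estimates
  when n is small;
- Wald statistic t = μ̂ / se(μ̂) with se from the shrunken variances,
  two-sided p from t(n0+n1−2) — the degrees of freedom are not
  moderated after shrinkage;
- Benjamini–Hochberg FDR across all tested sites.

Degenerate sites (zero residual variance in both groups) get p = 1
when μ̂ = 0, else p → 0, with a `degenerate` flag rather than NaN.
Sites with any missing value among the used samples are dropped
complete-case with a logged count.

Because shrinkage tightens the variance estimates while the reference
distribution keeps n0+n1−2 df, the test is mildly conservative: at
n0 = n1 = 30 the realized null level at nominal α = 0.05 is ≈ 0.046.
This is a property of the formulas as specified, not a defect of the
implementation, and disappears as w → 0.

When all λ = 1 the design reduces to the two-group indicator and the
statistic coincides with the heteroscedastic two-sample comparison
from the same variance estimators; scaling the purity column by k
rescales μ̂ by exactly 1/k (an exact linear-algebra identity, the
operational form of the multiplicative-effect claim).

## Control-free DM calling

With Y′_is ~ N(m_i + λ_s μ_i, σ′²), a per-site OLS of the transformed
tumor values on (1, λ) estimates μ_i as the slope; its t statistic
(n1 − 2 residual df) is algebraically r·sqrt((n1−2)/(1−r²)) where r
is the Pearson correlation with the purities.  Sites are ranked by

    Pr(|μ_i| > c) = Φ((−c − μ̂)/se) + 1 − Φ((c − μ̂)/se),

the plug-in posterior μ ~ N(μ̂, se²) — the minimal Bayesian reading of
a posterior exceedance probability; no prior is imposed.  The
threshold c (default 0.1) is on the **arcsine scale**, the scale on
which μ is defined; users thinking in beta units should note that 0.1
rad corresponds to a beta difference of about 0.05 at mid-methylation.
At c = 0 the probability is identically 1 (returned exactly so), and
the ranking degrades cleanly to the |t| tie-break — equivalently the
|r| ranking.  Raising c demotes sites whose statistic is large only
because the standard error is tiny.  By default no p-value column is
emitted (the output is a ranking); `emit_p` adds two-sided t(n1−2)
p-values.

Requirements: ≥ 4 tumors (hard), > 20 recommended (warning below),
and purity dispersion sd(λ) ≥ 0.05 (configurable floor) — with
near-constant purities the slope is unidentifiable.

## Synthetic data generator

`generate(SynthConfig)` draws, per site, a baseline transformed mean
m_i from a two-component Beta mixture on the beta scale (shapes
(3, 20) and (20, 3), modes near beta 0.1 and 0.9, mimicking methylome
bimodality); marks a fraction `frac_dmc` of sites as true DMCs; gives
each DMC a signed effect μ_i = ±`effect_mean` whose sign is drawn
with baseline-dependent probability so that corr(m_i, μ_i) is
negative (`x_delta_corr`, default −0.3): lowly methylated sites tend
to gain methylation and highly methylated sites to lose it.  Per
tumor sample, λ_s ~ Uniform(0.3, 0.9) by default; per sample-site,
δ_is ~ N(μ_i, τ²) at DMC sites (τ = `effect_sample_sd`, default 0.2)
and exactly 0 at null sites, so "not a DMC" means literally
unaffected.  Technical noise ε ~ N(0, `noise_sd`) enters the
normal-cell realization; the default 0.25 rad (≈ 0.12 beta-scale sd
at mid-methylation) reflects the biological heterogeneity of tumor
tissue and places moderate effects in a mid-power regime where test
comparisons are informative rather than saturated.

Mixing is on the **beta scale** by default — the physically literal
reading, since fluorescence fractions average over cells:
observed = (1 − λ)g(t_x) + λg(t_x + δ) with g the inverse transform,
sharing the normal-cell realization t_x between the X and Y terms
(Y = X + δ).  `mixing="transformed"` switches to
observed = g(t_x + λδ), under which the downstream linear model is
exact; noiseless transformed mixing is what makes algebraic-identity
tests exact.  Transformed values are clamped to [−π/2, π/2] before
the inverse map (events logged), so emitted betas always lie in
[0, 1].

`idmc_grade_config()` parameterizes DMC sites as purity markers:
effect 2.2 rad (baseline beta 0.1 → pure-cancer ≈ 0.97) and
x_delta_corr = −0.9, since marker-grade differential methylation is
directionally consistent with its baseline (predominantly CpG-island
hypermethylation from low baselines) — effects pointing outward would
saturate at the beta boundary and be unobservable.

**What the generator does not emulate**: probe-type (Infinium I/II)
artifacts, per-site variance heterogeneity beyond the DMC/null
dichotomy, spatial correlation along the genome, batch effects,
copy-number interference, or the marginal distributions of any real
cancer type.  Passing the synthetic benchmarks therefore shows the
estimators are correct *under the model they assume*, with realistic
magnitudes; it does not certify accuracy on any particular real
dataset.

## Numerical choices

- Rank-sum variance uses the standard tie correction
  n_x n_y/12 · [(n+1) − ΣT/(n(n−1))], T = t³ − t; zero variance (all
  values tied) → p = 1, logged.
- All per-site fits (rank-sum, normal equation, slope regression) are
  vectorized across sites; a genome-scale matrix (500k sites) fits in
  memory as a single float array.
- Zero variances are floored at the smallest positive float before
  log-shrinkage; degenerate-input paths (point-mass KDE, zero
  residuals, se = 0) return defined values with flags or warnings
  rather than NaN.
- Sorting is stable (mergesort) everywhere a ranking is emitted, with
  explicit tie-break keys, so outputs are invariant to input row and
  column order.
- Tests with hard bounds on simulation statistics (selection
  precision, control-free AUC) average over three generator
  replicates; a single replicate's statistic fluctuates by a few
  hundredths and would measure the draw rather than the method.
- Problem sizes in the test and acceptance runs (1000–5000 sites,
  30–50 samples) were chosen as the smallest at which the asymptotic
  approximations and rank statistics stabilize; everything completes
  in seconds.

## Known limitations

- λ̂ has the boundary-attenuation bias described above; it is not
  recalibrated against external purity callers by design.
- The with-control test is mildly conservative under shrinkage (see
  above) and assumes within-group homoscedasticity across samples; at
  DMC sites the λδ term makes tumor variance weakly depend on λ,
  which the model absorbs into σ′².
- The posterior in control-free mode is a plug-in normal, not a full
  Bayesian treatment; Pr(|μ| > c) is a ranking score, not a
  calibrated probability.
- Per-site complete-case handling of missing values discards
  information when missingness is structured.
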