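# Methods

This note documents the statistical procedures implemented in `tauperf`, the
generative model behind the synthetic cohorts, the numerical choices, and
the limits of what the test suite demonstrates.

## Data model

All analyses operate on subjects × regions SUVr tables for the 246-region
Brainnetome parcellation, one table per tracer phase (EARLY = perfusion
surrogate, LATE = tau), plus a cohort table with diagnosis group (`FOURRT`,
`OTHER_ND`, `HC`), subgroup, age, sex, disease duration, clinical scores
(PSP rating scale 0–100, MoCA 0–30, SEADL 0–100; missing as explicit nulls)
and site (`training` / `external`). Region columns are canonicalized to
atlas order on read, so downstream code never matches columns by position.
The bundled atlas TSV lists label, lobar compartment and hemisphere for all
246 regions and flags the 21 established 4RT hypoperfusion target regions
with their reported percent differences. The 21 target rows are exact; the
remaining 225 labels follow the public Brainnetome nomenclature, which may
not correspond region-for-region to any particular site's extraction
pipeline — only the target set carries scientific weight here.

## Regional contrast

Per region, the covariate-adjusted group comparison is an ANCOVA: the linear
model `suvr ~ group + age + sex` is fit on the two groups of interest and
the group term tested by its partial F on one degree of freedom (equivalent
to the squared t of the group coefficient). Two-sided p-values are used:
hyperperfusion is a real possibility (e.g. putaminal signal in PSP), so the
direction is not constrained. Constant covariate columns are dropped with a
warning — the degenerate limit is the pooled-variance two-sample t-test — and
covariates collinear with the group indicator raise an error. All 246
p-values are corrected by Benjamini–Hochberg step-up FDR; significance is
declared at adjusted p ≤ 0.01. BH (not Benjamini–Yekutieli) is the default
reading of "FDR correction" absent a named variant. Percent differences are
computed on raw (unadjusted) group means, and the output table lists
significant rows first, sorted by descending |percent difference|.

The region loop is implemented as a single vectorized least-squares solve
over all regions (one design matrix, 246 response columns), so the 50-seed
power simulations in the test suite complete in seconds.

## Normative hypoperfusion classifier

Per target region, healthy-control mean and SD (denominator n − 1, pooled
over control subjects) define the cutoff `τ_r = mean − k·SD`. The comparison
is inclusive (`suvr ≤ τ_r` marks the region affected), and a subject is
positive when at least `m` target regions are affected. The (k, m) grid is a
deterministic re-run with altered parameters, not a resampling procedure.
Target regions default to the bundled 21-region set but any discovered
contrast table can be supplied; the pipeline uses the negative-direction
significant regions it discovers. Control statistics are pooled across
scanners/sites; per-site normative databases are out of scope.

## Pattern-expression score

Training population is the pooled patient set (4RT + other neurodegenerative,
training site), excluding controls — discrimination is defined between those
two classes; an option includes controls. The steps:

1. **Correlation screen.** A region is retained iff its |Pearson r| with at
   least one other region is ≥ 0.3 (`max_abs` rule; a `mean_abs` variant is
   available). Zero-variance regions are excluded first with a warning.
2. **Sampling adequacy.** The overall Kaiser–Meyer–Olkin measure
   (anti-image partial correlations from the inverse correlation matrix)
   and Bartlett's sphericity test
   (`χ² = −(n − 1 − (2p+5)/6)·ln det R`, df = p(p−1)/2) are computed and
   reported but never gate the pipeline; on a singular correlation matrix
   they are recorded as unavailable.
3. **PCA.** Regions are z-standardized on training mean/SD (ddof = 1); the
   correlation matrix is eigendecomposed; components with eigenvalue > 1.0
   (with a 1e-10 numerical guard) are retained; loadings are
   eigenvector·√eigenvalue with a deterministic sign convention (largest
   |loading| positive).
4. **Varimax.** Kaiser-normalized pairwise planar rotations, converged when
   the relative criterion gain falls below 1e-6 (≤ 500 sweeps, error
   otherwise). Rotated components are re-ordered by explained variance.
   Rotation orthogonality and per-region communality conservation are
   asserted at 1e-8 in the tests.
5. **Component scores** use the regression method, `W = R⁺·Λ_rot`. The
   Moore–Penrose pseudo-inverse handles the subjects < regions case: the
   rotated loadings lie in the span of the non-null eigenvectors, where the
   pseudo-inverse agrees with the inverse, so scores are exact whenever R is
   invertible and well-defined when it is not.
6. **Weighting.** Unpenalized logistic regression of the binary 4RT
   indicator on the component scores yields weights `w_c` (a
   linear-probability OLS fit is available as a sensitivity option). The
   expression score is `Σ_c w_c·s_c`; the intercept is omitted because it
   shifts all subjects equally and cannot affect rank-based downstream
   statistics (ROC, correlations).

External projection standardizes new data with the *training* mean/SD and
applies the frozen coefficients and weights — the score is a fixed linear
functional of a new subject's regional values. The combined perfusion–tau
score is the plain sum of the two phase scores, as the two weighted scores
are on comparable logit-derived scales; a z-standardized sum (each score
standardized on training patients) is provided as an option.

## Evaluation

AUC is the Mann–Whitney probability (ties ½), computed from DeLong placement
values; its variance is `var(V10)/n_pos + var(V01)/n_neg` and the 95% CI a
normal approximation truncated to [0, 1] (the CI method is not prescribed by
convention; DeLong-normal is the common default). The paired test for two
correlated AUCs uses the placement-value covariance; p-values are two-sided.

Partial correlation residualizes both variables on the covariates (with
intercept) by least squares and correlates the residuals;
`t = r·√(df/(1−r²))` with `df = n − 2 − c`. Incomplete cases are removed
listwise per cell (the clinical scales have different missingness), constant
covariates are dropped (and do not count toward c), and collinear covariates
raise an error naming them. Sex enters as a single indicator. The clinical
report is the 3 × 3 table {PSPRS, SEADL, MoCA} × {perfusion, tau, combined}
restricted to 4RT patients, adjusted for age, sex and disease duration.

## Synthetic cohort generator

For subject j (pattern π, group g), phase p, region r:

```
suvr_jpr = μ_pr·(1 + δ_πpr·(1 + γ_p·a_jp)) + b_pr·u_j + s_g·σ_pr·ε_jpr
```

* `μ` = 1.0 (cerebellar-ratio scale), `σ` = 0.05, `ε` i.i.d. standard normal,
  values floored at 0.05.
* `δ` — planted fractional group effects. The 4RT early-phase effects are
  the 21 published target-region percent differences (−28.34% … −8.96%).
  All other patterns are synthetic design choices, not published values:
  AD-like (temporoparietal −10% early, +25% late), FTLD-like (frontal −12%
  early, +5% late), αSyn-like (−4% diffuse early), 4RT late-phase tau
  (+12% basal ganglia, +10% thalamus).
* Two latent standard-normal factors per disease subject (zero for
  controls): clinical severity `u` scales the early-phase deficit
  (γ_EARLY = 0.5) and drives the clinical scores; an independent tau-burden
  factor `v` scales the late-phase pattern (γ_LATE = 0.8). Both amplitude
  terms have mean zero, so planted group-mean percent differences are exact,
  while subjects express the patterns to varying degree — the source of
  between-patient overlap that keeps discrimination below ceiling and of
  the perfusion-specific severity coupling (tau expression is orthogonal to
  severity by construction, mirroring the empirical dissociation).
* Clinical scores are affine in `u` plus noise, truncated to their ranges
  (pre-truncation values kept in the truth record): PSPRS slope 6, noise 12
  (corr(u, PSPRS) ≈ 0.45); SEADL slope −9, noise 18; MoCA uncoupled. With
  the pattern score correlating ≈ 0.8 with `u`, the implied score–PSPRS
  partial correlation is ≈ 0.4.
* Cohort layout mirrors the study: training 78 4RT (PSP-RS/PSP-CBS/CBS/
  other), 79 other-ND (47 AD, 10 FTLD, 12 αSyn, 10 unspecified), 12 HC;
  external site 21 + 16. Ages, sex ratios and disease durations follow the
  tabulated group means/SDs; sex composition is drawn as an exact rounded
  fraction (avoids degenerate single-sex designs in the 12-control group).

Calibration rationale: the residual SD and γ_EARLY were chosen by power
arithmetic so that the weakest planted effect (−8.96%) remains detectable at
FDR 0.01 with the study's group sizes (78 vs 12) with ≈ 90% power, while
per-subject amplitude heterogeneity is as large as that constraint allows.
A consequence is that multivariate discrimination on the synthetic cohort is
easier than in the clinical data (training AUCs near 1.0 versus ≈ 0.85–0.90
reported on patients); the synthetic cohort validates the machinery and the
qualitative orderings, not the clinical effect sizes.

Named scenarios: `paper_like` (above); `null` (all effects, loadings and
couplings zero — used for FDR and type-I calibration); `separable` (±50%
disjoint effects, distractors shifted away from the hypoperfusion direction,
σ = 0.02 — threshold classification is error-free); `complementary` (each
4RT subject expresses the disease in only one phase, alternating, so the
combined score must beat either single score).

What the generator does **not** emulate: scanner/site effects and
harmonization residuals, partial-volume effects, spatially correlated noise
beyond the single amplitude factor per phase, non-Gaussian outliers,
diagnosis errors, and realistic missingness mechanisms (scores are missing
by group, not informatively). Passing tests therefore demonstrate
correctness and statistical calibration of the procedures, not clinical
performance.

## Numerical choices and edge cases

* Eigenvalue retention uses a 1e-10 tolerance above 1.0 so an exactly
  spherical correlation matrix retains nothing (and errors informatively).
* Varimax on a single component is the identity; rotation angles below
  1e-15 are skipped.
* Threshold comparison in the classifier is inclusive (≤), so a subject
  exactly at the cutoff counts as affected.
* `read_csv` uses round-trip float parsing; written artifacts re-read
  bit-identically, and two pipeline runs with the same config and seed
  produce byte-identical CSVs. (Feeding a run's own CSV exports back
  through the file-input path reproduces scores to ~1e-11 rather than
  bitwise — array memory layout changes floating-point summation order.)
* Degenerate inputs raise with the offending quantity named: non-positive
  SUVr, duplicate subject ids, unknown/missing region labels, empty
  id intersections, single-class label vectors, singular designs.

## Known limitations

* The logistic weighting is unpenalized; on perfectly separable training
  sets the weights are unbounded in theory (lbfgs stops at max_iter) though
  score *rankings* remain stable. The linear-probability option avoids this.
* KMO/Bartlett require an invertible correlation matrix; with more retained
  regions than subjects they are reported as unavailable rather than
  computed on a regularized matrix.
* The classifier's normative statistics assume pooled controls; site-level
  normative modelling is out of scope.
* Only regional tables are handled — no image I/O, spatial normalization,
  partial-volume correction or kinetic modelling.
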