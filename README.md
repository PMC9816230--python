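# tauperf

Statistical analysis of **dual-phase tau-PET** in 4-repeat tauopathies (4RT:
progressive supranuclear palsy and corticobasal syndrome). A single dynamic
scan with a next-generation tau tracer yields two biomarkers at once: the
**early frame** (0.5–2.5 min post injection) is a surrogate of cerebral
perfusion and hence neuronal injury, while the **late frame** (20–40 min)
measures tau load. Both are quantified as standardized uptake value ratios
(SUVr, cerebellar reference) over the 246 regions of the Brainnetome atlas.

The package is aimed at neuroimaging statisticians who have regional SUVr
tables (not images) and want the full downstream analysis:

1. **Regional contrast** — per-region ANCOVA (`SUVr ~ group + age + sex`,
   partial F for the group term) of 4RT patients against healthy controls,
   Benjamini–Hochberg FDR across all 246 regions (`p_FDR ≤ 0.01`), signed
   percent differences of group means.
2. **Normative classifier** — a region is "affected" when
   `SUVr ≤ mean_HC − k·SD_HC`; a patient is positive for a 4RT-like scan
   when ≥ m target regions are affected; the (k, m) grid
   {2.0, 2.5, 3.0} × {1, 3, 5} maps the sensitivity/specificity trade-off.
3. **Pattern expression** — a scaled-subprofile-style score: regions passing
   an inter-correlation screen (max |r| ≥ 0.3) are z-standardized, the
   correlation matrix is eigendecomposed, components with eigenvalue > 1 are
   varimax-rotated, component scores follow the regression method
   (`W = R⁻¹·Λ_rot`), and a logistic regression of the 4RT diagnosis on the
   component scores supplies weights `w_c`, giving a single expression score
   per subject, `score = Σ_c w_c·s_c`. External cohorts are projected with
   the frozen training standardization, coefficients and weights. The
   combined perfusion–tau score is the plain sum of the two phase scores.
4. **Evaluation** — ROC/AUC as the Mann–Whitney probability with DeLong
   variance (95% CI) and the paired DeLong test for correlated AUCs;
   partial Pearson correlations of expression scores with clinical scales
   (PSP rating scale, SEADL, MoCA) adjusted for age, sex and disease
   duration.

Because clinical PET cohorts of this kind are not publicly deposited, the
package ships a first-class **synthetic cohort generator** that emulates the
study design: 78 4RT / 79 mixed neurodegenerative / 12 control training
subjects plus a 21 + 16 external site, with the published 21-region
hypoperfusion effect sizes planted in the early phase, distractor disease
patterns (AD-like temporoparietal, FTLD-like frontal, mild diffuse
α-synucleinopathy-like), and a latent severity factor coupling the perfusion
pattern to the clinical scores. See `docs/methods.md` for the generative
model and its limitations.

## Worked example

Run the whole pipeline on a synthetic paper-scale cohort:

```bash
tauperf run-all --scenario paper_like --seed 1 --out demo_run
```

`demo_run/contrast_summary.json` then reads

```json
{"hemisphere_tally": {"L": 10, "R": 11}, "n_significant": 21, "q": 0.01}
```

i.e. 21 of 246 regions show significant hypoperfusion in the 4RT group at
FDR 0.01, with no hemispheric dominance (11 right / 10 left). The head of
`demo_run/contrast_table.csv`:

```
   label   compartment  p_fdr  percent_diff
 rTtha_R      Thalamus    0.0      -26.4783
   dCa_R Basal ganglia    0.0      -26.3683
 cTtha_R      Thalamus    0.0      -26.1720
   dCa_L Basal ganglia    0.0      -24.4674
mPFtha_R      Thalamus    0.0      -19.4277
```

— thalamic and caudate perfusion is reduced by roughly a quarter relative to
controls, the expected 4RT topology. `demo_run/grid_metrics.csv` shows the
single-region rule (k = 2, m = 1) is sensitive (98.7%) but unspecific (87.3%
of other neurodegenerative patients are also positive), while
`demo_run/roc_results.json` shows the pattern-expression scores discriminate
cleanly (training AUC: perfusion 1.00, tau 0.95, combined 1.00) — on this
synthetic cohort the planted pattern is stronger than in clinical data, so
AUCs sit near ceiling. `demo_run/clinical_associations.csv` reproduces the
perfusion/tau dissociation: the perfusion score correlates with the PSP
rating scale (r ≈ 0.47, p ≈ 2e-5 at seed 1) while the tau score does not.

Every stage is also available separately (`tauperf simulate | contrast |
classify | pattern fit|score|project | evaluate`), reading and writing plain
CSV/JSON, and as library functions (`tauperf.build_contrast_table`,
`tauperf.fit_pattern_model`, ...).

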