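# famstress

Counterfactual mediation pipeline for estimating how much of the effect of
low household income in early childhood on later child mental-health
difficulty runs through two sequentially ordered binary mediators — reduced
maternal wellbeing and poor parent–child relationship quality — and how much
is direct.

The package implements the full analysis chain on child-level cohort tables:

- **`famstress.synthetic`** — family-stress cohort simulator: confounders →
  low income (X) → reduced maternal wellbeing (M1) → poor relationship
  quality (M2) → SDQ difficulties (Y), each a logistic structural equation.
  Raw scale scores (income, DASS items, CPRS-SF subscales, SDQ totals) are
  back-generated consistently with the binary latents, missingness is
  injected under MCAR / MAR / MNAR mechanisms, and
  `oracle_effects` computes ground-truth marginal natural-effect odds
  ratios by nested-counterfactual Monte Carlo.
- **`famstress.preprocessing`** — OECD-modified income equivalisation,
  weighted quintile flags (ties flagged), SDQ banding (<14 / 14–16 / ≥17),
  DASS 6-item and CPRS-SF closeness/conflict flags, confounder codings, and
  derivation of the binary analysis set.
- **`famstress.missing`** — Little's MCAR chi-square test (EM under
  multivariate normality) and a chained-equations multiple imputer
  (logistic / multinomial / predictive-mean-matching conditionals) with
  observed-vs-imputed diagnostics.
- **`famstress.descriptive`** — exposure-stratified prevalence tables and
  2×2 odds ratios with Woolf confidence intervals.
- **`famstress.mediation`** — the core estimator: imputation-based
  natural-effects decomposition for one binary exposure and two sequential
  binary mediators. Records are expanded over counterfactual exposure
  copies (x0, x1) with the third copy pinned to observed exposure, outcome
  expectations are imputed by mixing over the first mediator, and a
  weighted fractional-response logistic natural model yields
  `OR_NDE = exp(θ1)`, `OR_NIE_M1 = exp(θ2)`, `OR_NIE_M2 = exp(θ3)` with the
  exact identity `OR_TE = OR_NDE × OR_NIE_joint`. Percentile bootstrap CIs,
  Rubin pooling over imputations and the odds-ratio proportion-mediated
  formula `PM = OR_NDE(OR_NIE − 1) / (OR_NDE·OR_NIE − 1)` are included.
- **`famstress.pipeline` / `famstress.cli`** — YAML-configured end-to-end
  orchestration with full seed provenance.

## CLI

```sh
famstress simulate --n 5000 --seed 1 --out cohort.csv
famstress derive cohort.csv --cutoffs cohort_cutoffs.json --out analysis.csv
famstress mcar-test analysis.csv
famstress impute analysis.csv --m 20 --iterations 50 --seed 1 --out-dir imputed/
famstress describe analysis.csv --out table2.csv
famstress mediate analysis.csv --n-boot 1000 --seed 1 --out fit.json
famstress run-all --config run.yaml
```

`run-all` writes the report bundle (characteristics table, stratified
table, effects table, JSON fit record, log with all seeds) to the
configured output directory. A minimal `run.yaml`:

```yaml
output_dir: out/
simulation:          # or: input_path: cohort.csv
  n_children: 20000
  seed: 1
  conf_prevalences: {low_mat_education: 0.215, low_mat_age: 0.044,
                     mat_unemployed: 0.344, gt4_children: 0.039,
                     one_parent: 0.141, ethnic_minority: 0.027}
  alpha_x:  {intercept: -1.8063, conf: {one_parent: 2.3542}}
  alpha_m1: {intercept: -1.6216, x: 0.4707}
  alpha_m2: {intercept: -0.9779, x: 0.1780, m1: 0.5}
  alpha_y:  {intercept: -4.2434, x: 0.7636, m1: 0.8, m2: 0.7}
m_imputations: 20
imputation_iterations: 50
n_boot: 1000
```

## Notes

- Quintile cut-points default to within-sample estimation; fixed cut-offs
  (as recorded by the simulator, mirroring reference-sample cuts) can be
  passed explicitly.
- Survey weights are consumed, not constructed; they enter every model fit
  as estimating-equation weights and travel with resampled rows in the
  bootstrap. They are not used inside imputation models.
- The estimator does not adjust for exposure-induced mediator–outcome
  confounding, and supports binary exposure/mediators/outcome only.
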