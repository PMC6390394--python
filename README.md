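# twinkit

Variance-component modelling for five-group twin studies: maximum-likelihood
twin correlations, univariate ACE/ADE sex-limitation models, multivariate
Cholesky decompositions fitted by full-information maximum likelihood (FIML),
derived genetic and environmental correlations with profile-likelihood
confidence intervals, and a synthetic twin-data generator for end-to-end
validation by parameter recovery.

## What it does

Input is a wide per-family CSV of twin pairs labelled with one of five
zygosity groups (`MZm`, `DZm`, `MZf`, `DZf`, `DOS`), sex and age per twin,
and scores on one or more continuous traits. The analysis chain:

1. **Preprocessing** — skewness assessment, square-root transformation of
   positively skewed traits, residualization on `{sex, age, age×sex, age²}`,
   standardization (`twinkit.preprocessing`).
2. **Saturated correlations** — ML twin correlations per zygosity group
   (order-constrained bivariate normal, FIML over partial pairs,
   profile-likelihood CIs), cross-twin cross-trait and phenotypic
   correlations (`twinkit.correlations`).
3. **Biometric models** — ACE/ADE/DE models, univariate or multivariate,
   with optional general sex limitation. Components are parameterized by
   lower-triangular Cholesky loadings (`Σ_X = L_X L_Xᵀ`, PSD by
   construction); cross-twin blocks scale A/D/C by the classical zygosity
   coefficients (1/0.5, 1/0.25, 1/1). The FIML −2LL is minimized by bounded
   quasi-Newton with exact analytic gradients and seeded multi-start
   (`twinkit.biometric`).
4. **Derived statistics** — standardized variance proportions, total
   genetic (A+D) proportions, per-component cross-trait correlation
   matrices, implied phenotypic correlations (`twinkit.derived`).
5. **Model comparison** — likelihood-ratio χ² tests of nested submodels and
   AIC; a pipeline running the full model ladder and selecting the
   best-fitting model (`twinkit.pipeline`).
6. **Synthetic data** — a five-group generator with configurable A/C/D/E
   covariance structure (per sex if desired), sex/age mean effects, positive
   skew, and missingness (`twinkit.synthetic`); simulate-and-refit recovery
   experiments (`twinkit.recovery`).

## CLI

```sh
# simulate a reference five-group dataset (1742 pairs, 3 traits)
twinkit simulate --seed 1 --out twins.csv

# twin / cross-trait / phenotypic correlations on preprocessed scores
twinkit correlations twins.csv --out correlations.csv

# fit one model by FIML
twinkit fit twins.csv --components DE --out fit.json
twinkit report fit.json

# full pipeline: preprocess, correlations, model ladder, comparison, report
twinkit run twins.csv --out results/ --seed 1
```

`twinkit simulate --config cfg.yaml` accepts a YAML config with
`group_sizes`, `traits`, component variances/correlations (`d2`, `rd`, `e2`,
`re`), `mean_coefs`, `transform: square`, and `missing_rate`.

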