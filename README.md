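# msocc — multi-species occupancy modelling for clustered bird surveys

`msocc` is a Python package for asking, from replicated presence/absence
surveys with very imperfect detection: *which species occur where, how well
can a model predict the bird community at an unsurveyed station, and how
much survey effort would it take to notice an occupancy decline?* It was
built around the kind of data long-running tropical monitoring programmes
produce — hundreds of survey stations clustered around field centres,
surveyed between one and a dozen times by mist nets or point counts, with
per-survey detection probabilities of only a few percent — and around
covariates derived either from categorical habitat maps or from
satellite-reflectance summaries.

## The model

For species *i* at station *j*, replicate survey *k*:

```
z_ij  ~ Bernoulli(psi_ij)            logit(psi_ij) = x_j' beta_i + lambda_i' w_j
y_ijk ~ Bernoulli(z_ij * p_ijk)      logit(p_ijk)  = v_jk' alpha_i
```

- `z` is true (latent) presence, constant over a single closed season;
  there are no false positives, so a detection forces `z = 1`.
- Detection covariates `v` are survey method (net/point) and time of day
  (am/pm), with alphabetical baselines (am, net).
- Species share information through community hyperdistributions
  `beta_i ~ N(mu_beta, diag tau_beta)`, `alpha_i ~ N(mu_alpha, diag tau_alpha)`.
- Each spatial latent factor `w_.q` is a zero-mean, unit-variance Gaussian
  process with correlation `exp(-phi_q d)`; its loadings `lambda` absorb
  residual spatial structure in occupancy. The effective range — the
  distance beyond which autocorrelation is negligible — is `3 / phi`.

Fitting is a single-chain Gibbs sampler using Pólya-Gamma data augmentation
for every logit layer (an exact Devroye sampler, numba-compiled, lives in
`msocc.polyagamma`) with Metropolis updates for the decay rates `phi`.
Model assessment uses WAIC, chi-squared posterior-predictive Bayesian
p-values, Geweke diagnostics and effective sample sizes.

Around the model sit the rest of the analysis chain:

- `msocc.simulate` — synthetic landscapes, covariates, communities and
  detection histories with known parameters (the package's test bed);
- `msocc.reflectance` — NDVI/EVI/NBR/NDWI and tasselled-cap indices from
  six-band reflectance rasters, 100 m buffered means/SDs per station, and
  correlation-matrix PCA of the resulting 26 variables;
- `msocc.validation` — centre-stratified holdouts; per posterior sample the
  occupied community is thinned by the cumulative detection probability
  `p* = 1 - (1 - p)^n` to give a *detected* community, compared with
  observation via per-species AUC, species-accumulation curves and
  presence/absence Bray-Curtis dissimilarity `1 - 2|A∩B| / (|A| + |B|)`;
- `msocc.power` — closed-form power of a two-occasion Wald test for a
  proportional occupancy reduction (after Guillera-Arroita &
  Lahoz-Monfort's occupancy-design method), verified by a Monte-Carlo
  oracle, plus effort-grid search for minimal designs.

## Worked example

How likely is a monitoring programme to notice a 50% occupancy decline for
a species occupying 30% of stations, detected on 6.5% of point-count
surveys, with 250 stations surveyed 4 times on both occasions?

```python
>>> from msocc.power import PowerQuery, wald_power
>>> from msocc.validation import cumulative_detection
>>> float(cumulative_detection(0.065, 4))   # chance of >= 1 detection at an occupied station
0.23573064937499988
>>> wald_power(PowerQuery(psi1=0.3, R=0.5, p=0.065, S=250, K=4))
0.0935...
>>> wald_power(PowerQuery(psi1=0.3, R=0.5, p=0.065, S=2500, K=4))
0.4867...
```

Even with one detection chance in four per occupied station, 1,000 total
surveys give under a 10% chance of flagging a halving of occupancy — a
tenfold effort increase still only reaches ~0.49. This is the package's
central design message: at tropical-forest detection rates, naive survey
designs are far from sufficient to detect even dramatic declines.

The full chain — simulate a clustered survey, filter species, fit the four
model variants, validate community predictions, and map survey effort —
is driven by the numbered scripts:

```
python analysis/01_simulate_survey.py
python analysis/02_fit_models.py
python analysis/03_validate_community.py
python analysis/04_power_analysis.py
```

`01` prints the survey structure it generated (300 stations over 20
centres; replicate counts with mode 1, median 3; per-survey detection rate
0.029; 35 of 60 species retained by the >10-station filter). `02` writes
`results/model_comparison.csv` with WAIC, ΔWAIC, Bayesian p-values and
explanatory/predictive AUC per model variant. `03` writes per-species AUC
and per-station Bray-Curtis tables plus accumulation-curve and
richness-dissimilarity figures. `04` writes the power grid and the
cheapest design reaching mean power 0.7 for a 50% decline.

There is also a thin CLI: `msocc simulate`, `msocc run`, `msocc power`,
`msocc power-grid`.

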