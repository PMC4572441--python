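# wcoxboost

Weighted, stratified componentwise likelihood-based boosting for Cox
proportional hazards models in high dimensions (p ≫ n), with
resampling-based variable-selection stability analysis across a grid of
down-weighting factors, stability visualizations, and 0.632+
prediction-error evaluation.

## The problem

When a survival study contains known patient subgroups (cytogenetic risk
categories, tumor stages, ...), a stratified Cox model

λ⁽ˢ⁾(t │ xᵢ) = λ₀⁽ˢ⁾(t) · exp(xᵢᵀβ)

gives each stratum s its own baseline hazard but shares the covariate
effects β. When those effects actually differ between strata, the
estimated β is a weighted average driven by the relative stratum sizes in
the sample — which are often a convenience sample, not representative of
future patients. A pure subgroup analysis avoids this but discards most of
the data, which is fatal when p runs to tens of thousands of gene
expression or methylation covariates and n is a few hundred.

`wcoxboost` takes the middle road: it estimates β by maximizing a
*weighted* stratified partial log-likelihood in which observations in the
focus stratum carry weight 1 and all other observations a common weight
w ∈ [0, 1]:

l(β) = Σₛ Σᵢ I(sᵢ=s) wᵢ δᵢ [ xᵢᵀβ − log Σₖ I(sₖ=s) wₖ I(tᵢ ≤ tₖ) exp(xₖᵀβ) ]

w = 1 recovers the global stratified analysis, w = 0 the subgroup
analysis, and intermediate w borrows a controlled amount of information
from the other strata. Estimation uses componentwise likelihood-based
boosting: each of M steps updates a single covariate coefficient by the
penalized one-step Newton estimate γ̂ⱼ = U⁽ʲ⁾(0)/(I⁽ʲ⁾(0)+ρ), selecting the
covariate with the largest penalized score statistic U²/(I+ρ), which
yields sparse models and implicit variable selection. The penalty defaults
to ρ = Σᵢ wᵢδᵢ (1/ν − 1) with ν = 0.02, so each update is roughly 2 % of
the one-step maximum partial likelihood estimate; M is chosen by 10-fold
cross-validation. Mandatory clinical covariates (age, gender, ...) are
refit without penalty before every step, with stratum-specific
coefficients.

Rather than tuning w, the package *profiles* it: for a grid of weights it
computes per-covariate resampling inclusion frequencies (RIFs) — the
proportion of 0.632-subsample refits in which a covariate receives a
nonzero coefficient — and displays them as **stability trajectories** (RIF
versus covariate, one series per weight) and a **weight-frequency map**
(a heat map of RIFs clustered by the Pearson correlation of each
covariate's RIF profile across weights). Prediction performance of the
weighted models is compared through IPCW Brier-score prediction error
curves with the 0.632+ resampling estimator and integrated prediction
errors.

Everything is exercised on a built-in two-subgroup simulator (n = 250,
p = 1000 uncorrelated N(0,1) covariates, exponential survival and
censoring with scale 1/20, ten covariates with subgroup-specific
log-hazard effects 1, 0.5 or 0).

## Worked example

```python
import numpy as np
from wcoxboost import (SimulationScenario, generate, WeightedCoxBoost,
                       cv_select_steps, BoostingConfig, WeightScheme,
                       simulate_ifs, WeightGrid, stabtrajec)

scenario = SimulationScenario(n=250, p=200)
data = generate(scenario, seed=7)

# choose the number of boosting steps by 10-fold CV at weight 0.25
cfg = BoostingConfig(steps=100, scheme=WeightScheme(w=0.25))
cv = cv_select_steps(data, cfg, K=10, seed=7)
print("selected M:", cv.best_m)

model = WeightedCoxBoost(n_steps=cv.best_m, weight=0.25).fit(data)
nz = np.flatnonzero(model.coef_)
print("selected covariates:", [data.covariate_names[j] for j in nz[:6]], "...")

# inclusion frequencies over 20 fresh replicates, four weights
rifs = simulate_ifs(scenario, grid=WeightGrid((0.001, 0.1, 0.5, 0.99)),
                    n_replicates=20, fixed_steps=50, seed=7)
print(np.round(rifs.rif[:3], 2))   # focus-stratum effects: Cov1..Cov3
print(np.round(rifs.rif[7:10], 2)) # other-stratum effects: Cov8..Cov10
```

Output:

```
selected M: 100
selected covariates: ['Cov1', 'Cov2', 'Cov3', 'Cov4', 'Cov5'] ...
[[0.95 0.95 0.65 0.45]
 [0.9  0.85 0.85 0.5 ]
 [0.95 0.95 0.8  0.45]]
[[0.   0.   0.1  0.3 ]
 [0.   0.   0.05 0.3 ]
 [0.   0.   0.05 0.55]]
```

The first block shows the covariates with effects only in the focus
stratum: they are selected in almost every replicate at small weights and
lose stability under the global analysis. The second block shows the
covariates whose effects live in the *down-weighted* stratum: invisible to
the subgroup analysis (RIF ≈ 0 at w ≈ 0) and increasingly stable as w
grows. `stabtrajec(rifs)` and `weightfreqmap(rifs)` draw the two standard
pictures of this trade-off.

The same workflow is available from the shell:

```bash
wcoxboost simulate --preset tiny --out-covariates cov.csv --out-endpoint end.csv
wcoxboost fit --covariates cov.csv --endpoint end.csv --weight 0.5 --steps 20
wcoxboost resample --covariates cov.csv --endpoint end.csv \
    --weights 0.01,0.5,0.99 --n-resamples 10 --fixed-steps 5 --out rif.csv
wcoxboost plot-stabtrajec --rif rif.csv --mark-best --out trajectories.svg
```

## Layout

- `src/wcoxboost/datasets.py` — stratified survival data container, delimited IO,
  all-missing-covariate filtering, standardization
- `src/wcoxboost/core.py` — weighted stratified partial likelihood, score and
  information, weighted Breslow baseline hazards
- `src/wcoxboost/boosting.py` — the boosting engine and the `WeightedCoxBoost`
  estimator (scikit-learn style)
- `src/wcoxboost/cv.py` — cross-validation for the step number
- `src/wcoxboost/stability.py` — subsampling, RIF matrices over weight grids
- `src/wcoxboost/prediction.py` — IPCW Brier curves, 0.632+ estimator, IPEC
- `src/wcoxboost/simulate.py` — the two-subgroup scenario simulator
- `src/wcoxboost/plots.py`, `src/wcoxboost/cli.py` — visualizations and CLI

See `docs/methods.md` for the statistical details and design choices.
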