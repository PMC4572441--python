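# Methods

## Model

We observe right-censored data (tᵢ, δᵢ, xᵢ, sᵢ), i = 1..n: observed time
tᵢ = min(Tᵢ, Cᵢ), event indicator δᵢ, a p-vector of baseline covariates,
and a stratum label sᵢ ∈ {1..S}. The model is a stratified Cox
proportional hazards model, λ⁽ˢ⁾(t│x) = λ₀⁽ˢ⁾(t)·exp(xᵀβ): one free
baseline hazard per stratum, covariate effects shared. The focus of the
analysis is one stratum (internally coded 1); observations elsewhere enter
the stratified partial log-likelihood with a down-weight w ∈ [0, 1]:

l(β) = Σₛ Σᵢ I(sᵢ=s) wᵢ δᵢ [ ηᵢ − log Σₖ I(sₖ=s) wₖ I(tᵢ ≤ tₖ) exp(ηₖ) ],

with ηᵢ = xᵢᵀβ and wᵢ = 1 on the focus stratum, wᵢ = w otherwise. The
risk-set convention I(tᵢ ≤ tₖ) keeps tied observations at risk, i.e. ties
are handled Breslow-style (simultaneous events share one risk set).
w = 1 is the global stratified analysis, w = 0 the subgroup analysis.

Because a common positive factor on all weights shifts l by a
β-independent constant and scales every derivative uniformly, the weight
vector is only defined up to scale. `WeightScheme` therefore stores the
canonical form (focus weight ≡ 1) and canonicalizes any explicit weight
vector on input; likelihood, score and information values at the module
surface are consequently invariant to global weight rescaling.

## Componentwise likelihood-based boosting

Starting from β̂⁽⁰⁾ = 0, each boosting step m considers for every
penalized covariate j the one-parameter model ηᵢ + γ xᵢⱼ. With

U⁽ʲ⁾(0) = Σₛ Σᵢ I(sᵢ=s) wᵢδᵢ [xᵢⱼ − Aᵢⱼ],
I⁽ʲ⁾(0) = Σₛ Σᵢ I(sᵢ=s) wᵢδᵢ [Bᵢⱼ − Aᵢⱼ²],

where Aᵢⱼ and Bᵢⱼ are the risk-set means of xₖⱼ and xₖⱼ² under masses
wₖ·exp(ηₖ), the step selects j* = argmax U²/(I+ρ) and updates
β̂ⱼ* by γ̂ = U/(I+ρ). I⁽ʲ⁾ is a weighted sum of risk-set variances and
hence nonnegative. All risk-set sums are computed by one reverse
cumulative pass over the time-sorted observations of each stratum, so a
full candidate scan costs O(np); zero-weight observations are dropped
before fitting (they contribute nothing, and dropping them makes the
w = 0 reduction to the subgroup analysis bit-exact).

Selection statistic. The selection criterion uses the penalized
denominator U²/(I+ρ), consistent with the update; this avoids favoring
near-zero-information covariates. `penalized_selection=False` restores
the raw score statistic U²/I.

Penalty. ρ defaults to Σᵢ wᵢδᵢ·(1/ν − 1) with shrinkage ν = 0.02. On
covariates standardized to unit variance *in the weighted metric*,
I⁽ʲ⁾(0) ≈ Σᵢ wᵢδᵢ, so γ̂ ≈ ν · U/I: each update is about 2 % of the
one-step maximum partial likelihood estimate (the package's calibration
script measures ≈ 0.018 under the default simulation conditions; the
risk-set variance of a standardized covariate sits slightly below 1,
which accounts for the shortfall). Using the *weighted* event count makes
the calibration hold uniformly in w and makes the limiting cases exact:
at w = 1 the rule is the plain event-count rule, at w = 0 it is the rule
computed on the focus subgroup alone.

Standardization. Penalized covariates are standardized internally with
weighted moments — mean Σwx/Σw and reliability-weight variance
Σw(x−m)²/(Σw − Σw²/Σw), which interpolates between the focus-subgroup
sample variance (w = 0) and the full-sample variance (w = 1). Covariates
with zero weighted variance are excluded from the candidate set with a
record. Coefficients are always reported on the original covariate scale;
centering only shifts η by a global constant, which the partial
likelihood ignores.

Mandatory covariates. Covariates declared mandatory (clinical adjustment
variables) are excluded from penalized selection and refit before every
boosting step by unpenalized Newton–Raphson (relative step change
< 1e−8, at most 25 iterations), holding the penalized contribution fixed
as an offset. Their coefficients are stratum-specific; with this
interaction coding the weighted likelihood separates over strata, so each
stratum is refit on its own observations. Strata with zero weight or no
events keep coefficient 0 (their likelihood contribution vanishes).

Baseline hazard and prediction. For survival probabilities the package
uses the weighted Breslow estimator
Λ̂₀⁽ˢ⁾(t) = Σ_{event times tᵢ ≤ t in s} wᵢδᵢ / Σₖ I(sₖ=s) wₖ I(tᵢ≤tₖ) exp(ηₖ),
the canonical partial-likelihood companion, and Ŝ(t│x) = exp(−Λ̂₀⁽ˢ⁾(t)·eᵉᵗᵃ).
Strata without positive-weight events get the empty step function
(cumulative hazard 0).

## Choosing the number of steps

M is the critical complexity parameter and is chosen by K-fold
cross-validation (default K = 10). Folds are stratified jointly by
stratum and event status, so every training split mirrors the
event/stratum composition; infeasible draws (an eventless stratum in some
training split) are redrawn up to 10 times. Each step count m is scored
by the Verweij–van Houwelingen predictive contribution
l_full(β̂ₘ) − l_train(β̂ₘ), summed over folds and reported relative to the
step-0 contribution (so m = 0 scores exactly 0, also in the presence of
mandatory covariates). This full-minus-train form avoids the unstable
risk sets of small test folds. Ties in the argmax go to the smallest m.

## Resampling inclusion frequencies

Selection stability at each weight is the proportion of resampling fits
in which a covariate's final coefficient is nonzero. Resamples draw
round(0.632·nₛ) observations per stratum without replacement —
stratified subsampling keeps stratum proportions and prevents
empty-stratum resamples — and the identical subsample sequence is reused
across the whole weight grid (paired design: weight effects are not
confounded with resampling noise; an audit trail of index sets can be
stored). Within each resample the step count is chosen by 10-fold CV by
default; a fixed-M mode exists for controlled experiments and tests. The
default weight grid is {0, 0.001, 0.01, 0.05, 0.1, 0.25, 0.5, 0.7, 0.9,
0.99}. For simulation studies, `simulate_ifs` generates a fresh dataset
per replicate instead of resampling one dataset. Mandatory covariates are
reported as NaN rows (they are always in the model). Per-cell random
streams are spawned from a single seed, so any execution order (including
parallel execution) yields identical results.

## Visualization

Stability trajectories show the covariates whose RIF reaches a threshold
(default 0.1) at some weight: RIF on the y-axis, covariates on the
x-axis, one series per weight in graded gray (lighter = smaller weight),
each covariate's points joined by a dotted line, and optionally a
triangle at the weight maximizing the mean RIF over the displayed
covariates (ties to the smaller weight). The weight-frequency map shows a
larger covariate set (threshold 0.05) as a heat map, rows ordered by
hierarchical clustering under the distance 1 − Pearson correlation of the
RIF profile across weights; the grayscale maps RIF 0 → black and
1 → white, so lighter rows are more stably selected. Average linkage is
used; rows are sorted by name before clustering so the leaf order does
not depend on input order, and constant rows (undefined correlation) are
assigned the maximal distance 2 to every other row. Both functions return
their backing table/row order, which is the tested surface.

## Prediction error

Time-dependent Brier scores with inverse-probability-of-censoring
weighting: at time t a subject with an observed event before t weighs
1/Ĝ(tᵢ⁻), a subject still under observation 1/Ĝ(t), a subject censored
before t weighs 0, with Ĝ the Kaplan–Meier estimate of the censoring
distribution computed on the evaluation subgroup (the focus stratum),
unconditional on covariates. The default time grid is the unique event
times of the focus stratum truncated at their 95th percentile (tail risk
sets are too small to be informative). Out-of-sample error uses the same
paired 0.632-subsamples as the stability analysis: each subject's error
is averaged over the resamples that excluded it (subjects never excluded
contribute their apparent error, so a frozen prediction rule has
out-of-bag error exactly equal to its apparent error), and the 0.632+
combination uses the relative overfitting rate
R(t) = (err_oob − err_app)/(err_noinf − err_app) clipped to [0, 1], with
the permutation (all subject–prediction pairings) no-information error.
R = 0 reduces the estimator to the plain 0.632 rule. The integrated
prediction error is the trapezoidal area under a curve over the grid.

## The simulator

`SimulationScenario` emulates a two-subgroup study: subgroup membership
Bernoulli(0.5), p uncorrelated N(0,1) covariates, and event times from
the proportional-hazards inversion construction T = E/(rate·exp(xᵀβ⁽ˢ⁾))
with E a unit exponential and rate the inverse of the survival scale
(default 1/20, i.e. rate 20 — the scale parameter is exposed because the
orderings of interest are invariant to the shared time scale).
Censoring is independent exponential with the same default scale, giving
≈ 50 % censoring under no effects. The default effect pattern assigns
log-hazard effects (1, 0) to covariates 1–3, (0.5, 0.5) to 4–7 and
(0, 1) to 8–10 in (focus, other) subgroups — every effect covariate has
mean effect 0.5 across subgroups, so a global analysis cannot separate
the three groups while the weight profile can.

What the simulator does *not* emulate: correlated covariate blocks,
non-proportional hazards, non-normal covariate distributions
(methylation M-values, skewed expression), informative censoring, and
partially missing covariates. Passing tests therefore demonstrate the
correctness and the qualitative weight-stability behavior of the
machinery, not performance guarantees on real omics data.

## Numerical choices and degenerate inputs

- Ties: Breslow risk sets throughout; no Efron correction.
- Argmax ties in candidate selection: smallest covariate index.
- Mandatory Newton: singular information or nonfinite steps raise with a
  rescaling suggestion.
- An event whose weighted risk-set sum is zero raises, naming stratum and
  time (cannot occur under the two-level scheme, where each event is in
  its own risk set with positive weight).
- Partially missing covariate values are a fit-time error; only
  covariates missing for *all* observations are removable
  (`filter_all_missing`), since anything else needs an imputation model
  the package deliberately does not provide.
- Delimited IO writes floats in shortest round-trip form and reads them
  with round-trip precision, so write→read is bit-identical.

## Problem sizes used in the checks

The test-suite simulation studies run the scenario at p = 200 with 20
replicates and fixed M = 50 over the weight grid {0.001, 0.1, 0.5,
0.99}, and the prediction-error comparison at 20 resamples per replicate;
these sizes preserve the qualitative structure of the full-scale study
(p = 1000, CV-selected M, 100 resamples) at a few minutes of compute.
One known consequence: with only four grid weights and inclusion
frequencies in steps of 1/20, the correlation-distance profiles of the
shared-effect group (4–7) and the other-stratum group (8–10) are both
monotone increasing and differ mainly in level, which the
correlation distance discards — so the weight-frequency map separates
these two groups less reliably than at full scale, where ten grid
weights and CV-chosen step counts give the profiles more shape.

## Known limitations

- No Efron ties, time-varying covariates, or left truncation.
- The weight w is profiled, never tuned automatically: picking a single
  "optimal" w is deliberately out of scope.
- The candidate scan is exact (no screening heuristics), so very large p
  costs O(np) per boosting step.
- Concordance/AUC metrics and calibration plots are not provided.
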