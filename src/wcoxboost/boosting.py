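"""Componentwise likelihood-based boosting for the weighted stratified Cox model.

Each boosting step considers, for every penalized covariate j, the
one-parameter candidate model ``eta_i + gamma * x_ij`` and the penalized
one-step Newton estimate ``gamma_j = U_j(0) / (I_j(0) + rho)``.  The best
candidate is chosen by the penalized score statistic ``U_j(0)^2 / (I_j(0) + rho)``
(a switch restores the unpenalized form ``U^2/I``), its coefficient is
incremented, and the linear predictor updated; all other penalized
coefficients are left untouched, which yields sparse fits.  Mandatory
(clinical) covariates are refit without penalty, with stratum-specific
coefficients, before every boosting step.

The penalty defaults to ``rho = sum_i w_i delta_i * (1/nu - 1)`` with
shrinkage ``nu = 0.02``; on covariates standardized to unit (weighted)
variance, ``I_j(0)`` is approximately the weighted event count, so each
update is roughly ``nu`` times the unpenalized one-step estimate.  With all
weights equal to one this reduces to the event-count rule
``sum_i delta_i (1/0.02 - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core import BaselineHazard, CoxWorkspace, breslow_baseline, newton_cox
from .datasets import SurvivalDataset
from .weights import WeightScheme

__all__ = [
    "BoostingConfig",
    "BoostingFit",
    "LinearPredictorState",
    "WeightedCoxBoost",
    "fit_boosting",
    "boost_step",
    "update_mandatory",
    "export_coef_path",
]

_VAR_EPS = 1e-12


@dataclass
class BoostingConfig:
    """Settings for one boosting run.

    steps: number of boosting steps M (>= 0).
    penalty: "auto" for ``sum w_i delta_i (1/shrinkage - 1)`` or a number.
    shrinkage: nu in (0,1); each update is about nu times the one-step MLE.
    scheme: the down-weighting scheme (focus stratum, weight w).
    standardize: internally standardize penalized covariates to weighted
        mean 0 / weighted variance 1 (coefficients are reported on the
        original scale either way).
    penalized_selection: rank candidates by U^2/(I+rho) (default) rather
        than the unpenalized U^2/I.
    """

    steps: int = 100
    penalty: float | str = "auto"
    shrinkage: float = 0.02
    scheme: WeightScheme = field(default_factory=WeightScheme)
    standardize: bool = True
    penalized_selection: bool = True

    def __post_init__(self):
        if self.steps < 0:
            raise ValueError("steps must be >= 0")
        if not (0.0 < self.shrinkage < 1.0):
            raise ValueError("shrinkage must lie in (0, 1)")
        if self.penalty != "auto" and float(self.penalty) < 0:
            raise ValueError("penalty must be nonnegative")

    def resolve_penalty(self, weights: np.ndarray, status: np.ndarray) -> float:
        if self.penalty == "auto":
            return float(np.sum(weights * status) * (1.0 / self.shrinkage - 1.0))
        return float(self.penalty)


@dataclass
class LinearPredictorState:
    """Current model state: linear predictor, coefficients, mandatory coefficients.

    ``beta`` lives on the scale of the covariates as given (mandatory
    entries stay 0; their contribution is carried by ``mandatory_coefs``,
    one coefficient vector per stratum).
    """

    eta: np.ndarray
    beta: np.ndarray
    mandatory_coefs: dict[int, np.ndarray]

    @classmethod
    def null(cls, data: SurvivalDataset) -> "LinearPredictorState":
        return cls(
            eta=np.zeros(data.n),
            beta=np.zeros(data.p),
            mandatory_coefs={},
        )

    def recompute_eta(self, data: SurvivalDataset) -> np.ndarray:
        eta = data.covariates @ self.beta
        if data.mandatory_mask.any() and self.mandatory_coefs:
            Z = data.covariates[:, data.mandatory_mask]
            for s, th in self.mandatory_coefs.items():
                m = data.strata == s
                eta[m] += Z[m] @ th
        return eta


@dataclass
class BoostingFit:
    """Result of a boosting run.

    coef_path: (M+1) x p coefficient history on the original covariate
        scale (row m = state after m boosting steps; mandatory columns 0).
    selected: index of the covariate updated at each step (length M).
    mandatory_path: per step, dict stratum -> mandatory coefficient vector.
    state: final LinearPredictorState (original scale, all observations).
    baseline: weighted Breslow baseline hazards per stratum.
    """

    coef_path: np.ndarray
    selected: list[int]
    mandatory_path: list[dict[int, np.ndarray]]
    state: LinearPredictorState
    baseline: BaselineHazard
    config: BoostingConfig
    covariate_names: list[str]
    excluded: list[str]

    @property
    def coef(self) -> np.ndarray:
        return self.coef_path[-1]

    @property
    def selected_names(self) -> list[str]:
        return [self.covariate_names[j] for j in self.selected]


def _weighted_standardize(X, weights):
    """Weighted center/scale with reliability-weight variance.

    V_j = sum w (x - m)^2 / (sum w - sum w^2 / sum w); with two-level
    weights this reduces to the plain sample variance of the focus subgroup
    at w=0 and of the full sample at w=1.
    """
    sw = weights.sum()
    m = (weights[:, None] * X).sum(axis=0) / sw
    denom = sw - (weights**2).sum() / sw
    if denom <= 0:
        denom = sw  # single effective observation; variance degenerate anyway
    V = (weights[:, None] * np.square(X - m)).sum(axis=0) / denom
    scale = np.sqrt(V)
    ok = np.isfinite(scale) & (scale > _VAR_EPS)
    return m, scale, ok


def _select_update(U, I, rho, mask, penalized_selection):
    denom = I + rho
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.square(U) / (denom if penalized_selection else I)
    stat = np.where(mask & (denom > 0) & np.isfinite(stat), stat, -np.inf)
    if not np.any(stat > -np.inf):
        raise ValueError("no candidate covariate with positive penalized information")
    j = int(np.argmax(stat))  # ties: smallest index
    return j, float(U[j] / denom[j])


def fit_boosting(data: SurvivalDataset, config: BoostingConfig) -> BoostingFit:
    """Run M steps of weighted componentwise boosting and record the path."""
    weights_all = config.scheme.weights(data.strata)
    pos = weights_all > 0
    fit_idx = np.flatnonzero(pos)
    sub = data.subset(fit_idx)
    weights = weights_all[fit_idx]

    for s in np.unique(sub.strata):
        if sub.status[sub.strata == s].sum() < 1:
            raise ValueError(f"stratum {s} retained for fitting has no events")

    pen_cols = np.flatnonzero(~data.mandatory_mask)
    mand_cols = np.flatnonzero(data.mandatory_mask)
    Xpen = sub.covariates[:, pen_cols]
    if np.isnan(Xpen).any():
        bad = [data.covariate_names[pen_cols[j]] for j in np.flatnonzero(np.isnan(Xpen).any(axis=0))]
        raise ValueError(f"penalized covariates with missing values cannot be fit: {bad[:10]}")

    if config.standardize and pen_cols.size:
        center, scale, ok = _weighted_standardize(Xpen, weights)
        Xcand = np.where(ok, (Xpen - center) / np.where(ok, scale, 1.0), Xpen)
        candidate_mask = ok
    else:
        center = np.zeros(pen_cols.size)
        scale = np.ones(pen_cols.size)
        ok = np.zeros(pen_cols.size, dtype=bool)
        Xcand = Xpen
        candidate_mask = np.ones(pen_cols.size, dtype=bool)
    excluded = [data.covariate_names[pen_cols[j]] for j in np.flatnonzero(~candidate_mask)] \
        if config.standardize else []

    if config.steps > 0 and pen_cols.size == 0:
        raise ValueError("no penalized covariates available for boosting steps")
    rho = config.resolve_penalty(weights, sub.status)
    ws = CoxWorkspace(sub.times, sub.status, sub.strata, weights, Xcand) if pen_cols.size else None
    Z = sub.covariates[:, mand_cols] if mand_cols.size else None

    beta_std = np.zeros(pen_cols.size)
    eta_pen = np.zeros(sub.n)
    thetas: dict[int, np.ndarray] = {}

    def refit_mandatory():
        if Z is None:
            return
        for s in np.unique(sub.strata):
            m = sub.strata == s
            if sub.status[m].sum() < 1:
                continue
            thetas[int(s)] = newton_cox(
                sub.times[m], sub.status[m], weights[m], Z[m],
                offset=eta_pen[m], theta0=thetas.get(int(s)),
            )

    def eta_now():
        eta = eta_pen.copy()
        if Z is not None:
            for s, th in thetas.items():
                m = sub.strata == s
                eta[m] += Z[m] @ th
        return eta

    path_std = [None] * (config.steps + 1)
    mandatory_path: list[dict[int, np.ndarray]] = []
    selected: list[int] = []

    refit_mandatory()
    path_std[0] = beta_std.copy()
    mandatory_path.append({s: th.copy() for s, th in thetas.items()})

    for m in range(1, config.steps + 1):
        refit_mandatory()
        U, I = ws.score_info(eta_now())
        j_loc, gamma = _select_update(U, I, rho, candidate_mask, config.penalized_selection)
        beta_std[j_loc] += gamma
        eta_pen += gamma * Xcand[:, j_loc]
        selected.append(int(pen_cols[j_loc]))
        path_std[m] = beta_std.copy()
        mandatory_path.append({s: th.copy() for s, th in thetas.items()})

    # back-transform to the original covariate scale (centering only shifts
    # eta by a global constant, which the partial likelihood ignores)
    def to_original(b_std):
        b = np.zeros(data.p)
        b_pen = b_std.copy()
        b_pen[ok] = b_pen[ok] / scale[ok]
        b[pen_cols] = b_pen
        return b

    coef_path = np.vstack([to_original(b) for b in path_std]) if config.steps >= 0 else None
    beta_orig = coef_path[-1]

    eta_all = data.covariates @ beta_orig
    if mand_cols.size:
        Zall = data.covariates[:, mand_cols]
        for s, th in thetas.items():
            mrows = data.strata == s
            eta_all[mrows] += Zall[mrows] @ th
    state = LinearPredictorState(
        eta=eta_all, beta=beta_orig, mandatory_coefs={s: th.copy() for s, th in thetas.items()}
    )
    baseline = breslow_baseline(data, config.scheme, eta_all)
    return BoostingFit(
        coef_path=coef_path,
        selected=selected,
        mandatory_path=mandatory_path,
        state=state,
        baseline=baseline,
        config=config,
        covariate_names=list(data.covariate_names),
        excluded=excluded,
    )


def boost_step(
    state: LinearPredictorState, data: SurvivalDataset, config: BoostingConfig
) -> tuple[LinearPredictorState, int, float]:
    """One componentwise boosting step on covariates as given (no rescaling).

    Returns the new state, the selected covariate index j* and its update
    gamma.  ``fit_boosting`` applies the same update rule after internal
    standardization; this op is the raw single-step primitive.
    """
    weights = config.scheme.weights(data.strata)
    rho = config.resolve_penalty(weights[weights > 0], data.status[weights > 0])
    pen_cols = np.flatnonzero(~data.mandatory_mask)
    ws = CoxWorkspace(data.times, data.status, data.strata, weights, data.covariates[:, pen_cols])
    U, I = ws.score_info(state.eta)
    mask = np.ones(pen_cols.size, dtype=bool)
    j_loc, gamma = _select_update(U, I, rho, mask, config.penalized_selection)
    j = int(pen_cols[j_loc])
    beta = state.beta.copy()
    beta[j] += gamma
    new = LinearPredictorState(
        eta=state.eta + gamma * data.covariates[:, j],
        beta=beta,
        mandatory_coefs={s: th.copy() for s, th in state.mandatory_coefs.items()},
    )
    return new, j, gamma


def update_mandatory(
    state: LinearPredictorState, data: SurvivalDataset, scheme: WeightScheme
) -> LinearPredictorState:
    """Refit stratum-specific mandatory coefficients by unpenalized Newton-Raphson.

    Penalized contributions are held fixed as an offset.  With interaction
    (per-stratum) coding the weighted likelihood separates over strata, so
    each stratum is refit on its own observations.
    """
    if not data.mandatory_mask.any():
        return state
    weights = scheme.weights(data.strata)
    Z = data.covariates[:, data.mandatory_mask]
    eta_pen = data.covariates @ state.beta
    thetas = {s: th.copy() for s, th in state.mandatory_coefs.items()}
    for s in np.unique(data.strata):
        m = (data.strata == s) & (weights > 0)
        if not m.any() or data.status[m].sum() < 1:
            continue
        thetas[int(s)] = newton_cox(
            data.times[m], data.status[m], weights[m], Z[m],
            offset=eta_pen[m], theta0=thetas.get(int(s)),
        )
    eta = eta_pen.copy()
    for s, th in thetas.items():
        m = data.strata == s
        eta[m] += Z[m] @ th
    return LinearPredictorState(eta=eta, beta=state.beta.copy(), mandatory_coefs=thetas)


def export_coef_path(fit: BoostingFit, path, sparse: bool = False) -> None:
    """Write the coefficient path as a delimited table.

    Wide form: one row per step (step, selected_name, then every covariate
    that is nonzero anywhere along the path).  Sparse triplets: columns
    step, name, value for nonzero entries only.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    nz = np.flatnonzero((fit.coef_path != 0).any(axis=0))
    sel = [""] + [fit.covariate_names[j] for j in fit.selected]
    if sparse:
        rows = [
            {"step": m, "name": fit.covariate_names[j], "value": fit.coef_path[m, j]}
            for m in range(fit.coef_path.shape[0])
            for j in nz
            if fit.coef_path[m, j] != 0
        ]
        pd.DataFrame(rows, columns=["step", "name", "value"]).to_csv(path, sep=sep, index=False)
    else:
        df = pd.DataFrame(fit.coef_path[:, nz], columns=[fit.covariate_names[j] for j in nz])
        df.insert(0, "selected_name", sel)
        df.insert(0, "step", np.arange(fit.coef_path.shape[0]))
        df.to_csv(path, sep=sep, index=False)


def _as_survival_dataset(X, y, strata, mandatory, feature_names) -> SurvivalDataset:
    if isinstance(X, SurvivalDataset):
        return X
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        names = list(feature_names) if feature_names is not None else [
            f"x{j + 1}" for j in range(Xv.shape[1])
        ]
    if y is None:
        raise ValueError("y (time, status) is required when X is a plain matrix")
    if isinstance(y, pd.DataFrame):
        times, status = y["time"].to_numpy(float), y["status"].to_numpy()
    elif hasattr(y, "dtype") and getattr(y.dtype, "names", None):
        fields = y.dtype.names
        tfield = "time" if "time" in fields else fields[1]
        sfield = "status" if "status" in fields else fields[0]
        times, status = y[tfield].astype(float), y[sfield].astype(int)
    else:
        y = np.asarray(y)
        times, status = y[:, 0].astype(float), y[:, 1]
    strata = np.ones(len(times), dtype=int) if strata is None else np.asarray(strata, int)
    mandatory = mandatory or []
    mmask = np.array([n in mandatory or j in mandatory for j, n in enumerate(names)])
    return SurvivalDataset(
        times=times, status=status, strata=strata, covariates=Xv,
        covariate_names=names, mandatory_mask=mmask,
    )


class WeightedCoxBoost(BaseEstimator):
    """Weighted stratified Cox regression via componentwise likelihood-based boosting.

    A sparse high-dimensional survival model: each of ``n_steps`` boosting
    steps updates a single covariate coefficient by a penalized one-step
    Newton estimate, while observations outside the focus stratum are
    down-weighted by ``weight`` in the stratified partial likelihood.

    Parameters
    ----------
    n_steps : number of boosting steps M (select by cross-validation;
        see :func:`wcoxboost.cv.cv_select_steps`).
    weight : down-weight in [0, 1] for observations outside the focus
        stratum; 1 = global stratified analysis, 0 = subgroup analysis.
    focus_stratum : stratum label receiving weight 1.
    penalty : "auto" (event-count rule) or an explicit nonnegative number.
    shrinkage : nu, the approximate fraction of the one-step MLE applied
        per update under the automatic penalty.
    standardize : standardize penalized covariates internally (weighted
        moments); coefficients are always reported on the original scale.
    penalized_selection : rank candidates by U^2/(I+rho) rather than U^2/I.
    mandatory : names (or column indices) of unpenalized covariates refit
        with stratum-specific coefficients before every step.

    Attributes
    ----------
    coef_ : (p,) final coefficients, original covariate scale.
    coef_path_ : (n_steps+1, p) coefficient history.
    selected_ : covariate index updated at each step.
    mandatory_coef_ : dict stratum -> coefficients of mandatory covariates.
    baseline_hazard_ : per-stratum weighted Breslow cumulative hazards.
    """

    def __init__(
        self,
        n_steps: int = 100,
        weight: float = 1.0,
        focus_stratum: int = 1,
        penalty="auto",
        shrinkage: float = 0.02,
        standardize: bool = True,
        penalized_selection: bool = True,
        mandatory=None,
    ):
        self.n_steps = n_steps
        self.weight = weight
        self.focus_stratum = focus_stratum
        self.penalty = penalty
        self.shrinkage = shrinkage
        self.standardize = standardize
        self.penalized_selection = penalized_selection
        self.mandatory = mandatory

    def _config(self) -> BoostingConfig:
        return BoostingConfig(
            steps=self.n_steps,
            penalty=self.penalty,
            shrinkage=self.shrinkage,
            scheme=WeightScheme(w=self.weight, focus_stratum=self.focus_stratum),
            standardize=self.standardize,
            penalized_selection=self.penalized_selection,
        )

    def fit(self, X, y=None, strata=None, feature_names=None):
        data = _as_survival_dataset(X, y, strata, self.mandatory, feature_names)
        fit = fit_boosting(data, self._config())
        self.result_ = fit
        self.coef_ = fit.coef
        self.coef_path_ = fit.coef_path
        self.selected_ = list(fit.selected)
        self.mandatory_coef_ = fit.state.mandatory_coefs
        self.baseline_hazard_ = fit.baseline
        self.feature_names_in_ = np.asarray(data.covariate_names, dtype=object)
        self.n_features_in_ = data.p
        self._mandatory_cols_ = np.flatnonzero(data.mandatory_mask)
        return self

    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise ValueError("this WeightedCoxBoost instance is not fitted yet")

    def _X_strata(self, X, strata):
        if isinstance(X, SurvivalDataset):
            return X.covariates, X.strata
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if strata is None:
            strata = np.full(X.shape[0], self.focus_stratum, dtype=int)
        return X, np.asarray(strata, int)

    def predict(self, X, strata=None) -> np.ndarray:
        """Linear predictor (log relative hazard), including mandatory terms."""
        self._check_fitted()
        Xv, strata = self._X_strata(X, strata)
        eta = Xv @ self.coef_
        if self._mandatory_cols_.size:
            Z = Xv[:, self._mandatory_cols_]
            for s, th in self.mandatory_coef_.items():
                m = strata == s
                eta[m] += Z[m] @ th
        return eta

    def predict_cumulative_hazard(self, X, times, strata=None) -> np.ndarray:
        self._check_fitted()
        Xv, strata = self._X_strata(X, strata)
        eta = self.predict(Xv, strata)
        times = np.asarray(times, float)
        out = np.empty((Xv.shape[0], times.shape[0]))
        for i in range(Xv.shape[0]):
            out[i] = self.baseline_hazard_.cumulative_hazard(strata[i], times) * np.exp(eta[i])
        return out

    def predict_survival_function(self, X, times, strata=None) -> np.ndarray:
        """Matrix S(t | x_i) over the given time grid, one row per subject."""
        return np.exp(-self.predict_cumulative_hazard(X, times, strata))

    def score(self, X, y=None, strata=None) -> float:
        """Weighted stratified partial log-likelihood of the fitted coefficients."""
        from .core import weighted_partial_loglik

        data = _as_survival_dataset(X, y, strata, self.mandatory, None)
        eta = self.predict(data.covariates, data.strata)
        return weighted_partial_loglik(
            data, WeightScheme(w=self.weight, focus_stratum=self.focus_stratum), eta
        )
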