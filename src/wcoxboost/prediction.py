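"""Time-dependent Brier-score prediction error with censoring weighting.

The prediction error of a survival model at time t is the mean squared
difference between the event-free indicator I(T_i > t) and the predicted
survival probability S(t | x_i), reweighted by the inverse probability of
censoring (IPCW): subjects with an observed event before t contribute with
weight 1/G(t_i-), subjects still under observation at t with weight
1/G(t), and subjects censored before t contribute 0, where G is the
Kaplan-Meier estimate of the censoring distribution on the evaluation
data.  Without censoring all weights are 1 and the curve is the raw mean
squared error.

Out-of-sample error is estimated by the 0.632+ rule over stratified
0.632-subsamples: the apparent error (model fit and evaluated on the full
data) and the out-of-bag error (averaged over evaluations of each subject
in the resamples that excluded it) are combined as

    err_632+(t) = (1 - w(t)) err_app(t) + w(t) err_oob(t),
    w(t) = 0.632 / (1 - 0.368 R(t)),

with relative overfitting rate R(t) = (err_oob - err_app) /
(err_noinf - err_app) clipped to [0, 1]; the no-information error
err_noinf averages the error over all subject-prediction pairings.
Evaluation is restricted to the focus stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from sklearn.base import clone

from .datasets import SurvivalDataset
from .stability import draw_subsample

__all__ = [
    "PredictionErrorCurves",
    "KaplanMeierNull",
    "StaticSurvival",
    "censoring_survival",
    "brier_curve",
    "dot632plus_curves",
    "ipec",
]


def _km_step(times, events):
    """Kaplan-Meier step function as (jump times incl. 0, survival values)."""
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def censoring_survival(times, status):
    """KM estimate G of the censoring distribution (status flipped)."""
    times = np.asarray(times, float)
    status = np.asarray(status)
    return _km_step(times, 1 - status)


def _step_eval(ts, vals, t, side):
    pos = np.searchsorted(ts, t, side=side) - 1
    return np.where(pos >= 0, vals[np.clip(pos, 0, None)], 1.0)


def ipcw_weights(times, status, grid, censor_step=None):
    """(n, T) IPCW weight matrix on the evaluation data."""
    times = np.asarray(times, float)
    status = np.asarray(status)
    grid = np.asarray(grid, float)
    ts, vals = censor_step if censor_step is not None else censoring_survival(times, status)
    G_at_grid = _step_eval(ts, vals, grid, side="right")
    G_before_ti = _step_eval(ts, vals, times, side="left")
    event_before = (times[:, None] <= grid[None, :]) & (status[:, None] == 1)
    at_risk = times[:, None] > grid[None, :]
    with np.errstate(divide="ignore"):
        w_event = np.where(G_before_ti[:, None] > 0, 1.0 / G_before_ti[:, None], 0.0)
        w_risk = np.where(G_at_grid[None, :] > 0, 1.0 / G_at_grid[None, :], 0.0)
    return np.where(event_before, w_event, 0.0) + np.where(at_risk, w_risk, 0.0)


def brier_curve(surv, times, status, grid, censor_step=None) -> np.ndarray:
    """IPCW Brier score at each grid time.

    ``surv`` is the (n, T) matrix of predicted survival probabilities
    S(t | x_i) over the grid (a 1-d curve is broadcast to all subjects).
    """
    times = np.asarray(times, float)
    status = np.asarray(status)
    grid = np.asarray(grid, float)
    surv = np.asarray(surv, float)
    if surv.ndim == 1:
        surv = np.broadcast_to(surv, (times.shape[0], grid.shape[0]))
    W = ipcw_weights(times, status, grid, censor_step)
    Y = (times[:, None] > grid[None, :]).astype(float)
    return np.mean(W * np.square(Y - surv), axis=0)


class KaplanMeierNull:
    """Null model: the Kaplan-Meier curve of the focus stratum, same for all x."""

    def __init__(self, focus_stratum: int = 1):
        self.focus_stratum = focus_stratum

    def fit(self, data: SurvivalDataset):
        rows = data.strata == self.focus_stratum
        self._step = _km_step(data.times[rows], data.status[rows])
        return self

    def survival(self, data: SurvivalDataset, rows, grid) -> np.ndarray:
        ts, vals = self._step
        s = _step_eval(ts, vals, np.asarray(grid, float), side="right")
        return np.broadcast_to(s, (len(rows), len(grid))).copy()

    def get_params(self, deep=True):
        return {"focus_stratum": self.focus_stratum}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self


class StaticSurvival:
    """A frozen prediction rule (no refitting across resamples)."""

    def __init__(self, curve: np.ndarray):
        self.curve = np.asarray(curve, float)

    def survival(self, data, rows, grid) -> np.ndarray:
        if self.curve.ndim == 1:
            return np.broadcast_to(self.curve, (len(rows), len(grid))).copy()
        return self.curve[rows]


def _fit_and_predict(model, fit_data: SurvivalDataset, eval_data: SurvivalDataset, rows, grid):
    """Fit (if the model fits) and return S(t|x) for eval_data rows over grid."""
    if isinstance(model, str) and model == "null":
        model = KaplanMeierNull(focus_stratum=1)
    if hasattr(model, "fit"):
        try:
            fitted = clone(model)
        except TypeError:
            fitted = model.__class__(**model.get_params())
        fitted.fit(fit_data)
        if hasattr(fitted, "survival"):
            return fitted.survival(eval_data, rows, grid)
        return fitted.predict_survival_function(
            eval_data.covariates[rows], grid, strata=eval_data.strata[rows]
        )
    return model.survival(eval_data, rows, grid)


def dot632plus_combine(err_app, err_oob, err_noinf):
    """Pointwise 0.632+ combination; returns (estimate, R, weight).

    R is the relative overfitting rate clipped to [0, 1]; R = 0 (oob error
    not above apparent) reduces the estimate to the plain 0.632 rule.
    """
    err_app = np.asarray(err_app, float)
    err_oob = np.asarray(err_oob, float)
    err_noinf = np.asarray(err_noinf, float)
    denom = err_noinf - err_app
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(np.abs(denom) > 1e-12, (err_oob - err_app) / denom, 0.0)
    R = np.clip(R, 0.0, 1.0)
    wt = 0.632 / (1.0 - 0.368 * R)
    return (1.0 - wt) * err_app + wt * err_oob, R, wt


@dataclass
class PredictionErrorCurves:
    """Apparent / out-of-bag / 0.632+ Brier curves and integrated errors per model."""

    times: np.ndarray
    curves: dict[str, dict[str, np.ndarray]]
    ipec: dict[str, float]
    focus_stratum: int
    n_resamples: int


def default_time_grid(data: SurvivalDataset, focus_stratum: int = 1, quantile: float = 0.95):
    """Unique event times of the focus stratum, truncated at a tail quantile."""
    rows = (data.strata == focus_stratum) & (data.status == 1)
    et = np.unique(data.times[rows])
    if et.size == 0:
        raise ValueError("focus stratum has no events; cannot build a time grid")
    return et[et <= np.quantile(et, quantile)]


def dot632plus_curves(
    data: SurvivalDataset,
    models: dict[str, object],
    n_resamples: int = 100,
    fraction: float = 0.632,
    time_grid=None,
    seed=None,
    focus_stratum: int = 1,
) -> PredictionErrorCurves:
    """0.632+ prediction error curves, evaluated on the focus stratum.

    ``models`` maps a display name to either the string ``"null"``
    (Kaplan-Meier), an estimator with ``fit``/``predict_survival_function``
    (e.g. :class:`~wcoxboost.boosting.WeightedCoxBoost`), or a
    :class:`StaticSurvival`.  The same subsample sequence is used for every
    model (paired with :func:`wcoxboost.stability.draw_subsample`).
    """
    eval_rows = np.flatnonzero(data.strata == focus_stratum)
    if eval_rows.size == 0:
        raise ValueError(f"focus stratum {focus_stratum} absent from data")
    t_eval = data.times[eval_rows]
    d_eval = data.status[eval_rows]
    grid = (
        np.asarray(time_grid, float)
        if time_grid is not None
        else default_time_grid(data, focus_stratum)
    )
    censor = censoring_survival(t_eval, d_eval)
    W = ipcw_weights(t_eval, d_eval, grid, censor)
    Y = (t_eval[:, None] > grid[None, :]).astype(float)

    root = np.random.SeedSequence(seed)
    sub_idx = [
        draw_subsample(data, fraction, seed=s) for s in root.spawn(n_resamples)
    ]
    oob_rows = [np.setdiff1d(eval_rows, idx) for idx in sub_idx]
    row_pos = {g: i for i, g in enumerate(eval_rows)}

    curves: dict[str, dict[str, np.ndarray]] = {}
    ipec_map: dict[str, float] = {}
    for name, model in models.items():
        S_app = np.asarray(_fit_and_predict(model, data, data, eval_rows, grid), float)
        err_app = np.mean(W * np.square(Y - S_app), axis=0)
        # no-information error: average over all subject-prediction pairings
        E1 = S_app.mean(axis=0)
        E2 = np.square(S_app).mean(axis=0)
        err_noinf = np.mean(W * (np.square(Y) - 2.0 * Y * E1 + E2), axis=0)

        err_sum = np.zeros((eval_rows.size, grid.size))
        cnt = np.zeros(eval_rows.size)
        for idx, oob in zip(sub_idx, oob_rows):
            if oob.size == 0:
                continue
            S_oob = np.asarray(_fit_and_predict(model, data.subset(idx), data, oob, grid), float)
            pos = np.asarray([row_pos[g] for g in oob])
            err_sum[pos] += W[pos] * np.square(Y[pos] - S_oob)
            cnt[pos] += 1
        # subjects never left out contribute their apparent error, so the
        # estimate is defined for every subject and a frozen prediction rule
        # has err_oob == err_app exactly
        app_by_subject = W * np.square(Y - S_app)
        used = cnt > 0
        per_subject = np.where(used[:, None], err_sum / np.maximum(cnt, 1)[:, None], app_by_subject)
        err_oob = np.mean(per_subject, axis=0)

        err_632, _, _ = dot632plus_combine(err_app, err_oob, err_noinf)
        curves[name] = {"apparent": err_app, "oob": err_oob, "dot632plus": err_632}
        ipec_map[name] = float(np.trapezoid(err_632, grid)) if grid.size >= 2 else 0.0
    return PredictionErrorCurves(
        times=grid,
        curves=curves,
        ipec=ipec_map,
        focus_stratum=focus_stratum,
        n_resamples=n_resamples,
    )


def ipec(curves: PredictionErrorCurves, time_range=None, which: str = "dot632plus"):
    """Integrated prediction error (trapezoidal area) per model.

    ``time_range`` restricts integration to [t0, t1]; default is the full
    curve grid.
    """
    t = curves.times
    if t.size < 2:
        raise ValueError("need at least two grid points to integrate")
    mask = np.ones(t.size, dtype=bool)
    if time_range is not None:
        mask = (t >= time_range[0]) & (t <= time_range[1])
        if mask.sum() < 2:
            raise ValueError("time_range contains fewer than two grid points")
    return {
        name: float(np.trapezoid(c[which][mask], t[mask])) for name, c in curves.curves.items()
    }
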