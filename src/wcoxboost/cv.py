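"""K-fold cross-validation for the number of boosting steps M.

Folds are stratified jointly by stratum and event status so that every
fold mirrors the event/stratum composition (this keeps small strata from
producing eventless training splits).  Each candidate step count m is
scored by the cross-validated predictive partial log-likelihood in the
Verweij-van Houwelingen form

    score(m) = sum_folds [ l_full(beta_m) - l_train(beta_m) ]

reported relative to the step-0 (null / mandatory-only) contribution, so
the score at m = 0 is exactly 0.  The selected M maximizes the score;
ties go to the smallest M.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boosting import BoostingConfig, BoostingFit, fit_boosting
from .core import CoxWorkspace
from .datasets import SurvivalDataset

__all__ = ["CVResult", "cv_select_steps"]


@dataclass
class CVResult:
    """Fold assignments, per-step CV scores and the selected step count."""

    folds: np.ndarray
    scores: np.ndarray
    best_m: int
    n_folds: int

    def __post_init__(self):
        assert 0 <= self.best_m < self.scores.shape[0]


def _stratified_folds(data: SurvivalDataset, K: int, rng: np.random.Generator) -> np.ndarray:
    folds = np.empty(data.n, dtype=int)
    for s in data.stratum_ids:
        for d in (0, 1):
            idx = np.flatnonzero((data.strata == s) & (data.status == d))
            if idx.size == 0:
                continue
            idx = rng.permutation(idx)
            folds[idx] = (np.arange(idx.size) % K) + 1
    return folds


def _eta_path(fit: BoostingFit, data: SurvivalDataset):
    """Yield the linear predictor on ``data`` for every step 0..M (incremental)."""
    X = data.covariates
    mand_cols = np.flatnonzero(data.mandatory_mask)
    Z = X[:, mand_cols] if mand_cols.size else None
    eta_pen = X @ fit.coef_path[0]
    for m in range(fit.coef_path.shape[0]):
        if m > 0:
            diff = fit.coef_path[m] - fit.coef_path[m - 1]
            nz = np.flatnonzero(diff)
            for j in nz:
                eta_pen = eta_pen + diff[j] * X[:, j]
        eta = eta_pen.copy()
        if Z is not None:
            for s, th in fit.mandatory_path[m].items():
                rows = data.strata == s
                eta[rows] += Z[rows] @ th
        yield eta


def cv_select_steps(
    data: SurvivalDataset,
    config: BoostingConfig,
    K: int = 10,
    M_max: int | None = None,
    seed=None,
) -> CVResult:
    """Choose the number of boosting steps by K-fold cross-validation.

    Fits the boosting path up to ``M_max`` steps on each training split and
    scores every step count by the fold-summed predictive partial
    log-likelihood (see module docstring).  Folds with an eventless stratum
    in some training split are redrawn (up to 10 attempts).
    """
    if M_max is None:
        M_max = config.steps
    rng = np.random.default_rng(seed)
    weights_all = config.scheme.weights(data.strata)
    required = [s for s in data.stratum_ids if np.any(weights_all[data.strata == s] > 0)]

    folds = None
    for _ in range(10):
        cand = _stratified_folds(data, K, rng)
        feasible = all(
            data.status[(cand != k) & (data.strata == s)].sum() >= 1
            for k in range(1, K + 1)
            for s in required
        )
        if feasible:
            folds = cand
            break
    if folds is None:
        raise ValueError(
            "could not draw cross-validation folds with at least one event "
            "per stratum in every training split (10 attempts)"
        )

    full_ws = CoxWorkspace(data.times, data.status, data.strata, weights_all)
    cfg = BoostingConfig(
        steps=M_max,
        penalty=config.penalty,
        shrinkage=config.shrinkage,
        scheme=config.scheme,
        standardize=config.standardize,
        penalized_selection=config.penalized_selection,
    )
    scores = np.zeros(M_max + 1)
    for k in range(1, K + 1):
        train_idx = np.flatnonzero(folds != k)
        train = data.subset(train_idx)
        train_w = weights_all[train_idx]
        train_ws = CoxWorkspace(train.times, train.status, train.strata, train_w)
        fit = fit_boosting(train, cfg)
        contrib = np.empty(M_max + 1)
        for m, eta_full in enumerate(_eta_path(fit, data)):
            contrib[m] = full_ws.loglik(eta_full) - train_ws.loglik(eta_full[train_idx])
        scores += contrib - contrib[0]
    best_m = int(np.argmax(scores))  # ties: smallest m
    return CVResult(folds=folds, scores=scores, best_m=best_m, n_folds=K)
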