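"""Weighted stratified Cox partial likelihood, derivatives and baseline hazard.

For observations ``(t_i, delta_i, x_i, s_i)`` with weights ``w_i`` the
weighted stratified partial log-likelihood is

    l = sum_s sum_i I(s_i=s) w_i delta_i
            [ eta_i - log sum_k I(s_k=s) w_k I(t_i <= t_k) exp(eta_k) ]

with linear predictor ``eta_i``.  Risk sets use the convention
``I(t_i <= t_k)`` — observations tied with the event time are at risk —
which is the Breslow tie treatment (simultaneous events share a risk set).

For a single-direction update ``eta_i + gamma * x_ij`` the score and
(observed) information at gamma = 0 are

    U_j = sum_s sum_i I(s_i=s) w_i delta_i [ x_ij - A_ij ]
    I_j = sum_s sum_i I(s_i=s) w_i delta_i [ B_ij - A_ij^2 ]

where A and B are the weighted risk-set means of x and x^2 under masses
``w_k exp(eta_k)``.  ``I_j`` is a weighted sum of risk-set variances, hence
nonnegative.

All risk-set sums are computed by one reverse cumulative pass over the
time-sorted observations of each stratum, so a full scan over p candidate
covariates costs O(n p) after a one-time sort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import SurvivalDataset
from .weights import WeightScheme

__all__ = [
    "BaselineHazard",
    "weighted_partial_loglik",
    "directional_score_info",
    "score_information",
    "breslow_baseline",
]


def _suffix_cumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


class CoxWorkspace:
    """Per-stratum sorted views of the data, reused across likelihood scans.

    Observations with weight exactly 0 are dropped: they contribute nothing
    to any weighted quantity, and dropping them makes the w=0 subgroup
    reduction exact.
    """

    def __init__(self, times, status, strata, weights, X=None):
        times = np.asarray(times, float)
        status = np.asarray(status)
        strata = np.asarray(strata)
        weights = np.asarray(weights, float)
        if np.any(weights < 0):
            raise ValueError("weights must be nonnegative")
        self.strata_blocks = []
        for s in np.unique(strata):
            idx = np.flatnonzero((strata == s) & (weights > 0))
            if idx.size == 0:
                continue
            order = np.argsort(times[idx], kind="stable")
            idx = idx[order]
            t = times[idx]
            d = status[idx]
            w = weights[idx]
            ev = d == 1
            starts = np.searchsorted(t, t[ev], side="left")
            block = {
                "stratum": int(s),
                "idx": idx,
                "t": t,
                "w": w,
                "ev": ev,
                "starts": starts,
                "w_ev": w[ev],
                "Xs": None if X is None else np.ascontiguousarray(X[idx]),
            }
            self.strata_blocks.append(block)

    def loglik(self, eta: np.ndarray) -> float:
        total = 0.0
        for b in self.strata_blocks:
            if b["w_ev"].size == 0:
                continue
            e = eta[b["idx"]]
            r = b["w"] * np.exp(e)
            s0 = _suffix_cumsum(r)
            denom = s0[b["starts"]]
            if np.any(denom <= 0):
                i = int(np.flatnonzero(denom <= 0)[0])
                raise ValueError(
                    f"zero weighted risk-set sum in stratum {b['stratum']} "
                    f"at event time {b['t'][b['ev']][i]}"
                )
            total += float(np.sum(b["w_ev"] * (e[b["ev"]] - np.log(denom))))
        return total

    def score_info(self, eta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Componentwise score U_j and information I_j at gamma=0, all columns."""
        p = self.strata_blocks[0]["Xs"].shape[1]
        U = np.zeros(p)
        I = np.zeros(p)
        for b in self.strata_blocks:
            if b["w_ev"].size == 0:
                continue
            e = eta[b["idx"]]
            r = b["w"] * np.exp(e)
            Xs = b["Xs"]
            s0 = _suffix_cumsum(r)
            s1 = _suffix_cumsum(r[:, None] * Xs)
            s2 = _suffix_cumsum(r[:, None] * np.square(Xs))
            d0 = s0[b["starts"]][:, None]
            if np.any(d0 <= 0):
                raise ValueError(f"zero weighted risk-set sum in stratum {b['stratum']}")
            A = s1[b["starts"]] / d0
            B = s2[b["starts"]] / d0
            wev = b["w_ev"][:, None]
            U += np.sum(wev * (Xs[b["ev"]] - A), axis=0)
            I += np.sum(wev * (B - np.square(A)), axis=0)
        return U, I

    def breslow(self, eta: np.ndarray) -> dict[int, tuple[np.ndarray, np.ndarray]]:
        out = {}
        for b in self.strata_blocks:
            if b["w_ev"].size == 0:
                out[b["stratum"]] = (np.empty(0), np.empty(0))
                continue
            e = eta[b["idx"]]
            r = b["w"] * np.exp(e)
            s0 = _suffix_cumsum(r)
            denom = s0[b["starts"]]
            tev = b["t"][b["ev"]]
            ut, inv = np.unique(tev, return_inverse=True)
            inc = np.zeros(ut.shape[0])
            np.add.at(inc, inv, b["w_ev"] / denom)
            out[b["stratum"]] = (ut, np.cumsum(inc))
        return out


@dataclass
class BaselineHazard:
    """Per-stratum weighted Breslow cumulative baseline hazards.

    ``hazards[s]`` is a pair (sorted unique event times, cumulative hazard
    values).  Strata with no (positive-weight) events have an empty step
    function, i.e. cumulative hazard identically 0.
    """

    hazards: dict[int, tuple[np.ndarray, np.ndarray]]

    def cumulative_hazard(self, stratum: int, times) -> np.ndarray:
        times = np.atleast_1d(np.asarray(times, float))
        ut, ch = self.hazards.get(int(stratum), (np.empty(0), np.empty(0)))
        if ut.size == 0:
            return np.zeros(times.shape[0])
        pos = np.searchsorted(ut, times, side="right") - 1
        out = np.where(pos >= 0, ch[np.clip(pos, 0, None)], 0.0)
        return out

    def survival(self, stratum: int, times, eta: float) -> np.ndarray:
        """S(t | x) = exp(-Lambda_0^(s)(t) * exp(eta))."""
        return np.exp(-self.cumulative_hazard(stratum, times) * np.exp(eta))


def _workspace(data: SurvivalDataset, scheme: WeightScheme, with_X: bool) -> CoxWorkspace:
    w = scheme.weights(data.strata)
    return CoxWorkspace(
        data.times, data.status, data.strata, w, data.covariates if with_X else None
    )


def weighted_partial_loglik(data: SurvivalDataset, scheme: WeightScheme, eta) -> float:
    """Weighted stratified partial log-likelihood at linear predictor ``eta``."""
    eta = np.asarray(eta, float)
    if eta.shape[0] != data.n:
        raise ValueError("eta must have one entry per observation")
    return _workspace(data, scheme, with_X=False).loglik(eta)


def score_information(
    data: SurvivalDataset, scheme: WeightScheme, eta, columns=None
) -> tuple[np.ndarray, np.ndarray]:
    """Score and information at gamma=0 for every covariate (or ``columns``)."""
    eta = np.asarray(eta, float)
    ds = data if columns is None else data.select_covariates(
        np.asarray([data.column(c) for c in columns])
    )
    if np.isnan(ds.covariates).any():
        raise ValueError("covariates with missing values cannot be scored")
    return _workspace(ds, scheme, with_X=True).score_info(eta)


def directional_score_info(
    data: SurvivalDataset, scheme: WeightScheme, eta, j
) -> tuple[float, float]:
    """Score U and information I at gamma=0 for candidate covariate ``j``."""
    U, I = score_information(data, scheme, eta, columns=[j])
    return float(U[0]), float(I[0])


def breslow_baseline(data: SurvivalDataset, scheme: WeightScheme, eta) -> BaselineHazard:
    """Weighted Breslow cumulative baseline hazard per stratum at fitted ``eta``."""
    eta = np.asarray(eta, float)
    ws = _workspace(data, scheme, with_X=False)
    hazards = ws.breslow(eta)
    for s in data.stratum_ids:  # zero-weight strata never enter the workspace
        hazards.setdefault(int(s), (np.empty(0), np.empty(0)))
    return BaselineHazard(hazards=hazards)


def newton_cox(times, status, weights, Z, offset, theta0=None, max_iter=25, tol=1e-8):
    """Unpenalized Newton-Raphson for a (single-stratum) weighted Cox model.

    Fits coefficients for the columns of ``Z`` with ``offset`` held fixed in
    the linear predictor.  Used for mandatory-covariate refits; ``Z`` has few
    columns.  Raises on nonfinite steps (typically wildly scaled covariates).
    """
    times = np.asarray(times, float)
    status = np.asarray(status)
    weights = np.asarray(weights, float)
    Z = np.atleast_2d(np.asarray(Z, float))
    if Z.shape[0] != times.shape[0]:
        Z = Z.T
    q = Z.shape[1]
    theta = np.zeros(q) if theta0 is None else np.asarray(theta0, float).copy()

    keep = weights > 0
    t, d, w, Zk = times[keep], status[keep], weights[keep], Z[keep]
    off = np.asarray(offset, float)[keep]
    order = np.argsort(t, kind="stable")
    t, d, w, Zk, off = t[order], d[order], w[order], Zk[order], off[order]
    ev = d == 1
    if not ev.any():
        return theta
    starts = np.searchsorted(t, t[ev], side="left")
    wev = w[ev]

    for _ in range(max_iter):
        eta = off + Zk @ theta
        r = w * np.exp(eta)
        s0 = _suffix_cumsum(r)
        s1 = _suffix_cumsum(r[:, None] * Zk)
        s2 = _suffix_cumsum(np.einsum("n,na,nb->nab", r, Zk, Zk))
        d0 = s0[starts]
        zbar = s1[starts] / d0[:, None]
        U = np.sum(wev[:, None] * (Zk[ev] - zbar), axis=0)
        H = np.einsum(
            "i,iab->ab", wev, s2[starts] / d0[:, None, None]
        ) - np.einsum("i,ia,ib->ab", wev, zbar, zbar)
        try:
            step = np.linalg.solve(H, U)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular information matrix in mandatory-covariate refit"
            ) from exc
        if not np.all(np.isfinite(step)):
            raise ValueError(
                "Newton-Raphson diverged for mandatory covariates; "
                "consider rescaling them"
            )
        theta = theta + step
        if np.max(np.abs(step)) < tol * (1.0 + np.max(np.abs(theta))):
            break
    return theta
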