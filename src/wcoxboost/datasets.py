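"""Stratified survival data with high-dimensional covariates: container and delimited IO.

The central container is :class:`SurvivalDataset`, holding right-censored
observations ``(t_i, delta_i, x_i, s_i)`` — observed time, event indicator,
covariate vector and stratum label — together with covariate names and a
mask of mandatory (unpenalized) covariates.  Strata are coded internally as
integers ``1..S``; the stratum of interest ("focus") is coded 1.

Files are plain delimited text (comma or tab, auto-detected by extension):
one covariate matrix file with a header of covariate names, and one endpoint
file with columns ``time``, ``status``, ``stratum``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalDataset",
    "StandardizationRecord",
    "read_dataset",
    "write_dataset",
    "filter_all_missing",
    "standardize",
]


def _sep_for(path) -> str:
    suffix = Path(path).suffix.lower()
    return "," if suffix == ".csv" else "\t"


@dataclass
class SurvivalDataset:
    """Right-censored, stratified survival data with an n x p covariate matrix.

    Parameters
    ----------
    times : array of nonnegative observed times (event or censoring).
    status : array of event indicators, 1 = event, 0 = censored.
    strata : integer stratum labels in ``1..S`` (1 = focus stratum).
    covariates : float matrix, shape (n, p); NaN marks a missing value
        (allowed on input; any missing value among fitted covariates is an
        error at fit time).
    covariate_names : p unique names.
    mandatory_mask : boolean mask of mandatory (unpenalized) covariates;
        mandatory columns must be free of missing values.
    stratum_labels : optional mapping internal code -> original label, kept
        so files round-trip with the user's own stratum labels.
    """

    times: np.ndarray
    status: np.ndarray
    strata: np.ndarray
    covariates: np.ndarray
    covariate_names: list[str]
    mandatory_mask: np.ndarray | None = None
    stratum_labels: dict[int, object] | None = field(default=None, repr=False)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.status = np.asarray(self.status)
        self.strata = np.asarray(self.strata, dtype=int)
        self.covariates = np.asarray(self.covariates, dtype=float)
        self.covariate_names = [str(c) for c in self.covariate_names]
        n = self.times.shape[0]
        if n < 2:
            raise ValueError(f"need at least 2 observations, got {n}")
        if self.covariates.ndim != 2:
            raise ValueError("covariates must be a 2-d matrix")
        if not (self.status.shape[0] == self.strata.shape[0] == self.covariates.shape[0] == n):
            raise ValueError("times, status, strata and covariates must have identical length")
        if not np.all(np.isin(self.status, (0, 1))):
            bad = np.setdiff1d(np.unique(self.status), [0, 1])
            raise ValueError(f"status must be binary 0/1; found values {bad.tolist()}")
        self.status = self.status.astype(np.int8)
        if np.any(~np.isfinite(self.times)) or np.any(self.times < 0):
            raise ValueError("times must be finite and nonnegative")
        if len(set(self.covariate_names)) != len(self.covariate_names):
            raise ValueError("covariate names must be unique")
        if len(self.covariate_names) != self.covariates.shape[1]:
            raise ValueError("covariate_names length does not match covariate matrix width")
        if self.mandatory_mask is None:
            self.mandatory_mask = np.zeros(self.p, dtype=bool)
        else:
            self.mandatory_mask = np.asarray(self.mandatory_mask, dtype=bool)
            if self.mandatory_mask.shape[0] != self.p:
                raise ValueError("mandatory_mask length does not match number of covariates")
        if self.mandatory_mask.any() and np.isnan(self.covariates[:, self.mandatory_mask]).any():
            raise ValueError("mandatory covariates must not contain missing values")

    @property
    def n(self) -> int:
        return self.times.shape[0]

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @property
    def stratum_ids(self) -> np.ndarray:
        return np.unique(self.strata)

    @property
    def n_strata(self) -> int:
        return self.stratum_ids.shape[0]

    @property
    def mandatory_names(self) -> list[str]:
        return [c for c, m in zip(self.covariate_names, self.mandatory_mask) if m]

    def column(self, name_or_index) -> int:
        """Resolve a covariate name or integer position to a column index."""
        if isinstance(name_or_index, str):
            try:
                return self.covariate_names.index(name_or_index)
            except ValueError:
                raise KeyError(f"unknown covariate {name_or_index!r}") from None
        j = int(name_or_index)
        if not 0 <= j < self.p:
            raise IndexError(f"covariate index {j} out of range for p={self.p}")
        return j

    def subset(self, idx) -> "SurvivalDataset":
        """Row subset (observations), keeping all covariates and metadata."""
        idx = np.asarray(idx)
        return SurvivalDataset(
            times=self.times[idx],
            status=self.status[idx],
            strata=self.strata[idx],
            covariates=self.covariates[idx],
            covariate_names=list(self.covariate_names),
            mandatory_mask=self.mandatory_mask.copy(),
            stratum_labels=self.stratum_labels,
        )

    def select_covariates(self, keep: np.ndarray) -> "SurvivalDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return SurvivalDataset(
            times=self.times,
            status=self.status,
            strata=self.strata,
            covariates=self.covariates[:, keep],
            covariate_names=[self.covariate_names[j] for j in keep],
            mandatory_mask=self.mandatory_mask[keep],
            stratum_labels=self.stratum_labels,
        )

    def validate_for_fitting(self) -> None:
        """Fit-time checks: >=1 event per stratum, no missing fitted values."""
        for s in self.stratum_ids:
            if self.status[self.strata == s].sum() < 1:
                raise ValueError(f"stratum {s} has no events; cannot fit")
        if np.isnan(self.covariates).any():
            bad = [self.covariate_names[j] for j in np.flatnonzero(np.isnan(self.covariates).any(axis=0))]
            raise ValueError(
                "missing covariate values present at fit time (use filter_all_missing "
                f"for all-missing columns; partial missingness is not imputed): {bad[:10]}"
            )

    def __eq__(self, other) -> bool:
        if not isinstance(other, SurvivalDataset):
            return NotImplemented
        return (
            np.array_equal(self.times, other.times)
            and np.array_equal(self.status, other.status)
            and np.array_equal(self.strata, other.strata)
            and np.array_equal(self.covariates, other.covariates, equal_nan=True)
            and self.covariate_names == other.covariate_names
            and np.array_equal(self.mandatory_mask, other.mandatory_mask)
        )


def read_dataset(
    covariate_path,
    endpoint_path,
    mandatory: list[str] | None = None,
    focus=None,
    log_transform: bool = False,
    log_offset: float = 1.0,
) -> SurvivalDataset:
    """Read a covariate matrix file and an endpoint file into a SurvivalDataset.

    The endpoint file needs columns ``time``, ``status`` (0/1) and
    ``stratum`` (arbitrary labels).  Strata are re-coded to ``1..S`` in order
    of first appearance; if ``focus`` names one label, that stratum becomes 1.
    ``log_transform`` applies ``log(x + log_offset)`` to non-mandatory
    columns (a convenience for skewed count-like expression matrices).
    """
    mandatory = list(mandatory or [])
    cov = pd.read_csv(
        covariate_path, sep=_sep_for(covariate_path), na_values=["NA"],
        float_precision="round_trip",
    )
    end = pd.read_csv(
        endpoint_path, sep=_sep_for(endpoint_path), na_values=["NA"],
        float_precision="round_trip",
    )
    for col in ("time", "status", "stratum"):
        if col not in end.columns:
            raise ValueError(f"endpoint file lacks required column {col!r}")
    if len(cov) != len(end):
        raise ValueError(
            f"row-count mismatch: covariate file has {len(cov)} rows, endpoint file {len(end)}"
        )
    names = [str(c) for c in cov.columns]
    unknown = [m for m in mandatory if m not in names]
    if unknown:
        raise ValueError(f"mandatory covariates not found in covariate file: {unknown}")

    raw_strata = end["stratum"].tolist()
    order: list[object] = []
    if focus is not None:
        if focus not in raw_strata:
            raise ValueError(f"focus stratum {focus!r} not present in endpoint file")
        order.append(focus)
    for lab in raw_strata:
        if lab not in order:
            order.append(lab)
    code = {lab: i + 1 for i, lab in enumerate(order)}
    strata = np.array([code[lab] for lab in raw_strata], dtype=int)

    X = cov.to_numpy(dtype=float)
    mmask = np.array([c in mandatory for c in names])
    if log_transform:
        pen = ~mmask
        X[:, pen] = np.log(X[:, pen] + log_offset)
    return SurvivalDataset(
        times=end["time"].to_numpy(dtype=float),
        status=end["status"].to_numpy(),
        strata=strata,
        covariates=X,
        covariate_names=names,
        mandatory_mask=mmask,
        stratum_labels={v: k for k, v in code.items()},
    )


def write_dataset(data: SurvivalDataset, covariate_path, endpoint_path) -> None:
    """Write the dataset back to delimited files (inverse of :func:`read_dataset`)."""
    fmt = lambda x: repr(float(x))  # shortest round-trippable decimal form
    cov = pd.DataFrame(data.covariates, columns=data.covariate_names)
    cov.to_csv(
        covariate_path, sep=_sep_for(covariate_path), index=False, na_rep="NA", float_format=fmt
    )
    labels = data.stratum_labels or {}
    end = pd.DataFrame(
        {
            "time": data.times,
            "status": data.status,
            "stratum": [labels.get(int(s), int(s)) for s in data.strata],
        }
    )
    end.to_csv(
        endpoint_path, sep=_sep_for(endpoint_path), index=False, na_rep="NA", float_format=fmt
    )


def filter_all_missing(data: SurvivalDataset) -> tuple[SurvivalDataset, list[str]]:
    """Drop covariates whose values are missing for *all* observations.

    Returns the filtered dataset and the removed names.  Partially missing
    covariates are kept (and rejected later at fit time); only columns with
    no observed value at all are removable without an imputation model.
    """
    all_missing = np.isnan(data.covariates).all(axis=0)
    if not all_missing.any():
        return data, []
    removed = [data.covariate_names[j] for j in np.flatnonzero(all_missing)]
    removed_mand = [n for n in removed if n in data.mandatory_names]
    if removed_mand:
        raise ValueError(f"mandatory covariates are entirely missing: {removed_mand}")
    return data.select_covariates(~all_missing), removed


@dataclass
class StandardizationRecord:
    """Per-covariate centering/scaling applied by :func:`standardize`.

    ``applied`` is False for mandatory covariates (never touched) and for
    zero-variance covariates (excluded from standardization with a warning).
    ``invert_coefficients`` maps coefficients estimated on the standardized
    scale back to the original covariate scale.
    """

    center: np.ndarray
    scale: np.ndarray
    applied: np.ndarray

    def invert_coefficients(self, beta_std: np.ndarray) -> np.ndarray:
        beta = np.asarray(beta_std, dtype=float).copy()
        beta[self.applied] = beta[self.applied] / self.scale[self.applied]
        return beta


def standardize(data: SurvivalDataset) -> tuple[SurvivalDataset, StandardizationRecord]:
    """Center/scale penalized covariates to mean 0, sample sd 1 (ddof=1).

    Mandatory covariates are left untouched.  Zero-variance penalized
    covariates cannot be scaled; they are flagged ``applied=False`` with a
    warning and should be excluded from candidate sets.
    """
    X = data.covariates.copy()
    center = np.zeros(data.p)
    scale = np.ones(data.p)
    applied = np.zeros(data.p, dtype=bool)
    for j in range(data.p):
        if data.mandatory_mask[j]:
            continue
        col = X[:, j]
        if np.isnan(col).any():
            raise ValueError(
                f"covariate {data.covariate_names[j]!r} has missing values; "
                "standardize requires complete penalized covariates"
            )
        m = col.mean()
        s = col.std(ddof=1)
        if not np.isfinite(s) or s <= 0:
            warnings.warn(
                f"covariate {data.covariate_names[j]!r} has zero variance; left unstandardized",
                UserWarning,
                stacklevel=2,
            )
            continue
        X[:, j] = (col - m) / s
        center[j], scale[j], applied[j] = m, s, True
    new = replace(data, covariates=X)
    return new, StandardizationRecord(center=center, scale=scale, applied=applied)
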