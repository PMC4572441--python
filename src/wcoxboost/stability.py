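"""Resampling inclusion frequencies (RIFs) across a grid of down-weights.

The stability of variable selection under a given down-weight w is
measured by the proportion of resampling datasets in which a covariate
receives a nonzero coefficient from the boosting fit.  Resampling draws
``round(0.632 n)`` observations without replacement (stratified, so
stratum proportions are preserved up to rounding); the same subsample
sequence is reused for every weight in the grid (a paired design, so
weight effects are not confounded with resampling noise).  For simulation
scenarios, fresh datasets can be generated per replicate instead of
resampling one dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from .boosting import BoostingConfig, fit_boosting
from .cv import cv_select_steps
from .datasets import SurvivalDataset
from .simulate import SimulationScenario, generate
from .weights import WeightScheme

__all__ = ["WeightGrid", "RIFMatrix", "draw_subsample", "compute_rifs", "simulate_ifs"]

DEFAULT_WEIGHTS = (0.0, 0.001, 0.01, 0.05, 0.1, 0.25, 0.5, 0.7, 0.9, 0.99)


@dataclass(frozen=True)
class WeightGrid:
    """Ordered grid of down-weights in [0, 1]."""

    weights: tuple[float, ...] = DEFAULT_WEIGHTS

    def __post_init__(self):
        w = np.asarray(self.weights, float)
        if w.size == 0 or np.any((w < 0) | (w > 1)) or np.any(np.diff(w) <= 0):
            raise ValueError("weights must be strictly increasing values in [0, 1]")

    def __len__(self):
        return len(self.weights)

    def __iter__(self):
        return iter(self.weights)


@dataclass
class RIFMatrix:
    """Covariates x weights matrix of (resampling) inclusion frequencies.

    Entries are multiples of 1/n_resamples in [0, 1].  Rows of mandatory
    covariates are NaN (they are always in the model by construction and
    carry no selection information).  ``subsamples`` keeps the per-resample
    index sets when requested, as an audit trail of the paired design.
    """

    rif: np.ndarray
    covariate_names: list[str]
    weights: tuple[float, ...]
    n_resamples: int
    fraction: float | None
    seed: int | None
    kind: str = "resample"
    subsamples: list[np.ndarray] | None = field(default=None, repr=False)
    selected_steps: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rif, index=self.covariate_names, columns=list(self.weights))

    def write(self, path, metadata_path=None) -> None:
        sep = "," if str(path).endswith(".csv") else "\t"
        df = self.to_frame()
        df.index.name = "covariate"
        df.to_csv(path, sep=sep)
        meta = {
            "kind": self.kind,
            "n_resamples": int(self.n_resamples),
            "fraction": self.fraction,
            "seed": self.seed,
            "weights": [float(w) for w in self.weights],
        }
        mpath = metadata_path or (str(path) + ".meta.yaml")
        Path(mpath).write_text(yaml.safe_dump(meta, sort_keys=False))


def draw_subsample(data: SurvivalDataset, fraction: float = 0.632, seed=None) -> np.ndarray:
    """Draw round(fraction * n_s) indices per stratum, without replacement.

    Redraws (up to 50 times) until every stratum contributes at least one
    event, then errors if that is infeasible.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    sizes = {}
    for s in data.stratum_ids:
        idx = np.flatnonzero(data.strata == s)
        k = int(np.rint(fraction * idx.size))
        sizes[int(s)] = (idx, k)
    total = sum(k for _, k in sizes.values())
    if total < 2:
        raise ValueError(f"subsample of size {total} is too small")
    infeasible = [s for s, (idx, k) in sizes.items() if k > 0 and data.status[idx].sum() < 1]
    if infeasible:
        raise ValueError(f"strata {infeasible} have no events; subsampling infeasible")
    for _ in range(50):
        parts = [rng.choice(idx, size=k, replace=False) for idx, k in sizes.values()]
        out = np.sort(np.concatenate(parts))
        ok = all(
            data.status[part].sum() >= 1 for part, (_, k) in zip(parts, sizes.values()) if k > 0
        )
        if ok:
            return out
    raise ValueError("could not draw a subsample with events in every stratum (50 attempts)")


def _fit_inclusion(sub: SurvivalDataset, cfg: BoostingConfig, cv, cv_folds, max_steps, seed):
    """Fit one resample x weight cell; return (inclusion vector, steps used)."""
    if cv:
        res = cv_select_steps(sub, cfg, K=cv_folds, M_max=max_steps, seed=seed)
        steps = res.best_m
    else:
        steps = cfg.steps
    fit = fit_boosting(
        sub,
        BoostingConfig(
            steps=steps,
            penalty=cfg.penalty,
            shrinkage=cfg.shrinkage,
            scheme=cfg.scheme,
            standardize=cfg.standardize,
            penalized_selection=cfg.penalized_selection,
        ),
    )
    return fit.coef != 0, steps


def _cell_configs(grid, focus_stratum, shrinkage, penalty, standardize, penalized_selection, steps):
    return [
        BoostingConfig(
            steps=steps,
            penalty=penalty,
            shrinkage=shrinkage,
            scheme=WeightScheme(w=w, focus_stratum=focus_stratum),
            standardize=standardize,
            penalized_selection=penalized_selection,
        )
        for w in grid
    ]


def _one_resample(data, r_seed, grid_cfgs, fraction, cv, cv_folds, max_steps):
    sub_seq, *cv_seqs = r_seed.spawn(len(grid_cfgs) + 1)
    idx = draw_subsample(data, fraction, seed=sub_seq)
    sub = data.subset(idx)
    inc = np.zeros((data.p, len(grid_cfgs)), dtype=bool)
    steps_used = np.zeros(len(grid_cfgs), dtype=int)
    for g, cfg in enumerate(grid_cfgs):
        inc[:, g], steps_used[g] = _fit_inclusion(sub, cfg, cv, cv_folds, max_steps, cv_seqs[g])
    return idx, inc, steps_used


def compute_rifs(
    data: SurvivalDataset,
    grid: WeightGrid | None = None,
    n_resamples: int = 100,
    cv: bool = True,
    fixed_steps: int | None = None,
    fraction: float = 0.632,
    seed: int | None = None,
    focus_stratum: int = 1,
    shrinkage: float = 0.02,
    penalty="auto",
    standardize: bool = True,
    penalized_selection: bool = True,
    cv_folds: int = 10,
    max_steps: int = 100,
    store_audit: bool = False,
    n_jobs: int = 1,
) -> RIFMatrix:
    """Resampling inclusion frequencies over the weight grid.

    For each of ``n_resamples`` stratified 0.632-subsamples and each weight,
    a boosting model is fit on the subsample (step count chosen by K-fold
    cross-validation inside the subsample when ``cv=True``, or fixed at
    ``fixed_steps``); a covariate counts as included when its final
    coefficient is nonzero.  Subsamples are identical across weights.
    """
    grid = grid or WeightGrid()
    if not cv and fixed_steps is None:
        raise ValueError("fixed_steps is required when cv=False")
    steps = max_steps if cv else int(fixed_steps)
    cfgs = _cell_configs(
        grid, focus_stratum, shrinkage, penalty, standardize, penalized_selection, steps
    )
    root = np.random.SeedSequence(seed)
    r_seeds = root.spawn(n_resamples)
    runner = Parallel(n_jobs=n_jobs) if n_jobs != 1 else None
    job = delayed(_one_resample)
    args = [(data, rs, cfgs, fraction, cv, cv_folds, max_steps) for rs in r_seeds]
    results = runner(job(*a) for a in args) if runner else [_one_resample(*a) for a in args]

    counts = np.zeros((data.p, len(grid)))
    subsamples = []
    steps_used = np.zeros((n_resamples, len(grid)), dtype=int)
    for r, (idx, inc, st) in enumerate(results):
        counts += inc
        steps_used[r] = st
        if store_audit:
            subsamples.append(idx)
    rif = counts / n_resamples
    rif[data.mandatory_mask] = np.nan
    return RIFMatrix(
        rif=rif,
        covariate_names=list(data.covariate_names),
        weights=tuple(grid),
        n_resamples=n_resamples,
        fraction=fraction,
        seed=seed,
        kind="resample",
        subsamples=subsamples if store_audit else None,
        selected_steps=steps_used,
    )


def simulate_ifs(
    scenario: SimulationScenario,
    grid: WeightGrid | None = None,
    n_replicates: int = 20,
    cv: bool = False,
    fixed_steps: int | None = None,
    seed: int | None = None,
    focus_stratum: int = 1,
    shrinkage: float = 0.02,
    penalty="auto",
    standardize: bool = True,
    penalized_selection: bool = True,
    cv_folds: int = 10,
    max_steps: int = 100,
    n_jobs: int = 1,
) -> RIFMatrix:
    """Inclusion frequencies over freshly generated replicate datasets.

    As :func:`compute_rifs`, but each replicate is a new draw from the
    simulation scenario rather than a subsample of one dataset.
    """
    grid = grid or WeightGrid()
    if not cv and fixed_steps is None:
        raise ValueError("fixed_steps is required when cv=False")
    steps = max_steps if cv else int(fixed_steps)
    cfgs = _cell_configs(
        grid, focus_stratum, shrinkage, penalty, standardize, penalized_selection, steps
    )
    root = np.random.SeedSequence(seed)
    rep_seeds = root.spawn(n_replicates)

    def one_rep(rep_seed):
        gen_seq, *cv_seqs = rep_seed.spawn(len(cfgs) + 1)
        ds = generate(scenario, seed=gen_seq)
        inc = np.zeros((scenario.p, len(cfgs)), dtype=bool)
        for g, cfg in enumerate(cfgs):
            inc[:, g], _ = _fit_inclusion(ds, cfg, cv, cv_folds, max_steps, cv_seqs[g])
        return inc

    if n_jobs != 1:
        results = Parallel(n_jobs=n_jobs)(delayed(one_rep)(rs) for rs in rep_seeds)
    else:
        results = [one_rep(rs) for rs in rep_seeds]
    counts = np.sum(results, axis=0, dtype=float)
    names = [f"Cov{j + 1}" for j in range(scenario.p)]
    return RIFMatrix(
        rif=counts / n_replicates,
        covariate_names=names,
        weights=tuple(grid),
        n_resamples=n_replicates,
        fraction=None,
        seed=seed,
        kind="simulate",
    )
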