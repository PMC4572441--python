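"""Stability visualizations: trajectories and the weight-frequency map.

Both plots display resampling inclusion frequencies (RIFs) as a function
of the down-weight grid.  The *stability trajectories* show a small set of
stably selected covariates (RIF above a threshold for at least one
weight): covariates on the x-axis, RIF on the y-axis, one point series per
weight in graded gray (lighter = smaller weight, i.e. less information
from the other strata), with each covariate's points connected by a dotted
line; optionally the weight with the best mean RIF over the displayed
covariates is marked with a triangle.  The *weight-frequency map* is a
heat map of RIFs (covariates x weights) for a larger covariate set, with
rows ordered by hierarchical clustering under the correlation distance
1 - Pearson(rif rows across weights); lighter gray = more stable selection.

Every figure returns its backing table (or row order) so the displayed
numbers are testable without touching pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .stability import RIFMatrix

__all__ = ["TrajectoryFilter", "MapSpec", "stabtrajec", "weightfreqmap", "plot_coef_paths"]


@dataclass(frozen=True)
class TrajectoryFilter:
    """Keep covariates whose RIF reaches ``threshold`` at >= 1 grid weight."""

    threshold: float = 0.1

    def __post_init__(self):
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must lie in [0, 1]")


@dataclass(frozen=True)
class MapSpec:
    """Weight-frequency map settings: RIF threshold and linkage method."""

    threshold: float = 0.05
    linkage_method: str = "average"

    def __post_init__(self):
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must lie in [0, 1]")


def _filtered_table(rifs: RIFMatrix, threshold: float) -> pd.DataFrame:
    df = rifs.to_frame().dropna(how="all")  # mandatory covariates carry NaN rows
    keep = (df >= threshold).any(axis=1)
    return df.loc[keep]


def _weight_grays(k: int) -> list:
    # lighter gray = smaller weight (less information from the other strata)
    shades = np.linspace(0.8, 0.0, k)
    return [str(s) for s in shades]


def best_weight(table: pd.DataFrame) -> float:
    """Weight maximizing the mean RIF over the displayed covariates (ties: smaller)."""
    means = table.mean(axis=0).to_numpy()
    return float(table.columns[int(np.argmax(means))])


def stabtrajec(
    rifs: RIFMatrix,
    filter: TrajectoryFilter | None = None,
    mark_best: bool = False,
    ax=None,
):
    """Stability trajectory plot; returns (figure, backing table).

    Raises a ValueError when no covariate passes the RIF filter.
    """
    filter = filter or TrajectoryFilter()
    table = _filtered_table(rifs, filter.threshold)
    if table.empty:
        raise ValueError(
            f"no covariate reaches RIF >= {filter.threshold} at any weight; "
            "lower the threshold or increase resampling"
        )
    if ax is None:
        fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(table)), 4))
    else:
        fig = ax.figure
    x = np.arange(len(table))
    grays = _weight_grays(len(table.columns))
    for g, w in enumerate(table.columns):
        ax.plot(x, table[w].to_numpy(), "o", color=grays[g], label=f"w={w:g}", markersize=5)
    for i in range(len(table)):
        ax.plot(x[[i] * len(table.columns)], table.iloc[i].to_numpy(), ":", color="0.6", lw=0.8)
    if mark_best:
        bw = best_weight(table)
        g = list(table.columns).index(bw)
        ax.plot(x, table[bw].to_numpy(), "^", color=grays[g], markersize=9)
        ax.set_title(f"best mean-RIF weight: {bw:g}")
    ax.set_xticks(x)
    ax.set_xticklabels(table.index, rotation=90)
    ax.set_ylabel("resampling inclusion frequency")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    return fig, table


def correlation_row_order(table: pd.DataFrame, method: str = "average") -> list[str]:
    """Row order from hierarchical clustering under 1 - Pearson correlation.

    Rows are sorted by name before clustering so the result is invariant
    to input row order.  Constant rows (undefined correlation) are given
    the maximal distance 2 to every other row.
    """
    table = table.sort_index()
    M = table.to_numpy(dtype=float)
    if M.shape[0] < 2:
        raise ValueError("need at least two covariates to cluster")
    sd = M.std(axis=1)
    D = np.full((M.shape[0], M.shape[0]), 2.0)
    ok = sd > 0
    if ok.sum() >= 2:
        corr = np.corrcoef(M[ok])
        D[np.ix_(ok, ok)] = 1.0 - corr
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    Z = linkage(squareform(D, checks=False), method=method)
    return [table.index[i] for i in leaves_list(Z)]


def weightfreqmap(rifs: RIFMatrix, spec: MapSpec | None = None, ax=None):
    """Weight-frequency heat map; returns (figure, clustered row order).

    Grayscale maps RIF 0 -> black and 1 -> white, so lighter shades mark
    more stable selection.
    """
    spec = spec or MapSpec()
    table = _filtered_table(rifs, spec.threshold)
    if len(table) < 2:
        raise ValueError(
            f"fewer than two covariates reach RIF >= {spec.threshold}; cannot cluster"
        )
    order = correlation_row_order(table, method=spec.linkage_method)
    table = table.loc[order]
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, max(3, 0.25 * len(table))))
    else:
        fig = ax.figure
    im = ax.imshow(
        table.to_numpy(), aspect="auto", cmap="gray", vmin=0.0, vmax=1.0,
        interpolation="nearest",
    )
    ax.set_xticks(np.arange(len(table.columns)))
    ax.set_xticklabels([f"{w:g}" for w in table.columns], rotation=90)
    ax.set_yticks(np.arange(len(table)))
    ax.set_yticklabels(table.index, fontsize=7)
    ax.set_xlabel("weight")
    fig.colorbar(im, ax=ax, label="RIF")
    fig.tight_layout()
    return fig, order


def plot_coef_paths(fit, top: int = 15, ax=None):
    """Coefficient paths over boosting steps for the most-updated covariates."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 4))
    else:
        fig = ax.figure
    path = fit.coef_path
    final = np.abs(path[-1])
    show = np.argsort(final)[::-1][:top]
    show = [j for j in show if final[j] > 0]
    steps = np.arange(path.shape[0])
    for j in show:
        ax.plot(steps, path[:, j], label=fit.covariate_names[j], lw=1)
    ax.set_xlabel("boosting step")
    ax.set_ylabel("coefficient (original scale)")
    if show:
        ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    return fig, [fit.covariate_names[j] for j in show]
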