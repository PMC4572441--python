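"""Synthetic two-subgroup survival data with subgroup-specific covariate effects.

The default scenario mirrors a two-stratum study: n = 250 individuals,
p = 1000 uncorrelated standard-normal covariates, subgroup membership
drawn Bernoulli(0.5), and exponential survival and censoring times with a
common scale of 1/20 (rate 20).  Ten covariates carry effects on the
log-hazard scale: covariates 1-3 have effect 1 in subgroup 1 and 0 in
subgroup 2, covariates 4-7 have effect 0.5 in both, and covariates 8-10
have effect 0 in subgroup 1 and 1 in subgroup 2 — so the mean effect over
subgroups is 0.5 for all ten, and a global analysis cannot tell the three
groups apart.  All remaining covariates have no effect.

Event times follow the proportional-hazards inversion construction:
T = E / (rate * exp(x' beta)) with E a unit exponential draw, so the
baseline is exponential with the stated scale and covariates act
multiplicatively on the hazard.  With equal survival and censoring scales
and no effects, about half the observations are censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datasets import SurvivalDataset, write_dataset

__all__ = ["SimulationScenario", "generate", "make_fixture", "PRESETS"]

DEFAULT_EFFECTS: tuple[tuple[int, float, float], ...] = tuple(
    [(i, 1.0, 0.0) for i in (1, 2, 3)]
    + [(i, 0.5, 0.5) for i in (4, 5, 6, 7)]
    + [(i, 0.0, 1.0) for i in (8, 9, 10)]
)


@dataclass(frozen=True)
class SimulationScenario:
    """Parameters of the two-subgroup simulation.

    ``effects`` lists (covariate number 1..p, effect in subgroup 1, effect
    in subgroup 2) on the log-hazard scale; unspecified covariates have no
    effect.  ``survival_scale`` and ``censoring_scale`` are exponential
    scale (mean) parameters; the baseline hazard rate is their inverse.
    """

    n: int = 250
    p: int = 1000
    subgroup_prob: float = 0.5
    survival_scale: float = 1.0 / 20.0
    censoring_scale: float = 1.0 / 20.0
    effects: tuple[tuple[int, float, float], ...] = DEFAULT_EFFECTS
    seed: int | None = None

    def __post_init__(self):
        idx = [e[0] for e in self.effects]
        if len(set(idx)) != len(idx):
            raise ValueError("effect covariate indices must be distinct")
        if idx and (min(idx) < 1 or max(idx) > self.p):
            raise ValueError("effect covariate indices must lie in 1..p")
        if not (0.0 <= self.subgroup_prob <= 1.0):
            raise ValueError("subgroup probability must lie in [0, 1]")
        if self.survival_scale <= 0 or self.censoring_scale <= 0:
            raise ValueError("scale parameters must be positive")

    def beta_matrix(self) -> np.ndarray:
        """(p, 2) matrix of log-hazard effects per subgroup."""
        B = np.zeros((self.p, 2))
        for i, b1, b2 in self.effects:
            B[i - 1] = (b1, b2)
        return B


def generate(scenario: SimulationScenario, seed=None) -> SurvivalDataset:
    """Draw one dataset from the scenario (``seed`` overrides ``scenario.seed``)."""
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n, p = scenario.n, scenario.p
    groups = rng.binomial(1, scenario.subgroup_prob, size=n) + 1
    X = rng.standard_normal((n, p))
    B = scenario.beta_matrix()
    eta = np.einsum("ij,ij->i", X, B[:, groups - 1].T)
    rate = np.exp(eta) / scenario.survival_scale
    T = rng.exponential(1.0, size=n) / rate
    C = rng.exponential(scenario.censoring_scale, size=n)
    times = np.minimum(T, C)
    status = (T <= C).astype(int)
    return SurvivalDataset(
        times=times,
        status=status,
        strata=groups,
        covariates=X,
        covariate_names=[f"Cov{j + 1}" for j in range(p)],
    )


_TINY_EFFECTS = tuple(
    [(1, 1.0, 0.0), (2, 1.0, 0.0), (3, 0.5, 0.5), (4, 0.5, 0.5), (5, 0.0, 1.0), (6, 0.0, 1.0)]
)

PRESETS: dict[str, SimulationScenario] = {
    "default": SimulationScenario(),
    "null": SimulationScenario(effects=()),
    "tiny": SimulationScenario(n=60, p=30, effects=_TINY_EFFECTS),
}


def make_fixture(name: str, covariate_path, endpoint_path, seed: int = 0) -> SurvivalDataset:
    """Write a preset scenario dataset to covariate/endpoint files.

    Presets: ``default`` (n=250, p=1000, the default effect pattern),
    ``null`` (same dimensions, no effects), ``tiny`` (n=60, p=30, scaled
    effect pattern; loads in well under a second).
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    data = generate(PRESETS[name], seed=seed)
    Path(covariate_path).parent.mkdir(parents=True, exist_ok=True)
    Path(endpoint_path).parent.mkdir(parents=True, exist_ok=True)
    write_dataset(data, covariate_path, endpoint_path)
    return data
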