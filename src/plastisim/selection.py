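"""Gaussian viability selection against the local selection-stage optimum."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environment import DemeEnvironment
from .errors import ConfigurationError
from .genome import Population


@dataclass(frozen=True)
class SelectionSpec:
    """Strength of stabilizing selection; larger sigma means weaker selection."""

    sigma: float = 2.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ConfigurationError(f"sigma must be > 0, got {self.sigma}")


def fitness(phenotype, optimum, sigma: float):
    """Survival probability: W = exp(-(T - theta)^2 / (2 sigma^2)).

    Vectorized over phenotype/optimum; W lies in (0, 1] for finite inputs.
    """
    if not sigma > 0:
        raise ConfigurationError(f"sigma must be > 0, got {sigma}")
    dev = np.asarray(phenotype, dtype=float) - np.asarray(optimum, dtype=float)
    return np.exp(-(dev**2) / (2.0 * sigma**2))


def apply_selection(
    population: Population,
    env: DemeEnvironment,
    spec: SelectionSpec,
    rng: np.random.Generator,
) -> Population:
    """Independent viability selection in each individual's current deme.

    An individual dies if its fitness is below a Uniform[0, 1] draw, so it
    survives with probability W.
    """
    if population.n == 0:
        return population
    w = fitness(population.phenotype, env.sel_env[population.deme - 1], spec.sigma)
    alive = rng.random(population.n) <= w
    return population.subset(alive)
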