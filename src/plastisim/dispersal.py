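"""Stepping-stone and island movement between demes.

Stepping-stone moves round a zero-mean Gaussian displacement to the nearest
integer number of demes, so the probability of moving at all and the distance
moved are governed by a single kernel SD; island moves send a migrant to a
uniformly chosen other deme.  Dispersal is cost-free and never alters the
(already fixed) phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri

from .errors import ConfigurationError
from .genome import Population

MODES = ("stepping_stone", "island")


def rate_to_kernel_sd(rate: float) -> float:
    """Gaussian kernel SD whose rounded draws leave the deme at ``rate``.

    Solves P(|round(Normal(0, s))| >= 1) = P(|g| >= 0.5) = rate in closed form
    via the normal quantile function.  rate = 1 has no finite solution.
    """
    if not 0 <= rate < 1:
        raise ConfigurationError(
            f"stepping-stone dispersal rate must be in [0, 1), got {rate}"
        )
    if rate == 0:
        return 0.0
    return 0.5 / ndtri(1.0 - rate / 2.0)


@dataclass(frozen=True)
class DispersalSpec:
    """Movement mode and per-individual probability of leaving the deme."""

    mode: str = "stepping_stone"
    rate: float = 0.0
    kernel_sd: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not 0 <= self.rate <= 1:
            raise ConfigurationError(f"rate must be in [0, 1], got {self.rate}")
        if self.kernel_sd is None:
            sd = rate_to_kernel_sd(self.rate) if self.mode == "stepping_stone" else 0.0
            object.__setattr__(self, "kernel_sd", sd)
        if self.kernel_sd < 0:
            raise ConfigurationError(f"kernel_sd must be >= 0, got {self.kernel_sd}")


def stepping_stone_move(deme, spec: DispersalSpec, n_demes: int, rng: np.random.Generator):
    """Destination deme(s) under the Gaussian stepping-stone kernel.

    Displacements beyond the gradient ends are clamped to the terminal demes.
    ``deme`` may be a scalar or an array of current 1-based deme indices.
    """
    deme = np.asarray(deme)
    if spec.kernel_sd == 0:
        return deme if deme.shape else int(deme)
    shift = np.rint(rng.normal(0.0, spec.kernel_sd, size=deme.shape)).astype(np.int64)
    dest = np.clip(deme + shift, 1, n_demes)
    return dest if dest.shape else int(dest)


def island_move(deme, spec: DispersalSpec, n_demes: int, rng: np.random.Generator):
    """Destination deme(s) under island migration.

    With probability ``rate`` an individual moves, landing on any of the other
    ``n_demes - 1`` demes with equal probability; otherwise it stays put.
    """
    deme = np.asarray(deme)
    if spec.rate == 0:
        return deme if deme.shape else int(deme)
    if n_demes < 2:
        raise ConfigurationError("island migration needs at least 2 demes")
    moves = rng.random(size=deme.shape) < spec.rate
    # uniform over the other demes: offset 1..D-1 around a ring, then unwrap
    offset = rng.integers(1, n_demes, size=deme.shape)
    dest = np.where(moves, (deme - 1 + offset) % n_demes + 1, deme)
    return dest if dest.shape else int(dest)


def disperse_population(
    population: Population, spec: DispersalSpec, n_demes: int, rng: np.random.Generator
) -> Population:
    """Move every individual once; total count is conserved exactly."""
    if population.n == 0 or spec.rate == 0:
        return population
    mover = stepping_stone_move if spec.mode == "stepping_stone" else island_move
    population.deme = mover(population.deme, spec, n_demes, rng)
    return population
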