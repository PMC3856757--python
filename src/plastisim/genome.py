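"""Genotypes, phenotype determination, inheritance, and initialization.

A genotype is an array of shape ``(10, 2)``: ten diploid loci with two allelic
values each.  Loci 0-4 are nonplastic, loci 5-9 are plastic.  The phenotype is

    T = sum(nonplastic alleles) + multiplier * sum(plastic alleles)

with no random component; it is fixed once, at development.  Populations are
stored as flat arrays over individuals for vectorized generation updates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .environment import DemeEnvironment, GradientSpec, multipliers
from .errors import ConfigurationError

N_LOCI = 10
NONPLASTIC = slice(0, 5)
PLASTIC = slice(5, 10)
#: Equally likely allelic values in the founding generation.
INIT_VALUES = (-2, -1, 0, 1, 2)

#: A genotype is any float array of shape (..., 10, 2).
Genotype = np.ndarray


@dataclass
class Individual:
    """Single-individual view used by the per-individual operations."""

    genotype: Genotype
    natal_deme: int
    current_deme: int
    phenotype: Optional[float] = None
    alive: bool = True


@dataclass
class Population:
    """Column-oriented container of all living individuals.

    ``alleles`` has shape ``(n, 10, 2)``; ``deme`` and ``natal`` are 1-based
    deme labels; ``phenotype`` is NaN until development.
    """

    alleles: np.ndarray
    deme: np.ndarray
    natal: np.ndarray
    phenotype: np.ndarray

    def __len__(self) -> int:
        return self.alleles.shape[0]

    @property
    def n(self) -> int:
        return self.alleles.shape[0]

    @property
    def nonplastic_sum(self) -> np.ndarray:
        return self.alleles[:, NONPLASTIC, :].sum(axis=(1, 2))

    @property
    def plastic_sum(self) -> np.ndarray:
        return self.alleles[:, PLASTIC, :].sum(axis=(1, 2))

    def subset(self, mask: np.ndarray) -> "Population":
        return Population(
            self.alleles[mask], self.deme[mask], self.natal[mask], self.phenotype[mask]
        )

    @classmethod
    def empty(cls) -> "Population":
        return cls(
            np.empty((0, N_LOCI, 2)),
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
            np.empty(0),
        )


def develop(genotype: Genotype, multiplier) -> np.ndarray:
    """Phenotype of one or many genotypes at the given expression multiplier.

    Deterministic and linear in the multiplier.
    """
    g = np.asarray(genotype, dtype=float)
    n_sum = g[..., NONPLASTIC, :].sum(axis=(-2, -1))
    p_sum = g[..., PLASTIC, :].sum(axis=(-2, -1))
    return n_sum + np.asarray(multiplier) * p_sum


def develop_population(
    population: Population, env: DemeEnvironment, gradient: GradientSpec
) -> Population:
    """Fix each individual's phenotype using its current deme's multiplier."""
    m = multipliers(env, gradient)
    population.phenotype = (
        population.nonplastic_sum + m[population.deme - 1] * population.plastic_sum
    )
    return population


def mate_genotypes(
    alleles_a: np.ndarray, alleles_b: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Offspring genotypes from paired parents, free recombination.

    For every locus one of the two allelic values is drawn from each parent
    independently.  Inputs have shape ``(m, 10, 2)``.
    """
    m = alleles_a.shape[0]
    pick = rng.random((2, m, N_LOCI)) < 0.5
    child = np.empty((m, N_LOCI, 2))
    child[:, :, 0] = np.where(pick[0], alleles_a[:, :, 0], alleles_a[:, :, 1])
    child[:, :, 1] = np.where(pick[1], alleles_b[:, :, 0], alleles_b[:, :, 1])
    return child


def mutate_alleles(
    alleles: np.ndarray,
    mutation_rate: float,
    mutation_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Infinite-alleles mutation, in place.

    Each allelic value independently gains a Normal(0, mutation_sd) deviate
    with probability ``mutation_rate``.
    """
    if mutation_rate == 0:
        return alleles
    hit = rng.random(alleles.shape) < mutation_rate
    n_hit = int(hit.sum())
    if n_hit:
        alleles[hit] += rng.normal(0.0, mutation_sd, size=n_hit)
    return alleles


def make_offspring(
    parent_a: Individual,
    parent_b: Individual,
    mutation_rate: float,
    mutation_sd: float,
    rng: np.random.Generator,
) -> Genotype:
    """One offspring genotype from two parents (inheritance then mutation)."""
    if not (0 <= mutation_rate <= 1):
        raise ConfigurationError(f"mutation_rate must be in [0, 1], got {mutation_rate}")
    if mutation_sd < 0:
        raise ConfigurationError(f"mutation_sd must be >= 0, got {mutation_sd}")
    ga = np.asarray(parent_a.genotype, dtype=float)[None]
    gb = np.asarray(parent_b.genotype, dtype=float)[None]
    child = mate_genotypes(ga, gb, rng)
    mutate_alleles(child, mutation_rate, mutation_sd, rng)
    return child[0]


def init_population(
    gradient: GradientSpec, deme_size: int, rng: np.random.Generator
) -> Population:
    """Founding generation: ``deme_size`` newborns per deme, discrete alleles.

    Every allelic value is drawn uniformly from ``INIT_VALUES``; mutation makes
    values continuous from the next generation on.
    """
    if deme_size < 1:
        raise ConfigurationError(f"deme_size must be >= 1, got {deme_size}")
    d = gradient.n_demes
    n = d * deme_size
    alleles = rng.choice(np.asarray(INIT_VALUES, dtype=float), size=(n, N_LOCI, 2))
    deme = np.repeat(np.arange(1, d + 1, dtype=np.int64), deme_size)
    return Population(alleles, deme, deme.copy(), np.full(n, np.nan))
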