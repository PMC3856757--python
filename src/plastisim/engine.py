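"""Generational life cycle, soft-selection reproduction, replicate protocol.

Each generation runs: temporal environment update, development (phenotypes
fixed in the natal deme), then either dispersal-selection ("move first") or
selection-dispersal ("select first"), then reproduction.  Reproduction is
soft-selective: every deme holding at least one survivor is refilled to its
carrying capacity by random mating with replacement (self-pairing allowed, so
a lone survivor still refills its deme).  A run ends early, flagged extinct,
if no individual anywhere survives to reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np

from .dispersal import DispersalSpec, disperse_population
from .environment import (
    DemeEnvironment,
    GradientSpec,
    TemporalSpec,
    step_temporal,
)
from .errors import ConfigurationError
from .genome import (
    Population,
    develop_population,
    init_population,
    mate_genotypes,
    mutate_alleles,
)
from .metrics import mean_plasticity, per_deme_means
from .selection import SelectionSpec, apply_selection

if TYPE_CHECKING:  # pragma: no cover
    from .config import RunConfig

ORDERS = ("select_first", "move_first")


@dataclass(frozen=True)
class LifeHistorySpec:
    """Life-cycle ordering and run length."""

    order: str = "select_first"
    n_generations: int = 10_000
    deme_capacity: int = 100
    single_deme: bool = False

    def __post_init__(self) -> None:
        if self.order not in ORDERS:
            raise ConfigurationError(f"order must be one of {ORDERS}, got {self.order!r}")
        if self.n_generations < 1:
            raise ConfigurationError("n_generations must be >= 1")
        if self.deme_capacity < 1:
            raise ConfigurationError("deme_capacity must be >= 1")


@dataclass(frozen=True)
class ModelSpecs:
    """Bundle of all module specifications driving one simulation."""

    gradient: GradientSpec
    temporal: TemporalSpec
    selection: SelectionSpec
    dispersal: DispersalSpec
    life: LifeHistorySpec
    mutation_rate: float = 0.1
    mutation_sd: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate <= 1:
            raise ConfigurationError("mutation_rate must be in [0, 1]")
        if self.mutation_sd < 0:
            raise ConfigurationError("mutation_sd must be >= 0")


@dataclass
class RunResult:
    """Outcome of one realization."""

    plasticity_trajectory: np.ndarray
    pop_size_trajectory: np.ndarray
    end_deme_plasticity: np.ndarray
    end_deme_nonplastic: np.ndarray
    end_deme_phenotype: np.ndarray
    extinct: bool
    generations_completed: int
    seed: int
    replicate: int = 0


def reproduce(
    population: Population,
    capacity: int,
    mutation_rate: float,
    mutation_sd: float,
    rng: np.random.Generator,
) -> Population:
    """Soft-selection reproduction across all demes at once.

    For every occupied deme, ``capacity`` offspring are produced by drawing
    parent pairs uniformly with replacement from that deme's survivors.  Empty
    demes produce nothing (recolonizable only by later dispersal).
    """
    if population.n == 0:
        return Population.empty()
    order = np.argsort(population.deme, kind="stable")
    occupied, counts = np.unique(population.deme, return_counts=True)
    offsets = np.concatenate(([0], np.cumsum(counts[:-1])))
    k = len(occupied)
    grp = np.repeat(np.arange(k), capacity)
    pa = order[offsets[grp] + rng.integers(0, counts[grp])]
    pb = order[offsets[grp] + rng.integers(0, counts[grp])]
    child = mate_genotypes(population.alleles[pa], population.alleles[pb], rng)
    mutate_alleles(child, mutation_rate, mutation_sd, rng)
    deme = np.repeat(occupied, capacity).astype(np.int64)
    return Population(child, deme, deme.copy(), np.full(k * capacity, np.nan))


def reproduce_deme(
    occupants: Population,
    capacity: int,
    rng: np.random.Generator,
    mutation_rate: float = 0.1,
    mutation_sd: float = 0.1,
) -> Population:
    """Reproduction restricted to a single deme's survivors."""
    if occupants.n == 0:
        return Population.empty()
    if len(np.unique(occupants.deme)) != 1:
        raise ConfigurationError("reproduce_deme expects occupants of one deme")
    return reproduce(occupants, capacity, mutation_rate, mutation_sd, rng)


def run_generation(
    population: Population,
    env: DemeEnvironment,
    specs: ModelSpecs,
    rng: np.random.Generator,
) -> Population:
    """One full generation; returns the next generation's newborns.

    An empty returned population signals metapopulation extinction (no
    survivor reached reproduction).
    """
    step_temporal(env, specs.temporal, specs.gradient, rng)
    develop_population(population, env, specs.gradient)
    n_demes = specs.gradient.n_demes
    if specs.life.order == "move_first":
        population = disperse_population(population, specs.dispersal, n_demes, rng)
        population = apply_selection(population, env, specs.selection, rng)
    else:
        population = apply_selection(population, env, specs.selection, rng)
        population = disperse_population(population, specs.dispersal, n_demes, rng)
    return reproduce(
        population, specs.life.deme_capacity, specs.mutation_rate, specs.mutation_sd, rng
    )


def run_simulation(
    specs: ModelSpecs,
    seed: int = 0,
    replicate: int = 0,
    rng: Optional[np.random.Generator] = None,
    init_deme_size: Optional[int] = None,
    end_window: int = 100,
) -> RunResult:
    """Run one realization from a founding population to the horizon.

    Mean plasticity is recorded every generation on the freshly developed
    cohort.  End-state per-deme means are averaged over the cohorts of the
    final ``end_window`` generations (grouped by development deme) to damp
    single-cohort sampling noise; a run that goes extinct before the window
    opens reports its last developed cohort instead.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(replicate,)))
    gradient = specs.gradient
    n_demes = gradient.n_demes
    capacity = specs.life.deme_capacity
    pop = init_population(gradient, init_deme_size or capacity, rng)
    env = DemeEnvironment.initial(gradient)

    n_gen = specs.life.n_generations
    traj = np.full(n_gen, np.nan)
    sizes = np.zeros(n_gen, dtype=np.int64)
    cohort = pop
    extinct = False
    completed = 0
    window_start = max(n_gen - end_window, 0)
    acc_sums = np.zeros((3, n_demes))  # plastic, nonplastic, phenotype
    acc_counts = np.zeros(n_demes)

    for t in range(n_gen):
        step_temporal(env, specs.temporal, gradient, rng)
        develop_population(pop, env, gradient)
        _, overall = mean_plasticity(pop, n_demes)
        traj[t] = overall
        cohort = pop
        if t >= window_start:
            acc_sums[0] += np.bincount(pop.natal, weights=pop.plastic_sum, minlength=n_demes + 1)[1:]
            acc_sums[1] += np.bincount(pop.natal, weights=pop.nonplastic_sum, minlength=n_demes + 1)[1:]
            acc_sums[2] += np.bincount(pop.natal, weights=pop.phenotype, minlength=n_demes + 1)[1:]
            acc_counts += np.bincount(pop.natal, minlength=n_demes + 1)[1:]

        if specs.life.order == "move_first":
            pop = disperse_population(pop, specs.dispersal, n_demes, rng)
            pop = apply_selection(pop, env, specs.selection, rng)
        else:
            pop = apply_selection(pop, env, specs.selection, rng)
            pop = disperse_population(pop, specs.dispersal, n_demes, rng)

        completed = t + 1
        if pop.n == 0:
            extinct = True
            break
        pop = reproduce(pop, capacity, specs.mutation_rate, specs.mutation_sd, rng)
        sizes[t] = pop.n

    # end state grouped by development deme, window-averaged when available
    if acc_counts.sum() > 0:
        occupied = acc_counts > 0
        end_p, end_n, end_t = (np.full(n_demes, np.nan) for _ in range(3))
        end_p[occupied] = acc_sums[0, occupied] / acc_counts[occupied]
        end_n[occupied] = acc_sums[1, occupied] / acc_counts[occupied]
        end_t[occupied] = acc_sums[2, occupied] / acc_counts[occupied]
    else:
        end_p = per_deme_means(cohort.natal, n_demes, cohort.plastic_sum)
        end_n = per_deme_means(cohort.natal, n_demes, cohort.nonplastic_sum)
        end_t = per_deme_means(cohort.natal, n_demes, cohort.phenotype)

    return RunResult(
        plasticity_trajectory=traj[:completed],
        pop_size_trajectory=sizes[:completed],
        end_deme_plasticity=end_p,
        end_deme_nonplastic=end_n,
        end_deme_phenotype=end_t,
        extinct=extinct,
        generations_completed=completed,
        seed=seed,
        replicate=replicate,
    )


def run_replicates(
    config: "RunConfig",
    n_success: Optional[int] = None,
    max_attempts: Optional[int] = None,
) -> list[RunResult]:
    """Replicate protocol: run until enough successes or the attempt cap.

    Attempt k draws its generator from the master seed and the attempt index,
    so each replicate is reproducible independent of execution order.  All
    attempts (including extinct ones) are returned; aggregation downstream
    averages over the successful ones only.
    """
    specs = config.model_specs()
    n_success = config.n_success if n_success is None else n_success
    max_attempts = config.max_attempts if max_attempts is None else max_attempts
    results: list[RunResult] = []
    successes = 0
    attempt = 0
    while successes < n_success and attempt < max_attempts:
        res = run_simulation(
            specs,
            seed=config.master_seed,
            replicate=attempt,
            init_deme_size=config.init_deme_size,
        )
        results.append(res)
        if not res.extinct:
            successes += 1
        attempt += 1
    return results
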