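"""Run configuration: defaults, validation, YAML loading, sweeps, presets."""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from .dispersal import MODES, DispersalSpec
from .engine import ORDERS, LifeHistorySpec, ModelSpecs
from .environment import PATTERNS, GradientSpec, TemporalSpec, tau_from_percent
from .errors import ConfigurationError
from .selection import SelectionSpec


@dataclass
class RunConfig:
    """Complete, validated description of one parameter combination.

    Defaults are the fixed model parameters: 50 demes, gradient step 0.4,
    multiplier step 0.04, sigma 2, capacity 100 per deme, 10,000 generations,
    5 + 5 diploid loci, 10% mutation at SD 0.1, 20 successful replicates out
    of at most 60 attempts.
    """

    # gradient
    n_demes: int = 50
    optimum_slope: float = 0.4
    expression_slope: float = 0.04
    # temporal variation
    pattern: str = "none"
    tau_pct: float = 0.0
    rho_among: float = 0.0
    corr_within: float = 0.0
    synchronized: bool = False
    # selection
    sigma: float = 2.0
    # dispersal
    migration: str = "stepping_stone"
    dispersal_rate: float = 0.0
    # life history
    order: str = "select_first"
    n_generations: int = 10_000
    deme_capacity: Optional[int] = None
    single_deme: bool = False
    # genome
    mutation_rate: float = 0.1
    mutation_sd: float = 0.1
    # replication / reporting
    master_seed: int = 42
    n_success: int = 20
    max_attempts: int = 60
    end_window: int = 100

    def __post_init__(self) -> None:
        if self.single_deme:
            self.n_demes = 1
        if self.deme_capacity is None:
            # temporal-only single-deme runs use a tenfold larger population
            self.deme_capacity = 1000 if self.single_deme else 100
        self.validate()

    def validate(self) -> None:
        if self.pattern not in PATTERNS:
            raise ConfigurationError(f"pattern: expected one of {PATTERNS}, got {self.pattern!r}")
        if self.migration not in MODES:
            raise ConfigurationError(f"migration: expected one of {MODES}, got {self.migration!r}")
        if self.order not in ORDERS:
            raise ConfigurationError(f"order: expected one of {ORDERS}, got {self.order!r}")
        if self.corr_within != 0 and self.pattern != "p3":
            raise ConfigurationError(
                f"corr_within is only meaningful for pattern p3 (got pattern {self.pattern!r})"
            )
        if not 0 <= self.dispersal_rate <= 1:
            raise ConfigurationError(f"dispersal_rate must be in [0, 1], got {self.dispersal_rate}")
        if self.migration == "stepping_stone" and self.dispersal_rate == 1:
            raise ConfigurationError("dispersal_rate = 1 has no stepping-stone kernel")
        if self.single_deme and self.dispersal_rate > 0:
            raise ConfigurationError("single_deme runs cannot have dispersal_rate > 0")
        if self.migration == "island" and self.dispersal_rate > 0 and self.n_demes < 2:
            raise ConfigurationError("island migration needs at least 2 demes")
        if self.n_success < 1 or self.max_attempts < self.n_success:
            raise ConfigurationError("need 1 <= n_success <= max_attempts")
        if self.end_window < 1:
            raise ConfigurationError("end_window must be >= 1")
        # spec constructors validate their own fields
        self.model_specs()

    # ---- spec builders -------------------------------------------------
    def gradient(self) -> GradientSpec:
        return GradientSpec(self.n_demes, self.optimum_slope, self.expression_slope)

    def temporal(self) -> TemporalSpec:
        return TemporalSpec(
            pattern=self.pattern,
            tau=tau_from_percent(self.tau_pct, self.gradient()),
            rho_among=self.rho_among,
            corr_within=self.corr_within,
            synchronized=self.synchronized,
        )

    def selection(self) -> SelectionSpec:
        return SelectionSpec(self.sigma)

    def dispersal(self) -> DispersalSpec:
        return DispersalSpec(self.migration, self.dispersal_rate)

    def life_history(self) -> LifeHistorySpec:
        return LifeHistorySpec(
            self.order, self.n_generations, self.deme_capacity, self.single_deme
        )

    def model_specs(self) -> ModelSpecs:
        return ModelSpecs(
            gradient=self.gradient(),
            temporal=self.temporal(),
            selection=self.selection(),
            dispersal=self.dispersal(),
            life=self.life_history(),
            mutation_rate=self.mutation_rate,
            mutation_sd=self.mutation_sd,
        )

    @property
    def init_deme_size(self) -> int:
        return self.deme_capacity

    # ---- (de)serialization --------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(
                f"unknown config key(s): {', '.join(sorted(unknown))}"
            )
        coerced: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            value = data[f.name]
            try:
                coerced[f.name] = _coerce(value, f.name)
            except (TypeError, ValueError) as exc:
                raise ConfigurationError(f"config key {f.name!r}: {exc}") from exc
        return cls(**coerced)


_INT_KEYS = {
    "n_demes", "n_generations", "deme_capacity", "master_seed",
    "n_success", "max_attempts", "end_window",
}
_BOOL_KEYS = {"synchronized", "single_deme"}
_STR_KEYS = {"pattern", "migration", "order"}


def _coerce(value: Any, key: str) -> Any:
    if key in _STR_KEYS:
        if not isinstance(value, str):
            raise TypeError(f"expected string, got {type(value).__name__}")
        return value.lower()
    if key in _BOOL_KEYS:
        if not isinstance(value, bool):
            raise TypeError(f"expected boolean, got {type(value).__name__}")
        return value
    if key in _INT_KEYS:
        if value is None:
            return None
        if isinstance(value, bool) or int(value) != value:
            raise TypeError(f"expected integer, got {value!r}")
        return int(value)
    return float(value)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; an empty file yields all defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    return RunConfig.from_dict(data)


def expand_sweep(grid: dict[str, Any]) -> list[RunConfig]:
    """Expand a sweep grid into validated configs with distinct derived seeds.

    ``grid`` holds a ``base`` mapping of shared keys and an ``axes`` mapping of
    key -> finite list.  The Cartesian product is taken in axis order;
    duplicate combinations are dropped with a warning.  Each config's seed is
    derived from the base master seed and its index in the product.
    """
    base = dict(grid.get("base", {}))
    axes = grid.get("axes", {})
    if not isinstance(axes, dict) or not axes:
        raise ConfigurationError("sweep grid needs a non-empty 'axes' mapping")
    for key, values in axes.items():
        if not isinstance(values, (list, tuple)) or len(values) == 0:
            raise ConfigurationError(f"sweep axis {key!r} must be a non-empty list")
    master = int(base.get("master_seed", RunConfig.master_seed))
    keys = list(axes)
    configs: list[RunConfig] = []
    seen: set[tuple] = set()
    for idx, combo in enumerate(product(*(axes[k] for k in keys))):
        point = dict(base)
        point.update(zip(keys, combo))
        sig = tuple(sorted((k, repr(v)) for k, v in point.items() if k != "master_seed"))
        if sig in seen:
            warnings.warn(f"duplicate sweep point dropped: {dict(zip(keys, combo))}")
            continue
        seen.add(sig)
        point["master_seed"] = int(
            np.random.SeedSequence(master, spawn_key=(idx,)).generate_state(1)[0]
        )
        configs.append(RunConfig.from_dict(point))
    return configs


# ---- figure-style presets ----------------------------------------------
# Each preset gives the captioned point of one published panel ("base") and
# the axes swept in that panel ("axes").  `simulate --preset X` runs the base
# point; `sweep --preset X` expands base x axes.
_TAU_AXIS = [0.0, 5.0, 10.0, 15.0, 20.0, 30.0]
_DISPERSAL_AXIS = [0.01, 0.02, 0.04, 0.08, 0.16, 0.32, 0.64]
_RHO_AXIS = [-0.75, -0.5, -0.25, 0.0, 0.25, 0.5, 0.75]

PRESETS: dict[str, dict[str, Any]] = {
    # single deme, change before development carried through to selection
    "fig1a": {
        "base": {"single_deme": True, "pattern": "p3", "corr_within": 1.0, "tau_pct": 20.0},
        "axes": {"tau_pct": _TAU_AXIS, "rho_among": _RHO_AXIS},
    },
    # single deme, independent change before and after development
    "fig1b": {
        "base": {"single_deme": True, "pattern": "p3", "corr_within": 0.0, "tau_pct": 20.0},
        "axes": {"tau_pct": _TAU_AXIS, "rho_among": _RHO_AXIS},
    },
    # single deme, correlated within-generation change
    "fig1c": {
        "base": {"single_deme": True, "pattern": "p3", "corr_within": -0.75, "tau_pct": 20.0},
        "axes": {"tau_pct": _TAU_AXIS, "corr_within": [-1.0, -0.75, -0.5, 0.5, 0.75, 1.0]},
    },
    # gradient, change before selection only
    "fig2a": {
        "base": {"pattern": "p1", "order": "select_first", "dispersal_rate": 0.64, "tau_pct": 10.0},
        "axes": {"dispersal_rate": _DISPERSAL_AXIS, "tau_pct": _TAU_AXIS},
    },
    "fig2b": {
        "base": {"pattern": "p1", "order": "move_first", "dispersal_rate": 0.64, "tau_pct": 30.0},
        "axes": {"dispersal_rate": _DISPERSAL_AXIS, "tau_pct": _TAU_AXIS},
    },
    "fig2c": {
        "base": {"pattern": "p1", "order": "select_first", "dispersal_rate": 0.64, "tau_pct": 10.0},
        "axes": {"tau_pct": _TAU_AXIS, "rho_among": _RHO_AXIS},
    },
    "fig2d": {
        "base": {"pattern": "p1", "order": "move_first", "dispersal_rate": 0.64,
                 "tau_pct": 30.0, "rho_among": -0.75},
        "axes": {"tau_pct": _TAU_AXIS, "rho_among": _RHO_AXIS},
    },
    # gradient, change before development carried through to selection
    "fig3a": {
        "base": {"pattern": "p3", "corr_within": 1.0, "order": "select_first",
                 "dispersal_rate": 0.64, "tau_pct": 10.0},
        "axes": {"dispersal_rate": _DISPERSAL_AXIS, "tau_pct": _TAU_AXIS},
    },
    "fig3b": {
        "base": {"pattern": "p3", "corr_within": 1.0, "order": "move_first",
                 "dispersal_rate": 0.64, "tau_pct": 10.0},
        "axes": {"dispersal_rate": _DISPERSAL_AXIS, "tau_pct": _TAU_AXIS},
    },
    "fig3c": {
        "base": {"pattern": "p3", "corr_within": 1.0, "order": "move_first",
                 "synchronized": True, "dispersal_rate": 0.16, "tau_pct": 10.0},
        "axes": {"dispersal_rate": _DISPERSAL_AXIS, "tau_pct": _TAU_AXIS},
    },
    "fig3d": {
        "base": {"pattern": "p3", "corr_within": 1.0, "order": "move_first",
                 "dispersal_rate": 0.64, "tau_pct": 10.0},
        "axes": {"tau_pct": _TAU_AXIS, "rho_among": _RHO_AXIS},
    },
    # gradient, independent change at both stages
    "fig4a": {
        "base": {"pattern": "p3", "corr_within": 0.0, "order": "select_first",
                 "dispersal_rate": 0.64, "tau_pct": 10.0},
        "axes": {"dispersal_rate": _DISPERSAL_AXIS, "tau_pct": _TAU_AXIS},
    },
    "fig4b": {
        "base": {"pattern": "p3", "corr_within": 0.0, "order": "move_first",
                 "dispersal_rate": 0.64, "tau_pct": 10.0},
        "axes": {"dispersal_rate": _DISPERSAL_AXIS, "tau_pct": _TAU_AXIS},
    },
    "fig4c": {
        "base": {"pattern": "p3", "order": "select_first", "dispersal_rate": 0.64,
                 "tau_pct": 10.0, "corr_within": 0.75},
        "axes": {"tau_pct": _TAU_AXIS, "corr_within": [-1.0, -0.75, -0.5, 0.0, 0.5, 0.75, 1.0]},
    },
    "fig4d": {
        "base": {"pattern": "p3", "order": "move_first", "dispersal_rate": 0.64,
                 "tau_pct": 20.0, "corr_within": -0.75},
        "axes": {"tau_pct": _TAU_AXIS, "corr_within": [-1.0, -0.75, -0.5, 0.0, 0.5, 0.75, 1.0]},
    },
    # spatial variation only: island vs stepping-stone
    "fig5": {
        "base": {"pattern": "none", "order": "select_first",
                 "migration": "island", "dispersal_rate": 0.05},
        "axes": {"migration": ["stepping_stone", "island"],
                 "dispersal_rate": [0.01, 0.02, 0.05, 0.1, 0.2, 0.4, 0.64]},
    },
}


def preset_config(name: str, **overrides: Any) -> RunConfig:
    """The captioned point of a figure preset as a single RunConfig."""
    if name not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        )
    data = dict(PRESETS[name]["base"])
    data.update(overrides)
    return RunConfig.from_dict(data)


def preset_grid(name: str, **base_overrides: Any) -> list[RunConfig]:
    """Expand a figure preset's sweep axes into configs."""
    if name not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        )
    grid = PRESETS[name]
    base = dict(grid["base"])
    base.update(base_overrides)
    return expand_sweep({"base": base, "axes": grid["axes"]})
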