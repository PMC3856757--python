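"""Spatial gradient of trait optima and temporally fluctuating deme environments.

The landscape is a one-dimensional linear gradient of ``n_demes`` demes.  Deme
``i`` (1-based) has a fixed mean optimum ``optimum_slope * (i - midpoint)``
with ``midpoint = (n_demes + 1) / 2``, so the optima are symmetric about the
centre of the gradient.  Plastic allelic values are expressed through a
multiplier that follows the same linear form with slope ``expression_slope``;
under the default slopes (0.4 and 0.04) the multiplier is exactly one tenth of
the local optimum.

On top of the static gradient, each deme's environment at two life-history
stages -- development and selection -- can fluctuate among generations.  The
fluctuation of each stage is a stationary AR(1) process on the trait scale::

    d_t = rho * d_{t-1} + tau * sqrt(1 - rho**2) * z_t

with ``z_t`` i.i.d. standard normal, so the marginal standard deviation equals
``tau`` for any ``|rho| < 1``.  Which stages fluctuate is controlled by the
temporal pattern:

========  ================  ===============
pattern   development env   selection env
========  ================  ===============
none      fixed             fixed
p1        fixed             AR(1)
p2        AR(1)             fixed
p3        AR(1)             AR(1)
========  ================  ===============

Under ``p3`` the per-generation innovations of the two stages are bivariate
standard normal with correlation ``corr_within``; a correlation of 1 means a
single environmental change carries through the whole life cycle.  With
``synchronized`` set, one shared innovation per stage drives every deme, so
all demes shift together while keeping the gradient shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

PATTERNS = ("none", "p1", "p2", "p3")

#: Span of the default 50-deme gradient in trait units; used as the
#: percentage base for tau in single-deme runs so temporal-only and
#: gradient runs are comparable on one axis.
DEFAULT_GRADIENT_RANGE = 0.4 * 49


@dataclass(frozen=True)
class GradientSpec:
    """Static linear gradient of optima and expression multipliers."""

    n_demes: int = 50
    optimum_slope: float = 0.4
    expression_slope: float = 0.04

    def __post_init__(self) -> None:
        if self.n_demes < 1:
            raise ConfigurationError(f"n_demes must be >= 1, got {self.n_demes}")
        for name in ("optimum_slope", "expression_slope"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")
        if self.optimum_slope == 0:
            raise ConfigurationError("optimum_slope must be nonzero")

    @property
    def midpoint(self) -> float:
        return (self.n_demes + 1) / 2

    @property
    def optimum_range(self) -> float:
        """Difference between the optima at the two ends of the gradient."""
        return self.optimum_slope * (self.n_demes - 1)

    @property
    def plastic_sum_optimum(self) -> float:
        """Plastic allelic sum that makes the phenotype track the optimum.

        A genotype with zero nonplastic sum and this plastic sum expresses the
        locally optimal phenotype in every deme (10 under default slopes).
        """
        if self.expression_slope == 0:
            raise ConfigurationError(
                "plastic_sum_optimum undefined for expression_slope = 0"
            )
        return self.optimum_slope / self.expression_slope

    def optimum(self, deme):
        """Mean optimum of 1-based ``deme`` (scalar or array)."""
        deme = np.asarray(deme)
        if np.any(deme < 1) or np.any(deme > self.n_demes):
            raise IndexError(f"deme out of range 1..{self.n_demes}")
        return self.optimum_slope * (deme - self.midpoint)

    def optima(self) -> np.ndarray:
        """Mean optima of all demes, shape ``(n_demes,)``."""
        return self.optimum_slope * (np.arange(1, self.n_demes + 1) - self.midpoint)


def build_gradient(
    n_demes: int, optimum_slope: float = 0.4, expression_slope: float = 0.04
) -> GradientSpec:
    """Construct a linear gradient; raises ConfigurationError on bad input."""
    return GradientSpec(n_demes, optimum_slope, expression_slope)


def tau_from_percent(tau_pct: float, gradient: GradientSpec) -> float:
    """Convert a percentage-scale noise magnitude to trait units.

    The base is the gradient's optimum range; for a single deme (range 0) the
    default 50-deme range is used so percentage axes remain comparable.
    """
    if tau_pct < 0:
        raise ConfigurationError(f"tau_pct must be >= 0, got {tau_pct}")
    base = gradient.optimum_range if gradient.n_demes > 1 else DEFAULT_GRADIENT_RANGE
    return tau_pct / 100.0 * base


@dataclass(frozen=True)
class TemporalSpec:
    """Timing, magnitude, and correlation structure of temporal variation.

    ``tau`` is in trait units (the stationary SD of each fluctuating stage);
    use :func:`tau_from_percent` or :meth:`from_percent` to convert from the
    percentage scale.
    """

    pattern: str = "none"
    tau: float = 0.0
    rho_among: float = 0.0
    corr_within: float = 0.0
    synchronized: bool = False

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ConfigurationError(
                f"pattern must be one of {PATTERNS}, got {self.pattern!r}"
            )
        if self.tau < 0:
            raise ConfigurationError(f"tau must be >= 0, got {self.tau}")
        if abs(self.rho_among) > 0.75:
            raise ConfigurationError(
                f"rho_among must lie in [-0.75, 0.75], got {self.rho_among}"
            )
        if abs(self.corr_within) > 1:
            raise ConfigurationError(
                f"corr_within must lie in [-1, 1], got {self.corr_within}"
            )
        if self.corr_within != 0 and self.pattern != "p3":
            raise ConfigurationError(
                "corr_within is only meaningful for pattern p3"
            )

    @classmethod
    def from_percent(cls, tau_pct: float, gradient: GradientSpec, **kwargs) -> "TemporalSpec":
        return cls(tau=tau_from_percent(tau_pct, gradient), **kwargs)

    @property
    def dev_varies(self) -> bool:
        return self.pattern in ("p2", "p3") and self.tau > 0

    @property
    def sel_varies(self) -> bool:
        return self.pattern in ("p1", "p3") and self.tau > 0


@dataclass
class DemeEnvironment:
    """Per-deme environments at development and selection, plus AR(1) states."""

    optima: np.ndarray
    dev_state: np.ndarray = field(default=None)  # type: ignore[assignment]
    sel_state: np.ndarray = field(default=None)  # type: ignore[assignment]
    dev_env: np.ndarray = field(default=None)  # type: ignore[assignment]
    sel_env: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        d = len(self.optima)
        if self.dev_state is None:
            self.dev_state = np.zeros(d)
        if self.sel_state is None:
            self.sel_state = np.zeros(d)
        if self.dev_env is None:
            self.dev_env = self.optima.copy()
        if self.sel_env is None:
            self.sel_env = self.optima.copy()

    @classmethod
    def initial(cls, gradient: GradientSpec) -> "DemeEnvironment":
        return cls(optima=gradient.optima())


def step_temporal(
    env: DemeEnvironment,
    spec: TemporalSpec,
    gradient: GradientSpec,
    rng: np.random.Generator,
) -> DemeEnvironment:
    """Advance both stage environments by one generation (in place).

    Innovations are drawn dev-stage first, then sel-stage, so a run is
    reproducible for a fixed generator state.  With ``corr_within = c`` the
    selection innovation is ``c*z_dev + sqrt(1-c^2)*w``, which makes c = 1 an
    exact carry-over of the development deviation.
    """
    size = 1 if spec.synchronized else len(env.optima)
    scale = spec.tau * math.sqrt(1.0 - spec.rho_among**2)

    z_dev = z_sel = None
    if spec.pattern == "p3":
        z_dev = rng.standard_normal(size)
        w = rng.standard_normal(size)
        c = spec.corr_within
        z_sel = c * z_dev + math.sqrt(max(0.0, 1.0 - c * c)) * w
    elif spec.pattern == "p2":
        z_dev = rng.standard_normal(size)
    elif spec.pattern == "p1":
        z_sel = rng.standard_normal(size)

    if spec.dev_varies:
        env.dev_state = spec.rho_among * env.dev_state + scale * z_dev
        env.dev_env = env.optima + env.dev_state
    if spec.sel_varies:
        env.sel_state = spec.rho_among * env.sel_state + scale * z_sel
        env.sel_env = env.optima + env.sel_state
    return env


def expression_multiplier(env: DemeEnvironment, gradient: GradientSpec, deme):
    """Environment-dependent multiplier of plastic allelic values.

    The development environment is mapped to the multiplier scale by the fixed
    ratio expression_slope/optimum_slope, so with no temporal noise the
    multiplier of deme i is exactly ``expression_slope * (i - midpoint)``.
    """
    deme = np.asarray(deme)
    if np.any(deme < 1) or np.any(deme > gradient.n_demes):
        raise IndexError(f"deme out of range 1..{gradient.n_demes}")
    ratio = gradient.expression_slope / gradient.optimum_slope
    return env.dev_env[deme - 1] * ratio


def multipliers(env: DemeEnvironment, gradient: GradientSpec) -> np.ndarray:
    """Expression multipliers for all demes, shape ``(n_demes,)``."""
    return env.dev_env * (gradient.expression_slope / gradient.optimum_slope)
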