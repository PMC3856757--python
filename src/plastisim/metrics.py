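"""Plasticity summaries, standardization, replicate aggregation, trend checks.

The headline statistic is the mean over individuals of the plastic allelic
sum, averaged per deme (empty demes excluded) and then unweighted across
demes.  It is standardized by the optimum-matching plastic sum
(``optimum_slope / expression_slope``, 10 under the defaults) so that 1 marks
a pure-plasticity outcome and 0 flat reaction norms; values outside [0, 1]
indicate hyperplastic or reversed reaction norms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .environment import GradientSpec
from .errors import ConfigurationError
from .genome import Population


def mean_plasticity(population: Population, n_demes: int) -> tuple[np.ndarray, float]:
    """Per-deme and overall mean plastic allelic sum.

    Returns ``(deme_means, overall)`` where ``deme_means[i-1]`` is the mean
    over residents of deme i (NaN if empty) and ``overall`` is the unweighted
    mean across occupied demes.
    """
    if population.n == 0:
        return np.full(n_demes, np.nan), float("nan")
    sums = np.bincount(
        population.deme, weights=population.plastic_sum, minlength=n_demes + 1
    )[1:]
    counts = np.bincount(population.deme, minlength=n_demes + 1)[1:]
    deme_means = np.full(n_demes, np.nan)
    occupied = counts > 0
    deme_means[occupied] = sums[occupied] / counts[occupied]
    return deme_means, float(deme_means[occupied].mean())


def per_deme_means(deme_labels: np.ndarray, n_demes: int, values: np.ndarray) -> np.ndarray:
    """Mean of ``values`` per 1-based deme label; NaN where a deme is empty."""
    sums = np.bincount(deme_labels, weights=values, minlength=n_demes + 1)[1:]
    counts = np.bincount(deme_labels, minlength=n_demes + 1)[1:]
    out = np.full(n_demes, np.nan)
    occupied = counts > 0
    out[occupied] = sums[occupied] / counts[occupied]
    return out


def relative_plasticity(mean_plastic_sum, gradient: GradientSpec):
    """Standardize a mean plastic sum to the optimal reaction norm.

    1 = optimum-matching slope, 0 = flat; values < 0 and > 1 are meaningful.
    """
    if gradient.expression_slope == 0:
        raise ConfigurationError(
            "relative plasticity undefined for expression_slope = 0"
        )
    return np.asarray(mean_plastic_sum) / gradient.plastic_sum_optimum + 0.0


def end_state_plastic_sum(trajectory: np.ndarray, window: int = 100) -> float:
    """Mean plastic sum over the final ``window`` recorded generations."""
    if len(trajectory) == 0:
        return float("nan")
    return float(np.asarray(trajectory)[-window:].mean())


@dataclass
class PlasticitySummary:
    """Replicate-averaged end state of a parameter combination."""

    deme_mean_plasticity: Optional[np.ndarray]
    overall_mean: Optional[float]
    relative_plasticity: Optional[float]
    cv_across_replicates: Optional[float]
    extinction_probability: float
    n_successful: int
    n_attempted: int


def aggregate_replicates(
    results: Sequence, gradient: GradientSpec, window: int = 100
) -> PlasticitySummary:
    """Average end states over successful (non-extinct) replicates only.

    Each replicate's end state is the mean plastic sum over its final
    ``window`` generations, standardized.  The CV uses the sample (n-1) SD and
    is reported in percent.  With zero successes the summary is marked missing
    (None values) and the extinction probability is 100%.
    """
    n_attempted = len(results)
    successes = [r for r in results if not r.extinct]
    extinct_frac = 100.0 * (n_attempted - len(successes)) / max(n_attempted, 1)
    if not successes:
        return PlasticitySummary(None, None, None, None, extinct_frac, 0, n_attempted)

    per_rep = np.array(
        [
            float(relative_plasticity(end_state_plastic_sum(r.plasticity_trajectory, window), gradient))
            for r in successes
        ]
    )
    mean_rel = float(per_rep.mean())
    if len(per_rep) > 1 and mean_rel != 0:
        cv = float(100.0 * per_rep.std(ddof=1) / abs(mean_rel))
    else:
        cv = 0.0
    deme_means = np.nanmean(
        np.stack([r.end_deme_plasticity for r in successes]), axis=0
    )
    return PlasticitySummary(
        deme_mean_plasticity=deme_means,
        overall_mean=mean_rel * gradient.plastic_sum_optimum,
        relative_plasticity=mean_rel,
        cv_across_replicates=cv,
        extinction_probability=extinct_frac,
        n_successful=len(successes),
        n_attempted=n_attempted,
    )


def equilibrium_check(trajectory: np.ndarray, window: int, tol: float = 0.5) -> str:
    """Directional-trend verdict over the final ``window`` generations.

    Fits a least-squares line to the last ``window`` points; the verdict is
    ``"no-trend"`` when the fitted total drift ``|slope| * (window - 1)`` is at
    most ``tol`` (plastic-sum units), else ``"trend"``.  Trajectories shorter
    than ``2 * window`` yield ``"insufficient"``.
    """
    trajectory = np.asarray(trajectory, dtype=float)
    if window < 2:
        raise ConfigurationError(f"window must be >= 2, got {window}")
    if len(trajectory) < 2 * window:
        return "insufficient"
    tail = trajectory[-window:]
    slope = np.polyfit(np.arange(window), tail, 1)[0]
    return "no-trend" if abs(slope) * (window - 1) <= tol else "trend"
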