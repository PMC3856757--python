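import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastisim import (
    ConfigurationError,
    DemeEnvironment,
    GradientSpec,
    TemporalSpec,
    build_gradient,
    expression_multiplier,
    step_temporal,
)
from plastisim.environment import multipliers, tau_from_percent


class TestGradient:
    def test_default_endpoints(self):
        g = build_gradient(50, 0.4, 0.04)
        assert g.optimum(1) == pytest.approx(-9.8)
        assert g.optimum(50) == pytest.approx(9.8)

    def test_adjacent_difference(self):
        g = build_gradient(50, 0.4, 0.04)
        opt = g.optima()
        assert np.allclose(np.diff(opt), 0.4)
        assert g.optimum(26) - g.optimum(25) == pytest.approx(0.4)

    def test_optima_symmetric_about_midpoint(self, gradient):
        assert gradient.optima().sum() == pytest.approx(0.0)
        assert gradient.midpoint == pytest.approx(25.5)

    def test_optimum_range(self, gradient):
        assert gradient.optimum_range == pytest.approx(19.6)

    def test_single_deme_flat(self):
        g = build_gradient(1, 0.4, 0.04)
        assert g.optimum(1) == pytest.approx(0.0)
        assert g.midpoint == 1.0

    def test_nonpositive_deme_count_rejected(self):
        with pytest.raises(ConfigurationError):
            build_gradient(0)

    def test_deme_out_of_range(self, gradient):
        with pytest.raises(IndexError):
            gradient.optimum(51)

    def test_plastic_sum_optimum(self, gradient):
        assert gradient.plastic_sum_optimum == pytest.approx(10.0)

    def test_expression_multiplier_matches_linear_form(self, gradient):
        """Multiplier of deme i is expression_slope * (i - midpoint) exactly."""
        env = DemeEnvironment.initial(gradient)
        m = multipliers(env, gradient)
        assert np.allclose(m, 0.04 * (np.arange(1, 51) - 25.5))
        assert np.allclose(np.diff(m), 0.04)

    def test_expression_multiplier_deme50(self, gradient):
        env = DemeEnvironment.initial(gradient)
        assert expression_multiplier(env, gradient, 50) == pytest.approx(0.98)

    def test_expression_multiplier_midpoint_offset_zero(self):
        g = build_gradient(51, 0.4, 0.04)  # odd count: deme 26 at the midpoint
        env = DemeEnvironment.initial(g)
        assert expression_multiplier(env, g, 26) == pytest.approx(0.0)

    def test_expression_multiplier_out_of_range(self, gradient):
        env = DemeEnvironment.initial(gradient)
        with pytest.raises(IndexError):
            expression_multiplier(env, gradient, 0)

    def test_perturbed_multiplier_mapping(self, gradient):
        """A +1.0 trait-unit shift of the development environment adds 0.1."""
        env = DemeEnvironment.initial(gradient)
        env.dev_env = env.optima.copy()
        env.dev_env[24] += 1.0  # deme 25, unperturbed optimum -0.2
        assert expression_multiplier(env, gradient, 25) == pytest.approx((-0.2 + 1.0) / 10)


class TestTemporalSpec:
    def test_tau_from_percent_default_base(self, gradient):
        assert tau_from_percent(10.0, gradient) == pytest.approx(1.96)

    def test_tau_single_deme_uses_default_base(self, single_deme_gradient):
        assert tau_from_percent(10.0, single_deme_gradient) == pytest.approx(1.96)

    def test_corr_within_requires_p3(self):
        with pytest.raises(ConfigurationError):
            TemporalSpec(pattern="p1", tau=1.0, corr_within=0.5)

    @pytest.mark.parametrize("bad", [{"tau": -1.0}, {"rho_among": 0.9}, {"corr_within": 1.5, "pattern": "p3"}, {"pattern": "p9"}])
    def test_invalid_parameters(self, bad):
        with pytest.raises(ConfigurationError):
            TemporalSpec(**{"tau": 1.0, **bad})


def _run_series(spec, gradient, n_steps, rng):
    env = DemeEnvironment.initial(gradient)
    dev = np.empty((n_steps, gradient.n_demes))
    sel = np.empty((n_steps, gradient.n_demes))
    for t in range(n_steps):
        step_temporal(env, spec, gradient, rng)
        dev[t] = env.dev_env
        sel[t] = env.sel_env
    return dev, sel


class TestStepTemporal:
    def test_zero_tau_keeps_both_stages_fixed(self, gradient, rng):
        spec = TemporalSpec(pattern="p3", tau=0.0)
        dev, sel = _run_series(spec, gradient, 20, rng)
        assert np.allclose(dev, gradient.optima())
        assert np.allclose(sel, gradient.optima())

    def test_pattern_none_fixed(self, gradient, rng):
        dev, sel = _run_series(TemporalSpec(), gradient, 10, rng)
        assert np.allclose(dev, gradient.optima())
        assert np.allclose(sel, gradient.optima())

    def test_p1_development_stage_fixed(self, gradient, rng):
        spec = TemporalSpec(pattern="p1", tau=2.0)
        dev, sel = _run_series(spec, gradient, 50, rng)
        assert np.allclose(dev, gradient.optima())
        assert not np.allclose(sel, gradient.optima())

    def test_p2_selection_stage_fixed(self, gradient, rng):
        spec = TemporalSpec(pattern="p2", tau=2.0)
        dev, sel = _run_series(spec, gradient, 50, rng)
        assert np.allclose(sel, gradient.optima())
        assert not np.allclose(dev, gradient.optima())

    def test_stationary_sd_matches_tau(self, gradient, rng):
        """Sample SD of the deviations approaches tau (oracle: AR(1) theory)."""
        tau = 1.96
        spec = TemporalSpec(pattern="p1", tau=tau, rho_among=0.0)
        n = 20_000
        _, sel = _run_series(spec, GradientSpec(n_demes=4), n, rng)
        devs = sel - GradientSpec(n_demes=4).optima()
        sd = devs.std()
        se = tau / math.sqrt(2 * (n * 4 - 1))
        assert abs(sd - tau) < 3 * se

    @pytest.mark.parametrize("rho", [-0.5, 0.5, 0.75])
    def test_lag1_autocorrelation_matches_rho(self, rho, rng):
        g = GradientSpec(n_demes=2)
        spec = TemporalSpec(pattern="p1", tau=1.0, rho_among=rho)
        n = 30_000
        _, sel = _run_series(spec, g, n, rng)
        x = sel[:, 0] - g.optimum(1)
        r = np.corrcoef(x[:-1], x[1:])[0, 1]
        se = (1 - rho**2) / math.sqrt(n)
        assert abs(r - rho) < 3 * se

    def test_sd_matches_tau_at_nonzero_rho(self, rng):
        """Stationary SD stays tau for any rho (the chosen AR(1) scaling)."""
        g = GradientSpec(n_demes=2)
        tau, rho = 2.0, 0.75
        spec = TemporalSpec(pattern="p1", tau=tau, rho_among=rho)
        n = 50_000
        _, sel = _run_series(spec, g, n, rng)
        x = sel[200:, 0] - g.optimum(1)
        # effective sample size shrinks by (1-rho)/(1+rho) under AR(1)
        n_eff = len(x) * (1 - rho) / (1 + rho)
        se = tau / math.sqrt(2 * (n_eff - 1))
        assert abs(x.std() - tau) < 3 * se

    def test_carryover_correlation_one(self, gradient, rng):
        spec = TemporalSpec(pattern="p3", tau=3.0, corr_within=1.0)
        dev, sel = _run_series(spec, gradient, 100, rng)
        assert np.allclose(dev, sel)

    def test_within_generation_correlation(self, rng):
        g = GradientSpec(n_demes=2)
        c = -0.6
        spec = TemporalSpec(pattern="p3", tau=1.0, corr_within=c)
        n = 30_000
        dev, sel = _run_series(spec, g, n, rng)
        opt = g.optima()
        r = np.corrcoef((dev - opt).ravel(), (sel - opt).ravel())[0, 1]
        se = (1 - c**2) / math.sqrt(2 * n)
        assert abs(r - c) < 3 * se

    def test_synchronized_demes_share_deviation(self, gradient, rng):
        spec = TemporalSpec(pattern="p3", tau=2.0, synchronized=True, corr_within=0.3)
        dev, sel = _run_series(spec, gradient, 50, rng)
        d_dev = dev - gradient.optima()
        d_sel = sel - gradient.optima()
        assert np.allclose(d_dev, d_dev[:, :1])
        assert np.allclose(d_sel, d_sel[:, :1])

    def test_unsynchronized_demes_differ(self, gradient, rng):
        spec = TemporalSpec(pattern="p1", tau=2.0)
        _, sel = _run_series(spec, gradient, 5, rng)
        d = sel - gradient.optima()
        assert not np.allclose(d[:, 0], d[:, 1])


@settings(max_examples=50, deadline=None)
@given(
    n_demes=st.integers(2, 200),
    slope=st.floats(0.01, 5.0),
    ratio=st.floats(0.5, 100.0),
)
def test_multiplier_slope_equals_expression_slope(n_demes, slope, ratio):
    g = GradientSpec(n_demes=n_demes, optimum_slope=slope, expression_slope=slope / ratio)
    env = DemeEnvironment.initial(g)
    m = multipliers(env, g)
    assert np.allclose(np.diff(m), slope / ratio, rtol=1e-9, atol=1e-12)
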