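import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dnmodel import (
    DNParams,
    SIM_DEFAULTS,
    MetricsUndefinedError,
    ResponseTimecourse,
    StimulusTimecourse,
    TimeGrid,
    cascade_dn,
    dn_response,
    linear_response,
    make_gamma_kernel,
    step_stimulus,
    summarize_dynamics,
)
from dnmodel.kernels import default_kernel_grid


def constant_stim(c, duration=3.0, dt=0.001):
    grid = TimeGrid(dt=dt, n=int(round(duration / dt)))
    return StimulusTimecourse(grid, np.full(grid.n, c))


class TestLinearStage:
    def test_zero_stimulus_gives_zero_response(self, epoch_grid):
        stim = StimulusTimecourse(epoch_grid, np.zeros(epoch_grid.n))
        irf = make_gamma_kernel(0.05, default_kernel_grid(epoch_grid.dt, 0.05))
        assert not np.any(linear_response(stim, irf).values)

    def test_unit_step_asymptote(self, epoch_grid):
        """A unit-sum kernel drives a long step to an asymptote of 1."""
        stim = step_stimulus(1.0, epoch_grid)
        irf = make_gamma_kernel(0.05, default_kernel_grid(epoch_grid.dt, 0.05))
        resp = linear_response(stim, irf)
        i = epoch_grid.index_at(8 * 0.05)  # essentially all kernel mass passed
        assert abs(resp.values[i] - 1.0) < 0.01

    def test_time_invariance(self, epoch_grid):
        irf = make_gamma_kernel(0.05, default_kernel_grid(epoch_grid.dt, 0.05))
        a = linear_response(step_stimulus(0.2, epoch_grid), irf).values
        b = linear_response(step_stimulus(0.2, epoch_grid, onset=0.05), irf).values
        k = 50
        assert np.allclose(b[k:], a[: epoch_grid.n - k], atol=1e-12)

    @given(a=st.floats(0.0, 1.0))
    def test_homogeneity(self, a):
        """Scaling the stimulus scales the linear response identically."""
        grid = TimeGrid(dt=0.001, n=600)
        stim = step_stimulus(0.3, grid)
        irf = make_gamma_kernel(0.05, default_kernel_grid(grid.dt, 0.05))
        full = linear_response(stim, irf).values
        scaled = linear_response(stim.scaled(a), irf).values
        assert np.allclose(scaled, a * full, atol=1e-12)


class TestDNResponse:
    def test_maximally_biphasic_steady_state_is_zero(self):
        """With w = 1 the IRF integrates to 0: no sustained response."""
        resp = dn_response(constant_stim(1.0, 2.0), SIM_DEFAULTS.replace(w=1.0))
        assert abs(resp.values[-100:].mean()) < 1e-6 * resp.values.max()

    @pytest.mark.parametrize("c", [0.25, 0.5, 1.0])
    def test_steady_state_closed_form(self, c):
        """Constant contrast c settles at gain * c^n / (sigma^n + c^n)."""
        params = DNParams(tau1=0.05, tau2=0.1, n=2.0, sigma=0.5, gain=1.7)
        resp = dn_response(constant_stim(c), params)
        expected = params.gain * c**2 / (params.sigma**2 + c**2)
        assert resp.values[-100:].mean() == pytest.approx(expected, rel=0.005)

    def test_transient_exceeds_sustained(self, step_500):
        """A 500 ms step evokes a transient above the late response."""
        v = dn_response(step_500, SIM_DEFAULTS).values
        t = step_500.grid.times
        late = v[(t >= 0.4) & (t < 0.5)].mean()
        assert v.max() > late

    def test_large_sigma_limit(self, step_500):
        """For huge sigma the denominator is sigma^n: pure LN scaling."""
        params = SIM_DEFAULTS.replace(sigma=1e6, gain=2.0)
        resp = dn_response(step_500, params).values
        irf = make_gamma_kernel(0.05, default_kernel_grid(0.001, 0.075))
        ln = params.gain * np.abs(
            np.convolve(step_500.values, irf.values)[: step_500.grid.n]
        ) ** 2 / 1e6**2
        mask = ln > 1e-20
        assert np.max(np.abs(resp[mask] - ln[mask]) / ln[mask]) < 1e-3

    def test_sigma_zero_zero_stim_is_guarded(self, epoch_grid):
        stim = StimulusTimecourse(epoch_grid, np.zeros(epoch_grid.n))
        params = DNParams(tau1=0.05, tau2=0.1, n=2.0, sigma=0.0)
        out = dn_response(stim, params).values
        assert np.all(np.isfinite(out)) and not np.any(out)

    def test_sigma_zero_nonzero_stim_warns(self, step_500):
        with pytest.warns(RuntimeWarning):
            dn_response(step_500, DNParams(tau1=0.05, tau2=0.1, n=2.0, sigma=0.0))

    def test_integer_shift_delays_output(self, step_500):
        base = dn_response(step_500, SIM_DEFAULTS).values
        shifted = dn_response(step_500, SIM_DEFAULTS.replace(shift=0.01)).values
        assert np.allclose(shifted[10:], base[:-10], atol=1e-12)
        assert not np.any(shifted[:10])

    def test_pool_order_switch(self, step_500):
        """The two denominator conventions differ for n != 1, agree at n = 1."""
        p2 = SIM_DEFAULTS.replace(sigma=0.3)
        a = dn_response(step_500, p2, pool_order="filter_then_power").values
        b = dn_response(step_500, p2, pool_order="power_then_filter").values
        assert np.max(np.abs(a - b)) > 1e-4
        p1 = p2.replace(n=1.0)
        a1 = dn_response(step_500, p1, pool_order="filter_then_power").values
        b1 = dn_response(step_500, p1, pool_order="power_then_filter").values
        assert np.allclose(a1, b1, atol=1e-12)


class TestCascade:
    def test_single_stage_matches_dn_response(self, step_500):
        assert np.array_equal(
            cascade_dn(step_500, SIM_DEFAULTS, 1).values,
            dn_response(step_500, SIM_DEFAULTS).values,
        )

    def test_second_stage_delays_peak(self, step_500):
        one = cascade_dn(step_500, SIM_DEFAULTS, 1).values
        two = cascade_dn(step_500, SIM_DEFAULTS, 2).values
        assert np.argmax(two) > np.argmax(one)

    def test_zero_stimulus_stays_zero(self, epoch_grid):
        stim = StimulusTimecourse(epoch_grid, np.zeros(epoch_grid.n))
        assert not np.any(cascade_dn(stim, SIM_DEFAULTS, 3).values)

    def test_invalid_stage_count(self, step_500):
        with pytest.raises(ValueError):
            cascade_dn(step_500, SIM_DEFAULTS, 0)


class TestSummaryMetrics:
    def test_peak_time_excludes_latency(self, epoch_grid):
        v = np.zeros(epoch_grid.n)
        v[130] = 1.0
        v[400:501] = 0.2
        resp = ResponseTimecourse(epoch_grid, v)
        m = summarize_dynamics(resp, shift=0.03, stim_offset=0.5)
        assert m.t_peak == pytest.approx(130 * 0.001 - 0.03)
        assert m.peak_amplitude == 1.0

    def test_constant_response_asymptote_is_one(self, epoch_grid):
        resp = ResponseTimecourse(epoch_grid, np.full(epoch_grid.n, 0.7))
        assert summarize_dynamics(resp, stim_offset=0.5).r_asymp == pytest.approx(1.0)

    def test_all_zero_response_is_undefined(self, epoch_grid):
        resp = ResponseTimecourse(epoch_grid, np.zeros(epoch_grid.n))
        with pytest.raises(MetricsUndefinedError):
            summarize_dynamics(resp, stim_offset=0.5)

    def test_asymptote_matches_brute_force(self, step_500):
        """r_asymp equals tail-mean / peak computed directly from the trace."""
        resp = dn_response(step_500, SIM_DEFAULTS)
        m = summarize_dynamics(resp, shift=0.0, stim_offset=0.5)
        t = step_500.grid.times
        v = resp.values
        oracle = v[(t >= 0.4) & (t <= 0.5)].mean() / v.max()
        assert m.r_asymp == pytest.approx(oracle, rel=1e-12)
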