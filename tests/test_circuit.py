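"""Microcircuit structure, mass dynamics, equilibria and Jacobians."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import bisect

from lamcsd.circuit import (BurstInputSpec, CANONICAL_STRENGTHS, CONNECTION_NAMES,
                            HiddenState, MassParameters, build_canonical_circuit,
                            default_mass_parameters, firing, fixed_point, flow,
                            jacobian_at, simulate)


def _decoupled(params, **kw):
    d = dict(a=np.zeros(10), kappa=params.kappa, h=params.h,
             sigmoid_slope=params.sigmoid_slope,
             sigmoid_threshold=params.sigmoid_threshold,
             input_weights=params.input_weights)
    d.update(kw)
    return MassParameters(**d)


class TestCircuitStructure:
    def test_four_populations_ten_connections(self):
        mc = build_canonical_circuit()
        assert mc.populations == ("SI", "DI", "DP", "SP")
        assert len(mc.connections) == 10

    def test_edge_set_matches_canonical_table(self):
        mc = build_canonical_circuit()
        assert {c.name for c in mc.connections} == set(CONNECTION_NAMES)
        # a31 reads "drive to deep pyramidal neurons from superficial interneurons"
        c = mc.connection("a31")
        assert (c.target, c.source) == ("DP", "SI")

    def test_interneuron_sources_and_self_edges_inhibit(self):
        mc = build_canonical_circuit()
        for c in mc.connections:
            if c.source in ("SI", "DI") or c.source == c.target:
                assert c.sign == -1
            else:
                assert c.sign == +1

    def test_canonical_strengths(self):
        assert CANONICAL_STRENGTHS["a44"] == 4.4
        assert CANONICAL_STRENGTHS["a41"] == 3.8
        assert CANONICAL_STRENGTHS["a22"] == 4.16

    def test_parameter_validation(self, params):
        with pytest.raises(ValueError):
            MassParameters(a=-np.ones(10), kappa=params.kappa, h=params.h,
                           sigmoid_slope=2.0, sigmoid_threshold=0.0,
                           input_weights=params.input_weights)
        with pytest.raises(ValueError):
            MassParameters(a=params.a, kappa=np.zeros(4), h=params.h,
                           sigmoid_slope=2.0, sigmoid_threshold=0.0,
                           input_weights=params.input_weights)


class TestFlow:
    def test_zero_state_zero_drive_is_equilibrium(self, params):
        dx = flow(HiddenState.zeros(), params, 0.0)
        assert np.allclose(dx, 0.0)

    def test_non_finite_state_rejected(self, params):
        with pytest.raises(ValueError):
            flow(np.full(8, np.nan), params)

    def test_step_response_derivative_matches_kernel(self, params):
        # no connections, constant drive: dw/dt(0) = kappa^2 h c u, dv/dt(0) = 0
        p = _decoupled(params)
        u = 0.3
        dx = flow(HiddenState.zeros(), p, u)
        assert np.allclose(dx[:4], 0.0)
        assert np.allclose(dx[4:], p.kappa**2 * p.h * p.input_weights * u)

    def test_zero_coupling_decouples_populations(self, params):
        p = _decoupled(params)
        x = np.zeros(8)
        x[0] = 0.7  # only SI perturbed
        dx = flow(x, p, 0.0)
        # other populations see no effect
        assert np.allclose(dx[[1, 2, 3]], 0.0) and np.allclose(dx[[5, 6, 7]], 0.0)
        assert dx[4] != 0.0

    def test_step_response_closed_form(self, params):
        # critically damped 2nd-order kernel: v(t) = h c u (1 - (1 + k t) e^{-k t})
        p = _decoupled(params)
        u = 0.2
        dt, T = 1e-4, 0.08
        t, v = simulate(p, dt, T, drive=lambda _t: u)
        k = p.kappa
        expect = p.h * p.input_weights * u * (1 - (1 + k * t[-1]) * np.exp(-k * t[-1]))
        assert np.allclose(v[-1], expect, rtol=1e-3)


class TestFixedPoint:
    def test_zero_drive_origin(self, params):
        st8 = fixed_point(params, 0.0)
        assert np.allclose(st8.x, 0.0, atol=1e-9)

    def test_single_population_matches_bisection(self, params):
        # SP with only its self-inhibition active, constant drive
        a = np.zeros(10)
        a[CONNECTION_NAMES.index("a44")] = 4.4
        p = _decoupled(params, a=a)
        u = 0.4
        fp = fixed_point(p, u)
        i = 3  # SP
        f = lambda v: p.h[i] * (-4.4 * firing(v, p.sigmoid_slope) + p.input_weights[i] * u) - v
        v_star = bisect(f, -10, 10, xtol=1e-12)
        assert fp.v[i] == pytest.approx(v_star, abs=1e-8)

    def test_flow_vanishes_at_fixed_point(self, params):
        fp = fixed_point(params, 0.15)
        assert np.max(np.abs(flow(fp, params, 0.15))) < 1e-7


class TestJacobian:
    def test_block_structure_when_decoupled(self, params):
        p = _decoupled(params)
        J = jacobian_at(p, np.zeros(8))
        assert np.allclose(J[:4, 4:], np.eye(4))
        assert np.allclose(J[4:, :4], -np.diag(p.kappa**2))
        assert np.allclose(J[4:, 4:], -np.diag(2 * p.kappa))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_finite_differences(self, params, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 0.3, 8)
        u = 0.1
        J = jacobian_at(params, x)
        eps = 1e-6
        Jfd = np.empty((8, 8))
        for k in range(8):
            e = np.zeros(8)
            e[k] = eps
            Jfd[:, k] = (flow(x + e, params, u) - flow(x - e, params, u)) / (2 * eps)
        assert np.max(np.abs(J - Jfd)) / np.max(np.abs(J)) < 1e-6

    def test_stable_at_canonical_parameters(self, params):
        ev = np.linalg.eigvals(jacobian_at(params, np.zeros(8)))
        assert np.all(ev.real < 0)


class TestSimulate:
    def test_stays_at_fixed_point(self, params):
        t, v = simulate(params, 2.5e-4, 0.5)
        assert np.max(np.abs(v)) < 1e-12

    def test_dt_guard(self, params):
        with pytest.raises(ValueError, match="kappa"):
            simulate(params, 0.5, 1.0)

    def test_halving_dt_converges(self, params):
        u = lambda t: 0.2 * np.sin(2 * np.pi * 10 * t)
        _, v1 = simulate(params, 2e-4, 0.5, drive=u)
        _, v2 = simulate(params, 1e-4, 0.5, drive=u)
        _, v3 = simulate(params, 5e-5, 0.5, drive=u)
        err12 = np.max(np.abs(v1[-1] - v2[-1]))
        err23 = np.max(np.abs(v2[-1] - v3[-1]))
        scale = np.max(np.abs(v2[-1]))
        assert err12 < 0.05 * scale        # small endpoint change on halving
        assert err23 < 0.75 * err12        # and shrinking with the step

    def test_linearized_decay_rate_matches_jacobian(self, params):
        # small perturbation along the slowest eigenmode decays at its eigenrate
        J = jacobian_at(params, np.zeros(8))
        ev, V = np.linalg.eig(J)
        k = np.argmax(ev.real)
        x0 = 1e-3 * np.real(V[:, k])
        dt, T = 1e-4, 0.05
        _, v = simulate(params, dt, T, x0=x0)
        amp0 = np.linalg.norm(v[0])
        amp1 = np.linalg.norm(v[-1])
        # envelope decay bounded by the dominant eigenvalue (oscillation phase
        # makes pointwise comparison loose; check the decade-scale rate)
        expected = np.exp(ev.real[k] * T)
        assert amp1 / amp0 == pytest.approx(expected, rel=0.35)


class TestBurstInput:
    def test_default_event_times(self):
        spec = BurstInputSpec()
        t = spec.event_times(1.0)
        expect = sorted([0.1 * g + 0.01 * s for g in range(10) for s in range(2)])
        assert np.allclose(t, expect)

    def test_pattern_tiles_beyond_one_second(self):
        spec = BurstInputSpec()
        t = spec.event_times(2.0)
        assert len(t) == 40 and t[20] == pytest.approx(1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            BurstInputSpec(n_groups=0)

    def test_drive_array_peaks_at_events(self):
        spec = BurstInputSpec(kernel_width_ms=1.0)
        d = spec.drive_array(2.5e-4, 1.0)
        assert d[int(0.1 / 2.5e-4)] > 0.9 * spec.amplitude


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.01, 2.0), min_size=10, max_size=10))
def test_equilibrium_consistency_random_parameters(scales):
    """flow(fixed_point(p, u), p, u) ~ 0 for randomized stable parameter boxes."""
    base = default_mass_parameters()
    p = MassParameters(a=base.a * np.array(scales), kappa=base.kappa, h=base.h,
                       sigmoid_slope=base.sigmoid_slope,
                       sigmoid_threshold=base.sigmoid_threshold,
                       input_weights=base.input_weights)
    fp = fixed_point(p, 0.2)
    assert np.max(np.abs(flow(fp, p, 0.2))) < 1e-7


def test_inhibition_monotonically_suppresses_target(params):
    """Raising an inhibitory weight never raises its target's equilibrium firing."""
    i41 = CONNECTION_NAMES.index("a41")  # SP <- SI, inhibitory
    last = np.inf
    for scale in np.linspace(0.5, 2.0, 6):
        a = params.a.copy()
        a[i41] *= scale
        p = MassParameters(a=a, kappa=params.kappa, h=params.h,
                           sigmoid_slope=params.sigmoid_slope,
                           sigmoid_threshold=params.sigmoid_threshold,
                           input_weights=params.input_weights)
        v_sp = fixed_point(p, 0.3).v[3]
        f_sp = firing(v_sp, p.sigmoid_slope)
        assert f_sp <= last + 1e-12
        last = f_sp
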