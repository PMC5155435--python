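import numpy as np
import pytest
from scipy.integrate import solve_ivp

import qsflute as q
from qsflute.core import ConfigError, DomainError


class TestHillActivation:
    def test_half_saturation(self):
        assert q.hill_fraction(5.0, 5.0, 1) == pytest.approx(0.5)

    def test_no_signal_no_activation(self):
        assert q.hill_fraction(0.0, 5.0, 2) == 0.0

    def test_first_order_closed_form(self):
        assert q.hill_fraction(15.0, 5.0, 1) == pytest.approx(0.75)

    def test_cooperativity_sharpens_switch(self):
        below = q.hill_fraction(2.5, 5.0, 4)
        above = q.hill_fraction(10.0, 5.0, 4)
        assert below < q.hill_fraction(2.5, 5.0, 1)
        assert above > q.hill_fraction(10.0, 5.0, 1)

    def test_invalid_threshold(self):
        with pytest.raises(DomainError):
            q.hill_fraction(1.0, 0.0, 1)
        with pytest.raises(DomainError):
            q.hill_fraction(1.0, 5.0, 0)

    def test_enzyme_production_saturates(self, params):
        assert q.enzyme_production_rate(0.0, params) == 0.0
        assert q.enzyme_production_rate(1e9, params) == pytest.approx(
            params.A_tot, rel=1e-6)
        assert q.enzyme_production_rate(params.C_star, params) == pytest.approx(
            params.A_tot / 2)


def _closed_system_rhs(p):
    def rhs(t, y):
        C, E, ES, S, P = y
        f = (C / p.C_star) ** p.m / (1 + (C / p.C_star) ** p.m)
        bind = p.k1 * E * S
        unbind = p.k_m1 * ES
        cat = p.k2 * ES
        return [p.alpha * p.rho_P - p.k_tot * C,
                p.A_tot * f - bind + unbind + cat,
                bind - unbind - cat,
                -bind + unbind,
                cat]
    return rhs


def _species_vector(state):
    return np.array([state.C[0], state.E[0], state.ES[0], state.S[0], state.P[0]])


class TestZeroDimensionalOracle:
    """With diffusion off, the five-species system must match an independent
    stiff ODE integration (the PDE path never calls scipy)."""

    def test_matches_reference_integration(self):
        p = q.default_params().replace(rho_P=1e5)
        grid = q.Grid1D(h=2.0, dx=0.2)
        t_end = 6.0
        sol = solve_ivp(_closed_system_rhs(p), (0, t_end), [0, 0, 0, p.S0, 0],
                        method="LSODA", rtol=1e-11, atol=1e-12, t_eval=[t_end])
        ref = sol.y[:, -1]
        y1 = _species_vector(q.simulate_cascade(p, grid, t_end, dt=2e-4,
                                                closed_system=True)[-1])
        y2 = _species_vector(q.simulate_cascade(p, grid, t_end, dt=1e-4,
                                                closed_system=True)[-1])
        rel1 = np.abs(y1 - ref) / np.abs(ref)
        assert rel1.max() < 5e-4          # first-order scheme at dt = 2e-4 h
        rich = 2 * y2 - y1                # eliminates the O(dt) error term
        assert (np.abs(rich - ref) / np.abs(ref)).max() < 1e-6

    def test_progress_curve_with_preformed_enzyme(self):
        # A_tot = 0, k_m1 = 0, fixed starting enzyme: classical single-enzyme
        # substrate depletion; no signal needed
        p = q.default_params().replace(A_tot=0.0, k_m1=0.0, alpha=0.0)
        grid = q.Grid1D(h=2.0, dx=0.2)
        E0, t_end = 500.0, 4.0
        sol = solve_ivp(_closed_system_rhs(p), (0, t_end), [0, E0, 0, p.S0, 0],
                        method="LSODA", rtol=1e-11, atol=1e-12, t_eval=[t_end])
        ref = sol.y[:, -1]
        state = q.simulate_cascade(p, grid, t_end, dt=1e-4,
                                   closed_system=True, initial_E=E0)[-1]
        y = _species_vector(state)
        keep = np.abs(ref) > 1e-9 * p.S0
        assert (np.abs(y - ref)[keep] / np.abs(ref)[keep]).max() < 5e-4
        assert ref[3] < 0.99 * p.S0       # substrate visibly consumed

    def test_closed_system_conserves_substrate_moiety(self):
        p = q.default_params().replace(rho_P=1e5)
        state = q.simulate_cascade(p, q.Grid1D(h=2.0, dx=0.2), 6.0, dt=2e-4,
                                   closed_system=True)[-1]
        total = state.S + state.P + state.ES
        assert np.abs(total - p.S0).max() <= 1e-8 * p.S0


class TestCascadePDE:
    def test_no_promoter_no_product(self, params):
        p = params.replace(A_tot=0.0, rho_P=1e6)
        states = q.simulate_cascade(p, q.Grid1D(h=4.0, dx=0.2), 24.0,
                                    record_times=[12.0, 24.0])
        for s in states:
            assert np.all(s.P == 0.0) and np.all(s.E == 0.0)

    def test_enzyme_bookkeeping(self, params):
        # E and ES do not diffuse, so E + ES must equal the time-integrated
        # production at every node
        p = params.replace(rho_P=1e5)
        state = q.simulate_cascade(p, q.Grid1D(h=6.0, dx=0.2), 48.0)[-1]
        resid = np.abs(state.E + state.ES - state.E_cum)
        assert resid.max() <= 1e-6 * max(state.E_cum.max(), 1.0)

    def test_positivity_and_draining_boundary(self, params):
        p = params.replace(rho_P=1e5)
        states = q.simulate_cascade(p, q.Grid1D(h=6.0, dx=0.2), 48.0,
                                    record_times=[24.0, 48.0])
        for s in states:
            for arr in (s.C, s.E, s.ES, s.S, s.P):
                assert arr.min() >= -1e-9 * p.S0
            assert s.C[0] == 0.0 and s.S[0] == 0.0 and s.P[0] == 0.0

    def test_product_accumulates_in_tall_column(self, params):
        p = params.replace(rho_P=1e5)
        states = q.simulate_cascade(p, q.Grid1D(h=20.0, dx=0.2), 96.0,
                                    record_times=[48.0, 72.0, 96.0])
        tops = [s.P[-1] for s in states]
        assert tops[0] < tops[1] < tops[2]

    def test_stability_bound_uses_fastest_diffusivity(self, params):
        grid = q.Grid1D(h=4.0, dx=0.2)
        bad_dt = grid.dx ** 2 / max(params.D_s, params.D_x)
        with pytest.raises(ConfigError, match="stability"):
            q.simulate_cascade(params, grid, 1.0, dt=bad_dt)

    def test_batch_agrees_with_single_column(self, params):
        from qsflute.cascade import simulate_columns
        p = params.replace(rho_P=1e5)
        single = q.simulate_cascade(p, q.Grid1D(h=4.0, dx=0.2), 12.0)[-1]
        batch = simulate_columns(p, [(1e5, 4.0), (1e4, 8.0)], 0.2, [12.0])[0]
        assert np.allclose(batch["P"][0, :21], single.P, rtol=1e-12, atol=0)
        assert np.allclose(batch["C"][0, :21], single.C, rtol=1e-12, atol=0)
        assert np.all(batch["S"][0, 21:] == 0.0)  # padding stays empty
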