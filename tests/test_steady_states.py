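"""Steady-state solver: closed forms, the NL quadratic, residual oracle."""

import numpy as np
import pytest
import sympy as sp

from vasctum import (
    NLQuadratic,
    Regime,
    all_steady_states,
    c_nullcline_branches,
    make_params,
    nl_steady_states,
    preset,
    sl_admissibility_bound,
    sl_steady_states,
    t_nullcline,
)

from conftest import brute_force_steady_states, random_params


class TestSpatiallyLimited:
    def test_tumour_free_state_for_any_parameters(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            ss1 = sl_steady_states(random_params(rng))[0]
            assert (ss1.identity, ss1.T, ss1.c, ss1.admissible) == ("SS1", 0.0, 1.0, True)

    def test_space_filling_state_closed_form(self):
        p = make_params(q1=0.1, q3=1.0, V0=0.005)
        ss2 = sl_steady_states(p)[1]
        assert ss2.T == 1 - p.V0
        assert ss2.c == pytest.approx(0.005 / (0.005 + 0.02 * 0.995), rel=1e-12)
        assert ss2.admissible  # V0 = 5e-3 above the bound 1/4951

    def test_space_filling_state_needs_enough_vasculature(self):
        p = make_params(q1=0.1, q3=1.0, V0=1e-4)  # below 1/4951
        assert not sl_steady_states(p)[1].admissible

    def test_bound_equality_case_is_admissible_with_threshold_oxygen(self):
        V0 = sl_admissibility_bound(0.1, 5.0, 0.01)
        ss2 = sl_steady_states(make_params(q1=0.1, q3=1.0, V0=V0))[1]
        assert ss2.c == pytest.approx(0.01, rel=1e-12)
        assert ss2.admissible and ss2.regime is Regime.SL


class TestNullclines:
    def test_starvation_nullcline_reaches_space_limit_at_threshold(self, table1):
        assert t_nullcline(table1.c_min, table1) == pytest.approx(1 - table1.V0, rel=1e-14)

    def test_starvation_nullcline_negative_at_half_threshold(self):
        p = make_params(q1=0.1, q3=1.0, V0=0.005)
        assert t_nullcline(p.c_min / 2, p) == pytest.approx(-0.005, rel=1e-12)

    def test_general_death_rate_loses_correction_at_threshold(self):
        p = make_params(q1=0.1, q3=1.0, V0=0.005, delta1=200.0, allow_general_delta1=True)
        assert p.delta1 == 2 * p.q2
        assert t_nullcline(p.c_min, p) == pytest.approx(1 - p.V0, rel=1e-14)

    def test_starvation_nullcline_rejects_nonpositive_oxygen(self, table1):
        with pytest.raises(ValueError):
            t_nullcline(0.0, table1)

    def test_oxygen_nullcline_at_full_oxygenation(self, table1):
        p = table1
        lo, hi = c_nullcline_branches(1.0, p)
        assert lo == pytest.approx(0.0, abs=1e-14)
        assert hi == pytest.approx((p.q1 + p.q3 * (1 - p.V0)) / p.q3, rel=1e-12)

    def test_oxygen_nullcline_vanishes_below_its_reach(self):
        # strong consumption + weak supply: the nullcline cannot reach low c
        p = make_params(q1=0.1, q3=0.8, V0=0.014)
        assert c_nullcline_branches(0.005, p) is None

    def test_both_branches_real_in_the_hypoxic_band(self):
        p = preset("fig3a")
        lo, hi = c_nullcline_branches(p.c_min, p)
        assert 0 < lo < hi

    def test_starvation_nullcline_increasing_in_oxygen(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            p = random_params(rng)
            c = np.linspace(p.c_min * 1e-3, p.c_min, 200)
            T = [t_nullcline(x, p) for x in c]
            assert np.all(np.diff(T) > 0)


class TestNLQuadratic:
    def test_coefficients_match_their_definition(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = random_params(rng)
            q = NLQuadratic.from_params(p)
            X = p.q1 - 3 * p.q3 + (p.g / p.c_min + p.q3) * p.V0
            Y = 2 * (p.q1 - p.q3) + (p.g + p.q3 - p.q1) * p.V0
            assert q.X == pytest.approx(X, rel=1e-14)
            assert q.Y == pytest.approx(Y, rel=1e-14)
            assert (q.a, q.b, q.d) == (q.Y, -p.c_min * q.X, -p.q3 * p.c_min**2)

    def test_quadratic_is_the_nullcline_intersection_polynomial(self):
        """Symbolic oracle: eliminating T from the oxygen balance along the
        starvation nullcline must reproduce the assembled quadratic."""
        q1, q3, g, cm, V0, c = sp.symbols("q1 q3 g c_min V0 c", positive=True)
        T = (1 - V0) - (cm / c - 1)
        F = g * (1 - c) * V0 - q1 * c * T - q3 * c * T * (1 - (T + V0))
        poly = sp.Poly(sp.expand(F * c), c)
        rng = np.random.default_rng(5)
        for _ in range(5):
            p = random_params(rng)
            subs = {q1: p.q1, q3: p.q3, g: p.g, cm: p.c_min, V0: p.V0}
            a, b, d = [float(x.subs(subs)) for x in poly.all_coeffs()]
            q = NLQuadratic.from_params(p)
            # the symbolic polynomial is -1 times the assembled quadratic
            assert -a == pytest.approx(q.a, rel=1e-12)
            assert -b == pytest.approx(q.b, rel=1e-12, abs=1e-18)
            assert -d == pytest.approx(q.d, rel=1e-12)

    def test_roots_satisfy_the_quadratic(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            p = random_params(rng)
            q = NLQuadratic.from_params(p)
            for r in q.roots():
                scale = max(abs(q.a * r * r), abs(q.b * r), abs(q.d))
                assert abs(q.a * r * r + q.b * r + q.d) <= 1e-12 * scale

    def test_degenerate_case_is_the_excluded_vascular_volume(self):
        q1, q3, g = 0.1, 0.2, 5.0
        V0 = 2 * (q3 - q1) / (g + q3 - q1)
        p = make_params(q1=q1, q3=q3, V0=V0)
        q = NLQuadratic.from_params(p)
        assert q.degenerate
        assert len(q.roots()) <= 1
        states = nl_steady_states(p)
        assert all(s.identity != "SS4" for s in states)


class TestNLStates:
    def test_single_hypoxic_state_when_vasculature_is_sparse(self):
        states = nl_steady_states(preset("fig3a"))
        assert [s.identity for s in states] == ["SS3"]
        assert states[0].T == pytest.approx(0.0942684, abs=1e-6)
        assert states[0].c == pytest.approx(0.0052487, abs=1e-6)

    def test_two_hypoxic_states_with_denser_vasculature(self):
        states = nl_steady_states(preset("fig3b"))
        assert [s.identity for s in states] == ["SS3", "SS4"]
        ss3, ss4 = states
        assert ss3.T < ss4.T and ss3.c < ss4.c

    def test_all_returned_states_are_true_equilibria(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            p = random_params(rng)
            for s in nl_steady_states(p):
                assert s.residual(p) < 1e-10

    def test_general_death_rate_path_agrees_with_quadratic_at_coupling(self):
        # delta1 = q2 passed through the decoupled (numeric) code path must
        # reproduce the quadratic's roots
        base = preset("fig3b")
        p = make_params(q1=base.q1, q3=base.q3, V0=base.V0,
                        delta1=base.q2, allow_general_delta1=True)
        from vasctum.steady_states import _nl_roots_general

        numeric = sorted(_nl_roots_general(p))
        closed = sorted(s.c for s in nl_steady_states(base))
        assert numeric == pytest.approx(closed, rel=1e-9)


class TestFullInventory:
    def test_no_state_missed_or_invented(self):
        """Brute-force oracle: nullcline sign-scan finds exactly the states
        the module reports, for random parameter sets."""
        rng = np.random.default_rng(23)
        for _ in range(30):
            p = random_params(rng)
            reported = sorted(
                (s.T, s.c) for s in all_steady_states(p, annotate_stability=False)
                if s.admissible
            )
            oracle = sorted(brute_force_steady_states(p))
            assert len(reported) == len(oracle)
            for (Tr, cr), (To, co) in zip(reported, oracle):
                assert Tr == pytest.approx(To, abs=1e-8)
                assert cr == pytest.approx(co, abs=1e-8)

    def test_three_admissibility_patterns_on_a_parameter_slice(self):
        # coarse (V0, q3) sweep at q1 = 0.5: sparse vasculature supports only
        # the hypoxic state, dense+greedy supports all four, dense+frugal
        # only the space-filling pair
        patterns = set()
        for V0 in np.geomspace(1e-4, 5e-3, 12):
            for q3 in np.geomspace(1e-2, 10, 12):
                p = make_params(q1=0.5, q3=float(q3), V0=float(V0))
                states = all_steady_states(p, annotate_stability=False)
                patterns.add("+".join(s.identity for s in states if s.admissible))
        assert patterns == {"SS1+SS3", "SS1+SS2+SS3+SS4", "SS1+SS2"}

    def test_frugal_tumour_with_dense_vasculature_fills_space(self):
        # q3 << q1 and V0 above the bound: no hypoxic state at all
        p = make_params(q1=1.0, q3=0.01, V0=0.005)
        states = all_steady_states(p, annotate_stability=False)
        assert [s.identity for s in states if s.admissible] == ["SS1", "SS2"]
        assert len(brute_force_steady_states(p)) == 2
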