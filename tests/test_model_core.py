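"""Vector fields, Monod kinetics, simulation and outcome classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mutucomp import (
    InvalidParameterError,
    Trajectory,
    chemostat_rhs,
    classify_outcome,
    elv_rhs,
    fixture,
    growth_rate,
    monod,
    simulate,
    simulate_to_steady,
)
from mutucomp.model_core import SimulationError, rhs_for


class TestMonod:
    @pytest.mark.parametrize("s, k, expected", [
        (0.0, 200.0, 0.0),
        (200.0, 200.0, 0.5),
        (50.0, 200.0, 0.2),
    ])
    def test_values(self, s, k, expected):
        assert monod(s, k) == pytest.approx(expected, abs=1e-15)

    @given(st.floats(0, 1e6), st.floats(1e-3, 1e6))
    def test_bounded_fraction(self, s, k):
        v = monod(s, k)
        assert 0.0 <= v < 1.0

    @given(st.floats(0, 1e5), st.floats(0, 1e5), st.floats(1e-3, 1e4))
    def test_monotone_in_s(self, s1, s2, k):
        lo, hi = sorted([s1, s2])
        assert monod(lo, k) <= monod(hi, k)

    def test_nonpositive_k_rejected(self):
        with pytest.raises(InvalidParameterError):
            monod(1.0, 0.0)


class TestGrowthRate:
    def test_strict_dependence_on_both_nutrients(self, eq3):
        assert growth_rate(1, 0.0, 123.0, eq3) == 0.0
        assert growth_rate(1, 123.0, 0.0, eq3) == 0.0

    def test_half_saturation_product(self, eq3):
        # both nutrients at their half-saturation constants -> mu/4
        assert growth_rate(1, 200.0, 200.0, eq3) == pytest.approx(400.0)

    def test_hand_value(self, eq3):
        # mu * (50/250) * (1/201)
        expected = 1600.0 * (50.0 / 250.0) * (1.0 / 201.0)
        assert growth_rate(1, 50.0, 1.0, eq3) == pytest.approx(expected)
        assert expected == pytest.approx(1.592, abs=5e-4)

    def test_bounded_by_mu(self, eq3):
        assert growth_rate(2, 1e9, 1e9, eq3) < eq3.mu2

    def test_bad_species_index(self, eq3):
        with pytest.raises(ValueError):
            growth_rate(3, 1.0, 1.0, eq3)


class TestChemostatRHS:
    def test_washout_is_equilibrium(self, eq3):
        state = [0.0, 0.0, eq3.s0_in, eq3.s1_in, eq3.s2_in]
        assert np.allclose(chemostat_rhs(state, eq3), 0.0)

    def test_pure_dilution_without_biomass(self, eq3):
        # X = 0, S0 = 0: carbon refills at phi * s0_in = 2 * 50
        d = chemostat_rhs([0.0, 0.0, 0.0, eq3.s1_in, eq3.s2_in], eq3)
        assert d[2] == pytest.approx(100.0)

    def test_growth_dilution_balance(self, eq3):
        # find s2 such that f1 = phi at s0 = 50, then dX1/dt must vanish
        from scipy.optimize import brentq

        f = lambda s2: growth_rate(1, 50.0, s2, eq3) - eq3.phi
        s2 = brentq(f, 1e-6, 1e6)
        d = chemostat_rhs([3.0, 0.0, 50.0, 1.0, s2], eq3)
        assert d[0] == pytest.approx(0.0, abs=1e-9)

    def test_negative_state_rejected(self, eq3):
        with pytest.raises(InvalidParameterError):
            chemostat_rhs([-1.0, 0.0, 50.0, 1.0, 1.0], eq3)


class TestElvRHS:
    def test_origin_is_equilibrium(self, eq6):
        assert np.all(elv_rhs(0.0, 0.0, eq6) == 0.0)

    def test_hand_value(self, eq6):
        d = elv_rhs(1.0, 0.0, eq6)
        assert d[0] == pytest.approx(0.027 * (50 - 5) - 2)  # -0.785
        assert d[1] == 0.0

    def test_symmetric_coexistence_root(self, eq6):
        # positive root of 0.2 X^2 - 5 X + (2/0.027 - 50) = 0
        alpha = eq6.d / eq6.r1 - eq6.a1
        x = (5 + np.sqrt(25 - 4 * 0.2 * alpha)) / 0.4
        assert np.allclose(elv_rhs(x, x, eq6), 0.0, atol=1e-9)

    def test_mutualism_turns_competitive_with_density(self, eq6):
        # d(dX1/dt)/dX2 changes sign at X2 = b12 / (2 c1) = 25
        x1 = 0.5

        def slope(x2, h=1e-6):
            return (elv_rhs(x1, x2 + h, eq6)[0]
                    - elv_rhs(x1, x2 - h, eq6)[0]) / (2 * h)

        assert slope(10.0) > 0
        assert slope(40.0) < 0


class TestSimulate:
    def test_low_growth_rates_wash_out(self):
        p = fixture("fig2a")  # mu = [800, 800]
        traj = simulate("chemostat", p,
                        [10.0, 10.0, p.s0_in, p.s1_in, p.s2_in],
                        t_end=100.0 / p.phi)
        out = classify_outcome(traj, params=p)
        assert out.pattern == (False, False)

    def test_elv_origin_attracts_low_density(self, eq6):
        end, ok = simulate_to_steady("elv", eq6, (0.01, 0.01))
        assert ok
        assert np.allclose(end, 0.0, atol=1e-6)

    def test_elv_coexistence_attracts_high_density(self, eq6):
        end, ok = simulate_to_steady("elv", eq6, (15.0, 15.0))
        assert ok
        assert np.allclose(end, 18.4899607, atol=1e-4)

    def test_nonnegativity_along_trajectories(self, eq3, eq6):
        atol = 1e-10
        for model, p, init in [
            ("chemostat", eq3, [10.0, 10.0, eq3.s0_in, eq3.s1_in, eq3.s2_in]),
            ("elv", eq6, [15.0, 15.0]),
            ("elv", eq6, [0.5, 0.5]),
        ]:
            traj = simulate(model, p, init, atol=atol)
            assert np.min(traj.states) >= -10 * atol

    def test_washout_relaxes_nutrients_to_inflow(self, eq3):
        traj = simulate("chemostat", eq3, [0.0, 0.0, 10.0, 0.0, 5.0],
                        t_end=20.0)
        assert np.allclose(traj.final_state[2:],
                           [eq3.s0_in, eq3.s1_in, eq3.s2_in], atol=1e-6)

    def test_invalid_inputs(self, eq6):
        with pytest.raises(InvalidParameterError):
            simulate("elv", eq6, [-1.0, 1.0])
        with pytest.raises(ValueError):
            simulate("elv", eq6, [1.0, 1.0], t_end=-5.0)
        with pytest.raises(ValueError):
            rhs_for("nonsense", eq6)


class TestDilutionRelations:
    def test_conserved_quantities_relax_exponentially(self, eq3):
        """Q_j = S_j - sum_i nu_ji X_i obeys dQ/dt = phi (S̃_j - Q_j), so it
        relaxes to the inflow concentration at exactly the flow rate."""
        init = np.array([10.0, 5.0, eq3.s0_in, eq3.s1_in, eq3.s2_in])
        traj = simulate("chemostat", eq3, init, t_end=5.0, n_out=100)
        nu = np.array([[eq3.nu01, eq3.nu02],
                       [eq3.nu11, eq3.nu12],
                       [eq3.nu21, eq3.nu22]])
        s_in = np.array([eq3.s0_in, eq3.s1_in, eq3.s2_in])
        x = traj.states[:, :2]
        s = traj.states[:, 2:]
        q = s - x @ nu.T
        q0 = q[0]
        expected = s_in + (q0 - s_in) * np.exp(-eq3.phi * traj.times[:, None])
        scale = np.max(np.abs(q0 - s_in)) + 1.0
        assert np.max(np.abs(q - expected)) < 1e-6 * scale


class TestClassifyOutcome:
    def _traj(self, final):
        states = np.array([[1.0, 1.0], list(final)])
        return Trajectory(times=np.array([0.0, 1.0]), states=states,
                          model="elv")

    def test_threshold_logic(self):
        out = classify_outcome(self._traj((0.0, 0.0)))
        assert out.pattern == (False, False)
        out = classify_outcome(self._traj((2.0, 1e-9)), eps=1e-6)
        assert out.pattern == (True, False)
        out = classify_outcome(self._traj((18.49, 18.49)), eps=1e-6)
        assert out.pattern == (True, True)

    def test_nonconverged_flagged_not_raised(self, eq6):
        traj = self._traj((5.0, 5.0))  # not a steady state of eq6
        with pytest.warns(UserWarning):
            out = classify_outcome(traj, params=eq6)
        assert not out.converged

    def test_roundoff_negatives_clipped(self):
        out = classify_outcome(self._traj((-1e-12, 1.0)))
        assert out.final_state[0] == 0.0
        assert out.pattern == (False, True)
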