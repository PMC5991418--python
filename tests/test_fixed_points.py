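"""Steady-state enumeration, Newton solver and stability classification."""

import numpy as np
import pytest

from mutucomp import (
    chemostat_fixed_points,
    chemostat_jacobian,
    chemostat_rhs,
    elv_fixed_points,
    elv_jacobian,
    elv_rhs,
    fixture,
    newton_solve,
    reduce_to_lv,
    stability_of,
    steady_nutrients,
)
from mutucomp.model_core import rhs_for

from conftest import brute_force_coexistence, match_root_sets, random_elv_params


def by_label(points):
    out = {}
    for fp in points:
        out.setdefault(fp.label, []).append(fp)
    return out


class TestStabilityOf:
    @pytest.mark.parametrize("eig, verdict", [
        ([-0.65, -0.65], "stable"),
        ([0.42, -2.18], "saddle"),
        ([1.0, 2.0], "unstable"),
        ([complex(-1, 5), complex(-1, -5)], "stable"),
    ])
    def test_verdicts(self, eig, verdict):
        v, marginal = stability_of(eig)
        assert v == verdict and not marginal

    def test_marginal_flag(self):
        v, marginal = stability_of([0.0, -1.0], tol=1e-9)
        assert marginal

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            stability_of([np.nan, 1.0])


class TestNewtonSolve:
    def test_exact_root_returns_immediately(self, eq6):
        f = rhs_for("elv", eq6)
        jac = lambda y: elv_jacobian(eq6, y[0], y[1])
        res = newton_solve(f, jac, np.zeros(2))
        assert res.converged and res.iterations == 0

    @pytest.mark.parametrize("start, root", [
        ((15.0, 15.0), 18.4899607),
        ((7.0, 6.0), 6.5100393),
    ])
    def test_converges_to_nearby_coexistence_root(self, eq6, start, root):
        f = rhs_for("elv", eq6)
        jac = lambda y: elv_jacobian(eq6, y[0], y[1])
        res = newton_solve(f, jac, np.array(start), tol=1e-10)
        assert res.converged
        assert np.allclose(res.x, root, atol=1e-6)

    def test_singular_jacobian_flagged(self):
        f = lambda x: np.array([x[0] ** 2])
        jac = lambda x: np.array([[0.0]])
        res = newton_solve(f, jac, np.array([1.0]))
        assert not res.converged
        assert "singular" in res.message or "max iterations" in res.message


class TestElvJacobian:
    def test_origin_is_diagonal(self, eq6):
        j = elv_jacobian(eq6, 0.0, 0.0)
        assert np.allclose(np.diag(j), 0.027 * 50 - 2)
        assert j[0, 1] == 0.0 and j[1, 0] == 0.0

    def test_coexistence_entries(self, eq6):
        x = 18.4899607
        j = elv_jacobian(eq6, x, x)
        assert j[0, 0] == pytest.approx(-2.4961, abs=1e-3)
        assert j[0, 1] == pytest.approx(1.3001, abs=1e-3)

    def test_matches_finite_differences(self, eq6):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x1, x2 = rng.uniform(0.1, 30, size=2)
            j = elv_jacobian(eq6, x1, x2)
            h = 1e-6
            num = np.zeros((2, 2))
            for k, dx in enumerate(np.eye(2) * h):
                num[:, k] = (elv_rhs(x1 + dx[0], x2 + dx[1], eq6)
                             - elv_rhs(x1 - dx[0], x2 - dx[1], eq6)) / (2 * h)
            assert np.allclose(j, num, atol=1e-5)


class TestElvFixedPoints:
    def test_reference_set_structure(self, eq6):
        pts = by_label(elv_fixed_points(eq6))
        assert pts["E"][0].stable
        assert "L1" not in pts and "L2" not in pts
        coords = sorted(fp.coords[0] for fp in pts["L12"])
        assert coords == pytest.approx([6.5100393, 18.4899607], abs=1e-4)
        verdicts = {round(fp.coords[0], 3): fp.verdict for fp in pts["L12"]}
        assert verdicts[6.51] == "saddle"
        assert verdicts[18.49] == "stable"

    def test_low_growth_has_no_coexistence(self, eq6):
        pts = by_label(elv_fixed_points(eq6.replace(r1=0.02, r2=0.02)))
        assert "L12" not in pts
        assert pts["E"][0].stable

    def test_boundary_state_for_unbalanced_growth(self, eq6):
        pts = by_label(elv_fixed_points(eq6.replace(r1=0.05, r2=0.02)))
        l1 = pts["L1"][0]
        assert np.allclose(l1.coords, [2.0, 0.0], atol=1e-9)
        assert l1.stable
        # transverse eigenvalue r2 (a2 + 2 b21 - 4 c2) - d = -0.616
        assert min(np.real(l1.eigenvalues)) == pytest.approx(-0.616) or \
            max(np.real(l1.eigenvalues)) == pytest.approx(-0.616)

    def test_residuals_below_tolerance(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            p = random_elv_params(rng)
            for fp in elv_fixed_points(p):
                assert fp.residual < 1e-9 * max(
                    1.0, float(np.max(np.abs(fp.coords))) ** 2)

    def test_species_swap_permutes_fixed_points(self):
        rng = np.random.default_rng(22)
        for _ in range(50):
            p = random_elv_params(rng)
            a = {(fp.label, round(fp.coords[0], 6), round(fp.coords[1], 6))
                 for fp in elv_fixed_points(p)}
            swap = {"E": "E", "L1": "L2", "L2": "L1", "L12": "L12"}
            b = {(swap[fp.label], round(fp.coords[1], 6),
                  round(fp.coords[0], 6))
                 for fp in elv_fixed_points(p.swapped())}
            assert a == b

    def test_matches_brute_force_oracle(self):
        """Quartic enumeration agrees with dense nullcline scanning in count
        and location on random parameter sets."""
        rng = np.random.default_rng(23)
        for _ in range(100):
            p = random_elv_params(rng)
            found = [fp.coords for fp in elv_fixed_points(p)
                     if fp.label == "L12"]
            expected = brute_force_coexistence(p)
            assert match_root_sets(found, expected, tol=1e-6), p

    def test_finds_all_four_intersections_when_parabolae_tangle(self):
        p = fixture("s2fig")
        found = [fp.coords for fp in elv_fixed_points(p) if fp.label == "L12"]
        assert len(found) == len(brute_force_coexistence(p)) > 2


class TestChemostatFixedPoints:
    def test_washout_always_present_with_zero_residual(self, eq3):
        pts = chemostat_fixed_points(eq3, include_simulation_starts=False)
        w = [fp for fp in pts if fp.label == "washout"]
        assert len(w) == 1
        assert np.all(w[0].coords == [0, 0, eq3.s0_in, eq3.s1_in, eq3.s2_in])
        assert w[0].residual == 0.0

    def test_reference_set_is_bistable(self, eq3):
        pts = chemostat_fixed_points(eq3, include_simulation_starts=False)
        stable = [fp for fp in pts if fp.stable]
        assert sorted(fp.label for fp in stable) == ["coexistence", "washout"]

    def test_low_growth_only_washout_stable(self):
        p = fixture("fig2a")
        pts = chemostat_fixed_points(p, include_simulation_starts=False)
        stable = [fp for fp in pts if fp.stable]
        assert [fp.label for fp in stable] == ["washout"]

    def test_all_residuals_small(self, eq3):
        scale = eq3.phi * eq3.s0_in
        for fp in chemostat_fixed_points(eq3):
            assert fp.residual <= 1e-9 * scale

    def test_steady_nutrients_zero_vector_field(self, eq3):
        pts = chemostat_fixed_points(eq3, include_simulation_starts=False)
        coex = [fp for fp in pts if fp.label == "coexistence"]
        for fp in coex:
            s = steady_nutrients(eq3, fp.coords[0], fp.coords[1])
            assert np.allclose(fp.coords[2:], s, atol=1e-8)

    def test_jacobian_matches_finite_differences(self, eq3):
        state = np.array([5.0, 7.0, 30.0, 1.5, 1.2])
        j = chemostat_jacobian(state, eq3)
        h = 1e-6
        num = np.zeros((5, 5))
        for k in range(5):
            dx = np.zeros(5)
            dx[k] = h * max(1.0, state[k])
            num[:, k] = (chemostat_rhs(state + dx, eq3, check=False)
                         - chemostat_rhs(state - dx, eq3, check=False)) \
                / (2 * dx[k])
        assert np.allclose(j, num, rtol=1e-4, atol=1e-5)

    def test_survival_pattern_matches_reduced_model(self, eq3):
        """Stable-state survival patterns agree between the chemostat and
        its reduction (printed growth-rate correspondence)."""
        chem = {fp.survival for fp in
                chemostat_fixed_points(eq3, include_simulation_starts=False)
                if fp.stable}
        lv = reduce_to_lv(eq3, mode="leading_order", r_scale="eq6")
        red = {fp.survival for fp in elv_fixed_points(lv) if fp.stable}
        assert chem == red
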