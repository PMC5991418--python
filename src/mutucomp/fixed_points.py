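"""Steady-state enumeration and linear stability for both models.

Reduced model: the extinction state E = (0, 0) and the boundary states
L1/L2 are available in closed form; interior coexistence states L12 are the
positive intersections of the two parabolic nullclines, found globally as
the roots of a quartic (companion-matrix eigenvalues) and polished by
Newton iteration.

Chemostat: at any steady state the dilution relations pin the nutrients to
``S_j = S̃_j + sum_i nu_ji X_i``, so the five-variable problem collapses to
the species densities.  Boundary states are bracketed scalar roots, interior
states come from multi-start Newton (deterministic starts — the washout
state, endpoints of simulations from a fixed set of initial densities, the
reduced-model predictions — plus seeded random starts), each polished on
the full five-variable system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import Polynomial
from scipy.optimize import brentq

from .model_core import EXTINCTION_EPS, chemostat_rhs, elv_rhs, simulate_to_steady
from .params import ChemostatParams, ExtendedLVParams
from .reduction import reduce_to_lv

#: tolerance on eigenvalue real parts when calling stability
STABILITY_TOL = 1e-9
#: relative tolerance for merging duplicate roots
DEDUP_RTOL = 1e-6
#: ten initial density pairs spanning [0, 20]^2 (corners, diagonal, flanks)
DEFAULT_PROTOCOL_ICS: tuple[tuple[float, float], ...] = (
    (0.5, 0.5), (20.0, 20.0), (20.0, 0.5), (0.5, 20.0), (4.0, 4.0),
    (12.0, 12.0), (4.0, 12.0), (12.0, 4.0), (20.0, 8.0), (8.0, 20.0),
)


@dataclass
class FixedPoint:
    """A steady state with its linearization.

    ``label`` is E/L1/L2/L12 for the reduced model and
    washout/single1/single2/coexistence for the chemostat; ``residual`` is
    the max-norm of the vector field at ``coords``.
    """

    coords: np.ndarray
    label: str
    eigenvalues: np.ndarray
    stable: bool
    verdict: str
    marginal: bool
    residual: float

    @property
    def survival(self) -> tuple[bool, bool]:
        return (bool(self.coords[0] > EXTINCTION_EPS),
                bool(self.coords[1] > EXTINCTION_EPS))


@dataclass
class NewtonResult:
    converged: bool
    x: np.ndarray
    iterations: int
    message: str = ""


def stability_of(eigenvalues, tol: float = STABILITY_TOL) -> tuple[str, bool]:
    """Classify a spectrum as stable / saddle / unstable.

    Returns ``(verdict, marginal)``; ``marginal`` is set when any real part
    lies within ``±tol`` of zero, in which case the verdict is undecidable
    at this tolerance.
    """
    re = np.real(np.asarray(eigenvalues, dtype=complex))
    if not np.all(np.isfinite(re)):
        raise ValueError("eigenvalues must be finite")
    marginal = bool(np.any(np.abs(re) <= tol))
    if np.all(re < -tol):
        return "stable", marginal
    if np.all(re > tol):
        return "unstable", marginal
    return "saddle", marginal


def newton_solve(rhs, jac, start, tol: float = 1e-10,
                 max_iter: int = 50) -> NewtonResult:
    """Damped Newton-Raphson root finder; never returns an unconverged point
    as converged."""
    x = np.asarray(start, dtype=float).copy()
    for it in range(max_iter + 1):
        f = np.asarray(rhs(x), dtype=float)
        if not np.all(np.isfinite(f)):
            return NewtonResult(False, x, it, "non-finite residual")
        if np.max(np.abs(f)) < tol:
            return NewtonResult(True, x, it)
        j = np.asarray(jac(x), dtype=float)
        try:
            step = np.linalg.solve(j, -f)
        except np.linalg.LinAlgError:
            return NewtonResult(False, x, it, "singular Jacobian")
        # backtracking on the residual norm
        lam, f0 = 1.0, np.max(np.abs(f))
        for _ in range(8):
            x_new = x + lam * step
            f_new = np.asarray(rhs(x_new), dtype=float)
            if np.all(np.isfinite(f_new)) and np.max(np.abs(f_new)) < f0:
                break
            lam *= 0.5
        else:
            x_new = x + step
        x = x_new
    return NewtonResult(False, x, max_iter, "max iterations reached")


# --------------------------------------------------------------------------
# reduced (extended Lotka-Volterra) model
# --------------------------------------------------------------------------

def elv_jacobian(p: ExtendedLVParams, x1: float, x2: float) -> np.ndarray:
    """Analytic Jacobian of the reduced vector field at ``(x1, x2)``."""
    g1 = p.r1 * (p.a1 - p.b11 * x1 + p.b12 * x2 - p.c1 * x2 * x2) - p.d
    g2 = p.r2 * (p.a2 - p.b22 * x2 + p.b21 * x1 - p.c2 * x1 * x1) - p.d
    return np.array([
        [g1 - p.r1 * p.b11 * x1, x1 * p.r1 * (p.b12 - 2 * p.c1 * x2)],
        [x2 * p.r2 * (p.b21 - 2 * p.c2 * x1), g2 - p.r2 * p.b22 * x2],
    ])


def _elv_point(p: ExtendedLVParams, coords, label: str,
               stability_tol: float = STABILITY_TOL) -> FixedPoint:
    coords = np.asarray(coords, dtype=float)
    eig = np.linalg.eigvals(elv_jacobian(p, coords[0], coords[1]))
    verdict, marginal = stability_of(eig, stability_tol)
    residual = float(np.max(np.abs(elv_rhs(coords[0], coords[1], p))))
    return FixedPoint(coords=coords, label=label, eigenvalues=eig,
                      stable=verdict == "stable", verdict=verdict,
                      marginal=marginal, residual=residual)


def _dedup(points: list[np.ndarray], rtol: float = DEDUP_RTOL) -> list[np.ndarray]:
    kept: list[np.ndarray] = []
    for x in points:
        scale = max(1.0, float(np.max(np.abs(x))))
        if not any(np.max(np.abs(x - y)) < rtol * scale for y in kept):
            kept.append(x)
    return kept


def elv_coexistence_roots(p: ExtendedLVParams, pos_tol: float = 1e-9
                          ) -> list[np.ndarray]:
    """All interior nullcline intersections, via the companion-matrix quartic.

    The alive branch of nullcline 1 gives ``X1 = P1(X2)`` explicitly;
    substituting into nullcline 2 leaves a polynomial of degree <= 4 in
    ``X2`` whose real roots with both densities positive are kept and
    Newton-polished.
    """
    alpha1 = p.a1 - p.d / p.r1
    alpha2 = p.a2 - p.d / p.r2
    p1 = Polynomial([alpha1, p.b12, -p.c1]) / p.b11
    g = Polynomial([alpha2, -p.b22]) + p.b21 * p1 - p.c2 * p1 ** 2
    coef = g.coef
    if np.max(np.abs(coef)) == 0:
        return []

    def percap(x):
        return np.array([
            p.r1 * (p.a1 - p.b11 * x[0] + p.b12 * x[1] - p.c1 * x[1] ** 2) - p.d,
            p.r2 * (p.a2 - p.b22 * x[1] + p.b21 * x[0] - p.c2 * x[0] ** 2) - p.d,
        ])

    def percap_jac(x):
        return np.array([
            [-p.r1 * p.b11, p.r1 * (p.b12 - 2 * p.c1 * x[1])],
            [p.r2 * (p.b21 - 2 * p.c2 * x[0]), -p.r2 * p.b22],
        ])

    roots: list[np.ndarray] = []
    for z in g.roots():
        if abs(z.imag) > 1e-7 * max(1.0, abs(z)):
            continue
        x2 = float(z.real)
        if x2 <= pos_tol:
            continue
        x1 = float(p1(x2))
        if x1 <= pos_tol:
            continue
        res = newton_solve(percap, percap_jac, np.array([x1, x2]), tol=1e-12)
        cand = res.x if res.converged else np.array([x1, x2])
        if cand[0] > pos_tol and cand[1] > pos_tol and \
                np.max(np.abs(percap(cand))) < 1e-8 * max(1.0, p.d):
            roots.append(cand)
    return _dedup(roots)


def elv_fixed_points(p: ExtendedLVParams, *, pos_tol: float = 1e-9,
                     stability_tol: float = STABILITY_TOL) -> list[FixedPoint]:
    """Enumerate E, L1, L2 and all L12 states with their stability."""
    out = [_elv_point(p, (0.0, 0.0), "E", stability_tol)]
    l1 = (p.a1 - p.d / p.r1) / p.b11
    if l1 > pos_tol:
        out.append(_elv_point(p, (l1, 0.0), "L1", stability_tol))
    l2 = (p.a2 - p.d / p.r2) / p.b22
    if l2 > pos_tol:
        out.append(_elv_point(p, (0.0, l2), "L2", stability_tol))
    for xy in elv_coexistence_roots(p, pos_tol):
        out.append(_elv_point(p, xy, "L12", stability_tol))
    return out


# --------------------------------------------------------------------------
# chemostat
# --------------------------------------------------------------------------

def steady_nutrients(p: ChemostatParams, x1: float, x2: float) -> np.ndarray:
    """Nutrient concentrations implied by the dilution relations at steady
    state: ``S_j = S̃_j + nu_j1 X1 + nu_j2 X2``."""
    return np.array([
        p.s0_in + p.nu01 * x1 + p.nu02 * x2,
        p.s1_in + p.nu11 * x1 + p.nu12 * x2,
        p.s2_in + p.nu21 * x1 + p.nu22 * x2,
    ])


def chemostat_jacobian(state, p: ChemostatParams) -> np.ndarray:
    """Analytic 5x5 Jacobian of the chemostat vector field."""
    x1, x2, s0, s1, s2 = np.asarray(state, dtype=float)
    m10 = s0 / (p.k10 + s0)
    m12 = s2 / (p.k12 + s2)
    m20 = s0 / (p.k20 + s0)
    m21 = s1 / (p.k21 + s1)
    f1 = p.mu1 * m10 * m12
    f2 = p.mu2 * m20 * m21
    df1_s0 = p.mu1 * p.k10 / (p.k10 + s0) ** 2 * m12
    df1_s2 = p.mu1 * m10 * p.k12 / (p.k12 + s2) ** 2
    df2_s0 = p.mu2 * p.k20 / (p.k20 + s0) ** 2 * m21
    df2_s1 = p.mu2 * m20 * p.k21 / (p.k21 + s1) ** 2
    j = np.zeros((5, 5))
    j[0] = [f1 - p.phi, 0.0, x1 * df1_s0, 0.0, x1 * df1_s2]
    j[1] = [0.0, f2 - p.phi, x2 * df2_s0, x2 * df2_s1, 0.0]
    for row, (nu1, nu2) in enumerate(
            [(p.nu01, p.nu02), (p.nu11, p.nu12), (p.nu21, p.nu22)], start=2):
        j[row, 0] = nu1 * f1
        j[row, 1] = nu2 * f2
        j[row, 2] = nu1 * x1 * df1_s0 + nu2 * x2 * df2_s0
        j[row, 3] = nu2 * x2 * df2_s1
        j[row, 4] = nu1 * x1 * df1_s2
        j[row, row] -= p.phi
    return j


def _chem_point(p: ChemostatParams, state, eps: float,
                stability_tol: float) -> FixedPoint:
    state = np.asarray(state, dtype=float)
    eig = np.linalg.eigvals(chemostat_jacobian(state, p))
    verdict, marginal = stability_of(eig, stability_tol)
    residual = float(np.max(np.abs(chemostat_rhs(state, p, check=False))))
    alive = (state[0] > eps, state[1] > eps)
    label = {(False, False): "washout", (True, False): "single1",
             (False, True): "single2", (True, True): "coexistence"}[alive]
    return FixedPoint(coords=state, label=label, eigenvalues=eig,
                      stable=verdict == "stable", verdict=verdict,
                      marginal=marginal, residual=residual)


def _density_cap(p: ChemostatParams) -> float:
    """Upper bound on feasible densities from carbon-source positivity."""
    drain = max(-p.nu01, -p.nu02, 1e-12)
    return (p.s0_in + p.s1_in + p.s2_in) / drain + 1.0


def _boundary_roots(p: ChemostatParams, species: int, n_scan: int = 400
                    ) -> list[float]:
    """Densities at which a lone species exactly balances dilution."""
    def excess(x: float) -> float:
        xs = (x, 0.0) if species == 1 else (0.0, x)
        s0, s1, s2 = steady_nutrients(p, *xs)
        if min(s0, s1, s2) < 0:
            return np.nan
        if species == 1:
            f = p.mu1 * s0 / (p.k10 + s0) * s2 / (p.k12 + s2)
        else:
            f = p.mu2 * s0 / (p.k20 + s0) * s1 / (p.k21 + s1)
        return f - p.phi

    cap = _density_cap(p)
    xs = np.linspace(1e-9, cap, n_scan)
    vals = np.array([excess(x) for x in xs])
    roots = []
    for i in range(len(xs) - 1):
        a, b = vals[i], vals[i + 1]
        if np.isnan(a) or np.isnan(b) or a * b > 0:
            continue
        try:
            roots.append(brentq(excess, xs[i], xs[i + 1], xtol=1e-12))
        except ValueError:
            continue
    return [r for r in roots if r > 1e-9]


def chemostat_fixed_points(
    p: ChemostatParams,
    n_starts: int = 16,
    seed: int = 0,
    *,
    include_simulation_starts: bool = True,
    eps: float = EXTINCTION_EPS,
    stability_tol: float = STABILITY_TOL,
) -> list[FixedPoint]:
    """Enumerate chemostat steady states.

    The washout state (densities zero, nutrients at inflow) is exact and
    always present.  Boundary states come from a bracketed scalar solve on
    the dilution-relation manifold; interior states from multi-start Newton
    on the two-density system, with starts from a density grid, the
    reduced-model prediction, seeded random draws and (optionally) endpoints
    of simulations from the fixed initial-density protocol.  Every candidate
    is polished by Newton on the full five-variable system and kept only if
    its residual is below tolerance.
    """
    cap = _density_cap(p)
    washout = np.array([0.0, 0.0, p.s0_in, p.s1_in, p.s2_in])
    out = [_chem_point(p, washout, eps, stability_tol)]
    states: list[np.ndarray] = []

    for sp in (1, 2):
        for x in _boundary_roots(p, sp):
            xs = (x, 0.0) if sp == 1 else (0.0, x)
            states.append(np.concatenate([xs, steady_nutrients(p, *xs)]))

    # interior candidates on the two-density manifold
    def percap(x):
        s = steady_nutrients(p, x[0], x[1])
        if np.min(s) < -1e-9:
            return np.array([np.nan, np.nan])
        s = np.clip(s, 0.0, None)
        f1 = p.mu1 * s[0] / (p.k10 + s[0]) * s[2] / (p.k12 + s[2])
        f2 = p.mu2 * s[0] / (p.k20 + s[0]) * s[1] / (p.k21 + s[1])
        return np.array([f1 - p.phi, f2 - p.phi])

    def percap_jac(x, h=1e-7):
        j = np.zeros((2, 2))
        for k in range(2):
            dx = np.zeros(2)
            dx[k] = h * max(1.0, abs(x[k]))
            j[:, k] = (percap(x + dx) - percap(x - dx)) / (2 * dx[k])
        return j

    starts: list[np.ndarray] = []
    grid = np.linspace(0.05, 0.95, 5) * cap / 2
    starts.extend(np.array([u, v]) for u in grid for v in grid)
    try:
        starts.extend(elv_coexistence_roots(reduce_to_lv(p, mode="full")))
    except Exception:
        pass
    rng = np.random.default_rng(seed)
    lo, hi = np.log(1e-3), np.log(cap)
    starts.extend(np.exp(rng.uniform(lo, hi, size=(n_starts, 2))))
    if include_simulation_starts:
        for ic in DEFAULT_PROTOCOL_ICS:
            init = np.array([ic[0], ic[1], p.s0_in, p.s1_in, p.s2_in])
            try:
                end, _ = simulate_to_steady("chemostat", p, init,
                                            max_doublings=1, rtol=1e-6,
                                            atol=1e-9)
            except Exception:
                continue
            if end[0] > eps and end[1] > eps:
                starts.append(end[:2])

    for s0 in starts:
        res = newton_solve(percap, percap_jac, np.asarray(s0, float), tol=1e-10)
        if not res.converged:
            continue
        x1, x2 = res.x
        if x1 <= 1e-9 or x2 <= 1e-9:
            continue
        snut = steady_nutrients(p, x1, x2)
        if np.min(snut) < -1e-9:
            continue
        states.append(np.concatenate([[x1, x2], snut]))

    # polish on the full system and keep verified roots
    full_rhs = lambda y: chemostat_rhs(y, p, check=False)
    full_jac = lambda y: chemostat_jacobian(y, p)
    scale = max(1.0, p.phi * p.s0_in)
    polished: list[np.ndarray] = []
    for y0 in states:
        res = newton_solve(full_rhs, full_jac, y0, tol=1e-9 * scale)
        if res.converged and np.min(res.x[:2]) > -1e-9 and np.min(res.x[2:]) > -1e-9:
            polished.append(np.clip(res.x, 0.0, None))
    for y in _dedup(polished):
        if np.max(np.abs(y[:2] - washout[:2])) < 1e-6:
            continue
        out.append(_chem_point(p, y, eps, stability_tol))
    return out
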