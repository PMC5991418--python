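"""Right-hand sides, simulation driver and outcome classification.

The chemostat model tracks two species densities and three nutrient
concentrations; growth is a product of two Monod factors (each species
strictly requires both the carbon source and its partner's metabolite).
The reduced model tracks only the densities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .params import ChemostatParams, ExtendedLVParams, InvalidParameterError

#: default extinction threshold in density units
EXTINCTION_EPS = 1e-6


class SimulationError(RuntimeError):
    """Raised when the ODE integrator fails or produces non-finite states."""


def monod(s, k):
    """Saturating growth factor ``s / (k + s)``.

    Rises monotonically from 0 towards 1; ``k`` is the half-saturation
    concentration (``monod(k, k) == 0.5``).
    """
    s = np.asarray(s, dtype=float)
    if np.any(np.asarray(k) <= 0):
        raise InvalidParameterError(f"half-saturation constant must be > 0, got {k}")
    if np.any(s < 0):
        raise InvalidParameterError(f"concentration must be >= 0, got {s}")
    out = s / (k + s)
    return out.item() if out.ndim == 0 else out


def growth_rate(species: int, s0, scross, p: ChemostatParams):
    """Double-Monod growth rate of one species.

    Species 1 grows on the carbon source ``s0`` and its partner's metabolite
    ``s2``; species 2 on ``s0`` and ``s1``.  ``scross`` is the relevant
    cross-feeding nutrient concentration.  Bounded above by ``mu_i``.
    """
    if species == 1:
        return p.mu1 * monod(s0, p.k10) * monod(scross, p.k12)
    if species == 2:
        return p.mu2 * monod(s0, p.k20) * monod(scross, p.k21)
    raise ValueError(f"species index must be 1 or 2, got {species}")


def chemostat_rhs(state, p: ChemostatParams, *, check: bool = True):
    """Time derivatives of ``(X1, X2, S0, S1, S2)``.

    Species balance growth against dilution; each nutrient is diluted towards
    its inflow concentration and produced/consumed proportionally to growth
    (``nu > 0``: production, ``nu < 0``: consumption).
    """
    state = np.asarray(state, dtype=float)
    if check and np.any(state < 0):
        raise InvalidParameterError(f"negative state component: {state}")
    x1, x2, s0, s1, s2 = state
    f1 = p.mu1 * (s0 / (p.k10 + s0)) * (s2 / (p.k12 + s2))
    f2 = p.mu2 * (s0 / (p.k20 + s0)) * (s1 / (p.k21 + s1))
    g1 = f1 * x1
    g2 = f2 * x2
    return np.array([
        (f1 - p.phi) * x1,
        (f2 - p.phi) * x2,
        p.phi * (p.s0_in - s0) + p.nu01 * g1 + p.nu02 * g2,
        p.phi * (p.s1_in - s1) + p.nu11 * g1 + p.nu12 * g2,
        p.phi * (p.s2_in - s2) + p.nu21 * g1 + p.nu22 * g2,
    ])


def elv_rhs(x1, x2, p: ExtendedLVParams):
    """Time derivatives of ``(X1, X2)`` in the reduced model."""
    g1 = p.r1 * (p.a1 - p.b11 * x1 + p.b12 * x2 - p.c1 * x2 * x2) - p.d
    g2 = p.r2 * (p.a2 - p.b22 * x2 + p.b21 * x1 - p.c2 * x1 * x1) - p.d
    return np.array([g1 * x1, g2 * x2])


def rhs_for(model: str, params):
    """Vector-field closure ``f(y) -> dy/dt`` for ``model`` in {chemostat, elv}."""
    if model == "chemostat":
        return lambda y: chemostat_rhs(y, params, check=False)
    if model == "elv":
        return lambda y: elv_rhs(y[0], y[1], params)
    raise ValueError(f"model must be 'chemostat' or 'elv', got {model!r}")


@dataclass
class Trajectory:
    """Uniform-grid ODE solution with its model tag."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, n_vars)
    model: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape[0] != self.times.shape[0]:
            raise ValueError("state count must equal time count")

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def column_names(self) -> list[str]:
        if self.model == "chemostat":
            return ["t", "X1", "X2", "S0", "S1", "S2"]
        return ["t", "X1", "X2"]


@dataclass
class OutcomePattern:
    """Survival verdict of a finished simulation."""

    survives1: bool
    survives2: bool
    final_state: np.ndarray
    converged: bool = True

    @property
    def pattern(self) -> tuple[bool, bool]:
        return (self.survives1, self.survives2)


def simulate(
    model: str,
    params,
    init,
    t_end: float | None = None,
    n_out: int = 200,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate either model from ``init`` and return a uniform-grid trajectory.

    ``t_end`` defaults to 50 dilution times (``50/phi`` for the chemostat,
    ``50/d`` for the reduced model with a floor for ``d == 0``).
    """
    init = np.asarray(init, dtype=float)
    if np.any(init < 0):
        raise InvalidParameterError(f"initial state must be nonnegative: {init}")
    if t_end is None:
        rate = params.phi if model == "chemostat" else max(params.d, 1e-2)
        t_end = 50.0 / rate
    if not t_end > 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    f = rhs_for(model, params)
    times = np.linspace(0.0, t_end, n_out)
    sol = solve_ivp(
        lambda t, y: f(y), (0.0, t_end), init,
        t_eval=times, method=method, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise SimulationError(f"integrator failed: {sol.message}")
    states = sol.y.T
    if not np.all(np.isfinite(states)):
        raise SimulationError("non-finite values in simulated states")
    return Trajectory(times=times, states=states, model=model)


def final_state(
    model: str,
    params,
    init,
    t_end: float,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> np.ndarray:
    """Endpoint-only integration (no intermediate output grid)."""
    init = np.asarray(init, dtype=float)
    f = rhs_for(model, params)
    sol = solve_ivp(
        lambda t, y: f(y), (0.0, t_end), init,
        method=method, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise SimulationError(f"integrator failed: {sol.message}")
    y = sol.y[:, -1]
    if not np.all(np.isfinite(y)):
        raise SimulationError("non-finite values in simulated states")
    return y


def simulate_to_steady(
    model: str,
    params,
    init,
    *,
    t_end: float | None = None,
    max_doublings: int = 3,
    conv_tol: float = 1e-7,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[np.ndarray, bool]:
    """Integrate until the vector field is numerically quiescent.

    Returns ``(endpoint, converged)``; the horizon starts at 100 dilution
    times and doubles up to ``max_doublings`` times if the scaled derivative
    norm still exceeds ``conv_tol``.
    """
    if t_end is None:
        rate = params.phi if model == "chemostat" else max(params.d, 1e-2)
        t_end = 100.0 / rate
    f = rhs_for(model, params)
    y = np.asarray(init, dtype=float)
    for _ in range(max_doublings + 1):
        y = final_state(model, params, np.clip(y, 0.0, None), t_end,
                        rtol=rtol, atol=atol)
        scale = max(1.0, float(np.max(np.abs(y))))
        if np.max(np.abs(f(y))) / scale < conv_tol:
            return y, True
        t_end *= 2.0
    return y, False


def classify_outcome(
    traj: Trajectory,
    eps: float = EXTINCTION_EPS,
    *,
    params=None,
    conv_tol: float = 1e-6,
) -> OutcomePattern:
    """Survival verdict from a trajectory's endpoint.

    Species *i* survives when its final density exceeds ``eps`` (round-off
    negatives are clipped to zero first).  If ``params`` is given the final
    derivative norm is checked and a non-converged run is flagged with a
    warning rather than an error.
    """
    final = np.clip(traj.final_state, 0.0, None)
    converged = True
    if params is not None:
        f = rhs_for(traj.model, params)
        scale = max(1.0, float(np.max(np.abs(final))))
        if np.max(np.abs(f(final))) / scale > conv_tol:
            converged = False
            warnings.warn("trajectory has not converged to a steady state",
                          stacklevel=2)
    return OutcomePattern(
        survives1=bool(final[0] > eps),
        survives2=bool(final[1] > eps),
        final_state=final,
        converged=converged,
    )
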