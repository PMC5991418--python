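"""Nullclines and basins of attraction for the reduced model.

The alive branch of each nullcline is a downward parabola in the partner
density; the dead branch is the coordinate axis.  Basins are mapped by
integrating from every cell of a density grid and matching the endpoint to
the nearest stable steady state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fixed_points import FixedPoint, elv_fixed_points
from .model_core import simulate_to_steady
from .params import ExtendedLVParams, InvalidParameterError

#: sentinel label for grid cells that did not converge to any attractor
NON_CONVERGED = -1


@dataclass
class NullclineCurve:
    """Explicit alive branch of one species' nullcline on a partner grid."""

    species: int
    other: np.ndarray      # partner density grid (X_j)
    own: np.ndarray        # X_i on the alive branch
    negative: np.ndarray   # True where the branch leaves the positive quadrant


def nullcline(p: ExtendedLVParams, species: int, other_grid) -> NullclineCurve:
    """Alive-branch nullcline ``X_i = (a_i - d/r_i + b_ij X_j - c_i X_j^2)/b_ii``.

    Points with negative ``X_i`` are returned but flagged (they lie outside
    the biological quadrant).  The dead branch is the ``X_i = 0`` axis and
    needs no evaluation.
    """
    other = np.asarray(other_grid, dtype=float)
    if species == 1:
        if p.b11 == 0:
            raise InvalidParameterError("b11 must be nonzero")
        own = (p.a1 - p.d / p.r1 + p.b12 * other - p.c1 * other**2) / p.b11
    elif species == 2:
        if p.b22 == 0:
            raise InvalidParameterError("b22 must be nonzero")
        own = (p.a2 - p.d / p.r2 + p.b21 * other - p.c2 * other**2) / p.b22
    else:
        raise ValueError(f"species index must be 1 or 2, got {species}")
    return NullclineCurve(species=species, other=other, own=own,
                          negative=own < 0)


@dataclass
class GridSpec:
    x1_max: float
    x2_max: float
    n1: int = 101
    n2: int = 101
    x1_min: float = 0.0
    x2_min: float = 0.0

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.linspace(self.x1_min, self.x1_max, self.n1),
                np.linspace(self.x2_min, self.x2_max, self.n2))


@dataclass
class BasinMap:
    """Per-cell attractor assignment over a density grid.

    ``labels[i, j]`` indexes ``attractors`` for the cell at
    ``(x1_grid[i], x2_grid[j])``; ``NON_CONVERGED`` marks cells whose
    endpoint matched no attractor.
    """

    x1_grid: np.ndarray
    x2_grid: np.ndarray
    labels: np.ndarray
    attractors: list[FixedPoint]
    n_non_converged: int


def default_grid(p: ExtendedLVParams, n: int = 101) -> GridSpec:
    """Grid covering 1.5x the largest attractor coordinate (floor of 10)."""
    pts = [fp for fp in elv_fixed_points(p) if fp.stable]
    top = max((float(np.max(fp.coords)) for fp in pts), default=10.0)
    lim = max(1.5 * top, 10.0)
    return GridSpec(x1_max=lim, x2_max=lim, n1=n, n2=n)


def basin_map(
    p: ExtendedLVParams,
    grid: GridSpec | None = None,
    t_end: float = 400.0,
    *,
    match_rtol: float = 1e-3,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> BasinMap:
    """Assign every grid cell to the stable steady state it converges to.

    Deterministic for a fixed grid and integrator settings.  Matching radius
    is ``match_rtol`` relative to the attractor norm with an absolute floor
    of ``match_rtol`` (so the origin attracts endpoints below that floor).
    """
    attractors = [fp for fp in elv_fixed_points(p) if fp.stable]
    if not attractors:
        raise ValueError("no stable fixed point: basin map undefined")
    if grid is None:
        grid = default_grid(p)
    x1s, x2s = grid.centers()
    labels = np.full((len(x1s), len(x2s)), NON_CONVERGED, dtype=int)
    n_bad = 0
    coords = np.array([fp.coords for fp in attractors])
    radii = np.maximum(match_rtol * np.linalg.norm(coords, axis=1), match_rtol)
    for i, x1 in enumerate(x1s):
        for j, x2 in enumerate(x2s):
            end, ok = simulate_to_steady(
                "elv", p, (x1, x2), t_end=t_end, max_doublings=2,
                rtol=rtol, atol=atol)
            end = np.clip(end, 0.0, None)
            dists = np.linalg.norm(coords - end, axis=1)
            k = int(np.argmin(dists))
            if ok and dists[k] <= radii[k]:
                labels[i, j] = k
            else:
                n_bad += 1
    return BasinMap(x1_grid=x1s, x2_grid=x2s, labels=labels,
                    attractors=attractors, n_non_converged=n_bad)
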