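"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings
from scipy.optimize import brentq

from mutucomp import ExtendedLVParams, fixture

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def eq3():
    return fixture("eq3")


@pytest.fixture(scope="session")
def eq6():
    return fixture("eq6")


def random_elv_params(rng: np.random.Generator) -> ExtendedLVParams:
    """Draw a valid reduced-model parameter set with diverse root structure."""
    def lu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return ExtendedLVParams(
        d=lu(0.5, 5.0),
        r1=lu(0.01, 0.1), r2=lu(0.01, 0.1),
        a1=lu(10.0, 100.0), a2=lu(10.0, 100.0),
        b11=lu(1.0, 10.0), b22=lu(1.0, 10.0),
        b12=lu(0.5, 20.0), b21=lu(0.5, 20.0),
        c1=lu(0.05, 0.5), c2=lu(0.05, 0.5),
    )


def brute_force_coexistence(p: ExtendedLVParams, n_grid: int = 40001,
                            pos_tol: float = 1e-9) -> list[np.ndarray]:
    """Brute-force interior nullcline intersections.

    Independent of the package's quartic route: the alive branch of
    nullcline 1 is sampled densely on the partner interval where it is
    positive, the residual of nullcline 2 along it is bracketed for sign
    changes, and each bracket is refined with a scalar root finder.
    """
    alpha1 = p.a1 - p.d / p.r1
    alpha2 = p.a2 - p.d / p.r2

    def x1_of(x2):
        return (alpha1 + p.b12 * x2 - p.c1 * x2 ** 2) / p.b11

    def resid(x2):
        x1 = x1_of(x2)
        return alpha2 - p.b22 * x2 + p.b21 * x1 - p.c2 * x1 ** 2

    # partner interval where the alive branch is positive
    disc = p.b12 ** 2 + 4 * p.c1 * alpha1
    if disc <= 0:
        return []
    lo = (p.b12 - np.sqrt(disc)) / (2 * p.c1)
    hi = (p.b12 + np.sqrt(disc)) / (2 * p.c1)
    lo = max(lo, 0.0) + 1e-12
    if hi <= lo:
        return []
    grid = np.linspace(lo, hi - 1e-12, n_grid)
    vals = resid(grid)
    roots: list[np.ndarray] = []
    sign_change = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
    for i in sign_change:
        x2 = brentq(resid, grid[i], grid[i + 1], xtol=1e-13, rtol=1e-15)
        x1 = x1_of(x2)
        if x1 > pos_tol and x2 > pos_tol:
            roots.append(np.array([x1, x2]))
    # exact zeros on grid nodes (measure zero for random draws)
    for i in np.nonzero(vals == 0)[0]:
        x2 = float(grid[i])
        x1 = x1_of(x2)
        if x1 > pos_tol and x2 > pos_tol:
            roots.append(np.array([x1, x2]))
    dedup: list[np.ndarray] = []
    for r in roots:
        if not any(np.max(np.abs(r - s)) < 1e-6 * max(1.0, np.max(np.abs(r)))
                   for s in dedup):
            dedup.append(r)
    return dedup


def match_root_sets(found, expected, tol=1e-6) -> bool:
    """True when two root sets agree pairwise within ``tol`` (relative)."""
    if len(found) != len(expected):
        return False
    remaining = list(expected)
    for f in found:
        for i, e in enumerate(remaining):
            if np.max(np.abs(f - e)) < tol * max(1.0, float(np.max(np.abs(e)))):
                remaining.pop(i)
                break
        else:
            return False
    return True
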