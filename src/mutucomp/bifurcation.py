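"""Regime classification, two-parameter scans and one-parameter branch
tracing with saddle-node / transcritical detection.

Regimes are named by which steady states are stable:

====  =======================  ==========================================
code  stable set               meaning
====  =======================  ==========================================
R1    {E}                      extinction of both species
R2    {L1}                     competitive exclusion, species 1 survives
R3    {L2}                     competitive exclusion, species 2 survives
R4    {E, L12}                 bistability extinction / coexistence
R5    {L1, L12}                bistability survival-of-1 / coexistence
R6    {L2, L12}                bistability survival-of-2 / coexistence
R7    {L12}                    coexistence for all initial densities
====  =======================  ==========================================

Any other stable set (e.g. two stable coexistence states) is labelled
``other``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fixed_points import (
    DEFAULT_PROTOCOL_ICS,
    FixedPoint,
    chemostat_fixed_points,
    elv_fixed_points,
)
from .model_core import EXTINCTION_EPS, simulate_to_steady
from .params import ChemostatParams, ExtendedLVParams
from .reduction import reduce_to_lv

_CHEM_TO_ELV_LABEL = {"washout": "E", "single1": "L1", "single2": "L2",
                      "coexistence": "L12"}
_REGIME_OF_SET = {
    frozenset({"E"}): "R1",
    frozenset({"L1"}): "R2",
    frozenset({"L2"}): "R3",
    frozenset({"E", "L12"}): "R4",
    frozenset({"L1", "L12"}): "R5",
    frozenset({"L2", "L12"}): "R6",
    frozenset({"L12"}): "R7",
}


@dataclass(frozen=True)
class RegimeLabel:
    code: str                     # R1..R7 or "other"
    stable_set: frozenset[str]    # which of E/L1/L2/L12 are stable


def regime_from_stable_labels(labels: list[str]) -> RegimeLabel:
    """Map a multiset of stable-state labels to a regime code.

    Two stable states with the same label (e.g. two coexistence states) do
    not fit the seven-regime taxonomy and yield ``other``.
    """
    if len(labels) != len(set(labels)):
        return RegimeLabel("other", frozenset(labels))
    s = frozenset(labels)
    return RegimeLabel(_REGIME_OF_SET.get(s, "other"), s)


def regime_classify(model: str, params, **fp_kwargs) -> RegimeLabel:
    """Classify a parameter set by enumerating its stable steady states."""
    if model == "elv":
        pts = elv_fixed_points(params)
        stable = [fp.label for fp in pts if fp.stable]
    elif model == "chemostat":
        pts = chemostat_fixed_points(params, **fp_kwargs)
        stable = [_CHEM_TO_ELV_LABEL[fp.label] for fp in pts if fp.stable]
    else:
        raise ValueError(f"model must be 'chemostat' or 'elv', got {model!r}")
    if not stable:
        return RegimeLabel("other", frozenset())
    return regime_from_stable_labels(stable)


def regime_from_simulations(
    model: str,
    params,
    ics=DEFAULT_PROTOCOL_ICS,
    *,
    eps: float = EXTINCTION_EPS,
    cluster_rtol: float = 1e-3,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> RegimeLabel:
    """Classify by simulating from a set of initial densities.

    Endpoints are clustered and each distinct attractor is labelled by its
    survival pattern — the protocol behind the time-simulation panels
    (initial densities spread over [0, 20], nutrients starting at inflow).
    """
    attractors: list[np.ndarray] = []
    for ic in ics:
        if model == "chemostat":
            init = np.array([ic[0], ic[1],
                             params.s0_in, params.s1_in, params.s2_in])
        else:
            init = np.asarray(ic, dtype=float)
        end, ok = simulate_to_steady(model, params, init, rtol=rtol, atol=atol)
        if not ok:
            continue
        end = np.clip(end, 0.0, None)
        end[:2] = np.where(end[:2] > eps, end[:2], 0.0)
        scale = max(1.0, float(np.max(np.abs(end))))
        if not any(np.max(np.abs(end - a)) < cluster_rtol * scale
                   for a in attractors):
            attractors.append(end)
    labels = []
    for a in attractors:
        alive = (a[0] > eps, a[1] > eps)
        labels.append({(False, False): "E", (True, False): "L1",
                       (False, True): "L2", (True, True): "L12"}[alive])
    if not labels:
        return RegimeLabel("other", frozenset())
    return regime_from_stable_labels(labels)


# --------------------------------------------------------------------------
# two-parameter scans
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AxisSpec:
    """One scan axis: a parameter field name and a sampling grid."""

    name: str
    lo: float
    hi: float
    n: int
    log: bool = False

    def values(self) -> np.ndarray:
        if self.log:
            return np.geomspace(self.lo, self.hi, self.n)
        return np.linspace(self.lo, self.hi, self.n)


@dataclass
class RegimeMap:
    axis1: AxisSpec
    axis2: AxisSpec
    codes: np.ndarray           # shape (axis1.n, axis2.n), dtype object/str
    counts: dict[str, int] = field(default_factory=dict)


def scan_2d(model: str, axis1: AxisSpec, axis2: AxisSpec, base,
            **fp_kwargs) -> RegimeMap:
    """Classify every cell of a two-parameter grid.

    Per-cell failures are recorded as ``other`` and never abort the scan.
    For the chemostat, cells where Newton enumeration finds no stable state
    fall back to the simulation protocol.
    """
    v1, v2 = axis1.values(), axis2.values()
    codes = np.empty((axis1.n, axis2.n), dtype=object)
    for i, a in enumerate(v1):
        for j, b in enumerate(v2):
            params = base.replace(**{axis1.name: a, axis2.name: b})
            try:
                lab = regime_classify(model, params, **fp_kwargs)
                if not lab.stable_set and model == "chemostat":
                    lab = regime_from_simulations(model, params)
                codes[i, j] = lab.code
            except Exception:
                codes[i, j] = "other"
    uniq, cnt = np.unique(codes.astype(str), return_counts=True)
    return RegimeMap(axis1=axis1, axis2=axis2, codes=codes,
                     counts=dict(zip(uniq.tolist(), cnt.tolist())))


def regime_agreement(
    base: ChemostatParams,
    mu_lo: float,
    mu_hi: float,
    n: int = 21,
    *,
    r_scale: float | str = "eq6",
    **fp_kwargs,
) -> tuple[float, RegimeMap, RegimeMap]:
    """Cellwise regime agreement between the chemostat and its reduction.

    Both models are scanned over the same growth-rate grid; the reduced
    model's cell uses the parameter mapping (leading order, with the stated
    growth-rate scale) applied to the chemostat cell.  Returns the agreeing
    cell fraction plus the two maps.
    """
    ax1 = AxisSpec("mu1", mu_lo, mu_hi, n)
    ax2 = AxisSpec("mu2", mu_lo, mu_hi, n)
    chem = scan_2d("chemostat", ax1, ax2, base,
                   include_simulation_starts=False, **fp_kwargs)
    codes = np.empty((n, n), dtype=object)
    for i, m1 in enumerate(ax1.values()):
        for j, m2 in enumerate(ax2.values()):
            p = reduce_to_lv(base.replace(mu1=m1, mu2=m2),
                             mode="leading_order", r_scale=r_scale)
            codes[i, j] = regime_classify("elv", p).code
    uniq, cnt = np.unique(codes.astype(str), return_counts=True)
    elv = RegimeMap(axis1=ax1, axis2=ax2, codes=codes,
                    counts=dict(zip(uniq.tolist(), cnt.tolist())))
    agree = float(np.mean(chem.codes.astype(str) == elv.codes.astype(str)))
    return agree, chem, elv


# --------------------------------------------------------------------------
# one-parameter branch tracing
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BifurcationPoint:
    kind: str        # "SN" or "T"
    value: float     # sweep-parameter value
    detail: str = ""


@dataclass
class BranchDiagram:
    values: np.ndarray                   # sweep-parameter grid
    points: list[list[FixedPoint]]       # fixed points at each sweep value
    bifurcations: list[BifurcationPoint]


def symmetric_closed_forms(p: ExtendedLVParams, rtol: float = 1e-9
                           ) -> tuple[float, float, str]:
    """Closed-form bifurcation points of the symmetric growth-rate sweep.

    Requires the species-symmetric parameter set (``a1 = a2``,
    ``b11 = b22``, ``b12 = b21``, ``c1 = c2``).  On the diagonal the
    coexistence pair solves ``c X^2 - (b12 - b11) X + (d/r - a) = 0``; the
    saddle-node sits at zero discriminant, ``r_SN = d / (a + (b12 -
    b11)^2 / (4 c))``, and extinction loses stability transcritically at
    ``r_T = d / a``.  Returns ``(r_SN, r_T, audit)``.
    """
    pairs = [(p.a1, p.a2), (p.b11, p.b22), (p.b12, p.b21), (p.c1, p.c2)]
    for u, v in pairs:
        if abs(u - v) > rtol * max(abs(u), abs(v), 1.0):
            raise ValueError("closed forms require a species-symmetric set")
    if p.c1 <= 0:
        raise ValueError("closed forms require c > 0")
    r_t = p.d / p.a1 if p.a1 > 0 else np.inf
    denom = p.a1 + (p.b12 - p.b11) ** 2 / (4 * p.c1)
    r_sn = p.d / denom
    audit = (f"r_T = d/a = {p.d:.6g}/{p.a1:.6g}; "
             f"r_SN = d/(a + (b12-b11)^2/(4c)) = {p.d:.6g}/{denom:.6g}")
    return r_sn, r_t, audit


def _n_coexistence(p: ExtendedLVParams, r: float) -> int:
    q = p.replace(r1=r, r2=r)
    return sum(1 for fp in elv_fixed_points(q) if fp.label == "L12")


def _max_re_eig_origin(p: ExtendedLVParams, r: float) -> float:
    return max(r * p.a1 - p.d, r * p.a2 - p.d)


def _bisect(f, lo: float, hi: float, n_iter: int = 60) -> float:
    flo = f(lo)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if f(mid) == flo if isinstance(flo, bool) else f(mid) * flo > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12 * max(1.0, abs(hi)):
            break
    return 0.5 * (lo + hi)


def branch_trace_1d(p: ExtendedLVParams, lo: float, hi: float, n: int = 201
                    ) -> BranchDiagram:
    """Trace all fixed-point branches along a symmetric growth-rate sweep.

    The sweep sets ``r1 = r2 = r``.  A saddle-node (SN) is reported where
    the number of coexistence states changes between consecutive sweep
    values (refined by bisection on the count); a transcritical (T) where
    the extinction state's leading eigenvalue crosses zero (refined on its
    sign).
    """
    values = np.linspace(lo, hi, n)
    points = [elv_fixed_points(p.replace(r1=r, r2=r)) for r in values]
    bifs: list[BifurcationPoint] = []

    def _lost_root_exits_boundary(r_star: float) -> bool:
        # distinguish a fold (two interior roots merge) from a boundary exit
        # (a root's coordinate passes through zero, i.e. a transcritical)
        delta = max(1e-7 * abs(r_star), 1e-10)
        sides = []
        for r in (r_star - delta, r_star + delta):
            q = p.replace(r1=r, r2=r)
            sides.append([fp.coords for fp in elv_fixed_points(q)
                          if fp.label == "L12"])
        rich, poor = (sides[0], sides[1]) if len(sides[0]) > len(sides[1]) \
            else (sides[1], sides[0])
        lost = []
        for x in rich:
            scale = max(1.0, float(np.max(np.abs(x))))
            if not any(np.max(np.abs(x - y)) < 1e-2 * scale for y in poor):
                lost.append(x)
        if not lost:
            return False
        return all(float(np.min(x)) < 1e-3 * max(1.0, float(np.max(x)))
                   for x in lost)

    counts = [sum(1 for fp in pts if fp.label == "L12") for pts in points]
    for i in range(n - 1):
        if counts[i] != counts[i + 1]:
            c0 = counts[i]
            r_star = _bisect(lambda r: _n_coexistence(p, r) == c0,
                             values[i], values[i + 1])
            if _lost_root_exits_boundary(r_star):
                bifs.append(BifurcationPoint(
                    "T", r_star,
                    "coexistence state exits through the boundary"))
            else:
                bifs.append(BifurcationPoint(
                    "SN", r_star,
                    f"coexistence count {counts[i]} -> {counts[i + 1]}"))

    eigs = [_max_re_eig_origin(p, r) for r in values]
    for i in range(n - 1):
        if eigs[i] == 0.0:
            bifs.append(BifurcationPoint("T", float(values[i]),
                                         "extinction state marginal"))
        elif eigs[i] * eigs[i + 1] < 0:
            r_star = _bisect(lambda r: _max_re_eig_origin(p, r),
                             values[i], values[i + 1])
            bifs.append(BifurcationPoint(
                "T", r_star, "extinction state exchanges stability"))
    bifs.sort(key=lambda b: b.value)
    merged: list[BifurcationPoint] = []
    for b in bifs:
        if merged and merged[-1].kind == b.kind and \
                abs(merged[-1].value - b.value) < 1e-6 * max(1.0, abs(b.value)):
            continue
        merged.append(b)
    return BranchDiagram(values=values, points=points, bifurcations=merged)
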