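"""Monte-Carlo survey of how often random chemostat parameter sets are
bistable.

Each draw is simulated from a fixed spread of initial densities; a draw
counts as bistable when the converged endpoints cluster into at least two
distinct attractors.  The default sampling is log-uniform over two decades
centred on the reference chemostat set, with the production/consumption
sign pattern of the cross-feeding scheme held fixed; the constrained mode
pins a high carbon-source inflow and draws low inflows of the exchanged
metabolites, the operating regime that strengthens the mutualistic
feedback.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import beta

from .fixed_points import DEFAULT_PROTOCOL_ICS, chemostat_fixed_points
from .fixtures import EQ3_CHEMOSTAT
from .model_core import EXTINCTION_EPS, simulate_to_steady
from .params import ChemostatParams

_FIELD_ORDER = (
    "phi", "mu1", "mu2", "s0_in", "s1_in", "s2_in",
    "k10", "k12", "k20", "k21",
    "nu01", "nu02", "nu11", "nu12", "nu21", "nu22",
)


@dataclass(frozen=True)
class SamplingSpec:
    """Per-parameter sampling plan.

    ``ranges`` maps each chemostat field either to a fixed value (float) or
    to log-uniform magnitude bounds ``(lo, hi)``; signs of the ``nu`` fields
    are carried separately so the production/consumption scheme is
    preserved.
    """

    n: int
    seed: int = 0
    constrained: bool = False
    ranges: dict[str, float | tuple[float, float]] = field(default_factory=dict)
    signs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for name, rng in self.ranges.items():
            if isinstance(rng, tuple):
                lo, hi = rng
                if not (0 < lo <= hi):
                    raise ValueError(
                        f"bounds for {name} must be positive and ordered, "
                        f"got {rng}")


def default_spec(n: int, seed: int = 0, constrained: bool = False
                 ) -> SamplingSpec:
    """Default sampling plans for the two survey modes.

    Kinetic constants (flow rate, maximal growth rates, half-saturations,
    production/consumption magnitudes) are log-uniform over two decades
    centred on the reference set in both modes.  The nutrient inflows
    differ: the unconstrained mode treats the three nutrients exchangeably
    and draws every inflow from one shared range spanning the union of the
    per-nutrient spans (0.1 to 500), so no nutrient is privileged a priori;
    the constrained mode pins a high carbon inflow (S̃0 = 50) and draws low
    metabolite inflows from [0.1, 2], the operating regime that strengthens
    the cross-feeding feedback.
    """
    ref = EQ3_CHEMOSTAT.to_dict()
    ranges: dict[str, float | tuple[float, float]] = {}
    signs: dict[str, float] = {}
    for name in _FIELD_ORDER:
        v = ref[name]
        mag = abs(v)
        ranges[name] = (mag / 10.0, mag * 10.0)
        signs[name] = 1.0 if v >= 0 else -1.0
    if constrained:
        ranges["s0_in"] = 50.0
        ranges["s1_in"] = (0.1, 2.0)
        ranges["s2_in"] = (0.1, 2.0)
    else:
        for name in ("s0_in", "s1_in", "s2_in"):
            ranges[name] = (0.1, 500.0)
    return SamplingSpec(n=n, seed=seed, constrained=constrained,
                        ranges=ranges, signs=signs)


def sample_parameters(spec: SamplingSpec) -> list[ChemostatParams]:
    """Draw ``spec.n`` parameter sets; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n):
        kwargs = {}
        for name in _FIELD_ORDER:
            r = spec.ranges[name]
            sign = spec.signs.get(name, 1.0)
            if isinstance(r, tuple):
                lo, hi = r
                mag = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                mag = abs(float(r))
                sign = 1.0 if float(r) >= 0 else -1.0
            kwargs[name] = sign * mag
        out.append(ChemostatParams(**kwargs))
    return out


@dataclass(frozen=True)
class Protocol:
    """Simulation protocol for the bistability verdict."""

    ics: tuple[tuple[float, float], ...] = DEFAULT_PROTOCOL_ICS
    eps: float = EXTINCTION_EPS
    cluster_rtol: float = 1e-3
    rtol: float = 1e-6
    atol: float = 1e-9
    horizon_dilutions: float = 100.0
    crosscheck: bool = False


@dataclass
class BistabilityVerdict:
    bistable: bool
    states: list[np.ndarray]
    indeterminate: bool
    crosscheck_agrees: bool | None = None


def detect_bistability(p: ChemostatParams,
                       protocol: Protocol = Protocol()) -> BistabilityVerdict:
    """Simulate from the protocol's initial densities and cluster endpoints.

    Bistable iff at least two distinct converged attractors are reached;
    runs that never settle are flagged indeterminate (never counted as
    bistable).  With ``protocol.crosscheck`` the verdict is compared against
    an independent fixed-point enumeration.
    """
    t_end = protocol.horizon_dilutions / p.phi
    states: list[np.ndarray] = []
    any_converged = False
    for ic in protocol.ics:
        init = np.array([ic[0], ic[1], p.s0_in, p.s1_in, p.s2_in])
        try:
            end, ok = simulate_to_steady(
                "chemostat", p, init, t_end=t_end, max_doublings=2,
                rtol=protocol.rtol, atol=protocol.atol)
        except Exception:
            ok = False
        if not ok:
            continue
        any_converged = True
        end = np.clip(end, 0.0, None)
        end[:2] = np.where(end[:2] > protocol.eps, end[:2], 0.0)
        scale = max(1.0, float(np.max(np.abs(end))))
        if not any(np.max(np.abs(end - s)) < protocol.cluster_rtol * scale
                   for s in states):
            states.append(end)
        if len(states) >= 2:
            break
    bistable = len(states) >= 2
    verdict = BistabilityVerdict(bistable=bistable, states=states,
                                 indeterminate=not any_converged)
    if protocol.crosscheck and any_converged:
        try:
            pts = chemostat_fixed_points(p, include_simulation_starts=False)
            n_stable = sum(1 for fp in pts if fp.stable)
            verdict.crosscheck_agrees = (n_stable >= 2) == bistable
        except Exception:
            verdict.crosscheck_agrees = None
    return verdict


@dataclass
class SurveyResult:
    n: int
    n_bistable: int
    n_indeterminate: int
    fraction: float
    ci_low: float
    ci_high: float
    labels: list[str]
    spec: SamplingSpec
    n_crosscheck_disagree: int = 0

    @property
    def fraction_determinate(self) -> float:
        """Secondary statistic excluding indeterminate draws."""
        denom = self.n - self.n_indeterminate
        return self.n_bistable / denom if denom else float("nan")


def _clopper_pearson(k: int, n: int, alpha: float = 0.05
                     ) -> tuple[float, float]:
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def survey_fraction(spec: SamplingSpec,
                    protocol: Protocol = Protocol()) -> SurveyResult:
    """Estimate the bistable fraction over random draws.

    The headline fraction uses the full denominator (indeterminate draws
    count as not bistable); an exact binomial confidence interval is
    attached.  Fully reproducible from the spec and its seed.
    """
    if spec.n < 1:
        raise ValueError("survey needs n >= 1")
    draws = sample_parameters(spec)
    labels: list[str] = []
    n_bi = n_ind = n_dis = 0
    for p in draws:
        v = detect_bistability(p, protocol)
        if v.indeterminate:
            labels.append("indeterminate")
            n_ind += 1
        elif v.bistable:
            labels.append("bistable")
            n_bi += 1
        else:
            labels.append("monostable")
        if v.crosscheck_agrees is False:
            n_dis += 1
    frac = n_bi / spec.n
    lo, hi = _clopper_pearson(n_bi, spec.n)
    return SurveyResult(n=spec.n, n_bistable=n_bi, n_indeterminate=n_ind,
                        fraction=frac, ci_low=lo, ci_high=hi, labels=labels,
                        spec=spec, n_crosscheck_disagree=n_dis)
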