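"""Reference parameter sets.

``eq3`` is the chemostat set used throughout the study of the cross-feeding
competitor pair; ``eq6`` is its printed two-variable reduction.  The
``fig2*`` / ``fig3*`` variants override only the growth rates, and ``s2fig``
is the weak-self-inhibition set for which the reduced model predicts two
coexistence states.
"""

from __future__ import annotations

from .params import ChemostatParams, ExtendedLVParams

EQ3_CHEMOSTAT = ChemostatParams(
    phi=2.0,
    mu1=1600.0, mu2=1600.0,
    s0_in=50.0, s1_in=1.0, s2_in=1.0,
    k10=200.0, k12=200.0, k20=200.0, k21=200.0,
    nu01=-1.0, nu02=-1.0,
    nu11=0.2, nu12=-0.1,
    nu21=-0.1, nu22=0.2,
)

EQ6_ELV = ExtendedLVParams(
    d=2.0,
    r1=0.027, r2=0.027,
    a1=50.0, a2=50.0,
    b11=5.0, b12=10.0, b21=10.0, b22=5.0,
    c1=0.2, c2=0.2,
)

_FIXTURES: dict[str, ChemostatParams | ExtendedLVParams] = {
    "eq3": EQ3_CHEMOSTAT,
    "eq6": EQ6_ELV,
    "fig2a": EQ3_CHEMOSTAT.replace(mu1=800.0, mu2=800.0),
    "fig2b": EQ3_CHEMOSTAT.replace(mu1=1600.0, mu2=1600.0),
    "fig2c": EQ3_CHEMOSTAT.replace(mu1=2400.0, mu2=1200.0),
    "fig2d": EQ3_CHEMOSTAT.replace(mu1=2400.0, mu2=2400.0),
    "fig3a": EQ6_ELV.replace(r1=0.02, r2=0.02),
    "fig3b": EQ6_ELV.replace(r1=0.027, r2=0.027),
    "fig3c": EQ6_ELV.replace(r1=0.05, r2=0.02),
    "fig3d": EQ6_ELV.replace(r1=0.05, r2=0.05),
    "s2fig": EQ6_ELV.replace(b11=2.0, b22=2.0, r1=0.023, r2=0.023),
}


def fixture(name: str) -> ChemostatParams | ExtendedLVParams:
    """Return a named reference parameter set.

    Raises ``KeyError`` listing the available names if ``name`` is unknown.
    """
    try:
        return _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None


def available_fixtures() -> list[str]:
    return sorted(_FIXTURES)
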