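"""Parameter containers for the chemostat model and its two-variable reduction.

Two species ``X1``, ``X2`` grow in a chemostat on a shared carbon source
``S0`` while cross-feeding the metabolites ``S1`` (produced by species 1,
consumed by species 2) and ``S2`` (produced by species 2, consumed by
species 1).  The reduced model keeps only the two species densities and
folds the nutrient dynamics into density-dependent growth terms: linear
mutualism/self-inhibition (``b``) and quadratic competition (``c``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields


class InvalidParameterError(ValueError):
    """Raised when a parameter set violates its physical constraints."""


@dataclass(frozen=True)
class ChemostatParams:
    """Constants of the five-variable chemostat model.

    Attributes
    ----------
    phi : float
        Flow (dilution) rate, 1/time.
    mu1, mu2 : float
        Maximal growth rates of the two species, 1/time.
    s0_in, s1_in, s2_in : float
        Inflow concentrations of the carbon source and of the two
        cross-feeding nutrients, mass/volume.
    k10, k12, k20, k21 : float
        Half-saturation constants, mass/volume; ``kij`` is species *i*'s
        constant for nutrient *j*.
    nu01 ... nu22 : float
        Production (positive) / consumption (negative) constants,
        mass/number; ``nu_ji`` couples nutrient *j* to species *i*.
    """

    phi: float
    mu1: float
    mu2: float
    s0_in: float
    s1_in: float
    s2_in: float
    k10: float
    k12: float
    k20: float
    k21: float
    nu01: float
    nu02: float
    nu11: float
    nu12: float
    nu21: float
    nu22: float

    def __post_init__(self) -> None:
        if not self.phi > 0:
            raise InvalidParameterError(f"phi must be > 0, got {self.phi}")
        for name in ("mu1", "mu2", "k10", "k12", "k20", "k21"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(
                    f"{name} must be > 0, got {getattr(self, name)}"
                )
        for name in ("s0_in", "s1_in", "s2_in"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(
                    f"{name} must be >= 0, got {getattr(self, name)}"
                )

    @property
    def mu(self) -> tuple[float, float]:
        return (self.mu1, self.mu2)

    def replace(self, **changes: float) -> "ChemostatParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class ExtendedLVParams:
    """Constants of the reduced (extended Lotka-Volterra) model.

    Per-capita growth of species 1 is
    ``r1 * (a1 - b11*X1 + b12*X2 - c1*X2**2) - d`` (and symmetrically for
    species 2): ``a`` carries the nutrient inflow, ``b_ii`` self-inhibition,
    ``b_ij`` mutualism, ``c`` quadratic competition and ``d`` the outflow
    (death) rate.
    """

    d: float
    r1: float
    r2: float
    a1: float
    a2: float
    b11: float
    b12: float
    b21: float
    b22: float
    c1: float
    c2: float

    def __post_init__(self) -> None:
        if self.d < 0:
            raise InvalidParameterError(f"d must be >= 0, got {self.d}")
        for name in ("r1", "r2", "b11", "b22"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(
                    f"{name} must be > 0, got {getattr(self, name)}"
                )
        for name in ("c1", "c2"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(
                    f"{name} must be >= 0, got {getattr(self, name)}"
                )

    @property
    def r(self) -> tuple[float, float]:
        return (self.r1, self.r2)

    def replace(self, **changes: float) -> "ExtendedLVParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def swapped(self) -> "ExtendedLVParams":
        """Parameter set with the species indices 1 and 2 exchanged."""
        return ExtendedLVParams(
            d=self.d, r1=self.r2, r2=self.r1, a1=self.a2, a2=self.a1,
            b11=self.b22, b12=self.b21, b21=self.b12, b22=self.b11,
            c1=self.c2, c2=self.c1,
        )
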