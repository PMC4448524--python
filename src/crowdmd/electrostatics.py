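"""Dipole–dipole continuum electrostatics and barrier→timescale conversion.

Two globular proteins far apart interact mainly through their molecular
dipoles.  With μₐ, μ_b the dipole magnitudes, θ the angle between the dipole
vectors and r the separation, the scalar interaction energy in a uniform
dielectric D is

    E(r, θ) = μₐ μ_b (1 − 3 cos²θ) / (4π ε₀ D r³)

per molecule pair (negative = attractive; the form vanishes at the magic
angle θ ≈ 54.74° and changes sign across it).  The radial force magnitude is
|F| = |dE/dr| = 3|E|/r.  This single-angle scalar form is an approximation
of the full two-angle dipole tensor; it is what the package implements.

``arrhenius_timescale`` converts a free-energy barrier into a characteristic
escape time τ = exp(ΔG/RT)/k₀ given an attempt frequency k₀ (default
1 µs⁻¹), e.g. to translate dissociation barriers from enhanced sampling
into dissociation timescales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import ANGSTROM, DEBYE, EPSILON_0, R_KCAL

__all__ = [
    "DipolePairState",
    "BarrierSpec",
    "DipoleForce",
    "dipole_energy",
    "dipole_force",
    "arrhenius_timescale",
    "MAGIC_ANGLE_DEG",
]

#: θ at which 1 − 3cos²θ = 0 and the scalar dipole–dipole interaction vanishes
MAGIC_ANGLE_DEG = math.degrees(math.acos(1.0 / math.sqrt(3.0)))


@dataclass(frozen=True)
class DipolePairState:
    """Geometry of two interacting molecular dipoles.

    mu_a, mu_b in Debye; theta = angle between the dipole vectors, degrees
    in [0, 180]; r = separation in Å; dielectric = relative permittivity of
    the medium (78 for water).
    """

    mu_a: float
    mu_b: float
    theta: float
    r: float
    dielectric: float = 78.0

    def __post_init__(self):
        if self.mu_a <= 0 or self.mu_b <= 0:
            raise ValueError("dipole magnitudes must be positive")
        if not 0.0 <= self.theta <= 180.0:
            raise ValueError("theta must be in [0, 180] degrees")
        if self.r <= 0:
            raise ValueError("separation r must be positive")
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")


@dataclass(frozen=True)
class BarrierSpec:
    """A free-energy barrier (kcal/mol) with temperature and attempt
    frequency (default 1 µs⁻¹)."""

    delta_g: float
    temperature: float = 300.0
    prefactor: float = 1e6  # s⁻¹

    def __post_init__(self):
        if self.delta_g < 0:
            raise ValueError("delta_g must be non-negative")
        if self.temperature <= 0 or self.prefactor <= 0:
            raise ValueError("temperature and prefactor must be positive")


@dataclass(frozen=True)
class DipoleForce:
    magnitude_pN: float
    attractive: bool


def dipole_energy(state: DipolePairState) -> float:
    """Scalar dipole–dipole interaction energy per molecule pair, in joules.

    Negative values are attractive.  Zero exactly at the magic angle.
    """
    mu_a = state.mu_a * DEBYE
    mu_b = state.mu_b * DEBYE
    r = state.r * ANGSTROM
    cos_t = math.cos(math.radians(state.theta))
    return (
        mu_a
        * mu_b
        * (1.0 - 3.0 * cos_t**2)
        / (4.0 * math.pi * EPSILON_0 * state.dielectric * r**3)
    )


def dipole_force(state: DipolePairState) -> DipoleForce:
    """Radial force magnitude |F| = 3|E|/r per molecule, in piconewtons,
    with a flag marking whether the interaction is attractive (E < 0)."""
    e = dipole_energy(state)
    f_newton = 3.0 * abs(e) / (state.r * ANGSTROM)
    return DipoleForce(magnitude_pN=f_newton * 1e12, attractive=e < 0)


def arrhenius_timescale(spec: BarrierSpec) -> float:
    """Escape time τ = exp(ΔG/RT)/k₀ in seconds."""
    return math.exp(spec.delta_g / (R_KCAL * spec.temperature)) / spec.prefactor
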