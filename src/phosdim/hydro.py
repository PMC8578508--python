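"""Hydrodynamic utilities: s20,w correction and Svedberg relations.

Sedimentation coefficients measured in an experimental buffer are corrected
to standard conditions (water, 20 degC):

    s20,w = s_obs * (eta_b / eta_20,w) * (1 - vbar*rho_20,w) / (1 - vbar*rho_b)

The frictional ratio f/f0 compares the molecule's friction coefficient,
f = M (1 - vbar rho) / (N_A s), with that of the anhydrous sphere of equal
mass and partial specific volume, f0 = 6 pi eta r0 with
r0 = (3 M vbar / (4 pi N_A))^(1/3).  Hydration is ignored (anhydrous-sphere
convention).  Units are cgs: M in g/mol (Da), rho in g/cm^3, eta in poise,
s in Svedberg (1e-13 s), vbar in cm^3/g (default 0.73).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AVOGADRO = 6.02214076e23  # 1/mol
SVEDBERG = 1e-13  # s


@dataclass(frozen=True)
class SolventConditions:
    density: float  # g/cm^3
    viscosity: float  # poise
    label: str = ""

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be > 0")


#: Water at 20 degC — the standard reference conditions.
WATER_20C = SolventConditions(density=0.998234, viscosity=0.0100194, label="water, 20C")


def _buoyancy(vbar: float, density: float) -> float:
    b = 1.0 - vbar * density
    if b <= 0:
        raise ValueError(
            f"buoyancy term 1 - vbar*rho = {b:.4g} <= 0; species would float"
        )
    return b


def s20w(
    s_obs: float,
    buffer: SolventConditions,
    vbar: float = 0.73,
) -> float:
    """Correct an observed sedimentation coefficient to water at 20 degC."""
    if s_obs <= 0:
        raise ValueError("sedimentation coefficient must be > 0")
    return (
        s_obs
        * (buffer.viscosity / WATER_20C.viscosity)
        * _buoyancy(vbar, WATER_20C.density)
        / _buoyancy(vbar, buffer.density)
    )


def observed_from_s20w(
    s_std: float, buffer: SolventConditions, vbar: float = 0.73
) -> float:
    """Inverse of :func:`s20w` (what would be observed in ``buffer``)."""
    return (
        s_std
        * (WATER_20C.viscosity / buffer.viscosity)
        * _buoyancy(vbar, buffer.density)
        / _buoyancy(vbar, WATER_20C.density)
    )


def stokes_radius_anhydrous(mass: float, vbar: float = 0.73) -> float:
    """Radius (cm) of the anhydrous sphere of a given molar mass."""
    if mass <= 0:
        raise ValueError("mass must be > 0")
    return (3.0 * mass * vbar / (4.0 * np.pi * AVOGADRO)) ** (1.0 / 3.0)


def frictional_ratio(
    mass: float,
    s: float,
    vbar: float = 0.73,
    solvent: SolventConditions = WATER_20C,
) -> float:
    """f/f0 from molar mass (Da) and sedimentation coefficient (Svedberg).

    Values below 1 are physically inconsistent (faster than the equivalent
    sphere) and trigger a warning rather than an error.
    """
    if s <= 0:
        raise ValueError("sedimentation coefficient must be > 0")
    f = mass * _buoyancy(vbar, solvent.density) / (AVOGADRO * s * SVEDBERG)
    f0 = 6.0 * np.pi * solvent.viscosity * stokes_radius_anhydrous(mass, vbar)
    ratio = f / f0
    if ratio < 1.0 - 1e-9:
        import warnings

        warnings.warn(
            f"f/f0 = {ratio:.3f} < 1: inputs are physically inconsistent",
            stacklevel=2,
        )
    return ratio


def sphere_s(
    mass: float,
    vbar: float = 0.73,
    solvent: SolventConditions = WATER_20C,
) -> float:
    """Sedimentation coefficient (Svedberg) of the anhydrous sphere, i.e. the
    s at which f/f0 equals 1."""
    f0 = 6.0 * np.pi * solvent.viscosity * stokes_radius_anhydrous(mass, vbar)
    return mass * _buoyancy(vbar, solvent.density) / (AVOGADRO * f0) / SVEDBERG


def mass_from_s_ff0(
    s: float,
    ff0: float,
    vbar: float = 0.73,
    solvent: SolventConditions = WATER_20C,
) -> float:
    """Molar mass (Da) from sedimentation coefficient and frictional ratio.

    Algebraic inverse of :func:`frictional_ratio` at fixed vbar and solvent:
    M^(2/3) proportional to s * ff0, so M = (s*ff0*C)^(3/2).
    """
    if s <= 0 or ff0 <= 0:
        raise ValueError("s and f/f0 must be > 0")
    c = (
        ff0
        * 6.0
        * np.pi
        * solvent.viscosity
        * (3.0 * vbar / (4.0 * np.pi * AVOGADRO)) ** (1.0 / 3.0)
        * AVOGADRO
        * s
        * SVEDBERG
        / _buoyancy(vbar, solvent.density)
    )
    return c ** 1.5
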