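"""Marcus electron-transfer kinetics and diffusion-limited encounter rates.

The Marcus activation free energy for an outer-sphere electron transfer with
driving force dG and reorganization energy lambda is

    dG_act = (lambda / 4) * (1 + dG / lambda)^2 ,

zero at dG = -lambda (activationless point) and rising again for more
exergonic reactions — the inverted region. The thermal rate
k_act = (k_B T / h) exp(-dG_act / RT) is corrected for diffusion with the
Collins-Kimball (harmonic) combination against the encounter rate k_D, so the
apparent rate can never exceed either limit.

Encounter rates come from Smoluchowski theory with Stokes-Einstein
diffusivities: D = k_B T / (6 pi eta a), k_D = 4 pi (a_A + a_B)(D_A + D_B) N_A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import AVOGADRO, BOLTZMANN, GAS_CONSTANT, eyring_prefactor, kj_to_j
from .core import Solvent

__all__ = [
    "ETParameters",
    "marcus_activation",
    "reorganization_energy",
    "stokes_einstein_diffusivity",
    "smoluchowski_rate",
    "et_rate",
]

#: Van der Waals-ish contact radius used when nothing better is known (m).
DEFAULT_RADIUS = 2.0e-10


@dataclass(frozen=True)
class ETParameters:
    delta_G_ET: float  # kJ mol^-1, driving force of the ET step
    lam: float  # kJ mol^-1, reorganization energy (lambda)
    k_D: float  # M^-1 s^-1, diffusion-limited encounter rate

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError(f"reorganization energy must be positive, got {self.lam}")
        if self.k_D <= 0:
            raise ValueError(f"diffusion rate must be positive, got {self.k_D}")


def marcus_activation(delta_G_ET: float, lam: float) -> float:
    """Marcus activation free energy (kJ mol^-1)."""
    if lam <= 0:
        raise ValueError(f"reorganization energy must be positive, got {lam}")
    return (lam / 4.0) * (1.0 + delta_G_ET / lam) ** 2


def reorganization_energy(vertical_energy: float, delta_G_ET: float) -> float:
    """lambda = vertical ET energy minus adiabatic free energy (kJ mol^-1)."""
    lam = vertical_energy - delta_G_ET
    if lam <= 0:
        raise ValueError(
            "vertical energy below adiabatic: "
            f"lambda = {vertical_energy} - ({delta_G_ET}) = {lam} <= 0"
        )
    return lam


def stokes_einstein_diffusivity(radius: float, solvent: Solvent) -> float:
    """Stokes-Einstein diffusivity D = k_B T / (6 pi eta a), in m^2 s^-1."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return BOLTZMANN * solvent.temperature / (6.0 * math.pi * solvent.viscosity * radius)


def smoluchowski_rate(radius_A: float, radius_B: float, solvent: Solvent) -> float:
    """Diffusion-limited encounter rate constant, M^-1 s^-1.

    k_D = 4 pi (a_A + a_B)(D_A + D_B) N_A, converted from m^3 s^-1 per pair
    to M^-1 s^-1 (x 1000 L/m^3).
    """
    d_sum = stokes_einstein_diffusivity(radius_A, solvent) + stokes_einstein_diffusivity(
        radius_B, solvent
    )
    k_m3 = 4.0 * math.pi * (radius_A + radius_B) * d_sum
    return k_m3 * AVOGADRO * 1000.0


def solvent_diffusion_rate(solvent: Solvent) -> float:
    """The rate assigned to barrierless pathways in this solvent.

    Uses the explicit per-solvent override when set, otherwise Smoluchowski
    with default contact radii.
    """
    if solvent.diffusion_rate_default is not None:
        return solvent.diffusion_rate_default
    return smoluchowski_rate(DEFAULT_RADIUS, DEFAULT_RADIUS, solvent)


def et_rate(
    params: ETParameters, T: float = 298.15, *, clipping: str = "collins-kimball"
) -> tuple[float, float, float]:
    """Apparent ET rate constant with diffusion correction.

    Returns ``(k_app, k_act, dG_act)`` with energies in kJ mol^-1 and rates
    in M^-1 s^-1. ``clipping`` selects how the activation-controlled rate is
    merged with the encounter rate: ``"collins-kimball"`` (default, harmonic
    combination) or ``"min"`` (hard clip, for sensitivity checks).
    """
    dg_act = marcus_activation(params.delta_G_ET, params.lam)
    k_act = eyring_prefactor(T) * math.exp(-kj_to_j(dg_act) / (GAS_CONSTANT * T))
    if clipping == "collins-kimball":
        k_app = params.k_D * k_act / (params.k_D + k_act)
    elif clipping == "min":
        k_app = min(k_act, params.k_D)
    else:
        raise ValueError(f"unknown clipping mode {clipping!r}")
    return k_app, k_act, dg_act
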