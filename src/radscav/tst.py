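"""Conventional transition state theory with Eckart (ZCT-0) tunneling.

Bimolecular rate constants at 1 M standard state:

    k = sigma * kappa * (k_B T / h) * exp(-dG_act / RT)

where sigma is the reaction-path degeneracy and kappa >= 1 the tunneling
transmission coefficient. Activation free energies are taken as already
referenced to the 1 M standard state, so no concentration factor is applied.

The ZCT-0 correction tunnels through a one-dimensional asymmetric Eckart
barrier fitted to the forward barrier V_f, reverse barrier V_r and the
magnitude of the imaginary frequency at the saddle point. The transmission
probability uses the classic closed form (Johnston-Heicklen parameterisation):
with alpha_i = 2 pi V_i / (h nu) and energy E above the reactant asymptote,

    a = 2 sqrt(alpha_1 E / V_f) / (1/sqrt(alpha_1) + 1/sqrt(alpha_2))
    b = same with E replaced by E - (V_f - V_r)   [energy above products]
    d = 2 sqrt(alpha_1 alpha_2 - pi^2 / 4)

    P(E) = (cosh(a+b) - cosh(a-b)) / (cosh(a+b) + cosh(d))

and kappa is the Boltzmann average  exp(V_f/RT) * <P(E) exp(-E/RT)> / RT
integrated from the higher asymptote upward. cosh terms are evaluated in log
space so stiff barriers (tiny h nu, large V) cannot overflow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.special import logsumexp

from .constants import GAS_CONSTANT, WAVENUMBER_TO_J_MOL, eyring_prefactor, kj_to_j
from .core import Mechanism, Pathway, RateMethod, RateRow, Solvent
from .electron_transfer import (
    ETParameters,
    et_rate,
    reorganization_energy,
    solvent_diffusion_rate,
)

__all__ = [
    "EckartBarrier",
    "eyring_rate",
    "eckart_kappa",
    "eckart_transmission",
    "rate_for_pathway",
    "temperature_profile",
]


@dataclass(frozen=True)
class EckartBarrier:
    """Asymmetric Eckart barrier parameters (kJ mol^-1 and cm^-1)."""

    forward_barrier: float  # V_f > 0
    reverse_barrier: float  # V_r > 0
    imag_freq: float  # |nu*| > 0, cm^-1

    def __post_init__(self) -> None:
        if self.forward_barrier <= 0 or self.reverse_barrier <= 0:
            raise ValueError("Eckart barriers must be positive")
        if self.imag_freq <= 0:
            raise ValueError("imaginary frequency magnitude must be positive")


def eyring_rate(
    delta_G_act: float,
    T: float = 298.15,
    degeneracy: int = 1,
    kappa: float = 1.0,
) -> float:
    """Eyring rate constant (M^-1 s^-1) for a 1 M standard-state barrier.

    A negative barrier is physically suspect (recrossing is not modelled)
    and triggers a warning, but the arithmetic is carried out anyway.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    if degeneracy < 1:
        raise ValueError("degeneracy must be >= 1")
    if kappa < 1.0:
        raise ValueError("transmission coefficient must be >= 1")
    if delta_G_act < 0:
        warnings.warn(
            f"negative activation free energy ({delta_G_act} kJ/mol); "
            "computing the Eyring expression anyway",
            stacklevel=2,
        )
    # log-space assembly: exact to the last ulp even for 200 kJ/mol barriers
    log_k = (
        math.log(degeneracy)
        + math.log(kappa)
        + math.log(eyring_prefactor(T))
        - kj_to_j(delta_G_act) / (GAS_CONSTANT * T)
    )
    return math.exp(log_k)


def _log_cosh_pair(x: float) -> float:
    """log(2 cosh x) = logaddexp(x, -x)."""
    return np.logaddexp(x, -x)


def eckart_transmission(barrier: EckartBarrier, energy: float) -> float:
    """Transmission probability P(E) at energy E (kJ mol^-1 above reactants)."""
    vf = kj_to_j(barrier.forward_barrier)
    vr = kj_to_j(barrier.reverse_barrier)
    hnu = barrier.imag_freq * WAVENUMBER_TO_J_MOL
    e = kj_to_j(energy)
    if e <= max(0.0, vf - vr):
        return 0.0

    a1 = 2.0 * math.pi * vf / hnu
    a2 = 2.0 * math.pi * vr / hnu
    denom = 1.0 / math.sqrt(a1) + 1.0 / math.sqrt(a2)
    a = 2.0 * math.sqrt(a1 * e / vf) / denom
    b = 2.0 * math.sqrt(a1 * e / vf - a1 + a2) / denom

    disc = a1 * a2 - math.pi**2 / 4.0
    # log-space: P = (2 sinh a)(2 sinh b) / (2 cosh(a+b) + 2 cosh d)
    log_num = a + math.log1p(-math.exp(-2.0 * a)) + b + math.log1p(-math.exp(-2.0 * b))
    if disc >= 0.0:
        d = 2.0 * math.sqrt(disc)
        log_den = logsumexp([_log_cosh_pair(a + b), _log_cosh_pair(d)])
    else:
        two_cos = 2.0 * math.cos(2.0 * math.sqrt(-disc))  # in [-2, 2]
        lc = _log_cosh_pair(a + b)
        log_den = lc + math.log1p(two_cos * math.exp(-lc))
    return float(math.exp(log_num - log_den))


def eckart_kappa(
    barrier: EckartBarrier,
    T: float = 298.15,
    *,
    rel_tol: float = 1e-6,
    upper_rt_span: float = 20.0,
) -> float:
    """Tunneling transmission coefficient kappa >= 1 at temperature T.

    Boltzmann-averages the Eckart transmission probability from the higher
    asymptote up to ``upper_rt_span`` RT above the barrier top (the remaining
    classical tail, where P ~ 1, is added analytically). Adaptive quadrature
    at relative tolerance ``rel_tol``; raises on non-convergence.
    """
    rt_kj = GAS_CONSTANT * T / 1000.0
    vf = barrier.forward_barrier
    e_min = max(0.0, vf - barrier.reverse_barrier)
    e_max = vf + upper_rt_span * rt_kj

    def integrand(e_kj: float) -> float:
        return eckart_transmission(barrier, e_kj) * math.exp((vf - e_kj) / rt_kj)

    value, abserr = quad(
        integrand,
        e_min,
        e_max,
        points=[vf],
        limit=400,
        epsrel=rel_tol,
        epsabs=0.0,
    )
    if not math.isfinite(value) or (value > 0 and abserr / value > 100 * rel_tol):
        raise RuntimeError(
            f"Eckart quadrature did not converge: value={value}, abserr={abserr}"
        )
    kappa = value / rt_kj + math.exp(-(e_max - vf) / rt_kj)  # analytic P=1 tail
    return max(kappa, 1.0)


def rate_for_pathway(pathway: Pathway, solvent: Solvent) -> RateRow:
    """Dispatch one retained pathway to its rate law.

    Barrierless -> solvent diffusion rate. HAT/RAF/PT/SPL with a barrier ->
    TST (Eckart kappa when an imaginary frequency and reverse barrier are
    supplied, else plain Eyring). SET/ET -> Marcus with Collins-Kimball
    diffusion correction, needing a vertical ET energy for lambda.
    """
    T = solvent.temperature
    if pathway.barrierless:
        return RateRow(
            pathway_id=pathway.pathway_id,
            k=solvent_diffusion_rate(solvent),
            method=RateMethod.DIFFUSION,
        )

    if pathway.mechanism in (Mechanism.SET, Mechanism.ET):
        if pathway.vertical_energy is None:
            raise ValueError(
                f"pathway {pathway.pathway_id}: electron transfer needs a "
                "vertical energy to derive the reorganization energy"
            )
        lam = reorganization_energy(pathway.vertical_energy, pathway.delta_rG)
        params = ETParameters(
            delta_G_ET=pathway.delta_rG, lam=lam, k_D=solvent_diffusion_rate(solvent)
        )
        k_app, k_act, dg_act = et_rate(params, T)
        return RateRow(
            pathway_id=pathway.pathway_id,
            k=k_app,
            method=RateMethod.MARCUS,
            delta_G_act_marcus=dg_act,
            k_activation=k_act,
        )

    if pathway.delta_G_act is None:
        raise ValueError(
            f"pathway {pathway.pathway_id}: activated pathway missing delta_G_act"
        )
    if pathway.imag_freq is not None and pathway.reverse_barrier is not None:
        barrier = EckartBarrier(
            forward_barrier=pathway.delta_G_act,
            reverse_barrier=pathway.reverse_barrier,
            imag_freq=pathway.imag_freq,
        )
        kappa = eckart_kappa(barrier, T)
        method = RateMethod.TST_ECKART
    else:
        kappa = 1.0
        method = RateMethod.TST_PLAIN
    k = eyring_rate(pathway.delta_G_act, T, degeneracy=1, kappa=kappa)
    return RateRow(pathway_id=pathway.pathway_id, k=k, method=method, kappa=kappa)


def temperature_profile(
    pathway: Pathway, T_grid: list[float], solvent: Solvent | None = None
) -> list[tuple[float, float]]:
    """k(T) over a temperature grid for an activated pathway."""
    if not T_grid:
        raise ValueError("empty temperature grid")
    if pathway.barrierless or pathway.delta_G_act is None:
        raise ValueError("temperature profile requires an activated pathway")
    out = []
    for T in T_grid:
        if pathway.imag_freq is not None and pathway.reverse_barrier is not None:
            kappa = eckart_kappa(
                EckartBarrier(pathway.delta_G_act, pathway.reverse_barrier, pathway.imag_freq),
                T,
            )
        else:
            kappa = 1.0
        out.append((T, eyring_rate(pathway.delta_G_act, T, kappa=kappa)))
    return out
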