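"""Synthetic mechanism networks and scan profiles for end-to-end testing.

The generator emulates the *structure* of the quantum-chemistry inputs the
pipeline consumes — per-mechanism reaction free energies, activation energies
for the activated channels, barrierless channels, ring-symmetry degeneracies,
two-step channels — without any electronic-structure realism. Default
distributions are loose caricatures of typical phenolic-scavenger
thermochemistry: hydrogen-atom transfer strongly exergonic, adduct formation
mildly exergonic, and the electron-transfer first steps prohibitively
endergonic in a non-polar solvent but frequently feasible in water.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import truncnorm

from .core import (
    CompositeMechanism,
    Mechanism,
    MechanismNetwork,
    Pathway,
    SpeciesForm,
    Solvent,
)
from .scans import ScanProfile

__all__ = [
    "GeneratorParams",
    "generate_network",
    "ScanTruth",
    "generate_scan",
    "BENZENE",
    "WATER",
]

# standard handbook viscosities at 298.15 K; water diffusion rate pinned to
# the value used for barrierless aqueous channels
BENZENE = Solvent(name="benzene", dielectric=2.2706, viscosity=6.04e-4)
WATER = Solvent(
    name="water", dielectric=78.3553, viscosity=8.91e-4, diffusion_rate_default=1.91e9
)


@dataclass(frozen=True)
class GeneratorParams:
    """Distribution settings for synthetic networks (energies in kJ mol^-1)."""

    solvent: Solvent = BENZENE
    hat_mean: float = -100.0
    hat_sd: float = 30.0
    raf_mean: float = -30.0
    raf_sd: float = 15.0
    #: first (electron- or proton-loss) step of the two-step channels
    et_step1_mean: Optional[float] = None  # default: +300 non-polar, +50 water
    et_step1_sd: Optional[float] = None  # default: 100 non-polar, 80 water
    et_step2_mean: float = -450.0
    et_step2_sd: float = 50.0
    #: activation energies for exergonic activated channels: truncated normal on (0, 80]
    act_mean: float = 35.0
    act_sd: float = 15.0
    act_max: float = 80.0
    barrierless_fraction: float = 0.2
    #: reorganization energy for electron-transfer steps
    lambda_mean: float = 60.0
    lambda_sd: float = 15.0
    #: sites per symmetry class (1 = no symmetry; 3 = benzene-like C3 classes)
    sigma: int = 1

    def step1_params(self) -> tuple[float, float]:
        polar = self.solvent.dielectric > 15.0
        mean = self.et_step1_mean if self.et_step1_mean is not None else (50.0 if polar else 300.0)
        sd = self.et_step1_sd if self.et_step1_sd is not None else (80.0 if polar else 100.0)
        return mean, sd


def _truncated(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def generate_network(
    seed: int, n_sites: int = 6, params: GeneratorParams | None = None
) -> MechanismNetwork:
    """Reproducible random mechanism network.

    A ring with ``n_sites`` positions yields ``n_sites`` adduct-formation
    candidates and ``ceil(n_sites / 2)`` H-abstraction candidates (hydroxyls
    on alternating positions), plus one SET-PT and one SPLET two-step
    channel. With ``params.sigma`` > 1 sites are grouped into symmetry
    classes sharing one transition state with that reaction-path degeneracy.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    params = params or GeneratorParams()
    if params.barrierless_fraction < 0 or params.barrierless_fraction > 1:
        raise ValueError("barrierless_fraction must be in [0, 1]")
    for sd in (params.hat_sd, params.raf_sd, params.et_step2_sd, params.act_sd, params.lambda_sd):
        if sd <= 0:
            raise ValueError("distribution scales must be positive")
    rng = np.random.default_rng(seed)
    form = SpeciesForm(name="CMPD", net_charge=0, protons_removed=0, molar_fraction=1.0)

    def activation(drg: float) -> tuple[Optional[float], bool]:
        """(delta_G_act, barrierless) for an exergonic HAT/RAF channel."""
        if drg >= 0:
            return None, False  # screened out later; no TS search attempted
        if rng.random() < params.barrierless_fraction:
            return None, True
        return _truncated(rng, params.act_mean, params.act_sd, 1e-9, params.act_max), False

    pathways: list[Pathway] = []
    sigma = max(1, params.sigma)

    n_raf_classes = math.ceil(n_sites / sigma)
    for c in range(n_raf_classes):
        drg = float(rng.normal(params.raf_mean, params.raf_sd))
        act, free = activation(drg)
        members = range(c * sigma + 1, min((c + 1) * sigma, n_sites) + 1)
        site = ",".join(f"{i}-C" for i in members)
        pathways.append(
            Pathway(
                mechanism=Mechanism.RAF,
                site=site,
                reactant_form=form.name,
                delta_rG=drg,
                delta_G_act=act,
                degeneracy=len(list(members)),
                barrierless=free,
            )
        )

    n_hat = math.ceil(n_sites / 2)
    n_hat_classes = math.ceil(n_hat / sigma)
    for c in range(n_hat_classes):
        drg = float(rng.normal(params.hat_mean, params.hat_sd))
        act, free = activation(drg)
        members = range(c * sigma + 1, min((c + 1) * sigma, n_hat) + 1)
        site = ",".join(f"{2 * i - 1}-OH" for i in members)
        pathways.append(
            Pathway(
                mechanism=Mechanism.HAT,
                site=site,
                reactant_form=form.name,
                delta_rG=drg,
                delta_G_act=act,
                degeneracy=len(list(members)),
                barrierless=free,
            )
        )

    s1_mean, s1_sd = params.step1_params()
    for comp, step1_mech, step2_mech in (
        (CompositeMechanism.SET_PT, Mechanism.SET, Mechanism.PT),
        (CompositeMechanism.SPLET, Mechanism.SPL, Mechanism.ET),
    ):
        drg1 = float(rng.normal(s1_mean, s1_sd))
        drg2 = float(rng.normal(params.et_step2_mean, params.et_step2_sd))
        lam1 = _truncated(rng, params.lambda_mean, params.lambda_sd, 1.0, np.inf)
        lam2 = _truncated(rng, params.lambda_mean, params.lambda_sd, 1.0, np.inf)
        cid = comp.value.lower()
        pathways.append(
            Pathway(
                mechanism=step1_mech,
                site="ring",
                reactant_form=form.name,
                delta_rG=drg1,
                barrierless=step1_mech is Mechanism.SPL,
                vertical_energy=(drg1 + lam1) if step1_mech is Mechanism.SET else None,
                composite=comp,
                composite_id=cid,
                composite_step=1,
            )
        )
        pathways.append(
            Pathway(
                mechanism=step2_mech,
                site="ring",
                reactant_form=form.name,
                delta_rG=drg2,
                barrierless=step2_mech is Mechanism.PT,
                vertical_energy=(drg2 + lam2) if step2_mech is Mechanism.ET else None,
                composite=comp,
                composite_id=cid,
                composite_step=2,
            )
        )

    return MechanismNetwork(
        compound=f"synthetic-{seed}",
        solvent=params.solvent,
        forms=[form],
        pathways=pathways,
    )


@dataclass(frozen=True)
class ScanTruth:
    """A generated scan (or pair) with its engineered ground truth."""

    kind: str
    profiles: tuple[ScanProfile, ...]
    barrier: Optional[float] = None  # kJ mol^-1, ACTIVATED
    crossing: Optional[tuple[float, float]] = None  # (pm, kJ mol^-1), CROSSING_PAIR


def _descent(r: np.ndarray, depth: float = 120.0, rc: float = 200.0, tau: float = 8.0) -> np.ndarray:
    """Monotone sigmoidal descent into the product well, ~0 for r >> rc."""
    return -depth / (1.0 + np.exp((r - rc) / tau))


def generate_scan(
    seed: int,
    kind: str = "BARRIERLESS",
    noise_sd: float = 0.0,
    *,
    grid_step: float = 2.0,
    bump_height: float = 20.0,
    crossing_at: Optional[float] = None,
) -> ScanTruth:
    """Synthetic relaxed-scan profile(s) on a 400 -> 152 pm approach grid.

    BARRIERLESS: Morse-like monotone descent. ACTIVATED: the same with an
    interior Gaussian bump of ``bump_height``. CROSSING_PAIR: a monotone
    low-spin descent plus a high-spin profile offset linearly in distance so
    the two cross exactly once, at ``crossing_at`` (drawn uniformly from
    [210, 300] pm when not given). Bounded energy jitter, uniform on
    [-noise_sd, +noise_sd], is added to every point (bounded so a stated
    noise amplitude cannot fake a barrier); ground truths refer to the
    noiseless curves.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    r = np.arange(400.0, 151.0, -grid_step)

    def jitter(e: np.ndarray) -> np.ndarray:
        return e + rng.uniform(-noise_sd, noise_sd, size=e.shape) if noise_sd > 0 else e

    if kind == "BARRIERLESS":
        e = _descent(r)
        e = e - e[0]
        return ScanTruth(kind, (ScanProfile(tuple(r), tuple(jitter(e))),))

    if kind == "ACTIVATED":
        e = _descent(r) + bump_height * np.exp(-(((r - 300.0) / 20.0) ** 2))
        e = e - e[0]
        barrier = float(np.max(e) - e[0])
        return ScanTruth(kind, (ScanProfile(tuple(r), tuple(jitter(e))),), barrier=barrier)

    if kind == "CROSSING_PAIR":
        r_star = crossing_at if crossing_at is not None else float(rng.uniform(210.0, 300.0))
        e_low = _descent(r)
        e_low = e_low - e_low[0]
        slope = 0.5  # kJ mol^-1 per pm separation of the two surfaces
        e_high = e_low + slope * (r - r_star)
        e_star = float(np.interp(r_star, r[::-1], e_low[::-1]))
        return ScanTruth(
            kind,
            (
                ScanProfile(tuple(r), tuple(jitter(e_low)), spin_label="singlet"),
                ScanProfile(tuple(r), tuple(jitter(e_high)), spin_label="triplet"),
            ),
            crossing=(r_star, e_star),
        )

    raise ValueError(f"unknown scan kind {kind!r}")
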