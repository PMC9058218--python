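"""Domain types for radical-scavenging mechanism networks.

A :class:`MechanismNetwork` bundles everything the pipeline needs for one
scavenger in one solvent: the acid-base forms of the compound, the candidate
antioxidative pathways (HAT, RAF and the two-step SPLET / SET-PT channels)
with their reaction free energies and, where a transition state exists,
activation free energies, plus solvent descriptors and optional pKa/pH data
for aqueous speciation.

Energies are kJ mol^-1 at the interface; rate constants are M^-1 s^-1.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

__all__ = [
    "Mechanism",
    "CompositeMechanism",
    "RateMethod",
    "Solvent",
    "SpeciesForm",
    "Pathway",
    "MechanismNetwork",
    "RateRow",
    "RateTable",
    "ActivityReport",
    "validate_network",
]


class Mechanism(str, enum.Enum):
    """Elementary antioxidative step types."""

    HAT = "HAT"  # hydrogen atom transfer
    RAF = "RAF"  # radical adduct formation
    SET = "SET"  # single electron transfer (first step of SET-PT)
    PT = "PT"  # proton transfer (second step of SET-PT / first of SPLET variants)
    SPL = "SPL"  # sequential proton loss (first step of SPLET)
    ET = "ET"  # electron transfer (second step of SPLET)


class CompositeMechanism(str, enum.Enum):
    """Two-step mechanisms whose steps are screened jointly."""

    SPLET = "SPLET"
    SET_PT = "SET_PT"


class RateMethod(str, enum.Enum):
    """Provenance of a rate constant."""

    TST_ECKART = "TST_ECKART"
    TST_PLAIN = "TST_PLAIN"
    MARCUS = "MARCUS"
    DIFFUSION = "DIFFUSION"
    REFERENCE = "REFERENCE"  # carried from a published table, not recomputed


#: Elementary steps that consume the scavenged radical (HO. here); only these
#: contribute to k_overall — deprotonation steps involve HO-, not the radical.
RADICAL_CONSUMING = frozenset({Mechanism.HAT, Mechanism.RAF, Mechanism.SET, Mechanism.ET})


@dataclass(frozen=True)
class Solvent:
    name: str
    dielectric: float
    viscosity: float  # Pa s
    temperature: float = 298.15  # K
    pressure: float = 101325.0  # Pa
    diffusion_rate_default: Optional[float] = None  # M^-1 s^-1 override

    def __post_init__(self) -> None:
        if self.dielectric <= 1:
            raise ValueError(f"dielectric must exceed 1, got {self.dielectric}")
        if self.viscosity <= 0:
            raise ValueError(f"viscosity must be positive, got {self.viscosity}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")


@dataclass(frozen=True)
class SpeciesForm:
    """One acid-base macrostate of the scavenger (by protons removed)."""

    name: str
    net_charge: int = 0
    protons_removed: int = 0
    molar_fraction: Optional[float] = None  # filled by speciation


@dataclass(frozen=True)
class Pathway:
    """One elementary antioxidative step.

    Two-step channels (SPLET, SET-PT) are represented as two Pathway rows
    sharing ``composite`` and ``composite_id`` with ``composite_step`` 1 / 2.
    ``degeneracy`` is the reaction-path degeneracy sigma: the number of
    symmetry-equivalent sites served by one unique transition state.
    ``secondary`` marks downstream-radical chemistry (e.g. reactions of the
    phenoxyl radical itself) so aggregation can include or exclude it.
    """

    mechanism: Mechanism
    site: str
    reactant_form: str
    delta_rG: float  # kJ mol^-1
    delta_G_act: Optional[float] = None  # kJ mol^-1
    degeneracy: int = 1
    barrierless: bool = False
    imag_freq: Optional[float] = None  # cm^-1, for Eckart tunneling
    reverse_barrier: Optional[float] = None  # kJ mol^-1 (V_r)
    vertical_energy: Optional[float] = None  # kJ mol^-1 (vertical ET energy)
    composite: Optional[CompositeMechanism] = None
    composite_id: Optional[str] = None
    composite_step: Optional[int] = None
    secondary: bool = False

    @property
    def pathway_id(self) -> str:
        base = f"{self.reactant_form}/{self.mechanism.value}/{self.site}"
        if self.composite is not None:
            base += f"#{self.composite.value}.{self.composite_step}"
        return base

    def split_degeneracy(self) -> list["Pathway"]:
        """sigma identical degeneracy-1 copies (site suffixed for uniqueness)."""
        if self.degeneracy == 1:
            return [self]
        return [
            replace(self, degeneracy=1, site=f"{self.site}[{i}]")
            for i in range(self.degeneracy)
        ]


@dataclass
class MechanismNetwork:
    compound: str
    solvent: Solvent
    forms: list[SpeciesForm]
    pathways: list[Pathway]
    pH: Optional[float] = None
    pKa: Optional[list[float]] = None
    reference_k_overall: Optional[float] = None  # Trolox k_overall, M^-1 s^-1

    def form(self, name: str) -> SpeciesForm:
        for f in self.forms:
            if f.name == name:
                return f
        raise KeyError(f"unknown species form {name!r}")

    def pathway(self, pathway_id: str) -> Pathway:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(f"unknown pathway {pathway_id!r}")


@dataclass(frozen=True)
class RateRow:
    pathway_id: str
    k: float  # M^-1 s^-1
    method: RateMethod
    kappa: Optional[float] = None  # tunneling transmission coefficient
    delta_G_act_marcus: Optional[float] = None  # kJ mol^-1, Marcus barrier
    k_activation: Optional[float] = None  # thermal (pre-diffusion) ET rate


@dataclass
class RateTable:
    rows: list[RateRow] = field(default_factory=list)

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def get(self, pathway_id: str) -> RateRow:
        for row in self.rows:
            if row.pathway_id == pathway_id:
                return row
        raise KeyError(f"no rate for pathway {pathway_id!r}")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "pathway": r.pathway_id,
                    "method": r.method.value,
                    "kappa": r.kappa,
                    "k_M-1s-1": r.k,
                }
                for r in self.rows
            ]
        )


@dataclass
class ActivityReport:
    k_overall: Optional[float]  # M^-1 s^-1; None when nothing survives screening
    gamma: dict[str, float] = field(default_factory=dict)  # pathway id -> percent
    r_T: Optional[float] = None  # relative to the reference antioxidant
    status: str = "ok"


def _check_form_consistency(f: SpeciesForm, neutral_charge: int) -> Optional[str]:
    # removing n protons from the neutral form lowers the charge by n
    expected = neutral_charge - f.protons_removed
    if f.net_charge != expected:
        return (
            f"form {f.name!r}: net_charge {f.net_charge} inconsistent with "
            f"{f.protons_removed} protons removed (expected {expected})"
        )
    return None


def validate_network(network: MechanismNetwork) -> list[str]:
    """Check every type invariant; return one diagnostic per violation.

    Never raises: an invalid network yields a non-empty list, a valid one
    yields ``[]``. The network is not modified.
    """
    diags: list[str] = []
    sv = network.solvent
    if sv.temperature <= 0:
        diags.append(f"solvent {sv.name!r}: non-positive temperature")

    if not network.forms:
        diags.append("network has no species forms")
    neutral = [f for f in network.forms if f.protons_removed == 0]
    neutral_charge = neutral[0].net_charge if neutral else 0
    for f in network.forms:
        msg = _check_form_consistency(f, neutral_charge)
        if msg:
            diags.append(msg)
        if f.molar_fraction is not None and not (0.0 <= f.molar_fraction <= 1.0):
            diags.append(f"form {f.name!r}: molar_fraction outside [0, 1]")

    # aqueous mode: pH and pKa must come together
    if (network.pH is None) != (network.pKa is None):
        diags.append("pH and pKa must be given together (aqueous mode) or both absent")

    form_names = {f.name for f in network.forms}
    for p in network.pathways:
        pid = p.pathway_id
        if p.reactant_form not in form_names:
            diags.append(f"pathway {pid}: reactant form {p.reactant_form!r} not in forms")
        if p.degeneracy < 1:
            diags.append(f"pathway {pid}: degeneracy must be >= 1, got {p.degeneracy}")
        if p.barrierless and p.delta_G_act is not None:
            diags.append(f"pathway {pid}: barrierless pathway must not carry delta_G_act")
        if p.mechanism in (Mechanism.SET, Mechanism.ET) and (
            p.imag_freq is not None or p.reverse_barrier is not None
        ):
            diags.append(f"pathway {pid}: electron-transfer step must not carry Eckart fields")
        if not math.isfinite(p.delta_rG):
            diags.append(f"pathway {pid}: non-finite delta_rG")
        if (p.composite is None) != (p.composite_step is None):
            diags.append(f"pathway {pid}: composite and composite_step must come together")

    # composite channels need exactly steps 1 and 2
    groups: dict[tuple, list[int]] = {}
    for p in network.pathways:
        if p.composite is not None:
            key = (p.reactant_form, p.composite, p.composite_id)
            groups.setdefault(key, []).append(p.composite_step or 0)
    for key, steps in groups.items():
        if sorted(steps) != [1, 2]:
            diags.append(
                f"composite channel {key[1].value}:{key[2]} of {key[0]!r} "
                f"has steps {sorted(steps)}, expected [1, 2]"
            )
    return diags


def unique_pathways(pathways: Iterable[Pathway]) -> list[Pathway]:
    """Pathways with duplicate ids removed (first occurrence wins)."""
    seen: set[str] = set()
    out: list[Pathway] = []
    for p in pathways:
        if p.pathway_id not in seen:
            seen.add(p.pathway_id)
            out.append(p)
    return out
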