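"""Published reference networks for two hydroxyl-radical scavengers.

Encodes the reported thermochemistry and kinetics for phloroglucinol
(1,3,5-trihydroxybenzene, THB-OH) and 2,4,6-trihydroxypyridine (THP-OH)
reacting with HO. in benzene and in water at physiological pH: reaction free
energies for every candidate pathway, activation free energies and rate
constants where transition states were located, diffusion-limited
assignments for the barrierless channels, and the Trolox reference overall
rate constants (1.31e8 in benzene, 1.94e9 in water, M^-1 s^-1).

Published rate constants are carried as REFERENCE rows rather than
recomputed: the tunneling transmission coefficients and imaginary
frequencies behind the tabulated TST values, and the reorganization energies
behind the Marcus values, were not reported, so the printed k are the
authoritative kinetic inputs for aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (
    CompositeMechanism as CM,
    Mechanism as M,
    MechanismNetwork,
    Pathway,
    RateMethod,
    RateRow,
    RateTable,
    SpeciesForm,
)
from .synthetic import BENZENE, WATER

__all__ = ["FIXTURE_NAMES", "load_fixture", "Fixture", "TROLOX_K_OVERALL"]

#: Trolox overall rate constants vs HO. (M^-1 s^-1), by solvent
TROLOX_K_OVERALL = {"benzene": 1.31e8, "water": 1.94e9}

#: diffusion-limited rate assigned to barrierless aqueous channels
K_DIFFUSION_WATER = 1.91e9


@dataclass
class Fixture:
    network: MechanismNetwork
    reference_rates: RateTable
    printed: dict = field(default_factory=dict)  # published headline numbers


def _p(mech, site, form, drg, act=None, sigma=1, free=False, comp=None, cid=None, step=None, secondary=False):
    return Pathway(
        mechanism=mech,
        site=site,
        reactant_form=form,
        delta_rG=drg,
        delta_G_act=act,
        degeneracy=sigma,
        barrierless=free,
        composite=comp,
        composite_id=cid,
        composite_step=step,
        secondary=secondary,
    )


def _thb_benzene() -> Fixture:
    f = "THB-OH"
    pathways = [
        _p(M.HAT, "1-OH,3-OH,5-OH", f, -118.7, act=34.0, sigma=3),
        _p(M.RAF, "1-C,3-C,5-C", f, -28.7, act=51.7, sigma=3),
        _p(M.RAF, "2-C,4-C,6-C", f, -39.0, act=21.5, sigma=3),
        _p(M.SET, "ring", f, 357.3, comp=CM.SET_PT, cid="setpt", step=1),
        _p(M.PT, "ring", f, -476.1, comp=CM.SET_PT, cid="setpt", step=2),
        _p(M.SPL, "ring", f, 432.4, comp=CM.SPLET, cid="splet", step=1),
        _p(M.ET, "ring", f, 21.7, comp=CM.SPLET, cid="splet", step=2),
    ]
    net = MechanismNetwork(
        compound="THB-OH",
        solvent=BENZENE,
        forms=[SpeciesForm(f, 0, 0, molar_fraction=1.0)],
        pathways=pathways,
        reference_k_overall=TROLOX_K_OVERALL["benzene"],
    )
    refs = RateTable(
        [
            RateRow(pathways[0].pathway_id, 3.65e7, RateMethod.REFERENCE),
            RateRow(pathways[1].pathway_id, 1.91e5, RateMethod.REFERENCE),
            RateRow(pathways[2].pathway_id, 7.18e7, RateMethod.REFERENCE),
        ]
    )
    printed = {
        "k_overall": 3.26e8,
        "r_T": 2.60,
        "gamma": {pathways[2].pathway_id: 22.0, pathways[0].pathway_id: 11.2},
    }
    return Fixture(net, refs, printed)


def _thp_benzene() -> Fixture:
    f = "THP-OH"
    hat = [
        _p(M.HAT, "2-OH", f, -97.7, act=48.5),
        _p(M.HAT, "4-OH", f, -35.9, act=42.3),
        _p(M.HAT, "6-OH", f, -99.0, act=45.9),
    ]
    raf = [
        _p(M.RAF, "2-C", f, -32.2, act=58.2),
        _p(M.RAF, "3-C", f, -27.4, act=31.5),
        _p(M.RAF, "4-C", f, 2.6),  # endergonic: no TS searched
        _p(M.RAF, "5-C", f, -32.0, act=25.7),
        _p(M.RAF, "6-C", f, -32.3, act=58.9),
    ]
    two_step = []
    for oh, s2_setpt, s1_splet, s2_splet in (
        ("2-OH", -473.6, 419.6, 55.5),
        ("4-OH", -392.4, 402.4, 153.9),
        ("6-OH", -475.0, 415.7, 58.1),
    ):
        cid = oh.lower()
        two_step += [
            _p(M.SET, oh, f, 375.5, comp=CM.SET_PT, cid=f"setpt-{cid}", step=1),
            _p(M.PT, oh, f, s2_setpt, comp=CM.SET_PT, cid=f"setpt-{cid}", step=2),
            _p(M.SPL, oh, f, s1_splet, comp=CM.SPLET, cid=f"splet-{cid}", step=1),
            _p(M.ET, oh, f, s2_splet, comp=CM.SPLET, cid=f"splet-{cid}", step=2),
        ]
    net = MechanismNetwork(
        compound="THP-OH",
        solvent=BENZENE,
        forms=[SpeciesForm(f, 0, 0, molar_fraction=1.0)],
        pathways=hat + raf + two_step,
        reference_k_overall=TROLOX_K_OVERALL["benzene"],
    )
    k_hat = [9.24e5, 1.45e7, 2.56e6]
    k_raf = {0: 1.43e4, 1: 9.95e7, 3: 1.12e8, 4: 1.06e4}
    refs = RateTable(
        [RateRow(p.pathway_id, k, RateMethod.REFERENCE) for p, k in zip(hat, k_hat)]
        + [RateRow(raf[i].pathway_id, k, RateMethod.REFERENCE) for i, k in k_raf.items()]
    )
    printed = {
        "k_overall": 2.29e8,
        "r_T": 1.80,
        "gamma": {raf[1].pathway_id: 43.4, raf[3].pathway_id: 48.8},
    }
    return Fixture(net, refs, printed)


def _thb_water() -> Fixture:
    f0, f1 = "THB-OH", "THB-O-"
    neutral = [
        _p(M.HAT, "1-OH,3-OH,5-OH", f0, -124.5, act=35.5, sigma=3),
        _p(M.RAF, "1-C,3-C,5-C", f0, -26.7, act=54.5, sigma=3),
        _p(M.RAF, "2-C,4-C,6-C", f0, -34.5, act=20.5, sigma=3),
        _p(M.SET, "ring", f0, 130.5, comp=CM.SET_PT, cid="setpt", step=1),
        _p(M.PT, "ring", f0, -255.0, comp=CM.SET_PT, cid="setpt", step=2),
        # SPLET of the neutral: proton loss to hydroxide (barrierless scan),
        # then electron transfer from the phenolate
        _p(M.SPL, "1-OH", f0, -94.3, free=True, comp=CM.SPLET, cid="splet", step=1),
        _p(M.ET, "ring", f0, -30.3, comp=CM.SPLET, cid="splet", step=2),
    ]
    anion = [
        # SET-PT of the monoanion: spontaneous electron donation, then
        # barrierless proton transfer to hydroxide
        _p(M.SET, "ring", f1, -30.3, comp=CM.SET_PT, cid="setpt-anion", step=1),
        _p(M.PT, "3-OH", f1, -125.7, free=True, comp=CM.SET_PT, cid="setpt-anion", step=2),
        _p(M.SPL, "3-OH", f1, -125.7, free=True, comp=CM.SPLET, cid="splet-anion", step=1),
        _p(M.ET, "ring", f1, -6.2, comp=CM.SPLET, cid="splet-anion", step=2),
    ]
    # downstream chemistry of the phenoxyl radical formed above: barrierless
    # H-abstraction (triplet diradical product) and spin-crossing-mediated
    # adduct formation; tagged secondary so aggregation policy decides
    secondary = [
        _p(M.HAT, "3-OH,5-OH", f1, -131.8, sigma=2, free=True, secondary=True),
        _p(M.RAF, "2-C", f1, -246.7, free=True, secondary=True),
        _p(M.RAF, "4-C", f1, -240.7, free=True, secondary=True),
        _p(M.RAF, "6-C", f1, -242.4, free=True, secondary=True),
    ]
    net = MechanismNetwork(
        compound="THB-OH",
        solvent=WATER,
        forms=[
            SpeciesForm(f0, 0, 0, molar_fraction=0.797),
            SpeciesForm(f1, -1, 1, molar_fraction=0.200),
        ],
        pathways=neutral + anion + secondary,
        reference_k_overall=TROLOX_K_OVERALL["water"],
    )
    refs = RateTable(
        [
            RateRow(neutral[0].pathway_id, 3.65e7, RateMethod.REFERENCE),
            RateRow(neutral[1].pathway_id, 1.91e5, RateMethod.REFERENCE),
            RateRow(neutral[2].pathway_id, 7.18e7, RateMethod.REFERENCE),
            # electron transfers (activation energies 9.2 and 0.6 kJ/mol)
            RateRow(neutral[6].pathway_id, 7.63e9, RateMethod.REFERENCE),
            RateRow(anion[0].pathway_id, 7.63e9, RateMethod.REFERENCE),
            RateRow(anion[3].pathway_id, 7.94e9, RateMethod.REFERENCE),
            RateRow(secondary[0].pathway_id, K_DIFFUSION_WATER, RateMethod.REFERENCE),
            RateRow(secondary[1].pathway_id, K_DIFFUSION_WATER, RateMethod.REFERENCE),
            RateRow(secondary[2].pathway_id, K_DIFFUSION_WATER, RateMethod.REFERENCE),
            RateRow(secondary[3].pathway_id, K_DIFFUSION_WATER, RateMethod.REFERENCE),
        ]
    )
    printed = {"k_overall": 7.76e9, "r_T": 4.00}
    return Fixture(net, refs, printed)


def _thp_water() -> Fixture:
    f1 = "THP-O-"
    mono = [
        _p(M.HAT, "2-OH,6-OH", f1, -134.6, act=7.8, sigma=2),
        _p(M.RAF, "2-C,6-C", f1, -32.4, act=33.4, sigma=2),
        _p(M.RAF, "3-C,5-C", f1, -33.8, sigma=2, free=True),
        _p(M.RAF, "4-C", f1, 51.6),  # para carbon not susceptible
        _p(M.SET, "ring", f1, 87.8, comp=CM.SET_PT, cid="setpt", step=1),
        _p(M.PT, "ring", f1, -222.4, comp=CM.SET_PT, cid="setpt", step=2),
        # SPLET: barrierless proton loss to hydroxide, then the strongly
        # exergonic electron transfer that lands in the Marcus inverted region
        _p(M.SPL, "2-OH", f1, -63.3, free=True, comp=CM.SPLET, cid="splet", step=1),
        _p(M.ET, "ring", f1, -71.3, comp=CM.SPLET, cid="splet", step=2),
    ]
    net = MechanismNetwork(
        compound="THP-OH",
        solvent=WATER,
        forms=[
            SpeciesForm(f1, -1, 1, molar_fraction=0.974),
            SpeciesForm("THP-O2-", -2, 2, molar_fraction=0.025),
        ],
        pathways=mono,
        reference_k_overall=TROLOX_K_OVERALL["water"],
    )
    refs = RateTable(
        [
            RateRow(mono[0].pathway_id, 3.80e7, RateMethod.REFERENCE),
            RateRow(mono[1].pathway_id, 2.94e7, RateMethod.REFERENCE),
            RateRow(mono[2].pathway_id, K_DIFFUSION_WATER, RateMethod.REFERENCE),
            # inverted-region electron transfer (activation energy 31.3 kJ/mol)
            RateRow(mono[7].pathway_id, 2.06e7, RateMethod.REFERENCE),
        ]
    )
    printed = {"k_overall": 5.92e9, "r_T": 3.05}
    return Fixture(net, refs, printed)


_BUILDERS = {
    "THB_benzene": _thb_benzene,
    "THP_benzene": _thp_benzene,
    "THB_water": _thb_water,
    "THP_water": _thp_water,
}

FIXTURE_NAMES = tuple(_BUILDERS) + ("trolox_refs",)


def load_fixture(name: str):
    """Load a published network fixture, or the Trolox reference pair.

    ``trolox_refs`` returns ``(1.31e8, 1.94e9)`` (benzene, water); the other
    names return a :class:`Fixture` with the network, the published rate
    constants as a reference table, and the headline printed values.
    """
    if name == "trolox_refs":
        return (TROLOX_K_OVERALL["benzene"], TROLOX_K_OVERALL["water"])
    try:
        return _BUILDERS[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; valid names: {', '.join(FIXTURE_NAMES)}"
        ) from None
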