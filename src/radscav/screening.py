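"""Exergonicity screening: select the pathways worth rating kinetically.

A single-step pathway is retained iff its reaction free energy is strictly
negative. A two-step channel (SPLET, SET-PT) is retained iff *both* steps are
exergonic; rejection records the offending step. The boundary is sharp:
delta_rG = 0 (and any positive value, however small) rejects.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import MechanismNetwork, Pathway

__all__ = ["Rejection", "screen_pathways"]


@dataclass(frozen=True)
class Rejection:
    pathway: Pathway
    reason: str


def _composite_key(p: Pathway) -> tuple:
    return (p.reactant_form, p.composite, p.composite_id)


def screen_pathways(
    network: MechanismNetwork,
) -> tuple[list[Pathway], list[Rejection]]:
    """Partition the network's pathways into (retained, rejected).

    Every input pathway appears in exactly one of the two lists. Raises
    ``ValueError`` if a pathway lacks delta_rG (dataclass typing makes this
    only possible via a non-finite value).
    """
    for p in network.pathways:
        if p.delta_rG is None:
            raise ValueError(f"pathway {p.pathway_id} has no delta_rG")

    # endergonic steps per composite channel
    bad_steps: dict[tuple, list[int]] = {}
    for p in network.pathways:
        if p.composite is not None and p.delta_rG >= 0:
            bad_steps.setdefault(_composite_key(p), []).append(p.composite_step)

    retained: list[Pathway] = []
    rejected: list[Rejection] = []
    for p in network.pathways:
        if p.composite is None:
            if p.delta_rG < 0:
                retained.append(p)
            else:
                rejected.append(
                    Rejection(p, f"endergonic (delta_rG = {p.delta_rG:+.1f} kJ/mol)")
                )
        else:
            bad = bad_steps.get(_composite_key(p))
            if bad is None:
                retained.append(p)
            else:
                steps = ", ".join(f"step {s}" for s in sorted(set(bad)))
                rejected.append(
                    Rejection(
                        p,
                        f"{p.composite.value} channel endergonic at {steps} "
                        f"(this step delta_rG = {p.delta_rG:+.1f} kJ/mol)",
                    )
                )
    return retained, rejected
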