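"""Assemble per-pathway rate constants into overall scavenging metrics.

The overall rate constant sums, over the acid-base forms present, the
degeneracy-weighted rate constants of every favourable radical-consuming
pathway:

    k_overall = sum_f w_f * sum_i sigma_i * k_i

with w_f the form's molar fraction in aqueous work (w_f = 1 in non-polar
solvents, where only the neutral form exists). Proton-transfer steps of the
two-step mechanisms involve the hydroxide ion rather than the scavenged
radical and are excluded from the sum. Branching ratios report each unique
site's per-site share,

    Gamma_i = 100 * w_f * k_i / k_overall   [%],

so a degeneracy-sigma pathway carries sigma times its printed share, and the
relative antioxidative capacity is r^T = k_overall / k_overall(reference).
"""

from __future__ import annotations

import enum

from .core import (
    RADICAL_CONSUMING,
    ActivityReport,
    MechanismNetwork,
    Pathway,
    RateTable,
)

__all__ = ["AggregationPolicy", "overall_rate", "branching_ratios", "relative_activity", "activity_report"]


class AggregationPolicy(str, enum.Enum):
    PRIMARY_ONLY = "PRIMARY_ONLY"  # exclude downstream-radical (secondary) chemistry
    ALL_PATHWAYS = "ALL_PATHWAYS"


def _form_weight(network: MechanismNetwork, form_name: str, weight_by_fraction: bool) -> float:
    if not weight_by_fraction:
        return 1.0
    frac = network.form(form_name).molar_fraction
    if frac is None:
        raise ValueError(
            f"form {form_name!r} has no molar fraction; run speciation first "
            "or aggregate with weight_by_fraction=False"
        )
    return frac


def _contributing(
    network: MechanismNetwork,
    rates: RateTable,
    policy: AggregationPolicy,
) -> list[tuple[Pathway, float]]:
    """(pathway, k) pairs entering the sum; errors on a missing rate."""
    rated = {row.pathway_id: row.k for row in rates}
    out = []
    for p in network.pathways:
        if p.mechanism not in RADICAL_CONSUMING:
            continue
        if policy is AggregationPolicy.PRIMARY_ONLY and p.secondary:
            continue
        if p.pathway_id not in rated:
            raise ValueError(f"no rate constant for retained pathway {p.pathway_id}")
        out.append((p, rated[p.pathway_id]))
    return out


def overall_rate(
    rates: RateTable,
    network: MechanismNetwork,
    policy: AggregationPolicy = AggregationPolicy.PRIMARY_ONLY,
    weight_by_fraction: bool = False,
) -> float:
    """Degeneracy- (and optionally molar-fraction-) weighted total rate constant.

    Only pathways present in ``network.pathways`` (i.e. those that survived
    screening, if the caller screened) and carrying a rate in ``rates`` are
    summed; a retained radical-consuming pathway without a rate is an error.
    """
    total = 0.0
    for p, k in _contributing(network, rates, policy):
        w = _form_weight(network, p.reactant_form, weight_by_fraction)
        total += w * p.degeneracy * k
    return total


def branching_ratios(
    rates: RateTable,
    k_overall: float,
    network: MechanismNetwork | None = None,
    policy: AggregationPolicy = AggregationPolicy.PRIMARY_ONLY,
    weight_by_fraction: bool = False,
) -> dict[str, float]:
    """Per-unique-site branching ratios in percent.

    Each entry is the share of one symmetry-unique pathway *per site*; a
    degeneracy-sigma entry therefore appears once but accounts for sigma
    times its printed percentage, and sum_i sigma_i Gamma_i = 100.
    """
    if k_overall <= 0:
        raise ValueError("k_overall must be positive")
    gamma: dict[str, float] = {}
    if network is None:
        for row in rates:
            gamma[row.pathway_id] = 100.0 * row.k / k_overall
        return gamma
    for p, k in _contributing(network, rates, policy):
        w = _form_weight(network, p.reactant_form, weight_by_fraction)
        gamma[p.pathway_id] = 100.0 * w * k / k_overall
    return gamma


def relative_activity(k_overall: float, k_ref: float) -> float:
    """r^T = k_overall / k_overall(reference antioxidant)."""
    if k_ref <= 0:
        raise ValueError("reference overall rate constant must be positive")
    return k_overall / k_ref


def activity_report(
    rates: RateTable,
    network: MechanismNetwork,
    policy: AggregationPolicy = AggregationPolicy.PRIMARY_ONLY,
    weight_by_fraction: bool = False,
    k_ref: float | None = None,
) -> ActivityReport:
    """Full report: k_overall, branching ratios, and r^T when a reference is known."""
    if not _contributing(network, rates, policy):
        return ActivityReport(
            k_overall=None, gamma={}, r_T=None, status="no favourable pathways"
        )
    k = overall_rate(rates, network, policy, weight_by_fraction)
    gamma = branching_ratios(rates, k, network, policy, weight_by_fraction)
    ref = k_ref if k_ref is not None else network.reference_k_overall
    r_t = relative_activity(k, ref) if ref else None
    return ActivityReport(k_overall=k, gamma=gamma, r_T=r_t)
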