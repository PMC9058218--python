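"""Acid-base speciation: molar fractions of deprotonation macrostates at a pH.

For a polyprotic acid with stepwise constants pKa_1 < pKa_2 < ... the molar
fraction of the form with j protons removed follows the standard polyprotic
Henderson-Hasselbalch distribution

    f_j  proportional to  10^(j*pH - sum_{i<=j} pKa_i),

normalised over j = 0..n. Exponents are accumulated in log space so very long
pKa lists cannot overflow. Only macrostates (by protons removed) are resolved;
microspecies (which hydroxyl deprotonates first) are not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = ["SpeciationProfile", "species_fractions", "dominant_forms"]

_LN10 = np.log(10.0)


@dataclass(frozen=True)
class SpeciationProfile:
    """Molar fractions by protons removed (index 0 = fully protonated)."""

    pH: float
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        total = float(np.sum(self.fractions))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")
        if any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be non-negative")


def species_fractions(pKa: list[float], pH: float) -> SpeciationProfile:
    """Distribution over acid-base forms at ``pH`` given stepwise ``pKa``.

    Raises ``ValueError`` on an empty pKa list; warns if the list is not
    strictly increasing (physically stepwise constants should increase).
    """
    if not pKa:
        raise ValueError("no dissociation constants")
    pka = np.asarray(pKa, dtype=float)
    if np.any(np.diff(pka) <= 0):
        warnings.warn("pKa values are not strictly increasing", stacklevel=2)

    j = np.arange(len(pka) + 1)
    cum_pka = np.concatenate([[0.0], np.cumsum(pka)])
    log10_w = j * pH - cum_pka  # log10 of unnormalised weights
    log_w = log10_w * _LN10
    fractions = np.exp(log_w - logsumexp(log_w))
    fractions = fractions / fractions.sum()  # exact renormalisation
    return SpeciationProfile(pH=float(pH), fractions=tuple(float(f) for f in fractions))


def dominant_forms(profile: SpeciationProfile, threshold: float = 0.05) -> list[int]:
    """Protons-removed indices with fraction >= ``threshold``, descending.

    Never empty: the most populated form is always included even when every
    fraction falls below the threshold.
    """
    frac = np.asarray(profile.fractions)
    order = np.argsort(-frac, kind="stable")
    kept = [int(i) for i in order if frac[i] >= threshold]
    if not kept:
        kept = [int(order[0])]
    return kept
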