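"""Relaxed-scan profile analysis: barrierless classification and spin crossings.

When no transition state can be located for a strongly exergonic step, the
energy along the approach coordinate (e.g. the HO.-X distance) decides the
kinetics: a profile that decreases continuously from the separated reactants
is diffusion-controlled, while an interior maximum marks an activated
channel. For reactions that change spin multiplicity, the crossing between
the two spin-state profiles (the spin crossing point, SCP) locates where spin
inversion lets the system hop to the lower surface (two-state reactivity).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["ScanProfile", "ScanClass", "classify_scan", "find_spin_crossing"]


class ScanClass(str, enum.Enum):
    BARRIERLESS = "BARRIERLESS"
    ACTIVATED = "ACTIVATED"


@dataclass(frozen=True)
class ScanProfile:
    """Energy (kJ mol^-1, relative to reactants) vs approach distance (pm)."""

    coordinate: tuple[float, ...]  # pm
    energy: tuple[float, ...]  # kJ mol^-1
    spin_label: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.coordinate) != len(self.energy):
            raise ValueError("coordinate and energy must have equal length")
        if len(self.coordinate) < 3:
            raise ValueError("scan profile needs at least 3 points")
        diffs = np.diff(self.coordinate)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("scan coordinate must be strictly monotone")

    def along_approach(self) -> tuple[np.ndarray, np.ndarray]:
        """(coordinate, energy) ordered by decreasing distance (the approach)."""
        r = np.asarray(self.coordinate, dtype=float)
        e = np.asarray(self.energy, dtype=float)
        if r[0] < r[-1]:
            r, e = r[::-1], e[::-1]
        return r, e


@dataclass(frozen=True)
class ScanClassification:
    label: ScanClass
    barrier: float  # kJ mol^-1; 0 for barrierless

    def __eq__(self, other):  # comparable against the bare enum for convenience
        if isinstance(other, ScanClass):
            return self.label is other
        return (
            isinstance(other, ScanClassification)
            and self.label is other.label
            and self.barrier == other.barrier
        )

    __hash__ = None


def classify_scan(profile: ScanProfile, noise_tol: float = 0.5) -> ScanClassification:
    """BARRIERLESS iff the energy never rises by more than ``noise_tol`` along
    the approach and the global maximum sits at the start (within noise_tol);
    otherwise ACTIVATED with barrier = max(E) - E[start].

    The result is invariant to adding a constant to all energies and to the
    traversal direction of the stored coordinate.
    """
    _, e = profile.along_approach()
    steps = np.diff(e)
    rises_ok = np.all(steps <= noise_tol)
    barrier = float(np.max(e) - e[0])
    if rises_ok and barrier <= noise_tol:
        return ScanClassification(ScanClass.BARRIERLESS, 0.0)
    return ScanClassification(ScanClass.ACTIVATED, barrier)


def find_spin_crossing(
    profile_low: ScanProfile, profile_high: ScanProfile
) -> Optional[tuple[float, float]]:
    """Locate where two spin-state profiles cross: (r_SCP in pm, E_SCP in kJ mol^-1).

    The energy difference is evaluated on the union of the two grids over the
    overlapping coordinate range (linear interpolation within each profile);
    sign changes are refined by linear interpolation between the bracketing
    points. With several crossings the one at the largest approach distance —
    the first met along the approach — is returned. ``None`` if the profiles
    never cross. Symmetric in its two arguments.
    """
    r1, e1 = profile_low.along_approach()
    r2, e2 = profile_high.along_approach()
    lo = max(r1.min(), r2.min())
    hi = min(r1.max(), r2.max())
    if lo >= hi:
        raise ValueError("scan profiles do not overlap in coordinate range")

    grid = np.unique(np.concatenate([r1, r2]))
    grid = grid[(grid >= lo) & (grid <= hi)]
    # np.interp wants ascending abscissae
    f1 = np.interp(grid, r1[::-1], e1[::-1])
    f2 = np.interp(grid, r2[::-1], e2[::-1])
    diff = f1 - f2

    crossings: list[tuple[float, float]] = []
    for i in range(len(grid) - 1):
        d0, d1 = diff[i], diff[i + 1]
        if d0 == 0.0:
            crossings.append((float(grid[i]), float(0.5 * (f1[i] + f2[i]))))
        elif d0 * d1 < 0.0:
            t = d0 / (d0 - d1)
            r_cross = grid[i] + t * (grid[i + 1] - grid[i])
            # both surfaces agree at the crossing; average for exact symmetry
            e1c = f1[i] + t * (f1[i + 1] - f1[i])
            e2c = f2[i] + t * (f2[i + 1] - f2[i])
            crossings.append((float(r_cross), float(0.5 * (e1c + e2c))))
    if diff[-1] == 0.0:
        crossings.append((float(grid[-1]), float(0.5 * (f1[-1] + f2[-1]))))
    if not crossings:
        return None
    # first encountered along the approach = largest distance
    return max(crossings, key=lambda c: c[0])
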