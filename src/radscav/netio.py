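"""Readers and writers for mechanism networks, scan profiles and reports.

Network files are YAML with a flat key-value header (compound, solvent,
speciation data) and a ``pathways`` table; a plain-CSV pathway table with the
columns ``mechanism, site, form, delta_rG_kJmol, delta_G_act_kJmol,
degeneracy, barrierless, imag_freq_cm1`` is accepted as an alternative for
the pathway section. Scan profiles are two-column CSV
(``distance_pm, energy_kJmol``) with an optional ``spin_label`` comment.

Reals survive a write/read round trip to full precision (YAML uses repr-
style floats); scientific notation is accepted both as ``3.65e7`` and in the
typographic form ``3.65 × 10^7`` in fixture sources.
"""

from __future__ import annotations

import csv
import json
import re
from pathlib import Path
import yaml

from .core import (
    CompositeMechanism,
    Mechanism,
    MechanismNetwork,
    Pathway,
    RateTable,
    SpeciesForm,
    Solvent,
    ActivityReport,
)
from .scans import ScanProfile

__all__ = [
    "parse_rate",
    "read_network",
    "write_network",
    "read_pathways_csv",
    "read_scan_csv",
    "write_scan_csv",
    "write_rates_tsv",
    "write_report",
]

_TYPOGRAPHIC = re.compile(
    r"^\s*([0-9.]+)\s*[x×]\s*10\s*\^?\s*(?:\^)?(-?[0-9]+)\^?\s*$"
)


def parse_rate(text: str | float) -> float:
    """Parse ``3.65e7`` or the typographic ``3.65 × 10^7`` form."""
    if isinstance(text, (int, float)):
        return float(text)
    m = _TYPOGRAPHIC.match(text)
    if m:
        return float(m.group(1)) * 10.0 ** int(m.group(2))
    return float(text)


def _pathway_to_dict(p: Pathway) -> dict:
    d: dict = {
        "mechanism": p.mechanism.value,
        "site": p.site,
        "form": p.reactant_form,
        "delta_rG_kJmol": p.delta_rG,
        "degeneracy": p.degeneracy,
        "barrierless": p.barrierless,
    }
    if p.delta_G_act is not None:
        d["delta_G_act_kJmol"] = p.delta_G_act
    if p.imag_freq is not None:
        d["imag_freq_cm1"] = p.imag_freq
    if p.reverse_barrier is not None:
        d["reverse_barrier_kJmol"] = p.reverse_barrier
    if p.vertical_energy is not None:
        d["vertical_energy_kJmol"] = p.vertical_energy
    if p.composite is not None:
        d["composite"] = p.composite.value
        d["composite_id"] = p.composite_id
        d["composite_step"] = p.composite_step
    if p.secondary:
        d["secondary"] = True
    return d


def _pathway_from_dict(d: dict) -> Pathway:
    return Pathway(
        mechanism=Mechanism(d["mechanism"]),
        site=str(d["site"]),
        reactant_form=str(d["form"]),
        delta_rG=float(d["delta_rG_kJmol"]),
        delta_G_act=(
            float(d["delta_G_act_kJmol"]) if d.get("delta_G_act_kJmol") is not None else None
        ),
        degeneracy=int(d.get("degeneracy", 1)),
        barrierless=bool(d.get("barrierless", False)),
        imag_freq=float(d["imag_freq_cm1"]) if d.get("imag_freq_cm1") is not None else None,
        reverse_barrier=(
            float(d["reverse_barrier_kJmol"])
            if d.get("reverse_barrier_kJmol") is not None
            else None
        ),
        vertical_energy=(
            float(d["vertical_energy_kJmol"])
            if d.get("vertical_energy_kJmol") is not None
            else None
        ),
        composite=CompositeMechanism(d["composite"]) if d.get("composite") else None,
        composite_id=d.get("composite_id"),
        composite_step=int(d["composite_step"]) if d.get("composite_step") else None,
        secondary=bool(d.get("secondary", False)),
    )


def write_network(network: MechanismNetwork, path: str | Path) -> None:
    doc: dict = {
        "compound": network.compound,
        "solvent": {
            "name": network.solvent.name,
            "dielectric": network.solvent.dielectric,
            "viscosity_Pa_s": network.solvent.viscosity,
            "temperature_K": network.solvent.temperature,
            "pressure_Pa": network.solvent.pressure,
        },
        "forms": [
            {
                "name": f.name,
                "net_charge": f.net_charge,
                "protons_removed": f.protons_removed,
                **(
                    {"molar_fraction": f.molar_fraction}
                    if f.molar_fraction is not None
                    else {}
                ),
            }
            for f in network.forms
        ],
        "pathways": [_pathway_to_dict(p) for p in network.pathways],
    }
    if network.solvent.diffusion_rate_default is not None:
        doc["solvent"]["diffusion_rate_M-1s-1"] = network.solvent.diffusion_rate_default
    if network.pH is not None:
        doc["pH"] = network.pH
    if network.pKa is not None:
        doc["pKa"] = list(network.pKa)
    if network.reference_k_overall is not None:
        doc["reference_k_overall_M-1s-1"] = network.reference_k_overall
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_network(path: str | Path) -> MechanismNetwork:
    doc = yaml.safe_load(Path(path).read_text())
    sv = doc["solvent"]
    solvent = Solvent(
        name=sv["name"],
        dielectric=float(sv["dielectric"]),
        viscosity=float(sv["viscosity_Pa_s"]),
        temperature=float(sv.get("temperature_K", 298.15)),
        pressure=float(sv.get("pressure_Pa", 101325.0)),
        diffusion_rate_default=(
            parse_rate(sv["diffusion_rate_M-1s-1"])
            if sv.get("diffusion_rate_M-1s-1") is not None
            else None
        ),
    )
    forms = [
        SpeciesForm(
            name=f["name"],
            net_charge=int(f.get("net_charge", 0)),
            protons_removed=int(f.get("protons_removed", 0)),
            molar_fraction=(
                float(f["molar_fraction"]) if f.get("molar_fraction") is not None else None
            ),
        )
        for f in doc["forms"]
    ]
    return MechanismNetwork(
        compound=doc["compound"],
        solvent=solvent,
        forms=forms,
        pathways=[_pathway_from_dict(d) for d in doc["pathways"]],
        pH=float(doc["pH"]) if doc.get("pH") is not None else None,
        pKa=[float(x) for x in doc["pKa"]] if doc.get("pKa") is not None else None,
        reference_k_overall=(
            parse_rate(doc["reference_k_overall_M-1s-1"])
            if doc.get("reference_k_overall_M-1s-1") is not None
            else None
        ),
    )


CSV_COLUMNS = [
    "mechanism",
    "site",
    "form",
    "delta_rG_kJmol",
    "delta_G_act_kJmol",
    "degeneracy",
    "barrierless",
    "imag_freq_cm1",
]


def read_pathways_csv(path: str | Path) -> list[Pathway]:
    """Columnar pathway table (header per :data:`CSV_COLUMNS`)."""
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    out = []
    for row in rows:
        d = {k: (v if v not in ("", None) else None) for k, v in row.items()}
        d["barrierless"] = str(d.get("barrierless") or "false").lower() in ("1", "true", "yes")
        out.append(_pathway_from_dict(d))
    return out


def read_scan_csv(path: str | Path) -> ScanProfile:
    spin = None
    coords, energies = [], []
    with open(path, newline="") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "spin_label" in line:
                    spin = line.split("=", 1)[1].strip()
                continue
            if line.lower().startswith("distance"):
                continue
            r, e = line.split(",")[:2]
            coords.append(float(r))
            energies.append(float(e))
    return ScanProfile(tuple(coords), tuple(energies), spin_label=spin)


def write_scan_csv(profile: ScanProfile, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        if profile.spin_label:
            fh.write(f"# spin_label = {profile.spin_label}\n")
        fh.write("distance_pm,energy_kJmol\n")
        for r, e in zip(profile.coordinate, profile.energy):
            fh.write(f"{float(r)!r},{float(e)!r}\n")


def write_rates_tsv(rates: RateTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pathway\tmethod\tkappa\tk_M-1s-1\n")
        for row in rates:
            kappa = f"{row.kappa:.4f}" if row.kappa is not None else ""
            fh.write(f"{row.pathway_id}\t{row.method.value}\t{kappa}\t{row.k:.6e}\n")


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + sig - 1)


def write_report(report: ActivityReport, path: str | Path, fmt: str = "json") -> None:
    """Serialise an activity report (k to 3 significant digits, Gamma to 0.1%)."""
    doc = {
        "k_overall_M-1s-1": _round_sig(report.k_overall) if report.k_overall else None,
        "gamma_percent": {k: round(v, 1) for k, v in report.gamma.items()},
        "r_T": round(report.r_T, 2) if report.r_T is not None else None,
        "status": report.status,
    }
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(doc, indent=2) + "\n")
    elif fmt == "tsv":
        lines = [f"k_overall\t{doc['k_overall_M-1s-1']}", f"r_T\t{doc['r_T']}"]
        lines += [f"gamma\t{k}\t{v}" for k, v in doc["gamma_percent"].items()]
        lines.append(f"status\t{doc['status']}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")
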