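"""Conceptual-DFT global reactivity descriptors.

Computes ionization potential (IP), electron affinity (EA) and the
derived global indices — chemical hardness/rigidity ``eta``, softness
``S``, electronegativity ``chi`` and the electrophilicity index
``omega`` — either from total electronic energies of the neutral,
cation-radical and anion-radical species, or from frontier-orbital
energies via the Koopmans approximation (IP = -eps_HOMO,
EA = -eps_LUMO).

Conventions
-----------
* IP = E(A+) - E(A)   (vertical/adiabatic, depending on the energies fed in)
* EA = E(A)  - E(A-)  (positive for electron-binding species)
* gap = EA - IP, reported signed; the conventional positive magnitude is
  exposed as ``abs_gap``.  Note gap = -2*eta.
* eta = (IP - EA)/2, S = 1/(2*eta), chi = (IP + EA)/2, omega = chi**2/(2*eta)

The calculator is agnostic about whether the supplied energies are
electronic energies or enthalpies: it consumes whatever energy column
the caller provides.  Energies may be given in eV or Hartree; the
internal canonical unit is eV.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

__all__ = [
    "HARTREE_TO_EV",
    "SpeciesEnergySet",
    "FrontierOrbitals",
    "ReactivityDescriptors",
    "DegenerateHardnessError",
    "compute_ip",
    "compute_ea",
    "descriptors_from_ip_ea",
    "descriptors_from_orbitals",
    "compare_compounds",
    "descriptor_table",
    "read_energy_table",
]

HARTREE_TO_EV = 27.211386


class DegenerateHardnessError(ValueError):
    """Raised when eta == 0 and softness/electrophilicity are requested."""


def _to_ev(value: float, unit: str) -> float:
    if unit == "eV":
        return value
    if unit == "Hartree":
        return value * HARTREE_TO_EV
    raise ValueError(f"unknown energy unit {unit!r}; expected 'eV' or 'Hartree'")


@dataclass(frozen=True)
class SpeciesEnergySet:
    """Energies of the neutral (A), cation-radical (A+) and anion-radical
    (A-) species of one compound, in a single declared unit."""

    compound_id: str
    E_neutral: float
    E_cation: float
    E_anion: float
    unit: str = "eV"

    def __post_init__(self) -> None:
        if self.unit not in ("eV", "Hartree"):
            raise ValueError(f"unit must be 'eV' or 'Hartree', got {self.unit!r}")
        for name in ("E_neutral", "E_cation", "E_anion"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} is not finite: {v!r}")


@dataclass(frozen=True)
class FrontierOrbitals:
    """Frontier molecular-orbital energies (eV) of one compound."""

    compound_id: str
    eps_homo: float
    eps_lumo: float

    def __post_init__(self) -> None:
        for name in ("eps_homo", "eps_lumo"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} is not finite: {v!r}")
        if self.eps_homo > self.eps_lumo:
            warnings.warn(
                f"{self.compound_id}: eps_homo ({self.eps_homo}) > eps_lumo "
                f"({self.eps_lumo}); physically questionable input",
                stacklevel=3,
            )


@dataclass(frozen=True)
class ReactivityDescriptors:
    """Global reactivity indices of one compound, all in eV except the
    softness (1/eV).  ``softness`` and ``omega`` are None when eta == 0
    (degenerate hardness)."""

    compound_id: str
    IP: float
    EA: float
    gap: float           # signed, EA - IP  (== -2*eta)
    eta: float           # hardness/rigidity, (IP - EA)/2
    chi: float           # electronegativity, (IP + EA)/2
    softness: Optional[float] = None   # 1/(2*eta), 1/eV
    omega: Optional[float] = None      # chi**2/(2*eta)
    abs_gap: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "abs_gap", abs(self.gap))


def compute_ip(species: SpeciesEnergySet) -> float:
    """Ionization potential IP = E(A+) - E(A), returned in eV."""
    return _to_ev(species.E_cation - species.E_neutral, species.unit)


def compute_ea(species: SpeciesEnergySet) -> float:
    """Electron affinity EA = E(A) - E(A-), returned in eV.

    Positive for species that bind an extra electron (E(A-) below E(A)).
    """
    return _to_ev(species.E_neutral - species.E_anion, species.unit)


def descriptors_from_ip_ea(
    IP: float, EA: float, compound_id: str = ""
) -> ReactivityDescriptors:
    """Derive all global indices from IP and EA (both eV).

    When eta == 0 the softness and electrophilicity are undefined; they
    are returned as None and accessing them through
    :func:`require_softness` raises :class:`DegenerateHardnessError`.
    """
    if not (math.isfinite(IP) and math.isfinite(EA)):
        raise ValueError("IP and EA must be finite")
    eta = (IP - EA) / 2.0
    chi = (IP + EA) / 2.0
    gap = EA - IP
    if eta != 0.0:
        softness: Optional[float] = 1.0 / (2.0 * eta)
        omega: Optional[float] = chi * chi / (2.0 * eta)
    else:
        softness = None
        omega = None
    return ReactivityDescriptors(
        compound_id=compound_id, IP=IP, EA=EA, gap=gap, eta=eta,
        chi=chi, softness=softness, omega=omega,
    )


def require_softness(d: ReactivityDescriptors) -> float:
    if d.softness is None:
        raise DegenerateHardnessError(
            f"{d.compound_id or 'compound'}: eta == 0, softness undefined"
        )
    return d.softness


def require_omega(d: ReactivityDescriptors) -> float:
    if d.omega is None:
        raise DegenerateHardnessError(
            f"{d.compound_id or 'compound'}: eta == 0, electrophilicity undefined"
        )
    return d.omega


def descriptors_from_species(species: SpeciesEnergySet) -> ReactivityDescriptors:
    """Full route: species energies -> IP, EA -> descriptors."""
    return descriptors_from_ip_ea(
        compute_ip(species), compute_ea(species), compound_id=species.compound_id
    )


def descriptors_from_orbitals(orb: FrontierOrbitals) -> ReactivityDescriptors:
    """Koopmans route: IP = -eps_HOMO, EA = -eps_LUMO, then the same
    index formulas as the explicit IP/EA route."""
    return descriptors_from_ip_ea(
        -orb.eps_homo, -orb.eps_lumo, compound_id=orb.compound_id
    )


_COMPARE_FIELDS = ("IP", "EA", "gap", "eta", "chi", "softness", "omega")


def compare_compounds(
    a: ReactivityDescriptors, b: ReactivityDescriptors
) -> dict:
    """Signed per-field differences (a - b) plus a donor/acceptor verdict.

    The compound with both the larger EA and the larger electrophilicity
    omega is flagged the stronger electron acceptor; if the two criteria
    disagree, or either omega is undefined, the verdict is 'indeterminate'.
    """
    diffs = {}
    for f in _COMPARE_FIELDS:
        va, vb = getattr(a, f), getattr(b, f)
        diffs[f"d_{f}"] = None if va is None or vb is None else va - vb
    if a.EA == b.EA and a.omega == b.omega:
        verdict = "equivalent"
    elif a.omega is None or b.omega is None:
        verdict = "indeterminate"
    elif a.EA > b.EA and a.omega > b.omega:
        verdict = f"{a.compound_id or 'a'} stronger acceptor"
    elif b.EA > a.EA and b.omega > a.omega:
        verdict = f"{b.compound_id or 'b'} stronger acceptor"
    else:
        verdict = "indeterminate"
    return {"a": a.compound_id, "b": b.compound_id, **diffs, "verdict": verdict}


# ---------------------------------------------------------------------------
# table I/O

def read_energy_table(path) -> pd.DataFrame:
    """Read a CSV of species energies (columns compound_id, E_neutral,
    E_cation, E_anion, unit) or frontier orbitals (compound_id,
    eps_homo, eps_lumo)."""
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"eps_homo", "eps_lumo"} <= cols:
        return df
    required = {"compound_id", "E_neutral", "E_cation", "E_anion"}
    if not required <= cols:
        raise ValueError(
            f"energy table needs columns {sorted(required)} (+ optional "
            f"'unit') or compound_id/eps_homo/eps_lumo; got {sorted(cols)}"
        )
    if "unit" not in cols:
        df = df.assign(unit="eV")
    return df


def descriptor_table(df: pd.DataFrame, from_orbitals: bool = False) -> pd.DataFrame:
    """Compute a descriptor row per compound from an energy table."""
    rows = []
    for rec in df.to_dict("records"):
        if from_orbitals or "eps_homo" in rec and "E_neutral" not in rec:
            d = descriptors_from_orbitals(FrontierOrbitals(
                compound_id=str(rec["compound_id"]),
                eps_homo=float(rec["eps_homo"]),
                eps_lumo=float(rec["eps_lumo"]),
            ))
        else:
            d = descriptors_from_species(SpeciesEnergySet(
                compound_id=str(rec["compound_id"]),
                E_neutral=float(rec["E_neutral"]),
                E_cation=float(rec["E_cation"]),
                E_anion=float(rec["E_anion"]),
                unit=str(rec.get("unit", "eV")),
            ))
        rows.append({
            "compound_id": d.compound_id, "IP": d.IP, "EA": d.EA,
            "gap": d.gap, "abs_gap": d.abs_gap, "eta": d.eta,
            "softness": d.softness, "chi": d.chi, "omega": d.omega,
        })
    return pd.DataFrame(rows)
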