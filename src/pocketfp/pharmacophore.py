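"""Pharmacophore typing: interaction-capable sites of protein, waters
and ligand merged into one model.

Protein residues are typed from the built-in template table
(``data/residue_templates.json``): donor-capable heavy atoms, acceptors
with their bonded neighbours, aromatic pi rings, formally charged groups
(LYS +1, ARG +1, ASP -1, GLU -1; termini ignored, no pKa modelling) and
apolar side-chain carbon/sulfur hydrophobes.  HIS is treated as a
neutral pi ring with ND1/NE2 both donor- and acceptor-capable.  Waters
contribute one acceptor (O, with its hydrogens as neighbours) and one
donor per hydrogen.  Ligand sites come from the user's
:class:`~pocketfp.structure_io.LigandAnnotation`.

Donor hydrogens are resolved geometrically: a hydrogen belongs to a
donor heavy atom if it lies within ``H_BOND_CUTOFF`` (1.3 Å) of it in
frame 0.  A donor-capable heavy atom without any such hydrogen is
silently not a donor (common for heavy-atom-only structures).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np

from .structure_io import LigandAnnotation, Structure

__all__ = [
    "DonorSite",
    "AcceptorSite",
    "RingSite",
    "ChargedSite",
    "HydrophobeSite",
    "PharmacophoreModel",
    "type_protein",
    "type_waters",
    "build_model",
    "ring_centroid",
    "ring_normal",
]

#: covalent H attachment cutoff, Å (frame 0)
H_BOND_CUTOFF = 1.3

_HYDROGEN_ELEMENTS = {"H", "D"}


@dataclass(frozen=True)
class DonorSite:
    donor: int      # heavy atom index
    hydrogen: int
    owner: str      # ligand | protein | water


@dataclass(frozen=True)
class AcceptorSite:
    acceptor: int
    neighbors: tuple[int, ...]   # bonded heavy neighbours X (may be empty)
    owner: str


@dataclass(frozen=True)
class RingSite:
    atoms: tuple[int, ...]
    owner: str


@dataclass(frozen=True)
class ChargedSite:
    atoms: tuple[int, ...]
    charge: int
    owner: str


@dataclass(frozen=True)
class HydrophobeSite:
    atom: int
    owner: str


@dataclass
class PharmacophoreModel:
    """Typed interaction sites over one topology."""

    structure: Structure
    donors: list[DonorSite] = field(default_factory=list)
    acceptors: list[AcceptorSite] = field(default_factory=list)
    rings: list[RingSite] = field(default_factory=list)
    cations: list[ChargedSite] = field(default_factory=list)
    anions: list[ChargedSite] = field(default_factory=list)
    hydrophobes: list[HydrophobeSite] = field(default_factory=list)

    def merged_with(self, other: "PharmacophoreModel") -> "PharmacophoreModel":
        if other.structure is not self.structure:
            raise ValueError("models must share one topology")
        return PharmacophoreModel(
            structure=self.structure,
            donors=self.donors + other.donors,
            acceptors=self.acceptors + other.acceptors,
            rings=self.rings + other.rings,
            cations=self.cations + other.cations,
            anions=self.anions + other.anions,
            hydrophobes=self.hydrophobes + other.hydrophobes,
        )

    def residue_key(self, atom_index: int) -> tuple[str, int, str]:
        return self.structure.atoms[atom_index].residue_key

    def by_owner(self, owner: str) -> "PharmacophoreModel":
        return PharmacophoreModel(
            structure=self.structure,
            donors=[s for s in self.donors if s.owner == owner],
            acceptors=[s for s in self.acceptors if s.owner == owner],
            rings=[s for s in self.rings if s.owner == owner],
            cations=[s for s in self.cations if s.owner == owner],
            anions=[s for s in self.anions if s.owner == owner],
            hydrophobes=[s for s in self.hydrophobes if s.owner == owner],
        )

    def validate(self) -> None:
        n = self.structure.n_atoms
        coords = self.structure.coordinates
        for s in self.donors:
            if not (0 <= s.donor < n and 0 <= s.hydrogen < n):
                raise ValueError(f"donor site {s} out of range")
            d = float(np.linalg.norm(coords[s.hydrogen] - coords[s.donor]))
            if d >= H_BOND_CUTOFF:
                raise ValueError(
                    f"donor H {s.hydrogen} is {d:.2f} Å from heavy atom "
                    f"{s.donor} in frame 0 (must be < {H_BOND_CUTOFF} Å)"
                )
        for ring in self.rings:
            if len(ring.atoms) < 5:
                raise ValueError(f"ring {ring} has fewer than 5 atoms")
        for grp in (self.acceptors, self.cations, self.anions, self.hydrophobes):
            for s in grp:
                idxs = (
                    (s.atom,) if isinstance(s, HydrophobeSite)
                    else (s.acceptor, *s.neighbors) if isinstance(s, AcceptorSite)
                    else s.atoms
                )
                for i in idxs:
                    if not (0 <= i < n):
                        raise ValueError(f"site {s} references atom {i} out of range")


# ---------------------------------------------------------------------------
# geometry helpers

def ring_centroid(coords: np.ndarray, ring: RingSite) -> np.ndarray:
    """Arithmetic mean of the ring-atom coordinates in one frame."""
    return coords[list(ring.atoms)].mean(axis=0)


def ring_normal(coords: np.ndarray, ring: RingSite) -> np.ndarray:
    """Unit normal of the best-fit ring plane (sign arbitrary)."""
    pts = coords[list(ring.atoms)]
    centred = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    normal = vt[-1]
    return normal / np.linalg.norm(normal)


# ---------------------------------------------------------------------------
# templates

def load_templates() -> dict:
    text = (
        resources.files("pocketfp").joinpath("data/residue_templates.json")
        .read_text()
    )
    return json.loads(text)


def _residue_groups(structure: Structure, indices: Iterable[int]):
    """Yield (residue_key, {atom_name: index}) in first-appearance order."""
    groups: dict[tuple, dict[str, int]] = {}
    for i in indices:
        a = structure.atoms[int(i)]
        groups.setdefault(a.residue_key, {})[a.name] = int(i)
    yield from groups.items()


def _attached_hydrogens(
    structure: Structure, heavy: int, name_to_idx: dict[str, int]
) -> list[int]:
    coords = structure.coordinates
    out = []
    for name, i in name_to_idx.items():
        if structure.atoms[i].element.upper() not in _HYDROGEN_ELEMENTS:
            continue
        if np.linalg.norm(coords[i] - coords[heavy]) < H_BOND_CUTOFF:
            out.append(i)
    return sorted(out)


def type_protein(structure: Structure) -> PharmacophoreModel:
    """Type all non-ligand, non-water residues from the template table.

    Nonstandard residues are skipped with a warning; template atoms
    missing from a residue (truncated side chains) are silently ignored,
    except that a charged group or ring loses the site entirely only if
    none of its atoms are present.
    """
    tpl = load_templates()
    residues = tpl["residues"]
    backbone = tpl["backbone"]
    model = PharmacophoreModel(structure=structure)

    for res_key, names in _residue_groups(structure, structure.protein_indices):
        _, _, resname = res_key
        entry = residues.get(resname)
        if entry is None:
            warnings.warn(f"nonstandard residue {res_key}: skipped", stacklevel=2)
            continue

        donor_names = list(entry.get("donors", []))
        if not entry.get("no_backbone_donor", False):
            donor_names = backbone["donors"] + donor_names
        acceptor_map = {**backbone["acceptors"], **entry.get("acceptors", {})}

        for dn in donor_names:
            if dn not in names:
                continue
            for h in _attached_hydrogens(structure, names[dn], names):
                model.donors.append(DonorSite(names[dn], h, "protein"))
        for an, nbrs in acceptor_map.items():
            if an not in names:
                continue
            nbr_idx = tuple(names[x] for x in nbrs if x in names)
            model.acceptors.append(AcceptorSite(names[an], nbr_idx, "protein"))
        for ring in entry.get("rings", []):
            if all(x in names for x in ring):
                model.rings.append(
                    RingSite(tuple(names[x] for x in ring), "protein")
                )
        for group, charge in entry.get("cations", []):
            present = tuple(names[x] for x in group if x in names)
            if present:
                model.cations.append(ChargedSite(present, charge, "protein"))
        for group, charge in entry.get("anions", []):
            present = tuple(names[x] for x in group if x in names)
            if present:
                model.anions.append(ChargedSite(present, charge, "protein"))
        for hn in entry.get("hydrophobes", []):
            if hn in names:
                model.hydrophobes.append(HydrophobeSite(names[hn], "protein"))
    return model


def type_waters(structure: Structure) -> PharmacophoreModel:
    """O -> acceptor (its hydrogens as neighbours); each bonded H -> donor.

    A water without hydrogens still provides its acceptor but is flagged:
    it cannot act as a donor leg of a water bridge.
    """
    model = PharmacophoreModel(structure=structure)
    for res_key, names in _residue_groups(structure, structure.water_indices):
        o_idx = None
        for name, i in names.items():
            if structure.atoms[i].element.upper() == "O":
                o_idx = i
                break
        if o_idx is None:
            warnings.warn(f"water {res_key} has no oxygen: skipped", stacklevel=2)
            continue
        hyds = _attached_hydrogens(structure, o_idx, names)
        model.acceptors.append(AcceptorSite(o_idx, tuple(hyds), "water"))
        if not hyds:
            warnings.warn(
                f"water {res_key} has no hydrogens; it cannot donate in "
                f"water bridges", stacklevel=2,
            )
        for h in hyds:
            model.donors.append(DonorSite(o_idx, h, "water"))
    return model


def type_ligand(
    structure: Structure, annotation: LigandAnnotation
) -> PharmacophoreModel:
    annotation.validate(structure)
    ligand_names = {
        structure.atoms[int(i)].name: int(i) for i in structure.ligand_indices
    }
    model = PharmacophoreModel(structure=structure)
    for d, h in annotation.donors:
        model.donors.append(DonorSite(ligand_names[d], ligand_names[h], "ligand"))
    for a, nbrs in annotation.acceptors.items():
        model.acceptors.append(
            AcceptorSite(ligand_names[a], tuple(ligand_names[x] for x in nbrs),
                         "ligand")
        )
    for ring in annotation.rings:
        model.rings.append(
            RingSite(tuple(ligand_names[x] for x in ring), "ligand")
        )
    for group, charge in annotation.cations:
        model.cations.append(
            ChargedSite(tuple(ligand_names[x] for x in group), charge, "ligand")
        )
    for group, charge in annotation.anions:
        model.anions.append(
            ChargedSite(tuple(ligand_names[x] for x in group), charge, "ligand")
        )
    for hn in annotation.hydrophobes:
        model.hydrophobes.append(HydrophobeSite(ligand_names[hn], "ligand"))
    return model


def build_model(
    structure: Structure, annotation: LigandAnnotation
) -> PharmacophoreModel:
    """Union of ligand, protein and water sites over one topology."""
    model = (
        type_ligand(structure, annotation)
        .merged_with(type_protein(structure))
        .merged_with(type_waters(structure))
    )
    model.validate()
    return model
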