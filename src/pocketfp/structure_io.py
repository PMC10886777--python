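"""Structures, trajectories and ligand annotations.

The data model every analysis module consumes: an ordered atom table
(:class:`Structure`) shared by all frames of a :class:`Trajectory`
(coordinates in Å, frame spacing in ns), read from / written to
multi-model PDB files via gemmi, plus a JSON ligand annotation that
declares the ligand's interaction-capable sites (donor pairs, acceptors
with bonded neighbours, aromatic rings, charged groups, hydrophobes).

Residue identity throughout the package is ``(chain, resseq, resname)``
with 1-based PDB numbering.  No periodic-boundary handling is done:
input trajectories are assumed imaged/whole.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "LigandAnnotation",
    "FormatError",
    "DEFAULT_WATER_RESNAMES",
    "read_multimodel_pdb",
    "write_pdb",
    "read_ligand_annotation",
]

DEFAULT_WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "SPC"})

#: default frame spacing, ns (a 100 ns run recorded in 5000 frames)
DEFAULT_DT_NS = 0.02


class FormatError(ValueError):
    """Malformed structure or annotation input."""


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    resname: str
    chain: str
    resseq: int
    formal_charge: int = 0
    is_ligand: bool = False
    is_water: bool = False

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.resseq, self.resname)


@dataclass
class Structure:
    """Ordered atom table with one coordinate set (Å)."""

    atoms: list[Atom]
    coordinates: np.ndarray  # (n_atoms, 3) Å
    bonds: Optional[list[tuple[int, int]]] = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.atoms), 3):
            raise FormatError(
                f"coordinate array {self.coordinates.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        seen = set()
        for a in self.atoms:
            key = (a.chain, a.resseq, a.name)
            if key in seen:
                raise FormatError(f"duplicate atom {key} in structure")
            seen.add(key)
        if self.bonds:
            n = len(self.atoms)
            for i, j in self.bonds:
                if not (0 <= i < n and 0 <= j < n):
                    raise FormatError(f"bond index ({i}, {j}) out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom_index(self, chain: str, resseq: int, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.chain == chain and a.resseq == resseq and a.name == name:
                return i
        raise KeyError(f"no atom ({chain}, {resseq}, {name})")

    def indices_where(self, predicate) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.atoms) if predicate(a)], dtype=int
        )

    @property
    def ligand_indices(self) -> np.ndarray:
        return self.indices_where(lambda a: a.is_ligand)

    @property
    def water_indices(self) -> np.ndarray:
        return self.indices_where(lambda a: a.is_water)

    @property
    def protein_indices(self) -> np.ndarray:
        return self.indices_where(lambda a: not a.is_ligand and not a.is_water)

    @property
    def calpha_indices(self) -> np.ndarray:
        return self.indices_where(
            lambda a: a.name == "CA" and not a.is_ligand and not a.is_water
        )


@dataclass
class Trajectory:
    """Coordinate frames over a fixed atom table.

    ``frames`` has shape (n_frames, n_atoms, 3); frame 0's coordinates
    also live in ``topology.coordinates``.
    """

    topology: Structure
    frames: np.ndarray
    dt_ns: float = DEFAULT_DT_NS

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (
            self.topology.n_atoms,
            3,
        ):
            raise FormatError(
                f"frames shape {self.frames.shape} incompatible with "
                f"{self.topology.n_atoms} atoms"
            )
        if self.frames.shape[0] < 1:
            raise FormatError("a trajectory needs at least one frame")
        if not self.dt_ns > 0:
            raise FormatError("dt_ns must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_ns

    def slice_frames(self, indices: Sequence[int]) -> "Trajectory":
        """New trajectory over the same topology (identity preserved)."""
        idx = np.asarray(indices, dtype=int)
        if idx.size == 0:
            raise ValueError("empty frame selection")
        if idx.min() < 0 or idx.max() >= self.n_frames:
            raise IndexError("frame index out of range")
        return Trajectory(self.topology, self.frames[idx], dt_ns=self.dt_ns)


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)

def _element_of(at: gemmi.Atom) -> str:
    el = at.element.name
    if el and el != "X":
        return el
    # fall back on the leading letter(s) of the atom name
    guess = "".join(c for c in at.name if c.isalpha())[:1].upper() or "C"
    warnings.warn(
        f"atom {at.name!r}: element missing, inferred {guess!r} from name",
        stacklevel=4,
    )
    return guess


def read_multimodel_pdb(
    path,
    ligand_resnames: Iterable[str] = (),
    water_resnames: Iterable[str] = DEFAULT_WATER_RESNAMES,
    dt_ns: float = DEFAULT_DT_NS,
) -> Trajectory:
    """Read a (multi-)model PDB file into a :class:`Trajectory`.

    One frame per MODEL block (a single-model file yields one frame).
    All models must share the atom ordering of the first; a mismatch is
    a :class:`FormatError` naming the offending model.
    """
    path = str(path)
    ligand_set = {r.upper() for r in ligand_resnames}
    water_set = {r.upper() for r in water_resnames}
    st = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise FormatError(f"{path}: no models found")

    atoms: list[Atom] = []
    frames = []
    for mi, model in enumerate(st):
        coords = []
        count = 0
        for chain in model:
            for res in chain:
                resname = res.name.strip().upper()
                for at in res:
                    if mi == 0:
                        atoms.append(
                            Atom(
                                serial=at.serial,
                                name=at.name,
                                element=_element_of(at),
                                resname=resname,
                                chain=chain.name,
                                resseq=res.seqid.num,
                                formal_charge=int(at.charge),
                                is_ligand=resname in ligand_set,
                                is_water=resname in water_set,
                            )
                        )
                    coords.append([at.pos.x, at.pos.y, at.pos.z])
                    count += 1
        if mi > 0 and count != len(atoms):
            raise FormatError(
                f"{path}: model {model.num} has {count} atoms, "
                f"model {st[0].num} has {len(atoms)}"
            )
        frames.append(coords)

    frames_arr = np.asarray(frames, dtype=float)
    topo = Structure(atoms=atoms, coordinates=frames_arr[0].copy())
    return Trajectory(topology=topo, frames=frames_arr, dt_ns=dt_ns)


def _build_gemmi(traj: Trajectory, frame_indices: Sequence[int]) -> gemmi.Structure:
    st = gemmi.Structure()
    for k, fi in enumerate(frame_indices):
        model = gemmi.Model(k + 1)
        coords = traj.frames[fi]
        chain_obj = None
        res_obj = None
        prev_chain = prev_res = None
        for i, a in enumerate(traj.topology.atoms):
            if a.chain != prev_chain:
                if chain_obj is not None:
                    model.add_chain(chain_obj)
                chain_obj = gemmi.Chain(a.chain)
                prev_chain, prev_res = a.chain, None
            if (a.resseq, a.resname) != prev_res:
                if res_obj is not None:
                    chain_obj.add_residue(res_obj)
                res_obj = gemmi.Residue()
                res_obj.name = a.resname
                res_obj.seqid = gemmi.SeqId(a.resseq, " ")
                prev_res = (a.resseq, a.resname)
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.serial = a.serial
            at.charge = a.formal_charge
            at.occ = 1.0
            at.b_iso = 0.0
            x, y, z = coords[i]
            at.pos = gemmi.Position(float(x), float(y), float(z))
            res_obj.add_atom(at)
        if res_obj is not None:
            chain_obj.add_residue(res_obj)
        if chain_obj is not None:
            model.add_chain(chain_obj)
        st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(
    traj: Trajectory,
    path,
    frame_indices: Optional[Sequence[int]] = None,
    keep_model_records: bool = True,
) -> None:
    """Write trajectory frames as a standard multi-model PDB.

    ``frame_indices`` defaults to all frames; an empty selection or an
    out-of-range index raises.  For a single frame, MODEL/ENDMDL records
    are kept by default (``keep_model_records=False`` drops them).
    """
    if frame_indices is None:
        frame_indices = list(range(traj.n_frames))
    frame_indices = list(frame_indices)
    if not frame_indices:
        raise ValueError("empty frame selection")
    for fi in frame_indices:
        if not (0 <= fi < traj.n_frames):
            raise IndexError(f"frame index {fi} out of range")

    st = _build_gemmi(traj, frame_indices)
    path = str(path)
    st.write_pdb(path)
    if len(frame_indices) == 1 and keep_model_records:
        # gemmi omits MODEL records for a single model; re-insert them
        lines = Path(path).read_text().splitlines()
        out, inserted = [], False
        for ln in lines:
            if not inserted and ln.startswith(("ATOM", "HETATM")):
                out.append("MODEL        1")
                inserted = True
            if ln.startswith("END") and not ln.startswith("ENDMDL") and inserted:
                out.append("ENDMDL")
                inserted = False
            out.append(ln)
        Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# ligand annotation

@dataclass
class LigandAnnotation:
    """Interaction-capable sites of the ligand, by PDB atom name.

    ``donors``   — (donor-heavy-atom, hydrogen) name pairs
    ``acceptors``— acceptor name -> list of bonded-neighbour names
    ``rings``    — lists of ring atom names (>= 5 atoms each)
    ``cations``  — (atom-name list, +charge) groups
    ``anions``   — (atom-name list, -charge) groups
    ``hydrophobes`` — atom names
    """

    donors: list[tuple[str, str]] = field(default_factory=list)
    acceptors: dict[str, list[str]] = field(default_factory=dict)
    rings: list[list[str]] = field(default_factory=list)
    cations: list[tuple[list[str], int]] = field(default_factory=list)
    anions: list[tuple[list[str], int]] = field(default_factory=list)
    hydrophobes: list[str] = field(default_factory=list)

    def all_names(self) -> set[str]:
        names = set(self.hydrophobes)
        for d, h in self.donors:
            names.update((d, h))
        for a, nbrs in self.acceptors.items():
            names.add(a)
            names.update(nbrs)
        for ring in self.rings:
            names.update(ring)
        for group, _ in self.cations + self.anions:
            names.update(group)
        return names

    def validate(self, structure: Structure) -> None:
        """Every named atom must exist in the ligand residue."""
        ligand_names = {
            structure.atoms[i].name for i in structure.ligand_indices
        }
        missing = sorted(self.all_names() - ligand_names)
        if missing:
            raise FormatError(
                f"annotation names atoms absent from the ligand: {missing}"
            )
        for ring in self.rings:
            if len(ring) < 5:
                raise FormatError(f"ring {ring} has fewer than 5 atoms")

    def to_dict(self) -> dict:
        return {
            "donors": [list(p) for p in self.donors],
            "acceptors": {k: list(v) for k, v in self.acceptors.items()},
            "rings": [list(r) for r in self.rings],
            "cations": [[list(g), c] for g, c in self.cations],
            "anions": [[list(g), c] for g, c in self.anions],
            "hydrophobes": list(self.hydrophobes),
        }

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")


def read_ligand_annotation(path) -> LigandAnnotation:
    """Read the ligand annotation JSON (see :class:`LigandAnnotation`)."""
    raw = json.loads(Path(path).read_text())
    try:
        return LigandAnnotation(
            donors=[tuple(p) for p in raw.get("donors", [])],
            acceptors={k: list(v) for k, v in raw.get("acceptors", {}).items()},
            rings=[list(r) for r in raw.get("rings", [])],
            cations=[(list(g), int(c)) for g, c in raw.get("cations", [])],
            anions=[(list(g), int(c)) for g, c in raw.get("anions", [])],
            hydrophobes=list(raw.get("hydrophobes", [])),
        )
    except (TypeError, ValueError) as e:
        raise FormatError(f"malformed ligand annotation {path}: {e}") from e
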