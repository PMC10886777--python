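"""Seeded synthetic inputs with the statistical structure the analysis
assumes.

Three generators:

* :func:`gen_pocket_trajectory` — a small binding pocket (ligand +
  typed residues + optional waters) in which each planted interaction
  toggles on/off per frame, independently, with a stated probability
  (or an explicit per-frame schedule), plus truncated Gaussian
  positional jitter.  The realized on/off state per frame is returned
  as ground truth, so detector frequencies can be checked against the
  planted Bernoulli rate.
* :func:`gen_two_state_trajectory` — a rigid ligand alternating between
  two poses a fixed displacement apart over a static protein, the test
  bed for pose clustering.
* :func:`gen_species_energies` — species-energy tables with known true
  IP/EA for round-tripping the reactivity calculator.

Each planted interaction occupies its own geometric unit: a ligand site
and a partner residue (or water) built at a dedicated bearing on a wide
circle, far enough from every other unit that no cross-unit contact can
satisfy any default criterion.  On-geometries satisfy and
off-geometries violate the active criteria; both are validated with the
real detectors at build time, so the planted truth is unambiguous.
Jitter is truncated at 3 sigma per coordinate and the geometric margins
exceed the worst-case truncated displacement, so jitter never flips the
on/off classification.

The generator produces geometric, not dynamical, truth: there is no
force field and no thermostat.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .interactions import (
    InteractionCriteria,
    detect_frame,
)
from .pharmacophore import build_model
from .reactivity import SpeciesEnergySet
from .structure_io import Atom, LigandAnnotation, Structure, Trajectory, write_pdb

__all__ = [
    "PlantedInteraction",
    "PocketSpec",
    "PocketResult",
    "SpecError",
    "gen_pocket_trajectory",
    "gen_two_state_trajectory",
    "gen_species_energies",
]

PLANTED_KINDS = (
    "hbond", "hbond2", "ionic", "hydrophobic", "pi_pi", "pi_cation",
    "water_bridge",
)

#: event kind each planted unit produces, and how many events per on-frame
_UNIT_EVENT = {
    "hbond": ("hbond", 1),
    "hbond2": ("hbond", 2),
    "ionic": ("ionic", 1),
    "hydrophobic": ("hydrophobic", 1),
    "pi_pi": ("pi_pi", 1),
    "pi_cation": ("pi_cation", 1),
    "water_bridge": ("water_bridge", 1),
}

_LIGAND_RADIUS = 12.0   # Å, bearing circle for ligand anchor points
_MAX_UNITS = 12         # 30° spacing keeps every unit pair > 6 Å apart


class SpecError(ValueError):
    """Infeasible or inconsistent pocket specification."""


@dataclass
class PlantedInteraction:
    """One interaction toggling at per-frame probability ``p`` (or an
    explicit boolean ``schedule`` overriding ``p``)."""

    kind: str
    p: float = 1.0
    schedule: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.kind not in PLANTED_KINDS:
            raise SpecError(f"unknown planted kind {self.kind!r}")
        if not (0.0 <= self.p <= 1.0):
            raise SpecError(f"p must be in [0, 1], got {self.p}")
        if self.schedule is not None:
            self.schedule = np.asarray(self.schedule, dtype=bool)


@dataclass
class PocketSpec:
    planted: list[PlantedInteraction]
    n_filler_residues: int = 8
    n_frames: int = 100
    dt_ns: float = 0.02
    jitter_sigma: float = 0.03   # Å; truncated at 3 sigma per coordinate
    seed: int = 0
    criteria: InteractionCriteria = field(default_factory=InteractionCriteria)

    def __post_init__(self) -> None:
        if len(self.planted) > _MAX_UNITS:
            raise SpecError(f"at most {_MAX_UNITS} planted interactions")
        if self.n_frames < 1:
            raise SpecError("n_frames must be >= 1")
        if self.jitter_sigma < 0:
            raise SpecError("jitter_sigma must be >= 0")
        for pi in self.planted:
            if pi.schedule is not None and len(pi.schedule) != self.n_frames:
                raise SpecError("schedule length must equal n_frames")


@dataclass
class PlantedTruth:
    """Realized per-frame state of one planted interaction."""

    kind: str                  # event kind produced
    residue: tuple[str, int, str]
    events_per_on_frame: int
    states: np.ndarray         # bool per frame

    @property
    def expected_frequency(self) -> float:
        return float(self.states.mean() * self.events_per_on_frame)


@dataclass
class PocketResult:
    trajectory: Trajectory
    annotation: LigandAnnotation
    truth: list[PlantedTruth]
    seed: int

    def write(self, outdir) -> dict:
        """Emit multi-model PDB + annotation JSON + ground-truth JSON
        lines; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "trajectory": outdir / "pocket_trajectory.pdb",
            "annotation": outdir / "ligand_annotation.json",
            "ground_truth": outdir / "ground_truth.jsonl",
            "metadata": outdir / "metadata.json",
        }
        write_pdb(self.trajectory, paths["trajectory"])
        self.annotation.write(paths["annotation"])
        with open(paths["ground_truth"], "w") as fh:
            for t in self.truth:
                for frame, on in enumerate(t.states):
                    fh.write(json.dumps({
                        "frame": frame, "kind": t.kind,
                        "residue": list(t.residue), "on": bool(on),
                    }) + "\n")
        paths["metadata"].write_text(json.dumps({
            "seed": self.seed,
            "n_frames": self.trajectory.n_frames,
            "dt_ns": self.trajectory.dt_ns,
            "planted": [
                {"kind": t.kind, "residue": list(t.residue),
                 "events_per_on_frame": t.events_per_on_frame,
                 "expected_frequency": t.expected_frequency}
                for t in self.truth
            ],
        }, indent=1) + "\n")
        return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# geometry units

@dataclass
class _Unit:
    kind: str
    ligand_atoms: list[tuple[str, np.ndarray]]
    residue: tuple[str, list[tuple[str, np.ndarray]]]   # (resname, atoms)
    water_atoms: list[tuple[str, np.ndarray]]
    moving: str          # 'residue' or 'water'
    off_shift: np.ndarray
    annotation: dict     # fragment merged into the LigandAnnotation


def _frame_axes(theta: float):
    u = np.array([np.cos(theta), np.sin(theta), 0.0])
    v = np.array([-np.sin(theta), np.cos(theta), 0.0])
    w = np.array([0.0, 0.0, 1.0])
    return u, v, w


def _build_unit(kind: str, index: int, theta: float) -> _Unit:
    u, v, w = _frame_axes(theta)
    P = _LIGAND_RADIUS * u
    i = index
    lig: list[tuple[str, np.ndarray]] = []
    wat: list[tuple[str, np.ndarray]] = []
    ann: dict = {}

    if kind == "hbond":
        # ligand N-H donor pointing at an ALA backbone O, collinear
        lig = [(f"N{i}", P), (f"H{i}", P + 1.0 * u)]
        O = P + (1.0 + 1.9) * u
        # C placed so the H-O-C angle is ~115 deg
        cdir = np.cos(np.radians(115)) * (-u) + np.sin(np.radians(115)) * v
        res = ("ALA", [
            ("O", O), ("C", O + 1.23 * cdir),
            ("CA", O + 1.23 * cdir + 1.5 * u), ("CB", O + 1.23 * cdir + 2.6 * u),
        ])
        ann = {"donors": [(f"N{i}", f"H{i}")]}
        return _Unit(kind, lig, res, wat, "residue", 2.6 * u, ann)

    if kind == "hbond2":
        # two ligand donors to the two carboxylate oxygens of one ASP
        n1, h1 = P + 1.4 * v, P + 1.4 * v + 1.0 * u
        n2, h2 = P - 1.4 * v, P - 1.4 * v + 1.0 * u
        od1 = h1 + 1.9 * u
        od2 = h2 + 1.9 * u
        cg = 0.5 * (od1 + od2) + 0.7 * u
        lig = [(f"N{i}A", n1), (f"H{i}A", h1), (f"N{i}B", n2), (f"H{i}B", h2)]
        res = ("ASP", [
            ("OD1", od1), ("OD2", od2), ("CG", cg),
            ("CB", cg + 1.5 * u), ("CA", cg + 3.0 * u),
        ])
        ann = {"donors": [(f"N{i}A", f"H{i}A"), (f"N{i}B", f"H{i}B")]}
        return _Unit(kind, lig, res, wat, "residue", 2.6 * u, ann)

    if kind == "ionic":
        # ligand carboxylate-like anion vs LYS ammonium
        o1, o2 = P + 0.6 * v, P - 0.6 * v
        lig = [(f"O{i}A", o1), (f"O{i}B", o2)]
        nz = P + 3.0 * u
        res = ("LYS", [
            ("NZ", nz), ("CE", nz + 1.5 * u), ("CA", nz + 4.0 * u),
        ])
        ann = {"anions": [([f"O{i}A", f"O{i}B"], -1)]}
        return _Unit(kind, lig, res, wat, "residue", 3.0 * u, ann)

    if kind == "hydrophobic":
        lig = [(f"C{i}", P)]
        cd1 = P + 3.25 * u
        res = ("LEU", [
            ("CD1", cd1), ("CG", cd1 + 1.5 * u), ("CD2", cd1 + 1.5 * u + 1.5 * v),
            ("CB", cd1 + 3.0 * u), ("CA", cd1 + 4.5 * u),
        ])
        ann = {"hydrophobes": [f"C{i}"]}
        return _Unit(kind, lig, res, wat, "residue", 3.0 * u, ann)

    if kind in ("pi_pi", "pi_cation"):
        # ligand benzene ring in the u-v plane (normal along z)
        names, ring_atoms = [], []
        for k in range(6):
            ang = np.radians(60 * k)
            pos = P + 1.39 * (np.cos(ang) * u + np.sin(ang) * v)
            name = f"C{i}{chr(ord('A') + k)}"
            names.append(name)
            ring_atoms.append((name, pos))
        lig = ring_atoms
        ann = {"rings": [names]}
        if kind == "pi_pi":
            res_atoms = []
            for k, nm in enumerate(("CG", "CD1", "CE1", "CZ", "CE2", "CD2")):
                ang = np.radians(60 * k)
                res_atoms.append(
                    (nm, P + 3.6 * w + 1.39 * (np.cos(ang) * u + np.sin(ang) * v))
                )
            res_atoms += [("CB", P + 3.6 * w + 2.9 * u), ("CA", P + 3.6 * w + 4.4 * u)]
            return _Unit(kind, lig, ("PHE", res_atoms), wat, "residue", 2.9 * w, ann)
        nz = P + 4.0 * w
        res = ("LYS", [("NZ", nz), ("CE", nz + 1.5 * w), ("CA", nz + 4.0 * w)])
        return _Unit(kind, lig, res, wat, "residue", 2.5 * w, ann)

    if kind == "water_bridge":
        # ligand acceptor <- water H1; water O <- SER hydroxyl donor,
        # approaching at 40 deg off the outward axis so both water
        # hydrogens stay > 90 deg from the incoming donor hydrogen
        ol, cl = P, P - 1.3 * u
        h1w = P + 1.9 * u
        ow = P + 2.86 * u
        h2dir = np.cos(np.radians(104.5)) * (-u) + np.sin(np.radians(104.5)) * v
        h2w = ow + 0.96 * h2dir
        q = np.cos(np.radians(40)) * u - np.sin(np.radians(40)) * v
        hg = ow + 1.9 * q
        og = hg + 0.96 * q
        lig = [(f"O{i}", ol), (f"C{i}", cl)]
        # OG is the donor heavy atom, HG its hydrogen (between OG and Ow)
        res = ("SER", [
            ("OG", og), ("HG", hg), ("CB", og + 1.4 * q), ("CA", og + 2.9 * q),
        ])
        wat = [("O", ow), ("H1", h1w), ("H2", h2w)]
        ann = {"acceptors": {f"O{i}": [f"C{i}"]}}
        return _Unit(kind, lig, res, wat, "water", 5.0 * v, ann)

    raise SpecError(f"unknown planted kind {kind!r}")


def _merge_annotation(fragments: Sequence[dict]) -> LigandAnnotation:
    ann = LigandAnnotation()
    for f in fragments:
        ann.donors.extend(tuple(p) for p in f.get("donors", []))
        ann.acceptors.update(f.get("acceptors", {}))
        ann.rings.extend(f.get("rings", []))
        ann.cations.extend(f.get("cations", []))
        ann.anions.extend(f.get("anions", []))
        ann.hydrophobes.extend(f.get("hydrophobes", []))
    return ann


def _validate_unit(
    unit: _Unit, criteria: InteractionCriteria, jitter_sigma: float
) -> None:
    """Run the real detectors on the isolated unit at nominal on and off
    geometry; the on state must yield exactly the expected events, the
    off state none."""
    kind, expected = _UNIT_EVENT[unit.kind]
    for on in (True, False):
        atoms, coords = [], []
        serial = 1
        for name, pos in unit.ligand_atoms:
            el = name[0]
            atoms.append(Atom(serial, name, el, "LIG", "L", 1, is_ligand=True))
            coords.append(pos)
            serial += 1
        resname, res_atoms = unit.residue
        shift = np.zeros(3)
        if not on and unit.moving == "residue":
            shift = unit.off_shift
        for name, pos in res_atoms:
            el = "H" if name.startswith("H") else name[0]
            atoms.append(Atom(serial, name, el, resname, "A", 1))
            coords.append(pos + shift)
            serial += 1
        wshift = unit.off_shift if (not on and unit.moving == "water") else np.zeros(3)
        for name, pos in unit.water_atoms:
            el = "H" if name.startswith("H") else "O"
            atoms.append(Atom(serial, name, el, "HOH", "W", 1, is_water=True))
            coords.append(pos + wshift)
            serial += 1
        # an inert hydrogen so hydrogen-dependent detectors can run
        atoms.append(Atom(serial, "HX", "H", "LIG", "L", 1, is_ligand=True))
        coords.append(np.array([0.0, 0.0, 50.0]))
        structure = Structure(atoms=atoms, coordinates=np.array(coords))
        ann = _merge_annotation([unit.annotation])
        model = build_model(structure, ann)
        events = [e for e in detect_frame(structure.coordinates, model, criteria)
                  if e.kind == kind]
        want = expected if on else 0
        if len(events) != want:
            state = "on" if on else "off"
            raise SpecError(
                f"planted {unit.kind}: {state}-geometry yields "
                f"{len(events)} {kind} events, expected {want} "
                f"(on/off geometries may collide with the active criteria)"
            )
    # jitter must not be able to flip a classification
    worst_pair_shift = 2 * 3 * jitter_sigma * np.sqrt(3)
    if worst_pair_shift > 0.32:
        raise SpecError(
            f"jitter_sigma {jitter_sigma} too large: worst-case pair "
            f"displacement {worst_pair_shift:.2f} Å exceeds the smallest "
            f"geometric margin (0.34 Å)"
        )


# ---------------------------------------------------------------------------
# pocket generator

def gen_pocket_trajectory(spec: PocketSpec) -> PocketResult:
    """Build the pocket trajectory and its ground-truth event log.

    Per frame, each planted interaction is independently on with
    probability ``p`` (or follows its explicit schedule); off states
    displace the unit's mobile part (residue or bridging water) well
    past the relevant cutoff.  All atoms then receive truncated
    Gaussian jitter.  A single seeded random stream drives everything,
    so identical specs give bit-identical trajectories.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames

    thetas = np.radians(30.0 * np.arange(len(spec.planted)))
    units = [
        _build_unit(pi.kind, i, thetas[i]) for i, pi in enumerate(spec.planted)
    ]
    for unit in units:
        _validate_unit(unit, spec.criteria, spec.jitter_sigma)

    # --- topology -----------------------------------------------------
    atoms: list[Atom] = []
    base: list[np.ndarray] = []
    serial = 1

    def _add(name, el, resname, chain, resseq, pos, lig=False, water=False):
        nonlocal serial
        atoms.append(Atom(serial, name, el, resname, chain, resseq,
                          is_ligand=lig, is_water=water))
        base.append(np.asarray(pos, float))
        serial += 1
        return len(atoms) - 1

    # ligand core: an inert C-H pair at the centre (guarantees hydrogens)
    _add("CC", "C", "LIG", "L", 1, [0.0, 0.0, 0.0], lig=True)
    _add("HC", "H", "LIG", "L", 1, [0.0, 0.0, 1.09], lig=True)

    moving_idx: list[list[int]] = []
    residues: list[tuple] = []
    for ri, unit in enumerate(units):
        for name, pos in unit.ligand_atoms:
            el = "H" if name.startswith("H") else name[0]
            _add(name, el, "LIG", "L", 1, pos, lig=True)
        resname, res_atoms = unit.residue
        res_idx = []
        for name, pos in res_atoms:
            el = "H" if name.startswith("H") else name[0]
            res_idx.append(_add(name, el, resname, "A", ri + 1, pos))
        wat_idx = []
        for name, pos in unit.water_atoms:
            el = "H" if name.startswith("H") else "O"
            wat_idx.append(_add(name, el, "HOH", "W", ri + 1, pos, water=True))
        moving_idx.append(res_idx if unit.moving == "residue" else wat_idx)
        residues.append(("A", ri + 1, resname))

    # inert filler residues on an outer ring
    n_res = len(units)
    for k in range(spec.n_filler_residues):
        ang = np.radians(15.0 + 30.0 * k)
        centre = 20.0 * np.array([np.cos(ang), np.sin(ang), 0.0])
        rs = n_res + k + 1
        _add("N", "N", "GLY", "A", rs, centre)
        _add("CA", "C", "GLY", "A", rs, centre + [1.46, 0, 0])
        _add("C", "C", "GLY", "A", rs, centre + [2.0, 1.4, 0])
        _add("O", "O", "GLY", "A", rs, centre + [3.2, 1.5, 0])

    # group atoms by chain (L, A, W) so the written PDB keeps each chain
    # contiguous; remap the mobile-atom index lists accordingly
    order = sorted(range(len(atoms)),
                   key=lambda i: ({"L": 0, "A": 1, "W": 2}[atoms[i].chain], i))
    remap = {old: new for new, old in enumerate(order)}
    atoms = [dataclasses.replace(atoms[i], serial=k + 1)
             for k, i in enumerate(order)]
    base_arr = np.array(base)[order]
    moving_idx = [[remap[i] for i in idx] for idx in moving_idx]

    annotation = _merge_annotation([u.annotation for u in units])

    # --- realized states (drawn first, in planted order) --------------
    truth: list[PlantedTruth] = []
    states_all = []
    for i, pi in enumerate(spec.planted):
        if pi.schedule is not None:
            states = pi.schedule.copy()
        else:
            states = rng.random(n) < pi.p
        kind, per_frame = _UNIT_EVENT[pi.kind]
        truth.append(PlantedTruth(
            kind=kind, residue=residues[i],
            events_per_on_frame=per_frame, states=states,
        ))
        states_all.append(states)

    # --- frames --------------------------------------------------------
    frames = np.empty((n, base_arr.shape[0], 3))
    sig = spec.jitter_sigma
    for f in range(n):
        coords = base_arr.copy()
        for i, unit in enumerate(units):
            if not states_all[i][f]:
                coords[moving_idx[i]] += unit.off_shift
        if sig > 0:
            jit = rng.normal(0.0, sig, size=coords.shape)
            np.clip(jit, -3 * sig, 3 * sig, out=jit)
            coords += jit
        frames[f] = coords

    topo = Structure(atoms=atoms, coordinates=frames[0].copy())
    traj = Trajectory(topology=topo, frames=frames, dt_ns=spec.dt_ns)
    return PocketResult(
        trajectory=traj, annotation=annotation, truth=truth, seed=spec.seed
    )


# ---------------------------------------------------------------------------
# two-state pose mixture

def gen_two_state_trajectory(
    weights: Sequence[float] = (0.7, 0.3),
    displacement: float = 5.0,
    jitter: float = 0.3,
    n_frames: int = 5000,
    seed: int = 0,
    dt_ns: float = 0.02,
) -> tuple[Trajectory, np.ndarray]:
    """Rigid ligand hopping between two poses ``displacement`` Å apart
    (along x) over a static 16-residue C-alpha scaffold; returns the
    trajectory and the per-frame state labels (0 = first pose)."""
    weights = np.asarray(weights, float)
    if weights.shape != (2,) or np.any(weights < 0):
        raise ValueError("weights must be two non-negative numbers")
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    if displacement <= 2 * jitter:
        warnings.warn(
            f"displacement {displacement} Å <= 2 x jitter {jitter} Å: "
            f"the two states may overlap", stacklevel=2,
        )
    rng = np.random.default_rng(seed)

    atoms: list[Atom] = []
    base: list[list[float]] = []
    serial = 1
    for k in range(16):
        ang = 2 * np.pi * k / 8
        z = -3.0 if k < 8 else 3.0
        atoms.append(Atom(serial, "CA", "C", "GLY", "A", k + 1))
        base.append([10 * np.cos(ang), 10 * np.sin(ang), z])
        serial += 1
    lig_template = np.array([
        [0, 0, 0], [1.5, 0, 0], [0, 1.5, 0], [0, 0, 1.5],
        [1.5, 1.5, 0], [1.5, 0, 1.5], [0, 1.5, 1.5], [1.5, 1.5, 1.5],
    ], dtype=float) - 0.75
    lig_start = len(atoms)
    for k in range(8):
        atoms.append(Atom(serial, f"C{k + 1}", "C", "LIG", "L", 1,
                          is_ligand=True))
        base.append(list(lig_template[k]))
        serial += 1
    base_arr = np.array(base)

    labels = rng.choice(2, size=n_frames, p=weights)
    frames = np.empty((n_frames, base_arr.shape[0], 3))
    shift = np.array([displacement, 0.0, 0.0])
    for f in range(n_frames):
        coords = base_arr.copy()
        if labels[f] == 1:
            coords[lig_start:] += shift
        if jitter > 0:
            coords += rng.normal(0.0, jitter, size=coords.shape)
        frames[f] = coords

    topo = Structure(atoms=atoms, coordinates=frames[0].copy())
    return Trajectory(topo, frames, dt_ns=dt_ns), labels


def gen_species_energies(
    true_ip: float,
    true_ea: float,
    E_neutral: float = -11530.0,
    compound_id: str = "synthetic",
    unit: str = "eV",
) -> SpeciesEnergySet:
    """Species energies with exactly known IP/EA:
    E(A+) = E(A) + IP, E(A-) = E(A) - EA."""
    return SpeciesEnergySet(
        compound_id=compound_id,
        E_neutral=E_neutral,
        E_cation=E_neutral + true_ip,
        E_anion=E_neutral - true_ea,
        unit=unit,
    )
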