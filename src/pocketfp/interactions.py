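"""Per-frame protein-ligand interaction detection and aggregation.

Five interaction classes are registered between ligand and protein,
each by purely geometric criteria:

hbond         H···A < 2.5 Å, angle(D-H-A) >= 120°, and, when the
              acceptor has bonded neighbours X, min angle(H-A-X) >= 90°
hydrophobic   any apolar-atom pair < 3.6 Å (at most one event per
              residue per frame)
pi_pi         ring-centroid to ring-centroid distance <= 4.5 Å
pi_cation     ring centroid to charged-group centre <= 4.5 Å
ionic         minimum inter-atom distance between oppositely charged
              groups <= 3.4 Å
water_bridge  ligand<->water and water<->protein hydrogen bonds through
              one water, with relaxed thresholds (< 2.8 Å, 110°, 90°)

The two angle conditions are conjunctive by default (both must hold
when the acceptor has neighbours); ``angle_mode='or'`` switches to the
disjunctive reading in which the distance plus either angle admits the
bond.

Aggregation produces per-(residue, kind) contact frequencies: mean
qualifying contacts per frame.  1.0 means the contact is present in
every frame; values above 1 mean multiple simultaneous distinct
contacts (e.g. two hydrogen bonds to one residue).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .pharmacophore import (
    AcceptorSite,
    ChargedSite,
    DonorSite,
    PharmacophoreModel,
    RingSite,
    ring_centroid,
)

__all__ = [
    "InteractionCriteria",
    "InteractionEvent",
    "ContactFrequencyTable",
    "Timeline",
    "CapabilityError",
    "detect_hbonds",
    "detect_ionic",
    "detect_hydrophobic",
    "detect_pi",
    "detect_water_bridges",
    "detect_frame",
    "detect_trajectory",
    "aggregate",
    "timeline",
]

KINDS = ("hbond", "hydrophobic", "pi_pi", "pi_cation", "ionic", "water_bridge")


class CapabilityError(RuntimeError):
    """The topology cannot support the requested detection (e.g. no
    hydrogens for hydrogen-bond geometry)."""


@dataclass(frozen=True)
class InteractionCriteria:
    """Geometric admission thresholds (distances Å, angles degrees)."""

    hbond_max_HA: float = 2.5
    hbond_min_DHA: float = 120.0
    hbond_min_HAX: float = 90.0
    water_max_HA: float = 2.8
    water_min_DHA: float = 110.0
    water_min_HAX: float = 90.0
    ionic_max: float = 3.4
    hydrophobic_max: float = 3.6
    pi_max: float = 4.5
    angle_mode: str = "and"   # 'and' (default) or 'or'

    def __post_init__(self) -> None:
        for name in (
            "hbond_max_HA", "water_max_HA", "ionic_max",
            "hydrophobic_max", "pi_max",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "hbond_min_DHA", "hbond_min_HAX", "water_min_DHA", "water_min_HAX",
        ):
            v = getattr(self, name)
            if not (0 < v <= 180):
                raise ValueError(f"{name} must be in (0, 180]")
        if self.angle_mode not in ("and", "or"):
            raise ValueError("angle_mode must be 'and' or 'or'")


@dataclass(frozen=True)
class InteractionEvent:
    frame: int
    kind: str
    ligand_site: tuple
    residue: tuple[str, int, str]
    partner_site: tuple
    geometry: dict = field(compare=False, hash=False, default_factory=dict)
    water: Optional[tuple[str, int, str]] = None

    @property
    def key(self) -> tuple:
        """Identity of the contact, excluding measured geometry."""
        return (self.kind, self.residue, self.ligand_site,
                self.partner_site, self.water)

    @property
    def sort_key(self) -> tuple:
        return (self.frame, self.kind, self.residue, self.ligand_site,
                self.partner_site, self.water or ("", -1, ""))


def _angle_deg(p1: np.ndarray, vertex: np.ndarray, p3: np.ndarray) -> float:
    u = p1 - vertex
    v = p3 - vertex
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    c = float(np.dot(u, v) / (nu * nv))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _hbond_geometry(
    coords: np.ndarray,
    donor: DonorSite,
    acceptor: AcceptorSite,
    max_HA: float,
    min_DHA: float,
    min_HAX: float,
    angle_mode: str,
) -> Optional[dict]:
    """Geometry dict if the donor/acceptor pair qualifies, else None."""
    if acceptor.acceptor in (donor.donor, donor.hydrogen):
        return None
    H = coords[donor.hydrogen]
    A = coords[acceptor.acceptor]
    d_HA = float(np.linalg.norm(A - H))
    if not d_HA < max_HA:
        return None
    a_DHA = _angle_deg(coords[donor.donor], H, A)
    xs = [x for x in acceptor.neighbors
          if x not in (donor.donor, donor.hydrogen)]
    a_HAX = min((_angle_deg(H, A, coords[x]) for x in xs), default=None)
    dha_ok = a_DHA >= min_DHA
    hax_ok = a_HAX is None or a_HAX >= min_HAX
    if angle_mode == "and":
        ok = dha_ok and hax_ok
    else:  # disjunctive reading of the two angle clauses
        ok = dha_ok or (a_HAX is not None and a_HAX >= min_HAX)
    if not ok:
        return None
    return {"d_HA": d_HA, "angle_DHA": a_DHA, "angle_HAX": a_HAX}


def _require_hydrogens(model: PharmacophoreModel) -> None:
    if not any(
        a.element.upper() in ("H", "D") for a in model.structure.atoms
    ):
        raise CapabilityError(
            "topology contains no hydrogens: hydrogen-bond and water-bridge "
            "geometry (H···A distance, D-H-A angle) cannot be evaluated"
        )


def _donor_site_key(s: DonorSite) -> tuple:
    return ("donor", s.donor, s.hydrogen)


def _acceptor_site_key(s: AcceptorSite) -> tuple:
    return ("acceptor", s.acceptor)


def detect_hbonds(
    frame_coords: np.ndarray,
    model: PharmacophoreModel,
    criteria: InteractionCriteria = InteractionCriteria(),
    frame: int = 0,
) -> list[InteractionEvent]:
    """Direct ligand<->protein hydrogen bonds, both directions."""
    _require_hydrogens(model)
    lig = model.by_owner("ligand")
    prot = model.by_owner("protein")
    events = []
    pairs = [
        (lig.donors, prot.acceptors, True),
        (prot.donors, lig.acceptors, False),
    ]
    for donors, acceptors, ligand_is_donor in pairs:
        for d in donors:
            for a in acceptors:
                g = _hbond_geometry(
                    frame_coords, d, a,
                    criteria.hbond_max_HA, criteria.hbond_min_DHA,
                    criteria.hbond_min_HAX, criteria.angle_mode,
                )
                if g is None:
                    continue
                if ligand_is_donor:
                    lig_site, prot_site = _donor_site_key(d), _acceptor_site_key(a)
                    residue = model.residue_key(a.acceptor)
                else:
                    lig_site, prot_site = _acceptor_site_key(a), _donor_site_key(d)
                    residue = model.residue_key(d.donor)
                events.append(InteractionEvent(
                    frame=frame, kind="hbond", ligand_site=lig_site,
                    residue=residue, partner_site=prot_site, geometry=g,
                ))
    return sorted(events, key=lambda e: e.sort_key)


def detect_ionic(
    frame_coords: np.ndarray,
    model: PharmacophoreModel,
    criteria: InteractionCriteria = InteractionCriteria(),
    frame: int = 0,
) -> list[InteractionEvent]:
    """Salt bridges: opposite formal charges within the cutoff (minimum
    inter-atom distance over the two groups' members)."""
    lig = model.by_owner("ligand")
    prot = model.by_owner("protein")
    events = []
    for lig_grp, prot_grp in (
        (lig.cations, prot.anions), (lig.anions, prot.cations),
    ):
        for gl in lig_grp:
            for gp in prot_grp:
                dmin, pair = _min_group_distance(frame_coords, gl.atoms, gp.atoms)
                if dmin <= criteria.ionic_max:
                    events.append(InteractionEvent(
                        frame=frame, kind="ionic",
                        ligand_site=(_charge_tag(gl), *gl.atoms),
                        residue=model.residue_key(gp.atoms[0]),
                        partner_site=(_charge_tag(gp), *gp.atoms),
                        geometry={"d_min": dmin, "closest_pair": pair},
                    ))
    return sorted(events, key=lambda e: e.sort_key)


def _charge_tag(g: ChargedSite) -> str:
    return "cation" if g.charge > 0 else "anion"


def _min_group_distance(
    coords: np.ndarray, a: Sequence[int], b: Sequence[int]
) -> tuple[float, tuple[int, int]]:
    pa = coords[list(a)]
    pb = coords[list(b)]
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    i, j = np.unravel_index(int(np.argmin(d)), d.shape)
    return float(d[i, j]), (int(a[i]), int(b[j]))


def detect_hydrophobic(
    frame_coords: np.ndarray,
    model: PharmacophoreModel,
    criteria: InteractionCriteria = InteractionCriteria(),
    frame: int = 0,
) -> list[InteractionEvent]:
    """Apolar contacts, capped at one event per residue per frame."""
    lig_atoms = [s.atom for s in model.hydrophobes if s.owner == "ligand"]
    if not lig_atoms:
        return []
    by_res: dict[tuple, list[int]] = {}
    for s in model.hydrophobes:
        if s.owner == "protein":
            by_res.setdefault(model.residue_key(s.atom), []).append(s.atom)
    events = []
    for residue, atoms in by_res.items():
        dmin, pair = _min_group_distance(frame_coords, lig_atoms, atoms)
        if dmin < criteria.hydrophobic_max:
            events.append(InteractionEvent(
                frame=frame, kind="hydrophobic",
                ligand_site=("hydrophobes",),
                residue=residue,
                partner_site=("hydrophobes",),
                geometry={"d_min": dmin, "closest_pair": pair},
            ))
    return sorted(events, key=lambda e: e.sort_key)


def detect_pi(
    frame_coords: np.ndarray,
    model: PharmacophoreModel,
    criteria: InteractionCriteria = InteractionCriteria(),
    frame: int = 0,
) -> list[InteractionEvent]:
    """pi-pi (ring/ring centroid distance) and pi-cation (ring centroid
    to charged-group centre), both within ``pi_max``; centroid-distance
    only, no ring-plane angle filter."""
    lig = model.by_owner("ligand")
    prot = model.by_owner("protein")
    events = []
    for rl in lig.rings:
        cl = ring_centroid(frame_coords, rl)
        for rp in prot.rings:
            d = float(np.linalg.norm(ring_centroid(frame_coords, rp) - cl))
            if d <= criteria.pi_max:
                events.append(InteractionEvent(
                    frame=frame, kind="pi_pi",
                    ligand_site=("ring", *rl.atoms),
                    residue=model.residue_key(rp.atoms[0]),
                    partner_site=("ring", *rp.atoms),
                    geometry={"d_centroid": d},
                ))
        for gp in prot.cations:
            centre = frame_coords[list(gp.atoms)].mean(axis=0)
            d = float(np.linalg.norm(centre - cl))
            if d <= criteria.pi_max:
                events.append(InteractionEvent(
                    frame=frame, kind="pi_cation",
                    ligand_site=("ring", *rl.atoms),
                    residue=model.residue_key(gp.atoms[0]),
                    partner_site=("cation", *gp.atoms),
                    geometry={"d_centroid": d},
                ))
    for gl in lig.cations:
        centre = frame_coords[list(gl.atoms)].mean(axis=0)
        for rp in prot.rings:
            d = float(np.linalg.norm(ring_centroid(frame_coords, rp) - centre))
            if d <= criteria.pi_max:
                events.append(InteractionEvent(
                    frame=frame, kind="pi_cation",
                    ligand_site=("cation", *gl.atoms),
                    residue=model.residue_key(rp.atoms[0]),
                    partner_site=("ring", *rp.atoms),
                    geometry={"d_centroid": d},
                ))
    return sorted(events, key=lambda e: e.sort_key)


def detect_water_bridges(
    frame_coords: np.ndarray,
    model: PharmacophoreModel,
    criteria: InteractionCriteria = InteractionCriteria(),
    frame: int = 0,
) -> list[InteractionEvent]:
    """Ligand-water-protein bridges: both legs must satisfy the relaxed
    hydrogen-bond geometry; one event per distinct (ligand site, water,
    protein site) triple, the bridging water recorded."""
    _require_hydrogens(model)
    lig = model.by_owner("ligand")
    prot = model.by_owner("protein")
    wat = model.by_owner("water")

    waters: dict[tuple, dict[str, list]] = {}
    for d in wat.donors:
        waters.setdefault(model.residue_key(d.donor), {"d": [], "a": []})["d"].append(d)
    for a in wat.acceptors:
        waters.setdefault(model.residue_key(a.acceptor), {"d": [], "a": []})["a"].append(a)

    def _legs(side: PharmacophoreModel, wsites: dict[str, list]):
        """(side site key, geometry) pairs hydrogen-bonded to this water."""
        out = []
        for d in side.donors:
            for a in wsites["a"]:
                g = _hbond_geometry(
                    frame_coords, d, a, criteria.water_max_HA,
                    criteria.water_min_DHA, criteria.water_min_HAX,
                    criteria.angle_mode,
                )
                if g is not None:
                    out.append((_donor_site_key(d), g))
        for a in side.acceptors:
            for d in wsites["d"]:
                g = _hbond_geometry(
                    frame_coords, d, a, criteria.water_max_HA,
                    criteria.water_min_DHA, criteria.water_min_HAX,
                    criteria.angle_mode,
                )
                if g is not None:
                    out.append((_acceptor_site_key(a), g))
        return out

    events = []
    for wkey in sorted(waters):
        wsites = waters[wkey]
        lig_legs = _legs(lig, wsites)
        if not lig_legs:
            continue
        prot_legs = _legs(prot, wsites)
        seen = set()
        for lig_site, g1 in lig_legs:
            for prot_site, g2 in prot_legs:
                residue = model.residue_key(prot_site[1])
                triple = (lig_site, prot_site, residue)
                if triple in seen:
                    continue
                seen.add(triple)
                events.append(InteractionEvent(
                    frame=frame, kind="water_bridge",
                    ligand_site=lig_site, residue=residue,
                    partner_site=prot_site,
                    geometry={"ligand_leg": g1, "protein_leg": g2},
                    water=wkey,
                ))
    return sorted(events, key=lambda e: e.sort_key)


_DETECTORS = (
    detect_hbonds,
    detect_hydrophobic,
    detect_pi,
    detect_ionic,
    detect_water_bridges,
)


def detect_frame(
    frame_coords: np.ndarray,
    model: PharmacophoreModel,
    criteria: InteractionCriteria = InteractionCriteria(),
    frame: int = 0,
) -> list[InteractionEvent]:
    """Union of all five detectors, deterministically ordered."""
    events: list[InteractionEvent] = []
    for det in _DETECTORS:
        events.extend(det(frame_coords, model, criteria, frame=frame))
    return sorted(events, key=lambda e: e.sort_key)


def detect_trajectory(
    traj_frames: np.ndarray,
    model: PharmacophoreModel,
    criteria: InteractionCriteria = InteractionCriteria(),
) -> list[InteractionEvent]:
    """Run :func:`detect_frame` over every frame of a trajectory array
    (or of a :class:`~pocketfp.structure_io.Trajectory`'s ``frames``)."""
    events: list[InteractionEvent] = []
    for fi in range(traj_frames.shape[0]):
        events.extend(detect_frame(traj_frames[fi], model, criteria, frame=fi))
    return events


# ---------------------------------------------------------------------------
# aggregation

@dataclass
class ContactFrequencyTable:
    """Per-(residue, kind) mean contacts per frame.

    ``value == count / n_frames`` exactly; 1.0 corresponds to a contact
    present in 100% of frames, values above 1 to multiple simultaneous
    distinct contacts with that residue.
    """

    table: pd.DataFrame   # columns: chain, resseq, resname, kind, count, value
    n_frames: int

    def value(self, residue: tuple[str, int, str], kind: str) -> float:
        t = self.table
        m = (
            (t["chain"] == residue[0]) & (t["resseq"] == residue[1])
            & (t["resname"] == residue[2]) & (t["kind"] == kind)
        )
        sel = t.loc[m, "value"]
        return float(sel.iloc[0]) if len(sel) else 0.0

    def total_events(self) -> int:
        return int(self.table["count"].sum())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def aggregate(
    events: Iterable[InteractionEvent], n_frames: int
) -> ContactFrequencyTable:
    """Count events per (residue, kind) and divide by the frame count.

    Each distinct simultaneous contact counts, so values may exceed 1.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    counts: dict[tuple, int] = {}
    for e in events:
        key = (e.residue, e.kind)
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {
            "chain": res[0], "resseq": res[1], "resname": res[2],
            "kind": kind, "count": c, "value": c / n_frames,
        }
        for (res, kind), c in sorted(counts.items())
    ]
    table = pd.DataFrame(
        rows, columns=["chain", "resseq", "resname", "kind", "count", "value"]
    )
    return ContactFrequencyTable(table=table, n_frames=n_frames)


@dataclass
class Timeline:
    """Per-frame contact counts for one key, with the longest unbroken
    run of presence."""

    key: tuple
    counts: np.ndarray     # int per frame
    longest_run: int

    @property
    def presence(self) -> np.ndarray:
        return self.counts > 0


def timeline(
    events: Iterable[InteractionEvent],
    key: tuple,
    n_frames: int,
) -> Timeline:
    """Count events matching ``key`` per frame.

    ``key`` is ``(residue, kind)`` or ``(residue,)`` (all kinds).  An
    unknown key simply yields an all-zero series.
    """
    counts = np.zeros(n_frames, dtype=int)
    for e in events:
        ekey = (e.residue, e.kind)
        if ekey[: len(key)] == key:
            counts[e.frame] += 1
    longest = run = 0
    for c in counts:
        run = run + 1 if c > 0 else 0
        longest = max(longest, run)
    return Timeline(key=key, counts=counts, longest_run=longest)
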