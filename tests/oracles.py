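"""Independent brute-force oracles for the interaction detectors, plus
a random-scene generator.

Everything here is deliberately naive: plain-Python triple loops and
math-module trigonometry, sharing no geometry code with the package.
Oracles return sets of event identity keys in the same key format the
detectors use, so the comparison is exact set equality.
"""

from __future__ import annotations

import math

import numpy as np

from pocketfp.pharmacophore import (
    AcceptorSite,
    ChargedSite,
    DonorSite,
    HydrophobeSite,
    PharmacophoreModel,
    RingSite,
)
from pocketfp.structure_io import Atom, Structure


def _dist(p, q):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def _angle(p1, vertex, p3):
    u = [a - b for a, b in zip(p1, vertex)]
    v = [a - b for a, b in zip(p3, vertex)]
    nu = math.sqrt(sum(x * x for x in u))
    nv = math.sqrt(sum(x * x for x in v))
    if nu == 0 or nv == 0:
        return 0.0
    c = sum(a * b for a, b in zip(u, v)) / (nu * nv)
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _hb_ok(coords, d, a, max_ha, min_dha, min_hax, mode="and"):
    if a.acceptor in (d.donor, d.hydrogen):
        return False
    if _dist(coords[d.hydrogen], coords[a.acceptor]) >= max_ha:
        return False
    dha = _angle(coords[d.donor], coords[d.hydrogen], coords[a.acceptor])
    xs = [x for x in a.neighbors if x not in (d.donor, d.hydrogen)]
    haxs = [_angle(coords[d.hydrogen], coords[a.acceptor], coords[x]) for x in xs]
    dha_ok = dha >= min_dha
    hax_ok = (not haxs) or min(haxs) >= min_hax
    if mode == "and":
        return dha_ok and hax_ok
    return dha_ok or (bool(haxs) and min(haxs) >= min_hax)


def _reskey(model, i):
    a = model.structure.atoms[i]
    return (a.chain, a.resseq, a.resname)


def oracle_hbonds(coords, model, crit):
    keys = set()
    lig = model.by_owner("ligand")
    prot = model.by_owner("protein")
    for d in lig.donors:
        for a in prot.acceptors:
            if _hb_ok(coords, d, a, crit.hbond_max_HA, crit.hbond_min_DHA,
                      crit.hbond_min_HAX, crit.angle_mode):
                keys.add(("hbond", _reskey(model, a.acceptor),
                          ("donor", d.donor, d.hydrogen),
                          ("acceptor", a.acceptor), None))
    for d in prot.donors:
        for a in lig.acceptors:
            if _hb_ok(coords, d, a, crit.hbond_max_HA, crit.hbond_min_DHA,
                      crit.hbond_min_HAX, crit.angle_mode):
                keys.add(("hbond", _reskey(model, d.donor),
                          ("acceptor", a.acceptor),
                          ("donor", d.donor, d.hydrogen), None))
    return keys


def oracle_ionic(coords, model, crit):
    keys = set()
    lig = model.by_owner("ligand")
    prot = model.by_owner("protein")
    for gl_list, gp_list in ((lig.cations, prot.anions), (lig.anions, prot.cations)):
        for gl in gl_list:
            for gp in gp_list:
                dmin = min(
                    _dist(coords[i], coords[j])
                    for i in gl.atoms for j in gp.atoms
                )
                if dmin <= crit.ionic_max:
                    tag_l = "cation" if gl.charge > 0 else "anion"
                    tag_p = "cation" if gp.charge > 0 else "anion"
                    keys.add(("ionic", _reskey(model, gp.atoms[0]),
                              (tag_l, *gl.atoms), (tag_p, *gp.atoms), None))
    return keys


def oracle_hydrophobic(coords, model, crit):
    keys = set()
    lig_atoms = [s.atom for s in model.hydrophobes if s.owner == "ligand"]
    prot = [s.atom for s in model.hydrophobes if s.owner == "protein"]
    residues = {}
    for j in prot:
        residues.setdefault(_reskey(model, j), []).append(j)
    for res, atoms in residues.items():
        hit = any(
            _dist(coords[i], coords[j]) < crit.hydrophobic_max
            for i in lig_atoms for j in atoms
        )
        if hit:
            keys.add(("hydrophobic", res, ("hydrophobes",), ("hydrophobes",), None))
    return keys


def _centroid(coords, atoms):
    return [sum(coords[i][k] for i in atoms) / len(atoms) for k in range(3)]


def oracle_pi(coords, model, crit):
    keys = set()
    lig = model.by_owner("ligand")
    prot = model.by_owner("protein")
    for rl in lig.rings:
        cl = _centroid(coords, rl.atoms)
        for rp in prot.rings:
            if _dist(cl, _centroid(coords, rp.atoms)) <= crit.pi_max:
                keys.add(("pi_pi", _reskey(model, rp.atoms[0]),
                          ("ring", *rl.atoms), ("ring", *rp.atoms), None))
        for gp in prot.cations:
            if _dist(cl, _centroid(coords, gp.atoms)) <= crit.pi_max:
                keys.add(("pi_cation", _reskey(model, gp.atoms[0]),
                          ("ring", *rl.atoms), ("cation", *gp.atoms), None))
    for gl in lig.cations:
        cg = _centroid(coords, gl.atoms)
        for rp in prot.rings:
            if _dist(cg, _centroid(coords, rp.atoms)) <= crit.pi_max:
                keys.add(("pi_cation", _reskey(model, rp.atoms[0]),
                          ("cation", *gl.atoms), ("ring", *rp.atoms), None))
    return keys


def oracle_water_bridges(coords, model, crit):
    keys = set()
    lig = model.by_owner("ligand")
    prot = model.by_owner("protein")
    wat = model.by_owner("water")
    waters = {}
    for d in wat.donors:
        waters.setdefault(_reskey(model, d.donor), {"d": [], "a": []})["d"].append(d)
    for a in wat.acceptors:
        waters.setdefault(_reskey(model, a.acceptor), {"d": [], "a": []})["a"].append(a)

    def sides(side, ws):
        found = []
        for d in side.donors:
            for a in ws["a"]:
                if _hb_ok(coords, d, a, crit.water_max_HA, crit.water_min_DHA,
                          crit.water_min_HAX, crit.angle_mode):
                    found.append(("donor", d.donor, d.hydrogen))
        for a in side.acceptors:
            for d in ws["d"]:
                if _hb_ok(coords, d, a, crit.water_max_HA, crit.water_min_DHA,
                          crit.water_min_HAX, crit.angle_mode):
                    found.append(("acceptor", a.acceptor))
        return found

    for wkey, ws in waters.items():
        for ls in sides(lig, ws):
            for ps in sides(prot, ws):
                keys.add(("water_bridge", _reskey(model, ps[1]), ls, ps, wkey))
    return keys


ORACLES = {
    "hbond": oracle_hbonds,
    "ionic": oracle_ionic,
    "hydrophobic": oracle_hydrophobic,
    "pi": oracle_pi,
    "water_bridge": oracle_water_bridges,
}


# ---------------------------------------------------------------------------
# random scenes

def random_scene(rng: np.random.Generator, box: float = 11.0):
    """A random <=300-atom structure with mixed site types on ligand,
    protein and waters, positioned so hits near every threshold are
    common.  Returns (structure, model)."""
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    serial = [0]

    def add(name, el, resname, chain, resseq, pos, lig=False, water=False):
        serial[0] += 1
        atoms.append(Atom(serial[0], name, el, resname, chain, resseq,
                          is_ligand=lig, is_water=water))
        coords.append(np.asarray(pos, float))
        return len(atoms) - 1

    def rand_pos():
        return rng.uniform(0, box, 3)

    def rand_h(heavy_pos):
        v = rng.normal(size=3)
        return heavy_pos + v / np.linalg.norm(v)

    model = PharmacophoreModel.__new__(PharmacophoreModel)
    model.structure = None
    donors, acceptors, rings, cations, anions, hydrophobes = [], [], [], [], [], []

    # --- ligand (chain L, res 1)
    ln = 0
    for k in range(rng.integers(2, 5)):
        p = rand_pos()
        d = add(f"LD{k}", "N", "LIG", "L", 1, p, lig=True)
        h = add(f"LH{k}", "H", "LIG", "L", 1, rand_h(p), lig=True)
        donors.append(DonorSite(d, h, "ligand"))
    for k in range(rng.integers(2, 5)):
        p = rand_pos()
        a = add(f"LA{k}", "O", "LIG", "L", 1, p, lig=True)
        nn = add(f"LX{k}", "C", "LIG", "L", 1, p + rng.normal(size=3) * 0.5, lig=True)
        acceptors.append(AcceptorSite(a, (nn,), "ligand"))
    ring_idx = []
    centre = rand_pos()
    for k in range(6):
        ang = k * np.pi / 3
        ring_idx.append(add(f"LR{k}", "C", "LIG", "L", 1,
                            centre + 1.39 * np.array([np.cos(ang), np.sin(ang), 0]),
                            lig=True))
    rings.append(RingSite(tuple(ring_idx), "ligand"))
    p = rand_pos()
    cations.append(ChargedSite((add("LC+", "N", "LIG", "L", 1, p, lig=True),),
                               1, "ligand"))
    p = rand_pos()
    g = (add("LO-A", "O", "LIG", "L", 1, p, lig=True),
         add("LO-B", "O", "LIG", "L", 1, p + [1.2, 0, 0], lig=True))
    anions.append(ChargedSite(g, -1, "ligand"))
    for k in range(rng.integers(2, 5)):
        hydrophobes.append(HydrophobeSite(
            add(f"LF{k}", "C", "LIG", "L", 1, rand_pos(), lig=True), "ligand"))

    # --- protein (chain A, residues 1..n)
    n_res = int(rng.integers(8, 14))
    for r in range(1, n_res + 1):
        roll = rng.random()
        p = rand_pos()
        if roll < 0.3:
            d = add("ND", "N", "RSD", "A", r, p)
            h = add("HD", "H", "RSD", "A", r, rand_h(p))
            donors.append(DonorSite(d, h, "protein"))
            a = add("OA", "O", "RSD", "A", r, rand_pos())
            nn = add("CX", "C", "RSD", "A", r, coords[a] + rng.normal(size=3) * 0.6)
            acceptors.append(AcceptorSite(a, (nn,), "protein"))
        elif roll < 0.5:
            ring = []
            for k in range(6):
                ang = k * np.pi / 3
                ring.append(add(f"R{k}", "C", "RSD", "A", r,
                                p + 1.39 * np.array([np.cos(ang), np.sin(ang), 0])))
            rings.append(RingSite(tuple(ring), "protein"))
        elif roll < 0.7:
            if rng.random() < 0.5:
                cations.append(ChargedSite(
                    (add("NZ", "N", "RSD", "A", r, p),), 1, "protein"))
            else:
                g = (add("OD1", "O", "RSD", "A", r, p),
                     add("OD2", "O", "RSD", "A", r, p + [1.2, 0, 0]))
                anions.append(ChargedSite(g, -1, "protein"))
        else:
            for k in range(2):
                hydrophobes.append(HydrophobeSite(
                    add(f"CH{k}", "C", "RSD", "A", r, rand_pos()), "protein"))

    # --- waters (chain W)
    for r in range(1, int(rng.integers(6, 12)) + 1):
        p = rand_pos()
        o = add("O", "O", "HOH", "W", r, p, water=True)
        h1 = add("H1", "H", "HOH", "W", r, p + 0.96 * _unit(rng), water=True)
        h2 = add("H2", "H", "HOH", "W", r, p + 0.96 * _unit(rng), water=True)
        acceptors.append(AcceptorSite(o, (h1, h2), "water"))
        donors.append(DonorSite(o, h1, "water"))
        donors.append(DonorSite(o, h2, "water"))

    structure = Structure(atoms=atoms, coordinates=np.array(coords))
    model = PharmacophoreModel(
        structure=structure, donors=donors, acceptors=acceptors,
        rings=rings, cations=cations, anions=anions, hydrophobes=hydrophobes,
    )
    return structure, model


def _unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)
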