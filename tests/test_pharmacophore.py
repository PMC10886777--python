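"""Template typing of protein residues and waters, and model assembly."""

import numpy as np
import pytest

from pocketfp.pharmacophore import (
    PharmacophoreModel,
    RingSite,
    build_model,
    ring_centroid,
    ring_normal,
    type_protein,
    type_waters,
)
from pocketfp.structure_io import Atom, Structure

# side-chain hydrogen names for every donor-capable side-chain atom
_SIDE_H = {
    "ARG": {"NE": "HE", "NH1": "HH1", "NH2": "HH2"},
    "ASN": {"ND2": "HD2"},
    "CYS": {"SG": "HG"},
    "GLN": {"NE2": "HE2"},
    "HIS": {"ND1": "HD1", "NE2": "HE2"},
    "LYS": {"NZ": "HZ"},
    "SER": {"OG": "HG"},
    "THR": {"OG1": "HG1"},
    "TRP": {"NE1": "HE1"},
    "TYR": {"OH": "HH"},
}

# hand-enumerated expected site counts per residue:
# (donor pairs, acceptors, rings, cations, anions, hydrophobes),
# assuming a backbone N-H (except PRO) and one hydrogen per
# donor-capable side-chain heavy atom
EXPECTED = {
    "ALA": (1, 1, 0, 0, 0, 1),
    "ARG": (4, 1, 0, 1, 0, 0),
    "ASN": (2, 2, 0, 0, 0, 0),
    "ASP": (1, 3, 0, 0, 1, 0),
    "CYS": (2, 2, 0, 0, 0, 2),
    "GLN": (2, 2, 0, 0, 0, 0),
    "GLU": (1, 3, 0, 0, 1, 0),
    "GLY": (1, 1, 0, 0, 0, 0),
    "HIS": (3, 3, 1, 0, 0, 0),
    "ILE": (1, 1, 0, 0, 0, 4),
    "LEU": (1, 1, 0, 0, 0, 4),
    "LYS": (2, 1, 0, 1, 0, 0),
    "MET": (1, 1, 0, 0, 0, 4),
    "PHE": (1, 1, 1, 0, 0, 7),
    "PRO": (0, 1, 0, 0, 0, 3),
    "SER": (2, 2, 0, 0, 0, 0),
    "THR": (2, 2, 0, 0, 0, 0),
    "TRP": (2, 1, 2, 0, 0, 9),
    "TYR": (2, 2, 1, 0, 0, 7),
    "VAL": (1, 1, 0, 0, 0, 3),
}


def _element(name):
    return "H" if name.startswith("H") else name[0]


def _build_residue(resname, entry, resseq, origin, atoms, coords, serial):
    """All heavy atoms the template names, plus backbone, plus one H per
    donor-capable heavy atom."""
    names = ["N", "CA", "C", "O"]
    for d in entry.get("donors", []):
        names.append(d)
    for a, nbrs in entry.get("acceptors", {}).items():
        names.extend([a, *nbrs])
    for ring in entry.get("rings", []):
        names.extend(ring)
    for grp, _ in entry.get("cations", []) + entry.get("anions", []):
        names.extend(grp)
    names.extend(entry.get("hydrophobes", []))
    seen, heavy = set(), []
    for n in names:
        if n not in seen:
            seen.add(n)
            heavy.append(n)
    pos = {}
    for k, n in enumerate(heavy):
        pos[n] = origin + np.array([2.0 * k, 0.0, 0.0])
    h_names = dict(_SIDE_H.get(resname, {}))
    if not entry.get("no_backbone_donor", False):
        h_names["N"] = "H"
    for hv, hn in h_names.items():
        pos[hn] = pos[hv] + np.array([0.0, 1.0, 0.0])
    for n, p in pos.items():
        serial[0] += 1
        atoms.append(Atom(serial[0], n, _element(n), resname, "A", resseq))
        coords.append(p)


@pytest.fixture(scope="module")
def peptide_model():
    from pocketfp.pharmacophore import load_templates

    tpl = load_templates()["residues"]
    atoms, coords, serial = [], [], [0]
    for k, resname in enumerate(sorted(EXPECTED)):
        _build_residue(resname, tpl[resname], k + 1,
                       np.array([0.0, 30.0 * k, 0.0]), atoms, coords, serial)
    structure = Structure(atoms, np.array(coords))
    return structure, type_protein(structure)


def test_20_residue_peptide_matches_hand_enumerated_counts(peptide_model):
    structure, model = peptide_model

    def count(sites, resname, idx_of):
        return sum(
            structure.atoms[idx_of(s)].resname == resname for s in sites
        )

    for resname, (nd, na, nr, nc, nan_, nh) in EXPECTED.items():
        assert count(model.donors, resname, lambda s: s.donor) == nd, resname
        assert count(model.acceptors, resname, lambda s: s.acceptor) == na, resname
        assert count(model.rings, resname, lambda s: s.atoms[0]) == nr, resname
        assert count(model.cations, resname, lambda s: s.atoms[0]) == nc, resname
        assert count(model.anions, resname, lambda s: s.atoms[0]) == nan_, resname
        assert count(model.hydrophobes, resname, lambda s: s.atom) == nh, resname


def test_lone_lysine_has_one_cation_at_nz():
    atoms = [
        Atom(1, "N", "N", "LYS", "A", 1), Atom(2, "CA", "C", "LYS", "A", 1),
        Atom(3, "NZ", "N", "LYS", "A", 1),
    ]
    s = Structure(atoms, np.array([[0, 0, 0], [2, 0, 0], [4, 0, 0.0]]))
    m = type_protein(s)
    assert len(m.cations) == 1 and m.cations[0].atoms == (2,)
    assert m.cations[0].charge == 1


def test_lone_glycine_has_backbone_sites_only():
    atoms = [
        Atom(1, "N", "N", "GLY", "A", 1), Atom(2, "H", "H", "GLY", "A", 1),
        Atom(3, "CA", "C", "GLY", "A", 1), Atom(4, "C", "C", "GLY", "A", 1),
        Atom(5, "O", "O", "GLY", "A", 1),
    ]
    s = Structure(atoms, np.array(
        [[0, 0, 0], [0, 1, 0], [2, 0, 0], [4, 0, 0], [4.5, 1, 0.0]]))
    m = type_protein(s)
    assert len(m.donors) == 1 and m.donors[0].donor == 0 and m.donors[0].hydrogen == 1
    assert len(m.acceptors) == 1 and m.acceptors[0].acceptor == 4
    assert not (m.rings or m.cations or m.anions or m.hydrophobes)


def test_nonstandard_residue_skipped_with_warning():
    atoms = [Atom(1, "C1", "C", "UNK", "A", 1)]
    s = Structure(atoms, np.zeros((1, 3)))
    with pytest.warns(UserWarning, match="nonstandard"):
        m = type_protein(s)
    assert not (m.donors or m.acceptors or m.hydrophobes)


def test_waters_give_one_acceptor_and_two_donors_each():
    atoms, coords = [], []
    n = 5
    for r in range(1, n + 1):
        o = np.array([5.0 * r, 0.0, 0.0])
        atoms += [
            Atom(3 * r - 2, "O", "O", "HOH", "W", r, is_water=True),
            Atom(3 * r - 1, "H1", "H", "HOH", "W", r, is_water=True),
            Atom(3 * r, "H2", "H", "HOH", "W", r, is_water=True),
        ]
        coords += [o, o + [0.96, 0, 0], o + [-0.24, 0.93, 0]]
    s = Structure(atoms, np.array(coords))
    m = type_waters(s)
    assert len(m.acceptors) == n and len(m.donors) == 2 * n
    assert all(len(a.neighbors) == 2 for a in m.acceptors)


def test_oxygen_only_water_warns_and_gives_no_donors():
    atoms = [Atom(1, "O", "O", "HOH", "W", 1, is_water=True)]
    s = Structure(atoms, np.zeros((1, 3)))
    with pytest.warns(UserWarning, match="no hydrogens"):
        m = type_waters(s)
    assert len(m.acceptors) == 1 and not m.donors


def test_ring_centroid_and_unit_normal():
    pts = np.array(
        [[np.cos(a), np.sin(a), 0.0] for a in np.linspace(0, 2 * np.pi, 6, False)]
    )
    ring = RingSite(tuple(range(6)), "ligand")
    c = ring_centroid(pts, ring)
    n = ring_normal(pts, ring)
    assert np.allclose(c, pts.mean(axis=0))
    assert np.isclose(np.linalg.norm(n), 1.0)
    assert np.isclose(abs(n[2]), 1.0)  # planar ring in z=0


def test_build_model_matches_generator_ground_truth(pocket_all_kinds):
    topo = pocket_all_kinds.trajectory.topology
    model = build_model(topo, pocket_all_kinds.annotation)
    lig = model.by_owner("ligand")
    ann = pocket_all_kinds.annotation
    assert len(lig.donors) == len(ann.donors)
    assert len(lig.acceptors) == len(ann.acceptors)
    assert len(lig.rings) == len(ann.rings)
    assert len(lig.hydrophobes) == len(ann.hydrophobes)
    # deterministic: same inputs give the identical model
    model2 = build_model(topo, pocket_all_kinds.annotation)
    assert model.donors == model2.donors
    assert model.acceptors == model2.acceptors
    assert model.rings == model2.rings
    # owner index sets are disjoint
    def idxs(m):
        out = set()
        for s in m.donors:
            out |= {s.donor, s.hydrogen}
        for s in m.acceptors:
            out |= {s.acceptor}
        for s in m.rings:
            out |= set(s.atoms)
        for s in m.hydrophobes:
            out |= {s.atom}
        return out

    assert idxs(model.by_owner("ligand")).isdisjoint(idxs(model.by_owner("protein")))
    assert idxs(model.by_owner("ligand")).isdisjoint(idxs(model.by_owner("water")))
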