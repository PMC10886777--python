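"""Interaction detectors against constructed geometries and the
brute-force oracle, plus contact-frequency aggregation semantics."""

import dataclasses

import numpy as np
import pytest

from pocketfp.interactions import (
    CapabilityError,
    InteractionCriteria,
    InteractionEvent,
    aggregate,
    detect_frame,
    detect_hbonds,
    detect_hydrophobic,
    detect_ionic,
    detect_pi,
    detect_water_bridges,
    timeline,
)
from pocketfp.pharmacophore import (
    AcceptorSite,
    ChargedSite,
    DonorSite,
    HydrophobeSite,
    PharmacophoreModel,
    RingSite,
)
from pocketfp.structure_io import Atom, Structure

from oracles import (
    ORACLES,
    oracle_hbonds,
    oracle_hydrophobic,
    oracle_ionic,
    oracle_pi,
    oracle_water_bridges,
    random_scene,
)

CRIT = InteractionCriteria()


def _hbond_scene(d_ha=1.9, dha=180.0):
    """Ligand N-H donor aimed at protein O acceptor; DHA set by bending
    the donor arm."""
    rad = np.radians(180.0 - dha)
    atoms = [
        Atom(1, "N1", "N", "LIG", "L", 1, is_ligand=True),
        Atom(2, "H1", "H", "LIG", "L", 1, is_ligand=True),
        Atom(3, "O", "O", "ALA", "A", 7),
        Atom(4, "C", "C", "ALA", "A", 7),
    ]
    h = np.array([0.0, 0.0, 0.0])
    n = h - np.array([np.cos(rad), np.sin(rad), 0.0])
    o = h + np.array([d_ha, 0.0, 0.0])
    c = o + np.array([0.5, 1.2, 0.0])   # H-O-C angle ~112 deg
    s = Structure(atoms, np.array([n, h, o, c]))
    model = PharmacophoreModel(
        structure=s,
        donors=[DonorSite(0, 1, "ligand")],
        acceptors=[AcceptorSite(2, (3,), "protein")],
    )
    return s, model


def test_ideal_hbond_detected():
    s, m = _hbond_scene(d_ha=1.9, dha=180.0)
    ev = detect_hbonds(s.coordinates, m, CRIT)
    assert len(ev) == 1
    assert ev[0].residue == ("A", 7, "ALA")
    assert ev[0].geometry["d_HA"] == pytest.approx(1.9)
    assert ev[0].geometry["angle_DHA"] == pytest.approx(180.0)


def test_hbond_distance_threshold_is_strict():
    s, m = _hbond_scene(d_ha=2.6)
    assert detect_hbonds(s.coordinates, m, CRIT) == []
    s, m = _hbond_scene(d_ha=2.49)
    assert len(detect_hbonds(s.coordinates, m, CRIT)) == 1


def test_hbond_dha_angle_threshold():
    s, m = _hbond_scene(dha=119.0)
    assert detect_hbonds(s.coordinates, m, CRIT) == []
    s, m = _hbond_scene(dha=121.0)
    assert len(detect_hbonds(s.coordinates, m, CRIT)) == 1


def test_hbond_hax_condition_and_or_modes():
    # place the acceptor neighbour so angle(H, A, X) ~ 40 deg < 90
    s, m = _hbond_scene()
    coords = s.coordinates.copy()
    coords[3] = coords[2] + np.array([-1.0, 0.4, 0.0])  # X back toward H
    assert detect_hbonds(coords, m, CRIT) == []
    # disjunctive reading: DHA=180 passes on its own
    or_crit = dataclasses.replace(CRIT, angle_mode="or")
    assert len(detect_hbonds(coords, m, or_crit)) == 1


def test_hbond_without_hydrogens_is_capability_error():
    atoms = [
        Atom(1, "O1", "O", "LIG", "L", 1, is_ligand=True),
        Atom(2, "O", "O", "ALA", "A", 1),
    ]
    s = Structure(atoms, np.zeros((2, 3)))
    m = PharmacophoreModel(structure=s,
                           acceptors=[AcceptorSite(0, (), "ligand"),
                                      AcceptorSite(1, (), "protein")])
    with pytest.raises(CapabilityError, match="hydrogens"):
        detect_hbonds(s.coordinates, m, CRIT)


def _ionic_scene(dist, lig_charge=-1, prot_charge=1):
    atoms = [
        Atom(1, "O1", "O", "LIG", "L", 1, is_ligand=True),
        Atom(2, "O2", "O", "LIG", "L", 1, is_ligand=True),
        Atom(3, "NZ", "N", "LYS", "A", 9),
    ]
    coords = np.array([[0, 0.6, 0], [0, -0.6, 0], [dist, 0, 0.0]])
    s = Structure(atoms, coords)
    lig_site = ChargedSite((0, 1), lig_charge, "ligand")
    prot_site = ChargedSite((2,), prot_charge, "protein")
    m = PharmacophoreModel(
        structure=s,
        cations=[x for x in (lig_site, prot_site) if x.charge > 0],
        anions=[x for x in (lig_site, prot_site) if x.charge < 0],
    )
    return s, m


def test_ionic_at_cutoff_and_min_group_distance():
    # group O at (0, +-0.6); NZ at 3.3 -> min distance 3.354 <= 3.4
    s, m = _ionic_scene(3.3)
    ev = detect_ionic(s.coordinates, m, CRIT)
    assert len(ev) == 1
    assert ev[0].geometry["d_min"] == pytest.approx(np.hypot(3.3, 0.6))
    s, m = _ionic_scene(3.45)  # min distance 3.50 > 3.4
    assert detect_ionic(s.coordinates, m, CRIT) == []


def test_like_charges_never_interact():
    s, m = _ionic_scene(2.0, lig_charge=1, prot_charge=1)
    assert detect_ionic(s.coordinates, m, CRIT) == []


def test_hydrophobic_capped_at_one_event_per_residue():
    atoms = [Atom(i + 1, f"C{i}", "C", "LIG", "L", 1, is_ligand=True)
             for i in range(5)]
    atoms += [Atom(10 + i, f"CD{i}", "C", "LEU", "A", 3) for i in range(2)]
    coords = np.array([[0, i, 0] for i in range(5)]
                      + [[3.5, 0, 0], [3.5, 1, 0]], dtype=float)
    s = Structure(atoms, coords)
    m = PharmacophoreModel(
        structure=s,
        hydrophobes=[HydrophobeSite(i, "ligand") for i in range(5)]
        + [HydrophobeSite(5, "protein"), HydrophobeSite(6, "protein")],
    )
    ev = detect_hydrophobic(s.coordinates, m, CRIT)
    assert len(ev) == 1  # many qualifying pairs, one residue -> one event
    assert ev[0].geometry["d_min"] == pytest.approx(3.5)


def test_pi_centroid_distance_rule():
    def ring_at(offset, owner, resname, resseq, start):
        pts = [offset + 1.39 * np.array([np.cos(a), np.sin(a), 0.0])
               for a in np.linspace(0, 2 * np.pi, 6, False)]
        ats = [Atom(start + k, f"C{k}", "C", resname, "L" if owner == "ligand" else "A",
                    resseq, is_ligand=owner == "ligand") for k in range(6)]
        return ats, pts

    for d, expect in ((3.8, 1), (4.6, 0)):
        a1, p1 = ring_at(np.zeros(3), "ligand", "LIG", 1, 1)
        a2, p2 = ring_at(np.array([0, 0, d]), "protein", "PHE", 4, 7)
        s = Structure(a1 + a2, np.array(p1 + p2))
        m = PharmacophoreModel(
            structure=s,
            rings=[RingSite(tuple(range(6)), "ligand"),
                   RingSite(tuple(range(6, 12)), "protein")],
        )
        ev = detect_pi(s.coordinates, m, CRIT)
        assert len(ev) == expect, d
        if expect:
            assert ev[0].kind == "pi_pi"
            assert ev[0].geometry["d_centroid"] == pytest.approx(d)


def _bridge_scene(protein_leg_ha=1.9):
    """Ligand acceptor <- water H1; water O <- SER O-H donor."""
    u = np.array([1.0, 0, 0])
    v = np.array([0, 1.0, 0])
    ol = np.zeros(3)
    cl = ol - 1.3 * u
    h1w = ol + 1.9 * u
    ow = ol + 2.86 * u
    h2 = ow + 0.96 * (np.cos(np.radians(104.5)) * (-u) + np.sin(np.radians(104.5)) * v)
    q = np.cos(np.radians(40)) * u - np.sin(np.radians(40)) * v
    hg = ow + protein_leg_ha * q
    og = hg + 0.96 * q
    atoms = [
        Atom(1, "O1", "O", "LIG", "L", 1, is_ligand=True),
        Atom(2, "C1", "C", "LIG", "L", 1, is_ligand=True),
        Atom(3, "O", "O", "HOH", "W", 1, is_water=True),
        Atom(4, "H1", "H", "HOH", "W", 1, is_water=True),
        Atom(5, "H2", "H", "HOH", "W", 1, is_water=True),
        Atom(6, "OG", "O", "SER", "A", 5),
        Atom(7, "HG", "H", "SER", "A", 5),
    ]
    s = Structure(atoms, np.array([ol, cl, ow, h1w, h2, og, hg]))
    m = PharmacophoreModel(
        structure=s,
        donors=[DonorSite(2, 3, "water"), DonorSite(2, 4, "water"),
                DonorSite(5, 6, "protein")],
        acceptors=[AcceptorSite(0, (1,), "ligand"),
                   AcceptorSite(2, (3, 4), "water")],
    )
    return s, m


def test_water_bridge_detected_and_names_the_water():
    s, m = _bridge_scene()
    ev = detect_water_bridges(s.coordinates, m, CRIT)
    assert len(ev) == 1
    assert ev[0].water == ("W", 1, "HOH")
    assert ev[0].residue == ("A", 5, "SER")


def test_water_bridge_fails_when_one_leg_too_long():
    s, m = _bridge_scene(protein_leg_ha=2.9)  # > 2.8 relaxed cutoff
    assert detect_water_bridges(s.coordinates, m, CRIT) == []


# ---------------------------------------------------------------------------
# oracle equivalence and properties

def _keys(events):
    return {e.key for e in events}


def test_detectors_equal_brute_force_oracle_on_random_scenes(rng):
    """Every detector's event set must exactly match an exhaustive
    enumeration on randomly generated mixed scenes."""
    for _ in range(40):
        s, m = random_scene(rng)
        coords = s.coordinates
        assert _keys(detect_hbonds(coords, m, CRIT)) == oracle_hbonds(coords, m, CRIT)
        assert _keys(detect_ionic(coords, m, CRIT)) == oracle_ionic(coords, m, CRIT)
        assert _keys(detect_hydrophobic(coords, m, CRIT)) == \
            oracle_hydrophobic(coords, m, CRIT)
        assert _keys(detect_pi(coords, m, CRIT)) == oracle_pi(coords, m, CRIT)
        assert _keys(detect_water_bridges(coords, m, CRIT)) == \
            oracle_water_bridges(coords, m, CRIT)


def test_detect_frame_is_union_of_detectors(rng):
    s, m = random_scene(rng)
    all_ev = detect_frame(s.coordinates, m, CRIT)
    parts = (
        detect_hbonds(s.coordinates, m, CRIT)
        + detect_ionic(s.coordinates, m, CRIT)
        + detect_hydrophobic(s.coordinates, m, CRIT)
        + detect_pi(s.coordinates, m, CRIT)
        + detect_water_bridges(s.coordinates, m, CRIT)
    )
    assert _keys(all_ev) == _keys(parts)
    assert len(all_ev) == len(parts)
    # deterministic ordering
    assert [e.sort_key for e in all_ev] == sorted(e.sort_key for e in all_ev)


def test_empty_model_yields_no_events():
    atoms = [Atom(1, "C1", "C", "LIG", "L", 1, is_ligand=True),
             Atom(2, "H1", "H", "LIG", "L", 1, is_ligand=True)]
    s = Structure(atoms, np.zeros((2, 3)) + [[0, 0, 0], [1, 0, 0]])
    m = PharmacophoreModel(structure=s)
    assert detect_frame(s.coordinates, m, CRIT) == []


def test_enlarging_cutoffs_never_removes_events(rng):
    for _ in range(10):
        s, m = random_scene(rng)
        base = _keys(detect_frame(s.coordinates, m, CRIT))
        wider = InteractionCriteria(
            hbond_max_HA=3.0, water_max_HA=3.3, ionic_max=4.2,
            hydrophobic_max=4.4, pi_max=5.5,
        )
        assert base <= _keys(detect_frame(s.coordinates, m, wider))


def test_criteria_validation():
    with pytest.raises(ValueError):
        InteractionCriteria(hbond_max_HA=-1)
    with pytest.raises(ValueError):
        InteractionCriteria(hbond_min_DHA=200)
    with pytest.raises(ValueError):
        InteractionCriteria(angle_mode="maybe")


# ---------------------------------------------------------------------------
# aggregation and timelines

def _event(frame, residue=("A", 1, "LEU"), kind="hbond", site=("donor", 0, 1)):
    return InteractionEvent(frame=frame, kind=kind, ligand_site=site,
                            residue=residue, partner_site=("acceptor", 9))


def test_frequency_is_count_over_frames():
    events = [_event(f) for f in range(250)]
    t = aggregate(events, 1000)
    assert t.value(("A", 1, "LEU"), "hbond") == 0.25
    t = aggregate([_event(f) for f in range(1000)], 1000)
    assert t.value(("A", 1, "LEU"), "hbond") == 1.0


def test_two_simultaneous_contacts_give_two():
    events = []
    for f in range(100):
        events.append(_event(f, site=("donor", 0, 1)))
        events.append(_event(f, site=("donor", 2, 3)))
    t = aggregate(events, 100)
    assert t.value(("A", 1, "LEU"), "hbond") == 2.0


def test_aggregation_conserves_event_count(rng):
    events = []
    for _ in range(500):
        events.append(_event(
            int(rng.integers(0, 50)),
            residue=("A", int(rng.integers(1, 6)), "XXX"),
            kind=["hbond", "ionic", "pi_pi"][int(rng.integers(0, 3))],
        ))
    t = aggregate(events, 50)
    total = (t.table["value"] * 50).sum()
    assert total == pytest.approx(len(events), abs=1e-9)
    assert t.total_events() == len(events)


def test_aggregate_rejects_zero_frames():
    with pytest.raises(ValueError):
        aggregate([], 0)


def test_timeline_runs_and_unknown_key():
    events = [_event(f) for f in list(range(10)) + list(range(20, 25))]
    tl = timeline(events, (("A", 1, "LEU"), "hbond"), 30)
    assert tl.counts.sum() == 15
    assert tl.longest_run == 10
    empty = timeline(events, (("B", 9, "GLY"), "hbond"), 30)
    assert empty.counts.sum() == 0 and empty.longest_run == 0
    # residue-only key matches all kinds
    tl2 = timeline(events, (("A", 1, "LEU"),), 30)
    assert tl2.counts.sum() == 15


def test_all_frames_contact_longest_run():
    events = [_event(f) for f in range(40)]
    tl = timeline(events, (("A", 1, "LEU"), "hbond"), 40)
    assert tl.longest_run == 40
    assert (tl.counts == 1).all()
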