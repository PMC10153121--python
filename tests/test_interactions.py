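"""Interaction detectors vs exhaustive brute-force oracles."""

import numpy as np
import pytest
import mdtraj as md

import oracles
from allonet.interactions import (HbondCriteria, detect_hbonds, occupancy,
                                  pi_stacking, residue_contacts,
                                  sp2_carbon_pairs)
from allonet.regions import RegionMap
from allonet.synth import (LigandSpec, PlantedHbond, SyntheticSpec,
                           generate_trajectory)


def _single_residue_regions(top):
    regions = {f"r{r.index}": (r.index, r.index + 1)
               for r in top.residues if r.is_protein}
    return RegionMap(regions=regions, catalytic_acid=0, nucleophile=1)


def _place(traj, updates):
    """Return a copy of frame 0 with atoms moved (Angstrom coordinates)."""
    xyz = traj.xyz.copy()
    for idx, pos in updates.items():
        xyz[0, idx] = np.asarray(pos) / 10.0
    return md.Trajectory(xyz, traj.topology)


# --------------------------------------------------------------- contacts

def test_contact_at_3p9_but_not_4p0(rng):
    traj = oracles.toy_system(rng, n_res=2, n_frames=1, box=30.0)
    top = traj.topology
    ca0 = top.residue(0).atom(2).index
    ca1 = top.residue(1).atom(2).index
    xyz = np.zeros_like(traj.xyz)
    xyz[0, :, 0] = np.arange(top.n_atoms) * 2.0   # spread out along x (nm)
    xyz[0, ca0] = (0.0, 0.0, 0.0)
    t39 = md.Trajectory(xyz.copy(), top)
    t39.xyz[0, ca1] = (0.39, 0.0, 0.0)
    t40 = md.Trajectory(xyz.copy(), top)
    t40.xyz[0, ca1] = (0.40, 0.0, 0.0)
    rm = _single_residue_regions(top)
    res39 = residue_contacts(t39, rm, [("r0", "r1")])
    res40 = residue_contacts(t40, rm, [("r0", "r1")])
    assert res39.present[0, 0]
    assert not res40.present[0, 0]     # strict <, boundary excluded


def test_empty_scope_rejected(rng):
    traj = oracles.toy_system(rng, n_res=2, n_frames=1)
    with pytest.raises(ValueError, match="scope"):
        residue_contacts(traj, _single_residue_regions(traj.topology), [])


@pytest.mark.parametrize("seed", range(6))
def test_contacts_equal_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    traj = oracles.toy_system(rng, n_res=5, n_frames=3, box=9.0,
                              with_ligand=True)
    rm = _single_residue_regions(traj.topology)
    names = sorted(rm.regions)
    scope = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    scope += [(a, "ligand") for a in names]
    got = residue_contacts(traj, rm, scope)
    lig = traj.topology.n_residues - 1
    for rec, col in zip(got.records, got.present.T):
        a = lig if rec.a == "ligand" else rec.a
        b = lig if rec.b == "ligand" else rec.b
        assert list(col) == oracles.brute_contacts(traj, a, b), rec.key


# --------------------------------------------------------------- h-bonds

def test_ideal_hbond_detected_and_rotated_not(rng):
    traj = oracles.toy_system(rng, n_res=2, n_frames=1, box=40.0)
    top = traj.topology
    i = {(a.residue.index, a.name): a.index for a in top.atoms}
    # donor N-H of residue 0 along +x; acceptor O of residue 1
    base = {i[(0, "N")]: (0, 0, 0), i[(0, "H")]: (1.0, 0, 0),
            i[(0, "CA")]: (-0.7, 1.0, 0), i[(0, "C")]: (-1.5, 1.5, 0),
            i[(0, "O")]: (-2.5, 1.5, 0)}
    ideal = dict(base)
    ideal[i[(1, "O")]] = (2.9, 0.12, 0)        # H···A 1.9, D-H-A ≈ 175°
    rotated = dict(base)
    rotated[i[(1, "O")]] = (1.0, 1.9, 0)       # D-H-A = 90°
    t1 = _place(traj, ideal)
    t2 = _place(traj, rotated)
    keys1 = {r.key for r in detect_hbonds(t1).records}
    assert any(":0:1:" in k for k in keys1)
    assert not any(":0:1:" in k for k in {r.key for r in detect_hbonds(t2).records})


def test_hbond_requires_hydrogens():
    top = md.Topology()
    ch = top.add_chain()
    res = top.add_residue("ALA", ch)
    top.add_atom("N", md.element.nitrogen, res)
    top.add_atom("O", md.element.oxygen, res)
    traj = md.Trajectory(np.zeros((1, 2, 3), np.float32), top)
    with pytest.raises(ValueError, match="hydrogens"):
        detect_hbonds(traj)


def test_as_printed_conventions_change_the_verdict(rng):
    """D-A = 2.3 Å with D-H-A = 100°: invisible to the Baker-Hubbard
    default, detected under the as-printed reading."""
    traj = oracles.toy_system(rng, n_res=2, n_frames=1, box=40.0)
    top = traj.topology
    i = {(a.residue.index, a.name): a.index for a in top.atoms}
    h = np.array([1.0, 0.0, 0.0])
    ang = np.deg2rad(100.0)
    acc = h + 1.9 * np.array([-np.cos(ang), np.sin(ang), 0.0])  # D-H-A=100°
    acc = acc / np.linalg.norm(acc) * 2.3       # |D-A| = 2.3
    t = _place(traj, {i[(0, "N")]: (0, 0, 0), i[(0, "H")]: tuple(h),
                      i[(0, "CA")]: (-0.7, 1.0, 0), i[(0, "C")]: (-1.5, 1.5, 0),
                      i[(0, "O")]: (-2.5, 1.5, 0), i[(1, "O")]: tuple(acc)})
    default = detect_hbonds(t)
    printed = detect_hbonds(t, HbondCriteria(distance_convention="donor-acceptor",
                                             angle_convention="dha-below"))
    assert not any(r.a == 0 and r.b == 1 for r in default.records)
    assert any(r.a == 0 and r.b == 1 for r in printed.records)


def test_planted_occupancy_recovered(two_state):
    spec, traj, truth = two_state
    det = detect_hbonds(traj)
    keymap = {(r.a, r.b): k for k, r in enumerate(det.records)}
    for b in truth.bonds:
        col = det.present[:, keymap[(b["donor"], b["acceptor"])]]
        assert np.array_equal(col, np.asarray(b["present"]))


@pytest.mark.parametrize("seed", range(6))
def test_hbonds_equal_brute_force_oracle(seed):
    rng = np.random.default_rng(100 + seed)
    traj = oracles.toy_system(rng, n_res=6, n_frames=3, box=7.0)
    got = detect_hbonds(traj)
    want = oracles.brute_hbonds(traj)
    got_map = {}
    top = traj.topology
    atom = {}
    for a in top.atoms:
        atom[(a.residue.index, a.name)] = a.index
    for rec, col in zip(got.records, got.present.T):
        d = atom[(rec.a, rec.atoms[0])]
        h = atom[(rec.a, rec.atoms[1])]
        ac = atom[(rec.b, rec.atoms[2])]
        got_map[(d, h, ac)] = list(col)
    assert got_map == want


# --------------------------------------------------------------- stacking

def _two_ring_system(gap, t_shape=False):
    """Protein PHE ring + ligand ring, parallel at ``gap`` Å (or T-shaped)."""
    from allonet.geometry import ring_coords
    top = md.Topology()
    ch = top.add_chain()
    res = top.add_residue("PHE", ch, resSeq=1)
    for nm, el in (("N", md.element.nitrogen), ("H", md.element.hydrogen),
                   ("CA", md.element.carbon), ("C", md.element.carbon),
                   ("O", md.element.oxygen)):
        top.add_atom(nm, el, res)
    ring = [top.add_atom(nm, md.element.carbon, res)
            for nm in ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")]
    for a, b in zip(ring, ring[1:] + ring[:1]):
        top.add_bond(a, b)
    lch = top.add_chain()
    lres = top.add_residue("LIG", lch, resSeq=1)
    latoms = [top.add_atom(f"C{k+1}", md.element.carbon, lres)
              for k in range(6)]
    for a, b in zip(latoms, latoms[1:] + latoms[:1]):
        top.add_bond(a, b)
    xyz = np.zeros((1, top.n_atoms, 3))
    xyz[0, :5] = [[-20, 0, 0], [-21, 0, 0], [-22, 0, 0], [-23, 0, 0],
                  [-24, 0, 0]]
    xyz[0, 5:11] = ring_coords([0, 0, 0], normal=[0, 0, 1])
    if t_shape:
        xyz[0, 11:] = ring_coords([0, 1.39 + gap, 1.39], normal=[0, 1, 0],
                                  phase_deg=0.0)
    else:
        xyz[0, 11:] = ring_coords([0, 0, gap], normal=[0, 0, 1])
    return md.Trajectory((xyz / 10.0).astype(np.float32), top)


def test_parallel_rings_at_3p4_stack_but_not_3p6():
    # face-to-face sandwich: under the pair-to-pair (all-four) rule ideal
    # rigid hexagons at 3.4 Å plane gap cannot close all four distances,
    # so the geometric detection of the sandwich uses the any-pair rule
    assert pi_stacking(_two_ring_system(3.4), rule="any-pair").present.any()
    assert not pi_stacking(_two_ring_system(3.6), rule="any-pair").present.any()
    assert not pi_stacking(_two_ring_system(3.4)).present.any()


def test_t_shaped_rings_follow_all_four_rule():
    t = _two_ring_system(2.0, t_shape=True)
    prot = sp2_carbon_pairs(t.topology)
    prot = [p for p in prot if t.topology.atom(p[0]).residue.name == "PHE"]
    lig = sp2_carbon_pairs(t.topology, residue=1)
    want_all4 = oracles.brute_stacking(t, prot, lig, rule="all-four")
    want_any = oracles.brute_stacking(t, prot, lig, rule="any-pair")
    got_all4 = pi_stacking(t, rule="all-four")
    got_any = pi_stacking(t, rule="any-pair")
    assert got_all4.present.any() == bool(want_all4)
    assert got_any.present.any() == bool(want_any)
    assert bool(want_any)              # edge-on rings do come within 3.5 Å


def test_stacking_requires_ligand(rng):
    traj = oracles.toy_system(rng, n_res=2, n_frames=1)
    with pytest.raises(ValueError, match="ligand"):
        pi_stacking(traj)


@pytest.mark.parametrize("seed", range(6))
def test_stacking_equals_enumeration_oracle(seed):
    rng = np.random.default_rng(200 + seed)
    traj = oracles.toy_system(rng, n_res=4, n_frames=3, box=8.0,
                              with_ligand=True, aromatic=True)
    top = traj.topology
    lig = top.n_residues - 1
    prot = [p for p in sp2_carbon_pairs(top)
            if top.atom(p[0]).residue.index != lig]
    ligp = sp2_carbon_pairs(top, residue=lig)
    want = oracles.brute_stacking(traj, prot, ligp)
    got = pi_stacking(traj)
    got_map = {r.a: list(c) for r, c in zip(got.records, got.present.T)}
    assert got_map == want


# --------------------------------------------------------------- occupancy

def test_occupancy_fraction_and_exclusions(two_state):
    spec, traj, truth = two_state
    det = detect_hbonds(traj)
    table = occupancy({"t": det}, {"t": list(range(100))},
                      {"t": "apo-closed"})
    b = truth.bonds[0]
    key = f"hbond:{b['donor']}:{b['acceptor']}:N/H/O"
    want = np.asarray(b["present"])[:100].mean()
    assert table.data.loc[key, "t"] == pytest.approx(want)
    assert (table.data["t"] > 0).all()   # never-seen rows are excluded


def test_occupancy_zero_retained_frames_errors(two_state):
    _, traj, _ = two_state
    det = detect_hbonds(traj[:10])
    with pytest.raises(ValueError, match="zero retained"):
        occupancy({"t": det}, {"t": []}, {"t": "apo-open"})


def test_seventy_of_hundred_frames_is_0p70():
    from allonet.interactions import DetectionResult, InteractionRecord
    rec = InteractionRecord("contact", 1, 5)
    present = np.zeros((100, 1), bool)
    present[:70, 0] = True
    table = occupancy({"t": DetectionResult([rec], present)}, {"t": None},
                      {"t": "apo-open"})
    assert table.data.iloc[0, 0] == 0.70
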