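"""Independent brute-force oracles for cross-checking the library.

Everything here is deliberately naive — explicit Python loops over all
atom/pair combinations, textbook formulas — and shares no code with the
implementations it checks.
"""

from __future__ import annotations

import math

import mdtraj as md
import numpy as np


# ---------------------------------------------------------------- geometry

def kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Optimal-superposition RMSD between two (n, 3) coordinate sets."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = (R @ P.T).T - Q
    return float(np.sqrt((diff ** 2).sum() / len(P)))


def angle_deg(a, b, c) -> float:
    v1 = np.asarray(a) - np.asarray(b)
    v2 = np.asarray(c) - np.asarray(b)
    cos = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, cos))))


# ---------------------------------------------------------------- detectors

def brute_contacts(traj: md.Trajectory, res_a: int, res_b: int,
                   cutoff: float = 4.0) -> list[bool]:
    """Per-frame contact of two residues: min heavy-atom distance < cutoff."""
    top = traj.topology
    heavy_a = [a.index for a in top.residue(res_a).atoms
               if a.element.symbol != "H"]
    heavy_b = [a.index for a in top.residue(res_b).atoms
               if a.element.symbol != "H"]
    out = []
    for f in range(traj.n_frames):
        x = traj.xyz[f].astype(np.float64) * 10.0
        dmin = min(np.linalg.norm(x[i] - x[j])
                   for i in heavy_a for j in heavy_b)
        out.append(bool(dmin < cutoff))
    return out


def brute_hbonds(traj: md.Trajectory, dist_cut: float = 2.5,
                 ang_cut: float = 120.0,
                 dist_conv: str = "hydrogen-acceptor",
                 ang_conv: str = "dha-above") -> dict:
    """All (donor, H, acceptor) triples and their per-frame presence."""
    top = traj.topology
    donors = []
    for b in top.bonds:
        for heavy, hyd in ((b[0], b[1]), (b[1], b[0])):
            if hyd.element.symbol == "H" and heavy.element.symbol in ("N", "O"):
                donors.append((heavy.index, hyd.index))
    acceptors = [a.index for a in top.atoms if a.element.symbol in ("N", "O")]
    out = {}
    for f in range(traj.n_frames):
        x = traj.xyz[f].astype(np.float64) * 10.0
        for d, h in sorted(donors):
            for a in sorted(acceptors):
                if top.atom(d).residue.index == top.atom(a).residue.index:
                    continue
                ref = x[h] if dist_conv == "hydrogen-acceptor" else x[d]
                dist = np.linalg.norm(x[a] - ref)
                ang = angle_deg(x[d], x[h], x[a])
                ok = dist < dist_cut and (
                    ang > ang_cut if ang_conv == "dha-above" else ang < ang_cut)
                key = (d, h, a)
                out.setdefault(key, [False] * traj.n_frames)[f] = bool(ok)
    return {k: v for k, v in out.items() if any(v)}


def brute_stacking(traj: md.Trajectory, protein_pairs, ligand_pairs,
                   cutoff: float = 3.5, rule: str = "all-four") -> dict:
    """Residue -> per-frame stacking presence by exhaustive enumeration."""
    top = traj.topology
    out = {}
    for f in range(traj.n_frames):
        x = traj.xyz[f].astype(np.float64) * 10.0
        for (p1, p2) in protein_pairs:
            res = top.atom(p1).residue.index
            for (l1, l2) in ligand_pairs:
                ds = [np.linalg.norm(x[i] - x[j])
                      for i in (p1, p2) for j in (l1, l2)]
                hit = (all(d < cutoff for d in ds) if rule == "all-four"
                       else any(d < cutoff for d in ds))
                if hit:
                    out.setdefault(res, [False] * traj.n_frames)[f] = True
    return out


# ---------------------------------------------------------------- stats

def welch_reference(x, y):
    """Textbook Welch-Satterthwaite t, df and two-sided p."""
    from scipy.stats import t as tdist
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2 ** 2 / (v1 ** 2 / (n1 ** 2 * (n1 - 1))
                     + v2 ** 2 / (n2 ** 2 * (n2 - 1)))
    p = 2 * float(tdist.sf(abs(t), df))
    return t, df, p


# ---------------------------------------------------------------- clustering

def brute_gromos(dist: np.ndarray, cutoff: float):
    """Gromos clustering from a full pairwise distance matrix."""
    n = dist.shape[0]
    alive = set(range(n))
    clusters = []
    while alive:
        best, best_count = None, -1
        for i in sorted(alive):
            count = sum(1 for j in alive if dist[i, j] < cutoff)
            if count > best_count:
                best, best_count = i, count
        members = sorted(j for j in alive if dist[best, j] < cutoff)
        clusters.append(members)
        alive -= set(members)
    return clusters


# ---------------------------------------------------------------- misc

def brute_greedy_poses(coms: np.ndarray, radius: float):
    kept = []
    for i in range(len(coms)):
        if all(np.linalg.norm(coms[i] - coms[j]) >= radius for j in kept):
            kept.append(i)
    return kept


def bfs_reachable(edges, sources, targets) -> bool:
    adj = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    seen = set()
    stack = [s for s in sources if s in adj]
    while stack:
        u = stack.pop()
        if u in seen:
            continue
        seen.add(u)
        if u in targets:
            return True
        stack.extend(adj.get(u, ()))
    return bool(seen & set(targets))


# ---------------------------------------------------------------- toys

def toy_system(rng: np.random.Generator, n_res: int = 5, n_frames: int = 3,
               box: float = 8.0, with_ligand: bool = False,
               aromatic: bool = False) -> md.Trajectory:
    """A random small molecular system for oracle-equivalence tests.

    Residues carry N(+H), CA, C, O; coordinates are uniform in a box
    (Angstrom) so the 2.5/3.5/4 Å cutoffs are all exercised.
    """
    top = md.Topology()
    ch = top.add_chain()
    for i in range(n_res):
        name = "PHE" if (aromatic and i == 0) else "ALA"
        res = top.add_residue(name, ch, resSeq=i + 1)
        aN = top.add_atom("N", md.element.nitrogen, res)
        aH = top.add_atom("H", md.element.hydrogen, res)
        aCA = top.add_atom("CA", md.element.carbon, res)
        aC = top.add_atom("C", md.element.carbon, res)
        aO = top.add_atom("O", md.element.oxygen, res)
        for a, b in ((aN, aH), (aN, aCA), (aCA, aC), (aC, aO)):
            top.add_bond(a, b)
        if name == "PHE":
            ring = [top.add_atom(nm, md.element.carbon, res)
                    for nm in ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")]
            for a, b in zip(ring, ring[1:] + ring[:1]):
                top.add_bond(a, b)
            top.add_bond(aCA, ring[0])
    if with_ligand:
        lch = top.add_chain()
        lres = top.add_residue("LIG", lch, resSeq=1)
        latoms = [top.add_atom(f"C{k+1}", md.element.carbon, lres)
                  for k in range(6)]
        for a, b in zip(latoms, latoms[1:] + latoms[:1]):
            top.add_bond(a, b)
    xyz = rng.uniform(0, box, size=(n_frames, top.n_atoms, 3)) / 10.0
    return md.Trajectory(xyz.astype(np.float32), top)
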