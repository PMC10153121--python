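"""Per-frame interaction detectors and occupancy aggregation.

Three interaction classes are detected, following common MD practice:

* **contacts** — a residue-residue (or residue-ligand) contact exists in a
  frame iff the minimum heavy-atom distance is strictly below 4 Å;
* **h-bonds** — Baker-Hubbard-style geometric criterion. The default
  convention is hydrogen···acceptor distance < 2.5 Å together with a
  donor-hydrogen-acceptor angle > 120°; the alternative "as-printed"
  conventions (donor-acceptor distance, angle < 120°) are selectable via
  :class:`HbondCriteria` because published criteria are frequently
  transcribed with either convention;
* **π-stacking** — a protein residue stacks with the ligand in a frame iff
  a bonded sp² carbon pair in the residue and a bonded sp² carbon pair in
  the ligand have all four cross-distances strictly below 3.5 Å (the
  any-single-pair reading is selectable).

All cutoffs are strict inequalities; geometry exactly at a cutoff is
excluded. Aggregation over retained frames produces an
:class:`OccupancyTable`: rows are interactions, columns are trajectories,
cells are the fraction of retained frames in which the interaction is
present — the substrate of all downstream statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import mdtraj as md
import numpy as np
import pandas as pd

from .regions import RegionMap

__all__ = [
    "InteractionRecord", "HbondCriteria", "DetectionResult", "OccupancyTable",
    "residue_contacts", "detect_hbonds", "pi_stacking", "occupancy",
    "find_donors_acceptors", "sp2_carbon_pairs", "ligand_residue_index",
]

LIGAND = "ligand"

#: ring-carbon atom names of aromatic residues (sp2 by construction)
_AROMATIC_RING = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
}


@dataclass(frozen=True)
class InteractionRecord:
    """Identity of one interaction; hashable and stable across frames."""
    kind: str                       # contact | hbond | pistack
    a: int | str                    # residue index or "ligand"
    b: int | str
    atoms: tuple[str, ...] = ()     # hbond: (donor, hydrogen, acceptor) names

    def __post_init__(self):
        if self.kind == "contact" and self.a == self.b:
            raise ValueError("contact of a residue with itself")

    @property
    def key(self) -> str:
        at = "/".join(self.atoms)
        return f"{self.kind}:{self.a}:{self.b}" + (f":{at}" if at else "")

    def residue_pair(self) -> tuple[int | str, int | str]:
        return self.a, self.b


@dataclass
class HbondCriteria:
    distance_cutoff: float = 2.5        # Angstrom
    angle_cutoff: float = 120.0         # degrees
    distance_convention: str = "hydrogen-acceptor"   # or "donor-acceptor"
    angle_convention: str = "dha-above"              # or "dha-below"

    def __post_init__(self):
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.distance_convention not in ("hydrogen-acceptor", "donor-acceptor"):
            raise ValueError(f"unknown distance convention {self.distance_convention!r}")
        if self.angle_convention not in ("dha-above", "dha-below"):
            raise ValueError(f"unknown angle convention {self.angle_convention!r}")


@dataclass
class DetectionResult:
    """Per-frame presence matrix for a list of interaction records."""
    records: list[InteractionRecord]
    present: np.ndarray     # (n_frames, n_records) bool

    def frame_set(self, frame: int) -> set[InteractionRecord]:
        return {r for r, p in zip(self.records, self.present[frame]) if p}

    def fractions(self, frames=None) -> np.ndarray:
        if frames is None:
            sub = self.present
        else:
            idx = np.asarray(frames, dtype=int)
            sub = self.present[idx] if idx.size else self.present[:0]
        if sub.shape[0] == 0:
            raise ValueError("zero retained frames")
        return sub.mean(axis=0)

    @staticmethod
    def merge(results: list["DetectionResult"]) -> "DetectionResult":
        recs: list[InteractionRecord] = []
        for r in results:
            recs.extend(r.records)
        n_frames = results[0].present.shape[0] if results else 0
        pres = (np.hstack([r.present for r in results])
                if results else np.zeros((0, 0), bool))
        return DetectionResult(recs, pres.reshape(n_frames, -1))


# ---------------------------------------------------------------- helpers

def ligand_residue_index(topology) -> int | None:
    """Index of the single non-protein, non-solvent residue, if present."""
    cands = [r.index for r in topology.residues
             if not r.is_protein and not r.is_water and r.n_atoms > 1]
    if len(cands) > 1:
        raise ValueError(f"exactly one ligand supported, found {len(cands)}")
    return cands[0] if cands else None


def find_donors_acceptors(topology):
    """(donor_heavy, hydrogen) index pairs and acceptor heavy-atom indices.

    Donors are N/O atoms with a covalently bonded hydrogen; acceptors are
    all N/O atoms. Raises if the topology carries no hydrogens (they must
    be added before h-bond analysis).
    """
    if not any(a.element.symbol == "H" for a in topology.atoms):
        raise ValueError("topology has no hydrogens; add hydrogens before "
                         "hydrogen-bond detection")
    donors = []
    for b in topology.bonds:
        a1, a2 = b[0], b[1]
        for heavy, hyd in ((a1, a2), (a2, a1)):
            if hyd.element.symbol == "H" and heavy.element.symbol in ("N", "O"):
                donors.append((heavy.index, hyd.index))
    donors.sort()
    acceptors = sorted(a.index for a in topology.atoms
                       if a.element.symbol in ("N", "O"))
    return donors, acceptors


def sp2_carbon_pairs(topology, residue=None):
    """Bonded sp² carbon pairs, inferred per residue.

    Protein side: ring atoms of aromatic residues (PHE/TYR/TRP/HIS) by
    atom name. Ligand side: carbons that belong to a ring of the ligand's
    bond graph (aromatic assumption for a rigid planar ligand). Returns a
    list of (atom_i, atom_j) index pairs; restrict with ``residue``.
    """
    import networkx as nx
    pairs = []
    ring_atoms: set[int] = set()
    for res in topology.residues:
        if residue is not None and res.index != residue:
            continue
        if res.is_protein:
            names = _AROMATIC_RING.get(res.name)
            if names:
                ring_atoms |= {a.index for a in res.atoms
                               if a.name in names and a.element.symbol == "C"}
        elif not res.is_water:
            g = nx.Graph((b[0].index, b[1].index) for b in topology.bonds
                         if b[0].residue is res and b[1].residue is res)
            for cycle in nx.cycle_basis(g):
                ring_atoms |= {i for i in cycle
                               if topology.atom(i).element.symbol == "C"}
    for b in topology.bonds:
        i, j = b[0].index, b[1].index
        if i in ring_atoms and j in ring_atoms:
            pairs.append((min(i, j), max(i, j)))
    return sorted(set(pairs))


# ---------------------------------------------------------------- contacts

def residue_contacts(traj: md.Trajectory, regions: RegionMap,
                     scope: list[tuple[str, str]],
                     cutoff: float = 4.0) -> DetectionResult:
    """Detect residue-residue / residue-ligand contacts for region pairs.

    ``scope`` lists pairs of region names; the special name ``"ligand"``
    refers to the single non-protein molecule. Presence = minimum
    heavy-atom distance strictly < ``cutoff`` (Å). The relation is
    symmetric and a residue is never paired with itself.
    """
    if not scope:
        raise ValueError("empty contact scope")
    lig = ligand_residue_index(traj.topology)

    def _residues(name):
        if name == LIGAND:
            if lig is None:
                raise ValueError("scope names the ligand but none is present")
            return [lig]
        return list(regions.residues(name))

    pair_list: list[tuple[int, int]] = []
    seen = set()
    for ra, rb in scope:
        for i in _residues(ra):
            for j in _residues(rb):
                if i == j:
                    continue
                p = (min(i, j), max(i, j))
                if p not in seen:
                    seen.add(p)
                    pair_list.append(p)
    pair_list.sort()
    d, _ = md.compute_contacts(traj, contacts=pair_list, scheme="closest-heavy",
                               periodic=False)
    present = (d * 10.0) < cutoff

    def _tag(i):
        return LIGAND if i == lig else i

    records = [InteractionRecord("contact", _tag(i), _tag(j))
               for i, j in pair_list]
    return DetectionResult(records, present)


# ---------------------------------------------------------------- h-bonds

def detect_hbonds(traj: md.Trajectory, criteria: HbondCriteria | None = None,
                  chunk: int = 100) -> DetectionResult:
    """Geometric h-bond detection over all donor/acceptor combinations.

    Records the full donor/hydrogen/acceptor triple per bond. Pairs within
    one residue are excluded (a residue cannot h-bond itself through its
    own backbone in this analysis). Output is bit-identical to exhaustive
    per-pair evaluation; the implementation only accelerates it by
    pre-screening candidate pairs on the distance criterion.
    """
    crit = criteria or HbondCriteria()
    top = traj.topology
    donors, acceptors = find_donors_acceptors(top)
    if not donors:
        return DetectionResult([], np.zeros((traj.n_frames, 0), bool))
    res_of = np.array([top.atom(i).residue.index for i in range(top.n_atoms)])
    d_heavy = np.array([d for d, _ in donors])
    d_hyd = np.array([h for _, h in donors])
    acc = np.array(acceptors)
    valid = res_of[d_heavy][:, None] != res_of[acc][None, :]

    xyz = traj.xyz.astype(np.float64) * 10.0  # Angstrom
    dist_ref = d_hyd if crit.distance_convention == "hydrogen-acceptor" else d_heavy

    # pass 1: exact pre-screen on per-atom bounding boxes over the whole
    # trajectory. The box-gap distance lower-bounds every per-frame
    # distance, so discarded pairs can never satisfy the cutoff.
    lo = xyz.min(axis=0)
    hi = xyz.max(axis=0)
    gaps = np.maximum(0.0, np.maximum(
        lo[dist_ref][:, None, :] - hi[acc][None, :, :],
        lo[acc][None, :, :] - hi[dist_ref][:, None, :]))
    any_pass = np.einsum("ijd,ijd->ij", gaps, gaps) < crit.distance_cutoff ** 2
    any_pass &= valid
    di, aj = np.nonzero(any_pass)
    if di.size == 0:
        return DetectionResult([], np.zeros((traj.n_frames, 0), bool))

    # pass 2: exact evaluation of candidates across all frames
    D = xyz[:, d_heavy[di], :]
    H = xyz[:, d_hyd[di], :]
    A = xyz[:, acc[aj], :]
    ref = H if crit.distance_convention == "hydrogen-acceptor" else D
    dist = np.linalg.norm(A - ref, axis=-1)
    v1 = D - H
    v2 = A - H
    cosang = (np.einsum("fid,fid->fi", v1, v2)
              / (np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ok_d = dist < crit.distance_cutoff
    ok_a = ang > crit.angle_cutoff if crit.angle_convention == "dha-above" \
        else ang < crit.angle_cutoff
    present = ok_d & ok_a

    keep = present.any(axis=0)
    records = []
    for k in np.nonzero(keep)[0]:
        dh, hh, ah = top.atom(int(d_heavy[di[k]])), top.atom(int(d_hyd[di[k]])), \
            top.atom(int(acc[aj[k]]))
        records.append(InteractionRecord(
            "hbond", dh.residue.index, ah.residue.index,
            (dh.name, hh.name, ah.name)))
    order = np.argsort([r.key for r in records], kind="stable")
    kept = np.nonzero(keep)[0][order]
    return DetectionResult([records[i] for i in order], present[:, kept])


# ---------------------------------------------------------------- stacking

def pi_stacking(traj: md.Trajectory, cutoff: float = 3.5,
                rule: str = "all-four",
                protein_pairs=None, ligand_pairs=None) -> DetectionResult:
    """π-stacking between protein residues and the ligand.

    Present iff a bonded sp² carbon pair of the residue and a bonded sp²
    carbon pair of the ligand satisfy the cross-distance rule:
    ``all-four`` (default) requires all four cross-distances < cutoff;
    ``any-pair`` requires one sp²-sp² distance < cutoff.
    """
    if rule not in ("all-four", "any-pair"):
        raise ValueError(f"unknown stacking rule {rule!r}")
    top = traj.topology
    lig = ligand_residue_index(top)
    if lig is None:
        raise ValueError("no ligand in topology")
    if ligand_pairs is None:
        ligand_pairs = sp2_carbon_pairs(top, residue=lig)
    if protein_pairs is None:
        protein_pairs = [p for p in sp2_carbon_pairs(top)
                         if top.atom(p[0]).residue.index != lig]
    F = traj.n_frames
    by_res: dict[int, list] = {}
    for p in protein_pairs:
        by_res.setdefault(top.atom(p[0]).residue.index, []).append(p)
    records, cols = [], []
    xyz = traj.xyz.astype(np.float64) * 10.0
    for res_idx in sorted(by_res):
        hit = np.zeros(F, bool)
        for (p1, p2) in by_res[res_idx]:
            for (l1, l2) in ligand_pairs:
                d = np.linalg.norm(
                    xyz[:, [p1, p2], None, :] - xyz[:, None, [l1, l2], :],
                    axis=-1)                    # (F, 2, 2)
                if rule == "all-four":
                    hit |= (d < cutoff).all(axis=(1, 2))
                else:
                    hit |= (d < cutoff).any(axis=(1, 2))
        if hit.any():
            records.append(InteractionRecord("pistack", res_idx, LIGAND))
            cols.append(hit)
    present = (np.stack(cols, axis=1) if cols else np.zeros((F, 0), bool))
    return DetectionResult(records, present)


# ---------------------------------------------------------------- occupancy

@dataclass
class OccupancyTable:
    """Interactions × trajectories matrix of presence fractions."""
    data: pd.DataFrame                       # index: record key, cols: traj
    records: dict[str, InteractionRecord]
    labels: dict[str, str]                   # trajectory -> ensemble label

    def __post_init__(self):
        missing = set(self.data.columns) - set(self.labels)
        if missing:
            raise ValueError(f"trajectories without ensemble label: {missing}")

    def subset(self, keys) -> "OccupancyTable":
        keys = [k for k in self.data.index if k in set(keys)]
        return OccupancyTable(self.data.loc[keys],
                              {k: self.records[k] for k in keys},
                              dict(self.labels))

    def columns_with_label(self, label: str) -> list[str]:
        return [c for c in self.data.columns if self.labels[c] == label]

    def to_tsv(self, path, labels_path=None) -> None:
        out = self.data.copy()
        meta = pd.DataFrame({
            "kind": [self.records[k].kind for k in out.index],
            "partner_a": [self.records[k].a for k in out.index],
            "partner_b": [self.records[k].b for k in out.index],
            "atoms": ["/".join(self.records[k].atoms) for k in out.index],
        }, index=out.index)
        pd.concat([meta, out], axis=1).to_csv(path, sep="\t",
                                              index_label="interaction")
        if labels_path is not None:
            with open(labels_path, "w") as fh:
                json.dump(self.labels, fh, sort_keys=True)

    @classmethod
    def from_tsv(cls, path, labels_path) -> "OccupancyTable":
        raw = pd.read_csv(path, sep="\t", index_col="interaction")
        meta_cols = ["kind", "partner_a", "partner_b", "atoms"]
        data = raw.drop(columns=meta_cols)
        records = {}
        for key, row in raw[meta_cols].iterrows():
            def _p(v):
                try:
                    return int(v)
                except (TypeError, ValueError):
                    return str(v)
            atoms = tuple(str(row["atoms"]).split("/")) \
                if isinstance(row["atoms"], str) and row["atoms"] else ()
            records[key] = InteractionRecord(row["kind"], _p(row["partner_a"]),
                                             _p(row["partner_b"]), atoms)
        with open(labels_path) as fh:
            labels = json.load(fh)
        return cls(data, records, labels)


def occupancy(results: dict[str, DetectionResult],
              selections: dict[str, "np.ndarray | list[int] | None"],
              labels: dict[str, str]) -> OccupancyTable:
    """Aggregate per-frame detections into an occupancy table.

    ``selections[name]`` lists the retained frame indices of trajectory
    ``name`` (None = all frames). Interactions never present in any
    trajectory are excluded; interactions absent from one trajectory get
    occupancy 0 there.
    """
    all_keys: dict[str, InteractionRecord] = {}
    cols: dict[str, dict[str, float]] = {}
    for name, res in results.items():
        sel = selections.get(name)
        fr = res.fractions(frames=sel)
        col = {}
        for rec, f in zip(res.records, fr):
            if f > 0:
                col[rec.key] = float(f)
                all_keys.setdefault(rec.key, rec)
        cols[name] = col
    keys = sorted(all_keys)
    df = pd.DataFrame(
        {name: [cols[name].get(k, 0.0) for k in keys] for name in results},
        index=keys)
    return OccupancyTable(df, {k: all_keys[k] for k in keys}, dict(labels))
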