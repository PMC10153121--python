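"""Synthetic trajectory ensembles with planted, machine-readable ground truth.

Real PTP trajectory ensembles are hundreds of nanoseconds of all-atom MD;
none are needed to test the analysis layer. This module builds toy
poly-alanine systems in which every quantity the downstream analysis
measures is *planted* by construction:

* a two-state WPD-loop schedule, realized as Gaussian draws of the
  catalytic-acid/nucleophile Cα-Cα distance (open and closed distributions
  separated by many SDs so classification is unambiguous);
* per-state hydrogen-bond occupancies, realized as per-frame Bernoulli
  draws that toggle the acceptor carbonyl O between an ideal geometry
  (H···A = 1.9 Å, D-H-A = 180°) and an unambiguous violation (D-H-A = 90°,
  same H···A distance, so contact maps stay stable);
* an α7-helicity schedule, realized as ideal α-helical backbone dihedrals
  on the first ``k`` α7 residues (DSSP recovers such runs exactly for
  k = 0 or k ≥ 4);
* an optional rigid 6-carbon ring ligand whose per-frame position realizes
  a scheduled binding-site label (α site, β site, other-bound, unbound)
  and an optional dissociation frame after which it sits > 10 Å from the
  protein.

The protein is laid out as rigid extended segments placed at well-separated
stations so that no interactions exist other than the planted ones (plus
sequence-local backbone contacts, which the network filters discard).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import mdtraj as md
import numpy as np

from . import geometry as geom
from .regions import RegionMap

__all__ = [
    "SyntheticSpec", "PlantedHbond", "LigandSpec", "GroundTruth",
    "default_layout", "generate_topology", "generate_trajectory",
    "write_fixture", "load_truth", "spec_from_yaml",
    "benchmark_hbonds", "network_ensemble_specs", "null_ensemble_specs",
]

SITE_LABELS = ("alpha", "beta", "other", "unbound")

#: residues absorbed into the α7 segment so DSSP sees a continuous chain
#: around the helix and the segment anchor stays conformation-independent
A7_PAD_BEFORE = 5
A7_PAD_AFTER = 2

_ROW_SPACING = 26.0  # Angstrom between segment stations; >> every cutoff


def default_layout(n_residues: int = 100) -> dict[str, tuple[int, int]]:
    """Canonical synthetic region layout (0-based, half-open ranges).

    Mimics the sequence order of a PTP catalytic domain: WPD loop and
    P loop near the N-terminus, L-11/α3/α6 in the middle, β8-β10 and the
    C-terminal α7 helix at the end. Residues beyond index 99 (if any) are
    free linker, useful as donors/acceptors for large planted-bond sets.
    """
    if n_residues < 100:
        raise ValueError("default layout needs n_residues >= 100")
    return {
        "wpd": (8, 16),
        "ploop": (20, 28),
        "l11": (32, 38),
        "a3": (42, 52),
        "a6": (56, 64),
        "b8": (68, 72),
        "b9": (74, 78),
        "b10": (80, 84),
        "a7": (87, 98),
    }


@dataclass(frozen=True)
class PlantedHbond:
    """A donor-residue -> acceptor-residue backbone h-bond (N-H···O=C) with
    a target occupancy in each WPD state."""
    donor: int
    acceptor: int
    occ_open: float
    occ_closed: float


@dataclass
class LigandSpec:
    """Per-frame binding-site schedule for the rigid ring ligand.

    ``site_schedule`` holds one of :data:`SITE_LABELS` per frame;
    ``dissociation_frame`` (if set) forces 'unbound' from that frame on.
    """
    site_schedule: list[str]
    dissociation_frame: int | None = None


@dataclass
class SyntheticSpec:
    n_residues: int = 100
    region_layout: dict[str, tuple[int, int]] | None = None
    catalytic_acid: int = 12
    nucleophile: int = 24
    n_frames: int = 300
    dt: float = 0.1  # ns per frame
    state_schedule: list[str] | str = "closed"
    planted_hbonds: list[PlantedHbond] = field(default_factory=list)
    helicity_schedule: list[float] | float = 1.0
    ligand: LigandSpec | None = None
    aromatic_residues: list[int] = field(default_factory=list)
    wpd_closed_mean: float = 8.0
    wpd_closed_sd: float = 0.25
    wpd_open_mean: float = 12.0
    wpd_open_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_layout is None:
            self.region_layout = default_layout(max(self.n_residues, 100) if
                                                self.n_residues >= 100 else 100)
        self.validate()

    # ------------------------------------------------------------ schedules
    @property
    def states(self) -> list[str]:
        s = self.state_schedule
        if isinstance(s, str):
            return [s] * self.n_frames
        return list(s)

    @property
    def helicity_fractions(self) -> np.ndarray:
        h = self.helicity_schedule
        if np.isscalar(h):
            return np.full(self.n_frames, float(h))
        return np.asarray(h, dtype=float)

    def n_alpha7(self) -> int:
        lo, hi = self.region_layout["a7"]
        return hi - lo

    def helical_counts(self) -> np.ndarray:
        return np.rint(self.helicity_fractions * self.n_alpha7()).astype(int)

    # ------------------------------------------------------------ validation
    def validate(self) -> None:
        lay = self.region_layout
        spans = sorted(lay.items(), key=lambda kv: kv[1][0])
        for (na, (a0, a1)), (nb, (b0, b1)) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError(f"regions {na!r} and {nb!r} overlap")
        for name, (lo, hi) in lay.items():
            if lo < 0 or hi > self.n_residues:
                raise ValueError(f"region {name!r} outside [0, {self.n_residues})")
        a7lo, a7hi = lay["a7"]
        if a7lo - A7_PAD_BEFORE < 0 or a7hi + A7_PAD_AFTER > self.n_residues:
            raise ValueError("a7 needs %d free residues before and %d after"
                             % (A7_PAD_BEFORE, A7_PAD_AFTER))
        if self.catalytic_acid == self.nucleophile:
            raise ValueError("catalytic_acid and nucleophile must differ")
        states = self.states
        if len(states) != self.n_frames:
            raise ValueError("state_schedule length != n_frames")
        if any(s not in ("open", "closed") for s in states):
            raise ValueError("state labels must be 'open' or 'closed'")
        hf = self.helicity_fractions
        if len(hf) != self.n_frames:
            raise ValueError("helicity_schedule length != n_frames")
        if hf.min() < 0 or hf.max() > 1:
            raise ValueError("helicity fractions must lie in [0, 1]")
        bad = {k for k in self.helical_counts() if 0 < k < 4}
        if bad:
            raise ValueError(
                f"helicity fractions imply helical runs of {sorted(bad)} "
                "residues; DSSP cannot represent runs shorter than 4")
        forb = set(range(a7lo - A7_PAD_BEFORE, a7hi + A7_PAD_AFTER))
        forb.add(self.catalytic_acid)
        donors, acceptors = set(), set()
        for hb in self.planted_hbonds:
            if not (0.0 <= hb.occ_open <= 1.0 and 0.0 <= hb.occ_closed <= 1.0):
                raise ValueError(f"occupancies of {hb} outside [0, 1]")
            if hb.donor == hb.acceptor:
                raise ValueError("planted bond donor == acceptor")
            for r in (hb.donor, hb.acceptor):
                if not 0 <= r < self.n_residues:
                    raise ValueError(f"planted-bond residue {r} out of range")
                if r in forb:
                    raise ValueError(
                        f"planted-bond residue {r} falls in the α7 segment or "
                        "on the catalytic acid; its geometry must be static")
            if hb.donor in donors:
                raise ValueError(f"residue {hb.donor} donates in two planted bonds")
            if hb.acceptor in acceptors:
                raise ValueError(f"residue {hb.acceptor} accepts two planted bonds")
            donors.add(hb.donor)
            acceptors.add(hb.acceptor)
        if self.ligand is not None:
            lig = self.ligand
            if len(lig.site_schedule) != self.n_frames:
                raise ValueError("ligand site_schedule length != n_frames")
            if any(s not in SITE_LABELS for s in lig.site_schedule):
                raise ValueError(f"site labels must be one of {SITE_LABELS}")
            if lig.dissociation_frame is not None and not (
                    0 <= lig.dissociation_frame <= self.n_frames):
                raise ValueError("dissociation frame outside [0, n_frames]")

    def region_map(self) -> RegionMap:
        return RegionMap(regions=dict(self.region_layout),
                         catalytic_acid=self.catalytic_acid,
                         nucleophile=self.nucleophile)


@dataclass
class GroundTruth:
    """What the generator actually realized, frame by frame."""
    wpd_distance: np.ndarray            # (F,) Angstrom
    wpd_state: list[str]                # per-frame planted label
    helicity_pct: np.ndarray            # (F,) percent of α7 residues helical
    bonds: list[dict]                   # per planted bond: occupancies + mask
    site_labels: list[str] | None       # per-frame ligand site label
    dissociation_ns: float | None
    dt: float

    def realized_occupancy(self, donor: int, acceptor: int,
                           state: str | None = None) -> float:
        for b in self.bonds:
            if b["donor"] == donor and b["acceptor"] == acceptor:
                mask = np.asarray(b["present"], dtype=bool)
                if state is None:
                    return float(mask.mean())
                sel = np.array([s == state for s in self.wpd_state])
                return float(mask[sel].mean()) if sel.any() else float("nan")
        raise KeyError(f"no planted bond {donor}->{acceptor}")

    def to_json(self, path) -> None:
        data = {
            "dt": self.dt,
            "wpd_distance": [round(float(x), 6) for x in self.wpd_distance],
            "wpd_state": self.wpd_state,
            "helicity_pct": [round(float(x), 6) for x in self.helicity_pct],
            "bonds": [dict(b, present=[int(v) for v in b["present"]])
                      for b in self.bonds],
            "site_labels": self.site_labels,
            "dissociation_ns": self.dissociation_ns,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(wpd_distance=np.asarray(d["wpd_distance"]),
                   wpd_state=d["wpd_state"],
                   helicity_pct=np.asarray(d["helicity_pct"]),
                   bonds=[dict(b, present=np.asarray(b["present"], bool))
                          for b in d["bonds"]],
                   site_labels=d["site_labels"],
                   dissociation_ns=d["dissociation_ns"],
                   dt=d["dt"])


def load_truth(path) -> GroundTruth:
    return GroundTruth.from_json(path)


# =====================================================================
# benchmark ensembles
# =====================================================================

def benchmark_hbonds(occ_hi: float = 0.9, occ_lo: float = 0.1,
                     occ_ubiq: float = 0.95) -> dict[str, list[PlantedHbond]]:
    """The planted-bond benchmark set on the default 100-residue layout.

    Three groups, all between linker residues outside the moving
    α7/catalytic segments: 10 state-specific bonds (5 favoring the closed
    WPD state, 5 the open state, ``occ_hi`` in the primary state vs
    ``occ_lo`` in the other), 10 ubiquitous decoys at ``occ_ubiq`` in both
    states, and 5 state-specific decoys between sequence-adjacent
    residues (|Δ| ≤ 3) that only the adjacency filter removes.
    """
    closed_pairs = [(28, 64), (29, 65), (30, 66), (31, 67), (38, 72)]
    open_pairs = [(39, 73), (40, 54), (41, 55), (52, 78), (53, 79)]
    ubiq_pairs = [(5, 28), (6, 29), (7, 30), (18, 31), (19, 38),
                  (64, 39), (65, 40), (66, 41), (72, 52), (73, 53)]
    adj_pairs = [(2, 5), (3, 6), (4, 7), (16, 19), (17, 18)]
    return {
        "closed": [PlantedHbond(d, a, occ_lo, occ_hi) for d, a in closed_pairs],
        "open": [PlantedHbond(d, a, occ_hi, occ_lo) for d, a in open_pairs],
        "ubiquitous": [PlantedHbond(d, a, occ_ubiq, occ_ubiq)
                       for d, a in ubiq_pairs],
        "adjacent": [PlantedHbond(d, a, occ_lo, occ_hi) for d, a in adj_pairs],
    }


def network_ensemble_specs(seed: int, n_open: int = 4, n_closed: int = 4,
                           n_frames: int = 300,
                           bonds: list[PlantedHbond] | None = None):
    """Specs for a network-recovery ensemble: ``n_open`` apo-open plus
    ``n_closed`` apo-closed trajectories sharing one planted-bond set.

    Returns ``[(name, SyntheticSpec, ensemble_label), ...]``; member seeds
    derive deterministically from ``seed``.
    """
    if bonds is None:
        groups = benchmark_hbonds()
        bonds = [b for g in groups.values() for b in g]
    out = []
    member = 0
    for label, state, count in (("apo-open", "open", n_open),
                                ("apo-closed", "closed", n_closed)):
        for k in range(count):
            spec = SyntheticSpec(n_frames=n_frames, state_schedule=state,
                                 planted_hbonds=list(bonds),
                                 helicity_schedule=1.0,
                                 seed=(seed * 97 + member) % (2 ** 31))
            out.append((f"{label.replace('-', '_')}_{k}", spec, label))
            member += 1
    return out


def null_ensemble_specs(seed: int, n_bonds: int = 100, occ: float = 0.5,
                        n_open: int = 4, n_closed: int = 4,
                        n_frames: int = 300):
    """Null-calibration ensemble: ``n_bonds`` bonds planted at the same
    occupancy in both WPD states, between trailing free-linker residues
    of an enlarged chain."""
    n_res = 100 + 2 * n_bonds + 8
    donors = [100 + i for i in range(n_bonds)]
    acceptors = [100 + n_bonds + i for i in range(n_bonds)]
    bonds = [PlantedHbond(d, a, occ, occ) for d, a in zip(donors, acceptors)]
    out = []
    member = 0
    for label, state, count in (("apo-open", "open", n_open),
                                ("apo-closed", "closed", n_closed)):
        for k in range(count):
            spec = SyntheticSpec(n_residues=n_res,
                                 region_layout=default_layout(n_res),
                                 n_frames=n_frames, state_schedule=state,
                                 planted_hbonds=list(bonds),
                                 helicity_schedule=1.0,
                                 seed=(seed * 89 + member) % (2 ** 31))
            out.append((f"{label.replace('-', '_')}_{k}", spec, label))
            member += 1
    return out


def spec_from_yaml(path) -> SyntheticSpec:
    """Build a SyntheticSpec from a YAML file.

    Keys mirror the dataclass fields; ``planted_hbonds`` is a list of
    mappings with donor/acceptor/occ_open/occ_closed; ``ligand`` is a
    mapping with site_schedule (list of labels) and dissociation_frame;
    ``region_layout`` values are [start, stop) pairs.
    """
    import yaml
    with open(path) as fh:
        d = yaml.safe_load(fh)
    kwargs = dict(d)
    if "region_layout" in kwargs and kwargs["region_layout"] is not None:
        kwargs["region_layout"] = {k: (int(v[0]), int(v[1]))
                                   for k, v in kwargs["region_layout"].items()}
    if "planted_hbonds" in kwargs:
        kwargs["planted_hbonds"] = [PlantedHbond(**hb)
                                    for hb in kwargs["planted_hbonds"]]
    if kwargs.get("ligand") is not None:
        kwargs["ligand"] = LigandSpec(**kwargs["ligand"])
    return SyntheticSpec(**kwargs)


# =====================================================================
# topology
# =====================================================================

_AROMATIC_RING_NAMES = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")


def generate_topology(spec: SyntheticSpec) -> md.Topology:
    """Build the mdtraj Topology for a spec: one protein chain of ALA (PHE
    for aromatic residues, with a bonded 6-carbon ring) plus, if requested,
    a separate-chain 6-carbon ring ligand (residue LIG)."""
    top = md.Topology()
    chain = top.add_chain()
    aromatic = set(spec.aromatic_residues)
    prev_c = None
    for i in range(spec.n_residues):
        name = "PHE" if i in aromatic else "ALA"
        res = top.add_residue(name, chain, resSeq=i + 1)
        aN = top.add_atom("N", md.element.nitrogen, res)
        aH = top.add_atom("H", md.element.hydrogen, res)
        aCA = top.add_atom("CA", md.element.carbon, res)
        aC = top.add_atom("C", md.element.carbon, res)
        aO = top.add_atom("O", md.element.oxygen, res)
        top.add_bond(aN, aH)
        top.add_bond(aN, aCA)
        top.add_bond(aCA, aC)
        top.add_bond(aC, aO)
        if prev_c is not None:
            top.add_bond(prev_c, aN)
        prev_c = aC
        if i in aromatic:
            ring = [top.add_atom(n, md.element.carbon, res)
                    for n in _AROMATIC_RING_NAMES]
            for a, b in zip(ring, ring[1:] + ring[:1]):
                top.add_bond(a, b)
            top.add_bond(aCA, ring[0])
    if spec.ligand is not None:
        lchain = top.add_chain()
        lres = top.add_residue("LIG", lchain, resSeq=1)
        latoms = [top.add_atom(f"C{k + 1}", md.element.carbon, lres)
                  for k in range(6)]
        for a, b in zip(latoms, latoms[1:] + latoms[:1]):
            top.add_bond(a, b)
    return top


# =====================================================================
# coordinates
# =====================================================================

def _segment_bounds(spec: SyntheticSpec) -> list[tuple[int, int]]:
    """Cut the chain into segments at region boundaries; the α7 segment
    absorbs its flanking pad so DSSP sees a continuous local chain."""
    lay = spec.region_layout
    a7lo, a7hi = lay["a7"]
    lo_pad, hi_pad = a7lo - A7_PAD_BEFORE, a7hi + A7_PAD_AFTER
    cuts = {0, spec.n_residues, lo_pad, hi_pad}
    for name, (lo, hi) in lay.items():
        if name == "a7":
            continue
        cuts.update((lo, hi))
    cuts = sorted(c for c in cuts if 0 <= c <= spec.n_residues)
    # drop any cut strictly inside the padded α7 span
    cuts = [c for c in cuts if not (lo_pad < c < hi_pad)]
    return list(zip(cuts, cuts[1:]))


def _build_segment(lo: int, hi: int, helical: set[int]) -> np.ndarray:
    phis = [geom.PHI_HELIX if r in helical else geom.PHI_EXT
            for r in range(lo, hi)]
    psis = [geom.PSI_HELIX if r in helical else geom.PSI_EXT
            for r in range(lo, hi)]
    return geom.backbone_to_array(geom.build_backbone(phis, psis))


def _ca_index(res: int) -> int:
    return 5 * res + 2


class _Layout:
    """Static station placement for one spec; holds the base protein
    coordinates (all-extended α7) and anchor/pocket geometry."""

    def __init__(self, spec: SyntheticSpec):
        self.spec = spec
        lay = spec.region_layout
        self.a7lo, self.a7hi = lay["a7"]
        self.seg_bounds = _segment_bounds(spec)
        self.a7_seg = next(
            (lo, hi) for lo, hi in self.seg_bounds
            if lo <= self.a7lo < hi)
        # local (untranslated) geometry per segment, extended everywhere
        self.local = {b: _build_segment(*b, helical=set())
                      for b in self.seg_bounds}
        # segment stations: consecutive rows along z, except α7/β8/β9 which
        # anchor relative to α3 to form the two ligand pockets
        offs: dict[tuple[int, int], np.ndarray] = {}
        row = 0
        special = {}
        for name in ("a3", "b8", "b9"):
            special[lay[name][0]] = name
        seg_of_region = {}
        for b in self.seg_bounds:
            for start, name in special.items():
                if b[0] <= start < b[1]:
                    seg_of_region[name] = b
        a7_first = None
        for b in self.seg_bounds:
            if b == self.a7_seg or b in (seg_of_region.get("b8"),
                                         seg_of_region.get("b9")):
                continue  # placed below
            offs[b] = np.array([0.0, 0.0, _ROW_SPACING * row])
            row += 1
        # α3 anchors
        a3b = seg_of_region["a3"]
        a3lo, a3hi = lay["a3"]
        self.a3_first_ca = (self.local[a3b][_ca_index(a3lo) - 5 * a3b[0]]
                            + offs[a3b])
        self.a3_last_ca = (self.local[a3b][_ca_index(a3hi - 1) - 5 * a3b[0]]
                           + offs[a3b])
        # α7: anchor its first α7 residue CA 9 A above α3's last CA
        a7_anchor_local = self.local[self.a7_seg][
            _ca_index(self.a7lo) - 5 * self.a7_seg[0]]
        self.a7_offset = self.a3_last_ca + np.array([0.0, 9.0, 0.0]) - a7_anchor_local
        offs[self.a7_seg] = self.a7_offset
        # β8/β9: anchors around the β pocket, below α3's first CA
        self.pocket_beta = self.a3_first_ca + np.array([0.0, -5.0, 0.0])
        for name, anchor in (("b8", self.pocket_beta + np.array([0.0, -5.0, 0.0])),
                             ("b9", self.pocket_beta + np.array([0.0, -1.0, 4.8]))):
            b = seg_of_region[name]
            lo, hi = lay[name]
            mid = (lo + hi) // 2
            offs[b] = anchor - self.local[b][_ca_index(mid) - 5 * b[0]]
        self.offsets = offs
        self.pocket_alpha = self.a3_last_ca + np.array([0.0, 4.5, 0.0])
        # assemble base protein coordinates
        base = np.empty((5 * spec.n_residues, 3))
        for b, xyz in self.local.items():
            base[5 * b[0]:5 * b[1]] = xyz + offs[b]
        self.base = base
        # catalytic-pair geometry: unit vector from nucleophile CA toward
        # the acid's station CA
        nuc_ca = base[_ca_index(spec.nucleophile)]
        acid_ca = base[_ca_index(spec.catalytic_acid)]
        u = acid_ca - nuc_ca
        self.wpd_dir = u / np.linalg.norm(u)
        self.nuc_ca = nuc_ca
        # ligand ring templates per site label
        self.rings = {
            "alpha": geom.ring_coords(self.pocket_alpha, normal=[1, 0, 0]),
            "beta": geom.ring_coords(self.pocket_beta, normal=[1, 0, 0]),
            "other": geom.ring_coords(base[_ca_index(0)] + np.array([0.0, 5.0, 0.0]),
                                      normal=[1, 0, 0]),
            "unbound": geom.ring_coords(np.array([0.0, 200.0, 0.0]),
                                        normal=[1, 0, 0]),
        }

    def a7_variant(self, k: int) -> np.ndarray:
        """α7 segment coordinates with the first k α7 residues helical."""
        helical = set(range(self.a7lo, self.a7lo + k))
        return _build_segment(*self.a7_seg, helical=helical) + self.a7_offset


def generate_trajectory(spec: SyntheticSpec) -> tuple[md.Trajectory, GroundTruth]:
    """Realize a spec as an mdtraj Trajectory plus its GroundTruth.

    Deterministic: the same spec (including seed) yields identical
    coordinates. Self-checks verify pocket-contact and h-bond geometry.
    """
    rng = np.random.default_rng(spec.seed)
    top = generate_topology(spec)
    layout = _Layout(spec)
    F = spec.n_frames
    n_prot_atoms = 5 * spec.n_residues + 6 * len(spec.aromatic_residues)
    n_atoms = top.n_atoms
    states = spec.states
    is_open = np.array([s == "open" for s in states])

    # ---- protein base, tiled ------------------------------------------
    # aromatic ring sidecars sit at a fixed offset from their CA
    base = np.empty((n_atoms, 3))
    ptr = 0
    for res in top.residues:
        if res.name == "LIG":
            continue
        i = res.index
        base[ptr:ptr + 5] = layout.base[5 * i:5 * i + 5]
        if res.name == "PHE":
            ca = layout.base[_ca_index(i)]
            ring = geom.ring_coords(ca + np.array([0.0, 3.0, 0.0]),
                                    normal=[0, 1, 0])
            base[ptr + 5:ptr + 11] = ring
            ptr += 11
        else:
            ptr += 5
    atom_index = {}
    for a in top.atoms:
        atom_index[(a.residue.index, a.name)] = a.index
    xyz = np.broadcast_to(base, (F, n_atoms, 3)).copy()

    # ---- WPD distance schedule ----------------------------------------
    d_closed = rng.normal(spec.wpd_closed_mean, spec.wpd_closed_sd, size=F)
    d_open = rng.normal(spec.wpd_open_mean, spec.wpd_open_sd, size=F)
    wpd_d = np.where(is_open, d_open, d_closed)
    acid = spec.catalytic_acid
    acid_atoms = [atom_index[(acid, n)] for n in ("N", "H", "CA", "C", "O")]
    acid_base = base[acid_atoms]
    acid_ca = base[atom_index[(acid, "CA")]]
    target_ca = layout.nuc_ca[None, :] + wpd_d[:, None] * layout.wpd_dir[None, :]
    shift = target_ca - acid_ca[None, :]
    xyz[:, acid_atoms, :] = acid_base[None, :, :] + shift[:, None, :]

    # ---- planted h-bonds ----------------------------------------------
    bonds_truth = []
    for hb in spec.planted_hbonds:
        iN = atom_index[(hb.donor, "N")]
        iH = atom_index[(hb.donor, "H")]
        iO = atom_index[(hb.acceptor, "O")]
        N, H = base[iN], base[iH]
        u = H - N
        u = u / np.linalg.norm(u)
        # any unit vector perpendicular to the N-H axis
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(ref, u)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        v = np.cross(u, ref)
        v = v / np.linalg.norm(v)
        pos_on = H + 1.9 * u        # D-H-A = 180 deg, H···A = 1.9 A
        pos_off = H + 1.9 * v       # D-H-A = 90 deg, same distance
        occ = np.where(is_open, hb.occ_open, hb.occ_closed)
        present = rng.random(F) < occ
        xyz[:, iO, :] = np.where(present[:, None], pos_on, pos_off)
        bonds_truth.append({
            "donor": hb.donor, "acceptor": hb.acceptor,
            "occ_open": hb.occ_open, "occ_closed": hb.occ_closed,
            "realized_open": float(present[is_open].mean()) if is_open.any() else None,
            "realized_closed": float(present[~is_open].mean()) if (~is_open).any() else None,
            "present": present,
        })

    # ---- α7 helicity ---------------------------------------------------
    ks = spec.helical_counts()
    seg_lo, seg_hi = layout.a7_seg
    seg_atoms = []
    for r in range(seg_lo, seg_hi):
        seg_atoms.extend(atom_index[(r, n)] for n in ("N", "H", "CA", "C", "O"))
    seg_atoms = np.array(seg_atoms)
    variants = {k: None for k in np.unique(ks)}
    for k in variants:
        variants[k] = layout.a7_variant(int(k))
    for k, coords in variants.items():
        xyz[np.where(ks == k)[0][:, None], seg_atoms[None, :], :] = coords
    helicity_pct = 100.0 * ks / spec.n_alpha7()

    # ---- ligand --------------------------------------------------------
    site_labels = None
    diss_ns = None
    if spec.ligand is not None:
        lig_atoms = np.array([a.index for a in top.atoms
                              if a.residue.name == "LIG"])
        labels = list(spec.ligand.site_schedule)
        if spec.ligand.dissociation_frame is not None:
            df = spec.ligand.dissociation_frame
            labels = labels[:df] + ["unbound"] * (F - df)
            diss_ns = df * spec.dt
        for lab in SITE_LABELS:
            sel = [t for t, l in enumerate(labels) if l == lab]
            if sel:
                xyz[np.array(sel)[:, None], lig_atoms[None, :], :] = layout.rings[lab]
        site_labels = labels

    traj = md.Trajectory(xyz / 10.0, top,
                         time=np.arange(F) * spec.dt * 1000.0)  # ps
    truth = GroundTruth(wpd_distance=wpd_d, wpd_state=states,
                        helicity_pct=helicity_pct, bonds=bonds_truth,
                        site_labels=site_labels, dissociation_ns=diss_ns,
                        dt=spec.dt)
    _self_check(spec, layout, traj, n_prot_atoms)
    return traj, truth


def _self_check(spec, layout, traj, n_prot_atoms) -> None:
    """Verify planted geometry on the assembled first frame (cheap)."""
    xyz = traj.xyz[0] * 10.0
    lay = spec.region_layout
    top = traj.topology
    if spec.ligand is not None:
        def _min_region_dist(ring, name):
            lo, hi = lay[name]
            idx = [a.index for a in top.atoms
                   if lo <= a.residue.index < hi and a.residue.name != "LIG"]
            prot = xyz[idx]
            d = np.linalg.norm(ring[:, None, :] - prot[None, :, :], axis=-1)
            return d.min()
        ring_a = layout.rings["alpha"]
        ring_b = layout.rings["beta"]
        assert _min_region_dist(ring_a, "a3") < 4.0, "alpha pocket lost a3 contact"
        assert _min_region_dist(ring_a, "a7") < 4.0, "alpha pocket lost a7 contact"
        assert _min_region_dist(ring_b, "a3") < 4.0, "beta pocket lost a3 contact"
        n_sheets = sum(_min_region_dist(ring_b, s) < 4.0
                       for s in ("b8", "b9", "b10"))
        assert n_sheets >= 2, "beta pocket must touch >= 2 beta sheets"
        assert _min_region_dist(ring_a, "b8") > 4.0
        assert _min_region_dist(ring_b, "a7") > 4.0


# =====================================================================
# fixture IO
# =====================================================================

def write_fixture(traj: md.Trajectory, paths: dict | str | Path,
                  truth: GroundTruth | None = None,
                  regions: RegionMap | None = None,
                  coord_format: str = "xtc") -> dict[str, Path]:
    """Write topology.pdb + traj.xtc/.dcd (+ truth.json, regions.yaml).

    ``paths`` may be an output directory or a dict with explicit keys
    ``topology``/``coords``/``truth``/``regions``.
    """
    if traj.n_frames == 0:
        raise ValueError("cannot write an empty trajectory")
    if coord_format not in ("xtc", "dcd"):
        raise ValueError(f"unsupported coordinate format {coord_format!r}")
    if isinstance(paths, (str, Path)):
        outdir = Path(paths)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"topology": outdir / "topology.pdb",
                 "coords": outdir / f"traj.{coord_format}",
                 "truth": outdir / "truth.json",
                 "regions": outdir / "regions.yaml"}
    out = {}
    traj[0].save_pdb(str(paths["topology"]))
    out["topology"] = Path(paths["topology"])
    traj.save(str(paths["coords"]))
    out["coords"] = Path(paths["coords"])
    if truth is not None and "truth" in paths:
        truth.to_json(paths["truth"])
        out["truth"] = Path(paths["truth"])
    if regions is not None and "regions" in paths:
        regions.to_yaml(paths["regions"])
        out["regions"] = Path(paths["regions"])
    return out
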