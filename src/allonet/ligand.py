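"""Ligand binding-site classification, retention and mobility analysis.

Two allosteric pockets are distinguished by which structural regions the
ligand touches simultaneously (heavy-atom distance < 4 Å):

* **α site** — contacts with both the α3 and α7 helices;
* **β site** — contacts with the α3 helix and at least two of the β8-β10
  sheets (the pocket sits at the sheet/helix interface; requiring a
  single sheet is selectable for a looser reading).

Frames touching the protein without satisfying a site predicate are
*other-bound*; frames without any protein contact are *unbound*. When
both predicates hold the α site wins by default (precedence is
configurable; the sites are treated as mutually exclusive).

Derived per-trajectory quantities: site retention time (how long the
ligand stayed at a site, with an optional grace window bridging brief
exits), dissociation time (first sustained loss of all protein contacts),
and the bootstrapped ligand center-of-mass displacement in the
protein-backbone frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import mdtraj as md
import numpy as np

from .interactions import ligand_residue_index
from .prep import FrameSelection, backbone_atoms
from .regions import RegionMap

__all__ = [
    "SiteDefinition", "default_sites", "SiteTrace", "ComRmsdResult",
    "ligand_region_contacts", "classify_site", "retention_time",
    "detect_dissociation", "ligand_com_rmsd", "select_distinct_poses",
]

ALPHA, BETA, OTHER_BOUND, UNBOUND = "alpha", "beta", "other-bound", "unbound"


@dataclass(frozen=True)
class SiteDefinition:
    """A site predicate: every clause is a (region-group, minimum number
    of contacted regions) requirement; all clauses must hold."""
    name: str
    clauses: tuple[tuple[tuple[str, ...], int], ...]

    def holds(self, contacted: set[str]) -> bool:
        return all(len(contacted & set(group)) >= need
                   for group, need in self.clauses)


def default_sites(min_beta_sheets: int = 2) -> list[SiteDefinition]:
    """α and β pocket definitions. ``min_beta_sheets`` controls how many
    of β8-β10 the β predicate requires (2 = sheet-interface reading,
    1 = any-sheet reading)."""
    return [
        SiteDefinition(ALPHA, ((("a3",), 1), (("a7",), 1))),
        SiteDefinition(BETA, ((("a3",), 1), (("b8", "b9", "b10"),
                                             min_beta_sheets))),
    ]


@dataclass
class SiteTrace:
    labels: list[str]
    dt: float                       # ns per frame
    retention_ns: dict[str, float] = field(default_factory=dict)
    dissociation_ns: float | None = None


def ligand_region_contacts(traj: md.Trajectory, regions: RegionMap,
                           cutoff: float = 4.0):
    """Per-frame set of region names the ligand contacts, plus a per-frame
    any-protein-contact flag.

    Contact = minimum ligand/residue heavy-atom distance strictly below
    ``cutoff`` (Å). Deterministic in the contact set only; atom order is
    irrelevant.
    """
    top = traj.topology
    lig = ligand_residue_index(top)
    if lig is None:
        raise ValueError("no ligand in topology")
    lig_atoms = np.array([a.index for a in top.residue(lig).atoms
                          if a.element.symbol != "H"])
    xyz = traj.xyz.astype(np.float64) * 10.0
    region_contact: dict[str, np.ndarray] = {}
    prot_heavy = np.array([a.index for a in top.atoms
                           if a.residue.is_protein and a.element.symbol != "H"])
    d = np.linalg.norm(xyz[:, lig_atoms, None, :] - xyz[:, None, prot_heavy, :],
                       axis=-1)                  # (F, n_lig, n_prot)
    dmin_per_atom = d.min(axis=1)                # (F, n_prot)
    res_of = np.array([top.atom(i).residue.index for i in prot_heavy])
    any_contact = (dmin_per_atom < cutoff).any(axis=1)
    for name, (lo, hi) in regions.regions.items():
        cols = np.nonzero((res_of >= lo) & (res_of < hi))[0]
        region_contact[name] = ((dmin_per_atom[:, cols] < cutoff).any(axis=1)
                                if cols.size else
                                np.zeros(traj.n_frames, bool))
    return region_contact, any_contact


def classify_site(traj: md.Trajectory, regions: RegionMap,
                  sites: list[SiteDefinition] | None = None,
                  cutoff: float = 4.0,
                  precedence: tuple[str, ...] = (ALPHA, BETA)) -> SiteTrace:
    """Per-frame site labels from the ligand's region-contact sets."""
    sites = sites if sites is not None else default_sites()
    by_name = {s.name: s for s in sites}
    order = [by_name[n] for n in precedence if n in by_name]
    order += [s for s in sites if s.name not in precedence]
    region_contact, any_contact = ligand_region_contacts(traj, regions, cutoff)
    labels = []
    for f in range(traj.n_frames):
        contacted = {name for name, flags in region_contact.items() if flags[f]}
        label = None
        for site in order:
            if site.holds(contacted):
                label = site.name
                break
        if label is None:
            label = OTHER_BOUND if any_contact[f] else UNBOUND
        labels.append(label)
    dt = float(traj.time[1] - traj.time[0]) / 1000.0 if traj.n_frames > 1 else 0.1
    return SiteTrace(labels=labels, dt=dt)


def retention_time(labels: list[str], dt: float, site: str,
                   grace: int = 0) -> float:
    """Time (ns) from first occupancy of ``site`` to the first departure
    lasting more than ``grace`` consecutive frames; shorter departures are
    bridged. Never-departing ligands retain until the end of the
    trajectory. A never-occupied site retains 0 ns.
    """
    n = len(labels)
    entry = next((i for i, l in enumerate(labels) if l == site), None)
    if entry is None:
        return 0.0
    i = entry
    while i < n:
        if labels[i] == site:
            i += 1
            continue
        j = i
        while j < n and labels[j] != site:
            j += 1
        if j - i > grace:          # real departure (bridged otherwise)
            return (i - entry) * dt
        i = j
    return (n - entry) * dt


def detect_dissociation(traj: md.Trajectory, regions: RegionMap,
                        cutoff: float = 4.0, window: int = 10,
                        any_contact: np.ndarray | None = None) -> float | None:
    """Time (ns) of the first frame starting a run of >= ``window`` frames
    with zero protein contacts, or None if the ligand never fully
    dissociates. Single-frame contact losses shorter than the window do
    not count."""
    if any_contact is None:
        _, any_contact = ligand_region_contacts(traj, regions, cutoff)
    n = len(any_contact)
    dt = float(traj.time[1] - traj.time[0]) / 1000.0 if n > 1 else 0.1
    run_start = None
    for i, c in enumerate(any_contact):
        if c:
            run_start = None
        elif run_start is None:
            run_start = i
        if run_start is not None and i - run_start + 1 >= window:
            return run_start * dt
    return None


def bootstrap_mean_se(values: np.ndarray, n_boot: int = 1000,
                      seed: int = 0) -> tuple[float, float]:
    """Bootstrap mean-of-means and its standard error (SD of replicate
    means) by resampling with replacement; deterministic per seed."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        raise ValueError("empty sample")
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        reps[b] = values[rng.integers(0, n, size=n)].mean()
    return float(reps.mean()), float(reps.std(ddof=0))


@dataclass
class ComRmsdResult:
    per_frame: np.ndarray    # (n_selected,) displacement, Angstrom
    mean: float              # bootstrap mean of replicate means
    se: float                # SD of replicate means
    n_boot: int
    seed: int


def ligand_com_rmsd(traj: md.Trajectory,
                    selection: FrameSelection | list[int] | None = None,
                    reference: int = 0, n_boot: int = 1000,
                    seed: int = 0) -> ComRmsdResult:
    """Ligand center-of-mass displacement from its reference-frame
    position, measured in the protein frame.

    Frames are first superposed on the protein backbone; the per-frame
    value is |COM(frame) - COM(reference)| (Å) with a mass-weighted COM
    over all ligand atoms. The mean and standard error come from
    bootstrap resampling of the retained frames (deterministic per seed).
    """
    lig = ligand_residue_index(traj.topology)
    if lig is None:
        raise ValueError("no ligand in topology")
    if isinstance(selection, FrameSelection):
        frames = list(selection.frames)
    elif selection is None:
        frames = list(range(traj.n_frames))
    else:
        frames = list(selection)
    if not frames:
        raise ValueError("empty frame selection")
    work = traj[:]
    work.superpose(traj, frame=reference,
                   atom_indices=backbone_atoms(traj.topology))
    lig_atoms = [a.index for a in traj.topology.residue(lig).atoms]
    masses = np.array([a.element.mass for a in traj.topology.residue(lig).atoms])
    com = (work.xyz[:, lig_atoms, :].astype(np.float64)
           * masses[None, :, None]).sum(axis=1) / masses.sum()
    disp = np.linalg.norm(com - com[reference], axis=-1) * 10.0
    vals = disp[np.asarray(frames)]
    mean, se = bootstrap_mean_se(vals, n_boot=n_boot, seed=seed)
    return ComRmsdResult(per_frame=vals, mean=mean, se=se,
                         n_boot=n_boot, seed=seed)


def poses_from_pdb(path) -> np.ndarray:
    """Ligand COM coordinates (Å) per model of a multi-model PDB, in model
    (affinity-rank) order."""
    traj = md.load(str(path))
    lig = ligand_residue_index(traj.topology)
    atoms = [a.index for a in traj.topology.residue(lig).atoms] \
        if lig is not None else list(range(traj.n_atoms))
    masses = np.array([traj.topology.atom(i).element.mass for i in atoms])
    com = (traj.xyz[:, atoms, :].astype(np.float64)
           * masses[None, :, None]).sum(axis=1) / masses.sum()
    return com * 10.0


def poses_from_table(path) -> np.ndarray:
    """COM coordinates from a whitespace/TSV table with x, y, z columns
    (Å), one row per pose in affinity-rank order."""
    import pandas as pd
    df = pd.read_csv(path, sep=None, engine="python")
    cols = [c for c in df.columns if c.lower() in ("x", "y", "z")]
    if len(cols) != 3:
        raise ValueError("pose table needs x, y, z columns")
    return df[cols].to_numpy(dtype=float)


def select_distinct_poses(coms: np.ndarray, merge_radius: float = 5.0):
    """Greedy distinct-pose selection in affinity-rank (input) order.

    A pose is kept iff its center of mass lies at least ``merge_radius``
    (Å) from every already-kept pose; closer poses are merged into the
    earlier (higher-affinity) one. Returns the kept indices, in order.
    """
    coms = np.asarray(coms, dtype=float)
    if coms.size == 0:
        return []
    kept: list[int] = []
    for i, c in enumerate(coms):
        if all(np.linalg.norm(c - coms[j]) >= merge_radius for j in kept):
            kept.append(i)
    return kept
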