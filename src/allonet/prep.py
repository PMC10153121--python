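"""Trajectory loading and preprocessing.

Reproduces the standard pre-analysis pipeline for MD ensembles: load
topology + coordinates, compute the backbone RMSD series relative to the
starting structure, prune unequilibrated frames, thin correlated frames by
change-point segmentation plus autocorrelation-time subsampling, and
extract a representative centroid frame by gromos-style clustering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import mdtraj as md
import numpy as np

from .changepoint import default_penalty, integrated_autocorr_time, pelt_l2
from .interactions import ligand_residue_index

__all__ = [
    "FrameSelection", "load_trajectory", "backbone_atoms",
    "backbone_rmsd_series", "detect_equilibration", "decorrelate",
    "cluster_centroid",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass
class FrameSelection:
    """Equilibration start plus retained (uncorrelated) frame indices."""
    equil_start: int
    frames: list[int] = field(default_factory=list)

    def __post_init__(self):
        fr = list(self.frames)
        if fr != sorted(set(fr)):
            raise ValueError("retained frames must be sorted and unique")
        if fr and fr[0] < self.equil_start:
            raise ValueError("retained frames precede equilibration start")
        self.frames = fr

    def __len__(self) -> int:
        return len(self.frames)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"equil_start": self.equil_start,
                       "frames": [int(f) for f in self.frames]}, fh)

    @classmethod
    def from_json(cls, path) -> "FrameSelection":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["equil_start"], d["frames"])

    @classmethod
    def all_frames(cls, n_frames: int) -> "FrameSelection":
        return cls(0, list(range(n_frames)))


def load_trajectory(coord_path, topology_path=None) -> md.Trajectory:
    """Load coordinates (+ topology); validates that at most one ligand
    (non-protein, non-solvent molecule) is present.

    Accepts XTC/DCD with a PDB topology, or a multi-model PDB alone.
    """
    if topology_path is None:
        traj = md.load(str(coord_path))
    else:
        traj = md.load(str(coord_path), top=str(topology_path))
    ligand_residue_index(traj.topology)  # raises on >1 ligand
    return traj


def backbone_atoms(topology) -> np.ndarray:
    idx = [a.index for a in topology.atoms
           if a.residue.is_protein and a.name in BACKBONE_NAMES]
    if not idx:
        raise ValueError("no protein backbone atoms (N, CA, C, O) in topology")
    return np.array(idx)


def backbone_rmsd_series(traj: md.Trajectory, reference: int = 0) -> np.ndarray:
    """Backbone RMSD (nm) of every frame to ``reference`` after optimal
    superposition on N/CA/C/O atoms."""
    if not 0 <= reference < traj.n_frames:
        raise ValueError(f"reference frame {reference} out of range")
    bb = backbone_atoms(traj.topology)
    return np.asarray(md.rmsd(traj, traj, reference, atom_indices=bb),
                      dtype=float)


def detect_equilibration(series: np.ndarray, window: int | None = None) -> int:
    """First index of the equilibrated regime of an RMSD series.

    Reverse-cumulative plateau rule: the smallest index ``i`` whose
    forward window mean differs from the final window's mean by at most
    one SD of the final window. ``window`` defaults to 5% of the series
    (minimum 2). Degenerate cases: a series shorter than the window
    returns 0 with a warning; a series that never plateaus (monotone
    drift) returns ``n - window`` with a warning.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if window is None:
        window = max(2, int(round(0.05 * n)))
    if n < 2 * window or n < 2:
        warnings.warn("series shorter than the equilibration window; "
                      "keeping all frames")
        return 0
    tail = series[n - window:]
    mu, sd = float(tail.mean()), float(tail.std())
    # probe windows may not overlap the final reference window, which
    # would trivially match itself
    for i in range(0, n - 2 * window + 1):
        if abs(float(series[i:i + window].mean()) - mu) <= sd + 1e-12:
            return i
    warnings.warn("RMSD series never plateaus (monotone drift?); "
                  "equilibration start set to n - window")
    return n - window


def decorrelate(series: np.ndarray, equil_start: int = 0,
                penalty: float | None = None,
                significance: float = 2.58) -> FrameSelection:
    """Thin the post-equilibration series to approximately uncorrelated
    frames.

    The series after ``equil_start`` is segmented with PELT (L2 cost,
    penalty defaulting to ``2 log(n) Var``); within each segment frames
    are subsampled every ``ceil(tau)`` frames, with tau the integrated
    autocorrelation time of the segment. The autocorrelation sum
    truncates at the 99% white-noise significance floor so an
    effectively uncorrelated segment keeps every frame. A zero-variance
    segment contributes a single frame.
    """
    series = np.asarray(series, dtype=float)
    post = series[equil_start:]
    if len(post) == 0:
        warnings.warn("empty post-equilibration region; empty selection")
        return FrameSelection(equil_start, [])
    ends = pelt_l2(post, penalty=penalty if penalty is not None
                   else default_penalty(post))
    frames: list[int] = []
    start = 0
    for end in ends:
        seg = post[start:end]
        tau = integrated_autocorr_time(seg, significance=significance)
        interval = max(1, int(np.ceil(tau - 1e-9)))
        frames.extend(range(equil_start + start, equil_start + end, interval))
        start = end
    return FrameSelection(equil_start, frames)


def _pairwise_rmsd(traj: md.Trajectory, frames: list[int]) -> np.ndarray:
    bb = backbone_atoms(traj.topology)
    sub = traj[frames]
    m = len(frames)
    d = np.empty((m, m))
    for i in range(m):
        d[i] = md.rmsd(sub, sub, i, atom_indices=bb)
    return 0.5 * (d + d.T)   # symmetrize float32 asymmetry


def cluster_centroid(traj: md.Trajectory,
                     selection: FrameSelection | list[int] | None = None,
                     cutoff: float = 0.2):
    """Gromos-style clustering on backbone pairwise RMSD.

    Iteratively takes the frame with the most neighbors within ``cutoff``
    (nm) as a cluster leader, removes the cluster, and repeats. Ties break
    toward the lowest frame index. Returns ``(centroid_frame,
    populations)`` where the centroid is the member of the largest cluster
    with the most within-cluster neighbors and populations (sizes in
    formation order) sum to the number of selected frames.
    """
    if selection is None:
        frames = list(range(traj.n_frames))
    elif isinstance(selection, FrameSelection):
        frames = list(selection.frames)
    else:
        frames = list(selection)
    if len(frames) == 0:
        raise ValueError("no frames selected")
    if len(frames) == 1:
        return frames[0], [1]
    d = _pairwise_rmsd(traj, frames)
    neigh = d < cutoff      # includes self
    alive = np.ones(len(frames), bool)
    clusters: list[list[int]] = []
    while alive.any():
        counts = (neigh & alive[None, :]).sum(axis=1)
        counts[~alive] = -1
        leader = int(np.argmax(counts))      # argmax: lowest index on ties
        members = np.nonzero(neigh[leader] & alive)[0]
        clusters.append(list(members))
        alive[members] = False
    sizes = [len(c) for c in clusters]
    best = int(np.argmax(sizes))             # earliest-formed wins ties
    members = clusters[best]
    sub = neigh[np.ix_(members, members)]
    within = sub.sum(axis=1)
    centroid_local = members[int(np.argmax(within))]
    return frames[centroid_local], sizes
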