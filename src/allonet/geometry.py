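"""Internal-coordinate construction of toy backbone geometry.

All lengths are in Angstrom unless noted. Builders here serve the synthetic
trajectory generator: they produce idealized poly-alanine backbones (N, H,
CA, C, O per residue) from per-residue (phi, psi) dihedrals via the NeRF
(natural extension reference frame) algorithm, plus planar carbon rings for
ligand / aromatic-sidechain fixtures.
"""

from __future__ import annotations

import numpy as np

# Ideal backbone internal coordinates (Engh-Huber-like averages).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.010
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_C_N_H = 119.0

#: canonical alpha-helix and extended (beta-like) backbone dihedrals, degrees
PHI_HELIX, PSI_HELIX = -57.0, -47.0
PHI_EXT, PSI_EXT = -139.0, 135.0


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Position atom D given atoms A-B-C, the C-D bond length, the B-C-D
    angle and the A-B-C-D dihedral (degrees)."""
    angle = np.deg2rad(angle)
    dihedral = np.deg2rad(dihedral)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * np.cos(angle),
        bond * np.cos(dihedral) * np.sin(angle),
        bond * np.sin(dihedral) * np.sin(angle),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(phis: np.ndarray, psis: np.ndarray) -> dict[str, np.ndarray]:
    """Build an n-residue backbone from per-residue dihedrals.

    Returns a dict with (n, 3) arrays for atoms ``N``, ``H``, ``CA``, ``C``,
    ``O``. Omega is fixed trans (180 deg). The chain starts at the origin and
    extends roughly along +x for extended dihedrals.
    """
    phis = np.asarray(phis, dtype=float)
    psis = np.asarray(psis, dtype=float)
    n = len(phis)
    if n == 0 or len(psis) != n:
        raise ValueError("phis and psis must be equal-length, non-empty")
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    O = np.zeros((n, 3))
    H = np.zeros((n, 3))
    seed = np.array([0.0, 1.0, 0.0])  # virtual predecessor for residue 0
    N[0] = [0.0, 0.0, 0.0]
    CA[0] = [BOND_N_CA, 0.0, 0.0]
    C[0] = place_atom(seed, N[0], CA[0], BOND_CA_C, ANGLE_N_CA_C, phis[0])
    for i in range(1, n):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N,
                          ANGLE_CA_C_N, psis[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], BOND_N_CA,
                           ANGLE_C_N_CA, 180.0)  # omega trans
        C[i] = place_atom(C[i - 1], N[i], CA[i], BOND_CA_C,
                          ANGLE_N_CA_C, phis[i])
    for i in range(n):
        # carbonyl O anti to the next amide N across the C(=O) plane
        O[i] = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O,
                          psis[i] + 180.0)
        if i > 0:
            # amide H trans to the preceding carbonyl O (planar peptide bond)
            H[i] = place_atom(O[i - 1], C[i - 1], N[i], BOND_N_H,
                              ANGLE_C_N_H, 180.0)
        else:
            H[0] = place_atom(seed, CA[0], N[0], BOND_N_H, ANGLE_C_N_H, 0.0)
    return {"N": N, "H": H, "CA": CA, "C": C, "O": O}


def backbone_to_array(bb: dict[str, np.ndarray]) -> np.ndarray:
    """Interleave a backbone dict to an (n_res * 5, 3) coordinate array in
    atom order N, H, CA, C, O per residue."""
    n = bb["N"].shape[0]
    out = np.empty((n * 5, 3))
    for k, name in enumerate(("N", "H", "CA", "C", "O")):
        out[k::5] = bb[name]
    return out


def ring_coords(center: np.ndarray, normal: np.ndarray, radius: float = 1.39,
                phase_deg: float = 90.0) -> np.ndarray:
    """Coordinates of a planar regular hexagon (benzene-like carbon ring).

    ``normal`` is the ring-plane normal; ``phase_deg`` rotates the first
    atom within the plane (90 deg puts atom 0 along the first in-plane
    basis vector obtained from the normal).
    """
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    # build an in-plane orthonormal basis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u = u / np.linalg.norm(u)
    v = np.cross(normal, u)
    ang = np.deg2rad(phase_deg + 60.0 * np.arange(6))
    return (np.asarray(center, dtype=float)
            + radius * (np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * v))


def dha_angle(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    """Donor-hydrogen-acceptor angle in degrees (vertex at H)."""
    v1 = np.asarray(d) - np.asarray(h)
    v2 = np.asarray(a) - np.asarray(h)
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
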