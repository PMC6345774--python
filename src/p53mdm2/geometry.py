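"""Ideal-geometry peptide backbone construction and dihedral math.

Backbones are built residue-by-residue from (φ, ψ) dihedrals with fixed
bond lengths and angles (ω held at 180°), the standard internal-to-
Cartesian (NeRF) chain construction. Only N, Cα and C atoms are placed —
downstream consumers need Cα-level RMSD/R_g and backbone dihedrals only.

All coordinates are in nanometres.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "BOND_LENGTHS_NM",
    "BOND_ANGLES_DEG",
    "ALPHA_PHI_DEG",
    "ALPHA_PSI_DEG",
    "place_atom",
    "build_backbone",
    "dihedral_angle",
    "backbone_dihedrals",
    "ideal_helix",
]

#: ideal backbone bond lengths, nm
BOND_LENGTHS_NM = {"N-CA": 0.1458, "CA-C": 0.1525, "C-N": 0.1329}

#: ideal backbone bond angles, degrees
BOND_ANGLES_DEG = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7}

#: canonical alpha-helical backbone dihedrals, degrees
ALPHA_PHI_DEG = -60.0
ALPHA_PSI_DEG = -45.0

_OMEGA_DEG = 180.0


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float
               ) -> np.ndarray:
    """Place atom D given atoms A-B-C, the C-D bond length, the B-C-D
    angle and the A-B-C-D dihedral."""
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    # in-plane components negated so the measured A-B-C-D dihedral equals
    # the requested one (IUPAC sign convention)
    d_local = bond * np.array([-np.cos(theta),
                               -np.sin(theta) * np.cos(chi),
                               -np.sin(theta) * np.sin(chi)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi_deg: np.ndarray, psi_deg: np.ndarray) -> np.ndarray:
    """Backbone (N, Cα, C per residue) from per-residue (φ, ψ).

    φ of the first residue and ψ of the last are ignored (undefined).
    Returns an array of shape (3·n_residues, 3); atom order is
    N1, CA1, C1, N2, CA2, C2, ...
    """
    phi = np.asarray(phi_deg, dtype=float)
    psi = np.asarray(psi_deg, dtype=float)
    n_res = phi.size
    if n_res != psi.size:
        raise ValueError("phi and psi must have equal length")
    if n_res < 3:
        raise ValueError("need at least 3 residues")
    coords = np.zeros((3 * n_res, 3))
    b_nca, b_cac, b_cn = (BOND_LENGTHS_NM["N-CA"], BOND_LENGTHS_NM["CA-C"],
                          BOND_LENGTHS_NM["C-N"])
    ang_ncac = np.deg2rad(BOND_ANGLES_DEG["N-CA-C"])
    # first residue in the xy-plane
    coords[0] = (0.0, 0.0, 0.0)                      # N1
    coords[1] = (b_nca, 0.0, 0.0)                    # CA1
    coords[2] = coords[1] + b_cac * np.array(
        [-np.cos(ang_ncac), np.sin(ang_ncac), 0.0])  # C1
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = coords[3 * i - 3: 3 * i]
        coords[3 * i] = place_atom(n_prev, ca_prev, c_prev, b_cn,
                                   BOND_ANGLES_DEG["CA-C-N"],
                                   psi[i - 1])                       # N_i
        coords[3 * i + 1] = place_atom(ca_prev, c_prev, coords[3 * i],
                                       b_nca, BOND_ANGLES_DEG["C-N-CA"],
                                       _OMEGA_DEG)                   # CA_i
        coords[3 * i + 2] = place_atom(c_prev, coords[3 * i],
                                       coords[3 * i + 1], b_cac,
                                       BOND_ANGLES_DEG["N-CA-C"],
                                       phi[i])                       # C_i
    return coords


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral (degrees) of four points, IUPAC convention."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def backbone_dihedrals(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(φ, ψ) per residue from an (3·n_res, 3) backbone.

    φ of the first residue and ψ of the last are NaN (undefined).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] % 3:
        raise ValueError("expected N, CA, C atoms for every residue")
    n_res = coords.shape[0] // 3
    phi = np.full(n_res, np.nan)
    psi = np.full(n_res, np.nan)
    for i in range(n_res):
        n_i, ca_i, c_i = coords[3 * i: 3 * i + 3]
        if i > 0:
            c_prev = coords[3 * i - 1]
            phi[i] = dihedral_angle(c_prev, n_i, ca_i, c_i)
        if i < n_res - 1:
            n_next = coords[3 * i + 3]
            psi[i] = dihedral_angle(n_i, ca_i, c_i, n_next)
    return phi, psi


def ideal_helix(n_residues: int) -> np.ndarray:
    """Backbone of an ideal α-helix (φ=−60°, ψ=−45°)."""
    phi = np.full(n_residues, ALPHA_PHI_DEG)
    psi = np.full(n_residues, ALPHA_PSI_DEG)
    return build_backbone(phi, psi)
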