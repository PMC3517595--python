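"""Internal peptide-geometry primitives: NeRF atom placement, backbone
construction from φ/ψ dihedrals, and dihedral measurement.

Standard trans-peptide geometry (Engh & Huber averages, Å / degrees):
N-CA 1.458, CA-C 1.525, C-N 1.329, CA-CB 1.521; angles N-CA-C 111.2,
CA-C-N 116.2, C-N-CA 121.7, ω = 180° unless stated.
"""

from __future__ import annotations

import numpy as np

B_N_CA = 1.458
B_CA_C = 1.525
B_C_N = 1.329
B_CA_CB = 1.521

A_N_CA_C = 111.2
A_CA_C_N = 116.2
A_C_N_CA = 121.7
A_C_CA_CB = 110.1
# N-C-CA-CB improper dihedral placing CB for an L-amino acid
D_N_C_CA_CB = 122.6


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float
               ) -> np.ndarray:
    """Place atom d given chain a-b-c, |c-d|, angle(b,c,d), dihedral(a,b,c,d).

    The natural-extension (NeRF) construction: d is expressed in the local
    frame at c and rotated into the lab frame.
    """
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        # a, b, c collinear: any perpendicular will do (dihedral undefined)
        n = np.cross(bc, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(n) < 1e-12:
            n = np.cross(bc, np.array([0.0, 1.0, 0.0]))
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(chi),
        bond * np.sin(theta) * np.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def measure_dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, in (-180, 180]."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def build_backbone(phi_psi: list, omega: float = 180.0,
                   gly_positions: frozenset | set | tuple = (),
                   ) -> tuple[np.ndarray, list]:
    """Build N/CA/C/CB coordinates for a chain from per-residue (φ, ψ).

    φ of the first residue and ψ of the last are geometrically irrelevant
    and ignored.  CB is placed at the standard tetrahedral offset except at
    glycine positions.  Returns (coords, layout) where layout is the list
    of (residue_index, atom_name) in output order — residue order, then
    N, CA, C, CB.
    """
    n_res = len(phi_psi)
    if n_res < 2:
        raise ValueError("need at least 2 residues to define a dihedral")
    gly = set(gly_positions)

    # backbone trace first: N1 CA1 C1 N2 CA2 C2 ...
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([B_N_CA, 0.0, 0.0])]
    theta = np.deg2rad(A_N_CA_C)
    C = [CA[0] + B_CA_C * np.array([-np.cos(theta), np.sin(theta), 0.0])]
    for i in range(1, n_res):
        psi_prev = phi_psi[i - 1][1]
        Ni = place_atom(N[i - 1], CA[i - 1], C[i - 1],
                        B_C_N, A_CA_C_N, psi_prev)
        CAi = place_atom(CA[i - 1], C[i - 1], Ni,
                         B_N_CA, A_C_N_CA, omega)
        phi_i = phi_psi[i][0]
        Ci = place_atom(C[i - 1], Ni, CAi, B_CA_C, A_N_CA_C, phi_i)
        N.append(Ni)
        CA.append(CAi)
        C.append(Ci)

    coords, layout = [], []
    for i in range(n_res):
        coords += [N[i], CA[i], C[i]]
        layout += [(i, "N"), (i, "CA"), (i, "C")]
        if i not in gly:
            cb = place_atom(N[i], C[i], CA[i],
                            B_CA_CB, A_C_CA_CB, D_N_C_CA_CB)
            coords.append(cb)
            layout.append((i, "CB"))
    return np.array(coords), layout


def backbone_dihedrals(N: np.ndarray, CA: np.ndarray, C: np.ndarray
                       ) -> list:
    """(φ, ψ) per residue from backbone atom arrays; None where undefined
    (φ of the first residue, ψ of the last)."""
    n_res = len(N)
    out = []
    for i in range(n_res):
        phi = (measure_dihedral(C[i - 1], N[i], CA[i], C[i])
               if i > 0 else None)
        psi = (measure_dihedral(N[i], CA[i], C[i], N[i + 1])
               if i < n_res - 1 else None)
        out.append((phi, psi))
    return out
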