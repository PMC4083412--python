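"""Internal-coordinate backbone construction for synthetic fixtures."""

from __future__ import annotations

import numpy as np

# Ideal backbone internal coordinates (Engh & Huber era averages), Angstrom/deg.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement of atom D from three predecessors and internal coords.

    `bond` = |C-D|, `angle_deg` = angle B-C-D, `torsion_deg` = dihedral A-B-C-D.
    """
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def cb_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal tetrahedral C-beta from the backbone N-CA-C frame."""
    u = n - ca
    u /= np.linalg.norm(u)
    v = c - ca
    v /= np.linalg.norm(v)
    cos_nacb = np.cos(np.deg2rad(110.5))
    dot_uv = float(u @ v)
    a = cos_nacb / (1.0 + dot_uv)
    b_sq = 1.0 - a * a * (2.0 + 2.0 * dot_uv)
    b = np.sqrt(max(b_sq, 0.0))
    nrm = np.cross(u, v)
    nrm /= np.linalg.norm(nrm)
    direction = a * (u + v) + b * nrm
    return ca + BOND_CA_CB * direction / np.linalg.norm(direction)


def backbone_from_torsions(phis: list[float], psis: list[float]) -> list[dict[str, np.ndarray]]:
    """Build N/CA/C/O/CB coordinates for a chain with the given phi/psi lists."""
    n_res = len(phis)
    assert len(psis) == n_res
    coords: list[dict[str, np.ndarray]] = []
    # seed the first residue in the xy-plane
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0]) * -1.0
    # rotate so the N-CA-C angle is correct: place C in-plane
    c0 = ca0 + BOND_CA_C * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = coords[-1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psis[i - 1])
        ca_i = place_atom(prev["CA"], prev["C"], n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_i = place_atom(prev["C"], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phis[i])
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})
    # carbonyl O: dihedral N-CA-C-O = psi + 180 (points away from the next N)
    for i in range(n_res):
        res = coords[i]
        res["O"] = place_atom(res["N"], res["CA"], res["C"], BOND_C_O, ANGLE_CA_C_O, psis[i] + 180.0)
        res["CB"] = cb_position(res["N"], res["CA"], res["C"])
    return coords
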