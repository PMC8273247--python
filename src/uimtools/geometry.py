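"""Backbone geometry: chain construction, dihedrals, superposition.

Coordinates are in angstrom, angles in degrees unless a function says
otherwise.  Chains are built with ideal, fixed internal coordinates
(trans peptide, omega = 180 deg) by sequential natural-extension (NeRF)
placement, so a conformer is fully specified by its (phi, psi) list.
"""

from __future__ import annotations

import numpy as np

# ideal backbone internal coordinates (angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
ANGLE_C_CA_CB = 110.1
TORSION_N_C_CA_CB = -122.6  # L-amino-acid chirality
OMEGA_TRANS = 180.0

#: atom order of the coordinate arrays produced by :func:`build_backbone_coordinates`
BACKBONE_ATOMS = ("N", "CA", "C", "O", "CB")


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg) -> np.ndarray:
    """Place atom D given atoms A, B, C and internal coordinates.

    ``bond`` is the C-D distance, ``angle_deg`` the B-C-D angle and
    ``torsion_deg`` the A-B-C-D dihedral (IUPAC sign).  Broadcasts over
    leading axes, so whole trajectory frames can be extended at once.
    """
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(np.asarray(torsion_deg, dtype=float))[..., None]
    bc = _normalize(c - b)
    n = _normalize(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d = (bond * np.cos(np.pi - theta)) * bc \
        + (bond * np.sin(np.pi - theta) * np.cos(chi)) * m \
        + (bond * np.sin(np.pi - theta) * np.sin(chi)) * n
    return c + d


def dihedral_angle(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral p0-p1-p2-p3 in degrees, broadcast over leading axes."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    v = np.cross(b0, b1)
    w = np.cross(b1, b2)
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(v, w) * _normalize(b1), axis=-1)
    return np.degrees(np.arctan2(y, x))


def build_backbone_coordinates(dihedrals: np.ndarray,
                               sequence: str | None = None) -> np.ndarray:
    """Build N/CA/C/O/CB coordinates from per-residue (phi, psi).

    Parameters
    ----------
    dihedrals : array, shape (n_res, 2) or (n_frames, n_res, 2)
        Per-residue (phi, psi) in degrees.  ``phi`` of the first residue
        and ``psi`` of the last are undefined by construction and may be
        NaN; any finite value there is ignored.
    sequence : str, optional
        One-letter sequence; when given, CB of glycine residues is set to
        NaN (glycine has no beta carbon).

    Returns
    -------
    array, shape (..., n_res, 5, 3)
        Atom order ``N, CA, C, O, CB``; consecutive CA-CA distances are
        ~3.8 A (fixed trans geometry).
    """
    dih = np.asarray(dihedrals, dtype=float)
    single = dih.ndim == 2
    if single:
        dih = dih[None]
    if dih.ndim != 3 or dih.shape[-1] != 2:
        raise ValueError("dihedrals must have shape (n_res, 2) or (n_frames, n_res, 2)")
    n_frames, n_res = dih.shape[:2]
    if n_res < 2:
        raise ValueError("need at least 2 residues to build a chain")
    interior = dih[:, 1:, 0], dih[:, :-1, 1]  # phi (2..n), psi (1..n-1)
    for block in interior:
        if not np.all(np.isfinite(block)):
            raise ValueError("interior phi/psi angles must be finite")
    if sequence is not None and len(sequence) != n_res:
        raise ValueError("sequence length does not match dihedral table")

    phi = dih[..., 0]
    psi = dih[..., 1]
    N = np.empty((n_frames, n_res, 3))
    CA = np.empty_like(N)
    C = np.empty_like(N)

    # first residue in a canonical local frame
    N[:, 0] = 0.0
    CA[:, 0] = (BOND_N_CA, 0.0, 0.0)
    ang = np.deg2rad(ANGLE_N_CA_C)
    C[:, 0] = CA[:, 0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])

    for i in range(1, n_res):
        N[:, i] = place_atom(N[:, i - 1], CA[:, i - 1], C[:, i - 1],
                             BOND_C_N, ANGLE_CA_C_N, psi[:, i - 1])
        CA[:, i] = place_atom(CA[:, i - 1], C[:, i - 1], N[:, i],
                              BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        C[:, i] = place_atom(C[:, i - 1], N[:, i], CA[:, i],
                             BOND_CA_C, ANGLE_N_CA_C, phi[:, i])

    # carbonyl O: anti to the following N (psi + 180); last residue uses a
    # fixed convention since its psi is undefined
    psi_eff = np.where(np.isfinite(psi), psi, OMEGA_TRANS)
    O = place_atom(N, CA, C, BOND_C_O, ANGLE_CA_C_O, psi_eff + 180.0)
    CB = place_atom(N, C, CA, BOND_CA_CB, ANGLE_C_CA_CB, TORSION_N_C_CA_CB)
    if sequence is not None:
        gly = np.array([aa == "G" for aa in sequence])
        CB[:, gly] = np.nan

    coords = np.stack([N, CA, C, O, CB], axis=-2)
    return coords[0] if single else coords


def backbone_dihedrals(coords: np.ndarray) -> np.ndarray:
    """Recompute per-residue (phi, psi) in degrees from N/CA/C coordinates.

    ``coords`` has shape (..., n_res, >=3, 3) with atom order starting
    ``N, CA, C``.  phi of the first and psi of the last residue are NaN.
    """
    coords = np.asarray(coords, dtype=float)
    N, CA, C = coords[..., 0, :], coords[..., 1, :], coords[..., 2, :]
    lead = coords.shape[:-3]
    n_res = coords.shape[-3]
    out = np.full(lead + (n_res, 2), np.nan)
    out[..., 1:, 0] = dihedral_angle(C[..., :-1, :], N[..., 1:, :],
                                     CA[..., 1:, :], C[..., 1:, :])
    out[..., :-1, 1] = dihedral_angle(N[..., :-1, :], CA[..., :-1, :],
                                      C[..., :-1, :], N[..., 1:, :])
    return out


def radius_of_gyration(coords: np.ndarray) -> float:
    """Unweighted radius of gyration (A) of a point set, shape (n, 3)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("expected a non-empty (n, 3) coordinate array")
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``target``.  The
    rotation is proper (reflections are excluded by flipping the smallest
    singular direction, which for degenerate/collinear sets selects the
    smallest-angle proper rotation).

    Parameters
    ----------
    mobile, target : array, shape (n, 3)
        Matched atom coordinates, n >= 3.
    """
    A = np.asarray(mobile, dtype=float)
    B = np.asarray(target, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"coordinate sets differ in shape: {A.shape} vs {B.shape}")
    if A.ndim != 2 or A.shape[1] != 3 or A.shape[0] < 3:
        raise ValueError("need matched (n, 3) arrays with n >= 3")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    H = A0.T @ B0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    rmsd = float(np.sqrt(np.mean(np.sum((A0 @ R.T - B0) ** 2, axis=1))))
    return R, t, rmsd


def superposed_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """RMSD after optimal rigid superposition (convenience wrapper)."""
    return kabsch_superpose(mobile, target)[2]
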