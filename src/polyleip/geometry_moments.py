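"""Chain geometry and exact ensemble-averaged squared site-site distances.

Coordinates follow the rotational-isomeric-state convention: rigid bond
lengths and bond (valence) angles, discrete dihedrals trans = 180 deg,
gauche+/- = +/-60 deg (the three states are 120 deg apart).  Changing the
state of a rotatable bond rigidly rotates all downstream nodes about that
bond's axis.

``mean_square_distance`` returns <d_ij^2>_0, the average of the squared
site i - site j distance over the unperturbed SBRIS ensemble (including
the ionization weights).  It is computed exactly by a Flory-Jernigan
style contraction: a dynamic program over the 6-state super-matrix chain
that carries, per chain state, the statistical weight, the weighted
partial displacement vector (in the local bond frame) and the weighted
partial squared norm.  Sampling never enters the solver path.
"""

from __future__ import annotations

import numpy as np

from .model_core import ChainSpec, EnergyParams
from .transfer_matrix import ION6, ChainEngine, sbris_engine

__all__ = [
    "site_positions",
    "dihedral_angle",
    "segment_operators",
    "mean_square_distance",
    "msd_matrix",
    "write_xyz",
]

#: dihedral angle (radians) of each bond state: trans, gauche+, gauche-.
STATE_DIHEDRALS = np.array([np.pi, np.pi / 3.0, -np.pi / 3.0])


def _extend(p0, p1, p2, length, theta, phi):
    """Place the next node given the three preceding ones.

    ``theta`` is the valence angle at p2 (between the bonds p1-p2 and
    p2-p3) and ``phi`` the signed dihedral of the quadruple p0,p1,p2,p3.
    """
    b1 = p1 - p0
    b2 = p2 - p1
    u2 = b2 / np.linalg.norm(b2)
    n = np.cross(b1, b2)
    n = n / np.linalg.norm(n)
    m = np.cross(n, u2)
    d = length * (
        -np.cos(theta) * u2 + np.sin(theta) * (np.cos(phi) * m + np.sin(phi) * n)
    )
    return p2 + d


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral (radians) of four points, in (-pi, pi]."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    u2 = b2 / np.linalg.norm(b2)
    x = float(n1 @ n2)
    y = float(np.cross(n1, n2) @ u2)
    return float(np.arctan2(y, x))


def _bond_dihedrals(c: np.ndarray, chain: ChainSpec) -> np.ndarray:
    """Dihedral of every bond: trans except the rotatable bonds."""
    phi = np.full(chain.n_bonds, np.pi)
    if chain.n_rotatable:
        phi[chain.rotatable_bonds] = STATE_DIHEDRALS[np.asarray(c, dtype=int)]
    return phi


def site_positions(c, chain: ChainSpec) -> np.ndarray:
    """3-D coordinates (nm) of all chain nodes for conformation ``c``.

    The chain start is oriented by two fictitious trans bonds, so every
    segment (including the first) is built identically; inter-node
    distances are independent of that choice.
    """
    c = np.asarray(c, dtype=int)
    if c.shape != (chain.n_rotatable,):
        raise ValueError("conformation vector length does not match chain")
    length = chain.bond_length
    theta = np.deg2rad(chain.bond_angle)
    phi = _bond_dihedrals(c, chain)

    # Two fictitious trans nodes preceding node 0.
    pts = np.empty((chain.n_nodes + 2, 3))
    pts[0] = (0.0, 0.0, 0.0)
    pts[1] = (length, 0.0, 0.0)
    ref = np.array([0.0, 1.0, 0.0])  # fixes the plane of the first placement
    pts[2] = _extend(pts[0] + ref, pts[0], pts[1], length, theta, np.pi)
    for k in range(3, chain.n_nodes + 2):
        # node k is reached by bond k-3 (in real-bond indexing the bond
        # being appended is k-3; its placement uses the torsion of the
        # previous bond, which for real bonds is phi[k-4]).
        torsion = np.pi if k == 3 else phi[k - 4]
        pts[k] = _extend(pts[k - 3], pts[k - 2], pts[k - 1], length, theta, torsion)
    out = pts[2:] - pts[2]
    return out


def _site_frame(pts: np.ndarray, node: int) -> np.ndarray:
    """Orthonormal frame at a node, built from the two entering bonds."""
    b_prev = pts[node - 1] - pts[node - 2]
    b_in = pts[node] - pts[node - 1]
    e1 = b_in / np.linalg.norm(b_in)
    e3 = np.cross(b_prev, b_in)
    e3 = e3 / np.linalg.norm(e3)
    e2 = np.cross(e3, e1)
    return np.column_stack([e1, e2, e3])


def segment_operators(chain: ChainSpec):
    """Per-state rigid-body operators of one inter-site segment.

    Returns ``(R, d)`` with ``R[s]`` the rotation from the local frame at
    site k to the frame at site k+1 and ``d[s]`` the site-to-site
    displacement expressed in the frame at site k, for segment state
    s in (t, g+, g-).  The chain is homogeneous, so one segment's
    operators describe them all.
    """
    if chain.is_rigid:
        raise ValueError("segment operators are undefined for a rigid chain")
    probe = ChainSpec(
        n_sites=3,
        spacing=chain.spacing,
        bond_length=chain.bond_length,
        bond_angle=chain.bond_angle,
        rotatable_index=chain.rotatable_index,
    )
    R = np.empty((3, 3, 3))
    d = np.empty((3, 3))
    for s in range(3):
        # middle segment (sites 1 -> 2) carries the probed state
        pts = site_positions(np.array([0, s]), probe)
        n1 = probe.spacing
        n2 = 2 * probe.spacing
        F1 = _site_frame(pts, n1)
        F2 = _site_frame(pts, n2)
        R[s] = F1.T @ F2
        d[s] = F1.T @ (pts[n2] - pts[n1])
    return R, d


def _msd_sweep(
    eng: ChainEngine,
    R: np.ndarray,
    d: np.ndarray,
    conditioned: bool = False,
) -> np.ndarray:
    """All-pairs <d_ij^2> under the engine's ensemble.

    Checkpoint m of the engine is site m; the DP carries, for every start
    site i and chain state xi, the weight W, the local-frame partial
    vector V and the partial squared norm Q, updated per segment with the
    per-state rotation/displacement operators.  When ``conditioned`` the
    average is restricted to states with both end sites protonated.
    """
    n = eng.n  # segments; sites 0..n
    k = eng.k
    d2 = (d**2).sum(axis=1)  # |d_s|^2 per state
    conf_of = np.tile(np.arange(3), k // 3)  # conf component of state index

    msd = np.full((n + 1, n + 1), np.nan)
    start_proj = ION6 if conditioned else np.ones(k)
    end_proj = ION6 if conditioned else np.ones(k)

    W = np.zeros((n + 1, k))
    V = np.zeros((n + 1, k, 3))
    Q = np.zeros((n + 1, k))
    active = 0
    for seg in range(1, n + 1):
        # activate start site seg-1 before stepping over segment seg
        W[seg - 1] = eng.P[seg - 1] * start_proj
        V[seg - 1] = 0.0
        Q[seg - 1] = 0.0
        active = seg
        A = W[:active] @ eng.Bh  # (active, k)
        BV = np.einsum("xX,ixc->iXc", eng.Bh, V[:active])
        M = BV + A[:, :, None] * d[conf_of][None, :, :]
        # rotate the partial vectors into the new local frame
        Rt = R[conf_of].transpose(0, 2, 1)  # (k, 3, 3): per-state R^T
        Vnew = np.einsum("Xab,iXb->iXa", Rt, M)
        crossterm = 2.0 * np.einsum("iXc,Xc->iX", BV, d[conf_of])
        Qnew = Q[:active] @ eng.Bh + crossterm + A * d2[conf_of][None, :]
        W[:active] = A
        V[:active] = Vnew
        Q[:active] = Qnew
        # record msd to site `seg` for all starts i < seg
        proj_S = end_proj * eng.S[seg]
        num = Q[:active] @ proj_S
        den = W[:active] @ proj_S
        with np.errstate(invalid="ignore", divide="ignore"):
            msd[:active, seg] = num / den
    return msd


def msd_matrix(
    chain: ChainSpec,
    params: EnergyParams,
    pH: float,
    x: float = 0.0,
    x_sigma: float = 0.0,
    conditioned: bool = False,
    eng: ChainEngine | None = None,
) -> np.ndarray:
    """<d_ij^2>_0 (nm^2) for all site pairs i < j of the minimal chain.

    The average runs over the full unperturbed short-range ensemble
    (all s, c); set ``conditioned=True`` to restrict it to states with
    both end sites protonated (a sensitivity-check variant).
    """
    if eng is None:
        eng = sbris_engine(chain, params, pH, x, x_sigma)
    R, d = segment_operators(chain)
    return _msd_sweep(eng, R, d, conditioned=conditioned)


def mean_square_distance(
    i: int,
    j: int,
    chain: ChainSpec,
    params: EnergyParams,
    pH: float,
    x: float = 0.0,
    x_sigma: float = 0.0,
    conditioned: bool = False,
) -> float:
    """<d_ij^2>_0 for one site pair (i < j)."""
    if i == j:
        raise ValueError("site indices must differ")
    if i > j:
        i, j = j, i
    if not (0 <= i < chain.n_sites and 0 <= j < chain.n_sites):
        raise IndexError("site index out of range")
    return float(
        msd_matrix(chain, params, pH, x, x_sigma, conditioned=conditioned)[i, j]
    )


def write_xyz(path, coords: np.ndarray, comment: str = "") -> None:
    """Write node coordinates as a plain xyz snapshot (nm units)."""
    coords = np.asarray(coords)
    with open(path, "w") as fh:
        fh.write(f"{len(coords)}\n{comment}\n")
        for x, y, z in coords:
            fh.write(f"C {x:.9f} {y:.9f} {z:.9f}\n")
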