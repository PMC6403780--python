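"""Exact short-range partition functions and observables by transfer matrices.

Three chain models share one engine:

* the rigid site-binding (SB) chain: 2-state sites, nearest-neighbour
  interaction ``u``, transfer matrix ``T = [[1, z], [1, z u]]`` with
  reduced activity ``z = 10**(pK - pH)``;
* the neutral rotational-isomeric-state (RIS) chain: 3-state bonds
  (t, g+, g-) with statistical weight matrix ``U`` built from sigma,
  psi, omega;
* the combined SBRIS chain: 6x6 super-matrices coupling the ionization
  of consecutive sites to the state of the rotatable bond between them,
  with the diagonal short-range block ``u = diag(u_t, u_g, u_g)``.

Site- and bond-resolved observables are computed exactly by projector
insertion (replacing one matrix in the product by its protonated- or
gauche-selecting part), never by finite differences; matrix products are
accumulated with running renormalization so 50-site chains at extreme pH
do not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import ChainSpec, EnergyParams

__all__ = [
    "EnsembleObservables",
    "sb_matrix",
    "ris_matrix",
    "sb_partition",
    "sb_observables",
    "ris_gauche_fraction",
    "sbris_partition",
    "sbris_observables",
]

# Diagonal projectors (as vectors) for the 6x6 SBRIS state (ion block x conf).
ION6 = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
GAUCHE6 = np.array([0.0, 1.0, 1.0, 0.0, 1.0, 1.0])
ION2 = np.array([0.0, 1.0])
GAUCHE3 = np.array([0.0, 1.0, 1.0])

_TINY = np.finfo(float).tiny


def sb_matrix(z: float, u: float) -> np.ndarray:
    """2x2 site-binding transfer matrix [[1, z], [1, z*u]]."""
    if z < 0 or u < 0:
        raise ValueError("z and u must be non-negative weights")
    return np.array([[1.0, z], [1.0, z * u]])


def ris_matrix(sigma: float, psi: float, omega: float) -> np.ndarray:
    """3x3 RIS statistical weight matrix over (t, g+, g-).

    Same-orientation consecutive gauche pairs weigh sigma*psi, opposite
    pairs sigma*omega (pentane effect).
    """
    if min(sigma, psi, omega) < 0:
        raise ValueError("sigma, psi, omega must be non-negative weights")
    return np.array(
        [
            [1.0, sigma, sigma],
            [1.0, sigma * psi, sigma * omega],
            [1.0, sigma * omega, sigma * psi],
        ]
    )


def sbris_supermatrix(z: float, U: np.ndarray, u_t: float, u_g: float) -> np.ndarray:
    """6x6 super-matrix for an ionization-bearing rotatable bond.

    Block rows index the previous site's ionization, block columns the
    new site's; the short-range diagonal block scales the columns of the
    protonated-protonated block by u_t (trans) or u_g (gauche).
    """
    usr = np.array([u_t, u_g, u_g])
    return np.block([[U, z * U], [U, z * (U * usr[None, :])]])


class ChainEngine:
    """Renormalized product of one repeated transfer matrix.

    Checkpoint ``m`` (0..n_steps) is the state vector after ``m`` matrix
    applications.  Prefixes and suffixes are stored max-normalized with
    per-checkpoint log scales, so expectations of projector insertions at
    one or two checkpoints are exact and overflow-free.
    """

    def __init__(self, B: np.ndarray, r: np.ndarray, t: np.ndarray, n_steps: int):
        B = np.asarray(B, dtype=float)
        self.k = B.shape[0]
        self.n = int(n_steps)
        scale = max(float(np.abs(B).sum(axis=1).max()), _TINY)
        self.Bh = B / scale
        self.log_scale = float(np.log(scale))

        P = np.empty((self.n + 1, self.k))
        lp = np.empty(self.n + 1)
        v = np.asarray(r, dtype=float).copy()
        lv = 0.0
        for m in range(self.n + 1):
            mx = float(np.abs(v).max())
            if mx <= 0:
                raise FloatingPointError("transfer-matrix product vanished")
            v = v / mx
            lv += np.log(mx)
            P[m], lp[m] = v, lv
            if m < self.n:
                v = v @ self.Bh
                lv += self.log_scale
        S = np.empty((self.n + 1, self.k))
        ls = np.empty(self.n + 1)
        w = np.asarray(t, dtype=float).copy()
        lw = 0.0
        for m in range(self.n, -1, -1):
            mx = float(np.abs(w).max())
            if mx <= 0:
                raise FloatingPointError("transfer-matrix product vanished")
            w = w / mx
            lw += np.log(mx)
            S[m], ls[m] = w, lw
            if m > 0:
                w = self.Bh @ w
                lw += self.log_scale
        self.P, self.lp, self.S, self.ls = P, lp, S, ls
        xi = float(P[0] @ S[0])
        if xi <= 0:
            raise FloatingPointError("partition function is zero")
        self.log_partition = float(np.log(xi) + lp[0] + ls[0])

    # -- single-checkpoint expectations ---------------------------------
    def diag_profile(self, diag: np.ndarray) -> np.ndarray:
        """<X_m> for the diagonal projector at every checkpoint m."""
        num = np.einsum("mk,k,mk->m", self.P, diag, self.S)
        return num * np.exp(self.lp + self.ls - self.log_partition)

    def expect_diag(self, m: int, diag: np.ndarray) -> float:
        num = float(self.P[m] @ (diag * self.S[m]))
        return num * float(np.exp(self.lp[m] + self.ls[m] - self.log_partition))

    # -- two-checkpoint correlations -------------------------------------
    def pair_matrix(self, diagL: np.ndarray, diagR: np.ndarray) -> np.ndarray:
        """C[m, m'] = <X_m Y_m'> for all checkpoint pairs m < m'."""
        n = self.n
        C = np.zeros((n + 1, n + 1))
        X = self.P * diagL[None, :]
        RS = self.S * diagR[None, :]
        lgap = 0.0
        for gap in range(1, n + 1):
            X = X @ self.Bh
            lgap += self.log_scale
            rows = np.arange(0, n - gap + 1)
            num = np.einsum("ik,ik->i", X[: n - gap + 1], RS[gap:])
            C[rows, rows + gap] = num * np.exp(
                self.lp[rows] + self.ls[rows + gap] + lgap - self.log_partition
            )
        return C

    def adjacent_pair_profile(self, diag: np.ndarray) -> np.ndarray:
        """<X_m X_{m+1}> for consecutive checkpoints (one matrix between)."""
        n = self.n
        left = (self.P[:n] * diag[None, :]) @ self.Bh
        num = np.einsum("mk,k,mk->m", left, diag, self.S[1:])
        return num * np.exp(
            self.lp[:n] + self.ls[1:] + self.log_scale - self.log_partition
        )


@dataclass
class EnsembleObservables:
    """Exact ensemble averages of a short-range chain model.

    ``theta`` are per-site protonation probabilities, ``nu`` their sum,
    ``g`` the mean gauche-bond count, ``D`` the mean count of adjacent
    protonated pairs, ``p_gauche`` per-bond gauche probabilities and
    ``pair_corr`` the requested <s_i s_j> values.
    """

    log_partition: float
    theta: np.ndarray
    nu: float
    g: float = 0.0
    D: float = 0.0
    p_gauche: np.ndarray = field(default_factory=lambda: np.empty(0))
    pair_corr: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Rigid SB chain
# ---------------------------------------------------------------------------

def sb_engine(n_sites: int, z: float, u: float) -> ChainEngine:
    T = sb_matrix(z, u)
    return ChainEngine(T, np.array([1.0, 0.0]), np.array([1.0, 1.0]), n_sites)


def sb_partition(n_sites: int, z: float, u: float) -> float:
    """ln Xi of the nearest-neighbour SB chain (Xi = q T^N p)."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    return sb_engine(n_sites, z, u).log_partition


def sb_observables(
    n_sites: int, z: float, u: float, pairs: list[tuple[int, int]] | None = None
) -> EnsembleObservables:
    """Exact theta_i, nu, D and requested <s_i s_j> of the SB chain.

    Sites are indexed 0..n_sites-1; site i corresponds to checkpoint i+1
    of the matrix product.
    """
    eng = sb_engine(n_sites, z, u)
    theta = eng.diag_profile(ION2)[1:]  # checkpoint 0 carries no site
    adj = eng.adjacent_pair_profile(ION2)[1:]  # <s_i s_{i+1}>
    obs = EnsembleObservables(
        log_partition=eng.log_partition,
        theta=theta,
        nu=float(theta.sum()),
        D=float(adj.sum()),
    )
    if pairs:
        H = eng.pair_matrix(ION2, ION2)
        for i, j in pairs:
            if not (0 <= i < n_sites and 0 <= j < n_sites and i != j):
                raise IndexError(f"pair index out of range: {(i, j)}")
            a, b = sorted((i, j))
            obs.pair_corr[(i, j)] = float(H[a + 1, b + 1])
    return obs


def sb_pair_matrix(n_sites: int, z: float, u: float) -> np.ndarray:
    """Full <s_i s_j> matrix (upper triangle, 0-based site indices)."""
    eng = sb_engine(n_sites, z, u)
    return eng.pair_matrix(ION2, ION2)[1:, 1:]


def sb_fluctuations(n_sites: int, z: float, u: float):
    """(Var n, Cov(n, D), Var D) of the SB chain, exactly.

    D = sum_i s_i s_{i+1}.  Used for the exact Jacobian of the rigid
    effective-parameter equations.
    """
    eng = sb_engine(n_sites, z, u)
    n = eng.n
    theta = eng.diag_profile(ION2)[1:]
    nu = theta.sum()
    H = eng.pair_matrix(ION2, ION2)[1:, 1:]
    var_n = float(nu + 2.0 * np.triu(H, 1).sum() - nu**2)

    d_mean = eng.adjacent_pair_profile(ION2)[1:]  # delta_m, m = 1..N-1
    D0 = float(d_mean.sum())

    # Bond-pair vectors: Xd[m] lives at checkpoint m+1, Rd[m] at checkpoint m.
    # (checkpoint indices: site i <-> checkpoint i+1; bond variable
    # delta_i = s_i s_{i+1} spans checkpoints i+1, i+2, i = 0..N-2)
    nb = n - 1  # number of adjacent pairs
    Xd = (eng.P[1:n] * ION2[None, :]) @ eng.Bh * ION2[None, :]
    lXd = eng.lp[1:n] + eng.log_scale  # at checkpoint m+1, m = 1..n-1
    Rd = (eng.Bh @ (ION2[:, None] * eng.S[2:].T)).T * ION2[None, :]
    lRd = eng.ls[2:] + eng.log_scale  # at checkpoint m, m = 1..n-1

    # <delta_m delta_m'>, m' > m: Xd[m] Bh^{m'-m-1} Rd[m']
    cross = 0.0
    Y = Xd.copy()
    lY = lXd.copy()
    for gap in range(0, nb - 1):
        rows = np.arange(0, nb - 1 - gap)
        num = np.einsum("ik,ik->i", Y[: nb - 1 - gap], Rd[1 + gap:])
        cross += float(
            (num * np.exp(lY[rows] + lRd[rows + 1 + gap] - eng.log_partition)).sum()
        )
        Y = Y @ eng.Bh
        lY = lY + eng.log_scale
    var_D = float(D0 + 2.0 * cross - D0**2)

    # <n D>: overlap terms (site is an end of the pair) give <delta>.
    nD = 2.0 * D0
    # site strictly left of the pair: P[m]*ion Bh^{m'-m} Rd[m'] (m < m')
    A = eng.P[1:n + 1] * ION2[None, :]  # site checkpoints 1..n
    lA = eng.lp[1:n + 1]
    Y = A.copy()
    lY = lA.copy()
    for gap in range(1, nb):
        Y = Y @ eng.Bh
        lY = lY + eng.log_scale
        # site checkpoint m = i+1, pair left end m' = m+gap <= n-1
        count = nb - gap
        if count <= 0:
            break
        num = np.einsum("ik,ik->i", Y[:count], Rd[gap: gap + count])
        nD += float(
            (num * np.exp(lY[:count] + lRd[gap: gap + count] - eng.log_partition)).sum()
        )
    # site strictly right of the pair: Xd[m'] Bh^{m-(m'+1)} ion*S[m]
    RS = eng.S * ION2[None, :]
    Y = Xd.copy()
    lY = lXd.copy()
    for gap in range(1, n):
        Y = Y @ eng.Bh
        lY = lY + eng.log_scale
        # site checkpoint = (m'+1) + gap, with m' = 1..n-1
        count = min(nb, n - gap - 1)
        if count <= 0:
            break
        tgt = np.arange(0, count) + 2 + gap  # checkpoint indices of the site
        num = np.einsum("ik,ik->i", Y[:count], RS[tgt])
        nD += float((num * np.exp(lY[:count] + eng.ls[tgt] - eng.log_partition)).sum())
    cov_nD = float(nD - nu * D0)
    return var_n, cov_nD, var_D


# ---------------------------------------------------------------------------
# Neutral RIS chain
# ---------------------------------------------------------------------------

def ris_gauche_fraction(
    n_bonds: int, sigma: float, psi: float, omega: float
) -> tuple[float, float]:
    """Per-bond gauche probability g/M and ln Xi_rot of the RIS chain.

    The sigma-derivative of ln Xi_rot is evaluated analytically by
    projector insertion (summed bond-state probabilities).
    """
    if n_bonds < 1:
        raise ValueError("n_bonds must be >= 1")
    U = ris_matrix(sigma, psi, omega)
    eng = ChainEngine(U, np.array([1.0, 0.0, 0.0]), np.ones(3), n_bonds)
    p_gauche = eng.diag_profile(GAUCHE3)[1:]
    return float(p_gauche.mean()), eng.log_partition


# ---------------------------------------------------------------------------
# Combined SBRIS chain
# ---------------------------------------------------------------------------

def _shift_values(shifts) -> tuple[float, float]:
    if shifts is None:
        return 0.0, 0.0
    if isinstance(shifts, (tuple, list)):
        x, x_sigma = shifts
        return float(x), float(x_sigma)
    return float(getattr(shifts, "x", 0.0)), float(getattr(shifts, "x_sigma", 0.0))


def sbris_engine(
    chain: ChainSpec,
    params: EnergyParams,
    pH: float,
    x: float = 0.0,
    x_sigma: float = 0.0,
) -> ChainEngine:
    """Engine for the minimal SBRIS chain under shifted parameters.

    The shifts act as pK -> pK - x and p_sigma -> p_sigma + x_sigma
    before matrix construction.  Checkpoint m carries site m's ionization
    and (for m >= 1) rotatable bond m-1's state.  The first site's
    activity factor is absorbed into the left decoration r = (q, z q),
    the convention fixed by equality with brute-force enumeration.
    """
    if chain.n_rotatable != chain.n_sites - 1:
        raise ValueError("sbris engine requires the minimal chain topology")
    z = 10.0 ** ((params.pK - x) - pH)
    sigma_eff = params.sigma * 10.0 ** (-x_sigma)
    U = ris_matrix(sigma_eff, params.psi, params.omega)
    B = sbris_supermatrix(z, U, params.u_t, params.u_g)
    r = np.array([1.0, 0.0, 0.0, z, 0.0, 0.0])
    t = np.ones(6)
    return ChainEngine(B, r, t, chain.n_sites - 1)


def sbris_partition(
    chain: ChainSpec,
    params: EnergyParams,
    pH: float,
    shifts=None,
) -> float:
    """ln Xi_SBRIS: exact sum over all roto-microstates, LR disabled."""
    x, x_sigma = _shift_values(shifts)
    return sbris_engine(chain, params, pH, x, x_sigma).log_partition


def sbris_observables(
    chain: ChainSpec,
    params: EnergyParams,
    pH: float,
    shifts=None,
    pairs: list[tuple[int, int]] | None = None,
) -> EnsembleObservables:
    """Exact SBRIS observables under the (possibly shifted) SR model."""
    x, x_sigma = _shift_values(shifts)
    eng = sbris_engine(chain, params, pH, x, x_sigma)
    theta = eng.diag_profile(ION6)  # sites live at checkpoints 0..N-1
    p_gauche = eng.diag_profile(GAUCHE6)[1:]  # bonds at checkpoints 1..N-1
    adj = eng.adjacent_pair_profile(ION6)
    obs = EnsembleObservables(
        log_partition=eng.log_partition,
        theta=theta,
        nu=float(theta.sum()),
        g=float(p_gauche.sum()),
        D=float(adj.sum()),
        p_gauche=p_gauche,
    )
    if pairs:
        H = eng.pair_matrix(ION6, ION6)
        for i, j in pairs:
            if not (0 <= i < chain.n_sites and 0 <= j < chain.n_sites and i != j):
                raise IndexError(f"pair index out of range: {(i, j)}")
            a, b = sorted((i, j))
            obs.pair_corr[(i, j)] = float(H[a, b])
    return obs


def sbris_pair_matrix(eng: ChainEngine) -> np.ndarray:
    """Full <s_i s_j> matrix of the SBRIS chain (sites = checkpoints)."""
    return eng.pair_matrix(ION6, ION6)


def sbris_fluctuations(eng: ChainEngine):
    """(Var n, Cov(n, g), Var g) of the SBRIS chain, exactly."""
    theta = eng.diag_profile(ION6)
    nu = float(theta.sum())
    pg = eng.diag_profile(GAUCHE6)
    pg[0] = 0.0  # checkpoint 0 carries no bond
    g = float(pg.sum())

    Hss = eng.pair_matrix(ION6, ION6)
    var_n = float(nu + 2.0 * np.triu(Hss, 1).sum() - nu**2)

    Hgg = eng.pair_matrix(GAUCHE6, GAUCHE6)
    Hgg[0, :] = 0.0
    var_g = float(g + 2.0 * np.triu(Hgg, 1).sum() - g**2)

    Hsg = eng.pair_matrix(ION6, GAUCHE6)
    Hsg[:, 0] = 0.0
    Hgs = eng.pair_matrix(GAUCHE6, ION6)
    Hgs[0, :] = 0.0
    same = eng.diag_profile(ION6 * GAUCHE6)
    same[0] = 0.0
    ng = float(np.triu(Hsg, 1).sum() + np.triu(Hgs, 1).sum() + same.sum())
    cov_ng = float(ng - nu * g)
    return var_n, cov_ng, var_g
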