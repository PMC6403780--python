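"""Brute-force enumeration references for small chains.

These exhaustive sums exist to validate the transfer-matrix engine, the
distance-moment contraction and the effective-parameter solver; they are
test support and never enter any solver path.  Iteration order over
states is lexicographic for reproducible debugging output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .electrostatics import dh_pair
from .model_core import (
    ChainSpec,
    EnergyParams,
    RotoMicrostate,
    SolutionConditions,
    reduced_free_energy,
)

__all__ = ["ExactEnsemble", "enumerate_rigid", "enumerate_sbris"]

MAX_RIGID_SITES = 16
MAX_SBRIS_SITES = 5


@dataclass
class ExactEnsemble:
    """All states of a small chain with exact ensemble averages."""

    states: list
    weights: np.ndarray
    log_partition: float
    theta: np.ndarray
    h: np.ndarray  # <s_i s_j>, full symmetric matrix
    nu: float
    D: float  # mean adjacent-protonated-pair count
    g: float = 0.0
    p_gauche: np.ndarray = field(default_factory=lambda: np.empty(0))
    msd: np.ndarray | None = None  # <d_ij^2>, unconditional
    msd_conditioned: np.ndarray | None = None  # <d_ij^2 | s_i = s_j = 1>

    @property
    def omega(self) -> float:
        """Semi-grand canonical potential Omega = -ln Xi."""
        return -self.log_partition


def _finalize_site_sums(states_s, weights):
    weights = np.asarray(weights, dtype=float)
    Z = weights.sum()
    if Z <= 0:
        raise FloatingPointError("partition function vanished in enumeration")
    S = np.asarray(states_s, dtype=float)  # (n_states, n_sites)
    theta = (weights @ S) / Z
    h = (S.T * weights) @ S / Z
    D = float(np.sum(weights @ (S[:, :-1] * S[:, 1:])) / Z) if S.shape[1] > 1 else 0.0
    return Z, theta, h, D


def enumerate_rigid(
    n_sites: int,
    params: EnergyParams,
    cond: SolutionConditions,
    include_lr: bool = True,
) -> ExactEnsemble:
    """Exact sums over all 2^N ionization states of the rigid chain.

    The Hamiltonian has per-site reduced chemical potential pH - pK,
    nearest-neighbour energy epsilon, and (when ``include_lr``) the
    Debye-Huckel interaction over collinear sites d_ij = |j - i| * b.
    """
    if n_sites > MAX_RIGID_SITES:
        raise ValueError(f"enumeration limited to {MAX_RIGID_SITES} sites")
    b = 0.2  # default site separation; overridden by callers via ChainSpec
    return enumerate_rigid_chain(
        ChainSpec(n_sites, spacing=1, bond_length=b), params, cond, include_lr
    )


def enumerate_rigid_chain(
    chain: ChainSpec,
    params: EnergyParams,
    cond: SolutionConditions,
    include_lr: bool = True,
) -> ExactEnsemble:
    """As :func:`enumerate_rigid`, with the site separation from ``chain``."""
    n_sites = chain.n_sites
    if n_sites > MAX_RIGID_SITES:
        raise ValueError(f"enumeration limited to {MAX_RIGID_SITES} sites")
    mu = cond.pH - params.pK
    b = chain.bond_length
    pot = cond.potential
    # precompute pair energies
    phi = np.zeros((n_sites, n_sites))
    if include_lr and cond.lr_enabled:
        for i in range(n_sites):
            for j in range(i + 2, n_sites):
                phi[i, j] = dh_pair((j - i) * b, pot)
    # vectorized sweep over all 2^N bit patterns (lexicographic order)
    codes = np.arange(2**n_sites, dtype=np.int64)
    S = (codes[:, None] >> np.arange(n_sites - 1, -1, -1)[None, :]) & 1
    S = S.astype(float)
    F = mu * S.sum(axis=1) + params.epsilon * (S[:, :-1] * S[:, 1:]).sum(axis=1)
    F = F + np.einsum("wi,ij,wj->w", S, phi, S)
    # shift energies so the weights neither overflow nor all underflow
    f_shift = float(F[np.isfinite(F)].min())
    weights = np.where(np.isinf(F), 0.0, 10.0 ** (-(F - f_shift)))
    states = list(S.astype(np.int8))
    Z, theta, h, D = _finalize_site_sums(states, weights)
    return ExactEnsemble(
        states=states,
        weights=np.asarray(weights),
        log_partition=float(np.log(Z) - f_shift * np.log(10.0)),
        theta=theta,
        h=h,
        nu=float(theta.sum()),
        D=D,
    )


def enumerate_sbris(
    chain: ChainSpec,
    params: EnergyParams,
    cond: SolutionConditions,
    include_lr: bool = True,
) -> ExactEnsemble:
    """Exact sums over all 2^N * 3^(N-1) roto-microstates.

    Uses the full reduced free energy (conformational, protonation and,
    when flagged, long-range terms) and explicit 3-D site coordinates,
    and also supplies the exact squared-distance averages (unconditional
    and protonation-conditioned) used by the geometry tests.
    """
    from .geometry_moments import site_positions

    N = chain.n_sites
    if N > MAX_SBRIS_SITES:
        raise ValueError(f"enumeration limited to {MAX_SBRIS_SITES} sites")
    M = chain.n_rotatable
    if not cond.lr_enabled:
        include_lr = False
    eff_cond = SolutionConditions(
        pH=cond.pH,
        ionic_strength=cond.ionic_strength,
        bjerrum_length=cond.bjerrum_length,
        lr_enabled=include_lr,
    )

    # cache geometry per conformation
    conf_list = list(itertools.product((0, 1, 2), repeat=M))
    d2_by_conf = {}
    for c in conf_list:
        pos = site_positions(np.array(c), chain)[chain.site_nodes]
        diff = pos[:, None, :] - pos[None, :, :]
        d2_by_conf[c] = (diff**2).sum(axis=-1)

    states, weights = [], []
    svecs, gauche_counts, pg_rows, d2_rows = [], [], [], []
    for s in itertools.product((0, 1), repeat=N):
        for c in conf_list:
            state = RotoMicrostate(np.array(s), np.array(c))
            F = reduced_free_energy(state, chain, params, eff_cond)
            w = 0.0 if np.isinf(F) else 10.0 ** (-F)
            states.append(state)
            weights.append(w)
            svecs.append(s)
            carr = np.array(c)
            gauche_counts.append(int(np.count_nonzero(carr)))
            pg_rows.append((carr > 0).astype(float))
            d2_rows.append(d2_by_conf[c])
    weights_arr = np.asarray(weights)
    Z, theta, h, D = _finalize_site_sums(svecs, weights_arr)
    gauche = np.asarray(gauche_counts, dtype=float)
    g = float((weights_arr * gauche).sum() / Z)
    p_gauche = (weights_arr @ np.asarray(pg_rows)) / Z if M else np.empty(0)

    d2_stack = np.asarray(d2_rows)  # (n_states, N, N)
    msd = np.einsum("w,wij->ij", weights_arr, d2_stack) / Z
    S = np.asarray(svecs, dtype=float)
    ss = np.einsum("wi,wj->wij", S, S)
    num = np.einsum("w,wij,wij->ij", weights_arr, ss, d2_stack)
    den = np.einsum("w,wij->ij", weights_arr, ss)
    with np.errstate(invalid="ignore", divide="ignore"):
        msd_cond = num / den
    return ExactEnsemble(
        states=states,
        weights=weights_arr,
        log_partition=float(np.log(Z)),
        theta=theta,
        h=h,
        nu=float(theta.sum()),
        D=D,
        g=g,
        p_gauche=np.asarray(p_gauche),
        msd=msd,
        msd_conditioned=msd_cond,
    )
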