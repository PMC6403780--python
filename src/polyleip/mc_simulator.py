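"""Semi-grand canonical (constant-pH) Metropolis Monte Carlo.

The validation standard for the effective-parameter method: explicit 3-D
chain geometry, exact short-range energies and the full Debye-Huckel
long-range sum.  Trial moves are single-bond rotations (probability
``p_bond_move``, default 0.999) or single-site protonation toggles
(``p_site_move``, default 0.001); a bond move rotates all downstream
nodes rigidly about the bond axis and re-sums only the cross-pair
long-range terms, a site toggle re-sums only the pairs involving that
site.  Acceptance follows Metropolis on the reduced free energy
difference: always accepted when dF < 0, else with probability
10**(-dF) (the decimal-log analogue of exp(-beta dF)).

Energies inside the kernels are clamped at 1e3 decimal-log units:
10**(-1000) underflows to exactly zero, so forbidden moves (u_g = 0 with
both flanking sites protonated) are always rejected without special
cases.  All kernels are numba-compiled; ``delta_energy`` and ``mc_step``
are thin wrappers over the same jitted helpers used by the production
run loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .electrostatics import ConfigurationError
from .model_core import ChainSpec, EnergyParams, RotoMicrostate, SolutionConditions
from .geometry_moments import site_positions

__all__ = ["McConfig", "McEstimate", "delta_energy", "mc_step", "run_titration"]

_ECLAMP = 1.0e3  # decimal-log clamp standing in for +inf inside kernels


@dataclass(frozen=True)
class McConfig:
    """Run protocol; the defaults are the full-scale study conditions
    (5e7 equilibration + 4.5e8 production configurations, bond/site trial
    probabilities 0.999/0.001, eight replicas).  Scaled-down runs pass
    smaller step counts explicitly."""

    steps_equilibration: int = 50_000_000
    steps_production: int = 450_000_000
    p_bond_move: float = 0.999
    p_site_move: float = 0.001
    n_replicas: int = 8
    seed: int = 0
    sampling_stride: int = 100

    def __post_init__(self) -> None:
        if abs(self.p_bond_move + self.p_site_move - 1.0) > 1e-12:
            raise ConfigurationError("p_bond_move + p_site_move must equal 1")
        if min(self.steps_equilibration, self.steps_production) < 0:
            raise ConfigurationError("step counts must be non-negative")
        if self.steps_production <= 0:
            raise ConfigurationError("steps_production must be positive")
        if self.n_replicas < 1 or self.sampling_stride < 1:
            raise ConfigurationError("n_replicas and sampling_stride must be >= 1")


@dataclass
class McEstimate:
    """Cross-replica mean and standard error of one observable."""

    mean: float
    stderr: float
    per_replica: np.ndarray = field(default_factory=lambda: np.empty(0))


def _energy_pack(params: EnergyParams, cond: SolutionConditions):
    return (
        cond.pH,
        params.pK,
        min(params.p_sigma, _ECLAMP),
        min(params.p_psi, _ECLAMP),
        min(params.p_omega, _ECLAMP),
        min(params.eps_t, _ECLAMP),
        min(params.eps_g, _ECLAMP),
        cond.bjerrum_length,
        cond.kappa,
        bool(cond.lr_enabled),
    )


# ---------------------------------------------------------------------------
# jitted geometry and energy helpers
# ---------------------------------------------------------------------------

@njit(cache=False)
def _dh(d, lB, kappa):
    return (lB / d) * np.exp(-kappa * d) / np.log(10.0)


@njit(cache=False)
def _rotated_positions(coords, i0, i1, dphi, start):
    """Positions of nodes >= start after rotating about bond (i0, i1)."""
    axis = coords[i1] - coords[i0]
    axis = axis / np.sqrt((axis**2).sum())
    cphi = np.cos(dphi)
    sphi = np.sin(dphi)
    out = np.empty((coords.shape[0] - start, 3))
    pivot = coords[i1]
    for k in range(start, coords.shape[0]):
        v = coords[k] - pivot
        cr0 = axis[1] * v[2] - axis[2] * v[1]
        cr1 = axis[2] * v[0] - axis[0] * v[2]
        cr2 = axis[0] * v[1] - axis[1] * v[0]
        dot = axis[0] * v[0] + axis[1] * v[1] + axis[2] * v[2]
        out[k - start, 0] = pivot[0] + v[0] * cphi + cr0 * sphi + axis[0] * dot * (1 - cphi)
        out[k - start, 1] = pivot[1] + v[1] * cphi + cr1 * sphi + axis[1] * dot * (1 - cphi)
        out[k - start, 2] = pivot[2] + v[2] * cphi + cr2 * sphi + axis[2] * dot * (1 - cphi)
    return out


@njit(cache=False)
def _pair_conf_energy(a, b, p_psi, p_omega):
    """Consecutive rotatable-bond coupling (0 unless both gauche)."""
    if a == 0 or b == 0:
        return 0.0
    return p_psi if a == b else p_omega


@njit(cache=False)
def _delta_site_toggle(
    i, s, c, coords, site_nodes, pH, pK, eps_t, eps_g, lB, kappa, lr_on
):
    dn = 1 - 2 * s[i]  # +1 protonate, -1 deprotonate
    dF = (pH - pK) * dn
    n_sites = len(s)
    # SR with adjacent sites through the connecting rotatable bond
    if i > 0 and s[i - 1] == 1:
        dF += dn * (eps_t if c[i - 1] == 0 else eps_g)
    if i < n_sites - 1 and s[i + 1] == 1:
        dF += dn * (eps_t if c[i] == 0 else eps_g)
    if lr_on:
        ri = coords[site_nodes[i]]
        for j in range(n_sites):
            if abs(j - i) >= 2 and s[j] == 1:
                rj = coords[site_nodes[j]]
                d = np.sqrt(
                    (ri[0] - rj[0]) ** 2 + (ri[1] - rj[1]) ** 2 + (ri[2] - rj[2]) ** 2
                )
                dF += dn * _dh(d, lB, kappa)
    return dF


@njit(cache=False)
def _delta_bond_rotation(
    alpha,
    new_state,
    s,
    c,
    coords,
    site_nodes,
    rot_bonds,
    dihedrals,
    p_sigma,
    p_psi,
    p_omega,
    eps_t,
    eps_g,
    lB,
    kappa,
    lr_on,
):
    """Energy difference of rotating bond alpha to new_state, plus the
    rotated downstream node coordinates (applied only on acceptance)."""
    old = c[alpha]
    dF = p_sigma * ((1 if new_state > 0 else 0) - (1 if old > 0 else 0))
    if alpha > 0:
        dF += _pair_conf_energy(c[alpha - 1], new_state, p_psi, p_omega)
        dF -= _pair_conf_energy(c[alpha - 1], old, p_psi, p_omega)
    if alpha < len(c) - 1:
        dF += _pair_conf_energy(new_state, c[alpha + 1], p_psi, p_omega)
        dF -= _pair_conf_energy(old, c[alpha + 1], p_psi, p_omega)
    if s[alpha] == 1 and s[alpha + 1] == 1:
        dF += (eps_t if new_state == 0 else eps_g) - (eps_t if old == 0 else eps_g)

    bond = rot_bonds[alpha]
    dphi = dihedrals[new_state] - dihedrals[old]
    start = bond + 2  # nodes strictly downstream of the bond's far node
    moved = _rotated_positions(coords, bond, bond + 1, dphi, start)
    if lr_on:
        n_sites = len(s)
        for i in range(alpha + 1):
            if s[i] == 0:
                continue
            ri = coords[site_nodes[i]]
            for j in range(alpha + 1, n_sites):
                if s[j] == 0 or j - i < 2:
                    continue
                nj = site_nodes[j]
                rj_old = coords[nj]
                rj_new = moved[nj - start]
                d_old = np.sqrt(
                    (ri[0] - rj_old[0]) ** 2
                    + (ri[1] - rj_old[1]) ** 2
                    + (ri[2] - rj_old[2]) ** 2
                )
                d_new = np.sqrt(
                    (ri[0] - rj_new[0]) ** 2
                    + (ri[1] - rj_new[1]) ** 2
                    + (ri[2] - rj_new[2]) ** 2
                )
                dF += _dh(d_new, lB, kappa) - _dh(d_old, lB, kappa)
    return dF, moved, start


@njit(cache=False)
def _mc_kernel(
    n_steps,
    s,
    c,
    coords,
    site_nodes,
    rot_bonds,
    dihedrals,
    p_bond,
    pH,
    pK,
    p_sigma,
    p_psi,
    p_omega,
    eps_t,
    eps_g,
    lB,
    kappa,
    lr_on,
    stride,
    seed,
    collect,
):
    """Metropolis loop; mutates (s, c, coords) in place.

    Returns (theta_sum, gauche_sum, n_samples, accepted bond, tried bond,
    accepted site, tried site); sums are of per-sample mean protonation /
    gauche fraction taken every ``stride`` steps when ``collect``."""
    np.random.seed(seed)
    n_sites = len(s)
    n_rot = len(c)
    th_sum = 0.0
    g_sum = 0.0
    n_samp = 0
    acc_b = 0
    try_b = 0
    acc_s = 0
    try_s = 0
    for step in range(n_steps):
        if n_rot > 0 and np.random.random() < p_bond:
            try_b += 1
            alpha = np.random.randint(n_rot)
            new_state = (c[alpha] + 1 + np.random.randint(2)) % 3
            dF, moved, start = _delta_bond_rotation(
                alpha, new_state, s, c, coords, site_nodes, rot_bonds, dihedrals,
                p_sigma, p_psi, p_omega, eps_t, eps_g, lB, kappa, lr_on,
            )
            if dF <= 0.0 or np.random.random() < 10.0 ** (-dF):
                c[alpha] = new_state
                coords[start:] = moved
                acc_b += 1
        else:
            try_s += 1
            i = np.random.randint(n_sites)
            dF = _delta_site_toggle(
                i, s, c, coords, site_nodes, pH, pK, eps_t, eps_g, lB, kappa, lr_on
            )
            if dF <= 0.0 or np.random.random() < 10.0 ** (-dF):
                s[i] = 1 - s[i]
                acc_s += 1
        if collect and (step + 1) % stride == 0:
            n_samp += 1
            ssum = 0
            for i in range(n_sites):
                ssum += s[i]
            th_sum += ssum / n_sites
            if n_rot > 0:
                gsum = 0
                for a in range(n_rot):
                    if c[a] > 0:
                        gsum += 1
                g_sum += gsum / n_rot
    return th_sum, g_sum, n_samp, acc_b, try_b, acc_s, try_s


# ---------------------------------------------------------------------------
# python-facing API
# ---------------------------------------------------------------------------

_DIHEDRALS = np.array([np.pi, np.pi / 3.0, -np.pi / 3.0])


def delta_energy(
    state: RotoMicrostate,
    move: tuple,
    chain: ChainSpec,
    params: EnergyParams,
    cond: SolutionConditions,
    coords: np.ndarray | None = None,
):
    """Incremental reduced-free-energy change of one trial move.

    ``move`` is ``("site", i)`` or ``("bond", alpha, new_state)``.
    Equals F(new) - F(old) of the full energy; bond moves re-sum only
    cross-pair long-range terms, site toggles only that site's pairs.
    """
    state.validate(chain)
    if coords is None:
        coords = site_positions(state.c, chain)
    pack = _energy_pack(params, cond)
    pH, pK, p_sigma, p_psi, p_omega, eps_t, eps_g, lB, kappa, lr_on = pack
    s = np.ascontiguousarray(state.s)
    c = np.ascontiguousarray(state.c)
    site_nodes = chain.site_nodes
    if move[0] == "site":
        i = move[1]
        if not 0 <= i < chain.n_sites:
            raise IndexError("site index out of range")
        return float(
            _delta_site_toggle(
                i, s, c, coords, site_nodes, pH, pK, eps_t, eps_g, lB, kappa, lr_on
            )
        )
    if move[0] == "bond":
        alpha, new_state = move[1], move[2]
        if not 0 <= alpha < chain.n_rotatable:
            raise IndexError("bond index out of range")
        dF, _, _ = _delta_bond_rotation(
            alpha, new_state, s, c, coords, site_nodes, chain.rotatable_bonds,
            _DIHEDRALS, p_sigma, p_psi, p_omega, eps_t, eps_g, lB, kappa, lr_on,
        )
        return float(dF)
    raise ValueError(f"unknown move type {move[0]!r}")


def mc_step(
    state: RotoMicrostate,
    chain: ChainSpec,
    params: EnergyParams,
    cond: SolutionConditions,
    mc: McConfig,
    rng: np.random.Generator,
    coords: np.ndarray | None = None,
):
    """One Metropolis step; returns (state, coords, accepted).

    Mutates ``state`` (and ``coords`` when a bond move is accepted).
    Move type is chosen with (p_bond_move, p_site_move); within a type
    the target is uniform and a proposed bond state is uniform over the
    other two.
    """
    if coords is None:
        coords = site_positions(state.c, chain)
    if chain.n_rotatable > 0 and rng.random() < mc.p_bond_move:
        alpha = int(rng.integers(chain.n_rotatable))
        new_state = int((state.c[alpha] + 1 + rng.integers(2)) % 3)
        move = ("bond", alpha, new_state)
    else:
        move = ("site", int(rng.integers(chain.n_sites)))
    dF = delta_energy(state, move, chain, params, cond, coords=coords)
    accepted = dF <= 0.0 or rng.random() < 10.0 ** (-dF)
    if accepted:
        if move[0] == "site":
            state.s[move[1]] = 1 - state.s[move[1]]
        else:
            alpha, new_state = move[1], move[2]
            bond = int(chain.rotatable_bonds[alpha])
            dphi = _DIHEDRALS[new_state] - _DIHEDRALS[state.c[alpha]]
            start = bond + 2
            coords[start:] = _rotated_positions(coords, bond, bond + 1, dphi, start)
            state.c[alpha] = new_state
    return state, coords, accepted


def run_point(
    chain: ChainSpec,
    params: EnergyParams,
    cond: SolutionConditions,
    mc: McConfig,
):
    """MC estimates of theta and the gauche fraction at one (pH, I).

    Each replica starts all-trans and fully deprotonated, equilibrates,
    then samples every ``sampling_stride`` steps; the estimate is the
    cross-replica mean with its standard error.  Replica seeds are
    ``seed + replica`` (counter style), so identical configurations give
    bit-identical trajectories.
    """
    pack = _energy_pack(params, cond)
    pH, pK, p_sigma, p_psi, p_omega, eps_t, eps_g, lB, kappa, lr_on = pack
    th_rep = np.empty(mc.n_replicas)
    pg_rep = np.empty(mc.n_replicas)
    diags = []
    for rep in range(mc.n_replicas):
        seed = int((mc.seed + rep) % (2**31 - 1))
        s = np.zeros(chain.n_sites, dtype=np.int8)
        c = np.zeros(max(chain.n_rotatable, 0), dtype=np.int8)
        coords = np.ascontiguousarray(site_positions(c, chain))
        if mc.steps_equilibration > 0:
            _mc_kernel(
                mc.steps_equilibration, s, c, coords, chain.site_nodes,
                chain.rotatable_bonds, _DIHEDRALS, mc.p_bond_move,
                pH, pK, p_sigma, p_psi, p_omega, eps_t, eps_g, lB, kappa, lr_on,
                mc.sampling_stride, seed, False,
            )
        th, g, n_samp, acc_b, try_b, acc_s, try_s = _mc_kernel(
            mc.steps_production, s, c, coords, chain.site_nodes,
            chain.rotatable_bonds, _DIHEDRALS, mc.p_bond_move,
            pH, pK, p_sigma, p_psi, p_omega, eps_t, eps_g, lB, kappa, lr_on,
            mc.sampling_stride, seed + 7919, True,
        )
        th_rep[rep] = th / max(n_samp, 1)
        pg_rep[rep] = g / max(n_samp, 1)
        diags.append(
            {
                "replica": rep,
                "seed": seed,
                "samples": n_samp,
                "acc_bond": acc_b / max(try_b, 1),
                "acc_site": acc_s / max(try_s, 1),
            }
        )
    def est(vals):
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        return McEstimate(mean=mean, stderr=se, per_replica=vals.copy())

    return est(th_rep), est(pg_rep), diags


def run_titration(
    chain: ChainSpec,
    params: EnergyParams,
    conditions,
    mc: McConfig,
) -> pd.DataFrame:
    """MC titration over a grid of conditions.

    ``conditions`` is an iterable of :class:`SolutionConditions` (or of
    (pH, ionic_strength) tuples, taken with default Bjerrum length and
    LR enabled).  Returns a DataFrame with theta / p_gauche means and
    cross-replica standard errors per point.
    """
    rows = []
    for item in conditions:
        cond = (
            item
            if isinstance(item, SolutionConditions)
            else SolutionConditions(pH=item[0], ionic_strength=item[1])
        )
        th, pg, diags = run_point(chain, params, cond, mc)
        rows.append(
            {
                "pH": cond.pH,
                "ionic_strength": cond.ionic_strength,
                "theta": th.mean,
                "theta_stderr": th.stderr,
                "p_gauche": pg.mean,
                "p_gauche_stderr": pg.stderr,
                "n_replicas": mc.n_replicas,
                "steps_production": mc.steps_production,
                "acc_bond": float(np.mean([d["acc_bond"] for d in diags])),
                "acc_site": float(np.mean([d["acc_site"] for d in diags])),
            }
        )
    return pd.DataFrame(rows)
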