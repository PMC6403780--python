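"""Variational effective short-range parameters (the LEIP method).

Long-range Debye-Huckel interactions are folded into pH- and ionic-
strength-dependent corrections of the short-range model: the site pK is
shifted (pK_eff = pK - x) together with, optionally, the nearest-
neighbour energy (eps -> eps + x_eps, rigid chains) or the gauche bond
energy (p_sigma -> p_sigma + x_sigma, flexible chains).  The shifts
minimize the Gibbs-Bogoliubov upper bound

    Omega <= Omega~ = Omega_0(shifts) + <Delta H>_0,
    <Delta H>_0 / ln 10 = phi_0 - x nu_0 - x_sigma g_0  (or - x_eps D_0),

where phi_0 is the long-range energy averaged over the unperturbed
(short-range) ensemble: exactly sum phi(|j-i| b) <s_i s_j>_0 for the
rigid chain, and approximately sum phi(sqrt(<d_ij^2>_0)) <s_i s_j>_0 for
the flexible one.  Stationarity of Omega~ yields the 2x2 system

    J (x, x_sigma)^T = (d phi_0/dx, d phi_0/dx_sigma)^T,
    J = [[d nu_0/dx, d g_0/dx], [d nu_0/dx_sigma, d g_0/dx_sigma]],

equivalently x = (d phi_0/d nu_0)|_g0 and x_sigma = (d phi_0/d g_0)|_nu0.
The solver is a damped Newton iteration with the Jacobian entries from
exact fluctuation formulas (projector-based pair correlations) and the
phi_0 partials from central finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .electrostatics import LN10, ScreenedPotential, dh_pair
from .model_core import ChainSpec, EnergyParams, SolutionConditions
from . import transfer_matrix as tm
from .geometry_moments import msd_matrix

__all__ = [
    "LeipCorrections",
    "phi0",
    "solve_rigid",
    "solve_flexible",
    "gb_bound",
    "titrate",
    "TITRATION_COLUMNS",
]

#: finite-difference step (decimal-log units) for the phi_0 partials
FD_STEP = 1e-4
DEFAULT_TOL = 1e-7
MAX_ITER = 80

TITRATION_COLUMNS = [
    "pH",
    "ionic_strength",
    "theta",
    "p_gauche",
    "x",
    "x_sigma",
    "x_eps",
    "omega0",
    "omega_bound",
    "converged",
    "iterations",
    "residual",
]


@dataclass
class LeipCorrections:
    """Effective-parameter shifts with convergence diagnostics.

    ``x`` shifts the protonation constant (pK_eff = pK - x); ``x_eps``
    the rigid nearest-neighbour energy; ``x_sigma`` the gauche energy
    (p_sigma_eff = p_sigma + x_sigma).  All are zero when long-range
    interactions are disabled.
    """

    x: float = 0.0
    x_eps: float = 0.0
    x_sigma: float = 0.0
    converged: bool = True
    iterations: int = 0
    residual: float = 0.0


# ---------------------------------------------------------------------------
# phi_0: the LR energy averaged over the unperturbed ensemble
# ---------------------------------------------------------------------------

def _rigid_distance_matrix(chain: ChainSpec) -> np.ndarray:
    idx = np.arange(chain.n_sites)
    return np.abs(idx[:, None] - idx[None, :]) * chain.bond_length


def _phi0_rigid(
    x: float,
    x_eps: float,
    chain: ChainSpec,
    params: EnergyParams,
    cond: SolutionConditions,
    distances: np.ndarray | None = None,
) -> float:
    N = chain.n_sites
    if N < 3:
        return 0.0
    z = 10.0 ** ((params.pK - x) - cond.pH)
    u = 10.0 ** (-(params.epsilon + x_eps))
    H = tm.sb_pair_matrix(N, z, u)
    d = distances if distances is not None else _rigid_distance_matrix(chain)
    iu, ju = np.triu_indices(N, k=2)
    return float(np.sum(dh_pair(d[iu, ju], cond.potential) * H[iu, ju]))


def _phi0_flexible(
    x: float,
    x_sigma: float,
    chain: ChainSpec,
    params: EnergyParams,
    cond: SolutionConditions,
) -> float:
    N = chain.n_sites
    if N < 3:
        return 0.0
    eng = tm.sbris_engine(chain, params, cond.pH, x, x_sigma)
    H = tm.sbris_pair_matrix(eng)
    M = msd_matrix(chain, params, cond.pH, x, x_sigma, eng=eng)
    iu, ju = np.triu_indices(N, k=2)
    dbar = np.sqrt(M[iu, ju])
    return float(np.sum(dh_pair(dbar, cond.potential) * H[iu, ju]))


def phi0(
    shifts: LeipCorrections,
    chain: ChainSpec,
    params: EnergyParams,
    cond: SolutionConditions,
    mode: str = "flexible",
    distances: np.ndarray | None = None,
) -> float:
    """LR interaction energy phi_0 averaged over the shifted SR ensemble.

    Rigid mode sums phi(|j-i| b) <s_i s_j>_0 over site pairs separated by
    at least two sites; flexible mode uses phi(sqrt(<d_ij^2>_0)).
    Non-negative; zero when the chain is uncharged or has fewer than
    three sites.
    """
    if not cond.lr_enabled:
        return 0.0
    if mode == "rigid":
        return _phi0_rigid(shifts.x, shifts.x_eps, chain, params, cond, distances)
    if mode == "flexible":
        return _phi0_flexible(shifts.x, shifts.x_sigma, chain, params, cond)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# solver internals
# ---------------------------------------------------------------------------

def _rigid_state(x, x_eps, chain, params, cond):
    z = 10.0 ** ((params.pK - x) - cond.pH)
    u = 10.0 ** (-(params.epsilon + x_eps))
    obs = tm.sb_observables(chain.n_sites, z, u)
    var_n, cov, var_2 = tm.sb_fluctuations(chain.n_sites, z, u)
    return obs.nu, obs.D, var_n, cov, var_2, obs


def _flexible_state(x, x_sigma, chain, params, cond):
    eng = tm.sbris_engine(chain, params, cond.pH, x, x_sigma)
    theta = eng.diag_profile(tm.ION6)
    nu = float(theta.sum())
    pg = eng.diag_profile(tm.GAUCHE6)
    pg[0] = 0.0
    g = float(pg.sum())
    var_n, cov, var_2 = tm.sbris_fluctuations(eng)
    return nu, g, var_n, cov, var_2, eng


def _solve_shifts(
    phi_fn,
    state_fn,
    active2: bool,
    v0: np.ndarray,
    tol: float,
    max_iter: int,
):
    """Damped Newton for the stationarity system of Omega~.

    ``phi_fn(v)`` evaluates phi_0 at shifts v = (x, x2); ``state_fn(v)``
    returns (nu0, q0, var_n, cov, var_q) with q the second corrected
    observable (D for rigid, g for flexible).  Returns (v, iterations,
    residual, converged).
    """
    v = np.asarray(v0, dtype=float).copy()
    h = FD_STEP

    def gradient(v):
        nu0, q0, var_n, cov, var_q = state_fn(v)[:5]
        A = -LN10 * np.array([[var_n, cov], [cov, var_q]])
        dphi = np.empty(2)
        dphi[0] = (phi_fn(v + [h, 0.0]) - phi_fn(v - [h, 0.0])) / (2 * h)
        if active2:
            dphi[1] = (phi_fn(v + [0.0, h]) - phi_fn(v - [0.0, h])) / (2 * h)
        else:
            dphi[1] = 0.0
        grad = dphi - A @ v
        return grad, A

    scale = max(1.0, abs(phi_fn(v)))
    tol_eff = tol * scale
    grad, A = gradient(v)
    it = 0
    res = float(np.abs(grad[: 2 if active2 else 1]).max())
    while res > tol_eff and it < max_iter:
        it += 1
        # grad(v) = dphi - A v with d(grad)/dv ~= -A, so the Newton update
        # solves A step = grad.
        if active2:
            try:
                step = np.linalg.solve(A, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(A, grad, rcond=None)[0]
        else:
            a = A[0, 0]
            step = np.array([grad[0] / a if abs(a) > 1e-300 else 0.0, 0.0])
        nrm = float(np.abs(step).max())
        if nrm > 2.0:  # cap wild steps (log-unit shifts are O(1))
            step *= 2.0 / nrm
        lam = 1.0
        improved = False
        while lam > 1e-6:
            v_try = v + lam * step
            grad_try, A_try = gradient(v_try)
            res_try = float(np.abs(grad_try[: 2 if active2 else 1]).max())
            if res_try < res or res_try <= tol_eff:
                v, grad, A, res = v_try, grad_try, A_try, res_try
                improved = True
                break
            lam *= 0.5
        if not improved:
            break  # stalled at the FD noise floor
    if res > 10 * tol_eff:
        # Newton can stall on cold starts deep in saturation (Var(n) ~ 0);
        # fall back to bracketed bisection on the x-component, then retry.
        def g1(x1):
            return gradient(np.array([x1, v[1]]))[0][0]

        lo, hi = v[0] - 0.5, v[0] + 0.5
        glo, ghi = g1(lo), g1(hi)
        for _ in range(8):
            if glo * ghi <= 0:
                break
            lo, hi = lo - (hi - lo), hi + (hi - lo)
            glo, ghi = g1(lo), g1(hi)
        if glo * ghi <= 0:
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                gm = g1(mid)
                it += 1
                if glo * gm <= 0:
                    hi, ghi = mid, gm
                else:
                    lo, glo = mid, gm
            v = np.array([0.5 * (lo + hi), v[1]])
            grad, A = gradient(v)
            res = float(np.abs(grad[: 2 if active2 else 1]).max())
            if active2 and res > tol_eff:
                # polish the 2x2 system from the improved point
                for _ in range(20):
                    it += 1
                    try:
                        step = np.linalg.solve(A, grad)
                    except np.linalg.LinAlgError:
                        break
                    v = v + step
                    grad, A = gradient(v)
                    res_new = float(np.abs(grad[:2]).max())
                    if res_new >= res:
                        break
                    res = res_new
                    if res <= tol_eff:
                        break
    return v, it, res, bool(res <= max(tol_eff, 10 * tol * scale))


def solve_rigid(
    chain: ChainSpec,
    params: EnergyParams,
    cond: SolutionConditions,
    correct_eps: bool = False,
    x0: LeipCorrections | None = None,
    distances: np.ndarray | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = MAX_ITER,
) -> LeipCorrections:
    """Solve for x (and x_eps) of the rigid chain.

    ``distances`` optionally overrides the collinear site separations
    |j - i| * b (used e.g. to match a frozen flexible geometry).
    """
    if not cond.lr_enabled:
        return LeipCorrections()

    def phi_fn(v):
        return _phi0_rigid(v[0], v[1], chain, params, cond, distances)

    def state_fn(v):
        return _rigid_state(v[0], v[1], chain, params, cond)[:5]

    v0 = np.array([x0.x if x0 else 0.0, x0.x_eps if (x0 and correct_eps) else 0.0])
    v, it, res, ok = _solve_shifts(phi_fn, state_fn, correct_eps, v0, tol, max_iter)
    return LeipCorrections(
        x=float(v[0]), x_eps=float(v[1]), converged=ok, iterations=it, residual=res
    )


def solve_flexible(
    chain: ChainSpec,
    params: EnergyParams,
    cond: SolutionConditions,
    correct_sigma: bool = True,
    x0: LeipCorrections | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = MAX_ITER,
) -> LeipCorrections:
    """Solve for (x, x_sigma) of the minimal flexible chain.

    With ``correct_sigma=False`` the gauche-energy shift is pinned to
    zero and only the pK correction is solved (this reproduces the
    spurious transition artifact at low ionic strength).
    """
    if not cond.lr_enabled:
        return LeipCorrections()

    def phi_fn(v):
        return _phi0_flexible(v[0], v[1], chain, params, cond)

    def state_fn(v):
        return _flexible_state(v[0], v[1], chain, params, cond)[:5]

    v0 = np.array([x0.x if x0 else 0.0, x0.x_sigma if (x0 and correct_sigma) else 0.0])
    v, it, res, ok = _solve_shifts(phi_fn, state_fn, correct_sigma, v0, tol, max_iter)
    return LeipCorrections(
        x=float(v[0]), x_sigma=float(v[1]), converged=ok, iterations=it, residual=res
    )


# ---------------------------------------------------------------------------
# Gibbs-Bogoliubov bound
# ---------------------------------------------------------------------------

def gb_bound(
    shifts: LeipCorrections,
    chain: ChainSpec,
    params: EnergyParams,
    cond: SolutionConditions,
    mode: str = "flexible",
    distances: np.ndarray | None = None,
) -> float:
    """Variational upper bound Omega~ (natural-log units) at any shifts.

    Omega~ = Omega_0 + ln10 (phi_0 - x nu_0 - x_sigma g_0) (flexible) or
    Omega_0 + ln10 (phi_0 - x nu_0 - x_eps D_0) (rigid).  With long-range
    interactions disabled and zero shifts this reduces to the exact
    Omega_0.  In rigid mode (exact phi_0) the bound Omega~ >= Omega holds
    for every shift value; at the solver's optimum it is stationary.
    """
    if mode == "rigid":
        nu0, D0, *_rest, obs = _rigid_state(shifts.x, shifts.x_eps, chain, params, cond)
        omega0 = -obs.log_partition
        ph = phi0(shifts, chain, params, cond, "rigid", distances) if cond.lr_enabled else 0.0
        return float(omega0 + LN10 * (ph - shifts.x * nu0 - shifts.x_eps * D0))
    if mode == "flexible":
        nu0, g0, *_rest, eng = _flexible_state(
            shifts.x, shifts.x_sigma, chain, params, cond
        )
        omega0 = -eng.log_partition
        ph = phi0(shifts, chain, params, cond, "flexible") if cond.lr_enabled else 0.0
        return float(omega0 + LN10 * (ph - shifts.x * nu0 - shifts.x_sigma * g0))
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# titration curves
# ---------------------------------------------------------------------------

def titrate(
    chain: ChainSpec,
    params: EnergyParams,
    pH_values,
    ionic_strengths,
    mode: str = "flexible",
    correct_sigma: bool = True,
    correct_eps: bool = False,
    bjerrum_length: float = 0.7,
    lr_enabled: bool = True,
    tol: float = DEFAULT_TOL,
) -> pd.DataFrame:
    """Titration and conformer curves under the corrected SR model.

    The corrections are solved per pH point by continuation: each ionic
    strength is swept from the highest pH (where the shifts vanish)
    downward, warm-starting from the previous solution, which keeps the
    solver on one branch across sharp transitions.  Returns a DataFrame
    with columns :data:`TITRATION_COLUMNS`, sorted by (ionic strength,
    ascending pH).
    """
    pH_values = np.sort(np.asarray(pH_values, dtype=float))
    if np.isscalar(ionic_strengths):
        ionic_strengths = [float(ionic_strengths)]
    rows = []
    N = chain.n_sites
    for I in ionic_strengths:
        shifts = LeipCorrections()
        for pH in pH_values[::-1]:
            cond = SolutionConditions(
                pH=pH,
                ionic_strength=I,
                bjerrum_length=bjerrum_length,
                lr_enabled=lr_enabled,
            )
            if not lr_enabled:
                shifts = LeipCorrections()
            elif mode == "rigid":
                shifts = solve_rigid(
                    chain, params, cond, correct_eps=correct_eps, x0=shifts, tol=tol
                )
            else:
                shifts = solve_flexible(
                    chain, params, cond, correct_sigma=correct_sigma, x0=shifts, tol=tol
                )
            if mode == "rigid":
                nu0, D0, *_r, obs = _rigid_state(
                    shifts.x, shifts.x_eps, chain, params, cond
                )
                theta = nu0 / N
                p_g = np.nan
                omega0 = -obs.log_partition
            else:
                nu0, g0, *_r, eng = _flexible_state(
                    shifts.x, shifts.x_sigma, chain, params, cond
                )
                theta = nu0 / N
                p_g = g0 / chain.n_rotatable if chain.n_rotatable else np.nan
                omega0 = -eng.log_partition
            rows.append(
                {
                    "pH": pH,
                    "ionic_strength": I,
                    "theta": theta,
                    "p_gauche": p_g,
                    "x": shifts.x,
                    "x_sigma": shifts.x_sigma,
                    "x_eps": shifts.x_eps,
                    "omega0": omega0,
                    "omega_bound": gb_bound(shifts, chain, params, cond, mode),
                    "converged": shifts.converged,
                    "iterations": shifts.iterations,
                    "residual": shifts.residual,
                }
            )
    frame = pd.DataFrame(rows, columns=TITRATION_COLUMNS)
    frame = frame.sort_values(["ionic_strength", "pH"]).reset_index(drop=True)
    return frame
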