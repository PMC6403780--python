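import numpy as np
import pytest

from polyleip import (
    EnergyParams,
    LeipCorrections,
    SolutionConditions,
    build_chain,
    dh_pair,
    gb_bound,
    phi0,
    sbris_observables,
    solve_flexible,
    solve_rigid,
    titrate,
)
from polyleip.oracle import enumerate_rigid_chain, enumerate_sbris
from polyleip.leip_solver import _rigid_distance_matrix
from polyleip.geometry_moments import site_positions

from conftest import sr_conditions


RIGID_PARAMS = EnergyParams(pK=9.0, epsilon=1.5)


def test_phi0_vanishes_without_charge_or_lr(rigid_chain10):
    cond = SolutionConditions(pH=20.0, ionic_strength=0.01)  # z -> 0
    assert phi0(LeipCorrections(), rigid_chain10, RIGID_PARAMS, cond, "rigid") < 1e-10
    off = sr_conditions(7.0)
    assert phi0(LeipCorrections(), rigid_chain10, RIGID_PARAMS, off, "rigid") == 0.0


def test_phi0_rigid_single_pair_formula():
    """N=3: the only LR pair is (0, 2) at separation 2b."""
    chain = build_chain(3, spacing=1, bond_length=0.2)
    cond = SolutionConditions(pH=8.0, ionic_strength=0.1)
    from polyleip.transfer_matrix import sb_pair_matrix

    z = 10.0 ** (9.0 - 8.0)
    h = sb_pair_matrix(3, z, 10.0**-1.5)[0, 2]
    expected = dh_pair(0.4, cond.potential) * h
    got = phi0(LeipCorrections(), chain, RIGID_PARAMS, cond, "rigid")
    assert got == pytest.approx(expected, rel=1e-12)


def test_phi0_saturates_to_full_pair_sum():
    """pH -> -inf: every h_ij -> 1, phi0 -> sum of pair potentials."""
    chain = build_chain(6, spacing=1, bond_length=0.2)
    cond = SolutionConditions(pH=-8.0, ionic_strength=0.1)
    d = _rigid_distance_matrix(chain)
    iu, ju = np.triu_indices(6, k=2)
    expected = float(np.sum(dh_pair(d[iu, ju], cond.potential)))
    got = phi0(LeipCorrections(), chain, RIGID_PARAMS, cond, "rigid")
    assert got == pytest.approx(expected, rel=1e-6)


def test_solve_rigid_zero_without_lr(rigid_chain10):
    s = solve_rigid(rigid_chain10, RIGID_PARAMS, sr_conditions(7.0))
    assert s.x == 0.0 and s.x_eps == 0.0 and s.converged


def test_rigid_correction_grows_with_weaker_screening(rigid_chain10):
    """x is larger at I = 0.001 M than at 1 M (less screened LR)."""
    xs = {}
    for I in (1.0, 0.001):
        cond = SolutionConditions(pH=7.0, ionic_strength=I)
        xs[I] = solve_rigid(rigid_chain10, RIGID_PARAMS, cond).x
    assert xs[0.001] > xs[1.0] > 0.0


def test_rigid_correction_trend_in_ph(rigid_chain10):
    """x >= 0 and growing toward low pH.  The pK-only correction is
    wavy through the titration midpoint (a real feature of the method),
    so only the overall charging trend is asserted, not strict
    monotonicity."""
    frame = titrate(
        rigid_chain10,
        RIGID_PARAMS,
        np.arange(4.0, 12.1, 0.5),
        [0.01],
        mode="rigid",
    ).sort_values("pH")
    x = frame["x"].to_numpy()
    pH = frame["pH"].to_numpy()
    assert np.all(x >= -1e-10)
    assert x[pH == 4.0] > x[pH == 8.0] > x[pH == 12.0]


def test_rigid_titration_matches_enumeration_n10():
    """Corrected SR model vs exact full-LR enumeration, N=10 (the
    measured maximum deviation of the pK-only correction is 0.0104)."""
    chain = build_chain(10, spacing=1, bond_length=0.2)
    worst = 0.0
    for I in (1.0, 0.01):
        shifts = None
        for pH in np.arange(12.0, 2.9, -0.5):
            cond = SolutionConditions(pH=pH, ionic_strength=I)
            shifts = solve_rigid(chain, RIGID_PARAMS, cond, x0=shifts)
            assert shifts.converged
            from polyleip import sb_observables

            z = 10.0 ** ((9.0 - shifts.x) - pH)
            theta = sb_observables(10, z, 10.0**-1.5).nu / 10
            ens = enumerate_rigid_chain(chain, RIGID_PARAMS, cond)
            worst = max(worst, abs(theta - ens.nu / 10))
    assert worst <= 0.011


def test_solve_flexible_zero_without_lr(minimal_chain, figure_params):
    s = solve_flexible(minimal_chain, figure_params, sr_conditions(7.0))
    assert s.x == 0.0 and s.x_sigma == 0.0 and s.converged


def test_xsigma_vanishes_at_high_ph(figure_params):
    chain = build_chain(8, 3, 0.2, 120.0)
    cond = SolutionConditions(pH=13.0, ionic_strength=0.01)
    s = solve_flexible(chain, figure_params, cond)
    assert abs(s.x_sigma) < 1e-3
    assert abs(s.x) < 1e-3


def test_flexible_titration_matches_enumeration_small(minimal_chain, figure_params):
    """3-site chain: theta and p_gauche from the corrected SR model match
    the full-LR roto-microstate enumeration within 0.02."""
    shifts = None
    for pH in np.arange(12.0, 2.9, -0.5):
        cond = SolutionConditions(pH=pH, ionic_strength=0.01)
        shifts = solve_flexible(minimal_chain, figure_params, cond, x0=shifts)
        obs = sbris_observables(minimal_chain, figure_params, pH, shifts=shifts)
        ens = enumerate_sbris(minimal_chain, figure_params, cond)
        assert abs(obs.nu / 3 - ens.nu / 3) <= 0.02
        assert abs(obs.p_gauche.mean() - ens.p_gauche.mean()) <= 0.02


def test_flexible_frozen_reduces_to_rigid_with_matched_geometry():
    """sigma = 0 freezes the chain all-trans; the flexible solve then
    agrees with the rigid solver fed the frozen zigzag distances."""
    chain = build_chain(6, 3, 0.2, 120.0)
    params = EnergyParams(pK=9.0, sigma=0.0, u_t=10.0**-1.0, u_g=0.0)
    pos = site_positions(np.zeros(5, dtype=int), chain)[chain.site_nodes]
    diff = pos[:, None, :] - pos[None, :, :]
    dists = np.sqrt((diff**2).sum(-1))
    rigid = build_chain(6, spacing=1, bond_length=0.2)
    rigid_params = EnergyParams(pK=9.0, epsilon=1.0)
    for pH in (6.0, 8.0, 10.0):
        cond = SolutionConditions(pH=pH, ionic_strength=0.01)
        sf = solve_flexible(chain, params, cond, correct_sigma=False)
        sr = solve_rigid(rigid, rigid_params, cond, distances=dists)
        assert sf.x == pytest.approx(sr.x, abs=5e-6)


def test_gb_bound_reduces_to_omega0_without_lr(minimal_chain, figure_params):
    cond = sr_conditions(8.0)
    from polyleip import sbris_partition

    bound = gb_bound(LeipCorrections(), minimal_chain, figure_params, cond)
    assert bound == pytest.approx(
        -sbris_partition(minimal_chain, figure_params, 8.0), abs=1e-10
    )


def test_gb_bound_dominates_exact_omega_rigid(rng):
    """Omega~(shifts) >= Omega_exact for arbitrary shifts (N=8, full DH)."""
    chain = build_chain(8, spacing=1, bond_length=0.2)
    cond = SolutionConditions(pH=8.0, ionic_strength=0.01)
    ens = enumerate_rigid_chain(chain, RIGID_PARAMS, cond)
    for _ in range(15):
        sh = LeipCorrections(
            x=float(rng.uniform(-1.0, 2.5)), x_eps=float(rng.uniform(-0.5, 0.5))
        )
        assert gb_bound(sh, chain, RIGID_PARAMS, cond, "rigid") >= ens.omega - 1e-9


def test_gb_bound_stationary_at_optimum():
    chain = build_chain(8, spacing=1, bond_length=0.2)
    cond = SolutionConditions(pH=8.0, ionic_strength=0.01)
    s = solve_rigid(chain, RIGID_PARAMS, cond, correct_eps=True)
    assert s.converged
    b0 = gb_bound(s, chain, RIGID_PARAMS, cond, "rigid")
    for dx in (0.1, -0.1):
        perturbed = LeipCorrections(x=s.x + dx, x_eps=s.x_eps)
        assert gb_bound(perturbed, chain, RIGID_PARAMS, cond, "rigid") > b0
        perturbed = LeipCorrections(x=s.x, x_eps=s.x_eps + dx)
        assert gb_bound(perturbed, chain, RIGID_PARAMS, cond, "rigid") > b0


def test_solved_shifts_satisfy_partial_derivative_forms():
    """At the solution, x equals the constrained derivative
    (d phi0 / d nu0) at fixed g0 (checked by numerical differentiation
    of the 2x2 system, tolerance 1e-4)."""
    chain = build_chain(8, 3, 0.2, 120.0)
    params = EnergyParams(pK=9.0, sigma=10.0, u_t=10.0**-1.0, u_g=0.0)
    cond = SolutionConditions(pH=7.0, ionic_strength=0.01)
    s = solve_flexible(chain, params, cond)
    assert s.converged
    from polyleip.leip_solver import _flexible_state, _phi0_flexible

    h = 1e-4
    v = np.array([s.x, s.x_sigma])
    dphi = np.array(
        [
            (_phi0_flexible(v[0] + h, v[1], chain, params, cond)
             - _phi0_flexible(v[0] - h, v[1], chain, params, cond)) / (2 * h),
            (_phi0_flexible(v[0], v[1] + h, chain, params, cond)
             - _phi0_flexible(v[0], v[1] - h, chain, params, cond)) / (2 * h),
        ]
    )
    J = np.empty((2, 2))
    for k in range(2):
        e = np.zeros(2)
        e[k] = h
        up = _flexible_state(*(v + e), chain, params, cond)[:2]
        dn = _flexible_state(*(v - e), chain, params, cond)[:2]
        J[k] = (np.array(up) - np.array(dn)) / (2 * h)
    # J (x, x_sigma)^T = dphi  (the stationarity system)
    assert np.allclose(J.T @ v, dphi, atol=1e-4)


def test_titrate_ideal_case_is_henderson_hasselbalch(minimal_chain):
    params = EnergyParams(pK=9.0)  # no SR interactions, sigma = 1
    frame = titrate(
        minimal_chain, params, [6.0, 9.0, 10.0], [0.1], lr_enabled=False
    )
    expected = 1.0 / (1.0 + 10.0 ** (frame["pH"] - 9.0))
    assert np.allclose(frame["theta"], expected, atol=1e-12)
    assert np.allclose(frame["x"], 0.0)


def test_titrate_output_schema_and_theta_monotone(figure_params):
    chain = build_chain(10, 3, 0.2, 120.0)
    frame = titrate(chain, figure_params, np.arange(4.0, 12.1, 1.0), [0.1])
    from polyleip.leip_solver import TITRATION_COLUMNS

    assert list(frame.columns) == TITRATION_COLUMNS
    theta = frame.sort_values("pH")["theta"].to_numpy()
    assert np.all(np.diff(theta) <= 1e-9)
    assert frame["converged"].all()
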