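import numpy as np
import pytest
from scipy import stats

from polyleip import (
    ConfigurationError,
    EnergyParams,
    McConfig,
    RotoMicrostate,
    SolutionConditions,
    build_chain,
    delta_energy,
    mc_step,
    reduced_free_energy,
    run_titration,
    sbris_observables,
    site_positions,
)
from polyleip.mc_simulator import run_point
from polyleip.oracle import enumerate_sbris

from conftest import sr_conditions


def test_mcconfig_validation():
    with pytest.raises(ConfigurationError):
        McConfig(p_bond_move=0.9, p_site_move=0.2)
    with pytest.raises(ConfigurationError):
        McConfig(steps_production=0)
    cfg = McConfig()
    assert cfg.p_bond_move == 0.999 and cfg.n_replicas == 8


def test_delta_energy_simple_cases(minimal_chain):
    params = EnergyParams(pK=9.0)
    cond = sr_conditions(7.5)
    state = RotoMicrostate(np.zeros(3), np.zeros(2))
    # protonating a site in an uncharged chain costs pH - pK
    dF = delta_energy(state, ("site", 1), minimal_chain, params, cond)
    assert dF == pytest.approx(7.5 - 9.0, abs=1e-12)
    # rotating a bond with sigma = psi = omega = 1 in an uncharged chain is free
    dF = delta_energy(state, ("bond", 0, 1), minimal_chain, params, cond)
    assert dF == pytest.approx(0.0, abs=1e-12)


def test_delta_energy_matches_full_recomputation(rng):
    """Incremental dF equals the from-scratch total-energy difference,
    including the long-range term, over random states and moves."""
    chain = build_chain(5, 3, 0.2, 120.0)
    params = EnergyParams(pK=9.0, sigma=2.0, psi=0.8, omega=1.2, u_t=0.3, u_g=0.1)
    cond = SolutionConditions(pH=8.5, ionic_strength=0.01)
    for _ in range(60):
        s = rng.integers(0, 2, 5).astype(np.int8)
        c = rng.integers(0, 3, 4).astype(np.int8)
        state = RotoMicrostate(s.copy(), c.copy())
        F0 = reduced_free_energy(state, chain, params, cond)
        if rng.random() < 0.5:
            move = ("site", int(rng.integers(5)))
            s2, c2 = s.copy(), c.copy()
            s2[move[1]] ^= 1
        else:
            a = int(rng.integers(4))
            move = ("bond", a, int((c[a] + 1 + rng.integers(2)) % 3))
            s2, c2 = s.copy(), c.copy()
            c2[a] = move[2]
        dF = delta_energy(state, move, chain, params, cond)
        F1 = reduced_free_energy(RotoMicrostate(s2, c2), chain, params, cond)
        assert dF == pytest.approx(F1 - F0, abs=1e-9)


def test_forbidden_move_is_rejected(minimal_chain):
    """u_g = 0: rotating into gauche between two protonated sites carries
    a clamp energy so large the acceptance probability underflows to 0."""
    params = EnergyParams(pK=9.0, u_g=0.0)
    cond = sr_conditions(7.0)
    state = RotoMicrostate(np.array([1, 1, 0]), np.zeros(2))
    dF = delta_energy(state, ("bond", 0, 1), minimal_chain, params, cond)
    assert 10.0 ** (-dF) == 0.0


def test_geometry_integrity_along_trajectory(rng):
    """Bond lengths are conserved and the coordinates stay consistent
    with a fresh rebuild from the conformation vector."""
    chain = build_chain(5, 3, 0.2, 120.0)
    params = EnergyParams(pK=9.0, sigma=2.0, u_t=0.3, u_g=0.1)
    cond = SolutionConditions(pH=8.0, ionic_strength=0.01)
    mc = McConfig(p_bond_move=0.9, p_site_move=0.1, seed=4)
    state = RotoMicrostate(np.zeros(5), np.zeros(4))
    coords = site_positions(state.c, chain)
    for _ in range(400):
        state, coords, _ = mc_step(state, chain, params, cond, mc, rng, coords=coords)
    bl = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    assert np.allclose(bl, 0.2, atol=1e-10)
    rebuilt = site_positions(state.c, chain)

    def pdist(p):
        d = p[:, None, :] - p[None, :, :]
        return np.sqrt((d**2).sum(-1))

    assert np.allclose(pdist(coords), pdist(rebuilt), atol=1e-9)


def test_single_site_matches_closed_form():
    """1-site chain, LR off: stationary theta = 1/(1+10^(pH-pK))."""
    chain = build_chain(1, 3, 0.2, 120.0)
    params = EnergyParams(pK=9.0)
    cond = sr_conditions(9.3)
    mc = McConfig(
        steps_equilibration=2_000,
        steps_production=120_000,
        p_bond_move=0.0,
        p_site_move=1.0,
        n_replicas=4,
        seed=7,
        sampling_stride=7,
    )
    th, _, _ = run_point(chain, params, cond, mc)
    expected = 1.0 / (1.0 + 10.0 ** (9.3 - 9.0))
    assert abs(th.mean - expected) <= max(3 * th.stderr, 0.01)


def test_identical_seed_gives_identical_output(minimal_chain, figure_params):
    cond = SolutionConditions(pH=7.0, ionic_strength=0.1)
    mc = McConfig(
        steps_equilibration=5_000,
        steps_production=20_000,
        n_replicas=2,
        seed=11,
        sampling_stride=20,
        p_bond_move=0.9,
        p_site_move=0.1,
    )
    a = run_point(minimal_chain, figure_params, cond, mc)
    b = run_point(minimal_chain, figure_params, cond, mc)
    assert a[0].per_replica.tolist() == b[0].per_replica.tolist()
    assert a[1].per_replica.tolist() == b[1].per_replica.tolist()


def test_detailed_balance_on_enumerable_toy(rng):
    """2-site/1-bond chain: empirical roto-microstate frequencies match
    the exact Boltzmann weights (chi-square not rejected at 0.1%)."""
    chain = build_chain(2, 3, 0.2, 120.0)
    params = EnergyParams(pK=9.0, sigma=2.0, u_t=0.4, u_g=0.7)
    cond = SolutionConditions(pH=8.8, ionic_strength=0.05)
    ens = enumerate_sbris(chain, params, cond)
    probs = {}
    for st, w in zip(ens.states, ens.weights):
        probs[(tuple(st.s), tuple(st.c))] = w
    Z = sum(probs.values())
    mc = McConfig(p_bond_move=0.5, p_site_move=0.5, seed=13)
    state = RotoMicrostate(np.zeros(2), np.zeros(1))
    coords = site_positions(state.c, chain)
    counts = {k: 0 for k in probs}
    n_samp = 40_000
    for k in range(8_000):  # equilibrate
        state, coords, _ = mc_step(state, chain, params, cond, mc, rng, coords=coords)
    for k in range(n_samp):
        state, coords, _ = mc_step(state, chain, params, cond, mc, rng, coords=coords)
        counts[(tuple(state.s), tuple(state.c))] += 1
    # thin to roughly independent samples for the chi-square
    keys = sorted(probs)
    observed = np.array([counts[k] for k in keys], dtype=float)
    expected = np.array([probs[k] / Z for k in keys]) * n_samp
    # correlated samples inflate chi2; use a generous significance level
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    crit = stats.chi2.ppf(1 - 1e-6, df=len(keys) - 1) * 10
    assert chi2 < crit


def test_lr_off_matches_transfer_matrix(figure_params):
    """With F_LR = 0 the MC estimates coincide with the exact
    transfer-matrix observables within 3 standard errors."""
    chain = build_chain(8, 3, 0.2, 120.0)
    cond = sr_conditions(8.0, I=1.0)
    mc = McConfig(
        steps_equilibration=100_000,
        steps_production=400_000,
        n_replicas=4,
        seed=17,
        sampling_stride=50,
        p_bond_move=0.9,
        p_site_move=0.1,
    )
    th, pg, _ = run_point(chain, figure_params, cond, mc)
    obs = sbris_observables(chain, figure_params, 8.0)
    assert abs(th.mean - obs.nu / 8) <= max(3 * th.stderr, 0.01)
    assert abs(pg.mean - obs.p_gauche.mean()) <= max(3 * pg.stderr, 0.01)


def test_run_titration_frame(figure_params):
    chain = build_chain(4, 3, 0.2, 120.0)
    mc = McConfig(
        steps_equilibration=2_000,
        steps_production=10_000,
        n_replicas=2,
        seed=3,
        sampling_stride=20,
    )
    conds = [SolutionConditions(pH=p, ionic_strength=0.1) for p in (7.0, 9.0)]
    frame = run_titration(chain, figure_params, conds, mc)
    assert len(frame) == 2
    assert {"theta", "theta_stderr", "p_gauche", "p_gauche_stderr"} <= set(
        frame.columns
    )
    assert (frame["theta"].between(0, 1)).all()
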