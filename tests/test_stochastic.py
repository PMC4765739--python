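"""Stochastic simulation: parameter conversion, exact SSA, single-molecule
tracking, and the mean-field/individual-based oracles."""

import numpy as np
import pytest

from palmcycle import (
    Perturbation,
    WT,
    lag_statistics,
    mean_field_fate,
    simulate,
    ssa_run,
    steady_state,
    to_stochastic,
    track_molecule,
    track_molecules,
)
from palmcycle.kinetics import _percapita_rates
from palmcycle.stochastic import STOICHIOMETRY, _propensities


def test_stoichiometry_conserves_molecules():
    # interconversions conserve count; synthesis +1, degradations -1
    net = STOICHIOMETRY.sum(axis=1)
    assert net[0] == 1
    assert np.all(net[1:10] == 0)
    assert np.all(net[10:] == -1)


def test_identity_scale_propensities_match_rates(baseline):
    stoch = to_stochastic(baseline, steady_state(baseline).sum())
    assert stoch.omega == pytest.approx(1.0)
    y = np.array([0.1, 0.3, 0.02, 0.03, 0.5])
    a = _propensities(y, stoch.params.to_array(), np.ones(4), 1.0, True)
    from palmcycle import reaction_rates

    rr = reaction_rates(y, baseline)
    np.testing.assert_allclose(a[2:6], [rr.v_p1, rr.v_p2, rr.v_p12, rr.v_p21],
                               rtol=1e-12)


def test_omega_scales_counts_linearly(baseline):
    s1 = to_stochastic(baseline, 1e4)
    s2 = to_stochastic(baseline, 2e4)
    assert s2.omega == pytest.approx(2 * s1.omega)
    y1 = steady_state(s1.params)
    y2 = steady_state(s2.params)
    np.testing.assert_allclose(y2, 2 * y1, rtol=1e-6)


def test_ssa_constant_when_propensities_vanish(baseline):
    stoch = to_stochastic(baseline, 1e4)
    pert_off = Perturbation(synthesis_on=False)
    from palmcycle.stochastic import StochasticParameters

    frozen = StochasticParameters(stoch.params, stoch.omega, 1e4, pert_off)
    traj = ssa_run(frozen, np.zeros(5), [0.0, 1.0, 5.0], seed=1)
    assert np.all(traj == 0)


def test_ssa_seed_determinism(baseline):
    stoch = to_stochastic(baseline, 2000)
    y0 = np.round(steady_state(stoch.params))
    t = np.linspace(0, 5, 6)
    a = ssa_run(stoch, y0, t, seed=42)
    b = ssa_run(stoch, y0, t, seed=42)
    c = ssa_run(stoch, y0, t, seed=43)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_ssa_mean_tracks_ode_as_copies_grow(baseline):
    # relative deviation of the SSA ensemble mean from the ODE solution
    # shrinks roughly like 1/sqrt(copies)
    t = np.array([0.0, 1.0, 2.0])
    devs = []
    for copies, n_runs in ((2e3, 30), (2e4, 30)):
        stoch = to_stochastic(baseline, copies)
        y0 = np.round(steady_state(stoch.params) * 0.8)
        ode = simulate(y0, stoch.params, WT, times=t)
        runs = np.array([ssa_run(stoch, y0, t, seed=100 + i)
                         for i in range(n_runs)], dtype=float)
        mean = runs.mean(axis=0)
        devs.append(np.abs(mean[-1] - ode[-1]).sum() / ode[-1].sum())
    assert devs[1] < devs[0]
    assert devs[1] < 0.02


def test_pure_degradation_extinction_times_are_exponential(baseline):
    # one species, first-order decay: per-molecule lifetimes are exponential
    from palmcycle.stochastic import StochasticParameters

    p = baseline.replace(kdeg_f=0.5, E_apt=1e-300, k_fold=1e-300)
    stoch = StochasticParameters(p, 1.0, 200, Perturbation(
        synthesis_on=False, mutant="AA"))
    n0, t_end = 200, 40.0
    t = np.linspace(0, t_end, 81)
    y0 = np.array([0, n0, 0, 0, 0], float)
    counts = ssa_run(stoch, y0, t, seed=5)[:, 1]
    # survival curve matches exp(-k t) within binomial scatter
    expected = n0 * np.exp(-0.5 * t)
    sd = np.sqrt(n0 * np.exp(-0.5 * t) * (1 - np.exp(-0.5 * t)) + 1)
    assert np.all(np.abs(counts - expected) < 4 * sd)


def test_tracking_without_enzyme_always_degrades(baseline):
    stoch = to_stochastic(baseline, 1e4, Perturbation(pat_scale=0.0))
    traces = track_molecules(stoch, 50, seed=9)
    assert all(tr.terminal == "degraded" for tr in traces)
    assert all(np.isnan(tr.lag_h) for tr in traces)


def test_tracking_seed_determinism(baseline):
    stoch = to_stochastic(baseline, 1e4)
    a = track_molecules(stoch, 20, seed=3)
    b = track_molecules(stoch, 20, seed=3)
    assert [tr.times_h for tr in a] == [tr.times_h for tr in b]
    assert [tr.terminal for tr in a] == [tr.terminal for tr in b]


def test_tracking_matches_mean_field_fate(baseline):
    stoch = to_stochastic(baseline, 5e5)
    traces = track_molecules(stoch, 4000, seed=17)
    stats = lag_statistics(traces)
    fate = mean_field_fate(baseline)
    n = stats.n
    # binomial 3-sigma bands around the closed-form absorption probabilities
    for observed, p in ((stats.n_dual, fate.p_dual),
                        (stats.n_degraded_before_palm,
                         fate.p_degraded_before_palm)):
        sd = np.sqrt(n * p * (1 - p))
        assert abs(observed - n * p) < 3.5 * sd
    assert stats.mean_lag_h == pytest.approx(
        fate.mean_lag_h, rel=4 * stats.lags_h.std()
        / (np.sqrt(stats.n_dual) * fate.mean_lag_h))


def test_tracking_matches_individual_based_oracle(baseline):
    """Tagged-molecule statistics vs a fully individualized simulation.

    The oracle simulates every molecule of a small-copy-number system as its
    own agent (hazards from the per-capita rates at the current aggregate
    counts, synthesis included) and extracts the fate of molecules born
    after burn-in.
    """
    stoch = to_stochastic(baseline, 300)
    p = stoch.params
    rng = np.random.default_rng(21)
    mask = np.ones(4)
    # agent states: 0..4 species index
    y_ss = steady_state(p)
    agents = []
    for idx, count in enumerate(np.round(y_ss).astype(int)):
        agents += [idx] * count
    agents = np.array(agents)
    born_after = {}
    fates = []
    lags = []
    t, t_end, burn_in = 0.0, 3000.0, 300.0
    birth = {}
    while t < t_end:
        counts = np.bincount(agents, minlength=5).astype(float)
        qp, qd = _percapita_rates(counts, p, WT)
        hazard = np.array([
            p.k_fold + p.kdeg_r,
            qp[0] + qp[1] + p.kdeg_f,
            qp[2] + qd[0] + p.kdeg_c1,
            qp[3] + qd[1] + p.kdeg_c2,
            qd[2] + qd[3] + p.kdeg_c12,
        ])
        total = p.v_syn + hazard[agents].sum()
        t += rng.exponential(1.0 / total)
        u = rng.random() * total
        if u < p.v_syn:
            agents = np.append(agents, 0)
            birth[len(agents) - 1] = t
            continue
        u -= p.v_syn
        cum = np.cumsum(hazard[agents])
        i = int(np.searchsorted(cum, u))
        s = agents[i]
        r = u - (cum[i - 1] if i else 0.0)
        # resolve which reaction hit molecule i
        if s == 0:
            new = 1 if r < p.k_fold else -1
        elif s == 1:
            new = 2 if r < qp[0] else (3 if r < qp[0] + qp[1] else -1)
        elif s == 2:
            new = 4 if r < qp[2] else (1 if r < qp[2] + qd[0] else -1)
        elif s == 3:
            new = 4 if r < qp[3] else (1 if r < qp[3] + qd[1] else -1)
        else:
            new = 3 if r < qd[2] else (2 if r < qd[2] + qd[3] else -1)
        if i in birth and t > burn_in:
            if new == 4:
                fates.append("dual")
                lags.append(t - birth[i])
                del birth[i]
            elif new == -1:
                fates.append("degraded")
                del birth[i]
        if new == -1:
            agents = np.delete(agents, i)
            birth = {(k if k < i else k - 1): v for k, v in birth.items()
                     if k != i}
        else:
            agents[i] = new
    n_dual = fates.count("dual")
    frac_dual_oracle = n_dual / len(fates)
    lag_oracle = float(np.mean(lags))
    traces = track_molecules(stoch, 3000, seed=8)
    stats = lag_statistics(traces)
    frac_dual = stats.n_dual / stats.n
    assert frac_dual == pytest.approx(frac_dual_oracle, abs=0.06)
    assert stats.mean_lag_h == pytest.approx(lag_oracle, rel=0.30)


def test_lag_statistics_singleton_and_errors(baseline):
    stoch = to_stochastic(baseline, 1e4)
    tr = track_molecule(stoch, seed=2)
    while tr.terminal != "dual_palmitoylated":
        tr = track_molecule(stoch, seed=int(tr.times_h[-1] * 1e6) % 2**31)
    stats = lag_statistics([tr])
    assert stats.mean_lag_h == stats.median_lag_h == tr.lag_h
    assert stats.convergence[-1] == stats.mean_lag_h
    with pytest.raises(ValueError):
        lag_statistics([t for t in track_molecules(
            to_stochastic(baseline, 1e4, Perturbation(pat_scale=0.0)), 5, 1)])
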