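"""Rate laws, mass balances, integration and steady states.

The central check is the mass-action oracle: the competitive
Michaelis-Menten rates must agree with the quasi-stationary flux of the
explicit enzyme mechanism (free enzyme + one complex per reaction) at the
low enzyme-to-substrate ratios of this system.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from palmcycle import (
    Perturbation,
    SpeciesVector,
    WT,
    depalmitoylation_rates,
    derivatives,
    palmitoylation_rates,
    reaction_rates,
    simulate,
    steady_state,
)
from palmcycle.kinetics import aa_steady_state_closed_form
from palmcycle.params import KineticParameters


def test_zero_substrate_gives_zero_rates(baseline):
    state = SpeciesVector(rCAL=1.0)
    assert palmitoylation_rates(state, baseline) == (0, 0, 0, 0)
    assert depalmitoylation_rates(state, baseline) == (0, 0, 0, 0)


def test_no_enzyme_gives_zero_rates(baseline):
    state = SpeciesVector(fCAL=0.5, c1CAL=0.1, c2CAL=0.1, c12CAL=0.2)
    rates = palmitoylation_rates(state, baseline, Perturbation(pat_scale=0.0))
    assert rates == (0, 0, 0, 0)
    no_apt = baseline.replace(E_apt=1e-300)
    assert max(depalmitoylation_rates(state, no_apt)) < 1e-250


def test_saturation_plateau(baseline):
    # only fCAL present, site-2 reactions disabled, fCAL >> Km -> kcat*E
    p = baseline.replace(Km_p1=1e-6)
    state = SpeciesVector(fCAL=1.0)
    v_p1, *_ = palmitoylation_rates(state, p, Perturbation(mutant="CA"))
    assert v_p1 == pytest.approx(p.kcat_p1 * p.E_pat, rel=1e-3)


def test_negative_state_rejected(baseline):
    with pytest.raises(ValueError):
        palmitoylation_rates(np.array([-0.1, 1, 0, 0, 0]), baseline)


def _mass_action_flux(state, params, enzyme_frac):
    """Quasi-stationary palmitoylation fluxes of the explicit mechanism.

    Free enzyme E binds each substrate-site pair X with its own kon/koff
    (chosen so that (koff + kcat)/kon = Km); substrate concentrations are
    buffered; the enzyme-complex system is integrated to stationarity and
    the fluxes kcat * [C_X] are returned.
    """
    subs = np.array([state[1], state[1], state[2], state[3]])
    kcats = np.array([params.kcat_p1, params.kcat_p2,
                      params.kcat_p12, params.kcat_p21])
    kms = np.array([params.Km_p1, params.Km_p2, params.Km_p12, params.Km_p21])
    e_tot = enzyme_frac * sum(state)
    kon = 1e4  # fast binding: tQSS regime
    koff = kon * kms - kcats
    assert np.all(koff > 0)

    def rhs(_t, c):
        e_free = e_tot - c.sum()
        return kon * e_free * subs - (koff + kcats) * c

    sol = solve_ivp(rhs, (0, 100.0), np.zeros(4), method="LSODA",
                    rtol=1e-10, atol=1e-16)
    return kcats * sol.y[:, -1]


def test_competitive_mm_matches_mass_action_oracle(baseline):
    rng = np.random.default_rng(7)
    for _ in range(5):
        state = rng.uniform(0.05, 0.6, 5)
        for frac in (1 / 500, 1 / 100):
            p = baseline.replace(E_pat=frac * state.sum())
            v = np.array(palmitoylation_rates(state, p))
            v_oracle = _mass_action_flux(state, p, frac)
            np.testing.assert_allclose(v, v_oracle, rtol=0.05)


def test_reaction_rates_balance_at_aa_steady_state(baseline):
    pert = Perturbation(mutant="AA")
    y = aa_steady_state_closed_form(baseline)
    rr = reaction_rates(y, baseline, pert)
    assert rr.v_syn == pytest.approx(rr.v_fold + rr.v_deg_r, rel=1e-12)
    assert rr.v_fold == pytest.approx(rr.v_deg_f, rel=1e-12)


def test_derivative_bookkeeping_identity(baseline, rng):
    # total change = synthesis - total degradation
    y = rng.uniform(0.01, 0.5, 5)
    d = derivatives(y, baseline)
    rr = reaction_rates(y, baseline)
    total_deg = (rr.v_deg_r + rr.v_deg_f + rr.v_deg_c1
                 + rr.v_deg_c2 + rr.v_deg_c12)
    assert d.sum() == pytest.approx(rr.v_syn - total_deg, abs=1e-12)


def test_derivatives_match_trajectory_slope(baseline):
    y0 = np.array([0.1, 0.2, 0.01, 0.01, 0.3])
    h = 1e-4
    traj = simulate(y0, baseline, WT, times=[0.0, h, 2 * h])
    slope = (traj[2] - traj[0]) / (2 * h)
    np.testing.assert_allclose(slope, derivatives(y0, baseline), rtol=5e-3,
                               atol=1e-10)


def test_simulate_requires_increasing_times(baseline):
    with pytest.raises(ValueError):
        simulate(np.zeros(5), baseline, WT, times=[0.0, 2.0, 1.0])


def test_aa_mutant_converges_to_closed_form(baseline):
    pert = Perturbation(mutant="AA")
    traj = simulate(np.zeros(5), baseline, pert, times=np.linspace(0, 400, 5))
    np.testing.assert_allclose(traj[-1], aa_steady_state_closed_form(baseline),
                               rtol=1e-3, atol=1e-12)


def test_mass_conservation_without_synthesis_or_degradation(baseline):
    p = baseline.replace(kdeg_r=1e-12, kdeg_f=1e-12, kdeg_c1=1e-12,
                         kdeg_c2=1e-12, kdeg_c12=1e-12)
    pert = Perturbation(synthesis_on=False)
    y0 = np.array([0.1, 0.3, 0.05, 0.05, 0.5])
    traj = simulate(y0, p, pert, times=np.linspace(0, 50, 6))
    np.testing.assert_allclose(traj.sum(axis=1), y0.sum(), rtol=1e-7)


def test_linear_regime_steady_state_scales_with_synthesis(baseline):
    # with S << Km every rate law is linear, so the steady state is too
    p = baseline.replace(v_syn=baseline.v_syn * 1e-4)
    y1 = steady_state(p)
    y2 = steady_state(p.replace(v_syn=p.v_syn * 2))
    np.testing.assert_allclose(y2, 2 * y1, rtol=1e-3)


def test_steady_state_closed_form_aa(baseline):
    y = steady_state(baseline, Perturbation(mutant="AA"))
    np.testing.assert_allclose(y, aa_steady_state_closed_form(baseline),
                               rtol=1e-3, atol=1e-14)


def test_no_enzyme_equals_no_sites(baseline):
    y_no_enzyme = steady_state(baseline, Perturbation(pat_scale=0.0))
    y_no_sites = steady_state(baseline, Perturbation(mutant="AA"))
    np.testing.assert_allclose(y_no_enzyme, y_no_sites, rtol=1e-6, atol=1e-12)


def test_steady_state_independent_of_start(baseline, rng):
    y1 = steady_state(baseline, initial=rng.uniform(0, 1, 5))
    y2 = steady_state(baseline, initial=rng.uniform(0, 2, 5))
    np.testing.assert_allclose(y1, y2, rtol=1e-5, atol=1e-10)


def test_flux_balance_at_steady_state(baseline):
    y = steady_state(baseline)
    rr = reaction_rates(y, baseline)
    total_deg = (rr.v_deg_r + rr.v_deg_f + rr.v_deg_c1
                 + rr.v_deg_c2 + rr.v_deg_c12)
    assert abs(rr.v_syn - total_deg) / rr.v_syn < 1e-6


def test_c12_fraction_monotone_in_second_acylation_rate(baseline):
    fractions = []
    for factor in (0.25, 1.0, 4.0, 16.0):
        p = baseline.replace(kcat_p12=baseline.kcat_p12 * factor)
        y = steady_state(p)
        fractions.append(y[4] / y.sum())
    assert np.all(np.diff(fractions) >= -1e-9)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_trajectories_stay_nonnegative(seed):
    rng = np.random.default_rng(seed)
    from palmcycle.params import _PARAM_FIELDS

    base = np.array([0.05, 1.0, 50, 10, 100, 10, 1, 1, 1, 1, 100, 10, 5, 5,
                     1, 1, 1, 1, 0.1, 0.1, 0.1, 0.05, 0.01, 0.002, 0.002])
    p = KineticParameters.from_array(base * np.exp(rng.normal(0, 1, len(base))))
    y0 = rng.uniform(0, 1, 5)
    traj = simulate(y0, p, WT, times=np.linspace(0, 20, 5), rtol=1e-8,
                    atol=1e-10)
    assert np.all(traj >= -1e-9)
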