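"""Derived quantities of the calibrated model.

Steady-state species distributions under perturbations, per-species cohort
half-lives, depalmitoylation kinetics from different starting cohorts,
steady-state fluxes, and local sensitivity analysis.

The cohort half-life follows the persisting-cohort convention: a labeled
cohort is initialized in one state over the unlabeled steady-state
background, keeps its identity through state interconversion, and the
half-life is the time at which the cohort total reaches 50%.  Because the
cohort is a marked sub-population of a network at steady state, its dynamics
are exactly linear with per-capita rates frozen at the steady state.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .kinetics import percapita_matrix, reaction_rates, steady_state
from .labeling import (
    TimeCourse,
    _h3_label_system,
    _H3_MOIETY_WEIGHTS,
    apparent_half_life,
    h3_pulse_protocol,
    simulate_pulse_chase_3H,
)
from .params import C1, C12, C2, SPECIES, KineticParameters, Perturbation, WT

__all__ = [
    "steady_state_distribution",
    "distribution_report",
    "species_half_life",
    "half_life_report",
    "depalmitoylation_from_cohort",
    "site_rate_constants",
    "steady_state_fluxes",
    "flux_report",
    "sensitivity",
]

_SPECIES_IDX = dict(zip(SPECIES, range(5)))


def _linear_crossing(A: np.ndarray, x0: np.ndarray, weights: np.ndarray,
                     frac: float = 0.5, horizon: float = 2000.0) -> float:
    """First time w @ x(t) reaches ``frac`` of its initial value for x' = A x.

    Uses the eigendecomposition for an exact curve and a bracketed root
    solve; NaN when the level is not reached within the horizon
    (right-censored).
    """
    w_eig, V = np.linalg.eig(A.astype(complex))
    c0 = np.linalg.solve(V, x0.astype(complex))
    s0 = float((weights @ x0))
    if s0 <= 0:
        raise ValueError("cohort is empty")
    target = frac * s0

    def level(t: float) -> float:
        x = (V @ (np.exp(w_eig * t) * c0)).real
        return float(weights @ x) - target

    if level(horizon) > 0:
        return float("nan")
    grid = np.geomspace(1e-3, horizon, 200)
    lo = 0.0
    for t in grid:
        if level(t) <= 0:
            return float(brentq(level, lo, t, xtol=1e-10, rtol=1e-12))
        lo = t
    return float("nan")


def steady_state_distribution(params: KineticParameters,
                              perturbation: Perturbation = WT) -> np.ndarray:
    """Fractions of total calnexin per state at steady state (sum to 1)."""
    y = steady_state(params, perturbation)
    return y / y.sum()


def distribution_report(ensemble, perturbation: Perturbation = WT,
                        condition: str = "") -> pd.DataFrame:
    """Ensemble mean and quartiles of the steady-state species fractions."""
    rows = []
    for member in _members(ensemble):
        try:
            rows.append(steady_state_distribution(member, perturbation))
        except Exception:
            continue  # non-convergent member dropped
    arr = np.array(rows)
    if arr.size == 0:
        raise ValueError("no ensemble member converged to steady state")
    df = pd.DataFrame(
        {
            "species": SPECIES,
            "mean": arr.mean(axis=0),
            "q1": np.percentile(arr, 25, axis=0),
            "q3": np.percentile(arr, 75, axis=0),
        }
    )
    df.insert(0, "condition", condition or perturbation.mutant)
    return df


def species_half_life(params: KineticParameters, species: str,
                      perturbation: Perturbation = WT,
                      horizon: float = 2000.0,
                      y_ss: np.ndarray | None = None) -> float:
    """Persisting-cohort half-life (h) of one species.

    A cohort initialized 100% in ``species`` is placed over the unlabeled
    steady-state background (synthesis feeds the unlabeled pool only) and
    followed through interconversion and degradation until its total count
    halves.  NaN flags right-censoring at ``horizon``.
    """
    if species not in _SPECIES_IDX:
        raise ValueError(f"species must be one of {SPECIES}")
    if y_ss is None:
        y_ss = steady_state(params, perturbation)
    M = percapita_matrix(y_ss, params, perturbation)
    c0 = np.zeros(5)
    c0[_SPECIES_IDX[species]] = 1.0
    return _linear_crossing(M, c0, np.ones(5), 0.5, horizon)


def half_life_report(ensemble, species=("fCAL", "c1CAL", "c2CAL", "c12CAL"),
                     perturbation: Perturbation = WT) -> pd.DataFrame:
    """Ensemble median/quartiles of per-species cohort half-lives."""
    rows = {s: [] for s in species}
    for member in _members(ensemble):
        for s in species:
            rows[s].append(species_half_life(member, s, perturbation))
    recs = []
    for s in species:
        vals = np.array(rows[s], float)
        vals = vals[np.isfinite(vals)]
        recs.append(
            {
                "species": s,
                "median": np.median(vals),
                "mean": vals.mean(),
                "q1": np.percentile(vals, 25),
                "q3": np.percentile(vals, 75),
                "n": vals.size,
            }
        )
    return pd.DataFrame(recs)


def depalmitoylation_from_cohort(params: KineticParameters, cohort_spec: str,
                                 perturbation: Perturbation = WT,
                                 moiety_weighted: bool = True,
                                 y_ss: np.ndarray | None = None) -> float:
    """Apparent palmitate turnover time (h) for a chosen starting cohort.

    ``pulse_2h``: the cohort labeled during a standard 2-h 3H pulse.
    ``steady_state``: every palmitate of the standing steady-state
    population marked at t = 0 (the Fig-4-style comparison).
    """
    if y_ss is None:
        y_ss = steady_state(params, perturbation)
    w = _H3_MOIETY_WEIGHTS if moiety_weighted else np.ones(5)
    if cohort_spec == "pulse_2h":
        _tc, pools = simulate_pulse_chase_3H(
            params, h3_pulse_protocol(perturbation, chase_times_h=(0.0, 1.0)),
            moiety_weighted=moiety_weighted, y_ss=y_ss, return_pools=True,
        )
        x0 = pools[0]
    elif cohort_spec == "steady_state":
        x0 = np.array([y_ss[C1], y_ss[C2], 0.0, 0.0, y_ss[C12]])
    else:
        raise ValueError("cohort_spec must be 'pulse_2h' or 'steady_state'")
    A, _b = _h3_label_system(y_ss, params, perturbation, labeled_attach=False)
    return _linear_crossing(A, x0, w, 0.5)


def site_rate_constants(ensemble, with_enzyme: bool = True) -> pd.DataFrame:
    """First-order-regime depalmitoylation constants per site context.

    ``kcat_d * E_apt / Km_d`` (1/h) for loss from c1CAL (site 1, single
    occupancy), c2CAL (site 2, single occupancy) and the two losses from
    c12CAL (double occupancy).
    """
    recs = []
    for member in _members(ensemble):
        e = member.E_apt if with_enzyme else 1.0
        recs.append(
            {
                "c1CAL_site1": member.kcat_d1 * e / member.Km_d1,
                "c2CAL_site2": member.kcat_d2 * e / member.Km_d2,
                "c12CAL_site1": member.kcat_d121 * e / member.Km_d121,
                "c12CAL_site2": member.kcat_d122 * e / member.Km_d122,
            }
        )
    df = pd.DataFrame(recs)
    return df.describe(percentiles=[0.25, 0.5, 0.75]).T


_FLUX_FIELDS = (
    "v_syn", "v_fold", "v_p1", "v_p2", "v_p12", "v_p21",
    "v_d1", "v_d2", "v_d121", "v_d122",
    "v_deg_r", "v_deg_f", "v_deg_c1", "v_deg_c2", "v_deg_c12",
)


def steady_state_fluxes(params: KineticParameters,
                        perturbation: Perturbation = WT) -> dict:
    """All 15 reaction rates evaluated at the steady state."""
    y = steady_state(params, perturbation)
    rr = reaction_rates(y, params, perturbation)
    return {f: getattr(rr, f) for f in _FLUX_FIELDS}


def flux_report(ensemble, perturbation: Perturbation = WT) -> pd.DataFrame:
    """Ensemble summary (mean, quartiles) of the steady-state fluxes."""
    df = pd.DataFrame([steady_state_fluxes(m, perturbation) for m in _members(ensemble)])
    out = pd.DataFrame(
        {
            "mean": df.mean(),
            "median": df.median(),
            "q1": df.quantile(0.25),
            "q3": df.quantile(0.75),
        }
    )
    out.index.name = "flux"
    return out


_OUTPUTS = {}


def _output_value(params: KineticParameters, output_spec: str,
                  perturbation: Perturbation) -> float:
    """Evaluate a named scalar model output.

    ``frac_<species>``: steady-state fraction; ``halflife_<species>``:
    persisting-cohort half-life.
    """
    if output_spec.startswith("frac_"):
        sp = output_spec[len("frac_"):]
        return float(steady_state_distribution(params, perturbation)[_SPECIES_IDX[sp]])
    if output_spec.startswith("halflife_"):
        sp = output_spec[len("halflife_"):]
        return species_half_life(params, sp, perturbation)
    raise ValueError(f"unknown output spec {output_spec!r}")


def sensitivity(params: KineticParameters, output_spec: str,
                rel_delta: float = 0.01,
                perturbation: Perturbation = WT,
                parameters=None) -> pd.DataFrame:
    """Normalized local sensitivity coefficients by central finite difference.

    Coefficient = (p / y) * (dy / dp) approximated as
    (y(p(1+d)) - y(p(1-d))) / (2 d y).  When the reference output is zero
    the absolute derivative is reported instead, with ``absolute=True``.
    """
    if not (0 < rel_delta <= 0.1):
        raise ValueError("rel_delta must lie in (0, 0.1]")
    names = list(parameters) if parameters is not None else list(KineticParameters.names)
    y0 = _output_value(params, output_spec, perturbation)
    recs = []
    for name in names:
        p0 = getattr(params, name)
        hi = _output_value(params.replace(**{name: p0 * (1 + rel_delta)}),
                           output_spec, perturbation)
        lo = _output_value(params.replace(**{name: p0 * (1 - rel_delta)}),
                           output_spec, perturbation)
        slope = (hi - lo) / (2 * rel_delta)  # = p * dy/dp
        if y0 != 0:
            recs.append({"parameter": name, "coefficient": slope / y0, "absolute": False})
        else:
            recs.append({"parameter": name, "coefficient": slope, "absolute": True})
    df = pd.DataFrame(recs)
    df.insert(0, "output", output_spec)
    df.insert(0, "condition", perturbation.mutant)
    return df


def _members(ensemble):
    """Accept a ModelEnsemble, an iterable of parameter sets, or one set."""
    if isinstance(ensemble, KineticParameters):
        return [ensemble]
    members = getattr(ensemble, "members", ensemble)
    return list(members)
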