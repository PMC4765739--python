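"""Deterministic reaction network of calnexin palmitoylation.

Rate laws, mass balances, ODE integration and steady-state computation.
Palmitoylation and depalmitoylation follow irreversible Michaelis-Menten
kinetics with substrate competition: all four acylation reactions share the
DHHC6 pool, all four deacylation reactions share a lumped thioesterase pool.
The competitive form (free-substrate competition, no enzyme-depletion term)
is justified by the very low enzyme-to-substrate ratio (DHHC6:calnexin on
the order of 1:500) and is validated against an explicit mass-action enzyme
mechanism in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .params import (
    C1,
    C12,
    C2,
    F,
    R,
    KineticParameters,
    Perturbation,
    SpeciesVector,
    WT,
)

__all__ = [
    "ReactionRates",
    "palmitoylation_rates",
    "depalmitoylation_rates",
    "reaction_rates",
    "derivatives",
    "simulate",
    "steady_state",
    "percapita_matrix",
    "IntegrationError",
    "SteadyStateError",
]


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the solver diagnostic message."""


class SteadyStateError(RuntimeError):
    """Steady state not reached within the maximum horizon."""


@dataclass(frozen=True)
class ReactionRates:
    """Instantaneous rates of the 15 network reactions (a.u./h)."""

    v_syn: float
    v_fold: float
    v_p1: float
    v_p2: float
    v_p12: float
    v_p21: float
    v_d1: float
    v_d2: float
    v_d121: float
    v_d122: float
    v_deg_r: float
    v_deg_f: float
    v_deg_c1: float
    v_deg_c2: float
    v_deg_c12: float


@njit(cache=False)
def _rates_nb(y, p, mask, pat_scale, syn_on):  # pragma: no cover - jitted
    """All 15 reaction rates; `p` in KineticParameters.to_array() order."""
    r, f, c1, c2, c12 = y[0], y[1], y[2], y[3], y[4]
    a = np.zeros(15)
    a[0] = p[0] if syn_on else 0.0
    a[1] = p[1] * r
    e_pat = pat_scale * p[23]
    rat1 = mask[0] * f / p[6]
    rat2 = mask[1] * f / p[7]
    rat3 = mask[2] * c1 / p[8]
    rat4 = mask[3] * c2 / p[9]
    s = rat1 + rat2 + rat3 + rat4
    a[2] = mask[0] * p[2] * e_pat * f / (p[6] * (1.0 + s - rat1) + f)
    a[3] = mask[1] * p[3] * e_pat * f / (p[7] * (1.0 + s - rat2) + f)
    a[4] = mask[2] * p[4] * e_pat * c1 / (p[8] * (1.0 + s - rat3) + c1)
    a[5] = mask[3] * p[5] * e_pat * c2 / (p[9] * (1.0 + s - rat4) + c2)
    e_apt = p[24]
    rd1 = c1 / p[14]
    rd2 = c2 / p[15]
    rd3 = c12 / p[16]
    rd4 = c12 / p[17]
    sd = rd1 + rd2 + rd3 + rd4
    a[6] = p[10] * e_apt * c1 / (p[14] * (1.0 + sd - rd1) + c1)
    a[7] = p[11] * e_apt * c2 / (p[15] * (1.0 + sd - rd2) + c2)
    a[8] = p[12] * e_apt * c12 / (p[16] * (1.0 + sd - rd3) + c12)
    a[9] = p[13] * e_apt * c12 / (p[17] * (1.0 + sd - rd4) + c12)
    a[10] = p[18] * r
    a[11] = p[19] * f
    a[12] = p[20] * c1
    a[13] = p[21] * c2
    a[14] = p[22] * c12
    return a


@njit(cache=False)
def _deriv_nb(y, p, mask, pat_scale, syn_on):  # pragma: no cover - jitted
    yc = np.maximum(y, 0.0)
    a = _rates_nb(yc, p, mask, pat_scale, syn_on)
    d = np.empty(5)
    d[0] = a[0] - a[1] - a[10]
    d[1] = a[1] - a[2] - a[3] + a[6] + a[7] - a[11]
    d[2] = a[2] - a[4] - a[6] + a[9] - a[12]
    d[3] = a[3] - a[5] - a[7] + a[8] - a[13]
    d[4] = a[4] + a[5] - a[8] - a[9] - a[14]
    return d


@njit(cache=False)
def _percap_nb(y, p, mask, pat_scale):  # pragma: no cover - jitted
    """Per-capita rates (qp1, qp2, qp12, qp21, qd1, qd2, qd121, qd122)."""
    f, c1, c2, c12 = y[1], y[2], y[3], y[4]
    q = np.empty(8)
    e_pat = pat_scale * p[23]
    rat1 = mask[0] * f / p[6]
    rat2 = mask[1] * f / p[7]
    rat3 = mask[2] * c1 / p[8]
    rat4 = mask[3] * c2 / p[9]
    s = rat1 + rat2 + rat3 + rat4
    q[0] = mask[0] * p[2] * e_pat / (p[6] * (1.0 + s - rat1) + f)
    q[1] = mask[1] * p[3] * e_pat / (p[7] * (1.0 + s - rat2) + f)
    q[2] = mask[2] * p[4] * e_pat / (p[8] * (1.0 + s - rat3) + c1)
    q[3] = mask[3] * p[5] * e_pat / (p[9] * (1.0 + s - rat4) + c2)
    e_apt = p[24]
    rd1 = c1 / p[14]
    rd2 = c2 / p[15]
    rd3 = c12 / p[16]
    rd4 = c12 / p[17]
    sd = rd1 + rd2 + rd3 + rd4
    q[4] = p[10] * e_apt / (p[14] * (1.0 + sd - rd1) + c1)
    q[5] = p[11] * e_apt / (p[15] * (1.0 + sd - rd2) + c2)
    q[6] = p[12] * e_apt / (p[16] * (1.0 + sd - rd3) + c12)
    q[7] = p[13] * e_apt / (p[17] * (1.0 + sd - rd4) + c12)
    return q


def _rhs_closure(params: KineticParameters, pert: Perturbation):
    """Fast ODE right-hand side bound to one parameter set/perturbation."""
    p = params.to_array()
    mask = pert.palm_mask.astype(np.float64)
    scale = float(pert.pat_scale)
    syn = bool(pert.synthesis_on)

    def rhs(_t, y):
        return _deriv_nb(y, p, mask, scale, syn)

    return rhs


def _as_state(state) -> np.ndarray:
    y = state.to_array() if isinstance(state, SpeciesVector) else np.asarray(state, float)
    if y.shape != (5,):
        raise ValueError("state must have five entries")
    if np.any(y < 0):
        raise ValueError("state entries must be non-negative")
    return y


def _competitive_mm(substrates, kcats, kms, enzyme, mask) -> np.ndarray:
    """Competitive Michaelis-Menten rates for reactions sharing one enzyme.

    For reaction X with substrate S_X:

        v_X = kcat_X * E * S_X / (Km_X * (1 + sum_{Y != X} S_Y / Km_Y) + S_X)

    where the sum runs over the other *active* substrate-site pairs, each
    with its own Km.  Disabled reactions (mask 0) neither proceed nor
    compete.
    """
    s = np.asarray(substrates, float)
    km = np.asarray(kms, float)
    kc = np.asarray(kcats, float)
    m = np.asarray(mask, float)
    ratios = m * s / km
    comp = ratios.sum() - ratios  # sum over Y != X
    denom = km * (1.0 + comp) + s
    return m * kc * enzyme * s / denom


def _palm_rates_arr(y: np.ndarray, p: KineticParameters, pert: Perturbation) -> np.ndarray:
    subs = np.array([y[F], y[F], y[C1], y[C2]])
    kcats = np.array([p.kcat_p1, p.kcat_p2, p.kcat_p12, p.kcat_p21])
    kms = np.array([p.Km_p1, p.Km_p2, p.Km_p12, p.Km_p21])
    return _competitive_mm(subs, kcats, kms, pert.pat_scale * p.E_pat, pert.palm_mask)


def _depalm_rates_arr(y: np.ndarray, p: KineticParameters) -> np.ndarray:
    subs = np.array([y[C1], y[C2], y[C12], y[C12]])
    kcats = np.array([p.kcat_d1, p.kcat_d2, p.kcat_d121, p.kcat_d122])
    kms = np.array([p.Km_d1, p.Km_d2, p.Km_d121, p.Km_d122])
    return _competitive_mm(subs, kcats, kms, p.E_apt, np.ones(4))


def palmitoylation_rates(state, params: KineticParameters, perturbation: Perturbation = WT):
    """Rates (v_p1, v_p2, v_p12, v_p21) of the four acylation reactions.

    The four substrate-site pairs (fCAL site 1, fCAL site 2, c1CAL site 2,
    c2CAL site 1) compete for the shared DHHC6 pool; fCAL enters the
    competition once per site, with the site-specific Km.
    """
    return tuple(_palm_rates_arr(_as_state(state), params, perturbation))


def depalmitoylation_rates(state, params: KineticParameters):
    """Rates (v_d1, v_d2, v_d121, v_d122) of the four deacylation reactions."""
    return tuple(_depalm_rates_arr(_as_state(state), params))


def reaction_rates(state, params: KineticParameters, perturbation: Perturbation = WT) -> ReactionRates:
    """All 15 reaction rates at the given state."""
    y = _as_state(state)
    vp = _palm_rates_arr(y, params, perturbation)
    vd = _depalm_rates_arr(y, params)
    return ReactionRates(
        v_syn=params.v_syn if perturbation.synthesis_on else 0.0,
        v_fold=params.k_fold * y[R],
        v_p1=vp[0], v_p2=vp[1], v_p12=vp[2], v_p21=vp[3],
        v_d1=vd[0], v_d2=vd[1], v_d121=vd[2], v_d122=vd[3],
        v_deg_r=params.kdeg_r * y[R],
        v_deg_f=params.kdeg_f * y[F],
        v_deg_c1=params.kdeg_c1 * y[C1],
        v_deg_c2=params.kdeg_c2 * y[C2],
        v_deg_c12=params.kdeg_c12 * y[C12],
    )


def _deriv_arr(y: np.ndarray, p: KineticParameters, pert: Perturbation) -> np.ndarray:
    vp1, vp2, vp12, vp21 = _palm_rates_arr(y, p, pert)
    vd1, vd2, vd121, vd122 = _depalm_rates_arr(y, p)
    vsyn = p.v_syn if pert.synthesis_on else 0.0
    vfold = p.k_fold * y[R]
    d = np.empty(5)
    d[R] = vsyn - vfold - p.kdeg_r * y[R]
    d[F] = vfold - vp1 - vp2 + vd1 + vd2 - p.kdeg_f * y[F]
    d[C1] = vp1 - vp12 - vd1 + vd122 - p.kdeg_c1 * y[C1]
    d[C2] = vp2 - vp21 - vd2 + vd121 - p.kdeg_c2 * y[C2]
    d[C12] = vp12 + vp21 - vd121 - vd122 - p.kdeg_c12 * y[C12]
    return d


def derivatives(state, params: KineticParameters, perturbation: Perturbation = WT) -> np.ndarray:
    """Time derivative of the five species (mass balances)."""
    return _deriv_arr(_as_state(state), params, perturbation)


def simulate(
    initial,
    params: KineticParameters,
    perturbation: Perturbation = WT,
    times=None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Integrate the network over ``times`` (strictly increasing, hours).

    Returns an array of shape ``(len(times), 5)``; row 0 equals the initial
    state.  Uses LSODA (the system is stiff when depalmitoylation and
    degradation time scales separate widely).
    """
    y0 = _as_state(initial)
    t = np.asarray(times, float)
    if t.ndim != 1 or t.size < 1 or np.any(np.diff(t) <= 0) or t[0] < 0:
        raise ValueError("times must be a strictly increasing 1-d grid, times[0] >= 0")
    if t.size == 1:
        return y0[None, :].copy()

    sol = solve_ivp(
        _rhs_closure(params, perturbation), (t[0], t[-1]), y0,
        t_eval=t, method="LSODA", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    return np.clip(sol.y.T, 0.0, None)


def steady_state(
    params: KineticParameters,
    perturbation: Perturbation = WT,
    initial=None,
    tol: float = 1e-8,
    max_horizon: float = 10_000.0,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> np.ndarray:
    """Steady state, by long integration with a convergence test.

    Convergence criterion: ``max|dy/dt| / max(y) < tol``.  The integrated
    point is polished with a Newton-type root solve when that sharpens the
    residual.  Raises :class:`SteadyStateError` if the criterion is not met
    within ``max_horizon`` hours.
    """
    y = _as_state(initial) if initial is not None else np.zeros(5)
    if not perturbation.synthesis_on and y.sum() == 0:
        return y  # closed system from nothing stays nothing
    rhs = _rhs_closure(params, perturbation)

    def converged(yv):
        scale = max(yv.max(), atol)
        return np.abs(rhs(0.0, yv)).max() / scale < tol

    t_end, t0 = 100.0, 0.0
    while True:
        sol = solve_ivp(rhs, (t0, t_end), y, method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(f"steady-state integration failed: {sol.message}")
        y = np.clip(sol.y[:, -1], 0.0, None)
        # polish: Newton on the mass balances from the integrated point
        res = root(lambda yv: rhs(0.0, yv), y)
        if res.success and np.all(res.x > -atol):
            cand = np.clip(res.x, 0.0, None)
            if converged(cand):
                return cand
        if converged(y):
            return y
        t0, t_end = t_end, min(t_end * 10.0, max_horizon)
        if t0 >= max_horizon:
            raise SteadyStateError(
                f"no steady state within {max_horizon} h "
                f"(residual {np.abs(_deriv_arr(y, params, perturbation)).max():.3g})"
            )


def aa_steady_state_closed_form(params: KineticParameters) -> np.ndarray:
    """Closed-form steady state of the palmitoylation-deficient AA mutant.

    With all acylation off only synthesis, folding and degradation act:
    rCAL* = v_syn / (k_fold + kdeg_r), fCAL* = k_fold * rCAL* / kdeg_f.
    """
    r = params.v_syn / (params.k_fold + params.kdeg_r)
    f = params.k_fold * r / params.kdeg_f
    return np.array([r, f, 0.0, 0.0, 0.0])


def _percapita_rates(y: np.ndarray, p: KineticParameters, pert: Perturbation):
    """Per-capita (1/h) conversion rates of each species at background ``y``.

    For a Michaelis-Menten reaction the per-capita rate
    v_X / S_X = kcat_X E / (Km_X (1 + sum_{Y!=X} S_Y/Km_Y) + S_X)
    is well defined even at S_X = 0.
    """
    def percap(subs, kcats, kms, enzyme, mask):
        s = np.asarray(subs, float)
        km = np.asarray(kms, float)
        ratios = np.asarray(mask, float) * s / km
        comp = ratios.sum() - ratios
        return np.asarray(mask, float) * np.asarray(kcats, float) * enzyme / (
            km * (1.0 + comp) + s
        )

    qp = percap(
        [y[F], y[F], y[C1], y[C2]],
        [p.kcat_p1, p.kcat_p2, p.kcat_p12, p.kcat_p21],
        [p.Km_p1, p.Km_p2, p.Km_p12, p.Km_p21],
        pert.pat_scale * p.E_pat,
        pert.palm_mask,
    )
    qd = percap(
        [y[C1], y[C2], y[C12], y[C12]],
        [p.kcat_d1, p.kcat_d2, p.kcat_d121, p.kcat_d122],
        [p.Km_d1, p.Km_d2, p.Km_d121, p.Km_d122],
        p.E_apt,
        np.ones(4),
    )
    return qp, qd


def percapita_matrix(state, params: KineticParameters, perturbation: Perturbation = WT) -> np.ndarray:
    """Linear generator M of a tracer cohort at a fixed background state.

    A labeled sub-population that is chemically identical to the background
    (no isotope effect) evolves as dL/dt = M @ L + s(t), where s is any
    labeled synthesis input.  M is exact whenever the aggregate network sits
    at the background state (e.g. at steady state during a pulse-chase,
    where total synthesis is merely redirected between pools).
    """
    y = _as_state(state)
    p = params
    qp, qd = _percapita_rates(y, p, perturbation)
    qp1, qp2, qp12, qp21 = qp
    qd1, qd2, qd121, qd122 = qd
    M = np.zeros((5, 5))
    M[F, R] = p.k_fold
    M[R, R] = -(p.k_fold + p.kdeg_r)
    M[C1, F] = qp1
    M[C2, F] = qp2
    M[F, F] = -(qp1 + qp2 + p.kdeg_f)
    M[C12, C1] = qp12
    M[F, C1] = qd1
    M[C1, C1] = -(qp12 + qd1 + p.kdeg_c1)
    M[C12, C2] = qp21
    M[F, C2] = qd2
    M[C2, C2] = -(qp21 + qd2 + p.kdeg_c2)
    M[C2, C12] = qd121
    M[C1, C12] = qd122
    M[C12, C12] = -(qd121 + qd122 + p.kdeg_c12)
    return M
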