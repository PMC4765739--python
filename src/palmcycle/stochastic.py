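"""Stochastic formulation of the palmitoylation network.

Molecule-count simulation by the exact direct-method SSA, with hybrid
Michaelis-Menten propensities (the deterministic rate laws evaluated on
counts), and single-molecule tracking of the synthesis-to-dual-palmitoylation
lag.  Deterministic parameters are converted to count space by the scale
Omega = copies_total / (deterministic steady-state total): zero-order rates
and concentration-like quantities (Km, enzyme totals) scale with Omega,
first-order constants are unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .kinetics import _percapita_rates, _rates_nb, steady_state
from .params import C1, C12, C2, F, R, KineticParameters, Perturbation, WT

__all__ = [
    "StochasticParameters",
    "MoleculeTrace",
    "LagStatistics",
    "to_stochastic",
    "ssa_run",
    "track_molecule",
    "track_molecules",
    "lag_statistics",
    "mean_field_fate",
]

# Stoichiometric matrix, one row per reaction, columns (rCAL..c12CAL):
# synthesis, folding, p1, p2, p12, p21, d1, d2, d121, d122, 5x degradation.
STOICHIOMETRY = np.array(
    [
        [+1, 0, 0, 0, 0],   # synthesis -> rCAL
        [-1, +1, 0, 0, 0],  # folding
        [0, -1, +1, 0, 0],  # p1
        [0, -1, 0, +1, 0],  # p2
        [0, 0, -1, 0, +1],  # p12
        [0, 0, 0, -1, +1],  # p21
        [0, +1, -1, 0, 0],  # d1
        [0, +1, 0, -1, 0],  # d2
        [0, 0, 0, +1, -1],  # d121
        [0, 0, +1, 0, -1],  # d122
        [-1, 0, 0, 0, 0],   # degradation rCAL
        [0, -1, 0, 0, 0],   # degradation fCAL
        [0, 0, -1, 0, 0],   # degradation c1CAL
        [0, 0, 0, -1, 0],   # degradation c2CAL
        [0, 0, 0, 0, -1],   # degradation c12CAL
    ],
    dtype=np.int64,
)


@dataclass(frozen=True)
class StochasticParameters:
    """Count-space parameters: a scaled parameter set plus its scale."""

    params: KineticParameters  # Km, E and v_syn already in count units
    omega: float
    copies_total: float
    perturbation: Perturbation = WT


def to_stochastic(
    params: KineticParameters,
    copies_total: float,
    perturbation: Perturbation = WT,
) -> StochasticParameters:
    """Convert a deterministic parameter set to count space."""
    total = steady_state(params, perturbation).sum()
    omega = copies_total / total
    if not np.isfinite(omega) or omega <= 0:
        raise ValueError("non-positive scale Omega; steady-state total vanished")
    scaled = params.replace(
        v_syn=params.v_syn * omega,
        Km_p1=params.Km_p1 * omega, Km_p2=params.Km_p2 * omega,
        Km_p12=params.Km_p12 * omega, Km_p21=params.Km_p21 * omega,
        Km_d1=params.Km_d1 * omega, Km_d2=params.Km_d2 * omega,
        Km_d121=params.Km_d121 * omega, Km_d122=params.Km_d122 * omega,
        E_pat=params.E_pat * omega, E_apt=params.E_apt * omega,
    )
    return StochasticParameters(scaled, float(omega), float(copies_total), perturbation)


# propensity function: the deterministic rate law evaluated on counts
# (hybrid Michaelis-Menten propensities); shared with the ODE core
_propensities = _rates_nb


@njit(cache=False)
def _ssa_core(y0, p, mask, pat_scale, syn_on, t_grid, stoich, seed):  # pragma: no cover
    np.random.seed(seed)
    n_t = t_grid.shape[0]
    out = np.zeros((n_t, 5), dtype=np.int64)
    y = y0.copy().astype(np.float64)
    t = t_grid[0]
    k = 0
    while k < n_t:
        a = _propensities(y, p, mask, pat_scale, syn_on)
        a0 = a.sum()
        if a0 <= 0.0:
            t_next = np.inf
        else:
            t_next = t - np.log(np.random.random()) / a0
        while k < n_t and t_grid[k] <= t_next:
            for j in range(5):
                out[k, j] = np.int64(y[j])
            k += 1
        if k >= n_t:
            break
        if not np.isfinite(t_next):
            continue
        # choose reaction
        u = np.random.random() * a0
        c = 0.0
        idx = 14
        for j in range(15):
            c += a[j]
            if u <= c:
                idx = j
                break
        for j in range(5):
            y[j] += stoich[idx, j]
            if y[j] < 0:
                y[j] = 0
        t = t_next
    return out


def ssa_run(stoch: StochasticParameters, initial, t_grid, seed: int) -> np.ndarray:
    """Exact direct-method SSA trajectory sampled on ``t_grid``.

    Returns integer counts of shape ``(len(t_grid), 5)``; deterministic
    given ``seed``.
    """
    y0 = np.asarray(initial, float)
    if y0.shape != (5,) or np.any(y0 < 0):
        raise ValueError("initial counts must be five non-negative numbers")
    t = np.asarray(t_grid, float)
    pert = stoch.perturbation
    return _ssa_core(
        np.floor(y0),
        stoch.params.to_array(),
        pert.palm_mask.astype(np.float64),
        float(pert.pat_scale),
        pert.synthesis_on,
        t,
        STOICHIOMETRY,
        int(seed) % (2**31 - 1),
    )


# ---------------------------------------------------------------------------
# single-molecule tracking
# ---------------------------------------------------------------------------

_STATE_NAMES = {R: "rCAL", F: "fCAL", C1: "c1CAL", C2: "c2CAL", C12: "c12CAL"}


@dataclass
class MoleculeTrace:
    """Event history of one tagged molecule, from synthesis onwards."""

    times_h: list = field(default_factory=list)
    states: list = field(default_factory=list)
    terminal: str = ""  # "degraded" or "dual_palmitoylated"
    lag_h: float = float("nan")  # synthesis -> first entry into c12CAL
    palmitoylated_ever: bool = False


def _hazards(stoch: StochasticParameters):
    """Per-molecule transition hazards at the mean-field steady-state background.

    The tagged molecule is a continuous-time Markov chain over the five
    states; its hazard for a given reaction equals the per-capita rate of
    that reaction in the standing background (identical molecules are
    exchangeable), held constant at steady state.
    """
    p = stoch.params
    pert = stoch.perturbation
    bg = steady_state(p, pert)
    (qp1, qp2, qp12, qp21), (qd1, qd2, qd121, qd122) = _percapita_rates(bg, p, pert)
    # transitions[state] = list of (rate, target, kind)
    return {
        R: [(p.k_fold, F, "fold"), (p.kdeg_r, -1, "deg")],
        F: [(qp1, C1, "palm"), (qp2, C2, "palm"), (p.kdeg_f, -1, "deg")],
        C1: [(qp12, C12, "palm"), (qd1, F, "depalm"), (p.kdeg_c1, -1, "deg")],
        C2: [(qp21, C12, "palm"), (qd2, F, "depalm"), (p.kdeg_c2, -1, "deg")],
    }


def track_molecule(stoch: StochasticParameters, seed: int | None = None,
                   rng: np.random.Generator | None = None,
                   hazards=None) -> MoleculeTrace:
    """Track one tagged molecule from synthesis (rCAL) to its terminal event.

    The molecule is injected into the steady-state background and followed
    until degradation or first dual palmitoylation.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if hazards is None:
        hazards = _hazards(stoch)
    trace = MoleculeTrace(times_h=[0.0], states=["rCAL"])
    state, t = R, 0.0
    while True:
        moves = hazards[state]
        rates = np.array([m[0] for m in moves])
        total = rates.sum()
        if total <= 0:
            trace.terminal = "trapped"
            return trace
        t += rng.exponential(1.0 / total)
        kind_idx = rng.choice(len(moves), p=rates / total)
        rate, target, kind = moves[kind_idx]
        if kind == "palm":
            trace.palmitoylated_ever = True
        if kind == "deg":
            trace.times_h.append(t)
            trace.states.append("degraded")
            trace.terminal = "degraded"
            return trace
        trace.times_h.append(t)
        trace.states.append(_STATE_NAMES[target])
        if target == C12:
            trace.terminal = "dual_palmitoylated"
            trace.lag_h = t
            return trace
        state = target


def track_molecules(stoch: StochasticParameters, n: int, seed: int) -> list[MoleculeTrace]:
    """Track ``n`` independent tagged molecules (deterministic given seed)."""
    rng = np.random.default_rng(seed)
    hz = _hazards(stoch)
    return [track_molecule(stoch, rng=rng, hazards=hz) for _ in range(n)]


@dataclass
class LagStatistics:
    n: int
    n_dual: int
    n_degraded: int
    n_degraded_before_palm: int
    mean_lag_h: float
    median_lag_h: float
    lags_h: np.ndarray
    convergence: np.ndarray  # cumulative mean lag vs number of dual events


def lag_statistics(traces: list[MoleculeTrace]) -> LagStatistics:
    """Summary of synthesis-to-dual-palmitoylation lags over tracked molecules."""
    lags = np.array([tr.lag_h for tr in traces if tr.terminal == "dual_palmitoylated"])
    if lags.size == 0:
        raise ValueError("no molecule reached dual palmitoylation; lag undefined")
    n_deg = sum(tr.terminal == "degraded" for tr in traces)
    n_deg_before = sum(
        tr.terminal == "degraded" and not tr.palmitoylated_ever for tr in traces
    )
    conv = np.cumsum(lags) / np.arange(1, lags.size + 1)
    return LagStatistics(
        n=len(traces),
        n_dual=int(lags.size),
        n_degraded=int(n_deg),
        n_degraded_before_palm=int(n_deg_before),
        mean_lag_h=float(lags.mean()),
        median_lag_h=float(np.median(lags)),
        lags_h=lags,
        convergence=conv,
    )


def traces_to_frame(traces: list[MoleculeTrace]):
    """Long-format event table ``molecule_id, time_h, state, event``."""
    import pandas as pd

    rows = []
    for i, tr in enumerate(traces):
        for t, s in zip(tr.times_h, tr.states):
            rows.append((i, t, s, tr.terminal))
    return pd.DataFrame(rows, columns=["molecule_id", "time_h", "state", "event"])


@dataclass(frozen=True)
class MeanFieldFate:
    """Closed-form fate of a newly made molecule at the steady-state background."""

    p_dual: float           # reaches dual palmitoylation before degradation
    p_degraded: float
    p_degraded_before_palm: float  # degraded without a single acylation event
    mean_lag_h: float       # E[time to c12 | reaches c12]


def mean_field_fate(params: KineticParameters, perturbation: Perturbation = WT,
                    y_ss: np.ndarray | None = None) -> MeanFieldFate:
    """Absorption probabilities and conditional mean lag of the tracking chain.

    The tagged molecule is a CTMC over (rCAL, fCAL, c1CAL, c2CAL) with
    absorbing states "c12CAL" and "degraded"; all quantities follow from
    linear solves against the transient generator.  Serves as the exact
    mean-field oracle for :func:`track_molecules`.
    """
    bg = steady_state(params, perturbation) if y_ss is None else y_ss
    (qp1, qp2, qp12, qp21), (qd1, qd2, _qd121, _qd122) = _percapita_rates(
        bg, params, perturbation
    )
    p = params
    # transient generator over (R, F, C1, C2): T[i, j] = rate i -> j
    T = np.array(
        [
            [-(p.k_fold + p.kdeg_r), p.k_fold, 0.0, 0.0],
            [0.0, -(qp1 + qp2 + p.kdeg_f), qp1, qp2],
            [0.0, qd1, -(qp12 + qd1 + p.kdeg_c1), 0.0],
            [0.0, qd2, 0.0, -(qp21 + qd2 + p.kdeg_c2)],
        ]
    )
    a_dual = np.array([0.0, 0.0, qp12, qp21])
    h = np.linalg.solve(-T, a_dual)          # P(absorb at c12 | start state)
    g = np.linalg.solve(-T, h)               # E[tau * 1_dual]
    p_dual = h[0]
    mean_lag = g[0] / p_dual if p_dual > 0 else float("nan")
    # no-palmitoylation fate: make any acylation event absorbing
    T2 = np.array(
        [[-(p.k_fold + p.kdeg_r), p.k_fold], [0.0, -(qp1 + qp2 + p.kdeg_f)]]
    )
    a_deg2 = np.array([p.kdeg_r, p.kdeg_f])
    p_no_palm = np.linalg.solve(-T2, a_deg2)[0]
    return MeanFieldFate(
        p_dual=float(p_dual),
        p_degraded=float(1.0 - p_dual),
        p_degraded_before_palm=float(p_no_palm),
        mean_lag_h=float(mean_lag),
    )
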