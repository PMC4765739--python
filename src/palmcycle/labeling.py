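"""In-silico metabolic labeling experiments.

The network is duplicated into labeled and unlabeled pools that share every
rate constant (no isotope effect).  A 35S pulse redirects the synthesis flux
into the labeled pool; a 3H-palmitate pulse redirects the palmitate
*attachment* fluxes so that palmitates added during the pulse are labeled,
with site-resolved bookkeeping on the singly and dually acylated species.

Two solvers are provided.  Whenever the aggregate network sits exactly at
steady state throughout the protocol (the standard pulse-chase designs:
total synthesis or attachment flux is only redirected between pools, never
changed), the labeled pools obey piecewise-constant *linear* ODEs and are
propagated exactly through the matrix exponential.  Protocols that move the
aggregate state (palmitate incorporation under cycloheximide, synthesis
blockade before SNAP marking) use the general nonlinear two-pool
integrator.  The two routes agree to integrator tolerance and are
cross-checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from numba import njit

from .kinetics import (
    IntegrationError,
    _deriv_arr,
    _deriv_nb,
    _percap_nb,
    _percapita_rates,
    percapita_matrix,
    steady_state,
)
from .params import C1, C2, F, R, SPECIES, KineticParameters, Perturbation, WT

__all__ = [
    "PulseChaseProtocol",
    "TimeCourse",
    "simulate_pulse_chase_35S",
    "simulate_pulse_chase_3H",
    "simulate_3H_incorporation",
    "simulate_snap_decay",
    "species_distribution",
    "labeled_fraction_of_total",
    "apparent_half_life",
    "s35_protocol",
    "h3_pulse_protocol",
    "h3_incorporation_protocol",
    "snap_protocol",
]

LabelKind = Literal["S35", "H3_pulse_chase", "H3_incorporation", "SNAP_steady_state"]

# default sampling grids (h); the raw study time points are not public, so
# these cover both decay phases at desk scale
S35_CHASE_GRID = (0.0, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0, 48.0)
H3_CHASE_GRID = (0.0, 2.0, 4.0, 8.0, 12.0, 24.0)
H3_INCORPORATION_GRID = (1.0, 2.0, 3.0, 5.0, 7.0)
SNAP_CHASE_GRID = (0.0, 4.0, 8.0, 16.0, 24.0, 36.0, 48.0, 72.0, 96.0, 144.0)


@dataclass(frozen=True)
class PulseChaseProtocol:
    """Declarative description of an in-silico labeling experiment."""

    label_kind: LabelKind
    pulse_h: float
    chase_times_h: tuple
    perturbation: Perturbation = WT
    chx_pre_h: float = 0.0
    chx_during: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.chase_times_h, float)
        if t.ndim != 1 or t.size < 1 or np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("chase_times_h must be non-negative and increasing")
        if self.label_kind in ("S35", "H3_pulse_chase", "H3_incorporation"):
            if self.pulse_h <= 0:
                raise ValueError(f"{self.label_kind} requires pulse_h > 0")

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.chase_times_h, float)


def s35_protocol(perturbation: Perturbation = WT, pulse_h: float = 1.0 / 3.0,
                 chase_times_h=S35_CHASE_GRID) -> PulseChaseProtocol:
    """20-min 35S-Met/Cys pulse followed by a cold chase."""
    return PulseChaseProtocol("S35", pulse_h, tuple(chase_times_h), perturbation)


def h3_pulse_protocol(perturbation: Perturbation = WT, pulse_h: float = 2.0,
                      chase_times_h=H3_CHASE_GRID) -> PulseChaseProtocol:
    """2-h 3H-palmitate pulse followed by a cold chase."""
    return PulseChaseProtocol("H3_pulse_chase", pulse_h, tuple(chase_times_h), perturbation)


def h3_incorporation_protocol(perturbation: Perturbation = WT,
                              times_h=H3_INCORPORATION_GRID) -> PulseChaseProtocol:
    """Continuous 3H-palmitate labeling under cycloheximide (synthesis off)."""
    return PulseChaseProtocol(
        "H3_incorporation", float(np.asarray(times_h)[-1]), tuple(times_h), perturbation,
        chx_during=True,
    )


def snap_protocol(chx_pre_h: float = 0.0, perturbation: Perturbation = WT,
                  chase_times_h=SNAP_CHASE_GRID) -> PulseChaseProtocol:
    """Instantaneous whole-pool marking after an optional synthesis blockade."""
    return PulseChaseProtocol(
        "SNAP_steady_state", 0.0, tuple(chase_times_h), perturbation, chx_pre_h=chx_pre_h
    )


@dataclass
class TimeCourse:
    """A measured (or simulated) normalized signal versus time.

    ``sd`` optionally carries the per-point standard error of the (replicate
    averaged) signal; fitting objectives become chi-square when present.
    """

    times_h: np.ndarray
    signal: np.ndarray
    condition: str = ""
    normalization: int | None = 0
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, float)
        self.signal = np.asarray(self.signal, float)
        if self.times_h.shape != self.signal.shape:
            raise ValueError("times and signal must align")
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, float)
            if self.sd.shape != self.signal.shape or np.any(self.sd < 0):
                raise ValueError("sd must align with signal and be non-negative")

    def normalized(self) -> "TimeCourse":
        if self.normalization is None:
            return self
        ref = self.signal[self.normalization]
        return TimeCourse(self.times_h, self.signal / ref, self.condition, self.normalization)

    def to_frame(self, replicate: int = 0) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_h": self.times_h,
                "signal": self.signal,
                "condition": self.condition,
                "replicate": replicate,
            }
        )
        if self.sd is not None:
            df["sd"] = self.sd
        return df

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path, condition: str | None = None) -> "TimeCourse":
        df = pd.read_csv(path)
        if condition is not None:
            df = df[df["condition"] == condition]
        keys = {"signal": "mean"}
        if "sd" in df.columns:
            keys["sd"] = "mean"
        g = df.groupby("time_h", as_index=False).agg(keys)
        cond = condition or ""
        return cls(g["time_h"].to_numpy(), g["signal"].to_numpy(), cond,
                   sd=g["sd"].to_numpy() if "sd" in g.columns else None)


# ---------------------------------------------------------------------------
# linear (exact-at-steady-state) propagation
# ---------------------------------------------------------------------------

def _lin_solve(M: np.ndarray, b: np.ndarray | None, x0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Solve x' = M x + b (constant M, b) at the requested times.

    Uses the eigendecomposition of M; falls back to per-time matrix
    exponentials if M is close to defective.
    """
    times = np.asarray(times, float)
    if b is None:
        b = np.zeros(len(x0))
    # particular solution: x_p = -M^{-1} b (M invertible: every species degrades)
    xp = -np.linalg.solve(M, b)
    z0 = x0 - xp
    w, V = np.linalg.eig(M)
    try:
        c0 = np.linalg.solve(V, z0.astype(complex))
        ok = np.linalg.cond(V) < 1e10
    except np.linalg.LinAlgError:
        ok = False
    if ok:
        out = (V @ (np.exp(np.outer(times, w)) * c0).T).T.real + xp
    else:
        out = np.array([expm(M * t) @ z0 + xp for t in times])
    return np.clip(out, 0.0, None)


def _h3_label_system(y_ss: np.ndarray, params: KineticParameters, pert: Perturbation,
                     labeled_attach: bool):
    """Linear system for the labeled-palmitate sub-pools at steady state.

    State x = (c1*, c2*, c12[site1 labeled], c12[site2 labeled],
    c12[both labeled]); the unlabeled sub-pools are the steady-state
    complements.  Returns (A, b).
    """
    p = params
    (qp1, qp2, qp12, qp21), (qd1, qd2, qd121, qd122) = _percapita_rates(y_ss, p, pert)
    iC1, iC2, iLU, iUL, iLL = range(5)
    A = np.zeros((5, 5))
    b = np.zeros(5)
    A[iC1, iC1] = -(qp12 + qd1 + p.kdeg_c1)
    A[iC2, iC2] = -(qp21 + qd2 + p.kdeg_c2)
    for i in (iLU, iUL, iLL):
        A[i, i] = -(qd121 + qd122 + p.kdeg_c12)
    # site-2 removal returns c12 -> c1 keeping any site-1 label
    A[iC1, iLU] += qd122
    A[iC1, iLL] += qd122
    # site-1 removal returns c12 -> c2 keeping any site-2 label
    A[iC2, iUL] += qd121
    A[iC2, iLL] += qd121
    if labeled_attach:
        # new palmitates are hot: f -> c1*/c2*; c1 -> c12 gains hot site 2
        b[iC1] = qp1 * y_ss[F]
        b[iC2] = qp2 * y_ss[F]
        b[iUL] = qp12 * y_ss[C1]  # from unlabeled c1 (corrected below)
        b[iLU] = qp21 * y_ss[C2]
        A[iUL, iC1] -= qp12  # c1u = c1_ss - c1*, so hot c1 input moves to LL
        A[iLL, iC1] += qp12
        A[iLU, iC2] -= qp21
        A[iLL, iC2] += qp21
    else:
        # new palmitates are cold: labeled singles acylate into mixed c12
        A[iLU, iC1] += qp12
        A[iUL, iC2] += qp21
    return A, b


_H3_MOIETY_WEIGHTS = np.array([1.0, 1.0, 1.0, 1.0, 2.0])


@njit(cache=False)
def _incorp_rhs_nb(y, p, mask, pat_scale):  # pragma: no cover - jitted
    """Joint background + labeled-palmitate sub-pool derivative, synthesis off.

    y = (rCAL..c12CAL, c1*, c2*, c12[site1*], c12[site2*], c12[both*]).
    """
    bg = np.maximum(y[:5], 0.0)
    x = np.maximum(y[5:], 0.0)
    dbg = _deriv_nb(bg, p, mask, pat_scale, False)
    q = _percap_nb(bg, p, mask, pat_scale)
    qp1, qp2, qp12, qp21 = q[0], q[1], q[2], q[3]
    qd1, qd2, qd121, qd122 = q[4], q[5], q[6], q[7]
    k1, k2, k12 = p[20], p[21], p[22]
    c1u = max(bg[2] - x[0], 0.0)
    c2u = max(bg[3] - x[1], 0.0)
    out12 = qd121 + qd122 + k12
    dx = np.empty(5)
    dx[0] = qp1 * bg[1] - (qp12 + qd1 + k1) * x[0] + qd122 * (x[2] + x[4])
    dx[1] = qp2 * bg[1] - (qp21 + qd2 + k2) * x[1] + qd121 * (x[3] + x[4])
    dx[2] = qp21 * c2u - out12 * x[2]
    dx[3] = qp12 * c1u - out12 * x[3]
    dx[4] = qp12 * x[0] + qp21 * x[1] - out12 * x[4]
    return np.concatenate((dbg, dx))


def simulate_pulse_chase_35S(
    params: KineticParameters,
    protocol: PulseChaseProtocol,
    method: str = "linear",
    return_labeled: bool = False,
    y_ss: np.ndarray | None = None,
):
    """35S pulse-chase: synthesis redirected to the labeled pool for the pulse.

    Returns the normalized labeled-total time course; with
    ``return_labeled=True`` also the per-time labeled species array.
    ``y_ss`` may carry a precomputed steady state for the protocol's
    perturbation.
    """
    if protocol.label_kind != "S35":
        raise ValueError("protocol is not a 35S experiment")
    pert = protocol.perturbation
    if y_ss is None:
        y_ss = steady_state(params, pert)
    t = protocol.times
    if method == "linear":
        M = percapita_matrix(y_ss, params, pert)
        b = np.zeros(5)
        b[R] = params.v_syn if pert.synthesis_on else 0.0
        L0 = _lin_solve(M, b, np.zeros(5), np.array([protocol.pulse_h]))[0]
        L = _lin_solve(M, None, L0, t)
    elif method == "ode":
        L = _two_pool_protein(params, pert, y_ss, protocol.pulse_h, t)
    else:
        raise ValueError("method must be 'linear' or 'ode'")
    total = L.sum(axis=1)
    tc = TimeCourse(t, total / total[0], f"{pert.mutant}_35S")
    return (tc, L) if return_labeled else tc


def simulate_pulse_chase_3H(
    params: KineticParameters,
    protocol: PulseChaseProtocol,
    moiety_weighted: bool = True,
    return_pools: bool = False,
    y_ss: np.ndarray | None = None,
):
    """3H-palmitate pulse-chase with site-resolved label bookkeeping.

    During the pulse, palmitate attachments deposit labeled acyl groups;
    during the chase they deposit unlabeled ones.  The signal counts labeled
    palmitate moieties (a doubly labeled molecule contributes twice) unless
    ``moiety_weighted=False``.
    """
    if protocol.label_kind != "H3_pulse_chase":
        raise ValueError("protocol is not a 3H pulse-chase experiment")
    pert = protocol.perturbation
    if y_ss is None:
        y_ss = steady_state(params, pert)
    A_p, b_p = _h3_label_system(y_ss, params, pert, labeled_attach=True)
    x_pulse = _lin_solve(A_p, b_p, np.zeros(5), np.array([protocol.pulse_h]))[0]
    A_c, b_c = _h3_label_system(y_ss, params, pert, labeled_attach=False)
    x = _lin_solve(A_c, b_c, x_pulse, protocol.times)
    w = _H3_MOIETY_WEIGHTS if moiety_weighted else np.ones(5)
    sig = x @ w
    ref = sig[0] if sig[0] > 0 else 1.0
    tc = TimeCourse(protocol.times, sig / ref, f"{pert.mutant}_3H")
    return (tc, x) if return_pools else tc


def simulate_3H_incorporation(
    params: KineticParameters,
    protocol: PulseChaseProtocol,
    moiety_weighted: bool = True,
    normalize_to_first: bool = True,
    y_ss: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> TimeCourse:
    """3H-palmitate incorporation under cycloheximide (synthesis blocked).

    The aggregate pool decays during labeling, so the label sub-pools are
    integrated jointly with the nonlinear background.
    """
    if protocol.label_kind != "H3_incorporation":
        raise ValueError("protocol is not an incorporation experiment")
    if y_ss is None:
        y_ss = steady_state(params, protocol.perturbation)
    p_arr = params.to_array()
    mask = protocol.perturbation.palm_mask.astype(np.float64)
    pat = float(protocol.perturbation.pat_scale)

    t = protocol.times
    grid = t if t[0] == 0 else np.concatenate([[0.0], t])
    y0 = np.concatenate([y_ss, np.zeros(5)])
    sol = solve_ivp(lambda _t, y: _incorp_rhs_nb(y, p_arr, mask, pat),
                    (0.0, grid[-1]), y0, t_eval=grid, method="LSODA",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"incorporation integration failed: {sol.message}")
    x = np.clip(sol.y[5:, :].T, 0.0, None)
    if t[0] != 0:
        x = x[1:]
    w = _H3_MOIETY_WEIGHTS if moiety_weighted else np.ones(5)
    sig = x @ w
    if normalize_to_first and sig[0] > 0:
        sig = sig / sig[0]
        norm = 0
    else:
        norm = None
    return TimeCourse(t, sig, f"{protocol.perturbation.mutant}_3H_incorporation", norm)


def _two_pool_protein(params: KineticParameters, pert: Perturbation, y_ss: np.ndarray,
                      pulse_h: float, chase_times: np.ndarray) -> np.ndarray:
    """Nonlinear two-pool 35S reference route: returns labeled species per time."""

    def rhs(syn_labeled):
        def f(_t, y):
            u, l = np.maximum(y[:5], 0.0), np.maximum(y[5:], 0.0)
            agg = u + l
            M = percapita_matrix(agg, params, pert)
            du, dl = M @ u, M @ l
            if pert.synthesis_on:
                (dl if syn_labeled else du)[R] += params.v_syn
            return np.concatenate([du, dl])
        return f

    y0 = np.concatenate([y_ss, np.zeros(5)])
    sol = solve_ivp(rhs(True), (0.0, pulse_h), y0, method="LSODA", rtol=1e-10, atol=1e-14)
    if not sol.success:
        raise IntegrationError(sol.message)
    y1 = sol.y[:, -1]
    sol = solve_ivp(rhs(False), (0.0, chase_times[-1]), y1, t_eval=chase_times,
                    method="LSODA", rtol=1e-10, atol=1e-14)
    if not sol.success:
        raise IntegrationError(sol.message)
    return np.clip(sol.y[5:, :].T, 0.0, None)


def simulate_snap_decay(params: KineticParameters, protocol: PulseChaseProtocol,
                        rtol: float = 1e-10, atol: float = 1e-14) -> TimeCourse:
    """SNAP-tag style decay of the whole standing pool.

    Runs to steady state, blocks synthesis for ``chx_pre_h``, marks the
    entire standing population as labeled (labeling treated as
    instantaneous), then resumes synthesis into the unlabeled pool and
    follows the labeled total.
    """
    if protocol.label_kind != "SNAP_steady_state":
        raise ValueError("protocol is not a SNAP experiment")
    pert = protocol.perturbation
    y_ss = steady_state(params, pert)
    if protocol.chx_pre_h > 0:
        pert_off = Perturbation(pert.pat_scale, False, pert.mutant)
        sol = solve_ivp(
            lambda _t, y: _deriv_arr(np.maximum(y, 0.0), params, pert_off),
            (0.0, protocol.chx_pre_h), y_ss, method="LSODA", rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise IntegrationError(sol.message)
        y_mark = np.clip(sol.y[:, -1], 0.0, None)
    else:
        y_mark = y_ss

    def rhs(_t, y):
        u, l = np.maximum(y[:5], 0.0), np.maximum(y[5:], 0.0)
        M = percapita_matrix(u + l, params, pert)
        du, dl = M @ u, M @ l
        if pert.synthesis_on:
            du[R] += params.v_syn
        return np.concatenate([du, dl])

    t = protocol.times
    y0 = np.concatenate([np.zeros(5), y_mark])
    sol = solve_ivp(rhs, (0.0, t[-1]), y0, t_eval=t, method="LSODA",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(sol.message)
    lab = np.clip(sol.y[5:, :].T, 0.0, None).sum(axis=1)
    return TimeCourse(t, lab / lab[0], f"SNAP_chx{protocol.chx_pre_h:g}h")


def species_distribution(times: np.ndarray, labeled: np.ndarray) -> pd.DataFrame:
    """Fractional composition of the remaining labeled population per time."""
    labeled = np.asarray(labeled, float)
    totals = labeled.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("labeled population vanished; fractions undefined")
    frac = labeled / totals[:, None]
    df = pd.DataFrame(frac, columns=list(SPECIES))
    df.insert(0, "time_h", np.asarray(times, float))
    return df


def labeled_fraction_of_total(params: KineticParameters, pulse_h: float = 2.0,
                              perturbation: Perturbation = WT,
                              y_ss: np.ndarray | None = None) -> float:
    """Fraction of the total pool carrying label after a 3H pulse at steady state."""
    if y_ss is None:
        y_ss = steady_state(params, perturbation)
    proto = h3_pulse_protocol(perturbation, pulse_h=pulse_h, chase_times_h=(0.0, 1.0))
    _, pools = simulate_pulse_chase_3H(params, proto, return_pools=True, y_ss=y_ss)
    return float(pools[0].sum() / y_ss.sum())


def apparent_half_life(tc: TimeCourse, threshold: float = 0.5) -> float:
    """Time at which the normalized signal first crosses ``threshold``.

    Linear interpolation between grid points; NaN if the curve never
    crosses (right-censored).
    """
    s = tc.normalized().signal
    t = tc.times_h
    below = np.nonzero(s <= threshold)[0]
    if below.size == 0:
        return float("nan")
    i = below[0]
    if i == 0:
        return float(t[0])
    t0, t1, s0, s1 = t[i - 1], t[i], s[i - 1], s[i]
    return float(t0 + (s0 - threshold) / (s0 - s1) * (t1 - t0))
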