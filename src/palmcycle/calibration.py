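"""Ensemble parameter estimation by a multi-objective genetic algorithm.

Each calibration experiment is one objective (sum of squared residuals
between simulated and observed normalized signal).  The search runs NSGA-II
(non-dominated sorting, crowding distance, simulated binary crossover,
polynomial mutation) over log10-scaled parameters; the final population is
filtered by per-objective score thresholds into a :class:`ModelEnsemble`,
the unit of prediction (each member simulated independently; predictions
reported as pointwise mean with first/third quartile bands).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import steady_state
from .labeling import (
    PulseChaseProtocol,
    TimeCourse,
    simulate_3H_incorporation,
    simulate_pulse_chase_3H,
    simulate_pulse_chase_35S,
    simulate_snap_decay,
)
from .params import KineticParameters, Perturbation

__all__ = [
    "ExperimentSet",
    "ModelEnsemble",
    "score",
    "simulate_protocol",
    "fit_ensemble",
    "ensemble_predict",
    "EnsemblePrediction",
    "average_parameters",
    "SEARCH_PARAMETERS",
    "default_bounds",
]

#: Parameters explored by the GA.  ``v_syn``, ``E_pat`` and ``E_apt`` are
#: held fixed: all measurements are normalized intensities, so the overall
#: concentration scale (and with it the enzyme totals, which only enter
#: through kcat*E products) is not identifiable from the calibration data.
SEARCH_PARAMETERS = tuple(
    n for n in KineticParameters.names if n not in ("v_syn", "E_pat", "E_apt")
)


@dataclass(frozen=True)
class ExperimentSet:
    """Named (time course, protocol) pairs split into calibration/validation."""

    experiments: dict
    calibration: tuple
    validation: tuple = ()

    def __post_init__(self) -> None:
        missing = [n for n in (*self.calibration, *self.validation)
                   if n not in self.experiments]
        if missing:
            raise ValueError(f"experiments missing: {missing}")
        if set(self.calibration) & set(self.validation):
            raise ValueError("calibration and validation must be disjoint")

    def __getitem__(self, name: str):
        return self.experiments[name]

    def calibration_items(self):
        return [(n, *self.experiments[n]) for n in self.calibration]

    def validation_items(self):
        return [(n, *self.experiments[n]) for n in self.validation]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"calibration": list(self.calibration),
                    "validation": list(self.validation), "protocols": {}}
        for name, (tc, proto) in self.experiments.items():
            tc.save(directory / f"{name}.csv")
            manifest["protocols"][name] = {
                "label_kind": proto.label_kind,
                "pulse_h": proto.pulse_h,
                "chase_times_h": list(proto.chase_times_h),
                "pat_scale": proto.perturbation.pat_scale,
                "synthesis_on": proto.perturbation.synthesis_on,
                "mutant": proto.perturbation.mutant,
                "chx_pre_h": proto.chx_pre_h,
                "chx_during": proto.chx_during,
            }
        (directory / "experiments.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "ExperimentSet":
        directory = Path(directory)
        manifest = json.loads((directory / "experiments.json").read_text())
        experiments = {}
        for name, pr in manifest["protocols"].items():
            proto = PulseChaseProtocol(
                pr["label_kind"], pr["pulse_h"], tuple(pr["chase_times_h"]),
                Perturbation(pr["pat_scale"], pr["synthesis_on"], pr["mutant"]),
                pr["chx_pre_h"], pr["chx_during"],
            )
            df = pd.read_csv(directory / f"{name}.csv")
            df = df.groupby("time_h", as_index=False)["signal"].mean()
            tc = TimeCourse(df["time_h"].to_numpy(), df["signal"].to_numpy(), name)
            experiments[name] = (tc, proto)
        return cls(experiments, tuple(manifest["calibration"]),
                   tuple(manifest["validation"]))


def simulate_protocol(
    params: KineticParameters,
    protocol: PulseChaseProtocol,
    times=None,
    y_ss=None,
    fast: bool = False,
) -> np.ndarray:
    """Normalized signal of any labeling protocol at the requested times.

    ``fast`` loosens the integrator tolerances of the nonlinear protocols
    (used inside the GA objective, where 1e-6 relative accuracy is far below
    the measurement noise).
    """
    if times is not None and not np.array_equal(times, protocol.times):
        protocol = dc_replace(protocol, chase_times_h=tuple(np.asarray(times, float)))
    kind = protocol.label_kind
    if kind == "S35":
        return simulate_pulse_chase_35S(params, protocol, y_ss=y_ss).signal
    if kind == "H3_pulse_chase":
        return simulate_pulse_chase_3H(params, protocol, y_ss=y_ss).signal
    if kind == "H3_incorporation":
        rtol, atol = (1e-6, 1e-10) if fast else (1e-8, 1e-12)
        return simulate_3H_incorporation(params, protocol, y_ss=y_ss,
                                         rtol=rtol, atol=atol).signal
    if kind == "SNAP_steady_state":
        return simulate_snap_decay(params, protocol).signal
    raise ValueError(f"unknown label kind {kind!r}")


def score(params: KineticParameters, experiment_set: ExperimentSet,
          subset: str = "calibration", fast: bool = True) -> dict:
    """Per-experiment goodness of fit on normalized signals.

    Chi-square (residuals weighted by the per-point standard errors) when
    the time course carries them, plain sum of squared residuals otherwise.
    Simulation failures are encoded as infinite scores, never raised.
    """
    items = (experiment_set.calibration_items() if subset == "calibration"
             else experiment_set.validation_items())
    ss_kw = dict(rtol=1e-7, atol=1e-10, tol=1e-6) if fast else {}
    ss_cache: dict = {}
    out = {}
    for name, tc, proto in items:
        try:
            pert = proto.perturbation
            key = (pert.mutant, pert.pat_scale, pert.synthesis_on)
            if key not in ss_cache:
                ss_cache[key] = steady_state(params, pert, **ss_kw)
            sim = simulate_protocol(params, proto, times=tc.times_h,
                                    y_ss=ss_cache[key], fast=fast)
            resid = sim - tc.normalized().signal
            if tc.sd is not None and np.all(tc.sd > 0):
                resid = resid / tc.sd
            out[name] = float(np.sum(resid**2)) if np.all(np.isfinite(resid)) else np.inf
        except Exception:
            out[name] = np.inf
    return out


# ---------------------------------------------------------------------------
# NSGA-II
# ---------------------------------------------------------------------------

def _fast_non_dominated_sort(obj: np.ndarray) -> np.ndarray:
    """Pareto front index (0 = non-dominated) for each row of objectives."""
    n = obj.shape[0]
    rank = np.full(n, -1)
    dominated_by = [[] for _ in range(n)]
    n_dominating = np.zeros(n, int)
    for i in range(n):
        le = np.all(obj[i] <= obj, axis=1)
        lt = np.any(obj[i] < obj, axis=1)
        dom = le & lt  # i dominates j
        dom[i] = False
        for j in np.nonzero(dom)[0]:
            dominated_by[i].append(j)
        n_dominating += dom
    front = np.nonzero(n_dominating == 0)[0]
    r = 0
    while front.size:
        rank[front] = r
        nxt = []
        for i in front:
            for j in dominated_by[i]:
                n_dominating[j] -= 1
                if n_dominating[j] == 0:
                    nxt.append(j)
        front = np.array(sorted(set(nxt)), int)
        r += 1
    return rank


def _crowding_distance(obj: np.ndarray) -> np.ndarray:
    n, m = obj.shape
    d = np.zeros(n)
    for k in range(m):
        o = np.where(np.isfinite(obj[:, k]), obj[:, k], np.nanmax(
            np.where(np.isfinite(obj[:, k]), obj[:, k], np.nan)) if np.any(
            np.isfinite(obj[:, k])) else 1.0)
        order = np.argsort(o, kind="stable")
        span = o[order[-1]] - o[order[0]]
        d[order[0]] = d[order[-1]] = np.inf
        if span > 0 and n > 2:
            d[order[1:-1]] += (o[order[2:]] - o[order[:-2]]) / span
    return d


def _sbx(rng, a, b, eta=15.0):
    u = rng.random(a.shape)
    beta = np.where(u <= 0.5, (2 * u) ** (1 / (eta + 1)),
                    (1 / (2 * (1 - u))) ** (1 / (eta + 1)))
    swap = rng.random(a.shape) < 0.5
    c1 = 0.5 * ((1 + beta) * a + (1 - beta) * b)
    c2 = 0.5 * ((1 - beta) * a + (1 + beta) * b)
    child = np.where(swap, c1, c2)
    return np.clip(child, 0.0, 1.0)


def _poly_mutation(rng, x, prob, eta=20.0):
    y = x.copy()
    mask = rng.random(x.shape) < prob
    u = rng.random(x.shape)
    delta = np.where(u < 0.5, (2 * u) ** (1 / (eta + 1)) - 1,
                     1 - (2 * (1 - u)) ** (1 / (eta + 1)))
    y[mask] += delta[mask]
    return np.clip(y, 0.0, 1.0)


def _admissibility_refs(experiment_set, obj_names, obj_finite):
    """Per-objective admissibility scale: chi-square 99% quantile where the
    data carry standard errors, a robust population floor otherwise."""
    from scipy.stats import chi2 as _chi2

    best = np.min(obj_finite, axis=0)
    ref = np.maximum(np.maximum(best, np.percentile(obj_finite, 5, axis=0)),
                     1e-12)
    for j, n in enumerate(obj_names):
        tc = experiment_set[n][0]
        if tc.sd is not None and np.all(tc.sd > 0):
            ref[j] = float(_chi2.ppf(0.99, len(tc.times_h)))
    return ref


def _densify(evaluate, ax, ao, experiment_set, obj_names,
             n_evals, rng, z_cut: float = 2.0, sigma: float = 0.05,
             batch: int = 100):
    """Perturbation sampling of the admissible set.

    Seeds at the evaluated models whose every objective is within ``z_cut``
    times its admissibility scale; proposes lognormal perturbations (sigma
    in genotype units, i.e. fractions of the searched decade span) around
    random admissible members and keeps admissible offspring.
    """
    finite = np.all(np.isfinite(ao), axis=1)
    if not finite.any():
        return np.empty((0, ax.shape[1])), np.empty((0, ao.shape[1]))
    ref = _admissibility_refs(experiment_set, obj_names, ao[finite])
    worst = np.max(ao[finite] / ref, axis=1)
    cut = max(z_cut, float(np.min(worst)) * 1.05)
    pool_x = [x for x, w in zip(ax[finite], worst) if w <= cut]
    pool_o = [o for o, w in zip(ao[finite], worst) if w <= cut]
    if not pool_x:
        i = int(np.argmin(worst))
        pool_x, pool_o = [ax[finite][i]], [ao[finite][i]]
    new_x, new_o = [], []
    used = 0
    while used < n_evals:
        k = min(batch, n_evals - used)
        parents = rng.integers(0, len(pool_x), k)
        props = np.clip(
            np.array([pool_x[p] for p in parents])
            + rng.normal(0.0, sigma, (k, ax.shape[1])),
            0.0, 1.0,
        )
        pobj = evaluate(props)
        used += k
        ok = np.all(np.isfinite(pobj), axis=1) & np.all(pobj <= cut * ref, axis=1)
        for x, o in zip(props[ok], pobj[ok]):
            pool_x.append(x)
            pool_o.append(o)
            new_x.append(x)
            new_o.append(o)
    if not new_x:
        return np.empty((0, ax.shape[1])), np.empty((0, ao.shape[1]))
    return np.array(new_x), np.array(new_o)


@dataclass
class ModelEnsemble:
    """Admissible parameter sets with their per-objective scores."""

    members: list
    scores: pd.DataFrame
    thresholds: dict
    seed: int
    bounds: dict
    population_size: int = 0
    generations: int = 0

    def __len__(self) -> int:
        return len(self.members)

    def parameter_frame(self) -> pd.DataFrame:
        return pd.DataFrame([m.to_dict() for m in self.members])

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        table = pd.concat(
            [self.parameter_frame(), self.scores.add_prefix("score_")], axis=1
        )
        table.to_csv(directory / "ensemble.tsv", sep="\t", index=False)
        meta = {
            "seed": self.seed,
            "thresholds": self.thresholds,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "population_size": self.population_size,
            "generations": self.generations,
            "n_members": len(self.members),
        }
        (directory / "ensemble.meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "ModelEnsemble":
        directory = Path(directory)
        table = pd.read_csv(directory / "ensemble.tsv", sep="\t")
        meta = json.loads((directory / "ensemble.meta.json").read_text())
        pcols = [c for c in table.columns if not c.startswith("score_")]
        scols = [c for c in table.columns if c.startswith("score_")]
        members = [KineticParameters.from_dict(row[pcols].to_dict())
                   for _, row in table.iterrows()]
        scores = table[scols].rename(columns=lambda c: c[len("score_"):])
        return cls(members, scores, meta["thresholds"], meta["seed"],
                   {k: tuple(v) for k, v in meta["bounds"].items()},
                   meta["population_size"], meta["generations"])


def default_bounds(center: KineticParameters, span_decades: float = 4.0) -> dict:
    """Log-uniform search box spanning ``span_decades`` around a physiologic guess."""
    half = 10.0 ** (span_decades / 2.0)
    return {n: (getattr(center, n) / half, getattr(center, n) * half)
            for n in SEARCH_PARAMETERS}


def fit_ensemble(
    experiment_set: ExperimentSet,
    bounds: dict,
    population_size: int = 200,
    generations: int = 50,
    seed: int = 0,
    base_params: KineticParameters | None = None,
    threshold_factor: float | str = "auto",
    min_members: int | None = None,
    densify_evals: int = 4000,
    verbose: bool = False,
) -> ModelEnsemble:
    """NSGA-II search over log10-scaled parameters; returns the filtered ensemble.

    ``base_params`` supplies the fixed (non-searched) parameters.  Selection
    keeps final-population members whose score on every objective is within
    ``threshold_factor`` times the best score achieved for that objective,
    then removes strictly dominated members.  With six objectives a fixed
    small factor often empties the selection (the Pareto front trades the
    objectives against each other), so the default ``"auto"`` walks the
    ladder 1.5, 2, 3, 5, 8, 12, 20 and keeps the first factor admitting at
    least ``min_members`` members (default half the population, the
    desk-scale ensemble size).  Deterministic given ``seed``.
    """
    if population_size < 10:
        raise ValueError("population_size must be >= 10")
    if base_params is None:
        raise ValueError("base_params (fixed parameters and search center) required")
    rng = np.random.default_rng(seed)
    names = list(bounds)
    lo = np.log10([bounds[n][0] for n in names])
    hi = np.log10([bounds[n][1] for n in names])
    d = len(names)
    obj_names = list(experiment_set.calibration)

    def decode(x: np.ndarray) -> KineticParameters:
        vals = 10 ** (lo + x * (hi - lo))
        return base_params.replace(**dict(zip(names, vals)))

    def evaluate(pop: np.ndarray) -> np.ndarray:
        out = np.empty((pop.shape[0], len(obj_names)))
        for i, x in enumerate(pop):
            s = score(decode(x), experiment_set)
            out[i] = [s[n] for n in obj_names]
        return out

    # initial population: log-uniform within one decade of the physiologic
    # center (the search itself may roam the full bounds); rate constants
    # many decades from physiology rarely seed useful lineages
    center = np.array([
        (np.log10(getattr(base_params, n)) - l) / (h - l)
        for n, l, h in zip(names, lo, hi)
    ])
    span = 1.0 / (hi - lo)  # one decade in genotype units
    pop = np.clip(center + (rng.random((population_size, d)) - 0.5) * 2 * span,
                  0.0, 1.0)
    obj = evaluate(pop)
    archive_x, archive_obj = [pop.copy()], [obj.copy()]
    for gen in range(generations):
        rank = _fast_non_dominated_sort(obj)
        crowd = _crowding_distance(obj)
        # binary tournament on (rank, -crowding)
        cand = rng.integers(0, population_size, (population_size, 2))
        better = np.where(
            (rank[cand[:, 0]] < rank[cand[:, 1]])
            | ((rank[cand[:, 0]] == rank[cand[:, 1]])
               & (crowd[cand[:, 0]] >= crowd[cand[:, 1]])),
            cand[:, 0], cand[:, 1],
        )
        parents = pop[better]
        child = np.empty_like(parents)
        for i in range(0, population_size - 1, 2):
            if rng.random() < 0.9:
                child[i] = _sbx(rng, parents[i], parents[i + 1])
                child[i + 1] = _sbx(rng, parents[i + 1], parents[i])
            else:
                child[i], child[i + 1] = parents[i], parents[i + 1]
        if population_size % 2:
            child[-1] = parents[-1]
        child = _poly_mutation(rng, child, prob=1.0 / d)
        child_obj = evaluate(child)
        archive_x.append(child.copy())
        archive_obj.append(child_obj.copy())
        all_pop = np.vstack([pop, child])
        all_obj = np.vstack([obj, child_obj])
        rank = _fast_non_dominated_sort(all_obj)
        crowd = _crowding_distance(all_obj)
        order = np.lexsort((-crowd, rank))
        keep = order[:population_size]
        pop, obj = all_pop[keep], all_obj[keep]
        if verbose and (gen % 10 == 0 or gen == generations - 1):
            best = np.min(obj, axis=0)
            print(f"gen {gen:4d}  best per-objective SSE: "
                  + " ".join(f"{b:.3g}" for b in best))

    # densification: NSGA-II's diversity pressure retains per-objective
    # specialists and under-samples the jointly admissible region, so grow
    # the archive by perturbation sampling seeded at the best joint fits,
    # accepting candidates that stay admissible on every objective
    ax0 = np.vstack(archive_x)
    ao0 = np.vstack(archive_obj)
    if densify_evals > 0:
        dx, dobj = _densify(
            evaluate, ax0, ao0, experiment_set, obj_names,
            n_evals=densify_evals, rng=rng,
        )
        if len(dx):
            ax0 = np.vstack([ax0, dx])
            ao0 = np.vstack([ao0, dobj])
    # selection runs over every model evaluated during the search (the
    # population of candidate models), not just the survivors of the last
    # generation
    ax, ao = ax0, ao0
    _, uniq = np.unique(np.round(ax, 12), axis=0, return_index=True)
    ax, ao = ax[np.sort(uniq)], ao[np.sort(uniq)]
    finite = np.all(np.isfinite(ao), axis=1)
    if not finite.any():
        raise RuntimeError("every candidate failed to simulate; relax bounds")
    # per-objective admissibility reference: the 99% chi-square quantile at
    # the number of data points where the data carry standard errors (a
    # model is kept when it is statistically consistent with every
    # experiment), a robust population floor otherwise
    ref = _admissibility_refs(experiment_set, obj_names, ao[finite])
    if min_members is None:
        min_members = max(10, population_size // 2)
    worst_ratio = np.where(finite, np.max(ao / ref, axis=1), np.inf)
    if threshold_factor == "auto":
        admissible = np.nonzero(worst_ratio <= 2.0)[0]
        if admissible.size >= min_members:
            idx = admissible[np.argsort(worst_ratio[admissible], kind="stable")][:400]
            factor = float(min(2.0, worst_ratio[idx].max()))
        else:
            n_keep = int(min(max(min_members, 10), 400, finite.sum()))
            idx = np.argsort(worst_ratio, kind="stable")[:n_keep]
            factor = float(worst_ratio[idx[-1]])
    else:
        factor = float(threshold_factor)
        idx = np.nonzero(worst_ratio <= factor)[0]
        if idx.size == 0:
            raise RuntimeError(
                "no model passed the per-objective thresholds "
                f"(smallest worst-case score ratio {worst_ratio.min():.2f}); "
                "raise threshold_factor"
            )
    thresholds = {n: float(factor * r) for n, r in zip(obj_names, ref)}
    # drop strictly dominated members
    sel_obj = ao[idx]
    keep_nd = [i for k, i in enumerate(idx)
               if not np.any(np.all(sel_obj < ao[i], axis=1))]
    idx = np.array(keep_nd, int)
    members = [decode(x) for x in ax[idx]]
    scores = pd.DataFrame(ao[idx], columns=obj_names).reset_index(drop=True)
    return ModelEnsemble(
        members, scores, thresholds, seed,
        {n: tuple(bounds[n]) for n in names}, population_size, generations,
    )


@dataclass
class EnsemblePrediction:
    """Pointwise ensemble mean and first/third quartile band."""

    times_h: np.ndarray
    mean: np.ndarray
    q1: np.ndarray
    q3: np.ndarray
    condition: str = ""
    n_members: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.times_h, "mean": self.mean,
                             "q1": self.q1, "q3": self.q3})


def ensemble_predict(ensemble: ModelEnsemble, protocol: PulseChaseProtocol,
                     times=None) -> EnsemblePrediction:
    """Simulate every member independently; aggregate mean and quartiles."""
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    t = np.asarray(times if times is not None else protocol.times, float)
    curves = []
    for i, m in enumerate(ensemble.members):
        try:
            curves.append(simulate_protocol(m, protocol, times=t))
        except Exception as exc:  # non-convergent member
            warnings.warn(f"ensemble member {i} dropped: {exc}")
    arr = np.array(curves)
    return EnsemblePrediction(
        t, arr.mean(axis=0), np.percentile(arr, 25, axis=0),
        np.percentile(arr, 75, axis=0),
        condition=f"{protocol.perturbation.mutant}_{protocol.label_kind}",
        n_members=arr.shape[0],
    )


def average_parameters(ensemble: ModelEnsemble,
                       experiment_set: ExperimentSet | None = None,
                       refit_factor: float = 3.0) -> KineticParameters:
    """Geometric (log-space) mean of the ensemble parameters.

    If an experiment set is given, the averaged set is re-scored; a warning
    is emitted (the set still returned) when any objective exceeds
    ``refit_factor`` times the ensemble median for that objective.
    """
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    logs = np.log([m.to_array() for m in ensemble.members])
    avg = KineticParameters.from_array(np.exp(logs.mean(axis=0)))
    if experiment_set is not None:
        s = score(avg, experiment_set)
        med = ensemble.scores.median()
        bad = [n for n in experiment_set.calibration
               if s[n] > refit_factor * max(med[n], 1e-12)]
        if bad:
            warnings.warn(
                f"averaged parameter set fits worse than {refit_factor}x the "
                f"ensemble median on: {', '.join(bad)}"
            )
    return avg
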