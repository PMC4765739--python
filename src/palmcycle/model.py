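"""Model/Results facade over the calibration pipeline.

:class:`PalmitoylationModel` holds the experimental design (time courses +
protocols) and the search configuration; :meth:`PalmitoylationModel.fit`
runs the evolutionary ensemble calibration and returns
:class:`PalmitoylationResults`, which carries the admissible ensemble, its
scores, a representative (geometric-mean) parameter set, and the prediction
suite (curves with quartile bands, steady-state distributions, cohort
half-lives, fluxes, single-molecule statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import predictions as _pred
from .calibration import (
    EnsemblePrediction,
    ExperimentSet,
    ModelEnsemble,
    average_parameters,
    default_bounds,
    ensemble_predict,
    fit_ensemble,
    score,
)
from .labeling import (
    PulseChaseProtocol,
    TimeCourse,
    apparent_half_life,
    s35_protocol,
    simulate_snap_decay,
    snap_protocol,
)
from .params import KineticParameters, Perturbation, WT
from .stochastic import (
    LagStatistics,
    lag_statistics,
    mean_field_fate,
    to_stochastic,
    track_molecules,
)

__all__ = ["PalmitoylationModel", "PalmitoylationResults"]


class PalmitoylationModel:
    """Two-site palmitoylation cycle model bound to a set of experiments.

    Parameters
    ----------
    experiments
        Calibration/validation time courses with their protocols.
    base_params
        Fixed parameters and center of the search box (defaults to the
        physiologic baseline of the synthetic generator).
    bounds
        Log-uniform search box per parameter; defaults to four decades
        around ``base_params``.
    """

    def __init__(self, experiments: ExperimentSet,
                 base_params: KineticParameters | None = None,
                 bounds: dict | None = None):
        if base_params is None:
            from .synthetic import baseline_parameters

            base_params = baseline_parameters()
        self.experiments = experiments
        self.base_params = base_params
        self.bounds = bounds if bounds is not None else default_bounds(base_params)

    @classmethod
    def from_directory(cls, directory, **kw) -> "PalmitoylationModel":
        """Build from a saved dataset directory (see ExperimentSet.save)."""
        return cls(ExperimentSet.load(directory), **kw)

    @classmethod
    def from_synthetic(cls, seed: int = 0, noise=None, truth=None, **kw):
        """Build from a freshly generated synthetic dataset.

        Returns ``(model, truth)`` so recovery can be checked.
        """
        from .synthetic import generate_dataset, sample_ground_truth

        if truth is None:
            truth = sample_ground_truth(seed=seed)
        data = generate_dataset(truth, noise=noise, seed=seed)
        return cls(data, **kw), truth

    def score(self, params: KineticParameters, subset: str = "calibration") -> dict:
        return score(params, self.experiments, subset=subset)

    def fit(self, population_size: int = 200, generations: int = 50,
            seed: int = 0, **kw) -> "PalmitoylationResults":
        """Run the multi-objective evolutionary calibration.

        Deterministic given ``seed``.  The scale of the paper-style run
        (population 10,000) is available by passing ``population_size``;
        the default is the desk scale.
        """
        ensemble = fit_ensemble(
            self.experiments, self.bounds, population_size=population_size,
            generations=generations, seed=seed, base_params=self.base_params,
            **kw,
        )
        return PalmitoylationResults(self, ensemble)


@dataclass
class PalmitoylationResults:
    """Fitted ensemble with the prediction suite."""

    model: PalmitoylationModel
    ensemble: ModelEnsemble
    _avg: KineticParameters | None = field(default=None, repr=False)

    # -- parameters ---------------------------------------------------------
    @property
    def params(self) -> KineticParameters:
        """Geometric-mean (log-space averaged) parameter set."""
        if self._avg is None:
            self._avg = average_parameters(self.ensemble, self.model.experiments)
        return self._avg

    @property
    def scores(self) -> pd.DataFrame:
        return self.ensemble.scores

    def parameter_summary(self) -> pd.DataFrame:
        pf = self.ensemble.parameter_frame()
        out = pd.DataFrame(
            {
                "geometric_mean": np.exp(np.log(pf).mean()),
                "median": pf.median(),
                "q1": pf.quantile(0.25),
                "q3": pf.quantile(0.75),
            }
        )
        out.index.name = "parameter"
        return out

    # -- predictions --------------------------------------------------------
    def predict(self, protocol: PulseChaseProtocol, times=None) -> EnsemblePrediction:
        """Ensemble mean curve with first/third quartile band."""
        return ensemble_predict(self.ensemble, protocol, times=times)

    def apparent_half_life(self, protocol: PulseChaseProtocol, times=None) -> float:
        """50% crossing of the ensemble-mean normalized curve (h)."""
        pr = self.predict(protocol, times=times)
        return apparent_half_life(TimeCourse(pr.times_h, pr.mean))

    def steady_state_distribution(self, perturbation: Perturbation = WT,
                                  condition: str = "") -> pd.DataFrame:
        return _pred.distribution_report(self.ensemble, perturbation, condition)

    def species_half_lives(self, perturbation: Perturbation = WT) -> pd.DataFrame:
        return _pred.half_life_report(self.ensemble, perturbation=perturbation)

    def fluxes(self, perturbation: Perturbation = WT) -> pd.DataFrame:
        return _pred.flux_report(self.ensemble, perturbation)

    def site_rate_constants(self) -> pd.DataFrame:
        return _pred.site_rate_constants(self.ensemble)

    def palmitate_turnover(self, cohort_spec: str = "steady_state") -> np.ndarray:
        """Per-member apparent palmitate turnover times (h)."""
        return np.array([
            _pred.depalmitoylation_from_cohort(m, cohort_spec)
            for m in self.ensemble.members
        ])

    def snap_half_lives(self, chx_pre_h: float = 6.0, horizon: float = 200.0) -> np.ndarray:
        """Per-member whole-pool decay half-lives after synthesis blockade."""
        grid = np.linspace(0.0, horizon, int(horizon) + 1)
        return np.array([
            apparent_half_life(simulate_snap_decay(
                m, snap_protocol(chx_pre_h, chase_times_h=grid),
                rtol=1e-7, atol=1e-10,
            ))
            for m in self.ensemble.members
        ])

    def sensitivity(self, output_spec: str, perturbation: Perturbation = WT,
                    rel_delta: float = 0.01) -> pd.DataFrame:
        """Local sensitivities of a named output for the averaged parameters."""
        return _pred.sensitivity(self.params, output_spec, rel_delta, perturbation)

    # -- stochastic ---------------------------------------------------------
    def track(self, n: int = 5000, copies_total: float = 5e5,
              seed: int = 0) -> LagStatistics:
        """Single-molecule tracking on the averaged parameter set."""
        stoch = to_stochastic(self.params, copies_total)
        return lag_statistics(track_molecules(stoch, n, seed))

    def mean_field_fate(self):
        return mean_field_fate(self.params)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary table of the fit and headline predictions."""
        lines = []
        ens = self.ensemble
        lines.append("Calnexin palmitoylation cycle — ensemble calibration")
        lines.append("=" * 56)
        lines.append(f"members: {len(ens)}   population: {ens.population_size}"
                     f"   generations: {ens.generations}   seed: {ens.seed}")
        lines.append("")
        lines.append("Per-objective scores (chi-square):")
        desc = ens.scores.agg(["min", "median", "max"]).T
        lines.append(desc.round(2).to_string())
        lines.append("")
        grid = np.arange(0.0, 48.5, 0.5)
        wt = self.apparent_half_life(s35_protocol(chase_times_h=grid))
        aa = self.apparent_half_life(
            s35_protocol(Perturbation(mutant="AA"), chase_times_h=grid))
        lines.append(f"apparent half-life, 35S pulse-chase (ensemble mean curve):")
        lines.append(f"  WT: {wt:6.2f} h      AA mutant: {aa:6.2f} h")
        dist = self.steady_state_distribution()
        dual = dist[dist.species == "c12CAL"].iloc[0]
        lines.append(
            f"steady-state dually palmitoylated fraction: "
            f"{100 * dual['mean']:.1f}% (Q1 {100 * dual['q1']:.1f}, "
            f"Q3 {100 * dual['q3']:.1f})"
        )
        hl = self.species_half_lives()
        lines.append("cohort half-lives (h, ensemble median):")
        lines.append("  " + "   ".join(
            f"{r.species}: {r.median:.1f}" for r in hl.itertuples()))
        return "\n".join(lines)

    def plot_fit(self, condition: str, ax=None):
        """Data with the ensemble mean curve and quartile band."""
        import matplotlib.pyplot as plt

        tc, proto = self.model.experiments[condition]
        pr = self.predict(proto, times=np.linspace(
            tc.times_h[0], tc.times_h[-1], 100))
        if ax is None:
            _fig, ax = plt.subplots()
        ax.fill_between(pr.times_h, pr.q1, pr.q3, alpha=0.3, label="Q1-Q3")
        ax.plot(pr.times_h, pr.mean, label="ensemble mean")
        yerr = tc.sd if tc.sd is not None else None
        ax.errorbar(tc.times_h, tc.normalized().signal, yerr=yerr, fmt="o",
                    color="k", label="data")
        ax.set_xlabel("chase time (h)")
        ax.set_ylabel("normalized signal")
        ax.set_title(condition)
        ax.legend()
        return ax
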