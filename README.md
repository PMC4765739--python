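# palmcycle

Kinetic modelling of the two-site palmitoylation cycle of the ER chaperone
calnexin.

Calnexin carries two juxtamembrane cysteines (sites 1 and 2) that are
reversibly palmitoylated by the ER acyltransferase DHHC6 and deacylated by
a thioesterase pool. The protein therefore exists in five states — newly
synthesized (`rCAL`), folded non-palmitoylated (`fCAL`), singly acylated on
either site (`c1CAL`, `c2CAL`) and dually acylated (`c12CAL`) — whose
inter-conversion, synthesis and state-dependent degradation form an open
reaction network. Because no assay separates the acylation states directly,
the species distribution, the per-state half-lives and the
synthesis-to-acylation lag have to be inferred by fitting the network to
metabolic pulse-chase data. This package implements that pipeline for
modellers of reversible post-translational modification cycles:

* **Deterministic core** — mass balances with competitive Michaelis–Menten
  kinetics: the acylation reactions share one DHHC6 pool and the
  deacylation reactions one thioesterase pool, so for reaction *X* with
  substrate *S<sub>X</sub>*

  $$v_X = \frac{k^{cat}_X\,E\,S_X}{K^m_X\bigl(1+\sum_{Y\neq X} S_Y/K^m_Y\bigr)+S_X}.$$

  The form is validated against the explicit mass-action enzyme mechanism
  (the enzyme:substrate ratio is of order 1:500, deep in the
  quasi-steady-state regime).
* **In-silico labeling** — ³⁵S pulse-chase (synthesis flux redirected into a
  labeled pool), ³H-palmitate pulse-chase and incorporation (site-resolved
  labeled-acyl bookkeeping), and SNAP-style whole-pool marking after a
  cycloheximide block. Where the aggregate network sits at steady state the
  labeled pools follow exact piecewise-linear dynamics and are propagated
  through matrix exponentials.
* **Ensemble calibration** — NSGA-II over log-scaled parameters with one
  chi-square objective per calibration experiment; the admissible ensemble
  (models statistically consistent with every experiment) is selected from
  all evaluated candidates and is the unit of prediction (means with
  first/third quartile bands).
* **Stochastic layer** — exact direct-method SSA on molecule counts and
  single-molecule tracking of the synthesis-to-dual-acylation lag.
* **Synthetic data** — a generator that manufactures ground-truth parameter
  sets satisfying the study's summary constraints (WT apparent half-life
  ≈ 8 h, non-acylatable mutant ≈ 5 h, ≈ 70% dually acylated steady state,
  site-1-first cooperativity, …) plus noisy replicate datasets, so the whole
  pipeline is testable without downloads.

## Worked example

```python
import numpy as np
from palmcycle import PalmitoylationModel, s35_protocol

model, truth = PalmitoylationModel.from_synthetic(seed=2)
result = model.fit(population_size=200, generations=50, seed=3)
print(result.summary())
```

prints (abridged; ~2.5 minutes on one core):

```
Calnexin palmitoylation cycle — ensemble calibration
========================================================
members: 44   population: 200   generations: 50   seed: 3

Per-objective scores (chi-square):
                       min  median     max
AC_35S               19.98   34.06  240.11
WT_35S               17.48   88.77  274.23
WT_3H_incorporation   5.51   28.59  157.90
AC_3H                 5.33   25.51  231.71
AA_35S                0.94    7.04  191.64
WT_3H                 6.95   12.86  213.34

apparent half-life, 35S pulse-chase (ensemble mean curve):
  WT:   6.33 h      AA mutant:   5.71 h
steady-state dually palmitoylated fraction: 70.7% (Q1 65.5, Q3 75.5)
cohort half-lives (h, ensemble median):
  fCAL: 6.9   c1CAL: 31.8   c2CAL: 23.4   c12CAL: 53.6
```

The wild-type decay halves in ~6.3 h while the palmitoylation-deficient AA
mutant halves in ~5.7 h — acylation stabilizes the protein — and about 70%
of the steady-state pool is predicted to be dually acylated, with the
dually acylated cohort living roughly eight-fold longer than the folded
non-acylated one. `result.predict(s35_protocol())` returns any
labeling curve with its quartile band; `result.track(5000, seed=1)` runs
the single-molecule lag experiment.

## Layout

| module | contents |
| --- | --- |
| `palmcycle.params` | species/parameter containers, perturbations, config I/O |
| `palmcycle.kinetics` | rate laws, mass balances, integration, steady states |
| `palmcycle.labeling` | pulse-chase protocols and in-silico labeling |
| `palmcycle.calibration` | chi-square scoring, NSGA-II, ensemble selection |
| `palmcycle.stochastic` | SSA, parameter conversion, molecule tracking |
| `palmcycle.predictions` | distributions, cohort half-lives, fluxes, sensitivities |
| `palmcycle.synthetic` | ground-truth sampling and dataset generation |
| `palmcycle.model` | `PalmitoylationModel` / `PalmitoylationResults` facade |
| `palmcycle.cli` | `palmcycle synth/simulate/calibrate/predict/track/all` |

See `docs/methods.md` for the model assumptions, numerical choices and
known limitations.
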