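# Methods

## The model

Calnexin is treated as an open five-state reaction network: synthesis feeds
the newly made state `rCAL` at a constant rate `v_syn`; folding converts it
to `fCAL` at first order (`k_fold`); the two palmitoylation sites are
acylated and deacylated enzymatically; every state is degraded with its own
first-order constant. Fifteen reactions in total — synthesis, folding, four
acylations (`fCAL→c1CAL`, `fCAL→c2CAL`, `c1CAL→c12CAL`, `c2CAL→c12CAL`),
four deacylations (the reverse edges, with the two losses from `c12CAL`
resolved by site), and five degradations. A convenience switch
(`KineticParameters.tie_kdeg_rf`) ties the degradation of the unfolded and
folded states for the fourteen-reaction reading in which they are not
distinguished.

All four acylation reactions share one DHHC6 pool (`E_pat`) and all four
deacylation reactions one lumped thioesterase pool (`E_apt`, the enzyme
identity being unresolved for this substrate). Each reaction follows an
irreversible Michaelis–Menten law with free-substrate competition:

    v_X = kcat_X · E · S_X / ( Km_X · (1 + Σ_{Y≠X} S_Y / Km_Y) + S_X )

`fCAL` competes once per site (two terms, each with its own Km); reactions
removed by a site mutation neither proceed nor compete. No
enzyme-depletion correction is included: with a DHHC6:calnexin ratio of
order 1:500 the enzyme is far from stoichiometric, and the test suite
verifies the law against the explicit mass-action mechanism (free enzyme +
one complex per reaction, fast binding) to within 5% at enzyme:substrate
ratios up to 1:100.

**Units.** Concentrations are arbitrary units normalized so the wild-type
steady-state total is 1 (all measurements the model confronts are relative
intensities); time is hours. `E_pat` defaults to 1/500 of the pool.

**Numerics.** LSODA with rtol 1e-8 / atol 1e-10 (the network is stiff when
deacylation of the dually acylated state is slow); derivative kernels are
numba-compiled and shared verbatim with the stochastic propensities. Steady
states come from staged integration (horizon capped at 10,000 h) with a
Newton polish and the convergence test `max|dy/dt| / max(y) < 1e-8`.
Trajectories are clipped at zero; negative inputs are rejected.

## In-silico labeling

Labeling experiments duplicate the network into pools that share every
rate constant (no isotope effect):

* **³⁵S pulse-chase** — run to steady state, redirect the synthesis flux
  into a labeled pool for the pulse (default 20 min), redirect it back and
  follow the labeled total, normalized to the chase start.
* **³H-palmitate pulse-chase** — palmitate attachments deposit labeled acyl
  groups during the pulse (default 2 h) and unlabeled ones afterwards, with
  site-resolved bookkeeping (`c1*`, `c2*`, and `c12` with site 1, site 2 or
  both labeled). The default signal counts labeled moieties — a doubly
  labeled molecule contributes twice, as autoradiographic intensity is
  proportional to incorporated label — with per-molecule counting available
  as a switch.
* **³H incorporation** — continuous labeling with synthesis blocked
  (cycloheximide); degradation continues, so the background is integrated
  jointly with the label sub-pools.
* **SNAP-style marking** — optional synthesis blockade, then the entire
  standing pool is marked instantaneously (the 30-min labeling reaction is
  negligible against the relevant half-lives) and followed while synthesis
  refills the unlabeled pool.

Because a pulse-chase only redirects fluxes between pools, the aggregate
network sits exactly at its steady state throughout, and the labeled pools
obey piecewise-constant **linear** ODEs with per-capita rates frozen at
that steady state. These protocols are therefore solved exactly through
eigendecompositions/matrix exponentials; the general nonlinear two-pool
integrator (needed when the aggregate moves: incorporation under
cycloheximide, synthesis blockade before marking) is retained as the
reference route and the two are cross-checked in the tests. The same
linear machinery yields persisting-cohort half-lives (below) and 50%
crossings by bracketed root solves on the exact solution rather than grid
interpolation.

Apparent half-life = first 50% crossing of the normalized signal, linearly
interpolated when read off a sampled curve; right-censored curves report
NaN with the censoring horizon documented at each call site.

**Cohort half-life.** A labeled cohort initialized in one state is marked
within the steady-state population (synthesis feeds the unlabeled pool);
molecules keep cohort identity through state interconversion, and the
half-life is the time at which the cohort total halves. This persisting
cohort convention is the only reading under which a singly acylated cohort
can track the folded state while the dually acylated cohort is an order of
magnitude longer lived.

## Ensemble calibration

Each calibration experiment is one objective. Data carry per-point
standard errors (see the generator), so objectives are chi-squares;
without standard errors the score degrades to a plain sum of squared
residuals. Simulation failures score +∞ rather than raising.

The search is NSGA-II (non-dominated sorting, crowding distance, binary
tournament, SBX crossover η=15 at rate 0.9, polynomial mutation η=20 at
rate 1/d) over log10-scaled parameters. Searched: the 22 kinetic constants;
fixed: `v_syn`, `E_pat`, `E_apt`, because normalized intensities leave the
overall concentration scale — and with it the enzyme totals, which enter
only through kcat·E products — unidentifiable. Bounds default to four
decades around the physiologic baseline; the initial population is drawn
within one decade of it (rate constants many decades from physiology
rarely seed useful lineages — the search itself may roam the full box).

**Selection.** The admissible ensemble is drawn from *all* models evaluated
during the run, not the final population: the front's diversity pressure
retains per-objective specialists while the jointly consistent models live
at the knee. Two details matter with several objectives:

1. *Reference scales.* A min-relative threshold ("within a factor of the
   best score per objective") empties the selection, because single noisy
   curves can be overfit far below the attainable noise floor. Chi-square
   objectives instead use an absolute scale — the 99% chi-square quantile
   at the number of data points — so "admissible" means statistically
   consistent with every experiment; SSE objectives fall back to a robust
   floor (the lower 5% of evaluated models).
2. *Densification.* After the search, perturbation sampling around the
   jointly admissible models (lognormal proposals, offspring kept while
   every objective stays within twice its reference) populates the
   admissible region more evenly; 4,000 extra evaluations by default.

Members are then the models whose worst objective/reference ratio is
smallest (all ≤ 2 when enough exist, otherwise the best `min_members`,
default half the population, capped at 400), with strictly dominated
members removed. A fixed numeric `threshold_factor` reproduces plain
cut-off selection.

Predictions simulate every member independently and report the pointwise
mean with the first/third quartile band. `average_parameters` returns the
geometric (log-space) mean — rate constants are positive scale parameters —
and warns when that average fits any objective worse than three times the
ensemble median; with a heterogeneous admissible set the average is a
summary, not necessarily an admissible model itself.

## Stochastic layer

Deterministic parameters convert to count space by Ω = copies_total /
(deterministic steady-state total): zero-order rates, Michaelis constants
and enzyme totals scale with Ω, first-order constants are unchanged, and
propensities evaluate the deterministic rate laws on counts (hybrid
Michaelis–Menten propensities). The SSA is the exact direct method
(numba-compiled, seeded); no tau-leaping is needed at these event rates.
Tests verify that the ensemble mean tracks the ODE solution and that the
deviation shrinks with copy number.

**Single-molecule tracking.** A tagged molecule is injected as `rCAL` into
the steady-state background and followed until degradation or first entry
into the dually acylated state. The background is held at the mean-field
steady state, making the tagged molecule a continuous-time Markov chain
whose hazards are the per-capita reaction rates; its absorption
probabilities and conditional mean lag therefore also have closed forms
(`mean_field_fate`), used both as a fast oracle and inside the generator.
An agent-based simulation at 300 copies (every molecule individualized,
hazards from live counts, synthesis included) checks that the tagged
molecule is statistically exchangeable with molecules of the full system.

## Synthetic data generator

The generator manufactures the study conditions: ten labeling experiments
(six calibration — the AC and AA ³⁵S decays, the WT ³⁵S decay, WT ³H
incorporation, the AC and WT ³H decays; four validation — CA ³⁵S and ³H
decays and the WT ³⁵S decay under DHHC6 overexpression/silencing at
pat_scale 10 and 0.1), with replicate counts 3–7 as in the source assays
and multiplicative lognormal noise (CV 8% for ³⁵S, 12% for ³H; additive
Gaussian available as a robustness switch). Replicates are averaged, the
relative scatter is pooled across time points (per-point sample SDs at
n = 3–7 are far too unstable to weight a chi-square) and the resulting
standard errors accompany the mean curve. Default sampling grids cover
both decay phases: ³⁵S {0,1,2,4,8,12,24,48} h, ³H {0,2,4,8,12,24} h,
incorporation {1,2,3,5,7} h normalized to 1 h.

**Ground truth.** A truth parameter set is *designed*, not blindly sampled:
the free design variables are the steady-state composition and the
per-capita rates of the slow reactions, and the mass balances are solved
analytically for the remaining rates, so every decoded design has the
designed composition (dually acylated fraction exactly 0.70) as its steady
state. Seeded lognormal jitter plus bounded least squares in log-design
space then pulls the candidate onto the summary-constraint manifold:
apparent half-lives near 8 h (WT) and 5 h (non-acylatable mutant), cohort
half-life of the dually acylated state near 46 h, steady-state palmitate
turnover near 32 h, a ~60% chance of degradation before any acylation, a
mean acylation lag near 8 h, ≤3% labeling yield in a 2 h pulse, and
site-1-first cooperativity with occupancy-dependent deacylation.
Candidates violating the enforced constraints are rejected and resampled
with widening jitter; different seeds yield different admissible truths.

**A structural caveat.** Under this rate law the full wish list is
overdetermined. At steady state the maintenance flux of the dually
acylated pool ties together (i) the commitment probability of a singly
acylated molecule to proceed to dual acylation, (ii) the 2 h labeling
yield, and (iii) the palmitate turnover times. Consequences: a ~70% dual
fraction with a ~46 h dual-cohort half-life forces a high commitment
probability, which makes the *singly* acylated cohorts long-lived (tens of
hours rather than ~6.5 h); and a fast (~8 h) palmitate turnover of the 2 h
pulse cohort cannot coexist with a ≤3% labeling yield and a ~32 h
steady-state turnover. The refinement therefore treats those statistics as
soft anchors and settles the best joint compromise; the admissible truths
land at single-site cohort half-lives of ~15–28 h and a 2 h-pulse
turnover of ~35 h. An enzyme-sequestration (total-QSSA) variant of the
rate law could shift these couplings; that variant is out of scope here.

## What the synthetic data do and do not show

Passing the pipeline on generated data demonstrates correct bookkeeping,
a working estimator, and recovery of the identifiable structure — it does
not certify the biology of any real dataset. Two limits are worth naming.
First, the generator's noise is independent across replicates and
multiplicative; real pulse-chase data share gel- and normalization-level
errors. Second, at desk scale (population 200, 50 generations, CV 8–12%)
the six calibration curves identify the folded-state degradation constant
to a few percent and the headline curve shapes, but leave the single-site
branch broad: site-2 kinetics are probed directly by the AC-mutant
calibration experiments while site-1 kinetics enter only through the
wild-type curves (the CA data being reserved for validation), so
ensemble central values for the singly acylated cohort half-life, the
acylation-lag statistics and the steady-state turnover carry wide spreads
and can sit well away from the generating truth even when every member
fits the data. The quartile bands, not the means alone, are the
prediction.

## Defaults worth knowing

| quantity | default | why |
| --- | --- | --- |
| pulse lengths | 20 min (³⁵S), 2 h (³H) | assay protocol |
| DHHC6 silencing / overexpression | pat_scale 0.1 / 10 | order-of-magnitude perturbations; config-exposed |
| integrator tolerances | rtol 1e-8, atol 1e-10 (1e-7/1e-10 inside the GA objective) | objective accuracy far below measurement noise |
| GA | population 200, 50 generations, seed required | desk scale; the study-scale population of 10,000 is a config choice |
| ensemble size | ≤400, ≥ population/2 | admissible-set target |
| tracking | 5,000 molecules at 5·10⁵ copies | convergence of the mean lag well before 5,000 events |
| sensitivity step | central differences, ±1% | stable to step halving within 5% |

## Known limitations

* No phosphorylation state, no cytosolic-tail cleavage, no chaperone-client
  binding, no spatial effects; the thioesterase is one lumped pool.
* The competitive Michaelis–Menten law omits enzyme sequestration; it is
  validated against mass action at the physiologic enzyme ratio, but the
  structural couplings above are properties of this closure.
* The log-averaged parameter set used for tracking is a summary of a
  possibly multi-modal admissible set; its single-molecule statistics can
  deviate from the ensemble spread.
* `average_parameters`, cohort half-lives and turnover times right-censor
  at finite horizons (documented per function) and report NaN rather than
  extrapolating.
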