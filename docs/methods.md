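# Methods

## Model

A longitudinal microbiome study with perturbations is modelled as a finite
Markov decision process ⟨S, A, T, R⟩ with discount γ. The modelling
assumptions are:

- **Discrete states.** Microbial communities evolve continuously, but the
  samples are grouped into a small set of discrete community states
  (externally defined state types, or clusters of OTU vectors). Transitions
  are between states, not compositions.
- **Markov property.** The next state depends only on the current state and
  the action on the intervening interval, not on earlier history.
- **One MDP per perturbation.** Concurrent perturbations are modelled
  independently by default; a joint MDP over the cartesian product of a few
  action sets is available, at the cost of thinner count rows.
- **Stationarity.** A single transition table is estimated for the whole
  series; time-varying dynamics (e.g. ageing) surface as states rather than
  as non-stationary transitions.
- **State-only reward.** R maps states to {0, 1}; action costs and
  action-dependent rewards are out of scope.

Consecutive samples of a subject define a transition regardless of the gap
length (sampling frequency may differ between and within subjects); an
optional `max_gap` drops overly long intervals. Intervals whose perturbation
value is missing are skipped and counted. For interventions applied once at
the outset whose effect persists (e.g. a vaccine before day 0), the
`subject_constant` action mode propagates the subject-level value to every
interval.

## Estimation and solving

Transition rows are multinomial maximum-likelihood estimates,
P(s′|s, a) = counts(s, a, s′)/Σ counts(s, a, ·). (s, a) pairs with no
observations carry no information; they are filled by a configurable rule —
`self_loop` (default: an unknown action is presumed to keep the state;
conservative for policy search because it makes unexplored actions
unattractive wherever staying is suboptimal) or `uniform` — and flagged in
an `observed_mask` that downstream evaluation can consult.

Value iteration uses span-seminorm stopping: iterate V ← max_a [R + γ T_a V]
until span(V_{n+1} − V_n) < ε(1 − γ)/γ, which guarantees the greedy policy
is ε-optimal. Because span stopping leaves V short of the fixed point by
approximately a constant, the midpoint correction c·γ/(1 − γ) with
c = (max Δ + min Δ)/2 is applied before reporting values, so the returned V
satisfies ‖V − (R + γ T_π V)‖∞ < ε. Greedy ties break to the lowest action
index in schema order; this makes policies, and therefore stability ratios,
reproducible run to run.

## Parameters that matter

| parameter | default | notes |
|---|---|---|
| `min_reads` | 10 000 | samples with total reads strictly below are dropped; exactly 10 000 is kept |
| `normalize` | percent | rows rescaled to sum 100; `proportion` (sum 1) offered for numeric work |
| discount γ | 0.9 | unitless; the method's results are reported at an explicitly pinned γ — indefinite-horizon value iteration requires one even though the estimation step does not |
| ε (stopping) | 1e-6 | in reward units; drives the span threshold above |
| `prior_pseudocount` | 0.5 | Jeffreys-style pseudocount added **only** to Dirichlet rows containing a zero count; rows with all-positive counts use the raw counts as hyper-parameters |
| stability `n` | 1000 | resampled tables per stability report |
| clustering distance | Jensen–Shannon on proportions | Bray–Curtis and Euclidean available |
| k selection | max mean silhouette over k ∈ [k_min, k_max] | 5 seeded restarts per k |
| diversity metric | Shannon, natural log | the utility definition does not name an index; Shannon (nats) is the default, with base-2 and Gini–Simpson as options |

## Design choices where the design was open

- **Clustering stage.** The state-definition clustering is implemented as
  k-medoids (k-medoids++ seeding, alternating assignment/medoid update)
  over a precomputed distance matrix, with silhouette-based k selection and
  optional bootstrap cluster-wise Jaccard stability. This captures "robust
  clustering by compositional similarity" at the level the pipeline needs;
  the stage is pluggable — any function producing a `StateAssignment` can
  replace it.
- **Utility ties.** `R_best`/`R_not_worst` are undefined when argmax/argmin
  of U is tied; the package raises and asks for an external utility rather
  than breaking the tie silently.
- **Same-or-better direction.** Published descriptions of the LOOCV
  "same-or-better" criterion disagree internally about the inequality's
  direction (the formula as printed reads U(from) ≥ U(to), while the
  figure-level definition sorts states by diversity so that "better" means
  higher utility). This package uses U(to) ≥ U(from): a transition is
  *better* when the landing state has strictly higher utility, *equal* at
  equal utility, *worse* otherwise.
- **Aggregate stability.** The aggregate ratio is the mean over states of
  the reference action's resampling frequency. Averaging over states first
  or over resampled policies first yields the same number under this
  definition.
- **LOOCV compliance.** "Following the policy" is an exact action match
  (exact tuple match for combined actions). Transitions out of states the
  training fold never visited are reported in a separate `unscored` bucket
  and excluded from the frequencies.
- **Dominant-taxa filter.** "Dominant" is a cut on overall mean relative
  abundance (threshold, e.g. 1 % or 0.5 %), not on rank.
- **Discretisation bins** are left-closed, right-open, last bin closed
  above: with levels low/med/high and edges 10, 50, the value 10 maps to
  *med*.
- **Combined action labels** concatenate member labels in schema order, so
  two binary treatments {s, c} × {p, c} yield {cc, cp, sc, sp}. A warning
  fires beyond 16 combined actions — the table becomes too sparse to
  estimate (8 binary perturbations would already give 2⁸ = 256 actions).

## The synthetic-data generator

`GeneratorSpec`/`generate_cohort` simulate exactly the model under test: a
true ⟨S, A, T⟩ drives per-subject state sequences (initial state uniform
unless weighted; actions per-interval random or per-subject constant), and
each sample's counts are drawn multinomially at fixed read depth from a
Dirichlet around the state's taxon profile. The Dirichlet concentration is
the single knob coupling state separability to clustering difficulty
(defaults: 200 for realistic overdispersion with clearly separated states;
24 subjects × 6 time points, read depth 20 000, mirroring a small
animal-study design).

What the generator does **not** emulate: ecological interactions
(Lotka–Volterra-style dynamics), compositional zero-inflation beyond what
Dirichlet-multinomial sampling produces, uneven read depths, irregular
sampling grids (available via per-subject time-point lists but not the
default), or non-Markovian history effects. Passing tests therefore show the
pipeline is correct *for data generated by the model it assumes*; they do
not certify the Markov or discretisation assumptions on real cohorts.
Ground-truth state sequences are returned out of band so tests can score
recovery without leaking truth into pipeline inputs.

## Numerical notes and degenerate inputs

- Transition rows reproduce counts exactly when multiplied back by row
  sums (pure division, no smoothing on observed rows).
- Jensen–Shannon distance of identical compositions evaluates 0/0 inside
  scipy; it is mapped to 0.
- Clustering refuses fewer distinct compositions than `k_min`; an all-zero
  abundance row has undefined diversity and is rejected.
- Dirichlet resampling of an all-zero count row requires a positive
  pseudocount (the distribution is undefined at α = 0).
- All stochastic stages (clustering restarts, bootstrap, Dirichlet
  resampling, the generator) consume a single explicit seed each;
  pipeline-level runs thread one master seed through every stage.

## Problem sizes used by the shipped checks

The test suite and the acceptance script run entirely on synthetic cohorts:
the analytic random-policy floor at 100 000 sampled policies; solver
correctness on twenty 4-state × 3-action MDPs against exhaustive
enumeration of all 81 deterministic policies; stability asymptotics at
count scale ×1000 with 1000 Dirichlet resamples; LOOCV on 20 subjects × 11
time points; and whole-pipeline recovery on 100 subjects × 51 time points
(5000 triples, concentration 500), where the estimated table matches the
generator row-wise within 0.03 total variation and the solved policy equals
the policy solved on the true table.

## Known limitations

- Policies are evaluated retrospectively; imposing a learned policy on new
  subjects (prospective validation) is outside the package.
- No cost model: an action with marginal benefit and high real-world cost
  is still recommended.
- The aggregate stability ratio weights all states equally, including
  states visited rarely.
- Finite-horizon solving, partially observed states and continuous state
  spaces are not supported.
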