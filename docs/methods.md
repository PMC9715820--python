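# Methods

## Model

Follow-up after a baseline heart-failure assessment is discretised into
consecutive half-open 4-calendar-month windows ("cycles"):
cycle *k* covers `[baseline + 4(k−1) months, baseline + 4k months)`. Month
arithmetic is calendar-based with day-of-month overflow clamped to the month
end (31 October + 4 months → 28/29 February), and window starts are always
computed from the baseline date directly so clamping cannot accumulate.

Within each cycle a patient occupies exactly one of five states — Dead (D),
Left (L), Hosp (H), OPD (O), NoEvent (N) — with within-cycle precedence
D > H > O: death dominates because it is absorbing and defined for any
cause; hospitalization counts with or without a clinic visit; a clinic
visit counts only without admission or death. An event-free cycle is N if
any event occurs in a later window and L otherwise; L is therefore
*backdated* to the first fully event-free cycle of a terminal silent run.
Both D and L are absorbing by construction. Boundary dates belong to the
later cycle (half-open windows), so no event is ever counted twice.

The process is modelled as a time-homogeneous absorbing Markov chain over
the canonical state order (D, L | H, O, N):

```
P = [[I, 0], [R, Q]]
```

Transition tallies are formed per transition index *t* (t = 1 is baseline →
cycle 1, with every patient starting in the OPD pseudo-state at baseline;
t = 2 is cycle 1 → cycle 2), and the chain is the row-normalized tally. The
default model uses the second transition only — the first transition starts
from a degenerate all-OPD origin and supplies just the initial distribution
— with count-pooling available as an alternative. Long-run quantities come
from the fundamental matrix `F = (I − Q)⁻¹` (expected visits per transient
state before absorption; row sums = expected cycles to absorption) and
`B = F·R` (absorption probabilities). Internally these are computed by
linear solves of `(I − Q)`, never explicit inversion; `F` is still exposed
densely because the matrix itself is the reported object.

Forward validation iterates `P` from the *observed* cycle-2 distribution, so
cycles 1–2 carry no prediction, and reports the signed error
predicted − observed (negative = underestimation) per state and cycle.

## Assumptions

* One step of memory: the next state depends only on the current state, not
  on how it was reached, and the one-step matrix estimated at the second
  transition is assumed to hold for all later cycles.
* States are exhaustive and mutually exclusive given the precedence rules.
* Absorption is certain: the spectral radius of Q must be < 1 (checked; a
  waiver exists for degenerate algebraic cases such as the identity chain).
* Left means true disengagement, not administrative censoring: cycles whose
  window crosses the study end date are excluded from transition counting
  rather than coerced to L (a dated death in such a window is still
  recorded, since deaths are known independently of service contact).

## Published reference values

The package ships the transition blocks, first-transition tallies and
observed per-cycle distributions published for a UK single-centre registry
of 7496 consecutive patients. Three caveats, all disclosed in code and
repair reports:

* the printed O→L entry (0.18) makes that row sum to 1.09 and contradicts
  the published limiting matrix; it is treated as unspecified and completed
  by the unit-row-sum constraint (0.09), which reproduces the published
  limiting matrix and prediction table. The unprinted N→L entry completes
  to 0.00 the same way.
* the published long-run summary was evidently computed from unrounded
  source matrices: exact inversion of the printed 2-dp Q gives
  F[N,N] = 7.0325 and a NoEvent total of 10.5633 against printed 7.02 and
  10.55, and a Hosp-origin death probability of 0.4382 against printed
  0.43 (the NoEvent-origin value likewise computes to 0.52 vs printed
  0.51). These cells cannot be regenerated from the printed inputs; the
  package reports what the printed inputs imply.
* the published observed cycle-6 row lists four values for five states;
  the missing state is not identified, so that row carries a NaN and is
  never used as a numeric target.

## Synthetic cohort generator

Real registries of this kind are not publicly deposited, so every pipeline
stage is validated against a generator with a known ground truth. Each
patient starts at a common baseline date; a latent state path is simulated
— cycle 1 from a configurable first-transition distribution (default: the
published count-based fractions 427/1842/1559/2254/1414 over 7496, used
because the published 2-dp probabilities sum to 1.01), later cycles from
the ground-truth chain (default: the repaired reference chain) — and each
latent state is realized as one dated event drawn uniformly *strictly
inside* its window (Hosp → one admission, OPD → one visit, Dead → one death;
N and L → nothing). Strict interiority makes generator → state-engine
reconstruction unambiguous. Covariates (age, sex, LVEF, NT-proBNP with a
0.15 missingness fraction emulating the assay's mid-study introduction) are
drawn from marginals matching the published cohort summaries and are
independent of the trajectory by default; a hook can couple age/sex to
different ground-truth chains for subgroup-recovery tests.

**Identifiability of Left.** L and N both produce no events in their cycle;
they differ only in whether an event ever follows. A latent NoEvent run
that reaches the study end is therefore observationally identical to Left,
and the state engine — correctly, given the definitions — labels it Left.
Exact generator → engine recovery is accordingly asserted against the
*canonical observable path* (the latent path with terminal silent runs
relabelled L); with the default ground truth N→L = 0, this relabelling only
concerns runs that hit the horizon. The effect biases estimated
disengagement upward by roughly `0.63^(horizon−2)` per NoEvent cell, so
short simulated studies are not in the regime the estimator assumes:
recovery and self-consistency tests simulate 18–24-cycle (6–8-year)
horizons, where the bias (~4·10⁻⁵) is far below sampling error — matching
the multi-decade follow-up of the registries this emulates. The generator's
default horizon of 12 cycles (the 4-year long-term reporting window) is
convenient for demonstrations but too short for unbiased L estimation.

**What passing tests do not show.** The generator is exactly Markov,
time-homogeneous past cycle 1, with one event per state-cycle, a common
baseline date, and trajectory-independent covariates. Real cohorts have
staggered enrolment, repeated admissions within a cycle (the engine
tolerates them; the generator never emits them), long admissions spanning
windows (counted in the admission-date cycle only), covariate-dependent
dynamics, and no guarantee of Markovianity — so parameter recovery here
validates the *software*, not the clinical model.

## Numerical conventions and edge cases

* Probabilities are kept at full precision everywhere; table presentation
  rounds half away from zero to 2 dp (the convention of printed clinical
  tables, where 0.145 → 0.15).
* Row-stochasticity is validated to 1e-9; `F·(I−Q) = I` holds to 1e-10 in
  tests; the Neumann-series and Monte-Carlo oracles use 1e-8 and 3-SE
  bands respectively.
* A transient origin with no observed transitions is an error by default;
  an optional self-loop fallback (with warning) exists for exploratory
  subgroup fits and waives the certain-absorption check.
* Matrix repair accepts, per row, either a fully specified row within a
  sum tolerance of 1 (renormalized) or exactly one unspecified entry
  (completed by the unit-sum complement, clamped at 0); anything else is a
  validation error naming the offending rows.
* Subgroup models (sex; age ≥65/<65) are fitted as fully independent
  pipelines per stratum; strata must partition the cohort.

## Problem sizes

Desk-scale reproductions run from the 5×5 printed blocks in milliseconds.
Stochastic validation uses 20 000-patient cohorts for routine tests and
100 000 patients (18–24 cycles) for parameter-recovery and
self-consistency checks, with 10⁵ Monte-Carlo walks per origin for the
absorption oracle — sizes chosen so 3-SE bands sit well below the effects
being checked.

## Known limitations

* Time-homogeneity beyond the second transition is assumed, not tested;
  the predicted-vs-observed table is exactly the diagnostic for it.
* The censoring rule (exclude incomplete windows) is a documented choice;
  the source analyses do not state how enrolment near the study end was
  handled.
* No confidence intervals on transition probabilities, and no
  covariate-conditional chains beyond stratified refits.
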