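# Methods

## Model structure and assumptions

The package implements a cohort-level (Markov) state-transition model
with three health states — progression-free (PFS), progressed disease
(PD), death — monthly cycles, and a 10-year horizon. Transitions are
unidirectional: metastatic disease does not regress, so PD → PFS is
impossible and death is absorbing. The entire cohort enters in PFS.
Transition probabilities, state costs and utilities are constant over
time (no tunnel states, no time-varying hazards); adverse-event and
monitoring costs are assumed to be rolled into the per-state monthly
cost totals. The death state accrues neither cost nor utility and there
are no one-off transition costs.

Monthly transition probabilities are derived from cohort event counts
under a constant-hazard assumption: the naive cumulative proportion
`P = events/cohort` over the follow-up window `t` is converted to a
yearly rate `r = −ln(1−P)/t` and re-expressed over one month as
`1 − e^{−r/12}`. One month is exactly 1/12 year — the model is defined
on a monthly grid and the cycle and discount units must agree, so no
30/365 calendar correction is applied. The proportion estimator ignores
censoring and competing risks by design; its bias is *quantified* with
the synthetic-cohort generator (below) rather than corrected, because it
is the estimator actually used to produce the model's inputs. A
cumulative probability of exactly 1 raises an explicit infinite-rate
error instead of propagating `inf`.

## Numerical conventions

* **Within-cycle correction**: each cycle is credited with the
  trapezoidal average `(s_{k−1} + s_k)/2` of its boundary occupancies,
  the standard life-table correction. End-of-cycle and start-of-cycle
  variants remain selectable (`correction: none | start`); the corrected
  totals always lie between those two (property-tested).
* **Discounting**: per-cycle factor `(1+ρ)^{−(k−0.5)/12}` at the default
  annual rate ρ = 3.5 % — mid-cycle timing, chosen to be consistent with
  trapezoidal crediting; cycle-start and cycle-end variants are provided.
  Life-years are discounted with the same factor as costs and QALYs, and
  an undiscounted life-year total is always reported alongside.
* These conventions were fixed once by calibrating against the published
  base-case results of the source analysis (which states only "within-
  cycle-corrected" and "3.5 % annual discounting") and are frozen in the
  shipped configuration; with them the published per-arm costs and QALYs
  are reproduced to well under 0.1 %.
* The shipped configuration resolves two internal inconsistencies in the
  published input tables in favour of the values that reproduce the
  published results arithmetic: ribociclib monthly PFS cost 10,285.1 QAR
  (not 10,258.1) and ribociclib PFS utility 0.70 (not 0.710). The
  as-printed alternative pair is retained as
  `fixtures.ribociclib_table1_printed()`. One published figure — the
  palbociclib life-year total of 5.968 — cannot be reproduced under any
  correction/discounting convention (the same trace reproduces the
  ribociclib total, 6.330, to four significant figures, and the
  discounted palbociclib value is 5.698); it is reported as computed.
* Occupancy conservation is maintained to ~1e−12 per cycle (exact matrix
  multiplication, no renormalisation); tests assert conservation at
  1e−10 and death-occupancy monotonicity.

## Incremental analysis

Deltas are intervention − comparator (ribociclib − palbociclib in the
shipped configuration). Dominance is classified on the CE plane with
axis points folded into the weak categories (cheaper and no less
effective ⇒ dominant). ICER (per LY) and ICUR (per QALY) are computed
only in the trade-off quadrants; `NMB(λ) = λ·ΔQALY − ΔC`, and adoption
requires strictly positive NMB (an ICUR exactly at the threshold is
rejected — a conservative, deterministic tie rule).

## Deterministic sensitivity analysis

Each of the eight uncertain inputs is set to its lower and upper bound
in turn (one-sided published ranges are honoured as printed, not
symmetrised) with everything else at base case, and the model re-run in
full. Tornado ordering uses the spread of incremental NMB at the 3×GDP
threshold across the two bounds, because the ICUR is undefined in the
dominance regions this comparison occupies. Threshold search brackets a
decision flip by bisection to a tolerance of 1e−4 of the parameter's
base value, after a 64-point monotonicity pre-scan; two or more sign
changes on the scan grid raise an ambiguity error rather than returning
a bracket-dependent answer.

## Probabilistic sensitivity analysis

The eight parameters are given Gamma (costs) or Beta (probabilities,
utilities) distributions matched by method of moments to their published
mean and SD (`shape = m²/s², scale = s²/m`; for Beta,
`k = m(1−m)/s² − 1`, `α = mk`, `β = (1−m)k`, feasible only when
`s² < m(1−m)`). Draws are independent (no correlation structure is
specified by the source), generated parameter-major from a single
`numpy.random.default_rng(seed)` stream, so a run is reproducible from
the seed alone. A sampled PFS→PD probability whose sum with the arm's
fixed PFS→death probability exceeds 1 is rejected and redrawn; the count
of redraws is recorded on the result (at the shipped distributions this
is a negligible tail event). Beta-sampled utilities are not truncated
beyond their inherent [0, 1] support, so one arm's draw may cross the
other arm's fixed value.

Each draw rebuilds both arms and runs them through a vectorised batch
implementation of the identical cycle recursion (verified equivalent to
the scalar engine at 1e−12 relative tolerance), which keeps 10,000 draws
× 120 cycles × 2 arms around two seconds.

ICE-plane classification reports all five exhaustive categories
(dominant, NE below WTP, NE above WTP, SW, dominated). Two aggregates
are exposed because usage in the applied literature differs:
`favoring_below_wtp` (dominant + NE draws with ICUR < λ) and
`favoring_quadrant` (dominant + the entire NE quadrant); the source
analysis's headline "favoring" percentage is the quadrant-sum variant,
as its own quadrant percentages show. The CEAC reports the fraction of
draws with strictly positive NMB per WTP grid point; it is not forced to
be monotone (it need not be when SW/dominance mixtures are present), and
it can exceed the ICE "favoring" share because large cost savings with
small QALY losses also yield positive NMB.

## Synthetic individual-patient data

`generate_cohort` simulates the registry-style data the estimation chain
consumes: exponential time to PFS exit (rate = sum of the two PFS exit
hazards, cause drawn proportionally), exponential post-progression
survival, administrative censoring at a fixed horizon (default 4 years,
an observation-window length typical of the real-world cohorts such
models are estimated from), optional exponential dropout, and Gamma
monthly costs per state (month billed to the state occupied at its
start). Defaults plant the yearly hazards implied by the base-case
palbociclib monthly probabilities.

What the generator does *not* emulate: time-varying hazards, cure
fractions, itemised cost components, or informative censoring. Passing
recovery tests therefore show that the estimation chain is correctly
implemented and consistent under its own constant-hazard assumption —
not that the naive estimator is unbiased on real registry data. Indeed
the chain is consistent only when a single risk is active: with
competing PFS exits, or with delayed PD entry, the cumulative-proportion
estimator is structurally biased (and degrades as the horizon grows,
since the event proportion approaches 1 and the implied rate collapses
toward 0). Tests therefore check exact recovery of planted monthly
probabilities (n = 50,000, within 3 Monte-Carlo SEs via the delta
method) in single-risk configurations, and separately verify that the
full competing-risk configuration lands on its analytic estimand
(`expected_counts`), quantifying the bias direction (underestimation).

## Problem sizes and defaults

Base case and DSA are deterministic 120-cycle runs (milliseconds). The
PSA default is 10,000 draws, matching the source analysis; Monte-Carlo
standard errors on quadrant shares are then ≈0.5 percentage points. The
synthetic-cohort default in the shipped configuration is 2,000 patients
(a realistic single-centre scale); recovery tests use 50,000 to push
sampling error well below the 3-SE acceptance band.

## Known limitations

* Two-strategy comparisons only; no efficiency frontier or extended
  dominance over ≥3 strategies.
* No EVPI/EVPPI and no correlated (copula) PSA sampling.
* Constant hazards throughout; no parametric survival extrapolation.
* The probability/rate chain deliberately reproduces the naive
  cumulative-proportion estimator, censoring bias included.
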