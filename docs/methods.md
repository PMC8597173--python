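# Methods

## Model structure

The model is an average-cohort (Markov) state-transition model with five
health states defined on the visual acuity of the better-seeing eye
(BSE), incorporating both eyes: state 1 is unilateral DMO with good
acuity, states 2–4 are bilateral DMO with acuity bands ≥ 0.5,
[0.3, 0.5) and [0.05, 0.3), and state 5 is bilateral blindness
(< 0.05). Structural assumptions:

* every patient starts in state 1; there is no cured state and no
  transition back into state 1 (treatment, once started, continues for
  the whole follow-up);
* state 5 is absorbing; there is no background mortality and no other
  exit, so cohort mass is conserved exactly;
* transitions follow acuity-line changes: a 2-line change moves one
  state, a 3-line change can move two states (two-state jumps are
  allowed in both directions except into state 1);
* each strategy has an *early* transition matrix for cycles starting
  before month 12 and a *late* one afterwards, because first doses are
  more effective than later ones.

The cycle length equals the re-dosing interval: 5 months for the
dexamethasone implant (2.4 doses/year), 4 months for triamcinolone
(3 doses/year), fixed over the whole horizon. Horizons of 2 and 5 years
and discount rates of 0% and 3% per annum are run by default.

### Cycle grid and the truncated final cycle

A horizon that is not an integer number of cycles (24 months at
5-month cycles = 4.8) is handled as 4 full cycles plus one truncated
cycle of weight 0.8. The state transition in the truncated cycle is
applied in full — a state change is a discrete event tied to the dose —
while cost and QALY accrual is weighted by the fraction. This preserves
the annual utilisation figure of 2.4 doses/year without inventing an
extra dose. No half-cycle correction is applied: occupancy at the cycle
start is used for the whole cycle's accrual. Period selection (early
vs late) uses the cycle *start* time; a cycle beginning at month 10
uses the early matrix even though it ends after month 12, since dosing
and its effect are delivered at the start. Cycles starting exactly at
month 12 use the late matrix.

## Cost and QALY accrual

Per cycle, with occupancy taken at the cycle start:

* **Drug + administration.** One dose per treated eye:
  `treated_eyes = (1, 2, 2, 2, 0)`. Both eyes of a bilateral patient
  are treated, which doubles drug costs in states 2–4. Blind patients
  (state 5) receive no drug by default; because treatment is described
  both as continued throughout follow-up and as ending at the model
  endpoint, this is exposed as the `treat_in_state5` switch.
* **Follow-up** (OCT + medical visit 690, IOP measurement 988,
  angiography 77 EUR/person-year) accrues pro rata temporis for states
  1–4. Whether monitoring continues for blind patients is unstated in
  the source material; the default stops it (switch
  `followup_in_state5`).
* **Rehabilitation** (2496 + 2176 + 2648 = 7320 EUR/person-year) accrues
  for states 4 and 5.
* **Adverse events** strike the drug-treated population, i.e. states
  1–4 by default (they are treatment-caused). Recurring events (IOP
  medication, endophthalmitis, retinal detachment) contribute
  `treated x incidence x unit cost` every cycle. Once-only events
  (cataract surgery, laser and vitrectomy for IOP elevation) use a
  saturating ledger: each cycle the not-yet-affected treated fraction
  incurs the per-cycle incidence, and the affected fraction accumulates
  toward 1. This is the reading most consistent with per-cycle printed
  incidences plus a once-per-follow-up rule. The alternative reading —
  one lump sum of `incidence x unit cost` in the first cycle — is
  available as `once_only_mode = "lump_sum"`. Notably, the published
  per-year treatment cost totals are numerically much closer to the
  lump-sum reading; the saturating default is kept deliberately (it is
  the internally consistent interpretation of per-cycle incidences) and
  the discrepancy is treated as a known limitation, not calibrated
  away.
* **QALYs**: occupancy-weighted utilities times cycle duration.
  Base utilities (0.97, 0.89, 0.81, 0.55, 0.40); alternative (Sharma)
  set (0.93, 0.85, 0.66, 0.58, 0.53). Adverse events carry no
  disutility (costs only).

Discounting multiplies each cycle's costs and QALYs by
`(1 + r)^(-t_start)` with `t_start` in (possibly fractional) years.
At r = 0 discounted and undiscounted totals are identical by
construction. Currency is EUR at 2019 prices; no inflation adjustment.

## Incremental analysis

Deltas are reference (dexamethasone) minus comparator (triamcinolone).
The ICER `ΔC/ΔQ` is reported as a price only when ΔQ > 0 and neither
strategy dominates; when the reference costs more and yields less the
comparator is flagged dominant and the signed quotient is kept as a
secondary field (negative "ICERs" are ambiguous as bare numbers, though
they are sometimes printed). A WTP decision accepts the reference iff
it dominates or its ICER does not exceed the threshold; acceptance is
monotone in the threshold. ICERs are undefined when |ΔQ| < 1e-12.

### Sensitivity analyses

Three deterministic one-way scenarios are bundled: triamcinolone cycle
shortened to 3 months, dexamethasone implant price reduced by 20%, and
the alternative utility set. Scenarios run on deep copies; the base
configuration is never mutated. When matrices are synthetic, the
3-month scenario regenerates the triamcinolone matrices for the
3-month cycle, because the generator's disease progression is a
per-month hazard and per-cycle probabilities are therefore
cycle-length-dependent; reusing 4-month per-cycle probabilities on a
3-month grid would silently speed up the disease by a third.
Explicitly supplied matrices *are* reused unchanged on the shorter
grid (there is nothing to re-estimate them from), and that reuse is
the documented caveat of the scenario in that case.

## Synthetic transition matrices

The evaluation that this model operationalises drew its transition
probabilities from a meta-aggregation of 19 studies available only as a
supplement; they are treated strictly as inputs here and never
hard-coded. The generator emulates their documented structure with a
low-dimensional parameterisation:

* **Worsening** is a per-month hazard per state
  (`base_progression`, defaults (0.037, 0.0005, 0.039, 0.015) /month);
  the per-cycle probability is `1 − exp(−hazard x cycle_months)`, so the
  5-month implant cycle carries proportionally more per-cycle worsening
  than the 4-month injection cycle. Triamcinolone's hazards are scaled
  by `1 + progression_penalty_triamcinolone` (default 0.36),
  representing its markedly heavier adverse-event burden (e.g. roughly
  double the cataract incidence) degrading acuity.
* **Improvement** is per dose from states 3 and 4
  (`base_improvement`, defaults (0.27, 0.22)); states 1–2 cannot improve
  because improvement may never target state 1. Triamcinolone's
  improvement probabilities are scaled by
  `1 + improvement_advantage_triamcinolone` (default 1.0), keeping them
  elementwise at least dexamethasone's, as direct comparisons report.
  After month 12 improvements shrink by `early_late_decay`
  (default 0.91), making the early matrix more favourable.
* **Two-state jumps** (3-line changes) get `jump_damping` (default 0.5)
  times the one-state probability, in both directions where allowed.
* A seeded log-normal **jitter** (sd 0.02) perturbs the base rates,
  shared across strategies and periods so the structural orderings are
  preserved exactly; generation is bit-reproducible given the seed.

Infeasible parameter combinations (row movement exceeding 1) raise a
generation error naming the row. A validator reports *all* violations
of the structural invariants at once and can additionally check the
early ≥ late and triamcinolone ≥ dexamethasone improvement orderings.

### Calibration and the default parameters

`calibrate_matrices` inverts the model: Nelder-Mead minimisation of the
mean squared relative error between model outputs and expected
cost/QALY targets, in log/logit-transformed parameter space so every
candidate is feasible by construction. Only the ~10 generator
parameters move, never the 50 matrix entries — four targets cannot
identify dozens of free probabilities. Self-generated targets are
recovered to ~1e-16; 1%-perturbed targets to well within 2%.

The shipped defaults were fixed once by calibrating against the
published per-1000-patient 2-year expected costs and QALYs (0% and 3%)
under the constraint that the published qualitative directions hold: a
positive, finite 2-year ICER; triamcinolone cheaper *and* more
effective at 5 years; and the sensitivity-ICER ordering
price-cut < 3-month-cycle < base at 2 years. Under the defaults the
2-year dexamethasone advantage is a transient retention effect (its
longer interval spreads the per-dose load while triamcinolone's
progression penalty bites early), and the 5-year reversal emerges as
triamcinolone's per-dose improvement advantage compounds on the growing
below-state-1 population — the same "the longer the horizon, the better
the injections" mechanism the original analysis describes.

### What the synthetic matrices do and do not show

The achieved fit is deliberately reported rather than polished away:
model QALYs land within ~5–8% of the published 2-year values and costs
overshoot by ~20–30%. Three structural reasons, all documented above,
bound the attainable fit: (i) the published 2-year dexamethasone QALYs
(2016.28 per 1000) exceed the 24-month accrual ceiling of the truncated
final-cycle rule (1000 x 0.97 x 2 = 1940) and are consistent instead
with five full cycles (25 months); (ii) the saturating once-only ledger
accrues substantially more adverse-event cost than the published annual
totals imply; (iii) the bilateral drug doubling prices every
below-state-1 patient at twice the drug cost, so any progression at all
lifts costs above the published figures. Consequently, passing tests
demonstrate that the *engine, accrual rules, analytics and qualitative
economics* are correct, and that the generator reproduces the published
decision pattern and orderings — not that the synthetic matrices equal
the unavailable literature-derived probabilities, and not that the
headline published ICERs (56,591 or 56,243 EUR/QALY at 2 years,
−1,110,942 at 5 years) are numerically reproduced.

## Numerical choices

* Row-stochasticity tolerance 1e-9; occupancy conservation asserted to
  1e-6 per 1000 persons; ICER degeneracy cutoff |ΔQ| < 1e-12.
* Cycle-count arithmetic tolerates 1e-9 relative float error before
  declaring a fractional final cycle.
* Discounting compounds the annual rate to fractional years (the rates
  are quoted per annum; sub-annual cycles need a continuous-time
  convention).
* Calibration: Nelder-Mead, default budget 2000 evaluations,
  `xatol 1e-6 / fatol 1e-14`; non-convergence is reported in the fit
  report, never raised; the incoming spec is kept if the optimiser
  fails to improve on it.
* Zero horizons short-circuit to an empty grid (zero costs and QALYs);
  zero-length scenario lists yield empty tables.

## Problem sizes

All shipped analyses propagate a 5-state occupancy vector over at most
15 cycles per strategy and horizon; a full grid (two strategies, two
horizons, two rates) plus the three sensitivity scenarios completes in
well under a second, and calibration examples use a few hundred model
evaluations. These sizes are the model's natural scale — the cohort is
an expectation, so cohort size only rescales outputs linearly.

## Known limitations

* Hospital perspective only; no societal costs, no probabilistic
  sensitivity analysis, no budget impact, no subgroup analyses, no
  adverse-event disutilities — all outside the model's scope by design.
* No mortality: over 5 years in a population with mean age 66 this
  overstates person-time for both strategies alike.
* The dosing regimen is fixed; real-world interval extension is not
  modelled.
* The synthetic generator claims structural, not numerical, fidelity;
  all absolute cost/QALY levels it produces should be read as
  illustrative (see above).
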