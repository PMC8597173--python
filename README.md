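# dmocea

A two-eye, five-state Markov cohort model for the cost-effectiveness of
intravitreal corticosteroids in diabetic macular oedema (DMO):
dexamethasone 0.7 mg implants (re-dosed every 5 months) versus
triamcinolone 40 mg/ml injections (every 4 months), from a hospital
perspective with 2019 Kuopio University Hospital unit costs.

DMO is a complication of diabetic retinopathy and a leading cause of
vision loss in the working-age population. When anti-VEGF therapy is not
an option, clinicians choose between a cheap, frequently injected
steroid and an expensive, longer-acting implant. This package is for
health-economics analysts who want that trade-off as a transparent,
fully configurable decision model rather than a spreadsheet.

## The model

A cohort of N = 1000 hypothetical patients starts in state 1 (one eye
healthy, one with DMO, better-seeing-eye acuity ≥ 0.5) and moves each
cycle through states defined on better-seeing-eye Snellen decimal
acuity — 2: bilateral DMO, acuity ≥ 0.5; 3: [0.3, 0.5); 4: [0.05, 0.3);
5: blindness, < 0.05 — under strategy-specific 5×5 row-stochastic
matrices **P**. There is no cure and no return to state 1; state 5 is
absorbing. Each strategy has an *early* matrix for cycles starting
before month 12 (first doses are more effective) and a *late* matrix
afterwards. The cycle equals the re-dosing interval, so occupancy
evolves as `x_{t+1} = x_t P(t)` on a 5- or 4-month grid.

Per cycle, occupancy at the cycle start accrues

* drug + administration costs per treated eye (one eye in state 1, two
  in states 2–4 — bilateral disease doubles drug costs — none in
  state 5 by default),
* follow-up costs (OCT + visit, IOP measurements, angiography) pro rata
  for states 1–4, rehabilitation costs (7320 EUR/year) for states 4–5,
* adverse-event treatment costs on the drug-treated population, with
  cataract surgery, laser and vitrectomy charged at most once per
  patient (a saturating cohort-fraction ledger),
* QALYs as utility-weighted person-time, utilities
  (0.97, 0.89, 0.81, 0.55, 0.40) by state.

Costs and QALYs are discounted with `(1 + r)^(-t)` at each cycle's start
time, at 0% and 3% per annum. The headline statistic is the incremental
cost-effectiveness ratio

    ICER = (C_dex − C_ta) / (Q_dex − Q_ta)   [EUR per QALY],

with explicit dominance classification when one strategy is both
cheaper and more effective, and willingness-to-pay (WTP) decisions
against a threshold.

The supplementary literature-derived transition probabilities of the
original evaluation are not publicly deposited, so a seeded synthetic
generator (`dmocea.synthetic`) produces matrix sets with the documented
structural properties (no return to state 1, absorbing blindness,
early > late effectiveness, triamcinolone better at improving acuity,
one- and two-state moves) and can be calibrated against published
expected costs/QALYs. See `docs/methods.md` for what the synthetic
matrices can and cannot claim.

## Worked example

```sh
python examples/run_base_case.py
```

prints (abridged):

```
 horizon_years  discount_rate           row  expected_cost  expected_qalys      icer           dominance
           2.0           0.03 dexamethasone    11602105.98         1804.98       NaN                None
           2.0           0.03 triamcinolone     7085381.57         1787.09       NaN                None
           2.0           0.03    difference     4516724.42           17.89 252534.84                none
           5.0           0.03 dexamethasone    31791532.79         4130.26       NaN                None
           5.0           0.03 triamcinolone    17664863.58         4137.34       NaN                None
           5.0           0.03    difference    14126669.21           -7.08       NaN comparator_dominant

2-year horizon, 3% discounting: ICER 252,535 EUR per QALY gained by choosing dexamethasone
5-year horizon, 3% discounting: triamcinolone dominates (cheaper and more effective); signed ratio -1,994,237 EUR/QALY
WTP  55,000 EUR/QALY -> reject dexamethasone at 2 years
```

Reading: per 1000 patients over 2 years, the implant strategy costs
4.5 M EUR more and yields 17.9 more QALYs, i.e. ~252,535 EUR per QALY
gained — accepted only at a very high willingness-to-pay. By 5 years the
cheaper injections have also become the more effective strategy
(dominance), so the ICER is no longer a meaningful price and the
comparison is settled outright. `examples/sensitivity_analysis.py`,
`examples/generate_and_validate_matrices.py` and
`examples/calibrate_generator.py` walk through the one-way sensitivity
analyses, matrix generation/validation and generator calibration.

A thin CLI wraps the same functions:

```sh
dmocea run --seed 1 --out results/
dmocea sensitivity --out results/
dmocea summarize-costs
dmocea generate-matrices --seed 1 --out matrices.csv
dmocea validate-matrices matrices.csv
```

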