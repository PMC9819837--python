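# markovcea

Markov cohort cost-effectiveness and cost-utility analysis of the CDK4/6
inhibitors **palbociclib** and **ribociclib** in HR+/HER2− stage IV breast
cancer, from a healthcare-payer perspective (costs in Qatari riyal, QAR).
The package is aimed at health-economics modellers who want a scriptable,
testable replacement for spreadsheet/TreeAge-style decision models: every
modelling convention (cycle correction, discount timing, parameter
distributions) is explicit, seedable and exercised by tests.

## The model

A three-state Markov cohort model with monthly cycles over a 10-year
horizon (120 cycles):

* **PFS** — progression-free on treatment (entry state),
* **PD** — progressed disease (shared cost/utility across arms),
* **death** — absorbing.

Transitions are unidirectional (PFS → PD → death, plus PFS → death).
With monthly transition probabilities `p` the PFS row of the transition
matrix is `(1 − p_PFS→PD − p_PFS→death, p_PFS→PD, p_PFS→death)`.
Each cycle credits the trapezoidal (within-cycle-corrected) average of its
start and end occupancy, discounted mid-cycle at 3.5 %/year:
`v_k = 1.035^−(k−0.5)/12`. Costs accrue per month of state occupancy,
QALYs as utility-weighted person-time.

Cohort event counts are turned into monthly probabilities by the
constant-hazard chain

```
P = n_event / n_total          (cumulative probability over t years)
r = −ln(1 − P) / t             (constant yearly rate)
p(t') = 1 − exp(−r·t')         (probability over t' = 1/12 year)
```

Two strategies are compared incrementally: ΔC, ΔE, ICER (per life-year),
ICUR (per QALY), dominance classification on the cost-effectiveness
plane, and net monetary benefit `NMB = λ·ΔQALY − ΔC` at willingness-to-pay
λ = 1× or 3× the Qatari GDP per capita (QAR 192,050 / 576,150 per QALY).
Uncertainty is handled by one-way deterministic sensitivity analysis with
tornado ranking and bisection threshold search, and by a 10,000-draw
Monte-Carlo PSA with method-of-moments Gamma (costs) and Beta
(probabilities, utilities) distributions, ICE-plane classification and a
CEAC. A synthetic individual-patient-data generator produces censored
cohorts (exponential event times, Gamma monthly costs) so the
counts-to-probability estimation path can be tested end to end.

## Worked example

```python
import markovcea as mc

cfg = mc.paper_base_case()          # shipped calibrated configuration
model = cfg.two_arm_model()         # ribociclib (intervention) vs palbociclib
res = model.run()

print(f"palbociclib: cost {res.comparator.total_cost:,.1f} QAR, "
      f"{res.comparator.life_years:.3f} LY, {res.comparator.qalys:.3f} QALYs")
print(f"ribociclib:  cost {res.intervention.total_cost:,.1f} QAR, "
      f"{res.intervention.life_years:.3f} LY, {res.intervention.qalys:.3f} QALYs")
print(res.cea.verdict(), f"(delta cost {res.cea.delta_cost:,.1f} QAR, "
      f"delta QALY {res.cea.delta_qaly:+.3f})")
```

prints

```
palbociclib: cost 372,656.2 QAR, 5.698 LY, 3.059 QALYs
ribociclib:  cost 333,578.7 QAR, 6.330 LY, 3.161 QALYs
ribociclib dominates palbociclib (delta cost -39,077.5 QAR, delta QALY +0.102)
```

i.e. over 10 discounted years ribociclib saves about QAR 39,000 per
patient while adding ~0.10 QALYs — it *dominates*, so no ICER/ICUR is
reported and the adoption decision holds at any positive willingness-to-pay.

The same analysis from the shell:

```sh
cea run --config src/markovcea/data/paper_base_case.yaml \
        --stages base,dsa,psa --out results/ --seed 1
cea synth --config src/markovcea/data/paper_base_case.yaml --out results/
```

which writes the base-case table, per-cycle traces, DSA rows, tornado
table/figure, PSA draws, ICE plane, CEAC and a run manifest.

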