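# nutricea

Trial-based cost-effectiveness analysis of a maternal nutrition education
intervention for early-childhood cognitive development, built as a
reusable, tested Python library.

In a two-armed cluster-randomized trial in rural Uganda, educating mothers
about nutrition, hygiene and child stimulation raised children's BSID-III
cognitive composite scores by ΔE = 16.11 units (95% CI 11.72–20.50) by age
20–24 months, at an incremental cost of ΔC = $265.79 per child (2014 USD,
provider perspective, zero-cost comparator). This package implements the
economic evaluation around that result for analysts who want to reproduce,
stress or re-parameterise it:

- **cost ledger** (`nutricea.costs`) — load and validate an itemised cost
  table, aggregate to per-category and per-child costs, apply multipliers;
- **effect estimation** (`nutricea.effects`) — the difference-in-differences
  linear mixed model ΔE = coefficient of group×time with village and child
  random intercepts, plus descriptive means and baseline balance tests;
- **CEA algebra** (`nutricea.cea`) — ICER = ΔC/ΔE with cost-effectiveness
  plane quadrants and dominance flags, net monetary benefit
  NMB(λ) = λ·ΔE − ΔC, and a DALY-weight threshold translation;
- **uncertainty** (`nutricea.uncertainty`) — one-way (tornado) sensitivity
  analysis, Monte Carlo probabilistic sensitivity analysis, and the
  cost-effectiveness acceptability curve, with a semi-analytic
  convolution oracle for the CEAC;
- **synthetic trial** (`nutricea.simulate`) — a cluster-trial generator with
  the same statistical structure (village/child random intercepts, reported
  enrolment, retention, means and covariate marginals), standing in for the
  undeposited trial records;
- **pipeline** (`nutricea.pipeline`, `nutricea` CLI) — YAML-configured
  orchestration of all stages with deterministic CSV/JSON reports and
  optional figures.

See `docs/methods.md` for the model and its assumptions, and `examples/`
for narrative scripts (one per capability).

## Worked example

```python
import nutricea as nc

# per-child incremental cost from the packaged ledger
costs = nc.load_and_summarize(n_children=227, total_override=60335)
print(round(costs.per_child_total, 2))        # 265.79

# deterministic ICER at the published effect
print(nc.icer(costs.per_child_total, 16.11).to_dict())
# {'delta_c': 265.79, 'delta_e': 16.11, 'icer': 16.5, 'quadrant': 'NE', ...}

# probabilistic sensitivity analysis and acceptability curve
effect = nc.EffectEstimate.from_interval(16.11, 11.72, 20.50)
psa = nc.run_psa(nc.PSAConfig(n_samples=1000, seed=11),
                 nc.load_and_summarize(n_children=227), effect)
print(round(psa.icer_mean, 2))                # 14.81
for p in nc.ceac(psa, [8.0, 16.50, 24.0]):
    print(p.wtp, round(p.probability, 3))     # 8.0 0.004 / 16.5 0.693 / 24.0 0.991
```

Read: the intervention costs $16.50 per cognitive score unit gained; under
joint parameter uncertainty it is almost never worth funding at a
willingness to pay of $8 per unit, cost-effective with probability ≈0.7 at
$16.50, and near-certainly cost-effective at $24.

Or from the shell:

```sh
nutricea deterministic --total-override 60335   # base-case ICER table
nutricea dsa                                    # tornado
nutricea psa --seed 11                          # PSA summary + CEAC landmarks
nutricea simulate --seed 1 --out trial.csv      # synthetic trial data
nutricea fit trial.csv                          # DiD mixed-model estimate
nutricea run --config config.yaml               # full pipeline
```

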