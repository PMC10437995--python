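# Methods

`nutricea` implements a trial-based economic evaluation of a maternal
nutrition education intervention against current practice, from the
perspective of a healthcare provider over an 18-month horizon. This note
describes the model, its assumptions, the synthetic-data generator, and the
numerical choices, in the order the pipeline runs them.

## Costing

The intervention is costed bottom-up in 2014 USD across four categories:
personnel, materials and other variable costs, capacity building, and
capital. A ledger row carries either a direct amount or a unit cost and
quantity whose product is the amount; an optional `attributable_fraction`
scales items shared with the control arm (default 1; the packaged ledger
already holds intervention-attributable amounts). The packaged ledger
reproduces the category subtotals $46,485 / $11,496 / $1,822 / $533
(77/19/3/1% of the total).

The comparator is assumed to add no cost, so the incremental cost per child
is ΔC = total / n, with n = 227 the number of intervention children
retained through the final assessment. The four subtotals sum to $60,336
while the reported grand total is $60,335 (a rounding artefact of the
source figures); `summarize_costs(total_override=...)` lets a caller pin
the reported total, and the package treats the ledger as authoritative
otherwise. Monetary arithmetic is carried at full floating precision and
rounded to cents only at the reporting boundary. A constant 2,523 UGX/USD
(the 2014 rate) is exposed for display conversion only; no discounting or
inflation adjustment is applied anywhere, consistent with the short
horizon.

## Incremental effect: difference-in-differences mixed model

The health effect is the BSID-III cognitive composite score. The
incremental effect ΔE is the coefficient of the group×time interaction
(group: control = 0, intervention = 1; time: baseline = 0, follow-up = 1)
in a linear mixed model fitted to completers' baseline and final-wave
records:

    score ~ group + time + group:time + covariates
            + (1 | village) + (1 | child within village)

Estimation is by REML (statsmodels `MixedLM`, village as the grouping
factor and the child intercept as a nested variance component), with a
normal-theory Wald interval on the interaction coefficient. REML with a
Wald interval is the conventional default; at this scale the ML and REML
point estimates agree to well under 0.2 score units (tested). Covariates
default to the baseline variables the generator produces (child sex and
age, breastfeeding category, dietary diversity, maternal education and
age, household size, poverty score); categorical covariates enter as
indicator contrasts. Development measures that partly overlap with the
outcome (language, motor) are excluded by design. Only completers —
children assessed at both baseline and the final wave — enter the fit; the
mid wave is descriptive. No imputation or weighting for dropout is
attempted, and no small-sample (Kenward–Roger) correction is applied.

Descriptive outputs mirror the trial's reporting: arm×wave means over
completers, and a baseline balance table using Pearson chi-square tests
without continuity correction for categorical variables (this matches the
reference p-value 0.462 for the child-sex 2×2 table; the Yates-corrected
value would be 0.52) and pooled two-sample t-tests for numerical ones.

When only a published estimate is available, `se_from_ci` reconstructs the
standard error from the printed interval: SE = (hi − lo) / (2 z), giving
SE = 2.2398 for 16.11 (95% CI 11.72–20.50). The economic stages consume
an `EffectEstimate` regardless of whether it was fitted or supplied, so
the economics half is testable without trial data.

## Synthetic trial generator

The raw trial records are not deposited, so a generator emulates the
design: 263/248 mother–child dyads enrolled across 20 villages (10 per
arm, round-robin assignment within arm — village is the unit of
randomization), three assessment waves at child ages 6–8, 12–16 and 20–24
months, and missing-completely-at-random attrition down to 227/196
completers (423 in total; dropped children keep their baseline record).

Scores follow score = μ(arm, wave) + v + c + ε with v ~ N(0, σ²_village),
c ~ N(0, σ²_child), ε ~ N(0, σ²_resid). Cell means are anchored to the
reported descriptives: baseline 102.37/103.42 (intervention/control), mid
110.50/103.31, control final 99.37 (drift −4.05); the intervention final
mean is constructed so the DiD contrast of the four baseline/final cell
means equals the configured true effect (16.11 by default), which makes the
noise-free recovery test exact. Covariates are drawn independently from
the arm-specific reported marginals and have no effect on the score — the
simplest structure consistent with the reported null covariate effects —
so the generator provides a clean ground truth for parameter recovery.

The variance components default to (σ_village, σ_child, σ_resid) =
(3.0, 7.0, 10.55), chosen so their squares sum to the observed baseline
variance 13² within 1% with a plausible village ICC of ≈0.05. The true
cluster count, ICC and attrition mechanism of the emulated trial are not
reported; these defaults are stand-ins, configurable in `SyntheticConfig`.
One consequence worth stating: because the village and child intercepts are
constant over time, they cancel in the within-child contrast, so the
fitted DiD standard error on a default dataset is ≈1.4–1.5 — smaller than
the 2.24 implied by the published interval. Matching that SE under this
model would require more residual variance than the observed baseline SD
permits; the published SE plausibly reflects village×time variation that
this generator (and the fitted model) intentionally omits. Parameter
recovery and CI coverage are unaffected since the generator and the
analysis model coincide; the probabilistic sensitivity analysis uses the
published SE, not a fitted one.

What passing tests on synthetic data do not show: robustness to
informative dropout, covariate–outcome confounding, non-normal score
distributions, or cluster-size imbalance — none of which the generator
produces.

## Cost-effectiveness algebra

ICER = ΔC/ΔE, reported to 2 decimals, computed at full precision. On the
cost-effectiveness plane (x = ΔE, y = ΔC), a finite ratio is reported only
in the NE quadrant; SE is flagged "dominant", NW "dominated", and ΔE = 0
at positive cost is dominated with an undefined (infinite) ratio. The net
monetary benefit is NMB(λ) = λ·ΔE − ΔC; "cost-effective at λ" means
strictly NMB > 0, which makes the acceptability curve well defined even
for degenerate distributions (a draw exactly at its own ICER is on the
boundary and counts as not cost-effective).

Because no mapping from cognitive composite scores to DALYs exists,
`daly_weight_threshold(ΔC, λ_DALY, T)` = ΔC/(λ_DALY·T) answers the inverse
question: the smallest avoided-disability weight under which the
intervention meets a willingness-to-pay of λ_DALY per DALY averted over a
duration of T years. Both λ_DALY and T are explicit parameters rather than
baked-in GDP figures; at λ_DALY = $2,610 (≈3× GDP per capita) and T = 60
years the threshold is 0.0017, at $870 (1×) it is 0.0051.

## Sensitivity analyses

One-way (tornado): each cost category moves over a multiplicative range —
personnel 0.5–1.2 (personnel costs per participant fall as a programme
scales), all others 0.8–1.2 — and the effect moves to its 95% CI bounds,
one parameter at a time with the rest at reference. Entries are sorted by
decreasing ICER span, ties broken alphabetically.

Probabilistic (Monte Carlo): the effect is drawn from Normal(point, SE)
and each per-child category cost from an independent uniform over its
one-way range; 1000 draws by default, reproducible from a single integer
seed (`numpy.random.default_rng`; the effect is drawn first, then each
category in fixed order, so streams are stable across runs). Per-draw
ICERs are summarised over NE-quadrant draws only (a ratio across quadrants
is meaningless); draws with ΔE ≤ 0 — probability ≈ Φ(−16.11/2.24) ≈ 3×10⁻¹³
at the defaults — are counted and retained in the CEAC and quadrant
counts. Two "mean ICER" summaries are reported because the conventional
choice is ambiguous: the mean of per-draw ratios (≈14.9 at the defaults)
and the ratio of mean ΔC to mean ΔE (≈14.6); they differ by ≈2% here. The
95% simulation interval is the 2.5th–97.5th percentile of per-draw ICERs.

CEAC: P(λ·ΔE − ΔC > 0) over a willingness-to-pay grid (default $0–30 in
steps of $0.5). An independent semi-analytic evaluation
(`ceac_probability_analytic`) convolves the uniform cost densities on a
fine grid (step $0.01, renormalised to absorb truncation error) and
integrates the normal CDF against the resulting density of ΔC; the test
suite requires Monte Carlo and analytic probabilities to agree within 3
Monte Carlo standard errors at λ ∈ {8, 16.50, 24}.

## Problem sizes and tolerances in the test suite

Parameter recovery runs 200 replicate trials at the full design size
(511 children) — enough that the Monte Carlo SE of the mean estimate
(≈0.11) comfortably resolves the 0.5-unit unbiasedness band, and that the
93–97% coverage band is ≈±2 binomial SDs around the nominal 95%. Mixed-
model unit tests use a reduced design (120 children, 10 villages) where
one fit takes ≈0.1 s. The recovery loop fits the unadjusted model: the
generator gives covariates no effect, and the adjusted fit is checked
separately at a single seed. PSA checks use the default 1000 draws.

## Known limitations

- Single-comparator, single-outcome: no QALY machinery, no efficiency
  frontier, no EVPI, no correlated parameter sampling.
- Provider perspective only; societal costs (schooling, labour-market
  effects) are out of scope.
- The item-level ledger is summarised at category level plus one
  documented unit-cost line (food demonstrations, $14.50 × 150 sessions);
  finer item detail would change nothing downstream, which consumes only
  category subtotals.
- The generator's cluster count, ICC and MCAR attrition are stand-ins, as
  flagged above.
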