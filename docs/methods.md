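# Methods

This note documents the model, its assumptions, the parameter
conventions, and the numerical and design choices behind `heather-dss`.
It states nothing the test suite or `scripts/acceptance.py` does not
itself compute.

## The decision problem

An 8-ha commercial heather nursery chooses among three plant-health
monitoring strategies: keep the current occasional visual checks
(*Baseline*), intensify visual monitoring (*Improved*), or adopt
hyperspectral-sensor monitoring (*Sensor*). Each strategy has uncertain
costs (investment, maintenance, labor, data post-processing, laboratory
sampling) and uncertain benefits (high-quality plants saved in disease
years, resource savings in calm years). All inputs are expert estimates:
90% confidence intervals with a distribution family, shipped as the
built-in 32-variable table (`builtin_table1()`).

## Calibration of elicited intervals

An interval (L, U) is read as the 5th and 95th percentile of the
quantity. Families:

* `posnorm` — normal truncated below at 0 (costs, prices, counts);
* `tnorm` — normal truncated to [0, 100] (percentages);
* `const` — point mass. A zero-width stochastic interval is coerced to a
  constant with a logged warning (a zero-width CI is a point mass).

Location and scale are found by two-parameter quantile matching on the
*truncated* distribution (`scipy.optimize.least_squares` on the scaled
quantile residuals, parametrised by (μ, log σ)). When the truncation
would remove less than 10⁻⁶ probability mass under the closed-form
parameters μ = (L+U)/2, σ = (U−L)/(2·z₀.₉₅), the closed form is used
directly. The fit is verified to reproduce the bounds within relative
tolerance 10⁻³ (relative to the interval scale); an interval a truncated
normal cannot represent (e.g. a positive-truncated 90% interval spanning
four orders of magnitude) raises `CalibrationError` rather than
silently mis-calibrating.

Percent-unit variables (`var_CV`, `chance_high_risk`,
`adjustment_sample_size_*`) are sampled on the 0–100 scale and divided
by 100 at the point of use. `discount_rate` (unit "digit", bounds 1–5)
is interpreted as percent points, r = value/100: 1–5% is the plausible
financial range, 1–5 as a fraction would be absurd.

## Cash-flow model

Horizon t = 10 years (year 0 carries the establishment cost C₀,
undiscounted); area 8 ha; both are read from the input table.

Per iteration, the **shared block** is drawn once and reused by all
three strategies (common random numbers): discount rate, interannual CV,
chance of a high-risk year p, the year-by-year high-risk flags
(independent Bernoulli(p) per year), the per-sample laboratory fee, and
both plant values. **Strategy blocks** are drawn independently per
strategy.

Yearly accounting for strategy k in year i:

* samples: the full drawn sample number in high-risk years;
  round(sample_number × adjustment fraction) in normal years (fewer
  samples when infection risk is low);
* costs_i = additional_investment (whole-farm annual maintenance)
  + area × (labor + post-processing + samples × (lab fee + value of the
  destroyed sampled plant));
* benefits_i = area × saved_plants × A1 plant value in a high-risk year,
  area × resource_savings in a normal year;
* NPV = −C₀ + Σ (benefits_i − costs_i)/(1+r)ⁱ.

Design choices where the accounting was genuinely open:

* **Area scaling.** Initial investments and annual maintenance are
  whole-farm; *all further* costs and benefits — labor, post-processing,
  sampling costs, saved-plant benefits, resource savings — are
  per-hectare rates multiplied by the 8-ha area. Treating sampling costs
  as whole-farm instead biases the Improved strategy upward (it
  understates the cost side that grows with sample numbers) and was
  rejected.
* **Saved-plant benefit** uses the full A1 market value per plant, not
  the A1-minus-discard uplift: the benefit channel is more high-quality
  plants reaching the point of sale.
* **Discarded plants** are costed through sampling: each laboratory
  sample destroys one plant, so its value rides on the sample count. No
  separate discard-count variable exists in the input set.
* **Interannual variation** (the value varier) applies to the flow
  quantities — labor, post-processing, saved plants, resource savings —
  as normal noise with standard deviation mean × CV, clamped below at
  zero (costs, benefits and plant counts cannot be negative; the clamp
  rather than conditional resampling puts a point mass at 0, immaterial
  at the elicited CVs of 5–15%). Investments, prices and sample numbers
  are held fixed within an iteration.

With every input constant and CV = 0 the pipeline is deterministic and
is tested against an independently hand-coded closed form; monotonicity
(raising a price never lowers NPV, raising a cost never raises it) and
linearity in additive components are tested structurally.

## Monte Carlo plan and reproducibility

Default plan: 10,000 iterations, seed 42, both overridable. One global
seed; every random stream (each input variable, the high-risk flags,
each strategy's value varier) is a substream keyed by
SHA-256(variable name) combined with the seed, so adding or removing a
variable never perturbs the draws of another, and paired decision deltas
(DoMoreVisual = Improved − Baseline, UseSensor = Sensor − Baseline) are
exact per-iteration differences. Pairing with common random numbers is
verified to reduce the delta variance relative to unpaired subtraction.

## Sensitivity (PLS-VIP)

Decision outcomes are regressed on the inputs entering that decision
(shared block plus both strategy blocks; structurally constant inputs
excluded) with scikit-learn's NIPALS PLS, inputs and outcome
standardized. VIP_j = √(K·Σₐ w²ₐⱼ·SSYₐ / Σₐ SSYₐ); squared scores
average to 1 across the K inputs (tested to machine precision), VIP > 1
flags an input as influential, and the sign of the final regression
coefficient gives the direction. Default A = 2 components: the
qualitative result of interest is the importance *ranking*, which is
insensitive to the component count here; no cross-validated selection is
attempted. Constant columns are dropped with a warning and affine
duplicate columns consolidated; requesting more components than the
input rank is an error.

## Value of information (EVPI)

The decision is binary adopt/don't-adopt on a decision delta, so
EMV = max(0, E[outcome]). E[outcome | x] is estimated by equal-frequency
binning of the variable's draws (default 20 bins — coarse enough that
bin means are stable at 10,000/20 = 500 draws per bin, fine enough to
resolve the conditional mean), EV|PI = Σ p_bin·max(0, bin mean), and
EVPI = EV|PI − EMV. The estimator is validated against the closed form
EVPI = 1/8 for x ~ U(0,1), outcome x − ½; negative float residue (when
no bin changes the decision) is snapped to exactly zero, and raw
negative noise is clipped at zero and logged. Single-variable EVPI is
bounded above by the value of perfect information on everything,
E[max(0,y)] − max(0,E[y]) — an exact property of the estimator that is
tested. Binning is transparent and testable; regression-based EVPPI
estimators (GAM/GP) are out of scope.

## Expected utility (SERF)

Certainty equivalents CE = E[NPV] − RP under constant absolute risk
aversion, with two premium variants:

* variance (headline): RP = ½·rₐ·σ², the Arrow–Pratt approximation,
  exact for normal NPVs under exponential utility — tested against the
  CARA-normal closed form to <1% relative error;
* semi-variance (downside sensitivity): RP = rₐ·SV with
  SV = mean(min(0, x − mean)²), population divisor n. For symmetric
  distributions 2·SV = σ² and the variants coincide (tested).

Default grid: {±10⁻ᵏ, k = 1…7} ∪ {0}, spanning rₐ ∈ [−0.1, 0.1] with
log spacing, since behaviourally relevant coefficients differ by orders
of magnitude. CE(0) equals the sample mean exactly; CE is non-increasing
in rₐ. The recommendation at each grid point is the CE-maximising
strategy; strategies with CE ≤ 0 are flagged as "would not adopt".

## Synthetic data

`generate_table` produces structurally valid estimate tables over the
real variable manifest with bounds randomized within unit-class ranges
calibrated to the real magnitudes (investments 10²–10⁵ €, per-plant
values 0.1–1 €, lab fees tens of €, percentages 5–60), so synthetic runs
exercise the same numeric regimes. `all_const` collapses every interval
to a point *and* sets the interannual CV and the high-risk chance to
zero, making the whole pipeline deterministic. A planted driver (one
interval widened by a stated multiplier) provides ground truth for
sensitivity rankings. `planted_driver_scenario` (defaults: 10 standard
normal inputs, driver coefficient 1, noise SD 0.5, n = 2000) is the
recovery benchmark: VIP and EVPI must identify the driver in >95% of 100
seeded replicates.

What the synthetic generator does **not** emulate: correlated expert
estimates, non-normal elicitation shapes, serial correlation of
high-risk years, or price trends. Passing tests on synthetic data
therefore demonstrate estimator correctness under the model's own
assumptions, not robustness of the economics to violations of them.

## Problem sizes and limitations

All analyses run at their full study sizes (10,000 iterations, 32
variables, 10 years) in under a second on one CPU; tests use smaller
iteration counts only where the property under test does not need the
full distribution. Known limitations: no epidemiological dynamics or
spatial structure within the nursery; no fungicide-dose modelling; the
expert intervals are taken as given (the elicitation process itself is
out of scope); EVPI magnitudes depend on the conditional-mean smoother,
so they should be read as rankings, and the alternative-utility theories
(prospect theory, rank-dependent utility) are deliberately excluded.
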