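# Methods

## The estimation problem

`bedbench` produces benchmark rates of *needed* psychiatric inpatient beds
(per 100,000 population) for a cross-section of geographic units, from six
state-level indicators: the observed bed rate, three community-mental-health
(CMH) service rates (outpatient clients, residential beds, day programs),
an adult mental-disability proportion, the percent of persons 15+ who are
married, and life expectancy at birth. The premise is that observed
hospitalization reflects both need (disability) and context (community
services, social support, socioeconomic development), so a model fitted to
all units can be re-evaluated under a counterfactual "optimal community
services" scenario to say what each unit *would* need if community care
were as good as in the best-served decile of units.

## Pipeline and assumptions

1. **Composite CMH index.** Each of the three service rates is
   z-standardized across units (unweighted, sample SD with denominator
   n − 1) and the three z-scores are averaged into a composite c.
   Standardization is deliberately unweighted even though reporting is
   population-weighted: the index positions each unit relative to its
   peers, and weighting enters only at the aggregation stage. (A weighted
   mean of the composite is therefore generally nonzero.)

2. **Reciprocal outcome.** Bed rates are right-skewed; the model is fitted
   to y' = 1/y, which is close to normal for these data. The map is
   strictly decreasing, so coefficient signs invert their interpretation
   and interval endpoints swap on back-transformation. Corrected sample
   skewness and excess kurtosis (with the usual normal-theory SEs) are
   reported as diagnostics; they are descriptive, not a gate.

3. **Weighted polynomial fit.** y' is regressed on eight terms — intercept,
   disability d and d², composite c, c², c³, percent married m, life
   expectancy ℓ — by weighted least squares with weights proportional to
   population share, normalized to sum to n (frequency-weight convention,
   so residual df = n − 8 and s² = RSS_w/(n − 8) follow the unweighted
   accounting). The fit itself is delegated to statsmodels WLS; the module
   adds standardized betas (weighted SDs), partial correlations
   t/√(t² + df), mean Cook distance on the whitened design, and
   mean-response / prediction standard errors.

4. **Counterfactual projection.** The scenario value c* is the mean
   composite of the top decile (k = round(0.10·n), half away from zero;
   k = 5 for n = 50). For each unit two linear predictors are formed: at
   the unit's own c (unadjusted) and at c* with c² and c³ recomputed
   (adjusted). The 95% interval is fitted ± t₀.₉₇₅,ₙ₋₈ · SE on the
   transformed scale, then mapped through the reciprocal with endpoints
   swapped. Intervals whose transformed lower bound is non-positive have
   no finite upper rate bound; they are reported right-open and flagged
   `non_physical` rather than clipped.

5. **Gap classification and rollup.** A unit is UNDER_PROVIDED if its
   actual rate is below the interval, OVER_PROVIDED above it, WITHIN
   otherwise. Boundary ties count as WITHIN: the published rule uses
   strict "less than"/"exceeds", leaving equality unassigned, and the
   closed interval is the conservative completion. Group summaries report
   weighted (Σwᵢvᵢ/Σwᵢ) and unweighted means of every column; the group
   category classifies the weighted mean actual against the weighted mean
   bounds (a majority-vote alternative was considered and rejected as the
   default because it discards interval information). Empty or zero-weight
   groups are omitted with a warning.

## Interval type

The default interval is the **confidence interval of the mean response**.
The benchmark is an estimate of systematic need for a whole population
unit, not a forecast of one new observation; prediction intervals
(s²(1 + leverage)) are available behind `interval="prediction"`. The
shipped published table is consistent with transformed-scale construction
(its intervals are asymmetric around the adjusted estimates in just the
way the reciprocal map produces), which is what the engine does.

## Published-table mode

The per-unit covariates behind the published 2018 U.S. fit are not
distributed, so that exact regression cannot be refit; the published
coefficient vector is shipped as a fixture (`table1_us`) for
projection-mode use and as the generator's default truth. The published
50-state benchmark table (`table2`) is shipped bit-exactly; its printed
gap labels are stored but never trusted — classification always
recomputes categories from the printed actual rate and bounds. Two
internal inconsistencies of the published numbers are preserved rather
than corrected: the narrative cites an adjusted-column minimum of 24.66
(Wyoming) while the printed column's minimum is 23.60 (Utah); and the
printed regression/residual df (43/7) appear transposed relative to the
7-predictor, n − 8 = 42 accounting this package uses. The
population-weighted headline means additionally require 2018 state
population weights, which are an external input: the weighted path is
implemented and tested mechanically, but no published weighted value is
asserted.

## Synthetic-data generator

The generator emulates the 2018 indicator structure so every stage is
testable without downloads:

| quantity | distribution | default | why |
| --- | --- | --- | --- |
| disability d | truncated normal | 0.0526 ± 0.008 on [0.02, 0.10] | observed 2018 center; spread wide enough to identify d and d² |
| married m (%) | truncated normal | 38.4 ± 2.5 on [25, 55] | observed 2018 center |
| life expectancy ℓ (yr) | truncated normal | 79.15 ± 1.5 on [70, 90] | observed 2018 center |
| outpatient rate | log-normal | median 600, log-SD 0.5 | positive, right-skewed service rates |
| residential rate | log-normal | median 25, log-SD 0.6 | " |
| day-program rate | log-normal | median 3, log-SD 0.7 | " |
| population | log-normal, floored | median 4.4M, log-SD 0.95, min 500k | heavy-tailed state sizes |
| noise σ (on y') | — | 0.009 | calibrated once so the model explains ≈ ⅓ of outcome variance, the explanatory power of the real 2018 fit (measured signal SD ≈ 0.0064) |

B_true defaults to the published U.S. coefficient vector, which places
bed rates in a plausible 15–130 per-100,000 range. The composite is
re-standardized within each generated sample exactly as the pipeline
does. Units whose *noiseless* reciprocal rate is non-positive have their
covariates resampled (bounded budget); noise draws with y' ≤ 0 are
resampled likewise and logged — both affect well under 1% of draws at the
defaults. For n = 50 the units carry the real state names and Census
divisions; other n get synthetic labels with divisions assigned
round-robin.

What the generator does **not** emulate: interstate spatial correlation,
survey measurement error in the indicators, correlation between the three
service rates, or any dependence of noise variance on population. Passing
recovery and coverage tests therefore show the estimator is correct when
its assumptions hold — not that the assumptions hold for real survey data.

The recovery experiment refits each replicate from scratch (composite,
design, fit) and records per-coefficient bias, RMSE and 95% CI coverage.
Its default fit is **unweighted**: the generator's noise is homoscedastic,
so equal weights are the correctly specified choice and t-based coverage
is exact; fitting with population weights under homoscedastic noise is
offered as a robustness mode (`weighted=True`) but its nominal SEs are
then misspecified by construction. Per-replicate seeds are derived from
the base seed by a fixed stride (7919·i, mod 2³¹).

## Numerical choices

- Weights are rescaled to sum to n, making fits invariant to rescaling of
  the weight vector; at least 8 strictly positive weights are required.
- Rank deficiency is detected on the whitened design; the error names the
  columns that lie in the span of the others (lstsq residual ≤ 1e-8
  relative).
- A numerically constant outcome (weighted TSS at rounding level,
  ≤ 1e-14 of Σw y²) raises an undefined-R² error instead of returning a
  meaningless statistic; a numerically perfect fit reports F = ∞, p = 0.
- CSVs are read with round-trip float parsing, so write-then-read
  reproduces every stored numeric field bit-for-bit.
- Scenario ties at the k-th rank are broken by a stable descending sort
  taking exactly k items.
- Test and validation problem sizes: 500 replicates for coverage (binomial
  SE ≈ 0.01 at p = 0.95, so [0.93, 0.97] is a ≈ 2σ band), 20 random
  instances (n ≤ 100) for the normal-equations agreement check, 1000
  random draws for interval-membership properties.

## Known limitations

- The model explains only a minority of the variance in the real 2018
  data (R² 0.325, adjusted 0.214 as published); intervals are
  correspondingly wide, and the benchmark should be read alongside local
  evidence, not as a point prescription.
- No uncertainty from composite construction or from c* estimation is
  propagated into the intervals; the scenario value is treated as fixed.
- No multiple-testing adjustment is made across the 50 per-unit
  classifications (none is made in the published analysis either).
- Log, Box–Cox or other alternative normalizations are out of scope; the
  transform module is the extension point if they are ever needed.
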