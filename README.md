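# bedbench

**Predictive-analytics benchmarks of needed psychiatric inpatient beds for
sub-national units.**

How many psychiatric hospital beds does a state *need*? Waiting lists,
expert panels and global per-capita targets all ignore local conditions:
how much psychiatric disability there is in the population, how much
community mental health (CMH) care is available, and the social context
that substitutes for — or channels people into — inpatient care.
`bedbench` implements a needs-assessment pipeline for mental-health
planners and health-services researchers that turns state-level indicators
into individualized benchmark rates of needed beds per 100,000 population,
with 95% intervals and a three-way classification of each state as
under-provided, commensurate, or over-provided.

## The model

For each of n units (the 50 U.S. states in the shipped data), the observed
bed rate y (beds per 100,000) is reciprocal-transformed to y' = 1/y, which
is approximately normal. Three CMH service rates per 100,000 — outpatient
clients, residential beds, day programs — are z-standardized across units
and averaged into a composite index c. The model is a population-weighted
polynomial regression

    y'_i = β₀ + β₁ d_i + β₂ d_i² + β₃ c_i + β₄ c_i² + β₅ c_i³
            + β₆ m_i + β₇ ℓ_i + ε_i,      ε_i ~ N(0, σ²),

where d is the adult mental-disability proportion, m the percent of
persons 15+ married (a social-support proxy) and ℓ life expectancy at
birth (a socioeconomic proxy). Weights are proportional to population
share and normalized to sum to n. Because the outcome is a reciprocal,
negative coefficients represent positive associations with the bed rate
and vice versa.

The benchmark is counterfactual: each unit's composite c (and its powers)
is replaced by c*, the mean composite of the top decile of units — an
"optimal CMH availability" scenario — and the model is re-evaluated. The
projection and its 95% interval are built on the transformed scale
(t quantile, n − 8 residual df) and mapped back through the reciprocal,
which swaps the endpoints. Each unit is then classified by where its
actual rate falls relative to the interval of projected need.

## Worked example

The package ships the published 50-state benchmark table as a fixture.
Categories are always recomputed from the printed actual rates and
interval bounds — never read off the printed labels:

```python
import bedbench as bb

table2 = bb.load_fixture("table2")
ests = bb.estimates_from_published(table2)
print(bb.gap_census(ests)["counts"])
# {'UNDER_PROVIDED': 16, 'WITHIN': 20, 'OVER_PROVIDED': 14}

total = bb.aggregate(ests)[0]
print({k: round(v, 2) for k, v in total.unweighted.items()})
# {'actual': 38.81, 'unadjusted': 33.17, 'adjusted': 32.9,
#  'ci_low': 25.83, 'ci_high': 39.96}
```

So 16 of 50 states (32%) provide fewer beds than the projected need, 14
(28%) provide more, and 20 (40%) are within the 95% interval; the
unweighted mean benchmark is ≈ 32.9 needed beds per 100,000 against an
actual mean of ≈ 38.8.

Fitting is organised around a Model/Results pair. On a synthetic table
drawn from the generator (which emulates the 2018 indicator structure):

```python
table = bb.generate(bb.GeneratorConfig(seed=7))
res = bb.BedNeedModel(table).fit()   # returns BedNeedResults
print(res.summary())
```

```
Psychiatric bed-need benchmark model
================================================================
Units: 50    outcome: 1 / (beds per 100,000)    weights: population
Scenario: top 10% of units (k = 5), c* = 1.1592
----------------------------------------------------------------
                          b          se         t           p     beta  partial_r
const             -0.031746    0.094074  -0.33746     0.73745      NaN        NaN
disability          0.63127      2.2649   0.27872     0.78182  0.35965   0.042968
...
married           0.0031227  0.00054055    5.7768  8.3148e-07  0.66869     0.6654
life_expectancy -0.00091786   0.0010124  -0.90666     0.36976 -0.10243  -0.13855
----------------------------------------------------------------
R2 = 0.4887   adj R2 = 0.4035   F(7, 42) = 5.735   p = 0.0001064
```

`res.benchmark_frame()` gives the per-state table (actual, unadjusted,
adjusted, 95% bounds, category), `res.aggregate(group_by="division")` the
Census-division rollup, and `res.gap_census()` the category counts.

The same pipeline is scriptable:

```bash
bedbench benchmark --fixture table2 --out-dir out/   # classification + rollup
bedbench fit states.csv --out-dir out/               # fit report (JSON + text)
bedbench simulate --seed 1 --replicates 500          # generator + recovery study
```

## Layout

- `src/bedbench/data_model.py` — domain types, CSV schema I/O, packaged fixtures
- `src/bedbench/cmh_index.py` — composite CMH index and optimal-CMH scenario
- `src/bedbench/transform.py` — reciprocal normalization, moment diagnostics
- `src/bedbench/regression.py` — weighted polynomial least squares, SEs
- `src/bedbench/benchmark.py` — projection, gap classification, rollup
- `src/bedbench/synthetic_data.py` — generator + parameter-recovery experiments
- `src/bedbench/model.py` — `BedNeedModel` / `BedNeedResults`
- `src/bedbench/cli.py` — `bedbench fit | benchmark | simulate`
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
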