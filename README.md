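# clubconv

Log-t convergence testing and endogenous club clustering for balanced panels
of health-workforce densities (e.g. physicians per 10,000 population across
countries and years).

## The problem and the method

Whether countries are closing the gap in physician density is a question
about *convergence*: do national densities approach a common long-run path,
or do subsets of countries ("clubs") settle on permanently different levels?
`clubconv` implements the time-varying factor approach of Phillips and Sul.
A panel X_it is modelled as

    X_it = δ_it μ_t,

a common trend μ_t times unit-specific transition coefficients δ_it.
Convergence means δ_it → δ for all units. The common factor is removed via
the relative transition parameter and its cross-sectional variance

    h_it = X_it / (N⁻¹ Σ_i X_it),      H_t = N⁻¹ Σ_i (h_it − 1)²,

and convergence is tested with the trimmed **log-t regression**

    log(H_1/H_t) − 2 log(log t) = α + β log t + ν_t,   t = [rT]+1, …, T,

with r = 0.3 for annual data. Under convergence H_t decays like
t^(−2a)(log t)^(−2) and β̂ estimates 2a ≥ 0; the null of convergence is
rejected, one-sided at the 5% level, when the Newey–West (HAC) t-statistic
falls below −1.65. When the full sample rejects, a four-step clustering
algorithm (order units by final-window density, find a core group of
converging top units, sieve the remaining units into the club, recurse on
the leftovers) identifies convergence clubs endogenously, and adjacent clubs
whose union passes the test are merged; units joining no club are classified
divergent. The number of clubs is not set a priori — one club, several
clubs, or none are all possible outcomes.

The package also ships a synthetic panel generator with known club
structure (so every inference stage can be validated against ground truth),
and the descriptive elasticity arithmetic that typically accompanies such
analyses (growth-elasticity ratios, linear elasticity projections of an
index such as the GBD Healthcare Access and Quality index, and the
cross-sectional log-linear fit of an index on workforce densities).

## Worked example

Simulate a study-scale panel — three clubs of 110/66/28 units converging to
21, 7 and 2 per 10,000, plus 4 divergent "fan" units, 30 years — then test
and cluster it:

```sh
$ printf 'n_divergent: 4\nseed: 1\n' > sim.yaml
$ clubconv simulate --config sim.yaml --out-dir demo
wrote 208 units x 30 years to demo/panel.csv
$ clubconv run --input demo/panel.csv --out demo/report.json
        Coeff  t-stat  N. of countries  N. of years
Log(t) -0.416 -16.421              208           30
Club 1  0.830   2.902              110           30
Club 2  1.020   4.274               66           30
Club 3  0.979   3.547               28           30
Divergent units: 4
report written to demo/report.json
```

The full-sample row rejects global convergence decisively (t = −16.4 <
−1.65: the 208 units do not share one long-run path), while each recovered
club has a positive log-t slope and a t-statistic above −1.65 — internally
convergent groups, recovered at exactly the generating sizes, with the four
fan units correctly flagged divergent. Club 1 is the highest-density club.
The JSON report records every coefficient, standard error, club membership,
attempted merge, and the complete configuration (transform, smoothing,
trim, HAC bandwidth) plus library versions, so results are attributable.

The same pipeline is available as estimators:

```python
from clubconv import ClubConvergence, simulate_panel, SimulationConfig

panel, truth = simulate_panel(SimulationConfig(n_divergent=4, seed=1))
est = ClubConvergence().fit(panel)     # sklearn-style: labels_, n_clusters_
est.labels_                            # 0-based club per unit, -1 = divergent
est.full_sample_.t_stat                # -16.42
```

and the elasticity arithmetic as plain functions:

```python
>>> from clubconv import growth_elasticity, project_index
>>> growth_elasticity(129, 163)   # density growth vs income growth
0.79
>>> project_index(55.6, 0.23, 1.0)  # index level after doubling density
68.4
```

Real GBD-format extracts load with
`clubconv.load_panel("panel.csv", "long", value_col="density")`; the loader
validates balance, strict positivity and consecutive years, and reports the
exact offending cells otherwise.

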