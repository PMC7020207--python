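# weedshift

Diachronic analysis of arable weed surveys: which weeds became more or
less common in maize fields between two national survey periods, and which
traits predict their success once shared evolutionary history is accounted
for.

The package is aimed at community ecologists and weed scientists working
with class-scored vegetation surveys. It implements, as a tested reusable
pipeline:

* **Commonness metrics** — regional frequency `F`, local mean abundance
  from the six-class cover scale via midpoints,
  `A = [11.5 n₃ + 35.5 n₄ + 75.5 n₅ + 1.5 (N − n₃ − n₄ − n₅)]/N`
  (individuals/m²), crop fidelity, and the normalized change index
  `Ch = (S₂ − S₁)/(S₂ + S₁)`.
* **Stratified-bootstrap status calls** — the larger recent survey is
  resampled with replacement within regional strata at the historical
  stratum sizes (East 26, South-West 64, North-Parisian basin 41, West 26,
  South-East 17), and each species' historical point value is tested
  against the 95% percentile CI: `+` increase, `−` decrease, `=` stable,
  `N` new (below the 2.3% recording floor of the first survey), `?`
  undeterminable. Within-period trends use Spearman rank correlation with
  exact permutation p-values.
* **Phylogenetic GLS** — `y = Xβ + ε`, `ε ~ N(0, σ²V(λ, δ))` with `V` the
  shared branch-length covariance, Pagel's λ (off-diagonal scaling) and δ
  (power on node depths) estimated by profiled maximum likelihood, plus
  the likelihood-ratio test against λ = 0.
* **Hill–Smith ordination** of mixed quantitative/qualitative trait
  tables, with signed axis contributions and species scores usable as
  PGLS predictors.
* **Kruskal–Wallis / Dunn group contrasts** of PGLS residuals with a
  compact letter display.
* A **synthetic-survey generator** (occupancy–abundance coupling, Brownian
  trait evolution on pure-birth trees) standing in for the unreleased
  monitoring data, so every stage is testable end to end.

## Worked example

```python
import weedshift as ws

report = ws.run(ws.RunConfig(seed=4, B=200))
fa = report.manifest["fa_regression"]
print(f"{report.manifest['n_species_included']} species analyzed; "
      f"frequency~abundance slope {fa['slope']:.3f}, "
      f"lambda {fa['lambda']:.3f}, adj R^2 {fa['adj_r2']:.3f}")
```

prints (identically on every run with this seed):

```
107 species analyzed; frequency~abundance slope 1.189, lambda 0.010, adj R^2 0.597
```

That is: on the default synthetic scenario, 107 species pass the inclusion
rule (≥5 occurrences in the 2000s control plots); the PGLS of log
frequency on log abundance recovers the positive interspecific
abundance–occupancy relationship built into the generator (slope 1.19,
adjusted R² 0.60), and finds essentially no phylogenetic signal in the
residuals (λ̂ ≈ 0.01) — correctly, since the generator draws occupancies
independently of the tree. The same run is available from the shell:

```sh
weedshift simulate-run --seed 4 --out demo/ --B 200
```

which writes the full report (status tables, trend calls, change indices,
per-trait and per-axis PGLS coefficient tables, ordination contributions,
group-test summaries) as CSVs plus a provenance manifest. Lower-level
commands (`validate`, `summarize`, `status`, `pgls`, `ordinate`,
`residual-tests`, `run`) operate on your own CSV/Newick inputs; see
`weedshift --help`.

A status table row looks like:

| species | mean | ci_low | ci_high | point_P1 | status |
|---|---|---|---|---|---|
| sp012 | 0.391 | 0.331 | 0.451 | 0.265 | + |

read as: effort-equalized 2000s frequency 39.1% [33.1–45.1]; the 1970s
value 26.5% lies below the interval, so the species increased.

## Layout

```
src/weedshift/
  io.py          CSV/Newick readers and writers, validation, run manifest
  refdata.py     published survey-comparison table (embedded reference data)
  synthetic.py   survey/trait/tree generators (study-condition defaults)
  commonness.py  F, A, fidelity, change index
  bootstrap.py   stratified resampling, CIs, status and trend calls
  pgls.py        PGLS model + results, Pagel transforms, LRT
  ordination.py  Hill-Smith model + results, contributions
  group_tests.py Kruskal-Wallis, Dunn, compact letter display
  pipeline.py    end-to-end orchestration under one seeded config
  cli.py         `weedshift` console entry point
docs/methods.md  models, assumptions, defaults, limitations
```

The underlying models and all numerical choices are documented in
[docs/methods.md](docs/methods.md).
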