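# Methods

This note documents the statistical procedures implemented in `weedshift`,
the assumptions they make, the defaults they ship with, and what the
synthetic-data generator does and does not emulate.

## The analysis problem

Two national surveys of weeds in French maize fields — 174 control plots
across five regions in the 1970s (East 26, South-West 64, North-Parisian
basin 41, West 26, South-East 17) and 484 fields in the 2000s — are
compared to ask which species became more or less common, and which traits
predict success in maize. "Commonness" has three facets, computed on the
unweeded control plots only (the plot type both surveys share):

* **Regional frequency** `F`: fraction of surveyed fields where the
  species occurs. Fields visited in several years count once, keeping the
  maximum abundance class recorded (the tie rule is ours; the sources
  aggregate at field level without stating one).
* **Local mean abundance** `A` (individuals/m²): the survey records a
  six-class cover-abundance score ("+" = one individual per 2000 m² plot;
  1 = <1, 2 = 1–2, 3 = 3–20, 4 = 21–50, 5 = >50 individuals/m²), converted
  through class midpoints:

      A = [11.5 n3 + 35.5 n4 + 75.5 n5 + 1.5 (N − n3 − n4 − n5)] / N

  where `n3, n4, n5` count fields scored 3, 4, 5 and `N` is the number of
  fields of presence. Classes "+", 1 and 2 all carry the minimum midpoint
  1.5, the only reading consistent with the formula, which bounds `A` to
  [1.5, 75.5]. `A` is undefined (an error, not 0) when `N = 0`.
* **Fidelity** (specificity): the percentage of a species'
  midpoint-estimated individuals found in maize relative to all crops.
  Midpoints are used because they are the only density estimate class data
  afford; fidelities over all crops therefore sum to 100 per species.

Change between periods uses the normalized index
`Ch = (S2 − S1)/(S2 + S1)`, bounded to [−1, 1] and antisymmetric under
period swap; it is undefined when both values are zero.

## Stratified bootstrap and status calls

Raw frequencies are not comparable across periods because sampling effort
differs (174 vs 484 fields). The 2000s fields are therefore resampled with
replacement *within region*, at exactly the 1970s stratum sizes, and the
metric recomputed per replicate; every replicate conserves the strata (a
hard assertion in the code). The percentile interval of B replicates (B =
1000 by default; percentile rather than BCa, matching the published
phrasing — BCa is not offered) is the 95% CI around the effort-equalized
2000s mean. A species absent from a replicate contributes frequency 0 and
is excluded from that replicate's abundance mean.

A species' status is `+` if its 1970s point value falls below the CI, `−`
above, `=` inside. The 1970s survey recorded only the most frequent taxa,
so points below the recording floor (2.3% frequency by default) yield `N`
(new) when the species is present in the 2000s, `?` otherwise. Status is
monotone in the 1970s point by construction.

Within-2000s trends re-balance regional effort the same way within each
year (strata defaulting to the per-region minimum across years), then test
the yearly means against year with Spearman rank correlation. For series
of up to nine years the p-value is an exact two-sided permutation
probability (the full n! null is cheap at n = 7 and removes any
approximation doubt); longer series use the t approximation with midrank
ties. `p < 0.05` gives `+`/`−`, `0.05 ≤ p < 0.10` the marginal `(+)`/`(−)`.

## Phylogenetic generalized least squares

Species are phylogenetically dependent observations. Under Brownian trait
evolution the error covariance between species i and j is proportional to
`V[i,j]`, the root-to-tip depth of their most recent common ancestor. Two
transforms tune this structure: Pagel's λ ∈ [0, 1] multiplies the
off-diagonal entries (0 = star phylogeny/OLS, 1 = full Brownian motion),
and Pagel's δ ∈ (0.1, 3] raises node depths to a power after normalizing
the tree to unit depth (so δ is dimensionless); the matrix is rescaled
back afterwards, making λ = δ = 1 exactly the identity. The published
description of λ ("branch lengths multiplied by a factor") is ambiguous
between branch-length and covariance scaling; the standard Pagel
convention (off-diagonal scaling) is implemented.

Estimation is by maximum likelihood via the Cholesky-whitened regression:
β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y, σ̂² = rᵀV⁻¹r/n inside the likelihood, with standard
errors computed from (XᵀV⁻¹X)⁻¹σ̂²·n/(n−p) so t-tests follow the usual GLS
convention (this reproduces the behaviour of the standard comparative-
methods implementations). Free transform parameters are profiled on a
fixed 21-point grid and the bracketed optimum refined by bounded scalar
search (L-BFGS-B from the best grid point for joint λ+δ) — deterministic
and robust against local optima at this problem size. Reported R² and F
compare against the intercept-only GLS fit under the same covariance; the
exact null behind the published adjusted R² values is unstated, and this
is our choice. The LRT of λ = 0 uses the χ²(1) reference; the null value
lies on the boundary of the parameter space, so the test is conservative
(the true null is a 50:50 mixture of a point mass at 0 and χ²(1)), which
the type-I simulations confirm.

Fit diagnostics carried on the results object: coefficient table,
λ̂/δ̂, log-likelihood, adjusted R², F, response-scale residuals
(`y − Xβ̂`, satisfying XᵀV⁻¹r = 0), and β̂/t/p invariance under scaling of
V (checked by test). Frequency and abundance responses are natural-log
transformed before fitting, as are the heavily right-skewed traits (plant
height, seed weight, fecundity, seed longevity).

## Hill–Smith ordination

The mixed species-by-trait table (11 quantitative traits + 4 qualitative
traits in the generated schema) is ordinated by a PCA-like weighted
eigendecomposition. Quantitative columns are z-scored (population
variance, uniform row weights 1/n); each observed level k of a qualitative
trait becomes the centered indicator `(I_k − p_k)/√p_k` with `p_k` the
level frequency. A quantitative trait then contributes inertia 1 and a
qualitative trait with K levels contributes K − 1, the classic mixed-PCA
weighting; with only quantitative traits the eigenvalues equal those of
correlation-matrix PCA to numerical precision (a test asserts 1e−8).

Row (species) scores are principal coordinates whose weighted variance per
axis equals the eigenvalue; column loadings are scaled by √eigenvalue.
Each column's signed relative contribution to an axis is its squared
normalized loading (in %), signed by loading direction; absolute values
sum to 100 per axis. Contributions are reported both per design column and
aggregated per source trait, because the published contribution table is
ambiguous between the two views. Axis signs are arbitrary; each axis is
oriented so its largest-|loading| column is positive, so published axis
signs are matched only up to per-axis reflection. Species scores on the
leading axes are exported as orthogonal predictors for the PGLS stage.

## Group contrasts of residuals

Residuals of the frequency~abundance PGLS ("more/less abundant than
expected from frequency") are compared across taxonomic groups (Dicots,
Pooideae, Panicoideae), origin classes (native, archaeophyte, neophyte)
and herbicide-resistance status. Kruskal–Wallis H with midrank tie
correction (cross-checked against an independent implementation in the
tests) is followed by Dunn pairwise z tests on the pooled midranks,
two-sided, unadjusted by default (the published p-values look raw;
Bonferroni and Holm are available as flags). A compact letter display
summarizes the pairwise graph: letters are the maximal cliques of the
non-significance graph, pruned of redundant cliques, with deterministic
alphabetical ordering — groups share a letter if and only if they are not
significantly different. Response-scale residuals are tested by default;
whether the original analysis used one-sided Dunn tests or any adjustment
is unknown and exposed as options rather than guessed.

## Synthetic-data generator

Because the raw survey data were never deposited, the generator emulates
the study conditions so the machinery is testable end to end:

* **Design**: the historical strata (26/64/41/26/17 fields; note the
  printed sizes sum to 174, although the accompanying text says 175 —
  the strata are taken as operative) and 484 2000s fields apportioned
  proportionally by largest remainder; 2000s fields get years 2002–2008;
  treated plots are generated alongside controls in the 2000s only, and a
  second crop can be added for fidelity.
* **Occupancy**: lognormal per-species occupancy probabilities (median
  e^−3 ≈ 5%, log-sd 1.3, truncated at 0.95), giving the
  few-common/many-rare shape of real weed floras.
* **Abundance–occupancy coupling**: log mean density = 2.9 + 0.7·log
  occupancy + N(0, 0.5) across species, per-field densities lognormal
  around the species mean (log-sd 0.9), then discretized to the six-class
  scale with thresholds "+" ≤ 1 individual/plot, <1 → 1, [1,2] → 2,
  (2,20] → 3, (20,50] → 4, >50 → 5. The defaults put the most common
  species near 60% frequency and ~14 individuals/m², the scale of the
  published table. The slope 0.7 produces the positive interspecific
  frequency–abundance relationship; setting it to 0 decouples the facets
  (both verified by Monte-Carlo tests).
* **Traits and phylogeny**: pure-birth (Yule) trees with unit depth and
  strictly positive terminal branches; Brownian responses with tunable λ
  for parameter-recovery tests; a mixed trait table drawn within the
  published ranges and modality frequencies.
* **RNG discipline**: one integer seed drives named `SeedSequence`
  sub-streams per sub-generator, so every output is reproducible and
  sub-generators are independent.

What the generator does **not** emulate: spatial autocorrelation among
fields, seed-bank dynamics, herbicide-application effects, any causal link
between the generated traits and survey success, and any particular
interspecific abundance model asserted by the sources (there is none).
Passing tests therefore demonstrate the correctness and calibration of the
*procedures* — not that real weed communities satisfy the generator's
assumptions. An occurrence table cannot represent a weed-free field, so
presence vectors are redrawn until nonempty; with realistic pool sizes
this is vanishingly rare, but with very small species pools it conditions
frequencies upward, which matters for convergence tests (they use pools
large enough that the effect is below tolerance).

## Numerical choices and degenerate inputs

* Covariance factorizations go through Cholesky; non-positive-definite
  matrices raise with a condition-number diagnostic rather than silently
  regularizing.
* Perfect fits (zero residual variance) report infinite likelihood and
  adjusted R² = 1; they are legal inputs to fixed fits but poison LRTs,
  which then fail loudly.
* Eigendecompositions truncate at numerical rank (machine-epsilon
  threshold scaled by matrix size) with a warning when more axes are
  requested.
* Exact Spearman permutation p-values are used up to n = 9; midranks make
  the enumeration valid under ties.
* Ties in Kruskal–Wallis/Dunn use the standard (t³ − t) corrections; a
  fully constant sample returns H = 0, p = 1.
* `classify_status` requires a valid interval (low ≤ high) and treats NaN
  or sub-threshold 1970s points as "not recorded".

## Problem sizes used in the checks

The shipped verification suite uses: 200 outer replicates × B = 500 for
bootstrap coverage (surveys of exactly the historical stratum sizes, the
standard-bootstrap case); 100 replicates at 100 tips for λ recovery; 300
replicates at 50 tips for LRT type-I calibration; and the default
end-to-end scenario (120-species pool, 174 + 484 fields, B = 1000), which
runs in well under a minute on one CPU. These sizes give Monte-Carlo
standard errors comfortably below the tolerances they are checked against.

## Known limitations

* The species-inclusion rule for the analysis pool is a config parameter
  (default: ≥5 occurrences in the 2000s control plots); the rule behind
  the original 95-species set is not stated anywhere.
* Field-level aggregation is the default for multi-year fields;
  sample-level pooling is available as a flag but changes denominators.
* The published per-species numbers themselves are not reproducible
  without the raw data; only the printed table's internal arithmetic is.
* No OU or ACDC covariance structures, no measurement-error models, no
  phylogenetic ANOVA for the group contrasts.
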