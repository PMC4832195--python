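# Methods

This note documents the models and numerical choices behind soilnet's
four analysis stages and its synthetic-data generator, in enough detail
to judge what a passing test suite does and does not establish.

## Study design and data model

The package targets a factorial field design: S experimental sites × 2
fertilization treatments (CF = chemical NPK only, COF = chemical +
organic fertilizer) × R replicate plots, defaulting to S = 4, R = 3
(24 samples). Two response tables share the sample axis: 19
exchangeable-ion concentrations and 7 potential enzyme activities
(nmol · h⁻¹ · g⁻¹ soil). Metadata carries site, fertilization, replicate
and pH per sample. Values must be finite and non-negative; missing
values are rejected rather than imputed, because no defensible imputation
rule exists for this design and silent imputation would distort the
downstream dissimilarities and effect sizes. Variance estimation
requires at least two replicates per (site, treatment) cell, and the
metadata validator enforces this.

## Ordination

Bray–Curtis dissimilarity is the standard choice for non-negative
abundance-like profiles; it is computed exactly as
Σ|xᵥ − yᵥ| / Σ(xᵥ + yᵥ) and bounded in [0, 1].

NMDS minimizes Kruskal stress-1,
√(Σ(Dᵢⱼ − d̂ᵢⱼ)² / ΣDᵢⱼ²), where D are configuration distances and d̂
the isotonic regression of D on the rank order of the input
dissimilarities. Implementation choices:

* **Optimizer** — iterative majorization (Guttman transform) alternated
  with isotonic regression. A step-halving safeguard blends the proposal
  with the previous configuration whenever the raw step would increase
  stress, and stops when no blend improves; as a result the recorded
  stress trace is non-increasing by construction, which is exposed
  (`stress_path`) and tested rather than assumed.
* **Ties** — primary tie handling: pairs with tied dissimilarities are
  ordered by current configuration distance before the isotonic fit, so
  ties are never penalised. This is the common ecology default; no claim
  is made that it matches any particular other engine.
* **Initialisation** — restart 0 from classical (Torgerson) scaling,
  further restarts from seeded Gaussian configurations. Restart i draws
  from `SeedSequence([seed, i])`, so enlarging `n_restarts` appends
  candidates without perturbing earlier ones; the best-of-restarts stress
  is therefore monotone in the restart count.
* **Convergence** — relative stress decrease < `tol` (default 1e−7) or
  `max_iter` (default 500); non-convergence returns a flagged result with
  a logged warning rather than an exception.
* **Reporting** — the winning configuration is centred, rotated to
  principal axes with a deterministic sign convention, and stress is
  re-evaluated on the rotated coordinates. Stress is reported on the 0–1
  scale. Shepard diagnostics: non-linear R² = 1 − Σ(D − d̂)²/Σ(D − D̄)²,
  linear R² = squared Pearson correlation of D with the original
  dissimilarities, and a per-sample sum of squared disparity residuals
  for bubble sizing. The non-linear R² can never fall below the linear
  R² when the Shepard relation is increasing, since the isotonic fit
  minimizes the residual over all monotone fits including the linear one;
  this is verified empirically over seeded datasets.

## Variance partitioning

The response table is Hellinger-transformed (square root of row-relative
values), then column-centred; no column standardization is applied since
the Hellinger transform already puts rows on a common scale. Explanatory
blocks: centred pH (1 column), site indicators (drop-first, 3 columns at
S = 4), and a single COF indicator. R² of a block union is the ratio of
the projected to the total centred sum of squares (redundancy analysis
with an implicit intercept); the Ezekiel adjustment
1 − (1 − R²)(n − 1)/(n − m − 1) uses the *effective rank* m of the
centred predictor union, so perfectly collinear blocks are handled by
subspace projection rather than rejected — rank deficiency *within* a
single block still raises, naming the aliased columns. Adjusted R² is
the default because shared fractions can then be legitimately negative
(a suppression signature that raw R² cannot produce); `adjusted=False`
is available, and the exact algebraic identities (single-source response
→ a = 1, orthogonal additive signal → zero shared fractions) hold only
in that raw mode, where they are tested at 1e−6.

The inclusion–exclusion decomposition computes adjusted R² for the seven
non-empty unions and solves for unique (a, b, c), pairwise (ab, ac, bc)
and triple (abc) fractions; residual = 1 − R²(abc), so the eight
fractions sum to 1 identically.

Unique fractions are tested by permuting reduced-model residuals
(partial-RDA scheme): Y* = fitted_reduced + permuted residuals, statistic
is the partial pseudo-F on raw R², p = (1 + #{F* ≥ F})/(1 + B), B = 999
by default. The permutation engine is vectorised over permutations, so
999 permutations on a 24-sample design cost milliseconds.

## Response ratios

R = ln(X̄_COF / X̄_CF) per variable, with delta-method variance
v = SD²_COF/(n_COF X̄²_COF) + SD²_CF/(n_CF X̄²_CF), weight w = 1/v, CI
R ± λ√v (λ = 1.96 default), significance ⇔ CI excludes zero. Group
means, SDs and n pool all samples of a treatment across sites (n = 12
under the default design); this pooled reading is a deliberate
interpretation — per-site weighting schemes exist, but the pooled n = 12
summary is the convention this design reports. No between-study
heterogeneity variance τ² is added: effect sizes are displayed per
variable, not meta-analytically pooled across variables, so the
inverse-variance weights are carried in the output for downstream use
rather than consumed internally. Variables with a non-positive group
mean are reported as excluded with a reason instead of propagating NaNs.
Zero sampling variance collapses the CI to a point (flagged by w = ∞).

## Co-occurrence networks

Pearson correlations are computed over all variable pairs *within each
treatment group* (n = 12), because the CF and COF networks are separate
objects and 0.58 ≈ the two-sided α = 0.05 critical r at n = 12, which
makes the published double cutoff internally consistent under this
reading. p-values come from t = r√(n−2)/√(1−r²) with n − 2 df.

Edge admission uses |r| > 0.58 (strict) AND p < 0.05. The absolute-value
reading is deliberate and load-bearing: co-occurrence networks in this
setting contain negative edges, which a signed rule r > 0.58 could never
admit. Admission is monotone in both cutoffs, and at n = 12 every
admitted |r| implies p < 0.05, both property-tested. No multiple-testing
correction is applied by default (the reference procedure thresholds raw
p-values); correcting would be a one-line change on the p matrix.

Nodes with no admitted edge are excluded from the node set, so
`average_degree_paper` = E/N matches the convention under which a
19-node, 88-edge graph has average degree 4.632; the textbook mean degree
2E/N is reported alongside. Path length averages over connected pairs;
diameter is the maximum over components. Communities come from Louvain
modularity optimisation (networkx, unweighted, resolution 1, fixed
seed — deterministic), with the modularity value
Q = Σ_c (e_c/m − (d_c/2m)²) recomputed by the package's own evaluator.
Generalists are degree-ranked with lexicographic tie-breaks and a
per-node negative-edge fraction. Exports: GEXF, GraphML, TSV edge list.

## Synthetic generator

The generator emulates the design above; it is the package's test bed,
not a model of any real soil. On the log scale, variable v in sample i
of cell (site s, treatment t):

ln x = ln μᵥ + σ_site·aₛᵥ + δᵥ·1[t = COF] + σ·eᵢᵥ − σ²/2,

with σ = √ln(1 + cv²). Choices and defaults:

* **Lognormal noise** (cv default 0.2): extract concentrations and
  enzyme activities are positive and right-skewed; a 20% within-plot CV
  is typical for these assays. The −σ²/2 shift plants treatment effects
  on *cell means*, not on lognormal medians, so the log ratio of group
  means recovers δ without the exp(μ + σ²/2) mean bias.
* **Site effects** (σ_site default 0.4, multiplicative per variable per
  site): large enough that site is a dominant variance component, as a
  multi-site trial shows.
* **Planted ratios**: Al −1.2 and P +1.0 (the extremes this kind of
  trial reports), acid-mobilised metals negative, manure-borne nutrients
  positive, enzymes mostly positive with α-glucosidase strongest (+0.8).
* **pH covariate**: base 6.8, CF cells depressed by 1.1 units
  (chemical-only fertilization acidifies), site shifts SD 0.3, noise SD
  0.1, clipped to [0, 14].
* **Correlation blocks**: variables in a block share a latent factor in
  both site offsets and noise, with per-variable loadings λ ∈ [−1, 1];
  the planted log-scale correlation between members is λᵤλᵥ. Defaults
  plant an acid-metal block with negatively loaded glucosidases (the
  source of negative enzyme–ion edges) and a manure-nutrient block. A
  variable belongs to at most one block.
* **Determinism**: one seed, four spawned substreams in a fixed draw
  order (baselines → site offsets → pH → noise); identical seeds give
  bit-identical output.

What the generator does *not* emulate: real soil-chemistry covariance
beyond the planted blocks, detection limits/censoring, spatial
autocorrelation within sites, or inter-annual variation. Tests passing
on synthetic data therefore establish the correctness and calibration of
the *procedures*, not the field conclusions of any particular study.

## Calibration experiments and their conditions

Three of the acceptance experiments validate *nominal* statistical
behaviour and are run with `site_effect_sd = 0` (exchangeable samples
within treatment):

* the 95% CI rule's false-positive rate (expected ≈ 5%, measured over
  500 × 26 null effects);
* planted-block network recovery (within-block sensitivity ≥ 90%,
  cross-block false-edge rate ≤ 5% — the theoretical null admission rate
  of the |r| > 0.58 rule at n = 12 is 4.79%, so the measurement
  aggregates both treatment groups over 50 studies to keep Monte-Carlo
  error near 0.2%);
* the within-block |r| > 0.58 property of the generator itself.

This is by design, not convenience: with between-site heterogeneity, the
pooled SD makes the CI deliberately conservative, and clustered samples
shrink the effective n of a correlation toward the number of sites, so
the nominal rates are provably not recoverable under heterogeneity. The
effect-size *recovery* experiment (mean R over 200 studies within ±0.03
of δ ∈ {−1.2, 0, +1.0}) keeps the full default heterogeneity, since site
effects cancel from the ratio of group means.

Problem sizes used throughout (24-sample designs; 50–500 replicate
studies; 6–12-point NMDS oracle instances) keep the full suite and the
acceptance script each under a minute on one CPU while leaving
Monte-Carlo error well inside the tested tolerances.

## Known limitations

* NMDS finds local optima; with 8 restarts on 24 samples the best stress
  is stable in practice, but global optimality is not guaranteed, and no
  numeric agreement with any other NMDS engine's stress values is
  claimed (tie handling, convergence and restart policies differ).
* Adjusted-R² fractions are unbiased only asymptotically; at n = 24 with
  5 predictor columns the adjustment terms are of order 0.05 and shared
  fractions inherit that noise.
* The delta-method RR variance assumes moderate CVs; for CV ≫ 0.5 the
  log-ratio CI coverage degrades.
* Louvain is seed-deterministic but not canonical: different seeds can
  give different near-optimal partitions; modularity values are
  comparable, community labellings are not.
* The |r| cutoff admission treats correlations marginally; no
  conditional-independence (partial-correlation) structure is inferred.
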