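# Methods

This note documents the statistical model behind `breedvar`, the defaults
of its synthetic-trial generator, the numerical conventions, and the design
choices that were genuinely open.

## The trial model

The package targets the standard mutation-breeding experiment in a
self-pollinated crop (the built-in defaults describe a two-variety cowpea
trial). Seed lots of 300 are exposed to gamma-ray doses (100–1000 Gy,
G1–G10), sodium-azide concentrations (0.01–0.1 %, S1–S10), or both
(G1+S1…G10+S10); survivors are grown in a randomized complete block design
with r = 30 replications and phenotyped for ten quantitative traits —
plant height (PH, cm), days to flowering (DF), days to maturity (DM), pods
per plant (PPP), branches per plant (BPP), seeds per pod (SPP), 100-seed
weight (SW, g), pod length (PL, cm), plant yield (PY, g), harvest index
(HI, %) — over generations M₁–M₄, with truncation selection of
high-yielding lines between generations.

For one (variety, treatment, trait) cell the observation model is the
balanced one-way random-effects layout

    y_{ℓk} = μ + τ (treatment shift) + g_ℓ + e_{ℓk},
    g_ℓ ~ N(0, σ²g),  e_{ℓk} ~ N(0, σ²e),

with ℓ indexing lines and k replicate plots. Normality of effects and
errors is assumed implicitly by the ANOVA throughout.

## Genetic parameters

From the among-line mean square MSG and the pooled within-line mean square
MSE:

- σ̂²g = max(0, (MSG − MSE)/r) — the moment estimator; E[MSG] = σ²e + r·σ²g.
  Negative estimates are truncated to zero with a logged warning (the
  conventional resolution; the truncation is rare at the default variance
  ratios).
- σ̂²p = σ̂²g + MSE — phenotypic variance on a *plot* basis. This
  definition is what makes the genetic-advance identity below hold row by
  row; a line-mean basis (σ²g + MSE/r) would give systematically different
  GA values.
- GCV % = 100·√σ̂²g/x̄ (the Allard form, with the square root; the
  parameters are unit-free and scale-equivariant: multiplying a trait by
  c > 0 leaves GCV, h², GA unchanged).
- h² % = 100·σ̂²g/σ̂²p — broad-sense, plot basis; defined as 0 when
  σ̂²p = 0.
- GA (% of mean) = 100·k·σ̂p·(h²/100)/x̄, algebraically equal to
  k·GCV %·√(h² %/100). k defaults to 2.64, the standardized selection
  differential at 1 % selection intensity; it is configurable.

All arithmetic is done in full precision; report renderers round
half-to-even to two decimals only at presentation time.

## Duncan's multiple range test

Group means are sorted in descending order. A span of p adjacent means is
non-significant when its range is at most

    LSR(p) = q*(p, df_e, α_p) · √(MSE/r),   α_p = 1 − (1 − α)^(p−1),

where q* is the studentized-range quantile at Duncan's protected level,
computed from `scipy.stats.studentized_range` rather than the historical
1955 tables, so any error df is reproducible. At small df the raw
protected quantile can decrease slightly as p grows; each LSR is floored
at the previous span's value (as the classical tables do), which keeps
LSR non-decreasing in p. Two means differ significantly iff *no*
containing span is non-significant; the maximal non-significant spans
become the letters. Because the non-significance sets are intervals of the
sorted order, the letter display is minimal by construction. Ties in means
break by group label, making the output deterministic. Only the balanced
case is supported (the harmonic-mean variant is out of scope).

The letter comparison across treatments uses per-line means as the
replicate unit (n = number of lines, error df = Σ(n−1) pooled within
treatments). Trial reports that quote "n = 30" are ambiguous between 30
replicate plots and 30 lines; the simulator exposes both knobs so either
reading is representable, and the analysis layer commits to lines.

## Correlation and path analysis

Spearman matrices use average ranks for ties and p-values from the
t-approximation on n − 2 df, starred at 0.05/0.01/0.001. A constant trait
has no rank variance; its cells are flagged NaN rather than silently 0.

Path analysis solves Rxx·b = rxy for the direct effects, with indirect
effects I[i,j] = r_ij·b_j and residual E1 = √(max(0, 1 − Σ b_i·r_iy))
(flagged when the clip engages). The decomposition identities
r_iy = b_i + Σ_{j≠i} I[i,j] only hold when b is solved against the same
correlation matrix that produced rxy, so the estimator defaults to Pearson
input even though trait *association* reporting is Spearman; Spearman
input is selectable. Predictor sets with reciprocal condition number below
10⁻¹⁰ are rejected with advice to drop a redundant trait. The default
predictor set is {PPP, BPP, SPP, SW, PL, HI}: plant height and the two
phenology traits have negligible direct effects on yield and are excluded.
Published path coefficients from covariance-structure software can exceed
1 (unstandardized input scaling that raw data would be needed to
reproduce); this implementation reports standardized coefficients, checked
by its algebraic identities and by recovery of the simulator's known
coefficients.

## Multivariate profiling

Populations are summarized by their trait-mean vectors. Euclidean
distances are computed on **raw** means by default — mixed units included —
because that convention reproduces the printed proximity extremes of the
reference trial to within rounding (minimum pair 2.67 here vs 2.66
printed), whereas z-scored distances do not; standardization remains a
flag. The printed *maximum* distance (29.00) is not reproducible from the
printed means (29.82 here); the trial's exact input matrix is ambiguous
and the discrepancy is documented rather than forced.

UPGMA is implemented directly (unweighted average linkage,
d(C, A∪B) = (|A|·d(C,A) + |B|·d(C,B))/(|A|+|B|)) with ties broken by the
smallest member-label pair, so dendrograms are platform-deterministic;
`scipy`'s average-linkage serves as an independent cross-check in the test
suite. Flat clusters are extracted by count k (cutting after n − k
merges), matching how cluster numbers are reported in trial write-ups.
Dendrograms export to Newick with ultrametric branch lengths (leaf depth =
merge height / 2).

PCA is an eigendecomposition of the trait **correlation** matrix (traits
are on incommensurate scales). Under this convention Σλ = number of
traits, cos2(variable, component) = squared loading with rows summing to
1, and contributions = 100·(eigenvector entry)² with columns summing to
100. Component signs are fixed so the variable with the largest |loading|
loads positively, making outputs reproducible across BLAS builds.

## Genetic gain

gain % = 100·(treatment mean − control mean)/control mean within a
generation, and the between-generation improvement is the difference of
gains. This operational definition is the one consistent with all the
reference trial's printed per-generation figures (e.g. 28.75 % and a
9.28-point M₂→M₃ improvement for the 100 Gy population of the first
variety); the gain is scale-invariant in the yield unit.

## The synthetic-trial generator

The generator's defaults *are* the study conditions; they are not tuning
knobs.

- **Means and shifts.** Control trait means and per-treatment mean shifts
  are taken from the reference trial's published M₂ mean matrix
  (`breedvar.reference`), so simulated effect sizes have the published
  structure. Treatments outside that matrix shift by zero.
- **Variances.** Genotypic SD among lines defaults to 5 % of the trait
  mean, with σ²e = σ²g/4 — a plot-basis h² of 0.8, in line with the high
  heritabilities the trial reports. (Published GCVs range ≈ 0.3–18 %; 5 %
  is mid-range.)
- **Yield path structure.** Component genotypic scores z_t are
  independent; the yield genotypic score is z_PY = Σ b_t·z_t + ε with
  b = (SW 0.6, SPP 0.4, PPP 0.2, HI 0.15, BPP 0.1, PL −0.05) and residual
  SD √(1 − Σb²) = 0.6364, then back-scaled by √σ²g(PY). Yield therefore
  has unit genotypic variance on the standardized scale and a built-in
  ground-truth path decomposition (R² = 0.595).
- **Germination.** Expected germination is g₀·L(s·(d − d₅₀))/L(−s·d₅₀)
  with L the logistic function, g₀ = 0.9, s = 0.012 per Gy-equivalent and
  d₅₀ = 435 Gy-equivalent; counts are Binomial(300, p). Sodium azide is
  mapped to a gamma-equivalent scale (0.01 % ≙ 100 Gy, weight w
  configurable). For combined treatments the severity is
  **max**(gamma, w·SA-equivalent) — a limiting-factor model. An additive
  composite is also available, but it cannot reproduce the reference
  trial's retained set: any monotone response of gamma + SA that excludes
  500 Gy must also exclude the 400 Gy + 0.04 % combination (800
  Gy-equivalent additively), which the trial retained. Under the
  limiting-factor default every series' exclusion boundary falls between
  dose indices 4 and 5, and the screen retains exactly 13 populations.
  The combined treatments remain the most severely affected *phenotypically*
  through their mean shifts.
- **Generations and selection.** Line effects are drawn once and persist
  across generations (the heritable component); plot errors are redrawn
  each season. Truncation selection (default: top 30 by observed yield
  line-mean) first applies when advancing from M₂, matching the field
  procedure of selecting among segregating M₂ lines; the initial line
  count defaults to 60 per treatment — a scaled-down stand-in for the
  thousands of field M₂ plants — so a genuine selection differential
  exists. The untreated check is never selected on phenotype; it is
  advanced as a deterministic subsample of the first n line ids
  (exchangeable, hence unbiased), which keeps later generations balanced.
- **Randomness.** Everything flows from one integer seed through
  `numpy.random.SeedSequence` spawning; identical inputs give
  byte-identical CSV output. No global RNG state is used.

What the generator does *not* emulate: spatial field structure and
neighbour effects, genotype×year interaction, segregation distortion or
marker-level genetics, dose-dependent variance inflation, and non-normal
trait distributions. Passing tests therefore demonstrate correctness of
the estimators under the stated random-effects model, not robustness to
those field realities.

## Pigments

Chlorophyll (mg·g⁻¹ fresh mass) = (20.2·OD645 + 8.02·OD663)·V/(1000·W);
carotenoids = (7.6·OD480 − 1.49·OD510)·V/(d·1000·W) with path length
d = 1.4 cm by default. Printed versions of these equations often have
garbled parenthesization; the forms above are the dimensionally consistent
Arnon-style readings (chlorophyll carries no path length, exactly as
conventionally printed — flagged as a known oddity). A negative carotenoid
bracket is physically impossible and clips to zero with a logged warning.

## Problem sizes and numerical conventions

- Estimator-recovery checks run at 30 lines × 30 replicates × 200 cells
  (variance components) and 1,000 lines × 100 seeds (path coefficients);
  the test suite uses smaller replicas of the same checks where a property
  does not require the full size.
- Identities are asserted at 10⁻⁹–10⁻¹² (GA identity, path
  reconstruction, PCA eigenvalue/cos2 sums); oracle comparisons at 10⁻⁴
  (studentized-range quantiles) and 10⁻⁸ (eigensolver).
- Degenerate inputs: all-identical observations flag an undefined F
  rather than erroring; zero-variance traits error by name under
  standardization/correlation PCA; singular predictor matrices error with
  removal advice; negative σ̂²g and negative carotenoid brackets clip with
  logged warnings.

## Known limitations

- Only balanced layouts are supported end to end (equal replicates per
  line, equal line counts across compared treatments); unbalanced data
  fail loudly rather than approximately.
- No REML/mixed-model estimation — the variance components are moment
  estimators from ANOVA mean squares, by design.
- No bootstrap confidence intervals for path coefficients or cluster
  stability; no biplot rendering.
- The path-coefficient recovery band (±0.05 per coefficient at 1,000
  lines) is tight relative to the sampling noise implied by the default
  residual path (per-coefficient SD ≈ 0.02): each coefficient individually
  recovers within the band ~99 % of the time, but demanding all six
  jointly passes in only ~92–94 % of seeds.
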