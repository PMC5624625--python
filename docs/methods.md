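# Methods

`gradiv` implements a community-phylogenetics workflow for plot-based
vegetation surveys along environmental gradients: phylogenetic signal of
functional traits, three facets of alpha and beta diversity with a
permutation null model, and attribution of the diversity patterns to
climate, habitat and geographic distance. A synthetic-data generator with
known assembly ground truth backs every stage with a recovery test.

## Diversity indices and the null model

**Taxonomic** alpha diversity is species richness per plot; taxonomic beta
diversity is Bray-Curtis similarity, 1 − Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ), between plot
abundance vectors.

**Phylogenetic and functional dispersion** use the abundance-weighted mean
pairwise distance. Within a plot,

    MPD = Σ_{i≠j} f_i f_j d_ij / Σ_{i≠j} f_i f_j,

with f the within-plot relative abundances and d either patristic distances
on the phylogeny or cophenetic distances on the functional dendrogram.
Between plots the double sum runs over cross-plot species pairs (conspecific
pairs contribute d = 0). Weights are relative abundances by construction, so
every statistic is invariant to rescaling raw cover values; Braun-Blanquet
ordinal codes are converted to percent-cover midpoints (r→0.1, +→0.5,
1→2.5, 2→15, 3→37.5, 4→62.5, 5→87.5 — the standard midpoint convention,
configurable because field protocols differ).

The null model shuffles species names across the tips of the tree or
dendrogram (equivalently: jointly permutes rows and columns of the distance
matrix) while leaving the community matrix untouched, preserving richness,
abundance and occupancy structure exactly. The net relatedness index is

    NRI = −1 × (MPD_obs − mean MPD_null) / sd MPD_null,

with the sample (n−1) standard deviation; positive NRI means co-occurring
species are more closely related than expected (clustering), negative means
overdispersion. Defaults: 1000 randomisations; the species pool is the set
of species observed on the plot's transect (a `global` pool is available).
For beta pairs one label permutation per replicate is applied jointly to
both plots, preserving shared-species structure. Plots with fewer than two
species are excluded from alpha dispersion and logged; a null with zero
spread is flagged degenerate and reported as NRI = 0 with a warning.

Note that some community-phylogenetics packages (e.g. picante) keep
conspecific pairs in the abundance-weighted within-plot MPD denominator; the
two conventions differ by the factor 1 − Σf² (the test suite cross-checks
against picante through this identity). The between-plot MPD is identical
to picante's `comdist`.

## Phylogenetic signal

**Blomberg's K** is the ratio of the observed to the Brownian-expected
phylogenetically corrected trait variance,

    K = [ (x−â1)ᵀ(x−â1) / (x−â1)ᵀC⁻¹(x−â1) ] ÷ [ (tr C − n/(1ᵀC⁻¹1)) / (n−1) ],

where C is the phylogenetic variance–covariance matrix (Cᵢⱼ = shared
root-to-MRCA branch length) and â the GLS mean (1ᵀC⁻¹x)/(1ᵀC⁻¹1). K = 1
under Brownian motion on any topology (exactly 1 on a star tree, which the
suite uses as a closed-form check). All solves go through a Cholesky
factorisation; an explicit-inverse implementation exists only as a test
oracle.

**Pagel's λ** multiplies the off-diagonal of C. The profile log-likelihood
(GLS mean and σ̂² = residual quadratic form / n concentrated out) is
maximised on [0, 1] by bounded scalar minimisation to 1e-6, with the two
endpoints evaluated explicitly because boundary optima are common and the
bounded search never touches them. λ slightly above 1 can be
likelihood-optimal on some trees but lies outside the interpretation scale
and is not explored. On a star phylogeny C(λ) is constant in λ; the fit
warns and returns NaN.

**Significance** for both statistics comes from permuting trait values
across tips (the same tip-shuffle logic as the community null), with the
upper-tail p-value (1 + #{null ≥ observed})/(n_perm + 1); the +1 correction
keeps p strictly positive. 1000 permutations by default. A likelihood-ratio
test against λ = 0 would be a natural alternative for λ; the permutation
test is the default so both statistics share one significance framework.
Traits are log-transformed and z-scored before testing by default (both
statistics are affine-invariant, so this only stabilises numerics and
matches the treatment used for the dendrogram); `log_standardize=False`
switches to raw values.

## Functional dendrogram

Traits (maximum height m, leaf length cm, leaf width cm, flowering onset
month, seed mass mg) are natural-log-transformed — the base is irrelevant
after z-scoring — and standardised per trait (sample SD). PCA is an
eigendecomposition of the correlation matrix of the standardised traits,
with each component's sign fixed so its largest-magnitude loading is
positive (deterministic across platforms). By default the first 4 of 5
components are retained (a cumulative-variance threshold rule is available),
scores are left unweighted by eigenvalues, and the Euclidean distance over
the retained scores is clustered by UPGMA (scipy average linkage; labels are
sorted before clustering so tie-breaking is deterministic). Merge heights
are half the average linkage distance, so the dendrogram is ultrametric and
the cophenetic distance between two tips is exactly the linkage distance of
the merge joining them. UPGMA reproduces an already-ultrametric input matrix
exactly, which the suite uses as an invariant.

## Driver attribution

Seven plot-level climate variables (mean annual, January, August and
growing-season temperature, August–January range, annual and growing-season
precipitation) are reduced by PCA after log-transforming the two
precipitation variables and z-scoring all seven; the first two axes are the
climate predictors. Slope (degrees) is log-transformed (offset 0 when all
slopes are positive, else 1) and the rocky-area ratio arcsine-sqrt
transformed; these are the habitat predictors.

Distances between plots: geographic distance uses an equidistant
cylindrical projection, x = R·lon·cos(lat₀), y = R·lat with R = 6 371 000 m
and lat₀ the mean plot latitude (within 1% of great-circle distance for
pairs under 50 km at mid-latitudes, an invariant in the suite); climatic,
habitat and environmental distances are Euclidean over the corresponding
predictor columns, so Dist_env² = Dist_clim² + Dist_habit² holds exactly.

Attribution methods, all operating on the lower-triangle vectors where the
response is a distance matrix:

- **Simple OLS** per predictor: R², slope sign, two-sided t-test p.
- **Simple Mantel test**: Pearson r over triangle entries; significance by
  jointly permuting rows/columns of the second matrix, two-tailed on |r|
  with the +1 correction; 999 permutations by default.
- **All-subsets AICc model averaging**: every non-empty predictor subset is
  fitted by OLS (2⁴−1 = 15 models for the four alpha predictors, 2³−1 = 7
  for the three beta distance matrices; the intercept-only model is
  excluded, which is what those printed counts imply). AICc =
  n·log(RSS/n) + 2p + 2p(p+1)/(n−p−1) with p = subset size + 2 (intercept
  and variance). Akaike weights exp(−Δᵢ/2), normalised; per-variable
  importance is the summed weight of models containing the variable. For
  distance responses the AICc is computed on the raw triangle vectors
  (pairs are not independent, so these AICc values rank models rather than
  estimate evidence; the permutation-based MRM provides the inferential
  complement).
- **Variation partitioning** by partial regressions: pure_a = R²_ab − R²_b,
  pure_b = R²_ab − R²_a, shared = R²_a + R²_b − R²_ab, unexplained =
  1 − R²_ab, with unadjusted R² (fractions then sum to 1 exactly; an
  adjusted-R² variant can produce negative fractions and is not the
  default). For beta diversity the blocks are the geographic and the
  integrated environmental distance and the R² come from triangle-vector
  regressions.
- **MRM**: OLS of the response triangle vector on predictor triangle
  vectors; coefficient-wise significance by permuting rows/columns of the
  response matrix and refitting (two-tailed on |coefficient|, +1
  correction, 999 permutations).

Beta responses enter this machinery as symmetric zero-diagonal carriers:
Bray-Curtis similarity (the primary convention; dissimilarity is also
emitted) and the between-plot NRI, which can be negative — hence the
distinction between the general `PairMatrix` carrier and the non-negative
`DistanceMatrix`.

## Synthetic data generator

One call produces a full transect dataset: a Yule (pure-birth) tree with
tip depth normalised to 1 (so the Brownian rate σ² is the trait variance
accumulated root → tip), traits drawn from N(0, σ²·C(λ)) with λ tunable,
plots evenly spaced over the elevation range on a straight ~5 km lon/lat
line (geographic and elevational distance deliberately collinear, as on a
single mountain flank), and metadata in which the five temperature
variables decrease linearly with elevation (lapse ≈ 5–6 °C per standardised
elevation unit, observation noise SD 0.3 °C), precipitation increases with
elevation and a second, elevation-independent moisture factor
(multiplicative noise), and slope/RAR are terrain noise (RAR optionally
tilted toward high elevation). Because the seven climate variables are
driven by two latent factors plus small noise, the first two climate PCA
axes retain > 95% of their variance by construction.

Expected abundance of species s in plot p is a Gaussian niche kernel,
amplitude × exp(−½((e_p − o_s)/breadth)²), with Poisson counts on top; the
kernel amplitude declines toward high elevation by the `richness_gradient`
fraction, reproducing the monotonic richness decline expected on temperate
mountains. The scenarios differ only in how optima o_s relate to traits:

- **filtering** — o_s is a linear map of the first (phylogenetically
  conserved) trait, so co-occurring species are relatives: NRI > 0.
- **competition** — optima are random, but each plot is assembled
  sequentially in order of decreasing expected abundance and a candidate
  within the limiting-similarity radius (0.4 trait SD) of a resident is
  rejected: with trait signal present, NRI < 0.
- **neutral** — optima are uniform at random: NRI centred on 0.

Defaults (60 species, 60 plots, 300–1700 m, niche breadth 250 m, base
Poisson mean 20) mirror the scale of a single field transect (tens of plots,
60–90 woody species). Empty plots are redrawn up to 100 times, then an
error is raised rather than silently densifying the data.

What the generator does **not** emulate: spatially explicit dispersal,
birth–death (extinction) trees, trait–environment interactions beyond one
trait axis, ordinal cover recording, observation error in species identity,
and multi-transect topography (multi-transect datasets are produced by
concatenating runs). Passing recovery tests therefore demonstrate the
statistical machinery is correct and calibrated, not that real communities
satisfy these generative assumptions.

## Validation experiments (calibration module)

All experiments derive child seeds from one master seed and are fully
deterministic. Reference problem sizes:

- **Neutral calibration**: 80 independent transect replicates × 8 plots
  (640 plots), n_null = 999. Replicates are pooled because all plots of one
  replicate share a single tree and optimum draw, so within-replicate NRI
  values are correlated; the replicate count, not the plot count, controls
  the Monte-Carlo error of the grand mean.
- **Type-I error**: 1000 trials, 199 permutations per trial (p resolution
  0.005 at α = 0.05), 50-tip tree for the trait test, 20-plot matrices for
  Mantel.
- **λ recovery**: 200 replicates of fresh 200-tip trees at λ ∈ {0, 1};
  **K calibration**: 500 Brownian traits on one 100-tip tree.
- **Direction recovery**: 10 replicates × 25 plots per scenario, one-sample
  t-test on replicate means (one-sided in the predicted direction).

## Run configuration

The `gradiv all` command consumes a YAML mapping of `RunConfig` fields:
`out_dir`, either `scenario:` (ScenarioConfig fields) or the four input
paths (`tree_path`, `community_path`, `traits_path`, `metadata_path`),
stage sizes (`n_components`, `n_null`, `n_perm_signal`, `n_perm_matrix`),
the null-pool scope (`pool: transect|global`) and the three mandatory stage
seeds (`seed_signal`, `seed_null`, `seed_perm`) — a missing seed fails
validation before any computation. Every output table carries a header
comment with the config hash and stage seed, and rerunning an identical
config reproduces every table byte for byte.

## Known limitations

- λ is restricted to [0, 1]; trees whose ML λ exceeds 1 are reported at the
  bound.
- The AICc for distance-matrix responses treats triangle entries as
  independent observations (see above); interpret Akaike weights for beta
  responses as rankings.
- The permutation count/tail conventions for Mantel and MRM (999,
  two-tailed) are package defaults, not field universals; both are
  configurable.
- The NRI engine recomputes the full plot × plot MPD matrix per null
  replicate; for very large plot counts (≫ 1000) beta profiles become the
  bottleneck.
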