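# Methods

## Distances and the topological convention

All phylogenetic distances are node counts: the number of edges on the
path between two tips, equivalent to patristic distance after setting
every branch length to 1. This is the right convention when the tree is a
literature-assembled topology whose branch lengths would be fabricated;
any lengths present in an input file are kept on the tree object but never
used, and the reader flags them as unused. Node-count distances are
bounded (≥ 2 between distinct tips on a rooted tree, ≤ 2·depth), which is
what makes the similarity map below well behaved.

Species names are matched case-sensitively after trimming whitespace, with
spaces and underscores treated as equivalent (the newick convention).
Latitude is stored as absolute decimal degrees south — the regressions are
sign-invariant but one convention has to be fixed, and all bundled and
simulated sites are in the southern hemisphere; degree-minute strings
(`24°32'S`) are converted exactly (1/60°).

## Structure indices

NRI and NTI are sign-flipped standardized effect sizes of MPD and MNTD so
that clustering is positive. The null holds richness fixed and draws
uniform random subsets of the site's **regional pool** (the pool subtree,
not the metacommunity-wide tree); for presence/absence data this is
equivalent to shuffling the tip labels of the pool subtree. Defaults: 9,999
randomizations, significance flagged at |z| > 1.96 under the normal
approximation (a randomization-rank p is also emitted but the flag follows
the z rule). Numerical conventions:

- Monte-Carlo nulls use the sample (n−1) standard deviation; exhaustive
  enumeration (small pools) uses the population form, since the enumeration
  *is* the null population. Tests compare the two through their means and
  3-standard-error bands.
- A null with zero standard deviation (community = pool, or a star tree)
  makes the index undefined; the record is flagged `degenerate` rather than
  guessed at.
- Singleton communities have no MPD/MNTD and are reported as missing.

## Fuzzy weighting and PCPS

Similarity is `s = 1 − d/max(d)` — the fuzzy-weighting literature leaves
the distance-to-similarity map open; this one maps the bounded node-count
range onto [0, 1] and is invariant to uniform distance rescaling. Columns
of the similarity matrix are normalized to fuzzy weights Q (each species
spreads one unit of belonging over its relatives, including itself), and
`P = Q·W_rel` with composition first standardized to site relative
frequencies. Both Q and P are column-stochastic to machine precision, and
on a star phylogeny (no phylogenetic information) P reduces exactly to the
relative composition.

PCoA is classical scaling: double-center `−d²/2`, eigendecompose, keep
strictly positive eigenvalues, no Cailliez/Lingoes correction — axes with
non-positive eigenvalues are dropped and counted in the output. Variance
fractions are relative to the positive spectrum only. Site scores are
identified only up to rotation/translation/reflection, so output files fix
the sign by making each axis's first non-zero score positive, and tests
only ever compare inter-site distances and eigenvalue spectra. Species
scores for ordination plots are similarity-weighted averages of site
scores — a plotting convenience, not a canonical PCoA projection.

Axis selection evaluates a pooled redundancy statistic of axes 1..k on the
predictors: R² pools explained and total sums of squares over the
(centered) axes and `F = (R²/q)/((1−R²)/(n−q−1))`. With one axis this is
exactly the OLS R²/F. k maximizes F; because q and n are fixed, F is
monotone in R², so ties are detected on R² (numerically stable where
R² → 1 makes F explode) and resolved toward fewer axes.

## Trait convergence

The eight morphometric traits (six lengths in mm, two scale counts) are
augmented with **robustness** — the residual of log(CAM) on log(SVL)
across species, i.e. stoutness after removing the allometric expectation
for body length. (A raw-CAM alternative can be selected by passing a fixed
trait subset.) Traits are then ranged to [0, 1] across species; ranging is
the one standardization that puts millimetres and scale counts on one
scale without distributional assumptions, and constant traits are dropped
with a warning. Community trait means use presence/richness weights, so a
site's row of T is the plain average over its species.

Trait analyses restrict automatically to sites whose species all have
trait data (mirroring field datasets where morphology is only available
for a subset of communities); the model records which sites were kept.

Matrix correlations are Pearson correlations of strictly-lower-triangle
entries. The permutation unit is the **species**: trait rows are shuffled
and T (and everything downstream of it) rebuilt each draw. This is the
null "trait values are unrelated to species identity", which is the
hypothesis the convergence framework actually tests; the classical
site-shuffle Mantel permutation is exposed as an option
(`scheme="site"`). Tests are one-sided for high ρ (convergence is
directional), p-values carry the +1 correction so they are never zero, and
degenerate permutation draws (constant T) count as non-exceedances. Note
one consequence of the species-level null: fixtures with tied trait values
and symmetric site memberships have permutations that exactly reproduce
the observed ρ, so the p floor is the tie fraction, not 1/(n_perm+1).

The species-shuffle null of ρ(PT) is *positively* structured — sites that
share species have similar community means whatever the trait values — so
phylogenetic signal in traits is judged against that baseline, and power
at small site numbers is modest. This matches the behaviour of the
motivating analyses, where a ρ(PT) above 0.7 was still not significant at
eight sites.

The subset search is exhaustive over all non-empty trait subsets (511 for
9 traits; capped at 12 traits, beyond which the greedy mode must be used).
Ties break toward smaller subsets, then lexicographically. The
d-separation verdict follows the chain habitat → phylogeny → traits:
ρ(TE) significant and ρ(TE.P) not → niche conservatism; both significant →
convergence independent of phylogeny; ρ(TE) not significant → no
convergence. The partial correlation degenerates to the plain ρ(TE) when
the conditioning matrix is constant.

## Variation partitioning

Unique/shared/residual fractions are computed from the three OLS fits
(X1, X2, X1+X2), in both raw-R² form (sums to 1 exactly) and adjusted-R²
form (fractions can be negative and are reported as computed). Both forms
are emitted because published fraction percentages frequently do not state
which form — and sometimes quote a marginal R² — so the marginal R² of
each set alone is reported too. Habitat enters every design as a single
0/1 dummy (forest = 1), which with 12 sites and latitude gives the
F(2,9) reference distribution.

## The synthetic generator

The generator emulates the structure of a latitudinal snake metacommunity,
not any particular dataset:

- **Topology**: Yule (pure-birth) growth — a uniformly chosen extant
  lineage splits until n tips exist. Unit branch lengths (irrelevant
  downstream).
- **Clades**: the tree is partitioned into `n_clades` (default 4) major
  lineages by repeatedly opening the largest subtree from the root. Clades
  alternate habitat affinity ±1 and get latitudinal range centres spread
  across the gradient.
- **Traits**: independent Brownian motion per trait on unit edges
  (`sigma2`, default 0.1 per edge on the log scale), exponentiated into
  positive morphometric ranges around realistic baselines. The
  habitat-linked traits (TL, CAM, VS — tail length, girth, ventral scale
  count, the traits that plausibly respond to vertical habitat structure)
  have their clade optima shifted by ±`beta` on the log scale. A conserved
  affinity trait (clade affinity + low-rate Brownian noise,
  `affinity_sigma2` = 0.02) is stored as ground truth.
- **Ranges and pools**: species range centres sit near their clade centre
  (Gaussian scatter, sd 15% of the gradient span) with half-width
  `span/(1+gamma)`; a site's pool is every species whose range covers its
  latitude. `gamma = 0` puts every species in every pool; the default 1
  produces substantial clade turnover while keeping pools comfortably
  above the richness targets. Unattainable richness targets raise rather
  than silently shrink.
- **Assembly**: site richness is uniform on `richness_range`, membership
  drawn without replacement with weight `exp(−phi(a − h)²/2)` where `a` is
  the species affinity and `h = ±1` the site habitat. `phi = 0` is exactly
  neutral (uniform) assembly — the calibration condition.

The default ("snakelike") parameters are 182 species, 12 sites (6 forest /
6 non-forest) at the latitudes of the motivating communities (3.1–29.7°S),
richness 9–61. Ground truth (clade membership, affinities, latent traits,
range geometry, per-site inclusion weights) is carried with every dataset
so that tests are parameter-recovery tests, never snapshot tests.

What the generator does **not** emulate: real datasets have non-random
trait covariance (all size traits correlate through SVL), pools carved
from ecoregion maps rather than rectangular latitude bands, detection
error, and richness correlated with habitat. Passing recovery tests shows
the estimators respond correctly to planted filtering/convergence signals
of realistic size — not that they would be unbiased on any field dataset.
A latitudinal trend in NRI (clustering increasing poleward) can emerge
when clade turnover and filtering combine, but the generator does not
guarantee it: NRI is measured against each site's own pool, so a site
whose pool is already one clade shows no within-pool clustering.

## Problem sizes in the test-suite and acceptance runs

The suite enumerates all labeled topologies on 4–6 tips (1,065 trees) and
seeded samples of 100 each for 7–8 tips when checking NRI pair values
against the closed enumeration oracle; the neutral calibration uses 1,000
communities with 999-draw nulls; parameter recovery uses 50 replicates per
β grid point with 199 permutations per test. These sizes give stable
pass/fail behaviour (binomial CIs comfortably inside the asserted bands)
while keeping a full run around two minutes.

## Known limitations

- No abundance weighting anywhere (presence-only by design); no
  alternative dissimilarities to Bray-Curtis for matrix P.
- The z > 1.96 significance rule for NRI/NTI assumes approximate normality
  of the null; at very small richness or pool size the rank p is the safer
  quantity (both are reported).
- db-RDA here is the pooled-SS redundancy statistic on PCoA axes, not a
  full constrained ordination of the raw dissimilarities.
- The exhaustive subset search optimizes in-sample ρ(TE); with many traits
  and few sites the selected subset is exploratory, not inferential — the
  permutation test of the selected subset does not correct for selection.
- Species trait permutations treat species as exchangeable; phylogenetic
  autocorrelation among trait rows is not preserved under the null.
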