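# Methods

## Scope and data model

The package compares two essential-gene catalogues through five analysis
surfaces: set partition, directional differential-expression (DE)
comparison, developmental co-expression modules, categorical enrichment
(modules, risk lists, tissues) and de novo mutation burden, plus raw
feature comparisons. It consumes the *outputs* of upstream tools — DE
tables with fold changes and p-values, expression matrices, published
constraint scores, per-gene mutation probabilities — and never refits
those upstream models. Gene identifiers are matched as exact,
case-sensitive strings; no alias resolution is attempted, trading recall
for reproducibility.

## Directional DE comparison

Genes are assigned to the up or down slice by the sign of the log2 fold
change; zero or missing fold changes and missing p-values are excluded
(counted in the log). Scores are −log10 p with p floored at
`neglog10_floor` (default 1e-300) so they stay finite. Either the raw or
the BH-adjusted p-value can be compared (`p_column`); the default is the
raw p, with the adjusted column one switch away, because practice varies
and the choice does not alter the machinery.

The two-sided Wilcoxon rank-sum test uses the exact null when
n_x + n_y ≤ 20 and the data are tie-free (two-sided p =
min(1, 2·min(lower tail, upper tail)), tails inclusive of the observed
statistic); ties or larger samples use the normal approximation with tie
and continuity corrections. Both branches are delegated to
`scipy.stats.mannwhitneyu` under this branch policy; the test suite checks
the exact branch against an independent enumeration of all rank
assignments. If every value in both samples is identical the test is
declared uninformative (p = 1, warning) rather than an error, since this
arises naturally on heavily floored slices.

Cohen's d uses the pooled sample standard deviation because the two
blocks have unequal sizes; d is reported as missing when the pooled SD is
zero. Genes present in both input sets are removed from both samples —
the comparison is between set-specific blocks by construction.

The permutation null draws, per iteration, two *disjoint* sets of the
observed sample sizes, without replacement, from the pool of slice genes
belonging to neither input set, and repeats the Wilcoxon comparison.
Each direction gets its own null rather than pooling across directions,
matching the per-direction observed tests. The default 1000 iterations
follow the original analysis design.

## Co-expression modules

The network is signed: `a_ij = ((1 + cor_ij)/2)^β` with soft power
β = 15, so anti-correlated genes get near-zero adjacency. Correlation is
Pearson by default; biweight midcorrelation (tuning constant 9 MADs,
Pearson fallback for zero-MAD genes) is available for outlier-heavy data.
The topological overlap matrix is
`ω_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)` with
`ℓ_ij = Σ_{u≠i,j} a_iu a_uj`; it is validated against a naive O(n³)
implementation to 1e-10.

Module detection clusters 1 − TOM with average linkage and cuts the tree
at a **static height** (default 0.8); clusters below `min_module_size`
(default 30) become unassigned. The published dynamic tree-cut heuristic
("Dynamic Hybrid") is an external algorithm and is deliberately not
reimplemented; the static cut is simpler, fully deterministic, and the
downstream surfaces (enrichment, temporal patterns) are robust to the
exact cut. A consequence is that the number of modules found on real
data will not match counts obtained with dynamic tree cutting. The
default height of 0.8 was chosen on the synthetic design: with β = 15,
within-module TOM dissimilarity concentrates near 0.5–0.6, dissimilarity
between correlated-but-distinct temporal modules near 0.85, and
background near 1.0, so any cut in roughly [0.65, 0.85] separates them;
0.8 sits centrally and is exposed as a parameter.

Module eigengenes are the first right-singular vectors of the per-gene
standardized module submatrix (unit norm), sign-oriented to correlate
positively with the module's mean standardized profile — without that
convention temporal patterns would be defined only up to sign. Modules
whose eigengenes correlate above `merge_threshold` (default 0.9) are
merged greedily, highest correlation first (ties toward smaller labels),
recomputing the merged eigengene each step until fixpoint.

Temporal classification standardizes the eigengene to unit SD and
averages it in three windows: first and last thirds of the prenatal
samples **by sample count** (robust to irregular age sampling; age thirds
would be dominated by sparse late-prenatal sampling) and all postnatal
samples. With margin δ = 0.25 SD: a prenatal rise that is sustained
postnatally, a flat prenatal profile with higher postnatal level, and a
prenatal fall that stays down map to the three patterns; everything else
is unclassified. δ = 0.25 SD is small enough to accept the planted
templates at SNR 3 and large enough that flat noise is unclassified.

## Enrichment and de novo burden

Categorical enrichment is Fisher's exact test on the 2×2 membership
table, one-sided "greater" by default (enrichment is the question;
two-sided is a switch), BH-corrected across categories at FDR 0.05.
The universe is caller-supplied; for module enrichment the natural choice
is all genes in the expression matrix (assigned or not). The
implementation wraps `scipy.stats.fisher_exact` and
`statsmodels.multipletests`; both are checked against independent oracles
(exhaustive fixed-margins enumeration; hand-computed step-up examples).

The de novo expectation for a gene set is λ = 2 · n_trios · Σ_g p_g,
summing per-gene per-generation mutation probabilities over the set (two
transmitted haplotypes per trio). The LOF class aggregates nonsense,
frameshift and canonical-splice rate columns when provided separately;
protein-altering is the missense column. The burden test is the
upper-tail Poisson probability P(X ≥ observed | λ), with p = 1 for zero
observed events. This assumes independent mutation events across genes
and trios and takes the rate table as exact.

## Synthetic data: what it emulates and what it does not

The generators produce study-shaped inputs with planted, recoverable
truth:

- **Sets** with exact sizes and overlap (the screen-overlap preset is
  3838 / 2149 / 698 in a 20000-gene universe).
- **DE tables** whose background −log10 p is Exponential(mean 1/ln 10) —
  exactly the transform of Uniform(0,1) p-values — with a mean shift
  `delta` added to target-set genes in one fold-change direction. Because
  a location shift leaves the SD unchanged, the implied Cohen's d is
  `delta · ln 10`, making planted effect sizes exact by construction.
  Fold-change magnitudes are |N(0,1)| and only their signs matter.
- **Expression matrices** built as loading × template + Gaussian noise,
  loadings Uniform(0.5, 1), per-gene noise SD = loading / SNR (templates
  have unit SD), three trajectory templates matching the temporal
  patterns, background genes pure noise; 12 prenatal + 12 postnatal
  samples by default.
- **De novo rates** log-uniform in [1e-6, 1e-4] per class, observed
  counts Poisson with an enrichment factor γ inside the target set.
- **Feature tables** from a latent Gaussian shifted by a planted amount
  inside the target set, mapped per column (logistic squash for pLI,
  log-scale maps for mutation probability and transcript length).
- **Risk lists** with membership probabilities solved (by bisection on
  the base rate) so the planted odds ratio and expected list size hold in
  expectation.

These emulations capture the *statistical* structure the pipeline reacts
to — distribution shifts, block correlation, category enrichment,
Poisson counts — but not the messiness of real data: no library-size or
batch effects, no count noise (expression is Gaussian, not negative
binomial), no correlated p-values from shared regulation, no annotation
errors, and fold-change magnitudes carry no signal. Passing recovery
tests therefore demonstrates correctness of the statistics and the
plumbing, not robustness to real-data artefacts.

## Numerical and design choices

- p-value floor 1e-300 before −log10; exact-Wilcoxon branch bound at
  total n = 20; all variances are sample (n−1) variances.
- Permutation draws use numpy's PCG64 via `default_rng(seed)`; every
  stochastic function takes an explicit seed and identical seeds give
  bit-identical outputs (CLI outputs byte-identical files).
- Merging tie-break: higher correlation first, then smaller label pair;
  the merged module keeps the smaller label and modules are renumbered by
  decreasing size at the end, so labels are deterministic.
- Ortholog mapping keeps *all* targets of one-to-many relations and
  unions many-to-one relations; unmapped sources are dropped with a
  count. No best-hit heuristic is applied — any such choice would be
  arbitrary without alignment scores.
- Degenerate inputs: identical comparison samples → p = 1 with warning;
  zero pooled SD → d missing; zero Fisher margin → p = 1, odds ratio
  flagged undefined; rank-0 module submatrix → error.

## Problem sizes used in validation

The repeated-simulation checks run at reduced but statistically adequate
sizes chosen so the whole suite stays comfortably interactive: type-I
calibration uses 400/200-gene sets in a 4000-gene universe over 1000
simulations (binomial SE ≈ 0.007 around 0.05); effect-size recovery uses
6000/3000-gene sets (≈3000/1500 per direction slice) over 20 seeds, where
the per-seed sampling SE of d̂ is ≈0.03 so the seed-mean pins the planted
0.3 within ±0.05; module recovery uses three 40-gene modules plus 60
background genes over 10 seeds; de novo power uses a null expectation of
5 with trio counts solved per replicate. The acceptance script mirrors
these at the sizes printed in its output.

## Known limitations

- The static cut height, unlike dynamic tree cutting, cannot adapt to
  nested module structure; very unequal module tightness on real data may
  require tuning `cut_height`.
- The Poisson burden test ignores overdispersion across trios and
  uncertainty in the rate table.
- The permutation null conditions on the observed slice; it does not
  model gene–gene correlation of DE statistics, which real data have.
- Eigengene-based pattern labels depend on the ≥3 prenatal / ≥3 postnatal
  sample requirement and on prenatal samples spanning the rise/fall.
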