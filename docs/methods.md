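# Methods

This note records the models implemented by `trsopt`, the numerical and
design choices behind them, what the synthetic panels do and do not emulate,
and the known limitations.

## Mixed model and reliability criteria

The prediction model is standard GBLUP (VanRaden 2008; Habier et al. 2007):
phenotypes `y = Xβ + Zu + ε` with a single random genetic effect
`u ~ N(0, G σ_g²)` and i.i.d. residuals `ε ~ N(0, I σ_e²)`.  Fixed effects
default to an intercept — the population mean — which is the setting all
reliability computations assume; a user-supplied `X` is accepted by
`solve_mme` but is an untested extension surface.  The random-effect vector
`u` is indexed by *every* genotype of the kinship matrix passed in (training
members, unphenotyped candidates, test genotypes), with `Z` selecting the
phenotyped rows; this is what lets PEV/CD of unphenotyped candidates and
GEBV prediction fall out of one solved system.

The inverse of the Henderson coefficient matrix is assembled from
`θ = (Z′MZ + λG⁻¹)⁻¹` with `M = I − X(X′X)⁻X′` (Moore–Penrose generalized
inverse, the canonical deterministic choice), using the block-inverse
identities; `C22 = θ` is verified in the tests against direct inversion of
the full coefficient matrix.  For a zero-sum contrast `c`:

    PEV(c) = c′θc / c′c · σ_e²
    CD(c)  = c′(G − λθ)c / c′Gc = 1 − λ c′θc / c′Gc

Both CD forms are implemented (`form="difference"` / `"one_minus"`) so their
algebraic identity is checkable numerically; agreement is asserted to 1e-10.
Contrast zero-sum tolerance is 1e-9; a contrast with `c′Gc ≤ 1e-12` is
rejected as lying in the null space of G.  Symmetric systems are inverted by
Cholesky with an eigendecomposition fallback; symmetry checks use 1e-10.

PEV is reported in units of `σ_e²` (i.e. `σ_e² = 1`) inside the optimizer:
only rankings of candidate training sets matter to the exchange algorithm,
and the unit convention removes a free parameter.

`λ` used for optimization comes from the configured trait heritability via
`λ = (1 − h²)/h²` (one record per genotype), floored at 1e-6 so that the
noise-free limit `h² = 1` stays solvable.  REML is provided separately
(`reml_estimate`) for simulation studies: a single-kernel spectral
(EMMA-style) profile of the restricted likelihood over `log λ ∈ [−10, 10]`,
81-point grid plus bounded refinement.  Estimates on the search boundary or
with vanishing genetic variance are flagged, not silently returned.  Note
that with `G` exactly proportional to the identity the ratio `σ_e²/σ_g²` is
unidentifiable (the likelihood is flat), so recovery checks use
marker-derived kinship matrices with eigenvalue spread.

The multi-environment heritability helper implements the entry-mean formula
`h² = σ_g² / (σ_g² + σ_ge²/e + σ_e²/(e·r))` for `e` environments and `r`
replicates per environment.

## Kinship construction

Markers are oriented to minor-allele counts in-sample on the *full panel*
before any CS/TS split, so every subset criterion works on one fixed G.
Monomorphic markers and markers below the MAF threshold are dropped; missing
calls are imputed with the column mean of the non-missing calls.  Mean
imputation is a deliberate simplification: it is deterministic and
dependency-free, at the cost of shrinking the imputed genotypes toward the
panel mean (an EM-style multivariate imputation would preserve more
covariance but is out of scope).

`G = WW′/f` is ridged with 1e-6 on the diagonal only when its smallest
eigenvalue falls below 1e-8.  Two situations make the ridge necessary in
practice: in-sample centering always places the all-ones vector in the null
space of `WW′`, and duplicated inbred lines duplicate rows of `W`.  The
ridge actually applied is recorded on the `KinshipMatrix`.

## Selectors

*Random*: uniform without replacement.  *Stratified*: largest-remainder
(Hamilton) apportionment of slots over clusters — counts sum to the target,
never exceed a cluster, deviate from exact quotas by less than one except
when a saturated cluster cascades its surplus — then uniform sampling inside
each cluster.  Ties in remainder are broken by larger cluster, then input
order, making allocation deterministic.

*CDmean / PEVmean*: stochastic exchange search (Rincent et al. 2012).  The
proposal distribution is uniform over (TRS member, RS member) pairs; a
proposal is accepted only on *strict* improvement, so accepted-criterion
trajectories are strictly informative and monotone by construction.  The
budget is a fixed 2000 proposals by default (a plateau is typically reached
well before); an optional `patience` parameter stops early after that many
consecutive rejections.  Each criterion evaluation rebuilds
`Z′MZ = D_t − tt′/n` (intercept-only algebra) on top of a cached `λG⁻¹` and
re-inverts; no rank-one updating is used — correctness first, and at panel
sizes up to ~1,200 a full solve per proposal is desk-scale.

*StratCDmean*: proportional allocation first, then a CDmean exchange run per
cluster with swaps restricted to the cluster's members.  Two points were
genuinely open and are fixed as follows, deliberately: the contrasts scored
during a cluster's run are those of the *cluster's own* RS genotypes, but
the contrast target remains the full-CS mean and the full-CS G is used (not
a cluster-local submatrix); and clusters are optimized sequentially with the
other clusters' current members held fixed in the training set, so each
cluster's criterion sees the whole design.  A cluster whose allocation
equals its size enters the training set whole, with a log message.

Contrast machinery: one contrast per RS genotype, `c = e_i − (1/N)·1` over
the `N` CS genotypes.  For these mean-contrasts `c′Ac` reduces to
`A_ii − 2·rowmean_i(A) + mean(A)`, which the evaluator computes vectorized.

## Structure analysis

Distances are Euclidean on marker calls (column centering shifts all rows
identically, so raw and centered calls give identical distances).
Clustering is Ward's minimum-variance criterion in the ward.D2 dialect
(scipy `linkage(…, method="ward")` on condensed Euclidean distances) — the
standard modern reading of "Ward".  The cluster count K is user-supplied;
no automatic K selection is attempted.  Ward on integer-coded genotypes can
encounter exactly tied distances, in which case the agglomeration order (and
hence the cut) can depend on input order; the order-invariance property is
therefore guaranteed only for tie-free inputs.  PCA is the SVD of the
centered marker matrix, without variance scaling, matching the centering
already defined for G.  Cluster-explained trait variance is the one-way
ANOVA ratio SSB/SST with K−1 between-cluster degrees of freedom.

## Synthetic panels

`simpop` emulates a structured diversity panel: ancestral allele frequencies
uniform on (0.05, 0.95); per-subpopulation frequencies from the
Balding–Nichols beta distribution with variance `Fst·p(1−p)`; genotypes
independent across markers given those frequencies.  Inbred mode (0/2 calls)
is the default — selfing-crop panels are the motivating use case, and it
exercises the `diag(G) ≈ 1 + f` behavior and the duplicated-line
singularities; outbred `Binomial(2, p)` mode is a flag.  Traits are
polygenic: `n_qtl` markers with i.i.d. Gaussian effects; the residual
variance is set from the realized genetic variance so the sample heritability
hits the target (exactly `tbv` at `h² = 1`).  With `structure_aligned`,
causal markers are sampled with probability proportional to the variance of
their subpopulation frequencies, making subpopulation membership predictive
of the trait.

Presets: `mild` (K=4, Fst 0.08, subpopulation shares 137/93/41/29 of 300
lines), `strong` (K=3, Fst 0.30, shares 90/79/61 of 230, structure-aligned
trait) and `unstructured` (K=1, 500 lines); all at m=1000 markers,
h²=0.8, 100 QTL, with documented default seeds.  Panel sizes and marker
counts were chosen as the smallest scale at which the structure phenomena
are unambiguous; they are an order of magnitude below real wheat/rice
panels, which is why benchmark accuracies here should be read as orderings,
not as forecasts of real-data accuracy.

What the simulator does *not* emulate: linkage disequilibrium (markers are
independent given subpopulation frequencies), major genes, multi-environment
GxE structure, genotyping error or missingness patterns.  Consequently,
passing benchmarks show that the selectors behave correctly *given* the
GBLUP model assumptions — they do not certify performance on traits with
major genes or strong LD structure.

## Benchmark

One CS/TS split per repetition, shared verbatim by all methods and sizes
(asserted by id-set digests); per-repetition seeds are spawned from the
master seed with `SeedSequence`, so neither method order nor size order
perturbs any other cell of the grid.  The split preserves cluster
proportions by default (within one per cluster), avoiding the accuracy
deflation that arises when the test set is stratified differently from the
calibration set.  Cluster labels are computed once on the full panel by Ward
clustering (or supplied) and reused for both the split and the stratified
selectors, rather than re-clustered per repetition — the labels are
deterministic for a given panel, so this only removes redundant computation.
Accuracy is the Pearson correlation of predicted GEBVs against observed
test-set phenotypes (predicting observed phenotypes, not true breeding
values, is the default because that is what is available outside
simulation; TBV scoring can be done by passing `tbv` as the phenotype).

The variance-ratio diagnostic divides the sample variance (n−1 denominator)
of the phenotypes of the `top_n` most-selected genotypes by the panel's
phenotypic variance; values above 1 mean extreme phenotypes are
overrepresented in the criterion's training sets.  "Relative accuracy" is
defined as a *ratio* of mean accuracies (method over baseline), so the
neutral value is 1.0; it is configurable because a difference is equally
defensible.

## Known limitations

- Fixed effects beyond the intercept are accepted but not exercised by the
  validation suite.
- No Bayesian whole-genome regressions, multi-kernel or GxE models, no
  dominance/pedigree relationship matrices, no marker weighting.
- The exchange search is a local optimizer; optimality is only verified
  exhaustively at enumerable sizes, and multimodal criteria at large panel
  sizes warrant restarts.
- The stratified-vs-random accuracy gap under strong structure is small at
  desk-scale panel sizes; with 30 repetitions its sign is stable only in
  expectation, not in every realization.
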