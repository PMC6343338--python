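# Methods

## Data model

A dataset is a site × sample matrix of non-negative values with a site →
gene mapping and a design of `T ≥ 2` experiments, the `t`-th with `R(t) ≥ 1`
replicates (`R = Σ R(t)`). Values may be raw counts, abundances, or
per-gene relative usage (each site's share of its gene's total in a sample;
genes with zero total in a sample get all-zero usage rather than NaN so
downstream variances stay finite). Filtering removes sites supported by
fewer than `min_reads` reads in total (default 5) and then genes left with
fewer than two sites; selection of genes with differential site usage is
delegated to the caller via a gene list, since it needs an external test.

## Shrinkage error model

Per site and experiment, the replicate variance `K²` (unbiased, df
`R(t)−1`) estimates the squared measurement error but is unstable at the
2–3 replicates typical of sequencing studies; the pooled variance
`K̄² = Σₜ (R(t)−1)/(R−T)·K²ₜ` is stable but assumes a common error across
experiments. A quadratic-loss shrinkage factor

    ρ̌ = Σₜ (1 − (R(t)−1)/(R−T))·var(K²ₜ) / Σₜ (K²ₜ − K̄²)²,
    var(K²ₜ) = R(t)/(R(t)−1)³ · Σᵣ [(D − Ē)² − K²ₜ]²,   ρ* = clip(ρ̌, 0, 1)

interpolates between them: `W*ₜ = (1−ρ*)·K²ₜ + ρ*·K̄²`. The shrinkage error
`ψₜ = √(W*ₜ/R(t))` estimates the standard error of the experiment mean.
Site means are combined into a precision-weighted mean (weights `1/ψ²`),
and the correlation between two sites is the cosine of their
ψ-standardized deviation vectors, clipped to [−1, 1].

Conventions for degenerate inputs:

- `Σₜ (K²ₜ − K̄²)² = 0` (all experiment variances equal): ρ* = 1, the
  continuous limit; nothing is lost because `W* = K̄²` equals every `K²ₜ`.
- ψ is floored at `1e−6 · max(1, maxₜ|Ēₜ|)` so zero replicate variance
  cannot produce infinite precision weights.
- An experiment with `R(t) = 1` inside an otherwise replicated design
  contributes `K² = 0` with pooled weight 0 and `var(K²) = 0`.
- A fully unreplicated design (`R = T`) bypasses shrinkage: ψ ≡ 1 and the
  site correlation reduces to the plain Pearson correlation of the
  per-experiment values.
- A site flat across experiments has a zero standardized vector; its
  correlation with anything is defined as 0.

## Canonical correlation and the pair weight

For genes with `m` and `n` sites, the correlation blocks Σ_PP, Σ_QQ, Σ_PQ
are assembled from the shrinkage-weighted site correlations (unit
diagonal). The canonical correlations are the square roots of the
eigenvalues of `Σ_PP⁺ Σ_PQ Σ_QQ⁺ Σ_QP`; Moore–Penrose pseudo-inverses
(relative cutoff 1e−10) handle rank-deficient blocks — relative-usage
profiles are exactly collinear — and eigenvalues are clipped to
`[0, 1−1e−12]` so the test statistic below stays finite. `k = min(m, n)`
correlations are returned, descending; the tests agree with an independent
SVD-whitening oracle to 1e−8 on random blocks.

Coefficient `c` is tested with the Bartlett-style statistic

    χ²_c = −(g − (m+n)/2) · Σ_{i=c..k} ln(1 − ξᵢ²),  df = (m−c+1)(n−c+1),

with `g = T`, the number of observations the correlations are estimated
over. The sequence is accepted greedily: coefficient `c` counts as
significant only if tests `1..c` all reject at level α (default 0.05);
testing stops at the first acceptance. The gene-pair weight averages the
significant run with `−ln p` weights (p floored at 1e−300); with no
significant coefficient the weight is 0, and with exactly one it equals ξ₁.
Self-pairs are set to 1 by convention (ξ₁ = 1 makes the test singular).
`g > (m+n)/2` is required for the statistic's sign to be valid; the χ²
approximation is asymptotic in `g` and is known to be liberal when `T` is
small relative to `m+n` (see "Planted-cluster conditions" below).

Two comparators ship behind the same `weight_matrix(measure=...)`
interface: `cca` (plain CCA on replicate-averaged site values — the
shrinkage machinery with ψ ≡ 1 and plain centring) and `pcc` (gene-level
Pearson `r` on summed, replicate-averaged counts, mapped to a weight
`(1+r)/2` so the distance `(1−r)/2` lies in [0, 1]; significance by the
usual two-sided t test). The mapping of `r` to [0, 1] is a convention of
this package.

## Clustering and validation

Distances are `d = 1 − w`. Clustering is agglomerative with complete
linkage (scipy); cuts are exact-`k` tree cuts; the number of clusters can
be estimated by maximizing the mean silhouette width over a k range
(default 5–20 when unspecified; ties resolve to the smallest k).

Validation indices, with brute-force reference implementations in the test
suite:

- **CON** (connectivity, lower better): penalty `1/j` whenever the j-th
  nearest neighbour of an observation (ties by index, `L = 10` neighbours
  by default) lies in a different cluster.
- **DUNN** (higher better): minimum between-cluster distance over maximum
  cluster diameter; singleton-only clusterings are rejected.
- **AD / ADM** (stability, lower better): each experiment is deleted in
  turn with all its replicates — the observation axis of this method is
  experiments, so deleting single replicate columns would break the design
  — the weight matrix is recomputed and the genes re-clustered at the same
  k. AD averages each gene's mean full-data distance to the co-members of
  its perturbed cluster (genes isolated in the perturbed clustering are
  skipped); ADM averages the movement of each gene's cluster centre (mean
  gene-level profile on the full data) between the two clusterings.
- **BHI** (biological homogeneity, in [0, 1]): per cluster, the fraction of
  ordered pairs of distinct annotated genes sharing at least one
  functional class, averaged over clusters with ≥ 2 annotated genes.

Scores compared across methods and k are min–max normalized per metric with
lower-is-better metrics flipped, so larger is always better after
normalization; a metric constant across cells maps to 0.5.

Network metrics operate on the weight matrix binarized at `w > τ`
(default 0.5): mean eigenvector centrality (principal eigenvector of the
binary adjacency scaled to unit maximum), mean local clustering
coefficient over nodes of degree ≥ 2, and Newman modularity of a given
module partition. Module eigengenes are the first principal component of
the row-standardized within-module profile matrix (sign set so the mean
gene correlation is non-negative); hub genes correlate with the eigengene
above 0.7.

## Synthetic data

The generator draws, per gene and experiment, each site's base abundance
from `Binomial(N, pᵢ)` — `pᵢ` the site-usage probabilities, `N` the gene's
depth — with sites drawn independently (a gene's counts need not sum to
`N`), then adds per-replicate Gaussian noise and rounds/clips at zero. The
noise sd defaults to `c·√(base+1)` with `c = 0.5`, the heteroscedasticity
of count data; a constant sd or per-experiment scales (varying measurement
quality) can be set instead. Defaults emulate a multi-tissue 3′-seq
compendium: 14 experiments × 3 replicates. Usage probabilities can also be
estimated from a real dataset (`profile_from_counts`).

What the generator does *not* emulate: genomic coordinates and
3′-UTR structure, mapping artefacts, library-size differences between
samples, overdispersion beyond the binomial/Gaussian model, and correlated
noise between sites.

### Planted-cluster conditions

`planted_cluster_dataset` adds ground-truth structure for recovery
studies. Each cluster owns a latent per-experiment program; programs of
different clusters are orthogonalized over the sampled experiments, since
with few experiments two random programs are often substantially collinear
by chance, which makes the truth unrecoverable by *any* correlation
measure. Each gene responds along its own mean-centred unit direction over
site slots (centring guarantees a real usage contrast; a constant
component cancels in the renormalization): usage in experiment `t` is the
baseline Dirichlet(2) profile re-weighted by `exp(d·f_t)` and
renormalized.

The canonical recovery conditions are subtle shifts (`effect = 0.15` on
the log-odds scale) at deep coverage (5·10⁵–2·10⁶ reads per gene). Two
properties of the method dictate this regime. First, the measure is a
*linear* correlation method: large log-odds swings drive site responses
into the nonlinear range of the usage renormalization and cap attainable
correlations well below 1. Second, with `T = 8` experiments the χ²
approximation of the sequential test is liberal, so occasional
cross-cluster pairs pass it with a large ξ₁; recovery under complete
linkage then requires every gene's nearest within-cluster neighbour to be
closer than any such spurious pair, which subtle-but-clean signal
provides. Passing recovery tests therefore shows that the pipeline
recovers linear co-usage structure at high signal-to-noise; it does not
show robustness to strongly nonlinear usage responses or to very small
`T`, where the sequential test's size is inflated.

## Determinism and parallelism

All generators take explicit seeds and are bit-reproducible. The weight
matrix partitions unordered gene pairs into fixed-order chunks; workers
compute pure functions of their chunk and results are reduced in a stable
order, so any `workers` value yields bit-identical matrices. The CLI
writes a JSON sidecar with every output so runs can be reproduced from
their artefacts.

## Problem sizes

The shipped studies use 150 genes (recovery) and ten 45-gene trials
(comparator study); both complete in well under a minute on one core.
The per-pair cost is a CCA on blocks of size ≤ number of sites per gene,
so the weight matrix scales as `G²` with small constants; the
process-level `workers` option addresses larger gene sets.
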