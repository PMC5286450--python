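# Methods

This note records the statistical models implemented in popgenkit, the
conventions and defaults chosen where several were defensible, and what
the simulation-based tests do and do not establish.

## Data model

Genotypes are stored as alt-allele dosages (0/1/2, −1 missing); phase is
discarded because every statistic in the package is a function of allele
counts. Positions are 1-based and `contig:pos` is the locus key.
Multiallelic and non-SNP records are excluded at VCF read time (the
curation pipeline is biallelic throughout); the count of skipped records
is logged, never silently dropped. Metadata is plain delimited text with
sniffed separators, since no standard binary format adds anything here.

## Curation cascade

Stage order: depth mask → MAF/missingness → contig density → LD pruning →
spacing → outlier exclusion → paralog screen. Conventions:

- The depth filter masks individual calls (DP < 10 → missing) rather than
  dropping loci; masked calls then count toward the missingness filter.
  Boundary: DP = 10 passes.
- MAF must be strictly greater than the threshold (default 0.10) and the
  missing fraction strictly below its threshold (default 0.25), matching
  the "> 10%" / "< 25%" reading of those rules.
- Contig density is the mean inter-SNP gap, span/(n−1), because contig
  lengths are not recoverable from a VCF; single-SNP contigs always pass.
  Contigs failing the threshold are removed wholesale (a dense SNP run is
  evidence of mis-mapping for the whole contig, not one site).
- LD pruning computes dosage r² for all within-contig pairs over jointly
  non-missing samples and removes, in a greedy first-kept-wins pass in
  position order, the later member of any pair with r² above the cutoff
  (default 0.5). Cross-contig pruning is deliberately out of scope: for
  gene-sized contigs physical linkage information ends at the contig
  boundary, and within-contig all-pairs keeps the operation quadratic only
  per contig. Zero-variance dosage vectors contribute r² = 0.
- The spacing sweep keeps the first SNP of any too-close run; a gap equal
  to the minimum (default 100 bp) satisfies "at least".
- The outlier and paralog stages are the statistical models below; their
  flagged loci are removed with `drop_loci`, which appends an audit row.

The cascade is a pure function of (table, metadata, config, seed); every
stage is idempotent and the per-stage removal sets are disjoint.

## Heterozygosity and F_IS

Expected heterozygosity uses the small-sample factor 2n/(2n−1) (the
convention of the common desktop packages for these statistics); the
uncorrected value is available via `corrected=False`. Per-locus F_IS is
1 − H_O/H_E with group values pooled by genotyped sample size. The
permutation null redistributes the 2n alleles of each group among its
individuals, which leaves H_E fixed; the resulting heterozygote-count
distribution is sampled exactly by two nested hypergeometric draws, so
10,000 "permutations" cost two vectorized RNG calls. P-values use the
(b+1)/(m+1) estimator and the paralog screen flags loci with significantly
*negative* F_IS (excess heterozygosity) at α = 0.05 by default.

## Weir–Cockerham θ and nested AMOVA

θ follows the 1984 moment estimator with components a (among
populations), b (among individuals within populations) and c (within
individuals), combined over loci as Σa/Σ(a+b+c) — ratio of sums, never a
mean of per-locus ratios. Populations without data at a locus are dropped
from that locus; loci with fewer than two informative populations are
skipped.

The nested AMOVA decomposes allele-level variance over four strata on the
dosage representation (for biallelic SNPs the allele-indicator ANOVA is
equivalent to a squared-Euclidean AMOVA on allele frequencies). Because
each genotyped individual contributes exactly two alleles, the
among-individual coefficient in every expected mean square is exactly 2;
the population- and cluster-level coefficients use the standard
unbalanced-design formulas on allele counts. Components are summed over
loci before forming F_CT = σ²_AG/σ²_tot, F_SC = σ²_AP/(σ²_tot − σ²_AG),
F_IS = σ²_AI/(σ²_AI + σ²_WI), F_IT = 1 − σ²_WI/σ²_tot. Negative moment
estimates are retained per locus (truncation would bias the sums); a
degenerate stratum (single cluster, or one population per cluster) fixes
its component at zero. On exactly two populations in one cluster the
F_SC-level ratio equals pairwise θ to machine precision — the two code
paths are independent implementations of the same decomposition and the
test suite asserts agreement at 1e−8.

Permutation schemes: alleles re-paired among individuals within
populations (F_IS), individuals permuted among populations within their
cluster (F_SC), whole populations permuted among clusters (F_CT); p =
(hits+1)/(n_perm+1). `n_perm=0` skips p-values, which the recovery tests
use since only the indices are under test.

## F_ST-outlier model

A biallelic beta-binomial specialization of the multinomial-Dirichlet
island model: population alt counts a_{lj} ~ BetaBin(m_{lj}; p_l θ_{lj},
(1−p_l) θ_{lj}) with θ = (1−F)/F and logit F_{lj} = α_l γ_l + β_j.
Priors: p_l ~ U(0,1), β_j ~ N(−1,1), α_l ~ N(0,1) when included; the
inclusion indicator γ_l has prior odds 1:10. The reversible-jump birth
move draws α from its prior so proposal and prior densities cancel and the
acceptance ratio reduces to likelihood × prior odds. Random-walk widths
for p, α and β are adapted in ten 50-sweep pilot rounds at the start of
burn-in, targeting 25–45% acceptance, then frozen. All locus-level moves
are vectorized across loci; the per-population β moves are proposed and
accepted jointly since their likelihood rows are independent. Loci
monomorphic across all populations are excluded from the fit (no
information about F) and carry NaN posteriors.

Q-values rank loci by posterior inclusion probability; the q of rank k is
the minimum over j ≥ k of the mean (1 − posterior) among the top j — the
minimum FDR at which the locus would be declared. Loci with q ≤ 0.05 are
flagged by default. Default chain lengths are 5,000 burn-in + 50,000
sweeps (thinned by 10); the test and acceptance runs use 1,000 + 4,000,
which on the simulated problem sizes (≤ 525 loci × 10 populations)
reproduces the flag set of longer chains to within the seed-to-seed
variation the suite itself checks (< 5% of loci).

## DAPC

Missing dosages are mean-imputed for PCA only — never for diversity
statistics. The K scan runs k-means (20 restarts, seeded, ties by lowest
within-cluster SS) on the retained PCs and scores
BIC(K) = n·ln(W_K/n) + K·ln n, with W floored at 1e−12 to keep the
degenerate K = n case finite. The discriminant step fits an LDA on the
k-means labels; a singular within-class scatter falls back to an
eigen-solver with ridge shrinkage 1e−6 (logged). Membership probabilities
come from the discriminant-space Gaussian model; 40 PCs is the default
retention for both the scan and the fit.

## Admixture model

The Gibbs sampler alternates (i) the origin of each allele copy,
categorical in Q_i ⊗ P_k; (ii) cluster allele frequencies, Beta(1+alt,
1+ref); (iii) admixture rows, Dirichlet(α + copy counts) with symmetric
α = 1 held fixed — sampling α is a known refinement, not implemented. The
per-replicate score is the mean post-burn-in log P(genotypes | Q, P) with
allele copies independent given Q. Replicates are aligned by the label
permutation maximizing summed Q-column dot products (Hungarian algorithm —
the exact version of greedy CLUMPP matching) before averaging. Defaults
are 2,000 burn-in + 10,000 sweeps and 3 replicates; the Evanno scan in the
tests uses 250 + 1,000 sweeps and 5 replicates on 150-locus datasets —
with strong differentiation the chains converge within tens of sweeps, and
five replicates stabilize the across-replicate standard deviation that ΔK
divides by. ΔK(K) = |mean L(K+1) − 2 mean L(K) + mean L(K−1)| / sd(L(K)),
interior K only; identical replicates (zero sd) are an error, not a large
ΔK.

A caveat the tests make explicit: ΔK presumes replicate scatter. On data
where every K = 2 chain finds the same merge of the true three clusters,
sd(L(2)) collapses and ΔK(2) can spike — the same pathology known from
field use of this statistic. Unequal cluster sizes make this more likely;
the recovery tests therefore use balanced 3-cluster designs, and on the
unbalanced study-shaped design ΔK may legitimately prefer K = 2 while BIC
and the K = 3 admixture fit still recover the true partition.

## Spatial RDA

Populations, not individuals, are the rows; the response is the site ×
locus alt-frequency matrix, column-centered, unscaled (one allele per
locus suffices — the complementary allele only negates centered columns).
Coordinates are used as raw decimal degrees (no projection; a caveat for
continental extents), standardized per axis before monomials purely for
conditioning. The spatial basis is the bivariate monomials of total
degree ≤ 3 in fixed order, Gram–Schmidt orthogonalized against the
constant and each other, unit-normed, rank-deficient terms dropped; a
degenerate axis reduces to the univariate cubic basis.

Forward selection admits the candidate with the largest partial F when a
permutation p-value beats α = 0.05 (999 permutations by default). The
permutation null uses the *maximum* partial F over the remaining
candidates, because the observed statistic is itself a maximum: testing
the best of q candidates against its own marginal null would admit a
spurious term with probability near 1−(1−α)^q. Selection stops when no
candidate qualifies or the residual is numerically exhausted. The final
fit reports the constrained proportion trace(Ŷ'Ŷ)/trace(Y'Y), per-axis
proportions from the SVD of Ŷ, pseudo-F = (SS_fit/q)/(SS_res/(n−q−1)) and
a row-permutation p-value. The spatially explained differentiation is the
constrained proportion times the overall multi-locus θ, reported to three
decimals.

## Simulator

The generator is a Balding–Nichols hierarchy: ancestral p ~ U(0.1, 0.9)
(so simulated panels are plausibly post-MAF-filter), cluster frequencies
Beta(p(1−F_CT)/F_CT, (1−p)(1−F_CT)/F_CT), site frequencies likewise around
their cluster with F_SC, genotypes with P(het) = 2pq(1−F_IS). An F target
of zero degenerates to a point mass, handled analytically. Closed-form
expectations (`expected_fst`) follow the multiplicative composition
1 − (1−F_CT)(1−F_SC), making recovery tests exact in expectation. Defaults
reproduce the study design the package is organized around: 3 clusters,
17 sites of 5–8 diploids (89 total; cluster sizes 10/51/28), F_CT = 0.17,
F_SC = 0.05, F_IS = 0.12, depth ~ NegBin(mean 40, dispersion 5) so the
DP < 10 mask removes a few percent of calls, 3% missingness, and sites
scattered ~8° of latitude around spatially coherent cluster centres
(toggleable, so isolation-by-distance and cluster-only scenarios are both
generable).

Spiked artifact classes: outlier loci redrawn with elevated cluster-level
dispersion (default 0.5); paralog-like loci forced heterozygous at rate
0.9 (the signature of collapsed duplicates); LD copies duplicating a
neutral template's genotypes on the same contig, placed downstream of the
template so the first-kept-wins pruning pass removes the copy class with
full recall.

What the simulator does not emulate: genealogical correlation among loci,
mutation/recombination processes, allele dropout or depth-correlated
genotyping error, and selection beyond static elevated differentiation.
Passing recovery tests therefore demonstrate estimator correctness under
the Balding–Nichols generative law, not robustness to every real-data
pathology.

## Problem sizes and determinism

Simulation-based checks use deliberately modest sizes chosen to exercise
the estimators well inside their asymptotic regimes: 2,000 loci × 10
datasets for fixation-index recovery (±0.03), 500-locus/60-sample designs
for cluster recovery, 525 loci × 10 populations × 30 diploids for the
outlier scan's operating characteristics, and 150-locus scans for ΔK.
Every stochastic component takes an explicit integer seed
(`numpy.random.default_rng`); reruns with identical arguments are
bit-reproducible, and the pipeline report echoes the fully resolved
configuration including all seeds.

## Known limitations

- The outlier model is biallelic-only and has no hierarchical
  (among-group) variant; its priors are fixed constants, not arguments of
  a model-comparison study.
- AMOVA is dosage-based (allele-frequency AMOVA); haplotype/ΦST variants
  are out of scope.
- The LD pruner's within-contig scope will not catch inter-contig
  duplicates of the same gene.
- Permutation p-values are bounded below by 1/(n_perm+1).
- RDA treats longitude/latitude as Euclidean; at ~8° extent the distortion
  is modest but nonzero.
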