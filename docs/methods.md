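# Methods

`popstruct` implements a complete desk-scale workflow for delimiting weakly
differentiated subpopulations from genotyping-by-sequencing (GBS) SNP data:
quality filtering, ancestry estimation with model choice, ordination,
locality-level differentiation, and detection of a linked SNP block (an
"island of differentiation") against a weakly structured genomic background.
This note records the models, the defaults and why they hold, the numerical
choices, and what the synthetic-data tests do and do not establish.

## Genotype model

Genotypes are diploid biallelic SNP calls coded as alt-allele dosage
g ∈ {0, 1, 2} with one reserved integer sentinel for missing data (never
NaN, so counting stays exact). Half-calls (e.g. `./1`) are conservatively
treated as missing, phase is discarded, and multi-allelic or non-SNP VCF
records are retained at parse time but flagged for removal by the site
filter.

## Filtering

Four stages, applied once, in order:

1. **Site filter.** Non-biallelic or non-SNP records and sites with quality
   < 30 are dropped; genotypes with depth DP < 3 or genotype quality GQ < 30
   are set missing *before* computing minor-allele count (< 3 removes the
   site) and call rate (< 0.5 removes the site). Masking first means a
   low-quality genotype can never rescue a site.
2. **Missingness/MAF cascade.** A fixed sequence of steps, each removing
   individuals above a missing-data tolerance and then recomputing locus
   statistics on the reduced matrix: tolerances
   (0.70, —, —), (0.65, maf 0.005, call 0.90), (0.30, 0.005, 0.95),
   (0.20, —, 0.96), (0.15, —, —). Alternating the two removal directions
   retains more individuals and loci than one harsh pass, because poor
   individuals stop dragging down good loci and vice versa. Within a step
   the order (individuals first, then loci) is contractual; the cascade is
   idempotent and is tested for exact equivalence with a brute-force
   re-implementation.
3. **Heterozygosity filter.** Loci with observed heterozygosity strictly
   greater than 0.5 are removed as putative collapsed paralogs; a locus at
   exactly 0.5 is kept.
4. **HWE rule.** Per locus and collection locality (≥ 5 non-missing
   genotypes), a 1-df chi-square goodness-of-fit test against
   Hardy–Weinberg proportions at the locality allele frequency, no
   continuity correction. A locus is removed only when more than 60% of
   qualifying localities are out of HWE at p < 0.01. The minimum-genotype
   floor avoids degenerate tests in tiny localities; loci with no
   qualifying locality are exempt and logged.

MAF uses observed genotypes only as denominator (VCFtools `--maf`
semantics).

## Ancestry estimation (NMF)

Each genotype is expanded to a three-column genotype-class indicator, so the
data form an n × 3m matrix X with rows of per-locus one-hot blocks. The
model is X ≈ Q G with Q (n × K) on the probability simplex per row
(ancestry proportions) and G (K × 3m) a simplex per cluster-locus triple
(genotype-class frequencies). Cluster allele frequencies follow as
F = (G₁ + 2G₂)/2.

Fitting minimizes the squared reconstruction error over observed,
non-held-out entries by alternating projected-gradient blocks: each block
takes steps of length 1/L with L the exact Lipschitz constant
(2·λmax(GGᵀ) resp. 2·λmax(QᵀQ)), followed by Euclidean projection onto the
simplex (sort-based algorithm). Each block update minimizes a quadratic
majorizer over a convex set, so the loss is monotonically non-increasing —
asserted per iteration in tests. Convergence: relative loss change < 1e-6
or 500 iterations (non-convergence is reported, not raised). Three inner
steps per block per outer iteration. An optional ridge penalty on Q (the
sparsity-style regularizer) defaults to 0.

**Initialization.** Random restarts find poor local optima at the weak
differentiation levels this pipeline targets (pairwise F_st ~ 0.01–0.05),
while the leading principal components concentrate whatever population
signal exists. Q is therefore initialized from k-means on the top K−1 PC
scores of the mean-imputed matrix (0.90 on the assigned cluster, jittered
by a seed-dependent uniform perturbation so replicate fits differ), and G
from the partition's smoothed class counts. A `init="random"` fallback is
kept.

**Model choice.** Before fitting, a fraction (default 5%) of observed
genotypes is held out uniformly at random; the criterion is the mean
−log predicted probability of the held-out classes (predictions clipped to
[1e-10, 1]). `select_K` fits a contiguous K range with replicate seeds and
picks the K with minimum mean criterion, ties to the smaller K. The
held-out masks are drawn once per replicate and shared across all K, so
K-comparisons are paired on identical entries; without pairing,
mask-sampling noise is an order of magnitude larger than the criterion
differences that separate adjacent K at desk scale. The Evanno ΔK
statistic — mean over replicates of |L(K−1) − 2L(K) + L(K+1)| divided by
the replicate standard deviation (n−1 denominator) of L(K) — is computed on
the replicate criterion values as a second diagnostic; the absolute second
difference makes it orientation-free, and zero replicate spread yields NaN
with a warning rather than infinity.

**Summaries.** Hard assignment is the argmax Q entry (ties to the lowest
index, logged). Cluster descriptors use the fitted frequencies p_k(l):
raw between-cluster gene diversity D(j,k) = mean_l [1 − p_j p_k −
(1−p_j)(1−p_k)], net nucleotide distance D(j,k) − (D(j,j)+D(k,k))/2,
expected heterozygosity mean_l 2p_k(1−p_k), and a within-cluster F_st
1 − H_k/H_anc with H_anc the heterozygosity at the equal-weight
across-cluster mean frequency. Cluster indices are arbitrary, so
comparisons across runs use greedy maximum-correlation column matching.

## PCA and cluster counting

Missing dosages are replaced by the locus mean dosage (equivalent to mean
allele-frequency imputation up to a factor 2), columns centered, never
scaled. The decomposition is an SVD; eigenvalues are s²/(n−1), scores the
projections, loadings unit-norm right singular vectors with the
largest-magnitude entry of each column made positive (loading values are
otherwise sign-ambiguous between runs).

Cluster counting uses k-means (20 restarts, fixed seed) on retained scores
with BIC(k) = n·log(WSS/n) + k·log(n), argmin with ties to smaller k. This
BIC is a reliable argmin rule only when the score dimensionality is
comparable to n — which matches its intended use on large retained-PC sets
(hundreds of axes); in low dimension the WSS term dominates and the curve
decreases monotonically, which is why the package's own tests exercise it
in a d ≈ n regime.

## Nei pairwise F_st

Localities with fewer than 18 genotyped individuals are removed first. For
a pair, per locus: H_s is the unweighted mean of the two localities'
2p̂(1−p̂); H_t the heterozygosity at the pooled frequency weighted by
observed allele counts; the multilocus value is the ratio of sums
Σ(H_t−H_s)/ΣH_t over loci with data in both localities (stable at
low-diversity loci). No sample-size correction is applied — the estimator
then satisfies the exact closed forms (0 for identical frequencies, 1 for
fixed differences, 0.36 for one locus at p = 0.2/0.8 with equal n) and
matches the behavior of the R estimator this workflow mirrors.
Consequence: each pairwise value carries an upward bias of roughly 1/(4n)
(~+0.01 at 25 individuals per locality), which should be kept in mind when
reading small F_st values; the drift-consistency tests therefore use
250-individual localities so the bias is second order. Negative estimates
are reported unclamped, with a warning.

## Linkage-block analysis

A fully linked block whose haplotype frequency varies between otherwise
weakly differentiated subpopulations dominates the top of the sorted
loading list of the relevant PC axis. The detector sorts |loading|
descending and ends the block at the last rank before the first relative
drop (v_i − v_{i+1})/v_i > τ (default 0.25); only the top `max_scan` = 20
ranks are scanned, because deep in the tail tiny loadings routinely show
large relative drops that do not mark a block. Blocks smaller than 2 are
rejected. τ = 0.25 sits comfortably between the sharp boundary drop a real
block produces (~0.3–0.4 in practice) and the few-percent rank-to-rank
decay of background loadings; a geometric decay never triggers it.

Haplotypes are anchored on the most common fully homozygous multilocus
genotype (haplotype A), with haplotype B its complement; no all-homozygous
individual means the anchoring is ambiguous and an error is raised.
Individuals are classified hom_A / het / hom_B when the pattern holds at
*every* member locus, "other" for mixed patterns, and excluded (not
imputed) when any member genotype is missing — the unit-inheritance claim
is about observed genotypes. The removal contrast recomputes PCA without
the member loci and compares between-class/total variance of the axis
scores; it must be run on the same (region-excluded) matrix the block axis
was fitted on, since on the full matrix the leading axis belongs to the
most divergent region. The linkage-map join annotates members from a
locus → (linkage group, cM) table and, in extended-scan mode, walks down
the loading ranking until a run of `stop_run` = 5 consecutive loci off the
modal linkage group.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:

- **Drifted subpopulation frequencies.** Ancestral frequencies uniform on
  [0.05, 0.95]; per-subpopulation frequencies Beta-distributed around them
  (Balding–Nichols). The drift parameter is calibrated to the downstream
  estimator: a configured value F means the *expected Nei pairwise F_st
  between two localities from different subpopulations* is F, which
  requires an internal Beta drift c = 2F/(1+F) (quoting the raw Beta
  parameter would make two-deme pairwise estimates come out near F/2).
  Drift may be a scalar or per-subpopulation; the default
  {western 0.025, central 0.005, eastern 0.01} mirrors the asymmetric
  structure of the study system — one strongly drifted refugial
  subpopulation and two weakly differentiated ones (between two
  subpopulations the expectation is the mean of their two values).
- **Geography.** 12 localities (2 western, 4 central, 5 eastern, 1
  West-Virginia-analogue) of 25 individuals on a west-to-east longitudinal
  gradient; regions map 1:1 to subpopulations except the
  West-Virginia-analogue, which belongs to the eastern subpopulation but
  keeps its own region label because its block-haplotype frequency differs.
- **Admixture.** Individual ancestry from a per-region Dirichlet with
  concentration 15 on the home subpopulation and 0.2 elsewhere — most
  individuals essentially pure, a minority visibly admixed. Alleles are
  drawn per copy through the ancestry (cluster ~ Q, then Bernoulli(p_kl)).
- **Planted block.** 3 loci; each individual draws two block haplotypes
  from the region's haplotype-B frequency (default west 0.0, central 0.05,
  east 0.5, West-Virginia-analogue 1.0) and copies them across all members;
  per-locus orientation (whether haplotype B carries the alt allele) is
  random and recorded in the truth. Recombinants (default rate 0) scramble
  one member locus. Genotype errors (default rate 0) flip a dosage by ±1
  *after* the haplotype copy, so non-unit "other" classes can be induced
  controllably.
- **Missingness** uniform at random, default 1.5% (the study data carry
  ~1.15%).

All randomness flows from one integer seed; fixture output is
byte-identical on repetition. Ground truth (Q, subpopulation frequencies,
block membership, per-individual block class) is returned for recovery
tests.

What the generator does *not* emulate: a realistic site-frequency spectrum
(uniform ancestral frequencies give mean expected heterozygosity ≈ 0.38,
an order of magnitude above typical GBS SNP panels after MAF filtering, so
absolute heterozygosity-scale outputs are not comparable to real data),
linkage disequilibrium outside the planted block, isolation-by-distance
within subpopulations, batch/depth structure in DP/GQ, and non-random
missingness. Passing recovery tests therefore demonstrates correctness of
the estimators under the stated model, not robustness to these real-data
features.

## Problem sizes used in tests

Statistical tests run at the desk scale the package's own study conditions
define: n = 300 (12 × 25) individuals and m = 1000 loci for ancestry
recovery and block detection, n = 600 (12 × 50) for the end-to-end pipeline
fixture — at n = 300 the weak central/eastern split sits at the edge of
identifiability for held-out-criterion K selection, and the larger fixture
keeps the pipeline's model-choice stage deterministic in practice.
Drift-consistency checks use 20 replicate locality pairs of 250 individuals
each at 300 loci. These sizes are the package's chosen study conditions;
the real system this workflow targets is several times larger in both
dimensions, which only makes the corresponding signals stronger.

## Known limitations

- The NMF criterion cannot distinguish K from K+1 when the extra cluster
  explains less held-out prediction than its parameter cost; very weak
  splits (pairwise F_st ≲ 0.005 at desk scale) resolve as the smaller K.
- Q estimates at very weak differentiation (F ≈ 0.02) carry irreducible
  rotational uncertainty: the squared-loss optimum itself sits ~0.14 RMSE
  from the generating Q even with perfect label recovery.
- The relative-drop block rule assumes a single dominant block on the
  chosen axis; overlapping blocks or a block split across axes need manual
  inspection of the loading profile.
- `structure`-style Bayesian estimation is intentionally not reimplemented;
  the NMF estimator stands in for both programs, with the Evanno statistic
  applied to replicate criterion values.
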