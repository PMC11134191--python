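# Methods

This note documents the statistical models, the simulator, the numerical
choices, and the places where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model

Genotypes are unphased diploid alt-allele dosages in {0, 1, 2, missing}
(int8, −1 for missing), with a marker map (chromosome, 1-based bp position,
ref/alt alleles) kept sorted by (chromosome, position). Internally all
interval arithmetic is 0-based half-open; VCF positions are converted on
I/O and BED input is taken as already 0-based half-open. Every sample maps
to a population and every population to a class (`wild` or `selected`); a
popmap without a class column defaults to `wild` with a warning. Missing
data are handled pairwise-complete per locus throughout; loci with fewer
than two non-missing genotypes in a population are skipped for that
statistic.

## QC cascade and clumping

The filtering order is fixed: excluded regions → pooled MAF → per-sample
missingness → per-population call rate → per-population exact HWE. Pooled
MAF is computed on all retained samples combined, and the boundary is
inclusive-keep: a marker at exactly MAF 0.05 survives ("< 0.05" is
removed). The HWE test is the plain two-sided exact test (sum of
conditional probabilities ≤ the observed outcome's, no mid-p correction);
a marker fails when p < 0.01 in at least half of the populations.

LD clumping is a greedy left-to-right pass per chromosome: for each
surviving pair within the window (10 kb default) with r² ≥ 0.2 the
lower-MAF member is dropped, ties keeping the smaller-position marker.
This is provably equivalent to repeatedly eliminating the first violating
pair in position order (eliminations never create new violations), which
is what the brute-force O(n²) oracle in the test suite does. r² for
unphased dosages is the squared Pearson correlation over jointly
non-missing samples (composite-LD practice; phase is unknown on arrays).
An optional iterative PCA-loading-outlier pruning step (|loading z| > 6,
≤ 5 rounds) is available but off by default, since the threshold used by
the original tooling is not published.

Note the cascade is idempotent for ordinary inputs but not adversarially
so: removing a high-missingness sample can push a boundary-riding marker's
recomputed pooled MAF below the cutoff on a second pass. This is inherent
to the prescribed step order.

## Diversity, relatedness, FST

* Ho is the mean fraction of heterozygous calls over non-missing genotypes.
* He uses the unbiased small-sample factor: mean over loci of
  2p̂q̂ · 2n/(2n − 1).
* Allelic richness is rarefied to g = 2 × (the global minimum, over
  populations, of the per-locus non-missing sample count), so values are
  comparable across populations (hierfstat convention); per locus
  Ar = Σ_alleles [1 − C(2n − c_a, g) / C(2n, g)], validated against
  exhaustive subsample enumeration at 2n = 6.
* Ritland pairwise relatedness per locus is
  r_l = 2[Σ_a ẋ_a ẏ_a / p_a − 1] with ẋ_a ∈ {0, ½, 1}, averaged over
  polymorphic loci with both genotypes present; the scaling makes clones
  → 1 and unrelated pairs → 0 in expectation. Allele frequencies come from
  the focal population (the alternative — pooled-panel frequencies — is
  not what small-sample bias arguments favor); the estimator then carries
  a small negative bias of order −1/n for unrelated pairs, which the tests
  account for.
* FST is the Weir–Cockerham (1984) estimator: per-locus variance
  components a (among populations), b (among individuals within), c
  (within individuals), combined multilocus as the ratio of sums
  θ = Σa / Σ(a+b+c). Loci monomorphic across the compared populations are
  excluded. Small negative θ values are legitimate estimator behavior.

## LD-based Ne / Nb

Markers passing a within-population MAF ≥ 0.05 screen are subsampled
(5,000 by default, seeded) and only between-chromosome pairs are used, so
physical linkage cannot inflate the drift signal. The per-pair statistic
is the Burrows composite r²: squared Pearson correlation of dosages times
(S/(S−1))², the scaling under which the Waples (2006) sampling
expectations were derived. The drift component is
r²_drift = mean r² − (1/S + 3.19/S²) for S ≥ 30, or
mean r² − (0.0018 + 0.907/S + 4.44/S²) for S < 30, with S the harmonic
mean of per-pair joint sample sizes; inversion to Ne uses the matching
random-mating formulas, with nonpositive drift LD reported as an infinite
estimate (finite lower CI), as real studies print "∞" for large wild
populations. Without the (S/(S−1))² factor the estimator is visibly
biased: the acceptance suite's 20-replicate Wright–Fisher experiment at
true Ne = 100, S = 50 recovers a median of ~103 with the factor versus
~150 without it. Confidence intervals use a delete-one-individual
jackknife with the chi-square approximation (effective df n′ = 2/CV²);
the jackknife is cheap because the pairwise sufficient statistics admit
rank-one downdates per deleted sample.

## LD decay

Within-chromosome pairs up to 500 kb are binned into 100 equal-width bins
("100 increments" read as equal-width bins over [0, max]); per-bin mean r²
is fitted by weighted (pair-count) nonlinear least squares with the
Hill–Weir finite-sample expectation, with n = 2 × sampled individuals and
three fixed restarts for the initial decay rate. The half-decay distance
solves E[r²](c·d) = E[r²](0)/2 on the fitted curve — the fitted value at
d → 0, not the empirical maximum bin, for robustness. The two-way ANOVA
of half-decay on population type × chromosome uses an ordinary linear
model with interaction and sequential (type-I) sums of squares; a
constant response returns F = 0, p = 1 rather than 0/0.

## Runs of homozygosity

Window parameters follow the standardized-protocol formulas (L rounded up
— longer windows are conservative; t truncated, not rounded, to 3
decimals: the garbled typesetting of the threshold formula is read as
t = (N_out+1)/L per the protocol the study cites). By default one (L, t)
pair is computed from the whole panel (n_i = all individuals, mean
heterozygosity across all SNPs) — this matches the published worked
example (L = 78 from n_s = 141,676, n_i = 539, h̄ = 0.24) and keeps F_ROH
comparable between populations; a per-population mode exists
(`global_window=False`), since more-inbred populations otherwise receive
systematically longer windows from their lower heterozygosity.

Calling: a window of L consecutive SNPs qualifies when it has ≤ 1
heterozygote and ≤ 5 missing; a SNP is in-ROH when the fraction of
covering windows that qualify reaches t; maximal runs of in-ROH SNPs are
split at inter-SNP gaps > 1 Mb and then greedily at each heterozygote
beyond the per-segment allowance (all-or-nothing rejection of a run with
boundary heterozygotes would discard otherwise valid long tracts); the
surviving pieces must have ≥ L SNPs, ≥ 200 kb, and ≥ 1 SNP per 50 kb.
No MAF/HWE/LD filtering precedes ROH calling. Per-population QC: sample
call rate > 90%, near-duplicates (method-of-moments PI_HAT > 0.95 on a 5K
subset) removed, marker call rate ≥ 0.95 within the population, and
populations with ≤ 15 individuals skipped. F_ROH uses segments > 1 Mb by
default and divides by L_TOTAL from re-calling a simulated fully
homozygous individual on the same marker map and parameters, which bounds
F_ROH ≤ 1 by construction. The windowed caller is verified against a
windowless brute-force scanner on 50 random fixtures.

## Genome scans

Both scans test the pooled contrast (all wild samples as one deme, all
selected as the other) with neutral parameterization on the clumped set
and testing on the full set.

**FST scan.** The per-locus statistic is the uncorrected ratio
θ′ = s² / (p̄(1−p̄) + s²/r): the among-group variance of allele frequency
over the total, without finite-sample correction terms, hence nonnegative
with scale and effective df absorbed by the fitted null. Loci with pooled
He < 0.1 are excluded. The null is θ′·df/θ̄ ~ χ²(df) fitted by maximum
likelihood to the symmetrically 5%-trimmed clumped-set values, with the
likelihood truncated to the trimmed range and three df restarts;
right-tail p-values for all testable full-set loci get Benjamini–Hochberg
q-values (BH rather than Storey's estimator: the difference is
conservative).

**PC scan.** PCs come from the mean-imputed, √(2pq)-scaled clumped
matrix; K defaults to the largest eigenvalue gap among the first ten
components (overridable — the original analysis explored K = 1–10 without
fixing one). Each marker's centered dosages are regressed on an
orthonormalized basis of the K score vectors, giving K z-scores per
marker in one matrix product; the robust Mahalanobis distance of the
z-vectors uses the minimum covariance determinant (a MAD-based scale at
K = 1). Calibration deviates from the classical single median-based
genomic inflation factor: with strong per-strain drift and only a few
thousand markers the empirical null of the distances is heavier-tailed
than χ²(K), and median rescaling is anti-conservative exactly in the tail
that matters. The inflation factor used is the maximum quantile ratio
against χ²(K) over quantiles from the median up to the top order
statistics of the clumped-set null, so the calibrated null stochastically
dominates the observed neutral distances; the classical GIF is still
reported. The cost is power — this scan is deliberately conservative and
the union outlier list is usually carried by the FST scan in
drift-dominated regimes.

The union is deduplicated by marker id in stable order
(n_union = n_fst + n_pc − n_shared), and "clumped neutral" = full set
minus union, re-clumped.

## Random-Forest panel

The forest is a stratified-bootstrap ensemble of CART trees: each tree
draws an equal-size bootstrap from every class (size = smallest class),
the OOB error curve over tree count comes from cumulative OOB votes in a
single fit, and importance is permutation importance (mean decrease in
OOB accuracy), computed with one stacked prediction per tree. Tuning picks
the first tree count within one standard error of the minimum OOB-ER
(ignoring the noisy first 20 trees), then the first mtry grid value within
one SE at that tree count.

Backward purging: step 1 ranks all candidates by importance and evaluates
OOB-ER on nested top-fraction subsets ({1, 2, 5, 10, 20}% by default),
taking one subset size above the minimizer as a conservative candidate
list; when the largest fraction would truncate a small candidate list to
fewer than ~20 markers the full list is used instead (the published
fractions presume ~10³ candidates). Step 2 repeatedly drops the lowest
mean-importance marker (three replicate forests per iteration) down to two
markers. The final panel is the smallest one whose mean OOB-ER is within
one binomial standard error of the trace minimum — a one-SE parsimony
rule rather than the plain arg-min, because with flat OOB traces the
arg-min systematically favors panels inflated with selection-biased noise
markers (the planted-marker recovery experiment fails under plain
arg-min). DAPC validation retains PCs explaining ≥ 90% of panel variance,
fits a linear discriminant on the scores, and reports leave-one-out
predictions; singular within-class covariances trigger a PC-count
reduction.

## Enrichment, ellipses, report

Term enrichment is a one-sided hypergeometric test per term (a marker is
in a term when any of its genes carries it), with BH FDR at 0.1; the
universe is the annotated full-SNP list and candidates outside it are
ignored so counts stay nested. PCA ellipses use the per-population 2×2
covariance of PC1–2 scores: semi-axes √(λ·χ²₂(0.95)), area πAB, and
"standardized" area is the z-score across populations (any affine
standardization leaves the ANOVA F unchanged). The admixture index is the
Shannon–Wiener entropy of the population-mean Q rows (H = 0 for one
cluster, ln K for uniform). The ellipse ANOVA is sequential-F on
standardized area ~ H + relatedness, with the interaction in a separate
model, mirroring how the original analysis reports it. The report layer
writes per-population tables plus wild/selected group means, the FST
matrix with group means on all SNPs and on union outliers, F_ROH
summaries, and a manifest (config + seed) that reproduces the run.

## Simulator

The simulator is the pipeline's test substrate and defines the study
conditions; it deliberately models only what the analyses measure.

* **Genome.** 10 chromosomes × 300 markers at uniform random positions on
  10 Mb, each chromosome 1 Morgan; crossovers Poisson without
  interference; no mutation (array SNPs pre-exist) and monomorphic
  markers are retained so QC has work to do.
* **Wild populations.** Shared ancestral frequencies ~ U(0.05, 0.95);
  per-population starting frequencies Beta-spread around them with the
  Beta F calibrated analytically for the drift the ≥ 20-generation
  burn-in at Ne will add (d = 1 − (1 − 1/2Ne)^t), plus a short
  measure-and-adjust loop on the realized mean pairwise θ. Default:
  6 wild populations, Ne = 600, FST target 0.03, 30 samples each.
* **Strains.** Sexed broodstock drawn each generation (defaults 8–20 per
  sex), random mating across sexes, multiplicative viability (1+s) per
  selected-allele copy with batch-relative normalization (viability is
  inherently relative; absolute survival would extinguish multi-locus
  strains), optional Gamma-overdispersed parent weights for sweepstakes
  reproduction, and admixture crosses drawing an exact founder fraction
  from another strain. Truth per strain: expected Nb = 4NfNm/(Nf+Nm) and
  a family-size-corrected (Crow–Denniston) Nb per generation, exact
  pedigree inbreeding via the kinship-matrix recursion (founders assumed
  unrelated), founder-label IBD tracts (the same crossovers are applied
  to a label track), and per-individual admixture ancestry.
* **Demo design.** 9 strains over 3–6 generations, mirroring a pooled
  multi-strain contrast: with many fewer strains the pooled-drift null is
  too heavy for any scan to separate parallel selection from strain-level
  drift at desk scale. Ten parallel selected loci (the mid-chromosome
  marker of each chromosome, ancestral frequency anchored at 0.5,
  s = 1.0) are shared by all strains; strain S6 is an admixture cross.
* **Recovery experiments.** The F_ROH-vs-pedigree-F experiment uses four
  strains at a fixed 3-generation depth with broodstock 1×1 (full-sib),
  2×2, 5×5 and 12×12, spanning pedigree F ≈ 0–0.4: varying depth instead
  would confound the comparison, because deeper pedigrees produce shorter
  IBD tracts that the window caller increasingly misses. The LD-Ne
  experiment runs single populations at Ne = 100 with a 30-generation
  burn-in (cross-chromosome LD equilibrates quickly) and S = 50 sampled
  individuals.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: genotyping error and array ascertainment bias,
mutation, overlapping generations and mixed-age sampling, rotational
crossbreeding of sublines (admixture is a one-time founder mix),
chromosome-scale inversions or recombination-rate variation, and
environmental/plastic effects. Absolute values of Ne, F_ROH or half-decay
from the demo are not calibrated to any real species; only the
qualitative wild-vs-selected contrasts and the estimator-level recovery
experiments are.

## Problem sizes and determinism

Default analysis sizes (3,000 markers, 450 samples, 20 estimator
replicates, 10 scan seeds, 50 oracle fixtures) were chosen so the full
suite and the acceptance script each run in minutes on a single core
while keeping Monte-Carlo margins away from the asserted thresholds. All
randomness flows from one integer seed through stage-named sub-seeds
(CRC-hashed), so toggling one stage never shifts another's stream, and
fixed-seed runs are bitwise reproducible.
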