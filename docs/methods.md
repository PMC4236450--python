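# Methods

This note records the models, estimators, conventions and design choices
behind `popvar`, and what the synthetic-data generator does and does not
emulate.

## Data model and conventions

Genotypes live in a samples × variants matrix of alternate-allele dosages
(0/1/2) with missing (`./.`) as an explicit state. All variants are
biallelic; multiallelic VCF records are rejected rather than silently
split. Chromosome names are normalized to the bare dialect ("chr1" → "1")
at every boundary, because GRCh37-era resources mix the two spellings.
Variant positions are 1-based (VCF convention); all deletion-interval work
is 0-based half-open (BED convention), with the conversion confined to the
input layer and to het-site containment (1-based position p occupies
0-based [p−1, p)).

Missing genotypes are excluded from allele counts (the chromosome total
shrinks). The 1/2/3 genotype coding used by the structure pipeline has no
missing state, so the pipeline drops any variant with missingness before
coding; submitting a matrix with missing values to `code_genotypes` is a
contract error, not a silent imputation.

## Nucleotide diversity

Per-site π is the unbiased heterozygosity (n/(n−1))·2p̂(1−p̂), where n is
the number of called chromosomes. This equals the mean pairwise difference
over all C(n,2) chromosome pairs, which is how the test suite verifies it
(exactly, to 1e−12, against enumeration). Genome-wide π divides the sum of
site values by the total ungapped chromosome length supplied by the caller;
monomorphic sites contribute zero, and sites with any missing genotype in
the focal population are dropped from that population's sum. No
Hardy–Weinberg filtering is applied anywhere. Whether the small-sample
(n/(n−1)) correction is applied is a genuine free choice for this summary;
we chose the unbiased form because it makes the pairwise-difference
equivalence exact and testable.

## Sharing classes and enrichment

Classes partition all focal variants by the focal alternate-chromosome
count k and the pooled count elsewhere: monomorphic (k = 0), shared
(alternate allele seen elsewhere), rare (k = 1, absent elsewhere),
low-count private (k ∈ {2, 3}, absent elsewhere), private (k > 3, absent
elsewhere). The field uses "rare" both for strict population-confined
singletons and for plain singletons regardless of other populations, so
both predicates are exposed (`rare_strict` ≡ the class above, `singleton`
without the absence condition) and outputs name the stratum used.
Low-count private (k = 2–3 confined) is named explicitly rather than merged
into a neighbour class, so the partition is complete.

Enrichment between two strata is a 2×2 table of
(non-synonymous, synonymous) counts — variants labelled "other" are
excluded — tested with the Yates-corrected chi-square,
χ² = N(|ad−bc| − N/2)²/((a+b)(c+d)(a+c)(b+d)), with the correction floored
at zero when |ad−bc| ≤ N/2, and p from the 1-df survival function. A zero
margin is an error, not a zero statistic.

## Frequency differentiation scan

Group frequencies pool allele counts over member populations
(Σalt/Σtotal), never average member frequencies; this makes the group
frequency invariant to how a population is split across panel entries. The
scan takes per-variant |Δf| between the focal and comparison groups
(variants with an empty denominator in either group are excluded and
reported), computes the (100 − q)-th percentile of the |Δf| vector with the
linear-interpolation quantile (q = 0.1 by default), and flags values
strictly above it. Strict inequality is deliberate: a vector of identical
values produces no outliers. Whether the percentile should be an order
statistic instead of an interpolated quantile is not determined by the
problem; the interpolated form is used and documented. Below 1000 values
the tail quantile is noisy and the scan warns.

## Structure pipeline

The pipeline runs, in order: restriction to biallelic autosomal SNPs; the
subset-polymorphism filter (draw a fixed-size random subset — default 16
samples — from every population, keep a SNP only if 0 < alt < total in
every subset; populations smaller than the subset size are used whole);
LD pruning; 1/2/3 coding; PCA.

LD pruning slides a window of 50 currently retained variants per
chromosome, advancing by 5; while any within-window pair has squared
dosage correlation above 0.5, the later variant (position order) of the
first offending pair is removed. Zero-variance variants correlate 0 with
everything and are never removed by pruning. The retained set is re-checked
window-by-window in the tests: no surviving within-window pair exceeds the
threshold.

PCA centres and scales columns to unit variance (sd with n−1 denominator,
matching R's `prcomp(scale.=TRUE)` convention), drops zero-variance
columns with a warning, and takes scores from the SVD; explained fractions
use all non-zero singular values as denominator. A matrix with identical
rows yields a flagged degenerate result with zero explained fractions.

Genetic distance between individuals is the allele-sharing distance
mean(|gᵢ−gⱼ|)/2 ∈ [0, 1] (the formula behind individual-level trees is not
standardized; Euclidean distance on coded genotypes is available behind a
flag and both are labelled implementation choices). Geographic distance is
the haversine great-circle distance with Earth radius 6371 km.

The Mantel test correlates off-diagonal upper triangles, builds the null by
jointly permuting one matrix's row/column labels, and reports the
one-sided (positive association) p-value with the +1 correction:
p = (#{r* ≥ r} + 1)/(B + 1). One-sided was chosen because positive
isolation-by-distance is the only alternative of interest; the test's
type-I error at α = 0.05 is verified to sit in [0.02, 0.08] over 500 null
replicates at 199 permutations.

Neighbor joining is the standard Saitou–Nei agglomeration (Q-matrix
minimization, canonical branch-length formulas, three-node termination).
Ties in Q are broken toward the earliest pair in input order, so output is
deterministic; negative inferred branch lengths are clamped to zero with a
warning, negative input distances are an error. On additive matrices the
algorithm reproduces the generating tree exactly (verified to 1e−9 on
8-taxon matrices, and against an independent implementation on random
additive matrices).

## Deletion-callset algebra

Calls are size-filtered strictly: 50 bp < length < 100 kbp. Merging joins
calls with reciprocal overlap ≥ 0.8 by single linkage, then splits each
connected component greedily from its canonical seed (first call in
(chrom, start, end, sample) sort order): the seed absorbs every component
member overlapping it ≥ 0.8, the remainder re-seeds. This bounds the
chaining risk inherent in transitive merging — every emitted site has all
members at threshold overlap with its representative — and makes the
operation deterministic under input permutation and idempotent
(representatives of one component pairwise overlap < threshold by
construction). The representative interval is the seed's own interval, not
a consensus; how the original pairwise merge chose breakpoints is unknown,
so a deterministic, testable rule was preferred.

Novelty uses strict > 0.5 reciprocal overlap with any reference interval
("at least 80%" merges at ≥ 0.8, "more than 50%" excludes at > 0.5 —
each bound follows its own wording, and the test suite pins the boundary
cases). Validation counts heterozygous SNPs of carrier samples strictly
inside [start, end); a site passes with count zero. The external
genotyper's pass/fail is consumed as an input flag on calls (a merged site
counts as genotyped if any member call is); genotyping internals are out of
scope. Deleted-allele frequency is Σ genotypes of genotyped members over
2 × genotyped cohort size.

## Concordance against an array gold standard

The truth table defines the assayed sites (genotype 0 = assayed hom-ref). A
call is correct iff its site is assayed and the unphased genotype matches.
FDR is the fraction of assayed calls that contradict the truth; FNR is the
fraction of truth variants without a matching call. Genotype-level (not
site-level) matching was chosen; the alternative is defensible and the
choice is documented rather than asserted. Empty denominators produce
NaN with an explicit `*_defined` flag.

## The synthetic-data generator

The generator emulates the study design the analyses assume: one focal
population of 16 diploid samples plus 14 reference panels of 16 (labelled
with 1000 Genomes population codes, the Europeans forming the default
pooled comparison group), Balding–Nichols frequencies (ancestral
p ~ Beta(0.5, 0.5), per-population Beta(p(1−F)/F, (1−p)(1−F)/F), default
F = 0.1 — continental-scale differentiation), binomial dosages, and a
synthetic genome of 22 chromosomes × 10 Mbp. The default SNP count is
20,000 — enough for every downstream stage to operate at stable statistics
while a full pipeline run stays in the tens of seconds.

Planted structure, all recorded in a truth object:

- GWAS panel: 2000 SNPs; 2 planted outliers with |Δf| = 0.8 between focal
  and all comparison populations. The focal chromosome count of a planted
  outlier is set exactly (rounded), not drawn binomially, so the planted
  contrast is not eroded by focal sampling noise; 0.8 was chosen to stand
  clearly above the largest background |Δf| the F = 0.1 model produces on a
  2000-SNP panel (≈ 0.6).
- Confined variants: 200 singletons, 20 at 2–3 copies, 7 at > 3 copies,
  with all non-focal dosages forced to zero and exact focal chromosome
  counts distributed as heterozygotes where possible.
- Functional labels: non-synonymous with probability 0.6 for variants whose
  realized class is rare, 0.4 otherwise (synonymous else); labels are
  assigned after dosage realization, so the enrichment signal is exact by
  stratum. By default every SNP is labelled — the generator emulates
  labelled coding variation, not the genome-wide coding/non-coding mix.
- Deletions: 500 loci in pairwise-disjoint windows, log-uniform lengths
  strictly inside (50 bp, 100 kbp), carriers drawn per focal sample at rate
  0.1. Exactly round(0.1 × 500) loci are planted false: centred on a
  heterozygous SNP of a carrier, deep enough inside the interval that every
  jittered call still contains it. True loci avoid all carrier het SNPs
  with a jitter-sized margin. Per-carrier calls are whole-interval shifts
  of ≤ 2% of length, so same-locus calls reciprocally overlap ≥ 96% and
  distinct loci never approach the 0.8 merge threshold; validation failures
  are therefore exactly the planted fraction, by construction. Long loci
  that cannot be placed away from carrier hets are progressively shortened,
  biasing true-deletion lengths slightly toward SNP-sparse placements — as
  in real data, where long clean deletions are rarer.
- Reference catalogue: half the loci (shifted ≤ 5%, still > 50% reciprocal
  overlap) plus 100 decoy intervals placed away from every locus.
- Array truth: 5000 sites × all samples with a planted 0.2% per-genotype
  discordance, emulating residual array-vs-sequencing disagreement.

All draws flow from a single seeded numpy Generator in a documented order,
so a seed fully determines every fixture; the CLI writes byte-identical
outputs for repeated fixed-seed runs.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: linkage disequilibrium and haplotype structure
(sites are independent given population frequencies, so LD pruning is
exercised only by planted duplicate columns and chance correlation),
admixture and migration, ascertainment bias of real GWAS panels, sequencing
error and depth-dependent genotype quality, indel/SV breakpoint ambiguity
beyond uniform jitter, and any relationship between genotype and geography
(coordinates are noise, which is exactly what the Mantel null requires).

## Problem sizes and numerical choices

Unit tests run on cohorts of 2–8 populations and 1,500–8,000 SNPs; the
end-to-end property checks use the generator's default 500 deletion loci,
100 enrichment replicates at ~2,000 variants per stratum, 500 Mantel null
replicates at 199 permutations, and 50 seeds × 1,000 intervals for the
interval-algebra brute-force comparison. The acceptance script runs the
default study conditions (240 samples × 20,000 SNPs) end to end. Floating
point: site-π equals enumeration to 1e−12; PCA orthogonality to 1e−8;
newick branch lengths are written with 17 significant digits so additive
recovery round-trips exactly; quantiles use numpy's linear interpolation;
zero-variance columns are treated as correlation 0 in pruning and dropped
with a warning in PCA.

## Known limitations

Individual-level genetic distance and the interpolated percentile are
implementation choices where the field has no single convention; both are
flagged in the API. The merge rule's canonical-seed split is one defensible
reading of pairwise reciprocal-overlap merging; cluster-level results can
differ from tools that build consensus intervals. The simulator's
independence assumptions make LD-sensitive behaviour (pruning yield,
PCA eigenvalue spacing) optimistic relative to real genomes. Treemix-style
admixture-graph fitting, variant annotation, and read-level discovery are
out of scope: functional classes, genotyper success flags, and callsets are
consumed as inputs.
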