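# Methods

## Data model

A PAV (presence/absence variation) is a reference segment scored per sample
as 1 (the sample carries the backbone-like reference segment), 0 (it
carries the alternative structural allele) or NA (missing). Coordinates are
1-based inclusive throughout, matching VCF POS/END; conversion to 0-based
half-open happens only at the BED boundary. Within the VCF dialect read and
written here, a deletion's length is `|SVLEN|` when present, else
`END − POS + 1`; calls shorter than 20 bp are rejected at parse time.
(htslib itself canonicalizes END to `POS + |SVLEN|` for symbolic alleles
when writing; the reader prefers SVLEN, so round trips are exact either
way.)

## Consensus and merging

Two callers' per-sample call sets are intersected under a strict
reciprocal-overlap rule: both fractions `overlap/len` must exceed 0.5
("over 50%" read as strict; the exact-half case is tested). Insertions have
no reference extent, so they match by breakpoint distance ≤ 500 bp and
length ratio ≥ 0.5 — parameters of the merge, configurable at every call
site. Matching is greedy best-overlap with each call used once; consensus
coordinates come from caller 1, the declared primary caller (a
deterministic choice; the data carry no basis for preferring either).

Cross-sample merging is single-linkage clustering under the same predicate,
implemented as a sweep with union-find and validated against a brute-force
all-pairs oracle. Single linkage is the simplest transitive rule but can
chain through dense loci; this is a known divergence risk flagged here
deliberately. The longest member call represents each cluster. Records that
still overlap after merging carry distinct alternative alleles at one locus
and are reported as allelic pairs, with phenotype contrasts for the
A-like / B-like / reference-like genotype classes.

## Source categories and effect orientation

The source category is a pure function of the two parents' alleles:
(REF, ALT) → Parent#1-inherited, (ALT, REF) → Parent#2-inherited,
(ALT, ALT) → reference-specific, (REF, REF) → biparental; any missing
parent leaves the segment unclassified (excluded from category statistics,
retained in the map).

Effect orientation uses the improvement-oriented trait u (= trait when
higher is better, else −trait; the disease index is lower-is-better). A
Welch two-sided t-test compares reference-segment carriers with variation
carriers; at P ≤ 0.05, the segment is FAVORABLE when variation carriers do
worse, DELETERIOUS when they do better. Welch rather than pooled-variance
is the safer default where the source method states only "t-test". Groups
smaller than 2 yield NONE with a warning.

## Association scan

The genome-wide marker model is an ordinary linear scan
`trait ~ presence + PC1..PCk` with the top principal components of the
centered presence matrix as covariates (default k = 2), fitted by
Frisch–Waugh residualization. A kinship mixed model is a deliberate
extension point, not implemented: with a small marker set and raw-P
thresholds, the PC-adjusted scan has a directly testable type-I-error
contract — on a two-stratum structured null (n = 400, 2000 null segments)
the empirical rate at α = 0.01 is ~0.7–1.4% with PCs versus >20% without.
Thresholds are raw P values (marker P ≤ 0.01, divergence P ≤ 0.05) with no
multiple-testing correction, matching the method being reproduced. Segments
with a minor genotype group below 5, more than 20% missingness, or constant
presence are skipped with a recorded reason; missing genotypes are never
imputed for testing (the PC decomposition alone uses column-mean fill). The
scan is validated against an exact permutation oracle (full enumeration of
group labelings) on n ≤ 12 fixtures.

The eQTL scan applies the same linear contract to log2(TPM+1) expression
for every (segment, gene) pair, fully vectorized; reported links are the
cis pairs (segment within 1 Mb of the gene extent, configurable) plus trans
pairs surviving a Bonferroni genome-wide screen (0.05 / n_pairs). Genes
absent from the models are trans by convention.

The functional pool keeps (segment, trait) pairs with marker P ≤ 0.01 AND
divergence P ≤ 0.05 AND (genic/promoter context OR ≥1 expression link at
P ≤ 1e-3; the 1e-3 default is logged and configurable). SGP triplets then
label each (pool segment, linked gene, trait): s_trait = +1 iff carrying
the segment improves the oriented trait, s_expr = sign of the expression
slope; CONSISTENT iff s_trait·s_expr > 0. Zero slopes drop the triplet
rather than receive an arbitrary label.

## Heredity and the bottleneck

Hereditary stability of a segment is its retention count over the 18
progenies (the axis used in the category comparisons); the bottleneck
contrast instead counts carriers among all 20 pedigree members (parents
included), grouping segments below 6 against those above 12 and comparing
their population presence frequencies by Welch's t-test. Both denominators
are configurable; the defaults follow the respective statistic's framing.

## NMF sub-grouping

The binary segment-retain matrix S (m segments × n cultivars, 1 = cultivar
has the segment; foreign-introduced cultivars trimmed beforehand via the
sample-metadata flag) is factorized as S ≈ W·H by multiplicative updates
minimizing the Frobenius error. Initialization is seeded uniform noise
scaled to √(mean(S)/f); max_iter 500 and relative tolerance 1e-5 by
default; the objective trace is recorded and asserted non-increasing on
every run (a property of the update rule). The feature number f is chosen
over 2..10 by the silhouette of a seeded k-means (k = f) on the rows of W,
ties to the smaller f. Segments and samples take the argmax feature of
their W row / H column as sub-group, the maximal value as their score, ties
to the lowest index (logged).

Null calibration of the weak-structure flag: on unstructured random
matrices (binary or continuous) the f = 2 silhouette plateaus near 0.5 —
two-cluster k-means splits any unimodal cloud that well — while genuinely
blocked matrices score ≥ 0.85. The flag therefore fires when every
silhouette stays below 0.6, a threshold placed between those two regimes;
it is informational only.

Sub-group naming: SG1 is the sub-group with the higher favorable fraction
(override available). The per-sample ratio statistic is
(# SG1 segments present)/max(# SG2 segments present, 1) — the clamped
denominator is logged — correlated against the trait normalized by its
median. Synthetic traits carry a positive baseline (default 50 SD units)
precisely so that median normalization is well-defined and sign-preserving,
as it is for real agronomic scales.

## Fingerprint scores

tf = pedigree carriers / N_pedigree and idf = log10(N_population /
population carriers), score = tf·idf, FPS iff score strictly > 2. "lg" is
read as log base 10: only then does the published threshold geometry cohere
(at tf = 1 and N = 733, the score crosses 2 exactly between 7 and 8
population carriers: log10(733/7) ≈ 2.020, log10(733/8) ≈ 1.962). The tf
denominator defaults to all 20 pedigree members — the stated formula
divides by the full member count even though its numerator is described as
progenies — and a progeny-only convention (x/18) is provided as an option.
Zero population carriers take the pseudocount max(n, 1), flagged in the
output, which also caps the score at log10(N_population).

## Trait prediction

An RBF-kernel SVR (C = 10, ε = 0.1 in within-fold SD units, gamma =
"scale") is trained on the presence states of the trait's functional
segments under 5-fold cross-validation; only held-out predictions are
correlated with the observed phenotype (in-sample r would be inflated and
is never reported). The target is z-scored per training fold and mapped
back; missing presence entries are imputed with training-fold feature
means. Published accuracies on real cohorts are cohort-dependent and not
reproducible without those data; the package's claim is recovery of its
own planted signal, where held-out r matches the analytic signal fraction
√(var_signal / var_total) within ±0.1.

## Synthetic generator: what it emulates, and what it does not

The generator reproduces the statistical skeleton of the pedigree design:
2 parents + 18 progenies + reference, a 733-cultivar population with four
region labels (H, Y, NW, N), ~13k biallelic segments on ≥2 chromosomes
placed on a jittered grid sized so that distinct true segments never
satisfy the merge predicate against each other (segment lengths log-normal,
clipped to [20, 5000] bp). Parental alleles follow the drawn category;
progeny alleles are i.i.d. Bernoulli with per-category transmission
probabilities (defaults 0.75/0.75/0.45/0.90 — reference-specific segments
the least stable, mirroring the motivating observation); population
frequencies are uniform draws from per-category ranges, so pedigree
retention and population frequency are coupled through the category, which
is what the bottleneck contrast detects. Functional segments (default 30)
carry additive effects of fixed magnitude (1 phenotype-SD) on one trait,
split into two sub-groups with opposed effect signs and region-multiplied
population frequencies; each links to a cis gene whose log-expression
shifts by ±1 in carriers, with 75% sign agreement between trait and
expression effects (yielding both consistent and conflict triplets).
Planted fingerprint segments are biparental, retained by the whole
pedigree, and present in ≤7 of 733 cultivars (the cap scales
proportionally for smaller cohorts so the threshold geometry is
preserved). Traits add unit-SD Gaussian noise on a positive baseline;
expression is log-normal; caller emulation jitters breakpoints (SD 10 bp
default), drops calls at the false-negative rate and adds uniform
caller-private false positives (2%/2% defaults). Insertion/deletion status
is 50/50 and carries no downstream meaning. All draws derive from a single
seed via independent named streams; identical configs are bit-identical.

Not emulated: sequence content (no reads, no transposons), recombination
and linkage maps (segments are independent given category and sub-group),
multi-generation transmission, genotyping error in the population matrix,
and full transcriptome scale. Two consequences matter for interpreting the
tests. First, the scaled gene count (200 genes over a 120 Mb toy genome)
makes the genic-context/eQTL gate of the filter cascade stricter against
nulls than it would be at real gene density, so the measured
null-contamination of the pool (≈0%) is a property of these study
conditions, not a universal guarantee. Second, the planted sub-group
structure induces genuine genetic correlation between the two default
traits; functional segments therefore associate with the trait they were
not planted for (with divergence P far beyond chance), and the recovery
metrics count such hits as signal — "false discoveries" means truly-null
segments only. Problem sizes used in the shipped tests and the acceptance
script (2000 segments × 400 cultivars for recovery; 1000 × 300 for
heredity; 800 × 733 for fingerprints) keep full runs to seconds while
leaving every planted contrast many standard errors wide.

## Numerical choices and degenerate inputs

Exact ties in the overlap fraction fail the strict >0.5 rule by
construction. A constant trait yields P = 1 for every segment rather than
an error. The category/effect percentage is favorable/(favorable +
deleterious) rounded to one decimal, NA for empty cells; the chi-square
independence test is NaN when the contingency table is degenerate. The NMF
update guards denominators with 1e-12 and raises if the objective ever
increases beyond numerical tolerance. Pan/core curves treat NA as "does not
hold the variation". Empty bottleneck contrast groups, zero trait medians,
all-constant SVR features, and malformed gene models raise immediately with
specific messages.

## Known limitations

Single-linkage merging can chain dense SV loci into one record; the linear
scan substitutes PC adjustment for a kinship mixed model and will
under-correct cryptic relatedness that PCs miss; NMF is a local optimizer
(one seeded initialization per f, no multi-restart consensus); the allelic
pair rule reports any post-merge overlapping record pair and does not
attempt breakpoint-level allele resolution; and the generator's
independence assumptions (no LD) make marker-level power estimates
optimistic relative to real cohorts.
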