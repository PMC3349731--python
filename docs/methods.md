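# Methods

This note documents the models and procedures the package implements, the
assumptions behind them, the numerical choices, and what the synthetic
cohort does and does not emulate.

## Read processing

**Tag assignment.** The distance between a read's first six bases and an
index tag is positional (Hamming-like): 0 for a match, 0.25 for `N`
against anything, 1 otherwise. Levenshtein distance is deliberately not
used — both strings have fixed length 6 and the fractional N cost only
composes positionally. A read is assigned to the unique minimum-distance
tag when the minimum is below 2.75; ties and minima at or above the cutoff
leave it unassigned. The cutoff admits up to two substitutions plus N
noise but never three clean substitutions.

**Adapter trimming.** Stage 1 searches the adapter's first 12 bases at
every internal position with a mismatch budget of `floor(0.2 * 12) = 2`,
taking the leftmost hit (maximal trimmed adapter evidence; ties cannot
occur under the leftmost rule). Stage 2, used only when stage 1 finds
nothing, anchors adapter prefixes of length L = 12 down to 1 at the read's
3' end with budget `floor(0.2 * L)`. The floor rule is a choice; the
source protocol says only "up to 20%". Note a consequence of the anchored
rule: a read whose final base happens to equal the adapter's first base
always loses that base, so re-applying the trimmer can shorten such reads
further. Trimming is therefore applied exactly once per read; an
"idempotence" invariant holds only for reads whose trim removed a genuine
internal adapter occurrence.

**Cleanup order.** (1) any five-base window with ≥3 Ns truncates at the
window's first N; (2) an N within the last two bases truncates there;
(3) reads that are ≥90% one base are discarded (N counts only as itself);
(4) reads under 16 nt are discarded. The order matters and is fixed.

## Reference strata and ambiguity codes

Five prioritised strata: kit contaminants (every adapter, linker,
adapter+linker and adapter±tag combination plus its full single-nucleotide
edit neighbourhood, deduplicated), mature/star miRNA sequences extended by
up to 3 nt 5' and 5 nt 3' from the hairpin (star arms receive the same
extension), other ncRNA including full hairpins, ncRNA pseudogenes, and
the genome. Known variant positions are written as the minimal IUPAC code
covering reference and alternate alleles (multi-allelic sites use the
minimal superset code). De-ambiguating every code back to its reference
allele reproduces the input sequences exactly. Internal coordinates are
0-based half-open; BED-adjacent text output is 1-based inclusive.

## Alignment contract and the two matchers

An alignment admits at most 2 substitutions and at most 1 single-base
internal gap (insertion or deletion; terminal gaps are soft-clip
territory, not gaps). A read base matches a reference IUPAC symbol iff it
belongs to the symbol's allele set; read `N` matches nothing and always
costs a substitution. The genome stratum is searched on both strands —
implemented by aligning the reverse-complemented read forward, so all
offsets are forward-strand window starts; transcript strata are forward
only. Locations are keyed by (target, window start, strand); gap-placement
ties collapse to one location at the minimum distance.

*Exhaustive matcher*: a shifted-accumulation scan that computes, for every
window start in a stratum, the minimum mismatch count over the three
alignment shapes, using per-base-mask mismatch tracks shared across reads
and strands. It enumerates every qualifying location by construction.

*Heuristic matcher*: the read is split into four disjoint blocks of
`len // 4 >= 4` bases. Any alignment within budget (≤3 errors) leaves at
least one block error-free and unbroken by the gap, so that block matches
the reference exactly at an offset within ±1 of the alignment start.
Exact block hits from a k-mer index (IUPAC windows expanded to concrete
words) propose candidates, which are verified per candidate. Both
matchers share the final boundary validation; their candidate generation
and scoring paths are independent, and both are checked against a
pure-Python per-offset enumeration oracle in the tests.

Reads are retained for quantification only when the two matchers agree on
all aligned locations (the consensus rule). Any contaminant hit excludes
the read; otherwise the highest-priority stratum wins, only its
minimum-edit-distance locations are kept, and each of the k locations
receives 1/k counts. Multi-stratum ties cannot occur (priorities are
strict); a read hitting only the full hairpin within the ncRNA stratum is
counted to the hairpin id.

Unannotated loci are maximal runs of gap-free *pooled* (all-sample)
coverage by genome-resolved reads; two reads must share at least one
covered base to join a locus. The short subset contains loci under 100 bp
carrying at least 1000 read mass.

## Normalisation and batch screen

Size factors are median-of-ratios: `s_j = median_g (n_gj / GM_g)` with
genes containing zeros excluded from the median. Two exact properties
(derived, and asserted in tests): scaling sample j's counts by c scales
`s_j` by `c^((n-1)/n)` (the per-gene geometric means absorb `c^(1/n)`),
and size factors recomputed on corrected counts all equal the geometric
mean of the first-round factors — samples are fully equilibrated after one
round. Expression is `log2((n + 0.5)/s_j)`; the 0.5 pseudocount handles
zeros (scale invariance is exact only at pseudocount 0).

The batch screen correlates sample principal components (SVD of the
sample-centred log expression, covariance convention) with covariates;
categorical covariates enter one-hot and are scored by the level of
maximal |r|. The statistic is `t = r sqrt((n-2)/(1-r^2))` on n−2 df,
two-tailed, Bonferroni-corrected over the number of tests, which defaults
to the number of samples (the reference cohort screened one test per
component at n = 131, giving a two-decimal significance boundary of
|r| = 0.31: 0.30 is not significant, 0.31 is; the exact root is ≈0.306).

## Variant and editing calls

Pileups cover uniquely-resolved, ungapped transcript-stratum reads;
positions adjacent to indels are excluded. "Observed alleles" means
read-level allele observations (depth) — the only reading under which "at
least 10" is meaningful. Filters: ≥20 informative samples (≥1 covering
read), ≥1 sample with depth ≥10, ≥1 sample with ≥20% non-reference reads.
Sites at the final base of a mature product are flagged as likely
degradation artefacts rather than called. Classification against DNA
pileups (available for a subcohort, emulating ~30% whole-genome coverage):
≥5 DNA alternate reads in any sample ⇒ polymorphism; reference A, ≤2 DNA
G reads everywhere, and both A and G observed in ≥90% of RNA-informative
samples ⇒ A-to-I edit; otherwise unresolved. With no DNA at all a site
stays unresolved — never editing. The 90% clause denominator is
informative samples (the source is silent on the denominator).

Detectability boundary: with a fixed per-read editing rate p and depth d,
the probability that a sample reaches the 20% non-reference clause is the
binomial tail `P(X >= 0.2 d | p)`, which *decreases* with depth for
p < 0.2. Edits at p ≈ 0.18 and above are recovered essentially always at
d = 100 across 40 samples; at p = 0.10 the chance is under 10%. Real
cohorts recover lower mean fractions only through inter-individual rate
variation, which the generator intentionally does not model (its rates are
fixed per site, as configured).

The expected number of discoverable DNA variants sums, over sites, the
probability that at least one sample carries the alternate allele and
shows it on ≥10 reads, with Hardy-Weinberg genotype probabilities and
binomial alternate-read counts given carrier state and depth.

## Association

All tests are Gaussian likelihood-ratio tests on nested linear models:
`stat = n ln(RSS_null / RSS_full)` referred to χ²₁ (equal to twice the OLS
log-likelihood difference; verified against statsmodels). Covariates: age
numeric, library batch and multiplexing tag one-hot with first-level
reference. The χ² reference is asymptotic; with small n and many
covariate columns the tail is anticonservative relative to the exact
F-test, which matters for desk-scale runs with the full 12-level tag
factor but is negligible at n ≥ 100 with a lean covariate set.

cis-eQTL scans test every SNP with MAF > 0.05 and imputation info > 0.8
within 100 kb of the transcript; q-values are computed over the pooled
test list. Phenotype associations compute q-values per trait, floor
insulin values below the assay detection limit (values < 13 set to 12),
and skip traits with >20% missingness. The lean/obese contrast excludes
subjects with 25 ≤ BMI ≤ 30 and tests a binary indicator. Arm analysis
reports Spearman rho (average ranks, t approximation) between mature and
alternate-arm levels, flags |rho| > 0.4, and scans the mature−star log
difference for QTLs with the same machinery.

q-values are Storey's: `pi0(λ) = #{p>λ}/(m(1−λ))` on λ ∈ {0.05,…,0.95}
smoothed with a cubic polynomial and evaluated at the largest λ (clipped
to (1/m, 1]; pi0 = 1 for fewer than 100 tests, where the smoother is
unstable), then `q_i = min_{p_j≥p_i} pi0 · m · p_j / rank(p_j)` capped at
1. With pi0 = 1 this reduces exactly to Benjamini-Hochberg.

## Seed enrichment

For each adenosine-ending 8-mer, four words are tested along the ranked
UTR list: the middle 6-mer, the two 7-mers and the 8-mer itself.
Occurrences are counted with overlaps; the universe is all sliding word
positions. For a leading set of n UTRs the p-value is the one-sided upper
hypergeometric tail of the word's occurrences among the top-n positions.
The grid of n defaults to 20 evenly spaced cut points (results are
invariant to refinement beyond UTR-count resolution). The combined score
is the maximum over the grid of the summed −log10 p of the four words,
with each −log10 p capped at 320 to avoid infinities at underflow. The
focal miRNA's significance is the upper tail of a generalized
extreme-value distribution fitted by maximum likelihood to all 16,384
A-ending 8-mer scores (empirical-tail fallback on fit failure).

A third-order Markov composition correction is implemented and exposed as
an option: the null draw count of a word in the top-n set is rescaled by
the ratio of the word's probability under a Markov model estimated from
the top set's own 3-mer/4-mer counts to its probability under the
full-set model. It is **off by default** in this package: at the scale of
the synthetic cohorts (hundreds of UTRs of a few hundred bases), nearly
every occurrence of a planted seed word is signal, so a correction whose
composition is estimated from the top set absorbs the word's own
constituent 4-mers — each of the ~6 factors roughly doubles per planted
copy — and erases exactly the enrichment the score is built to detect. On
genome-scale UTR collections, where background occurrences dominate
composition, the correction behaves as intended; users analysing such
data can enable it. The uncorrected test is the exactly oracle-checked
path (it reproduces a brute-force hypergeometric computation to 1e-12).

Hypergeometric tails over all seeds are evaluated once per unique
(k, K, N) triple; the triples repeat heavily across seeds, which turns
~1.3 million tail evaluations into a few thousand.

## Expression statistics

Tissue specificity uses Welch Z-tests of adipose mean log expression
against each other tissue (`Z = (μ_a − μ_t)/sqrt(v_a/n_a + v_t/n_t)`),
two-tailed normal p, q across RNAs per tissue; an RNA is adipose-specific
when Z > 0 and q < 0.1 against every other tissue (a mean-q variant is
available by flag). Conservation-expression tests are Pearson chi-squared
(1 df, no continuity correction) on 2×2 tables of high/not expression (or
variance) by unconserved/not. Cluster co-expression compares per-cluster
median pairwise Pearson r (on covariate-residualised expression) against
size-matched random sets, drawn without replacement and seeded, by
two-sided Mann-Whitney U. Target-correlation summaries use per-pair
Pearson r on residualised data, a one-sample t-test of the mean against
zero and a Mann-Whitney comparison against random pairs.

## The synthetic cohort

The generator emulates the study design: a single synthetic chromosome
carrying miRNA hairpins (5' mature arm always, 3' star arm for a
configurable fraction, default 0.4), snoRNAs, other ncRNAs, mutated
pseudogene copies and unannotated transcribed loci, all as genome
substrings so every RNA also maps to its locus; hairpins placed within
10 kb share a cluster. Reads are 37 bases — six-base tag, insert with
genotype-consistent alleles, A-to-I edits at fixed per-read rates and
uniform substitution errors (default 0.5% per base, typical of the
sequencing platform generation emulated), then the 3' adapter. Abundances
are log-normal: baseline log2 levels are Gaussian per RNA class (mature
6, star 2, snoRNA 4, other 3; SD 2), matching the heavy-tailed library
composition of real small RNA data. Expected log2 expression adds
additive eQTL effects (beta × dosage), per-(gene, batch) effects (SD 0.5)
and Gaussian noise (SD 0.5); molecule counts are multinomial at
Poisson-distributed depth. Genotypes are Hardy-Weinberg at the configured
frequencies. Phenotypes (BMI, trunk fat, insulin, glucose) are linear in
standardised true RNA levels plus noise; glucose carries no planted links.
Contaminant reads are tag + linker + adapter ligation products, which
survive trimming as the bare linker and are excluded by the contaminant
stratum — the same mechanism as in real libraries. A fixed seed makes
every artefact byte-identical; read provenance covers each emitted read
exactly once.

Not modelled: ligation/tag sequence bias, PCR duplicates, size-selection
physics, base-quality variation (qualities are constant high; the
pipeline never uses them), inter-individual editing-rate variation, and
cluster-level co-expression beyond shared batch structure. Passing tests
therefore demonstrate correctness of the algorithms under the stated
generative assumptions, not robustness to these real-data artefacts.
Cohort-design defaults follow the study (131 samples, 12 tags per pool,
37-base reads); sequencing depth and gene counts default to desk scale,
with the coverage thresholds scale-configurable (the pipeline drivers
scale the 1000/100/500,000 thresholds by the ratio of simulated to study
depth).

## Problem sizes used by the tests and the acceptance script

End-to-end runs use 24 samples × ~2000 reads (≈48,000 pooled reads, 12
miRNAs, 6 snoRNAs, 4 other ncRNAs, 3 pseudogenes, 4 unannotated loci on a
260 kb genome). Matcher-equivalence checks run 10,000 mutated reads
against ~101 kb of references (zero disagreements required). eQTL power
uses 100 simulations at n = 100, beta = 1, MAF 0.3 with Poisson read
noise; calibration uses 5,000 all-null tests. Variant/edit recovery uses
60 pileup-level simulations each (40 samples; carrier depth ≥ 20 for
polymorphisms, rate 0.18 at depth 100 for edits; 300 null sites). Seed
enrichment uses 180 UTRs of 250 nt with 60 targets coupled at −0.5, and
30-50 null replicates for focal-p calibration. These sizes were chosen so
the full loop runs comfortably on a laptop-class single core while
keeping every statistical check well-powered.
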