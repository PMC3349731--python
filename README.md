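# srnavar

Population analysis of small RNA sequencing data: from multiplexed raw reads
to expression, sequence-variation and association results, with a synthetic
cohort generator that provides ground truth for every stage.

## The problem

Small RNAs (miRNAs, snoRNA-derived fragments) are quantified by sequencing
15–30 nt molecules from pooled, index-tagged libraries. Turning those reads
into population-level biology requires a chain of specialised steps, each
with its own pitfalls:

1. **Demultiplexing and cleanup** — reads carry a six-base index tag; a read
   is assigned to the library whose tag is closest under a fractional
   positional distance (`N` costs 0.25 against any base), discarded if the
   minimum distance reaches 2.75 or is tied. The 3' adapter is located
   internally (12-base seed, ≤20% mismatches) or by anchored overlap, and
   reads are cleaned (N-window truncation, terminal-N trimming, ≥90%
   single-base discard, minimum 16 nt).
2. **Ambiguity-aware stratified alignment** — five prioritised reference
   strata (kit contaminants > extended mature/star miRNA > other ncRNA >
   pseudogenes > genome), with known polymorphic positions written as IUPAC
   ambiguity codes so either allele maps without penalty (avoiding
   allele-specific mapping bias, which otherwise creates spurious eQTLs).
   Two independent matchers — an exhaustive all-offsets scan and a
   pigeonhole-seeded heuristic — must agree on all locations for a read to
   be retained. A read mapping to k locations in its winning stratum adds
   1/k to each target ("fractional counting").
3. **Normalisation** — median-of-ratios size factors
   `s_j = median_g(n_gj / GM_g)` and `log2((n+0.5)/s_j)` expression, plus a
   principal-component/covariate screen for batch effects using
   `t = r sqrt((n-2)/(1-r^2))` with Bonferroni correction.
4. **RNA-level variant and A-to-I editing calls** — per-site allele pileups
   filtered (≥20 informative samples, ≥10 alleles in some sample, ≥20%
   non-reference somewhere) and classified against DNA pileups: ≥5 DNA
   alternate reads ⇒ polymorphism; reference A with ≤2 DNA G reads and both
   A and G in ≥90% of informative samples ⇒ A-to-I edit.
5. **Association** — Gaussian likelihood-ratio tests
   (`-2 log LR = n ln(RSS_0/RSS_1)` on χ²₁) of expression against cis SNP
   dosages (±100 kb, MAF>5%, imputation info>0.8), metabolic phenotypes,
   lean/obese status and arm-ratio differences, with Storey q-value FDR
   control.
6. **Seed enrichment** — for UTRs ranked by correlation with a miRNA, the
   combined score `max_n Σ_w −log10 p_n(w)` over the four seed words
   (middle 6-mer, both 7-mers, the A-ending 8-mer), tested against a
   generalized extreme-value null fitted to all 16,384 adenosine-ending
   8-mer scores.

Every stage is closed-loop testable because the `simulate` module generates
a full cohort — genome, hairpins with mature/star arms, tagged 37-base
reads, planted variants/edits/eQTLs/phenotype links — with per-read truth.

## Worked example

```python
from srnavar.simulate import planted_config
from srnavar import pipeline, association

cfg, cat = planted_config(seed=2, n_samples=24, n_mirna=12, n_snorna=6,
                          n_other=4, n_pseudogene=3, n_unannotated=4,
                          genome_length=260_000, read_depth_mean=3000.0,
                          n_null_snps=10)
quant = pipeline.run_quantification(cfg, cat)
print(quant.counts.shape, quant.mapped_reads, quant.consensus_failures)

calls, artefacts, _ = pipeline.call_variants(quant)
for call, truth in calls:
    print(call.rna_id, call.offset, call.ref, "->", call.derived, call.kind)

filtered, s, expr = pipeline.expression_matrix(quant)
res = association.cis_eqtl_scan(expr, quant.cohort.genotypes,
                                quant.cohort.snp_info, cat.annotations(),
                                covariates=quant.cohort.covariates)
print(res.head(3))
```

prints (seed 2):

```
(26, 24) 68445 0
mir-1-5p 15 T -> G polymorphism
sno-2 22 T -> G polymorphism
mir-4-5p 9 A -> G editing
mir-3-5p 10 A -> G editing
    feature   predictor  sign       stat             p         q
0  mir-3-5p  eqtl-snp-3   1.0  30.591335  3.185130e-08  0.000004
1  mir-1-5p  eqtl-snp-1   1.0  23.081672  1.552637e-06  0.000093
...
```

All 68,445 retained reads passed the dual-matcher consensus (0 failures);
the planted polymorphisms and seed-region A-to-I edits are recovered with
their correct derived alleles (positions are reported in extended-reference
coordinates, 3 bases 5' of the mature start), and the planted cis-eQTLs top
the association table at q ≪ 0.05.

A `srnavar` command-line tool exposes the stages as subcommands
(`simulate`, `demux-trim`, `build-refs`, `quantify`, `normalise`,
`qc-screen`, `call-variants`, `eqtl`, `pheno-assoc`, `group-contrast`,
`arm-qtl`, `seed-enrich`); run `srnavar --help`.

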