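"""End-to-end drivers chaining the pipeline stages on a synthetic cohort.

The quantification driver runs: read synthesis -> demultiplex/trim/cleanup ->
dual-matcher alignment with consensus -> stratum resolution -> fractional
counting -> unannotated locus discovery.  Analysis drivers take the
quantification state on to normalisation, variant calling and association
scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import align, demux, references, variants
from .iupac import encode_read, encode_ref
from .simulate import (Catalogue, Cohort, SimConfig, make_reference_catalogue,
                       simulate_cohort, simulate_dna_pileups, synthesize_reads,
                       variant_site_list)


@dataclass
class QuantResult:
    cfg: SimConfig
    catalogue: Catalogue
    cohort: Cohort
    sidecar: pd.DataFrame
    strata: dict[str, references.ReferenceStratum]
    reads_by_sample: dict[str, list[demux.ReadRecord]]
    demux_report: dict
    counts: pd.DataFrame                  # annotated RNAs x samples
    locus_counts: pd.DataFrame            # unannotated loci x samples
    loci: pd.DataFrame
    resolution: dict[str, tuple]          # read id -> (status, winners, k)
    consensus_failures: int = 0
    mapped_reads: int = 0
    read_sample: dict[str, str] = field(default_factory=dict)

    @property
    def mapped_per_sample(self) -> pd.Series:
        both = pd.concat([self.counts, self.locus_counts])
        return both.sum(axis=0)


def kit_sequences(cfg: SimConfig) -> dict:
    return {"adapters": [cfg.adapter3], "linkers": [cfg.linker],
            "tags": list(cfg.tag_set)}


def run_quantification(cfg: SimConfig, catalogue: Catalogue | None = None,
                       dual: bool = True) -> QuantResult:
    """Simulate a cohort and quantify it through the full read pipeline.

    With ``dual=True`` (default, the study contract) reads are kept only
    when the heuristic and exhaustive matchers agree on all locations; with
    ``dual=False`` the heuristic matcher alone is used (the matchers are
    verified equivalent elsewhere).
    """
    if catalogue is None:
        catalogue = make_reference_catalogue(cfg)
    cohort = simulate_cohort(catalogue, cfg)
    reads_by_pool, sidecar = synthesize_reads(cohort, catalogue, cfg)

    tags = demux.TagSet(tuple(cfg.tag_set))
    sample_of = {(cohort.pool_of(s), cohort.tag_of(s)): s
                 for s in cohort.samples}
    reads_by_sample: dict[str, list[demux.ReadRecord]] = {
        s: [] for s in cohort.samples}
    report_total: dict[str, int] = {}
    for pool, reads in reads_by_pool.items():
        by_tag, report = demux.process_pool(reads, tags, cfg.adapter3)
        for key, val in report.items():
            report_total[key] = report_total.get(key, 0) + val
        for tag, tag_reads in by_tag.items():
            sample = sample_of.get((pool, tag))
            if sample is not None:
                reads_by_sample[sample].extend(tag_reads)

    strata = references.build_references(
        catalogue, variant_site_list(catalogue, cfg), kit_sequences(cfg))
    heur = align.HeuristicMatcher(strata)
    exh = align.ExhaustiveMatcher(strata) if dual else None

    cache: dict[str, tuple] = {}

    def resolve_seq(seq: str):
        if seq in cache:
            return cache[seq]
        a = heur.map_read(seq)
        if exh is not None:
            b = exh.map_read(seq)
            agreed = align.consensus(b, a)
            failed = ({x.location for x in a} != {x.location for x in b})
            res = align.resolve_strata(agreed) + (failed,)
        else:
            res = align.resolve_strata(a) + (False,)
        cache[seq] = res
        return res

    resolution: dict[str, tuple] = {}
    read_sample: dict[str, str] = {}
    resolved_stream = []
    genome_reads = []
    consensus_failures = 0
    mapped = 0
    for sample, reads in reads_by_sample.items():
        for read in reads:
            status, winners, k, failed = resolve_seq(read.seq)
            resolution[read.id] = (status, winners, k)
            read_sample[read.id] = sample
            consensus_failures += int(failed)
            if status in (align.CONTAMINANT, align.UNMAPPED):
                continue
            mapped += 1
            if status == "genome":
                m = len(read.seq)
                genome_reads.append((sample, read.id, winners, k, m))
            else:
                resolved_stream.append((sample, winners, k))
    counts = align.fractional_count(resolved_stream, cohort.samples)

    # unannotated loci from pooled genome-resolved coverage
    intervals = []
    for sample, rid, winners, k, m in genome_reads:
        for a in winners:
            intervals.append((a.target, a.offset, a.offset + m, 1.0 / k))
    if intervals:
        loci = align.call_unannotated_loci(intervals)
    else:
        loci = pd.DataFrame(columns=["chrom", "start", "end", "reads",
                                     "length", "short_locus"])
    locus_ids = [f"{r.chrom}_{r.start}_{r.end}" for r in loci.itertuples()]
    locus_counts = pd.DataFrame(0.0, index=locus_ids, columns=cohort.samples)
    if intervals:
        bychrom = {c: g.sort_values("start")
                   for c, g in loci.groupby("chrom")}
        for sample, rid, winners, k, m in genome_reads:
            for a in winners:
                grp = bychrom.get(a.target)
                if grp is None:
                    continue
                hit = grp[(grp["start"] <= a.offset)
                          & (grp["end"] >= a.offset + m)]
                for r in hit.itertuples():
                    locus_counts.loc[f"{r.chrom}_{r.start}_{r.end}",
                                     sample] += 1.0 / k
    return QuantResult(cfg=cfg, catalogue=catalogue, cohort=cohort,
                       sidecar=sidecar, strata=strata,
                       reads_by_sample=reads_by_sample,
                       demux_report=report_total, counts=counts,
                       locus_counts=locus_counts, loci=loci,
                       resolution=resolution,
                       consensus_failures=consensus_failures,
                       mapped_reads=mapped, read_sample=read_sample)


def _arm_shift(catalogue: Catalogue, arm_id: str) -> int:
    """Offset of the arm start within its extended mature reference."""
    _, start, _ = catalogue.arms[arm_id]
    return min(references.MATURE_EXT_5P, start)


def pileup_read_stacks(quant: QuantResult):
    """Transcript-space read stacks over the mature and ncRNA strata.

    Only uniquely resolved, ungapped transcript reads contribute; the
    ungapped check compares the read to the IUPAC reference window.
    """
    enc_cache = {}
    for name in ("mature_mirna", "ncrna"):
        for t, s in quant.strata[name].sequences.items():
            enc_cache[(name, t)] = encode_ref(s)
    for sample, reads in quant.reads_by_sample.items():
        for read in reads:
            status, winners, k = quant.resolution[read.id]
            if status not in ("mature_mirna", "ncrna") or k != 1:
                continue
            a = winners[0]
            ref = enc_cache[(status, a.target)]
            m = len(read.seq)
            if a.offset + m > len(ref):
                continue
            rb = encode_read(read.seq)
            subs = int(np.count_nonzero((ref[a.offset:a.offset + m] & rb) == 0))
            if subs > align.MAX_SUB:
                continue                      # gapped alignment; skip
            yield (sample, a.target, a.offset, read.seq, set())


def call_variants(quant: QuantResult, n_null_sites: int = 20,
                  dna_fraction: float = 0.3):
    """Build pileups at planted and null mature-arm sites, filter, classify.

    Returns ``(calls, artefact_calls, candidate_sites)``.
    """
    cfg, catalogue = quant.cfg, quant.catalogue
    site_defs = []                     # (arm, ext offset, ref, truth key)
    for rna, offset, ref, alt, af in cfg.variant_sites:
        if rna in catalogue.arms:
            ext = offset + _arm_shift(catalogue, rna)
        else:
            ext = offset                      # ncRNA: reference-space directly
        site_defs.append((rna, ext, ref, f"{rna}:{offset}"))
    for rna, offset, rate in cfg.edit_sites:
        ext = offset + _arm_shift(catalogue, rna)
        site_defs.append((rna, ext, "A", f"{rna}:{offset}"))
    rng = np.random.default_rng([cfg.seed, 7])
    planted = {(r, o) for r, o, _, _ in site_defs}
    arm_ids = list(catalogue.arms)
    mature = quant.strata["mature_mirna"]
    tries = 0
    while sum(1 for s in site_defs if s[3] is None) < n_null_sites and tries < 500:
        tries += 1
        arm = arm_ids[int(rng.integers(len(arm_ids)))]
        seq = catalogue.arm_sequence(arm)
        off = int(rng.integers(len(seq)))
        ext = off + _arm_shift(catalogue, arm)
        if (arm, ext) in planted or ext >= len(mature.sequences[arm]):
            continue
        planted.add((arm, ext))
        site_defs.append((arm, ext, seq[off], None))

    sites = [(rna, ext, ref) for rna, ext, ref, _ in site_defs]
    pile = variants.build_pileup(pileup_read_stacks(quant), sites)

    last_bases = set()
    for arm_id, (hp, start, end) in catalogue.arms.items():
        last_bases.add((arm_id, _arm_shift(catalogue, arm_id)
                        + (end - start) - 1))
    candidates, artefact_sites = variants.filter_sites(pile, last_bases)

    dna, dna_samples = simulate_dna_pileups(
        quant.cohort, cfg, n_dna_samples=max(
            2, int(dna_fraction * len(quant.cohort.samples))))
    truth_key = {(r, o): key for r, o, _, key in site_defs}
    calls = []
    for site in candidates:
        key = truth_key.get((site.rna_id, site.offset))
        call = variants.classify_site(site, dna.get(key) if key else {})
        calls.append((call, key))
    artefacts = []
    for site in artefact_sites:
        key = truth_key.get((site.rna_id, site.offset))
        call = variants.classify_site(site, dna.get(key) if key else {})
        call.kind = "artefact"
        artefacts.append((call, key))
    return calls, artefacts, candidates


def expression_matrix(quant: QuantResult, min_total: float | None = None,
                      min_single: float | None = None,
                      min_sample_reads: float | None = None):
    """Filter, size-factor normalise and log-transform the count matrix.

    Thresholds default to the study values scaled by the ratio of the
    simulated mean depth to the study's per-sample read yield.
    """
    from . import normalise
    scale = quant.cfg.read_depth_mean / 2_300_000
    if min_total is None:
        min_total = max(10.0, 1000 * scale)
    if min_single is None:
        min_single = max(2.0, 100 * scale)
    if min_sample_reads is None:
        min_sample_reads = 500_000 * scale
    filtered = align.filter_matrix(quant.counts, min_total, min_single,
                                   min_sample_reads)
    s = normalise.size_factors(filtered)
    expr = normalise.log_normalise(filtered, s)
    return filtered, s, expr
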