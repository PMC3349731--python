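"""RNA-level variant and A-to-I editing calls from read pileups.

Per-site, per-sample allele counts are built from transcript-space
alignments.  Candidate sites must be informative in at least 20 samples,
have at least one sample with at least 10 observed alleles (read depth), and
at least one sample with at least 20% non-reference reads.  A site is
classified against DNA pileups available for a subset of samples: a DNA
polymorphism needs at least five DNA reads supporting the non-reference
allele in some sample; an A-to-I edit requires reference A, no more than two
DNA reads with a G anywhere, and both A and G observed in at least 90% of the
RNA-informative samples.  Variants at the last base of a mature product are
flagged as likely degradation artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

BASES = ("A", "C", "G", "T", "N")

MIN_INFORMATIVE_SAMPLES = 20
MIN_SAMPLE_DEPTH = 10
MIN_NONREF_FRACTION = 0.20
MIN_DNA_ALT_READS = 5
MAX_DNA_G_READS = 2
MIN_EDIT_SAMPLE_FRACTION = 0.90


@dataclass
class PileupSite:
    """Per-sample allele counts at one transcript position."""

    rna_id: str
    offset: int                      # 0-based within the transcript
    ref: str
    counts: dict[str, np.ndarray] = field(default_factory=dict)
    # counts[sample] is a length-5 array over BASES

    def depth(self, sample: str) -> int:
        return int(self.counts[sample][:4].sum())

    def informative_samples(self) -> list[str]:
        return [s for s, c in self.counts.items() if c[:4].sum() > 0]

    def nonref_fraction(self, sample: str) -> float:
        c = self.counts[sample]
        d = c[:4].sum()
        if d == 0:
            return 0.0
        ref_i = BASES.index(self.ref)
        return float((d - c[ref_i]) / d)

    def derived_allele(self) -> str | None:
        """Most frequent non-reference base across all samples."""
        total = np.zeros(4)
        for c in self.counts.values():
            total += c[:4]
        ref_i = BASES.index(self.ref)
        total[ref_i] = -1
        if total.max() <= 0:
            return None
        return BASES[int(np.argmax(total))]


def build_pileup(read_stacks, sites) -> list[PileupSite]:
    """Tally per-sample allele counts at requested transcript sites.

    ``read_stacks`` yields ``(sample, rna_id, start, read_seq, skip)`` for
    each aligned read in transcript coordinates; ``skip`` is a set of read
    positions adjacent to an indel to exclude from the pileup (may be empty).
    ``sites`` is a list of ``(rna_id, offset, ref_base)``.
    """
    table: dict[tuple[str, int], PileupSite] = {}
    for rna_id, offset, ref in sites:
        table[(rna_id, offset)] = PileupSite(rna_id, offset, ref)
    for sample, rna_id, start, read_seq, skip in read_stacks:
        for j, base in enumerate(read_seq):
            pos = start + j
            if skip and j in skip:
                continue
            site = table.get((rna_id, pos))
            if site is None:
                continue
            counts = site.counts.get(sample)
            if counts is None:
                counts = site.counts.setdefault(sample, np.zeros(5, dtype=np.int64))
            if base in BASES:
                counts[BASES.index(base)] += 1
    return list(table.values())


def filter_sites(pileup: list[PileupSite], mature_last_bases=None
                 ) -> tuple[list[PileupSite], list[PileupSite]]:
    """Apply the site filters; return (candidates, artefacts).

    ``mature_last_bases`` is an optional set of ``(rna_id, offset)`` marking
    the final base of each mature product; qualifying variants there are
    returned as artefacts instead of candidates.
    """
    mature_last_bases = mature_last_bases or set()
    candidates, artefacts = [], []
    for site in pileup:
        informative = site.informative_samples()
        if len(informative) < MIN_INFORMATIVE_SAMPLES:
            continue
        if not any(site.depth(s) >= MIN_SAMPLE_DEPTH for s in informative):
            continue
        if not any(site.nonref_fraction(s) >= MIN_NONREF_FRACTION
                   for s in informative):
            continue
        if (site.rna_id, site.offset) in mature_last_bases:
            artefacts.append(site)
        else:
            candidates.append(site)
    return candidates, artefacts


@dataclass
class VariantCall:
    rna_id: str
    offset: int
    ref: str
    derived: str | None
    kind: str                        # polymorphism / editing / artefact / unresolved
    n_informative: int
    derived_sample_count: int
    derived_read_fraction: float

    def as_row(self) -> dict:
        return {
            "rna_id": self.rna_id, "position": self.offset, "ref": self.ref,
            "derived_allele": self.derived, "type": self.kind,
            "n_informative_samples": self.n_informative,
            "derived_allele_frequency": (self.derived_sample_count
                                         / max(1, self.n_informative)),
            "derived_read_fraction": self.derived_read_fraction,
        }


def classify_site(site: PileupSite, dna_pileup: dict[str, np.ndarray] | None
                  ) -> VariantCall:
    """Classify a filtered site against DNA evidence.

    ``dna_pileup`` maps sample -> length-4 DNA allele counts over ACGT for
    the samples with DNA available; None or empty means no DNA anywhere, in
    which case the site stays unresolved (never editing).
    """
    derived = site.derived_allele()
    informative = site.informative_samples()
    ref_i = BASES.index(site.ref)
    der_i = BASES.index(derived) if derived else None
    der_samples = sum(1 for s in informative
                      if der_i is not None and site.counts[s][der_i] > 0)
    total = np.zeros(4)
    for s in informative:
        total += site.counts[s][:4]
    der_frac = float(total[der_i] / total.sum()) if der_i is not None else 0.0
    call = VariantCall(site.rna_id, site.offset, site.ref, derived,
                       "unresolved", len(informative), der_samples, der_frac)
    if derived is None:
        return call
    if dna_pileup:
        if any(c[der_i] >= MIN_DNA_ALT_READS for c in dna_pileup.values()):
            call.kind = "polymorphism"
            return call
        if site.ref == "A" and derived == "G":
            g_ok = all(c[BASES.index("G")] <= MAX_DNA_G_READS
                       for c in dna_pileup.values())
            both_seen = sum(
                1 for s in informative
                if site.counts[s][BASES.index("A")] > 0
                and site.counts[s][BASES.index("G")] > 0)
            if (g_ok and informative
                    and both_seen >= MIN_EDIT_SAMPLE_FRACTION * len(informative)):
                call.kind = "editing"
    return call


def end_modification_scan(aligned_reads, references: dict[str, str]) -> pd.DataFrame:
    """Catalogue non-genomic terminal bases of mapped reads.

    ``aligned_reads`` yields ``(sample, rna_id, offset, read_seq)`` for
    ungapped transcript-space alignments.  For each RNA and end (5'/3'), the
    contiguous run of terminal bases mismatching the reference is tallied;
    the table reports the per-library frequency's median and the number of
    libraries the modification was seen in.
    """
    # (rna, end, modification sequence) -> {sample: [modified, total]}
    tallies: dict[tuple, dict[str, list[int]]] = {}
    totals: dict[tuple[str, str], dict[str, int]] = {}
    for sample, rna_id, offset, read_seq in aligned_reads:
        ref = references.get(rna_id)
        if ref is None or offset + len(read_seq) > len(ref):
            continue
        window = ref[offset:offset + len(read_seq)]
        for end in ("5p", "3p"):
            totals.setdefault((rna_id, end), {}).setdefault(sample, 0)
            totals[(rna_id, end)][sample] += 1
            if end == "5p":
                run = _mismatch_run(read_seq, window)
            else:
                run = _mismatch_run(read_seq[::-1], window[::-1])[::-1]
            if run:
                key = (rna_id, end, run)
                tallies.setdefault(key, {}).setdefault(sample, 0)
                tallies[key][sample] += 1
    rows = []
    for (rna_id, end, run), per_sample in tallies.items():
        freqs = [per_sample[s] / totals[(rna_id, end)][s] for s in per_sample]
        rows.append({
            "rna_id": rna_id, "end": end, "modification": run,
            "n_libraries": len(per_sample),
            "median_frequency": float(np.median(freqs)),
        })
    return pd.DataFrame(rows, columns=["rna_id", "end", "modification",
                                       "n_libraries", "median_frequency"])


def _mismatch_run(seq: str, ref: str, max_run: int = 3) -> str:
    run = []
    for a, b in zip(seq, ref):
        if a != b and len(run) < max_run:
            run.append(a)
        else:
            break
    return "".join(run)


def expected_discovery(sites, n_samples: int,
                       min_alt_reads: int = MIN_SAMPLE_DEPTH) -> float:
    """Expected number of DNA variant sites discoverable from RNA reads.

    ``sites`` yields ``(maf, depth)`` with ``depth`` the expected per-sample
    read depth at the site.  A site is discovered if at least one sample
    carries the alternate allele and shows it on at least ``min_alt_reads``
    reads; the alternate read count is binomial given the carrier genotype
    (expected alt fraction 0.5 for heterozygotes, 1 for homozygotes) under
    Hardy-Weinberg genotype frequencies.
    """
    total = 0.0
    for maf, depth in sites:
        if maf <= 0 or depth <= 0:
            continue
        p_het = 2 * maf * (1 - maf)
        p_hom = maf * maf
        d = int(round(depth))
        p_det = (p_het * float(stats.binom.sf(min_alt_reads - 1, d, 0.5))
                 + p_hom * float(stats.binom.sf(min_alt_reads - 1, d, 1.0)))
        total += 1.0 - (1.0 - p_det) ** n_samples
    return total
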