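"""Build the five prioritised reference strata used for read mapping.

The strata, in decreasing priority, are: kit contaminants (adapters, linkers
and their single-nucleotide neighbourhoods), extended mature/star miRNA
sequences, other ncRNA (including full hairpins), ncRNA pseudogenes, and the
genome backbone.  Known variant positions are written as IUPAC ambiguity
codes so that reads carrying either allele map without penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .iupac import ambiguity_code, CODE_TO_BASES

STRATUM_RANKS = {
    "contaminant": 0,
    "mature_mirna": 1,
    "ncrna": 2,
    "pseudogene": 3,
    "genome": 4,
}

#: bases added to each mature/star arm from the enclosing hairpin
MATURE_EXT_5P = 3
MATURE_EXT_3P = 5


@dataclass
class ReferenceStratum:
    """One prioritised reference sequence set.

    ``sequences`` maps sequence id to an IUPAC string; ``coord_map`` maps a
    sequence id to its genomic placements as ``(chrom, start, end, strand)``
    tuples (0-based half-open).  An id may have several placements.
    """

    name: str
    sequences: dict[str, str] = field(default_factory=dict)
    coord_map: dict[str, list[tuple[str, int, int, str]]] = field(default_factory=dict)

    @property
    def rank(self) -> int:
        return STRATUM_RANKS[self.name]


@dataclass(frozen=True)
class VariantSite:
    seq_id: str
    offset: int           # 0-based within the sequence
    ref: str
    alts: tuple[str, ...]
    maf: float


def enumerate_contaminants(adapters, linkers=(), tags=()) -> set[str]:
    """Kit-derived contaminant sequences plus their single-edit neighbourhood.

    The base set contains every adapter and linker, every adapter+linker
    concatenation, and every adapter+tag / tag+adapter combination.  For each
    base sequence all single substitutions, single insertions and single
    deletions are added, deduplicated.
    """
    adapters = list(adapters)
    linkers = list(linkers)
    tags = list(tags)
    if not (adapters or linkers):
        raise ValueError("need at least one adapter or linker sequence")
    bases: set[str] = set(adapters) | set(linkers)
    for a in adapters:
        for l in linkers:
            bases.add(a + l)
        for t in tags:
            bases.add(a + t)
            bases.add(t + a)
    out: set[str] = set()
    for s in bases:
        out |= _edit1_neighbourhood(s)
    return out


def _edit1_neighbourhood(s: str) -> set[str]:
    out = {s}
    for i in range(len(s)):
        for b in "ACGT":
            if b != s[i]:
                out.add(s[:i] + b + s[i + 1:])
        out.add(s[:i] + s[i + 1:])                      # deletion
    for i in range(len(s) + 1):
        for b in "ACGT":
            out.add(s[:i] + b + s[i:])                  # insertion
    return out


def extend_mature(hairpin: str, start: int, end: int) -> tuple[str, int, int]:
    """Extend a mature/star interval by up to 3 bases 5' and 5 bases 3'.

    Extension is truncated at the hairpin boundaries.  Returns the extended
    sequence and its interval within the hairpin (0-based half-open).
    """
    if not (0 <= start < end <= len(hairpin)):
        raise ValueError("mature interval outside hairpin")
    new_start = max(0, start - MATURE_EXT_5P)
    new_end = min(len(hairpin), end + MATURE_EXT_3P)
    return hairpin[new_start:new_end], new_start, new_end


def inject_ambiguity(sequence: str, sites) -> str:
    """Replace each variant position with the minimal covering IUPAC code."""
    seq = list(sequence)
    for site in sites:
        if not (0 <= site.offset < len(seq)):
            raise ValueError(f"variant offset {site.offset} outside sequence")
        ref = seq[site.offset].upper()
        if ref not in "ACGT":
            ref_bases = CODE_TO_BASES[ref]
        else:
            ref_bases = {ref}
        if site.ref not in ref_bases:
            raise ValueError(
                f"variant ref {site.ref} does not match sequence base {ref} "
                f"at offset {site.offset}")
        alleles = set(site.alts) | {site.ref}
        if alleles == {site.ref}:
            raise ValueError("alt allele equals ref")
        seq[site.offset] = ambiguity_code(alleles | ref_bases)
    return "".join(seq)


def build_references(catalogue, variants, kit_sequences) -> dict[str, ReferenceStratum]:
    """Assemble the five strata from a reference catalogue.

    ``catalogue`` must expose ``hairpins`` (id -> sequence), ``arms``
    (id -> (hairpin id, start, end)) for mature and star products, ``ncrna``,
    ``pseudogenes`` (id -> sequence), ``genome`` (chrom -> sequence) and
    ``placements`` (sequence id -> list of (chrom, start, end, strand)).
    ``variants`` is a list of VariantSite in *genome* or transcript space,
    keyed by the id of the sequence they fall in.  ``kit_sequences`` is a
    mapping with keys ``adapters``, ``linkers``, ``tags``.
    """
    by_seq: dict[str, list[VariantSite]] = {}
    for v in variants:
        by_seq.setdefault(v.seq_id, []).append(v)

    def with_variants(seq_id: str, seq: str) -> str:
        sites = by_seq.get(seq_id, [])
        return inject_ambiguity(seq, sites) if sites else seq

    contaminant = ReferenceStratum("contaminant")
    cont = enumerate_contaminants(kit_sequences.get("adapters", ()),
                                  kit_sequences.get("linkers", ()),
                                  kit_sequences.get("tags", ()))
    contaminant.sequences = {f"contam_{i}": s
                             for i, s in enumerate(sorted(cont))}

    mature = ReferenceStratum("mature_mirna")
    for arm_id, (hp_id, start, end) in catalogue.arms.items():
        hairpin = with_variants(hp_id, catalogue.hairpins[hp_id])
        seq, ext_start, ext_end = extend_mature(hairpin, start, end)
        mature.sequences[arm_id] = seq
        placements = []
        for chrom, hstart, hend, strand in catalogue.placements.get(hp_id, []):
            if strand == "+":
                placements.append((chrom, hstart + ext_start, hstart + ext_end, strand))
            else:
                placements.append((chrom, hend - ext_end, hend - ext_start, strand))
        mature.coord_map[arm_id] = placements

    ncrna = ReferenceStratum("ncrna")
    for rid, seq in catalogue.ncrna.items():
        ncrna.sequences[rid] = with_variants(rid, seq)
        ncrna.coord_map[rid] = list(catalogue.placements.get(rid, []))
    for hp_id, seq in catalogue.hairpins.items():        # full hairpins too
        ncrna.sequences[hp_id] = with_variants(hp_id, seq)
        ncrna.coord_map[hp_id] = list(catalogue.placements.get(hp_id, []))

    pseudo = ReferenceStratum("pseudogene")
    for rid, seq in catalogue.pseudogenes.items():
        pseudo.sequences[rid] = with_variants(rid, seq)
        pseudo.coord_map[rid] = list(catalogue.placements.get(rid, []))

    genome = ReferenceStratum("genome")
    for chrom, seq in catalogue.genome.items():
        genome.sequences[chrom] = with_variants(chrom, seq)
        genome.coord_map[chrom] = [(chrom, 0, len(seq), "+")]

    return {s.name: s for s in (contaminant, mature, ncrna, pseudo, genome)}
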