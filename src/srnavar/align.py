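"""Ambiguity-aware read alignment against prioritised reference strata.

Two independent matchers honour the same contract — report *every* location
where a read aligns with at most ``max_sub`` substitutions and at most
``max_gap`` single-base internal gaps:

* :class:`ExhaustiveMatcher` enumerates all window starts of all stratum
  sequences with a shifted-accumulation formulation of the mismatch count
  over the three alignment shapes (ungapped, one deletion, one insertion);
  it is the exhaustive oracle.
* :class:`HeuristicMatcher` is pigeonhole-seeded: the read is split into four
  disjoint blocks, at least one of which must match the reference exactly
  for any in-budget alignment, and exact block hits from a k-mer index
  propose candidate window starts that are then verified.

A read base matches a reference IUPAC symbol iff it is in the symbol's allele
set; ``N`` in a read matches nothing and always counts as a substitution.
The genome stratum is searched on both strands (by aligning the
reverse-complemented read forward), transcript strata forward only.

Downstream: reads are retained for quantification only when both matchers
agree on all aligned locations (consensus); any contaminant hit excludes a
read; otherwise the highest-priority stratum with hits wins, only its
minimum-edit-distance locations are kept, and each of the k winning targets
receives a fractional count of 1/k.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .iupac import encode_read, encode_ref, revcomp_masks
from .references import ReferenceStratum, STRATUM_RANKS

MAX_SUB = 2
MAX_GAP = 1
MIN_READ_LEN = 16
_SEP = 8   # zero-mask separator between concatenated sequences

CONTAMINANT = "CONTAMINANT"
UNMAPPED = "UNMAPPED"


@dataclass(frozen=True, order=True)
class Alignment:
    stratum: str
    target: str
    offset: int          # 0-based window start in forward target coordinates
    strand: str          # '+' or '-'
    distance: int        # substitutions + gaps

    @property
    def location(self) -> tuple[str, str, int, str]:
        return (self.stratum, self.target, self.offset, self.strand)


class _ConcatRef:
    """A stratum's sequences packed into one mask array with zero separators."""

    def __init__(self, stratum: ReferenceStratum):
        self.name = stratum.name
        self.ids = list(stratum.sequences)
        chunks, starts, ends = [np.zeros(_SEP, dtype=np.uint8)], [], []
        pos = _SEP
        for sid in self.ids:
            seq = stratum.sequences[sid]
            starts.append(pos)
            ends.append(pos + len(seq))
            chunks.append(encode_ref(seq))
            chunks.append(np.zeros(_SEP, dtype=np.uint8))
            pos += len(seq) + _SEP
        self.masks = (np.concatenate(chunks) if self.ids
                      else np.zeros(0, dtype=np.uint8))
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        self._kmer_cache: dict[int, dict] = {}
        self._mismatch_cache: dict[int, np.ndarray] = {}

    def mismatch_track(self, mask: int) -> np.ndarray:
        """int8 indicator of positions whose reference symbol does NOT admit
        the given read-base mask (shared by both strands and all reads)."""
        track = self._mismatch_cache.get(mask)
        if track is None:
            track = ((self.masks & mask) == 0).astype(np.int8)
            self._mismatch_cache[mask] = track
        return track

    def seq_index(self, offset: int) -> int:
        return int(np.searchsorted(self.starts, offset, side="right")) - 1

    def window_ok(self, offset: int, wlen: int) -> bool:
        i = self.seq_index(offset)
        return (i >= 0 and offset >= self.starts[i]
                and offset + wlen <= self.ends[i])

    def kmer_index(self, k: int):
        """Exact k-mer -> sorted position array, IUPAC windows expanded."""
        if k in self._kmer_cache:
            return self._kmer_cache[k]
        masks = self.masks
        n_win = len(masks) - k + 1
        pos_by_code: dict[int, np.ndarray] = {}
        extra: dict[int, list[int]] = {}
        if n_win > 0:
            codes = np.full(len(masks), -1, dtype=np.int64)
            for code, mask in enumerate((1, 2, 4, 8)):  # A, C, G, T
                codes[masks == mask] = code
            valid = codes >= 0
            win_valid = np.ones(n_win, dtype=bool)
            win_code = np.zeros(n_win, dtype=np.int64)
            for j in range(k):
                win_valid &= valid[j:j + n_win]
                win_code = win_code * 4 + np.clip(codes[j:j + n_win], 0, 3)
            # windows must stay inside a single sequence
            idx = np.searchsorted(self.starts, np.arange(n_win), side="right") - 1
            inb = (idx >= 0) & (np.arange(n_win) + k <= self.ends[np.clip(idx, 0, None)])
            ok = np.flatnonzero(win_valid & inb)
            order = ok[np.argsort(win_code[ok], kind="stable")]
            sorted_codes = win_code[order]
            uniq, first = np.unique(sorted_codes, return_index=True)
            bounds = np.append(first, len(order))
            for i, code in enumerate(uniq):
                pos_by_code[int(code)] = order[bounds[i]:bounds[i + 1]]
            # windows containing an ambiguity code: enumerate concrete words
            amb = np.flatnonzero((masks != 0) & ~valid)
            seen: set[int] = set()
            for p in amb:
                for start in range(max(0, p - k + 1), min(p + 1, n_win)):
                    if start in seen:
                        continue
                    seen.add(start)
                    if not self.window_ok(start, k):
                        continue
                    window = masks[start:start + k]
                    if np.any(window == 0):
                        continue
                    choices = [[b for b in range(4) if window[j] & (1 << b)]
                               for j in range(k)]
                    for combo in product(*choices):
                        code = 0
                        for c in combo:
                            code = code * 4 + c
                        extra.setdefault(code, []).append(start)
        if extra:
            for code, positions in extra.items():
                prev = pos_by_code.get(code, np.zeros(0, dtype=np.int64))
                pos_by_code[code] = np.unique(
                    np.concatenate([prev, np.asarray(positions, dtype=np.int64)]))
        self._kmer_cache[k] = pos_by_code
        return pos_by_code


def _finalise(concat: _ConcatRef, query: np.ndarray, cand: np.ndarray,
              strand: str, max_sub: int, max_gap: int) -> list[Alignment]:
    """Validate candidate window starts against sequence bounds and emit
    the minimum bounded distance per start (vectorised over candidates)."""
    if len(cand) == 0:
        return []
    masks = concat.masks
    m = len(query)
    L = len(masks)
    cand = cand[(cand >= 0) & (cand + m + 1 <= L)]
    if len(cand) == 0:
        return []
    seqidx = np.searchsorted(concat.starts, cand, side="right") - 1
    inside = seqidx >= 0
    sstart = concat.starts[np.clip(seqidx, 0, None)]
    send = concat.ends[np.clip(seqidx, 0, None)]
    inside &= cand >= sstart
    best = np.full(len(cand), 127, dtype=np.int16)

    ok = inside & (cand + m <= send)
    if ok.any():
        W = masks[cand[ok, None] + np.arange(m)]
        ng = ((W & query) == 0).sum(axis=1)
        best[ok] = np.where(ng <= max_sub, ng, 127)
    if max_gap >= 1:
        okd = inside & (cand + m + 1 <= send)
        if okd.any():
            W = masks[cand[okd, None] + np.arange(m + 1)]
            c0 = np.cumsum((W[:, :m] & query) == 0, axis=1, dtype=np.int16)
            c1 = np.cumsum((W[:, 1:] & query) == 0, axis=1, dtype=np.int16)
            subs = c0[:, :m - 1] + (c1[:, -1:] - c1[:, :m - 1])
            dmin = subs.min(axis=1)
            val = np.where(dmin <= max_sub, dmin + 1, 127).astype(np.int16)
            best[okd] = np.minimum(best[okd], val)
        oki = inside & (cand + m - 1 <= send) if m >= 3 else np.zeros(len(cand), bool)
        if oki.any():
            W = masks[cand[oki, None] + np.arange(m - 1)]
            cA = np.cumsum((W & query[:m - 1]) == 0, axis=1, dtype=np.int16)
            cB = np.cumsum((W & query[1:]) == 0, axis=1, dtype=np.int16)
            subs = cA[:, :m - 2] + (cB[:, -1:] - cB[:, :m - 2])
            dmin = subs.min(axis=1)
            val = np.where(dmin <= max_sub, dmin + 1, 127).astype(np.int16)
            best[oki] = np.minimum(best[oki], val)
    hit = best <= max_sub + max_gap
    out = []
    for o, i, d in zip(cand[hit], seqidx[hit], best[hit]):
        out.append(Alignment(concat.name, concat.ids[int(i)],
                             int(o - concat.starts[int(i)]), strand, int(d)))
    return out


class ExhaustiveMatcher:
    """All-offsets matcher over every stratum sequence."""

    def __init__(self, strata, max_sub: int = MAX_SUB, max_gap: int = MAX_GAP):
        if isinstance(strata, ReferenceStratum):
            strata = {strata.name: strata}
        self.max_sub = max_sub
        self.max_gap = max_gap
        self.concats = {name: _ConcatRef(s) for name, s in strata.items()}

    def map_read(self, seq: str) -> list[Alignment]:
        if len(seq) < MIN_READ_LEN:
            return []
        rb = encode_read(seq)
        out: list[Alignment] = []
        for name, concat in self.concats.items():
            strands = ("+", "-") if name == "genome" else ("+",)
            for strand in strands:
                query = rb if strand == "+" else revcomp_masks(rb)
                cand = self._scan(concat, query)
                out.extend(_finalise(concat, query, cand, strand,
                                     self.max_sub, self.max_gap))
        return sorted(out)

    def _scan(self, concat: _ConcatRef, query: np.ndarray) -> np.ndarray:
        """Window starts whose unbounded edit distance is within budget.

        Shifted accumulation over the three shapes; the ungapped mismatch
        profile is reused for the insertion shape
        (``sum_{j>=1} X_j[o+j-1] = ng[o-1] - X_0[o-1]``, valid because a
        leading separator keeps o >= 1 for every real window).
        """
        m = len(query)
        L = len(concat.masks)
        n = L - m - 1           # room for the widest (deletion) window
        if n <= 0:
            return np.zeros(0, dtype=np.int64)
        X = [concat.mismatch_track(int(b)) for b in query]
        n_ng = L - m + 1
        ngfull = np.zeros(n_ng, dtype=np.int8)
        for j in range(m):
            ngfull += X[j][j:j + n_ng]
        n = min(n, n_ng)
        within = ngfull[:n] <= self.max_sub
        if self.max_gap >= 1:
            nd = min(n, L - m)
            pref = np.zeros(nd, dtype=np.int8)
            mind = np.full(nd, 127, dtype=np.int8)
            for j in range(m - 1):
                pref += X[j][j:j + nd]
                pref -= X[j][j + 1:j + 1 + nd]
                np.minimum(mind, pref, out=mind)
            within[:nd] |= (ngfull[1:1 + nd] + mind) <= self.max_sub
            if m >= 3:
                # arrays indexed by i = o - 1 (leading separator keeps the
                # first real window at o >= 1):
                # ngs[i] = sum_{j>=1} X_j[(i+1)+j-1] = ng[i] - X_0[i]
                ngs = ngfull[0:nd] - X[0][0:nd]
                pref = np.zeros(nd, dtype=np.int8)
                mine = np.full(nd, 127, dtype=np.int8)
                for g in range(1, m - 1):
                    pref += X[g - 1][g:g + nd]
                    pref -= X[g][g:g + nd]
                    np.minimum(mine, pref, out=mine)
                ins_ok = (ngs + mine) <= self.max_sub      # offset i+1
                within[1:nd] |= ins_ok[0:nd - 1]
        return np.flatnonzero(within).astype(np.int64)


class HeuristicMatcher:
    """Pigeonhole-seeded matcher with k-mer candidate generation."""

    def __init__(self, strata, max_sub: int = MAX_SUB, max_gap: int = MAX_GAP):
        if isinstance(strata, ReferenceStratum):
            strata = {strata.name: strata}
        self.max_sub = max_sub
        self.max_gap = max_gap
        self.concats = {name: _ConcatRef(s) for name, s in strata.items()}

    def map_read(self, seq: str) -> list[Alignment]:
        if len(seq) < MIN_READ_LEN:
            return []
        rb = encode_read(seq)
        m = len(rb)
        k = m // 4
        out: list[Alignment] = []
        for name, concat in self.concats.items():
            strands = ("+", "-") if name == "genome" else ("+",)
            index = concat.kmer_index(k)
            L = len(concat.masks)
            for strand in strands:
                query = rb if strand == "+" else revcomp_masks(rb)
                cand = self._candidates(index, query, k, m, L)
                out.extend(_finalise(concat, query, cand, strand,
                                     self.max_sub, self.max_gap))
        return sorted(out)

    @staticmethod
    def _candidates(index, query: np.ndarray, k: int, m: int, L: int) -> np.ndarray:
        cand: list[np.ndarray] = []
        for b in range(4):
            s = b * k
            block = query[s:s + k]
            # a block with an N (mask 0) or ambiguous mask cannot match exactly
            if np.any(block == 0) or np.any((block & (block - 1)) != 0):
                continue
            code = 0
            for mask in block:
                code = code * 4 + (int(mask).bit_length() - 1)
            hits = index.get(code)
            if hits is None:
                continue
            base = hits - s
            for shift in (-1, 0, 1):
                cand.append(base + shift)
        if not cand:
            return np.zeros(0, dtype=np.int64)
        out = np.unique(np.concatenate(cand))
        return out[(out >= 0) & (out + m + 1 <= L)]


# ---------------------------------------------------------------------------
# operations on mapped reads


def match_iupac(read_seq: str, stratum: ReferenceStratum,
                max_sub: int = MAX_SUB, max_gap: int = MAX_GAP) -> list[Alignment]:
    """All qualifying alignments of one read against one stratum (exhaustive)."""
    return ExhaustiveMatcher(stratum, max_sub, max_gap).map_read(read_seq)


def consensus(alignments_a: list[Alignment],
              alignments_b: list[Alignment]) -> list[Alignment]:
    """Retain a read's alignments only if both matchers agree on all
    aligned locations; otherwise the read is dropped from quantification."""
    locs_a = {a.location for a in alignments_a}
    locs_b = {b.location for b in alignments_b}
    if locs_a != locs_b:
        return []
    return sorted(set(alignments_a))


def resolve_strata(alignments: list[Alignment]):
    """Resolve a read's consensus alignments to its winning locations.

    Returns ``(status, winners, k)`` where status is the winning stratum
    name, CONTAMINANT, or UNMAPPED.
    """
    if not alignments:
        return UNMAPPED, [], 0
    if any(a.stratum == "contaminant" for a in alignments):
        return CONTAMINANT, [], 0
    best_rank = min(STRATUM_RANKS[a.stratum] for a in alignments)
    in_stratum = [a for a in alignments if STRATUM_RANKS[a.stratum] == best_rank]
    dmin = min(a.distance for a in in_stratum)
    winners = sorted(a for a in in_stratum if a.distance == dmin)
    return winners[0].stratum, winners, len(winners)


def fractional_count(resolved, samples) -> pd.DataFrame:
    """RNA x sample fractional count matrix from resolved reads.

    ``resolved`` yields ``(sample, winners, k)``; each read adds 1/k to each
    of its k winning targets in its sample's column.
    """
    samples = list(samples)
    col = {s: i for i, s in enumerate(samples)}
    counts: dict[str, np.ndarray] = {}
    for sample, winners, k in resolved:
        if not winners:
            continue
        w = 1.0 / k
        j = col[sample]
        for a in winners:
            row = counts.get(a.target)
            if row is None:
                row = counts.setdefault(a.target, np.zeros(len(samples)))
            row[j] += w
    return pd.DataFrame(counts, index=samples).T.sort_index()


def call_unannotated_loci(genome_reads, min_total: float = 1000,
                          max_short_len: int = 100) -> pd.DataFrame:
    """Maximal gap-free pooled-coverage runs of genome-resolved reads.

    ``genome_reads`` yields ``(chrom, start, end, weight)`` intervals, 0-based
    half-open, pooled across samples.  Two reads sharing at least one covered
    base join the same locus.  The short subset flags loci under
    ``max_short_len`` bases carrying at least ``min_total`` read mass.
    """
    by_chrom: dict[str, list] = {}
    for chrom, start, end, weight in genome_reads:
        by_chrom.setdefault(chrom, []).append((start, end, weight))
    rows = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_start, cur_end, cur_w = ivs[0]
        for start, end, weight in ivs[1:]:
            if start < cur_end:
                cur_end = max(cur_end, end)
                cur_w += weight
            else:
                rows.append((chrom, cur_start, cur_end, cur_w))
                cur_start, cur_end, cur_w = start, end, weight
        rows.append((chrom, cur_start, cur_end, cur_w))
    loci = pd.DataFrame(rows, columns=["chrom", "start", "end", "reads"])
    loci["length"] = loci["end"] - loci["start"]
    loci["short_locus"] = ((loci["length"] < max_short_len)
                           & (loci["reads"] >= min_total))
    return loci.reset_index(drop=True)


def filter_matrix(counts: pd.DataFrame, min_total: float = 1000,
                  min_single: float = 100,
                  min_sample_reads: float = 500_000) -> pd.DataFrame:
    """Trim the count matrix: keep an RNA if its total reaches ``min_total``
    or any single sample reaches ``min_single``; keep a sample if its mapped
    total reaches ``min_sample_reads``."""
    sample_ok = counts.sum(axis=0) >= min_sample_reads
    if not sample_ok.any():
        raise ValueError("all samples fall below the mapped-read threshold")
    trimmed = counts.loc[:, sample_ok]
    rna_ok = (trimmed.sum(axis=1) >= min_total) | (trimmed.max(axis=1) >= min_single)
    return trimmed.loc[rna_ok]


def overlap_binomial_test(loci: pd.DataFrame, track, genome_length: int):
    """One-tailed binomial enrichment of loci overlapping an annotation track.

    A locus overlaps if it shares any base with a track interval; the null
    probability is the fraction of genome bases the track covers.  Returns
    ``(n_overlapping, upper-tail p)``.
    """
    if loci.empty:
        raise ValueError("empty locus set")
    merged: dict[str, list] = {}
    for chrom, start, end in sorted(track):
        ivs = merged.setdefault(chrom, [])
        if ivs and start < ivs[-1][1]:
            ivs[-1][1] = max(ivs[-1][1], end)
        else:
            ivs.append([start, end])
    covered = sum(e - s for ivs in merged.values() for s, e in ivs)
    frac = covered / genome_length
    n_overlap = 0
    for _, locus in loci.iterrows():
        ivs = merged.get(locus["chrom"], [])
        if any(s < locus["end"] and locus["start"] < e for s, e in ivs):
            n_overlap += 1
    p = float(stats.binom.sf(n_overlap - 1, len(loci), frac))
    return n_overlap, p
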