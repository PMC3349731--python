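"""Demultiplexing by six-base index tag, 3' adapter trimming, and read cleanup.

Pooled small-RNA libraries carry a six-base index tag at the 5' end of every
read, followed by the RNA insert and (for short inserts) the 3' sequencing
adapter.  Reads are assigned to a library by a fractional positional distance
between the read's first six bases and each tag (N costs 0.25 against any
base), the tag is stripped, the adapter located and removed, and a series of
cleanup filters applied.  Reads shorter than 16 bases after cleanup are
discarded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

UNASSIGNED = "UNASSIGNED"
DISCARD = None

#: distance threshold at or above which a read is left unassigned
TAG_DISTANCE_CUTOFF = 2.75
#: adapter prefix length used for the internal (stage 1) search
ADAPTER_SEED_LEN = 12
#: mismatch budget as a fraction of the alignment length
ADAPTER_MISMATCH_FRAC = 0.2
MIN_READ_LEN = 16


@dataclass
class ReadRecord:
    """A raw or processed sequencing read with tag assignment and trim log."""

    id: str
    seq: str
    qual: str
    tag: str = UNASSIGNED
    trim_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class TagSet:
    """Twelve pairwise-distinct six-base index tags."""

    tags: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.tags)) != len(self.tags):
            raise ValueError("index tags must be pairwise distinct")
        for t in self.tags:
            if len(t) != 6:
                raise ValueError(f"tag {t!r} is not six bases long")


def tag_distance(prefix: str, tag: str) -> float:
    """Positional distance between a read prefix and an index tag.

    Matching bases cost 0, N against any base costs 0.25, any other
    mismatch costs 1.
    """
    if len(prefix) != 6 or len(tag) != 6:
        raise ValueError("tag distance is defined for length-6 strings")
    d = 0.0
    for a, b in zip(prefix, tag):
        if a == b:
            continue
        d += 0.25 if (a == "N" or b == "N") else 1.0
    return d


def demultiplex(read: ReadRecord, tags: TagSet) -> ReadRecord:
    """Assign a read to its library and strip the six-base tag.

    The read is assigned to the unique minimum-distance tag when that minimum
    is below 2.75; ties for the minimum, or minima at/above the cutoff, leave
    the read UNASSIGNED (and untrimmed).
    """
    if len(read.seq) < 7:
        raise ValueError("read too short to carry a tag plus insert")
    prefix = read.seq[:6]
    dists = [tag_distance(prefix, t) for t in tags.tags]
    dmin = min(dists)
    if dmin >= TAG_DISTANCE_CUTOFF or dists.count(dmin) > 1:
        return ReadRecord(read.id, read.seq, read.qual, UNASSIGNED,
                          read.trim_log + ["demux:unassigned"])
    tag = tags.tags[dists.index(dmin)]
    return ReadRecord(read.id, read.seq[6:], read.qual[6:], tag,
                      read.trim_log + [f"demux:{tag}"])


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_adapter(read: ReadRecord, adapter3: str) -> ReadRecord:
    """Locate and remove the 3' adapter.

    Stage 1: the first 12 adapter bases are searched at every internal
    position; the leftmost hit with at most ``floor(0.2*12)`` mismatches trims
    the read from the match start.  Stage 2 (only if stage 1 found nothing):
    adapter prefixes of length L = 12 down to 1 are anchored at the read's 3'
    end and trim when mismatches are at most ``floor(0.2*L)``.
    """
    if len(adapter3) < ADAPTER_SEED_LEN:
        raise ValueError("adapter must be at least 12 bases long")
    seq = read.seq
    seed = adapter3[:ADAPTER_SEED_LEN]
    budget = int(ADAPTER_MISMATCH_FRAC * ADAPTER_SEED_LEN)
    for pos in range(len(seq) - ADAPTER_SEED_LEN + 1):
        if _mismatches(seq[pos:pos + ADAPTER_SEED_LEN], seed) <= budget:
            return ReadRecord(read.id, seq[:pos], read.qual[:pos], read.tag,
                              read.trim_log + [f"adapter:internal@{pos}"])
    for L in range(min(ADAPTER_SEED_LEN, len(seq)), 0, -1):
        if _mismatches(seq[-L:], adapter3[:L]) <= int(ADAPTER_MISMATCH_FRAC * L):
            cut = len(seq) - L
            return ReadRecord(read.id, seq[:cut], read.qual[:cut], read.tag,
                              read.trim_log + [f"adapter:anchored@{L}"])
    return read


def clean_read(read: ReadRecord) -> ReadRecord | None:
    """Apply cleanup filters in order; return the cleaned read or None.

    1. any five-base window containing at least three Ns truncates the read at
       the window's first N;
    2. an N within the last two bases truncates from that N;
    3. reads where a single base makes up >=90% of the remaining length are
       discarded (low complexity);
    4. reads shorter than 16 bases are discarded.
    """
    seq, qual, log = read.seq, read.qual, list(read.trim_log)
    for start in range(len(seq) - 4):
        window = seq[start:start + 5]
        if window.count("N") >= 3:
            cut = start + window.index("N")
            seq, qual = seq[:cut], qual[:cut]
            log.append(f"clean:n_window@{cut}")
            break
    for pos in range(max(0, len(seq) - 2), len(seq)):
        if seq[pos] == "N":
            seq, qual = seq[:pos], qual[:pos]
            log.append(f"clean:terminal_n@{pos}")
            break
    if seq and max(Counter(seq).values()) >= 0.9 * len(seq):
        return DISCARD
    if len(seq) < MIN_READ_LEN:
        return DISCARD
    return ReadRecord(read.id, seq, qual, read.tag, log)


def length_histogram(reads, lo: int = 16, hi: int = 31) -> dict[int, int]:
    """Read-length histogram over the retained size range (inclusive)."""
    hist = {L: 0 for L in range(lo, hi + 1)}
    for r in reads:
        L = len(r.seq)
        if lo <= L <= hi:
            hist[L] += 1
    return hist


def process_pool(reads, tags: TagSet, adapter3: str):
    """Demultiplex, trim and clean a pooled read iterable.

    Returns ``(clean_reads_by_tag, report)`` where the report counts reads
    in / assigned / discarded by rule.
    """
    by_tag: dict[str, list[ReadRecord]] = {t: [] for t in tags.tags}
    report = Counter()
    for read in reads:
        report["input"] += 1
        assigned = demultiplex(read, tags)
        if assigned.tag == UNASSIGNED:
            report["unassigned"] += 1
            continue
        report["assigned"] += 1
        trimmed = trim_adapter(assigned, adapter3)
        if len(trimmed.seq) < len(assigned.seq):
            report["adapter_trimmed"] += 1
        cleaned = clean_read(trimmed)
        if cleaned is DISCARD:
            report["discarded"] += 1
            continue
        report["retained"] += 1
        by_tag[cleaned.tag].append(cleaned)
    return by_tag, dict(report)
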