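"""Matcher contract, consensus, stratum resolution, counting and loci."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from srnavar import align, references
from srnavar.align import (Alignment, ExhaustiveMatcher, HeuristicMatcher,
                           call_unannotated_loci, consensus, filter_matrix,
                           fractional_count, match_iupac,
                           overlap_binomial_test, resolve_strata)
from srnavar.iupac import CODE_TO_BASES, revcomp


def python_oracle(read, stratum, max_sub=2, max_gap=1):
    """Independent per-offset enumeration of every qualifying alignment."""
    hits = set()
    strands = ("+", "-") if stratum.name == "genome" else ("+",)
    for strand in strands:
        q = read if strand == "+" else revcomp(read)
        m = len(q)

        def mism(a, refb):
            if a == "N":
                return 1
            return 0 if a in CODE_TO_BASES.get(refb, set()) else 1

        for tid, seq in stratum.sequences.items():
            L = len(seq)
            for o in range(L):
                best = None
                if o + m <= L:
                    s = sum(mism(q[j], seq[o + j]) for j in range(m))
                    if s <= max_sub:
                        best = s
                if max_gap >= 1 and o + m + 1 <= L:
                    for g in range(1, m):
                        s = (sum(mism(q[j], seq[o + j]) for j in range(g))
                             + sum(mism(q[j], seq[o + j + 1])
                                   for j in range(g, m)))
                        if s <= max_sub and (best is None or s + 1 < best):
                            best = s + 1
                if max_gap >= 1 and m >= 3 and o + m - 1 <= L:
                    for g in range(1, m - 1):
                        s = (sum(mism(q[j], seq[o + j]) for j in range(g))
                             + sum(mism(q[j], seq[o + j - 1])
                                   for j in range(g + 1, m)))
                        if s <= max_sub and (best is None or s + 1 < best):
                            best = s + 1
                if best is not None:
                    hits.add((stratum.name, tid, o, strand, best))
    return sorted(Alignment(*h) for h in hits)


@pytest.fixture(scope="module")
def iupac_stratum():
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACGT"), size=300))
    seq = seq[:40] + "R" + seq[41:90] + "Y" + seq[91:]
    return references.ReferenceStratum("ncrna", {"t1": seq, "t2": seq[50:200]})


class TestMatchIupac:
    def test_exact_substring_distance_zero(self, iupac_stratum):
        seq = iupac_stratum.sequences["t1"]
        read = seq[100:122]
        hits = match_iupac(read, iupac_stratum)
        assert any(h.target == "t1" and h.offset == 100 and h.distance == 0
                   for h in hits)

    def test_either_allele_matches_ambiguity_code(self, iupac_stratum):
        seq = iupac_stratum.sequences["t1"]
        window = seq[30:52]          # covers the R at position 40
        for allele in "AG":
            read = window[:10] + allele + window[11:]
            hits = match_iupac(read, iupac_stratum)
            assert any(h.target == "t1" and h.offset == 30 and h.distance == 0
                       for h in hits)

    def test_three_substitutions_rejected(self, iupac_stratum):
        seq = iupac_stratum.sequences["t1"]
        read = list(seq[120:142])
        for pos in (2, 9, 15):
            read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
        read = "".join(read)
        oracle = python_oracle(read, iupac_stratum)
        got = match_iupac(read, iupac_stratum)
        assert got == oracle
        assert not any(h.offset == 120 and h.target == "t1" for h in got)

    def test_read_n_counts_as_substitution(self, iupac_stratum):
        seq = iupac_stratum.sequences["t1"]
        read = "NNN" + seq[103:122]
        hits = match_iupac(read, iupac_stratum)
        assert not any(h.offset == 100 and h.target == "t1" for h in hits)

    def test_short_read_rejected(self, iupac_stratum):
        assert match_iupac("ACGTACGTACGTACG", iupac_stratum) == []


class TestMatcherEquivalence:
    def test_agreement_with_oracle_on_mutated_reads(self, iupac_stratum):
        rng = np.random.default_rng(5)
        ex = ExhaustiveMatcher({"ncrna": iupac_stratum})
        he = HeuristicMatcher({"ncrna": iupac_stratum})
        seq = iupac_stratum.sequences["t1"]
        for _ in range(60):
            m = int(rng.integers(16, 32))
            o = int(rng.integers(0, len(seq) - m))
            q = list(seq[o:o + m].replace("R", "A").replace("Y", "T"))
            for _ in range(int(rng.integers(0, 3))):
                p = int(rng.integers(m))
                q[p] = str(rng.choice(list("ACGTN")))
            if rng.random() < 0.4 and m > 18:
                p = int(rng.integers(1, m - 1))
                if rng.random() < 0.5:
                    q = q[:p] + q[p + 1:]
                else:
                    q = q[:p] + [str(rng.choice(list("ACGT")))] + q[p:]
            read = "".join(q)
            if len(read) < 16:
                continue
            oracle = python_oracle(read, iupac_stratum)
            assert ex.map_read(read) == oracle
            assert he.map_read(read) == oracle

    def test_genome_both_strands(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        genome = references.ReferenceStratum("genome", {"chr1": seq})
        ex = ExhaustiveMatcher({"genome": genome})
        he = HeuristicMatcher({"genome": genome})
        read = revcomp(seq[200:224])
        oracle = python_oracle(read, genome)
        assert any(h.strand == "-" and h.offset == 200 for h in oracle)
        assert ex.map_read(read) == oracle
        assert he.map_read(read) == oracle


class TestConsensus:
    A1 = Alignment("ncrna", "t1", 5, "+", 0)
    A2 = Alignment("ncrna", "t1", 9, "+", 2)

    def test_identical_sets_retained(self):
        assert consensus([self.A1], [self.A1]) == [self.A1]

    def test_subset_dropped(self):
        assert consensus([self.A1, self.A2], [self.A1]) == []

    def test_both_empty_unmapped(self):
        assert consensus([], []) == []


class TestResolveStrata:
    def test_stratum_priority_beats_distance(self):
        mature = Alignment("mature_mirna", "mir", 0, "+", 1)
        genome = Alignment("genome", "chr1", 100, "+", 0)
        status, winners, k = resolve_strata([mature, genome])
        assert status == "mature_mirna" and winners == [mature] and k == 1

    def test_contaminant_excludes_read(self):
        cont = Alignment("contaminant", "c1", 0, "+", 0)
        mature = Alignment("mature_mirna", "mir", 0, "+", 0)
        status, winners, k = resolve_strata([cont, mature])
        assert status == align.CONTAMINANT and winners == [] and k == 0

    def test_min_distance_within_stratum(self):
        g0 = Alignment("genome", "chr1", 10, "+", 0)
        g1 = Alignment("genome", "chr1", 50, "+", 1)
        g2 = Alignment("genome", "chr1", 90, "-", 1)
        status, winners, k = resolve_strata([g0, g1, g2])
        assert status == "genome" and winners == [g0] and k == 1

    def test_unmapped(self):
        assert resolve_strata([]) == (align.UNMAPPED, [], 0)


class TestFractionalCount:
    def test_multi_mapping_weight(self):
        a = Alignment("mature_mirna", "mirA", 0, "+", 0)
        b = Alignment("mature_mirna", "mirB", 0, "+", 0)
        counts = fractional_count([("s1", [a, b], 2), ("s1", [a], 1)],
                                  ["s1", "s2"])
        assert counts.loc["mirA", "s1"] == 1.5
        assert counts.loc["mirB", "s1"] == 0.5
        assert counts["s1"].sum() == 2.0
        assert counts["s2"].sum() == 0.0

    def test_column_total_equals_reads(self, rng):
        targets = [Alignment("ncrna", f"t{i}", 0, "+", 0) for i in range(4)]
        stream = []
        for i in range(200):
            k = int(rng.integers(1, 4))
            stream.append(("s1", targets[:k], k))
        counts = fractional_count(stream, ["s1"])
        assert counts["s1"].sum() == pytest.approx(200, abs=1e-9)


class TestUnannotatedLoci:
    def test_overlap_merges(self):
        loci = call_unannotated_loci([("c", 0, 20, 1.0), ("c", 19, 39, 1.0)])
        assert len(loci) == 1
        assert loci.iloc[0]["start"] == 0 and loci.iloc[0]["end"] == 39

    def test_gap_splits(self):
        loci = call_unannotated_loci([("c", 0, 20, 1.0), ("c", 21, 41, 1.0)])
        assert len(loci) == 2

    def test_adjacent_not_merged(self):
        # half-open [0,20) and [20,40) share no covered base
        loci = call_unannotated_loci([("c", 0, 20, 1.0), ("c", 20, 40, 1.0)])
        assert len(loci) == 2

    def test_short_subset_rule(self):
        reads = [("c", 0, 80, 600.0), ("c", 40, 80, 600.0),
                 ("d", 0, 120, 1200.0)]
        loci = call_unannotated_loci(reads)
        short = loci.set_index("chrom")["short_locus"]
        assert bool(short["c"]) is True       # 80 bp, 1200 reads
        assert bool(short["d"]) is False      # 120 bp


class TestFilterMatrix:
    def make(self, rows, samples=3):
        return pd.DataFrame(rows, columns=[f"s{i}" for i in range(samples)])

    def test_single_sample_rescue(self):
        counts = pd.DataFrame({"s1": [899.0], "s2": [100.0]}, index=["r1"])
        out = filter_matrix(counts, min_total=1000, min_single=100,
                            min_sample_reads=0)
        assert "r1" in out.index              # total 999 but one sample at 100

    def test_total_rule(self):
        counts = pd.DataFrame({"s1": [980.0], "s2": [20.0]}, index=["r1"])
        out = filter_matrix(counts, 1000, 100, 0)
        assert "r1" in out.index              # total exactly 1000

    def test_both_below_dropped(self):
        counts = pd.DataFrame({"s1": [60.0], "s2": [99.0]}, index=["r1"])
        out = filter_matrix(counts, 1000, 100, 0)
        assert "r1" not in out.index

    def test_sample_threshold(self):
        counts = pd.DataFrame({"s1": [499_999.0], "s2": [500_000.0]},
                              index=["r1"])
        out = filter_matrix(counts, 0, 0, 500_000)
        assert list(out.columns) == ["s2"]

    def test_all_samples_dropped_is_error(self):
        counts = pd.DataFrame({"s1": [10.0]}, index=["r1"])
        with pytest.raises(ValueError):
            filter_matrix(counts, 0, 0, 500_000)


class TestOverlapBinomial:
    def make_loci(self, ivs):
        df = pd.DataFrame(ivs, columns=["chrom", "start", "end"])
        return df

    def test_full_cover_p_one(self):
        loci = self.make_loci([("c", 0, 10), ("c", 50, 60)])
        n, p = overlap_binomial_test(loci, [("c", 0, 100)], 100)
        assert n == 2 and p == pytest.approx(1.0)

    def test_zero_overlaps_p_one(self):
        loci = self.make_loci([("c", 0, 10)])
        n, p = overlap_binomial_test(loci, [("c", 50, 60)], 100)
        assert n == 0 and p == pytest.approx(1.0)

    def test_exact_tail_value(self):
        # 10 loci, track covering 10% of the genome, 5 overlaps
        loci = self.make_loci(
            [("c", i * 100, i * 100 + 10) for i in range(10)])
        track = [("c", i * 100, i * 100 + 5) for i in range(5)]
        track.append(("d", 0, 75))            # pad coverage to 100/1000
        n, p = overlap_binomial_test(loci, track, 1000)
        assert n == 5
        expected = sum(stats.binom.pmf(i, 10, 0.1) for i in range(5, 11))
        assert p == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(1.635e-3, rel=1e-3)

    def test_empty_loci_rejected(self):
        with pytest.raises(ValueError):
            overlap_binomial_test(pd.DataFrame(columns=["chrom", "start", "end"]),
                                  [("c", 0, 1)], 10)
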