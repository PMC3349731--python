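"""Combined multi-length miRNA seed-enrichment score with an extreme-value null.

For a miRNA, 3'UTRs are ranked by correlation of their mRNA probe with the
miRNA (most negative first).  For each 8-mer ``s8`` ending in adenosine, four
words are tested — the middle 6-mer ``s6 = s8[1:7]``, the two constituent
7-mers ``s7_1 = s8[0:7]`` and ``s7_2 = s8[1:8]``, and ``s8`` itself.  For
each word and each leading-list size n on a grid, a one-sided hypergeometric
p-value assesses over-representation of word occurrences (counted with
overlaps) in the top-n UTRs relative to the full set.  The combined score is

    score(s8) = max_n [ -log10 p_n(s6) - log10 p_n(s7,1)
                        - log10 p_n(s7,2) - log10 p_n(s8) ]

The null for a focal miRNA's own seed score is a generalized extreme-value
distribution fitted to the scores of all adenosine-ending 8-mers.  An
optional third-order Markov composition correction rescales each word's
expected share of the top of the list before the test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import qvalues

LOG10_CAP = 320.0
DEFAULT_GRID = 20

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class SeedFamily:
    """The four seed words derived from an 8-mer ending in adenosine."""

    s8: str

    def __post_init__(self) -> None:
        if len(self.s8) != 8 or self.s8[7] != "A":
            raise ValueError("seed 8-mer must be 8 bases ending in A")

    @property
    def s6(self) -> str:
        return self.s8[1:7]

    @property
    def s7_1(self) -> str:
        return self.s8[0:7]

    @property
    def s7_2(self) -> str:
        return self.s8[1:8]

    @classmethod
    def from_mirna(cls, mature_seq: str) -> "SeedFamily":
        """Seed-complementary 8-mer for a mature miRNA: reverse complement
        of seed bases 2-8 followed by the canonical adenosine."""
        seed = mature_seq[1:8].upper().replace("U", "T")
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(seed))
        return cls(rc + "A")


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(len(arr), -1, dtype=np.int64)
    for b, c in _BASE_CODE.items():
        out[arr == ord(b)] = c
    return out


def _word_ids(codes: np.ndarray, k: int) -> np.ndarray:
    """Sliding-window word ids (overlapping); -1 where any base is not ACGT."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    ids = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        ids = ids * 4 + np.clip(codes[j:j + n], 0, 3)
        bad |= codes[j:j + n] < 0
    ids[bad] = -1
    return ids


def word_id(word: str) -> int:
    wid = 0
    for b in word.upper():
        wid = wid * 4 + _BASE_CODE[b]
    return wid


class UtrWordCounts:
    """Per-UTR overlapping occurrence counts for a subset of k-mers.

    ``wids`` restricts the table to the word ids of interest (sorted); by
    default every k-mer is kept, which is fine for k <= 7.
    """

    def __init__(self, utr_seqs: list[str], k: int,
                 wids: np.ndarray | None = None):
        self.k = k
        if wids is None:
            wids = np.arange(4 ** k, dtype=np.int64)
        self.wids = np.asarray(sorted(set(int(w) for w in wids)), dtype=np.int64)
        n_cols = len(self.wids)
        counts = np.zeros((len(utr_seqs), n_cols), dtype=np.int64)
        self.positions = np.zeros(len(utr_seqs), dtype=np.int64)
        for i, seq in enumerate(utr_seqs):
            ids = _word_ids(_encode(seq), k)
            ids = ids[ids >= 0]
            self.positions[i] = len(ids)
            if len(ids):
                col = np.searchsorted(self.wids, ids)
                ok = (col < n_cols) & (self.wids[np.clip(col, 0, n_cols - 1)] == ids)
                np.add.at(counts[i], col[ok], 1)
        self.counts = counts
        self._cum_cache: dict = {}

    def col(self, wid: int) -> int:
        c = int(np.searchsorted(self.wids, wid))
        if c >= len(self.wids) or self.wids[c] != wid:
            raise KeyError(f"word id {wid} not in count table")
        return c

    def cumulative(self, order: np.ndarray, grid_ns: np.ndarray):
        """(top-n counts per word, top-n positions, totals per word, total
        positions) for each grid n, UTRs taken in ranked ``order``."""
        key = (order.tobytes(), grid_ns.tobytes())
        if key not in self._cum_cache:
            csum = np.cumsum(self.counts[order], axis=0)
            cpos = np.cumsum(self.positions[order])
            self._cum_cache = {key: (csum[grid_ns - 1], cpos[grid_ns - 1],
                                     csum[-1], int(cpos[-1]))}
        return self._cum_cache[key]


class MarkovCorrector:
    """Third-order Markov composition correction for the word tests.

    The null draw count of a word in the top-n set is rescaled by the ratio
    of the word's probability under an order-3 Markov model estimated from
    the top-n UTRs' own 3-mer/4-mer counts to its probability under the model
    of the full set:  ``P(w) = P(w[0:3]) * prod_j P(w[j] | w[j-3:j])`` with
    conditionals taken as 4-mer / 3-mer count ratios.
    """

    def __init__(self, utr_seqs: list[str], order: int = 3):
        self.order = order
        self.c_ctx = UtrWordCounts(utr_seqs, order)        # 3-mers
        self.c_trans = UtrWordCounts(utr_seqs, order + 1)  # 4-mers

    def prob_ratio(self, words: list[str], order_idx: np.ndarray,
                   grid_ns: np.ndarray) -> np.ndarray:
        """(n_words x n_grid) ratio P_top(w) / P_all(w), 1 where undefined.

        All words must share one length.  Fully vectorised: the initial-
        context and transition factors are gathered from cumulative 3-mer
        and 4-mer count tables along the ranking.
        """
        o = self.order
        k = len(words[0])
        top3, _, tot3, _ = self.c_ctx.cumulative(order_idx, grid_ns)
        top4, _, tot4, _ = self.c_trans.cumulative(order_idx, grid_ns)
        pos3_top = top3.sum(axis=1)
        pos3_all = tot3.sum()
        c3_init = np.asarray([self.c_ctx.col(word_id(w[:o])) for w in words])
        num = top3[:, c3_init] / np.maximum(pos3_top, 1)[:, None]   # grid x words
        den = tot3[c3_init] / max(pos3_all, 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where((num > 0) & (den > 0), num / den, 1.0)
            for j in range(o, k):
                c4 = np.asarray([self.c_trans.col(word_id(w[j - o:j + 1]))
                                 for w in words])
                c3 = np.asarray([self.c_ctx.col(word_id(w[j - o:j]))
                                 for w in words])
                t_num = top4[:, c4] / np.maximum(top3[:, c3], 1)
                t_den = tot4[c4] / np.maximum(tot3[c3], 1)
                ok = (top3[:, c3] > 0) & (tot3[c3] > 0) & (t_den > 0)
                ratio *= np.where(ok, t_num / np.where(t_den > 0, t_den, 1.0),
                                  1.0)
        return ratio.T


def rank_utrs(mirna_expr, mrna_expr: pd.DataFrame) -> list:
    """Order probes by Pearson correlation to the miRNA, most negative first.

    Constant probes are dropped with a warning; ties break by stable probe
    order.  Requires at least 10 usable probes.
    """
    x = np.asarray(mirna_expr, dtype=float)
    x = x - x.mean()
    rows = mrna_expr.to_numpy(dtype=float)
    rows_c = rows - rows.mean(axis=1, keepdims=True)
    sx = np.sqrt((x * x).sum())
    sy = np.sqrt((rows_c * rows_c).sum(axis=1))
    const = sy == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant probes dropped")
    if (~const).sum() < 10 or sx == 0:
        raise ValueError("need at least 10 non-constant probes and a "
                         "non-constant miRNA profile")
    with np.errstate(invalid="ignore"):
        r = (rows_c @ x) / np.where(const, 1.0, sy) / sx
    probes = mrna_expr.index.to_numpy()
    keep = ~const
    order = np.argsort(r[keep], kind="stable")
    return list(probes[keep][order])


def _hyper_sf(kk: np.ndarray, M: int, K: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Upper-tail hypergeometric over large duplicated argument grids.

    The (k, K, N) triples repeat heavily across seeds, so the tail is
    evaluated once per unique triple.
    """
    kk = np.asarray(kk)
    K = np.broadcast_to(K, kk.shape)
    N = np.broadcast_to(N, kk.shape)
    stacked = np.stack([kk.ravel(), K.ravel(), N.ravel()], axis=1)
    uniq, inverse = np.unique(stacked, axis=0, return_inverse=True)
    vals = stats.hypergeom.sf(uniq[:, 0] - 1, M, uniq[:, 1], uniq[:, 2])
    return vals[inverse].reshape(kk.shape)


def make_grid(n_utrs: int, n_points: int = DEFAULT_GRID) -> np.ndarray:
    """Evenly spaced leading-list sizes, truncated to the list length."""
    ns = np.unique(np.linspace(1, n_utrs, min(n_points, n_utrs)
                               ).round().astype(int))
    return ns[ns >= 1]


def word_landscape(utr_counts: UtrWordCounts, order_idx: np.ndarray,
                   word: str, grid_ns: np.ndarray,
                   corrector: "MarkovCorrector | None" = None) -> np.ndarray:
    """Hypergeometric upper-tail p-values for one word along the grid.

    Universe: all overlapping word positions in the full UTR set (M); the
    word occupies K of them; the top-n UTRs draw N positions and show kk
    occurrences; ``p_n = P(X >= kk)``.  With the Markov correction the draw
    count is rescaled by the word's composition-probability ratio between
    the top set and the full set.
    """
    if len(word) != utr_counts.k:
        raise ValueError("word length does not match the count table")
    grid_ns = np.asarray(grid_ns, dtype=np.int64)
    order_idx = np.asarray(order_idx, dtype=np.int64)
    c = utr_counts.col(word_id(word))
    top_counts, top_pos, tot_counts, tot_pos = utr_counts.cumulative(
        order_idx, grid_ns)
    kk = top_counts[:, c]
    K = int(tot_counts[c])
    if corrector is not None:
        ratio = corrector.prob_ratio([word], order_idx, grid_ns)[0]
        N = np.clip(np.round(top_pos * ratio).astype(np.int64), 1, tot_pos)
    else:
        N = top_pos
    return _hyper_sf(kk, tot_pos, K, N)


def seed_score(counts_by_len: dict[int, UtrWordCounts], order_idx: np.ndarray,
               s8, grid_ns: np.ndarray,
               corrector: "MarkovCorrector | None" = None) -> float:
    """Combined score for one seed family: max over the grid of the summed
    -log10 p over the four seed words.  Monotone nonincreasing in each p."""
    fam = s8 if isinstance(s8, SeedFamily) else SeedFamily(s8)
    total = np.zeros(len(grid_ns))
    for word in (fam.s6, fam.s7_1, fam.s7_2, fam.s8):
        p = word_landscape(counts_by_len[len(word)], order_idx, word,
                           grid_ns, corrector)
        total += np.minimum(-np.log10(np.clip(p, 1e-320, 1.0)), LOG10_CAP)
    return float(total.max())


def _a_ending_seeds() -> list[str]:
    bases = "ACGT"
    out = []
    for i in range(4 ** 7):
        word = [bases[(i >> (2 * (6 - j))) & 3] for j in range(7)]
        out.append("".join(word) + "A")
    return out


def build_count_tables(utr_seqs: list[str]):
    """Count tables for word lengths 6-8, restricted to the words reachable
    from adenosine-ending 8-mers (all 6/7-mers; A-ending 8-mers)."""
    a_ids = np.arange(0, 4 ** 8, 4, dtype=np.int64)  # last base A (code 0)
    return {
        6: UtrWordCounts(utr_seqs, 6),
        7: UtrWordCounts(utr_seqs, 7),
        8: UtrWordCounts(utr_seqs, 8, wids=a_ids),
    }


def all_seed_scores(utr_seqs: list[str], ordered_probes: list,
                    probe_ids: list, grid_points: int = DEFAULT_GRID,
                    markov: bool = False,
                    counts_by_len: dict[int, UtrWordCounts] | None = None
                    ) -> pd.DataFrame:
    """Combined scores of every adenosine-ending 8-mer for one UTR ranking.

    ``utr_seqs`` is parallel to ``probe_ids``; ``ordered_probes`` is the
    ranked probe list (a subset or permutation of ``probe_ids``).  Returns a
    table (s8, score, argmax_n).
    """
    pos = {p: i for i, p in enumerate(probe_ids)}
    order_idx = np.asarray([pos[p] for p in ordered_probes], dtype=np.int64)
    grid_ns = make_grid(len(order_idx), grid_points)
    if counts_by_len is None:
        counts_by_len = build_count_tables(utr_seqs)
    seeds = _a_ending_seeds()
    n_seeds = len(seeds)
    total = np.zeros((n_seeds, len(grid_ns)))
    corrector = MarkovCorrector(utr_seqs) if markov else None
    for sl, k in (((1, 7), 6), ((0, 7), 7), ((1, 8), 7), ((0, 8), 8)):
        uc = counts_by_len[k]
        top_counts, top_pos, tot_counts, tot_pos = uc.cumulative(order_idx,
                                                                 grid_ns)
        words = [s[sl[0]:sl[1]] for s in seeds]
        cols = np.asarray([uc.col(word_id(w)) for w in words])
        kk = top_counts[:, cols].T                    # seeds x grid
        K = tot_counts[cols][:, None]
        if corrector is not None:
            uniq_words = sorted(set(words))
            ratio_u = corrector.prob_ratio(uniq_words, order_idx, grid_ns)
            lut = {w: i for i, w in enumerate(uniq_words)}
            ratio = ratio_u[[lut[w] for w in words]]
            N = np.clip(np.round(top_pos * ratio).astype(np.int64), 1, tot_pos)
        else:
            N = np.broadcast_to(top_pos, kk.shape)
        p = _hyper_sf(kk, tot_pos, K, N)
        total += np.minimum(-np.log10(np.clip(p, 1e-320, 1.0)), LOG10_CAP)
    argmax = total.argmax(axis=1)
    return pd.DataFrame({
        "s8": seeds,
        "score": total.max(axis=1),
        "argmax_n": grid_ns[argmax],
    })


def evd_test(background_scores, focal_scores: dict[str, float]) -> pd.DataFrame:
    """GEV-null p-values (and q-values) for focal miRNA seed scores.

    The null is a generalized extreme-value distribution fitted by maximum
    likelihood to the scores of all adenosine-ending 8-mers; each focal
    miRNA's p is the fitted upper tail at its own seed score.  Falls back to
    the empirical tail if the ML fit fails.
    """
    bg = np.asarray(background_scores, dtype=float)
    if bg.size < 100:
        raise ValueError("need at least 100 background scores for the null")
    try:
        shape, loc, scale = stats.genextreme.fit(bg)
        if not np.all(np.isfinite([shape, loc, scale])):
            raise RuntimeError("non-finite GEV parameters")

        def sf(x):
            return float(stats.genextreme.sf(x, shape, loc=loc, scale=scale))
    except Exception:
        warnings.warn("GEV fit failed; using empirical tail")

        def sf(x):
            return float(((bg >= x).sum() + 1) / (bg.size + 1))
    rows = [(name, score, max(sf(score), 5e-324))
            for name, score in focal_scores.items()]
    table = pd.DataFrame(rows, columns=["mirna", "score", "p"])
    table["q"] = qvalues(table["p"].to_numpy())
    return table.sort_values("p").reset_index(drop=True)
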