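"""Ranked-list k-mer enrichment landscapes and peak-based candidate calling.

Given genes ranked most-downregulated first, the landscape scans growing
leading edges (prefixes) of the list and asks, for every DNA word of
length k, whether the word is over- or under-represented among the
leading edge's 3'UTRs.  The sampling unit is the word *slot*
(``length - k + 1`` windows per UTR), so long UTRs contribute
proportionally more to the null: the leading edge's slots are treated as
a hypergeometric draw from the pooled slots of the whole corpus.

Scores are signed -log10 tail probabilities: for word w at cutoff n with
x occurrences in the leading edge, K in the corpus,

* if x exceeds its expectation: ``-log10 P(X >= x)``  (positive,
  overrepresented);
* otherwise: ``+log10 P(X <= x)``  (non-positive, underrepresented).

A miRNA whose targets crowd the top of the list produces a sharp
positive peak for its seed-match words; the maximum of the first
enrichment peak is a natural candidate-target cut-off, and genes above
it that carry at least one 6-mer seed match are the candidate targets.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, special, stats

from .io import UtrSet
from .seedmatch import MirnaRecord, has_any_6mer

__all__ = [
    "WordCountTable",
    "WordLandscape",
    "all_words",
    "word_counts",
    "landscape",
    "default_cutoffs",
    "peak_threshold",
    "candidate_targets",
]

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def all_words(k: int) -> list[str]:
    """The 4^k DNA words of length k in lexicographic (= code) order."""
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


def encode_kmers(seq: str, k: int) -> np.ndarray:
    """Base-4 integer codes of the overlapping k-mers of a DNA string."""
    arr = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        raise ValueError("sequence contains non-ACGT characters")
    if len(arr) < k:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(len(arr) - k + 1, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + arr[j : len(arr) - k + 1 + j]
    return codes


@dataclass
class WordCountTable:
    """Per-gene overlapping word counts for an ordered gene list.

    ``counts`` is a CSR matrix (genes x 4^k); ``slots[i]`` is
    ``max(len(UTR_i) - k + 1, 0)``.
    """

    k: int
    gene_ids: list[str]
    counts: sparse.csr_matrix
    slots: np.ndarray


def word_counts(utrs: UtrSet, ranked_genes: list[str], k: int) -> WordCountTable:
    """Count every k-mer in each ranked gene's UTR (overlapping).

    Genes without an annotated UTR are dropped (logged), mirroring the
    restriction of the analysis to genes with a 3'UTR sequence.
    """
    if k not in (6, 7, 8):
        raise ValueError("k must be 6, 7 or 8")
    kept = [g for g in ranked_genes if g in utrs]
    n_dropped = len(ranked_genes) - len(kept)
    if n_dropped:
        logger.info("dropping %d ranked genes without an annotated UTR", n_dropped)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    slots = np.zeros(len(kept), dtype=np.int64)
    for i, g in enumerate(kept):
        codes = encode_kmers(utrs[g].sequence, k)
        slots[i] = len(codes)
        if len(codes):
            rows.append(np.full(len(codes), i, dtype=np.int64))
            cols.append(codes)
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        mat = sparse.coo_matrix(
            (np.ones(len(r), dtype=np.int64), (r, c)), shape=(len(kept), 4**k)
        ).tocsr()
    else:
        mat = sparse.csr_matrix((len(kept), 4**k), dtype=np.int64)
    mat.sum_duplicates()
    return WordCountTable(k=k, gene_ids=kept, counts=mat, slots=slots)


@dataclass
class WordLandscape:
    """Signed -log10 significance of every word over leading-edge cutoffs."""

    k: int
    words: list[str]
    cutoffs: np.ndarray  # leading-edge sizes, in genes
    scores: np.ndarray  # words x cutoffs, signed -log10 p
    gene_order: list[str]

    @property
    def bonferroni_line(self) -> float:
        """-log10(0.05 / (n_words * n_cutoffs)) reference level."""
        return float(-np.log10(0.05 / (len(self.words) * len(self.cutoffs))))

    def word_profile(self, word: str) -> np.ndarray:
        return self.scores[self.words.index(word)]

    def mean_profile(self, words: list[str]) -> np.ndarray:
        idx = [self.words.index(w) for w in words]
        return self.scores[idx].mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=pd.Index(self.words, name="word"),
            columns=[int(c) for c in self.cutoffs],
        )


def default_cutoffs(n_genes: int, bins: int = 100) -> np.ndarray:
    """An even grid of ~``bins`` leading-edge sizes strictly inside (0, N)."""
    cuts = np.unique(np.round(np.linspace(0, n_genes, bins + 1)).astype(np.int64))
    return cuts[(cuts > 0) & (cuts < n_genes)]


def _log10_tail(x: int, M: int, K: int, m: int, upper: bool) -> float:
    """log10 of the hypergeometric tail P(X>=x) (upper) or P(X<=x),
    by log-sum-exp over the log-pmf; exact far beyond float underflow."""
    if upper:
        js = np.arange(x, min(K, m) + 1)
    else:
        js = np.arange(max(0, K + m - M), x + 1)
    if len(js) == 0:
        return -math.inf
    lp = stats.hypergeom.logpmf(js, M, K, m)
    return float(special.logsumexp(lp) / math.log(10.0))


def _hypergeom_minor_tails(
    x: np.ndarray, M: int, K: np.ndarray, m: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-entry hypergeometric tail away from the mean.

    For X ~ Hypergeom(M, K, m): where ``x`` exceeds the mean ``mK/M``
    returns P(X >= x) (``upper`` True), otherwise P(X <= x).  Summation
    runs outward from ``x`` via the pmf recurrence, vectorized with
    index compression; cost is the number of non-negligible tail terms,
    independent of scipy's parameter-dependent code paths.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    K = np.asarray(K, dtype=np.float64).ravel()
    m = np.asarray(m, dtype=np.float64).ravel()
    upper = x > m * K / M
    lo = np.maximum(0.0, K + m - M)
    hi = np.minimum(K, m)
    total = np.exp(stats.hypergeom.logpmf(x, M, K, m))
    term = total.copy()
    j = x.copy()
    active = np.nonzero(
        (total > 0) & np.where(upper, j < hi, j > lo)
    )[0]
    while active.size:
        ja, Ka, ma = j[active], K[active], m[active]
        ratio = np.where(
            upper[active],
            (Ka - ja) * (ma - ja) / ((ja + 1.0) * (M - Ka - ma + ja + 1.0)),
            ja * (M - Ka - ma + ja) / ((Ka - ja + 1.0) * (ma - ja + 1.0)),
        )
        term[active] *= ratio
        total[active] += term[active]
        j[active] += np.where(upper[active], 1.0, -1.0)
        keep = (term[active] > total[active] * 1e-17) & np.where(
            upper[active], j[active] < hi[active], j[active] > lo[active]
        )
        active = active[keep]
    return np.minimum(total, 1.0), upper


def landscape(table: WordCountTable, cutoffs: np.ndarray) -> WordLandscape:
    """Hypergeometric enrichment landscape over leading-edge cutoffs.

    For each word and cutoff the leading edge's occurrence count is
    compared with a hypergeometric draw of the leading-edge slots from
    the pooled corpus slots.  Tail probabilities are floored at 1e-300
    before taking logs.  Words absent from the corpus score 0.
    """
    cutoffs = np.asarray(cutoffs, dtype=np.int64)
    n_genes = len(table.gene_ids)
    if len(cutoffs) == 0:
        raise ValueError("empty cutoff grid")
    if (np.diff(cutoffs) <= 0).any() or cutoffs[0] <= 0 or cutoffs[-1] >= n_genes:
        raise ValueError("cutoffs must be strictly increasing within (0, N)")

    n_words = table.counts.shape[1]
    slot_cum = np.concatenate([[0], np.cumsum(table.slots)])
    total_slots = int(slot_cum[-1])
    corpus_counts = np.asarray(table.counts.sum(axis=0)).ravel().astype(np.int64)

    # leading-edge counts per word at each cutoff, by accumulating row blocks
    lead = np.zeros((len(cutoffs), n_words), dtype=np.int64)
    prev = 0
    acc = np.zeros(n_words, dtype=np.int64)
    for ci, n in enumerate(cutoffs):
        if n > prev:
            acc = acc + np.asarray(
                table.counts[prev:n].sum(axis=0)
            ).ravel().astype(np.int64)
            prev = int(n)
        lead[ci] = acc
    lead_slots = slot_cum[cutoffs]  # per cutoff

    shape = (n_words, len(cutoffs))
    x = lead.T  # words x cutoffs
    Kb = np.broadcast_to(corpus_counts[:, None], shape)
    mb = np.broadcast_to(lead_slots[None, :], shape)
    p_tail, over = _hypergeom_minor_tails(x, total_slots, Kb, mb)
    p_tail, over = p_tail.reshape(shape), over.reshape(shape)
    scores = np.where(
        over,
        -np.log10(np.maximum(p_tail, P_FLOOR)),
        np.log10(np.maximum(p_tail, P_FLOOR)),
    )
    scores[Kb == 0] = 0.0
    # extreme tails underflow the float pmf; recompute those entries in
    # log space so strongly enriched words stay strictly ordered
    tiny = (p_tail < 1e-250) & (Kb > 0)
    for wi, ci in zip(*np.nonzero(tiny)):
        lt = _log10_tail(
            int(x[wi, ci]), total_slots, int(corpus_counts[wi]),
            int(lead_slots[ci]), upper=bool(over[wi, ci]),
        )
        scores[wi, ci] = -lt if over[wi, ci] else lt
    return WordLandscape(
        k=table.k,
        words=all_words(table.k),
        cutoffs=cutoffs,
        scores=scores,
        gene_order=list(table.gene_ids),
    )


def peak_threshold(land: WordLandscape, seed_words: list[str]) -> int | None:
    """Cutoff index of the maximum of the first enrichment peak.

    The profile is the mean score of ``seed_words``; the first contiguous
    run of strictly positive values is located and the index of its
    maximum returned.  ``None`` when the profile is never positive.
    """
    if not seed_words:
        raise ValueError("seed_words must be non-empty")
    profile = land.mean_profile(seed_words)
    pos = profile > 0
    if not pos.any():
        return None
    start = int(np.argmax(pos))  # first True
    end = start
    while end < len(profile) and pos[end]:
        end += 1
    return start + int(np.argmax(profile[start:end]))


def candidate_targets(
    ranked_genes: list[str],
    threshold: int | None,
    utrs: UtrSet,
    mirna: MirnaRecord,
) -> set[str]:
    """Genes ranked above the cut-off carrying >= 1 6-mer seed match.

    ``threshold`` is a number of leading genes (e.g.
    ``land.cutoffs[peak_threshold(...)]``); ``None`` or 0 yields the
    empty set.
    """
    if not threshold:
        return set()
    leading = ranked_genes[: int(threshold)]
    return {g for g in leading if g in utrs and has_any_6mer(utrs[g], mirna)}


def seed_site_words(mirna: MirnaRecord) -> list[str]:
    """The three hexamers contained in the miRNA's UTR-side 8-mer site."""
    site = mirna.site8
    return [site[i : i + 6] for i in range(3)]
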