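"""Hexamer-composition comparison of enriched vs non-enriched 3'UTRs.

RIP experiments can pull down transcripts for reasons unrelated to
seed pairing; a tell-tale signature is a correlation between a UTR
word's GC content and its overrepresentation among IP-enriched
transcripts.  This module compares the pooled hexamer composition of an
enriched UTR set against a background set: per hexamer, normalized
frequencies in both sets, their log2 ratio (with a pseudocount), and the
Spearman correlation between log-ratio and hexamer GC fraction.  A
positive, significant correlation flags GC-driven background binding;
seed-site hexamers rising above that trend indicate genuine seed-driven
enrichment on top of it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import UtrSet
from .seedmatch import MirnaRecord
from .wordscape import all_words, encode_kmers

__all__ = [
    "HexamerComparison",
    "hexamer_profile",
    "compare_profiles",
    "seed_words_overlay",
]

logger = logging.getLogger(__name__)

K = 6
N_WORDS = 4**K

_HEXAMERS = all_words(K)
_HEX_GC = np.array([(w.count("G") + w.count("C")) / K for w in _HEXAMERS])


def hexamer_profile(utrs: UtrSet) -> np.ndarray:
    """Pooled overlapping hexamer frequencies (length 4096, sums to 1)."""
    counts = np.zeros(N_WORDS, dtype=np.int64)
    total = 0
    for utr in utrs:
        codes = encode_kmers(utr.sequence, K)
        if len(codes):
            counts += np.bincount(codes, minlength=N_WORDS)
            total += len(codes)
    if total == 0:
        raise ValueError("no UTR of length >= 6 in the set")
    return counts / total


@dataclass
class HexamerComparison:
    """Per-hexamer frequencies/log-ratios plus the GC-trend summary."""

    table: pd.DataFrame  # hexamer, gc, freq_enriched, freq_background, log_ratio
    rho: float
    p_value: float
    n_enriched: int
    n_background: int

    @property
    def gc_bias_detected(self) -> bool:
        return (not math.isnan(self.rho)) and self.rho > 0 and self.p_value < 0.01


def _pseudocount_freq(utrs: UtrSet, pseudocount: float) -> np.ndarray:
    counts = np.zeros(N_WORDS)
    for utr in utrs:
        codes = encode_kmers(utr.sequence, K)
        if len(codes):
            counts += np.bincount(codes, minlength=N_WORDS)
    counts += pseudocount
    return counts / counts.sum()


def compare_profiles(
    enriched: UtrSet,
    background: UtrSet,
    pseudocount: float = 0.5,
    mirna: MirnaRecord | None = None,
) -> HexamerComparison:
    """Contrast the hexamer composition of two UTR sets.

    A pseudocount (default 0.5 occurrences per hexamer) is added to both
    sets before normalization so every log2 ratio is finite.  The
    Spearman rho of log-ratio against hexamer GC (ties handled exactly)
    summarises GC-composition bias; ``rho`` is a NaN sentinel when the
    log-ratios are constant (e.g. identical sets).  When a miRNA is
    given, its three seed-site hexamers are flagged in the table.
    """
    if len(enriched) == 0 or len(background) == 0:
        raise ValueError("both UTR sets must be non-empty")
    shared = set(enriched.records) & set(background.records)
    if shared:
        logger.warning("enriched and background sets share %d genes", len(shared))
    freq_e = _pseudocount_freq(enriched, pseudocount)
    freq_b = _pseudocount_freq(background, pseudocount)
    log_ratio = np.log2(freq_e / freq_b)

    if np.allclose(log_ratio, log_ratio[0]):
        rho, p = math.nan, math.nan
    else:
        rho, p = stats.spearmanr(log_ratio, _HEX_GC)
        rho, p = float(rho), float(p)

    seed_hex = set(seed_words_overlay(mirna)) if mirna is not None else set()
    table = pd.DataFrame(
        {
            "hexamer": _HEXAMERS,
            "gc": _HEX_GC,
            "freq_enriched": freq_e,
            "freq_background": freq_b,
            "log_ratio": log_ratio,
            "is_seed_hexamer": [w in seed_hex for w in _HEXAMERS],
        }
    )
    return HexamerComparison(
        table=table,
        rho=rho,
        p_value=p,
        n_enriched=len(enriched),
        n_background=len(background),
    )


def seed_words_overlay(mirna: MirnaRecord | str) -> list[str]:
    """The three overlapping hexamers of the miRNA's 8-mer UTR site.

    Accepts a ``MirnaRecord`` or the 8-mer site sequence itself.
    """
    site = mirna if isinstance(mirna, str) else mirna.site8
    if len(site) != 8:
        raise ValueError(f"expected an 8-mer site, got length {len(site)}")
    return [site[i : i + 6] for i in range(3)]
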