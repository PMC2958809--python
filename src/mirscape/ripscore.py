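"""Binomial IP-vs-INPUT enrichment scoring of RIP-seq read counts.

For each gene, reads from the immunoprecipitated (IP) library and the
INPUT (total RNA) library are summarised as the IP fraction
``f = k_ip / (k_ip + k_in)``.  With balanced libraries, values near 0.5
mean the gene behaves identically in IP and INPUT; values above 0.5
suggest extra pull-down in the IP.

Differential representation is scored as the upper-tail probability
that ``k_ip`` out of ``n = k_ip + k_in`` reads came from the IP under a
binomial null with success probability ``p0``.  The default null uses
the global library proportion ``p0 = K_ip / (K_ip + K_in)`` (computed
over genes passing the read filter), which absorbs library-size
imbalance; a fixed ``p0 = 0.5`` is available as an alternative reading.

Genes are called enriched at raw ``p < alpha`` (default 0.003); no
multiple-testing correction is applied to the calls, but a BH-adjusted
column is emitted alongside for users.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ip_fraction",
    "estimate_p0",
    "binom_upper_tail",
    "score_table",
    "call_enriched",
    "fraction_cdf",
]

DEFAULT_ALPHA = 0.003
DEFAULT_MIN_READS = 10


def ip_fraction(k_ip: int, k_in: int) -> float:
    """IP read fraction k_ip/(k_ip+k_in); NaN sentinel when both are 0."""
    if k_ip < 0 or k_in < 0:
        raise ValueError("negative read count")
    n = k_ip + k_in
    if n == 0:
        return math.nan
    return k_ip / n


def estimate_p0(table: pd.DataFrame, min_reads: int = DEFAULT_MIN_READS) -> float:
    """Null IP proportion: pooled K_ip/(K_ip+K_in) over passing genes."""
    if len(table) == 0:
        raise ValueError("empty count table")
    n = table["ip_count"] + table["input_count"]
    passing = table[n >= min_reads]
    k_ip = int(passing["ip_count"].sum())
    k_in = int(passing["input_count"].sum())
    if k_ip + k_in == 0:
        raise ValueError("no reads in passing genes")
    return k_ip / (k_ip + k_in)


def binom_upper_tail(k, n, p0: float):
    """P(X >= k) for X ~ Binomial(n, p0); equals 1 at k = 0.

    Vectorized over k and n.  Uses the numerically stable regularized
    incomplete-beta tail, which is exact summation in exact arithmetic
    and accurate to ~1e-15 in floating point for any n.
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must be in (0,1), got {p0}")
    k_arr = np.asarray(k)
    n_arr = np.asarray(n)
    if (k_arr < 0).any() or (k_arr > n_arr).any():
        raise ValueError("require 0 <= k <= n")
    p = stats.binom.sf(k_arr - 1, n_arr, p0)
    p = np.minimum(p, 1.0)
    if np.isscalar(k) and np.isscalar(n):
        return float(p)
    return p


def score_table(
    table: pd.DataFrame,
    min_reads: int = DEFAULT_MIN_READS,
    p0: float | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Annotate a (gene_id, ip_count, input_count) table with the IP
    fraction, the binomial enrichment p-value, its BH adjustment, the
    read filter flag and the enrichment call.

    Low-coverage genes (n < min_reads) are flagged, not deleted: their
    ``p_enrich`` is NaN and they are never called.  ``p0=None`` estimates
    the null proportion from the data.
    """
    out = table.copy()
    k_ip = out["ip_count"].to_numpy(np.int64)
    k_in = out["input_count"].to_numpy(np.int64)
    if (k_ip < 0).any() or (k_in < 0).any():
        raise ValueError("negative read counts")
    n = k_ip + k_in
    out["n"] = n
    with np.errstate(invalid="ignore", divide="ignore"):
        out["f"] = np.where(n > 0, k_ip / np.maximum(n, 1), np.nan)
    out["pass_min_reads"] = n >= min_reads
    if p0 is None:
        p0 = estimate_p0(out, min_reads=min_reads)
    out.attrs["p0"] = p0
    mask = out["pass_min_reads"].to_numpy()
    p_enrich = np.full(len(out), np.nan)
    p_enrich[mask] = binom_upper_tail(k_ip[mask], n[mask], p0)
    out["p_enrich"] = p_enrich
    p_bh = np.full(len(out), np.nan)
    if mask.any():
        p_bh[mask] = multipletests(p_enrich[mask], method="fdr_bh")[1]
    out["p_bh"] = p_bh
    out["called"] = mask & (p_enrich < alpha)
    return out


def call_enriched(scored: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> list[str]:
    """Genes with p_enrich < alpha among passing genes, ordered by
    increasing p (ties broken by gene_id)."""
    ok = scored[scored["pass_min_reads"] & (scored["p_enrich"] < alpha)]
    ok = ok.sort_values(["p_enrich", "gene_id"], kind="mergesort")
    return list(ok["gene_id"])


def fraction_cdf(scored: pd.DataFrame) -> pd.DataFrame:
    """Empirical CDF of the IP fraction over passing genes.

    Returns a DataFrame with columns ``f`` (sorted unique fractions) and
    ``cdf`` (monotone, ending at 1); the analogue of the cumulative
    IP/(IP+INPUT) histogram used to compare transfection conditions.
    """
    f = scored.loc[scored["pass_min_reads"], "f"].dropna().sort_values().to_numpy()
    if len(f) == 0:
        raise ValueError("no passing genes")
    vals, counts = np.unique(f, return_counts=True)
    return pd.DataFrame({"f": vals, "cdf": np.cumsum(counts) / len(f)})
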