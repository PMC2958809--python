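"""miRNA seed extraction and seed-match site counting in 3'UTRs.

A metazoan miRNA recognises most of its targets through its *seed*,
nucleotides 2-8 of the mature sequence.  A target site in a 3'UTR is a
(DNA) match to the reverse complement of the seed.  Three nested site
classes are counted:

* 6-mer  -- match to the reverse complement of seed positions 2-7;
* 7-mer  -- match to the reverse complement of seed positions 2-8
  (the "7mer-m8" class);
* 8-mer  -- a 7-mer site immediately followed by an ``A`` in the UTR
  (the adenosine opposite miRNA position 1; "8mer-A1").

Every 8-mer site is a 7-mer site and every 7-mer site contains a 6-mer
site, so for any UTR/miRNA pair ``n8 <= n7 <= n6``.

Occurrences are counted with overlaps allowed, by exhaustive sliding
window over the UTR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "MirnaRecord",
    "UtrRecord",
    "SiteCounts",
    "extract_seed",
    "reverse_complement",
    "count_occurrences",
    "count_sites",
    "has_any_6mer",
]

_RNA_ALPHABET = set("ACGU")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _normalize_rna(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - _RNA_ALPHABET
    if bad:
        raise ValueError(f"non-ACGU characters in miRNA sequence: {sorted(bad)}")
    return s


def normalize_dna(seq: str) -> str:
    """Uppercase and map U->T; reject anything outside ACGTU."""
    s = seq.upper().replace("U", "T")
    for i, c in enumerate(s):
        if c not in "ACGT":
            raise ValueError(f"non-ACGTU character {c!r} at position {i}")
    return s


def extract_seed(sequence: str, start: int = 2, end: int = 8, name: str = "") -> str:
    """Return miRNA positions ``start..end`` (1-based, inclusive).

    The default ``(2, 8)`` yields the 7-nt seed; ``end=7`` yields the
    6-nt seed.  Raises ``ValueError`` (naming the miRNA if given) when
    the sequence is shorter than ``end``.
    """
    seq = _normalize_rna(sequence)
    if not 1 <= start <= end:
        raise ValueError(f"invalid seed coordinates [{start}..{end}]")
    if len(seq) < end:
        who = f" of miRNA {name!r}" if name else ""
        raise ValueError(
            f"sequence{who} has length {len(seq)} < seed end position {end}"
        )
    return seq[start - 1 : end]


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a DNA string (U accepted as T)."""
    return normalize_dna(seq).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MirnaRecord:
    """A mature miRNA: name, RNA sequence, and derived seed regions."""

    name: str
    sequence: str
    seed7: str = field(init=False)
    seed6: str = field(init=False)

    def __post_init__(self) -> None:
        seq = _normalize_rna(self.sequence)
        if not 18 <= len(seq) <= 26:
            raise ValueError(
                f"miRNA {self.name!r}: length {len(seq)} outside 18-26 nt"
            )
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "seed7", extract_seed(seq, 2, 8, self.name))
        object.__setattr__(self, "seed6", extract_seed(seq, 2, 7, self.name))

    @property
    def site7(self) -> str:
        """UTR-side 7-mer site: reverse complement of the 7-nt seed."""
        return reverse_complement(self.seed7)

    @property
    def site6(self) -> str:
        """UTR-side 6-mer site: reverse complement of the 6-nt seed."""
        return reverse_complement(self.seed6)

    @property
    def site8(self) -> str:
        """UTR-side 8-mer site: 7-mer site plus the downstream A."""
        return self.site7 + "A"


@dataclass(frozen=True)
class UtrRecord:
    """A gene's 3'UTR with length and GC-fraction metadata."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_dna(self.sequence))

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        if not self.sequence:
            return 0.0
        s = self.sequence
        return (s.count("G") + s.count("C")) / len(s)


@dataclass(frozen=True)
class SiteCounts:
    gene_id: str
    n6: int
    n7: int
    n8: int


def count_occurrences(haystack: str, needle: str) -> int:
    """Overlapping occurrence count by sliding window (``str.find`` step 1)."""
    if not needle or len(needle) > len(haystack):
        return 0
    n = 0
    i = haystack.find(needle)
    while i != -1:
        n += 1
        i = haystack.find(needle, i + 1)
    return n


def count_sites(utr: UtrRecord, mirna: MirnaRecord) -> SiteCounts:
    """Count nested 6/7/8-mer seed-match sites in a UTR (overlaps allowed)."""
    seq = utr.sequence
    n6 = count_occurrences(seq, mirna.site6)
    n7 = count_occurrences(seq, mirna.site7)
    n8 = count_occurrences(seq, mirna.site8)
    return SiteCounts(utr.gene_id, n6=n6, n7=n7, n8=n8)


def has_any_6mer(utr: UtrRecord, mirna: MirnaRecord) -> bool:
    """True iff the UTR carries at least one 6-mer seed match."""
    return count_occurrences(utr.sequence, mirna.site6) >= 1
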