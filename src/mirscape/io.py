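"""File interfaces: UTR FASTA, expression TSV + design, count tables.

All tabular interchange is tab-separated with a header row.  Gene
identifiers are taken from the first whitespace-delimited token of FASTA
headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seedmatch import SiteCounts, UtrRecord

__all__ = [
    "UtrSet",
    "ExpressionMatrix",
    "read_utr_fasta",
    "write_utr_fasta",
    "read_expression",
    "write_site_counts",
    "read_rip_counts",
]


@dataclass
class UtrSet:
    """An ordered, gene-keyed collection of 3'UTR records."""

    records: dict[str, UtrRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[UtrRecord]:
        return iter(self.records.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    def __getitem__(self, gene_id: str) -> UtrRecord:
        return self.records[gene_id]

    def add(self, utr: UtrRecord) -> None:
        if utr.gene_id in self.records:
            raise ValueError(f"duplicate gene_id {utr.gene_id!r}")
        self.records[utr.gene_id] = utr

    @property
    def gene_ids(self) -> list[str]:
        return list(self.records)

    def subset(self, gene_ids: Iterable[str]) -> "UtrSet":
        return UtrSet({g: self.records[g] for g in gene_ids})

    def metadata(self) -> pd.DataFrame:
        """Per-gene length and GC fraction."""
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "length": [u.length for u in self],
                "gc": [u.gc for u in self],
            }
        ).set_index("gene_id")


@dataclass
class ExpressionMatrix:
    """Log2 expression values (genes x samples) with a two-group design.

    ``groups`` maps each sample id to ``"treatment"`` or ``"control"``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"samples without group label: {missing}")
        labels = set(self.groups)
        if labels != {"treatment", "control"}:
            raise ValueError(f"expected groups treatment/control, got {labels}")
        counts = self.groups.value_counts()
        if (counts < 2).any():
            raise ValueError("each group needs >= 2 replicates")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene_ids in expression matrix")
        if self.values.isna().any().any():
            raise ValueError("missing values in expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def samples(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


def read_utr_fasta(path: str | Path) -> UtrSet:
    utrs = UtrSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        utrs.add(UtrRecord(gene_id=rec.id, sequence=str(rec.seq)))
    return utrs


def write_utr_fasta(utrs: UtrSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(u.sequence), id=u.gene_id, description="")
        for u in utrs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_expression(values_path: str | Path, design_path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV (first column gene_id) and a design TSV
    with columns ``sample_id`` and ``group``."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t")
    groups = design.set_index("sample_id")["group"]
    return ExpressionMatrix(values=values, groups=groups)


def write_site_counts(counts: Iterable[SiteCounts], path: str | Path) -> None:
    df = pd.DataFrame(
        [(c.gene_id, c.n6, c.n7, c.n8) for c in counts],
        columns=["gene_id", "n6", "n7", "n8"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_rip_counts(path: str | Path) -> pd.DataFrame:
    """Read a per-gene IP/INPUT count TSV (gene_id, ip_count, input_count)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "ip_count", "input_count"}
    if not required <= set(df.columns):
        raise ValueError(f"count table must have columns {sorted(required)}")
    return df
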