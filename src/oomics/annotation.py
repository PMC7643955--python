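"""Genome annotation container shared by the simulator and feature classifier."""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Dict, Optional

import numpy as np
import pandas as pd

GENE_COLUMNS = ["gene_id", "chrom", "strand", "start", "end", "tss"]
PART_COLUMNS = ["gene_id", "chrom", "start", "end"]


def _empty(columns) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object if c in ("gene_id", "chrom", "strand", "family") else np.int64) for c in columns})


@dataclass
class GenomeAnnotation:
    """Genes plus repeat/accessibility tracks on a set of chromosomes.

    ``genes``: gene_id, chrom, strand, start, end, tss — 0-based half-open
    transcript span; the TSS is ``start`` on + genes and ``end - 1`` on −
    genes. ``exons`` / ``utr5`` / ``utr3``: gene_id, chrom, start, end.
    ``repeats``: chrom, start, end, family (e.g. LINE1). ``genome`` maps
    chromosome id to its uppercase sequence (may be absent when only
    interval arithmetic is needed).
    """

    chrom_lengths: Dict[str, int]
    genes: pd.DataFrame = field(default_factory=lambda: _empty(GENE_COLUMNS))
    exons: pd.DataFrame = field(default_factory=lambda: _empty(PART_COLUMNS))
    utr5: pd.DataFrame = field(default_factory=lambda: _empty(PART_COLUMNS))
    utr3: pd.DataFrame = field(default_factory=lambda: _empty(PART_COLUMNS))
    repeats: pd.DataFrame = field(default_factory=lambda: _empty(["chrom", "start", "end", "family"]))
    accessibility: pd.DataFrame = field(default_factory=lambda: _empty(["chrom", "start", "end"]))
    genome: Optional[Dict[str, str]] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("genes", "exons", "utr5", "utr3", "repeats", "accessibility"):
            df = getattr(self, name)
            for _, row in df.iterrows():
                chrom = str(row["chrom"])
                if chrom not in self.chrom_lengths:
                    raise ValueError(f"{name}: unknown chromosome {chrom!r}")
                if not (0 <= row["start"] <= row["end"] <= self.chrom_lengths[chrom]):
                    raise ValueError(
                        f"{name}: interval [{row['start']}, {row['end']}) outside {chrom}"
                    )
        for _, g in self.genes.iterrows():
            expected_tss = g["start"] if g["strand"] == "+" else g["end"] - 1
            if g["tss"] != expected_tss:
                raise ValueError(f"gene {g['gene_id']}: TSS inconsistent with strand/span")
        if not self.exons.empty:
            spans = self.genes.set_index("gene_id")
            for _, ex in self.exons.iterrows():
                g = spans.loc[ex["gene_id"]]
                if not (g["start"] <= ex["start"] <= ex["end"] <= g["end"]):
                    raise ValueError(f"exon outside transcript span of {ex['gene_id']}")

    @cached_property
    def gene_lengths(self) -> pd.Series:
        """Union-of-exons length per gene (effective length for FPKM)."""
        if self.exons.empty:
            return pd.Series(dtype=np.int64, name="length")
        from .intervals import merge_intervals

        out = {}
        for gid, sub in self.exons.groupby("gene_id", sort=False):
            out[gid] = sum(e - s for s, e in merge_intervals(zip(sub["start"], sub["end"])))
        return pd.Series(out, name="length").loc[self.genes["gene_id"]].astype(np.int64)

    def gene_body(self, gene_id: str) -> tuple[str, int, int]:
        g = self.genes.set_index("gene_id").loc[gene_id]
        return str(g["chrom"]), int(g["start"]), int(g["end"])
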