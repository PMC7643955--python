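"""Classify regions against gene annotation and overlap them with tracks.

"Distal" follows the study definition literally: a region is distal when
it overlaps no gene promoter (−2 kb/+500 bp around the TSS, strand-aware),
no exon and no UTR. Introns therefore qualify as distal; the finer-grained
:func:`classify_feature` separates them.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation
from .intervals import GenomeIntervals, Region, merge_regions, regions_overlapping_track

PROMOTER_UPSTREAM = 2_000
PROMOTER_DOWNSTREAM = 500

FEATURE_PRIORITY = ("promoter", "utr5", "utr3", "exon", "intron", "distal")


def promoter_intervals(
    annotation: GenomeAnnotation,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> pd.DataFrame:
    """Strand-aware promoter windows around each TSS, clipped to the chromosome.

    A + gene with TSS t gets [t − upstream, t + downstream); a − gene gets
    the mirror image [t − downstream + 1, t + upstream + 1).
    """
    rows = []
    for _, g in annotation.genes.iterrows():
        t = int(g["tss"])
        if g["strand"] == "+":
            start, end = t - upstream, t + downstream
        else:
            start, end = t - downstream + 1, t + upstream + 1
        length = annotation.chrom_lengths[str(g["chrom"])]
        rows.append((g["gene_id"], g["chrom"], max(0, start), min(length, end)))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


class FeatureClassifier:
    """Reusable promoter/UTR/exon/gene-span overlap indexes for one annotation."""

    def __init__(self, annotation: GenomeAnnotation,
                 upstream: int = PROMOTER_UPSTREAM, downstream: int = PROMOTER_DOWNSTREAM):
        self.annotation = annotation
        self.promoters = GenomeIntervals(promoter_intervals(annotation, upstream, downstream))
        self.exons = GenomeIntervals(annotation.exons)
        self.utr5 = GenomeIntervals(annotation.utr5)
        self.utr3 = GenomeIntervals(annotation.utr3)
        self.gene_spans = GenomeIntervals(annotation.genes)

    def classify(self, region: Region) -> str:
        """Single label per region, priority promoter > 5'UTR > 3'UTR > exon > intron > distal."""
        chrom, start, end = region
        for label, index in (("promoter", self.promoters), ("utr5", self.utr5),
                             ("utr3", self.utr3), ("exon", self.exons)):
            if index.overlaps(chrom, start, end):
                return label
        if self.gene_spans.overlaps(chrom, start, end):
            return "intron"
        return "distal"

    def is_distal(self, region: Region) -> bool:
        """True iff the region touches no promoter, exon or UTR of any gene."""
        chrom, start, end = region
        return not (
            self.promoters.overlaps(chrom, start, end)
            or self.exons.overlaps(chrom, start, end)
            or self.utr5.overlaps(chrom, start, end)
            or self.utr3.overlaps(chrom, start, end)
        )


def classify_feature(region: Region, annotation: GenomeAnnotation) -> str:
    return FeatureClassifier(annotation).classify(region)


def is_distal(region: Region, annotation: GenomeAnnotation) -> bool:
    return FeatureClassifier(annotation).is_distal(region)


def classify_regions(regions: pd.DataFrame, annotation: GenomeAnnotation) -> pd.Series:
    """Feature label per row of a (chrom, start, end) frame."""
    clf = FeatureClassifier(annotation)
    return pd.Series(
        [clf.classify((str(c), int(s), int(e)))
         for c, s, e in zip(regions["chrom"], regions["start"], regions["end"])],
        index=regions.index, name="feature",
    )


def overlap_fraction(regions: pd.DataFrame, track: pd.DataFrame) -> float:
    """Fraction of regions with >= 1 bp overlap with any track interval.

    Invariant under merging of the track (overlap with the union is
    overlap with some member).
    """
    if len(regions) == 0:
        raise ValueError("overlap fraction undefined for an empty region list")
    hits = regions_overlapping_track(regions, merge_regions(track[["chrom", "start", "end"]]))
    return float(hits.mean())


def nearest_gene(
    region: Region, annotation: GenomeAnnotation, max_dist: int = 100_000
) -> Optional[str]:
    """Gene whose TSS is closest to the region midpoint, within max_dist.

    Ties break to the lexicographically smaller gene id; None when no TSS
    is close enough. This transparent nearest-TSS rule stands in for
    database-backed region-to-gene tools.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    chrom, start, end = region
    mid = (start + end) // 2
    genes = annotation.genes
    same = genes[genes["chrom"] == chrom]
    if same.empty:
        return None
    dist = (same["tss"] - mid).abs()
    order = pd.DataFrame({"dist": dist, "gene_id": same["gene_id"]}).sort_values(
        ["dist", "gene_id"], kind="mergesort"
    )
    best = order.iloc[0]
    return str(best["gene_id"]) if best["dist"] <= max_dist else None


def dmr_feature_summary(dmrs: pd.DataFrame, annotation: GenomeAnnotation) -> pd.DataFrame:
    """Per (context, direction): counts, distal fraction and feature breakdown."""
    clf = FeatureClassifier(annotation)
    work = dmrs.copy()
    work["feature"] = classify_regions(work, annotation)
    work["distal"] = [
        clf.is_distal((str(c), int(s), int(e)))
        for c, s, e in zip(work["chrom"], work["start"], work["end"])
    ]
    rows = []
    for (context, direction), sub in work.groupby(["context", "direction"], sort=True):
        row = {"context": context, "direction": direction, "n": len(sub),
               "frac_distal": float(sub["distal"].mean())}
        for label in FEATURE_PRIORITY:
            row[f"n_{label}"] = int((sub["feature"] == label).sum())
        rows.append(row)
    return pd.DataFrame(rows)
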