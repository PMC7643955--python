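"""Methylome-transcriptome integration.

Joins the DMR caller's output with expression results: gene-body
methylation vs expression correlation, intersection of differential genes
with gene-body DMRs, log-odds PWM scanning of DMR sequences, and the
triangulation of candidate regulatory transcription factors — TFs that
(i) are expressed in MI or MII (FPKM >= 1), (ii) appear in a supplied
list of DNMT3B protein-binding partners, and (iii) have a binding-motif
hit inside a DMR. Hypergeometric over-representation of query genes in
user-supplied target sets replaces web-service enrichment tools.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GenomeAnnotation
from .intervals import GenomeIntervals
from .methylome import DMR, methylation_level

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: default scan threshold as a fraction of the PWM's maximum attainable score
MOTIF_THRESHOLD_FRACTION = 0.8


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """Position probability matrix over A, C, G, T with a background model."""

    name: str
    probs: np.ndarray                       # shape (length, 4)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", np.asarray(self.background, dtype=float))
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("PWM matrix must be length x 4")
        if probs.shape[0] < 4:
            raise ValueError("PWM length must be >= 4")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM columns must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_consensus(cls, name: str, consensus: str, certainty: float = 1.0) -> "PWM":
        """PWM putting ``certainty`` mass on the consensus base per position."""
        off = (1.0 - certainty) / 3.0
        probs = np.full((len(consensus), 4), off)
        for i, base in enumerate(consensus):
            probs[i, _BASE_INDEX[base]] = certainty
        return cls(name, probs)

    @property
    def log_odds(self) -> np.ndarray:
        """log2(p / background) per position and base; zero-probability cells -> -inf."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs) - np.log2(self.background)

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def default_threshold(self) -> float:
        return MOTIF_THRESHOLD_FRACTION * self.max_score()


@dataclass(frozen=True)
class MotifHit:
    motif: str
    start: int       # within the scanned sequence, forward coordinates
    end: int
    strand: str      # "+" | "-"
    score: float


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), -1, dtype=np.int8)
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


def pwm_scan(seq: str, pwm: PWM, threshold_bits: Optional[float] = None) -> List[MotifHit]:
    """Score every offset on both strands; keep hits with score >= threshold.

    Scores are log-odds in bits against the PWM's background; any position
    covering a non-ACGT base scores −inf. The default threshold is 80% of
    the PWM's maximum attainable score. Minus-strand hits are reported in
    forward-sequence coordinates.
    """
    if threshold_bits is None:
        threshold_bits = pwm.default_threshold()
    length = len(pwm)
    hits: List[MotifHit] = []
    if len(seq) < length:
        return hits
    lo = pwm.log_odds
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        codes = _encode(s)
        n = len(s) - length + 1
        scores = np.zeros(n)
        for j in range(length):
            col = codes[j:j + n]
            valid = col >= 0
            scores[valid] += lo[j, col[valid]]
            scores[~valid] = -np.inf
        for i in np.flatnonzero(scores >= threshold_bits):
            if strand == "+":
                start = int(i)
            else:
                start = len(seq) - int(i) - length
            hits.append(MotifHit(pwm.name, start, start + length, strand, float(scores[i])))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_regions(
    genome: Mapping[str, str],
    regions: Sequence[Tuple[str, int, int]],
    pwm: PWM,
    threshold_bits: Optional[float] = None,
) -> pd.DataFrame:
    """PWM hits inside genomic regions, in genome coordinates."""
    rows = []
    for chrom, start, end in regions:
        for h in pwm_scan(genome[chrom][start:end], pwm, threshold_bits):
            rows.append((pwm.name, chrom, start + h.start, start + h.end, h.strand, h.score))
    return pd.DataFrame(rows, columns=["motif", "chrom", "start", "end", "strand", "score"])


def gene_body_meth_expr(
    pool: pd.DataFrame,
    fpkm: pd.Series,
    annotation: GenomeAnnotation,
    context: str,
    min_coverage: int = 5,
) -> Tuple[pd.DataFrame, float, float]:
    """Per-gene (gene-body methylation, log10 FPKM + 1) pairs and Pearson r.

    The gene body is the full transcript span. Genes whose pooled in-context
    coverage over the body is below ``min_coverage`` are dropped. Returns
    (pairs frame, r, two-sided p); a degenerate constant input yields r = 0
    with a warning.
    """
    sub = pool[pool["context"] == context]
    rows = []
    for _, g in annotation.genes.iterrows():
        lvl = methylation_level(sub, (g["chrom"], g["start"], g["end"]))
        if lvl is None or lvl.coverage < min_coverage:
            continue
        expr = float(fpkm.get(g["gene_id"], 0.0))
        rows.append((g["gene_id"], lvl.level, lvl.coverage, np.log10(expr + 1.0)))
    pairs = pd.DataFrame(rows, columns=["gene_id", "meth_level", "coverage", "log10_fpkm"])
    if len(pairs) < 3:
        raise ValueError(f"correlation undefined: only {len(pairs)} genes with data")
    if pairs["meth_level"].nunique() == 1 or pairs["log10_fpkm"].nunique() == 1:
        warnings.warn("constant input; correlation undefined, reporting r = 0")
        return pairs, 0.0, 1.0
    r, p = stats.pearsonr(pairs["meth_level"], pairs["log10_fpkm"])
    return pairs, float(r), float(p)


def _gene_body_dmrs(dmrs: Sequence[DMR], annotation: GenomeAnnotation) -> Dict[str, List[DMR]]:
    """gene id -> DMRs overlapping its transcript span."""
    frame = pd.DataFrame(
        [(d.chrom, d.start, d.end) for d in dmrs], columns=["chrom", "start", "end"]
    )
    index = GenomeIntervals(frame)
    out: Dict[str, List[DMR]] = {}
    for _, g in annotation.genes.iterrows():
        hits = index.overlapping(str(g["chrom"]), int(g["start"]), int(g["end"]))
        if len(hits):
            out[str(g["gene_id"])] = [dmrs[i] for i in hits.index]
    return out


def degs_with_gene_body_dmr(
    degs: pd.DataFrame,
    dmrs: Sequence[DMR],
    annotation: GenomeAnnotation,
    direction_filter: Optional[str] = "up",
) -> Tuple[Set[str], float, Dict[str, int]]:
    """Among (filtered) differential genes, those with a DMR in their gene body.

    Returns the gene set, its fraction of the filtered differential genes,
    and hyper/hypo tallies of DMR-bearing genes (a gene counts as hyper
    when at least one of its body DMRs is hyper, and hypo likewise — the
    two tallies can overlap).
    """
    flagged = degs[degs["deg"]] if "deg" in degs.columns else degs
    if direction_filter is not None:
        flagged = flagged[flagged["direction"] == direction_filter]
    if flagged.empty:
        raise ValueError("no differential genes after filtering; fraction undefined")
    by_gene = _gene_body_dmrs(dmrs, annotation)
    hit = {g for g in flagged.index if g in by_gene}
    tallies = {
        "hyper": sum(any(d.direction == "hyper" for d in by_gene[g]) for g in hit),
        "hypo": sum(any(d.direction == "hypo" for d in by_gene[g]) for g in hit),
    }
    return hit, len(hit) / len(flagged), tallies


@dataclass
class TFReport:
    tf: str
    expressed: bool
    partner: bool
    motif_in_dmr: Optional[bool]        # None when the TF has no PWM
    motif_in_distal_dmr: Optional[bool]
    upregulated: bool
    triangulated: bool


def tf_triangulate(
    fpkm: pd.DataFrame,
    partner_list: Iterable[str],
    pwms: Mapping[str, PWM],
    dmrs: Sequence[DMR],
    genome: Mapping[str, str],
    degs: Optional[pd.DataFrame] = None,
    annotation: Optional[GenomeAnnotation] = None,
    stages: Sequence[str] = ("MI", "MII"),
    expressed_threshold: float = 1.0,
    threshold_bits: Optional[float] = None,
) -> List[TFReport]:
    """Cross candidate TFs against expression, partnership and motif evidence.

    A TF is triangulated when it is expressed (FPKM >= threshold in any of
    ``stages``), is a binding partner, and has >= 1 PWM hit inside a DMR.
    TFs without a PWM have an unknown motif flag and are excluded from
    triangulation. When an annotation is given, a separate flag records
    motif presence in distal DMRs specifically.
    """
    partners = set(partner_list)
    candidates = sorted(partners | set(pwms))
    distal_flags: Dict[int, bool] = {}
    if annotation is not None:
        from .features import FeatureClassifier

        clf = FeatureClassifier(annotation)
        distal_flags = {i: clf.is_distal((d.chrom, d.start, d.end)) for i, d in enumerate(dmrs)}
    regions = [(d.chrom, d.start, d.end) for d in dmrs]
    up_genes: Set[str] = set()
    if degs is not None:
        flagged = degs[degs["deg"] & (degs["direction"] == "up")]
        up_genes = set(flagged.index)
    reports = []
    for tf in candidates:
        row = fpkm.loc[tf] if tf in fpkm.index else None
        expressed = bool(row is not None and any(
            float(row[s]) >= expressed_threshold for s in stages if s in fpkm.columns))
        if tf in pwms:
            hits = scan_regions(genome, regions, pwms[tf], threshold_bits)
            motif_in_dmr: Optional[bool] = bool(len(hits))
            if annotation is not None and len(hits):
                hit_dmr_idx = {
                    i for i, (c, s, e) in enumerate(regions)
                    if ((hits["chrom"] == c) & (hits["start"] >= s) & (hits["end"] <= e)).any()
                }
                motif_in_distal = any(distal_flags.get(i, False) for i in hit_dmr_idx)
            else:
                motif_in_distal = None if annotation is None else False
        else:
            logger.info("TF %s has no PWM; motif evidence unknown, excluded", tf)
            motif_in_dmr = None
            motif_in_distal = None
        triangulated = bool(expressed and tf in partners and motif_in_dmr)
        reports.append(TFReport(tf, expressed, tf in partners, motif_in_dmr,
                                motif_in_distal, tf in up_genes, triangulated))
    return reports


def tf_target_direction_tally(
    tf: str,
    target_genes: Iterable[str],
    dmrs: Sequence[DMR],
    annotation: GenomeAnnotation,
    genome: Mapping[str, str],
    pwm: PWM,
    threshold_bits: Optional[float] = None,
) -> Tuple[int, int]:
    """(n targets with a motif-bearing gene-body DMR, how many of those hyper).

    A target gene counts when at least one DMR overlapping its gene body
    contains a hit of the TF's motif; it counts as hyper when at least one
    such motif-bearing DMR is hypermethylated.
    """
    by_gene = _gene_body_dmrs(dmrs, annotation)
    has_hit = {
        i: bool(pwm_scan(genome[d.chrom][d.start:d.end], pwm, threshold_bits))
        for i, d in enumerate(dmrs)
    }
    index_of = {id(d): i for i, d in enumerate(dmrs)}
    n_with = n_hyper = 0
    for gene in sorted(set(target_genes)):
        motif_dmrs = [d for d in by_gene.get(gene, []) if has_hit[index_of[id(d)]]]
        if motif_dmrs:
            n_with += 1
            if any(d.direction == "hyper" for d in motif_dmrs):
                n_hyper += 1
    return n_with, n_hyper


def gene_set_enrichment(
    query_genes: Iterable[str],
    target_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of the query in each set.

    p = P(overlap >= observed) drawing |query| genes from the universe with
    |set| successes; BH across sets. Query and sets are intersected with
    the universe first.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes) & universe
    rows = []
    for name in sorted(target_sets):
        members = set(target_sets[name]) & universe
        overlap = len(query & members)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(query)))
        rows.append((name, len(members), overlap, p))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"]).set_index("set")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    return out
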