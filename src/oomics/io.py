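"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions: BED intervals are 0-based half-open; the GTF-like annotation
is 1-based inclusive on disk (per GTF) and converted at this boundary;
cytosine tables are Bismark-extractor-like TSVs with 0-based positions.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import GenomeAnnotation
from .config import SimConfig
from .expression import CountMatrix
from .integration import PWM
from .methylome import DMR

CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "context", "meth_count", "total_count",
                    "cell_id", "stage"]


# --- FASTA -----------------------------------------------------------------

def write_fasta(genome: Dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in sorted(genome.items())]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# --- GTF-like annotation ---------------------------------------------------

def write_gtf(annotation: GenomeAnnotation, path) -> None:
    """gene/exon/five_prime_utr/three_prime_utr features, 1-based inclusive."""
    strand_of = dict(zip(annotation.genes["gene_id"], annotation.genes["strand"]))
    lines = []

    def emit(feature, chrom, start, end, strand, gid):
        lines.append(
            f"{chrom}\toomics\t{feature}\t{start + 1}\t{end}\t.\t{strand}\t.\t"
            f'gene_id "{gid}";'
        )

    for _, g in annotation.genes.iterrows():
        emit("gene", g["chrom"], g["start"], g["end"], g["strand"], g["gene_id"])
    for name, feature in (("exons", "exon"), ("utr5", "five_prime_utr"),
                          ("utr3", "three_prime_utr")):
        for _, row in getattr(annotation, name).iterrows():
            emit(feature, row["chrom"], row["start"], row["end"],
                 strand_of[row["gene_id"]], row["gene_id"])
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_gtf(path, chrom_lengths: Dict[str, int],
             repeats: Optional[pd.DataFrame] = None,
             accessibility: Optional[pd.DataFrame] = None,
             genome: Optional[Dict[str, str]] = None) -> GenomeAnnotation:
    names = ["chrom", "source", "feature", "start", "end", "score", "strand", "frame", "attrs"]
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None, names=names)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=names)
    if len(df):
        df["gene_id"] = df["attrs"].str.extract(r'gene_id "([^"]+)"')
        df["start"] = df["start"].astype(int) - 1  # to 0-based half-open
        df["end"] = df["end"].astype(int)

    def part(feature):
        sub = df[df["feature"] == feature]
        return sub[["gene_id", "chrom", "start", "end"]].reset_index(drop=True)

    gene_rows = df[df["feature"] == "gene"].copy() if len(df) else df
    if len(gene_rows):
        gene_rows["tss"] = np.where(gene_rows["strand"] == "+", gene_rows["start"],
                                    gene_rows["end"] - 1)
        genes = gene_rows[["gene_id", "chrom", "strand", "start", "end", "tss"]].reset_index(drop=True)
    else:
        genes = None
    kwargs = {}
    if genes is not None:
        kwargs.update(genes=genes, exons=part("exon"), utr5=part("five_prime_utr"),
                      utr3=part("three_prime_utr"))
    if repeats is not None:
        kwargs["repeats"] = repeats
    if accessibility is not None:
        kwargs["accessibility"] = accessibility
    return GenomeAnnotation(chrom_lengths=chrom_lengths, genome=genome, **kwargs)


# --- BED -------------------------------------------------------------------

def write_bed(frame: pd.DataFrame, path, columns: Sequence[str] = ("chrom", "start", "end")) -> None:
    frame[list(columns)].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, extra_names: Sequence[str] = ()) -> pd.DataFrame:
    names = ["chrom", "start", "end", *extra_names]
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=names,
                         usecols=range(len(names)))
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=names)
    return df


def write_dmr_bed(dmrs: Sequence[DMR], path) -> None:
    """BED6+ with name=context, score=−10·log10(q), then levels/delta/direction."""
    rows = []
    for d in dmrs:
        score = 0.0 if d.q <= 0 else min(1000.0, -10.0 * math.log10(max(d.q, 1e-300)))
        rows.append((d.chrom, d.start, d.end, d.context, round(score, 3), ".",
                     round(d.level_a, 6), round(d.level_b, 6), round(d.delta, 6),
                     d.direction, d.q, d.n_windows))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_dmr_bed(path) -> List[DMR]:
    names = ["chrom", "start", "end", "context", "score", "bed_strand",
             "level_a", "level_b", "delta", "direction", "q", "n_windows"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=names)
    except pd.errors.EmptyDataError:
        return []
    return [
        DMR(str(r.chrom), int(r.start), int(r.end), str(r.context), str(r.direction),
            float(r.level_a), float(r.level_b), float(r.delta), float(r.q), int(r.n_windows))
        for r in df.itertuples()
    ]


# --- cytosine tables -------------------------------------------------------

def write_cytosine_tsv(cells: Dict[str, List[pd.DataFrame]], path) -> None:
    """One combined TSV with cell_id and stage columns."""
    frames = []
    for stage in cells:
        for j, table in enumerate(cells[stage]):
            t = table.copy()
            t["cell_id"] = f"{stage}_{j}"
            t["stage"] = stage
            frames.append(t)
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=CYTOSINE_COLUMNS))
    out[CYTOSINE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_cytosine_tsv(path) -> Dict[str, List[pd.DataFrame]]:
    df = pd.read_csv(path, sep="\t")
    out: Dict[str, List[pd.DataFrame]] = {}
    for stage, sub in df.groupby("stage", sort=True):
        out[stage] = [cell_df.drop(columns=["cell_id", "stage"]).reset_index(drop=True)
                      for _, cell_df in sub.groupby("cell_id", sort=True)]
    return out


# --- counts ----------------------------------------------------------------

def write_count_matrix(matrix: CountMatrix, prefix) -> None:
    prefix = Path(prefix)
    matrix.counts.rename_axis("gene_id").to_csv(prefix.with_suffix(".counts.tsv"), sep="\t")
    matrix.lengths.rename("length").rename_axis("gene_id").to_csv(
        prefix.with_suffix(".lengths.tsv"), sep="\t")
    matrix.cell_stage.rename("stage").rename_axis("cell_id").to_csv(
        prefix.with_suffix(".cells.tsv"), sep="\t")


def read_count_matrix(prefix) -> CountMatrix:
    prefix = Path(prefix)
    counts = pd.read_csv(prefix.with_suffix(".counts.tsv"), sep="\t", index_col="gene_id")
    lengths = pd.read_csv(prefix.with_suffix(".lengths.tsv"), sep="\t", index_col="gene_id")["length"]
    cells = pd.read_csv(prefix.with_suffix(".cells.tsv"), sep="\t", index_col="cell_id")["stage"]
    return CountMatrix(counts=counts, lengths=lengths, cell_stage=cells)


# --- PWMs and gene sets ----------------------------------------------------

def read_pwms_jaspar(path) -> Dict[str, PWM]:
    """JASPAR-format PWMs (count or frequency matrices), normalized per column."""
    out = {}
    with open(path) as handle:
        for m in motifs.parse(handle, "jaspar"):
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float).T
            probs = counts / counts.sum(axis=1, keepdims=True)
            name = m.name or m.matrix_id
            out[name] = PWM(name, probs)
    return out


def write_pwms_jaspar(pwms: Dict[str, PWM], path, scale: int = 100) -> None:
    lines = []
    for name in sorted(pwms):
        p = pwms[name]
        lines.append(f">{name} {name}")
        for bi, base in enumerate("ACGT"):
            vals = " ".join(str(int(round(x * scale))) for x in p.probs[:, bi])
            lines.append(f"{base} [ {vals} ]")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_sets(path) -> Dict[str, List[str]]:
    """Two-column TSV (set name, gene id) -> mapping of sets to gene lists."""
    df = pd.read_csv(path, sep="\t", header=None, names=["set", "gene"])
    return {name: sorted(sub["gene"]) for name, sub in df.groupby("set", sort=True)}


def write_gene_sets(sets: Dict[str, Sequence[str]], path) -> None:
    rows = [(name, g) for name in sorted(sets) for g in sets[name]]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_gene_list(path) -> List[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def write_gene_list(genes: Sequence[str], path) -> None:
    Path(path).write_text("\n".join(genes) + ("\n" if len(genes) else ""))


# --- config ----------------------------------------------------------------

def load_sim_config(path, seed: Optional[int] = None) -> SimConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    sim = data.get("sim", data)
    if seed is not None:
        sim["seed"] = seed
    return SimConfig.from_dict(sim)
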