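"""Ground-truth simulator for the oocyte maturation analysis.

Generates a random genome with non-overlapping genes, repeat and
accessibility tracks; per-cell cytosine call tables for three maturation
stages with sparse Poisson coverage; and a negative-binomial count matrix.
The statistical structure mirrors the biology the downstream analysis
assumes:

* CpG methylation is stable across stages; non-CpG methylation doubles in
  MII (``noncpg_mean_immature`` -> ``noncpg_mean_mature``).
* Planted non-CpG regions gain an extra ``dmr_effect`` of methylation in
  MII only, and lie preferentially inside (long, LINE1-like) repeats.
* A consensus motif of a designated "TF" gene is embedded in a fraction
  of the planted regions before cytosines are enumerated.
* Expression effects are confined to MII: GV and MI share gene means by
  construction, so the GV-vs-MI contrast is null. Genes whose body
  overlaps a planted DMR are upregulated (positive log2FC), emulating the
  positive gene-body methylation-expression association; other planted
  differential genes get random signs, biased towards downregulation.

Cytosine contexts are read off the simulated sequence with Bismark
semantics, both strands enumerated independently: CpG = C followed by G,
CHG = C-H-G, CHH otherwise (H is A, C or T).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation
from .config import MATURE_STAGE, SimConfig
from .expression import CountMatrix
from .integration import PWM

logger = logging.getLogger(__name__)

_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
LAMBDA_CHROM = "lambda"

# spacing that keeps separate planted DMRs from merging into one called
# region (one caller window on each side)
_DMR_MIN_GAP = 2 * 3_000

#: proximal fraction of each chromosome holding the genes; the remainder is
#: a repeat-rich gene desert
GENE_COMPARTMENT_FRACTION = 0.45


@dataclass(frozen=True)
class PlantedTF:
    """The simulated regulatory factor used by the triangulation fixture."""

    gene_id: str
    consensus: str
    motif_dmr_indices: Tuple[int, ...]
    target_genes: Tuple[str, ...]

    def pwm(self) -> PWM:
        return PWM.from_consensus(self.gene_id, self.consensus)


@dataclass(frozen=True)
class TruthSet:
    """Ground truth of one simulation run.

    ``planted_dmrs``: chrom, start, end, context, direction (all hyper in
    MII), in_repeat, has_motif. ``planted_degs``: gene_id, log2fc (signed,
    MII vs the immature stages). ``dmr_deg_links``: (gene_id, dmr_index)
    pairs where the expression effect was driven by a gene-body DMR.
    """

    planted_dmrs: pd.DataFrame = field(default_factory=pd.DataFrame)
    planted_degs: pd.DataFrame = field(default_factory=pd.DataFrame)
    dmr_deg_links: Tuple[Tuple[str, int], ...] = ()
    planted_tf: Optional[PlantedTF] = None


@dataclass
class MethylomeSim:
    """Per-cell cytosine tables and lambda spike-ins, keyed by stage."""

    cells: Dict[str, List[pd.DataFrame]]
    spikeins: Dict[str, List[pd.DataFrame]]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


# ---------------------------------------------------------------------------
# annotation


def _place_disjoint(rng, lengths: np.ndarray, chrom_length: int) -> np.ndarray:
    """Non-overlapping starts for blocks of given lengths via stick breaking."""
    free = chrom_length - int(lengths.sum())
    gaps = rng.multinomial(free, np.full(len(lengths) + 1, 1.0 / (len(lengths) + 1)))
    starts = np.cumsum(gaps[:-1]) + np.concatenate([[0], np.cumsum(lengths[:-1])])
    return starts.astype(np.int64)


def _gene_parts(rng, gid, chrom, start, end, strand, exon_range=(2, 4)):
    """Split a transcript span into exons/introns and carve the UTRs.

    Introns absorb most of the slack (as in real genes, where intronic
    length dwarfs exonic length), so classification of regions inside gene
    bodies is not dominated by exon overlap.
    """
    span = end - start
    n_ex = int(rng.integers(exon_range[0], exon_range[1] + 1))
    min_exon, min_intron = 450, 800
    base = n_ex * min_exon + (n_ex - 1) * min_intron
    while base > span and n_ex > 2:
        n_ex -= 1
        base = n_ex * min_exon + (n_ex - 1) * min_intron
    # intron segments get 4x the weight of exon segments when spreading slack
    weights = np.empty(2 * n_ex - 1)
    weights[0::2] = 1.0
    weights[1::2] = 4.0
    extra = rng.multinomial(span - base, weights / weights.sum())
    sizes = np.empty(2 * n_ex - 1, dtype=np.int64)
    sizes[0::2] = min_exon
    sizes[1::2] = min_intron
    sizes += extra
    bounds = start + np.concatenate([[0], np.cumsum(sizes)])
    exons = [(int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_ex)]
    u5_len = int(rng.integers(100, 301))
    u3_len = int(rng.integers(200, 401))
    first, last = exons[0], exons[-1]
    if strand == "+":
        utr5 = (first[0], first[0] + u5_len)
        utr3 = (last[1] - u3_len, last[1])
    else:
        utr5 = (last[1] - u5_len, last[1])
        utr3 = (first[0], first[0] + u3_len)
    return exons, utr5, utr3


def _random_track(rng, chrom_lengths, target_fraction, min_len, max_len):
    rows = []
    for chrom, length in chrom_lengths.items():
        covered = 0
        target = target_fraction * length
        guard = 0
        while covered < target and guard < 10_000:
            guard += 1
            size = int(rng.integers(min_len, max_len + 1))
            start = int(rng.integers(0, length - size))
            rows.append((chrom, start, start + size))
            covered += size
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def simulate_annotation(config: SimConfig) -> GenomeAnnotation:
    """Random genome, non-overlapping genes, repeat and accessibility tracks.

    Long LINE1-like repeats (>= dmr_length + 500 bp) are placed first —
    some deliberately overlapping gene bodies — so that planted DMRs can
    later sit fully inside repeats; shorter SINE/LTR-like elements fill the
    track to ``repeat_fraction``. Raises when the requested gene density
    cannot be placed without overlap.
    """
    rng = _rng(config, 0)
    chrom_lengths = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    genome = {
        chrom: _CODES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
        for chrom, length in chrom_lengths.items()
    }

    # each chromosome has a gene-rich proximal compartment and a distal
    # repeat-rich "gene desert", mimicking large-scale genome organisation
    lo, hi = config.gene_length_range
    chroms = sorted(chrom_lengths)
    per_chrom = np.full(len(chroms), config.n_genes // len(chroms))
    per_chrom[: config.n_genes % len(chroms)] += 1
    gene_rows, exon_rows, u5_rows, u3_rows = [], [], [], []
    gi = 0
    for chrom, n_here in zip(chroms, per_chrom):
        if n_here == 0:
            continue
        compartment = int(GENE_COMPARTMENT_FRACTION * chrom_lengths[chrom])
        lengths = rng.integers(lo, hi + 1, size=n_here)
        density = lengths.sum() / compartment
        if density > 0.8:
            raise ValueError(
                f"cannot place {n_here} genes on {chrom}: requested genic density "
                f"{density:.2f} in the gene compartment exceeds 0.8"
            )
        starts = _place_disjoint(rng, lengths, compartment)
        for start, length in zip(starts, lengths):
            gid = f"G{gi:04d}"
            gi += 1
            strand = "+" if rng.random() < 0.5 else "-"
            end = int(start + length)
            tss = int(start) if strand == "+" else end - 1
            gene_rows.append((gid, chrom, strand, int(start), end, tss))
            exons, utr5, utr3 = _gene_parts(rng, gid, chrom, int(start), end, strand,
                                            config.exons_per_gene)
            exon_rows += [(gid, chrom, s, e) for s, e in exons]
            u5_rows.append((gid, chrom, *utr5))
            u3_rows.append((gid, chrom, *utr3))

    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "strand", "start", "end", "tss"])

    # long repeats, non-overlapping among themselves with a merge-safe gap
    long_len_lo = config.dmr_length + 500
    long_len_hi = config.dmr_length + 3_000
    n_in_repeat = int(round(config.frac_dmr_in_repeats * config.n_planted_dmrs))
    n_long = int(np.ceil(n_in_repeat * 1.3)) + 1 if n_in_repeat else 0
    repeat_rows: List[tuple] = []
    placed: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}

    def _clashes(chrom, start, end) -> bool:
        return any(start < e + _DMR_MIN_GAP and end > s - _DMR_MIN_GAP
                   for s, e in placed[chrom])

    # purely intergenic repeats stay clear of genes by more than a promoter
    # plus one caller-window extension, so regions called around them remain
    # free of promoter/exon/UTR overlap
    gene_margin = 4_500
    gene_spans = {c: [(int(g["start"]) - gene_margin, int(g["end"]) + gene_margin)
                      for _, g in genes[genes["chrom"] == c].iterrows()]
                  for c in chroms}

    n_genic = int(round(config.frac_long_repeat_in_gene * n_long)) if len(genes) else 0
    n_placed_genic = 0
    attempts = 0
    while sum(len(v) for v in placed.values()) < n_long and attempts < 50_000:
        attempts += 1
        size = int(rng.integers(long_len_lo, long_len_hi + 1))
        in_gene = n_placed_genic < n_genic
        if in_gene:
            g = genes.iloc[int(rng.integers(0, len(genes)))]
            chrom = str(g["chrom"])
            offset = int(rng.integers(-size + 500, g["end"] - g["start"] - 500))
            start = int(g["start"]) + offset
        else:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(0, chrom_lengths[chrom] - size))
        end = start + size
        if start < 0 or end > chrom_lengths[chrom] or _clashes(chrom, start, end):
            continue
        if not in_gene and any(start < ge and end > gs for gs, ge in gene_spans[chrom]):
            continue
        placed[chrom].append((start, end))
        repeat_rows.append((chrom, start, end, "LINE1"))
        n_placed_genic += in_gene
    if sum(len(v) for v in placed.values()) < n_long:
        raise ValueError("could not place long repeats; genome too small for the request")

    short = _random_track(
        rng, chrom_lengths,
        max(0.0, config.repeat_fraction - sum(r[2] - r[1] for r in repeat_rows)
            / sum(chrom_lengths.values())),
        150, 900,
    )
    families = rng.choice(["SINE", "LTR", "LINE2"], size=len(short))
    repeat_rows += [(c, s, e, f) for (c, s, e), f in zip(short.itertuples(index=False), families)]
    repeats = pd.DataFrame(repeat_rows, columns=["chrom", "start", "end", "family"])
    repeats = repeats.sort_values(["chrom", "start"]).reset_index(drop=True)

    accessibility = _random_track(rng, chrom_lengths, config.accessible_fraction, 200, 1_200)
    accessibility = accessibility.sort_values(["chrom", "start"]).reset_index(drop=True)

    return GenomeAnnotation(
        chrom_lengths=chrom_lengths,
        genes=genes,
        exons=pd.DataFrame(exon_rows, columns=["gene_id", "chrom", "start", "end"]),
        utr5=pd.DataFrame(u5_rows, columns=["gene_id", "chrom", "start", "end"]),
        utr3=pd.DataFrame(u3_rows, columns=["gene_id", "chrom", "start", "end"]),
        repeats=repeats,
        accessibility=accessibility,
        genome=genome,
    )


# ---------------------------------------------------------------------------
# methylome


def cytosine_sites(genome: Dict[str, str]) -> pd.DataFrame:
    """All cytosines on both strands with their Bismark-style context.

    + strand: a C at i, looking at i+1 and i+2. − strand: a G at i (a C on
    the reverse strand), looking at i−1 and i−2. The two terminal bases of
    each strand, whose context is truncated, are skipped.
    """
    frames = []
    for chrom in sorted(genome):
        arr = np.frombuffer(genome[chrom].encode("ascii"), dtype=np.uint8)
        n = len(arr)
        c, g = ord("C"), ord("G")

        pos = np.flatnonzero(arr[: n - 2] == c)
        nxt1, nxt2 = arr[pos + 1], arr[pos + 2]
        ctx = np.where(nxt1 == g, "CpG", np.where(nxt2 == g, "CHG", "CHH"))
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos, "strand": "+", "context": ctx}))

        pos = np.flatnonzero(arr[2:] == g) + 2
        prv1, prv2 = arr[pos - 1], arr[pos - 2]
        ctx = np.where(prv1 == c, "CpG", np.where(prv2 == c, "CHG", "CHH"))
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos, "strand": "-", "context": ctx}))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)


def _choose_dmr_intervals(rng, config: SimConfig, annotation: GenomeAnnotation) -> pd.DataFrame:
    n = config.n_planted_dmrs
    if n == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "context", "direction", "in_repeat"])
    n_in_rep = int(round(config.frac_dmr_in_repeats * n))
    long_reps = annotation.repeats[
        annotation.repeats["end"] - annotation.repeats["start"] >= config.dmr_length
    ]
    if len(long_reps) < n_in_rep:
        raise ValueError(
            f"need {n_in_rep} repeats of >= {config.dmr_length} bp, found {len(long_reps)}"
        )
    chosen = long_reps.iloc[rng.choice(len(long_reps), size=n_in_rep, replace=False)]
    rows = []
    for _, rep in chosen.iterrows():
        slack = int(rep["end"] - rep["start"]) - config.dmr_length
        start = int(rep["start"]) + int(rng.integers(0, slack + 1))
        rows.append((str(rep["chrom"]), start, start + config.dmr_length, True))

    from .intervals import GenomeIntervals

    rep_index = GenomeIntervals(annotation.repeats)
    chroms = sorted(annotation.chrom_lengths)
    guard = 0
    while len(rows) < n and guard < 50_000:
        guard += 1
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, annotation.chrom_lengths[chrom] - config.dmr_length))
        end = start + config.dmr_length
        if rep_index.overlaps(chrom, start, end):
            continue
        if any(c == chrom and start < e + _DMR_MIN_GAP and end > s - _DMR_MIN_GAP
               for c, s, e, _ in rows):
            continue
        rows.append((chrom, start, end, False))
    if len(rows) < n:
        raise ValueError("could not place the requested number of planted DMRs")
    n_chh = int(round(config.frac_dmr_chh * n))
    contexts = np.array(["CHH"] * n_chh + ["CHG"] * (n - n_chh))
    rng.shuffle(contexts)
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "in_repeat"])
    out["context"] = contexts
    out["direction"] = "hyper"
    return out[["chrom", "start", "end", "context", "direction", "in_repeat"]]


def _embed_motifs(rng, config: SimConfig, genome: Dict[str, str],
                  dmrs: pd.DataFrame) -> List[int]:
    """Write the TF consensus into a fraction of planted DMRs; returns their indices."""
    if dmrs.empty or not config.tf_motif:
        return []
    n_with = int(round(config.frac_dmr_with_motif * len(dmrs)))
    chosen = sorted(rng.choice(len(dmrs), size=n_with, replace=False).tolist())
    motif = config.tf_motif
    for i in chosen:
        row = dmrs.iloc[i]
        offset = int(rng.integers(0, row["end"] - row["start"] - len(motif)))
        chrom = str(row["chrom"])
        pos = int(row["start"]) + offset
        seq = genome[chrom]
        genome[chrom] = seq[:pos] + motif + seq[pos + len(motif):]
    return chosen


def simulate_methylome(
    annotation: GenomeAnnotation, config: SimConfig
) -> Tuple[MethylomeSim, TruthSet]:
    """Per-cell cytosine tables per stage, plus lambda spike-ins and truth.

    Coverage per site per cell is Poisson(coverage_rate); methylated counts
    are Binomial(coverage, site mean). Site means: ``cpg_mean`` at CpG sites
    in every stage; ``noncpg_mean_immature`` (GV, MI) or
    ``noncpg_mean_mature`` (MII) elsewhere, plus ``dmr_effect`` at in-DMR
    sites of the planted context in MII only (clamped to 1 with a warning).
    Note: this call finalizes the genome (motif embedding) in place before
    enumerating cytosines.
    """
    if annotation.genome is None:
        raise ValueError("annotation must carry genome sequences")
    rng = _rng(config, 1)
    dmrs = _choose_dmr_intervals(rng, config, annotation)
    motif_indices = _embed_motifs(rng, config, annotation.genome, dmrs)
    dmrs["has_motif"] = False
    if motif_indices:
        dmrs.loc[dmrs.index[motif_indices], "has_motif"] = True

    sites = cytosine_sites(annotation.genome)
    is_cpg = (sites["context"] == "CpG").to_numpy()
    base_immature = np.where(is_cpg, config.cpg_mean, config.noncpg_mean_immature)
    base_mature = np.where(is_cpg, config.cpg_mean, config.noncpg_mean_mature).copy()

    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    ctx_arr = sites["context"].to_numpy()
    for _, d in dmrs.iterrows():
        mask = (chrom_arr == d["chrom"]) & (pos_arr >= d["start"]) & (pos_arr < d["end"]) \
            & (ctx_arr == d["context"])
        base_mature[mask] += config.dmr_effect
    if (base_mature > 1.0).any():
        warnings.warn("dmr_effect pushed site means above 1; clamping to 1")
        np.clip(base_mature, 0.0, 1.0, out=base_mature)

    cells: Dict[str, List[pd.DataFrame]] = {}
    spikeins: Dict[str, List[pd.DataFrame]] = {}
    lam_pos = np.arange(config.lambda_n_sites)
    for stage in config.stages:
        mean = base_mature if stage == MATURE_STAGE else base_immature
        cells[stage] = []
        spikeins[stage] = []
        for _ in range(config.n_cells_per_stage):
            p = mean
            if config.cell_level_sd > 0:
                with np.errstate(divide="ignore"):
                    logit = np.log(p) - np.log1p(-p)
                p = 1.0 / (1.0 + np.exp(-(logit + rng.normal(0, config.cell_level_sd))))
            cov = rng.poisson(config.coverage_rate, size=len(sites))
            covered = cov > 0
            meth = np.zeros(len(sites), dtype=np.int64)
            meth[covered] = rng.binomial(cov[covered], np.broadcast_to(p, len(sites))[covered])
            table = pd.DataFrame({
                "chrom": chrom_arr[covered],
                "pos": pos_arr[covered],
                "strand": sites["strand"].to_numpy()[covered],
                "context": ctx_arr[covered],
                "meth_count": meth[covered],
                "total_count": cov[covered],
            })
            cells[stage].append(table)

            lam_cov = rng.poisson(config.lambda_coverage, size=config.lambda_n_sites)
            lam_meth = rng.binomial(lam_cov, config.lambda_failure_rate)
            keep = lam_cov > 0
            spikeins[stage].append(pd.DataFrame({
                "chrom": LAMBDA_CHROM,
                "pos": lam_pos[keep],
                "strand": "+",
                "context": "CpG",
                "meth_count": lam_meth[keep],
                "total_count": lam_cov[keep],
            }))

    truth = TruthSet(planted_dmrs=dmrs.reset_index(drop=True))
    return MethylomeSim(cells=cells, spikeins=spikeins), truth


# ---------------------------------------------------------------------------
# transcriptome


def simulate_transcriptome(
    annotation: GenomeAnnotation, config: SimConfig, truth: TruthSet
) -> Tuple[CountMatrix, TruthSet]:
    """Negative-binomial counts per gene per cell, with MII-only effects.

    Baseline gene means are log-normal and shared by GV and MI; planted
    differential genes change only in MII. Genes whose body overlaps a
    planted DMR are preferentially chosen as upregulated targets (recorded
    as dmr_deg_links); the remaining planted genes get signed effects,
    ``frac_deg_down`` of them negative. The planted TF is the
    highest-baseline unperturbed gene.
    """
    if annotation.genes.empty:
        raise ValueError("transcriptome simulation needs a non-empty gene set")
    rng = _rng(config, 2)
    genes = list(annotation.genes["gene_id"])
    n = len(genes)
    base = rng.lognormal(config.count_meanlog, config.count_sdlog, size=n)
    base_s = pd.Series(base, index=genes)

    # genes whose body overlaps a planted DMR
    from .intervals import GenomeIntervals

    links: List[Tuple[str, int]] = []
    if len(truth.planted_dmrs):
        dmr_index = GenomeIntervals(truth.planted_dmrs)
        for _, g in annotation.genes.iterrows():
            hits = dmr_index.overlapping(str(g["chrom"]), int(g["start"]), int(g["end"]))
            for i in hits.index:
                links.append((str(g["gene_id"]), int(i)))

    eligible = [g for g in genes if base_s[g] >= config.deg_min_base_mean]
    linked_genes = sorted({g for g, _ in links if g in eligible})
    if len(linked_genes) > config.n_planted_degs:
        keep = sorted(rng.choice(len(linked_genes), size=config.n_planted_degs, replace=False))
        linked_genes = [linked_genes[i] for i in keep]
    links = tuple((g, i) for g, i in links if g in set(linked_genes))

    lo, hi = config.deg_log2fc_range
    l2fc = pd.Series(0.0, index=genes)
    for g in linked_genes:
        l2fc[g] = rng.uniform(lo, hi)
    n_other = max(0, config.n_planted_degs - len(linked_genes))
    pool = [g for g in eligible if g not in set(linked_genes)]
    other = [pool[i] for i in sorted(rng.choice(len(pool), size=min(n_other, len(pool)),
                                                replace=False))]
    for g in other:
        sign = -1.0 if rng.random() < config.frac_deg_down else 1.0
        l2fc[g] = sign * rng.uniform(lo, hi)

    planted = linked_genes + other
    tf_gene = None
    unperturbed = base_s.drop(planted).sort_values(ascending=False)
    if len(unperturbed):
        tf_gene = str(unperturbed.index[0])

    columns, stage_of = [], {}
    frames = {}
    disp_n = 1.0 / config.nb_dispersion
    for stage in config.stages:
        for j in range(config.n_cells_per_stage):
            cell = f"{stage}_{j}"
            columns.append(cell)
            stage_of[cell] = stage
            sf = rng.lognormal(0.0, config.libsize_sdlog)
            mu = base_s * sf
            if stage == MATURE_STAGE:
                mu = mu * np.power(2.0, l2fc)
            frames[cell] = rng.negative_binomial(disp_n, disp_n / (disp_n + mu))
    counts = pd.DataFrame(frames, index=genes, columns=columns)

    matrix = CountMatrix(
        counts=counts,
        lengths=annotation.gene_lengths,
        cell_stage=pd.Series(stage_of),
    )
    planted_degs = pd.DataFrame({
        "gene_id": planted,
        "log2fc": [float(l2fc[g]) for g in planted],
    })
    planted_tf = None
    if tf_gene is not None and config.tf_motif and len(truth.planted_dmrs):
        motif_idx = tuple(int(i) for i in truth.planted_dmrs.index[truth.planted_dmrs["has_motif"]])
        planted_tf = PlantedTF(tf_gene, config.tf_motif, motif_idx, tuple(linked_genes))
    new_truth = replace(truth, planted_degs=planted_degs, dmr_deg_links=links,
                        planted_tf=planted_tf)
    return matrix, new_truth


def simulate_all(config: SimConfig):
    """annotation, methylome sim, count matrix and complete truth in one call."""
    annotation = simulate_annotation(config)
    meth, truth = simulate_methylome(annotation, config)
    matrix, truth = simulate_transcriptome(annotation, config, truth)
    return annotation, meth, matrix, truth
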