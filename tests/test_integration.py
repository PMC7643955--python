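"""PWM scanning, enrichment, gene-body joins and TF triangulation."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from oomics.annotation import GenomeAnnotation
from oomics.integration import (
    PWM,
    degs_with_gene_body_dmr,
    gene_body_meth_expr,
    gene_set_enrichment,
    pwm_scan,
    reverse_complement,
    scan_regions,
    tf_target_direction_tally,
    tf_triangulate,
)
from oomics.methylome import DMR, pool_cells


def make_dmr(chrom, start, end, direction="hyper", context="CHH"):
    delta = 0.3 if direction == "hyper" else -0.3
    return DMR(chrom, start, end, context, direction, 0.05, 0.05 + delta, delta, 0.01, 2)


# --- PWM -------------------------------------------------------------------

def test_pwm_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        PWM("bad", np.full((5, 4), 0.3))
    with pytest.raises(ValueError, match="length"):
        PWM.from_consensus("short", "ACG")


def test_consensus_score_closed_form():
    pwm = PWM.from_consensus("m", "ACGT")
    hits = pwm_scan("ACGT", pwm, threshold_bits=7.9)
    fwd = [h for h in hits if h.strand == "+"]
    assert len(fwd) == 1 and fwd[0].score == pytest.approx(4 * math.log2(4))


def test_reverse_complement_strand_symmetry():
    pwm = PWM.from_consensus("m", "AGGAAGTG")
    seq = "TTTT" + "AGGAAGTG" + "CCCC"
    rc = reverse_complement(seq)
    fwd_hits = pwm_scan(seq, pwm)
    rc_hits = pwm_scan(rc, pwm)
    assert [h.strand for h in fwd_hits] == ["+"]
    assert [h.strand for h in rc_hits] == ["-"]
    h = rc_hits[0]
    assert rc[h.start:h.end] == reverse_complement("AGGAAGTG")
    assert h.score == fwd_hits[0].score


def test_n_bases_never_match():
    pwm = PWM.from_consensus("m", "ACGT")
    assert pwm_scan("ANGT" * 3, pwm, threshold_bits=0.0) == []


def test_short_sequence_yields_no_hits():
    assert pwm_scan("AC", PWM.from_consensus("m", "ACGT")) == []


def test_scan_matches_exhaustive_per_offset_scoring():
    rng = np.random.default_rng(10)
    seq = "".join(rng.choice(list("ACGT"), 1_000))
    probs = rng.dirichlet(np.ones(4), size=6)
    pwm = PWM("r", probs)
    threshold = 0.5 * pwm.max_score()
    got = {(h.start, h.strand): h.score for h in pwm_scan(seq, pwm, threshold)}
    lo = pwm.log_odds
    want = {}
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for i in range(len(s) - 6 + 1):
            score = sum(lo[j, base_idx[s[i + j]]] for j in range(6))
            if score >= threshold:
                start = i if strand == "+" else len(seq) - i - 6
                want[(start, strand)] = score
    assert got.keys() == want.keys()
    for key in want:
        assert got[key] == pytest.approx(want[key])


# --- enrichment ------------------------------------------------------------

def test_enrichment_exact_value_full_overlap():
    universe = [f"g{i}" for i in range(20)]
    out = gene_set_enrichment(universe[:5], {"s": universe[:5]}, universe)
    assert out.loc["s", "p"] == pytest.approx(1.0 / math.comb(20, 5), rel=1e-9)
    assert out.loc["s", "p"] == pytest.approx(6.45e-5, rel=1e-2)


def test_enrichment_null_overlap_is_unremarkable():
    universe = [f"g{i}" for i in range(100)]
    out = gene_set_enrichment(universe[:10], {"s": universe[9:19]}, universe)
    assert 0.3 <= out.loc["s", "p"] <= 1.0


def brute_force_tail(overlap, M, K, n):
    denom = math.comb(M, n)
    return sum(math.comb(K, k) * math.comb(M - K, n - k)
               for k in range(overlap, min(K, n) + 1)) / denom


def test_enrichment_matches_enumeration_small_universe():
    rng = np.random.default_rng(11)
    universe = [f"g{i}" for i in range(30)]
    for _ in range(50):
        k_set = int(rng.integers(1, 15))
        k_query = int(rng.integers(1, 15))
        members = list(rng.choice(universe, k_set, replace=False))
        query = list(rng.choice(universe, k_query, replace=False))
        out = gene_set_enrichment(query, {"s": members}, universe)
        overlap = len(set(members) & set(query))
        want = brute_force_tail(overlap, 30, k_set, k_query)
        assert out.loc["s", "p"] == pytest.approx(want, rel=1e-9)
    with pytest.raises(ValueError, match="universe"):
        gene_set_enrichment(["a"], {"s": ["a"]}, [])


def test_enrichment_q_at_least_p_and_order_invariant():
    rng = np.random.default_rng(12)
    universe = [f"g{i}" for i in range(50)]
    sets = {f"s{j}": list(rng.choice(universe, 8, replace=False)) for j in range(6)}
    query = list(rng.choice(universe, 12, replace=False))
    out = gene_set_enrichment(query, sets, universe)
    assert (out["q"] >= out["p"] - 1e-12).all()
    shuffled = gene_set_enrichment(query, sets, list(reversed(universe)))
    pd.testing.assert_frame_equal(out, shuffled)


# --- gene-body joins -------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_annotation():
    genes = pd.DataFrame(
        [("g1", "chr1", "+", 1_000, 5_000, 1_000),
         ("g2", "chr1", "+", 10_000, 14_000, 10_000),
         ("g3", "chr1", "-", 20_000, 24_000, 23_999)],
        columns=["gene_id", "chrom", "strand", "start", "end", "tss"])
    return GenomeAnnotation(chrom_lengths={"chr1": 40_000}, genes=genes)


def degs_frame(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "log2fc", "q", "direction", "deg"])
    return df.set_index("gene_id")


def test_degs_with_gene_body_dmr_fractions(tiny_annotation):
    degs = degs_frame([("g1", 2.0, 0.01, "up", True),
                       ("g2", 1.5, 0.01, "up", True),
                       ("g3", -2.0, 0.01, "down", True)])
    with pytest.raises(ValueError, match="undefined|no differential"):
        degs_with_gene_body_dmr(degs.iloc[0:0], [], tiny_annotation)
    genes, frac, tallies = degs_with_gene_body_dmr(degs, [], tiny_annotation, "up")
    assert genes == set() and frac == 0.0
    dmrs = [make_dmr("chr1", 4_000, 7_000), make_dmr("chr1", 11_000, 12_000, "hypo"),
            make_dmr("chr1", 21_000, 22_000)]
    genes, frac, tallies = degs_with_gene_body_dmr(degs, dmrs, tiny_annotation, "up")
    assert genes == {"g1", "g2"} and frac == 1.0
    assert tallies == {"hyper": 1, "hypo": 1}


def test_degs_with_gene_body_dmr_recovers_planted_links(default_sim, default_dmrs):
    from oomics.expression import call_degs

    cfg, annotation, meth, matrix, truth = default_sim
    dmrs = default_dmrs["CHH"] + default_dmrs["CHG"]
    degs = call_degs(matrix, "MI", "MII")
    linked = {g for g, _ in truth.dmr_deg_links}
    called_up = set(degs.index[degs["deg"] & (degs["direction"] == "up")])
    recoverable = linked & called_up
    genes, frac, tallies = degs_with_gene_body_dmr(degs, dmrs, annotation, "up")
    assert recoverable <= genes
    assert frac >= len(recoverable) / max(1, len(called_up)) - 1e-9
    assert tallies["hyper"] >= len(recoverable)


def test_gene_body_meth_expr_oracle_and_degenerate(tiny_annotation):
    rows = []
    rng = np.random.default_rng(13)
    for g_start in (1_000, 10_000, 20_000):
        for k in range(30):
            pos = g_start + 100 * k
            t = int(rng.integers(1, 6))
            rows.append(("chr1", pos, "+", "CHH", int(rng.integers(0, t + 1)), t))
    pool = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                       "meth_count", "total_count"])
    fpkm = pd.Series({"g1": 5.0, "g2": 50.0, "g3": 0.5})
    pairs, r, p = gene_body_meth_expr(pool, fpkm, tiny_annotation, "CHH", min_coverage=1)
    assert len(pairs) == 3
    from oomics.methylome import methylation_level
    for row in pairs.itertuples():
        chrom, s, e = tiny_annotation.gene_body(row.gene_id)
        want = methylation_level(pool, (chrom, s, e), "CHH")
        assert row.meth_level == pytest.approx(want.level)
        assert row.log10_fpkm == pytest.approx(np.log10(fpkm[row.gene_id] + 1))
    # degenerate constant methylation -> r = 0 with warning
    flat = pool.copy()
    flat["meth_count"] = 0
    with pytest.warns(UserWarning, match="constant"):
        _, r0, _ = gene_body_meth_expr(flat, fpkm, tiny_annotation, "CHH", min_coverage=1)
    assert r0 == 0.0


def test_gene_body_meth_expr_positive_on_linked_simulation():
    """Genes whose bodies carry hypermethylated CHH DMRs are upregulated, so the
    MII gene-body CHH level correlates positively with MII expression."""
    from oomics import SimConfig, simulate_all
    from oomics.expression import merged_fpkm
    from oomics.methylome import pool_cells

    cfg = SimConfig(seed=13, frac_long_repeat_in_gene=0.6, frac_dmr_chh=1.0,
                    dmr_effect=0.4, n_cells_per_stage=5)
    annotation, meth, matrix, truth = simulate_all(cfg)
    assert len(truth.dmr_deg_links) >= 5
    fpkm = merged_fpkm(matrix)
    pool = pool_cells(meth.cells["MII"])
    pairs, r, p = gene_body_meth_expr(pool, fpkm["MII"], annotation, "CHH")
    assert r > 0 and p < 0.05


# --- TF triangulation ------------------------------------------------------

def test_triangulation_conjunction_semantics(tiny_annotation):
    genome = {"chr1": "A" * 40_000}
    motif = "AGGAAGTG"
    seq = genome["chr1"]
    genome["chr1"] = seq[:4_500] + motif + seq[4_500 + len(motif):]
    dmrs = [make_dmr("chr1", 4_000, 7_000)]
    fpkm = pd.DataFrame({"MI": [5.0, 0.0], "MII": [8.0, 0.0]}, index=["g1", "g2"])
    pwms = {"g1": PWM.from_consensus("g1", motif), "g2": PWM.from_consensus("g2", "TTCCGGAATTCC")}
    reports = {r.tf: r for r in tf_triangulate(fpkm, ["g1", "g2", "g9"], pwms, dmrs, genome)}
    assert reports["g1"].triangulated
    assert not reports["g2"].triangulated          # not expressed, no motif in DMR
    assert reports["g9"].motif_in_dmr is None      # no PWM -> unknown, excluded
    assert not reports["g9"].triangulated
    # empty partner list -> nothing triangulated
    none = tf_triangulate(fpkm, [], pwms, dmrs, genome)
    assert not any(r.triangulated for r in none)
    # removing the PWM hits drops the TF (conjunction)
    no_hits = tf_triangulate(fpkm, ["g1"], pwms, [make_dmr("chr1", 30_000, 33_000)], genome)
    assert not any(r.triangulated for r in no_hits)


def test_triangulation_is_intersection_monotone(tiny_annotation):
    genome = {"chr1": "ACGT" * 10_000}
    motif = "AGGAAGTG"
    genome["chr1"] = genome["chr1"][:4_500] + motif + genome["chr1"][4_508:]
    dmrs = [make_dmr("chr1", 4_000, 7_000)]
    fpkm = pd.DataFrame({"MI": [5.0, 5.0], "MII": [8.0, 8.0]}, index=["g1", "g2"])
    pwms = {g: PWM.from_consensus(g, motif) for g in ("g1", "g2")}
    full = {r.tf for r in tf_triangulate(fpkm, ["g1", "g2"], pwms, dmrs, genome)
            if r.triangulated}
    fewer_partners = {r.tf for r in tf_triangulate(fpkm, ["g1"], pwms, dmrs, genome)
                      if r.triangulated}
    fewer_pwms = {r.tf for r in tf_triangulate(fpkm, ["g1", "g2"],
                                               {"g1": pwms["g1"]}, dmrs, genome)
                  if r.triangulated}
    assert fewer_partners <= full and fewer_pwms <= full


def test_target_direction_tally_matches_triple_loop(tiny_annotation):
    genome = {"chr1": "A" * 40_000}
    motif = "AGGAAGTG"
    for pos in (2_000, 11_000):
        genome["chr1"] = genome["chr1"][:pos] + motif + genome["chr1"][pos + len(motif):]
    pwm = PWM.from_consensus("tf", motif)
    dmrs = [make_dmr("chr1", 1_500, 4_500, "hyper"),      # motif, overlaps g1
            make_dmr("chr1", 10_500, 13_500, "hypo"),     # motif, overlaps g2
            make_dmr("chr1", 20_500, 23_500, "hyper")]    # no motif, overlaps g3
    targets = ["g1", "g2", "g3"]
    n_with, n_hyper = tf_target_direction_tally("tf", targets, dmrs, tiny_annotation,
                                                genome, pwm)
    # brute force: gene x DMR x hit
    want_with = want_hyper = 0
    for gene in targets:
        chrom, s, e = tiny_annotation.gene_body(gene)
        hit_dirs = []
        for d in dmrs:
            if d.chrom == chrom and d.start < e and d.end > s:
                if pwm_scan(genome[d.chrom][d.start:d.end], pwm):
                    hit_dirs.append(d.direction)
        if hit_dirs:
            want_with += 1
            want_hyper += any(x == "hyper" for x in hit_dirs)
    assert (n_with, n_hyper) == (want_with, want_hyper) == (2, 1)
    assert tf_target_direction_tally("tf", [], dmrs, tiny_annotation, genome, pwm) == (0, 0)
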