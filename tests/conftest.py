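"""Shared fixtures: one full-size and one reduced simulation, reused across tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from oomics import SimConfig, simulate_all
from oomics.methylome import call_dmrs, pool_cells


@pytest.fixture(scope="session")
def default_sim():
    """Generator defaults: the study conditions the analysis assumes."""
    cfg = SimConfig(seed=11)
    annotation, meth, matrix, truth = simulate_all(cfg)
    return cfg, annotation, meth, matrix, truth


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced genome for the cheaper property checks."""
    return SimConfig(
        n_chroms=1,
        chrom_length=300_000,
        n_genes=15,
        n_cells_per_stage=4,
        n_planted_dmrs=8,
        n_planted_degs=8,
        lambda_n_sites=300,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return (small_cfg, *simulate_all(small_cfg))


@pytest.fixture(scope="session")
def default_dmrs(default_sim):
    """Non-CpG DMRs called on the default simulation, MII vs MI."""
    cfg, annotation, meth, matrix, truth = default_sim
    out = {}
    for ctx in ("CHH", "CHG"):
        out[ctx] = call_dmrs(meth.cells["MI"], meth.cells["MII"], ctx,
                             annotation.chrom_lengths)
    return out


@pytest.fixture(scope="session")
def default_pools(default_sim):
    _, _, meth, _, _ = default_sim
    return {stage: pool_cells(tables) for stage, tables in meth.cells.items()}


def recovery_rate(called, planted: pd.DataFrame) -> float:
    """Fraction of planted intervals overlapped by >= 1 called DMR of the same context."""
    if not len(planted):
        return float("nan")
    hit = 0
    for row in planted.itertuples():
        if any(d.chrom == row.chrom and d.start < row.end and d.end > row.start
               and d.context == row.context for d in called):
            hit += 1
    return hit / len(planted)
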