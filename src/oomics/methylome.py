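"""Per-context methylation levels and sliding-window DMR calling.

Single-cell bisulfite data is far too sparse for per-site, per-cell
testing, so cells of a stage are pooled (counts summed per site) before
any statistics are computed. Differential methylation is then assessed in
3 kb windows stepped every 600 bp across the genome, one cytosine context
(CpG, CHG, CHH) at a time:

1. pool cells within each group;
2. tile each chromosome with windows;
3. per window, two-sided Fisher exact test (doubling rule) on the 2x2
   table of pooled (methylated, unmethylated) counts, provided both
   groups reach a minimum pooled coverage — windows below it are
   untestable and excluded from the multiple-testing universe;
4. Benjamini-Hochberg across testable windows;
5. keep windows with q <= q_max and |delta| >= delta_min;
6. merge overlapping kept windows of the same direction into DMRs.

Strands are counted independently and never collapsed, for all contexts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CONTEXTS = ("CpG", "CHG", "CHH")

#: Window geometry and significance defaults of the caller.
WINDOW_WIDTH = 3_000
WINDOW_STEP = 600
Q_MAX = 0.05
DELTA_MIN = 0.10
MIN_COVERAGE = 10

CALL_COLUMNS = ["chrom", "pos", "strand", "context", "meth_count", "total_count"]


class MethylationLevel(NamedTuple):
    level: float
    coverage: int


@dataclass(frozen=True)
class DMR:
    """Merged differential window: hyper/hypo refers to the later stage (group B)."""

    chrom: str
    start: int
    end: int
    context: str
    direction: str  # "hyper" | "hypo"
    level_a: float
    level_b: float
    delta: float
    q: float
    n_windows: int

    def __post_init__(self) -> None:
        sign = 1.0 if self.direction == "hyper" else -1.0
        if self.delta * sign < 0:
            raise ValueError("delta sign inconsistent with direction")


def conversion_efficiency(spikein_calls: pd.DataFrame) -> float:
    """Bisulfite conversion efficiency from unmethylated lambda spike-ins.

    Lambda phage DNA carries no methylation, so every methylated call on it
    is a conversion failure: efficiency = 1 − Σmeth / Σtotal. Libraries are
    expected to exceed 0.98 (see :data:`CONVERSION_QC_THRESHOLD`).
    """
    total = int(spikein_calls["total_count"].sum())
    if total == 0:
        raise ValueError("conversion efficiency undefined: zero spike-in coverage")
    return 1.0 - float(spikein_calls["meth_count"].sum()) / total


CONVERSION_QC_THRESHOLD = 0.98


def passes_conversion_qc(spikein_calls: pd.DataFrame, threshold: float = CONVERSION_QC_THRESHOLD) -> bool:
    return conversion_efficiency(spikein_calls) > threshold


def pool_cells(tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Sum per-site counts across cells (a stage's pooled profile).

    Sites are keyed by (chrom, pos, strand); context rides along unchanged.
    Pooling is associative: pooling pools equals pooling all cells at once.
    """
    tables = [t[CALL_COLUMNS] for t in tables]
    if not tables:
        raise ValueError("no cells to pool")
    cat = pd.concat(tables, ignore_index=True)
    pooled = (
        cat.groupby(["chrom", "pos", "strand", "context"], sort=True, observed=True)[
            ["meth_count", "total_count"]
        ]
        .sum()
        .reset_index()
    )
    return pooled


def methylation_level(
    calls: pd.DataFrame,
    region: Optional[tuple] = None,
    context: Optional[str] = None,
) -> Optional[MethylationLevel]:
    """Coverage-weighted methylation level over in-region, in-context sites.

    Returns ``None`` when no covered site qualifies — "no data" is distinct
    from a level of 0.
    """
    sub = calls
    if context is not None:
        sub = sub[sub["context"] == context]
    if region is not None:
        chrom, start, end = region
        sub = sub[(sub["chrom"] == chrom) & (sub["pos"] >= start) & (sub["pos"] < end)]
    total = int(sub["total_count"].sum())
    if total == 0:
        return None
    return MethylationLevel(float(sub["meth_count"].sum()) / total, total)


def sliding_windows(
    chrom_lengths: Dict[str, int], width: int = WINDOW_WIDTH, step: int = WINDOW_STEP
) -> pd.DataFrame:
    """Tile every chromosome with fixed-width windows.

    Starts at 0, step, 2*step, ...; if the last regular window ends before
    the chromosome end, one terminal window [L − width, L) is appended so
    the whole genome is covered. Chromosomes shorter than the width get a
    single truncated window [0, L).
    """
    if not (0 < step <= width):
        raise ValueError("require width >= step > 0")
    rows = []
    for chrom in sorted(chrom_lengths):
        length = int(chrom_lengths[chrom])
        if length < width:
            rows.append((chrom, 0, length))
            continue
        n = (length - width) // step + 1
        starts = [i * step for i in range(n)]
        for s in starts:
            rows.append((chrom, s, s + width))
        if starts[-1] + width < length:
            rows.append((chrom, length - width, length))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def fisher_two_sided(meth_a, unmeth_a, meth_b, unmeth_b):
    """Two-sided Fisher exact p via the doubling rule, vectorised.

    The hypergeometric null conditions on the margins of the 2x2 table
    [[meth_a, unmeth_a], [meth_b, unmeth_b]]; the two-sided p-value is
    twice the smaller tail probability, capped at 1.
    """
    meth_a = np.asarray(meth_a, dtype=np.int64)
    unmeth_a = np.asarray(unmeth_a, dtype=np.int64)
    meth_b = np.asarray(meth_b, dtype=np.int64)
    unmeth_b = np.asarray(unmeth_b, dtype=np.int64)
    total = meth_a + unmeth_a + meth_b + unmeth_b
    n_meth = meth_a + meth_b
    draws = meth_a + unmeth_a
    lower = stats.hypergeom.cdf(meth_a, total, n_meth, draws)
    upper = stats.hypergeom.sf(meth_a - 1, total, n_meth, draws)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


class WindowStat(NamedTuple):
    chrom: str
    start: int
    end: int
    level_a: float
    level_b: float
    delta: float
    coverage_a: int
    coverage_b: int
    p: float


def test_window(
    pool_a: pd.DataFrame,
    pool_b: pd.DataFrame,
    window: tuple,
    context: str,
    min_coverage: int = MIN_COVERAGE,
) -> Optional[WindowStat]:
    """Fisher test of one window on two pooled profiles; None if untestable."""
    chrom, start, end = window

    def _sums(pool: pd.DataFrame) -> tuple[int, int]:
        sub = pool[(pool["context"] == context) & (pool["chrom"] == chrom)
                   & (pool["pos"] >= start) & (pool["pos"] < end)]
        return int(sub["meth_count"].sum()), int(sub["total_count"].sum())

    ma, ta = _sums(pool_a)
    mb, tb = _sums(pool_b)
    if ta == 0 or tb == 0 or ta < min_coverage or tb < min_coverage:
        return None
    p = float(fisher_two_sided(ma, ta - ma, mb, tb - mb))
    return WindowStat(chrom, start, end, ma / ta, mb / tb, mb / tb - ma / ta, ta, tb, p)


test_window.__test__ = False  # not a pytest case despite the domain name


def _window_sums(pool: pd.DataFrame, windows: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-window (meth, total) sums via cumulative sums over sorted sites."""
    meth_out = np.zeros(len(windows), dtype=np.int64)
    total_out = np.zeros(len(windows), dtype=np.int64)
    for chrom, widx in windows.groupby("chrom", sort=False).groups.items():
        sub = pool[pool["chrom"] == chrom].sort_values("pos")
        pos = sub["pos"].to_numpy()
        cmeth = np.concatenate([[0], np.cumsum(sub["meth_count"].to_numpy())])
        ctotal = np.concatenate([[0], np.cumsum(sub["total_count"].to_numpy())])
        w = windows.loc[widx]
        lo = np.searchsorted(pos, w["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, w["end"].to_numpy(), side="left")
        meth_out[windows.index.get_indexer(widx)] = cmeth[hi] - cmeth[lo]
        total_out[windows.index.get_indexer(widx)] = ctotal[hi] - ctotal[lo]
    return meth_out, total_out


def window_statistics(
    pool_a: pd.DataFrame,
    pool_b: pd.DataFrame,
    context: str,
    chrom_lengths: Dict[str, int],
    width: int = WINDOW_WIDTH,
    step: int = WINDOW_STEP,
    min_coverage: int = MIN_COVERAGE,
) -> pd.DataFrame:
    """Testable-window table with delta, p and BH q for one context."""
    a = pool_a[pool_a["context"] == context]
    b = pool_b[pool_b["context"] == context]
    windows = sliding_windows(chrom_lengths, width, step)
    meth_a, total_a = _window_sums(a, windows)
    meth_b, total_b = _window_sums(b, windows)
    testable = (total_a >= max(min_coverage, 1)) & (total_b >= max(min_coverage, 1))
    out = windows.loc[testable].copy()
    if out.empty:
        logger.warning("no testable %s windows (min coverage %d)", context, min_coverage)
        for col in ("level_a", "level_b", "delta", "p", "q"):
            out[col] = pd.Series(dtype=float)
        return out
    ma, ta = meth_a[testable], total_a[testable]
    mb, tb = meth_b[testable], total_b[testable]
    out["level_a"] = ma / ta
    out["level_b"] = mb / tb
    out["delta"] = out["level_b"] - out["level_a"]
    out["coverage_a"] = ta
    out["coverage_b"] = tb
    out["p"] = fisher_two_sided(ma, ta - ma, mb, tb - mb)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.reset_index(drop=True)


def merge_significant_windows(
    windows: pd.DataFrame,
    pool_a: pd.DataFrame,
    pool_b: pd.DataFrame,
    context: str,
    q_max: float = Q_MAX,
    delta_min: float = DELTA_MIN,
) -> List[DMR]:
    """Merge overlapping significant same-direction windows into DMRs.

    Levels are recomputed over each merged interval from the pooled
    profiles; the DMR q is the smallest constituent-window q.
    """
    sig = windows[(windows["q"] <= q_max) & (windows["delta"].abs() >= delta_min)]
    a = pool_a[pool_a["context"] == context]
    b = pool_b[pool_b["context"] == context]
    dmrs: List[DMR] = []
    for direction, sign in (("hyper", 1), ("hypo", -1)):
        part = sig[np.sign(sig["delta"]) == sign]
        for chrom, sub in part.groupby("chrom", sort=True):
            sub = sub.sort_values("start")
            runs: List[list] = []  # [start, end, min_q, n]
            for _, row in sub.iterrows():
                if runs and row["start"] < runs[-1][1]:
                    runs[-1][1] = max(runs[-1][1], int(row["end"]))
                    runs[-1][2] = min(runs[-1][2], float(row["q"]))
                    runs[-1][3] += 1
                else:
                    runs.append([int(row["start"]), int(row["end"]), float(row["q"]), 1])
            for start, end, q, n in runs:
                la = methylation_level(a, (chrom, start, end))
                lb = methylation_level(b, (chrom, start, end))
                assert la is not None and lb is not None
                dmrs.append(
                    DMR(chrom, start, end, context, direction,
                        la.level, lb.level, lb.level - la.level, q, n)
                )
    dmrs.sort(key=lambda d: (d.chrom, d.start, d.end, d.direction))
    return dmrs


def call_dmrs(
    cells_a: Sequence[pd.DataFrame],
    cells_b: Sequence[pd.DataFrame],
    context: str,
    chrom_lengths: Dict[str, int],
    width: int = WINDOW_WIDTH,
    step: int = WINDOW_STEP,
    q_max: float = Q_MAX,
    delta_min: float = DELTA_MIN,
    min_coverage: int = MIN_COVERAGE,
) -> List[DMR]:
    """Call merged DMRs between two groups of cells for one context.

    Group B is conventionally the later maturation stage, so ``hyper``
    means higher methylation in the more mature cells.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}; expected one of {CONTEXTS}")
    if not cells_a or not cells_b:
        raise ValueError("need at least one cell per group")
    pool_a = pool_cells(cells_a)
    pool_b = pool_cells(cells_b)
    windows = window_statistics(pool_a, pool_b, context, chrom_lengths,
                                width, step, min_coverage)
    if windows.empty:
        logger.warning("call_dmrs: no testable windows for context %s", context)
        return []
    return merge_significant_windows(windows, pool_a, pool_b, context, q_max, delta_min)


def dmrs_to_frame(dmrs: Sequence[DMR]) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "context", "direction",
            "level_a", "level_b", "delta", "q", "n_windows"]
    return pd.DataFrame([{c: getattr(d, c) for c in cols} for d in dmrs], columns=cols)
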