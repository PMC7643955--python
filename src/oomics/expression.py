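"""Expression normalization, expressed/stage-specific sets, and differential expression.

Counts are normalized to TPM per cell and FPKM per cell or per merged
stage (cells of a stage summed into one pseudo-library before FPKM, the
way sparse single oocytes are usually combined). Differential expression
uses a self-contained negative-binomial Wald test with library-size
offsets and a method-of-moments common dispersion; genes are flagged as
differential at BH-adjusted p <= 0.05 and |log2 fold change| >= 1
(fold change >= 2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

EXPRESSED_FPKM = 1.0
DEG_Q_MAX = 0.05
DEG_MIN_ABS_L2FC = 1.0
#: pseudo-mean added to normalized group means before the log-ratio
LOG2FC_PSEUDO = 0.5


@dataclass
class CountMatrix:
    """Gene x cell raw counts with gene effective lengths and a cell→stage map."""

    counts: pd.DataFrame          # genes x cells, non-negative integers
    lengths: pd.Series            # bp per gene, > 0
    cell_stage: pd.Series         # cell id -> stage label

    def __post_init__(self) -> None:
        if not self.lengths.index.equals(self.counts.index):
            self.lengths = self.lengths.loc[self.counts.index]
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.cell_stage.index)
        if missing:
            raise ValueError(f"cells without a stage: {sorted(missing)}")

    def cells_of(self, stage: str) -> list:
        return [c for c in self.counts.columns if self.cell_stage[c] == stage]

    @property
    def stages(self) -> list:
        seen = []
        for c in self.counts.columns:
            s = self.cell_stage[c]
            if s not in seen:
                seen.append(s)
        return seen


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-normalized rates scaled to 1e6 per cell."""
    lengths = lengths.loc[counts.index].astype(float)
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    zero = denom == 0
    if zero.any():
        warnings.warn(f"all-zero cells in TPM: {list(denom.index[zero])}")
        denom = denom.replace(0, np.nan)
    tpm = rate.div(denom, axis=1) * 1e6
    return tpm.fillna(0.0)


def compute_fpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase per million mapped, per library (column)."""
    lengths = lengths.loc[counts.index].astype(float)
    n = counts.sum(axis=0)
    if (n == 0).any():
        raise ValueError(f"zero total counts in libraries: {list(n.index[n == 0])}")
    return counts.div(lengths, axis=0).div(n, axis=1) * 1e9


def merged_fpkm(matrix: CountMatrix) -> pd.DataFrame:
    """FPKM per stage after summing counts across the stage's cells."""
    merged = pd.DataFrame(
        {stage: matrix.counts[matrix.cells_of(stage)].sum(axis=1) for stage in matrix.stages}
    )
    return compute_fpkm(merged, matrix.lengths)


def expressed_set(fpkm: pd.DataFrame, threshold: float = EXPRESSED_FPKM) -> Dict[str, Set[str]]:
    """Genes with FPKM >= threshold, per stage (column)."""
    return {stage: set(fpkm.index[fpkm[stage] >= threshold]) for stage in fpkm.columns}


def stage_specific(fpkm: pd.DataFrame, threshold: float = EXPRESSED_FPKM) -> Dict[str, Set[str]]:
    """Genes expressed in exactly one stage: >= threshold there, < threshold elsewhere."""
    if fpkm.shape[1] < 2:
        raise ValueError("stage specificity needs at least two stages")
    on = fpkm >= threshold
    single = on.sum(axis=1) == 1
    return {stage: set(fpkm.index[single & on[stage]]) for stage in fpkm.columns}


def count_degs_by_direction(degs: pd.DataFrame,
                            q_max: float = DEG_Q_MAX,
                            min_abs_l2fc: float = DEG_MIN_ABS_L2FC) -> Dict[str, int]:
    """Up/down tallies from a DEG table under the standard thresholds.

    Accepts any table with ``log2fc`` and ``q`` columns (e.g. a published
    differential-expression list) and recounts significant genes per
    direction.
    """
    sig = degs[(degs["q"] <= q_max) & (degs["log2fc"].abs() >= min_abs_l2fc)]
    return {"up": int((sig["log2fc"] > 0).sum()), "down": int((sig["log2fc"] < 0).sum())}


def _size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors, robust to composition shifts.

    Each cell's factor is the median ratio of its counts to the per-gene
    geometric mean across cells (genes with any zero excluded); this keeps
    a large block of truly differential genes from dragging the scaling of
    the unchanged majority. Falls back to total-count scaling when too few
    genes are everywhere non-zero.
    """
    totals = counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        raise ValueError("cannot normalize a cell with zero total counts")
    arr = counts.to_numpy(dtype=float)
    everywhere = (arr > 0).all(axis=1)
    if everywhere.sum() >= 10:
        log = np.log(arr[everywhere])
        ratios = log - log.mean(axis=1, keepdims=True)
        sf = pd.Series(np.exp(np.median(ratios, axis=0)), index=counts.columns)
    else:
        sf = totals
    return sf / np.exp(np.log(sf).mean())


def estimate_common_dispersion(counts: pd.DataFrame, groups: Sequence[Sequence[str]]) -> float:
    """Method-of-moments NB dispersion shared across genes.

    For normalized counts y with mean mu, Var(y) ≈ mu + alpha mu^2 within a
    group; alpha is estimated per gene from pooled within-group moments and
    summarized by the median over informative genes.
    """
    sf = _size_factors(counts)
    y = counts / sf
    mus, variances, weights = [], [], []
    for cells in groups:
        sub = y[list(cells)]
        if sub.shape[1] < 2:
            continue
        mus.append(sub.mean(axis=1))
        variances.append(sub.var(axis=1, ddof=1))
        weights.append(sub.shape[1] - 1)
    if not mus:
        raise ValueError("dispersion estimation needs a group with >= 2 cells")
    mu = sum(m * w for m, w in zip(mus, weights)) / sum(weights)
    var = sum(v * w for v, w in zip(variances, weights)) / sum(weights)
    ok = mu > 1.0
    if not ok.any():
        return 1e-8
    alpha = ((var[ok] - mu[ok]) / mu[ok] ** 2).to_numpy()
    alpha = alpha[np.isfinite(alpha)]
    est = float(np.median(alpha)) if alpha.size else 0.0
    return float(np.clip(est, 1e-8, 10.0))


def call_degs(
    matrix: CountMatrix,
    stage_a: str,
    stage_b: str,
    q_max: float = DEG_Q_MAX,
    min_abs_l2fc: float = DEG_MIN_ABS_L2FC,
) -> pd.DataFrame:
    """NB Wald test of stage B over stage A, BH-corrected.

    Per gene: group means of size-factor-normalized counts; log2FC on
    pseudo-shifted means; Wald z from a delta-method standard error with
    the common dispersion; genes with zero counts in both groups are
    excluded from the testing universe. Returns a frame indexed by gene
    with log2fc, p, q, direction and the ``deg`` flag
    (q <= q_max and |log2fc| >= min_abs_l2fc).
    """
    cells_a = matrix.cells_of(stage_a)
    cells_b = matrix.cells_of(stage_b)
    if len(cells_a) < 2 or len(cells_b) < 2:
        raise ValueError("need >= 2 cells per stage for differential expression")
    counts = matrix.counts[cells_a + cells_b]
    sf = _size_factors(counts)
    y = counts / sf
    ya, yb = y[cells_a], y[cells_b]
    mu_a, mu_b = ya.mean(axis=1), yb.mean(axis=1)

    tested = (counts[cells_a].sum(axis=1) + counts[cells_b].sum(axis=1)) > 0
    alpha = estimate_common_dispersion(counts, [cells_a, cells_b])

    l2fc = np.log2((mu_b + LOG2FC_PSEUDO) / (mu_a + LOG2FC_PSEUDO))

    inv_sf_a = float((1.0 / sf[cells_a]).sum())
    inv_sf_b = float((1.0 / sf[cells_b]).sum())
    var_mu_a = (mu_a * inv_sf_a + alpha * mu_a**2 * len(cells_a)) / len(cells_a) ** 2
    var_mu_b = (mu_b * inv_sf_b + alpha * mu_b**2 * len(cells_b)) / len(cells_b) ** 2
    se = np.sqrt(var_mu_a / (mu_a + LOG2FC_PSEUDO) ** 2
                 + var_mu_b / (mu_b + LOG2FC_PSEUDO) ** 2) / np.log(2)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, l2fc / se, 0.0)
    p = pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=counts.index)
    p[l2fc == 0] = 1.0

    out = pd.DataFrame({
        "base_mean": (mu_a + mu_b) / 2,
        "mean_a": mu_a,
        "mean_b": mu_b,
        "log2fc": l2fc,
        "p": p,
    })
    out = out[tested].copy()
    out["q"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    out["direction"] = np.where(out["log2fc"] > 0, "up",
                                np.where(out["log2fc"] < 0, "down", "none"))
    out["deg"] = (out["q"] <= q_max) & (out["log2fc"].abs() >= min_abs_l2fc)
    out.index.name = "gene_id"
    return out


def pca_embedding(expr: pd.DataFrame, top_n: int = 1000) -> Tuple[pd.DataFrame, np.ndarray]:
    """PCA of cells on the top expressed genes.

    Genes (rows) are ranked by mean expression across cells, the top_n kept,
    log2(x + 1)-transformed and centered; returns per-cell coordinates and
    the explained-variance ratios (non-increasing).
    """
    if expr.shape[1] < 2:
        raise ValueError("PCA needs at least two cells")
    top_n = min(top_n, expr.shape[0])
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    top = expr.loc[expr.mean(axis=1).sort_values(ascending=False, kind="mergesort").index[:top_n]]
    x = np.log2(top.to_numpy(dtype=float).T + 1.0)
    n_comp = min(x.shape[0], x.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(x - x.mean(axis=0))
    frame = pd.DataFrame(coords, index=expr.columns,
                         columns=[f"PC{i + 1}" for i in range(coords.shape[1])])
    return frame, pca.explained_variance_ratio_
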