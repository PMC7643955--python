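"""Simulation and pipeline configuration.

The defaults of :class:`SimConfig` define the study conditions the rest of
the package is exercised against: three oocyte maturation stages (GV, MI,
MII), a handful of cells per stage, sparse per-cytosine coverage, CpG
methylation that is stable across stages, non-CpG methylation that doubles
in the mature MII stage, hypermethylated non-CpG regions planted
preferentially inside repeat elements, and expression effects confined to
the MII stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

IMMATURE_STAGES = ("GV", "MI")
MATURE_STAGE = "MII"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic multi-omics generator.

    All genomic fractions are in [0, 1]; lengths are in base pairs.
    ``noncpg_mean_mature`` must exceed ``noncpg_mean_immature`` (non-CpG
    methylation rises as the oocyte matures; by default it doubles).
    """

    # genome / annotation
    n_chroms: int = 2
    chrom_length: int = 500_000
    n_genes: int = 50
    gene_length_range: Tuple[int, int] = (3_000, 7_000)
    exons_per_gene: Tuple[int, int] = (2, 4)
    repeat_fraction: float = 0.25
    accessible_fraction: float = 0.30
    # fraction of long (LINE1-like) repeats that overlap gene bodies, the
    # route by which planted DMRs become gene-body DMRs
    frac_long_repeat_in_gene: float = 0.30

    # cells and stages
    stages: Tuple[str, ...] = ("GV", "MI", "MII")
    n_cells_per_stage: int = 7

    # methylome
    cpg_mean: float = 0.70
    noncpg_mean_immature: float = 0.03
    noncpg_mean_mature: float = 0.06
    coverage_rate: float = 2.0
    cell_level_sd: float = 0.0  # per-cell logit jitter; 0 = pure binomial

    # planted differential methylation (hyper in MII, non-CpG)
    n_planted_dmrs: int = 30
    dmr_length: int = 3_000
    dmr_effect: float = 0.30
    frac_dmr_in_repeats: float = 0.90
    frac_dmr_chh: float = 0.70
    frac_dmr_with_motif: float = 0.80
    tf_motif: str = "AGGAAGTG"

    # lambda phage spike-in (unmethylated control)
    lambda_n_sites: int = 2_000
    lambda_coverage: float = 20.0
    lambda_failure_rate: float = 0.005

    # transcriptome
    n_planted_degs: int = 30
    deg_log2fc_range: Tuple[float, float] = (1.5, 3.0)
    frac_deg_down: float = 0.75
    deg_min_base_mean: float = 5.0
    nb_dispersion: float = 0.10
    count_meanlog: float = 4.0
    count_sdlog: float = 1.0
    libsize_sdlog: float = 0.30

    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "cpg_mean": self.cpg_mean,
            "noncpg_mean_immature": self.noncpg_mean_immature,
            "noncpg_mean_mature": self.noncpg_mean_mature,
            "repeat_fraction": self.repeat_fraction,
            "accessible_fraction": self.accessible_fraction,
            "frac_dmr_in_repeats": self.frac_dmr_in_repeats,
            "frac_dmr_chh": self.frac_dmr_chh,
            "frac_dmr_with_motif": self.frac_dmr_with_motif,
            "frac_deg_down": self.frac_deg_down,
            "frac_long_repeat_in_gene": self.frac_long_repeat_in_gene,
            "lambda_failure_rate": self.lambda_failure_rate,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.noncpg_mean_mature <= self.noncpg_mean_immature:
            raise ValueError(
                "noncpg_mean_mature must exceed noncpg_mean_immature "
                f"({self.noncpg_mean_mature} <= {self.noncpg_mean_immature})"
            )
        if self.chrom_length < self.dmr_length:
            raise ValueError("chrom_length must be >= dmr_length")
        for name in ("n_chroms", "chrom_length", "n_genes", "n_cells_per_stage",
                     "n_planted_dmrs", "n_planted_degs", "lambda_n_sites"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.coverage_rate < 0 or self.lambda_coverage < 0:
            raise ValueError("coverage rates must be non-negative")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if len(self.stages) < 2:
            raise ValueError("need at least two stages")
        lo, hi = self.deg_log2fc_range
        if lo > hi or lo < 0:
            raise ValueError("deg_log2fc_range must be 0 <= lo <= hi")
        if set(self.tf_motif) - set("ACGT"):
            raise ValueError("tf_motif must be an ACGT string")

    @property
    def immature_stages(self) -> Tuple[str, ...]:
        return tuple(s for s in self.stages if s != MATURE_STAGE)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("gene_length_range", "exons_per_gene", "deg_log2fc_range", "stages"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)
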