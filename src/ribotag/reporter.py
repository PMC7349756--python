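"""Absolute reporter-transcript quantification from digital PCR.

A digital PCR reaction partitions the template over many microreactions;
with molecules Poisson-distributed across partitions of volume v, the
positive fraction f estimates 1 - exp(-lambda) and the mean copies per
partition is lambda = -ln(1 - f), giving a concentration lambda / v in
copies/µL.  The 95% interval is the Clopper-Pearson binomial interval on
f pushed through the same transform.

Each cell type in the co-culture expresses exactly one reporter (GFP or
mCherry), so the mCherry/GFP concentration ratio tracks the cell-type
mixture of an RNA sample, and the fold difference of that ratio between
the two IPs measures how well the IPs separated the two translatomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .sim import DpcrPartitions

__all__ = [
    "SaturatedReactionError",
    "ReporterQuant",
    "RatioRecord",
    "FoldDifference",
    "dpcr_concentration",
    "reporter_ratio",
    "fold_difference",
    "reporter_ratio_from_counts",
    "read_partitions",
]


class SaturatedReactionError(ValueError):
    """All partitions positive: the concentration is unbounded above."""


@dataclass
class ReporterQuant:
    sample_id: str
    target: str
    concentration: float  # copies/µL
    ci_low: float
    ci_high: float


@dataclass
class RatioRecord:
    sample_id: str
    context: str
    mcherry_gfp_ratio: float | None
    flag: str | None = None

    @property
    def defined(self) -> bool:
        return self.mcherry_gfp_ratio is not None


@dataclass
class FoldDifference:
    fold: float
    direction: str


def _lambda(fraction: float) -> float:
    return -math.log1p(-fraction)


def dpcr_concentration(partitions: DpcrPartitions, alpha: float = 0.05) -> ReporterQuant:
    """Poisson point estimate and binomial 95% interval in copies/µL."""
    if partitions.n_positive >= partitions.n_total:
        raise SaturatedReactionError(
            f"{partitions.target}: all {partitions.n_total} partitions positive"
        )
    f = partitions.n_positive / partitions.n_total
    v = partitions.partition_volume_ul
    conc = _lambda(f) / v
    lo, hi = proportion_confint(
        partitions.n_positive, partitions.n_total, alpha=alpha, method="beta"
    )
    hi = min(hi, 1.0 - 1e-12)  # keep the transform finite
    return ReporterQuant(
        sample_id=partitions.sample_id,
        target=partitions.target,
        concentration=conc,
        ci_low=_lambda(lo) / v,
        ci_high=_lambda(hi) / v,
    )


def reporter_ratio(
    mcherry: ReporterQuant, gfp: ReporterQuant, context: str = ""
) -> RatioRecord:
    """mCherry/GFP concentration ratio; undetected GFP is flagged, not 0-divided."""
    sample_id = mcherry.sample_id or gfp.sample_id
    if gfp.concentration <= 0:
        return RatioRecord(sample_id, context, None, flag="GFP not detected")
    if mcherry.concentration <= 0:
        return RatioRecord(sample_id, context, None, flag="mCherry not detected")
    return RatioRecord(sample_id, context, mcherry.concentration / gfp.concentration)


def fold_difference(ratio_a: RatioRecord, ratio_b: RatioRecord) -> FoldDifference:
    """Fold difference (>= 1) between two mCherry/GFP ratios, with direction."""
    if not (ratio_a.defined and ratio_b.defined):
        raise ValueError("both ratios must be defined to form a fold difference")
    a, b = ratio_a.mcherry_gfp_ratio, ratio_b.mcherry_gfp_ratio
    if a >= b:
        return FoldDifference(a / b, f"{ratio_a.context or 'a'} over {ratio_b.context or 'b'}")
    return FoldDifference(b / a, f"{ratio_b.context or 'b'} over {ratio_a.context or 'a'}")


def reporter_ratio_from_counts(
    counts: pd.DataFrame,
    sample_id: str,
    mcherry_gene: str = "mCherry",
    gfp_gene: str = "GFP",
    context: str = "",
) -> RatioRecord:
    """Sequencing-based proxy: ratio of reporter read counts in one sample."""
    for g in (mcherry_gene, gfp_gene):
        if g not in counts.index:
            raise KeyError(f"reporter gene {g!r} not in count matrix")
    gfp = int(counts.loc[gfp_gene, sample_id])
    mch = int(counts.loc[mcherry_gene, sample_id])
    if gfp == 0:
        return RatioRecord(sample_id, context, None, flag="GFP reads absent")
    if mch == 0:
        return RatioRecord(sample_id, context, None, flag="mCherry reads absent")
    return RatioRecord(sample_id, context, mch / gfp)


def read_partitions(path) -> list[DpcrPartitions]:
    """Read a partitions TSV (sample_id, target, n_total, n_positive, partition_volume_ul)."""
    df = pd.read_csv(path, sep="\t")
    required = ["sample_id", "target", "n_total", "n_positive", "partition_volume_ul"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        DpcrPartitions(
            target=row["target"],
            n_total=int(row["n_total"]),
            n_positive=int(row["n_positive"]),
            partition_volume_ul=float(row["partition_volume_ul"]),
            sample_id=str(row["sample_id"]),
        )
        for _, row in df.iterrows()
    ]
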