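"""Chromosome- and species-level read composition and IP-vs-input deltas.

Every downstream statistic starts from the same quantity: the percent of a
library's uniquely assigned reads on each chromosome.  The IP minus input
difference of those percentages, plotted against the input percentage, is
the scatter whose off-target regression slope defines the depletion
efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneTable, ValidationError, REPORTER_SPECIES

__all__ = [
    "ChromProportions",
    "chrom_proportions",
    "species_composition",
    "delta_table",
    "gene_delta",
]

MODES = ("all_genes", "protein_coding_only", "chromosome_level")


@dataclass
class ChromProportions:
    """Percent of one library's reads per chromosome (0-100 scale)."""

    sample_id: str
    mode: str
    percent: pd.Series  # index: chromosome

    def validate(self) -> None:
        total = float(self.percent.sum())
        if abs(total - 100.0) > 1e-9:
            raise ValidationError(
                f"{self.sample_id}: chromosome percentages sum to {total}, not 100"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "chromosome": self.percent.index,
                "percent": self.percent.to_numpy(),
                "mode": self.mode,
            }
        )


def _aggregate_gene_counts(
    counts: pd.DataFrame, gene_table: GeneTable, sample_id: str, mode: str
) -> pd.Series:
    col = counts[sample_id]
    ann = gene_table.df.loc[counts.index]
    if mode == "protein_coding_only":
        keep = ann["biotype"] == "protein_coding"
        col = col[keep.to_numpy()]
        ann = ann[keep]
    return col.groupby(ann["chromosome"], sort=False).sum()


def chrom_proportions(
    counts,
    gene_table: GeneTable,
    sample_id: str,
    mode: str = "all_genes",
    include_reporters: bool = False,
) -> ChromProportions:
    """Percent of the library represented by each chromosome.

    ``counts`` is either a genes x samples matrix (modes ``all_genes`` and
    ``protein_coding_only``) or a chromosomes x samples table
    (``chromosome_level``, the samtools-idxstats path).  Reporter contigs
    (GFP/mCherry) are excluded from numerator and denominator unless
    ``include_reporters`` — they are cell-type markers, not chromosomes of
    either species, and are analysed separately.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if sample_id not in counts.columns:
        raise KeyError(f"sample {sample_id!r} not in counts")
    if mode == "chromosome_level":
        known = set(gene_table.chrom_species().index)
        extra = set(counts.index) - known
        if extra:
            raise ValidationError(
                f"chromosome-level counts contain unknown chromosome {sorted(extra)[0]!r}"
            )
        per_chrom = counts[sample_id].copy()
    else:
        missing = counts.index.difference(gene_table.genes)
        if len(missing):
            raise ValidationError(f"counts contain unannotated gene {missing[0]!r}")
        per_chrom = _aggregate_gene_counts(counts, gene_table, sample_id, mode)
    if not include_reporters:
        cs = gene_table.chrom_species()
        reporter_chroms = cs.index[cs == REPORTER_SPECIES]
        per_chrom = per_chrom.drop(reporter_chroms, errors="ignore")
    total = float(per_chrom.sum())
    if total <= 0:
        raise ValidationError(f"sample {sample_id!r}: empty library in mode {mode!r}")
    percent = 100.0 * per_chrom / total
    percent.index.name = "chromosome"
    props = ChromProportions(sample_id=sample_id, mode=mode, percent=percent)
    props.validate()
    return props


def species_composition(props: ChromProportions, gene_table: GeneTable) -> pd.Series:
    """Per-species percent of the library (reporters excluded; sums to 100)."""
    cs = gene_table.chrom_species()
    species = cs.reindex(props.percent.index)
    keep = species != REPORTER_SPECIES
    by_species = props.percent[keep.to_numpy()].groupby(species[keep], sort=False).sum()
    total = float(by_species.sum())
    if total <= 0:
        raise ValidationError("no species-assigned reads")
    out = 100.0 * by_species / total
    out.index.name = "species"
    return out


def delta_table(
    input_props: ChromProportions,
    ip_props: ChromProportions,
    gene_table: GeneTable,
    on_target_species: str,
) -> pd.DataFrame:
    """Per-chromosome change in percent of library, IP minus input.

    Output columns: chromosome, species, is_mito, initial_percent (input),
    delta_percent (IP - input), target_class ("on" for chromosomes of
    ``on_target_species``, "off" otherwise).  Under a shared denominator
    the deltas sum to zero.
    """
    if input_props.mode != ip_props.mode:
        raise ValidationError(
            f"mode mismatch: input {input_props.mode!r} vs IP {ip_props.mode!r}"
        )
    if set(input_props.percent.index) != set(ip_props.percent.index):
        raise ValidationError("input and IP tables cover different chromosome sets")
    chroms = input_props.percent.index
    cs = gene_table.chrom_species().reindex(chroms)
    mito = gene_table.chrom_is_mito().reindex(chroms)
    initial = input_props.percent
    delta = ip_props.percent.reindex(chroms) - initial
    out = pd.DataFrame(
        {
            "chromosome": chroms,
            "species": cs.to_numpy(),
            "is_mito": mito.to_numpy(),
            "initial_percent": initial.to_numpy(),
            "delta_percent": delta.to_numpy(),
            "target_class": np.where(cs.to_numpy() == on_target_species, "on", "off"),
        }
    ).reset_index(drop=True)
    return out


def gene_delta(
    counts: pd.DataFrame,
    gene_table: GeneTable,
    input_sample: str,
    ip_sample: str,
    on_target_species: str,
    mode: str = "all_genes",
    include_reporters: bool = False,
) -> pd.DataFrame:
    """Per-gene analogue of :func:`delta_table`.

    Percentages are of the library total in the chosen mode, so the table
    supports the gene-level on-target scatter (protein coding vs
    non-coding, mitochondrial genes flagged).
    """
    if mode not in ("all_genes", "protein_coding_only"):
        raise ValueError("gene_delta requires a gene-level mode")
    ann = gene_table.df.loc[counts.index]
    keep = np.ones(len(ann), dtype=bool)
    if mode == "protein_coding_only":
        keep &= (ann["biotype"] == "protein_coding").to_numpy()
    if not include_reporters:
        keep &= (ann["species"] != REPORTER_SPECIES).to_numpy()
    sub = counts.loc[keep, [input_sample, ip_sample]]
    ann = ann[keep]
    totals = sub.sum(axis=0)
    if (totals <= 0).any():
        raise ValidationError("empty library in gene_delta")
    pct = 100.0 * sub / totals
    out = pd.DataFrame(
        {
            "gene_id": sub.index,
            "chromosome": ann["chromosome"].to_numpy(),
            "species": ann["species"].to_numpy(),
            "biotype": ann["biotype"].to_numpy(),
            "is_mito": ann["is_mito"].to_numpy(),
            "initial_percent": pct[input_sample].to_numpy(),
            "delta_percent": (pct[ip_sample] - pct[input_sample]).to_numpy(),
            "target_class": np.where(
                ann["species"].to_numpy() == on_target_species, "on", "off"
            ),
        }
    ).reset_index(drop=True)
    return out
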