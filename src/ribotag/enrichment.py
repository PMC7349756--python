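"""Permutation gene-set enrichment over biotypes and chromosomes.

Genes are ranked by the log2 fold change of library-normalised counts
(IP over matched input).  Enrichment of a gene set is the classic
weighted Kolmogorov-Smirnov running-sum statistic: walking down the
ranked list, the sum rises by the gene's |stat|^p share at set members
and falls by 1/(N - m) elsewhere; the enrichment score (ES) is the
signed maximal deviation.  Significance comes from a gene-permutation
null — random same-size sets drawn from the ranked universe — because
the single-pair IP/input design leaves nothing to permute at the sample
level.  P-values are one-sided on the sign of the observed ES,
conditional on same-sign null draws, and Benjamini-Hochberg adjusted
across the tested sets.

Two set collections mirror the two published analyses: Ensembl biotypes
over all annotated genes (protein coding up, lncRNA and pseudogenes
down), and chromosomes over protein-coding genes only (where the
mitochondrial chromosome is the expected depletion signal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import GeneTable, REPORTER_SPECIES

__all__ = [
    "rank_genes",
    "enrichment_score",
    "gsea",
    "biotype_and_chromosome_sets",
]

_MIN_SET_SIZE = 5


def rank_genes(
    counts: pd.DataFrame,
    input_sample: str,
    ip_sample: str,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Rank genes by log2((CPM_ip + c) / (CPM_input + c)), descending.

    CPM is counts per million of each sample's total, so a uniform count
    scaling of either library leaves every statistic unchanged.  Ties are
    broken by gene id (lexical, ascending) for a deterministic order.
    """
    sub = counts[[input_sample, ip_sample]]
    totals = sub.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("empty library")
    cpm = 1e6 * sub / totals
    stat = np.log2((cpm[ip_sample] + pseudocount) / (cpm[input_sample] + pseudocount))
    ranked = stat.to_frame("stat").reset_index(names="gene_id")
    ranked = ranked.sort_values(["stat", "gene_id"], ascending=[False, True])
    out = ranked.set_index("gene_id")["stat"]
    return out


def _hit_weights(stats_abs_p: np.ndarray, member: np.ndarray) -> np.ndarray:
    """Per-position increments of the running sum for one membership mask."""
    n = len(stats_abs_p)
    m = int(member.sum())
    inc = np.full(n, -1.0 / (n - m))
    s = stats_abs_p[member].sum()
    if s > 0:
        inc[member] = stats_abs_p[member] / s
    else:  # all member stats are zero: fall back to equal hit weights
        inc[member] = 1.0 / m
    return inc


def _es_from_increments(inc: np.ndarray) -> tuple[float, int]:
    run = np.cumsum(inc)
    j = int(np.argmax(np.abs(run)))
    # float accumulation can push an extreme sum a few ulp past +-1
    return float(np.clip(run[j], -1.0, 1.0)), j


def enrichment_score(
    ranked: pd.Series, gene_set, weight_exponent: float = 1.0
) -> float:
    """Signed maximal deviation of the weighted KS running sum in [-1, 1]."""
    es, _ = _enrichment_score_full(ranked, gene_set, weight_exponent)
    return es


def _enrichment_score_full(ranked, gene_set, weight_exponent):
    genes = ranked.index
    member = genes.isin(set(gene_set))
    m = int(member.sum())
    if m == 0:
        raise ValueError("gene set has no genes in the ranked list")
    if m == len(genes):
        raise ValueError("gene set covers the whole ranked list")
    w = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent
    inc = _hit_weights(w, member)
    es, peak = _es_from_increments(inc)
    if es >= 0:
        leading = int(member[: peak + 1].sum())
    else:
        leading = int(member[peak + 1 :].sum())
    return es, leading


def _null_es(
    w: np.ndarray, m: int, n_perm: int, rng: np.random.Generator, chunk: int = 2000
) -> np.ndarray:
    """Null ES for random size-m sets from an n-gene universe (vectorised)."""
    n = len(w)
    out = np.empty(n_perm)
    miss = -1.0 / (n - m)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        idx = np.argpartition(rng.random((b, n)), m - 1, axis=1)[:, :m]
        wm = w[idx]
        s = wm.sum(axis=1)
        hit = np.where(s[:, None] > 0, wm / np.where(s == 0, 1.0, s)[:, None], 1.0 / m)
        inc = np.full((b, n), miss)
        np.put_along_axis(inc, idx, hit, axis=1)
        run = np.cumsum(inc, axis=1)
        j = np.argmax(np.abs(run), axis=1)
        out[done : done + b] = np.clip(run[np.arange(b), j], -1.0, 1.0)
        done += b
    return out


def _permutation_p(es_obs: float, es_null: np.ndarray) -> float:
    """One-sided p on the sign of the observed ES, same-sign null only."""
    if es_obs > 0:
        side = es_null > 0
    elif es_obs < 0:
        side = es_null < 0
    else:
        return 1.0
    n_side = int(side.sum())
    n_extreme = int((np.abs(es_null[side]) >= abs(es_obs)).sum())
    return (1 + n_extreme) / (1 + n_side)


@dataclass
class GseaResult:
    set_label: str
    size: int
    es: float
    p_value: float
    p_adjusted: float
    leading_edge_size: int


def gsea(
    ranked: pd.Series,
    sets: dict,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    min_size: int = _MIN_SET_SIZE,
) -> pd.DataFrame:
    """Permutation GSEA over a collection of gene sets.

    Sets smaller than ``min_size`` (after intersection with the ranked
    universe) are skipped.  Null distributions are shared across sets of
    identical size.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    w = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent
    genes = set(ranked.index)

    observed = []
    skipped = []
    for label, members in sets.items():
        inter = [g for g in members if g in genes]
        if len(inter) < min_size or len(inter) >= len(ranked):
            skipped.append((label, len(inter)))
            continue
        es, leading = _enrichment_score_full(ranked, inter, weight_exponent)
        observed.append((label, len(inter), es, leading))

    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for label, size, es, leading in observed:
        if size not in null_cache:
            null_cache[size] = _null_es(w, size, n_perm, rng)
        p = _permutation_p(es, null_cache[size])
        rows.append(
            {
                "set_label": label,
                "size": size,
                "es": es,
                "p_value": p,
                "leading_edge_size": leading,
            }
        )
    result = pd.DataFrame(rows)
    if len(result):
        result["p_adjusted"] = multipletests(result["p_value"], method="fdr_bh")[1]
        result = result[
            ["set_label", "size", "es", "p_value", "p_adjusted", "leading_edge_size"]
        ]
    result.attrs["skipped"] = skipped
    return result


def biotype_and_chromosome_sets(
    gene_table: GeneTable, universe: str = "all"
) -> dict[str, list[str]]:
    """Gene sets for the two enrichment analyses.

    ``universe="all"``: one set per Ensembl biotype over every annotated
    gene (reporters excluded).  ``universe="protein_coding"``: one set per
    chromosome, restricted to protein-coding genes.
    """
    df = gene_table.df[gene_table.df["species"] != REPORTER_SPECIES]
    if universe == "all":
        grouped = df.groupby("biotype", sort=False)
    elif universe == "protein_coding":
        grouped = df[df["biotype"] == "protein_coding"].groupby("chromosome", sort=False)
    else:
        raise ValueError("universe must be 'all' or 'protein_coding'")
    return {label: list(sub.index) for label, sub in grouped}
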