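#!/usr/bin/env python
"""Gene-set enrichment by Ensembl biotype and by chromosome.

Ranks genes by log2 fold change of CPM (IP vs input) and runs the
permutation GSEA twice per IP: biotype sets over all genes (protein
coding expected up; lncRNA and pseudogenes down) and chromosome sets
over protein-coding genes only (the on-target mitochondrial chromosome
expected down).  Writes one TSV per analysis and bar plots under
results/enrichment/.
"""

import os

from ribotag import io as rio
from ribotag.enrichment import biotype_and_chromosome_sets, gsea, rank_genes
from ribotag.plots import gsea_barplot

BASE = os.path.join(os.path.dirname(__file__), "..", "results")
SIMDIR = os.path.join(BASE, "sim")
OUTDIR = os.path.join(BASE, "enrichment")
N_PERM = 10_000
SEED = 1


def main() -> None:
    if not os.path.exists(os.path.join(SIMDIR, "counts.tsv")):
        raise SystemExit("run analysis/01_simulate.py first")
    os.makedirs(OUTDIR, exist_ok=True)
    gene_table = rio.read_gene_table(os.path.join(SIMDIR, "gene_table.tsv"))
    counts = rio.read_counts_featurecounts(os.path.join(SIMDIR, "counts.tsv"), gene_table)
    sheet = rio.read_sample_sheet(os.path.join(SIMDIR, "sample_sheet.tsv"))
    pc = gene_table.df.index[gene_table.df["biotype"] == "protein_coding"]

    for ip_sample, input_sample in rio.pair_samples(sheet):
        ranked = rank_genes(counts, input_sample, ip_sample)
        res_bio = gsea(ranked, biotype_and_chromosome_sets(gene_table, "all"),
                       n_perm=N_PERM, seed=SEED)
        ranked_pc = rank_genes(counts.loc[counts.index.isin(pc)], input_sample, ip_sample)
        res_chrom = gsea(ranked_pc, biotype_and_chromosome_sets(gene_table, "protein_coding"),
                         n_perm=N_PERM, seed=SEED)
        rio.write_table(res_bio, os.path.join(OUTDIR, f"gsea_biotype_{ip_sample}.tsv"))
        rio.write_table(res_chrom, os.path.join(OUTDIR, f"gsea_chromosome_{ip_sample}.tsv"))
        gsea_barplot(res_bio, f"{ip_sample} biotypes",
                     os.path.join(OUTDIR, f"gsea_biotype_{ip_sample}"))
        gsea_barplot(res_chrom, f"{ip_sample} chromosomes (protein coding)",
                     os.path.join(OUTDIR, f"gsea_chromosome_{ip_sample}"))

        print(f"\n{ip_sample}: biotype enrichment (all genes, n_perm={N_PERM})")
        print(res_bio.round(4).to_string(index=False))
        mito = res_chrom[res_chrom.set_label.str.endswith("MT")]
        print(f"{ip_sample}: mitochondrial chromosome sets (protein-coding universe)")
        print(mito.round(4).to_string(index=False))
    print(f"\nwrote tables and bar plots to {os.path.relpath(OUTDIR)}")


if __name__ == "__main__":
    main()
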