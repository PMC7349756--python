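"""End-to-end orchestration: simulate or load, then analyse.

One :class:`RunConfig` drives simulate -> composition -> depletion ->
GSEA -> reporter quantification, writing every table under a run
directory together with a manifest (input checksums, seed, stage
timings).  Re-running with the same config and inputs reproduces every
non-plot output bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from . import io as rio
from .composition import chrom_proportions, species_composition, delta_table, gene_delta
from .depletion import depletion_report, fit_depletion
from .enrichment import rank_genes, gsea, biotype_and_chromosome_sets
from .reporter import reporter_ratio_from_counts
from .sim import SimConfig, simulate_experiment

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    outdir: str
    seed: int
    #: when set, inputs are simulated with these SimConfig overrides
    simulate: dict | None = None
    #: real-data mode: paths to gene table, featureCounts table, sample sheet
    gene_table: str | None = None
    counts: str | None = None
    sample_sheet: str | None = None
    mode: str = "all_genes"
    include_mito_on: bool = False
    include_mito_off: bool = True
    through_origin: bool = False
    gsea_n_perm: int = 1000
    gsea_pseudocount: float = 1.0
    gsea_weight_exponent: float = 1.0
    plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written as JSON)."""
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "stages": {},
        "outputs": [],
        "input_checksums": {},
    }
    with open(os.path.join(config.outdir, "run_config.yaml"), "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)

    def out(name):
        path = os.path.join(config.outdir, name)
        manifest["outputs"].append(name)
        return path

    def stage(name):
        manifest["stages"][name] = {"started": time.time()}
        return time.time()

    def done(name, t0):
        manifest["stages"][name]["seconds"] = round(time.time() - t0, 3)

    # -- inputs ------------------------------------------------------------
    t0 = stage("inputs")
    if config.simulate is not None:
        sim_cfg = SimConfig(**{"seed": config.seed, **config.simulate})
        gene_table, counts, sheet, truth = simulate_experiment(sim_cfg)
        rio.write_gene_table(gene_table, out("gene_table.tsv"))
        rio.write_counts_featurecounts(counts, gene_table, out("counts.tsv"))
        rio.write_sample_sheet(sheet, out("sample_sheet.tsv"))
        truth.to_json(out("sim_truth.json"))
    else:
        for key in ("gene_table", "counts", "sample_sheet"):
            path = getattr(config, key)
            if path is None:
                raise ValueError(f"real-data mode requires {key!r} path")
            manifest["input_checksums"][key] = _sha256(path)
        gene_table = rio.read_gene_table(config.gene_table)
        counts = rio.read_counts_featurecounts(config.counts, gene_table)
        sheet = rio.read_sample_sheet(config.sample_sheet)
    done("inputs", t0)

    # -- composition -------------------------------------------------------
    t0 = stage("composition")
    props = {
        sid: chrom_proportions(counts, gene_table, sid, mode=config.mode)
        for sid in sheet.samples
    }
    prop_frames = pd.concat([p.to_frame() for p in props.values()])
    rio.write_table(prop_frames, out("chromosome_proportions.tsv"))
    comp = pd.DataFrame(
        {sid: species_composition(p, gene_table) for sid, p in props.items()}
    ).T
    comp.index.name = "sample_id"
    rio.write_table(comp.reset_index(), out("species_composition.tsv"))

    deltas_by_ip = {}
    for ip_sample, input_sample in rio.pair_samples(sheet):
        on_species = sheet.df.loc[ip_sample, "on_target_species"]
        deltas = delta_table(props[input_sample], props[ip_sample], gene_table, on_species)
        deltas_by_ip[ip_sample] = (ip_sample, deltas)
        rio.write_table(deltas, out(f"delta_{ip_sample}.tsv"))
        if config.mode != "chromosome_level":
            gd = gene_delta(
                counts, gene_table, input_sample, ip_sample, on_species, mode=config.mode
            )
            rio.write_table(gd, out(f"gene_delta_{ip_sample}.tsv"))
    done("composition", t0)

    # -- depletion ---------------------------------------------------------
    t0 = stage("depletion")
    report = depletion_report(
        counts,
        gene_table,
        sheet,
        mode=config.mode,
        include_mito_on=config.include_mito_on,
        include_mito_off=config.include_mito_off,
        through_origin=config.through_origin,
    )
    rio.write_table(report, out("depletion_report.tsv"))
    with open(out("depletion_report.json"), "w") as fh:
        json.dump(report.to_dict(orient="records"), fh, indent=2, default=float)
    done("depletion", t0)

    # -- enrichment --------------------------------------------------------
    t0 = stage("gsea")
    gsea_tables = {}
    pc_genes = gene_table.df.index[gene_table.df["biotype"] == "protein_coding"]
    for ip_sample, input_sample in rio.pair_samples(sheet):
        ranked = rank_genes(counts, input_sample, ip_sample, config.gsea_pseudocount)
        biotype_sets = biotype_and_chromosome_sets(gene_table, universe="all")
        res_bio = gsea(
            ranked,
            biotype_sets,
            n_perm=config.gsea_n_perm,
            seed=config.seed,
            weight_exponent=config.gsea_weight_exponent,
        )
        pc_counts = counts.loc[counts.index.isin(pc_genes)]
        ranked_pc = rank_genes(pc_counts, input_sample, ip_sample, config.gsea_pseudocount)
        chrom_sets = biotype_and_chromosome_sets(gene_table, universe="protein_coding")
        res_chrom = gsea(
            ranked_pc,
            chrom_sets,
            n_perm=config.gsea_n_perm,
            seed=config.seed,
            weight_exponent=config.gsea_weight_exponent,
        )
        gsea_tables[f"{ip_sample}_biotype"] = res_bio
        gsea_tables[f"{ip_sample}_chromosome"] = res_chrom
        rio.write_table(res_bio, out(f"gsea_biotype_{ip_sample}.tsv"))
        rio.write_table(res_chrom, out(f"gsea_chromosome_{ip_sample}.tsv"))
    done("gsea", t0)

    # -- reporter ----------------------------------------------------------
    t0 = stage("reporter")
    reporter_rows = []
    if "GFP" in counts.index and "mCherry" in counts.index:
        for sid in sheet.samples:
            rec = reporter_ratio_from_counts(counts, sid, context=sid)
            reporter_rows.append(
                {
                    "sample_id": sid,
                    "mcherry_gfp_ratio": rec.mcherry_gfp_ratio,
                    "flag": rec.flag or "",
                }
            )
        rio.write_table(pd.DataFrame(reporter_rows), out("reporter_ratios.tsv"))
    done("reporter", t0)

    # -- plots -------------------------------------------------------------
    if config.plots:
        t0 = stage("plots")
        from .plots import plot_suite

        tables = {
            "deltas": deltas_by_ip,
            "species_composition": comp,
            "depletion_report": report,
            "gsea": gsea_tables,
        }
        figdir = os.path.join(config.outdir, "figures")
        os.makedirs(figdir, exist_ok=True)
        for p in plot_suite(tables, figdir):
            manifest["outputs"].append(os.path.relpath(p, config.outdir))
        done("plots", t0)

    manifest["seed"] = config.seed
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
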