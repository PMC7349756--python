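"""Generative model of a two-species RiboTag co-culture IP experiment.

The model emulates a co-culture of a human cell type carrying
GFP-T2A-RPL22-HA and a mouse cell type carrying mCherry-T2A-RPL22-V5,
sequenced against a hybrid human+mouse reference plus the two reporter
contigs.

Structure of the model
----------------------
Each cell type expresses its species' genes (plus its reporter) with
i.i.d. log-normal relative abundances.  Within a cell type the RNA mass is
apportioned: a fixed fraction to the mitochondrial chromosome, a fixed
fraction to the reporter transgene, and the remainder to nuclear genes.
The co-culture input is the mixture

    p = m * A + (1 - m) * B

where ``m`` is the mass fraction contributed by the human cell type.

An anti-HA (or anti-V5) IP reweights the input proportions by per-gene
capture factors and renormalises:

* on-target nuclear genes: a biotype-dependent factor (protein_coding
  ``c_pc``, lncRNA ``c_lnc``, pseudogene ``c_ps``), reflecting
  preferential recovery of translated, ribosome-bound mRNA;
* on-target mitochondrial genes: 0 — mitochondrial transcripts are
  translated by mitoribosomes, never by tagged RPL22-containing
  cytosolic ribosomes, so specific capture cannot recover them;
* every off-target transcript (including the off-target mitochondrial
  chromosome): a uniform retain factor ``k`` in [0, 1], modelling
  non-specific carry-over of input RNA.  Carry-over is not
  ribosome-mediated, so it does not distinguish biotypes or
  mitochondrial origin — this is what makes off-target depletion linear
  in the initial proportion;
* reporters: the protein-coding factor of their host cell type when that
  cell type is on target, else ``k``.

Counts are drawn multinomially with a fixed library size per sample.

The accompanying :class:`SimTruth` records the exact sampling
probabilities and the analytic expectation of the depletion-efficiency
statistic: with uniform off-target retention every expected off-target
point lies on a line through the origin with slope ``k / Z_eff - 1``,
where ``Z_eff`` is the retained mass fraction over non-reporter genes, so
the expected efficiency is ``D_exp = 1 - k / Z_eff``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .io import GeneTable, SampleSheet, REPORTER_SPECIES

__all__ = [
    "SimConfig",
    "IpTruth",
    "SimTruth",
    "DpcrPartitions",
    "simulate_experiment",
    "simulate_dpcr",
]


def _default_human_chromosomes() -> list[str]:
    return [f"hs_{c}" for c in [*map(str, range(1, 23)), "X", "Y", "MT"]]


def _default_mouse_chromosomes() -> list[str]:
    return [f"mm_{c}" for c in [*map(str, range(1, 20)), "X", "Y", "MT"]]


@dataclass
class SimConfig:
    """Parameters of the generative co-culture IP model.

    Defaults emulate the HEK293/NIH3T3 mixed co-culture: canonical
    chromosomes of both genomes, a 28% human / 72% mouse read mixture,
    log-normal per-gene expression, biotype-dependent on-target capture
    and uniform off-target retention.
    """

    seed: int = 0
    n_genes_per_chrom: int = 40
    human_chromosomes: list[str] = field(default_factory=_default_human_chromosomes)
    mouse_chromosomes: list[str] = field(default_factory=_default_mouse_chromosomes)
    #: fraction of co-culture RNA mass from the human (GFP/HA) cell type
    mixing_fraction: float = 0.28
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0
    #: gene-count proportions of nuclear biotypes, per species
    biotype_proportions: dict = field(
        default_factory=lambda: {"protein_coding": 0.70, "lncRNA": 0.20, "pseudogene": 0.10}
    )
    #: biotype mix of mitochondrial genes (human MT: 13 protein coding,
    #: 22 tRNA, 2 rRNA of 37 genes)
    mito_biotype_proportions: dict = field(
        default_factory=lambda: {"protein_coding": 0.35, "Mt_tRNA": 0.55, "Mt_rRNA": 0.10}
    )
    capture_protein_coding: float = 1.0
    capture_lncRNA: float = 0.5
    capture_pseudogene: float = 0.3
    capture_mito: float = 0.0  # fixed by the model; on-target mito is never captured
    #: uniform off-target retain factor (cross-species contamination)
    off_target_retain: float = 0.2
    #: fraction of each cell type's RNA mass on its mitochondrial chromosome
    mito_mass_fraction: float = 0.05
    #: fraction of each cell type's RNA mass on its reporter transgene
    reporter_mass_fraction: float = 0.01
    library_size: int = 1_000_000

    def validate(self) -> None:
        unit = {
            "mixing_fraction": self.mixing_fraction,
            "capture_protein_coding": self.capture_protein_coding,
            "capture_lncRNA": self.capture_lncRNA,
            "capture_pseudogene": self.capture_pseudogene,
            "off_target_retain": self.off_target_retain,
            "mito_mass_fraction": self.mito_mass_fraction,
            "reporter_mass_fraction": self.reporter_mass_fraction,
        }
        for name, v in unit.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.capture_mito != 0.0:
            raise ValueError("capture_mito is fixed at 0 in this model")
        for chroms, label in (
            (self.human_chromosomes, "human"),
            (self.mouse_chromosomes, "mouse"),
        ):
            n_mt = sum(c.rsplit("_", 1)[-1] in {"MT", "chrM", "chrMT"} for c in chroms)
            if n_mt != 1:
                raise ValueError(f"{label} chromosome list must contain exactly one MT")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.mito_mass_fraction + self.reporter_mass_fraction >= 1.0:
            raise ValueError("mito + reporter mass fractions must leave nuclear mass")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class IpTruth:
    """Analytic expectations for one IP sample."""

    sample_id: str
    antibody: str
    on_target_species: str
    #: total retained mass fraction sum_g w_g p_g (all genes)
    z_total: float
    #: retained mass over non-reporter genes / input mass over non-reporter
    #: genes — the normaliser governing reporter-excluded percentages
    z_effective: float
    #: expected off-target regression slope, k / z_effective - 1
    expected_slope: float
    #: expected depletion efficiency, 1 - k / z_effective
    expected_efficiency: float
    #: set when the retain factor exceeds z_total (efficiency < 0 regime)
    warning: str | None = None


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment."""

    config: SimConfig
    #: per-gene input proportions (index: gene_id)
    input_proportions: pd.Series
    #: per-sample sampling probabilities (genes x samples)
    sampling_probabilities: pd.DataFrame
    ip_truth: dict[str, IpTruth]

    def summary_dict(self) -> dict:
        return {
            "seed": self.config.seed,
            "mixing_fraction": self.config.mixing_fraction,
            "off_target_retain": self.config.off_target_retain,
            "ips": {sid: asdict(t) for sid, t in self.ip_truth.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2)


def _build_gene_table(config: SimConfig, rng: np.random.Generator) -> GeneTable:
    rows = []
    for species, chroms in (
        ("human", config.human_chromosomes),
        ("mouse", config.mouse_chromosomes),
    ):
        for chrom in chroms:
            is_mt = chrom.rsplit("_", 1)[-1] in {"MT", "chrM", "chrMT"}
            props = (
                config.mito_biotype_proportions if is_mt else config.biotype_proportions
            )
            labels = list(props)
            pvec = np.asarray([props[b] for b in labels], dtype=float)
            pvec = pvec / pvec.sum()
            biotypes = rng.choice(labels, size=config.n_genes_per_chrom, p=pvec)
            for j, bt in enumerate(biotypes):
                rows.append(
                    {
                        "gene_id": f"{chrom}_g{j:04d}",
                        "chromosome": chrom,
                        "species": species,
                        "biotype": bt,
                        "is_mito": is_mt,
                    }
                )
    for reporter in ("GFP", "mCherry"):
        rows.append(
            {
                "gene_id": reporter,
                "chromosome": reporter,
                "species": REPORTER_SPECIES,
                "biotype": "protein_coding",
                "is_mito": False,
            }
        )
    df = pd.DataFrame(rows).set_index("gene_id")
    return GeneTable(df)


def _cell_type_profile(
    gene_table: GeneTable,
    species: str,
    reporter: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.Series:
    """Relative RNA mass of one cell type over all genes (sums to 1)."""
    df = gene_table.df
    prof = pd.Series(0.0, index=df.index)
    own = df["species"] == species
    mito = own & df["is_mito"]
    nuclear = own & ~df["is_mito"]
    raw = pd.Series(
        rng.lognormal(config.lognormal_mu, config.lognormal_sigma, size=int(own.sum())),
        index=df.index[own],
    )
    nuc_mass = 1.0 - config.mito_mass_fraction - config.reporter_mass_fraction
    prof.loc[df.index[nuclear]] = (
        raw[df.index[nuclear]] / raw[df.index[nuclear]].sum() * nuc_mass
    )
    prof.loc[df.index[mito]] = (
        raw[df.index[mito]] / raw[df.index[mito]].sum() * config.mito_mass_fraction
    )
    prof.loc[reporter] = config.reporter_mass_fraction
    return prof


def _capture_weights(
    gene_table: GeneTable, on_target_species: str, config: SimConfig
) -> pd.Series:
    """Per-gene IP capture weight for the given on-target species."""
    df = gene_table.df
    factor_by_biotype = {
        "protein_coding": config.capture_protein_coding,
        "lncRNA": config.capture_lncRNA,
        "pseudogene": config.capture_pseudogene,
        "Mt_tRNA": config.capture_mito,
        "Mt_rRNA": config.capture_mito,
    }
    k = config.off_target_retain
    w = pd.Series(k, index=df.index, dtype=float)
    on = df["species"] == on_target_species
    w[on] = [
        factor_by_biotype.get(bt, config.capture_protein_coding)
        for bt in df.loc[on, "biotype"]
    ]
    w[on & df["is_mito"]] = 0.0  # ribosome-mediated capture misses mito RNA
    on_reporter = "GFP" if on_target_species == "human" else "mCherry"
    off_reporter = "mCherry" if on_target_species == "human" else "GFP"
    w[on_reporter] = config.capture_protein_coding
    w[off_reporter] = k
    return w


def simulate_experiment(
    config: SimConfig,
) -> tuple[GeneTable, pd.DataFrame, SampleSheet, SimTruth]:
    """Simulate one co-culture with a shared input and two IPs.

    Returns the gene annotation, a genes x samples count matrix
    (``coculture``, ``HA_IP``, ``V5_IP``), the sample sheet pairing each
    IP to the shared input, and the :class:`SimTruth` record.
    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gene_table = _build_gene_table(config, rng)

    prof_human = _cell_type_profile(gene_table, "human", "GFP", config, rng)
    prof_mouse = _cell_type_profile(gene_table, "mouse", "mCherry", config, rng)
    m = config.mixing_fraction
    p_input = m * prof_human + (1.0 - m) * prof_mouse
    p_input = p_input / p_input.sum()

    non_reporter = gene_table.df["species"] != REPORTER_SPECIES
    s_in = float(p_input[non_reporter].sum())

    samples = {"coculture": p_input}
    ip_specs = [("HA_IP", "HA", "human"), ("V5_IP", "V5", "mouse")]
    ip_truth: dict[str, IpTruth] = {}
    k = config.off_target_retain
    for sid, antibody, species in ip_specs:
        w = _capture_weights(gene_table, species, config)
        retained = w * p_input
        z_total = float(retained.sum())
        q = retained / z_total
        samples[sid] = q
        z_eff = float(retained[non_reporter].sum()) / s_in
        warning = None
        if k > z_total:
            warning = (
                f"off_target_retain k={k} exceeds retained mass Z={z_total:.4g}; "
                "expected efficiency is negative (model validity limit)"
            )
        ip_truth[sid] = IpTruth(
            sample_id=sid,
            antibody=antibody,
            on_target_species=species,
            z_total=z_total,
            z_effective=z_eff,
            expected_slope=k / z_eff - 1.0,
            expected_efficiency=1.0 - k / z_eff,
            warning=warning,
        )

    probs = pd.DataFrame(samples)
    counts = pd.DataFrame(
        {
            sid: rng.multinomial(config.library_size, probs[sid].to_numpy())
            for sid in probs.columns
        },
        index=probs.index,
    ).astype(np.int64)
    counts.index.name = "gene_id"

    sheet = SampleSheet(
        pd.DataFrame(
            {
                "role": ["input", "ip", "ip"],
                "antibody": ["none", "HA", "V5"],
                "on_target_species": ["", "human", "mouse"],
                "input_sample_id": ["", "coculture", "coculture"],
                "replicate_label": ["sim", "sim", "sim"],
            },
            index=pd.Index(["coculture", "HA_IP", "V5_IP"], name="sample_id"),
        )
    )
    truth = SimTruth(
        config=config,
        input_proportions=p_input,
        sampling_probabilities=probs,
        ip_truth=ip_truth,
    )
    return gene_table, counts, sheet, truth


# ---------------------------------------------------------------------------
# digital PCR partition simulator
# ---------------------------------------------------------------------------

@dataclass
class DpcrPartitions:
    """Partition counts from one digital-PCR reaction."""

    target: str
    n_total: int
    n_positive: int
    partition_volume_ul: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.n_positive <= self.n_total:
            raise ValueError("n_positive must be within [0, n_total]")
        if self.partition_volume_ul <= 0:
            raise ValueError("partition_volume_ul must be positive")


def simulate_dpcr(
    concentration: float,
    *,
    n_total: int = 496,
    partition_volume_ul: float = 0.024,
    seed: int = 0,
    target: str = "target",
    sample_id: str = "",
) -> DpcrPartitions:
    """Simulate partition counts for a template at ``concentration`` copies/µL.

    Molecules distribute over partitions as Poisson with mean
    ``concentration * partition_volume_ul``, so each partition is positive
    with probability ``1 - exp(-c * v)`` and the positive count is
    binomial.  Deterministic given ``seed``.
    """
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    p_pos = 1.0 - np.exp(-concentration * partition_volume_ul)
    rng = np.random.default_rng(seed)
    n_positive = int(rng.binomial(n_total, p_pos))
    return DpcrPartitions(
        target=target,
        n_total=n_total,
        n_positive=n_positive,
        partition_volume_ul=partition_volume_ul,
        sample_id=sample_id,
    )
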