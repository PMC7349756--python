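import numpy as np
import pandas as pd
import pytest

from ribotag.io import GeneTable, SampleSheet
from ribotag.sim import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def toy_gene_table() -> GeneTable:
    """Two species x two chromosomes each (incl. MT) plus reporters."""
    rows = [
        ("hG1", "hs_1", "human", "protein_coding", False),
        ("hG2", "hs_1", "human", "lncRNA", False),
        ("hG3", "hs_MT", "human", "protein_coding", True),
        ("mG1", "mm_1", "mouse", "protein_coding", False),
        ("mG2", "mm_1", "mouse", "pseudogene", False),
        ("mG3", "mm_MT", "mouse", "protein_coding", True),
        ("GFP", "GFP", "reporter", "protein_coding", False),
        ("mCherry", "mCherry", "reporter", "protein_coding", False),
    ]
    df = pd.DataFrame(
        rows, columns=["gene_id", "chromosome", "species", "biotype", "is_mito"]
    ).set_index("gene_id")
    return GeneTable(df)


@pytest.fixture(scope="session")
def toy_counts(toy_gene_table) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "inp": [100, 50, 20, 300, 100, 30, 10, 40],
            "ip": [200, 60, 2, 60, 20, 6, 30, 8],
        },
        index=toy_gene_table.genes,
    )


@pytest.fixture(scope="session")
def toy_sheet() -> SampleSheet:
    df = pd.DataFrame(
        {
            "role": ["input", "ip"],
            "antibody": ["none", "HA"],
            "on_target_species": ["", "human"],
            "input_sample_id": ["", "inp"],
            "replicate_label": ["r1", "r1"],
        },
        index=pd.Index(["inp", "ip"], name="sample_id"),
    )
    return SampleSheet(df)


@pytest.fixture(scope="session")
def default_sim():
    """One simulated experiment under the default study conditions."""
    cfg = SimConfig(seed=1)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def small_sim():
    """A cheaper simulation for tests that only need structure."""
    cfg = SimConfig(
        seed=7,
        n_genes_per_chrom=10,
        human_chromosomes=[f"hs_{c}" for c in ["1", "2", "3", "4", "5", "MT"]],
        mouse_chromosomes=[f"mm_{c}" for c in ["1", "2", "3", "4", "MT"]],
        library_size=200_000,
    )
    return simulate_experiment(cfg)
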