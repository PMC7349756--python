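import numpy as np
import pandas as pd
import pytest

from ribotag.enrichment import (
    biotype_and_chromosome_sets,
    enrichment_score,
    gsea,
    rank_genes,
)


def _ranked(stats: dict) -> pd.Series:
    s = pd.Series(stats, name="stat").sort_values(ascending=False)
    s.index.name = "gene_id"
    return s


def _brute_force_es(ranked, gene_set, p=1.0):
    """Independent enumeration of the running sum, plain python."""
    members = set(gene_set)
    n, m = len(ranked), len(members & set(ranked.index))
    s_total = sum(abs(ranked[g]) ** p for g in ranked.index if g in members)
    run, best = 0.0, 0.0
    for g, stat in ranked.items():
        if g in members:
            run += (abs(stat) ** p) / s_total if s_total > 0 else 1.0 / m
        else:
            run -= 1.0 / (n - m)
        if abs(run) > abs(best):
            best = run
    return best


class TestRankGenes:
    def test_identical_samples_rank_zero(self, toy_counts):
        counts = toy_counts.assign(ip=toy_counts["inp"])
        ranked = rank_genes(counts, "inp", "ip")
        assert np.allclose(ranked, 0.0)

    def test_uniform_doubling_is_cpm_invariant(self, toy_counts):
        counts = toy_counts.assign(ip=2 * toy_counts["inp"])
        ranked = rank_genes(counts, "inp", "ip")
        assert np.allclose(ranked, 0.0)

    def test_five_gene_hand_computation(self):
        counts = pd.DataFrame(
            {"inp": [10, 20, 30, 25, 15], "ip": [40, 10, 30, 10, 10]},
            index=[f"g{i}" for i in range(5)],
        )
        ranked = rank_genes(counts, "inp", "ip", pseudocount=1.0)
        cpm_in = 1e6 * counts["inp"] / 100
        cpm_ip = 1e6 * counts["ip"] / 100
        expected = np.log2((cpm_ip + 1) / (cpm_in + 1))
        for g in counts.index:
            assert ranked[g] == pytest.approx(expected[g], abs=1e-12)
        assert list(ranked.index) == list(expected.sort_values(ascending=False).index)

    def test_ties_broken_lexically(self):
        counts = pd.DataFrame({"inp": [10, 10, 5], "ip": [10, 10, 20]},
                              index=["zeta", "alpha", "beta"])
        ranked = rank_genes(counts, "inp", "ip")
        assert list(ranked.index) == ["beta", "alpha", "zeta"]


class TestEnrichmentScore:
    def test_top_gene_singleton_scores_one(self):
        ranked = _ranked({"a": 5.0, "b": 4.0, "c": 1.0, "d": 0.5})
        assert enrichment_score(ranked, {"a"}) == pytest.approx(1.0)

    def test_bottom_gene_singleton_scores_negative(self):
        ranked = _ranked({"a": 5.0, "b": 4.0, "c": 1.0, "d": 0.5})
        assert enrichment_score(ranked, {"d"}) < 0

    def test_matches_brute_force_walk(self):
        stats = {f"g{i}": float(10 - i) for i in range(10)}
        ranked = _ranked(stats)
        gene_set = {"g1", "g4", "g9"}
        es = enrichment_score(ranked, gene_set)
        assert es == pytest.approx(_brute_force_es(ranked, gene_set), abs=1e-12)

    def test_matches_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            n = int(rng.integers(8, 60))
            stats = {f"g{i}": float(rng.normal()) for i in range(n)}
            ranked = _ranked(stats)
            m = int(rng.integers(1, n - 1))
            gene_set = set(rng.choice(list(stats), size=m, replace=False))
            es = enrichment_score(ranked, gene_set)
            assert es == pytest.approx(_brute_force_es(ranked, gene_set), abs=1e-12)

    def test_scale_invariance(self):
        stats = {f"g{i}": float(i - 7) for i in range(15)}
        ranked = _ranked(stats)
        gene_set = {"g1", "g2", "g11"}
        a = enrichment_score(ranked, gene_set)
        b = enrichment_score(ranked * 1000.0, gene_set)
        assert a == pytest.approx(b, abs=1e-12)

    def test_degenerate_sets_rejected(self):
        ranked = _ranked({"a": 2.0, "b": 1.0})
        with pytest.raises(ValueError):
            enrichment_score(ranked, set())
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"a", "b"})


class TestGsea:
    def test_p_value_floor(self):
        # most extreme possible set: the single top gene, tiny universe of
        # strongly graded stats -> every same-sign null is weaker
        ranked = _ranked({f"g{i}": float(50 - i) for i in range(50)})
        res = gsea(ranked, {"top": [f"g{i}" for i in range(5)]}, n_perm=99, seed=1, min_size=5)
        assert res["p_value"].iloc[0] >= 1.0 / 100
        assert res["p_value"].iloc[0] <= 0.05

    def test_reproducible_given_seed(self, small_sim):
        gt, counts, _, _ = small_sim
        ranked = rank_genes(counts, "coculture", "HA_IP")
        sets = biotype_and_chromosome_sets(gt, universe="all")
        a = gsea(ranked, sets, n_perm=200, seed=3)
        b = gsea(ranked, sets, n_perm=200, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_small_sets_skipped(self):
        ranked = _ranked({f"g{i}": float(i) for i in range(20)})
        res = gsea(ranked, {"tiny": ["g1", "g2"]}, n_perm=50, seed=0)
        assert len(res) == 0
        assert res.attrs["skipped"] == [("tiny", 2)]

    def test_bh_adjustment_step_up(self):
        # hand oracle: BH on {0.01, 0.02, 0.03} is {0.03, 0.03, 0.03}
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.03])
        # and the gsea table respects padj >= p
        ranked = _ranked({f"g{i}": float(30 - i) for i in range(30)})
        sets = {"a": [f"g{i}" for i in range(6)], "b": [f"g{i}" for i in range(12, 20)]}
        res = gsea(ranked, sets, n_perm=200, seed=0)
        assert (res["p_adjusted"] >= res["p_value"] - 1e-15).all()

    def test_type_i_error_calibrated(self, default_sim):
        gt, counts, _, _ = default_sim
        ranked = rank_genes(counts, "coculture", "HA_IP")
        rng = np.random.default_rng(314)
        genes = ranked.index.to_numpy()
        rejections = 0
        n_draws = 200
        for _ in range(n_draws):
            random_set = list(rng.choice(genes, size=50, replace=False))
            res = gsea(ranked, {"null": random_set}, n_perm=199,
                       seed=int(rng.integers(2**31)))
            if res["p_value"].iloc[0] <= 0.05:
                rejections += 1
        rate = rejections / n_draws
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / n_draws)
        assert abs(rate - 0.05) <= half_width


class TestGeneSets:
    def test_biotype_sets_partition_universe(self, toy_gene_table):
        sets = biotype_and_chromosome_sets(toy_gene_table, universe="all")
        universe = toy_gene_table.df[toy_gene_table.df.species != "reporter"]
        assert sum(len(v) for v in sets.values()) == len(universe)
        assert set().union(*map(set, sets.values())) == set(universe.index)

    def test_protein_coding_universe_excludes_noncoding(self, toy_gene_table):
        sets = biotype_and_chromosome_sets(toy_gene_table, universe="protein_coding")
        assert "hG2" not in set().union(*map(set, sets.values()))  # lncRNA

    def test_set_sizes_match_groupby_oracle(self, small_sim):
        gt, _, _, _ = small_sim
        sets = biotype_and_chromosome_sets(gt, universe="all")
        ann = gt.df[gt.df.species != "reporter"]
        counts_by_biotype = ann.groupby("biotype").size()
        for label, members in sets.items():
            assert len(members) == counts_by_biotype[label]


class TestSignReproduction:
    def test_biotype_and_mito_signs_on_simulation(self, default_sim):
        gt, counts, _, _ = default_sim
        ranked = rank_genes(counts, "coculture", "HA_IP")
        sets = biotype_and_chromosome_sets(gt, universe="all")
        res = gsea(ranked, sets, n_perm=2000, seed=2).set_index("set_label")
        assert res.loc["protein_coding", "es"] > 0
        assert res.loc["lncRNA", "es"] < 0
        assert res.loc["protein_coding", "p_adjusted"] < 0.01
        assert res.loc["lncRNA", "p_adjusted"] < 0.01
        # mitochondrial chromosome depleted in the protein-coding universe
        pc = gt.df.index[gt.df["biotype"] == "protein_coding"]
        ranked_pc = rank_genes(counts.loc[counts.index.isin(pc)], "coculture", "HA_IP")
        csets = biotype_and_chromosome_sets(gt, universe="protein_coding")
        for mt in ("hs_MT", "mm_MT"):
            assert enrichment_score(ranked_pc, csets[mt]) < 0
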