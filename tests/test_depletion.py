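import numpy as np
import pandas as pd
import pytest

from ribotag.composition import chrom_proportions, delta_table
from ribotag.depletion import (
    classify_chromosome_direction,
    depletion_report,
    fit_depletion,
)
from ribotag.sim import SimConfig, simulate_experiment


def _deltas(points, target_class="off", species="mouse", mito=None):
    mito = mito or [False] * len(points)
    return pd.DataFrame(
        {
            "chromosome": [f"c{i}" for i in range(len(points))],
            "species": species,
            "is_mito": mito,
            "initial_percent": [p[0] for p in points],
            "delta_percent": [p[1] for p in points],
            "target_class": target_class,
        }
    )


def _normal_equation_oracle(x, y):
    """Closed-form simple OLS, independent of the fitting code."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    syy = ((y - y.mean()) ** 2).sum()
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    r2 = sxy**2 / (sxx * syy)
    return slope, intercept, r2


class TestFitDepletion:
    def test_full_depletion_line(self):
        # every off-target chromosome loses exactly its initial percent
        pts = [(p, -p) for p in (2.0, 5.0, 9.0, 14.0)]
        fit = fit_depletion(_deltas(pts))
        assert fit.slope == pytest.approx(-1.0, abs=1e-12)
        assert fit.depletion_efficiency == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_zero_deltas_zero_efficiency(self):
        fit = fit_depletion(_deltas([(2, 0), (5, 0), (9, 0)]))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.depletion_efficiency == pytest.approx(0.0, abs=1e-12)

    def test_worked_three_point_fixture(self):
        # closed-form normal equations give slope -0.85, intercept 1,
        # R^2 = 28900/29200
        fit = fit_depletion(_deltas([(10, -7), (20, -17), (30, -24)]))
        assert fit.slope == pytest.approx(-0.85, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(28900 / 29200, abs=1e-9)

    def test_matches_normal_equation_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = rng.integers(3, 30)
            x = rng.uniform(0.1, 20, n)
            y = -0.7 * x + rng.normal(0, 1, n)
            fit = fit_depletion(_deltas(list(zip(x, y))))
            slope, intercept, r2 = _normal_equation_oracle(x, y)
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, abs=1e-10)
            assert fit.r_squared == pytest.approx(r2, abs=1e-10)

    def test_p_value_is_two_sided_t_test(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, 8)
        y = -x + rng.normal(0, 2, 8)
        fit = fit_depletion(_deltas(list(zip(x, y))))
        slope, intercept, r2 = _normal_equation_oracle(x, y)
        resid = y - (slope * x + intercept)
        se = np.sqrt(resid @ resid / (len(x) - 2) / ((x - x.mean()) ** 2).sum())
        p = 2 * stats.t.sf(abs(slope / se), len(x) - 2)
        assert fit.p_value == pytest.approx(p, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_depletion(_deltas([(1, -1), (2, -2)]))

    def test_degenerate_initial_percent_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_depletion(_deltas([(5, -1), (5, -2), (5, -3)]))

    def test_mito_default_included_off_excluded_on(self):
        pts = [(2, -1), (5, -2.5), (9, -4.5), (4, -4)]
        mito = [False, False, False, True]
        off = fit_depletion(_deltas(pts, mito=mito), target_class="off")
        assert off.n_chromosomes == 4
        on = fit_depletion(
            _deltas(pts, target_class="on", species="human", mito=mito), "on"
        )
        assert on.n_chromosomes == 3

    def test_through_origin_flag(self):
        pts = [(1.0, -0.9), (2.0, -1.7), (4.0, -3.9)]
        fit = fit_depletion(_deltas(pts), through_origin=True)
        x = np.array([1.0, 2.0, 4.0])
        y = np.array([-0.9, -1.7, -3.9])
        assert fit.slope == pytest.approx((x @ y) / (x @ x), abs=1e-12)
        assert fit.intercept == 0.0

    def test_efficiency_invariant_to_order_and_scaling(self, default_sim):
        gt, counts, sheet, _ = default_sim
        base = depletion_report(counts, gt, sheet, mode="all_genes", fit_on_target=False)
        shuffled = counts.sample(frac=1, random_state=0)
        perm = depletion_report(shuffled, gt, sheet, mode="all_genes", fit_on_target=False)
        scaled = counts.copy()
        scaled["HA_IP"] *= 7  # uniform scaling of one library
        sc = depletion_report(scaled, gt, sheet, mode="all_genes", fit_on_target=False)
        for other in (perm, sc):
            np.testing.assert_allclose(
                base["depletion_efficiency"], other["depletion_efficiency"], atol=1e-12
            )


class TestDepletionReport:
    def test_off_target_fit_uses_other_species(self, default_sim):
        gt, counts, sheet, _ = default_sim
        rep = depletion_report(counts, gt, sheet, mode="all_genes")
        ha_off = rep[(rep.ip_sample == "HA_IP") & (rep.target_class == "off")].iloc[0]
        assert ha_off["species"] == "mouse"
        assert ha_off["n_chromosomes"] == 22  # mouse canonical incl. MT
        ha_on = rep[(rep.ip_sample == "HA_IP") & (rep.target_class == "on")].iloc[0]
        assert ha_on["species"] == "human"
        assert ha_on["n_chromosomes"] == 24  # human canonical minus MT

    def test_full_depletion_reports_efficiency_one(self):
        cfg = SimConfig(seed=9, n_genes_per_chrom=8, off_target_retain=0.0,
                        library_size=400_000)
        gt, counts, sheet, _ = simulate_experiment(cfg)
        rep = depletion_report(counts, gt, sheet, mode="all_genes", fit_on_target=False)
        assert np.allclose(rep["depletion_efficiency"], 1.0)

    def test_recovers_truth_at_k_02(self):
        cfg = SimConfig(seed=4, off_target_retain=0.2)
        gt, counts, sheet, truth = simulate_experiment(cfg)
        rep = depletion_report(counts, gt, sheet, mode="all_genes", fit_on_target=False)
        for _, row in rep.iterrows():
            exp = truth.ip_truth[row["ip_sample"]].expected_efficiency
            assert row["depletion_efficiency"] == pytest.approx(exp, abs=0.02)

    def test_monotone_decreasing_in_k(self):
        effs = []
        for k in (0.05, 0.2, 0.5, 0.75):
            cfg = SimConfig(seed=8, off_target_retain=k)
            gt, counts, sheet, _ = simulate_experiment(cfg)
            rep = depletion_report(counts, gt, sheet, mode="all_genes", fit_on_target=False)
            effs.append(rep["depletion_efficiency"].mean())
        assert all(a > b for a, b in zip(effs, effs[1:]))

    def test_rna_yield_passthrough(self, default_sim):
        gt, counts, sheet, _ = default_sim
        sheet2 = sheet
        sheet2.df["rna_yield_ng"] = [0.0, 593.6, 422.8]
        rep = depletion_report(counts, gt, sheet2, mode="all_genes", fit_on_target=False)
        assert rep.loc[rep.ip_sample == "HA_IP", "rna_yield_ng"].iloc[0] == 593.6


class TestClassifyDirection:
    def test_signs(self):
        deltas = _deltas([(1, 2.0), (2, -5.0), (3, 0.0)])
        labels = classify_chromosome_direction(deltas)
        assert list(labels) == ["enriched", "depleted", "unchanged"]

    def test_on_target_non_mito_enriched_in_simulation(self, default_sim):
        gt, counts, _, _ = default_sim
        din = chrom_proportions(counts, gt, "coculture")
        dip = chrom_proportions(counts, gt, "HA_IP")
        deltas = delta_table(din, dip, gt, "human")
        on = deltas[(deltas.target_class == "on") & ~deltas.is_mito.astype(bool)]
        labels = classify_chromosome_direction(on)
        assert (labels == "enriched").all()
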