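"""Quantile regression, CDF comparison, two-sample tests, FDR, Fisher-Z."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from sscentrality import (
    CentralityParams,
    CentralityProfile,
    CentralityValidation,
    GeneSet,
    SyntheticSpec,
    bh_fdr,
    fisher_z,
    fit_quantile_regression,
    generate_cohort,
    ks_cdf_compare,
    pool_quantiles,
    pooled_quantile_scores,
    quantile_ranks,
    sensitivity_scan,
    welch_test,
    wilcoxon_test,
    znormalize,
)
from sscentrality.validation import DEFAULT_ALPHA_GRID


def make_profile(scores, nodes=None, pathway_id="p"):
    scores = np.asarray(scores, dtype=float)
    if nodes is None:
        nodes = tuple(f"g{i}" for i in range(len(scores)))
    return CentralityProfile(pathway_id, "degree", "undirected", None,
                             tuple(nodes), scores)


class TestQuantileRanks:
    def test_four_distinct_scores(self):
        q = quantile_ranks(make_profile([0.1, 0.4, 0.2, 0.9]))
        # ascending rank r -> ceil(100 r / 4)
        assert q.tolist() == [25, 75, 50, 100]

    def test_extremes_of_200_nodes(self):
        q = quantile_ranks(make_profile(np.arange(200)))
        assert q[0] == 1 and q[-1] == 100

    def test_ties_share_a_quantile(self):
        q = quantile_ranks(make_profile([1.0, 1.0, 2.0]))
        # tied pair: average rank 1.5 -> ceil(100*1.5/3) = 50
        assert q.tolist() == [50, 50, 100]

    def test_constant_profile_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            quantile_ranks(make_profile([2.0, 2.0, 2.0]))


class TestPoolQuantiles:
    def test_single_bin_fraction(self):
        # two genes tied in quantile 50, one important -> F_50 = 50%
        profile = make_profile([1.0, 1.0, 2.0], nodes=("a", "b", "c"))
        table = pool_quantiles([profile], GeneSet("r", frozenset({"a"})))
        row = table[table["quantile"] == 50].iloc[0]
        assert row["n_total"] == 2 and row["n_important"] == 1
        assert row["fraction"] == pytest.approx(50.0)

    def test_recurring_gene_counts_per_occurrence(self):
        p1 = make_profile([1.0, 2.0], nodes=("shared", "x"), pathway_id="p1")
        p2 = make_profile([1.0, 2.0], nodes=("shared", "y"), pathway_id="p2")
        table = pool_quantiles([p1, p2], GeneSet("r", frozenset({"shared"})))
        row = table[table["quantile"] == 50].iloc[0]
        assert row["n_total"] == 2 and row["n_important"] == 2

    def test_empty_bins_omitted(self):
        table = pool_quantiles(
            [make_profile([1.0, 2.0])], GeneSet("r", frozenset({"g0"}))
        )
        assert set(table["quantile"]) == {50, 100}


class TestRegression:
    def test_exact_linear_data(self):
        table = pd.DataFrame({"quantile": [1, 2, 3], "fraction": [10.0, 20.0, 30.0]})
        fit = fit_quantile_regression(table)
        assert fit.slope == pytest.approx(10.0, abs=1e-10)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.adj_r_squared == pytest.approx(1.0, abs=1e-10)

    def test_flat_data(self):
        table = pd.DataFrame({"quantile": [1, 2, 3], "fraction": [10.0, 10.0, 10.0]})
        assert fit_quantile_regression(table).slope == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_normal_equations(self):
        table = pd.DataFrame({"quantile": [1, 2, 3, 4], "fraction": [1.0, 3.0, 2.0, 4.0]})
        fit = fit_quantile_regression(table)
        # closed form: slope = Sxy/Sxx = 4/5, intercept = ybar - slope*xbar
        assert fit.slope == pytest.approx(0.8, abs=1e-12)
        assert fit.intercept == pytest.approx(0.5, abs=1e-12)

    def test_random_fits_match_closed_form_ols(self):
        rng = np.random.default_rng(19)
        for _ in range(50):
            n = int(rng.integers(3, 30))
            x = np.sort(rng.choice(np.arange(1, 101), size=n, replace=False)).astype(float)
            y = rng.normal(size=n) * 10 + 0.3 * x
            fit = fit_quantile_regression(pd.DataFrame({"quantile": x, "fraction": y}))
            sxx = np.sum((x - x.mean()) ** 2)
            slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
            assert fit.slope == pytest.approx(slope, abs=1e-9)
            assert fit.intercept == pytest.approx(y.mean() - slope * x.mean(), abs=1e-9)

    def test_too_few_bins_rejected(self):
        table = pd.DataFrame({"quantile": [1, 2], "fraction": [1.0, 2.0]})
        with pytest.raises(ValueError, match="3"):
            fit_quantile_regression(table)


class TestZNormalize:
    def test_known_values(self):
        z = znormalize(make_profile([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_mean_zero_and_affine_invariance(self):
        rng = np.random.default_rng(23)
        scores = rng.normal(size=40)
        z = znormalize(make_profile(scores))
        assert abs(z.mean()) < 1e-12
        z2 = znormalize(make_profile(2.0 * scores + 5.0))
        np.testing.assert_allclose(z, z2, atol=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            znormalize(make_profile([1.0, 1.0]))


class TestPooledQuantileScores:
    def test_pooling_normalizes_per_pathway_then_ranks_globally(self):
        p1 = make_profile([1.0, 2.0, 3.0], nodes=("a", "b", "c"), pathway_id="p1")
        p2 = make_profile([10.0, 20.0, 30.0], nodes=("d", "e", "f"), pathway_id="p2")
        df = pooled_quantile_scores([p1, p2], GeneSet("r", frozenset({"c", "f"})))
        # both pathways z-normalize to [-1, 0, 1]; pooled tied ranks
        # 1.5, 3.5, 5.5 -> quantiles ceil(100 r / 6)
        assert sorted(df["quantile"]) == [25, 25, 59, 59, 92, 92]
        assert df.loc[df["node_id"] == "c", "is_important"].item()
        assert df["is_important"].sum() == 2


class TestKS:
    def test_complete_separation(self):
        d, _ = ks_cdf_compare([3.0, 4.0], [1.0, 2.0])
        assert d == pytest.approx(1.0)

    def test_identical_samples(self):
        d, p = ks_cdf_compare([1.0, 2.0], [1.0, 2.0])
        assert d == 0.0 and p == 1.0

    def test_wrong_direction_clamps_to_zero(self):
        d, p = ks_cdf_compare([1.0, 2.0], [3.0, 4.0])
        assert d == 0.0 and p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_cdf_compare([], [1.0])

    def test_matches_scipy_one_sided_asymptotic(self):
        rng = np.random.default_rng(29)
        for _ in range(200):
            n, m = rng.integers(5, 60, 2)
            a = rng.normal(0.4, 1.0, n)
            b = rng.normal(0.0, 1.0, m)
            d, p = ks_cdf_compare(a, b)
            ref = scipy.stats.ks_2samp(a, b, alternative="less", method="asymp")
            assert d == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)


class TestWelch:
    def test_worked_example(self):
        res = welch_test([3.0, 4.0, 5.0], [1.0, 2.0, 3.0])
        # t = 2 / sqrt(2/3), Welch-Satterthwaite df = 4
        assert res.statistic == pytest.approx(2.0 / np.sqrt(2.0 / 3.0), abs=1e-12)
        assert res.p_value == pytest.approx(
            float(scipy.stats.t.sf(res.statistic, 4)), abs=1e-12
        )

    def test_identical_groups(self):
        res = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(0.5, abs=1e-12)

    def test_large_shift_is_overwhelming(self):
        rng = np.random.default_rng(31)
        a = rng.normal(10.0, 1.0, 10)
        b = rng.normal(0.0, 1.0, 10)
        assert welch_test(a, b).p_value < 1e-6

    def test_small_groups_untestable(self):
        res = welch_test([1.0], [1.0, 2.0])
        assert not res.testable and np.isnan(res.p_value)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(37)
        for _ in range(100):
            n, m = rng.integers(2, 30, 2)
            a, b = rng.normal(0.5, 1.5, n), rng.normal(0.0, 1.0, m)
            res = welch_test(a, b)
            ref = scipy.stats.ttest_ind(a, b, equal_var=False, alternative="greater")
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)


def enumerate_rank_sum_p(a, b):
    """Oracle: exact one-sided p by enumerating all rank assignments."""
    pooled = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(pooled)
    observed = ranks[: len(a)].sum()
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), len(a)):
        total += 1
        if ranks[list(comb)].sum() >= observed - 1e-9:
            count += 1
    return count / total


class TestWilcoxon:
    def test_maximal_separation_exact(self):
        res = wilcoxon_test([4.0, 5.0, 6.0], [1.0, 2.0, 3.0])
        assert res.statistic == 9.0  # maximal U
        assert res.p_value == pytest.approx(1.0 / 20.0, abs=1e-12)

    def test_identical_groups(self):
        assert wilcoxon_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]).p_value >= 0.5

    def test_reversed_shift(self):
        assert wilcoxon_test([1.0, 2.0], [5.0, 6.0]).p_value > 0.5

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(41)
        for _ in range(25):
            n, m = rng.integers(2, 7, 2)
            a = rng.normal(0.5, 1.0, n)
            b = rng.normal(0.0, 1.0, m)
            res = wilcoxon_test(a, b)
            assert res.p_value == pytest.approx(enumerate_rank_sum_p(a, b), abs=1e-12)

    def test_asymptotic_with_ties_matches_hand_formula(self):
        rng = np.random.default_rng(43)
        for _ in range(25):
            n1, n2 = rng.integers(20, 50, 2)
            a = rng.integers(0, 8, n1).astype(float)
            b = rng.integers(0, 8, n2).astype(float)
            res = wilcoxon_test(a, b)
            pooled = np.concatenate([a, b])
            big_n = len(pooled)
            ranks = scipy.stats.rankdata(pooled)
            u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
            _, counts = np.unique(pooled, return_counts=True)
            tie = (counts**3 - counts).sum() / (big_n * (big_n - 1))
            sigma = np.sqrt(n1 * n2 / 12.0 * (big_n + 1 - tie))
            z = (u - n1 * n2 / 2.0 - 0.5) / sigma
            assert res.p_value == pytest.approx(
                float(scipy.stats.norm.sf(z)), abs=1e-9
            )


class TestBHFDR:
    def test_step_up_example(self):
        adj, flags = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04], atol=1e-12)
        assert flags.all()

    def test_single_p_identity(self):
        adj, flags = bh_fdr([0.5])
        assert adj[0] == 0.5 and not flags[0]

    def test_all_zero_rejected_everywhere(self):
        _, flags = bh_fdr(np.zeros(10))
        assert flags.all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.2])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(47)
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            adj, flags = bh_fdr(p, level=0.05)
            ref_flags, ref_adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_allclose(adj, ref_adj, atol=1e-12)
            # statsmodels flags p_adj <= level; ours is strict, so only
            # check agreement away from the boundary
            off_boundary = np.abs(adj - 0.05) > 1e-12
            assert (flags == ref_flags)[off_boundary].all()

    def test_rejections_superset_of_bonferroni(self):
        rng = np.random.default_rng(53)
        for _ in range(20):
            p = rng.uniform(size=30) ** 2
            _, bh_flags = bh_fdr(p, level=0.05)
            bonf = p * len(p) < 0.05
            assert np.all(bh_flags[bonf])


class TestFisherZ:
    def test_equal_correlations(self):
        z, p = fisher_z(0.5, 50, 0.5, 80)
        assert z == 0.0 and p == 1.0

    def test_hand_computed_example(self):
        z, p = fisher_z(0.9, 100, 0.3, 100)
        expected = (np.arctanh(0.9) - np.arctanh(0.3)) / np.sqrt(2.0 / 97.0)
        assert z == pytest.approx(expected, abs=1e-12)
        assert z == pytest.approx(8.09, abs=0.01)
        assert p < 1e-10

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(0.5, 3, 0.5, 10)


@pytest.fixture(scope="module")
def small_cohort():
    return generate_cohort(SyntheticSpec(n_pathways=25, seed=2))


class TestSensitivityScan:
    def test_default_grid_has_81_alphas(self):
        assert len(DEFAULT_ALPHA_GRID) == 81
        assert DEFAULT_ALPHA_GRID[0] == 0.1 and DEFAULT_ALPHA_GRID[-1] == 0.9

    def test_scan_rows_and_fisher_comparison(self, small_cohort):
        table = sensitivity_scan(
            small_cohort.graphs[:10], small_cohort.important, alphas=[0.3, 0.6]
        )
        assert len(table) == 8  # 2 alphas x 4 variants
        ssc_rows = table[table["variant"] == "ssc"]
        assert ssc_rows["fisher_p"].notna().all()
        other = table[table["variant"] != "ssc"]
        assert other["fisher_p"].isna().all()


class TestModelResults:
    def test_fit_produces_all_tables(self, small_cohort):
        model = CentralityValidation.from_cohort(small_cohort)
        res = model.fit()
        assert res.n_kept > 0
        labels = set(res.regression["centrality"])
        assert {"pagerank-ssc", "katz-ssc", "degree-undirected"} <= labels
        fit = res.regression_fit("pagerank", "ssc")
        assert fit["estimate"] > 0  # planted terminal-ends signal
        assert not res.ks.empty and not res.pathway_tests.empty
        assert res.n_significant("pagerank", "ssc", "wilcoxon") >= 0

    def test_fit_deterministic(self, small_cohort):
        model = CentralityValidation.from_cohort(small_cohort)
        r1, r2 = model.fit(), model.fit()
        for attr in ("filter_reports", "regression", "ks", "pathway_tests"):
            pd.testing.assert_frame_equal(getattr(r1, attr), getattr(r2, attr))

    def test_summary_mentions_key_sections(self, small_cohort):
        res = CentralityValidation.from_cohort(small_cohort).fit()
        text = res.summary()
        assert "Quantile regression" in text
        assert "pagerank-ssc" in text
        assert "CDF comparison" in text

    def test_report_files_written(self, small_cohort, tmp_path):
        res = CentralityValidation.from_cohort(small_cohort).fit()
        res.to_files(tmp_path / "report")
        for name in ("filter_report.tsv", "regression.tsv", "ks.tsv",
                     "pathway_tests.tsv"):
            assert (tmp_path / "report" / name).exists()

    def test_custom_parameters_propagate(self, small_cohort):
        model = CentralityValidation.from_cohort(
            small_cohort,
            models=[("pagerank", "ssc")],
            params={"pagerank": CentralityParams(alpha=0.5, beta=1.0)},
        )
        res = model.fit()
        assert set(res.regression["centrality"]) == {"pagerank-ssc"}
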