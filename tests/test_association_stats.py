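import numpy as np
import pandas as pd
import pytest
from scipy import stats

from teprom import association_stats as assoc
from teprom.expression_dynamics import FoldChangeTable, GeneClusters, rank_bins


def _fc(values, ids=None):
    ids = ids or [f"g{i:04d}" for i in range(len(values))]
    return FoldChangeTable(pd.Series(values, index=ids), ("a", "b"), 1.0)


class TestClusterEnrichment:
    def _setup(self, n_with_in=30, n_in=100, n_with_out=10, n_out=100):
        genes = [f"g{i:04d}" for i in range(n_in + n_out)]
        present = ([True] * n_with_in + [False] * (n_in - n_with_in)
                   + [True] * n_with_out + [False] * (n_out - n_with_out))
        binary = pd.DataFrame({"feat": present}, index=genes)
        labels = pd.Series([1] * n_in + [2] * n_out, index=genes)
        clusters = GeneClusters(labels, "hierarchical", k=2)
        return binary, clusters

    def test_hand_computed_chi2_and_fold(self):
        """2x2 table [[30,70],[10,90]]: expected cells 20/80/20/80 give
        chi2 = 100/20 + 100/80 + 100/20 + 100/80 = 12.5; fold = 0.30/0.10."""
        binary, clusters = self._setup()
        res = assoc.cluster_enrichment(binary, clusters)
        row = res[(res.cluster == 1)].iloc[0]
        assert row["chi2"] == pytest.approx(12.5)
        assert row["fold_enrichment"] == pytest.approx(3.0)
        assert row["test"] == "chi2"

    def test_identical_fractions_are_null(self):
        binary, clusters = self._setup(30, 100, 30, 100)
        res = assoc.cluster_enrichment(binary, clusters)
        row = res[(res.cluster == 1)].iloc[0]
        assert row["chi2"] == pytest.approx(0.0)
        assert row["fold_enrichment"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(1.0)

    def test_small_expected_cells_use_fisher(self):
        binary, clusters = self._setup(3, 10, 1, 10)
        res = assoc.cluster_enrichment(binary, clusters)
        assert set(res["test"]) == {"fisher"}

    def test_chi2_direction_consistent_with_fisher(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = int(rng.integers(5, 60))
            b = int(rng.integers(5, 60))
            binary, clusters = self._setup(a, 100, b, 100)
            res = assoc.cluster_enrichment(binary, clusters)
            row = res[res.cluster == 1].iloc[0]
            table = [[row.n_with, row.n_without], [row.n_with_bg, row.n_without_bg]]
            one_sided = stats.fisher_exact(table, alternative="greater")[1]
            if row.fold_enrichment > 1:
                assert one_sided < 0.5
            elif row.fold_enrichment < 1:
                assert one_sided > 0.5


class TestBH:
    def test_hand_bh_on_four_pvalues(self):
        np.testing.assert_allclose(assoc.bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_monotone_in_ranked_p(self):
        rng = np.random.default_rng(1)
        p = np.sort(rng.uniform(size=50))
        fdr = assoc.bh_fdr(p)
        assert (np.diff(fdr) >= -1e-12).all()
        assert ((fdr >= p - 1e-12) & (fdr <= 1 + 1e-12)).all()


class TestPresenceTest:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(2)
        y = list(rng.normal(size=25))
        fc = _fc(y + y)
        binary = pd.DataFrame({"f": [True] * 25 + [False] * 25},
                              index=fc.values.index)
        res = assoc.presence_fc_test(binary, fc, min_genes=2)
        assert res.iloc[0]["diff"] == pytest.approx(0.0)
        assert res.iloc[0]["p"] == pytest.approx(1.0)

    def test_zero_variance_flagged_degenerate(self):
        fc = _fc([0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0])
        binary = pd.DataFrame({"f": [False] * 4 + [True] * 4}, index=fc.values.index)
        res = assoc.presence_fc_test(binary, fc, min_genes=2)
        assert res.iloc[0]["diff"] == pytest.approx(1.0)
        assert res.iloc[0]["flag"] == "degenerate"
        assert np.isnan(res.iloc[0]["p"])

    def test_welch_statistic_matches_hand_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 4.0, 9.0])
        t, p = assoc.welch_t(a, b)
        se = np.sqrt(a.var(ddof=1) / 4 + b.var(ddof=1) / 3)
        assert t == pytest.approx((a.mean() - b.mean()) / se)


class TestDosage:
    def test_noise_free_planted_effect_forces_bin_means(self):
        beta = 0.4
        counts = pd.Series([0, 1, 2, 3, 4, 5, 6, 0, 1, 2],
                           index=[f"g{i:04d}" for i in range(10)])
        fc = _fc([beta * c for c in counts], list(counts.index))
        curve = assoc.dosage_analysis(counts, fc, cap=5)
        means = curve.set_index("category")["mean_fc"]
        for k in range(5):
            assert means[str(k)] == pytest.approx(beta * k)
        assert means[">=5"] == pytest.approx(beta * 5.5)

    def test_empty_bin_reported_missing(self):
        counts = pd.Series([0, 0, 1, 1, 5, 5], index=[f"g{i}" for i in range(6)])
        fc = _fc([0.1] * 6, list(counts.index))
        curve = assoc.dosage_analysis(counts, fc, cap=5)
        row = curve.set_index("category").loc["3"]
        assert row["n_genes"] == 0
        assert np.isnan(row["mean_fc"]) and np.isnan(row["p_vs_prev"])

    def test_adjacent_tests_skip_empty_bins(self):
        counts = pd.Series([0] * 5 + [5] * 5, index=[f"g{i}" for i in range(10)])
        rng = np.random.default_rng(3)
        fc = _fc(list(rng.normal(size=10)), list(counts.index))
        curve = assoc.dosage_analysis(counts, fc, cap=5)
        # the >=5 bin is compared against the last occupied bin (0)
        assert not np.isnan(curve.iloc[-1]["p_vs_prev"])


class TestDistance:
    def test_no_repeat_genes_form_zero_contrast_reference(self):
        nearest = pd.Series([np.nan, np.nan, 100.0, 1500.0],
                            index=["g0", "g1", "g2", "g3"])
        fc = _fc([0.5, 0.7, 2.0, 1.0], ["g0", "g1", "g2", "g3"])
        res = assoc.distance_analysis(nearest, fc, (0, 1000, 2000))
        ref = res[res.bin == "none"].iloc[0]
        assert ref["contrast"] == 0.0
        assert ref["mean_fc"] == pytest.approx(0.6)

    def test_half_open_bin_edges_honored(self):
        nearest = pd.Series([1000.0] + [np.nan] * 3, index=["g0", "g1", "g2", "g3"])
        fc = _fc([1.0, 0.0, 0.0, 0.0], ["g0", "g1", "g2", "g3"])
        res = assoc.distance_analysis(nearest, fc, (0, 1000, 2000)).set_index("bin")
        assert res.loc["[1000,2000)", "n_genes"] == 1
        assert res.loc["[0,1000)", "n_genes"] == 0

    def test_planted_exponential_decay_recovered_monotone(self):
        rng = np.random.default_rng(4)
        n = 3000
        dist = rng.uniform(0, 8000, size=n)
        none = rng.random(n) < 0.3
        nearest = pd.Series(np.where(none, np.nan, dist),
                            index=[f"g{i:05d}" for i in range(n)])
        effect = np.where(none, 0.0, 1.5 * np.exp(-dist / 1500))
        fc = _fc(list(effect + rng.normal(0, 0.3, size=n)), list(nearest.index))
        res = assoc.distance_analysis(nearest, fc, (0, 2000, 4000, 6000, 8000))
        contrasts = res[res.bin != "none"]["contrast"].to_numpy()
        assert (np.diff(contrasts) < 0).all()


class TestBinCorrelation:
    def test_linear_relation_gives_unit_pcc(self):
        rng = np.random.default_rng(5)
        n = 1200
        fc = _fc(list(np.sort(rng.normal(size=n))[::-1]))
        bins = rank_bins(fc, group_size=100)
        per_bin_mean = {lab: fc.values.loc[bins.members(lab)].mean()
                        for lab in bins.label_order()}
        # construct presence whose per-bin fraction is exactly linear in mean FC
        binary = pd.Series(False, index=fc.values.index)
        for lab in bins.label_order():
            members = bins.members(lab)
            frac = (per_bin_mean[lab] - min(per_bin_mean.values())) / \
                (max(per_bin_mean.values()) - min(per_bin_mean.values()))
            k = int(round(frac * len(members)))
            binary.loc[members[:k]] = True
            per_bin_mean[lab] = k / len(members)
        # replace fc by the achieved fractions to make the relation exact
        fc2 = _fc([per_bin_mean[bins.labels[g]] for g in fc.values.index],
                  list(fc.values.index))
        r, p, per_bin = assoc.bin_correlation(bins, binary, fc2)
        assert r == pytest.approx(1.0)

    def test_constant_fraction_flagged_undefined(self):
        fc = _fc(list(np.linspace(3, -3, 300)))
        bins = rank_bins(fc, group_size=100)
        binary = pd.Series(True, index=fc.values.index)
        r, p, per_bin = assoc.bin_correlation(bins, binary, fc)
        assert np.isnan(r)
        assert per_bin.attrs.get("flag") == "constant"

    def test_requires_three_bins(self):
        fc = _fc(list(np.linspace(1, -1, 200)))
        bins = rank_bins(fc, group_size=100)
        with pytest.raises(ValueError):
            assoc.bin_correlation(bins, pd.Series(True, index=fc.values.index), fc)


class TestMultipleRegression:
    def test_noise_free_exact_coefficients(self):
        rng = np.random.default_rng(6)
        n = 200
        X = pd.DataFrame({"x1": rng.poisson(2, n).astype(float),
                          "x2": rng.poisson(1, n).astype(float)},
                         index=[f"g{i:04d}" for i in range(n)])
        y = 0.3 * X["x1"] + 0.1 * X["x2"]
        fc = FoldChangeTable(y, ("a", "b"), 1.0)
        res = assoc.multiple_regression(fc, X).set_index("feature")
        assert res.loc["x1", "coef"] == pytest.approx(0.3, abs=1e-12)
        assert res.loc["x2", "coef"] == pytest.approx(0.1, abs=1e-12)

    def test_duplicated_column_dropped_with_warning(self):
        rng = np.random.default_rng(7)
        n = 50
        X = pd.DataFrame({"a_dup": rng.poisson(2, n).astype(float)},
                         index=[f"g{i:04d}" for i in range(n)])
        X["b_dup"] = X["a_dup"]
        fc = FoldChangeTable(pd.Series(rng.normal(size=n), index=X.index),
                             ("a", "b"), 1.0)
        with pytest.warns(UserWarning, match="b_dup"):
            res = assoc.multiple_regression(fc, X)
        assert list(res["feature"]) == ["a_dup"]
        assert res.attrs["dropped_collinear"] == ["b_dup"]

    def test_too_few_genes_errors(self):
        X = pd.DataFrame(np.eye(3), index=list("abc"), columns=["x", "y", "z"])
        fc = FoldChangeTable(pd.Series([1.0, 2, 3], index=list("abc")), ("a", "b"), 1)
        with pytest.raises(ValueError):
            assoc.multiple_regression(fc, X)


class TestExpressionCountCorrelation:
    def test_perfect_linear_gives_one(self):
        from teprom.io_formats import ExpressionMatrix
        counts = pd.Series(np.arange(50, dtype=float),
                           index=[f"g{i:03d}" for i in range(50)])
        values = pd.DataFrame({"s1": np.exp2(counts) - 1})
        values.index = counts.index
        expr = ExpressionMatrix(values, {"s1": "a"}, ["a"])
        res = assoc.expression_count_correlation(expr, counts, pseudocount=1)
        assert res.iloc[0]["pcc"] == pytest.approx(1.0)

    def test_partialling_out_the_variable_itself_zeroes(self):
        from teprom.io_formats import ExpressionMatrix
        rng = np.random.default_rng(8)
        counts = pd.Series(rng.poisson(3, 100).astype(float),
                           index=[f"g{i:03d}" for i in range(100)])
        values = pd.DataFrame({"s1": rng.lognormal(1, 1, 100)}, index=counts.index)
        expr = ExpressionMatrix(values, {"s1": "a"}, ["a"])
        res = assoc.expression_count_correlation(expr, counts, control=counts)
        assert abs(res.iloc[0]["partial_pcc"]) < 1e-8

    def test_null_counts_give_small_pcc(self):
        from teprom.io_formats import ExpressionMatrix
        rng = np.random.default_rng(9)
        n = 2000
        hits = 0
        for trial in range(20):
            counts = pd.Series(rng.poisson(2, n).astype(float),
                               index=[f"g{i:05d}" for i in range(n)])
            values = pd.DataFrame({"s1": rng.lognormal(1, 1, n)}, index=counts.index)
            expr = ExpressionMatrix(values, {"s1": "a"}, ["a"])
            res = assoc.expression_count_correlation(expr, counts)
            if abs(res.iloc[0]["pcc"]) < 3 / np.sqrt(n):
                hits += 1
        assert hits >= 18  # ~99.7% expected under the null


class TestOrthologs:
    def test_identical_counts_give_unit_pcc(self):
        rng = np.random.default_rng(10)
        ids = [f"g{i:03d}" for i in range(40)]
        counts = pd.Series(rng.poisson(3, 40).astype(float), index=ids)
        pairs = pd.DataFrame({"a": ids, "b": ids})
        res = assoc.ortholog_delta_association(pairs, counts, counts)
        assert res["count_pcc"] == pytest.approx(1.0)

    def test_planted_shared_latent_count_recovered(self):
        rng = np.random.default_rng(11)
        n = 500
        latent = rng.poisson(4, n)
        ca = pd.Series((latent + rng.poisson(1, n)).astype(float),
                       index=[f"m{i:04d}" for i in range(n)])
        cb = pd.Series((latent + rng.poisson(1, n)).astype(float),
                       index=[f"h{i:04d}" for i in range(n)])
        pairs = pd.DataFrame({"a": ca.index, "b": cb.index})
        res = assoc.ortholog_delta_association(pairs, ca, cb)
        assert res["count_pcc"] > 0.6
        assert res["count_p"] < 1e-6

    def test_empty_pair_list_errors(self):
        counts = pd.Series([1.0], index=["g1"])
        with pytest.raises(ValueError):
            assoc.ortholog_delta_association(
                pd.DataFrame({"a": [], "b": []}), counts, counts)


class TestGenesetEnrichment:
    def test_hand_hypergeometric(self):
        """Universe 10, set 5, query 3 all inside: P(X>=3) = C(5,3)/C(10,3)."""
        universe = [f"g{i}" for i in range(10)]
        collections = {"setA": ("", tuple(universe[:5]))}
        res = assoc.geneset_enrichment(universe[:3], universe, collections)
        assert res.iloc[0]["p"] == pytest.approx(10 / 120)

    def test_query_equal_universe_gives_p1(self):
        universe = [f"g{i}" for i in range(10)]
        collections = {"s1": ("", tuple(universe[:4])), "s2": ("", tuple(universe[5:]))}
        res = assoc.geneset_enrichment(universe, universe, collections)
        assert (res["p"] == 1.0).all()

    def test_disjoint_query_gives_zero_fold(self):
        universe = [f"g{i}" for i in range(10)]
        collections = {"s1": ("", tuple(universe[:5]))}
        res = assoc.geneset_enrichment(universe[5:], universe, collections)
        assert res.iloc[0]["fold"] == 0.0
        assert res.iloc[0]["p"] == pytest.approx(1.0)
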