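import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crabtree.omics import (MetaboliteAbundanceTable, compute_fpkm,
                            differential_metabolome, fold_change,
                            log2_expression_compare, read_abundance_table,
                            summarize_significance, welch_test)
from crabtree.synth import make_metabolome

from _oracles import welch_reference


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_known_groups_match_reference(self):
        t, df, p = welch_test([10, 12, 14], [20, 22, 24])
        rt, rdf, rp = welch_reference([10, 12, 14], [20, 22, 24])
        assert t == pytest.approx(rt, abs=1e-12)
        assert df == pytest.approx(rdf, abs=1e-12)
        assert p == pytest.approx(rp, abs=1e-12)

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n1, n2 = rng.integers(2, 9, 2)
            a = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), n1)
            b = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), n2)
            t, df, p = welch_test(a, b)
            rt, rdf, rp = welch_reference(a, b)
            assert abs(t - rt) < 1e-10 and abs(df - rdf) < 1e-10 and abs(p - rp) < 1e-10

    def test_matches_scipy_cross_check(self):
        """Independent route: scipy's unequal-variance t-test."""
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 6), rng.normal(1, 2, 6)
        t, _, p = welch_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_swap_antisymmetry(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 9.0]
        t1, _, p1 = welch_test(a, b)
        t2, _, p2 = welch_test(b, a)
        assert t1 == -t2 and p1 == p2

    def test_degenerate_zero_variance(self):
        t, _, p = welch_test([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)
        t, _, p = welch_test([2.0, 2.0], [3.0, 3.0])
        assert p == 0.0 and np.isinf(t)

    def test_type_one_error_calibration(self):
        """Null lognormal groups, n=6/6, 200 metabolites: the fraction with
        p <= 0.05 sits at the nominal level within 0.02."""
        rng = np.random.default_rng(42)
        hits = 0
        n = 200
        for _ in range(n):
            a = rng.lognormal(0, 0.4, 6)
            b = rng.lognormal(0, 0.4, 6)
            _, _, p = welch_test(a, b)
            hits += p <= 0.05
        assert abs(hits / n - 0.05) <= 0.02


class TestFoldChange:
    def test_planted_adenine_ratio_exact(self):
        table = make_metabolome(seed=0)
        a = table.group_values("adenine", "Ss")
        b = table.group_values("adenine", "Sc")
        assert fold_change(a, b) == pytest.approx(38.76, abs=1e-12)

    def test_equal_means(self):
        assert fold_change([2, 4], [1, 5]) == 1.0

    def test_reciprocal_product_is_one(self):
        a, b = [1.0, 3.0, 8.0], [2.0, 2.0, 5.0]
        assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0)

    def test_zero_denominator_flagged_infinite(self):
        assert fold_change([1.0, 2.0], [0.0, 0.0]) == float("inf")


class TestSummarize:
    def _results(self, ps, fcs):
        return pd.DataFrame({"p": ps, "fold_change": fcs,
                             "super_pathway": "SP", "sub_pathway": "sub"},
                            index=[f"m{i}" for i in range(len(ps))])

    def test_threshold_bins(self):
        res = self._results([0.01, 0.04, 0.07, 0.2, 0.9], [2, 2, 2, 2, 2])
        counts = summarize_significance(res)["counts"]
        assert counts["n_significant"] == 2
        assert counts["n_trend"] == 1

    def test_all_null(self):
        res = self._results([1.0] * 4, [1.5] * 4)
        counts = summarize_significance(res)["counts"]
        assert counts["n_significant"] == 0 and counts["n_trend"] == 0

    def test_direction_split(self):
        res = self._results([0.01, 0.02, 0.03, 0.04, 0.04, 0.5],
                            [2.0, 3.0, 1.5, 0.5, 0.2, 4.0])
        counts = summarize_significance(res)["counts"]
        assert counts["n_significant_up"] == 3
        assert counts["n_significant_down"] == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_significance(pd.DataFrame(columns=["p", "fold_change"]))


class TestDifferentialMetabolome:
    def test_pathways_carried_through(self):
        table = make_metabolome(seed=1)
        res = differential_metabolome(table, "Ss", "Sc")
        assert res.loc["adenine", "super_pathway"] == "NUCLEOTIDES"
        assert set(res.columns) >= {"fold_change", "t", "df", "p"}

    def test_bh_column_optional(self):
        table = make_metabolome(seed=1)
        res = differential_metabolome(table, "Ss", "Sc", bh_fdr=True)
        assert "p_bh" in res.columns
        assert (res["p_bh"] >= res["p"] - 1e-12).all()

    def test_two_groups_required(self):
        frame = pd.DataFrame({"super_pathway": ["x"], "sub_pathway": ["y"],
                              "s1": [1.0], "s2": [1.0]}, index=["m"])
        with pytest.raises(ValueError, match="two groups"):
            MetaboliteAbundanceTable(frame, {"s1": "A", "s2": "A"})


class TestDecimalCommaDialect:
    def test_read_decimal_comma(self, tmp_path):
        path = tmp_path / "table.tsv"
        path.write_text("metabolite\tfold\nadenine\t38,76\n")
        df = read_abundance_table(path, decimal=",")
        assert df["fold"].iloc[0] == pytest.approx(38.76)


class TestFPKM:
    def test_closed_form(self):
        rec = pd.DataFrame({"gene": ["a"], "length": [2000], "s1": [500]})
        out = compute_fpkm(rec, totals={"s1": 1e7})
        assert out["s1"].iloc[0] == pytest.approx(25.0, abs=1e-12)

    def test_zero_count(self):
        rec = pd.DataFrame({"gene": ["a", "b"], "length": [1000, 1000],
                            "s1": [0, 100]})
        assert compute_fpkm(rec)["s1"].iloc[0] == 0.0

    def test_depth_scale_invariance(self):
        rec = pd.DataFrame({"gene": list("abc"), "length": [500, 1000, 2000],
                            "s1": [10, 20, 40]})
        doubled = rec.copy()
        doubled["s1"] = rec["s1"] * 2
        pd.testing.assert_series_equal(compute_fpkm(rec)["s1"],
                                       compute_fpkm(doubled)["s1"])

    def test_inverts_to_counts_exactly(self):
        rng = np.random.default_rng(3)
        rec = pd.DataFrame({"gene": [f"g{i}" for i in range(50)],
                            "length": rng.integers(200, 5000, 50),
                            "s1": rng.integers(0, 1000, 50)})
        total = float(rec["s1"].sum())
        f = compute_fpkm(rec)
        back = f["s1"] * f["length"] * total / 1e9
        assert np.allclose(back, rec["s1"], atol=1e-9)

    def test_zero_total_rejected(self):
        rec = pd.DataFrame({"gene": ["a"], "length": [100], "s1": [0]})
        with pytest.raises(ValueError, match="total"):
            compute_fpkm(rec)


class TestLog2Compare:
    def test_pseudocount_arithmetic(self):
        rec = pd.DataFrame({"gene": ["a", "b"], "length": [1, 1],
                            "s1": [25.0, 0.0]})
        out = log2_expression_compare(rec)
        assert out["s1"].iloc[0] == pytest.approx(np.log2(26.0))
        assert out["s1"].iloc[1] == 0.0

    def test_monotone(self):
        rec = pd.DataFrame({"gene": list("ab"), "length": [1, 1],
                            "s1": [10.0, 20.0]})
        out = log2_expression_compare(rec)
        assert out["s1"].iloc[1] > out["s1"].iloc[0]
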