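import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regulomeshift import diffexpr
from regulomeshift.diffexpr import (
    ProteinQuantTable,
    QPCRRecord,
    condition_means,
    ddct_fold_change,
    filter_by_peptide_count,
    log2_fold_change,
    select_de_genes,
    tas_normalize,
    two_sample_t,
)


def closed_form_t(x, y, equal_variance=True):
    """Independent textbook two-sample t (oracle for the implementation)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if equal_variance:
        sp2 = ((n1 - 1) * vx + (n2 - 1) * vy) / (n1 + n2 - 2)
        t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    else:
        se2 = vx / n1 + vy / n2
        t = (x.mean() - y.mean()) / np.sqrt(se2)
        df = se2 ** 2 / ((vx / n1) ** 2 / (n1 - 1)
                         + (vy / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, p, df


class TestTwoSampleT:
    def test_pooled_variance_example(self):
        res = two_sample_t((1, 2, 3), (2, 3, 4), equal_variance=True)
        assert res.t == pytest.approx(-1.2247, abs=1e-4)
        assert res.df == 4
        assert res.p == pytest.approx(0.2879, abs=1e-4)

    def test_identical_groups_give_p_one(self):
        res = two_sample_t((1, 2, 3), (1, 2, 3))
        assert res.t == 0.0
        assert res.p == 1.0

    def test_welch_separates_tight_far_groups(self):
        res = two_sample_t((0, 0.1), (10, 10.1), equal_variance=False)
        assert res.p < 0.05

    def test_zero_variance_equal_means_flagged(self):
        res = two_sample_t((5, 5), (5, 5))
        assert res.degenerate
        assert res.p == 1.0

    @pytest.mark.parametrize("equal_variance", [True, False])
    def test_matches_closed_form_on_exhaustive_grids(self, equal_variance):
        """All |x|=|y|=3 integer grids in {0..3} vs the textbook formulas."""
        grid = list(itertools.product(range(4), repeat=3))
        for x in grid:
            for y in grid:
                vx = np.var(x, ddof=1)
                vy = np.var(y, ddof=1)
                if vx == 0 and vy == 0:
                    continue
                got = two_sample_t(x, y, equal_variance=equal_variance)
                t, p, df = closed_form_t(x, y, equal_variance)
                assert got.t == pytest.approx(t, abs=1e-9)
                assert got.p == pytest.approx(p, abs=1e-9)
                assert got.df == pytest.approx(df, abs=1e-9)


class TestFoldChange:
    @pytest.mark.parametrize("ko,wt,expected", [
        (5.0, 5.0, 0.0),
        (40.0, 5.0, 3.0),
        (0.0, 0.0, 0.0),  # symmetric floor
    ])
    def test_log2_fold_change(self, ko, wt, expected):
        assert log2_fold_change(ko, wt) == pytest.approx(expected)

    def test_floor_applied_only_when_a_mean_is_zero(self):
        assert log2_fold_change(8.0, 1.0) == pytest.approx(3.0)
        assert log2_fold_change(0.0, 7.0, floor=1.0) == pytest.approx(-3.0)


class TestSelection:
    def test_hand_enumerated_toy_table(self):
        df = pd.DataFrame({
            "gene_id": list("abcde"),
            "p": [0.01, 0.01, 0.2, 0.01, 0.04],
            "log2fc": [3.0, 1.0, 5.0, -2.5, -1.9],
        })
        sel = select_de_genes(df)
        assert list(sel["gene_id"]) == ["a", "d"]
        assert list(sel["direction"]) == ["up", "down"]

    def test_empty_input(self):
        df = pd.DataFrame(columns=["gene_id", "p", "log2fc"])
        assert len(select_de_genes(df)) == 0

    def test_boundary_is_strict(self):
        df = pd.DataFrame({
            "gene_id": ["x", "y"],
            "p": [0.001, 0.001],
            "log2fc": [2.0, -2.0],
        })
        assert len(select_de_genes(df)) == 0

    def test_count_matches_brute_force_on_random_tables(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 60))
            df = pd.DataFrame({
                "gene_id": [f"g{i}" for i in range(n)],
                "p": rng.uniform(0, 0.2, n),
                "log2fc": rng.normal(0, 3, n),
            })
            expected = sum(
                1 for _, r in df.iterrows()
                if r["p"] < 0.05 and (r["log2fc"] > 2 or r["log2fc"] < -2)
            )
            assert len(select_de_genes(df)) == expected


class TestConditionMeans:
    def test_arithmetic_means(self, toy_matrix):
        m = condition_means(toy_matrix)
        assert m.loc["gA", "mean_wt"] == pytest.approx(3.0)
        assert m.loc["gA", "mean_ko"] == pytest.approx(7.0)
        assert m.loc["gC", "mean_wt"] == pytest.approx(0.0)


class TestDdct:
    def test_unit_and_doubling_folds(self):
        base = QPCRRecord(ct_target=[20.0], ct_reference=[15.0])
        assert ddct_fold_change(base, base) == pytest.approx(1.0)
        test = QPCRRecord(ct_target=[19.0], ct_reference=[15.0])
        assert ddct_fold_change(test, base) == pytest.approx(2.0)

    def test_three_hundred_fold_anchor(self):
        # a ddCt of about -8.23 corresponds to a >300-fold induction
        control = QPCRRecord(ct_target=[25.0], ct_reference=[15.0])
        test = QPCRRecord(ct_target=[25.0 - 8.2288], ct_reference=[15.0])
        assert ddct_fold_change(test, control) == pytest.approx(300.0,
                                                                rel=1e-3)


class TestProteinQuant:
    def _table(self, areas, counts):
        return ProteinQuantTable(
            pd.DataFrame(areas).T.rename(columns=str),
            pd.Series(counts),
        )

    def test_tas_equalizes_totals_and_preserves_ratios(self):
        areas = pd.DataFrame(
            {"s1": [10.0, 30.0], "s2": [40.0, 40.0]}, index=["p1", "p2"])
        t = ProteinQuantTable(areas, pd.Series([3, 3],
                                               index=["p1", "p2"]))
        out = tas_normalize(t)
        totals = out.areas.sum(axis=0)
        assert totals["s1"] == pytest.approx(totals["s2"], abs=1e-9)
        # 2x2 arithmetic oracle: totals 40 and 80, target 60
        assert out.areas.loc["p1", "s1"] == pytest.approx(15.0)
        assert out.areas.loc["p1", "s2"] == pytest.approx(30.0)
        ratio = out.areas["s2"] / areas["s2"]
        assert ratio.std() == pytest.approx(0.0, abs=1e-12)

    def test_tas_identity_when_totals_equal(self):
        areas = pd.DataFrame({"s1": [1.0, 2.0], "s2": [2.0, 1.0]},
                             index=["p1", "p2"])
        t = ProteinQuantTable(areas, pd.Series([3, 3], index=["p1", "p2"]))
        out = tas_normalize(t)
        pd.testing.assert_frame_equal(out.areas, areas)

    def test_tas_zero_total_sample_errors(self):
        areas = pd.DataFrame({"s1": [1.0], "s2": [0.0]}, index=["p1"])
        t = ProteinQuantTable(areas, pd.Series([3], index=["p1"]))
        with pytest.raises(ValueError, match="s2"):
            tas_normalize(t)

    def test_peptide_count_filter(self):
        areas = pd.DataFrame({"s1": [1.0, 1.0, 1.0, 1.0]},
                             index=list("abcd"))
        t = ProteinQuantTable(areas,
                              pd.Series([1, 2, 3, 4], index=list("abcd")))
        assert list(filter_by_peptide_count(t).areas.index) == ["c", "d"]
        assert len(filter_by_peptide_count(t, min_peptides=1).areas) == 4


class TestDifferentialExpression:
    def test_full_table_columns_and_flags(self, toy_matrix):
        df = diffexpr.differential_expression(toy_matrix)
        assert set(["gene_id", "mean_wt", "mean_ko", "log2fc", "t", "p",
                    "significant", "selected",
                    "direction"]) <= set(df.columns)
        assert (df["selected"] <= df["significant"]).all()

    def test_bh_option_adds_monotone_q_values(self, toy_matrix):
        df = diffexpr.differential_expression(toy_matrix, bh_correct=True)
        assert (df["q_value"] >= df["p"] - 1e-12).all()
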