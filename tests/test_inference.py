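"""Contrast tests: robust difference-in-means and composition χ²."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rtiepi.episodes import TYPOLOGIES
from rtiepi.inference import (
    DegenerateMarginError,
    composition_chisq,
    index_level_records,
    robust_diff_test,
    table5_contrasts,
)


def make_records(group0, group1, index_type="in_person", splits=None):
    """Index-level records from two outcome vectors (fu_total counts).

    ``splits`` optionally gives per-record (ip, rt, tm) tuples; by default
    the whole count is in-person.
    """
    rows = []
    for g, counts in ((0, group0), (1, group1)):
        for i, total in enumerate(counts):
            if splits is not None:
                ip, rt, tm = splits[(g, i)]
            else:
                ip, rt, tm = total, 0, 0
            rows.append(
                {
                    "episode_id": f"E{g}_{i}",
                    "index_type": index_type,
                    "group": g,
                    "fu_in_person": ip,
                    "fu_remote_traditional": rt,
                    "fu_telemedicine": tm,
                    "fu_total": ip + rt + tm,
                }
            )
    return pd.DataFrame(rows)


def hc1_se_by_hand(y, g):
    """Sandwich variance of the slope, by explicit summation (HC1)."""
    X = np.column_stack([np.ones_like(g), g])
    n, k = X.shape
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    meat = X.T @ (X * resid[:, None] ** 2)
    bread = np.linalg.inv(X.T @ X)
    cov = bread @ meat @ bread * n / (n - k)
    return float(np.sqrt(cov[1, 1]))


class TestRobustDiff:
    def test_identical_groups_give_zero_difference(self):
        res = robust_diff_test(make_records([0, 1, 2], [0, 1, 2]))
        assert res.estimate == pytest.approx(0.0, abs=1e-12)

    def test_estimate_is_difference_in_group_means(self):
        res = robust_diff_test(make_records([0, 1, 2], [1, 2, 3]))
        assert res.estimate == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_ols_coefficient_equals_mean_difference(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.poisson(0.6, 40), rng.poisson(0.9, 55)
        res = robust_diff_test(make_records(a, b))
        assert res.estimate == pytest.approx(b.mean() - a.mean(), abs=1e-10)

    def test_robust_se_matches_hand_summed_hc1(self):
        rng = np.random.default_rng(3)
        a, b = rng.poisson(0.5, 30), rng.poisson(1.0, 20)
        res = robust_diff_test(make_records(a, b))
        y = np.concatenate([a, b]).astype(float)
        g = np.concatenate([np.zeros(30), np.ones(20)])
        assert res.se == pytest.approx(hc1_se_by_hand(y, g), abs=1e-10)

    def test_p_value_uses_t_reference_with_n_minus_2_df(self):
        rng = np.random.default_rng(4)
        a, b = rng.poisson(0.5, 25), rng.poisson(1.2, 25)
        res = robust_diff_test(make_records(a, b))
        t = res.estimate / res.se
        assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t), 48), rel=1e-9)

    def test_single_group_raises(self):
        records = make_records([1, 2], [])
        with pytest.raises(ValueError):
            robust_diff_test(records)

    def test_zero_variance_is_flagged_degenerate(self):
        res = robust_diff_test(make_records([1, 1, 1], [1, 1, 1]))
        assert res.degenerate
        assert res.estimate == 0.0
        assert np.isnan(res.p_value)


class TestCompositionChisq:
    @staticmethod
    def pearson_by_hand(table):
        table = np.asarray(table, dtype=float)
        total = table.sum()
        chi2 = 0.0
        for i in range(table.shape[0]):
            for j in range(table.shape[1]):
                expected = table[i].sum() * table[:, j].sum() / total
                chi2 += (table[i, j] - expected) ** 2 / expected
        return chi2

    @staticmethod
    def records_from_table(table):
        # one record per group holding the whole row's counts
        splits = {
            (0, 0): tuple(table[0]),
            (1, 0): tuple(table[1]),
        }
        return make_records([sum(table[0])], [sum(table[1])], splits=splits)

    def test_proportional_rows_give_zero(self):
        res = composition_chisq(self.records_from_table([[10, 20, 30], [20, 40, 60]]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.df == 2

    @pytest.mark.parametrize(
        "table", [[[10, 20, 30], [30, 20, 10]], [[5, 1, 7], [2, 9, 4]]]
    )
    def test_matches_hand_summed_pearson_formula(self, table):
        res = composition_chisq(self.records_from_table(table))
        assert res.statistic == pytest.approx(self.pearson_by_hand(table), abs=1e-10)
        assert res.df == 2
        assert res.p_value == pytest.approx(
            stats.chi2.sf(res.statistic, 2), rel=1e-12
        )

    def test_doubling_cells_doubles_statistic(self):
        t1 = [[10, 20, 30], [30, 20, 10]]
        t2 = [[20, 40, 60], [60, 40, 20]]
        r1 = composition_chisq(self.records_from_table(t1))
        r2 = composition_chisq(self.records_from_table(t2))
        assert r2.statistic == pytest.approx(2 * r1.statistic, rel=1e-12)

    def test_invariant_under_column_permutation(self):
        t = [[10, 20, 30], [30, 20, 10]]
        perm = [[30, 10, 20], [10, 30, 20]]
        r1 = composition_chisq(self.records_from_table(t))
        r2 = composition_chisq(self.records_from_table(perm))
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_zero_margin_raises_naming_the_margin(self):
        records = self.records_from_table([[10, 0, 30], [30, 0, 10]])
        with pytest.raises(DegenerateMarginError, match="column"):
            composition_chisq(records)


class TestTable5:
    def test_single_stratum_row_equals_all_row(self):
        rng = np.random.default_rng(9)
        records = make_records(rng.poisson(0.5, 60), rng.poisson(0.8, 60),
                               index_type="telemedicine")
        # give the table non-degenerate columns
        records.loc[::3, "fu_remote_traditional"] += 1
        records.loc[::5, "fu_telemedicine"] += 1
        records["fu_total"] = (
            records["fu_in_person"]
            + records["fu_remote_traditional"]
            + records["fu_telemedicine"]
        )
        out = table5_contrasts(records).set_index("index_type")
        for col in ["diff_total", "se_total", "chi2"]:
            assert out.loc["all", col] == pytest.approx(
                out.loc["telemedicine", col], abs=1e-12
            )

    def test_empty_stratum_emitted_with_flag(self):
        records = make_records([1, 2, 0], [2, 3, 1], index_type="in_person")
        out = table5_contrasts(records).set_index("index_type")
        assert "empty_group" in out.loc["remote_traditional", "flags"]
        assert np.isnan(out.loc["remote_traditional", "diff_total"])


class TestGroupAssignment:
    def test_records_split_by_march_june_windows(self):
        eps = pd.DataFrame(
            {
                "episode_id": ["a", "b", "c", "d"],
                "index_type": ["in_person"] * 4,
                "index_date": pd.to_datetime(
                    ["2020-04-01", "2018-05-10", "2020-01-15", "2019-03-01"]
                ),
                "fu_in_person": [1, 0, 2, 1],
                "fu_remote_traditional": [0, 1, 0, 0],
                "fu_telemedicine": [0, 0, 0, 0],
                "fu_total": [1, 1, 2, 1],
            }
        )
        rec = index_level_records(eps)
        assert set(rec["episode_id"]) == {"a", "b", "d"}  # January excluded
        assert rec.set_index("episode_id")["group"].to_dict() == {
            "a": 1, "b": 0, "d": 0
        }
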