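import numpy as np
import pandas as pd
import pytest
from scipy import stats

from p53lnc.survival_analysis import (
    cox_fit,
    km_estimate,
    normalize_scores,
    overlap_fisher,
    read_gene_set,
    split_by_p53,
    ssgsea_score,
    tertile_groups,
)


def literal_ssgsea(values, gene_names, gene_set, alpha):
    """Independent literal-summation oracle for one sample."""
    ranks = stats.rankdata(values)
    order = sorted(range(len(values)), key=lambda i: (-ranks[i], gene_names[i]))
    in_set = [gene_names[i] in gene_set for i in order]
    w_all = sum(ranks[i] ** alpha for i, flag in zip(order, in_set) if flag)
    n_out = sum(not f for f in in_set)
    es = 0.0
    cum_in = cum_out = 0.0
    for i, flag in zip(order, in_set):
        if flag:
            cum_in += ranks[i] ** alpha
        else:
            cum_out += 1
        es += cum_in / w_all - cum_out / n_out
    return es


class TestSsgsea:
    def test_hand_example_top_gene_unweighted(self):
        # expressions 4>3>2>1, set = top gene, alpha=0:
        # ES = 1 + 2/3 + 1/3 + 0 = 2
        expr = pd.DataFrame({"s": [4.0, 3.0, 2.0, 1.0]}, index=list("abcd"))
        assert ssgsea_score(expr, {"a"}, alpha=0.0)["s"] == pytest.approx(2.0)

    def test_rank_invariance_under_monotone_transform(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(30, 4)), index=[f"g{i}" for i in range(30)]
        )
        gene_set = {f"g{i}" for i in range(0, 30, 3)}
        base = ssgsea_score(expr, gene_set)
        transformed = ssgsea_score(np.exp(expr / 2), gene_set)
        pd.testing.assert_series_equal(base, transformed)

    def test_matches_literal_summation_oracle(self, rng):
        genes = [f"g{i}" for i in range(50)]
        expr = pd.DataFrame(rng.normal(size=(50, 10)),
                            index=genes, columns=[f"s{j}" for j in range(10)])
        gene_set = set(rng.choice(genes, 12, replace=False))
        scores = ssgsea_score(expr, gene_set, alpha=0.75)
        for j, col in enumerate(expr.columns):
            oracle = literal_ssgsea(expr[col].to_numpy(), genes, gene_set, 0.75)
            assert scores[col] == pytest.approx(oracle, abs=1e-9)

    def test_degenerate_gene_sets_error(self):
        expr = pd.DataFrame({"s": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            ssgsea_score(expr, {"zzz"})
        with pytest.raises(ValueError):
            ssgsea_score(expr, {"a", "b"})


class TestNormalizeAndTertiles:
    def test_range_scaling(self):
        raw = pd.Series([0.0, 5.0, 10.0], index=list("abc"))
        assert normalize_scores(raw).tolist() == [0.0, 0.5, 1.0]

    def test_constant_scores_normalize_to_zero_with_warning(self):
        raw = pd.Series([3.0, 3.0, 3.0], index=list("abc"))
        with pytest.warns(UserWarning, match="constant"):
            assert normalize_scores(raw).tolist() == [0.0, 0.0, 0.0]

    def test_affine_shift_preserves_groups(self, rng):
        raw = pd.Series(rng.normal(size=12), index=[f"s{i}" for i in range(12)])
        g1 = tertile_groups(normalize_scores(raw))
        g2 = tertile_groups(normalize_scores(raw * 3.0 + 11.0))
        pd.testing.assert_series_equal(g1, g2)

    def test_exact_and_remainder_group_sizes(self):
        nine = pd.Series(np.arange(9.0), index=[f"s{i}" for i in range(9)])
        counts = tertile_groups(nine).value_counts()
        assert counts.tolist() == [3, 3, 3]
        ten = pd.Series(np.arange(10.0), index=[f"s{i}" for i in range(10)])
        counts = tertile_groups(ten).value_counts()
        assert (counts["low"], counts["medium"], counts["high"]) == (4, 3, 3)
        # lowest scores end up in the low group
        assert tertile_groups(ten)["s0"] == "low" and tertile_groups(ten)["s9"] == "high"

    def test_ties_resolved_by_sample_id(self):
        scores = pd.Series([1.0] * 10, index=[f"s{i:02d}" for i in range(10)])
        groups = tertile_groups(scores)
        assert groups[[f"s{i:02d}" for i in range(4)]].eq("low").all()
        assert groups[["s07", "s08", "s09"]].eq("high").all()


def _cohort(times, events, ages=None, sexes=None, status=None):
    n = len(times)
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "time_days": times,
            "event": events,
            "age": ages if ages is not None else [60.0] * n,
            "sex": sexes if sexes is not None else ["male"] * n,
            "p53_status": status if status is not None else ["wild_type"] * n,
        }
    )


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        cohort = _cohort([5.0, 6.0, 7.0], [0, 0, 0])
        groups = pd.Series(["low", "low", "low"], index=cohort["sample_id"])
        curve = km_estimate(cohort, groups)["low"]
        assert (curve["survival"] == 1.0).all()

    def test_product_limit_hand_calculation(self):
        cohort = _cohort([1.0, 2.0], [1, 1])
        groups = pd.Series(["low", "low"], index=cohort["sample_id"])
        curve = km_estimate(cohort, groups)["low"].set_index("time")["survival"]
        assert curve.loc[1.0] == pytest.approx(0.5)
        assert curve.loc[2.0] == pytest.approx(0.0)

    def test_equals_one_minus_ecdf_without_censoring(self, rng):
        times = rng.exponential(100, size=40).round(2)
        cohort = _cohort(times, [1] * 40)
        groups = pd.Series(["low"] * 40, index=cohort["sample_id"])
        curve = km_estimate(cohort, groups)["low"]
        for t, s in zip(curve["time"], curve["survival"]):
            assert s == pytest.approx(1 - np.mean(times <= t))


class TestCox:
    def test_all_censored_is_an_error(self):
        cohort = _cohort([10.0] * 12, [0] * 12)
        groups = pd.Series(["low"] * 6 + ["high"] * 6, index=cohort["sample_id"])
        with pytest.raises(ValueError):
            cox_fit(cohort, groups)

    def test_event_free_stratum_named_in_error(self, rng):
        times = rng.exponential(100, 30)
        events = [1] * 15 + [0] * 15
        cohort = _cohort(times, events)
        groups = pd.Series(["low"] * 15 + ["high"] * 15, index=cohort["sample_id"])
        with pytest.raises(ValueError, match="high"):
            cox_fit(cohort, groups)

    def test_recovers_planted_group_hazard(self):
        from p53lnc.synthetic_data import simulate_cohort

        cohort, _, _, groups = simulate_cohort(n=600, hr_high=2.0, seed=42)
        groups.index = cohort["sample_id"]
        res = cox_fit(cohort, groups)
        hr = res.summary.loc["group_high", "hr"]
        assert res.summary.loc["group_high", "hr_ci_low"] < 2.0 < res.summary.loc[
            "group_high", "hr_ci_high"
        ]
        assert 1.5 < hr < 2.7
        assert res.lr_p < 0.001


class TestSplitAndFisher:
    def test_split_by_p53_partitions_and_drops_unknown(self):
        cohort = _cohort(
            [1.0] * 10, [1] * 10,
            status=["wild_type"] * 4 + ["mutant"] * 5 + ["unknown"],
        )
        wt, mut = split_by_p53(cohort)
        assert (len(wt), len(mut)) == (4, 5)

    def test_tertiles_recomputed_within_subcohort(self, rng):
        cohort = _cohort(
            rng.exponential(100, 12), [1] * 12,
            status=["wild_type"] * 6 + ["mutant"] * 6,
        )
        wt, _ = split_by_p53(cohort)
        scores = pd.Series(rng.normal(size=6), index=wt["sample_id"])
        counts = tertile_groups(scores).value_counts()
        assert counts.tolist() == [2, 2, 2]

    def test_full_overlap_matches_hypergeometric_enumeration(self):
        bg = [f"g{i}" for i in range(20)]
        a = bg[:5]
        odds, p = overlap_fisher(a, a, bg)
        # enumeration: only the maximal-overlap table is as extreme
        oracle = stats.hypergeom.pmf(5, 20, 5, 5)
        assert p == pytest.approx(oracle)
        assert np.isinf(odds)

    def test_disjoint_small_sets_not_enriched(self):
        bg = [f"g{i}" for i in range(1000)]
        _, p = overlap_fisher(bg[:5], bg[5:10], bg)
        assert p == pytest.approx(1.0, abs=0.05)

    def test_saturated_table_p_one(self):
        bg = [f"g{i}" for i in range(10)]
        _, p = overlap_fisher(bg, bg, bg)
        assert p == 1.0

    def test_empty_background_errors(self):
        with pytest.raises(ValueError):
            overlap_fisher([], [], [])


def test_gene_set_reader_plain_and_gmt(tmp_path):
    plain = tmp_path / "set.txt"
    plain.write_text("g1\ng2\n\n")
    assert read_gene_set(plain) == ["g1", "g2"]
    gmt = tmp_path / "sets.gmt"
    gmt.write_text("up\tdesc\tg1\tg2\tg3\n")
    assert read_gene_set(gmt) == ["g1", "g2", "g3"]
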