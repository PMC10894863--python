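"""Evaluation protocol: hit rates, median splits, score summaries, agreement."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lungcbir.evaluation import (
    at_least_one_score,
    icc,
    median_split_comparison,
    pair_retrieval_rate,
    proportion_summary,
    score_summaries,
    split_comparison_from_counts,
    weighted_kappa,
)
from lungcbir.retrieval import RetrievalResult


def _results_with_hits(hit_ranks, n=50, k=5):
    """n queries; query i's baseline is at rank hit_ranks[i] (None = miss)."""
    results, pairs = [], {}
    for i, rank in enumerate(hit_ranks):
        qid, bid = f"q{i}", f"b{i}"
        pairs[qid] = bid
        ranked = []
        for r in range(1, k + 1):
            sid = bid if r == rank else f"other{i}_{r}"
            ranked.append((sid, r / 10.0, {}))
        results.append(RetrievalResult(qid, ranked))
    return results, pairs


class TestPairRetrievalRate:
    def test_printed_count_reproduction(self):
        # 20, 30, 33 hits of 50 at k = 1, 3, 5
        ranks = [1] * 20 + [2] * 6 + [3] * 4 + [4] * 2 + [5] * 1 + [None] * 17
        results, pairs = _results_with_hits(ranks)
        rates = pair_retrieval_rate(results, pairs)
        assert rates[1].percent == pytest.approx(40.0)
        assert rates[3].percent == pytest.approx(60.0)
        assert rates[5].percent == pytest.approx(66.0)

    def test_monotone_in_k(self):
        rng = np.random.default_rng(0)
        ranks = [int(r) if r <= 5 else None for r in rng.integers(1, 9, 50)]
        results, pairs = _results_with_hits(ranks)
        rates = pair_retrieval_rate(results, pairs, ks=(1, 2, 3, 4, 5))
        percents = [rates[k].percent for k in (1, 2, 3, 4, 5)]
        assert percents == sorted(percents)

    def test_saturation_ci(self):
        results, pairs = _results_with_hits([1] * 50)
        rate = pair_retrieval_rate(results, pairs)[1]
        assert rate.percent == 100.0
        assert rate.ci_high == pytest.approx(100.0)

    def test_unknown_query_raises(self):
        results, pairs = _results_with_hits([1, 2])
        del pairs["q0"]
        with pytest.raises(KeyError):
            pair_retrieval_rate(results, pairs)

    def test_wilson_interval_against_closed_form(self):
        out = proportion_summary(20, 50)
        p_hat, n, z = 0.4, 50, stats.norm.ppf(0.975)
        centre = (p_hat + z**2 / (2 * n)) / (1 + z**2 / n)
        half = (
            z * math.sqrt(p_hat * (1 - p_hat) / n + z**2 / (4 * n**2))
            / (1 + z**2 / n)
        )
        assert out.ci_low == pytest.approx(100 * (centre - half), abs=1e-9)
        assert out.ci_high == pytest.approx(100 * (centre + half), abs=1e-9)


def _enumerated_fisher(a, b, c, d):
    """Independent oracle: exhaustive hypergeometric enumeration on the 2x2."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def pmf(x):
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    p_obs = pmf(a)
    two = sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-12))
    greater = sum(pmf(x) for x in range(a, hi + 1))
    return two, greater


class TestMedianSplit:
    def test_printed_subgroup_rates(self):
        # 18/25 hits above the median vs 12/25 below
        out = split_comparison_from_counts(18, 25, 12, 25)
        assert out.rate_high == pytest.approx(72.0)
        assert out.rate_low == pytest.approx(48.0)
        two, greater = _enumerated_fisher(18, 7, 12, 13)
        assert out.p_fisher_two_sided == pytest.approx(two, abs=1e-12)
        assert out.p_fisher_one_sided == pytest.approx(greater, abs=1e-12)
        # the exact one-sided value is ~0.074; plain chi-square gives ~0.083
        assert out.p_fisher_one_sided == pytest.approx(0.0741, abs=1e-3)

    def test_identical_groups_p_one(self):
        out = split_comparison_from_counts(10, 25, 10, 25)
        assert out.p_fisher_two_sided == pytest.approx(1.0)

    def test_extreme_table_point_mass(self):
        out = split_comparison_from_counts(25, 25, 0, 25)
        _, greater = _enumerated_fisher(25, 0, 0, 25)
        assert out.p_fisher_one_sided == pytest.approx(greater, rel=1e-9)
        assert out.p_fisher_one_sided < 1e-12

    @pytest.mark.parametrize(
        "table", [(7, 10, 3, 10), (5, 12, 9, 13), (1, 8, 6, 9), (0, 5, 5, 5)]
    )
    def test_fisher_matches_enumeration_oracle(self, table):
        h1, n1, h2, n2 = table
        out = split_comparison_from_counts(h1, n1, h2, n2)
        two, greater = _enumerated_fisher(h1, n1 - h1, h2, n2 - h2)
        assert out.p_fisher_two_sided == pytest.approx(two, abs=1e-12)
        assert out.p_fisher_one_sided == pytest.approx(greater, abs=1e-12)

    def test_median_split_semantics(self):
        ranks = [1] * 10 + [None] * 10
        results, pairs = _results_with_hits(ranks, n=20)
        values = {f"q{i}": float(i) for i in range(20)}  # distinct values
        out = median_split_comparison(results, pairs, values, k=3)
        assert out.n_high == out.n_low == 10
        assert out.rate_high == 0.0 and out.rate_low == 100.0

    def test_degenerate_split_rejected(self):
        results, pairs = _results_with_hits([1, 2, 3])
        with pytest.raises(ValueError, match="degenerate"):
            median_split_comparison(
                results, pairs, {r.query_id: 1.0 for r in results}, k=3
            )


def _ratings_from_counts(counts_ge4, n_queries=50, ranks=(1, 2, 3, 4, 5)):
    """Build a complete rating grid realizing per-(reader, rank) >=4 counts."""
    records = []
    for reader, per_rank in counts_ge4.items():
        for rank, n_hi in zip(ranks, per_rank):
            for q in range(n_queries):
                score = 4 if q < n_hi else 3
                records.append(
                    {"query_id": f"q{q}", "rank": rank, "reader": reader,
                     "score": score}
                )
    return pd.DataFrame(records)


class TestScoreSummaries:
    def test_pooled_percent_is_mean_of_equal_count_readers(self):
        # overall 53.2% and 76.4% over 250 ratings each pool to 64.8%
        counts = {1: (37, 32, 24, 23, 17), 2: (44, 41, 41, 32, 33)}
        ratings = _ratings_from_counts(counts)
        out = score_summaries(ratings, n_boot=10)
        assert out.loc[(1, "overall"), "percent_ge_threshold"] == pytest.approx(53.2)
        assert out.loc[(2, "overall"), "percent_ge_threshold"] == pytest.approx(76.4)
        assert out.loc[("pooled", "overall"), "percent_ge_threshold"] == pytest.approx(64.8)
        assert out.loc[("pooled", 1), "percent_ge_threshold"] == pytest.approx(81.0)

    def test_constant_scores(self):
        records = [
            {"query_id": f"q{q}", "rank": r, "reader": rd, "score": 5}
            for q in range(10) for r in (1, 2) for rd in (1, 2)
        ]
        out = score_summaries(pd.DataFrame(records), n_boot=10)
        row = out.loc[("pooled", "overall")]
        assert row["percent_ge_threshold"] == 100.0
        assert row["mean"] == 5.0
        assert row["se"] == 0.0

    def test_incomplete_grid_rejected(self):
        ratings = _ratings_from_counts({1: (5,), 2: (5,)}, n_queries=10, ranks=(1,))
        with pytest.raises(ValueError, match="duplicate|incomplete|unequal"):
            score_summaries(pd.concat([ratings, ratings.head(1)]), n_boot=5)


class TestAtLeastOne:
    def test_pooled_from_reader_counts(self):
        # reader 1: 38/50 queries with a score-5; reader 2: 36/50 -> 74%
        records = []
        for reader, n_with5 in ((1, 38), (2, 36)):
            for q in range(50):
                for rank in (1, 2, 3, 4, 5):
                    score = 5 if (q < n_with5 and rank == 1) else 3
                    records.append({"query_id": f"q{q}", "rank": rank,
                                    "reader": reader, "score": score})
        out = at_least_one_score(pd.DataFrame(records), score=5)
        assert out[1].percent == pytest.approx(76.0)
        assert out[2].percent == pytest.approx(72.0)
        assert out["pooled"].percent == pytest.approx(74.0)

    def test_zero_and_saturation(self):
        records = [
            {"query_id": f"q{q}", "rank": r, "reader": rd, "score": 4}
            for q in range(5) for r in (1, 2) for rd in (1, 2)
        ]
        ratings = pd.DataFrame(records)
        assert at_least_one_score(ratings, score=5)["pooled"].percent == 0.0
        assert at_least_one_score(ratings, score=4)["pooled"].percent == 100.0


class TestWeightedKappa:
    def test_identical_raters(self):
        r = np.array([1, 2, 3, 4, 5, 3, 2])
        out = weighted_kappa(r, r, n_boot=20)
        assert out.kappa == pytest.approx(1.0)

    def test_four_pair_oracle(self):
        """kappa on r1=[1,1,2,2], r2=[2,2,1,1] from the O/E formula by hand."""
        r1, r2 = [1, 1, 2, 2], [2, 2, 1, 1]
        # categories {1,2}; w = |i-j|; observed disagreement = 1;
        # expected = 0.5*0.5 + 0.5*0.5 = 0.5 -> kappa = 1 - 1/0.5 = -1
        out = weighted_kappa(r1, r2, n_boot=20)
        assert out.kappa == pytest.approx(-1.0, abs=1e-9)

    def test_independent_scores_near_zero(self):
        rng = np.random.default_rng(17)
        r1 = rng.integers(1, 6, 2000)
        r2 = rng.integers(1, 6, 2000)
        out = weighted_kappa(r1, r2, n_boot=20)
        assert abs(out.kappa) < 0.05

    def test_symmetry_and_order_preserving_relabel(self):
        rng = np.random.default_rng(3)
        r1 = rng.integers(1, 6, 300)
        r2 = np.clip(r1 + rng.integers(-1, 2, 300), 1, 5)
        a = weighted_kappa(r1, r2, n_boot=10).kappa
        b = weighted_kappa(r2, r1, n_boot=10).kappa
        assert a == pytest.approx(b, abs=1e-12)
        # common order-preserving relabel 1..5 -> 11..15
        c = weighted_kappa(r1 + 10, r2 + 10, n_boot=10).kappa
        assert c == pytest.approx(a, abs=1e-12)

    @pytest.mark.parametrize("weights", ["linear", "quadratic"])
    def test_against_sklearn(self, weights):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(5)
        r1 = rng.integers(1, 6, 400)
        r2 = np.clip(r1 + rng.integers(-2, 3, 400), 1, 5)
        ours = weighted_kappa(r1, r2, weights=weights, n_boot=10,
                              categories=[1, 2, 3, 4, 5]).kappa
        theirs = sklearn_metrics.cohen_kappa_score(r1, r2, weights=weights,
                                                   labels=[1, 2, 3, 4, 5])
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_single_category_rejected(self):
        with pytest.raises(ValueError):
            weighted_kappa([3, 3, 3], [3, 3, 3], n_boot=5)


class TestICC:
    def test_identical_raters(self):
        r = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        out = icc(r, r)
        assert out.icc == pytest.approx(1.0)

    def test_constant_shift_penalized(self):
        r1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        out = icc(r1, r1 + 1.0)
        assert out.icc < 1.0

    def test_six_unit_hand_anova(self):
        """ICC(2,1) equals the mean-squares formula evaluated by hand."""
        r1 = np.array([9.0, 6.0, 8.0, 7.0, 10.0, 6.0])
        r2 = np.array([2.0, 1.0, 4.0, 1.0, 5.0, 2.0])
        data = np.column_stack([r1, r2])
        n, k = data.shape
        grand = data.mean()
        msr = k * ((data.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((data.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = (
            ((data - grand) ** 2).sum()
            - (n - 1) * msr - (k - 1) * msc
        ) / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc(r1, r2).icc == pytest.approx(expected, abs=1e-9)

    def test_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        truth = rng.normal(3, 1, 40)
        r1 = truth + rng.normal(0, 0.5, 40)
        r2 = truth + rng.normal(0.3, 0.5, 40)
        df = pd.DataFrame({
            "targets": np.tile(np.arange(40), 2),
            "raters": np.repeat(["a", "b"], 40),
            "scores": np.concatenate([r1, r2]),
        })
        ref = pingouin.intraclass_corr(df, targets="targets", raters="raters",
                                       ratings="scores")
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        row = ref[ref.Type.str.replace("(", "").str.replace(")", "").str.replace(",", "")
                  .isin(["ICC2", "ICCA1"])].iloc[0]
        ours = icc(r1, r2)
        assert ours.icc == pytest.approx(row.ICC, abs=1e-9)
        # pingouin reports the interval rounded to 2 decimals
        assert ours.ci_low == pytest.approx(row[ci_col][0], abs=0.006)
        assert ours.ci_high == pytest.approx(row[ci_col][1], abs=0.006)

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning, match="variance"):
            out = icc([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert out.icc == 0.0
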