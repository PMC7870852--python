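"""Rank-sum exactness and cohort summaries."""

import numpy as np
import pandas as pd
import pytest
from itertools import combinations
from math import comb

from nirsosc import ConfigurationError, rank_sum_test, significance_label, summarize_groups
from scipy import stats as sps


def brute_force_p(a, b):
    """Independent oracle: enumerate every assignment of the pooled *values*
    to the two groups and recompute the rank sum each time."""
    pooled = np.concatenate([a, b])
    n, n_a = pooled.size, len(a)
    ranks = sps.rankdata(pooled)
    mu = n_a * (n + 1) / 2.0
    obs = ranks[:n_a].sum()
    count = 0
    for idx in combinations(range(n), n_a):
        if abs(ranks[list(idx)].sum() - mu) >= abs(obs - mu) - 1e-9:
            count += 1
    return count / comb(n, n_a)


class TestRankSum:
    def test_textbook_exact_third(self):
        """{1,2} vs {3,4}: 2 of the 6 rank splits are as extreme -> p = 1/3."""
        res = rank_sum_test([1, 2], [3, 4])
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(1 / 3)

    def test_identical_multisets_p_one(self):
        res = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.pvalue == pytest.approx(1.0)

    def test_swap_symmetric(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 5), rng.normal(0.5, 1, 6)
        assert rank_sum_test(a, b).pvalue == pytest.approx(rank_sum_test(b, a).pvalue)

    def test_degenerate_all_equal_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = rank_sum_test([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.pvalue == 1.0

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            a = rng.normal(0, 1, 5)
            b = rng.normal(0.8, 1, 7)
            ours = rank_sum_test(a, b).pvalue
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = rng.integers(0, 4, 4).astype(float)  # heavy ties
            b = rng.integers(0, 4, 5).astype(float)
            if np.all(np.concatenate([a, b]) == a[0]):
                continue
            assert rank_sum_test(a, b).pvalue == pytest.approx(brute_force_p(a, b))

    def test_normal_approximation_corridor(self):
        """Approximation within 0.02 of exact for combined n <= 20."""
        import nirsosc.stats as stats_mod

        rng = np.random.default_rng(7)
        for _ in range(15):
            a = rng.normal(0, 1, 8)
            b = rng.normal(0.4, 1, 9)
            exact = rank_sum_test(a, b)
            assert exact.method == "exact"
            old = stats_mod._EXACT_LIMIT
            try:
                stats_mod._EXACT_LIMIT = 0  # force the normal path
                approx = rank_sum_test(a, b)
            finally:
                stats_mod._EXACT_LIMIT = old
            assert approx.method == "normal"
            assert abs(approx.pvalue - exact.pvalue) < 0.02

    def test_tiny_samples_rejected(self):
        with pytest.raises(ConfigurationError):
            rank_sum_test([1.0], [2.0, 3.0])


class TestSignificanceTiers:
    @pytest.mark.parametrize(
        "p,label",
        [(0.2, "ns"), (0.03, "*"), (0.004, "**"), (0.00004, "****"), (0.000005, "*****")],
    )
    def test_labels(self, p, label):
        assert significance_label(p) == label


def _cohort_table():
    rows = []
    for group, values in {
        "young_C57": [8.0, 8.1, 7.9, 8.0],
        "old_C57": [14, 13, 15, 16, 12, 14, 14],
    }.items():
        for i, v in enumerate(values):
            rows.append(
                {"animal_id": f"{group}_{i}", "group": group, "metric": "period_min", "value": v}
            )
    return pd.DataFrame(rows)


class TestSummarizeGroups:
    def test_constant_group_mean_and_zero_se(self):
        df = pd.DataFrame(
            {
                "animal_id": list("abcd"),
                "group": ["g"] * 4,
                "metric": ["m"] * 4,
                "value": [8.0] * 4,
            }
        )
        out = summarize_groups(df)
        row = out.summary.iloc[0]
        assert row["mean"] == 8.0 and row["se"] == 0.0

    def test_se_is_sample_sd_over_sqrt_n(self):
        df = _cohort_table()
        out = summarize_groups(df)
        old = df[df["group"] == "old_C57"]["value"].to_numpy()
        row = out.summary.set_index("group").loc["old_C57"]
        assert row["se"] == pytest.approx(np.std(old, ddof=1) / np.sqrt(old.size))

    def test_order_invariance(self):
        df = _cohort_table()
        shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a, b = summarize_groups(df), summarize_groups(shuffled)
        pd.testing.assert_frame_equal(
            a.summary.sort_values(["group", "metric"]).reset_index(drop=True),
            b.summary.sort_values(["group", "metric"]).reset_index(drop=True),
        )
        assert a.pairwise["pvalue"].iloc[0] == pytest.approx(b.pairwise["pvalue"].iloc[0])

    def test_separated_groups_significant(self):
        out = summarize_groups(_cohort_table())
        assert out.pairwise["pvalue"].iloc[0] < 0.05
        assert out.n_uncorrected_contrasts == 1

    def test_small_group_excluded_with_warning(self):
        df = _cohort_table()
        df = pd.concat(
            [
                df,
                pd.DataFrame(
                    [{"animal_id": "solo", "group": "young_CFH", "metric": "period_min", "value": 16.0}]
                ),
            ],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="young_CFH"):
            out = summarize_groups(df)
        assert not (out.pairwise[["group_a", "group_b"]] == "young_CFH").any().any()

    def test_preset_effect_detected_in_most_replicate_cohorts(self):
        """Young vs old C57 period contrast reaches p<0.05 in >=90% of cohorts."""
        from nirsosc import animal_metrics, cohort_preset, generate_concentration_series, preprocess

        seeds = np.random.SeedSequence(77).generate_state(400) % 2**31
        k, hits, n_rep = 0, 0, 15
        for _ in range(n_rep):
            periods = {}
            for group, n in (("young_C57", 4), ("old_C57", 7)):
                vals = []
                for _ in range(n):
                    spec = cohort_preset(group, seed=int(seeds[k])).spec
                    k += 1
                    s = preprocess(generate_concentration_series(spec).with_composites())
                    vals.append(animal_metrics(s)["pooled"].period_minutes)
                periods[group] = vals
            p = rank_sum_test(periods["young_C57"], periods["old_C57"]).pvalue
            hits += p < 0.05
        assert hits >= 0.9 * n_rep
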