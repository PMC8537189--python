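import numpy as np
import pandas as pd
import pytest

from leafdepo import ValidationError
from leafdepo.stats import (
    correlate,
    kmeans_capacity_clusters,
    one_way_anova,
    tukey_hsd,
)


class TestAnova:
    def test_equal_means_give_zero_f(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [3.0, 2.0, 1.0]}
        assert one_way_anova(g).f == pytest.approx(0.0, abs=1e-12)

    def test_two_group_textbook(self):
        # SSB = 3*(2-3.5)^2 + 3*(5-3.5)^2 = 13.5, SSW = 4, MSW = 1 -> F = 13.5
        res = one_way_anova({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert res.f == pytest.approx(13.5)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_f_equals_t_squared_for_two_groups(self):
        from scipy.stats import ttest_ind

        a, b = [1.2, 3.4, 2.2, 4.0], [5.5, 4.4, 6.1]
        res = one_way_anova({"a": a, "b": b})
        t = ttest_ind(a, b).statistic
        assert res.f == pytest.approx(t**2)

    def test_shift_and_scale_invariance_of_f(self):
        rng = np.random.default_rng(0)
        g = {k: rng.normal(i, 1, 4) for i, k in enumerate("abc")}
        base = one_way_anova(g).f
        shifted = {k: v + 100.0 for k, v in g.items()}
        scaled = {k: v * 7.0 for k, v in g.items()}
        assert one_way_anova(shifted).f == pytest.approx(base)
        assert one_way_anova(scaled).f == pytest.approx(base)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValidationError, match="replicates"):
            one_way_anova({"a": [1.0], "b": [1.0, 2.0]})


class TestTukey:
    def test_identical_groups_nothing_significant(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
        assert tukey_hsd(g).significant_pairs == []

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(1)
        g = {"lo": rng.normal(0, 1, 3), "hi": rng.normal(100, 1, 3)}
        assert tukey_hsd(g).significant("lo", "hi")

    def test_matches_independent_implementation(self):
        """Same significance pattern as statsmodels' studentized-range test."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        g = {
            "a": [24.5, 23.5, 26.4, 27.1, 29.9],
            "b": [28.4, 34.2, 29.5, 32.2, 30.1],
            "c": [26.1, 28.3, 24.3, 26.2, 27.8],
        }
        from itertools import combinations

        mine = tukey_hsd(g)
        vals = np.concatenate([g[k] for k in g])
        labels = np.repeat(list(g), [len(g[k]) for k in g])
        ref = pairwise_tukeyhsd(vals, labels, alpha=0.05)
        pairs = list(combinations(sorted(g), 2))  # statsmodels pair order
        for pair, rej, p_ref in zip(pairs, ref.reject, ref.pvalues):
            assert mine.significant(*pair) == bool(rej)
            key = pair if pair in mine.pvalues else pair[::-1]
            assert mine.pvalues[key] == pytest.approx(p_ref, abs=2e-3)

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(2)
        g = {k: rng.normal(i * 1.5, 1, 4) for i, k in enumerate("abcd")}
        strict = set(tukey_hsd(g, alpha=0.01).significant_pairs)
        loose = set(tukey_hsd(g, alpha=0.10).significant_pairs)
        assert strict <= loose


class TestCorrelate:
    def test_perfect_negative(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = correlate(x, [-v for v in x])
        assert res.r == pytest.approx(-1.0)
        assert res.slope == pytest.approx(-1.0)

    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = correlate(x, [2 * v + 1 for v in x])
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError, match="variance"):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_generator_coupling_sign_recovered(self, default_study):
        """Total surface energy and total PM are positively coupled by design."""
        from leafdepo import quantify

        _, bundle = default_study
        res = quantify(bundle)
        row = res.correlations.set_index("x").loc["gamma_total"]
        assert row["r"] > 0
        assert row["p"] < 0.05


class TestKMeansCapacity:
    def test_three_separated_points(self):
        feats = pd.DataFrame(
            {"x": [0.0, 10.0, 20.0], "y": [0.0, 10.0, 20.0]},
            index=["lo", "mid", "hi"],
        )
        res = kmeans_capacity_clusters(feats, totals=[0.0, 20.0, 40.0])
        assert res.labels == {"lo": 1, "mid": 2, "hi": 3}

    def test_duplicated_rows_cluster_together(self):
        feats = pd.DataFrame(
            [[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [9.0, 9.0]],
            index=["a1", "a2", "b", "c"],
            columns=["x", "y"],
        )
        res = kmeans_capacity_clusters(feats)
        assert res.labels["a1"] == res.labels["a2"]

    def test_label_ordering_follows_totals(self):
        rng = np.random.default_rng(3)
        tiers = np.repeat([100.0, 500.0, 900.0], 4)
        feats = pd.DataFrame(
            tiers[:, None] + rng.normal(0, 10, (12, 3)),
            index=[f"s{i}" for i in range(12)],
        )
        res = kmeans_capacity_clusters(feats, totals=tiers)
        by_tier = np.array([res.labels[f"s{i}"] for i in range(12)]).reshape(3, 4)
        assert (by_tier == [[1], [2], [3]] * np.ones((3, 4), int)).all()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        feats = pd.DataFrame(rng.normal(0, 1, (10, 3)), index=[f"s{i}" for i in range(10)])
        a = kmeans_capacity_clusters(feats, seed=11)
        b = kmeans_capacity_clusters(feats, seed=11)
        assert a.labels == b.labels

    def test_too_few_species_rejected(self):
        feats = pd.DataFrame([[1.0], [2.0]], index=["a", "b"])
        with pytest.raises(ValidationError):
            kmeans_capacity_clusters(feats, k=3)
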