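"""ANOVA, Tukey HSD, homogeneous subsets and the axis-grouped comparison."""

import numpy as np
import pytest
from scipy import stats as sps

from insolenet.channels import CHANNEL_IDS
from insolenet.importance import (
    axis_group_comparison,
    homogeneous_subsets,
    one_way_anova,
    rank_sensors,
    subset_table,
    tukey_hsd,
)
from insolenet.preprocessing import StandardizationStats
from insolenet.training import FoldResult

rng = np.random.default_rng(0)


class TestOneWayAnova:
    def test_equal_means_give_zero_f(self):
        base = rng.normal(size=12)
        groups = [base + 0, base * 1.0, base[::-1]]  # same mean, nonzero spread
        t = one_way_anova(groups)
        assert t.ss_between == pytest.approx(0.0, abs=1e-12)
        assert t.f_statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_two_pass(self):
        groups = [rng.normal(loc=m, size=5) for m in (0.0, 0.5, 1.0)]
        t = one_way_anova(groups)
        # independent two-pass computation
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        assert t.ss_between == pytest.approx(ssb, abs=1e-9)
        assert t.ss_within == pytest.approx(ssw, abs=1e-9)
        assert t.ss_total == pytest.approx(ssb + ssw, abs=1e-9)
        assert t.ms_between == pytest.approx(ssb / 2, abs=1e-9)
        assert t.ms_within == pytest.approx(ssw / 12, abs=1e-9)
        assert t.f_statistic == pytest.approx((ssb / 2) / (ssw / 12), abs=1e-9)
        # degrees of freedom bookkeeping
        assert (t.df_between, t.df_within, t.df_total) == (2, 12, 14)
        # scipy's F test agrees
        f_ref, p_ref = sps.f_oneway(*groups)
        assert t.f_statistic == pytest.approx(f_ref, abs=1e-9)
        assert t.p_value == pytest.approx(p_ref, abs=1e-9)

    def test_additivity_on_random_data(self):
        for _ in range(20):
            k = int(rng.integers(2, 8))
            groups = [rng.normal(size=int(rng.integers(2, 20))) for _ in range(k)]
            t = one_way_anova(groups)
            assert t.ss_total == pytest.approx(t.ss_between + t.ss_within,
                                               abs=1e-9)

    def test_degenerate_within_variance(self):
        with pytest.raises(ValueError, match="degenerate"):
            one_way_anova([np.ones(3), np.full(3, 2.0)])

    def test_anova_table_frame_layout(self):
        t = one_way_anova([rng.normal(size=6) for _ in range(3)])
        frame = t.to_frame()
        assert list(frame.index) == ["between groups", "within groups", "total"]
        assert frame.loc["between groups", "MS"] == pytest.approx(
            frame.loc["between groups", "SS"] / frame.loc["between groups", "df"]
        )


class TestTukeyHsd:
    def test_identical_groups_p_near_one(self):
        g = rng.normal(size=10)
        res = tukey_hsd([g, g.copy() + 1e-12, g + rng.normal(0, 1e-6, 10)])
        off_diag = res.pairwise_p[np.triu_indices(3, 1)]
        assert np.all(off_diag > 0.99)

    def test_far_separated_groups_tiny_p(self):
        a = rng.normal(0, 0.01, size=10)
        b = rng.normal(10, 0.01, size=10)
        res = tukey_hsd([a, b, a + 0.001])
        assert res.pairwise_p[0, 1] < 1e-6

    def test_matches_scipy_tukey(self):
        """Cross-check against scipy's independent implementation (3 groups)."""
        groups = [rng.normal(loc=m, scale=1.0, size=8) for m in (0.0, 0.6, 1.4)]
        ours = tukey_hsd(groups)
        ref = sps.tukey_hsd(*groups)
        for a in range(3):
            for b in range(3):
                if a != b:
                    assert ours.pairwise_p[a, b] == pytest.approx(
                        ref.pvalue[a, b], abs=1e-6
                    )

    def test_p_monotone_in_mean_separation(self):
        base = rng.normal(size=20)
        other = rng.normal(size=20)
        other = other - other.mean() + base.mean()  # equal means at delta 0
        ps = []
        for delta in (0.0, 0.2, 0.4, 0.8, 1.6):
            res = tukey_hsd([base, other + delta])
            ps.append(res.pairwise_p[0, 1])
        assert all(p1 >= p2 - 1e-12 for p1, p2 in zip(ps, ps[1:]))


class TestHomogeneousSubsets:
    def tight_groups(self, means, sd=0.001, n=20):
        return [rng.normal(m, sd, size=n) for m in means]

    def test_all_similar_single_subset(self):
        res = tukey_hsd(self.tight_groups([0.0, 1e-5, 2e-5], sd=0.01))
        subs = homogeneous_subsets(res)
        assert len(subs) == 1
        assert len(subs[0]["members"]) == 3

    def test_all_separated_singletons(self):
        res = tukey_hsd(self.tight_groups([0.0, 1.0, 2.0, 3.0]))
        subs = homogeneous_subsets(res)
        assert len(subs) == 4
        assert all(len(s["members"]) == 1 and s["p"] == 1.0 for s in subs)

    def test_two_pairs(self):
        res = tukey_hsd(
            self.tight_groups([0.0, 0.0001, 0.5, 0.5001]),
            group_names=["a", "b", "c", "d"],
        )
        subs = homogeneous_subsets(res)
        assert [sorted(s["members"]) for s in subs] == [["a", "b"], ["c", "d"]]

    def test_subsets_cover_all_and_internal_p_above_alpha(self):
        means = np.sort(rng.uniform(0, 0.2, size=8))
        res = tukey_hsd(self.tight_groups(means, sd=0.05),
                        group_names=[f"g{i}" for i in range(8)])
        subs = homogeneous_subsets(res)
        covered = {m for s in subs for m in s["members"]}
        assert covered == set(res.group_names)
        for s in subs:
            idx = [res.group_names.index(m) for m in s["members"]]
            for a in idx:
                for b in idx:
                    if a != b:
                        assert res.pairwise_p[a, b] > res.alpha

    def test_subset_table_staircase(self):
        res = tukey_hsd(self.tight_groups([0.0, 1.0]), group_names=["lo", "hi"])
        table = subset_table(res)
        assert table.shape[1] == 2
        assert not np.isnan(table.loc["lo", "1"])
        assert np.isnan(table.loc["hi", "1"])


class TestAxisComparison:
    def test_identical_columns_not_significant(self):
        att = np.tile(rng.normal(0.5, 0.05, size=200)[:, None], (1, 20))
        att += rng.normal(0, 0.01, size=att.shape)
        out = axis_group_comparison(att)
        assert out["anova"].p_value > 0.05

    def test_z_shift_detected(self):
        att = rng.normal(0.5, 0.02, size=(300, 20))
        z_cols = [10, 13, 16, 19]
        att[:, z_cols] += 0.05
        out = axis_group_comparison(att)
        assert out["pairwise_p"]["x-z"] < 0.001
        assert out["pairwise_p"]["y-z"] < 0.001
        assert out["pairwise_p"]["x-y"] > 0.05
        assert out["axis_means"]["z"] > out["axis_means"]["x"]

    def test_group_sizes(self):
        att = rng.normal(0.5, 0.02, size=(50, 20))
        out = axis_group_comparison(att)
        np.testing.assert_array_equal(out["tukey"].group_ns, [200, 200, 200])


class TestRankSensors:
    def _folds(self, att):
        return [FoldResult("S1", np.zeros(2), np.zeros(2), att, 1, {},
                           StandardizationStats(np.zeros(20), np.ones(20), []))]

    def test_report_lists_each_channel_once(self):
        att = rng.normal(0.5, 0.02, size=(100, 20))
        out = rank_sensors(self._folds(att))
        assert sorted(out["report"]["channel"]) == sorted(CHANNEL_IDS)
        assert len(out["report"]) == 20
        # sorted by mean attention descending
        assert out["report"]["mean_attention"].is_monotonic_decreasing

    def test_attention_disabled_rejected(self):
        folds = self._folds(None)
        with pytest.raises(ValueError, match="attention"):
            rank_sensors(folds)

    def test_uniform_attention_rejects_at_chance(self):
        """On i.i.d. uniform attention matrices the pooled ANOVA's rejection
        rate stays near the nominal level (no subset structure beyond chance)."""
        r = np.random.default_rng(123)
        rejections = 0
        reps = 200
        for _ in range(reps):
            att = r.uniform(0, 1, size=(30, 20))
            out = one_way_anova([att[:, c] for c in range(20)])
            rejections += out.p_value < 0.05
        assert 0.01 <= rejections / reps <= 0.10

    def test_planted_shift_ranks_on_top(self):
        att = rng.normal(0.5, 0.01, size=(200, 20))
        att[:, [10, 13, 16, 19]] += 0.05  # vertical-axis IMU channels
        out = rank_sensors(self._folds(att))
        top4 = set(out["report"]["channel"].head(4))
        assert top4 == {"A_LZ", "A_RZ", "G_LZ", "G_RZ"}
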