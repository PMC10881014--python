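import numpy as np
import pytest

from fishrhythm.group_stats import (
    bonferroni,
    cohens_d,
    compare_sites,
    export_model_table,
    MODEL_TABLE_COLUMNS,
    one_way_anova,
    remove_outliers,
    welch_t_test,
)
from fishrhythm.rhythm_core import summarize_sequence
from fishrhythm.sequence_builder import CallSequence
from fishrhythm.selection_io import ElementRecord

from oracles import permutation_p_two_sample
from test_selection_io import make_meta


class TestRemoveOutliers:
    def test_extreme_point_removed(self, rng):
        values = np.concatenate([rng.normal(0.3, 0.05, 50), [10.0]])
        kept, removed = remove_outliers(values, k=3)
        assert removed.tolist() == [50]
        assert kept.size == 50

    def test_tiny_symmetric_set_untouched(self):
        kept, removed = remove_outliers([1.0, 2.0, 3.0], k=3)
        assert removed.size == 0
        assert kept.tolist() == [1.0, 2.0, 3.0]

    def test_k_zero_keeps_only_the_mean(self):
        kept, removed = remove_outliers([1.0, 2.0, 3.0], k=0)
        assert kept.tolist() == [2.0]
        assert removed.tolist() == [0, 2]

    def test_single_pass_not_iterated(self):
        # After removing 100, the SD of the remainder would flag 10 too; a
        # single pass must keep it.
        values = [1.0, 1.1, 0.9, 1.05, 0.95, 10.0, 100.0]
        kept, removed = remove_outliers(values, k=2)
        assert 10.0 in kept.tolist()
        assert removed.tolist() == [6]

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            remove_outliers([1.0, 2.0])


class TestWelchT:
    def test_identical_groups(self):
        res = welch_t_test([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_hand_computed_shifted_groups(self):
        # Equal variances, shift 1: t = -1 / sqrt(2 * (5/3) / 4), df = 6.
        res = welch_t_test([1, 2, 3, 4], [2, 3, 4, 5])
        assert res.statistic == pytest.approx(-1.0954451, abs=1e-6)
        assert res.df == pytest.approx(6.0)

    def test_antisymmetry(self):
        a, b = [1.0, 2.5, 3.0], [2.0, 4.0, 5.5, 6.0]
        fwd, rev = welch_t_test(a, b), welch_t_test(b, a)
        assert fwd.statistic == pytest.approx(-rev.statistic)
        assert fwd.p_two_sided == pytest.approx(rev.p_two_sided)

    def test_agrees_with_permutation_oracle(self, rng):
        a = rng.normal(0.36, 0.08, 15)
        b = rng.normal(0.40, 0.08, 15)
        res = welch_t_test(a, b)
        p_perm = permutation_p_two_sample(a, b, n_perm=10_000, seed=1)
        assert res.p_two_sided == pytest.approx(p_perm, abs=0.02)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0, 1.0], [1.0, 1.0])


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        res = one_way_anova({"a": [1, 2], "b": [1, 2], "c": [1, 2]})
        assert res.statistic == pytest.approx(0.0)

    def test_hand_computed_two_groups(self):
        # SSB = 4, SSW = 1, df (1, 2) -> F = 8.
        res = one_way_anova({"a": [1, 2], "b": [3, 4]})
        assert res.statistic == pytest.approx(8.0)
        assert res.df == (1.0, 2.0)

    def test_group_order_irrelevant(self, rng):
        groups = {k: rng.normal(0, 1, 10) for k in "abc"}
        fwd = one_way_anova(groups)
        rev = one_way_anova(dict(reversed(groups.items())))
        assert fwd.statistic == pytest.approx(rev.statistic)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova({"a": [1, 2], "b": [3]})


class TestCohensD:
    def test_identical_groups(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_unit_shift_at_unit_pooled_sd(self):
        assert cohens_d([1, 2, 3], [2, 3, 4]) == pytest.approx(1.0)

    def test_scale_invariance(self):
        a, b = [1.0, 2.0, 3.5], [2.0, 4.0, 5.0]
        assert cohens_d([2 * x for x in a], [2 * x for x in b]) == pytest.approx(
            cohens_d(a, b)
        )

    def test_concentrates_on_standardized_mean_difference(self, rng):
        a = rng.normal(0.36, 0.08, 4000)
        b = rng.normal(0.46, 0.08, 4000)
        assert cohens_d(a, b) == pytest.approx(0.10 / 0.08, rel=0.05)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        a, b = [1.0, 2.5, 3.0, 4.2], [2.0, 4.0, 5.5]
        assert cohens_d(a, b) == pytest.approx(
            abs(pingouin.compute_effsize(a, b, eftype="cohen"))
        )

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [2.0, 2.0])


class TestBonferroni:
    @pytest.mark.parametrize(
        "ps, expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.06, 0.09]),
            ([0.5, 0.7], [1.0, 1.0]),
            ([0.2], [0.2]),
        ],
    )
    def test_definition(self, ps, expected):
        assert bonferroni(ps) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.5, 1.2])

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        ps = [0.001, 0.04, 0.2, 0.9]
        _, adjusted, _, _ = sm.multipletests(ps, method="bonferroni")
        assert bonferroni(ps) == pytest.approx(adjusted.tolist())


class TestCompareSites:
    def test_pairs_cover_all_sites(self, rng):
        beats = {s: rng.normal(0.36, 0.08, 20) for s in ("crete", "trieste", "venice")}
        anova, pairwise = compare_sites(beats)
        assert anova.groups == ("crete", "trieste", "venice")
        assert [r.groups for r in pairwise] == [
            ("crete", "trieste"), ("crete", "venice"), ("trieste", "venice"),
        ]
        assert all(r.p_adjusted >= r.p_two_sided for r in pairwise)

    def test_shifted_site_has_largest_effect(self, rng):
        beats = {
            "a": rng.normal(0.36, 0.08, 40),
            "b": rng.normal(0.36, 0.08, 40),
            "venice": rng.normal(0.46, 0.08, 40),
        }
        _, pairwise = compare_sites(beats)
        by_d = max(pairwise, key=lambda r: r.effect_size_d)
        assert "venice" in by_d.groups

    def test_single_sequence_site_rejected(self):
        with pytest.raises(ValueError, match="venice"):
            compare_sites({"a": [0.3, 0.4], "venice": [0.5]})


class TestExportModelTable:
    def make_summary(self, source_id):
        onsets = np.arange(10) / 0.36
        elements = tuple(
            ElementRecord(selection_id=i + 1, begin_s=t, end_s=t + 0.2,
                          low_hz=100, high_hz=500, source_id=source_id)
            for i, t in enumerate(onsets)
        )
        seq = CallSequence(elements=elements, source_id=source_id)
        return summarize_sequence(seq)

    def test_join_produces_documented_schema(self, tmp_path):
        summaries = [self.make_summary("rec1"), self.make_summary("rec2")]
        metas = [make_meta("rec1"), make_meta("rec2")]
        path = tmp_path / "model.csv"
        frame = export_model_table(summaries, metas, path)
        assert tuple(frame.columns) == MODEL_TABLE_COLUMNS
        assert len(frame) == 2
        assert path.exists()

    def test_orphan_summary_rejected(self):
        with pytest.raises(ValueError, match="rec2"):
            export_model_table([self.make_summary("rec2")], [make_meta("rec1")])
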