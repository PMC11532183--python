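import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibroquant import (
    GroupSummary,
    RatingMatrix,
    StageLabel,
    anova_tukey,
    fleiss_kappa,
    kappa_band,
    paired_t_test,
    summarize_by_stage,
)
from fibroquant.stats import COARSE_ORDER, STAGE_ORDER, p_to_stars

from conftest import naive_fleiss_kappa


class TestStageLabel:
    def test_total_ordering(self):
        labels = [StageLabel(s) for s in STAGE_ORDER]
        for a, b in zip(labels, labels[1:]):
            assert a < b

    def test_coarse_mapping_surjective(self):
        coarse = {StageLabel(s).coarse for s in STAGE_ORDER}
        assert coarse == set(COARSE_ORDER)

    @pytest.mark.parametrize("text,expected", [("1a", "F1a"), ("f2", "F2"), ("F4", "F4"), (" 3 ", "F3")])
    def test_case_insensitive_parse(self, text, expected):
        assert StageLabel.parse(text).value == expected

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError):
            StageLabel.parse("F9")


class TestFleissKappa:
    def test_perfect_agreement(self):
        m = RatingMatrix(labels=np.array([["F2"] * 4, ["F3"] * 4, ["F4"] * 4], dtype=object))
        assert fleiss_kappa(m) == 1.0

    def test_single_category_everywhere(self):
        m = RatingMatrix(labels=np.array([["F2"] * 4] * 5, dtype=object))
        assert fleiss_kappa(m) == 1.0

    def test_two_item_antisymmetric_case(self):
        m = RatingMatrix(labels=np.array([["F2", "F3"], ["F3", "F2"]], dtype=object))
        assert fleiss_kappa(m) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n_items = int(rng.integers(3, 15))
            n_raters = int(rng.integers(2, 6))
            labels = rng.choice(STAGE_ORDER, size=(n_items, n_raters)).astype(object)
            m = RatingMatrix(labels=labels)
            table = m.count_table()
            if (table.max(axis=1) == n_raters).all():
                assert fleiss_kappa(m) == 1.0
                continue
            assert fleiss_kappa(m) == pytest.approx(naive_fleiss_kappa(table), abs=1e-12)

    def test_coarse_collapses_f1(self):
        labels = np.array([["F1a", "F1b"], ["F1c", "F1a"], ["F2", "F2"]], dtype=object)
        m = RatingMatrix(labels=labels)
        assert fleiss_kappa(m, coarse=True) == 1.0
        assert fleiss_kappa(m) < 1.0

    def test_requires_two_raters(self):
        with pytest.raises(ValueError):
            RatingMatrix(labels=np.array([["F2"], ["F3"]], dtype=object))


class TestKappaBand:
    @pytest.mark.parametrize(
        "kappa,band",
        [
            (0.44, "moderate"),
            (0.73, "substantial"),
            (0.405, "moderate"),  # rounds to 0.41
            (0.55, "moderate"),
            (0.15, "slight"),
            (0.21, "fair"),
            (0.85, "almost perfect"),
            (0.0, "poor/none"),
            (-0.5, "poor/none"),
            (1.0, "almost perfect"),
        ],
    )
    def test_bands(self, kappa, band):
        assert kappa_band(kappa) == band

    @given(st.floats(min_value=-1.0, max_value=1.0, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_total_over_domain(self, kappa):
        assert kappa_band(kappa) in {
            "poor/none",
            "slight",
            "fair",
            "moderate",
            "substantial",
            "almost perfect",
        }


class TestPairedTTest:
    def test_zero_variance_differences_error(self):
        with pytest.raises(ValueError):
            paired_t_test([1, 2, 3], [2, 3, 4])  # all diffs equal, nonzero
        with pytest.raises(ValueError):
            paired_t_test([1, 2, 3], [1, 2, 3])  # all diffs zero

    def test_short_input_error(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0], [2.0])

    def test_power_against_unit_shift(self):
        rng = np.random.default_rng(5)
        pre = rng.normal(0, 1, 200)
        post = pre + rng.normal(1, 1, 200)
        res = paired_t_test(pre, post)
        assert res.p < 0.05
        assert res.significant
        assert res.df == 199


class TestAnovaTukey:
    def test_null_groups_not_significant(self):
        rng = np.random.default_rng(9)
        values = np.concatenate([rng.normal(5, 1, 12) for _ in range(3)])
        groups = ["F2"] * 12 + ["F3"] * 12 + ["F4"] * 12
        res = anova_tukey(values, groups)
        assert res.p > 0.05 or all(res.tukey["p_adj"] > 0.01)

    def test_two_groups_matches_t_test(self):
        from scipy import stats as sps

        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.8, 1, 12)
        res = anova_tukey(np.concatenate([a, b]), ["F2"] * 10 + ["F3"] * 12)
        t_p = sps.ttest_ind(a, b, equal_var=True).pvalue
        assert res.tukey["p_adj"].iloc[0] == pytest.approx(t_p, abs=1e-9)

    def test_stage_gradient_all_pairs_significant(self):
        rng = np.random.default_rng(17)
        means = {"F2": 2.6, "F3": 5.7, "F4": 10.9}
        values, groups = [], []
        for g, m in means.items():
            values.extend(rng.normal(m, 0.8, 10))
            groups.extend([g] * 10)
        res = anova_tukey(values, groups)
        assert res.p < 0.05
        assert (res.tukey["p_adj"] < 0.05).all()

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey([1, 2, 3], ["F2", "F2", "F3"])

    def test_familywise_error_control(self):
        # 4 groups of 10 under the null: family-wise rejection rate at the
        # nominal 0.05 stays below 0.07 over 2000 simulations.
        rng = np.random.default_rng(100)
        rejections = 0
        n_sim = 2000
        groups = np.repeat(["F1", "F2", "F3", "F4"], 10)
        for _ in range(n_sim):
            values = rng.normal(0, 1, 40)
            res = anova_tukey(values, groups)
            if (res.tukey["p_adj"] < 0.05).any():
                rejections += 1
        assert rejections / n_sim <= 0.07


def test_stars_thresholds():
    assert p_to_stars(0.04) == "*"
    assert p_to_stars(0.005) == "**"
    assert p_to_stars(5e-4) == "***"
    assert p_to_stars(5e-5) == "****"
    assert p_to_stars(0.2) == "ns"


class TestSummaries:
    def test_basic_group(self):
        out = summarize_by_stage([2, 4, 6], ["F2", "F2", "F2"])
        s = out[0]
        assert (s.mean, s.min, s.max, s.n) == (4.0, 2.0, 6.0, 3)

    def test_single_value_group(self):
        out = summarize_by_stage([5.0, 1.0, 2.0], ["F4", "F2", "F2"])
        f4 = [s for s in out if s.group == "F4"][0]
        assert f4.sd == 0.0 and f4.iqr == 0.0 and f4.sem == 0.0

    def test_iqr_matches_naive_quantile_oracle(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(0, 1, 37)
        out = summarize_by_stage(vals, ["F3"] * 37)
        s = out[0]
        srt = np.sort(vals)

        def naive_quantile(q):
            pos = q * (len(srt) - 1)
            lo = int(np.floor(pos))
            hi = int(np.ceil(pos))
            return srt[lo] + (pos - lo) * (srt[hi] - srt[lo])

        assert s.iqr == pytest.approx(naive_quantile(0.75) - naive_quantile(0.25), abs=1e-12)
        assert s.mean == pytest.approx(vals.mean(), abs=1e-12)
        assert s.sem == pytest.approx(vals.std(ddof=1) / np.sqrt(37), abs=1e-12)

    def test_fine_grouping_and_ordering(self):
        out = summarize_by_stage([1, 2, 3], ["F1a", "F1b", "F2"], coarse=False)
        assert [s.group for s in out] == ["F1a", "F1b", "F2"]
        out_c = summarize_by_stage([1, 2, 3], ["F1a", "F1b", "F2"], coarse=True)
        assert [s.group for s in out_c] == ["F1", "F2"]
        assert isinstance(out_c[0], GroupSummary)
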