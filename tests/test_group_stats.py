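"""ANOVA routes, compact letters, percent change, normality."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from manuresub.group_stats import (
    GroupSummary,
    anova_from_raw,
    anova_from_summary,
    format_p,
    normality_check,
    pairwise_significant,
    percent_change,
    percent_change_range,
    tukey_letters,
    two_way_anova,
)
from manuresub.synthetic import TrialDataset

YIELD_SUMMARY = GroupSummary(
    labels=("CK", "25%", "50%", "75%", "100%"),
    means=(11.3, 11.7, 10.3, 8.35, 4.03),
    sds=(0.83, 1.46, 0.69, 1.22, 0.35),
    n=3,
)


def _dataset_from_groups(groups, variable="v", depth="0-20"):
    rows = [
        (t, r + 1, depth, variable, value, "")
        for t, values in groups.items()
        for r, value in enumerate(values)
    ]
    return TrialDataset(records=pd.DataFrame(
        rows, columns=["treatment", "replicate", "depth", "variable", "value", "unit"]
    ))


class TestSummaryAnova:
    def test_printed_yield_summary_is_highly_significant(self):
        res = anova_from_summary(YIELD_SUMMARY)
        assert res.df_between == 4 and res.df_within == 10
        assert res.p < 0.001
        assert format_p(res.p) == "<0.001"

    def test_identical_groups_give_f_zero(self):
        s = GroupSummary(("a", "b", "c"), (5.0, 5.0, 5.0), (1.0, 1.0, 1.0), 3)
        res = anova_from_summary(s)
        assert res.F == 0.0 and res.p == 1.0

    def test_zero_within_variance(self):
        s = GroupSummary(("a", "b"), (1.0, 2.0), (0.0, 0.0), 3)
        res = anova_from_summary(s)
        assert np.isinf(res.F) and res.p == 0.0
        s0 = GroupSummary(("a", "b"), (1.0, 1.0), (0.0, 0.0), 3)
        res0 = anova_from_summary(s0)
        assert res0.F == 0.0 and res0.p == 1.0

    @given(
        m1=st.floats(-10, 10), m2=st.floats(-10, 10),
        s1=st.floats(0.1, 5), s2=st.floats(0.1, 5),
        n=st.integers(2, 12),
    )
    def test_two_groups_f_equals_squared_pooled_t(self, m1, m2, s1, s2, n):
        summary = GroupSummary(("a", "b"), (m1, m2), (s1, s2), n)
        res = anova_from_summary(summary)
        sp2 = (s1**2 + s2**2) / 2
        t = (m1 - m2) / np.sqrt(sp2 * 2 / n)
        assert res.F == pytest.approx(t**2, rel=1e-9)


class TestRawAnova:
    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25)
    def test_raw_matches_summary_and_scipy(self, seed):
        rng = np.random.default_rng(seed)
        groups = {f"g{i}": rng.normal(i, 1.0, size=4) for i in range(4)}
        ds = _dataset_from_groups(groups)
        res = anova_from_raw(ds, "v", "0-20")
        via_summary = anova_from_summary(GroupSummary.from_raw(groups))
        assert res.F == pytest.approx(via_summary.F, abs=1e-10)
        # independent oracle: scipy's one-way ANOVA on the raw values
        f_ref, p_ref = stats.f_oneway(*groups.values())
        assert res.F == pytest.approx(f_ref, rel=1e-9)
        assert res.p == pytest.approx(p_ref, rel=1e-9)

    def test_constant_everything_gives_f_zero(self):
        ds = _dataset_from_groups({"a": [2.0, 2.0, 2.0], "b": [2.0, 2.0, 2.0]})
        assert anova_from_raw(ds, "v", "0-20").F == 0.0

    def test_power_against_large_injected_effect(self, rng):
        rejections = 0
        n_sim = 500
        for _ in range(n_sim):
            groups = {
                "CK": rng.normal(0.0, 1.0, size=3),
                "T1": rng.normal(0.0, 1.0, size=3),
                "T2": rng.normal(4.0, 1.0, size=3),  # large effect
            }
            res = anova_from_summary(GroupSummary.from_raw(groups))
            rejections += res.p < 0.05
        assert rejections / n_sim > 0.95


class TestTwoWayAnova:
    def test_null_calibration_of_all_terms(self):
        rng = np.random.default_rng(0)
        n_sim = 500
        hits = {"treatment": 0, "depth": 0, "treatment:depth": 0}
        for _ in range(n_sim):
            rows = []
            for t in ("CK", "25%", "50%"):
                for d in ("0-20", "20-40"):
                    for r in (1, 2, 3):
                        rows.append((t, r, d, "v", rng.normal(), ""))
            ds = TrialDataset(records=pd.DataFrame(
                rows, columns=["treatment", "replicate", "depth", "variable",
                               "value", "unit"]))
            table = two_way_anova(ds, "v")
            for term in hits:
                hits[term] += table.loc[term, "p"] < 0.05
        # binomial 95% CI around 0.05 with 500 simulations
        lo, hi = stats.binom.ppf([0.025, 0.975], n_sim, 0.05) / n_sim
        for term, count in hits.items():
            assert lo <= count / n_sim <= hi, f"{term}: {count / n_sim}"

    def test_depth_only_effect_detected(self, rng):
        detected = 0
        null_treatment = 0
        n_sim = 200
        for _ in range(n_sim):
            rows = []
            for t in ("CK", "25%", "50%"):
                for d, shift in (("0-20", 0.0), ("20-40", 3.0)):
                    for r in (1, 2, 3):
                        rows.append((t, r, d, "v", rng.normal(shift), ""))
            ds = TrialDataset(records=pd.DataFrame(
                rows, columns=["treatment", "replicate", "depth", "variable",
                               "value", "unit"]))
            table = two_way_anova(ds, "v")
            detected += table.loc["depth", "p"] < 0.05
            null_treatment += table.loc["treatment", "p"] < 0.05
        assert detected / n_sim > 0.95
        lo, hi = stats.binom.ppf([0.025, 0.975], n_sim, 0.05) / n_sim
        assert lo <= null_treatment / n_sim <= hi

    def test_single_depth_reduces_to_one_way(self, rng):
        groups = {f"g{i}": rng.normal(i, 1.0, size=3) for i in range(3)}
        ds = _dataset_from_groups(groups)
        one = anova_from_raw(ds, "v", "0-20")
        two = two_way_anova(ds, "v")
        assert two.loc["treatment", "F"] == pytest.approx(one.F, rel=1e-9)


class TestLetters:
    def test_identical_groups_share_one_letter(self):
        s = GroupSummary(("a", "b", "c"), (5.0, 5.0, 5.0), (1.0, 1.0, 1.0), 3)
        assert set(tukey_letters(s).values()) == {"a"}

    def test_overwhelming_separation_gives_distinct_letters(self):
        s = GroupSummary(("lo", "mid", "hi"), (0.0, 10.0, 20.0),
                         (0.01, 0.01, 0.01), 3)
        letters = tukey_letters(s)
        assert len(set(letters.values())) == 3
        assert letters["hi"] == "a" and letters["lo"] == "c"

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40)
    def test_letters_match_pairwise_significance_oracle(self, seed):
        """Two groups share a letter iff their pairwise test is
        non-significant, for every random 3-6 group summary."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 7))
        s = GroupSummary(
            labels=tuple(f"g{i}" for i in range(k)),
            means=tuple(rng.uniform(0, 6, size=k)),
            sds=tuple(rng.uniform(0.2, 2.0, size=k)),
            n=int(rng.integers(2, 6)),
        )
        sig = pairwise_significant(s)
        letters = tukey_letters(s)
        for i in range(k):
            for j in range(i + 1, k):
                share = bool(
                    set(letters[s.labels[i]]) & set(letters[s.labels[j]])
                )
                assert share == (not sig[i, j]), (letters, sig)

    @pytest.mark.parametrize("method", ["lsd", "duncan"])
    def test_alternative_families_also_satisfy_oracle(self, method):
        rng = np.random.default_rng(5)
        for _ in range(10):
            k = int(rng.integers(3, 6))
            s = GroupSummary(
                labels=tuple(f"g{i}" for i in range(k)),
                means=tuple(rng.uniform(0, 5, size=k)),
                sds=tuple(rng.uniform(0.3, 1.5, size=k)),
                n=3,
            )
            sig = pairwise_significant(s, method=method)
            letters = tukey_letters(s, method=method)
            for i in range(k):
                for j in range(i + 1, k):
                    share = bool(set(letters[s.labels[i]]) & set(letters[s.labels[j]]))
                    assert share == (not sig[i, j])

    def test_lsd_is_no_less_liberal_than_tukey(self):
        s = GroupSummary(("a", "b", "c", "d"), (0.0, 1.0, 2.0, 3.0),
                         (1.0, 1.0, 1.0, 1.0), 3)
        tukey = pairwise_significant(s, method="tukey")
        lsd = pairwise_significant(s, method="lsd")
        assert (lsd | ~tukey).all() or (lsd.sum() >= tukey.sum())


class TestPercentChange:
    @pytest.mark.parametrize(
        "ref, treat, expected",
        [
            (5.86, 4.99, -14.8),  # root length, half substitution
            (5.86, 3.32, -43.3),  # root length, full substitution
            (26.2, 21.5, -17.9),  # root volume, 75 % substitution
            (26.2, 12.2, -53.4),  # root volume, full substitution
        ],
    )
    def test_root_trait_percent_changes(self, ref, treat, expected):
        assert round(percent_change(ref, treat), 1) == expected

    def test_no_change_and_zero_reference(self):
        assert percent_change(3.2, 3.2) == 0.0
        with pytest.raises(ZeroDivisionError):
            percent_change(0.0, 1.0)

    def test_range_helper(self):
        lo, hi = percent_change_range(5.86, [5.12, 4.99, 4.92, 3.32])
        assert round(lo, 1) == 12.6 and round(hi, 1) == 43.3

    @given(a=st.floats(0.5, 100), b=st.floats(0.5, 100))
    def test_antisymmetry_relation(self, a, b):
        # pc(a,b) = -pc(b,a) * (b/a) algebraically
        assert percent_change(a, b) == pytest.approx(
            -percent_change(b, a) * (b / a), rel=1e-9
        )


class TestNormality:
    def test_calibration_on_normal_samples(self, rng):
        n_sim = 5000
        rejections = sum(
            normality_check(rng.standard_normal(15))[1] < 0.05
            for _ in range(n_sim)
        )
        rate = rejections / n_sim
        assert 0.035 <= rate <= 0.065

    def test_rejects_exponential_samples(self, rng):
        n_sim = 200
        rejections = sum(
            normality_check(rng.exponential(size=50))[1] < 0.05
            for _ in range(n_sim)
        )
        assert rejections / n_sim > 0.90

    def test_constant_sample_is_degenerate(self):
        with pytest.raises(ValueError, match="constant"):
            normality_check([3.0, 3.0, 3.0, 3.0])
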