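"""Diagnosis grouping rules and the statistical comparison battery."""

import numpy as np
import pytest

from plaquescope.cohort_stats import (
    CohortRecord,
    anova_tukey,
    assign_diagnosis_groups,
    kruskal_wallis,
    merge_reagan_levels,
    significance_stars,
    spearman_ordinal,
    two_sided_ttest,
)


def rec(sid, **kw):
    return CohortRecord(slide_id=sid, **kw)


def build_planted_cohort():
    """40 slides with flags planted to produce the canonical group sizes:
    control 5, pure AD 14, all AD 30, AD+TDP 8, AD+LBD 7."""
    records = []
    i = 0
    for _ in range(5):
        records.append(rec(f"s{i}", is_control=True)); i += 1
    for _ in range(2):  # clinically control, AD at autopsy -> excluded by default
        records.append(rec(f"s{i}", is_control=True, clinical_control_with_ad=True)); i += 1
    for _ in range(14):
        records.append(rec(f"s{i}", has_ad=True)); i += 1
    for _ in range(8):
        records.append(rec(f"s{i}", has_ad=True, has_tdp=True)); i += 1
    for _ in range(7):
        records.append(rec(f"s{i}", has_ad=True, has_lbd=True)); i += 1
    # AD with amygdala-predominant Lewy bodies only: in all_AD, nowhere else
    records.append(rec(f"s{i}", has_ad=True, has_lbd=True, amygdala_lbd_only=True)); i += 1
    for _ in range(40 - i):  # non-AD neurodegeneration, in no comparison group
        records.append(rec(f"s{i}")); i += 1
    return records


class TestDiagnosisGroups:
    def test_amygdala_predominant_lbd_excluded_from_lbd_group(self):
        r = rec("x", has_ad=True, has_lbd=True, amygdala_lbd_only=True)
        groups = assign_diagnosis_groups([r])
        assert "x" in groups["all_AD"]
        assert "x" not in groups["AD_LBD"]
        assert "x" not in groups["AD_TDP"]
        assert "x" not in groups["pure_AD"]

    def test_clinical_control_toggle(self):
        r = rec("y", is_control=True, clinical_control_with_ad=True)
        excluded = assign_diagnosis_groups([r], exclude_clinical_controls=True)
        assert all("y" not in ids for ids in excluded.values())
        included = assign_diagnosis_groups([r], exclude_clinical_controls=False)
        assert "y" in included["pure_AD"] and "y" in included["all_AD"]

    def test_planted_cohort_recovers_published_group_sizes(self):
        groups = assign_diagnosis_groups(build_planted_cohort())
        sizes = {g: len(ids) for g, ids in groups.items()}
        assert sizes == {
            "control": 5,
            "pure_AD": 14,
            "all_AD": 30,
            "AD_TDP": 8,
            "AD_LBD": 7,
        }

    def test_control_with_ad_flag_rejected(self):
        with pytest.raises(ValueError):
            rec("z", is_control=True, has_ad=True)


class TestReaganMerge:
    def test_no_and_low_map_to_merged_level(self):
        records = [rec("a", reagan="no"), rec("b", reagan="low")]
        groups = merge_reagan_levels(records)
        assert set(groups["no/low"]) == {"a", "b"}

    def test_planted_counts_merge_to_11_10_19(self):
        records = (
            [rec(f"n{i}", reagan="no") for i in range(7)]
            + [rec(f"l{i}", reagan="low") for i in range(4)]
            + [rec(f"i{i}", reagan="intermediate") for i in range(10)]
            + [rec(f"h{i}", reagan="high") for i in range(19)]
        )
        groups = merge_reagan_levels(records)
        assert [len(groups[g]) for g in ("no/low", "intermediate", "high")] == [11, 10, 19]

    def test_empty_cohort(self):
        groups = merge_reagan_levels([])
        assert all(len(v) == 0 for v in groups.values())

    def test_missing_level_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            groups = merge_reagan_levels([rec("a"), rec("b", reagan="high")])
        assert groups["high"] == ["b"]


class TestAnovaTukey:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            a = rng.normal(0, 1, size=int(rng.integers(3, 12)))
            b = rng.normal(0.5, 1.3, size=int(rng.integers(3, 12)))
            res = anova_tukey({"a": a, "b": b})
            t, _ = two_sided_ttest(a, b)
            assert res.f_statistic == pytest.approx(t**2, rel=1e-9)

    def test_identical_groups_f_zero(self):
        res = anova_tukey({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)

    def test_three_group_hand_example_matches_sum_of_squares(self):
        groups = {"g1": [1.0, 2.0, 3.0], "g2": [2.0, 3.0, 4.0], "g3": [8.0, 9.0, 10.0]}
        res = anova_tukey(groups)
        # direct sum-of-squares oracle
        allv = np.concatenate(list(groups.values()))
        grand = allv.mean()
        ss_between = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
        ss_within = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups.values())
        f_oracle = (ss_between / 2) / (ss_within / 6)
        assert res.f_statistic == pytest.approx(f_oracle, rel=1e-12)
        assert res.anova_p < 0.05

    def test_tukey_adjusted_p_at_least_unadjusted(self):
        rng = np.random.default_rng(1)
        groups = {
            "a": rng.normal(0, 1, 8),
            "b": rng.normal(0.4, 1, 8),
            "c": rng.normal(1.0, 1, 8),
        }
        res = anova_tukey(groups)
        from scipy import stats as sps

        for row in res.tukey:
            raw = sps.ttest_ind(groups[row["group1"]], groups[row["group2"]]).pvalue
            assert row["p_adj"] >= raw - 1e-12

    def test_adjacency_flags(self):
        res = anova_tukey(
            {"none": [1.0, 1.1, 0.9], "sparse": [2.0, 2.1, 1.9], "moderate": [4.0, 4.2, 3.8]}
        )
        flags = {frozenset((r["group1"], r["group2"])): r["adjacent"] for r in res.tukey}
        assert flags[frozenset(("none", "sparse"))] is True
        assert flags[frozenset(("sparse", "moderate"))] is True
        assert flags[frozenset(("none", "moderate"))] is False

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": [1.0, 1.0], "b": [2.0, 2.0]})


class TestTTest:
    def test_identical_samples(self):
        t, p = two_sided_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_swap_negates_t(self):
        t1, p1 = two_sided_ttest([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        t2, p2 = two_sided_ttest([4.0, 5.0, 6.0], [1.0, 2.0, 3.0])
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_hand_example_matches_pooled_formula(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        t, _ = two_sided_ttest(a, b)
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / 4
        t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert t == pytest.approx(t_oracle, rel=1e-12)

    def test_degenerate_equal_constants(self):
        t, p = two_sided_ttest([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = kruskal_wallis({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_all_tied_undefined(self):
        h, p = kruskal_wallis({"a": [5.0, 5.0], "b": [5.0, 5.0]})
        assert np.isnan(h) and np.isnan(p)

    def test_two_group_rank_sum_oracle(self):
        a, b = [1.0, 3.0, 5.0], [2.0, 4.0, 6.0]
        h, _ = kruskal_wallis({"a": a, "b": b})
        # no ties: H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2
        ranks = {1.0: 1, 2.0: 2, 3.0: 3, 4.0: 4, 5.0: 5, 6.0: 6}
        ra = np.mean([ranks[v] for v in a])
        rb = np.mean([ranks[v] for v in b])
        h_oracle = 12 / (6 * 7) * (3 * (ra - 3.5) ** 2 + 3 * (rb - 3.5) ** 2)
        assert h == pytest.approx(h_oracle, rel=1e-12)

    def test_monotone_separated_groups_significant(self):
        groups = {
            "lo": list(np.arange(10.0)),
            "mid": list(np.arange(20.0, 30.0)),
            "hi": list(np.arange(40.0, 50.0)),
        }
        _, p = kruskal_wallis(groups)
        assert p < 0.01


class TestSpearman:
    def test_monotone_is_one(self):
        assert spearman_ordinal([0.1, 0.2, 0.5, 0.9], [0, 1, 2, 3]) == pytest.approx(1.0)

    def test_antitone_is_minus_one(self):
        assert spearman_ordinal([0.9, 0.5, 0.2, 0.1], [0, 1, 2, 3]) == pytest.approx(-1.0)

    def test_tied_example_matches_pearson_on_ranks(self):
        scores = [1.0, 2.0, 2.0, 3.0, 5.0]
        labels = [0, 0, 1, 2, 3]
        rho = spearman_ordinal(scores, labels)
        # midranks by hand: scores -> 1, 2.5, 2.5, 4, 5 ; labels -> 1.5, 1.5, 3, 4, 5
        rs = np.array([1, 2.5, 2.5, 4, 5])
        rl = np.array([1.5, 1.5, 3, 4, 5])
        oracle = np.corrcoef(rs, rl)[0, 1]
        assert rho == pytest.approx(oracle, rel=1e-12)

    def test_string_levels_use_scale_order(self):
        rho = spearman_ordinal([0.0, 0.1, 0.4, 0.8], ["none", "sparse", "moderate", "frequent"])
        assert rho == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        scores = rng.random(20)
        labels = rng.integers(0, 4, 20)
        r1 = spearman_ordinal(scores, labels)
        r2 = spearman_ordinal(np.exp(5 * scores), labels)
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_constant_input_missing(self):
        assert np.isnan(spearman_ordinal([1.0, 1.0, 1.0], [0, 1, 2]))


def test_significance_stars_boundaries():
    assert significance_stars(0.2) == ""
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.009) == "**"
    assert significance_stars(0.0009) == "***"
    assert significance_stars(0.00009) == "****"
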