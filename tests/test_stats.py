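import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import pibquant as pq
from pibquant.phantom import CORTICAL_REGIONS, REGION_LABELS
from pibquant.stats import roc_analysis


def make_table(values_by_region, subject="s1", group="CTL", metric="DVR_L"):
    return pd.DataFrame([
        {"subject": subject, "group": group, "region": r, "metric": metric, "value": v}
        for r, v in values_by_region.items()
    ])


class TestRegionalMeans:
    def test_constant_image_gives_constant_means(self):
        labels = np.zeros((4, 4, 4), int)
        labels[0], labels[1] = 1, 2
        metric = pq.MetricImage(np.full((4, 4, 4), 2.5), kind="DVR_L")
        table = pq.regional_means(metric, labels, {"a": 1, "b": 2})
        assert np.allclose(table["value"], 2.5)

    def test_two_voxel_region_mean(self):
        labels = np.zeros((2, 2, 2), int)
        labels[0, 0, 0] = labels[0, 0, 1] = 3
        data = np.zeros((2, 2, 2))
        data[0, 0, 0], data[0, 0, 1] = 1.0, 3.0
        table = pq.regional_means(pq.MetricImage(data, kind="DV"), labels, {"r": 3})
        assert table["value"].iloc[0] == pytest.approx(2.0)

    def test_label_permutation_leaves_named_means_unchanged(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(1, 2, (5, 5, 5))
        labels = rng.integers(0, 4, (5, 5, 5))
        t1 = pq.regional_means(pq.MetricImage(data, "DV"), labels, {"a": 1, "b": 2, "c": 3})
        perm = {0: 0, 1: 3, 2: 1, 3: 2}
        relabeled = np.vectorize(perm.get)(labels)
        t2 = pq.regional_means(pq.MetricImage(data, "DV"), relabeled, {"a": 3, "b": 1, "c": 2})
        merged = t1.merge(t2, on="region", suffixes=("_1", "_2"))
        assert np.allclose(merged["value_1"], merged["value_2"])

    def test_invalid_voxels_excluded_and_empty_regions_absent(self):
        labels = np.zeros((3, 3, 3), int)
        labels[0, 0, :2] = 1
        data = np.array([5.0, 99.0])
        metric = pq.MetricImage(np.zeros((3, 3, 3)), kind="DV")
        metric.data[0, 0, :2] = data
        metric.valid[:] = True
        metric.valid[0, 0, 1] = False
        table = pq.regional_means(metric, labels, {"a": 1, "missing": 7})
        assert list(table["region"]) == ["a"]
        assert table["value"].iloc[0] == pytest.approx(5.0)


class TestCorticalMaxAndPcc:
    def test_matches_brute_force_max(self):
        rng = np.random.default_rng(5)
        vals = {r: v for r, v in zip(CORTICAL_REGIONS, rng.uniform(1.0, 2.1, 8))}
        vals["pcc"] = 2.4
        table = make_table(vals)
        cx, pcc = pq.cortical_max_and_pcc(table, "s1", "DVR_L")
        assert cx == pytest.approx(max(vals[r] for r in CORTICAL_REGIONS))
        assert pcc == pytest.approx(2.4)

    def test_missing_region_rejected(self):
        vals = {r: 1.0 for r in CORTICAL_REGIONS[:-1]}
        vals["pcc"] = 1.2
        with pytest.raises(ValueError, match="missing"):
            pq.cortical_max_and_pcc(make_table(vals), "s1", "DVR_L")


class TestPearsonRegression:
    def test_exact_line_recovered(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        slope, intercept, r2, p = pq.pearson_regression(x, 2 * x + 1)
        assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0))

    def test_closed_form_three_point_fit(self):
        # hand OLS: Sxy=3, Sxx=2, Syy=14/3 -> slope 1.5, intercept -2/3,
        # r^2 = 9/(2*14/3) = 27/28
        slope, intercept, r2, _ = pq.pearson_regression([1, 2, 3], [1, 2, 4])
        assert slope == pytest.approx(1.5)
        assert intercept == pytest.approx(-2.0 / 3.0)
        assert r2 == pytest.approx(27.0 / 28.0)

    def test_independent_samples_have_near_zero_r2(self):
        rng = np.random.default_rng(11)
        _, _, r2, _ = pq.pearson_regression(rng.normal(size=1000), rng.normal(size=1000))
        assert r2 < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pq.pearson_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBlandAltman:
    def test_identity_has_zero_mean_and_sd(self):
        x = np.array([1.0, 1.5, 2.0, 2.5])
        res = pq.bland_altman(x, x, regression_correct=False)
        assert res.mean_diff == 0.0 and res.sd_diff == 0.0
        assert res.loa_low == res.loa_high == 0.0

    def test_regression_correction_removes_exact_linear_offset(self):
        x = np.array([1.0, 1.4, 1.9, 2.2, 2.8])
        res = pq.bland_altman(x, 2.0 * x, regression_correct=True)
        assert res.mean_diff == pytest.approx(0.0, abs=1e-12)
        assert res.sd_diff == pytest.approx(0.0, abs=1e-12)
        assert res.slope == pytest.approx(2.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pq.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0])

    def test_noisier_pair_flagged_by_variance_comparison(self):
        rng = np.random.default_rng(2)
        truth = rng.uniform(1, 2.5, 500)
        d_a = truth + rng.normal(0, 0.05, 500) - truth
        d_b = truth + rng.normal(0, 0.10, 500) - truth
        t, p = pq.pitman_morgan(d_b, d_a)
        assert p < 0.05
        assert t > 0  # first argument is the more variable pair
        _, p_eq = pq.pitman_morgan(d_a, rng.permutation(d_a))
        assert p_eq > 0.05


class TestGroupTest:
    def test_identical_groups_give_p_one(self):
        vals = {"pcc": 1.3}
        rows = []
        for grp in ("CTL", "eAD"):
            for i in range(4):
                rows.append(make_table(vals, subject=f"{grp}{i}", group=grp))
        res = pq.group_test(pd.concat(rows), "pcc", "DVR_L")
        assert res.p_value == pytest.approx(1.0)
        assert res.ctl_mean == res.ead_mean

    def test_separated_groups_highly_significant(self):
        rng = np.random.default_rng(4)
        rows = []
        for i, v in enumerate(rng.normal(1.2, 0.15, 16)):
            rows.append(make_table({"pcc": v}, subject=f"c{i}", group="CTL"))
        for i, v in enumerate(rng.normal(2.1, 0.15, 19)):
            rows.append(make_table({"pcc": v}, subject=f"a{i}", group="eAD"))
        res = pq.group_test(pd.concat(rows), "pcc", "DVR_L")
        assert res.p_value < 1e-5

    def test_welch_p_consistent_with_permutation_oracle(self):
        rng = np.random.default_rng(8)
        ctl = rng.normal(1.2, 0.2, 12)
        ead = rng.normal(1.45, 0.2, 12)
        rows = [make_table({"pcc": v}, subject=f"c{i}", group="CTL") for i, v in enumerate(ctl)]
        rows += [make_table({"pcc": v}, subject=f"a{i}", group="eAD") for i, v in enumerate(ead)]
        res = pq.group_test(pd.concat(rows), "pcc", "DVR_L")

        pooled = np.concatenate([ctl, ead])
        obs = abs(ctl.mean() - ead.mean())
        count = 0
        n_perm = 1000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            count += abs(pooled[:12].mean() - pooled[12:].mean()) >= obs
        p_perm = (count + 1) / (n_perm + 1)
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p_perm - res.p_value) < 4 * se + 0.01

    def test_paired_vs_pcc(self):
        rng = np.random.default_rng(6)
        rows = []
        for i in range(10):
            base = rng.normal(2.0, 0.2)
            rows.append(make_table({"pcc": base + 0.3, "frontal_l": base}, subject=f"s{i}", group="eAD"))
        p = pq.paired_vs_pcc(pd.concat(rows), "frontal_l", "DVR_L", "eAD")
        assert p < 0.001

    def test_small_groups_rejected(self):
        table = pd.concat([
            make_table({"pcc": 1.0}, subject="a", group="CTL"),
            make_table({"pcc": 2.0}, subject="b", group="eAD"),
        ])
        with pytest.raises(ValueError):
            pq.group_test(table, "pcc", "DVR_L")


def auc_by_concordance(values, groups, positive="eAD"):
    """All-pairs oracle: AUC = P(pos > neg) + 0.5 P(tie)."""
    values = np.asarray(values, float)
    pos = values[np.asarray(groups) == positive]
    neg = values[np.asarray(groups) != positive]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        values = [1.0, 2.0, 3.0, 4.0]
        groups = ["CTL", "CTL", "eAD", "eAD"]
        res = pq.roc_analysis(values, groups)
        assert res.auc == 1.0
        assert 2.0 < res.threshold <= 3.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_identical_distributions_have_half_auc(self):
        rng = np.random.default_rng(13)
        values = rng.normal(size=400)
        groups = np.array(["CTL"] * 200 + ["eAD"] * 200)
        res = pq.roc_analysis(values, groups)
        assert abs(res.auc - 0.5) < 0.08

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pq.roc_analysis([1.0, 2.0], ["CTL", "CTL"])

    @given(st.data())
    def test_trapezoid_auc_equals_all_pairs_concordance(self, data):
        n_pos = data.draw(st.integers(1, 8))
        n_neg = data.draw(st.integers(1, 8))
        vals = data.draw(st.lists(st.integers(0, 6), min_size=n_pos + n_neg,
                                  max_size=n_pos + n_neg))
        values = np.array(vals, float)
        groups = np.array(["eAD"] * n_pos + ["CTL"] * n_neg)
        res = pq.roc_analysis(values, groups)
        assert res.auc == pytest.approx(auc_by_concordance(values, groups), abs=1e-12)

    @given(scale=st.floats(0.1, 10.0), power=st.floats(0.2, 3.0))
    def test_auc_invariant_under_monotone_transform(self, scale, power):
        rng = np.random.default_rng(21)
        values = rng.uniform(0.5, 3.0, 30)
        groups = np.array(["CTL"] * 15 + ["eAD"] * 15)
        base = pq.roc_analysis(values, groups).auc
        transformed = pq.roc_analysis(scale * values**power, groups).auc
        assert transformed == pytest.approx(base, abs=1e-12)
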