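"""Region summaries and nonparametric tests against exact-enumeration
oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from lamap.imaging import Mask, RegionAnnotation, SampleRecord
from lamap.stats import (RegionSummary, StatsPlan, classify_strength,
                         group_comparison_report, mann_whitney_one_tailed,
                         masked_summary, region_summary,
                         spearman_colocalization,
                         wilcoxon_signed_rank_two_tailed)

# ---------------------------------------------------------------------------
# enumeration oracles
# ---------------------------------------------------------------------------


def mwu_exact_p_b_greater(a, b):
    """P(U_a <= u_obs) by enumerating every assignment of the pooled values
    to the two groups (tie-free inputs)."""
    pooled = np.concatenate([a, b])
    na = len(a)

    def u_of(a_vals, b_vals):
        return sum(x > y for x in a_vals for y in b_vals)

    u_obs = u_of(a, b)
    us = []
    for idx in itertools.combinations(range(len(pooled)), na):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(idx)] = True
        us.append(u_of(pooled[sel], pooled[~sel]))
    us = np.array(us)
    return (us <= u_obs).mean()


def wilcoxon_exact_p_two_sided(d):
    """Two-sided signed-rank p by enumerating all 2^n sign patterns
    (tie-free nonzero differences)."""
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = np.array([sum(r for r, s in zip(ranks, signs) if s)
                   for signs in itertools.product([False, True], repeat=n)])
    cdf = (ws <= w_obs).mean()
    sf = (ws >= w_obs).mean()
    return min(1.0, 2 * min(cdf, sf))


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _annotation_1d(values_by_region):
    """Build a 1-row annotation + data array from {code: values}."""
    data, labels = [], []
    for code, vals in values_by_region.items():
        data.extend(vals)
        labels.extend([code] * len(vals))
    legend = {0: "background", 1: "adipose", 2: "epithelial"}
    return (np.array([data], dtype=float),
            RegionAnnotation(np.array([labels]), legend))


class TestRegionSummary:
    def test_closed_form_quartiles(self):
        data, ann = _annotation_1d({2: [1, 2, 3, 4, 5], 0: [0, 0]})
        s = region_summary(data, ann, "epithelial", sample_id="s1",
                          element="56Fe")
        assert (s.median, s.q1, s.q3, s.n_pixels) == (3.0, 2.0, 4.0, 5)

    def test_constant_region(self):
        data, ann = _annotation_1d({2: [7.0] * 4})
        s = region_summary(data, ann, "epithelial")
        assert s.median == s.q1 == s.q3 == 7.0

    def test_empty_selection_raises(self):
        data, ann = _annotation_1d({2: [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="adipose.*s9"):
            region_summary(data, ann, "adipose", sample_id="s9")

    def test_mask_intersection(self):
        data, ann = _annotation_1d({2: [1, 2, 3, 4, 5]})
        mask = Mask(np.array([[0, 0, 1, 1, 1]]))
        s = region_summary(data, ann, "epithelial", mask=mask)
        assert s.median == 4.0 and s.n_pixels == 3

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.gamma(2.0, 3.0, size=30)
        data, ann = _annotation_1d({2: vals})
        s1 = region_summary(data, ann, "epithelial")
        data2, _ = _annotation_1d({2: rng.permutation(vals)})
        s2 = region_summary(data2, ann, "epithelial")
        assert (s1.median, s1.q1, s1.q3) == (s2.median, s2.q1, s2.q3)

    def test_masked_summary_matches_region_free_median(self, rng):
        data = rng.gamma(2.0, 5.0, size=(6, 6))
        mask = Mask(rng.random((6, 6)) < 0.7)
        s = masked_summary(data, mask, sample_id="s", element="66Zn")
        assert s.median == np.median(data[mask.data])
        assert s.region == "retained"

    def test_summary_invariants_enforced(self):
        with pytest.raises(ValueError):
            RegionSummary("s", "56Fe", "adipose", median=1.0, q1=2.0, q3=3.0,
                          n_pixels=5)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_small_example_exact(self):
        res = mann_whitney_one_tailed([1, 2], [3, 4], "b_greater")
        assert res.p_value == pytest.approx(1 / 6)
        assert res.method == "exact"
        assert not res.significant

    def test_identical_groups_not_significant(self):
        res = mann_whitney_one_tailed([1, 2, 3], [1, 2, 3])
        assert res.p_value >= 0.4

    def test_sample_size_guard(self):
        with pytest.raises(ValueError):
            mann_whitney_one_tailed([1], [2, 3])

    @pytest.mark.parametrize("n1,n2", [(2, 2), (2, 5), (3, 4), (4, 4), (5, 5)])
    def test_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(100 * n1 + n2)
        for _ in range(5):
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # tie-free
            a, b = pooled[:n1], pooled[n1:]
            res = mann_whitney_one_tailed(a, b, "b_greater")
            assert res.method == "exact"
            assert res.p_value == pytest.approx(mwu_exact_p_b_greater(a, b),
                                                abs=1e-12)

    def test_ties_switch_to_asymptotic(self):
        res = mann_whitney_one_tailed([1, 2, 2, 3], [2, 3, 4, 4])
        assert res.method == "asymptotic"
        assert 0 <= res.p_value <= 1

    def test_one_tailed_direction(self):
        low, high = [1.0, 2, 3, 4], [10.0, 11, 12, 13]
        assert mann_whitney_one_tailed(low, high, "b_greater").significant
        assert not mann_whitney_one_tailed(high, low, "b_greater").significant


# ---------------------------------------------------------------------------
# Wilcoxon
# ---------------------------------------------------------------------------

class TestWilcoxon:
    def test_constant_shift_exact_p(self):
        a = np.array([1.0, 2, 3, 4, 5, 6])
        res = wilcoxon_signed_rank_two_tailed(a, a + 1.0)
        assert res.p_value == pytest.approx(2 / 64)
        assert res.method == "exact"

    def test_equal_pairs_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            wilcoxon_signed_rank_two_tailed([1, 2, 3], [1, 2, 3])

    def test_too_few_nonzero_pairs(self):
        with pytest.raises(ValueError, match="3 nonzero"):
            wilcoxon_signed_rank_two_tailed([1, 2, 3], [1, 2, 5])

    @pytest.mark.parametrize("n", [4, 6, 8, 10])
    def test_matches_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            mags = np.arange(1.0, n + 1)            # distinct -> tie-free
            d = mags * rng.choice([-1, 1], size=n)
            res = wilcoxon_signed_rank_two_tailed(np.zeros(n), d)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(wilcoxon_exact_p_two_sided(d),
                                                abs=1e-12)

    def test_zero_differences_dropped(self):
        a = np.array([1.0, 2, 3, 4, 5, 6, 7])
        b = a + np.array([0.0, 0, 1, 2, 3, 4, 5])
        res = wilcoxon_signed_rank_two_tailed(a, b)
        assert res.n1 == 5


# ---------------------------------------------------------------------------
# Spearman colocalization
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_monotone_transform_gives_unity(self, rng):
        a = rng.gamma(2.0, 5.0, size=(5, 5))
        res = spearman_colocalization(a, np.exp(a / 10), Mask(np.ones((5, 5))))
        assert res.rho == pytest.approx(1.0)
        assert res.strength == "strong"

    def test_negation_gives_minus_one(self, rng):
        a = rng.gamma(2.0, 5.0, size=(5, 5))
        res = spearman_colocalization(a, a.max() - a, Mask(np.ones((5, 5))))
        assert res.rho == pytest.approx(-1.0)

    def test_minimum_pixels_guard(self, rng):
        a = rng.random((3, 3))
        with pytest.raises(ValueError, match="10"):
            spearman_colocalization(a, a, Mask(np.ones((3, 3))))

    def test_constant_map_rank_degenerate(self):
        a = np.ones((4, 4))
        b = np.arange(16.0).reshape(4, 4)
        with pytest.raises(ValueError, match="rank-degenerate"):
            spearman_colocalization(a, b, Mask(np.ones((4, 4))))

    def test_strength_classification(self):
        assert classify_strength(0.85) == "strong"
        assert classify_strength(0.8) == "strong"
        assert classify_strength(0.6) == "moderate"
        assert classify_strength(0.39) == "weak"
        assert classify_strength(-0.9) == "weak"

    def test_equals_pearson_on_ranks(self, rng):
        a = rng.normal(size=200)
        b = 0.5 * a + rng.normal(size=200)
        mask = Mask(np.ones((10, 20)))
        res = spearman_colocalization(a.reshape(10, 20), b.reshape(10, 20), mask)
        expected = np.corrcoef(rankdata(a), rankdata(b))[0, 1]
        assert res.rho == pytest.approx(expected, abs=1e-12)

    def test_copula_phantom_recovers_configured_rank_correlation(self):
        from lamap.synthetic import PhantomConfig, generate_tissue_phantom

        config = PhantomConfig(shape=(100, 125), seed=2,
                               sr_ba_rank_correlation=0.9)
        phantom = generate_tissue_phantom(config, "NM", seed=2)
        epi = phantom.annotation.region_mask("epithelial")
        assert epi.n_retained >= 5000
        res = spearman_colocalization(phantom.truth_conc["88Sr"],
                                      phantom.truth_conc["138Ba"], epi)
        assert res.rho == pytest.approx(0.9, abs=0.02)


# ---------------------------------------------------------------------------
# cohort report
# ---------------------------------------------------------------------------

def _summary(sample_id, element, region, median):
    return RegionSummary(sample_id=sample_id, element=element, region=region,
                         median=median, q1=median * 0.8, q3=median * 1.3,
                         n_pixels=100)


def _cohort_summaries(group_medians, element="56Fe", region="retained"):
    """group_medians: {group: [per-sample medians]}"""
    summaries, records = [], []
    for group, meds in group_medians.items():
        for i, m in enumerate(meds):
            sid = f"{group}{i:02d}"
            summaries.append(_summary(sid, element, region, m))
            records.append(SampleRecord(sid, group))
    return summaries, records


class TestGroupReport:
    def test_separated_groups_flagged_significant(self):
        summaries, records = _cohort_summaries({
            "H": [1.0, 1.2, 0.9, 1.1],
            "NM": [5.0, 6.1, 5.5, 4.9, 6.3, 5.2, 5.8],
            "M": [5.1, 6.0, 5.4, 4.8, 6.6, 5.0, 5.9, 6.2, 5.3, 4.7, 5.6]})
        report = group_comparison_report(summaries, records)
        t = report.tests.set_index("comparison")
        assert t.loc["H_vs_NM", "significant"]
        assert t.loc["H_vs_M", "significant"]
        assert not t.loc["NM_vs_M", "significant"]

    def test_single_group_warns_without_tests(self):
        summaries, records = _cohort_summaries({"H": [1.0, 1.1, 0.9]})
        with pytest.warns(UserWarning, match="one patient group"):
            report = group_comparison_report(summaries, records)
        assert report.tests.empty
        assert len(report.group_summary) == 1

    def test_small_group_comparison_skipped(self):
        summaries, records = _cohort_summaries({"H": [1.0], "NM": [2.0, 2.1, 2.2]})
        with pytest.warns(UserWarning, match="< 2 samples"):
            report = group_comparison_report(summaries, records)
        assert report.tests.empty

    def test_paired_regions_and_stroma_exclusion(self):
        summaries, records = [], []
        for i in range(6):
            sid = f"M{i:02d}"
            records.append(SampleRecord(sid, "M"))
            summaries.append(_summary(sid, "66Zn", "adipose", 0.06 * (1 + i / 10)))
            summaries.append(_summary(sid, "66Zn", "epithelial", 0.5 * (1 + i / 10)))
            summaries.append(_summary(sid, "66Zn", "tumor_niche", 0.8))
            if i < 4:  # two samples lack stroma
                summaries.append(_summary(sid, "66Zn", "stroma", 0.4 + i / 50))
        summaries.append(_summary("M00", "66Zn", "retained", 0.5))
        summaries.append(_summary("M01", "66Zn", "retained", 0.5))
        report = group_comparison_report(summaries, records)
        t = report.tests.set_index("comparison")
        assert t.loc["adipose_vs_epithelial", "n1"] == 6
        assert t.loc["adipose_vs_epithelial", "significant"]
        assert t.loc["tumor_niche_vs_stroma", "n1"] == 4
        assert report.n_excluded["66Zn:tumor_niche_vs_stroma"] == 2

    def test_per_group_summary_of_sample_medians(self):
        summaries, records = _cohort_summaries({"H": [1.0, 2.0, 3.0],
                                                "NM": [4.0, 5.0]})
        report = group_comparison_report(summaries, records)
        h = report.group_summary.query("group == 'H'").iloc[0]
        assert h["median"] == 2.0 and h["n_samples"] == 3

    def test_unknown_sample_raises(self):
        summaries = [_summary("X1", "56Fe", "retained", 1.0)]
        with pytest.raises(ValueError, match="without records"):
            group_comparison_report(summaries, [SampleRecord("H1", "H")])

    def test_bh_qvalues_optional(self):
        summaries, records = _cohort_summaries({
            "H": [1.0, 1.2, 0.9], "NM": [5.0, 6.1, 5.5]})
        report = group_comparison_report(summaries, records,
                                         StatsPlan(bh_qvalues=True))
        assert "q_value" in report.tests.columns
        assert (report.tests["q_value"] >= report.tests["p_value"] - 1e-12).all()


# ---------------------------------------------------------------------------
# level / power simulations on the generator's statistical model
# ---------------------------------------------------------------------------

def test_wilcoxon_power_on_paired_region_medians():
    """Paired adipose-vs-epithelial medians at the configured effect size
    are detected in >= 95% of seeds."""
    from lamap.synthetic import PhantomConfig, sample_cohort_medians

    config = PhantomConfig()
    hits = 0
    n_seeds = 200
    for seed in range(n_seeds):
        df = sample_cohort_medians(config, {"H": 4, "NM": 7, "M": 11},
                                   seed=seed, regions=("adipose", "epithelial"))
        sub = df[df.element == "56Fe"].pivot_table(
            index="sample_id", columns="region", values="median")
        res = wilcoxon_signed_rank_two_tailed(sub["adipose"], sub["epithelial"])
        hits += res.significant
    assert hits / n_seeds >= 0.95
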