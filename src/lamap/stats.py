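"""Region summaries and nonparametric group statistics.

The statistical unit throughout is the per-sample region median (never
pooled pixels, which would pseudo-replicate): each sample contributes one
median (with Q1/Q3) per element x region, and inference runs on those.

Tests mirror standard practice for small tissue cohorts:

* one-tailed Mann-Whitney U between patient groups (elevation in cancer),
* two-tailed Wilcoxon signed-rank for paired regions within samples
  (adipose vs epithelial, tumor niche vs stroma),
* Spearman rank correlation for pixelwise colocalization of two elements
  within a mask, with a weak/moderate/strong classification.

Exact null distributions are used at small n without ties; the normal
approximation with tie and continuity corrections otherwise.  No
multiple-testing correction is applied by default (optional
Benjamini-Hochberg q-values can be added to the report).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calibration import ConcentrationMap
from .imaging import Mask, RegionAnnotation, SampleRecord

logger = logging.getLogger(__name__)

ALPHA = 0.05

#: Spearman strength classification thresholds.
STRONG_RHO = 0.8
MODERATE_RHO = 0.4

#: Switchover sample sizes from exact to approximate null distributions.
MWU_EXACT_MAX_N = 20     # n1 + n2
WILCOXON_EXACT_MAX_N = 25


@dataclass
class RegionSummary:
    """Median with quartiles for one element x region x sample."""

    sample_id: str
    element: str
    region: str
    median: float
    q1: float
    q3: float
    n_pixels: int
    pct_below_loq: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.q1 <= self.median <= self.q3:
            raise ValueError("requires q1 <= median <= q3")
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n1: int
    n2: int
    alternative: str
    method: str = "exact"
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")
        self.significant = bool(self.p_value <= ALPHA)


@dataclass
class CorrelationResult:
    sample_id: str
    elements: tuple[str, str]
    rho: float
    n_pixels: int
    strength: str
    p_value: float = float("nan")


def classify_strength(rho: float) -> str:
    """weak < 0.4 <= moderate < 0.8 <= strong (on the signed coefficient)."""
    if rho >= STRONG_RHO:
        return "strong"
    if rho >= MODERATE_RHO:
        return "moderate"
    return "weak"


def _map_data(conc_map) -> np.ndarray:
    return conc_map.data if isinstance(conc_map, ConcentrationMap) else np.asarray(conc_map)


def region_summary(conc_map, annotation: RegionAnnotation, region: str,
                   mask: Optional[Mask] = None, sample_id: str = "",
                   element: str = "") -> RegionSummary:
    """Median/Q1/Q3 over the pixels of one annotated region (optionally
    intersected with a retention mask).  Quantiles use the linear
    interpolation convention."""
    data = _map_data(conc_map)
    if isinstance(conc_map, ConcentrationMap) and not element:
        element = conc_map.element
    sel = annotation.region_mask(region).data
    if mask is not None:
        sel = sel & mask.data
    if not sel.any():
        raise ValueError(
            f"empty selection for region {region!r}"
            + (f" in sample {sample_id!r}" if sample_id else ""))
    vals = data[sel]
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    pct_loq = None
    if isinstance(conc_map, ConcentrationMap) and conc_map.below_loq is not None:
        pct_loq = float(conc_map.below_loq.data[sel].mean() * 100.0)
    return RegionSummary(sample_id=sample_id, element=element, region=region,
                         median=float(med), q1=float(q1), q3=float(q3),
                         n_pixels=int(sel.sum()), pct_below_loq=pct_loq)


def masked_summary(conc_map, mask: Mask, sample_id: str = "",
                   element: str = "", region: str = "retained") -> RegionSummary:
    """Summary over all retained pixels of a mask (the per-sample histogram
    median used for group comparisons after k-means background removal)."""
    data = _map_data(conc_map)
    if isinstance(conc_map, ConcentrationMap) and not element:
        element = conc_map.element
    if not mask.data.any():
        raise ValueError(f"mask retains no pixels for sample {sample_id!r}")
    vals = data[mask.data]
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    pct_loq = None
    if isinstance(conc_map, ConcentrationMap) and conc_map.below_loq is not None:
        pct_loq = float(conc_map.below_loq.data[mask.data].mean() * 100.0)
    return RegionSummary(sample_id=sample_id, element=element, region=region,
                         median=float(med), q1=float(q1), q3=float(q3),
                         n_pixels=mask.n_retained, pct_below_loq=pct_loq)


# ---------------------------------------------------------------------------
# Hypothesis tests
# ---------------------------------------------------------------------------

def mann_whitney_one_tailed(group_a: Sequence[float], group_b: Sequence[float],
                            alternative: str = "b_greater") -> TestResult:
    """One-tailed Mann-Whitney U test between two independent groups.

    ``alternative="b_greater"`` tests whether ``group_b`` is stochastically
    greater than ``group_a`` (e.g. cancer > healthy).  The exact null
    distribution is used when n1 + n2 <= 20 and there are no ties; otherwise
    the normal approximation with tie and continuity corrections.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if alternative not in ("b_greater", "a_greater"):
        raise ValueError("alternative must be 'b_greater' or 'a_greater'")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (a.size + b.size <= MWU_EXACT_MAX_N and not has_ties) \
        else "asymptotic"
    scipy_alt = "less" if alternative == "b_greater" else "greater"
    res = sps.mannwhitneyu(a, b, alternative=scipy_alt, method=method)
    return TestResult(test_name="mann_whitney_one_tailed",
                      statistic=float(res.statistic), p_value=float(res.pvalue),
                      n1=a.size, n2=b.size, alternative=alternative,
                      method=method)


def wilcoxon_signed_rank_two_tailed(paired_a: Sequence[float],
                                    paired_b: Sequence[float]) -> TestResult:
    """Two-tailed Wilcoxon signed-rank test on paired observations.

    Zero differences are dropped (Wilcoxon's original treatment); at least
    3 nonzero pairs are required.  Exact distribution for n <= 25 without
    tied absolute differences; with ties at n <= 15 the exact sign-flip
    permutation null is enumerated; otherwise the normal approximation with
    tie and continuity corrections.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    d = b - a
    dnz = d[d != 0]
    if dnz.size == 0:
        raise ValueError("degenerate pairing: all paired differences are zero")
    if dnz.size < 3:
        raise ValueError("need at least 3 nonzero paired differences")
    abs_d = np.abs(dnz)
    has_ties = np.unique(abs_d).size < abs_d.size
    if dnz.size <= WILCOXON_EXACT_MAX_N and not has_ties:
        method = "exact"
        res = sps.wilcoxon(dnz, method="exact", alternative="two-sided")
    elif has_ties and dnz.size <= 15:
        # tied |d|: the classical exact table does not apply; enumerate the
        # 2^n sign-flip null instead
        method = "exact"
        res = sps.wilcoxon(dnz, method=sps.PermutationMethod(),
                           alternative="two-sided")
    else:
        method = "approx"
        res = sps.wilcoxon(dnz, correction=True, method="approx",
                           alternative="two-sided")
    return TestResult(test_name="wilcoxon_two_tailed",
                      statistic=float(res.statistic), p_value=float(res.pvalue),
                      n1=dnz.size, n2=dnz.size, alternative="two-sided",
                      method=method)


def spearman_colocalization(map_a, map_b, mask: Mask, sample_id: str = "",
                            elements: tuple[str, str] = ("88Sr", "138Ba")) -> CorrelationResult:
    """Spearman rank correlation of two element maps within a pixel mask.

    Quantifies colocalization (monotone pixelwise co-variation); requires at
    least 10 masked pixels and non-constant inputs.
    """
    da = _map_data(map_a)[mask.data]
    db = _map_data(map_b)[mask.data]
    if da.size < 10:
        raise ValueError(f"need >= 10 masked pixels, got {da.size}")
    if np.unique(da).size < 2 or np.unique(db).size < 2:
        raise ValueError("rank-degenerate: constant input map within mask")
    rho, p = sps.spearmanr(da, db)
    return CorrelationResult(sample_id=sample_id, elements=elements,
                             rho=float(rho), n_pixels=int(da.size),
                             strength=classify_strength(float(rho)),
                             p_value=float(p))


# ---------------------------------------------------------------------------
# Cohort-level report
# ---------------------------------------------------------------------------

@dataclass
class StatsPlan:
    """What the cohort report computes.

    ``group_region`` is the pseudo-region used for between-group tests (the
    k-means-retained histogram median); paired comparisons use annotated
    regions directly.
    """

    alpha: float = ALPHA
    group_region: str = "retained"
    group_pairs: tuple[tuple[str, str], ...] = (("H", "NM"), ("H", "M"), ("NM", "M"))
    paired_regions: tuple[tuple[str, str], ...] = (
        ("adipose", "epithelial"), ("tumor_niche", "stroma"))
    bh_qvalues: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class ReportTables:
    group_summary: pd.DataFrame
    tests: pd.DataFrame
    n_excluded: dict[str, int] = field(default_factory=dict)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def group_comparison_report(summaries: Sequence[RegionSummary],
                            records: Sequence[SampleRecord],
                            plan: StatsPlan | None = None) -> ReportTables:
    """Build the cohort result tables.

    For each element x region: per-group median (Q1-Q3) of per-sample
    medians; pairwise one-tailed Mann-Whitney tests between groups (second
    group tested as greater) on the ``group_region`` medians; paired
    two-tailed Wilcoxon tests for adipose-vs-epithelial and
    tumor-niche-vs-stroma on samples carrying both regions.  Samples lacking
    a region are excluded from its paired comparison with a logged count.
    Groups with fewer than 2 samples are skipped with a warning.
    """
    if plan is None:
        plan = StatsPlan()
    df = pd.DataFrame([{
        "sample_id": s.sample_id, "element": s.element, "region": s.region,
        "median": s.median, "q1": s.q1, "q3": s.q3, "n_pixels": s.n_pixels,
        "pct_below_loq": s.pct_below_loq} for s in summaries])
    if df.empty:
        raise ValueError("no summaries supplied")
    group_of = {r.sample_id: r.group for r in records}
    df["group"] = df["sample_id"].map(group_of)
    if df["group"].isna().any():
        missing = df.loc[df["group"].isna(), "sample_id"].unique()
        raise ValueError(f"summaries for samples without records: {list(missing)}")

    groups_present = [g for g in ("H", "NM", "M") if (df["group"] == g).any()]

    # Per-group summary of per-sample medians.
    rows = []
    for (element, region, group), sub in df.groupby(["element", "region", "group"],
                                                    sort=True):
        q1, med, q3 = np.percentile(sub["median"].to_numpy(), [25, 50, 75])
        rows.append({"element": element, "region": region, "group": group,
                     "median": med, "q1": q1, "q3": q3,
                     "n_samples": len(sub)})
    group_summary = pd.DataFrame(rows)

    test_rows = []
    n_excluded: dict[str, int] = {}

    if len(groups_present) < 2:
        warnings.warn("only one patient group present; no group comparisons",
                      UserWarning, stacklevel=2)
    else:
        for element, sub in df[df["region"] == plan.group_region].groupby("element"):
            by_group = {g: s["median"].to_numpy()
                        for g, s in sub.groupby("group")}
            for ga, gb in plan.group_pairs:
                if ga not in by_group or gb not in by_group:
                    continue
                a, b = by_group[ga], by_group[gb]
                if len(a) < 2 or len(b) < 2:
                    warnings.warn(
                        f"{element} {ga}-vs-{gb}: group with < 2 samples, "
                        "comparison skipped", UserWarning, stacklevel=2)
                    continue
                res = mann_whitney_one_tailed(a, b, alternative="b_greater")
                test_rows.append({
                    "element": element, "region": plan.group_region,
                    "comparison": f"{ga}_vs_{gb}", "test": res.test_name,
                    "statistic": res.statistic, "p_value": res.p_value,
                    "n1": res.n1, "n2": res.n2,
                    "significant": res.p_value <= plan.alpha})

    for ra, rb in plan.paired_regions:
        for element, sub in df[df["region"].isin((ra, rb))].groupby("element"):
            wide = sub.pivot_table(index="sample_id", columns="region",
                                   values="median", aggfunc="first")
            if ra not in wide.columns or rb not in wide.columns:
                continue
            paired = wide[[ra, rb]].dropna()
            excluded = len(wide) - len(paired)
            if excluded:
                key = f"{element}:{ra}_vs_{rb}"
                n_excluded[key] = excluded
                logger.info("%s: %d samples lack %s or %s and are excluded",
                            key, excluded, ra, rb)
            if len(paired) < 3:
                warnings.warn(f"{element} {ra}-vs-{rb}: fewer than 3 complete "
                              "pairs, comparison skipped", UserWarning,
                              stacklevel=2)
                continue
            try:
                res = wilcoxon_signed_rank_two_tailed(paired[ra], paired[rb])
            except ValueError as err:
                warnings.warn(f"{element} {ra}-vs-{rb}: {err}", UserWarning,
                              stacklevel=2)
                continue
            test_rows.append({
                "element": element, "region": f"{ra}|{rb}",
                "comparison": f"{ra}_vs_{rb}", "test": res.test_name,
                "statistic": res.statistic, "p_value": res.p_value,
                "n1": res.n1, "n2": res.n2,
                "significant": res.p_value <= plan.alpha})

    tests = pd.DataFrame(test_rows, columns=[
        "element", "region", "comparison", "test", "statistic", "p_value",
        "n1", "n2", "significant"])
    if plan.bh_qvalues and not tests.empty:
        tests["q_value"] = _bh_adjust(tests["p_value"].to_numpy())
    return ReportTables(group_summary=group_summary, tests=tests,
                        n_excluded=n_excluded)
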