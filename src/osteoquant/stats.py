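"""Two-group statistical comparisons for animal-level means and pooled
distributions.

The decision tree mirrors standard small-sample practice: Shapiro-Wilk per
group and Levene (mean-centered) across groups validate the t-test
assumptions at the same alpha; both-normal + equal-variance data take a
Student's t-test, both-normal + unequal-variance data take the Welch
(unequal-variance) t-test, and any non-normal group routes to the Wilcoxon
rank-sum test (exact null at n <= 10 per group without ties).  The
normality gate takes precedence over the variance gate.  No
multiple-testing correction is applied by default (a-priori alpha = 0.05
per comparison); Holm correction is available behind a flag.

Pooled per-observation samples (all indents or fibrils from all animals of
a group) are compared with the two-sample Kolmogorov-Smirnov test, and a
heterogeneity panel operationalises "broader distribution" as group SDs
plus the proportion of each group's values beyond the joint 10th/90th
percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sstats

from .exceptions import ParameterError, SampleSizeError

ALPHA = 0.05


@dataclass
class GroupedMeasure:
    """Per-animal values for both groups, plus optional pooled samples."""

    name: str
    normal: np.ndarray
    cyplus: np.ndarray
    pooled_normal: np.ndarray | None = None
    pooled_cyplus: np.ndarray | None = None

    def __post_init__(self):
        self.normal = np.asarray(self.normal, dtype=float)
        self.cyplus = np.asarray(self.cyplus, dtype=float)
        if self.normal.size < 2 or self.cyplus.size < 2:
            raise SampleSizeError(
                f"{self.name}: each group needs n >= 2 for mean comparisons"
            )
        for attr in ("pooled_normal", "pooled_cyplus"):
            v = getattr(self, attr)
            if v is not None:
                setattr(self, attr, np.asarray(v, dtype=float))


@dataclass
class ComparisonResult:
    """Outcome of the two-group decision tree for one measure."""

    metric: str
    test_used: str  # student_t | welch_t | wilcoxon_ranksum
    statistic: float
    p_value: float
    normal_ok: tuple[bool, bool]
    variance_ok: bool
    percent_difference: float  # % of the normal-group mean
    significant: bool
    alpha: float = ALPHA
    degenerate: bool = False


def percent_difference(mean_normal: float, mean_cyplus: float) -> float:
    """(cyplus - normal) / normal * 100 -- the '% of normal' convention."""
    if mean_normal == 0:
        raise ParameterError("normal-group mean is zero; percent undefined")
    return (mean_cyplus - mean_normal) / mean_normal * 100.0


def _shapiro_ok(x: np.ndarray, alpha: float) -> bool:
    """True when normality is not rejected.  n < 3 cannot be tested."""
    if np.ptp(x) == 0:
        return False
    if x.size < 3:
        return True
    return float(sstats.shapiro(x).pvalue) > alpha


def choose_and_run_test(
    measure: GroupedMeasure, alpha: float = ALPHA
) -> ComparisonResult:
    """Run the assumption-gated two-group comparison for one measure."""
    a, b = measure.normal, measure.cyplus
    degenerate = np.ptp(a) == 0 or np.ptp(b) == 0

    normal_ok = (_shapiro_ok(a, alpha), _shapiro_ok(b, alpha))
    if degenerate:
        variance_ok = False
    else:
        # at n = 2 per group Levene's denominator can vanish; the undefined
        # case routes to the variance-robust Welch branch
        with np.errstate(divide="ignore", invalid="ignore"):
            lev_p = float(sstats.levene(a, b, center="mean").pvalue)
        variance_ok = bool(np.isfinite(lev_p) and lev_p > alpha)

    if degenerate or not all(normal_ok):
        # non-normal (or constant) data: Wilcoxon rank-sum
        exact = max(a.size, b.size) <= 10 and np.unique(
            np.concatenate([a, b])
        ).size == a.size + b.size
        res = sstats.mannwhitneyu(
            a, b, alternative="two-sided",
            method="exact" if exact else "asymptotic",
        )
        test_used = "wilcoxon_ranksum"
    elif variance_ok:
        res = sstats.ttest_ind(a, b, equal_var=True)
        test_used = "student_t"
    else:
        res = sstats.ttest_ind(a, b, equal_var=False)
        test_used = "welch_t"

    p = float(res.pvalue)
    if degenerate and np.array_equal(np.sort(a), np.sort(b)):
        p = 1.0  # identical constant groups: no evidence of difference
    return ComparisonResult(
        metric=measure.name,
        test_used=test_used,
        statistic=float(res.statistic),
        p_value=p,
        normal_ok=normal_ok,
        variance_ok=bool(variance_ok),
        percent_difference=percent_difference(
            float(np.mean(a)), float(np.mean(b))
        ),
        significant=p < alpha,
        alpha=alpha,
        degenerate=bool(degenerate),
    )


def compare_distributions(
    pooled_a: np.ndarray, pooled_b: np.ndarray
) -> tuple[float, float]:
    """Two-sample KS test: D = sup |ECDF_a - ECDF_b|, asymptotic p."""
    a = np.asarray(pooled_a, dtype=float)
    b = np.asarray(pooled_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise SampleSizeError("KS comparison needs at least 5 per sample")
    res = sstats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class HeterogeneityPanel:
    """Distribution-shape summary for two pooled samples."""

    bin_edges: np.ndarray
    hist_a: np.ndarray
    hist_b: np.ndarray
    sd_a: float
    sd_b: float
    joint_q10: float
    joint_q90: float
    low_tail_a: float  # proportion of group A below the joint 10th pct
    low_tail_b: float
    high_tail_a: float  # proportion of group A above the joint 90th pct
    high_tail_b: float
    ks_statistic: float
    ks_p_value: float


def heterogeneity_panel(
    pooled_a: np.ndarray, pooled_b: np.ndarray, bins: int = 20
) -> HeterogeneityPanel:
    """Shared-bin histograms, SDs and joint-decile tail proportions.

    The joint 10th/90th percentiles are computed over the two samples
    combined; a group whose distribution is broader than the other shows
    tail proportions above 0.10 at both ends.
    """
    a = np.asarray(pooled_a, dtype=float)
    b = np.asarray(pooled_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise SampleSizeError("pooled samples must be non-empty")
    joint = np.concatenate([a, b])
    edges = np.histogram_bin_edges(joint, bins=bins)
    q10, q90 = np.percentile(joint, [10.0, 90.0])
    ks_d, ks_p = compare_distributions(a, b)
    return HeterogeneityPanel(
        bin_edges=edges,
        hist_a=np.histogram(a, bins=edges)[0],
        hist_b=np.histogram(b, bins=edges)[0],
        sd_a=float(np.std(a, ddof=1)),
        sd_b=float(np.std(b, ddof=1)),
        joint_q10=float(q10),
        joint_q90=float(q90),
        low_tail_a=float(np.mean(a < q10)),
        low_tail_b=float(np.mean(b < q10)),
        high_tail_a=float(np.mean(a > q90)),
        high_tail_b=float(np.mean(b > q90)),
        ks_statistic=ks_d,
        ks_p_value=ks_p,
    )


def compare_all(
    measures: Sequence[GroupedMeasure],
    alpha: float = ALPHA,
    holm: bool = False,
) -> list[ComparisonResult]:
    """Run the decision tree over a set of measures.

    With ``holm=True`` the per-measure p-values get a Holm step-down
    adjustment before the significance call (off by default: the study
    design sets a-priori per-comparison alpha).
    """
    results = [choose_and_run_test(m, alpha) for m in measures]
    if holm and results:
        order = np.argsort([r.p_value for r in results])
        m = len(results)
        adj_prev = 0.0
        adjusted = {}
        for rank, idx in enumerate(order):
            adj = min(1.0, (m - rank) * results[idx].p_value)
            adj = max(adj, adj_prev)
            adj_prev = adj
            adjusted[idx] = adj
        for idx, r in enumerate(results):
            r.p_value = adjusted[idx]
            r.significant = r.p_value < alpha
    return results
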