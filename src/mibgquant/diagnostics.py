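"""Group comparison and diagnostic accuracy of the uptake indices.

Disease-positive (LBD) subjects are expected to have LOWER scores on all
three indices, so the operating convention throughout is *positive call =
score below threshold* and the ROC AUC is the probability that a random
non-LBD score exceeds a random LBD score (ties counted one half — the
Mann-Whitney identity).

The exact small-sample tests (Mann-Whitney by full enumeration, Fisher by
hypergeometric tail summation) follow the conventions stated in each
function; paired AUC comparison uses the structural-components (DeLong)
variance rather than a binormal model fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    EmptyGroup,
    EmptySample,
    LengthMismatch,
    NegativeCount,
    OneClassOnly,
    TooFewValues,
)

__all__ = [
    "CohortTable",
    "GroupSummary",
    "RocResult",
    "StatTestResult",
    "DiagnosticMetrics",
    "DiagnosticReport",
    "group_summary",
    "overlap_range",
    "empirical_roc",
    "youden_criterion",
    "diagnostic_metrics",
    "mann_whitney_u",
    "fisher_exact_2x2",
    "spearman_rho",
    "compare_auc",
    "evaluate_cohort",
]

POSITIVE_GROUP = "LBD"
NEGATIVE_GROUP = "non-LBD"


# --------------------------------------------------------------------------
# containers


@dataclass
class CohortTable:
    """Per-subject indices with group labels; thin wrapper over a DataFrame.

    Expected columns: subject, group ("LBD" | "non-LBD"), hm,
    planar_index, spect_index; optionally sex, age.
    """

    data: pd.DataFrame

    def __post_init__(self):
        required = {"subject", "group"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"cohort table needs columns {sorted(required)}")
        bad = set(self.data["group"]) - {POSITIVE_GROUP, NEGATIVE_GROUP}
        if bad:
            raise ValueError(f"invalid group labels: {sorted(bad)}")

    def scores(self, method: str) -> tuple[np.ndarray, np.ndarray]:
        """(scores, labels) for one index column, dropping missing values."""
        sub = self.data[["group", method]].dropna()
        return sub[method].to_numpy(float), sub["group"].to_numpy()

    def group_values(self, method: str, group: str) -> np.ndarray:
        sub = self.data[self.data["group"] == group][method].dropna()
        return sub.to_numpy(float)


@dataclass(frozen=True)
class GroupSummary:
    n: int
    min: float
    max: float
    median: float
    q1: float
    q3: float
    variance: float
    median_ci: tuple[float, float]

    def __post_init__(self):
        if not (self.min <= self.q1 <= self.median <= self.q3 <= self.max):
            raise ValueError("order statistics out of order")


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC: operating points (threshold, sensitivity, specificity)
    for the rule *positive iff score < threshold*, plus the tie-corrected
    AUC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def __post_init__(self):
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must be in [0, 1]")


@dataclass(frozen=True)
class StatTestResult:
    statistic: float
    p_value: float
    method: str

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError("p-value out of [0, 1]")


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: float
    specificity: float
    ppv: float  # NaN when no positive calls
    npv: float  # NaN when no negative calls
    accuracy: float
    ppv_defined: bool = True
    npv_defined: bool = True


@dataclass
class DiagnosticReport:
    """Per-method diagnostic accuracy plus group summaries and overlap."""

    methods: dict = field(default_factory=dict)  # name -> dict of metrics
    group_summaries: dict = field(default_factory=dict)
    overlaps: dict = field(default_factory=dict)
    excluded_subjects: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Comparison-table-shaped frame: one row per method."""
        rows = []
        for name, m in self.methods.items():
            rows.append(
                {
                    "method": name,
                    "auc": m["auc"],
                    "sensitivity": m["sensitivity"],
                    "specificity": m["specificity"],
                    "criterion": m["criterion"],
                    "ppv": m["ppv"],
                    "npv": m["npv"],
                    "accuracy": m["accuracy"],
                }
            )
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# summaries


def group_summary(values) -> GroupSummary:
    """Median, linear-interpolation quartiles, n-1 variance, and a binomial
    order-statistic confidence interval for the median (~95%)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 2:
        raise TooFewValues("group summary needs at least 2 values")
    q1, med, q3 = np.percentile(x, [25, 50, 75], method="linear")
    # largest l with P(X < l) <= 0.025 under Binomial(n, 1/2), 0-based ranks
    lo = int(stats.binom.ppf(0.025, n, 0.5))
    if stats.binom.cdf(lo - 1, n, 0.5) > 0.025:
        lo -= 1
    lo = max(lo, 0)
    hi = min(n - 1 - lo, n - 1)
    return GroupSummary(
        n=n,
        min=float(x[0]),
        max=float(x[-1]),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        variance=float(np.var(x, ddof=1)),
        median_ci=(float(x[lo]), float(x[hi])),
    )


def overlap_range(lbd_values, nonlbd_values) -> Optional[tuple[float, float]]:
    """Overlap interval [min(non-LBD), max(LBD)] of the two groups, or None
    when the (expected-lower) LBD maximum falls below the non-LBD minimum."""
    a = np.asarray(lbd_values, dtype=float)
    b = np.asarray(nonlbd_values, dtype=float)
    if a.size == 0 or b.size == 0:
        raise EmptyGroup("both groups must be non-empty")
    lo, hi = float(b.min()), float(a.max())
    return (lo, hi) if hi >= lo else None


# --------------------------------------------------------------------------
# ROC


def _split_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == POSITIVE_GROUP]
    neg = scores[labels == NEGATIVE_GROUP]
    if pos.size == 0 or neg.size == 0:
        raise OneClassOnly("both classes must be present")
    return pos, neg


def empirical_roc(scores, labels) -> RocResult:
    """Empirical ROC for the rule *positive (LBD) iff score < threshold*.

    AUC is P(non-LBD score > LBD score) with ties counted one half.
    Thresholds sweep the observed scores plus a cut below the minimum and
    one above the maximum.
    """
    pos, neg = _split_scores(scores, labels)
    uniq = np.unique(np.concatenate([pos, neg]))
    cuts = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]])
    sens = np.array([(pos < c).mean() for c in cuts])
    spec = np.array([(neg >= c).mean() for c in cuts])
    gt = (neg[:, None] > pos[None, :]).sum()
    ties = (neg[:, None] == pos[None, :]).sum()
    auc = (gt + 0.5 * ties) / (len(pos) * len(neg))
    return RocResult(thresholds=cuts, sensitivity=sens, specificity=spec, auc=float(auc))


def youden_criterion(roc: RocResult) -> tuple[float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidate cuts are the ROC's thresholds (midpoints between adjacent
    distinct scores); among equal-J cuts the lowest is returned.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    k = int(np.argmax(j))
    return float(roc.thresholds[k]), float(j[k])


def diagnostic_metrics(scores, labels, threshold: float) -> DiagnosticMetrics:
    """2x2 accuracy metrics for the rule *positive iff score < threshold*.

    PPV/NPV are NaN-flagged (with the corresponding ``*_defined`` field
    false) when there are no positive or no negative calls.
    """
    pos, neg = _split_scores(scores, labels)
    tp = int((pos < threshold).sum())
    fn = len(pos) - tp
    tn = int((neg >= threshold).sum())
    fp = len(neg) - tn
    n = tp + fn + tn + fp
    ppv_def = (tp + fp) > 0
    npv_def = (tn + fn) > 0
    return DiagnosticMetrics(
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        ppv=tp / (tp + fp) if ppv_def else float("nan"),
        npv=tn / (tn + fn) if npv_def else float("nan"),
        accuracy=(tp + tn) / n,
        ppv_defined=ppv_def,
        npv_defined=npv_def,
    )


# --------------------------------------------------------------------------
# hypothesis tests


def mann_whitney_u(x, y, exact_limit: int = 20) -> StatTestResult:
    """Mann-Whitney U test; statistic is min(U1, U2).

    With ``n_x + n_y <= exact_limit`` the two-sided p-value is computed by
    full enumeration of all rank splits (symmetric-deviation convention,
    tie-aware); larger samples use the normal approximation with tie
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise EmptySample("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    mu = n1 * n2 / 2.0

    if n1 + n2 <= exact_limit:
        idx = np.array(list(combinations(range(n1 + n2), n1)))
        all_u1 = ranks[idx].sum(axis=1) - n1 * (n1 + 1) / 2.0
        dev = np.abs(all_u1 - mu)
        p = float((dev >= abs(u1 - mu) - 1e-12).mean())
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return StatTestResult(statistic=u, p_value=min(p, 1.0), method="mann-whitney-u")


def fisher_exact_2x2(table) -> StatTestResult:
    """Fisher's exact test, two-sided by the sum-of-smaller-probabilities
    convention (all tables with fixed margins whose hypergeometric
    probability does not exceed the observed table's)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise NegativeCount("counts must be nonnegative integers")
    odds, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    return StatTestResult(statistic=float(odds), p_value=float(p), method="fisher-exact")


def spearman_rho(x, y) -> StatTestResult:
    """Spearman rank correlation (Pearson of mid-ranks, t-approximate p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise LengthMismatch("x and y must have equal length")
    if len(x) < 3:
        raise TooFewValues("need at least 3 pairs")
    rho, p = stats.spearmanr(x, y)
    return StatTestResult(statistic=float(rho), p_value=float(p), method="spearman-rho")


def _structural_components(scores, labels):
    """DeLong placements: per-positive and per-negative AUC components,
    oriented so that the positive (LBD) class is expected LOWER."""
    pos, neg = _split_scores(scores, labels)
    # V10: for each positive, fraction of negatives above it (ties half)
    v10 = ((neg[None, :] > pos[:, None]).sum(axis=1) + 0.5 * (neg[None, :] == pos[:, None]).sum(axis=1)) / len(neg)
    v01 = ((neg[:, None] > pos[None, :]).sum(axis=1) + 0.5 * (neg[:, None] == pos[None, :]).sum(axis=1)) / len(pos)
    return v10, v01


def compare_auc(scores_a, scores_b, labels) -> StatTestResult:
    """Paired two-sided test of equal ROC AUCs on the same subjects, using
    the structural-components (DeLong) variance of the AUC difference."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise LengthMismatch("paired scores must cover the same subjects")
    v10a, v01a = _structural_components(scores_a, labels)
    v10b, v01b = _structural_components(scores_b, labels)
    auc_a, auc_b = v10a.mean(), v10b.mean()
    d10 = v10a - v10b
    d01 = v01a - v01b
    m, n = len(v10a), len(v01a)
    var = (np.var(d10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(d01, ddof=1) / n if n > 1 else 0.0
    )
    diff = auc_a - auc_b
    if var <= 0:
        p = 1.0 if abs(diff) < 1e-12 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return StatTestResult(statistic=float(diff), p_value=min(p, 1.0), method="paired-delong")


# --------------------------------------------------------------------------
# cohort-level report


def evaluate_cohort(
    table: CohortTable,
    methods: tuple[str, ...] = ("hm", "planar_index", "spect_index"),
    excluded: Optional[list] = None,
) -> DiagnosticReport:
    """Full diagnostic report: per-method ROC/Youden/accuracy, group
    summaries, and overlap intervals."""
    report = DiagnosticReport(excluded_subjects=list(excluded or []))
    for method in methods:
        scores, labels = table.scores(method)
        roc = empirical_roc(scores, labels)
        thr, j = youden_criterion(roc)
        dm = diagnostic_metrics(scores, labels, thr)
        lbd = table.group_values(method, POSITIVE_GROUP)
        non = table.group_values(method, NEGATIVE_GROUP)
        mw = mann_whitney_u(lbd, non)
        report.methods[method] = {
            "auc": roc.auc,
            "criterion": thr,
            "youden_j": j,
            "sensitivity": dm.sensitivity,
            "specificity": dm.specificity,
            "ppv": dm.ppv,
            "npv": dm.npv,
            "accuracy": dm.accuracy,
            "group_p": mw.p_value,
        }
        report.group_summaries[method] = {
            POSITIVE_GROUP: group_summary(lbd),
            NEGATIVE_GROUP: group_summary(non),
        }
        report.overlaps[method] = overlap_range(lbd, non)
    return report
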