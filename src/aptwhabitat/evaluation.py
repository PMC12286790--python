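"""ROC/AUC machinery, DeLong inference, Youden thresholding, confusion-metric
algebra, reliability statistics and group-comparison tests.

Conventions fixed here (and relied on everywhere else):

* scores >= threshold  =>  predicted positive;
* AUC is computed with the midrank (Mann-Whitney) formula, ties counted 1/2;
* confusion matrices reconstructed from an operating point use nearest-integer
  rounding of the expected counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROCResult",
    "ConfusionMetrics",
    "DeLongComparison",
    "ReliabilityReport",
    "roc_auc",
    "youden_threshold",
    "confusion_from_operating_point",
    "confusion_from_counts",
    "delong_test",
    "delong_auc_variance",
    "auc_ci_delong",
    "icc_two_rater",
    "group_tests",
]


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROCResult:
    """ROC curve with DeLong AUC inference and the Youden operating point."""

    auc: float
    auc_ci95: tuple[float, float]
    auc_se: float
    #: DeLong z statistic for H0: AUC = 0.5 (the per-model "z" column).
    z_vs_chance: float
    p_vs_chance: float
    threshold_star: float
    youden_j: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    @property
    def curve(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr, self.thresholds])


def _validate_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    uniq = np.unique(labels)
    if not np.isin(uniq, [0, 1]).all():
        raise ValueError(f"labels must be binary 0/1, got {uniq}")
    if uniq.size < 2:
        raise ValueError("both classes must be present")
    return scores, labels.astype(int)


def _midrank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    ranks = stats.rankdata(scores)  # midranks
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    rank_sum_pos = ranks[labels == 1].sum()
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_auc(scores, labels) -> ROCResult:
    """ROC analysis of continuous scores against binary labels.

    AUC uses the midrank formula (equivalent to the Mann-Whitney pair
    probability with ties counted 1/2); the curve is enumerated at every
    unique score value with the convention score >= threshold => positive.
    The 95% CI and the test against AUC = 0.5 use the DeLong variance.
    """
    scores, labels = _validate_scores_labels(scores, labels)
    auc = _midrank_auc(scores, labels)

    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    y_sorted = labels[order]
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tps = np.cumsum(y_sorted)[distinct].astype(float)
    fps = np.cumsum(1 - y_sorted)[distinct].astype(float)
    thresholds = s_sorted[distinct]
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, thresholds]

    var = delong_auc_variance(scores, labels)
    se = float(np.sqrt(var))
    if se > 0:
        z = (auc - 0.5) / se
        p = 2.0 * stats.norm.sf(abs(z))
    elif auc == 0.5:
        z, p = 0.0, 1.0
    else:
        z, p = np.inf * np.sign(auc - 0.5), 0.0
    lo = max(0.0, auc - 1.959963984540054 * se)
    hi = min(1.0, auc + 1.959963984540054 * se)

    j = tpr - fpr
    best = int(np.flatnonzero(j == j.max())[-1])  # last = lowest threshold
    return ROCResult(
        auc=float(auc),
        auc_ci95=(float(lo), float(hi)),
        auc_se=se,
        z_vs_chance=float(z),
        p_vs_chance=float(p),
        threshold_star=float(thresholds[best]),
        youden_j=float(j[best]),
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
    )


def youden_threshold(curve) -> tuple[float, float]:
    """Maximum-Youden operating point from an (fpr, tpr, threshold) curve.

    Returns ``(threshold, J)``; among ties the lowest threshold wins.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 2 or curve.shape[1] != 3 or curve.shape[0] == 0:
        raise ValueError("curve must be a nonempty (n, 3) array of (fpr, tpr, threshold)")
    fpr, tpr, thr = curve.T
    j = tpr - fpr
    winners = np.flatnonzero(j == j.max())
    best = winners[np.argmin(thr[winners])]
    return float(thr[best]), float(j[best])


# ---------------------------------------------------------------------------
# Confusion-metric algebra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    accuracy: float = field(init=False)
    npv: float = field(init=False)
    ppv: float = field(init=False)
    precision: float = field(init=False)
    recall: float = field(init=False)
    youden: float = field(init=False)
    f1: float = field(init=False)

    def __post_init__(self):
        tp, fp, tn, fn = self.tp, self.fp, self.tn, self.fn
        if min(tp, fp, tn, fn) < 0:
            raise ValueError("counts must be non-negative")
        n = tp + fp + tn + fn
        if n == 0:
            raise ValueError("empty confusion matrix")
        sens = tp / (tp + fn) if tp + fn else float("nan")
        spec = tn / (tn + fp) if tn + fp else float("nan")
        object.__setattr__(self, "sensitivity", sens)
        object.__setattr__(self, "specificity", spec)
        object.__setattr__(self, "accuracy", (tp + tn) / n)
        object.__setattr__(self, "npv", tn / (tn + fn) if tn + fn else float("nan"))
        object.__setattr__(self, "ppv", tp / (tp + fp) if tp + fp else float("nan"))
        object.__setattr__(self, "precision", self.ppv)
        object.__setattr__(self, "recall", sens)
        object.__setattr__(self, "youden", sens + spec - 1.0)
        denom = 2 * tp + fp + fn
        object.__setattr__(self, "f1", 2 * tp / denom if denom else float("nan"))
        # hard identities — cheap, and they catch any later refactoring slip
        assert self.precision == self.ppv and self.recall == self.sensitivity
        assert abs(self.youden - (sens + spec - 1.0)) < 1e-12

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "npv": self.npv,
            "ppv": self.ppv,
            "precision": self.precision,
            "recall": self.recall,
            "youden": self.youden,
            "f1": self.f1,
        }


def confusion_from_counts(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    return ConfusionMetrics(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn))


def confusion_from_operating_point(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> ConfusionMetrics:
    """Reconstruct the integer confusion matrix behind a printed operating point.

    TP = round(sensitivity * n_pos) and TN = round(specificity * n_neg);
    FP/FN are the complements. All derived metrics come from the counts.
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both class counts must be >= 1")
    tp = int(round(sensitivity * n_pos))
    tn = int(round(specificity * n_neg))
    return ConfusionMetrics(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)


# ---------------------------------------------------------------------------
# DeLong machinery
# ---------------------------------------------------------------------------


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_s = np.r_[pos, neg]
    rk_all = stats.rankdata(all_s)
    rk_pos = stats.rankdata(pos)
    rk_neg = stats.rankdata(neg)
    auc = (rk_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (rk_all[:m] - rk_pos) / n
    v01 = 1.0 - (rk_all[m:] - rk_neg) / m
    return auc, v10, v01


def delong_auc_variance(scores, labels) -> float:
    scores, labels = _validate_scores_labels(scores, labels)
    _, v10, v01 = _structural_components(scores, labels)
    return float(np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size)


def auc_ci_delong(scores, labels, alpha: float = 0.05) -> tuple[float, float, float]:
    """(auc, lower, upper) with a DeLong Wald interval clipped to [0, 1]."""
    scores, labels = _validate_scores_labels(scores, labels)
    auc = _midrank_auc(scores, labels)
    se = float(np.sqrt(delong_auc_variance(scores, labels)))
    zq = stats.norm.ppf(1 - alpha / 2)
    return float(auc), max(0.0, auc - zq * se), min(1.0, auc + zq * se)


@dataclass(frozen=True)
class DeLongComparison:
    auc1: float
    auc2: float
    diff: float
    diff_ci95: tuple[float, float]
    z: float
    p: float


def delong_test(scores1, scores2, labels) -> DeLongComparison:
    """Paired comparison of two correlated AUCs (DeLong's test).

    Both score vectors must cover the same patients in the same order.
    """
    scores1 = np.asarray(scores1, dtype=float)
    scores2 = np.asarray(scores2, dtype=float)
    if scores1.shape != scores2.shape:
        raise ValueError("scores1 and scores2 must be paired (same length)")
    scores1, labels = _validate_scores_labels(scores1, labels)

    auc1, v10_1, v01_1 = _structural_components(scores1, labels)
    auc2, v10_2, v01_2 = _structural_components(scores2, labels)
    m, n = v10_1.size, v01_1.size
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    cov = s10 / m + s01 / n
    diff = auc1 - auc2
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    se = np.sqrt(max(var, 0.0))
    if se > 0:
        z = diff / se
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    zq = 1.959963984540054
    return DeLongComparison(
        auc1=float(auc1),
        auc2=float(auc2),
        diff=float(diff),
        diff_ci95=(float(diff - zq * se), float(diff + zq * se)),
        z=float(z),
        p=float(p),
    )


# ---------------------------------------------------------------------------
# Reliability (ICC + Bland-Altman)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReliabilityReport:
    icc: float
    icc_ci95: tuple[float, float]
    bias: float
    loa_low: float
    loa_high: float
    n: int


def icc_two_rater(x1, x2, alpha: float = 0.05) -> ReliabilityReport:
    """ICC(2,1) — two-way random effects, absolute agreement, single rater —
    with an F-based 95% CI, plus Bland-Altman bias and limits of agreement.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("x1 and x2 must be paired 1-D arrays")
    n = x1.size
    if n < 3:
        raise ValueError("need at least 3 paired measurements")
    data = np.column_stack([x1, x2])
    k = 2
    if np.ptp(data) == 0:
        raise ValueError("zero total variance: ICC undefined")

    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_rater = n * ((rater_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_rater
    msr = ss_subj / (n - 1)
    msc = ss_rater / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # McGraw & Wong CI for ICC(A,1)
    fj = msc / mse if mse > 0 else np.inf
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and mse > 0:
        v_num = (a * msc + b * mse) ** 2
        v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = v_num / v_den
        f_star1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_star2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_star1 * mse) / (
            f_star1 * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_star2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_star2 * msr
        )
    else:
        lo = hi = icc
    del fj

    diffs = x1 - x2
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return ReliabilityReport(
        icc=float(icc),
        icc_ci95=(float(lo), float(hi)),
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=n,
    )


# ---------------------------------------------------------------------------
# Group comparison tables
# ---------------------------------------------------------------------------


def group_tests(
    table: pd.DataFrame,
    labels,
    categorical: list[str] | None = None,
    yates_correction: bool = False,
) -> pd.DataFrame:
    """Baseline-characteristics comparison between the two label groups.

    Continuous columns: median (IQR) per group and a Mann-Whitney U p value
    (exact when both groups have n <= 8 and no ties, normal approximation
    with tie correction otherwise). Categorical columns: counts (percent)
    and a chi-squared p value (Yates correction off by default).
    """
    labels = np.asarray(labels).astype(int)
    if len(table) != labels.size:
        raise ValueError("table and labels must have matching length")
    categorical = list(categorical or [])
    g0 = table[labels == 0]
    g1 = table[labels == 1]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("both groups must be nonempty")

    rows = []
    for col in table.columns:
        if col in categorical:
            ct = pd.crosstab(table[col], labels)
            if ct.shape[0] < 2:
                p = 1.0
            else:
                expected = stats.contingency.expected_freq(ct.to_numpy())
                if (expected < 1).any():
                    warnings.warn(
                        f"column {col!r}: chi-squared expected cell < 1", stacklevel=2
                    )
                p = stats.chi2_contingency(ct.to_numpy(), correction=yates_correction)[1]
            pos_rate1 = float(np.mean(g1[col].to_numpy() == ct.index.max()))
            pos_rate0 = float(np.mean(g0[col].to_numpy() == ct.index.max()))
            rows.append(
                {
                    "variable": col,
                    "kind": "categorical",
                    "group0": pos_rate0,
                    "group1": pos_rate1,
                    "group0_iqr": (np.nan, np.nan),
                    "group1_iqr": (np.nan, np.nan),
                    "p": float(p),
                    "test": "chi2",
                }
            )
        else:
            a = g0[col].to_numpy(dtype=float)
            b = g1[col].to_numpy(dtype=float)
            method = "exact" if (a.size <= 8 and b.size <= 8) else "asymptotic"
            try:
                p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)[1]
            except ValueError:  # ties under exact -> fall back
                p = stats.mannwhitneyu(
                    a, b, alternative="two-sided", method="asymptotic"
                )[1]
            rows.append(
                {
                    "variable": col,
                    "kind": "continuous",
                    "group0": float(np.median(a)),
                    "group1": float(np.median(b)),
                    "group0_iqr": (float(np.percentile(a, 25)), float(np.percentile(a, 75))),
                    "group1_iqr": (float(np.percentile(b, 25)), float(np.percentile(b, 75))),
                    "p": float(p),
                    "test": "mannwhitneyu",
                }
            )
    return pd.DataFrame(rows).set_index("variable")
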