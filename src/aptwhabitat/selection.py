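"""Feature-selection cascade producing the linear radiomic score:

ICC filter -> z-scoring -> Welch t-test -> greedy correlation pruning ->
mRMR -> L1-penalized logistic regression with 10-fold CV over a lambda grid.

Every stage exposes fit-time state so the whole cascade can be refit inside
outer cross-validation folds (leakage contract); ``SelectionCascade`` bundles
that for the modeling layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .evaluation import icc_two_rater

__all__ = [
    "SelectionConfig",
    "SelectionReport",
    "icc_filter",
    "ttest_filter",
    "correlation_prune",
    "mrmr_select",
    "lasso_score",
    "compare_selected_features",
    "SelectionCascade",
]


@dataclass(frozen=True)
class SelectionConfig:
    icc_min: float = 0.85
    p_max: float = 0.05
    corr_max: float = 0.9
    mrmr_k: int = 30
    lasso_folds: int = 10
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.icc_min <= 1:
            raise ValueError("icc_min must lie in (0, 1]")
        if not 0 < self.p_max < 1:
            raise ValueError("p_max must lie in (0, 1)")
        if self.lasso_folds < 2:
            raise ValueError("need at least 2 CV folds")


@dataclass
class SelectionReport:
    surviving_per_stage: list[tuple[str, list[str]]]
    final_features: list[str]
    coefficients: np.ndarray
    intercept: float
    lambda_opt: float
    zscore_mean: pd.Series
    zscore_std: pd.Series

    def __post_init__(self):
        counts = [len(names) for _, names in self.surviving_per_stage]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("stage survivor counts must be non-increasing")
        if np.any(self.coefficients == 0):
            raise ValueError("final coefficients must all be nonzero")

    @property
    def stage_counts(self) -> dict[str, int]:
        return {name: len(cols) for name, cols in self.surviving_per_stage}

    def score(self, table: pd.DataFrame) -> pd.Series:
        """Radiomic score = intercept + sum(coef_i * z-scored feature_i)."""
        z = (table[self.final_features] - self.zscore_mean[self.final_features]) / (
            self.zscore_std[self.final_features]
        )
        return pd.Series(
            self.intercept + z.to_numpy() @ self.coefficients,
            index=table.index,
            name="radiomic_score",
        )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def icc_filter(
    table_reader1: pd.DataFrame, table_reader2: pd.DataFrame, icc_min: float = 0.85
) -> list[str]:
    """Columns whose two-rater ICC(2,1) is >= icc_min; zero-variance columns
    are dropped with a warning."""
    if list(table_reader1.columns) != list(table_reader2.columns):
        raise ValueError("reader tables must share identical columns")
    if len(table_reader1) != len(table_reader2):
        raise ValueError("reader tables must cover the same patients")
    x1 = table_reader1.to_numpy(dtype=float)
    x2 = table_reader2.to_numpy(dtype=float)
    n = x1.shape[0]
    k = 2.0
    # vectorized two-way ANOVA mean squares, per column
    grand = (x1 + x2).mean(axis=0) / k
    subj_mean = (x1 + x2) / k
    ss_subj = k * ((subj_mean - grand) ** 2).sum(axis=0)
    ss_rater = n * ((x1.mean(axis=0) - grand) ** 2 + (x2.mean(axis=0) - grand) ** 2)
    ss_total = ((x1 - grand) ** 2 + (x2 - grand) ** 2).sum(axis=0)
    ss_err = ss_total - ss_subj - ss_rater
    msr = ss_subj / (n - 1)
    msc = ss_rater / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    degenerate = np.ptp(np.vstack([x1, x2]), axis=0) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = np.where(denom > 0, (msr - mse) / denom, np.nan)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance features dropped (ICC undefined)",
            stacklevel=2,
        )
    keep_mask = ~degenerate & np.isfinite(icc) & (icc >= icc_min)
    return [c for c, m in zip(table_reader1.columns, keep_mask) if m]


def _welch_p(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized per-column Welch t-test p values."""
    a = x[labels == 1]
    b = x[labels == 0]
    return stats.ttest_ind(a, b, axis=0, equal_var=False).pvalue


def ttest_filter(table: pd.DataFrame, labels, p_max: float = 0.05) -> list[str]:
    labels = np.asarray(labels).astype(int)
    if min((labels == 0).sum(), (labels == 1).sum()) < 2:
        raise ValueError("each class needs at least 2 members for the t-test")
    p = _welch_p(table.to_numpy(dtype=float), labels)
    return [c for c, pv in zip(table.columns, p) if np.isfinite(pv) and pv < p_max]


def correlation_prune(table: pd.DataFrame, labels, corr_max: float = 0.9) -> list[str]:
    """Greedy elimination: while some pair has |r| > corr_max, take the most
    correlated pair and drop the member with the weaker class association
    (larger Welch p; ties -> lexicographically later name)."""
    cols = list(table.columns)
    if len(cols) < 2:
        return cols
    labels = np.asarray(labels).astype(int)
    X = table.to_numpy(dtype=float)
    p = _welch_p(X, labels)
    p = np.where(np.isfinite(p), p, 1.0)
    corr = np.abs(np.corrcoef(X, rowvar=False))
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)
    alive = np.ones(len(cols), dtype=bool)
    while True:
        flat = int(np.argmax(corr))
        if corr.flat[flat] <= corr_max:
            break
        i, j = np.unravel_index(flat, corr.shape)
        pa, pb = p[i], p[j]
        if pa > pb:
            drop = i
        elif pb > pa:
            drop = j
        else:  # tie -> lexicographically later name
            drop = i if cols[i] > cols[j] else j
        alive[drop] = False
        corr[drop, :] = 0.0
        corr[:, drop] = 0.0
    return [c for c, a in zip(cols, alive) if a]


def mrmr_select(table: pd.DataFrame, labels, k: int) -> list[str]:
    """Greedy mRMR (difference form): at each step pick the feature maximizing
    F-statistic relevance minus mean |Pearson r| redundancy with the already
    selected set."""
    if k <= 0:
        raise ValueError("k must be positive")
    cols = list(table.columns)
    k = min(k, len(cols))
    labels = np.asarray(labels).astype(int)
    X = table.to_numpy(dtype=float)

    a = X[labels == 1]
    b = X[labels == 0]
    f_stat = stats.f_oneway(a, b, axis=0).statistic
    f_stat = np.where(np.isfinite(f_stat), f_stat, 0.0)
    corr = np.abs(np.corrcoef(X, rowvar=False))
    corr = np.nan_to_num(corr, nan=1.0)

    selected: list[int] = []
    remaining = list(range(len(cols)))
    for _ in range(k):
        if selected:
            redundancy = corr[np.ix_(remaining, selected)].mean(axis=1)
        else:
            redundancy = np.zeros(len(remaining))
        score = f_stat[remaining] - redundancy
        best = int(np.argmax(score))  # first maximizer -> deterministic
        selected.append(remaining.pop(best))
    return [cols[i] for i in selected]


def _lambda_max_logistic(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest lambda that zeroes every coefficient of the L1 logistic fit
    (objective (1/n) * logloss + lambda * ||b||_1)."""
    resid = y - y.mean()
    return float(np.abs(X.T @ resid).max() / X.shape[0])


def lasso_score(
    table: pd.DataFrame,
    labels,
    folds: int = 10,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-4,
    seed: int = 0,
    prior_stages: list[tuple[str, list[str]]] | None = None,
    zscore_mean: pd.Series | None = None,
    zscore_std: pd.Series | None = None,
) -> SelectionReport:
    """L1-penalized logistic regression over a geometric lambda grid; lambda
    chosen by maximum mean CV log-likelihood; nonzero-coefficient features
    and their coefficients define the radiomic score."""
    labels = np.asarray(labels).astype(int)
    n = len(table)
    if min((labels == 0).sum(), (labels == 1).sum()) < folds:
        raise ValueError("need at least `folds` patients per class")
    if zscore_mean is None:
        zscore_mean = table.mean(axis=0)
        zscore_std = table.std(axis=0, ddof=0).replace(0.0, 1.0)
    Z = ((table - zscore_mean) / zscore_std).to_numpy(dtype=float)

    lam_max = _lambda_max_logistic(Z, labels)
    if lam_max <= 0:
        lam_max = 1.0
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(Z, labels))
    cv_ll = np.zeros((len(lambdas), folds))
    for fi, (tr, va) in enumerate(splits):
        for li, lam in enumerate(lambdas):
            clf = _l1_logistic(Z[tr], labels[tr], lam)
            p = clf.predict_proba(Z[va])[:, 1]
            p = np.clip(p, 1e-12, 1 - 1e-12)
            cv_ll[li, fi] = np.mean(
                labels[va] * np.log(p) + (1 - labels[va]) * np.log(1 - p)
            )
    mean_ll = cv_ll.mean(axis=1)
    li_opt = int(np.argmax(mean_ll))  # ties -> largest lambda (sparser model)
    lam_opt = float(lambdas[li_opt])

    clf = _l1_logistic(Z, labels, lam_opt)
    coef = clf.coef_.ravel()
    nz = np.flatnonzero(coef != 0)
    final = [table.columns[i] for i in nz]
    stages = list(prior_stages or [])
    stages.append(("lasso", final))
    if len(final) == 0:
        raise EmptySelectionError(
            "all LASSO coefficients are zero at the optimal lambda; "
            "no radiomic score can be formed"
        )
    return SelectionReport(
        surviving_per_stage=stages,
        final_features=final,
        coefficients=coef[nz],
        intercept=float(clf.intercept_[0]),
        lambda_opt=lam_opt,
        zscore_mean=zscore_mean,
        zscore_std=zscore_std,
    )


def lasso_linear_cd(
    X: np.ndarray, y: np.ndarray, lam: float, max_iter: int = 10_000, tol: float = 1e-12
) -> np.ndarray:
    """Cyclic coordinate descent for (1/2)||y - Xb||^2 + lam * ||b||_1.

    On an orthonormal design the solution is the soft-thresholded OLS
    estimate, which the tests use as a closed-form oracle.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    col_sq = (X**2).sum(axis=0)
    b = np.zeros(p)
    r = y.copy()
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            if col_sq[j] == 0:
                continue
            rho = X[:, j] @ r + col_sq[j] * b[j]
            new = np.sign(rho) * max(abs(rho) - lam, 0.0) / col_sq[j]
            if new != b[j]:
                r += X[:, j] * (b[j] - new)
                max_delta = max(max_delta, abs(new - b[j]))
                b[j] = new
        if max_delta < tol:
            break
    return b


class EmptySelectionError(RuntimeError):
    """Raised when the LASSO step selects no features; downstream modeling
    must fail loudly rather than silently fall back."""


def _l1_logistic(X: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    # liblinear minimizes C * logloss + ||b||_1  =>  C = 1 / (n * lambda)
    C = 1.0 / (X.shape[0] * lam)
    return LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", max_iter=1000, tol=1e-6, random_state=0
    ).fit(X, y)


def compare_selected_features(
    table: pd.DataFrame, labels, final_features: list[str]
) -> pd.DataFrame:
    """Per-selected-feature group means and Welch t-test p values."""
    if not final_features:
        raise ValueError("empty selection")
    labels = np.asarray(labels).astype(int)
    sub = table[final_features]
    p = _welch_p(sub.to_numpy(dtype=float), labels)
    return pd.DataFrame(
        {
            "mean_neg": sub[labels == 0].mean(axis=0),
            "mean_pos": sub[labels == 1].mean(axis=0),
            "p": p,
        }
    )


# ---------------------------------------------------------------------------
# the full cascade
# ---------------------------------------------------------------------------


@dataclass
class SelectionCascade:
    """Fit-on-training-only wrapper around the full cascade.

    ``reader2_table`` (when given) must cover at least the training patients;
    the ICC stage is evaluated on training rows only.
    """

    config: SelectionConfig = field(default_factory=SelectionConfig)
    report: SelectionReport | None = None

    def fit(
        self,
        table: pd.DataFrame,
        labels,
        reader2_table: pd.DataFrame | None = None,
    ) -> "SelectionCascade":
        cfg = self.config
        labels = np.asarray(labels).astype(int)
        work = table.dropna(axis=1)
        stages: list[tuple[str, list[str]]] = [("input", list(work.columns))]

        if reader2_table is not None:
            r2 = reader2_table.loc[work.index, work.columns]
            cols = icc_filter(work, r2, cfg.icc_min)
            stages.append(("icc", cols))
            work = work[cols]

        mean = work.mean(axis=0)
        std = work.std(axis=0, ddof=0).replace(0.0, 1.0)
        z = (work - mean) / std

        cols = ttest_filter(z, labels, cfg.p_max)
        stages.append(("ttest", cols))
        z = z[cols]

        cols = correlation_prune(z, labels, cfg.corr_max)
        stages.append(("correlation_prune", cols))
        z = z[cols]

        cols = mrmr_select(z, labels, cfg.mrmr_k)
        stages.append(("mrmr", cols))
        z = z[cols]

        self.report = lasso_score(
            work[cols],
            labels,
            folds=min(cfg.lasso_folds, int(np.bincount(labels).min())),
            n_lambdas=cfg.n_lambdas,
            lambda_min_ratio=cfg.lambda_min_ratio,
            seed=cfg.seed,
            prior_stages=stages,
            zscore_mean=mean[cols],
            zscore_std=std[cols],
        )
        return self

    def score(self, table: pd.DataFrame) -> pd.Series:
        if self.report is None:
            raise RuntimeError("cascade not fitted")
        return self.report.score(table)
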