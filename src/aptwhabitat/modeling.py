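"""The three logistic models (clinical-radiological, radiomic-score,
combined) under stratified 5-fold nested cross-validation, plus the
univariable/multivariable association analysis.

The radiomic score used by the ``aptw_h3`` and ``combined`` models is refit
inside every outer training fold via the full selection cascade, so no
held-out information reaches any preprocessing step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .evaluation import roc_auc
from .selection import EmptySelectionError, SelectionCascade, SelectionConfig

__all__ = [
    "ModelSpec",
    "CVResult",
    "AssociationReport",
    "MODEL_NAMES",
    "fit_cv",
    "association_analysis",
]

MODEL_NAMES = ("clinical_radiological", "aptw_h3", "combined")

_CLINICAL_PREDICTORS = ["ca125", "tumor_size"]
_L2_GRID = (1e-2, 1e-1, 1.0, 10.0, 1e4)  # 1e4 ~ effectively unpenalized


@dataclass(frozen=True)
class ModelSpec:
    name: str
    seed: int = 0
    l2_grid: tuple[float, ...] = _L2_GRID

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(f"model name must be one of {MODEL_NAMES}")

    @property
    def uses_clinical(self) -> bool:
        return self.name in ("clinical_radiological", "combined")

    @property
    def uses_score(self) -> bool:
        return self.name in ("aptw_h3", "combined")


@dataclass
class CVResult:
    model: str
    fold_auc: np.ndarray
    fold_accuracy: np.ndarray
    fold_f1: np.ndarray
    oof_probability: pd.Series  # pooled out-of-fold probabilities
    fold_assignment: pd.Series
    chosen_C: list[float]

    @property
    def mean_auc(self) -> float:
        return float(self.fold_auc.mean())

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracy.mean())

    @property
    def mean_f1(self) -> float:
        return float(self.fold_f1.mean())


def _stratified_folds(labels: np.ndarray, n_splits: int, seed: int, index) -> list:
    """Fold assignment as a pure function of (patient ids, labels, seed):
    rows are ordered by patient id before splitting, so row order in the
    caller's table cannot change the folds."""
    order = np.argsort(np.asarray(index))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = []
    for tr, va in skf.split(np.zeros(len(labels)), labels[order]):
        splits.append((order[tr], order[va]))
    return splits


def _inner_tune(X: np.ndarray, y: np.ndarray, grid, seed: int, folds: int = 3) -> float:
    """Inner CV over the L2 strength grid; returns the best C by mean AUC."""
    best_c, best_score = grid[0], -np.inf
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for C in grid:
        aucs = []
        for tr, va in skf.split(X, y):
            clf = LogisticRegression(C=C, max_iter=5000).fit(X[tr], y[tr])
            p = clf.predict_proba(X[va])[:, 1]
            if np.unique(y[va]).size < 2:
                continue
            aucs.append(roc_auc(p, y[va]).auc)
        score = np.mean(aucs) if aucs else -np.inf
        if score > best_score:
            best_score, best_c = score, C
    return best_c


def _design(
    spec: ModelSpec,
    clinical: pd.DataFrame,
    score: pd.Series | None,
    rows,
) -> np.ndarray:
    parts = []
    if spec.uses_clinical:
        parts.append(clinical.loc[rows, _CLINICAL_PREDICTORS].to_numpy(dtype=float))
    if spec.uses_score:
        parts.append(score.loc[rows].to_numpy(dtype=float)[:, None])
    return np.hstack(parts)


def fit_cv(
    spec: ModelSpec,
    clinical: pd.DataFrame,
    labels: pd.Series,
    feature_table: pd.DataFrame | None = None,
    reader2_table: pd.DataFrame | None = None,
    selection_config: SelectionConfig | None = None,
    folds: int = 5,
) -> CVResult:
    """Outer stratified K-fold CV with inner hyperparameter tuning; all
    scaling and feature selection are fit on outer-training rows only.

    ``clinical`` must carry columns ca125 and tumor_size indexed by patient;
    ``feature_table`` (same index) is required for models using the radiomic
    score.
    """
    y = np.asarray(labels).astype(int)
    if min(np.bincount(y)) < folds:
        raise ValueError("need at least `folds` patients in each class")
    if spec.uses_score and feature_table is None:
        raise ValueError(f"model {spec.name!r} requires a radiomic feature table")

    index = clinical.index
    splits = _stratified_folds(y, folds, spec.seed, index)
    oof = pd.Series(np.nan, index=index, dtype=float)
    fold_of = pd.Series(-1, index=index, dtype=int)
    fold_auc, fold_acc, fold_f1, chosen = [], [], [], []

    for fold_id, (tr, va) in enumerate(splits):
        tr_ids, va_ids = index[tr], index[va]
        score = None
        if spec.uses_score:
            cascade = SelectionCascade(config=selection_config or SelectionConfig())
            try:
                cascade.fit(
                    feature_table.loc[tr_ids],
                    y[tr],
                    reader2_table=reader2_table.loc[tr_ids]
                    if reader2_table is not None
                    else None,
                )
                score = cascade.score(feature_table)
            except EmptySelectionError:
                # legitimate null outcome inside a fold: the honest prediction
                # is an uninformative constant score
                warnings.warn(
                    f"fold {fold_id}: empty LASSO selection, using constant score",
                    stacklevel=2,
                )
                score = pd.Series(0.0, index=feature_table.index)
        X_tr = _design(spec, clinical, score, tr_ids)
        X_va = _design(spec, clinical, score, va_ids)
        scaler = StandardScaler().fit(X_tr)
        X_tr = scaler.transform(X_tr)
        X_va = scaler.transform(X_va)

        C = _inner_tune(X_tr, y[tr], spec.l2_grid, spec.seed)
        chosen.append(C)
        clf = LogisticRegression(C=C, max_iter=5000).fit(X_tr, y[tr])
        p = clf.predict_proba(X_va)[:, 1]
        oof.iloc[va] = p
        fold_of.iloc[va] = fold_id
        fold_auc.append(roc_auc(p, y[va]).auc)
        pred = (p >= 0.5).astype(int)
        fold_acc.append(float((pred == y[va]).mean()))
        fold_f1.append(float(f1_score(y[va], pred, zero_division=0.0)))

    assert not oof.isna().any()  # every patient out-of-fold exactly once
    return CVResult(
        model=spec.name,
        fold_auc=np.array(fold_auc),
        fold_accuracy=np.array(fold_acc),
        fold_f1=np.array(fold_f1),
        oof_probability=oof,
        fold_assignment=fold_of,
        chosen_C=chosen,
    )


# ---------------------------------------------------------------------------
# association analysis
# ---------------------------------------------------------------------------


@dataclass
class AssociationReport:
    univariable: pd.DataFrame
    multivariable: pd.DataFrame

    def __post_init__(self):
        sig = set(self.univariable.index[self.univariable["p"] < 0.05])
        if set(self.multivariable.index) != sig:
            raise ValueError(
                "multivariable model must contain exactly the univariable-"
                "significant variables"
            )


def _logit_or_table(X: pd.DataFrame, y: np.ndarray) -> pd.DataFrame:
    exog = sm.add_constant(X.to_numpy(dtype=float))
    rows = []
    try:
        fit = sm.Logit(y, exog).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", True))
        for i, name in enumerate(X.columns, start=1):
            coef = fit.params[i]
            se = fit.bse[i]
            rows.append(
                {
                    "variable": name,
                    "or": float(np.exp(coef)),
                    "ci_low": float(np.exp(coef - 1.959963984540054 * se)),
                    "ci_high": float(np.exp(coef + 1.959963984540054 * se)),
                    "p": float(fit.pvalues[i]),
                    "converged": converged,
                }
            )
    except Exception as exc:  # perfect separation etc.
        warnings.warn(f"logistic fit failed for {list(X.columns)}: {exc}", stacklevel=2)
        for name in X.columns:
            rows.append(
                {"variable": name, "or": np.nan, "ci_low": np.nan,
                 "ci_high": np.nan, "p": np.nan, "converged": False}
            )
    return pd.DataFrame(rows).set_index("variable")


def association_analysis(
    cohort_table: pd.DataFrame,
    label_col: str = "lvsi",
    variables: list[str] | None = None,
) -> AssociationReport:
    """Univariable logistic fits per variable; variables with p < 0.05 enter
    one multivariable fit. ORs are exponentiated coefficients with Wald CIs.
    """
    variables = variables or [
        c for c in ("age", "bmi", "ca125", "tumor_size", "radiomic_score")
        if c in cohort_table.columns
    ]
    y = cohort_table[label_col].to_numpy(dtype=int)
    uni = pd.concat([_logit_or_table(cohort_table[[v]], y) for v in variables])
    sig = [v for v in variables if np.isfinite(uni.loc[v, "p"]) and uni.loc[v, "p"] < 0.05]
    if sig:
        multi = _logit_or_table(cohort_table[sig], y)
    else:
        multi = uni.iloc[0:0].copy()
    return AssociationReport(univariable=uni, multivariable=multi)
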