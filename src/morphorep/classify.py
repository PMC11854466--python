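"""Classifier-agnostic evaluation harness for HC-vs-IBS prediction.

Any object exposing ``fit(X, y)`` and ``predict_proba(X)`` plugs in; the repo
ships a regularized-logistic reference model and an optional gradient-boosted
trees plug-in.  The positive class is IBS (coded 1) and the default decision
threshold is 0.5, with probabilities exactly at the threshold classified as
IBS.  Preprocessing (train-mean imputation + standardization) is always
fitted on the training partition only and applied to both partitions, so no
information leaks from test to train.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .io_tables import SubjectTable

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "SplitSpec",
    "ImportanceRecord",
    "EvaluationResult",
    "reference_classifier",
    "xgboost_classifier",
    "stratified_split",
    "make_preprocessor",
    "preprocess",
    "metrics_from_counts",
    "auc_rank",
    "evaluate",
    "cross_validate",
    "permutation_importance",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with IBS as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class MetricReport:
    """The 11-metric confusion-matrix suite plus chance-corrected agreement.

    Ratios with a zero denominator are NaN (undefined), never silently 0.
    """

    tpr: float
    tnr: float
    ppv: float
    npv: float
    fpr: float
    fnr: float
    fdr: float
    acc: float
    bacc: float
    f1: float
    mcc: float
    kappa: float = float("nan")
    auc: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def __getitem__(self, name: str) -> float:
        return self.as_dict()[name]


@dataclass(frozen=True)
class SplitSpec:
    """Evaluation design: stratified 70/30 split and stratified 10-fold CV."""

    test_fraction: float = 0.30
    cv_folds: int = 10
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass(frozen=True)
class ImportanceRecord:
    feature: str
    mean_drop: float
    sd_drop: float
    n_repeats: int


@dataclass
class EvaluationResult:
    counts: ConfusionCounts
    report: MetricReport
    predictions: pd.DataFrame = field(repr=False)


def reference_classifier(seed: int = 0) -> LogisticRegression:
    """The shipped reference model: L2-regularized logistic regression."""
    return LogisticRegression(C=1.0, max_iter=2000, random_state=seed)


def xgboost_classifier(seed: int = 0):
    """Optional gradient-boosted trees plug-in (requires xgboost)."""
    from xgboost import XGBClassifier

    return XGBClassifier(
        n_estimators=200, max_depth=3, learning_rate=0.1,
        random_state=seed, eval_metric="logloss",
    )


def stratified_split(table: SubjectTable, spec: SplitSpec) -> tuple[SubjectTable, SubjectTable]:
    """Stratified train/test partition preserving the HC/IBS mix.

    Class proportions in each partition stay within one subject of the global
    proportion; the partition is reproducible from ``spec.seed``.
    """
    sizes = table.group_sizes()
    if min(sizes.values()) < 2:
        raise ValueError(f"every class needs >= 2 members, got {sizes}")
    idx = np.arange(len(table))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=spec.test_fraction,
        stratify=table.labels,
        random_state=spec.seed,
    )
    return table.subset(np.sort(train_idx)), table.subset(np.sort(test_idx))


def make_preprocessor() -> Pipeline:
    """Train-mean imputation followed by standardization to zero mean, unit SD."""
    return Pipeline([
        ("impute", SimpleImputer(strategy="mean")),
        ("scale", StandardScaler()),
    ])


def preprocess(
    train_X: pd.DataFrame, test_X: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, Pipeline]:
    """Fit imputation/scaling on train only; transform both partitions.

    Constant training features pass through unscaled (unit divisor) with a
    warning; an all-missing feature is an error.
    """
    if train_X.isna().all().any():
        bad = list(train_X.columns[train_X.isna().all()])
        raise ValueError(f"features entirely missing in training data: {bad}")
    constant = list(train_X.columns[train_X.nunique(dropna=True) <= 1])
    if constant:
        warnings.warn(f"constant training features left unscaled: {constant}")
    prep = make_preprocessor()
    Xtr = prep.fit_transform(train_X)
    Xte = prep.transform(test_X)
    return Xtr, Xte, prep


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return float("nan")
    return num / den


def metrics_from_counts(c: ConfusionCounts) -> MetricReport:
    """Compute the full metric suite from 2x2 counts.

    mcc = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)); kappa is the
    chance-corrected observed agreement.  Identities tpr+fnr = 1,
    tnr+fpr = 1, ppv+fdr = 1 and bacc = (tpr+tnr)/2 hold whenever defined.
    """
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fn, tn, fp = c.tp, c.fn, c.tn, c.fp
    tpr = _safe_ratio(tp, tp + fn, "TPR")
    tnr = _safe_ratio(tn, tn + fp, "TNR")
    ppv = _safe_ratio(tp, tp + fp, "PPV")
    npv = _safe_ratio(tn, tn + fn, "NPV")
    acc = (tp + tn) / c.total
    bacc = (tpr + tnr) / 2
    f1 = _safe_ratio(2 * tp, 2 * tp + fp + fn, "F1")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_ratio(tp * tn - fp * fn, mcc_den, "MCC")
    # chance agreement from the marginals
    p_yes = ((tp + fp) / c.total) * ((tp + fn) / c.total)
    p_no = ((tn + fn) / c.total) * ((tn + fp) / c.total)
    pe = p_yes + p_no
    kappa = _safe_ratio(acc - pe, 1 - pe, "kappa") if pe != 1 else float("nan")
    return MetricReport(
        tpr=tpr, tnr=tnr, ppv=ppv, npv=npv,
        fpr=1 - tnr, fnr=1 - tpr, fdr=1 - ppv,
        acc=acc, bacc=bacc, f1=f1, mcc=mcc, kappa=kappa,
    )


def auc_rank(y_true, scores) -> float:
    """ROC-AUC via the rank (Mann-Whitney) identity U / (n1 n0), ties as 0.5."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    if pos.size == 0 or neg.size == 0:
        return float("nan")
    ranks = pd.Series(np.concatenate([pos, neg])).rank().to_numpy()
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def _counts_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    return ConfusionCounts(
        tp=int(((y_pred == 1) & (y_true == 1)).sum()),
        fn=int(((y_pred == 0) & (y_true == 1)).sum()),
        tn=int(((y_pred == 0) & (y_true == 0)).sum()),
        fp=int(((y_pred == 1) & (y_true == 0)).sum()),
    )


def _probabilities(model, X: np.ndarray) -> np.ndarray:
    proba = np.asarray(model.predict_proba(X))[:, 1]
    if ((proba < 0) | (proba > 1)).any() or np.isnan(proba).any():
        raise ValueError("classifier contract violation: probabilities outside [0, 1]")
    return proba


def evaluate(
    classifier,
    table: SubjectTable,
    features: list[str],
    spec: SplitSpec | None = None,
) -> EvaluationResult:
    """Train on the stratified train split, score the held-out test split.

    Per-subject probabilities and predicted classes are retained alongside
    subject metadata (sex, age, severity) for subgroup summaries.
    """
    spec = spec or SplitSpec()
    train, test = stratified_split(table, spec)
    Xtr, Xte, _ = preprocess(train.features(features), test.features(features))
    model = clone(classifier)
    model.fit(Xtr, train.labels)
    proba = _probabilities(model, Xte)
    y_pred = (proba >= spec.threshold).astype(int)  # proba == threshold -> IBS
    y_true = test.labels
    counts = _counts_from_predictions(y_true, y_pred)
    report = metrics_from_counts(counts)
    report = MetricReport(**{**report.as_dict(), "auc": auc_rank(y_true, proba)})
    meta = [c for c in ("subject_id", "group", "sex", "age", "ibs_sss") if c in test.data]
    preds = test.data[meta].copy()
    preds["probability"] = proba
    preds["predicted"] = y_pred
    return EvaluationResult(counts=counts, report=report, predictions=preds)


def cross_validate(
    classifier,
    table: SubjectTable,
    features: list[str],
    spec: SplitSpec | None = None,
) -> tuple[list[MetricReport], MetricReport]:
    """Stratified k-fold CV with fold-internal preprocessing (leakage-safe).

    Returns per-fold reports and the macro average (unweighted mean of the
    per-fold metrics, NaN-skipping).
    """
    spec = spec or SplitSpec()
    sizes = table.group_sizes()
    minority = min(sizes.values())
    if minority == 0:
        raise ValueError("both classes must be present for cross-validation")
    if spec.cv_folds > minority:
        raise ValueError(
            f"cv_folds={spec.cv_folds} exceeds minority class size {minority}; use fewer folds"
        )
    skf = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    X = table.features(features)
    y = table.labels
    reports: list[MetricReport] = []
    for train_idx, test_idx in skf.split(X, y):
        Xtr, Xte, _ = preprocess(X.iloc[train_idx], X.iloc[test_idx])
        model = clone(classifier)
        model.fit(Xtr, y[train_idx])
        proba = _probabilities(model, Xte)
        y_pred = (proba >= spec.threshold).astype(int)
        counts = _counts_from_predictions(y[test_idx], y_pred)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # small folds routinely empty a margin
            rep = metrics_from_counts(counts)
            rep = MetricReport(**{**rep.as_dict(), "auc": auc_rank(y[test_idx], proba)})
        reports.append(rep)
    agg = MetricReport(**{
        k: float(np.nanmean([r.as_dict()[k] for r in reports]))
        for k in reports[0].as_dict()
    })
    return reports, agg


def permutation_importance(
    model,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
    metric: str = "acc",
    n_repeats: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> list[ImportanceRecord]:
    """Model-agnostic importance: metric drop under within-column shuffles.

    ``model`` must already be fitted on (preprocessed) data commensurate with
    ``X_test``.  For each feature the named MetricReport entry is recomputed
    after independently shuffling that column, ``n_repeats`` times; records
    are ranked by mean drop, descending.  Deterministic given ``seed``.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")

    def score(Xmat: np.ndarray) -> float:
        proba = _probabilities(model, Xmat)
        if metric == "auc":
            return auc_rank(y_test, proba)
        y_pred = (proba >= threshold).astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = metrics_from_counts(_counts_from_predictions(y_test, y_pred))
        if metric not in rep.as_dict():
            raise KeyError(f"unknown metric {metric!r}; choose from {sorted(rep.as_dict())}")
        return rep[metric]

    X = np.asarray(X_test, dtype=float)
    columns = list(X_test.columns) if hasattr(X_test, "columns") else [
        f"feature_{i}" for i in range(X.shape[1])
    ]
    baseline = score(X)
    rng = np.random.default_rng(seed)
    records = []
    for j, name in enumerate(columns):
        drops = np.empty(n_repeats)
        for r in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops[r] = baseline - score(Xp)
        records.append(ImportanceRecord(
            feature=name,
            mean_drop=float(drops.mean()),
            sd_drop=float(drops.std(ddof=1)) if n_repeats > 1 else 0.0,
            n_repeats=n_repeats,
        ))
    records.sort(key=lambda rec: (-rec.mean_drop, rec.feature))
    return records
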