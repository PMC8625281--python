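"""Outcome-prediction models under repeated stratified cross-validation.

Four model specifications mirror the analysis design: a linear learner
(logistic regression, optionally with embedded LASSO selection) and a
nonlinear one (RBF-kernel SVM, optionally with Fisher-criterion feature
ranking plus an F1-driven feature-count search), each run on either the
three conventional covariates (age, baseline NIHSS, lesion volume; "p3") or
those plus all per-region ischemic percentages ("p4").

The protocol is k-fold stratified cross-validation with fresh random
partitions per repeat; feature selection, standardization and
hyperparameter choice all happen inside each training fold, and validation
predictions are pooled per repeat into one metric panel (accuracy,
sensitivity, specificity, PPV, NPV, Mann-Whitney AUC, F1). Per-metric
results are summarized as mean +/- SD over repeats. Repeat r uses seed
base_seed + r, so any single repeat is independently reproducible.

The positive class throughout is poor outcome (mRS 3-6), configurable via
``ModelSpec.positive_label``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

P3_FEATURES = ["age", "nihss", "volume_ml"]


class DegenerateFitError(ValueError):
    """Training data contain a single outcome class."""


class SingleClassError(ValueError):
    """AUC requested but only one class is present."""


class PairingError(ValueError):
    """Paired comparison requested for incompatible CV results."""


class NoSelectionError(ValueError):
    """Feature-selection report requested from a model without selection."""


@dataclass(frozen=True)
class ModelSpec:
    """One model specification.

    ``selector='lasso'`` is only valid with the logistic learner and
    ``selector='fscore_rank'`` only with the SVM, matching the analysis
    design. Hyperparameter grids are searched by inner stratified CV on the
    training fold; length-1 grids skip the search. ``gamma`` entries may be
    floats or the sklearn strings 'scale'/'auto'.
    """

    learner: str  # "logreg" | "svm_rbf"
    feature_set: str  # "p3" | "p4"
    selector: str = "none"
    lasso_c_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    svm_c_grid: tuple[float, ...] = tuple(2.0 ** k for k in range(-3, 8, 2))
    svm_gamma_grid: tuple = tuple(2.0 ** k for k in range(-7, 4, 2))
    inner_folds: int = 5
    max_curve_features: int | None = None
    curve_c: float = 1.0
    curve_gamma: float | str = "scale"
    positive_label: int = 1  # poor outcome
    threshold: float | None = None  # default 0.5 (logreg proba) / 0.0 (svm)

    def __post_init__(self):
        if self.learner not in ("logreg", "svm_rbf"):
            raise ValueError(f"unknown learner {self.learner!r}")
        if self.feature_set not in ("p3", "p4"):
            raise ValueError(f"unknown feature set {self.feature_set!r}")
        if self.selector not in ("none", "lasso", "fscore_rank"):
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.selector == "lasso" and self.learner != "logreg":
            raise ValueError("lasso selection requires the logistic learner")
        if self.selector == "fscore_rank" and self.learner != "svm_rbf":
            raise ValueError("fscore_rank selection requires the SVM learner")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")

    @property
    def name(self) -> str:
        return f"{'LogReg' if self.learner == 'logreg' else 'SVM'}-M{self.feature_set}"

    @property
    def decision_threshold(self) -> float:
        if self.threshold is not None:
            return self.threshold
        return 0.5 if self.learner == "logreg" else 0.0

    def desk_scale(self) -> "ModelSpec":
        """Reduced-search variant for single-CPU simulation studies: fixed
        SVM hyperparameters, a 3-point LASSO grid, 3 inner folds, and the
        feature curve capped at 25 candidates."""
        return replace(
            self,
            lasso_c_grid=(0.1, 1.0, 10.0),
            svm_c_grid=(1.0,),
            svm_gamma_grid=("scale",),
            inner_folds=3,
            max_curve_features=25,
        )


def default_specs(feature_sets: tuple[str, ...] = ("p3", "p4")) -> list[ModelSpec]:
    """The four analysis models: LogReg-Mp3/Mp4 and SVM-Mp3/Mp4."""
    specs = []
    for fs in feature_sets:
        specs.append(ModelSpec("logreg", fs, "lasso" if fs == "p4" else "none"))
        specs.append(ModelSpec("svm_rbf", fs, "fscore_rank" if fs == "p4" else "none"))
    return specs


@dataclass(frozen=True)
class MetricPanel:
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    auc: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "auc": self.auc,
            "f1": self.f1,
        }


@dataclass(frozen=True)
class FeatureCurve:
    """F1 vs number of ranked features, from inner cross-validation."""

    order: np.ndarray  # feature indices, best rank first
    train_f1: np.ndarray
    val_f1: np.ndarray
    selected_count: int


@dataclass
class CVResult:
    spec: ModelSpec
    panels: list[MetricPanel]
    feature_names: list[str]
    selection_counts: np.ndarray  # per feature, folds in which it was selected
    n_fold_fits: int
    folds: int
    repeats: int
    seed: int
    n_samples: int

    def per_repeat(self) -> pd.DataFrame:
        return pd.DataFrame([p.as_dict() for p in self.panels])

    def summary(self) -> pd.DataFrame:
        """Mean +/- SD over repeats; NaN cells (undefined ratios) are
        excluded with a warning noting how many."""
        df = self.per_repeat()
        n_nan = int(df.isna().sum().sum())
        if n_nan:
            warnings.warn(f"{n_nan} undefined metric cells excluded from mean/SD")
        return pd.DataFrame(
            {"mean": df.mean(), "sd": df.std(ddof=1) if len(df) > 1 else 0.0 * df.mean()}
        )

    def mean_metric(self, metric: str) -> float:
        return float(np.nanmean(self.per_repeat()[metric]))

    @property
    def partition_signature(self) -> tuple:
        return (self.folds, self.repeats, self.seed, self.n_samples)


def feature_columns(table: pd.DataFrame, feature_set: str) -> list[str]:
    pct = sorted(
        (c for c in table.columns if c.startswith("pct_")),
        key=lambda c: int(c.split("_", 1)[1]),
    )
    return list(P3_FEATURES) + (pct if feature_set == "p4" else [])


def fscore_rank(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rank features by the Fisher criterion, best first.

    F(j) = ((mean+_j - mean_j)^2 + (mean-_j - mean_j)^2) / (var+_j + var-_j)
    with sample variances within each class. A feature identical in both
    classes scores 0 and ranks last; a feature with zero within-class
    variance in both classes but differing means separates perfectly and is
    ranked by its between-class difference alone, with a warning. Ties break
    by feature index.

    Returns (order, scores): ``order`` is feature indices sorted by
    decreasing score.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise DegenerateFitError("fscore_rank requires exactly two classes")
    pos, neg = X[y == classes[1]], X[y == classes[0]]
    if len(pos) < 2 or len(neg) < 2:
        raise DegenerateFitError("need >= 2 samples per class")
    m, mp, mn = X.mean(axis=0), pos.mean(axis=0), neg.mean(axis=0)
    num = (mp - m) ** 2 + (mn - m) ** 2
    den = pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1)
    scores = np.zeros(X.shape[1])
    ok = den > 0
    scores[ok] = num[ok] / den[ok]
    degenerate = ~ok & (num > 0)
    if degenerate.any():
        warnings.warn(
            f"features {np.flatnonzero(degenerate).tolist()} have zero "
            "within-class variance; ranked by between-class difference"
        )
        # place above all finite scores, ordered among themselves by num
        top = scores[ok].max() if ok.any() else 0.0
        scores[degenerate] = top + 1.0 + num[degenerate]
    order = np.lexsort((np.arange(X.shape[1]), -scores))
    return order, scores


def _svm(spec: ModelSpec, c: float, gamma) -> SVC:
    return SVC(kernel="rbf", C=c, gamma=gamma)


def select_feature_count(
    order: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    seed: int,
    compute_train: bool = True,
) -> FeatureCurve:
    """Grow the SVM feature set in rank order and pick the count maximizing
    inner-CV validation F1.

    For k = 1..K the top-k ranked features are fed to an RBF-SVM at the
    curve's fixed hyperparameters; training and validation F1 are averaged
    over an inner stratified split. The selected count is the argmax of
    validation F1, smallest k on ties. Inner folds whose training side is
    single-class are skipped with a warning. Selection only needs the
    validation side of the curve, so the training side can be skipped
    (``compute_train=False``, reported as NaN) to save time inside CV loops.
    """
    K = len(order)
    if spec.max_curve_features is not None:
        K = min(K, spec.max_curve_features)
    n_splits = min(spec.inner_folds, int(np.bincount(y).min()))
    if n_splits < 2:
        raise DegenerateFitError("too few samples per class for the inner split")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed % (2**31))
    train_f1 = np.zeros(K)
    val_f1 = np.zeros(K)
    n_used = 0
    for tr, va in skf.split(X, y):
        if len(np.unique(y[tr])) < 2:
            warnings.warn("inner fold with single-class training side skipped")
            continue
        n_used += 1
        for k in range(1, K + 1):
            cols = order[:k]
            clf = _svm(spec, spec.curve_c, spec.curve_gamma)
            clf.fit(X[tr][:, cols], y[tr])
            if compute_train:
                train_f1[k - 1] += f1_score(
                    y[tr], clf.predict(X[tr][:, cols]),
                    pos_label=spec.positive_label, zero_division=0,
                )
            val_f1[k - 1] += f1_score(
                y[va], clf.predict(X[va][:, cols]),
                pos_label=spec.positive_label, zero_division=0,
            )
    if n_used == 0:
        raise DegenerateFitError("no usable inner folds")
    train_f1 = train_f1 / n_used if compute_train else np.full(K, np.nan)
    val_f1 /= n_used
    selected = int(np.argmax(val_f1)) + 1  # argmax returns smallest index on ties
    return FeatureCurve(order[:K], train_f1, val_f1, selected)


def _inner_cv_score(make_clf, X, y, inner_folds, seed, positive_label) -> float:
    n_splits = min(inner_folds, int(np.bincount(y).min()))
    if n_splits < 2:
        return np.nan
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed % (2**31))
    accs = []
    for tr, va in skf.split(X, y):
        if len(np.unique(y[tr])) < 2:
            continue
        clf = make_clf()
        clf.fit(X[tr], y[tr])
        accs.append(np.mean(clf.predict(X[va]) == y[va]))
    return float(np.mean(accs)) if accs else np.nan


@dataclass(frozen=True)
class FitResult:
    scores: np.ndarray  # probability (logreg) or decision value (svm)
    labels: np.ndarray
    selected: np.ndarray  # boolean per input feature
    curve: FeatureCurve | None = None


def fit_predict(
    spec: ModelSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    seed: int = 0,
) -> FitResult:
    """Fit one model on a training fold and score a held-out fold.

    Standardization statistics, feature ranking/selection and any
    hyperparameter search are computed from the training rows only, so no
    information leaks from the held-out fold.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train).astype(int)
    if len(np.unique(y_train)) < 2:
        raise DegenerateFitError("training fold contains a single class")
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd[sd == 0] = 1.0
    Xtr = (X_train - mu) / sd
    Xte = (X_test - mu) / sd
    n_feat = Xtr.shape[1]
    selected = np.ones(n_feat, dtype=bool)
    curve = None

    if spec.learner == "logreg":
        if spec.selector == "lasso":
            grid = spec.lasso_c_grid
            if len(grid) > 1:
                scores = [
                    _inner_cv_score(
                        lambda c=c: LogisticRegression(
                            solver="liblinear", l1_ratio=1.0, C=c, max_iter=2000
                        ),
                        Xtr, y_train, spec.inner_folds, seed, spec.positive_label,
                    )
                    for c in grid
                ]
                best_c = grid[int(np.nanargmax(scores))]
            else:
                best_c = grid[0]
            clf = LogisticRegression(
                solver="liblinear", l1_ratio=1.0, C=best_c, max_iter=2000
            )
            clf.fit(Xtr, y_train)
            selected = np.abs(clf.coef_[0]) > 0
        else:
            clf = LogisticRegression(C=np.inf, max_iter=2000)
            clf.fit(Xtr, y_train)
        pos_col = list(clf.classes_).index(spec.positive_label)
        out_scores = clf.predict_proba(Xte)[:, pos_col]
    else:  # svm_rbf
        if spec.selector == "fscore_rank":
            order, _ = fscore_rank(Xtr, y_train)
            curve = select_feature_count(
                order, Xtr, y_train, spec, seed, compute_train=False
            )
            cols = curve.order[: curve.selected_count]
            selected = np.zeros(n_feat, dtype=bool)
            selected[cols] = True
            Xtr, Xte = Xtr[:, cols], Xte[:, cols]
        combos = [(c, g) for c in spec.svm_c_grid for g in spec.svm_gamma_grid]
        if len(combos) > 1:
            scores = [
                _inner_cv_score(
                    lambda c=c, g=g: _svm(spec, c, g),
                    Xtr, y_train, spec.inner_folds, seed, spec.positive_label,
                )
                for c, g in combos
            ]
            best_c, best_g = combos[int(np.nanargmax(scores))]
        else:
            best_c, best_g = combos[0]
        clf = _svm(spec, best_c, best_g)
        clf.fit(Xtr, y_train)
        dec = clf.decision_function(Xte)
        # orient decision values so larger = more likely positive class
        out_scores = dec if clf.classes_[1] == spec.positive_label else -dec
    labels = np.where(
        out_scores >= spec.decision_threshold, spec.positive_label,
        1 - spec.positive_label,
    )
    return FitResult(out_scores, labels, selected, curve)


def mann_whitney_auc(y_true: np.ndarray, scores: np.ndarray, positive_label=1) -> float:
    """AUC as the Mann-Whitney rank statistic: the probability a random
    positive outscores a random negative, ties counted 1/2."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    pos = y == positive_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("AUC undefined with a single class")
    ranks = stats.rankdata(s)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def classification_metrics(
    y_true: np.ndarray,
    scores: np.ndarray,
    threshold: float = 0.5,
    positive_label: int = 1,
) -> MetricPanel:
    """Confusion-matrix panel at ``threshold`` plus the Mann-Whitney AUC.

    Ratios with a zero denominator are reported as NaN, never silently 0.
    """
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s) or len(y) < 2:
        raise ValueError("truth and scores must share a length >= 2")
    auc = mann_whitney_auc(y, s, positive_label)
    pred_pos = s >= threshold
    is_pos = y == positive_label
    tp = int((pred_pos & is_pos).sum())
    tn = int((~pred_pos & ~is_pos).sum())
    fp = int((pred_pos & ~is_pos).sum())
    fn = int((~pred_pos & is_pos).sum())

    def ratio(a, b):
        return a / b if b > 0 else float("nan")

    sens = ratio(tp, tp + fn)
    spec_ = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    acc = (tp + tn) / len(y)
    f1 = (
        2 * ppv * sens / (ppv + sens)
        if np.isfinite(ppv) and np.isfinite(sens) and (ppv + sens) > 0
        else float("nan")
    )
    return MetricPanel(acc, sens, spec_, ppv, npv, auc, f1)


def stratified_partition(y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Fold assignment (0..folds-1) per sample, stratified by class.

    Every sample lands in exactly one fold and per-fold class counts differ
    from perfect proportionality by at most one sample. ``folds == len(y)``
    degenerates to leave-one-out.
    """
    if folds == len(y):
        return np.arange(len(y))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    assignment = np.full(len(y), -1, dtype=int)
    for f, (_, va) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        assignment[va] = f
    return assignment


def repeated_cv(
    spec: ModelSpec,
    table: pd.DataFrame,
    folds: int = 10,
    repeats: int = 100,
    seed: int = 0,
) -> CVResult:
    """Repeated stratified k-fold cross-validation of one model spec.

    Each repeat r draws a fresh stratified partition (seed = base seed + r),
    trains on k-1 folds and scores the held-out fold, with all selection,
    standardization and hyperparameter search inside the training fold;
    pooled validation predictions give one metric panel per repeat.
    """
    y = table["mrs_binary"].to_numpy(int)
    cols = feature_columns(table, spec.feature_set)
    X = table[cols].to_numpy(float)
    class_counts = np.bincount(y)
    if class_counts.min() < folds and folds != len(y):
        raise ValueError(
            f"smallest class has {class_counts.min()} samples; "
            f"need >= {folds} to stratify into {folds} folds"
        )
    panels = []
    selection_counts = np.zeros(len(cols))
    n_fold_fits = 0
    for r in range(repeats):
        rep_seed = (seed + r) % (2**31)
        assignment = stratified_partition(y, folds, rep_seed)
        scores = np.zeros(len(y))
        for f in range(folds):
            va = assignment == f
            tr = ~va
            fit = fit_predict(spec, X[tr], y[tr], X[va], seed=rep_seed * folds + f)
            scores[va] = fit.scores
            if spec.selector != "none":
                selection_counts += fit.selected
            n_fold_fits += 1
        panels.append(
            classification_metrics(
                y, scores, spec.decision_threshold, spec.positive_label
            )
        )
    return CVResult(
        spec=spec,
        panels=panels,
        feature_names=cols,
        selection_counts=selection_counts,
        n_fold_fits=n_fold_fits,
        folds=folds,
        repeats=repeats,
        seed=seed,
        n_samples=len(y),
    )


def compare_models(a: CVResult, b: CVResult) -> dict[str, float]:
    """Paired two-sided Wilcoxon signed-rank over per-repeat AUCs and
    accuracies. Both results must come from the same partition schedule."""
    if a.repeats != b.repeats:
        raise PairingError(f"repeat counts differ: {a.repeats} vs {b.repeats}")
    if a.partition_signature != b.partition_signature:
        raise PairingError("CV results use different fold partitions; not paired")

    def paired_p(xa, xb):
        d = np.asarray(xa) - np.asarray(xb)
        d = d[np.isfinite(d)]
        if len(d) == 0 or np.all(d == 0):
            return 1.0
        return float(stats.wilcoxon(d, alternative="two-sided").pvalue)

    pa, pb = a.per_repeat(), b.per_repeat()
    return {
        "p_auc": paired_p(pa["auc"], pb["auc"]),
        "p_accuracy": paired_p(pa["accuracy"], pb["accuracy"]),
    }


def region_importance(
    cv: CVResult, label_table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-feature selection frequency across training folds, descending.

    Flags whether each conventional covariate (age, NIHSS, volume) was ever
    selected. Requires a model with feature selection (p4 + lasso or
    fscore_rank).
    """
    if cv.spec.selector == "none":
        raise NoSelectionError(f"{cv.spec.name} has no feature selection to report")
    freq = cv.selection_counts / cv.n_fold_fits
    df = pd.DataFrame({"feature": cv.feature_names, "selection_frequency": freq})
    if label_table is not None:
        names = dict(
            zip("pct_" + label_table["id"].astype(int).astype(str), label_table["name"])
        )
        df["region"] = df["feature"].map(names).fillna("")
    df["is_covariate"] = df["feature"].isin(P3_FEATURES)
    df = df.sort_values(
        ["selection_frequency", "feature"], ascending=[False, True]
    ).reset_index(drop=True)
    return df
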