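"""Binary classification of asymmetry features with repeated stratified CV.

Eight classical models are evaluated: Gaussian Naive Bayes, linear
discriminant analysis, four SVM kernels (linear, quadratic, cubic, medium
Gaussian), and two KNN variants (k=1 Euclidean "fine", k=10 cosine).  Their
hyperparameters are fixed defaults — no tuning — because the point of the
evaluation is whether asymmetry features are informative across models, not
which model wins after optimization.

The evaluation protocol is 10 simulation runs of stratified 10-fold
cross-validation with folds reshuffled each run.  Standardization is fitted
on training folds only (it lives inside the model pipeline), and an optional
per-fold feature builder lets fold-dependent features (e.g. a bag-of-features
codebook) be fitted on training folds only as well.

Metric conventions: the positive class is the more severe diagnosis of each
pair (AD > EMCI > NC), so sensitivity reads "fraction of disease cases
caught".  Accuracy/sensitivity/specificity are computed per fold from the
fold's confusion matrix and averaged over all folds of all runs; the
reported spread is the standard deviation across the per-run means.  ROC
curves pool the out-of-fold scores of every run; AUC is the trapezoid area,
which with rank-average tie handling equals the Mann-Whitney U statistic
divided by n1*n2.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import pairwise_distances
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

MODEL_NAMES = ("NB", "LD", "L-SVM", "Q-SVM", "C-SVM", "MG-SVM", "Fine-KNN", "Cos-KNN")

_SEVERITY = {"NC": 0, "EMCI": 1, "AD": 2}

_DEFAULT_HYPERPARAMETERS: Dict[str, Dict[str, object]] = {
    "NB": {"distribution": "gaussian"},
    "LD": {"discriminant_type": "linear"},
    "L-SVM": {"kernel": "linear", "box_constraint": 1.0, "kernel_scale": "auto", "standardize": True},
    "Q-SVM": {"kernel": "quadratic", "box_constraint": 1.0, "kernel_scale": "auto", "standardize": True},
    "C-SVM": {"kernel": "cubic", "box_constraint": 1.0, "kernel_scale": "auto", "standardize": True},
    "MG-SVM": {"kernel": "gaussian", "box_constraint": 1.0, "kernel_scale": 32.0, "standardize": True},
    "Fine-KNN": {"n_neighbors": 1, "metric": "euclidean", "distance_weight": "equal", "standardize": True},
    "Cos-KNN": {"n_neighbors": 10, "metric": "cosine", "distance_weight": "equal", "standardize": True},
}


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """A named model with its (default) hyperparameters."""

    name: str
    hyperparameters: Optional[Dict[str, object]] = None

    def resolved(self) -> Dict[str, object]:
        if self.name not in _DEFAULT_HYPERPARAMETERS:
            raise ValueError(f"unknown model {self.name!r}; valid options: {', '.join(MODEL_NAMES)}")
        params = dict(_DEFAULT_HYPERPARAMETERS[self.name])
        for key, value in (self.hyperparameters or {}).items():
            if key not in params:
                raise ValueError(f"unknown hyperparameter {key!r} for {self.name}; valid: {sorted(params)}")
            params[key] = value
        return params


def default_specs(names: Sequence[str] = MODEL_NAMES) -> List[ModelSpec]:
    return [ModelSpec(n) for n in names]


class MedianScaleSVC(BaseEstimator, ClassifierMixin):
    """SVC whose kernel scale mirrors the "divide predictors by s" convention.

    The input is divided by the kernel scale ``s`` before a standard SVC is
    fitted with gamma=1, so linear/poly kernels read ((x/s)'(y/s) + 1)^d and
    the Gaussian kernel exp(-||x - y||^2 / s^2).  ``kernel_scale="auto"`` is
    realized as the median of the nonzero pairwise training distances (the
    median heuristic).
    """

    def __init__(self, kernel: str = "linear", degree: int = 1, C: float = 1.0,
                 kernel_scale: Union[str, float] = "auto"):
        self.kernel = kernel
        self.degree = degree
        self.C = C
        self.kernel_scale = kernel_scale

    def _resolve_scale(self, X: np.ndarray) -> float:
        if self.kernel_scale != "auto":
            return float(self.kernel_scale)
        d = pairwise_distances(X[:500])
        nz = d[d > 0]
        return float(np.median(nz)) if nz.size else 1.0

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        self.scale_ = self._resolve_scale(X)
        skl_kernel = "linear" if self.kernel == "linear" else ("rbf" if self.kernel == "gaussian" else "poly")
        self.svc_ = SVC(kernel=skl_kernel, degree=self.degree, gamma=1.0,
                        coef0=1.0 if skl_kernel == "poly" else 0.0, C=self.C)
        self.svc_.fit(X / self.scale_, y)
        self.classes_ = self.svc_.classes_
        return self

    def decision_function(self, X):
        return self.svc_.decision_function(np.asarray(X, dtype=np.float64) / self.scale_)

    def predict(self, X):
        return self.svc_.predict(np.asarray(X, dtype=np.float64) / self.scale_)


def make_model(spec: ModelSpec) -> Pipeline:
    """Instantiate the untrained model pipeline for a spec.

    Standardization, where the spec calls for it, sits inside the returned
    pipeline so cross-validation fits it on training folds only.
    """
    p = spec.resolved()
    name = spec.name
    if name == "NB":
        if p["distribution"] != "gaussian":
            raise ValueError("NB supports only the gaussian distribution")
        est, standardize = GaussianNB(), False
    elif name == "LD":
        if p["discriminant_type"] != "linear":
            raise ValueError("LD supports only the linear discriminant type")
        est, standardize = LinearDiscriminantAnalysis(), False
    elif name in ("L-SVM", "Q-SVM", "C-SVM", "MG-SVM"):
        degree = {"linear": 1, "quadratic": 2, "cubic": 3, "gaussian": 0}[str(p["kernel"])]
        est = MedianScaleSVC(kernel=str(p["kernel"]), degree=max(degree, 1),
                             C=float(p["box_constraint"]), kernel_scale=p["kernel_scale"])
        standardize = bool(p["standardize"])
    else:  # KNN variants
        if p["distance_weight"] != "equal":
            raise ValueError("only equal distance weighting is supported")
        est = KNeighborsClassifier(n_neighbors=int(p["n_neighbors"]), metric=str(p["metric"]),
                                   weights="uniform")
        standardize = bool(p["standardize"])
    steps = ([("standardize", StandardScaler())] if standardize else []) + [("model", est)]
    return Pipeline(steps)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores: np.ndarray, y: np.ndarray, positive_label=None) -> Tuple[np.ndarray, float]:
    """ROC curve by threshold sweep over the distinct scores, AUC by trapezoid.

    Tied scores advance TPR and FPR jointly, which makes the trapezoid area
    identical to the rank-average Mann-Whitney statistic U / (n1 * n2).
    Returns (points, auc) with points an (m, 2) array of (FPR, TPR) from
    (0, 0) to (1, 1).
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(y)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    labels = np.unique(y)
    if labels.size != 2:
        raise ValueError(f"ROC needs exactly two classes, got {labels.size}")
    pos = positive_label if positive_label is not None else _positive_of(labels)
    yb = y == pos
    n_pos, n_neg = int(yb.sum()), int((~yb).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="mergesort")
    s, yo = scores[order], yb[order]
    # indices closing each group of tied scores
    last = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tps = np.cumsum(yo)[last]
    fps = (last + 1) - tps
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def _positive_of(labels: np.ndarray):
    """Disease class of a label pair: the more severe diagnosis when known,
    otherwise the lexicographically larger label."""
    a, b = labels[0], labels[1]
    if str(a) in _SEVERITY and str(b) in _SEVERITY:
        return a if _SEVERITY[str(a)] > _SEVERITY[str(b)] else b
    return max(labels.tolist())


def _scores_of(model: Pipeline, X: np.ndarray, pos_label) -> np.ndarray:
    est = model.named_steps["model"]
    if hasattr(est, "decision_function"):
        raw = model.decision_function(X)
        pos_is_last = model.classes_[-1] == pos_label
        return raw if pos_is_last else -raw
    proba = model.predict_proba(X)
    idx = int(np.nonzero(model.classes_ == pos_label)[0][0])
    return proba[:, idx]


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

FoldFeatureBuilder = Callable[[np.ndarray, np.ndarray], Tuple[np.ndarray, np.ndarray]]


@dataclasses.dataclass
class CVReport:
    """Result of repeated stratified cross-validation for one model/dataset."""

    model: ModelSpec
    dataset: str
    runs: int
    folds: int
    seed: int
    positive_label: str
    per_fold: List[Tuple[int, int, int, int]]  # (TP, FP, TN, FN) per fold
    accuracy_mean: float
    accuracy_std: float
    sensitivity_mean: float
    sensitivity_std: float
    specificity_mean: float
    specificity_std: float
    roc_points: np.ndarray
    auc: float


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    runs: int = 10,
    folds: int = 10,
    seed: int = 0,
    positive_label=None,
    dataset: str = "",
    fold_feature_builder: Optional[FoldFeatureBuilder] = None,
) -> CVReport:
    """Repeated stratified k-fold evaluation of one model.

    Folds are reshuffled every run from seeds derived deterministically from
    ``seed``.  ``fold_feature_builder(train_idx, test_idx)`` may supply extra
    feature columns fitted on the training fold only (the anti-leakage hook
    for fold-dependent encodings such as a bag-of-features codebook).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    labels = np.unique(y)
    if labels.size != 2:
        raise ValueError(f"binary cross-validation needs 2 classes, got {labels.size}")
    counts = [int((y == lab).sum()) for lab in labels]
    if min(counts) < folds:
        raise ValueError(f"need at least {folds} samples per class for {folds}-fold CV, got {counts}")
    pos = positive_label if positive_label is not None else _positive_of(labels)

    run_seeds = np.random.SeedSequence(seed).generate_state(runs) % (2**31)
    per_fold: List[Tuple[int, int, int, int]] = []
    acc_f: List[float] = []
    sen_f: List[float] = []
    spe_f: List[float] = []
    run_means: List[Tuple[float, float, float]] = []
    all_scores: List[np.ndarray] = []
    all_truth: List[np.ndarray] = []

    for run_seed in run_seeds:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(run_seed))
        run_acc, run_sen, run_spe = [], [], []
        for train_idx, test_idx in skf.split(X, y):
            Xtr, Xte = X[train_idx], X[test_idx]
            if fold_feature_builder is not None:
                extra_tr, extra_te = fold_feature_builder(train_idx, test_idx)
                Xtr = np.column_stack([Xtr, extra_tr])
                Xte = np.column_stack([Xte, extra_te])
            model = clone(make_model(spec))
            model.fit(Xtr, y[train_idx])
            pred = model.predict(Xte)
            truth = y[test_idx]
            tp = int(((pred == pos) & (truth == pos)).sum())
            fp = int(((pred == pos) & (truth != pos)).sum())
            tn = int(((pred != pos) & (truth != pos)).sum())
            fn = int(((pred != pos) & (truth == pos)).sum())
            per_fold.append((tp, fp, tn, fn))
            acc = 100.0 * (tp + tn) / len(truth)
            sen = 100.0 * tp / (tp + fn)
            spe = 100.0 * tn / (tn + fp)
            run_acc.append(acc), run_sen.append(sen), run_spe.append(spe)
            all_scores.append(_scores_of(model, Xte, pos))
            all_truth.append(truth)
        acc_f += run_acc
        sen_f += run_sen
        spe_f += run_spe
        run_means.append((float(np.mean(run_acc)), float(np.mean(run_sen)), float(np.mean(run_spe))))

    rm = np.asarray(run_means)
    roc_points, auc = roc_auc(np.concatenate(all_scores), np.concatenate(all_truth), positive_label=pos)
    return CVReport(
        model=spec, dataset=dataset, runs=runs, folds=folds, seed=seed,
        positive_label=str(pos), per_fold=per_fold,
        accuracy_mean=float(np.mean(acc_f)), accuracy_std=float(rm[:, 0].std()),
        sensitivity_mean=float(np.mean(sen_f)), sensitivity_std=float(rm[:, 1].std()),
        specificity_mean=float(np.mean(spe_f)), specificity_std=float(rm[:, 2].std()),
        roc_points=roc_points, auc=auc,
    )


# ---------------------------------------------------------------------------
# suite evaluation over class pairs
# ---------------------------------------------------------------------------

def evaluate_suite(
    X: np.ndarray,
    y: np.ndarray,
    dataset_pairs: Sequence[Tuple[str, str]],
    specs: Optional[Sequence[ModelSpec]] = None,
    runs: int = 10,
    folds: int = 10,
    seed: int = 0,
) -> Dict[Tuple[str, str], CVReport]:
    """One CVReport per (class pair, model spec).

    ``dataset_pairs`` lists (disease, control) label pairs, e.g.
    ``[("EMCI", "NC"), ("AD", "NC"), ("AD", "EMCI")]``; the first element is
    the positive class.  Returns a mapping keyed by (dataset name, model
    name); render with :func:`metrics_table` / :func:`auc_table`.
    """
    specs = list(specs) if specs is not None else default_specs()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    reports: Dict[Tuple[str, str], CVReport] = {}
    for pos_label, neg_label in dataset_pairs:
        mask = (y == pos_label) | (y == neg_label)
        for lab in (pos_label, neg_label):
            if not (y == lab).any():
                raise ValueError(f"class {lab!r} absent from the records")
        name = f"{pos_label} vs. {neg_label}"
        for spec in specs:
            reports[(name, spec.name)] = cross_validate(
                X[mask], y[mask], spec, runs=runs, folds=folds, seed=seed,
                positive_label=pos_label, dataset=name,
            )
    return reports


def metrics_table(reports: Dict[Tuple[str, str], CVReport]) -> pd.DataFrame:
    """Accuracy/sensitivity/specificity grid: one row per (dataset, metric),
    one column per model, values in percent."""
    datasets = sorted({k[0] for k in reports}, key=[k[0] for k in reports].index)
    models = sorted({k[1] for k in reports}, key=[k[1] for k in reports].index)
    rows = []
    for ds in datasets:
        for metric, attr in (("Accuracy", "accuracy_mean"),
                             ("Sensitivity", "sensitivity_mean"),
                             ("Specificity", "specificity_mean")):
            row = {"dataset": ds, "metric": metric}
            row.update({m: round(getattr(reports[(ds, m)], attr), 4) for m in models})
            rows.append(row)
    return pd.DataFrame(rows)


def auc_table(reports: Dict[Tuple[str, str], CVReport]) -> pd.DataFrame:
    """AUC summary: one row per dataset, one column per model."""
    datasets = sorted({k[0] for k in reports}, key=[k[0] for k in reports].index)
    models = sorted({k[1] for k in reports}, key=[k[1] for k in reports].index)
    rows = []
    for ds in datasets:
        row = {"dataset": ds}
        row.update({m: round(reports[(ds, m)].auc, 4) for m in models})
        rows.append(row)
    return pd.DataFrame(rows)
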