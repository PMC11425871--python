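"""Classifier training, cross-validation and metric reporting.

Three learners consume the 9-feature vectors: K-nearest neighbours (K = 8,
score = positive-neighbour fraction), a Gaussian-kernel SVM (decision values
mapped to [0, 1] by a logistic link fitted on the training fold), and plain
logistic regression.  Evaluation runs under repeated stratified 5-fold and
leave-one-out cross-validation; every sample is scored exactly once per
repeat by a model that never saw it, with feature standardisation fitted on
training folds only.

Metrics follow the usual immunogenicity-benchmark set: ROC AUC (computed by
the rank / Mann-Whitney formulation, ties counting one half), area under the
precision-recall curve, and precision/recall/F1 at the score cutoff that
maximises F1.  The headline numbers are means across repeats; pooled-over-
repeats variants and first-repeat curves are also carried.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ClassifierConfig",
    "CVScheme",
    "EvalReport",
    "make_classifier",
    "cross_validate",
    "roc_auc",
    "pr_metrics",
    "evaluate_methods",
    "compare",
]

METHODS = ("KNN", "SVM", "LR")


@dataclass
class ClassifierConfig:
    method: str = "LR"  # KNN | SVM | LR
    knn_k: int = 8
    standardize: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


@dataclass
class CVScheme:
    kind: str = "kfold"  # kfold | loo
    n_folds: int = 5
    n_repeats: int = 100
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("kfold", "loo"):
            raise ValueError("kind must be 'kfold' or 'loo'")
        if self.kind == "kfold" and self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


class _SigmoidSVC(BaseEstimator, ClassifierMixin):
    """RBF SVM whose score is the decision value through a logistic link.

    The link is a one-dimensional logistic regression fitted on the training
    fold's own decision values (Platt-style), giving a [0, 1] score the ROC
    and PR machinery can consume.
    """

    def __init__(self, random_state: int = 0):
        self.random_state = random_state

    def fit(self, X, y):
        self.svc_ = SVC(kernel="rbf", random_state=self.random_state)
        self.svc_.fit(X, y)
        d = self.svc_.decision_function(X).reshape(-1, 1)
        self.link_ = LogisticRegression(max_iter=1000)
        self.link_.fit(d, y)
        self.classes_ = self.svc_.classes_
        return self

    def predict_proba(self, X):
        d = self.svc_.decision_function(X).reshape(-1, 1)
        return self.link_.predict_proba(d)

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def make_classifier(config: ClassifierConfig):
    """sklearn pipeline for one method (standardisation fitted in-fold)."""
    if config.method == "KNN":
        est = KNeighborsClassifier(n_neighbors=config.knn_k)
    elif config.method == "SVM":
        est = _SigmoidSVC(random_state=config.seed)
    else:
        est = LogisticRegression(max_iter=1000)
    steps = []
    if config.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("clf", est))
    return Pipeline(steps)


def cross_validate(features, clf_config: ClassifierConfig, scheme: CVScheme) -> np.ndarray:
    """Out-of-fold scores, one row per repeat.

    Accepts a FeatureTable or a bare ``(X, y)`` pair.  Each repeat uses a
    different stratified fold split derived from the scheme seed; LOO has a
    single deterministic repeat.
    """
    X, y = _xy(features)
    if len(np.unique(y)) < 2:
        raise ValueError("cross-validation needs both classes present")
    n = y.size
    if scheme.kind == "loo":
        splits_per_repeat = [list(LeaveOneOut().split(X))]
    else:
        splits_per_repeat = []
        for rep in range(scheme.n_repeats):
            cv = StratifiedKFold(
                n_splits=scheme.n_folds, shuffle=True, random_state=scheme.seed + rep
            )
            splits_per_repeat.append(list(cv.split(X, y)))
    base = make_classifier(clf_config)
    out = np.empty((len(splits_per_repeat), n))
    for r, splits in enumerate(splits_per_repeat):
        for train, test in splits:
            if clf_config.method == "KNN" and train.size < clf_config.knn_k:
                raise ValueError("training fold smaller than knn_k")
            model = clone(base)
            model.fit(X[train], y[train])
            out[r, test] = model.predict_proba(X[test])[:, 1]
    return out


def _xy(features):
    if hasattr(features, "X"):
        return features.X, features.y
    X, y = features
    return np.asarray(X, dtype=float), np.asarray(y, dtype=int)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def roc_auc(scores, labels):
    """ROC AUC by the rank (Mann-Whitney) formulation, plus curve points.

    Ties contribute one half.  Returns ``(auc, fpr, tpr)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC needs both classes present")
    ranks = rankdata(scores, method="average")
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    # curve: sweep unique thresholds from high to low
    order = np.argsort(-scores, kind="mergesort")
    s, l = scores[order], labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tp = np.cumsum(l)[distinct]
    fp = np.cumsum(1 - l)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    return float(auc), fpr, tpr


def pr_metrics(scores, labels):
    """Precision-recall summary at the best-F1 cutoff.

    Candidate cutoffs are the unique score values (prediction rule: score >=
    cutoff); AUPR is the step-wise interpolation sum((R_k - R_{k-1}) * P_k)
    over descending cutoffs.  F1 ties resolve to the lowest cutoff.  Returns
    a dict with aupr, precision, recall, f1, cutoff and the PR curve arrays.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("PR metrics need at least one positive sample")
    order = np.argsort(-scores, kind="mergesort")
    s, l = scores[order], labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tp = np.cumsum(l)[distinct].astype(float)
    npred = (distinct + 1).astype(float)
    precision = tp / npred
    recall = tp / n_pos
    cutoffs = s[distinct]
    aupr = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.where(precision + recall > 0, 2 * precision * recall / (precision + recall), 0.0)
    best_f = f1.max()
    # ties -> lowest cutoff; cutoffs are descending, so take the last argmax
    best_idx = int(np.flatnonzero(f1 == best_f)[-1])
    return {
        "aupr": aupr,
        "precision": float(precision[best_idx]),
        "recall": float(recall[best_idx]),
        "f1": float(best_f),
        "cutoff": float(cutoffs[best_idx]),
        "precision_curve": precision,
        "recall_curve": recall,
        "cutoffs": cutoffs,
    }


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Results bundle for one (setting, scheme): baseline + augmented methods.

    ``metrics`` is the per-method mean-across-repeats table; ``per_repeat``
    maps method -> (n_repeats,) AUC/AUPR arrays; ``scores`` maps method ->
    (n_repeats, n) out-of-fold score matrix.  ``summary()`` renders the
    table in the conventional layout (Setting, Method, Precision, Recall,
    F1-measure, AUPR, AUC).
    """

    setting: str
    scheme: str
    labels: np.ndarray
    scores: dict = field(default_factory=dict)
    metrics: pd.DataFrame | None = None
    per_repeat: dict = field(default_factory=dict)
    curves: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return self.metrics

    def summary_text(self) -> str:
        return self.metrics.to_string(index=False, float_format=lambda v: f"{v:.4f}")

    def score_distributions(self) -> pd.DataFrame:
        """Pooled first-repeat scores with labels, for distribution plots."""
        rows = []
        for method, mat in self.scores.items():
            for s, y in zip(mat[0], self.labels):
                rows.append({"method": method, "score": s, "label": int(y)})
        return pd.DataFrame(rows)


def _metric_row(scores_1d, labels):
    auc, fpr, tpr = roc_auc(scores_1d, labels)
    pr = pr_metrics(scores_1d, labels)
    return {
        "Precision": pr["precision"],
        "Recall": pr["recall"],
        "F1-measure": pr["f1"],
        "AUPR": pr["aupr"],
        "AUC": auc,
        "cutoff": pr["cutoff"],
    }, (fpr, tpr)


def evaluate_methods(
    features,
    scheme: CVScheme,
    baseline_name: str = "baseline",
    setting: str = "surrogate",
    methods=METHODS,
    clf_seed: int = 0,
    knn_k: int = 8,
) -> EvalReport:
    """Evaluate the baseline score and all augmented learners on one dataset.

    The baseline is the raw score feature (no training, identical in every
    repeat); each learner is cross-validated on the full 9-feature matrix.
    """
    X, y = _xy(features)
    base_scores = X[:, 0]
    n_rep = 1 if scheme.kind == "loo" else scheme.n_repeats
    report = EvalReport(setting=setting, scheme=scheme.kind, labels=y)

    rows = []
    m, curve = _metric_row(base_scores, y)
    report.scores[baseline_name] = np.tile(base_scores, (n_rep, 1))
    report.per_repeat[baseline_name] = {
        "AUC": np.full(n_rep, m["AUC"]),
        "AUPR": np.full(n_rep, m["AUPR"]),
    }
    report.curves[baseline_name] = curve
    rows.append({"Setting": setting, "Method": baseline_name, **m})

    for method in methods:
        cfg = ClassifierConfig(method=method, knn_k=knn_k, seed=clf_seed)
        mat = cross_validate((X, y), cfg, scheme)
        report.scores[f"Plus3D-{method}"] = mat
        aucs = np.array([roc_auc(mat[r], y)[0] for r in range(mat.shape[0])])
        auprs = np.array([pr_metrics(mat[r], y)["aupr"] for r in range(mat.shape[0])])
        report.per_repeat[f"Plus3D-{method}"] = {"AUC": aucs, "AUPR": auprs}
        # headline: mean across repeats for AUC/AUPR; threshold metrics from
        # pooled out-of-fold scores of the first repeat (flagged in docs)
        m, curve = _metric_row(mat[0], y)
        m["AUC"] = float(aucs.mean())
        m["AUPR"] = float(auprs.mean())
        report.curves[f"Plus3D-{method}"] = curve
        rows.append({"Setting": setting, "Method": f"Plus3D-{method}", **m})

    report.metrics = pd.DataFrame(rows)
    return report


def compare(baseline_scores, labels, reports) -> pd.DataFrame:
    """Delta table: each augmented method against a fixed baseline.

    ``reports`` is an iterable of EvalReport sharing the same samples as
    ``baseline_scores``/``labels``.  Reports per method the across-repeat
    mean and sd of AUC and AUPR deltas.
    """
    baseline_scores = np.asarray(baseline_scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    base_auc, _, _ = roc_auc(baseline_scores, labels)
    base_aupr = pr_metrics(baseline_scores, labels)["aupr"]
    rows = []
    for rep in reports:
        if rep.labels.size != labels.size or not np.array_equal(rep.labels, labels):
            raise ValueError("comparison requires identical sample sets and labels")
        for method, pr in rep.per_repeat.items():
            if method == "baseline":
                continue
            d_auc = pr["AUC"] - base_auc
            d_aupr = pr["AUPR"] - base_aupr
            rows.append(
                {
                    "Setting": rep.setting,
                    "Scheme": rep.scheme,
                    "Method": method,
                    "dAUC_mean": float(d_auc.mean()),
                    "dAUC_sd": float(d_auc.std(ddof=0)),
                    "dAUPR_mean": float(d_aupr.mean()),
                    "dAUPR_sd": float(d_aupr.std(ddof=0)),
                }
            )
    return pd.DataFrame(rows)
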