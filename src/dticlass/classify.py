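"""Nested leave-one-out SVM classification with permutation inference.

Each LOOCV fold trains on N-1 subjects and tests on the held-out one;
feature selection (two-sample t-test, top D) and dimensionality
reduction (LLE to d) are fitted inside the fold on the N-1 training
subjects only, so no statistic of the held-out subject leaks into
training.  Performance is summarized by the generalization rate GR
(overall proportion correct), sensitivity SS (patients correct) and
specificity SC (controls correct), an ROC curve over the per-subject SVM
decision scores, and a label-permutation test using GR as the statistic:
the whole nested procedure is rerun under shuffled labels to build the
null distribution, and p = (1 + #{GR_perm >= GR0}) / (1 + n_perm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import sklearn
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.svm import SVC

from .cohort import CohortTable
from .features import lle_fit, lle_transform, select_top_features, ttest_scores

__all__ = [
    "SVMConfig",
    "FoldPrediction",
    "MetricsReport",
    "ROCResult",
    "PermutationResult",
    "svm_train",
    "loocv_run",
    "compute_metrics",
    "roc_curve_auc",
    "permutation_test",
]


@dataclass
class SVMConfig:
    """Soft-margin SVM: linear or Gaussian-RBF kernel.

    gamma may be a positive float or "scale" (1 / (d * var(X)), the
    variance-adaptive default appropriate for the low-dimensional
    embeddings this classifier consumes).
    """

    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | str = "scale"

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ValueError("kernel must be 'linear' or 'rbf'")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if isinstance(self.gamma, str):
            if self.gamma != "scale":
                raise ValueError("gamma must be a positive float or 'scale'")
        elif self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass
class FoldPrediction:
    """One LOOCV fold: held-out subject, truth, prediction, score."""

    subject_id: str
    true_label: int
    predicted_label: int
    score: float  # signed decision value; label = 1 iff score > 0


@dataclass
class MetricsReport:
    """Confusion counts and the GR/SS/SC proportions."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n_patients(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.tn + self.fp

    @property
    def n(self) -> int:
        return self.n_patients + self.n_controls

    @property
    def gr(self) -> float:
        """Generalization rate: overall proportion correct."""
        return (self.tp + self.tn) / self.n

    @property
    def ss(self) -> float:
        """Sensitivity: proportion of patients correctly classified."""
        return self.tp / self.n_patients

    @property
    def sc(self) -> float:
        """Specificity: proportion of controls correctly classified."""
        return self.tn / self.n_controls

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "gr": self.gr, "ss": self.ss, "sc": self.sc,
            "n_patients": self.n_patients, "n_controls": self.n_controls,
        }


@dataclass
class ROCResult:
    """ROC points from (0,0) to (1,1) and the trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass
class PermutationResult:
    """Observed GR0, the permuted-GR null, and the empirical p-value."""

    gr0: float
    permuted_gr: np.ndarray
    n_perm: int
    p_value: float
    seed: int


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def svm_train(X: np.ndarray, y: np.ndarray, cfg: SVMConfig) -> SVC:
    """Fit a soft-margin SVM; returns the estimator (use
    ``decision_function`` for signed scores)."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("SVM training requires both classes present")
    clf = SVC(kernel=cfg.kernel, C=cfg.C, gamma=cfg.gamma)
    clf.fit(np.asarray(X, dtype=float), y)
    return clf


def _fold_score(Xtr, ytr, x_test, D, k, d, cfg, equal_var=True):
    """Select-reduce-train on the training split, score one held-out row."""
    t, p, degenerate = ttest_scores(Xtr, ytr, equal_var=equal_var)
    sel = select_top_features(t, p, D, degenerate=degenerate).selected
    model = lle_fit(Xtr[:, sel], k=k, d=d)
    clf = svm_train(model.embedding, ytr, cfg)
    emb_te = lle_transform(model, x_test[sel])
    score = float(clf.decision_function(emb_te[None, :])[0])
    return score, sel


def loocv_run(table: CohortTable, D: int = 200, k: int = 12, d: int = 10,
              cfg: SVMConfig | None = None, equal_var: bool = True,
              selection_hook=None) -> list[FoldPrediction]:
    """Nested leave-one-out cross-validation.

    Per fold: two-sample t-test selection of D features and an LLE fit
    (k neighbors, d components) on the N-1 training subjects only; the
    held-out subject is mapped by the out-of-sample extension and scored
    by an SVM trained on the training embedding.  Predicted label is 1
    iff the decision score exceeds 0.

    ``selection_hook(fold_index, training_indices, selected_features)``
    is called once per fold with the subject indices the fold's
    selection/LLE consumed — instrumentation for leakage audits.
    """
    cfg = cfg or SVMConfig()
    X, y = table.X, table.y
    n = X.shape[0]
    if n < 4:
        raise ValueError("LOOCV needs at least 4 subjects")
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 subjects per class")
    if D > X.shape[1]:
        raise ValueError(f"D={D} exceeds the {X.shape[1]} features")
    preds = []
    # inputs are validated here once; skip sklearn's per-fit re-checks
    with sklearn.config_context(assume_finite=True,
                                skip_parameter_validation=True):
        for i in range(n):
            tr = np.concatenate([np.arange(i), np.arange(i + 1, n)])
            score, sel = _fold_score(X[tr], y[tr], X[i], D, k, d, cfg,
                                     equal_var=equal_var)
            if selection_hook is not None:
                selection_hook(i, tr, sel)
            preds.append(FoldPrediction(
                subject_id=table.subject_ids[i],
                true_label=int(y[i]),
                predicted_label=int(score > 0),
                score=score,
            ))
    return preds


def compute_metrics(preds) -> MetricsReport:
    """Confusion counts and GR/SS/SC from fold predictions."""
    if not preds:
        raise ValueError("no predictions")
    truth = np.array([p.true_label for p in preds])
    pred = np.array([p.predicted_label for p in preds])
    if (truth == 1).sum() == 0 or (truth == 0).sum() == 0:
        raise ValueError("both classes must be present")
    return MetricsReport(
        tp=int(((truth == 1) & (pred == 1)).sum()),
        fn=int(((truth == 1) & (pred == 0)).sum()),
        tn=int(((truth == 0) & (pred == 0)).sum()),
        fp=int(((truth == 0) & (pred == 1)).sum()),
    )


def roc_curve_auc(preds) -> ROCResult:
    """ROC over the per-subject decision scores; trapezoidal AUC.

    Thresholds sweep the unique scores; tied scores move the curve
    diagonally in one step, which makes the trapezoidal AUC identical to
    the Mann-Whitney concordant-pair fraction with ties counted 1/2.
    """
    truth = np.array([p.true_label for p in preds])
    scores = np.array([p.score for p in preds], dtype=float)
    if (truth == 1).sum() == 0 or (truth == 0).sum() == 0:
        raise ValueError("both classes must be present")
    if not np.isfinite(scores).all():
        raise ValueError("decision scores must be finite")
    if np.unique(scores).size == 1:
        warnings.warn("constant decision scores: degenerate ROC, AUC=0.5",
                      stacklevel=2)
        return ROCResult(fpr=np.array([0.0, 1.0]), tpr=np.array([0.0, 1.0]),
                         thresholds=np.array([np.inf, scores[0]]), auc=0.5)
    fpr, tpr, thr = _sk_roc_curve(truth, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def permutation_test(table: CohortTable, D: int = 200, k: int = 12,
                     d: int = 10, cfg: SVMConfig | None = None,
                     n_perm: int = 1000, seed: int = 0,
                     alpha: float | None = None,
                     equal_var: bool = True) -> PermutationResult:
    """Label-permutation null for the LOOCV generalization rate.

    Each permutation shuffles the class labels once and reruns the full
    nested LOOCV (selection and LLE refitted per fold per permutation).
    The empirical p-value uses the add-one estimator with a >=
    comparison, so it can never be 0 and the minimum attainable value is
    1/(n_perm+1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alpha is not None and 1.0 / (n_perm + 1) > alpha:
        warnings.warn(
            f"n_perm={n_perm} cannot reach p <= {alpha}; the minimum "
            f"attainable p is {1.0 / (n_perm + 1):.4g}",
            stacklevel=2,
        )
    cfg = cfg or SVMConfig()
    gr0 = compute_metrics(loocv_run(table, D, k, d, cfg,
                                    equal_var=equal_var)).gr
    # one child seed per permutation from the master seed
    children = np.random.SeedSequence(seed).spawn(n_perm)
    permuted = np.empty(n_perm)
    for j in range(n_perm):
        rng = np.random.default_rng(children[j])
        y_perm = rng.permutation(table.y)
        t_perm = CohortTable(X=table.X, y=y_perm,
                             subject_ids=list(table.subject_ids),
                             feature_ids=list(table.feature_ids))
        try:
            permuted[j] = compute_metrics(
                loocv_run(t_perm, D, k, d, cfg, equal_var=equal_var)
            ).gr
        except ValueError:
            # a permutation cannot unbalance a binary label vector, but
            # guard against degenerate inputs
            permuted[j] = np.nan
    valid = permuted[~np.isnan(permuted)]
    p = (1.0 + (valid >= gr0).sum()) / (1.0 + valid.size)
    return PermutationResult(gr0=gr0, permuted_gr=permuted,
                             n_perm=n_perm, p_value=float(p), seed=seed)
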