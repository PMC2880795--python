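"""Cross-validated SVM evaluation and wrapper forward feature selection.

The classifier is a support vector machine (RBF kernel by default,
linear for comparison) evaluated by stratified k-fold cross-validation:
features are standardized with training-fold statistics only, one SVM
is trained per fold, and the pooled out-of-fold predictions give the
confusion counts.  Forward selection greedily grows the feature set,
at each step adding the candidate that maximizes the same
cross-validated accuracy; with N candidates and M requested features
this costs at most N*M cross-validated fits.

Note the selection criterion and the reported accuracy share one
cross-validation loop; that mirrors the original protocol and is
optimistic.  ``nested_cv_evaluate`` reports an unbiased estimate by
re-running the selection inside each outer fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .synth import CASE

__all__ = [
    "ClassifierEval",
    "SelectionResult",
    "ForwardSelectingSVM",
    "cv_evaluate",
    "forward_select",
    "nested_cv_evaluate",
]


@dataclass(frozen=True)
class ClassifierEval:
    """Pooled out-of-fold confusion counts; 'positive' = the case group."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


@dataclass
class SelectionResult:
    """Ordered forward-selected features with their accuracy trace."""

    selected: list
    cv_accuracy_trace: list
    fold_assignment: np.ndarray
    kernel: str
    seed: int
    final_eval: ClassifierEval | None = None
    n_cv_calls: int = 0
    step_evals: list = field(default_factory=list)


def _validate_labels(y: np.ndarray, positive_label) -> np.ndarray:
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
    if positive_label not in classes:
        raise ValueError(f"positive_label {positive_label!r} not among classes {classes.tolist()}")
    return classes


def _fold_assignment(y: np.ndarray, k_folds: int, seed: int) -> np.ndarray:
    """Stratified fold index per subject, fixed by the seed."""
    counts = np.unique(y, return_counts=True)[1]
    if counts.min() < 2:
        raise ValueError("need >= 2 subjects per class")
    if k_folds > counts.min():
        raise ValueError(f"k_folds={k_folds} exceeds the smaller class size {counts.min()}")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        folds[test_idx] = f
    return folds


def _pooled_cv_predict(
    X: np.ndarray, y: np.ndarray, folds: np.ndarray, kernel: str, C: float, gamma
) -> np.ndarray:
    pred = np.empty(len(y), dtype=object)
    for f in np.unique(folds):
        train, test = folds != f, folds == f
        scaler = StandardScaler().fit(X[train])
        clf = SVC(kernel=kernel, C=C, gamma=gamma)
        clf.fit(scaler.transform(X[train]), y[train])
        pred[test] = clf.predict(scaler.transform(X[test]))
    return pred


def _confusion(y: np.ndarray, pred: np.ndarray, positive_label) -> ClassifierEval:
    pos = y == positive_label
    hit = pred == y
    return ClassifierEval(
        tp=int(np.sum(pos & hit)),
        tn=int(np.sum(~pos & hit)),
        fp=int(np.sum(~pos & ~hit)),
        fn=int(np.sum(pos & ~hit)),
    )


def cv_evaluate(
    X,
    feature_ids=None,
    kernel: str = "rbf",
    k_folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
    gamma="scale",
    positive_label=CASE,
    folds: np.ndarray | None = None,
) -> ClassifierEval:
    """k-fold cross-validated confusion counts for one feature subset.

    ``X`` is a FeatureMatrix (or anything with .values/.group_labels/
    .feature_ids); ``feature_ids`` restricts the columns used.
    """
    y = np.asarray(X.group_labels, dtype=object)
    _validate_labels(y, positive_label)
    if feature_ids is None:
        cols = list(range(len(X.feature_ids)))
    else:
        index = {fid: j for j, fid in enumerate(X.feature_ids)}
        cols = [index[f] for f in feature_ids]
    if not cols:
        raise ValueError("empty feature subset")
    Xv = np.asarray(X.values, dtype=float)[:, cols]
    if folds is None:
        folds = _fold_assignment(y, k_folds, seed)
    pred = _pooled_cv_predict(Xv, y, folds, kernel, C, gamma)
    return _confusion(y, pred, positive_label)


class ForwardSelectingSVM(BaseEstimator, ClassifierMixin):
    """SVM with greedy forward feature selection by CV accuracy.

    ``fit(X, y)`` greedily selects ``n_features_to_select`` columns: at
    each step every remaining candidate is appended in turn and scored
    by stratified ``k_folds``-fold CV accuracy of a standardized SVM;
    the best candidate (ties to the lowest column index) is kept.  A
    final SVM is refit on all rows with the selected columns.

    Fitted attributes: ``selected_`` (column indices, in selection
    order), ``cv_accuracy_trace_``, ``fold_assignment_``, ``eval_``
    (pooled out-of-fold confusion of the selected set), ``n_cv_calls_``.
    """

    def __init__(
        self,
        n_features_to_select: int = 5,
        kernel: str = "rbf",
        k_folds: int = 10,
        C: float = 1.0,
        gamma="scale",
        random_state: int = 0,
        positive_label=CASE,
    ) -> None:
        self.n_features_to_select = n_features_to_select
        self.kernel = kernel
        self.k_folds = k_folds
        self.C = C
        self.gamma = gamma
        self.random_state = random_state
        self.positive_label = positive_label

    def fit(self, X, y) -> "ForwardSelectingSVM":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        n, p = X.shape
        m = self.n_features_to_select
        if m > p:
            raise ValueError(f"cannot select {m} features from {p} candidates")
        _validate_labels(y, self.positive_label)
        folds = _fold_assignment(y, self.k_folds, self.random_state)

        selected: list[int] = []
        trace: list[float] = []
        evals: list[ClassifierEval] = []
        n_calls = 0
        for _ in range(m):
            best_j, best_acc, best_eval = -1, -np.inf, None
            for j in range(p):
                if j in selected:
                    continue
                cols = selected + [j]
                pred = _pooled_cv_predict(X[:, cols], y, folds, self.kernel, self.C, self.gamma)
                ev = _confusion(y, pred, self.positive_label)
                n_calls += 1
                # strict > keeps the lowest-index candidate on ties
                if ev.accuracy > best_acc:
                    best_j, best_acc, best_eval = j, ev.accuracy, ev
            selected.append(best_j)
            trace.append(best_acc)
            evals.append(best_eval)

        self.selected_ = selected
        self.cv_accuracy_trace_ = trace
        self.step_evals_ = evals
        self.fold_assignment_ = folds
        self.eval_ = evals[-1] if evals else None
        self.n_cv_calls_ = n_calls
        if selected:
            self._scaler = StandardScaler().fit(X[:, selected])
            self._svm = SVC(kernel=self.kernel, C=self.C, gamma=self.gamma)
            self._svm.fit(self._scaler.transform(X[:, selected]), y)
        self.classes_ = np.unique(y)
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if not self.selected_:
            raise ValueError("no features were selected (n_features_to_select=0)")
        return self._svm.predict(self._scaler.transform(X[:, self.selected_]))


def forward_select(
    X,
    M: int,
    kernel: str = "rbf",
    k_folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
    gamma="scale",
    positive_label=CASE,
) -> SelectionResult:
    """Greedy forward selection of M features from a FeatureMatrix."""
    est = ForwardSelectingSVM(
        n_features_to_select=M,
        kernel=kernel,
        k_folds=k_folds,
        C=C,
        gamma=gamma,
        random_state=seed,
        positive_label=positive_label,
    )
    if M > 0:
        est.fit(np.asarray(X.values, dtype=float), np.asarray(X.group_labels, dtype=object))
        selected_ids = [X.feature_ids[j] for j in est.selected_]
        return SelectionResult(
            selected=selected_ids,
            cv_accuracy_trace=list(est.cv_accuracy_trace_),
            fold_assignment=est.fold_assignment_,
            kernel=kernel,
            seed=seed,
            final_eval=est.eval_,
            n_cv_calls=est.n_cv_calls_,
            step_evals=list(est.step_evals_),
        )
    y = np.asarray(X.group_labels, dtype=object)
    _validate_labels(y, positive_label)
    return SelectionResult(
        selected=[],
        cv_accuracy_trace=[],
        fold_assignment=_fold_assignment(y, k_folds, seed),
        kernel=kernel,
        seed=seed,
    )


def nested_cv_evaluate(
    X,
    M: int,
    kernel: str = "rbf",
    k_folds: int = 10,
    seed: int = 0,
    **svm_kwargs,
) -> ClassifierEval:
    """Unbiased variant: forward selection re-run inside each outer fold,
    outer-fold predictions pooled.  Not the reference protocol."""
    y = np.asarray(X.group_labels, dtype=object)
    _validate_labels(y, CASE)
    Xv = np.asarray(X.values, dtype=float)
    outer = _fold_assignment(y, k_folds, seed)
    pred = np.empty(len(y), dtype=object)
    for f in np.unique(outer):
        train, test = outer != f, outer == f
        est = ForwardSelectingSVM(
            n_features_to_select=M, kernel=kernel, k_folds=k_folds, random_state=seed, **svm_kwargs
        )
        est.fit(Xv[train], y[train])
        pred[test] = est.predict(Xv[test])
    return _confusion(y, pred, CASE)
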