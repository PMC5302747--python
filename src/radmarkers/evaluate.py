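"""Panel refinement and scoring: stepwise LDA, stepwise-AIC logistic
regression, confusion matrices, ROC/AUC and PCA score projections.

The selected features from the stability stage are refined into a compact
panel by either forward stepwise linear discriminant analysis driven by
cross-validated accuracy, or bidirectional stepwise logistic regression
minimizing the Akaike information criterion.  The fitted panel is scored
with learning/test confusion matrices, ROC curves (resubstitution,
cross-validated and held-out, labeled separately since it is ambiguous
which convention a given reported AUC uses), and a PCA projection of the
samples on the panel variables for visual group separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.utils.validation import check_X_y, check_is_fitted

__all__ = [
    "FittedPanel",
    "RocResult",
    "ConfusionSummary",
    "EvalReport",
    "StepwiseLDA",
    "StepwiseLogisticAIC",
    "stepwise_lda",
    "stepwise_logistic_aic",
    "confusion_summary",
    "roc_auc",
    "pca_scores",
    "evaluate_panel",
]


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------

@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_dict(self) -> dict:
        return {
            "thresholds": np.asarray(self.thresholds).tolist(),
            "fpr": np.asarray(self.fpr).tolist(),
            "tpr": np.asarray(self.tpr).tolist(),
            "auc": float(self.auc),
        }


@dataclass
class ConfusionSummary:
    counts: np.ndarray  # 2x2, rows = true class, cols = predicted
    accuracy: float

    def to_dict(self) -> dict:
        return {"counts": np.asarray(self.counts).tolist(), "accuracy": float(self.accuracy)}


@dataclass
class FittedPanel:
    method: str
    variables: list
    coefficients: dict
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "variables": list(self.variables),
            "coefficients": self.coefficients,
            "flags": self.flags,
        }


@dataclass
class EvalReport:
    panel: FittedPanel
    confusion: dict[str, ConfusionSummary]
    roc: dict[str, RocResult]
    pca: dict
    histograms: dict

    def to_dict(self) -> dict:
        return {
            "panel": self.panel.to_dict(),
            "confusion": {k: v.to_dict() for k, v in self.confusion.items()},
            "roc": {k: v.to_dict() for k, v in self.roc.items()},
            "pca": self.pca,
            "histograms": self.histograms,
        }


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC by threshold sweep and trapezoidal AUC (ties half-credited).

    The AUC equals the Mann-Whitney U statistic divided by n1*n0: the
    probability that a random positive scores above a random negative,
    counting ties one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size != 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    return RocResult(thr, fpr, tpr, float(_trapezoid_auc(fpr, tpr)))


def confusion_summary(y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray) -> ConfusionSummary:
    """2x2 confusion counts (rows true, cols predicted) and accuracy."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    unseen = set(np.unique(y_true)) - set(classes)
    if unseen:
        raise ValueError(f"unseen class label(s) {sorted(unseen)}")
    counts = _sk_confusion(y_true, y_pred, labels=list(classes))
    return ConfusionSummary(counts, float((y_true == y_pred).mean()))


def pca_scores(
    X: np.ndarray, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic PCA on centered, unit-scaled columns.

    Zero-variance columns are dropped with a warning.  Component signs
    are fixed so the largest-magnitude loading of each component is
    positive.  Returns (scores, explained variance fractions, loadings).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need >= 2 samples and >= 1 feature")
    sd = X.std(axis=0)
    kept = sd > 0
    if not kept.any():
        raise ValueError("all features have zero variance")
    if not kept.all():
        warnings.warn(f"dropping {int((~kept).sum())} zero-variance feature(s)")
    Xs = (X[:, kept] - X[:, kept].mean(axis=0)) / sd[kept]
    k = int(min(n_components, Xs.shape[1], Xs.shape[0] - 1))
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Xs)
    loadings = pca.components_
    for a in range(k):
        j = int(np.argmax(np.abs(loadings[a])))
        if loadings[a, j] < 0:
            loadings[a] *= -1
            scores[:, a] *= -1
    return scores, pca.explained_variance_ratio_, loadings


# --------------------------------------------------------------------------
# stepwise LDA
# --------------------------------------------------------------------------

class StepwiseLDA(ClassifierMixin, BaseEstimator):
    """Forward stepwise linear discriminant analysis.

    Two entry criteria are available.  The default, ``criterion='wilks'``,
    is the classic stepwise-discriminant rule: a candidate enters when its
    partial Wilks'-lambda F-to-enter exceeds ``f_to_enter`` (3.84, the 5%
    point), and an entered variable is removed again when its F-to-remove
    falls below ``f_to_remove``.  ``criterion='cv_accuracy'`` instead adds
    the candidate that most improves stratified-CV accuracy until no
    candidate improves by more than ``tol`` (default 1/(2n)); note that
    accuracy saturates at the majority rate under class imbalance, which
    makes this criterion prone to truncating informative panels.  Ties
    break toward the smaller column index for determinism.  The final LDA
    is refit on all data over the selected columns; a singular
    within-class covariance triggers a shrinkage-regularized refit with a
    warning.  ``cv_accuracy_`` reports the stratified-CV accuracy of the
    final panel under either criterion.
    """

    def __init__(
        self,
        criterion: str = "wilks",
        cv: int = 5,
        tol: float | None = None,
        f_to_enter: float = 3.84,
        f_to_remove: float = 2.71,
        max_variables: int | None = None,
    ):
        self.criterion = criterion
        self.cv = cv
        self.tol = tol
        self.f_to_enter = f_to_enter
        self.f_to_remove = f_to_remove
        self.max_variables = max_variables

    def _cv_accuracy(self, X: np.ndarray, y: np.ndarray, cols: list[int]) -> float:
        if not cols:
            _, counts = np.unique(y, return_counts=True)
            return counts.max() / y.size
        accs = []
        for tr, te in self._splitter.split(X, y):
            lda = LinearDiscriminantAnalysis()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lda.fit(X[np.ix_(tr, cols)], y[tr])
            accs.append((lda.predict(X[np.ix_(te, cols)]) == y[te]).mean())
        return float(np.mean(accs))

    @staticmethod
    def _wilks_lambda(X: np.ndarray, y: np.ndarray, cols: list[int]) -> float:
        """det(W)/det(T) over the selected columns (1.0 for the empty set)."""
        if not cols:
            return 1.0
        Xs = X[:, cols]
        total = Xs - Xs.mean(axis=0)
        T = total.T @ total
        W = np.zeros_like(T)
        for c in np.unique(y):
            g = Xs[y == c] - Xs[y == c].mean(axis=0)
            W += g.T @ g
        sign_t, logdet_t = np.linalg.slogdet(T)
        sign_w, logdet_w = np.linalg.slogdet(W)
        if sign_t <= 0:  # degenerate (collinear) subset carries no information
            return 1.0
        if sign_w <= 0:
            return 0.0
        return float(np.exp(logdet_w - logdet_t))

    def _f_change(self, lam_small: float, lam_large: float, n: int, p_small: int) -> float:
        """Partial F for adding one variable to a p_small-variable model
        (two groups)."""
        if lam_large <= 0:
            return np.inf
        return (n - 2 - p_small) * (lam_small / lam_large - 1.0)

    def _fit_wilks(self, X: np.ndarray, y: np.ndarray, limit: int) -> list[int]:
        n = y.size
        selected: list[int] = []
        lam = 1.0
        while len(selected) < limit:
            # forward step
            best = None
            for j in range(X.shape[1]):
                if j in selected:
                    continue
                lam_j = self._wilks_lambda(X, y, selected + [j])
                f = self._f_change(lam, lam_j, n, len(selected))
                if best is None or (f, -j) > (best[0], -best[1]):
                    best = (f, j, lam_j)
            if best is None or best[0] <= self.f_to_enter:
                break
            selected.append(best[1])
            lam = best[2]
            # backward step: drop any variable whose F-to-remove collapsed
            changed = True
            while changed and len(selected) > 1:
                changed = False
                for j in list(selected):
                    rest = [c for c in selected if c != j]
                    lam_rest = self._wilks_lambda(X, y, rest)
                    f_rm = self._f_change(lam_rest, lam, n, len(rest))
                    if f_rm < self.f_to_remove:
                        selected = rest
                        lam = lam_rest
                        changed = True
                        break
        return selected

    def _fit_cv(self, X: np.ndarray, y: np.ndarray, limit: int, tol: float) -> list[int]:
        selected: list[int] = []
        best = self._cv_accuracy(X, y, selected)
        while len(selected) < limit:
            scores = [
                (self._cv_accuracy(X, y, selected + [j]), -j, j)
                for j in range(X.shape[1])
                if j not in selected
            ]
            if not scores:
                break
            acc, _, j = max(scores)
            if acc > best + tol:
                selected.append(j)
                best = acc
            else:
                break
        return selected

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, counts = np.unique(y, return_counts=True)
        if self.classes_.size != 2:
            raise ValueError("two classes required")
        n = y.size
        tol = self.tol if self.tol is not None else 1.0 / (2 * n)
        n_splits = int(min(self.cv, counts.min()))
        if n_splits < 2:
            raise ValueError("too few samples per class for stratified CV")
        self._splitter = StratifiedKFold(n_splits=n_splits, shuffle=False)

        limit = self.max_variables or X.shape[1]
        if self.criterion == "wilks":
            selected = self._fit_wilks(X, y, limit)
        elif self.criterion == "cv_accuracy":
            selected = self._fit_cv(X, y, limit, tol)
        else:
            raise ValueError(f"unknown criterion {self.criterion!r}")

        self.selected_idx_ = np.asarray(selected, dtype=int)
        self.cv_accuracy_ = self._cv_accuracy(X, y, selected)
        if selected:
            lda = LinearDiscriminantAnalysis()
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                lda.fit(X[:, selected], y)
            if any("collinear" in str(w.message).lower() for w in caught):
                warnings.warn("singular within-class covariance; using shrinkage LDA")
                lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
                lda.fit(X[:, selected], y)
            self.lda_ = lda
        else:
            self.lda_ = None
            self._majority_ = self.classes_[int(np.argmax(counts))]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "selected_idx_")
        X = np.asarray(X, dtype=float)
        if self.lda_ is None:
            return np.zeros(X.shape[0])
        return self.lda_.decision_function(X[:, self.selected_idx_])

    def predict(self, X):
        check_is_fitted(self, "selected_idx_")
        X = np.asarray(X, dtype=float)
        if self.lda_ is None:
            return np.full(X.shape[0], self._majority_)
        return self.lda_.predict(X[:, self.selected_idx_])


# --------------------------------------------------------------------------
# stepwise-AIC logistic regression
# --------------------------------------------------------------------------

def _logit_aic(y01: np.ndarray, X: np.ndarray, cols: list[int]) -> tuple[float, object | None, bool]:
    """AIC of a logit fit on the given columns; (aic, result, separated)."""
    design = sm.add_constant(X[:, cols] if cols else np.empty((y01.size, 0)), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y01, design).fit(disp=0, maxiter=200)
    except Exception:
        return np.inf, None, True
    separated = (not res.mle_retvals.get("converged", True)) or np.any(
        np.abs(res.params) > 1e3
    )
    return float(res.aic), res, separated


class StepwiseLogisticAIC(ClassifierMixin, BaseEstimator):
    """Bidirectional stepwise logistic regression minimizing AIC.

    The search starts from the intercept-only model, and at each step
    applies the single addition or removal that lowers AIC the most.
    Perfect separation (detected by a failed or diverging ML fit) stops
    the search and triggers a ridge-penalized fallback fit, flagged in
    ``flags_``.
    """

    def __init__(self, max_steps: int = 50):
        self.max_steps = max_steps

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("two classes required")
        y01 = (y == self.classes_[1]).astype(float)

        selected: list[int] = []
        self.flags_ = []
        best_aic, best_res, _ = _logit_aic(y01, X, selected)
        for _step in range(self.max_steps):
            moves = []
            for j in range(X.shape[1]):
                cand = selected + [j] if j not in selected else [c for c in selected if c != j]
                aic, res, sep = _logit_aic(y01, X, cand)
                moves.append((aic, sep, cand, res))
            moves.sort(key=lambda mv: (mv[0], len(mv[2])))
            aic, sep, cand, res = moves[0]
            if sep and aic < best_aic - 1e-9:
                selected = cand
                self.flags_.append("perfect_separation")
                best_res = None
                break
            if aic < best_aic - 1e-9:
                best_aic, best_res, selected = aic, res, cand
            else:
                break

        self.selected_idx_ = np.asarray(sorted(selected), dtype=int)
        if best_res is not None and len(selected):
            order = [selected.index(j) for j in self.selected_idx_]
            params = np.asarray(best_res.params)
            self.intercept_ = float(params[0])
            self.coef_ = params[1:][order]
            self.aic_ = best_aic
        elif "perfect_separation" in self.flags_ and len(selected):
            clf = LogisticRegression(penalty="l2", C=1.0, max_iter=1000)
            clf.fit(X[:, self.selected_idx_], y01)
            self.intercept_ = float(clf.intercept_[0])
            self.coef_ = clf.coef_.ravel()
            self.aic_ = float("nan")
        else:  # intercept-only
            p1 = y01.mean()
            p1 = min(max(p1, 1e-9), 1 - 1e-9)
            self.intercept_ = float(np.log(p1 / (1 - p1)))
            self.coef_ = np.zeros(0)
            self.aic_ = best_aic
        return self

    def decision_function(self, X):
        check_is_fitted(self, "selected_idx_")
        X = np.asarray(X, dtype=float)
        if self.selected_idx_.size == 0:
            return np.full(X.shape[0], self.intercept_)
        return self.intercept_ + X[:, self.selected_idx_] @ self.coef_

    def predict(self, X):
        eta = self.decision_function(X)
        return np.where(eta >= 0, self.classes_[1], self.classes_[0])


# --------------------------------------------------------------------------
# functional wrappers and the end-to-end report
# --------------------------------------------------------------------------

def stepwise_lda(X, y, cv_folds: int = 5, tol: float | None = None) -> StepwiseLDA:
    return StepwiseLDA(cv=cv_folds, tol=tol).fit(X, y)


def stepwise_logistic_aic(X, y) -> StepwiseLogisticAIC:
    return StepwiseLogisticAIC().fit(X, y)


def _histograms(scores: np.ndarray, y: np.ndarray, classes: np.ndarray, bins: int = 10) -> dict:
    """Per-class binned counts of the discriminant score."""
    lo, hi = float(np.min(scores)), float(np.max(scores))
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, bins + 1)
    return {
        "bin_edges": edges.tolist(),
        "counts": {
            str(c): np.histogram(scores[y == c], bins=edges)[0].tolist() for c in classes
        },
    }


def evaluate_panel(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    candidates: list[int],
    method: str = "lda",
    feature_ids: list[str] | None = None,
    cv_folds: int = 5,
) -> EvalReport:
    """Fit a panel on the learning sample only and score it end to end.

    ``candidates`` are column indices the stepwise search may use; an
    empty list yields a majority-rule baseline report.  ROC/AUC is
    reported for resubstitution, cross-validated (post-selection, on the
    learning sample) and held-out test scores, labeled accordingly.
    """
    X_train, y_train = np.asarray(X_train, float), np.asarray(y_train)
    X_test, y_test = np.asarray(X_test, float), np.asarray(y_test)
    classes = np.unique(y_train)
    names = feature_ids or [f"var{j}" for j in range(X_train.shape[1])]

    if len(candidates) == 0:
        _, counts = np.unique(y_train, return_counts=True)
        majority = classes[int(np.argmax(counts))]
        panel = FittedPanel(method, [], {}, flags=["empty_candidates_majority_baseline"])
        pred_tr = np.full(y_train.size, majority)
        pred_te = np.full(y_test.size, majority)
        zeros_tr, zeros_te = np.zeros(y_train.size), np.zeros(y_test.size)
        report = EvalReport(
            panel,
            {
                "learning": confusion_summary(y_train, pred_tr, classes),
                "test": confusion_summary(y_test, pred_te, classes),
            },
            {
                "resubstitution": roc_auc(zeros_tr, y_train),
                "test": roc_auc(zeros_te, y_test),
            },
            {},
            {},
        )
        return report

    cand = list(candidates)
    Xtr_c, Xte_c = X_train[:, cand], X_test[:, cand]
    if method == "lda":
        clf = StepwiseLDA(cv=cv_folds)
    elif method == "logistic":
        clf = StepwiseLogisticAIC()
    else:
        raise ValueError(f"unknown method {method!r}")
    clf.fit(Xtr_c, y_train)
    panel_cols = [cand[j] for j in clf.selected_idx_]
    coefs: dict = {}
    if isinstance(clf, StepwiseLogisticAIC):
        coefs = {"intercept": clf.intercept_,
                 "beta": {names[c]: float(b) for c, b in zip(panel_cols, clf.coef_)}}
    elif clf.lda_ is not None:
        coefs = {"intercept": float(clf.lda_.intercept_[0]),
                 "beta": {names[c]: float(b)
                          for c, b in zip(panel_cols, clf.lda_.coef_.ravel())}}
    panel = FittedPanel(method, [names[c] for c in panel_cols], coefs,
                        flags=list(getattr(clf, "flags_", [])))

    scores_tr = clf.decision_function(Xtr_c)
    scores_te = clf.decision_function(Xte_c)
    roc: dict[str, RocResult] = {
        "resubstitution": roc_auc(scores_tr, y_train),
        "test": roc_auc(scores_te, y_test),
    }
    if panel_cols:
        # post-selection CV scores of the refit panel (selection not re-run per fold)
        try:
            n_splits = int(min(cv_folds, np.unique(y_train, return_counts=True)[1].min()))
            if isinstance(clf, StepwiseLDA):
                refit = LinearDiscriminantAnalysis()
            else:
                refit = LogisticRegression(max_iter=1000)
            cv_scores = cross_val_predict(
                refit, X_train[:, panel_cols], y_train,
                cv=StratifiedKFold(n_splits=n_splits), method="decision_function",
            )
            roc["cv"] = roc_auc(cv_scores, y_train)
        except ValueError:
            pass

    confusion = {
        "learning": confusion_summary(y_train, clf.predict(Xtr_c), classes),
        "test": confusion_summary(y_test, clf.predict(Xte_c), classes),
    }

    pca_block: dict = {}
    if panel_cols:
        X_all = np.vstack([X_train[:, panel_cols], X_test[:, panel_cols]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores, evr, loadings = pca_scores(X_all)
        pca_block = {
            "variables": [names[c] for c in panel_cols],
            "scores": scores.tolist(),
            "explained_variance_ratio": evr.tolist(),
            "loadings": loadings.tolist(),
            "split": ["learning"] * y_train.size + ["test"] * y_test.size,
            "labels": np.concatenate([y_train, y_test]).tolist(),
        }

    hist = _histograms(np.concatenate([scores_tr, scores_te]),
                       np.concatenate([y_train, y_test]), classes)
    return EvalReport(panel, confusion, roc, pca_block, hist)
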