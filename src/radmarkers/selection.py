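"""Resampling stability selection of discriminant features.

Two engines, both retaining features that recur among the top importances
across many resampled fits:

* PLS-DA importance-frequency selection -- the data are split 10 times
  into a 70% learning and 30% test sample; after each fit the 30
  variables with the highest VIP (variable importance in projection) are
  recorded, and "good" variables are those appearing in at least 8 of the
  10 draws.
* Random-Forest frequency selection -- an elementary analysis grows 1000
  trees, each split choosing among 20 randomly drawn variables, on a
  bootstrap sample of the full size; the 10 most important variables
  (Gini mean decrease in impurity) are recorded, the analysis is repeated
  30 times with fresh resampling, and variables are retained by their
  top-10 membership count.

Both selectors follow the scikit-learn estimator contract and can be used
inside sklearn pipelines; module-level functions wrap them for use with
:class:`~radmarkers.containers.LabeledMatrix` inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_X_y, check_is_fitted

from .containers import LabeledMatrix

__all__ = [
    "PlsSelectParams",
    "RfSelectParams",
    "SelectionResult",
    "PLSDAModel",
    "fit_plsda",
    "vip_scores",
    "PLSDAStabilitySelector",
    "RandomForestStabilitySelector",
    "plsda_stability_select",
    "rf_stability_select",
    "rf_importance_run",
]


def child_seed(master: int | None, *path: int) -> int:
    """Deterministic 31-bit child seed for a named substream."""
    master = 0 if master is None else int(master)
    ss = np.random.SeedSequence([master, *path])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


# --------------------------------------------------------------------------
# PLS-DA core fit and VIP
# --------------------------------------------------------------------------

@dataclass
class PLSDAModel:
    """A fitted two-class PLS-DA model on centered, unit-variance data."""

    x_weights: np.ndarray       # (p, A), zero rows for dropped columns
    x_scores: np.ndarray        # (n, A)
    y_loadings: np.ndarray      # (A,)
    ssy: np.ndarray             # y-variance explained per component
    x_mean: np.ndarray
    x_scale: np.ndarray
    kept: np.ndarray            # boolean mask of non-constant columns
    classes: np.ndarray
    _pls: PLSRegression

    @property
    def n_components(self) -> int:
        return self.x_weights.shape[1]

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float)[:, self.kept] - self.x_mean) / self.x_scale
        return self._pls.predict(Xs).ravel()

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, self.classes[1], self.classes[0])


def fit_plsda(X: np.ndarray, y: np.ndarray, n_components: int = 2) -> PLSDAModel:
    """Deterministic PLS-DA fit: center + unit-variance scale X, regress
    against +/-1-coded class membership.

    Zero-variance columns are dropped with a warning (their weights and
    VIP are reported as 0).  ``n_components`` is capped at the available
    rank bound min(n_samples - 1, n_kept_features).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"PLS-DA needs exactly two classes, got {classes.size}")
    ypm = np.where(y == classes[1], 1.0, -1.0)

    sd = X.std(axis=0)
    kept = sd > 0
    if not kept.all():
        warnings.warn(f"dropping {int((~kept).sum())} zero-variance column(s)")
    if not kept.any():
        raise ValueError("all columns have zero variance")
    Xk = X[:, kept]
    mean, scale = Xk.mean(axis=0), Xk.std(axis=0)
    Xs = (Xk - mean) / scale

    a = int(min(n_components, X.shape[0] - 1, int(kept.sum())))
    if a < 1:
        raise ValueError("cannot fit PLS with zero components")
    pls = PLSRegression(n_components=a, scale=False)
    pls.fit(Xs, ypm)

    p = X.shape[1]
    w = np.zeros((p, a))
    w[kept] = pls.x_weights_
    t = pls.x_scores_
    q = pls.y_loadings_.ravel()
    ssy = (q**2) * np.einsum("ia,ia->a", t, t)
    return PLSDAModel(w, t, q, ssy, mean, scale, kept, classes, pls)


def vip_scores(model: PLSDAModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SSY_a (w_aj / ||w_a||)^2 / sum_a SSY_a ), so
    the mean squared VIP over the p variables equals 1 and
    sum_j VIP_j^2 = p exactly.
    """
    w = model.x_weights
    p = w.shape[0]
    norms = np.linalg.norm(w, axis=0)
    norms[norms == 0] = 1.0
    wn2 = (w / norms) ** 2
    ssy = model.ssy
    denom = ssy.sum()
    if denom <= 0:
        return np.zeros(p)
    return np.sqrt(p * (wn2 @ ssy) / denom)


# --------------------------------------------------------------------------
# parameter blocks and result container
# --------------------------------------------------------------------------

@dataclass
class PlsSelectParams:
    n_repeats: int = 10
    train_frac: float = 0.70
    top_k: int = 30
    min_freq: int = 8
    n_components: int = 2
    seed: int = 0

    def validate(self, n_features: int) -> None:
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        if self.min_freq > self.n_repeats:
            raise ValueError("min_freq must be <= n_repeats")
        if self.top_k >= n_features:
            raise ValueError("top_k must be < n_features")


@dataclass
class RfSelectParams:
    n_trees: int = 1000
    mtry: int = 20
    n_iterations: int = 30
    top_k: int = 10
    retain_min_count: int = 24
    importance: str = "gini"  # or "permutation"
    seed: int = 0

    def validate(self, n_features: int) -> None:
        if self.mtry > n_features:
            raise ValueError("mtry must be <= n_features")
        if self.retain_min_count > self.n_iterations:
            raise ValueError("retain_min_count must be <= n_iterations")


@dataclass
class SelectionResult:
    """Frequencies and the retained feature set of one selection run."""

    method: str
    frequencies: dict[str, int]
    selected: list[str]
    params: dict
    repeat_reports: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "params": self.params,
            "frequencies": self.frequencies,
            "selected": self.selected,
            "repeat_reports": self.repeat_reports,
        }


# --------------------------------------------------------------------------
# estimators
# --------------------------------------------------------------------------

def _top_k_stable(importances: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest values; ties resolved to the smaller index."""
    return np.argsort(-importances, kind="stable")[:k]


class PLSDAStabilitySelector(SelectorMixin, BaseEstimator):
    """Repeated-split PLS-DA importance-frequency feature selection.

    On each of ``n_repeats`` stratified 70/30 splits a PLS-DA model is fit
    on the learning sample, variables are ranked by VIP, and the ``top_k``
    are recorded; features recorded at least ``min_freq`` times are
    selected.  Per-repeat learning/test confusion summaries are kept for
    audit.

    Attributes (after fit): ``frequencies_`` (per-feature counts),
    ``support_``, ``selected_idx_``, ``repeat_reports_``.
    """

    def __init__(
        self,
        n_repeats: int = 10,
        train_frac: float = 0.70,
        top_k: int = 30,
        min_freq: int = 8,
        n_components: int = 2,
        random_state: int | None = 0,
    ):
        self.n_repeats = n_repeats
        self.train_frac = train_frac
        self.top_k = top_k
        self.min_freq = min_freq
        self.n_components = n_components
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        PlsSelectParams(
            self.n_repeats, self.train_frac, self.top_k, self.min_freq,
            self.n_components, 0,
        ).validate(X.shape[1])
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2:
            raise ValueError("two classes required")
        if counts.min() < 4:
            raise ValueError("each class needs at least 4 samples")

        freq = np.zeros(X.shape[1], dtype=int)
        reports = []
        for r in range(self.n_repeats):
            seed_r = child_seed(self.random_state, 1, r)
            try:
                Xtr, Xte, ytr, yte = train_test_split(
                    X, y, train_size=self.train_frac, stratify=y, random_state=seed_r
                )
            except ValueError as exc:  # pragma: no cover - guarded above
                raise ValueError(f"stratified split impossible: {exc}") from exc
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_plsda(Xtr, ytr, self.n_components)
            vip = vip_scores(model)
            freq[_top_k_stable(vip, self.top_k)] += 1
            reports.append(
                {
                    "repeat": r,
                    "train_accuracy": float((model.predict(Xtr) == ytr).mean()),
                    "test_accuracy": float((model.predict(Xte) == yte).mean()),
                    "n_train": int(len(ytr)),
                    "n_test": int(len(yte)),
                }
            )

        self.n_features_in_ = X.shape[1]
        self.classes_ = classes
        self.frequencies_ = freq
        threshold = self.min_freq if self.min_freq >= 1 else 1
        self.support_ = freq >= threshold
        self.selected_idx_ = np.flatnonzero(self.support_)
        self.repeat_reports_ = reports
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


class RandomForestStabilitySelector(SelectorMixin, BaseEstimator):
    """Iterated Random-Forest top-k frequency feature selection.

    Each of ``n_iterations`` elementary analyses grows ``n_trees`` CART
    trees on bootstrap samples of the full size with ``mtry`` candidate
    variables per split, ranks all variables by importance, and records
    the ``top_k``; features recorded at least ``retain_min_count`` times
    are selected.
    """

    def __init__(
        self,
        n_trees: int = 1000,
        mtry: int = 20,
        n_iterations: int = 30,
        top_k: int = 10,
        retain_min_count: int = 24,
        importance: str = "gini",
        random_state: int | None = 0,
    ):
        self.n_trees = n_trees
        self.mtry = mtry
        self.n_iterations = n_iterations
        self.top_k = top_k
        self.retain_min_count = retain_min_count
        self.importance = importance
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        RfSelectParams(
            self.n_trees, self.mtry, self.n_iterations, self.top_k,
            self.retain_min_count, self.importance, 0,
        ).validate(X.shape[1])
        if X.shape[0] < 8:
            raise ValueError("need at least 8 samples")
        if np.unique(y).size != 2:
            raise ValueError("two classes required")

        freq = np.zeros(X.shape[1], dtype=int)
        for it in range(self.n_iterations):
            imp = _forest_importances(
                X, y, self.n_trees, self.mtry, self.importance,
                child_seed(self.random_state, 2, it),
            )
            freq[_top_k_stable(imp, self.top_k)] += 1

        self.n_features_in_ = X.shape[1]
        self.frequencies_ = freq
        self.support_ = freq >= max(self.retain_min_count, 1)
        self.selected_idx_ = np.flatnonzero(self.support_)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def _forest_importances(
    X: np.ndarray, y: np.ndarray, n_trees: int, mtry: int, importance: str, seed: int
) -> np.ndarray:
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=mtry,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    if importance == "gini":
        return rf.feature_importances_
    if importance == "permutation":
        res = permutation_importance(rf, X, y, n_repeats=5, random_state=seed, n_jobs=1)
        return res.importances_mean
    raise ValueError(f"unknown importance {importance!r}")


def rf_importance_run(
    X: np.ndarray, y: np.ndarray, n_trees: int = 1000, mtry: int = 20,
    seed: int = 0, importance: str = "gini",
) -> tuple[np.ndarray, np.ndarray]:
    """One elementary forest analysis: (full descending ranking, importances)."""
    X, y = check_X_y(X, y)
    if mtry > X.shape[1]:
        raise ValueError("mtry must be <= n_features")
    imp = _forest_importances(X, y, n_trees, mtry, importance, seed)
    return np.argsort(-imp, kind="stable"), imp


# --------------------------------------------------------------------------
# LabeledMatrix wrappers
# --------------------------------------------------------------------------

def _as_result(
    method: str, selector, feature_ids: Sequence[str], params: dict
) -> SelectionResult:
    freq = {fid: int(c) for fid, c in zip(feature_ids, selector.frequencies_)}
    selected = [feature_ids[j] for j in selector.selected_idx_]
    reports = getattr(selector, "repeat_reports_", [])
    return SelectionResult(method, freq, selected, params, reports)


def plsda_stability_select(
    m: LabeledMatrix, labels: np.ndarray, params: PlsSelectParams | None = None
) -> SelectionResult:
    """Run PLS-DA stability selection on log-intensities of a LabeledMatrix."""
    params = params or PlsSelectParams()
    sel = PLSDAStabilitySelector(
        params.n_repeats, params.train_frac, params.top_k, params.min_freq,
        params.n_components, params.seed,
    ).fit(m.log_values(), np.asarray(labels))
    return _as_result("plsda", sel, m.feature_ids, asdict(params))


def rf_stability_select(
    m: LabeledMatrix, labels: np.ndarray, params: RfSelectParams | None = None
) -> SelectionResult:
    """Run Random-Forest frequency selection on log-intensities."""
    params = params or RfSelectParams()
    sel = RandomForestStabilitySelector(
        params.n_trees, params.mtry, params.n_iterations, params.top_k,
        params.retain_min_count, params.importance, params.seed,
    ).fit(m.log_values(), np.asarray(labels))
    return _as_result("rf", sel, m.feature_ids, asdict(params))
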