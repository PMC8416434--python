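"""Binary classifiers and the 10-fold cross-validation contract.

Three estimators share a common sklearn interface (fit / predict /
predict_proba / decision_function, trailing-underscore fitted
attributes): elastic-net penalized logistic regression with the penalty
strength chosen by inner cross-validated binomial deviance, an RBF SVM
with the margin parameter chosen from the fixed grid (0.1, 0.5, 1, 5, 10)
by inner cross-validated AUC, and a random forest with per-split feature
subsampling floor(sqrt(p)). All three z-score features inside ``fit``
using training statistics only, so cross-validation never leaks held-out
information (the forest is scale-invariant but standardizes anyway for
uniformity of the reported coefficients/importances).

:func:`cross_validate` runs the stratified 10-fold outer loop, collecting
per-fold AUC / sensitivity / specificity and, for the elastic net, the
per-fold coefficient vectors that feed the feature-survival rule.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, KFold
from sklearn.svm import SVC
from scipy.special import expit
from scipy.stats import rankdata

from ._cd import binomial_deviance, en_logistic_path, lambda_path
from .errors import (
    FitFailureError,
    InfeasibleStratificationError,
    MetricUndefinedError,
)
from .features import FeatureMatrix

EN, SVM, RF = "EN", "SVM", "RF"


def derive_seed(master: int, *tags) -> int:
    """Deterministic substream seed (< 2^31) from a master seed and tags."""
    h = hashlib.sha256(repr((int(master),) + tuple(tags)).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


# ---------------------------------------------------------------- folds


def stratified_kfold(labels, k: int = 10, seed: int = 0, stratified: bool = True) -> np.ndarray:
    """Fold assignments 1..k, one per subject, deterministic given seed.

    Stratified folds keep per-fold class proportions within one subject
    of the global proportion; a class with fewer than k members makes
    stratification infeasible.
    """
    y = np.asarray(labels, dtype=int)
    if stratified:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < k:
            raise InfeasibleStratificationError(
                f"smallest class has {counts.min()} members < {k} folds"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        if len(y) < k:
            raise InfeasibleStratificationError(f"{len(y)} subjects < {k} folds")
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    assign = np.zeros(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y), start=1):
        assign[test_idx] = fold
    return assign


def _inner_folds(y: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified inner splits, reducing k to the smallest class if needed."""
    classes, counts = np.unique(y, return_counts=True)
    k_eff = int(min(k, counts.min()))
    if k_eff < 2:
        raise FitFailureError("fewer than two members in a training class")
    rng = np.random.default_rng(seed)
    fold = np.empty(len(y), dtype=int)
    for c in classes:
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % k_eff
    return [
        (np.flatnonzero(fold != f), np.flatnonzero(fold == f)) for f in range(k_eff)
    ]


def mann_whitney_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the Mann-Whitney concordance: probability a random case
    outranks a random control, ties counted at half credit."""
    labels = np.asarray(labels, dtype=int)
    r = rankdata(scores)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise MetricUndefinedError("AUC undefined for a single-class sample")
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


# ---------------------------------------------------------------- estimators


class _StandardizingClassifier(BaseEstimator, ClassifierMixin):
    """Shared z-scoring + input plumbing for the three classifiers."""

    def _prepare_fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise FitFailureError(
                f"binary classifier requires 2 classes in training data, got {len(self.classes_)}"
            )
        yb = (y == self.classes_[1]).astype(float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return (X - self.mean_) / self.scale_, yb

    def _prepare_predict(self, X):
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        return (X - self.mean_) / self.scale_

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return np.where(p > 0.5, self.classes_[1], self.classes_[0])


class ElasticNetLogisticCV(_StandardizingClassifier):
    """Elastic-net logistic regression with inner-CV penalty selection.

    The mixing weight ``l1_ratio`` (default 0.5) balances the lasso and
    ridge penalties; the penalty strength is chosen by inner
    cross-validated binomial deviance over a log-spaced descending path
    from the null-model lambda_max. ``lambda_rule`` follows the glmnet
    conventions: "min" (default) picks the deviance minimum - the
    CV-optimal penalty, which also keeps the cross-validated AUC a
    continuous statistic under label permutation - while "1se" picks the
    largest penalty within one standard error of the minimum (the
    parsimonious choice). Coefficients are reported on the
    z-scored feature scale and may be exactly zero (lasso sparsity).

    Attributes (after fit): ``coef_``, ``intercept_``, ``lambda_``,
    ``lambda_path_``, ``cv_deviance_``, ``cv_deviance_se_``.
    """

    def __init__(
        self,
        l1_ratio: float = 0.5,
        n_lambdas: int = 30,
        lambda_min_ratio: float = 0.01,
        inner_cv: int = 10,
        lambda_rule: str = "min",
        penalty_free: tuple = (),
        tol: float = 1e-6,
        random_state: int = 0,
    ):
        self.l1_ratio = l1_ratio
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.inner_cv = inner_cv
        self.lambda_rule = lambda_rule
        self.penalty_free = penalty_free
        self.tol = tol
        self.random_state = random_state

    def _penalty_factor(self, p: int) -> np.ndarray | None:
        """Per-feature penalty factors; ``penalty_free`` lists column
        indices (or names when fit on a DataFrame) exempt from the
        penalty, e.g. covariates forced into the model."""
        if not self.penalty_free:
            return None
        pf = np.ones(p)
        names = list(getattr(self, "feature_names_in_", []))
        for item in self.penalty_free:
            if isinstance(item, str):
                if item not in names:
                    raise ValueError(f"unknown penalty-free column {item!r}")
                pf[names.index(item)] = 0.0
            else:
                pf[int(item)] = 0.0
        return pf

    def fit(self, X, y):
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError(f"unknown lambda_rule {self.lambda_rule!r}")
        Xs, yb = self._prepare_fit(X, y)
        pf = self._penalty_factor(Xs.shape[1])
        lams = lambda_path(
            Xs, yb, self.l1_ratio, self.n_lambdas, self.lambda_min_ratio, pf
        )
        folds = _inner_folds(yb.astype(int), self.inner_cv, self.random_state)
        dev_folds = np.zeros((len(folds), len(lams)))
        for fi, (tr, va) in enumerate(folds):
            Xt = Xs[tr]
            mu, sd = Xt.mean(0), Xt.std(0, ddof=0)
            sd = np.where(sd > 0, sd, 1.0)
            coefs, icepts, _ = en_logistic_path(
                (Xt - mu) / sd, yb[tr], lams, self.l1_ratio, self.tol,
                penalty_factor=pf,
            )
            dev_folds[fi] = binomial_deviance((Xs[va] - mu) / sd, yb[va], coefs, icepts)
        dev = dev_folds.mean(axis=0)
        dev_se = dev_folds.std(axis=0, ddof=1) / np.sqrt(len(folds))
        i_min = int(np.argmin(dev))
        if self.lambda_rule == "1se":
            # largest lambda (earliest on the descending path) within 1 SE
            best = int(np.flatnonzero(dev <= dev[i_min] + dev_se[i_min])[0])
        else:
            best = i_min
        self.cv_deviance_se_ = dev_se
        coefs, icepts, n_iter = en_logistic_path(
            Xs, yb, lams, self.l1_ratio, self.tol, penalty_factor=pf
        )
        if not np.all(np.isfinite(coefs[best])):
            raise FitFailureError("elastic-net path did not converge at any penalty")
        self.lambda_path_ = lams
        self.cv_deviance_ = dev
        self.lambda_ = float(lams[best])
        self.coef_ = coefs[best].copy()
        self.intercept_ = float(icepts[best])
        self.n_iter_ = int(n_iter[best])
        return self

    def decision_function(self, X):
        return self._prepare_predict(X) @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        p1 = expit(self.decision_function(X))
        return np.column_stack([1 - p1, p1])

    def coef_series(self) -> pd.Series:
        names = getattr(self, "feature_names_in_", None)
        if names is None:
            names = [f"x{j}" for j in range(len(self.coef_))]
        return pd.Series(self.coef_, index=names)


class GridSearchSVM(_StandardizingClassifier):
    """RBF (or linear) SVM; margin parameter C picked from a fixed grid.

    C is chosen from ``c_grid`` (default the clinical-pipeline grid
    0.1, 0.5, 1, 5, 10) by inner cross-validated AUC; the RBF bandwidth
    uses the median heuristic (gamma = 1 / median squared pairwise
    distance of the standardized training rows).
    """

    def __init__(
        self,
        c_grid: tuple = (0.1, 0.5, 1, 5, 10),
        kernel: str = "rbf",
        inner_cv: int = 10,
        random_state: int = 0,
    ):
        self.c_grid = c_grid
        self.kernel = kernel
        self.inner_cv = inner_cv
        self.random_state = random_state

    def _gamma(self, Xs):
        n = len(Xs)
        idx = np.arange(n)
        if n > 200:
            rng = np.random.default_rng(self.random_state)
            idx = rng.choice(n, 200, replace=False)
        sub = Xs[idx]
        d2 = np.sum((sub[:, None, :] - sub[None, :, :]) ** 2, axis=-1)
        med = np.median(d2[np.triu_indices(len(sub), k=1)])
        return 1.0 / med if med > 0 else "scale"

    def fit(self, X, y):
        Xs, yb = self._prepare_fit(X, y)
        gamma = self._gamma(Xs) if self.kernel == "rbf" else "scale"
        folds = _inner_folds(yb.astype(int), self.inner_cv, self.random_state)
        scores = []
        for C in self.c_grid:
            aucs = []
            for tr, va in folds:
                svc = SVC(C=C, kernel=self.kernel, gamma=gamma).fit(Xs[tr], yb[tr])
                if len(np.unique(yb[va])) < 2:
                    continue
                aucs.append(mann_whitney_auc(yb[va], svc.decision_function(Xs[va])))
            scores.append(np.mean(aucs) if aucs else 0.5)
        self.C_ = float(self.c_grid[int(np.argmax(scores))])
        self.cv_auc_ = np.asarray(scores)
        self.gamma_ = gamma
        self.svc_ = SVC(C=self.C_, kernel=self.kernel, gamma=gamma).fit(Xs, yb)
        return self

    def decision_function(self, X):
        return self.svc_.decision_function(self._prepare_predict(X))

    def predict_proba(self, X):
        # monotone squashing of the margin distance: the 0.5 threshold
        # coincides with the decision boundary
        p1 = expit(self.decision_function(X))
        return np.column_stack([1 - p1, p1])


class TunedRandomForest(_StandardizingClassifier):
    """Random forest with floor(sqrt(p)) features per split (Hastie default)."""

    def __init__(self, n_trees: int = 500, random_state: int = 0):
        self.n_trees = n_trees
        self.random_state = random_state

    def fit(self, X, y):
        Xs, yb = self._prepare_fit(X, y)
        self.mtry_ = max(1, int(np.sqrt(Xs.shape[1])))
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=self.mtry_,
            random_state=self.random_state,
        ).fit(Xs, yb.astype(int))
        self.feature_importances_ = self.forest_.feature_importances_
        return self

    def predict_proba(self, X):
        return self.forest_.predict_proba(self._prepare_predict(X))

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]


# ---------------------------------------------------------------- spec


@dataclass(frozen=True)
class ModelSpec:
    """Everything needed to instantiate one classifier reproducibly."""

    method: str = EN
    en_mixing: float = 0.5
    en_n_lambdas: int = 30
    en_lambda_min_ratio: float = 0.01
    en_lambda_rule: str = "min"
    en_penalize_covariates: bool = True
    en_tol: float = 1e-6
    svm_c_grid: tuple = (0.1, 0.5, 1, 5, 10)
    svm_kernel: str = "rbf"
    rf_n_trees: int = 500
    inner_cv_folds: int = 10
    outer_folds: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.method not in (EN, SVM, RF):
            raise ValueError(f"unknown method {self.method!r}")
        if not 0 < self.en_mixing <= 1:
            raise ValueError("en_mixing must be in (0, 1]")

    def make_estimator(self, seed: int | None = None):
        seed = self.seed if seed is None else seed
        if self.method == EN:
            return ElasticNetLogisticCV(
                l1_ratio=self.en_mixing,
                n_lambdas=self.en_n_lambdas,
                lambda_min_ratio=self.en_lambda_min_ratio,
                inner_cv=self.inner_cv_folds,
                lambda_rule=self.en_lambda_rule,
                tol=self.en_tol,
                random_state=seed,
            )
        if self.method == SVM:
            return GridSearchSVM(
                c_grid=self.svm_c_grid,
                kernel=self.svm_kernel,
                inner_cv=self.inner_cv_folds,
                random_state=seed,
            )
        return TunedRandomForest(n_trees=self.rf_n_trees, random_state=seed)


# ---------------------------------------------------------------- metrics


def evaluate_fold(scores, probs, labels) -> tuple[float, float, float]:
    """AUC (Mann-Whitney, ties at half credit), sensitivity, specificity.

    Sensitivity/specificity threshold the case probability at 0.5 with
    cases (label 1) positive.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise MetricUndefinedError("test fold contains a single class")
    auc = mann_whitney_auc(labels, scores)
    pred = np.asarray(probs) > 0.5
    pos, neg = labels == 1, labels == 0
    sens = float(np.mean(pred[pos]))
    spec = float(np.mean(~pred[neg]))
    return auc, sens, spec


@dataclass
class CVResult:
    """Per-fold metrics (and EN coefficients) for one model x combination."""

    method: str
    fold_assignments: pd.Series  # subject -> fold 1..k
    fold_metrics: pd.DataFrame  # columns fold, auc, sens, spec (proportions)
    coefficients: pd.DataFrame | None = None  # folds x features (EN only)
    combination_label: str = ""

    def to_tidy(self, contrast: str = "", method: str | None = None) -> pd.DataFrame:
        """Tidy per-fold rows (contrast, combination, method, fold, auc,
        sens, spec) matching the report-table layout after aggregation."""
        out = self.fold_metrics.copy()
        out.insert(0, "method", method or self.method)
        out.insert(0, "combination", self.combination_label)
        out.insert(0, "contrast", contrast)
        return out

    def summary(self) -> dict:
        """Mean and sample SD of each metric on the percent scale."""
        out = {}
        for m in ("auc", "sens", "spec"):
            vals = self.fold_metrics[m].to_numpy() * 100.0
            out[f"{m}_mean"] = float(vals.mean())
            out[f"{m}_sd"] = float(vals.std(ddof=1))
        return out

    @property
    def mean_auc(self) -> float:
        return self.summary()["auc_mean"]


def cross_validate(fm: FeatureMatrix, spec: ModelSpec, seed: int | None = None) -> CVResult:
    """Stratified 10-fold outer CV of one model on one feature matrix.

    Each fold fits on 9/10 of subjects (all preprocessing inside the
    fold) and is evaluated on the held-out tenth. Elastic-net coefficient
    vectors are retained per fold for the survival rule. Deterministic
    given the spec seed; ``seed`` overrides it (used by permutations).
    """
    master = spec.seed if seed is None else seed
    y = fm.y
    assign = stratified_kfold(
        y, spec.outer_folds, derive_seed(master, "folds"), spec.stratified
    )
    X = fm.X.to_numpy(dtype=float)
    columns = fm.X.columns
    rows, coef_rows = [], []
    for fold in range(1, spec.outer_folds + 1):
        test = assign == fold
        train = ~test
        est = spec.make_estimator(derive_seed(master, "fold", fold))
        if spec.method == EN and not spec.en_penalize_covariates:
            est.penalty_free = tuple(
                i for i, c in enumerate(columns) if str(c).startswith("cov_")
            )
        try:
            est.fit(X[train], y[train])
            scores = est.decision_function(X[test])
            probs = est.predict_proba(X[test])[:, 1]
            auc, sens, spec_ = evaluate_fold(scores, probs, y[test])
        except Exception as exc:
            raise type(exc)(f"fold {fold}: {exc}") from exc
        rows.append({"fold": fold, "auc": auc, "sens": sens, "spec": spec_})
        if spec.method == EN:
            coef_rows.append(pd.Series(est.coef_, index=columns, name=fold))
    return CVResult(
        method=spec.method,
        fold_assignments=pd.Series(assign, index=fm.X.index, name="fold"),
        fold_metrics=pd.DataFrame(rows),
        coefficients=pd.DataFrame(coef_rows) if coef_rows else None,
        combination_label=fm.combination.label() if fm.combination else "",
    )


def fit_en_fold(train_fm: FeatureMatrix, spec: ModelSpec, seed: int | None = None):
    """Fit one elastic-net training fold; thin wrapper over the estimator."""
    est = spec.make_estimator(spec.seed if seed is None else seed)
    if not isinstance(est, ElasticNetLogisticCV):
        raise ValueError("fit_en_fold requires an EN ModelSpec")
    return est.fit(train_fm.X, train_fm.y)


def fit_svm_fold(train_fm: FeatureMatrix, spec: ModelSpec, seed: int | None = None):
    est = spec.make_estimator(spec.seed if seed is None else seed)
    if not isinstance(est, GridSearchSVM):
        raise ValueError("fit_svm_fold requires an SVM ModelSpec")
    return est.fit(train_fm.X, train_fm.y)


def fit_rf_fold(train_fm: FeatureMatrix, spec: ModelSpec, seed: int | None = None):
    est = spec.make_estimator(spec.seed if seed is None else seed)
    if not isinstance(est, TunedRandomForest):
        raise ValueError("fit_rf_fold requires an RF ModelSpec")
    return est.fit(train_fm.X, train_fm.y)
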