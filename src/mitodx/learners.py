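"""The twelve base learners of the diagnostic benchmark.

Every learner is wrapped behind one contract: fit on a samples x features
DataFrame with binary labels (Treat = 1), expose calibrated probabilities
for the positive class, and report which features survive its own
selection rule:

* Lasso / Enet / glmBoost / plsRglm drop zero-coefficient features,
* stepwise logistic regression returns the variables in the final model,
* RF and GBM keep features with importance > 0,
* Ridge, SVM, LDA, XGBoost and NaiveBayes keep every feature.

Penalized logistic fits choose lambda by 10-fold cross-validated deviance;
boosting iteration counts come from cross-validation as well. All fits are
deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.cross_decomposition import PLSRegression
from sklearn.svm import SVC

__all__ = ["LearnerSpec", "FittedLearner", "LearnerError", "fit_learner", "extract_features",
           "ALGORITHMS", "SELECTOR_ALGORITHMS", "MODELER_ALGORITHMS"]

ALGORITHMS = (
    "Lasso", "Ridge", "Enet", "StepGLM", "SVM", "glmBoost",
    "LDA", "plsRglm", "RF", "GBM", "XGBoost", "NaiveBayes",
)
#: algorithms whose selection rule can shrink the feature set
SELECTOR_ALGORITHMS = ("Lasso", "Enet", "StepGLM", "glmBoost", "plsRglm", "RF", "GBM")
MODELER_ALGORITHMS = ALGORITHMS


class LearnerError(ValueError):
    pass


@dataclass(frozen=True)
class LearnerSpec:
    """One base algorithm plus the hyperparameters that identify it."""

    algorithm: str
    alpha: float | None = None  # elastic-net mixing, Enet only
    direction: str | None = None  # StepGLM: both / backward / forward

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise LearnerError(f"unknown algorithm {self.algorithm!r}")
        if self.algorithm == "Enet":
            if self.alpha is None or not 0 < self.alpha < 1:
                raise LearnerError(f"Enet requires alpha in (0, 1), got {self.alpha}")
        elif self.alpha is not None:
            raise LearnerError(f"alpha only applies to Enet, not {self.algorithm}")
        if self.algorithm == "StepGLM":
            if self.direction not in ("both", "backward", "forward"):
                raise LearnerError(
                    f"StepGLM direction must be both/backward/forward, got {self.direction}"
                )
        elif self.direction is not None:
            raise LearnerError(f"direction only applies to StepGLM, not {self.algorithm}")

    @property
    def label(self) -> str:
        if self.algorithm == "Enet":
            return f"Enet[α={self.alpha:g}]"
        if self.algorithm == "StepGLM":
            return f"StepGLM[{self.direction}]"
        return self.algorithm

    @property
    def can_select(self) -> bool:
        return self.algorithm in SELECTOR_ALGORITHMS

    @property
    def can_model(self) -> bool:
        return True


@dataclass
class FittedLearner:
    """A fitted learner: probability predictor plus its surviving features."""

    spec: LearnerSpec
    feature_names: list[str]
    selected: list[str]
    _predict: callable = field(repr=False)
    coef: pd.Series | None = None

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in X.columns]
        if missing:
            raise LearnerError(f"prediction input lacks features: {missing[:10]}")
        p = self._predict(X[self.feature_names].to_numpy(dtype=float))
        return np.clip(np.asarray(p, dtype=float), 0.0, 1.0)


def _check_xy(X: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if X.shape[1] < 1:
        raise LearnerError("no features to fit on")
    if X.isna().to_numpy().any():
        raise LearnerError("missing values in feature matrix")
    classes = np.unique(y)
    if classes.size < 2:
        raise LearnerError(f"labels contain a single class: {classes}")
    return y.astype(int)


def _cv_folds(y: np.ndarray, requested: int, seed: int) -> StratifiedKFold:
    smallest = int(np.bincount(y).min())
    folds = min(requested, smallest)
    if folds < requested:
        warnings.warn(
            f"reducing CV folds from {requested} to {folds} (small class)", stacklevel=3
        )
    if folds < 2:
        raise LearnerError("need at least 2 samples per class for cross-validation")
    return StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)


# --------------------------------------------------------------------------
# penalized logistic regression (Lasso / Ridge / Enet)

def _fit_glmnet(
    spec: LearnerSpec, X: pd.DataFrame, y: np.ndarray, seed: int, Cs=None
) -> FittedLearner:
    Xv = X.to_numpy(dtype=float)
    mean, sd = Xv.mean(axis=0), Xv.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xs = (Xv - mean) / sd
    cv = _cv_folds(y, 10, seed)
    if Cs is None:
        # a glmnet-like grid: three decades around the weakly-penalized regime
        Cs = np.logspace(-3, 2, 20)
    if spec.algorithm == "Enet":
        model = LogisticRegressionCV(
            Cs=Cs, cv=cv, penalty="elasticnet", solver="saga",
            l1_ratios=[spec.alpha], scoring="neg_log_loss", max_iter=5000,
            random_state=seed, n_jobs=1,
        )
    else:
        penalty = "l1" if spec.algorithm == "Lasso" else "l2"
        model = LogisticRegressionCV(
            Cs=Cs, cv=cv, penalty=penalty, solver="liblinear",
            scoring="neg_log_loss", max_iter=5000, random_state=seed, n_jobs=1,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        model.fit(Xs, y)
    coef = pd.Series(model.coef_[0], index=X.columns)
    if spec.algorithm == "Ridge":
        selected = list(X.columns)  # ridge never produces exact zeros
    else:
        selected = list(coef.index[np.abs(coef.to_numpy()) > 1e-10])

    def predict(A: np.ndarray) -> np.ndarray:
        return model.predict_proba((A - mean) / sd)[:, 1]

    return FittedLearner(spec, list(X.columns), selected, predict, coef)


# --------------------------------------------------------------------------
# stepwise logistic regression (AIC)

def _logistic_aic(Xv: np.ndarray, y: np.ndarray, cols: tuple[int, ...]) -> tuple[float, object]:
    # near-unpenalized fit; the weak ridge keeps separation finite
    model = LogisticRegression(penalty="l2", C=1e6, max_iter=2000, solver="lbfgs")
    A = Xv[:, cols] if cols else np.zeros((Xv.shape[0], 0))
    if A.shape[1] == 0:
        p = np.full(y.shape, y.mean())
        ll = -log_loss(y, p, normalize=False)
        return 2.0 * 1 - 2.0 * ll, None
    model.fit(A, y)
    p = model.predict_proba(A)[:, 1]
    ll = -log_loss(y, p, normalize=False)
    k = A.shape[1] + 1
    return 2.0 * k - 2.0 * ll, model


def _fit_stepglm(spec: LearnerSpec, X: pd.DataFrame, y: np.ndarray, seed: int) -> FittedLearner:
    Xv = X.to_numpy(dtype=float)
    p = Xv.shape[1]
    current: tuple[int, ...] = tuple(range(p)) if spec.direction in ("both", "backward") else ()
    best_aic, best_model = _logistic_aic(Xv, y, current)
    while True:
        moves: list[tuple[int, ...]] = []
        if spec.direction in ("forward", "both"):
            moves += [tuple(sorted(current + (j,))) for j in range(p) if j not in current]
        if spec.direction in ("backward", "both"):
            moves += [tuple(c for c in current if c != j) for j in current]
        scored = [(cand, *_logistic_aic(Xv, y, cand)) for cand in moves]
        if not scored:
            break
        cand, aic, model = min(scored, key=lambda t: t[1])
        if aic < best_aic - 1e-9:  # accept the single best move per round
            best_aic, best_model, current = aic, model, cand
        else:
            break
    selected = [X.columns[j] for j in current]
    model, cols = best_model, current

    def predict(A: np.ndarray) -> np.ndarray:
        if model is None:  # intercept-only
            return np.full(A.shape[0], float(y.mean()))
        return model.predict_proba(A[:, cols])[:, 1]

    return FittedLearner(spec, list(X.columns), selected, predict)


# --------------------------------------------------------------------------
# componentwise gradient boosting of the logistic loss (glmBoost)

def _glmboost_path(Xc: np.ndarray, y: np.ndarray, mstop: int, nu: float):
    """Boost and yield the coefficient vector after every iteration."""
    n, p = Xc.shape
    ybar = y.mean()
    f0 = np.log(ybar / (1.0 - ybar))
    f = np.full(n, f0)
    coef = np.zeros(p)
    ss = (Xc**2).sum(axis=0)
    ss[ss == 0] = np.inf
    for _ in range(mstop):
        u = y - 1.0 / (1.0 + np.exp(-f))
        b = Xc.T @ u / ss
        gain = b**2 * ss
        j = int(np.argmax(gain))
        coef[j] += nu * b[j]
        f += nu * b[j] * Xc[:, j]
        yield coef, f0


def _fit_glmboost(
    spec: LearnerSpec, X: pd.DataFrame, y: np.ndarray, seed: int,
    max_mstop: int = 1000, nu: float = 0.1, mstop: int | None = None,
) -> FittedLearner:
    Xv = X.to_numpy(dtype=float)
    mean = Xv.mean(axis=0)
    Xc = Xv - mean
    if mstop is None:
        cv = _cv_folds(y, 10, seed)
        risks = np.zeros(max_mstop)
        for tr, te in cv.split(Xc, y):
            for m, (coef, f0) in enumerate(_glmboost_path(Xc[tr], y[tr], max_mstop, nu)):
                eta = f0 + Xc[te] @ coef
                risks[m] += np.sum(np.log1p(np.exp(-np.where(y[te] == 1, eta, -eta))))
        mstop = int(np.argmin(risks)) + 1
    for coef, f0 in _glmboost_path(Xc, y, mstop, nu):
        pass
    coef_s = pd.Series(coef, index=X.columns)
    selected = list(coef_s.index[np.abs(coef_s.to_numpy()) > 0])

    def predict(A: np.ndarray) -> np.ndarray:
        eta = f0 + (A - mean) @ coef
        return 1.0 / (1.0 + np.exp(-eta))

    return FittedLearner(spec, list(X.columns), selected, predict, coef_s)


# --------------------------------------------------------------------------
# PLS logistic regression (plsRglm-style)

def _fit_plsrglm(
    spec: LearnerSpec, X: pd.DataFrame, y: np.ndarray, seed: int, max_comp: int = 5
) -> FittedLearner:
    Xv = X.to_numpy(dtype=float)
    mean, sd = Xv.mean(axis=0), Xv.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xs = (Xv - mean) / sd
    max_comp = min(max_comp, Xs.shape[1], Xs.shape[0] - 1)
    cv = _cv_folds(y, 10, seed)
    errs = []
    for ncomp in range(1, max_comp + 1):
        miss = 0
        for tr, te in cv.split(Xs, y):
            pls = PLSRegression(n_components=ncomp, scale=False)
            pls.fit(Xs[tr], y[tr].astype(float))
            lr = LogisticRegression(penalty=None, max_iter=2000)
            lr.fit(pls.transform(Xs[tr]), y[tr])
            miss += int((lr.predict(pls.transform(Xs[te])) != y[te]).sum())
        errs.append(miss)
    ncomp = int(np.argmin(errs)) + 1
    pls = PLSRegression(n_components=ncomp, scale=False)
    pls.fit(Xs, y.astype(float))
    lr = LogisticRegression(penalty=None, max_iter=2000)
    lr.fit(pls.transform(Xs), y)
    beta = (pls.x_rotations_ @ lr.coef_[0]) / sd  # per original feature
    coef_s = pd.Series(beta, index=X.columns)
    selected = list(coef_s.index[np.abs(coef_s.to_numpy()) > 1e-8])

    def predict(A: np.ndarray) -> np.ndarray:
        return lr.predict_proba(pls.transform((A - mean) / sd))[:, 1]

    return FittedLearner(spec, list(X.columns), selected, predict, coef_s)


# --------------------------------------------------------------------------
# GBM with cross-validated number of trees

def _fit_gbm(
    spec: LearnerSpec, X: pd.DataFrame, y: np.ndarray, seed: int,
    max_trees: int = 300, depth: int = 2, lr: float = 0.1,
) -> FittedLearner:
    Xv = X.to_numpy(dtype=float)
    cv = _cv_folds(y, 10, seed)
    losses = np.zeros(max_trees)
    for tr, te in cv.split(Xv, y):
        m = GradientBoostingClassifier(
            n_estimators=max_trees, max_depth=depth, learning_rate=lr, random_state=seed
        )
        m.fit(Xv[tr], y[tr])
        for i, proba in enumerate(m.staged_predict_proba(Xv[te])):
            losses[i] += log_loss(y[te], proba[:, 1], labels=[0, 1], normalize=False)
    best = int(np.argmin(losses)) + 1
    model = GradientBoostingClassifier(
        n_estimators=best, max_depth=depth, learning_rate=lr, random_state=seed
    )
    model.fit(Xv, y)
    imp = pd.Series(model.feature_importances_, index=X.columns)
    selected = list(imp.index[imp.to_numpy() > 0])

    def predict(A: np.ndarray) -> np.ndarray:
        return model.predict_proba(A)[:, 1]

    return FittedLearner(spec, list(X.columns), selected, predict)


# --------------------------------------------------------------------------
# XGBoost with cross-validated number of rounds

def _fit_xgboost(
    spec: LearnerSpec, X: pd.DataFrame, y: np.ndarray, seed: int,
    max_rounds: int = 500, early_stopping: int = 25,
) -> FittedLearner:
    params = {
        "objective": "binary:logistic",
        "max_depth": 6,
        "eta": 0.3,
        "seed": seed,
        "nthread": 1,
        "eval_metric": "logloss",
    }
    dtrain = xgb.DMatrix(X.to_numpy(dtype=float), label=y)
    folds = _cv_folds(y, 5, seed).n_splits
    cvres = xgb.cv(
        params, dtrain, num_boost_round=max_rounds, nfold=folds,
        stratified=True, early_stopping_rounds=early_stopping, seed=seed,
    )
    best = len(cvres)
    booster = xgb.train(params, dtrain, num_boost_round=best)

    def predict(A: np.ndarray) -> np.ndarray:
        return booster.predict(xgb.DMatrix(A))

    return FittedLearner(spec, list(X.columns), list(X.columns), predict)


# --------------------------------------------------------------------------

def fit_learner(spec: LearnerSpec, X: pd.DataFrame, y, seed: int = 0) -> FittedLearner:
    """Fit one base learner on a samples x features DataFrame.

    ``y`` is binary with 1 = Treat (the positive class). Returns a
    :class:`FittedLearner` exposing positive-class probabilities and the
    features surviving the learner's own selection rule.
    """
    y = _check_xy(X, y)
    alg = spec.algorithm
    if alg in ("Lasso", "Ridge", "Enet"):
        return _fit_glmnet(spec, X, y, seed)
    if alg == "StepGLM":
        return _fit_stepglm(spec, X, y, seed)
    if alg == "glmBoost":
        return _fit_glmboost(spec, X, y, seed)
    if alg == "plsRglm":
        return _fit_plsrglm(spec, X, y, seed)
    if alg == "GBM":
        return _fit_gbm(spec, X, y, seed)
    if alg == "XGBoost":
        return _fit_xgboost(spec, X, y, seed)
    if alg == "SVM":
        Xv = X.to_numpy(dtype=float)
        mean, sd = Xv.mean(axis=0), Xv.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        model = SVC(C=1.0, kernel="rbf", gamma="auto", probability=True, random_state=seed)
        model.fit((Xv - mean) / sd, y)
        return FittedLearner(
            spec, list(X.columns), list(X.columns),
            lambda A: model.predict_proba((A - mean) / sd)[:, 1],
        )
    if alg == "LDA":
        model = LinearDiscriminantAnalysis()
        model.fit(X.to_numpy(dtype=float), y)
        return FittedLearner(
            spec, list(X.columns), list(X.columns),
            lambda A: model.predict_proba(A)[:, 1],
        )
    if alg == "RF":
        model = RandomForestClassifier(n_estimators=1000, random_state=seed, n_jobs=1)
        model.fit(X.to_numpy(dtype=float), y)
        imp = pd.Series(model.feature_importances_, index=X.columns)
        return FittedLearner(
            spec, list(X.columns), list(imp.index[imp.to_numpy() > 0]),
            lambda A: model.predict_proba(A)[:, 1],
        )
    if alg == "NaiveBayes":
        model = GaussianNB()
        model.fit(X.to_numpy(dtype=float), y)
        return FittedLearner(
            spec, list(X.columns), list(X.columns),
            lambda A: model.predict_proba(A)[:, 1],
        )
    raise LearnerError(f"unhandled algorithm {alg!r}")  # pragma: no cover


def extract_features(fitted: FittedLearner) -> list[str]:
    """The features surviving the learner's selection contract."""
    if not isinstance(fitted, FittedLearner):
        raise LearnerError("extract_features expects a FittedLearner")
    return list(fitted.selected)
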