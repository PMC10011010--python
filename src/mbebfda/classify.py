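"""Supervised curve discrimination.

Functional covariates enter every classifier through their FPCA scores
(the spectral decomposition of the sample covariance operator, computed in
coefficient space against the basis Gram matrix).  The reference model is
an additive logistic classifier with one fixed-df spline smooth per
retained score and linear terms for the binary scalar covariates; six
standard classifiers are fitted on the same score features for comparison.
Cross-validation is stratified and re-estimates FPCA inside each training
fold so no test-fold information leaks into the features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.interpolate import BSpline
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .basis import FunctionalSample

BASELINE_MODELS = ("LDA", "RPART", "RF", "SVM", "NNET", "KNN")
ALL_MODELS = ("GSAM",) + BASELINE_MODELS

#: smallest K reaching this cumulative variance share, capped
DEFAULT_VAR_THRESHOLD = 0.95
MAX_COMPONENTS = 10


class ClassificationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FPCA

@dataclass
class FPCABasis:
    """Eigen-decomposition of the sample covariance operator of a curve set."""

    mean_coefficients: np.ndarray
    eigen_coefficients: np.ndarray  # K x n_basis, rows are eigenfunctions
    eigenvalues: np.ndarray  # nonincreasing
    scores: np.ndarray  # n x K
    varprop: np.ndarray  # cumulative proportion of variance
    gram: np.ndarray

    @property
    def n_components(self) -> int:
        return self.eigen_coefficients.shape[0]

    def transform(self, coefficients: np.ndarray) -> np.ndarray:
        """Project (new) curves, given by basis coefficients, onto the
        eigenfunctions: s_ij = <x_i - mean, phi_j>_L2."""
        C = np.atleast_2d(coefficients) - self.mean_coefficients
        return C @ self.gram @ self.eigen_coefficients.T


def fpca(
    sample: FunctionalSample,
    n_components: int | None = None,
    var_threshold: float = DEFAULT_VAR_THRESHOLD,
    max_components: int = MAX_COMPONENTS,
) -> FPCABasis:
    """FPCA in coefficient space.

    With curves x_i = Phi' c_i on a shared basis, eigenfunctions of the
    covariance operator solve a symmetric eigenproblem in the metric of
    the basis Gram matrix W; for n << n_basis the dual n x n problem is
    solved instead.  Components are retained by fixed ``n_components`` or
    by the variance-threshold rule.
    """
    n = sample.n_curves
    if n < 2:
        raise ClassificationError("fpca needs at least 2 curves")
    if n_components is not None and n_components > n - 1:
        raise ClassificationError(f"n_components must be <= n-1 = {n - 1}")
    W = sample.basis.gram(0)
    L = np.linalg.cholesky(W)
    mean_c = sample.coefficients.mean(axis=0)
    C = sample.coefficients - mean_c
    M = C @ L
    S = M @ M.T / (n - 1)
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    total = float(evals.sum())
    if total <= 0:
        raise ClassificationError("zero-variance sample")
    cumprop = np.cumsum(evals) / total
    if n_components is None:
        k = int(np.searchsorted(cumprop, var_threshold) + 1)
        k = min(k, max_components, n - 1)
    else:
        k = int(n_components)
    k = max(k, 1)
    nz = evals[:k] > 1e-12 * evals[0]
    k = int(max(np.sum(nz), 1))
    # a_j = M' u_j / sqrt((n-1) eval_j);  b_j = L^{-T} a_j;  scores = sqrt((n-1) eval) u
    denom = np.sqrt((n - 1) * evals[:k])
    A = (M.T @ evecs[:, :k]) / denom
    B = sla.solve_triangular(L, A, lower=True, trans="T").T  # K x n_basis
    scores = evecs[:, :k] * denom
    return FPCABasis(
        mean_coefficients=mean_c,
        eigen_coefficients=B,
        eigenvalues=evals[:k],
        scores=scores,
        varprop=cumprop[:k],
        gram=W,
    )


# ---------------------------------------------------------------------------
# classifiers

@dataclass(frozen=True)
class ClassifierSpec:
    model_name: str
    functional_inputs: tuple[str, ...] = ()
    scalar_inputs: tuple[str, ...] = ()
    n_components: int | None = None
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_name not in ALL_MODELS:
            raise ClassificationError(f"unknown model {self.model_name!r}")
        if not self.functional_inputs and not self.scalar_inputs:
            raise ClassificationError("at least one input is required")

    @property
    def inputs_label(self) -> str:
        return "+".join(list(self.functional_inputs) + list(self.scalar_inputs))


class _SplineEncoder:
    """Fixed-df cubic B-spline expansion of one score column (knots from
    the training range; the leading basis column is dropped in favour of
    the model intercept)."""

    def __init__(self, df: int = 3):
        self.df = max(int(df), 1)

    def fit(self, x: np.ndarray) -> "_SplineEncoder":
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi - lo < 1e-12:
            lo, hi = lo - 0.5, hi + 0.5
        degree = 3
        n_interior = max(self.df - degree, 0)
        interior = np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1]) if n_interior else np.array([])
        self.lo, self.hi = lo, hi
        self.knots = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
        self.degree = degree
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        xc = np.clip(x, self.lo, self.hi)
        D = BSpline.design_matrix(xc, self.knots, self.degree, extrapolate=False).toarray()
        return D[:, 1 : self.df + 1]


class GsamClassifier:
    """Additive logistic model: spline smooths of FPC scores + linear
    scalar terms, fitted by ridge-stabilized IRLS."""

    def __init__(self, smooth_df: int = 3, ridge: float = 1e-3, max_iter: int = 100):
        self.smooth_df = smooth_df
        self.ridge = ridge
        self.max_iter = max_iter

    def fit(self, scores: np.ndarray, scalars: np.ndarray | None, labels: np.ndarray):
        scores = np.atleast_2d(np.asarray(scores, float))
        y = np.asarray(labels, float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ClassificationError("labels must be binary 0/1")
        frac = min(y.mean(), 1 - y.mean())
        if frac < 0.2:
            warnings.warn(f"minority class fraction {frac:.2f} < 0.20", stacklevel=2)
        self._encoders = [
            _SplineEncoder(self.smooth_df).fit(scores[:, j])
            for j in range(scores.shape[1])
        ]
        X = self._design(scores, scalars)
        self._mu = X.mean(axis=0)
        self._sd = np.where(X.std(axis=0) > 1e-12, X.std(axis=0), 1.0)
        Xs = (X - self._mu) / self._sd
        self._beta = self._irls(Xs, y, self.ridge)
        return self

    def _design(self, scores: np.ndarray, scalars: np.ndarray | None) -> np.ndarray:
        cols = [enc.transform(scores[:, j]) for j, enc in enumerate(self._encoders)]
        if scalars is not None and np.size(scalars):
            cols.append(np.atleast_2d(np.asarray(scalars, float).T).T)
        return np.hstack(cols)

    def _irls(self, X: np.ndarray, y: np.ndarray, ridge: float) -> np.ndarray:
        n, p = X.shape
        Xi = np.hstack([np.ones((n, 1)), X])
        beta = np.zeros(p + 1)
        pen = np.eye(p + 1) * ridge
        pen[0, 0] = 0.0  # intercept unpenalized
        for _ in range(self.max_iter):
            eta = np.clip(Xi @ beta, -30, 30)
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = np.maximum(mu * (1 - mu), 1e-10)
            z = eta + (y - mu) / w
            A = Xi.T @ (w[:, None] * Xi) + pen
            try:
                beta_new = np.linalg.solve(A, Xi.T @ (w * z))
            except np.linalg.LinAlgError:
                beta_new = np.linalg.lstsq(A, Xi.T @ (w * z), rcond=None)[0]
            if np.max(np.abs(beta_new - beta)) < 1e-8:
                beta = beta_new
                break
            beta = beta_new
        eta = Xi @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        separated = bool(
            np.all((mu > 0.5) == (y == 1)) and np.min(np.abs(eta)) > 8.0
        )
        if separated or np.max(np.abs(beta[1:])) > 1e3:
            # (near-)perfect separation: refit with a heavier ridge
            warnings.warn(
                "possible perfect separation; refitting with stronger ridge",
                stacklevel=3,
            )
            return self._irls_once_heavy(Xi, y, pen)
        return beta

    def _irls_once_heavy(self, Xi: np.ndarray, y: np.ndarray, pen: np.ndarray) -> np.ndarray:
        beta = np.zeros(Xi.shape[1])
        heavy = pen * 1e3
        for _ in range(self.max_iter):
            eta = np.clip(Xi @ beta, -30, 30)
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = np.maximum(mu * (1 - mu), 1e-10)
            z = eta + (y - mu) / w
            beta_new = np.linalg.solve(Xi.T @ (w[:, None] * Xi) + heavy, Xi.T @ (w * z))
            if np.max(np.abs(beta_new - beta)) < 1e-8:
                return beta_new
            beta = beta_new
        return beta

    def predict_proba(self, scores: np.ndarray, scalars: np.ndarray | None = None) -> np.ndarray:
        X = self._design(np.atleast_2d(np.asarray(scores, float)), scalars)
        Xs = (X - self._mu) / self._sd
        eta = np.clip(self._beta[0] + Xs @ self._beta[1:], -30, 30)
        return 1.0 / (1.0 + np.exp(-eta))


def fit_gsam(
    scores: np.ndarray,
    scalars: np.ndarray | None,
    labels: np.ndarray,
    smooth_df: int = 3,
) -> GsamClassifier:
    return GsamClassifier(smooth_df=smooth_df).fit(scores, scalars, labels)


class _SklearnWrapper:
    def __init__(self, pipeline, use_decision: bool = False):
        self.pipeline = pipeline
        self.use_decision = use_decision

    def fit(self, scores, scalars, labels):
        X = _concat(scores, scalars)
        self.pipeline.fit(X, np.asarray(labels, int))
        return self

    def predict_proba(self, scores, scalars=None):
        X = _concat(scores, scalars)
        if self.use_decision:
            # margin squashed through a logistic link: monotone, in [0,1],
            # and the 0.5 decision matches the sign of the margin
            d = self.pipeline.decision_function(X)
            return 1.0 / (1.0 + np.exp(-np.clip(d, -30, 30)))
        proba = self.pipeline.predict_proba(X)
        classes = list(self.pipeline.classes_)
        if 1 not in classes:
            return np.zeros(X.shape[0])
        return proba[:, classes.index(1)]


def _concat(scores, scalars):
    parts = [np.atleast_2d(np.asarray(scores, float))]
    if scalars is not None and np.size(scalars):
        parts.append(np.atleast_2d(np.asarray(scalars, float).T).T)
    return np.hstack(parts)


def fit_baseline(spec: ClassifierSpec, scores, scalars, labels, seed: int = 0):
    """Fit one of the six non-GSAM models on concatenated score/scalar
    features (standardized), with the same predict_proba contract."""
    name = spec.model_name
    if name == "GSAM":
        raise ClassificationError("use fit_gsam for the GSAM model")
    hp = spec.hyperparameters
    use_decision = False
    if name == "LDA":
        est = LinearDiscriminantAnalysis()
    elif name == "RPART":
        est = DecisionTreeClassifier(random_state=seed, **hp)
    elif name == "RF":
        est = RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 200), random_state=seed
        )
    elif name == "SVM":
        est = SVC(random_state=seed, **hp)
        use_decision = True
    elif name == "NNET":
        est = MLPClassifier(
            hidden_layer_sizes=hp.get("hidden_layer_sizes", (8,)),
            max_iter=hp.get("max_iter", 2000),
            random_state=seed,
        )
    elif name == "KNN":
        est = KNeighborsClassifier(
            n_neighbors=min(hp.get("n_neighbors", 5), len(np.asarray(labels)))
        )
    else:  # pragma: no cover
        raise ClassificationError(f"unknown model {name!r}")
    pipe = Pipeline([("scale", StandardScaler()), ("model", est)])
    return _SklearnWrapper(pipe, use_decision).fit(scores, scalars, labels)


# ---------------------------------------------------------------------------
# metrics and cross-validation

@dataclass(frozen=True)
class CVMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    fold_assignments: tuple[int, ...] = ()
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else 0.0

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return tp, fp, tn, fn


SCALAR_CODING = {"sex": {"F": 0.0, "M": 1.0}, "puberty": {"early": 0.0, "late": 1.0}}


def _scalar_matrix(meta: pd.DataFrame, scalar_inputs: tuple[str, ...], train_idx=None):
    cols = []
    for name in scalar_inputs:
        if name in SCALAR_CODING:
            cols.append(meta[name].map(SCALAR_CODING[name]).to_numpy(float))
        elif name == "body_mass":
            x = meta["body_mass_kg"].to_numpy(float)
            ref = x[train_idx] if train_idx is not None else x
            cols.append((x - ref.mean()) / (ref.std() + 1e-12))
        else:
            raise ClassificationError(f"unknown scalar input {name!r}")
    return np.column_stack(cols) if cols else None


def _fit_predict(
    spec: ClassifierSpec,
    samples: dict[str, FunctionalSample],
    meta: pd.DataFrame,
    labels: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    seed: int,
) -> np.ndarray:
    """FPCA per functional input on the training fold only, then fit the
    requested model and return test-fold failure probabilities."""
    train_scores, test_scores = [], []
    for sig in spec.functional_inputs:
        fs = samples[sig]
        pca = fpca(fs.subset(train_idx), n_components=spec.n_components)
        train_scores.append(pca.scores)
        test_scores.append(pca.transform(fs.coefficients[test_idx]))
    if train_scores:
        Xtr = np.hstack(train_scores)
        Xte = np.hstack(test_scores)
    else:
        Xtr = np.empty((train_idx.size, 0))
        Xte = np.empty((test_idx.size, 0))
    str_tr = _scalar_matrix(meta, spec.scalar_inputs, train_idx)
    Str = str_tr[train_idx] if str_tr is not None else None
    Ste = str_tr[test_idx] if str_tr is not None else None
    if spec.model_name == "GSAM":
        model = fit_gsam(
            Xtr, Str, labels[train_idx], smooth_df=spec.hyperparameters.get("smooth_df", 3)
        )
    else:
        model = fit_baseline(spec, Xtr, Str, labels[train_idx], seed=seed)
    return model.predict_proba(Xte, Ste)


def crossvalidate(
    spec: ClassifierSpec,
    samples: dict[str, FunctionalSample],
    meta: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
) -> CVMetrics:
    """Stratified k-fold CV with a pooled confusion matrix.

    The class decision is probability > 0.5; exact ties classify as
    completer (class 0).
    """
    labels = meta["label"].to_numpy(int)
    n = labels.size
    if k < 2 or n < k:
        raise ClassificationError("need k >= 2 and n >= k")
    for sig in spec.functional_inputs:
        if sig not in samples:
            raise ClassificationError(f"missing functional sample for {sig!r}")

    def run(fold_seed: int):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed)
        preds = np.empty(n)
        assign = np.empty(n, int)
        for fold, (tr, te) in enumerate(skf.split(np.zeros(n), labels)):
            if np.unique(labels[tr]).size < 2:
                raise _SingleClassFold()
            preds[te] = _fit_predict(spec, samples, meta, labels, tr, te, fold_seed)
            assign[te] = fold
        return preds, assign

    try:
        preds, assign = run(seed)
    except _SingleClassFold:
        try:
            preds, assign = run(seed + 1)
        except _SingleClassFold as e:
            raise ClassificationError(
                "a training fold contained a single class even after refolding"
            ) from e
    y_pred = (preds > 0.5).astype(int)
    tp, fp, tn, fn = confusion_counts(labels, y_pred)
    return CVMetrics(tp, fp, tn, fn, tuple(assign.tolist()), seed)


class _SingleClassFold(Exception):
    pass


def full_spec(model_name: str = "GSAM", include_body_mass: bool = False) -> ClassifierSpec:
    scalars = ("sex", "puberty") + (("body_mass",) if include_body_mass else ())
    return ClassifierSpec(model_name, ("HR", "RR", "VO2", "VCO2"), scalars)


def run_model_battery(
    samples: dict[str, FunctionalSample],
    meta: pd.DataFrame,
    specs: list[ClassifierSpec],
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate every spec on shared CV folds; table sorted by F1."""
    if not specs:
        raise ClassificationError("specs must be nonempty")
    rows = []
    for spec in specs:
        m = crossvalidate(spec, samples, meta, k=k, seed=seed)
        rows.append(
            {
                "Model": spec.model_name,
                "Inputs": spec.inputs_label,
                "Accuracy (%)": round(100 * m.accuracy, 1),
                "F1 Score (%)": round(100 * m.f1, 1),
                "TP": m.tp,
                "FP": m.fp,
                "TN": m.tn,
                "FN": m.fn,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("F1 Score (%)", ascending=False)
        .reset_index(drop=True)
    )
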