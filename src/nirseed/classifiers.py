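"""Binary spectral classifiers and their cross-validated tuning protocols.

Four classifiers are provided, each with the tuning protocol used for
harvest-year discrimination:

* PLS-DA — partial least squares regression (SIMPLS) against the ±1 class
  code, thresholded at 0; latent variables chosen by stratified 10-fold CV.
* LS-SVM — least-squares SVM with an RBF kernel ``exp(−‖x−z‖²/σ²)``; the
  dual linear system is solved exactly; (γ, σ²) by grid search + 10-fold CV.
* KNN — majority vote among K nearest training kernels; (K, metric) by
  10-fold CV.
* ELM — single hidden layer of random sigmoid units, output weights by
  pseudo-inverse; hidden size swept 10..150 in steps of 10 by 10-fold CV.

Ties are deterministic throughout: a discriminant score of exactly 0 maps to
class +1; CV ties prefer the simpler model (fewer LVs / smaller γ then σ² /
fewer neurons / smaller K).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import expit

__all__ = [
    "PLSDAModel", "LSSVMModel", "KNNModel", "ELMModel", "CVResult",
    "kfold_split", "simpls_coefficients",
    "plsda_fit", "plsda_predict", "choose_lvs",
    "lssvm_fit", "lssvm_predict", "lssvm_tune",
    "knn_predict", "knn_tune_fit",
    "elm_fit", "elm_predict", "elm_tune",
    "class_accuracy",
]


# ---------------------------------------------------------------------------
# shared machinery

def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(int)
    vals = set(np.unique(y))
    if not vals <= {-1, 1}:
        raise ValueError(f"labels must be -1/+1, found {sorted(vals - {-1, 1})}")
    if vals != {-1, 1}:
        raise ValueError("both classes must be present")
    return y


def _scores_to_labels(scores: np.ndarray) -> np.ndarray:
    # score exactly 0 -> +1 (documented tie rule)
    return np.where(scores >= 0, 1, -1)


def kfold_split(n: int, k: int, seed: int, labels: np.ndarray | None = None) -> np.ndarray:
    """Stratified k-fold assignment vector (fold ids 0..k−1).

    Per class the shuffled samples are dealt round-robin, so per-class fold
    sizes differ by at most one.  Deterministic per seed.
    """
    if k > n:
        raise ValueError("k must not exceed n")
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    assign = np.empty(n, dtype=int)
    if labels is None:
        labels = np.zeros(n, dtype=int)
    labels = np.asarray(labels)
    for cls in np.unique(labels):
        rows = np.flatnonzero(labels == cls)
        perm = rng.permutation(rows)
        assign[perm] = np.arange(perm.size) % k
    return assign


@dataclass
class CVResult:
    """Outcome of a cross-validated tuning run."""

    fold_assignment: np.ndarray
    per_fold_accuracy: np.ndarray
    mean_accuracy: float
    per_class_accuracy: dict
    params: dict = field(default_factory=dict)


def _cv_accuracy(X, y, fold_assignment, fit_predict) -> CVResult:
    """Generic stratified-CV accuracy for a fit_predict(Xtr,ytr,Xte)->labels."""
    k = int(fold_assignment.max()) + 1
    fold_acc = np.empty(k)
    pred = np.empty_like(y)
    for f in range(k):
        test = fold_assignment == f
        yhat = fit_predict(X[~test], y[~test], X[test])
        pred[test] = yhat
        fold_acc[f] = float(np.mean(yhat == y[test]))
    per_class = {int(c): float(np.mean(pred[y == c] == c)) for c in (-1, 1)}
    return CVResult(
        fold_assignment=fold_assignment,
        per_fold_accuracy=fold_acc,
        mean_accuracy=float(np.mean(pred == y)),
        per_class_accuracy=per_class,
    )


def class_accuracy(truth: np.ndarray, predicted: np.ndarray) -> tuple[float, float, float]:
    """Per-class and total accuracy in percent: (class −1, class +1, total)."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.size == 0:
        raise ValueError("empty input")
    if truth.shape != predicted.shape:
        raise ValueError("length mismatch")
    accs = []
    for cls in (-1, 1):
        rows = truth == cls
        accs.append(100.0 * float(np.mean(predicted[rows] == cls)) if rows.any() else float("nan"))
    total = 100.0 * float(np.mean(predicted == truth))
    return accs[0], accs[1], total


# ---------------------------------------------------------------------------
# PLS-DA (SIMPLS)

@dataclass
class PLSDAModel:
    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    coefficients: np.ndarray  # b on centered data
    threshold: float = 0.0


def simpls_coefficients(Xc: np.ndarray, yc: np.ndarray, n_lv: int,
                        strict: bool = True) -> np.ndarray:
    """SIMPLS regression vector for centered X (n×p) and centered y (n,).

    Deflates the cross-product s = X'y against an orthonormal basis of
    loading directions; returns b with ŷ = Xc·b.  When the requested number
    of components exceeds the effective rank, raises if ``strict`` else
    returns the coefficients of the components extracted so far.
    """
    n, p = Xc.shape
    R = np.zeros((p, n_lv))
    V = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    s = Xc.T @ yc
    ref_scale = None
    for a in range(n_lv):
        r = s.copy()
        t = Xc @ r
        tnorm = float(np.linalg.norm(t))
        if ref_scale is None:
            ref_scale = max(tnorm, 1e-300)
        if tnorm <= 1e-10 * ref_scale:
            if not strict:
                return R[:, :a] @ q[:a] if a else np.zeros(p)
            raise ValueError(
                f"n_lv={n_lv} exceeds the effective rank (deflation collapsed at {a})"
            )
        t /= tnorm
        r /= tnorm
        pa = Xc.T @ t
        v = pa.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ pa)
        v /= np.linalg.norm(v)
        s -= v * (v @ s)
        R[:, a] = r
        V[:, a] = v
        q[a] = float(yc @ t)
    return R @ q


def plsda_fit(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSDAModel:
    """Fit PLS-DA on ±1 labels with ``n_lv`` latent variables (SIMPLS)."""
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    n, p = X.shape
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(f"n_lv must lie in [1, {min(n - 1, p)}], got {n_lv}")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    b = simpls_coefficients(X - x_mean, y - y_mean, n_lv)
    return PLSDAModel(n_lv=n_lv, x_mean=x_mean, y_mean=y_mean, coefficients=b)


def plsda_predict(model: PLSDAModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Continuous discriminant scores and thresholded ±1 labels."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.coefficients.size:
        raise ValueError("channel count mismatch")
    scores = (X - model.x_mean) @ model.coefficients + model.y_mean
    return scores, np.where(scores > model.threshold, 1,
                            np.where(scores < model.threshold, -1, 1))


def choose_lvs(X: np.ndarray, y: np.ndarray, max_lv: int = 10,
               k: int = 10, seed: int = 0) -> tuple[int, CVResult]:
    """Latent-variable count by stratified k-fold CV accuracy.

    Returns the smallest ``n_lv`` attaining the maximum mean CV accuracy.
    ``max_lv`` is capped so every CV fold keeps a valid fit.
    """
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    n, p = X.shape
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    fold = kfold_split(n, k, seed, labels=y)
    smallest_train = min(int(np.sum(fold != f)) for f in range(int(fold.max()) + 1))
    max_lv = min(max_lv, smallest_train - 1, p)
    results = []
    for n_lv in range(1, max_lv + 1):
        def fit_predict(Xtr, ytr, Xte, n_lv=n_lv):
            model = plsda_fit(Xtr, ytr, n_lv)
            return plsda_predict(model, Xte)[1]
        try:
            cv = _cv_accuracy(X, y, fold, fit_predict)
        except ValueError:  # rank collapse inside a fold
            break
        cv.params = {"n_lv": n_lv}
        results.append((n_lv, cv))
    if not results:
        raise ValueError("no valid latent-variable count")
    best_acc = max(cv.mean_accuracy for _, cv in results)
    for n_lv, cv in results:  # ordered by n_lv: first hit = fewest LVs
        if cv.mean_accuracy == best_acc:
            return n_lv, cv
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# LS-SVM with RBF kernel

@dataclass
class LSSVMModel:
    gamma: float
    sigma2: float
    alphas: np.ndarray
    bias: float
    support_X: np.ndarray
    support_y: np.ndarray


def _rbf(A: np.ndarray, B: np.ndarray, sigma2: float) -> np.ndarray:
    d2 = cdist(A, B, metric="sqeuclidean")
    return np.exp(-d2 / sigma2)


def lssvm_fit(X: np.ndarray, y: np.ndarray, gamma: float, sigma2: float) -> LSSVMModel:
    """Solve the LS-SVM dual system [[0, 1ᵀ],[1, K + I/γ]]·[b; α] = [0; y]."""
    if gamma <= 0 or sigma2 <= 0:
        raise ValueError("gamma and sigma2 must be > 0")
    X = np.asarray(X, dtype=float)
    y = _check_labels(y).astype(float)
    n = X.shape[0]
    K = _rbf(X, X, sigma2)
    A = np.empty((n + 1, n + 1))
    A[0, 0] = 0.0
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gamma
    rhs = np.concatenate([[0.0], y])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular LS-SVM system") from exc
    resid = float(np.linalg.norm(A @ sol - rhs))
    if resid > 1e-6 * max(1.0, float(np.linalg.norm(rhs))):
        import warnings

        warnings.warn(f"LS-SVM system nearly singular (residual {resid:.2e})")
    return LSSVMModel(gamma=float(gamma), sigma2=float(sigma2),
                      alphas=sol[1:], bias=float(sol[0]),
                      support_X=X, support_y=y)


def lssvm_predict(model: LSSVMModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    K = _rbf(np.asarray(X, dtype=float), model.support_X, model.sigma2)
    scores = K @ model.alphas + model.bias
    return scores, _scores_to_labels(scores)


def default_lssvm_grid() -> np.ndarray:
    """Log-spaced 13-point grid 1e−2..1e6 for both γ and σ²."""
    return np.logspace(-2, 6, 13)


def lssvm_tune(X: np.ndarray, y: np.ndarray,
               gamma_grid=None, sigma2_grid=None,
               k: int = 10, seed: int = 0) -> tuple[LSSVMModel, CVResult]:
    """Exhaustive (γ, σ²) grid search by stratified k-fold CV accuracy."""
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    gamma_grid = default_lssvm_grid() if gamma_grid is None else np.asarray(gamma_grid, dtype=float)
    sigma2_grid = default_lssvm_grid() if sigma2_grid is None else np.asarray(sigma2_grid, dtype=float)
    if gamma_grid.size == 0 or sigma2_grid.size == 0:
        raise ValueError("empty grid")
    n = X.shape[0]
    fold = kfold_split(n, k, seed, labels=y)
    n_folds = int(fold.max()) + 1
    # The kernel depends only on sigma2: precompute squared distances once
    # and reuse exp(-D2/sigma2) slices across the whole gamma sweep.
    D2 = cdist(X, X, metric="sqeuclidean")
    yf = y.astype(float)
    best = None
    for sigma2 in sorted(sigma2_grid):
        K = np.exp(-D2 / sigma2)
        for gamma in sorted(gamma_grid):
            pred = np.empty_like(y)
            fold_acc = np.empty(n_folds)
            for f in range(n_folds):
                test = fold == f
                tr = ~test
                ntr = int(tr.sum())
                A = np.empty((ntr + 1, ntr + 1))
                A[0, 0] = 0.0
                A[0, 1:] = 1.0
                A[1:, 0] = 1.0
                A[1:, 1:] = K[np.ix_(tr, tr)] + np.eye(ntr) / gamma
                sol = np.linalg.solve(A, np.concatenate([[0.0], yf[tr]]))
                scores = K[np.ix_(test, tr)] @ sol[1:] + sol[0]
                pred[test] = _scores_to_labels(scores)
                fold_acc[f] = float(np.mean(pred[test] == y[test]))
            cv = CVResult(
                fold_assignment=fold,
                per_fold_accuracy=fold_acc,
                mean_accuracy=float(np.mean(pred == y)),
                per_class_accuracy={int(c): float(np.mean(pred[y == c] == c)) for c in (-1, 1)},
                params={"gamma": float(gamma), "sigma2": float(sigma2)},
            )
            if best is None or cv.mean_accuracy > best.mean_accuracy:
                best = cv
            elif cv.mean_accuracy == best.mean_accuracy:
                # tie -> smaller gamma, then smaller sigma2
                if (gamma, sigma2) < (best.params["gamma"], best.params["sigma2"]):
                    best = cv
    model = lssvm_fit(X, y, best.params["gamma"], best.params["sigma2"])
    return model, best


# ---------------------------------------------------------------------------
# KNN

@dataclass
class KNNModel:
    k: int
    metric: str
    X: np.ndarray
    y: np.ndarray


def knn_predict(model: KNNModel, X: np.ndarray) -> np.ndarray:
    """Majority vote of the K nearest training kernels.

    Distance ties resolve to the smaller training index (stable sort);
    vote ties resolve to +1.
    """
    D = cdist(np.asarray(X, dtype=float), model.X, metric=model.metric)
    order = np.argsort(D, axis=1, kind="stable")[:, : model.k]
    votes = model.y[order].sum(axis=1)
    return _scores_to_labels(votes)


def knn_tune_fit(X: np.ndarray, y: np.ndarray,
                 k_candidates=range(1, 16),
                 metric_candidates=("euclidean", "cityblock", "cosine"),
                 folds: int = 10, seed: int = 0) -> tuple[KNNModel, CVResult]:
    """Pick (K, metric) minimizing stratified CV misclassification."""
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    n = X.shape[0]
    k_candidates = list(k_candidates)
    if any(k >= n for k in k_candidates):
        raise ValueError("every K must be below the sample count")
    fold = kfold_split(n, folds, seed, labels=y)
    best = None
    for metric in metric_candidates:
        D = cdist(X, X, metric=metric)
        for k in sorted(k_candidates):
            pred = np.empty_like(y)
            fold_acc = []
            for f in range(int(fold.max()) + 1):
                test = fold == f
                train_rows = np.flatnonzero(~test)
                order = np.argsort(D[np.ix_(test, train_rows)], axis=1, kind="stable")[:, :k]
                votes = y[train_rows][order].sum(axis=1)
                pred[test] = _scores_to_labels(votes)
                fold_acc.append(float(np.mean(pred[test] == y[test])))
            cv = CVResult(
                fold_assignment=fold,
                per_fold_accuracy=np.asarray(fold_acc),
                mean_accuracy=float(np.mean(pred == y)),
                per_class_accuracy={int(c): float(np.mean(pred[y == c] == c)) for c in (-1, 1)},
                params={"k": int(k), "metric": metric},
            )
            if best is None or cv.mean_accuracy > best.mean_accuracy:
                best = cv
    model = KNNModel(k=best.params["k"], metric=best.params["metric"], X=X, y=y)
    return model, best


# ---------------------------------------------------------------------------
# ELM

@dataclass
class ELMModel:
    n_hidden: int
    input_weights: np.ndarray  # (p, h)
    hidden_bias: np.ndarray    # (h,)
    output_weights: np.ndarray  # (h,)
    seed: int


def _elm_hidden(X: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    return expit(X @ W + b[None, :])


def elm_fit(X: np.ndarray, y: np.ndarray, n_hidden: int, seed: int = 0) -> ELMModel:
    """Random sigmoid hidden layer; output weights by Moore–Penrose pinv."""
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    X = np.asarray(X, dtype=float)
    y = _check_labels(y).astype(float)
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(X.shape[1], n_hidden))
    b = rng.uniform(-1.0, 1.0, size=n_hidden)
    H = _elm_hidden(X, W, b)
    beta = np.linalg.pinv(H) @ y
    return ELMModel(n_hidden=n_hidden, input_weights=W, hidden_bias=b,
                    output_weights=beta, seed=seed)


def elm_predict(model: ELMModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    H = _elm_hidden(np.asarray(X, dtype=float), model.input_weights, model.hidden_bias)
    scores = H @ model.output_weights
    return scores, _scores_to_labels(scores)


def elm_tune(X: np.ndarray, y: np.ndarray, hidden_grid=None,
             folds: int = 10, seed: int = 0) -> tuple[ELMModel, CVResult]:
    """Sweep hidden-layer sizes (default 10..150 step 10) by CV accuracy."""
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    hidden_grid = list(range(10, 151, 10)) if hidden_grid is None else list(hidden_grid)
    if not hidden_grid:
        raise ValueError("empty hidden grid")
    fold = kfold_split(X.shape[0], folds, seed, labels=y)
    best = None
    for h in sorted(hidden_grid):
        def fit_predict(Xtr, ytr, Xte, h=h):
            return elm_predict(elm_fit(Xtr, ytr, h, seed=seed), Xte)[1]
        cv = _cv_accuracy(X, y, fold, fit_predict)
        cv.params = {"n_hidden": int(h)}
        if best is None or cv.mean_accuracy > best.mean_accuracy:
            best = cv  # ties keep fewer neurons
    model = elm_fit(X, y, best.params["n_hidden"], seed=seed)
    return model, best
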