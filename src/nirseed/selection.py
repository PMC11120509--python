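"""Effective-wavelength selection: MC-UVE, CARS, BOSS, SPA and their chains.

All selectors operate on a training matrix ``X`` (n kernels × p channels)
and ±1 labels ``y``, and return a :class:`WavelengthSubset` of 0-based
channel indices together with a :class:`SelectionTrace` of diagnostics.
Model errors for a discriminant response are root-mean-square errors of the
continuous PLS score against the ±1 label: RMSECV under k-fold
cross-validation, RMSEP on a held-out evaluation set.

The methods:

* **MC-UVE** — Monte-Carlo uninformative variable elimination.  Many PLS
  models are fitted on random sample subsets; each channel's *stability* is
  mean/std of its regression coefficient across the fits.  Channels are
  ranked by |stability| and the retained count N is chosen by the minimum
  RMSEP over a sweep (default 20..500 step 20).
* **CARS** — competitive adaptive reweighted sampling.  Over ``n_runs``
  iterations the retained-channel budget shrinks along an exponentially
  decreasing function from p to 2 while adaptive reweighted sampling keeps
  channels in proportion to |PLS coefficient|; the iteration subset with the
  minimum RMSECV wins.
* **BOSS** — bootstrapping soft shrinkage.  Weighted bootstrap sampling
  generates variable subsets; the best 10% of sub-models (by RMSECV)
  re-weight the variables, softly shrinking the pool until one variable
  remains; the globally best sub-model subset wins.
* **SPA** — successive projections algorithm.  From every start channel a
  chain of minimally collinear channels is grown by maximal orthogonal
  projection norm; candidate chains are scored by the RMSECV of a
  multiple-linear-regression model.
* **Chains** (e.g. MC-UVE→BOSS): each stage runs on the previous stage's
  subset, with indices mapped back to the original grid.

Determinism: every selector takes a seed and reruns bit-identically,
traces included.  Tie-breaks prefer fewer variables, then smaller indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .classifiers import choose_lvs, kfold_split, simpls_coefficients

__all__ = [
    "WavelengthSubset", "SelectionTrace",
    "pls_rmsecv", "pls_rmsep",
    "mcuve_stability", "mcuve_select",
    "cars_edf_ratios", "cars_edf_budgets", "cars_select",
    "boss_select", "spa_select", "chain_select", "SELECTORS",
]


@dataclass
class SelectionTrace:
    """Per-run diagnostics mirroring the usual selector plots."""

    stability: np.ndarray | None = None            # MC-UVE, per channel
    rmsep_curve: list = field(default_factory=list)   # [(N, RMSEP)]
    nvar_per_iteration: list = field(default_factory=list)
    rmsecv_per_iteration: list = field(default_factory=list)
    seeds: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)


@dataclass
class WavelengthSubset:
    """Sorted unique channel indices with provenance and diagnostics."""

    indices: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    trace: SelectionTrace = field(default_factory=SelectionTrace)

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=int))
        if idx.size == 0:
            raise ValueError("empty wavelength subset")
        if idx.min() < 0:
            raise ValueError("negative channel index")
        self.indices = idx

    @property
    def n_wavelengths(self) -> int:
        return int(self.indices.size)


# ---------------------------------------------------------------------------
# discriminant-score error measures

def _cap_lv(n_lv: int, n_samples: int, n_vars: int) -> int:
    return max(1, min(n_lv, n_samples - 1, n_vars))


def _coefficients_capped(Xc: np.ndarray, yc: np.ndarray, n_lv: int) -> np.ndarray:
    """SIMPLS coefficients with the component count capped at the rank.

    Sub-models inside selectors run on arbitrary small channel subsets where
    the requested component count routinely exceeds what the deflation can
    support; here that caps gracefully instead of failing the whole run.
    """
    lv = _cap_lv(n_lv, Xc.shape[0] + 1, Xc.shape[1])
    return simpls_coefficients(Xc, yc, lv, strict=False)


def _resolve_sub_lv(X, y, n_lv, seed: int, max_lv: int = 10) -> int:
    """Sub-model component count: CV-chosen on the full input pool if unset."""
    if n_lv is not None:
        return int(n_lv)
    best, _ = choose_lvs(X, np.asarray(y).astype(int), max_lv=max_lv, seed=seed)
    return best


def pls_rmsep(X_train, y_train, X_eval, y_eval, n_lv: int) -> float:
    """RMSEP of continuous PLS scores on a held-out evaluation set."""
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    xm = X_train.mean(axis=0)
    ym = float(y_train.mean())
    b = _coefficients_capped(X_train - xm, y_train - ym, n_lv)
    scores = (np.asarray(X_eval, dtype=float) - xm) @ b + ym
    return float(np.sqrt(np.mean((scores - np.asarray(y_eval, dtype=float)) ** 2)))


def pls_rmsecv(X, y, n_lv: int, fold_assignment: np.ndarray) -> float:
    """k-fold RMSECV of continuous PLS scores against ±1 labels.

    The fold assignment is passed in so that all sub-models of one selector
    run share identical folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    scores = np.empty_like(y)
    for f in range(int(fold_assignment.max()) + 1):
        test = fold_assignment == f
        Xtr, ytr = X[~test], y[~test]
        xm = Xtr.mean(axis=0)
        ym = float(ytr.mean())
        b = _coefficients_capped(Xtr - xm, ytr - ym, n_lv)
        scores[test] = (X[test] - xm) @ b + ym
    return float(np.sqrt(np.mean((scores - y) ** 2)))


def _stratified_holdout(y: np.ndarray, val_fraction: float, seed: int):
    """Index split (fit_rows, val_rows), stratified per class."""
    rng = np.random.default_rng(seed)
    fit_rows, val_rows = [], []
    for cls in np.unique(y):
        rows = rng.permutation(np.flatnonzero(y == cls))
        n_val = max(1, int(round(val_fraction * rows.size)))
        val_rows.append(rows[:n_val])
        fit_rows.append(rows[n_val:])
    return np.sort(np.concatenate(fit_rows)), np.sort(np.concatenate(val_rows))


# ---------------------------------------------------------------------------
# MC-UVE

def mcuve_stability(X, y, n_mc: int = 500, sample_ratio: float = 0.8,
                    n_lv: int | None = None, seed: int = 0) -> np.ndarray:
    """Channel stability = mean/std of PLS coefficients over MC resamples.

    Each of ``n_mc`` Monte-Carlo rounds fits a PLS model on
    ``floor(sample_ratio · n)`` kernels drawn without replacement; the
    stability of channel j is mean_j / std_j of its regression coefficient
    across rounds (sample std, n−1).
    """
    if n_mc < 2:
        raise ValueError("n_mc must be >= 2")
    if not 0.0 < sample_ratio < 1.0:
        raise ValueError("sample_ratio must lie in (0, 1)")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    n_lv = _resolve_sub_lv(X, y, n_lv, seed)
    n_sub = int(math.floor(sample_ratio * n))
    if n_sub < n_lv + 1:
        raise ValueError("Monte-Carlo subset smaller than n_lv + 1")
    rng = np.random.default_rng(seed)
    coefs = np.empty((n_mc, p))
    for m in range(n_mc):
        rows = rng.choice(n, size=n_sub, replace=False)
        Xs, ys = X[rows], y[rows]
        coefs[m] = _coefficients_capped(Xs - Xs.mean(axis=0), ys - ys.mean(), n_lv)
    sd = coefs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stab = coefs.mean(axis=0) / sd
    stab[~np.isfinite(stab)] = 0.0
    return stab


def mcuve_select(X, y, n_grid=None, n_mc: int = 500, sample_ratio: float = 0.8,
                 n_lv: int | None = None, seed: int = 0,
                 eval_set: tuple | None = None,
                 val_fraction: float = 0.25) -> WavelengthSubset:
    """MC-UVE: rank by |stability|, choose N by the minimum-RMSEP sweep.

    By default an inner stratified validation split (``val_fraction``) is
    carved from (X, y); stability and the top-N models are computed on the
    remaining kernels and RMSEP on the inner hold-out, so no external data
    leaks into the selection.  Passing ``eval_set=(X_eval, y_eval)``
    reproduces the protocol that scores the sweep on an external prediction
    set instead.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    if n_grid is None:
        n_grid = list(range(20, 501, 20))
    n_grid = sorted({int(N) for N in n_grid if 1 <= N <= p})
    if not n_grid:
        raise ValueError("empty N grid after capping at channel count")

    if eval_set is not None:
        X_fit, y_fit = X, y
        X_eval, y_eval = np.asarray(eval_set[0], dtype=float), np.asarray(eval_set[1], dtype=float)
        mode = "external-eval"
    else:
        fit_rows, val_rows = _stratified_holdout(y, val_fraction, seed + 101)
        X_fit, y_fit = X[fit_rows], y[fit_rows]
        X_eval, y_eval = X[val_rows], y[val_rows]
        mode = "inner-holdout"

    n_lv = _resolve_sub_lv(X_fit, y_fit, n_lv, seed)
    stability = mcuve_stability(X_fit, y_fit, n_mc=n_mc, sample_ratio=sample_ratio,
                                n_lv=n_lv, seed=seed)
    order = np.argsort(-np.abs(stability), kind="stable")
    curve = []
    best = None
    for N in n_grid:
        top = order[:N]
        rmsep = pls_rmsep(X_fit[:, top], y_fit, X_eval[:, top], y_eval, n_lv)
        curve.append((N, rmsep))
        if best is None or rmsep < best[1]:
            best = (N, rmsep)  # ties keep the smaller N (grid is ascending)
    top = np.sort(order[: best[0]])
    trace = SelectionTrace(stability=stability, rmsep_curve=curve,
                           seeds={"seed": seed}, notes=[f"eval mode: {mode}"])
    return WavelengthSubset(
        indices=top, method="MC-UVE",
        params={"n_mc": n_mc, "sample_ratio": sample_ratio, "n_lv": n_lv,
                "N": best[0], "rmsep": best[1]},
        trace=trace,
    )


# ---------------------------------------------------------------------------
# CARS

def cars_edf_ratios(p: int, n_runs: int) -> np.ndarray:
    """Exponentially decreasing retained-channel ratios r_1..r_{n_runs}.

    r_i = a·e^{−k·i} with a = (p/2)^{1/(n_runs−1)} and
    k = ln(p/2)/(n_runs−1), so r_1 = 1 and r_{n_runs}·p = 2.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if p < 3:
        raise ValueError("need at least 3 channels")
    i = np.arange(1, n_runs + 1, dtype=float)
    return (p / 2.0) ** ((1.0 - i) / (n_runs - 1))


def cars_edf_budgets(p: int, n_runs: int) -> np.ndarray:
    """Integer channel budgets ⌈r_i·p⌉ along the EDF (p at i=1, 2 at the end)."""
    budgets = np.ceil(cars_edf_ratios(p, n_runs) * p - 1e-9).astype(int)
    return np.clip(budgets, 2, p)


def cars_select(X, y, n_runs: int = 100, folds: int = 10,
                n_lv: int | None = None, seed: int = 0,
                sample_ratio: float = 0.8) -> WavelengthSubset:
    """Competitive adaptive reweighted sampling.

    Each iteration fits a PLS model on a random ``sample_ratio`` subset of
    kernels restricted to the retained channels, weights channels by |b|,
    enforces the EDF budget (top channels by weight), then resamples the
    budget with replacement proportionally to weight (adaptive reweighted
    sampling) keeping the unique draws.  Every iteration's subset is scored
    by k-fold RMSECV; the global minimum wins (ties: fewer variables, then
    the earlier iteration).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    n_lv = _resolve_sub_lv(X, y, n_lv, seed)
    budgets = cars_edf_budgets(p, n_runs)
    rng = np.random.default_rng(seed)
    fold = kfold_split(n, folds, seed + 1, labels=y)
    retained = np.arange(p)
    nvar_trace, rmsecv_trace = [], []
    best = None  # (rmsecv, size, iteration, subset)
    n_sub = max(int(math.floor(sample_ratio * n)), 2)
    for it in range(n_runs):
        rows = rng.choice(n, size=n_sub, replace=False)
        Xs, ys = X[np.ix_(rows, retained)], y[rows]
        lv = min(n_lv, retained.size - 1) if retained.size > 1 else 1
        b = _coefficients_capped(Xs - Xs.mean(axis=0), ys - ys.mean(), lv)
        w = np.abs(b)
        m = int(min(budgets[it], retained.size))
        keep_order = np.argsort(-w, kind="stable")[:m]
        kept = retained[keep_order]
        kw = w[keep_order]
        if kw.sum() <= 0:
            probs = np.full(m, 1.0 / m)
        else:
            probs = kw / kw.sum()
        draws = rng.choice(m, size=m, replace=True, p=probs)
        retained = np.unique(kept[draws])
        lv_eval = _cap_lv(min(n_lv, max(retained.size - 1, 1)), n, retained.size)
        rmsecv = pls_rmsecv(X[:, retained], y, lv_eval, fold)
        nvar_trace.append(int(retained.size))
        rmsecv_trace.append(rmsecv)
        cand = (rmsecv, retained.size, it, retained.copy())
        if best is None or cand[:3] < best[:3]:
            best = cand
    trace = SelectionTrace(nvar_per_iteration=nvar_trace,
                           rmsecv_per_iteration=rmsecv_trace,
                           seeds={"seed": seed})
    return WavelengthSubset(
        indices=best[3], method="CARS",
        params={"n_runs": n_runs, "folds": folds, "n_lv": n_lv,
                "iteration": best[2], "rmsecv": best[0]},
        trace=trace,
    )


# ---------------------------------------------------------------------------
# BOSS

def boss_select(X, y, n_bootstrap: int = 500, keep_fraction: float = 0.10,
                folds: int = 10, n_lv: int | None = None, seed: int = 0,
                pool: np.ndarray | None = None) -> WavelengthSubset:
    """Bootstrapping soft shrinkage.

    Starting from equal weights on the pool, each iteration draws
    ``n_bootstrap`` variable subsets by weighted bootstrap sampling
    (pool-size draws with replacement; the subset is the set of unique
    draws), scores each sub-model by k-fold RMSECV, keeps the best
    ``keep_fraction``, and sums the kept sub-models' normalized |b| into the
    next weights.  Variables with zero weight leave the pool; iteration
    continues until one variable remains.  The returned subset is the
    sub-model with the global minimum RMSECV.

    If shrinkage ever stalls (identical pool after an iteration), the single
    minimum-weight variable is dropped to honour the strictly terminating,
    non-increasing contract.
    """
    if n_bootstrap < 10:
        raise ValueError("n_bootstrap must be >= 10")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    pool = np.arange(p) if pool is None else np.unique(np.asarray(pool, dtype=int))
    n_lv = _resolve_sub_lv(X[:, pool], y, n_lv, seed)
    rng = np.random.default_rng(seed)
    fold = kfold_split(n, folds, seed + 1, labels=y)
    weights = np.full(pool.size, 1.0 / pool.size)
    nvar_trace, rmsecv_trace = [], []
    best = None  # (rmsecv, size, iteration, subset)
    it = 0
    while pool.size > 1:
        nvar_trace.append(int(pool.size))
        n_keep = max(1, int(math.ceil(keep_fraction * n_bootstrap)))
        submodels = []
        for bnum in range(n_bootstrap):
            draws = rng.choice(pool.size, size=pool.size, replace=True, p=weights)
            sub = pool[np.unique(draws)]
            rmsecv = pls_rmsecv(X[:, sub], y, min(n_lv, sub.size), fold)
            submodels.append((rmsecv, sub.size, bnum, sub))
        submodels.sort(key=lambda s: (s[0], s[1], s[2]))
        kept = submodels[:n_keep]
        iter_best = kept[0]
        rmsecv_trace.append(iter_best[0])
        cand = (iter_best[0], iter_best[1], it, iter_best[3])
        if best is None or cand[:3] < best[:3]:
            best = cand
        new_w = np.zeros(p)
        for rmsecv, size, _, sub in kept:
            Xs = X[:, sub]
            b = np.abs(_coefficients_capped(Xs - Xs.mean(axis=0), y - y.mean(),
                                            min(n_lv, sub.size)))
            total = b.sum()
            if total > 0:
                new_w[sub] += b / total
        new_pool = np.flatnonzero(new_w > 0)
        if new_pool.size == 0:
            break
        if new_pool.size == pool.size and np.array_equal(new_pool, pool):
            # stall guard: drop the weakest variable (tie -> larger index)
            w_pool = new_w[pool]
            drop = pool[np.flatnonzero(w_pool == w_pool.min())[-1]]
            new_pool = pool[pool != drop]
            if new_pool.size == 0:
                break
        pool = new_pool
        w_pool = new_w[pool]
        weights = w_pool / w_pool.sum() if w_pool.sum() > 0 else np.full(pool.size, 1.0 / pool.size)
        it += 1
    # final single-variable model
    if pool.size >= 1:
        nvar_trace.append(int(pool.size))
        lv = 1
        rmsecv = pls_rmsecv(X[:, pool], y, lv, fold)
        rmsecv_trace.append(rmsecv)
        cand = (rmsecv, pool.size, it, pool.copy())
        if best is None or cand[:3] < best[:3]:
            best = cand
    trace = SelectionTrace(nvar_per_iteration=nvar_trace,
                           rmsecv_per_iteration=rmsecv_trace,
                           seeds={"seed": seed})
    return WavelengthSubset(
        indices=best[3], method="BOSS",
        params={"n_bootstrap": n_bootstrap, "keep_fraction": keep_fraction,
                "folds": folds, "n_lv": n_lv, "rmsecv": best[0]},
        trace=trace,
    )


# ---------------------------------------------------------------------------
# SPA

def _spa_chain(X: np.ndarray, start: int, length: int) -> list[int]:
    """Greedy successive-projection chain from a start column."""
    n, p = X.shape
    chain = [start]
    R = np.array(X, dtype=float, copy=True)
    for _ in range(length - 1):
        u = R[:, chain[-1]]
        uu = float(u @ u)
        if uu <= 1e-30:
            break
        R = R - np.outer(u, u @ R) / uu
        norms = np.einsum("ij,ij->j", R, R)
        norms[chain] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] <= 1e-30:
            break
        chain.append(nxt)
    return chain


def _mlr_rmsecv(X, y, fold_assignment) -> tuple[float, bool]:
    """k-fold RMSECV of an intercept MLR model; flags rank deficiency."""
    n = X.shape[0]
    scores = np.empty(n)
    deficient = False
    Z = np.column_stack([np.ones(n), X])
    for f in range(int(fold_assignment.max()) + 1):
        test = fold_assignment == f
        coef, _, rank, _ = np.linalg.lstsq(Z[~test], y[~test], rcond=None)
        if rank < Z.shape[1]:
            deficient = True
        scores[test] = Z[test] @ coef
    return float(np.sqrt(np.mean((scores - y) ** 2))), deficient


def spa_select(X, y, min_vars: int = 1, max_vars: int = 10,
               folds: int = 10, seed: int = 0) -> WavelengthSubset:
    """Successive projections algorithm with MLR RMSECV model choice.

    For every start channel a projection chain of ``max_vars`` channels is
    grown; every (start, length) candidate with length in
    [``min_vars``, ``max_vars``] is scored by k-fold RMSECV of a
    multiple-linear-regression model on the chain prefix.  The global
    minimum wins (ties: fewer variables, then smaller start index).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if not 1 <= min_vars <= max_vars:
        raise ValueError("need 1 <= min_vars <= max_vars")
    if max_vars > min(n - 2, p):
        raise ValueError(f"max_vars must be <= min(n-2, p) = {min(n - 2, p)}")
    fold = kfold_split(n, folds, seed, labels=np.sign(y).astype(int))
    best = None  # (rmsecv, length, start, subset, flagged)
    for start in range(p):
        chain = _spa_chain(X, start, max_vars)
        for length in range(min_vars, min(max_vars, len(chain)) + 1):
            sub = chain[:length]
            rmsecv, deficient = _mlr_rmsecv(X[:, sub], y, fold)
            cand = (rmsecv, length, start, sub, deficient)
            if best is None or cand[:3] < best[:3]:
                best = cand
    trace = SelectionTrace(seeds={"seed": seed})
    if best[4]:
        trace.notes.append("rank-deficient MLR: pseudo-inverse fallback used")
    return WavelengthSubset(
        indices=np.sort(best[3]), method="SPA",
        params={"min_vars": min_vars, "max_vars": max_vars,
                "start": best[2], "rmsecv": best[0]},
        trace=trace,
    )


# ---------------------------------------------------------------------------
# chains

SELECTORS = {
    "mcuve": mcuve_select,
    "cars": cars_select,
    "boss": boss_select,
    "spa": spa_select,
}

_METHOD_LABEL = {"mcuve": "MC-UVE", "cars": "CARS", "boss": "BOSS", "spa": "SPA"}


def chain_select(stages, X, y) -> WavelengthSubset:
    """Run selectors sequentially, each on the previous stage's channels.

    ``stages`` is an ordered list of ``(name, kwargs)`` with names from
    :data:`SELECTORS`.  Returned indices always refer to the original grid.
    """
    if not stages:
        raise ValueError("need at least one stage")
    X = np.asarray(X, dtype=float)
    current = np.arange(X.shape[1])
    labels = []
    traces = []
    params = {}
    for name, kwargs in stages:
        if name not in SELECTORS:
            raise ValueError(f"unknown selector {name!r}")
        subset = SELECTORS[name](X[:, current], y, **kwargs)
        current = current[subset.indices]
        if current.size == 0:
            raise ValueError(f"stage {name} returned an empty set")
        labels.append(_METHOD_LABEL[name])
        traces.append(subset.trace)
        params[name] = subset.params
    trace = traces[0] if len(traces) == 1 else _merge_traces(traces)
    return WavelengthSubset(indices=current, method=">".join(labels),
                            params=params, trace=trace)


def _merge_traces(traces: list[SelectionTrace]) -> SelectionTrace:
    merged = SelectionTrace()
    for t in traces:
        if t.stability is not None and merged.stability is None:
            merged.stability = t.stability
        merged.rmsep_curve.extend(t.rmsep_curve)
        merged.nvar_per_iteration.extend(t.nvar_per_iteration)
        merged.rmsecv_per_iteration.extend(t.rmsecv_per_iteration)
        merged.seeds.update(t.seeds)
        merged.notes.extend(t.notes)
    return merged
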