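"""Model-level selection: category order, covariate count, covariate subset.

Three selection layers sit on top of the likelihood core:

* **Working-order / baseline selection.**  The cumulative,
  adjacent-categories and continuation-ratio links depend on the order of
  the response categories, and the baseline-category po model depends on
  which category is the reference.  Even for nominal responses, the order
  (or baseline) minimizing AIC — the *working* order — can improve
  prediction substantially.  For J small enough the search is exhaustive
  over all J! permutations; for adjacent-categories po models an order and
  its reverse are guaranteed to tie.

* **Covariate-count selection by cross-validated cross-entropy.**  Given a
  screening ranking, the number t of top covariates is chosen to minimize
  ``CE(t) = -(1/n) sum_i log(pihat_{i, y_i})`` where ``pihat`` is predicted
  for observation i by the model fitted on the K-1 folds not containing i.
  The fold partition is an unstratified seeded split of the *original*
  observations into K blocks of near-equal size.

* **Backward elimination by AIC.**  Starting from the chosen covariate set,
  repeatedly refit with each single covariate removed; drop the one whose
  removal lowers AIC most, while any removal strictly lowers it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .mlogit import (
    CategoricalDataset,
    FitResult,
    ModelSpec,
    fit,
    hard_labels,
    predict,
)

__all__ = [
    "OrderSearchResult",
    "CVReport",
    "SelectionTrace",
    "select_order",
    "select_baseline",
    "fold_assignment",
    "cross_entropy",
    "cv_cross_entropy",
    "choose_num_covariates",
    "backward_select",
]

_TOL = 1e-6


@dataclass
class OrderSearchResult:
    """Exhaustive AIC table over category orders, plus the argmin."""

    table: list  # list of (order tuple, aic)
    best_order: tuple
    best_aic: float
    tied_orders: list = field(default_factory=list)


def select_order(
    spec: ModelSpec,
    data: CategoricalDataset,
    exhaustive_limit: int = 8,
    fit_options: dict | None = None,
) -> OrderSearchResult:
    """Fit ``spec`` under every permutation of the category order.

    Only meaningful for po structure (npo fits are order-invariant for the
    baseline and adjacent links, and order selection is defined for po
    models).  Ties — including the guaranteed reversal tie of the
    adjacent-categories po model — are broken by the lexicographically
    smallest permutation.
    """
    if spec.structure != "po":
        raise ValueError("order selection applies to po models")
    J = data.J
    if J > exhaustive_limit:
        raise ValueError(
            f"J={J} exceeds exhaustive_limit={exhaustive_limit}; "
            "supply a candidate order list instead"
        )
    opts = fit_options or {}
    table = []
    for perm in itertools.permutations(range(J)):
        res = fit(spec, data.with_order(np.array(perm)), **opts)
        table.append((perm, res.aic))
    best_aic = min(a for _, a in table)
    tied = sorted(p for p, a in table if a <= best_aic + _TOL)
    return OrderSearchResult(table, tied[0], best_aic, tied)


def select_baseline(
    data: CategoricalDataset,
    spec: ModelSpec,
    fit_options: dict | None = None,
) -> tuple[int, list]:
    """Choose the reference category of a baseline-category po model by AIC.

    Returns ``(best_index, table)`` with one fit per candidate baseline;
    ties go to the smallest category index.  Rejected for npo structure,
    where the baseline choice cannot change the fit.
    """
    if spec.link != "baseline_category":
        raise ValueError("baseline selection applies to the baseline_category link")
    if spec.structure != "po":
        raise ValueError("baseline choice is irrelevant for npo models")
    opts = fit_options or {}
    table = []
    for b in range(data.J):
        res = fit(ModelSpec(spec.link, spec.structure, baseline_index=b), data, **opts)
        table.append((b, res.aic))
    best_aic = min(a for _, a in table)
    best = min(b for b, a in table if a <= best_aic + _TOL)
    return best, table


def fold_assignment(n: int, K: int, seed=None, y=None) -> np.ndarray:
    """Seeded K-fold map: k(i) in {0..K-1}, sizes differ by <= 1.

    Default is unstratified: a seeded permutation of 0..n-1 cut into
    blocks, the first ``n mod K`` blocks of size ceil(n/K), the rest
    floor(n/K).  Passing the label vector ``y`` switches to stratified
    folding (labels dealt round-robin within each class) — an optional
    variant; the procedure's own choice is unstratified.
    """
    if n < K:
        raise ValueError("need n >= K observations")
    rng = np.random.default_rng(seed)
    if y is not None:
        y = np.asarray(y)
        if y.size != n:
            raise ValueError("y must have length n")
        folds = np.empty(n, dtype=int)
        offset = 0
        for cls in np.unique(y):
            idx = np.nonzero(y == cls)[0]
            perm = rng.permutation(idx.size)
            folds[idx[perm]] = (offset + np.arange(idx.size)) % K
            offset += idx.size
        return folds
    perm = rng.permutation(n)
    sizes = np.full(K, n // K)
    sizes[: n % K] += 1
    folds = np.empty(n, dtype=int)
    start = 0
    for k, s in enumerate(sizes):
        folds[perm[start : start + s]] = k
        start += s
    return folds


def cross_entropy(prob_matrix, y) -> float:
    """-(1/n) sum_i log p_i(y_i); infinite if any true-class probability is 0."""
    pm = np.asarray(prob_matrix, dtype=float)
    y = np.asarray(y, dtype=int)
    p = pm[np.arange(y.size), y]
    if np.any(p <= 0.0):
        return float("inf")
    return float(-np.mean(np.log(p)))


@dataclass
class CVReport:
    """K-fold cross-validation outcome for one model configuration."""

    fold_map: np.ndarray
    ce: float
    error_count: int
    error_rate: float
    probs: np.ndarray  # (n, J) held-out predictive probabilities
    fold_fits: list
    failed_folds: list


def cv_cross_entropy(
    spec: ModelSpec,
    X,
    y,
    K: int = 5,
    seed=None,
    order=None,
    J: int | None = None,
    fit_options: dict | None = None,
    fold_map: np.ndarray | None = None,
    stratified: bool = False,
) -> CVReport:
    """K-fold cross-validated cross-entropy and error count for ``spec``.

    Operates on the original per-observation data: each fold's model is
    fitted on the other K-1 blocks (summarized internally) and predicts
    held-out probabilities.  A fold whose fit is infeasible (e.g. too few
    distinct rows after screening) poisons the configuration with
    ``ce = +inf`` rather than being dropped, so comparisons stay
    conservative.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = y.size
    if J is None:
        J = int(y.max()) + 1
    if fold_map is None:
        fold_map = fold_assignment(n, K, seed, y=y if stratified else None)
    else:
        fold_map = np.asarray(fold_map, dtype=int)
        K = int(fold_map.max()) + 1
    opts = fit_options or {}
    probs = np.full((n, J), np.nan)
    fold_fits = []
    failed = []
    for k in range(K):
        test = fold_map == k
        train = ~test
        try:
            ds = CategoricalDataset.from_raw(X[train], y[train], J=J, order=order)
            res = fit(spec, ds, **opts)
        except ValueError:
            failed.append(k)
            fold_fits.append(None)
            continue
        pi, _ = predict(res, X[test])
        probs[test] = pi
        fold_fits.append(
            {"fold": k, "loglik": res.loglik, "aic": res.aic,
             "converged": res.converged, "separation": res.separation_flag}
        )
    if failed:
        ce = float("inf")
        ok = ~np.isnan(probs[:, 0])
        errors = int(np.sum(hard_labels(probs[ok]) != y[ok])) + int(np.sum(~ok))
    else:
        ce = cross_entropy(probs, y)
        errors = int(np.sum(hard_labels(probs) != y))
    return CVReport(fold_map, ce, errors, errors / n, probs, fold_fits, failed)


#: Covariate-count grid used by default when sizing models from a ranking.
DEFAULT_T_GRID = (25, 30, 50, 60, 70, 80, 100, 150)


def choose_num_covariates(
    ranked_columns,
    X,
    y,
    specs,
    t_grid=DEFAULT_T_GRID,
    K: int = 5,
    seed=None,
    J: int | None = None,
    fit_options: dict | None = None,
) -> tuple[ModelSpec, int, list]:
    """Pick (spec, t) minimizing CV cross-entropy over top-t ranked columns.

    All configurations share one seeded fold map so they are compared on
    identical partitions.  Ties go to the smaller t, then to the order the
    specs were given in.  Returns ``(best_spec, best_t, table)`` where the
    table rows are ``(spec, t, ce, error_count, error_rate)``.
    """
    ranked_columns = list(ranked_columns)
    t_grid = [t for t in t_grid if t <= len(ranked_columns)]
    if not t_grid:
        raise ValueError("no t in t_grid is <= the number of ranked covariates")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    folds = fold_assignment(y.size, K, seed)
    table = []
    best = None
    best_key = None
    for si, spec in enumerate(specs):
        for t in t_grid:
            cols = ranked_columns[:t]
            rep = cv_cross_entropy(
                spec, X[:, cols], y, K=K, J=J, fold_map=folds,
                fit_options=fit_options,
            )
            table.append((spec, t, rep.ce, rep.error_count, rep.error_rate))
            key = (rep.ce, t, si)
            if best is None or key < best_key:
                best, best_key = (spec, t), key
    return best[0], best[1], table


@dataclass
class SelectionTrace:
    """Backward-elimination path: removals in order, with the AIC after each."""

    start_ids: list
    steps: list  # list of (removed_id, aic_after_removal)
    final_ids: list
    start_aic: float
    final_aic: float


def backward_select(
    spec: ModelSpec,
    X,
    y,
    start_columns,
    order=None,
    J: int | None = None,
    warm_start: bool = True,
    fit_options: dict | None = None,
) -> SelectionTrace:
    """Backward AIC elimination from ``start_columns``.

    At each round, the covariate whose removal yields the smallest AIC is
    dropped if that AIC strictly improves on the current one (ties on the
    removal candidate go to the smallest column index); the procedure stops
    when no single removal helps, or when the set is empty.  Warm starts
    reuse the surviving coefficients of the current fit as the initial
    point of each candidate refit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if J is None:
        J = int(y.max()) + 1
    opts = fit_options or {}
    current = list(start_columns)

    def _fit_subset(cols, init=None):
        ds = CategoricalDataset.from_raw(X[:, cols], y, J=J, order=order)
        kw = dict(opts)
        if init is not None:
            kw["init"] = init
        return fit(spec, ds, **kw)

    res = _fit_subset(current)
    if not np.isfinite(res.aic):
        raise ValueError("AIC is not finite for the starting covariate set")
    start_aic = res.aic
    steps = []
    while current:
        best_drop = None
        best_aic = None
        best_res = None
        for pos, col in enumerate(current):
            reduced = current[:pos] + current[pos + 1 :]
            init = _drop_params(res, pos) if warm_start else None
            try:
                cand = _fit_subset(reduced, init=init)
            except ValueError:
                continue
            if best_aic is None or cand.aic < best_aic - _TOL or (
                abs(cand.aic - best_aic) <= _TOL and col < best_drop
            ):
                best_drop, best_aic, best_res = col, cand.aic, cand
        if best_aic is None or best_aic >= res.aic:
            break
        current = [c for c in current if c != best_drop]
        res = best_res
        steps.append((best_drop, best_aic))
    return SelectionTrace(list(start_columns), steps, current, start_aic, res.aic)


def _drop_params(res: FitResult, pos: int):
    """Initial parameters for a refit with the covariate at ``pos`` removed."""
    from .mlogit import Params

    if res.spec.structure == "po":
        beta = [b.copy() for b in res.params.beta]
        zeta = np.delete(res.params.zeta, pos)
        return Params(beta, zeta)
    beta = [np.delete(b, pos + 1) for b in res.params.beta]  # slot 0 is intercept
    return Params(beta, np.zeros(0))
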