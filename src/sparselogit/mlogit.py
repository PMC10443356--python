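"""Maximum-likelihood core for multinomial logistic models.

Grouped categorical data ``{(x_i, Y_i)}`` with distinct covariate rows
``x_i`` and multinomial count vectors ``Y_i`` (``n_i = sum_j Y_ij``) is
modelled through one of four logit links, each relating the category
probabilities ``pi_{i1..iJ}`` to linear predictors
``eta_j = h_j(x)' beta_j + h_c(x)' zeta``, j = 1..J-1:

* ``baseline_category``:    log(pi_j / pi_J)
* ``cumulative``:           log((pi_1+..+pi_j) / (pi_{j+1}+..+pi_J))
* ``adjacent_categories``:  log(pi_j / pi_{j+1})
* ``continuation_ratio``:   log(pi_j / (pi_{j+1}+..+pi_J))

Two main-effects structures are supported: proportional odds (``po``,
category-specific intercepts beta_j with a shared slope vector zeta, so
h_j = 1 and h_c(x) = x) and nonproportional odds (``npo``, a full
per-category coefficient vector, h_j(x) = (1, x')' and h_c = 0).  Four links
times two structures give the eight candidate models.  At J = 2 every
combination reduces to ordinary binary logistic regression.

Fitting is Fisher scoring with step halving, which keeps the likelihood
ascent monotone and — important for the cumulative link, whose probabilities
can leave the simplex — never steps onto an invalid iterate.  Quasi-separated
data (common once informative covariates are selected) is handled by an
iteration cap plus a ``separation_flag`` rather than by penalisation.

The multinomial coefficient is omitted from the log-likelihood: it is a
constant of the data, identical across the eight models, so AIC comparisons
are unaffected; absolute values differ from implementations that include it
by that data-only constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

__all__ = [
    "LINKS",
    "STRUCTURES",
    "ModelSpec",
    "Params",
    "CategoricalDataset",
    "FitResult",
    "linear_predictors",
    "probs_from_eta",
    "loglik",
    "fit",
    "aic",
    "predict",
    "hard_labels",
]

LINKS = (
    "baseline_category",
    "cumulative",
    "adjacent_categories",
    "continuation_ratio",
)
STRUCTURES = ("po", "npo")


@dataclass(frozen=True)
class ModelSpec:
    """A link + structure choice (one of the eight candidate models).

    ``baseline_index`` (original category index, 0-based) applies only to
    the baseline-category link: that category is moved to the end of the
    working order and serves as the reference.  The choice matters for po
    models; for npo models it is irrelevant to the fit.
    """

    link: str
    structure: str
    baseline_index: int | None = None

    def __post_init__(self) -> None:
        if self.link not in LINKS:
            raise ValueError(f"link must be one of {LINKS}, got {self.link!r}")
        if self.structure not in STRUCTURES:
            raise ValueError(f"structure must be 'po' or 'npo', got {self.structure!r}")
        if self.baseline_index is not None and self.link != "baseline_category":
            raise ValueError("baseline_index applies only to the baseline_category link")

    def n_params(self, J: int, d: int) -> int:
        """Parameter count p of the main-effects model."""
        if self.structure == "po":
            return (J - 1) + d
        return (J - 1) * (d + 1)

    def min_rows(self, J: int, d: int) -> int:
        """Smallest number m of distinct covariate rows that can be fitted.

        p_c + 1 for po models, max_j p_j for npo models; for main-effects
        models both equal d + 1.
        """
        return d + 1


@dataclass
class Params:
    """Regression parameters: per-category ``beta`` plus shared ``zeta``.

    po main-effects: each beta_j is a length-1 intercept and zeta has
    length d (p = J-1+d).  npo main-effects: each beta_j has length d+1
    (intercept first) and zeta is empty (p = (J-1)(d+1)).
    """

    beta: list
    zeta: np.ndarray

    @property
    def p(self) -> int:
        return sum(len(b) for b in self.beta) + len(self.zeta)

    def flatten(self) -> np.ndarray:
        return np.concatenate([np.concatenate(self.beta), np.asarray(self.zeta)])

    @classmethod
    def from_flat(cls, theta: np.ndarray, spec: ModelSpec, J: int, d: int) -> "Params":
        theta = np.asarray(theta, dtype=float)
        if spec.structure == "po":
            beta = [theta[j : j + 1].copy() for j in range(J - 1)]
            zeta = theta[J - 1 :].copy()
        else:
            w = d + 1
            beta = [theta[j * w : (j + 1) * w].copy() for j in range(J - 1)]
            zeta = np.zeros(0)
        return cls(beta, zeta)

    @classmethod
    def zeros(cls, spec: ModelSpec, J: int, d: int) -> "Params":
        return cls.from_flat(np.zeros(spec.n_params(J, d)), spec, J, d)


class CategoricalDataset:
    """Summarized categorical data: distinct rows X, count matrix Y.

    ``order`` is the working order of the response categories — the
    permutation of ``range(J)`` under which order-dependent links are
    fitted.  Changing the order only permutes the columns of Y that the
    optimizer sees; predictions are always mapped back to the original
    category labelling.
    """

    def __init__(self, X, Y, category_names=None, order=None):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y)
        if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
            raise ValueError("X must be (m, d) and Y (m, J) with matching m")
        if np.any(Y < 0) or not np.issubdtype(Y.dtype, np.integer):
            raise ValueError("Y must hold non-negative integer counts")
        if Y.shape[1] < 2:
            raise ValueError("need at least 2 response categories")
        n_i = Y.sum(axis=1)
        if np.any(n_i <= 0):
            raise ValueError("every row must have a positive total count")
        if X.shape[1] > 0:
            uniq = np.unique(X, axis=0)
            if uniq.shape[0] != X.shape[0]:
                raise ValueError("rows of X must be distinct (summarized form)")
        self.X = X
        self.Y = Y.astype(np.int64)
        J = Y.shape[1]
        if category_names is None:
            category_names = tuple(f"cat{j + 1}" for j in range(J))
        if len(category_names) != J:
            raise ValueError("category_names length must equal J")
        self.category_names = tuple(category_names)
        if order is None:
            order = np.arange(J)
        order = np.asarray(order, dtype=int)
        if sorted(order.tolist()) != list(range(J)):
            raise ValueError("order must be a permutation of range(J)")
        self.order = order

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def J(self) -> int:
        return self.Y.shape[1]

    @property
    def n_i(self) -> np.ndarray:
        return self.Y.sum(axis=1)

    @property
    def n(self) -> int:
        return int(self.Y.sum())

    def with_order(self, order) -> "CategoricalDataset":
        """Same data viewed under a different working order."""
        return CategoricalDataset(self.X, self.Y, self.category_names, order)

    @classmethod
    def from_raw(cls, X, y, J=None, category_names=None, order=None):
        """Summarize per-observation data (x_i, y_i) into distinct-row form.

        ``y`` holds 0-based category indices.  Identical covariate rows are
        merged into one row with aggregated counts (lossless: ``to_raw``
        recovers the multiset of (x, y) pairs).
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
            raise ValueError("X must be (n, d) and y a length-n label vector")
        if J is None:
            J = int(y.max()) + 1
        if np.any(y < 0) or np.any(y >= J):
            raise ValueError("labels must lie in [0, J)")
        if X.shape[1] == 0:
            inv = np.zeros(X.shape[0], dtype=int)
            ux = np.zeros((1, 0))
        else:
            ux, inv = np.unique(X, axis=0, return_inverse=True)
        Y = np.zeros((ux.shape[0], J), dtype=np.int64)
        np.add.at(Y, (inv, y), 1)
        return cls(ux, Y, category_names, order)

    def to_raw(self) -> tuple[np.ndarray, np.ndarray]:
        """Expand back to per-observation form (row-repeated X, labels)."""
        rows, labels = [], []
        for i in range(self.m):
            for j in range(self.J):
                c = self.Y[i, j]
                if c > 0:
                    rows.append(np.repeat(self.X[i : i + 1], c, axis=0))
                    labels.append(np.full(c, j))
        return np.vstack(rows), np.concatenate(labels)


@dataclass
class FitResult:
    """A fitted model: spec, parameters, likelihood, AIC, convergence record.

    ``perm`` records the category order (original indices) the optimizer
    used, including any baseline move; ``predict`` maps through it.
    """

    spec: ModelSpec
    params: Params
    loglik: float
    aic: float
    n_iter: int
    converged: bool
    grad_norm: float
    separation_flag: bool
    perm: np.ndarray
    J: int
    d: int
    category_names: tuple = ()


# ---------------------------------------------------------------------------
# link functions: probabilities and Jacobians from linear predictors
# ---------------------------------------------------------------------------

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def probs_from_eta(link: str, eta) -> np.ndarray:
    """Map linear predictors (m, J-1) to category probabilities (m, J).

    Log-sum-exp stabilized.  For every link the rows sum to one; the
    cumulative link can produce *negative* entries when the latent
    cumulative logits are not increasing — these are returned as-is so the
    fitter can reject the iterate rather than silently clipping.
    """
    eta = np.asarray(eta, dtype=float)
    squeeze = eta.ndim == 1
    if squeeze:
        eta = eta[None, :]
    m, Jm1 = eta.shape
    J = Jm1 + 1
    if link == "baseline_category":
        z = np.concatenate([eta, np.zeros((m, 1))], axis=1)
        pi = _softmax(z)
    elif link == "adjacent_categories":
        # u_j = sum_{l>=j} eta_l, u_J = 0
        u = np.concatenate(
            [np.cumsum(eta[:, ::-1], axis=1)[:, ::-1], np.zeros((m, 1))], axis=1
        )
        pi = _softmax(u)
    elif link == "continuation_ratio":
        # log rho = -softplus(-eta), log(1-rho) = -softplus(eta)
        log_rho = -np.logaddexp(0.0, -eta)
        log_1m = -np.logaddexp(0.0, eta)
        csum = np.concatenate([np.zeros((m, 1)), np.cumsum(log_1m, axis=1)], axis=1)
        logpi = np.concatenate([log_rho + csum[:, :-1], csum[:, -1:]], axis=1)
        pi = np.exp(logpi)
        pi /= pi.sum(axis=1, keepdims=True)
    elif link == "cumulative":
        gamma = 1.0 / (1.0 + np.exp(-eta))
        full = np.concatenate([np.zeros((m, 1)), gamma, np.ones((m, 1))], axis=1)
        pi = np.diff(full, axis=1)
    else:
        raise ValueError(f"unknown link {link!r}")
    return pi[0] if squeeze else pi


def _jacobian(link: str, eta: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """d pi / d eta, shape (m, J, J-1)."""
    m, Jm1 = eta.shape
    J = Jm1 + 1
    if link == "baseline_category":
        E = np.zeros((J, Jm1))
        E[:Jm1, :] = np.eye(Jm1)
        return pi[:, :, None] * (E[None, :, :] - pi[:, None, :Jm1])
    if link == "adjacent_categories":
        U = np.zeros((J, Jm1))
        for j in range(Jm1):
            U[: j + 1, j] = 1.0  # du_l/d eta_j = 1 for l <= j
        piU = np.einsum("ij,jk->ik", pi, U)
        return pi[:, :, None] * (U[None, :, :] - piU[:, None, :])
    if link == "cumulative":
        gamma = 1.0 / (1.0 + np.exp(-eta))
        dg = gamma * (1.0 - gamma)
        jac = np.zeros((m, J, Jm1))
        for k in range(Jm1):
            jac[:, k, k] += dg[:, k]
            jac[:, k + 1, k] -= dg[:, k]
        return jac
    if link == "continuation_ratio":
        rho = 1.0 / (1.0 + np.exp(-eta))
        jac = np.zeros((m, J, Jm1))
        for j in range(J):
            for k in range(Jm1):
                if k < j:
                    jac[:, j, k] = -pi[:, j] * rho[:, k]
                elif k == j:
                    jac[:, j, k] = pi[:, j] * (1.0 - rho[:, j])
        return jac
    raise ValueError(f"unknown link {link!r}")


# ---------------------------------------------------------------------------
# design matrices and linear predictors
# ---------------------------------------------------------------------------

def _design(spec: ModelSpec, X: np.ndarray, J: int) -> np.ndarray:
    """Per-row design tensor A with eta_i = A_i @ theta, shape (m, J-1, p)."""
    m, d = X.shape
    Jm1 = J - 1
    if spec.structure == "po":
        p = Jm1 + d
        A = np.zeros((m, Jm1, p))
        for j in range(Jm1):
            A[:, j, j] = 1.0
            A[:, j, Jm1:] = X
    else:
        w = d + 1
        p = Jm1 * w
        A = np.zeros((m, Jm1, p))
        for j in range(Jm1):
            A[:, j, j * w] = 1.0
            A[:, j, j * w + 1 : (j + 1) * w] = X
    return A


def linear_predictors(spec: ModelSpec, params: Params, x) -> np.ndarray:
    """eta_j = h_j(x)' beta_j + h_c(x)' zeta for a single covariate vector."""
    x = np.asarray(x, dtype=float).ravel()
    Jm1 = len(params.beta)
    eta = np.empty(Jm1)
    if spec.structure == "po":
        if len(params.zeta) != x.size:
            raise ValueError("zeta length must match the covariate dimension")
        shared = float(x @ params.zeta)
        for j in range(Jm1):
            if len(params.beta[j]) != 1:
                raise ValueError("po models carry a single intercept per category")
            eta[j] = params.beta[j][0] + shared
    else:
        for j in range(Jm1):
            b = params.beta[j]
            if len(b) != x.size + 1:
                raise ValueError("npo beta_j must have length d + 1")
            eta[j] = b[0] + float(x @ b[1:])
    return eta


def _eta_matrix(spec: ModelSpec, theta: np.ndarray, A: np.ndarray) -> np.ndarray:
    return np.einsum("ijp,p->ij", A, theta)


# ---------------------------------------------------------------------------
# likelihood and fitting
# ---------------------------------------------------------------------------

def _loglik_from_pi(Y: np.ndarray, pi: np.ndarray) -> float:
    """sum_ij Y_ij log pi_ij with the 0*log(0) = 0 convention."""
    mask = Y > 0
    if np.any(pi[mask] <= 0):
        return -np.inf
    return float(np.sum(Y[mask] * np.log(pi[mask])))


def loglik(spec: ModelSpec, params: Params, data: CategoricalDataset) -> float:
    """Grouped multinomial log-likelihood (multinomial coefficient omitted)."""
    perm = _fit_perm(spec, data)
    Yw = data.Y[:, perm]
    A = _design(spec, data.X, data.J)
    eta = _eta_matrix(spec, params.flatten(), A)
    pi = probs_from_eta(spec.link, eta)
    return _loglik_from_pi(Yw, pi)


def _fit_perm(spec: ModelSpec, data: CategoricalDataset) -> np.ndarray:
    """Category order used by the optimizer (working order, baseline last)."""
    perm = data.order.copy()
    if spec.link == "baseline_category" and spec.baseline_index is not None:
        b = spec.baseline_index
        if not 0 <= b < data.J:
            raise ValueError("baseline_index out of range")
        perm = np.array([c for c in perm if c != b] + [b])
    return perm


def _valid_pi(link: str, pi: np.ndarray, Y: np.ndarray) -> bool:
    if link == "cumulative":
        return bool(np.all(pi > 0))
    return bool(np.all(pi[Y > 0] > 0))


def _init_theta(spec: ModelSpec, Yw: np.ndarray, J: int, d: int) -> np.ndarray:
    """beta = 0, zeta = 0; cumulative intercepts from marginal cumulative logits."""
    theta = np.zeros(spec.n_params(J, d))
    if spec.link == "cumulative":
        freq = Yw.sum(axis=0) / Yw.sum()
        q = np.clip(np.cumsum(freq)[:-1], 1e-6, 1 - 1e-6)
        # enforce strictly increasing in case of empty categories
        q = np.maximum.accumulate(q + 1e-9 * np.arange(J - 1))
        cuts = np.log(q / (1 - q))
        if spec.structure == "po":
            theta[: J - 1] = cuts
        else:
            for j in range(J - 1):
                theta[j * (d + 1)] = cuts[j]
    return theta


def fit(
    spec: ModelSpec,
    data: CategoricalDataset,
    max_iter: int = 30,
    tol: float = 1e-8,
    gtol: float = 1e-4,
    init: Params | None = None,
) -> FitResult:
    """Fisher-scoring MLE with step halving (monotone likelihood ascent).

    Returns ``converged=False`` with the best iterate if ``max_iter`` is
    reached, and sets ``separation_flag`` when the likelihood stalls with a
    non-vanishing gradient or the fitted probabilities at observed
    categories reach 1 to within 1e-10 — the signature of quasi-separation,
    where the supremum is approached but not attained.
    """
    J, d, m = data.J, data.d, data.m
    if m < spec.min_rows(J, d):
        raise ValueError(
            f"need at least {spec.min_rows(J, d)} distinct covariate rows to fit "
            f"{spec.link}-{spec.structure} with d={d} (have m={m}); "
            "screen covariates down first"
        )
    perm = _fit_perm(spec, data)
    Yw = data.Y[:, perm].astype(float)
    n_i = Yw.sum(axis=1)
    A = _design(spec, data.X, J)
    p = spec.n_params(J, d)

    theta = _init_theta(spec, Yw, J, d) if init is None else init.flatten().copy()
    if theta.size != p:
        raise ValueError("init has the wrong number of parameters")
    eta = _eta_matrix(spec, theta, A)
    pi = probs_from_eta(spec.link, eta)
    if not _valid_pi(spec.link, pi, Yw):
        theta = _init_theta(spec, Yw, J, d)
        eta = _eta_matrix(spec, theta, A)
        pi = probs_from_eta(spec.link, eta)
    ll = _loglik_from_pi(Yw, pi)
    if not np.isfinite(ll):
        raise ValueError("log-likelihood not finite at the initial point")

    grad_norm = np.inf
    converged = False
    stalled = False
    improve = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        safe_pi = np.maximum(pi, 1e-12)
        jac = _jacobian(spec.link, eta, pi)
        S = np.where(Yw > 0, Yw / safe_pi, 0.0)
        g_eta = np.einsum("ijk,ij->ik", jac, S)
        g = np.einsum("ikp,ik->p", A, g_eta)
        grad_norm = float(np.linalg.norm(g))
        W = np.einsum("ija,ij,ijb->iab", jac, n_i[:, None] / safe_pi, jac)
        T = np.einsum("iab,ibp->iap", W, A)
        F = np.einsum("iap,iaq->pq", A, T)
        # tiny ridge keeps the solve well-posed under quasi-separation
        ridge = 1e-10 * (np.trace(F) / p + 1.0)
        try:
            delta = sla.solve(F + ridge * np.eye(p), g, assume_a="pos")
        except sla.LinAlgError:
            delta = np.linalg.lstsq(F + ridge * np.eye(p), g, rcond=None)[0]
        if not np.all(np.isfinite(delta)):
            stalled = True
            break

        lam = 1.0
        accepted = False
        while lam >= 2.0**-30:
            cand = theta + lam * delta
            eta_c = _eta_matrix(spec, cand, A)
            pi_c = probs_from_eta(spec.link, eta_c)
            if _valid_pi(spec.link, pi_c, Yw):
                ll_c = _loglik_from_pi(Yw, pi_c)
                if np.isfinite(ll_c) and ll_c >= ll:
                    accepted = True
                    break
            lam *= 0.5
        if not accepted:
            stalled = True
            break
        theta, eta, pi = cand, eta_c, pi_c
        improve = ll_c - ll
        ll = ll_c
        if improve < tol:
            converged = grad_norm <= gtol * (1.0 + abs(ll))
            break

    mask = Yw > 0
    near_one = bool(np.any(pi[mask] >= 1.0 - 1e-10)) and d > 0
    stalled_short = improve < tol and not converged
    separation = near_one or stalled or stalled_short
    params = Params.from_flat(theta, spec, J, d)
    result = FitResult(
        spec=spec,
        params=params,
        loglik=float(ll),
        aic=-2.0 * float(ll) + 2.0 * p,
        n_iter=n_iter,
        converged=converged,
        grad_norm=grad_norm,
        separation_flag=separation,
        perm=perm,
        J=J,
        d=d,
        category_names=data.category_names,
    )
    return result


def aic(result: FitResult) -> float:
    """AIC = -2 loglik + 2 p."""
    if not np.isfinite(result.loglik):
        raise ValueError("AIC undefined for a non-finite log-likelihood")
    return -2.0 * result.loglik + 2.0 * result.params.p


def hard_labels(prob_matrix) -> np.ndarray:
    """Argmax category per row; exact ties go to the smallest category index."""
    pm = np.asarray(prob_matrix, dtype=float)
    if pm.ndim == 1:
        pm = pm[None, :]
    return pm.argmax(axis=1)


def predict(result: FitResult, X_new) -> tuple[np.ndarray, np.ndarray]:
    """Predictive probabilities and hard labels for new covariate rows.

    Probabilities are computed under the fit's working order and mapped back
    to the original category labelling.  The cumulative link can produce
    slightly negative probabilities for covariate values outside the
    training range; those are clipped to zero and the row renormalized
    (prediction only — the fitter itself never clips).
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != result.d:
        raise ValueError(f"X_new must have {result.d} columns")
    A = _design(result.spec, X_new, result.J)
    eta = _eta_matrix(result.spec, result.params.flatten(), A)
    pi_work = probs_from_eta(result.spec.link, eta)
    if result.spec.link == "cumulative":
        pi_work = np.clip(pi_work, 0.0, None)
        pi_work /= pi_work.sum(axis=1, keepdims=True)
    pi = np.empty_like(pi_work)
    pi[:, result.perm] = pi_work
    return pi, hard_labels(pi)
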