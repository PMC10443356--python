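"""Candidate distributions for sparse non-negative continuous measurements.

Expression-level vectors in RNA-seq style data are continuous, skewed, and
carry a substantial fraction of exact zeros.  The screening stage therefore
models each covariate with one member of a 12-family candidate set: four
continuous baselines (normal, half-normal, log-normal, exponential) each in a
plain, a zero-inflated (``zi_``) and a hurdle variant.  A zero-inflated or
hurdle family is a mixture of a point mass at zero with weight ``phi`` and
the continuous baseline carrying weight ``1 - phi``; because a continuous
baseline assigns zero probability to {0}, the zero-inflated and hurdle
likelihoods coincide here, but both labels are kept so the candidate set has
its full 12 members.

All maximum-likelihood estimates are closed form:

* normal: sample mean and the 1/n variance;
* half-normal: ``sigma^2`` = mean of squares;
* log-normal: mean and 1/n-sd of the logs of the positive values;
* exponential: rate = 1 / mean;
* ``phi`` in zero-mass families: fraction of exact zeros, with the baseline
  fitted to the nonzero values only.

Goodness of fit is a one-sample Kolmogorov–Smirnov statistic against the
fitted mixed CDF (a jump of size ``phi`` at zero where applicable).  Because
parameters are estimated and the CDF may have an atom, the classical KS null
distribution does not apply; p-values come from a seeded parametric
bootstrap: resample from the fitted model, refit, recompute the statistic,
and report the proportion of bootstrap statistics at least as large as the
observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import special

__all__ = [
    "FAMILY_NAMES",
    "DistFamily",
    "SparseDistFit",
    "NoFeasibleFamilyError",
    "fit_family",
    "ks_statistic",
    "ks_pvalue",
    "select_family",
    "sample_fit",
    "rvs",
]

#: Canonical order of the 12-family candidate set; also the tie-break order.
FAMILY_NAMES = (
    "normal",
    "zi_normal",
    "normal_hurdle",
    "half_normal",
    "zi_half_normal",
    "half_normal_hurdle",
    "log_normal",
    "zi_log_normal",
    "log_normal_hurdle",
    "exponential",
    "zi_exponential",
    "exponential_hurdle",
)

# baseline name -> (parameter names, parameter count)
_BASELINES = {
    "normal": (("mean", "sd"), 2),
    "half_normal": (("sigma",), 1),
    "log_normal": (("logmean", "logsd"), 2),
    "exponential": (("rate",), 1),
}


class NoFeasibleFamilyError(ValueError):
    """Raised when no candidate family has a finite likelihood on the data."""


@dataclass(frozen=True)
class DistFamily:
    """One member of the candidate set, identified by name."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in FAMILY_NAMES:
            raise ValueError(
                f"unknown family {self.name!r}; choose one of {FAMILY_NAMES}"
            )

    @property
    def baseline(self) -> str:
        """Name of the continuous component."""
        n = self.name
        if n.startswith("zi_"):
            return n[3:]
        if n.endswith("_hurdle"):
            return n[: -len("_hurdle")]
        return n

    @property
    def has_zero_mass(self) -> bool:
        """True for zero-inflated and hurdle variants (extra atom at 0)."""
        return self.name.startswith("zi_") or self.name.endswith("_hurdle")

    @property
    def k(self) -> int:
        """Number of free parameters (baseline params, plus phi if any)."""
        return _BASELINES[self.baseline][1] + int(self.has_zero_mass)

    @property
    def supports_negative(self) -> bool:
        """Whether the continuous component's support is all of the reals."""
        return self.baseline == "normal"

    @property
    def index(self) -> int:
        return FAMILY_NAMES.index(self.name)


def _as_family(family) -> DistFamily:
    return family if isinstance(family, DistFamily) else DistFamily(str(family))


@dataclass(frozen=True)
class SparseDistFit:
    """A fitted family: MLEs, likelihood, AIC and (optionally) KS results.

    ``loglik = -inf`` flags an infeasible family for the data (for example a
    plain log-normal when exact zeros are present, or a zero-mass family with
    fewer than two nonzero observations to fit the baseline on).
    """

    family: DistFamily
    phi: float | None
    theta: dict
    loglik: float
    k: int
    aic: float
    n: int
    n_zero: int
    ks_stat: float | None = None
    ks_pvalue: float | None = None

    @property
    def feasible(self) -> bool:
        return np.isfinite(self.loglik)


_LOG_2PI = float(np.log(2.0 * np.pi))


def _baseline_mle(baseline: str, x: np.ndarray) -> tuple[dict, float]:
    """Closed-form MLE of a continuous baseline; returns (theta, loglik).

    The maximized log-likelihoods are evaluated in closed form as well
    (e.g. for the normal, -n/2 (log(2 pi sd^2) + 1)); they match direct
    density summation but avoid per-call distribution objects, which
    matters inside the bootstrap.
    """
    n = x.size
    if baseline == "normal":
        mean = float(x.mean())
        sd = float(np.sqrt(np.mean((x - mean) ** 2)))
        if sd <= 0.0:
            return {"mean": mean, "sd": sd}, -np.inf
        ll = -0.5 * n * (_LOG_2PI + 2.0 * np.log(sd) + 1.0)
        return {"mean": mean, "sd": sd}, float(ll)
    if baseline == "half_normal":
        if np.any(x < 0):
            return {}, -np.inf
        sigma = float(np.sqrt(np.mean(x**2)))
        if sigma <= 0.0:
            return {"sigma": sigma}, -np.inf
        ll = n * (0.5 * np.log(2.0 / np.pi) - np.log(sigma) - 0.5)
        return {"sigma": sigma}, float(ll)
    if baseline == "log_normal":
        if np.any(x <= 0):
            return {}, -np.inf
        lx = np.log(x)
        mu = float(lx.mean())
        sd = float(np.sqrt(np.mean((lx - mu) ** 2)))
        if sd <= 0.0:
            return {"logmean": mu, "logsd": sd}, -np.inf
        ll = -0.5 * n * (_LOG_2PI + 2.0 * np.log(sd) + 1.0) - float(lx.sum())
        return {"logmean": mu, "logsd": sd}, float(ll)
    if baseline == "exponential":
        if np.any(x < 0):
            return {}, -np.inf
        m = float(x.mean())
        if m <= 0.0:
            return {"rate": np.inf}, -np.inf
        rate = 1.0 / m
        ll = n * (np.log(rate) - 1.0)
        return {"rate": rate}, float(ll)
    raise ValueError(f"unknown baseline {baseline!r}")


def fit_family(values, family) -> SparseDistFit:
    """Fit one candidate family to ``values`` by closed-form MLE.

    Zero-mass variants estimate ``phi`` as the exact-zero fraction and fit
    the baseline on the nonzero values; the log-likelihood is the mixture
    of the atom at zero and the continuous density, with 0*log(0) = 0 at
    the ``phi`` boundaries.
    """
    fam = _as_family(family)
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 values to fit a family")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    n_zero = int(np.count_nonzero(x == 0.0))

    def infeasible(phi, theta):
        return SparseDistFit(fam, phi, theta, -np.inf, fam.k, np.inf, n, n_zero)

    if fam.has_zero_mass:
        phi = n_zero / n
        nz = x[x != 0.0]
        if nz.size < 2:
            return infeasible(phi, {})
        theta, ll_base = _baseline_mle(fam.baseline, nz)
        if not np.isfinite(ll_base):
            return infeasible(phi, theta)
        ll = ll_base
        if n_zero > 0:
            ll += n_zero * np.log(phi)
        if n_zero < n:
            ll += (n - n_zero) * np.log1p(-phi)
        aic = -2.0 * ll + 2.0 * fam.k
        return SparseDistFit(fam, float(phi), theta, float(ll), fam.k, aic, n, n_zero)

    theta, ll = _baseline_mle(fam.baseline, x)
    if not np.isfinite(ll):
        return infeasible(None, theta)
    aic = -2.0 * ll + 2.0 * fam.k
    return SparseDistFit(fam, None, theta, float(ll), fam.k, aic, n, n_zero)


def _baseline_cdf(baseline: str, theta: dict, t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if baseline == "normal":
        return special.ndtr((t - theta["mean"]) / theta["sd"])
    if baseline == "half_normal":
        return np.where(t < 0.0, 0.0, 2.0 * special.ndtr(t / theta["sigma"]) - 1.0)
    if baseline == "log_normal":
        out = np.zeros_like(t)
        pos = t > 0.0
        out[pos] = special.ndtr((np.log(t[pos]) - theta["logmean"]) / theta["logsd"])
        return out
    if baseline == "exponential":
        return np.where(t < 0.0, 0.0, -np.expm1(-theta["rate"] * np.maximum(t, 0.0)))
    raise ValueError(f"unknown baseline {baseline!r}")


def _mixed_cdf(fit: SparseDistFit, t: np.ndarray) -> np.ndarray:
    """CDF of the fitted model, with a jump of size phi at 0 if present."""
    g = _baseline_cdf(fit.family.baseline, fit.theta, t)
    if fit.phi is None:
        return g
    return np.where(np.asarray(t) >= 0.0, fit.phi + (1.0 - fit.phi) * g,
                    (1.0 - fit.phi) * g)


def ks_statistic(values, fit: SparseDistFit) -> float:
    """One-sample KS statistic of ``values`` against the fitted mixed CDF.

    Uses the right-continuous empirical CDF; the sup-distance accounts for
    the atom at zero by evaluating the fitted CDF from the left at 0.
    """
    if not fit.feasible:
        raise ValueError("cannot compute a KS statistic for an infeasible fit")
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    u, counts = np.unique(x, return_counts=True)
    cum = np.cumsum(counts) / n  # F_n at each unique point
    cum_prev = cum - counts / n  # F_n just below each unique point
    f = _mixed_cdf(fit, u)
    f_minus = f.copy()
    if fit.phi is not None:
        f_minus = np.where(u == 0.0, f - fit.phi, f_minus)
    d = max(np.max(cum - f), np.max(f_minus - cum_prev), 0.0)
    return float(min(d, 1.0))


def _baseline_rvs(baseline: str, theta: dict, size: int,
                  rng: np.random.Generator) -> np.ndarray:
    if baseline == "normal":
        return rng.normal(theta["mean"], theta["sd"], size)
    if baseline == "half_normal":
        return np.abs(rng.normal(0.0, theta["sigma"], size))
    if baseline == "log_normal":
        return rng.lognormal(theta["logmean"], theta["logsd"], size)
    if baseline == "exponential":
        return rng.exponential(1.0 / theta["rate"], size)
    raise ValueError(f"unknown baseline {baseline!r}")


def sample_fit(fit: SparseDistFit, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` values from the fitted model (atom at 0, then baseline)."""
    out = _baseline_rvs(fit.family.baseline, fit.theta, size, rng)
    if fit.phi is not None and fit.phi > 0:
        out[rng.random(size) < fit.phi] = 0.0
    return out


def rvs(family, params: dict, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw from a family given explicit parameters (``phi`` + baseline).

    Convenience entry point for the synthetic-data generator; ``params``
    holds the baseline parameter names of :data:`_BASELINES` plus ``phi``
    for zero-mass families.
    """
    fam = _as_family(family)
    theta = {k: v for k, v in params.items() if k != "phi"}
    names, _ = _BASELINES[fam.baseline]
    missing = [p for p in names if p not in theta]
    if missing:
        raise ValueError(f"{fam.name}: missing parameter(s) {missing}")
    phi = params.get("phi")
    if fam.has_zero_mass:
        if phi is None or not 0.0 <= phi <= 1.0:
            raise ValueError(f"{fam.name}: needs phi in [0, 1]")
    elif phi is not None:
        raise ValueError(f"{fam.name}: phi given for a family without zero mass")
    fit = SparseDistFit(fam, phi, theta, 0.0, fam.k, 0.0, 0, 0)
    return sample_fit(fit, size, rng)


def ks_pvalue(values, fit: SparseDistFit, n_boot: int = 200, seed=None) -> tuple[float, float]:
    """Parametric-bootstrap KS p-value for a fitted family.

    Resamples ``n_boot`` datasets from the fitted model, refits the same
    family to each, recomputes the KS statistic, and returns
    ``(ks_stat, p)`` with ``p`` the proportion of bootstrap statistics at
    least as large as the observed one.  A bootstrap replicate on which the
    family is infeasible (e.g. too few nonzero draws) counts with statistic
    1, which can only make the p-value more conservative.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be a positive integer")
    x = np.asarray(values, dtype=float).ravel()
    obs = ks_statistic(x, fit)
    rng = np.random.default_rng(seed)
    n = x.size
    exceed = 0
    for _ in range(n_boot):
        xb = sample_fit(fit, n, rng)
        refit = fit_family(xb, fit.family)
        stat = ks_statistic(xb, refit) if refit.feasible else 1.0
        if stat >= obs:
            exceed += 1
    return obs, exceed / n_boot


def select_family(values, candidates=None, n_boot: int = 200, seed=None) -> SparseDistFit:
    """Fit every feasible candidate and return the best by KS p-value.

    Ties on the p-value are broken by larger log-likelihood, then by the
    canonical order of :data:`FAMILY_NAMES`.  Each family consumes its own
    deterministic sub-seed (spawned from ``seed`` by canonical index), so
    the result does not depend on which other candidates are feasible.
    """
    if candidates is None:
        candidates = FAMILY_NAMES
    candidates = [_as_family(c) for c in candidates]
    if not candidates:
        raise ValueError("candidates must be non-empty")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    # stateless spawn: repeated calls with the same seed follow the same path
    children = [
        np.random.SeedSequence(entropy=ss.entropy, spawn_key=ss.spawn_key + (i,))
        for i in range(len(FAMILY_NAMES))
    ]
    best = None
    best_key = None
    for fam in sorted(candidates, key=lambda f: f.index):
        fit = fit_family(values, fam)
        if not fit.feasible:
            continue
        stat, p = ks_pvalue(values, fit, n_boot=n_boot, seed=children[fam.index])
        fit = replace(fit, ks_stat=stat, ks_pvalue=p)
        key = (p, fit.loglik)
        if best is None or key > best_key:
            best, best_key = fit, key
    if best is None:
        raise NoFeasibleFamilyError(
            "no candidate family has a finite likelihood on these values"
        )
    return best
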