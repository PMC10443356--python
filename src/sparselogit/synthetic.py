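"""Synthetic datasets with the structure the analysis pipeline assumes.

Two generative directions are provided, because the two halves of the
procedure make different conditional assumptions:

* ``labels_first`` — draw class labels from fixed class probabilities, then
  draw each gene conditionally on the label from a (possibly group-specific)
  zero-inflated continuous distribution.  This is the regime the screening
  stage tests: informative genes have group-dependent distributions, null
  genes are i.i.d. across groups.

* ``logit_first`` — draw gene values first, then draw labels from a
  multinomial logistic model with known link, structure, parameters and
  working order.  This is the regime the regression stages (fitting, order
  selection, cross-validation, backward elimination) test, with full ground
  truth available for recovery checks.

The generator emulates the *shape* of sparse expression data — non-negative
continuous values with exact-zero fractions in a chosen band — not its
read-level structure: no library-size, batch, correlation or overdispersion
modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import rvs
from .mlogit import ModelSpec, Params, probs_from_eta

__all__ = ["GeneBlock", "GenSpec", "gen_dataset", "preset", "PRESETS"]


@dataclass(frozen=True)
class GeneBlock:
    """A block of genes sharing a distributional recipe.

    ``dists`` holds ``(family_name, params)`` pairs: one pair for a null
    block (same distribution in every group) or one per response group for
    an informative block.
    """

    count: int
    dists: tuple

    @property
    def informative(self) -> bool:
        return len(self.dists) > 1


@dataclass(frozen=True)
class GenSpec:
    """Full recipe for one synthetic dataset; the seed pins it down exactly."""

    n: int
    class_probs: tuple
    blocks: tuple
    response_mode: str = "labels_first"
    logit: dict | None = None  # link, structure, beta, zeta, order (logit_first)
    seed: int = 0
    category_names: tuple | None = None

    @property
    def J(self) -> int:
        return len(self.class_probs)

    @property
    def d(self) -> int:
        return sum(b.count for b in self.blocks)


def _validate(spec: GenSpec) -> None:
    if spec.n < 2:
        raise ValueError("n must be at least 2")
    probs = np.asarray(spec.class_probs, dtype=float)
    if np.any(probs <= 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("class_probs must be positive and sum to 1")
    if spec.response_mode not in ("labels_first", "logit_first"):
        raise ValueError("response_mode must be 'labels_first' or 'logit_first'")
    for b in spec.blocks:
        if b.count < 1:
            raise ValueError("block count must be positive")
        if len(b.dists) not in (1, spec.J):
            raise ValueError("a block needs 1 dist (null) or J dists (informative)")
        for fam, params in b.dists:
            # dry-run validation of the family/params pair before generating
            rvs(fam, params, 1, np.random.default_rng(0))
    if spec.response_mode == "logit_first":
        if spec.logit is None:
            raise ValueError("logit_first mode needs the `logit` field")
        if any(b.informative for b in spec.blocks):
            raise ValueError(
                "logit_first blocks must be single-distribution; group structure "
                "comes from the logistic model"
            )


def gen_dataset(spec: GenSpec):
    """Generate ``(X, y, truth)`` from a :class:`GenSpec`.

    ``X`` is the n-by-d expression matrix, ``y`` the 0-based label vector
    and ``truth`` a record of informative columns and true parameters for
    recovery tests.  Fully determined by ``spec.seed``.
    """
    _validate(spec)
    rng = np.random.default_rng(spec.seed)
    n, J, d = spec.n, spec.J, spec.d
    probs = np.asarray(spec.class_probs, dtype=float)
    X = np.empty((n, d))
    informative_cols = []

    if spec.response_mode == "labels_first":
        y = rng.choice(J, size=n, p=probs)
        col = 0
        for block in spec.blocks:
            for _ in range(block.count):
                if block.informative:
                    informative_cols.append(col)
                    for g in range(J):
                        idx = np.nonzero(y == g)[0]
                        fam, params = block.dists[g]
                        X[idx, col] = rvs(fam, params, idx.size, rng)
                else:
                    fam, params = block.dists[0]
                    X[:, col] = rvs(fam, params, n, rng)
                col += 1
        truth = {
            "mode": "labels_first",
            "informative_columns": informative_cols,
            "class_probs": tuple(probs),
            "blocks": spec.blocks,
        }
        return X, y, truth

    # logit_first: covariates, then labels through the logistic model
    col = 0
    for block in spec.blocks:
        fam, params = block.dists[0]
        for _ in range(block.count):
            X[:, col] = rvs(fam, params, n, rng)
            col += 1
    lg = spec.logit
    mspec = ModelSpec(lg["link"], lg["structure"])
    params = Params([np.asarray(b, dtype=float) for b in lg["beta"]],
                    np.asarray(lg.get("zeta", ()), dtype=float))
    order = np.asarray(lg.get("order", np.arange(J)), dtype=int)
    if mspec.structure == "po":
        eta = np.stack([b[0] + X @ params.zeta for b in params.beta], axis=1)
    else:
        eta = np.stack([b[0] + X @ b[1:] for b in params.beta], axis=1)
    pi_work = probs_from_eta(mspec.link, eta)
    if np.any(pi_work < 0):
        raise ValueError("logit parameters produce invalid cumulative probabilities")
    u = rng.random(n)
    pos = (u[:, None] > np.cumsum(pi_work, axis=1)).sum(axis=1)
    y = order[pos]
    truth = {
        "mode": "logit_first",
        "informative_columns": list(range(d)),
        "spec": mspec,
        "params": params,
        "order": tuple(order.tolist()),
        "class_probs": tuple(probs),
    }
    return X, y, truth


def _null_block(count: int) -> GeneBlock:
    return GeneBlock(
        count, (("zi_log_normal", {"phi": 0.2, "logmean": 1.0, "logsd": 0.6}),)
    )


def _presets() -> dict:
    # Informative genes: group-dependent zero-inflation (phi inside the
    # [0.05, 0.50] sparsity band) and group-dependent log-means, so both the
    # atom and the continuous part carry signal.
    inf_dists = tuple(
        ("zi_log_normal", {"phi": phi, "logmean": mu, "logsd": 0.5})
        for phi, mu in ((0.10, 0.5), (0.25, 1.2), (0.45, 1.9))
    )
    presets = {
        "null": GenSpec(
            n=400,
            class_probs=(0.4, 0.35, 0.25),
            blocks=(_null_block(20),),
            seed=11,
        ),
        "informative_zi": GenSpec(
            n=500,
            class_probs=(0.4, 0.3, 0.3),
            blocks=(GeneBlock(5, inf_dists), _null_block(20)),
            seed=12,
        ),
        "adjacent_po_truth": GenSpec(
            n=2000,
            class_probs=(1 / 3, 1 / 3, 1 / 3),  # nominal; labels come from the logit
            blocks=(
                GeneBlock(2, (("log_normal", {"logmean": 0.0, "logsd": 0.5}),)),
            ),
            response_mode="logit_first",
            logit={
                "link": "adjacent_categories",
                "structure": "po",
                "beta": [(0.6,), (-0.3,)],
                "zeta": (1.0, -0.8),
                "order": (1, 2, 0),
            },
            seed=13,
        ),
        "binary_equivalence": GenSpec(
            n=100,
            class_probs=(0.5, 0.5),
            blocks=(
                GeneBlock(2, (("log_normal", {"logmean": 0.0, "logsd": 0.6}),)),
            ),
            response_mode="logit_first",
            logit={
                "link": "baseline_category",
                "structure": "npo",
                "beta": [(0.4, 0.9, -1.1)],
            },
            seed=14,
        ),
    }
    return presets


PRESETS = tuple(sorted(_presets()))


def preset(name: str) -> GenSpec:
    """A documented, fixed :class:`GenSpec` for tests and examples."""
    presets = _presets()
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; available: {', '.join(PRESETS)}")
    return presets[name]
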