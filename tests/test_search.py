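"""Tests of order selection, CV cross-entropy, backward elimination, pipeline."""

import itertools
from dataclasses import replace

import numpy as np
import pytest

import sparselogit as sl
from sparselogit.mlogit import CategoricalDataset, ModelSpec, fit
from sparselogit.search import (
    backward_select,
    choose_num_covariates,
    cross_entropy,
    cv_cross_entropy,
    fold_assignment,
    select_baseline,
    select_order,
)
from sparselogit.synthetic import gen_dataset, preset


# ------------------------------------------------------------- select_order

def test_select_order_enumerates_all_permutations(j4_dataset):
    res = select_order(ModelSpec("adjacent_categories", "po"), j4_dataset)
    assert len(res.table) == 24
    assert res.best_aic == pytest.approx(min(a for _, a in res.table))


def test_select_order_binary_orders_tie():
    X, y, _ = gen_dataset(preset("binary_equivalence"))
    ds = CategoricalDataset.from_raw(X, y)
    res = select_order(ModelSpec("adjacent_categories", "po"), ds)
    assert len(res.table) == 2
    aics = [a for _, a in res.table]
    assert aics[0] == pytest.approx(aics[1], abs=1e-6)
    assert res.best_order == (0, 1)  # canonical on ties


def test_adjacent_po_reversal_symmetry(j4_dataset):
    res = select_order(ModelSpec("adjacent_categories", "po"), j4_dataset,
                       fit_options={"max_iter": 100})
    aic_of = dict(res.table)
    for perm in itertools.permutations(range(4)):
        assert aic_of[perm] == pytest.approx(aic_of[perm[::-1]], abs=1e-6)


def test_select_order_recovers_generating_order():
    X, y, truth = gen_dataset(preset("adjacent_po_truth"))
    ds = CategoricalDataset.from_raw(X, y)
    res = select_order(ModelSpec("adjacent_categories", "po"), ds,
                       fit_options={"max_iter": 100})
    sigma = truth["order"]
    assert res.best_order in (sigma, sigma[::-1])


def test_select_order_guards():
    X = np.arange(10, dtype=float)[:, None]
    y = np.tile(np.arange(2), 5)
    ds = CategoricalDataset.from_raw(X, y)
    with pytest.raises(ValueError):
        select_order(ModelSpec("adjacent_categories", "npo"), ds)
    with pytest.raises(ValueError, match="candidate order"):
        select_order(ModelSpec("adjacent_categories", "po"), ds, exhaustive_limit=1)


# ---------------------------------------------------------- select_baseline

def test_select_baseline_fits_one_model_per_category(j3_dataset):
    X, y = j3_dataset
    ds = CategoricalDataset.from_raw(X, y)
    best, table = select_baseline(ds, ModelSpec("baseline_category", "po"))
    assert len(table) == 3
    assert 0 <= best < 3


def test_select_baseline_rejects_npo(j3_dataset):
    X, y = j3_dataset
    ds = CategoricalDataset.from_raw(X, y)
    with pytest.raises(ValueError):
        select_baseline(ds, ModelSpec("baseline_category", "npo"))


def test_select_baseline_recovers_distinct_reference():
    """When one category is distinctly 'other', po prefers it as baseline."""
    rng = np.random.default_rng(60)
    wins = 0
    reps = 20
    for s in range(reps):
        rng = np.random.default_rng(1000 + s)
        n = 400
        X = rng.lognormal(0, 0.6, (n, 2))
        # categories 0 and 1 respond to x with equal slopes; category 2 is flat
        eta = np.stack([0.3 + X @ [1.0, -0.8], -0.2 + X @ [1.0, -0.8]], axis=1)
        pi = sl.probs_from_eta("baseline_category", eta)
        u = rng.random(n)
        y = (u[:, None] > np.cumsum(pi, axis=1)).sum(axis=1)
        ds = CategoricalDataset.from_raw(X, y)
        best, _ = select_baseline(ds, ModelSpec("baseline_category", "po"))
        wins += best == 2
    assert wins > reps / 2


# ------------------------------------------------------------ cross entropy

def test_cross_entropy_closed_forms():
    y = np.array([0, 1, 2, 1])
    oracle = np.eye(3)[y]
    assert cross_entropy(oracle, y) == 0.0
    uniform = np.full((4, 3), 1 / 3)
    assert cross_entropy(uniform, y) == pytest.approx(np.log(3))
    assert cross_entropy(np.eye(3)[(y + 1) % 3], y) == np.inf


def test_fold_assignment_sizes_and_determinism():
    folds = fold_assignment(33, 5, seed=3)
    sizes = np.bincount(folds)
    assert sizes.max() - sizes.min() <= 1 and sizes.sum() == 33
    assert np.array_equal(folds, fold_assignment(33, 5, seed=3))
    with pytest.raises(ValueError):
        fold_assignment(3, 5)


def test_stratified_fold_option_balances_classes():
    y = np.repeat([0, 1, 2], [50, 25, 25])
    folds = fold_assignment(100, 5, seed=1, y=y)
    assert np.bincount(folds).tolist() == [20] * 5
    for cls in range(3):
        per_fold = np.bincount(folds[y == cls], minlength=5)
        assert per_fold.max() - per_fold.min() <= 1


def test_cv_report_matches_hand_recomputation(j3_dataset):
    X, y = j3_dataset
    X, y = X[:30], y[:30]
    spec = ModelSpec("baseline_category", "npo")
    rep = cv_cross_entropy(spec, X, y, K=5, seed=21)
    hand = -np.mean(np.log(rep.probs[np.arange(30), y]))
    assert rep.ce == pytest.approx(hand)
    assert rep.error_rate == rep.error_count / 30
    # CE recomputed from the stored fold map and predictions is identical
    assert cross_entropy(rep.probs, y) == rep.ce


def test_cv_infeasible_fold_poisons_configuration():
    # 6 observations, K=5 -> training folds have < d+1 distinct rows
    X = np.arange(6, dtype=float)[:, None] @ np.ones((1, 8))
    y = np.tile([0, 1, 2], 2)
    rep = cv_cross_entropy(ModelSpec("baseline_category", "npo"), X, y, K=5, seed=0)
    assert rep.ce == np.inf
    assert rep.failed_folds


def test_cv_order_invariance_for_npo(j4_dataset):
    X, y = j4_dataset.to_raw()
    spec = ModelSpec("adjacent_categories", "npo")
    base = cv_cross_entropy(spec, X, y, K=5, seed=33, fit_options={"max_iter": 100})
    for perm in [(3, 1, 0, 2), (2, 3, 1, 0)]:
        other = cv_cross_entropy(spec, X, y, K=5, seed=33, order=np.array(perm),
                                 fit_options={"max_iter": 100})
        assert other.ce == pytest.approx(base.ce, abs=1e-6)
        assert other.error_count == base.error_count


# ------------------------------------------------- choose_num_covariates

def test_choose_num_single_configuration(j3_dataset):
    X, y = j3_dataset
    spec = ModelSpec("baseline_category", "npo")
    best_spec, best_t, table = choose_num_covariates(
        [0, 1], X, y, [spec], t_grid=[2], K=5, seed=2
    )
    assert best_spec is spec and best_t == 2
    assert len(table) == 1


def test_choose_num_recovers_informative_count():
    """With 10 informative columns ranked first, t=10 usually wins."""
    spec = ModelSpec("baseline_category", "npo")
    # fixed moderate weights: every one of the 10 columns carries real signal
    w1 = np.array([0.9, -0.8, 0.7, -0.9, 0.8, -0.7, 0.9, -0.8, 0.7, -0.9])
    w2 = -w1[::-1]
    wins = 0
    reps = 10
    for s in range(reps):
        rng = np.random.default_rng(4000 + s)
        n = 300
        signal = rng.lognormal(0, 0.5, (n, 10))
        noise = rng.lognormal(0, 0.5, (n, 30))
        eta = np.stack([0.2 + signal @ w1, -0.1 + signal @ w2], axis=1)
        pi = sl.probs_from_eta("baseline_category", eta)
        u = rng.random(n)
        y = (u[:, None] > np.cumsum(pi, axis=1)).sum(axis=1)
        X = np.hstack([signal, noise])
        _, best_t, _ = choose_num_covariates(
            list(range(40)), X, y, [spec], t_grid=[5, 10, 40], K=5, seed=s
        )
        wins += best_t == 10
    assert wins > reps / 2


# ------------------------------------------------------- backward_select

def test_backward_removes_pure_noise_covariate():
    rng = np.random.default_rng(70)
    n = 200
    X = rng.normal(0, 1, (n, 1))
    y = rng.integers(0, 2, n)  # labels independent of X
    trace = backward_select(ModelSpec("baseline_category", "npo"), X, y, [0])
    assert trace.final_ids == []
    assert len(trace.steps) == 1
    assert trace.final_aic < trace.start_aic


def test_backward_stops_immediately_when_nothing_helps(j3_dataset):
    X, y = j3_dataset
    trace = backward_select(ModelSpec("baseline_category", "npo"), X, y, [0, 1])
    assert trace.steps == []
    assert trace.final_ids == [0, 1]
    assert trace.final_aic == trace.start_aic


def _backward_fixture():
    rng = np.random.default_rng(80)
    n = 500
    X = rng.lognormal(0, 0.5, (n, 8))
    # columns 0-2 informative, 3-7 noise
    eta = np.stack(
        [0.3 + X[:, :3] @ [1.2, -1.0, 0.8], -0.2 + X[:, :3] @ [-0.6, 0.9, -1.1]],
        axis=1,
    )
    pi = sl.probs_from_eta("baseline_category", eta)
    u = rng.random(n)
    y = (u[:, None] > np.cumsum(pi, axis=1)).sum(axis=1)
    return X, y


def test_backward_trace_decreases_and_matches_best_subset_oracle():
    X, y = _backward_fixture()
    spec = ModelSpec("baseline_category", "npo")
    trace = backward_select(spec, X, y, list(range(8)))
    # strictly decreasing AIC along the trace
    aics = [trace.start_aic] + [a for _, a in trace.steps]
    assert all(b < a for a, b in zip(aics, aics[1:]))
    # replaying the trace reproduces each recorded AIC
    current = list(range(8))
    for removed, recorded in trace.steps:
        current = [c for c in current if c != removed]
        ds = CategoricalDataset.from_raw(X[:, current], y, J=3)
        assert fit(spec, ds, max_iter=100).aic == pytest.approx(recorded, abs=1e-6)
    # exhaustive best-subset oracle over all 2^8 - 1 nonempty subsets
    best_aic = np.inf
    for r in range(1, 9):
        for subset in itertools.combinations(range(8), r):
            ds = CategoricalDataset.from_raw(X[:, list(subset)], y, J=3)
            best_aic = min(best_aic, fit(spec, ds, max_iter=100).aic)
    assert trace.final_aic >= best_aic - 1e-6
    assert trace.final_aic == pytest.approx(best_aic, abs=1e-6)
    assert {0, 1, 2} <= set(trace.final_ids)


def test_backward_warm_starts_match_cold_starts():
    X, y = _backward_fixture()
    X, y = X[:150], y[:150]
    spec = ModelSpec("baseline_category", "npo")
    warm = backward_select(spec, X, y, list(range(5)), warm_start=True,
                           fit_options={"max_iter": 100})
    cold = backward_select(spec, X, y, list(range(5)), warm_start=False,
                           fit_options={"max_iter": 100})
    assert warm.final_ids == cold.final_ids
    assert warm.final_aic == pytest.approx(cold.final_aic, abs=1e-5)


def test_backward_retains_informative_covariates_across_replicates():
    spec = ModelSpec("baseline_category", "npo")
    kept = 0
    reps = 10
    for s in range(reps):
        rng = np.random.default_rng(6000 + s)
        n = 300
        X = rng.lognormal(0, 0.5, (n, 8))
        eta = np.stack(
            [0.3 + X[:, :3] @ [1.2, -1.0, 0.8],
             -0.2 + X[:, :3] @ [-0.6, 0.9, -1.1]],
            axis=1,
        )
        pi = sl.probs_from_eta("baseline_category", eta)
        u = rng.random(n)
        y = (u[:, None] > np.cumsum(pi, axis=1)).sum(axis=1)
        trace = backward_select(spec, X, y, list(range(8)))
        kept += {0, 1, 2} <= set(trace.final_ids)
    assert kept >= int(0.9 * reps)


# ------------------------------------------------------------- pipeline

def test_pipeline_end_to_end_improves_on_full_model():
    from sparselogit.pipeline import PipelineConfig, run_pipeline

    X, y, _ = gen_dataset(preset("adjacent_po_truth"))
    X, y = X[:600], y[:600]
    cfg = PipelineConfig(seed=4, screening=False, t_grid=(1, 2),
                         specs=(ModelSpec("adjacent_categories", "po"),
                                ModelSpec("baseline_category", "npo")),
                         n_finalists=1)
    rep = run_pipeline(X, y, cfg)
    assert rep.failed_stage is None
    final = rep.finalists[0]
    full_cv = cv_cross_entropy(final["spec"], X, y, K=5, seed=4)
    assert final["final_cv"].error_rate <= full_cv.error_rate + 1e-12


def test_pipeline_skips_ranking_when_screening_disabled(j3_dataset):
    from sparselogit.pipeline import PipelineConfig, run_pipeline

    X, y = j3_dataset
    cfg = PipelineConfig(seed=1, screening=False, t_grid=(2,),
                         specs=(ModelSpec("baseline_category", "npo"),),
                         n_finalists=1)
    rep = run_pipeline(X, y, cfg)
    assert rep.failed_stage is None
    assert rep.ranking == []
    assert rep.best_t == 2


def test_pipeline_rerun_is_byte_identical(tmp_path):
    from sparselogit.pipeline import PipelineConfig, run_pipeline

    X, y, _ = gen_dataset(replace(preset("informative_zi"), n=120))
    cfg = PipelineConfig(seed=3, n_boot=10, t_grid=(2, 4), n_finalists=1,
                         specs=(ModelSpec("baseline_category", "npo"),
                                ModelSpec("adjacent_categories", "po")))
    out1, out2 = tmp_path / "a", tmp_path / "b"
    run_pipeline(X, y, cfg, out_dir=out1)
    run_pipeline(X, y, cfg, out_dir=out2)
    for f1 in sorted(out1.iterdir()):
        if f1.name == "run.log":  # wall-clock stage timings, not a result
            continue
        assert (out2 / f1.name).read_bytes() == f1.read_bytes()
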