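"""End-to-end driver: screen, size, order, and prune the candidate models.

Stage order mirrors the analysis workflow: sparsity filter, AIC-difference
screening, cross-validated choice of covariate count over the eight
candidate models, working-order selection for the surviving po models,
backward AIC elimination per finalist, and a final cross-validated report
per finalist.  Every stage is a pure function of (data, config, master
seed); all artifacts are written as TSV/plain text together with a manifest
recording the seed, so a rerun with the same inputs is byte-identical.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .io import write_coefficients, write_fit_report, write_manifest
from .mlogit import CategoricalDataset, ModelSpec, fit
from .screening import rank_covariates, sparsity_filter, write_ranking
from .search import (
    DEFAULT_T_GRID,
    backward_select,
    choose_num_covariates,
    cv_cross_entropy,
    select_order,
)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "ALL_SPECS"]

#: The eight candidate models: four links, each po and npo.
ALL_SPECS = tuple(
    ModelSpec(link, structure)
    for link in ("baseline_category", "cumulative",
                 "adjacent_categories", "continuation_ratio")
    for structure in ("po", "npo")
)


@dataclass
class PipelineConfig:
    """Knobs of the full run; defaults follow the procedure's own choices."""

    seed: int = 0
    K: int = 5
    t_grid: tuple = DEFAULT_T_GRID
    specs: tuple = ALL_SPECS
    filter_lo: float = 0.05
    filter_hi: float = 0.50
    n_boot: int = 200
    screening: bool = True
    n_finalists: int = 3
    max_iter: int = 30
    order_exhaustive_limit: int = 8

    def as_dict(self) -> dict:
        d = asdict(self)
        d["specs"] = ",".join(f"{s.link}:{s.structure}" for s in self.specs)
        d["t_grid"] = ",".join(str(t) for t in self.t_grid)
        return d


@dataclass
class PipelineReport:
    """Everything the run computed, stage by stage."""

    config: PipelineConfig
    kept_columns: np.ndarray
    ranking: list
    cv_table: list
    best_spec: ModelSpec
    best_t: int
    finalists: list  # per finalist: dict with spec, order, trace, final CV
    stage_seconds: dict
    failed_stage: str | None = None
    failure: str | None = None


def _spec_label(spec: ModelSpec) -> str:
    return f"{spec.link}:{spec.structure}"


def run_pipeline(X, y, config: PipelineConfig | None = None, out_dir=None,
                 covariate_ids=None) -> PipelineReport:
    """Run every stage on an (expression matrix, label vector) pair.

    ``X`` is n samples by d covariates, ``y`` a 0-based label vector.  When
    ``out_dir`` is given, each stage writes its table there and a manifest
    records the seed and configuration.  Stage failures are reported with
    the stage name; downstream stages are skipped.
    """
    cfg = config or PipelineConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, d = X.shape
    J = int(y.max()) + 1
    if covariate_ids is None:
        covariate_ids = list(range(d))
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    timings: dict = {}
    fit_options = {"max_iter": cfg.max_iter}

    report = PipelineReport(cfg, np.arange(d), [], [], None, 0, [], timings)
    stage = "filter"
    try:
        t0 = time.perf_counter()
        if cfg.screening:
            kept = sparsity_filter(X, cfg.filter_lo, cfg.filter_hi)
            if kept.size == 0:
                raise ValueError("sparsity filter removed every covariate")
        else:
            kept = np.arange(d)
        report.kept_columns = kept
        timings[stage] = time.perf_counter() - t0

        stage = "rank"
        t0 = time.perf_counter()
        if cfg.screening:
            records = rank_covariates(
                X[:, kept], y, n_boot=cfg.n_boot, seed=cfg.seed,
                covariate_ids=[covariate_ids[c] for c in kept],
            )
            ranked_cols = [kept[r.column] for r in records]
            report.ranking = records
            if out is not None:
                write_ranking(records, out / "ranking.tsv")
        else:
            # screening disabled: keep the natural column order
            ranked_cols = list(kept)
        timings[stage] = time.perf_counter() - t0

        stage = "choose_num_covariates"
        t0 = time.perf_counter()
        t_grid = [t for t in cfg.t_grid if t <= len(ranked_cols)] or [len(ranked_cols)]
        best_spec, best_t, cv_table = choose_num_covariates(
            ranked_cols, X, y, cfg.specs, t_grid=t_grid, K=cfg.K,
            seed=cfg.seed, J=J, fit_options=fit_options,
        )
        report.cv_table = cv_table
        report.best_spec, report.best_t = best_spec, best_t
        if out is not None:
            with open(out / "cv_table.tsv", "w") as fh:
                fh.write("model\tt\tce\terror_count\terror_rate\n")
                for spec, t, ce, ec, er in cv_table:
                    fh.write(f"{_spec_label(spec)}\t{t}\t{ce:.6g}\t{ec}\t{er:.6g}\n")
        timings[stage] = time.perf_counter() - t0

        stage = "finalists"
        t0 = time.perf_counter()
        # rank specs by their best CE; keep the top n_finalists with their best t
        per_spec: dict = {}
        for spec, t, ce, ec, er in cv_table:
            key = _spec_label(spec)
            if key not in per_spec or (ce, t) < (per_spec[key][1], per_spec[key][2]):
                per_spec[key] = (spec, ce, t)
        order_of_spec = [_spec_label(s) for s in cfg.specs]
        chosen = sorted(
            per_spec.values(),
            key=lambda v: (v[1], v[2], order_of_spec.index(_spec_label(v[0]))),
        )[: cfg.n_finalists]

        finalists = []
        for spec, ce, t in chosen:
            entry = {"spec": spec, "t": t, "cv_ce_start": ce}
            cols = ranked_cols[:t]
            order = None
            if spec.structure == "po" and J <= cfg.order_exhaustive_limit:
                ds = CategoricalDataset.from_raw(X[:, cols], y, J=J)
                osr = select_order(spec, ds, cfg.order_exhaustive_limit,
                                   fit_options=fit_options)
                order = np.array(osr.best_order)
                entry["order_search"] = osr
                if out is not None:
                    fn = out / f"order_{_spec_label(spec).replace(':', '_')}.tsv"
                    with open(fn, "w") as fh:
                        fh.write("order\taic\n")
                        for perm, a in osr.table:
                            fh.write(f"{','.join(map(str, perm))}\t{a:.6f}\n")
            trace = backward_select(spec, X, y, cols, order=order, J=J,
                                    fit_options=fit_options)
            entry["trace"] = trace
            final_cols = trace.final_ids
            if final_cols:
                rep = cv_cross_entropy(spec, X[:, final_cols], y, K=cfg.K,
                                       seed=cfg.seed, order=order, J=J,
                                       fit_options=fit_options)
                entry["final_cv"] = rep
            else:
                entry["final_cv"] = None
            entry["final_columns"] = final_cols
            if final_cols:
                ds_final = CategoricalDataset.from_raw(X[:, final_cols], y, J=J,
                                                       order=order)
                final_fit = fit(spec, ds_final, **fit_options)
                entry["final_fit"] = final_fit
                if out is not None:
                    tag = _spec_label(spec).replace(":", "_")
                    write_coefficients(
                        final_fit, out / f"coefficients_{tag}.tsv",
                        covariate_names=[str(covariate_ids[c]) for c in final_cols],
                    )
                    write_fit_report(final_fit, out / f"fit_{tag}.txt")
            finalists.append(entry)
            if out is not None:
                fn = out / f"trace_{_spec_label(spec).replace(':', '_')}.tsv"
                with open(fn, "w") as fh:
                    fh.write("step\tremoved\taic\n")
                    fh.write(f"0\t-\t{trace.start_aic:.6f}\n")
                    for i, (rm, a) in enumerate(trace.steps, 1):
                        fh.write(f"{i}\t{rm}\t{a:.6f}\n")
        report.finalists = finalists
        timings[stage] = time.perf_counter() - t0
    except ValueError as exc:
        report.failed_stage = stage
        report.failure = str(exc)

    if out is not None:
        write_manifest(
            out / "manifest.txt",
            inputs={"n_samples": n, "n_covariates": d, "n_categories": J},
            config=cfg.as_dict(),
            seed=cfg.seed,
        )
        with open(out / "run.log", "w") as fh:
            for name, secs in timings.items():
                fh.write(f"stage {name}: {secs:.3f} s\n")
            if report.failed_stage is not None:
                fh.write(f"failed at stage {report.failed_stage}: {report.failure}\n")
    return report
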