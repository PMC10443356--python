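"""Readers and writers for expression matrices, labels and run artifacts.

Input format follows the common CSV/TSV layout of public expression
datasets: a header row, an id column, and a dense numeric matrix in either
samples-in-rows or genes-in-rows orientation.  Parsing is strict — duplicate
ids, ragged rows, missing or non-numeric cells are rejected with the row and
column named — because silently coerced expression values corrupt every
downstream stage.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionTable",
    "read_expression",
    "read_labels",
    "write_expression",
    "write_labels",
    "write_coefficients",
    "write_fit_report",
    "write_manifest",
]


@dataclass
class ExpressionTable:
    """Samples-by-genes matrix with ids; canonical orientation only."""

    samples: list
    genes: list
    values: np.ndarray  # (n_samples, n_genes), float

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.genes)


def _sniff_sep(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    has_tab = "\t" in first
    has_comma = "," in first
    if has_tab and not has_comma:
        return "\t"
    if has_comma and not has_tab:
        return ","
    raise ValueError(
        f"{path}: cannot auto-detect delimiter (expected exactly one of comma or tab "
        "in the header line)"
    )


def _check_numeric(df: pd.DataFrame, path) -> np.ndarray:
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = bad.idxmax()
            raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        missing = converted.isna()
        if missing.any():
            row = missing.idxmax()
            raise ValueError(f"{path}: missing cell at row {row!r}, column {col!r}")
        df[col] = converted
    return df.to_numpy(dtype=float)


def read_expression(path, orientation: str = "samples_in_rows",
                    allow_negative: bool = False) -> ExpressionTable:
    """Parse a delimited expression matrix into canonical orientation.

    ``orientation`` says what the *file* contains; genes_in_rows files are
    transposed on read.  Values must be finite, and non-negative unless
    ``allow_negative`` is set (normal-family covariates).
    """
    if orientation not in ("samples_in_rows", "genes_in_rows"):
        raise ValueError("orientation must be samples_in_rows or genes_in_rows")
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row ids {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate column ids {dup}")
    values = _check_numeric(df, path)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: non-finite values present")
    if orientation == "genes_in_rows":
        values = values.T
        samples = df.columns.tolist()
        genes = df.index.tolist()
    else:
        samples = df.index.tolist()
        genes = df.columns.tolist()
    if not allow_negative and np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: negative value for sample {samples[i]!r}, gene {genes[j]!r} "
            "(pass allow_negative for normal-family data)"
        )
    return ExpressionTable(samples, genes, values)


def read_labels(path, expression: ExpressionTable | None = None,
                category_order=None):
    """Parse a two-column (sample id, class) file.

    If an :class:`ExpressionTable` is given, labels are realigned to its
    sample order; missing or unknown sample ids are reported explicitly.
    Categories are indexed 0..J-1 in first-appearance order unless an
    explicit ``category_order`` list is supplied.

    Returns ``(labels, category_names)`` with ``labels`` a 0-based int
    vector.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] != 1:
        raise ValueError(f"{path}: expected exactly two columns (sample id, class)")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids {dup}")
    series = df.iloc[:, 0].astype(str)
    if expression is not None:
        want = pd.Index(expression.samples)
        missing = want.difference(series.index).tolist()
        extra = series.index.difference(want).tolist()
        if missing or extra:
            raise ValueError(
                f"{path}: sample mismatch with expression table; "
                f"missing={missing[:5]} unknown={extra[:5]}"
            )
        series = series.loc[want]
    classes = series.tolist()
    if category_order is None:
        names = list(dict.fromkeys(classes))  # first-appearance order
    else:
        names = list(category_order)
        unknown = sorted(set(classes) - set(names))
        if unknown:
            raise ValueError(f"{path}: classes {unknown} absent from category order")
    index = {c: i for i, c in enumerate(names)}
    labels = np.array([index[c] for c in classes], dtype=int)
    return labels, names


def write_expression(table: ExpressionTable, path, sep: str = "\t") -> None:
    table.to_frame().to_csv(path, sep=sep, float_format="%.17g")


def write_labels(labels, names, samples, path, sep: str = "\t") -> None:
    df = pd.DataFrame({"class": [names[i] for i in labels]}, index=samples)
    df.index.name = "sample"
    df.to_csv(path, sep=sep)


def write_coefficients(result, path, covariate_names=None, sep: str = "\t") -> None:
    """Fitted coefficients as a (category, predictor, estimate) table.

    Categories are reported under the fit's working order; po fits list the
    shared slopes once under category ``shared``.
    """
    J = result.J
    if covariate_names is None:
        covariate_names = [f"x{j + 1}" for j in range(result.d)]
    names = result.category_names or tuple(f"cat{j + 1}" for j in range(J))
    rows = []
    for j, beta in enumerate(result.params.beta):
        cat = names[result.perm[j]]
        rows.append((cat, "intercept", beta[0]))
        for c, est in enumerate(beta[1:]):
            rows.append((cat, covariate_names[c], est))
    for c, est in enumerate(result.params.zeta):
        rows.append(("shared", covariate_names[c], est))
    with open(path, "w") as fh:
        fh.write("category\tpredictor\testimate\n".replace("\t", sep))
        for cat, pred, est in rows:
            fh.write(f"{cat}{sep}{pred}{sep}{est:.10g}\n")


def write_fit_report(result, path) -> None:
    """Fit metadata (loglik, AIC, iterations, flags) as key: value lines."""
    lines = [
        f"link: {result.spec.link}",
        f"structure: {result.spec.structure}",
        f"loglik: {result.loglik:.10g}",
        f"aic: {result.aic:.10g}",
        f"n_params: {result.params.p}",
        f"n_iter: {result.n_iter}",
        f"converged: {result.converged}",
        f"grad_norm: {result.grad_norm:.6g}",
        f"separation_flag: {result.separation_flag}",
        f"order: {','.join(map(str, result.perm.tolist()))}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_manifest(path, inputs: dict, config: dict, seed) -> None:
    """Plain-text run manifest: inputs, config hash, seed, versions."""
    import scipy

    from . import __version__

    cfg_repr = repr(sorted(config.items())).encode()
    digest = hashlib.sha256(cfg_repr).hexdigest()
    lines = ["[manifest]"]
    for k, v in sorted(inputs.items()):
        lines.append(f"input.{k}: {v}")
    for k, v in sorted(config.items()):
        lines.append(f"config.{k}: {v}")
    lines.append(f"config_hash: {digest}")
    lines.append(f"seed: {seed}")
    lines.append(f"version.sparselogit: {__version__}")
    lines.append(f"version.numpy: {np.__version__}")
    lines.append(f"version.scipy: {scipy.__version__}")
    lines.append(f"version.pandas: {pd.__version__}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
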