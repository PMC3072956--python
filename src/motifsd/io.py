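"""Readers and writers for the TSV/GMT formats used throughout the pipeline.

Expression and binding matrices travel as tab-separated files with a header
row and row labels. The on-disk convention for expression follows the common
microarray dialect (genes in rows, samples in columns); internally the
canonical orientation is samples x genes.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    BindingMatrix,
    ExpressionMatrix,
    RegulatoryModule,
    StrengthMatrix,
    TFAMatrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "read_binding",
    "read_truth_edges",
    "align",
    "write_expression",
    "write_binding",
    "write_outputs",
    "read_tfa",
    "read_strengths",
    "read_gmt",
]

_FLOAT_FMT = "%.12g"


def _read_numeric_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row ids {dupes[:5]}")
    # locate the first offending cell, if any, for a usable error message
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(f"{path}: non-numeric cell at row '{row}', column '{col}'")
        if coerced.isna().any():
            row = df.index[coerced.isna().to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"{path}: missing value at row '{row}', column '{col}'; "
                "impute expression data before running (e.g. KNN imputation)"
            )
        df[col] = coerced
    return df


def read_expression(path, genes_in_rows: bool = True) -> ExpressionMatrix:
    """Read a log-ratio expression TSV.

    Parameters
    ----------
    path:
        TSV file with a header row and row labels.
    genes_in_rows:
        If True (default), the file stores genes in rows and samples in
        columns; the matrix is transposed into the internal samples x genes
        orientation.
    """
    df = _read_numeric_tsv(path)
    if genes_in_rows:
        df = df.T
    X = ExpressionMatrix(df.to_numpy(float), list(df.index), list(df.columns))
    logger.info("read expression %s: %d samples x %d genes", path, X.n_samples, X.n_genes)
    zeros = X.zero_gene_columns()
    if zeros:
        logger.warning("all-zero expression for %d genes (e.g. %s)", len(zeros), zeros[:5])
    return X


def read_binding(path) -> BindingMatrix:
    """Read a TF x gene binding-strength TSV (TFs in rows)."""
    df = _read_numeric_tsv(path)
    W = BindingMatrix(df.to_numpy(float), list(df.index), list(df.columns))
    logger.info("read binding %s: %d TFs x %d genes", path, W.n_tfs, len(W.gene_ids))
    return W


def read_truth_edges(path) -> set[tuple[str, str]]:
    """Read a two-column (tf_id, gene_id) edge list, no header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["tf", "gene"], dtype=str)
    return set(zip(df["tf"], df["gene"]))


def align(X: ExpressionMatrix, W: BindingMatrix) -> tuple[ExpressionMatrix, BindingMatrix]:
    """Restrict both matrices to their common genes, in X's gene order."""
    common = [g for g in X.gene_ids if g in set(W.gene_ids)]
    if not common:
        raise ValueError("expression and binding matrices share no gene ids")
    dropped_x = [g for g in X.gene_ids if g not in set(common)]
    dropped_w = [g for g in W.gene_ids if g not in set(common)]
    if dropped_x:
        logger.warning("align: dropping %d expression genes (e.g. %s)", len(dropped_x), dropped_x[:5])
    if dropped_w:
        logger.warning("align: dropping %d binding genes (e.g. %s)", len(dropped_w), dropped_w[:5])
    xi = [X.gene_ids.index(g) for g in common]
    wi = [W.gene_ids.index(g) for g in common]
    Xa = ExpressionMatrix(X.values[:, xi], list(X.sample_ids), common)
    Wa = BindingMatrix(W.values[:, wi], list(W.tf_ids), common)
    return Xa, Wa


def _write_frame(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def write_expression(X: ExpressionMatrix, path, genes_in_rows: bool = True) -> None:
    df = X.to_frame()
    _write_frame(df.T if genes_in_rows else df, Path(path))


def write_binding(W: BindingMatrix, path) -> None:
    _write_frame(W.to_frame(), Path(path))


def write_outputs(
    A: TFAMatrix,
    S: StrengthMatrix,
    modules: list[RegulatoryModule],
    outdir,
    stats: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write A.tsv, S.tsv, modules.gmt and stats.tsv under ``outdir``.

    All files are re-readable bit-exactly by the matching readers. ``stats``
    may be supplied pre-computed; otherwise a minimal (gene, tf, strength)
    table is derived from S.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "A": outdir / "A.tsv",
        "S": outdir / "S.tsv",
        "modules": outdir / "modules.gmt",
        "stats": outdir / "stats.tsv",
    }
    _write_frame(A.to_frame(), paths["A"])
    _write_frame(S.to_frame(), paths["S"])
    with open(paths["modules"], "w") as fh:
        for mod in modules:
            targets = "\t".join(mod.targets)
            line = f"{mod.tf_id}\tmsd_module"
            if targets:
                line += "\t" + targets
            fh.write(line + "\n")
    if stats is None:
        rows = []
        for ti, tf in enumerate(S.tf_ids):
            for gi, g in enumerate(S.gene_ids):
                rows.append((g, tf, S.values[ti, gi], np.nan, np.nan))
        stats = pd.DataFrame(rows, columns=["gene", "tf", "strength", "p", "FDR"])
    stats.to_csv(paths["stats"], sep="\t", index=False, float_format=_FLOAT_FMT)
    logger.info("wrote outputs to %s", outdir)
    return paths


def read_tfa(path) -> TFAMatrix:
    df = _read_numeric_tsv(path)
    return TFAMatrix(df.to_numpy(float), list(df.index), list(df.columns))


def read_strengths(path) -> StrengthMatrix:
    df = _read_numeric_tsv(path)
    return StrengthMatrix(df.to_numpy(float), list(df.index), list(df.columns))


def read_gmt(path) -> list[RegulatoryModule]:
    modules = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or not parts[0]:
                continue
            tf_id, _desc, *targets = parts + [""] * (2 - len(parts))
            modules.append(RegulatoryModule(tf_id, {g: float("nan") for g in targets if g}))
    return modules
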