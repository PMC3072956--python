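"""Core data containers for the motif-guided sparse decomposition pipeline.

The central latent-variable model is ``X = A S``: log-ratio expression
``X`` (m samples x N genes) is a linear mixture of transcription-factor
activities ``A`` (m x n) weighted by regulation strengths ``S`` (n x N).
A non-negative motif binding-strength matrix ``W`` (n x N) supplies prior
evidence on the support of ``S``.

All containers are thin wrappers over a numpy array plus ordered string
labels; :meth:`to_frame` exposes each as a pandas DataFrame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "BindingMatrix",
    "TFAMatrix",
    "StrengthMatrix",
    "RegulatoryModule",
]


def _check_labels(labels, what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate {what} ids: {dupes[:5]}")
    return labels


@dataclass
class ExpressionMatrix:
    """Log-ratio expression, samples x genes (internal canonical orientation)."""

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D")
        self.sample_ids = _check_labels(self.sample_ids, "sample")
        self.gene_ids = _check_labels(self.gene_ids, "gene")
        m, N = self.values.shape
        if m != len(self.sample_ids) or N != len(self.gene_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if m < 2:
            raise ValueError("need at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(
                "expression contains missing/non-finite values; "
                "impute before loading (imputation is out of scope)"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def zero_gene_columns(self) -> list[str]:
        """Gene ids whose expression is identically zero (flagged, not dropped)."""
        mask = np.all(self.values == 0.0, axis=0)
        return [g for g, z in zip(self.gene_ids, mask) if z]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


@dataclass
class BindingMatrix:
    """Non-negative TF-gene binding strengths, TFs x genes."""

    values: np.ndarray
    tf_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("binding values must be 2-D")
        self.tf_ids = _check_labels(self.tf_ids, "tf")
        self.gene_ids = _check_labels(self.gene_ids, "gene")
        if self.values.shape != (len(self.tf_ids), len(self.gene_ids)):
            raise ValueError("binding matrix shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("binding matrix contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("binding strengths must be non-negative")

    @property
    def n_tfs(self) -> int:
        return self.values.shape[0]

    def validate_rows(self) -> None:
        """Every TF needs at least one nonzero binding entry to be usable."""
        empty = [t for t, row in zip(self.tf_ids, self.values) if not np.any(row > 0)]
        if empty:
            raise ValueError(f"TFs with all-zero binding rows: {empty}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.tf_ids, columns=self.gene_ids)


@dataclass
class TFAMatrix:
    """Estimated transcription-factor activities, samples x TFs.

    ``provenance`` maps each TF to the exemplar gene (or rule) that seeded
    its activity column.
    """

    values: np.ndarray
    sample_ids: list[str]
    tf_ids: list[str]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = _check_labels(self.sample_ids, "sample")
        self.tf_ids = _check_labels(self.tf_ids, "tf")
        if self.values.shape != (len(self.sample_ids), len(self.tf_ids)):
            raise ValueError("TFA matrix shape does not match labels")

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.tf_ids)


@dataclass
class StrengthMatrix:
    """Estimated regulation strengths, TFs x genes (sparse by construction).

    ``residuals`` holds the per-gene reconstruction residual ||A s_g - x_g||_2
    and ``flags`` per-gene solver annotations ('ok', 'projected', 'fallback',
    'maxiter').
    """

    values: np.ndarray
    tf_ids: list[str]
    gene_ids: list[str]
    residuals: np.ndarray | None = None
    iterations: np.ndarray | None = None
    flags: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.tf_ids = _check_labels(self.tf_ids, "tf")
        self.gene_ids = _check_labels(self.gene_ids, "gene")
        if self.values.shape != (len(self.tf_ids), len(self.gene_ids)):
            raise ValueError("strength matrix shape does not match labels")

    @property
    def frobenius_residual(self) -> float:
        if self.residuals is None:
            return float("nan")
        return float(np.sqrt(np.sum(np.asarray(self.residuals) ** 2)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.tf_ids, columns=self.gene_ids)


@dataclass
class RegulatoryModule:
    """One TF together with its inferred target genes.

    ``targets`` maps gene id -> regulation strength; ``p_values`` and ``fdr``
    are keyed the same way.
    """

    tf_id: str
    targets: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)
    fdr: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, q in self.fdr.items():
            if not (0.0 <= q <= 1.0):
                raise ValueError(f"FDR out of [0,1] for {self.tf_id}/{g}: {q}")

    @property
    def size(self) -> int:
        return len(self.targets)
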