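"""End-to-end motif-guided sparse decomposition.

Wires the stages together: align expression and binding, pick (or accept)
the trade-off lambda, cluster genes, map clusters to TFs via motif
enrichment to form the activity matrix A, then estimate the regulation
strengths S and assemble statistically annotated modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as msd_io
from .clustering import ClusterResult, affinity_propagation, estimate_tfa, joint_similarity
from .containers import BindingMatrix, ExpressionMatrix, RegulatoryModule, StrengthMatrix, TFAMatrix
from .decomposition import decompose
from .stats import assemble_modules, strength_stats_table
from .tradeoff import TradeoffCurve, enrichment_table, select_lambda

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run", "run_sd_baseline"]

DEFAULT_LAMBDA = 0.1


@dataclass
class PipelineResult:
    """Everything one full run produces."""

    X: ExpressionMatrix
    W: BindingMatrix
    clusters: ClusterResult
    A: TFAMatrix
    S: StrengthMatrix
    modules: list[RegulatoryModule]
    stats: pd.DataFrame
    lambda_used: float
    curve: TradeoffCurve | None = None
    dropped_tfs: list[str] = field(default_factory=list)

    def full_strengths(self) -> StrengthMatrix:
        """S padded with zero rows for TFs dropped during rank repair."""
        if not self.dropped_tfs:
            return self.S
        tf_ids = list(self.W.tf_ids)
        values = np.zeros((len(tf_ids), len(self.S.gene_ids)))
        for i, tf in enumerate(self.S.tf_ids):
            values[tf_ids.index(tf)] = self.S.values[i]
        return StrengthMatrix(values, tf_ids, list(self.S.gene_ids))

    def write(self, outdir) -> dict:
        return msd_io.write_outputs(self.A, self.S, self.modules, outdir, self.stats)


def run(
    X: ExpressionMatrix,
    W: BindingMatrix,
    lam: float | str = "auto",
    mu: float = 0.5,
    seed: int | None = None,
    grid: np.ndarray | None = None,
    sparseness: float = 0.8,
    tau: float = 0.1,
    restrict_to_w: bool = True,
    cutoff: float = 0.7,
    fdr_threshold: float = 1.0,
    enrichment_mode: str = "sampling",
    enrichment_draws: int = 10_000,
    preference: float | str = "median",
    damping: float = 0.9,
    standardize: str = "center",
    tfa_profile: str = "exemplar",
    max_iter: int = 100,
    tol: float = 1e-6,
) -> PipelineResult:
    """Full mSD pipeline on aligned (or alignable) inputs.

    ``lam='auto'`` selects the trade-off by minimizing C(mu, lambda) on a
    grid; a float fixes it. All stochastic stages (enrichment nulls) derive
    from ``seed``.
    """
    X, W = msd_io.align(X, W)
    W.validate_rows()
    rng = np.random.default_rng(seed)
    curve = None
    if lam == "auto":
        curve = select_lambda(
            X, W, grid=grid, mu=mu, seed=None if seed is None else seed + 1,
            mode=enrichment_mode, draws=enrichment_draws,
            damping=damping, preference=preference, standardize=standardize,
        )
        lam = curve.lambda_star
    lam = float(lam)

    sim = joint_similarity(X, W, lam, standardize=standardize)
    sim.set_preference(preference)
    clusters = affinity_propagation(sim, damping=damping)
    table = enrichment_table(clusters, W, mode=enrichment_mode, draws=enrichment_draws, rng=rng)
    A = estimate_tfa(X, clusters, table.p, W, profile=tfa_profile)
    dropped = [t for t in W.tf_ids if t not in A.tf_ids]
    if dropped:
        logger.warning("TFs dropped during rank repair: %s", dropped)

    S = decompose(X, A, W, spec=sparseness, tau=tau, restrict_to_w=restrict_to_w,
                  max_iter=max_iter, tol=tol)
    w_order = [W.tf_ids.index(t) for t in S.tf_ids]
    support = W.values[w_order] > 0
    stats = strength_stats_table(S, support)
    modules = assemble_modules(S, cutoff=cutoff, fdr_threshold=fdr_threshold, stats=stats)
    return PipelineResult(X, W, clusters, A, S, modules, stats, lam, curve, dropped)


def run_sd_baseline(
    X: ExpressionMatrix,
    W: BindingMatrix,
    seed: int | None = None,
    **kwargs,
) -> PipelineResult:
    """Binding-agnostic sparse-decomposition baseline.

    Clusters on expression alone (lambda = 0) and decomposes with an
    uninformative all-ones binding matrix (no support restriction). W is
    used only to label clusters with TFs via enrichment, which any method
    needs in order to attribute components to named TFs for evaluation.
    """
    kwargs.setdefault("restrict_to_w", False)
    X_a, W_a = msd_io.align(X, W)
    ones = BindingMatrix(np.ones_like(W_a.values), list(W_a.tf_ids), list(W_a.gene_ids))

    rng = np.random.default_rng(seed)
    sim = joint_similarity(X_a, W_a, 0.0, standardize=kwargs.get("standardize", "center"))
    sim.set_preference(kwargs.get("preference", "median"))
    clusters = affinity_propagation(sim, damping=kwargs.get("damping", 0.9))
    table = enrichment_table(
        clusters, W_a,
        mode=kwargs.get("enrichment_mode", "sampling"),
        draws=kwargs.get("enrichment_draws", 10_000), rng=rng,
    )
    A = estimate_tfa(X_a, clusters, table.p, W_a, profile=kwargs.get("tfa_profile", "exemplar"))
    dropped = [t for t in W_a.tf_ids if t not in A.tf_ids]
    S = decompose(
        X_a, A, ones, spec=kwargs.get("sparseness", 0.8), tau=kwargs.get("tau", 0.1),
        restrict_to_w=False, max_iter=kwargs.get("max_iter", 100), tol=kwargs.get("tol", 1e-6),
    )
    stats = strength_stats_table(S)
    modules = assemble_modules(S, cutoff=kwargs.get("cutoff", 0.7))
    return PipelineResult(X_a, W_a, clusters, A, S, modules, stats, 0.0, None, dropped)
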