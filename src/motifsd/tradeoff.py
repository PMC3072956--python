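"""Selecting the expression/motif trade-off parameter lambda.

For each candidate lambda the genes are re-clustered and two [0, 1]
summaries are computed: the mean normalized entropy of motif occupancy
across clusters (low when each cluster is dominated by few motifs, i.e.
cluster-specific regulation) and the non-uniformity of expression within
clusters (high when clusters are expression-noisy). Their weighted sum
C(mu, lambda) = mu * H + (1 - mu) * NonU is minimized over a grid; both
noise channels pull the optimum away from the endpoints, giving a U-shaped
curve on data where expression and motif evidence are each informative but
independently noisy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .clustering import ClusterResult, affinity_propagation, joint_similarity
from .containers import BindingMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentTable",
    "TradeoffCurve",
    "enrichment_pvalue",
    "enrichment_table",
    "motif_frequencies",
    "cluster_entropy",
    "mean_entropy",
    "non_uniformity",
    "default_lambda_grid",
    "select_lambda",
]

DEFAULT_NULL_DRAWS = 10_000


@dataclass
class EnrichmentTable:
    """Per-cluster per-motif enrichment p-values and normalized frequencies."""

    p: np.ndarray  # J x n, in (0, 1]
    theta: np.ndarray  # J x n, rows sum to 1

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.p.shape != self.theta.shape:
            raise ValueError("p and theta must have the same shape")
        if np.any(self.p <= 0) or np.any(self.p > 1):
            raise ValueError("p-values must lie in (0, 1]")
        if np.any(self.theta < 0) or not np.allclose(self.theta.sum(axis=1), 1.0):
            raise ValueError("theta rows must be non-negative and sum to 1")


@dataclass
class TradeoffCurve:
    """Evaluated C(mu, lambda) over a lambda grid with its argmin."""

    grid: np.ndarray
    H: np.ndarray
    NonU: np.ndarray
    C: np.ndarray
    J: np.ndarray
    mu: float
    lambda_star: float = field(init=False)

    def __post_init__(self) -> None:
        valid = np.isfinite(self.C)
        if not valid.any():
            raise ValueError("no valid grid point in trade-off curve")
        order = np.argsort(self.grid, kind="stable")
        cmin = np.nanmin(self.C[valid])
        # ties resolve to the smallest lambda
        for i in order:
            if valid[i] and self.C[i] == cmin:
                self.lambda_star = float(self.grid[i])
                break

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lambda": self.grid, "H": self.H, "NonU": self.NonU, "C": self.C, "J": self.J}
        )

    def lambda_star_for_mu(self, mu: float) -> float:
        """Argmin of the re-weighted cost mu*H + (1-mu)*NonU on this grid.

        C(mu, lambda) is linear in the stored H and NonU curves, so
        alternative mu values need no re-clustering.
        """
        C = mu * self.H + (1.0 - mu) * self.NonU
        return TradeoffCurve(self.grid, self.H, self.NonU, C, self.J, mu).lambda_star


def enrichment_pvalue(
    cluster_genes: np.ndarray,
    motif_index: int,
    W: BindingMatrix,
    cutoff: float = 0.0,
    mode: str = "sampling",
    draws: int = DEFAULT_NULL_DRAWS,
    rng: np.random.Generator | None = None,
) -> float:
    """Motif enrichment p-value for one cluster against a resampling null.

    Motif presence is w(t, g) > cutoff. The null counts motif-bearing genes
    in random clusters of the same size drawn from the whole population
    (``draws`` replicates, hypergeometric by construction); the p-value is
    Pr(null overlap >= observed) with a +1/(R+1) continuity correction.
    ``mode='exact'`` uses the analytic hypergeometric tail instead.
    """
    cluster_genes = np.asarray(cluster_genes, dtype=int)
    if cluster_genes.size < 1:
        raise ValueError("cluster must contain at least one gene")
    present = W.values[motif_index] > cutoff
    N = present.size
    N_B = int(present.sum())
    N_j = cluster_genes.size
    N_b = int(present[cluster_genes].sum())
    if N_B == 0:
        logger.warning("motif %s absent from population; p = 1", W.tf_ids[motif_index])
        return 1.0
    if mode == "exact":
        return float(min(1.0, hypergeom.sf(N_b - 1, N, N_B, N_j)))
    if mode != "sampling":
        raise ValueError(f"unknown mode: {mode}")
    if rng is None:
        rng = np.random.default_rng()
    null = rng.hypergeometric(N_B, N - N_B, N_j, size=draws)
    return float((1 + np.sum(null >= N_b)) / (draws + 1))


def enrichment_table(
    clusters: ClusterResult,
    W: BindingMatrix,
    cutoff: float = 0.0,
    mode: str = "sampling",
    draws: int = DEFAULT_NULL_DRAWS,
    rng: np.random.Generator | None = None,
) -> EnrichmentTable:
    """Enrichment p-values and motif frequencies for every (cluster, motif)."""
    J, n = clusters.J, W.n_tfs
    p = np.ones((J, n))
    for j in range(J):
        members = clusters.members(j)
        for t in range(n):
            p[j, t] = enrichment_pvalue(members, t, W, cutoff, mode, draws, rng)
    theta = np.vstack([motif_frequencies(p[j]) for j in range(J)])
    return EnrichmentTable(p, theta)


def motif_frequencies(p_row: np.ndarray) -> np.ndarray:
    """Normalized motif frequencies theta = -log10(p), sum-normalized.

    A row of all-ones p-values (no enrichment anywhere) maps to the uniform
    distribution.
    """
    p_row = np.asarray(p_row, dtype=float)
    if np.any(p_row <= 0) or np.any(p_row > 1):
        raise ValueError("p-values must lie in (0, 1]")
    theta = -np.log10(p_row)
    total = theta.sum()
    if total <= 0:
        return np.full(p_row.size, 1.0 / p_row.size)
    return theta / total


def cluster_entropy(theta_row: np.ndarray) -> float:
    """Normalized entropy of a motif-frequency row, in [0, 1]."""
    theta = np.asarray(theta_row, dtype=float)
    n = theta.size
    if n < 2:
        raise ValueError("entropy needs at least 2 motifs")
    if np.any(theta < 0) or not np.isclose(theta.sum(), 1.0):
        raise ValueError("theta must be a probability vector")
    nz = theta[theta > 0]
    H = -np.sum(nz * np.log(nz))
    return float(H / np.log(n))


def mean_entropy(table: EnrichmentTable) -> float:
    """Mean normalized motif-occupancy entropy over clusters, in [0, 1]."""
    return float(np.mean([cluster_entropy(row) for row in table.theta]))


def _cluster_variances(X: ExpressionMatrix, clusters: ClusterResult) -> tuple[np.ndarray, np.ndarray]:
    N = X.n_genes
    variances = np.zeros(clusters.J)
    weights = np.zeros(clusters.J)
    for j in range(clusters.J):
        members = clusters.members(j)
        weights[j] = members.size / N
        if members.size > 1:
            variances[j] = float(X.values[:, members].var(axis=1).mean())
    return variances, weights


def non_uniformity(
    X: ExpressionMatrix, clusters: ClusterResult, sigma2_max: float | None = None
) -> float:
    """Size-weighted within-cluster expression variance, in [0, 1].

    For cluster j, sigma2_j is the across-gene variance of member expression
    averaged over samples (0 for singletons); clusters are weighted by their
    gene fraction and scaled by the maximum cluster variance. ``sigma2_max``
    may be supplied externally so the measure is comparable across
    alternative clusterings of the same data (as in ``select_lambda``);
    values then cap at 1.
    """
    variances, weights = _cluster_variances(X, clusters)
    vmax = variances.max() if sigma2_max is None else float(sigma2_max)
    if vmax <= 0:
        return 0.0
    return float(min(np.sum(weights * variances / vmax), 1.0))


def default_lambda_grid(lam_max: float = 1.0, points: int = 21) -> np.ndarray:
    """Zero plus log-spaced lambda values up to ``lam_max``."""
    return np.concatenate([[0.0], np.geomspace(lam_max / 100.0, lam_max, points - 1)])


def select_lambda(
    X: ExpressionMatrix,
    W: BindingMatrix,
    grid: np.ndarray | None = None,
    mu: float = 0.5,
    seed: int | None = None,
    cutoff: float = 0.0,
    mode: str = "sampling",
    draws: int = DEFAULT_NULL_DRAWS,
    damping: float = 0.9,
    max_iter: int = 1000,
    preference: float | str = "median",
    standardize: str = "center",
) -> TradeoffCurve:
    """Minimize C(mu, lambda) = mu*H + (1-mu)*NonU over a lambda grid.

    Failed grid points (clustering errors) are marked invalid and excluded
    from the argmin; ties go to the smaller lambda.
    """
    if grid is None:
        grid = default_lambda_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size < 5:
        raise ValueError("lambda grid needs at least 5 values")
    rng = np.random.default_rng(seed)
    H = np.full(grid.size, np.nan)
    NonU = np.full(grid.size, np.nan)
    C = np.full(grid.size, np.nan)
    Js = np.zeros(grid.size, dtype=int)
    raw = np.full(grid.size, np.nan)
    vmax_all = 0.0
    for i, lam in enumerate(grid):
        try:
            S = joint_similarity(X, W, lam, standardize=standardize)
            S.set_preference(preference)
            clusters = affinity_propagation(S, damping=damping, max_iter=max_iter)
            table = enrichment_table(clusters, W, cutoff, mode, draws, rng)
            H[i] = mean_entropy(table)
            variances, weights = _cluster_variances(X, clusters)
            raw[i] = float(np.sum(weights * variances))
            vmax_all = max(vmax_all, float(variances.max()))
            Js[i] = clusters.J
        except Exception as exc:  # pragma: no cover - defensive per-grid-point guard
            logger.warning("lambda=%g failed (%s); grid point excluded", lam, exc)
    # one normalizer across the whole grid so NonU(lambda) values are
    # mutually comparable (the maximum cluster variance over all clusterings)
    if vmax_all > 0:
        NonU = np.minimum(raw / vmax_all, 1.0)
    else:
        NonU = np.where(np.isfinite(raw), 0.0, np.nan)
    C = mu * H + (1.0 - mu) * NonU
    curve = TradeoffCurve(grid, H, NonU, C, Js, mu)
    logger.info("selected lambda* = %g (mu=%g)", curve.lambda_star, mu)
    return curve
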