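"""Stage 1: motif-guided gene clustering and TF-activity estimation.

Genes are clustered by affinity propagation on a joint similarity that
blends expression distance with a motif co-regulation likelihood:

    s(i, k) = -d_hat(i, k) + lambda * L_hat(i, k)

where d(i, k) = ||x_i - x_k||^2 on (optionally centered) expression columns,
L(i, k) = sum_t w(t, i) w(t, k) is the summed joint binding strength over
TFs, and both terms are divided by their off-diagonal maxima so the
trade-off lambda is scale-free. Each TF's activity profile is then taken
from the exemplar of the cluster most enriched for its motif.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import BindingMatrix, ExpressionMatrix, TFAMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityMatrix",
    "ClusterResult",
    "coregulation_likelihood",
    "joint_similarity",
    "affinity_propagation",
    "estimate_tfa",
]


@dataclass
class SimilarityMatrix:
    """Pairwise similarities with AP preference values on the diagonal."""

    values: np.ndarray
    lam: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("similarity matrix must be finite")
        off = ~np.eye(n, dtype=bool)
        if not np.allclose(self.values[off], self.values.T[off]):
            raise ValueError("similarity matrix must be symmetric off-diagonal")

    def set_preference(self, preference: float | str = "median") -> None:
        """Set the diagonal (self-similarity) that controls cluster count."""
        n = self.values.shape[0]
        if preference == "median":
            off = self.values[~np.eye(n, dtype=bool)]
            preference = float(np.median(off))
        np.fill_diagonal(self.values, float(preference))


@dataclass
class ClusterResult:
    """An exemplar-indexed partition of genes."""

    labels: np.ndarray  # gene index -> cluster index 0..J-1
    exemplars: np.ndarray  # cluster index -> gene index
    lam: float = 0.0
    converged: bool = True

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.exemplars = np.asarray(self.exemplars, dtype=int)
        for j, e in enumerate(self.exemplars):
            if self.labels[e] != j:
                raise ValueError(f"exemplar {e} not a member of its own cluster {j}")

    @property
    def J(self) -> int:
        return len(self.exemplars)

    def members(self, j: int) -> np.ndarray:
        return np.nonzero(self.labels == j)[0]

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.J)


def coregulation_likelihood(w_i: np.ndarray, w_k: np.ndarray) -> float:
    """Summed joint binding strength sum_t w(t,i) * w(t,k) for a gene pair."""
    w_i = np.asarray(w_i, dtype=float)
    w_k = np.asarray(w_k, dtype=float)
    if w_i.shape != w_k.shape:
        raise ValueError("TF-strength vectors must have equal length")
    return float(np.dot(w_i, w_k))


def _center_expression(X: ExpressionMatrix, mode: str) -> np.ndarray:
    V = X.values
    if mode == "none":
        return V
    if mode == "center":
        return V - V.mean(axis=0, keepdims=True)
    if mode == "zscore":
        sd = V.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        return (V - V.mean(axis=0, keepdims=True)) / sd
    raise ValueError(f"unknown standardization mode: {mode}")


def joint_similarity(
    X: ExpressionMatrix,
    W: BindingMatrix,
    lam: float,
    standardize: str = "center",
    blend: str = "additive",
) -> SimilarityMatrix:
    """Joint expression/motif similarity matrix for AP clustering.

    ``blend='additive'`` gives s = -d_hat + lambda * L_hat (default);
    ``blend='convex'`` gives s = -(1-lambda') d_hat + lambda' L_hat with
    lambda' = lambda/(1+lambda), an equivalent reparametrization.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    N = X.n_genes
    if N < 3:
        raise ValueError("affinity propagation needs at least 3 genes")
    if X.gene_ids != W.gene_ids:
        raise ValueError("X and W must be aligned on genes (run align first)")
    V = _center_expression(X, standardize)
    sq = np.sum(V * V, axis=0)
    d = sq[:, None] + sq[None, :] - 2.0 * (V.T @ V)
    np.clip(d, 0.0, None, out=d)
    L = W.values.T @ W.values
    off = ~np.eye(N, dtype=bool)
    d_max = d[off].max()
    L_max = L[off].max()
    d_hat = d / d_max if d_max > 0 else d
    L_hat = L / L_max if L_max > 0 else L
    if blend == "additive":
        s = -d_hat + lam * L_hat
    elif blend == "convex":
        t = lam / (1.0 + lam)
        s = -(1.0 - t) * d_hat + t * L_hat
    else:
        raise ValueError(f"unknown blend: {blend}")
    s = 0.5 * (s + s.T)  # enforce exact symmetry against rounding
    return SimilarityMatrix(s, lam)


def affinity_propagation(
    S: SimilarityMatrix,
    damping: float = 0.9,
    max_iter: int = 1000,
    convergence_window: int = 50,
) -> ClusterResult:
    """Deterministic affinity-propagation clustering on a similarity matrix.

    Standard responsibility/availability message passing. No noise is
    injected; argmax ties resolve to the lowest index, so results are
    reproducible bit-for-bit. If the exemplar set is not stable for
    ``convergence_window`` iterations by ``max_iter``, the current result is
    returned with ``converged=False``.
    """
    if not (0.5 <= damping < 1.0):
        raise ValueError("damping must be in [0.5, 1)")
    Sv = S.values
    n = Sv.shape[0]
    R = np.zeros((n, n))
    Av = np.zeros((n, n))
    idx = np.arange(n)
    stable = 0
    prev_exemplars: np.ndarray | None = None
    converged = False

    for _ in range(max_iter):
        # responsibilities
        AS = Av + Sv
        first = AS.argmax(axis=1)
        first_val = AS[idx, first]
        AS[idx, first] = -np.inf
        second_val = AS.max(axis=1)
        AS[idx, first] = first_val
        Rnew = Sv - first_val[:, None]
        Rnew[idx, first] = Sv[idx, first] - second_val
        R = damping * R + (1.0 - damping) * Rnew
        # availabilities
        Rp = np.maximum(R, 0.0)
        Rp[idx, idx] = R[idx, idx]
        colsum = Rp.sum(axis=0)
        Anew = np.minimum(0.0, colsum[None, :] - Rp)
        Anew[idx, idx] = colsum - Rp[idx, idx]  # = sum of others' positive evidence
        Av = damping * Av + (1.0 - damping) * Anew

        exemplars = np.nonzero(np.diag(R) + np.diag(Av) > 0)[0]
        if prev_exemplars is not None and np.array_equal(exemplars, prev_exemplars):
            stable += 1
            if stable >= convergence_window and exemplars.size > 0:
                converged = True
                break
        else:
            stable = 0
        prev_exemplars = exemplars

    exemplars = np.nonzero(np.diag(R) + np.diag(Av) > 0)[0]
    if exemplars.size == 0:
        # degenerate: fall back to the single best self-evidence point
        exemplars = np.array([int(np.argmax(np.diag(R) + np.diag(Av)))])
        logger.warning("affinity propagation found no exemplars; using best candidate")
    if not converged:
        logger.warning("affinity propagation did not converge in %d iterations", max_iter)
    labels = exemplars[np.argmax(Sv[:, exemplars], axis=1)]
    labels[exemplars] = exemplars
    # compact cluster indices in exemplar order
    used = np.unique(labels)
    remap = {e: j for j, e in enumerate(used)}
    compact = np.array([remap[e] for e in labels], dtype=int)
    return ClusterResult(compact, used, lam=S.lam, converged=converged)


def _assign_clusters(
    enrichment_p: np.ndarray, sizes: np.ndarray, unique: bool
) -> dict[int, int]:
    """Map TF index -> cluster index by enrichment.

    ``unique=False``: each TF independently takes its minimum-p cluster
    (ties: larger cluster, then lower index). ``unique=True``: greedy
    one-to-one assignment in order of ascending p, so no two TFs share a
    cluster while clusters remain — distinct activity sources keep A well
    conditioned. TFs with no enriched cluster (all p == 1) are left out.
    """
    J, n = enrichment_p.shape
    assignment: dict[int, int] = {}
    if not unique:
        for t in range(n):
            p_col = enrichment_p[:, t]
            if p_col.min() >= 1.0:
                continue
            tied = np.nonzero(p_col == p_col.min())[0]
            if tied.size > 1:
                tied = tied[sizes[tied] == sizes[tied].max()]
            assignment[t] = int(tied[0])
        return assignment
    # candidates sorted by (p, -cluster size, cluster idx, tf idx)
    candidates = sorted(
        ((enrichment_p[j, t], -sizes[j], j, t) for j in range(J) for t in range(n)
         if enrichment_p[j, t] < 1.0),
        key=lambda c: (c[0], c[1], c[2], c[3]),
    )
    taken: set[int] = set()
    for p, _negsize, j, t in candidates:
        if t in assignment:
            continue
        if j in taken:
            continue
        assignment[t] = j
        taken.add(j)
    if len(taken) == J:  # more TFs than clusters: fall back to sharing
        for t in range(n):
            if t not in assignment and enrichment_p[:, t].min() < 1.0:
                assignment[t] = int(np.argmin(enrichment_p[:, t]))
    return assignment


def estimate_tfa(
    X: ExpressionMatrix,
    clusters: ClusterResult,
    enrichment_p: np.ndarray,
    W: BindingMatrix,
    profile: str = "exemplar",
    assignment: str = "unique",
    enforce_rank: bool = True,
) -> TFAMatrix:
    """Build the TF-activity matrix A from cluster exemplars.

    Each TF's activity column is the exemplar expression profile of the
    cluster with the smallest motif-enrichment p-value for that TF;
    ``assignment='unique'`` (default) additionally forbids two TFs from
    claiming the same cluster (greedy by ascending p) so the activity
    columns stay distinct, while ``'min-p'`` allows sharing. A TF with no
    enriched cluster (all p == 1) falls back to the W-weighted mean
    expression of its bound genes. Residual rank deficiency is repaired by
    dropping the most collinear TF columns (with a warning); dropped TFs
    are reported via ``provenance``.
    """
    enrichment_p = np.asarray(enrichment_p, dtype=float)
    J, n = enrichment_p.shape
    if J != clusters.J or n != W.n_tfs:
        raise ValueError("enrichment table shape must be J clusters x n TFs")
    sizes = clusters.sizes()
    m = X.n_samples
    cols = np.zeros((m, n))
    provenance: dict[str, str] = {}
    if assignment not in {"unique", "min-p"}:
        raise ValueError(f"unknown assignment mode: {assignment}")
    tf_to_cluster = _assign_clusters(enrichment_p, sizes, assignment == "unique")
    for t in range(n):
        if t not in tf_to_cluster:
            w_t = W.values[t]
            total = w_t.sum()
            if total <= 0:
                raise ValueError(f"TF {W.tf_ids[t]} has no binding information")
            cols[:, t] = X.values @ (w_t / total)
            provenance[W.tf_ids[t]] = "w-weighted-mean"
            logger.warning("TF %s not enriched in any cluster; W-weighted mean profile", W.tf_ids[t])
            continue
        j = tf_to_cluster[t]
        if profile == "exemplar":
            g = int(clusters.exemplars[j])
            cols[:, t] = X.values[:, g]
            provenance[W.tf_ids[t]] = f"exemplar:{X.gene_ids[g]}"
        elif profile == "mean":
            cols[:, t] = X.values[:, clusters.members(j)].mean(axis=1)
            provenance[W.tf_ids[t]] = f"cluster-mean:{j}"
        else:
            raise ValueError(f"unknown profile mode: {profile}")

    keep = list(range(n))
    while enforce_rank and len(keep) > 1 and np.linalg.matrix_rank(cols[:, keep]) < len(keep):
        sub = cols[:, keep]
        sd = sub.std(axis=0)
        safe = np.where(sd == 0, 1.0, sd)
        Z = (sub - sub.mean(axis=0)) / safe
        corr = np.abs(Z.T @ Z) / m
        np.fill_diagonal(corr, 0.0)
        worst = int(np.argmax(corr.max(axis=0)[::-1]))  # ties -> higher index
        worst = len(keep) - 1 - worst
        dropped_tf = W.tf_ids[keep[worst]]
        logger.warning("dropping collinear TFA column for %s", dropped_tf)
        provenance[dropped_tf] = provenance.get(dropped_tf, "") + " [dropped:collinear]"
        keep.pop(worst)
    tf_ids = [W.tf_ids[t] for t in keep]
    return TFAMatrix(cols[:, keep], list(X.sample_ids), tf_ids, provenance)
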