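"""Validation statistics for inferred regulatory modules.

Turns the strength matrix S into ranked, statistically annotated target
lists: per-gene p-values against a gamma null fitted to "negative" genes
(no motif connection), Benjamini-Hochberg FDR, a GSEA-style KS rank
statistic with a permutation null, a motif-enrichment permutation test, and
ROC/AUC evaluation against a ground-truth edge set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import RegulatoryModule, StrengthMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "gamma_null_pvalues",
    "bh_fdr",
    "ks_enrichment",
    "motif_enrichment_test",
    "roc_auc",
    "assemble_modules",
    "strength_stats_table",
]

_GAMMA_MIN_NULL = 30
_EPS = 1e-12


def gamma_null_pvalues(strengths: np.ndarray, null_strengths: np.ndarray) -> np.ndarray:
    """Upper-tail p-values of strengths under a gamma null.

    The null is fitted (maximum likelihood, location fixed at 0,
    method-of-moments start) to the magnitudes of the negative-set
    strengths; with fewer than 30 null points an empirical tail with
    continuity correction is used instead. Strength magnitudes regulated by
    a TF roughly follow a gamma law because most TFs regulate few targets.
    """
    strengths = np.abs(np.asarray(strengths, dtype=float))
    null = np.abs(np.asarray(null_strengths, dtype=float))
    if null.size == 0:
        raise ValueError("empty negative set")
    if np.allclose(null, null[0]):
        raise ValueError("degenerate (zero-variance) negative set")
    if null.size >= _GAMMA_MIN_NULL:
        fit_vals = np.maximum(null, _EPS)  # gamma ML needs strictly positive data
        mean, var = fit_vals.mean(), fit_vals.var()
        a0 = max(mean * mean / max(var, _EPS), _EPS)
        shape, _, scale = sps.gamma.fit(fit_vals, a0, floc=0.0, scale=mean / a0)
        return sps.gamma.sf(strengths, shape, loc=0.0, scale=scale)
    logger.warning("negative set < %d; empirical tail p-values", _GAMMA_MIN_NULL)
    counts = np.sum(null[None, :] >= strengths[:, None], axis=1)
    return (1.0 + counts) / (null.size + 1.0)


def bh_fdr(p_values: np.ndarray, G: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg FDR: raw G*p_k/r_k and its step-up monotonization.

    ``G`` defaults to the number of p-values but may be set to the full
    experiment size when only a subset is scored. Returns (raw, adjusted),
    both in the input order and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if G is None:
        G = n
    order = np.argsort(p, kind="stable")
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.arange(1, n + 1)
    raw = np.minimum(G * p / ranks, 1.0)
    adjusted_sorted = np.minimum.accumulate((G * p[order] / np.arange(1, n + 1))[::-1])[::-1]
    adjusted = np.empty(n)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return raw, adjusted


def _ks_statistic(indicator: np.ndarray, mode: str) -> float:
    # indicator: 1 where the ranked gene is in the reference set
    n = indicator.shape[-1]
    x = indicator.sum(axis=-1, keepdims=True)
    y = n - x
    V = np.where(indicator, y, -x)
    walk = np.cumsum(V, axis=-1)
    if mode == "max":
        stat = walk.max(axis=-1)
        return np.maximum(stat, 0.0)
    if mode == "max-abs":
        return np.abs(walk).max(axis=-1)
    raise ValueError(f"unknown KS mode: {mode}")


def ks_enrichment(
    ranked_genes: list[str],
    reference_set: set[str],
    permutations: int = 10_000,
    seed: int | None = None,
    mode: str = "max",
) -> tuple[float, float]:
    """KS rank statistic of a reference set within a ranked gene list.

    Genes in the reference set step the walk up by y (the non-overlap
    count), others step down by x (the overlap count), so the walk ends at
    zero; the statistic is the maximum prefix sum (floored at 0; GSEA-style
    one-sided, ``mode='max-abs'`` for the two-sided variant). Significance
    is the fraction of ``permutations`` random same-size sets reaching an
    equal or larger statistic, with continuity correction.
    """
    if not reference_set:
        raise ValueError("empty reference set")
    n = len(ranked_genes)
    indicator = np.array([g in reference_set for g in ranked_genes], dtype=np.int64)
    x = int(indicator.sum())
    if x < 1:
        raise ValueError("reference set does not overlap the ranked list")
    observed = float(_ks_statistic(indicator, mode))
    rng = np.random.default_rng(seed)
    # permute overlap positions: B random binary rows with exactly x ones
    u = rng.random((permutations, n))
    null_ind = (u.argsort(axis=1).argsort(axis=1) < x).astype(np.int64)
    null = _ks_statistic(null_ind, mode)
    p = float((1 + np.sum(null >= observed)) / (permutations + 1))
    return observed, p


def motif_enrichment_test(
    gene_set: list[str],
    scores: dict[str, float] | pd.Series,
    permutations: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation test for motif enrichment in a gene set.

    The statistic is the mean binding score of the motif over the set; the
    null redraws same-size sets from the whole scored population. One-sided
    p with continuity correction. (A sum statistic differs only by the
    constant set size under fixed-size permutation, so p-values agree.)
    """
    if len(gene_set) < 2:
        raise ValueError("gene set must contain at least 2 genes")
    scores = pd.Series(scores, dtype=float)
    missing = [g for g in gene_set if g not in scores.index]
    if missing:
        raise ValueError(f"genes without scores: {missing[:5]}")
    all_scores = scores.to_numpy()
    if not np.any(all_scores != 0):
        return 0.0, 1.0
    observed = float(scores.loc[list(gene_set)].mean())
    rng = np.random.default_rng(seed)
    k = len(gene_set)
    draws = np.empty(permutations)
    for b in range(permutations):
        draws[b] = all_scores[rng.choice(all_scores.size, k, replace=False)].mean()
    p = float((1 + np.sum(draws >= observed)) / (permutations + 1))
    return observed, p


def _auc_from_scores(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal AUC by running down the ranked list (ties grouped)."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    P = int(y.sum())
    Ng = y.size - P
    boundaries = np.nonzero(np.diff(s))[0]
    cut = np.concatenate([boundaries, [y.size - 1]])
    tp = np.concatenate([[0], np.cumsum(y)[cut]])
    fp = np.concatenate([[0], np.cumsum(1 - y)[cut]])
    return float(np.trapezoid(tp / P, fp / Ng))


def roc_auc(
    S: StrengthMatrix,
    truth_edges: set[tuple[str, str]],
) -> tuple[dict[str, float], float]:
    """Per-TF ROC AUC of |strength| rankings against a truth edge set.

    Genes are ranked by decreasing |s_tg| per TF; TFs with no true target
    (or no true negative) are excluded with a warning. Returns the per-TF
    table and the macro-average.
    """
    per_tf: dict[str, float] = {}
    for ti, tf in enumerate(S.tf_ids):
        labels = np.array([(tf, g) in truth_edges for g in S.gene_ids], dtype=float)
        P = labels.sum()
        if P == 0 or P == labels.size:
            logger.warning("TF %s has no usable truth labels; excluded from AUC", tf)
            continue
        per_tf[tf] = _auc_from_scores(np.abs(S.values[ti]), labels)
    if not per_tf:
        raise ValueError("no TF has ground-truth targets")
    return per_tf, float(np.mean(list(per_tf.values())))


def strength_stats_table(
    S: StrengthMatrix,
    W_support: np.ndarray | None = None,
    G: int | None = None,
) -> pd.DataFrame:
    """Per (gene, TF) strength, gamma-null p and BH FDR.

    The null for each TF is the strengths of genes with no binding support
    in W (requires ``W_support``, a boolean TFs x genes mask); without it
    every gene scores p = FDR = NaN.
    """
    rows = []
    for ti, tf in enumerate(S.tf_ids):
        s_row = np.abs(S.values[ti])
        p = np.full(s_row.size, np.nan)
        raw = np.full(s_row.size, np.nan)
        adj = np.full(s_row.size, np.nan)
        if W_support is not None:
            negatives = s_row[~W_support[ti]]
            try:
                p = gamma_null_pvalues(s_row, negatives)
                raw, adj = bh_fdr(p, G)
            except ValueError as exc:
                logger.warning("no null p-values for %s: %s", tf, exc)
        for gi, g in enumerate(S.gene_ids):
            rows.append((g, tf, S.values[ti, gi], p[gi], raw[gi], adj[gi]))
    return pd.DataFrame(rows, columns=["gene", "tf", "strength", "p", "FDR_raw", "FDR"])


def assemble_modules(
    S: StrengthMatrix,
    cutoff: float = 0.7,
    fdr_threshold: float = 1.0,
    stats: pd.DataFrame | None = None,
) -> list[RegulatoryModule]:
    """Per-TF modules: targets with per-TF max-normalized |strength| >= cutoff
    and (when stats are supplied) FDR <= threshold."""
    modules = []
    for ti, tf in enumerate(S.tf_ids):
        mags = np.abs(S.values[ti])
        mmax = mags.max()
        norm = mags / mmax if mmax > 0 else mags
        selected = norm >= cutoff
        fdr_map: dict[str, float] = {}
        p_map: dict[str, float] = {}
        if stats is not None:
            sub = stats[stats["tf"] == tf].set_index("gene")
            fdr = sub["FDR"].reindex(S.gene_ids).to_numpy()
            pvals = sub["p"].reindex(S.gene_ids).to_numpy()
            with np.errstate(invalid="ignore"):
                selected = selected & ~(fdr > fdr_threshold)
            for gi, g in enumerate(S.gene_ids):
                if selected[gi] and np.isfinite(fdr[gi]):
                    fdr_map[g] = float(np.clip(fdr[gi], 0.0, 1.0))
                    p_map[g] = float(pvals[gi])
        targets = {g: float(S.values[ti, gi]) for gi, g in enumerate(S.gene_ids) if selected[gi]}
        modules.append(RegulatoryModule(tf, targets, p_map, fdr_map))
    return modules
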