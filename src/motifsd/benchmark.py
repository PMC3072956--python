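"""Synthetic benchmarks for end-to-end testing of the decomposition pipeline.

Emulates a small transcriptional network experiment: latent TF activities
evolve as smooth random walks across samples, each gene is regulated by a
few TFs with signed gamma-magnitude strengths, expression is the linear
mixture plus Gaussian noise, and the motif prior W is the true support
corrupted by false-positive/false-negative edges with jittered strengths.
Defaults mirror a compendium-style experiment of 15 samples x 345 genes x
11 TFs. A companion generator emits planted-motif promoters and PWMs so
sequence scanning can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import BindingMatrix, ExpressionMatrix
from .pwm import ALPHABET, PWM

__all__ = ["BenchmarkSpec", "GroundTruth", "simulate", "simulate_promoters"]


@dataclass
class BenchmarkSpec:
    """Study conditions for one synthetic benchmark replicate."""

    m: int = 15  # samples
    N: int = 345  # genes
    n: int = 11  # TFs
    K: int = 3  # max regulators per gene
    noise_sd: float = 0.1  # expression noise, log-ratio units
    fp_rate: float = 0.1  # spurious binding edges
    fn_rate: float = 0.1  # missed binding edges
    signed: bool = True  # allow repressive (negative) strengths
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K > self.n:
            raise ValueError("max regulators per gene cannot exceed the TF count")
        if self.K < 1 or self.m < 2 or self.n < 2 or self.N < self.n:
            raise ValueError("invalid benchmark dimensions")
        for r in (self.fp_rate, self.fn_rate):
            if not (0.0 <= r < 1.0):
                raise ValueError("edge corruption rates must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


@dataclass
class GroundTruth:
    """The latent quantities behind one simulated dataset."""

    A_true: np.ndarray  # m x n
    S_true: np.ndarray  # n x N
    edges: set[tuple[str, str]]
    W_clean: np.ndarray  # n x N, support == edges
    tf_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)


def _random_walk_activities(rng: np.random.Generator, m: int, n: int) -> np.ndarray:
    """Smooth, unit-variance activity profiles (one random walk per TF)."""
    steps = rng.normal(size=(m, n))
    A = np.cumsum(steps, axis=0)
    A -= A.mean(axis=0, keepdims=True)
    sd = A.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return A / sd


def simulate(spec: BenchmarkSpec) -> tuple[ExpressionMatrix, BindingMatrix, GroundTruth]:
    """Generate one (expression, binding, ground-truth) benchmark replicate.

    All randomness flows from ``spec.seed``; identical specs produce
    bit-identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    m, N, n, K = spec.m, spec.N, spec.n, spec.K
    sample_ids = [f"s{p + 1:02d}" for p in range(m)]
    gene_ids = [f"g{g + 1:04d}" for g in range(N)]
    tf_ids = [f"tf{t + 1:02d}" for t in range(n)]

    A_true = _random_walk_activities(rng, m, n)

    S_true = np.zeros((n, N))
    for g in range(N):
        k = int(rng.integers(1, K + 1))
        regs = rng.choice(n, size=k, replace=False)
        mags = rng.gamma(shape=2.0, scale=1.0, size=k) + 0.2
        signs = rng.choice([-1.0, 1.0], size=k) if spec.signed else np.ones(k)
        S_true[regs, g] = signs * mags

    X = A_true @ S_true
    if spec.noise_sd > 0:
        X = X + rng.normal(scale=spec.noise_sd, size=X.shape)

    support = S_true != 0
    W_clean = np.abs(S_true)
    W = W_clean.copy()
    if spec.fn_rate > 0:
        drop = support & (rng.random(W.shape) < spec.fn_rate)
        # never silence a TF's whole row: keep its strongest edge
        for t in range(n):
            if np.all(drop[t] == support[t]) and support[t].any():
                drop[t, np.argmax(W_clean[t])] = False
        W[drop] = 0.0
    if spec.fp_rate > 0:
        add = (~support) & (rng.random(W.shape) < spec.fp_rate)
        W[add] = rng.gamma(shape=2.0, scale=1.0, size=int(add.sum())) + 0.2
    jitter = rng.lognormal(mean=0.0, sigma=0.25, size=W.shape)
    W = W * jitter

    edges = {(tf_ids[t], gene_ids[g]) for t, g in zip(*np.nonzero(support))}
    Xm = ExpressionMatrix(X, sample_ids, gene_ids)
    Wm = BindingMatrix(W, tf_ids, gene_ids)
    truth = GroundTruth(A_true, S_true, edges, W_clean, tf_ids, gene_ids, sample_ids)
    return Xm, Wm, truth


def simulate_promoters(
    truth: GroundTruth,
    motif_length: int = 8,
    promoter_length: int = 200,
    dominance: float = 0.85,
    seed: int = 0,
) -> tuple[list[PWM], dict[str, str]]:
    """Planted-motif promoters matching a simulated network's edge set.

    Each TF gets a high-information-content PWM (one dominant base per
    position with probability ``dominance``); each true edge plants that
    TF's consensus at a random offset in the target's promoter, over random
    background sequence.
    """
    if motif_length < 4:
        raise ValueError("motif length must be >= 4")
    if promoter_length < motif_length:
        raise ValueError("promoter shorter than motif")
    rng = np.random.default_rng(seed)
    n = len(truth.tf_ids)
    pwms = []
    for t in range(n):
        consensus_idx = rng.integers(0, 4, size=motif_length)
        counts = np.full((4, motif_length), (1.0 - dominance) / 3 * 100.0)
        counts[consensus_idx, np.arange(motif_length)] = dominance * 100.0
        pwms.append(PWM(truth.tf_ids[t], counts))

    bases = np.array(list(ALPHABET))
    promoters: dict[str, str] = {}
    edge_lookup = {(t, g) for t, g in truth.edges}
    n_slots = promoter_length // motif_length  # disjoint slots avoid overwrites
    for gi, gene in enumerate(truth.gene_ids):
        seq = list(bases[rng.integers(0, 4, size=promoter_length)])
        bound = [t for t in range(n) if (truth.tf_ids[t], gene) in edge_lookup]
        if len(bound) > n_slots:
            raise ValueError("promoter too short for this gene's regulator count")
        slots = rng.choice(n_slots, size=len(bound), replace=False)
        for t, slot in zip(bound, slots):
            offset = int(slot) * motif_length
            seq[offset : offset + motif_length] = list(pwms[t].consensus())
        promoters[gene] = "".join(seq)
    return pwms, promoters
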