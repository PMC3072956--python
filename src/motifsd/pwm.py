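"""Promoter scanning with position weight matrices.

Builds the TF-gene binding-strength matrix W from motif models and upstream
promoter sequences. Each motif is a position weight matrix (PWM) converted
to log-odds weights; a promoter's binding strength for a TF is the best
window score over both strands, min-max normalized into [0, 1] by the PWM's
attainable score extremes, with sub-threshold scores zeroed (an open
substitute for proprietary matrix-match scanners whose cutoffs minimize the
false-positive rate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO, motifs as bio_motifs

logger = logging.getLogger(__name__)

__all__ = [
    "PWM",
    "read_pwms",
    "read_promoters",
    "revcomp",
    "score_window",
    "scan_promoter",
    "build_binding_matrix",
]

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_PSEUDOCOUNT = 0.25
DEFAULT_CUTOFF = 0.75  # fraction of the attainable score range


@dataclass
class PWM:
    """A binding motif as per-position base counts (or frequencies).

    ``counts`` is 4 x L over A,C,G,T. Log-odds weights are
    log2(freq / background) with a per-base pseudocount, so a window score
    is the sum over positions of the weight of its base.
    """

    tf_id: str
    counts: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("PWM counts must be 4 x L over ACGT")
        if self.counts.shape[1] < 4:
            raise ValueError("motif length must be >= 4")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def weights(self) -> np.ndarray:
        """4 x L log2-odds weights (finite thanks to the pseudocount)."""
        adj = self.counts + self.pseudocount
        freqs = adj / adj.sum(axis=0, keepdims=True)
        w = np.log2(freqs / self.background[:, None])
        if not np.all(np.isfinite(w)):
            raise ValueError(f"non-finite log-odds weights for {self.tf_id}")
        return w

    @property
    def score_range(self) -> tuple[float, float]:
        w = self.weights
        return float(w.min(axis=0).sum()), float(w.max(axis=0).sum())

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.weights, axis=0))


def read_pwms(path, fmt: str = "jaspar", **kwargs) -> list[PWM]:
    """Parse PWMs from a JASPAR- or TRANSFAC-format file (via Bio.motifs)."""
    fmt = fmt.lower()
    if fmt not in {"jaspar", "transfac"}:
        raise ValueError(f"unsupported PWM format: {fmt}")
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, fmt)
    out = []
    for m in parsed:
        name = m.name or getattr(m, "matrix_id", None) or f"motif{len(out) + 1}"
        counts = np.array([list(m.counts[b]) for b in ALPHABET], dtype=float)
        out.append(PWM(str(name), counts, **kwargs))
    if not out:
        raise ValueError(f"no motifs parsed from {path}")
    return out


def read_promoters(path) -> dict[str, str]:
    """Read promoter sequences from FASTA, keyed by the first header token."""
    promoters: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = rec.id.split()[0]
        promoters[gene] = str(rec.seq).upper()
    if not promoters:
        raise ValueError(f"no sequences in {path}")
    return promoters


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def score_window(pwm: PWM, window: str) -> float:
    """Log-odds score of one window; 'N' contributes the position minimum."""
    if len(window) != pwm.length:
        raise ValueError(f"window length {len(window)} != motif length {pwm.length}")
    w = pwm.weights
    mins = w.min(axis=0)
    total = 0.0
    for pos, base in enumerate(window.upper()):
        idx = _BASE_INDEX.get(base)
        total += mins[pos] if idx is None else w[idx, pos]
    return float(total)


def _best_raw_score(weights5: np.ndarray, idx: np.ndarray, L: int) -> float:
    # idx encodes bases 0..3 plus 4 for N/unknown; weights5 row 4 holds the
    # per-position minimum so N always scores conservatively.
    n_win = idx.size - L + 1
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    pos = np.arange(L)
    scores = weights5[windows, pos].sum(axis=1)
    return float(scores.max()) if n_win > 0 else -np.inf


def scan_promoter(
    pwm: PWM,
    seq: str,
    cutoff: float = DEFAULT_CUTOFF,
    threshold_after_normalize: bool = True,
) -> float:
    """Binding strength of a motif on one promoter, in [0, 1].

    Best window score over both strands, min-max normalized by the PWM's
    attainable extremes; values below ``cutoff`` (a fraction of the range,
    after normalization by default) are zeroed.
    """
    seq = seq.upper()
    if len(seq) < pwm.length:
        logger.warning("sequence shorter than motif %s; binding strength 0", pwm.tf_id)
        return 0.0
    w = pwm.weights
    weights5 = np.vstack([w, w.min(axis=0)])

    def encode(s: str) -> np.ndarray:
        arr = np.frombuffer(s.encode(), dtype=np.uint8)
        idx = np.full(arr.size, 4, dtype=np.intp)
        for base, i in _BASE_INDEX.items():
            idx[arr == ord(base)] = i
        return idx

    best = max(
        _best_raw_score(weights5, encode(seq), pwm.length),
        _best_raw_score(weights5, encode(revcomp(seq)), pwm.length),
    )
    lo, hi = pwm.score_range
    if hi <= lo:
        return 0.0
    norm = (best - lo) / (hi - lo)
    norm = float(np.clip(norm, 0.0, 1.0))
    if threshold_after_normalize:
        return norm if norm >= cutoff else 0.0
    raw_cut = lo + cutoff * (hi - lo)
    return norm if best >= raw_cut else 0.0


def build_binding_matrix(
    pwms: list[PWM],
    promoters: dict[str, str],
    gene_ids: list[str] | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    threshold_after_normalize: bool = True,
):
    """Scan every promoter with every PWM to form the n x N matrix W.

    ``gene_ids`` fixes the column set; genes without a promoter sequence get
    all-zero columns (with a warning).
    """
    from .containers import BindingMatrix

    if not pwms or not promoters:
        raise ValueError("need at least one PWM and one promoter")
    if gene_ids is None:
        gene_ids = list(promoters)
    missing = [g for g in gene_ids if g not in promoters]
    if missing:
        logger.warning("no promoter for %d genes (e.g. %s); zero columns", len(missing), missing[:5])
    values = np.zeros((len(pwms), len(gene_ids)))
    for ti, pwm in enumerate(pwms):
        for gi, gene in enumerate(gene_ids):
            seq = promoters.get(gene)
            if seq:
                values[ti, gi] = scan_promoter(pwm, seq, cutoff, threshold_after_normalize)
    if not np.any(values > 0):
        raise ValueError("binding matrix is all zero: no usable motif information")
    return BindingMatrix(values, [p.tf_id for p in pwms], list(gene_ids))
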