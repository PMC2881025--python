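"""PWM scanning with exact score-distribution p-values, and the
class-conditional motif-abundance estimator.

The scanner scores every position of both strands with a log-odds position
weight matrix and converts scores to p-values by exact dynamic programming
over the discretized score distribution under an i.i.d. background — the
p-value of a score is the probability that a random background word of the
motif's width scores at least as high.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import hmm
from .hmm import COMP, N_CODE

DEFAULT_MT = 1e-4          # p-value threshold for reporting a hit
SCORE_STEP = 1e-3          # log-odds discretization step (bits)
PSEUDOCOUNT = 1e-4


@dataclass
class MotifMatrix:
    """Base-probability matrix of a motif with an i.i.d. background."""

    probs: np.ndarray                       # (width, 4)
    background: np.ndarray | None = None    # (4,), uniform if None
    pseudocount: float = PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("motif must have shape (width, 4)")
        if self.width == 0:
            raise ValueError("zero-width motif")
        if (self.probs < 0).any():
            raise ValueError("negative motif probability")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("motif rows must sum to 1")
        if self.background is None:
            self.background = np.full(4, 0.25)
        else:
            self.background = np.asarray(self.background, dtype=float)
            self.background = self.background / self.background.sum()

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def reverse_complement(self) -> "MotifMatrix":
        return MotifMatrix(self.probs[::-1][:, COMP],
                           background=self.background[COMP],
                           pseudocount=self.pseudocount)

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        """(width, 4) log2 odds against the background, pseudocounted."""
        bg = self.background if background is None else np.asarray(background)
        p = self.probs + self.pseudocount
        p = p / p.sum(axis=1, keepdims=True)
        return np.log2(p) - np.log2(bg)[None, :]

    @classmethod
    def from_consensus(cls, consensus: str, certainty: float = 1.0,
                       background=None) -> "MotifMatrix":
        codes = hmm.encode(consensus)
        if (codes >= 4).any():
            raise ValueError("consensus must be over {A,C,G,T}")
        w = len(codes)
        probs = np.full((w, 4), (1.0 - certainty) / 3)
        probs[np.arange(w), codes.astype(np.int64)] = certainty
        return cls(probs, background=background)


@dataclass
class MotifHit:
    seq_id: str
    start: int              # 0-based start of the motif span
    strand: str             # '+' or '-'
    score: float            # log-odds (bits)
    pvalue: float


def _quantize(lo: np.ndarray, step: float) -> np.ndarray:
    return np.round(lo / step).astype(np.int64)


def score_pvalue_table(motif: MotifMatrix, background: np.ndarray | None = None,
                       step: float = SCORE_STEP):
    """Exact null distribution of the quantized PWM score.

    Returns (offset, pvals) where for a quantized score q the p-value is
    ``pvals[q - offset]``: the probability that a random background word
    scores >= q.
    """
    bg = motif.background if background is None else np.asarray(background)
    bg = bg / bg.sum()
    Q = _quantize(motif.log_odds(bg), step)   # (w, 4)
    # DP over positions: dist[i] = P(quantized partial score == base + i)
    dist = np.ones(1)
    base = 0
    for j in range(motif.width):
        qj = Q[j]
        lo, hi = int(qj.min()), int(qj.max())
        new = np.zeros(len(dist) + hi - lo)
        for b in range(4):
            sh = int(qj[b]) - lo
            new[sh:sh + len(dist)] += bg[b] * dist
        dist = new
        base += lo
    # survival function: P(score_q >= q)
    sf = np.cumsum(dist[::-1])[::-1]
    return base, sf


def _strand_scores(codes: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Quantized sliding scores; windows containing N get -2**62."""
    w = Q.shape[0]
    L = len(codes)
    n_pos = L - w + 1
    if n_pos <= 0:
        return np.empty(0, dtype=np.int64)
    safe = np.where(codes < N_CODE, codes, 0).astype(np.int64)
    scores = np.zeros(n_pos, dtype=np.int64)
    for j in range(w):
        scores += Q[j][safe[j:j + n_pos]]
    bad = codes >= N_CODE
    if bad.any():
        invalid = np.convolve(bad.astype(np.int64), np.ones(w, dtype=np.int64),
                              mode="valid") > 0
        scores[invalid] = -(2 ** 62)
    return scores


def scan(seq, motif: MotifMatrix, mt: float = DEFAULT_MT,
         background: np.ndarray | None = None, seq_id: str = "seq",
         step: float = SCORE_STEP) -> list[MotifHit]:
    """Scan both strands; report hits with p-value <= mt.

    Overlapping hits are allowed; when both strands hit at the same start
    position only the better p-value is kept.
    """
    if not 0 < mt < 1:
        raise ValueError("mt must be in (0, 1)")
    codes = seq if isinstance(seq, np.ndarray) else hmm.encode(seq)
    if len(codes) < motif.width:
        return []
    bg = motif.background if background is None else np.asarray(background)
    bg = bg / bg.sum()
    hits: dict[int, MotifHit] = {}
    for strand, m in (("+", motif), ("-", motif.reverse_complement())):
        Q = _quantize(m.log_odds(bg), step)
        base, sf = score_pvalue_table(m, background=bg, step=step)
        scores = _strand_scores(codes, Q)
        ok = scores > -(2 ** 61)
        pv = np.ones_like(scores, dtype=float)
        pv[ok] = sf[np.clip(scores[ok] - base, 0, len(sf) - 1)]
        for pos in np.flatnonzero(ok & (pv <= mt)):
            hit = MotifHit(seq_id, int(pos), strand,
                           float(scores[pos] * step), float(pv[pos]))
            old = hits.get(int(pos))
            if old is None or hit.pvalue < old.pvalue:
                hits[int(pos)] = hit
    return [hits[k] for k in sorted(hits)]


# ---------------------------------------------------------------------------
# class-conditional motif abundance

def single_class_model(model: hmm.MosaicModel, state: int) -> hmm.MosaicModel:
    """Clamp the chain to one state (used to simulate pure-class sequence)."""
    K = model.K
    pi = np.zeros(K)
    pi[state] = 1.0
    A = np.zeros((K, K))
    A[:, state] = 1.0
    return hmm.MosaicModel(pi, A, model.E.copy(), model.e0.copy(),
                           model.pair.copy())


def count_in_class_simulations(model: hmm.MosaicModel, motif: MotifMatrix,
                               mt: float = DEFAULT_MT, n_seqs: int = 10,
                               seq_len: int = 1_000_000, seed=None
                               ) -> np.ndarray:
    """Per-state motif density c: hits per 10^7 simulated pure-class bases.

    Each class is simulated with its state clamped; scanning uses the
    class's stationary composition as background.
    """
    rng = np.random.default_rng(seed)
    c = np.zeros(model.K)
    for s in range(model.K):
        clamped = single_class_model(model, s)
        sims = [hmm.simulate(clamped, seq_len, seed=rng.integers(2 ** 31))[0]
                for _ in range(n_seqs)]
        try:
            bg = hmm.class_base_composition(model, s)
        except hmm.ModelError:
            # degenerate emission chain: use the empirical composition
            counts = sum(np.bincount(o, minlength=4)[:4] for o in sims)
            bg = (counts + 1.0) / (counts.sum() + 4.0)
        n_hits = sum(len(scan(o, motif, mt=mt, background=bg)) for o in sims)
        c[s] = n_hits / (n_seqs * seq_len) * 1e7
    return c


def motif_class_proportions(b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Normalized per-class motif proportions, proportional to b * c.

    ``b`` is each class's share of genome bases and ``c`` its motif density
    per 10^7 bases; the genome size cancels in the normalization.
    """
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    if b.shape != c.shape:
        raise ValueError("b and c must align")
    w = b * c
    total = w.sum()
    if total <= 0:
        raise ValueError("all classes have zero motif density")
    return w / total
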