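"""Strand-symmetric paired-state mosaic HMM.

The genome is modelled as a mosaic of short classes (typically tens of
bases), each class a single HMM state with a geometric dwell time.  The
emission probability of a base depends on the state and on the immediately
previous emitted base, so each state carries a 4x4 conditional table
``E[s][y][x] = P(x | state s, previous base y)`` plus a length-4 initial-base
distribution ``e0[s]`` used at the start of a sequence (and after masked
positions, where conditioning is reset).

Because the two DNA strands are chemically equivalent, states come in
strand-symmetric pairs: state ``pair[s]`` emits the A<->T / C<->G complement
of state ``s``, and transition probabilities between two states equal those
between their partners.  The tying is imposed at initialization and
re-imposed after every EM M-step.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

BASES = "ACGT"
A_, C_, G_, T_ = 0, 1, 2, 3
N_CODE = 4
#: base complement in integer coding (A<->T, C<->G)
COMP = np.array([3, 2, 1, 0], dtype=np.int64)

_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i
_LUT[ord("N")] = N_CODE
_LUT[ord("n")] = N_CODE


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into int8 codes (A=0, C=1, G=2, T=3, N=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _LUT[raw]
    if (codes < 0).any():
        bad = seq[int(np.argmax(codes < 0))]
        raise ValueError(f"invalid base {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


class ModelError(ValueError):
    """Raised when a model violates its probability or symmetry invariants."""


@dataclass
class MosaicModel:
    """Full parameter set of the mosaic HMM.

    Attributes
    ----------
    pi : (K,) initial state distribution
    A : (K, K) state transition matrix
    E : (K, 4, 4) conditional emission tables, ``E[s, y, x] = P(x | s, prev=y)``
    e0 : (K, 4) per-state initial-base distribution
    pair : (K,) involution mapping each state to its strand partner
    """

    pi: np.ndarray
    A: np.ndarray
    E: np.ndarray
    e0: np.ndarray
    pair: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        self.e0 = np.asarray(self.e0, dtype=float)
        self.pair = np.asarray(self.pair, dtype=np.int64)

    @property
    def K(self) -> int:
        return len(self.pi)

    @property
    def n_pairs(self) -> int:
        return self.K // 2

    def validate(self, atol: float = 1e-6, symmetry: bool = True) -> None:
        K = self.K
        if K % 2:
            raise ModelError(f"odd number of states: {K}")
        for name, arr, shape in (
            ("pi", self.pi, (K,)),
            ("A", self.A, (K, K)),
            ("E", self.E, (K, 4, 4)),
            ("e0", self.e0, (K, 4)),
            ("pair", self.pair, (K,)),
        ):
            if arr.shape != shape:
                raise ModelError(f"{name} has shape {arr.shape}, expected {shape}")
        if (self.pair[self.pair] != np.arange(K)).any():
            raise ModelError("pair map is not an involution")
        if (self.pair == np.arange(K)).any():
            raise ModelError("a state cannot be its own strand partner")
        for name, arr in (("pi", self.pi[None]), ("A", self.A),
                          ("e0", self.e0), ("E", self.E.reshape(-1, 4))):
            if (arr < -atol).any():
                raise ModelError(f"negative probability in {name}")
            sums = arr.sum(axis=-1)
            if not np.allclose(sums, 1.0, atol=atol):
                off = int(np.argmax(np.abs(sums - 1)))
                raise ModelError(
                    f"row {off} of {name} sums to {sums.flat[off]:.6g}, not 1")
        if symmetry and not is_symmetric(self, atol=max(atol, 1e-9)):
            raise ModelError("model violates strand-symmetry tying")

    def copy(self) -> "MosaicModel":
        return MosaicModel(self.pi.copy(), self.A.copy(), self.E.copy(),
                           self.e0.copy(), self.pair.copy())


@dataclass
class PosteriorMatrix:
    """Per-position posterior state probabilities plus sequence log-likelihood."""

    gamma: np.ndarray          # (L, K), rows sum to 1
    log_likelihood: float


@dataclass
class ClassSummary:
    """One class pair's summary row: composition, dwell length, CpG, share."""

    pair_index: int            # 1-based, ordered by descending genome share
    canonical_state: int
    partner_state: int
    composition: np.ndarray    # (4,) A,C,G,T of the canonical member
    mean_length: float
    cpg_proportion: float
    genome_proportion: float


def is_symmetric(model: MosaicModel, atol: float = 1e-9) -> bool:
    p = model.pair
    ok = np.allclose(model.A, model.A[p][:, p], atol=atol)
    ok &= np.allclose(model.pi, model.pi[p], atol=atol)
    ok &= np.allclose(model.E, model.E[p][:, COMP][:, :, COMP], atol=atol)
    ok &= np.allclose(model.e0, model.e0[p][:, COMP], atol=atol)
    return bool(ok)


def reimpose_symmetry(model: MosaicModel) -> MosaicModel:
    """Average every parameter with its strand-tied counterpart and renormalize.

    Idempotent; an already-symmetric model is returned unchanged (up to
    floating-point noise).
    """
    p = model.pair
    A = 0.5 * (model.A + model.A[p][:, p])
    A /= A.sum(axis=1, keepdims=True)
    pi = 0.5 * (model.pi + model.pi[p])
    pi /= pi.sum()
    E = 0.5 * (model.E + model.E[p][:, COMP][:, :, COMP])
    E /= E.sum(axis=2, keepdims=True)
    e0 = 0.5 * (model.e0 + model.e0[p][:, COMP])
    e0 /= e0.sum(axis=1, keepdims=True)
    return MosaicModel(pi, A, E, e0, model.pair.copy())


# ---------------------------------------------------------------------------
# emission bookkeeping

def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, str):
        return encode(seq)
    codes = np.asarray(seq, dtype=np.int8)
    if codes.ndim != 1:
        raise ValueError("sequence must be one-dimensional")
    return codes


def _emission_matrix(model: MosaicModel, obs: np.ndarray) -> np.ndarray:
    """Per-position emission factors B[t, s] for one encoded sequence.

    N positions contribute a factor of 1 (missing data); a base following an
    N (or the first base) is scored by the initial-base distribution e0.
    """
    L = len(obs)
    prev = np.empty(L, dtype=np.int8)
    prev[0] = N_CODE
    prev[1:] = obs[:-1]
    valid = obs < N_CODE
    reset = (prev == N_CODE) & valid
    cond = (prev < N_CODE) & valid
    B = np.ones((L, model.K))
    if reset.any():
        B[reset] = model.e0[:, obs[reset].astype(np.int64)].T
    if cond.any():
        B[cond] = model.E[:, prev[cond].astype(np.int64),
                          obs[cond].astype(np.int64)].T
    return B


def _emission_matrix_batch(model: MosaicModel, obs: np.ndarray) -> np.ndarray:
    """Batched emission factors, obs shape (n, L) -> B shape (n, L, K)."""
    n, L = obs.shape
    prev = np.empty((n, L), dtype=np.int8)
    prev[:, 0] = N_CODE
    prev[:, 1:] = obs[:, :-1]
    valid = obs < N_CODE
    reset = (prev == N_CODE) & valid
    cond = (prev < N_CODE) & valid
    B = np.ones((n, L, model.K))
    if reset.any():
        B[reset] = model.e0[:, obs[reset].astype(np.int64)].T
    if cond.any():
        B[cond] = model.E[:, prev[cond].astype(np.int64),
                          obs[cond].astype(np.int64)].T
    return B


# ---------------------------------------------------------------------------
# inference

def _check_seq(obs: np.ndarray) -> None:
    if len(obs) == 0:
        raise ValueError("empty sequence")


def log_likelihood(model: MosaicModel, seq) -> float:
    obs = _as_codes(seq)
    _check_seq(obs)
    B = _emission_matrix(model, obs)
    alpha = model.pi * B[0]
    ll = 0.0
    for t in range(len(obs)):
        if t:
            alpha = (alpha @ model.A) * B[t]
        c = alpha.sum()
        if c <= 0:
            raise ValueError(f"emission underflow at position {t}")
        ll += np.log(c)
        alpha = alpha / c
    return float(ll)


def forward_backward(model: MosaicModel, seq) -> PosteriorMatrix:
    """Scaled forward-backward posterior decoding of one sequence."""
    obs = _as_codes(seq)
    _check_seq(obs)
    gamma, ll = _posterior_batch(model, obs[None, :])
    return PosteriorMatrix(gamma[0], float(ll[0]))


def _forward_batch(model: MosaicModel, B: np.ndarray):
    n, L, K = B.shape
    alpha = np.empty((n, L, K))
    c = np.empty((n, L))
    a = model.pi * B[:, 0]
    c[:, 0] = a.sum(axis=1)
    if (c[:, 0] <= 0).any():
        raise ValueError("emission underflow at position 0")
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, L):
        a = (alpha[:, t - 1] @ model.A) * B[:, t]
        ct = a.sum(axis=1)
        if (ct <= 0).any():
            raise ValueError(f"emission underflow at position {t}")
        c[:, t] = ct
        alpha[:, t] = a / ct[:, None]
    return alpha, c


def _posterior_batch(model: MosaicModel, obs: np.ndarray):
    """Posteriors for a batch of equal-length encoded sequences.

    Returns (gamma (n, L, K), loglik (n,)).
    """
    B = _emission_matrix_batch(model, obs)
    alpha, c = _forward_batch(model, B)
    n, L, K = B.shape
    gamma = np.empty((n, L, K))
    beta = np.ones((n, K))
    gamma[:, L - 1] = alpha[:, L - 1]
    for t in range(L - 1, 0, -1):
        bn = (B[:, t] * beta) / c[:, t, None]
        beta = bn @ model.A.T
        gamma[:, t - 1] = alpha[:, t - 1] * beta
    return gamma, np.log(c).sum(axis=1)


def posterior_windows(model: MosaicModel, sequences: Sequence,
                      chunk: int = 256):
    """Posterior matrices for many sequences, batched by equal length.

    Yields PosteriorMatrix objects in input order; memory is bounded by
    ``chunk`` sequences per batch.
    """
    coded = [_as_codes(s) for s in sequences]
    for o in coded:
        _check_seq(o)
    out: list[PosteriorMatrix | None] = [None] * len(coded)
    by_len: dict[int, list[int]] = {}
    for i, o in enumerate(coded):
        by_len.setdefault(len(o), []).append(i)
    for L, idxs in by_len.items():
        for j in range(0, len(idxs), chunk):
            sel = idxs[j:j + chunk]
            obs = np.stack([coded[i] for i in sel])
            gamma, ll = _posterior_batch(model, obs)
            for k, i in enumerate(sel):
                out[i] = PosteriorMatrix(gamma[k], float(ll[k]))
    return out


def viterbi(model: MosaicModel, seq) -> np.ndarray:
    """Most probable joint state path (log-space dynamic programme)."""
    obs = _as_codes(seq)
    _check_seq(obs)
    with np.errstate(divide="ignore"):
        logB = np.log(_emission_matrix(model, obs))
        logA = np.log(model.A)
        logpi = np.log(model.pi)
    L, K = logB.shape
    delta = logpi + logB[0]
    back = np.empty((L, K), dtype=np.int64)
    for t in range(1, L):
        cand = delta[:, None] + logA
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(K)] + logB[t]
    path = np.empty(L, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(L - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


# ---------------------------------------------------------------------------
# stationary quantities

def _stationary(P: np.ndarray, what: str) -> np.ndarray:
    n_comp, labels = connected_components(csr_matrix(P > 0), connection="strong")
    if n_comp > 1:
        blocks = [np.flatnonzero(labels == c).tolist() for c in range(n_comp)]
        raise ModelError(f"{what} is reducible; strongly connected blocks: {blocks}")
    w, v = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    s = np.real(v[:, i])
    s = np.abs(s)
    return s / s.sum()


def steady_state(model: MosaicModel) -> np.ndarray:
    """Stationary distribution of the state chain (per-state genome share)."""
    return _stationary(model.A, "transition matrix")


def pair_proportions(model: MosaicModel) -> np.ndarray:
    """Genome share per class pair (sum over the two member states).

    Pairs are indexed by their canonical member order (see ``pair_states``).
    """
    ss = steady_state(model)
    return np.array([ss[a] + ss[b] for a, b in pair_states(model)])


def expected_class_length(model: MosaicModel, state: int) -> float:
    """Mean geometric dwell time 1 / (1 - self-transition)."""
    a = model.A[state, state]
    if a >= 1.0:
        raise ModelError(f"state {state} is absorbing (self-transition {a})")
    return 1.0 / (1.0 - a)


def class_base_composition(model: MosaicModel, state: int) -> np.ndarray:
    """Stationary A/C/G/T composition of the within-class base chain E[s]."""
    return _stationary(model.E[state], f"emission chain of state {state}")


def cpg_proportion(model: MosaicModel, state: int) -> float:
    """Stationary frequency of the CG doublet within a class:
    P(C) * P(G | C)."""
    comp = class_base_composition(model, state)
    return float(comp[C_] * model.E[state, C_, G_])


def pair_states(model: MosaicModel) -> list[tuple[int, int]]:
    """(canonical, partner) state indices for each pair.

    The canonical member is the one with T+C >= 0.5 in its stationary
    composition (ties broken by T+G, then by state index), so that the same
    strand image is chosen consistently across independently trained models.
    """
    seen = set()
    pairs = []
    for s in range(model.K):
        t = int(model.pair[s])
        if s in seen or t in seen:
            continue
        seen.update((s, t))
        ca = class_base_composition(model, s)
        key_s = (ca[T_] + ca[C_], ca[T_] + ca[G_], -s)
        cb = class_base_composition(model, t)
        key_t = (cb[T_] + cb[C_], cb[T_] + cb[G_], -t)
        pairs.append((s, t) if key_s >= key_t else (t, s))
    return pairs


def class_summaries(model: MosaicModel,
                    proportions: np.ndarray | None = None) -> list[ClassSummary]:
    """Per-pair summary rows sorted by descending genome proportion."""
    ps = pair_states(model)
    if proportions is None:
        proportions = pair_proportions(model)
    order = np.argsort(-np.asarray(proportions), kind="stable")
    rows = []
    for rank, k in enumerate(order, start=1):
        canon, partner = ps[k]
        rows.append(ClassSummary(
            pair_index=rank,
            canonical_state=canon,
            partner_state=partner,
            composition=class_base_composition(model, canon),
            mean_length=expected_class_length(model, canon),
            cpg_proportion=cpg_proportion(model, canon),
            genome_proportion=float(proportions[k]),
        ))
    return rows


# ---------------------------------------------------------------------------
# simulation

def simulate(model: MosaicModel, length: int, seed=None):
    """Draw (sequence codes, state path) of the given length.

    The first base is emitted from e0 of the initial state; every later base
    is emitted from E conditioned on the previously emitted base, regardless
    of whether the state just changed.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    K = model.K
    # state path first (vectorized in blocks via inverse-cdf sampling)
    path = np.empty(length, dtype=np.int64)
    cumA = np.cumsum(model.A, axis=1)
    u = rng.random(length)
    s = int(np.searchsorted(np.cumsum(model.pi), u[0], side="right"))
    s = min(s, K - 1)
    path[0] = s
    for t in range(1, length):
        s = int(np.searchsorted(cumA[s], u[t], side="right"))
        s = min(s, K - 1)
        path[t] = s
    # bases
    cumE = np.cumsum(model.E, axis=2)
    cume0 = np.cumsum(model.e0, axis=1)
    v = rng.random(length)
    obs = np.empty(length, dtype=np.int8)
    b = int(np.searchsorted(cume0[path[0]], v[0], side="right"))
    obs[0] = min(b, 3)
    for t in range(1, length):
        b = int(np.searchsorted(cumE[path[t], obs[t - 1]], v[t], side="right"))
        obs[t] = min(b, 3)
    return obs, path


# ---------------------------------------------------------------------------
# EM training

@dataclass
class EMIteration:
    iteration: int
    log_likelihood: float
    delta_proportion: float
    delta_composition: float


def _pair_metrics(model: MosaicModel):
    props = pair_proportions(model)
    comps = np.stack([class_base_composition(model, a)
                      for a, _ in pair_states(model)])
    return props, comps


def _estep(model: MosaicModel, obs: np.ndarray):
    """Sufficient statistics for a batch of equal-length encoded sequences."""
    n, L = obs.shape
    K = model.K
    B = _emission_matrix_batch(model, obs)
    alpha, c = _forward_batch(model, B)
    gamma = np.empty((n, L, K))
    beta = np.ones((n, K))
    gamma[:, L - 1] = alpha[:, L - 1]
    M = np.zeros((K, K))
    for t in range(L - 1, 0, -1):
        bn = (B[:, t] * beta) / c[:, t, None]
        M += alpha[:, t - 1].T @ bn
        beta = bn @ model.A.T
        gamma[:, t - 1] = alpha[:, t - 1] * beta
    prev = np.empty((n, L), dtype=np.int8)
    prev[:, 0] = N_CODE
    prev[:, 1:] = obs[:, :-1]
    valid = obs < N_CODE
    cond = (prev < N_CODE) & valid
    reset = (prev == N_CODE) & valid
    E_counts = np.zeros((K, 16))
    if cond.any():
        idx = (prev[cond].astype(np.int64) * 4 + obs[cond].astype(np.int64))
        G = gamma[cond]
        for s in range(K):
            E_counts[s] = np.bincount(idx, weights=G[:, s], minlength=16)
    e0_counts = np.zeros((K, 4))
    if reset.any():
        idx = obs[reset].astype(np.int64)
        G = gamma[reset]
        for s in range(K):
            e0_counts[s] = np.bincount(idx, weights=G[:, s], minlength=4)
    return {
        "pi": gamma[:, 0].sum(axis=0),
        "A": model.A * M,
        "E": E_counts.reshape(K, 4, 4),
        "e0": e0_counts,
        "loglik": float(np.log(c).sum()),
    }


def _normalize_rows(counts: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    sums = counts.sum(axis=-1, keepdims=True)
    out = np.where(sums > 0, counts / np.where(sums > 0, sums, 1.0), fallback)
    return out / out.sum(axis=-1, keepdims=True)


def em_train(model_init: MosaicModel, sequences: Sequence,
             tol: float = 1e-4, max_iter: int = 500):
    """Batch Baum-Welch with strand-symmetry tying re-imposed each M-step.

    Convergence is declared when the largest absolute change in per-pair
    steady-state proportions and in per-pair base compositions both fall
    below ``tol``.  Returns (trained model, list of EMIteration records).
    """
    model_init.validate(symmetry=True)
    coded = [_as_codes(s if not hasattr(s, "sequence") else s.sequence)
             for s in sequences]
    if not coded:
        raise ValueError("no training sequences")
    for o in coded:
        _check_seq(o)
        if (o >= N_CODE).all():
            raise ValueError("training sequence consists entirely of N")
    by_len: dict[int, list[np.ndarray]] = {}
    for o in coded:
        by_len.setdefault(len(o), []).append(o)
    batches = [np.stack(v) for v in by_len.values()]

    model = model_init.copy()
    log: list[EMIteration] = []
    props, comps = _pair_metrics(model)
    for it in range(1, max_iter + 1):
        acc = None
        for obs in batches:
            st = _estep(model, obs)
            if acc is None:
                acc = st
            else:
                for k in ("pi", "A", "E", "e0"):
                    acc[k] += st[k]
                acc["loglik"] += st["loglik"]
        pi = acc["pi"] / acc["pi"].sum()
        A = _normalize_rows(acc["A"], model.A)
        E = _normalize_rows(acc["E"], model.E)
        e0 = _normalize_rows(acc["e0"], model.e0)
        model = reimpose_symmetry(MosaicModel(pi, A, E, e0, model.pair))
        new_props, new_comps = _pair_metrics(model)
        d_prop = float(np.max(np.abs(new_props - props)))
        d_comp = float(np.max(np.abs(new_comps - comps)))
        props, comps = new_props, new_comps
        log.append(EMIteration(it, acc["loglik"], d_prop, d_comp))
        if d_prop < tol and d_comp < tol:
            break
    return model, log


def random_initial_model(n_pairs: int, sequences: Sequence, seed=None,
                         self_transition: float = 0.97,
                         concentration: float = 50.0) -> MosaicModel:
    """Random symmetric initialization for EM.

    Emission rows are Dirichlet perturbations around the global conditional
    dinucleotide composition of the training batch; self-transitions start at
    ``self_transition`` (mean dwell about 33 bases); the partner of each
    state is the complement image of its parameters.
    """
    rng = np.random.default_rng(seed)
    counts = np.ones((4, 4))
    for s in sequences:
        o = _as_codes(s if not hasattr(s, "sequence") else s.sequence)
        prev, cur = o[:-1], o[1:]
        ok = (prev < N_CODE) & (cur < N_CODE)
        counts += np.bincount(
            prev[ok].astype(np.int64) * 4 + cur[ok].astype(np.int64),
            minlength=16).reshape(4, 4)
    global_E = counts / counts.sum(axis=1, keepdims=True)

    K = 2 * n_pairs
    pair = np.arange(K) ^ 1  # states 2k, 2k+1 are partners
    E = np.empty((K, 4, 4))
    for k in range(n_pairs):
        for y in range(4):
            E[2 * k, y] = rng.dirichlet(concentration * global_E[y] + 0.1)
        E[2 * k + 1] = E[2 * k][COMP][:, COMP]
    A = np.full((K, K), (1.0 - self_transition) / (K - 1))
    np.fill_diagonal(A, self_transition)
    e0 = np.stack([_stationary(E[s], f"init emission {s}") for s in range(K)])
    pi = np.full(K, 1.0 / K)
    model = reimpose_symmetry(MosaicModel(pi, A, E, e0, pair))
    model.validate()
    return model
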