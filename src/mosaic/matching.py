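"""Matching mosaic classes across replicate training runs.

Independently trained models label equivalent classes arbitrarily, so
replicate runs are reconciled in base-composition space: each class pair is
represented by one canonical member's stationary composition mapped to the
coordinates (T+A, T+C, T+G).  Runs are merged sequentially — match, average
positions with equal run weighting, match the next run — under a hard
distance cap D, and the whole procedure is repeated over many run orders,
keeping the order that yields the most matched sets (ties: smaller average
within-set distance).  Matched classes' parameters are then averaged into a
consensus model used to initialize a final training round.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import hmm
from .hmm import COMP, MosaicModel

DEFAULT_D = 0.12
_BIG = 1e9


def class_coordinates(composition) -> np.ndarray:
    """Map an (A, C, G, T) composition to (T+A, T+C, T+G).

    These three sums give an undistorted view of the composition simplex;
    strand-paired classes land mirrored through 0.5 in the T+C and T+G
    coordinates.
    """
    a, c, g, t = np.asarray(composition, dtype=float)
    return np.array([t + a, t + c, t + g])


@dataclass
class ClassPoint:
    """One class (canonical pair member) of one run, in coordinate space."""

    run: int
    state: int
    coords: np.ndarray
    weight: float = 1.0


@dataclass
class MatchSet:
    """A consensus class: members keyed by run id, plus the averaged position."""

    members: dict[int, ClassPoint]
    position: np.ndarray
    weight: float

    @property
    def size(self) -> int:
        return len(self.members)

    def mean_member_distance(self) -> float:
        d = [np.linalg.norm(p.coords - self.position)
             for p in self.members.values()]
        return float(np.mean(d))

    def rms_member_distance(self) -> float:
        d = [np.linalg.norm(p.coords - self.position) ** 2
             for p in self.members.values()]
        return float(np.sqrt(np.mean(d)))


@dataclass
class MatchResult:
    sets: list[MatchSet]            # multi-member sets
    unmatched: list[ClassPoint]     # singletons never matched within the cap
    order: tuple[int, ...]

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    def average_distance(self) -> float:
        if not self.sets:
            return 0.0
        return float(np.mean([s.mean_member_distance() for s in self.sets]))


def match_two_sets(points_a, points_b, D: float = DEFAULT_D):
    """Optimal partial assignment between two point sets under a distance cap.

    Maximizes the number of matched pairs at Euclidean distance <= D and,
    among such assignments, minimizes the total distance.  Returns a list of
    (index_a, index_b) pairs.  Implemented as a rectangular assignment with a
    prohibitive cost on capped edges, which realizes the lexicographic
    optimum exactly.
    """
    if D <= 0:
        raise ValueError("distance cap D must be positive")
    if not points_a or not points_b:
        return []
    pa = np.stack([np.asarray(p.coords if isinstance(p, ClassPoint) else p)
                   for p in points_a])
    pb = np.stack([np.asarray(p.coords if isinstance(p, ClassPoint) else p)
                   for p in points_b])
    dist = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    cost = np.where(dist <= D, dist, _BIG)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols)
            if dist[i, j] <= D]


def sequential_match(runs, order, D: float = DEFAULT_D) -> MatchResult:
    """Merge runs one at a time in the given order.

    The pool holds current sets (including still-unmatched singletons from
    earlier runs); at each step the pool's averaged positions are matched
    against the next run's classes.  Averaged positions are weighted by the
    number of constituent classes so every run contributes equally to the
    final average.
    """
    order = tuple(order)
    if len(order) < 2:
        raise ValueError("need at least two runs")
    pool: list[MatchSet] = [
        MatchSet({order[0]: p}, np.asarray(p.coords, dtype=float), p.weight)
        for p in runs[order[0]]
    ]
    for run_id in order[1:]:
        incoming = list(runs[run_id])
        pairs = match_two_sets([s.position for s in pool],
                               [p.coords for p in incoming], D)
        matched_pool = {i for i, _ in pairs}
        matched_new = {j for _, j in pairs}
        for i, j in pairs:
            s, p = pool[i], incoming[j]
            new_w = s.weight + p.weight
            s.position = (s.weight * s.position + p.weight * p.coords) / new_w
            s.weight = new_w
            s.members[run_id] = p
        for j, p in enumerate(incoming):
            if j not in matched_new:
                pool.append(MatchSet({run_id: p},
                                     np.asarray(p.coords, dtype=float),
                                     p.weight))
    sets = [s for s in pool if s.size >= 2]
    unmatched = [next(iter(s.members.values())) for s in pool if s.size == 1]
    return MatchResult(sets, unmatched, order)


def candidate_orders(n_runs: int, prefix: int = 4) -> list[tuple[int, ...]]:
    """All run orders differing in the first ``prefix`` places.

    The remaining runs follow in ascending order, giving
    n*(n-1)*...*(n-prefix+1) orders; with fewer runs than the prefix length,
    all full permutations are enumerated.
    """
    ids = list(range(n_runs))
    if n_runs <= prefix:
        return [tuple(p) for p in itertools.permutations(ids)]
    orders = []
    for head in itertools.permutations(ids, prefix):
        tail = tuple(i for i in ids if i not in head)
        orders.append(head + tail)
    return orders


def order_search(runs, D: float = DEFAULT_D, prefix: int = 4) -> MatchResult:
    """Best sequential match over the enumerated run orders.

    Scored by most matched sets, then smallest average within-set distance,
    then lexicographically smallest order (deterministic)."""
    best: MatchResult | None = None
    for order in candidate_orders(len(runs), prefix):
        res = sequential_match(runs, order, D)
        key = (-res.n_sets, res.average_distance(), res.order)
        if best is None or key < (-best.n_sets, best.average_distance(),
                                  best.order):
            best = res
    assert best is not None
    return best


def position_uncertainty(match_result: MatchResult) -> list[float]:
    """Per-set positional uncertainty, analogous to a standard error:
    RMS member distance to the consensus position over sqrt(set size)."""
    return [s.rms_member_distance() / np.sqrt(s.size)
            for s in match_result.sets]


# ---------------------------------------------------------------------------
# model-level interface

def model_class_points(model: MosaicModel, run: int) -> list[ClassPoint]:
    """One ClassPoint per pair: the canonical member's stationary composition."""
    return [ClassPoint(run, canon,
                       class_coordinates(hmm.class_base_composition(model,
                                                                    canon)))
            for canon, _partner in hmm.pair_states(model)]


def _default_min_runs(n_runs: int) -> int:
    return n_runs // 2 + 1


def average_models(models, match_result: MatchResult,
                   min_runs: int | None = None) -> MosaicModel:
    """Average matched classes into a consensus model.

    Sets covering fewer than ``min_runs`` runs (default: a majority) are
    dropped.  Emissions, initial probabilities and transitions are averaged
    with equal run weighting, partner states are reconstructed by complement
    symmetry and the full symmetry tying is re-imposed.
    """
    if min_runs is None:
        min_runs = _default_min_runs(len(models))
    sets = [s for s in match_result.sets if s.size >= min_runs]
    if not sets:
        raise ValueError(f"no matched set covers >= {min_runs} runs")
    partner_of = [
        {run: int(models[run].pair[p.state]) for run, p in s.members.items()}
        for s in sets
    ]
    # a run's state and its strand partner may not both be averaged as
    # canonical members: the partner's assignment must mirror the state's
    used: set[tuple[int, int]] = set()
    for s, partners in zip(sets, partner_of):
        for run, p in s.members.items():
            if (run, p.state) in used:
                raise ValueError(
                    f"state {p.state} of run {run} appears in two match sets")
            if (run, partners[run]) in used:
                raise ValueError(
                    f"state {p.state} of run {run} is matched separately "
                    "from its strand partner")
            used.add((run, p.state))

    n_sets = len(sets)
    K = 2 * n_sets
    pair = np.arange(K) ^ 1
    E = np.empty((K, 4, 4))
    pi = np.empty(K)
    e0 = np.empty((K, 4))
    for k, s in enumerate(sets):
        Es = np.mean([models[run].E[p.state] for run, p in s.members.items()],
                     axis=0)
        E[2 * k] = Es / Es.sum(axis=1, keepdims=True)
        E[2 * k + 1] = E[2 * k][COMP][:, COMP]
        pi[2 * k] = pi[2 * k + 1] = np.mean(
            [models[run].pi[p.state] for run, p in s.members.items()])
        e0s = np.mean([models[run].e0[p.state]
                       for run, p in s.members.items()], axis=0)
        e0[2 * k] = e0s / e0s.sum()
        e0[2 * k + 1] = e0[2 * k][COMP]
    pi = pi / pi.sum()

    # transitions between consensus states, averaged over runs covering both
    A = np.zeros((K, K))
    counts = np.zeros((K, K))
    state_of = []  # per set: run -> (canonical state, partner state)
    for s, partners in zip(sets, partner_of):
        state_of.append({run: (p.state, partners[run])
                         for run, p in s.members.items()})
    for ki in range(n_sets):
        for kj in range(n_sets):
            shared = set(state_of[ki]) & set(state_of[kj])
            for run in shared:
                Ar = models[run].A
                si = state_of[ki][run]
                sj = state_of[kj][run]
                for a in range(2):
                    for b in range(2):
                        A[2 * ki + a, 2 * kj + b] += Ar[si[a], sj[b]]
                        counts[2 * ki + a, 2 * kj + b] += 1
    if (counts == 0).any():
        # sets with disjoint run coverage: fall back to a uniform small mass
        A[counts == 0] = 1e-6
        counts[counts == 0] = 1
    A = A / counts
    A = A / A.sum(axis=1, keepdims=True)

    consensus = hmm.reimpose_symmetry(MosaicModel(pi, A, E, e0, pair))
    consensus.validate()
    return consensus


def match_replicates(models, D: float = DEFAULT_D, prefix: int = 4,
                     min_runs: int | None = None):
    """Full replicate-reconciliation: coordinates, order search, averaging.

    Returns (consensus model, MatchResult)."""
    runs = [model_class_points(m, r) for r, m in enumerate(models)]
    result = order_search(runs, D=D, prefix=prefix)
    consensus = average_models(models, result, min_runs=min_runs)
    return consensus, result
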