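"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates, at desk scale, the study conditions the pipeline is
built for: a genome emitted by a known strand-symmetric mosaic HMM
(geometric class lengths, class-specific dinucleotide composition, one
CpG-rich pair), motif occurrences planted with a configurable bias toward a
designated "preferred" subset of classes, TSS annotations, and an integer
control-tag-density track.

Default conditions (see docs/methods.md for rationale): four class pairs
with strongly separated compositions, mean lengths 60/150/60/150 so the
preferred pairs 1 and 3 hold about 29% of bases, a base-balanced CpG-free
planted consensus (TGACTCAG) whose occurrence rate therefore tracks base
content across classes, 2000 planted sites at a 75% preferred-placement
rate.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import hmm
from .hmm import C_, G_, MosaicModel, COMP
from .sequence_io import Interval, SeqRecord
from .tfbs import SiteRecord

DEFAULT_COMPOSITIONS = (
    (0.45, 0.05, 0.05, 0.45),   # AT-rich (preferred)
    (0.05, 0.45, 0.45, 0.05),   # GC-rich, CpG-rich
    (0.30, 0.45, 0.05, 0.20),   # C-skewed (preferred)
    (0.45, 0.20, 0.05, 0.30),   # A-skewed
)
DEFAULT_LENGTHS = (200.0, 500.0, 200.0, 500.0)
DEFAULT_CPG = (0.001, 0.10, 0.004, 0.002)


@dataclass
class GeneratorConfig:
    n_pairs: int = 4
    compositions: tuple = DEFAULT_COMPOSITIONS
    mean_lengths: tuple = DEFAULT_LENGTHS
    cpg_proportions: tuple | None = DEFAULT_CPG
    genome_n_seqs: int = 40
    genome_seq_len: int = 100_000
    motif_consensus: str = "TGACTCAG"
    n_sites: int = 2000
    preferred_pairs: tuple = (1, 3)      # 1-based indices into compositions
    p_pref: float = 0.75
    subseq_length: tuple = (200, 500)
    tss_far_fraction: float = 0.85
    tag_lambda_bg: float = 1.0
    tag_lambda_site: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_pref <= 1:
            raise ValueError("p_pref must be in [0, 1]")
        if len(self.compositions) != self.n_pairs:
            raise ValueError("one composition per pair required")
        if len(self.mean_lengths) != self.n_pairs:
            raise ValueError("one mean length per pair required")
        if any(l < 2 for l in self.mean_lengths):
            raise ValueError("mean lengths must be >= 2")


@dataclass
class GroundTruth:
    model: MosaicModel
    paths: list[np.ndarray]            # per sequence, state per position
    site_states: list[int]             # true class of each planted site
    sites: list[SiteRecord]


# ---------------------------------------------------------------------------
# model construction

def _pair_emission(comp: np.ndarray, cpg: float | None) -> np.ndarray:
    """4x4 conditional table with stationary composition ``comp`` and,
    when requested, a CG-doublet frequency of ``cpg``.

    Rows start as the i.i.d. composition; the C row's G entry is pinned to
    cpg / P(C) and a short fixed-point loop restores the stationary
    composition."""
    comp = np.asarray(comp, dtype=float)
    comp = comp / comp.sum()
    v = comp.copy()
    E = np.tile(v, (4, 1))
    for _ in range(200):
        E = np.tile(v, (4, 1))
        if cpg is not None:
            target_cg = cpg / comp[C_]
            if not 0 < target_cg < 1:
                raise ValueError(
                    f"CpG proportion {cpg} infeasible for composition {comp}")
            row = v.copy()
            row[G_] = 0.0
            row = row / row.sum() * (1.0 - target_cg)
            row[G_] = target_cg
            E[C_] = row
        E = E / E.sum(axis=1, keepdims=True)
        stat = hmm._stationary(E, "pair emission")
        if np.abs(stat - comp).max() < 1e-12:
            break
        v = v * comp / stat
        v = v / v.sum()
    return E


def make_model(config: GeneratorConfig) -> MosaicModel:
    """Symmetric-by-construction model realizing the configured per-pair
    compositions, mean lengths and CpG frequencies."""
    K = 2 * config.n_pairs
    pair = np.arange(K) ^ 1
    E = np.empty((K, 4, 4))
    A = np.zeros((K, K))
    cpgs = (config.cpg_proportions
            if config.cpg_proportions is not None else [None] * config.n_pairs)
    for k in range(config.n_pairs):
        E[2 * k] = _pair_emission(np.asarray(config.compositions[k]), cpgs[k])
        E[2 * k + 1] = E[2 * k][COMP][:, COMP]
        a_self = 1.0 - 1.0 / config.mean_lengths[k]
        A[2 * k, 2 * k] = A[2 * k + 1, 2 * k + 1] = a_self
    for s in range(K):
        leave = 1.0 - A[s, s]
        others = [t for t in range(K) if t != s]
        A[s, others] = leave / (K - 1)
    e0 = np.stack([hmm._stationary(E[s], f"emission {s}") for s in range(K)])
    pi = hmm._stationary(A, "transition matrix")
    model = hmm.reimpose_symmetry(MosaicModel(pi, A, E, e0, pair))
    model.validate()
    return model


def preferred_states(config: GeneratorConfig) -> frozenset[int]:
    """State indices of the designated preferred pairs."""
    out = set()
    for p in config.preferred_pairs:
        out.update((2 * (p - 1), 2 * (p - 1) + 1))
    return frozenset(out)


def preferred_pair_indices(model: MosaicModel,
                           config: GeneratorConfig) -> tuple[int, ...]:
    """The preferred pairs' 1-based indices under the model's own ordering
    (descending genome proportion), as used by factor summaries."""
    pref = preferred_states(config)
    rows = hmm.class_summaries(model)
    return tuple(sorted(r.pair_index for r in rows
                        if r.canonical_state in pref))


# ---------------------------------------------------------------------------
# genome generation

def generate_genome(model: MosaicModel, n_seqs: int, seq_len: int, seed=None):
    """Simulate sequences plus true state paths.

    Returns (records, paths): SeqRecord list and per-sequence int arrays.
    """
    rng = np.random.default_rng(seed)
    records, paths = [], []
    for i in range(n_seqs):
        obs, path = hmm.simulate(model, seq_len, seed=rng.integers(2 ** 31))
        records.append(SeqRecord(f"seq{i}", hmm.decode(obs)))
        paths.append(path)
    return records, paths


def run_length_intervals(seq_id: str, path: np.ndarray) -> list[Interval]:
    """Run-length encode a state path as labelled intervals."""
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(path)]])
    return [Interval(seq_id, int(a), int(b), ".", str(int(path[a])))
            for a, b in zip(starts, ends)]


# ---------------------------------------------------------------------------
# site planting

def _eligible_starts(path: np.ndarray, width: int, margin: int,
                     flank: int = 12) -> np.ndarray:
    """Starts where the motif plus ``flank`` bases on each side lie within
    one class run (so the site's true class is unambiguous), away from the
    sequence ends."""
    L = len(path)
    if L < 2 * margin + width:
        return np.empty(0, dtype=np.int64)
    w_ext = width + 2 * flank
    n = L - w_ext + 1
    same = np.ones(n, dtype=bool)
    for j in range(1, w_ext):
        same &= path[j:n + j] == path[:n]
    starts = np.flatnonzero(same) + flank
    keep = (starts >= margin) & (starts <= L - width - margin)
    return starts[keep]


def plant_sites(records, paths, config: GeneratorConfig, model: MosaicModel,
                seed=None):
    """Write the motif consensus into class-chosen positions.

    Each site's class group is Bernoulli(p_pref) preferred; a position whose
    true class is in (resp. out of) the preferred set is chosen uniformly
    among eligible positions (motif fully inside one class run).  A
    subsequence of 200-500 bases is drawn with the site near its middle, and
    a TSS is placed so that about ``tss_far_fraction`` of sites are farther
    than 1500 bases from it.

    Returns (new records, GroundTruth, tss positions per sequence).
    """
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    consensus = config.motif_consensus
    codes = hmm.encode(consensus)
    w = len(codes)
    margin = config.subseq_length[1] + 10
    pref = preferred_states(config)

    groups: dict[bool, list[np.ndarray]] = {True: [], False: []}
    for i, path in enumerate(paths):
        starts = _eligible_starts(path, w, margin)
        in_pref = np.isin(path[starts], list(pref))
        for flag in (True, False):
            sel = starts[in_pref if flag else ~in_pref]
            arr = np.empty((len(sel), 2), dtype=np.int64)
            arr[:, 0] = i
            arr[:, 1] = sel
            groups[flag].append(arr)
    cand = {flag: np.concatenate(groups[flag]) for flag in (True, False)}

    draws = rng.random(config.n_sites) < config.p_pref
    seq_arrays = [hmm.encode(r.sequence) for r in records]
    blocked: dict[int, set[int]] = {}
    sites: list[SiteRecord] = []
    site_states: list[int] = []
    tss_positions: dict[str, list[int]] = {r.id: [] for r in records}

    for flag in (True, False):
        need = int(draws.sum()) if flag else int((~draws).sum())
        pool = cand[flag]
        if len(pool) < need:
            raise ValueError(
                f"only {len(pool)} eligible positions for "
                f"{'preferred' if flag else 'non-preferred'} group, "
                f"need {need}")
        order = rng.permutation(len(pool))
        taken = 0
        for idx in order:
            if taken >= need:
                break
            i, start = int(pool[idx, 0]), int(pool[idx, 1])
            occupied = blocked.setdefault(i, set())
            span = range(start - w, start + w)
            if any(p in occupied for p in span):
                continue
            occupied.update(span)
            taken += 1
            state = int(paths[i][start])
            strand = "+" if rng.random() < 0.5 else "-"
            word = codes if strand == "+" else codes[::-1].copy()
            if strand == "-":
                word = COMP[word.astype(np.int64)].astype(np.int8)
            seq_arrays[i][start:start + w] = word

            sub_len = int(rng.integers(config.subseq_length[0],
                                       config.subseq_length[1] + 1))
            mid = start + w // 2
            center = sub_len // 2
            jitter = int(rng.normal(0, sub_len * 0.08))
            sub_start = mid - center + jitter
            sub_start = max(0, min(sub_start, len(paths[i]) - sub_len))
            site = SiteRecord(
                factor="synthetic",
                subsequence=Interval(records[i].id, sub_start,
                                     sub_start + sub_len),
                motif_start=start, motif_end=start + w, strand=strand)
            far = rng.random() < config.tss_far_fraction
            dist = (int(rng.integers(1501, 50_000)) if far
                    else int(rng.integers(0, 1501)))
            site.tss_distance = float(dist)
            tss = mid + dist * (1 if rng.random() < 0.5 else -1)
            tss_positions[records[i].id].append(
                int(np.clip(tss, 0, len(paths[i]) - 1)))
            sites.append(site)
            site_states.append(state)
        if taken < need:
            raise ValueError(f"could not place {need} non-overlapping sites "
                             f"({taken} placed)")

    new_records = [SeqRecord(r.id, hmm.decode(arr))
                   for r, arr in zip(records, seq_arrays)]
    truth = GroundTruth(model, paths, site_states, sites)
    return new_records, truth, tss_positions


# ---------------------------------------------------------------------------
# control-tag track

def make_control_track(records, sites=None, lambda_bg: float = 1.0,
                       lambda_site: float | None = None, seed=None,
                       halfwidth: int = 100) -> dict[str, np.ndarray]:
    """Integer tag-density track: Poisson(lambda_bg) background, optionally
    Poisson(lambda_site) in site neighbourhoods (emulating the enrichment of
    control libraries near bound regions)."""
    rng = np.random.default_rng(seed)
    track = {r.id: rng.poisson(lambda_bg, size=len(r.sequence))
             for r in records}
    if sites is not None and lambda_site is not None \
            and lambda_site != lambda_bg:
        for s in sites:
            arr = track[s.subsequence.seq_id]
            a = max(0, s.motif_start - halfwidth)
            b = min(len(arr), s.motif_end + halfwidth)
            arr[a:b] = rng.poisson(lambda_site, size=b - a)
    return track


def annotate_tag_density(sites, track: dict[str, np.ndarray]) -> None:
    for s in sites:
        arr = track[s.subsequence.seq_id]
        mid = (s.motif_start + s.motif_end) // 2
        s.control_tag_density = int(arr[mid])


# ---------------------------------------------------------------------------
# replicate-training harness

def train_replicates(truth: MosaicModel, n_replicates: int = 8,
                     n_seqs: int = 200, seq_len: int = 2000,
                     n_pairs: int | None = None, seed: int = 0,
                     tol: float = 1e-4, max_iter: int = 60,
                     n_restarts: int = 3):
    """Train several models from scratch on fresh simulations of the truth.

    Each replicate gets its own training sequences; within a replicate,
    ``n_restarts`` random initializations are trained and the best final
    log-likelihood kept (Baum-Welch is multimodal; a lost class is a
    genuinely worse optimum, so likelihood selects against it).  Returns
    (models, iteration logs, all training sequences)."""
    rng = np.random.default_rng(seed)
    if n_pairs is None:
        n_pairs = truth.n_pairs
    models, logs, data = [], [], []
    for _ in range(n_replicates):
        seqs = [hmm.simulate(truth, seq_len, seed=rng.integers(2 ** 31))[0]
                for _ in range(n_seqs)]
        data.extend(seqs)
        best = None
        for _r in range(n_restarts):
            init = hmm.random_initial_model(n_pairs, seqs,
                                            seed=rng.integers(2 ** 31))
            model, log = hmm.em_train(init, seqs, tol=tol, max_iter=max_iter)
            if best is None or log[-1].log_likelihood > best[1][-1].log_likelihood:
                best = (model, log)
        models.append(best[0])
        logs.append(best[1])
    return models, logs, data


def consensus_training(truth: MosaicModel, n_replicates: int = 8,
                       n_seqs: int = 200, seq_len: int = 2000,
                       seed: int = 0, D: float = 0.12,
                       min_runs: int | None = None, tol: float = 1e-4,
                       max_iter: int = 60, n_restarts: int = 3,
                       final_max_iter: int = 30):
    """The full replication protocol against a known generating model.

    Replicate trainings on fresh data, class matching across the runs,
    parameter averaging, and a final training round (initialized from the
    consensus) on the pooled sequences of all replicates.  Returns
    (final model, consensus model, MatchResult, per-replicate logs).
    """
    from . import matching
    models, logs, data = train_replicates(
        truth, n_replicates=n_replicates, n_seqs=n_seqs, seq_len=seq_len,
        seed=seed, tol=tol, max_iter=max_iter, n_restarts=n_restarts)
    consensus, result = matching.match_replicates(models, D=D,
                                                  min_runs=min_runs)
    final, final_log = hmm.em_train(consensus, data, tol=tol,
                                    max_iter=final_max_iter)
    logs = logs + [final_log]
    return final, consensus, result, logs
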