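"""Binding-site class analysis.

Given a trained mosaic model, a genome, and per-factor binding-site
coordinates, this module assigns each site a per-class probability vector by
posterior (expectation-step) decoding of a window centred on the motif,
aggregates the vectors into per-pair proportions for each factor, and
implements the supporting analyses: subsequence preprocessing filters, the
near/far TSS split, the low-control-tag subset, the within-subsequence
position histogram, and posterior-weighted class composition of arbitrary
regions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import hmm
from .hmm import MosaicModel
from .sequence_io import Interval

DEFAULT_WINDOW = 4000
TSS_THRESHOLD = 1500


@dataclass
class SiteRecord:
    """One binding site and its per-class posterior."""

    factor: str
    subsequence: Interval
    motif_start: int                  # genome coordinates, 0-based
    motif_end: int
    strand: str = "."
    tss_distance: float | None = None   # unsigned bases to nearest TSS
    control_tag_density: int | None = None
    class_posterior: np.ndarray | None = None   # (K,)

    @property
    def relative_position(self) -> float:
        """min(distance to either subsequence end) / subsequence length,
        measured from the motif midpoint; in [0, 0.5]."""
        mid = 0.5 * (self.motif_start + self.motif_end)
        sub = self.subsequence
        d = min(mid - sub.start, sub.end - mid)
        return max(0.0, d / sub.length)


@dataclass
class FactorSummary:
    factor: str
    n_sites: int
    pair_proportions: np.ndarray      # (n_pairs,), ordered by pair index
    preferred_pairs: tuple[int, ...]  # 1-based pair indices
    bookkeeping: float | None = None  # P/Q pass-through column

    @property
    def preferred_total(self) -> float:
        return float(sum(self.pair_proportions[p - 1]
                         for p in self.preferred_pairs))


def pair_index_map(model: MosaicModel) -> np.ndarray:
    """state -> 0-based pair index, pairs ordered by descending genome share
    (the same ordering class summaries use)."""
    rows = hmm.class_summaries(model)
    out = np.empty(model.K, dtype=np.int64)
    for row in rows:
        out[row.canonical_state] = row.pair_index - 1
        out[row.partner_state] = row.pair_index - 1
    return out


def aggregate_to_pairs(posterior: np.ndarray, pair_map: np.ndarray) -> np.ndarray:
    n_pairs = int(pair_map.max()) + 1
    out = np.zeros(posterior.shape[:-1] + (n_pairs,))
    for s, p in enumerate(pair_map):
        out[..., p] += posterior[..., s]
    return out


# ---------------------------------------------------------------------------
# preprocessing

@dataclass
class FilterLog:
    n_input: int
    n_subsampled: int
    n_length_excluded: int
    n_extended: int
    n_mask_excluded: int
    n_output: int


def preprocess_subsequences(intervals, masked_fractions=None,
                            target_n: int = 5000, max_length: int = 700,
                            min_length: int = 30, extension: int = 15,
                            max_masked: float = 0.25):
    """Apply the standard subsequence filters.

    Datasets larger than ``target_n`` are thinned to about that many by
    even deterministic striding over coordinate-sorted records; sequences
    longer than ``max_length`` are dropped; sequences shorter than
    ``min_length`` are extended by ``extension`` bases on each side; records
    with more than ``max_masked`` of their bases masked are dropped.
    Returns (filtered intervals, FilterLog).
    """
    items = list(intervals)
    n_input = len(items)
    order = sorted(range(n_input),
                   key=lambda i: (items[i].seq_id, items[i].start))
    if masked_fractions is not None and len(masked_fractions) != n_input:
        raise ValueError("masked_fractions must align with intervals")
    if n_input > target_n:
        keep = np.unique(np.linspace(0, n_input - 1, target_n).round()
                         .astype(int))
    else:
        keep = np.arange(n_input)
    n_sub = len(keep)
    out = []
    n_long = n_ext = n_mask = 0
    for pos in keep:
        i = order[pos]
        iv = items[i]
        if masked_fractions is not None and masked_fractions[i] > max_masked:
            n_mask += 1
            continue
        if iv.length > max_length:
            n_long += 1
            continue
        if iv.length < min_length:
            iv = Interval(iv.seq_id, max(0, iv.start - extension),
                          iv.end + extension, iv.strand, iv.label)
            n_ext += 1
        out.append(iv)
    return out, FilterLog(n_input, n_sub, n_long, n_ext, n_mask, len(out))


# ---------------------------------------------------------------------------
# windowed class assignment

def extract_window(genome: dict[str, str], seq_id: str, motif_start: int,
                   motif_end: int, window: int = DEFAULT_WINDOW):
    """Window of about ``window`` bases with the motif in the middle.

    The window spans [mid - window//2, mid + window//2 + width) where
    mid is the integer motif midpoint, so the motif sits centrally and the
    full span is window + motif width in the interior.  Near sequence ends
    the window is truncated and flagged.  Returns
    (sequence, window_start, motif_offset, truncated).
    """
    seq = genome[seq_id]
    if not (0 <= motif_start < motif_end <= len(seq)):
        raise ValueError(f"motif span {motif_start}-{motif_end} outside "
                         f"{seq_id} (length {len(seq)})")
    half = window // 2
    left = motif_start - half
    right = motif_end + half
    truncated = left < 0 or right > len(seq)
    left_c = max(0, left)
    right_c = min(len(seq), right)
    return seq[left_c:right_c], left_c, motif_start - left_c, truncated


def assign_site_classes(model: MosaicModel, window_seq: str, motif_offset: int,
                        motif_length: int, decoder: str = "posterior"
                        ) -> np.ndarray:
    """Per-class probability vector for one site.

    ``posterior`` averages the forward-backward state posterior over the
    motif's positions (the expectation-step assignment); ``viterbi`` returns
    the indicator average of the decoded path over the same span.
    """
    if motif_offset < 0 or motif_offset + motif_length > len(window_seq):
        raise ValueError("motif span outside window")
    span = slice(motif_offset, motif_offset + motif_length)
    if decoder == "posterior":
        post = hmm.forward_backward(model, window_seq)
        return post.gamma[span].mean(axis=0)
    if decoder == "viterbi":
        path = hmm.viterbi(model, window_seq)
        out = np.zeros(model.K)
        for s in path[span]:
            out[s] += 1
        return out / out.sum()
    raise ValueError(f"unknown decoder {decoder!r}")


def assign_sites(model: MosaicModel, genome: dict[str, str], sites,
                 window: int = DEFAULT_WINDOW, decoder: str = "posterior",
                 chunk: int = 128) -> list["SiteRecord"]:
    """Posterior class vectors for many sites, batched for speed.

    Sites sharing a window length are decoded together; each site's
    ``class_posterior`` is filled in place and the list returned.
    """
    prepared = []
    for site in sites:
        seq, start, off, _trunc = extract_window(
            genome, site.subsequence.seq_id, site.motif_start,
            site.motif_end, window)
        prepared.append((site, seq, off, site.motif_end - site.motif_start))
    if decoder == "viterbi":
        for site, seq, off, mlen in prepared:
            site.class_posterior = assign_site_classes(model, seq, off, mlen,
                                                       decoder="viterbi")
        return [p[0] for p in prepared]
    # batch windows of equal length; reduce each batch's posteriors to the
    # motif-span means immediately to bound memory
    by_len: dict[int, list[int]] = {}
    for i, (_s, seq, _o, _m) in enumerate(prepared):
        by_len.setdefault(len(seq), []).append(i)
    for idxs in by_len.values():
        for j in range(0, len(idxs), chunk):
            sel = idxs[j:j + chunk]
            obs = np.stack([hmm.encode(prepared[i][1]) for i in sel])
            gamma, _ll = hmm._posterior_batch(model, obs)
            for k, i in enumerate(sel):
                site, _seq, off, mlen = prepared[i]
                site.class_posterior = gamma[k, off:off + mlen].mean(axis=0)
    return [p[0] for p in prepared]


# ---------------------------------------------------------------------------
# aggregation

def summarize_factor(sites, model: MosaicModel,
                     preferred_pairs=(2, 7, 9, 14), factor: str | None = None,
                     bookkeeping: float | None = None) -> FactorSummary:
    """Mean of site posteriors aggregated to class pairs."""
    sites = list(sites)
    if not sites:
        raise ValueError("no sites to summarize")
    pmap = pair_index_map(model)
    mat = np.stack([s.class_posterior for s in sites])
    pair_props = aggregate_to_pairs(mat.mean(axis=0), pmap)
    name = factor if factor is not None else sites[0].factor
    preferred = tuple(p for p in preferred_pairs if p <= len(pair_props))
    return FactorSummary(name, len(sites), pair_props, preferred, bookkeeping)


def split_by_tss(sites, model: MosaicModel, threshold: int = TSS_THRESHOLD,
                 preferred_pairs=(2, 7, 9, 14)):
    """(far summary, near summary, Q) with Q = fraction of sites farther than
    the threshold from the nearest TSS."""
    sites = list(sites)
    missing = [i for i, s in enumerate(sites) if s.tss_distance is None]
    if missing:
        raise ValueError(f"sites without TSS annotation at indices {missing}")
    far = [s for s in sites if s.tss_distance > threshold]
    near = [s for s in sites if s.tss_distance <= threshold]
    q = len(far) / len(sites)
    far_sum = (summarize_factor(far, model, preferred_pairs,
                                bookkeeping=q) if far else None)
    near_sum = (summarize_factor(near, model, preferred_pairs,
                                 bookkeeping=1 - q) if near else None)
    return far_sum, near_sum, q


def low_tag_subset(sites, control_track: dict[str, np.ndarray],
                   reference_id: str, n_samples: int = 10_000, seed=None):
    """Subset of sites in low control-tag-density regions.

    M is the median tag density of ``n_samples`` random positions on the
    designated reference sequence; a site is kept when its density is zero
    or strictly below M.  Returns (subset, M, ratio kept).
    """
    track = np.asarray(control_track[reference_id])
    if track.size == 0:
        raise ValueError("empty control track")
    rng = np.random.default_rng(seed)
    positions = rng.integers(0, track.size, size=n_samples)
    m = float(np.median(track[positions]))
    subset = [s for s in sites
              if s.control_tag_density == 0 or s.control_tag_density < m]
    ratio = len(subset) / len(list(sites)) if sites else 0.0
    return subset, m, ratio


def relative_positions(datasets, n_bins: int = 25):
    """Average histogram of within-subsequence site positions.

    ``datasets`` is an iterable of site lists; each dataset's histogram of
    p = (bases to the nearer subsequence end) / length, binned on [0, 0.5],
    is density-normalized and the histograms averaged with equal dataset
    weight.  Returns (bin edges, mean heights)."""
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    hists = []
    for sites in datasets:
        p = np.array([s.relative_position for s in sites])
        h, _ = np.histogram(p, bins=edges, density=True)
        hists.append(h)
    return edges, np.mean(hists, axis=0)


def region_class_composition(model: MosaicModel, genome: dict[str, str],
                             regions, chunk: int = 64) -> np.ndarray:
    """Posterior-weighted per-pair base proportions of a region set.

    Computed for each region separately, then averaged with equal region
    weight regardless of region lengths."""
    pmap = pair_index_map(model)
    seqs = []
    for iv in regions:
        seq = genome[iv.seq_id][iv.start:iv.end]
        if len(seq) != iv.length:
            raise ValueError(f"region {iv.seq_id}:{iv.start}-{iv.end} not "
                             "resolvable")
        seqs.append(seq)
    posts = hmm.posterior_windows(model, seqs, chunk=chunk)
    per_region = np.stack([aggregate_to_pairs(p.gamma.mean(axis=0), pmap)
                           for p in posts])
    return per_region.mean(axis=0)
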