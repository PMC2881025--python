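"""Cross-replicate class matching: coordinates, optimal assignment under a
distance cap, sequential merging, order search, consensus averaging."""
import itertools

import numpy as np
import pytest

from mosaic import hmm, matching
from mosaic.matching import ClassPoint

from conftest import random_symmetric_model


def brute_force_match(pa, pb, D):
    """Exhaustive search over all partial injections a->b."""
    best = (0, 0.0, [])
    na, nb = len(pa), len(pb)
    for k in range(min(na, nb), -1, -1):
        found = None
        for rows in itertools.combinations(range(na), k):
            for cols in itertools.permutations(range(nb), k):
                d = [np.linalg.norm(np.asarray(pa[i]) - np.asarray(pb[j]))
                     for i, j in zip(rows, cols)]
                if all(x <= D for x in d):
                    tot = sum(d)
                    if found is None or tot < found[0]:
                        found = (tot, list(zip(rows, cols)))
        if found:
            return k, found[0], found[1]
    return 0, 0.0, []


class TestCoordinates:
    def test_uniform_composition_center(self):
        np.testing.assert_allclose(
            matching.class_coordinates([0.25] * 4), [0.5, 0.5, 0.5])

    def test_a_rich_class_and_its_complement(self):
        # a class with 40% A, 20% each C/G/T, and its reverse-complement image
        h = matching.class_coordinates([0.4, 0.2, 0.2, 0.2])
        k = matching.class_coordinates([0.2, 0.2, 0.2, 0.4])
        np.testing.assert_allclose(h, [0.6, 0.4, 0.4])
        np.testing.assert_allclose(k, [0.6, 0.6, 0.6])
        # mirrored through 0.5 in the second and third coordinates
        np.testing.assert_allclose(h[1:], 1.0 - k[1:])


class TestMatchTwoSets:
    def test_identical_sets_identity_match(self):
        pts = [np.array([0.1, 0.2, 0.3]), np.array([0.5, 0.5, 0.5])]
        assert matching.match_two_sets(pts, pts, 0.12) == [(0, 0), (1, 1)]

    def test_cap_blocks_distant_points(self):
        a = [np.array([0.0, 0.0, 0.0])]
        b = [np.array([1.0, 1.0, 1.0])]
        assert matching.match_two_sets(a, b, 0.12) == []

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(2, 5, size=2)
        pa = [rng.random(3) * 0.4 for _ in range(na)]
        pb = [rng.random(3) * 0.4 for _ in range(nb)]
        D = 0.2
        got = matching.match_two_sets(pa, pb, D)
        k, tot, _ = brute_force_match(pa, pb, D)
        assert len(got) == k
        got_tot = sum(np.linalg.norm(np.asarray(pa[i]) - np.asarray(pb[j]))
                      for i, j in got)
        assert got_tot == pytest.approx(tot, abs=1e-9)


class TestSequentialMatch:
    def _runs(self, positions):
        return [[ClassPoint(r, s, np.asarray(p, dtype=float))
                 for s, p in enumerate(run)]
                for r, run in enumerate(positions)]

    def test_identical_runs_full_sets(self):
        base = [[0.1, 0.1, 0.1], [0.4, 0.4, 0.4]]
        runs = self._runs([base] * 3)
        res = matching.sequential_match(runs, (0, 1, 2), 0.12)
        assert res.n_sets == 2
        assert all(s.size == 3 for s in res.sets)
        assert res.average_distance() == pytest.approx(0.0)

    def test_class_absent_from_middle_run_still_matches(self):
        # a class present only in runs 0 and 2 survives as a singleton in
        # the pool at step 1 and is matched at step 2
        runs = self._runs([
            [[0.1, 0.1, 0.1], [0.8, 0.8, 0.8]],
            [[0.1, 0.1, 0.1]],
            [[0.1, 0.1, 0.1], [0.8, 0.8, 0.8]],
        ])
        res = matching.sequential_match(runs, (0, 1, 2), 0.12)
        sizes = sorted(s.size for s in res.sets)
        assert sizes == [2, 3]

    def test_weighted_average_position(self):
        # merging a size-3 set with a singleton: (3*old + new) / 4
        runs = self._runs([
            [[0.10, 0.1, 0.1]], [[0.10, 0.1, 0.1]], [[0.10, 0.1, 0.1]],
            [[0.18, 0.1, 0.1]],
        ])
        res = matching.sequential_match(runs, (0, 1, 2, 3), 0.12)
        assert res.n_sets == 1
        np.testing.assert_allclose(res.sets[0].position,
                                   [(3 * 0.10 + 0.18) / 4, 0.1, 0.1])


class TestOrderSearch:
    def test_order_count_for_eight_runs(self):
        assert len(matching.candidate_orders(8)) == 8 * 7 * 6 * 5

    def test_few_runs_enumerate_all_permutations(self):
        assert len(matching.candidate_orders(3)) == 6

    def test_identical_runs_invariant(self):
        pts = [[0.1, 0.1, 0.1], [0.5, 0.5, 0.5]]
        runs = [[ClassPoint(r, s, np.asarray(p)) for s, p in enumerate(pts)]
                for r in range(4)]
        res = matching.order_search(runs, 0.12)
        assert res.n_sets == 2
        assert all(s.size == 4 for s in res.sets)

    def test_search_finds_order_dependent_maximum(self):
        # run 1's point bridges runs 0 and 2: order determines whether the
        # chain merges into one set of 3 or splits
        D = 0.12
        runs = [
            [ClassPoint(0, 0, np.array([0.00, 0.0, 0.0]))],
            [ClassPoint(1, 0, np.array([0.11, 0.0, 0.0]))],
            [ClassPoint(2, 0, np.array([0.22, 0.0, 0.0]))],
        ]
        # order (0,2,1): 0 vs 2 distance 0.22 > D -> two singletons; then 1
        # joins one of them -> one set of 2
        res_bad = matching.sequential_match(runs, (0, 2, 1), D)
        # order (0,1,2): 0+1 merge at 0.055, then 2 at distance 0.165 > D
        # -> one set of 2.  order search must do at least as well
        best = matching.order_search(runs, D)
        assert best.n_sets >= res_bad.n_sets
        all_orders = [matching.sequential_match(runs, o, D).n_sets
                      for o in matching.candidate_orders(3)]
        assert best.n_sets == max(all_orders)


class TestPositionUncertainty:
    def test_identical_members_zero_radius(self):
        runs = [[ClassPoint(r, 0, np.array([0.2, 0.2, 0.2]))]
                for r in range(4)]
        res = matching.sequential_match(runs, (0, 1, 2, 3), 0.12)
        assert matching.position_uncertainty(res) == [pytest.approx(0.0)]

    def test_two_points_closed_form(self):
        d = 0.1
        runs = [[ClassPoint(0, 0, np.array([0.0, 0.0, 0.0]))],
                [ClassPoint(1, 0, np.array([d, 0.0, 0.0]))]]
        res = matching.sequential_match(runs, (0, 1), 0.2)
        # RMS distance from midpoint = d/2; radius = d / (2 sqrt 2)
        assert matching.position_uncertainty(res)[0] == \
               pytest.approx(d / (2 * np.sqrt(2)))

    def test_four_points_at_common_radius(self):
        r = 0.05
        pts = [[r, 0, 0], [-r, 0, 0], [0, r, 0], [0, -r, 0]]
        runs = [[ClassPoint(i, 0, np.array(p) + 0.5)] for i, p in enumerate(pts)]
        res = matching.sequential_match(runs, (0, 1, 2, 3), 0.2)
        assert res.n_sets == 1
        assert matching.position_uncertainty(res)[0] == pytest.approx(r / 2)


class TestAverageModels:
    def test_identical_models_consensus_identity(self, rng):
        m = random_symmetric_model(2, rng)
        models = [m.copy() for _ in range(3)]
        consensus, result = matching.match_replicates(models, D=0.12)
        assert consensus.n_pairs == 2
        # consensus classes carry the same emissions (up to pair relabeling)
        ps_m = hmm.pair_states(m)
        ps_c = hmm.pair_states(consensus)
        pts_m = matching.model_class_points(m, 0)
        pts_c = matching.model_class_points(consensus, 1)
        pairs = matching.match_two_sets(pts_m, pts_c, 0.01)
        assert len(pairs) == 2
        for i, j in pairs:
            np.testing.assert_allclose(m.E[ps_m[i][0]],
                                       consensus.E[ps_c[j][0]], atol=1e-9)

    def test_epsilon_perturbation_averaged_to_midpoint(self, rng):
        m = random_symmetric_model(1, rng)
        eps = 0.004
        hi, lo = m.copy(), m.copy()
        hi.E[0, 0, 0] += eps
        hi.E[0, 0, 1] -= eps
        lo.E[0, 0, 0] -= eps
        lo.E[0, 0, 1] += eps
        hi = hmm.reimpose_symmetry(hi)
        lo = hmm.reimpose_symmetry(lo)
        consensus, _ = matching.match_replicates([hi, lo], D=0.12)
        ps_m = hmm.pair_states(m)
        ps_c = hmm.pair_states(consensus)
        np.testing.assert_allclose(consensus.E[ps_c[0][0]], m.E[ps_m[0][0]],
                                   atol=1e-9)

    def test_consensus_satisfies_symmetry(self, rng):
        models = [random_symmetric_model(2, np.random.default_rng(s))
                  for s in (1, 2, 3)]
        # force comparable compositions so everything matches: use copies
        m = models[0]
        consensus, _ = matching.match_replicates([m.copy(), m.copy(),
                                                  m.copy()], D=0.12)
        consensus.validate(symmetry=True)

    def test_spurious_class_dropped_by_min_runs(self):
        # 4 runs share two classes; two runs carry an extra spurious class
        common = [[0.2, 0.6, 0.4], [0.7, 0.7, 0.6]]
        rng_pts = []
        for r in range(4):
            pts = [ClassPoint(r, s, np.asarray(p)) for s, p in enumerate(common)]
            if r < 2:
                pts.append(ClassPoint(r, 2, np.array([0.45, 0.55, 0.5])))
            rng_pts.append(pts)
        res = matching.order_search(rng_pts, 0.12)
        big = [s for s in res.sets if s.size >= 3]
        small = [s for s in res.sets if s.size < 3]
        assert len(big) == 2
        assert len(small) == 1
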