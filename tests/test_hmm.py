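"""Core HMM: likelihood, decoding, symmetry tying, stationary summaries, EM."""
import numpy as np
import pytest

from mosaic import hmm
from mosaic.hmm import MosaicModel, ModelError

from conftest import brute_force_posterior, random_model, random_symmetric_model


def uniform_model(K: int = 2) -> MosaicModel:
    return MosaicModel(np.full(K, 1 / K), np.full((K, K), 1 / K),
                       np.full((K, 4, 4), 0.25), np.full((K, 4), 0.25),
                       np.arange(K) ^ 1)


class TestLikelihoodAndDecoding:
    def test_uniform_model_closed_form(self):
        m = uniform_model()
        assert hmm.log_likelihood(m, "ACG") == pytest.approx(np.log(1 / 64))

    def test_length_one_closed_form(self, rng):
        m = random_model(4, rng)
        expected = np.log(np.sum(m.pi * m.e0[:, 0]))
        assert hmm.log_likelihood(m, "A") == pytest.approx(expected)

    @pytest.mark.parametrize("K,L,seed", [(2, 8, 0), (3, 6, 1), (4, 5, 2)])
    def test_matches_exhaustive_enumeration(self, K, L, seed):
        rng = np.random.default_rng(seed)
        m = random_model(K, rng)
        seq = "".join(rng.choice(list("ACGT"), L))
        ll, post, best = brute_force_posterior(m, seq)
        assert hmm.log_likelihood(m, seq) == pytest.approx(ll, abs=1e-10)
        fb = hmm.forward_backward(m, seq)
        assert fb.log_likelihood == pytest.approx(ll, abs=1e-10)
        np.testing.assert_allclose(fb.gamma, post, atol=1e-10)
        np.testing.assert_array_equal(hmm.viterbi(m, seq), best)

    def test_posterior_rows_sum_to_one(self, rng):
        m = random_model(4, rng)
        seq = "".join(rng.choice(list("ACGT"), 300))
        fb = hmm.forward_backward(m, seq)
        np.testing.assert_allclose(fb.gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_single_state_pair_posterior_degenerate(self):
        m = uniform_model(2)
        fb = hmm.forward_backward(m, "ACGTAC")
        np.testing.assert_allclose(fb.gamma, 0.5)  # states indistinguishable

    def test_long_sequence_stays_finite(self, rng):
        m = random_symmetric_model(2, rng)
        obs, _ = hmm.simulate(m, 200_000, seed=1)
        ll = hmm.log_likelihood(m, obs)
        assert np.isfinite(ll) and ll < 0

    def test_viterbi_beats_sampled_paths(self):
        rng = np.random.default_rng(5)
        m = random_model(3, rng)
        seq = "".join(rng.choice(list("ACGT"), 40))
        obs = hmm.encode(seq)

        def joint_logp(path):
            lp = np.log(m.pi[path[0]] * m.e0[path[0], obs[0]])
            for t in range(1, len(obs)):
                lp += np.log(m.A[path[t - 1], path[t]]
                             * m.E[path[t], obs[t - 1], obs[t]])
            return lp

        best = joint_logp(hmm.viterbi(m, seq))
        for _ in range(50):
            assert best >= joint_logp(rng.integers(0, 3, len(obs))) - 1e-12

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            hmm.log_likelihood(uniform_model(), "")

    def test_n_positions_contribute_factor_one(self, rng):
        m = random_model(2, rng)
        # trailing N adds nothing; N resets conditioning to e0
        assert hmm.log_likelihood(m, "AN") == pytest.approx(
            hmm.log_likelihood(m, "A"))
        # a fully masked sequence carries no information at all
        assert hmm.log_likelihood(m, "NNNN") == pytest.approx(0.0)


class TestSymmetry:
    def test_reimpose_is_idempotent_and_fixed_point(self, rng):
        m = random_model(4, rng)
        s1 = hmm.reimpose_symmetry(m)
        s2 = hmm.reimpose_symmetry(s1)
        assert hmm.is_symmetric(s1)
        np.testing.assert_allclose(s1.E, s2.E, atol=1e-12)
        np.testing.assert_allclose(s1.A, s2.A, atol=1e-12)

    def test_perturbation_restored_to_midpoint(self, rng):
        m = random_symmetric_model(2, rng)
        eps = 0.01
        p = m.copy()
        p.E[0, 0, 0] += eps
        p.E[int(p.pair[0]), 3, 3] -= eps   # partner entry, complement indices
        fixed = hmm.reimpose_symmetry(p)
        # both tied entries land at the common average, then renormalized
        a = fixed.E[0, 0, 0]
        b = fixed.E[int(p.pair[0]), 3, 3]
        assert a == pytest.approx(b, abs=1e-12)

    def test_validate_rejects_asymmetric(self, rng):
        m = random_symmetric_model(2, rng)
        m.E[0, 0, 0] += 0.05
        m.E[0, 0] /= m.E[0, 0].sum()
        with pytest.raises(ModelError):
            m.validate(symmetry=True)

    def test_paired_states_complementary_composition(self, rng):
        m = random_symmetric_model(3, rng)
        for s in range(m.K):
            ca = hmm.class_base_composition(m, s)
            cb = hmm.class_base_composition(m, int(m.pair[s]))
            np.testing.assert_allclose(ca, cb[hmm.COMP], atol=1e-9)

    def test_paired_states_equal_stationary_mass(self, rng):
        m = random_symmetric_model(3, rng)
        ss = hmm.steady_state(m)
        np.testing.assert_allclose(ss, ss[m.pair], atol=1e-9)


class TestStationarySummaries:
    def test_two_state_symmetric_steady_state(self):
        m = uniform_model(2)
        m.A = np.array([[0.9, 0.1], [0.1, 0.9]])
        np.testing.assert_allclose(hmm.steady_state(m), [0.5, 0.5])

    def test_steady_state_matches_power_iteration(self, rng):
        A = rng.dirichlet(np.ones(5), size=5)
        m = MosaicModel(np.full(5, 0.2), A, np.full((5, 4, 4), 0.25),
                        np.full((5, 4), 0.25), np.array([1, 0, 3, 2, 4]))
        power = np.linalg.matrix_power(A, 1000)[0]
        np.testing.assert_allclose(hmm.steady_state(m), power, atol=1e-10)

    def test_reducible_chain_reports_blocks(self):
        m = uniform_model(2)
        m.A = np.eye(2)
        with pytest.raises(ModelError, match="reducible"):
            hmm.steady_state(m)

    @pytest.mark.parametrize("self_p,expected", [(0.0, 1.0), (0.9, 10.0),
                                                 (1 - 1 / 504.7, 504.7)])
    def test_expected_class_length_closed_form(self, self_p, expected):
        m = uniform_model(2)
        m.A = np.array([[self_p, 1 - self_p], [1 - self_p, self_p]])
        assert hmm.expected_class_length(m, 0) == pytest.approx(expected)

    def test_absorbing_state_rejected(self):
        m = uniform_model(2)
        m.A = np.array([[1.0, 0.0], [0.5, 0.5]])
        with pytest.raises(ModelError):
            hmm.expected_class_length(m, 0)

    def test_uniform_emission_composition(self):
        m = uniform_model(2)
        np.testing.assert_allclose(hmm.class_base_composition(m, 0),
                                   np.full(4, 0.25))

    def test_composition_and_cpg_match_simulation(self, rng):
        m = random_symmetric_model(1, rng)
        clamped_pi = np.array([1.0, 0.0])
        clamp = MosaicModel(clamped_pi, np.array([[1 - 1e-12, 1e-12],
                                                  [1e-12, 1 - 1e-12]]),
                            m.E, m.e0, m.pair)
        obs, _ = hmm.simulate(clamp, 300_000, seed=3)
        emp = np.bincount(obs, minlength=4)[:4] / len(obs)
        np.testing.assert_allclose(hmm.class_base_composition(m, 0), emp,
                                   atol=0.005)
        cg = np.mean((obs[:-1] == hmm.C_) & (obs[1:] == hmm.G_))
        assert hmm.cpg_proportion(m, 0) == pytest.approx(cg, abs=0.002)

    def test_cpg_closed_form(self):
        m = uniform_model(2)
        m.E[0, hmm.C_] = np.array([0.2, 0.2, 0.5, 0.1])
        # composition solves the stationary equation; check the product form
        comp = hmm.class_base_composition(m, 0)
        assert hmm.cpg_proportion(m, 0) == pytest.approx(comp[hmm.C_] * 0.5)

    def test_class_summaries_sorted_and_complete(self, rng):
        m = random_symmetric_model(3, rng)
        rows = hmm.class_summaries(m)
        assert len(rows) == 3
        props = [r.genome_proportion for r in rows]
        assert props == sorted(props, reverse=True)
        assert sum(props) == pytest.approx(1.0)
        for r in rows:
            assert r.composition.sum() == pytest.approx(1.0)
            assert r.mean_length >= 1.0


class TestSimulate:
    def test_deterministic_emission(self):
        K = 2
        E = np.zeros((K, 4, 4))
        E[:, :, hmm.T_] = 1.0
        e0 = np.zeros((K, 4))
        e0[:, hmm.T_] = 1.0
        m = MosaicModel(np.array([0.5, 0.5]), np.full((2, 2), 0.5), E, e0,
                        np.array([1, 0]))
        obs, _ = hmm.simulate(m, 5, seed=0)
        assert hmm.decode(obs) == "TTTTT"

    def test_same_seed_reproducible(self, rng):
        m = random_symmetric_model(2, rng)
        a = hmm.simulate(m, 1000, seed=42)
        b = hmm.simulate(m, 1000, seed=42)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_occupancy_matches_steady_state(self, rng):
        m = random_symmetric_model(2, rng)
        _, path = hmm.simulate(m, 400_000, seed=9)
        occ = np.bincount(path, minlength=m.K) / len(path)
        np.testing.assert_allclose(occ, hmm.steady_state(m), atol=0.02)


class TestEMTraining:
    def _training_setup(self, n_pairs=2, n_seqs=60, seq_len=1000, seed=11):
        from mosaic import synthetic
        from conftest import RECOVERY_COMPOSITIONS
        cfg = synthetic.GeneratorConfig(
            n_pairs=n_pairs, compositions=RECOVERY_COMPOSITIONS[:n_pairs],
            mean_lengths=(40.0, 80.0, 30.0, 60.0)[:n_pairs],
            cpg_proportions=None)
        truth = synthetic.make_model(cfg)
        rng = np.random.default_rng(seed)
        seqs = [hmm.simulate(truth, seq_len, seed=rng.integers(2 ** 31))[0]
                for _ in range(n_seqs)]
        return truth, seqs

    def test_self_consistency_at_generating_model(self):
        truth, seqs = self._training_setup(n_seqs=150, seq_len=2000)
        trained, log = hmm.em_train(truth, seqs, tol=1e-9, max_iter=1)
        # one EM step from the truth moves parameters only by sampling noise
        assert np.abs(trained.E - truth.E).max() < 0.02
        assert np.abs(trained.A - truth.A).max() < 0.02

    def test_loglik_monotone_and_symmetry_maintained(self):
        truth, seqs = self._training_setup()
        init = hmm.random_initial_model(2, seqs, seed=3)
        model, log = hmm.em_train(init, seqs, tol=1e-5, max_iter=15)
        lls = [it.log_likelihood for it in log]
        assert all(b >= a - 1e-6 * abs(a) for a, b in zip(lls, lls[1:]))
        assert hmm.is_symmetric(model, atol=1e-9)

    def test_asymmetric_init_rejected(self, rng):
        truth, seqs = self._training_setup()
        bad = random_model(4, np.random.default_rng(0))
        with pytest.raises(ModelError):
            hmm.em_train(bad, seqs)

    def test_all_n_sequence_rejected(self):
        truth, seqs = self._training_setup(n_seqs=2, seq_len=50)
        with pytest.raises(ValueError, match="entirely of N"):
            hmm.em_train(truth, ["NNNNNN"])

    def test_convergence_metrics_reported(self):
        truth, seqs = self._training_setup(n_seqs=30, seq_len=500)
        _, log = hmm.em_train(truth, seqs, tol=1e-3, max_iter=10)
        assert log[-1].delta_proportion < 1e-3
        assert log[-1].delta_composition < 1e-3


def test_random_initial_model_valid_and_seeded():
    seqs = ["ACGTACGTTTAACCGG" * 20]
    a = hmm.random_initial_model(3, seqs, seed=5)
    b = hmm.random_initial_model(3, seqs, seed=5)
    a.validate()
    assert hmm.is_symmetric(a)
    np.testing.assert_array_equal(a.E, b.E)
    assert a.n_pairs == 3
    assert a.A[0, 0] == pytest.approx(0.97)
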