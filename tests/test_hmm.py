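import itertools

import numpy as np
import pytest

from snparray import SNPArrayError, build_hmm, posterior, viterbi
from snparray.hmm import path_log_prob, simulate_mosaic, transition_matrix


def toy_hmm(panel, cm=None, jump_rate=0.05, error_rate=0.05, mode="haploid"):
    panel = np.asarray(panel)
    if cm is None:
        cm = np.arange(panel.shape[0], dtype=float)
    return build_hmm(panel, cm, jump_rate, error_rate, mode=mode)


class TestBuildHmm:
    def test_zero_distance_transition_is_identity(self):
        h = toy_hmm(np.zeros((3, 2), dtype=int))
        np.testing.assert_allclose(transition_matrix(h, 0.0), np.eye(2))

    def test_infinite_distance_transition_is_uniform(self):
        h = toy_hmm(np.zeros((3, 2), dtype=int))
        np.testing.assert_allclose(transition_matrix(h, 1e9),
                                   np.full((2, 2), 0.5))

    def test_diploid_state_count(self):
        h = toy_hmm(np.zeros((3, 3), dtype=int), mode="diploid")
        assert h.n_states == 6  # H(H+1)/2

    def test_transition_rows_are_distributions(self):
        h = toy_hmm(np.zeros((3, 3), dtype=int), mode="diploid")
        for d in (0.0, 0.3, 2.0):
            T = transition_matrix(h, d)
            np.testing.assert_allclose(T.sum(axis=1), 1.0)

    @pytest.mark.parametrize("kw,msg", [
        (dict(jump_rate=0.0), "jump_rate"),
        (dict(error_rate=0.7), "error_rate"),
        (dict(mode="triploid"), "mode"),
    ])
    def test_invalid_parameters_rejected(self, kw, msg):
        args = dict(jump_rate=0.01, error_rate=0.01, mode="haploid")
        args.update(kw)
        with pytest.raises(SNPArrayError, match=msg):
            build_hmm(np.zeros((3, 2), dtype=int), np.arange(3.0), **args)

    def test_misaligned_map_rejected(self):
        with pytest.raises(SNPArrayError, match="different markers"):
            build_hmm(np.zeros((3, 2), dtype=int), np.arange(4.0), 0.01, 0.01)


def brute_best_logprob(h, obs):
    return max(path_log_prob(h, path, obs)
               for path in itertools.product(range(h.n_states),
                                             repeat=h.n_markers))


def brute_posterior(h, obs):
    post = np.zeros((h.n_markers, h.n_states))
    for path in itertools.product(range(h.n_states), repeat=h.n_markers):
        p = np.exp(path_log_prob(h, path, obs))
        for t, s in enumerate(path):
            post[t, s] += p
    return post / post.sum(axis=1, keepdims=True)


class TestViterbi:
    def test_pure_reference_sample_single_segment(self):
        rng = np.random.default_rng(0)
        panel = rng.integers(0, 2, (12, 3))
        panel[:, 1] = 1 - panel[:, 0]  # make hap1 distinguishable
        h = toy_hmm(panel, error_rate=0.01)
        path = viterbi(h, panel[:, 1].astype(float))
        assert (path.states == 1).all()
        assert len(path.segments) == 1

    def test_matches_exhaustive_argmax_haploid(self):
        """6-marker, 2-haplotype decode with a recombinant observation block
        attains the same joint probability as brute-force enumeration of all
        2^6 paths."""
        panel = np.array([[0, 1]] * 6)
        h = toy_hmm(panel, jump_rate=0.2, error_rate=0.1)
        obs = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        path = viterbi(h, obs)
        assert path.log_prob == pytest.approx(brute_best_logprob(h, obs))
        assert path.log_prob == pytest.approx(
            path_log_prob(h, path.states, obs))
        assert list(path.states) == [0, 0, 0, 1, 1, 1]

    def test_matches_exhaustive_argmax_diploid(self):
        rng = np.random.default_rng(3)
        panel = rng.integers(0, 2, (5, 3))
        h = toy_hmm(panel, jump_rate=0.1, error_rate=0.05, mode="diploid")
        obs = rng.integers(0, 3, 5).astype(float)
        path = viterbi(h, obs)
        assert path.log_prob == pytest.approx(brute_best_logprob(h, obs))

    def test_missing_marker_equivalent_to_removal(self):
        """With the middle observation missing, the decoded states at the
        remaining markers match decoding with that marker excised."""
        panel = np.array([[0, 1]] * 7)
        cm = np.arange(7, dtype=float)
        h = build_hmm(panel, cm, 0.05, 0.02)
        obs = np.array([0, 0, 0, np.nan, 1, 1, 1])
        full = viterbi(h, obs)
        keep = [0, 1, 2, 4, 5, 6]
        h2 = build_hmm(panel[keep], cm[keep], 0.05, 0.02)
        short = viterbi(h2, obs[keep])
        np.testing.assert_array_equal(full.states[keep], short.states)

    def test_all_missing_decodes_to_prior_argmax(self):
        h = toy_hmm(np.array([[0, 1]] * 4))
        with pytest.warns(UserWarning, match="missing"):
            path = viterbi(h, np.full(4, np.nan))
        assert (path.states == 0).all()  # lowest-index tie break

    def test_beats_every_enumerated_path(self):
        """Viterbi log-probability upper-bounds all 3^5 paths."""
        rng = np.random.default_rng(5)
        panel = rng.integers(0, 2, (5, 3))
        h = toy_hmm(panel, jump_rate=0.3, error_rate=0.2)
        obs = rng.integers(0, 2, 5).astype(float)
        best = viterbi(h, obs).log_prob
        for path in itertools.product(range(3), repeat=5):
            assert best >= path_log_prob(h, path, obs) - 1e-9


class TestPosterior:
    def test_uninformative_observations_uniform_rows(self):
        h = toy_hmm(np.array([[0, 1]] * 4))
        post = posterior(h, np.full(4, np.nan))
        np.testing.assert_allclose(post, 0.5)

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(7)
        panel = rng.integers(0, 2, (5, 3))
        h = toy_hmm(panel, jump_rate=0.2, error_rate=0.1)
        obs = rng.integers(0, 2, 5).astype(float)
        np.testing.assert_allclose(posterior(h, obs), brute_posterior(h, obs),
                                   atol=1e-10)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(8)
        panel = rng.integers(0, 2, (30, 4))
        h = toy_hmm(panel, mode="diploid")
        post = posterior(h, rng.integers(0, 3, 30).astype(float))
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_marginal_argmax_agrees_with_viterbi_on_clean_mosaic(self):
        rng = np.random.default_rng(9)
        panel = rng.integers(0, 2, (60, 3))
        cm = np.cumsum(rng.uniform(0.5, 1.5, 60))
        h = build_hmm(panel, cm, 0.02, 0.01)
        states, obs = simulate_mosaic(h, rng, observe_error=0.0)
        vit = viterbi(h, obs)
        post = posterior(h, obs)
        agree = (post.argmax(axis=1) == vit.states).mean()
        assert agree > 0.97


class TestParameterRecovery:
    def test_mosaic_ancestry_recovered(self):
        """On simulated mosaics (jump 0.01/cM, eps 0.005, H=4, 500 markers)
        Viterbi recovers at least 95% of true ancestry labels."""
        rng = np.random.default_rng(11)
        panel = rng.integers(0, 2, (500, 4))
        cm = np.cumsum(rng.uniform(0.1, 0.3, 500))
        h = build_hmm(panel, cm, jump_rate=0.01, error_rate=0.005)
        states, obs = simulate_mosaic(h, rng)
        path = viterbi(h, obs)
        assert (path.states == states).mean() >= 0.95

    def test_segments_partition_the_chromosome(self):
        rng = np.random.default_rng(12)
        panel = rng.integers(0, 2, (100, 3))
        cm = np.cumsum(rng.uniform(0.2, 0.5, 100))
        h = build_hmm(panel, cm, 0.05, 0.01)
        _, obs = simulate_mosaic(h, rng)
        seg = viterbi(h, obs).segments
        assert seg["start_marker"].iloc[0] == 0
        assert seg["end_marker"].iloc[-1] == 99
        assert (seg["start_marker"].iloc[1:].to_numpy()
                == seg["end_marker"].iloc[:-1].to_numpy() + 1).all()
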