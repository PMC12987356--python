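"""The probabilistic core against brute-force oracles and its contracts."""

import numpy as np
import pytest

from dmmstream import (
    ConfigError,
    GibbsConfig,
    Hyperparameters,
    Segment,
    assign,
    dm_log_pmf,
    dm_sequence_log_prob,
    estimated_cluster_count,
    fit,
    gibbs_conditional,
    joint_log_prob,
    load_model,
    save_model,
)
import _oracles as oracle
from conftest import make_corpus


class TestDmLogPmf:
    def test_single_outcome_distribution_is_certain(self):
        for N in (0, 1, 7):
            assert dm_log_pmf(np.array([N]), np.array([0.7])) == pytest.approx(0.0, abs=1e-12)

    def test_one_draw_reduces_to_compound_categorical(self):
        beta = np.array([0.5, 1.5, 3.0])
        for v in range(3):
            x = np.zeros(3, dtype=int)
            x[v] = 1
            assert dm_log_pmf(x, beta) == pytest.approx(np.log(beta[v] / beta.sum()), abs=1e-12)

    @pytest.mark.parametrize(
        "beta", [np.array([0.5, 1.0, 2.0]), np.array([0.1, 0.1, 0.1]), np.array([3.0, 7.0, 0.2])]
    )
    def test_normalizes_over_all_count_vectors(self, beta):
        total = sum(np.exp(dm_log_pmf(np.array(x), beta)) for x in oracle.all_count_vectors(4, 3))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_matches_direct_product_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            V = rng.integers(1, 5)
            x = rng.integers(0, 6, size=V)
            beta = rng.uniform(0.05, 3.0, size=V)
            assert dm_log_pmf(x, beta) == pytest.approx(np.log(oracle.dm_prob(x, beta)), abs=1e-10)

    def test_rejects_invalid_arguments(self):
        with pytest.raises(ConfigError):
            dm_log_pmf(np.array([-1, 2]), np.array([1.0, 1.0]))
        with pytest.raises(ConfigError):
            dm_log_pmf(np.array([1, 2]), np.array([1.0, 0.0]))


class TestDmSequenceLogProb:
    def test_empty_counts_give_log_one(self):
        assert dm_sequence_log_prob(np.zeros(4, dtype=int), np.full(4, 0.3)) == pytest.approx(0.0)

    def test_hand_evaluated_gamma_ratio(self):
        # x=(2,0), beta=(1,1): Gamma(2)Gamma(3)Gamma(1) / (Gamma(4)Gamma(1)Gamma(1)) = 1/3
        assert dm_sequence_log_prob(np.array([2, 0]), np.array([1.0, 1.0])) == pytest.approx(
            np.log(1 / 3), abs=1e-12
        )

    def test_differs_from_pmf_by_multinomial_coefficient(self):
        from scipy.special import gammaln

        rng = np.random.default_rng(1)
        for _ in range(20):
            V = rng.integers(1, 5)
            x = rng.integers(0, 5, size=V)
            beta = rng.uniform(0.1, 2.0, size=V)
            coeff = gammaln(x.sum() + 1) - gammaln(x + 1).sum()
            assert dm_sequence_log_prob(x, beta) == pytest.approx(
                dm_log_pmf(x, beta) - coeff, abs=1e-10
            )


class TestJointLogProb:
    def test_single_segment_single_stream_closed_form(self):
        corpus = make_corpus({"w": [[0, 1, 1]]}, vocab_sizes={"w": 3})
        alpha = np.array([2.0, 1.0])
        beta = 0.5
        hyper = Hyperparameters(alpha=alpha, beta=beta)
        x = np.array([1, 2, 0])
        for z in (0, 1):
            expected = np.log(alpha[z] / alpha.sum()) + dm_sequence_log_prob(x, np.full(3, beta))
            assert joint_log_prob(corpus, [z], hyper, K=2) == pytest.approx(expected, abs=1e-10)

    def test_duplicated_stream_doubles_the_stream_term(self):
        tok = [[0, 1], [2, 2], [1]]
        one = make_corpus({"w": tok}, vocab_sizes={"w": 3})
        two = make_corpus({"w": tok, "w2": tok}, vocab_sizes={"w": 3, "w2": 3})
        hyper = Hyperparameters(alpha=1.0, beta=0.4)
        z = [0, 1, 0]
        prior = joint_log_prob(make_corpus({"w": [[], [], []]}, vocab_sizes={"w": 1}), z, hyper, K=2)
        j1 = joint_log_prob(one, z, hyper, K=2)
        j2 = joint_log_prob(two, z, hyper, K=2)
        assert j2 - prior == pytest.approx(2 * (j1 - prior), abs=1e-10)

    def test_word_and_segment_permutation_invariance(self, two_stream_corpus):
        hyper = Hyperparameters(alpha=0.7, beta=0.3)
        z = [0, 1, 1, 0]
        base = joint_log_prob(two_stream_corpus, z, hyper, K=2)
        # shuffle tokens within each segment
        rng = np.random.default_rng(3)
        shuffled = make_corpus(
            {
                s: [rng.permutation(seg.tokens[s]).tolist() for seg in two_stream_corpus.segments]
                for s in two_stream_corpus.schema.streams
            },
            vocab_sizes={s: two_stream_corpus.schema.vocab_size(s) for s in ("w", "y")},
        )
        assert joint_log_prob(shuffled, z, hyper, K=2) == pytest.approx(base, abs=1e-12)
        # permute segments together with assignments
        perm = [2, 0, 3, 1]
        permuted = make_corpus(
            {
                s: [two_stream_corpus.segments[i].tokens[s].tolist() for i in perm]
                for s in two_stream_corpus.schema.streams
            },
            vocab_sizes={s: two_stream_corpus.schema.vocab_size(s) for s in ("w", "y")},
        )
        z_perm = [z[i] for i in perm]
        assert joint_log_prob(permuted, z_perm, hyper, K=2) == pytest.approx(base, abs=1e-12)

    def test_exp_joint_sums_to_enumerated_marginal(self):
        """Sum of exp(joint) over all K^M assignments equals the brute-force marginal."""
        from itertools import product

        rng = np.random.default_rng(4)
        corpus = make_corpus(
            {
                "w": [rng.integers(0, 4, size=3).tolist() for _ in range(3)],
                "y": [rng.integers(0, 2, size=2).tolist() for _ in range(3)],
            },
            vocab_sizes={"w": 4, "y": 2},
        )
        K = 2
        alpha = np.array([1.2, 0.8])
        beta = {"w": np.full((K, 4), 0.5), "y": np.full((K, 2), 1.5)}
        hyper = Hyperparameters(alpha=alpha, beta=beta)
        total = sum(
            np.exp(joint_log_prob(corpus, list(z), hyper, K=K))
            for z in product(range(K), repeat=3)
        )
        assert total == pytest.approx(oracle.marginal(corpus, alpha, beta, K), rel=1e-10)


class TestGibbsConditional:
    def _random_state(self, corpus, z, K, alpha, beta):
        from dmmstream import DmmModelState, recompute_counts

        tau, omega = recompute_counts(corpus, z, K)
        return DmmModelState(
            K=K, alpha=alpha, beta=beta, tau=tau, omega=omega, assignments=np.array(z), seed=0
        )

    def test_matches_enumeration_oracle_everywhere(self, two_stream_corpus):
        """Collapsed conditional == exact ratio of enumerated joints, every m and Z."""
        rng = np.random.default_rng(8)
        K = 2
        alpha = np.array([0.9, 1.4])
        beta = {"w": rng.uniform(0.1, 1.5, size=(K, 5)), "y": rng.uniform(0.1, 1.5, size=(K, 3))}
        for _ in range(5):
            z = rng.integers(0, K, size=4).tolist()
            state = self._random_state(two_stream_corpus, z, K, alpha, beta)
            for m in range(4):
                got = gibbs_conditional(m, state, two_stream_corpus)
                want = oracle.conditional(two_stream_corpus, z, m, alpha, beta, K)
                assert np.max(np.abs(got - want)) < 1e-10

    def test_empty_segment_conditional_is_prior_only(self):
        corpus = make_corpus({"w": [[0, 1], [], [1, 1]]}, vocab_sizes={"w": 2})
        K = 3
        alpha = np.array([0.5, 2.0, 1.0])
        z = [0, 1, 2]
        state = self._random_state(corpus, z, K, alpha, {"w": np.full((K, 2), 0.3)})
        got = gibbs_conditional(1, state, corpus)
        tau_ex = np.array([1, 0, 1], dtype=float)
        want = (tau_ex + alpha) / (tau_ex + alpha).sum()
        assert np.allclose(got, want, atol=1e-12)

    def test_lone_segment_with_symmetric_alpha_is_dm_likelihood_ratio(self):
        corpus = make_corpus({"w": [[0, 0, 1]]}, vocab_sizes={"w": 2})
        K = 2
        beta = {"w": np.array([[0.2, 0.8], [1.0, 1.0]])}
        state = self._random_state(corpus, [0], K, np.array([1.0, 1.0]), beta)
        got = gibbs_conditional(0, state, corpus)
        x = np.array([2, 1])
        lik = np.array([np.exp(dm_sequence_log_prob(x, beta["w"][k])) for k in range(K)])
        assert np.allclose(got, lik / lik.sum(), atol=1e-12)

    def test_constant_second_stream_leaves_conditional_unchanged(self, two_stream_corpus):
        """Adding a 1-word-vocabulary stream multiplies every cluster weight equally."""
        rng = np.random.default_rng(9)
        K = 3
        alpha = np.full(K, 1.0)
        beta_w = {"w": np.full((K, 5), 0.4), "y": np.full((K, 3), 0.7)}
        z = rng.integers(0, K, size=4).tolist()
        state2 = self._random_state(two_stream_corpus, z, K, alpha, beta_w)
        # same corpus plus a constant third stream
        const = make_corpus(
            {
                "w": [seg.tokens["w"].tolist() for seg in two_stream_corpus.segments],
                "y": [seg.tokens["y"].tolist() for seg in two_stream_corpus.segments],
                "c": [[0, 0, 0]] * 4,
            },
            vocab_sizes={"w": 5, "y": 3, "c": 1},
        )
        beta3 = dict(beta_w, c=np.full((K, 1), 0.6))
        state3 = self._random_state(const, z, K, alpha, beta3)
        for m in range(4):
            assert np.allclose(
                gibbs_conditional(m, state2, two_stream_corpus),
                gibbs_conditional(m, state3, const),
                atol=1e-10,
            )


class TestFit:
    def test_two_disjoint_clusters_recovered_exactly(self, separable_corpus):
        result = fit(separable_corpus, Hyperparameters(), GibbsConfig(K=5, iterations=30, seed=2))
        assert result.estimated_clusters == 2
        z = result.state.assignments
        truth = np.array([m % 2 for m in range(20)])
        # partition identity up to relabeling
        assert len({(t, p) for t, p in zip(truth, z.tolist())}) == 2

    def test_iteration_contract(self, two_stream_corpus):
        with pytest.raises(ConfigError):
            GibbsConfig(K=2, iterations=0)
        result = fit(two_stream_corpus, Hyperparameters(), GibbsConfig(K=2, iterations=1, seed=0))
        assert result.state.iterations_run == 1

    def test_same_seed_identical_assignments(self, separable_corpus):
        cfg = GibbsConfig(K=4, iterations=10, seed=42)
        r1 = fit(separable_corpus, Hyperparameters(), cfg)
        r2 = fit(separable_corpus, Hyperparameters(), cfg)
        assert np.array_equal(r1.state.assignments, r2.state.assignments)

    def test_token_shuffle_does_not_change_trajectory(self, separable_corpus):
        """Counts are sufficient: shuffling words within segments leaves the run identical."""
        rng = np.random.default_rng(6)
        shuffled = make_corpus(
            {
                "d0": [rng.permutation(seg.tokens["d0"]).tolist() for seg in separable_corpus.segments]
            },
            labels=separable_corpus.labels(),
            vocab_sizes={"d0": 8},
        )
        cfg = GibbsConfig(K=4, iterations=10, seed=13, record_history=True)
        r1 = fit(separable_corpus, Hyperparameters(), cfg)
        r2 = fit(shuffled, Hyperparameters(), cfg)
        assert np.array_equal(r1.state.assignments, r2.state.assignments)
        assert r1.log_joint_trace == pytest.approx(r2.log_joint_trace, abs=1e-9)

    def test_count_conservation_after_fit(self, two_stream_corpus):
        result = fit(two_stream_corpus, Hyperparameters(), GibbsConfig(K=3, iterations=4, seed=5))
        state = result.state
        assert state.tau.sum() == two_stream_corpus.M
        for s in two_stream_corpus.schema.streams:
            total = sum(seg.tokens[s].size for seg in two_stream_corpus.segments)
            assert state.omega[s].sum() == total

    def test_resume_equals_uninterrupted_run(self, tmp_path, separable_corpus):
        """Save / load / continue with the same generator stream matches one long run."""
        hyper = Hyperparameters()
        rng_a = np.random.default_rng(77)
        full = fit(separable_corpus, hyper, GibbsConfig(K=4, iterations=10, seed=77), rng=rng_a)

        rng_b = np.random.default_rng(77)
        half = fit(separable_corpus, hyper, GibbsConfig(K=4, iterations=5, seed=77), rng=rng_b)
        path = save_model(half.state, tmp_path / "half.json")
        resumed_state = load_model(path)
        resumed = fit(
            separable_corpus,
            hyper,
            GibbsConfig(K=4, iterations=5, seed=77),
            init_state=resumed_state,
            rng=rng_b,
        )
        assert np.array_equal(full.state.assignments, resumed.state.assignments)
        assert resumed.state.iterations_run == 10

    def test_single_stream_reduction_matches_standard_dmm(self):
        """A constant extra stream changes no sampled trajectory."""
        rng = np.random.default_rng(12)
        toks = [rng.integers(0, 6, size=15).tolist() for _ in range(12)]
        single = make_corpus({"w": toks}, vocab_sizes={"w": 6})
        padded = make_corpus(
            {"w": toks, "c": [[0, 0]] * 12}, vocab_sizes={"w": 6, "c": 1}
        )
        cfg = GibbsConfig(K=3, iterations=8, seed=21)
        hyper = Hyperparameters(alpha=1.0, beta=0.2)
        r1 = fit(single, hyper, cfg)
        r2 = fit(padded, hyper, cfg)
        assert np.array_equal(r1.state.assignments, r2.state.assignments)


class TestAssign:
    @pytest.fixture
    def fitted(self, separable_corpus):
        return fit(separable_corpus, Hyperparameters(), GibbsConfig(K=5, iterations=30, seed=2))

    def test_training_lookalike_goes_to_its_cluster(self, fitted, separable_corpus):
        seg0 = separable_corpus.segments[0]
        k = assign(seg0, fitted.state, mode="map")
        assert k == fitted.state.assignments[0]

    def test_empty_segment_goes_to_largest_prior_cluster(self, fitted):
        empty = Segment(id="e", tokens={"d0": np.zeros(0, dtype=np.int64)})
        k = assign(empty, fitted.state, mode="map")
        assert k == int(np.argmax(fitted.state.tau + fitted.state.alpha))

    def test_map_mode_invariant_to_token_order(self, fitted, separable_corpus):
        seg = separable_corpus.segments[3]
        rev = Segment(id="r", tokens={"d0": seg.tokens["d0"][::-1].copy()})
        assert assign(seg, fitted.state, "map") == assign(rev, fitted.state, "map")

    def test_gibbs_mode_deterministic_given_seed(self, fitted, separable_corpus):
        seg = separable_corpus.segments[1]
        a = assign(seg, fitted.state, mode="gibbs", iterations=10, seed=4)
        b = assign(seg, fitted.state, mode="gibbs", iterations=10, seed=4)
        assert a == b

    def test_unknown_mode_rejected(self, fitted, separable_corpus):
        with pytest.raises(ConfigError):
            assign(separable_corpus.segments[0], fitted.state, mode="viterbi")


def test_effective_cluster_count_robust_to_capacity():
    """Raising K from K_true to 4*K_true barely changes the number of
    non-empty clusters: surplus capacity stays empty."""
    from dmmstream import default_recovery_spec, generate

    syn = generate(default_recovery_spec(seed=0))
    est = {}
    for K in (4, 16):
        res = fit(syn.corpus, Hyperparameters(), GibbsConfig(K=K, iterations=50, seed=7))
        est[K] = res.estimated_clusters
    assert est[16] - est[4] <= 2


class TestEstimatedClusterCount:
    def test_counts_non_empty_clusters(self, separable_corpus):
        result = fit(separable_corpus, Hyperparameters(), GibbsConfig(K=10, iterations=20, seed=3))
        state = result.state
        assert estimated_cluster_count(state) == np.count_nonzero(state.tau)
        assert estimated_cluster_count(state) <= min(state.K, separable_corpus.M)
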