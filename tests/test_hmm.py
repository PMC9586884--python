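import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slipfret.hmm import (DiscretizedTrace, HmmModel, VAR_FLOOR, fit_hmm,
                          viterbi_path)


def make_model(means, variances, a, pi):
    return HmmModel(K=len(means), means=np.asarray(means, float),
                    variances=np.asarray(variances, float),
                    transition_probs=np.asarray(a, float),
                    initial_probs=np.asarray(pi, float),
                    log_likelihood=0.0, n_iterations=0, converged=True)


def brute_force_viterbi(x, model):
    """Enumerate all K^T paths; ties resolved toward the lexicographically
    smallest path, matching the decoder's lowest-index convention."""
    K, T = model.K, len(x)
    best_lp, best_path = -np.inf, None
    for path in itertools.product(range(K), repeat=T):
        lp = np.log(model.initial_probs[path[0]])
        lp += -0.5 * (np.log(2 * np.pi * model.variances[path[0]])
                      + (x[0] - model.means[path[0]]) ** 2
                      / model.variances[path[0]])
        for t in range(1, T):
            with np.errstate(divide="ignore"):
                lp += np.log(model.transition_probs[path[t - 1], path[t]])
            lp += -0.5 * (np.log(2 * np.pi * model.variances[path[t]])
                          + (x[t] - model.means[path[t]])
                          ** 2 / model.variances[path[t]])
        if lp > best_lp + 1e-12 or best_path is None:
            best_lp, best_path = lp, path
    return np.array(best_path) + 1


class TestFitHmm:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.5, 0.1, size=400)
        m = fit_hmm(x, K=1, n_restarts=1, seed=0)
        assert m.means[0] == pytest.approx(x.mean(), abs=1e-9)
        assert m.variances[0] == pytest.approx(x.var(), abs=1e-9)
        v = x.var()
        ll = -0.5 * np.sum(np.log(2 * np.pi * v) + (x - x.mean()) ** 2 / v)
        assert m.log_likelihood == pytest.approx(ll, rel=1e-9)

    def test_noiseless_square_wave(self):
        x = np.tile(np.r_[np.full(10, 0.2), np.full(10, 0.8)], 5)
        m = fit_hmm(x, K=2, n_restarts=5, seed=1)
        np.testing.assert_allclose(m.means, [0.2, 0.8], atol=1e-6)
        # exact transition counting: 5 low->high switches out of 50 low
        # frames (49 with a successor), 4 high->low out of 49
        assert m.transition_probs[0, 1] == pytest.approx(5 / 50, abs=1e-3)
        assert m.transition_probs[1, 0] == pytest.approx(4 / 49, abs=1e-3)

    def test_em_loglik_monotone(self):
        rng = np.random.default_rng(3)
        x = np.r_[rng.normal(0.3, 0.05, 300), rng.normal(0.7, 0.05, 300)]
        rng.shuffle(x)
        m = fit_hmm(x, K=2, n_restarts=3, seed=3)
        assert np.all(np.diff(m.ll_history) >= -1e-9 * np.abs(m.ll_history[:-1]))

    def test_parameter_recovery_cag10(self, cag10_scheme):
        # per-trace state labels need not align across molecules, so the
        # fitted means are pooled and grouped by the nearest generator
        # level; each group's center must recover that level
        from slipfret.synthetic import simulate_traces
        ts, _ = simulate_traces(cag10_scheme, n_traces=30, seed=21)
        pooled = []
        for i, tr in enumerate(ts.traces):
            m = fit_hmm(tr.fret, K=6, n_restarts=10, seed=100 + i)
            pooled.extend(m.means)
        pooled = np.array(pooled)
        truth = cag10_scheme.distinct_means
        for level in truth:
            near = pooled[np.abs(pooled - level) < 0.07]
            assert len(near) >= 20
            assert abs(np.median(near) - level) < 0.03

    def test_multiple_sequences_share_model(self):
        rng = np.random.default_rng(4)
        seqs = [np.r_[rng.normal(0.2, 0.05, 60), rng.normal(0.8, 0.05, 60)]
                for _ in range(4)]
        m = fit_hmm(seqs, K=2, n_restarts=5, seed=4)
        np.testing.assert_allclose(m.means, [0.2, 0.8], atol=0.02)

    def test_identical_values_degenerate_model(self):
        with pytest.warns(UserWarning, match="identical"):
            m = fit_hmm(np.full(100, 0.5), K=2, n_restarts=2, seed=0)
        assert m.degenerate

    def test_too_few_frames_fatal(self):
        with pytest.raises(ValueError, match="frames"):
            fit_hmm(np.linspace(0, 1, 20), K=2, n_restarts=1, seed=0)

    def test_canonical_order_and_permutation_invariance(self):
        a = np.array([[0.9, 0.06, 0.04], [0.1, 0.8, 0.1], [0.2, 0.3, 0.5]])
        m1 = make_model([0.7, 0.2, 0.5], [0.01, 0.02, 0.03], a,
                        [0.5, 0.3, 0.2])
        perm = [1, 2, 0]   # arbitrary relabeling of the same model
        m2 = make_model(np.array([0.7, 0.2, 0.5])[perm],
                        np.array([0.01, 0.02, 0.03])[perm],
                        a[np.ix_(perm, perm)],
                        np.array([0.5, 0.3, 0.2])[perm])
        np.testing.assert_allclose(m1.means, m2.means)
        np.testing.assert_allclose(m1.variances, m2.variances)
        np.testing.assert_allclose(m1.transition_probs, m2.transition_probs)
        np.testing.assert_allclose(m1.initial_probs, m2.initial_probs)
        assert np.all(np.diff(m1.means) >= 0)

    def test_forward_loglik_matches_hmmlearn(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(8)
        x = np.r_[rng.normal(0.25, 0.06, 150), rng.normal(0.75, 0.06, 150)]
        m = fit_hmm(x, K=2, n_restarts=5, seed=8)
        ref = hmmlearn.GaussianHMM(n_components=2, covariance_type="diag",
                                   init_params="")
        ref.startprob_ = m.initial_probs
        ref.transmat_ = m.transition_probs
        ref.means_ = m.means.reshape(-1, 1)
        ref.covars_ = m.variances.reshape(-1, 1)
        assert m.log_likelihood == pytest.approx(
            ref.score(x.reshape(-1, 1)), rel=1e-8)


class TestViterbi:
    def test_noiseless_decoding_exact(self):
        x = np.tile(np.r_[np.full(5, 0.2), np.full(5, 0.8)], 4)
        m = make_model([0.2, 0.8], [0.0025, 0.0025],
                       [[0.9, 0.1], [0.1, 0.9]], [0.5, 0.5])
        d = viterbi_path(m, x)
        expected = np.tile(np.r_[np.full(5, 1), np.full(5, 2)], 4)
        np.testing.assert_array_equal(d.state_path, expected)
        np.testing.assert_allclose(d.ideal_fret, m.means[d.state_path - 1])

    def test_three_frames_k3_matches_enumeration(self):
        rng = np.random.default_rng(11)
        m = make_model(np.sort(rng.uniform(0, 1, 3)),
                       rng.uniform(0.002, 0.02, 3),
                       _random_stochastic(rng, 3), _random_simplex(rng, 3))
        x = rng.uniform(0, 1, 3)
        d = viterbi_path(m, x)
        np.testing.assert_array_equal(d.state_path, brute_force_viterbi(x, m))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(data=st.data())
    def test_viterbi_matches_brute_force(self, data):
        seed = data.draw(st.integers(0, 10_000))
        K = data.draw(st.integers(1, 3))
        T = data.draw(st.integers(1, 8))
        rng = np.random.default_rng(seed)
        m = make_model(np.sort(rng.uniform(0, 1, K)),
                       rng.uniform(0.002, 0.05, K),
                       _random_stochastic(rng, K), _random_simplex(rng, K))
        x = rng.uniform(-0.1, 1.1, T)
        d = viterbi_path(m, x)
        np.testing.assert_array_equal(d.state_path, brute_force_viterbi(x, m))

    def test_tie_breaks_to_lowest_state(self):
        # two identical states: every path probability ties; the decoder
        # must stay in state 1 throughout
        m = make_model([0.5, 0.5], [0.01, 0.01],
                       [[0.5, 0.5], [0.5, 0.5]], [0.5, 0.5])
        d = viterbi_path(m, np.full(6, 0.5))
        np.testing.assert_array_equal(d.state_path, np.ones(6, dtype=int))

    def test_transitions_extracted_at_changes(self):
        d = DiscretizedTrace("t", np.array([1, 1, 2, 2, 1]),
                             np.array([0.2, 0.2, 0.8, 0.8, 0.2]),
                             np.zeros(5))
        trs = d.transitions
        assert [(f, sb, sa) for f, sb, sa, *_ in trs] == [(2, 1, 2), (4, 2, 1)]
        assert all(fb != fa for *_, fb, fa in trs)

    def test_recovered_transition_prob_matches_rate(self, two_state_scheme):
        from slipfret.synthetic import simulate_traces
        ts, _ = simulate_traces(two_state_scheme, n_traces=30, seed=13,
                                max_duration=30.0)
        m = fit_hmm([t.fret for t in ts], K=2, n_restarts=5, seed=13)
        # per-frame switch probability of a symmetric 2-state chain:
        # p = (1 - exp(-2k dt)) / 2 with k = 1/s, dt = 0.05 s
        p_expected = (1 - np.exp(-2 * 1.0 * 0.05)) / 2
        n_frames = sum(len(t) for t in ts)
        mc_sd = np.sqrt(p_expected * (1 - p_expected) / (n_frames / 2))
        assert abs(m.transition_probs[0, 1] - p_expected) < max(3 * mc_sd, 0.01)


def _random_stochastic(rng, k):
    a = rng.uniform(0.05, 1.0, size=(k, k))
    return a / a.sum(axis=1, keepdims=True)


def _random_simplex(rng, k):
    p = rng.uniform(0.05, 1.0, size=k)
    return p / p.sum()
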