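import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slipfret.hmm import DiscretizedTrace
from slipfret.tdp import (KoptResult, TransitionDensity, build_tdp,
                          consensus_k, fit_tdp_mixture, iter_transitions,
                          select_k_opt)


def alternating_trace(levels, period, n_periods, trace_id="t"):
    """Noiseless idealized trace alternating between two levels."""
    path, fret = [], []
    for i in range(2 * n_periods):
        s = i % 2
        path.extend([s + 1] * period)
        fret.extend([levels[s]] * period)
    return DiscretizedTrace(trace_id, np.array(path), np.array(fret),
                            np.array(fret))


class TestBuildTdp:
    def test_no_transitions_zero_grid(self):
        d = DiscretizedTrace("t", np.ones(50, dtype=int), np.full(50, 0.4),
                             np.full(50, 0.4))
        with pytest.warns(UserWarning, match="no transitions"):
            tdp = build_tdp([d])
        assert tdp.n_transitions == 0
        assert tdp.grid.sum() == 0

    def test_single_transition_placement(self):
        d = DiscretizedTrace("t", np.r_[np.ones(5, int), np.full(5, 2, int)],
                             np.r_[np.full(5, 0.2), np.full(5, 0.8)],
                             np.zeros(10))
        tdp = build_tdp([d])
        assert tdp.n_transitions == 1
        assert tdp.grid.sum() == pytest.approx(1.0, abs=1e-9)
        i, j = np.unravel_index(np.argmax(tdp.grid), tdp.grid.shape)
        assert i == int(0.2 * 100) and j == int(0.8 * 100)

    def test_mass_conservation_after_smoothing(self):
        d = alternating_trace((0.3, 0.7), period=5, n_periods=40)
        for bins, sigma2 in ((100, 0.0005), (50, 0.002), (100, 0.01)):
            tdp = build_tdp([d], bins=bins, sigma2=sigma2)
            assert tdp.grid.sum() == pytest.approx(tdp.n_transitions,
                                                   rel=1e-9)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 9999), n=st.integers(2, 60))
    def test_mass_conservation_random_paths(self, seed, n):
        rng = np.random.default_rng(seed)
        means = np.sort(rng.uniform(0, 1, 3))
        path = rng.integers(1, 4, size=n)
        d = DiscretizedTrace("t", path, means[path - 1], means[path - 1])
        tdp = build_tdp([d], min_dwell_frames=1, min_amplitude=0.0)
        assert tdp.grid.sum() == pytest.approx(tdp.n_transitions, rel=1e-9)

    def test_symmetry_under_reversal(self):
        # odd number of runs: equal counts of 1->2 and 2->1 transitions
        path = np.r_[np.tile([1] * 5 + [2] * 5, 40), [1] * 5]
        means = np.array([0.3, 0.7])
        d = DiscretizedTrace("t", path, means[path - 1], means[path - 1])
        tdp = build_tdp([d])
        np.testing.assert_allclose(tdp.grid, tdp.grid.T, atol=1e-9)

    def test_min_dwell_filter_collapses_blips(self):
        # 0.2 -> blip(0.5, 1 frame) -> 0.8 counts as one 0.2 -> 0.8 jump
        path = np.r_[np.ones(5, int), [2], np.full(5, 3, int)]
        fret = np.r_[np.full(5, 0.2), [0.5], np.full(5, 0.8)]
        d = DiscretizedTrace("t", path, fret, fret)
        pairs = iter_transitions([d], min_dwell_frames=2, min_amplitude=0.0)
        assert pairs.shape == (1, 2)
        np.testing.assert_allclose(pairs[0], [0.2, 0.8])

    def test_min_amplitude_filter(self):
        d = alternating_trace((0.40, 0.44), period=5, n_periods=10)
        pairs = iter_transitions([d], min_dwell_frames=1, min_amplitude=0.1)
        assert len(pairs) == 0


class TestMixtureFit:
    def test_two_state_exact_construction(self):
        d = alternating_trace((0.3, 0.7), period=5, n_periods=100)
        tdp = build_tdp([d])
        fit = fit_tdp_mixture(tdp, K=2, n_init=5, seed=0)
        np.testing.assert_allclose(fit.state_means, [0.3, 0.7], atol=0.005)
        assert fit.cluster_pairs == [(0, 1), (1, 0)]
        np.testing.assert_allclose(fit.cluster_weights, [0.5, 0.5], atol=0.01)

    def test_bic_arithmetic(self):
        d = alternating_trace((0.3, 0.7), period=5, n_periods=100)
        tdp = build_tdp([d])
        fit = fit_tdp_mixture(tdp, K=2, n_init=3, seed=1)
        expected = -2 * fit.log_likelihood + fit.n_params * np.log(
            tdp.n_transitions)
        assert fit.BIC == pytest.approx(expected, rel=1e-12)
        # parameter count: K means + (K(K-1) - 1) weights + K(K-1) sigmas
        assert fit.n_params == 2 + 1 + 2

    def test_k1_with_transitions_is_infinite_bic(self):
        d = alternating_trace((0.3, 0.7), period=5, n_periods=20)
        tdp = build_tdp([d])
        fit = fit_tdp_mixture(tdp, K=1, seed=0)
        assert fit.log_likelihood == -np.inf
        assert fit.BIC == np.inf

    def test_k2_without_transitions_fatal(self):
        tdp = TransitionDensity(np.zeros((100, 100)), 0)
        with pytest.raises(ValueError, match="no transitions"):
            fit_tdp_mixture(tdp, K=2, seed=0)

    def test_em_loglik_monotone(self):
        rng = np.random.default_rng(5)
        path = rng.integers(1, 4, size=2000)
        means = np.array([0.2, 0.5, 0.8])
        d = DiscretizedTrace("t", path, means[path - 1], means[path - 1])
        tdp = build_tdp([d])
        fit = fit_tdp_mixture(tdp, K=3, n_init=2, seed=5)
        diffs = np.diff(fit.ll_history)
        assert np.all(diffs >= -1e-6 * np.abs(fit.ll_history[:-1]))


class TestKoptSelection:
    def test_argmin_contract(self):
        d = alternating_trace((0.3, 0.7), period=5, n_periods=100)
        tdp = build_tdp([d])
        res = select_k_opt(tdp, k_range=range(1, 5), n_init=3, seed=2)
        assert res.K_opt == min(res.per_K_BIC, key=lambda k:
                                (res.per_K_BIC[k], k))
        assert res.K_opt == 2

    def test_hairpin_pipeline_recovers_two_states(self, hairpin_traces):
        from slipfret.hmm import fit_hmm, viterbi_path
        ts, _ = hairpin_traces
        disc = []
        for i, tr in enumerate(ts.traces):
            m = fit_hmm(tr.fret, K=2, n_restarts=5, seed=50 + i)
            disc.append(viterbi_path(m, tr))
        tdp = build_tdp(disc)
        res = select_k_opt(tdp, k_range=range(1, 6), n_init=5, seed=3)
        assert res.K_opt == 2
        np.testing.assert_allclose(res.state_means_at_Kopt, [0.25, 0.75],
                                   atol=0.03)


class TestConsensus:
    def test_single_deviation_at_high_k(self):
        res = {k: KoptResult(per_K_BIC={v: 0.0}, K_opt=v)
               for k, v in {6: 6, 7: 6, 8: 6, 9: 6, 10: 7}.items()}
        consensus, report = consensus_k(res)
        assert consensus == 6
        assert report["deviating"] == {10: 7}

    def test_unanimous(self):
        res = {k: KoptResult(per_K_BIC={2: 0.0}, K_opt=2) for k in (6, 7)}
        assert consensus_k(res)[0] == 2

    def test_tie_breaks_to_smaller(self):
        res = {6: KoptResult(per_K_BIC={5: 0.0}, K_opt=5),
               7: KoptResult(per_K_BIC={6: 0.0}, K_opt=6)}
        assert consensus_k(res)[0] == 5

    def test_too_few_entries_fatal(self):
        with pytest.raises(ValueError):
            consensus_k({6: KoptResult(per_K_BIC={2: 0.0}, K_opt=2)})
        with pytest.raises(ValueError):
            consensus_k({})
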