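import numpy as np
import pytest
from scipy import stats

from slipfret.synthetic import (KineticScheme, build_preset, simulate_traces,
                                stitch)
from slipfret.trace_io import TraceSet


class TestPresets:
    def test_cag10_states_and_means(self):
        s = build_preset("cag10")
        assert s.n_states == 8
        np.testing.assert_allclose(
            s.distinct_means, [0.08, 0.26, 0.43, 0.62, 0.79, 0.93])
        assert set(np.round(s.emission_sd, 2)) <= {0.05, 0.06}

    def test_middle_levels_doubly_degenerate(self):
        s = build_preset("cag10")
        counts = {m: int(np.sum(s.emission_mean == m))
                  for m in s.distinct_means}
        assert counts[0.43] == 2 and counts[0.62] == 2
        assert counts[0.08] == counts[0.26] == counts[0.79] == counts[0.93] == 1

    def test_degenerate_pair_exit_rates_differ_fourfold(self):
        s = build_preset("cag10")
        exit_rates = -np.diag(s.rate_matrix)
        for mean in (0.43, 0.62):
            pair = np.sort(exit_rates[s.emission_mean == mean])
            assert pair[1] / pair[0] == pytest.approx(4.0)

    def test_two_state_controls(self):
        for name in ("hairpin2", "static3wj", "fullcomp3wj"):
            s = build_preset(name)
            assert s.n_states == 2
            assert len(s.distinct_means) == 2

    def test_cag40_rates_are_half_of_cag10(self):
        a = build_preset("cag10").rate_matrix
        b = build_preset("cag40").rate_matrix
        off = ~np.eye(8, dtype=bool)
        np.testing.assert_allclose(b[off], a[off] / 2.0)

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(ValueError, match="hairpin2"):
            build_preset("nope")

    def test_rate_matrix_rows_sum_to_zero(self):
        for name in ("cag10", "cag40", "ctg30", "hairpin2"):
            q = build_preset(name).rate_matrix
            np.testing.assert_allclose(q.sum(axis=1), 0.0, atol=1e-12)

    def test_yaml_roundtrip(self, tmp_path):
        s = build_preset("cag10")
        s.to_yaml(tmp_path / "scheme.yaml")
        back = KineticScheme.from_yaml(tmp_path / "scheme.yaml")
        assert back.name == s.name
        np.testing.assert_allclose(back.rate_matrix, s.rate_matrix)
        np.testing.assert_allclose(back.emission_mean, s.emission_mean)
        assert back.level_offset_sd == s.level_offset_sd


class TestSchemeValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            KineticScheme("bad", np.array([[1.0, -1.0], [1.0, -1.0]]),
                          np.array([0.2, 0.8]), np.array([0.05, 0.05]))

    def test_mean_outside_unit_interval_rejected(self):
        q = np.array([[-1.0, 1.0], [1.0, -1.0]])
        with pytest.raises(ValueError):
            KineticScheme("bad", q, np.array([0.2, 1.2]),
                          np.array([0.05, 0.05]))


class TestSimulation:
    def test_one_state_constant_level(self):
        s = KineticScheme("one", np.zeros((1, 1)), np.array([0.6]),
                          np.array([0.05]), bleach_rate=0.0,
                          level_offset_sd=0.0)
        ts, gt = simulate_traces(s, n_traces=5, seed=3, max_duration=30.0)
        fret = np.concatenate([t.fret for t in ts])
        n = len(fret)
        assert abs(fret.mean() - 0.6) < 4 * 0.05 / np.sqrt(n)

    def test_two_state_occupancy_matches_stationary(self, two_state_scheme):
        ts, gt = simulate_traces(two_state_scheme, n_traces=200, seed=5,
                                 max_duration=30.0, min_frames=100)
        occ = gt.frame_occupancy()
        assert abs(occ[0] - 0.5) < 0.02

    def test_two_state_mean_dwell(self, two_state_scheme):
        ts, gt = simulate_traces(two_state_scheme, n_traces=200, seed=6,
                                 max_duration=30.0)
        d = gt.complete_dwells(0)
        sem = d.std(ddof=1) / np.sqrt(len(d))
        assert abs(d.mean() - 1.0) < 3 * sem

    def test_dwells_exponential_ks(self, two_state_scheme):
        # long traces so window truncation is negligible: interior dwells
        # must be Exp(1); KS at n = 10,000 must not reject at alpha = 0.001
        ts, gt = simulate_traces(two_state_scheme, n_traces=8, seed=7,
                                 max_duration=3000.0)
        d = gt.complete_dwells(0)
        assert len(d) >= 10000
        stat, p = stats.kstest(d[:10000], "expon", args=(0, 1.0))
        assert p > 0.001

    def test_same_seed_bit_identical(self, two_state_scheme):
        a, _ = simulate_traces(two_state_scheme, n_traces=5, seed=9)
        b, _ = simulate_traces(two_state_scheme, n_traces=5, seed=9)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.fret, tb.fret)
            np.testing.assert_array_equal(ta.donor, tb.donor)

    def test_cag40_ground_truth_dwells_double_cag10(self):
        t10, g10 = simulate_traces(build_preset("cag10"), n_traces=40, seed=2)
        t40, g40 = simulate_traces(build_preset("cag40"), n_traces=40, seed=2)
        # expected dwell per hidden state doubles exactly by construction
        np.testing.assert_allclose(build_preset("cag40").mean_dwell(),
                                   2.0 * build_preset("cag10").mean_dwell())
        for s in range(8):
            d10, d40 = g10.complete_dwells(s), g40.complete_dwells(s)
            ratio = d40.mean() / d10.mean()
            sem = ratio * np.sqrt(1 / len(d10) + 1 / len(d40))
            assert abs(ratio - 2.0) < 4 * sem

    def test_all_zero_rates_fatal(self):
        s = KineticScheme("frozen", np.zeros((2, 2)), np.array([0.2, 0.8]),
                          np.array([0.05, 0.05]))
        with pytest.raises(ValueError, match="no dynamics"):
            simulate_traces(s, n_traces=1, seed=0)

    def test_invalid_seed_fatal(self, two_state_scheme):
        with pytest.raises(ValueError, match="seed"):
            simulate_traces(two_state_scheme, n_traces=1, seed=-1)


class TestStitch:
    def test_length_is_sum(self, hairpin_traces):
        ts, _ = hairpin_traces
        st = stitch(ts)
        assert len(st) == ts.n_frames

    def test_single_trace_identity(self, hairpin_traces):
        ts, _ = hairpin_traces
        one = TraceSet(ts.sample_name, ts.traces[:1], ts.dt)
        st = stitch(one)
        np.testing.assert_array_equal(st.fret, ts.traces[0].fret)

    def test_constant_traces_make_boundary_jumps(self):
        traces = []
        means = [0.1, 0.5, 0.9]
        for i, m in enumerate(means):
            n = 50
            from slipfret.trace_io import Trace
            traces.append(Trace(f"c{i}", np.arange(n) * 0.05,
                                np.full(n, (1 - m) * 1000),
                                np.full(n, m * 1000), np.full(n, m)))
        st = stitch(TraceSet("flat", traces, 0.05))
        jumps = np.count_nonzero(np.diff(st.fret))
        assert jumps == len(means) - 1
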