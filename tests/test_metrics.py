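import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from eventarena import (AgentParams, ArenaGeometry, Location, LuckyShotSpec,
                        TrialLog, classify_lucky_shot, decompose_block1,
                        discrete_frechet, path_efficiency, path_length,
                        resample_polyline, summarize_trials,
                        trajectory_frechet)


def make_trial(xy, start=None, goal=None, phase="NPA", block=1, found=True):
    xy = np.asarray(xy, dtype=float)
    start = Location(*xy[0]) if start is None else start
    goal = Location(*xy[-1]) if goal is None else goal
    return TrialLog(participant_id="p0", room_id=0, phase=phase, block=block,
                    start=start, goal=goal, t=np.arange(len(xy), dtype=float),
                    xy=xy, found=found)


class TestPathLength:
    @pytest.mark.parametrize("pts,expected", [
        ([(0, 0), (3, 4)], 5.0),
        ([(0, 0), (0, 4), (3, 4)], 7.0),
    ])
    def test_known_lengths(self, pts, expected):
        assert path_length(pts) == pytest.approx(expected)

    def test_closed_loop_has_positive_length(self):
        loop = [(0, 0), (3, 0), (3, 3), (0, 0)]
        assert path_length(loop) > 0

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            path_length([(1, 1)])


class TestPathEfficiency:
    def test_straight_path_is_one(self):
        trial = make_trial([(0, 0), (3, 4)])
        assert path_efficiency(trial) == pytest.approx(1.0)

    def test_detour_ratio(self):
        trial = make_trial([(0, 0), (0, 4), (3, 4)], goal=Location(3, 4))
        assert path_efficiency(trial) == pytest.approx(1.4)

    def test_contact_radius_termination_gives_pe_below_one(self):
        # trial ends 1 a.u. short of the goal center; denominator is full ED
        trial = make_trial([(0, 0), (9, 0)], goal=Location(10, 0))
        assert 0.85 < path_efficiency(trial) < 1.0

    def test_zero_optimal_length_rejected(self):
        trial = make_trial([(1, 1), (2, 2), (1, 1)], goal=Location(1, 1))
        with pytest.raises(ValueError):
            path_efficiency(trial)


class TestResample:
    def test_unit_spacing_on_segment(self):
        out = resample_polyline([(0, 0), (4, 0)], step=1.0)
        np.testing.assert_allclose(out[:, 0], np.arange(5.0))
        np.testing.assert_allclose(out[:, 1], 0.0)

    def test_large_step_keeps_endpoints(self):
        out = resample_polyline([(0, 0), (1, 1), (5, 5)], step=100.0)
        np.testing.assert_allclose(out, [[0, 0], [5, 5]])

    @given(hst.lists(hst.tuples(hst.floats(-50, 50), hst.floats(-50, 50)),
                     min_size=2, max_size=8),
           hst.floats(0.1, 5.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_resampled_length_matches_original(self, pts, step):
        original = path_length(pts)
        resampled = resample_polyline(pts, step)
        if original > 0:
            assert path_length(resampled) == pytest.approx(original, abs=1e-6)


def brute_force_frechet(P, Q):
    """Minimax over all monotone couplings (exhaustive oracle)."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)

    def couplings(i, j):
        if i == len(P) - 1 and j == len(Q) - 1:
            yield [(i, j)]
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ni, nj = i + di, j + dj
            if ni < len(P) and nj < len(Q):
                for rest in couplings(ni, nj):
                    yield [(i, j)] + rest

    best = np.inf
    for coupling in couplings(0, 0):
        worst = max(np.hypot(*(P[i] - Q[j])) for i, j in coupling)
        best = min(best, worst)
    return best


class TestDiscreteFrechet:
    def test_identical_sequences_are_zero(self):
        pts = [(0, 0), (1, 2), (3, 3)]
        assert discrete_frechet(pts, pts) == 0.0

    @pytest.mark.parametrize("P,Q,expected", [
        ([(0, 0), (4, 0)], [(0, 3), (4, 3)], 3.0),
        ([(0, 0), (2, 0), (4, 0)], [(0, 0), (4, 0)], 2.0),
    ])
    def test_known_values_match_brute_force(self, P, Q, expected):
        assert discrete_frechet(P, Q) == pytest.approx(expected)
        assert brute_force_frechet(P, Q) == pytest.approx(expected)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            discrete_frechet([], [(0, 0)])

    @given(hst.integers(1, 5), hst.integers(1, 5), hst.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_exhaustive_oracle(self, n, m, seed):
        rng = np.random.default_rng(seed)
        P = rng.uniform(0, 10, size=(n, 2))
        Q = rng.uniform(0, 10, size=(m, 2))
        assert discrete_frechet(P, Q) == pytest.approx(
            brute_force_frechet(P, Q), abs=1e-10)

    @given(hst.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_symmetry_and_endpoint_bound(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.uniform(0, 10, size=(rng.integers(1, 7), 2))
        Q = rng.uniform(0, 10, size=(rng.integers(1, 7), 2))
        d = discrete_frechet(P, Q)
        assert d == pytest.approx(discrete_frechet(Q, P))
        assert d >= np.hypot(*(P[0] - Q[0])) - 1e-12
        assert d >= np.hypot(*(P[-1] - Q[-1])) - 1e-12


class TestLuckyShot:
    def test_straight_trajectory_is_lucky(self):
        xy = np.column_stack([np.linspace(0, 20, 40), np.linspace(0, 15, 40)])
        assert classify_lucky_shot(make_trial(xy)) is True

    def test_large_deviation_is_not_lucky(self):
        xy = np.array([(0, 0), (10, 10), (20, 0)], float)
        trial = make_trial(xy, goal=Location(20, 0))
        assert classify_lucky_shot(trial) is False

    def test_zigzag_with_high_pe_is_still_lucky(self):
        # amplitude below the cutoff but ~31% extra path length
        x = np.linspace(0, 30, 301)
        y = 2.8 * np.sin(x * 2.0)
        trial = make_trial(np.column_stack([x, y]), goal=Location(30, 0))
        assert path_efficiency(trial) > 1.25
        assert classify_lucky_shot(trial) is True

    def test_restricted_to_naive_block(self):
        trial = make_trial([(0, 0), (5, 5)], phase="NPA", block=2)
        with pytest.raises(ValueError):
            classify_lucky_shot(trial)

    def test_classification_invariant_to_vertex_density(self):
        x = np.linspace(0, 25, 6)
        sparse = np.column_stack([x, 3.0 * np.sin(x)])
        trial_sparse = make_trial(sparse, goal=Location(25, 3.0 * np.sin(25)))
        dense = resample_polyline(sparse, 0.05)
        trial_dense = make_trial(dense, start=trial_sparse.start,
                                 goal=trial_sparse.goal)
        assert (classify_lucky_shot(trial_sparse)
                == classify_lucky_shot(trial_dense))


class TestDecomposeBlock1:
    def _table(self, frechets, pes):
        return pd.DataFrame({"room": np.arange(len(pes)),
                             "pe": pes, "frechet": frechets})

    def test_all_lucky_get_imputed_constant(self):
        out = decompose_block1(self._table([0.1, 0.2, 0.3], [1.0, 1.1, 1.05]))
        assert out["lucky"].tolist() == [1, 1, 1]
        assert out["residual_pe"].nunique() == 1

    def test_no_lucky_keeps_raw_pe(self):
        pes = [4.0, 5.5, 6.1]
        out = decompose_block1(self._table([8, 9, 10], pes))
        assert out["lucky"].tolist() == [0, 0, 0]
        np.testing.assert_allclose(out["residual_pe"], pes)

    def test_mixed_indicator_count_matches_cutoff(self):
        frechets = [1.0, 5.0, 3.4, 3.6, 0.0]
        out = decompose_block1(self._table(frechets, [1.0] * 5))
        assert out["lucky"].sum() == sum(f <= 3.5 for f in frechets)

    def test_missing_rooms_reported(self):
        with pytest.raises(ValueError, match=r"\[3, 4\]"):
            decompose_block1(self._table([1, 2], [1, 2]),
                             expected_rooms=[0, 1, 3, 4])


class TestCohortMetrics:
    def test_pe_and_time_strongly_correlated(self, trial_metrics):
        r = np.corrcoef(trial_metrics["pe"], trial_metrics["time_to_goal"])[0, 1]
        assert r > 0.9

    def test_lucky_flag_only_on_naive_block(self, trial_metrics):
        flagged = trial_metrics[trial_metrics["lucky"].notna()]
        assert set(flagged["phase"]) == {"NPA"}
        assert set(flagged["block"]) == {1}
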