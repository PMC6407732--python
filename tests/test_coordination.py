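import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazepair import coordination as co
from gazepair.data import HighlightLog, TrialRecord
from gazepair.errors import InvalidMatrixError, UndefinedMetricError
from gazepair.events import Dwell


def _dwell(hex_id, onset, offset=None):
    offset = onset + 0.25 if offset is None else offset
    return Dwell(hex_id, onset, offset, 1, (0.0, 0.0), (0.0, 0.0))


def _log_from_intervals(intervals, frame_rate=60.0, end=None):
    """HighlightLog showing hex h over [t0, t1) for each (h, t0, t1)."""
    end = end or max(t1 for _, _, t1 in intervals)
    n = int(round(end * frame_rate))
    frame_t = (np.arange(n) + 1) / frame_rate
    hexes = np.full(n, -1)
    for h, t0, t1 in intervals:
        hexes[(frame_t >= t0) & (frame_t < t1)] = h
    return HighlightLog(frame_t, hexes, frame_rate)


def _trial(target, rt, correct=True):
    return TrialRecord("individual", target, "a", target if correct else 0, rt, correct, 0)


class TestDwellOverlap:
    def test_only_prior_durable_highlights_count(self):
        own = [_dwell(1, 1.0), _dwell(2, 2.0), _dwell(3, 3.0)]
        log = _log_from_intervals([(2, 0.5, 1.5), (3, 4.0, 5.0)])
        assert co.dwell_overlap_proportion(own, log) == pytest.approx(1 / 3)

    def test_empty_partner_log_gives_zero(self):
        own = [_dwell(1, 1.0), _dwell(2, 2.0)]
        log = HighlightLog(np.empty(0), np.empty(0, dtype=int))
        assert co.dwell_overlap_proportion(own, log) == 0.0

    def test_everything_prehighlighted_gives_one(self):
        own = [_dwell(h, 2.0 + 0.3 * h) for h in range(5)]
        log = _log_from_intervals([(h, 0.1 * h, 0.1 * h + 0.2) for h in range(5)], end=2.0)
        assert co.dwell_overlap_proportion(own, log) == 1.0

    def test_flicker_runs_are_ignored(self):
        own = [_dwell(2, 2.0)]
        # one 2-frame (33 ms) highlight of hex 2: measurement error, ignored
        log = _log_from_intervals([(2, 0.5, 0.534)], end=1.0)
        assert co.dwell_overlap_proportion(own, log) == 0.0

    def test_no_dwells_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            co.dwell_overlap_proportion([], _log_from_intervals([(1, 0.0, 1.0)]))


class TestCumulativeOverlap:
    def test_starts_at_zero(self):
        curve = co.cumulative_overlap_curve({0: 0.0}, {0: 0.0}, duration=1.0)
        assert curve.time[0] == 0.0
        assert curve.value[0] == 0.0

    def test_set_intersection_by_hand(self):
        a = {0: 0.1, 1: 0.2, 2: 0.3}
        b = {2: 0.15, 3: 0.4}
        curve = co.cumulative_overlap_curve(a, b, duration=1.0)
        assert curve.value[-1] == pytest.approx(1 / 25)

    def test_full_coverage_reaches_one(self):
        a = {h: 0.01 * h for h in range(25)}
        b = {h: 0.02 * h for h in range(25)}
        curve = co.cumulative_overlap_curve(a, b, duration=2.0)
        assert curve.value[-1] == pytest.approx(1.0)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        a = {h: float(rng.uniform(0, 3)) for h in rng.choice(25, 15, replace=False)}
        b = {h: float(rng.uniform(0, 3)) for h in rng.choice(25, 15, replace=False)}
        curve = co.cumulative_overlap_curve(a, b, duration=3.0)
        assert np.all(np.diff(curve.value) >= 0)
        assert np.all((curve.value >= 0) & (curve.value <= 1))


class TestAggregateCurves:
    def _curve(self, values, frame_rate=60.0):
        t = np.arange(len(values)) / frame_rate
        return co.OverlapCurve(t, np.asarray(values, dtype=float))

    def test_identical_curves_have_zero_width_band(self):
        curves = [self._curve([0, 0.2, 0.4])] * 5
        agg = co.aggregate_overlap_curves(curves, n_boot=200, seed=1)
        assert np.allclose(agg.lo, agg.hi)
        assert np.allclose(agg.mean, [0, 0.2, 0.4])

    def test_single_curve_mean_is_that_curve(self):
        agg = co.aggregate_overlap_curves([self._curve([0, 0.1, 0.3])], n_boot=50, seed=0)
        assert np.allclose(agg.mean, [0, 0.1, 0.3])

    def test_two_curves_band_endpoints_enumerable(self):
        curves = [self._curve([0.2, 0.2]), self._curve([0.4, 0.4])]
        agg = co.aggregate_overlap_curves(curves, n_boot=500, seed=2)
        assert agg.mean[0] == pytest.approx(0.3)
        # all 4 equally likely resamples average to 0.2, 0.3, 0.3 or 0.4
        assert agg.lo[0] in (0.2, 0.3, 0.4)
        assert agg.hi[0] in (0.2, 0.3, 0.4)

    def test_trials_of_unequal_length_average_only_alive(self):
        curves = [self._curve([0, 0.5]), self._curve([0, 0.1, 0.9])]
        agg = co.aggregate_overlap_curves(curves, n_boot=50, seed=0)
        assert agg.n_alive.tolist() == [2, 2, 1]
        assert agg.mean[2] == pytest.approx(0.9)


class TestBlindBaseline:
    def test_faster_member_wins(self):
        a = [_trial(5, 3.0, correct=True)]
        b = [_trial(5, 4.0, correct=False)]
        base = co.blind_baseline(a, b)
        assert base.n_matched == 1
        bt = base.trials[0]
        assert (bt.target_hex, bt.rt, bt.correct, bt.source) == (5, 3.0, True, "a")

    def test_disjoint_targets_match_nothing(self):
        base = co.blind_baseline([_trial(5, 1.0)], [_trial(9, 1.0)])
        assert base.n_matched == 0

    def test_greedy_matching_in_order_of_occurrence(self):
        a = [_trial(5, 1.0), _trial(5, 2.0), _trial(9, 3.0)]
        b = [_trial(5, 1.5), _trial(9, 2.5), _trial(9, 3.5)]
        base = co.blind_baseline(a, b)
        assert base.n_matched == 2
        assert sorted(t.target_hex for t in base.trials) == [5, 9]

    def test_rt_tie_goes_to_first_searcher(self):
        base = co.blind_baseline([_trial(5, 2.0, True)], [_trial(5, 2.0, False)])
        assert base.trials[0].source == "a"
        assert base.trials[0].correct is True

    def test_matches_brute_force_oracle_on_random_sets(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            a = [_trial(int(rng.integers(0, 6)), float(rng.uniform(1, 5))) for _ in range(12)]
            b = [_trial(int(rng.integers(0, 6)), float(rng.uniform(1, 5))) for _ in range(12)]
            base = co.blind_baseline(a, b)
            # oracle: per target, pair the k-th occurrences in each list
            expected = []
            for target in range(6):
                qa = [t for t in a if t.target_hex == target]
                qb = [t for t in b if t.target_hex == target]
                for ta, tb in zip(qa, qb):
                    expected.append(min(ta.rt, tb.rt))
            assert base.n_matched == len(expected)
            assert np.allclose(sorted(t.rt for t in base.trials), sorted(expected))

    def test_baseline_median_below_individual_medians_on_simulated_session(self):
        # each artificial trial takes the faster member, so the baseline
        # runs faster than either searcher alone
        from gazepair.simulate import simulate_session

        sess = simulate_session(40, conditions=("individual",), seed=3)
        ra = [r.record for r in sess.individual["a"]]
        rb = [r.record for r in sess.individual["b"]]
        base = co.blind_baseline(ra, rb)
        assert base.n_matched > 0
        med = np.median([t.rt for t in base.trials])
        assert med < np.median([t.rt for t in ra])
        assert med < np.median([t.rt for t in rb])

    def test_exponential_rts_baseline_mean_halves(self):
        # min of two iid Exp(mu) trials is Exp(mu/2); matched-target pairing
        # preserves independence, so the baseline mean converges to mu / 2.
        rng = np.random.default_rng(23)
        mu = 4.0
        n = 6000
        targets = rng.integers(0, 24, size=n)
        a = [_trial(int(h), float(rng.exponential(mu))) for h in targets]
        b = [_trial(int(h), float(rng.exponential(mu))) for h in rng.permutation(targets)]
        base = co.blind_baseline(a, b)
        mean_rt = np.mean([t.rt for t in base.trials])
        assert mean_rt == pytest.approx(mu / 2, rel=0.05)


def _entropy_oracle(m):
    """Direct double-loop summation of both entropy variants."""
    m = np.asarray(m, dtype=float)
    total = m.sum()
    joint = 0.0
    cond = 0.0
    origin = m.sum(axis=1)
    for i in range(m.shape[0]):
        for j in range(m.shape[1]):
            if m[i, j] > 0:
                p = m[i, j] / total
                joint -= p * math.log2(p)
                pj = m[i, j] / origin[i]
                cond -= (origin[i] / total) * pj * math.log2(pj)
    return cond, joint


class TestEntropy:
    def test_uniform_dwell_distribution_is_log2_25(self):
        assert co.dwell_distribution_entropy(np.ones(25)) == pytest.approx(math.log2(25))

    def test_single_element_dwells_have_zero_entropy(self):
        c = np.zeros(25)
        c[3] = 17
        assert co.dwell_distribution_entropy(c) == 0.0

    def test_small_count_vector_by_hand(self):
        assert co.dwell_distribution_entropy([2, 1, 1]) == pytest.approx(1.5)

    def test_all_zero_counts_undefined(self):
        with pytest.raises(UndefinedMetricError):
            co.dwell_distribution_entropy(np.zeros(25))

    def test_uniform_transitions_joint_and_conditional_maxima(self):
        m = np.ones((25, 25))
        np.fill_diagonal(m, 0)
        te = co.transition_entropy(m)
        assert round(te.joint, 2) == 9.23  # log2(600)
        assert te.conditional == pytest.approx(math.log2(24))

    def test_deterministic_cycle(self):
        m = np.zeros((25, 25))
        for i in range(25):
            m[i, (i + 1) % 25] = 7
        te = co.transition_entropy(m)
        assert te.conditional == pytest.approx(0.0, abs=1e-12)
        assert te.joint == pytest.approx(math.log2(25))

    def test_nonzero_diagonal_rejected(self):
        m = np.ones((25, 25))
        with pytest.raises(InvalidMatrixError):
            co.transition_entropy(m)

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            m = rng.integers(0, 20, size=(5, 5)).astype(float)
            np.fill_diagonal(m, 0)
            if m.sum() == 0:
                continue
            cond, joint = _entropy_oracle(m)
            te = co.transition_entropy(m)
            assert te.conditional == pytest.approx(cond, abs=1e-12)
            assert te.joint == pytest.approx(joint, abs=1e-12)
            assert te.joint >= te.conditional - 1e-12

    def test_joint_decomposes_into_conditional_plus_origin_entropy(self):
        rng = np.random.default_rng(9)
        m = rng.integers(0, 30, size=(6, 6)).astype(float)
        np.fill_diagonal(m, 0)
        te = co.transition_entropy(m)
        origin = m.sum(axis=1)
        h_origin = co.dwell_distribution_entropy(origin)
        assert te.joint == pytest.approx(te.conditional + h_origin, abs=1e-12)


class TestPerformance:
    def test_all_correct_fixed_rt(self):
        trials = [_trial(1, 2.0, True) for _ in range(10)]
        perf = co.performance_summary(trials)
        assert perf.targets_per_second == pytest.approx(0.5)
        assert perf.error_rate == 0.0

    def test_all_wrong_gives_zero_rate(self):
        trials = [_trial(1, 2.0, False) for _ in range(4)]
        assert co.performance_summary(trials).targets_per_second == 0.0

    def test_mixed_by_hand(self):
        trials = [_trial(1, 2.0, c) for c in (True, True, True, False)]
        perf = co.performance_summary(trials)
        assert perf.error_rate == pytest.approx(0.25)
        assert perf.targets_per_second == pytest.approx(3 / 8)


class TestHeatmap:
    def test_single_dwell_peaks_at_its_location(self):
        x, y, z = co.overlap_heatmap([(0.0, 0.0)])
        j, i = np.unravel_index(np.argmax(z), z.shape)
        assert abs(x[i]) < 1e-9 and abs(y[j]) < 1e-9

    def test_empty_input_gives_zero_map(self):
        _, _, z = co.overlap_heatmap(np.empty((0, 2)))
        assert np.all(z == 0)

    def test_two_distant_dwells_have_equal_maxima(self):
        x, y, z = co.overlap_heatmap([(-5.0, 0.0), (5.0, 0.0)], sigma=1.0)
        left = z[:, x < 0].max()
        right = z[:, x > 0].max()
        assert left == pytest.approx(right, abs=1e-6)

    def test_floor_removes_low_density(self):
        _, _, z = co.overlap_heatmap([(0.0, 0.0)], floor=0.10)
        nonzero = z[z > 0]
        assert nonzero.min() >= 0.10 * z.max()


class TestRatingCorrelation:
    def test_perfect_negative_relation(self):
        x = np.arange(10.0)
        res = co.rating_overlap_correlation(x, -2 * x + 3)
        assert res.r == pytest.approx(-1.0)

    def test_constant_variable_undefined(self):
        with pytest.raises(UndefinedMetricError):
            co.rating_overlap_correlation(np.ones(5), np.arange(5.0))

    def test_t_statistic_closed_form_at_known_r(self):
        # construct n=17 data with sample correlation exactly -0.79
        rng = np.random.default_rng(1)
        n, r = 17, -0.79
        x = rng.normal(size=n)
        e = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        e = e - e.mean()
        e -= (e @ x) / (x @ x) * x  # orthogonalise
        e /= e.std()
        y = r * x + math.sqrt(1 - r**2) * e
        res = co.rating_overlap_correlation(x, y)
        assert res.r == pytest.approx(r, abs=1e-9)
        assert res.df == 15
        assert res.t == pytest.approx(-4.99, abs=0.01)


@given(st.lists(st.integers(0, 24), min_size=2, max_size=40))
@settings(max_examples=50, deadline=None)
def test_transition_counts_have_zero_diagonal_and_match_sequence_length(seq):
    dwells = []
    for i, h in enumerate(seq):
        if not dwells or dwells[-1].hex != h:
            dwells.append(_dwell(h, 0.3 * i))
    m = co.transition_counts([dwells])
    assert np.all(np.diagonal(m) == 0)
    assert m.sum() == len(dwells) - 1
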