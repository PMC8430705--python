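"""Directionality ratio, MSD, α and VAC: closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from cellmotility import (CurveSeries, aggregate_curves,
                          directionality_ratio_curve, loglog_alpha, msd_curve,
                          step_vectors, velocity_autocorrelation)
from cellmotility.persistence import ZeroMotionError
from tests.conftest import make_track

finite_steps = hnp.arrays(
    dtype=float, shape=st.tuples(st.integers(3, 12), st.just(2)),
    elements=st.floats(-5, 5, allow_nan=False, width=32))


def track_from_steps(steps):
    pos = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
    return make_track(pos, dt=30.0)


# ---------------------------------------------------------------- step vectors
class TestStepVectors:
    def test_toy_arithmetic(self):
        t = make_track([[0, 0], [1, 0], [1, 1]])
        vec, lengths = step_vectors(t)
        np.testing.assert_array_equal(vec, [[1, 0], [0, 1]])
        np.testing.assert_array_equal(lengths, [1, 1])

    def test_stationary_gives_zero_vectors(self):
        vec, lengths = step_vectors(make_track(np.ones((5, 2))))
        assert np.all(vec == 0) and np.all(lengths == 0)

    def test_reversed_track_negates_vectors(self, random_walk_track):
        vec, _ = step_vectors(random_walk_track)
        rev = make_track(random_walk_track.positions[::-1])
        vec_r, _ = step_vectors(rev)
        np.testing.assert_allclose(vec_r, -vec[::-1])


# ---------------------------------------------------------- directionality ratio
class TestDirectionalityRatio:
    def test_straight_track_is_one_everywhere(self, ballistic_track):
        dr = directionality_ratio_curve(ballistic_track)
        np.testing.assert_allclose(dr.mean, 1.0, rtol=1e-12)

    def test_out_and_back_ends_at_zero(self):
        dr = directionality_ratio_curve(make_track([[0, 0], [1, 0], [0, 0]]))
        np.testing.assert_allclose(dr.mean, [1.0, 0.0], atol=1e-15)

    def test_right_angle_toy_value(self):
        # displacement sqrt(2) over path length 2
        dr = directionality_ratio_curve(make_track([[0, 0], [1, 0], [1, 1]]))
        assert dr.mean[-1] == pytest.approx(np.sqrt(2) / 2, abs=1e-12)

    def test_motionless_prefix_defined_as_one(self):
        dr = directionality_ratio_curve(
            make_track([[0, 0], [0, 0], [1, 0], [2, 0]]))
        assert dr.mean[0] == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(steps=finite_steps)
    def test_bounded_and_first_point_one(self, steps):
        dr = directionality_ratio_curve(track_from_steps(steps))
        assert np.all((dr.mean >= 0) & (dr.mean <= 1))
        assert dr.mean[0] == pytest.approx(1.0)

    def test_lag_grid_in_minutes(self):
        dr = directionality_ratio_curve(make_track([[0, 0], [1, 0], [1, 1]]))
        np.testing.assert_array_equal(dr.lag_minutes, [30.0, 60.0])


# ------------------------------------------------------------------------- MSD
def msd_bruteforce(pos, n):
    acc = [np.sum((pos[i + n] - pos[i]) ** 2)
           for i in range(len(pos) - n)]
    return float(np.mean(acc))


class TestMSD:
    def test_ballistic_closed_form(self, ballistic_track):
        # speed 1 um/frame -> MSD(n) = (n * step)^2
        msd = msd_curve(ballistic_track)
        n = np.arange(1, 48)
        np.testing.assert_allclose(msd.mean, n**2.0, rtol=1e-12)

    def test_stationary_is_zero(self):
        msd = msd_curve(make_track(np.ones((6, 2)) * 3.0))
        np.testing.assert_array_equal(msd.mean, 0.0)

    def test_four_point_toy_equals_double_loop(self):
        pos = np.array([[0, 0], [1, 0], [1, 2], [-1, 3]], dtype=float)
        msd = msd_curve(make_track(pos))
        expected = [msd_bruteforce(pos, n) for n in (1, 2, 3)]
        np.testing.assert_allclose(msd.mean, expected, rtol=1e-14)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(steps=finite_steps)
    def test_equals_bruteforce_on_random_tracks(self, steps):
        t = track_from_steps(steps)
        msd = msd_curve(t)
        expected = [msd_bruteforce(t.positions, n)
                    for n in range(1, len(t.positions))]
        np.testing.assert_allclose(msd.mean, expected, rtol=1e-10, atol=1e-12)


# ----------------------------------------------------------------------- alpha
class TestLogLogAlpha:
    def test_ballistic_alpha_two(self, ballistic_track):
        res = loglog_alpha(msd_curve(ballistic_track))
        assert res.alpha == pytest.approx(2.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0)

    def test_linear_msd_alpha_one(self):
        n = np.arange(1, 24)
        msd = CurveSeries(kind="msd", lag_minutes=n * 30.0, mean=7.5 * n,
                          sem=np.full(23, np.nan))
        assert loglog_alpha(msd, (1, 23)).alpha == pytest.approx(1.0, abs=1e-12)

    def test_default_fit_window_is_first_half(self, ballistic_track):
        res = loglog_alpha(msd_curve(ballistic_track))
        assert res.fit_lag_range == (1, 23)

    def test_zero_msd_dropped_with_warning_then_error_if_too_few(self):
        mean = np.array([0.0, 4.0, 9.0, 0.0, 25.0])
        msd = CurveSeries(kind="msd", lag_minutes=np.arange(1, 6) * 30.0,
                          mean=mean, sem=np.full(5, np.nan))
        with pytest.warns(UserWarning, match="non-positive"):
            res = loglog_alpha(msd, (1, 5))
        assert np.isfinite(res.alpha)
        tiny = CurveSeries(kind="msd", lag_minutes=np.arange(1, 5) * 30.0,
                           mean=np.array([0.0, 0.0, 1.0, 2.0]),
                           sem=np.full(4, np.nan))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="fewer than 3"):
                loglog_alpha(tiny, (1, 4))


# ------------------------------------------------------------------------- VAC
def vac_bruteforce(pos, n):
    v = np.diff(pos, axis=0)
    m = len(v)
    num = np.mean([v[i] @ v[i + n] for i in range(m - n)])
    den = np.mean([v[i] @ v[i] for i in range(m)])
    return num / den


class TestVelocityAutocorrelation:
    def test_constant_velocity_all_ones(self, ballistic_track):
        vac = velocity_autocorrelation(ballistic_track)
        np.testing.assert_allclose(vac.mean, 1.0, rtol=1e-12)

    def test_vac_zero_lag_is_exactly_one(self, random_walk_track):
        vac = velocity_autocorrelation(random_walk_track)
        assert vac.lag_minutes[0] == 0.0
        assert vac.mean[0] == 1.0

    def test_alternating_steps_give_minus_one_at_lag_one(self):
        pos = np.array([[0, 0], [1, 0], [0, 0], [1, 0], [0, 0]], dtype=float)
        vac = velocity_autocorrelation(make_track(pos))
        assert vac.mean[1] == pytest.approx(-1.0)

    def test_five_step_toy_equals_bruteforce(self):
        pos = np.array([[0, 0], [1, 0], [1, 2], [-1, 3], [0, 5], [2, 4]],
                       dtype=float)
        vac = velocity_autocorrelation(make_track(pos))
        expected = [vac_bruteforce(pos, n) for n in range(5)]
        np.testing.assert_allclose(vac.mean, expected, rtol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(steps=finite_steps)
    def test_equals_bruteforce_on_random_tracks(self, steps):
        t = track_from_steps(steps)
        if np.all(np.linalg.norm(steps, axis=1) == 0):
            with pytest.raises(ZeroMotionError):
                velocity_autocorrelation(t)
            return
        vac = velocity_autocorrelation(t)
        expected = [vac_bruteforce(t.positions, n)
                    for n in range(len(vac.mean))]
        np.testing.assert_allclose(vac.mean, expected, rtol=1e-10, atol=1e-10)

    def test_stationary_track_raises_naming_cell(self):
        t = make_track(np.zeros((6, 2)), cell_id="frozen")
        with pytest.raises(ZeroMotionError, match="frozen"):
            velocity_autocorrelation(t)


# ----------------------------------------------------------------- aggregation
class TestAggregateCurves:
    def _const_dr(self, value, n=5):
        return CurveSeries(kind="directionality_ratio",
                           lag_minutes=np.arange(1, n + 1) * 30.0,
                           mean=np.full(n, value), sem=np.full(n, np.nan))

    def test_identical_curves_mean_equals_curve_sem_zero(self):
        agg = aggregate_curves([self._const_dr(0.3)] * 4,
                               line_ids=list("aabb"))
        np.testing.assert_allclose(agg.mean, 0.3)
        np.testing.assert_allclose(agg.sem, 0.0)
        assert agg.n_units == 2

    def test_two_line_arithmetic(self):
        agg = aggregate_curves([self._const_dr(0.2), self._const_dr(0.4)],
                               line_ids=["L1", "L2"])
        np.testing.assert_allclose(agg.mean, 0.3)
        np.testing.assert_allclose(agg.sem, 0.1)

    def test_hierarchical_differs_from_pooled_with_unequal_cells(self):
        # line A: 3 cells at 0.2; line B: 1 cell at 0.8
        curves = [self._const_dr(0.2)] * 3 + [self._const_dr(0.8)]
        lines = ["A", "A", "A", "B"]
        hier = aggregate_curves(curves, line_ids=lines)
        pooled = aggregate_curves(curves, pooled=True)
        # explicit two-stage oracle: mean of line means
        np.testing.assert_allclose(hier.mean, (0.2 + 0.8) / 2)
        np.testing.assert_allclose(pooled.mean, (3 * 0.2 + 0.8) / 4)
        assert not np.allclose(hier.mean, pooled.mean)

    def test_invariant_to_cell_and_line_order(self, rng):
        curves, lines = [], []
        for lid in ("L1", "L2", "L3"):
            for _ in range(3):
                vals = rng.random(5)
                curves.append(CurveSeries(
                    kind="msd", lag_minutes=np.arange(1, 6) * 30.0,
                    mean=vals, sem=np.full(5, np.nan)))
                lines.append(lid)
        a = aggregate_curves(curves, line_ids=lines)
        perm = rng.permutation(len(curves))
        b = aggregate_curves([curves[i] for i in perm],
                             line_ids=[lines[i] for i in perm])
        np.testing.assert_allclose(a.mean, b.mean)
        np.testing.assert_allclose(a.sem, b.sem)

    def test_mismatched_lag_grids_error(self):
        a = self._const_dr(0.5, n=5)
        b = self._const_dr(0.5, n=6)
        with pytest.raises(ValueError, match="lag grid"):
            aggregate_curves([a, b], pooled=True)
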