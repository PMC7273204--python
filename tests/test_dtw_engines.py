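"""The shared dynamic program and the four alignment engines."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist

from conftest import brute_force_min_cost
from eventdtw import (
    ParameterError,
    SignalError,
    Signal,
    derivative_dtw_align,
    dtw_align,
    event_dtw_align,
    make_uniform_signal,
    shape_dtw_align,
)
from eventdtw.dtw_engines import keogh_derivative


def assert_valid_path(path):
    path.validate()
    assert len(path) >= max(path.n_r, path.n_q)
    assert path.per_q_counts().sum() == len(path)


values = st.lists(
    st.floats(-10, 10, allow_nan=False, allow_infinity=False),
    min_size=2,
    max_size=50,
)


class TestClassicDTW:
    def test_identical_signals_give_diagonal(self, sine100):
        path = dtw_align(sine100, sine100)
        np.testing.assert_array_equal(path.links[:, 0], path.links[:, 1])
        assert (path.per_q_counts() == 1).all()
        assert path.cost == 0.0

    def test_toy_matches_exhaustive_minimum(self):
        r = make_uniform_signal([1.0, 3.0, 2.0, 0.0])
        q = make_uniform_signal([1.0, 3.0, 0.0])
        path = dtw_align(r, q)
        cost = np.abs(r.values[:, None] - q.values[None, :])
        assert path.cost == pytest.approx(brute_force_min_cost(cost), abs=1e-12)
        assert_valid_path(path)

    def test_rejects_short_signal(self):
        with pytest.raises(SignalError):
            dtw_align(make_uniform_signal([1.0]), make_uniform_signal([1.0, 2.0]))

    @given(values, values)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_path_invariants_random_inputs(self, rv, qv):
        path = dtw_align(make_uniform_signal(rv), make_uniform_signal(qv))
        assert_valid_path(path)


class TestDerivativeDTW:
    def test_keogh_estimator_hand_values(self):
        # interior: ((v_i - v_{i-1}) + (v_{i+1} - v_{i-1}) / 2) / 2
        d = keogh_derivative(np.array([0.0, 1.0, 4.0, 9.0]))
        assert d[1] == pytest.approx((1.0 + 4.0 / 2) / 2)
        assert d[2] == pytest.approx((3.0 + 8.0 / 2) / 2)
        assert d[0] == d[1] and d[3] == d[2]

    def test_identical_ramps_diagonal(self):
        ramp = make_uniform_signal(np.linspace(0, 5, 12))
        path = derivative_dtw_align(ramp, ramp)
        np.testing.assert_array_equal(path.links[:, 0], path.links[:, 1])

    def test_amplitude_offset_invisible(self):
        base = np.array([0.0, 1.0, 3.0, 4.0, 2.0, 1.0])
        r = make_uniform_signal(base)
        q = make_uniform_signal(base + 10.0)
        path = derivative_dtw_align(r, q)
        np.testing.assert_array_equal(path.links[:, 0], path.links[:, 1])
        assert path.cost == pytest.approx(0.0, abs=1e-12)

    def test_constant_signals_degenerate_tiebreak(self):
        r = make_uniform_signal(np.full(5, 2.0))
        q = make_uniform_signal(np.full(5, 9.0))
        path = derivative_dtw_align(r, q)
        # zero cost everywhere: the diagonal-first tie-break pins the
        # canonical stair-free path
        np.testing.assert_array_equal(path.links[:, 0], path.links[:, 1])

    def test_rejects_length_two(self):
        s2 = make_uniform_signal([1.0, 2.0])
        with pytest.raises(SignalError):
            derivative_dtw_align(s2, s2)

    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=3, max_size=30),
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=3, max_size=30),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_path_invariants_random_inputs(self, rv, qv):
        path = derivative_dtw_align(make_uniform_signal(rv), make_uniform_signal(qv))
        assert_valid_path(path)


class TestShapeDTW:
    def test_window_one_equals_plain_dtw(self, rng):
        r = make_uniform_signal(rng.normal(size=15))
        q = make_uniform_signal(rng.normal(size=11))
        np.testing.assert_array_equal(
            shape_dtw_align(r, q, 1).links, dtw_align(r, q).links
        )

    def test_identical_signals_diagonal(self, sine100):
        path = shape_dtw_align(sine100, sine100, 5)
        np.testing.assert_array_equal(path.links[:, 0], path.links[:, 1])

    def test_even_window_rejected(self, sine100):
        with pytest.raises(ParameterError):
            shape_dtw_align(sine100, sine100, 4)

    def test_toy_matches_exhaustive_minimum(self, rng):
        r = make_uniform_signal(rng.normal(size=6))
        q = make_uniform_signal(rng.normal(size=5))
        path = shape_dtw_align(r, q, 3)
        # independent descriptor construction: explicit edge-padded windows
        def desc(v):
            p = np.concatenate([[v[0]], v, [v[-1]]])
            return np.array([p[i : i + 3] for i in range(len(v))])

        cost = cdist(desc(r.values), desc(q.values))
        assert path.cost == pytest.approx(brute_force_min_cost(cost), abs=1e-10)

    @given(values, values)
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_path_invariants_random_inputs(self, rv, qv):
        path = shape_dtw_align(make_uniform_signal(rv), make_uniform_signal(qv), 3)
        assert_valid_path(path)


class TestEventDTW:
    def test_constant_signals_reduce_to_dtw(self):
        r = make_uniform_signal(np.full(8, 1.0))
        q = make_uniform_signal(np.full(6, 3.0))
        np.testing.assert_array_equal(
            event_dtw_align(r, q).links, dtw_align(r, q).links
        )

    def test_identical_peaked_signals_diagonal(self):
        v = np.concatenate([np.linspace(0, 3, 6), np.linspace(3, 0, 6)[1:]])
        s = make_uniform_signal(v)
        path = event_dtw_align(s, s)
        np.testing.assert_array_equal(path.links[:, 0], path.links[:, 1])

    def test_toy_peak_matches_exhaustive_minimum(self):
        # one clear up+down peak in both signals, unequal lengths
        r = make_uniform_signal([0.0, 1.0, 2.5, 4.0, 2.0, 1.0, 0.5])
        q = Signal([0.0, 2.0, 3.5, 5.0, 6.0], [0.0, 2.5, 4.0, 1.5, 0.3])
        path = event_dtw_align(r, q, frac=1.0)
        from eventdtw.dtw_engines import (
            Event,
            detect_slopes,
            info_matrix,
            match_events,
            select_key_slopes,
        )

        pairs = match_events(
            select_key_slopes(detect_slopes(r), 1.0), detect_slopes(q)
        )
        assert pairs  # the peak must be matched for this test to bite
        vr = info_matrix(r, [Event.from_slope(a) for a, _ in pairs])
        vq = info_matrix(q, [Event.from_slope(b) for _, b in pairs])
        cost = cdist(vr, vq)
        assert path.cost == pytest.approx(brute_force_min_cost(cost), abs=1e-10)

    def test_weights_validated(self, sine100):
        with pytest.raises(ParameterError):
            event_dtw_align(sine100, sine100, channel_weights=[1.0, -1.0, 1.0])

    @given(values, values)
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_path_invariants_random_inputs(self, rv, qv):
        path = event_dtw_align(make_uniform_signal(rv), make_uniform_signal(qv))
        assert_valid_path(path)


class TestComplexity:
    def test_event_preparation_scales_linearly(self):
        """Smoke test: doubling the input does not blow up event preparation."""
        import time

        from eventdtw.dtw_engines import (
            Event,
            detect_slopes,
            info_matrix,
            match_events,
            select_key_slopes,
        )

        def prep(n: int) -> float:
            t = np.arange(n)
            v = np.sin(2 * np.pi * 8 * t / n) + 0.1 * np.cos(2 * np.pi * 40 * t / n)
            s = make_uniform_signal(v)
            best = np.inf
            for _ in range(3):
                t0 = time.perf_counter()
                slopes = detect_slopes(s)
                pairs = match_events(select_key_slopes(slopes, 0.2), slopes)
                info_matrix(s, [Event.from_slope(a) for a, _ in pairs])
                best = min(best, time.perf_counter() - t0)
            return best

        t_small, t_big = prep(2000), prep(8000)
        # linear growth predicts ~4x; allow a wide margin for timer noise
        assert t_big < 25.0 * t_small + 0.05
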