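"""Spline smoothing: interpolation, derivatives, end conditions, presmoothing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fdanet as fn
from fdanet.smoothing import dump_spline_coefficients


def notaknot_spline_oracle(x, y):
    """Independent not-a-knot cubic construction by direct linear solve.

    Unknowns: 4 polynomial coefficients per interval (in (t - x_j) powers).
    Conditions: interpolation at both ends of each interval, first- and
    second-derivative continuity at interior knots, third-derivative
    continuity at the second and penultimate knots.
    """
    n = len(x) - 1  # intervals
    A = np.zeros((4 * n, 4 * n))
    b = np.zeros(4 * n)
    row = 0

    def powers(dt):
        return np.array([dt**3, dt**2, dt, 1.0])

    for j in range(n):
        A[row, 4 * j : 4 * j + 4] = powers(0.0)
        b[row] = y[j]
        row += 1
        A[row, 4 * j : 4 * j + 4] = powers(x[j + 1] - x[j])
        b[row] = y[j + 1]
        row += 1
    for j in range(n - 1):
        dt = x[j + 1] - x[j]
        A[row, 4 * j : 4 * j + 4] = [3 * dt**2, 2 * dt, 1, 0]
        A[row, 4 * (j + 1) : 4 * (j + 1) + 4] = [0, 0, -1, 0]
        row += 1
        A[row, 4 * j : 4 * j + 4] = [6 * dt, 2, 0, 0]
        A[row, 4 * (j + 1) : 4 * (j + 1) + 4] = [0, -2, 0, 0]
        row += 1
    # third-derivative continuity across second and penultimate knots
    A[row, 0] = 6
    A[row, 4] = -6
    row += 1
    A[row, 4 * (n - 2)] = 6
    A[row, 4 * (n - 1)] = -6
    row += 1
    assert row == 4 * n
    coef = np.linalg.solve(A, b)

    def evaluate(t):
        t = np.atleast_1d(t)
        out = np.empty_like(t, dtype=float)
        for i, ti in enumerate(t):
            j = min(np.searchsorted(x, ti, side="right") - 1, n - 1)
            j = max(j, 0)
            c = coef[4 * j : 4 * j + 4]
            dt = ti - x[j]
            out[i] = c[0] * dt**3 + c[1] * dt**2 + c[2] * dt + c[3]
        return out

    return evaluate


def test_linear_data_reproduced_exactly(linear_series):
    traj = fn.fit_spline(linear_series)
    t = np.linspace(0, 4, 101)
    assert np.allclose(fn.eval_spline(traj, t)[0], 2 * t + 1, atol=1e-12)
    assert np.allclose(fn.eval_derivative(traj, t)[0], 2.0, atol=1e-12)


def test_four_point_cubic_is_exact():
    # with 4 points the not-a-knot spline is the unique interpolating cubic
    t = np.array([0.0, 1.0, 2.0, 3.0])
    series = fn.ExpressionSeries("cubic", ("g",), t, (t**3)[None, :])
    traj = fn.fit_spline(series)
    grid = np.linspace(0, 3, 61)
    assert np.allclose(fn.eval_spline(traj, grid)[0], grid**3, atol=1e-10)
    assert np.isclose(fn.eval_derivative(traj, 2.0)[0, 0], 12.0, atol=1e-10)


def test_matches_independent_notaknot_oracle(sin_series):
    traj = fn.fit_spline(sin_series)
    oracle = notaknot_spline_oracle(sin_series.times, sin_series.values[0])
    t = np.linspace(0, np.pi, 100)
    assert np.max(np.abs(fn.eval_spline(traj, t)[0] - oracle(t))) < 1e-10


def test_sin_value_and_derivative_accuracy(sin_series):
    traj = fn.fit_spline(sin_series)
    assert abs(fn.eval_spline(traj, np.pi / 2)[0, 0] - 1.0) < 1e-3
    t = np.linspace(0.2, np.pi - 0.2, 50)
    assert np.max(np.abs(fn.eval_derivative(traj, t)[0] - np.cos(t))) < 1e-2
    # error shrinks with more knots
    t16 = np.linspace(0, np.pi, 16)
    traj16 = fn.fit_spline(
        fn.ExpressionSeries("sin16", ("g1",), t16, np.sin(t16)[None, :])
    )
    err8 = np.max(np.abs(fn.eval_derivative(traj, t)[0] - np.cos(t)))
    err16 = np.max(np.abs(fn.eval_derivative(traj16, t)[0] - np.cos(t)))
    assert err16 < err8


def test_interpolates_at_knots(benchmark):
    _, series, _, _ = benchmark
    for s in series:
        traj = fn.fit_spline(s)
        assert np.max(np.abs(fn.eval_spline(traj, s.times) - s.values)) < 1e-9


def test_derivative_matches_central_differences(sin_series):
    traj = fn.fit_spline(sin_series)
    t = np.linspace(0.3, np.pi - 0.3, 20)
    d = fn.eval_derivative(traj, t)[0]
    for h in (1e-4, 1e-5):
        fd = (fn.eval_spline(traj, t + h)[0] - fn.eval_spline(traj, t - h)[0]) / (2 * h)
        assert np.max(np.abs(fd - d)) < 50 * h


def test_third_derivative_continuous_at_second_and_penultimate_knot(sin_series):
    traj = fn.fit_spline(sin_series)
    d3 = traj.spline.derivative(3)
    for knot in (sin_series.times[1], sin_series.times[-2]):
        left = d3(knot - 1e-9)[0]
        right = d3(knot + 1e-9)[0]
        assert abs(left - right) / max(abs(left), 1e-12) < 1e-6


def test_no_extrapolation():
    t = np.linspace(0, 4, 5)
    traj = fn.fit_spline(fn.ExpressionSeries("s", ("g",), t, (t**2)[None, :]))
    with pytest.raises(ValueError, match="domain"):
        fn.eval_spline(traj, 4.5)
    with pytest.raises(ValueError, match="domain"):
        fn.eval_derivative(traj, -0.1)


def test_too_few_points_rejected_by_name():
    s = fn.ExpressionSeries("tiny", ("g",), [0, 1, 2], [[1.0, 2.0, 3.0]])
    with pytest.raises(ValueError, match="tiny"):
        fn.fit_spline(s)


def test_nonmonotone_times_rejected():
    with pytest.raises(ValueError, match="increasing"):
        fn.ExpressionSeries("bad", ("g",), [0, 2, 1, 3], [[1.0, 2, 3, 4]])


@pytest.mark.parametrize(
    "values,window,expected",
    [
        ([0.0, 3, 0, 3, 0], 3, [1.0, 1, 2, 1, 1]),  # hand convolution, edge-replicated
        ([5.0, 5, 5, 5, 5], 5, [5.0, 5, 5, 5, 5]),
    ],
)
def test_presmooth_moving_average(values, window, expected):
    s = fn.ExpressionSeries("s", ("g",), np.arange(len(values)), [values])
    out = fn.presmooth(s, window)
    assert np.allclose(out.values[0], expected)
    assert np.array_equal(out.times, s.times)


def test_presmooth_window_one_is_identity(sin_series):
    assert fn.presmooth(sin_series, 1) is sin_series


@pytest.mark.parametrize("window", [0, 2, 4, -1])
def test_presmooth_rejects_even_or_nonpositive_window(sin_series, window):
    with pytest.raises(ValueError, match="odd"):
        fn.presmooth(sin_series, window)


@settings(deadline=None, max_examples=25)
@given(
    data=st.lists(
        st.floats(min_value=0.0, max_value=100.0), min_size=4, max_size=12
    )
)
def test_interpolation_property_random_series(data):
    t = np.arange(len(data), dtype=float)
    s = fn.ExpressionSeries("h", ("g",), t, [data])
    traj = fn.fit_spline(s)
    assert np.max(np.abs(fn.eval_spline(traj, t)[0] - np.asarray(data))) < 1e-9


def test_expression_tsv_roundtrip(tmp_path, benchmark):
    _, series, _, _ = benchmark
    p = tmp_path / "expr.tsv"
    fn.write_expression_tsv(series[:3], p)
    back = fn.read_expression_tsv(p)
    assert len(back) == 3
    for a, b in zip(series[:3], back):
        assert a.gene_names == b.gene_names
        assert np.allclose(a.times, b.times)
        assert np.allclose(a.values, b.values, rtol=1e-9)


def test_spline_coefficient_dump(tmp_path, sin_series):
    traj = fn.fit_spline(sin_series)
    p = tmp_path / "coef.tsv"
    dump_spline_coefficients(traj, p)
    import pandas as pd

    df = pd.read_csv(p, sep="\t")
    assert len(df) == (len(sin_series.times) - 1) * len(sin_series.gene_names)
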