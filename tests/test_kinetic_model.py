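"""Forward model: compartment solution, frame averaging, Ki, Patlak."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad, solve_ivp

from bcaapet import (
    FrameSchedule,
    KineticParameters,
    PlasmaInputFunction,
    TimeActivityCurve,
    default_grid,
    frame_average,
    macro_ki,
    patlak_estimate,
    solve_2tc,
)
from bcaapet.errors import (
    CoverageError,
    InsufficientDataError,
    InvalidGridError,
    InvalidInputError,
    UndefinedRatioError,
)


def constant_input(c):
    return PlasmaInputFunction(lambda t: np.full_like(np.asarray(t, float), c))


def ode_oracle(params, cp_samples, t_grid):
    """Reference stiff integrator on the same piecewise-linear input."""

    def rhs(t, y):
        c = np.interp(t, t_grid, cp_samples)
        return [
            params.K1 * c - (params.k2 + params.k3) * y[0],
            params.k3 * y[0],
        ]

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        [0.0, 0.0],
        t_eval=t_grid,
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
    )
    return sol.y[0], sol.y[1]


class TestFrameSchedule:
    def test_canonical_protocol(self, schedule):
        assert schedule.n_frames == 32
        assert schedule.total_span_s == 1500.0
        assert schedule.total_span_min == 25.0
        durations = schedule.durations_s
        np.testing.assert_array_equal(
            durations, np.repeat([5.0, 10.0, 30.0, 60.0, 120.0], [12, 3, 3, 6, 8])
        )
        mids = schedule.mid_times_min
        np.testing.assert_allclose(
            mids, (schedule.frames[:, 0] + schedule.frames[:, 1]) / 120.0
        )
        assert np.all(np.diff(mids) > 0)

    @pytest.mark.parametrize(
        "frames",
        [
            [[5.0, 10.0]],          # does not start at 0
            [[0.0, 5.0], [6.0, 10.0]],  # gap
            [[0.0, 0.0]],           # zero duration
            [[0.0, 10.0], [5.0, 15.0]],  # overlap
        ],
    )
    def test_invalid_schedules_rejected(self, frames):
        with pytest.raises(ValueError):
            FrameSchedule(np.array(frames))


class TestSolve2TC:
    def test_no_delivery_gives_pure_blood_signal(self, feng, grid):
        p = KineticParameters(K1=0.0, k2=0.3, k3=0.1, vb=0.05)
        curves = solve_2tc(p, feng, grid)
        assert np.all(curves.cf == 0) and np.all(curves.cc == 0)
        np.testing.assert_allclose(curves.ct_total, 0.05 * feng.cb(grid))

    def test_single_compartment_closed_form(self):
        # constant Cp = c, k3 = 0, vb = 0: Cf(t) = (K1 c / k2)(1 - e^{-k2 t})
        c, K1, k2 = 10.0, 0.05, 0.4
        p = KineticParameters(K1=K1, k2=k2, k3=0.0, vb=0.0)
        t = np.linspace(0.0, 20.0, 2401)
        curves = solve_2tc(p, constant_input(c), t)
        expected = (K1 * c / k2) * (1.0 - np.exp(-k2 * t))
        np.testing.assert_allclose(curves.cf, expected, rtol=1e-10, atol=1e-12)
        assert np.all(curves.cc == 0)

    def test_matches_ode_oracle_on_bolus(self, feng, grid):
        p = KineticParameters(K1=0.05, k2=0.4, k3=0.08, vb=0.05)
        curves = solve_2tc(p, feng, grid)
        cf_o, cc_o = ode_oracle(p, feng.cp(grid), grid)
        ct_o = p.vb * feng.cb(grid) + (1 - p.vb) * (cf_o + cc_o)
        err = np.max(np.abs(curves.ct_total - ct_o)) / np.max(np.abs(ct_o))
        assert err < 1e-6

    def test_linearity_in_input(self, feng, grid, scv_params):
        base = solve_2tc(scv_params, feng, grid)
        scaled_input = PlasmaInputFunction(lambda t: 3.0 * feng.cp(t))
        scaled = solve_2tc(scv_params, scaled_input, grid)
        np.testing.assert_allclose(scaled.cf, 3.0 * base.cf, rtol=1e-12)
        np.testing.assert_allclose(scaled.cc, 3.0 * base.cc, rtol=1e-12)
        np.testing.assert_allclose(scaled.ct_total, 3.0 * base.ct_total, rtol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(
        K1=st.floats(0.0, 0.5),
        k2=st.floats(0.0, 2.0),
        k3=st.floats(0.0, 1.0),
        vb=st.floats(0.0, 0.3),
    )
    def test_trapping_invariants(self, feng, grid, K1, k2, k3, vb):
        """Nonnegative input: all curves >= 0 and Cc nondecreasing (k4=0)."""
        p = KineticParameters(K1=K1, k2=k2, k3=k3, vb=vb)
        curves = solve_2tc(p, feng, grid)
        assert np.all(curves.cf >= -1e-12)
        assert np.all(curves.cc >= -1e-12)
        assert np.all(curves.ct_total >= -1e-12)
        assert np.all(np.diff(curves.cc) >= -1e-12)

    def test_constant_input_late_slope(self):
        # with Cp=Cb=c, dCT/dt -> (1-vb)*Ki*c once the free pool equilibrates
        c = 8.0
        p = KineticParameters(K1=0.05, k2=0.4, k3=0.08, vb=0.05)
        t = np.linspace(0.0, 60.0, 7201)
        curves = solve_2tc(p, constant_input(c), t)
        tail = t >= 50.0
        slope = np.polyfit(t[tail], curves.ct_total[tail], 1)[0]
        expected = (1 - p.vb) * macro_ki(p) * c
        assert abs(slope / expected - 1) < 0.01

    def test_grid_and_input_validation(self, feng):
        p = KineticParameters(K1=0.05, k2=0.4, k3=0.08)
        with pytest.raises(InvalidGridError):
            solve_2tc(p, feng, np.array([0.0]))
        with pytest.raises(InvalidGridError):
            solve_2tc(p, feng, np.array([1.0, 2.0, 3.0]))
        with pytest.raises(InvalidGridError):
            solve_2tc(p, feng, np.array([0.0, 0.1, 0.3]))
        negative = PlasmaInputFunction(lambda t: np.asarray(t, float) - 5.0)
        with pytest.raises(InvalidInputError):
            solve_2tc(p, negative, np.linspace(0, 10, 101))

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            KineticParameters(K1=-0.1, k2=0.4, k3=0.1)
        with pytest.raises(ValueError):
            KineticParameters(K1=0.1, k2=0.4, k3=0.1, vb=1.0)
        with pytest.raises(ValueError):
            KineticParameters(K1=0.1, k2=0.4, k3=0.1, k4=0.01)


class TestMacroKi:
    @pytest.mark.parametrize(
        "K1,k2,k3,expected",
        [
            (0.05, 0.4, 0.0, 0.0),       # no trapping
            (0.05, 0.0, 0.3, 0.05),      # everything delivered is trapped
            (0.06, 0.3, 0.1, 0.015),     # K1*k3/(k2+k3) by hand
        ],
    )
    def test_values(self, K1, k2, k3, expected):
        assert macro_ki(KineticParameters(K1=K1, k2=k2, k3=k3)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_undefined_when_no_efflux_or_trapping(self):
        with pytest.raises(UndefinedRatioError):
            macro_ki(KineticParameters(K1=0.05, k2=0.0, k3=0.0))

    def test_bounded_by_k1_and_monotone(self, rng):
        for _ in range(50):
            K1, k2, k3 = rng.uniform(0.01, 1.0, 3)
            p = KineticParameters(K1=K1, k2=k2, k3=k3)
            ki = macro_ki(p)
            assert 0.0 <= ki <= K1
            eps = 1e-3
            assert macro_ki(KineticParameters(K1=K1 + eps, k2=k2, k3=k3)) >= ki
            assert macro_ki(KineticParameters(K1=K1, k2=k2, k3=k3 + eps)) >= ki
            assert macro_ki(KineticParameters(K1=K1, k2=k2 + eps, k3=k3)) <= ki


class TestFrameAverage:
    def test_constant_curve(self, schedule, grid):
        from bcaapet.kinetic import TissueCurves

        curves = TissueCurves(
            t=grid, cf=np.zeros_like(grid), cc=np.zeros_like(grid),
            ct_total=np.full_like(grid, 7.5),
        )
        tac = frame_average(curves, schedule)
        np.testing.assert_allclose(tac.values, 7.5, rtol=1e-12)

    def test_linear_curve_gives_mid_frame_values(self, schedule, grid):
        from bcaapet.kinetic import TissueCurves

        a = 0.3
        curves = TissueCurves(
            t=grid, cf=np.zeros_like(grid), cc=np.zeros_like(grid), ct_total=a * grid
        )
        tac = frame_average(curves, schedule)
        np.testing.assert_allclose(tac.values, a * schedule.mid_times_min, rtol=1e-9)

    def test_bolus_matches_adaptive_quadrature(self, feng, schedule, grid, scv_params):
        curves = solve_2tc(scv_params, feng, grid)
        tac = frame_average(curves, schedule)
        ct_interp = lambda t: np.interp(t, grid, curves.ct_total)
        for i in [0, 3, 11, 14, 20, 31]:
            a, b = schedule.frames[i] / 60.0
            ref, _ = quad(ct_interp, a, b, limit=200)
            ref /= b - a
            assert abs(tac.values[i] / ref - 1) < 1e-3

    def test_schedule_beyond_grid_raises(self, schedule, feng, scv_params):
        short = np.linspace(0.0, 10.0, 1201)
        curves = solve_2tc(scv_params, feng, short)
        with pytest.raises(CoverageError):
            frame_average(curves, schedule)


class TestPatlak:
    def test_zero_delivery_gives_zero_line(self, feng, schedule, grid):
        p = KineticParameters(K1=0.0, k2=0.3, k3=0.1, vb=0.0)
        tac = frame_average(solve_2tc(p, feng, grid), schedule)
        slope, intercept = patlak_estimate(tac, feng, 10.0)
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_slope_near_ki_for_irreversible_tracer(self, feng, schedule, grid):
        # SCV-like depot; finite-time Patlak bias is ~1% here
        p = KineticParameters(K1=0.05, k2=0.4, k3=0.12632, vb=0.0)
        tac = frame_average(solve_2tc(p, feng, grid), schedule)
        slope, _ = patlak_estimate(tac, feng, 10.0)
        assert abs(slope / macro_ki(p) - 1) < 0.02

    def test_blood_volume_scales_slope(self, feng, schedule, grid):
        p = KineticParameters(K1=0.05, k2=0.4, k3=0.12632, vb=0.05)
        tac = frame_average(solve_2tc(p, feng, grid), schedule)
        slope, _ = patlak_estimate(tac, feng, 10.0)
        assert abs(slope / ((1 - p.vb) * macro_ki(p)) - 1) < 0.02

    def test_insufficient_late_frames(self, feng, schedule, grid, scv_params):
        tac = frame_average(solve_2tc(scv_params, feng, grid), schedule)
        with pytest.raises(InsufficientDataError):
            patlak_estimate(tac, feng, t_star=24.0)


class TestIO:
    def test_tac_csv_round_trip(self, schedule, tmp_path):
        values = np.linspace(0.0, 5.0, schedule.n_frames)
        tac = TimeActivityCurve(schedule=schedule, values=values)
        path = tmp_path / "tac.csv"
        tac.to_csv(path)
        back = TimeActivityCurve.from_csv(path)
        np.testing.assert_allclose(back.values, tac.values, rtol=1e-12)
        np.testing.assert_array_equal(back.schedule.frames, schedule.frames)
        header = path.read_text().splitlines()[0]
        assert header == "frame_start_s,frame_end_s,mid_time_min,conc_kBq_per_mL"

    def test_input_function_json_specs(self, tmp_path):
        tab = PlasmaInputFunction.from_json(
            {"model": "tabulated", "t_min": [0, 1, 2], "cp": [0.0, 10.0, 5.0]}
        )
        assert tab.cp(0.5) == pytest.approx(5.0)
        fg = PlasmaInputFunction.from_json(
            {"model": "feng", "params": [851.1, 21.9, 20.8, -4.13, -0.12, -0.01]}
        )
        assert fg.cp(0.0) == 0.0
        with pytest.raises(ValueError):
            PlasmaInputFunction.from_json({"model": "spline"})
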