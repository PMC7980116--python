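"""Euler extraction, variation series, summaries, and report formatting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial.transform import Rotation

from gaitbalance import (
    EulerSeries,
    GaitParams,
    VariationSeries,
    diff_series,
    euler_from_matrix,
    euler_to_matrix,
    extract_series,
    format_report,
    pairwise_scatter,
    report_frame,
    simulate_orientation,
    summarize,
    wrap_angle,
)
from gaitbalance.fusion import RotationSeries
from gaitbalance.rotation import AxisSummary, _fmt3


def _random_triples(n, seed, ylim=math.pi / 2 - 0.01):
    r = np.random.default_rng(seed)
    a = r.uniform(-math.pi, math.pi, n)
    b = r.uniform(-ylim, ylim, n)
    c = r.uniform(-math.pi, math.pi, n)
    return a, b, c


class TestEulerExtraction:
    def test_identity_matrix_gives_zero_angles(self):
        assert euler_from_matrix(np.eye(3)) == (0.0, 0.0, 0.0)

    def test_compose_then_extract_recovers_1000_triples(self):
        a, b, c = _random_triples(1000, seed=11)
        R = euler_to_matrix(a, b, c)
        es = extract_series(RotationSeries(t=np.arange(1000) * 0.02, R=R))
        np.testing.assert_allclose(es.theta_x, a, atol=1e-9)
        np.testing.assert_allclose(es.theta_y, b, atol=1e-9)
        np.testing.assert_allclose(es.theta_z, c, atol=1e-9)

    def test_composition_matches_scipy_zyx(self):
        a, b, c = _random_triples(200, seed=5)
        ours = euler_to_matrix(a, b, c)
        theirs = Rotation.from_euler(
            "ZYX", np.stack([c, b, a], axis=1)).as_matrix()
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_extraction_matches_scipy_zyx(self):
        a, b, c = _random_triples(200, seed=6)
        R = Rotation.from_euler("ZYX", np.stack([c, b, a], axis=1))
        zyx = R.as_euler("ZYX")
        got = np.array([euler_from_matrix(m) for m in R.as_matrix()])
        np.testing.assert_allclose(got[:, 0], zyx[:, 2], atol=1e-9)
        np.testing.assert_allclose(got[:, 1], zyx[:, 1], atol=1e-9)
        np.testing.assert_allclose(got[:, 2], zyx[:, 0], atol=1e-9)

    @pytest.mark.parametrize("sign", [1.0, -1.0])
    def test_gimbal_lock_reconstructs_exactly(self, sign):
        """At θy = ±π/2 the free angle lands in θx, θz is zeroed, and the
        reconstructed matrix still matches the input."""
        for a, c in [(0.3, 1.1), (-2.0, 0.4), (1.0, -1.0)]:
            R = euler_to_matrix(a, sign * math.pi / 2, c)
            tx, ty, tz = euler_from_matrix(R)
            assert ty == pytest.approx(sign * math.pi / 2, abs=1e-12)
            assert tz == 0.0
            np.testing.assert_allclose(euler_to_matrix(tx, ty, tz), R,
                                       atol=1e-9)

    def test_gimbal_lock_flagged_in_series(self, caplog):
        R = euler_to_matrix(np.array([0.1, 0.2]),
                            np.array([0.0, math.pi / 2]),
                            np.array([0.0, 0.0]))
        with caplog.at_level("WARNING", logger="gaitbalance.rotation"):
            es = extract_series(RotationSeries(t=[0.0, 0.02], R=R))
        assert list(es.gimbal_locked) == [False, True]
        assert any("gimbal" in r.message for r in caplog.records)

    def test_simulator_ground_truth_round_trip(self, quiet_walk):
        gt = simulate_orientation(quiet_walk)
        es = extract_series(gt.rotations)
        np.testing.assert_allclose(es.theta_x, gt.euler.theta_x, atol=1e-9)
        np.testing.assert_allclose(es.theta_y, gt.euler.theta_y, atol=1e-9)
        np.testing.assert_allclose(es.theta_z, gt.euler.theta_z, atol=1e-9)

    def test_single_sample_series(self):
        es = extract_series(RotationSeries(t=[0.0], R=np.eye(3)[None]))
        assert len(es) == 1


class TestDiffSeries:
    def test_plain_differences(self):
        es = EulerSeries(t=[0.0, 0.02, 0.04],
                         theta_x=[0.0, 0.0, 0.0],
                         theta_y=[0.0, 0.0, 0.0],
                         theta_z=[0.1, 0.3, 0.2])
        vs = diff_series(es)
        np.testing.assert_allclose(vs.dz, [0.2, -0.1])
        np.testing.assert_allclose(vs.dx, [0.0, 0.0])
        np.testing.assert_array_equal(vs.t, [0.02, 0.04])

    def test_constant_angles_give_zero_variation(self):
        es = EulerSeries(t=np.arange(5) * 0.02, theta_x=np.full(5, 0.7),
                         theta_y=np.full(5, -0.2), theta_z=np.full(5, 3.0))
        vs = diff_series(es)
        for ax in "xyz":
            np.testing.assert_array_equal(vs.axis(ax), 0.0)

    def test_wrap_folds_branch_jump(self):
        es = EulerSeries(t=[0.0, 0.02], theta_x=[3.1, -3.1],
                         theta_y=[0.0, 0.0], theta_z=[0.0, 0.0])
        assert diff_series(es, wrap=False).dx[0] == pytest.approx(-6.2)
        assert diff_series(es, wrap=True).dx[0] == pytest.approx(
            2 * math.pi - 6.2)

    def test_needs_two_samples(self):
        es = EulerSeries(t=[0.0], theta_x=[0.0], theta_y=[0.0],
                         theta_z=[0.0])
        with pytest.raises(ValueError, match="at least 2"):
            diff_series(es)

    @settings(derandomize=True, max_examples=50)
    @given(arrays(float, st.integers(2, 30),
                  elements=st.floats(-50.0, 50.0)))
    def test_wrapped_differences_in_principal_branch(self, theta):
        es = EulerSeries(t=np.arange(theta.size) * 0.02, theta_x=theta,
                         theta_y=np.zeros_like(theta),
                         theta_z=np.zeros_like(theta))
        dx = diff_series(es, wrap=True).dx
        assert np.all(dx > -math.pi) and np.all(dx <= math.pi)


def _vs(dx, dy=None, dz=None):
    dx = np.asarray(dx, float)
    z = np.zeros_like(dx)
    return VariationSeries(t=np.arange(dx.size) * 0.02, dx=dx,
                           dy=z if dy is None else np.asarray(dy, float),
                           dz=z if dz is None else np.asarray(dz, float))


class TestSummarize:
    def test_all_zero_series(self):
        s = summarize(_vs(np.zeros(10)))
        for ax in "xyz":
            assert (s[ax].maximum, s[ax].minimum, s[ax].mean,
                    s[ax].variance, s[ax].sd) == (0, 0, 0, 0, 0)

    def test_two_value_example(self):
        s = summarize(_vs([0.2, -0.1]))["x"]
        assert s.maximum == pytest.approx(0.2)
        assert s.minimum == pytest.approx(-0.1)
        assert s.mean == pytest.approx(0.05)
        assert s.variance == pytest.approx(0.045)  # sample variance, N-1
        assert s.sd == pytest.approx(math.sqrt(0.045))

    @settings(derandomize=True, max_examples=50)
    @given(arrays(float, st.integers(2, 200),
                  elements=st.floats(-10.0, 10.0)))
    def test_telescoping_mean(self, theta):
        """Mean of the differences is (θ_last − θ_first)/(N−1) exactly."""
        es = EulerSeries(t=np.arange(theta.size) * 0.02, theta_x=theta,
                         theta_y=np.zeros_like(theta),
                         theta_z=np.zeros_like(theta))
        vs = diff_series(es)
        expected = (theta[-1] - theta[0]) / (theta.size - 1)
        assert summarize(vs)["x"].mean == pytest.approx(
            expected, abs=1e-10 * theta.size)

    @settings(derandomize=True, max_examples=50)
    @given(d=arrays(float, st.integers(2, 50),
                    elements=st.floats(-5.0, 5.0)),
           shift=st.floats(-3.0, 3.0))
    def test_translation_covariance(self, d, shift):
        base = summarize(_vs(d))["x"]
        moved = summarize(_vs(d + shift))["x"]
        assert moved.mean == pytest.approx(base.mean + shift, abs=1e-9)
        assert moved.maximum == pytest.approx(base.maximum + shift, abs=1e-9)
        assert moved.minimum == pytest.approx(base.minimum + shift, abs=1e-9)
        assert moved.variance == pytest.approx(base.variance, abs=1e-9)
        assert moved.sd == pytest.approx(base.sd, abs=1e-9)

    def test_sinusoid_difference_sd_closed_form(self):
        """SD(diff) ≈ A·2πf·Δt/√2 for a pure sway tone (fΔt = 0.036)."""
        A, f, dt = 0.05, 1.8, 0.02
        t = np.arange(int(60 / dt) + 1) * dt
        es = EulerSeries(t=t, theta_x=A * np.sin(2 * np.pi * f * t),
                         theta_y=np.zeros_like(t), theta_z=np.zeros_like(t))
        sd = summarize(diff_series(es))["x"].sd
        assert sd == pytest.approx(A * 2 * np.pi * f * dt / np.sqrt(2),
                                   rel=0.02)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize(_vs(np.zeros(0)))


class TestReportFormatting:
    def test_three_decimal_half_even_and_zero_stripping(self):
        assert _fmt3(0.0042) == "0.004"
        assert _fmt3(1.6e-5) == "0"
        assert _fmt3(-0.0001) == "0"
        assert _fmt3(0.13) == "0.13"
        assert _fmt3(-1.715) == "-1.715"
        assert _fmt3(0.0025) == "0.002"  # banker's rounding
        assert _fmt3(0.0035) == "0.004"

    def test_variance_prints_zero_while_sd_prints(self):
        """A 0.004 SD row keeps its SD but its variance (1.6e-5) rounds away."""
        sd = 0.004
        s = AxisSummary(maximum=0.02, minimum=-0.02, mean=0.0,
                        variance=sd**2, sd=sd)
        report = format_report({"M1": {"x": s, "y": s, "z": s}})
        row = [ln for ln in report.splitlines() if "x-axis" in ln][0]
        assert row.split() == ["x-axis", "0.02", "-0.02", "0", "0", "0.004"]

    def test_all_zero_row(self):
        s = AxisSummary(0.0, 0.0, 0.0, 0.0, 0.0)
        report = format_report({"P": {"x": s, "y": s, "z": s}})
        row = [ln for ln in report.splitlines() if "x-axis" in ln][0]
        assert row.split() == ["x-axis", "0", "0", "0", "0", "0"]

    def test_layout_one_block_per_participant(self):
        s = AxisSummary(0.0, 0.0, 0.0, 0.0, 0.0)
        block = {"x": s, "y": s, "z": s}
        report = format_report({"F1": block, "M1": block})
        lines = report.splitlines()
        assert lines[0].split() == ["Participant,", "rotation", "vector",
                                    "Maximum", "Minimum", "Mean",
                                    "Variance", "SD"]
        assert "F1" in lines and "M1" in lines
        assert sum("axis" in ln for ln in lines) == 6

    def test_tidy_frame_is_unrounded(self):
        s = AxisSummary(maximum=0.0042, minimum=-0.0042, mean=1e-6,
                        variance=1.6e-5, sd=0.004)
        df = report_frame({"P": {"x": s, "y": s, "z": s}})
        assert list(df.columns) == ["participant", "axis", "max", "min",
                                    "mean", "variance", "sd"]
        assert df.loc[0, "variance"] == 1.6e-5


class TestPairwiseScatter:
    def test_writes_one_file_per_axis_pair(self, tmp_path):
        vs = _vs(np.zeros(4))
        for a, b in [("x", "y"), ("x", "z"), ("y", "z")]:
            out = tmp_path / f"p_{a}{b}.png"
            pairwise_scatter(vs, (a, b), out)
            assert out.exists() and out.stat().st_size > 0

    def test_multi_participant_panels(self, tmp_path):
        vs = _vs(np.zeros(4))
        out = tmp_path / "panels.png"
        pairwise_scatter({"F1": vs, "M1": vs, "M2": vs}, ("x", "y"), out)
        assert out.exists()

    def test_distinct_axes_required(self, tmp_path):
        with pytest.raises(ValueError, match="distinct"):
            pairwise_scatter(_vs(np.zeros(4)), ("x", "x"), tmp_path / "p.png")

    def test_symmetric_sway_centered_at_origin(self, quiet_walk):
        """A symmetric simulated sway scatters symmetrically about 0."""
        gt = simulate_orientation(quiet_walk)
        vs = diff_series(gt.euler)
        for ax in ("x", "y"):
            d = vs.axis(ax)
            se = d.std(ddof=1) / math.sqrt(d.size)
            assert abs(d.mean()) < 3 * se


def test_wrap_angle_principal_branch():
    assert wrap_angle(math.pi) == pytest.approx(math.pi)
    assert wrap_angle(-math.pi) == pytest.approx(math.pi)
    assert wrap_angle(3 * math.pi / 2) == pytest.approx(-math.pi / 2)
    np.testing.assert_allclose(wrap_angle(np.array([0.0, 2 * math.pi])),
                               [0.0, 0.0], atol=1e-12)
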