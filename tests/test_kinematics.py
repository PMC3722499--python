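import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import gravity_trace
from lbmm.errors import DegenerateInputError, ParameterError, ValidationError
from lbmm.kinematics import (
    GRAVITY_G,
    AccelTrace,
    calibrate,
    detect_movement,
    estimate_gravity_frame,
    movement_angles,
    movement_magnitude,
    to_gravity_frame,
)

FS = 5000.0


def sensor_trace(a, n_base=2500):
    a = np.asarray(a, dtype=float)
    t = (np.arange(a.shape[0]) - n_base) / FS
    return AccelTrace(t=t, a=a, frame="sensor")


class TestCalibrate:
    @pytest.mark.parametrize(
        "volts,v_per_g,expected_g",
        [(0.22, 0.22, 1.0), (0.0, 0.22, 0.0), (0.11, 0.22, 0.5)],
    )
    def test_voltage_to_g(self, volts, v_per_g, expected_g):
        raw = np.full((20, 3), volts)
        t = (np.arange(20) - 10) / FS
        trace = calibrate(raw, v_per_g, t)
        assert trace.frame == "sensor"
        np.testing.assert_allclose(trace.a, expected_g)

    def test_nonpositive_calibration_rejected(self):
        with pytest.raises(ParameterError):
            calibrate(np.zeros((20, 3)), 0.0, np.arange(20) / FS - 0.002)


class TestGravityFrame:
    def test_already_aligned_gives_identity(self):
        trace = sensor_trace(np.tile([0.0, 0.0, -1.0], (100, 1)), n_base=50)
        f = estimate_gravity_frame(trace)
        np.testing.assert_allclose(f.R, np.eye(3), atol=1e-12)
        assert f.s == pytest.approx(1.0)

    def test_quarter_turn_about_y(self):
        trace = sensor_trace(np.tile([-1.0, 0.0, 0.0], (100, 1)), n_base=50)
        f = estimate_gravity_frame(trace)
        np.testing.assert_allclose(f.apply(f.g_sensor), GRAVITY_G, atol=1e-12)
        # 90-degree rotation: trace of R = 1 + 2 cos(90 deg) = 1
        assert np.trace(f.R) == pytest.approx(1.0, abs=1e-12)

    def test_generic_tilt_realigns_mean(self):
        mean = np.array([0.3, 0.4, -1.2])
        trace = sensor_trace(np.tile(mean, (100, 1)), n_base=50)
        f = estimate_gravity_frame(trace)
        assert np.linalg.norm(f.apply(mean) - GRAVITY_G) <= 1e-9
        assert f.s == pytest.approx(1.0 / np.linalg.norm(mean))

    def test_antiparallel_gravity_still_aligns(self):
        trace = sensor_trace(np.tile([0.0, 0.0, 1.0], (100, 1)), n_base=50)
        f = estimate_gravity_frame(trace)
        np.testing.assert_allclose(f.apply(f.g_sensor), GRAVITY_G, atol=1e-9)

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(
        gx=st.floats(-2, 2), gy=st.floats(-2, 2),
        gz=st.floats(-2, 2),
    )
    def test_rotation_is_orthonormal_and_aligning(self, gx, gy, gz):
        """For any non-degenerate baseline mean, R is a proper rotation and
        (R, s) sends the mean exactly to (0, 0, -1) g."""
        mean = np.array([gx, gy, gz])
        if np.linalg.norm(mean) < 0.1:
            return
        trace = sensor_trace(np.tile(mean, (40, 1)), n_base=20)
        f = estimate_gravity_frame(trace)
        assert np.abs(f.R @ f.R.T - np.eye(3)).max() <= 1e-12
        assert np.linalg.det(f.R) == pytest.approx(1.0, abs=1e-12)
        assert np.linalg.norm(f.apply(mean) - GRAVITY_G) <= 1e-9

    def test_disconnected_sensor_is_degenerate(self):
        trace = sensor_trace(np.full((100, 3), 0.01), n_base=50)
        with pytest.raises(DegenerateInputError):
            estimate_gravity_frame(trace)

    def test_short_baseline_rejected(self):
        trace = sensor_trace(np.tile([0.0, 0.0, -1.0], (20, 1)), n_base=5)
        with pytest.raises(ParameterError):
            estimate_gravity_frame(trace)


class TestToGravityFrame:
    def test_still_limb_baseline_maps_to_minus_z(self):
        mean = np.array([0.5, -0.2, -0.9])
        trace = sensor_trace(np.tile(mean, (200, 1)), n_base=100)
        f = estimate_gravity_frame(trace)
        rotated = to_gravity_frame(trace, f)
        assert rotated.frame == "gravity"
        np.testing.assert_allclose(
            rotated.a[rotated.baseline], np.tile(GRAVITY_G, (100, 1)), atol=1e-9
        )

    def test_norms_scale_uniformly(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, (50, 3)) + [0.2, 0.1, -1.0]
        trace = sensor_trace(a, n_base=40)
        f = estimate_gravity_frame(trace)
        rotated = to_gravity_frame(trace, f)
        np.testing.assert_allclose(
            np.linalg.norm(rotated.a, axis=1),
            f.s * np.linalg.norm(a, axis=1),
            rtol=1e-12,
        )


class TestMovementMagnitude:
    @pytest.mark.parametrize(
        "a_prime,expected",
        [((0.6, 0.8, -1.0), 1.0), ((0.0, 0.0, -1.0), 0.0), ((1.0, 2.0, 1.0), 3.0)],
    )
    def test_gravity_subtracted_norm(self, a_prime, expected):
        trace = gravity_trace(np.tile(a_prime, (10, 1)))
        np.testing.assert_allclose(movement_magnitude(trace), expected)

    def test_sensor_frame_rejected(self):
        trace = sensor_trace(np.tile([0.0, 0.0, -1.0], (20, 1)), n_base=10)
        with pytest.raises(ValidationError):
            movement_magnitude(trace)

    def test_invariant_under_extra_yaw(self):
        """Rotating a gravity-frame trace about the vertical axis does not
        change the movement magnitude."""
        rng = np.random.default_rng(1)
        a = GRAVITY_G + rng.normal(0, 0.3, (100, 3))
        trace = gravity_trace(a)
        c, s = math.cos(0.7), math.sin(0.7)
        rz = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        yawed = gravity_trace((a - GRAVITY_G) @ rz.T + GRAVITY_G)
        np.testing.assert_allclose(
            movement_magnitude(yawed), movement_magnitude(trace), rtol=1e-9
        )


def make_transient_trace(
    amplitude=1.0, onset_s=0.018, noise_sd=0.01, seed=0, n=5000, n_base=2500,
    direction=(1.0, 0.0, 0.0),
):
    """Gravity-frame trace with a step-attack, exponentially decaying
    transient at a known onset (instant rise, 20-ms decay)."""
    rng = np.random.default_rng(seed)
    t = (np.arange(n) - n_base) / FS
    pulse = np.where(
        t > onset_s, amplitude * np.exp(-np.maximum(t - onset_s, 0.0) / 0.02), 0.0
    )
    d = np.asarray(direction) / np.linalg.norm(direction)
    a = GRAVITY_G + pulse[:, None] * d[None, :] + rng.normal(0, noise_sd, (n, 3))
    return AccelTrace(t=t, a=a, frame="gravity")


def first_crossing_oracle(trace, window):
    """Brute-force scan: first sample in the window where m exceeds the
    baseline-mean-plus-5-pooled-SD threshold."""
    m = movement_magnitude(trace)
    base = trace.t < 0
    dev = trace.a[base] - trace.a[base].mean(axis=0)
    th = m[base].mean() + 5 * float(np.sqrt((dev**2).sum() / (dev.size - 1)))
    for i in np.nonzero((trace.t >= window[0]) & (trace.t <= window[1]))[0]:
        if m[i] > th:
            return trace.t[i]
    return None


class TestDetectMovement:
    def test_subthreshold_peak_not_detected(self):
        """A bump whose magnitude stays below the five-SD threshold is not a
        movement."""
        ev_null = detect_movement(make_transient_trace(amplitude=0.0, noise_sd=0.01, seed=2))
        # Bump small enough that noise peak + bump stays below threshold.
        bump = make_transient_trace(
            amplitude=0.3 * ev_null.threshold_g, noise_sd=0.01, seed=2
        )
        ev = detect_movement(bump)
        assert ev.peak_g <= ev.threshold_g
        assert not ev.detected and ev.onset_latency_s is None and ev.vec is None

    def test_zero_signal_not_detected(self):
        trace = gravity_trace(np.tile(GRAVITY_G, (5000, 1)))
        ev = detect_movement(trace)
        assert not ev.detected and ev.peak_g == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_onset_matches_brute_force_scan(self, seed):
        """Detected onset equals the brute-force first-crossing scan and lies
        within one sample of the injected onset."""
        trace = make_transient_trace(amplitude=1.0, onset_s=0.018, seed=seed)
        ev = detect_movement(trace)
        assert ev.detected
        assert ev.onset_latency_s == first_crossing_oracle(trace, (0.0, 0.5))
        assert abs(ev.onset_latency_s - 0.018) <= 1.5 / FS

    def test_noise_free_onset_exact(self):
        trace = make_transient_trace(amplitude=1.0, onset_s=0.02, noise_sd=0.0)
        ev = detect_movement(trace)
        # Zero baseline SD: the first nonzero sample after onset crosses.
        assert ev.detected
        assert ev.onset_latency_s == pytest.approx(0.02 + 1 / FS, abs=1e-12)
        assert ev.peak_g == pytest.approx(1.0, rel=0.02)

    def test_threshold_is_five_baseline_sds(self):
        trace = make_transient_trace(amplitude=1.0, seed=4)
        ev = detect_movement(trace)
        m = movement_magnitude(trace)
        assert ev.threshold_g == pytest.approx(
            m[trace.t < 0].mean() + 5 * ev.baseline_sd_g
        )

    def test_scale_consistency(self):
        """Scaling raw voltages by k > 0 (same calibration) leaves detection
        and onset unchanged: the gravity-frame scale factor absorbs k."""
        rng = np.random.default_rng(6)
        n, n_base = 5000, 2500
        t = (np.arange(n) - n_base) / FS
        pulse = np.where((t > 0.018) & (t < 0.058), 1.0, 0.0)
        a = np.array([0.2, -0.1, -0.95]) + pulse[:, None] * np.array([0.5, 0.2, 0.3])
        a = a + rng.normal(0, 0.01, (n, 3))
        events = []
        for k in (1.0, 3.7):
            trace = AccelTrace(t=t, a=k * a, frame="sensor")
            f = estimate_gravity_frame(trace)
            events.append(detect_movement(to_gravity_frame(trace, f)))
        assert events[0].detected == events[1].detected
        assert events[0].onset_latency_s == pytest.approx(events[1].onset_latency_s)

    def test_window_outside_recording_rejected(self):
        trace = make_transient_trace()
        with pytest.raises(ParameterError):
            detect_movement(trace, response_window_s=(0.0, 5.0))

    def test_integration_window_follows_anchor(self):
        trace = make_transient_trace(amplitude=2.0, onset_s=0.05, noise_sd=0.0)
        ev_onset = detect_movement(trace, integration_anchor="onset")
        ev_stim = detect_movement(trace, integration_anchor="stimulus")
        # Anchored at the stimulus, the 30-ms window misses the late movement.
        assert np.linalg.norm(ev_stim.vec) < np.linalg.norm(ev_onset.vec)

    def test_false_positive_rate_under_two_percent(self):
        """No-movement trials (white noise sigma = 0.01 g plus respiration-like
        sway) trigger the five-SD criterion in fewer than 2% of 1000 trials."""
        rng = np.random.default_rng(123)
        n, n_base = 5000, 2500
        t = (np.arange(n) - n_base) / FS
        resp_dir = np.array([0.25, 0.25, 0.935])
        resp_dir /= np.linalg.norm(resp_dir)
        fp = 0
        for _ in range(1000):
            resp = 0.005 * np.sin(
                2 * np.pi * 2.0 * t + rng.uniform(0, 2 * np.pi)
            )[:, None] * resp_dir
            a = GRAVITY_G + resp + rng.normal(0, 0.01, (n, 3))
            ev = detect_movement(AccelTrace(t=t, a=a, frame="gravity"))
            fp += ev.detected
        assert fp / 1000 < 0.02


class TestMovementAngles:
    @pytest.mark.parametrize(
        "vec,expected",
        [
            ((1, 0, 0), (0.0, 0.0)),
            ((0, 0, 1), (0.0, 90.0)),
            ((1, 1, math.sqrt(2)), (45.0, 45.0)),
            ((-1, 0, 0), (180.0, 0.0)),
            ((0, 1, 0), (90.0, 0.0)),
            ((0, 0, -1), (0.0, -90.0)),
        ],
    )
    def test_quadrant_correct_angles(self, vec, expected):
        horiz, elev = movement_angles(np.array(vec, dtype=float))
        assert horiz == pytest.approx(expected[0], abs=1e-9)
        assert elev == pytest.approx(expected[1], abs=1e-9)

    def test_zero_vector_undefined(self):
        with pytest.raises(DegenerateInputError):
            movement_angles(np.zeros(3))

    def test_horizontal_range_half_open(self):
        horiz, _ = movement_angles(np.array([-1.0, -1e-300, 0.0]))
        assert -180.0 < horiz <= 180.0
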