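"""Accelerometer kinematics: calibration, gravity-frame rotation and
evoked-movement detection.

The core idea: with the limb at rest before the stimulus, the accelerometer
reads only gravity. The baseline-mean acceleration vector therefore defines
the sensor's orientation, and the minimal (shortest-arc) rotation taking
that vector to (0, 0, -1), together with a scale factor normalising its
magnitude to 1 g, moves every trial into a common *gravity frame*. In that
frame X is anterior/posterior, Y medial/lateral and Z dorsal/ventral
(assuming consistent sensor mounting), so movement directions are
comparable across trials, sessions and animals.

Movement detection operates on the gravity-subtracted magnitude
``m(t) = ||a'(t) - (0, 0, -1)||``: a trial contains an evoked movement when
m(t) exceeds the baseline mean of m plus five times the baseline standard
deviation within the response window. The SD is the pooled per-axis SD of
the baseline acceleration about its mean (the magnitude itself is a folded,
non-Gaussian quantity whose five-SD exceedances are far more frequent than
the Gaussian intuition behind the five-SD rule; thresholding against the
per-axis noise scale keeps the false-positive rate of a no-movement trial
well below 2% at the nominal noise level). The movement vector is the per-axis integral
of the gravity-subtracted acceleration over the first 30 ms of the
movement, and its direction is summarised by a horizontal-plane angle
(atan2(Vy, Vx); 0 deg = anterior) and an elevation angle
(atan2(Vz, sqrt(Vx^2 + Vy^2)); +90 deg = dorsal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateInputError, ParameterError, ValidationError
from .io_session import Session, TrialRecord

__all__ = [
    "GRAVITY_G",
    "AccelTrace",
    "GravityFrame",
    "MovementEvent",
    "calibrate",
    "trial_accel_trace",
    "estimate_gravity_frame",
    "to_gravity_frame",
    "movement_magnitude",
    "detect_movement",
    "movement_angles",
    "analyze_trial_limb",
    "detect_session",
]

#: Gravity in the aligned frame, in units of g.
GRAVITY_G = np.array([0.0, 0.0, -1.0])

#: Baseline-mean magnitudes below this are treated as a disconnected sensor.
MIN_GRAVITY_NORM_G = 0.1


@dataclass
class AccelTrace:
    """Three-axis acceleration series for one limb in one trial.

    ``t`` is in seconds relative to stimulus onset (negative = baseline);
    ``a`` is (n, 3) in units of g; ``frame`` is ``"sensor"`` (as wired) or
    ``"gravity"`` (rotated so static gravity is (0, 0, -1) g).
    """

    t: np.ndarray
    a: np.ndarray
    frame: str = "sensor"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.a.ndim != 2 or self.a.shape[1] != 3:
            raise ValidationError(f"acceleration must be (n, 3), got {self.a.shape}")
        if self.t.shape[0] != self.a.shape[0]:
            raise ValidationError("time and acceleration lengths differ")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("time axis must be strictly increasing")
        if self.frame not in ("sensor", "gravity"):
            raise ValidationError(f"unknown frame {self.frame!r}")

    @property
    def baseline(self) -> np.ndarray:
        return self.t < 0

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass(frozen=True)
class GravityFrame:
    """Rotation + scale taking sensor coordinates into the gravity frame.

    ``R`` is the shortest-arc rotation (orthonormal, det +1) aligning the
    unit baseline-mean vector with (0, 0, -1); ``s = 1 / ||g_sensor||``
    rescales so static gravity has magnitude exactly 1 g (absorbing small
    calibration error); ``g_sensor`` is the baseline-mean acceleration in
    the sensor frame.
    """

    R: np.ndarray
    s: float
    g_sensor: np.ndarray

    def apply(self, a: np.ndarray) -> np.ndarray:
        """Transform (n, 3) or (3,) sensor-frame vectors: a' = R (s a)."""
        return (self.s * np.asarray(a, dtype=float)) @ self.R.T


def calibrate(raw_v: np.ndarray, v_per_g: float, t: np.ndarray) -> AccelTrace:
    """Convert 3-channel accelerometer voltages to acceleration in g.

    The sensor outputs ``v_per_g`` volts per g (manufacturer calibration,
    0.22 V/g for the standard part), so acceleration = voltage / v_per_g.
    """
    if not v_per_g > 0:
        raise ParameterError(f"v_per_g must be > 0, got {v_per_g}")
    return AccelTrace(t=t, a=np.asarray(raw_v, dtype=float) / v_per_g, frame="sensor")


def trial_accel_trace(trial: TrialRecord, limb: str, v_per_g: float) -> AccelTrace:
    """Calibrated sensor-frame trace for one limb of a trial record."""
    if limb not in trial.accel_raw:
        raise ParameterError(f"limb {limb!r} not in trial (has {trial.limb_labels})")
    return calibrate(trial.accel_raw[limb], v_per_g, trial.time_s())


def _shortest_arc_rotation(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal-angle rotation matrix taking unit vector u onto unit vector v."""
    c = float(np.dot(u, v))
    axis = np.cross(u, v)
    s = float(np.linalg.norm(axis))
    if s < 1e-15:
        if c > 0:
            return np.eye(3)
        # Antiparallel: rotate pi about any axis perpendicular to u.
        perp = np.cross(u, np.eye(3)[np.argmin(np.abs(u))])
        perp /= np.linalg.norm(perp)
        return Rotation.from_rotvec(math.pi * perp).as_matrix()
    angle = math.atan2(s, c)
    return Rotation.from_rotvec(angle * axis / s).as_matrix()


def estimate_gravity_frame(
    trace: AccelTrace, baseline_window: tuple[float, float] | None = None
) -> GravityFrame:
    """Estimate the gravity frame from the resting baseline of a trace.

    ``baseline_window`` is a (start, stop) span in trace time; it must lie
    entirely before the stimulus. Default: the full pre-stimulus span.
    """
    if trace.frame != "sensor":
        raise ValidationError("gravity frame is estimated from sensor-frame traces")
    if baseline_window is None:
        sel = trace.baseline
    else:
        lo, hi = baseline_window
        if hi > 0:
            raise ParameterError("baseline_window must end before the stimulus (t=0)")
        sel = (trace.t >= lo) & (trace.t < hi)
    if int(sel.sum()) < 10:
        raise ParameterError("baseline window must contain at least 10 samples")
    g_sensor = trace.a[sel].mean(axis=0)
    norm = float(np.linalg.norm(g_sensor))
    if norm < MIN_GRAVITY_NORM_G:
        raise DegenerateInputError(
            f"baseline mean magnitude {norm:.3g} g < {MIN_GRAVITY_NORM_G} g; "
            "sensor disconnected or miscalibrated"
        )
    R = _shortest_arc_rotation(g_sensor / norm, GRAVITY_G)
    return GravityFrame(R=R, s=1.0 / norm, g_sensor=g_sensor)


def to_gravity_frame(trace: AccelTrace, frame: GravityFrame) -> AccelTrace:
    """Rotate and scale a sensor-frame trace into the gravity frame."""
    if trace.frame != "sensor":
        raise ValidationError("trace is already in the gravity frame")
    return AccelTrace(t=trace.t, a=frame.apply(trace.a), frame="gravity")


def movement_magnitude(trace: AccelTrace) -> np.ndarray:
    """Magnitude of the gravity-subtracted (movement-only) acceleration, in g.

    ``m(t) = ||a'(t) - (0, 0, -1)||`` so a perfectly still limb gives
    m = 0 rather than the static 1 g.
    """
    if trace.frame != "gravity":
        raise ValidationError("movement_magnitude requires a gravity-frame trace")
    return np.linalg.norm(trace.a - GRAVITY_G, axis=1)


@dataclass
class MovementEvent:
    """Detection result for one trial/limb.

    ``vec`` is the per-axis trapezoidal integral of the gravity-subtracted
    acceleration over the 30-ms integration window, in g*s; angles are in
    degrees (horizontal in (-180, 180], 0 = anterior; elevation in
    [-90, 90], +90 = dorsal). ``baseline_sd_g`` is the pooled per-axis SD
    of the baseline acceleration and ``threshold_g`` the detection level
    built from it. Onset, vector and angles are ``None`` when no movement
    was detected.
    """

    detected: bool
    threshold_g: float
    baseline_sd_g: float
    peak_g: float
    onset_latency_s: float | None = None
    vec: np.ndarray | None = None
    horiz_deg: float | None = None
    elev_deg: float | None = None


def movement_angles(vec: np.ndarray) -> tuple[float, float]:
    """Horizontal-plane and elevation angles (degrees) of a movement vector.

    Quadrant-correct via the two-argument arctangent: horizontal =
    atan2(Vy, Vx), elevation = atan2(Vz, sqrt(Vx^2 + Vy^2)).
    """
    vx, vy, vz = (float(v) for v in np.asarray(vec, dtype=float))
    if vx == 0.0 and vy == 0.0 and vz == 0.0:
        raise DegenerateInputError("movement angles undefined for zero vector")
    horiz = math.degrees(math.atan2(vy, vx))
    if horiz <= -180.0:
        horiz = 180.0
    elev = math.degrees(math.atan2(vz, math.hypot(vx, vy)))
    return horiz, elev


def detect_movement(
    trace: AccelTrace,
    response_window_s: tuple[float, float] = (0.0, 0.5),
    integration_s: float = 0.030,
    threshold_multiplier: float = 5.0,
    integration_anchor: str = "onset",
) -> MovementEvent:
    """Detect an evoked movement and characterise it.

    The movement magnitude m(t) is compared against a threshold of the
    baseline mean of m plus ``threshold_multiplier`` times the pooled
    per-axis baseline SD; a movement is detected when any post-stimulus
    sample inside ``response_window_s`` exceeds that threshold. Onset is
    the first crossing; the movement
    vector integrates the gravity-subtracted acceleration for
    ``integration_s`` starting at the onset (or at the stimulus, with
    ``integration_anchor="stimulus"``).
    """
    if trace.frame != "gravity":
        raise ValidationError("detect_movement requires a gravity-frame trace")
    if integration_anchor not in ("onset", "stimulus"):
        raise ParameterError(f"unknown integration_anchor {integration_anchor!r}")
    lo, hi = response_window_s
    if lo < 0 or hi <= lo:
        raise ParameterError(f"invalid response window {response_window_s}")
    # Post-stimulus span runs to the last sample plus one sample period.
    if hi > trace.t[-1] + trace.dt * (1 + 1e-9):
        raise ParameterError(
            f"response window end {hi} s beyond recording ({trace.t[-1]:.3f} s)"
        )
    m = movement_magnitude(trace)
    base = trace.baseline
    if not base.any():
        raise ParameterError("trace has no baseline samples")
    mu_b = float(m[base].mean())
    if base.sum() > 1:
        # Pooled per-axis SD of the baseline acceleration about its mean.
        dev = trace.a[base] - trace.a[base].mean(axis=0)
        sd_b = float(np.sqrt((dev**2).sum() / (dev.size - 1)))
    else:
        sd_b = 0.0
    threshold = mu_b + threshold_multiplier * sd_b

    window = (trace.t >= lo) & (trace.t <= hi)
    m_win = m[window]
    peak = float(m_win.max())
    above = m_win > threshold
    if not above.any():
        return MovementEvent(
            detected=False, threshold_g=threshold, baseline_sd_g=sd_b, peak_g=peak
        )
    onset = float(trace.t[window][np.argmax(above)])

    t0 = onset if integration_anchor == "onset" else 0.0
    isel = (trace.t >= t0) & (trace.t <= t0 + integration_s)
    dev = trace.a[isel] - GRAVITY_G
    vec = np.trapezoid(dev, trace.t[isel], axis=0)
    try:
        horiz, elev = movement_angles(vec)
    except DegenerateInputError:
        horiz = elev = None
    return MovementEvent(
        detected=True,
        threshold_g=threshold,
        baseline_sd_g=sd_b,
        peak_g=peak,
        onset_latency_s=onset,
        vec=vec,
        horiz_deg=horiz,
        elev_deg=elev,
    )


def analyze_trial_limb(
    trial: TrialRecord,
    limb: str,
    v_per_g: float,
    **detect_kwargs,
) -> MovementEvent:
    """Full single-limb pipeline: calibrate, align to gravity, detect."""
    sensor = trial_accel_trace(trial, limb, v_per_g)
    frame = estimate_gravity_frame(sensor)
    return detect_movement(to_gravity_frame(sensor, frame), **detect_kwargs)


def detect_session(session: Session, **detect_kwargs) -> list[dict[str, MovementEvent]]:
    """Run movement detection on every trial and limb of a session.

    Returns a list parallel to ``session.trials``, each element mapping
    limb label -> :class:`MovementEvent`.
    """
    out = []
    for trial in session.trials:
        out.append(
            {
                limb: analyze_trial_limb(
                    trial, limb, session.calibration_v_per_g, **detect_kwargs
                )
                for limb in trial.limb_labels
            }
        )
    return out
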