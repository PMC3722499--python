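"""Synthetic light-based motor-mapping sessions with known ground truth.

The generative model reproduces the structure of a real mapping session so
every pipeline stage (calibration, gravity-frame rotation, movement
detection, EEG quantification, map assembly) can be validated against
injected parameters:

* the accelerometer sits at an arbitrary (but fixed-per-session) tilt, so
  its baseline reads a rotated constant gravity vector plus a small
  respiration-locked sinusoid and white Gaussian sensor noise;
* stimulating a grid site injects a movement transient whose peak
  amplitude follows a 2-D Gaussian field over the grid (defaults chosen to
  reproduce a forelimb map of roughly 3 mm^2 centred 1.65 mm lateral and
  0.74 mm anterior of bregma, with evoked amplitudes in the 0.5-5 g
  range), with a fixed onset latency (18 ms default) and a configurable
  direction;
* the movement waveform is a half-sine-windowed damped oscillation of
  ~50 ms, normalised to unit peak magnitude;
* the EEG channel carries baseline noise plus a stimulus-locked
  depolarization transient scaled by a second, spatially broader Gaussian
  field — so EEG-responsive but movement-silent sites ring the motor map,
  as they do in vivo;
* laser power acts as a simple multiplicative gain on both fields.

Injected movement directions are defined in the gravity frame that the
analysis reconstructs (the consistent-mounting assumption of the real
protocol): aligning one vector to -Z leaves rotation about the vertical
free, so directions expressed in an arbitrary world frame would be
unrecoverable in principle. The sensor trace is built as
``R_align^T (gravity + respiration + movement)`` where ``R_align`` is the
exact shortest-arc rotation of the tilted gravity vector, so the baseline
still reads tilted gravity and the full rotation path is exercised.

Everything is driven by one seed: identical config + seed reproduces the
session bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import ParameterError
from .io_session import GridSpec, Session, TrialRecord
from .kinematics import _shortest_arc_rotation

__all__ = [
    "GaussianField",
    "MovementTemplate",
    "SimConfig",
    "SimGroundTruth",
    "default_direction",
    "simulate_session",
    "simulate_trial",
]


@dataclass(frozen=True)
class GaussianField:
    """Isotropic 2-D Gaussian amplitude field over the map plane.

    ``center_mm`` is (lateral, anterior) relative to bregma; ``peak`` is in
    the field's own units (g for motor fields, uV for EEG fields).
    """

    center_mm: tuple[float, float]
    sigma_mm: float
    peak: float

    def __post_init__(self) -> None:
        if not self.sigma_mm > 0:
            raise ParameterError(f"sigma_mm must be > 0, got {self.sigma_mm}")
        if self.peak < 0:
            raise ParameterError(f"peak must be >= 0, got {self.peak}")

    def values(self, grid: GridSpec) -> np.ndarray:
        """Field amplitude at every grid pixel, shape (n_rows, n_cols)."""
        lat, ant = grid.coords_mm()
        d2 = (lat - self.center_mm[0]) ** 2 + (ant - self.center_mm[1]) ** 2
        return self.peak * np.exp(-d2 / (2.0 * self.sigma_mm**2))


@dataclass(frozen=True)
class MovementTemplate:
    """Evoked-movement waveform: a half-sine-windowed damped oscillation,
    normalised so its peak magnitude is 1 (amplitudes then scale it
    directly). ``latency_s`` is the onset delay after the stimulus."""

    latency_s: float = 0.018
    duration_s: float = 0.050
    carrier_hz: float = 30.0
    decay_s: float = 0.010

    def waveform(self, u: np.ndarray) -> np.ndarray:
        """Normalised waveform at times ``u`` (s) after movement onset."""
        u = np.asarray(u, dtype=float)
        w = np.where(
            (u > 0) & (u < self.duration_s),
            np.sin(np.pi * u / self.duration_s)
            * np.sin(2 * np.pi * self.carrier_hz * u)
            * np.exp(-u / self.decay_s),
            0.0,
        )
        # Normalise peak on a dense grid so amplitude == peak magnitude.
        dense = np.linspace(0, self.duration_s, 2001)
        ref = (
            np.sin(np.pi * dense / self.duration_s)
            * np.sin(2 * np.pi * self.carrier_hz * dense)
            * np.exp(-dense / self.decay_s)
        )
        return w / np.abs(ref).max()


def default_direction() -> np.ndarray:
    """Default injected movement direction: anterior with a 20 deg elevation
    (the dominant pattern of evoked forelimb movements)."""
    v = np.array([np.cos(np.deg2rad(20.0)), 0.0, np.sin(np.deg2rad(20.0))])
    return v / np.linalg.norm(v)


def _default_motor_fields() -> dict[str, GaussianField]:
    # Peak 5 g with sigma 0.45 mm puts the 0.5 g contour at r ~ 0.97 mm,
    # i.e. a super-threshold area of ~3 mm^2.
    return {"left_forelimb": GaussianField((1.65, 0.735), 0.45, 5.0)}


@dataclass
class SimConfig:
    """All generative parameters of a synthetic session.

    Defaults emulate the standard protocol: an 18 x 23 grid at 0.3 mm
    spacing sampled at 5 kHz with 0.5 s baseline and 1 s post-stimulus
    spans, 5-ms 1-mW pulses, a 0.22 V/g accelerometer and a 1000x EEG
    amplifier. ``sensor_tilt_deg`` are extrinsic XYZ Euler angles of the
    sensor mounting; ``detection_floor_g`` is the field amplitude below
    which no movement is injected (sites below it are true negatives);
    ``direction_field`` optionally gives a per-pixel (n_rows, n_cols, 3)
    unit-vector direction, overriding the constant default direction.
    """

    grid: GridSpec = field(
        default_factory=lambda: GridSpec(18, 23, 0.3, (8.0, 3.0))
    )
    sample_rate_hz: float = 5000.0
    baseline_s: float = 0.5
    post_s: float = 1.0
    sensor_tilt_deg: tuple[float, float, float] = (25.0, -15.0, 40.0)
    noise_sd_g: float = 0.01
    respiration_amp_g: float = 0.005
    respiration_hz: float = 2.0
    motor_fields: dict[str, GaussianField] = field(default_factory=_default_motor_fields)
    movement: MovementTemplate = field(default_factory=MovementTemplate)
    direction: np.ndarray = field(default_factory=default_direction)
    direction_field: np.ndarray | None = None
    detection_floor_g: float = 0.5
    eeg_field: GaussianField = field(
        default_factory=lambda: GaussianField((1.65, 0.735), 1.0, 200.0)
    )
    eeg_noise_uV: float = 10.0
    eeg_tau_s: float = 0.015
    eeg_gain: float = 1000.0
    calibration_v_per_g: float = 0.22
    stim_power_mW: float = 1.0
    reference_power_mW: float = 1.0
    stim_duration_s: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_s", "post_s", "sample_rate_hz", "stim_duration_s"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0")
        if self.noise_sd_g < 0 or self.respiration_amp_g < 0 or self.eeg_noise_uV < 0:
            raise ParameterError("noise amplitudes must be >= 0")
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if n == 0:
            raise ParameterError("direction must be a nonzero vector")
        self.direction = self.direction / n

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        """Build a config from plain nested dicts (e.g. a YAML file)."""
        d = dict(d)
        if isinstance(d.get("grid"), dict):
            d["grid"] = GridSpec(
                n_rows=int(d["grid"]["n_rows"]),
                n_cols=int(d["grid"]["n_cols"]),
                spacing_mm=float(d["grid"]["spacing_mm"]),
                bregma_rc=tuple(d["grid"]["bregma_rc"]),
            )
        if "motor_fields" in d:
            d["motor_fields"] = {
                limb: f if isinstance(f, GaussianField) else GaussianField(
                    center_mm=tuple(f["center_mm"]),
                    sigma_mm=float(f["sigma_mm"]),
                    peak=float(f["peak"]),
                )
                for limb, f in d["motor_fields"].items()
            }
        if isinstance(d.get("eeg_field"), dict):
            f = d["eeg_field"]
            d["eeg_field"] = GaussianField(
                center_mm=tuple(f["center_mm"]),
                sigma_mm=float(f["sigma_mm"]),
                peak=float(f["peak"]),
            )
        if isinstance(d.get("movement"), dict):
            d["movement"] = MovementTemplate(**d["movement"])
        return cls(**d)


@dataclass
class SimGroundTruth:
    """Injected per-site parameters of a synthetic session.

    ``sites`` has one row per stimulated site and limb: grid position,
    injected movement amplitude (0 where below the detection floor), onset,
    direction components and angles, and the injected EEG amplitude (uV).
    """

    sites: pd.DataFrame
    config: SimConfig


# Respiration moves the limb mostly dorso-ventrally with a small
# horizontal component; direction fixed for reproducibility.
_RESP_DIR = np.array([0.25, 0.25, 0.935])
_RESP_DIR = _RESP_DIR / np.linalg.norm(_RESP_DIR)


def _eeg_shape(u: np.ndarray, tau: float) -> np.ndarray:
    """Unit-peak alpha-function depolarization transient."""
    return np.where(u > 0, (u / tau) * np.exp(1.0 - u / tau), 0.0)


def simulate_session(config: SimConfig) -> tuple[Session, SimGroundTruth]:
    """Generate one synthetic session plus its ground truth.

    Every grid site is stimulated exactly once, in a seeded random order
    (mirroring the randomised acquisition protocol). Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate_hz
    n_base = int(round(config.baseline_s * fs))
    n_post = int(round(config.post_s * fs))
    n = n_base + n_post
    t = (np.arange(n) - n_base) / fs

    g_world = np.array([0.0, 0.0, -1.0])
    tilt = Rotation.from_euler("xyz", config.sensor_tilt_deg, degrees=True).as_matrix()
    g_sensor = tilt @ g_world
    # Exact aligning rotation; its transpose maps the gravity-frame signal
    # into the sensor frame while keeping the baseline gravity tilted.
    r_align = _shortest_arc_rotation(g_sensor / np.linalg.norm(g_sensor), g_world)
    gravity_to_sensor = r_align.T

    power_gain = config.stim_power_mW / config.reference_power_mW
    motor_amps = {
        limb: f.values(config.grid) * power_gain for limb, f in config.motor_fields.items()
    }
    eeg_amps = config.eeg_field.values(config.grid) * power_gain

    limbs = tuple(config.motor_fields)
    wave = config.movement.waveform(t - config.movement.latency_s)

    sites = [(r, c) for r in range(config.grid.n_rows) for c in range(config.grid.n_cols)]
    order = rng.permutation(len(sites))

    trials: list[TrialRecord] = []
    truth_rows: list[dict] = []
    for idx in order:
        r, c = sites[idx]
        resp_phase = rng.uniform(0, 2 * np.pi)
        resp = (
            config.respiration_amp_g
            * np.sin(2 * np.pi * config.respiration_hz * t + resp_phase)[:, None]
            * _RESP_DIR[None, :]
        )
        eeg_noise = rng.normal(0.0, config.eeg_noise_uV, n)

        accel_raw: dict[str, np.ndarray] = {}
        for limb in limbs:
            amp = float(motor_amps[limb][r, c])
            inject = amp >= config.detection_floor_g
            if config.direction_field is not None:
                direction = np.asarray(config.direction_field[r, c], dtype=float)
                direction = direction / np.linalg.norm(direction)
            else:
                direction = config.direction
            movement = (
                amp * wave[:, None] * direction[None, :]
                if inject
                else np.zeros((n, 3))
            )
            a_gravity = g_world[None, :] + resp + movement
            a_sensor = a_gravity @ gravity_to_sensor.T + rng.normal(
                0.0, config.noise_sd_g, (n, 3)
            )
            accel_raw[limb] = a_sensor * config.calibration_v_per_g
            horiz = float(np.degrees(np.arctan2(direction[1], direction[0])))
            elev = float(
                np.degrees(np.arctan2(direction[2], np.hypot(direction[0], direction[1])))
            )
            truth_rows.append(
                {
                    "row": r,
                    "col": c,
                    "limb": limb,
                    "amplitude_g": amp if inject else 0.0,
                    "onset_s": config.movement.latency_s if inject else np.nan,
                    "dir_x": direction[0] if inject else np.nan,
                    "dir_y": direction[1] if inject else np.nan,
                    "dir_z": direction[2] if inject else np.nan,
                    "horiz_deg": horiz if inject else np.nan,
                    "elev_deg": elev if inject else np.nan,
                    "eeg_uV": float(eeg_amps[r, c]),
                }
            )

        eeg_elec_uV = eeg_noise + eeg_amps[r, c] * _eeg_shape(t, config.eeg_tau_s)
        eeg_raw = eeg_elec_uV * 1e-6 * config.eeg_gain

        trials.append(
            TrialRecord(
                grid_rc=(r, c),
                stim_power_mW=config.stim_power_mW,
                stim_duration_s=config.stim_duration_s,
                sample_rate_hz=fs,
                t_stim_index=n_base,
                accel_raw=accel_raw,
                eeg_raw=eeg_raw,
                limb_labels=limbs,
            )
        )

    session = Session(
        grid=config.grid,
        trials=trials,
        calibration_v_per_g=config.calibration_v_per_g,
        eeg_gain=config.eeg_gain,
    )
    truth = SimGroundTruth(sites=pd.DataFrame(truth_rows), config=config)
    return session, truth


def simulate_trial(
    amplitude_g: float = 2.0,
    direction: np.ndarray | None = None,
    noise_sd_g: float = 0.01,
    seed: int = 0,
    **config_overrides,
) -> tuple[Session, SimGroundTruth]:
    """One-trial convenience session: a 1x1 grid stimulated once, with the
    motor field peak pinned at the site so the injected amplitude is
    exactly ``amplitude_g`` (or zero when below the detection floor)."""
    grid = GridSpec(1, 1, 0.3, (0.0, 0.0))
    cfg = SimConfig(
        grid=grid,
        motor_fields={
            "left_forelimb": GaussianField(grid.site_mm(0, 0), 1.0, amplitude_g)
        },
        eeg_field=GaussianField(grid.site_mm(0, 0), 1.0, 200.0),
        noise_sd_g=noise_sd_g,
        seed=seed,
        **config_overrides,
    )
    if direction is not None:
        cfg = replace(cfg, direction=np.asarray(direction, dtype=float))
    return simulate_session(cfg)
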