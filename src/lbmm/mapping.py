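"""Assembly of per-trial results into cortical grid maps, and map statistics.

A *motor map* holds the peak evoked acceleration at each stimulation site,
masked to the *active pixels* — sites whose movement magnitude exceeded
five baseline standard deviations. *Direction maps* hold the
horizontal-plane or elevation angle of the evoked movement at each active
pixel. *EEG maps* hold the mean evoked deflection at every stimulated site
(no activity mask — sub-motor-threshold depolarization is exactly what the
EEG map is for) and are smoothed with a 3x3 neighbourhood average to damp
spontaneous EEG fluctuations.

Map statistics follow the field's conventions: area = active pixels x
pixel area; mean motor output = mean peak acceleration over active pixels;
centre of gravity (COG) = amplitude-weighted balance point of the map
reported in mm lateral/anterior of bregma. Two COG estimators are
provided: ``quadrant_balance`` (default) finds, independently per axis,
the coordinate splitting the amplitude mass in half, with each pixel's
amplitude spread uniformly over its physical extent; ``weighted_mean`` is
the amplitude-weighted mean of pixel centres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .eeg import EEGResponse
from .errors import DegenerateInputError, ParameterError, ValidationError
from .io_session import GridSpec, Session
from .kinematics import MovementEvent

__all__ = [
    "GridMap",
    "MapStats",
    "build_motor_map",
    "build_direction_map",
    "build_eeg_map",
    "smooth_3x3",
    "map_area",
    "map_cog",
    "mean_motor_output",
    "map_stats",
    "compare_sessions",
]


@dataclass
class GridMap:
    """Scalar (or angular) value per stimulation-grid pixel.

    ``mask`` marks pixels whose value participates in statistics (for motor
    and direction maps: the active pixels; for EEG maps: all stimulated
    sites). Unstimulated or masked-out pixels carry NaN values.
    """

    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray
    units: str = ""
    limb: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        shape = (self.grid.n_rows, self.grid.n_cols)
        if self.values.shape != shape or self.mask.shape != shape:
            raise ValidationError(
                f"map arrays must have grid shape {shape}, got "
                f"values {self.values.shape}, mask {self.mask.shape}"
            )

    @property
    def n_active(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class MapStats:
    """Summary statistics of one map: area, centre of gravity (mm lateral,
    mm anterior of bregma), mean value over active pixels."""

    area_mm2: float
    n_active: int
    cog_mm: tuple[float, float] | None
    cog_distance_mm: float | None
    mean_output: float | None


def _select_trials(session: Session, power_mW: float | None):
    for i, tr in enumerate(session.trials):
        if power_mW is None or tr.stim_power_mW == power_mW:
            yield i, tr


def build_motor_map(
    session: Session,
    events: list[dict[str, MovementEvent]],
    limb: str,
    power_mW: float | None = None,
) -> GridMap:
    """Peak-acceleration motor map for one limb.

    ``events`` is the per-trial detection output of
    :func:`lbmm.kinematics.detect_session`. The mask is exactly the set of
    sites whose trial passed the five-SD movement criterion; unstimulated
    sites stay masked with NaN values.
    """
    if session.trials and limb not in session.limb_labels:
        raise ParameterError(f"limb {limb!r} not in session ({session.limb_labels})")
    shape = (session.grid.n_rows, session.grid.n_cols)
    values = np.full(shape, np.nan)
    mask = np.zeros(shape, dtype=bool)
    for i, tr in _select_trials(session, power_mW):
        ev = events[i][limb]
        r, c = tr.grid_rc
        if ev.detected:
            values[r, c] = ev.peak_g
            mask[r, c] = True
    return GridMap(grid=session.grid, values=values, mask=mask, units="g", limb=limb)


def build_direction_map(
    session: Session,
    events: list[dict[str, MovementEvent]],
    limb: str,
    plane: str,
    power_mW: float | None = None,
) -> GridMap:
    """Movement-direction map (``plane``: "horizontal" or "elevation").

    Values are angles in degrees at active pixels; the mask equals the
    motor-map mask. When rendered, hue should encode the angle and
    brightness the movement magnitude of the matching motor map.
    """
    if plane not in ("horizontal", "elevation"):
        raise ParameterError(f"plane must be 'horizontal' or 'elevation', got {plane!r}")
    if session.trials and limb not in session.limb_labels:
        raise ParameterError(f"limb {limb!r} not in session ({session.limb_labels})")
    shape = (session.grid.n_rows, session.grid.n_cols)
    values = np.full(shape, np.nan)
    mask = np.zeros(shape, dtype=bool)
    for i, tr in _select_trials(session, power_mW):
        ev = events[i][limb]
        r, c = tr.grid_rc
        angle = ev.horiz_deg if plane == "horizontal" else ev.elev_deg
        if ev.detected and angle is not None:
            values[r, c] = angle
            mask[r, c] = True
    return GridMap(grid=session.grid, values=values, mask=mask, units="deg", limb=limb)


def build_eeg_map(
    session: Session,
    responses: list[EEGResponse],
    power_mW: float | None = None,
    smooth: bool = True,
) -> GridMap:
    """Evoked-EEG map in microvolts, spatially averaged over 3x3 pixels.

    All stimulated sites are unmasked: the EEG map intentionally has no
    movement-threshold mask.
    """
    shape = (session.grid.n_rows, session.grid.n_cols)
    values = np.full(shape, np.nan)
    mask = np.zeros(shape, dtype=bool)
    for i, tr in _select_trials(session, power_mW):
        r, c = tr.grid_rc
        values[r, c] = responses[i].deflection_uV
        mask[r, c] = True
    gm = GridMap(grid=session.grid, values=values, mask=mask, units="uV")
    return smooth_3x3(gm) if smooth else gm


def smooth_3x3(grid_map: GridMap) -> GridMap:
    """Replace each pixel by the mean of its 3x3 neighbourhood (self
    included). At borders, and next to unstimulated (NaN) pixels, the mean
    runs over the available neighbours only. The mask is unchanged."""
    values = grid_map.values
    valid = np.isfinite(values)
    filled = np.where(valid, values, 0.0)
    kernel = np.ones((3, 3))
    sums = ndimage.correlate(filled, kernel, mode="constant", cval=0.0)
    counts = ndimage.correlate(valid.astype(float), kernel, mode="constant", cval=0.0)
    out = np.full_like(values, np.nan)
    has = counts > 0
    out[has] = sums[has] / counts[has]
    out[~valid] = np.nan
    return GridMap(
        grid=grid_map.grid, values=out, mask=grid_map.mask.copy(),
        units=grid_map.units, limb=grid_map.limb,
    )


def map_area(grid_map: GridMap) -> float:
    """Map area in mm^2: active pixels x spacing^2."""
    return grid_map.n_active * grid_map.grid.spacing_mm**2


def _balance_point(coords: np.ndarray, weights: np.ndarray, h: float) -> float:
    """Coordinate at which cumulative mass reaches half the total, with each
    pixel's weight spread uniformly over its extent of width h."""
    uniq, inv = np.unique(coords, return_inverse=True)
    col_mass = np.zeros(uniq.size)
    np.add.at(col_mass, inv, weights)
    cum = np.cumsum(col_mass)
    half = cum[-1] / 2.0
    k = int(np.searchsorted(cum, half))
    # Half-mass exactly at a column's right edge: every point up to the next
    # massive column's left edge balances; take the midpoint of that span.
    if cum[k] - half <= 1e-12 * cum[-1] and k + 1 < uniq.size:
        return float((uniq[k] + h / 2.0 + uniq[k + 1] - h / 2.0) / 2.0)
    before = cum[k - 1] if k > 0 else 0.0
    frac = (half - before) / col_mass[k]
    return float(uniq[k] - h / 2.0 + frac * h)


def map_cog(grid_map: GridMap, method: str = "quadrant_balance") -> tuple[float, float]:
    """Centre of gravity of a map, (lateral_mm, anterior_mm) from bregma.

    ``quadrant_balance`` (default): per-axis amplitude balance point — the
    coordinate where the cumulative active-pixel amplitude, spread
    uniformly over each pixel's 1-pixel physical extent, reaches half the
    total; computed independently for the lateral and anterior axes so the
    amplitude mass is equal on both sides of each axis through the COG.
    ``weighted_mean``: amplitude-weighted mean of active-pixel centres.
    """
    if method not in ("quadrant_balance", "weighted_mean"):
        raise ParameterError(f"unknown COG method {method!r}")
    if grid_map.n_active == 0:
        raise DegenerateInputError("COG undefined for a map with no active pixels")
    rows, cols = np.nonzero(grid_map.mask)
    w = grid_map.values[rows, cols]
    if np.any(~np.isfinite(w)) or np.any(w < 0):
        raise ValidationError("COG requires finite non-negative active-pixel values")
    if w.sum() == 0:
        raise DegenerateInputError("COG undefined when all active amplitudes are zero")
    lat_all, ant_all = grid_map.grid.coords_mm()
    lat = lat_all[rows, cols]
    ant = ant_all[rows, cols]
    if method == "weighted_mean":
        return float(np.average(lat, weights=w)), float(np.average(ant, weights=w))
    h = grid_map.grid.spacing_mm
    return _balance_point(lat, w, h), _balance_point(ant, w, h)


def mean_motor_output(grid_map: GridMap) -> float:
    """Mean value over active pixels (mean evoked acceleration, in g, for a
    motor map)."""
    if grid_map.n_active == 0:
        raise DegenerateInputError("mean output undefined for an empty map")
    return float(grid_map.values[grid_map.mask].mean())


def map_stats(grid_map: GridMap, cog_method: str = "quadrant_balance") -> MapStats:
    """Area, COG and mean output of a map in one record."""
    n = grid_map.n_active
    if n == 0:
        return MapStats(
            area_mm2=0.0, n_active=0, cog_mm=None, cog_distance_mm=None,
            mean_output=None,
        )
    cog = map_cog(grid_map, cog_method)
    return MapStats(
        area_mm2=map_area(grid_map),
        n_active=n,
        cog_mm=cog,
        cog_distance_mm=float(np.hypot(*cog)),
        mean_output=mean_motor_output(grid_map),
    )


def compare_sessions(
    maps: list[GridMap], cog_method: str = "quadrant_balance"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-session stability report for repeated maps of one subject.

    Returns ``(per_session, pairwise)``: per-session MapStats rows, and for
    every session pair the COG displacement (mm), the Jaccard overlap of
    the active-pixel sets and the ratio of mean outputs (later / earlier).
    """
    if not maps:
        raise ParameterError("compare_sessions needs at least one map")
    g0 = maps[0].grid
    for i, m in enumerate(maps[1:], 1):
        if m.grid != g0:
            raise ParameterError(f"map {i} grid differs from map 0 grid")
    stats = [map_stats(m, cog_method) for m in maps]
    per_session = pd.DataFrame(
        {
            "session": range(len(maps)),
            "area_mm2": [s.area_mm2 for s in stats],
            "n_active": [s.n_active for s in stats],
            "cog_lateral_mm": [s.cog_mm[0] if s.cog_mm else np.nan for s in stats],
            "cog_anterior_mm": [s.cog_mm[1] if s.cog_mm else np.nan for s in stats],
            "mean_output": [
                s.mean_output if s.mean_output is not None else np.nan for s in stats
            ],
        }
    )
    rows = []
    for i in range(len(maps)):
        for j in range(i + 1, len(maps)):
            si, sj = stats[i], stats[j]
            if si.cog_mm and sj.cog_mm:
                disp = float(
                    np.hypot(sj.cog_mm[0] - si.cog_mm[0], sj.cog_mm[1] - si.cog_mm[1])
                )
            else:
                disp = np.nan
            inter = int((maps[i].mask & maps[j].mask).sum())
            union = int((maps[i].mask | maps[j].mask).sum())
            jac = inter / union if union else np.nan
            ratio = (
                sj.mean_output / si.mean_output
                if si.mean_output and sj.mean_output is not None
                else np.nan
            )
            rows.append(
                {
                    "session_a": i, "session_b": j,
                    "cog_displacement_mm": disp,
                    "jaccard": jac,
                    "mean_output_ratio": ratio,
                }
            )
    return per_session, pd.DataFrame(rows)
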