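"""Session container I/O.

A session lives in a directory holding a ``session.yaml`` manifest plus one
CSV file per stimulation trial.  The manifest records the stimulation-grid
geometry, sampling/calibration metadata and the ordered trial list; each
trial CSV carries a ``time_s`` column, three accelerometer voltage columns
per instrumented limb (``<limb>_ax_V``, ``<limb>_ay_V``, ``<limb>_az_V``)
and one ``eeg_V`` column.  Everything is plain text so sessions can be
inspected, diffed and produced by any acquisition wrapper.

Grid coordinate convention: row 0 is the most anterior grid row, rows and
columns are 0-based, and bregma may sit at a fractional (row, col) position
because the cranial window is not centred on bregma.  Physical map
coordinates follow from the spacing::

    lateral_mm  = (col - bregma_col) * spacing_mm
    anterior_mm = (bregma_row - row) * spacing_mm
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ParameterError, ValidationError

__all__ = [
    "GridSpec",
    "TrialRecord",
    "Session",
    "read_session",
    "write_session",
    "write_map",
    "read_map",
]

MANIFEST_NAME = "session.yaml"
# %.12g round-trips comfortably within 1e-9 relative error.
_FLOAT_FMT = "%.12g"

#: Minimum spans tolerated on read (half the nominal 0.5 s / 1 s protocol,
#: so truncated fixtures remain loadable).
MIN_BASELINE_S = 0.25
MIN_POST_S = 0.5


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the stimulation grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid extent; rows run anterior -> posterior, columns medial -> lateral.
    spacing_mm
        Inter-point distance in mm (0.3 mm in the standard protocol).
    bregma_rc
        Fractional (row, col) grid position of bregma.
    """

    n_rows: int
    n_cols: int
    spacing_mm: float
    bregma_rc: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValidationError(
                f"grid must be at least 1x1, got {self.n_rows}x{self.n_cols}"
            )
        if not self.spacing_mm > 0:
            raise ValidationError(f"spacing_mm must be > 0, got {self.spacing_mm}")
        object.__setattr__(self, "bregma_rc", tuple(float(v) for v in self.bregma_rc))

    @property
    def n_sites(self) -> int:
        return self.n_rows * self.n_cols

    def site_mm(self, row: float, col: float) -> tuple[float, float]:
        """(lateral_mm, anterior_mm) of a grid position relative to bregma."""
        br, bc = self.bregma_rc
        return (col - bc) * self.spacing_mm, (br - row) * self.spacing_mm

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-pixel (lateral, anterior) coordinate arrays, shape (n_rows, n_cols)."""
        rows = np.arange(self.n_rows)[:, None]
        cols = np.arange(self.n_cols)[None, :]
        br, bc = self.bregma_rc
        lat = (cols - bc) * self.spacing_mm + np.zeros_like(rows, dtype=float)
        ant = (br - rows) * self.spacing_mm + np.zeros_like(cols, dtype=float)
        return lat, ant

    def contains(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols


@dataclass
class TrialRecord:
    """Raw recordings and metadata for one stimulation trial.

    ``accel_raw`` maps limb label -> (n_samples, 3) voltage array;
    ``eeg_raw`` is the (n_samples,) amplifier-output voltage series.
    ``t_stim_index`` is the sample index of stimulus onset.
    """

    grid_rc: tuple[int, int]
    stim_power_mW: float
    stim_duration_s: float
    sample_rate_hz: float
    t_stim_index: int
    accel_raw: dict[str, np.ndarray]
    eeg_raw: np.ndarray
    limb_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.grid_rc = (int(self.grid_rc[0]), int(self.grid_rc[1]))
        if not self.limb_labels:
            self.limb_labels = tuple(self.accel_raw)
        self.eeg_raw = np.asarray(self.eeg_raw, dtype=float)
        n = self.eeg_raw.shape[0]
        for limb in self.limb_labels:
            a = np.asarray(self.accel_raw[limb], dtype=float)
            if a.ndim != 2 or a.shape[1] != 3:
                raise ValidationError(
                    f"limb {limb!r}: accelerometer data must be (n, 3), got {a.shape}"
                )
            if a.shape[0] != n:
                raise ValidationError(
                    f"limb {limb!r}: channel length {a.shape[0]} != EEG length {n}"
                )
            self.accel_raw[limb] = a
        if not (0 < self.t_stim_index < n):
            raise ValidationError(
                f"t_stim_index {self.t_stim_index} outside recording of {n} samples"
            )
        fs = self.sample_rate_hz
        if self.t_stim_index / fs < MIN_BASELINE_S:
            raise ValidationError(
                f"baseline span {self.t_stim_index / fs:.3f} s < {MIN_BASELINE_S} s"
            )
        if (n - self.t_stim_index) / fs < MIN_POST_S:
            raise ValidationError(
                f"post-stimulus span {(n - self.t_stim_index) / fs:.3f} s < {MIN_POST_S} s"
            )

    @property
    def n_samples(self) -> int:
        return int(self.eeg_raw.shape[0])

    def time_s(self) -> np.ndarray:
        """Time axis in s relative to stimulus onset (negative = baseline)."""
        return (np.arange(self.n_samples) - self.t_stim_index) / self.sample_rate_hz


@dataclass
class Session:
    """One mapping session: grid geometry plus ordered stimulation trials.

    Trial order is the stimulation order (sites are stimulated in random
    order during acquisition) and is preserved on disk.
    """

    grid: GridSpec
    trials: list[TrialRecord] = field(default_factory=list)
    calibration_v_per_g: float = 0.22
    eeg_gain: float = 1000.0
    allow_repeats: bool = False

    def __post_init__(self) -> None:
        if not self.calibration_v_per_g > 0:
            raise ValidationError(
                f"calibration_v_per_g must be > 0, got {self.calibration_v_per_g}"
            )
        if not self.eeg_gain > 0:
            raise ValidationError(f"eeg_gain must be > 0, got {self.eeg_gain}")
        seen: set[tuple[int, int, float]] = set()
        for i, tr in enumerate(self.trials):
            r, c = tr.grid_rc
            if not self.grid.contains(r, c):
                raise ValidationError(
                    f"trial {i}: site ({r}, {c}) outside "
                    f"{self.grid.n_rows}x{self.grid.n_cols} grid"
                )
            key = (r, c, float(tr.stim_power_mW))
            if key in seen and not self.allow_repeats:
                raise ValidationError(
                    f"trial {i}: repeated site/power {key} without allow_repeats"
                )
            seen.add(key)

    @property
    def limb_labels(self) -> tuple[str, ...]:
        return self.trials[0].limb_labels if self.trials else ()


def _accel_columns(limbs: tuple[str, ...]) -> list[str]:
    cols: list[str] = []
    for limb in limbs:
        cols += [f"{limb}_ax_V", f"{limb}_ay_V", f"{limb}_az_V"]
    return cols


def write_session(session: Session, path: str | os.PathLike) -> None:
    """Write a session directory (manifest + one CSV per trial)."""
    path = os.fspath(path)
    os.makedirs(path, exist_ok=True)
    limbs = list(session.limb_labels)
    manifest: dict = {
        "grid": {
            "n_rows": session.grid.n_rows,
            "n_cols": session.grid.n_cols,
            "spacing_mm": session.grid.spacing_mm,
            "bregma_rc": list(session.grid.bregma_rc),
        },
        "sample_rate_hz": session.trials[0].sample_rate_hz if session.trials else None,
        "calibration_v_per_g": session.calibration_v_per_g,
        "eeg_gain": session.eeg_gain,
        "limbs": limbs,
        "trials": [],
    }
    for i, tr in enumerate(session.trials):
        fname = f"trial_{i:04d}.csv"
        manifest["trials"].append(
            {
                "file": fname,
                "row": tr.grid_rc[0],
                "col": tr.grid_rc[1],
                "power_mW": float(tr.stim_power_mW),
                "duration_s": float(tr.stim_duration_s),
                "stim_index": int(tr.t_stim_index),
            }
        )
        data = {"time_s": tr.time_s()}
        for limb in tr.limb_labels:
            a = tr.accel_raw[limb]
            for j, ax in enumerate(("ax", "ay", "az")):
                data[f"{limb}_{ax}_V"] = a[:, j]
        data["eeg_V"] = tr.eeg_raw
        pd.DataFrame(data).to_csv(
            os.path.join(path, fname), index=False, float_format=_FLOAT_FMT
        )
    with open(os.path.join(path, MANIFEST_NAME), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_session(path: str | os.PathLike) -> Session:
    """Read and validate a session directory written by :func:`write_session`."""
    path = os.fspath(path)
    manifest_path = os.path.join(path, MANIFEST_NAME)
    if not os.path.exists(manifest_path):
        raise FormatError(f"missing manifest file: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    try:
        g = manifest["grid"]
        grid = GridSpec(
            n_rows=int(g["n_rows"]),
            n_cols=int(g["n_cols"]),
            spacing_mm=float(g["spacing_mm"]),
            bregma_rc=tuple(g["bregma_rc"]),
        )
        limbs = tuple(manifest.get("limbs", []))
        sample_rate = manifest["sample_rate_hz"]
        cal = float(manifest["calibration_v_per_g"])
        gain = float(manifest["eeg_gain"])
        trial_entries = manifest.get("trials", [])
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed manifest {manifest_path}: {exc}") from exc

    expected_cols = ["time_s", *_accel_columns(limbs), "eeg_V"]
    trials: list[TrialRecord] = []
    for entry in trial_entries:
        fpath = os.path.join(path, entry["file"])
        if not os.path.exists(fpath):
            raise FormatError(f"missing trial file: {fpath}")
        df = pd.read_csv(fpath)
        if list(df.columns) != expected_cols:
            raise ValidationError(
                f"trial file {entry['file']}: expected columns {expected_cols}, "
                f"got {list(df.columns)}"
            )
        accel = {
            limb: df[_accel_columns((limb,))].to_numpy(dtype=float) for limb in limbs
        }
        trials.append(
            TrialRecord(
                grid_rc=(int(entry["row"]), int(entry["col"])),
                stim_power_mW=float(entry["power_mW"]),
                stim_duration_s=float(entry["duration_s"]),
                sample_rate_hz=float(sample_rate),
                t_stim_index=int(entry["stim_index"]),
                accel_raw=accel,
                eeg_raw=df["eeg_V"].to_numpy(dtype=float),
                limb_labels=limbs,
            )
        )
    return Session(
        grid=grid, trials=trials, calibration_v_per_g=cal, eeg_gain=gain
    )


def write_map(grid_map, path: str | os.PathLike) -> None:
    """Write a grid map as TSV (row 0 = most anterior) plus a YAML sidecar.

    Inactive pixels are emitted as the literal token ``NA``; the sidecar
    (``<path minus .tsv>.meta.yaml``) records the grid geometry, units and
    limb label so the map is self-describing.
    """
    path = os.fspath(path)
    values = np.asarray(grid_map.values, dtype=float)
    mask = np.asarray(grid_map.mask, dtype=bool)
    lines = []
    for r in range(values.shape[0]):
        cells = [
            (_FLOAT_FMT % values[r, c]) if mask[r, c] and np.isfinite(values[r, c])
            else "NA"
            for c in range(values.shape[1])
        ]
        lines.append("\t".join(cells))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    meta = {
        "grid": {
            "n_rows": grid_map.grid.n_rows,
            "n_cols": grid_map.grid.n_cols,
            "spacing_mm": grid_map.grid.spacing_mm,
            "bregma_rc": list(grid_map.grid.bregma_rc),
        },
        "units": grid_map.units,
        "limb": grid_map.limb,
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def _sidecar_path(path: str) -> str:
    base = path[:-4] if path.endswith(".tsv") else path
    return base + ".meta.yaml"


def read_map(path: str | os.PathLike):
    """Read a map TSV + sidecar back into a :class:`~lbmm.mapping.GridMap`."""
    from .mapping import GridMap  # deferred: mapping imports GridSpec from here

    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"missing map file: {path}")
    sidecar = _sidecar_path(path)
    if not os.path.exists(sidecar):
        raise FormatError(f"missing map sidecar: {sidecar}")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    g = meta["grid"]
    grid = GridSpec(
        n_rows=int(g["n_rows"]),
        n_cols=int(g["n_cols"]),
        spacing_mm=float(g["spacing_mm"]),
        bregma_rc=tuple(g["bregma_rc"]),
    )
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                rows.append(line.split("\t"))
    if len(rows) != grid.n_rows or any(len(r) != grid.n_cols for r in rows):
        raise ValidationError(
            f"map body shape does not match sidecar grid "
            f"{grid.n_rows}x{grid.n_cols} in {path}"
        )
    values = np.full((grid.n_rows, grid.n_cols), np.nan)
    mask = np.zeros((grid.n_rows, grid.n_cols), dtype=bool)
    for r, cells in enumerate(rows):
        for c, cell in enumerate(cells):
            if cell != "NA":
                values[r, c] = float(cell)
                mask[r, c] = True
    return GridMap(
        grid=grid, values=values, mask=mask,
        units=meta.get("units", ""), limb=meta.get("limb"),
    )
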