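"""Quantification of light-evoked cortical depolarization from the EEG channel.

Each stimulation trial yields one scalar: the mean evoked deflection over a
fixed post-stimulus integration window (70 ms by default). The amplifier
output is baseline-corrected by the pre-stimulus mean, rectified (so
mixed-polarity deflections do not cancel; a signed mode is available),
integrated by the trapezoid rule, divided by the window duration and
referred back to the electrode by dividing out the amplifier gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ValidationError
from .io_session import Session, TrialRecord

__all__ = ["EEGTrace", "EEGResponse", "eeg_deflection", "trial_eeg_trace", "eeg_session"]


@dataclass
class EEGTrace:
    """Single-channel EEG series: time (s, relative to stimulus), amplifier
    output voltage (V) and dimensionless amplifier gain."""

    t: np.ndarray
    v: np.ndarray
    gain: float = 1000.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape:
            raise ValidationError("time and voltage lengths differ")
        if not self.gain > 0:
            raise ValidationError(f"gain must be > 0, got {self.gain}")


@dataclass(frozen=True)
class EEGResponse:
    """Mean evoked deflection (electrode-referred volts) over ``window_s``."""

    deflection: float
    window_s: float
    rectified: bool = True

    @property
    def deflection_uV(self) -> float:
        return self.deflection * 1e6


def trial_eeg_trace(trial: TrialRecord, gain: float) -> EEGTrace:
    return EEGTrace(t=trial.time_s(), v=trial.eeg_raw, gain=gain)


def eeg_deflection(
    trace: EEGTrace, window_s: float = 0.070, rectified: bool = True
) -> EEGResponse:
    """Mean baseline-subtracted EEG deflection over [0, window_s].

    With ``rectified=True`` (default) the absolute deviation from the
    baseline mean is integrated, so the result is a non-negative
    deflection magnitude; ``rectified=False`` keeps the signed integral.
    """
    if not window_s > 0:
        raise ParameterError(f"window_s must be > 0, got {window_s}")
    base = trace.t < 0
    if not base.any():
        raise ParameterError("trace has no baseline samples")
    dt = float(trace.t[1] - trace.t[0])
    if trace.t[-1] + dt / 2 < window_s:
        raise ParameterError(
            f"integration window {window_s} s exceeds post-stimulus span "
            f"({trace.t[-1]:.3f} s)"
        )
    baseline_mean = float(trace.v[base].mean())
    sel = (trace.t >= 0) & (trace.t <= window_s)
    dev = trace.v[sel] - baseline_mean
    if rectified:
        dev = np.abs(dev)
    integral = float(np.trapezoid(dev, trace.t[sel]))
    return EEGResponse(
        deflection=integral / window_s / trace.gain,
        window_s=window_s,
        rectified=rectified,
    )


def eeg_session(
    session: Session, window_s: float = 0.070, rectified: bool = True
) -> list[EEGResponse]:
    """Per-trial evoked EEG deflections for a whole session."""
    return [
        eeg_deflection(trial_eeg_trace(tr, session.eeg_gain), window_s, rectified)
        for tr in session.trials
    ]
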