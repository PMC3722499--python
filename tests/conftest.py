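import numpy as np
import pytest

from lbmm.io_session import GridSpec, Session, TrialRecord
from lbmm.kinematics import AccelTrace, detect_session
from lbmm.simulate import GaussianField, SimConfig, simulate_session

#: Short-trace study conditions used by session-level tests: same grid,
#: rates and fields as the full protocol, but 0.3 s baseline / 0.5 s
#: post-stimulus spans to keep simulated sessions fast.
SHORT = dict(baseline_s=0.3, post_s=0.5)
SHORT_DETECT = dict(response_window_s=(0.0, 0.4))


def short_config(**overrides) -> SimConfig:
    return SimConfig(**{**SHORT, **overrides})


@pytest.fixture(scope="session")
def default_session_and_truth():
    """One full-grid synthetic session (short traces) with ground truth."""
    return simulate_session(short_config(seed=11))


@pytest.fixture(scope="session")
def default_events(default_session_and_truth):
    session, _ = default_session_and_truth
    return detect_session(session, **SHORT_DETECT)


def gravity_trace(a: np.ndarray, fs: float = 5000.0, n_base: int | None = None) -> AccelTrace:
    """Wrap an (n, 3) gravity-frame acceleration array as an AccelTrace
    whose stimulus onset sits at ``n_base`` (default: half the samples)."""
    a = np.asarray(a, dtype=float)
    if n_base is None:
        n_base = a.shape[0] // 2
    t = (np.arange(a.shape[0]) - n_base) / fs
    return AccelTrace(t=t, a=a, frame="gravity")


def tiny_session(n_limbs: int = 1, n_trials: int = 4, seed: int = 0) -> Session:
    """Small hand-built session (3x4 grid, 1 kHz) for container tests."""
    rng = np.random.default_rng(seed)
    grid = GridSpec(3, 4, 0.3, (1.0, 1.5))
    fs = 1000.0
    n = 900  # 0.3 s baseline + 0.6 s post
    limbs = tuple(f"limb{i}" for i in range(n_limbs))
    trials = []
    sites = [(r, c) for r in range(3) for c in range(4)]
    for k in range(n_trials):
        trials.append(
            TrialRecord(
                grid_rc=sites[k],
                stim_power_mW=1.0,
                stim_duration_s=0.005,
                sample_rate_hz=fs,
                t_stim_index=300,
                accel_raw={limb: rng.normal(0, 0.05, (n, 3)) - np.array([0, 0, 0.22])
                           for limb in limbs},
                eeg_raw=rng.normal(0, 0.01, n),
                limb_labels=limbs,
            )
        )
    return Session(grid=grid, trials=trials)


def zero_field(peak: float = 0.0) -> dict[str, GaussianField]:
    return {"left_forelimb": GaussianField((1.65, 0.735), 0.45, peak)}
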