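"""Shared fixtures: small geometries, synthetic recordings, brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from megfalff.cohort import make_cohort
from megfalff.forward import SensorArray, SourceModel
from megfalff.simulate import RawRecording, SignalScenario, simulate_recording


def make_raw(data: np.ndarray, fs: float, eog: np.ndarray | None = None,
             subject_id: str = "sub-test") -> RawRecording:
    """Wrap a plain array as a RawRecording (dummy sensor geometry)."""
    data = np.atleast_2d(np.asarray(data, float))
    n_ch = data.shape[0]
    sensors = SensorArray.default(n_channels=max(n_ch, 4))
    sensors = SensorArray(sensors.positions[:n_ch], sensors.orientations[:n_ch])
    if eog is None:
        eog = np.zeros((2, data.shape[1]))
    return RawRecording(data=data, fs=fs, eog=eog, sensor_array=sensors,
                        subject_id=subject_id)


def brute_force_mad_outliers(g: np.ndarray, mult: float = 5.0) -> np.ndarray:
    """Literal scaled-MAD outlier rule, written independently of the package."""
    g = np.asarray(g, float)
    med = float(np.median(g))
    abs_dev = np.abs(g - med)
    mad = float(np.median(abs_dev))
    out = []
    for i in range(len(g)):
        if abs_dev[i] > mult * 1.4826 * mad:
            out.append(i)
    return np.array(out, int)


@pytest.fixture(scope="session")
def sensors32() -> SensorArray:
    return SensorArray.default(n_channels=32)

@pytest.fixture(scope="session")
def sensors48() -> SensorArray:
    return SensorArray.default(n_channels=48)


@pytest.fixture(scope="session")
def sources25() -> SourceModel:
    return SourceModel.make_grid(spacing_mm=25.0)


@pytest.fixture(scope="session")
def short_scenario() -> SignalScenario:
    """64-s scenario (60-s analysis window, 30 epochs) for preprocessing tests.

    Blinks are denser and larger than the study default so blink-locked
    averages are not noise-floor-limited over a 1-minute fixture.
    """
    return SignalScenario(duration=64.0, fs=400.0, blink_rate=20.0,
                          blink_amplitude=4e-12)


@pytest.fixture(scope="session")
def sim_subject(short_scenario, sources25, sensors32) -> RawRecording:
    """One simulated subject with blinks, line noise and 3 injected bursts."""
    cohort = make_cohort(4, seed=42)
    return simulate_recording(cohort.iloc[0], short_scenario, sources25,
                              sensors32, seed=2024)
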