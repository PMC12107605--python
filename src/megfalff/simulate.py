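"""Synthetic resting-state MEG recordings with a planted trait effect.

Each cortical source is an amplitude-modulated band-limited noise process

    x_j(t) = e_j(t) * c_j(t)

where ``c_j`` is unit-variance Gaussian noise band-limited to the source's
carrier band, and the envelope

    e_j(t) = mu + a_j * (1 + sin(2*pi*f_slow*t + phi_j)) / 2 + sigma_e * eta_j(t)

(clipped at zero) fluctuates slowly, at a rate inside the fALFF band of the
downstream analysis (0.01–0.1 Hz). The planted effect lives in the slow
fluctuation *amplitude* of the gamma-band target source:

    a_s = a0 * (1 + coupling * z_s),      z_s = (happiness - 4.6) / 0.8

with negative coupling, so happier subjects have a flatter gamma envelope at
the target location while mean power stays trait-independent. Background
sources carry trait-independent envelopes in all four canonical bands.
Sensor data add 60-Hz line noise, a frontal blink topography driven by a
gamma-function blink train (also written to the EOG channels), white sensor
noise, and a few injected high-amplitude bad epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .forward import SensorArray, SourceModel, lead_field

__all__ = ["SignalScenario", "RawRecording", "simulate_recording", "blink_pulse"]

CANONICAL_CARRIERS = ((4.0, 8.0), (8.0, 12.0), (12.0, 30.0), (30.0, 60.0))


@dataclass
class SignalScenario:
    """Generating parameters for one synthetic recording.

    Durations in seconds, frequencies in Hz, source moments in A*m,
    sensor-level amplitudes in tesla-like units.
    """

    duration: float = 184.0       # 180-s analysis window + 2-s trim each side
    fs: float = 1000.0
    # target carrier sits inside the gamma band, clear of the 30-Hz beta/gamma
    # boundary: the two-pass Butterworth transition bands extend ~15-25% past
    # a shared cutoff, so a carrier flush against 30 Hz would plant the effect
    # in both bands' filtered power and the truth would not be band-specific
    carrier_band: tuple[float, float] = (38.0, 55.0)
    envelope_slow_freq: float = 0.03
    envelope_mu: float = 1.0
    baseline_amplitude: float = 0.8        # a0
    coupling: float = -0.5                 # gamma_eff; <0: happier -> flatter
    envelope_noise: float = 0.2            # sigma_e
    source_moment: float = 2e-8            # dipole moment scale, A*m (~20 nA*m)
    sensor_noise: float = 5e-14            # sigma_n, per-sample white noise
    blink_rate: float = 12.0               # events / minute
    blink_amplitude: float = 2e-12         # peak sensor deflection, frontal
    line_freq: float = 60.0
    line_amplitude: float = 1.5e-13
    n_background: int = 8
    background_amplitude: float = 0.8
    n_bad_epochs: int = 3
    bad_epoch_gain: float = 20.0
    trim: float = 2.0                      # analysis window starts here
    epoch_s: float = 2.0
    background_indices: tuple[int, ...] | None = None

    def validate(self) -> None:
        vals = [self.duration, self.fs, self.envelope_mu, self.baseline_amplitude,
                self.coupling, self.envelope_noise, self.sensor_noise,
                self.blink_rate, self.line_freq, *self.carrier_band]
        if not np.all(np.isfinite(vals)):
            raise ValueError("scenario parameters must be finite")
        if self.duration <= 0 or self.fs <= 0:
            raise ValueError("duration and fs must be positive")
        if not (0.0 < self.carrier_band[0] < self.carrier_band[1] < self.fs / 2):
            raise ValueError("carrier band must lie inside (0, fs/2)")

    @property
    def n_samples(self) -> int:
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * fs must be an integer sample count")
        return int(round(n))


@dataclass
class RawRecording:
    """Multichannel sensor data with simultaneous EOG."""

    data: np.ndarray          # (channels, samples)
    fs: float
    eog: np.ndarray           # (2, samples)
    sensor_array: SensorArray
    subject_id: str
    truth: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kw) -> "RawRecording":
        return replace(self, **kw)


def band_limited_noise(band: tuple[float, float], n: int, fs: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise with spectrum confined to ``band``."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def blink_pulse(t: np.ndarray, tau: float = 0.15) -> np.ndarray:
    """Gamma-function ocular pulse ``(t/tau) * exp(1 - t/tau)`` (peak 1 at t=tau)."""
    out = np.zeros_like(t)
    pos = t >= 0
    out[pos] = (t[pos] / tau) * np.exp(1.0 - t[pos] / tau)
    return out


def _blink_train(n: int, fs: float, rate_per_min: float,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    train = np.zeros(n)
    onsets = []
    if rate_per_min <= 0:
        return train, np.array(onsets)
    t = rng.exponential(60.0 / rate_per_min)
    while t * fs < n:
        onsets.append(t)
        t += rng.exponential(60.0 / rate_per_min)
    kernel_t = np.arange(0, int(1.0 * fs)) / fs
    kernel = blink_pulse(kernel_t)
    for onset in onsets:
        i0 = int(round(onset * fs))
        seg = min(len(kernel), n - i0)
        train[i0:i0 + seg] += kernel[:seg]
    return train, np.array(onsets)


def choose_background_sources(sources: SourceModel, n: int, seed: int = 987_654_321,
                              min_dist_mm: float = 30.0,
                              min_ecc_mm: float = 30.0) -> np.ndarray:
    """Fixed background source indices, away from the target and not too deep."""
    rng = np.random.default_rng(seed)
    pos = sources.grid_positions
    ecc = np.linalg.norm(pos - sources.centre_mm, axis=1)
    dist = np.linalg.norm(pos - sources.target_position, axis=1)
    ok = np.flatnonzero((dist >= min_dist_mm) & (ecc >= min_ecc_mm))
    if len(ok) < n:
        raise ValueError("not enough eligible grid points for background sources")
    return np.sort(rng.choice(ok, size=n, replace=False))


def target_slow_amplitude(happiness: float, scenario: SignalScenario) -> float:
    """Planted slow-fluctuation amplitude ``a_s`` for one subject (clipped >= 0)."""
    z = (happiness - 4.6) / 0.8
    return max(0.0, scenario.baseline_amplitude * (1.0 + scenario.coupling * z))


def simulate_recording(subject: pd.Series, scenario: SignalScenario,
                       sources: SourceModel, sensors: SensorArray,
                       seed: int) -> RawRecording:
    """Synthesize one subject's raw recording; bit-deterministic for a fixed seed.

    The ``truth`` dict records the per-source slow amplitudes ``a_j``, the
    source grid indices, blink onsets and injected bad-epoch indices, so that
    downstream recovery claims can be checked against ground truth.
    """
    scenario.validate()
    rng = np.random.default_rng(seed)
    n = scenario.n_samples
    fs = scenario.fs
    t = np.arange(n) / fs

    bg = scenario.background_indices
    if bg is None:
        bg = choose_background_sources(sources, scenario.n_background)
    bg = np.asarray(bg, int)

    src_indices = np.concatenate([[sources.target_index], bg])
    a_target = target_slow_amplitude(float(subject["happiness"]), scenario)
    amplitudes = np.concatenate(
        [[a_target], np.full(len(bg), scenario.background_amplitude)])
    carriers = [scenario.carrier_band] + [
        CANONICAL_CARRIERS[k % len(CANONICAL_CARRIERS)] for k in range(len(bg))]

    f_slows = np.empty(len(src_indices))
    X = np.empty((len(src_indices), n))
    gains = np.empty((sensors.n_channels, len(src_indices)))
    for j, (idx, a_j, carrier) in enumerate(zip(src_indices, amplitudes, carriers)):
        f_slow = (scenario.envelope_slow_freq if j == 0
                  else rng.uniform(0.02, 0.08))
        f_slows[j] = f_slow
        phi = rng.uniform(0, 2 * np.pi)
        eta = band_limited_noise((1e-4, 1.0), n, fs, rng)
        env = (scenario.envelope_mu
               + a_j * (1.0 + np.sin(2 * np.pi * f_slow * t + phi)) / 2.0
               + scenario.envelope_noise * eta)
        np.clip(env, 0.0, None, out=env)
        X[j] = env * band_limited_noise(carrier, n, fs, rng)
        gains[:, j] = lead_field(
            sources.grid_positions[idx], sources.dipole_orientations[idx],
            sensors, sources.conductor_radius_mm, sources.centre_mm)
    data = scenario.source_moment * (gains @ X)

    # 60-Hz line noise: common sinusoid, per-channel coupling
    if scenario.line_amplitude > 0:
        line_phase = rng.uniform(0, 2 * np.pi)
        coupling = 1.0 + 0.2 * rng.standard_normal(sensors.n_channels)
        line = np.sin(2 * np.pi * scenario.line_freq * t + line_phase)
        data += scenario.line_amplitude * np.outer(coupling, line)

    # blinks: frontal-weighted topography, copied into EOG
    train, onsets = _blink_train(n, fs, scenario.blink_rate, rng)
    front = np.array([0.0, 0.09, 0.03])
    w = np.exp(-np.sum((sensors.positions - front) ** 2, axis=1) / (2 * 0.06**2))
    data += scenario.blink_amplitude * np.outer(w, train)

    if scenario.sensor_noise > 0:
        data += scenario.sensor_noise * rng.standard_normal(data.shape)

    eog = np.vstack([
        100e-6 * train + 5e-6 * rng.standard_normal(n),
        30e-6 * train + 5e-6 * rng.standard_normal(n),
    ])

    # injected high-amplitude bad epochs, aligned to the analysis epoch grid
    n_epochs = int((scenario.duration - 2 * scenario.trim) // scenario.epoch_s)
    bad = np.array([], int)
    if scenario.n_bad_epochs > 0:
        # non-adjacent epochs, cosine-tapered gain: the burst energy stays in
        # its own epoch even after the pipeline's anti-alias / band filters
        # spread edges by a few tens of milliseconds
        chosen: list[int] = []
        for k in rng.permutation(n_epochs):
            if all(abs(k - c) >= 2 for c in chosen):
                chosen.append(int(k))
            if len(chosen) == scenario.n_bad_epochs:
                break
        bad = np.sort(np.array(chosen, int))
        for k in bad:
            i0 = int(round((scenario.trim + k * scenario.epoch_s) * fs))
            i1 = i0 + int(round(scenario.epoch_s * fs))
            taper = signal.windows.tukey(i1 - i0, alpha=0.5)
            data[:, i0:i1] *= 1.0 + (scenario.bad_epoch_gain - 1.0) * taper

    truth = {
        "source_indices": src_indices,
        "a": amplitudes,
        "target_source": 0,
        "target_grid_index": int(sources.target_index),
        "f_slow": f_slows,
        "blink_onsets": onsets,
        "bad_epochs": bad,
        "happiness": float(subject["happiness"]),
    }
    return RawRecording(data=data, fs=fs, eog=eog, sensor_array=sensors,
                        subject_id=str(subject["subject_id"]), truth=truth)
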