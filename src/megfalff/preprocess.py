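"""Sensor-space preprocessing: decimation, line-noise removal, ICA-based
artifact rejection, band filtering, epoching and robust bad-epoch detection.

Fixed stage order: downsample -> DFT line filter -> trim -> ICA
decompose/remove -> bandpass -> epoch -> bad-epoch flagging. Every stage is a
pure function of its inputs. Bad epochs are detected on the broadband
(pre-bandpass) data and the resulting mask is shared across bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats
from sklearn.decomposition import FastICA

from .simulate import RawRecording

__all__ = [
    "BandDefinition", "CANONICAL_BANDS", "EpochedBandData",
    "ComponentDecomposition", "downsample", "remove_line_noise", "trim",
    "decompose_and_flag", "remove_components", "bandpass", "epoch",
    "detect_bad_epochs",
]

MAD_SCALE = 1.4826  # consistency factor: scaled MAD estimates sigma for normal data


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float

    def validate(self, fs: float) -> None:
        if not (0.0 < self.lo < self.hi < fs / 2):
            raise ValueError(
                f"band {self.name} ({self.lo}-{self.hi} Hz) must lie inside (0, {fs / 2})"
            )


CANONICAL_BANDS: dict[str, BandDefinition] = {
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "beta": BandDefinition("beta", 12.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 60.0),
}


@dataclass
class EpochedBandData:
    """Band-limited sensor data cut into contiguous non-overlapping epochs."""

    data: np.ndarray                 # (channels, epochs, samples_per_epoch)
    band: BandDefinition | None
    fs: float
    epoch_ms: float
    bad_epochs: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def n_epochs(self) -> int:
        return self.data.shape[1]

    @property
    def good_epochs(self) -> np.ndarray:
        return np.setdiff1d(np.arange(self.n_epochs), self.bad_epochs)


@dataclass
class ComponentDecomposition:
    """Linear unmixing of sensor data with per-component artifact flags.

    input = channel_mean + mixing @ sources + residual, where residual is the
    part of the data outside the retained component subspace.
    """

    mixing: np.ndarray               # (channels, components)
    sources: np.ndarray              # (components, samples)
    channel_mean: np.ndarray         # (channels,)
    residual: np.ndarray             # (channels, samples)
    eog_correlated: np.ndarray       # bool per component
    high_kurtosis: np.ndarray
    spectral_artifact: np.ndarray

    @property
    def flagged(self) -> np.ndarray:
        return self.eog_correlated | self.high_kurtosis | self.spectral_artifact

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]

    def reconstruct(self) -> np.ndarray:
        return self.channel_mean[:, None] + self.mixing @ self.sources + self.residual


def downsample(rec: RawRecording, target_fs: float) -> RawRecording:
    """Anti-aliased decimation to ``target_fs`` (must divide the sampling rate)."""
    q = rec.fs / target_fs
    if abs(q - round(q)) > 1e-9:
        raise ValueError(f"target_fs {target_fs} must divide fs {rec.fs}")
    q = int(round(q))
    if q == 1:
        return rec
    data = signal.resample_poly(rec.data, up=1, down=q, axis=1)
    eog = signal.resample_poly(rec.eog, up=1, down=q, axis=1)
    return rec.copy_with(data=data, eog=eog, fs=float(target_fs))


def remove_line_noise(rec: RawRecording, base: float = 60.0,
                      half_width: float = 0.1) -> RawRecording:
    """DFT filter: zero the Fourier bins at ``base`` and its harmonics.

    Bins within ``half_width`` Hz of each harmonic below Nyquist are zeroed;
    with minutes-long recordings the bin spacing is a few mHz, so content
    1 Hz away is untouched.
    """
    if base >= rec.fs / 2:
        raise ValueError(f"line frequency {base} must be below Nyquist {rec.fs / 2}")
    n = rec.n_samples
    f = np.fft.rfftfreq(n, 1.0 / rec.fs)
    spec = np.fft.rfft(rec.data, axis=1)
    for k in range(1, int(np.floor((rec.fs / 2) / base)) + 1):
        spec[:, np.abs(f - k * base) <= half_width] = 0.0
    return rec.copy_with(data=np.fft.irfft(spec, n, axis=1))


def trim(rec: RawRecording, seconds: float) -> RawRecording:
    """Drop ``seconds`` from each end of the recording."""
    if seconds <= 0:
        return rec
    k = int(round(seconds * rec.fs))
    if 2 * k >= rec.n_samples:
        raise ValueError("trim longer than the recording")
    return rec.copy_with(data=rec.data[:, k:-k], eog=rec.eog[:, k:-k])


def _power_fraction_above(x: np.ndarray, fs: float, f_cut: float) -> np.ndarray:
    f, pxx = signal.welch(x, fs=fs, nperseg=min(x.shape[-1], 1024), axis=-1)
    total = pxx.sum(axis=-1)
    total[total == 0] = 1.0
    return pxx[..., f > f_cut].sum(axis=-1) / total


def _robust_sample_mask(X: np.ndarray, fs: float, win_s: float = 2.0,
                        mad_multiplier: float = 5.0) -> np.ndarray:
    """Samples outside provisional high-amplitude windows (scaled-MAD rule)."""
    n = X.shape[1]
    w = max(1, int(round(win_s * fs)))
    nw = n // w
    if nw < 3:
        return np.ones(n, bool)
    g = np.sqrt(np.mean(
        X[:, : nw * w].reshape(X.shape[0], nw, w) ** 2, axis=(0, 2)))
    med = np.median(g)
    mad = MAD_SCALE * np.median(np.abs(g - med))
    mask = np.ones(n, bool)
    if mad == 0:
        return mask
    for i in np.flatnonzero(np.abs(g - med) > mad_multiplier * mad):
        mask[i * w:(i + 1) * w] = False
    return mask


def decompose_and_flag(rec: RawRecording, eog: np.ndarray | None = None,
                       corr_thresh: float = 0.5, kurt_z_thresh: float = 5.0,
                       spectral_frac: float = 0.5, spectral_freq: float = 80.0,
                       n_components: int | None = None,
                       random_state: int = 0) -> ComponentDecomposition:
    """ICA unmixing plus automated artifact flagging.

    The unmixing is *fitted* on robustly selected samples (provisional
    high-amplitude windows excluded, so rare huge bursts cannot dominate the
    decomposition) and then applied to all samples; component metrics are
    likewise evaluated on the robust samples. A component is flagged
    *eog-correlated* iff its absolute Pearson correlation with either EOG
    channel reaches ``corr_thresh``; *high-kurtosis* iff the robust z-score
    of its excess kurtosis (median / scaled-MAD across components) reaches
    ``kurt_z_thresh``; and *spectral-artifact* iff more than
    ``spectral_frac`` of its spectral power lies above ``spectral_freq`` Hz
    (muscle-like broadband activity).
    """
    X = rec.data
    if X.shape[0] < 2:
        raise ValueError("need at least 2 channels for a decomposition")
    if eog is None:
        eog = rec.eog
    k = n_components or min(X.shape[0], 30)
    if k > X.shape[0]:
        raise ValueError("more components than channels")
    fit_mask = _robust_sample_mask(X, rec.fs)
    mean = X[:, fit_mask].mean(axis=1)
    ica = FastICA(n_components=k, whiten="unit-variance", max_iter=500,
                  tol=1e-3, random_state=random_state)
    ica.fit(X[:, fit_mask].T)
    sources = ica.transform(X.T).T                        # (k, samples)
    mixing = ica.mixing_                                  # (channels, k)
    residual = X - mean[:, None] - mixing @ sources
    src_fit = sources[:, fit_mask]

    eog_flags = np.zeros(k, bool)
    for ch in range(eog.shape[0]):
        e = eog[ch][fit_mask]
        if np.std(e) == 0:
            warnings.warn("constant EOG channel: correlation flag skipped")
            continue
        ez = (e - e.mean()) / e.std()
        r = (src_fit - src_fit.mean(1, keepdims=True)) @ ez / (
            src_fit.shape[1] * src_fit.std(1).clip(1e-30))
        eog_flags |= np.abs(r) >= corr_thresh

    kurt = stats.kurtosis(src_fit, axis=1, fisher=True)
    med = np.median(kurt)
    mad = MAD_SCALE * np.median(np.abs(kurt - med))
    if mad == 0:
        kurt_flags = np.zeros(k, bool)
    else:
        kurt_flags = (kurt - med) / mad >= kurt_z_thresh

    if spectral_freq < rec.fs / 2:
        frac = _power_fraction_above(src_fit, rec.fs, spectral_freq)
        spec_flags = frac > spectral_frac
    else:
        spec_flags = np.zeros(k, bool)

    return ComponentDecomposition(
        mixing=mixing, sources=sources, channel_mean=mean, residual=residual,
        eog_correlated=eog_flags, high_kurtosis=kurt_flags,
        spectral_artifact=spec_flags,
    )


def remove_components(rec: RawRecording, decomp: ComponentDecomposition,
                      flags: np.ndarray | None = None) -> RawRecording:
    """Subtract the flagged components' sensor projection from the data."""
    flags = decomp.flagged if flags is None else np.asarray(flags)
    if flags.dtype != bool:
        idx = np.asarray(flags, int)
        flags = np.zeros(decomp.n_components, bool)
        flags[idx] = True
    if flags.all():
        raise ValueError("all components flagged as artifacts; refusing to "
                         "remove the entire recording")
    if decomp.mixing.shape[0] != rec.data.shape[0]:
        raise ValueError("decomposition does not match the recording")
    cleaned = rec.data - decomp.mixing[:, flags] @ decomp.sources[flags]
    return rec.copy_with(data=cleaned)


def bandpass(rec: RawRecording, band: BandDefinition, order: int = 5) -> RawRecording:
    """Zero-phase (forward-backward) Butterworth bandpass."""
    band.validate(rec.fs)
    sos = signal.butter(order, [band.lo, band.hi], btype="bandpass",
                        output="sos", fs=rec.fs)
    return rec.copy_with(data=signal.sosfiltfilt(sos, rec.data, axis=1))


def epoch(rec: RawRecording, epoch_ms: float = 2000.0,
          band: BandDefinition | None = None) -> EpochedBandData:
    """Cut into contiguous non-overlapping epochs; trailing remainder dropped."""
    if epoch_ms <= 0:
        raise ValueError("epoch_ms must be positive")
    spe = int(round(epoch_ms / 1000.0 * rec.fs))
    n_ep = rec.n_samples // spe
    if n_ep == 0:
        raise ValueError(
            f"recording ({rec.duration:.3f} s) shorter than one epoch "
            f"({epoch_ms / 1000.0:.3f} s)")
    data = rec.data[:, : n_ep * spe].reshape(rec.data.shape[0], n_ep, spe)
    return EpochedBandData(data=data.copy(), band=band, fs=rec.fs, epoch_ms=epoch_ms)


def global_signal(ep: EpochedBandData) -> np.ndarray:
    """Per-epoch global signal: RMS over all channels and samples."""
    return np.sqrt(np.mean(ep.data**2, axis=(0, 2)))


def detect_bad_epochs(ep: EpochedBandData, mad_multiplier: float = 5.0) -> np.ndarray:
    """Flag epochs whose global signal is an outlier under the scaled-MAD rule.

    Epoch i is bad iff |g_i - median(g)| > multiplier * 1.4826 * MAD(g).
    """
    if ep.n_epochs < 3:
        raise ValueError("need at least 3 epochs to detect outliers")
    g = global_signal(ep)
    med = np.median(g)
    mad = MAD_SCALE * np.median(np.abs(g - med))
    if mad == 0 and np.ptp(g) > 0:
        # zero threshold: every deviation from the majority value is flagged
        warnings.warn("zero MAD with non-constant global signal; any epoch "
                      "deviating from the median is flagged")
    return np.flatnonzero(np.abs(g - med) > mad_multiplier * mad)
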