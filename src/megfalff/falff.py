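"""fALFF: fractional amplitude of low-frequency fluctuation of band-limited
power time series.

The 90-point per-epoch power series is sampled at 0.5 Hz (one value per 2-s
epoch), so its spectrum covers (0, 0.25] Hz with a bin spacing of 1/180 Hz.
fALFF is the ratio of summed Fourier amplitudes (moduli) in the low-frequency
band (0.01-0.1 Hz by default) to the sum over all positive frequencies; the
DC bin is excluded from both sums. Before the spectrum is taken, censored
(bad-epoch) timepoints are repaired by natural cubic-spline interpolation and
nuisance signals (constant, linear drift, two EOG band-limited power
regressors) are regressed out voxel-wise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .volume import VolumeGrid, VolumeMap, VolumeSeries

__all__ = ["SubjectExcluded", "NuisanceSet", "FALFFMap", "censor_interpolate",
           "build_nuisance", "regress_nuisance", "compute_falff", "falff_map",
           "zscore_map"]


class SubjectExcluded(RuntimeError):
    """Raised when a subject cannot be analysed (e.g., too many bad epochs)."""


@dataclass
class NuisanceSet:
    """Nuisance design: constant, drift, and two EOG band-power regressors."""

    matrix: np.ndarray           # (timepoints, 4)
    names: tuple[str, ...] = ("constant", "drift", "eog_v_power", "eog_h_power")


@dataclass
class FALFFMap:
    """Per-subject, per-band fALFF map: raw fractions and z-scored values."""

    values: np.ndarray           # z-scored, (n_mask_voxels,)
    raw_values: np.ndarray       # fALFF in [0, 1]
    grid: VolumeGrid
    mask: np.ndarray
    band: str | None = None
    subject_id: str | None = None


def censor_interpolate(series: VolumeSeries) -> VolumeSeries:
    """Replace censored timepoints by natural cubic-spline interpolation.

    Leading/trailing censored points take the nearest good value. Good
    timepoints are untouched. Raises :class:`SubjectExcluded` when more than
    half the timepoints are censored.
    """
    bad = np.asarray(series.bad_epochs, int)
    n = series.n_timepoints
    if bad.size == 0:
        return series
    if bad.size > n / 2:
        raise SubjectExcluded(
            f"{bad.size}/{n} timepoints censored (> 50%); subject excluded")
    good = np.setdiff1d(np.arange(n), bad)
    vals = series.values.copy()
    inner = bad[(bad > good[0]) & (bad < good[-1])]
    if inner.size:
        # spline interpolation is linear in the data: evaluate the natural
        # spline of the identity basis once and apply the weights to all voxels
        W = CubicSpline(good, np.eye(good.size), axis=0, bc_type="natural")(inner)
        vals[:, inner] = vals[:, good] @ W.T
    vals[:, bad[bad < good[0]]] = vals[:, [good[0]]]
    vals[:, bad[bad > good[-1]]] = vals[:, [good[-1]]]
    out = VolumeSeries(values=vals, grid=series.grid, mask=series.mask,
                       band=series.band, bad_epochs=np.array([], int))
    return out


def _epoch_band_power(eog: np.ndarray, fs: float, band, epoch_ms: float,
                      n_epochs: int) -> np.ndarray:
    """Per-epoch mean squared band-limited amplitude of one EOG channel."""
    from .preprocess import bandpass, epoch as cut
    from .simulate import RawRecording
    from .forward import SensorArray
    dummy = SensorArray(np.array([[0.0, 0.0, 0.2]]), np.array([[0.0, 0.0, 1.0]]))
    rec = RawRecording(data=np.atleast_2d(eog), fs=fs,
                       eog=np.zeros((2, len(eog))), sensor_array=dummy,
                       subject_id="eog")
    ep = cut(bandpass(rec, band), epoch_ms)
    p = np.mean(ep.data[0] ** 2, axis=1)
    return p[:n_epochs]


def build_nuisance(eog: np.ndarray, fs: float, band, epoch_ms: float,
                   n_epochs: int) -> NuisanceSet:
    """Assemble the 4-column nuisance set for one subject and band."""
    const = np.ones(n_epochs)
    drift = np.linspace(-1.0, 1.0, n_epochs)
    ev = _epoch_band_power(eog[0], fs, band, epoch_ms, n_epochs)
    eh = _epoch_band_power(eog[1], fs, band, epoch_ms, n_epochs)
    return NuisanceSet(matrix=np.column_stack([const, drift, ev, eh]))


def regress_nuisance(series: VolumeSeries, nuisance: NuisanceSet) -> VolumeSeries:
    """Voxel-wise OLS residuals of the series on the nuisance columns."""
    N = nuisance.matrix
    if N.shape[0] != series.n_timepoints:
        raise ValueError("nuisance rows must match the number of timepoints")
    Nc = N - N.mean(axis=0)
    keep = np.ones(N.shape[1], bool)
    # drop columns that are (near-)collinear after centering, constant first
    rank = np.linalg.matrix_rank(N)
    if rank < N.shape[1]:
        warnings.warn("rank-deficient nuisance set; dropping dependent columns")
        q = np.zeros((N.shape[0], 0))
        for j in range(N.shape[1]):
            cand = np.column_stack([q, N[:, j]])
            if np.linalg.matrix_rank(cand) > q.shape[1]:
                q = cand
            else:
                keep[j] = False
    X = N[:, keep]
    beta, *_ = np.linalg.lstsq(X, series.values.T, rcond=None)
    resid = series.values - (X @ beta).T
    return VolumeSeries(values=resid, grid=series.grid, mask=series.mask,
                        band=series.band, bad_epochs=series.bad_epochs.copy())


def compute_falff(ts: np.ndarray, fs_env: float = 0.5, lo: float = 0.01,
                  hi: float = 0.1) -> np.ndarray:
    """Fractional amplitude of low-frequency fluctuation of one or many series.

    ``ts`` is (..., timepoints). Amplitude is the modulus of the DFT at
    positive frequencies f_k = k * fs_env / N, k = 1..floor(N/2); fALFF is
    the in-band amplitude sum divided by the total. Result lies in [0, 1];
    an all-zero series yields 0 (with a warning).
    """
    ts = np.asarray(ts, float)
    n = ts.shape[-1]
    if n < 8:
        raise ValueError("need at least 8 timepoints")
    if not np.all(np.isfinite(ts)):
        raise ValueError("non-finite values in time series")
    amp = np.abs(np.fft.rfft(ts, axis=-1))[..., 1:]      # DC excluded
    f = np.fft.rfftfreq(n, d=1.0 / fs_env)[1:]
    in_band = (f >= lo) & (f <= hi)
    total = amp.sum(axis=-1)
    zero = total == 0
    if np.any(zero):
        warnings.warn("all-zero time series; fALFF set to 0")
    total = np.where(zero, 1.0, total)
    out = amp[..., in_band].sum(axis=-1) / total
    return np.where(zero, 0.0, out)


def falff_map(series: VolumeSeries, fs_env: float = 0.5, lo: float = 0.01,
              hi: float = 0.1) -> np.ndarray:
    """Raw (pre-z) fALFF at every masked voxel of a volume series."""
    return compute_falff(series.values, fs_env=fs_env, lo=lo, hi=hi)


def zscore_map(raw: np.ndarray, grid: VolumeGrid, mask: np.ndarray,
               band: str | None = None,
               subject_id: str | None = None) -> FALFFMap:
    """Standardize a voxel map over the analysis mask (mean 0, SD 1)."""
    raw = np.asarray(raw, float)
    if raw.size < 2:
        raise ValueError("need at least 2 masked voxels")
    sd = raw.std()
    if sd == 0:
        raise ValueError("zero variance over the mask; cannot z-score")
    z = (raw - raw.mean()) / sd
    return FALFFMap(values=z, raw_values=raw, grid=grid, mask=mask,
                    band=band, subject_id=subject_id)
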