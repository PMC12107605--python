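"""LCMV beamformer: sensor covariance, unit-gain spatial filters and
band-limited power image series on the source grid.

The spatial filter at grid point j is the linearly-constrained
minimum-variance solution

    w_j = C^-1 L_j / (L_j' C^-1 L_j)

which passes unit gain on the point's lead field while minimizing output
variance. With free orientation the dipole orientation is chosen per grid
point to maximize output power (the generalized-eigenvector solution on the
lead-field triplet). Points with a near-zero lead field (magnetically silent
in a sphere) are marked invalid and excluded from maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import SensorArray, SourceModel, lead_field_matrix
from .preprocess import BandDefinition, EpochedBandData

__all__ = ["SensorCovariance", "BeamformerWeights", "SourcePowerSeries",
           "compute_covariance", "lcmv_weights", "band_power_images"]


@dataclass
class SensorCovariance:
    matrix: np.ndarray
    band: BandDefinition | None = None
    regularization: float = 0.0

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]


@dataclass
class BeamformerWeights:
    weights: np.ndarray          # (grid_points, channels); NaN rows where invalid
    grid: SourceModel
    orientations: np.ndarray     # (grid_points, 3) chosen dipole orientations
    valid: np.ndarray            # bool per grid point


@dataclass
class SourcePowerSeries:
    """Per-epoch band-limited power at each source-space location."""

    values: np.ndarray           # (voxels, epochs), >= 0
    band: BandDefinition | None
    bad_epochs: np.ndarray
    positions_mm: np.ndarray     # (voxels, 3) MNI mm
    grid_spacing_mm: float

    @property
    def n_epochs(self) -> int:
        return self.values.shape[1]


def compute_covariance(ep: EpochedBandData, good: np.ndarray | None = None,
                       reg: float = 0.05) -> SensorCovariance:
    """Sample covariance over good epochs with diagonal loading.

    C = (1/T) sum_good X X' + reg * mean(diag) * I.
    """
    if reg < 0:
        raise ValueError("regularization must be non-negative")
    good = ep.good_epochs if good is None else np.asarray(good, int)
    if good.size == 0:
        raise ValueError("no good epochs to compute a covariance from")
    if good.size < ep.data.shape[0] / 4:
        import warnings
        warnings.warn("fewer good epochs than channels/4; covariance may be "
                      "poorly conditioned")
    X = ep.data[:, good, :].reshape(ep.data.shape[0], -1)
    C = (X @ X.T) / X.shape[1]
    C = 0.5 * (C + C.T)
    if reg > 0:
        C = C + reg * np.mean(np.diag(C)) * np.eye(C.shape[0])
    return SensorCovariance(matrix=C, band=ep.band, regularization=reg)


def _optimal_orientation(Lj: np.ndarray, Cinv: np.ndarray) -> np.ndarray:
    """Power-maximizing orientation: minimize u' (L' C^-1 L) u over unit u.

    The near-radial direction is magnetically silent in a sphere, so the
    minimization is restricted to the numerically visible column space of L.
    """
    U, s, _ = np.linalg.svd(Lj, full_matrices=False)
    keep = s > 1e-8 * s[0]
    B = Lj.T @ Cinv @ Lj
    # work in the visible subspace spanned by right singular vectors
    _, _, Vt = np.linalg.svd(Lj, full_matrices=False)
    V = Vt[keep].T                       # (3, k)
    M = V.T @ B @ V
    evals, evecs = np.linalg.eigh(M)
    u = V @ evecs[:, 0]
    return u / np.linalg.norm(u)


def lcmv_weights(C: SensorCovariance, grid: SourceModel, sensors: SensorArray,
                 fixed_orientations: bool = False, silent_tol: float = 1e-6,
                 lead_fields: list | None = None) -> BeamformerWeights:
    """Unit-gain LCMV weights at every valid grid point.

    ``lead_fields`` may supply precomputed (channels, 3) gain matrices per
    grid point (they are recomputed from the geometry otherwise).
    """
    evals = np.linalg.eigvalsh(C.matrix)
    if evals[0] <= 0:
        raise ValueError("covariance must be positive-definite (regularize)")
    Cinv = np.linalg.inv(C.matrix)
    n_pts = grid.n_sources
    W = np.full((n_pts, C.n_channels), np.nan)
    oris = np.zeros((n_pts, 3))
    valid = np.zeros(n_pts, bool)
    # gain threshold relative to the strongest grid point
    gains = np.empty(n_pts)
    if lead_fields is not None:
        Lmats = list(lead_fields)
        for j in range(n_pts):
            gains[j] = np.linalg.norm(Lmats[j], 2)
    else:
        Lmats = []
        for j in range(n_pts):
            Lj = lead_field_matrix(grid.grid_positions[j], sensors,
                                   grid.conductor_radius_mm, grid.centre_mm)
            Lmats.append(Lj)
            gains[j] = np.linalg.norm(Lj, 2)
    gmax = gains.max()
    for j in range(n_pts):
        if gains[j] < silent_tol * gmax:
            continue
        Lj = Lmats[j]
        if fixed_orientations:
            u = grid.dipole_orientations[j]
        else:
            u = _optimal_orientation(Lj, Cinv)
        lj = Lj @ u
        denom = lj @ Cinv @ lj
        if denom <= 0 or np.linalg.norm(lj) < silent_tol * gmax:
            continue
        W[j] = (Cinv @ lj) / denom
        oris[j] = u
        valid[j] = True
    return BeamformerWeights(weights=W, grid=grid, orientations=oris, valid=valid)


def band_power_images(ep: EpochedBandData, w: BeamformerWeights) -> SourcePowerSeries:
    """Per-epoch mean squared beamformer output at every valid grid point."""
    if ep.data.shape[0] != w.weights.shape[1]:
        raise ValueError("weights and epochs have mismatched channel counts")
    n_ch, n_ep, spe = ep.data.shape
    Wv = w.weights[w.valid]                                   # (V, C)
    proj = np.tensordot(Wv, ep.data, axes=(1, 0))             # (V, E, S)
    values = np.mean(proj**2, axis=2)
    return SourcePowerSeries(
        values=values, band=ep.band, bad_epochs=ep.bad_epochs.copy(),
        positions_mm=w.grid.grid_positions[w.valid],
        grid_spacing_mm=w.grid.spacing_mm,
    )
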