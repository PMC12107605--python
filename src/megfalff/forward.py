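"""Sensor array, volumetric source grid and the single-sphere magnetic forward model.

The conductor is a homogeneous sphere. For MEG this admits the closed-form
field of a current dipole (Sarvas' formula), which has two convenient exact
properties used throughout the tests: a radially oriented dipole produces no
external magnetic field, and the field is linear in the dipole moment.

Coordinates: source positions are MNI millimetres. The conductor sphere is
centred at a head-centre offset in MNI space (the MNI origin is the anterior
commissure, not the centre of the head), default ``(0, -18, 18)`` mm. Sensor
positions are metres in the head-centred frame (origin at the sphere centre).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InvalidGeometryError",
    "SensorArray",
    "SourceModel",
    "HEAD_CENTRE_MM",
    "lead_field",
    "lead_field_matrix",
]

#: Conductor-sphere centre in MNI mm (superior/posterior of the AC origin).
HEAD_CENTRE_MM = np.array([0.0, -18.0, 18.0])

#: Default conductor radius, mm.
CONDUCTOR_RADIUS_MM = 90.0


class InvalidGeometryError(ValueError):
    """Source outside the conductor, or sensors inside it."""


@dataclass
class SensorArray:
    """Magnetometer-like sensors on a spherical cap.

    positions : (n, 3) metres, head-centred frame.
    orientations : (n, 3) unit vectors (radial by default).
    eog_channels : labels of the two EOG channels recorded alongside.
    """

    positions: np.ndarray
    orientations: np.ndarray
    eog_channels: tuple[str, str] = ("EOG_V", "EOG_H")

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.orientations = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        if self.positions.shape != self.orientations.shape:
            raise ValueError("positions and orientations must have matching shape")
        norms = np.linalg.norm(self.orientations, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-length sensor orientation")
        self.orientations = self.orientations / norms[:, None]

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    @classmethod
    def default(
        cls,
        n_channels: int = 120,
        radius_m: float = 0.11,
        max_polar_deg: float = 120.0,
    ) -> "SensorArray":
        """Radial magnetometers on a Fibonacci-spiral spherical cap.

        The cap opens downward from the +z pole to ``max_polar_deg`` so the
        array covers the whole head the way a helmet does.
        """
        i = np.arange(n_channels)
        z_lo = np.cos(np.deg2rad(max_polar_deg))
        z = 1.0 - (1.0 - z_lo) * (i + 0.5) / n_channels
        phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
        rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
        unit = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
        return cls(positions=radius_m * unit, orientations=unit)

    def jittered(self, sigma_m: float, rng: np.random.Generator) -> "SensorArray":
        """Copy with Gaussian position jitter (forward-model mismatch tests)."""
        pos = self.positions + rng.normal(scale=sigma_m, size=self.positions.shape)
        return SensorArray(pos, self.orientations.copy(), self.eog_channels)


def _tangential_orientation(offsets: np.ndarray) -> np.ndarray:
    """A deterministic unit vector tangential to the sphere at each offset."""
    radial = offsets / np.maximum(np.linalg.norm(offsets, axis=1, keepdims=True), 1e-12)
    ref = np.tile(np.array([0.0, 0.0, 1.0]), (len(offsets), 1))
    near_pole = np.abs(radial[:, 2]) > 0.9
    ref[near_pole] = [1.0, 0.0, 0.0]
    tang = np.cross(radial, ref)
    n = np.linalg.norm(tang, axis=1, keepdims=True)
    n[n == 0] = 1.0
    return tang / n


@dataclass
class SourceModel:
    """Cubic-lattice source grid inside the conductor.

    grid_positions : (m, 3) MNI mm.
    target_index : index of the grid point nearest the planted-effect
        location (default MNI ``(6, -62, 66)``, right precuneus).
    dipole_orientations : (m, 3) unit vectors, tangential by default
        (radial dipoles are magnetically silent in a sphere).
    """

    grid_positions: np.ndarray
    target_index: int
    dipole_orientations: np.ndarray
    spacing_mm: float
    centre_mm: np.ndarray = field(default_factory=lambda: HEAD_CENTRE_MM.copy())
    conductor_radius_mm: float = CONDUCTOR_RADIUS_MM

    @property
    def n_sources(self) -> int:
        return self.grid_positions.shape[0]

    @property
    def target_position(self) -> np.ndarray:
        return self.grid_positions[self.target_index]

    @classmethod
    def make_grid(
        cls,
        spacing_mm: float = 10.0,
        radius_mm: float = 80.0,
        centre_mm: np.ndarray | None = None,
        target_mni: np.ndarray | tuple = (6.0, -62.0, 66.0),
        conductor_radius_mm: float = CONDUCTOR_RADIUS_MM,
    ) -> "SourceModel":
        centre = HEAD_CENTRE_MM.copy() if centre_mm is None else np.asarray(centre_mm, float)
        if radius_mm >= conductor_radius_mm:
            raise InvalidGeometryError("source sphere must be inside the conductor")
        k = int(np.floor(radius_mm / spacing_mm))
        ax = np.arange(-k, k + 1) * spacing_mm
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        offs = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        norms = np.linalg.norm(offs, axis=1)
        # the exact centre is magnetically silent for every orientation
        inside = (norms < radius_mm) & (norms > 1e-9)
        offs = offs[inside]
        pos = offs + centre
        d = np.linalg.norm(pos - np.asarray(target_mni, float), axis=1)
        order = np.argsort(d)
        if len(order) > 1 and np.isclose(d[order[0]], d[order[1]]):
            # break ties toward the lexicographically smallest position
            tied = np.flatnonzero(np.isclose(d, d[order[0]]))
            order0 = tied[np.lexsort(pos[tied].T[::-1])][0]
        else:
            order0 = order[0]
        return cls(
            grid_positions=pos,
            target_index=int(order0),
            dipole_orientations=_tangential_orientation(offs),
            spacing_mm=float(spacing_mm),
            centre_mm=centre,
            conductor_radius_mm=float(conductor_radius_mm),
        )


def lead_field_matrix(
    source_pos_mm: np.ndarray,
    sensors: SensorArray,
    conductor_radius_mm: float = CONDUCTOR_RADIUS_MM,
    centre_mm: np.ndarray | None = None,
) -> np.ndarray:
    """Sarvas forward solution: (n_channels, 3) gains for unit dipoles along x/y/z.

    Gains are the projection of the dipole's external magnetic field onto each
    sensor's orientation, in tesla per (A·m) of dipole moment.
    """
    centre = HEAD_CENTRE_MM if centre_mm is None else np.asarray(centre_mm, float)
    r0 = (np.asarray(source_pos_mm, float) - centre) / 1000.0  # metres, centred
    if np.linalg.norm(r0) >= conductor_radius_mm / 1000.0:
        raise InvalidGeometryError(
            f"source at {source_pos_mm} lies outside the conductor sphere"
        )
    r = sensors.positions  # (n, 3), metres, centred
    rn = np.linalg.norm(r, axis=1)
    if np.any(rn <= conductor_radius_mm / 1000.0):
        raise InvalidGeometryError("sensors must lie strictly outside the conductor")

    a_vec = r - r0[None, :]
    a = np.linalg.norm(a_vec, axis=1)
    ar = np.einsum("ij,ij->i", a_vec, r)
    F = a * (rn * a + rn**2 - r @ r0)
    gradF = (
        (a**2 / rn + ar / a + 2.0 * a + 2.0 * rn)[:, None] * r
        - (a + 2.0 * rn + ar / a)[:, None] * r0[None, :]
    )
    mu0_4pi = 1e-7
    # B for unit moment e_k: (mu0/4pi F^2) * (F (e_k x r0) - ((e_k x r0).r) gradF)
    eye = np.eye(3)
    qxr0 = np.cross(eye, r0[None, :])  # (3, 3): row k = e_k x r0
    term1 = F[:, None, None] * qxr0[None, :, :]  # (n, 3, 3)
    qxr0_dot_r = r @ qxr0.T  # (n, 3)
    term2 = qxr0_dot_r[:, :, None] * gradF[:, None, :]
    B = mu0_4pi / (F**2)[:, None, None] * (term1 - term2)  # (n, 3moment, 3field)
    return np.einsum("nkj,nj->nk", B, sensors.orientations)


def lead_field(
    source_pos_mm: np.ndarray,
    source_ori: np.ndarray,
    sensors: SensorArray,
    conductor_radius_mm: float = CONDUCTOR_RADIUS_MM,
    centre_mm: np.ndarray | None = None,
) -> np.ndarray:
    """Per-channel gain vector of a current dipole with moment ``source_ori`` (A·m)."""
    L = lead_field_matrix(source_pos_mm, sensors, conductor_radius_mm, centre_mm)
    return L @ np.asarray(source_ori, float)
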