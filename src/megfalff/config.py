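"""Run configuration: every tunable of the study in one YAML-serialisable object."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "default_config", "reduced_config"]


@dataclass
class RunConfig:
    """Parameters of a full synthetic-cohort run.

    The defaults are the study conditions: 48 subjects, 184-s recordings at
    1000 Hz (2-s trim each side -> 180-s analysis window), 120 sensors,
    10-mm source grid, 2-mm output grid, the four canonical bands, and a
    planted coupling of -0.5 between the standardized happiness score and
    the gamma-envelope slow-fluctuation amplitude at the right-precuneus
    target. ``reduced_config`` scales the desk-expensive axes (sensors,
    grids, bands, permutations) for quick end-to-end runs.
    """

    seed: int = 7
    n_subjects: int = 48
    # generator
    duration_s: float = 184.0
    fs: float = 1000.0
    n_channels: int = 120
    coupling: float = -0.5
    envelope_slow_freq: float = 0.03
    n_bad_epochs: int = 3
    blink_rate: float = 12.0
    sensor_jitter_mm: float = 0.0       # forward-model mismatch, simulation side
    # preprocessing
    target_fs: float = 200.0
    line_freq: float = 60.0
    trim_s: float = 2.0
    epoch_ms: float = 2000.0
    mad_multiplier: float = 5.0
    ica_components: int = 30
    eog_corr_thresh: float = 0.5
    kurt_z_thresh: float = 5.0
    bands: tuple[str, ...] = ("theta", "alpha", "beta", "gamma")
    # source reconstruction
    grid_spacing_mm: float = 10.0
    source_radius_mm: float = 80.0
    covariance_reg: float = 0.05
    out_spacing_mm: float = 2.0
    fwhm_mm: float = 8.0
    # fALFF
    falff_band: tuple[float, float] = (0.01, 0.1)
    # group statistics
    covariates: tuple[str, ...] = ("sex", "age", "iq")
    n_perm: int = 1000
    roi_centres: tuple[tuple[float, float, float], ...] = ((6.0, -62.0, 66.0),
                                                          (-6.0, -62.0, 66.0))
    roi_radius_mm: float = 15.0
    roi_path: str | None = None         # optional NIfTI mask overriding the spheres
    # paths
    outdir: str = "results"

    @property
    def fs_env(self) -> float:
        """Sampling rate of the per-epoch power series (Hz)."""
        return 1000.0 / self.epoch_ms

    @property
    def n_epochs(self) -> int:
        return int((self.duration_s - 2 * self.trim_s) // (self.epoch_ms / 1000.0))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("bands", "covariates", "falff_band"):
            if key in known and isinstance(known[key], list):
                known[key] = tuple(known[key])
        if "roi_centres" in known:
            known["roi_centres"] = tuple(tuple(c) for c in known["roi_centres"])
        cfg = cls(**known)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    def validate(self) -> None:
        for name in ("duration_s", "fs", "target_fs", "epoch_ms",
                     "mad_multiplier", "fwhm_mm", "grid_spacing_mm",
                     "out_spacing_mm", "n_perm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        if not 0 < self.falff_band[0] < self.falff_band[1]:
            raise ValueError("falff_band must be an increasing positive interval")


def default_config(**overrides) -> RunConfig:
    return RunConfig(**overrides)


def reduced_config(**overrides) -> RunConfig:
    """Desk-scale preset: coarser grids, fewer sensors, gamma+beta only."""
    base = dict(
        fs=400.0,
        n_channels=48,
        ica_components=12,
        bands=("beta", "gamma"),
        grid_spacing_mm=25.0,
        out_spacing_mm=5.0,
        n_perm=499,
    )
    base.update(overrides)
    return RunConfig(**base)
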