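"""Group-level voxel-wise multiple regression of fALFF maps on a trait score.

:class:`FALFFRegression` is the model object (built from a subjects x voxels
outcome matrix and a cohort table); its :meth:`~FALFFRegression.fit` returns a
:class:`FALFFRegressionResults` carrying voxel-wise t, Z, partial-r, F and R2
maps plus permutation-based family-wise-error control, leverage diagnostics,
cluster reporting and a text summary.

Sign convention: the reported t tests the *negative* association (positive t
means higher trait -> lower fALFF), matching how such effects are tabulated;
the partial correlation keeps the raw association's sign. Family-wise error
is controlled by Freedman-Lane max-|t| permutation: the outcome is
residualised on the covariate-only model, residual rows are permuted, the
full model is refit, and the maximum |t| over the search region (whole mask,
or a region-of-interest mask for small-volume correction) builds the null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, special, stats

from .volume import VolumeGrid, VolumeMap

__all__ = ["FALFFRegression", "FALFFRegressionResults", "t_to_partial_r",
           "t_to_z", "leverage_check", "report_clusters", "permutation_fwe"]

_T_CAP = 1e6  # sentinel for perfect-fit voxels


def t_to_partial_r(t, df: int, flip_sign: bool = False):
    """Partial correlation from a t statistic: |r| = |t| / sqrt(t^2 + df).

    With ``flip_sign`` the sign is inverted, recovering the raw association's
    sign from a negative-association t. The inverse map is
    t = r * sqrt(df / (1 - r^2)).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    t = np.asarray(t, float)
    r = t / np.sqrt(t**2 + df)
    out = -r if flip_sign else r
    return out if out.ndim else float(out)


def partial_r_to_t(r, df: int):
    """Inverse of :func:`t_to_partial_r` (same-sign convention)."""
    r = np.asarray(r, float)
    out = r * np.sqrt(df / (1.0 - r**2))
    return out if out.ndim else float(out)


def t_to_z(t, df: int):
    """Map a t statistic to the standard-normal quantile of equal tail mass.

    Monotone and sign-preserving; extreme tails are evaluated in log space
    so large |t| do not saturate to +/-inf prematurely.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    t = np.asarray(t, float)
    log_sf = stats.t.logsf(np.abs(t), df)
    z = -special.ndtri_exp(log_sf)         # positive tail quantile
    out = np.sign(t) * z
    return out if out.ndim else float(out)


def leverage_check(X: np.ndarray, threshold: float = 0.21):
    """Hat-matrix diagonal per subject and flags above ``threshold``.

    The leverages sum to the number of model columns.
    """
    X = np.asarray(X, float)
    Q, R = np.linalg.qr(X)
    if np.linalg.matrix_rank(R) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    h = np.sum(Q**2, axis=1)
    return h, h > threshold


def _design_from_dataframe(cohort: pd.DataFrame, trait: str,
                           covariates: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    cols = ["intercept", trait, *covariates]
    X = np.column_stack([np.ones(len(cohort)), cohort[trait].to_numpy(float)]
                        + [cohort[c].to_numpy(float) for c in covariates])
    return X, cols


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = []
        q = np.zeros((X.shape[0], 0))
        for j in range(X.shape[1]):
            cand = np.column_stack([q, X[:, j]])
            if np.linalg.matrix_rank(cand) > q.shape[1]:
                q = cand
            else:
                bad.append(names[j])
        raise ValueError(f"design matrix rank deficient; collinear columns: {bad}")


def _t_stats(Y: np.ndarray, X: np.ndarray, c: np.ndarray):
    """Vectorized OLS contrast t over voxels. Returns (t, beta, sigma2, mse_den)."""
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y                     # (p, V)
    resid = Y - X @ beta
    df = n - p
    sigma2 = np.sum(resid**2, axis=0) / df
    var_c = float(c @ XtX_inv @ c)
    denom = np.sqrt(sigma2 * var_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (c @ beta) / np.where(denom == 0, 1.0, denom),
                     np.sign(c @ beta) * _T_CAP)
    return t, beta, sigma2


def permutation_fwe(Y: np.ndarray, X: np.ndarray, contrast: np.ndarray,
                    roi: np.ndarray | None = None, n_perm: int = 1000,
                    seed: int = 0) -> np.ndarray:
    """Freedman-Lane max-|t| permutation p-values.

    ``roi`` is a boolean vector over the voxel axis restricting the maximum
    (small-volume correction); p-values are returned for ROI voxels and NaN
    elsewhere. The minimum attainable p is 1 / (n_perm + 1).
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    n, V = Y.shape
    if n < 8:
        raise ValueError("too few subjects for a meaningful permutation test")
    c = np.asarray(contrast, float)
    sel = np.ones(V, bool) if roi is None else np.asarray(roi, bool)
    if not sel.any():
        raise ValueError("empty ROI")
    Yr = Y[:, sel]
    t_obs, *_ = _t_stats(Yr, X, c)

    # reduced model: all columns with zero contrast weight
    Z = X[:, c == 0]
    Zpinv = np.linalg.pinv(Z)
    Rz = Yr - Z @ (Zpinv @ Yr)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        t_b, *_ = _t_stats(Rz[perm], X, c)
        maxima[b] = np.max(np.abs(t_b))
    exceed = (maxima[:, None] >= np.abs(t_obs)[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (n_perm + 1.0)
    out = np.full(V, np.nan)
    out[sel] = p
    return out


def report_clusters(t_full: np.ndarray, grid: VolumeGrid, threshold: float,
                    connectivity: int = 26) -> pd.DataFrame:
    """Connected suprathreshold components of a 3D t map.

    Returns one row per cluster: peak MNI coordinates, peak t, extent in
    voxels and in mm^3 (extent x voxel volume).
    """
    if connectivity == 26:
        structure = np.ones((3, 3, 3), bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    supra = np.nan_to_num(t_full, nan=-np.inf) > threshold
    labels, n_lab = ndimage.label(supra, structure=structure)
    rows = []
    for lab in range(1, n_lab + 1):
        where = np.nonzero(labels == lab)
        vals = t_full[where]
        k = int(np.argmax(vals))
        peak_ijk = np.array([where[0][k], where[1][k], where[2][k]])
        xyz = grid.voxel_to_mni(peak_ijk)[0]
        rows.append({
            "x_mm": xyz[0], "y_mm": xyz[1], "z_mm": xyz[2],
            "t": float(vals[k]), "k_voxels": int(len(vals)),
            "k_mm3": float(len(vals) * grid.voxel_volume_mm3),
        })
    df = pd.DataFrame(rows, columns=["x_mm", "y_mm", "z_mm", "t",
                                     "k_voxels", "k_mm3"])
    return df.sort_values("t", ascending=False, ignore_index=True) if len(df) else df


class FALFFRegression:
    """Voxel-wise multiple regression model for subject-level fALFF maps.

    Parameters
    ----------
    Y : (n_subjects, n_voxels) outcome matrix (z-scored fALFF values).
    cohort : cohort table with the trait and covariate columns.
    trait : name of the regressor of interest (default ``happiness``).
    covariates : covariate columns entered as effects of no interest.
    negative_contrast : report t for the negative association (default True).
    grid, mask : optional volume geometry enabling cluster reporting.
    """

    def __init__(self, Y: np.ndarray, cohort: pd.DataFrame,
                 trait: str = "happiness",
                 covariates: tuple[str, ...] = ("sex", "age", "iq"),
                 negative_contrast: bool = True,
                 grid: VolumeGrid | None = None,
                 mask: np.ndarray | None = None,
                 interactions: tuple[tuple[str, str], ...] = ()):
        Y = np.atleast_2d(np.asarray(Y, float))
        if Y.shape[0] != len(cohort):
            raise ValueError("Y rows must match the cohort table")
        if not np.all(np.isfinite(Y)):
            raise ValueError("missing values in Y")
        X, names = _design_from_dataframe(cohort, trait, covariates)
        for a, b in interactions:
            X = np.column_stack(
                [X, cohort[a].to_numpy(float) * cohort[b].to_numpy(float)])
            names.append(f"{a}x{b}")
        if X.shape[0] <= X.shape[1]:
            raise ValueError("need more subjects than design columns")
        if np.ptp(cohort[trait].to_numpy(float)) == 0:
            raise ValueError("trait column is constant")
        _check_rank(X, names)
        self.Y = Y
        self.X = X
        self.column_names = names
        self.cohort = cohort.reset_index(drop=True)
        self.trait = trait
        self.negative_contrast = negative_contrast
        self.grid = grid
        self.mask = mask
        c = np.zeros(X.shape[1])
        c[names.index(trait)] = -1.0 if negative_contrast else 1.0
        self.contrast = c

    @classmethod
    def from_maps(cls, maps, cohort: pd.DataFrame, **kw) -> "FALFFRegression":
        """Build from a list of per-subject :class:`~megfalff.falff.FALFFMap`."""
        Y = np.vstack([m.values for m in maps])
        return cls(Y, cohort, grid=maps[0].grid, mask=maps[0].mask, **kw)

    @property
    def df_resid(self) -> int:
        return self.X.shape[0] - self.X.shape[1]

    def fit(self) -> "FALFFRegressionResults":
        t, beta, sigma2 = _t_stats(self.Y, self.X, self.contrast)
        n, p = self.X.shape
        # R^2 / F over all non-intercept columns jointly
        yc = self.Y - self.Y.mean(axis=0)
        ss_tot = np.sum(yc**2, axis=0)
        ss_res = sigma2 * (n - p)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(ss_tot > 0, 1.0 - ss_res / np.where(ss_tot == 0, 1.0, ss_tot),
                          0.0)
        r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
        F = (r2 / (p - 1)) / ((1.0 - r2) / (n - p))
        return FALFFRegressionResults(model=self, t=t, beta=beta, sigma2=sigma2,
                                      r2=r2, F_all=F)


@dataclass
class FALFFRegressionResults:
    """Estimates and diagnostics from a fitted voxel-wise regression."""

    model: FALFFRegression
    t: np.ndarray
    beta: np.ndarray
    sigma2: np.ndarray
    r2: np.ndarray
    F_all: np.ndarray
    p_fwe: np.ndarray | None = field(default=None)

    @property
    def df(self) -> int:
        return self.model.df_resid

    @property
    def df_model(self) -> int:
        return self.model.X.shape[1] - 1

    @property
    def perfect_fit(self) -> np.ndarray:
        return np.abs(self.t) >= _T_CAP

    @property
    def z(self) -> np.ndarray:
        t = np.clip(self.t, -_T_CAP, _T_CAP)
        return t_to_z(np.where(self.perfect_fit, 39.0 * np.sign(t), t), self.df)

    @property
    def partial_r(self) -> np.ndarray:
        """Partial correlation with the raw association's sign."""
        return t_to_partial_r(self.t, self.df,
                              flip_sign=self.model.negative_contrast)

    @property
    def p_uncorrected(self) -> np.ndarray:
        return stats.t.sf(self.t, self.df)

    def permutation_fwe(self, roi: np.ndarray | None = None,
                        n_perm: int = 1000, seed: int = 0) -> np.ndarray:
        """Max-|t| permutation FWE p-values (small-volume if ``roi`` given)."""
        p = permutation_fwe(self.model.Y, self.model.X, self.model.contrast,
                            roi=roi, n_perm=n_perm, seed=seed)
        self.p_fwe = p
        return p

    def leverage(self, threshold: float = 0.21):
        return leverage_check(self.model.X, threshold)

    def t_map(self) -> VolumeMap:
        if self.model.grid is None:
            raise ValueError("model was built without volume geometry")
        return VolumeMap(self.t, self.model.grid, self.model.mask)

    def clusters(self, threshold: float, connectivity: int = 26) -> pd.DataFrame:
        tm = self.t_map().to_full()
        df = report_clusters(tm, self.model.grid, threshold, connectivity)
        if len(df):
            df["z"] = t_to_z(df["t"].to_numpy(), self.df)
            df["partial_r"] = t_to_partial_r(
                df["t"].to_numpy(), self.df,
                flip_sign=self.model.negative_contrast)
        return df

    def peak(self, roi: np.ndarray | None = None) -> dict:
        """Peak-voxel statistics (optionally within a flat ROI selector)."""
        sel = np.arange(self.t.size) if roi is None else np.flatnonzero(roi)
        k = sel[np.argmax(self.t[sel])]
        out = {"voxel": int(k), "t": float(self.t[k]),
               "z": float(self.z[k]),
               "partial_r": float(self.partial_r[k]),
               "r2": float(self.r2[k]), "F_all": float(self.F_all[k]),
               "df": self.df}
        if self.p_fwe is not None and np.isfinite(self.p_fwe[k]):
            out["p_fwe"] = float(self.p_fwe[k])
        if self.model.grid is not None:
            full_idx = np.column_stack(np.nonzero(self.model.mask))[k]
            out["mni_mm"] = self.model.grid.voxel_to_mni(full_idx)[0].tolist()
        return out

    def summary(self, roi: np.ndarray | None = None) -> str:
        pk = self.peak(roi)
        lines = [
            "Voxel-wise multiple regression of fALFF on "
            f"{self.model.trait} (n={self.model.X.shape[0]}, "
            f"df={self.df}, columns={self.model.column_names})",
            f"contrast: {'negative' if self.model.negative_contrast else 'positive'}"
            f" association with {self.model.trait}",
            f"peak t({self.df}) = {pk['t']:.2f}, Z = {pk['z']:.2f}, "
            f"partial r = {pk['partial_r']:.2f}",
            f"peak F({self.df_model},{self.df}) = {pk['F_all']:.2f}, "
            f"R^2 = {pk['r2']:.3f}",
        ]
        if "mni_mm" in pk:
            x, y, z = pk["mni_mm"]
            lines.append(f"peak MNI (mm): ({x:.0f}, {y:.0f}, {z:.0f})")
        if "p_fwe" in pk:
            lines.append(f"peak permutation FWE p = {pk['p_fwe']:.4f}")
        return "\n".join(lines)

    def plot_adjusted(self, voxel: int, ax=None):
        """Scatter of covariate-adjusted fALFF at one voxel vs the trait."""
        import matplotlib.pyplot as plt
        X, names = self.model.X, self.model.column_names
        j = names.index(self.model.trait)
        other = np.delete(np.arange(X.shape[1]), j)
        Z = X[:, other]
        Rz = lambda v: v - Z @ np.linalg.lstsq(Z, v, rcond=None)[0]
        y_adj = Rz(self.model.Y[:, voxel])
        x_adj = Rz(X[:, j])
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(x_adj + X[:, j].mean(), y_adj, s=18)
        b = float(x_adj @ y_adj / (x_adj @ x_adj))
        xs = np.linspace(x_adj.min(), x_adj.max(), 10)
        ax.plot(xs + X[:, j].mean(), b * xs, color="C3")
        ax.set_xlabel(f"{self.model.trait} (adjusted)")
        ax.set_ylabel("fALFF (z, adjusted)")
        return ax
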