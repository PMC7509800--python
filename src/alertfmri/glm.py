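"""Voxelwise GLM, percent-signal-change, smoothing, and group maps.

First-level fits are ordinary least squares per in-mask voxel (no
prewhitening; temporal autocorrelation is absorbed by the residual variance
and is a documented limitation).  Because task regressors are scaled to
unit peak, betas are response amplitudes in raw signal units and the PSC
transform is simply ``100 * beta / voxel temporal mean``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as _st

from alertfmri.errors import (
    ConfigurationError,
    DimensionError,
    GeometryError,
    RankDeficientDesignError,
)
from alertfmri.taskdesign import DesignMatrix

__all__ = [
    "ActivationMap",
    "GroupMap",
    "smooth_volume",
    "fit_glm",
    "beta_to_psc",
    "group_map",
    "GROUP_DISPLAY_T",
]

#: |T| display/selection threshold for thresholded group overlays.
GROUP_DISPLAY_T = 4.0


@dataclass
class ActivationMap:
    """First-level results on the session's voxel grid."""

    beta: dict[str, np.ndarray]  # regressor name -> 3D array, signal units
    residual_variance: np.ndarray
    df_resid: int
    mask: np.ndarray
    affine: np.ndarray
    psc: dict[str, np.ndarray] = field(default_factory=dict)  # % of baseline
    excluded_voxels: np.ndarray | None = None  # in-mask voxels with bad baseline

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape


@dataclass
class GroupMap:
    """Voxelwise one-sample statistics of subject PSC maps against zero."""

    mean_psc: np.ndarray
    sem: np.ndarray
    t: np.ndarray
    p: np.ndarray
    n_subjects: int
    mask: np.ndarray
    affine: np.ndarray

    def thresholded(self, t_threshold: float = GROUP_DISPLAY_T) -> np.ndarray:
        """Overlay volume: +1 where T >= thr, -1 where T <= -thr, else 0."""
        out = np.zeros(self.t.shape, dtype=np.int8)
        out[self.t >= t_threshold] = 1
        out[self.t <= -t_threshold] = -1
        return out


def smooth_volume(
    volume: np.ndarray, fwhm_mm: float, voxel_size_mm: float
) -> np.ndarray:
    """Separable spatial Gaussian smoothing of a 3D or 4D volume.

    ``sigma = fwhm / (2 * sqrt(2 * ln 2))`` per axis, in voxel units; the
    time axis (last axis of a 4D array) is untouched.  ``fwhm_mm = 0`` is
    the identity.
    """
    if fwhm_mm < 0:
        raise ConfigurationError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    if voxel_size_mm <= 0:
        raise ConfigurationError("voxel_size_mm must be > 0")
    vol = np.asarray(volume, dtype=float)
    if fwhm_mm == 0:
        return vol.copy()
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    if vol.ndim == 3:
        sigma = (sigma_vox,) * 3
    elif vol.ndim == 4:
        sigma = (sigma_vox, sigma_vox, sigma_vox, 0.0)
    else:
        raise DimensionError(f"expected 3D or 4D volume, got {vol.ndim}D")
    return ndimage.gaussian_filter(vol, sigma=sigma, mode="reflect")


def _collinear_columns(x: np.ndarray, names: tuple[str, ...]) -> list[str]:
    # name columns implicated in the rank deficiency via tiny R diagonal
    r = np.linalg.qr(x, mode="r")
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps if diag.max() > 0 else 0.0
    return [names[i] for i in np.where(diag <= tol)[0]] or list(names)


def fit_glm(session, dm: DesignMatrix) -> ActivationMap:
    """Ordinary least squares per in-mask voxel.

    Betas for every design column are retained (task columns are what the
    caller cares about; high-pass basis and intercept act as nuisance).
    """
    data = session.data
    if dm.n_timepoints != data.shape[-1]:
        raise DimensionError(
            f"design has {dm.n_timepoints} timepoints, session has {data.shape[-1]}"
        )
    x = dm.values
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise RankDeficientDesignError(_collinear_columns(x, dm.names))

    mask = np.asarray(session.brain_mask, dtype=bool)
    y = data[mask].T  # (T, n_voxels)
    pinv = np.linalg.pinv(x)
    beta = pinv @ y
    resid = y - x @ beta
    df = x.shape[0] - rank
    resid_var = (resid**2).sum(axis=0) / df

    betas: dict[str, np.ndarray] = {}
    for i, name in enumerate(dm.names):
        vol = np.zeros(mask.shape)
        vol[mask] = beta[i]
        betas[name] = vol
    rv = np.zeros(mask.shape)
    rv[mask] = resid_var
    return ActivationMap(
        beta=betas,
        residual_variance=rv,
        df_resid=df,
        mask=mask,
        affine=np.asarray(session.affine, dtype=float),
    )


def beta_to_psc(
    amap: ActivationMap, session, regressors: tuple[str, ...] = ("CUE", "CUE_STIM")
) -> ActivationMap:
    """Populate percent-signal-change maps: 100 * beta / voxel temporal mean.

    Valid because task columns are unit peak.  In-mask voxels whose
    temporal mean is not positive are excluded from the PSC maps (set to
    NaN) and reported on ``excluded_voxels``.
    """
    mask = amap.mask
    baseline = session.data.mean(axis=-1)
    bad = mask & ~(baseline > 0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} in-mask voxels have non-positive baseline; "
            "excluded from PSC"
        )
    for name in regressors:
        if name not in amap.beta:
            continue
        psc = np.zeros(mask.shape)
        valid = mask & (baseline > 0)
        psc[valid] = 100.0 * amap.beta[name][valid] / baseline[valid]
        psc[bad] = np.nan
        amap.psc[name] = psc
    amap.excluded_voxels = bad
    return amap


def group_map(maps: list[ActivationMap], regressor: str) -> GroupMap:
    """Voxelwise one-sample t of subject PSC maps against zero.

    Two-sided p at df = n − 1.  Where the across-subject SEM is zero the t
    statistic is reported as a signed infinity sentinel with p = 0 (or t =
    0, p = 1 when the mean is also zero).
    """
    if len(maps) < 2:
        raise ConfigurationError("group map needs at least 2 subjects")
    shape = maps[0].shape
    affine = maps[0].affine
    for m in maps[1:]:
        if m.shape != shape or not np.allclose(m.affine, affine):
            raise GeometryError("activation maps have mismatched geometry")
        if regressor not in m.psc:
            raise ConfigurationError(f"regressor {regressor!r} has no PSC map")
    stack = np.stack([m.psc[regressor] for m in maps])  # (n, x, y, z)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n)

    t = np.zeros(shape)
    p = np.ones(shape)
    ok = sem > 0
    t[ok] = mean[ok] / sem[ok]
    p[ok] = 2.0 * _st.t.sf(np.abs(t[ok]), df=n - 1)
    degenerate = (~ok) & (mean != 0)
    t[degenerate] = np.sign(mean[degenerate]) * np.inf
    p[degenerate] = 0.0
    mask = maps[0].mask
    return GroupMap(
        mean_psc=mean, sem=sem, t=t, p=p, n_subjects=n, mask=mask, affine=affine
    )
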