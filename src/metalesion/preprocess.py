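"""Mask construction, background-signal estimation, smoothing, downsampling
and confound residualization.

The stages mirror a standard coarse-resolution PET preparation: an
optimal-threshold grey-matter mask (the candidate threshold maximizing the
Pearson correlation between the binary inclusion indicator and the cohort
mean image), per-scan background activity sums (global / white-matter /
ventricular), Gaussian smoothing stated as FWHM in mm, block-mean
downsampling to a coarser isotropic grid, and voxel-wise least-squares
removal of confounds (age, handedness, background sums) from the cohort
matrix.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import BackgroundSignals, CohortStack, GreyMatterMask
from .volumes import ImageVolume

__all__ = [
    "optimal_threshold_mask",
    "estimate_background",
    "gaussian_smooth",
    "downsample",
    "build_confound_matrix",
    "residualize",
    "stack_from_volumes",
]

FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))


def optimal_threshold_mask(
    mean_volume: ImageVolume,
    n_candidate_thresholds: int | None = None,
) -> GreyMatterMask:
    """Sweep inclusion thresholds and keep the mask best correlated with the
    mean image.

    Every distinct voxel value of ``mean_volume`` is a candidate threshold
    (optionally subsampled to ``n_candidate_thresholds`` evenly spaced
    quantiles for speed); the mask at threshold ``t`` includes voxels with
    value >= ``t``.  The returned mask maximizes the Pearson correlation
    between the 0/1 inclusion indicator and the mean volume over all voxels;
    ties break toward the higher threshold (smaller mask).
    """
    data = mean_volume.data
    if not np.all(np.isfinite(data)):
        raise ValueError("mean volume contains non-finite voxels")
    flat = data.ravel()
    candidates = np.unique(flat)
    if candidates.size < 2:
        raise ValueError("constant mean volume: no threshold is defined")
    # thresholds above the minimum only (the minimum includes everything,
    # a constant indicator with undefined correlation)
    candidates = candidates[1:]
    if n_candidate_thresholds is not None and candidates.size > n_candidate_thresholds:
        qs = np.linspace(0, 1, int(n_candidate_thresholds))
        candidates = np.unique(np.quantile(candidates, qs))

    n = flat.size
    mean_all = flat.mean()
    centred = flat - mean_all
    ss_tot = float(centred @ centred)
    order = np.argsort(flat, kind="stable")
    sorted_vals = flat[order]
    sorted_cum = np.cumsum(centred[order][::-1])[::-1]  # suffix sums of centred

    best_r, best_t = -np.inf, None
    for t in candidates:
        i = np.searchsorted(sorted_vals, t, side="left")
        k = n - i  # voxels included at this threshold
        if k == 0 or k == n:
            continue
        # corr(indicator, x) = sum_{included} centred / sqrt(k(1-k/n) * ss_tot)
        num = sorted_cum[i]
        r = num / np.sqrt(k * (1.0 - k / n) * ss_tot)
        if r > best_r or (r == best_r and best_t is not None and t > best_t):
            best_r, best_t = r, t
    if best_t is None:
        raise ValueError("no admissible threshold found")
    grid = data >= best_t
    return GreyMatterMask(grid, mean_volume.affine, float(mean_volume.voxel_size_mm[0]))


def estimate_background(
    volume: ImageVolume,
    mask: GreyMatterMask,
    wm_mask: np.ndarray,
    vent_mask: np.ndarray,
) -> BackgroundSignals:
    """Sum raw counts within the analysis mask and the white-matter and
    ventricular compartments."""
    wm_mask = np.asarray(wm_mask, dtype=bool)
    vent_mask = np.asarray(vent_mask, dtype=bool)
    if volume.data.shape != mask.grid.shape:
        raise ValueError("volume grid does not match mask grid")
    if wm_mask.shape != volume.data.shape or vent_mask.shape != volume.data.shape:
        raise ValueError("compartment mask grid mismatch")
    if not wm_mask.any():
        raise ValueError("white-matter compartment is empty")
    if not vent_mask.any():
        raise ValueError("ventricular compartment is empty")
    return BackgroundSignals(
        global_sum=float(volume.data[mask.grid].sum()),
        white_matter_sum=float(volume.data[wm_mask].sum()),
        ventricular_sum=float(volume.data[vent_mask].sum()),
    )


def gaussian_smooth(volume: ImageVolume, fwhm_mm: float) -> ImageVolume:
    """Separable Gaussian smoothing specified as FWHM in mm.

    Per-axis SD in voxels is ``fwhm / (voxel_size * 2*sqrt(2*ln 2))``;
    boundaries use reflect padding, which conserves total intensity for
    interior-supported images.  An FWHM below 0.1 voxel-SD is not
    representable: a warning is issued and the volume returned unchanged.
    """
    fwhm_mm = float(fwhm_mm)
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be > 0")
    sigmas = fwhm_mm / (volume.voxel_size_mm * FWHM_TO_SD)
    if np.all(sigmas < 0.1):
        warnings.warn(
            f"FWHM {fwhm_mm} mm is below 0.1 voxel SD; returning input unchanged",
            stacklevel=2,
        )
        return volume.copy()
    out = ndimage.gaussian_filter(volume.data, sigma=sigmas, mode="reflect")
    return ImageVolume(out, volume.affine.copy(), volume.space)


def downsample(volume: ImageVolume, target_mm: float) -> ImageVolume:
    """Block-mean aggregation to ``target_mm`` isotropic voxels.

    ``target_mm`` must be an integer multiple of each source voxel size;
    trailing voxels that do not fill a complete block are dropped.
    """
    target_mm = float(target_mm)
    sizes = volume.voxel_size_mm
    factors = target_mm / sizes
    if np.any(np.abs(factors - np.round(factors)) > 1e-9) or np.any(factors < 1):
        raise ValueError(
            f"target {target_mm} mm is not an integer multiple of voxel sizes {sizes}"
        )
    f = np.round(factors).astype(int)
    shape = volume.data.shape
    trimmed = volume.data[
        : shape[0] // f[0] * f[0], : shape[1] // f[1] * f[1], : shape[2] // f[2] * f[2]
    ]
    new_shape = (
        trimmed.shape[0] // f[0], f[0],
        trimmed.shape[1] // f[1], f[1],
        trimmed.shape[2] // f[2], f[2],
    )
    out = trimmed.reshape(new_shape).mean(axis=(1, 3, 5))
    affine = volume.affine.copy()
    affine[:3, :3] = affine[:3, :3] @ np.diag(f)
    # shift origin so voxel centres sit at block centres
    affine[:3, 3] += volume.affine[:3, :3] @ ((f - 1) / 2.0)
    return ImageVolume(out, affine, volume.space)


def build_confound_matrix(confounds: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Assemble the standard confound design: intercept, age, handedness
    indicators, and the three background sums.

    Handedness is a categorical column encoded as indicator columns with an
    explicit ``unknown`` level (missing entries are common in clinical
    records); the first observed level is the reference.  Any other columns
    present (``age``, ``global_sum``, ``white_matter_sum``,
    ``ventricular_sum``, or user extras) enter as numeric covariates.
    """
    cols: list[np.ndarray] = [np.ones(len(confounds))]
    names: list[str] = ["intercept"]
    for name in confounds.columns:
        series = confounds[name]
        if name == "handedness" or series.dtype == object:
            levels = sorted(
                {str(v) if pd.notna(v) else "unknown" for v in series}
            )
            filled = series.where(pd.notna(series), "unknown").astype(str)
            for lev in levels[1:]:  # first level is the reference
                cols.append((filled == lev).to_numpy(dtype=float))
                names.append(f"{name}[{lev}]")
        else:
            vals = series.to_numpy(dtype=float)
            if np.isnan(vals).any():
                raise ValueError(f"confound {name!r} has missing numeric entries")
            cols.append(vals)
            names.append(str(name))
    return np.column_stack(cols), names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns not adding rank, for the error message
        collinear = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                collinear.append(names[j])
        raise ValueError(f"confound matrix is rank deficient; collinear columns: {collinear}")


def residualize(stack: CohortStack, confounds: pd.DataFrame) -> CohortStack:
    """Per-voxel least-squares residuals of intensity on the confounds.

    The design always includes an intercept (added by
    :func:`build_confound_matrix`); residual columns are orthogonal to every
    confound column to within 1e-8.  Raises on rank-deficient designs, naming
    the collinear columns.
    """
    if len(confounds) != stack.n_subjects:
        raise ValueError("confound row count does not match stack")
    X, names = build_confound_matrix(confounds)
    _check_full_rank(X, names)
    Q, _ = np.linalg.qr(X)
    resid = stack.data - Q @ (Q.T @ stack.data)
    return CohortStack(
        data=resid,
        subject_ids=list(stack.subject_ids),
        mask=stack.mask,
        smoothed_fwhm_mm=stack.smoothed_fwhm_mm,
        resolution_mm=stack.resolution_mm,
        residualized=True,
        volumes=None,
    )


def stack_from_volumes(
    volumes: list[ImageVolume] | np.ndarray,
    mask: GreyMatterMask,
    subject_ids: list[str] | None = None,
    **flags,
) -> CohortStack:
    """Flatten a list of co-registered volumes onto the mask."""
    if isinstance(volumes, np.ndarray):
        arrs = [volumes[i] for i in range(volumes.shape[0])]
    else:
        arrs = [v.data for v in volumes]
    data = np.stack([mask.flatten(a) for a in arrs]) if arrs else np.empty((0, mask.n_voxels))
    if subject_ids is None:
        subject_ids = [f"sub-{i:03d}" for i in range(len(arrs))]
    return CohortStack(data=data, subject_ids=subject_ids, mask=mask, **flags)
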