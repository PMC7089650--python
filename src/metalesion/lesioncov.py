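"""Spatial covariance diagnostics of binary lesion maps.

Mass-univariate lesion-deficit inference is distorted when the lesions that
drive it are spatially anisotropic (as vascular lesions are, following
arterial territories).  Two complementary diagnostics quantify this:

* **Local dependency** — at each voxel, the conditional probability that each
  of its six face neighbours is co-lesioned is treated as a vector of that
  probability pointing to the neighbour; their mean (the *mean resultant
  length* vector) points towards the direction of greatest local dependence
  and has magnitude in [0, 1].  Isotropic lesions yield small, randomly
  oriented vectors; anisotropic lesions large, systematically directed ones.
  Magnitude distributions of two lesion classes are compared with a
  two-sample Kolmogorov-Smirnov test.

* **Global dependency** — every in-mask voxel pair is binned by its 3D
  displacement and the median pairwise correlation (phi coefficient of the
  binary indicator columns) is reported per bin; elongated isocontours of
  the resulting correlogram reveal long-range anisotropy.  Hemispheres may
  be analysed separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .containers import BinaryLesionStack, CohortStack

__all__ = [
    "DependencyVectorField",
    "DisplacementCorrelogram",
    "binarize_lesion_stack",
    "local_dependency_field",
    "ks_compare_magnitudes",
    "global_correlogram",
    "axis_decay_lengths",
]

# face-neighbour offsets and their unit directions, fixed order
_NEIGHBOUR_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


@dataclass
class DependencyVectorField:
    """Per-voxel local conditional-dependency vectors.

    ``vectors`` is (n_voxels, 3); ``magnitude`` the Euclidean norm (in
    [0, 1]); ``lesion_count`` the number of subjects lesioned at the voxel.
    Voxels never lesioned have no defined conditional probability and are
    flagged in ``defined`` and excluded from summaries.
    """

    vectors: np.ndarray
    magnitude: np.ndarray
    lesion_count: np.ndarray
    defined: np.ndarray
    mask: object  # GreyMatterMask

    def defined_magnitudes(self) -> np.ndarray:
        return self.magnitude[self.defined]

    def to_frame(self) -> pd.DataFrame:
        coords = self.mask.coordinates()
        return pd.DataFrame(
            {
                "i": coords[:, 0],
                "j": coords[:, 1],
                "k": coords[:, 2],
                "vx": self.vectors[:, 0],
                "vy": self.vectors[:, 1],
                "vz": self.vectors[:, 2],
                "magnitude": self.magnitude,
                "lesion_count": self.lesion_count,
                "defined": self.defined,
            }
        )


@dataclass
class DisplacementCorrelogram:
    """Median pairwise phi correlation per canonical displacement bin.

    ``offsets`` is (n_bins, 3) integer displacements under the canonical
    sign convention (first non-zero component positive); bin (0,0,0) is
    excluded by convention.  ``median_rho`` in [-1, 1] where defined (NaN
    otherwise); ``n_pairs`` counts pairs with a defined phi per bin;
    ``n_skipped`` counts pairs skipped because a column was constant.
    """

    offsets: np.ndarray
    median_rho: np.ndarray
    n_pairs: np.ndarray
    hemisphere: str
    n_skipped: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dx": self.offsets[:, 0],
                "dy": self.offsets[:, 1],
                "dz": self.offsets[:, 2],
                "median_rho": self.median_rho,
                "n_pairs": self.n_pairs,
            }
        )

    def total_pairs(self) -> int:
        return int(self.n_pairs.sum())


def binarize_lesion_stack(stack: CohortStack) -> BinaryLesionStack:
    """Dichotomize a residualized metabolic stack into binary lesion maps.

    A subject is lesioned at a voxel when its intensity falls below the
    per-voxel median minus two sample standard deviations (ddof=1, across
    subjects).  Zero-variance voxels are never lesioned.  Requires at least
    three subjects for the SD to be meaningful.
    """
    if stack.n_subjects < 3:
        raise ValueError("binarization requires at least 3 subjects")
    med = np.median(stack.data, axis=0)
    sd = stack.data.std(axis=0, ddof=1)
    thresh = med - 2.0 * sd
    with np.errstate(invalid="ignore"):
        lesioned = (stack.data < thresh) & (sd > 0)
    return BinaryLesionStack(lesioned, stack.mask, source="metabolic-thresholded")


def local_dependency_field(lesions: BinaryLesionStack) -> DependencyVectorField:
    """Mean-resultant-length conditional dependency vector at every voxel.

    For voxel ``v`` with at least one lesioned subject, each face neighbour
    ``u`` contributes ``P(u lesioned | v lesioned)`` times the unit vector
    towards ``u``; the dependency vector is the mean of the six
    contributions (out-of-mask neighbours contribute probability 0 and the
    divisor stays 6, keeping the magnitude within [0, 1]).  Never-lesioned
    voxels are flagged undefined.
    """
    mask = lesions.mask
    shape = mask.grid.shape
    n_sub = lesions.n_subjects
    # scatter lesion indicators onto the full grid for cheap shifting
    full = np.zeros((n_sub,) + shape, dtype=bool)
    flat = full.reshape(n_sub, -1)
    flat[:, mask.indices] = lesions.data
    counts = full.sum(axis=0)  # lesioned subjects per grid voxel

    co_counts = np.zeros((6,) + shape)
    inmask_nb = np.zeros((6,) + shape, dtype=bool)
    for a, off in enumerate(_NEIGHBOUR_OFFSETS):
        shifted = np.zeros_like(full)
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        for ax, o in enumerate(off):
            if o == 1:
                src[ax], dst[ax] = slice(1, None), slice(0, -1)
            elif o == -1:
                src[ax], dst[ax] = slice(0, -1), slice(1, None)
        shifted[(slice(None), *dst)] = full[(slice(None), *src)]
        co_counts[a] = (full & shifted).sum(axis=0)
        nb_grid = np.zeros(shape, dtype=bool)
        nb_grid[tuple(dst)] = mask.grid[tuple(src)]
        inmask_nb[a] = nb_grid

    counts_m = mask.flatten(counts)
    defined = counts_m > 0
    probs = np.zeros((6, mask.n_voxels))
    for a in range(6):
        co = mask.flatten(co_counts[a])
        valid = defined & mask.flatten(inmask_nb[a].astype(float)).astype(bool)
        probs[a, valid] = co[valid] / counts_m[valid]
    vectors = np.tensordot(probs.T, _NEIGHBOUR_OFFSETS.astype(float), axes=(1, 0)) / 6.0
    vectors[~defined] = np.nan
    magnitude = np.linalg.norm(vectors, axis=1)
    return DependencyVectorField(
        vectors=vectors,
        magnitude=magnitude,
        lesion_count=counts_m.astype(int),
        defined=defined,
        mask=mask,
    )


def ks_compare_magnitudes(
    field_a: DependencyVectorField, field_b: DependencyVectorField
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on defined dependency magnitudes.

    Returns ``(D, p)`` with ``D = sup |ECDF_a - ECDF_b|`` and the asymptotic
    Kolmogorov p-value at effective size ``n_a * n_b / (n_a + n_b)``.
    """
    a = np.sort(field_a.defined_magnitudes())
    b = np.sort(field_b.defined_magnitudes())
    if a.size == 0 or b.size == 0:
        raise ValueError("KS comparison requires at least one defined magnitude per field")
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    d = float(np.abs(cdf_a - cdf_b).max())
    en = np.sqrt(a.size * b.size / (a.size + b.size))
    p = float(np.clip(special.kolmogorov(en * d), 0.0, 1.0))
    return d, p


def _canonicalize(offsets: np.ndarray) -> np.ndarray:
    """Flip displacement signs so the first non-zero component is positive."""
    out = offsets.copy()
    nz = out != 0
    first = np.argmax(nz, axis=1)
    sign = np.sign(out[np.arange(len(out)), first])
    sign[~nz.any(axis=1)] = 1
    return out * sign[:, None]


def global_correlogram(
    lesions: BinaryLesionStack,
    hemisphere: str = "both",
    max_offset_voxels: int = 6,
) -> DisplacementCorrelogram:
    """Median phi correlation of lesion indicators per displacement bin.

    For every in-mask voxel pair within ``max_offset_voxels`` along each
    axis (and within the requested hemisphere; the midline is the mask's
    central x-coordinate, midline voxels excluded from hemispheric runs),
    the Pearson correlation of the two binary indicator columns (the phi
    coefficient) is computed across subjects and assigned to the canonical
    displacement bin.  Pairs with a constant column are skipped but counted.
    """
    if hemisphere not in ("left", "right", "both"):
        raise ValueError(f"unknown hemisphere {hemisphere!r}")
    mask = lesions.mask
    coords = mask.coordinates()
    X = lesions.data.astype(np.float64)
    n = lesions.n_subjects

    if hemisphere != "both":
        mid = (mask.grid.shape[0] - 1) / 2.0
        keep = coords[:, 0] < mid if hemisphere == "left" else coords[:, 0] > mid
        coords = coords[keep]
        X = X[:, keep]
    nv = coords.shape[0]
    if nv < 2 or n < 2:
        warnings.warn("no valid voxel pairs in range; empty correlogram", stacklevel=2)
        return DisplacementCorrelogram(
            offsets=np.empty((0, 3), dtype=int),
            median_rho=np.empty(0),
            n_pairs=np.empty(0, dtype=int),
            hemisphere=hemisphere,
        )

    m = X.sum(axis=0)  # lesion counts per column
    var = m * (n - m)  # n^2 * variance * n ... proportional column variance
    cross = X.T @ X  # co-lesion counts, (nv, nv)
    # phi = (n*n11 - m_i*m_j) / sqrt(m_i (n-m_i) m_j (n-m_j))
    ii, jj = np.triu_indices(nv, k=1)
    d = coords[jj] - coords[ii]
    in_range = np.abs(d).max(axis=1) <= max_offset_voxels
    ii, jj, d = ii[in_range], jj[in_range], d[in_range]
    denom = var[ii] * var[jj]
    ok = denom > 0
    n_skipped = int((~ok).sum())
    ii, jj, d = ii[ok], jj[ok], d[ok]
    phi = (n * cross[ii, jj] - m[ii] * m[jj]) / np.sqrt(var[ii] * var[jj])

    d = _canonicalize(d)
    if len(d) == 0:
        warnings.warn("no valid voxel pairs in range; empty correlogram", stacklevel=2)
        return DisplacementCorrelogram(
            offsets=np.empty((0, 3), dtype=int),
            median_rho=np.empty(0),
            n_pairs=np.empty(0, dtype=int),
            hemisphere=hemisphere,
            n_skipped=n_skipped,
        )
    # group by displacement bin
    span = 2 * max_offset_voxels + 1
    keys = (d[:, 0] * span + (d[:, 1] + max_offset_voxels)) * span + (
        d[:, 2] + max_offset_voxels
    )
    order = np.argsort(keys, kind="stable")
    keys_s, phi_s, d_s = keys[order], phi[order], d[order]
    uniq, starts = np.unique(keys_s, return_index=True)
    bounds = np.append(starts, len(keys_s))
    offsets = d_s[starts]
    medians = np.array(
        [np.median(phi_s[bounds[b] : bounds[b + 1]]) for b in range(len(uniq))]
    )
    n_pairs = np.diff(bounds)
    return DisplacementCorrelogram(
        offsets=offsets,
        median_rho=medians,
        n_pairs=n_pairs.astype(int),
        hemisphere=hemisphere,
        n_skipped=n_skipped,
    )


def axis_decay_lengths(
    corr: DisplacementCorrelogram, level: float = 0.5
) -> np.ndarray:
    """Correlation decay length along each coordinate axis.

    For the pure-axis bins (displacement non-zero on one axis only), the
    decay length is the linearly interpolated offset at which the median
    correlation first falls to ``level`` (relative to the lag-1 value
    extrapolated through rho=1 at lag 0).  Used to compare correlogram
    isocontour extents between axes: elongation ratio = length on the
    favoured axis over the orthogonal ones.
    """
    lengths = np.full(3, np.nan)
    for ax in range(3):
        others = [a for a in range(3) if a != ax]
        sel = (
            (corr.offsets[:, others[0]] == 0)
            & (corr.offsets[:, others[1]] == 0)
            & (corr.offsets[:, ax] > 0)
        )
        if not sel.any():
            continue
        lags = corr.offsets[sel, ax].astype(float)
        rhos = corr.median_rho[sel]
        order = np.argsort(lags)
        lags, rhos = lags[order], rhos[order]
        lags = np.concatenate([[0.0], lags])
        rhos = np.concatenate([[1.0], rhos])
        below = np.flatnonzero(rhos <= level)
        if below.size == 0:
            lengths[ax] = lags[-1]  # never decays within range
            continue
        b = below[0]
        if b == 0:
            lengths[ax] = 0.0
            continue
        # linear interpolation between the bracketing lags
        l0, l1 = lags[b - 1], lags[b]
        r0, r1 = rhos[b - 1], rhos[b]
        lengths[ax] = l0 + (r0 - level) / (r0 - r1) * (l1 - l0) if r0 != r1 else l1
    return lengths
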