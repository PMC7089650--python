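"""In-memory containers shared across the pipeline stages.

The working representation of a cohort is a subjects x in-mask-voxels matrix
(:class:`CohortStack`) tied to a :class:`GreyMatterMask` that remembers how the
flat voxel axis maps back onto the 3D grid.  Behavioural data travel as a
:class:`ScoreTable` (a pandas DataFrame plus per-instrument direction flags);
binary lesion maps as a :class:`BinaryLesionStack`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GreyMatterMask",
    "BackgroundSignals",
    "CohortStack",
    "BinaryLesionStack",
    "ScoreTable",
]


@dataclass
class GreyMatterMask:
    """Binary analysis mask on the common grid.

    ``indices`` is the sorted flat (C-order) index list of in-mask voxels;
    flatten/unflatten round-trip exactly by construction.
    """

    grid: np.ndarray  # bool, 3D
    affine: np.ndarray
    voxel_size_mm: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3:
            raise ValueError("mask grid must be 3D")
        if not self.grid.any():
            raise ValueError("mask is empty")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def indices(self) -> np.ndarray:
        """Sorted, duplicate-free flat indices of in-mask voxels."""
        return np.flatnonzero(self.grid.ravel())

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def coordinates(self) -> np.ndarray:
        """(n_voxels, 3) integer grid coordinates of in-mask voxels."""
        return np.column_stack(np.unravel_index(self.indices, self.grid.shape))

    def world_coordinates(self) -> np.ndarray:
        """(n_voxels, 3) voxel-centre coordinates in mm (mask affine frame)."""
        ijk = self.coordinates()
        hom = np.column_stack([ijk, np.ones(len(ijk))])
        return (hom @ self.affine.T)[:, :3]

    def flatten(self, volume_data: np.ndarray) -> np.ndarray:
        """Extract the in-mask voxels of a 3D grid as a flat vector."""
        volume_data = np.asarray(volume_data)
        if volume_data.shape != self.grid.shape:
            raise ValueError(
                f"grid mismatch: volume {volume_data.shape} vs mask {self.grid.shape}"
            )
        return volume_data.ravel()[self.indices]

    def unflatten(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter a flat in-mask vector back onto the 3D grid."""
        values = np.asarray(values)
        if values.shape[-1] != self.n_voxels:
            raise ValueError("value count does not match mask size")
        out = np.full(self.grid.size, fill, dtype=float)
        out[self.indices] = values
        return out.reshape(self.grid.shape)


@dataclass
class BackgroundSignals:
    """Per-scan background activity estimates (arbitrary intensity units)."""

    global_sum: float
    white_matter_sum: float
    ventricular_sum: float

    def __post_init__(self) -> None:
        for name in ("global_sum", "white_matter_sum", "ventricular_sum"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
            setattr(self, name, v)


@dataclass
class CohortStack:
    """Subjects x in-mask-voxels intensity matrix with provenance flags."""

    data: np.ndarray  # (n_subjects, n_voxels) float
    subject_ids: list[str]
    mask: GreyMatterMask
    smoothed_fwhm_mm: float | None = None
    resolution_mm: float | None = None
    residualized: bool = False
    volumes: np.ndarray | None = field(default=None, repr=False)  # optional (n, nx, ny, nz)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[1] != self.mask.n_voxels:
            raise ValueError(
                f"stack has {self.data.shape[1]} columns but mask has "
                f"{self.mask.n_voxels} voxels"
            )
        if len(self.subject_ids) != self.data.shape[0]:
            raise ValueError("subject id count does not match row count")
        if self.residualized and not np.all(np.isfinite(self.data)):
            raise ValueError("residualized stack contains non-finite entries")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


@dataclass
class BinaryLesionStack:
    """Subjects x voxels boolean lesion indicators tied to a mask."""

    data: np.ndarray  # (n_subjects, n_voxels) bool
    mask: GreyMatterMask
    source: str = "synthetic"  # metabolic-thresholded | ischaemic | synthetic

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.dtype != bool:
            if not np.isin(arr, (0, 1)).all():
                raise ValueError("lesion stack must be boolean")
            arr = arr.astype(bool)
        self.data = np.atleast_2d(arr)
        if self.data.shape[1] != self.mask.n_voxels:
            raise ValueError("lesion stack column count != mask size")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    def lesion_counts(self) -> np.ndarray:
        """Number of subjects lesioned at each voxel."""
        return self.data.sum(axis=0)


class ScoreTable:
    """A subjects x instruments score battery with missing entries.

    Wraps a pandas DataFrame (NaN = missing) plus a ``higher_is_worse``
    flag per instrument (e.g. HADS anxiety/depression, where larger scores
    mean worse affect and are sign-flipped before deficit mapping).
    """

    def __init__(
        self,
        values: pd.DataFrame,
        higher_is_worse: dict[str, bool] | None = None,
    ) -> None:
        if not isinstance(values, pd.DataFrame):
            values = pd.DataFrame(values)
        self.values = values.astype(float)
        flags = dict.fromkeys(values.columns, False)
        if higher_is_worse:
            unknown = set(higher_is_worse) - set(values.columns)
            if unknown:
                raise ValueError(f"direction flags for unknown instruments: {unknown}")
            flags.update(higher_is_worse)
        self.higher_is_worse = flags

    @property
    def instruments(self) -> list[str]:
        return list(self.values.columns)

    @property
    def subjects(self) -> list[str]:
        return [str(s) for s in self.values.index]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_instruments(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.values.isna().to_numpy()

    def missing_fraction(self) -> float:
        return float(self.missing_mask.mean())

    def unusable(self) -> dict[str, list[str]]:
        """Subjects/instruments with no observed entry at all."""
        obs = ~self.values.isna()
        return {
            "subjects": [str(s) for s in self.values.index[~obs.any(axis=1)]],
            "instruments": [str(c) for c in self.values.columns[~obs.any(axis=0)]],
        }

    def oriented(self, instrument: str) -> np.ndarray:
        """Scores with higher-is-worse instruments sign-flipped, so that a
        larger value always means better function."""
        col = self.values[instrument].to_numpy(dtype=float)
        return -col if self.higher_is_worse[instrument] else col

    def copy(self) -> "ScoreTable":
        return ScoreTable(self.values.copy(), dict(self.higher_is_worse))

    def to_csv(self, path: str | Path) -> Path:
        """Write as UTF-8 CSV, empty cell = missing."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.values.to_csv(path, index_label="subject_id", na_rep="")
        return path

    @classmethod
    def from_csv(
        cls, path: str | Path, higher_is_worse: dict[str, bool] | None = None
    ) -> "ScoreTable":
        df = pd.read_csv(path, index_col="subject_id")
        return cls(df, higher_is_worse)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ScoreTable({self.n_subjects} subjects x {self.n_instruments} "
            f"instruments, {100 * self.missing_fraction():.1f}% missing)"
        )
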