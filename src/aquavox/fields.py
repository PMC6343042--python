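"""Voxel lattice specification and the scalar fields defined on it.

A :class:`GridSpec` is an axis-aligned cubic lattice: ``origin`` is the
*center* of voxel (0, 0, 0) and voxel (i, j, k) has center
``origin + spacing * (i, j, k)``.  All lengths are in Ångström.

Three field types share the lattice:

``OccupancyField``
    per-voxel fraction of snapshots in which the voxel center lay within
    the probe radius of a water oxygen (values in [0, 1]);
``DifferenceField``
    voxelwise mutant-minus-wild-type occupancy (values in [-1, 1]);
``CountField``
    integer docking-pose occupancy counts, at most one per
    (snapshot, run) pose per voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NumericError, ValidationError

__all__ = [
    "GridSpec",
    "OccupancyField",
    "DifferenceField",
    "CountField",
    "voxel_centers",
]


@dataclass(frozen=True)
class GridSpec:
    """Cubic voxel lattice: ``center(i,j,k) = origin + spacing*(i,j,k)``."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValidationError(f"grid spacing must be > 0, got {self.spacing}")
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise ValidationError(f"grid dims must be three integers >= 1, got {self.dims}")
        object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        if not np.all(np.isfinite(self.origin)):
            raise ValidationError("grid origin must be finite")

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in Å³."""
        return float(self.spacing) ** 3

    def centers(self) -> np.ndarray:
        """All voxel centers as an (n_voxels, 3) array, C-ordered to match
        ``values.reshape(-1)`` of a dims-shaped field."""
        return voxel_centers(self)

    def index_to_center(self, ijk: np.ndarray) -> np.ndarray:
        return np.asarray(self.origin) + self.spacing * np.asarray(ijk, dtype=float)

    def compatible_with(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.dims == other.dims
            and abs(self.spacing - other.spacing) <= tol
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )


def voxel_centers(spec: GridSpec) -> np.ndarray:
    nx, ny, nz = spec.dims
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    ijk = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    return np.asarray(spec.origin) + spec.spacing * ijk.astype(float)


def _require_spec_match(a: GridSpec, b: GridSpec, what: str) -> None:
    if not a.compatible_with(b):
        raise ValidationError(
            f"{what}: grid specs differ (dims {a.dims} vs {b.dims}, "
            f"spacing {a.spacing} vs {b.spacing}, origin {a.origin} vs {b.origin}); "
            "no resampling is performed"
        )


@dataclass
class OccupancyField:
    """Mean of per-snapshot 0/1 voxel indicators over ``n_snapshots`` frames.

    ``n_snapshots`` may be None for fields re-read from disk, where the
    frame count is no longer known.
    """

    spec: GridSpec
    values: np.ndarray
    n_snapshots: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.dims:
            raise ValidationError(
                f"field shape {self.values.shape} does not match grid dims {self.spec.dims}"
            )
        if not np.all(np.isfinite(self.values)):
            raise NumericError("occupancy field contains non-finite values")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValidationError("occupancy values must lie in [0, 1]")


@dataclass
class DifferenceField:
    """Signed voxelwise difference of two occupancy fields on one lattice."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.dims:
            raise ValidationError(
                f"field shape {self.values.shape} does not match grid dims {self.spec.dims}"
            )
        if not np.all(np.isfinite(self.values)):
            raise NumericError("difference field contains non-finite values")
        if np.abs(self.values).max() > 1 + 1e-12:
            raise ValidationError("difference values must lie in [-1, 1]")


@dataclass
class CountField:
    """Integer pose-occupancy counts; each (snapshot, run) pose contributes
    at most 1 per voxel, so counts are bounded by ``max_possible``."""

    spec: GridSpec
    counts: np.ndarray
    max_possible: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValidationError("counts must be integers")
            self.counts = rounded.astype(np.int64)
        if self.counts.shape != self.spec.dims:
            raise ValidationError(
                f"count shape {self.counts.shape} does not match grid dims {self.spec.dims}"
            )
        if self.counts.min() < 0 or (self.max_possible >= 0 and self.counts.max() > self.max_possible):
            raise ValidationError(
                f"counts must lie in [0, max_possible={self.max_possible}]"
            )
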