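"""Docking-pose voxel density and high-density substrate binding regions.

Each docking pose — one ligand placement per (snapshot, run) key — marks a
voxel when the voxel center lies within the probe radius of any ligand heavy
atom, contributing at most 1 per voxel regardless of how many atoms fall
nearby.  Summing over all keys gives an integer count field whose ceiling is
the number of keys (1,000 for the canonical 10 docking runs × 100 snapshots).
Voxels with counts strictly above the threshold (default 750) form the
high-density region (HDR); its volume, count × spacing³, proxies the size of
the substrate binding chamber.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .fields import CountField, GridSpec, voxel_centers
from .hydration_grid import DEFAULT_PROBE_RADIUS, mark_voxels

__all__ = [
    "PoseEnsemble",
    "CountField",
    "HDRResult",
    "HDROverlap",
    "DEFAULT_HDR_THRESHOLD",
    "pose_count_field",
    "extract_hdr",
    "compare_hdr",
    "count_histogram",
]

DEFAULT_HDR_THRESHOLD = 750


@dataclass
class PoseEnsemble:
    """Ligand heavy-atom coordinates indexed by (snapshot, run)."""

    poses: dict[tuple[int, int], np.ndarray]
    ligand_label: str = "ligand"

    def __post_init__(self) -> None:
        clean: dict[tuple[int, int], np.ndarray] = {}
        for key, coords in self.poses.items():
            coords = np.asarray(coords, dtype=float).reshape(-1, 3)
            if len(coords) == 0:
                raise ValidationError(f"pose {key} has no atoms")
            if not np.all(np.isfinite(coords)):
                raise ValidationError(f"pose {key} has non-finite coordinates")
            clean[(int(key[0]), int(key[1]))] = coords
        self.poses = clean

    def __len__(self) -> int:
        return len(self.poses)

    @property
    def n_snapshots(self) -> int:
        return len({k[0] for k in self.poses})

    @property
    def n_runs(self) -> int:
        return len({k[1] for k in self.poses})

    def add_pose(self, snapshot: int, run: int, coords: np.ndarray) -> None:
        key = (int(snapshot), int(run))
        if key in self.poses:
            raise ValidationError(f"duplicate pose key (snapshot={key[0]}, run={key[1]})")
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        if len(coords) == 0:
            raise ValidationError(f"pose {key} has no atoms")
        self.poses[key] = coords

    def all_coords(self) -> np.ndarray:
        if not self.poses:
            return np.zeros((0, 3))
        return np.concatenate(list(self.poses.values()), axis=0)


def pose_count_field(ensemble: PoseEnsemble, spec: GridSpec,
                     probe_radius: float = DEFAULT_PROBE_RADIUS) -> CountField:
    """Integer voxel counts: per pose, a voxel scores at most 1 when its
    center lies within ``probe_radius`` (closed ball) of any ligand heavy
    atom; counts are summed over all (snapshot, run) keys.

    An empty ensemble is legal and yields all-zero counts with
    ``max_possible = 0``.
    """
    if probe_radius <= 0:
        raise ValidationError(f"probe_radius must be > 0, got {probe_radius}")
    centers = voxel_centers(spec)
    tree = cKDTree(centers)
    counts = np.zeros(spec.n_voxels, dtype=np.int64)
    for coords in ensemble.poses.values():
        counts += mark_voxels(tree, coords, probe_radius, spec.n_voxels)
    return CountField(spec=spec, counts=counts.reshape(spec.dims),
                      max_possible=len(ensemble))


@dataclass
class HDRResult:
    """High-density region: voxels whose count strictly exceeds ``threshold``."""

    spec: GridSpec
    voxel_indices: frozenset[tuple[int, int, int]]
    threshold: int
    max_possible: int

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_indices)

    @property
    def volume(self) -> float:
        """HDR volume in Å³ (voxel count × spacing³)."""
        return self.n_voxels * self.spec.voxel_volume

    def centers(self) -> np.ndarray:
        if not self.voxel_indices:
            return np.zeros((0, 3))
        ijk = np.array(sorted(self.voxel_indices), dtype=float)
        return np.asarray(self.spec.origin) + self.spec.spacing * ijk

    def to_dict(self) -> dict:
        return {
            "threshold": int(self.threshold),
            "max_possible": int(self.max_possible),
            "n_voxels": self.n_voxels,
            "volume_A3": self.volume,
            "voxel_indices": sorted(list(map(list, self.voxel_indices))),
        }


def extract_hdr(counts: CountField, threshold: int = DEFAULT_HDR_THRESHOLD) -> HDRResult:
    """Voxels with count *strictly above* the threshold (a count equal to the
    threshold is excluded).  An empty result (volume 0) is valid."""
    if threshold < 0:
        raise ValidationError(f"threshold must be >= 0, got {threshold}")
    idx = np.argwhere(counts.counts > threshold)
    voxels = frozenset(tuple(int(x) for x in row) for row in idx)
    return HDRResult(spec=counts.spec, voxel_indices=voxels, threshold=int(threshold),
                     max_possible=int(counts.max_possible))


@dataclass(frozen=True)
class HDROverlap:
    """Set overlap of two HDRs on one lattice."""

    n_shared: int
    jaccard: float
    volume_a: float
    volume_b: float
    shared_volume: float

    def to_dict(self) -> dict:
        return {
            "n_shared": self.n_shared,
            "jaccard": self.jaccard,
            "volume_a_A3": self.volume_a,
            "volume_b_A3": self.volume_b,
            "shared_volume_A3": self.shared_volume,
        }


def compare_hdr(a: HDRResult, b: HDRResult) -> HDROverlap:
    """Shared voxels, Jaccard index and volumes of two HDRs.

    Two empty HDRs have Jaccard 1.0 by the identical-empty-set convention.
    """
    if not a.spec.compatible_with(b.spec):
        raise ValidationError("compare_hdr: HDRs are on different grids")
    shared = a.voxel_indices & b.voxel_indices
    union = a.voxel_indices | b.voxel_indices
    jaccard = 1.0 if not union else len(shared) / len(union)
    return HDROverlap(
        n_shared=len(shared),
        jaccard=float(jaccard),
        volume_a=a.volume,
        volume_b=b.volume,
        shared_volume=len(shared) * a.spec.voxel_volume,
    )


def count_histogram(counts: CountField, bins: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of voxel occupancy counts (sums to the total voxel count)."""
    hist, edges = np.histogram(counts.counts.reshape(-1),
                               bins=bins, range=(0, max(counts.max_possible, 1)))
    return hist, edges
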