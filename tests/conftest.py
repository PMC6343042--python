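"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's spatial-index code path: voxel
marking is re-derived from the all-pairs Euclidean rule with plain numpy so
the accelerated implementations can be checked for bit-identical output.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from aquavox.fields import GridSpec, voxel_centers
from aquavox.structure_io import AtomRecord, Snapshot, Trajectory


def make_atoms(coords) -> list[AtomRecord]:
    return [
        AtomRecord(atom_name="CA", residue_name="ALA", residue_id=i + 1, chain_id="A",
                   element="C", position=tuple(float(c) for c in xyz))
        for i, xyz in enumerate(np.asarray(coords, dtype=float))
    ]


def make_snapshot(coords, waters=None, frame_index=0) -> Snapshot:
    waters = np.zeros((0, 3)) if waters is None else np.asarray(waters, dtype=float)
    return Snapshot(make_atoms(coords), waters, frame_index=frame_index)


def make_trajectory(frames, label="WT", replicate=0) -> Trajectory:
    """frames: list of (protein_coords, water_coords) pairs."""
    snaps = [make_snapshot(c, w, i) for i, (c, w) in enumerate(frames)]
    return Trajectory(snaps, variant_label=label, replicate_id=replicate)


def brute_force_indicator(spec: GridSpec, points: np.ndarray, radius: float) -> np.ndarray:
    """All-pairs closed-ball voxel indicator (flat, C-ordered)."""
    centers = voxel_centers(spec)
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) == 0:
        return np.zeros(spec.n_voxels, dtype=bool)
    d2 = cdist(centers, points, metric="sqeuclidean")
    return (d2 <= radius * radius).any(axis=1)


def brute_force_occupancy(traj: Trajectory, spec: GridSpec, radius: float) -> np.ndarray:
    acc = np.zeros(spec.n_voxels, dtype=np.int64)
    for snap in traj:
        acc += brute_force_indicator(spec, snap.water_oxygens, radius)
    return (acc / len(traj)).reshape(spec.dims)


def brute_force_pose_counts(poses: dict, spec: GridSpec, radius: float) -> np.ndarray:
    acc = np.zeros(spec.n_voxels, dtype=np.int64)
    for coords in poses.values():
        acc += brute_force_indicator(spec, coords, radius)
    return acc.reshape(spec.dims)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
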