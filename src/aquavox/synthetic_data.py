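"""Seeded generators for synthetic trajectories and docking-pose ensembles.

The generators exist so every analysis stage can be validated against known
ground truth without running molecular dynamics or docking:

* a toy protein (helix-like curve or random cloud) is moved by a small
  random rigid motion each frame, with optional Gaussian jitter, so the
  superposition stage is genuinely exercised;
* waters are resampled independently every frame — Poisson-distributed
  counts placed uniformly inside spheres — so each voxel's occupancy has an
  exact closed-form expectation (:func:`analytic_hit_probability`) and
  recovery tests can use exact binomial intervals instead of MD folklore;
* pose ensembles place a chosen fraction of poses inside a hotspot ball and
  the rest in a larger envelope, reproducing the high-density-region
  structure that the pose-count analysis is meant to find.

Waters and jitter are defined in the protein's own (base) frame and then
carried into the lab frame by the same per-frame rigid motion as the
protein, so occupancy analysis is only meaningful after superposition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ValidationError
from .pose_density import PoseEnsemble
from .structure_io import AtomRecord, Snapshot, Trajectory

__all__ = [
    "ToyProteinSpec",
    "WaterRegion",
    "WaterDensitySpec",
    "PoseConcentrationSpec",
    "gen_trajectory",
    "gen_pose_ensemble",
    "base_coordinates",
    "analytic_hit_probability",
    "sphere_overlap_volume",
]


@dataclass(frozen=True)
class ToyProteinSpec:
    """Rigid toy protein: ``helix`` (CA-trace-like curve, 2.3 Å radius,
    1.5 Å rise, 100°/residue) or ``cloud`` (uniform in a 20 Å box).

    ``max_rotation_deg``/``max_translation`` bound the per-frame rigid
    motion; ``jitter_sd`` is per-atom isotropic Gaussian noise in Å applied
    before the rigid motion.  Rotations are kept small by default so fits
    never approach degeneracy.
    """

    n_atoms: int = 30
    shape: str = "helix"
    jitter_sd: float = 0.0
    max_rotation_deg: float = 8.0
    max_translation: float = 2.0

    def __post_init__(self) -> None:
        if self.n_atoms < 3:
            raise ValidationError(f"toy protein needs >= 3 atoms, got {self.n_atoms}")
        if self.shape not in ("helix", "cloud"):
            raise ValidationError(f"unknown protein shape {self.shape!r}")
        if self.jitter_sd < 0 or self.max_rotation_deg < 0 or self.max_translation < 0:
            raise ValidationError("jitter_sd / motion magnitudes must be >= 0")


@dataclass(frozen=True)
class WaterRegion:
    """Uniform-in-ball water density: Poisson(``lam``) waters per frame,
    placed uniformly inside the ball of radius ``rho`` around ``center``."""

    center: tuple[float, float, float]
    rho: float
    lam: float

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValidationError(f"water region radius must be > 0, got {self.rho}")
        if self.lam < 0:
            raise ValidationError(f"expected water count must be >= 0, got {self.lam}")


@dataclass(frozen=True)
class WaterDensitySpec:
    """Collection of independent uniform-ball water regions."""

    regions: tuple[WaterRegion, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))


@dataclass(frozen=True)
class PoseConcentrationSpec:
    """Pose ensemble with a known concentration hotspot.

    A fraction ``f`` of the ``n_runs × n_snapshots`` poses is placed
    uniformly inside the hotspot ball, the remainder uniformly in the larger
    envelope ball (same center).  Multi-atom ligands scatter the extra atoms
    within ``ligand_spread`` Å of the placed point.
    """

    hotspot_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    hotspot_radius: float = 1.0
    fraction: float = 1.0
    n_runs: int = 10
    n_snapshots: int = 100
    n_atoms: int = 1
    envelope_radius: float = 10.0
    ligand_spread: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ValidationError(f"fraction must be in [0, 1], got {self.fraction}")
        if self.hotspot_radius < 0 or self.envelope_radius <= 0:
            raise ValidationError("hotspot_radius must be >= 0 and envelope_radius > 0")
        if self.n_runs < 1 or self.n_snapshots < 1 or self.n_atoms < 1:
            raise ValidationError("n_runs, n_snapshots and n_atoms must be >= 1")
        if self.ligand_spread < 0:
            raise ValidationError("ligand_spread must be >= 0")


def _uniform_in_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """n points uniform in the ball of given radius around the origin."""
    if radius == 0.0:
        return np.zeros((n, 3))
    direction = rng.normal(size=(n, 3))
    norms = np.linalg.norm(direction, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return direction / norms * r[:, None]


def base_coordinates(protein: ToyProteinSpec, seed: int) -> np.ndarray:
    """Deterministic base (reference-frame) coordinates of the toy protein."""
    if protein.shape == "helix":
        i = np.arange(protein.n_atoms)
        theta = np.deg2rad(100.0) * i
        return np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])
    rng = np.random.default_rng(seed)
    return rng.uniform(-10.0, 10.0, size=(protein.n_atoms, 3))


def _toy_atoms(coords: np.ndarray) -> list[AtomRecord]:
    return [
        AtomRecord(atom_name="CA", residue_name="ALA", residue_id=i + 1, chain_id="A",
                   element="C", position=(float(x), float(y), float(z)))
        for i, (x, y, z) in enumerate(coords)
    ]


def gen_trajectory(protein: ToyProteinSpec, water: WaterDensitySpec, n_snapshots: int,
                   seed: int, variant_label: str = "SYN", replicate_id: int = 0) -> Trajectory:
    """Generate a seeded synthetic trajectory.

    Per frame, waters are drawn afresh from the density spec in the protein
    base frame, the protein gets Gaussian jitter, and one random rigid
    motion then moves protein *and* waters into the lab frame.  Ground truth
    (specs, seed, the un-moved reference snapshot) is stored in
    ``metadata`` so recovery tests can compute expectations analytically.
    """
    if n_snapshots < 1:
        raise ValidationError(f"n_snapshots must be >= 1, got {n_snapshots}")
    rng = np.random.default_rng(seed)
    base = base_coordinates(protein, seed)
    reference = Snapshot(_toy_atoms(base), np.zeros((0, 3)), frame_index=-1)

    snapshots: list[Snapshot] = []
    for frame in range(n_snapshots):
        waters = []
        for region in water.regions:
            n_w = rng.poisson(region.lam)
            waters.append(np.asarray(region.center) + _uniform_in_ball(rng, n_w, region.rho))
        water_coords = (np.concatenate(waters, axis=0) if waters else np.zeros((0, 3)))

        coords = base.copy()
        if protein.jitter_sd > 0:
            coords = coords + rng.normal(scale=protein.jitter_sd, size=coords.shape)

        if protein.max_rotation_deg > 0:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = np.deg2rad(rng.uniform(0.0, protein.max_rotation_deg))
            R = Rotation.from_rotvec(angle * axis).as_matrix()
        else:
            R = np.eye(3)
        t = _uniform_in_ball(rng, 1, protein.max_translation)[0]

        coords = coords @ R.T + t
        if len(water_coords):
            water_coords = water_coords @ R.T + t
        snapshots.append(Snapshot(_toy_atoms(coords), water_coords, frame_index=frame))

    return Trajectory(
        snapshots,
        variant_label=variant_label,
        replicate_id=replicate_id,
        metadata={
            "generator": "synthetic",
            "seed": int(seed),
            "protein_spec": protein,
            "water_spec": water,
            "reference_snapshot": reference,
        },
    )


def gen_pose_ensemble(spec: PoseConcentrationSpec, seed: int,
                      ligand_label: str = "ligand") -> PoseEnsemble:
    """Generate a seeded pose ensemble with the spec's hotspot concentration.

    Yields exactly ``n_runs × n_snapshots`` poses keyed by (snapshot, run).
    """
    rng = np.random.default_rng(seed)
    center = np.asarray(spec.hotspot_center, dtype=float)
    poses: dict[tuple[int, int], np.ndarray] = {}
    for snap in range(spec.n_snapshots):
        for run in range(spec.n_runs):
            in_hotspot = rng.random() < spec.fraction
            radius = spec.hotspot_radius if in_hotspot else spec.envelope_radius
            point = center + _uniform_in_ball(rng, 1, radius)[0]
            if spec.n_atoms == 1:
                coords = point[None, :]
            else:
                extra = point + _uniform_in_ball(rng, spec.n_atoms - 1, spec.ligand_spread)
                coords = np.vstack([point[None, :], extra])
            poses[(snap, run)] = coords
    return PoseEnsemble(poses=poses, ligand_label=ligand_label)


# ---------------------------------------------------------------------------
# closed-form expectations


def sphere_overlap_volume(r1: float, r2: float, d: float) -> float:
    """Volume of the intersection of two spheres with radii ``r1``, ``r2``
    and center distance ``d`` (standard spherical-lens formula)."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return 4.0 / 3.0 * math.pi * r**3
    return (
        math.pi
        * (r1 + r2 - d) ** 2
        * (d**2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
        / (12.0 * d)
    )


def analytic_hit_probability(voxel_center: np.ndarray, water: WaterDensitySpec,
                             probe_radius: float) -> float:
    """Exact per-frame probability that a voxel is marked occupied.

    One water uniform in a region's ball hits the voxel with probability
    p = overlap(ball(center, probe), region ball) / region volume; with a
    Poisson(λ) count per region and independent regions, the thinned hit
    process is Poisson with rate Σ λᵢ pᵢ, so
    P(occupied) = 1 − exp(−Σ λᵢ pᵢ).
    """
    c = np.asarray(voxel_center, dtype=float)
    rate = 0.0
    for region in water.regions:
        d = float(np.linalg.norm(c - np.asarray(region.center)))
        overlap = sphere_overlap_volume(probe_radius, region.rho, d)
        p = overlap / (4.0 / 3.0 * math.pi * region.rho**3)
        rate += region.lam * p
    return 1.0 - math.exp(-rate)
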