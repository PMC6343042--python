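"""Least-squares rigid-body superposition of snapshots onto a reference.

Every snapshot's protein part is fitted onto a common reference structure
with the Kabsch algorithm (SVD of the weighted cross-covariance, reflection
branch corrected) and the resulting proper rotation + translation is applied
to the protein *and* water coordinates of that snapshot.  Using one shared
reference across variants is what makes occupancy grids comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import NumericError, ValidationError
from .structure_io import AtomRecord, Snapshot, Trajectory

__all__ = [
    "RigidTransform",
    "AtomSelection",
    "kabsch_fit",
    "superpose_trajectory",
]

_DEGENERACY_RATIO = 1e-10


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R @ x + t`` (rotation orthonormal, det +1)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3):
            raise ValidationError(f"rotation must be 3x3, got {R.shape}")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValidationError("rotation matrix is not orthonormal (RᵀR != I)")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValidationError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        if coords.size == 0:
            return coords.reshape(-1, 3)
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass(frozen=True)
class AtomSelection:
    """Declarative atom filter used to pick the fitting subset.

    All given criteria must hold (conjunction).  ``exclude_residue_ids``
    removes residues after the positive criteria — the knob used to drop a
    mutated residue whose atoms differ between variant rosters.  ``heavy``
    keeps non-hydrogen atoms; ``name`` restricts to specific atom names
    (e.g. ``{"CA"}`` for a backbone-trace fit).
    """

    atom_names: frozenset[str] | None = None
    residue_names: frozenset[str] | None = None
    residue_ids: frozenset[int] | None = None
    chain_ids: frozenset[str] | None = None
    exclude_residue_ids: frozenset[int] = frozenset()
    heavy_only: bool = True

    @classmethod
    def protein_heavy(cls, exclude_residue_ids: Iterable[int] = ()) -> "AtomSelection":
        return cls(exclude_residue_ids=frozenset(int(i) for i in exclude_residue_ids))

    @classmethod
    def calpha(cls, exclude_residue_ids: Iterable[int] = ()) -> "AtomSelection":
        return cls(atom_names=frozenset({"CA"}),
                   exclude_residue_ids=frozenset(int(i) for i in exclude_residue_ids))

    @classmethod
    def single_atom(cls, residue_id: int | None = None, atom_name: str | None = None,
                    residue_name: str | None = None) -> "AtomSelection":
        return cls(
            atom_names=frozenset({atom_name}) if atom_name else None,
            residue_ids=frozenset({int(residue_id)}) if residue_id is not None else None,
            residue_names=frozenset({residue_name}) if residue_name else None,
            heavy_only=False,
        )

    def matches(self, atom: AtomRecord) -> bool:
        if self.heavy_only and atom.element == "H":
            return False
        if self.atom_names is not None and atom.atom_name not in self.atom_names:
            return False
        if self.residue_names is not None and atom.residue_name not in self.residue_names:
            return False
        if self.residue_ids is not None and atom.residue_id not in self.residue_ids:
            return False
        if self.chain_ids is not None and atom.chain_id not in self.chain_ids:
            return False
        if atom.residue_id in self.exclude_residue_ids:
            return False
        return True

    def indices(self, snapshot: Snapshot) -> np.ndarray:
        idx = np.array(
            [i for i, a in enumerate(snapshot.protein_atoms) if self.matches(a)],
            dtype=int,
        )
        return idx

    def resolve_one(self, snapshot: Snapshot) -> AtomRecord:
        idx = self.indices(snapshot)
        if len(idx) != 1:
            raise ValidationError(
                f"selection must resolve to exactly one atom, matched {len(idx)}"
            )
        return snapshot.protein_atoms[int(idx[0])]


def _check_degenerate(centered: np.ndarray, label: str) -> None:
    s = np.linalg.svd(centered, compute_uv=False)
    if s[0] == 0.0 or s[1] / s[0] < _DEGENERACY_RATIO:
        raise NumericError(
            f"{label} point set is collinear or degenerate; rotation is underdetermined"
        )


def kabsch_fit(
    reference_coords: np.ndarray,
    mobile_coords: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Optimal proper rigid motion mapping ``mobile`` onto ``reference``.

    Returns the transform minimising the (weighted) RMSD together with the
    post-fit RMSD in Å.  The reflection branch of the SVD solution is
    corrected by flipping the sign attached to the smallest singular value,
    so the rotation always has determinant +1.
    """
    ref = np.asarray(reference_coords, dtype=float)
    mob = np.asarray(mobile_coords, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValidationError(
            f"coordinate sets must both be (N, 3), got {ref.shape} and {mob.shape}"
        )
    n = ref.shape[0]
    if n < 3:
        raise NumericError(f"superposition needs at least 3 atoms, got {n}")
    if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(mob))):
        raise NumericError("coordinates contain NaN or infinite values")

    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float).reshape(-1)
        if w.shape[0] != n or np.any(w < 0) or w.sum() <= 0:
            raise ValidationError("weights must be non-negative, length N, with positive sum")
        w = w / w.sum()

    c_ref = w @ ref
    c_mob = w @ mob
    ref_c = ref - c_ref
    mob_c = mob - c_mob
    _check_degenerate(ref_c * np.sqrt(w)[:, None], "reference")
    _check_degenerate(mob_c * np.sqrt(w)[:, None], "mobile")

    # Weighted cross-covariance; SVD gives the optimal rotation up to a
    # possible reflection, removed via the sign of det(V Uᵀ).
    H = (mob_c * w[:, None]).T @ ref_c
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = c_ref - R @ c_mob

    transform = RigidTransform(R, t)
    dev = transform.apply(mob) - ref
    rmsd = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", dev, dev))))
    return transform, rmsd


def superpose_trajectory(
    traj: Trajectory,
    reference: Snapshot,
    selection: AtomSelection | None = None,
) -> Trajectory:
    """Fit every snapshot's selected protein atoms onto ``reference`` and
    apply the per-frame transform to all protein and water coordinates.

    Per-frame post-fit RMSDs are recorded in ``metadata['rmsd_per_frame']``.
    The selection must resolve to the same, at-least-3-atom index set on the
    reference and on every snapshot (rosters are already enforced identical
    within a trajectory).
    """
    selection = selection or AtomSelection.protein_heavy()
    ref_idx = selection.indices(reference)
    if len(ref_idx) < 3:
        raise ValidationError(
            f"fitting selection resolves to {len(ref_idx)} atoms on the reference; need >= 3"
        )
    mob_idx = selection.indices(traj.snapshots[0])
    ref_ids = [reference.protein_atoms[i].identity for i in ref_idx]
    mob_ids = [traj.snapshots[0].protein_atoms[i].identity for i in mob_idx]
    if ref_ids != mob_ids:
        raise ValidationError(
            "fitting selection resolves to different atoms on reference and trajectory; "
            "exclude mismatching residues (e.g. the mutated position) from the fit"
        )
    ref_coords = reference.protein_coords[ref_idx]

    new_snaps: list[Snapshot] = []
    rmsds: list[float] = []
    for snap in traj.snapshots:
        coords = snap.protein_coords
        transform, rmsd = kabsch_fit(ref_coords, coords[mob_idx])
        new_snaps.append(
            snap.with_coords(transform.apply(coords), transform.apply(snap.water_oxygens))
        )
        rmsds.append(rmsd)

    metadata = dict(traj.metadata)
    metadata["rmsd_per_frame"] = rmsds
    metadata["superposed"] = True
    return Trajectory(
        new_snaps,
        variant_label=traj.variant_label,
        replicate_id=traj.replicate_id,
        metadata=metadata,
    )
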