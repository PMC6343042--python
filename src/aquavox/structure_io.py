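"""Readers and writers for coordinate snapshots, voxel grids and titer tables.

Formats
-------
* multi-model PDB (``MODEL``/``ENDMDL``) — one model per trajectory snapshot;
  parsed with Biopython's ``PDBParser``.  Water molecules are identified by
  residue name (default ``{HOH, WAT, SOL}``) and only their oxygen atoms are
  kept; every other atom — including hetero ligands such as NADH or Zn, which
  are needed as selection anchors — counts as a protein-side atom.
* OpenDX scalar grids (``.dx``) via ``gridData`` for occupancy, difference
  and count fields.
* docking-pose CSV with columns ``snapshot,run,atom,x,y,z`` (Å).
* fermentation titer CSV with columns
  ``strain,butanol,acetone,ethanol,butyrate,acetate,glucose_consumed`` (g/L).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from gridData import Grid

from .errors import InputError, NumericError, ValidationError
from .fields import CountField, DifferenceField, GridSpec, OccupancyField

__all__ = [
    "AtomRecord",
    "Snapshot",
    "Trajectory",
    "DEFAULT_WATER_RESIDUES",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "write_grid_dx",
    "read_grid_dx",
    "read_pose_ensemble",
    "write_pose_ensemble",
    "read_titer_table",
]

DEFAULT_WATER_RESIDUES = frozenset({"HOH", "WAT", "SOL"})


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the protein-side roster (protein + retained hetero groups)."""

    atom_name: str
    residue_name: str
    residue_id: int
    chain_id: str
    element: str
    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise ValidationError("atom_name must be non-empty")
        if not all(math.isfinite(c) for c in self.position):
            raise NumericError(f"non-finite position for atom {self.atom_name}")

    @property
    def identity(self) -> tuple:
        """Roster identity — everything except the coordinates."""
        return (self.atom_name, self.residue_name, self.residue_id, self.chain_id, self.element)


@dataclass
class Snapshot:
    """One frame: the protein-side atom roster plus water oxygen positions."""

    protein_atoms: list[AtomRecord]
    water_oxygens: np.ndarray  # (n_waters, 3) Å; may be empty
    frame_index: int = 0

    def __post_init__(self) -> None:
        if len(self.protein_atoms) == 0:
            raise ValidationError("snapshot must contain at least one protein atom")
        self.water_oxygens = np.asarray(self.water_oxygens, dtype=float).reshape(-1, 3)
        if self.water_oxygens.size and not np.all(np.isfinite(self.water_oxygens)):
            raise NumericError(f"non-finite water coordinates in frame {self.frame_index}")

    @property
    def protein_coords(self) -> np.ndarray:
        return np.array([a.position for a in self.protein_atoms], dtype=float)

    def roster(self) -> tuple:
        return tuple(a.identity for a in self.protein_atoms)

    def with_coords(self, protein_coords: np.ndarray, water_coords: np.ndarray) -> "Snapshot":
        atoms = [
            replace(a, position=tuple(float(x) for x in xyz))
            for a, xyz in zip(self.protein_atoms, np.asarray(protein_coords, dtype=float))
        ]
        return Snapshot(atoms, np.asarray(water_coords, dtype=float), self.frame_index)


@dataclass
class Trajectory:
    """Ordered snapshots sharing one protein atom roster.

    ``variant_label`` names the structure (e.g. ``WT`` or ``M619A``);
    ``replicate_id`` distinguishes independent simulations of the same
    variant.  ``metadata`` carries provenance such as per-frame RMSDs after
    superposition or generator ground truth for synthetic trajectories.
    """

    snapshots: list[Snapshot]
    variant_label: str = "WT"
    replicate_id: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.snapshots) == 0:
            raise ValidationError("trajectory must contain at least one snapshot")
        ref = self.snapshots[0].roster()
        for i, snap in enumerate(self.snapshots[1:], start=1):
            if snap.roster() != ref:
                raise ValidationError(
                    f"protein atom roster of snapshot {i} differs from snapshot 0"
                )

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self):
        return iter(self.snapshots)


# ---------------------------------------------------------------------------
# multi-model PDB


def read_multimodel_pdb(
    path: str | Path,
    water_residue_names: Iterable[str] = DEFAULT_WATER_RESIDUES,
    variant_label: str = "WT",
    replicate_id: int = 0,
) -> Trajectory:
    """Parse a multi-model PDB into a :class:`Trajectory`.

    Each ``MODEL`` block becomes one snapshot (a file without MODEL records
    is a single-snapshot trajectory).  Waters are recognised by residue name
    and reduced to their oxygen atoms; all remaining atoms form the
    protein-side roster, which must be identical across models.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise InputError(f"coordinate file not found: {path}")
    waters = {w.upper() for w in water_residue_names}

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(path.stem, str(path))

    snapshots: list[Snapshot] = []
    reference_roster: tuple | None = None
    for model_index, model in enumerate(structure):
        atoms: list[AtomRecord] = []
        water_oxy: list[np.ndarray] = []
        for chain in model:
            for residue in chain:
                resname = residue.get_resname().strip().upper()
                resid = int(residue.get_id()[1])
                if resname in waters:
                    for atom in residue:
                        if (atom.element or "").strip().upper() == "O":
                            water_oxy.append(np.asarray(atom.get_coord(), dtype=float))
                    continue
                for atom in residue:
                    pos = atom.get_coord()
                    atoms.append(
                        AtomRecord(
                            atom_name=atom.get_name().strip(),
                            residue_name=resname,
                            residue_id=resid,
                            chain_id=chain.get_id().strip() or "A",
                            element=(atom.element or "").strip().upper(),
                            position=(float(pos[0]), float(pos[1]), float(pos[2])),
                        )
                    )
        if not atoms:
            raise ValidationError(f"model {model_index} of {path} has no protein atoms")
        snap = Snapshot(
            atoms,
            np.array(water_oxy, dtype=float).reshape(-1, 3),
            frame_index=model_index,
        )
        if reference_roster is None:
            reference_roster = snap.roster()
        elif snap.roster() != reference_roster:
            raise ValidationError(
                f"protein atom roster of model {model_index} in {path} "
                "differs from model 0"
            )
        snapshots.append(snap)

    if not snapshots:
        raise ValidationError(f"{path} contains no models")
    return Trajectory(snapshots, variant_label=variant_label, replicate_id=replicate_id)


def _pdb_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resid: int,
    xyz: Sequence[float],
    element: str,
    hetatm: bool,
) -> str:
    record = "HETATM" if hetatm else "ATOM  "
    # Standard PDB column 13-16 convention: short names are indented one space
    if len(name) >= 4:
        name_field = name[:4]
    else:
        name_field = f" {name:<3s}"
    return (
        f"{record}{serial % 100000:5d} {name_field}{'':1s}{resname[:3]:>3s} "
        f"{(chain or 'A')[:1]}{resid % 10000:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element[:2]:>2s}"
    )


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (waters as HETATM HOH/O)."""
    path = Path(path)
    lines: list[str] = []
    for m, snap in enumerate(traj.snapshots, start=1):
        lines.append(f"MODEL     {m:4d}")
        serial = 1
        for atom in snap.protein_atoms:
            hetatm = atom.residue_name not in _STANDARD_RESIDUES
            lines.append(
                _pdb_atom_line(
                    serial, atom.atom_name, atom.residue_name, atom.chain_id,
                    atom.residue_id, atom.position, atom.element, hetatm,
                )
            )
            serial += 1
        for w, xyz in enumerate(snap.water_oxygens, start=1):
            lines.append(_pdb_atom_line(serial, "O", "HOH", "W", w, xyz, "O", True))
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


_STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


# ---------------------------------------------------------------------------
# OpenDX grids


def write_grid_dx(field, path: str | Path) -> None:
    """Write an occupancy/difference/count field as an OpenDX regular grid.

    The DX origin is the center of voxel (0,0,0) and the deltas are the
    grid spacing on each axis; a round-trip read reproduces dims, origin and
    spacing exactly and values to better than 1e-6 relative.
    """
    values = getattr(field, "counts", None)
    if values is None:
        values = field.values
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise NumericError("cannot write grid with non-finite values")
    spec: GridSpec = field.spec
    grid = Grid(values, origin=np.asarray(spec.origin), delta=[spec.spacing] * 3)
    grid.export(str(path), file_format="dx", typequote='"', type="double")


def read_grid_dx(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    """Read an OpenDX scalar grid, returning its lattice and values array."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"grid file not found: {path}")
    grid = Grid(str(path))
    delta = np.asarray(grid.delta)
    if delta.ndim == 2:
        delta = np.diag(delta)
    spacing = float(delta[0])
    if not np.allclose(delta, spacing):
        raise ValidationError(f"anisotropic grid spacing {delta} is not supported")
    spec = GridSpec(origin=tuple(np.asarray(grid.origin, dtype=float)), spacing=spacing,
                    dims=tuple(int(d) for d in grid.grid.shape))
    return spec, np.asarray(grid.grid, dtype=float)


# ---------------------------------------------------------------------------
# docking-pose CSV


def read_pose_ensemble(path: str | Path, ligand_label: str = "ligand"):
    """Read a pose-ensemble CSV (columns ``snapshot,run,atom,x,y,z``).

    Rows sharing (snapshot, run) form one pose; a repeated
    (snapshot, run, atom) triple means the same pose is defined twice and is
    rejected.  An empty file yields an empty (but valid) ensemble.
    """
    from .pose_density import PoseEnsemble

    path = Path(path)
    if not path.exists():
        raise InputError(f"pose file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return PoseEnsemble(poses={}, ligand_label=ligand_label)
    if df.empty:
        return PoseEnsemble(poses={}, ligand_label=ligand_label)
    required = {"snapshot", "run", "atom", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"pose CSV {path} missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["snapshot", "run", "atom"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate pose key (snapshot={int(row['snapshot'])}, run={int(row['run'])}, "
            f"atom={int(row['atom'])}) in {path}"
        )
    poses: dict[tuple[int, int], np.ndarray] = {}
    for (snap, run), block in df.groupby(["snapshot", "run"], sort=True):
        block = block.sort_values("atom")
        poses[(int(snap), int(run))] = block[["x", "y", "z"]].to_numpy(dtype=float)
    return PoseEnsemble(poses=poses, ligand_label=ligand_label)


def write_pose_ensemble(ensemble, path: str | Path) -> None:
    """Write a pose ensemble to the CSV dialect read by :func:`read_pose_ensemble`."""
    rows = []
    for (snap, run), coords in sorted(ensemble.poses.items()):
        for a, xyz in enumerate(coords):
            rows.append((snap, run, a, xyz[0], xyz[1], xyz[2]))
    df = pd.DataFrame(rows, columns=["snapshot", "run", "atom", "x", "y", "z"])
    df.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# fermentation titer CSV


def read_titer_table(path: str | Path) -> pd.DataFrame:
    """Read a titer CSV into a validated DataFrame (g/L columns, one strain per row)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"titer table not found: {path}")
    df = pd.read_csv(path)
    required = {"strain", "butanol", "acetone", "ethanol"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"titer table {path} missing columns: {sorted(missing)}")
    titer_cols = [c for c in ("butanol", "acetone", "ethanol", "butyrate", "acetate",
                              "glucose_consumed") if c in df.columns]
    if (df[titer_cols].fillna(0.0) < 0).any().any():
        raise ValidationError(f"titer table {path} contains negative titers")
    return df
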