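"""End-to-end analyses: hydration difference mapping and pose-HDR analysis.

These wire the library stages together the way the CLI exposes them: read
snapshots, superpose onto one shared reference, grid, occupancy per
replicate, replicate-mean per variant, mutant-minus-wild-type difference
(plus optional sphere-region summaries); and pose ensembles → count fields
→ high-density regions → overlap report.  All outputs are deterministic for
a fixed configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import hydration_grid as hg
from . import pose_density as pdn
from .errors import InputError, ValidationError
from .structure_io import (
    Snapshot,
    Trajectory,
    read_grid_dx,
    read_multimodel_pdb,
    read_pose_ensemble,
    write_grid_dx,
)
from .superposition import AtomSelection, superpose_trajectory

__all__ = [
    "HydrationConfig",
    "HDRConfig",
    "parse_anchor",
    "parse_selection",
    "run_hydration_pipeline",
    "run_hdr_pipeline",
]


def parse_anchor(text: str) -> AtomSelection:
    """Parse ``RESID:ATOM`` or ``RESNAME:ATOM`` (e.g. ``836:OE1``,
    ``NADH:O7N``) into a single-atom selection."""
    try:
        left, atom = text.split(":")
    except ValueError as exc:
        raise ValidationError(f"anchor {text!r} must look like RES:ATOM") from exc
    left = left.strip()
    atom = atom.strip()
    if left.isdigit():
        return AtomSelection.single_atom(residue_id=int(left), atom_name=atom)
    return AtomSelection.single_atom(residue_name=left.upper(), atom_name=atom)


def parse_selection(name: str, exclude_residues: tuple[int, ...] = ()) -> AtomSelection:
    """Named fitting selections: ``protein-heavy`` (default) or ``ca``."""
    if name in ("protein-heavy", "heavy", ""):
        return AtomSelection.protein_heavy(exclude_residue_ids=exclude_residues)
    if name in ("ca", "calpha", "CA"):
        return AtomSelection.calpha(exclude_residue_ids=exclude_residues)
    raise ValidationError(f"unknown selection {name!r}; use 'protein-heavy' or 'ca'")


@dataclass
class HydrationConfig:
    """Inputs for the hydration difference analysis.

    ``wildtype`` lists replicate trajectory paths; ``mutants`` maps variant
    labels to their replicate path lists.  Defaults are the canonical
    analysis constants: 0.7 Å grid, 1.4 Å probe, 4.0 Å region radius.
    """

    wildtype: list[str]
    mutants: dict[str, list[str]] = field(default_factory=dict)
    reference: str | None = None  # default: first wild-type frame
    spacing: float = hg.DEFAULT_SPACING
    probe_radius: float = hg.DEFAULT_PROBE_RADIUS
    margin: float = hg.DEFAULT_MARGIN
    selection: str = "protein-heavy"
    exclude_residues: tuple[int, ...] = ()
    region_anchors: tuple[str, str] | None = None
    region_radius: float = hg.DEFAULT_REGION_RADIUS
    out_dir: str = "."


def _read_replicates(paths: list[str], label: str) -> list[Trajectory]:
    if not paths:
        raise ValidationError(f"no trajectory paths given for {label}")
    return [
        read_multimodel_pdb(p, variant_label=label, replicate_id=i)
        for i, p in enumerate(paths)
    ]


def run_hydration_pipeline(config: HydrationConfig) -> dict:
    """Occupancy per replicate → replicate mean per variant → differences.

    Writes ``occ_<variant>.dx`` and ``diff_<variant>.dx`` plus a JSON
    report to ``out_dir``; returns the report dict.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    groups: dict[str, list[Trajectory]] = {"WT": _read_replicates(config.wildtype, "WT")}
    for label, paths in config.mutants.items():
        groups[label] = _read_replicates(paths, label)

    if config.reference:
        reference = read_multimodel_pdb(config.reference).snapshots[0]
    else:
        reference = groups["WT"][0].snapshots[0]

    selection = parse_selection(config.selection, config.exclude_residues)
    aligned: dict[str, list[Trajectory]] = {}
    rmsd_report: dict[str, list[list[float]]] = {}
    for label, trajs in groups.items():
        aligned[label] = [superpose_trajectory(t, reference, selection) for t in trajs]
        rmsd_report[label] = [t.metadata["rmsd_per_frame"] for t in aligned[label]]

    all_trajs = [t for ts in aligned.values() for t in ts]
    spec = hg.make_grid_multi(all_trajs, spacing=config.spacing, margin=config.margin)

    fields: dict[str, hg.OccupancyField] = {}
    for label, trajs in aligned.items():
        per_replicate = [hg.occupancy_field(t, spec, config.probe_radius) for t in trajs]
        fields[label] = hg.mean_field(per_replicate)
        write_grid_dx(fields[label], out_dir / f"occ_{label}.dx")

    region = None
    if config.region_anchors:
        region = hg.SphereRegion(
            parse_anchor(config.region_anchors[0]),
            parse_anchor(config.region_anchors[1]),
            radius=config.region_radius,
        )

    report: dict = {
        "grid": {"origin": list(spec.origin), "spacing": spec.spacing, "dims": list(spec.dims)},
        "probe_radius": config.probe_radius,
        "rmsd_per_frame": rmsd_report,
        "variants": {},
    }
    for label in groups:
        entry: dict = {"n_snapshots": fields[label].n_snapshots}
        if region is not None:
            summary = hg.sphere_occupancy(fields[label], region, reference)
            entry["region_occupancy"] = summary.mean
        if label != "WT":
            diff = hg.difference_field(fields[label], fields["WT"])
            write_grid_dx(diff, out_dir / f"diff_{label}.dx")
            entry["diff_mean"] = float(diff.values.mean())
            if region is not None:
                entry["region_delta"] = hg.sphere_occupancy(diff, region, reference).mean
        report["variants"][label] = entry

    (out_dir / "hydration_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


@dataclass
class HDRConfig:
    """Inputs for the pose-density / HDR analysis.

    ``poses`` maps ligand (or variant) labels to pose-CSV paths.  The grid
    comes from an existing DX file (``grid_from``) or is derived from the
    union of pose coordinates plus ``margin``.
    """

    poses: dict[str, str]
    grid_from: str | None = None
    spacing: float = hg.DEFAULT_SPACING
    margin: float = 2.0
    probe_radius: float = hg.DEFAULT_PROBE_RADIUS
    threshold: int = pdn.DEFAULT_HDR_THRESHOLD
    out_dir: str = "."


def run_hdr_pipeline(config: HDRConfig) -> dict:
    """Count fields and HDRs per ligand plus pairwise overlap report."""
    if not config.poses:
        raise ValidationError("HDR pipeline needs at least one pose file")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ensembles = {
        label: read_pose_ensemble(path, ligand_label=label)
        for label, path in config.poses.items()
    }

    if config.grid_from:
        spec, _ = read_grid_dx(config.grid_from)
    else:
        coords = [e.all_coords() for e in ensembles.values() if len(e)]
        if not coords:
            raise ValidationError("all pose ensembles are empty and no grid was supplied")
        allc = np.concatenate(coords, axis=0)
        lo = allc.min(axis=0) - config.margin
        hi = allc.max(axis=0) + config.margin
        dims = tuple(int(np.ceil((h - l) / config.spacing)) + 1 for l, h in zip(lo, hi))
        spec = hg.GridSpec(origin=tuple(lo), spacing=config.spacing, dims=dims)

    report: dict = {
        "grid": {"origin": list(spec.origin), "spacing": spec.spacing, "dims": list(spec.dims)},
        "threshold": config.threshold,
        "probe_radius": config.probe_radius,
        "ligands": {},
        "overlaps": {},
    }
    hdrs: dict[str, pdn.HDRResult] = {}
    for label, ensemble in ensembles.items():
        counts = pdn.pose_count_field(ensemble, spec, config.probe_radius)
        write_grid_dx(counts, out_dir / f"counts_{label}.dx")
        hdr = pdn.extract_hdr(counts, config.threshold)
        hdrs[label] = hdr
        report["ligands"][label] = {
            "n_poses": len(ensemble),
            "max_count": int(counts.counts.max()) if counts.counts.size else 0,
            "hdr": hdr.to_dict(),
        }
    labels = sorted(hdrs)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            report["overlaps"][f"{a}|{b}"] = pdn.compare_hdr(hdrs[a], hdrs[b]).to_dict()

    (out_dir / "hdr_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
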