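# Methods

## Superposition

Each snapshot's protein part is fitted onto a shared reference with the
Kabsch algorithm: centroids are removed (weighted, weights normalised to
sum 1), the SVD of the weighted cross-covariance gives the rotation, and
the reflection branch is corrected by flipping the sign attached to the
smallest singular value, so the returned rotation always has det +1 to
1e-8. The same per-frame transform is applied to protein and water
coordinates, and per-frame post-fit RMSDs are recorded in trajectory
metadata. Degenerate inputs are rejected: fewer than 3 atoms, NaNs, or
point sets whose second singular value falls below 1e-10 of the first
(collinear configurations leave the rotation underdetermined).

The default fitting selection is all protein heavy atoms; a CA-only
selection is available. Because a mutant's roster differs from the wild
type's at the mutated residue, the selection accepts an exclusion list of
residue ids (`--exclude-residues`); fits across rosters that still differ
on the selected atoms are refused rather than silently mis-paired. The
reference defaults to the first wild-type frame; one common reference
across variants is enforced by construction in the hydration pipeline,
since difference fields require identical lattices.

## Water occupancy

The lattice has cubic voxels of 0.7 Å (default) whose (0,0,0) voxel center
sits at the grid origin; the grid covers the union bounding box of protein
atoms over all frames (and all variants, in the pipeline) plus a margin,
default 5 Å. "Within 1.4 Å" is read as *voxel center inside the closed
Euclidean ball* of the probe radius around a water oxygen; ties at exactly
the radius are included. Alternative readings (any-corner inside, or
voxel/sphere volume overlap) were considered and rejected as harder to
specify and test without changing the science. Marking uses a k-d tree over
voxel centers; the test suite holds it bit-identical to the brute-force
all-pairs rule.

Occupancy is the mean of per-snapshot 0/1 indicators, so every value is a
multiple of 1/N. Replicate simulations are averaged *as fields* (equal
weight per replicate regardless of snapshot count) before differencing;
whether one should instead pool snapshots is a genuinely open convention,
and the field-averaging choice is documented as this package's, chosen so
that a replicate with fewer frames cannot be swamped. Difference fields
are plain voxelwise subtraction and refuse mismatched lattices — no
resampling or interpolation is offered.

Sphere-restricted summaries average a field over voxels whose centers lie
inside a ball (default 4 Å) centered on the midpoint of two anchor atoms,
each resolved by a single-atom selection against the reference snapshot
(the numbering scheme of anchors like `836:OE1` is the caller's
responsibility).

The production-scale analysis this mirrors uses 5,000 snapshots per
trajectory and five replicates; snapshot count is an ordinary parameter
here, and the bundled tests and acceptance checks run at 8–500 snapshots,
sizes at which the statistical guarantees below are already sharp.

## Pose density and HDR

No marking rule for poses is standard, so the water rule is reused: a
(snapshot, run) pose marks a voxel when the voxel center lies within the
probe radius of *any* ligand heavy atom, contributing at most 1 per voxel
per pose. Counts therefore cannot exceed the number of keys (1,000 at the
canonical 10 runs × 100 snapshots). The HDR threshold is strict
(count > 750 by default; 750 itself is excluded) and applied per count
field. HDR volume is voxel count × spacing³. Overlaps of two HDRs report
shared voxels and the Jaccard index, with the identical-empty-set
convention Jaccard(∅, ∅) = 1.

## Synthetic data

The generator trades physical realism for exact testability:

* **Protein** — a helix-like curve (2.3 Å radius, 1.5 Å rise, 100°/residue)
  or a uniform random cloud, moved each frame by a random rotation
  (≤ 8° by default, small enough that fits never approach degeneracy) and
  translation (≤ 2 Å), with optional per-atom Gaussian jitter.
* **Waters** — per frame, each density region draws Poisson(λ) waters
  uniformly inside its ball (radius ρ), *independently across frames*.
  Waters are defined in the protein's base frame and carried into the lab
  frame by the frame's rigid motion, so occupancy analysis genuinely
  requires the superposition stage.
* **Poses** — a fraction f of the n_runs × n_snapshots poses lands
  uniformly in a hotspot ball, the rest uniformly in a 10 Å envelope.

Because waters are i.i.d. across frames, a voxel's occupancy is Binomial
(N, p)/N with p known in closed form: one water in a region hits the voxel
with probability `overlap(ball(center, r_probe), region ball) / region
volume` (spherical-lens formula), and thinning the Poisson count gives
`p = 1 − exp(−Σ λᵢ pᵢ)`. Recovery tests check observed occupancies against
exact binomial 99% intervals of this probability. What passing does *not*
show: real MD water is autocorrelated in time and structured by the protein
surface, so these tests validate the bookkeeping and geometry of the
analysis, not any claim about real hydration thermodynamics.

All generators take an explicit seed and are bit-reproducible for a fixed
seed and package version.

## Selectivity metrics

B/E ratio, butanol selectivity and yield are elementary ratios of measured
titers; they are computed at full precision, rounded (half-to-even) only
for display, and flagged — not raised — when a denominator is zero or a
required input is missing. Specific activity converts a μmol NADH/min rate
to mU/mg; the absorbance-to-rate helper requires the caller to supply the
extinction coefficient (the textbook 6.22 mM⁻¹cm⁻¹ is the default
argument, not a hidden constant).

Two arithmetic caveats about published tables of this kind: selectivity
columns recompute exactly from the printed mean titers (2 dp), but B/E
columns generally do not, because the source ratios were formed per
replicate and then averaged; recomputation from mean titers agrees only to
about ±0.35 and is treated as approximate. And the headline biological
outcomes themselves — titers like 11.66 g/L butanol, or hydration maps
from real trajectories — are wet-lab/MD measurements that no desk analysis
can regenerate: this package recomputes the arithmetic *derived from*
them and validates the pipeline on synthetic ground truth, and claims
nothing more.

## Numerical choices

* Lattice equality for differencing/averaging: dims exact, origin and
  spacing within 1e-9 Å.
* Grid files are OpenDX double-precision scalars; round-trips preserve the
  lattice exactly and values to better than 1e-6 relative.
* PDB coordinates carry 3 decimals; round-trips are exact at that
  precision. Waters are written as HETATM `HOH`/`O`; residue-name sets
  (`HOH`, `WAT`, `SOL`) identify waters on input, never element heuristics.
* Snapshots are assumed whole/unwrapped; no periodic-boundary handling is
  attempted (superposable protein parts imply unwrapped frames).
* Empty HDRs, empty pose ensembles and empty difference regions are valid
  results, not errors; empty fitting selections, roster mismatches and
  duplicate pose keys are errors.

## Known limitations

* No water kinetics (residence times, exchange) — occupancy only.
* No grid resampling: fields on different lattices cannot be compared.
* The docking and MD engines themselves are out of scope; the package
  consumes their outputs (or synthetic stand-ins) and never integrates
  dynamics or scores poses.
* Statistical comparison across fermentation strains (tests, error
  propagation) is out of scope; published means ± SD pass through as-is.
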