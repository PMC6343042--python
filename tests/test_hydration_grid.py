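"""Occupancy fields: lattice construction, marking rule, differences, regions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aquavox.errors import ValidationError
from aquavox.fields import GridSpec, OccupancyField, voxel_centers
from aquavox.hydration_grid import (
    SphereRegion,
    difference_field,
    make_grid,
    make_grid_multi,
    mean_field,
    occupancy_field,
    sphere_occupancy,
)
from aquavox.superposition import AtomSelection

from conftest import brute_force_occupancy, make_snapshot, make_trajectory


def single_atom_traj(position=(0.0, 0.0, 0.0), waters=None, n_frames=1):
    coords = np.array([position, np.add(position, (0.5, 0, 0)),
                       np.add(position, (0, 0.5, 0))])
    waters = np.zeros((0, 3)) if waters is None else waters
    return make_trajectory([(coords, waters) for _ in range(n_frames)])


class TestMakeGrid:
    def test_single_point_margin_and_spacing_arithmetic(self):
        traj = make_trajectory([(np.zeros((3, 3)), np.zeros((0, 3)))])
        spec = make_grid(traj, spacing=0.7, margin=1.4)
        assert spec.dims == (5, 5, 5)
        np.testing.assert_allclose(spec.origin, (-1.4, -1.4, -1.4))

    def test_zero_margin_single_point_is_one_voxel(self):
        traj = make_trajectory([(np.zeros((3, 3)), np.zeros((0, 3)))])
        spec = make_grid(traj, spacing=0.7, margin=0.0)
        assert spec.dims == (1, 1, 1)
        np.testing.assert_allclose(spec.origin, (0.0, 0.0, 0.0))

    def test_identical_proteins_get_identical_grids(self, rng):
        coords = rng.uniform(-8, 8, (10, 3))
        t1 = make_trajectory([(coords, np.zeros((0, 3)))])
        t2 = make_trajectory([(coords.copy(), np.zeros((0, 3)))])
        assert make_grid(t1).compatible_with(make_grid(t2))
        shared = make_grid_multi([t1, t2])
        assert shared.compatible_with(make_grid(t1))

    def test_grid_covers_union_bounding_box(self, rng):
        frames = [(rng.uniform(-5, 5, (6, 3)), np.zeros((0, 3))) for _ in range(4)]
        traj = make_trajectory(frames)
        spec = make_grid(traj, spacing=0.7, margin=2.0)
        allc = np.concatenate([s.protein_coords for s in traj])
        lo = np.asarray(spec.origin)
        hi = lo + spec.spacing * (np.asarray(spec.dims) - 1)
        assert np.all(allc.min(0) - 2.0 >= lo - 1e-9)
        assert np.all(allc.max(0) + 2.0 <= hi + 1e-9)


class TestOccupancyField:
    def test_no_waters_all_zero(self):
        traj = single_atom_traj(n_frames=4)
        spec = make_grid(traj, margin=2.0)
        field = occupancy_field(traj, spec)
        assert np.all(field.values == 0.0)
        assert field.n_snapshots == 4

    def test_water_at_voxel_center_marks_exactly_the_probe_ball(self):
        traj = single_atom_traj(waters=np.array([[0.0, 0.0, 0.0]]), n_frames=3)
        spec = make_grid(traj, spacing=0.7, margin=2.8)
        field = occupancy_field(traj, spec, probe_radius=1.4)
        centers = voxel_centers(spec)
        d = np.linalg.norm(centers, axis=1)
        flat = field.values.reshape(-1)
        assert np.all(flat[d <= 1.4] == 1.0)
        assert np.all(flat[d > 1.4] == 0.0)

    def test_water_in_half_the_snapshots_gives_half_occupancy(self):
        coords = np.array([[0.0, 0, 0], [0.5, 0, 0], [0, 0.5, 0]])
        water = np.array([[0.0, 0.0, 0.0]])
        frames = [(coords, water if i % 2 == 0 else np.zeros((0, 3))) for i in range(10)]
        traj = make_trajectory(frames)
        spec = make_grid(traj, margin=2.0)
        field = occupancy_field(traj, spec)
        covered = field.values[field.values > 0]
        assert np.all(covered == 0.5)

    def test_matches_brute_force_exactly_on_random_instances(self, rng):
        for _ in range(5):
            n_frames = int(rng.integers(2, 8))
            coords = rng.uniform(-4, 4, (5, 3))
            frames = [
                (coords, rng.uniform(-6, 6, (int(rng.integers(0, 30)), 3)))
                for _ in range(n_frames)
            ]
            traj = make_trajectory(frames)
            spec = make_grid(traj, spacing=0.9, margin=2.0)
            field = occupancy_field(traj, spec, probe_radius=1.4)
            oracle = brute_force_occupancy(traj, spec, 1.4)
            assert np.array_equal(field.values, oracle)

    def test_boundary_tie_at_probe_radius_included(self):
        """Closed-ball rule: a water exactly probe_radius from a voxel center
        marks that voxel."""
        coords = np.array([[0.0, 0, 0], [0.5, 0, 0], [0, 0.5, 0]])
        water = np.array([[1.4, 0.0, 0.0]])  # exactly 1.4 from the origin voxel
        traj = make_trajectory([(coords, water)])
        spec = GridSpec(origin=(0.0, 0.0, 0.0), spacing=0.7, dims=(1, 1, 1))
        field = occupancy_field(traj, spec, probe_radius=1.4)
        assert field.values[0, 0, 0] == 1.0

    def test_probe_radius_monotonicity(self, rng):
        coords = rng.uniform(-3, 3, (4, 3))
        frames = [(coords, rng.uniform(-4, 4, (10, 3))) for _ in range(5)]
        traj = make_trajectory(frames)
        spec = make_grid(traj, margin=2.0)
        small = occupancy_field(traj, spec, probe_radius=1.0)
        large = occupancy_field(traj, spec, probe_radius=1.8)
        assert np.all(large.values >= small.values)

    def test_translation_symmetry(self, rng):
        shift = np.array([3.7, -1.2, 9.4])
        coords = rng.uniform(-3, 3, (4, 3))
        waters = rng.uniform(-4, 4, (12, 3))
        t0 = make_trajectory([(coords, waters)])
        t1 = make_trajectory([(coords + shift, waters + shift)])
        spec0 = make_grid(t0, margin=2.0)
        spec1 = GridSpec(origin=tuple(np.asarray(spec0.origin) + shift),
                         spacing=spec0.spacing, dims=spec0.dims)
        f0 = occupancy_field(t0, spec0)
        f1 = occupancy_field(t1, spec1)
        np.testing.assert_allclose(f0.values, f1.values, atol=1e-12)

    def test_values_times_n_snapshots_are_integers(self, rng):
        coords = rng.uniform(-3, 3, (4, 3))
        frames = [(coords, rng.uniform(-4, 4, (8, 3))) for _ in range(7)]
        traj = make_trajectory(frames)
        spec = make_grid(traj, margin=1.0)
        field = occupancy_field(traj, spec)
        counts = field.values * field.n_snapshots
        np.testing.assert_allclose(counts, np.rint(counts), atol=1e-9)
        assert field.values.min() >= 0.0 and field.values.max() <= 1.0


class TestMeanAndDifference:
    def _random_field(self, rng, spec, n=10):
        return OccupancyField(spec, rng.integers(0, n + 1, spec.dims) / n, n_snapshots=n)

    def test_mean_of_field_with_itself_is_identity(self, rng):
        spec = GridSpec((0, 0, 0), 0.7, (3, 3, 3))
        f = self._random_field(rng, spec)
        m = mean_field([f, f])
        np.testing.assert_array_equal(m.values, f.values)
        assert m.n_snapshots == 2 * f.n_snapshots

    def test_mean_of_zero_and_one_fields_is_half(self):
        spec = GridSpec((0, 0, 0), 0.7, (2, 2, 2))
        z = OccupancyField(spec, np.zeros(spec.dims), n_snapshots=4)
        o = OccupancyField(spec, np.ones(spec.dims), n_snapshots=4)
        assert np.all(mean_field([z, o]).values == 0.5)

    def test_mean_matches_elementwise_oracle(self, rng):
        spec = GridSpec((0, 0, 0), 0.7, (4, 2, 3))
        fields = [self._random_field(rng, spec) for _ in range(5)]
        m = mean_field(fields)
        oracle = np.mean([f.values for f in fields], axis=0)
        np.testing.assert_allclose(m.values, oracle, atol=1e-15)

    def test_mean_rejects_mismatched_grids(self, rng):
        a = self._random_field(rng, GridSpec((0, 0, 0), 0.7, (3, 3, 3)))
        b = self._random_field(rng, GridSpec((0, 0, 0), 0.7, (3, 3, 4)))
        with pytest.raises(ValidationError):
            mean_field([a, b])

    def test_difference_of_field_with_itself_is_zero(self, rng):
        spec = GridSpec((0, 0, 0), 0.7, (3, 3, 3))
        f = self._random_field(rng, spec)
        assert np.all(difference_field(f, f).values == 0.0)

    def test_difference_all_one_minus_all_zero(self):
        spec = GridSpec((0, 0, 0), 0.7, (2, 2, 2))
        o = OccupancyField(spec, np.ones(spec.dims), n_snapshots=1)
        z = OccupancyField(spec, np.zeros(spec.dims), n_snapshots=1)
        assert np.all(difference_field(o, z).values == 1.0)

    def test_difference_matches_subtraction_oracle(self, rng):
        spec = GridSpec((0, 0, 0), 0.7, (4, 3, 2))
        a, b = self._random_field(rng, spec), self._random_field(rng, spec)
        np.testing.assert_array_equal(difference_field(a, b).values, a.values - b.values)

    def test_difference_rejects_mismatched_origin(self, rng):
        a = self._random_field(rng, GridSpec((0, 0, 0), 0.7, (3, 3, 3)))
        b = self._random_field(rng, GridSpec((0.1, 0, 0), 0.7, (3, 3, 3)))
        with pytest.raises(ValidationError):
            difference_field(a, b)


class TestSphereOccupancy:
    def _reference_with_anchors(self):
        # anchors: atom "O7N" of residue NAI 900, atom "OE1" of residue 836
        from aquavox.structure_io import AtomRecord, Snapshot

        atoms = [
            AtomRecord("CA", "ALA", 1, "A", "C", (0.0, 0.0, 0.0)),
            AtomRecord("CA", "ALA", 2, "A", "C", (1.0, 0.0, 0.0)),
            AtomRecord("CA", "ALA", 3, "A", "C", (0.0, 1.0, 0.0)),
            AtomRecord("O7N", "NAI", 900, "A", "O", (2.0, 0.0, 0.0)),
            AtomRecord("OE1", "ASN", 836, "A", "O", (-2.0, 0.0, 0.0)),
        ]
        return Snapshot(atoms, np.zeros((0, 3)))

    def _region(self, radius=4.0):
        return SphereRegion(
            AtomSelection.single_atom(atom_name="O7N", residue_name="NAI"),
            AtomSelection.single_atom(residue_id=836, atom_name="OE1"),
            radius=radius,
        )

    def test_midpoint_of_anchor_atoms_is_the_center(self):
        region = self._region()
        np.testing.assert_allclose(region.center(self._reference_with_anchors()), 0.0)

    def test_uniform_field_returns_its_constant(self, rng):
        spec = GridSpec((-3.5, -3.5, -3.5), 0.7, (11, 11, 11))
        field = OccupancyField(spec, np.full(spec.dims, 0.4), n_snapshots=5)
        summary = sphere_occupancy(field, self._region(), self._reference_with_anchors())
        assert summary.mean == pytest.approx(0.4)
        assert summary.total == pytest.approx(0.4 * summary.n_voxels)

    def test_matches_exhaustive_voxel_scan(self, rng):
        spec = GridSpec((-3.5, -3.5, -3.5), 0.7, (11, 11, 11))
        vals = rng.random(spec.dims)
        field = OccupancyField(spec, vals, n_snapshots=None)
        summary = sphere_occupancy(field, self._region(4.0), self._reference_with_anchors())
        centers = voxel_centers(spec)
        inside = np.linalg.norm(centers, axis=1) <= 4.0
        assert summary.n_voxels == int(inside.sum())
        assert summary.mean == pytest.approx(vals.reshape(-1)[inside].mean(), abs=1e-12)

    def test_no_voxels_inside_is_an_error(self):
        spec = GridSpec((100.0, 100.0, 100.0), 0.7, (3, 3, 3))
        field = OccupancyField(spec, np.zeros(spec.dims), n_snapshots=1)
        with pytest.raises(ValidationError):
            sphere_occupancy(field, self._region(0.5), self._reference_with_anchors())

    def test_unresolvable_anchor_is_an_error(self):
        spec = GridSpec((-3.5, -3.5, -3.5), 0.7, (11, 11, 11))
        field = OccupancyField(spec, np.zeros(spec.dims), n_snapshots=1)
        region = SphereRegion(
            AtomSelection.single_atom(atom_name="XX9"),
            AtomSelection.single_atom(residue_id=836, atom_name="OE1"),
        )
        with pytest.raises(ValidationError):
            sphere_occupancy(field, region, self._reference_with_anchors())


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_occupancy_stays_in_unit_interval(seed):
    """Property: any random instance yields values in [0,1] with
    value × n_snapshots integral."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-3, 3, (3, 3))
    n_frames = int(rng.integers(1, 6))
    frames = [(coords, rng.uniform(-4, 4, (int(rng.integers(0, 12)), 3)))
              for _ in range(n_frames)]
    traj = make_trajectory(frames)
    spec = make_grid(traj, spacing=1.1, margin=1.5)
    field = occupancy_field(traj, spec)
    assert field.values.min() >= 0.0 and field.values.max() <= 1.0
    scaled = field.values * n_frames
    np.testing.assert_allclose(scaled, np.rint(scaled), atol=1e-9)
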