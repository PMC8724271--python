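"""Geometry oracles and coverage-count invariants.

Every analytic classification is checked against an independent oracle:
surface rejection sampling for point-box distance, grid maximisation for
the farthest-point distance, an independently coded brute-force offset
loop for the coverage counts, and a voxel oracle for the criterion
classifications.
"""

import math
from fractions import Fraction

import numpy as np
import pytest

from pararange.lattice import (
    Box,
    CoverageCriterion,
    LatticeSpec,
    convention_sweep,
    count_affected,
    distance_point_to_box,
    farthest_point_distance,
    published_matching_convention,
    rate_to_dose_note,
    voxel_fraction_within,
)

CM_HALF = (60.0, 10.0, 10.0)


def sample_box_surface(box: Box, n: int, rng) -> np.ndarray:
    """Uniform points on the surface of an axis-aligned box (oracle)."""
    c = np.array(box.center)
    h = np.array(box.half)
    dims = 2 * h
    areas = np.array([dims[1] * dims[2], dims[0] * dims[2], dims[0] * dims[1]])
    areas = np.repeat(areas, 2)  # +/- face per axis
    face = rng.choice(6, size=n, p=areas / areas.sum())
    u = rng.uniform(-1, 1, (n, 3)) * h
    pts = c + u
    axis = face // 2
    sign = np.where(face % 2 == 0, 1.0, -1.0)
    pts[np.arange(n), axis] = c[axis] + sign * h[axis]
    return pts


class TestDistancePointToBox:
    def test_interior_point_is_zero(self, cm_box):
        assert distance_point_to_box((0, 0, 0), cm_box) == 0.0
        assert distance_point_to_box((59.9, -9.9, 9.9), cm_box) == 0.0

    def test_face_normal_offset(self, cm_box):
        assert distance_point_to_box((70, 0, 0), cm_box) == pytest.approx(10.0)

    def test_edge_diagonal(self, cm_box):
        assert distance_point_to_box((70, 20, 0), cm_box) == pytest.approx(
            math.sqrt(200.0)
        )

    def test_vectorised_over_points(self, cm_box):
        pts = np.array([[0, 0, 0], [70, 0, 0], [70, 20, 0]])
        np.testing.assert_allclose(
            distance_point_to_box(pts, cm_box),
            [0.0, 10.0, math.sqrt(200.0)],
        )

    @pytest.mark.parametrize(
        "point", [(75.0, 0.0, 0.0), (70.0, 20.0, 0.0), (80.0, 25.0, 30.0),
                  (0.0, -40.0, 0.0), (-90.0, 18.0, -22.0)]
    )
    def test_rejection_sampling_oracle(self, cm_box, point, rng):
        """Min distance to 2x10^5 random surface points approximates the
        clamped-distance formula from above."""
        surf = sample_box_surface(cm_box, 200_000, rng)
        oracle = np.linalg.norm(surf - np.array(point), axis=1).min()
        d = distance_point_to_box(point, cm_box)
        # the sampled minimum bounds the true distance from above, with a
        # gap set by the surface sampling density (~0.5 um near corners)
        assert d <= oracle + 1e-9
        assert oracle - d < 0.3


class TestFarthestPointDistance:
    def grid_oracle(self, neighbor: Box, infected: Box, step=0.5) -> float:
        """Maximise the point-box distance over a grid of neighbour points
        including all corners (where the maximum is attained)."""
        c, h = np.array(neighbor.center), np.array(neighbor.half)
        axes = [
            np.linspace(c[a] - h[a], c[a] + h[a], int(2 * h[a] / step) + 1)
            for a in range(3)
        ]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
        return distance_point_to_box(pts, infected).max()

    def test_coincident_boxes_have_zero_farthest_distance(self, cm_box):
        assert farthest_point_distance(cm_box, cm_box) == 0.0

    def test_face_sharing_neighbor(self, cm_box):
        nb = Box((0.0, 20.0, 0.0), CM_HALF)
        assert farthest_point_distance(nb, cm_box) == pytest.approx(20.0)
        assert self.grid_oracle(nb, cm_box) == pytest.approx(20.0)

    @pytest.mark.parametrize(
        "center",
        [(120.0, 0.0, 0.0), (0.0, 40.0, 20.0), (120.0, 20.0, 20.0),
         (0.0, -20.0, 0.0), (60.0, 30.0, -40.0)],
    )
    def test_grid_maximisation_oracle(self, cm_box, center):
        nb = Box(center, CM_HALF)
        far = farthest_point_distance(nb, cm_box)
        assert far == pytest.approx(self.grid_oracle(nb, cm_box), abs=1e-9)

    def test_dominates_every_sampled_point(self, cm_box, rng):
        nb = Box((120.0, 40.0, 20.0), CM_HALF)
        far = farthest_point_distance(nb, cm_box)
        pts = np.array(nb.center) + rng.uniform(-1, 1, (50_000, 3)) * CM_HALF
        assert (distance_point_to_box(pts, cm_box) <= far + 1e-9).all()


class TestVoxelFraction:
    def test_huge_radius_covers_everything(self, cm_box):
        nb = Box((240.0, 40.0, 40.0), CM_HALF)
        assert voxel_fraction_within(nb, cm_box, 1e6) == 1.0

    def test_zero_radius_disjoint_boxes(self, cm_box):
        nb = Box((240.0, 0.0, 0.0), CM_HALF)
        assert voxel_fraction_within(nb, cm_box, 0.0) == 0.0

    def test_resolution_self_convergence(self, cm_box):
        nb = Box((0.0, 20.0, 0.0), CM_HALF)
        f1 = voxel_fraction_within(nb, cm_box, 20.0, resolution=1.0)
        f05 = voxel_fraction_within(nb, cm_box, 20.0, resolution=0.5)
        assert abs(f1 - f05) < 0.02

    def test_bad_resolution_raises(self, cm_box):
        with pytest.raises(ValueError):
            voxel_fraction_within(cm_box, cm_box, 10.0, resolution=0.0)

    def test_uneven_resolution_warns(self, cm_box):
        with pytest.warns(UserWarning, match="resolution"):
            voxel_fraction_within(cm_box, cm_box, 10.0, resolution=7.3)


def brute_force_count(packing: str, radius: float, kind: str, vox: float = 1.0) -> int:
    """Independently coded offset loop over i,j,k in [-8, 8].

    Re-derives every classification from raw coordinates: clamp formulas
    written inline, voxel criteria from an explicit voxel-centre grid.
    """
    n = 0
    lx, ly, lz = 120.0, 20.0, 20.0
    hx, hy, hz = 60.0, 10.0, 10.0
    for i in range(-8, 9):
        for j in range(-8, 9):
            for k in range(-8, 9):
                if (i, j, k) == (0, 0, 0):
                    continue
                cx = lx * i + (lx / 2 if packing == "brick_staggered_x" and j % 2 else 0)
                cy, cz = ly * j, lz * k
                if kind == "center_in":
                    d = math.sqrt(
                        max(abs(cx) - hx, 0) ** 2
                        + max(abs(cy) - hy, 0) ** 2
                        + max(abs(cz) - hz, 0) ** 2
                    )
                    ok = d <= radius
                elif kind == "whole_cell":
                    d = math.sqrt(
                        max(abs(cx) + hx - hx, 0) ** 2
                        + max(abs(cy) + hy - hy, 0) ** 2
                        + max(abs(cz) + hz - hz, 0) ** 2
                    )
                    ok = d <= radius
                else:  # voxel criteria
                    gap = math.sqrt(
                        max(abs(cx) - 2 * hx, 0) ** 2
                        + max(abs(cy) - 2 * hy, 0) ** 2
                        + max(abs(cz) - 2 * hz, 0) ** 2
                    )
                    if gap > radius:  # no voxel centre can be in range
                        continue
                    xs = cx - hx + (np.arange(int(lx / vox)) + 0.5) * vox
                    ys = cy - hy + (np.arange(int(ly / vox)) + 0.5) * vox
                    zs = cz - hz + (np.arange(int(lz / vox)) + 0.5) * vox
                    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
                    D = np.sqrt(
                        np.maximum(np.abs(X) - hx, 0) ** 2
                        + np.maximum(np.abs(Y) - hy, 0) ** 2
                        + np.maximum(np.abs(Z) - hz, 0) ** 2
                    )
                    frac = (D <= radius).mean()
                    ok = frac >= (0.5 if kind == "half_volume" else 1.0)
                n += int(ok)
    return n


class TestCountAffected:
    def test_zero_radius_reaches_nobody(self, cm_spec):
        res = count_affected(cm_spec, 0.0, CoverageCriterion("whole_cell"))
        assert res.n_affected == 0
        assert res.min_infection_rate == Fraction(1, 1)
        assert res.rate_percent == 100.0

    def test_center_in_at_study_radius_matches_brute_force(self, cm_spec):
        res = count_affected(cm_spec, 84.5, CoverageCriterion("center_in"))
        assert res.n_affected == brute_force_count("axis_aligned", 84.5, "center_in")
        assert res.n_affected == 158  # frozen from the oracle

    @pytest.mark.parametrize("packing", ["axis_aligned", "brick_staggered_x"])
    @pytest.mark.parametrize("kind", ["whole_cell", "center_in"])
    def test_analytic_criteria_match_brute_force_everywhere(self, packing, kind):
        spec = LatticeSpec(packing=packing)
        res = count_affected(spec, 84.5, CoverageCriterion(kind), check_extent=False)
        assert res.n_affected == brute_force_count(packing, 84.5, kind)

    def test_rate_bookkeeping_is_exact_rational(self, cm_spec):
        res = count_affected(cm_spec, 84.5, CoverageCriterion("whole_cell"))
        assert res.min_infection_rate * (res.n_affected + 1) == 1
        assert isinstance(res.min_infection_rate, Fraction)
        assert res.n_total == res.n_affected + 1

    def test_monotone_in_radius(self, cm_spec):
        for kind in ("whole_cell", "center_in"):
            counts = [
                count_affected(cm_spec, r, CoverageCriterion(kind),
                               check_extent=False).n_affected
                for r in (0.0, 20.0, 40.0, 60.0, 84.5, 100.0)
            ]
            assert counts == sorted(counts)
        counts = [
            count_affected(cm_spec, r, CoverageCriterion("half_volume"),
                           check_extent=False).n_affected
            for r in (0.0, 50.0, 84.5, 100.0)
        ]
        assert counts == sorted(counts)

    def test_extent_independence(self, cm_spec):
        auto = count_affected(cm_spec, 84.5, CoverageCriterion("center_in"))
        big = count_affected(
            LatticeSpec(extent=(8, 16, 16)), 84.5, CoverageCriterion("center_in"),
            check_extent=False,
        )
        assert auto.n_affected == big.n_affected

    def test_affected_offsets_are_reflection_symmetric(self, cm_spec):
        res = count_affected(cm_spec, 84.5, CoverageCriterion("whole_cell"))
        offsets = set(res.offsets)
        for i, j, k in offsets:
            for refl in [(-i, j, k), (i, -j, k), (i, j, -k)]:
                assert refl in offsets

    def test_criterion_ordering(self, cm_spec):
        n = {
            kind: count_affected(cm_spec, 84.5, CoverageCriterion(kind),
                                 check_extent=False).n_affected
            for kind in ("whole_cell", "whole_cell_voxel", "center_in", "half_volume")
        }
        assert n["whole_cell"] <= n["whole_cell_voxel"] <= n["half_volume"]
        assert n["whole_cell"] <= n["center_in"]

    def test_negative_radius_raises(self, cm_spec):
        with pytest.raises(ValueError):
            count_affected(cm_spec, -1.0)


class TestVoxelOracleEquivalence:
    """Analytic classifications agree with a fine-voxel oracle."""

    def frac(self, center, radius, res):
        nb = Box(center, CM_HALF)
        return voxel_fraction_within(nb, Box((0, 0, 0), CM_HALF), radius, res)

    def test_analytic_classifications_vs_half_micron_voxels(self, cm_box):
        infected = cm_box
        for i in (-1, 0, 1):
            for j in range(-5, 6):
                for k in range(-5, 6):
                    if (i, j, k) == (0, 0, 0):
                        continue
                    nb = Box((120.0 * i, 20.0 * j, 20.0 * k), CM_HALF)
                    # skip offsets that cannot interact at all
                    gap = distance_point_to_box(np.array(nb.center), infected)
                    if gap - math.sqrt(60**2 + 10**2 + 10**2) > 84.5:
                        continue
                    frac = voxel_fraction_within(nb, infected, 84.5, 0.5)
                    # voxel centres sit up to half a voxel inside the surface,
                    # so analytic whole-cell coverage implies full voxel cover
                    if farthest_point_distance(nb, infected) <= 84.5:
                        assert frac == 1.0
                    # the centre's side of the (locally flat) boundary decides
                    # the voxel majority
                    center_analytic = gap <= 84.5
                    assert center_analytic == (frac >= 0.5)

    def test_borderline_corner_cells_at_quarter_micron(self):
        """Cells whose farthest corner misses the radius by <0.5 um flip
        between the analytic and 1-um voxel whole-cell readings but agree
        again at 0.25 um."""
        for j, k in [(3, 3), (-3, 3), (3, -3), (-3, -3)]:
            center = (0.0, 20.0 * j, 20.0 * k)
            far = farthest_point_distance(Box(center, CM_HALF), Box((0, 0, 0), CM_HALF))
            assert far > 84.5  # analytically not whole-cell covered
            assert self.frac(center, 84.5, 1.0) == 1.0   # 1-um voxels: covered
            assert self.frac(center, 84.5, 0.25) < 1.0   # refined: not covered


class TestConventionSweep:
    def test_sweep_reports_every_convention(self):
        table = convention_sweep(voxel_resolution=1.0)
        assert len(table) == 8
        assert set(table.packing) == {"axis_aligned", "brick_staggered_x"}
        got = table.set_index(["packing", "criterion"]).n_affected
        assert got["axis_aligned", "whole_cell"] == 56
        assert got["axis_aligned", "whole_cell_voxel"] == 60
        assert got["axis_aligned", "center_in"] == 158
        assert got["axis_aligned", "half_volume"] == 158

    def test_published_matching_convention_is_documented_and_consistent(self):
        conv = published_matching_convention()
        assert conv["packing"] == "axis_aligned"
        spec = LatticeSpec(packing=conv["packing"])
        whole = count_affected(spec, 84.5, conv["whole_cell"], check_extent=False)
        assert whole.n_affected == 60  # the published whole-cell count


class TestRateToDoseNote:
    def test_twenty_fold_reduction(self):
        note = rate_to_dose_note(0.0167, 0.334)
        assert note["fold_reduction"] == pytest.approx(20.0)

    @pytest.mark.parametrize("f,ref", [(0.334, 0.334), (0.0064, 0.0064)])
    def test_equal_rates_are_one_fold(self, f, ref):
        assert rate_to_dose_note(f, ref)["fold_reduction"] == pytest.approx(1.0)

    def test_rate_above_reference_raises(self):
        with pytest.raises(ValueError):
            rate_to_dose_note(0.5, 0.334)
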