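"""Sine-corrected projection, alpha-shape metrics, functional centre,
regressions — each checked against an independent implementation."""

import numpy as np
import pytest
from scipy.spatial import Delaunay

from promorom.rom_metrics import (
    IntensityMap,
    alpha_shape_area,
    alpha_shape_volume,
    axial_intensity,
    circumduction_envelope,
    functional_centre,
    mobility,
    project_poses,
    project_sine,
    regress_metrics,
)
from promorom.rom_simulator import Pose


# -- independent (naive) alpha-shape implementation for cross-checks --------


def _naive_circumradius(simplex):
    """Circumradius via the circumcentre normal equations, one simplex."""
    p0 = simplex[0]
    rows = [2 * (p - p0) for p in simplex[1:]]
    rhs = [p @ p - p0 @ p0 for p in simplex[1:]]
    try:
        c = np.linalg.solve(np.array(rows), np.array(rhs))
    except np.linalg.LinAlgError:
        return np.inf
    return float(np.linalg.norm(c - p0))


def naive_alpha_measure(points, alpha):
    """Slow per-simplex alpha-shape volume (3D) or area (2D)."""
    pts = np.unique(np.asarray(points, float), axis=0)
    tri = Delaunay(pts)
    total = 0.0
    dim = pts.shape[1]
    for s in tri.simplices:
        sx = pts[s]
        if _naive_circumradius(sx) > alpha:
            continue
        mat = sx[1:] - sx[0]
        total += abs(np.linalg.det(mat)) / (6.0 if dim == 3 else 2.0)
    return total


class TestProjection:
    def test_sine_correction_examples(self):
        assert project_sine(Pose(120, 90, 0)).x == pytest.approx(120.0)
        assert project_sine(Pose(77, 0, 0)).x == pytest.approx(0.0)

    def test_jacobian_is_sin_abduction(self, rng):
        # equal-area property: |d(x, y) / d(poe, abd)| = sin(abd)
        for _ in range(1000):
            poe = rng.uniform(-180, 180)
            abd = rng.uniform(1, 179)
            h = 1e-6
            dx_dpoe = (
                project_sine(Pose(poe + h, abd, 0)).x
                - project_sine(Pose(poe - h, abd, 0)).x
            ) / (2 * h)
            jac = dx_dpoe * 1.0  # dy/dabd = 1, dx/dabd term drops out of det
            assert jac == pytest.approx(np.sin(np.radians(abd)), abs=1e-6)

    def test_small_geodesic_steps_undistorted(self, rng):
        # 1-degree steps on the joint sphere keep their length on the map
        # to within 1% near the central meridian
        for _ in range(100):
            abd = rng.uniform(20, 160)
            p0 = Pose(0.0, abd, 0)
            p1 = Pose(1.0 / np.sin(np.radians(abd)), abd, 0)  # 1 deg geodesic
            a = project_sine(p0)
            b = project_sine(p1)
            step = np.hypot(b.x - a.x, b.y - a.y)
            assert step == pytest.approx(1.0, rel=0.01)

    def test_pole_duplicates_removed(self):
        poses = [Pose(p, 0.0, 0.0) for p in (-90.0, 0.0, 90.0)]
        assert len(project_poses(poses)) == 1


class TestAlphaShapes:
    def test_single_pose_gives_zero_measures(self):
        with pytest.warns(UserWarning):
            assert mobility([Pose(10, 20, 30)]) == 0.0
        with pytest.warns(UserWarning):
            assert circumduction_envelope([Pose(10, 20, 30)]) == 0.0

    def test_dense_box_volume_within_five_percent(self, rng):
        grid = np.stack(
            np.meshgrid(*[np.linspace(0, 30, 11)] * 3, indexing="ij"), axis=-1
        ).reshape(-1, 3)
        vol = alpha_shape_volume(grid, alpha_radius=5.0)
        assert vol == pytest.approx(30.0**3, rel=0.05)

    def test_volume_matches_naive_implementation(self, rng):
        pts = rng.uniform(0, 40, size=(300, 3))
        for alpha in (5.0, 10.0):
            assert alpha_shape_volume(pts, alpha) == pytest.approx(
                naive_alpha_measure(pts, alpha), rel=1e-3
            )

    def test_area_matches_naive_implementation(self, rng):
        pts = rng.uniform(0, 40, size=(400, 2))
        for alpha in (4.0, 8.0):
            assert alpha_shape_area(pts, alpha) == pytest.approx(
                naive_alpha_measure(pts, alpha), rel=1e-3
            )

    def test_alpha_monotonicity(self, rng):
        pts = rng.uniform(0, 30, size=(200, 3))
        vols = [alpha_shape_volume(pts, a) for a in (3.0, 5.0, 8.0)]
        assert vols[0] <= vols[1] <= vols[2]

    def test_full_coverage_envelope_matches_sphere_map_area(self):
        # every long-axis direction admissible: the 2D map covers the full
        # sinusoidal projection of the joint sphere, whose area equals the
        # total solid angle in square degrees
        poses = [
            Pose(p, a, 0.0)
            for p in np.linspace(-180, 180, 73)
            for a in np.linspace(0, 180, 37)
        ]
        area = circumduction_envelope(poses, alpha_radius=6.0)
        exact = 4 * np.pi * (180 / np.pi) ** 2
        assert area == pytest.approx(exact, rel=0.05)

    def test_masked_subset_has_strictly_smaller_envelope(self):
        full = [
            Pose(p, a, 0.0)
            for p in np.linspace(-180, 180, 25)
            for a in np.linspace(0, 180, 13)
        ]
        subset = [p for p in full if p.abduction <= 90]
        assert circumduction_envelope(subset, 16.0) < circumduction_envelope(full, 16.0)


class TestAxialIntensity:
    def test_counting_convention_includes_both_axial_endpoints(self):
        poses = [Pose(30.0, 60.0, a) for a in np.linspace(-180, 180, 73)]
        imap = axial_intensity(poses, increment_deg=5.0)
        assert imap.intensity[0] == pytest.approx(365.0)

    def test_nodes_without_admissible_axials_absent(self):
        poses = [Pose(0.0, 30.0, 0.0)]
        imap = axial_intensity(poses, 15.0)
        assert len(imap.poe) == 1

    def test_total_intensity_proportional_to_pose_count(self):
        poses = [
            Pose(p, a, x)
            for p in (0.0, 15.0)
            for a in (30.0, 45.0)
            for x in (0.0, 15.0, 30.0)
        ]
        imap = axial_intensity(poses, 15.0)
        assert imap.intensity.sum() == pytest.approx(len(poses) * 15.0)

    def test_empty_rom_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            axial_intensity([], 5.0)


class TestFunctionalCentre:
    def _bump_map(self, centre=(30.0, 110.0), inc=5.0):
        poe, abd = np.meshgrid(
            np.arange(-180, 181, inc), np.arange(0, 181, inc), indexing="ij"
        )
        poe, abd = poe.ravel(), abd.ravel()
        d2 = (poe - centre[0]) ** 2 + (abd - centre[1]) ** 2
        inten = 100.0 + 260.0 * np.exp(-d2 / (2 * 30.0**2))
        return IntensityMap(poe=poe, abd=abd, intensity=inten, increment=inc)

    def test_gaussian_bump_recovered_within_one_cell(self):
        imap = self._bump_map()
        # brute force: evaluate the same objective on a dense half-degree grid
        mob = 50.0**3  # search radius = 0.3 * 50 = 15 degrees
        fc = functional_centre(imap, mob, radius_coeff=0.3)

        def mean_in_circle(cp, ca):
            from promorom.rom_metrics import _geodesic_deg

            d = _geodesic_deg(imap.poe, imap.abd, cp, ca)
            m = d <= 15.0
            return imap.intensity[m].mean() if m.any() else -np.inf

        best, best_s = None, -np.inf
        for cp in np.arange(20, 41, 0.5):
            for ca in np.arange(100, 121, 0.5):
                s = mean_in_circle(cp, ca)
                if s > best_s:
                    best, best_s = (cp, ca), s
        assert abs(fc[0] - best[0]) <= imap.increment
        assert abs(fc[1] - best[1]) <= imap.increment

    def test_symmetric_map_tie_breaks_to_zero_poe(self):
        poe, abd = np.meshgrid(
            np.arange(-60, 61, 10.0), np.arange(40, 141, 10.0), indexing="ij"
        )
        imap = IntensityMap(
            poe=poe.ravel(), abd=abd.ravel(),
            intensity=np.full(poe.size, 200.0), increment=10.0,
        )
        fc = functional_centre(imap, 20.0**3, radius_coeff=0.3)
        assert fc[0] == pytest.approx(0.0, abs=1e-9)

    def test_intensity_scaling_leaves_centre_unchanged(self):
        imap = self._bump_map()
        fc1 = functional_centre(imap, 50.0**3, radius_coeff=0.3)
        imap2 = IntensityMap(imap.poe, imap.abd, 2.0 * imap.intensity, imap.increment)
        fc2 = functional_centre(imap2, 50.0**3, radius_coeff=0.3)
        assert fc1 == fc2

    def test_oversized_circle_falls_back_to_weighted_centroid(self):
        imap = self._bump_map()
        with pytest.warns(UserWarning, match="whole sphere"):
            functional_centre(imap, 1e9, radius_coeff=1.0)


class TestRegressMetrics:
    def test_exact_linear_relation(self):
        x = np.arange(10, 30, dtype=float)
        out = regress_metrics(x, 2 * x)
        assert out["r_squared"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(2.0)
        assert out["p_value"] < 1e-12

    def test_type_one_error_calibration_of_f_test(self):
        hits = 0
        reps = 1000
        for seed in range(reps):
            r = np.random.default_rng(seed)
            x = r.normal(size=40)
            y = r.normal(size=40)
            hits += regress_metrics(x, y)["significant_5pct"]
        assert 0.035 <= hits / reps <= 0.065

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            regress_metrics(np.ones(10), np.arange(10.0))


class TestMirrorSymmetry:
    def test_negated_poe_preserves_measures_and_negates_centre(self):
        rng = np.random.default_rng(5)
        poses = [
            Pose(float(p), float(a), float(x))
            for p, a, x in zip(
                rng.uniform(-170, 170, 400).round(0),
                rng.uniform(10, 170, 400).round(0),
                rng.uniform(-180, 180, 400).round(0),
            )
        ]
        mirrored = [Pose(-p.plane_of_elevation, p.abduction, p.axial) for p in poses]
        assert mobility(mirrored, 25.0) == pytest.approx(mobility(poses, 25.0), rel=1e-9)
        assert circumduction_envelope(mirrored, 25.0) == pytest.approx(
            circumduction_envelope(poses, 25.0), rel=1e-9
        )
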