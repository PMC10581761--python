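"""Procrustes superimposition, shape-space PCA and discrete measures."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from promorom.morphometrics import (
    LandmarkSet,
    centroid_size,
    concatenate_blocks,
    discrete_measures,
    pca,
    procrustes_block,
    procrustes_distance,
    regress_on_components,
)
from promorom.synthetic_fixtures import JointSpec, make_joint


def _random_config(rng, k=22):
    return rng.normal(size=(k, 3)) * 10


class TestProcrustes:
    def test_rigid_and_scale_invariance(self, rng):
        base = _random_config(rng)
        R = Rotation.random(random_state=0).as_matrix()
        moved = 3.0 * base @ R.T + np.array([5.0, 1.0, -2.0])
        assert procrustes_distance(base, moved) < 1e-9

    def test_reflection_not_removed(self, rng):
        base = _random_config(rng)
        mirrored = base @ np.diag([1.0, 1.0, -1.0])
        assert procrustes_distance(base, mirrored) > 1e-3

    def test_gpa_mean_recovery_under_noise(self):
        truth = _random_config(np.random.default_rng(42))
        truth = truth - truth.mean(axis=0)
        sigma = 0.5
        per_coord_errors = []
        for rep in range(100):
            rng = np.random.default_rng(rep)
            sets = [
                LandmarkSet(f"s{i}", "scapula", truth + rng.normal(0, sigma, truth.shape))
                for i in range(10)
            ]
            aligned, _, _ = procrustes_block(sets)
            mean = aligned.mean(axis=0)
            ref = truth - truth.mean(axis=0)
            ref = ref / np.sqrt((ref**2).sum())
            # align estimated mean to the normalized truth before comparing
            d = procrustes_distance(mean, ref)
            per_coord_errors.append(d / np.sqrt(truth.size))
        # consistency: error shrinks like sigma / (cs * sqrt(n))
        cs = np.sqrt((truth**2).sum())
        assert np.mean(per_coord_errors) < sigma / (cs / np.sqrt(truth.size)) / np.sqrt(10)

    def test_mixed_blocks_rejected(self, rng):
        a = LandmarkSet("a", "scapula", _random_config(rng, 22))
        b = LandmarkSet("b", "humerus", _random_config(rng, 25))
        with pytest.raises(ValueError, match="mixed"):
            procrustes_block([a, b])

    def test_block_size_contract(self, rng):
        with pytest.raises(ValueError, match="22"):
            LandmarkSet("a", "scapula", _random_config(rng, 21))


class TestShapeSpace:
    def _cohort(self, n=18, seed=0):
        rng = np.random.default_rng(seed)
        sc_truth = _random_config(rng, 22)
        hu_truth = _random_config(rng, 25)
        sc = [
            LandmarkSet(f"s{i}", "scapula", sc_truth + rng.normal(0, 0.5, (22, 3)))
            for i in range(n)
        ]
        hu = [
            LandmarkSet(f"s{i}", "humerus", hu_truth + rng.normal(0, 0.5, (25, 3)))
            for i in range(n)
        ]
        return sc, hu

    def test_concatenated_matrix_dimensions(self):
        sc, hu = self._cohort()
        space = concatenate_blocks(procrustes_block(sc), procrustes_block(hu))
        assert space.matrix.shape == (18, 141)
        assert len(space.column_map) == 141

    def test_column_map_round_trip(self):
        sc, hu = self._cohort()
        space = concatenate_blocks(procrustes_block(sc), procrustes_block(hu))
        for col in (0, 65, 66, 140):
            block, lm, ax = space.column_map[col]
            offset = 0 if block == "scapula" else 66
            assert offset + lm * 3 + ax == col

    def test_roster_mismatch_rejected(self):
        sc, hu = self._cohort()
        hu = hu[::-1]
        with pytest.raises(ValueError, match="roster"):
            concatenate_blocks(procrustes_block(sc), procrustes_block(hu))

    def test_pca_variance_fractions_and_reconstruction(self):
        sc, hu = self._cohort()
        space = pca(concatenate_blocks(procrustes_block(sc), procrustes_block(hu)))
        assert space.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)
        recon = space.mean_shape + space.scores @ space.components
        assert np.abs(recon - space.matrix).max() < 1e-9
        cov = np.cov(space.scores[:, :5], rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-9

    def test_pca_of_exact_line_concentrates_variance(self):
        t = np.linspace(-1, 1, 10)
        X = np.outer(t, np.array([1.0, 2.0, -1.0, 0.5]))
        space = pca(X)
        assert space.variance_fractions[0] == pytest.approx(1.0, abs=1e-12)

    def test_planted_two_factor_variances_recovered(self):
        # two orthogonal deformation directions with variance ratio 4:1
        fracs = np.zeros((100, 2))
        for rep in range(100):
            rng = np.random.default_rng(rep)
            d1 = rng.normal(size=30)
            d1 /= np.linalg.norm(d1)
            d2 = rng.normal(size=30)
            d2 -= (d2 @ d1) * d1
            d2 /= np.linalg.norm(d2)
            scores = rng.normal(size=(40, 2)) * [2.0, 1.0]
            X = scores[:, :1] * d1 + scores[:, 1:] * d2
            space = pca(X)
            fracs[rep] = space.variance_fractions[:2]
        assert np.abs(fracs.mean(axis=0) - [0.8, 0.2]).max() < 0.05

    def test_scores_stable_under_specimen_reordering(self):
        sc, hu = self._cohort()
        space = pca(concatenate_blocks(procrustes_block(sc), procrustes_block(hu)))
        perm = np.random.default_rng(1).permutation(18)
        sc_p = [sc[i] for i in perm]
        hu_p = [hu[i] for i in perm]
        space_p = pca(concatenate_blocks(procrustes_block(sc_p), procrustes_block(hu_p)))
        assert np.allclose(space_p.scores, space.scores[perm], atol=1e-6)


@pytest.fixture(scope="module")
def joint():
    return make_joint(JointSpec(tubercle_height=2.0))


@pytest.fixture(scope="module")
def measures(joint):
    return discrete_measures(
        joint.scapula_landmarks, joint.humerus_landmarks,
        joint.scapula, joint.humerus,
    )


class TestDiscreteMeasures:
    def test_all_twelve_measures_present(self, measures):
        assert len(measures) == 12
        assert all(np.isfinite(v) for v in measures.values())

    def test_humeral_patch_area_matches_analytic_cap(self):
        # without tubercle exclusions the patch is a spherical cap
        joint = make_joint(JointSpec())
        spec = joint.spec
        analytic = 2 * np.pi * spec.head_radius**2 * (
            1 - np.cos(np.radians(spec.head_patch_angle))
        )
        measured = joint.humerus.face_areas(
            joint.humerus.labels["head_articular"]
        ).sum()
        assert measured == pytest.approx(analytic, rel=0.02)

    def test_area_ratio_matches_independent_area_computation(self, joint, measures):
        import trimesh

        def region_area(mesh, label):
            tm = trimesh.Trimesh(mesh.vertices, mesh.faces[mesh.labels[label]],
                                 process=False)
            return tm.area

        expected = region_area(joint.humerus, "head_articular") / region_area(
            joint.scapula, "glenoid_face"
        )
        assert measures["articular_surface_area_ratio"] == pytest.approx(
            expected, rel=1e-9
        )
        assert measures["articular_surface_area_ratio"] > 1.0

    def test_sphericity_one_for_sphere_and_lower_when_flattened(self):
        round_joint = make_joint(JointSpec())
        flat_joint = make_joint(JointSpec(head_flattening=0.5))
        m_round = discrete_measures(
            round_joint.scapula_landmarks, round_joint.humerus_landmarks,
            round_joint.scapula, round_joint.humerus,
        )
        m_flat = discrete_measures(
            flat_joint.scapula_landmarks, flat_joint.humerus_landmarks,
            flat_joint.scapula, flat_joint.humerus,
        )
        assert m_round["sphericity"] == pytest.approx(1.0, abs=1e-3)
        assert m_flat["sphericity"] < m_round["sphericity"] - 0.01

    def test_cranial_angle_tracks_glenoid_tilt(self):
        m0 = make_joint(JointSpec())
        m1 = make_joint(JointSpec(glenoid_cranial_tilt=20.0))
        a0 = discrete_measures(
            m0.scapula_landmarks, m0.humerus_landmarks, m0.scapula, m0.humerus
        )["cranial_angle"]
        a1 = discrete_measures(
            m1.scapula_landmarks, m1.humerus_landmarks, m1.scapula, m1.humerus
        )["cranial_angle"]
        assert a1 - a0 == pytest.approx(20.0, abs=2.0)

    def test_uniform_scaling_leaves_measures_unchanged(self, joint, measures):
        s = 2.0
        sc = joint.scapula_landmarks.copy()
        hu = joint.humerus_landmarks.copy()
        sc[["x", "y", "z"]] *= s
        hu[["x", "y", "z"]] *= s
        from promorom.mesh_fields import TriangleMesh

        scm = TriangleMesh(
            joint.scapula.vertices * s, joint.scapula.faces, dict(joint.scapula.labels)
        )
        hum = TriangleMesh(
            joint.humerus.vertices * s, joint.humerus.faces, dict(joint.humerus.labels)
        )
        scaled = discrete_measures(sc, hu, scm, hum)
        for key, val in measures.items():
            assert scaled[key] == pytest.approx(val, rel=1e-9), key

    def test_missing_landmark_degrades_gracefully(self, joint):
        broken = joint.scapula_landmarks[
            joint.scapula_landmarks.name != "acromion"
        ].reset_index(drop=True)
        with pytest.warns(UserWarning, match="critical_shoulder_angle"):
            out = discrete_measures(
                broken, joint.humerus_landmarks, joint.scapula, joint.humerus
            )
        assert np.isnan(out["critical_shoulder_angle"])
        assert np.isfinite(out["glenoid_surface_area"])


class TestRegressOnComponents:
    def test_metric_equal_to_predictor_gives_perfect_fit(self):
        x = np.linspace(0, 1, 20)
        table = regress_on_components(x, pd.DataFrame({"p": x}))
        assert table.iloc[0].r_squared == pytest.approx(1.0)
        assert table.iloc[0].direction == "↑"

    def test_shuffled_labels_calibrate_to_nominal_rate(self):
        hits, total = 0, 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=18)
            y = rng.permutation(x) + rng.normal(size=18)
            table = regress_on_components(y, pd.DataFrame({"p": x}))
            hits += int(table.iloc[0].significant)
            total += 1
        assert 0.005 <= hits / total <= 0.11

    def test_zero_variance_predictor_skipped(self):
        with pytest.warns(UserWarning, match="skipped"):
            table = regress_on_components(
                np.arange(10.0),
                pd.DataFrame({"flat": np.ones(10), "ok": np.arange(10.0)}),
            )
        assert list(table.predictor) == ["ok"]
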