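"""Synthetic cohorts: inverse-geometry realizer, noise and pose model."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from cephalomorph import (
    CLUSTER_PROPORTION_MEANS,
    SEX_PROPORTION_MEANS,
    CohortSpec,
    GroupSpec,
    Shape,
    generate_cohort,
    generate_toy_mesh,
    measure_proportions,
    morph_template,
    realize_proportions,
    realized_proportion_targets,
)
from cephalomorph.landmarks import PROPORTION_CODES
from cephalomorph.synthetic import RealizationError


def random_realizable_targets(rng):
    """Target vectors inside the anatomical realizability envelope."""
    return {
        "P01": rng.uniform(0.95, 1.25), "P02": rng.uniform(1.7, 2.3),
        "P03": rng.uniform(0.95, 1.2), "P04": rng.uniform(0.88, 1.08),
        "P05": rng.uniform(4.4, 5.8), "P06": rng.uniform(1.65, 2.05),
        "P07": rng.uniform(1.5, 2.0), "P08": rng.uniform(1.6, 1.9),
    }


class TestRealizeProportions:
    def test_all_ones_isotropic_scaffold(self):
        lm = realize_proportions({c: 1.0 for c in PROPORTION_CODES}, base_scale_mm=100.0)
        np.testing.assert_allclose(measure_proportions(lm).as_array(), 1.0, atol=1e-9)

    def test_reference_male_calibration_measures_back_exactly(self):
        lm = realize_proportions(SEX_PROPORTION_MEANS["male"])
        p = measure_proportions(lm)
        assert p.P02 == pytest.approx(2.008, abs=1e-12)
        assert p.P01 == pytest.approx(1.115, abs=1e-12)
        assert p.P05 == pytest.approx(5.293, abs=1e-12)

    def test_measured_equals_target_on_random_realizable_vectors(self, rng):
        """Forward-measurement oracle over 100 random target vectors:
        P01-P06 exact; P07/P08 equal their geometrically-forced values."""
        for _ in range(100):
            targets = random_realizable_targets(rng)
            lm = realize_proportions(targets)
            measured = measure_proportions(lm).as_dict()
            expected = realized_proportion_targets(targets).as_dict()
            for code in PROPORTION_CODES:
                assert measured[code] == pytest.approx(expected[code], abs=1e-9)

    def test_forced_p07_p08_identities(self, rng):
        t = random_realizable_targets(rng)
        realized = realized_proportion_targets(t)
        assert realized.P07 == pytest.approx(t["P01"] / t["P04"], rel=1e-12)
        assert realized.P08 == pytest.approx(t["P02"] / t["P01"], rel=1e-12)

    def test_base_scale_sets_fronto_orbital_width(self, rng):
        from cephalomorph import compute_distances

        lm = realize_proportions(random_realizable_targets(rng), base_scale_mm=87.5)
        assert compute_distances(lm).H1 == pytest.approx(87.5, abs=1e-9)

    def test_unrealizable_geometry_raises(self):
        bad = {c: 1.0 for c in PROPORTION_CODES}
        bad["P06"] = 30.0  # Z1 far too short to reach the condyle
        with pytest.raises(RealizationError, match="unrealizable|V4|Z1"):
            realize_proportions(bad)
        with pytest.raises(RealizationError, match="positive"):
            realize_proportions(dict(bad, P02=-1.0))


class TestGenerateCohort:
    def test_zero_noise_canonical_specimens_are_identical(self):
        spec = CohortSpec(
            groups=(
                GroupSpec(label="g", n=5, proportion_targets=SEX_PROPORTION_MEANS["female"],
                          sex="female", noise_sd_mm=0.0, pose="canonical"),
            ),
            seed=11,
        )
        cohort = generate_cohort(spec)
        assert len(cohort.specimens) == 5
        for s in cohort.specimens[1:]:
            np.testing.assert_array_equal(s.points, cohort.specimens[0].points)

    def test_seed_determinism_and_divergence(self):
        spec = lambda seed: CohortSpec(  # noqa: E731
            groups=(
                GroupSpec(label="g", n=4, proportion_targets=SEX_PROPORTION_MEANS["male"],
                          sex="male", noise_sd_mm=0.5, pose="random_similarity"),
            ),
            seed=seed,
        )
        c1, c2 = generate_cohort(spec(3)), generate_cohort(spec(3))
        for a, b in zip(c1.specimens, c2.specimens):
            np.testing.assert_array_equal(a.points, b.points)
        c3 = generate_cohort(spec(4))
        assert not np.array_equal(c1.specimens[0].points, c3.specimens[0].points)

    def test_pose_invariance_of_proportion_statistics(self):
        """At zero noise, random-similarity posing leaves every measured
        proportion untouched (ratios are similarity invariants)."""
        for pose in ("canonical", "random_similarity"):
            spec = CohortSpec(
                groups=(
                    GroupSpec(label="g", n=8, proportion_targets=SEX_PROPORTION_MEANS["male"],
                              sex="male", noise_sd_mm=0.0, pose=pose),
                ),
                seed=5,
            )
            cohort = generate_cohort(spec)
            P = np.stack([measure_proportions(s).as_array() for s in cohort.specimens])
            expected = realized_proportion_targets(SEX_PROPORTION_MEANS["male"]).as_array()
            np.testing.assert_allclose(P - expected[None, :], 0.0, atol=1e-9)

    def test_proportion_scatter_grows_with_noise(self):
        sds = []
        for noise in (0.0, 0.1, 0.5, 1.0):
            spec = CohortSpec(
                groups=(
                    GroupSpec(label="g", n=60, proportion_targets=SEX_PROPORTION_MEANS["male"],
                              sex="male", noise_sd_mm=noise, pose="canonical"),
                ),
                seed=9,
            )
            cohort = generate_cohort(spec)
            P = np.stack([measure_proportions(s).as_array() for s in cohort.specimens])
            sds.append(P.std(axis=0, ddof=1).mean())
        assert sds[0] <= 1e-12  # summation round-off floor on identical specimens
        assert np.all(np.diff(sds) > 0)

    def test_group_bookkeeping(self):
        spec = CohortSpec(
            groups=(
                GroupSpec(label="m1", n=3, proportion_targets=CLUSTER_PROPORTION_MEANS["male"]["m1"],
                          sex="male", true_cluster=0),
                GroupSpec(label="m2", n=2, proportion_targets=CLUSTER_PROPORTION_MEANS["male"]["m2"],
                          sex="male", true_cluster=1),
            ),
            seed=0,
        )
        cohort = generate_cohort(spec)
        assert cohort.group_labels == ["m1"] * 3 + ["m2"] * 2
        assert cohort.true_clusters == [0, 0, 0, 1, 1]
        assert all(s.sex == "male" for s in cohort.specimens)


class TestToyMesh:
    def test_cube_corner_hull_face_count(self):
        """On a landmark cloud whose hull is a cube the toy mesh matches the
        ConvexHull oracle's simplex count."""
        corners = np.array(
            [[x, y, z] for x in (0, 100.0) for y in (0, 100.0) for z in (0, 100.0)]
        )
        rng = np.random.default_rng(1)
        interior = rng.uniform(20, 80, size=(10, 3))
        pts = np.vstack([corners, interior])
        from cephalomorph import LANDMARK_NAMES, validate_landmark_set

        lm = validate_landmark_set(
            {name: pts[i] for i, name in enumerate(LANDMARK_NAMES)}
        )
        mesh = generate_toy_mesh(lm, subdivisions=0)
        oracle = ConvexHull(pts)
        assert len(mesh.faces) == len(oracle.simplices)

    def test_mesh_bounds_contain_all_landmarks(self, male_scaffold):
        mesh = generate_toy_mesh(male_scaffold, subdivisions=0)
        lo, hi = mesh.vertices.min(axis=0), mesh.vertices.max(axis=0)
        assert np.all(male_scaffold.points >= lo - 1e-9)
        assert np.all(male_scaffold.points <= hi + 1e-9)

    def test_identity_morph_fixture(self, male_scaffold):
        mesh = generate_toy_mesh(male_scaffold, subdivisions=1)
        out = morph_template(mesh, target_mean=Shape(male_scaffold.points))
        np.testing.assert_allclose(out.vertices, mesh.vertices, atol=1e-8)
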