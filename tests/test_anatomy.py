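"""Synthetic population sampling and parametric anatomy construction."""

import numpy as np
import pytest

from hipsnap.anatomy import (
    PARAMETER_BOUNDS,
    PARAMETER_FIELDS,
    AnatomicalParameters,
    ConfigurationError,
    ConstructionError,
    LandmarkSet,
    PopulationConfig,
    build_anatomy,
    sample_parameter_table,
    sample_parameters,
)


class TestSampling:
    def test_seeded_determinism(self):
        a = sample_parameters("male", 1, seed=7)
        b = sample_parameters("male", 1, seed=7)
        np.testing.assert_array_equal(a[0].as_array(), b[0].as_array())

    def test_draws_respect_validity_bounds(self):
        table = sample_parameter_table("female", 5000, seed=3)
        for j, name in enumerate(PARAMETER_FIELDS):
            lo, hi = PARAMETER_BOUNDS[name]
            assert table[:, j].min() > lo and table[:, j].max() < hi

    @pytest.mark.parametrize("sex", ["male", "female"])
    def test_calibration_to_configured_moments(self, sex, default_config):
        """Empirical mean/SD of every measure matches config within 3 SE."""
        n = 20000
        table = sample_parameter_table(sex, n, seed=11, config=default_config)
        mean, sd = default_config.mean_sd(sex)
        se = sd / np.sqrt(n)
        assert (np.abs(table.mean(axis=0) - mean) < 3 * se).all()
        sd_emp = table.std(axis=0, ddof=1)
        assert (np.abs(sd_emp - sd) / sd < 0.03).all()

    def test_correlated_sampling(self):
        C = np.eye(5)
        C[0, 1] = C[1, 0] = 0.8
        cfg = PopulationConfig(correlation=C)
        table = sample_parameter_table("male", 20000, seed=5, config=cfg)
        r = np.corrcoef(table[:, 0], table[:, 1])[0, 1]
        assert abs(r - 0.8) < 0.03

    def test_invalid_correlation_matrix_rejected(self):
        C = np.eye(5)
        C[0, 1] = C[1, 0] = 1.5  # not PSD
        with pytest.raises(ConfigurationError):
            PopulationConfig(correlation=C)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            sample_parameters("male", 0, seed=1)


class TestConstruction:
    def test_deterministic_build(self, male_params, default_config):
        a = build_anatomy(male_params, default_config)
        b = build_anatomy(male_params, default_config)
        np.testing.assert_array_equal(a.landmarks.points, b.landmarks.points)
        for k in a.femur_components:
            np.testing.assert_array_equal(
                a.component_mesh(k).vertices, b.component_mesh(k).vertices
            )

    def test_landmark_template_size_and_labels(self, male_anatomy, default_config):
        assert len(male_anatomy.landmarks.points) == default_config.n_landmarks
        assert set(male_anatomy.landmarks.labels) == {
            "head_surface",
            "neck_axis",
            "shaft_axis",
            "lesser_trochanter",
            "greater_trochanter",
            "acetabulum",
            "iliopectineal_ridge",
            "ischium",
            "psoas_origin",
            "psoas_insertion",
            "condylar_axis",
        }

    def test_correspondence_across_instances(self, default_config):
        """Landmark index k carries the same label on every instance."""
        params = sample_parameters("female", 3, seed=2)
        instances = [build_anatomy(p, default_config) for p in params]
        labels = [a.landmarks.labels for a in instances]
        assert labels[0] == labels[1] == labels[2]

    def test_meshes_watertight_per_component(self, male_anatomy):
        for name in male_anatomy.femur_components:
            assert male_anatomy.component_mesh(name).is_watertight, name
        for name in ("ischium", "iliopectineal_ridge"):
            assert male_anatomy.component_mesh(name).is_watertight, name

    def test_psoas_attachments_on_bone(self, male_anatomy):
        origin_d = min(
            abs(c.signed_distance(male_anatomy.psoas_origin[None])[0])
            for c in male_anatomy.pelvis_components.values()
        )
        lt = male_anatomy.femur_components["lesser_trochanter"]
        ins_d = abs(lt.signed_distance(male_anatomy.psoas_insertion[None])[0])
        assert origin_d < 3.0  # on/near the pelvic brim surface
        assert ins_d < 1e-6  # exactly on the lesser trochanter surface

    def test_geometric_couplings_move_lesser_trochanter_medially(self, default_config):
        """Anteversion up / offset down move the LT tip medially (+y-ish)."""
        stats = default_config.statistics["male"]
        base = {k: v[0] for k, v in stats.items()}

        def lt_tip(**over):
            p = AnatomicalParameters(**{**base, **over}, sex="male")
            return build_anatomy(p, default_config).femur_components["lesser_trochanter"].b

        ref = lt_tip()
        more_av = lt_tip(anteversion=base["anteversion"] + 10)
        less_off = lt_tip(femoral_offset=base["femoral_offset"] - 10)
        less_ifd = lt_tip(ischiofemoral_distance=base["ischiofemoral_distance"] - 6)
        assert more_av[1] > ref[1]
        # reduced offset / reduced gap leave the tip no less medially reaching
        assert np.linalg.norm(less_off[:2]) >= np.linalg.norm(ref[:2]) - 1e-9
        assert np.linalg.norm(less_ifd[:2]) > np.linalg.norm(ref[:2])

    def test_infeasible_parameters_raise(self):
        with pytest.raises(ConstructionError):
            build_anatomy(
                AnatomicalParameters(179.5, 10, 44, 29, 25, sex="male")
            )  # offset unreachable at that neck angle
        with pytest.raises(ConstructionError):
            AnatomicalParameters(125, 10, -5, 29, 25).validate()

    def test_rigid_transform_carries_everything(self, male_anatomy):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
        t = np.array([5.0, -3.0, 8.0])
        moved = male_anatomy.transformed(R, t)
        np.testing.assert_allclose(
            moved.landmarks.points, male_anatomy.landmarks.points @ R.T + t
        )
        np.testing.assert_allclose(moved.head_center, R @ male_anatomy.head_center + t)


class TestIO:
    def test_population_config_yaml_round_trip(self, tmp_path, default_config):
        path = tmp_path / "pop.yaml"
        default_config.to_yaml(path)
        loaded = PopulationConfig.from_yaml(path)
        assert loaded.statistics == default_config.statistics
        assert loaded.n_landmarks == default_config.n_landmarks

    def test_landmark_csv_round_trip(self, tmp_path, male_anatomy):
        path = tmp_path / "lms.csv"
        male_anatomy.landmarks.to_csv(path)
        loaded = LandmarkSet.from_csv(path)
        assert loaded.labels == male_anatomy.landmarks.labels
        np.testing.assert_allclose(loaded.points, male_anatomy.landmarks.points, atol=1e-5)

    def test_export_writes_meshes_and_landmarks(self, tmp_path, male_anatomy):
        male_anatomy.export(tmp_path, stem="case")
        for suffix in (
            "case_femur.ply",
            "case_femur.obj",
            "case_pelvis.ply",
            "case_pelvis.obj",
            "case_landmarks.csv",
            "case_landmarks.json",
        ):
            assert (tmp_path / suffix).exists()
        import trimesh

        mesh = trimesh.load(tmp_path / "case_femur.ply")
        assert len(mesh.vertices) > 100
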