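import numpy as np
import pytest

from ecostab.persistence import compute_persistence, select_ecological_classes
from ecostab.sampling import combine_labels
from ecostab.synth import (
    SceneConfig,
    generate_covariates,
    generate_scene,
    load_scene,
    write_scene,
)


class TestGenerateCovariates:
    def test_deterministic_in_seed(self):
        a = generate_covariates((20, 20), 3, smoothness=2.0, seed=9)
        b = generate_covariates((20, 20), 3, smoothness=2.0, seed=9)
        for la, lb in zip(a.layers, b.layers):
            np.testing.assert_array_equal(la.values, lb.values)
        c = generate_covariates((20, 20), 3, smoothness=2.0, seed=10)
        assert not np.array_equal(a.layers[0].values, c.layers[0].values)

    def test_scaled_exactly_to_stated_range(self):
        stack = generate_covariates((15, 15), 2, 1.5, seed=0, ranges=[(-5.0, 7.0), (0.0, 1.0)])
        assert stack.layers[0].values.min() == -5.0
        assert stack.layers[0].values.max() == 7.0
        assert stack.layers[1].values.min() == 0.0
        assert stack.layers[1].values.max() == 1.0

    def test_zero_smoothness_is_spatially_uncorrelated(self):
        stack = generate_covariates((100, 100), 1, smoothness=0.0, seed=1)
        v = stack.layers[0].values
        r = np.corrcoef(v[:, :-1].ravel(), v[:, 1:].ravel())[0, 1]
        assert abs(r) < 0.03

    def test_positive_smoothness_autocorrelates(self):
        stack = generate_covariates((100, 100), 1, smoothness=5.0, seed=1)
        v = stack.layers[0].values
        r = np.corrcoef(v[:, :-1].ravel(), v[:, 1:].ravel())[0, 1]
        assert r > 0.8

    def test_tiny_scene_rejected(self):
        with pytest.raises(ValueError, match="10x10"):
            generate_covariates((5, 5), 1, 1.0, seed=0)


class TestGenerateScene:
    def test_reproducible_from_config_and_seed(self):
        a = generate_scene(SceneConfig(shape=(30, 30)), seed=5)
        b = generate_scene(SceneConfig(shape=(30, 30)), seed=5)
        np.testing.assert_array_equal(a.labels.values, b.labels.values)
        np.testing.assert_array_equal(a.true_pi.values, b.true_pi.values)
        for y in a.years:
            np.testing.assert_array_equal(
                a.lulc_by_year[y].values, b.lulc_by_year[y].values
            )

    def test_high_intercept_makes_almost_everything_steady(self):
        # beta0 = +10: Bernoulli mean e^10/(1+e^10) = 0.99995
        cfg = SceneConfig(
            shape=(100, 100),
            true_beta={name: (10.0, {}) for name in ("forest", "grassland_sparse",
                                                     "grassland_high", "wetland")},
        )
        scene = generate_scene(cfg, seed=2)
        lab = scene.labels.values
        eco = lab >= 0
        assert eco.sum() >= 5000
        assert lab[eco].mean() > 0.999

    def test_zero_model_gives_fair_coin(self):
        cfg = SceneConfig(
            shape=(100, 100),
            true_beta={name: (0.0, {}) for name in ("forest", "grassland_sparse",
                                                    "grassland_high", "wetland")},
        )
        scene = generate_scene(cfg, seed=3)
        lab = scene.labels.values
        eco = lab >= 0
        n = eco.sum()
        assert abs(lab[eco].mean() - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_persistence_recovers_realized_labels_exactly(self):
        scene = generate_scene(SceneConfig(shape=(40, 40)), seed=4)
        codes = select_ecological_classes(scene.config.legend)
        masks = [compute_persistence(scene.lulc_stack(), c) for c in codes]
        recovered = combine_labels(masks).values
        np.testing.assert_array_equal(recovered, scene.labels.values)

    def test_steady_fraction_matches_mean_true_pi(self):
        scene = generate_scene(SceneConfig(shape=(80, 80)), seed=6)
        lab = scene.labels.values
        eco = lab >= 0
        n = eco.sum()
        mean_pi = np.nanmean(scene.true_pi.values[eco])
        mc_sd = np.sqrt(mean_pi * (1 - mean_pi) / n)
        assert abs(lab[eco].mean() - mean_pi) < 2.576 * mc_sd  # 99% MC interval

    def test_unsteady_pixels_change_exactly_once(self):
        scene = generate_scene(SceneConfig(shape=(30, 30)), seed=7)
        cube = np.stack([scene.lulc_by_year[y].values for y in scene.years])
        lab = scene.labels.values
        changes = (np.diff(cube, axis=0) != 0).sum(axis=0)
        assert (changes[lab == 0] == 1).all()
        assert (changes[lab == 1] == 0).all()

    def test_evi_tracks_true_pi(self):
        scene = generate_scene(SceneConfig(shape=(60, 60)), seed=8)
        eco = scene.labels.values >= 0
        r = np.corrcoef(scene.true_pi.values[eco], scene.evi_mean.values[eco])[0, 1]
        assert r > 0.5

    def test_reserve_sits_on_high_probability_block(self):
        from ecostab.validation import rasterize_reserves

        scene = generate_scene(SceneConfig(shape=(60, 60)), seed=9)
        mask = rasterize_reserves(scene.reserves, scene.true_pi)
        eco = scene.labels.values >= 0
        inside = np.nanmean(scene.true_pi.values[eco & (mask.values == 1)])
        outside = np.nanmean(scene.true_pi.values[eco & (mask.values == 0)])
        assert inside > outside

    def test_unknown_factor_in_beta_rejected(self):
        cfg = SceneConfig(true_beta={"forest": (0.0, {"X99": 1.0}),
                                     "grassland_sparse": (0.0, {}),
                                     "grassland_high": (0.0, {}),
                                     "wetland": (0.0, {})})
        with pytest.raises(ValueError, match="unknown factors"):
            generate_scene(cfg, seed=0)


class TestSceneIO:
    def test_write_then_load_roundtrips(self, tmp_path, demo_scene):
        d = write_scene(demo_scene, tmp_path / "scene")
        data = load_scene(d)
        assert data["years"] == list(demo_scene.config.years)
        assert data["legend"] == demo_scene.config.legend
        np.testing.assert_array_equal(
            data["lulc"].layers[0].values, demo_scene.lulc_by_year[2000].values
        )
        # float layers survive within float32 storage precision
        got = data["factors_by_year"][2000].layers[0].values
        want = demo_scene.factors_by_year[2000].layers[0].values
        assert np.max(np.abs(got - want)) < 1e-4 * (want.max() - want.min())
        assert (tmp_path / "scene" / "reserves.geojson").exists()
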