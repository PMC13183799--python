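"""Scene synthesis: illuminants, competitor geometry, rendering, cue silencing."""

from dataclasses import replace

import numpy as np
import pytest

from constancy import colorspace as cs
from constancy import scenes as sc


class TestIlluminantSet:
    def test_zero_offset_degenerates_to_neutral(self):
        ills = sc.make_illuminant_set(axis_offset=0.0)
        for spec in ills.values():
            assert np.allclose(spec.gain, ills["neutral"].gain)

    def test_neutral_is_centroid(self, illuminants):
        gains = np.stack([illuminants[n].gain
                          for n in ("blue", "yellow", "red", "green")])
        assert np.allclose(gains.mean(axis=0), illuminants["neutral"].gain)

    def test_pairs_average_to_neutral(self, illuminants):
        gn = illuminants["neutral"].gain
        assert np.allclose((illuminants["blue"].gain + illuminants["yellow"].gain) / 2, gn)
        assert np.allclose((illuminants["red"].gain + illuminants["green"].gain) / 2, gn)

    def test_excessive_offset_rejected(self):
        with pytest.raises(ValueError):
            sc.make_illuminant_set(axis_offset=200.0)

    def test_axis_tags(self, illuminants):
        assert illuminants["blue"].axis == illuminants["yellow"].axis == "daylight"
        assert illuminants["red"].axis == illuminants["green"].axis == "orthogonal"


class TestCompetitorSet:
    def test_neutral_illuminant_degenerate(self, illuminants, neutral):
        comp = sc.make_competitor_set(0.35, neutral, neutral)
        assert comp.degenerate
        assert np.allclose(comp.labs["R"], comp.labs["T"])

    def test_equal_spacing_and_collinearity(self, illuminants, neutral):
        for name in ("blue", "yellow", "red", "green"):
            comp = sc.make_competitor_set(0.35, illuminants[name], neutral)
            labs = comp.labs
            steps = [labs["R"] - labs["S2"], labs["S2"] - labs["S1"],
                     labs["S1"] - labs["T"], labs["O"] - labs["R"]]
            for s in steps[1:]:
                assert np.abs(s - steps[0]).max() < 1e-9

    def test_tristimulus_match_light(self, illuminants, neutral):
        # T's rendered light under the test illuminant equals the target's
        # light under neutral, channel by channel.
        illum = illuminants["yellow"]
        comp = sc.make_competitor_set(0.35, illum, neutral)
        lhs = comp.reflectances["T"] * illum.gain
        rhs = comp.target_reflectance * neutral.gain
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_chromatic_target_rejected(self, illuminants, neutral):
        with pytest.raises(ValueError):
            sc.make_competitor_set([0.3, 0.4, 0.3], illuminants["blue"], neutral)


class TestRender:
    def test_unit_gain_identity(self):
        unit = sc.IlluminantSpec("unit", np.ones(3), "none")
        spec = sc.make_scene_spec(seed=1, with_white_patch=False)
        scene = sc.render(spec, unit, unit)
        assert np.array_equal(scene.rgb, scene.reflectance)

    def test_linearity_in_gain(self, neutral):
        spec = sc.make_scene_spec(seed=2)
        half = sc.IlluminantSpec("half", neutral.gain / 2, "none")
        s1 = sc.render(spec, neutral, neutral)
        s2 = sc.render(spec, half, neutral)
        assert np.allclose(s1.rgb, 2 * s2.rgb)

    def test_scene_mean_matches_brute_force(self, illuminants, neutral):
        spec = sc.make_scene_spec(seed=3)
        scene = sc.render(spec, illuminants["red"], neutral)
        expected = (scene.reflectance * illuminants["red"].gain).mean(axis=(0, 1))
        assert np.allclose(scene.rgb.mean(axis=(0, 1)), expected)

    def test_mask_reflectance_matches_assignment(self, illuminants, neutral,
                                                 competitors_blue):
        spec = sc.make_scene_spec(seed=4)
        spec = replace(spec, target_entries=[(2, competitors_blue.reflectances["S1"], 7)])
        scene = sc.render(spec, illuminants["blue"], neutral)
        assert (scene.mask == 7).sum() > 0
        assert np.allclose(scene.reflectance[scene.mask == 7],
                           competitors_blue.reflectances["S1"])


class TestManipulations:
    def test_baseline_is_noop(self, illuminants, neutral):
        spec = sc.make_scene_spec(seed=5)
        scene = sc.render(spec, illuminants["green"], neutral)
        out = sc.apply_manipulation(scene, "baseline", illuminants["green"], neutral)
        assert out is scene

    def test_unknown_mechanism_rejected(self, illuminants, neutral):
        spec = sc.make_scene_spec(seed=5)
        scene = sc.render(spec, illuminants["green"], neutral)
        with pytest.raises(ValueError):
            sc.apply_manipulation(scene, "nope", illuminants["green"], neutral)

    def test_local_surround_constant_across_illuminants(self, illuminants, neutral):
        surround = sc.make_surround_color_set(illuminants)["rose"]
        spec = sc.make_scene_spec(seed=6, mechanism="local_surround",
                                  surround_reflectance=surround)
        s_blue = sc.render(spec, illuminants["blue"], neutral)
        s_red = sc.render(spec, illuminants["red"], neutral)
        leaf = s_blue.roles == sc.ROLE_LEAF
        assert leaf.sum() > 0
        assert np.allclose(s_blue.rgb[leaf], s_red.rgb[leaf])

    def test_maximum_flux_patch_achromatic_and_selective(self, illuminants, neutral):
        spec = sc.make_scene_spec(seed=7, mechanism="maximum_flux")
        base = sc.render(replace(spec, mechanism="baseline"), illuminants["blue"], neutral)
        manip = sc.render(spec, illuminants["blue"], neutral)
        wp = manip.roles == sc.ROLE_WHITE_PATCH
        px = manip.rgb[wp]
        assert np.allclose(px[:, 0], px[:, 1]) and np.allclose(px[:, 1], px[:, 2])
        # Selectivity: everything outside the patch is untouched.
        assert np.array_equal(manip.rgb[~wp], base.rgb[~wp])
        # The patch covers ~1% of the scene, so the scene mean barely moves.
        shift = np.abs(manip.rgb.mean(axis=(0, 1)) - base.rgb.mean(axis=(0, 1)))
        assert shift.max() < 0.01

    @pytest.mark.parametrize("mechanism", ["spatial_mean_add", "spatial_mean_change"])
    def test_spatial_mean_moves_opposite(self, mechanism, illuminants, neutral):
        spec = sc.make_scene_spec(seed=8, mechanism=mechanism)
        base = sc.render(replace(spec, mechanism="baseline"), illuminants["blue"], neutral)
        base_n = sc.render(replace(spec, mechanism="baseline"), neutral, neutral)
        manip = sc.render(spec, illuminants["blue"], neutral)

        def mean_ab(scene):
            return cs.linear_rgb_to_lab(scene.rgb.reshape(-1, 3)).mean(axis=0)[1:]

        illum_dir = mean_ab(base) - mean_ab(base_n)
        moved = mean_ab(manip) - mean_ab(base)
        # Direct pixel averaging: the manipulation moves the scene mean
        # against the illuminant's chromatic displacement.
        assert np.dot(illum_dir, moved) < 0
        if mechanism == "spatial_mean_change":
            # Strong version: the mean lands on the opposite side of neutral.
            assert np.dot(illum_dir, mean_ab(manip) - mean_ab(base_n)) < 0


class TestSurroundsAndDirection:
    def test_opposite_pairs_average_to_neutral(self, illuminants, neutral):
        sur = sc.make_surround_color_set(illuminants)
        base = cs.linear_rgb_to_lab(0.35 * np.ones(3) * neutral.gain)

        def ab(name):
            return cs.linear_rgb_to_lab(sur[name] * neutral.gain)[1:]

        assert np.allclose((ab("khaki") + ab("purple")) / 2, base[1:], atol=1e-9)
        assert np.allclose((ab("rose") + ab("teal")) / 2, base[1:], atol=1e-9)

    def test_diagonals_45_degrees_from_daylight_axis(self, illuminants, neutral):
        sur = sc.make_surround_color_set(illuminants)
        u_y = sc._illuminant_ab_direction(illuminants["yellow"], neutral)
        for name, refl in sur.items():
            lab = cs.linear_rgb_to_lab(refl * neutral.gain)
            d = lab[1:] - cs.linear_rgb_to_lab(0.35 * np.ones(3) * neutral.gain)[1:]
            cosang = abs(np.dot(d / np.linalg.norm(d), u_y))
            assert cosang == pytest.approx(np.cos(np.radians(45.0)), abs=1e-9)

    def test_purple_direction_classification(self, illuminants, neutral):
        # Purple surround: blue and red neighbor it; green and yellow oppose.
        sur = sc.make_surround_color_set(illuminants)
        lab = cs.linear_rgb_to_lab(sur["purple"] * neutral.gain)
        hue = float(np.degrees(np.arctan2(lab[2], lab[1])) % 360)
        got = {n: sc.classify_direction(illuminants[n], hue, neutral)
               for n in ("blue", "red", "green", "yellow")}
        assert got == {"blue": "Neighboring", "red": "Neighboring",
                       "green": "Opposing", "yellow": "Opposing"}

    def test_neutral_illuminant_rejected(self, neutral):
        with pytest.raises(ValueError):
            sc.classify_direction(neutral, 45.0, neutral)

    def test_leaf_render_differs_except_under_neutral(self, illuminants, neutral):
        sur = sc.make_surround_color_set(illuminants)["teal"]
        spec_b = sc.make_scene_spec(seed=9, surround_reflectance=sur)
        spec_s = replace(spec_b, mechanism="local_surround")
        for name in sc.ILLUMINANT_NAMES:
            sb = sc.render(spec_b, illuminants[name], neutral)
            ss = sc.render(spec_s, illuminants[name], neutral)
            leaf = sb.roles == sc.ROLE_LEAF
            same = np.allclose(sb.rgb[leaf], ss.rgb[leaf])
            assert same == (name == "neutral")


class TestDataset:
    def test_counts_and_masks(self, illuminants):
        records = sc.generate_experiment_dataset(
            palette="indoor", illuminants=illuminants, n_locations=2, seed=11)
        assert len(records) == 5 * 5 * 2
        for r in records:
            area = (r.scene.mask == 1).sum()
            assert area > 0
            want = r.competitors.reflectances[r.meta["competitor"]]
            assert np.allclose(r.scene.reflectance[r.scene.mask == 1], want)

    def test_determinism(self, illuminants):
        a = sc.generate_experiment_dataset(palette="outdoor", illuminants=illuminants,
                                           n_locations=2, seed=12)
        b = sc.generate_experiment_dataset(palette="outdoor", illuminants=illuminants,
                                           n_locations=2, seed=12)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.scene.rgb, rb.scene.rgb)
            assert ra.meta == rb.meta


class TestSceneIO:
    def test_bundle_roundtrip(self, illuminants, neutral, tmp_path, competitors_blue):
        spec = sc.make_scene_spec(seed=13)
        spec = replace(spec, target_entries=[(0, competitors_blue.reflectances["R"], 1)])
        scene = sc.render(spec, illuminants["blue"], neutral)
        sc.save_scene(scene, tmp_path / "bundle", {"illuminant": "blue"})
        loaded, meta = sc.load_scene(tmp_path / "bundle")
        assert meta == {"illuminant": "blue"}
        assert np.abs(loaded.rgb - scene.rgb).max() < 1e-6  # float32 roundtrip
        assert np.abs(loaded.reflectance - scene.reflectance).max() < 1e-6
        assert np.array_equal(loaded.mask, scene.mask)
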