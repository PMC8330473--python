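"""Scene analysis: smoothing, segmentation, patches, zones, contrasts."""

import numpy as np
import pandas as pd
import pytest

from patchcamo import synth
from patchcamo.color import delta_e_ciede2000
from patchcamo.design import ColorGroup
from patchcamo.scene import (
    NO_LABEL,
    FilterParams,
    classify_pixels,
    contrast_predictors,
    fit_classifier,
    habitat_proportions,
    near_zone_mask,
    particle_analysis,
    patch_summaries,
    ranked_smooth,
)


class TestRankedSmooth:
    def test_uniform_fixed_point(self):
        img = np.full((20, 20, 3), [50.0, 5.0, -5.0])
        out = ranked_smooth(img, FilterParams(iterations=2))
        assert np.allclose(out, img)

    def test_boundary_preserved(self):
        """Two homogeneous half-planes with a large colour difference keep
        their per-half means (the gate stops cross-boundary mixing)."""
        img = np.zeros((40, 40, 3))
        img[:, :20] = [40.0, -20.0, 10.0]
        img[:, 20:] = [70.0, 20.0, -10.0]
        de = float(delta_e_ciede2000(img[0, 0], img[0, -1]))
        assert de > 25  # genuinely high-contrast boundary
        out = ranked_smooth(img)
        for half in (np.s_[:, :20], np.s_[:, 20:]):
            shift = delta_e_ciede2000(out[half].mean(axis=(0, 1)), img[half].mean(axis=(0, 1)))
            assert float(shift) < 0.5

    def test_subthreshold_outliers_removed(self, rng):
        img = np.full((50, 50, 3), [50.0, 0.0, 0.0])
        idx = rng.choice(2500, size=25, replace=False)
        noisy = img.reshape(-1, 3).copy()
        noisy[idx] += [5.0, 2.0, 2.0]  # below the default gates
        noisy = noisy.reshape(50, 50, 3)
        out = ranked_smooth(noisy)
        still_off = np.sum(np.abs(out[..., 0] - 50.0) > 1.0)
        assert still_off <= 2  # >= 90% of 25 outliers flattened

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            FilterParams(iterations=0)
        with pytest.raises(ValueError):
            FilterParams(weber_lum=-0.1)


def _two_groups():
    a = ColorGroup("a", np.array([[30.0, 0, 0], [32.0, 2, 2], [28.0, -2, -2]]))
    b = ColorGroup("b", np.array([[70.0, 0, 0], [72.0, 2, 2], [68.0, -2, -2]]))
    return [a, b]


class TestClassifier:
    def test_pixel_at_mean_wins(self):
        clf = fit_classifier(_two_groups())
        img = np.full((1, 1, 3), [30.0, 0.0, 0.0])
        assert classify_pixels(clf, img)[0, 0] == 0

    def test_degenerate_prior(self):
        clf = fit_classifier(_two_groups(), priors=[1.0, 0.0])
        img = np.full((2, 2, 3), [70.0, 0.0, 0.0])  # b's mean, but prior kills b
        assert np.all(classify_pixels(clf, img) == 0)

    def test_posterior_tie_breaks_low_index(self):
        groups = [
            ColorGroup("a", np.array([[40.0, 0, 0], [44.0, 0, 0]])),
            ColorGroup("b", np.array([[60.0, 0, 0], [56.0, 0, 0]])),
        ]
        clf = fit_classifier(groups)
        img = np.full((1, 1, 3), [50.0, 0.0, 0.0])  # exactly between
        assert classify_pixels(clf, img)[0, 0] == 0

    def test_excluded_pixels_unlabelled(self):
        clf = fit_classifier(_two_groups())
        img = np.full((3, 3, 3), [30.0, 0.0, 0.0])
        lm = classify_pixels(clf, img, exclude_mask=np.ones((3, 3), bool))
        assert np.all(lm == NO_LABEL)

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            fit_classifier(_two_groups()[:1])

    def test_recovers_synthetic_ground_truth(self, small_scene, rng):
        """Well-separated habitats are recovered almost pixel-perfectly."""
        sc = small_scene
        groups = []
        for i in range(4):
            pix = sc.lab_image[sc.label_map == i]
            groups.append(ColorGroup(f"h{i}", pix[rng.choice(len(pix), 300, replace=False)]))
        clf = fit_classifier(groups)
        lm = classify_pixels(clf, sc.lab_image, exclude_mask=sc.target_mask)
        ok = lm == sc.label_map
        acc = ok[~sc.target_mask].mean()
        assert acc >= 0.99


class TestParticles:
    def test_uniform_map_single_patch(self):
        lm = np.zeros((100, 100), dtype=int)
        tab = particle_analysis(lm)
        assert len(tab) == 1 and tab.area_px.iloc[0] == 10000

    def test_checkerboard_4conn(self):
        lm = np.indices((8, 8)).sum(axis=0) % 2
        tab = particle_analysis(lm, connectivity=4)
        assert len(tab) == 64 and (tab.area_px == 1).all()

    def test_patch_scale_monotone(self):
        """Median patch area grows with the generator's patch scale."""
        def median_area(scale, seed):
            mhs = tuple(
                synth.MicrohabitatSpec(f"h{i}", (float(30 + 15 * i), 0.0, 0.0), (1, 1, 1), 0.25, scale)
                for i in range(4)
            )
            sc = synth.generate_scene(synth.SceneSpec(192, 192, 1.0, mhs, seed=seed))
            return particle_analysis(sc.label_map).area_px.median()

        for seed in range(5):
            assert median_area(32, seed) > median_area(8, seed)

    def test_no_label_excluded(self, small_scene):
        tab = particle_analysis(small_scene.label_map)
        assert tab.area_px.sum() == (small_scene.label_map != NO_LABEL).sum()
        summ = patch_summaries(tab)
        assert np.isclose(summ.proportion.sum(), 1.0)


class TestNearZone:
    def test_disjoint_from_target(self, small_scene):
        nz = near_zone_mask(small_scene.target_mask, band_width_px=10, exclusion_px=2)
        assert not (nz & small_scene.target_mask).any()

    def test_zero_band_empty(self):
        t = np.zeros((10, 10), bool)
        t[4:6, 4:6] = True
        assert near_zone_mask(t, 0).sum() == 0

    def test_closed_form_area(self):
        """10x10 square target, exclusion 1, band 3: 18^2 - 12^2 = 180."""
        t = np.zeros((40, 40), bool)
        t[15:25, 15:25] = True
        nz = near_zone_mask(t, band_width_px=3, exclusion_px=1)
        assert nz.sum() == 18**2 - 12**2 == 180

    def test_clipped_at_borders(self):
        t = np.zeros((12, 12), bool)
        t[0:4, 0:4] = True
        nz = near_zone_mask(t, band_width_px=3, exclusion_px=1)
        assert nz.sum() < 18**2 - 12**2
        assert not (nz & t).any()


class TestContrast:
    def test_uniform_background_zero(self):
        img = np.full((30, 30, 3), [50.0, 0.0, 0.0])
        t = np.zeros((30, 30), bool)
        t[12:18, 12:18] = True
        near, whole = contrast_predictors([50.0, 0.0, 0.0], img, t, 4, 1)
        assert near == 0.0 and whole == 0.0

    def test_uniform_background_near_equals_whole(self):
        img = np.full((30, 30, 3), [50.0, 0.0, 0.0])
        t = np.zeros((30, 30), bool)
        t[12:18, 12:18] = True
        near, whole = contrast_predictors([70.0, 10.0, 0.0], img, t, 4, 1)
        assert np.isclose(near, whole)

    def test_ringed_target_constructed(self):
        """Near zone pure habitat A, far field habitat B: dE_near equals the
        distance to A, dE_whole sits between the distances to A and B."""
        A, B = np.array([40.0, -10.0, 5.0]), np.array([70.0, 15.0, -5.0])
        img = np.empty((60, 60, 3))
        img[:] = B
        t = np.zeros((60, 60), bool)
        t[27:33, 27:33] = True
        ring = near_zone_mask(t, band_width_px=5, exclusion_px=1)
        img[ring] = A
        target_colour = np.array([45.0, -5.0, 0.0])
        near, whole = contrast_predictors(target_colour, img, t, 5, 1)
        dA = float(delta_e_ciede2000(target_colour, A))
        dB = float(delta_e_ciede2000(target_colour, B))
        assert abs(near - dA) < 1e-9
        assert min(dA, dB) < whole < max(dA, dB)

    def test_translation_invariance(self):
        img = np.full((40, 40, 3), [55.0, 2.0, -3.0])
        img[:, :10] = [35.0, -2.0, 3.0]
        for r0 in (14, 20):
            t = np.zeros((40, 40), bool)
            t[r0 : r0 + 6, 25:31] = True
            vals = contrast_predictors([50.0, 0.0, 0.0], img, t, 3, 1)
        t2 = np.roll(t, 3, axis=0)
        vals2 = contrast_predictors([50.0, 0.0, 0.0], img, t2, 3, 1)
        assert np.allclose(vals, vals2)

    def test_empty_background_raises(self):
        img = np.zeros((6, 6, 3))
        t = np.ones((6, 6), bool)
        with pytest.raises(ValueError):
            contrast_predictors([0, 0, 0], img, t, 2, 1)


class TestProportions:
    def test_half_and_half(self):
        lm = np.zeros((10, 10), int)
        lm[:, 5:] = 1
        assert np.allclose(habitat_proportions(lm), [0.5, 0.5])

    def test_single_habitat(self):
        lm = np.zeros((5, 5), int)
        assert np.allclose(habitat_proportions(lm, n_habitats=3), [1.0, 0.0, 0.0])

    def test_near_zone_enrichment(self):
        lm = np.ones((50, 50), int)
        t = np.zeros((50, 50), bool)
        t[22:28, 22:28] = True
        ring = near_zone_mask(t, 4, 1)
        lm[ring] = 0  # habitat 0 wraps the target
        lm[t] = NO_LABEL
        whole = habitat_proportions(lm, n_habitats=2)
        near = habitat_proportions(lm, region_mask=ring, n_habitats=2)
        assert near[0] > whole[0]

    def test_empty_region_raises(self):
        lm = np.full((4, 4), NO_LABEL)
        with pytest.raises(ValueError):
            habitat_proportions(lm)
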