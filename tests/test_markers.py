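import numpy as np
import pytest

from orrquant import geometry as G
from orrquant import grouping as gp
from orrquant import markers as M
from orrquant import synthdata as S


def _disk_image(centers, radius=5.0, shape=(60, 200), value=200.0):
    img = np.zeros(shape, dtype=float)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for cy, cx in centers:
        img[np.hypot(yy + 0.5 - cy, xx + 0.5 - cx) <= radius] = value
    return img


class TestFluorescenceIntensity:
    def test_background_subtraction(self):
        img = np.zeros((10, 10))
        t = np.zeros_like(img, bool)
        c = np.zeros_like(img, bool)
        t[:5], c[5:] = True, True
        img[t], img[c] = 100.0, 20.0
        assert M.fluorescence_intensity(img, t, c) == pytest.approx(80.0)

    def test_target_equal_to_background_is_zero(self):
        img = np.full((10, 10), 37.0)
        t = np.zeros_like(img, bool)
        c = np.zeros_like(img, bool)
        t[:5], c[5:] = True, True
        assert M.fluorescence_intensity(img, t, c) == pytest.approx(0.0)

    def test_offset_invariance(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 100, (20, 20))
        t = np.zeros_like(img, bool)
        c = np.zeros_like(img, bool)
        t[:10], c[10:] = True, True
        v0 = M.fluorescence_intensity(img, t, c)
        v1 = M.fluorescence_intensity(img + 55.5, t, c)
        assert v0 == pytest.approx(v1)

    def test_empty_or_overlapping_masks_rejected(self):
        img = np.zeros((4, 4))
        full = np.ones_like(img, bool)
        with pytest.raises(ValueError):
            M.fluorescence_intensity(img, np.zeros_like(full), full)
        with pytest.raises(ValueError):
            M.fluorescence_intensity(img, full, full)

    def test_synthetic_os_band_recovered(self, treated_section):
        images, truth = treated_section
        ppu = images.px_per_um
        x0, x1 = 0, int(250 * ppu)
        osm = np.zeros_like(images.labels, bool)
        osm[:, x0:x1] = images.labels[:, x0:x1] == G.LAYER_LABELS["OS"]
        ch = np.zeros_like(images.choroid_mask)
        ch[:, x0:x1] = images.choroid_mask[:, x0:x1]
        v = M.fluorescence_intensity(images.marker, osm, ch)
        assert v == pytest.approx(truth.regions["os_marker_intensity"][0], abs=1.0)


class TestNormalizeToControl:
    @pytest.mark.parametrize("value,expected", [(80.0, 1.0), (40.0, 0.5)])
    def test_ratios(self, value, expected):
        assert M.normalize_to_control(value, [80.0, 80.0]) == expected

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            M.normalize_to_control(10.0, [0.0, 0.0])


class TestCountNuclei:
    def test_disjoint_disks(self):
        centers = [(30, 20 + 15 * k) for k in range(12)]
        img = _disk_image(centers, radius=5.0)
        mask = np.ones(img.shape, bool)
        nuclei, per_mm = M.count_nuclei(img, mask, px_per_um=1.0)
        assert len(nuclei) == 12
        assert per_mm == pytest.approx(12 / 0.2)  # 200 um lateral extent

    def test_watershed_splits_overlapping_pair(self):
        # two disks overlapping ~30% (centre distance 1.17 r) with distinct
        # centres are split into two nuclei
        img = _disk_image([(30, 60), (30, 71.7)], radius=10.0)
        mask = np.ones(img.shape, bool)
        nuclei, _ = M.count_nuclei(img, mask, px_per_um=1.0, min_distance_um=5.0)
        assert len(nuclei) == 2

    def test_circularity_filter_excludes_elongated_blob(self):
        img = _disk_image([(30, 30), (30, 70)], radius=8.0)
        img[10:15, 120:150] = 200.0  # elongated 5 x 30 bar
        mask = np.ones(img.shape, bool)
        # seed spacing larger than the bar keeps each object one component
        all_n, _ = M.count_nuclei(img, mask, 1.0, min_distance_um=35.0,
                                  circularity=(0.0, 1.0))
        round_n, _ = M.count_nuclei(img, mask, 1.0, min_distance_um=35.0,
                                    circularity=(0.7, 1.0))
        assert len(all_n) == 3
        assert len(round_n) == 2
        assert all(c >= 0.7 for c in round_n.props["circularity"])

    def test_permissive_settings_impose_no_shape_filter(self):
        # size 0-infinity and circularity 0-1 give the raw post-watershed
        # component count
        rng = np.random.default_rng(3)
        centers = [(rng.uniform(10, 50), rng.uniform(10, 190)) for _ in range(8)]
        img = _disk_image(centers, radius=4.0)
        mask = np.ones(img.shape, bool)
        base, _ = M.count_nuclei(img, mask, 1.0)
        filt, _ = M.count_nuclei(img, mask, 1.0, min_area_um2=0.0,
                                 circularity=(0.0, 1.0))
        assert len(base) == len(filt)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            M.count_nuclei(np.zeros((5, 5)), np.zeros((5, 5), bool))


class TestPositiveNuclei:
    def _nuclei(self):
        img = _disk_image([(30, 30), (30, 60), (30, 90)], radius=6.0)
        return M.count_nuclei(img, np.ones(img.shape, bool), 1.0)[0]

    def test_zero_channel_gives_zero(self):
        n = self._nuclei()
        count, _ = M.positive_nuclei(n, np.zeros(n.labels.shape), 0.0)
        assert count == 0

    def test_saturated_channel_counts_all(self):
        n = self._nuclei()
        count, _ = M.positive_nuclei(n, np.full(n.labels.shape, 255.0), 100.0)
        assert count == len(n)

    def test_recovers_generator_flags(self, treated_section):
        images, truth = treated_section
        ppu = images.px_per_um
        gcl = images.labels == G.LAYER_LABELS["GCL"]
        nuclei, _ = M.count_nuclei(images.dapi, gcl, ppu, min_distance_um=2.0)
        count, _ = M.positive_nuclei(nuclei, images.marker, 75.0)
        true_pos = int(truth.nuclei[truth.nuclei["layer"] == "GCL"]
                       ["marker_positive"].sum())
        assert count == pytest.approx(true_pos, abs=max(2, 0.1 * true_pos))


class TestDabPositiveArea:
    def test_white_image_zero(self):
        rgb = np.full((40, 100, 3), 255, np.uint8)
        assert M.dab_positive_area(rgb, np.ones((40, 100), bool)) == 0.0

    def test_known_brown_patch_area(self):
        # 500 um^2 of DAB over a 250 um window -> 2.0 um^2/um
        from skimage.color import rgb_from_hed

        hed = np.zeros((40, 250, 3))
        hed[..., 0] = 0.35
        hed[10:20, 100:150, 2] = 0.6  # 500 px = 500 um^2 at 1 px/um
        rgb = np.clip(10.0 ** (-(hed @ rgb_from_hed)) * 255, 0, 255).astype(np.uint8)
        mask = np.ones((40, 250), bool)
        area = M.dab_positive_area(rgb, mask, px_per_um=1.0)
        assert area == pytest.approx(2.0, rel=0.02)

    def test_hematoxylin_only_negative_under_both_rules(self):
        from skimage.color import rgb_from_hed

        hed = np.zeros((40, 100, 3))
        hed[..., 0] = 0.5
        rgb = np.clip(10.0 ** (-(hed @ rgb_from_hed)) * 255, 0, 255).astype(np.uint8)
        mask = np.ones((40, 100), bool)
        assert M.dab_positive_area(rgb, mask) == 0.0
        assert M.dab_positive_area(rgb, mask, rule="hue") == 0.0

    def test_additive_over_disjoint_masks(self, treated_section):
        images, _ = treated_section
        ppu = images.px_per_um
        ipl = images.labels == G.LAYER_LABELS["IPL"]
        half = images.labels.shape[1] // 2
        m1 = ipl.copy()
        m1[:, half:] = False
        m2 = ipl.copy()
        m2[:, :half] = False
        a_all = M.dab_positive_area(images.dab, ipl, ppu)
        a1 = M.dab_positive_area(images.dab, m1, ppu)
        a2 = M.dab_positive_area(images.dab, m2, ppu)
        l_all = np.nonzero(ipl.any(axis=0))[0].size
        l1 = np.nonzero(m1.any(axis=0))[0].size
        l2 = np.nonzero(m2.any(axis=0))[0].size
        assert a_all * l_all == pytest.approx(a1 * l1 + a2 * l2, rel=1e-9)

    def test_grayscale_rejected(self):
        with pytest.raises(ValueError):
            M.dab_positive_area(np.zeros((5, 5)), np.ones((5, 5), bool))

    def test_generator_truth_recovered(self, treated_section):
        images, truth = treated_section
        ppu = images.px_per_um
        for i, row in truth.regions.iterrows():
            x0 = int(row["x_start_um"] * ppu)
            x1 = x0 + int(250 * ppu)
            mask = np.zeros_like(images.labels, bool)
            mask[:, x0:x1] = images.labels[:, x0:x1] == G.LAYER_LABELS["IPL"]
            area = M.dab_positive_area(images.dab, mask, ppu)
            assert area == pytest.approx(row["dab_area_per_um"], rel=0.05)


class TestRbpmsRatio:
    def test_simple_ratios(self):
        assert M.rbpms_ratio(10, 20) == 0.5
        assert M.rbpms_ratio(20, 20) == 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            M.rbpms_ratio(1, 0)

    def test_treated_decrease_matches_generator(self):
        # generator encodes a 44% RBPMS/GCL decrease for every treated group
        ctl = S.DEFAULT_MARKER_EFFECTS[0].rbpms_fraction
        for g in (1, 2, 3, 4):
            frac = S.DEFAULT_MARKER_EFFECTS[g].rbpms_fraction
            assert 1 - frac / ctl == pytest.approx(0.44, abs=0.01)


class TestGroup4Exclusion:
    def test_group4_and_indeterminate_refused(self):
        with pytest.raises(M.Group4ExclusionError):
            M.assert_photoreceptor_analyzable(gp.GroupLabel(4, "severe"))
        with pytest.raises(M.Group4ExclusionError):
            M.assert_photoreceptor_analyzable(gp.INDETERMINATE)

    @pytest.mark.parametrize("g", [0, 1, 2, 3])
    def test_groups_0_to_3_allowed(self, g):
        M.assert_photoreceptor_analyzable(gp.GroupLabel(g, gp.GROUP_NAMES[g]))
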