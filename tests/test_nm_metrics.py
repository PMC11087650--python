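import numpy as np
import pandas as pd
import pytest

from nigraquant import (
    MeasurementError,
    PhantomGeometry,
    SliceSet,
    compute_cnr,
    compute_volume,
    corrected_volume,
    dice,
    icc,
    generate_phantom,
    subject_measures,
)
from nigraquant.nm_metrics import slice_signal_stats

from conftest import VOX, make_image, make_mask


class TestCnr:
    def _one_slice_setup(self):
        data = np.full((4, 4, 7), 100.0)
        data[0, 0, 2] = data[0, 1, 2] = 110.0
        data[2, 0, 2], data[2, 1, 2], data[2, 2, 2], data[2, 3, 2] = 100, 100, 98, 102
        image = make_image(data)
        snc = make_mask((4, 4, 7), [(0, 0, 2), (0, 1, 2)])
        bnd = make_mask((4, 4, 7), [(2, y, 2) for y in range(4)], label="background")
        return image, snc, bnd

    def test_hand_computed_single_slice(self):
        image, snc, bnd = self._one_slice_setup()
        stats = slice_signal_stats(image, snc, bnd, 2)
        # background sample SD = sqrt(8/3); (110 - 100) / 1.63299 = 6.12372
        assert stats.std_bnd == pytest.approx(np.sqrt(8 / 3), rel=1e-6)
        assert stats.cnr == pytest.approx(6.12372, abs=1e-4)

    def test_zero_contrast_gives_zero_cnr(self):
        data = np.zeros((4, 4, 7))
        rng = np.random.default_rng(1)
        for z in (2, 3, 4):
            data[2:, :, z] = rng.normal(100, 5, size=(2, 4))
            data[:2, :, z] = 100.0
        # SNc mean exactly equals background mean on every slice
        data[2:, :, 2] += 100 - data[2:, :, 2].mean()
        data[2:, :, 3] += 100 - data[2:, :, 3].mean()
        data[2:, :, 4] += 100 - data[2:, :, 4].mean()
        image = make_image(data)
        snc = make_mask((4, 4, 7), [(0, y, z) for y in range(4) for z in (2, 3, 4)])
        bnd = make_mask((4, 4, 7), [(x, y, z) for x in (2, 3) for y in range(4) for z in (2, 3, 4)], label="background")
        cnr = compute_cnr(image, snc, bnd, SliceSet(indices=(2, 3, 4)))
        assert cnr == pytest.approx(0.0, abs=1e-4)

    def test_affine_intensity_rescaling_invariance(self):
        image, snc, bnd = self._one_slice_setup()
        before = slice_signal_stats(image, snc, bnd, 2).cnr
        rescaled = make_image(3.5 * image.data + 42.0)
        after = slice_signal_stats(rescaled, snc, bnd, 2).cnr
        assert after == pytest.approx(before, rel=1e-5)

    def test_empty_snc_on_selected_slice_raises(self):
        image, snc, bnd = self._one_slice_setup()
        with pytest.raises(MeasurementError, match="slice 3"):
            slice_signal_stats(image, snc, bnd, 3)

    def test_zero_background_sd_raises(self):
        data = np.full((4, 4, 7), 100.0)
        data[0, 0, 2] = 110.0
        image = make_image(data)
        snc = make_mask((4, 4, 7), [(0, 0, 2)])
        bnd = make_mask((4, 4, 7), [(2, y, 2) for y in range(4)], label="background")
        with pytest.raises(MeasurementError, match="SD is zero"):
            slice_signal_stats(image, snc, bnd, 2)


class TestVolume:
    def test_empty_mask_is_zero(self):
        mask = make_mask((4, 4, 7), [])
        assert compute_volume(mask, SliceSet(indices=(2, 3, 4))) == 0.0

    def test_thousand_voxels_at_default_spacing(self):
        # 1000 x 0.35 x 0.35 x 3 mm^3 = 367.5 mm^3
        vox = [(x, y, z) for x in range(10) for y in range(34) for z in (2, 3, 4)][:1000]
        mask = make_mask((10, 34, 7), vox)
        assert compute_volume(mask, SliceSet(indices=(2, 3, 4))) == pytest.approx(367.5)

    def test_only_selected_slices_counted(self):
        vox = [(1, 1, z) for z in range(7)]
        mask = make_mask((4, 4, 7), vox)
        assert compute_volume(mask, SliceSet(indices=(2, 3, 4))) == pytest.approx(3 * 0.3675)

    def test_additive_over_disjoint_masks_and_linear_in_voxel_volume(self):
        a = make_mask((6, 6, 7), [(0, 0, 2), (1, 1, 3)])
        b = make_mask((6, 6, 7), [(2, 2, 2), (3, 3, 4)])
        both = make_mask((6, 6, 7), [(0, 0, 2), (1, 1, 3), (2, 2, 2), (3, 3, 4)])
        s = SliceSet(indices=(2, 3, 4))
        assert compute_volume(both, s) == pytest.approx(
            compute_volume(a, s) + compute_volume(b, s)
        )
        doubled = make_mask((6, 6, 7), [(0, 0, 2), (1, 1, 3)], voxel_size=(0.7, 0.35, 3.0))
        assert compute_volume(doubled, s) == pytest.approx(2 * compute_volume(a, s))


class TestCorrectedVolume:
    def test_mm3_over_ml_convention(self):
        assert corrected_volume(394.2, 1460.0) == pytest.approx(0.270, abs=5e-4)

    def test_zero_volume_and_homogeneity(self):
        assert corrected_volume(0.0, 1500.0) == 0.0
        assert corrected_volume(300.0, 2920.0) == pytest.approx(corrected_volume(300.0, 1460.0) / 2)

    def test_nonpositive_tiv_raises(self):
        with pytest.raises(MeasurementError):
            corrected_volume(300.0, 0.0)


class TestDice:
    def test_identical_disjoint_and_partial(self):
        a = make_mask((4, 4, 7), [(0, 0, 0), (1, 1, 1), (2, 2, 2), (3, 3, 3)])
        assert dice(a, a) == 1.0
        b = make_mask((4, 4, 7), [(0, 1, 0), (1, 2, 1)])
        assert dice(a, b) == 0.0
        # |A| = 4, |B| = 6, |A n B| = 3 -> 2*3/10 = 0.6
        c_vox = [(0, 0, 0), (1, 1, 1), (2, 2, 2), (0, 1, 0), (1, 2, 1), (2, 3, 2)]
        c = make_mask((4, 4, 7), c_vox)
        assert dice(a, c) == pytest.approx(0.6)
        assert dice(c, a) == pytest.approx(0.6)

    def test_both_empty_is_one_with_warning(self):
        e = make_mask((3, 3, 3), [])
        with pytest.warns(UserWarning):
            assert dice(e, e) == 1.0


class TestIcc:
    S1 = [10.0, 12.0, 14.0, 18.0, 22.0]
    S2 = [11.0, 12.5, 13.0, 19.5, 21.0]

    def test_matches_two_way_absolute_agreement_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        n = len(self.S1)
        long = pd.DataFrame(
            {
                "subject": list(range(n)) * 2,
                "rater": ["a"] * n + ["b"] * n,
                "y": self.S1 + self.S2,
            }
        )
        table = pingouin.intraclass_corr(long, targets="subject", raters="rater", ratings="y")
        # two-way random, absolute agreement, single measurement
        expected = float(
            table.loc[table["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0]
        )
        assert icc(self.S1, self.S2) == pytest.approx(expected, abs=1e-10)

    def test_identical_sessions_give_one(self):
        assert icc(self.S1, self.S1) == pytest.approx(1.0)

    def test_constant_offset_decreases_absolute_agreement(self):
        shifted = [v + 3.0 for v in self.S2]
        assert icc(self.S1, shifted) < icc(self.S1, self.S2)

    def test_zero_between_subject_variance_raises(self):
        # all subjects identical (sessions differ only by a constant offset)
        with pytest.raises(MeasurementError, match="undefined"):
            icc([5.0, 5.0, 5.0], [7.0, 7.0, 7.0])


class TestSubjectMeasures:
    def _symmetric_setup(self):
        shape = (12, 10, 7)
        rng = np.random.default_rng(5)
        data = rng.normal(100, 10, size=shape)
        data = (data + data[::-1]) / 2  # mirror-symmetric about the x midplane
        snc_left = [(2, y, z) for y in (5, 6) for z in (2, 3, 4)]
        snc_right = [(9, y, z) for y in (5, 6) for z in (2, 3, 4)]
        for v in snc_left + snc_right:
            data[v] += 15.0
        image = make_image(data)
        l_mask = make_mask(shape, snc_left)
        r_mask = make_mask(shape, snc_right)
        bnd = make_mask(shape, [(x, 1, z) for x in range(12) for z in range(7)], label="background")
        templates = {
            "sensorimotor": make_mask(shape, [(x, y, z) for x in range(12) for y in range(0, 4) for z in range(7)], label="sensorimotor"),
            "associative": make_mask(shape, [(x, y, z) for x in range(12) for y in range(4, 7) for z in range(7)], label="associative"),
            "limbic": make_mask(shape, [(x, y, z) for x in range(12) for y in range(7, 10) for z in range(7)], label="limbic"),
        }
        return image, (l_mask, r_mask), bnd, templates

    def test_symmetric_phantom_has_equal_hemisphere_cnr(self):
        image, raters, bnd, templates = self._symmetric_setup()
        m = subject_measures(image, raters, raters, bnd, templates, tiv_ml=1460.0)
        assert m.cnr.left == pytest.approx(m.cnr.right, rel=1e-6)
        assert m.cnr.mean == pytest.approx(m.cnr.left, rel=1e-6)
        assert m.volume_mm3.left == m.volume_mm3.right
        assert m.c_vol.mean == pytest.approx(m.volume_mm3.mean / 1460.0)

    def test_regional_volumes_sum_to_whole_under_partition(self):
        image, raters, bnd, templates = self._symmetric_setup()
        m = subject_measures(image, raters, raters, bnd, templates, tiv_ml=1460.0)
        total = sum(hv.mean for hv in m.regional_volume_mm3.values())
        assert total == pytest.approx(m.volume_mm3.mean, rel=1e-9)

    def test_fully_empty_region_is_missing(self):
        image, raters, bnd, templates = self._symmetric_setup()
        m = subject_measures(image, raters, raters, bnd, templates, tiv_ml=1460.0)
        # the SNc sits entirely inside the associative band in this toy setup
        assert np.isnan(m.regional_cnr["limbic"].mean)
        assert m.regional_volume_mm3["limbic"].mean == 0.0


class TestEstimatorCalibration:
    def test_zero_contrast_phantoms_average_to_zero_cnr(self, geometry):
        cnrs = []
        for seed in range(60):
            image, gt = generate_phantom(
                {"cnr": 0.0, "volume_mm3": 700.0}, geometry, seed=seed
            )
            snc = make_mask(
                geometry.grid_shape, np.argwhere(gt.true_snc_mask_left.data | gt.true_snc_mask_right.data)
            )
            cnrs.append(
                compute_cnr(image, snc, gt.background_mask, SliceSet(indices=(2, 3, 4)))
            )
        cnrs = np.asarray(cnrs)
        se = cnrs.std(ddof=1) / np.sqrt(len(cnrs))
        assert abs(cnrs.mean()) < 3 * se + 1e-12

    def test_cnr_estimator_tracks_generator_contrast_with_unit_slope(self, geometry):
        targets = np.linspace(0.5, 2.0, 7)
        measured = []
        for i, c in enumerate(targets):
            image, gt = generate_phantom(
                {"cnr": float(c), "volume_mm3": 780.0}, geometry, seed=100 + i
            )
            snc = make_mask(
                geometry.grid_shape, np.argwhere(gt.true_snc_mask_left.data | gt.true_snc_mask_right.data)
            )
            measured.append(
                compute_cnr(image, snc, gt.background_mask, SliceSet(indices=(2, 3, 4)))
            )
        slope = np.polyfit(targets, measured, 1)[0]
        assert 0.95 <= slope <= 1.05
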