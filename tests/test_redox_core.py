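"""Per-cell computation: SNR thresholding, ORR, compartments, areas."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import redoxim as rx
from redoxim.errors import DegenerateCompartmentError, ParameterError
from redoxim.redox_core import COMPARTMENTS
from tests.conftest import make_annotation, square_mask


def uniform_field(value, bg_mean=100.0, noise_sd=4.0, shape=(32, 32)):
    img = np.full(shape, float(bg_mean + value))
    bg = rx.BackgroundEstimate(bg_mean, noise_sd, "blank_image")
    return rx.RedoxField("f", "d", img, img.copy(), background_nadh=bg, background_fp=bg)


class TestSubtractAndThreshold:
    def test_background_only_field_has_empty_valid_grid(self):
        fld = uniform_field(0.0)
        ch = rx.subtract_and_threshold(fld)
        assert not ch.valid.any()

    def test_threshold_is_inclusive_at_the_boundary(self):
        # signal 30 over noise 4 is exactly SNR 7.5 and must pass
        fld = uniform_field(30.0, bg_mean=100.0, noise_sd=4.0)
        ch = rx.subtract_and_threshold(fld, snr_min=7.5)
        assert ch.valid.all()
        assert np.allclose(ch.nadh[ch.valid], 30.0)
        # one count less fails
        ch2 = rx.subtract_and_threshold(uniform_field(29.9, noise_sd=4.0), snr_min=7.5)
        assert not ch2.valid.any()

    def test_noise_free_footprint_equals_generator_masks(self, noise_free_field):
        fld, anns, _ = noise_free_field
        ch = rx.subtract_and_threshold(fld)
        footprint = np.zeros(fld.shape, dtype=bool)
        for ann in anns:
            footprint |= ann.cell_mask
        np.testing.assert_array_equal(ch.valid, footprint)

    def test_joint_rule_requires_both_channels(self):
        bg = rx.BackgroundEstimate(100.0, 4.0, "blank_image")
        nadh = np.full((8, 8), 200.0)
        fp = np.full((8, 8), 100.0)  # fp carries no signal at all
        fld = rx.RedoxField("f", "d", nadh, fp, background_nadh=bg, background_fp=bg)
        ch = rx.subtract_and_threshold(fld)
        assert not ch.valid.any()

    def test_invalid_snr_min_rejected(self):
        with pytest.raises(ParameterError):
            rx.subtract_and_threshold(uniform_field(50.0), snr_min=0.0)

    def test_raising_snr_min_is_monotone(self, study_bundle):
        fld = study_bundle.fields[0]
        counts = [
            int(rx.subtract_and_threshold(fld, snr_min=s).valid.sum())
            for s in (2.0, 5.0, 7.5, 10.0, 15.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestMakeMasks:
    def test_nested_squares_pixel_arithmetic(self):
        cell = square_mask((16, 16), 0, 0, 10, 10)
        nuc = square_mask((16, 16), 3, 3, 7, 7)
        masks = rx.make_masks(make_annotation(cell, nuc))
        assert masks.cytoplasm.sum() == 100 - 16
        assert (masks.nucleus ^ masks.cytoplasm == masks.cell).all()

    def test_nucleus_filling_cell_is_degenerate(self):
        cell = square_mask((8, 8), 1, 1, 5, 5)
        with pytest.raises(DegenerateCompartmentError):
            rx.make_masks(make_annotation(cell, cell.copy()))

    def test_partition_is_exact_on_generated_cells(self, study_bundle):
        for ann in study_bundle.annotations[:20]:
            masks = rx.make_masks(ann)
            assert not (masks.nucleus & masks.cytoplasm).any()
            np.testing.assert_array_equal(masks.nucleus | masks.cytoplasm, masks.cell)
            assert masks.nucleus.sum() + masks.cytoplasm.sum() == masks.cell.sum()


class TestRatioImage:
    def test_pixel_values(self):
        bg = rx.BackgroundEstimate(0.0, 1.0, "blank_image")
        nadh = np.array([[100.0, 100.0]])
        fp = np.array([[100.0, 300.0]])
        fld = rx.RedoxField("f", "d", nadh, fp, background_nadh=bg, background_fp=bg)
        orr = rx.ratio_image(rx.subtract_and_threshold(fld))
        assert orr[0, 0] == pytest.approx(0.5)
        assert orr[0, 1] == pytest.approx(0.75)

    def test_scale_invariance_under_joint_rescaling(self, noise_free_field):
        fld, _, _ = noise_free_field
        orr1 = rx.ratio_image(rx.subtract_and_threshold(fld))
        scaled = rx.RedoxField(
            fld.field_id, fld.dish_id,
            fld.nadh_image * 3.7, fld.fp_image * 3.7,
            pixel_size_um=fld.pixel_size_um, bit_depth=fld.bit_depth + 2,
            background_nadh=rx.BackgroundEstimate(
                fld.background_nadh.mean * 3.7, fld.background_nadh.noise_sd * 3.7,
                "blank_image"),
            background_fp=rx.BackgroundEstimate(
                fld.background_fp.mean * 3.7, fld.background_fp.noise_sd * 3.7,
                "blank_image"),
        )
        orr2 = rx.ratio_image(rx.subtract_and_threshold(scaled))
        valid = np.isfinite(orr1)
        np.testing.assert_array_equal(valid, np.isfinite(orr2))
        np.testing.assert_allclose(orr2[valid], orr1[valid], rtol=1e-12)


class TestCompartmentIndices:
    def test_uniform_cell_means(self):
        bg = rx.BackgroundEstimate(100.0, 1.0, "blank_image")
        img = np.full((16, 16), 160.0)
        fld = rx.RedoxField("f", "d", img, img.copy(), background_nadh=bg, background_fp=bg)
        cell = square_mask((16, 16), 2, 2, 12, 12)
        nuc = square_mask((16, 16), 5, 5, 9, 9)
        rec = rx.analyze_cell(fld, make_annotation(cell, nuc))
        for comp in COMPARTMENTS:
            assert rec.compartments[comp].mean_orr == pytest.approx(0.5)
            assert rec.compartments[comp].mean_nadh == pytest.approx(60.0)
            assert rec.compartments[comp].mean_fp == pytest.approx(60.0)

    def test_whole_cell_mean_is_mean_of_pixel_ratios(self):
        # two half-cells at ORR 0.4 and 0.6 with equal pixel counts -> 0.5
        bg = rx.BackgroundEstimate(0.0, 1.0, "blank_image")
        nadh = np.full((10, 10), 60.0)
        fp = np.where(np.arange(10)[None, :] < 5, 40.0, 90.0)
        fp = np.broadcast_to(fp, (10, 10)).copy()
        fld = rx.RedoxField("f", "d", nadh, fp, background_nadh=bg, background_fp=bg)
        cell = np.ones((10, 10), dtype=bool)
        nuc = square_mask((10, 10), 4, 2, 6, 8)  # straddles both halves evenly
        rec = rx.analyze_cell(fld, make_annotation(cell, nuc))
        assert rec.compartments["whole_cell"].mean_orr == pytest.approx(0.5)

    def test_nuclear_contrast_recovered_noise_free(self, noise_free_field):
        fld, anns, gts = noise_free_field
        for ann, gt in zip(anns, gts):
            rec = rx.analyze_cell(fld, ann)
            ratio = rec.compartments["nucleus"].mean_nadh / rec.compartments["cytoplasm"].mean_nadh
            assert ratio == pytest.approx(0.51, abs=1e-6)

    def test_compartment_snr_uses_background_noise(self, noise_free_field):
        fld, anns, _ = noise_free_field
        rec = rx.analyze_cell(fld, anns[0])
        cs = rec.compartments["cytoplasm"]
        assert cs.snr_nadh == pytest.approx(cs.mean_nadh / fld.background_nadh.noise_sd)

    def test_area_um2_scaling(self, noise_free_field):
        fld, anns, _ = noise_free_field
        rec = rx.analyze_cell(fld, anns[0])
        for comp in COMPARTMENTS:
            assert rec.area_um2[comp] == pytest.approx(
                rec.area_px[comp] * fld.pixel_size_um**2
            )


def bwarea_window_enumeration(mask):
    """Independent oracle: explicit loop over every 2x2 window."""
    p = np.pad(np.asarray(mask, dtype=bool), 1)
    total = 0.0
    for i in range(p.shape[0] - 1):
        for j in range(p.shape[1] - 1):
            blk = p[i : i + 2, j : j + 2]
            n = int(blk.sum())
            if n == 0:
                w = 0.0
            elif n == 1:
                w = 0.25
            elif n == 2:
                diag = (blk[0, 0] and blk[1, 1]) or (blk[0, 1] and blk[1, 0])
                w = 0.75 if diag else 0.5
            elif n == 3:
                w = 0.875
            else:
                w = 1.0
            total += w
    return total


class TestWeightedArea:
    def test_empty_grid(self):
        assert rx.weighted_area(np.zeros((5, 5), dtype=bool)) == 0.0

    def test_single_pixel_is_one(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = True
        # four windows contain the pixel, each weight 1/4
        assert rx.weighted_area(m) == pytest.approx(1.0)

    def test_two_by_two_block_is_four(self):
        m = np.zeros((6, 6), dtype=bool)
        m[2:4, 2:4] = True
        # 1 full window + 4 two-adjacent + 4 single-corner windows
        assert rx.weighted_area(m) == pytest.approx(1.0 + 4 * 0.5 + 4 * 0.25)

    @pytest.mark.parametrize("h", range(1, 7))
    @pytest.mark.parametrize("w", range(1, 7))
    def test_solid_rectangles_equal_pixel_count(self, h, w):
        m = np.zeros((h + 4, w + 4), dtype=bool)
        m[2 : 2 + h, 2 : 2 + w] = True
        assert rx.weighted_area(m) == pytest.approx(h * w)
        assert bwarea_window_enumeration(m) == pytest.approx(h * w)

    @given(
        hnp.arrays(dtype=bool, shape=st.tuples(st.integers(1, 8), st.integers(1, 8)))
    )
    def test_matches_window_enumeration_oracle(self, mask):
        assert rx.weighted_area(mask) == pytest.approx(bwarea_window_enumeration(mask))


class TestNCRatio:
    def test_worked_arithmetic(self):
        assert rx.nc_ratio(16.0, 116.0) == pytest.approx(0.16)

    def test_half_cell_nucleus_gives_unity(self):
        assert rx.nc_ratio(50.0, 100.0) == pytest.approx(1.0)

    def test_degenerate_cytoplasm_rejected(self):
        with pytest.raises(DegenerateCompartmentError):
            rx.nc_ratio(100.0, 100.0)

    def test_mitotic_two_lobe_nucleus_matches_ground_truth(self):
        spec = rx.preset_spec(
            "tnbc_like", read_noise_sd=0.0, intensity_cv=0.0, cells_per_fov=3
        )
        fld, anns, gts = rx.generate_field(spec, "d", "f", seed=5, n_mitotic=3)
        for ann, gt in zip(anns, gts):
            assert ann.mitotic
            rec = rx.analyze_cell(fld, ann)
            assert rec.nc_ratio == pytest.approx(gt.nc_ratio, rel=0.02)
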