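import numpy as np
import pytest

from conftest import match_planted_counts
from fociquant.focus_quant import (CellFociRecord, FociDetectionConfig,
                                   PresetConfig, SingleCellQCError,
                                   count_foci_per_nucleus, detect_foci,
                                   patient_mean_foci, preset_enhance,
                                   quantify_image, segment_nuclei)
from fociquant.image_model import ImageSimParams, generate_image


class TestPresetEnhance:
    def test_constant_image_only_inverted_with_warning(self):
        img = np.full((16, 16), 40, dtype=np.uint8)
        with pytest.warns(UserWarning, match="constant"):
            out = preset_enhance(img)
        assert np.all(out == 255 - 40)

    def test_two_point_image_stretched_then_inverted(self):
        # {10, 200} with zero clip on 8-bit -> {0, 255} -> inverted {255, 0}
        img = np.full((10, 10), 10, dtype=np.uint8)
        img[5:, :] = 200
        cfg = PresetConfig(clip_fraction_low=0.0, clip_fraction_high=0.0)
        out = preset_enhance(img, cfg)
        assert set(np.unique(out)) == {0, 255}
        assert np.all(out[:5, :] == 255) and np.all(out[5:, :] == 0)

    def test_full_range_ramp_auto_steps_are_identity(self):
        ramp = np.tile(np.arange(256, dtype=np.uint8), (4, 1))
        cfg = PresetConfig(clip_fraction_low=0.0, clip_fraction_high=0.0)
        assert np.array_equal(preset_enhance(ramp, cfg), 255 - ramp)

    def test_double_application_restores_full_range_input(self):
        # invert is an involution and the zero-clip stretches are idempotent,
        # so the chain is an involution on a full-range single-band raster
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        img.flat[0], img.flat[1] = 0, 255
        cfg = PresetConfig(clip_fraction_low=0.0, clip_fraction_high=0.0)
        assert np.array_equal(preset_enhance(preset_enhance(img, cfg), cfg),
                              img)

    def test_three_band_desaturate_is_midchannel_gray(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        img[..., 1] = 100
        img[..., 2] = 200
        img[0, 0] = (0, 0, 255)  # pin the luminance range
        cfg = PresetConfig(clip_fraction_low=0.0, clip_fraction_high=0.0)
        out = preset_enhance(img.astype(float) / 255.0, cfg)
        assert out.shape == img.shape
        assert np.allclose(out[..., 0], out[..., 1])
        assert np.allclose(out[..., 1], out[..., 2])

    def test_output_dtype_matches_input(self):
        img = (np.arange(64, dtype=np.uint16).reshape(8, 8)) * 1000
        assert preset_enhance(img).dtype == np.uint16

    def test_invalid_clip_fraction_rejected(self):
        with pytest.raises(ValueError):
            preset_enhance(np.zeros((4, 4), dtype=np.uint8),
                           PresetConfig(clip_fraction_low=0.2))


class TestSegmentNuclei:
    def test_clean_round_nuclei_all_pass_qc(self):
        params = ImageSimParams(n_nuclei=20, image_width_px=448,
                                image_height_px=448, nucleus_radius_px=15,
                                deformed_fraction=0.0, noise_sd=150.0, seed=1)
        img, _ = generate_image(params)
        records = segment_nuclei(img.dapi)
        assert len(records) == 20
        assert all(r.qc_pass for r in records)

    def test_deformed_nuclei_excluded_at_planted_rate(self):
        # 100 planted nuclei, 30% deformed: QC exclusion inside the binomial
        # 95% band and every surviving nucleus is an intact one
        n_pass = n_planted = 0
        for s in range(5):
            params = ImageSimParams(n_nuclei=20, image_width_px=448,
                                    image_height_px=448, nucleus_radius_px=15,
                                    deformed_fraction=0.3, noise_sd=150.0,
                                    seed=600 + s)
            img, truth = generate_image(params)
            n_planted += len(truth.nuclei)
            n_pass += sum(r.qc_pass for r in segment_nuclei(img.dapi))
        excluded = 1.0 - n_pass / n_planted
        band = 1.96 * np.sqrt(0.3 * 0.7 / n_planted)
        assert abs(excluded - 0.3) < band

    def test_blank_image_yields_no_records(self):
        assert segment_nuclei(np.full((64, 64), 7.0)) == []

    def test_qc_invariant_holds_on_every_record(self):
        params = ImageSimParams(n_nuclei=20, image_width_px=448,
                                image_height_px=448, nucleus_radius_px=15,
                                deformed_fraction=0.4, noise_sd=150.0, seed=9)
        img, _ = generate_image(params)
        for r in segment_nuclei(img.dapi):
            if r.qc_pass:
                assert not r.touches_border
                assert r.solidity >= 0.85


class TestDetectFoci:
    @staticmethod
    def spot_image(centers, amplitude=15000.0, sigma=1.5, shape=(64, 64)):
        img = np.full(shape, 800.0)
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
        for r0, c0 in centers:
            img += amplitude * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2)
                                      / (2 * sigma ** 2))
        return img

    def test_single_spot_found_within_one_pixel(self):
        dets = detect_foci(self.spot_image([(31.3, 40.7)]))
        assert len(dets) == 1
        assert np.hypot(dets[0].row - 31.3, dets[0].col - 40.7) <= 1.0

    def test_no_spots_no_detections(self):
        assert detect_foci(self.spot_image([])) == []

    def test_close_pair_merged_keeping_stronger(self):
        img = self.spot_image([(32, 30)]) + \
            self.spot_image([(32, 32)], amplitude=8000.0) - 800.0
        dets = detect_foci(img)
        assert len(dets) == 1
        assert abs(dets[0].col - 30) <= 1.0  # the stronger one survives

    def test_bad_sigma_order_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            detect_foci(np.zeros((8, 8)),
                        FociDetectionConfig(sigma_min_px=3.0, sigma_max_px=1.0))

    def test_per_nucleus_count_error_small_under_noise(self):
        # ~500 nuclei at rate 4 with read noise: MAE of pipeline counts vs
        # planted counts at the default configuration
        errs = []
        for s in range(25):
            params = ImageSimParams(n_nuclei=20, image_width_px=448,
                                    image_height_px=448, nucleus_radius_px=15,
                                    focus_rate_lambda=4.0,
                                    deformed_fraction=0.0, noise_sd=200.0,
                                    seed=100 + s)
            img, truth = generate_image(params)
            records = quantify_image(img)
            errs.extend(abs(a - b)
                        for a, b in match_planted_counts(img, truth, records))
        assert len(errs) >= 500
        assert np.mean(errs) <= 0.5


class TestCounting:
    def test_noiseless_pipeline_counts_equal_planted(self, noiseless_batch):
        pairs = []
        for img, truth in noiseless_batch:
            pairs.extend(match_planted_counts(img, truth, quantify_image(img)))
        assert len(pairs) == 210
        assert all(a == b for a, b in pairs)

    def test_counting_is_order_independent(self, noiseless_batch):
        img, _ = noiseless_batch[0]
        from fociquant.focus_quant import _dtype_vmax, preset_enhance
        bright = _dtype_vmax(img.cy3) - preset_enhance(img.cy3).astype(float)
        dets = detect_foci(bright)
        nuclei = segment_nuclei(img.dapi)
        forward = count_foci_per_nucleus(dets, nuclei)
        reverse = count_foci_per_nucleus(dets[::-1], nuclei)
        assert {r.nucleus_label: r.foci_count for r in forward} == \
               {r.nucleus_label: r.foci_count for r in reverse}

    def test_background_detection_discarded_and_zero_counts_kept(self):
        params = ImageSimParams(n_nuclei=5, image_width_px=256,
                                image_height_px=256, nucleus_radius_px=12,
                                focus_rate_lambda=0.0, deformed_fraction=0.0,
                                noise_sd=0.0, seed=2)
        img, _ = generate_image(params)
        nuclei = segment_nuclei(img.dapi)
        from fociquant.focus_quant import FocusDetection
        fake = [FocusDetection(row=2.0, col=2.0, sigma_px=1.5, response=1.0)]
        records = count_foci_per_nucleus(fake, nuclei)
        assert len(records) == 5
        assert all(r.foci_count == 0 for r in records)

    def test_record_invariant_count_matches_positions(self):
        with pytest.raises(ValueError):
            CellFociRecord(image_id="x", nucleus_label=1, foci_count=2,
                           foci_xy=((1.0, 1.0),))


class TestPatientMean:
    def test_equal_counts_have_zero_sem(self):
        recs = [CellFociRecord("i", k, 2, ((0.0, 0.0), (1.0, 1.0)))
                for k in range(3)]
        mean, sem, n = patient_mean_foci(recs)
        assert (mean, sem, n) == (2.0, 0.0, 3)

    def test_hand_computed_sem(self):
        recs = [CellFociRecord("i", k, c, tuple((float(j), 0.0)
                                                for j in range(c)))
                for k, c in enumerate([0, 4, 8])]
        mean, sem, n = patient_mean_foci(recs)
        assert mean == 4.0 and n == 3
        assert sem == pytest.approx(4.0 / np.sqrt(3), abs=1e-9)

    def test_no_cells_is_an_error(self):
        with pytest.raises(SingleCellQCError):
            patient_mean_foci([])

    def test_pooled_mean_near_true_rate(self, noiseless_batch):
        # one simulated patient, 210 cells at rate 4.25: CLT band of 3 SE
        records = []
        for img, _ in noiseless_batch:
            records.extend(quantify_image(img))
        mean, _, n = patient_mean_foci(records)
        assert n == 210
        assert abs(mean - 4.25) < 3 * np.sqrt(4.25 / n)
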