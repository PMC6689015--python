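"""Ventricular segmentation, volumetry and the comparison statistics."""

import numpy as np
import pytest

from cine5d.benchmarks import dice
from cine5d.function import (FunctionReport, SegmentationParams,
                             chamber_volumes, compare_phases, hough_lv_init,
                             levelset_segment, rv_segment)


def _disk_image(shape=(64, 64), center=(30, 34), radius=10, value=1.0,
                background=0.15):
    X, Y = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                       indexing="ij")
    img = np.full(shape, background)
    mask = (X - center[0]) ** 2 + (Y - center[1]) ** 2 <= radius**2
    img[mask] = value
    return img, mask


class TestHoughInit:
    def test_disk_radius_recovered_within_2mm(self):
        img, _ = _disk_image(radius=10)          # 2 mm pixels -> 20 mm
        circles = hough_lv_init(img[:, :, None], (2.0, 2.0, 8.0))
        cx, cy, r = circles[0]
        assert abs(r * 2.0 - 20.0) <= 2.0
        assert abs(cx - 30) <= 1 and abs(cy - 34) <= 1

    def test_blank_image_flagged_not_crashing(self):
        circles = hough_lv_init(np.zeros((32, 32, 2)), (2.0, 2.0, 8.0))
        assert circles == [None, None]

    def test_radius_range_selects_the_in_range_disk(self):
        img, _ = _disk_image(center=(20, 20), radius=10)
        img2, _ = _disk_image(center=(48, 48), radius=4)
        both = np.maximum(img, img2)
        circles = hough_lv_init(both[:, :, None], (2.0, 2.0, 8.0),
                                radius_range_mm=(14.0, 26.0))
        cx, cy, r = circles[0]
        assert np.hypot(cx - 20, cy - 20) <= 2   # the 20 mm disk wins


class TestLevelSet:
    def test_bright_disk_dice(self):
        img, mask = _disk_image()
        out = levelset_segment(img[:, :, None], [(30.0, 34.0, 10.0)])
        assert dice(out.masks[0][:, :, 0], mask) > 0.95

    def test_ellipse_beyond_circular_init(self):
        X, Y = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        ell = ((X - 30) / 15.0) ** 2 + ((Y - 34) / 10.0) ** 2 <= 1
        img = np.full((64, 64), 0.15)
        img[ell] = 1.0
        out = levelset_segment(img[:, :, None], [(30.0, 34.0, 10.0)])
        assert dice(out.masks[0][:, :, 0], ell) > 0.9

    def test_init_outside_cavity_is_flagged(self):
        img, mask = _disk_image(center=(16, 16), radius=6)
        out = levelset_segment(img[:, :, None], [(50.0, 50.0, 6.0)])
        assert out.flags        # leakage / no-contrast / collapse flag
        assert dice(out.masks[0][:, :, 0], mask) < 0.5


class TestRvSegment:
    @staticmethod
    def _crescent():
        X, Y = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        outer = ((X - 32) / 16.0) ** 2 + ((Y - 30) / 14.0) ** 2 <= 1
        bite = ((X - 32) / 20.0) ** 2 + ((Y - 14) / 16.0) ** 2 <= 1
        cres = outer & ~bite
        img = np.full((64, 64), 0.15)
        img[cres] = 0.9
        return img, cres

    def test_crescent_dice(self):
        img, cres = self._crescent()
        out = rv_segment(img[:, :, None], (32.0, 32.0, 17.5))
        assert dice(out.masks[0][:, :, 0], cres) > 0.85

    def test_determinism(self):
        img, _ = self._crescent()
        a = rv_segment(img[:, :, None], (32.0, 32.0, 17.5))
        b = rv_segment(img[:, :, None], (32.0, 32.0, 17.5))
        assert np.array_equal(a.masks, b.masks)

    def test_seed_missing_target_is_flagged_or_empty(self):
        img, _ = self._crescent()
        out = rv_segment(img[:, :, None], (8.0, 55.0, 5.0))
        assert out.flags or not out.masks.any()


class TestChamberVolumes:
    def test_constant_volume_zero_ef(self):
        masks = np.ones((3, 10, 10, 4), bool)
        res = chamber_volumes(masks, (5.0, 5.0, 5.0))
        assert res["SV_mL"] == 0.0 and res["EF_pct"] == 0.0

    def test_forty_over_hundred_is_sixty_percent(self):
        vox = (10.0, 10.0, 10.0)   # 1 mL voxels
        masks = np.zeros((2, 10, 10, 2), bool)
        masks[0].flat[:100] = True     # EDV 100 mL
        masks[1].flat[:40] = True      # ESV 40 mL
        res = chamber_volumes(masks, vox)
        assert res["EDV_mL"] == 100.0 and res["ESV_mL"] == 40.0
        assert res["SV_mL"] == 60.0 and res["EF_pct"] == pytest.approx(60.0)

    def test_empty_masks_flag_nan_ef(self):
        res = chamber_volumes(np.zeros((2, 4, 4, 2), bool), (1, 1, 1))
        assert np.isnan(res["EF_pct"])

    def test_needs_two_phases(self):
        with pytest.raises(ValueError):
            chamber_volumes(np.ones((1, 4, 4, 2), bool), (1, 1, 1))


class TestComparePhases:
    def test_identical_vectors_t_zero_p_one(self):
        v = np.array([10.0, 12.0, 14.0, 13.0])
        out = compare_phases(v, v.copy())
        assert out["paired_t"]["p"] == pytest.approx(1.0)
        assert np.isnan(out["paired_t"]["statistic"]) \
            or out["paired_t"]["statistic"] == pytest.approx(0.0)

    def test_mean_change_percent_hand_computed(self):
        # per-pair changes: +10%, +8.333%, +7.143% -> mean 8.49%
        out = compare_phases(np.array([10.0, 12.0, 14.0]),
                             np.array([11.0, 13.0, 15.0]))
        assert out["change_pct_mean"] == pytest.approx(8.492, abs=0.01)

    def test_perfect_correlation(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        out = compare_phases(a, a + 1,
                             corr_pairs=[(a, 2 * a + 3, "linear")])
        assert out["correlations"]["linear"]["r"] == pytest.approx(1.0)

    def test_small_n_skips_tests(self):
        out = compare_phases(np.array([1.0, 2.0]), np.array([2.0, 3.0]))
        assert "skipped" in out["paired_t"]

    def test_mann_whitney_between_groups(self):
        ee = np.array([1.0, 1.2, 0.9, 5.0, 5.2, 4.9])
        out = compare_phases(ee, ee + 0.1,
                             group_labels=np.array([0, 0, 0, 1, 1, 1]))
        assert out["mann_whitney"]["p"] < 0.2


class TestFunctionReport:
    def test_json_round_trip(self):
        rep = FunctionReport(
            measurements={"LV": {"EE": {"ESV_mL": 40.0, "EDV_mL": 100.0,
                                        "SV_mL": 60.0, "EF_pct": 60.0},
                                 "EI": {"ESV_mL": 42.0, "EDV_mL": 99.0,
                                        "SV_mL": 57.0, "EF_pct": 57.6}}},
            resp_metrics={"Respiratory Depth (mm)": 5.3},
            qc_flags=["slice 0: no initialisation"])
        text = rep.to_json()
        back = FunctionReport.from_json(text)
        assert back.measurements == rep.measurements
        assert back.resp_metrics == rep.resp_metrics
        assert back.qc_flags == rep.qc_flags
        assert back.change_pct("LV", "ESV_mL") == pytest.approx(5.0)

    def test_table_layout(self):
        rep = FunctionReport(
            measurements={"LV": {"EE": {"ESV_mL": 40.0, "EDV_mL": 100.0,
                                        "SV_mL": 60.0, "EF_pct": 60.0},
                                 "EI": {"ESV_mL": 42.0, "EDV_mL": 99.0,
                                        "SV_mL": 57.0, "EF_pct": 57.6}}})
        df = rep.to_table()
        assert set(df.columns) >= {"ventricle", "phase", "ESV_mL", "EDV_mL",
                                   "SV_mL", "EF_pct", "change_pct"}
        ei = df[(df.ventricle == "LV") & (df.phase == "EI")].iloc[0]
        assert ei["change_pct"] == pytest.approx((57.6 - 60) / 60 * 100)
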