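"""Generator determinism, truth-field calibration, and mask growth."""

import math

import numpy as np
import pytest

from ccflow import (
    ScanGeometry,
    SyntheticConfig,
    generate_cohort,
    grow_mask,
    lesion_area,
    simulate_eye_records,
)
from conftest import circle_mask


class TestGrowMask:
    def test_circle_grows_to_analytic_area(self):
        g = ScanGeometry(512, 6.0)
        m0 = circle_mask(g, 0.5)
        m1 = grow_mask(m0, 0.1, 1.0)
        assert lesion_area(m1) == pytest.approx(math.pi * 0.36, rel=0.02)

    def test_zero_speed_is_identity(self):
        g = ScanGeometry(256, 6.0)
        m0 = circle_mask(g, 0.4)
        m1 = grow_mask(m0, 0.0, 1.0)
        assert np.array_equal(m0.pixels, m1.pixels)

    def test_nearby_foci_merge_when_growth_bridges_gap(self):
        # two r=0.3 mm circles 0.7 mm apart (centers): after growing 0.1 mm
        # each radius is 0.4 and 2*0.4 = 0.8 > 0.7 -> one component
        from scipy import ndimage

        g = ScanGeometry(512, 6.0)
        px = g.mm_per_px
        m = circle_mask(g, 0.3, center_px=(200, 256)).pixels
        m |= circle_mask(g, 0.3, center_px=(200 + 0.7 / px, 256)).pixels
        from ccflow import LesionMask

        m0 = LesionMask(m, g)
        _, n0 = ndimage.label(m0.pixels, structure=np.ones((3, 3)))
        m1 = grow_mask(m0, 0.1, 1.0)
        _, n1 = ndimage.label(m1.pixels, structure=np.ones((3, 3)))
        assert n0 == 2 and n1 == 1

    def test_negative_speed_rejected(self):
        g = ScanGeometry(256, 6.0)
        with pytest.raises(ValueError):
            grow_mask(circle_mask(g, 0.3), -0.1, 1.0)


class TestCohortGeneration:
    def test_determinism_bit_identical(self):
        cfg = SyntheticConfig(n_patients=2, eyes_per_patient=2, grid_px=128, seed=13)
        b1, t1, c1 = generate_cohort(cfg)
        b2, t2, c2 = generate_cohort(cfg)
        for x, y in zip(b1, b2):
            assert np.array_equal(x.flow.pixels, y.flow.pixels)
            assert np.array_equal(x.structure.pixels, y.structure.pixels)
            assert np.array_equal(x.mask_t0.pixels, y.mask_t0.pixels)
            assert np.array_equal(x.mask_t1.pixels, y.mask_t1.pixels)
        assert t1.equals(t2)
        assert c1.equals(c2)

    def test_truth_invariants(self):
        cfg = SyntheticConfig(n_patients=4, eyes_per_patient=2, grid_px=256, seed=2)
        _, truth, cohort = generate_cohort(cfg)
        assert (truth["followup_area"] >= truth["baseline_area"]).all()
        for col in ["true_void_frac_out", "true_void_frac_para", "true_void_frac_peri"]:
            assert truth[col].between(0, 1).all()
        assert (truth["fu_years"] >= 1.0).all()
        assert len(truth) == 8
        assert cohort["patient_id"].nunique() == 4

    def test_realized_void_fraction_matches_truth_field(self):
        # realized fraction of suppressed pixels per region vs the stored
        # mean of the void-probability field: within one percentage point
        from ccflow import BinarizationParams, build_regions

        cfg = SyntheticConfig(
            n_patients=1, eyes_per_patient=1, grid_px=512, seed=31,
            drusen_density=0.0, texture_noise_sd=0.0,
            area_log_mean=math.log(3.0), area_log_sd=0.1,  # large lesion, wide rings
        )
        bundles, truth, _ = generate_cohort(cfg)
        b = bundles[0]
        realized = b.flow.pixels < (cfg.void_level + cfg.signal_level) / 2
        rs = build_regions(b.mask_t0)
        for region, col in [
            (rs.outside, "true_void_frac_out"),
            (rs.para, "true_void_frac_para"),
            (rs.peri, "true_void_frac_peri"),
        ]:
            assert realized[region].mean() == pytest.approx(truth[col][0], abs=0.01)

    def test_no_effect_null_has_no_ring_gradient(self):
        # flat void field: expected FV_500 - FV_1000 is zero up to sampling
        cfg = SyntheticConfig(
            n_patients=6, eyes_per_patient=1, grid_px=256, seed=8,
            ring_excess_range=(0.0, 0.0), eccentricity_gradient=0.0,
            growth_coupling=0.0, drusen_density=0.0,
        )
        bundles, truth, _ = generate_cohort(cfg)
        assert np.allclose(truth["true_void_frac_para"], truth["true_void_frac_peri"])
        from ccflow import BinarizationParams
        from ccflow.run import analyze_bundles

        res = analyze_bundles(bundles, bin_params=BinarizationParams(radius_px=4))
        assert abs(res["dfv"].mean()) < 1.0

    def test_decoupled_null_breaks_speed_excess_correlation(self):
        cfg = SyntheticConfig(
            n_patients=50, eyes_per_patient=1, grid_px=128, seed=4, growth_coupling=0.0
        )
        _, truth, _ = generate_cohort(cfg)
        r = np.corrcoef(truth["true_edge_speed"], truth["true_ring_excess"])[0, 1]
        assert abs(r) < 0.2

    def test_sqrt_transform_removes_baseline_dependence(self):
        # equal edge speed across a 25x range of baseline areas -> equal yGR
        from ccflow import compute_ygr

        g = ScanGeometry(512, 6.0)
        ygrs = []
        for area in np.linspace(0.2, 5.0, 8):
            m0 = circle_mask(g, math.sqrt(area / math.pi))
            m1 = grow_mask(m0, 0.13, 1.2)
            ygrs.append(compute_ygr(lesion_area(m0), lesion_area(m1), 1.2))
        cv = np.std(ygrs) / np.mean(ygrs)
        assert cv < 0.05

    def test_border_truncated_eye_flagged(self):
        # a huge fast-growing lesion must hit the scan edge and be flagged
        cfg = SyntheticConfig(
            n_patients=1, eyes_per_patient=1, grid_px=256, seed=3,
            area_log_mean=math.log(7.9), area_log_sd=0.01,
            base_edge_speed=1.2, edge_speed_sd=0.0, growth_coupling=0.0,
        )
        _, truth, _ = generate_cohort(cfg)
        assert bool(truth["border_truncated"][0])

    def test_disk_roundtrip(self, tmp_path):
        cfg = SyntheticConfig(n_patients=1, eyes_per_patient=2, grid_px=128, seed=6)
        bundles, truth, cohort = generate_cohort(cfg, outdir=tmp_path)
        from ccflow.run import _bundles_from_directory

        loaded = _bundles_from_directory(tmp_path)
        assert len(loaded) == 2
        for orig, back in zip(bundles, loaded):
            assert np.array_equal(orig.mask_t0.pixels, back.mask_t0.pixels)
            # 16-bit quantization on the way to disk
            assert np.abs(orig.flow.pixels - back.flow.pixels).max() < 1e-4


class TestRecordSimulator:
    def test_dfv_identity_and_clustering(self):
        cfg = SyntheticConfig(n_patients=10)
        df = simulate_eye_records(cfg, np.random.default_rng(0))
        assert np.allclose(df["dfv"], df["fv_500"] - df["fv_1000"])
        assert df["patient_id"].nunique() == 10
        assert len(df) == 20

    def test_expected_dfv_tracks_excess_range(self):
        cfg = SyntheticConfig(n_patients=400, ring_excess_range=(0.04, 0.04))
        df = simulate_eye_records(cfg, np.random.default_rng(1))
        # excess fixed at 0.04 -> expected measured dFV = 50 * 0.04 = 2 points
        assert df["dfv"].mean() == pytest.approx(2.0, abs=0.2)
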