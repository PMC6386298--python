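"""Flow-void percentages, growth rates, and the per-eye pipeline."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccflow import (
    BinarizationParams,
    BinaryFlowMap,
    ScanGeometry,
    SyntheticConfig,
    analyze_eye,
    build_regions,
    compute_ygr,
    fv_percentage,
    generate_cohort,
)


def _voids(arr, geom):
    return BinaryFlowMap(np.asarray(arr, bool), geom)


class TestFvPercentage:
    def test_all_void_region_is_100(self, geom256):
        vm = _voids(np.ones((256, 256)), geom256)
        region = np.zeros((256, 256), bool)
        region[10:20, 10:20] = True
        assert fv_percentage(vm, region) == 100.0

    def test_counting_arithmetic(self, geom256):
        voids = np.zeros((256, 256), bool)
        region = np.zeros((256, 256), bool)
        region[0, :200] = True
        voids[0, :50] = True
        assert fv_percentage(_voids(voids, geom256), region) == 25.0

    def test_empty_region_error_names_region(self, geom256):
        vm = _voids(np.zeros((256, 256)), geom256)
        with pytest.raises(ValueError, match="para"):
            fv_percentage(vm, np.zeros((256, 256), bool), name="para")


class TestComputeYgr:
    @pytest.mark.parametrize(
        "a0, a1, fu, expected",
        [
            (1.0, 4.0, 1.0, 1.0),  # perfect squares
            (2.5, 2.5, 1.3, 0.0),  # no growth
            (0.8, 1.63, 1.31, 0.2918),  # typical GA medians over a 1.31-yr follow-up
        ],
    )
    def test_closed_form(self, a0, a1, fu, expected):
        assert compute_ygr(a0, a1, fu) == pytest.approx(expected, abs=1e-4)

    def test_negative_growth_passes_through(self):
        assert compute_ygr(4.0, 1.0, 1.0) == -1.0

    def test_nonpositive_followup_rejected(self):
        with pytest.raises(ValueError):
            compute_ygr(1.0, 2.0, 0.0)

    @given(
        a0=st.floats(0.0, 30.0),
        a1=st.floats(0.0, 36.0),
        fu=st.floats(1.0, 3.0),
        k=st.floats(0.1, 3.0),
    )
    @settings(derandomize=True, max_examples=200)
    def test_sign_and_area_scaling_properties(self, a0, a1, fu, k):
        # growth sign follows the area ordering, and scaling both areas by
        # k^2 scales yGR by k (the transform lives on a length scale)
        y = compute_ygr(a0, a1, fu)
        assert (y >= 0) == (a1 >= a0)
        assert compute_ygr(k**2 * a0, k**2 * a1, fu) == pytest.approx(k * y, rel=1e-9, abs=1e-12)


def _one_eye_bundle(**overrides):
    kw = dict(
        n_patients=1, eyes_per_patient=1, grid_px=256, seed=9, drusen_density=0.5
    )
    kw.update(overrides)
    bundles, truth, _ = generate_cohort(SyntheticConfig(**kw))
    return bundles[0], truth


BIN256 = BinarizationParams(radius_px=4)  # ~94 µm window on a 256 px / 6 mm grid


class TestAnalyzeEye:
    def test_null_eye_has_small_dfv(self):
        b, _ = _one_eye_bundle(ring_excess_range=(0.0, 0.0), eccentricity_gradient=0.0)
        rec = analyze_eye(
            b.flow, b.structure, b.mask_t0, b.mask_t1,
            eye_id=b.eye_id, patient_id=b.patient_id, fu_years=b.fu_years,
            bin_params=BIN256,
        )
        assert abs(rec.dfv) < 2.0

    def test_identity_visit_gives_zero_growth_and_same_fv(self):
        b, _ = _one_eye_bundle()
        rec = analyze_eye(
            b.flow, b.structure, b.mask_t0, b.mask_t0,
            eye_id=b.eye_id, patient_id=b.patient_id, fu_years=b.fu_years,
            bin_params=BIN256,
        )
        assert rec.ygr == 0.0
        assert rec.area_baseline_mm2 == rec.area_followup_mm2

    def test_dfv_additivity_to_machine_precision(self):
        b, _ = _one_eye_bundle()
        rec = analyze_eye(
            b.flow, b.structure, b.mask_t0, b.mask_t1,
            eye_id=b.eye_id, patient_id=b.patient_id, fu_years=b.fu_years,
            bin_params=BIN256,
        )
        assert rec.dfv == rec.fv_500 - rec.fv_1000

    def test_errors_carry_eye_context(self):
        b, _ = _one_eye_bundle()
        from ccflow import LesionMask

        empty = LesionMask(np.zeros_like(b.mask_t0.pixels), b.mask_t0.geometry)
        with pytest.raises(RuntimeError, match=b.eye_id):
            analyze_eye(
                b.flow, b.structure, empty, empty,
                eye_id=b.eye_id, patient_id=b.patient_id, fu_years=b.fu_years,
                bin_params=BIN256,
            )

    def test_regression_frozen_record(self):
        """Fixed 128 px bundle: the record must be stable across runs/platforms."""
        bundles, _, _ = generate_cohort(
            SyntheticConfig(n_patients=1, eyes_per_patient=1, grid_px=128, seed=77)
        )
        b = bundles[0]
        rec = analyze_eye(
            b.flow, b.structure, b.mask_t0, b.mask_t1,
            eye_id=b.eye_id, patient_id=b.patient_id, fu_years=b.fu_years,
            bin_params=BinarizationParams(radius_px=2),
        )
        frozen = FROZEN_128PX_RECORD
        for key, value in frozen.items():
            assert getattr(rec, key) == pytest.approx(value, abs=1e-9), key


# Captured once from the deterministic 128 px / seed 77 bundle above.
FROZEN_128PX_RECORD = {
    "area_baseline_mm2": 0.283447265625,
    "area_followup_mm2": 4.524169921875,
    "fu_years": 1.3515032164889527,
    "ygr": 1.1798802568334206,
    "fv_out": 40.11688711165795,
    "fv_500": 50.42219541616405,
    "fv_1000": 43.73810430148458,
    "dfv": 6.684091114679468,
    "fv_out_beyond": 37.89473684210526,
    "fovea_dist_mm": 1.3091144322808914,
}


class TestScaleConsistency:
    def test_fv_stable_when_grid_doubles(self):
        # same cohort conditions sampled at 256 and 512 px with the window
        # radius scaled to hold its physical size: mean FV shifts < 1 point.
        # (Texture realizations are grid-specific, so the comparison is on
        # the 6-eye mean, where realization noise is well below a point.)
        from ccflow.run import analyze_bundles

        means = {}
        for grid, radius in ((256, 4), (512, 8)):
            bundles, _, _ = generate_cohort(
                SyntheticConfig(
                    n_patients=6, eyes_per_patient=1, grid_px=grid, seed=21, drusen_density=0.5
                )
            )
            res = analyze_bundles(bundles, bin_params=BinarizationParams(radius_px=radius))
            means[grid] = res[["fv_out", "fv_500", "fv_1000"]].mean()
        for attr in ("fv_out", "fv_500", "fv_1000"):
            assert abs(means[256][attr] - means[512][attr]) < 1.0


class TestBaselineIndependence:
    def test_ygr_uncorrelated_with_baseline_area_at_equal_speed(self):
        # circles from 0.2 to 5 mm^2 all growing at the same edge speed
        from ccflow import grow_mask, lesion_area
        from conftest import circle_mask

        g = ScanGeometry(512, 6.0)
        ygrs, areas = [], []
        for area in np.linspace(0.2, 5.0, 30):
            r = math.sqrt(area / math.pi)
            m0 = circle_mask(g, r)
            m1 = grow_mask(m0, 0.13, 1.0)
            a0, a1 = lesion_area(m0), lesion_area(m1)
            areas.append(a0)
            ygrs.append(compute_ygr(a0, a1, 1.0))
        r_corr = np.corrcoef(areas, ygrs)[0, 1]
        assert abs(r_corr) < 0.1
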