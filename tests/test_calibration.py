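"""Adaptive calibration sessions, curve fitting, and state persistence."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromaflow import (
    BUILTIN_ASSAYS,
    AbsorbanceReading,
    Channel,
    Role,
    adaptive_factor,
    check_water,
    estimate_concentration,
    fit_curve,
    load_state,
    measure_sample,
    render_sample,
    run_session,
    save_state,
    scene_for_assay,
    validate_linearity,
)
from chromaflow.calibration import CalibrationState
from chromaflow.errors import (
    CalibrationFailureError,
    DegenerateBlankError,
    FormatError,
    MustCalibrateError,
    ParameterError,
    WaterCheckError,
)
from chromaflow.imaging import RawRGB


def reading(value, channel=Channel.GREEN):
    vals = [0.0, 0.0, 0.0]
    vals[channel.index] = value
    return AbsorbanceReading(*vals, channel=channel)


class TestWaterCheck:
    @pytest.mark.parametrize(
        "value,tol,ok",
        [(0.001, 0.02, True), (0.5, 0.02, False), (-0.015, 0.02, True),
         (-0.03, 0.02, False)],
    )
    def test_symmetric_band(self, value, tol, ok):
        assert check_water(reading(value), tol) is ok

    def test_tolerance_must_be_positive(self):
        with pytest.raises(ParameterError):
            check_water(reading(0.0), 0.0)


class TestFitCurve:
    def test_exact_line(self):
        slope, r2 = fit_curve([(1, 0.05), (2, 0.10), (4, 0.20)])
        assert slope == pytest.approx(0.05, abs=1e-15)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_single_point_ratio(self):
        slope, _ = fit_curve([(8, 0.40)])
        assert slope == pytest.approx(0.05)

    def test_matches_closed_form_oracle_on_noisy_points(self):
        rng = np.random.default_rng(42)
        c = rng.uniform(0.5, 30, size=6)
        a = 0.05 * c + rng.normal(0, 0.005, size=6)
        slope, _ = fit_curve(list(zip(c, a)))
        oracle = np.sum(c * a) / np.sum(c * c)
        assert slope == pytest.approx(oracle, abs=1e-12)

    def test_all_zero_concentrations_degenerate(self):
        with pytest.raises(ParameterError, match="degenerate"):
            fit_curve([(0, 0.0), (0, 0.01)])

    def test_negative_slope_is_calibration_failure(self):
        with pytest.raises(CalibrationFailureError):
            fit_curve([(1, -0.05), (2, -0.10)])

    def test_linearity_gate(self):
        # strongly curved data fails the R^2 >= 0.99 gate
        c = np.array([1, 2, 4, 8, 16, 30.0])
        a = 0.4 * np.sqrt(c)
        with pytest.raises(CalibrationFailureError, match="R\\^2"):
            validate_linearity(list(zip(c, a)))
        slope, r2 = validate_linearity([(x, 0.05 * x) for x in c])
        assert r2 >= 0.99 and slope == pytest.approx(0.05)


class TestAdaptiveFactor:
    @pytest.mark.parametrize(
        "assay_id,a_std,expected",
        [("uric_acid", 0.40, 20.0), ("creatinine", 0.25, 8.0)],
    )
    def test_factor_is_standard_over_absorbance(self, assay_id, a_std, expected):
        assert adaptive_factor(a_std, BUILTIN_ASSAYS[assay_id]) == pytest.approx(expected)

    def test_zero_absorbance_fails(self):
        with pytest.raises(CalibrationFailureError):
            adaptive_factor(0.0, BUILTIN_ASSAYS["uric_acid"])

    def test_single_point_fit_is_reciprocal_of_factor(self):
        assay = BUILTIN_ASSAYS["uric_acid"]
        a_std = 0.37
        slope, _ = fit_curve([(assay.standard_concentration, a_std)])
        assert slope == pytest.approx(1.0 / adaptive_factor(a_std, assay), rel=1e-12)


def make_state(factor=20.0, water_ok=True, assay_id="uric_acid"):
    return CalibrationState(
        assay_id=assay_id,
        water_ok=water_ok,
        blank_rgb=RawRGB(200, 200, 200),
        curve_points=[(8.0, 0.4)],
        slope=1.0 / factor,
        factor=factor,
        created_at="2026-01-01T00:00:00+00:00",
        session_label="test",
    )


class TestEstimateConcentration:
    def test_linear_scaling(self):
        res = estimate_concentration(0.20, make_state(20.0), BUILTIN_ASSAYS["uric_acid"])
        assert res.value == pytest.approx(4.0)
        assert res.in_linear_range

    def test_reference_interval_inference(self):
        assay = BUILTIN_ASSAYS["creatinine"]
        state = make_state(8.0, assay_id="creatinine")
        assert estimate_concentration(1.0 / 8.0, state, assay).inference == "within_reference"
        assert estimate_concentration(0.0, state, assay).inference == "below_reference"
        assert estimate_concentration(2.0 / 8.0 + 0.2, state, assay).inference == "above_reference"

    def test_no_reference_interval(self):
        res = estimate_concentration(0.2, make_state(), BUILTIN_ASSAYS["uric_acid"])
        assert res.inference == "no_reference"

    def test_out_of_linear_range_flagged_not_truncated(self):
        res = estimate_concentration(2.0, make_state(20.0), BUILTIN_ASSAYS["uric_acid"])
        assert res.value == pytest.approx(40.0)
        assert not res.in_linear_range

    def test_invalid_state_requires_calibration(self):
        with pytest.raises(MustCalibrateError):
            estimate_concentration(0.2, make_state(water_ok=False),
                                   BUILTIN_ASSAYS["uric_acid"])

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0.001, 2.0), st.floats(0.001, 2.0))
    def test_monotone_in_absorbance(self, a1, a2):
        lo = min(a1, a2)
        hi = max(a1, a2)
        if lo == hi:
            hi = lo + 1e-6
        state = make_state(20.0)
        assay = BUILTIN_ASSAYS["uric_acid"]
        assert (estimate_concentration(hi, state, assay).value
                > estimate_concentration(lo, state, assay).value)


class TestRunSession:
    def test_noise_free_triplet_gives_exact_factor(self, calibrated_session):
        state, assay, _ = calibrated_session("uric_acid")
        # scene absorptivity gives A_std = 0.4 at the 8 mg/dL standard
        assert state.factor == pytest.approx(20.0, rel=1e-6)
        assert state.water_ok and state.slope == pytest.approx(0.05, rel=1e-6)

    def test_contaminated_water_aborts(self):
        assay = BUILTIN_ASSAYS["uric_acid"]
        scene = scene_for_assay("uric_acid")
        # water rendered as if something absorbed 0.3 AU on the green channel
        contaminated = render_sample(0.3 / scene.absorptivity[1], Role.TEST, scene)
        contaminated = dataclasses.replace(contaminated, role=Role.WATER)
        blank = render_sample(0.0, Role.BLANK, scene)
        std = render_sample(8.0, Role.STANDARD, scene)
        with pytest.raises(WaterCheckError):
            run_session(contaminated, blank, std, assay)

    def test_zero_channel_blank_propagates_degenerate_error(self):
        import numpy as np

        from chromaflow.imaging import ImageSample

        assay = BUILTIN_ASSAYS["uric_acid"]
        scene = scene_for_assay("uric_acid")
        water = render_sample(0.0, Role.WATER, scene)
        std = render_sample(8.0, Role.STANDARD, scene)
        px = np.zeros((100, 100, 3))
        px[..., 0] = 100  # red alive, green/blue dead
        blank = ImageSample(pixels=px, role=Role.BLANK)
        with pytest.raises(DegenerateBlankError):
            run_session(water, blank, std, assay)

    def test_round_trip_recovers_truth(self, calibrated_session):
        state, assay, scene = calibrated_session("albumin")
        for conc in (0.5, 2.0, 4.0, 7.5):
            img = render_sample(conc, Role.TEST, scene, "albumin")
            res = measure_sample(img, state, assay)
            assert res.value == pytest.approx(conc, rel=1e-6)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        store = tmp_path / "store.json"
        state = make_state()
        save_state(state, store)
        loaded = load_state("uric_acid", store)
        assert loaded == state

    def test_never_calibrated_assay(self, tmp_path):
        store = tmp_path / "store.json"
        save_state(make_state(), store)
        with pytest.raises(MustCalibrateError):
            load_state("albumin", store)
        with pytest.raises(MustCalibrateError):
            load_state("uric_acid", tmp_path / "missing.json")

    def test_corrupted_store_names_file(self, tmp_path):
        store = tmp_path / "bad.json"
        store.write_text("{ not json")
        with pytest.raises(FormatError, match="bad.json"):
            load_state("uric_acid", store)

    def test_two_assays_coexist(self, tmp_path):
        store = tmp_path / "store.json"
        save_state(make_state(20.0, assay_id="uric_acid"), store)
        save_state(make_state(8.0, assay_id="creatinine"), store)
        assert load_state("uric_acid", store).factor == 20.0
        assert load_state("creatinine", store).factor == 8.0
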