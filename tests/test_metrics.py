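"""Microbeam metrics on synthetic profiles with closed-form ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrtsim.fixtures import SyntheticProfileSpec, generate_fixture
from mrtsim.metrics import (
    LateralProfile,
    MetricsError,
    calibrate_detector_psf,
    compute_metrics,
    detect_beams,
    valley_profile_summary,
)

STD = SyntheticProfileSpec()  # 49 beams, peak 3.0, valley 0.1, flank 25 um


def _metrics(spec=STD):
    prof = generate_fixture(spec)
    centers = detect_beams(prof, spec.pitch)
    return prof, centers, compute_metrics(prof, centers)


class TestDetectBeams:
    def test_finds_all_beams_on_the_pitch(self):
        prof = generate_fixture(STD)
        centers = detect_beams(prof, 400.0)
        assert len(centers) == 49
        assert np.allclose(np.diff(centers), 400.0, atol=1.0)

    def test_flat_profile_has_no_peaks(self):
        prof = LateralProfile(np.arange(0, 2000.0, 2.0), np.ones(1000))
        with pytest.raises(MetricsError, match="no peaks"):
            detect_beams(prof, 400.0)

    def test_missing_beam_leaves_a_double_gap(self):
        prof = generate_fixture(STD)
        # erase beam 25 down to the valley pedestal
        mask = np.abs(prof.positions) < 180.0
        prof.dose[mask] = 0.1
        centers = detect_beams(prof, 400.0)
        assert len(centers) == 48
        gaps = np.diff(centers)
        assert np.sum(np.abs(gaps - 800.0) < 40.0) == 1

    def test_profile_shorter_than_pitch_rejected(self):
        prof = LateralProfile(np.arange(0, 100.0, 2.0), np.ones(50))
        with pytest.raises(MetricsError, match="pitch"):
            detect_beams(prof, 400.0)


class TestComputeMetrics:
    def test_trapezoid_fixture_recovered_exactly(self):
        _, _, m = _metrics()
        interior = m.per_beam[~m.per_beam.edge_flag]
        assert np.allclose(interior.peak_dose, 3.0)
        assert np.allclose(interior.valley_dose, 0.1)
        assert np.allclose(interior.pvdr, 30.0)
        assert m.field["field_pvdr"] == pytest.approx(30.0, abs=1e-9)
        pens = interior[["penumbra_left_um", "penumbra_right_um"]].to_numpy()
        assert np.allclose(pens, 20.0, atol=0.02)

    def test_constant_profile_gives_unit_pvdr(self):
        x = np.arange(-600.0, 601.0, 2.0)
        prof = LateralProfile(x, np.full(len(x), 2.5))
        m = compute_metrics(prof, np.array([-400.0, 0.0, 400.0]))
        assert m.per_beam.iloc[1].pvdr == pytest.approx(1.0)

    def test_edge_beams_flagged_and_excluded_from_field_pvdr(self):
        _, _, m = _metrics()
        assert m.per_beam.edge_flag.sum() == 2
        assert m.per_beam.iloc[0].edge_flag and m.per_beam.iloc[-1].edge_flag

    def test_noisy_profiles_recover_pvdr_unbiased(self):
        vals = []
        for seed in range(200):
            spec = SyntheticProfileSpec(n_beams=9, noise_sd=0.01, seed=seed)
            prof = generate_fixture(spec)
            m = compute_metrics(prof, detect_beams(prof, 400.0))
            vals.append(m.field["field_pvdr"])
        assert np.mean(vals) == pytest.approx(30.0, rel=0.01)

    def test_scale_invariance(self):
        prof, centers, m0 = _metrics()
        scaled = LateralProfile(prof.positions, prof.dose * 7.5)
        m1 = compute_metrics(scaled, centers)
        assert m1.field["field_pvdr"] == pytest.approx(
            m0.field["field_pvdr"], rel=1e-12
        )
        assert m1.field["mean_penumbra_um"] == pytest.approx(
            m0.field["mean_penumbra_um"], rel=1e-12
        )
        assert m1.field["odd_even_alternation"] == pytest.approx(
            m0.field["odd_even_alternation"], abs=1e-12
        )
        assert m1.field["mean_peak"] == pytest.approx(
            7.5 * m0.field["mean_peak"], rel=1e-12
        )
        assert np.allclose(
            m1.per_beam.valley_dose, 7.5 * m0.per_beam.valley_dose
        )

    def test_translation_invariance(self):
        prof, centers, m0 = _metrics()
        shifted = LateralProfile(prof.positions + 1234.0, prof.dose)
        m1 = compute_metrics(shifted, centers + 1234.0)
        for key in ("field_pvdr", "mean_peak", "mean_penumbra_um"):
            assert m1.field[key] == pytest.approx(m0.field[key], rel=1e-12)

    @given(
        peak=st.floats(1.0, 100.0),
        valley=st.floats(0.01, 0.5),
        flank=st.floats(15.0, 60.0),
        plateau=st.floats(10.0, 60.0),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_window_exactness_for_any_valid_fixture(self, peak, valley,
                                                    flank, plateau):
        if peak <= valley * 12:  # keep the 10% level above the pedestal
            return
        try:
            spec = SyntheticProfileSpec(
                n_beams=9, peak_dose=peak, valley_dose=valley,
                flank_width=flank, plateau_width=plateau,
            )
        except ValueError:
            return
        prof = generate_fixture(spec)
        m = compute_metrics(prof, detect_beams(prof, spec.pitch))
        interior = m.per_beam[~m.per_beam.edge_flag]
        assert np.allclose(interior.peak_dose, peak, rtol=1e-9)
        assert np.allclose(interior.valley_dose, valley, rtol=1e-9)
        assert np.allclose(interior.pvdr, peak / valley, rtol=1e-9)


class TestPsfCalibration:
    def test_target_equal_to_unconvolved_gives_zero_sigma(self):
        prof = generate_fixture(STD)
        base = compute_metrics(
            prof, detect_beams(prof, 400.0)
        ).per_beam.iloc[24]
        target = float(np.mean([base.penumbra_left_um,
                                base.penumbra_right_um]))
        assert calibrate_detector_psf(prof, target) == 0.0

    def test_sharp_edge_yields_gaussian_closed_form(self):
        # near-step flanks over a negligible pedestal: the 10-90% width of a
        # Gaussian-blurred step is 2.5631 sigma
        spec = SyntheticProfileSpec(flank_width=1.0, plateau_width=60.0,
                                    valley_dose=0.01)
        prof = generate_fixture(spec)
        sigma = calibrate_detector_psf(prof, 20.0)
        assert sigma == pytest.approx(20.0 / 2.5631, rel=0.03)

    def test_unreachable_target_rejected(self):
        prof = generate_fixture(STD)
        with pytest.raises(MetricsError, match="narrower"):
            calibrate_detector_psf(prof, 5.0)

    def test_psf_monotonicity(self):
        spec = SyntheticProfileSpec(plateau_width=20.0)
        prof = generate_fixture(spec)
        pens, pvdrs = [], []
        for s in (0.0, 5.0, 10.0, 20.0):
            p = prof.convolved(s)
            m = compute_metrics(p, detect_beams(p, 400.0))
            mid = m.per_beam.iloc[24]
            pens.append(np.mean([mid.penumbra_left_um,
                                 mid.penumbra_right_um]))
            pvdrs.append(m.field["field_pvdr"])
        assert np.all(np.diff(pens) > 0)
        assert np.all(np.diff(pvdrs) < 0)


class TestValleySummary:
    def test_flat_valley_edge_ratio_unity(self):
        _, _, m = _metrics()
        s = valley_profile_summary(m)
        assert s["edge_ratio_low"] == pytest.approx(1.0, abs=1e-9)
        assert s["edge_ratio_high"] == pytest.approx(1.0, abs=1e-9)

    def test_tapered_valley_reports_the_taper(self):
        spec = SyntheticProfileSpec(valley_edge_taper=0.32)
        prof = generate_fixture(spec)
        m = compute_metrics(prof, detect_beams(prof, 400.0))
        s = valley_profile_summary(m)
        assert s["edge_ratio_high"] == pytest.approx(0.68, abs=1e-6)
        assert s["edge_ratio_low"] == pytest.approx(1.0, abs=1e-6)

    def test_alternating_peaks_reported_by_index(self):
        spec = SyntheticProfileSpec(odd_even_alternation=0.05)
        prof = generate_fixture(spec)
        m = compute_metrics(prof, detect_beams(prof, 400.0))
        truth = prof.metadata["ground_truth"]["alternation_index"]
        assert m.field["odd_even_alternation"] == pytest.approx(truth,
                                                                rel=1e-6)
        assert truth == pytest.approx(0.0488, abs=0.001)

    def test_too_few_beams_rejected(self):
        x = np.arange(-600.0, 601.0, 2.0)
        prof = LateralProfile(x, np.full(len(x), 1.0))
        m = compute_metrics(prof, np.array([0.0]))
        with pytest.raises(MetricsError):
            valley_profile_summary(m)


class TestLateralProfileContainer:
    def test_validation(self):
        with pytest.raises(MetricsError):
            LateralProfile(np.array([0.0]), np.array([1.0]))
        with pytest.raises(MetricsError):
            LateralProfile(np.array([0.0, 1.0, 1.5]), np.ones(3))
        with pytest.raises(MetricsError):
            LateralProfile(np.array([0.0, 1.0]), np.array([1.0, -2.0]))

    def test_round_trip(self, tmp_path):
        prof = generate_fixture(SyntheticProfileSpec(n_beams=5))
        p = tmp_path / "prof.csv"
        prof.save(p)
        back = LateralProfile.load(p)
        assert np.allclose(back.positions, prof.positions)
        assert np.allclose(back.dose, prof.dose, rtol=1e-6)
        assert back.metadata["provenance"] == "synthetic"
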