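"""UV/synchronous shift reports, CD quantitation, site-marker displacement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from albind import (
    DisplacementCurve,
    IntensityTrend,
    Marker,
    ShiftDirection,
    Spectrum,
    SpectrumKind,
    ValidationError,
    analyze_sync_shift,
    analyze_uv_titration,
    displacement_percent,
    helix_content,
    helix_to_mre208,
    mean_residue_ellipticity,
    predict_binding_site,
    simulate_displacement,
    simulate_sync_spectra,
)


def _uv(center, amp, grid=None):
    wl = np.arange(240.0, 411.0, 1.0) if grid is None else grid
    return Spectrum(wl, amp * np.exp(-0.5 * ((wl - center) / 15.0) ** 2), SpectrumKind.UV_VIS)


class TestUVShift:
    def test_hyperchromic_no_shift(self):
        spectra = [_uv(280.0, a) for a in (0.5, 0.55, 0.6, 0.65)]
        rep = analyze_uv_titration(spectra)
        assert rep.intensity_trend is IntensityTrend.HYPERCHROMIC
        assert rep.direction is ShiftDirection.NONE
        assert rep.total_shift_nm == 0.0

    def test_blue_shift_detected(self):
        spectra = [_uv(c, 0.5) for c in (280.0, 279.0, 278.0, 277.0)]
        rep = analyze_uv_titration(spectra)
        assert rep.direction is ShiftDirection.BLUE
        assert rep.total_shift_nm == pytest.approx(-3.0)

    def test_identical_spectra_flat_none(self):
        spectra = [_uv(280.0, 0.5)] * 3
        rep = analyze_uv_titration(spectra)
        assert rep.intensity_trend is IntensityTrend.FLAT
        assert rep.direction is ShiftDirection.NONE

    def test_mismatched_grids_rejected(self):
        a = _uv(280.0, 0.5)
        b = _uv(280.0, 0.5, grid=np.arange(240.0, 410.0, 1.0))
        with pytest.raises(ValidationError):
            analyze_uv_titration([a, b])


class TestSyncShift:
    def test_quenching_without_shift(self):
        spectra = simulate_sync_spectra(quench_factors=(1.0, 0.9, 0.8, 0.7), shift_nm=0.0)
        rep = analyze_sync_shift(spectra, delta_lambda=15)
        assert rep.intensity_trend is IntensityTrend.HYPOCHROMIC
        assert rep.direction is ShiftDirection.NONE
        assert rep.residue == "Y"

    def test_red_shift_detected_for_tryptophan_scan(self):
        spectra = simulate_sync_spectra(quench_factors=(1.0, 0.9), shift_nm=4.0)
        rep = analyze_sync_shift(spectra, delta_lambda=60)
        assert rep.direction is ShiftDirection.RED
        assert rep.total_shift_nm == pytest.approx(4.0)
        assert rep.residue == "W"

    def test_single_spectrum_rejected(self):
        spectra = simulate_sync_spectra(quench_factors=(1.0,))
        with pytest.raises(ValidationError):
            analyze_sync_shift(spectra, delta_lambda=15)

    def test_invalid_offset_rejected(self):
        spectra = simulate_sync_spectra(quench_factors=(1.0, 0.9))
        with pytest.raises(ValidationError):
            analyze_sync_shift(spectra, delta_lambda=30)


class TestCD:
    def test_mre_arithmetic(self):
        assert mean_residue_ellipticity(-292.5, 5e-6, 585, 1.0) == pytest.approx(-10000.0)
        assert mean_residue_ellipticity(0.0, 5e-6, 585, 1.0) == 0.0

    def test_mre_homogeneity(self):
        base = mean_residue_ellipticity(-292.5, 5e-6, 585, 1.0)
        assert mean_residue_ellipticity(-292.5, 1e-5, 585, 1.0) == pytest.approx(base / 2)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValidationError):
            mean_residue_ellipticity(-100.0, 0.0, 585, 1.0)

    @pytest.mark.parametrize(
        "mre,expected",
        [(-20216.8, 55.92), (-18175.2, 48.88), (-4000.0, 0.0), (-33000.0, 100.0)],
    )
    def test_helix_calibration(self, mre, expected):
        assert helix_content(mre) == pytest.approx(expected, abs=1e-9)

    def test_out_of_range_returned_with_warning_not_clamped(self):
        with pytest.warns(UserWarning, match="outside"):
            pct = helix_content(-40000.0)
        assert pct > 100.0

    @given(st.floats(0.0, 100.0))
    @settings(max_examples=100, deadline=None)
    def test_helix_round_trip_identity(self, pct):
        assert helix_content(helix_to_mre208(pct)) == pytest.approx(pct, abs=1e-9)

    @given(
        theta=st.floats(-1000.0, -1.0),
        conc=st.floats(1e-6, 1e-4),
        path=st.floats(0.1, 2.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_mre_linearity_and_inverse_proportionality(self, theta, conc, path):
        base = mean_residue_ellipticity(theta, conc, 585, path)
        assert mean_residue_ellipticity(2 * theta, conc, 585, path) == pytest.approx(2 * base, rel=1e-12)
        assert mean_residue_ellipticity(theta, 2 * conc, 585, path) == pytest.approx(base / 2, rel=1e-12)
        assert mean_residue_ellipticity(theta, conc, 585, 2 * path) == pytest.approx(base / 2, rel=1e-12)


class TestDisplacement:
    def test_percent_closed_forms(self):
        assert displacement_percent(100.0, 100.0) == 100.0
        assert displacement_percent(100.0, 40.0) == 40.0
        assert displacement_percent(100.0, 0.0) == 0.0
        with pytest.raises(ValidationError):
            displacement_percent(0.0, 50.0)

    def test_curve_invariants(self):
        curves = simulate_displacement()
        for c in curves:
            np.testing.assert_allclose(c.I_pct, 100.0 * c.F2 / c.F1)
            assert c.I_pct[0] == 100.0

    def test_dominant_hemin_maps_to_site_three(self):
        curves = simulate_displacement(
            {Marker.HEMIN: 0.6, Marker.WARFARIN: 0.2, Marker.IBUPROFEN: 0.1}
        )
        call = predict_binding_site(curves)
        assert call.winner is Marker.HEMIN
        assert call.subdomain == "IB"
        assert not call.indeterminate

    def test_dominant_warfarin_maps_to_sudlow_one(self):
        curves = simulate_displacement({Marker.WARFARIN: 0.5, Marker.IBUPROFEN: 0.05})
        call = predict_binding_site(curves)
        assert call.winner is Marker.WARFARIN
        assert call.subdomain == "IIA"

    def test_no_displacement_is_indeterminate(self):
        curves = simulate_displacement(
            {Marker.HEMIN: 0.0, Marker.WARFARIN: 0.0, Marker.IBUPROFEN: 0.0}
        )
        assert predict_binding_site(curves).indeterminate

    def test_margin_rule(self):
        # two closest terminal I% within 2 points -> indeterminate at default margin
        curves = simulate_displacement({Marker.HEMIN: 0.40, Marker.WARFARIN: 0.41})
        assert predict_binding_site(curves).indeterminate
        assert not predict_binding_site(curves, margin_pct=0.1).indeterminate

    def test_fewer_than_two_markers_rejected(self):
        curves = simulate_displacement({Marker.HEMIN: 0.5})
        with pytest.raises(ValidationError):
            predict_binding_site(curves)

    def test_recovers_injected_dominant_marker_when_gap_exceeds_margin(self):
        rng = np.random.default_rng(5)
        markers = list(Marker)
        for _ in range(20):
            strengths = rng.uniform(0.0, 0.9, size=3)
            order = np.argsort(strengths)
            if strengths[order[-1]] - strengths[order[-2]] < 0.15:
                continue  # terminal gap could fall inside the margin
            curves = simulate_displacement(dict(zip(markers, strengths)))
            call = predict_binding_site(curves)
            assert call.winner is markers[int(order[-1])]
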