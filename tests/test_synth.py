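"""Synthetic-data generators: closed forms, determinism, noise behaviour."""

import numpy as np
import pytest

from albind import (
    GroundTruth,
    Marker,
    ValidationError,
    fit_stern_volmer,
    helix_content,
    kb_at_temperature,
    mean_residue_ellipticity,
    simulate_cd,
    simulate_displacement,
    simulate_esterase,
    simulate_quench_titration,
    simulate_sync_spectra,
    simulate_temperature_family,
    simulate_thermal,
)
from albind.stability import fit_melt


class TestQuenchGenerator:
    def test_closed_form_point(self):
        # F = F0/(1 + Ksv [Q]) at Ksv = 0.7e4, [Q] = 20 uM
        truth = GroundTruth(Ksv_M=0.7e4, noise_sd=0.0)
        series = simulate_quench_titration(truth, [0.0, 20e-6], F0=1000.0)
        assert series.intensities[1] == pytest.approx(1000.0 / 1.14, abs=1e-9)
        assert series.intensities[1] == pytest.approx(877.19, abs=0.01)

    def test_zero_concentration_gives_f0_exactly(self, noiseless_truth):
        series = simulate_quench_titration(noiseless_truth, F0=1234.5)
        assert series.f0 == 1234.5

    def test_same_seed_bit_identical(self):
        truth = GroundTruth(noise_sd=0.05, seed=42)
        a = simulate_quench_titration(truth)
        b = simulate_quench_titration(truth)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_negative_concentration_rejected(self, noiseless_truth):
        with pytest.raises(ValidationError):
            simulate_quench_titration(noiseless_truth, [-1e-6, 0.0, 5e-6])

    def test_grid_without_zero_rejected(self, noiseless_truth):
        with pytest.raises(ValidationError):
            simulate_quench_titration(noiseless_truth, [5e-6, 10e-6])


class TestTemperatureFamily:
    def test_vant_hoff_closed_form(self):
        # Kb(295) = exp(-dH/(R 295) + dS/R) evaluated independently
        kb = kb_at_temperature(-5090.0, 61.6, 295.0)
        assert kb == pytest.approx(
            np.exp(5090.0 / (8.314 * 295.0) + 61.6 / 8.314), rel=1e-12
        )

    def test_exothermic_truth_gives_decreasing_ksv(self, noiseless_truth):
        family = simulate_temperature_family(noiseless_truth)
        fits = [fit_stern_volmer(s) for s in family]
        ksv = [f.Ksv for f in fits]
        assert ksv[0] > ksv[1] > ksv[2]

    def test_zero_enthalpy_gives_identical_constants(self):
        truth = GroundTruth(dH_J=0.0, dS_J=61.6, noise_sd=0.0)
        family = simulate_temperature_family(truth)
        fits = [fit_stern_volmer(s) for s in family]
        assert fits[0].Ksv == pytest.approx(fits[1].Ksv, rel=1e-9)
        assert fits[1].Ksv == pytest.approx(fits[2].Ksv, rel=1e-9)

    def test_single_temperature_rejected(self, noiseless_truth):
        with pytest.raises(ValidationError):
            simulate_temperature_family(noiseless_truth, temps_K=[295.0])


class TestSyncGenerator:
    def test_zero_shift_keeps_argmax_constant(self):
        spectra = simulate_sync_spectra(shift_nm=0.0, quench_factors=(1.0, 0.8, 0.6))
        peaks = [s.wavelength_nm[np.argmax(s.intensity)] for s in spectra]
        assert len(set(peaks)) == 1

    def test_unit_factors_give_identical_spectra(self):
        spectra = simulate_sync_spectra(quench_factors=(1.0, 1.0, 1.0))
        for s in spectra[1:]:
            np.testing.assert_array_equal(s.intensity, spectra[0].intensity)

    def test_cumulative_shift(self):
        spectra = simulate_sync_spectra(shift_nm=2.0, quench_factors=(1.0, 0.9, 0.8, 0.7))
        peaks = [s.wavelength_nm[np.argmax(s.intensity)] for s in spectra]
        assert peaks[-1] - peaks[0] == pytest.approx(6.0)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValidationError):
            simulate_sync_spectra(peak_width_nm=0.0)


class TestCDGenerator:
    @pytest.mark.parametrize(
        "helix_frac,mre208",
        [
            (0.5592, -20216.8),  # apo helix content
            (0.0, -4000.0),
            (1.0, -33000.0),
        ],
    )
    def test_208nm_encodes_helix_fraction(self, helix_frac, mre208):
        spec = simulate_cd(helix_frac, protein_conc=5e-6, n_residues=585, path_length_cm=1.0)
        mre = mean_residue_ellipticity(spec.value_at(208.0), 5e-6, 585, 1.0)
        assert mre == pytest.approx(mre208, rel=1e-9)
        assert helix_content(mre) == pytest.approx(100.0 * helix_frac, abs=1e-9)

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValidationError):
            simulate_cd(1.2)


class TestDisplacementGenerator:
    def test_zero_strength_keeps_100_percent(self):
        (curve,) = simulate_displacement({Marker.WARFARIN: 0.0})
        np.testing.assert_allclose(curve.I_pct, 100.0)

    def test_half_strength_at_kd(self):
        kd = 10e-6
        (curve,) = simulate_displacement({Marker.HEMIN: 0.5}, Kd_marker=kd,
                                         marker_grid=[0.0, kd])
        assert curve.I_pct[1] == pytest.approx(75.0)

    def test_curves_monotone_nonincreasing(self):
        for curve in simulate_displacement():
            assert np.all(np.diff(curve.I_pct) <= 1e-12)

    def test_strength_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            simulate_displacement({Marker.HEMIN: 1.5})


class TestThermalGenerator:
    def test_zero_shift_gives_identical_profiles(self):
        apo, cpx = simulate_thermal(dTm_C=0.0)
        np.testing.assert_array_equal(apo.fi343, cpx.fi343)

    def test_complex_brighter_between_midpoints(self):
        apo, cpx = simulate_thermal(Tm_C=55.0, dTm_C=5.0, temps_C=np.arange(25.0, 81.0, 2.5))
        idx = int(np.argmin(np.abs(apo.temps_C - 57.5)))
        assert cpx.fi343[idx] > apo.fi343[idx]

    def test_noiseless_refit_recovers_midpoint(self):
        # grid-search oracle inside fit_melt's fallback agrees with curve fit
        apo, _ = simulate_thermal(Tm_C=57.0, dTm_C=0.0)
        tm, _ = fit_melt(apo)
        assert tm == pytest.approx(57.0, abs=0.1)


class TestEsteraseGenerator:
    def test_factor_scales_slope(self):
        curves = simulate_esterase(v0=0.02, inhibition_factors={0.0: 1.0, 10e-6: 0.5})
        slope0 = np.polyfit(curves[0].time_min, curves[0].a400, 1)[0]
        slope1 = np.polyfit(curves[1].time_min, curves[1].a400, 1)[0]
        assert slope1 == pytest.approx(0.5 * slope0, rel=1e-9)

    def test_zero_rate_is_flat(self):
        (curve,) = simulate_esterase(v0=0.0, inhibition_factors={0.0: 1.0})
        assert np.ptp(curve.a400) == 0.0

    def test_negative_times_rejected(self):
        with pytest.raises(ValidationError):
            simulate_esterase(t_grid_min=[-1.0, 0.0, 1.0])


class TestNoiseScaling:
    def test_sv_rmse_decreases_when_noise_halves(self):
        """Estimator RMSE over 200 replicates shrinks with the noise level."""

        import warnings

        def rmse(noise_sd: float) -> float:
            errs = []
            for seed in range(200):
                truth = GroundTruth(Ksv_M=1e4, noise_sd=noise_sd, seed=seed)
                with warnings.catch_warnings():
                    # noisy replicates may trip the anti-quenching warning
                    warnings.simplefilter("ignore", UserWarning)
                    fit = fit_stern_volmer(simulate_quench_titration(truth))
                errs.append((fit.Ksv - 1e4) / 1e4)
            return float(np.sqrt(np.mean(np.square(errs))))

        assert rmse(0.01) < rmse(0.02)
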