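"""Double-log binding fit, van 't Hoff analysis, Gibbs energy, force signs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from albind import (
    BindingFit,
    BindingForce,
    GroundTruth,
    TitrationPoint,
    TitrationSeries,
    ValidationError,
    classify_forces,
    fit_double_log,
    fit_stern_volmer,
    fit_vant_hoff,
    gibbs,
    simulate_quench_titration,
)
from conftest import ols_slope_intercept

R = 8.314


def _series_from_double_log(kb, n, conc_um, f0=1000.0):
    """Exact data from the double-log model: (F0-F)/F = Kb [Q]^n."""
    conc = np.asarray(conc_um) * 1e-6
    ratio = kb * conc ** n
    f = f0 / (1.0 + ratio)
    points = [TitrationPoint(0.0, f0)] + [
        TitrationPoint(float(c), float(v)) for c, v in zip(conc, f)
    ]
    return TitrationSeries(tuple(points), temperature_K=295.0)


class TestDoubleLog:
    def test_noiseless_recovery_of_kb_and_n(self):
        series = _series_from_double_log(1.326e4, 1.28, [5, 10, 15, 20, 25, 30, 35])
        fit = fit_double_log(series)
        assert fit.Kb == pytest.approx(1.326e4, rel=1e-6)
        assert fit.n_stoich == pytest.approx(1.28, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_static_one_to_one_data_gives_unit_stoichiometry(self):
        # Eq-1 data (1:1 complex) is algebraically the n = 1 double-log model
        truth = GroundTruth(Ksv_M=1e4, noise_sd=0.0)
        series = simulate_quench_titration(truth)
        fit = fit_double_log(series)
        assert abs(fit.n_stoich - 1.0) < 0.05
        assert abs(fit.Kb - 1e4) / 1e4 < 0.05
        # and agrees with the Stern-Volmer constant on the same data
        sv = fit_stern_volmer(series)
        assert fit.Kb == pytest.approx(sv.Ksv, rel=1e-6)

    def test_points_at_or_above_f0_dropped_with_warning(self):
        pts = (
            TitrationPoint(0.0, 1000.0),
            TitrationPoint(5e-6, 1001.0),  # above F0: unusable
            TitrationPoint(1e-5, 900.0),
            TitrationPoint(1.5e-5, 850.0),
            TitrationPoint(2e-5, 800.0),
        )
        series = TitrationSeries(pts, temperature_K=295.0)
        with pytest.warns(UserWarning, match="F >= F0"):
            fit_double_log(series)

    def test_insufficient_usable_points_rejected(self):
        series = _series_from_double_log(1e4, 1.0, [5, 10])
        with pytest.raises(ValidationError):
            fit_double_log(series)


class TestVantHoff:
    def test_noiseless_parameter_recovery(self):
        dh, ds = -5.09e3, 61.6
        fits = [
            BindingFit(Kb=np.exp(-dh / (R * t) + ds / R), n_stoich=1.0,
                       r_squared=1.0, temperature_K=t)
            for t in (295.0, 305.0, 310.0)
        ]
        result = fit_vant_hoff(fits)
        assert result.dH_J == pytest.approx(dh, rel=1e-6)
        assert result.dS_J == pytest.approx(ds, rel=1e-6)

    def test_matches_closed_form_ols_oracle_on_tabulated_constants(self):
        """Measured Kb family (1.326/1.236/1.200 x1e4 M^-1 at 295/305/310 K)
        forces an exothermic fit; the package must agree with a closed-form
        OLS oracle to 1e-6 and flag the negative enthalpy."""
        temps = np.array([295.0, 305.0, 310.0])
        kb = np.array([1.326e4, 1.236e4, 1.200e4])
        slope, intercept = ols_slope_intercept(1.0 / temps, np.log(kb))
        fits = [
            BindingFit(Kb=float(k), n_stoich=1.0, r_squared=1.0, temperature_K=float(t))
            for k, t in zip(kb, temps)
        ]
        result = fit_vant_hoff(fits)
        assert result.dH_J == pytest.approx(-R * slope, rel=1e-6)
        assert result.dS_J == pytest.approx(R * intercept, rel=1e-6)
        # the sign conflict with a claimed endothermic/hydrophobic picture
        # is surfaced, not hidden:
        assert result.exothermic
        assert classify_forces(result.dH_J, result.dS_J).label is BindingForce.ELECTROSTATIC

    def test_two_points_fit_passes_through_both(self):
        fits = [
            BindingFit(Kb=1.3e4, n_stoich=1.0, r_squared=1.0, temperature_K=295.0),
            BindingFit(Kb=1.2e4, n_stoich=1.0, r_squared=1.0, temperature_K=310.0),
        ]
        result = fit_vant_hoff(fits)
        for f in fits:
            predicted = -result.dH_J / (R * f.temperature_K) + result.dS_J / R
            assert predicted == pytest.approx(np.log(f.Kb), rel=1e-12)

    def test_duplicate_temperatures_rejected(self):
        fits = [
            BindingFit(Kb=1.3e4, n_stoich=1.0, r_squared=1.0, temperature_K=295.0),
            BindingFit(Kb=1.2e4, n_stoich=1.0, r_squared=1.0, temperature_K=295.0),
        ]
        with pytest.raises(ValidationError):
            fit_vant_hoff(fits)

    def test_identities_hold_to_machine_precision(self):
        fits = [
            BindingFit(Kb=float(k), n_stoich=1.0, r_squared=1.0, temperature_K=t)
            for k, t in ((1.326e4, 295.0), (1.236e4, 305.0), (1.200e4, 310.0))
        ]
        result = fit_vant_hoff(fits)
        for e in result.per_T:
            assert e.TdS_J == e.temperature_K * result.dS_J
            assert e.dG_J == result.dH_J - e.TdS_J
            # reported consistency against -RT ln Kb is small for a good line
            assert e.dG_vs_lnKb_residual_J < 100.0

    def test_spontaneity_flags(self):
        fits = [
            BindingFit(Kb=float(k), n_stoich=1.0, r_squared=1.0, temperature_K=t)
            for k, t in ((1.326e4, 295.0), (1.236e4, 305.0), (1.200e4, 310.0))
        ]
        result = fit_vant_hoff(fits)
        assert result.spontaneous  # dG < 0 at every temperature


class TestGibbs:
    @pytest.mark.parametrize(
        "dH,dS,T,expected",
        [
            (5087.0, 81.0, 295.0, -18808.0),
            (5087.0, 81.0, 305.0, -19618.0),
            (0.0, 0.0, 300.0, 0.0),
        ],
    )
    def test_closed_form(self, dH, dS, T, expected):
        assert gibbs(dH, dS, T) == pytest.approx(expected, abs=1e-9)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValidationError):
            gibbs(1.0, 1.0, 0.0)


class TestForces:
    @pytest.mark.parametrize(
        "dH,dS,label",
        [
            (5087.0, 81.0, BindingForce.HYDROPHOBIC),
            (-10000.0, -50.0, BindingForce.VDW_HBOND),
            (-5090.0, 61.6, BindingForce.ELECTROSTATIC),
            (1.0, -1.0, BindingForce.UNCLASSIFIED),
        ],
    )
    def test_sign_rules(self, dH, dS, label):
        assert classify_forces(dH, dS).label is label

    @pytest.mark.parametrize("sh", [-1.0, 0.0, 1.0])
    @pytest.mark.parametrize("ss", [-1.0, 0.0, 1.0])
    def test_all_nine_sign_combinations_defined(self, sh, ss):
        call = classify_forces(sh * 1e3, ss * 10.0)
        assert isinstance(call.label, BindingForce)
        if sh == 0.0 or ss == 0.0:
            assert call.label is BindingForce.UNCLASSIFIED

    @given(st.floats(-1e6, 1e6), st.floats(-1e3, 1e3))
    @settings(max_examples=100, deadline=None)
    def test_label_depends_only_on_signs(self, dH, dS):
        call = classify_forces(dH, dS)
        assert call.signs == (int(np.sign(dH)), int(np.sign(dS)))
        assert isinstance(call.label, BindingForce)
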