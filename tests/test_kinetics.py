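"""Calibration, initial-velocity, Michaelis-Menten, IC50, K_I and kcat logic."""

import numpy as np
import pandas as pd
import pytest

from egfr19.kinetics import (
    ActiveFractionWarning,
    AssayConditions,
    EstimationError,
    FitError,
    NonCompetitiveBehaviourWarning,
    ProgressCurve,
    calibrate_fluorescence,
    correct_kcat,
    estimate_initial_velocity,
    fit_ic50,
    fit_ki_cheng_prusoff,
    fit_michaelis_menten,
    fold_change_table,
    predict_ic50,
)
from egfr19.simulate import KineticsScenario, gen_progress_curve, initial_rate


class TestCalibration:
    def test_exact_line_recovered(self):
        model = calibrate_fluorescence([(0, 0), (10, 1000), (20, 2000)])
        assert model.slope == pytest.approx(100.0)
        assert model.intercept == pytest.approx(0.0)
        assert model.to_conc(model.to_counts(np.array([7.3])))[0] == pytest.approx(7.3)

    def test_single_standard_is_underdetermined(self):
        with pytest.raises(FitError):
            calibrate_fluorescence([(10, 1000)])
        with pytest.raises(FitError):
            calibrate_fluorescence([(10, 1000), (10, 1001)])

    def test_noisy_slope_recovered_within_2pct(self, rng):
        conc = np.linspace(0, 200, 8)
        counts = 87.5 * conc * (1 + 0.01 * rng.standard_normal(8))
        model = calibrate_fluorescence(list(zip(conc, counts)))
        assert model.slope == pytest.approx(87.5, rel=0.02)


def _curve(times, signal, pept=10.0):
    return ProgressCurve(
        times_s=np.asarray(times, float),
        signal=np.asarray(signal, float),
        conditions=AssayConditions(
            tkd_conc_nM=100, atp_conc_uM=1000, peptide_conc_uM=pept
        ),
    )


class TestInitialVelocity:
    def test_exactly_linear_curve(self):
        t = np.arange(0, 300, 10.0)
        est = estimate_initial_velocity(_curve(t, 0.002 * t, pept=100.0))
        assert est.v0 == pytest.approx(0.002, rel=1e-9)

    def test_depleting_curve_matches_analytic_initial_rate(self):
        scenario = KineticsScenario(noise_cv=0.0)
        curve = gen_progress_curve(
            scenario, atp_uM=1000.0, pept_uM=20.0,
            times_s=np.arange(0.0, 241.0, 5.0),
        )
        est = estimate_initial_velocity(curve)
        v_true = initial_rate(scenario, 1000.0, 20.0)
        assert est.v0 == pytest.approx(v_true, rel=0.05)

    def test_blank_curve_gives_zero_rate(self):
        t = np.arange(0, 300, 10.0)
        est = estimate_initial_velocity(_curve(t, np.zeros_like(t)))
        assert est.v0 == pytest.approx(0.0, abs=1e-12)

    def test_no_linear_window_raises(self):
        t = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([0.0, 5.0, 0.5, 8.0, 0.2, 9.0])  # wildly non-linear
        with pytest.raises(EstimationError):
            estimate_initial_velocity(_curve(t, y, pept=1000.0))

    def test_too_few_points_raises(self):
        with pytest.raises(EstimationError):
            estimate_initial_velocity(_curve([0, 1, 2], [0, 1, 2]))


class TestMichaelisMenten:
    def test_noiseless_parameters_recovered(self):
        s = np.array([1, 3, 10, 30, 100, 300, 1000, 3000], float)
        v = 0.06 * s / (158.0 + s)
        fit = fit_michaelis_menten(list(zip(s, v)), tkd_conc_nM=100.0)
        assert fit.km == pytest.approx(158.0, rel=1e-6)
        assert fit.vmax == pytest.approx(0.06, rel=1e-6)
        assert fit.apparent_kcat == pytest.approx(0.6, rel=1e-6)

    def test_half_maximal_rate_at_km(self):
        s = np.array([1, 5, 20, 80, 320, 1280], float)
        v = 0.02 * s / (23.0 + s)
        fit = fit_michaelis_menten(list(zip(s, v)), tkd_conc_nM=10.0)
        assert fit.rate(np.array([fit.km]))[0] == pytest.approx(fit.vmax / 2)

    def test_km_outside_data_range_warns(self):
        s = np.array([500, 1000, 2000, 3000], float)
        v = 0.06 * s / (5.0 + s)
        with pytest.warns(UserWarning, match="outside the substrate range"):
            fit_michaelis_menten(list(zip(s, v)), tkd_conc_nM=100.0)


class TestIC50:
    doses = np.array([0, 1, 3, 10, 30, 100, 300, 1000, 3000, 10000, 40000], float)

    def test_noiseless_inversion(self):
        rate = 100.0 / (1.0 + self.doses / 232.0)
        fit = fit_ic50(list(zip(self.doses, rate)))
        assert fit.ic50_nM == pytest.approx(232.0, rel=1e-6)
        assert not fit.censored

    def test_rate_at_ic50_is_50(self):
        rate = 100.0 / (1.0 + self.doses / 36.0)
        fit = fit_ic50(list(zip(self.doses, rate)))
        assert fit.rate(np.array([fit.ic50_nM]))[0] == pytest.approx(50.0)

    def test_weak_inhibition_censored_without_estimate(self):
        doses = np.array([0, 10, 100, 1000], float)
        rate = np.array([100, 99, 97, 95], float)
        fit = fit_ic50(list(zip(doses, rate)))
        assert fit.censored and fit.ic50_nM is None
        assert fit.bound == ">1000"

    def test_top_dose_under_50pct_inhibition_flagged(self):
        doses = np.array([0, 10, 30, 100, 300, 1000], float)
        rate = 100.0 / (1.0 + doses / 2000.0)
        fit = fit_ic50(list(zip(doses, rate)))
        assert fit.censored
        assert fit.ic50_nM == pytest.approx(2000.0, rel=1e-3)


class TestChengPrusoff:
    atp = np.array([10, 50, 100, 500, 1000, 2000], float)

    def test_noiseless_two_parameter_fit(self):
        ic50 = 5.3 * (1 + self.atp / 23.0)
        fit = fit_ki_cheng_prusoff(list(zip(self.atp, ic50)))
        assert fit.ki_nM == pytest.approx(5.3, rel=1e-6)
        assert fit.km_atp_uM == pytest.approx(23.0, rel=1e-6)
        assert not fit.non_competitive_flag

    def test_one_parameter_fit_with_known_km(self):
        ic50 = 6.2 * (1 + self.atp / 21.0)
        fit = fit_ki_cheng_prusoff(list(zip(self.atp, ic50)), km_atp_uM=21.0)
        assert fit.ki_nM == pytest.approx(6.2, rel=1e-9)
        assert fit.method == "one-parameter"

    def test_ic50_at_zero_atp_equals_ki(self):
        ic50 = 4.2 * (1 + self.atp / 101.0)
        fit = fit_ki_cheng_prusoff(list(zip(self.atp, ic50)))
        assert predict_ic50(fit.ki_nM, fit.km_atp_uM, 0.0) == pytest.approx(
            fit.ki_nM
        )

    def test_flat_series_raises_non_competitive_flag(self):
        ic50 = np.full_like(self.atp, 30.0)
        with pytest.warns(NonCompetitiveBehaviourWarning):
            fit = fit_ki_cheng_prusoff(list(zip(self.atp, ic50)))
        assert fit.non_competitive_flag

    def test_too_few_levels_rejected(self):
        with pytest.raises(FitError):
            fit_ki_cheng_prusoff([(10, 10), (100, 20)])

    def test_round_trip_identity_noiseless(self):
        ki, km = 5.3, 23.0
        series = [(a, predict_ic50(ki, km, a)) for a in self.atp]
        fit = fit_ki_cheng_prusoff(series)
        for a, ic in series:
            assert predict_ic50(fit.ki_nM, fit.km_atp_uM, a) == pytest.approx(ic)


class TestPredictIC50:
    def test_forward_arithmetic(self):
        assert predict_ic50(5.3, 23.0, 1000.0) == pytest.approx(235.73, abs=0.05)
        assert predict_ic50(4.2, 101.0, 1000.0) == pytest.approx(45.8, abs=0.05)

    def test_zero_atp_returns_ki(self):
        assert predict_ic50(7.7, 50.0, 0.0) == 7.7


class TestCorrectKcat:
    def test_fully_active_preparation_is_identity(self):
        corr = correct_kcat(0.5, 100.0, 50.0)  # IC50 = [TKD]/2
        assert corr.active_fraction == pytest.approx(1.0)
        assert corr.corrected_kcat == pytest.approx(0.5)

    def test_published_worked_example(self):
        corr = correct_kcat(0.91, 100.0, 36.0)
        assert round(corr.corrected_kcat, 2) == 1.26

    def test_low_tkd_scale_worked_example(self):
        # assayed at 1 μM enzyme; published IC50 was presentation-scaled /10
        corr = correct_kcat(0.044, 1000.0, 420.0)
        assert round(corr.corrected_kcat, 3) == 0.052

    def test_active_fraction_above_one_warns_but_reports(self):
        with pytest.warns(ActiveFractionWarning):
            corr = correct_kcat(0.5, 100.0, 80.0)
        assert corr.active_fraction == pytest.approx(1.6)
        assert corr.corrected_kcat == pytest.approx(0.5 / 1.6)

    def test_rejects_non_positive_inputs(self):
        with pytest.raises(ValueError):
            correct_kcat(0.0, 100.0, 36.0)


class TestFoldChange:
    def _table(self):
        return pd.DataFrame(
            [
                {"variant": "ΔL747-A750InsP", "inhibitor": "erlotinib",
                 "mean": 232.0, "sd": 48.0, "n": 6},
                {"variant": "ΔL747-A750InsP", "inhibitor": "afatinib",
                 "mean": 36.0, "sd": 15.0, "n": 6},
                {"variant": "ΔE746-A750", "inhibitor": "erlotinib",
                 "mean": 31.0, "sd": 8.0, "n": 6},
                {"variant": "ΔE746-A750", "inhibitor": "afatinib",
                 "mean": 27.0, "sd": 9.0, "n": 6},
            ]
        )

    def test_published_fold_changes(self):
        table = fold_change_table(self._table(), "ΔE746-A750")
        by = table.set_index(["variant", "inhibitor"])
        erl = by.loc[("ΔL747-A750InsP", "erlotinib")]
        afa = by.loc[("ΔL747-A750InsP", "afatinib")]
        assert round(erl["fold"], 1) == 7.5
        assert round(afa["fold"], 1) == 1.3
        assert erl["p_value"] < 0.0001

    def test_identical_groups_fold_one_p_one(self):
        df = pd.DataFrame(
            [
                {"variant": "a", "inhibitor": "erlotinib", "mean": 10.0,
                 "sd": 2.0, "n": 5},
                {"variant": "b", "inhibitor": "erlotinib", "mean": 10.0,
                 "sd": 2.0, "n": 5},
            ]
        )
        table = fold_change_table(df, "b").set_index("variant")
        assert table.loc["a", "fold"] == pytest.approx(1.0)
        assert table.loc["a", "p_value"] == pytest.approx(1.0)

    def test_zero_reference_mean_is_undefined(self):
        df = pd.DataFrame(
            [
                {"variant": "a", "inhibitor": "x", "mean": 5.0, "sd": 1.0, "n": 3},
                {"variant": "ref", "inhibitor": "x", "mean": 0.0, "sd": 1.0, "n": 3},
            ]
        )
        with pytest.raises(ZeroDivisionError):
            fold_change_table(df, "ref")
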