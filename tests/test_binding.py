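"""Isotherm and fluorescence-polarization model and fit behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fretquant import binding
from fretquant.binding import (FPSeries, IsothermFit, TitrationSeries, dynamic_range,
                               fit_fp_competition, fit_fp_direct, fit_isotherm,
                               fp_direct_forward, fp_from_intensities, hyperbola,
                               isotherm_forward, isotherm_invert, selectivity_fold)
from fretquant.synthetic import SyntheticScenario, gen_fp_series, gen_titration

FIT = IsothermFit(r_min=1.0, r_max=2.8, c50=14.0)


class TestIsothermForward:
    @pytest.mark.parametrize("conc, fit, expected", [
        (0.0, IsothermFit(1.0, 2.8, 14.0), 1.0),            # zero-analyte limit
        (14.0, IsothermFit(1.0, 2.8, 14.0), (1.0 + 2.8) / 2),  # midpoint at c50
        # 10x c50: hand evaluation 1 + 2/(1 + 1/10) = 31/11
        (140.0, IsothermFit(1.0, 3.0, 14.0), 31.0 / 11.0),
    ])
    def test_known_values(self, conc, fit, expected):
        assert isotherm_forward(conc, fit) == pytest.approx(expected, rel=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            isotherm_forward(-1.0, FIT)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(rmin=st.floats(0.1, 5), delta=st.floats(-3, 3), c50=st.floats(0.01, 1000))
    def test_monotone_iff_response_direction(self, rmin, delta, c50):
        """Strictly increasing iff r_max > r_min, decreasing iff <."""
        fit = IsothermFit(rmin, rmin + delta, c50)
        conc = np.geomspace(1e-3, 1e4, 50)
        r = isotherm_forward(conc, fit)
        if delta > 1e-9:
            assert np.all(np.diff(r) > 0)
        elif delta < -1e-9:
            assert np.all(np.diff(r) < 0)


class TestIsothermInvert:
    def test_midpoint_maps_to_c50(self):
        assert isotherm_invert((FIT.r_min + FIT.r_max) / 2, FIT) == pytest.approx(FIT.c50)

    @pytest.mark.parametrize("factor", [0.1, 1.0, 10.0])
    def test_round_trip(self, factor):
        c = factor * FIT.c50
        back = isotherm_invert(isotherm_forward(c, FIT), FIT)
        assert back == pytest.approx(c, rel=1e-9)

    @pytest.mark.parametrize("ratio", [2.8, 1.0, 0.5, 3.5])
    def test_out_of_range_ratio_rejected(self, ratio):
        with pytest.raises(ValueError, match="r_min|r_max"):
            isotherm_invert(ratio, FIT)

    def test_error_names_violated_bound(self):
        with pytest.raises(ValueError, match="r_max"):
            isotherm_invert(3.0, FIT)
        with pytest.raises(ValueError, match="r_min"):
            isotherm_invert(0.9, FIT)


class TestFitIsotherm:
    def test_noiseless_recovery_is_exact(self, scenario):
        series, truth = gen_titration(scenario, variant="G41", noise=False)
        fit = fit_isotherm(series)
        assert fit.r_min == pytest.approx(truth["r_min"], rel=1e-6)
        assert fit.r_max == pytest.approx(truth["r_max"], rel=1e-6)
        assert fit.c50 == pytest.approx(truth["c50_uM"], rel=1e-6)

    def test_noisy_recovery_close(self, scenario):
        series, truth = gen_titration(scenario, variant="G41", noise=True)
        fit = fit_isotherm(series)
        assert fit.c50 == pytest.approx(truth["c50_uM"], rel=0.10)
        assert fit.standard_errors["c50"] > 0

    def test_monte_carlo_bias_small(self):
        """Seeded ensemble: c50 estimates scatter tightly around truth at 1% noise."""
        sc = SyntheticScenario(seed=11)
        errs = []
        for rep in range(60):
            series, truth = gen_titration(sc, variant="G41", rng=sc.rng(1000 + rep))
            errs.append(fit_isotherm(series).c50 / truth["c50_uM"] - 1.0)
        errs = np.asarray(errs)
        assert abs(np.mean(errs)) < 0.02
        assert np.median(np.abs(errs)) < 0.05

    def test_flat_series_flagged_unidentifiable(self):
        conc = np.geomspace(0.01, 1000, 8)
        series = TitrationSeries("x", conc, np.full(8, 2.0))
        with pytest.warns(UserWarning, match="unidentifiable"):
            fit = fit_isotherm(series)
        assert dynamic_range(fit) == pytest.approx(1.0, abs=1e-3)
        assert "unidentifiable" in " ".join(fit.warnings)

    def test_too_few_concentrations_rejected(self):
        series = TitrationSeries("x", [0, 1, 10, 10], [1.0, 1.5, 2.0, 2.0])
        with pytest.raises(ValueError, match="5 distinct"):
            fit_isotherm(series)

    def test_extrapolated_c50_flagged(self):
        fit_true = IsothermFit(1.0, 2.8, 5000.0)
        conc = np.geomspace(0.01, 10, 8)  # samples far below c50
        series = TitrationSeries("x", conc, isotherm_forward(conc, fit_true))
        with pytest.warns(UserWarning, match="extrapolated"):
            fit = fit_isotherm(series)
        assert any("extrapolated" in w for w in fit.warnings)


class TestDynamicRange:
    @pytest.mark.parametrize("rmin, rmax, expected", [
        (1.0, 2.8, 2.8),   # the defining arithmetic of the fold change
        (2.0, 2.0, 1.0),
        (0.5, 2.0, 4.0),
    ])
    def test_values(self, rmin, rmax, expected):
        assert dynamic_range(IsothermFit(rmin, rmax, 1.0)) == pytest.approx(expected)

    def test_nonpositive_rmin_rejected(self):
        with pytest.raises(ValueError):
            dynamic_range(IsothermFit(0.0, 2.0, 1.0))


class TestSelectivity:
    @pytest.mark.parametrize("other, analyte, expected", [
        (163.0, 13.9, 163.0 / 13.9),  # ~11.7-fold
        (5.0, 5.0, 1.0),
        (100.0, 10.0, 10.0),
    ])
    def test_values(self, other, analyte, expected):
        assert selectivity_fold(other, analyte) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            selectivity_fold(-1.0, 10.0)


class TestFPFromIntensities:
    @pytest.mark.parametrize("ipar, iperp, g, expected", [
        (5.0, 5.0, 1.0, 0.0),    # fully depolarized
        (5.0, 0.0, 1.0, 1.0),    # fully polarized
        (3.0, 1.0, 2.0, 0.2),    # (3-2)/(3+2), hand arithmetic
    ])
    def test_values(self, ipar, iperp, g, expected):
        assert fp_from_intensities(ipar, iperp, g) == pytest.approx(expected)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            fp_from_intensities(0.0, 0.0, 1.0)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(ipar=st.floats(0, 1e6), iperp=st.floats(0, 1e6),
           g=st.floats(0.1, 10))
    def test_always_in_unit_interval(self, ipar, iperp, g):
        if ipar + iperp * g == 0:
            return
        assert -1.0 <= fp_from_intensities(ipar, iperp, g) <= 1.0


class TestFPDirect:
    def test_noiseless_recovery_exact(self, scenario):
        series, truth = gen_fp_series(scenario, "direct", noise=False)
        fit = fit_fp_direct(series)
        assert fit.kd == pytest.approx(truth["kd_uM"], rel=1e-6)
        assert fit.fp0 == pytest.approx(truth["fp0"], abs=1e-8)
        assert fit.fps == pytest.approx(truth["fps"], abs=1e-8)

    def test_zero_protein_passes_through_fp0(self, scenario):
        series, _ = gen_fp_series(scenario, "direct", noise=False)
        fit = fit_fp_direct(series)
        assert fp_direct_forward(0.0, fit.fp0, fit.fps, fit.kd,
                                 series.tracer_conc) == pytest.approx(fit.fp0)

    def test_noisy_recovery(self, scenario):
        series, truth = gen_fp_series(scenario, "direct", noise=True)
        assert fit_fp_direct(series).kd == pytest.approx(truth["kd_uM"], rel=0.10)

    def test_wrong_mode_rejected(self, scenario):
        series, _ = gen_fp_series(scenario, "competition", noise=False)
        with pytest.raises(ValueError):
            fit_fp_direct(series)

    def test_depleting_reduces_to_hyperbola_at_trace_tracer(self):
        """With [L]/Kd <= 0.01 the quadratic and hyperbolic fits agree within 1%."""
        kd = 1.2
        x = np.concatenate([[0.0], np.geomspace(kd / 30, kd * 30, 11)])
        fp = fp_direct_forward(x, 0.05, 0.30, kd, tracer_conc=0.01 * kd)
        quad = fit_fp_direct(FPSeries(x, fp, "direct", tracer_conc=0.01 * kd))
        hyp = fit_fp_competition(FPSeries(x, fp, "competition"))
        assert quad.kd == pytest.approx(kd, rel=1e-6)
        assert hyp.c50 == pytest.approx(quad.kd, rel=0.01)


class TestFPCompetition:
    def test_noiseless_recovery_exact(self, scenario):
        series, truth = gen_fp_series(scenario, "competition",
                                      competition_c50_uM=50.0, noise=False)
        fit = fit_fp_competition(series)
        assert fit.c50 == pytest.approx(50.0, rel=1e-6)

    def test_midpoint_at_c50(self):
        fp_mid = hyperbola(50.0, 0.3, 0.05, 50.0)
        assert fp_mid == pytest.approx((0.3 + 0.05) / 2)

    def test_noisy_recovery(self, scenario):
        series, truth = gen_fp_series(scenario, "competition", noise=True)
        assert fit_fp_competition(series).c50 == pytest.approx(truth["c50_uM"], rel=0.10)


class TestSeriesValidation:
    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            TitrationSeries("x", [1, 2], [1.0])

    def test_negative_concentration(self):
        with pytest.raises(ValueError):
            TitrationSeries("x", [-1, 2, 3, 4, 5], np.ones(5))

    def test_nonpositive_ratio(self):
        with pytest.raises(ValueError):
            TitrationSeries("x", [1, 2, 3, 4, 5], [1, 1, 0, 1, 1])

    def test_fp_direct_requires_tracer(self):
        with pytest.raises(ValueError):
            FPSeries([0, 1, 2], [0.1, 0.2, 0.3], "direct")
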