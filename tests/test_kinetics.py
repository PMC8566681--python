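"""Zero-order log-linear kinetics and shelf-life extrapolation."""

import math

import pytest

from oxishelf import (
    CurveParams,
    DetectionConfig,
    ExtrapolationError,
    InsufficientDataError,
    IPMeasurement,
    KineticLaw,
    OxishelfError,
    extrapolate_shelf_life,
    fit_kinetics,
    pipeline_shelf_life,
    simulate_temperature_series,
)


def measurements(ips, temps=(70.0, 90.0, 100.0)):
    return [IPMeasurement(ip=ip, temperature=t) for ip, t in zip(ips, temps)]


class TestFitKinetics:
    def test_almond_series(self):
        fit = fit_kinetics(measurements([85.00, 20.62, 8.83]))
        assert fit.log_ip0 == 4.2126
        assert fit.k0 == 0.0325
        assert fit.r_squared == 0.9979

    def test_pecan_series(self):
        fit = fit_kinetics(measurements([151.00, 25.08, 10.11]))
        assert fit.log_ip0 == 4.9179

    def test_exact_generating_law_recovered(self):
        ips = [10.0 ** (5.0 - 0.04 * t) for t in (70.0, 90.0, 100.0)]
        fit = fit_kinetics(measurements(ips))
        assert (fit.log_ip0, fit.k0, fit.r_squared) == (5.0, 0.04, 1.0)

    def test_all_reference_oils_reproduce_printed_parameters(
        self, reference_ips, reference_kinetics
    ):
        for oil_id, ms in reference_ips.items():
            usable = [m for m in ms if not m.censored]
            if len(usable) < 3:
                continue  # the censored series cannot be refitted
            fit = fit_kinetics(usable)
            row = reference_kinetics.loc[oil_id]
            assert fit.log_ip0 == pytest.approx(row["log_ip0"], abs=1e-4), oil_id
            assert fit.k0 == pytest.approx(row["k0"], abs=1e-4), oil_id
            assert fit.r_squared == pytest.approx(row["r_squared"], abs=2e-4), oil_id

    def test_censored_measurements_excluded_with_warning(self):
        ms = measurements([85.0, 20.62, 8.83]) + [
            IPMeasurement(ip=240.0, temperature=60.0, censored=True)
        ]
        with pytest.warns(UserWarning, match="censored"):
            fit = fit_kinetics(ms)
        assert fit.n_points == 3

    def test_too_few_distinct_temperatures(self):
        with pytest.raises(InsufficientDataError):
            fit_kinetics(measurements([85.0, 20.0], temps=(70.0, 90.0)))

    def test_nonpositive_ip_rejected_at_construction(self):
        with pytest.raises(OxishelfError, match="non-positive"):
            IPMeasurement(ip=0.0, temperature=100.0)


class TestExtrapolation:
    def test_almond_ambient_shelf_life(self):
        fit = fit_kinetics(measurements([85.00, 20.62, 8.83]))
        assert extrapolate_shelf_life(fit, 25.0).days == 105
        assert extrapolate_shelf_life(fit, 20.0).days == 152

    def test_peanut_from_published_parameters(self):
        law = KineticLaw(log_ip0=5.3799, k0=0.0385)
        assert extrapolate_shelf_life(law, 25.0).days == 1089
        assert extrapolate_shelf_life(law, 20.0).days == 1697

    def test_constant_law_gives_one_day(self):
        law = KineticLaw(log_ip0=math.log10(24.0), k0=0.0)
        for temp in (5.0, 20.0, 25.0):
            assert extrapolate_shelf_life(law, temp).days == 1

    def test_all_reference_day_counts_reproduce(
        self, reference_ips, reference_kinetics
    ):
        for oil_id, ms in reference_ips.items():
            usable = [m for m in ms if not m.censored]
            if len(usable) < 3:
                fit = KineticLaw(
                    log_ip0=reference_kinetics.loc[oil_id, "log_ip0"],
                    k0=reference_kinetics.loc[oil_id, "k0"],
                )
            else:
                fit = fit_kinetics(usable)
            for temp in (20, 25):
                printed = reference_kinetics.loc[oil_id, f"shelf_life_{temp}_days"]
                assert extrapolate_shelf_life(fit, temp).days == printed, oil_id

    def test_upward_extrapolation_rejected(self):
        fit = fit_kinetics(measurements([85.00, 20.62, 8.83]))
        with pytest.raises(ExtrapolationError):
            extrapolate_shelf_life(fit, 70.0)
        with pytest.raises(ExtrapolationError):
            extrapolate_shelf_life(fit, 80.0)

    def test_shelf_life_decreasing_in_ambient_temperature(self):
        fit = fit_kinetics(measurements([85.00, 20.62, 8.83]))
        hours = [
            extrapolate_shelf_life(fit, t).ip_hours for t in (5.0, 15.0, 25.0)
        ]
        assert hours[0] > hours[1] > hours[2]


class TestPipeline:
    def test_noiseless_pipeline_reproduces_closed_form(self, almond_law):
        curves = simulate_temperature_series(
            almond_law, [70.0, 90.0, 100.0], CurveParams(noise_sd=0.0)
        )
        result = pipeline_shelf_life(curves, ambient=25.0)
        assert result.estimate.days == 105
        assert len(result.measurements) == 3

    def test_noiseless_parameter_recovery_within_half_percent(self, almond_law):
        curves = simulate_temperature_series(
            almond_law, [70.0, 90.0, 100.0], CurveParams(noise_sd=0.0)
        )
        fit = pipeline_shelf_life(curves, ambient=25.0).fit
        assert fit.log_ip0 == pytest.approx(4.2126, rel=0.005)
        assert fit.k0 == pytest.approx(0.0325, rel=0.005)

    def test_noisy_pipeline_within_five_percent(self, almond_law):
        curves = simulate_temperature_series(
            almond_law, [70.0, 90.0, 100.0], CurveParams(noise_sd=0.5, seed=11)
        )
        result = pipeline_shelf_life(curves, ambient=25.0)
        closed_form = 10.0 ** (4.2126 - 0.0325 * 25.0) / 24.0
        assert result.estimate.days == pytest.approx(closed_form, rel=0.05)

    def test_too_few_usable_curves_fails_with_stage_context(self, almond_law):
        curves = simulate_temperature_series(
            almond_law, [90.0, 100.0], CurveParams(noise_sd=0.0)
        )
        with pytest.raises(InsufficientDataError, match="kinetics stage"):
            pipeline_shelf_life(curves, ambient=25.0)

    def test_detection_failure_identifies_stage(self, almond_law):
        curves = simulate_temperature_series(
            almond_law, [70.0, 90.0, 100.0], CurveParams(noise_sd=0.0)
        )
        bad_cfg = DetectionConfig(min_slope_separation=1e6)
        with pytest.raises(OxishelfError, match="detection stage"):
            pipeline_shelf_life(curves, config=bad_cfg, ambient=25.0)
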