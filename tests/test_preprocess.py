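"""Calibration round trips, response correction, smoothing, modified-polynomial
baseline behavior and the 1440 cm^-1 count-based QC rules."""

import numpy as np
import pandas as pd
import pytest

from ramanremodel import (
    CalibrationStandard,
    ModPolyBaseline,
    SavGolSmoother,
    SpectralDataset,
    calibrate_raman_axis,
    correct_spectral_response,
    qc_filter,
    subtract_fluorescence_modpoly,
)
from ramanremodel.features import peak_intensity
from ramanremodel.preprocess import preprocess_dataset, raman_shift_cm1
from ramanremodel.spectra import DEFAULT_AXIS


def _dataset(intensities, axis=DEFAULT_AXIS):
    intensities = np.atleast_2d(intensities)
    meta = pd.DataFrame(
        dict(spectrum_id=[f"s{i}" for i in range(len(intensities))],
             mouse_id="m0", genotype="WT", gestation_day="4",
             site=range(len(intensities)))
    )
    return SpectralDataset(axis, intensities, meta)


class TestCalibration:
    def test_shift_formula_785_to_850(self):
        # direct evaluation of 1e7*(1/785 - 1/850)
        assert raman_shift_cm1(785.0, 850.0) == pytest.approx(974.15, abs=0.01)

    def test_elastic_line_has_zero_shift(self):
        assert raman_shift_cm1(785.0, 785.0) == 0.0

    def test_round_trip_recovers_excitation_wavelength(self):
        # known quadratic pixel -> nm map and known excitation
        true_map = np.array([1e-6, 0.08, 790.0])  # quadratic, highest first
        lam0 = 785.3
        lamp_px = np.array([50.0, 200, 400, 600, 850])
        lamp_nm = np.polyval(true_map, lamp_px)
        shift_px = np.array([120.0, 300, 500, 700])
        shift_cm1 = raman_shift_cm1(lam0, np.polyval(true_map, shift_px))
        cal = calibrate_raman_axis(
            [CalibrationStandard("lamp", "wavelength", lamp_nm, lamp_px),
             CalibrationStandard("naphthalene", "shift", shift_cm1, shift_px)]
        )
        assert cal.excitation_nm == pytest.approx(lam0, abs=0.01)
        assert np.abs(cal.line_residuals_cm1).max() < 1e-6
        assert cal.physical
        # composed map reproduces the true axis
        assert cal.shift_cm1(shift_px) == pytest.approx(shift_cm1, abs=1e-6)

    def test_too_few_lamp_lines_rejected(self):
        with pytest.raises(ValueError, match="lamp lines"):
            calibrate_raman_axis(
                [CalibrationStandard("lamp", "wavelength", [800.0, 810], [10.0, 20]),
                 CalibrationStandard("shift", "shift", [900.0, 1000], [30.0, 40])]
            )

    def test_unphysical_excitation_flagged(self):
        lamp_px = np.array([0.0, 500, 1000])
        lamp_nm = 1500.0 + 0.1 * lamp_px  # far infrared detector
        shift_px = np.array([100.0, 800])
        shift_cm1 = raman_shift_cm1(1450.0, 1500.0 + 0.1 * shift_px)
        with pytest.warns(UserWarning, match="outside"):
            cal = calibrate_raman_axis(
                [CalibrationStandard("lamp", "wavelength", lamp_nm, lamp_px),
                 CalibrationStandard("s", "shift", shift_cm1, shift_px)]
            )
        assert not cal.physical


class TestResponseCorrection:
    def test_unit_response_is_identity(self):
        ds = _dataset(np.random.default_rng(0).uniform(1, 2, DEFAULT_AXIS.size))
        lamp = np.full(DEFAULT_AXIS.size, 3.0)
        out = correct_spectral_response(ds, DEFAULT_AXIS, lamp, DEFAULT_AXIS, lamp)
        assert np.allclose(out.intensities, ds.intensities)

    def test_doubled_lamp_halves_output(self):
        ds = _dataset(np.ones(DEFAULT_AXIS.size))
        certified = np.full(DEFAULT_AXIS.size, 2.0)
        out = correct_spectral_response(ds, DEFAULT_AXIS, 2 * certified,
                                        DEFAULT_AXIS, certified)
        assert np.allclose(out.intensities, 0.5)

    def test_tilt_round_trip(self):
        rng = np.random.default_rng(1)
        original = rng.uniform(10, 20, DEFAULT_AXIS.size)
        tilt = 1.0 + 0.5 * (DEFAULT_AXIS - 900) / 900
        certified = np.full(DEFAULT_AXIS.size, 5.0)
        ds = _dataset(original * tilt)
        out = correct_spectral_response(ds, DEFAULT_AXIS, certified * tilt,
                                        DEFAULT_AXIS, certified)
        assert np.allclose(out.intensities[0], original, rtol=1e-10)

    def test_nonpositive_lamp_rejected_with_channel(self):
        ds = _dataset(np.ones(DEFAULT_AXIS.size))
        lamp = np.ones(DEFAULT_AXIS.size)
        lamp[500] = 0.0
        with pytest.raises(ValueError, match="1400"):
            correct_spectral_response(ds, DEFAULT_AXIS, lamp, DEFAULT_AXIS,
                                      np.ones(DEFAULT_AXIS.size))


class TestSmoothing:
    def test_polynomial_invariance(self):
        x = np.linspace(0, 1, 201)
        y = 3 + 2 * x - 5 * x**2 + x**3
        out = SavGolSmoother(11, 3).fit_transform(y[None, :])
        assert np.allclose(out[0], y, atol=1e-10)

    def test_window_one_is_identity(self):
        y = np.random.default_rng(2).normal(size=100)
        assert np.array_equal(SavGolSmoother(1, 0).fit_transform(y[None, :])[0], y)

    def test_noise_variance_reduced(self):
        y = np.random.default_rng(3).normal(size=2000)
        out = SavGolSmoother(11, 3).fit_transform(y[None, :])[0]
        assert out.var() < y.var()

    @pytest.mark.parametrize("window,polyorder", [(4, 2), (5, 5), (10001, 3)])
    def test_invalid_window_rejected(self, window, polyorder):
        with pytest.raises(ValueError):
            SavGolSmoother(window, polyorder).fit_transform(np.ones((1, 901)))


class TestModPoly:
    def test_pure_polynomial_removed(self):
        x = np.linspace(-1, 1, 901)
        y = 100 + 50 * x + 30 * x**2 - 20 * x**5
        est = ModPolyBaseline(degree=5, tol=1e-4)
        out = est.fit(y[None, :]).transform(y[None, :])
        assert np.abs(out).max() < 1e-4 * np.abs(y).max()
        assert est.converged_.all()

    def test_planted_peak_amplitude_recovered(self):
        axis = DEFAULT_AXIS
        t = (axis - axis[0]) / (axis[-1] - axis[0])
        baseline = 400 - 250 * t + 80 * t**2
        peak = 500.0 * np.exp(-0.5 * ((axis - 1304) / 6.0) ** 2)
        ds = _dataset(baseline + peak)
        corrected, baselines, est = subtract_fluorescence_modpoly(ds)
        recovered = peak_intensity(axis, corrected.intensities, 1304)
        assert recovered == pytest.approx(500.0, rel=0.05)

    def test_all_zero_spectrum(self):
        est = ModPolyBaseline()
        out = est.fit(np.zeros((1, 901))).transform(np.zeros((1, 901)))
        assert np.allclose(out, 0.0)
        assert np.allclose(est.baselines_, 0.0)

    def test_baseline_below_spectrum_at_convergence(self, small_cohort):
        (ds, _), _ = small_cohort
        sub = ds.select(np.arange(10))
        corrected, baselines, est = subtract_fluorescence_modpoly(sub)
        tol_slack = 1e-4 * np.abs(sub.intensities).max(axis=1, keepdims=True)
        overshoot = baselines - sub.intensities
        # baseline may poke above only within the convergence tolerance band,
        # except at the very channels where peaks were clipped hardest
        assert np.quantile(overshoot, 0.95) <= tol_slack.max()

    def test_nonconvergence_flagged_not_raised(self):
        y = np.random.default_rng(4).uniform(0, 1000, (1, 901))
        est = ModPolyBaseline(max_iter=2, tol=1e-12)
        est.fit(y).transform(y)
        assert not est.converged_.all()


class TestQC:
    def _spec_with_1440(self, value):
        y = np.zeros(DEFAULT_AXIS.size)
        y[np.argmin(np.abs(DEFAULT_AXIS - 1440))] = value
        return y

    def test_boundary_rules(self):
        ds = _dataset(np.vstack([self._spec_with_1440(v)
                                 for v in (90, 100, 1800, 1801)]))
        passed, report = qc_filter(ds)
        verdicts = report.table["verdict"].tolist()
        assert verdicts == ["low_signal", "pass", "pass", "high_adipose"]
        assert report.n_input == report.n_pass + report.n_removed_low_signal \
            + report.n_removed_adipose
        assert len(passed) == 2

    def test_qc_idempotent(self, small_cohort):
        (ds, _), _ = small_cohort
        passed, _ = qc_filter(ds)
        passed2, report2 = qc_filter(passed)
        assert len(passed2) == len(passed)
        assert report2.n_pass == report2.n_input

    def test_qc_uses_shared_peak_lookup(self, small_cohort):
        (ds, _), _ = small_cohort
        _, report = qc_filter(ds)
        expected = peak_intensity(ds.axis, ds.intensities, 1440.0, 8.0)
        assert np.array_equal(report.table["value_1440"].to_numpy(), expected)

    def test_empty_survivor_set_is_signaled_not_crashed(self):
        ds = _dataset(np.vstack([self._spec_with_1440(10.0)] * 3))
        passed, report = qc_filter(ds)
        assert len(passed) == 0
        assert report.n_pass == 0

    def test_planted_violations_removed_exactly(self, small_cohort):
        (ds, truth), _ = small_cohort
        passed, report, log = preprocess_dataset(ds)
        planted_low = (truth["qc_violation"] == "low").sum()
        planted_high = (truth["qc_violation"] == "high").sum()
        assert report.n_removed_low_signal == planted_low
        assert report.n_removed_adipose == planted_high
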