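"""Raw-detector to analysis-ready Raman spectra.

Stages, in instrument order: wavenumber-axis calibration (lamp emission lines
plus Raman-shift standards), spectral-response correction against a certified
tungsten lamp, optional dark-frame subtraction, Savitzky-Golay smoothing,
iterative modified-polynomial fluorescence subtraction, and the count-based
quality-control filter at the 1440 cm^-1 lipid peak.

The smoothing and baseline stages are scikit-learn transformers operating on
``(n_spectra, n_channels)`` arrays so they compose with sklearn pipelines;
dataset-level helpers wrap them for :class:`~ramanremodel.spectra.SpectralDataset`.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .features import peak_intensity
from .spectra import SpectralDataset, interp_to_axis

# ---------------------------------------------------------------- calibration


@dataclasses.dataclass
class CalibrationStandard:
    """A calibration standard: either a lamp with known emission wavelengths
    (``kind="wavelength"``, values in nm) or a Raman-shift standard such as
    naphthalene or acetaminophen (``kind="shift"``, values in cm^-1), each with
    the detected pixel position of every line."""

    name: str
    kind: str  # "wavelength" | "shift"
    known: Sequence[float]
    pixels: Sequence[float]

    def __post_init__(self):
        if self.kind not in ("wavelength", "shift"):
            raise ValueError("kind must be 'wavelength' or 'shift'")
        if len(self.known) != len(self.pixels):
            raise ValueError("known lines and pixel positions must pair up")


def raman_shift_cm1(excitation_nm: float, scattered_nm) -> np.ndarray:
    """Raman shift 1e7 * (1/lambda0 - 1/lambda), wavelengths in nm."""
    return 1e7 * (1.0 / excitation_nm - 1.0 / np.asarray(scattered_nm, float))


@dataclasses.dataclass
class AxisCalibration:
    """Composed pixel -> Raman shift map with the estimated excitation line."""

    wavelength_coeffs: np.ndarray  # pixel -> nm polynomial (numpy poly1d order)
    excitation_nm: float
    line_residuals_cm1: np.ndarray
    physical: bool  # excitation within 400-1100 nm

    def wavelength_nm(self, pixels) -> np.ndarray:
        return np.polyval(self.wavelength_coeffs, np.asarray(pixels, float))

    def shift_cm1(self, pixels) -> np.ndarray:
        return raman_shift_cm1(self.excitation_nm, self.wavelength_nm(pixels))


def calibrate_raman_axis(
    standards: Sequence[CalibrationStandard],
    laser_nm_guess: float = 785.0,
    degree: int = 2,
) -> AxisCalibration:
    """Fit the pixel -> wavelength polynomial from lamp lines and solve for the
    excitation wavelength from Raman-shift standards.

    The excitation line lambda0 minimizes the squared error between the known
    shifts and 1e7*(1/lambda0 - 1/lambda(pixel)); since the model is linear in
    1/lambda0 the minimizer is closed-form.  ``laser_nm_guess`` is only used
    to sanity-order the solution and plays no numerical role.
    """
    lamp_px, lamp_nm, shift_px, shift_cm1 = [], [], [], []
    for std in standards:
        if std.kind == "wavelength":
            lamp_px.extend(std.pixels)
            lamp_nm.extend(std.known)
        else:
            shift_px.extend(std.pixels)
            shift_cm1.extend(std.known)
    if len(lamp_px) < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} lamp lines for a degree-{degree} pixel map, "
            f"got {len(lamp_px)}"
        )
    if len(shift_px) < 2:
        raise ValueError("need at least 2 known-shift lines to solve for the excitation")
    coeffs = np.polyfit(np.asarray(lamp_px, float), np.asarray(lamp_nm, float), degree)

    lam = np.polyval(coeffs, np.asarray(shift_px, float))
    nu = np.asarray(shift_cm1, float)
    # nu_k = 1e7/lambda0 - 1e7/lambda_k  =>  1e7/lambda0 = mean(nu_k + 1e7/lambda_k)
    inv0 = np.mean(nu + 1e7 / lam) / 1e7
    excitation = 1.0 / inv0
    residuals = nu - raman_shift_cm1(excitation, lam)
    physical = 400.0 <= excitation <= 1100.0
    if not physical:
        warnings.warn(
            f"estimated excitation {excitation:.1f} nm is outside 400-1100 nm",
            stacklevel=2,
        )
    return AxisCalibration(coeffs, float(excitation), residuals, physical)


# ------------------------------------------------------------------ response


def correct_spectral_response(
    dataset: SpectralDataset,
    measured_lamp_axis: np.ndarray,
    measured_lamp: np.ndarray,
    certified_axis: np.ndarray,
    certified_curve: np.ndarray,
) -> SpectralDataset:
    """Flat-field against a NIST-traceable tungsten lamp.

    Both lamp records are linearly interpolated onto the dataset axis; output
    intensity is ``input * certified / measured`` channel-wise.
    """
    measured = interp_to_axis(measured_lamp_axis, measured_lamp, dataset.axis)
    certified = interp_to_axis(certified_axis, certified_curve, dataset.axis)
    bad = np.flatnonzero(measured <= 0)
    if bad.size:
        raise ValueError(
            f"measured lamp is non-positive at {dataset.axis[bad[0]]:.1f} cm^-1 "
            f"(channel {bad[0]})"
        )
    factor = certified / measured
    return dataset.with_intensities(dataset.intensities * factor)


def subtract_dark(dataset: SpectralDataset, dark) -> SpectralDataset:
    """Subtract a recorded dark frame (or constant offset) from every spectrum."""
    dark = np.asarray(dark, dtype=float)
    return dataset.with_intensities(dataset.intensities - dark)


# ----------------------------------------------------------------- smoothing


class SavGolSmoother(BaseEstimator, TransformerMixin):
    """Savitzky-Golay smoothing transformer (odd ``window`` > ``polyorder``).

    Endpoints are handled by polynomial fits on the truncated window
    (``mode="interp"``); ``window=1`` is the identity.
    """

    def __init__(self, window: int = 11, polyorder: int = 3):
        self.window = window
        self.polyorder = polyorder

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, float))
        self._validate(X.shape[1])
        self.n_features_in_ = X.shape[1]
        return self

    def _validate(self, n_channels: int) -> None:
        if self.window % 2 == 0 or self.window < 1:
            raise ValueError("window must be odd and >= 1")
        if self.window > 1 and self.window <= self.polyorder:
            raise ValueError("window must exceed polyorder")
        if self.window > n_channels:
            raise ValueError(
                f"window {self.window} is longer than the spectrum ({n_channels})"
            )

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        self._validate(X.shape[1])
        if self.window == 1:
            return X.copy()
        return savgol_filter(X, self.window, self.polyorder, axis=-1, mode="interp")


def smooth(dataset: SpectralDataset, window: int = 11, polyorder: int = 3) -> SpectralDataset:
    return dataset.with_intensities(
        SavGolSmoother(window, polyorder).fit_transform(dataset.intensities)
    )


# ------------------------------------------------- modified-polynomial baseline


class ModPolyBaseline(BaseEstimator, TransformerMixin):
    """Iterative modified-polynomial fluorescence baseline removal.

    Each iteration fits a degree-``degree`` polynomial to the working spectrum
    and clips the working spectrum to the fit wherever it exceeds it, so the
    polynomial migrates to the fluorescence envelope beneath the Raman bands.
    Iteration stops when the maximum relative change of the fit drops below
    ``tol`` or after ``max_iter`` rounds.  ``transform`` returns the
    baseline-subtracted spectra (no non-negativity clipping); the baselines,
    iteration counts and convergence flags from the last transform are kept in
    ``baselines_``, ``n_iter_`` and ``converged_``.
    """

    def __init__(self, degree: int = 5, tol: float = 1e-4, max_iter: int = 100):
        self.degree = degree
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        self.n_features_in_ = np.atleast_2d(np.asarray(X, float)).shape[1]
        return self

    def transform(self, X, axis: np.ndarray | None = None) -> np.ndarray:
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        Y = np.atleast_2d(np.asarray(X, float))
        n, m = Y.shape
        x = np.linspace(-1.0, 1.0, m) if axis is None else (
            2.0 * (np.asarray(axis, float) - axis[0]) / (axis[-1] - axis[0]) - 1.0
        )
        V = np.polynomial.polynomial.polyvander(x, self.degree)  # (m, d+1)
        Q, R = np.linalg.qr(V)
        proj = Q @ Q.T  # least-squares hat matrix, shared across spectra

        work = Y.copy()
        fit = work @ proj.T
        converged = np.zeros(n, dtype=bool)
        n_iter = np.full(n, self.max_iter, dtype=int)
        for it in range(1, self.max_iter + 1):
            prev = fit
            work = np.minimum(work, fit)
            fit = work @ proj.T
            scale = np.maximum(np.abs(fit).max(axis=1), 1e-12)
            delta = np.abs(fit - prev).max(axis=1) / scale
            newly = (~converged) & (delta < self.tol)
            n_iter[newly] = it
            converged |= newly
            if converged.all():
                break
        self.baselines_ = fit
        self.n_iter_ = n_iter
        self.converged_ = converged
        return Y - fit


def subtract_fluorescence_modpoly(
    dataset: SpectralDataset, degree: int = 5, tol: float = 1e-4, max_iter: int = 100
) -> tuple[SpectralDataset, np.ndarray, ModPolyBaseline]:
    """Dataset-level modified-polynomial subtraction.

    Returns ``(corrected dataset, baselines, fitted transformer)``; spectra
    that hit ``max_iter`` are returned with ``converged_`` False, not raised.
    """
    est = ModPolyBaseline(degree=degree, tol=tol, max_iter=max_iter)
    corrected = est.fit(dataset.intensities).transform(dataset.intensities, axis=dataset.axis)
    return dataset.with_intensities(corrected), est.baselines_, est


# ------------------------------------------------------------------------ QC


@dataclasses.dataclass
class QCReport:
    """Per-spectrum QC verdicts at the 1440 cm^-1 peak plus summary counts."""

    table: pd.DataFrame  # spectrum_id, value_1440, verdict
    low_thresh: float
    high_thresh: float

    @property
    def n_input(self) -> int:
        return len(self.table)

    @property
    def n_removed_low_signal(self) -> int:
        return int((self.table["verdict"] == "low_signal").sum())

    @property
    def n_removed_adipose(self) -> int:
        return int((self.table["verdict"] == "high_adipose").sum())

    @property
    def n_pass(self) -> int:
        return int((self.table["verdict"] == "pass").sum())

    def write(self, path) -> None:
        self.table.to_csv(path, index=False)


def qc_filter(
    dataset: SpectralDataset,
    low_thresh: float = 100.0,
    high_thresh: float = 1800.0,
    peak: float = 1440.0,
    half_window: float = 8.0,
) -> tuple[SpectralDataset, QCReport]:
    """Remove low-signal (< ``low_thresh`` counts at 1440 cm^-1) and
    high-adipose (> ``high_thresh`` counts) spectra.

    Both comparisons are strict, so a spectrum at exactly 1800 counts is
    retained.  The peak lookup is the same windowed maximum used everywhere
    else in the pipeline.  An empty surviving set is returned as an empty
    dataset, never raised.
    """
    values = peak_intensity(dataset.axis, dataset.intensities, peak, half_window)
    verdict = np.where(
        values < low_thresh, "low_signal", np.where(values > high_thresh, "high_adipose", "pass")
    )
    report = QCReport(
        pd.DataFrame(
            {
                "spectrum_id": dataset.meta["spectrum_id"].to_numpy(),
                "value_1440": values,
                "verdict": verdict,
            }
        ),
        low_thresh,
        high_thresh,
    )
    passed = dataset.select(verdict == "pass")
    return passed, report


# ------------------------------------------------------------- full pipeline


def preprocess_dataset(
    dataset: SpectralDataset,
    *,
    dark=None,
    sg_window: int = 11,
    sg_polyorder: int = 3,
    modpoly_degree: int = 5,
    modpoly_tol: float = 1e-4,
    modpoly_max_iter: int = 100,
    qc_low: float = 100.0,
    qc_high: float = 1800.0,
) -> tuple[SpectralDataset, QCReport, dict]:
    """Dark-subtract, smooth, remove fluorescence, and QC-filter a dataset.

    Returns the surviving dataset, the QC report and a log dict of the
    parameters actually applied (the smoothing window/order and baseline
    settings are instrument-dependent and always recorded).
    """
    work = dataset
    if dark is not None:
        work = subtract_dark(work, dark)
    work = smooth(work, sg_window, sg_polyorder)
    work, baselines, est = subtract_fluorescence_modpoly(
        work, modpoly_degree, modpoly_tol, modpoly_max_iter
    )
    passed, report, = qc_filter(work, qc_low, qc_high)
    log = dict(
        sg_window=sg_window,
        sg_polyorder=sg_polyorder,
        modpoly_degree=modpoly_degree,
        modpoly_tol=modpoly_tol,
        modpoly_max_iter=modpoly_max_iter,
        modpoly_converged_frac=float(np.mean(est.converged_)),
        qc_low=qc_low,
        qc_high=qc_high,
        n_input=report.n_input,
        n_removed_low_signal=report.n_removed_low_signal,
        n_removed_adipose=report.n_removed_adipose,
        n_pass=report.n_pass,
    )
    return passed, report, log
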