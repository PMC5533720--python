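"""Peak intensities, peak ratios, per-mouse averaging, display normalization.

The windowed peak lookup here is the single implementation shared with the
QC filter.  Ratios are always computed on non-normalized spectra, per
spectrum, *before* any averaging (ratio-then-average, not the reverse); the
raw 1440 cm^-1 intensity is carried along as the longitudinal model's
intensity covariate.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .spectra import SpectralDataset

log = logging.getLogger(__name__)

#: nominal peak centers (cm^-1) extracted for every spectrum
DEFAULT_PEAKS = (1003, 1265, 1304, 1440, 1657)

#: ratio name -> (numerator peak, denominator peak)
DEFAULT_RATIOS = {
    "r1304_1265": (1304, 1265),
    "r1265_1440": (1265, 1440),
    "r1657_1440": (1657, 1440),
    "r1003_1440": (1003, 1440),
}

GROUP_KEYS = ["mouse_id", "genotype", "gestation_day"]


def peak_intensity(axis, intensities, center: float, half_window: float = 8.0):
    """Maximum intensity within ``center +/- half_window`` cm^-1.

    Works on a single spectrum (1-D) or a stack (2-D, channels last); the
    windowed maximum is robust to small calibration jitter of the peak.
    """
    axis = np.asarray(axis, float)
    mask = np.abs(axis - center) <= half_window
    if not mask.any():
        raise ValueError(
            f"window {center}+/-{half_window} cm^-1 does not intersect the axis "
            f"[{axis[0]}, {axis[-1]}]"
        )
    intensities = np.asarray(intensities, float)
    return intensities[..., mask].max(axis=-1)


def compute_ratio_table(
    dataset: SpectralDataset,
    peaks=DEFAULT_PEAKS,
    ratios: dict[str, tuple[float, float]] = DEFAULT_RATIOS,
    half_window: float = 8.0,
) -> pd.DataFrame:
    """Per-spectrum peak intensities and ratios (one row per QC-passed spectrum).

    Rows whose ratio denominator is non-positive are flagged, logged and
    excluded.  Refuses display-normalized datasets: statistics always run on
    raw intensities.
    """
    if dataset.display_normalized:
        raise ValueError(
            "dataset is display-normalized; statistics must use non-normalized spectra"
        )
    out = dataset.meta.copy()
    for p in peaks:
        out[f"i{p}"] = peak_intensity(dataset.axis, dataset.intensities, p, half_window)
    ok = np.ones(len(out), dtype=bool)
    for name, (num, den) in ratios.items():
        denom = out[f"i{den}"].to_numpy()
        valid = denom > 0
        out[name] = np.where(valid, out[f"i{num}"].to_numpy() / np.where(valid, denom, 1.0), np.nan)
        ok &= valid
    if not ok.all():
        bad = out.loc[~ok, "spectrum_id"].tolist()
        log.warning("excluding %d spectra with non-positive ratio denominators: %s",
                    len(bad), bad)
    return out[ok].reset_index(drop=True)


def average_by_mouse(table: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of every feature per mouse x gestation day.

    Keeps an ``n_spectra`` column; order of input rows is irrelevant.
    """
    value_cols = [c for c in table.columns
                  if c not in GROUP_KEYS + ["spectrum_id", "site"]]
    grouped = table.groupby(GROUP_KEYS, sort=True, dropna=False)
    out = grouped[value_cols].mean().reset_index()
    out["n_spectra"] = grouped.size().to_numpy()
    return out


def group_summary(per_mouse: pd.DataFrame, feature: str) -> pd.DataFrame:
    """Group mean +/- SEM of ``feature`` over mice (biological replicates)."""
    g = per_mouse.groupby(["genotype", "gestation_day"], dropna=False)[feature]
    out = g.agg(mean="mean", sd="std", n_mice="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n_mice"])
    return out.drop(columns=["sd"])


def normalize_for_display(dataset: SpectralDataset, peak: float = 1440.0,
                          half_window: float = 8.0) -> SpectralDataset:
    """Divide each spectrum by its 1440 cm^-1 peak — plotting only.

    The returned dataset is flagged ``display_normalized`` and is rejected by
    the statistics path.
    """
    peaks = peak_intensity(dataset.axis, dataset.intensities, peak, half_window)
    if np.any(peaks <= 0):
        bad = dataset.meta["spectrum_id"].to_numpy()[np.asarray(peaks) <= 0]
        raise ValueError(f"non-positive {peak} cm^-1 peak in spectra {bad.tolist()}")
    return dataset.with_intensities(
        dataset.intensities / np.atleast_1d(peaks)[:, None], display_normalized=True
    )
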