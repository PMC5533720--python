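"""Containers for calibrated Raman spectra and cohort manifests.

A :class:`SpectralDataset` holds a stack of spectra sharing one wavenumber
axis together with a per-spectrum metadata table (mouse, genotype, gestation
day, measurement site).  All cross-spectrum arithmetic in the pipeline happens
on a common 1 cm^-1 grid; :func:`interp_to_axis` is the single resampling
entry point.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

#: default common analysis grid, cm^-1 (fingerprint region)
DEFAULT_AXIS = np.arange(900.0, 1801.0, 1.0)

META_COLUMNS = ["spectrum_id", "mouse_id", "genotype", "gestation_day", "site"]


def _check_axis(axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 2:
        raise ValueError("axis must be a 1-D array with at least 2 points")
    if not np.all(np.diff(axis) > 0):
        raise ValueError("wavenumber axis must be strictly increasing")
    return axis


@dataclasses.dataclass
class SpectralDataset:
    """A stack of spectra on one wavenumber axis plus per-spectrum metadata.

    Parameters
    ----------
    axis : (n_channels,) strictly increasing wavenumber grid in cm^-1.
    intensities : (n_spectra, n_channels) detector counts per channel.
    meta : DataFrame with one row per spectrum; at minimum ``spectrum_id``,
        ``mouse_id``, ``genotype``, ``gestation_day``, ``site``.
    display_normalized : True only for peak-normalized copies intended for
        plotting; the statistics path refuses such datasets.
    """

    axis: np.ndarray
    intensities: np.ndarray
    meta: pd.DataFrame
    display_normalized: bool = False

    def __post_init__(self) -> None:
        self.axis = _check_axis(self.axis)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.intensities.shape[1] != self.axis.size:
            raise ValueError(
                f"intensities have {self.intensities.shape[1]} channels, "
                f"axis has {self.axis.size}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if len(self.meta) != self.intensities.shape[0]:
            raise ValueError("meta must have one row per spectrum")
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.axis.size

    def select(self, mask) -> "SpectralDataset":
        """Row-subset by boolean mask or integer index array."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SpectralDataset(
            self.axis,
            self.intensities[idx],
            self.meta.iloc[idx].reset_index(drop=True),
            display_normalized=self.display_normalized,
        )

    def with_intensities(self, intensities: np.ndarray, *, display_normalized=None) -> "SpectralDataset":
        return SpectralDataset(
            self.axis,
            intensities,
            self.meta.copy(),
            display_normalized=(
                self.display_normalized if display_normalized is None else display_normalized
            ),
        )

    # ------------------------------------------------------------------ IO
    def write(self, directory: str | Path) -> pd.DataFrame:
        """Write one two-column CSV per spectrum plus a manifest CSV.

        Returns the manifest (with ``spectrum_path`` relative to *directory*).
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = self.meta.copy()
        paths = []
        for i in range(len(self)):
            name = f"{manifest['spectrum_id'].iloc[i]}.csv"
            pd.DataFrame(
                {"wavenumber_cm1": self.axis, "intensity_counts": self.intensities[i]}
            ).to_csv(directory / name, index=False)
            paths.append(name)
        manifest.insert(0, "spectrum_path", paths)
        manifest.to_csv(directory / "manifest.csv", index=False)
        return manifest

    @classmethod
    def read(cls, manifest_path: str | Path) -> "SpectralDataset":
        """Load a dataset written by :meth:`write` (all spectra must share one axis)."""
        manifest_path = Path(manifest_path)
        manifest = pd.read_csv(manifest_path)
        base = manifest_path.parent
        axis = None
        rows = []
        for rel in manifest["spectrum_path"]:
            tbl = pd.read_csv(base / rel)
            ax = tbl["wavenumber_cm1"].to_numpy(float)
            if axis is None:
                axis = ax
            elif not np.allclose(ax, axis):
                raise ValueError(f"spectrum {rel} is not on the shared axis")
            rows.append(tbl["intensity_counts"].to_numpy(float))
        meta = manifest.drop(columns=["spectrum_path"])
        return cls(axis, np.vstack(rows), meta)


def interp_to_axis(axis_src, values, axis_dst=DEFAULT_AXIS) -> np.ndarray:
    """Linearly resample ``values`` (1-D or 2-D, channels last) onto ``axis_dst``."""
    axis_src = _check_axis(axis_src)
    axis_dst = _check_axis(axis_dst)
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        return np.interp(axis_dst, axis_src, values)
    return np.vstack([np.interp(axis_dst, axis_src, row) for row in values])
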