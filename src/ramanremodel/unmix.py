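"""Non-negative least-squares decomposition into collagen, water and adipose.

Each fluorescence-subtracted tissue spectrum Y is decomposed as
Y = X beta + eps with beta >= 0, where the design matrix X holds the pure
reference spectra.  For the dimensionless residual-exclusion rule each
spectrum is max-normalized before fitting (the published 0.3 threshold cannot
apply to raw counts spanning 100-1800+), and the raw-scale coefficients are
recovered by multiplying back; both scales are reported.  The "summed
residual" defaults to the sum of absolute residuals (a signed sum would
cancel; configurable to ``signed`` or ``squared``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin

from .features import GROUP_KEYS
from .spectra import SpectralDataset
from .synthetic import PureComponentLibrary


def preprocess_library(
    library: PureComponentLibrary,
    scale_counts: float = 500.0,
    sg_window: int = 11,
    sg_polyorder: int = 3,
    modpoly_degree: int = 5,
    modpoly_tol: float = 1e-4,
    modpoly_max_iter: int = 100,
) -> PureComponentLibrary:
    """Run each pure component through the tissue preprocessing path.

    Reference spectra entering the design matrix X should see the same
    smoothing and modified-polynomial baseline treatment as the tissue
    spectra they will be fit to, so the envelope bias of the baseline step
    largely cancels between X and Y.  Components are scaled to a tissue-like
    count level first, then re-normalized to unit maximum.
    """
    from .preprocess import ModPolyBaseline, SavGolSmoother

    Y = library.matrix().T * scale_counts
    Y = SavGolSmoother(sg_window, sg_polyorder).fit_transform(Y)
    est = ModPolyBaseline(modpoly_degree, modpoly_tol, modpoly_max_iter)
    Y = est.fit(Y).transform(Y, axis=library.axis)
    Y = np.clip(Y, 0.0, None)
    Y /= Y.max(axis=1, keepdims=True)
    return PureComponentLibrary(
        library.axis,
        pd.DataFrame(Y.T, columns=library.names),
        provenance=library.provenance + " (mirrored tissue preprocessing)",
    )


class NNLSUnmixer(BaseEstimator, TransformerMixin):
    """Active-set NNLS spectral unmixing against a fixed component library.

    ``fit`` takes the component matrix (``(n_components, n_channels)`` array
    or a :class:`PureComponentLibrary`); ``transform`` maps spectra to
    non-negative coefficients, sklearn-decomposition style.  Fitted
    attributes: ``components_``, ``component_names_``.
    """

    def fit(self, X, y=None):
        if isinstance(X, PureComponentLibrary):
            comps = X.matrix().T
            names = X.names
        else:
            comps = np.atleast_2d(np.asarray(X, float))
            names = [f"c{i}" for i in range(comps.shape[0])]
        if np.linalg.matrix_rank(comps) < comps.shape[0]:
            raise ValueError("degenerate component library: components are collinear")
        self.components_ = comps
        self.component_names_ = list(names)
        self.n_features_in_ = comps.shape[1]
        return self

    def transform(self, Y) -> np.ndarray:
        Y = np.atleast_2d(np.asarray(Y, float))
        A = self.components_.T  # (n_channels, k)
        beta = np.empty((Y.shape[0], A.shape[1]))
        for i, y in enumerate(Y):
            beta[i], _ = nnls(A, y)
        return beta

    def inverse_transform(self, beta) -> np.ndarray:
        return np.atleast_2d(np.asarray(beta, float)) @ self.components_


def summed_residual(residual: np.ndarray, stat: str = "abs") -> np.ndarray:
    """Scalar residual per spectrum: sum of ``abs`` (default), ``signed`` or
    ``squared`` channel residuals."""
    residual = np.atleast_2d(residual)
    if stat == "abs":
        return np.abs(residual).sum(axis=1)
    if stat == "signed":
        return residual.sum(axis=1)
    if stat == "squared":
        return (residual**2).sum(axis=1)
    raise ValueError(f"unknown residual statistic {stat!r}")


def nnls_fit(
    dataset: SpectralDataset,
    library: PureComponentLibrary,
    residual_stat: str = "abs",
) -> pd.DataFrame:
    """Unmix every spectrum; one row per spectrum with both coefficient scales.

    Columns: ``beta_<comp>`` (raw counts scale), ``beta_<comp>_norm``
    (max-normalized scale used for the exclusion rule), ``summed_residual``
    (on the normalized scale), and the spectrum metadata.  Coefficients are
    non-negative by construction and asserted so.
    """
    if not np.allclose(dataset.axis, library.axis):
        raise ValueError("spectra and component library must share one axis")
    est = NNLSUnmixer().fit(library)
    Y = dataset.intensities
    scale = np.abs(Y).max(axis=1)
    scale = np.where(scale > 0, scale, 1.0)
    Yn = Y / scale[:, None]
    beta_norm = est.transform(Yn)
    assert (beta_norm >= 0).all(), "NNLS returned a negative coefficient"
    resid = Yn - est.inverse_transform(beta_norm)
    out = dataset.meta.copy()
    for j, name in enumerate(est.component_names_):
        out[f"beta_{name}"] = beta_norm[:, j] * scale
        out[f"beta_{name}_norm"] = beta_norm[:, j]
    out["spectrum_scale"] = scale
    out["summed_residual"] = summed_residual(resid, residual_stat)
    return out


def filter_by_residual(
    results: pd.DataFrame, threshold: float = 0.3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude fits whose summed residual is strictly greater than ``threshold``.

    Returns ``(kept, exclusion_report)``; a summed residual of exactly the
    threshold is kept.
    """
    excluded = results["summed_residual"] > threshold
    report = results.loc[excluded, ["spectrum_id", "summed_residual"]].reset_index(drop=True)
    return results[~excluded].reset_index(drop=True), report


def component_summary(
    kept: pd.DataFrame, components=("collagen", "water", "adipose")
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-mouse mean coefficients, then group mean +/- SEM per genotype x day.

    Empty genotype-day groups simply have no row; groups present in the
    per-mouse table always appear.  Returns ``(per_mouse, per_group)``.
    """
    cols = [f"beta_{c}" for c in components]
    grouped = kept.groupby(GROUP_KEYS, sort=True, dropna=False)
    per_mouse = grouped[cols].mean().reset_index()
    per_mouse["n_spectra"] = grouped.size().to_numpy()

    g = per_mouse.groupby(["genotype", "gestation_day"], dropna=False)
    rows = []
    for (genotype, day), sub in g:
        row = dict(genotype=genotype, gestation_day=day, n_mice=len(sub))
        for c in cols:
            row[f"{c}_mean"] = sub[c].mean()
            row[f"{c}_sem"] = sub[c].std() / np.sqrt(len(sub)) if len(sub) > 1 else np.nan
        rows.append(row)
    return per_mouse, pd.DataFrame(rows)
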