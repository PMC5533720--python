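"""Cross-modality Spearman correlation of Raman features vs mechanics measures.

Rows are per-animal Raman features (four peak ratios plus the collagen
unmixing coefficient), columns the seven biomechanical measures; pairing is
at the animal level (in vivo spectra acquired before excision of the same
cervix).  No multiplicity correction is applied across cells; the raw
significance tiers are reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_FEATURES = ("r1304_1265", "r1265_1440", "r1657_1440", "r1003_1440",
                    "beta_collagen")
DEFAULT_MEASURES = ("impulse_A", "impulse_x_intercept",
                    "equilibrium_A", "equilibrium_x_intercept",
                    "initial_dilation_mm", "total_dilation_mm", "max_stress")


def spearman_matrix(
    raman: pd.DataFrame,
    mechanics: pd.DataFrame,
    features=DEFAULT_FEATURES,
    measures=DEFAULT_MEASURES,
    key: str = "mouse_id",
    min_n: int = 3,
) -> pd.DataFrame:
    """Spearman rho (mid-rank ties), two-sided p and n for every
    feature x measure cell, paired on ``key``.

    Cells with fewer than ``min_n`` paired animals are flagged ``low_n`` and
    carry NaN statistics.  Raises if the tables share no animals at all.
    """
    merged = raman.merge(mechanics, on=key, how="inner", suffixes=("", "_mech"))
    if merged.empty:
        raise ValueError("no overlapping animals between Raman and mechanics tables")
    rows = []
    for f in features:
        for m in measures:
            sub = merged[[f, m]].dropna()
            n = len(sub)
            if n < min_n:
                rows.append(dict(feature=f, measure=m, rho=np.nan, p=np.nan,
                                 n=n, low_n=True))
                continue
            rho, p = stats.spearmanr(sub[f], sub[m])
            rows.append(dict(feature=f, measure=m, rho=float(rho), p=float(p),
                             n=n, low_n=False))
    return pd.DataFrame(rows)


def matrix_pivot(cells: pd.DataFrame, value: str = "rho") -> pd.DataFrame:
    return cells.pivot(index="feature", columns="measure", values=value)


def plot_heatmap(cells: pd.DataFrame, path) -> None:
    """Diverging heatmap of the correlation matrix (figure companion to the
    CSV the matrix is always written as)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = matrix_pivot(cells)
    fig, ax = plt.subplots(figsize=(1.2 * grid.shape[1] + 2, 0.8 * grid.shape[0] + 2))
    im = ax.imshow(grid.to_numpy(float), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(grid.shape[1]), grid.columns, rotation=45, ha="right")
    ax.set_yticks(range(grid.shape[0]), grid.index)
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            v = grid.iat[i, j]
            if np.isfinite(v):
                ax.text(j, i, f"{v:.2f}", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    ax.set_title("Raman features vs biomechanical measures\n(no multiplicity correction)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
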