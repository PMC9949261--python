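"""V x J primer-pair dependence diagnostics.

Every primer pair shares its V primer with the other J primers and vice
versa, so template counts need not be independent across pairs.  Laying
the per-pair means on the |V| x |J| grid and treating it as a contingency
table, deviation from row/column independence is measured by signed
Pearson residuals

    (O - E) / sqrt(E),   E = row total x column total / grand total,

positive where a pair is over-represented relative to its margins.  The
sum of squared residuals is the classic chi-squared statistic.
Hierarchical clustering of residual rows/columns (average linkage,
Euclidean) exposes groups of V and J primers that move together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .panel import PanelError, PrimerPanel

__all__ = ["ResidualMatrix", "vj_table", "pearson_residuals", "cluster_order"]


def vj_table(means, panel: PrimerPanel) -> pd.DataFrame:
    """Reshape a pair-indexed vector onto the |V| x |J| grid."""
    values = np.asarray(means, dtype=float)
    if values.shape != (panel.n_pairs,):
        raise PanelError(
            f"vector length {values.shape} does not match {panel.n_pairs} pairs"
        )
    return pd.DataFrame(values.reshape(panel.n_v, panel.n_j),
                        index=list(panel.v_names), columns=list(panel.j_names))


@dataclass
class ResidualMatrix:
    """Signed Pearson residuals of a V x J table under independence."""

    values: pd.DataFrame
    chi_square: float
    expected: pd.DataFrame
    dropped_rows: tuple[str, ...] = ()
    dropped_cols: tuple[str, ...] = ()


def pearson_residuals(observed) -> ResidualMatrix:
    """Residuals (O - E)/sqrt(E) with E from the table margins.

    All-zero rows/columns are dropped with a warning (their expectation
    is zero).  A rank-one table — exactly independent margins — gives
    all-zero residuals and chi_square 0.
    """
    O = pd.DataFrame(observed).astype(float)
    if O.size == 0 or float(O.to_numpy().sum()) <= 0:
        raise ValueError("observed table must have a positive grand total")
    if np.any(O.to_numpy() < 0):
        raise ValueError("observed table must be non-negative")
    row_zero = O.sum(axis=1) == 0
    col_zero = O.sum(axis=0) == 0
    if row_zero.any() or col_zero.any():
        warnings.warn(
            f"dropping {int(row_zero.sum())} all-zero row(s) and "
            f"{int(col_zero.sum())} all-zero column(s)", stacklevel=2,
        )
        O = O.loc[~row_zero, ~col_zero]
    vals = O.to_numpy()
    r = vals.sum(axis=1, keepdims=True)
    c = vals.sum(axis=0, keepdims=True)
    E = r @ c / vals.sum()
    res = (vals - E) / np.sqrt(E)
    return ResidualMatrix(
        values=pd.DataFrame(res, index=O.index, columns=O.columns),
        chi_square=float((res**2).sum()),
        expected=pd.DataFrame(E, index=O.index, columns=O.columns),
        dropped_rows=tuple(row_zero.index[row_zero]),
        dropped_cols=tuple(col_zero.index[col_zero]),
    )


def cluster_order(res: ResidualMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Leaf orders from average-linkage Euclidean clustering of residuals.

    Returns (row permutation, column permutation); deterministic for a
    given input.  Rows (columns) with identical residual profiles end up
    adjacent.
    """
    vals = res.values.to_numpy()
    if vals.shape[0] < 2 or vals.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns to cluster")
    row_order = leaves_list(linkage(vals, method="average", metric="euclidean"))
    col_order = leaves_list(linkage(vals.T, method="average", metric="euclidean"))
    return row_order, col_order


def plot_heatmap(res: ResidualMatrix, path=None, cluster: bool = True,
                 cmap: str = "bwr"):
    """Optional heatmap export of the (clustered) residual matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = res.values
    if cluster:
        ro, co = cluster_order(res)
        vals = vals.iloc[ro, co]
    lim = float(np.abs(vals.to_numpy()).max()) or 1.0
    fig, ax = plt.subplots(figsize=(0.45 * vals.shape[1] + 2,
                                    0.3 * vals.shape[0] + 2))
    im = ax.imshow(vals.to_numpy(), cmap=cmap, vmin=-lim, vmax=lim,
                   aspect="auto")
    ax.set_xticks(range(vals.shape[1]), vals.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(vals.shape[0]), vals.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="(O - E)/sqrt(E)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
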