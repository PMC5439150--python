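"""Derived genetic summaries: heritability trajectories, correlation matrices,
eigen-decomposition of the genetic covariance.

In the no-residual model the pseudo-permanent covariance P already contains
the residual variance, so heritability at time t is simply
``h2 = U_tt / (U_tt + P_tt [+ group variance])`` with the diagonals taken per
trait; whether extra random-intercept variances (e.g. contemporary group)
enter the phenotypic denominator is switchable and on by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .covariance import TraitTimeIndex, correlation_from_covariance

__all__ = [
    "heritability_from_matrices",
    "labelled_correlation",
    "eigen_summary",
    "plot_correlation_heatmap",
]


def heritability_from_matrices(
    U: np.ndarray,
    P: np.ndarray,
    traits,
    times,
    group_vars: np.ndarray | None = None,
) -> pd.DataFrame:
    """Heritability per trait and time from the cell-diagonal variance
    components; rows are times, columns traits.  Raises on a non-positive
    phenotypic variance."""
    traits = list(traits)
    n_traits = len(traits)
    du = np.diag(np.asarray(U, dtype=float))
    dp = np.diag(np.asarray(P, dtype=float))
    extra = np.zeros(n_traits)
    if group_vars is not None:
        extra = np.asarray(group_vars, dtype=float).reshape(-1, n_traits).sum(axis=0)
    out = np.empty((len(times), n_traits))
    for j in range(len(times)):
        for k in range(n_traits):
            cell = j * n_traits + k
            denom = du[cell] + dp[cell] + extra[k]
            if denom <= 0:
                raise ValueError(f"non-positive phenotypic variance at time {times[j]}, trait {traits[k]}")
            out[j, k] = du[cell] / denom
    return pd.DataFrame(out, index=[f"t{j + 1}" for j in range(len(times))], columns=traits)


def labelled_correlation(cov: np.ndarray, index: TraitTimeIndex) -> pd.DataFrame:
    corr = correlation_from_covariance(np.asarray(cov, dtype=float))
    labels = index.labels()
    return pd.DataFrame(corr, index=labels, columns=labels)


def eigen_summary(U) -> tuple[np.ndarray, pd.DataFrame]:
    """Spectral decomposition of a symmetric genetic covariance matrix:
    eigenvalues in descending order and the matching eigenvectors (columns),
    indicating which linear combinations of breeding values carry the genetic
    variation."""
    if isinstance(U, pd.DataFrame):
        labels = list(U.index)
        M = U.values
    else:
        M = np.asarray(U, dtype=float)
        labels = [f"cell{i}" for i in range(M.shape[0])]
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("eigen_summary expects a symmetric matrix")
    vals, vecs = np.linalg.eigh(M)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    frame = pd.DataFrame(vecs, index=labels, columns=[f"ev{i + 1}" for i in range(len(vals))])
    return vals, frame


def plot_correlation_heatmap(corr: pd.DataFrame, ax=None, title: str | None = None):
    """Heatmap of a correlation matrix (values in [-1, 1], annotated)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.0 + 0.6 * corr.shape[0],) * 2)
    im = ax.imshow(corr.values, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(corr.shape[1]), corr.columns, rotation=90)
    ax.set_yticks(range(corr.shape[0]), corr.index)
    for i in range(corr.shape[0]):
        for j in range(corr.shape[1]):
            ax.text(j, i, f"{corr.values[i, j]:.2f}", ha="center", va="center", fontsize=7)
    if title:
        ax.set_title(title)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    return ax
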