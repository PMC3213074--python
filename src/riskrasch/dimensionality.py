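"""Unidimensionality and local-independence diagnostics.

Principal components are extracted from the item × item Pearson
correlation matrix of standardized residuals — the variance the Rasch
dimension has already explained is removed first, so the leading
component (the "first contrast") gauges a possible secondary dimension.
On the correlation scale each item contributes one eigen-unit, so the
eigenvalues of a complete-data run sum to the number of items and the
total unexplained variance is L.

The share of variance explained by the Rasch measures is approximated as
V_m = L · var(E_ni) / mean(W_ni) over estimation cells, split into a
person part and an item part proportional to the variance of the row
means versus column means of the expected-score matrix.  This is a
documented convention for the variance table, monotone in the simulated
ability spread, not a reproduction of any vendor's arithmetic.

Local dependence is screened by the largest pairwise residual
correlations; |r| >= 0.30 is the conventional flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .diagnostics import ResidualMatrix
from .engine import RaschFit

__all__ = [
    "VarianceDecomposition",
    "residual_pca",
    "residual_correlations",
    "dimensionality_report",
]


@dataclass
class VarianceDecomposition:
    explained_by_measures_pct: float
    explained_by_persons_pct: float
    explained_by_items_pct: float
    unexplained_pct: float
    eigenvalues: np.ndarray
    first_contrast_eigenvalue: float
    first_contrast_loadings: np.ndarray
    item_labels: list[str] = field(default_factory=list)
    excluded_items: list[str] = field(default_factory=list)


def _residual_frame(residuals: ResidualMatrix) -> pd.DataFrame:
    """Standardized residuals on estimation cells as a labelled frame."""
    z = np.where(residuals.estimation, residuals.standardized, np.nan)
    df = pd.DataFrame(z, columns=residuals.item_labels)
    keep_rows = residuals.estimation.any(axis=1)
    df = df.loc[keep_rows]
    keep_cols = [c for c, ext in zip(residuals.item_labels, residuals.item_extreme)
                 if not ext]
    return df[keep_cols]


def residual_pca(residuals: ResidualMatrix, fit: RaschFit) -> VarianceDecomposition:
    """Eigen-decomposition of the standardized-residual correlation matrix
    plus the Rasch variance decomposition."""
    df = _residual_frame(residuals)
    if df.shape[1] < 3:
        raise ValueError("residual PCA needs at least 3 non-extreme items")
    variances = df.var(ddof=0)
    dead = variances[variances <= 0].index.tolist()
    if dead:
        warnings.warn(
            f"excluding constant residual columns from PCA: {dead}",
            RuntimeWarning,
        )
        df = df.drop(columns=dead)
    corr = df.corr(min_periods=2).to_numpy()  # pairwise-complete Pearson
    if np.isnan(corr).any():
        raise ValueError("residual correlation matrix has undefined entries")
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    loadings = evecs[:, 0]
    if loadings[np.argmax(np.abs(loadings))] < 0:  # sign convention
        loadings = -loadings

    L = df.shape[1]
    est = residuals.estimation
    E = residuals.expected[est]
    W = residuals.variance[est]
    v_m = L * float(np.var(E)) / float(np.mean(W))

    Emat = np.where(est, residuals.expected, np.nan)
    rows_with_cells = est.any(axis=1)
    cols_with_cells = est.any(axis=0)
    row_means = np.nanmean(Emat[rows_with_cells], axis=1)
    col_means = np.nanmean(Emat[:, cols_with_cells], axis=0)
    vr = float(np.nanvar(row_means))
    vc = float(np.nanvar(col_means))
    split = vr + vc
    total = v_m + L
    pct_m = 100.0 * v_m / total
    pct_p = pct_m * (vr / split) if split > 0 else 0.0
    pct_i = pct_m * (vc / split) if split > 0 else 0.0

    return VarianceDecomposition(
        explained_by_measures_pct=pct_m,
        explained_by_persons_pct=pct_p,
        explained_by_items_pct=pct_i,
        unexplained_pct=100.0 * L / total,
        eigenvalues=evals,
        first_contrast_eigenvalue=float(evals[0]),
        first_contrast_loadings=loadings,
        item_labels=df.columns.tolist(),
        excluded_items=dead,
    )


def residual_correlations(
    residuals: ResidualMatrix, threshold: float = 0.30
) -> pd.DataFrame:
    """All item pairs sorted by |residual correlation|, flagged at the
    local-dependence threshold."""
    df = _residual_frame(residuals)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 non-extreme items")
    variances = df.var(ddof=0)
    dead = variances[variances <= 0].index.tolist()
    if dead:
        warnings.warn(
            f"excluding constant residual columns: {dead}", RuntimeWarning
        )
        df = df.drop(columns=dead)
    corr = df.corr(min_periods=2)
    rows = []
    for a, b in combinations(corr.columns, 2):
        r = float(corr.loc[a, b])
        rows.append(
            {
                "item_a": a,
                "item_b": b,
                "residual_correlation": r,
                "flagged": abs(r) >= threshold,
            }
        )
    out = pd.DataFrame(rows)
    out = out.reindex(
        out["residual_correlation"].abs().sort_values(ascending=False).index
    )
    return out.reset_index(drop=True)


def dimensionality_report(
    decomposition: VarianceDecomposition,
    pairs: pd.DataFrame,
    correlation_threshold: float = 0.30,
) -> str:
    """One-page text verdict against the three conventional guidelines:
    measures explain > 50% of variance; items explain > 4× the first
    contrast; first-contrast eigenvalue < 3.0."""
    d = decomposition
    first_pct = 100.0 * d.first_contrast_eigenvalue / (
        len(d.eigenvalues) / (d.unexplained_pct / 100.0)
    )
    checks = [
        ("variance explained by measures > 50%",
         d.explained_by_measures_pct, d.explained_by_measures_pct > 50.0),
        ("variance explained by items > 4x first contrast",
         d.explained_by_items_pct / first_pct if first_pct > 0 else np.inf,
         d.explained_by_items_pct > 4.0 * first_pct),
        ("first-contrast eigenvalue < 3.0",
         d.first_contrast_eigenvalue, d.first_contrast_eigenvalue < 3.0),
    ]
    lines = ["Dimensionality report", "=" * 21, ""]
    lines.append(f"variance explained by measures: {d.explained_by_measures_pct:.1f}%")
    lines.append(f"  by persons: {d.explained_by_persons_pct:.1f}%")
    lines.append(f"  by items:   {d.explained_by_items_pct:.1f}%")
    lines.append(f"unexplained:  {d.unexplained_pct:.1f}%")
    lines.append(f"first-contrast eigenvalue: {d.first_contrast_eigenvalue:.2f}"
                 f" (of {len(d.eigenvalues)} eigen-units)")
    lines.append("")
    for name, value, ok in checks:
        lines.append(f"[{'PASS' if ok else 'FAIL'}] {name} (value {value:.2f})")
    lines.append("")
    n_flag = int(pairs["flagged"].sum())
    lines.append(
        f"{n_flag} item pair(s) with |residual correlation| >= "
        f"{correlation_threshold:.2f}"
    )
    top = pairs.iloc[0]
    lines.append(
        f"largest: {top['item_a']} / {top['item_b']} "
        f"r = {top['residual_correlation']:+.2f}"
    )
    return "\n".join(lines) + "\n"
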