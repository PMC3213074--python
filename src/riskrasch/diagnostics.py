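"""Residual-based fit statistics and separation reliability.

For each observed cell the model gives an expected score P_ni and a
variance W_ni = P_ni(1 - P_ni); the standardized residual is
z_ni = (x_ni - P_ni) / sqrt(W_ni).  Outfit is the plain mean of z², an
outlier-sensitive statistic; infit weights each squared residual by its
information, sum(x-P)² / sum W, so responses near a unit's own measure
dominate.  Both have expectation 1 under the model.  Mean squares are
mapped to approximate t deviates (ZSTD) by the Wilson–Hilferty cube-root
transform.

Extreme persons and items are excluded from fit and reliability
computations: at a boundary score the residual variance degenerates and
the mean squares are undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ResponseMatrix
from .engine import RaschFit, rasch_probability

__all__ = [
    "ResidualMatrix",
    "ReliabilityReport",
    "standardized_residuals",
    "fit_statistics",
    "flag_misfit",
    "separation_reliability",
]


@dataclass
class ResidualMatrix:
    """Raw and standardized residuals with their model variances.

    ``observed`` masks non-missing cells; ``estimation`` additionally
    drops rows/columns of extreme persons/items, the cells on which fit
    statistics and PCA operate.
    """

    raw: np.ndarray
    variance: np.ndarray
    standardized: np.ndarray
    observed: np.ndarray
    estimation: np.ndarray
    expected: np.ndarray
    person_ids: list[str]
    item_labels: list[str]
    person_extreme: np.ndarray
    item_extreme: np.ndarray


def standardized_residuals(
    fit: RaschFit, matrix: ResponseMatrix
) -> ResidualMatrix:
    """Score residuals of a calibrated matrix against model expectations."""
    if len(fit.persons) != matrix.n_persons or len(fit.items) != matrix.n_items:
        raise ValueError("fit and matrix dimensions do not agree")
    theta = fit.measures
    delta = fit.difficulties
    P = rasch_probability(theta[:, None], delta[None, :])
    W = P * (1.0 - P)
    obs = matrix.observed
    x = np.where(obs, np.nan_to_num(matrix.scores), np.nan)
    raw = x - P
    z = raw / np.sqrt(W)
    est = obs & ~fit.person_extreme[:, None] & ~fit.item_extreme[None, :]
    return ResidualMatrix(
        raw=raw,
        variance=W,
        standardized=z,
        observed=obs,
        estimation=est,
        expected=P,
        person_ids=list(matrix.person_ids),
        item_labels=list(matrix.item_labels),
        person_extreme=fit.person_extreme.copy(),
        item_extreme=fit.item_extreme.copy(),
    )


def _fit_stats_1d(raw, W, z, mask, reduce_axis: int, ids) -> pd.DataFrame:
    """Mean squares and ZSTD per unit; ``reduce_axis`` is summed over
    (0 = over persons, giving per-item stats; 1 = per-person stats)."""
    m = mask
    other = reduce_axis
    n_obs = m.sum(axis=other)
    raw2 = np.where(m, raw**2, 0.0)
    Wm = np.where(m, W, 0.0)
    z2 = np.where(m, z**2, 0.0)
    C = Wm * (1.0 - 3.0 * Wm)  # Bernoulli fourth central moment

    sumW = Wm.sum(axis=other)
    infit_ms = raw2.sum(axis=other) / np.where(sumW > 0, sumW, np.nan)
    outfit_ms = z2.sum(axis=other) / np.where(n_obs > 0, n_obs, np.nan)

    q2_in = (C - Wm**2).sum(axis=other) / np.where(sumW > 0, sumW, np.nan) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(m, C / W**2, 0.0)
        q2_out = ratio.sum(axis=other) / np.where(n_obs > 0, n_obs, np.nan) ** 2 \
            - 1.0 / np.where(n_obs > 0, n_obs, np.nan)

    def wh(ms, q2):
        q = np.sqrt(np.maximum(q2, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (np.cbrt(ms) - 1.0) * (3.0 / q) + q / 3.0
        return np.where(q > 0, t, np.nan)

    out = pd.DataFrame(
        {
            "unit_id": ids,
            "n_obs": n_obs,
            "infit_ms": infit_ms,
            "outfit_ms": outfit_ms,
            "infit_zstd": wh(infit_ms, q2_in),
            "outfit_zstd": wh(outfit_ms, q2_out),
        }
    )
    # units with fewer than 2 usable cells: statistics undefined
    under = n_obs < 2
    out.loc[under, ["infit_ms", "outfit_ms", "infit_zstd", "outfit_zstd"]] = np.nan
    return out


def fit_statistics(residuals: ResidualMatrix, axis: str = "items") -> pd.DataFrame:
    """Infit/outfit mean squares and ZSTD per item or per person.

    Only estimation cells (non-extreme person × non-extreme item,
    observed) contribute.  Extreme units appear with NaN statistics.
    """
    if axis not in ("items", "persons"):
        raise ValueError("axis must be 'items' or 'persons'")
    r = residuals
    if axis == "items":
        return _fit_stats_1d(r.raw, r.variance, r.standardized, r.estimation,
                             0, r.item_labels)
    return _fit_stats_1d(r.raw, r.variance, r.standardized, r.estimation,
                         1, r.person_ids)


def flag_misfit(
    stats: pd.DataFrame, flag_t: float = 2.0, review_t: float = 3.0
) -> pd.DataFrame:
    """Two-sided ZSTD misfit screen.

    A unit is ``flagged`` when |infit ZSTD| or |outfit ZSTD| exceeds
    ``flag_t`` (conventionally 2, p < .05) and marked for ``review``
    beyond ``review_t`` (conventionally 3).  Rows are ordered by
    |infit ZSTD| first — infit is the statistic scrutinized most closely
    — then |outfit ZSTD|.
    """
    out = stats.copy()
    ain = out["infit_zstd"].abs()
    aout = out["outfit_zstd"].abs()
    out["flagged"] = (ain > flag_t) | (aout > flag_t)
    out["review"] = (ain > review_t) | (aout > review_t)
    out = out.assign(_a=ain.fillna(-np.inf), _b=aout.fillna(-np.inf))
    out = out.sort_values(["_a", "_b"], ascending=False).drop(columns=["_a", "_b"])
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class ReliabilityReport:
    observed_variance: float
    mean_error_variance: float
    reliability: float
    separation: float


def separation_reliability(measures, ses) -> ReliabilityReport:
    """Separation reliability of a set of measures.

    reliability = (observed variance - mean error variance) / observed
    variance, clipped to [0, 1]; the observed spread uses the population
    (divide-by-n) variance and the error variance is the mean squared
    standard error.  separation = sqrt(rel / (1 - rel)).
    """
    m = np.asarray(measures, dtype=float)
    s = np.asarray(ses, dtype=float)
    if m.shape != s.shape or m.ndim != 1:
        raise ValueError("measures and ses must be 1-D vectors of equal length")
    if m.size < 2:
        raise ValueError("need at least 2 measures")
    if not (s > 0).all():
        raise ValueError("standard errors must be positive")
    obs_var = float(np.var(m))
    err_var = float(np.mean(s**2))
    rel = 0.0 if obs_var <= 0 else (obs_var - err_var) / obs_var
    rel = float(np.clip(rel, 0.0, 1.0))
    sep = float(np.sqrt(rel / (1.0 - rel))) if rel < 1.0 else np.inf
    return ReliabilityReport(obs_var, err_var, rel, sep)
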