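"""Dichotomous Rasch calibration by PROX-initialized joint maximum likelihood.

The model: the probability that person *n* endorses item *i* is

    P_ni = exp(theta_n - delta_i) / (1 + exp(theta_n - delta_i)),

with person measures theta and item difficulties delta on a common logit
scale.  JMLE alternates damped Newton–Raphson updates of all deltas and
all thetas until the largest parameter change and the largest
expected-minus-observed marginal score are both below tolerance.  The
scale origin is fixed by re-centering non-extreme item difficulties to
mean 0 every cycle.

Persons or items with perfect (zero or maximal) marginal scores carry no
likelihood information and are excluded from estimation; they receive
measures afterwards by solving the score equation at a fractional
adjustment (default 0.3 score units) inside the boundary.

JMLE difficulty estimates are statistically inconsistent for a fixed
test length; the classical multiplicative correction (L-1)/L can be
switched on via ``EstimationConfig.bias_correction`` but is off by
default, matching common practice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.special import expit

from .data import ResponseMatrix

__all__ = [
    "EstimationConfig",
    "ItemCalibration",
    "PersonMeasure",
    "RaschFit",
    "ScoreConversionRow",
    "rasch_probability",
    "prox_initialize",
    "fit_jmle",
    "person_measure_for_score",
    "score_conversion_table",
]


@dataclass(frozen=True)
class EstimationConfig:
    """JMLE settings.

    tol: convergence threshold on the largest absolute parameter change,
        logits.
    score_tol: convergence threshold on the largest absolute difference
        between observed and expected marginal scores, score units.
    max_iter: iteration cap; non-convergence is flagged, not raised.
    extreme_adjust: fractional score adjustment for zero/perfect scores,
        in (0, 1).
    bias_correction: apply the (L-1)/L shrinkage to item difficulties
        after convergence (then re-fit person measures).
    step_limit: per-cycle cap on any single Newton step, logits.
    """

    tol: float = 1e-3
    score_tol: float = 0.01
    max_iter: int = 200
    extreme_adjust: float = 0.3
    bias_correction: bool = False
    step_limit: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.extreme_adjust < 1.0:
            raise ValueError("extreme_adjust must be in (0, 1)")
        if self.tol <= 0 or self.score_tol <= 0 or self.max_iter < 1:
            raise ValueError("invalid convergence settings")


@dataclass
class ItemCalibration:
    item_label: str
    difficulty: float
    se: float
    endorsed_count: int
    administered_count: int
    extreme_flag: bool = False


@dataclass
class PersonMeasure:
    person_id: str
    raw_score: float
    measure: float
    se: float
    extreme_flag: bool = False


@dataclass
class RaschFit:
    items: list[ItemCalibration]
    persons: list[PersonMeasure]
    iterations: int
    max_logit_change: float
    converged: bool
    config_echo: dict = field(default_factory=dict)

    @property
    def difficulties(self) -> np.ndarray:
        return np.array([it.difficulty for it in self.items])

    @property
    def difficulty_ses(self) -> np.ndarray:
        return np.array([it.se for it in self.items])

    @property
    def measures(self) -> np.ndarray:
        return np.array([p.measure for p in self.persons])

    @property
    def measure_ses(self) -> np.ndarray:
        return np.array([p.se for p in self.persons])

    @property
    def item_extreme(self) -> np.ndarray:
        return np.array([it.extreme_flag for it in self.items])

    @property
    def person_extreme(self) -> np.ndarray:
        return np.array([p.extreme_flag for p in self.persons])


@dataclass(frozen=True)
class ScoreConversionRow:
    raw_score: int
    measure: float
    se: float


# ----------------------------------------------------------------------

def rasch_probability(theta, delta):
    """P(X=1 | theta, delta) = expit(theta - delta), overflow-safe.

    Accepts scalars or broadcastable arrays.
    """
    t = np.asarray(theta, dtype=float)
    d = np.asarray(delta, dtype=float)
    if not (np.isfinite(t).all() and np.isfinite(d).all()):
        raise ValueError("theta and delta must be finite")
    out = expit(t - d)
    if out.ndim == 0:
        return float(out)
    return out


def _extreme_masks(scores: np.ndarray, observed: np.ndarray):
    """Iteratively flag extreme persons and items until stable.

    A person is extreme when their observed raw score over non-extreme
    items is 0 or maximal; symmetrically for items.  Removing one can
    expose the other, hence the loop.
    """
    n, l = scores.shape
    p_ext = np.zeros(n, dtype=bool)
    i_ext = np.zeros(l, dtype=bool)
    s = np.where(observed, scores, 0.0)
    while True:
        changed = False
        cols = ~i_ext
        r = s[:, cols].sum(axis=1)
        cnt = observed[:, cols].sum(axis=1)
        new_p = (~p_ext) & ((r <= 0) | (r >= cnt) | (cnt == 0))
        if new_p.any():
            p_ext |= new_p
            changed = True
        rows = ~p_ext
        si = s[rows].sum(axis=0)
        ci = observed[rows].sum(axis=0)
        new_i = (~i_ext) & ((si <= 0) | (si >= ci) | (ci == 0))
        if new_i.any():
            i_ext |= new_i
            changed = True
        if not changed:
            return p_ext, i_ext


def prox_initialize(matrix: ResponseMatrix):
    """Normal-approximation (PROX) starting values for JMLE.

    Item logits ln((N_i - s_i)/s_i) and person logits ln(r_n/(L_n - r_n))
    are each expanded by the usual factor sqrt(1 + var(other side)/2.89)
    and item difficulties centered at 0.  Extreme persons/items get NaN
    and are excluded from the centering.

    Returns ``(difficulties, abilities, person_extreme, item_extreme)``.
    """
    obs = matrix.observed
    p_ext, i_ext = _extreme_masks(matrix.scores, obs)
    core_rows = ~p_ext
    core_cols = ~i_ext
    s = np.where(obs, np.nan_to_num(matrix.scores), 0.0)

    si = s[core_rows][:, core_cols].sum(axis=0)
    ni = obs[core_rows][:, core_cols].sum(axis=0)
    item_logit = np.log((ni - si) / si)

    r = s[core_rows][:, core_cols].sum(axis=1)
    ln = obs[core_rows][:, core_cols].sum(axis=1)
    person_logit = np.log(r / (ln - r))

    # symmetric PROX variance expansion (2.89 = 1.7^2)
    xf_item = math.sqrt(1.0 + np.var(person_logit) / 2.89)
    xf_person = math.sqrt(1.0 + np.var(item_logit) / 2.89)

    d = item_logit * xf_item
    d -= d.mean()
    b = person_logit * xf_person

    difficulties = np.full(matrix.n_items, np.nan)
    difficulties[core_cols] = d
    abilities = np.full(matrix.n_persons, np.nan)
    abilities[core_rows] = b
    return difficulties, abilities, p_ext, i_ext


def fit_jmle(
    matrix: ResponseMatrix, config: EstimationConfig | None = None
) -> RaschFit:
    """Calibrate person measures and item difficulties by JMLE."""
    cfg = config or EstimationConfig()
    obs = matrix.observed
    scores = np.where(obs, np.nan_to_num(matrix.scores), 0.0)
    delta0, theta0, p_ext, i_ext = prox_initialize(matrix)
    core_rows = ~p_ext
    core_cols = ~i_ext
    if not core_rows.any() or not core_cols.any():
        raise ValueError("no non-extreme persons or items to estimate")

    X = scores[core_rows][:, core_cols]
    M = obs[core_rows][:, core_cols]
    r = X.sum(axis=1)
    s = X.sum(axis=0)
    delta = delta0[core_cols].copy()
    theta = theta0[core_rows].copy()

    it = 0
    max_change = np.inf
    converged = False
    for it in range(1, cfg.max_iter + 1):
        P = expit(theta[:, None] - delta[None, :]) * M
        W = P * (1.0 - P)
        # items first, then recenter; persons against updated items
        d_step = (P.sum(axis=0) - s) / np.maximum(W.sum(axis=0), 1e-12)
        d_step = np.clip(d_step, -cfg.step_limit, cfg.step_limit)
        delta_new = delta + d_step
        delta_new -= delta_new.mean()

        P = expit(theta[:, None] - delta_new[None, :]) * M
        W = P * (1.0 - P)
        t_step = (r - P.sum(axis=1)) / np.maximum(W.sum(axis=1), 1e-12)
        t_step = np.clip(t_step, -cfg.step_limit, cfg.step_limit)
        theta_new = theta + t_step

        max_change = max(
            float(np.abs(delta_new - delta).max()),
            float(np.abs(theta_new - theta).max()),
        )
        delta, theta = delta_new, theta_new
        if max_change < cfg.tol:
            P = expit(theta[:, None] - delta[None, :]) * M
            score_gap = max(
                float(np.abs(P.sum(axis=1) - r).max()),
                float(np.abs(P.sum(axis=0) - s).max()),
            )
            if score_gap < cfg.score_tol:
                converged = True
                break

    if cfg.bias_correction:
        lbar = M.sum(axis=1).mean()
        delta *= (lbar - 1.0) / lbar
        delta -= delta.mean()
        for _ in range(100):
            P = expit(theta[:, None] - delta[None, :]) * M
            W = P * (1.0 - P)
            t_step = (r - P.sum(axis=1)) / np.maximum(W.sum(axis=1), 1e-12)
            t_step = np.clip(t_step, -cfg.step_limit, cfg.step_limit)
            theta += t_step
            if np.abs(t_step).max() < cfg.tol:
                break

    P = expit(theta[:, None] - delta[None, :]) * M
    W = P * (1.0 - P)
    d_se = 1.0 / np.sqrt(np.maximum(W.sum(axis=0), 1e-12))
    t_se = 1.0 / np.sqrt(np.maximum(W.sum(axis=1), 1e-12))

    # ---- assemble full-length results, filling extremes afterwards ----
    items: list[ItemCalibration] = []
    core_d = dict(zip(np.flatnonzero(core_cols), zip(delta, d_se)))
    all_totals = scores.sum(axis=0)
    all_counts = obs.sum(axis=0)
    for i, label in enumerate(matrix.item_labels):
        if i in core_d:
            di, sei = core_d[i]
            items.append(
                ItemCalibration(label, float(di), float(sei),
                                int(all_totals[i]), int(all_counts[i]), False)
            )
        else:
            di, sei = _extreme_item_measure(
                theta, float(all_totals[i]), cfg.extreme_adjust
            )
            items.append(
                ItemCalibration(label, di, sei,
                                int(all_totals[i]), int(all_counts[i]), True)
            )

    persons: list[PersonMeasure] = []
    core_t = dict(zip(np.flatnonzero(core_rows), zip(theta, t_se)))
    raw_all = scores.sum(axis=1)
    adm_all = obs.sum(axis=1)
    delta_full = np.array([it_.difficulty for it_ in items])
    for n, pid in enumerate(matrix.person_ids):
        if n in core_t:
            th, se = core_t[n]
            persons.append(PersonMeasure(pid, float(raw_all[n]), float(th),
                                         float(se), False))
        else:
            d_n = delta_full[obs[n]]
            th, se = person_measure_for_score(
                d_n, float(raw_all[n]), adjust=cfg.extreme_adjust
            )
            persons.append(PersonMeasure(pid, float(raw_all[n]), th, se, True))

    fit = RaschFit(
        items=items,
        persons=persons,
        iterations=it,
        max_logit_change=float(max_change),
        converged=converged,
        config_echo=asdict(cfg),
    )
    if not converged:
        warnings.warn(
            f"JMLE did not converge in {cfg.max_iter} iterations "
            f"(last max change {max_change:.4g})",
            RuntimeWarning,
        )
    return fit


def _extreme_item_measure(theta: np.ndarray, total: float, adjust: float):
    """Difficulty for an item endorsed by nobody or everybody: solve the
    item margin equation at a fractional adjustment inside the boundary."""
    n = len(theta)
    target = adjust if total <= 0 else n - adjust

    def score(d: float):
        p = expit(theta - d)
        return p.sum(), (p * (1 - p)).sum()

    d = 0.0
    for _ in range(200):
        f, w = score(d)
        step = (f - target) / max(w, 1e-12)
        step = float(np.clip(step, -5, 5))
        d += step
        if abs(step) < 1e-8:
            break
    _, w = score(d)
    return float(d), float(1.0 / math.sqrt(max(w, 1e-12)))


def person_measure_for_score(
    difficulties: Sequence[float],
    raw_score: float,
    adjust: float = 0.3,
) -> tuple[float, float]:
    """Measure and SE for a raw score on a set of calibrated items.

    Solves sum_i P(theta, delta_i) = raw_score for theta by safeguarded
    Newton iteration (|step| < 1e-8 stopping rule).  Boundary scores 0
    and L, which have no finite solution, are solved at ``adjust`` and
    ``L - adjust`` respectively.  The SE is the usual
    1/sqrt(sum_i P_i (1 - P_i)) at the solution.
    """
    d = np.asarray(difficulties, dtype=float)
    if d.ndim != 1 or d.size < 1 or not np.isfinite(d).all():
        raise ValueError("difficulties must be a finite 1-D vector")
    L = d.size
    if not 0.0 <= raw_score <= L:
        raise ValueError(f"raw score {raw_score} outside [0, {L}]")
    if not 0.0 < adjust < 1.0:
        raise ValueError("adjust must be in (0, 1)")
    target = raw_score
    if raw_score == 0.0:
        target = adjust
    elif raw_score == float(L):
        target = L - adjust

    theta = 0.0
    lo, hi = -60.0, 60.0  # safeguard bracket: score() is increasing in theta
    for _ in range(200):
        p = expit(theta - d)
        f = p.sum() - target
        if f > 0:
            hi = min(hi, theta)
        else:
            lo = max(lo, theta)
        w = (p * (1.0 - p)).sum()
        step = f / max(w, 1e-15)
        new = theta - step
        if not lo < new < hi:
            new = 0.5 * (lo + hi)
        if abs(new - theta) < 1e-8:
            theta = new
            break
        theta = new
    p = expit(theta - d)
    w = (p * (1.0 - p)).sum()
    return float(theta), float(1.0 / math.sqrt(w))


def score_conversion_table(
    difficulties: Sequence[float], adjust: float = 0.3
) -> list[ScoreConversionRow]:
    """Raw-score → measure conversion for the complete test.

    One row per raw score 0..L; measures are strictly increasing in the
    raw score because the score function is strictly increasing in theta.
    """
    d = np.asarray(difficulties, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 item difficulties")
    rows = []
    for r in range(d.size + 1):
        m, se = person_measure_for_score(d, float(r), adjust=adjust)
        rows.append(ScoreConversionRow(raw_score=r, measure=m, se=se))
    return rows
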