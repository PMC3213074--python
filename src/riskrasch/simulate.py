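"""Synthetic cohorts with the statistical structure the analysis assumes.

No respondent-level data were ever deposited for the original
administration of the scale, so every pipeline stage is exercised on
simulated cohorts: abilities drawn from a normal distribution on the
logit scale, responses Bernoulli under the Rasch model with a fixed
difficulty vector, and optional injections of differential item
functioning, local dependence, or a second latent dimension for testing
the diagnostic modules' power.

The default population reproduces the published study conditions: N=351
respondents, the published difficulty vector, and a Normal(-2.52, 1.83)
ability distribution calibrated so that model-implied endorsement
margins match the published per-item percentages (75.5%, 39.6%, ...,
59.3%).  Generation is fully determined by ``PopulationSpec.seed``; no
global random state is touched.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import brentq, minimize
from scipy.special import expit

from .data import ResponseMatrix
from .preprocessing import BEHAVIOR_CONTEXTS, Behavior, SurveyRecord
from .reference import ITEM_DIFFICULTIES, ITEM_LABELS

__all__ = [
    "CALIBRATED_ABILITY_MEAN",
    "CALIBRATED_ABILITY_SD",
    "DifSpec",
    "DependenceSpec",
    "SecondFactorSpec",
    "PopulationSpec",
    "SimulatedResponses",
    "CalibrationResult",
    "simulate_responses",
    "inject_structure",
    "calibrate_population",
    "simulate_survey_records",
]

#: Normal ability parameters calibrated to the published endorsement
#: margins under the published difficulty vector (see
#: :func:`calibrate_population`; a test verifies the round-trip).
CALIBRATED_ABILITY_MEAN: float = -2.52
CALIBRATED_ABILITY_SD: float = 1.83


@dataclass(frozen=True)
class DifSpec:
    """Uniform difficulty shift for one item within an ability group.

    The group is defined on the latent ability (above/below the sample
    median) so the injected effect exists before any response is drawn.
    """

    item: int
    shift: float
    group: str = "above_median"

    def __post_init__(self) -> None:
        if self.group not in ("above_median", "below_median"):
            raise ValueError("group must be 'above_median' or 'below_median'")


@dataclass(frozen=True)
class DependenceSpec:
    """Shared-draw local dependence between a pair of items.

    With probability ``rho`` per person, both items' outcomes are
    replaced by a single shared Bernoulli draw at the mean of the two
    cell probabilities, inducing positive residual correlation that is
    monotone in rho.
    """

    item_a: int
    item_b: int
    rho: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if self.item_a == self.item_b:
            raise ValueError("dependence pair must be two distinct items")


@dataclass(frozen=True)
class SecondFactorSpec:
    """Second latent dimension loading on a subset of items.

    Each person gets an independent N(0,1) factor score u; for the
    listed items the response logit becomes theta - delta + loading*u.
    """

    items: tuple[int, ...]
    loading: float = 1.0


@dataclass(frozen=True)
class PopulationSpec:
    n_persons: int = 351
    ability_mean: float = CALIBRATED_ABILITY_MEAN
    ability_sd: float = CALIBRATED_ABILITY_SD
    difficulties: tuple[float, ...] = ITEM_DIFFICULTIES
    seed: int = 0
    dif: DifSpec | None = None
    dependence: DependenceSpec | None = None
    second_factor: SecondFactorSpec | None = None

    def __post_init__(self) -> None:
        if self.n_persons < 2:
            raise ValueError("n_persons must be >= 2")
        if self.ability_sd <= 0:
            raise ValueError("ability_sd must be positive")
        if len(self.difficulties) < 2:
            raise ValueError("need at least 2 item difficulties")
        L = len(self.difficulties)
        for idx in self._injected_indices():
            if not 0 <= idx < L:
                raise ValueError(f"injected item index {idx} out of range 0..{L-1}")

    def _injected_indices(self) -> list[int]:
        idx = []
        if self.dif is not None:
            idx.append(self.dif.item)
        if self.dependence is not None:
            idx += [self.dependence.item_a, self.dependence.item_b]
        if self.second_factor is not None:
            idx += list(self.second_factor.items)
        return idx


@dataclass
class SimulatedResponses:
    matrix: ResponseMatrix
    abilities: np.ndarray
    spec: PopulationSpec

    def generating_fit(self):
        """Calibration object at the generating parameters.

        Packages the true difficulties and retained abilities as a
        :class:`~riskrasch.engine.RaschFit` so downstream residual
        diagnostics can be run free of estimation error — the oracle for
        residual-nullity and injection-detection checks.  Standard
        errors are the usual information-based values at the true
        parameters; nothing is estimated.
        """
        from .engine import ItemCalibration, PersonMeasure, RaschFit

        d = np.asarray(self.spec.difficulties, dtype=float)
        X = self.matrix.scores
        P = expit(self.abilities[:, None] - d[None, :])
        W = P * (1.0 - P)
        item_se = 1.0 / np.sqrt(W.sum(axis=0))
        person_se = 1.0 / np.sqrt(W.sum(axis=1))
        items = [
            ItemCalibration(lbl, float(di), float(se), int(X[:, i].sum()),
                            self.matrix.n_persons, False)
            for i, (lbl, di, se) in enumerate(
                zip(self.matrix.item_labels, d, item_se))
        ]
        persons = [
            PersonMeasure(pid, float(X[n].sum()), float(th), float(se), False)
            for n, (pid, th, se) in enumerate(
                zip(self.matrix.person_ids, self.abilities, person_se))
        ]
        return RaschFit(items=items, persons=persons, iterations=0,
                        max_logit_change=0.0, converged=True,
                        config_echo={"source": "generating parameters"})


def _item_labels(L: int) -> list[str]:
    if L == len(ITEM_LABELS):
        return list(ITEM_LABELS)
    return [f"Item {i + 1}" for i in range(L)]


def inject_structure(
    logits: np.ndarray,
    abilities: np.ndarray,
    dif: DifSpec | None,
    second_factor: SecondFactorSpec | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply pre-draw injections to the response logit matrix.

    DIF shifts the target item's difficulty (subtracting ``shift`` from
    the logit) for persons in the ability group; the second factor adds
    loading·u_n to the listed items' logits.  Post-draw dependence is
    handled inside :func:`simulate_responses` because it replaces
    realized outcomes rather than probabilities.
    """
    out = logits.copy()
    if dif is not None:
        med = np.median(abilities)
        in_group = abilities > med if dif.group == "above_median" else abilities <= med
        out[in_group, dif.item] -= dif.shift
    if second_factor is not None:
        u = rng.standard_normal(len(abilities))
        for i in second_factor.items:
            out[:, i] += second_factor.loading * u
    return out


def simulate_responses(spec: PopulationSpec) -> SimulatedResponses:
    """Draw a response matrix under the Rasch forward model.

    The draw order is fixed (abilities, second-factor scores, response
    uniforms, dependence replacements) so identical specs give
    bit-identical matrices and a zero-shift DIF injection is exactly the
    null generation.
    """
    rng = np.random.default_rng(spec.seed)
    d = np.asarray(spec.difficulties, dtype=float)
    L = d.size
    theta = rng.normal(spec.ability_mean, spec.ability_sd, spec.n_persons)
    logits = theta[:, None] - d[None, :]
    logits = inject_structure(logits, theta, spec.dif, spec.second_factor, rng)
    P = expit(logits)
    X = (rng.random((spec.n_persons, L)) < P).astype(float)
    if spec.dependence is not None:
        dep = spec.dependence
        hit = rng.random(spec.n_persons) < dep.rho
        p_shared = 0.5 * (P[:, dep.item_a] + P[:, dep.item_b])
        shared = (rng.random(spec.n_persons) < p_shared).astype(float)
        X[hit, dep.item_a] = shared[hit]
        X[hit, dep.item_b] = shared[hit]
    matrix = ResponseMatrix(
        X,
        person_ids=[f"P{n + 1:04d}" for n in range(spec.n_persons)],
        item_labels=_item_labels(L),
    )
    return SimulatedResponses(matrix=matrix, abilities=theta, spec=spec)


@dataclass
class CalibrationResult:
    ability_mean: float
    ability_sd: float
    achieved_margins: np.ndarray
    target_margins: np.ndarray


def _model_margins(mu: float, sd: float, d: np.ndarray,
                   nodes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    theta = mu + sd * nodes
    P = expit(theta[:, None] - d[None, :])
    return weights @ P


def calibrate_population(
    target_margins: Sequence[float],
    difficulties: Sequence[float],
) -> CalibrationResult:
    """Find the normal ability distribution reproducing target margins.

    Minimizes the squared error between target endorsement proportions
    and model-implied margins E[P(theta, delta_i)] computed by
    Gauss–Hermite quadrature over Normal(mu, sd²).  With a single item
    the problem is underdetermined in sd, which is fixed at 1 by
    convention and mu solved directly.
    """
    t = np.asarray(target_margins, dtype=float)
    d = np.asarray(difficulties, dtype=float)
    if t.shape != d.shape or t.ndim != 1:
        raise ValueError("margins and difficulties must be equal-length vectors")
    if not ((t > 0) & (t < 1)).all():
        raise ValueError("target margins must lie strictly in (0, 1)")
    nodes, weights = hermegauss(61)
    weights = weights / weights.sum()

    if d.size == 1:
        mu = brentq(
            lambda m: _model_margins(m, 1.0, d, nodes, weights)[0] - t[0],
            -50.0, 50.0,
        )
        achieved = _model_margins(mu, 1.0, d, nodes, weights)
        return CalibrationResult(float(mu), 1.0, achieved, t)

    def objective(p):
        mu, log_sd = p
        m = _model_margins(mu, float(np.exp(log_sd)), d, nodes, weights)
        return float(((m - t) ** 2).sum())

    res = minimize(objective, x0=[0.0, 0.0], method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000})
    if not res.success:
        raise RuntimeError(f"population calibration failed: {res.message}")
    mu, sd = float(res.x[0]), float(np.exp(res.x[1]))
    achieved = _model_margins(mu, sd, d, nodes, weights)
    return CalibrationResult(mu, sd, achieved, t)


_UNSAFE_FREQUENCIES = ("often", "sometimes", "rarely", "never")


def simulate_survey_records(
    spec: PopulationSpec,
    concurrency_rate: float = 0.3,
    window_end: dt.date = dt.date(2009, 6, 30),
) -> list[SurveyRecord]:
    """Raw survey records whose scored matrix matches ``simulate_responses``.

    The binary outcomes are drawn by :func:`simulate_responses` under the
    same seed, then dressed into survey form with an independent
    substream: a 1 on a condom item becomes a random not-every-time
    frequency, a 0 becomes either every-time use or non-engagement; a 1
    on the concurrency item becomes two overlapping partnership
    intervals, a 0 becomes one partnership or — with probability
    ``concurrency_rate`` — two disjoint ones.  All dates fall in the
    six-month recall window ending at ``window_end``.
    """
    if len(spec.difficulties) != 9:
        raise ValueError("survey records require the 9-item scale layout")
    if not 0.0 <= concurrency_rate <= 1.0:
        raise ValueError("concurrency_rate must be in [0, 1]")
    sim = simulate_responses(spec)
    X = sim.matrix.scores
    dress = np.random.default_rng([spec.seed, 9017])
    window_start = window_end - dt.timedelta(days=182)
    span = (window_end - window_start).days

    records: list[SurveyRecord] = []
    for n, pid in enumerate(sim.matrix.person_ids):
        behaviors = {}
        for i, ctx in enumerate(BEHAVIOR_CONTEXTS):
            if X[n, i] == 1.0:
                freq = _UNSAFE_FREQUENCIES[dress.integers(len(_UNSAFE_FREQUENCIES))]
                behaviors[ctx] = Behavior(engaged=True, frequency=freq)
            elif dress.random() < 0.4:
                behaviors[ctx] = Behavior(engaged=True, frequency="every_time")
            else:
                behaviors[ctx] = Behavior(engaged=False, frequency="not_applicable")
        if X[n, 8] == 1.0:
            # two intervals sharing at least one day
            a = int(dress.integers(0, span - 60))
            length1 = int(dress.integers(20, 60))
            b = int(dress.integers(a, a + length1 + 1))  # starts inside first
            length2 = int(dress.integers(10, 50))
            partnerships = [
                (window_start + dt.timedelta(days=a),
                 window_start + dt.timedelta(days=a + length1)),
                (window_start + dt.timedelta(days=b),
                 window_start + dt.timedelta(days=min(b + length2, span))),
            ]
        elif dress.random() < concurrency_rate:
            # two strictly disjoint intervals
            a = int(dress.integers(0, span // 2 - 20))
            e1 = a + int(dress.integers(5, 20))
            b = e1 + 1 + int(dress.integers(1, 20))
            e2 = min(b + int(dress.integers(5, 20)), span)
            partnerships = [
                (window_start + dt.timedelta(days=a),
                 window_start + dt.timedelta(days=e1)),
                (window_start + dt.timedelta(days=b),
                 window_start + dt.timedelta(days=e2)),
            ]
        else:
            a = int(dress.integers(0, span - 30))
            e = a + int(dress.integers(1, 30))
            partnerships = [
                (window_start + dt.timedelta(days=a),
                 window_start + dt.timedelta(days=e)),
            ]
        records.append(
            SurveyRecord(respondent_id=pid, behaviors=behaviors,
                         partnerships=partnerships)
        )
    return records
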