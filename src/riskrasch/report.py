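"""Full-pipeline analysis results and the persisted report bundle."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .data import ResponseMatrix
from .diagnostics import (
    ReliabilityReport,
    fit_statistics,
    flag_misfit,
    separation_reliability,
    standardized_residuals,
)
from .dimensionality import (
    VarianceDecomposition,
    dimensionality_report,
    residual_correlations,
    residual_pca,
)
from .engine import (
    EstimationConfig,
    RaschFit,
    ScoreConversionRow,
    fit_jmle,
    score_conversion_table,
)
from .invariance import InvarianceResult, invariance_analysis, split_by_raw_score
from .wright import render_wright_map

__all__ = ["AnalysisResults", "analyze", "write_report", "read_summary"]

log = logging.getLogger("riskrasch")


@dataclass
class AnalysisResults:
    matrix: ResponseMatrix
    fit: RaschFit
    item_stats: pd.DataFrame
    person_stats: pd.DataFrame
    item_flags: pd.DataFrame
    item_reliability: ReliabilityReport
    person_reliability: ReliabilityReport
    decomposition: VarianceDecomposition
    dependence_pairs: pd.DataFrame
    invariance: list[InvarianceResult]
    invariance_band: pd.DataFrame
    score_table: list[ScoreConversionRow]
    wright_map: str


def item_table(fit: RaschFit, item_stats: pd.DataFrame) -> pd.DataFrame:
    base = pd.DataFrame(
        {
            "item_label": [it.item_label for it in fit.items],
            "difficulty": [it.difficulty for it in fit.items],
            "se": [it.se for it in fit.items],
            "count": [it.endorsed_count for it in fit.items],
            "extreme": [it.extreme_flag for it in fit.items],
        }
    )
    stats = item_stats.rename(columns={"unit_id": "item_label"})
    cols = ["item_label", "infit_ms", "infit_zstd", "outfit_ms", "outfit_zstd"]
    return base.merge(stats[cols], on="item_label", how="left")


def person_table(fit: RaschFit, person_stats: pd.DataFrame) -> pd.DataFrame:
    base = pd.DataFrame(
        {
            "person_id": [p.person_id for p in fit.persons],
            "raw_score": [p.raw_score for p in fit.persons],
            "measure": [p.measure for p in fit.persons],
            "se": [p.se for p in fit.persons],
            "extreme": [p.extreme_flag for p in fit.persons],
        }
    )
    stats = person_stats.rename(columns={"unit_id": "person_id"})
    cols = ["person_id", "infit_ms", "infit_zstd", "outfit_ms", "outfit_zstd"]
    return base.merge(stats[cols], on="person_id", how="left")


def analyze(
    matrix: ResponseMatrix,
    config: EstimationConfig | None = None,
    low_max: int = 2,
    correlation_threshold: float = 0.30,
) -> AnalysisResults:
    """Run the complete measurement analysis on a scored matrix."""
    cfg = config or EstimationConfig()
    fit = fit_jmle(matrix, cfg)
    log.info("JMLE converged=%s in %d iterations", fit.converged, fit.iterations)
    residuals = standardized_residuals(fit, matrix)
    item_stats = fit_statistics(residuals, "items")
    person_stats = fit_statistics(residuals, "persons")
    item_flags = flag_misfit(item_stats)
    log.info("flagged items: %d; flagged persons: %d",
             int(item_flags["flagged"].sum()),
             int(flag_misfit(person_stats)["flagged"].sum()))

    core_items = ~fit.item_extreme
    item_rel = separation_reliability(
        fit.difficulties[core_items], fit.difficulty_ses[core_items]
    )
    core_persons = ~fit.person_extreme
    person_rel = separation_reliability(
        fit.measures[core_persons], fit.measure_ses[core_persons]
    )

    decomposition = residual_pca(residuals, fit)
    pairs = residual_correlations(residuals, threshold=correlation_threshold)

    low, high = split_by_raw_score(matrix, low_max=low_max)
    inv_results, inv_band = invariance_analysis(low, high, cfg)

    score_rows = score_conversion_table(
        fit.difficulties[core_items], adjust=cfg.extreme_adjust
    )
    wm = render_wright_map(fit)
    return AnalysisResults(
        matrix=matrix,
        fit=fit,
        item_stats=item_stats,
        person_stats=person_stats,
        item_flags=item_flags,
        item_reliability=item_rel,
        person_reliability=person_rel,
        decomposition=decomposition,
        dependence_pairs=pairs,
        invariance=inv_results,
        invariance_band=inv_band,
        score_table=score_rows,
        wright_map=wm,
    )


def write_report(
    results: AnalysisResults,
    dest: str | Path,
    seed: int | None = None,
) -> Path:
    """Persist the full report bundle (tables, text reports, summary).

    Writes item, person, score-conversion, dependence-pair and
    invariance tables as CSV, the dimensionality report and Wright map
    as text, and a machine-readable YAML summary whose headline numbers
    round-trip through :func:`read_summary`.
    """
    out = Path(dest)
    out.mkdir(parents=True, exist_ok=True)
    r = results

    item_table(r.fit, r.item_stats).to_csv(out / "items.csv", index=False)
    person_table(r.fit, r.person_stats).to_csv(out / "persons.csv", index=False)
    pd.DataFrame([row.__dict__ for row in r.score_table]).to_csv(
        out / "score_table.csv", index=False
    )
    (out / "dimensionality.txt").write_text(
        dimensionality_report(r.decomposition, r.dependence_pairs)
    )
    r.dependence_pairs.to_csv(out / "dependence_pairs.csv", index=False)
    pd.DataFrame([i.__dict__ for i in r.invariance]).to_csv(
        out / "invariance.csv", index=False
    )
    r.invariance_band.to_csv(out / "invariance_band.csv", index=False)
    (out / "wright_map.txt").write_text(r.wright_map)

    summary = {
        "package_version": __version__,
        "seed": seed,
        "config": r.fit.config_echo,
        "n_persons": r.matrix.n_persons,
        "n_items": r.matrix.n_items,
        "converged": bool(r.fit.converged),
        "iterations": int(r.fit.iterations),
        "item_reliability": round(float(r.item_reliability.reliability), 4),
        "person_reliability": round(float(r.person_reliability.reliability), 4),
        "item_separation": round(float(r.item_reliability.separation), 4),
        "explained_by_measures_pct": round(
            float(r.decomposition.explained_by_measures_pct), 2
        ),
        "first_contrast_eigenvalue": round(
            float(r.decomposition.first_contrast_eigenvalue), 4
        ),
        "n_flagged_items": int(r.item_flags["flagged"].sum()),
        "n_dependent_pairs": int(r.dependence_pairs["flagged"].sum()),
        "n_items_outside_band": sum(
            1 for i in r.invariance if i.estimable and not i.within_band
        ),
        "score_table": {
            int(row.raw_score): [round(row.measure, 4), round(row.se, 4)]
            for row in r.score_table
        },
    }
    with open(out / "summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    log.info("report bundle written to %s", out)
    return out


def read_summary(dest: str | Path) -> dict:
    with open(Path(dest) / "summary.yaml") as fh:
        return yaml.safe_load(fh)
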