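"""Turn raw survey records into the nine-item dichotomous response matrix.

Eight condom-use behaviors are dichotomized (0 = condom used in every
act or behavior not practiced, 1 = any act without a condom); the ninth
item flags concurrent partnerships, detected from overlap of first/last
intercourse date intervals within the recall window.  Records are
assumed pre-restricted to the six-month recall window; no date filtering
happens here.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import ResponseMatrix
from .reference import ITEM_LABELS

__all__ = [
    "CONDOM_FREQUENCIES",
    "SAFE_FREQUENCIES",
    "BEHAVIOR_CONTEXTS",
    "Behavior",
    "SurveyRecord",
    "dichotomize_condom_frequency",
    "detect_concurrency",
    "build_response_matrix",
    "endorsement_summary",
    "read_survey_records",
    "write_survey_records",
]

#: Recognized condom-use frequency tokens.
CONDOM_FREQUENCIES = (
    "every_time", "often", "sometimes", "rarely", "never", "not_applicable",
)

#: Tokens scored 0 (safer sex).  Non-engagement ("not_applicable") is
#: scored 0, not missing: an act that never happened cannot be unsafe,
#: and the original administration used the full-sample denominator for
#: every item.
SAFE_FREQUENCIES = frozenset({"every_time", "not_applicable"})

#: The eight condom-use behavior contexts, in scale order (items 1-8).
BEHAVIOR_CONTEXTS = (
    "oral_sex_msm",
    "anal_sex_msm",
    "anal_sex_male_sex_worker",
    "oral_sex_male_sex_worker",
    "anal_sex_male_client",
    "oral_sex_male_client",
    "sex_female_sex_worker",
    "sex_regular_partner",
)


@dataclass(frozen=True)
class Behavior:
    """Engagement flag plus condom-use frequency for one context."""

    engaged: bool
    frequency: str

    def __post_init__(self) -> None:
        if self.frequency not in CONDOM_FREQUENCIES:
            raise ValueError(f"unrecognized condom frequency {self.frequency!r}")
        if (self.frequency == "not_applicable") != (not self.engaged):
            raise ValueError(
                "frequency must be 'not_applicable' exactly when not engaged"
            )


@dataclass
class SurveyRecord:
    respondent_id: str
    behaviors: Mapping[str, Behavior]
    partnerships: list[tuple[dt.date, dt.date]] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in BEHAVIOR_CONTEXTS if c not in self.behaviors]
        if missing:
            raise ValueError(f"record {self.respondent_id}: missing contexts {missing}")
        for first, last in self.partnerships:
            if first > last:
                raise ValueError(
                    f"record {self.respondent_id}: partnership interval "
                    f"{first}..{last} has first > last"
                )


def dichotomize_condom_frequency(category: str) -> int:
    """Score a condom-use frequency: 0 if every act was protected (or the
    behavior was not practiced), 1 otherwise."""
    if category not in CONDOM_FREQUENCIES:
        raise ValueError(f"unrecognized condom frequency {category!r}")
    return 0 if category in SAFE_FREQUENCIES else 1


def detect_concurrency(
    partnerships: Sequence[tuple[dt.date, dt.date]],
) -> int:
    """1 if any two partnership date intervals overlap, else 0.

    Overlap is closed-interval: a shared boundary day counts as
    concurrent.  Zero or one partnership can never be concurrent.
    """
    ivs = list(partnerships)
    for first, last in ivs:
        if first > last:
            raise ValueError(f"inverted interval {first}..{last}")
    ivs.sort()
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 <= e1:  # sorted, so s1 <= s2 already
            return 1
    return 0


def build_response_matrix(records: Iterable[SurveyRecord]) -> ResponseMatrix:
    """Score survey records into an N × 9 response matrix.

    Columns 1-8 dichotomize the condom-use contexts in scale order;
    column 9 is the concurrency flag.  This path produces no missing
    cells.
    """
    recs = list(records)
    if len(recs) < 2:
        raise ValueError("need at least 2 survey records")
    ids = [r.respondent_id for r in recs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate respondent ids: {dupes}")
    rows = np.empty((len(recs), 9))
    for n, rec in enumerate(recs):
        for i, ctx in enumerate(BEHAVIOR_CONTEXTS):
            rows[n, i] = dichotomize_condom_frequency(rec.behaviors[ctx].frequency)
        rows[n, 8] = detect_concurrency(rec.partnerships)
    return ResponseMatrix(rows, ids, list(ITEM_LABELS))


def endorsement_summary(matrix: ResponseMatrix) -> pd.DataFrame:
    """Per-item endorsement frequency and percentage (1 decimal place)."""
    counts = matrix.item_totals().astype(int)
    ns = matrix.item_counts()
    pct = np.round(100.0 * counts / ns, 1)
    return pd.DataFrame(
        {
            "item": matrix.item_labels,
            "frequency": counts,
            "administered": ns,
            "percent": pct,
        }
    )


# ----------------------------------------------------------------------
# Delimited-text survey I/O
#
# Behaviors file: one row per respondent-context with columns
#   respondent_id, context, engaged (yes/no), frequency
# Partnerships file: one row per partnership with columns
#   respondent_id, first_date, last_date   (ISO-8601 dates)

def write_survey_records(
    records: Iterable[SurveyRecord],
    behaviors_path: str | Path,
    partnerships_path: str | Path,
) -> None:
    brows, prows = [], []
    for rec in records:
        for ctx in BEHAVIOR_CONTEXTS:
            b = rec.behaviors[ctx]
            brows.append(
                {
                    "respondent_id": rec.respondent_id,
                    "context": ctx,
                    "engaged": "yes" if b.engaged else "no",
                    "frequency": b.frequency,
                }
            )
        for first, last in rec.partnerships:
            prows.append(
                {
                    "respondent_id": rec.respondent_id,
                    "first_date": first.isoformat(),
                    "last_date": last.isoformat(),
                }
            )
    pd.DataFrame(brows).to_csv(behaviors_path, index=False)
    cols = ["respondent_id", "first_date", "last_date"]
    pd.DataFrame(prows, columns=cols).to_csv(partnerships_path, index=False)


def read_survey_records(
    behaviors_path: str | Path,
    partnerships_path: str | Path,
) -> list[SurveyRecord]:
    bdf = pd.read_csv(behaviors_path, dtype=str)
    pdf = pd.read_csv(partnerships_path, dtype=str)
    partnerships: dict[str, list[tuple[dt.date, dt.date]]] = {}
    for _, row in pdf.iterrows():
        partnerships.setdefault(row["respondent_id"], []).append(
            (
                dt.date.fromisoformat(row["first_date"]),
                dt.date.fromisoformat(row["last_date"]),
            )
        )
    records = []
    for rid, grp in bdf.groupby("respondent_id", sort=False):
        behaviors = {
            row["context"]: Behavior(
                engaged=row["engaged"] == "yes", frequency=row["frequency"]
            )
            for _, row in grp.iterrows()
        }
        records.append(
            SurveyRecord(
                respondent_id=str(rid),
                behaviors=behaviors,
                partnerships=partnerships.get(str(rid), []),
            )
        )
    return records
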