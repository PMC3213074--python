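"""Person × item binary response matrix, the pipeline's central container.

Scores are stored as a float array with entries 0.0, 1.0, or NaN for
missing cells; persons are rows, items columns.  CSV serialization uses
``NA`` for missing, a ``person_id`` first column, and item labels as the
header, so matrices round-trip through plain text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ResponseMatrix"]


@dataclass
class ResponseMatrix:
    scores: np.ndarray
    person_ids: list[str]
    item_labels: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.person_ids = [str(p) for p in self.person_ids]
        self.item_labels = [str(l) for l in self.item_labels]
        n, l = self.scores.shape if self.scores.ndim == 2 else (0, 0)
        if self.scores.ndim != 2:
            raise ValueError("scores must be a 2-D persons × items array")
        if n < 2 or l < 2:
            raise ValueError(f"need at least 2 persons and 2 items, got {n}×{l}")
        if len(self.person_ids) != n:
            raise ValueError("person_ids length does not match score rows")
        if len(self.item_labels) != l:
            raise ValueError("item_labels length does not match score columns")
        if len(set(self.person_ids)) != n:
            raise ValueError("person_ids must be unique")
        if len(set(self.item_labels)) != l:
            raise ValueError("item_labels must be unique")
        obs = ~np.isnan(self.scores)
        vals = self.scores[obs]
        if not np.isin(vals, (0.0, 1.0)).all():
            bad = sorted(set(vals) - {0.0, 1.0})
            raise ValueError(f"scores must be 0, 1 or missing; found {bad}")

    # ------------------------------------------------------------------
    @property
    def n_persons(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing cells."""
        return ~np.isnan(self.scores)

    def raw_scores(self) -> np.ndarray:
        """Per-person sum of observed item scores."""
        return np.nansum(self.scores, axis=1)

    def administered(self) -> np.ndarray:
        """Per-person count of observed items."""
        return self.observed.sum(axis=1)

    def item_totals(self) -> np.ndarray:
        """Per-item count of 1-scores among observed cells."""
        return np.nansum(self.scores, axis=0)

    def item_counts(self) -> np.ndarray:
        """Per-item count of observed cells."""
        return self.observed.sum(axis=0)

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=self.item_labels)
        df.insert(0, "person_id", self.person_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ResponseMatrix":
        if "person_id" not in df.columns:
            raise ValueError("expected a 'person_id' column")
        items = [c for c in df.columns if c != "person_id"]
        return cls(
            scores=df[items].to_numpy(dtype=float),
            person_ids=df["person_id"].astype(str).tolist(),
            item_labels=items,
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, na_rep="NA",
                               float_format="%.0f")

    @classmethod
    def read_csv(cls, path: str | Path) -> "ResponseMatrix":
        return cls.from_frame(pd.read_csv(path, na_values=["NA"]))

    def subset_persons(self, row_mask: Sequence[bool]) -> "ResponseMatrix":
        mask = np.asarray(row_mask, dtype=bool)
        return ResponseMatrix(
            scores=self.scores[mask],
            person_ids=[p for p, m in zip(self.person_ids, mask) if m],
            item_labels=list(self.item_labels),
        )
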