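"""ASCII Wright map: persons and items on the shared logit ruler.

Higher logits — riskier persons, harder-to-endorse behaviors — are at
the top.  Persons appear as '#' blocks left of the ruler, items by label
on the right; M/S/T mark the mean and one/two standard deviations of
each distribution.
"""

from __future__ import annotations

import math

import numpy as np

from .engine import RaschFit

__all__ = ["render_wright_map"]

_PERSON_COL = 30


def _marker_rows(values: np.ndarray, edges: np.ndarray) -> dict[int, str]:
    """Map bin index -> marker string (M, S, T) for a measure set."""
    mean = values.mean()
    sd = values.std()
    marks: dict[int, list[str]] = {}
    for label, pos in (("M", [mean]), ("S", [mean - sd, mean + sd]),
                       ("T", [mean - 2 * sd, mean + 2 * sd])):
        for p in pos:
            idx = int(np.clip(np.searchsorted(edges, p, side="right") - 1,
                              0, len(edges) - 2))
            marks.setdefault(idx, []).append(label)
    return {k: "".join(sorted(set(v))) for k, v in marks.items()}


def render_wright_map(fit: RaschFit, bin_width: float = 0.25) -> str:
    """Two-column vertical text map of person measures and item difficulties."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    theta = fit.measures
    delta = fit.difficulties
    if theta.size == 0 or delta.size == 0:
        raise ValueError("fit has no measured persons or items")

    lo = math.floor(min(theta.min(), delta.min()) / bin_width) * bin_width
    hi = math.ceil(max(theta.max(), delta.max()) / bin_width) * bin_width
    n_bins = max(int(round((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)

    p_bins = np.clip(((theta - lo) / bin_width).astype(int), 0, n_bins - 1)
    i_bins = np.clip(((delta - lo) / bin_width).astype(int), 0, n_bins - 1)
    p_counts = np.bincount(p_bins, minlength=n_bins)
    per_hash = max(1, math.ceil(p_counts.max() / (_PERSON_COL - 2)))

    item_rows: dict[int, list[str]] = {}
    for b, item in zip(i_bins, fit.items):
        item_rows.setdefault(int(b), []).append(item.item_label)

    p_marks = _marker_rows(theta, edges)
    i_marks = _marker_rows(delta, edges)

    lines = [
        "MEASURE  PERSONS (left) | ITEMS (right)",
        f"each '#' = {per_hash} person(s)",
        "-" * 72,
    ]
    for b in range(n_bins - 1, -1, -1):
        center = lo + (b + 0.5) * bin_width
        hashes = "#" * math.ceil(p_counts[b] / per_hash) if p_counts[b] else ""
        pm = p_marks.get(b, "")
        im = i_marks.get(b, "")
        labels = ", ".join(sorted(item_rows.get(b, [])))
        lines.append(
            f"{center:7.2f} {hashes:>{_PERSON_COL}}{pm:>2} |{im:<2} {labels}"
        )
    lines.append("-" * 72)
    lines.append(
        f"{len(theta)} persons, {len(delta)} items; bin width {bin_width} logits"
    )
    return "\n".join(lines) + "\n"
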