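"""Reference values for the nine-item HIV/STI sexual-risk scale.

These are the published figures from the original administration of the
scale to N=351 men who have sex with men: item wordings, endorsement
frequencies, and the published item difficulty calibration with its
standard errors.  They serve as inputs — fixture margins for the
synthetic cohort, the difficulty vector behind the raw-score→measure
conversion — not as values this package re-estimates.
"""

from __future__ import annotations

import numpy as np

#: Item wordings, in scale order.  Items 1–8 are dichotomized condom-use
#: behaviors (0 = condom used in every act, 1 = otherwise); item 9 is
#: partnership concurrency derived from first/last intercourse dates.
ITEM_LABELS: tuple[str, ...] = (
    "Had unsafe oral sex with MSM",
    "Had unsafe anal sex with MSM",
    "Had unsafe anal sex with male sex workers",
    "Had unsafe oral sex with male sex workers",
    "Had unsafe anal sex with male clients",
    "Had unsafe oral sex with male clients",
    "Had unsafe sex with female sex workers",
    "Had unsafe sex with regular sex partners",
    "Had concurrent sex partners",
)

#: Number of respondents in the original administration.
SAMPLE_SIZE: int = 351

#: Published endorsement counts per item (out of SAMPLE_SIZE).
ENDORSEMENT_COUNTS: tuple[int, ...] = (265, 139, 6, 23, 15, 40, 5, 62, 208)

#: Published item difficulty estimates, logits, centered at 0.
ITEM_DIFFICULTIES: tuple[float, ...] = (
    -4.36, -1.80, 2.85, 1.24, 1.79, 0.48, 3.06, -0.20, -3.06,
)

#: Published standard errors of the item difficulties, logits.
ITEM_DIFFICULTY_SES: tuple[float, ...] = (
    0.17, 0.13, 0.43, 0.24, 0.29, 0.19, 0.47, 0.16, 0.14,
)


def endorsement_margins() -> np.ndarray:
    """Published endorsement proportions (counts / sample size)."""
    return np.asarray(ENDORSEMENT_COUNTS, dtype=float) / SAMPLE_SIZE


def difficulty_vector() -> np.ndarray:
    """Published difficulty estimates as a float array."""
    return np.asarray(ITEM_DIFFICULTIES, dtype=float)
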