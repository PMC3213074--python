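"""Calibrate the scale: JMLE item difficulties and person measures.

Fits the dichotomous Rasch model to the simulated cohort matrix and
writes the item and person tables (difficulties/measures, standard
errors, fit statistics).
"""

from pathlib import Path

import riskrasch as rr
from riskrasch.report import item_table, person_table

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    matrix = rr.ResponseMatrix.read_csv(OUT / "matrix.csv")
    fit = rr.fit_jmle(matrix)
    print(f"JMLE converged={fit.converged} in {fit.iterations} iterations "
          f"(last max change {fit.max_logit_change:.5f} logits)")

    res = rr.standardized_residuals(fit, matrix)
    items = item_table(fit, rr.fit_statistics(res, "items"))
    persons = person_table(fit, rr.fit_statistics(res, "persons"))
    items.to_csv(OUT / "items.csv", index=False)
    persons.to_csv(OUT / "persons.csv", index=False)

    print(items.round(2).to_string(index=False))
    hardest = items.loc[items.difficulty.idxmax(), "item_label"]
    easiest = items.loc[items.difficulty.idxmin(), "item_label"]
    print(f"\nhardest to endorse: {hardest}\neasiest to endorse: {easiest}")


if __name__ == "__main__":
    main()
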