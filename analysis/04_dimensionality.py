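"""Unidimensionality and local independence.

PCA of standardized residuals against the three conventional guidelines
and the largest pairwise residual correlations at the 0.30 screen.
"""

from pathlib import Path

import riskrasch as rr

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    matrix = rr.ResponseMatrix.read_csv(OUT / "matrix.csv")
    fit = rr.fit_jmle(matrix)
    res = rr.standardized_residuals(fit, matrix)

    decomp = rr.residual_pca(res, fit)
    pairs = rr.residual_correlations(res)
    pairs.to_csv(OUT / "dependence_pairs.csv", index=False)

    report = rr.dimensionality_report(decomp, pairs)
    (OUT / "dimensionality.txt").write_text(report)
    print(report)
    print("top five pairs by |residual correlation|:")
    print(pairs.head(5).round(3).to_string(index=False))


if __name__ == "__main__":
    main()
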