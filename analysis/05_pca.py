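#!/usr/bin/env python
"""PCA ordination of the four analysis variables.

Correlation-matrix PCA over free acidity, L*, a* and the Power of Honey,
with explained variance, per-component variable contributions and
per-floral-type score centroids.
"""

from pathlib import Path

import pandas as pd

import honeypower as hp
from honeypower.ordination import PCA_VARIABLES

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    samples = pd.read_csv(OUT / "samples.csv")
    indices = pd.read_csv(OUT / "indices.csv")
    table = pd.DataFrame({
        "free_acidity": samples["free_acidity"],
        "colour_L": samples["colour_L"],
        "colour_a": samples["colour_a"],
        "power_of_honey": indices["power_of_honey"],
    })
    res = hp.run_pca(table, PCA_VARIABLES)

    expl = pd.DataFrame({
        "component": [f"PC{i + 1}" for i in range(4)],
        "eigenvalue": res.eigenvalues,
        "explained_pct": res.explained_pct,
        **{f"contrib_{v}": res.contributions_pct[i]
           for i, v in enumerate(res.variable_names)},
    })
    expl.to_csv(OUT / "pca.csv", index=False, float_format="%.10g")
    centroids = hp.summarize_groups(res.scores, samples["floral_type"].to_numpy())
    centroids.to_csv(OUT / "pca_centroids.csv", index=False, float_format="%.10g")

    print("explained variance:")
    for i in range(4):
        print(f"  PC{i + 1}: {res.explained_pct[i]:5.2f}%")
    print(f"  PC1+PC2: {res.explained_pct[:2].sum():.2f}%")
    print("\nvariable contributions to PC1/PC2 (%):")
    for i, v in enumerate(res.variable_names):
        print(f"  {v:14s} {res.contributions_pct[i, 0]:6.1f}  {res.contributions_pct[i, 1]:6.1f}")
    print("\nfloral-type centroids (PC1, PC2):")
    print(centroids[["floral_type", "pc1", "pc2"]].round(2).to_string(index=False))
    print(f"\nwrote {OUT / 'pca.csv'}")


if __name__ == "__main__":
    main()
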