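#!/usr/bin/env python
"""Macronutrient breakdown of the 12 toy diets and composition PCA.

Writes results/composition/macronutrients.tsv plus macro- and
micronutrient PCA coordinates, and prints the headline composition facts
(the Keto diet's fat energy share, the Unhealthy diet's energy excess).
"""

from pathlib import Path

import pandas as pd

from dietwbm.diet import diet_energy_kcal, macronutrient_breakdown, nutrient_matrix
from dietwbm.embedding import pca
from dietwbm.synthetic_data import make_toy_diets, nutrient_table_fixture

OUT = Path(__file__).resolve().parents[1] / "results" / "composition"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    diets = make_toy_diets()
    table = nutrient_table_fixture()

    rows = []
    for d in diets:
        row = {"diet": d.name, "kcal": diet_energy_kcal(d, table)}
        row.update(macronutrient_breakdown(d, table))
        rows.append(row)
    df = pd.DataFrame(rows).fillna(0.0).set_index("diet")
    df.to_csv(OUT / "macronutrients.tsv", sep="\t", float_format="%.6g")
    print(df.round(3))

    keto_fat = df.loc["toy-Keto", "fat"]
    ratio = df.loc["toy-Unhealthy", "kcal"] / df.loc["toy-Balanced", "kcal"]
    print(f"\nKeto fat energy share: {keto_fat:.1%} (> 53%)")
    print(f"Unhealthy/Balanced energy ratio: {ratio:.2f}")

    for scope in ("macro", "micro"):
        M, feats, names = nutrient_matrix(diets, table, scope)
        res = pca(M, k=2, sample_names=names, feature_names=feats)
        res.to_tsv(OUT / f"pca_{scope}nutrients.tsv")
        print(f"{scope} PCA: PC1 {res.variance_explained[0]:.1%}, "
              f"PC2 {res.variance_explained[1]:.1%} of variance")


if __name__ == "__main__":
    main()
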