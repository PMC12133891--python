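#!/usr/bin/env python
"""Summarize the MetS biomarker readouts of the study.

Reads the per-sex biomarker summaries written by 03_run_intervention.py,
ranks the diets per readout, and states the directional findings the toy
mechanisms plant (TAG: Unhealthy > Balanced; LDL/HDL: Unhealthy > Vegan;
beta-oxidation: Keto > Balanced in the male parameterization).  Writes
results/findings.tsv.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "results" / "study"


def main() -> None:
    findings = []
    for sex in ("male", "female"):
        df = pd.read_csv(STUDY / sex / "biomarkers" / "summary.tsv",
                         sep="\t").set_index("diet")
        print(f"\n=== {sex} ===")
        for metric in ("tag_synthesis", "ldl_hdl_ratio", "fao",
                       "glucose_secretion"):
            ranked = df[metric].sort_values(ascending=False)
            print(f"{metric}: " + " > ".join(
                f"{d.removeprefix('toy-')}({v:.2f})"
                for d, v in ranked.head(3).items()))
            findings.append({"sex": sex, "metric": metric,
                             "highest": ranked.index[0],
                             "lowest": ranked.index[-1],
                             "max": ranked.iloc[0], "min": ranked.iloc[-1]})
        checks = {
            "TAG Unhealthy > Balanced":
                df.loc["toy-Unhealthy", "tag_synthesis"]
                > df.loc["toy-Balanced", "tag_synthesis"],
            "LDL/HDL Unhealthy > Vegan":
                df.loc["toy-Unhealthy", "ldl_hdl_ratio"]
                > df.loc["toy-Vegan", "ldl_hdl_ratio"],
        }
        if sex == "male":
            checks["FAO Keto > Balanced"] = (df.loc["toy-Keto", "fao"]
                                             > df.loc["toy-Balanced", "fao"])
        for label, ok in checks.items():
            print(f"  [{'ok' if ok else 'FAIL'}] {label}")

    pd.DataFrame(findings).to_csv(ROOT / "results" / "findings.tsv",
                                  sep="\t", index=False, float_format="%.6g")
    print(f"\nwrote {ROOT / 'results' / 'findings.tsv'}")


if __name__ == "__main__":
    main()
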