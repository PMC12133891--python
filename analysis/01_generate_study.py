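#!/usr/bin/env python
"""Generate the synthetic study inputs: toy whole-body models for both
sexes, the 12 toy diets, and the nutrient classification table.

Writes everything under results/synthetic/ and prints a short inventory.
"""

from pathlib import Path

from dietwbm.model_core import parse_model, validate_model
from dietwbm.synthetic_data import write_synthetic_study

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main() -> None:
    for sex in ("male", "female"):
        paths = write_synthetic_study(OUT, sex=sex, seed=0)
        model = parse_model(paths["model"])
        report = validate_model(model)
        print(f"{sex}: {len(model.reactions)} reactions, "
              f"{len(model.metabolites)} metabolites, "
              f"{len(model.organs)} organs -> {paths['model'].name} "
              f"(validation: {'clean' if not report else report})")
    n_diets = len(list((OUT / 'diets').glob('*.tsv')))
    print(f"{n_diets} diet files in {OUT / 'diets'}")


if __name__ == "__main__":
    main()
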