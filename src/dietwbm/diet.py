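"""Diets as uptake bounds, plus macro/micronutrient composition features.

A diet is a named map nutrient -> average daily uptake (mmol/day), in the
two-column dialect used by the Virtual Metabolic Human pre-defined diets
(``Diet_EX_<nutrient>[d]  amount``).  Applying a diet rewrites only the diet
exchange bounds of a whole-body model; energy accounting uses per-nutrient
grams/mmol and kcal/gram factors (Atwater 4/9/4 kcal/g, 7 for alcohol, by
default).
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import ReactionKind, WholeBodyModel, split_compartment

log = logging.getLogger(__name__)

ATWATER_KCAL_PER_G = {"carbohydrate": 4.0, "fat": 9.0, "protein": 4.0, "alcohol": 7.0}

NUTRIENT_CLASSES = ("carbohydrate", "fat", "protein", "alcohol", "fiber",
                    "micronutrient", "other")


class DietError(ValueError):
    pass


class UndefinedCompositionError(DietError):
    """Total dietary energy is zero; fractions are undefined."""


@dataclass(frozen=True)
class DietSpec:
    name: str
    entries: dict[str, float]  # nutrient base_id -> mmol/day, >= 0

    def __post_init__(self) -> None:
        for nut, amount in self.entries.items():
            if not math.isfinite(amount) or amount < 0:
                raise DietError(f"diet {self.name}: amount for {nut} must be "
                                f"finite and non-negative, got {amount}")

    def total_mmol(self) -> float:
        return float(sum(self.entries.values()))


@dataclass(frozen=True)
class NutrientInfo:
    nutrient_class: str
    g_per_mmol: float
    kcal_per_g: float

    def __post_init__(self) -> None:
        if self.nutrient_class not in NUTRIENT_CLASSES:
            raise DietError(f"unknown nutrient class {self.nutrient_class!r}")
        if self.g_per_mmol <= 0:
            raise DietError("g_per_mmol must be positive")
        if self.kcal_per_g < 0:
            raise DietError("kcal_per_g must be non-negative")


@dataclass
class NutrientTable:
    info: dict[str, NutrientInfo]

    def __getitem__(self, base_id: str) -> NutrientInfo:
        return self.info[base_id]

    def __contains__(self, base_id: str) -> bool:
        return base_id in self.info

    def kcal_per_mmol(self, base_id: str) -> float:
        rec = self.info[base_id]
        return rec.g_per_mmol * rec.kcal_per_g

    def to_tsv(self, path: str | Path) -> None:
        rows = [{"base_id": k, "class": v.nutrient_class,
                 "g_per_mmol": v.g_per_mmol, "kcal_per_g": v.kcal_per_g}
                for k, v in self.info.items()]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NutrientTable":
        df = pd.read_csv(path, sep="\t")
        return cls({row.base_id: NutrientInfo(row["class"], float(row.g_per_mmol),
                                              float(row.kcal_per_g))
                    for _, row in df.iterrows()})


class DietMode(str, enum.Enum):
    OPTIONAL_UPTAKE = "optional_uptake"
    FORCED_UPTAKE = "forced_uptake"


@dataclass(frozen=True)
class DietApplicationPolicy:
    """How listed intakes become flux bounds on diet exchange reactions.

    ``optional_uptake`` allows uptake up to the listed amount ([-a, 0]);
    ``forced_uptake`` additionally forces at least ``force_fraction * a`` to
    be consumed ([-a, -f*a]), the convention used for VMH diet simulations.
    ``close_unlisted`` shuts uptake of every diet exchange absent from the
    diet file.
    """

    mode: DietMode = DietMode.OPTIONAL_UPTAKE
    force_fraction: float = 0.8
    close_unlisted: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.force_fraction <= 1.0:
            raise DietError("force_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def normalize_diet_identifier(identifier: str, diet_prefix: str = "Diet_EX_") -> str:
    """Strip the diet exchange prefix and compartment tag from an identifier."""
    s = identifier.strip()
    if s.startswith(diet_prefix):
        s = s[len(diet_prefix):]
    base, _comp = split_compartment(s)
    return base


def parse_diet(path: str | Path, name: str | None = None,
               diet_prefix: str = "Diet_EX_") -> DietSpec:
    """Read a two-column (identifier, mmol/day) TSV/CSV diet file.

    Identifiers are normalized to nutrient base ids; duplicate rows for the
    same nutrient are summed.  An optional header row is skipped.
    """
    path = Path(path)
    entries: dict[str, float] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p for p in line.replace(",", "\t").split("\t") if p.strip()]
        if len(parts) != 2:
            raise DietError(f"{path.name}:{lineno}: expected 2 columns, got {len(parts)}")
        ident, amount_s = parts[0].strip(), parts[1].strip()
        try:
            amount = float(amount_s)
        except ValueError:
            if lineno == 1:  # header
                continue
            raise DietError(f"{path.name}:{lineno}: unparseable amount {amount_s!r}")
        if amount < 0:
            raise DietError(f"{path.name}:{lineno}: negative amount {amount}")
        base = normalize_diet_identifier(ident, diet_prefix)
        entries[base] = entries.get(base, 0.0) + amount
    return DietSpec(name=name or path.stem, entries=entries)


def write_diet(diet: DietSpec, path: str | Path, diet_prefix: str = "Diet_EX_",
               lumen_tag: str = "[d]") -> None:
    lines = ["rxn_or_nutrient_id\tamount_mmol_per_day"]
    for nut, amount in diet.entries.items():
        lines.append(f"{diet_prefix}{nut}{lumen_tag}\t{amount:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# applying a diet to a model
# ---------------------------------------------------------------------------

def apply_diet(model: WholeBodyModel, diet: DietSpec,
               policy: DietApplicationPolicy | None = None) -> WholeBodyModel:
    """Return a copy of the model with diet exchange bounds set from the diet.

    Uptake is negative flux on diet exchanges, so an intake of ``a`` becomes
    ``[-a, 0]`` (optional) or ``[-a, -f*a]`` (forced).  All non-diet bounds
    are left untouched.  Diet entries with no matching exchange reaction are
    logged as warnings, never fatal.
    """
    policy = policy or DietApplicationPolicy()
    new = model.copy()
    conv = new.convention
    by_base: dict[str, list] = {}
    for r in new.reactions:
        if r.kind is ReactionKind.DIET_EXCHANGE:
            by_base.setdefault(normalize_diet_identifier(r.id, conv.diet_prefix),
                               []).append(r)

    matched: set[str] = set()
    unmatched: list[str] = []
    for nut, amount in diet.entries.items():
        rxns = by_base.get(nut)
        if not rxns:
            unmatched.append(nut)
            continue
        matched.add(nut)
        for r in rxns:
            r.lb = -amount
            r.ub = (-policy.force_fraction * amount
                    if policy.mode is DietMode.FORCED_UPTAKE else 0.0)
    if policy.close_unlisted:
        for base, rxns in by_base.items():
            if base not in matched:
                for r in rxns:
                    r.lb = 0.0
                    r.ub = max(r.ub, 0.0)
    if unmatched:
        log.warning("diet %s: %d entries without a diet exchange reaction: %s",
                    diet.name, len(unmatched), ", ".join(sorted(unmatched)))
    new.report = list(new.report) + [
        f"applied diet {diet.name} ({policy.mode.value}); "
        f"{len(matched)} matched, {len(unmatched)} unmatched"
    ]
    return new


# ---------------------------------------------------------------------------
# composition features
# ---------------------------------------------------------------------------

def macronutrient_breakdown(diet: DietSpec, table: NutrientTable) -> dict[str, float]:
    """Energy fraction per macronutrient class (sums to 1 over energy classes).

    kcal(class) = sum over members of amount * g_per_mmol * kcal_per_g;
    nutrients missing from the table are counted under "other" (0 kcal) and
    logged.
    """
    kcal: dict[str, float] = {}
    missing = []
    for nut, amount in diet.entries.items():
        if nut not in table:
            missing.append(nut)
            kcal["other"] = kcal.get("other", 0.0)
            continue
        rec = table[nut]
        kcal[rec.nutrient_class] = (kcal.get(rec.nutrient_class, 0.0)
                                    + amount * rec.g_per_mmol * rec.kcal_per_g)
    if missing:
        log.warning("diet %s: nutrients missing from table counted as 'other': %s",
                    diet.name, ", ".join(sorted(missing)))
    total = sum(kcal.values())
    if total <= 0:
        raise UndefinedCompositionError(
            f"diet {diet.name} carries no dietary energy; fractions undefined")
    return {cls: v / total for cls, v in kcal.items() if v > 0}


def diet_energy_kcal(diet: DietSpec, table: NutrientTable) -> float:
    return float(sum(amount * table.kcal_per_mmol(nut)
                     for nut, amount in diet.entries.items() if nut in table))


def nutrient_matrix(diets: list[DietSpec], table: NutrientTable,
                    scope: str = "macro") -> tuple[np.ndarray, list[str], list[str]]:
    """Diet x feature matrix for composition embeddings.

    ``macro`` scope: energy fractions per macronutrient class.  ``micro``
    scope: mmol/day amounts of micronutrient-class entries.  Returns
    (matrix, feature_names, diet_names) with deterministic column order.
    """
    if len(diets) < 2:
        raise DietError("nutrient_matrix needs at least 2 diets")
    if scope == "macro":
        features = [c for c in NUTRIENT_CLASSES if c not in ("micronutrient", "other")]
        rows = []
        for d in diets:
            breakdown = macronutrient_breakdown(d, table)
            rows.append([breakdown.get(c, 0.0) for c in features])
        return np.array(rows), features, [d.name for d in diets]
    if scope == "micro":
        features = sorted(n for n, rec in table.info.items()
                          if rec.nutrient_class == "micronutrient")
        if not features:
            raise DietError("nutrient table contains no micronutrients")
        rows = [[d.entries.get(n, 0.0) for n in features] for d in diets]
        return np.array(rows), features, [d.name for d in diets]
    raise DietError(f"unknown scope {scope!r}")
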