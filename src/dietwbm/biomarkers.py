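"""Metabolic-syndrome biomarker reaction panels and flux summary statistics.

The readouts mirror the flux-level surrogates used for MetS risk:

* organ-resolved glucose exchange with systemic blood (secretion > 0),
* summed adipocyte TAG esterification flux (proxy for TAG storage),
* ratio of total LDL-C to HDL-C secretion flux into blood,
* summed thiolase-step butyryl-CoA -> acetyl-CoA flux in muscle and heart
  (surrogate for fatty-acid beta-oxidation activity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import ReactionKind, WholeBodyModel, find_organ_exchanges
from .solver import FluxSolution

log = logging.getLogger(__name__)


class PanelResolutionError(ValueError):
    """A configured biomarker pattern resolved to no reactions."""


class UndefinedRatioError(ValueError):
    """HDL-C secretion is below the guard; the LDL/HDL ratio is undefined."""


class PartialTableError(ValueError):
    """Some diets lack an optimal solution; the organ table is incomplete."""


@dataclass
class BiomarkerPanel:
    """Resolved reaction-identifier sets per biomarker for one model."""

    sex: str
    glucose_exchange: list[str] = field(default_factory=list)
    tag_synthesis: list[str] = field(default_factory=list)
    ldl_exchange: list[str] = field(default_factory=list)
    hdl_exchange: list[str] = field(default_factory=list)
    fao: list[str] = field(default_factory=list)

    def all_reactions(self) -> list[str]:
        seen: dict[str, None] = {}
        for group in (self.glucose_exchange, self.tag_synthesis,
                      self.ldl_exchange, self.hdl_exchange, self.fao):
            for r in group:
                seen[r] = None
        return list(seen)


def default_panel_config() -> dict:
    """Structural pattern rules matching the synthetic toy models."""
    return {
        "glucose": {"pattern": {"exchange_base_id": "glc_D"}},
        "ldl": {"pattern": {"exchange_base_id": "ldl"}},
        "hdl": {"pattern": {"exchange_base_id": "hdl"}},
        "tag": {"pattern": {"organ": "Adipocyte", "produces": "tag"}},
        "fao": {"pattern": {"organs": ["Muscle", "Heart"],
                            "consumes": "btcoa", "produces": "accoa"}},
    }


def _resolve_one(model: WholeBodyModel, name: str, spec: dict) -> list[str]:
    if "ids" in spec:
        ids = list(spec["ids"])
        known = set(model.reaction_ids)
        missing = [r for r in ids if r not in known]
        if missing:
            raise PanelResolutionError(
                f"{name}: explicit ids not in model: {missing}")
        return ids
    pattern = spec.get("pattern", {})
    if "exchange_base_id" in pattern:
        hits = find_organ_exchanges(model, pattern["exchange_base_id"])
    else:
        met_base = {m.id: m.base_id for m in model.metabolites}
        met_organ = {m.id: m.organ for m in model.metabolites}
        organs = set(pattern.get("organs") or
                     ([pattern["organ"]] if "organ" in pattern else model.organs))
        hits = []
        for r in model.reactions:
            if r.kind is not ReactionKind.INTERNAL or r.organ not in organs:
                continue
            consumed = {met_base[m] for m, c in r.stoich.items() if c < 0}
            produced = {met_base[m] for m, c in r.stoich.items() if c > 0}
            if "consumes" in pattern and pattern["consumes"] not in consumed:
                continue
            if "produces" in pattern and pattern["produces"] not in produced:
                continue
            if not all(met_organ[m] in organs for m in r.stoich):
                continue
            hits.append(r.id)
        hits = sorted(hits)
    if not hits:
        raise PanelResolutionError(f"{name}: pattern {pattern} resolved to "
                                   "no reactions in the model")
    return hits


def resolve_panel(model: WholeBodyModel, config: dict | None = None) -> BiomarkerPanel:
    """Resolve explicit id lists or structural patterns to concrete reactions.

    Raises :class:`PanelResolutionError` if a requested metric resolves to
    zero reactions; the resolution manifest is logged.
    """
    config = config or default_panel_config()
    panel = BiomarkerPanel(sex=model.sex)
    mapping = {"glucose": "glucose_exchange", "tag": "tag_synthesis",
               "ldl": "ldl_exchange", "hdl": "hdl_exchange", "fao": "fao"}
    for key, attr in mapping.items():
        if key in config:
            ids = _resolve_one(model, key, config[key])
            setattr(panel, attr, ids)
            log.info("panel %s (%s): %d reactions: %s", key, model.sex,
                     len(ids), ", ".join(ids))
    return panel


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def secretion_uptake_totals(solution: FluxSolution,
                            reactions: list[str]) -> dict[str, float]:
    """Positive-part secretion and uptake totals over exchange reactions.

    With the secretion-positive sign convention: total_secretion is the sum
    of positive fluxes (organs secreting), total_uptake the sum of negative
    flux magnitudes (organs taking up), net their difference.
    """
    v = solution.vector(reactions) if reactions else np.zeros(0)
    secretion = float(np.sum(np.maximum(v, 0.0)))
    uptake = float(np.sum(np.maximum(-v, 0.0)))
    return {"total_secretion": secretion, "total_uptake": uptake,
            "net": secretion - uptake}


def sum_flux(solution: FluxSolution, reactions: list[str]) -> float:
    """Plain signed sum of fluxes over a resolved reaction set."""
    if not reactions:
        log.warning("sum_flux called with an empty reaction list")
        return 0.0
    return float(np.sum(solution.vector(reactions)))


def ldl_hdl_ratio(solution: FluxSolution, ldl: list[str], hdl: list[str],
                  guard: float = 1e-9) -> float:
    """Total LDL-C over total HDL-C secretion flux into blood."""
    ldl_secretion = secretion_uptake_totals(solution, ldl)["total_secretion"]
    hdl_secretion = secretion_uptake_totals(solution, hdl)["total_secretion"]
    if hdl_secretion <= guard:
        raise UndefinedRatioError(
            f"HDL-C secretion {hdl_secretion:.3g} is at or below the guard "
            f"{guard:.3g}; ratio undefined")
    return ldl_secretion / hdl_secretion


# ---------------------------------------------------------------------------
# organ x diet tables
# ---------------------------------------------------------------------------

@dataclass
class OrganFluxTable:
    """Organ x diet matrix of exchange fluxes (mmol/day/person; secretion > 0)."""

    organs: list[str]
    diets: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.organs), len(self.diets)):
            raise ValueError("organ/diet labels do not match the value matrix")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.organs, columns=self.diets)

    def to_tsv(self, path) -> None:
        self.to_frame().rename_axis("organ").to_csv(path, sep="\t",
                                                    float_format="%.10g")


def organ_contribution_table(solutions: dict[str, FluxSolution],
                             reactions_by_organ: dict[str, list[str]]
                             ) -> OrganFluxTable:
    """Per-organ exchange flux per diet; multiple reactions per organ summed.

    ``solutions`` maps diet name -> optimal FluxSolution.  Raises
    :class:`PartialTableError` listing diets without an optimal solution.
    """
    from .solver import SolverStatus

    bad = [d for d, s in solutions.items() if s.status is not SolverStatus.OPTIMAL]
    if bad:
        raise PartialTableError(f"diets without optimal solutions: {bad}")
    organs = sorted(reactions_by_organ)
    diets = list(solutions)
    values = np.zeros((len(organs), len(diets)))
    for i, organ in enumerate(organs):
        for j, d in enumerate(diets):
            values[i, j] = sum(solutions[d][r] for r in reactions_by_organ[organ])
    return OrganFluxTable(organs=organs, diets=diets, values=values)


def classify_organ_roles(table: OrganFluxTable,
                         tau: float = 1e-6) -> dict[str, str]:
    """Label each organ by its consistent exchange direction across diets.

    secretor: flux > tau under every diet; uptaker: flux < -tau under every
    diet; inactive: |flux| <= tau under every diet; otherwise mixed.
    """
    out = {}
    for i, organ in enumerate(table.organs):
        row = table.values[i]
        if np.all(row > tau):
            out[organ] = "secretor"
        elif np.all(row < -tau):
            out[organ] = "uptaker"
        elif np.all(np.abs(row) <= tau):
            out[organ] = "inactive"
        else:
            out[organ] = "mixed"
    return out
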