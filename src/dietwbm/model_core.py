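"""Data model and I/O for organ-resolved whole-body stoichiometric models.

A whole-body model (WBM) integrates per-organ metabolic sub-networks through
shared biofluid compartments (systemic blood, gastrointestinal lumen).  This
module defines the in-memory types, the identifier conventions used to
classify reactions (diet exchange, organ-blood exchange, maintenance, sink),
and readers/writers for a plain JSON model dialect plus an SBML Level 3
reader.  Flux bounds are in mmol/day/person throughout.

Sign convention, fixed package-wide: for organ-blood exchange reactions a
positive flux means secretion of the metabolite into blood.  Readers
re-orient reactions written the other way round and record the flip.
"""

from __future__ import annotations

import enum
import json
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

#: Finite stand-in for an unbounded flux bound.  A strictly convex pFBA
#: objective keeps optima well inside this box.
INF_BOUND = 1.0e6


class ReactionKind(str, enum.Enum):
    INTERNAL = "internal"
    ORGAN_BLOOD_EXCHANGE = "organ_blood_exchange"
    DIET_EXCHANGE = "diet_exchange"
    MAINTENANCE = "maintenance"
    SINK_DEMAND = "sink_demand"


@dataclass(frozen=True)
class NamingConvention:
    """Identifier grammar for WBM-style models.

    Mirrors the VMH/WBM style: reactions are prefixed ``<Organ>_``, the
    systemic blood compartment is tagged ``[bc]``, dietary boundary
    reactions are prefixed ``Diet_EX_`` and lumen metabolites tagged ``[d]``.
    """

    organ_separator: str = "_"
    blood_tag: str = "[bc]"
    diet_prefix: str = "Diet_EX_"
    lumen_tag: str = "[d]"

    def __post_init__(self) -> None:
        tags = [self.organ_separator, self.blood_tag, self.diet_prefix, self.lumen_tag]
        if any(not t for t in tags):
            raise ValueError("naming convention tags must be non-empty")
        if len(set(tags)) != len(tags):
            raise ValueError("naming convention tags must be mutually distinct")


@dataclass(frozen=True)
class Metabolite:
    id: str
    base_id: str
    organ: str | None
    compartment: str


@dataclass
class Reaction:
    id: str
    stoich: dict[str, float]
    lb: float
    ub: float
    kind: ReactionKind = ReactionKind.INTERNAL
    organ: str | None = None

    def __post_init__(self) -> None:
        if self.lb > self.ub:
            raise ModelIntegrityError(
                f"reaction {self.id}: lb {self.lb} > ub {self.ub}"
            )


class ModelFormatError(ValueError):
    """Unreadable or syntactically invalid model file."""


class ModelIntegrityError(ValueError):
    """Structurally inconsistent model (duplicate ids, bad bounds, ...)."""


class ModelError(ValueError):
    """Semantically invalid model (e.g. maintenance reaction count != 1)."""


@dataclass
class WholeBodyModel:
    sex: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    maintenance_reaction_id: str
    organs: list[str]
    physiology: dict[str, float] = field(default_factory=dict)
    convention: NamingConvention = field(default_factory=NamingConvention)
    #: reader notes, e.g. sign flips applied to off-convention exchanges
    report: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise ModelIntegrityError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelIntegrityError("duplicate reaction ids")
        n_maint = sum(1 for r in self.reactions if r.kind is ReactionKind.MAINTENANCE)
        if n_maint != 1:
            raise ModelError(f"model must have exactly one maintenance reaction, found {n_maint}")
        if self.maintenance_reaction_id not in set(rxn_ids):
            raise ModelError("maintenance_reaction_id not among reactions")
        for k, v in self.physiology.items():
            if v is not None and v <= 0:
                raise ModelIntegrityError(f"physiology value {k}={v} must be positive")

    # -- lookups ------------------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index()[rxn_id]
        except KeyError:
            raise KeyError(f"no reaction {rxn_id!r} in model") from None

    def _rxn_index(self) -> dict[str, Reaction]:
        idx = getattr(self, "_rxn_idx_cache", None)
        if idx is None or len(idx) != len(self.reactions):
            idx = {r.id: r for r in self.reactions}
            object.__setattr__(self, "_rxn_idx_cache", idx)
        return idx

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(f"no metabolite {met_id!r} in model")

    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """(|metabolites| x |reactions|) sparse stoichiometric matrix S."""
        met_pos = {m.id: i for i, m in enumerate(self.metabolites)}
        rows, cols, vals = [], [], []
        for j, r in enumerate(self.reactions):
            for met_id, coef in r.stoich.items():
                rows.append(met_pos[met_id])
                cols.append(j)
                vals.append(float(coef))
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([max(r.lb, -INF_BOUND) for r in self.reactions])
        ub = np.array([min(r.ub, INF_BOUND) for r in self.reactions])
        return lb, ub

    def copy(self) -> "WholeBodyModel":
        return WholeBodyModel(
            sex=self.sex,
            metabolites=list(self.metabolites),
            reactions=[replace(r, stoich=dict(r.stoich)) for r in self.reactions],
            maintenance_reaction_id=self.maintenance_reaction_id,
            organs=list(self.organs),
            physiology=dict(self.physiology),
            convention=self.convention,
            report=list(self.report),
        )


# ---------------------------------------------------------------------------
# identifier parsing / classification
# ---------------------------------------------------------------------------

_COMPARTMENT_RE = re.compile(r"\[([a-zA-Z]+)\]$")


def split_compartment(met_id: str) -> tuple[str, str]:
    """Split ``base[tag]`` into (base, "[tag]"); compartment defaults to "[c]"."""
    m = _COMPARTMENT_RE.search(met_id)
    if m is None:
        return met_id, "[c]"
    return met_id[: m.start()], f"[{m.group(1)}]"


def organ_of_identifier(identifier: str, organs: Iterable[str], sep: str = "_") -> str | None:
    """Longest-prefix match of an id against the model's organ list."""
    best = None
    for organ in organs:
        if identifier.startswith(organ + sep) and (best is None or len(organ) > len(best)):
            best = organ
    return best


def parse_metabolite_id(met_id: str, organs: Iterable[str],
                        convention: NamingConvention | None = None) -> Metabolite:
    conv = convention or NamingConvention()
    stem, comp = split_compartment(met_id)
    organ = organ_of_identifier(stem, organs, conv.organ_separator)
    base = stem[len(organ) + len(conv.organ_separator):] if organ else stem
    return Metabolite(id=met_id, base_id=base, organ=organ, compartment=comp)


def classify_reaction(rxn_id: str, stoich: Mapping[str, float], organs: Iterable[str],
                      maintenance_reaction_id: str,
                      convention: NamingConvention | None = None) -> ReactionKind:
    """Assign exactly one kind to a reaction from its id and stoichiometry."""
    conv = convention or NamingConvention()
    if rxn_id == maintenance_reaction_id:
        return ReactionKind.MAINTENANCE
    if rxn_id.startswith(conv.diet_prefix):
        return ReactionKind.DIET_EXCHANGE
    organ = organ_of_identifier(rxn_id, organs, conv.organ_separator)
    touches_blood = any(m.endswith(conv.blood_tag) for m in stoich)
    touches_nonblood = any(not m.endswith(conv.blood_tag) for m in stoich)
    if organ and touches_blood and (touches_nonblood or len(stoich) == 1):
        # transport between an organ compartment and systemic blood
        if f"{conv.organ_separator}EX{conv.organ_separator}" in rxn_id:
            return ReactionKind.ORGAN_BLOOD_EXCHANGE
    if len(stoich) == 1 and not rxn_id.startswith(conv.diet_prefix):
        return ReactionKind.SINK_DEMAND
    return ReactionKind.INTERNAL


def find_organ_exchanges(model: WholeBodyModel, base_id: str) -> list[str]:
    """All organ-blood exchange reactions moving ``base_id`` to/from blood.

    Returns reaction ids in deterministic lexicographic order; unknown
    metabolites yield an empty list.
    """
    if not base_id:
        raise ValueError("base_id must be non-empty")
    conv = model.convention
    met_by_id = {m.id: m for m in model.metabolites}
    hits = []
    for r in model.reactions:
        if r.kind is not ReactionKind.ORGAN_BLOOD_EXCHANGE:
            continue
        for met_id in r.stoich:
            met = met_by_id.get(met_id)
            base = met.base_id if met else split_compartment(met_id)[0]
            if met_id.endswith(conv.blood_tag) and base == base_id:
                hits.append(r.id)
                break
    return sorted(hits)


def group_exchanges_by_organ(model: WholeBodyModel, base_id: str) -> dict[str, list[str]]:
    """``find_organ_exchanges`` grouped by the owning organ."""
    out: dict[str, list[str]] = {}
    for rxn_id in find_organ_exchanges(model, base_id):
        organ = model.reaction(rxn_id).organ or organ_of_identifier(
            rxn_id, model.organs, model.convention.organ_separator
        ) or "?"
        out.setdefault(organ, []).append(rxn_id)
    return out


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationEntry:
    severity: str  # "error" | "warning"
    code: str
    message: str


def validate_model(model: WholeBodyModel) -> list[ValidationEntry]:
    """Structural checks; returns a report (empty iff the model passes)."""
    report: list[ValidationEntry] = []
    conv = model.convention
    maint = model.reaction(model.maintenance_reaction_id)
    if not (math.isfinite(maint.lb) and math.isfinite(maint.ub)):
        report.append(ValidationEntry("error", "MAINTENANCE_BOUNDS",
                                      "maintenance reaction has non-finite bounds"))
    if not any(r.kind is ReactionKind.DIET_EXCHANGE for r in model.reactions):
        report.append(ValidationEntry("error", "NO_DIET_EXCHANGE",
                                      "model has no diet exchange reactions"))
    for r in model.reactions:
        if math.isnan(r.lb) or math.isnan(r.ub):
            report.append(ValidationEntry("error", "NAN_BOUND",
                                          f"reaction {r.id} has NaN bound"))
        elif r.lb > r.ub:
            report.append(ValidationEntry("error", "BOUND_ORDER",
                                          f"reaction {r.id}: lb > ub"))
        if r.kind is ReactionKind.ORGAN_BLOOD_EXCHANGE:
            n_blood = sum(1 for m in r.stoich if m.endswith(conv.blood_tag))
            if n_blood != 1:
                report.append(ValidationEntry(
                    "error", "BLOOD_TAG_COUNT",
                    f"organ-blood exchange {r.id} touches {n_blood} blood metabolites"))
        organ = r.organ
        if organ is not None and organ not in model.organs:
            report.append(ValidationEntry("error", "UNKNOWN_ORGAN",
                                          f"reaction {r.id} names organ {organ!r} "
                                          "absent from the organ list"))
    return report


# ---------------------------------------------------------------------------
# JSON model dialect
# ---------------------------------------------------------------------------

def write_model(model: WholeBodyModel, path: str | Path) -> None:
    """Serialize to the package's JSON model dialect (deterministic bytes)."""
    doc = {
        "format": "dietwbm-model/1",
        "sex": model.sex,
        "organs": model.organs,
        "maintenance_reaction_id": model.maintenance_reaction_id,
        "physiology": model.physiology,
        "convention": {
            "organ_separator": model.convention.organ_separator,
            "blood_tag": model.convention.blood_tag,
            "diet_prefix": model.convention.diet_prefix,
            "lumen_tag": model.convention.lumen_tag,
        },
        "metabolites": [
            {"id": m.id, "base_id": m.base_id, "organ": m.organ, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {"id": r.id, "organ": r.organ, "kind": r.kind.value,
             "lb": r.lb, "ub": r.ub, "stoich": r.stoich}
            for r in model.reactions
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=False) + "\n")


def _orient_exchange(rxn: Reaction, blood_tag: str, report: list[str]) -> Reaction:
    """Flip an organ-blood exchange so that positive flux = secretion into blood."""
    blood_coefs = [c for m, c in rxn.stoich.items() if m.endswith(blood_tag)]
    if len(blood_coefs) == 1 and blood_coefs[0] < 0:
        rxn = replace(
            rxn,
            stoich={m: -c for m, c in rxn.stoich.items()},
            lb=-rxn.ub,
            ub=-rxn.lb,
        )
        report.append(f"flipped {rxn.id} to secretion-positive orientation")
    return rxn


def write_model_tsv(model: WholeBodyModel, directory: str | Path) -> None:
    """Serialize to the triplet-TSV dialect: ``metabolites.tsv``,
    ``reactions.tsv`` and ``stoich.tsv`` in one directory."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    met_lines = ["id\tbase_id\torgan\tcompartment"]
    met_lines += [f"{m.id}\t{m.base_id}\t{m.organ or ''}\t{m.compartment}"
                  for m in model.metabolites]
    (d / "metabolites.tsv").write_text("\n".join(met_lines) + "\n")
    rxn_lines = ["id\torgan\tkind\tlb\tub"]
    sto_lines = ["reaction_id\tmetabolite_id\tcoefficient"]
    for r in model.reactions:
        rxn_lines.append(f"{r.id}\t{r.organ or ''}\t{r.kind.value}"
                         f"\t{r.lb:.17g}\t{r.ub:.17g}")
        sto_lines += [f"{r.id}\t{m}\t{c:.17g}" for m, c in r.stoich.items()]
    (d / "reactions.tsv").write_text("\n".join(rxn_lines) + "\n")
    (d / "stoich.tsv").write_text("\n".join(sto_lines) + "\n")
    meta = {"sex": model.sex, "organs": model.organs,
            "maintenance_reaction_id": model.maintenance_reaction_id,
            "physiology": model.physiology}
    (d / "model_meta.json").write_text(json.dumps(meta, indent=1) + "\n")


def _parse_tsv_dir(d: Path, convention: NamingConvention | None) -> WholeBodyModel:
    import pandas as pd

    conv = convention or NamingConvention()
    meta = json.loads((d / "model_meta.json").read_text()) \
        if (d / "model_meta.json").exists() else {}
    mets_df = pd.read_csv(d / "metabolites.tsv", sep="\t",
                          keep_default_na=False)
    rxns_df = pd.read_csv(d / "reactions.tsv", sep="\t",
                          keep_default_na=False, float_precision="round_trip")
    sto_df = pd.read_csv(d / "stoich.tsv", sep="\t", float_precision="round_trip")
    stoich_by_rxn: dict[str, dict[str, float]] = {}
    for rec in sto_df.itertuples(index=False):
        stoich_by_rxn.setdefault(rec.reaction_id, {})[rec.metabolite_id] = \
            float(rec.coefficient)
    metabolites = [Metabolite(r.id, r.base_id, r.organ or None, r.compartment)
                   for r in mets_df.itertuples(index=False)]
    report: list[str] = []
    reactions = []
    for r in rxns_df.itertuples(index=False):
        rxn = Reaction(id=r.id, stoich=stoich_by_rxn.get(r.id, {}),
                       lb=float(r.lb), ub=float(r.ub),
                       kind=ReactionKind(r.kind), organ=r.organ or None)
        if rxn.kind is ReactionKind.ORGAN_BLOOD_EXCHANGE:
            rxn = _orient_exchange(rxn, conv.blood_tag, report)
        reactions.append(rxn)
    return WholeBodyModel(
        sex=meta.get("sex", "male"), metabolites=metabolites,
        reactions=reactions,
        maintenance_reaction_id=meta.get("maintenance_reaction_id", ""),
        organs=list(meta.get("organs", [])),
        physiology={k: float(v) for k, v in meta.get("physiology", {}).items()},
        convention=conv, report=report)


def parse_model(path: str | Path,
                convention: NamingConvention | None = None) -> WholeBodyModel:
    """Read a model from SBML, the JSON dialect, or a triplet-TSV directory."""
    path = Path(path)
    if path.is_dir():
        if not (path / "reactions.tsv").exists():
            raise ModelFormatError(f"{path} is not a triplet-TSV model directory")
        return _parse_tsv_dir(path, convention)
    if not path.exists():
        raise ModelFormatError(f"model file not found: {path}")
    head = path.read_text(errors="replace")[:200].lstrip()
    if head.startswith("<?xml") or head.startswith("<sbml"):
        return _parse_sbml(path, convention)
    return _parse_json(path, convention)


def _parse_json(path: Path, convention: NamingConvention | None) -> WholeBodyModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"not valid JSON model dialect: {exc}") from exc
    if not isinstance(doc, dict) or "reactions" not in doc:
        raise ModelFormatError("JSON file lacks a 'reactions' section")
    conv = convention or NamingConvention(**doc.get("convention", {}))
    organs = list(doc.get("organs", []))
    maint_id = doc.get("maintenance_reaction_id", "")
    report: list[str] = []

    metabolites = [
        Metabolite(id=m["id"], base_id=m.get("base_id") or split_compartment(m["id"])[0],
                   organ=m.get("organ"), compartment=m.get("compartment") or
                   split_compartment(m["id"])[1])
        for m in doc.get("metabolites", [])
    ]
    known_mets = {m.id for m in metabolites}
    reactions: list[Reaction] = []
    for rec in doc["reactions"]:
        stoich = {m: float(c) for m, c in rec["stoich"].items()}
        missing = set(stoich) - known_mets
        if missing:
            raise ModelIntegrityError(
                f"reaction {rec['id']} references unknown metabolites {sorted(missing)}")
        kind = (ReactionKind(rec["kind"]) if rec.get("kind")
                else classify_reaction(rec["id"], stoich, organs, maint_id, conv))
        rxn = Reaction(id=rec["id"], stoich=stoich,
                       lb=float(rec["lb"]), ub=float(rec["ub"]), kind=kind,
                       organ=rec.get("organ") if "organ" in rec
                       else organ_of_identifier(rec["id"], organs, conv.organ_separator))
        if kind is ReactionKind.ORGAN_BLOOD_EXCHANGE:
            rxn = _orient_exchange(rxn, conv.blood_tag, report)
        reactions.append(rxn)

    model = WholeBodyModel(
        sex=doc.get("sex", "male"), metabolites=metabolites, reactions=reactions,
        maintenance_reaction_id=maint_id, organs=organs,
        physiology={k: float(v) for k, v in doc.get("physiology", {}).items()},
        convention=conv, report=report,
    )
    return model


def _parse_sbml(path: Path, convention: NamingConvention | None) -> WholeBodyModel:
    """Read an SBML Level 3 (fbc) file into a WholeBodyModel.

    Organ membership is recovered by prefix-matching reaction/species ids
    against the organ list stored in the model notes (``organs: a;b;c``) or,
    failing that, inferred from id prefixes shared by >=2 reactions.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors() > 0 and doc.getError(0).getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
        raise ModelFormatError(f"libsbml: {doc.getError(0).getMessage()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelFormatError("SBML file contains no model")
    conv = convention or NamingConvention()
    fbc = sbml_model.getPlugin("fbc")

    notes = sbml_model.getNotesString() if sbml_model.isSetNotes() else ""
    organs: list[str] = []
    maint_id = ""
    for line in notes.splitlines():
        line = re.sub(r"<[^>]+>", "", line).strip()
        if line.startswith("organs:"):
            organs = [o.strip() for o in line.split(":", 1)[1].split(";") if o.strip()]
        if line.startswith("maintenance:"):
            maint_id = line.split(":", 1)[1].strip()

    def _undo_sbml_id(sid: str) -> str:
        # libsbml ids cannot contain brackets; we store  x__91__bc__93__ style
        return sid.replace("__91__", "[").replace("__93__", "]")

    metabolites = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        mid = _undo_sbml_id(sp.getId())
        metabolites.append(parse_metabolite_id(mid, organs, conv))

    params = {sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
              for i in range(sbml_model.getNumParameters())}
    reactions = []
    report: list[str] = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        rid = _undo_sbml_id(rx.getId())
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            met = _undo_sbml_id(ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            met = _undo_sbml_id(ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        rfbc = rx.getPlugin("fbc")
        if rfbc is not None and rfbc.isSetLowerFluxBound():
            lb = params[rfbc.getLowerFluxBound()]
            ub = params[rfbc.getUpperFluxBound()]
        else:
            lb = -INF_BOUND if rx.getReversible() else 0.0
            ub = INF_BOUND
        if not maint_id and "maintenance" in rid.lower():
            maint_id = rid
        kind = classify_reaction(rid, stoich, organs, maint_id, conv)
        rxn = Reaction(id=rid, stoich=stoich, lb=float(lb), ub=float(ub), kind=kind,
                       organ=organ_of_identifier(rid, organs, conv.organ_separator))
        if kind is ReactionKind.ORGAN_BLOOD_EXCHANGE:
            rxn = _orient_exchange(rxn, conv.blood_tag, report)
        reactions.append(rxn)

    sex = "male"
    if fbc is not None and sbml_model.isSetName() and "female" in sbml_model.getName().lower():
        sex = "female"
    return WholeBodyModel(sex=sex, metabolites=metabolites, reactions=reactions,
                          maintenance_reaction_id=maint_id, organs=organs,
                          convention=conv, report=report)
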