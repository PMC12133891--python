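"""Orchestration of the full in silico diet-intervention study.

For each (sex, diet) cell: apply the diet's uptake bounds, solve
L2-parsimonious FBA with maintenance pinned to one, compute the biomarker
readouts, then build nutrient-composition PCA and flux-space t-SNE
embeddings.  Failed (infeasible) diets are diagnosed and reported without
aborting the study.  Outputs are deterministic TSV/JSON files: re-running
with an identical config and seeds reproduces them byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .biomarkers import (
    classify_organ_roles,
    default_panel_config,
    ldl_hdl_ratio,
    organ_contribution_table,
    resolve_panel,
    secretion_uptake_totals,
    sum_flux,
)
from .diet import (
    DietApplicationPolicy,
    DietMode,
    DietSpec,
    NutrientTable,
    apply_diet,
    macronutrient_breakdown,
    nutrient_matrix,
    parse_diet,
)
from .embedding import flux_matrix, pca, tsne_embed
from .model_core import group_exchanges_by_organ, parse_model
from .solver import SolverSettings, SolverStatus, diagnose_infeasibility, pfba

log = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    model_paths: dict[str, str]  # sex -> model file
    diet_dir: str
    nutrient_table_path: str
    output_dir: str
    panel_config: dict | None = None
    policy: DietApplicationPolicy = field(
        default_factory=lambda: DietApplicationPolicy(mode=DietMode.FORCED_UPTAKE))
    solver: SolverSettings = field(default_factory=SolverSettings)
    embedding_seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        doc = yaml.safe_load(Path(path).read_text())
        policy = DietApplicationPolicy(
            mode=DietMode(doc.get("policy", {}).get("mode", "forced_uptake")),
            force_fraction=doc.get("policy", {}).get("force_fraction", 0.8),
            close_unlisted=doc.get("policy", {}).get("close_unlisted", True))
        solver = SolverSettings(
            maintenance_value=doc.get("solver", {}).get("maintenance_value", 1.0))
        return cls(model_paths=dict(doc["model_paths"]),
                   diet_dir=doc["diet_dir"],
                   nutrient_table_path=doc["nutrient_table"],
                   output_dir=doc["output_dir"],
                   panel_config=doc.get("panel"),
                   policy=policy, solver=solver,
                   embedding_seed=int(doc.get("embedding_seed", 0)),
                   log_level=doc.get("log_level", "INFO"))

    def validate_paths(self) -> None:
        for sex, p in self.model_paths.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"model for {sex}: {p}")
        for p in (self.diet_dir, self.nutrient_table_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)

    def content_hash(self) -> str:
        doc = {"model_paths": self.model_paths, "diet_dir": self.diet_dir,
               "nutrient_table": self.nutrient_table_path,
               "policy": [self.policy.mode.value, self.policy.force_fraction,
                          self.policy.close_unlisted],
               "maintenance": self.solver.maintenance_value,
               "embedding_seed": self.embedding_seed}
        return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class StudyResult:
    """In-memory result bundle; files mirror it under ``output_dir``."""

    solutions: dict  # (sex, diet) -> FluxSolution
    biomarkers: dict  # sex -> DataFrame-like rows
    organ_tables: dict  # sex -> OrganFluxTable (glucose)
    organ_roles: dict  # sex -> organ -> role
    failed: dict  # (sex, diet) -> diagnosis list
    output_dir: Path


def run_intervention(config: StudyConfig) -> StudyResult:
    """Run the diets x sexes study and write the result bundle to disk."""
    import pandas as pd

    config.validate_paths()
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    table = NutrientTable.from_tsv(config.nutrient_table_path)
    diet_files = sorted(Path(config.diet_dir).glob("*.tsv"))
    if not diet_files:
        raise FileNotFoundError(f"no diet TSVs in {config.diet_dir}")

    diets: list[DietSpec] = []
    for f in diet_files:
        try:
            diets.append(parse_diet(f))
        except Exception as exc:
            log.error("diet file %s failed to parse: %s", f.name, exc)
            diets.append(None)  # placeholder keeps bookkeeping aligned
    diet_names = [d.name if d else f.stem for d, f in zip(diets, diet_files)]

    solutions: dict = {}
    failed: dict = {}
    biomarker_rows: dict[str, list[dict]] = {}
    organ_tables: dict = {}
    organ_roles: dict = {}

    for sex in sorted(config.model_paths):
        t_sex = time.perf_counter()
        model = parse_model(config.model_paths[sex])
        panel = resolve_panel(model, config.panel_config or default_panel_config())
        sex_dir = out_root / sex
        for sub in ("solutions", "biomarkers", "embeddings"):
            (sex_dir / sub).mkdir(parents=True, exist_ok=True)

        rows: list[dict] = []
        sex_solutions: dict[str, object] = {}
        for diet, name in zip(diets, diet_names):
            t0 = time.perf_counter()
            if diet is None:
                failed[(sex, name)] = [{"error": "diet file unparseable"}]
                continue
            constrained = apply_diet(model, diet, config.policy)
            sol = pfba(constrained, config.solver)
            if sol.status is not SolverStatus.OPTIMAL:
                diagnosis = (diagnose_infeasibility(constrained, config.solver)
                             if sol.status is SolverStatus.INFEASIBLE else [])
                failed[(sex, name)] = diagnosis
                log.warning("[%s/%s] %s; %d relaxations suggested",
                            sex, name, sol.status.value, len(diagnosis))
                continue
            solutions[(sex, name)] = sol
            sex_solutions[name] = sol
            sol.to_tsv(sex_dir / "solutions" / f"{name}.tsv")

            glc = secretion_uptake_totals(sol, panel.glucose_exchange)
            row = {
                "diet": name, "sex": sex,
                "glucose_secretion": glc["total_secretion"],
                "glucose_uptake": glc["total_uptake"],
                "glucose_net": glc["net"],
                "tag_synthesis": sum_flux(sol, panel.tag_synthesis),
                "ldl_hdl_ratio": ldl_hdl_ratio(sol, panel.ldl_exchange,
                                               panel.hdl_exchange),
                "fao": sum_flux(sol, panel.fao),
                "maintenance_flux": sol[model.maintenance_reaction_id],
                "kcal": sum(a * table.kcal_per_mmol(n)
                            for n, a in diet.entries.items() if n in table),
            }
            row.update({f"frac_{c}": v for c, v in
                        macronutrient_breakdown(diet, table).items()})
            rows.append(row)
            log.info("[%s/%s] optimal in %.2fs; residual %.2e", sex, name,
                     time.perf_counter() - t0, sol.max_mass_balance_residual)

        biomarker_rows[sex] = rows
        bdf = pd.DataFrame(rows)
        bdf.to_csv(sex_dir / "biomarkers" / "summary.tsv", sep="\t",
                   index=False, float_format="%.10g")

        if sex_solutions:
            by_organ = group_exchanges_by_organ(model, "glc_D")
            tbl = organ_contribution_table(sex_solutions, by_organ)
            tbl.to_tsv(sex_dir / "biomarkers" / "glucose_organ_table.tsv")
            organ_tables[sex] = tbl
            organ_roles[sex] = classify_organ_roles(tbl)
            (sex_dir / "biomarkers" / "glucose_organ_roles.json").write_text(
                json.dumps(organ_roles[sex], indent=1, sort_keys=True) + "\n")

            ok_diets = [d for d in diets if d and d.name in sex_solutions]
            if len(ok_diets) >= 2:
                M, feats, names = nutrient_matrix(ok_diets, table, "macro")
                pca(M, k=2, sample_names=names, feature_names=feats).to_tsv(
                    sex_dir / "embeddings" / "pca_macronutrients.tsv")
                try:
                    Mm, mfeats, names = nutrient_matrix(ok_diets, table, "micro")
                    pca(Mm, k=2, sample_names=names, feature_names=mfeats
                        ).to_tsv(sex_dir / "embeddings" / "pca_micronutrients.tsv")
                except Exception as exc:
                    log.warning("micronutrient PCA skipped: %s", exc)
            if len(sex_solutions) >= 4:
                F, cols, labels = flux_matrix(sex_solutions, "all_reactions")
                tsne_embed(F, seed=config.embedding_seed, sample_names=labels
                           ).to_tsv(sex_dir / "embeddings" / "tsne_fluxes_all.tsv")
                Fp, pcols, labels = flux_matrix(sex_solutions,
                                                "panel_reactions", panel=panel)
                tsne_embed(Fp, seed=config.embedding_seed, sample_names=labels
                           ).to_tsv(sex_dir / "embeddings" / "tsne_fluxes_panel.tsv")
        log.info("[%s] study finished in %.1fs", sex,
                 time.perf_counter() - t_sex)

    from . import __version__ as pkg_version

    provenance = {
        "package_version": pkg_version,
        "config_hash": config.content_hash(),
        "embedding_seed": config.embedding_seed,
        "policy": config.policy.mode.value,
        "force_fraction": config.policy.force_fraction,
        "maintenance_value": config.solver.maintenance_value,
        "n_cells_total": len(config.model_paths) * len(diet_files),
        "n_cells_solved": len(solutions),
        "failed_cells": sorted(f"{s}/{d}" for s, d in failed),
    }
    (out_root / "provenance.json").write_text(
        json.dumps(provenance, indent=1, sort_keys=True) + "\n")

    if not solutions:
        raise RuntimeError("every (sex, diet) cell failed")
    return StudyResult(solutions=solutions, biomarkers=biomarker_rows,
                       organ_tables=organ_tables, organ_roles=organ_roles,
                       failed=failed, output_dir=out_root)
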