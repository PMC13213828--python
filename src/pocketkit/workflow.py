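"""Four-stage workflow orchestration.

(A) define the binding-site region and plan/emit a masked-MSA ensemble;
(B) evaluate labeled docking score tables for every model;
(C) select the top ligand-enriching fraction of models (default 1%);
(D) report, with provenance, per-model metrics and — when reference
structures are supplied — site accuracy and plasticity summaries.

Stages run independently: structure prediction and docking happen in
external engines, possibly days apart, so the workflow executes the
stages whose inputs exist and logs a notice for each one it skips.
An ensemble of at least 250 models and ligand sets of at least 10
actives with 50 decoys per active are recommended; smaller inputs get
a warning, not an error.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import enrichment as enr
from . import msa as msa_mod
from . import site_metrics as sm
from . import structures as st

__all__ = ["WorkflowConfig", "RunReport", "validate_config", "run_workflow"]

log = logging.getLogger("pocketkit.workflow")

MIN_RECOMMENDED_MODELS = 250
MIN_RECOMMENDED_ACTIVES = 10
MIN_RECOMMENDED_DECOYS_PER_ACTIVE = 50


class ThresholdGrid(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min: float = 1.0
    max: float = 2.0
    step: float = 0.05

    def grid(self):
        return sm.default_thresholds(self.min, self.max, self.step)


class WorkflowConfig(BaseModel):
    """Validated, defaulted workflow configuration (strict about unknown keys)."""

    model_config = ConfigDict(extra="forbid", populate_by_name=True)

    receptor_id: str
    seed: int = 0
    out_dir: Path = Path("pocketkit_out")

    # stage A: masking / planning
    msa: Optional[Path] = None
    region: Optional[Path] = None
    levels: list[float] = [0.0, 0.1, 0.2, 0.3]
    per_level: int = 250
    states: list[str] = ["active", "inactive"]
    mask_char: str = "X"
    include_query: bool = False

    # site evaluation
    models_dir: Optional[Path] = None
    reference: Optional[Path] = None
    ligand_resname: Optional[str] = None
    site_cutoff: float = 5.0
    atom_class: str = "sidechain"
    thresholds: ThresholdGrid = ThresholdGrid()

    # enrichment / selection
    scores: Optional[Path] = None
    metric: str = "alogauc"
    top_fraction: float = 0.01
    lam: float = Field(default=enr.DEFAULT_LAMBDA, alias="lambda")

    @field_validator("levels")
    @classmethod
    def _normalise_levels(cls, v: list[float]) -> list[float]:
        if not v:
            raise ValueError("levels must be non-empty")
        if any(x > 1 for x in v):  # percent form, e.g. "0,10,20,30"
            v = [x / 100.0 for x in v]
        if any(not 0.0 <= x <= 1.0 for x in v):
            raise ValueError("masking levels must lie in [0, 1] (or percent form)")
        if len(set(v)) != len(v):
            raise ValueError("duplicate masking levels")
        return v

    @field_validator("top_fraction")
    @classmethod
    def _check_top_fraction(cls, v: float) -> float:
        if not 0.0 < v <= 1.0:
            raise ValueError("top_fraction must be in (0, 1]")
        return v

    @field_validator("metric")
    @classmethod
    def _check_metric(cls, v: str) -> str:
        if v not in {"alogauc", "ef1"}:
            raise ValueError("metric must be 'alogauc' or 'ef1'")
        return v

    @field_validator("atom_class")
    @classmethod
    def _check_atom_class(cls, v: str) -> str:
        if v not in {"sidechain", "backbone"}:
            raise ValueError("atom_class must be 'sidechain' or 'backbone'")
        return v

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(path: str | Path) -> WorkflowConfig:
    """Parse and schema-validate a YAML workflow config, filling defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return WorkflowConfig.model_validate(raw)


@dataclass
class RunReport:
    """Everything one workflow run produced, regenerable from inputs + config."""

    receptor_id: str
    stages_run: list[str] = field(default_factory=list)
    stages_skipped: dict[str, str] = field(default_factory=dict)
    manifest: Optional[dict[str, Any]] = None
    site_metrics: Optional[dict[str, Any]] = None
    enrichment: Optional[dict[str, Any]] = None
    selected_models: list[str] = field(default_factory=list)
    provenance: dict[str, Any] = field(default_factory=dict)
    timestamp: str = ""  # kept separate so reports are comparable without it

    def to_json(self) -> str:
        d = {k: v for k, v in self.__dict__.items()}
        return json.dumps(d, indent=2, default=str)


def _stage_masking(config: WorkflowConfig, report: RunReport) -> None:
    alignment = msa_mod.read_a3m(config.msa)
    region = msa_mod.load_region_file(config.region,
                                      query_length=alignment.n_match_columns)
    manifest = msa_mod.build_ensemble_manifest(
        receptor_id=config.receptor_id,
        levels=config.levels,
        per_level=config.per_level,
        states=config.states,
        base_seed=config.seed,
    )
    total = len(manifest)
    if total < MIN_RECOMMENDED_MODELS:
        log.warning(
            "stage=masking receptor=%s planned %d models; "
            ">= %d recommended for ensemble coverage",
            config.receptor_id, total, MIN_RECOMMENDED_MODELS,
        )
    masked_dir = config.out_dir / "masked_msas"
    masked_dir.mkdir(parents=True, exist_ok=True)
    (config.out_dir / "manifest.json").write_text(manifest.to_json())
    for entry in manifest.entries:
        plan = msa_mod.sample_mask(
            region, entry.masking_level, entry.seed,
            mask_char=config.mask_char, include_query=config.include_query,
        )
        masked = msa_mod.apply_mask(alignment, plan)
        stem = (f"{config.receptor_id}_p{int(round(entry.masking_level * 100)):02d}"
                f"_{entry.state}_r{entry.replicate:04d}")
        msa_mod.write_a3m(masked, masked_dir / f"{stem}.a3m")
        (masked_dir / f"{stem}.maskplan.json").write_text(plan.to_json())
    report.manifest = {
        "n_entries": total,
        "n_active": manifest.count(state="active"),
        "n_inactive": manifest.count(state="inactive"),
        "levels": config.levels,
        "masked_dir": str(masked_dir),
    }
    report.stages_run.append("masking")
    log.info("stage=masking receptor=%s entries=%d levels=%s",
             config.receptor_id, total, config.levels)


def _stage_site_eval(config: WorkflowConfig, report: RunReport) -> None:
    ref = st.read_structure(config.reference)
    if config.ligand_resname is None:
        raise ValueError("site evaluation requires ligand_resname in the config")
    ligand = ref.ligand_atoms(config.ligand_resname)
    site = st.binding_site(ref, ligand, cutoff=config.site_cutoff)
    model_paths = sorted(
        p for p in Path(config.models_dir).iterdir()
        if p.suffix.lower() in {".pdb", ".cif", ".mmcif"}
    )
    if not model_paths:
        raise ValueError(f"no structure files found in {config.models_dir}")
    models = [st.read_structure(p) for p in model_paths]
    rmsds = []
    for m in models:
        aligned = sm.align_to_reference(m, ref, site)
        r = sm.symmetry_rmsd(aligned, ref, site, atom_class=config.atom_class)
        rmsds.append(r)
    curve = sm.capture_curve(
        np.array([[r.value for r in rmsds]]), config.thresholds.grid()
    )
    rows = pd.DataFrame(
        {
            "model_id": [m.model_id for m in models],
            "rmsd": [r.value for r in rmsds],
            "naive_rmsd": [r.naive_value for r in rmsds],
            "n_atoms": [r.n_atoms for r in rmsds],
            "swaps": [r.swaps_applied for r in rmsds],
        }
    )
    config.out_dir.mkdir(parents=True, exist_ok=True)
    rows.to_csv(config.out_dir / "site_rmsd.csv", index=False)
    site_summary: dict[str, Any] = {
        "n_models": len(models),
        "site_residues": len(site),
        "atom_class": config.atom_class,
        "min_rmsd": float(min(r.value for r in rmsds)),
        "capture_auc": curve.auc,
    }
    if len(models) >= 2:
        profile = sm.ensemble_rmsf(models, site, atom_class=config.atom_class)
        pd.DataFrame(
            [
                {"chain": k[0], "res_id": k[1], "rmsf": v}
                for k, v in sorted(profile.per_residue.items())
            ]
        ).to_csv(config.out_dir / "site_rmsf.csv", index=False)
        site_summary["median_rmsf"] = profile.median
    report.site_metrics = site_summary
    report.stages_run.append("site_eval")
    log.info("stage=site_eval receptor=%s models=%d site=%d auc=%.3f",
             config.receptor_id, len(models), len(site), curve.auc)


def _stage_enrichment(config: WorkflowConfig, report: RunReport) -> None:
    df = pd.read_csv(config.scores)
    required = {"model_id", "compound_id", "score", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{config.scores}: missing columns {sorted(missing)}")
    if "receptor_id" in df.columns:
        receptors = set(df["receptor_id"].astype(str))
        if receptors - {config.receptor_id}:
            raise ValueError(
                f"score table receptor ids {sorted(receptors)} are inconsistent "
                f"with configured receptor {config.receptor_id!r}"
            )
    results = []
    for model_id, group in df.groupby("model_id", sort=True):
        table = enr.ScoreTable(
            records=[
                enr.ScoreRecord(str(i), float(s), str(l).strip().lower())
                for i, s, l in zip(group["compound_id"], group["score"],
                                   group["label"])
            ],
            model_id=str(model_id),
            receptor_id=config.receptor_id,
        )
        table.require_both_classes()
        if table.n_actives < MIN_RECOMMENDED_ACTIVES:
            log.warning("stage=enrichment model=%s only %d actives; >= %d recommended",
                        model_id, table.n_actives, MIN_RECOMMENDED_ACTIVES)
        if table.n_decoys < MIN_RECOMMENDED_DECOYS_PER_ACTIVE * table.n_actives:
            log.warning(
                "stage=enrichment model=%s %d decoys for %d actives; "
                ">= %d per active recommended",
                model_id, table.n_decoys, table.n_actives,
                MIN_RECOMMENDED_DECOYS_PER_ACTIVE,
            )
        results.append(enr.evaluate(table, lam=config.lam))
    selected, ranking = enr.rank_models(results, metric=config.metric,
                                        top_fraction=config.top_fraction)
    summary = enr.aggregate_receptors({config.receptor_id: results})
    config.out_dir.mkdir(parents=True, exist_ok=True)
    enr.results_dataframe(ranking).to_csv(config.out_dir / "enrichment.csv",
                                          index=False)
    rec = summary.per_receptor[0]
    report.enrichment = {
        "n_models": len(results),
        "metric": config.metric,
        "median_alogauc": rec.median_alogauc,
        "max_alogauc": rec.max_alogauc,
        "median_ef1": rec.median_ef1,
        "max_ef1": rec.max_ef1,
    }
    report.selected_models = [r.model_id for r in selected]
    report.stages_run.append("enrichment")
    log.info("stage=enrichment receptor=%s models=%d selected=%d",
             config.receptor_id, len(results), len(selected))


def run_workflow(config: WorkflowConfig) -> RunReport:
    """Execute the stages whose inputs are available, in order; emit a report."""
    from . import __version__

    report = RunReport(receptor_id=config.receptor_id)
    config.out_dir.mkdir(parents=True, exist_ok=True)

    if config.msa and config.region:
        for p in (config.msa, config.region):
            if not Path(p).exists():
                raise FileNotFoundError(f"masking input not found: {p}")
        _stage_masking(config, report)
    else:
        report.stages_skipped["masking"] = "no MSA/region supplied"
        log.info("stage=masking receptor=%s skipped (no MSA/region)",
                 config.receptor_id)

    if config.models_dir and config.reference:
        for p in (config.models_dir, config.reference):
            if not Path(p).exists():
                raise FileNotFoundError(f"site-evaluation input not found: {p}")
        _stage_site_eval(config, report)
    else:
        report.stages_skipped["site_eval"] = "no models/reference supplied"
        log.info("stage=site_eval receptor=%s skipped (no models/reference)",
                 config.receptor_id)

    if config.scores:
        if not Path(config.scores).exists():
            raise FileNotFoundError(f"score table not found: {config.scores}")
        _stage_enrichment(config, report)
    else:
        report.stages_skipped["enrichment"] = "no score table supplied"
        log.info("stage=enrichment receptor=%s skipped (no score table)",
                 config.receptor_id)

    report.provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }
    report.timestamp = datetime.now(timezone.utc).isoformat()
    (config.out_dir / "run_report.json").write_text(report.to_json())
    return report
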