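"""End-to-end pipeline: simulate -> preprocess -> rank -> enrich -> select.

Every stage consumes and produces documented tabular-text artifacts in one
output directory, so any stage can be rerun from its predecessor's files.
A run manifest (seed, thresholds, artifact digests) makes byte-identical
reproduction checkable: identical config plus seed gives identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .candidates import annotate_candidates, candidates_to_frame, consensus_targets, read_prediction_evidence
from .enrichment import EnrichmentReport, apply_report_filters, enrich_collection
from .fixtures import _data_path
from .qpcr import ExpressionMatrix, call_cq_table, interplate_calibrate, normalize_delta_cq, qc_spike_ins
from .ranking import RankedList, rank_differential
from .set_collections import filter_tissue_sets, read_gmt, restrict_to_universe
from .synthetic_data import (
    CurveParams,
    PlantedSet,
    SimulationConfig,
    make_default_layout,
    simulate_experiment,
)

logger = logging.getLogger(__name__)

ARTIFACTS = {
    "curves": "curves.tsv",
    "layout": "layout.tsv",
    "ground_truth": "ground_truth.tsv",
    "conditions": "conditions.tsv",
    "cq_records": "cq_records.tsv",
    "spike_qc": "spike_qc.tsv",
    "expression": "expression.tsv",
    "ranked": "ranked.tsv",
    "enrichment_report": "enrichment_report.tsv",
    "significance_table": "significance_table.tsv",
    "es_rank_table": "es_rank_table.tsv",
    "candidates": "candidates.tsv",
    "manifest": "manifest.json",
}


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; every field can come from a YAML file."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    permutations: int = 1000
    p_cut: float = 0.05
    abs_es_cut: float = 0.25
    min_tools: int = 2
    tissue_min_index: float = 0.7
    min_set_size: int = 2
    ranking_metric: str = "log2_fold_change"
    target_gene: str = "WWOX"
    gmt_path: str = ""  # empty -> packaged reference collection
    evidence_path: str = ""  # empty -> packaged WWOX prediction evidence
    simulate: bool = True
    plant_reference_sets: bool = True
    n_samples_per_condition: int = 3
    n_de_mirnas: int = 0
    de_effect_size: float = 2.0
    noise_sd: float = 0.1
    base_name_match: bool = True
    fdr_scope: str = "category"

    def resolved_gmt(self) -> Path:
        return Path(self.gmt_path) if self.gmt_path else _data_path("tables12_sets.gmt")

    def resolved_evidence(self) -> Path:
        return (
            Path(self.evidence_path)
            if self.evidence_path
            else _data_path("table3_wwox_predictions.tsv")
        )

    def validate(self) -> None:
        """Fail fast before any computation."""
        if not (0.0 <= self.p_cut <= 1.0):
            raise ValueError("p_cut must be in [0, 1]")
        if not (0.0 <= self.abs_es_cut <= 1.0):
            raise ValueError("abs_es_cut must be in [0, 1]")
        if not (0.0 <= self.tissue_min_index <= 1.0):
            raise ValueError("tissue_min_index must be in [0, 1]")
        if self.min_tools < 1 or self.min_set_size < 1 or self.permutations < 1:
            raise ValueError("min_tools, min_set_size and permutations must be >= 1")
        for p in (self.resolved_gmt(), self.resolved_evidence()):
            if not p.exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {unknown}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _apath(config: PipelineConfig, key: str) -> Path:
    return Path(config.out_dir) / ARTIFACTS[key]


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.8g")


def reference_planted_sets() -> tuple[PlantedSet, ...]:
    """Mutually direction-consistent planted sets mirroring the reference
    tables: all six top enriched sets plus the Apoptosis, Cell proliferation
    and DNA Repair functional sets (the AKT Pathway set is omitted: its
    positive ES conflicts with the negative sets sharing its members)."""
    from .fixtures import enriched_sets_as_results, functional_sets_as_results

    keep_functional = {"Apoptosis", "Cell proliferation", "DNA Repair"}
    planted = []
    for r in enriched_sets_as_results() + [
        r for r in functional_sets_as_results() if r.set_name in keep_functional
    ]:
        planted.append(
            PlantedSet(
                name=r.set_name,
                members=tuple(sorted(r.members)),
                direction="up" if r.es > 0 else "down",
            )
        )
    return tuple(planted)


def stage_simulate(config: PipelineConfig) -> dict[str, Path]:
    """Simulate the panel experiment and write raw-data artifacts."""
    layout = make_default_layout()
    planted = reference_planted_sets() if config.plant_reference_sets else ()
    sim_cfg = SimulationConfig(
        n_samples_per_condition=config.n_samples_per_condition,
        n_de_mirnas=config.n_de_mirnas,
        de_effect_size=config.de_effect_size,
        curve_params=CurveParams(noise_sd=config.noise_sd),
        planted_sets=planted,
        seed=config.seed,
    )
    exp = simulate_experiment(layout, sim_cfg)
    return exp.write(config.out_dir)


def stage_preprocess(config: PipelineConfig) -> dict[str, Path]:
    """Curves -> calibrated Cq records -> spike QC -> expression matrix."""
    curves = pd.read_csv(_apath(config, "curves"), sep="\t")
    cq = call_cq_table(curves)
    cq = interplate_calibrate(cq)
    qc = qc_spike_ins(cq)
    conditions = _read_conditions(config)
    matrix = normalize_delta_cq(cq, conditions)
    paths = {
        "cq_records": _apath(config, "cq_records"),
        "spike_qc": _apath(config, "spike_qc"),
        "expression": _apath(config, "expression"),
    }
    _write_tsv(cq, paths["cq_records"])
    _write_tsv(qc, paths["spike_qc"])
    _write_tsv(matrix.values.rename_axis("mirna"), paths["expression"], index=True)
    return paths


def _read_conditions(config: PipelineConfig) -> pd.Series:
    df = pd.read_csv(_apath(config, "conditions"), sep="\t")
    return pd.Series(df["condition"].to_numpy(), index=df["sample_id"], name="condition")


def _read_matrix(config: PipelineConfig) -> ExpressionMatrix:
    values = pd.read_csv(_apath(config, "expression"), sep="\t", index_col="mirna")
    conditions = _read_conditions(config)
    order = tuple(dict.fromkeys(conditions))
    return ExpressionMatrix(values=values, conditions=conditions, condition_order=order)


def stage_rank(config: PipelineConfig) -> dict[str, Path]:
    """Expression matrix -> ranked differential list."""
    ranked = rank_differential(_read_matrix(config), metric=config.ranking_metric)
    path = _apath(config, "ranked")
    path.parent.mkdir(parents=True, exist_ok=True)
    ranked.write(path)
    return {"ranked": path}


def _load_restricted_collection(config: PipelineConfig, ranked: RankedList):
    collection = read_gmt(config.resolved_gmt())
    collection = filter_tissue_sets(collection, min_index=config.tissue_min_index)
    return restrict_to_universe(collection, ranked.names, min_size=config.min_set_size)


def stage_enrich(config: PipelineConfig) -> dict[str, Path]:
    """Ranked list + set collection -> enrichment report and plot tables."""
    ranked = RankedList.read(_apath(config, "ranked"))
    collection = _load_restricted_collection(config, ranked)
    report = enrich_collection(
        ranked,
        collection,
        B=config.permutations,
        seed=config.seed,
        p_cut=config.p_cut,
        abs_es_cut=config.abs_es_cut,
        fdr_scope=config.fdr_scope,
    )
    paths = {
        "enrichment_report": _apath(config, "enrichment_report"),
        "significance_table": _apath(config, "significance_table"),
        "es_rank_table": _apath(config, "es_rank_table"),
    }
    _write_tsv(report.to_frame(), paths["enrichment_report"])
    _write_tsv(report.significance_table(), paths["significance_table"])
    _write_tsv(report.es_rank_table(), paths["es_rank_table"])
    return paths


def _report_from_file(config: PipelineConfig, ranked: RankedList) -> EnrichmentReport:
    """Rehydrate the enrichment report, restoring full set membership."""
    from .enrichment import EnrichmentResult

    df = pd.read_csv(_apath(config, "enrichment_report"), sep="\t")
    collection = _load_restricted_collection(config, ranked)
    members_of = {(s.category, s.name): s.members for s in collection}
    results = []
    for row in df.itertuples(index=False):
        leading = tuple(str(row.leading_members).split(",")) if isinstance(
            row.leading_members, str
        ) and row.leading_members else ()
        results.append(
            EnrichmentResult(
                set_name=row.set_name,
                category=row.category,
                es=float(row.es),
                nes=float(row.nes),
                p_nominal=float(row.p_nominal),
                fdr_q=float(row.fdr_q),
                set_size=int(row.set_size),
                peak_rank=int(row.peak_rank),
                leading_members=leading,
                members=members_of.get((row.category, row.set_name), frozenset()),
            )
        )
    return EnrichmentReport(
        results=results,
        p_cut=config.p_cut,
        abs_es_cut=config.abs_es_cut,
        permutations=config.permutations,
    )


def stage_select(config: PipelineConfig) -> dict[str, Path]:
    """Filtered report + prediction consensus -> candidate annotations."""
    ranked = RankedList.read(_apath(config, "ranked"))
    report = _report_from_file(config, ranked)
    filters = apply_report_filters(report, p_cut=config.p_cut, abs_es_cut=config.abs_es_cut)
    evidence = read_prediction_evidence(config.resolved_evidence())
    consensus = consensus_targets(evidence, config.target_gene, min_tools=config.min_tools)
    annotations = annotate_candidates(
        filters.retained, consensus, base_name_match=config.base_name_match
    )
    path = _apath(config, "candidates")
    _write_tsv(candidates_to_frame(annotations), path)
    return {"candidates": path}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run all stages, write every artifact and the run manifest.

    Raises with the failing stage named in the log; identical config and
    seed reproduce byte-identical artifacts (and hence manifest digests).
    """
    config.validate()
    Path(config.out_dir).mkdir(parents=True, exist_ok=True)
    stages = [
        ("simulate", stage_simulate),
        ("preprocess", stage_preprocess),
        ("rank", stage_rank),
        ("enrich", stage_enrich),
        ("select", stage_select),
    ]
    if not config.simulate:
        stages = stages[1:]
    artifact_paths: dict[str, Path] = {}
    for name, fn in stages:
        logger.info("pipeline stage: %s", name)
        try:
            artifact_paths.update(fn(config))
        except Exception:
            logger.error("pipeline stage %r failed", name)
            raise
    manifest = {
        "package": "mirsea",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "p_cut": config.p_cut,
            "abs_es_cut": config.abs_es_cut,
            "min_tools": config.min_tools,
            "tissue_min_index": config.tissue_min_index,
            "min_set_size": config.min_set_size,
        },
        "permutations": config.permutations,
        "artifacts": {
            k: {"path": str(p), "sha256": _sha256(p)} for k, p in sorted(artifact_paths.items())
        },
    }
    manifest_path = _apath(config, "manifest")
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
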