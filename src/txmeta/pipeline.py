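"""End-to-end orchestration: subset -> QC -> DE -> harmonize -> meta -> GSEA.

A validated :class:`PipelineConfig` (YAML-loadable) drives the run. Every
stochastic step draws its seed from the global seed through a counter-based
``numpy.random.SeedSequence`` expansion, so the whole run — and each stage
re-run from saved intermediates — is reproducible byte for byte.
"""

from __future__ import annotations

import json
import platform as _platform
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__, diffexpr, io, qc
from .enrich import RankedList, gsea, read_gmt, trim_sets
from .metamodel import harmonize, presence_filter, results_table, run_meta
from .synthdata import (
    CohortConfig,
    ExpressionStudy,
    StudyConfig,
    default_studies,
    generate_cohort,
    generate_ortholog_table,
)

__all__ = [
    "PipelineConfig",
    "subset_samples",
    "summarize_cohort",
    "run_pipeline",
    "simulate_stage",
    "qc_stage",
    "de_stage",
    "meta_stage",
    "gsea_stage",
]

# stage indices for counter-based seed expansion
_STAGE_SEEDS = {"simulate": 0, "qc": 1, "de": 2, "meta": 3, "gsea": 4}


def stage_seed(global_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence(global_seed, spawn_key=(_STAGE_SEEDS[stage],))
    return int(ss.generate_state(1)[0] % 2**31)


class SimulateSpec(BaseModel):
    n_genes: int = 2000
    effect_fraction: float = Field(0.1, ge=0.0, le=1.0)
    effect_mean: float = 0.5
    effect_sd: float = 0.2
    tau: float = Field(0.1, ge=0.0)
    missing_fraction_per_study: float = Field(0.1, ge=0.0, lt=1.0)
    ortholog_missing_fraction: float = Field(0.0, ge=0.0, le=1.0)


class StudySpec(BaseModel):
    study_id: str
    platform: Literal["intensity", "count"]
    species: Literal["mouse", "rat"]
    formula: Literal["eq1", "eq2"] = "eq2"
    expression_path: Optional[str] = None
    metadata_path: Optional[str] = None


class QCSpec(BaseModel):
    fence_multiplier: float = Field(1.5, gt=0.0)
    correlation: Literal["spearman", "pearson"] = "spearman"
    distinct_threshold: float = Field(0.70, gt=0.0, le=1.0)


class GSEASpec(BaseModel):
    gmt_path: Optional[str] = None
    n_perm: int = Field(1000, ge=100)
    stat: Literal["z", "estimate"] = "z"
    exclude_labels: list[str] = Field(default_factory=list)
    min_size: int = 10
    max_size: int = 1000


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; all thresholds are named here."""

    outdir: str
    seed: int = 0
    simulate: Optional[SimulateSpec] = None
    studies: list[StudySpec] = Field(default_factory=list)
    ortholog_path: Optional[str] = None
    organism_part: str = "PFC"
    qc: QCSpec = Field(default_factory=QCSpec)
    min_k: int = Field(4, ge=2)
    tau2_method: Literal["reml", "dl"] = "reml"
    fdr_threshold: float = Field(0.05, gt=0.0, lt=1.0)
    fdr_trend_threshold: float = Field(0.10, gt=0.0, lt=1.0)
    gsea: Optional[GSEASpec] = None

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        n_studies = len(self.studies) if self.studies else (
            len(default_studies()) if self.simulate is not None else 0
        )
        if n_studies == 0:
            raise ValueError("configure either 'simulate' or a 'studies' list")
        if self.min_k > n_studies:
            raise ValueError(
                f"min_k={self.min_k} exceeds the number of studies ({n_studies})"
            )
        if not self.simulate:
            for s in self.studies:
                if not s.expression_path or not s.metadata_path:
                    raise ValueError(f"{s.study_id}: expression/metadata paths required")
            if not self.ortholog_path:
                raise ValueError("ortholog_path required when not simulating")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


def subset_samples(
    study: ExpressionStudy,
    organism_part: str = "PFC",
    treatment_levels: tuple[str, ...] = ("reference", "ELS"),
) -> ExpressionStudy:
    """Restrict a study to the region of interest and treatment levels.

    Raises if the filter leaves no samples or empties a treatment group.
    """
    meta = study.metadata
    for col in ("organism_part", "treatment"):
        if col not in meta.columns:
            raise ValueError(f"{study.study_id}: metadata lacks column {col!r}")
    keep = meta["organism_part"].eq(organism_part) & meta["treatment"].isin(treatment_levels)
    if not keep.any():
        raise ValueError(f"{study.study_id}: subsetting removed every sample")
    sub = meta.loc[keep]
    present = set(sub["treatment"])
    missing = [lv for lv in treatment_levels if lv not in present]
    if missing:
        raise ValueError(f"{study.study_id}: treatment group(s) emptied: {missing}")
    return ExpressionStudy(
        study.study_id, study.platform, study.species,
        study.expression.loc[:, sub.index], sub.copy(),
    )


def summarize_cohort(manifest: pd.DataFrame) -> dict[str, int]:
    """Totals over a cohort manifest: final reference, ELS and overall n."""
    if len(manifest) == 0:
        return {"n_ref": 0, "n_els": 0, "n_total": 0}
    n_ref = int(manifest["n_ref_final"].sum())
    n_els = int(manifest["n_els_final"].sum())
    return {"n_ref": n_ref, "n_els": n_els, "n_total": n_ref + n_els}


def _load_study(spec: StudySpec, base: Path) -> ExpressionStudy:
    expr = io.read_expression(base / spec.expression_path)
    meta = io.read_metadata(base / spec.metadata_path)
    return ExpressionStudy(spec.study_id, spec.platform, spec.species, expr, meta)


def simulate_stage(config: PipelineConfig) -> dict:
    """Generate and persist the synthetic cohort (inputs for later stages)."""
    out = Path(config.outdir)
    indir = out / "input"
    indir.mkdir(parents=True, exist_ok=True)
    sim = config.simulate
    cohort_cfg = CohortConfig(
        n_genes=sim.n_genes,
        effect_fraction=sim.effect_fraction,
        effect_mean=sim.effect_mean,
        effect_sd=sim.effect_sd,
        tau=sim.tau,
        missing_fraction_per_study=sim.missing_fraction_per_study,
        seed=stage_seed(config.seed, "simulate"),
    )
    studies, truth = generate_cohort(cohort_cfg)
    ortholog = generate_ortholog_table(
        truth, sim.ortholog_missing_fraction, seed=stage_seed(config.seed, "simulate")
    )
    specs = []
    for study, scfg in zip(studies, cohort_cfg.studies):
        io.write_expression(study.expression, indir / f"{study.study_id}_expression.tsv")
        io.write_metadata(study.metadata, indir / f"{study.study_id}_metadata.tsv")
        specs.append(
            StudySpec(
                study_id=study.study_id,
                platform=study.platform,
                species=study.species,
                formula="eq1" if scfg.covariates else "eq2",
                expression_path=f"input/{study.study_id}_expression.tsv",
                metadata_path=f"input/{study.study_id}_metadata.tsv",
            )
        )
    io.write_ortholog_table(ortholog, indir / "ortholog.tsv")
    truth.genes.to_csv(indir / "truth_genes.tsv", sep="\t")
    truth.realized.to_csv(indir / "truth_realized.tsv", sep="\t")
    truth.presence.to_csv(indir / "truth_presence.tsv", sep="\t")
    return {"studies": specs, "ortholog_path": "input/ortholog.tsv", "truth": truth}


def qc_stage(config: PipelineConfig, studies: list[ExpressionStudy]) -> tuple[list[ExpressionStudy], pd.DataFrame]:
    """Per-study QC: gene filter, correlation outlier flagging, removal.

    Returns the cleaned studies and the cohort manifest.
    """
    cleaned = []
    manifest_rows = []
    out = Path(config.outdir)
    qcdir = out / "qc"
    qcdir.mkdir(parents=True, exist_ok=True)
    for study in studies:
        sub = subset_samples(study, config.organism_part)
        expr, removal_log = qc.filter_genes(sub.expression, config.qc.distinct_threshold)
        log_mat = (
            diffexpr.log2_cpm(expr, sub.metadata["library_size"])
            if study.platform == "count"
            else expr
        )
        report = qc.sample_correlations(log_mat, method=config.qc.correlation)
        report = qc.detect_outliers(report, config.qc.fence_multiplier)
        kept = [s for s in expr.columns if s not in set(report.flags)]
        meta = sub.metadata.loc[kept]
        cleaned.append(
            ExpressionStudy(study.study_id, study.platform, study.species,
                            expr.loc[:, kept], meta)
        )
        manifest_rows.append(
            {
                "study_id": study.study_id,
                "platform": study.platform,
                "species": study.species,
                "n_total": sub.expression.shape[1],
                "n_outliers_removed": len(report.flags),
                "n_ref_final": int((meta["treatment"] == "reference").sum()),
                "n_els_final": int((meta["treatment"] == "ELS").sum()),
            }
        )
        removal_log.to_csv(qcdir / f"{study.study_id}_gene_filter.tsv", sep="\t", index=False)
        io.write_json(
            {
                "study_id": study.study_id,
                "correlation": config.qc.correlation,
                "fence_multiplier": config.qc.fence_multiplier,
                "flagged_samples": report.flags,
                "n_genes_removed": int(len(removal_log)),
            },
            qcdir / f"{study.study_id}_qc.json",
        )
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return cleaned, manifest


def de_stage(config: PipelineConfig, studies: list[ExpressionStudy]) -> dict[str, pd.DataFrame]:
    """Per-study differential expression; writes one DE TSV per study."""
    out = Path(config.outdir)
    dedir = out / "de"
    dedir.mkdir(parents=True, exist_ok=True)
    formulas = {s.study_id: s.formula for s in config.studies}
    results = {}
    for study in studies:
        table = diffexpr.run_de(
            study.expression, study.metadata, study.platform,
            formula_spec=formulas.get(study.study_id, "eq2"),
        )
        io.write_de_results(table, dedir / f"{study.study_id}_de.tsv")
        results[study.study_id] = table
    return results


def meta_stage(
    config: PipelineConfig,
    de_results: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Harmonize, presence-filter, fit the random-effects model, BH-adjust.

    When ``de_results`` is omitted the stage reloads the saved DE TSVs, so
    it can be re-run from intermediates.
    """
    out = Path(config.outdir)
    base = Path(config.outdir)
    if de_results is None:
        de_results = {
            s.study_id: io.read_de_results(out / "de" / f"{s.study_id}_de.tsv")
            for s in config.studies
        }
    ortholog = io.read_ortholog_table(base / config.ortholog_path)
    species = {s.study_id: s.species for s in config.studies}
    effects, drop_log = harmonize(de_results, ortholog, species)
    effects = presence_filter(effects, config.min_k)
    table, unstable = run_meta(effects, tau2_method=config.tau2_method, ortholog=ortholog)
    drop_log.to_csv(out / "harmonize_drop_log.tsv", sep="\t", index=False)
    (out / "unstable_genes.txt").write_text("\n".join(unstable) + ("\n" if unstable else ""))
    results_table(
        table, out / "meta_results.tsv",
        fdr_significant=config.fdr_threshold, fdr_trend=config.fdr_trend_threshold,
    )
    return table


def gsea_stage(config: PipelineConfig, meta_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Preranked GSEA over the meta-analysis table; writes the result TSV."""
    out = Path(config.outdir)
    if meta_table is None:
        meta_table = pd.read_csv(out / "meta_results.tsv", sep="\t", index_col=0,
                                float_precision="round_trip")
        meta_table.index = meta_table.index.astype(str)
    spec = config.gsea
    ranked = RankedList.from_meta(meta_table, stat=spec.stat)
    collection = read_gmt(Path(config.outdir) / spec.gmt_path
                          if not Path(spec.gmt_path).is_absolute() else spec.gmt_path)
    collection = trim_sets(
        collection,
        exclude_labels=tuple(spec.exclude_labels),
        min_size=spec.min_size,
        max_size=spec.max_size,
        background=set(ranked.genes),
    )
    table = gsea(ranked, collection, n_perm=spec.n_perm,
                 seed=stage_seed(config.seed, "gsea"))
    table.to_csv(out / "gsea_results.tsv", sep="\t", index=False)
    return table


def run_pipeline(config: PipelineConfig | dict | str | Path) -> dict:
    """Run every configured stage in order and return the results bundle."""
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig.model_validate(config)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.simulate is not None:
        sim = simulate_stage(config)
        config = config.model_copy(
            update={"studies": sim["studies"], "ortholog_path": sim["ortholog_path"]}
        )
        truth = sim["truth"]

    base = Path(config.outdir)
    studies = [_load_study(s, base) for s in config.studies]
    cleaned, manifest = qc_stage(config, studies)
    de_results = de_stage(config, cleaned)
    meta_table = meta_stage(config, de_results)
    gsea_table = None
    if config.gsea is not None and config.gsea.gmt_path:
        gsea_table = gsea_stage(config, meta_table)

    totals = summarize_cohort(manifest)
    metadata = {
        "txmeta_version": __version__,
        "python_version": _platform.python_version(),
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "stage_seeds": {k: stage_seed(config.seed, k) for k in _STAGE_SEEDS},
        "tau2_method": config.tau2_method,
        "min_k": config.min_k,
        "cohort_totals": totals,
        "config": json.loads(config.model_dump_json()),
    }
    io.write_json(metadata, out / "run_metadata.json")
    return {
        "config": config,
        "manifest": manifest,
        "totals": totals,
        "de": de_results,
        "meta": meta_table,
        "gsea": gsea_table,
        "truth": truth,
        "outdir": out,
    }
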