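"""End-to-end orchestration: simulate/load -> filter -> DE -> signatures ->
stability curves -> enrichment -> survival screen, driven by one config.

Every stage writes a self-describing TSV to the output directory and the
run ends with a machine-readable ``summary.json``.  The whole run is a
pure function of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import consensus, de, enrichment, isoforms, survival
from .io import (
    harmonize_samples,
    read_clinical,
    read_expression,
    read_feature_map,
    read_gmt,
)
from .simulate import SyntheticConfig, generate_cohort, synthetic_gene_sets, write_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of a full run; defaults follow the study design."""

    # inputs: either file paths or a simulate block
    gene_expression: str | None = None
    isoform_expression: str | None = None
    clinical: str | None = None
    feature_map: str | None = None
    gene_sets: str | None = None
    simulate: SyntheticConfig | None = None

    # thresholds
    tpm_threshold: float = 0.001
    fc_min: float = 2.0
    fdr_max: float = 0.001
    enrichment_fdr: float = 0.05
    survival_fdr: float = 0.05
    filter_genes: bool = True

    # cohort split
    discovery_stages: tuple[str, str] = ("I", "IV")
    validation_stages: tuple[str, ...] = ("II", "III")

    # stability block
    n_resamples: int = 500
    resample_fraction: float = 0.8
    engines: tuple[str, ...] = ("hierarchical", "kmeans")
    signature_grid: tuple[int, ...] = tuple(range(20, 221, 20))

    seed: int = 0
    output_dir: str = "stagesig_run"

    def validate(self) -> None:
        if min(self.tpm_threshold, self.fc_min, self.fdr_max,
               self.enrichment_fdr, self.survival_fdr) <= 0:
            raise ValueError("thresholds must be positive")
        if not self.signature_grid:
            raise ValueError("signature grid must be non-empty")
        if list(self.signature_grid) != sorted(self.signature_grid):
            raise ValueError("signature grid must be ascending")
        if self.simulate is None and not (self.gene_expression and self.clinical):
            raise ValueError("either a simulate block or input paths are required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if sim is not None:
            cfg.simulate = SyntheticConfig(**sim)
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the summary dict (also written
    as ``summary.json``)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "parameters": _params_dict(config)}
    stage = "load"
    try:
        # ------------------------------------------------------------ load
        if config.simulate is not None:
            cohort = generate_cohort(config.simulate)
            write_cohort(cohort, out / "cohort")
            gene, iso, clinical, fmap = (
                cohort.gene, cohort.isoform, cohort.clinical, cohort.feature_map
            )
            gene_sets = (
                read_gmt(config.gene_sets) if config.gene_sets
                else synthetic_gene_sets(cohort.truth, seed=config.seed)
            )
        else:
            gene = read_expression(config.gene_expression, "gene")
            clinical = read_clinical(config.clinical)
            iso = (read_expression(config.isoform_expression, "isoform")
                   if config.isoform_expression else None)
            fmap = read_feature_map(config.feature_map) if config.feature_map else None
            gene_sets = read_gmt(config.gene_sets) if config.gene_sets else None
        gene, clinical = harmonize_samples(gene, clinical)
        if iso is not None:
            iso, _ = harmonize_samples(iso, clinical)
        run_isoform = iso is not None and fmap is not None
        if not run_isoform:
            logger.info("isoform matrix or map absent: gene-level analysis only")

        early, late = config.discovery_stages
        disc = clinical.stage_subset([early, late])
        disc_samples = disc.sample_ids
        disc_labels = disc.stages().to_numpy()
        summary["n_discovery"] = {early: int((disc_labels == early).sum()),
                                  late: int((disc_labels == late).sum())}

        # ---------------------------------------------------------- filter
        stage = "filter"
        gene_disc = gene.subset_samples(disc_samples)
        if config.filter_genes:
            gene_disc = isoforms.filter_expressed_isoforms(
                gene_disc, disc, threshold=config.tpm_threshold,
                groups=config.discovery_stages,
            )
        if run_isoform:
            iso_disc = isoforms.filter_expressed_isoforms(
                iso.subset_samples(disc_samples), disc,
                threshold=config.tpm_threshold, groups=config.discovery_stages,
            )
            summary["n_isoforms_filtered"] = iso_disc.n_features
        summary["n_genes_filtered"] = gene_disc.n_features

        # --------------------------------------------- isoform structure
        if run_isoform:
            stage = "isoform_structure"
            ratios = isoforms.major_isoform_ratios(
                iso_disc, gene.subset_samples(disc_samples), fmap
            )
            ratios.per_gene.to_csv(out / "major_isoform_ratios.tsv", sep="\t",
                                   float_format="%.6g")
            summary["major_isoform_ratio"] = ratios.summaries
            frac = isoforms.expressed_isoform_fraction(iso_disc, fmap,
                                                       threshold=config.tpm_threshold)
            if frac is not None:
                summary["mean_expressed_isoform_fraction"] = float(frac.mean())

        # ------------------------------------------------------------- DE
        stage = "differential_expression"
        log_gene = de.log_transform(gene_disc)
        de_gene = de.moderated_t(log_gene, disc_labels, early=early, late=late,
                                 level="gene")
        de.write_de_table(de_gene, out / "de_gene.tsv")
        gene_sigs = de.select_signatures(de_gene, config.fc_min, config.fdr_max)
        de.write_signatures(gene_sigs, out / "signatures_gene.tsv")
        summary["n_gene_signatures"] = len(gene_sigs)

        if run_isoform:
            log_iso = de.log_transform(iso_disc)
            de_iso = de.moderated_t(log_iso, disc_labels, early=early, late=late,
                                    level="isoform")
            de.write_de_table(de_iso, out / "de_isoform.tsv")
            iso_sigs = de.select_signatures(de_iso, config.fc_min, config.fdr_max)
            de.write_signatures(iso_sigs, out / "signatures_isoform.tsv")
            summary["n_isoform_signatures"] = len(iso_sigs)

            combined = de.combine_signatures(gene_sigs, iso_sigs, fmap)
            de.write_signatures(combined, out / "signatures_combined.tsv")
            summary["n_combined_signatures"] = len(combined)
            summary["provenance_counts"] = (
                combined.table["provenance"].value_counts().to_dict()
            )
            switches = de.detect_switches(iso_sigs, fmap)
            summary["switch_genes"] = switches
            summary["n_switch_genes"] = len(switches)
            summary["overlap"] = de.signature_overlap(gene_sigs, iso_sigs, fmap)

        # ------------------------------------------------------ stability
        stage = "stability"
        curves = []
        sources = {"gene": (gene_sigs, log_gene)}
        if run_isoform:
            sources["isoform"] = (iso_sigs, log_iso)
            combined_expr = de.log_transform(_stack_levels(gene_disc, iso_disc))
            sources["combined"] = (combined, combined_expr)
        for name, (sigs, log_expr) in sources.items():
            ranked = de.rank_signatures(sigs)
            if not ranked:
                logger.warning("no %s signatures: stability curve skipped", name)
                continue
            curve = consensus.stability_curve(
                ranked, log_expr, disc_labels, config.signature_grid,
                engines=config.engines, n_resamples=config.n_resamples,
                fraction=config.resample_fraction, seed=config.seed, source=name,
            )
            curves.append(curve)
        if curves:
            import pandas as pd

            curve_tab = pd.concat(curves, ignore_index=True)
            curve_tab.to_csv(out / "stability_curves.tsv", sep="\t", index=False,
                             float_format="%.6g")
            summary["stability"] = curve_tab.to_dict(orient="records")

        # ----------------------------------------------------- enrichment
        if gene_sets is not None and run_isoform:
            stage = "enrichment"
            universe = enrichment.map_to_genes(
                list(gene_disc.feature_ids) + list(iso_disc.feature_ids), fmap
            )
            enr_tables = {}
            for name, sigs in (("gene", gene_sigs), ("isoform", iso_sigs),
                               ("combined", combined)):
                sig_genes = enrichment.map_to_genes(sigs.feature_ids, fmap)
                if not sig_genes:
                    continue
                tab = enrichment.hypergeom_enrich(
                    sig_genes, universe, gene_sets, fdr_max=config.enrichment_fdr
                )
                tab.to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False,
                           float_format="%.6g")
                enr_tables[name] = int(tab["selected"].sum()) if len(tab) else 0
            summary["n_enriched_sets"] = enr_tables

        # ------------------------------------------------------- survival
        stage = "survival"
        validation = clinical.stage_subset(config.validation_stages)
        if len(validation.sample_ids) >= 4 and validation.data["event"].fillna(0).sum() > 0:
            screens = {}
            gene_feats = [f for f in gene_sigs.feature_ids if f in set(gene.feature_ids)]
            if gene_feats:
                scr = survival.survival_screen(
                    gene, clinical, features=gene_feats,
                    fdr_max=config.survival_fdr, stages=config.validation_stages,
                )
                scr.to_csv(out / "survival_gene.tsv", sep="\t", float_format="%.6g")
                screens["gene"] = int(scr["selected"].sum())
            if run_isoform and len(iso_sigs):
                scr = survival.survival_screen(
                    iso, clinical, features=iso_sigs.feature_ids,
                    fdr_max=config.survival_fdr, stages=config.validation_stages,
                )
                scr.to_csv(out / "survival_isoform.tsv", sep="\t", float_format="%.6g")
                screens["isoform"] = int(scr["selected"].sum())
            summary["n_prognostic"] = screens
        else:
            logger.info("no usable validation cohort: survival screen skipped")

    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(_jsonable(summary), indent=2, sort_keys=True))
    logger.info("pipeline complete; summary at %s", summary_path)
    return summary


def _stack_levels(gene, iso):
    """Row-stack gene and isoform matrices over the shared samples."""
    import pandas as pd

    from .io import ExpressionMatrix

    stacked = pd.concat([gene.data, iso.data])
    return ExpressionMatrix(stacked, "isoform")


def _params_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
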