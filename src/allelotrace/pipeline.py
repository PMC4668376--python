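"""End-to-end orchestration: load -> control filter -> classify -> summarize
-> depth/SC filter -> cluster -> ASE -> DPRE -> prioritize.

Outputs are deterministic (fixed column orders, fixed float formatting, no
timestamps): two runs with the same config and seed produce byte-identical
files.  The run manifest records the config, the seed, per-stage record
counts and the package version, and suffices to re-execute the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .af_clustering import assign_clusters, cluster_af_summary
from .allelic_evidence import FilterConfig, apply_filters, remove_nonref_control
from .ase_dpre import ase_table, compare_dpre_groups, compute_dpre
from .expression_classify import (
    PresenceRule,
    classify_patterns,
    cross_level_identification,
    summarize_patterns,
)
from .io_formats import (
    read_allele_counts,
    read_expression_table,
    read_gene_list,
    read_mutation_table,
    write_driver_report,
    write_site_report,
)
from .prioritize import prioritize_drivers

logger = logging.getLogger("allelotrace")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    mutations: str
    rna_counts: str
    protein_counts: str
    rna_expression: str
    protein_expression: str
    out_dir: str
    germline_genes: Optional[str] = None
    driver_genes: Optional[str] = None
    pathway_genes: Optional[str] = None
    mutation_format: str = "tsv"
    filters: FilterConfig = field(default_factory=FilterConfig)
    presence: PresenceRule = field(default_factory=PresenceRule)
    fdr: float = 0.05
    af_floor: float = 0.1
    fc_sentinel: float = 10.0
    seed: int = 0
    em_tol: float = 1e-8
    em_max_iter: int = 500
    equal_variance: bool = False

    def __post_init__(self):
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")
        if not 0 <= self.af_floor <= 1:
            raise ValueError("af_floor must lie in [0, 1]")
        if self.fc_sentinel <= 0:
            raise ValueError("fc_sentinel must be > 0")

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class PipelineResult:
    patterns: list
    filtered_patterns: list
    summary: object
    mixture_fit: object
    ase: pd.DataFrame
    dpre: pd.DataFrame
    dpre_exclusions: pd.DataFrame
    group_comparison: pd.DataFrame
    candidates: list
    manifest: dict


def _check_site_keys(records, rna_counts, protein_counts) -> None:
    known = {(r.site.chrom, r.site.pos) for r in records}
    orphans = sorted(
        (rna_counts.site_keys() | protein_counts.site_keys()) - known
    )
    if orphans:
        shown = ", ".join(f"{c}:{p}" for c, p in orphans[:10])
        raise ValueError(
            f"{len(orphans)} count-table site(s) not in the mutation table: {shown}"
        )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_manifest(),
        "package_version": __version__,
        "stages": {},
    }

    def stage(name, **counts):
        logger.info("stage %s: %s", name, counts)
        manifest["stages"][name] = counts

    try:
        records = read_mutation_table(config.mutations, format=config.mutation_format)
        rna_counts = read_allele_counts(config.rna_counts, "RNA")
        protein_counts = read_allele_counts(config.protein_counts, "PROTEIN")
        rna_expr = read_expression_table(config.rna_expression, "RNA")
        protein_expr = read_expression_table(config.protein_expression, "PROTEIN")
        germline = read_gene_list(config.germline_genes) if config.germline_genes else set()
        drivers = read_gene_list(config.driver_genes) if config.driver_genes else set()
        pathways = read_gene_list(config.pathway_genes) if config.pathway_genes else set()
        _check_site_keys(records, rna_counts, protein_counts)
        stage("load", n_sites=len(records),
              n_rna_rows=len(rna_counts.frame), n_protein_rows=len(protein_counts.frame))
    except Exception as exc:
        raise RuntimeError(f"stage load failed: {exc}") from exc

    try:
        kept, removed = remove_nonref_control(
            records, rna_counts, min_alt_reads=config.presence.min_alt_reads
        )
        stage("remove_nonref_control", n_kept=len(kept), n_removed=len(removed))
    except Exception as exc:
        raise RuntimeError(f"stage remove_nonref_control failed: {exc}") from exc

    try:
        patterns = classify_patterns(
            kept, rna_counts, protein_counts, rna_expr, protein_expr, config.presence
        )
        summary = summarize_patterns(patterns)
        cross = cross_level_identification(patterns)
        stage(
            "classify",
            n_patterns=len(patterns),
            transcribed_n=summary.transcribed_n,
            protein_identified_n=summary.protein_identified_n,
            translated_n=summary.translated_n,
            transcription_counts=summary.transcription_counts,
            cross_level=cross,
        )
    except Exception as exc:
        raise RuntimeError(f"stage classify failed: {exc}") from exc

    try:
        filtered_records, dropped = apply_filters(
            kept, rna_counts, protein_counts, config.filters
        )
        filtered_keys = {r.site.key for r in filtered_records}
        filtered_patterns = [p for p in patterns if p.site.key in filtered_keys]
        stage("filter", n_pass=len(filtered_records), n_fail=len(dropped))
    except Exception as exc:
        raise RuntimeError(f"stage filter failed: {exc}") from exc

    try:
        filtered_patterns, fit = assign_clusters(
            filtered_patterns,
            seed=config.seed,
            tol=config.em_tol,
            max_iter=config.em_max_iter,
            equal_variance=config.equal_variance,
        )
        cluster_counts = pd.Series(
            [p.cluster for p in filtered_patterns]
        ).value_counts().to_dict() if filtered_patterns else {}
        stage("cluster", cluster_counts=cluster_counts)
    except Exception as exc:
        raise RuntimeError(f"stage cluster failed: {exc}") from exc

    try:
        ase = ase_table(kept, rna_counts, protein_counts)
        stage("ase", n_tests=len(ase),
              n_significant=int((ase["q_value"] < config.fdr).sum()))
    except Exception as exc:
        raise RuntimeError(f"stage ase failed: {exc}") from exc

    try:
        somatic = {r.site.gene for r in kept}
        dpre, excl = compute_dpre(
            rna_expr, protein_expr, somatic, germline, sentinel=config.fc_sentinel
        )
        comparison = compare_dpre_groups(dpre)
        stage("dpre", n_records=len(dpre), n_excluded=len(excl),
              n_genes=int(dpre["gene"].nunique()) if len(dpre) else 0)
    except Exception as exc:
        raise RuntimeError(f"stage dpre failed: {exc}") from exc

    try:
        # cluster-labelled patterns take precedence in the merged site report
        by_key = {p.site.key: p for p in filtered_patterns}
        merged = [by_key.get(p.site.key, p) for p in patterns]
        candidates = prioritize_drivers(
            merged, ase, drivers, pathways, fdr=config.fdr, af_floor=config.af_floor
        )
        stage("prioritize", n_candidates=len(candidates))
    except Exception as exc:
        raise RuntimeError(f"stage prioritize failed: {exc}") from exc

    # ---- outputs ---------------------------------------------------------
    write_site_report(out / "site_report.tsv", merged)
    cluster_af_summary(filtered_patterns).to_csv(
        out / "cluster_af_summary.tsv", sep="\t", index=False, float_format="%.6g"
    )
    if fit is not None:
        (out / "mixture_fit.json").write_text(fit.to_json() + "\n")
    ase.to_csv(out / "ase_table.tsv", sep="\t", index=False, float_format="%.6g")
    dpre.to_csv(out / "dpre_records.tsv", sep="\t", index=False, float_format="%.6g")
    excl.to_csv(out / "dpre_exclusions.tsv", sep="\t", index=False)
    comparison.to_csv(
        out / "dpre_group_comparison.tsv", sep="\t", index=False, float_format="%.6g"
    )
    write_driver_report(out / "driver_report.tsv", candidates)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")

    return PipelineResult(
        patterns=merged,
        filtered_patterns=filtered_patterns,
        summary=summary,
        mixture_fit=fit,
        ase=ase,
        dpre=dpre,
        dpre_exclusions=excl,
        group_comparison=comparison,
        candidates=candidates,
        manifest=manifest,
    )
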