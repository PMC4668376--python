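"""Transcription / translation status of each somatic site.

A tumor-mutated allele counts as *transcribed* when the site's tumor RNA shows
the mutant allele (heterozygous or alternative homozygous), and as *translated*
when an allele-discriminating mutant peptide is observed in the tumor but not
in the control tissue.  Absence of coverage is tracked separately from absence
of the allele at every level.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

from .allelic_evidence import compute_af
from .io_formats import (
    AlleleCountTable,
    ExpressionTable,
    MutationSite,
    SiteRecord,
)

__all__ = [
    "TRANSCRIPTION_STATUSES",
    "TRANSLATION_STATUSES",
    "PresenceRule",
    "SitePattern",
    "PatternSummary",
    "classify_transcription",
    "classify_translation",
    "classify_patterns",
    "summarize_patterns",
    "unexpressed_lower_bound",
    "cross_level_identification",
    "gene_rollup",
]

TRANSCRIPTION_STATUSES = (
    "GENE_NOT_EXPRESSED", "SITE_NOT_COVERED", "WT_ONLY", "BOTH", "MUT_ONLY",
)
TRANSLATION_STATUSES = (
    "GENE_NO_SPECTRUM", "SITE_NOT_COVERED", "WT_ONLY", "BOTH", "MUT_ONLY",
)


@dataclass(frozen=True)
class PresenceRule:
    """Evidence needed to call an allele present.

    RNA presence requires >= 2 supporting reads by default (a guard against
    sequencing error at depth-limited sites); protein presence requires a
    single spectral count, since mutant peptides pass their own FDR control in
    the upstream search.
    """

    min_alt_reads: int = 2
    min_alt_sc: int = 1

    def __post_init__(self):
        if self.min_alt_reads < 1 or self.min_alt_sc < 1:
            raise ValueError("presence thresholds must be >= 1")


@dataclass(frozen=True)
class SitePattern:
    """Per-site expression pattern with AFs, depths and (optional) cluster."""

    site: MutationSite
    transcription: str
    translation: str
    mut_in_control_protein: bool = False
    cluster: Optional[str] = None
    af_dna: Optional[float] = None
    af_rna: Optional[float] = None
    af_protein: Optional[float] = None
    dp_dna: Optional[int] = None
    dp_rna: Optional[int] = None
    sc_total: Optional[int] = None

    @property
    def mutant_transcribed(self) -> bool:
        return self.transcription in ("BOTH", "MUT_ONLY")

    @property
    def mutant_translated(self) -> bool:
        """Tumor-specific mutant protein evidence (absent from control)."""
        return (
            self.translation in ("BOTH", "MUT_ONLY")
            and not self.mut_in_control_protein
        )

    @property
    def protein_identified(self) -> bool:
        """Site covered by allele-discriminating peptides, tumor-specific."""
        return (
            self.translation in ("WT_ONLY", "BOTH", "MUT_ONLY")
            and not self.mut_in_control_protein
        )


def classify_transcription(
    record: SiteRecord,
    rna_counts: AlleleCountTable,
    rna_expr: ExpressionTable,
    rule: PresenceRule = PresenceRule(),
) -> str:
    """Transcription status of the site in tumor RNA (replicates combined)."""
    site = record.site
    tumor_total = rna_expr.tumor_total(site.gene)
    if tumor_total is None:
        raise KeyError(f"no RNA expression record for gene {site.gene!r}")
    if tumor_total == 0:
        return "GENE_NOT_EXPRESSED"
    counts = rna_counts.combined(site.chrom, site.pos, "tumor")
    if counts is None or counts.total == 0:
        return "SITE_NOT_COVERED"
    wt = counts.ref_count >= rule.min_alt_reads
    mut = counts.alt_count >= rule.min_alt_reads
    if not wt and not mut:
        return "SITE_NOT_COVERED"
    if wt and mut:
        return "BOTH"
    return "MUT_ONLY" if mut else "WT_ONLY"


def classify_translation(
    record: SiteRecord,
    protein_counts: AlleleCountTable,
    protein_expr: ExpressionTable,
    rule: PresenceRule = PresenceRule(),
) -> tuple:
    """(translation status, mutant-seen-in-control flag).

    Gene-level "no spectrum" is decided on the union of both MS replicates via
    the gene's protein abundance; a site with its own spectra is always
    classified from those counts.  The control flag marks sites whose mutant
    peptide also appears in the control tissue — such sites are not counted as
    tumor mutated-amino-acid identifications downstream.
    """
    site = record.site
    counts = protein_counts.combined(site.chrom, site.pos, "tumor")
    control = protein_counts.combined(site.chrom, site.pos, "control")
    mut_in_control = control is not None and control.alt_count >= rule.min_alt_sc
    if counts is None or counts.total == 0:
        abundance = protein_expr.tumor_total(site.gene)
        if abundance is None or abundance == 0:
            return "GENE_NO_SPECTRUM", mut_in_control
        return "SITE_NOT_COVERED", mut_in_control
    wt = counts.ref_count >= rule.min_alt_sc
    mut = counts.alt_count >= rule.min_alt_sc
    if not wt and not mut:
        return "SITE_NOT_COVERED", mut_in_control
    if wt and mut:
        return "BOTH", mut_in_control
    return ("MUT_ONLY" if mut else "WT_ONLY"), mut_in_control


def classify_patterns(
    records: Iterable[SiteRecord],
    rna_counts: AlleleCountTable,
    protein_counts: AlleleCountTable,
    rna_expr: ExpressionTable,
    protein_expr: ExpressionTable,
    rule: PresenceRule = PresenceRule(),
) -> list:
    """Build the full SitePattern (statuses, AFs, tumor depths) per site."""
    patterns = []
    for rec in records:
        site = rec.site
        tx = classify_transcription(rec, rna_counts, rna_expr, rule)
        tl, mut_in_control = classify_translation(rec, protein_counts, protein_expr, rule)
        dna = rec.dna.get("tumor")
        rna = rna_counts.combined(site.chrom, site.pos, "tumor")
        prot = protein_counts.combined(site.chrom, site.pos, "tumor")
        af_dna = compute_af(dna).value if dna is not None else None
        af_rna = compute_af(rna).value if rna is not None else None
        af_protein = compute_af(prot).value if prot is not None else None
        patterns.append(SitePattern(
            site=site,
            transcription=tx,
            translation=tl,
            mut_in_control_protein=mut_in_control,
            af_dna=af_dna,
            af_rna=af_rna,
            af_protein=af_protein,
            dp_dna=dna.total if dna is not None else None,
            dp_rna=rna.total if rna is not None else None,
            sc_total=prot.total if prot is not None else None,
        ))
    return patterns


@dataclass(frozen=True)
class PatternSummary:
    """Counts per status category plus derived transcribed/translated tallies.

    ``transcription_counts`` percentages are relative to all input sites.
    ``translation_counts`` composition percentages are relative to the set of
    protein-identified sites (tumor-specific allele-discriminating coverage).
    Percentages are None when the denominator is 0.
    """

    n_sites: int
    transcription_counts: dict
    translation_counts: dict
    transcribed_n: int
    protein_identified_n: int
    translated_n: int
    transcription_pct: dict
    translation_pct: dict


def summarize_patterns(patterns: Iterable[SitePattern]) -> PatternSummary:
    patterns = list(patterns)
    n = len(patterns)
    tx_counts = {s: 0 for s in TRANSCRIPTION_STATUSES}
    tl_counts = {s: 0 for s in TRANSLATION_STATUSES}
    identified = 0
    translated = 0
    for p in patterns:
        tx_counts[p.transcription] += 1
        tl_counts[p.translation] += 1
        if p.protein_identified:
            identified += 1
            if p.mutant_translated:
                translated += 1
    transcribed = tx_counts["BOTH"] + tx_counts["MUT_ONLY"]
    tx_pct = {
        s: (100.0 * c / n if n else None) for s, c in tx_counts.items()
    }
    identified_counts = {s: 0 for s in ("WT_ONLY", "BOTH", "MUT_ONLY")}
    for p in patterns:
        if p.protein_identified:
            identified_counts[p.translation] += 1
    tl_pct = {
        s: (100.0 * c / identified if identified else None)
        for s, c in identified_counts.items()
    }
    return PatternSummary(
        n_sites=n,
        transcription_counts=tx_counts,
        translation_counts=tl_counts,
        transcribed_n=transcribed,
        protein_identified_n=identified,
        translated_n=translated,
        transcription_pct=tx_pct,
        translation_pct=tl_pct,
    )


def unexpressed_lower_bound(n_wt_only: int, n_mut_only: int) -> int:
    """Conservative lower bound on mutated alleles that are not expressed.

    If every wild-type allele were expressed, the sites where only the mutant
    was seen would each hide one missed wild-type identification; the excess
    of wild-type-only sites over mutant-only sites therefore bounds from below
    the number of mutated alleles that were truly unexpressed.
    """
    if n_wt_only < 0 or n_mut_only < 0:
        raise ValueError("counts must be >= 0")
    return max(n_wt_only - n_mut_only, 0)


def cross_level_identification(patterns: Iterable[SitePattern]) -> dict:
    """Among protein-identified sites, fractions with mutant-allele evidence
    in RNA and in protein.  Fractions are None when the denominator is 0."""
    patterns = [p for p in patterns if p.protein_identified]
    denom = len(patterns)
    rna_n = sum(p.mutant_transcribed for p in patterns)
    prot_n = sum(p.mutant_translated for p in patterns)
    return {
        "denominator": denom,
        "rna_n": rna_n,
        "protein_n": prot_n,
        "rna_fraction": (rna_n / denom if denom else None),
        "protein_fraction": (prot_n / denom if denom else None),
    }


def with_cluster(pattern: SitePattern, label: str) -> SitePattern:
    return replace(pattern, cluster=label)


_ROLLUP_RANK = {"MUT_ONLY": 0, "BOTH": 1, "WT_ONLY": 2, "SITE_NOT_COVERED": 3,
                "GENE_NOT_EXPRESSED": 4, "GENE_NO_SPECTRUM": 4}


def gene_rollup(patterns: Iterable[SitePattern]) -> dict:
    """Most-expressed status per gene, for reporting on multi-site genes.

    Statuses are ranked MUT_ONLY > BOTH > WT_ONLY > covered-absent; the
    per-site statuses remain the unit of analysis everywhere else.
    Returns ``{gene: (transcription, translation)}``.
    """
    out: dict = {}
    for p in patterns:
        gene = p.site.gene
        tx, tl = out.get(gene, ("GENE_NOT_EXPRESSED", "GENE_NO_SPECTRUM"))
        if _ROLLUP_RANK[p.transcription] < _ROLLUP_RANK[tx]:
            tx = p.transcription
        if _ROLLUP_RANK[p.translation] < _ROLLUP_RANK[tl]:
            tl = p.translation
        out[gene] = (tx, tl)
    return out
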