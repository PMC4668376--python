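"""Allelic fractions and the depth / spectral-count site filters.

The allelic fraction (AF) of a somatic site is the number of times the
mutated base (or mutated residue, for protein spectra) is observed divided by
the total number of observations at the locus.  An AF with a zero denominator
is *undefined* — it propagates as "uncovered", never as 0, because a zero AF
asserts the mutant allele's absence while an uncovered site asserts nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .io_formats import AlleleCounts, AlleleCountTable, SiteRecord

__all__ = [
    "AllelicFraction",
    "FilterConfig",
    "compute_af",
    "remove_nonref_control",
    "apply_filters",
]


@dataclass(frozen=True)
class AllelicFraction:
    """AF value with its denominator; ``value is None`` when undefined."""

    value: Optional[float]
    total: int
    level: str

    @property
    def defined(self) -> bool:
        return self.value is not None


def compute_af(counts: AlleleCounts) -> AllelicFraction:
    """alt / (ref + alt + other); undefined (flagged) when the total is 0."""
    total = counts.total
    if total == 0:
        return AllelicFraction(value=None, total=0, level=counts.level)
    return AllelicFraction(value=counts.alt_count / total, total=total, level=counts.level)


def remove_nonref_control(
    records: Iterable[SiteRecord],
    rna_counts: AlleleCountTable,
    min_alt_reads: int = 2,
) -> tuple:
    """Drop sites whose control tissue is not reference homozygous in RNA.

    A site is removed iff its combined control-tissue RNA evidence shows the
    alternate allele present (>= ``min_alt_reads`` supporting reads, the same
    presence rule used for transcription classification).  Control-uncovered
    sites are kept.  Returns ``(kept, removed)``; the two lists partition the
    input.
    """
    kept, removed = [], []
    for rec in records:
        control = rna_counts.combined(rec.site.chrom, rec.site.pos, "control")
        if control is not None and control.alt_count >= min_alt_reads:
            removed.append(rec)
        else:
            kept.append(rec)
    return kept, removed


@dataclass(frozen=True)
class FilterConfig:
    """Depth / spectral-count thresholds guarding against sampling noise.

    Defaults: site depth >= 8 in both WES and tumor RNA (DP >= 8) and total
    tumor spectral count >= 3 (SC >= 3), with replicates combined before
    thresholding.
    """

    dp_min: int = 8
    sc_min: int = 3

    def __post_init__(self):
        if self.dp_min < 0 or self.sc_min < 0:
            raise ValueError("filter thresholds must be >= 0")


def apply_filters(
    records: Iterable[SiteRecord],
    rna_counts: AlleleCountTable,
    protein_counts: AlleleCountTable,
    config: FilterConfig = FilterConfig(),
) -> tuple:
    """Keep sites with DNA DP, tumor RNA DP and tumor SC above thresholds.

    RNA depths and SCs are summed across replicates before thresholding;
    thresholds apply to tumor-tissue evidence.  Returns ``(kept, removed)``.
    Monotone: raising either threshold never grows the kept set.
    """
    kept, removed = [], []
    for rec in records:
        chrom, pos = rec.site.chrom, rec.site.pos
        dna = rec.dna.get("tumor")
        dp_dna = dna.total if dna is not None else 0
        rna = rna_counts.combined(chrom, pos, "tumor")
        dp_rna = rna.total if rna is not None else 0
        prot = protein_counts.combined(chrom, pos, "tumor")
        sc = prot.total if prot is not None else 0
        if dp_dna >= config.dp_min and dp_rna >= config.dp_min and sc >= config.sc_min:
            kept.append(rec)
        else:
            removed.append(rec)
    return kept, removed
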