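"""Per-patient prioritization of candidate mutation-driver genes.

A candidate must carry tumor-specific mutant-allele evidence at the protein
level (hard gate).  Two further criteria contribute to the rank: the mutant
allelic fraction should be *comparable* across DNA, RNA and protein —
operationalized as no significant cross-level ASE at the chosen FDR plus an
AF floor — and the gene should appear in a supplied known-driver or
disease-pathway list.  The output ordering is a deterministic total order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .expression_classify import SitePattern
from .io_formats import MutationSite

__all__ = ["DriverCandidate", "check_af_comparable", "prioritize_drivers"]


@dataclass(frozen=True)
class DriverCandidate:
    gene: str
    site: MutationSite
    translated: bool
    af_comparable: bool
    in_annotation: bool
    af_dna: Optional[float]
    af_rna: Optional[float]
    af_protein: Optional[float]
    rank_score: int

    @property
    def af_triplet(self) -> tuple:
        return (self.af_dna, self.af_rna, self.af_protein)


def check_af_comparable(
    af_dna: Optional[float],
    af_rna: Optional[float],
    af_protein: Optional[float],
    ase_q_values: Iterable[float],
    fdr: float = 0.05,
    af_floor: float = 0.1,
) -> tuple:
    """(comparable?, reason) for the cross-level AF comparability criterion.

    True iff all three AFs are defined, none of the site's ASE tests is
    significant at the FDR threshold, and the smallest AF clears the floor
    (default 0.1, below the 0.22-0.57 band observed for prioritized genes).
    """
    afs = (af_dna, af_rna, af_protein)
    if any(v is None for v in afs):
        return False, "uncovered"
    qs = [q for q in ase_q_values if q is not None and not pd.isna(q)]
    if any(q < fdr for q in qs):
        return False, "significant_ase"
    if min(afs) < af_floor:
        return False, "below_af_floor"
    return True, None


def prioritize_drivers(
    patterns: Iterable[SitePattern],
    ase_results: pd.DataFrame,
    driver_genes: set,
    pathway_genes: set,
    fdr: float = 0.05,
    af_floor: float = 0.1,
) -> list:
    """Rank candidate mutation-driver genes for one patient.

    Candidates are the sites whose mutant allele has tumor-specific protein
    evidence (translation BOTH or MUT_ONLY).  ``rank_score`` counts satisfied
    criteria (translated + comparable AFs + annotation membership, 0-3);
    candidates sort by rank_score descending, then protein AF descending,
    then gene symbol and genomic position as final tiebreaks.
    """
    driver_genes = set(driver_genes)
    pathway_genes = set(pathway_genes)
    if not driver_genes and not pathway_genes:
        warnings.warn(
            "empty driver and pathway gene lists: the annotation criterion is "
            "vacuously false for every candidate",
            stacklevel=2,
        )
    q_by_site: dict = {}
    if len(ase_results):
        for row in ase_results.itertuples(index=False):
            q_by_site.setdefault((row.chrom, row.pos), []).append(row.q_value)

    candidates = []
    for p in patterns:
        if not p.mutant_translated:
            continue
        qs = q_by_site.get((p.site.chrom, p.site.pos), [])
        comparable, _ = check_af_comparable(
            p.af_dna, p.af_rna, p.af_protein, qs, fdr=fdr, af_floor=af_floor
        )
        in_annotation = p.site.gene in driver_genes or p.site.gene in pathway_genes
        candidates.append(DriverCandidate(
            gene=p.site.gene,
            site=p.site,
            translated=True,
            af_comparable=comparable,
            in_annotation=in_annotation,
            af_dna=p.af_dna,
            af_rna=p.af_rna,
            af_protein=p.af_protein,
            rank_score=1 + int(comparable) + int(in_annotation),
        ))
    candidates.sort(
        key=lambda c: (
            -c.rank_score,
            -(c.af_protein if c.af_protein is not None else -1.0),
            c.gene,
            c.site.chrom,
            c.site.pos,
        )
    )
    return candidates
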