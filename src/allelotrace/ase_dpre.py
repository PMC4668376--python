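"""Allele-specific expression tests and the DPRE statistic.

ASE between two molecular levels is tested with a two-sided Fisher exact test
on the 2x2 table of (wild-type, mutant) observation counts at the two levels,
with Benjamini-Hochberg control at FDR < 0.05 per level pair.

DPRE (Difference of normalized fold change of Protein and RNA Expression)
quantifies a gene's relative protein abundance after correcting for its
transcriptional change: ``DPRE = NormFC_protein - NormFC_RNA`` where
``FC = log2(Exp_cancer / Exp_cirrhosis)`` (with sentinel values +/-10 when one
tissue's abundance is zero) and ``NormFC = (FC - median(FC)) / IQR(FC)``
computed platform-wise.  DPRE < 0 indicates protein under-expression relative
to the transcript.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import AlleleCountTable, ExpressionTable, SiteRecord

__all__ = [
    "LEVEL_PAIRS",
    "AseResult",
    "DpreRecord",
    "fisher_ase",
    "bh_fdr",
    "ase_table",
    "fold_change",
    "normalize_fc",
    "compute_dpre",
    "compare_dpre_groups",
]

LEVEL_PAIRS = ("DNA_RNA", "RNA_PROTEIN", "DNA_PROTEIN")


@dataclass(frozen=True)
class AseResult:
    site_key: tuple
    gene: str
    level_pair: str
    wt_a: int
    mut_a: int
    wt_b: int
    mut_b: int
    p_value: Optional[float]
    q_value: Optional[float]
    direction: str  # toward_mutant | toward_wildtype | none


@dataclass(frozen=True)
class DpreRecord:
    gene: str
    replicate: str
    fc_rna: float
    fc_protein: float
    norm_fc_rna: float
    norm_fc_protein: float
    dpre: float
    group: str  # somatic | germline | none


def fisher_ase(wt_a: int, mut_a: int, wt_b: int, mut_b: int) -> Optional[float]:
    """Two-sided Fisher exact p for the table [[wt_a, mut_a], [wt_b, mut_b]].

    Returns None (untestable) for the all-zero table.
    """
    for v in (wt_a, mut_a, wt_b, mut_b):
        if v < 0 or v != int(v):
            raise ValueError("counts must be non-negative integers")
    if wt_a + mut_a + wt_b + mut_b == 0:
        return None
    _, p = stats.fisher_exact([[wt_a, mut_a], [wt_b, mut_b]], alternative="two-sided")
    return float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving w.r.t. p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def _direction(wt_a, mut_a, wt_b, mut_b) -> str:
    tot_a, tot_b = wt_a + mut_a, wt_b + mut_b
    if tot_a == 0 or tot_b == 0:
        return "none"
    fa, fb = mut_a / tot_a, mut_b / tot_b
    if fb > fa:
        return "toward_mutant"
    if fb < fa:
        return "toward_wildtype"
    return "none"


def ase_table(
    records: Iterable[SiteRecord],
    rna_counts: AlleleCountTable,
    protein_counts: AlleleCountTable,
) -> pd.DataFrame:
    """Per-site ASE tests for every level pair with coverage on both sides.

    One BH family per level pair.  Columns: chrom, pos, gene, level_pair,
    wt_a, mut_a, wt_b, mut_b, p_value, q_value, direction.
    """
    rows = []
    for rec in records:
        site = rec.site
        dna = rec.dna.get("tumor")
        rna = rna_counts.combined(site.chrom, site.pos, "tumor")
        prot = protein_counts.combined(site.chrom, site.pos, "tumor")
        levels = {"DNA": dna, "RNA": rna, "PROTEIN": prot}
        for pair in LEVEL_PAIRS:
            name_a, name_b = pair.split("_")
            a, b = levels[name_a], levels[name_b]
            if a is None or b is None or (a.total + b.total) == 0:
                continue
            p = fisher_ase(a.ref_count, a.alt_count, b.ref_count, b.alt_count)
            rows.append(dict(
                chrom=site.chrom, pos=site.pos, gene=site.gene, level_pair=pair,
                wt_a=a.ref_count, mut_a=a.alt_count,
                wt_b=b.ref_count, mut_b=b.alt_count,
                p_value=p,
                direction=_direction(a.ref_count, a.alt_count, b.ref_count, b.alt_count),
            ))
    frame = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "gene", "level_pair", "wt_a", "mut_a",
                 "wt_b", "mut_b", "p_value", "direction"],
    )
    frame["q_value"] = np.nan
    for pair in LEVEL_PAIRS:
        mask = (frame["level_pair"] == pair) & frame["p_value"].notna()
        if mask.any():
            frame.loc[mask, "q_value"] = bh_fdr(frame.loc[mask, "p_value"].to_numpy())
    return frame[["chrom", "pos", "gene", "level_pair", "wt_a", "mut_a",
                  "wt_b", "mut_b", "p_value", "q_value", "direction"]]


def fold_change(
    exp_cancer: float, exp_cirrhosis: float, sentinel: float = 10.0
) -> Optional[float]:
    """log2 tumor/control abundance ratio with sentinel values at zeros.

    ``exp_cirrhosis == 0`` maps to ``+sentinel``, ``exp_cancer == 0`` to
    ``-sentinel`` and both zero to None (flagged undefined).
    """
    if exp_cancer < 0 or exp_cirrhosis < 0:
        raise ValueError("abundances must be >= 0")
    if exp_cancer == 0 and exp_cirrhosis == 0:
        return None
    if exp_cirrhosis == 0:
        return sentinel
    if exp_cancer == 0:
        return -sentinel
    return math.log2(exp_cancer / exp_cirrhosis)


def normalize_fc(fcs) -> np.ndarray:
    """Robust-scale fold changes: (FC - median) / (Q3 - Q1), type-7 quantiles.

    Undefined entries (None/NaN) are excluded from the median/IQR and return
    as NaN in the output, which preserves input positions.  A degenerate
    distribution (IQR = 0) raises ValueError.
    """
    arr = np.array(
        [np.nan if v is None else float(v) for v in np.ravel(np.asarray(fcs, dtype=object))]
    )
    finite = arr[np.isfinite(arr)]
    if finite.size < 2:
        raise ValueError("need at least 2 defined fold changes")
    med = np.quantile(finite, 0.5)
    iqr = np.quantile(finite, 0.75) - np.quantile(finite, 0.25)
    if iqr == 0:
        raise ValueError("degenerate fold-change distribution (IQR = 0)")
    return (arr - med) / iqr


def _signs_consistent(fc1: Optional[float], fc2: Optional[float]) -> bool:
    # zeros count as agreeing with anything
    if fc1 is None or fc2 is None:
        return False
    if fc1 == 0 or fc2 == 0:
        return True
    return (fc1 > 0) == (fc2 > 0)


def compute_dpre(
    rna_expr: ExpressionTable,
    protein_expr: ExpressionTable,
    somatic_genes: set,
    germline_genes: set,
    sentinel: float = 10.0,
) -> tuple:
    """Per-gene, per-MS-replicate DPRE records with mutation-group membership.

    Eligibility requires the RNA fold change to be sign-consistent across the
    two RNA-Seq replicates; the RNA term of DPRE is then computed from the
    replicate-combined abundances.  Protein fold changes are per MS replicate,
    each normalized within its own replicate over eligible genes.  Genes with
    a somatic mutation take precedence over germline membership.

    Returns ``(records, exclusions)`` DataFrames; ``exclusions`` carries one
    (gene, reason) row per gene dropped.
    """
    rna_reps = rna_expr.replicates
    if len(rna_reps) < 2:
        raise ValueError("need two RNA replicates for the consistency rule")

    exclusions = []
    eligible = {}
    for gene in rna_expr.genes:
        per_rep = []
        for rep in rna_reps[:2]:
            m = rna_expr.get(gene, rep)
            per_rep.append(
                None if m is None else fold_change(m.exp_cancer, m.exp_cirrhosis, sentinel)
            )
        if any(v is None for v in per_rep):
            exclusions.append((gene, "rna_undefined"))
            continue
        if not _signs_consistent(per_rep[0], per_rep[1]):
            exclusions.append((gene, "rna_inconsistent"))
            continue
        cancer, cirrhosis = rna_expr.combined(gene)
        fc = fold_change(cancer, cirrhosis, sentinel)
        if fc is None:
            exclusions.append((gene, "rna_undefined"))
            continue
        eligible[gene] = fc

    if len(eligible) < 2:
        raise ValueError("fewer than 2 genes pass the RNA consistency rule")
    genes = sorted(eligible)
    norm_rna = dict(zip(genes, normalize_fc([eligible[g] for g in genes])))

    def group_of(gene: str) -> str:
        if gene in somatic_genes:
            return "somatic"
        if gene in germline_genes:
            return "germline"
        return "none"

    rows = []
    seen_protein = set()
    for rep in protein_expr.replicates:
        rep_genes, rep_fcs = [], []
        for gene in genes:
            m = protein_expr.get(gene, rep)
            if m is None:
                continue
            seen_protein.add(gene)
            fc = fold_change(m.exp_cancer, m.exp_cirrhosis, sentinel)
            if fc is None:
                exclusions.append((gene, f"protein_undefined_{rep}"))
                continue
            rep_genes.append(gene)
            rep_fcs.append(fc)
        if len(rep_genes) < 2:
            continue
        norm_prot = normalize_fc(rep_fcs)
        for gene, fc, nfc in zip(rep_genes, rep_fcs, norm_prot):
            rows.append(dict(
                gene=gene, replicate=rep,
                fc_rna=eligible[gene], fc_protein=fc,
                norm_fc_rna=norm_rna[gene], norm_fc_protein=nfc,
                dpre=nfc - norm_rna[gene],
                group=group_of(gene),
            ))
    for gene in genes:
        if gene not in seen_protein:
            exclusions.append((gene, "no_protein_record"))

    records = pd.DataFrame(
        rows,
        columns=["gene", "replicate", "fc_rna", "fc_protein",
                 "norm_fc_rna", "norm_fc_protein", "dpre", "group"],
    )
    excl = pd.DataFrame(sorted(set(exclusions)), columns=["gene", "reason"])
    return records, excl


def compare_dpre_groups(records: pd.DataFrame) -> pd.DataFrame:
    """Pairwise group comparisons of DPRE distributions, per MS replicate.

    For each group pair: two-sample two-sided Kolmogorov-Smirnov test, the
    per-group proportions of genes with DPRE <= 0, and a Pearson chi-square
    test (no continuity correction) on the 2x2 of (DPRE <= 0, DPRE > 0).
    Pairs where either group has fewer than 2 members are skipped.
    """
    rows = []
    for rep in sorted(records["replicate"].unique()):
        sub = records[records["replicate"] == rep]
        groups = sorted(sub["group"].unique())
        for i, ga in enumerate(groups):
            for gb in groups[i + 1:]:
                da = sub.loc[sub["group"] == ga, "dpre"].to_numpy()
                db = sub.loc[sub["group"] == gb, "dpre"].to_numpy()
                if da.size < 2 or db.size < 2:
                    continue
                ks = stats.ks_2samp(da, db, alternative="two-sided")
                le_a, le_b = int((da <= 0).sum()), int((db <= 0).sum())
                table = np.array(
                    [[le_a, da.size - le_a], [le_b, db.size - le_b]]
                )
                if (table.sum(axis=0) == 0).any():
                    chi2_p = np.nan
                else:
                    chi2_p = stats.chi2_contingency(table, correction=False)[1]
                rows.append(dict(
                    replicate=rep, group_a=ga, group_b=gb,
                    n_a=int(da.size), n_b=int(db.size),
                    ks_stat=float(ks.statistic), ks_p=float(ks.pvalue),
                    prop_le0_a=le_a / da.size, prop_le0_b=le_b / db.size,
                    chi2_p=float(chi2_p),
                ))
    return pd.DataFrame(
        rows,
        columns=["replicate", "group_a", "group_b", "n_a", "n_b",
                 "ks_stat", "ks_p", "prop_le0_a", "prop_le0_b", "chi2_p"],
    )
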