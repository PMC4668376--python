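"""Readers and writers for the tabular and sequence formats the pipeline touches.

All coordinates are 1-based, fully closed (VCF convention).  Absence of a row
in a per-site count table means the site is *uncovered* at that level/tissue/
replicate; a present row with ``alt_count == 0`` means the site is covered but
the mutant allele was not observed.  The two states are never conflated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

__all__ = [
    "EFFECTS",
    "LEVELS",
    "TISSUES",
    "CLUSTER_LABELS",
    "MutationSite",
    "AlleleCounts",
    "SiteRecord",
    "ExpressionMeasure",
    "ProteinRecord",
    "AlleleCountTable",
    "ExpressionTable",
    "ParseError",
    "read_mutation_table",
    "read_allele_counts",
    "read_expression_table",
    "read_gene_list",
    "build_sav_database",
    "write_sav_database",
    "write_site_report",
    "read_site_report",
    "write_driver_report",
    "read_driver_report",
]

EFFECTS = frozenset(
    {"missense", "nonsense", "nonstop", "translation_start", "silent"}
)
LEVELS = ("DNA", "RNA", "PROTEIN")
TISSUES = ("tumor", "control")

#: The four expression-based somatic-mutation classes, serialized literally.
CLUSTER_LABELS = ("Cluster_nTCM", "Cluster_nTCS", "Cluster_nTL", "Cluster_TL")

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*")


class ParseError(ValueError):
    """Raised for malformed input rows; carries the offending line number."""


@dataclass(frozen=True)
class MutationSite:
    """One somatic variant: genomic position, alleles, gene and effect class."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene: str
    effect: str
    protein_change: Optional[str] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r} at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.alt_allele)


@dataclass(frozen=True)
class AlleleCounts:
    """Ref/alt evidence counts at one site for one level, tissue and replicate.

    Counts are sequencing reads for DNA/RNA and spectral counts (SC) of
    allele-discriminating peptides for PROTEIN.  ``other_count`` holds reads
    supporting neither allele and is always 0 at the protein level.
    """

    level: str
    tissue: str
    replicate: str
    ref_count: int
    alt_count: int
    other_count: int = 0

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        for name in ("ref_count", "alt_count", "other_count"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.level == "PROTEIN" and self.other_count != 0:
            raise ValueError("other_count must be 0 at the PROTEIN level")

    @property
    def total(self) -> int:
        return self.ref_count + self.alt_count + self.other_count


@dataclass(frozen=True)
class SiteRecord:
    """A mutation site with its DNA allele counts per tissue (one WES run)."""

    site: MutationSite
    dna: dict  # tissue -> AlleleCounts

    @property
    def key(self) -> tuple:
        return self.site.key


@dataclass(frozen=True)
class ExpressionMeasure:
    """Gene-level abundance (FPKM for RNA, XIC for protein) in both tissues."""

    gene: str
    platform: str  # RNA | PROTEIN
    replicate: str
    exp_cancer: float
    exp_cirrhosis: float

    def __post_init__(self):
        if self.platform not in ("RNA", "PROTEIN"):
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.exp_cancer < 0 or self.exp_cirrhosis < 0:
            raise ValueError(f"negative abundance for gene {self.gene}")


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    sequence: str
    gene: str

    def __post_init__(self):
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.protein_id}: invalid residues {sorted(bad)}"
            )


class AlleleCountTable:
    """Per-site allele counts at one molecular level, indexed for lookup.

    Missing (site, tissue, replicate) combinations are *uncovered*: lookups
    return ``None`` and :meth:`uncovered` enumerates them.  Nothing is ever
    imputed as a zero count.
    """

    def __init__(self, frame: pd.DataFrame, level: str):
        if level not in LEVELS:
            raise ValueError(f"unknown level {level!r}")
        self.level = level
        cols = ["chrom", "pos", "tissue", "replicate", "ref_count", "alt_count", "other_count"]
        self.frame = frame[cols].copy()
        self._index: dict = {}
        self._combined: dict = {}
        for row in self.frame.itertuples(index=False):
            counts = AlleleCounts(
                level=level,
                tissue=row.tissue,
                replicate=str(row.replicate),
                ref_count=int(row.ref_count),
                alt_count=int(row.alt_count),
                other_count=int(row.other_count),
            )
            self._index[(row.chrom, int(row.pos), row.tissue, str(row.replicate))] = counts
            key = (row.chrom, int(row.pos), row.tissue)
            self._combined.setdefault(key, []).append(counts)

    @classmethod
    def empty(cls, level: str) -> "AlleleCountTable":
        frame = pd.DataFrame(
            columns=["chrom", "pos", "tissue", "replicate", "ref_count", "alt_count", "other_count"]
        )
        return cls(frame, level)

    def get(self, chrom: str, pos: int, tissue: str, replicate: str) -> Optional[AlleleCounts]:
        return self._index.get((chrom, pos, tissue, str(replicate)))

    def combined(self, chrom: str, pos: int, tissue: str) -> Optional[AlleleCounts]:
        """Counts summed over the replicates that cover the site, or None."""
        rows = self._combined.get((chrom, pos, tissue))
        if not rows:
            return None
        return AlleleCounts(
            level=self.level,
            tissue=tissue,
            replicate="combined",
            ref_count=sum(c.ref_count for c in rows),
            alt_count=sum(c.alt_count for c in rows),
            other_count=sum(c.other_count for c in rows),
        )

    def covered(self, chrom: str, pos: int, tissue: str) -> bool:
        return (chrom, pos, tissue) in self._combined

    @property
    def replicates(self) -> tuple:
        return tuple(sorted(self.frame["replicate"].astype(str).unique()))

    @property
    def n_sites(self) -> int:
        return len({(c, p) for (c, p, _t) in self._combined})

    def site_keys(self) -> set:
        return {(c, p) for (c, p, _t) in self._combined}

    def uncovered(
        self,
        sites: Iterable[tuple],
        tissues: Iterable[str] = TISSUES,
        replicates: Optional[Iterable[str]] = None,
    ) -> list:
        """List (chrom, pos, tissue, replicate) combinations with no row."""
        reps = tuple(replicates) if replicates is not None else self.replicates
        out = []
        for chrom, pos in sites:
            for tissue in tissues:
                for rep in reps:
                    if (chrom, pos, tissue, str(rep)) not in self._index:
                        out.append((chrom, pos, tissue, str(rep)))
        return out


class ExpressionTable:
    """Gene-level abundances for one platform, one row per gene x replicate."""

    def __init__(self, frame: pd.DataFrame, platform: str):
        if platform not in ("RNA", "PROTEIN"):
            raise ValueError(f"unknown platform {platform!r}")
        self.platform = platform
        self.frame = frame[["gene", "replicate", "exp_cancer", "exp_cirrhosis"]].copy()
        dup = self.frame.duplicated(subset=["gene", "replicate"])
        if dup.any():
            first = self.frame[dup].iloc[0]
            raise ValueError(
                f"duplicate gene x replicate: {first['gene']} / {first['replicate']}"
            )
        if (self.frame[["exp_cancer", "exp_cirrhosis"]] < 0).any().any():
            raise ValueError("negative abundance in expression table")
        self._index = {
            (r.gene, str(r.replicate)): ExpressionMeasure(
                gene=r.gene,
                platform=platform,
                replicate=str(r.replicate),
                exp_cancer=float(r.exp_cancer),
                exp_cirrhosis=float(r.exp_cirrhosis),
            )
            for r in self.frame.itertuples(index=False)
        }
        self._by_gene: dict = {}
        for (gene, _rep), m in self._index.items():
            self._by_gene.setdefault(gene, []).append(m)

    def get(self, gene: str, replicate: str) -> Optional[ExpressionMeasure]:
        return self._index.get((gene, str(replicate)))

    def combined(self, gene: str) -> Optional[tuple]:
        """(sum exp_cancer, sum exp_cirrhosis) over replicates, or None."""
        rows = self._by_gene.get(gene)
        if not rows:
            return None
        return (
            sum(m.exp_cancer for m in rows),
            sum(m.exp_cirrhosis for m in rows),
        )

    def tumor_total(self, gene: str) -> Optional[float]:
        combined = self.combined(gene)
        return None if combined is None else combined[0]

    def __contains__(self, gene: str) -> bool:
        return gene in self._by_gene

    @property
    def replicates(self) -> tuple:
        return tuple(sorted(self.frame["replicate"].astype(str).unique()))

    @property
    def genes(self) -> tuple:
        return tuple(self._by_gene)


# ---------------------------------------------------------------------------
# readers

_MUTATION_COLUMNS = [
    "chrom", "pos", "ref_allele", "alt_allele", "gene", "effect",
    "protein_change", "tumor_ref", "tumor_alt", "control_ref", "control_alt",
]


def read_mutation_table(
    path,
    format: str = "tsv",
    tumor_sample: str = "TUMOR",
    control_sample: str = "CONTROL",
) -> list:
    """Read the somatic mutation table with per-tissue DNA depths.

    TSV columns: chrom pos ref_allele alt_allele gene effect protein_change
    tumor_ref tumor_alt control_ref control_alt.  VCF input must carry
    per-sample AD (allele depth) values for the tumor and control samples and
    GENE / EFFECT / PCHANGE INFO fields.
    """
    if format == "tsv":
        return _read_mutation_tsv(path)
    if format == "vcf":
        return _read_mutation_vcf(path, tumor_sample, control_sample)
    raise ValueError(f"unknown mutation table format {format!r}")


def _read_mutation_tsv(path) -> list:
    records = []
    seen = set()
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != _MUTATION_COLUMNS:
            raise ParseError(
                f"{path}: line 1: expected columns {_MUTATION_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_MUTATION_COLUMNS):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(_MUTATION_COLUMNS)} fields, "
                    f"got {len(fields)}"
                )
            row = dict(zip(_MUTATION_COLUMNS, fields))
            try:
                site = MutationSite(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref_allele=row["ref_allele"],
                    alt_allele=row["alt_allele"],
                    gene=row["gene"],
                    effect=row["effect"],
                    protein_change=row["protein_change"] or None,
                )
                dna = {
                    "tumor": AlleleCounts(
                        "DNA", "tumor", "R1",
                        ref_count=int(row["tumor_ref"]),
                        alt_count=int(row["tumor_alt"]),
                    ),
                    "control": AlleleCounts(
                        "DNA", "control", "R1",
                        ref_count=int(row["control_ref"]),
                        alt_count=int(row["control_alt"]),
                    ),
                }
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if site.key in seen:
                raise ParseError(
                    f"{path}: line {lineno}: duplicate site {site.chrom}:{site.pos} "
                    f"{site.ref_allele}>{site.alt_allele}"
                )
            seen.add(site.key)
            records.append(SiteRecord(site=site, dna=dna))
    return records


def _read_mutation_vcf(path, tumor_sample: str, control_sample: str) -> list:
    import pysam

    records = []
    seen = set()
    with pysam.VariantFile(str(path)) as vcf:
        for sample in (tumor_sample, control_sample):
            if sample not in vcf.header.samples:
                raise ParseError(f"{path}: sample {sample!r} not in VCF header")
        for rec in vcf:
            info = rec.info
            site = MutationSite(
                chrom=rec.chrom,
                pos=rec.pos,  # pysam exposes the 1-based POS here
                ref_allele=rec.ref,
                alt_allele=rec.alts[0],
                gene=str(info.get("GENE", "")),
                effect=str(info.get("EFFECT", "")),
                protein_change=(str(info["PCHANGE"]) if "PCHANGE" in info else None),
            )
            dna = {}
            for tissue, sample in (("tumor", tumor_sample), ("control", control_sample)):
                ad = rec.samples[sample].get("AD")
                if ad is None or ad[0] is None:
                    raise ParseError(
                        f"{path}: {rec.chrom}:{rec.pos}: missing AD for sample {sample}"
                    )
                dna[tissue] = AlleleCounts(
                    "DNA", tissue, "R1", ref_count=int(ad[0]), alt_count=int(ad[1])
                )
            if site.key in seen:
                raise ParseError(
                    f"{path}: duplicate site {site.chrom}:{site.pos} "
                    f"{site.ref_allele}>{site.alt_allele}"
                )
            seen.add(site.key)
            records.append(SiteRecord(site=site, dna=dna))
    return records


def read_allele_counts(path, level: str) -> AlleleCountTable:
    """Read per-site allele counts (RNA reads or PROTEIN spectral counts).

    Columns: chrom pos tissue replicate ref_count alt_count [other_count].
    A PROTEIN file may include the other_count column only if it is all zero.
    """
    if level not in ("RNA", "PROTEIN"):
        raise ValueError(f"level must be RNA or PROTEIN, got {level!r}")
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "replicate": str})
    required = ["chrom", "pos", "tissue", "replicate", "ref_count", "alt_count"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if "other_count" not in frame.columns:
        frame["other_count"] = 0
    bad_tissue = ~frame["tissue"].isin(TISSUES)
    if bad_tissue.any():
        raise ParseError(
            f"{path}: unknown tissue label "
            f"{frame.loc[bad_tissue, 'tissue'].iloc[0]!r}"
        )
    counts = frame[["ref_count", "alt_count", "other_count"]]
    if (counts < 0).any().any():
        raise ParseError(f"{path}: negative count")
    if level == "PROTEIN" and (frame["other_count"] != 0).any():
        raise ParseError(f"{path}: nonzero other_count in a PROTEIN table")
    return AlleleCountTable(frame, level)


def read_expression_table(path, platform: str) -> ExpressionTable:
    """Read gene-level abundances; zeros are preserved exactly (FC sentinels
    downstream depend on them)."""
    frame = pd.read_csv(path, sep="\t", dtype={"gene": str, "replicate": str})
    required = ["gene", "replicate", "exp_cancer", "exp_cirrhosis"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return ExpressionTable(frame, platform)


def read_gene_list(path) -> set:
    """Plain text, one gene symbol per line; blank lines and '#' comments skipped."""
    genes = set()
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return genes


# ---------------------------------------------------------------------------
# SAV database construction

def build_sav_database(proteins: Iterable[ProteinRecord], variants: Iterable[tuple]) -> list:
    """Build single-amino-acid-variant records for a proteogenomic search.

    ``variants`` holds (protein_id, position, ref_aa, alt_aa) with a 1-based
    position.  Each output record carries exactly one substitution relative to
    its parent; multiple variants on one protein yield separate records (no
    combinatorial haplotypes).  Returns Biopython SeqRecords with id
    ``<accession>_p.<ref><pos><alt>``.
    """
    by_id = {p.protein_id: p for p in proteins}
    out = []
    for protein_id, position, ref_aa, alt_aa in variants:
        parent = by_id.get(protein_id)
        if parent is None:
            raise ValueError(f"unknown protein {protein_id!r} for variant "
                             f"({protein_id}, {position}, {ref_aa}, {alt_aa})")
        seq = parent.sequence
        if not (1 <= position <= len(seq)):
            raise ValueError(
                f"variant ({protein_id}, {position}, {ref_aa}, {alt_aa}): "
                f"position out of range 1..{len(seq)}"
            )
        if seq[position - 1] != ref_aa:
            raise ValueError(
                f"variant ({protein_id}, {position}, {ref_aa}, {alt_aa}): "
                f"reference residue mismatch (sequence has {seq[position - 1]!r})"
            )
        mutated = seq[: position - 1] + alt_aa + seq[position:]
        change = f"p.{ref_aa}{position}{alt_aa}"
        out.append(
            SeqRecord(
                Seq(mutated),
                id=f"{protein_id}_{change}",
                description=f"gene={parent.gene} parent={protein_id} variant={change}",
            )
        )
    return out


def write_sav_database(path, records: Iterable[SeqRecord]) -> int:
    return SeqIO.write(list(records), str(path), "fasta")


# ---------------------------------------------------------------------------
# reports

_SITE_REPORT_COLUMNS = [
    "chrom", "pos", "ref_allele", "alt_allele", "gene", "effect",
    "protein_change", "transcription", "translation", "mut_in_control_protein",
    "cluster", "af_dna", "af_rna", "af_protein", "dp_dna", "dp_rna", "sc_total",
]


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return format(value, ".10g")
    return str(value)


def write_site_report(path, patterns: Iterable) -> None:
    """Write per-site transcription/translation statuses, AFs and clusters.

    Deterministic column order; ``read_site_report`` round-trips the table.
    """
    with open(path, "w") as handle:
        handle.write("\t".join(_SITE_REPORT_COLUMNS) + "\n")
        for p in patterns:
            s = p.site
            row = [
                s.chrom, s.pos, s.ref_allele, s.alt_allele, s.gene, s.effect,
                s.protein_change, p.transcription, p.translation,
                p.mut_in_control_protein, p.cluster,
                p.af_dna, p.af_rna, p.af_protein,
                p.dp_dna, p.dp_rna, p.sc_total,
            ]
            handle.write("\t".join(_fmt(v) for v in row) + "\n")


def read_site_report(path) -> list:
    from .expression_classify import SitePattern  # local import: layering

    patterns = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != _SITE_REPORT_COLUMNS:
            raise ParseError(f"{path}: unexpected site report header")
        for line in handle:
            f = dict(zip(_SITE_REPORT_COLUMNS, line.rstrip("\n").split("\t")))
            site = MutationSite(
                chrom=f["chrom"], pos=int(f["pos"]),
                ref_allele=f["ref_allele"], alt_allele=f["alt_allele"],
                gene=f["gene"], effect=f["effect"],
                protein_change=f["protein_change"] or None,
            )
            patterns.append(SitePattern(
                site=site,
                transcription=f["transcription"],
                translation=f["translation"],
                mut_in_control_protein=f["mut_in_control_protein"] == "True",
                cluster=f["cluster"] or None,
                af_dna=float(f["af_dna"]) if f["af_dna"] else None,
                af_rna=float(f["af_rna"]) if f["af_rna"] else None,
                af_protein=float(f["af_protein"]) if f["af_protein"] else None,
                dp_dna=int(f["dp_dna"]) if f["dp_dna"] else None,
                dp_rna=int(f["dp_rna"]) if f["dp_rna"] else None,
                sc_total=int(f["sc_total"]) if f["sc_total"] else None,
            ))
    return patterns


_DRIVER_REPORT_COLUMNS = [
    "rank", "gene", "chrom", "pos", "ref_allele", "alt_allele", "effect",
    "protein_change", "translated", "af_comparable", "in_annotation",
    "af_dna", "af_rna", "af_protein", "rank_score",
]


def write_driver_report(path, candidates: Iterable) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(_DRIVER_REPORT_COLUMNS) + "\n")
        for rank, c in enumerate(candidates, start=1):
            s = c.site
            row = [
                rank, c.gene, s.chrom, s.pos, s.ref_allele, s.alt_allele,
                s.effect, s.protein_change, c.translated, c.af_comparable,
                c.in_annotation, c.af_dna, c.af_rna, c.af_protein, c.rank_score,
            ]
            handle.write("\t".join(_fmt(v) for v in row) + "\n")


def read_driver_report(path) -> list:
    from .prioritize import DriverCandidate  # local import: layering

    out = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != _DRIVER_REPORT_COLUMNS:
            raise ParseError(f"{path}: unexpected driver report header")
        for line in handle:
            f = dict(zip(_DRIVER_REPORT_COLUMNS, line.rstrip("\n").split("\t")))
            site = MutationSite(
                chrom=f["chrom"], pos=int(f["pos"]),
                ref_allele=f["ref_allele"], alt_allele=f["alt_allele"],
                gene=f["gene"], effect=f["effect"],
                protein_change=f["protein_change"] or None,
            )
            out.append(DriverCandidate(
                gene=f["gene"], site=site,
                translated=f["translated"] == "True",
                af_comparable=f["af_comparable"] == "True",
                in_annotation=f["in_annotation"] == "True",
                af_dna=float(f["af_dna"]) if f["af_dna"] else None,
                af_rna=float(f["af_rna"]) if f["af_rna"] else None,
                af_protein=float(f["af_protein"]) if f["af_protein"] else None,
                rank_score=int(f["rank_score"]),
            ))
    return out
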