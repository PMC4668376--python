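"""Synthetic hyper-mutated-tumor multi-omics fixtures with ground truth.

The generator emulates the study conditions of a single hyper-mutated liver
tumor with matched control tissue: ~5,000 non-silent somatic sites in ~3,800
genes, a clonal/subclonal DNA allelic-fraction structure (clonal sites at
purity/2, subclonal sites in a small-AF band), WES depth ~110x, per-site RNA
depth proportional to gene expression with heavy-tailed capture efficiency
(so uncovered sites arise from low abundance, not a separate flag),
allele-elimination events at transcription and translation, spectral counts
proportional to protein abundance and allele share, and a negative protein-FC
shift for genes carrying somatic mutations (the DPRE signal).  Everything is
a pure function of ``GeneratorConfig`` (including its seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    AlleleCounts,
    AlleleCountTable,
    ExpressionTable,
    MutationSite,
    SiteRecord,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_dataset",
    "make_worked_fixture",
    "largest_remainder",
    "WORKED_FIXTURES",
]

_BASES = np.array(list("ACGT"))
_AAS = list("ARNDCQEGHILKMFPSTWYV")
_EFFECTS = np.array(["missense", "nonsense", "nonstop", "translation_start"])
_EFFECT_P = np.array([0.90, 0.06, 0.02, 0.02])

# AF bands of the two untranscribed clusters (observed ranges).  Planted
# draws are uniform over the band shrunk by an inner margin, so the two
# groups stay well separated (no mass hugging the shared gap) and finite
# sequencing depth cannot push an observed AF across it.
_NTCM_BAND = (0.13, 0.53)
_NTCS_BAND = (0.03, 0.11)
_BAND_MARGIN = 0.075  # fraction of the band width kept clear at each edge


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic hyper-mutated tumor.

    Anchors: ~5,000 non-silent somatic sites, WES mean depth 110x, 34% of
    mutated alleles not transcribed, 8.5% of sites in unexpressed genes, a
    -0.3 log2 protein-FC shift for somatically mutated genes, and the
    moderate/small untranscribed AF bands 0.13-0.53 / 0.03-0.11.
    """

    n_sites: int = 5000
    n_genes: int = 3800
    n_germline_genes: int = 3200
    n_background_genes: int = 11800
    purity: float = 0.8
    clonal_fraction: float = 0.6
    subclonal_af_range: tuple = (0.03, 0.15)
    p_gene_silent: float = 0.085
    p_site_uncovered_scale: float = 1.0
    p_allele_not_transcribed: float = 0.34
    p_not_translated_given_transcribed: float = 0.5
    p_control_alt: float = 0.0036
    p_ms_site: float = 0.22
    dpre_shift_somatic: float = -0.3
    dpre_shift_germline: float = -0.05
    dpre_noise_sd: float = 0.5
    mean_dna_depth: int = 110
    rna_depth_scale: float = 20.0
    sc_rate_scale: float = 2.0
    expression_log_mean: float = 1.5
    expression_log_sd: float = 1.0
    fc_log2_sd: float = 1.0
    replicate_log2_sd: float = 0.25
    protein_af_log2_sd: float = 0.35
    n_planted_drivers: int = 5
    n_decoy_driver_listed: int = 20
    n_pathway_genes: int = 45
    cluster_proportions: Optional[tuple] = None
    multi_site_genes: bool = True
    seed: int = 0

    def __post_init__(self):
        probs = {
            "purity": self.purity,
            "clonal_fraction": self.clonal_fraction,
            "p_gene_silent": self.p_gene_silent,
            "p_allele_not_transcribed": self.p_allele_not_transcribed,
            "p_not_translated_given_transcribed": self.p_not_translated_given_transcribed,
            "p_control_alt": self.p_control_alt,
            "p_ms_site": self.p_ms_site,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.purity == 0:
            raise ValueError("purity must be in (0, 1]")
        if self.n_sites < 1 or self.n_genes < 1:
            raise ValueError("n_sites and n_genes must be >= 1")
        if self.mean_dna_depth < 1:
            raise ValueError("mean_dna_depth must be >= 1")
        lo, hi = self.subclonal_af_range
        if not (0 <= lo < hi <= 1):
            raise ValueError(f"invalid subclonal_af_range {self.subclonal_af_range}")
        if not self.multi_site_genes and self.n_sites > self.n_genes:
            raise ValueError(
                "multi_site_genes=False requires n_sites <= n_genes"
            )
        if self.cluster_proportions is not None:
            p = np.asarray(self.cluster_proportions, dtype=float)
            # printed percentages may sum to 0.999 from rounding
            if p.size != 4 or (p < 0).any() or not np.isclose(p.sum(), 1.0, atol=0.01):
                raise ValueError(
                    "cluster_proportions must be 4 non-negative values summing to 1"
                )


@dataclass(frozen=True)
class GroundTruth:
    """Per-site and per-gene generative labels, consistent with the tables."""

    sites: pd.DataFrame
    genes: pd.DataFrame


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    site_records: list
    rna_counts: AlleleCountTable
    protein_counts: AlleleCountTable
    rna_expr: ExpressionTable
    protein_expr: ExpressionTable
    somatic_genes: set
    germline_genes: set
    driver_genes: set
    pathway_genes: set
    planted_drivers: tuple
    truth: GroundTruth

    def write(self, outdir) -> dict:
        """Emit every table in the exact TSV dialects the readers accept."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        paths["mutations"] = outdir / "mutations.tsv"
        with open(paths["mutations"], "w") as fh:
            fh.write(
                "chrom\tpos\tref_allele\talt_allele\tgene\teffect\tprotein_change"
                "\ttumor_ref\ttumor_alt\tcontrol_ref\tcontrol_alt\n"
            )
            for rec in self.site_records:
                s = rec.site
                t, c = rec.dna["tumor"], rec.dna["control"]
                fh.write(
                    f"{s.chrom}\t{s.pos}\t{s.ref_allele}\t{s.alt_allele}\t{s.gene}"
                    f"\t{s.effect}\t{s.protein_change or ''}"
                    f"\t{t.ref_count}\t{t.alt_count}\t{c.ref_count}\t{c.alt_count}\n"
                )

        for name, table in (("rna_counts", self.rna_counts),
                            ("protein_counts", self.protein_counts)):
            paths[name] = outdir / f"{name}.tsv"
            frame = table.frame.copy()
            if name == "protein_counts":
                frame = frame.drop(columns=["other_count"])
            frame.to_csv(paths[name], sep="\t", index=False)

        for name, table in (("rna_expression", self.rna_expr),
                            ("protein_expression", self.protein_expr)):
            paths[name] = outdir / f"{name}.tsv"
            table.frame.to_csv(paths[name], sep="\t", index=False, float_format="%.6g")

        for name, genes in (("germline_genes", self.germline_genes),
                            ("driver_genes", self.driver_genes),
                            ("pathway_genes", self.pathway_genes)):
            paths[name] = outdir / f"{name}.txt"
            with open(paths[name], "w") as fh:
                for g in sorted(genes):
                    fh.write(g + "\n")

        paths["truth_sites"] = outdir / "truth_sites.tsv"
        self.truth.sites.to_csv(paths["truth_sites"], sep="\t", index=False,
                                float_format="%.6g")
        paths["truth_genes"] = outdir / "truth_genes.tsv"
        self.truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False,
                                float_format="%.6g")

        paths["config"] = outdir / "generator_config.yaml"
        cfg = dataclasses.asdict(self.config)
        cfg["subclonal_af_range"] = list(cfg["subclonal_af_range"])
        if cfg["cluster_proportions"] is not None:
            cfg["cluster_proportions"] = list(cfg["cluster_proportions"])
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
        return paths


def largest_remainder(proportions, n: int) -> np.ndarray:
    """Deterministic multinomial rounding: counts sum to n exactly."""
    p = np.asarray(proportions, dtype=float)
    raw = p * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def _count_frame(chroms, poss, tissues, reps, refs, alts, others=None):
    return pd.DataFrame({
        "chrom": chroms,
        "pos": np.asarray(poss, dtype=int),
        "tissue": tissues,
        "replicate": reps,
        "ref_count": np.asarray(refs, dtype=int),
        "alt_count": np.asarray(alts, dtype=int),
        "other_count": (np.zeros(len(refs), dtype=int) if others is None
                        else np.asarray(others, dtype=int)),
    })


def generate_dataset(config: GeneratorConfig = GeneratorConfig()) -> SyntheticDataset:
    """Generate the full multi-omics fixture plus its ground truth.

    With ``cluster_proportions`` set, the generator plants exactly those
    cluster memberships (largest-remainder rounding) with generous, clamped
    depths so that classification and filtering recover the planted labels;
    otherwise it simulates the default hyper-mutated-tumor conditions.
    """
    if config.cluster_proportions is not None:
        return _generate_proportions(config)
    return _generate_default(config)


def _site_identities(rng, n_sites, genes_of_sites):
    chroms = np.array([f"chr{(i % 22) + 1}" for i in range(n_sites)])
    poss = 1_000_000 + (np.arange(n_sites) // 22) * 150 + 1
    ref_idx = rng.integers(0, 4, n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, n_sites)) % 4
    effects = rng.choice(_EFFECTS, size=n_sites, p=_EFFECT_P)
    pchanges = [
        f"p.{_AAS[i % 20]}{(i % 400) + 1}{_AAS[(i + 7) % 20]}" for i in range(n_sites)
    ]
    return chroms, poss, _BASES[ref_idx], _BASES[alt_idx], effects, pchanges


def _generate_default(config: GeneratorConfig) -> SyntheticDataset:
    rng = np.random.default_rng(config.seed)
    n = config.n_sites

    # ---- gene universe and abundances -----------------------------------
    mut_genes = np.array([f"SMG{i:05d}" for i in range(config.n_genes)])
    germ_genes = np.array([f"GLV{i:05d}" for i in range(config.n_germline_genes)])
    bkg_genes = np.array([f"BKG{i:05d}" for i in range(config.n_background_genes)])
    all_genes = np.concatenate([mut_genes, germ_genes, bkg_genes])
    g_total = all_genes.size

    base = rng.lognormal(config.expression_log_mean, config.expression_log_sd, g_total)
    silent_gene = np.zeros(g_total, dtype=bool)
    silent_gene[: config.n_genes] = rng.random(config.n_genes) < config.p_gene_silent

    # ---- sites -----------------------------------------------------------
    if config.multi_site_genes and n > config.n_genes:
        gene_idx = np.concatenate([
            np.arange(config.n_genes),
            rng.integers(0, config.n_genes, n - config.n_genes),
        ])
    else:
        gene_idx = rng.permutation(config.n_genes)[:n]
    # planted drivers: single-site, non-silent genes
    counts_per_gene = np.bincount(gene_idx, minlength=config.n_genes)
    single = np.flatnonzero((counts_per_gene == 1) & ~silent_gene[: config.n_genes])
    planted_gene_idx = rng.choice(single, size=config.n_planted_drivers, replace=False)
    planted_sites = np.array(
        [np.flatnonzero(gene_idx == g)[0] for g in planted_gene_idx], dtype=int
    )
    planted_mask = np.zeros(n, dtype=bool)
    planted_mask[planted_sites] = True

    tumor_fpkm = base.copy()
    tumor_fpkm[silent_gene] = 0.0
    control_fpkm = base * np.exp2(rng.normal(0.0, config.fc_log2_sd, g_total))

    group = np.array(["none"] * g_total, dtype=object)
    group[: config.n_genes] = "somatic"
    group[config.n_genes: config.n_genes + config.n_germline_genes] = "germline"
    shift = np.where(
        group == "somatic", config.dpre_shift_somatic,
        np.where(group == "germline", config.dpre_shift_germline, 0.0),
    )
    prot_tumor = tumor_fpkm * np.exp2(shift + rng.normal(0.0, config.dpre_noise_sd, g_total))
    prot_control = control_fpkm * np.exp2(rng.normal(0.0, config.dpre_noise_sd, g_total))

    chroms, poss, refs, alts, effects, pchanges = _site_identities(rng, n, gene_idx)
    site_genes = mut_genes[gene_idx]

    clonal = rng.random(n) < config.clonal_fraction
    lo, hi = config.subclonal_af_range
    true_af = np.where(clonal, config.purity / 2.0, rng.uniform(lo, hi, n))
    clonal[planted_mask] = True
    true_af[planted_mask] = 0.4

    # ---- DNA counts ------------------------------------------------------
    dna_depth_t = rng.poisson(config.mean_dna_depth, n)
    dna_alt_t = rng.binomial(dna_depth_t, true_af)
    dna_depth_c = rng.poisson(config.mean_dna_depth, n)
    contaminated = rng.random(n) < config.p_control_alt
    contaminated[planted_mask] = False
    dna_alt_c = np.zeros(n, dtype=int)

    # ---- RNA depths (tumor) ---------------------------------------------
    kappa = 1.0 / config.p_site_uncovered_scale
    capture = rng.gamma(kappa, 1.0 / kappa, n)
    fpkm_site = tumor_fpkm[gene_idx]
    rna_depth = np.stack([
        rng.poisson(config.rna_depth_scale * fpkm_site * capture) for _ in range(2)
    ])  # (2, n)
    rna_depth[:, planted_mask] = 100

    silent_site = silent_gene[gene_idx]
    depth_total = rna_depth.sum(axis=0)
    covered = depth_total > 0
    eligible = covered & ~silent_site
    # Calibrate the per-site elimination rate q so the *observed* wild-type-
    # only share matches the configured rate: a transcribed allele at a
    # low-AF subclonal site can still read as wild-type-only when fewer than
    # min_alt_reads mutant reads are drawn, and that detectability loss
    # (beta, exact from the binomial) is accounted for here.
    with np.errstate(over="ignore"):
        beta = (1.0 - true_af) ** depth_total + (
            depth_total * true_af * (1.0 - true_af) ** np.maximum(depth_total - 1, 0)
        )
    c_share = max(eligible.mean(), 1e-9)
    mean_beta = beta[eligible].mean() if eligible.any() else 0.0
    q = np.clip(
        (config.p_allele_not_transcribed / c_share - mean_beta)
        / max(1.0 - mean_beta, 1e-9),
        0.0, 1.0,
    )
    elim_tx = (rng.random(n) < q) & eligible
    elim_tx[planted_mask] = False
    mut_transcribed = covered & ~silent_site & ~elim_tx

    rna_p = np.where(mut_transcribed, true_af, 0.0)
    rna_alt = np.stack([rng.binomial(rna_depth[r], rna_p) for r in range(2)])
    rna_alt[:, planted_mask] = 40

    # control RNA
    ctrl_fpkm_site = control_fpkm[gene_idx]
    rna_depth_ctrl = np.stack([
        rng.poisson(config.rna_depth_scale * ctrl_fpkm_site * capture) for _ in range(2)
    ])
    rna_depth_ctrl[:, planted_mask] = 100
    rna_alt_ctrl = np.zeros_like(rna_depth_ctrl)
    if contaminated.any():
        for r in range(2):
            rna_alt_ctrl[r, contaminated] = rng.binomial(
                rna_depth_ctrl[r, contaminated], 0.25
            )
        dna_alt_c[contaminated] = rng.binomial(dna_depth_c[contaminated], 0.25)

    # ---- protein spectral counts ----------------------------------------
    pa_site = prot_tumor[gene_idx]
    nonzero = pa_site[pa_site > 0]
    pa_median = np.median(nonzero) if nonzero.size else 1.0
    p_det = config.p_ms_site * (1.0 - np.exp(-pa_site / pa_median))
    detected = rng.random(n) < p_det
    detected[planted_mask] = True
    elim_tl = rng.random(n) < config.p_not_translated_given_transcribed
    elim_tl[planted_mask] = False
    mut_translated = mut_transcribed & ~elim_tl & detected

    af_prot = np.where(
        mut_translated,
        np.clip(true_af * np.exp2(rng.normal(0.0, config.protein_af_log2_sd, n)),
                0.01, 0.95),
        0.0,
    )
    sc_rate = config.sc_rate_scale * np.log2(1.0 + pa_site)
    sc_wt = np.stack([
        rng.poisson(np.where(detected, sc_rate * (1 - af_prot), 0.0)) for _ in range(2)
    ])
    sc_mut = np.stack([
        rng.poisson(np.where(detected, sc_rate * af_prot, 0.0)) for _ in range(2)
    ])
    sc_wt[:, planted_mask] = 12
    sc_mut[:, planted_mask] = 8
    pc_site = prot_control[gene_idx]
    sc_rate_c = config.sc_rate_scale * np.log2(1.0 + pc_site)
    sc_wt_ctrl = np.stack([
        rng.poisson(np.where(detected, sc_rate_c, 0.0)) for _ in range(2)
    ])
    sc_wt_ctrl[:, planted_mask] = 20

    # planted drivers: generous, comparable evidence at every level
    dna_depth_t[planted_mask], dna_alt_t[planted_mask] = 110, 44
    dna_depth_c[planted_mask], dna_alt_c[planted_mask] = 110, 0

    # ---- assemble io objects --------------------------------------------
    site_records = _build_site_records(
        chroms, poss, refs, alts, site_genes, effects, pchanges,
        dna_depth_t, dna_alt_t, dna_depth_c, dna_alt_c,
    )
    rna_table = _build_count_table(
        "RNA", chroms, poss,
        tumor=(rna_depth, rna_alt), control=(rna_depth_ctrl, rna_alt_ctrl),
    )
    prot_table = _build_count_table(
        "PROTEIN", chroms, poss,
        tumor=(sc_wt + sc_mut, sc_mut), control=(sc_wt_ctrl, np.zeros_like(sc_wt_ctrl)),
    )
    rna_expr = _expression_table(
        rng, all_genes, tumor_fpkm, control_fpkm, "RNA", config.replicate_log2_sd
    )
    prot_expr = _expression_table(
        rng, all_genes, prot_tumor, prot_control, "PROTEIN", config.replicate_log2_sd
    )

    planted_genes = tuple(sorted(mut_genes[planted_gene_idx]))
    decoy_pool = np.setdiff1d(mut_genes, np.asarray(planted_genes))
    decoys = rng.choice(decoy_pool, size=config.n_decoy_driver_listed, replace=False)
    driver_list = set(planted_genes) | set(decoys.tolist())
    pathway_list = set(
        rng.choice(decoy_pool, size=config.n_pathway_genes, replace=False).tolist()
    )

    true_cluster = np.where(
        mut_translated, "Cluster_TL",
        np.where(
            mut_transcribed, "Cluster_nTL",
            np.where(true_af >= 0.12, "Cluster_nTCM", "Cluster_nTCS"),
        ),
    )
    truth_sites = pd.DataFrame({
        "chrom": chroms, "pos": poss, "gene": site_genes,
        "true_af": true_af, "clonal": clonal,
        "silent_gene": silent_site, "rna_covered": covered,
        "elim_transcription": elim_tx, "elim_translation": elim_tl,
        "ms_detected": detected,
        "mut_transcribed": mut_transcribed, "mut_translated": mut_translated,
        "control_contaminated": contaminated,
        "planted_driver": planted_mask,
        "true_cluster": true_cluster,
    })
    truth_genes = pd.DataFrame({
        "gene": all_genes, "group": group, "dpre_shift": shift,
        "silent": silent_gene,
        "tumor_fpkm": tumor_fpkm, "control_fpkm": control_fpkm,
    })

    return SyntheticDataset(
        config=config,
        site_records=site_records,
        rna_counts=rna_table,
        protein_counts=prot_table,
        rna_expr=rna_expr,
        protein_expr=prot_expr,
        somatic_genes=set(mut_genes.tolist()),
        germline_genes=set(germ_genes.tolist()),
        driver_genes=driver_list,
        pathway_genes=pathway_list,
        planted_drivers=planted_genes,
        truth=GroundTruth(sites=truth_sites, genes=truth_genes),
    )


def _generate_proportions(config: GeneratorConfig) -> SyntheticDataset:
    """Plant exact cluster memberships (nTCM, nTCS, nTL, TL proportions)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_sites
    counts = largest_remainder(config.cluster_proportions, n)
    labels = np.repeat(
        np.array(["Cluster_nTCM", "Cluster_nTCS", "Cluster_nTL", "Cluster_TL"]),
        counts,
    )
    labels = labels[rng.permutation(n)]

    true_af = np.empty(n)
    for label, (lo, hi) in (
        ("Cluster_nTCM", _NTCM_BAND), ("Cluster_nTCS", _NTCS_BAND),
    ):
        mask = labels == label
        margin = _BAND_MARGIN * (hi - lo)
        true_af[mask] = rng.uniform(lo + margin, hi - margin, mask.sum())
    expressed = np.isin(labels, ["Cluster_nTL", "Cluster_TL"])
    true_af[expressed] = rng.uniform(0.2, 0.5, expressed.sum())

    genes = np.array([f"PG{i:05d}" for i in range(n)])
    gene_idx = np.arange(n)
    chroms, poss, refs, alts, effects, pchanges = _site_identities(rng, n, gene_idx)

    # generous clamped depths; allele counts deterministic given the AF so the
    # planted split survives classification and filtering exactly
    dna_depth = np.maximum(rng.poisson(config.mean_dna_depth, n), 100)
    dna_alt = np.round(dna_depth * true_af).astype(int)
    rna_depth_rep = 80
    rna_alt_site = np.where(expressed, np.round(rna_depth_rep * true_af), 0).astype(int)
    translated = labels == "Cluster_TL"
    sc_total_rep = 10
    sc_mut_site = np.where(
        translated, np.maximum(np.round(sc_total_rep * true_af), 1), 0
    ).astype(int)
    sc_wt_site = np.where(translated | ~expressed | (labels == "Cluster_nTL"),
                          sc_total_rep - sc_mut_site, sc_total_rep)

    site_records = _build_site_records(
        chroms, poss, refs, alts, genes, effects, pchanges,
        dna_depth, dna_alt, dna_depth, np.zeros(n, dtype=int),
    )
    depth2 = np.stack([np.full(n, rna_depth_rep)] * 2)
    alt2 = np.stack([rna_alt_site] * 2)
    rna_table = _build_count_table(
        "RNA", chroms, poss,
        tumor=(depth2, alt2),
        control=(depth2, np.zeros_like(depth2)),
    )
    sc_tot2 = np.stack([sc_wt_site + sc_mut_site] * 2)
    sc_mut2 = np.stack([sc_mut_site] * 2)
    prot_table = _build_count_table(
        "PROTEIN", chroms, poss,
        tumor=(sc_tot2, sc_mut2),
        control=(np.stack([np.full(n, 5)] * 2), np.zeros((2, n), dtype=int)),
    )

    tumor_abund = 20.0 * np.exp2(rng.normal(0.0, 0.1, n))
    control_abund = 15.0 * np.exp2(rng.normal(0.0, 0.1, n))
    rna_expr = _expression_table(rng, genes, tumor_abund, control_abund, "RNA", 0.05)
    prot_expr = _expression_table(rng, genes, tumor_abund, control_abund, "PROTEIN", 0.05)

    truth_sites = pd.DataFrame({
        "chrom": chroms, "pos": poss, "gene": genes,
        "true_af": true_af, "clonal": np.zeros(n, dtype=bool),
        "silent_gene": np.zeros(n, dtype=bool),
        "rna_covered": np.ones(n, dtype=bool),
        "elim_transcription": ~expressed,
        "elim_translation": labels == "Cluster_nTL",
        "ms_detected": np.ones(n, dtype=bool),
        "mut_transcribed": expressed, "mut_translated": translated,
        "control_contaminated": np.zeros(n, dtype=bool),
        "planted_driver": np.zeros(n, dtype=bool),
        "true_cluster": labels,
    })
    truth_genes = pd.DataFrame({
        "gene": genes, "group": "somatic", "dpre_shift": 0.0,
        "silent": False, "tumor_fpkm": tumor_abund, "control_fpkm": control_abund,
    })

    return SyntheticDataset(
        config=config,
        site_records=site_records,
        rna_counts=rna_table,
        protein_counts=prot_table,
        rna_expr=rna_expr,
        protein_expr=prot_expr,
        somatic_genes=set(genes.tolist()),
        germline_genes=set(),
        driver_genes=set(),
        pathway_genes=set(),
        planted_drivers=(),
        truth=GroundTruth(sites=truth_sites, genes=truth_genes),
    )


def _build_site_records(chroms, poss, refs, alts, genes, effects, pchanges,
                        dt, at, dc, ac) -> list:
    records = []
    for i in range(len(chroms)):
        site = MutationSite(
            chrom=str(chroms[i]), pos=int(poss[i]),
            ref_allele=str(refs[i]), alt_allele=str(alts[i]),
            gene=str(genes[i]), effect=str(effects[i]),
            protein_change=str(pchanges[i]),
        )
        records.append(SiteRecord(site=site, dna={
            "tumor": AlleleCounts("DNA", "tumor", "R1",
                                  ref_count=int(dt[i] - at[i]), alt_count=int(at[i])),
            "control": AlleleCounts("DNA", "control", "R1",
                                    ref_count=int(dc[i] - ac[i]), alt_count=int(ac[i])),
        }))
    return records


def _build_count_table(level, chroms, poss, tumor, control) -> AlleleCountTable:
    """Stack per-replicate (depth, alt) arrays into a long count table.

    Rows are emitted only where depth > 0: absence of a row encodes an
    uncovered site, exactly as the readers interpret it.
    """
    frames = []
    for tissue, (depth, alt) in (("tumor", tumor), ("control", control)):
        for r in range(depth.shape[0]):
            mask = depth[r] > 0
            if not mask.any():
                continue
            frames.append(_count_frame(
                np.asarray(chroms)[mask], np.asarray(poss)[mask],
                [tissue] * int(mask.sum()), [f"R{r + 1}"] * int(mask.sum()),
                depth[r][mask] - alt[r][mask], alt[r][mask],
            ))
    if frames:
        frame = pd.concat(frames, ignore_index=True)
    else:
        frame = _count_frame([], [], [], [], [], [])
    return AlleleCountTable(frame, level)


def _expression_table(rng, genes, tumor, control, platform, rep_sd) -> ExpressionTable:
    rows = []
    for rep in ("R1", "R2"):
        noise_t = np.exp2(rng.normal(0.0, rep_sd, len(genes)))
        noise_c = np.exp2(rng.normal(0.0, rep_sd, len(genes)))
        rows.append(pd.DataFrame({
            "gene": genes, "replicate": rep,
            "exp_cancer": tumor * noise_t, "exp_cirrhosis": control * noise_c,
        }))
    return ExpressionTable(pd.concat(rows, ignore_index=True), platform)


# ---------------------------------------------------------------------------
# worked single-site fixtures

@dataclass(frozen=True)
class WorkedFixture:
    name: str
    site_records: list
    rna_counts: AlleleCountTable
    protein_counts: AlleleCountTable
    rna_expr: ExpressionTable
    protein_expr: ExpressionTable


def _fixture_hist1h4e() -> WorkedFixture:
    """Mutant peptide seen at the protein level (AF 12/667 ~ 0.018) while the
    mutant allele is absent from the mRNA (total read depth 69)."""
    site = MutationSite("chr6", 26205363, "A", "G", "HIST1H4E", "missense", "p.D86G")
    rec = SiteRecord(site=site, dna={
        "tumor": AlleleCounts("DNA", "tumor", "R1", ref_count=60, alt_count=50),
        "control": AlleleCounts("DNA", "control", "R1", ref_count=108, alt_count=0),
    })
    rna = AlleleCountTable(_count_frame(
        ["chr6", "chr6", "chr6"], [26205363] * 3,
        ["tumor", "tumor", "control"], ["R1", "R2", "R1"],
        [35, 34, 40], [0, 0, 0],
    ), "RNA")
    prot = AlleleCountTable(_count_frame(
        ["chr6", "chr6", "chr6"], [26205363] * 3,
        ["tumor", "tumor", "control"], ["R1", "R2", "R1"],
        [328, 327, 300], [6, 6, 0],
    ), "PROTEIN")
    expr = pd.DataFrame({
        "gene": ["HIST1H4E"] * 2, "replicate": ["R1", "R2"],
        "exp_cancer": [120.0, 118.0], "exp_cirrhosis": [90.0, 95.0],
    })
    return WorkedFixture(
        "hist1h4e", [rec], rna, prot,
        ExpressionTable(expr, "RNA"), ExpressionTable(expr.copy(), "PROTEIN"),
    )


def _fixture_hnf1a() -> WorkedFixture:
    """Both alleles translated at the known-driver site chr12:121431992."""
    site = MutationSite("chr12", 121431992, "G", "C", "HNF1A", "missense", "p.S247T")
    rec = SiteRecord(site=site, dna={
        "tumor": AlleleCounts("DNA", "tumor", "R1", ref_count=55, alt_count=30),
        "control": AlleleCounts("DNA", "control", "R1", ref_count=80, alt_count=0),
    })
    rna = AlleleCountTable(_count_frame(
        ["chr12"] * 3, [121431992] * 3,
        ["tumor", "tumor", "control"], ["R1", "R2", "R1"],
        [22, 18, 38], [10, 8, 0],
    ), "RNA")
    prot = AlleleCountTable(_count_frame(
        ["chr12"] * 3, [121431992] * 3,
        ["tumor", "tumor", "control"], ["R1", "R2", "R1"],
        [6, 4, 8], [2, 2, 0],
    ), "PROTEIN")
    expr = pd.DataFrame({
        "gene": ["HNF1A"] * 2, "replicate": ["R1", "R2"],
        "exp_cancer": [35.0, 33.0], "exp_cirrhosis": [40.0, 42.0],
    })
    return WorkedFixture(
        "hnf1a", [rec], rna, prot,
        ExpressionTable(expr, "RNA"), ExpressionTable(expr.copy(), "PROTEIN"),
    )


def _fixture_msh2() -> WorkedFixture:
    """Nonsense mutation in a mismatch-repair gene; the site itself is not
    covered by RNA-Seq although the gene is expressed."""
    site = MutationSite("chr2", 47630358, "C", "T", "MSH2", "nonsense", "p.Q10*")
    rec = SiteRecord(site=site, dna={
        "tumor": AlleleCounts("DNA", "tumor", "R1", ref_count=48, alt_count=41),
        "control": AlleleCounts("DNA", "control", "R1", ref_count=85, alt_count=0),
    })
    rna = AlleleCountTable.empty("RNA")
    prot = AlleleCountTable.empty("PROTEIN")
    expr = pd.DataFrame({
        "gene": ["MSH2"] * 2, "replicate": ["R1", "R2"],
        "exp_cancer": [8.0, 7.5], "exp_cirrhosis": [15.0, 16.0],
    })
    return WorkedFixture(
        "msh2", [rec], rna, prot,
        ExpressionTable(expr, "RNA"), ExpressionTable(expr.copy(), "PROTEIN"),
    )


def _fixture_empty() -> WorkedFixture:
    expr = pd.DataFrame(columns=["gene", "replicate", "exp_cancer", "exp_cirrhosis"])
    return WorkedFixture(
        "empty", [], AlleleCountTable.empty("RNA"), AlleleCountTable.empty("PROTEIN"),
        ExpressionTable(expr, "RNA"), ExpressionTable(expr.copy(), "PROTEIN"),
    )


WORKED_FIXTURES = {
    "hist1h4e": _fixture_hist1h4e,
    "hnf1a": _fixture_hnf1a,
    "msh2": _fixture_msh2,
    "empty": _fixture_empty,
}


def make_worked_fixture(name: str) -> WorkedFixture:
    """Byte-stable single-site fixtures for worked examples and doctests."""
    try:
        factory = WORKED_FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; registry: {sorted(WORKED_FIXTURES)}"
        ) from None
    return factory()
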