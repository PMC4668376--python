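import pandas as pd
import pytest

import allelotrace as at
from allelotrace.expression_classify import SitePattern
from allelotrace.io_formats import (
    AlleleCounts,
    AlleleCountTable,
    ExpressionTable,
    MutationSite,
    SiteRecord,
)
from allelotrace.synthetic_data import _count_frame


def _site(gene="GENE", pos=100):
    return MutationSite("chr1", pos, "A", "G", gene, "missense")


def _record(gene="GENE", pos=100):
    return SiteRecord(site=_site(gene, pos), dna={
        "tumor": AlleleCounts("DNA", "tumor", "R1", 60, 40),
        "control": AlleleCounts("DNA", "control", "R1", 100, 0),
    })


def _counts(level, rows):
    """rows: (pos, tissue, rep, ref, alt)"""
    return AlleleCountTable(_count_frame(
        ["chr1"] * len(rows), [r[0] for r in rows], [r[1] for r in rows],
        [r[2] for r in rows], [r[3] for r in rows], [r[4] for r in rows],
    ), level)


def _expr(platform, gene="GENE", cancer=10.0, cirrhosis=8.0):
    frame = pd.DataFrame({
        "gene": [gene, gene], "replicate": ["R1", "R2"],
        "exp_cancer": [cancer, cancer], "exp_cirrhosis": [cirrhosis, cirrhosis],
    })
    return ExpressionTable(frame, platform)


class TestClassifyTranscription:
    def test_both_alleles(self):
        rna = _counts("RNA", [(100, "tumor", "R1", 40, 35)])
        assert at.classify_transcription(_record(), rna, _expr("RNA")) == "BOTH"

    def test_unexpressed_gene(self):
        rna = _counts("RNA", [(100, "tumor", "R1", 40, 35)])
        status = at.classify_transcription(_record(), rna, _expr("RNA", cancer=0.0))
        assert status == "GENE_NOT_EXPRESSED"

    def test_expressed_gene_without_site_reads(self):
        status = at.classify_transcription(_record(), _counts("RNA", []), _expr("RNA"))
        assert status == "SITE_NOT_COVERED"

    def test_presence_threshold_boundary(self):
        # one stray mutant read is not presence at the default threshold;
        # lowering the threshold to 1 flips the call to BOTH
        rna = _counts("RNA", [(100, "tumor", "R1", 20, 1)])
        assert at.classify_transcription(
            _record(), rna, _expr("RNA"), at.PresenceRule(min_alt_reads=2)
        ) == "WT_ONLY"
        assert at.classify_transcription(
            _record(), rna, _expr("RNA"), at.PresenceRule(min_alt_reads=1)
        ) == "BOTH"

    def test_mut_only(self):
        rna = _counts("RNA", [(100, "tumor", "R1", 0, 15)])
        assert at.classify_transcription(_record(), rna, _expr("RNA")) == "MUT_ONLY"

    def test_missing_gene_expression_names_gene(self):
        rna = _counts("RNA", [(100, "tumor", "R1", 40, 35)])
        with pytest.raises(KeyError, match="GENE"):
            at.classify_transcription(
                _record(), rna, _expr("RNA", gene="OTHER")
            )


class TestClassifyTranslation:
    def test_both_alleles_tumor_specific(self):
        prot = _counts("PROTEIN", [(100, "tumor", "R1", 10, 4),
                                   (100, "control", "R1", 8, 0)])
        status, in_control = at.classify_translation(_record(), prot, _expr("PROTEIN"))
        assert status == "BOTH" and not in_control

    def test_mut_only(self):
        prot = _counts("PROTEIN", [(100, "tumor", "R1", 0, 3)])
        status, _ = at.classify_translation(_record(), prot, _expr("PROTEIN"))
        assert status == "MUT_ONLY"

    def test_mutant_in_control_is_flagged_and_excluded_from_identified(self):
        prot = _counts("PROTEIN", [(100, "tumor", "R1", 10, 4),
                                   (100, "control", "R1", 8, 3)])
        status, in_control = at.classify_translation(_record(), prot, _expr("PROTEIN"))
        assert status == "BOTH" and in_control
        pattern = SitePattern(_site(), "BOTH", status, mut_in_control_protein=in_control)
        assert not pattern.protein_identified
        assert not pattern.mutant_translated

    def test_gene_without_spectra(self):
        status, _ = at.classify_translation(
            _record(), _counts("PROTEIN", []), _expr("PROTEIN", cancer=0.0)
        )
        assert status == "GENE_NO_SPECTRUM"

    def test_gene_with_spectra_but_site_uncovered(self):
        status, _ = at.classify_translation(
            _record(), _counts("PROTEIN", []), _expr("PROTEIN")
        )
        assert status == "SITE_NOT_COVERED"


class TestWorkedFixtures:
    def test_hist1h4e_protein_af_but_no_mutant_mrna(self):
        fx = at.make_worked_fixture("hist1h4e")
        patterns = at.classify_patterns(
            fx.site_records, fx.rna_counts, fx.protein_counts,
            fx.rna_expr, fx.protein_expr,
        )
        p = patterns[0]
        assert p.transcription == "WT_ONLY"
        assert p.translation == "BOTH"
        assert p.sc_total == 667
        assert round(p.af_protein, 3) == 0.018
        assert p.dp_rna == 69

    def test_hnf1a_both_alleles_at_every_level(self):
        fx = at.make_worked_fixture("hnf1a")
        patterns = at.classify_patterns(
            fx.site_records, fx.rna_counts, fx.protein_counts,
            fx.rna_expr, fx.protein_expr,
        )
        p = patterns[0]
        assert p.transcription == "BOTH"
        assert p.translation == "BOTH"
        assert p.mutant_translated

    def test_msh2_site_not_covered_by_rna(self):
        fx = at.make_worked_fixture("msh2")
        patterns = at.classify_patterns(
            fx.site_records, fx.rna_counts, fx.protein_counts,
            fx.rna_expr, fx.protein_expr,
        )
        assert patterns[0].transcription == "SITE_NOT_COVERED"


def _patterns_from_counts(tx_counts, tl_counts):
    """Build minimal SitePattern lists pairing per-status counts positionally."""
    patterns = []
    tx_list = [s for s, n in tx_counts.items() for _ in range(n)]
    tl_list = [s for s, n in tl_counts.items() for _ in range(n)]
    size = max(len(tx_list), len(tl_list))
    tx_list += ["WT_ONLY"] * (size - len(tx_list))
    tl_list += ["GENE_NO_SPECTRUM"] * (size - len(tl_list))
    for i, (tx, tl) in enumerate(zip(tx_list, tl_list)):
        patterns.append(SitePattern(_site(gene=f"G{i}", pos=100 + i), tx, tl))
    return patterns


class TestSummaries:
    def test_transcribed_count_from_printed_composition(self):
        patterns = _patterns_from_counts(
            {"BOTH": 1981, "MUT_ONLY": 80, "WT_ONLY": 1688,
             "GENE_NOT_EXPRESSED": 1231, "SITE_NOT_COVERED": 0},
            {},
        )
        summary = at.summarize_patterns(patterns)
        assert summary.transcribed_n == 2061
        # status labels partition the input
        assert sum(summary.transcription_counts.values()) == summary.n_sites
        assert (
            summary.transcribed_n
            + summary.transcription_counts["WT_ONLY"]
            + summary.transcription_counts["SITE_NOT_COVERED"]
            + summary.transcription_counts["GENE_NOT_EXPRESSED"]
            == summary.n_sites
        )

    def test_translated_composition_percentages(self):
        patterns = _patterns_from_counts(
            {}, {"WT_ONLY": 281, "BOTH": 134, "MUT_ONLY": 40},
        )
        summary = at.summarize_patterns(patterns)
        assert summary.protein_identified_n == 455
        assert summary.translated_n == 174
        assert round(summary.translation_pct["WT_ONLY"], 1) == 61.8
        assert round(summary.translation_pct["MUT_ONLY"], 1) == 8.8

    def test_empty_input_flags_percentages_undefined(self):
        summary = at.summarize_patterns([])
        assert summary.n_sites == 0
        assert all(v is None for v in summary.transcription_pct.values())
        assert all(v is None for v in summary.translation_pct.values())

    @pytest.mark.parametrize("wt, mut, expected", [
        (281, 40, 241),
        (5, 5, 0),
        (0, 7, 0),
    ])
    def test_unexpressed_lower_bound(self, wt, mut, expected):
        assert at.unexpressed_lower_bound(wt, mut) == expected

    def test_cross_level_identification_fractions(self):
        # 455 protein-identified sites: 313 with the mutant allele in RNA,
        # 174 with the mutant allele in protein
        patterns = []
        for i in range(455):
            tx = "BOTH" if i < 313 else "WT_ONLY"
            tl = "BOTH" if i < 134 else ("MUT_ONLY" if i < 174 else "WT_ONLY")
            patterns.append(SitePattern(_site(gene=f"G{i}", pos=100 + i), tx, tl))
        out = at.cross_level_identification(patterns)
        assert out["denominator"] == 455
        assert (out["rna_n"], out["protein_n"]) == (313, 174)
        assert round(100 * out["rna_fraction"], 1) == 68.8
        assert round(100 * out["protein_fraction"], 1) == 38.2

    def test_cross_level_zero_denominator_flagged(self):
        out = at.cross_level_identification([])
        assert out["rna_fraction"] is None and out["protein_fraction"] is None


class TestGeneRollup:
    def test_most_expressed_status_wins(self):
        from allelotrace.expression_classify import gene_rollup

        patterns = [
            SitePattern(_site("G1", 100), "WT_ONLY", "GENE_NO_SPECTRUM"),
            SitePattern(_site("G1", 101), "BOTH", "WT_ONLY"),
            SitePattern(_site("G1", 102), "SITE_NOT_COVERED", "MUT_ONLY"),
            SitePattern(_site("G2", 200), "GENE_NOT_EXPRESSED", "GENE_NO_SPECTRUM"),
        ]
        rollup = gene_rollup(patterns)
        assert rollup["G1"] == ("BOTH", "MUT_ONLY")
        assert rollup["G2"] == ("GENE_NOT_EXPRESSED", "GENE_NO_SPECTRUM")


class TestSyntheticRecovery:
    def test_classification_accuracy_on_generous_depths(self):
        # with mean site depth >= 50 the presence rule recovers the generative
        # transcription flags almost perfectly
        config = at.GeneratorConfig(
            n_sites=1500, n_genes=1200, n_germline_genes=200,
            n_background_genes=300, rna_depth_scale=60.0, seed=5,
        )
        ds = at.generate_dataset(config)
        patterns = at.classify_patterns(
            ds.site_records, ds.rna_counts, ds.protein_counts,
            ds.rna_expr, ds.protein_expr,
        )
        truth = ds.truth.sites.set_index(["chrom", "pos"])["mut_transcribed"]
        eligible = ds.truth.sites.set_index(["chrom", "pos"])
        hits = total = 0
        mean_depth = 0
        for p in patterns:
            key = (p.site.chrom, p.site.pos)
            if not eligible.loc[key, "rna_covered"] or eligible.loc[key, "silent_gene"]:
                continue
            total += 1
            mean_depth += p.dp_rna or 0
            hits += p.mutant_transcribed == bool(truth.loc[key])
        assert mean_depth / total >= 50
        assert hits / total >= 0.95
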