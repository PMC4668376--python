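import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from helpers_oracles import bh_stepup_oracle, fisher_two_sided_oracle

import allelotrace as at
from allelotrace.io_formats import ExpressionTable


class TestFisherAse:
    @pytest.mark.parametrize("table", [(50, 50, 50, 50), (5, 5, 5, 5)])
    def test_identical_proportions_give_p_one(self, table):
        assert at.fisher_ase(*table) == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        assert at.fisher_ase(20, 0, 10, 10) == pytest.approx(
            fisher_two_sided_oracle(20, 0, 10, 10), rel=1e-9
        )

    def test_all_zero_table_is_untestable(self):
        assert at.fisher_ase(0, 0, 0, 0) is None

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            at.fisher_ase(-1, 2, 3, 4)

    @settings(derandomize=True, max_examples=200)
    @given(
        w1=st.integers(0, 12), m1=st.integers(0, 12),
        w2=st.integers(0, 12), m2=st.integers(0, 12),
    )
    def test_agrees_with_oracle_on_small_tables(self, w1, m1, w2, m2):
        ours = at.fisher_ase(w1, m1, w2, m2)
        oracle = fisher_two_sided_oracle(w1, m1, w2, m2)
        if oracle is None:
            assert ours is None
        else:
            assert ours == pytest.approx(oracle, rel=1e-8, abs=1e-12)


class TestBhFdr:
    def test_stepup_hand_computation(self):
        assert at.bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_passes_through(self):
        assert at.bh_fdr([0.2]) == pytest.approx([0.2])

    def test_all_ones_stay_one(self):
        assert at.bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_matches_stepup_oracle_and_bounds(self, ps):
        q = at.bh_fdr(ps)
        assert q == pytest.approx(bh_stepup_oracle(ps), rel=1e-12, abs=1e-12)
        assert np.all(q <= 1.0) and np.all(q >= np.asarray(ps) / len(ps))
        # order-preserving with respect to p
        order = np.argsort(ps, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestFoldChange:
    @pytest.mark.parametrize("cancer, cirrhosis, expected", [
        (2.0, 1.0, 1.0),
        (3.7, 0.0, 10.0),   # zero-control sentinel
        (0.0, 5.1, -10.0),  # zero-tumor sentinel
        (8.0, 8.0, 0.0),
    ])
    def test_values(self, cancer, cirrhosis, expected):
        assert at.fold_change(cancer, cirrhosis) == pytest.approx(expected)

    def test_both_zero_is_flagged_undefined(self):
        assert at.fold_change(0.0, 0.0) is None

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            at.fold_change(-1.0, 2.0)

    def test_configurable_sentinel(self):
        assert at.fold_change(3.7, 0.0, sentinel=5.0) == 5.0


class TestNormalizeFc:
    def test_hand_computed_example(self):
        out = at.normalize_fc([1, 2, 3, 4, 5])
        assert out == pytest.approx([-1.0, -0.5, 0.0, 0.5, 1.0])

    def test_constant_list_is_degenerate(self):
        with pytest.raises(ValueError, match="IQR"):
            at.normalize_fc([2.0, 2.0, 2.0])

    def test_output_median_is_zero(self):
        rng = np.random.default_rng(0)
        out = at.normalize_fc(rng.normal(3, 2, 101))
        assert np.median(out) == pytest.approx(0.0, abs=1e-12)

    def test_undefined_entries_preserved_as_nan_positions(self):
        out = at.normalize_fc([1.0, None, 2.0, 3.0, np.nan, 4.0, 5.0])
        assert np.isnan(out[1]) and np.isnan(out[4])
        assert out[[0, 2, 3, 5, 6]] == pytest.approx([-1, -0.5, 0, 0.5, 1])

    @settings(derandomize=True, max_examples=50)
    @given(
        shift=st.floats(-50, 50, allow_nan=False),
        scale=st.floats(0.01, 50, allow_nan=False),
    )
    def test_shift_invariance_and_inverse_scaling(self, shift, scale):
        base = np.array([0.5, 1.0, 2.0, 3.5, 7.0, 9.0])
        ref = at.normalize_fc(base)
        shifted = at.normalize_fc(base + shift)
        assert shifted == pytest.approx(ref, abs=1e-8)
        scaled = at.normalize_fc(base * scale)
        assert scaled == pytest.approx(ref, rel=1e-8)


def _expr(platform, rows):
    """rows: (gene, rep, cancer, cirrhosis)"""
    return ExpressionTable(pd.DataFrame(
        rows, columns=["gene", "replicate", "exp_cancer", "exp_cirrhosis"]
    ), platform)


class TestComputeDpre:
    def _tables(self):
        rna = _expr("RNA", [
            ("A", "R1", 4.0, 1.0), ("A", "R2", 3.0, 1.0),
            ("B", "R1", 1.0, 2.0), ("B", "R2", 1.0, 4.0),
            ("C", "R1", 2.0, 1.0), ("C", "R2", 3.0, 1.0),
            ("D", "R1", 4.0, 1.0), ("D", "R2", 1.0, 2.0),  # sign-inconsistent
            ("E", "R1", 6.0, 1.0), ("E", "R2", 5.0, 1.0),  # no protein record
        ])
        protein = _expr("PROTEIN", [
            ("A", "R1", 2.0, 2.0), ("B", "R1", 1.0, 1.0), ("C", "R1", 4.0, 1.0),
            ("D", "R1", 2.0, 1.0),
        ])
        return rna, protein

    def test_dpre_is_exactly_the_normalized_difference(self):
        rna, protein = self._tables()
        records, _ = at.compute_dpre(rna, protein, {"A"}, {"B"})
        for row in records.itertuples(index=False):
            assert row.dpre == pytest.approx(row.norm_fc_protein - row.norm_fc_rna)

    def test_sign_inconsistent_rna_gene_is_excluded(self):
        rna, protein = self._tables()
        records, excl = at.compute_dpre(rna, protein, set(), set())
        assert "D" not in set(records["gene"])
        assert ("D", "rna_inconsistent") in set(map(tuple, excl.to_numpy()))

    def test_gene_without_protein_record_logged(self):
        rna, protein = self._tables()
        records, excl = at.compute_dpre(rna, protein, set(), set())
        assert ("E", "no_protein_record") in set(map(tuple, excl.to_numpy()))

    def test_group_assignment_with_somatic_precedence(self):
        rna, protein = self._tables()
        records, _ = at.compute_dpre(rna, protein, {"A"}, {"A", "B"})
        groups = dict(zip(records["gene"], records["group"]))
        assert groups["A"] == "somatic"  # somatic wins over germline
        assert groups["B"] == "germline"
        assert groups["C"] == "none"

    def test_worked_difference(self):
        record = at.ase_dpre.DpreRecord(
            gene="X", replicate="R1", fc_rna=1.0, fc_protein=0.5,
            norm_fc_rna=0.1, norm_fc_protein=-0.4, dpre=-0.5, group="somatic",
        )
        assert record.dpre == pytest.approx(record.norm_fc_protein - record.norm_fc_rna)


class TestCompareGroups:
    def _frame(self, groups_values):
        rows = []
        for group, values in groups_values.items():
            for v in values:
                rows.append(dict(gene=f"g{len(rows)}", replicate="R1", dpre=v,
                                 group=group))
        return pd.DataFrame(rows)

    def test_identical_groups(self):
        values = list(np.linspace(-1, 1, 50))
        out = at.compare_dpre_groups(self._frame({"somatic": values, "none": values}))
        row = out.iloc[0]
        assert row.ks_stat == pytest.approx(0.0)
        assert row.ks_p == pytest.approx(1.0)

    def test_chi2_matches_closed_form(self):
        rng = np.random.default_rng(0)
        somatic = np.concatenate([-rng.uniform(0, 1, 580), rng.uniform(0, 1, 420)])
        none = np.concatenate([-rng.uniform(0, 1, 470), rng.uniform(0, 1, 530)])
        out = at.compare_dpre_groups(self._frame({"somatic": somatic, "none": none}))
        row = out.iloc[0]
        assert (row.prop_le0_a, row.prop_le0_b) == (0.47, 0.58)  # sorted group names
        # Pearson chi-square computed by hand from observed/expected counts
        observed = np.array([[580, 420], [470, 530]])
        total = observed.sum()
        expected = np.outer(observed.sum(1), observed.sum(0)) / total
        chi2 = ((observed - expected) ** 2 / expected).sum()
        from scipy.stats import chi2 as chi2_dist

        assert row.chi2_p == pytest.approx(chi2_dist.sf(chi2, df=1), rel=1e-9)

    def test_small_group_skipped(self):
        frame = self._frame({"somatic": [0.1], "none": list(np.linspace(-1, 1, 20))})
        assert len(at.compare_dpre_groups(frame)) == 0

    def test_graded_shifts_order_the_ecdfs_at_zero(self, default_pipeline):
        _, _, result = default_pipeline
        sub = result.dpre[result.dpre["replicate"] == "R1"]
        props = {
            g: (sub.loc[sub.group == g, "dpre"] <= 0).mean()
            for g in ("somatic", "germline", "none")
        }
        assert props["somatic"] >= props["germline"] >= props["none"]
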