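"""Patient stratification rules and marker group comparisons."""

import numpy as np
import pandas as pd
import pytest

from splicescreen.stats import student_t_two_sample
from splicescreen.strata import (
    ExprGroup,
    MutStatus,
    SplitRule,
    classify_mut_status,
    compare_marker_by_group,
    flag_pdl1_high,
    functional_group,
    split_by_expression,
)
from splicescreen.types import ExprMatrix, MutationRecord, VariantClass


def _expr(gene_values):
    """gene_values: {gene: {sample: fpkm}}"""
    return ExprMatrix(pd.DataFrame(gene_values).T)


class TestMutStatus:
    def _setup(self, n=20):
        samples = {f"P{i}": f"P{i}-T" for i in range(n)}
        vals = {f"P{i}-T": float(i + 1) for i in range(n)}
        return samples, _expr({"PBRM1": vals})

    def test_mutation_takes_precedence_over_expression(self):
        samples, expr = self._setup()
        muts = [MutationRecord("P0", "PBRM1", VariantClass.FRAMESHIFT)]
        status = classify_mut_status(muts, expr, "PBRM1", samples)
        assert status["P0"] == MutStatus.MUT  # despite lowest expression

    def test_silent_mutation_does_not_confer_mut(self):
        samples, expr = self._setup()
        muts = [MutationRecord("P19", "PBRM1", VariantClass.SILENT)]
        status = classify_mut_status(muts, expr, "PBRM1", samples)
        assert status["P19"] == MutStatus.WT

    def test_low_percentile_classified_low_expr(self):
        samples, expr = self._setup(100)
        status = classify_mut_status([], expr, "PBRM1", samples, low_pct=12)
        assert status["P0"] == MutStatus.LOW_EXPR  # bottom of the range
        assert status["P50"] == MutStatus.WT

    def test_gene_absent_is_error(self):
        samples, expr = self._setup()
        with pytest.raises(KeyError):
            classify_mut_status([], expr, "NOPE", samples)

    def test_brute_force_reclassification_oracle(self):
        rng = np.random.default_rng(0)
        n = 100
        samples = {f"P{i}": f"P{i}-T" for i in range(n)}
        fpkm = {f"P{i}-T": float(rng.gamma(3, 2)) for i in range(n)}
        expr = _expr({"G": fpkm})
        mut_pat = set(rng.choice(n, 25, replace=False))
        muts = [MutationRecord(f"P{i}", "G", VariantClass.MISSENSE) for i in mut_pat]
        status = classify_mut_status(muts, expr, "G", samples, low_pct=12)
        non_mut_vals = [fpkm[f"P{i}-T"] for i in range(n) if i not in mut_pat]
        cut = np.percentile(non_mut_vals, 12)
        for i in range(n):
            if i in mut_pat:
                expect = MutStatus.MUT
            elif fpkm[f"P{i}-T"] < cut:
                expect = MutStatus.LOW_EXPR
            else:
                expect = MutStatus.WT
            assert status[f"P{i}"] == expect


class TestExpressionSplit:
    def test_median_rule_ties_to_high(self):
        out = split_by_expression({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        assert out == {
            "a": ExprGroup.LOW, "b": ExprGroup.LOW,
            "c": ExprGroup.HIGH, "d": ExprGroup.HIGH,
        }
        # odd n: the median value itself goes high
        out = split_by_expression({"a": 1.0, "b": 2.0, "c": 3.0})
        assert out["b"] == ExprGroup.HIGH

    def test_constant_values_all_high_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = split_by_expression({"a": 2.0, "b": 2.0})
        assert set(out.values()) == {ExprGroup.HIGH}

    def test_tertile_partition_matches_sort_oracle(self):
        vals = {f"p{i}": v for i, v in enumerate([9.0, 1.0, 5.0, 3.0, 7.0, 2.0, 8.0, 4.0, 6.0])}
        out = split_by_expression(vals, SplitRule.TERTILE)
        order = sorted(vals, key=vals.get)
        assert all(out[k] == ExprGroup.LOW for k in order[:3])
        assert all(out[k] == ExprGroup.UNASSIGNED for k in order[3:6])
        assert all(out[k] == ExprGroup.HIGH for k in order[6:])

    def test_threshold_rule_requires_threshold(self):
        with pytest.raises(ValueError, match="threshold"):
            split_by_expression({"a": 1.0, "b": 2.0}, SplitRule.THRESHOLD)

    def test_all_missing_is_error(self):
        with pytest.raises(ValueError):
            split_by_expression({"a": float("nan")})


class TestMarkerFlag:
    def _expr_marker(self, vals):
        samples = {p: f"{p}-T" for p in vals}
        return _expr({"PD-L1": {f"{p}-T": v for p, v in vals.items()}}), samples

    def test_cut_is_strict(self):
        expr, samples = self._expr_marker({"P1": 1.75, "P2": 1.76})
        flags, _ = flag_pdl1_high(expr, "PD-L1", samples, cut=1.75)
        assert flags == {"P1": False, "P2": True}

    def test_per_stratum_percentages(self):
        expr, samples = self._expr_marker({"P1": 2.0, "P2": 1.0, "P3": 3.0, "P4": 0.5})
        strata = {"P1": "WT", "P2": "WT", "P3": "Mut", "P4": "Mut"}
        _, pct = flag_pdl1_high(expr, "PD-L1", samples, strata=strata)
        assert pct["WT"] == (50.0, 1, 2)
        assert pct["Mut"] == (50.0, 1, 2)

    def test_marker_absent_is_error(self):
        expr, samples = self._expr_marker({"P1": 1.0})
        with pytest.raises(KeyError):
            flag_pdl1_high(expr, "NOPE", samples)

    def test_wt_coupling_raises_flag_rate_with_psi(self, default_study, default_cfg):
        """In the synthetic construction the marker tracks the planted
        event's PSI only in non-mutant patients, so among WT patients the
        high-PSI half is flagged more often than the low-PSI half."""
        from splicescreen.types import Tissue

        bundles, gt = default_study
        b = bundles[0]
        gene = default_cfg.planted_event.gene
        samples = {s.patient_id: s.sample_id for s in b.samples_by_tissue(Tissue.TUMOR)}
        status = classify_mut_status(b.mutations, b.expr, gene, samples)
        psi_row = b.psi.row(gt.planted_event_id)
        wt = {p: s for p, s in samples.items() if status[p] == MutStatus.WT}
        psi_group = split_by_expression({p: psi_row[s] for p, s in wt.items()})
        flags, pct = flag_pdl1_high(
            b.expr, gt.marker_gene, wt, cut=1.75, strata=psi_group
        )
        assert pct["high"][0] > pct["low"][0]


class TestGroupComparison:
    def test_identical_groups_p_one(self):
        cmp = compare_marker_by_group({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]})
        assert cmp.p_values == (1.0,)

    def test_two_group_t_matches_closed_form(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        cmp = compare_marker_by_group({"a": a, "b": b}, marker="PD-L1")
        ref = student_t_two_sample(a, b)
        assert cmp.test == "t"
        assert cmp.p_values[0] == pytest.approx(ref.p_value, abs=1e-15)
        assert cmp.group_means == (2.0, 3.0)

    def test_three_groups_bonferroni_contrasts(self):
        rng = np.random.default_rng(1)
        groups = {k: rng.normal(m, 1, 10) for k, m in (("a", 0), ("b", 1), ("c", 2))}
        cmp = compare_marker_by_group(groups)
        assert cmp.test == "anova_bonferroni"
        assert len(cmp.p_values) == 3
        raw = [
            student_t_two_sample(groups[i], groups[j]).p_value
            for i, j in (("a", "b"), ("a", "c"), ("b", "c"))
        ]
        for adj, r in zip(cmp.p_values, raw):
            assert adj == pytest.approx(min(1.0, 3 * r), abs=1e-12)

    def test_tiny_group_is_error(self):
        with pytest.raises(ValueError, match="'b'"):
            compare_marker_by_group({"a": [1.0, 2.0], "b": [1.0]})


class TestFunctionalGroup:
    @pytest.mark.parametrize(
        "status,reg,expect",
        [
            (MutStatus.WT, ExprGroup.LOW, "high_E27"),
            (MutStatus.WT, ExprGroup.HIGH, "low_E27"),
            (MutStatus.MUT, ExprGroup.LOW, "low_E27"),
            (MutStatus.LOW_EXPR, ExprGroup.LOW, "low_E27"),
        ],
    )
    def test_rule(self, status, reg, expect):
        assert functional_group(status, reg) == expect
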