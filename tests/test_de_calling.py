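"""Unit and property tests for confirmation, TPM, Fisher, BH and DE gating.

The exact-test oracle here is an exhaustive hypergeometric enumeration over
the whole support of the 2x2 table with fixed margins, written from the
definition, independently of the implementation route.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirqtl import de_calling
from mirqtl.de_calling import (
    Contrast,
    ContrastError,
    bh_adjust,
    call_de,
    categorize_de,
    confirm_mirnas,
    fisher_exact_2x2,
    log2_fold_change,
    tpm_normalize,
    DECall,
)
from mirqtl.io_formats import CountMatrix, LibraryMeta, MirqtlError


from oracles import bh_stepup as bh_stepup_oracle
from oracles import fisher_enumeration as fisher_enumeration_oracle


class TestConfirmation:
    @pytest.mark.parametrize(
        "max_count, kept", [(10, True), (9, False), (11, True)]
    )
    def test_ten_reads_in_either_library_is_inclusive(self, tiny_meta, max_count, kept):
        cm = CountMatrix(
            ["mir-x"], ["GXN-6hC", "GXN-6hT"],
            np.array([[max_count, 0]]), tiny_meta,
        )
        confirmed = confirm_mirnas(cm, min_reads=10)
        assert ("mir-x" in confirmed.mirna_ids) is kept

    def test_zero_threshold_is_identity(self, tiny_counts):
        confirmed = confirm_mirnas(tiny_counts, min_reads=0)
        assert confirmed.mirna_ids == tiny_counts.mirna_ids
        assert np.array_equal(confirmed.counts, tiny_counts.counts)


class TestTPM:
    def test_definition(self, tiny_meta):
        cm = CountMatrix(
            ["mir-a", "mir-b"], ["GXN-6hC", "GXN-6hT"],
            np.array([[10, 2], [999_990, 2]]), tiny_meta,
        )
        tpm = tpm_normalize(cm)
        assert tpm.values[0, 0] == pytest.approx(10.0)
        assert tpm.values[:, 1] == pytest.approx([500_000.0, 500_000.0])

    def test_columns_sum_to_one_million(self, tiny_counts):
        tpm = tpm_normalize(tiny_counts)
        assert tpm.values.sum(axis=0) == pytest.approx([1e6, 1e6], rel=1e-9)

    def test_zero_total_library_named(self, tiny_meta):
        cm = CountMatrix(
            ["mir-a"], ["GXN-6hC", "GXN-6hT"], np.array([[5, 0]]), tiny_meta
        )
        with pytest.raises(MirqtlError, match="GXN-6hT"):
            tpm_normalize(cm)

    def test_meta_totals_override_matrix_sum(self):
        meta = {
            "L1": LibraryMeta("GXN", "control", 6, total_reads=1_000_000),
            "L2": LibraryMeta("GXN", "heat", 6, total_reads=2_000_000),
        }
        cm = CountMatrix(["mir-a"], ["L1", "L2"], np.array([[10, 10]]), meta)
        tpm = tpm_normalize(cm, total_from="meta")
        assert tpm.values[0] == pytest.approx([10.0, 5.0])


class TestLog2FoldChange:
    @pytest.mark.parametrize(
        "treat, ctrl, pseudo, expected",
        [
            (20.0, 5.0, 1e-12, 2.0),
            (5.0, 5.0, 0.25, 0.0),
            (0.0, 8.0, 1.0, math.log2(1 / 9)),  # == -3.169925...
        ],
    )
    def test_stated_formula(self, treat, ctrl, pseudo, expected):
        assert log2_fold_change(treat, ctrl, pseudo) == pytest.approx(expected)

    def test_zero_pseudo_rejected(self):
        with pytest.raises(ValueError):
            log2_fold_change(1.0, 1.0, 0.0)


class TestFisherExact:
    def test_symmetric_table_is_one(self):
        assert fisher_exact_2x2(5, 95, 5, 95) == pytest.approx(1.0)

    def test_extreme_table_closed_form(self):
        # both one-sided extremes have probability 1/C(20,10)
        assert fisher_exact_2x2(0, 10, 10, 0) == pytest.approx(
            2 / math.comb(20, 10), rel=1e-12
        )

    def test_deep_library_table_matches_enumeration(self):
        p = fisher_exact_2x2(10, 999_990, 40, 999_960)
        assert p == pytest.approx(fisher_enumeration_oracle(10, 999_990, 40, 999_960), rel=1e-10)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 5, 5, 5)

    @given(
        a=st.integers(0, 30), b=st.integers(0, 30),
        c=st.integers(0, 30), d=st.integers(0, 30),
    )
    @settings(derandomize=True, max_examples=300)
    def test_matches_enumeration_oracle_small_margins(self, a, b, c, d):
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            fisher_enumeration_oracle(a, b, c, d), rel=1e-10
        )


class TestBHAdjust:
    @pytest.mark.parametrize(
        "pvals, expected",
        [
            ([0.05, 0.05, 0.05], [0.05, 0.05, 0.05]),
            ([0.01, 0.04], [0.02, 0.04]),
            ([], []),
        ],
    )
    def test_hand_computed_stepup(self, pvals, expected):
        assert bh_adjust(pvals) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    @settings(derandomize=True, max_examples=200)
    def test_matches_oracle_and_never_decreases(self, pvals):
        adj = bh_adjust(pvals)
        assert adj == pytest.approx(bh_stepup_oracle(pvals))
        assert (adj >= np.asarray(pvals) - 1e-12).all()

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=10), st.randoms())
    @settings(derandomize=True, max_examples=100)
    def test_permutation_invariance(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        base = bh_adjust(pvals)
        permuted = bh_adjust([pvals[i] for i in perm])
        assert permuted == pytest.approx([base[i] for i in perm])


class TestCallDE:
    def _matrix(self, heat_counts, ctrl_counts, filler=100_000):
        meta = {
            "C": LibraryMeta("GXN", "control", 6),
            "T": LibraryMeta("GXN", "heat", 6),
        }
        ids = [f"mir-{i}" for i in range(len(heat_counts))] + ["filler"]
        counts = np.array(
            [[c, h] for c, h in zip(ctrl_counts, heat_counts)] + [[filler, filler]]
        )
        return CountMatrix(ids, ["C", "T"], counts, meta)

    def test_all_gates_must_pass(self):
        # mir-0 quadruples (passes), mir-1 rises 1.5x (fails the FC gate
        # despite a tiny p-value at these depths)
        cm = self._matrix(heat_counts=[4000, 3000], ctrl_counts=[1000, 2000])
        tpm = tpm_normalize(cm)
        calls = call_de(tpm, cm, Contrast("GXN", 6))
        by_id = {c.mirna_id: c for c in calls}
        assert by_id["mir-0"].direction == "up"
        assert by_id["mir-1"].direction == "ns"
        assert by_id["mir-1"].p_value <= 0.05  # it fails only on fold change

    def test_fdr_never_below_p(self):
        cm = self._matrix(heat_counts=[4000, 10, 55], ctrl_counts=[1000, 12, 50])
        tpm = tpm_normalize(cm)
        for call in call_de(tpm, cm, Contrast("GXN", 6)):
            assert call.fdr >= call.p_value - 1e-12

    def test_missing_contrast_library_rejected(self):
        cm = self._matrix(heat_counts=[10], ctrl_counts=[10])
        tpm = tpm_normalize(cm)
        with pytest.raises(ContrastError, match="24"):
            call_de(tpm, cm, Contrast("GXN", 24))


def _call(mirna, genotype, tp, direction):
    lfc = {"up": 2.0, "down": -2.0, "ns": 0.0}[direction]
    p = 0.001 if direction != "ns" else 0.9
    return DECall(mirna, genotype, tp, lfc, p, p, direction)


class TestCategorize:
    def test_same_direction_in_both_genotypes(self):
        cats = categorize_de(
            {
                "GXN": [_call("mir-a", "GXN", 6, "down")],
                "HJX": [_call("mir-a", "HJX", 6, "down")],
            }
        )
        assert cats == [de_calling.DECategory("mir-a", "co-regulated-same-direction")]

    def test_opposite_directions(self):
        cats = categorize_de(
            {
                "GXN": [_call("mir-a", "GXN", 6, "up")],
                "HJX": [_call("mir-a", "HJX", 6, "down")],
            }
        )
        assert cats[0].category == "co-regulated-opposite"

    def test_single_genotype_specific(self):
        cats = categorize_de(
            {
                "GXN": [_call("mir-a", "GXN", 6, "up")],
                "HJX": [_call("mir-a", "HJX", 6, "ns")],
            }
        )
        assert cats[0].category == "GXN-specific"

    def test_within_genotype_tie_counts_as_opposite(self):
        calls_gxn = [_call("mir-a", "GXN", 1, "up"), _call("mir-a", "GXN", 24, "down")]
        calls_hjx = [_call("mir-a", "HJX", 6, "down")]
        cats = categorize_de({"GXN": calls_gxn, "HJX": calls_hjx})
        assert cats[0].category == "co-regulated-opposite"
        cats = categorize_de({"GXN": calls_gxn, "HJX": calls_hjx}, tie_break="latest")
        assert cats[0].category == "co-regulated-same-direction"

    def test_every_de_mirna_categorised_exactly_once(self):
        cats = categorize_de(
            {
                "GXN": [_call("mir-a", "GXN", 6, "up"), _call("mir-b", "GXN", 6, "down")],
                "HJX": [_call("mir-c", "HJX", 6, "down")],
            }
        )
        assert sorted(c.mirna_id for c in cats) == ["mir-a", "mir-b", "mir-c"]

    def test_three_genotypes_rejected(self):
        with pytest.raises(MirqtlError):
            categorize_de({"A": [], "B": [], "C": []})
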