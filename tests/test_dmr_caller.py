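"""Fisher test, DMC calling, windowing, merging and DMR filters."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from dmrkit import (
    AnchorRegion,
    DMRThresholds,
    MethylomeTable,
    call_dmcs,
    call_dmrs,
    finalize_dmrs,
    fisher_exact_two_tailed,
    merge_anchor_regions,
    scan_anchor_regions,
    weighted_methylation,
)


def enumeration_fisher(a, b, c, d):
    """Independent oracle: exact two-tailed Fisher p by integer-arithmetic
    enumeration of all tables with the observed margins."""
    row1, col1, total = a + b, a + c, a + b + c + d
    k_min, k_max = max(0, row1 - (total - col1)), min(row1, col1)
    col2 = total - col1
    nums = [comb(col1, k) * comb(col2, row1 - k) for k in range(k_min, k_max + 1)]
    obs = nums[a - k_min]
    return sum(v for v in nums if v <= obs) / comb(total, row1)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((10, 0, 0, 10), 2 / 184756),
            ((5, 5, 5, 5), 1.0),
            ((3, 7, 7, 3), 33052 / 184756),
        ],
    )
    def test_known_tables(self, table, expected):
        assert fisher_exact_two_tailed(*table) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_tailed(0, 0, 0, 0)
        with pytest.raises(ValueError):
            fisher_exact_two_tailed(-1, 2, 3, 4)

    def test_matches_enumeration_small_margins(self):
        """Exhaustive agreement with the integer-enumeration oracle for all
        tables with row sums <= 12."""
        for r1 in range(13):
            for r2 in range(13):
                if r1 + r2 == 0:
                    continue
                for c1 in range(r1 + r2 + 1):
                    k_min = max(0, r1 - (r1 + r2 - c1))
                    k_max = min(r1, c1)
                    for a in range(k_min, k_max + 1):
                        table = (a, r1 - a, c1 - a, r2 - (c1 - a))
                        assert fisher_exact_two_tailed(*table) == pytest.approx(
                            enumeration_fisher(*table), abs=1e-9
                        )

    @given(st.tuples(*[st.integers(0, 40)] * 4).filter(lambda t: sum(t) > 0))
    def test_matches_scipy(self, table):
        """scipy's fisher_exact as an independent cross-check."""
        ours = fisher_exact_two_tailed(*table)
        theirs = stats.fisher_exact([[table[0], table[1]], [table[2], table[3]]])[1]
        assert ours == pytest.approx(theirs, abs=1e-9)


def _table(sample_id, rows):
    frame = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]
    )
    return MethylomeTable(sample_id, frame)


class TestCallDmcs:
    def test_extreme_difference_is_hyper_dmc(self):
        a = _table("a", [("c", 10, "+", "CG", 0, 10)])
        b = _table("b", [("c", 10, "+", "CG", 10, 0)])
        dmcs = call_dmcs(a, b, "CG")
        assert len(dmcs) == 1
        row = dmcs.iloc[0]
        assert row["direction"] == "hyper"
        assert row["p_value"] == pytest.approx(2 / 184756, rel=1e-9)
        assert row["delta"] == pytest.approx(1.0)

    def test_equal_proportions_not_dmc(self):
        a = _table("a", [("c", 10, "+", "CG", 5, 5)])
        b = _table("b", [("c", 10, "+", "CG", 5, 5)])
        assert len(call_dmcs(a, b, "CG")) == 0

    def test_low_coverage_site_not_tested(self):
        a = _table("a", [("c", 10, "+", "CG", 0, 2)])  # coverage 2 < 4
        b = _table("b", [("c", 10, "+", "CG", 10, 0)])
        assert len(call_dmcs(a, b, "CG")) == 0

    def test_invalid_context_rejected(self):
        a = _table("a", [("c", 10, "+", "CG", 5, 5)])
        with pytest.raises(ValueError):
            call_dmcs(a, a, "CXG")

    def test_swapping_samples_flips_direction_not_p(self):
        rows_a = [("c", p, "+", "CG", m, u) for p, m, u in
                  [(1, 0, 10), (5, 2, 8), (9, 10, 2), (13, 7, 7)]]
        rows_b = [("c", p, "+", "CG", m, u) for p, m, u in
                  [(1, 9, 1), (5, 9, 2), (9, 1, 12), (13, 6, 6)]]
        a, b = _table("a", rows_a), _table("b", rows_b)
        fwd = call_dmcs(a, b, "CG")
        rev = call_dmcs(b, a, "CG")
        assert list(fwd["pos"]) == list(rev["pos"])
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"])
        np.testing.assert_allclose(fwd["delta"], -rev["delta"])
        flip = {"hyper": "hypo", "hypo": "hyper"}
        assert [flip[d] for d in fwd["direction"]] == list(rev["direction"])


class TestAnchorScan:
    def test_three_dmcs_in_window_make_anchor(self):
        anchors = scan_anchor_regions([10, 60, 110], "c", "CG", "hyper")
        assert len(anchors) == 1
        a = anchors[0]
        assert (a.start, a.end, a.dmc_count) == (10, 111, 3)

    def test_two_dmcs_insufficient(self):
        assert scan_anchor_regions([10, 60], "c", "CG", "hyper") == []

    def test_sparse_dmcs_never_qualify(self):
        assert scan_anchor_regions([0, 300, 600], "c", "CG", "hyper") == []

    def test_empty_input(self):
        assert scan_anchor_regions([], "c", "CG", "hyper") == []

    def test_overlapping_windows_unioned_and_trimmed(self):
        # DMCs spanning > one window; qualifying windows overlap and union
        pos = [10, 60, 110, 160, 210, 260]
        anchors = scan_anchor_regions(pos, "c", "CG", "hyper")
        assert len(anchors) == 1
        assert (anchors[0].start, anchors[0].end) == (10, 261)
        assert anchors[0].dmc_count == 6


class TestMergeAnchors:
    def _anchor(self, start, end, n=3):
        return AnchorRegion("c", start, end, n, "CG", "hyper")

    def test_gap_below_threshold_merges(self):
        merged = merge_anchor_regions([self._anchor(100, 300), self._anchor(350, 500)])
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end, merged[0].dmc_count) == (100, 500, 6)

    def test_gap_of_exactly_100_not_merged(self):
        merged = merge_anchor_regions([self._anchor(100, 300), self._anchor(400, 500)])
        assert len(merged) == 2

    def test_single_anchor_unchanged(self):
        a = self._anchor(100, 300)
        assert merge_anchor_regions([a]) == [a]

    def test_overlapping_input_rejected(self):
        with pytest.raises(ValueError):
            merge_anchor_regions([self._anchor(100, 300), self._anchor(200, 400)])

    @given(
        st.lists(
            st.tuples(st.integers(0, 2000), st.integers(1, 300)), min_size=1, max_size=8
        )
    )
    def test_merge_idempotent(self, raw):
        # build disjoint anchors from sorted raw intervals
        anchors, cursor = [], 0
        for start, length in sorted(raw):
            s = max(start, cursor)
            anchors.append(AnchorRegion("c", s, s + length, 3, "CG", "hyper"))
            cursor = s + length + 1
        once = merge_anchor_regions(anchors)
        twice = merge_anchor_regions(once)
        assert once == twice


class TestWeightedMethylationAndFinalize:
    def test_weighted_methylation_pools_counts(self):
        t = _table("a", [("c", 5, "+", "CG", 5, 5), ("c", 8, "+", "CG", 10, 0)])
        assert weighted_methylation(("c", 0, 20), t, "CG") == pytest.approx(0.75)

    def test_fully_unmethylated_region(self):
        t = _table("a", [("c", 5, "+", "CG", 0, 7)])
        assert weighted_methylation(("c", 0, 20), t, "CG") == 0.0

    def test_zero_coverage_region_is_error(self):
        t = _table("a", [("c", 5, "+", "CG", 0, 7)])
        with pytest.raises(ValueError):
            weighted_methylation(("c", 100, 200), t, "CG")

    def _pair_with_region(self, n_sites=6, span=150, delta=0.35):
        rows_a, rows_b = [], []
        for i in range(n_sites):
            pos = 10 + i * (span // n_sites)
            rows_a.append(("c", pos, "+", "CG", 2, 8))  # level 0.2
            meth_b = int(round((0.2 + delta) * 10))
            rows_b.append(("c", pos, "+", "CG", meth_b, 10 - meth_b))
        return _table("a", rows_a), _table("b", rows_b)

    def test_region_passing_all_filters_kept(self):
        a, b = self._pair_with_region(n_sites=6, span=150, delta=0.4)
        anchor = AnchorRegion("c", 10, 140, 5, "CG", "hyper")
        dmrs = finalize_dmrs([anchor], a, b)
        assert len(dmrs) == 1
        assert dmrs[0].abs_delta == pytest.approx(0.4)

    def test_too_few_dmcs_dropped(self):
        a, b = self._pair_with_region(delta=0.4)
        anchor = AnchorRegion("c", 10, 140, 4, "CG", "hyper")
        assert finalize_dmrs([anchor], a, b) == []

    def test_short_region_dropped(self):
        a, b = self._pair_with_region(delta=0.4)
        anchor = AnchorRegion("c", 10, 90, 5, "CG", "hyper")
        assert finalize_dmrs([anchor], a, b) == []

    def test_small_delta_dropped(self):
        a, b = self._pair_with_region(delta=0.1)
        anchor = AnchorRegion("c", 10, 140, 5, "CG", "hyper")
        assert finalize_dmrs([anchor], a, b) == []

    def test_chh_threshold_applied(self):
        rows_a = [("c", 10 + i * 25, "+", "CHH", 0, 10) for i in range(6)]
        rows_b = [("c", 10 + i * 25, "+", "CHH", 1, 19) for i in range(6)]
        a, b = _table("a", rows_a), _table("b", rows_b)
        anchor = AnchorRegion("c", 10, 140, 5, "CHH", "hyper")
        assert finalize_dmrs([anchor], a, b) == []  # delta 0.05 < 0.10

    def test_thresholds_must_cover_all_contexts(self):
        with pytest.raises(ValueError, match="missing contexts"):
            DMRThresholds(min_abs_delta={"CG": 0.3})


class TestEndToEnd:
    def test_swapping_samples_flips_dmr_directions(self, sim_pair):
        _, ta, tb, _ = sim_pair
        fwd = call_dmrs(ta, tb, contexts=("CG",))
        rev = call_dmrs(tb, ta, contexts=("CG",))
        assert [(d.chrom, d.start, d.end) for d in fwd] == [
            (d.chrom, d.start, d.end) for d in rev
        ]
        flip = {"hyper": "hypo", "hypo": "hyper"}
        assert [flip[d.direction] for d in fwd] == [d.direction for d in rev]
        np.testing.assert_allclose(
            [d.abs_delta for d in fwd], [d.abs_delta for d in rev]
        )

    def test_planted_dmrs_recovered(self, sim_pair):
        from dmrkit import overlap_dmr_sets

        _, ta, tb, truth = sim_pair
        dmrs = call_dmrs(ta, tb, contexts=("CG",))
        recall = overlap_dmr_sets(truth.dmrs, dmrs).fraction_a_in_b
        assert recall >= 0.9
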