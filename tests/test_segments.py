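"""Segment calling, the minimum-overlap partition, and the ancient scan."""

import itertools

import numpy as np
import pandas as pd
import pytest

from csslqtl.segments import (BinCall, SegmentSet, call_bin_genotypes,
                              detect_ancient_is, merge_bins_to_segments,
                              partition_min_overlap)
from conftest import make_segment_sets, snp_panel_from_segments


def snp_table(calls, chrom="chr1"):
    n = len(calls)
    return pd.DataFrame({"chrom": chrom, "pos": (np.arange(n) + 1) * 10,
                         "donor_allele": "A", "recipient_allele": "G",
                         "L1": calls})


class TestBinCalls:
    @pytest.mark.parametrize("nd, nr, expected", [
        (30, 0, "donor_hom"),       # ratio infinite
        (2, 28, "recipient_hom"),   # 2/28 < 1/5
        (15, 15, "het"),            # between the two cutoffs
        (26, 4, "donor_hom"),       # 26/4 > 5
        (25, 5, "het"),             # exactly 5 is not greater than 5
        (0, 30, "recipient_hom"),
    ])
    def test_ratio_rule(self, nd, nr, expected):
        calls = [2.0] * nd + [0.0] * nr + [1.0] * (30 - nd - nr)
        bins = call_bin_genotypes(snp_table(calls), "L1")
        assert len(bins) == 1 and bins[0].state == expected

    def test_all_het_or_missing_is_het(self):
        bins = call_bin_genotypes(snp_table([1.0] * 30), "L1")
        assert bins[0].state == "het"

    def test_mostly_missing_inherits_previous_state(self):
        calls = [2.0] * 30 + [np.nan] * 20 + [2.0] * 10
        bins = call_bin_genotypes(snp_table(calls), "L1")
        assert [b.state for b in bins] == ["donor_hom", "donor_hom"]

    def test_mostly_missing_at_chromosome_start_is_het(self):
        calls = [np.nan] * 25 + [2.0] * 5 + [2.0] * 30
        bins = call_bin_genotypes(snp_table(calls), "L1")
        assert bins[0].state == "het"

    def test_terminal_partial_bin_dropped(self):
        bins = call_bin_genotypes(snp_table([2.0] * 45), "L1")
        assert len(bins) == 1

    def test_empty_table_raises(self):
        with pytest.raises(ValueError, match="empty"):
            call_bin_genotypes(snp_table([])[0:0], "L1")

    def test_unknown_line_raises(self):
        with pytest.raises(KeyError, match="unknown line"):
            call_bin_genotypes(snp_table([2.0] * 30), "L99")

    def test_unsorted_positions_raise(self):
        t = snp_table([2.0] * 30)
        t.loc[5, "pos"] = 1
        with pytest.raises(ValueError, match="strictly increasing"):
            call_bin_genotypes(t, "L1")


class TestMergeBins:
    def _bins(self, states):
        return [BinCall(chrom="chr1", snp_start=i * 30, snp_end=(i + 1) * 30,
                        pos_start=i * 300 + 1, pos_end=(i + 1) * 300,
                        donor_count=0, recipient_count=0, het_count=0,
                        missing_count=0, state=s)
                for i, s in enumerate(states)]

    def test_single_donor_run(self):
        seg = merge_bins_to_segments(
            self._bins(["donor_hom"] * 3 + ["recipient_hom"] * 2), "L1")
        assert len(seg.intervals) == 1
        iv = seg.intervals.iloc[0]
        assert (iv.start, iv.end, iv.state) == (0, 900, "donor_hom")

    def test_state_change_breaks_run(self):
        seg = merge_bins_to_segments(
            self._bins(["donor_hom", "het", "donor_hom"]), "L1")
        assert seg.intervals.state.tolist() == ["donor_hom", "het", "donor_hom"]

    def test_all_recipient_empty(self):
        seg = merge_bins_to_segments(self._bins(["recipient_hom"] * 4), "L1")
        assert len(seg.intervals) == 0

    def test_round_trip_recovers_breakpoints_within_one_bin(self):
        """Calling + merging on SNPs synthesized from known segments finds
        every true breakpoint to within one 30-SNP bin."""
        spacing, bin_bp = 100, 30 * 100
        truth = {
            "L1": [(60, 240, 2)],
            "L2": [(0, 120, 2), (300, 420, 1)],
            "L3": [(150, 450, 2)],
        }
        snps = snp_panel_from_segments(truth, n_snps=600, spacing=spacing,
                                       seed=3)
        for line, ivs in truth.items():
            bins = call_bin_genotypes(snps, line)
            seg = merge_bins_to_segments(bins, line)
            assert len(seg.intervals) == len(ivs)
            for (s, e, code), (_, iv) in zip(ivs, seg.intervals.iterrows()):
                assert abs(iv.start - s * spacing) <= bin_bp
                assert abs(iv.end - e * spacing) <= bin_bp
                assert iv.state == ("donor_hom" if code == 2 else "het")


def brute_force_min_partition(segment_sets):
    """Exhaustive minimality oracle for small instances: try every grouping
    of consecutive covered atoms and return the smallest valid marker count
    (valid = every segment is an exact union of whole markers)."""
    segs = [(iv.chrom, iv.start, iv.end)
            for s in segment_sets for _, iv in s.intervals.iterrows()]
    chroms = sorted({c for c, *_ in segs})
    total = 0
    for chrom in chroms:
        local = [(s, e) for c, s, e in segs if c == chrom]
        cuts = sorted({x for s, e in local for x in (s, e)})
        atoms = [(lo, hi) for lo, hi in zip(cuts[:-1], cuts[1:])
                 if any(s <= lo and e >= hi for s, e in local)]
        # group consecutive atoms: choose which internal junctions to drop
        junctions = [i for i in range(1, len(atoms))
                     if atoms[i - 1][1] == atoms[i][0]]
        best = None
        for keep in itertools.product([True, False], repeat=len(junctions)):
            kept = {j for j, k in zip(junctions, keep) if k}
            markers, cur = [], list(atoms[0])
            for i in range(1, len(atoms)):
                if atoms[i - 1][1] == atoms[i][0] and i not in kept:
                    cur[1] = atoms[i][1]
                else:
                    markers.append(tuple(cur))
                    cur = list(atoms[i])
            markers.append(tuple(cur))
            ok = all(
                sorted([m for m in markers if s <= m[0] and m[1] <= e])
                and s == min(m[0] for m in markers if s <= m[0] and m[1] <= e)
                and e == max(m[1] for m in markers if s <= m[0] and m[1] <= e)
                and sum(m[1] - m[0] for m in markers
                        if s <= m[0] and m[1] <= e) == e - s
                for s, e in local)
            if ok and (best is None or len(markers) < best):
                best = len(markers)
        total += best
    return total


class TestPartition:
    def test_breakpoint_union_example(self):
        sets = make_segment_sets({
            "A": [("chr1", 0, 10, "donor_hom")],
            "B": [("chr1", 5, 15, "donor_hom")],
        })
        part = partition_min_overlap(sets)
        assert part.markers[["start", "end"]].values.tolist() == [
            [0, 5], [5, 10], [10, 15]]
        assert part.membership.loc["A"].tolist() == [2, 2, 0]
        assert part.membership.loc["B"].tolist() == [0, 2, 2]

    def test_identical_segments_collapse_to_one_marker(self):
        sets = make_segment_sets({
            l: [("chr1", 100, 900, "donor_hom")] for l in "ABC"})
        part = partition_min_overlap(sets)
        assert len(part.markers) == 1

    def test_disjoint_segments_stay_separate(self):
        sets = make_segment_sets({
            f"L{i}": [("chr1", i * 100, i * 100 + 50, "donor_hom")]
            for i in range(5)})
        part = partition_min_overlap(sets)
        assert len(part.markers) == 5

    def test_abutting_same_line_segments_not_fused(self):
        sets = make_segment_sets({
            "A": [("chr1", 0, 5, "donor_hom"), ("chr1", 5, 10, "donor_hom")]})
        part = partition_min_overlap(sets)
        assert len(part.markers) == 2

    def test_invalid_interval_raises(self):
        with pytest.raises(ValueError, match="end <= start"):
            make_segment_sets({"A": [("chr1", 10, 10, "donor_hom")]})

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="at least one"):
            partition_min_overlap(make_segment_sets({}))

    def _random_instance(self, rng):
        n_lines = rng.integers(2, 7)
        cuts = np.sort(rng.choice(np.arange(1, 50), size=8, replace=False))
        sets = {}
        for i in range(n_lines):
            k = rng.integers(1, 3)
            ivs = []
            for _ in range(k):
                a, b = sorted(rng.choice(cuts, 2, replace=False))
                state = "het" if rng.random() < 0.2 else "donor_hom"
                if not any(a < e and b > s for _, s, e, _ in ivs):
                    ivs.append(("chr1", int(a), int(b), state))
            if ivs:
                sets[f"L{i}"] = ivs
        return make_segment_sets(sets) if sets else None

    def test_exact_union_and_disjoint_property(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            sets = self._random_instance(rng)
            if sets is None:
                continue
            part = partition_min_overlap(sets)
            mk = part.markers.sort_values("start")
            assert (mk.end.values[:-1] <= mk.start.values[1:]).all()
            for s in sets:
                for _, iv in s.intervals.iterrows():
                    cover = mk[(mk.start >= iv.start) & (mk.end <= iv.end)]
                    assert cover.start.min() == iv.start
                    assert cover.end.max() == iv.end
                    assert (cover.end - cover.start).sum() == iv.end - iv.start
                    col = part.membership.loc[s.line_id, cover.marker_id]
                    assert (col == (1 if iv.state == "het" else 2)).all()

    def test_matches_exhaustive_minimum(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            sets = self._random_instance(rng)
            if sets is None:
                continue
            part = partition_min_overlap(sets)
            assert len(part.markers) == brute_force_min_partition(sets)


class TestAncientScan:
    def test_no_difference_not_ancient(self):
        f = np.full(500, 0.3)
        res = detect_ancient_is(f, f)
        assert res.mean_freq_diff.iloc[0] == 0.0
        assert not res.is_ancient.iloc[0]

    def test_rule_application(self):
        f1 = np.full(500, 0.40)
        f2 = np.full(500, 0.10)
        res = detect_ancient_is(f1, f2)
        assert res.is_ancient.iloc[0]          # diff 0.3, maf 0.4

    def test_maf_filter(self):
        f1 = np.full(500, 0.31)
        f2 = np.full(500, 0.01)
        res = detect_ancient_is(f1, f2, maf_threshold=0.4)
        assert not res.is_ancient.iloc[0]      # diff 0.3 but maf 0.31 < 0.4

    def test_low_maf_not_ancient(self):
        res = detect_ancient_is(np.full(500, 0.04), np.full(500, 0.0))
        assert not res.is_ancient.iloc[0]      # maf 0.04 < 0.05 despite diff

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError, match="mismatched"):
            detect_ancient_is(np.zeros(10), np.zeros(9))

    def test_windowed_mean_is_direct_sum(self):
        rng = np.random.default_rng(4)
        f1 = rng.random(2000)
        f2 = rng.random(2000)
        res = detect_ancient_is(f1, f2, window=500)
        for i, row in res.iterrows():
            s = slice(i * 500, (i + 1) * 500)
            assert row.mean_freq_diff == pytest.approx(
                np.sum(f1[s] - f2[s]) / 500, abs=1e-12)

    def test_invariant_to_zero_difference_dilution(self):
        """Adding SNPs with zero frequency difference in proportion leaves
        the windowed mean difference unchanged."""
        base1, base2 = np.full(250, 0.5), np.full(250, 0.2)
        mix1 = np.empty(500)
        mix2 = np.empty(500)
        mix1[0::2], mix1[1::2] = base1, 0.3
        mix2[0::2], mix2[1::2] = base2, 0.3
        r_base = detect_ancient_is(base1, base2, window=250)
        r_mix = detect_ancient_is(mix1, mix2, window=500)
        assert r_mix.mean_freq_diff.iloc[0] == pytest.approx(
            r_base.mean_freq_diff.iloc[0] / 2, abs=1e-12)
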