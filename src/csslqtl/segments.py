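"""Introgression-segment calling, the minimum-overlap marker partition,
and the ancient-introgression frequency scan.

Segment calling works on parental-differentiating SNPs: sites where the two
parents carry different alleles, so that each line's allele state reveals
local ancestry.  SNPs are tallied in consecutive non-overlapping bins of 30;
a bin is donor-homozygous when donor calls outnumber recipient calls more
than 5:1 (the 25/5 rule), recipient-homozygous below 1:5, heterozygous in
between.  Runs of non-recipient bins merge into per-line segments.

The population-level partition ("principle of minimum overlap") splits the
introgressed footprint at the union of all segment endpoints; the resulting
atomic intervals are the smallest set of non-overlapping markers such that
every input segment is an exact union of markers.  Each atom junction is an
endpoint of some segment, so re-merging adjacent atoms with identical
line-membership can only ever fuse abutting same-line segments — which
would break the exact-union property — and is therefore guarded against.

The ancient-introgression scan detects donor tracts segregating in a
diversity panel: per window of 500 SNPs, the mean donor-allele frequency
difference between the two species panels must exceed 0.2 and the windowed
minor-haplotype frequency must exceed 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BinCall", "SegmentSet", "MarkerPartition",
    "call_bin_genotypes", "merge_bins_to_segments", "partition_min_overlap",
    "detect_ancient_is",
]

DONOR, HET, RECIPIENT, MISSING = 2, 1, 0, np.nan


@dataclass
class BinCall:
    """Genotype call for one bin of consecutive parental-differentiating SNPs."""

    chrom: str
    snp_start: int          # half-open indices into the chromosome's SNP list
    snp_end: int
    pos_start: int          # bp of the first SNP (1-based, as on disk)
    pos_end: int            # bp of the last SNP
    donor_count: int
    recipient_count: int
    het_count: int
    missing_count: int
    state: str              # donor_hom | het | recipient_hom


@dataclass
class SegmentSet:
    """Per-line introgression intervals (0-based half-open bp coordinates)."""

    line_id: str
    intervals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "start", "end", "state"]))
    provenance: str = "called"

    def __post_init__(self):
        iv = self.intervals
        if len(iv) and not (iv.end > iv.start).all():
            bad = iv[~(iv.end > iv.start)].iloc[0]
            raise ValueError(
                f"segment with end <= start for line {self.line_id}: "
                f"{bad.chrom}:{bad.start}-{bad.end}")


@dataclass
class MarkerPartition:
    """Non-overlapping markers tiling the introgressed footprint, with the
    per-line genotype membership matrix (0/1/2 = absent/het/donor_hom)."""

    markers: pd.DataFrame        # marker_id, chrom, start, end
    membership: pd.DataFrame     # lines x markers


def _validate_snp_table(snps: pd.DataFrame) -> None:
    if snps is None or len(snps) == 0:
        raise ValueError("empty SNP table")
    for col in ("chrom", "pos"):
        if col not in snps.columns:
            raise ValueError(f"SNP table missing required column {col!r}")
    for chrom, grp in snps.groupby("chrom", sort=False):
        pos = grp.pos.to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(
                f"SNP positions not strictly increasing on {chrom}")


def call_bin_genotypes(snps: pd.DataFrame, line_id: str, bin_size: int = 30,
                       ratio_hi: float = 5.0, ratio_lo: float = 0.2,
                       max_missing_frac: float = 0.5) -> list[BinCall]:
    """Call donor/het/recipient genotype for consecutive SNP bins of one line.

    ``snps`` holds columns chrom, pos (1-based, strictly increasing per
    chromosome) and one column per line coded 0=recipient, 1=het, 2=donor,
    NaN=missing.  Chromosome-terminal windows with fewer than ``bin_size``
    SNPs are dropped.  The ratio is taken on *allele* counts — a
    homozygous call contributes two alleles to its parent's tally and a
    heterozygous call contributes one to each (this is what makes a single
    miscalled SNP in a heterozygous tract harmless): > ``ratio_hi`` is
    donor_hom, < ``ratio_lo`` recipient_hom, else het.  A zero recipient
    tally with donor alleles present counts as infinite ratio (donor_hom);
    a bin with no called alleles at all is het.  A bin with more than
    ``max_missing_frac`` missing calls inherits the previous bin's state
    (het at the start of a chromosome).
    """
    _validate_snp_table(snps)
    if line_id not in snps.columns:
        raise KeyError(f"unknown line {line_id!r}")
    bins: list[BinCall] = []
    for chrom, grp in snps.groupby("chrom", sort=False):
        calls = grp[line_id].to_numpy(dtype=float)
        pos = grp.pos.to_numpy()
        prev_state = "het"
        for s in range(0, len(calls) - bin_size + 1, bin_size):
            window = calls[s:s + bin_size]
            nd = int(np.sum(window == DONOR))
            nr = int(np.sum(window == RECIPIENT))
            nh = int(np.sum(window == HET))
            nm = int(np.sum(np.isnan(window)))
            donor_alleles = 2 * nd + nh
            recipient_alleles = 2 * nr + nh
            if nm > max_missing_frac * bin_size:
                state = prev_state
            elif donor_alleles == 0 and recipient_alleles == 0:
                state = "het"
            elif recipient_alleles == 0:
                state = "donor_hom"          # ratio +inf
            elif donor_alleles / recipient_alleles > ratio_hi:
                state = "donor_hom"
            elif donor_alleles / recipient_alleles < ratio_lo:
                state = "recipient_hom"
            else:
                state = "het"
            prev_state = state
            bins.append(BinCall(chrom=chrom, snp_start=s, snp_end=s + bin_size,
                                pos_start=int(pos[s]),
                                pos_end=int(pos[s + bin_size - 1]),
                                donor_count=nd, recipient_count=nr,
                                het_count=nh, missing_count=nm, state=state))
    return bins


def merge_bins_to_segments(bins: list[BinCall], line_id: str = "") -> SegmentSet:
    """Fuse maximal runs of equal-state non-recipient bins into intervals.

    A state change or a recipient_hom bin breaks the run (no gap tolerance).
    Interval coordinates span from the first SNP of the first bin to the
    last SNP of the last bin, converted to 0-based half-open bp.
    """
    rows = []
    run: list[BinCall] = []

    def flush():
        if run and run[0].state != "recipient_hom":
            rows.append((run[0].chrom, run[0].pos_start - 1, run[-1].pos_end,
                         run[0].state))

    for b in bins:
        if run and (b.chrom != run[-1].chrom or b.state != run[-1].state
                    or b.snp_start != run[-1].snp_end):
            flush()
            run = []
        run.append(b)
    flush()
    iv = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    return SegmentSet(line_id=line_id, intervals=iv, provenance="called")


def partition_min_overlap(segment_sets: list[SegmentSet]) -> MarkerPartition:
    """Partition all lines' segments into the minimal non-overlapping markers.

    Splits the covered footprint of each chromosome at the union of all
    segment endpoints; adjacent atoms are re-merged only when their
    line-membership patterns are identical *and* no input segment ends at
    the junction (otherwise the exact-union invariant would break — every
    segment must remain a union of whole markers).
    """
    if not segment_sets or all(len(s.intervals) == 0 for s in segment_sets):
        raise ValueError("need at least one line with at least one segment")
    for s in segment_sets:
        SegmentSet(line_id=s.line_id, intervals=s.intervals)  # re-validate

    line_ids = [s.line_id for s in segment_sets]
    state_code = {"het": 1, "donor_hom": 2}
    marker_rows = []
    membership_cols: dict[str, np.ndarray] = {}
    chroms: list[str] = []
    for s in segment_sets:
        for c in s.intervals.chrom:
            if c not in chroms:
                chroms.append(c)

    for chrom in chroms:
        endpoints = set()
        per_line = []
        for s in segment_sets:
            iv = s.intervals[s.intervals.chrom == chrom]
            per_line.append(iv)
            endpoints.update(iv.start.tolist())
            endpoints.update(iv.end.tolist())
        cuts = sorted(endpoints)
        atoms = []
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            pattern = np.zeros(len(segment_sets), dtype=np.int8)
            for li, iv in enumerate(per_line):
                hit = iv[(iv.start <= lo) & (iv.end >= hi)]
                if len(hit):
                    pattern[li] = state_code[hit.state.iloc[0]]
            if pattern.any():
                atoms.append((lo, hi, pattern))
        # guarded re-merge of adjacent identical-membership atoms
        merged = []
        for lo, hi, pattern in atoms:
            if merged:
                plo, phi, ppat = merged[-1]
                junction_is_endpoint = any(
                    ((iv.start == lo) | (iv.end == lo)).any() for iv in per_line)
                if (phi == lo and np.array_equal(ppat, pattern)
                        and not junction_is_endpoint):
                    merged[-1] = (plo, hi, ppat)
                    continue
            merged.append((lo, hi, pattern))
        for lo, hi, pattern in merged:
            mid = f"M{len(marker_rows)+1}"
            marker_rows.append((mid, chrom, lo, hi))
            membership_cols[mid] = pattern

    markers = pd.DataFrame(marker_rows,
                           columns=["marker_id", "chrom", "start", "end"])
    membership = pd.DataFrame(membership_cols, index=line_ids)
    membership.index.name = "line_id"
    return MarkerPartition(markers=markers, membership=membership)


def detect_ancient_is(pop1_freqs, pop2_freqs, window: int = 500,
                      diff_threshold: float = 0.2,
                      maf_threshold: float = 0.05) -> pd.DataFrame:
    """Windowed donor-allele frequency scan for ancient introgression.

    ``pop1_freqs`` / ``pop2_freqs`` are positionally matched per-SNP
    donor-allele frequencies in the recipient-species panel and the
    donor-species panel.  SNPs are clustered into consecutive windows of
    ``window``; a window is flagged ancient when the mean frequency
    difference (pop1 - pop2 ... conventionally Fre_Gh - Fre_Gb) exceeds
    ``diff_threshold`` and the minor-haplotype frequency in the recipient
    panel, ``min(p, 1-p)`` of the windowed mean pop1 frequency, exceeds
    ``maf_threshold``.  Terminal windows shorter than ``window`` are
    dropped.
    """
    f1 = np.asarray(pop1_freqs, dtype=float)
    f2 = np.asarray(pop2_freqs, dtype=float)
    if f1.shape != f2.shape:
        raise ValueError("frequency vectors have mismatched lengths")
    if f1.size and (np.nanmin(np.minimum(f1, f2)) < 0
                    or np.nanmax(np.maximum(f1, f2)) > 1):
        raise ValueError("allele frequencies must lie in [0, 1]")
    rows = []
    for s in range(0, f1.size - window + 1, window):
        w1, w2 = f1[s:s + window], f2[s:s + window]
        diff = float(np.mean(w1 - w2))
        p = float(np.mean(w1))
        maf = min(p, 1.0 - p)
        rows.append((s, s + window, float(np.mean(w1)), float(np.mean(w2)),
                     diff, maf,
                     bool(diff > diff_threshold and maf > maf_threshold)))
    return pd.DataFrame(rows, columns=["snp_start", "snp_end", "fre_pop1",
                                       "fre_pop2", "mean_freq_diff", "maf",
                                       "is_ancient"])
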