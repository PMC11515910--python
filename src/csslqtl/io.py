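"""Schema-validated TSV readers and writers.

Everything on disk is tab-separated text with optional ``#``-prefixed
metadata header lines.  Coordinates follow the usual conventions: BED-like
segment and gene tables are 0-based half-open; SNP tables are 1-based
(VCF-like) and converted on read where needed.  Genotypes are coded
0/1/2 = aa/Aa/AA with NA for missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .segments import SegmentSet

__all__ = [
    "read_genotypes", "write_genotypes",
    "read_phenotypes", "write_table",
    "read_expression", "read_snp_table",
    "read_segments_bed", "write_segments_bed",
    "read_markers", "write_markers",
    "read_gene_bed",
]


def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def write_table(df: pd.DataFrame, path, metadata: dict | None = None,
                index: bool = False) -> None:
    """Write any result table as TSV with ``#key=value`` metadata lines."""
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"#{k}={v}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_genotypes(path) -> pd.DataFrame:
    """Lines x markers genotype matrix, first column line_id."""
    df = _read_tsv(path).set_index("line_id")
    vals = df.to_numpy(dtype=float)
    bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"genotype value {vals[i, j]!r} outside {{0,1,2,NA}} at line "
            f"{df.index[i]!r}, marker {df.columns[j]!r}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicated line id {dup!r}")
    return df


def write_genotypes(G, line_ids, marker_ids, path,
                    metadata: dict | None = None) -> None:
    df = pd.DataFrame(np.asarray(G), index=pd.Index(line_ids, name="line_id"),
                      columns=marker_ids)
    write_table(df, path, metadata=metadata, index=True)


def read_phenotypes(path) -> pd.DataFrame:
    """line_id plus one column per trait."""
    df = _read_tsv(path).set_index("line_id")
    if df.index.duplicated().any():
        raise ValueError("duplicated line id in phenotype table")
    return df


def read_expression(path) -> pd.DataFrame:
    """gene_id plus one column per line; values must be nonnegative."""
    df = _read_tsv(path).set_index("gene_id")
    if (df.to_numpy(dtype=float) < 0).any():
        raise ValueError("negative expression value")
    return df


def read_snp_table(path) -> pd.DataFrame:
    """Parental-differentiating SNP table: chrom, pos (1-based),
    donor_allele, recipient_allele, then one column per line coded
    0/1/2/NA."""
    df = _read_tsv(path)
    required = ["chrom", "pos", "donor_allele", "recipient_allele"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"SNP table missing columns {missing}")
    return df


def read_segments_bed(path) -> list[SegmentSet]:
    """BED6-like segments: chrom start end line_id . state."""
    df = _read_tsv(path, header=None,
                   names=["chrom", "start", "end", "line_id", "score", "state"])
    bad = df[df.start >= df.end]
    if len(bad):
        r = bad.iloc[0]
        raise ValueError(f"BED row with start >= end: {r.chrom}:{r.start}-{r.end} "
                         f"(line {r.line_id})")
    out = []
    for line_id, grp in df.groupby("line_id", sort=False):
        out.append(SegmentSet(line_id=str(line_id),
                              intervals=grp[["chrom", "start", "end", "state"]]
                              .reset_index(drop=True),
                              provenance="imported"))
    return out


def write_segments_bed(segment_sets: list[SegmentSet], path) -> None:
    with open(path, "w") as fh:
        for s in segment_sets:
            for _, iv in s.intervals.iterrows():
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s.line_id}\t.\t"
                         f"{iv.state}\n")


def read_markers(path) -> pd.DataFrame:
    df = _read_tsv(path)
    for col in ("marker_id", "chrom", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"marker table missing column {col!r}")
    if (df.start >= df.end).any():
        raise ValueError("marker with start >= end")
    return df


def write_markers(markers: pd.DataFrame, path,
                  metadata: dict | None = None) -> None:
    write_table(markers, path, metadata=metadata)


def read_gene_bed(path) -> pd.DataFrame:
    """Gene coordinates: chrom start end gene_id (BED4)."""
    df = _read_tsv(path, header=None,
                   names=["chrom", "start", "end", "gene_id"])
    if (df.start >= df.end).any():
        raise ValueError("gene with start >= end")
    return df[["gene_id", "chrom", "start", "end"]]
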