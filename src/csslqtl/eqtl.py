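"""Expression-QTL mapping and downstream regulatory analytics.

Per gene, expression is rank-transformed to normal scores (the qqnorm
convention) and scanned with the multi-locus additive/dominance mapper;
records with LOD >= 4 are kept and labelled local (marker within 1 Mb of
the gene on the same chromosome) or distal.  On top of the records sit:
hotspot detection (markers regulating >= 5x the mean number of eGenes per
eQTL), cross-timepoint sharing (same sign, additive effects within 2-fold),
QTL-eQTL colocalization (a shared marker within 300 kb of the QTL and
within 1 Mb of the gene), the genetic-perturbation network (eQTL-eGene
edges restricted to lines where the eGene is differentially expressed), and
shared homoeolog eQTLs (one marker regulating both subgenome copies).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .qtl import LassoConfig, scan_trait

__all__ = [
    "inverse_normal_transform", "scan_eqtl", "find_hotspots",
    "classify_sharing", "colocalize", "build_perturbation_network",
    "shared_homoeolog_eqtl",
]

log = logging.getLogger(__name__)


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based normal scores, matching R's qqnorm/ppoints convention.

    Scores are ``Phi^-1((r - a) / (n + 1 - 2a))`` with ``a = 3/8`` for
    n <= 10 and ``a = 1/2`` otherwise; ties get the average rank.  An
    all-equal input returns a zero vector with a warning.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations to transform")
    if np.all(x == x[0]):
        warnings.warn("constant input; inverse-normal transform is a zero vector")
        return np.zeros(n)
    a = 3.0 / 8.0 if n <= 10 else 0.5
    r = rankdata(x, method="average")
    return ndtri((r - a) / (n + 1.0 - 2.0 * a))


def _marker_gene_distance(mrow, grow) -> float:
    """Distance between nearest interval edges; 0 if overlapping; inf if on
    different chromosomes."""
    if mrow.chrom != grow.chrom:
        return np.inf
    if mrow.end <= grow.start:
        return float(grow.start - mrow.end)
    if grow.end <= mrow.start:
        return float(mrow.start - grow.end)
    return 0.0


def scan_eqtl(genotypes, expr: pd.DataFrame, gene_coords: pd.DataFrame,
              markers: pd.DataFrame, cfg: LassoConfig | None = None,
              lod_threshold: float = 4.0, local_window: float = 1_000_000,
              timepoint: str = "tp", transform: bool = True) -> pd.DataFrame:
    """Scan every gene's expression, keep loci with LOD >= threshold.

    ``genotypes``: (n_lines, n_markers) codes matching the row order of
    ``markers`` and the column order of ``expr``.  ``expr``: genes x lines
    FPKM.  ``gene_coords``: gene_id, chrom, start, end.  Genes with zero
    expression variance are skipped with a log entry.  Returns a DataFrame
    with gene_id, marker_id, timepoint, a_hat, d_hat, lod, distance and
    category (local/distal by the 1 Mb nearest-edge rule).
    """
    coords = gene_coords.set_index("gene_id")
    records = []
    for gene_id, row in expr.iterrows():
        y = row.to_numpy(dtype=float)
        if np.var(y) == 0.0:
            log.info("gene %s has zero expression variance; skipped", gene_id)
            continue
        if transform:
            y = inverse_normal_transform(y)
        table = scan_trait(genotypes, y, cfg, lod_threshold=lod_threshold,
                           trait_id=str(gene_id),
                           marker_ids=markers.marker_id.tolist())
        hits = table[table.significant]
        if not len(hits):
            continue
        grow = coords.loc[gene_id]
        for _, h in hits.iterrows():
            mrow = markers[markers.marker_id == h.marker].iloc[0]
            dist = _marker_gene_distance(mrow, grow)
            records.append({
                "gene_id": gene_id, "marker_id": h.marker,
                "timepoint": timepoint, "a_hat": h.a_hat, "d_hat": h.d_hat,
                "lod": max(h.lod_a, h.lod_d), "lod_a": h.lod_a,
                "lod_d": h.lod_d, "distance": dist,
                "category": "local" if dist <= local_window else "distal",
            })
    return pd.DataFrame(records, columns=[
        "gene_id", "marker_id", "timepoint", "a_hat", "d_hat", "lod",
        "lod_a", "lod_d", "distance", "category"])


def find_hotspots(records: pd.DataFrame, fold: float = 5.0,
                  per_timepoint: bool = True,
                  inclusive: bool = True) -> pd.DataFrame:
    """Flag eQTLs regulating at least ``fold`` times the mean eGene count.

    The mean number of eGenes per eQTL is computed over significant eQTLs,
    per timepoint by default (set ``per_timepoint=False`` to pool, which is
    how a single population-wide mean such as 17.9 eGenes/eQTL arises).
    """
    if not len(records):
        raise ValueError("no eQTL records")
    group_cols = ["marker_id"] + (["timepoint"] if per_timepoint else [])
    counts = (records.groupby(group_cols)["gene_id"].nunique()
              .rename("n_egenes").reset_index())
    if per_timepoint:
        means = counts.groupby("timepoint").n_egenes.transform("mean")
    else:
        means = pd.Series(counts.n_egenes.mean(), index=counts.index)
    counts["mean_egenes_per_eqtl"] = means
    thresh = fold * means
    counts["is_hotspot"] = (counts.n_egenes >= thresh if inclusive
                            else counts.n_egenes > thresh)
    return counts


def classify_sharing(records: pd.DataFrame, fold: float = 2.0) -> pd.DataFrame:
    """Cross-timepoint sharing of marker-gene eQTL pairs.

    A pair significant in two timepoints is shared between them when the
    additive effects have the same sign and differ by at most ``fold``;
    otherwise the eQTL is timepoint-specific.  Only pairs significant in at
    least two timepoints are classified.
    """
    out = []
    for (marker, gene), grp in records.groupby(["marker_id", "gene_id"]):
        tps = grp.timepoint.tolist()
        if len(tps) < 2:
            continue
        effects = dict(zip(grp.timepoint, grp.a_hat))
        shared_tps = set()
        for i, t1 in enumerate(tps):
            for t2 in tps[i + 1:]:
                e1, e2 = effects[t1], effects[t2]
                if e1 == 0 or e2 == 0 or np.sign(e1) != np.sign(e2):
                    continue
                ratio = max(abs(e1), abs(e2)) / min(abs(e1), abs(e2))
                if ratio <= fold:
                    shared_tps.update((t1, t2))
        out.append({
            "marker_id": marker, "gene_id": gene,
            "timepoints": sorted(tps),
            "effects": [effects[t] for t in sorted(tps)],
            "shared": bool(shared_tps),
            "timepoints_shared": sorted(shared_tps),
        })
    return pd.DataFrame(out, columns=["marker_id", "gene_id", "timepoints",
                                      "effects", "shared", "timepoints_shared"])


def colocalize(qtls: pd.DataFrame, eqtls: pd.DataFrame,
               markers: pd.DataFrame, gene_coords: pd.DataFrame,
               qtl_pad: float = 300_000,
               gene_window: float = 1_000_000) -> pd.DataFrame:
    """Match trait QTLs with eQTLs sharing a marker at the same site.

    For each significant QTL, the candidate set holds markers within
    ``qtl_pad`` (nearest edges) of the QTL marker on the same chromosome;
    for each gene, the eQTL set holds its significant eQTL markers within
    ``gene_window`` of the gene.  A (QTL, gene) pair colocalizes when the
    identical marker appears in both sets.
    """
    mk = markers.set_index("marker_id")
    coords = gene_coords.set_index("gene_id")
    sig_qtls = qtls[qtls.significant] if "significant" in qtls.columns else qtls
    rows = []
    for _, q in sig_qtls.iterrows():
        qrow = mk.loc[q.marker]
        near = mk[(mk.chrom == qrow.chrom)
                  & (mk.start < qrow.end + qtl_pad)
                  & (mk.end > qrow.start - qtl_pad)]
        candidate = set(near.index)
        for gene_id, grp in eqtls.groupby("gene_id"):
            grow = coords.loc[gene_id]
            for _, e in grp.iterrows():
                erow = mk.loc[e.marker_id]
                if _marker_gene_distance(erow, grow) > gene_window:
                    continue
                if e.marker_id in candidate:
                    rows.append({
                        "trait": q.trait, "qtl_marker": q.marker,
                        "gene_id": gene_id, "eqtl_marker": e.marker_id,
                        "timepoint": e.timepoint, "colocalized": True,
                    })
    return pd.DataFrame(rows, columns=["trait", "qtl_marker", "gene_id",
                                       "eqtl_marker", "timepoint",
                                       "colocalized"])


def build_perturbation_network(eqtls: pd.DataFrame, deg_calls: pd.DataFrame,
                               membership: pd.DataFrame,
                               deg_column: str = "is_deg_vs_recipient") -> pd.DataFrame:
    """Line-resolved eQTL-eGene edges of the genetic-perturbation network.

    An edge (line, marker, gene, timepoint) exists when the line carries the
    marker's introgression (membership code > 0), the marker is a
    significant eQTL of the gene at that timepoint, and the gene is
    differentially expressed in that line at that timepoint (``deg_calls``
    columns: gene_id, line_id, timepoint, and a boolean ``deg_column``).
    """
    degs = deg_calls[deg_calls[deg_column]]
    deg_index = set(zip(degs.gene_id, degs.line_id, degs.timepoint))
    rows = []
    for _, e in eqtls.iterrows():
        if e.marker_id not in membership.columns:
            continue
        carriers = membership.index[membership[e.marker_id] > 0]
        for line in carriers:
            if (e.gene_id, line, e.timepoint) in deg_index:
                rows.append({"line_id": line, "marker_id": e.marker_id,
                             "gene_id": e.gene_id, "timepoint": e.timepoint})
    return pd.DataFrame(rows, columns=["line_id", "marker_id", "gene_id",
                                       "timepoint"])


def shared_homoeolog_eqtl(eqtls: pd.DataFrame,
                          homoeolog_pairs: pd.DataFrame) -> pd.DataFrame:
    """Markers that regulate both members of a homoeologous gene pair.

    ``homoeolog_pairs`` has columns at_gene, dt_gene.  Returns
    (marker_id, at_gene, dt_gene) triples where the marker is a significant
    eQTL for both copies (any timepoint).
    """
    by_gene = eqtls.groupby("gene_id")["marker_id"].agg(set)
    rows = []
    for _, p in homoeolog_pairs.iterrows():
        m_at = by_gene.get(p.at_gene, set())
        m_dt = by_gene.get(p.dt_gene, set())
        for m in sorted(m_at & m_dt):
            rows.append({"marker_id": m, "at_gene": p.at_gene,
                         "dt_gene": p.dt_gene})
    return pd.DataFrame(rows, columns=["marker_id", "at_gene", "dt_gene"])
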