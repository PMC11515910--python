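"""Expression consequences of introgression: DEG calling against the two
parents, stable/altered pattern classification, extreme-expression rank
enrichment, and homoeolog/random pair co-expression.

A gene copy inherited from the donor can keep its donor expression state
("stable"), diverge from it ("altered"), or simply match both parents
("no_change").  DEGs use a fold-change rule (>= 3-fold either way, with a
pseudocount); pattern calls are then filtered on how often the gene is
differentially expressed in lines *not* carrying the introgression —
a stable call tolerates few background DE lines, an altered call demands
many, and failures fall into "ambiguous".
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "filter_expressed", "call_deg", "classify_pattern", "rank_enrichment",
    "pair_correlation",
]

log = logging.getLogger(__name__)


def filter_expressed(expr: pd.DataFrame, min_fpkm: float = 1.0,
                     min_lines: int = 3) -> pd.DataFrame:
    """Keep genes expressed above ``min_fpkm`` in at least ``min_lines``
    lines — the expressed-gene filter applied before pattern analyses."""
    keep = (expr > min_fpkm).sum(axis=1) >= min_lines
    return expr.loc[keep]


def call_deg(expr: pd.DataFrame, parent_means: pd.DataFrame,
             fold: float = 3.0, pseudocount: float = 0.1,
             timepoint: str = "tp") -> pd.DataFrame:
    """Per gene x line fold changes against each parent.

    ``parent_means`` has columns recipient, donor indexed by gene_id (means
    of >= 3 parental replicates).  A line is a DEG for a gene when the
    pseudocounted ratio is >= ``fold`` or <= 1/``fold`` (the boundary
    counts).  Negative expression raises.
    """
    if (expr.to_numpy() < 0).any() or (parent_means.to_numpy() < 0).any():
        raise ValueError("expression values must be nonnegative")
    genes = expr.index.intersection(parent_means.index)
    x = expr.loc[genes].to_numpy() + pseudocount
    rec = parent_means.loc[genes, "recipient"].to_numpy()[:, None] + pseudocount
    don = parent_means.loc[genes, "donor"].to_numpy()[:, None] + pseudocount
    fc_rec = x / rec
    fc_don = x / don
    deg_rec = (fc_rec >= fold) | (fc_rec <= 1.0 / fold)
    deg_don = (fc_don >= fold) | (fc_don <= 1.0 / fold)
    long = pd.DataFrame({
        "gene_id": np.repeat(genes.to_numpy(), expr.shape[1]),
        "line_id": np.tile(expr.columns.to_numpy(), len(genes)),
        "timepoint": timepoint,
        "fc_recipient": fc_rec.ravel(),
        "fc_donor": fc_don.ravel(),
        "is_deg_vs_recipient": deg_rec.ravel(),
        "is_deg_vs_donor": deg_don.ravel(),
    })
    return long


def classify_pattern(deg_calls: pd.DataFrame, introgressed: pd.DataFrame,
                     max_stable_bg: int = 7,
                     min_altered_bg: int = 20) -> pd.DataFrame:
    """Gene-level stable/altered/no_change/ambiguous pattern calls.

    ``introgressed`` is a boolean genes x lines matrix (does this line carry
    an introgression overlapping the gene).  Among carrier lines, a gene is
    no_change when no carrier differs from either parent; otherwise stable
    when the majority of carriers match the donor, altered when the
    majority differ from the donor (a tie is ambiguous).  The background
    filter then counts DE-vs-recipient calls among non-carrier lines
    (a non-introgressed line carries the recipient allele, so divergence
    from the recipient parent is the background-instability signal): stable
    survives only with <= ``max_stable_bg`` such lines, altered only with
    >= ``min_altered_bg``; failures become ambiguous.  Genes never
    introgressed are skipped with a log entry.
    """
    calls = deg_calls.set_index(["gene_id", "line_id"])
    rows = []
    for gene in introgressed.index:
        carriers = introgressed.columns[introgressed.loc[gene]]
        if len(carriers) == 0:
            log.info("gene %s carried by no line; skipped", gene)
            continue
        non_carriers = introgressed.columns[~introgressed.loc[gene]]
        sub = calls.loc[gene]
        car = sub.loc[sub.index.intersection(carriers)]
        bg = sub.loc[sub.index.intersection(non_carriers)]
        n_deg_donor = int(car.is_deg_vs_donor.sum())
        n_deg_any = int((car.is_deg_vs_donor | car.is_deg_vs_recipient).sum())
        n_bg_de = int(bg.is_deg_vs_recipient.sum())
        half = len(car) / 2.0
        if n_deg_any == 0:
            pattern = "no_change"
        elif n_deg_donor < half:
            pattern = "stable" if n_bg_de <= max_stable_bg else "ambiguous"
        elif n_deg_donor > half:
            pattern = "altered" if n_bg_de >= min_altered_bg else "ambiguous"
        else:
            pattern = "ambiguous"
        rows.append({"gene_id": gene, "pattern": pattern,
                     "n_carriers": len(car),
                     "n_carriers_deg_vs_donor": n_deg_donor,
                     "n_background_de": n_bg_de})
    return pd.DataFrame(rows, columns=["gene_id", "pattern", "n_carriers",
                                       "n_carriers_deg_vs_donor",
                                       "n_background_de"])


def rank_enrichment(expr: pd.DataFrame, introgressed: pd.DataFrame,
                    top_n_genes: int = 5000,
                    tail_frac: float = 0.05) -> dict:
    """Are introgressed gene copies enriched at extreme expression ranks?

    For each of the ``top_n_genes`` most-expressed genes, lines are sorted
    by that gene's expression; at every rank the fraction of genes whose
    line at that rank carries the introgression is recorded.  The ratio
    curve is fit with a least-squares quadratic in rank, and tail
    enrichment is the mean ratio in the bottom/top ``tail_frac`` of ranks
    divided by the mean ratio over the middle two quartiles.

    Returns a dict with keys ranks, ratio, quadratic (coefficients
    highest-degree first), r_squared, enrichment_low, enrichment_high.
    """
    order = expr.mean(axis=1).sort_values(ascending=False)
    genes = order.index[:top_n_genes]
    sub = expr.loc[genes]
    intro = introgressed.loc[genes, sub.columns].to_numpy()
    n_lines = sub.shape[1]
    counts = np.zeros(n_lines)
    x = sub.to_numpy()
    # per gene: sort lines by expression (stable to make ties deterministic)
    for i in range(len(genes)):
        idx = np.argsort(x[i], kind="stable")
        counts += intro[i, idx]
    ratio = counts / len(genes)
    ranks = np.arange(1, n_lines + 1)
    coeffs = np.polyfit(ranks, ratio, 2)
    fitted = np.polyval(coeffs, ranks)
    ss_res = float(np.sum((ratio - fitted) ** 2))
    ss_tot = float(np.sum((ratio - ratio.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    k = max(1, int(round(tail_frac * n_lines)))
    mid = ratio[n_lines // 4: n_lines - n_lines // 4]
    mid_mean = float(mid.mean())
    low = float(ratio[:k].mean())
    high = float(ratio[-k:].mean())
    return {
        "ranks": ranks, "ratio": ratio, "quadratic": coeffs,
        "r_squared": r2,
        "enrichment_low": low / mid_mean if mid_mean > 0 else np.inf,
        "enrichment_high": high / mid_mean if mid_mean > 0 else np.inf,
        "n_genes": len(genes), "n_lines": n_lines, "tail_size": k,
    }


def pair_correlation(expr: pd.DataFrame, pairs: pd.DataFrame,
                     pair_type: str = "homoeolog",
                     min_expressed: int = 3,
                     min_fpkm: float = 0.0) -> pd.DataFrame:
    """Spearman rank correlation of expression across lines for gene pairs.

    ``pairs`` has columns gene_a, gene_b.  Pairs where either member is
    expressed above ``min_fpkm`` in fewer than ``min_expressed`` lines, or
    has constant expression (undefined coefficient), are skipped with a
    flag column rather than dropped silently.
    """
    rows = []
    for _, p in pairs.iterrows():
        ok = p.gene_a in expr.index and p.gene_b in expr.index
        if not ok:
            rows.append({"gene_a": p.gene_a, "gene_b": p.gene_b,
                         "pair_type": pair_type, "rho": np.nan,
                         "flag": "missing_gene"})
            continue
        xa = expr.loc[p.gene_a].to_numpy(dtype=float)
        xb = expr.loc[p.gene_b].to_numpy(dtype=float)
        if ((xa > min_fpkm).sum() < min_expressed
                or (xb > min_fpkm).sum() < min_expressed):
            flag, rho = "not_expressed", np.nan
        elif np.all(xa == xa[0]) or np.all(xb == xb[0]):
            flag, rho = "constant", np.nan
        else:
            rho = float(spearmanr(xa, xb).statistic)
            flag = None
        rows.append({"gene_a": p.gene_a, "gene_b": p.gene_b,
                     "pair_type": pair_type, "rho": rho, "flag": flag})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "pair_type",
                                       "rho", "flag"])
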