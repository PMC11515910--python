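"""Synthetic CSSL populations, traits, expression, and the power study.

The generator emulates an introgression-line population: each line carries a
small number of contiguous donor segments (mostly homozygous, occasionally
heterozygous) over an ordered map of non-overlapping segment markers; all
remaining markers are recipient-homozygous.  Traits are simulated under the
additive+dominance model with each QTL's effect pair rescaled so that its
realized genetic-variance contribution on the generated genotypes hits an
exact target — calibration uses the empirical genotype frequencies of the
QTL's marker, not Hardy–Weinberg formulas, because a CSSL design is nothing
like a random-mating population.

`run_power_study` is the Monte Carlo engine: repeated trait simulation and
scanning on one fixed genotype draw, reporting per-QTL and average detection
power for additive and dominance effects and the false-positive rate over
non-QTL markers (per mille).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qtl import AA, Aa, LassoConfig, encode_design, scan_trait
from .segments import SegmentSet

__all__ = [
    "PopulationConfig", "TraitConfig", "PowerReport",
    "simulate_population", "simulate_trait", "choose_qtl_markers",
    "run_power_study", "simulate_expression", "plan_cis_eqtls",
]

#: default degrees of dominance for the eight simulated QTLs: one purely
#: additive (d/a = 0), one purely dominant (a = 0, coded as +inf), and six
#: additive-dominance QTLs spanning the stated range symmetrically.
DEFAULT_DOMINANCE_RATIOS = (0.0, np.inf, -3.0, -1.0, -0.5, 0.5, 1.0, 3.0)


@dataclass
class PopulationConfig:
    """Shape of the simulated introgression-line population.

    Defaults mirror the mapped population: 307 lines and a marker map that
    realizes ~1448 non-overlapping segment markers.  Per-line segment
    counts are 1 + Poisson(mean_segments - 1) clipped to
    [min_segments, max_segments]; the default mean of 3.96 reproduces the
    population total of ~1217 segments over 307 lines.  Segments are laid
    on a candidate-breakpoint grid ``grid_oversample`` times finer than
    the marker target with mean length ``mean_segment_markers`` markers,
    and the markers themselves are derived by the minimum-overlap
    principle, so adjacent markers are strongly correlated but never
    identical and every marker is carried by at least one line.  Segment
    placement is non-uniform: block-constant Gamma(hotspot_alpha) start
    weights emulate the introgression hotspots of designed CSSL
    libraries, so per-marker carrier counts span one to a few tens of
    lines (maximum in the high twenties at the defaults, matching the
    maximum introgression frequency of the mapped population).
    ``het_fraction`` is the probability that a carried segment is
    heterozygous rather than fixed (heterozygous tracts are rare in
    advanced-backcross material).
    """

    n_lines: int = 307
    n_markers: int = 1448
    min_segments: int = 1
    max_segments: int = 21
    mean_segments: float = 3.96
    mean_segment_markers: float = 5.0
    het_fraction: float = 0.10
    hotspot_alpha: float = 0.85
    grid_oversample: float = 2.4
    n_chromosomes: int = 26
    marker_length_bp: int = 1_500_000
    seed: int | None = None


@dataclass
class TraitConfig:
    """The Monte Carlo trait design: 8 QTLs of unit genetic variance each
    (total 8), residual variance 2, population mean 100."""

    mu: float = 100.0
    dominance_ratios: tuple = DEFAULT_DOMINANCE_RATIOS
    qtl_variance: float = 1.0
    residual_variance: float = 2.0
    qtl_markers: np.ndarray | None = None   # None = draw eligible markers
    seed: int | None = None


@dataclass
class PowerReport:
    """Outcome of a Monte Carlo power study."""

    dominance_ratios: tuple
    power_additive: np.ndarray       # per-QTL, % (NaN where a = 0)
    power_dominance: np.ndarray      # per-QTL, % (NaN where d = 0)
    avg_power_additive: float        # % over additive-effect QTLs
    avg_power_dominance: float       # % over dominance-effect QTLs
    fpr_per_mille: float             # significant non-QTL markers, per mille
    n_replicates: int
    n_lines: int
    n_markers: int
    lod_threshold: float

    def to_dict(self) -> dict:
        return {
            "dominance_ratios": [float(r) for r in self.dominance_ratios],
            "power_additive": [float(x) for x in self.power_additive],
            "power_dominance": [float(x) for x in self.power_dominance],
            "avg_power_additive": float(self.avg_power_additive),
            "avg_power_dominance": float(self.avg_power_dominance),
            "fpr_per_mille": float(self.fpr_per_mille),
            "n_replicates": self.n_replicates,
            "n_lines": self.n_lines,
            "n_markers": self.n_markers,
            "lod_threshold": self.lod_threshold,
        }


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _grid_layout(cfg: PopulationConfig, n_cells: int):
    """Chromosome id and bp span of each breakpoint-grid cell."""
    per = np.full(cfg.n_chromosomes, n_cells // cfg.n_chromosomes)
    per[: n_cells % cfg.n_chromosomes] += 1
    chrom_of = np.repeat(np.arange(cfg.n_chromosomes), per)
    total_bp = cfg.n_markers * cfg.marker_length_bp
    cell_bp = total_bp / n_cells
    offset = np.concatenate([[0], np.cumsum(per)])
    start_bp = np.empty(n_cells)
    for c in range(cfg.n_chromosomes):
        idx = np.arange(offset[c], offset[c + 1])
        start_bp[idx] = (idx - offset[c]) * cell_bp
    return chrom_of, start_bp, cell_bp


def simulate_population(cfg: PopulationConfig | None = None, rng=None):
    """Draw a CSSL genotype matrix and the matching per-line segment sets.

    Donor segments are placed on a fine candidate-breakpoint grid
    (``grid_oversample`` times the marker target), then the marker map is
    *derived* the same way it is from real data: maximal runs of grid
    cells with identical line-membership collapse into one marker and
    uncovered cells produce none (the minimum-overlap principle).  The
    realized marker count therefore fluctuates around ``n_markers``
    (``grid_oversample`` is calibrated for the defaults), every marker is
    carried by at least one line, and no two adjacent markers have
    identical membership — exactly the properties of a partition-derived
    map.

    Returns ``(G, segment_sets, markers)``: ``G`` is an
    (n_lines, n_realized_markers) int8 matrix coded 0/1/2 = aa/Aa/AA,
    ``segment_sets`` the per-line bp intervals, and ``markers`` the
    coordinate table (one row per realized marker).
    """
    cfg = cfg or PopulationConfig()
    rng = _rng(rng if rng is not None else cfg.seed)
    n_cells = max(int(round(cfg.n_markers * cfg.grid_oversample)),
                  cfg.n_chromosomes)
    if cfg.max_segments > cfg.n_markers:
        raise ValueError("more segments requested than markers available")
    chrom_of, start_bp, cell_bp = _grid_layout(cfg, n_cells)
    scale = n_cells / cfg.n_markers
    mean_extra = max(cfg.mean_segment_markers * scale - 1.0, 0.0)
    # one hotspot profile per population draw: start-position weights are
    # block-constant (~10 markers wide) so hotspots survive the smoothing
    # induced by multi-cell segment lengths
    block_cells = max(1, int(round(10 * scale)))
    n_blocks = max(1, n_cells // block_cells)
    block_w = rng.gamma(cfg.hotspot_alpha, 1.0, n_blocks)
    weights = block_w[np.minimum(np.arange(n_cells) // block_cells,
                                 n_blocks - 1)]
    weights = weights / weights.sum()

    Gc = np.zeros((cfg.n_lines, n_cells), dtype=np.int8)
    segment_sets = []
    for i in range(cfg.n_lines):
        k = 1 + int(rng.poisson(max(cfg.mean_segments - 1.0, 0.0)))
        k = int(np.clip(k, cfg.min_segments, cfg.max_segments))
        intervals = []
        occupied = np.zeros(n_cells, dtype=bool)
        for _ in range(k):
            for _try in range(100):
                L = 1 + int(rng.poisson(mean_extra))
                L = min(L, n_cells)
                s = int(rng.choice(n_cells, p=weights))
                s = min(s, n_cells - L)
                if not occupied[s:s + L].any():
                    break
            else:
                continue  # line too crowded to place another segment
            occupied[s:s + L] = True
            state = Aa if rng.random() < cfg.het_fraction else AA
            Gc[i, s:s + L] = state
            intervals.append((s, s + L, state))
        # coalesce abutting same-state draws: a segment caller would see
        # one continuous tract, not two
        merged = []
        for s, e, state in sorted(intervals):
            if merged and merged[-1][1] == s and merged[-1][2] == state:
                merged[-1][1] = e
            else:
                merged.append([s, e, state])
        rows = []
        for s, e, state in merged:
            # clip segments that straddle a simulated chromosome boundary
            for c in np.unique(chrom_of[s:e]):
                idx = np.arange(s, e)[chrom_of[s:e] == c]
                rows.append((f"chr{c+1:02d}", start_bp[idx[0]],
                             start_bp[idx[-1]] + cell_bp,
                             "het" if state == Aa else "donor_hom"))
        seg_df = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
        seg_df[["start", "end"]] = seg_df[["start", "end"]].round().astype(int)
        segment_sets.append(SegmentSet(line_id=f"L{i+1:03d}", intervals=seg_df,
                                       provenance="called"))

    # minimum-overlap merge: runs of covered cells with identical membership
    covered = (Gc > 0).any(axis=0)
    cols, marker_rows = [], []
    run_start = None
    for j in range(n_cells + 1):
        boundary = (j == n_cells or not covered[j]
                    or (run_start is not None
                        and (chrom_of[j] != chrom_of[j - 1]
                             or not np.array_equal(Gc[:, j], Gc[:, j - 1]))))
        if run_start is not None and boundary:
            cols.append(Gc[:, run_start].copy())
            marker_rows.append((f"M{len(cols)}",
                                f"chr{chrom_of[run_start]+1:02d}",
                                int(round(start_bp[run_start])),
                                int(round(start_bp[j - 1] + cell_bp))))
            run_start = None
        if j < n_cells and covered[j] and run_start is None:
            run_start = j
    G = np.column_stack(cols).astype(np.int8) if cols else \
        np.zeros((cfg.n_lines, 0), dtype=np.int8)
    markers = pd.DataFrame(marker_rows,
                           columns=["marker_id", "chrom", "start", "end"])
    return G, segment_sets, markers


def choose_qtl_markers(G, dominance_ratios, rng, min_carriers: int = 2,
                       min_hets: int = 2,
                       require_unique: bool = False) -> np.ndarray:
    """Draw one marker per QTL, uniformly among eligible markers.

    A marker is eligible when at least ``min_carriers`` lines carry the
    donor segment; QTLs with a dominance component additionally require
    ``min_hets`` heterozygous lines, without which the dominance variance
    target is unreachable.  ``require_unique`` additionally restricts to
    markers whose genotype column appears only once in the matrix (two
    separated regions carried by identical line sets make effect placement
    unidentifiable for any estimator).
    """
    G = np.asarray(G)
    carriers = (G > 0).sum(axis=0)
    hets = (G == Aa).sum(axis=0)
    homs = (G == AA).sum(axis=0)
    base_ok = (carriers >= min_carriers) & (homs >= 1)
    if require_unique:
        _, first, counts = np.unique(G.T, axis=0, return_index=True,
                                     return_counts=True)
        unique_cols = np.zeros(G.shape[1], dtype=bool)
        unique_cols[first[counts == 1]] = True
        base_ok &= unique_cols
    dom_ok = base_ok & (hets >= min_hets)
    chosen: list[int] = []
    for r in dominance_ratios:
        pool = np.flatnonzero((dom_ok if r != 0 else base_ok))
        pool = pool[~np.isin(pool, chosen)]
        if pool.size == 0:
            raise ValueError("no eligible marker left for QTL placement")
        chosen.append(int(rng.choice(pool)))
    return np.asarray(chosen, dtype=int)


def simulate_trait(G, cfg: TraitConfig | None = None, rng=None):
    """Simulate one trait under the additive+dominance model.

    Effects at each QTL are set from its dominance ratio (``d/a``; ``inf``
    means a purely dominant QTL with ``a = 0``) and rescaled so the QTL's
    realized genetic variance on these genotypes equals ``qtl_variance``
    exactly.  Returns ``(y, truth)`` where ``truth`` is a DataFrame with
    columns marker, a, d, d_over_a.
    """
    cfg = cfg or TraitConfig()
    rng = _rng(rng if rng is not None else cfg.seed)
    G = np.asarray(G, dtype=float)
    design = encode_design(G)
    W, V = design.W, design.V
    n = design.n

    if cfg.qtl_markers is None:
        qtl = choose_qtl_markers(G, cfg.dominance_ratios, rng)
    else:
        qtl = np.asarray(cfg.qtl_markers, dtype=int)
        if len(qtl) != len(cfg.dominance_ratios):
            raise ValueError("qtl_markers and dominance_ratios length mismatch")

    a_eff = np.zeros(len(qtl))
    d_eff = np.zeros(len(qtl))
    genetic = np.zeros(n)
    for q, (mk, r) in enumerate(zip(qtl, cfg.dominance_ratios)):
        a0, d0 = (0.0, 1.0) if np.isinf(r) else (1.0, float(r))
        g = W[:, mk] * a0 + V[:, mk] * d0
        var = float(np.var(g))
        if var <= 0.0:
            raise ValueError(
                f"QTL marker {mk} has zero genetic variance for d/a = {r}")
        s = np.sqrt(cfg.qtl_variance / var)
        a_eff[q], d_eff[q] = a0 * s, d0 * s
        genetic += g * s
    y = cfg.mu + genetic + rng.normal(0.0, np.sqrt(cfg.residual_variance), n)
    truth = pd.DataFrame({"marker": qtl, "a": a_eff, "d": d_eff,
                          "d_over_a": list(cfg.dominance_ratios)})
    return y, truth


def run_power_study(pop_cfg: PopulationConfig | None = None,
                    trait_cfg: TraitConfig | None = None,
                    lasso_cfg: LassoConfig | None = None,
                    n_replicates: int = 200, lod_threshold: float = 2.5,
                    redraw_genotypes: bool = False,
                    redraw_qtl_positions: bool = True,
                    seed: int | None = None,
                    progress=None) -> PowerReport:
    """Monte Carlo power and false-positive study of the mapping method.

    One genotype matrix is drawn and held fixed (``redraw_genotypes``
    resamples it each replicate); QTL marker positions are redrawn per
    replicate by default so the reported powers average over the carrier-
    frequency distribution of the map rather than one arbitrary placement.
    A QTL counts as additive-detected when the additive LOD at its own
    marker reaches the threshold (likewise for dominance); averages are
    taken over QTLs with a non-zero effect of the relevant kind.  The
    false-positive rate counts non-QTL markers whose additive or dominance
    LOD reaches the threshold, per (non-QTL marker x replicate), in per
    mille.
    """
    pop_cfg = pop_cfg or PopulationConfig()
    trait_cfg = trait_cfg or TraitConfig()
    lasso_cfg = lasso_cfg or LassoConfig()
    rng = _rng(seed)
    if lasso_cfg.seed is None:
        lasso_cfg = LassoConfig(**{**lasso_cfg.__dict__,
                                   "seed": int(rng.integers(2**31 - 1))})

    G, _, _ = simulate_population(pop_cfg, rng=rng)
    ratios = trait_cfg.dominance_ratios
    nq = len(ratios)
    add_mask = ~np.isinf(np.asarray(ratios))            # a != 0
    dom_mask = np.asarray(ratios) != 0.0                # d != 0
    hits_a = np.zeros(nq)
    hits_d = np.zeros(nq)
    false_pos = 0
    qtl_fixed = None
    if not redraw_qtl_positions:
        qtl_fixed = choose_qtl_markers(G, ratios, rng)

    m = G.shape[1]
    for rep in range(n_replicates):
        if redraw_genotypes:
            G, _, _ = simulate_population(pop_cfg, rng=rng)
        qtl = qtl_fixed if qtl_fixed is not None else choose_qtl_markers(G, ratios, rng)
        cfg_rep = TraitConfig(**{**trait_cfg.__dict__, "qtl_markers": qtl})
        y, truth = simulate_trait(G, cfg_rep, rng=rng)
        table = scan_trait(G, y, lasso_cfg, lod_threshold=lod_threshold)
        lod_a = table.lod_a.to_numpy()
        lod_d = table.lod_d.to_numpy()
        hits_a += (lod_a[qtl] >= lod_threshold)
        hits_d += (lod_d[qtl] >= lod_threshold)
        nonqtl = np.setdiff1d(np.arange(m), qtl)
        false_pos += int(np.sum(np.maximum(lod_a[nonqtl], lod_d[nonqtl])
                                >= lod_threshold))
        if progress is not None:
            progress(rep + 1, n_replicates)

    power_a = np.where(add_mask, 100.0 * hits_a / n_replicates, np.nan)
    power_d = np.where(dom_mask, 100.0 * hits_d / n_replicates, np.nan)
    fpr = 1000.0 * false_pos / ((m - nq) * n_replicates)
    return PowerReport(
        dominance_ratios=ratios,
        power_additive=power_a,
        power_dominance=power_d,
        avg_power_additive=float(np.nanmean(power_a[add_mask])),
        avg_power_dominance=float(np.nanmean(power_d[dom_mask])),
        fpr_per_mille=float(fpr),
        n_replicates=n_replicates,
        n_lines=G.shape[0],
        n_markers=m,
        lod_threshold=lod_threshold,
    )


# ------------------------------------------------------------- expression

def plan_cis_eqtls(markers: pd.DataFrame, G, n_genes: int,
                   effect: float = 2.0, rng=None,
                   min_carriers: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant one cis eQTL per gene: each gene sits inside a random marker
    with enough carriers and gets an additive effect of ``±effect`` (in
    units of the log-expression residual SD).

    Returns ``(gene_table, effects)`` ready for :func:`simulate_expression`.
    """
    rng = _rng(rng)
    G = np.asarray(G)
    carriers = (np.asarray(G) > 0).sum(axis=0)
    eligible = np.flatnonzero((carriers >= min_carriers)
                              & ((G == AA).sum(axis=0) >= 1))
    if eligible.size == 0:
        raise ValueError("no marker has enough carriers for a cis plan")
    idx = rng.choice(eligible, size=n_genes, replace=n_genes > eligible.size)
    genes, effects = [], []
    for g, j in enumerate(idx):
        row = markers.iloc[j]
        width = row.end - row.start
        gs = int(row.start + 0.4 * width)
        genes.append((f"G{g+1:05d}", row.chrom, gs, gs + max(1, width // 5),
                      float(rng.normal(2.0, 0.5))))
        effects.append((f"G{g+1:05d}", row.marker_id,
                        float(effect * rng.choice([-1.0, 1.0])), 0.0))
    gene_table = pd.DataFrame(genes, columns=["gene_id", "chrom", "start",
                                              "end", "log_baseline"])
    eff = pd.DataFrame(effects, columns=["gene_id", "marker_id",
                                         "additive", "dominance"])
    return gene_table, eff


def simulate_expression(G, gene_table: pd.DataFrame, effects: pd.DataFrame,
                        markers: pd.DataFrame, noise_sd: float = 1.0,
                        rng=None, line_ids=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an FPKM matrix with planted eQTL effects.

    Log expression of gene g in line i is
    ``log_baseline_g + sum_k (a_k w_ik + d_k v_ik) + N(0, noise_sd^2)`` and
    FPKM is its exponential (log-normal noise, as is typical of expression
    data).  ``effects`` may plant several markers per gene (trans effects,
    shared homoeolog eQTLs).  Returns ``(expr, truth)`` where ``expr`` is a
    genes x lines DataFrame and ``truth`` echoes the plan.
    """
    rng = _rng(rng)
    G = np.asarray(G, dtype=float)
    design = encode_design(G)
    n = design.n
    if line_ids is None:
        line_ids = [f"L{i+1:03d}" for i in range(n)]
    midx = {m: j for j, m in enumerate(markers.marker_id)}
    logx = np.tile(gene_table.log_baseline.to_numpy()[:, None], (1, n)).astype(float)
    gidx = {g: i for i, g in enumerate(gene_table.gene_id)}
    for _, row in effects.iterrows():
        i, j = gidx[row.gene_id], midx[row.marker_id]
        logx[i] += design.W[:, j] * row.additive + design.V[:, j] * row.dominance
    logx += rng.normal(0.0, noise_sd, size=logx.shape)
    expr = pd.DataFrame(np.exp(logx), index=gene_table.gene_id.to_numpy(),
                        columns=line_ids)
    expr.index.name = "gene_id"
    return expr, effects.copy()
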