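import numpy as np
import pandas as pd
import pytest

from csslqtl.segments import SegmentSet
from csslqtl.simulate import PopulationConfig, simulate_population


@pytest.fixture(scope="session")
def small_population():
    """An 80-line, 120-marker CSSL draw shared across tests."""
    cfg = PopulationConfig(n_lines=80, n_markers=120, n_chromosomes=4, seed=11)
    G, sets, markers = simulate_population(cfg)
    return np.asarray(G), sets, markers


def make_segment_sets(spec: dict) -> list[SegmentSet]:
    """Build SegmentSets from {line: [(chrom, start, end, state), ...]}."""
    out = []
    for line, ivs in spec.items():
        df = pd.DataFrame(ivs, columns=["chrom", "start", "end", "state"])
        out.append(SegmentSet(line_id=line, intervals=df))
    return out


def snp_panel_from_segments(truth: dict, n_snps: int = 600, spacing: int = 100,
                            error_rate: float = 0.01, missing_rate: float = 0.02,
                            seed: int = 0) -> pd.DataFrame:
    """Synthesize a parental-differentiating SNP table from known per-line
    donor segments given as {line: [(start_snp, end_snp, code), ...]} with
    half-open SNP-index intervals and code 2 (donor hom) or 1 (het)."""
    rng = np.random.default_rng(seed)
    pos = (np.arange(n_snps) + 1) * spacing
    table = {"chrom": ["chr1"] * n_snps, "pos": pos,
             "donor_allele": ["A"] * n_snps, "recipient_allele": ["G"] * n_snps}
    for line, ivs in truth.items():
        calls = np.zeros(n_snps)
        for s, e, code in ivs:
            calls[s:e] = code
        flip = rng.random(n_snps) < error_rate
        calls[flip] = rng.integers(0, 3, flip.sum())
        calls[rng.random(n_snps) < missing_rate] = np.nan
        table[line] = calls
    return pd.DataFrame(table)
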