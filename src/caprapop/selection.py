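"""Two-group selection-signature scans: per-SNP F_ST and the delta H-score.

F_ST uses Wright's two-population form on group allele frequencies:
with p_bar = (p_a + p_b)/2, H_T = 2 p_bar (1 - p_bar) and
H_S = [2 p_a (1 - p_a) + 2 p_b (1 - p_b)]/2, F_ST = (H_T - H_S)/H_T.
The delta H-score is the absolute difference between the two groups in the
proportion of animals whose ROH cover each SNP.  SNPs in the top quantile of
either statistic are retained and mapped onto user-supplied gene intervals;
genes hit by both scans form the consensus candidate list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, DataError, GenotypeMatrix, chrom_sort_key


@dataclass(frozen=True)
class GeneInterval:
    chrom: str
    start_bp: int  # 1-based inclusive
    end_bp: int
    name: str

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise DataError(f"gene {self.name}: start > end")


@dataclass
class ScanResult:
    """Per-SNP statistic track with top-quantile flags.

    ``records`` columns: snp, chrom, bp, value, rank (1 = largest, NaN for
    undefined values), selected.
    """

    records: pd.DataFrame
    statistic_name: str
    threshold_value: float
    n_selected: int

    @property
    def selected(self) -> pd.DataFrame:
        return self.records[self.records["selected"]]

    def to_tsv(self, path):
        self.records.to_csv(path, sep="\t", index=False)


def snp_fst(gm: GenotypeMatrix, group_a, group_b) -> np.ndarray:
    """Per-SNP Wright F_ST between two sample-id groups (NaN where undefined).

    A SNP is undefined when either group has fewer than 2 callable samples;
    F_ST is 0 by convention when H_T = 0, and clamped to [0, 1].
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    fst = np.full(gm.n_snps, np.nan)
    freqs = []
    defined = np.ones(gm.n_snps, dtype=bool)
    for grp in (group_a, group_b):
        calls = gm.calls[gm.sample_index(grp)]
        called = calls != MISSING
        n = called.sum(axis=0)
        defined &= n >= 2
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, calls, 0).sum(axis=0) / (2.0 * np.maximum(n, 1))
        freqs.append(p)
    pa, pb = freqs
    pbar = (pa + pb) / 2.0
    ht = 2.0 * pbar * (1.0 - pbar)
    hs = (2.0 * pa * (1.0 - pa) + 2.0 * pb * (1.0 - pb)) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        val = np.where(ht > 0, (ht - hs) / np.where(ht > 0, ht, 1.0), 0.0)
    val = np.clip(val, 0.0, 1.0)
    fst[defined] = val[defined]
    return fst


def delta_h(incidence_a: np.ndarray, incidence_b: np.ndarray) -> np.ndarray:
    """|incidence_a - incidence_b| per SNP."""
    incidence_a = np.asarray(incidence_a, dtype=np.float64)
    incidence_b = np.asarray(incidence_b, dtype=np.float64)
    if incidence_a.shape != incidence_b.shape:
        raise DataError("incidence tracks are on different SNP panels")
    return np.abs(incidence_a - incidence_b)


def select_top(gm: GenotypeMatrix, values: np.ndarray, fraction: float,
               statistic_name: str = "fst") -> ScanResult:
    """Flag the top ``floor(fraction * n_defined)`` SNPs by statistic value.

    Ordering is by value descending with a stable positional (chrom, bp)
    tie-break, so the flagged set is invariant to input permutations.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0,1)")
    values = np.asarray(values, dtype=np.float64)
    if values.size != gm.n_snps:
        raise DataError("values length must match SNP panel")
    defined = ~np.isnan(values)
    m = int(defined.sum())
    if m == 0:
        raise DataError("all statistic values are undefined")
    n_keep = math.floor(fraction * m)

    chrom_keys = [chrom_sort_key(s.chrom) for s in gm.snps]
    order = sorted(
        np.flatnonzero(defined),
        key=lambda j: (-values[j], chrom_keys[j], gm.snps[j].bp),
    )
    rank = np.full(gm.n_snps, np.nan)
    for r, j in enumerate(order, 1):
        rank[j] = r
    selected = np.zeros(gm.n_snps, dtype=bool)
    flagged = order[:n_keep]
    selected[flagged] = True
    threshold = float(values[flagged[-1]]) if flagged else float("nan")
    records = pd.DataFrame(
        {
            "snp": [s.id for s in gm.snps],
            "chrom": [s.chrom for s in gm.snps],
            "bp": [s.bp for s in gm.snps],
            "value": values,
            "rank": rank,
            "selected": selected,
        }
    )
    return ScanResult(
        records=records,
        statistic_name=statistic_name,
        threshold_value=threshold,
        n_selected=int(selected.sum()),
    )


def read_bed_genes(path) -> list:
    """Gene intervals from a BED file (0-based half-open on disk; converted
    to 1-based inclusive in memory)."""
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise DataError(f"{path}: line {ln}: need chrom,start,end,name")
            genes.append(
                GeneInterval(
                    chrom=parts[0],
                    start_bp=int(parts[1]) + 1,
                    end_bp=int(parts[2]),
                    name=parts[3],
                )
            )
    return genes


def map_to_genes(scan: ScanResult, genes, flank_bp: int = 0) -> list:
    """(snp_id, gene_name) for flagged SNPs inside flanked gene intervals.

    Flagged SNPs overlapping no interval are reported with gene ``None``.
    """
    pairs = []
    sel = scan.selected
    for snp_id, chrom, bp in zip(sel["snp"], sel["chrom"], sel["bp"]):
        hit = False
        for g in genes:
            if g.chrom == chrom and g.start_bp - flank_bp <= bp <= g.end_bp + flank_bp:
                pairs.append((snp_id, g.name))
                hit = True
        if not hit:
            pairs.append((snp_id, None))
    return pairs


def consensus_hits(scan_a: ScanResult, scan_b: ScanResult, genes,
                   flank_bp: int = 0) -> list:
    """Genes hit by flagged SNPs in both scans (sorted name list)."""
    hits_a = {g for _, g in map_to_genes(scan_a, genes, flank_bp) if g is not None}
    hits_b = {g for _, g in map_to_genes(scan_b, genes, flank_bp) if g is not None}
    return sorted(hits_a & hits_b)
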