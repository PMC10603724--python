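"""Effective population size from binned linkage disequilibrium.

Under the Sved relation, expected r-squared between loci at recombination
distance c Morgans is approximately 1/(alpha + 4 Ne c), where alpha absorbs
the mutation model (1 without mutation).  Observed dosage r-squared, corrected
for finite sample size by subtracting 1/(2n), therefore yields
Ne = (1/(4c)) * (1/r2_adj - alpha) per distance bin, with each bin's midpoint
mapping to a time horizon of t = 1/(2c) generations ago: short-range LD
reflects ancient population size, long-range LD recent size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class NeEstimate:
    generations_ago: float
    c_morgans: float
    mean_r2: float
    r2_adj: float
    ne: float  # NaN when r2_adj <= 0 (flagged undefined)
    n_pairs: int


def pairwise_r2(gm: GenotypeMatrix, breed: str, max_dist_mb: float):
    """Intra-chromosomal dosage r-squared for SNP pairs within ``max_dist_mb``.

    Returns ``(distances_bp, r2)`` arrays over all chromosomes.  r-squared is
    the squared Pearson correlation of genotype dosages over jointly called
    samples; pairs with zero variance at either SNP are skipped.
    """
    idx = gm.breed_index(breed)
    if idx.size < 10:
        warnings.warn(
            f"breed {breed!r} has only {idx.size} samples; r2 will be noisy",
            stacklevel=2,
        )
    calls = gm.calls[idx]
    chroms = gm.chroms
    pos = gm.positions
    max_bp = max_dist_mb * 1e6
    out_d, out_r2 = [], []
    for c in sorted(set(chroms)):
        snp_idx = np.flatnonzero(chroms == c)
        if snp_idx.size < 2:
            continue
        g = calls[:, snp_idx].astype(np.float64)
        called = (calls[:, snp_idx] != MISSING).astype(np.float64)
        g0 = np.where(called > 0, g, 0.0)
        # pairwise moments over jointly called samples, via matmuls
        n = called.T @ called
        sx = g0.T @ called
        sy = sx.T
        sxy = g0.T @ g0
        sxx = (g0 * g0).T @ called
        syy = sxx.T
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = n * sxy - sx * sy
            varx = n * sxx - sx**2
            vary = n * syy - sy**2
            r2 = cov**2 / (varx * vary)
        bp = pos[snp_idx].astype(np.float64)
        dist = np.abs(bp[:, None] - bp[None, :])
        iu, ju = np.triu_indices(snp_idx.size, k=1)
        ok = (
            (dist[iu, ju] <= max_bp)
            & (n[iu, ju] >= 2)
            & (varx[iu, ju] > 0)
            & (vary[iu, ju] > 0)
        )
        out_d.append(dist[iu, ju][ok])
        out_r2.append(r2[iu, ju][ok])
    if not out_d:
        return np.array([]), np.array([])
    return np.concatenate(out_d), np.concatenate(out_r2)


def bins_from_generations(generations, rel_width: float = 0.10):
    """(c_lo, c_hi, c_mid) bins from target generations via c = 1/(2t).

    Each bin is a +-``rel_width`` multiplicative window around its midpoint.
    """
    bins = []
    for t in generations:
        if t <= 0:
            raise ValueError("generations must be positive")
        c = 1.0 / (2.0 * float(t))
        bins.append((c * (1.0 - rel_width), c * (1.0 + rel_width), c))
    return bins


def ne_trend(
    pairs,
    bins,
    n_samples: int,
    alpha: float = 1.0,
    cm_per_mb: float = 1.0,
):
    """Binned Ne estimates from a ``(distances_bp, r2)`` pair stream.

    ``bins`` are ``(c_lo, c_hi)`` or ``(c_lo, c_hi, c_mid)`` tuples in
    Morgans; physical distance maps to c via ``cm_per_mb``/100 per Mb.
    Bins whose sample-size-adjusted r2 is non-positive get ne = NaN.
    """
    if len(bins) == 0:
        raise ValueError("bins must be non-empty")
    dist_bp, r2 = pairs
    dist_bp = np.asarray(dist_bp, dtype=np.float64)
    r2 = np.asarray(r2, dtype=np.float64)
    c_pairs = dist_bp / 1e6 * cm_per_mb / 100.0
    correction = 1.0 / (2.0 * n_samples)
    out = []
    for b in bins:
        if len(b) == 3:
            lo, hi, mid = b
        else:
            lo, hi = b
            mid = (lo + hi) / 2.0
        if lo <= 0 or hi <= 0:
            raise ValueError("bin bounds must be positive")
        sel = (c_pairs >= lo) & (c_pairs < hi)
        n_pairs = int(sel.sum())
        mean_r2 = float(r2[sel].mean()) if n_pairs else float("nan")
        r2_adj = mean_r2 - correction
        if n_pairs and r2_adj > 0:
            ne = (1.0 / (4.0 * mid)) * (1.0 / r2_adj - alpha)
        else:
            ne = float("nan")
        out.append(
            NeEstimate(
                generations_ago=1.0 / (2.0 * mid),
                c_morgans=mid,
                mean_r2=mean_r2,
                r2_adj=r2_adj,
                ne=ne,
                n_pairs=n_pairs,
            )
        )
    return out


def write_ne_tsv(estimates, path, breed: str = "") -> None:
    with open(path, "w") as fh:
        fh.write("breed\tgenerations_ago\tc_morgans\tmean_r2\tr2_adj\tne\tn_pairs\n")
        for e in estimates:
            fh.write(
                f"{breed}\t{e.generations_ago:.2f}\t{e.c_morgans:.6f}\t"
                f"{e.mean_r2:.6f}\t{e.r2_adj:.6f}\t{e.ne:.2f}\t{e.n_pairs}\n"
            )
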