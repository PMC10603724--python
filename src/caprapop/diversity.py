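"""Per-breed heterozygosity and Wright's within-population fixation index.

For breed samples at SNP l with alternate-allele frequency p_l:
He_l = 2 p_l (1 - p_l), Ho_l = heterozygote fraction among non-missing calls.
Breed-level He and Ho are means over SNPs with at least one callable
genotype, and F_IS = (He - Ho) / He (0 by convention when He = 0); positive
values indicate a heterozygote deficit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class DiversityRow:
    breed: str
    he: float
    ho: float
    fis: float
    n_samples: int
    n_snps: int


def breed_diversity(gm: GenotypeMatrix, breed: str,
                    small_sample_correction: bool = False) -> DiversityRow:
    """He, Ho and F_IS for one breed.

    With ``small_sample_correction`` the per-SNP He is rescaled by
    2n_l/(2n_l - 1) (unbiased gene diversity); off by default.
    """
    idx = gm.breed_index(breed)
    if idx.size < 2:
        raise ValueError(f"breed {breed!r} needs >= 2 samples, has {idx.size}")
    calls = gm.calls[idx]
    called = calls != MISSING
    n = called.sum(axis=0)
    usable = n > 0
    if not usable.any():
        raise ValueError(f"breed {breed!r} has no callable SNP")
    alt = np.where(called, calls, 0).sum(axis=0)
    p = alt[usable] / (2.0 * n[usable])
    he_l = 2.0 * p * (1.0 - p)
    if small_sample_correction:
        nn = n[usable]
        he_l = np.where(nn > 0.5, he_l * (2.0 * nn) / (2.0 * nn - 1.0), he_l)
    ho_l = (calls == 1)[:, usable].sum(axis=0) / n[usable]
    he = float(he_l.mean())
    ho = float(ho_l.mean())
    fis = float((he - ho) / he) if he > 0 else 0.0
    return DiversityRow(breed=breed, he=he, ho=ho, fis=fis,
                        n_samples=int(idx.size), n_snps=int(usable.sum()))


def diversity_table(gm: GenotypeMatrix, **kwargs) -> list:
    """DiversityRow for every breed, in first-appearance order."""
    return [breed_diversity(gm, b, **kwargs) for b in gm.breeds]


def write_diversity_tsv(rows, path) -> None:
    with open(path, "w") as fh:
        fh.write("breed\tn\the\tho\tfis\n")
        for r in rows:
            fh.write(f"{r.breed}\t{r.n_samples}\t{r.he:.4f}\t{r.ho:.4f}\t{r.fis:.4f}\n")
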