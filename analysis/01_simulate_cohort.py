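#!/usr/bin/env python
"""Generate the synthetic multi-breed cohort used by the downstream analyses.

A scaled-down analogue of a 15-breed goat SNP-chip survey: 6 breeds with
unequal census sizes, ~50 kb SNP spacing, 1% missingness, a few first-degree
pairs, planted homozygous tracts of 2-18 Mb, and one trait-associated window
(a horned/polled-style contrast).  Genotypes (bulky) go to scratch/cohort/;
the truth record needed to score later stages goes there too.
"""

from dataclasses import replace
from pathlib import Path

import numpy as np

from caprapop.genotypes import GenotypeMatrix, write_metadata, write_ped_map
from caprapop.simulate import SimConfig, simulate_cohort

OUT = Path("scratch/cohort")

CFG = SimConfig(
    n_breeds=6,
    breed_sizes=(48, 24, 30, 78, 32, 24),
    breed_names=("ARG", "ASP", "CAM", "CCS", "DDS", "MES"),
    n_snps=10_000,
    n_chroms=6,
    chrom_length=40_000_000,  # ~24 kb spacing at 10k SNPs
    fst_per_breed=(0.08, 0.08, 0.08, 0.08, 0.08, 0.08),
    missing_rate=0.01,
    n_related_pairs=8,
    planted_roh=(
        ("CCS", 0.3, 2.5, 1),
        ("CCS", 0.2, 18.0, 1),
        ("DDS", 0.4, 6.0, 1),
    ),
    trait_loci=(("2", 20_000_000, 2_000_000, 0.6),),
    seed=1,
)


def plant_sweep(gm, truth, rng, carrier_frac=0.7):
    """Give most trait-present animals one shared homozygous haplotype over
    the trait window, emulating a recent selective sweep so the ROH-based
    delta-H scan has true signal alongside the frequency shift."""
    locus = truth.trait_loci[0]
    ids = {s: j for j, s in enumerate(sn.id for sn in gm.snps)}
    window = np.array([ids[s] for s in locus["snp_ids"]])
    present = [i for i, s in enumerate(gm.samples)
               if s.traits.get("horns") == "present"]
    carriers = rng.choice(present, size=int(len(present) * carrier_frac),
                          replace=False)
    hap = rng.binomial(1, 0.5, size=window.size).astype(np.int8)
    calls = gm.calls.copy()
    calls[np.ix_(carriers, window)] = 2 * hap
    return GenotypeMatrix(gm.samples, gm.snps, calls), len(carriers)


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    gm, truth = simulate_cohort(CFG)
    rng = np.random.default_rng(CFG.seed + 1)
    gm, n_carriers = plant_sweep(gm, truth, rng)
    # sexes for the trait tabulation (does dominate a dairy-goat survey)
    gm = GenotypeMatrix(
        [replace(s, sex=("male" if rng.random() < 0.12 else "female"))
         for s in gm.samples],
        gm.snps, gm.calls,
    )
    write_ped_map(gm, OUT / "cohort.ped", OUT / "cohort.map")
    write_metadata(gm.samples, OUT / "metadata.csv")
    truth.to_json(OUT / "truth.json")
    print(f"simulated {gm.n_samples} animals x {gm.n_snps} SNPs "
          f"({CFG.n_breeds} breeds, {CFG.n_chroms} autosomes)")
    print(f"planted {len(truth.planted_segments)} homozygous tracts; "
          f"{len(truth.related_pairs)} first-degree pairs; "
          f"trait window (delta=0.6) on chromosome 2 with a swept haplotype "
          f"in {n_carriers} trait-present animals")
    print(f"wrote PED/MAP + metadata + truth under {OUT}/")


if __name__ == "__main__":
    main()
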