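#!/usr/bin/env python
"""QC, relative exclusion, and breed-size capping of the simulated cohort.

Mirrors the survey's screening: 95% call rate for animals and autosomal
SNPs, MAF >= 0.1%, removal of one member per directly related pair, then a
35-per-breed cap for the population-structure dataset.  Writes the cohort
accounting table (initial / post-QC / capped, per breed) to results/.
"""

import json
from pathlib import Path

from caprapop.genotypes import (
    QCParams,
    apply_qc,
    attach_metadata,
    cap_breed_size,
    exclude_related,
    read_metadata,
    read_ped_map,
    write_ped_map,
)

IN = Path("scratch/cohort")
OUT = Path("results")


def main():
    OUT.mkdir(exist_ok=True)
    gm = attach_metadata(
        read_ped_map(IN / "cohort.ped", IN / "cohort.map"),
        read_metadata(IN / "metadata.csv"),
    )
    params = QCParams()
    gm_qc, report = apply_qc(gm, params)
    gm_unrel, removed = exclude_related(gm_qc, params.relatedness_threshold)
    gm_cap = cap_breed_size(gm_unrel, params.max_per_breed, seed=1)

    truth = json.loads((IN / "truth.json").read_text())
    truth_children = {pair[1] for pair in truth["related_pairs"]}
    flagged_ok = sum(
        1 for r in removed
        if any(r in pair for pair in truth["related_pairs"])
    )

    rows = []
    for breed in sorted(gm.breeds):
        initial = sum(s.breed == breed for s in gm.samples)
        post = sum(s.breed == breed for s in gm_unrel.samples)
        capped = sum(s.breed == breed for s in gm_cap.samples)
        rows.append((breed, initial, post, capped))
    with open(OUT / "cohort_accounting.tsv", "w") as fh:
        fh.write("breed\tinitial\tpost_qc_unrelated\tcapped\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
        fh.write("TOTAL\t%d\t%d\t%d\n" % tuple(
            sum(r[i] for r in rows) for i in (1, 2, 3)))

    write_ped_map(gm_unrel, IN / "postqc.ped", IN / "postqc.map")
    write_ped_map(gm_cap, IN / "capped.ped", IN / "capped.map")

    print(f"input: {gm.n_samples} animals, {gm.n_snps} SNPs")
    print(f"QC: {report.n_snps_low_call} low-call + {report.n_snps_low_maf} "
          f"low-MAF SNPs dropped, {report.n_samples_low_call} animals dropped")
    print(f"relatives: removed {len(removed)} animals "
          f"({flagged_ok}/{len(removed)} belong to a planted first-degree pair; "
          f"{len(truth_children)} pairs planted)")
    print(f"capping at {params.max_per_breed}: {gm_unrel.n_samples} -> "
          f"{gm_cap.n_samples} animals")
    print(f"wrote {OUT}/cohort_accounting.tsv and post-QC/capped PED sets")


if __name__ == "__main__":
    main()
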