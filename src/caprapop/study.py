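"""Breed census of the Italian goat cohort the pipeline was designed around.

The focal breed is the Capra Comune di Sicilia (CCS), genotyped alongside 14
other Italian breeds.  For each breed the census records the number of
genotyped subjects, the number surviving quality control and exclusion of
direct relatives, and the number after capping every breed at 35 subjects
for population-structure analyses.
"""

from dataclasses import dataclass

FOCAL_BREED = "CCS"
MAX_PER_BREED = 35


@dataclass(frozen=True)
class BreedCensusRow:
    code: str
    name: str
    initial: int
    post_qc: int
    capped: int


BREED_CENSUS = (
    BreedCensusRow("ARG", "Argentata dell'Etna", 48, 46, 35),
    BreedCensusRow("ASP", "Aspromontana", 24, 24, 24),
    BreedCensusRow("BIA", "Bianca Monticellana", 24, 24, 24),
    BreedCensusRow("CAM", "Camosciata delle Alpi", 30, 30, 30),
    BreedCensusRow("CCS", "Capra Comune di Sicilia", 78, 72, 35),
    BreedCensusRow("DDS", "Derivata di Siria", 32, 25, 25),
    BreedCensusRow("GAR", "Garganica", 40, 37, 35),
    BreedCensusRow("GCI", "Gricia Ciociara", 43, 40, 35),
    BreedCensusRow("GIR", "Girgentana", 59, 56, 35),
    BreedCensusRow("JON", "Jonica", 16, 15, 15),
    BreedCensusRow("MAL", "Maltese", 16, 16, 16),
    BreedCensusRow("MES", "Messinese", 24, 23, 23),
    BreedCensusRow("MON", "Capra di Montefalcone", 24, 23, 23),
    BreedCensusRow("NIC", "Nicastrese", 24, 24, 24),
    BreedCensusRow("SAR", "Sarda", 33, 32, 32),
)

N_CHIP_SNPS = 48_039  # autosomal SNPs retained after QC on the ~50K goat chip


def comparison_cohort_size() -> int:
    """Initial genotyped animals in the 14 comparison (non-focal) breeds."""
    return sum(r.initial for r in BREED_CENSUS if r.code != FOCAL_BREED)


def post_qc_cohort_size() -> int:
    """Animals retained after QC and exclusion of direct relatives."""
    return sum(r.post_qc for r in BREED_CENSUS)


def capped_cohort_size() -> int:
    """Animals retained after capping each breed at 35 subjects."""
    return sum(r.capped for r in BREED_CENSUS)
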