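"""Genotype data model, PLINK-text I/O, and cohort-construction rules.

The central object is :class:`GenotypeMatrix`: an individuals x SNPs table of
diploid genotype codes (0/1/2 copies of the designated alternate allele, -1
for missing) together with the SNP map and per-sample metadata.  Quality
control follows the usual SNP-array screening for livestock panels: restrict
to autosomes, drop low-call-rate individuals, then low-call-rate and
low-MAF markers, exclude one member of each directly related pair, and
optionally cap each breed at a maximum number of subjects so that breed
representation is balanced for population-structure work.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

MISSING = -1

_VALID_ALLELES = {"A", "C", "G", "T", "1", "2"}


class FormatError(ValueError):
    """Malformed PED/MAP/CSV input."""


class DataError(ValueError):
    """Structurally valid input with inconsistent content."""


def chrom_sort_key(chrom: str):
    """Order chromosome labels numerically where possible ('2' < '10')."""
    try:
        return (0, int(chrom), "")
    except ValueError:
        return (1, 0, chrom)


@dataclass(frozen=True)
class SNPRecord:
    chrom: str
    id: str
    cm: float
    bp: int
    ref: str = "0"  # major allele symbol as read from file ("0" if unknown)
    alt: str = "0"  # designated alternate (minor) allele; "0" when unseen

    def __post_init__(self):
        if self.bp < 1:
            raise DataError(f"SNP {self.id}: bp must be >= 1, got {self.bp}")


@dataclass
class SampleRecord:
    sample_id: str
    breed: str
    farm: str = ""
    sex: str = "unknown"  # {male, female, unknown}
    traits: dict = field(default_factory=dict)  # trait -> present/absent/unknown

    def __post_init__(self):
        if not self.breed:
            raise DataError(f"sample {self.sample_id}: breed must be non-empty")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs diploid genotype codes with map and metadata.

    ``calls`` is an ``int8`` array of shape ``(n_samples, n_snps)`` holding
    counts of the designated alternate allele; ``-1`` marks a missing call.
    SNPs are kept sorted by (chromosome, bp).
    """

    samples: list
    snps: list
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise DataError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise DataError("genotype codes must be in {0,1,2,-1}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate sample ids")
        snp_ids = [s.id for s in self.snps]
        if len(set(snp_ids)) != len(snp_ids):
            raise DataError("duplicate SNP ids")
        keys = [(chrom_sort_key(s.chrom), s.bp) for s in self.snps]
        if any(keys[i] > keys[i + 1] for i in range(len(keys) - 1)):
            raise DataError("SNPs must be sorted by (chrom, bp)")

    # -- convenience accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def sample_ids(self) -> list:
        return [s.sample_id for s in self.samples]

    @property
    def breeds(self) -> list:
        """Breed codes in first-appearance order."""
        seen = []
        for s in self.samples:
            if s.breed not in seen:
                seen.append(s.breed)
        return seen

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.bp for s in self.snps], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([s.chrom for s in self.snps])

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s.sample_id: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[i] for i in ids], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"unknown sample id {e.args[0]!r}") from None

    def breed_index(self, breed: str) -> np.ndarray:
        idx = np.array(
            [i for i, s in enumerate(self.samples) if s.breed == breed], dtype=np.intp
        )
        if idx.size == 0:
            raise KeyError(f"breed {breed!r} not present")
        return idx

    def subset_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return GenotypeMatrix(
            [self.samples[i] for i in idx], list(self.snps), self.calls[idx]
        )

    def subset_snps(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask.astype(np.intp)
        return GenotypeMatrix(
            list(self.samples), [self.snps[i] for i in idx], self.calls[:, idx]
        )


@dataclass(frozen=True)
class QCParams:
    min_sample_call_rate: float = 0.95
    min_snp_call_rate: float = 0.95
    min_maf: float = 0.001
    autosomes: frozenset = frozenset(str(c) for c in range(1, 30))
    relatedness_threshold: float = 0.25
    max_per_breed: int = 35
    seed: int = 0

    def __post_init__(self):
        for name in ("min_sample_call_rate", "min_snp_call_rate", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.max_per_breed < 1:
            raise ValueError("max_per_breed must be >= 1")


@dataclass
class QCReport:
    n_samples_in: int
    n_snps_in: int
    n_snps_non_autosomal: int
    n_samples_low_call: int
    n_snps_low_call: int
    n_snps_low_maf: int
    n_samples_out: int
    n_snps_out: int
    removed_samples: list = field(default_factory=list)

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("step\tremoved\tremaining\n")
            fh.write(f"input\t0\t{self.n_samples_in} samples / {self.n_snps_in} SNPs\n")
            fh.write(f"non_autosomal_snps\t{self.n_snps_non_autosomal}\t-\n")
            fh.write(f"low_call_samples\t{self.n_samples_low_call}\t-\n")
            fh.write(f"low_call_snps\t{self.n_snps_low_call}\t-\n")
            fh.write(f"low_maf_snps\t{self.n_snps_low_maf}\t-\n")
            fh.write(
                f"output\t0\t{self.n_samples_out} samples / {self.n_snps_out} SNPs\n"
            )


# ---------------------------------------------------------------------------
# PLINK text I/O
# ---------------------------------------------------------------------------

_SEX_CODE = {"1": "male", "2": "female"}
_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Read whitespace-delimited PLINK PED/MAP text files.

    The alternate allele at each SNP is the minor allele observed in the file
    (lexicographically larger symbol on a count tie); a "0 0" allele pair is a
    missing call.  SNPs are returned sorted by (chromosome, bp).
    """
    snps_raw = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{map_path}: line {ln}: expected 4 columns")
            chrom, snp_id, cm, bp = parts
            snps_raw.append((chrom, snp_id, float(cm), int(bp)))
    n_snps = len(snps_raw)

    sample_rows = []
    allele_rows = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_snps:
                raise FormatError(
                    f"{ped_path}: line {ln}: expected {6 + 2 * n_snps} columns "
                    f"for {n_snps} MAP SNPs, got {len(parts)}"
                )
            fid, iid, _pat, _mat, sex, _pheno = parts[:6]
            sample_rows.append(
                SampleRecord(sample_id=iid, breed=fid or "UNK",
                             sex=_SEX_CODE.get(sex, "unknown"))
            )
            alleles = np.array(parts[6:], dtype="U1").reshape(n_snps, 2)
            allele_rows.append(alleles)

    n_samples = len(sample_rows)
    calls = np.full((n_samples, n_snps), MISSING, dtype=np.int8)
    refs = ["0"] * n_snps
    alts = ["0"] * n_snps
    if n_samples:
        allele_arr = np.stack(allele_rows)  # (n_samples, n_snps, 2)
        for j in range(n_snps):
            col = allele_arr[:, j, :]
            missing_pair = (col == "0").any(axis=1)
            seen = col[~missing_pair]
            symbols, counts = np.unique(seen, return_counts=True)
            bad = [s for s in symbols if s not in _VALID_ALLELES]
            if bad:
                raise DataError(
                    f"SNP {snps_raw[j][1]}: invalid allele symbol(s) {bad}"
                )
            if len(symbols) > 2:
                raise DataError(
                    f"SNP {snps_raw[j][1]}: more than two alleles {list(symbols)}"
                )
            if len(symbols) == 0:
                continue  # all missing; alt unknown, calls stay -1 -> set below
            if len(symbols) == 1:
                refs[j] = str(symbols[0])
                calls[~missing_pair, j] = 0
                continue
            order = np.argsort(counts, kind="stable")
            s0, s1 = symbols[order[0]], symbols[order[1]]
            if counts[order[0]] == counts[order[1]]:
                # tie: lexicographically smaller symbol is the reference
                ref, alt = sorted((s0, s1))
            else:
                ref, alt = s1, s0
            refs[j], alts[j] = str(ref), str(alt)
            calls[~missing_pair, j] = (seen == alt).sum(axis=1)

    snps = [
        SNPRecord(chrom=c, id=i, cm=cm, bp=bp, ref=refs[j], alt=alts[j])
        for j, (c, i, cm, bp) in enumerate(snps_raw)
    ]
    order = sorted(range(n_snps), key=lambda j: (chrom_sort_key(snps[j].chrom), snps[j].bp))
    snps = [snps[j] for j in order]
    calls = calls[:, order] if n_samples else calls[:, order]
    return GenotypeMatrix(sample_rows, snps, calls)


def write_ped_map(gm: GenotypeMatrix, ped_path, map_path) -> None:
    """Write PED/MAP text readable by :func:`read_ped_map` with identical codes."""
    with open(map_path, "w") as fh:
        for s in gm.snps:
            cm = f"{s.cm:g}"
            fh.write(f"{s.chrom}\t{s.id}\t{cm}\t{s.bp}\n")
    with open(ped_path, "w") as fh:
        for i, samp in enumerate(gm.samples):
            row = [samp.breed, samp.sample_id, "0", "0", _SEX_OUT[samp.sex], "-9"]
            for j, snp in enumerate(gm.snps):
                g = gm.calls[i, j]
                ref = snp.ref if snp.ref != "0" else "A"
                alt = snp.alt if snp.alt != "0" else "C"
                if g == MISSING:
                    row += ["0", "0"]
                elif g == 0:
                    row += [ref, ref]
                elif g == 1:
                    row += [ref, alt]
                else:
                    row += [alt, alt]
            fh.write(" ".join(row) + "\n")


def read_metadata(path) -> list:
    """Read the sample-metadata CSV (sample_id,breed,farm,sex,horns,wattles,ears)."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"sample_id", "breed"}
        if not required <= set(reader.fieldnames or ()):
            raise FormatError(f"{path}: header must include {sorted(required)}")
        for row in reader:
            traits = {
                t: row.get(t, "unknown") or "unknown"
                for t in ("horns", "wattles", "ears")
            }
            records.append(
                SampleRecord(
                    sample_id=row["sample_id"],
                    breed=row["breed"],
                    farm=row.get("farm", "") or "",
                    sex=row.get("sex", "unknown") or "unknown",
                    traits=traits,
                )
            )
    return records


def write_metadata(samples, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "breed", "farm", "sex", "horns", "wattles", "ears"])
        for s in samples:
            writer.writerow(
                [s.sample_id, s.breed, s.farm, s.sex]
                + [s.traits.get(t, "unknown") for t in ("horns", "wattles", "ears")]
            )


def attach_metadata(gm: GenotypeMatrix, records) -> GenotypeMatrix:
    """Replace sample metadata by matching sample_id; unmatched ids error."""
    lookup = {r.sample_id: r for r in records}
    new = []
    for s in gm.samples:
        if s.sample_id not in lookup:
            raise DataError(f"no metadata for sample {s.sample_id}")
        new.append(lookup[s.sample_id])
    return GenotypeMatrix(new, list(gm.snps), gm.calls.copy())


# ---------------------------------------------------------------------------
# Allele frequencies and QC
# ---------------------------------------------------------------------------


def allele_freq(gm: GenotypeMatrix, sample_subset=None) -> np.ndarray:
    """Per-SNP alternate-allele frequency; NaN where all calls are missing.

    ``sample_subset`` is a list of sample ids (default: all samples).
    """
    if sample_subset is None:
        idx = np.arange(gm.n_samples)
    else:
        if len(sample_subset) == 0:
            raise ValueError("sample subset must be non-empty")
        idx = gm.sample_index(sample_subset)
    calls = gm.calls[idx]
    called = calls != MISSING
    n = called.sum(axis=0)
    total = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, total / (2.0 * np.maximum(n, 1)), np.nan)
    p[n == 0] = np.nan
    return p


def apply_qc(gm: GenotypeMatrix, params: QCParams = QCParams()):
    """Fixed-order QC: autosomes -> sample call rate -> SNP call rate -> MAF.

    Returns ``(filtered GenotypeMatrix, QCReport)``.  Raises :class:`DataError`
    if no sample survives.
    """
    n_samples_in, n_snps_in = gm.n_samples, gm.n_snps

    # 1. autosomes
    auto = np.array([s.chrom in params.autosomes for s in gm.snps])
    n_non_auto = int((~auto).sum())
    gm1 = gm.subset_snps(auto)

    # 2. sample call rate
    if gm1.n_snps:
        rate = (gm1.calls != MISSING).mean(axis=1)
    else:
        rate = np.ones(gm1.n_samples)
    keep_samp = rate >= params.min_sample_call_rate
    removed_samples = [s.sample_id for s, k in zip(gm1.samples, keep_samp) if not k]
    gm2 = gm1.subset_samples(np.flatnonzero(keep_samp))
    if gm2.n_samples == 0:
        raise DataError("empty cohort: every sample failed the call-rate filter")

    # 3. SNP call rate
    snp_rate = (gm2.calls != MISSING).mean(axis=0)
    keep_rate = snp_rate >= params.min_snp_call_rate
    n_low_call = int((~keep_rate).sum())
    gm3 = gm2.subset_snps(keep_rate)

    # 4. MAF
    p = allele_freq(gm3)
    with np.errstate(invalid="ignore"):
        maf = np.fmin(p, 1.0 - p)
    keep_maf = np.where(np.isnan(maf), False, maf >= params.min_maf)
    n_low_maf = int((~keep_maf).sum())
    gm4 = gm3.subset_snps(keep_maf)

    report = QCReport(
        n_samples_in=n_samples_in,
        n_snps_in=n_snps_in,
        n_snps_non_autosomal=n_non_auto,
        n_samples_low_call=int((~keep_samp).sum()),
        n_snps_low_call=n_low_call,
        n_snps_low_maf=n_low_maf,
        n_samples_out=gm4.n_samples,
        n_snps_out=gm4.n_snps,
        removed_samples=removed_samples,
    )
    return gm4, report


# ---------------------------------------------------------------------------
# Relatedness and breed capping
# ---------------------------------------------------------------------------


def relatedness_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Allele-sharing kinship proxy for every sample pair.

    For a pair, over jointly called SNPs, the mean allele-sharing similarity
    ``s = mean(1 - |g_i - g_j| / 2)`` is normalized against its expectation for
    unrelated individuals at the cohort allele frequencies,
    ``s0 = 1 - 2 p q (1 - p q)``, giving ``phi = (s - s0) / (1 - s0)``:
    ~1 for duplicates, ~1/3 for first-degree relatives, ~0 for unrelated pairs.
    """
    calls = gm.calls.astype(np.float64)
    called = (gm.calls != MISSING).astype(np.float64)
    g = np.where(gm.calls == MISSING, 0, gm.calls).astype(np.float64)

    ind = [(gm.calls == k).astype(np.float64) for k in (0, 1, 2)]
    # sum over jointly-called SNPs of |g_i - g_j|
    absdiff = (
        ind[0] @ ind[1].T + ind[1] @ ind[0].T
        + 2.0 * (ind[0] @ ind[2].T + ind[2] @ ind[0].T)
        + ind[1] @ ind[2].T + ind[2] @ ind[1].T
    )
    n_joint = called @ called.T
    p = allele_freq(gm)
    q = 1.0 - p
    s0_l = 1.0 - 2.0 * p * q * (1.0 - p * q)
    s0_l = np.where(np.isnan(s0_l), 1.0, s0_l)
    s0_sum = (called * s0_l) @ called.T
    with np.errstate(invalid="ignore", divide="ignore"):
        s_sum = n_joint - absdiff / 2.0
        phi = (s_sum - s0_sum) / (n_joint - s0_sum)
    phi[n_joint == 0] = 0.0
    denom_zero = np.isclose(n_joint - s0_sum, 0.0)
    phi[denom_zero] = 0.0
    np.fill_diagonal(phi, 1.0)
    return phi


def exclude_related(gm: GenotypeMatrix, threshold: float = 0.25):
    """Drop one member per directly related pair (kinship proxy >= threshold).

    Greedy cover: repeatedly remove the sample in the most flagged pairs
    (ties broken by larger missingness, then lexicographic sample id).
    Returns ``(filtered GenotypeMatrix, removed id list)``.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0,1], got {threshold}")
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    phi = relatedness_matrix(gm)
    n = gm.n_samples
    flagged = phi >= threshold
    np.fill_diagonal(flagged, False)
    missingness = (gm.calls == MISSING).mean(axis=1)
    ids = gm.sample_ids
    active = np.ones(n, dtype=bool)
    removed = []
    while True:
        deg = (flagged & active[None, :] & active[:, None]).sum(axis=1)
        deg[~active] = 0
        if deg.max() == 0:
            break
        worst = np.flatnonzero(deg == deg.max())
        worst = sorted(worst, key=lambda i: (-missingness[i], ids[i]))[0]
        active[worst] = False
        removed.append(ids[worst])
    return gm.subset_samples(np.flatnonzero(active)), removed


def cap_breed_size(gm: GenotypeMatrix, max_per_breed: int = 35, seed: int = 0):
    """Subsample each breed uniformly at random down to ``max_per_breed``."""
    if max_per_breed < 1:
        raise ValueError("max_per_breed must be >= 1")
    rng = np.random.default_rng(seed)
    keep = np.zeros(gm.n_samples, dtype=bool)
    for breed in sorted(gm.breeds):
        idx = gm.breed_index(breed)
        if idx.size <= max_per_breed:
            keep[idx] = True
        else:
            chosen = rng.choice(idx, size=max_per_breed, replace=False)
            keep[chosen] = True
    return gm.subset_samples(np.flatnonzero(keep))
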