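"""Sliding-window detection of runs of homozygosity (ROH) and F_ROH.

The detector scores overlapping windows of ``windef`` consecutive SNPs,
stepped by ``interval`` SNPs along each chromosome (a single whole-chromosome
window when the chromosome has fewer SNPs than ``windef``).  A window
qualifies when it contains at most ``hetallowed`` heterozygotes and at most
``maxmiss`` missing calls.  A SNP becomes an ROH candidate when at least a
fraction ``ROHquartile`` of the windows covering it qualify; maximal runs of
candidate SNPs, split at inter-SNP gaps larger than ``maxInternalGap`` kb,
are accepted as segments when they hold at least ``minNsnp`` SNPs, span at
least ``minKblength`` kb, and average at most ``density`` kb per SNP.

The genomic inbreeding coefficient F_ROH is the summed ROH length of an
individual divided by the SNP-covered autosome length, reported in total and
within length classes (up to 2 / 2-4 / 4-8 / 8-16 / >16 Mb) whose relative
weight indicates how recent the underlying inbreeding was.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, DataError, GenotypeMatrix, chrom_sort_key

CLASS_BOUNDS_MB = (2.0, 4.0, 8.0, 16.0)
CLASS_LABELS = ("1-2Mb", "2-4Mb", "4-8Mb", "8-16Mb", ">16Mb")


@dataclass(frozen=True)
class ROHParams:
    ROHquartile: float = 0.99
    minNsnp: int = 10
    maxNsnp: int = 30  # accepted for completeness; no upper SNP bound is applied
    windef: int = 20
    interval: int = 5
    hetallowed: int = 0
    minKblength: float = 1000.0
    density: float = 500.0  # max mean kb per SNP inside a segment
    maxInternalGap: float = 500.0  # kb
    maxmiss: int = 2

    def __post_init__(self):
        if self.interval > self.windef:
            raise ValueError("interval must be <= windef")
        if self.minNsnp < 1:
            raise ValueError("minNsnp must be >= 1")
        for name in ("minKblength", "density", "maxInternalGap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class ROHSegment:
    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1000.0

    @property
    def length_mb(self) -> float:
        return self.length_kb / 1000.0


@dataclass(frozen=True)
class FrohRecord:
    sample_id: str
    froh_total: float
    froh_by_class: tuple  # five fractions per CLASS_LABELS
    covered_autosome_bp: int
    n_segments: int
    total_length_kb: float


def _candidate_mask(g: np.ndarray, params: ROHParams) -> np.ndarray:
    """Candidate flags for one individual's genotype vector on one chromosome."""
    L = g.size
    het = (g == 1).astype(np.int32)
    mis = (g == MISSING).astype(np.int32)
    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(mis)])
    if L < params.windef:
        starts = np.array([0])
        wlen = L
    else:
        starts = np.arange(0, L - params.windef + 1, params.interval)
        wlen = params.windef
    ends = starts + wlen  # exclusive
    qual = (chet[ends] - chet[starts] <= params.hetallowed) & (
        cmis[ends] - cmis[starts] <= params.maxmiss
    )
    cover = np.zeros(L + 1, dtype=np.int32)
    qcover = np.zeros(L + 1, dtype=np.int32)
    np.add.at(cover, starts, 1)
    np.add.at(cover, ends, -1)
    np.add.at(qcover, starts[qual], 1)
    np.add.at(qcover, ends[qual], -1)
    cover = np.cumsum(cover)[:L]
    qcover = np.cumsum(qcover)[:L]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(cover > 0, qcover / np.maximum(cover, 1), 0.0)
    return (cover > 0) & (frac >= params.ROHquartile - 1e-12)


def _runs(mask: np.ndarray):
    """(start, end) index pairs (inclusive) of maximal True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts, ends))


def detect_roh(gm: GenotypeMatrix, params: ROHParams = ROHParams()) -> list:
    """Accepted ROH segments for every individual, sorted by (sample, chrom, bp)."""
    chroms = gm.chroms
    pos = gm.positions
    segments = []
    uniq = sorted(set(chroms), key=chrom_sort_key)
    chrom_idx = {c: np.flatnonzero(chroms == c) for c in uniq}
    for i, samp in enumerate(gm.samples):
        for c in uniq:
            idx = chrom_idx[c]
            bp = pos[idx]
            if np.any(np.diff(bp) < 0):
                raise DataError(f"SNP map on chromosome {c} is not sorted")
            g = gm.calls[i, idx]
            cand = _candidate_mask(g, params)
            for s, e in _runs(cand):
                # split at internal gaps larger than maxInternalGap kb
                pieces = []
                prev = s
                for t in range(s, e):
                    if (bp[t + 1] - bp[t]) / 1000.0 > params.maxInternalGap:
                        pieces.append((prev, t))
                        prev = t + 1
                pieces.append((prev, e))
                for ps, pe in pieces:
                    n = pe - ps + 1
                    length_kb = (bp[pe] - bp[ps] + 1) / 1000.0
                    if (
                        n >= params.minNsnp
                        and length_kb >= params.minKblength
                        and length_kb / n <= params.density
                    ):
                        segments.append(
                            ROHSegment(
                                sample_id=samp.sample_id,
                                chrom=c,
                                start_bp=int(bp[ps]),
                                end_bp=int(bp[pe]),
                                n_snps=int(n),
                            )
                        )
    return segments


def covered_autosome_bp(gm: GenotypeMatrix) -> int:
    """Sum over chromosomes of (last SNP bp - first SNP bp + 1)."""
    total = 0
    chroms = gm.chroms
    pos = gm.positions
    for c in set(chroms):
        bp = pos[chroms == c]
        total += int(bp.max() - bp.min() + 1)
    return total


def compute_froh(segments, gm: GenotypeMatrix) -> list:
    """One :class:`FrohRecord` per sample of ``gm`` (zeros without segments).

    The first length class absorbs everything below 2 Mb so the per-class
    fractions always sum exactly to the total.
    """
    known = set(gm.chroms)
    for seg in segments:
        if seg.chrom not in known:
            raise DataError(f"segment on unknown chromosome {seg.chrom!r}")
    covered = covered_autosome_bp(gm)
    by_sample = {s.sample_id: [] for s in gm.samples}
    for seg in segments:
        if seg.sample_id in by_sample:
            by_sample[seg.sample_id].append(seg)
    records = []
    for s in gm.samples:
        segs = by_sample[s.sample_id]
        class_bp = [0.0] * 5
        for seg in segs:
            mb = seg.length_mb
            k = sum(mb >= b for b in CLASS_BOUNDS_MB)
            class_bp[k] += seg.end_bp - seg.start_bp + 1
        total_bp = float(sum(class_bp))
        records.append(
            FrohRecord(
                sample_id=s.sample_id,
                froh_total=total_bp / covered,
                froh_by_class=tuple(x / covered for x in class_bp),
                covered_autosome_bp=covered,
                n_segments=len(segs),
                total_length_kb=total_bp / 1000.0,
            )
        )
    return records


def roh_incidence(segments, gm: GenotypeMatrix, sample_subset) -> np.ndarray:
    """Per-SNP fraction of subset individuals with an ROH covering the SNP."""
    if len(sample_subset) == 0:
        raise ValueError("sample subset must be non-empty")
    subset = set(sample_subset)
    unknown = subset - set(gm.sample_ids)
    if unknown:
        raise KeyError(f"unknown sample ids {sorted(unknown)}")
    chroms = gm.chroms
    pos = gm.positions
    chrom_idx = {c: np.flatnonzero(chroms == c) for c in set(chroms)}
    count = np.zeros(gm.n_snps, dtype=np.int64)
    by_sample = {}
    for seg in segments:
        if seg.sample_id in subset:
            by_sample.setdefault(seg.sample_id, []).append(seg)
    for sid, segs in by_sample.items():
        covered = np.zeros(gm.n_snps, dtype=bool)
        for seg in segs:
            idx = chrom_idx.get(seg.chrom)
            if idx is None:
                raise DataError(f"segment on unknown chromosome {seg.chrom!r}")
            bp = pos[idx]
            covered[idx[(bp >= seg.start_bp) & (bp <= seg.end_bp)]] = True
        count += covered
    return count / float(len(subset))


def write_segments_tsv(segments, path) -> None:
    with open(path, "w") as fh:
        fh.write("# 1-based inclusive coordinates\n")
        fh.write("sample_id\tchrom\tstart_bp\tend_bp\tn_snps\tlength_kb\n")
        for s in segments:
            fh.write(
                f"{s.sample_id}\t{s.chrom}\t{s.start_bp}\t{s.end_bp}\t"
                f"{s.n_snps}\t{s.length_kb:.3f}\n"
            )


def write_froh_tsv(records, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sample_id\tn_segments\ttotal_length_kb\t"
            + "\t".join(f"froh_{c}" for c in CLASS_LABELS)
            + "\tfroh_total\n"
        )
        for r in records:
            fh.write(
                f"{r.sample_id}\t{r.n_segments}\t{r.total_length_kb:.1f}\t"
                + "\t".join(f"{x:.5f}" for x in r.froh_by_class)
                + f"\t{r.froh_total:.5f}\n"
            )
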