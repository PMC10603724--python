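"""Synthetic multi-breed SNP-chip cohorts with known ground truth.

Breed structure follows the Balding-Nichols model: each SNP has an ancestral
frequency p drawn uniformly on [0.05, 0.95]; breed b with differentiation
parameter F_b draws its frequency from Beta(p(1-F)/F, (1-p)(1-F)/F), and
genotypes are Binomial(2, breed frequency).  SNPs are unlinked except inside
planted homozygous segments and trait-associated windows, which is what makes
recovery tests against the generative model interpretable.

The default configuration mirrors the goat-breed survey the pipeline was
built for: 15 breeds with the census sizes of :mod:`caprapop.study`, 48,039
autosomal SNPs on 29 autosomes of 85 Mb (about one SNP per 50 kb, the density
of a ~50K chip on the ~2.5 Gb goat autosome), 1% missingness, and a handful
of first-degree pairs created by gamete copying.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .genotypes import (
    MISSING,
    GenotypeMatrix,
    SampleRecord,
    SNPRecord,
    allele_freq,
)
from . import study


class ConfigError(ValueError):
    """Infeasible simulation configuration."""


@dataclass
class SimConfig:
    n_breeds: int = 15
    breed_sizes: tuple = tuple(r.initial for r in study.BREED_CENSUS)
    breed_names: tuple = tuple(r.code for r in study.BREED_CENSUS)
    n_snps: int = study.N_CHIP_SNPS
    n_chroms: int = 29
    chrom_length: int = 85_000_000
    fst_per_breed: tuple = (0.08,) * 15
    missing_rate: float = 0.01
    n_related_pairs: int = 10
    # entries: (breed, fraction of individuals, length Mb, segments per individual)
    planted_roh: tuple = ()
    # entries: (chrom, bp center, window bp, frequency shift delta)
    trait_loci: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if len(self.breed_sizes) != self.n_breeds:
            raise ConfigError("breed_sizes length must equal n_breeds")
        if len(self.fst_per_breed) != self.n_breeds:
            raise ConfigError("fst_per_breed length must equal n_breeds")
        if not self.breed_names:
            self.breed_names = tuple(f"B{i + 1:02d}" for i in range(self.n_breeds))
        if len(self.breed_names) != self.n_breeds:
            raise ConfigError("breed_names length must equal n_breeds")
        for f in self.fst_per_breed:
            if not 0.0 <= f < 1.0:
                raise ConfigError(f"Balding-Nichols F must be in [0,1), got {f}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigError("missing_rate must be in [0,1]")
        for entry in self.planted_roh:
            _, frac, length_mb, count = entry
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("planted_roh fraction must be in [0,1]")
            if length_mb * 1e6 > self.chrom_length:
                raise ConfigError(
                    f"planted segment of {length_mb} Mb exceeds chromosome length"
                )
            if count < 1:
                raise ConfigError("planted_roh count must be >= 1")


@dataclass
class TruthRecord:
    """Every latent quantity of a simulated cohort (no hidden state)."""

    config: SimConfig
    ancestral_freq: np.ndarray = None
    breed_freq: dict = field(default_factory=dict)  # breed -> per-SNP frequency
    related_pairs: list = field(default_factory=list)  # (parent_id, child_id)
    planted_segments: list = field(default_factory=list)  # dicts with bp bounds
    trait_assignments: dict = field(default_factory=dict)  # trait -> {id: status}
    trait_loci: list = field(default_factory=list)

    def to_json(self, path):
        payload = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.config).items()
            },
            "ancestral_freq": self.ancestral_freq.tolist(),
            "breed_freq": {k: v.tolist() for k, v in self.breed_freq.items()},
            "related_pairs": self.related_pairs,
            "planted_segments": self.planted_segments,
            "trait_assignments": self.trait_assignments,
            "trait_loci": self.trait_loci,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _simulate_map(cfg: SimConfig, rng) -> list:
    """Uniform SNP positions over equal-length chromosomes, sorted by (chrom, bp)."""
    per_chrom = np.full(cfg.n_chroms, cfg.n_snps // cfg.n_chroms, dtype=int)
    per_chrom[: cfg.n_snps % cfg.n_chroms] += 1
    snps = []
    k = 0
    for c in range(cfg.n_chroms):
        n = int(per_chrom[c])
        pos = np.unique(rng.integers(1, cfg.chrom_length + 1, size=n))
        while pos.size < n:  # replace collisions
            extra = rng.integers(1, cfg.chrom_length + 1, size=n - pos.size)
            pos = np.unique(np.concatenate([pos, extra]))
        for bp in np.sort(pos):
            snps.append(
                SNPRecord(chrom=str(c + 1), id=f"snp{k:06d}", cm=0.0, bp=int(bp),
                          ref="A", alt="C")
            )
            k += 1
    return snps


def simulate_cohort(cfg: SimConfig):
    """Draw a multi-breed cohort; returns ``(GenotypeMatrix, TruthRecord)``."""
    rng = np.random.default_rng(cfg.seed)
    snps = _simulate_map(cfg, rng)
    n_snps = len(snps)
    p_anc = rng.uniform(0.05, 0.95, size=n_snps)

    samples = []
    blocks = []
    truth = TruthRecord(config=cfg, ancestral_freq=p_anc)
    for b in range(cfg.n_breeds):
        name, size, F = cfg.breed_names[b], cfg.breed_sizes[b], cfg.fst_per_breed[b]
        if F > 0:
            a = p_anc * (1.0 - F) / F
            bb = (1.0 - p_anc) * (1.0 - F) / F
            p_b = rng.beta(a, bb)
        else:
            p_b = p_anc.copy()
        truth.breed_freq[name] = p_b
        g = rng.binomial(2, p_b, size=(size, n_snps)).astype(np.int8)
        blocks.append(g)
        for i in range(size):
            samples.append(SampleRecord(sample_id=f"{name}_{i + 1:03d}", breed=name))
    calls = np.concatenate(blocks, axis=0)

    # first-degree pairs: child keeps one gamete copied from the parent
    offsets = np.cumsum([0] + list(cfg.breed_sizes))
    eligible = [b for b in range(cfg.n_breeds) if cfg.breed_sizes[b] >= 2]
    for k in range(cfg.n_related_pairs):
        if not eligible:
            break
        b = eligible[k % len(eligible)]
        lo, hi = offsets[b], offsets[b + 1]
        parent, child = rng.choice(np.arange(lo, hi), size=2, replace=False)
        p_b = truth.breed_freq[cfg.breed_names[b]]
        transmitted = rng.binomial(1, calls[parent] / 2.0)
        other = rng.binomial(1, p_b)
        calls[child] = (transmitted + other).astype(np.int8)
        truth.related_pairs.append(
            (samples[parent].sample_id, samples[child].sample_id)
        )

    gm = GenotypeMatrix(samples, snps, calls)

    if cfg.planted_roh:
        gm, segs = plant_roh(gm, cfg.planted_roh, seed=int(rng.integers(2**31)))
        truth.planted_segments = segs
    if cfg.trait_loci:
        gm, tr = assign_trait_groups(gm, cfg.trait_loci, seed=int(rng.integers(2**31)))
        truth.trait_assignments = tr["assignments"]
        truth.trait_loci = tr["loci"]

    if cfg.missing_rate > 0:
        mask = rng.random(gm.calls.shape) < cfg.missing_rate
        calls = gm.calls.copy()
        calls[mask] = MISSING
        gm = GenotypeMatrix(gm.samples, gm.snps, calls)

    # recode so the designated alternate is the observed minor allele, the
    # same designation read_ped_map derives from a written file (round-trip)
    calls = gm.calls.copy()
    called = calls != MISSING
    alt_count = np.where(called, calls, 0).sum(axis=0)
    flip = alt_count > 2 * called.sum(axis=0) - alt_count  # alt is the majority
    if flip.any():
        sub = calls[:, flip]
        calls[:, flip] = np.where(sub != MISSING, 2 - sub, MISSING).astype(np.int8)
        snps = [
            SNPRecord(s.chrom, s.id, s.cm, s.bp, ref=s.alt, alt=s.ref)
            if f else s
            for s, f in zip(gm.snps, flip)
        ]
        gm = GenotypeMatrix(gm.samples, snps, calls)
        truth.ancestral_freq = np.where(flip, 1.0 - p_anc, p_anc)
        for name in truth.breed_freq:
            pb = truth.breed_freq[name]
            truth.breed_freq[name] = np.where(flip, 1.0 - pb, pb)
    return gm, truth


def plant_roh(gm: GenotypeMatrix, spec, seed: int = 0):
    """Overwrite intervals with a homozygous haplotype in chosen individuals.

    ``spec`` entries are ``(breed, fraction, length_mb, count_per_individual)``.
    Returns ``(GenotypeMatrix, truth list)`` where each truth entry records the
    exact bp bounds of a planted segment.
    """
    rng = np.random.default_rng(seed)
    calls = gm.calls.copy()
    chroms = gm.chroms
    pos = gm.positions
    freq = allele_freq(gm)
    freq = np.where(np.isnan(freq), 0.5, freq)
    truth = []
    for breed, frac, length_mb, count in spec:
        idx = gm.breed_index(breed)
        n_pick = max(1, int(round(frac * idx.size))) if frac > 0 else 0
        chosen = rng.choice(idx, size=min(n_pick, idx.size), replace=False)
        length_bp = int(round(length_mb * 1e6))
        for i in chosen:
            for _ in range(count):
                # pick a chromosome whose SNP span can hold the segment
                uniq = list(np.unique(chroms))
                labels = [uniq[j] for j in rng.permutation(len(uniq))]
                placed = False
                for c in labels:
                    in_c = np.flatnonzero(chroms == c)
                    span_lo, span_hi = pos[in_c[0]], pos[in_c[-1]]
                    if span_hi - span_lo + 1 < length_bp:
                        continue
                    start = int(rng.integers(span_lo, span_hi - length_bp + 2))
                    end = start + length_bp - 1
                    inside = in_c[(pos[in_c] >= start) & (pos[in_c] <= end)]
                    if inside.size == 0:
                        continue
                    hap = rng.binomial(1, freq[inside])
                    calls[i, inside] = (2 * hap).astype(np.int8)
                    truth.append(
                        {
                            "sample_id": gm.samples[i].sample_id,
                            "chrom": str(c),
                            "start_bp": start,
                            "end_bp": end,
                            "length_mb": length_mb,
                        }
                    )
                    placed = True
                    break
                if not placed:
                    raise ConfigError(
                        f"no chromosome can hold a {length_mb} Mb planted segment"
                    )
    return GenotypeMatrix(list(gm.samples), list(gm.snps), calls), truth


def assign_trait_groups(gm: GenotypeMatrix, loci, seed: int = 0, trait: str = "horns"):
    """Split the cohort into present/absent groups and shift window frequencies.

    Each locus is ``(chrom, bp_center, window_bp, delta)``: SNPs within
    ``window_bp`` of the center get group frequencies shifted by +-delta/2
    (clamped to [0,1]) and their genotypes are re-drawn inside the window only.
    Returns ``(GenotypeMatrix, truth dict)``; sample records carry the trait.
    """
    rng = np.random.default_rng(seed)
    n = gm.n_samples
    perm = rng.permutation(n)
    present = np.zeros(n, dtype=bool)
    present[perm[: n // 2]] = True

    calls = gm.calls.copy()
    chroms = gm.chroms
    pos = gm.positions
    base = allele_freq(gm)
    base = np.where(np.isnan(base), 0.5, base)
    loci_truth = []
    for chrom, center, window, delta in loci:
        inside = np.flatnonzero(
            (chroms == str(chrom)) & (np.abs(pos - center) <= window / 2)
        )
        if inside.size == 0:
            raise ConfigError(
                f"trait locus window {chrom}:{center}+-{window / 2:.0f} contains no SNP"
            )
        p_pres = np.clip(base[inside] + delta / 2.0, 0.0, 1.0)
        p_abs = np.clip(base[inside] - delta / 2.0, 0.0, 1.0)
        was_missing = gm.calls[:, inside] == MISSING
        redrawn = np.empty((n, inside.size), dtype=np.int8)
        redrawn[present] = rng.binomial(2, p_pres, size=(int(present.sum()), inside.size))
        redrawn[~present] = rng.binomial(2, p_abs, size=(int((~present).sum()), inside.size))
        redrawn[was_missing] = MISSING
        calls[:, inside] = redrawn
        loci_truth.append(
            {
                "chrom": str(chrom),
                "center_bp": int(center),
                "window_bp": int(window),
                "delta": float(delta),
                "snp_ids": [gm.snps[j].id for j in inside],
            }
        )

    samples = []
    assignments = {}
    for i, s in enumerate(gm.samples):
        traits = dict(s.traits)
        traits[trait] = "present" if present[i] else "absent"
        samples.append(
            SampleRecord(s.sample_id, s.breed, s.farm, s.sex, traits)
        )
        assignments[s.sample_id] = traits[trait]
    truth = {"assignments": {trait: assignments}, "loci": loci_truth, "trait": trait}
    return GenotypeMatrix(samples, list(gm.snps), calls), truth
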