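"""Naive pure-Python ROH enumerator used as an independent oracle in tests.

Re-derives the window-scoring detection rule with explicit loops and no
shared code with the package implementation: for every individual and
chromosome it scores every stepped window, classifies every SNP by the
fraction of qualifying covering windows, enumerates maximal candidate runs,
splits them at large gaps, and applies each acceptance predicate directly.
"""


def oracle_detect(gm, params):
    """Segments as a set of (sample_id, chrom, start_bp, end_bp, n_snps)."""
    out = set()
    chrom_order = sorted(set(s.chrom for s in gm.snps))
    for i, samp in enumerate(gm.samples):
        for chrom in chrom_order:
            idx = [j for j in range(gm.n_snps) if gm.snps[j].chrom == chrom]
            bp = [gm.snps[j].bp for j in idx]
            g = [int(gm.calls[i, j]) for j in idx]
            L = len(idx)
            if L == 0:
                continue
            if L < params.windef:
                windows = [(0, L)]
            else:
                windows = [
                    (s, s + params.windef)
                    for s in range(0, L - params.windef + 1, params.interval)
                ]
            qual = []
            for s, e in windows:
                w = g[s:e]
                qual.append(
                    w.count(1) <= params.hetallowed
                    and w.count(-1) <= params.maxmiss
                )
            cand = []
            for t in range(L):
                covering = [k for k, (s, e) in enumerate(windows) if s <= t < e]
                if not covering:
                    cand.append(False)
                else:
                    frac = sum(qual[k] for k in covering) / len(covering)
                    cand.append(frac >= params.ROHquartile - 1e-12)
            t = 0
            while t < L:
                if not cand[t]:
                    t += 1
                    continue
                u = t
                while u + 1 < L and cand[u + 1]:
                    u += 1
                piece_start = t
                for v in range(t, u + 1):
                    at_end = v == u
                    big_gap = (not at_end) and (
                        (bp[v + 1] - bp[v]) / 1000.0 > params.maxInternalGap
                    )
                    if at_end or big_gap:
                        ps, pe = piece_start, v
                        n = pe - ps + 1
                        kb = (bp[pe] - bp[ps] + 1) / 1000.0
                        if (
                            n >= params.minNsnp
                            and kb >= params.minKblength
                            and kb / n <= params.density
                        ):
                            out.add((samp.sample_id, chrom, bp[ps], bp[pe], n))
                        piece_start = v + 1
                t = u + 1
    return out


def random_fixture(rng, n_samples=5, n_snps=300, n_chroms=2):
    """Genotype fixture biased toward long homozygous stretches.

    Positions mix short and occasionally long inter-SNP gaps so that the
    length, density and internal-gap acceptance predicates all get exercised.
    """
    import numpy as np
    from conftest import make_gm

    het_rate = rng.uniform(0.02, 0.3)
    miss_rate = rng.uniform(0.0, 0.1)
    calls = rng.choice(
        [0, 2, 1, -1],
        size=(n_samples, n_snps),
        p=[
            (1 - het_rate - miss_rate) / 2,
            (1 - het_rate - miss_rate) / 2,
            het_rate,
            miss_rate,
        ],
    ).astype(np.int8)
    per = n_snps // n_chroms
    chroms, positions = [], []
    for c in range(n_chroms):
        n_c = per if c < n_chroms - 1 else n_snps - per * (n_chroms - 1)
        gaps = rng.exponential(scale=rng.uniform(30_000, 200_000), size=n_c)
        big = rng.random(n_c) < 0.02
        gaps[big] *= 20
        pos = 1 + np.cumsum(gaps).astype(np.int64)
        pos = np.unique(pos)
        while pos.size < n_c:
            pos = np.unique(np.append(pos, pos[-1] + rng.integers(1, 50_000)))
        chroms += [str(c + 1)] * n_c
        positions += list(pos[:n_c])
    return make_gm(calls, positions=positions, chroms=chroms)
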