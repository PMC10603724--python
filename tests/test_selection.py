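"""F_ST and delta-H scans, top-quantile retention, gene mapping."""

import numpy as np
import pytest

from caprapop.genotypes import DataError
from caprapop.selection import (
    GeneInterval,
    consensus_hits,
    delta_h,
    map_to_genes,
    read_bed_genes,
    select_top,
    snp_fst,
)
from caprapop.simulate import SimConfig, simulate_cohort, assign_trait_groups
from conftest import make_gm


def groups(gm, trait="horns"):
    a = [s.sample_id for s in gm.samples if s.traits.get(trait) == "present"]
    b = [s.sample_id for s in gm.samples if s.traits.get(trait) == "absent"]
    return a, b


class TestSnpFst:
    def test_equal_frequencies_zero(self):
        calls = np.array([[0, 2], [2, 0], [0, 2], [2, 0]], dtype=np.int8)
        gm = make_gm(calls)
        fst = snp_fst(gm, ["S001", "S002"], ["S003", "S004"])
        assert np.allclose(fst, 0.0)

    def test_fixed_difference_one(self):
        calls = np.array([[2], [2], [0], [0]], dtype=np.int8)
        gm = make_gm(calls)
        fst = snp_fst(gm, ["S001", "S002"], ["S003", "S004"])
        assert fst[0] == pytest.approx(1.0)

    def test_arithmetic_example(self):
        # p_a = 0.8, p_b = 0.2 -> (0.5 - 0.32)/0.5 = 0.36
        a = np.array([[2], [2], [2], [2], [0]], dtype=np.int8)
        b = np.array([[0], [0], [0], [0], [2]], dtype=np.int8)
        gm = make_gm(np.vstack([a, b]))
        fst = snp_fst(gm, [f"S{i:03d}" for i in range(1, 6)],
                      [f"S{i:03d}" for i in range(6, 11)])
        assert fst[0] == pytest.approx(0.36)

    def test_undefined_when_group_too_small(self):
        calls = np.array([[0], [-1], [2], [2]], dtype=np.int8)
        gm = make_gm(calls)
        fst = snp_fst(gm, ["S001", "S002"], ["S003", "S004"])
        assert np.isnan(fst[0])

    def test_empty_group_rejected(self):
        gm = make_gm(np.zeros((2, 2), dtype=np.int8))
        with pytest.raises(ValueError):
            snp_fst(gm, [], ["S001"])

    def test_bounded(self, small_cohort):
        gm, _ = small_cohort
        a = [s.sample_id for s in gm.samples if s.breed == "A"]
        b = [s.sample_id for s in gm.samples if s.breed == "B"]
        fst = snp_fst(gm, a, b)
        ok = ~np.isnan(fst)
        assert (fst[ok] >= 0).all() and (fst[ok] <= 1).all()


class TestDeltaH:
    def test_extremes_and_equality(self):
        assert delta_h(np.array([1.0]), np.array([0.0]))[0] == 1.0
        assert delta_h(np.array([0.3]), np.array([0.3]))[0] == 0.0
        assert delta_h(np.array([0.75]), np.array([0.25]))[0] == 0.5

    def test_panel_mismatch_rejected(self):
        with pytest.raises(DataError):
            delta_h(np.zeros(3), np.zeros(4))


class TestSelectTop:
    def test_retention_count_floor(self, rng):
        values = rng.random(48_039)
        gm = make_gm(np.zeros((1, 48_039), dtype=np.int8), spacing=50_000)
        scan = select_top(gm, values, 0.01)
        assert scan.n_selected == 480

    def test_single_max_when_fraction_small(self, rng):
        values = rng.permutation(100).astype(float)
        gm = make_gm(np.zeros((1, 100), dtype=np.int8))
        scan = select_top(gm, values, 0.01)
        assert scan.n_selected == 1
        assert scan.selected["value"].iloc[0] == values.max()
        assert scan.threshold_value == values.max()

    def test_tie_break_positional(self):
        values = np.ones(10)
        gm = make_gm(np.zeros((1, 10), dtype=np.int8))
        scan = select_top(gm, values, 0.2)
        sel = scan.selected
        assert len(sel) == 2
        assert sel["bp"].tolist() == sorted(sel["bp"].tolist())
        assert sel["bp"].tolist() == [s.bp for s in gm.snps[:2]]

    def test_nan_values_excluded_from_count(self, rng):
        values = rng.random(300)
        values[:100] = np.nan
        gm = make_gm(np.zeros((1, 300), dtype=np.int8))
        scan = select_top(gm, values, 0.05)
        assert scan.n_selected == 10  # floor(0.05 * 200)

    def test_all_undefined_rejected(self):
        gm = make_gm(np.zeros((1, 5), dtype=np.int8))
        with pytest.raises(DataError):
            select_top(gm, np.full(5, np.nan), 0.1)


class TestGeneMapping:
    def test_snp_inside_gene(self, rng):
        gm = make_gm(np.zeros((1, 10), dtype=np.int8), spacing=100_000)
        values = np.zeros(10)
        values[3] = 1.0  # bp 300001
        scan = select_top(gm, values, 0.1)
        genes = [GeneInterval("1", 250_000, 350_000, "G1")]
        assert map_to_genes(scan, genes) == [("snp00003", "G1")]

    def test_snp_outside_all_genes_unannotated(self, rng):
        gm = make_gm(np.zeros((1, 10), dtype=np.int8), spacing=100_000)
        values = np.zeros(10)
        values[9] = 1.0
        scan = select_top(gm, values, 0.1)
        genes = [GeneInterval("1", 1, 100, "G1")]
        assert map_to_genes(scan, genes, flank_bp=0) == [("snp00009", None)]

    def test_matches_brute_force(self, rng):
        gm = make_gm(np.zeros((1, 200), dtype=np.int8),
                     chroms=["1"] * 100 + ["2"] * 100,
                     positions=list(range(1, 101 * 100, 100))[:100] * 2)
        values = rng.random(200)
        scan = select_top(gm, values, 0.2)
        genes = [
            GeneInterval(str(rng.integers(1, 3)), int(lo), int(lo + rng.integers(50, 500)),
                         f"G{k}")
            for k, lo in enumerate(rng.integers(1, 10_000, size=30))
        ]
        flank = 25
        got = set(p for p in map_to_genes(scan, genes, flank) if p[1] is not None)
        expect = set()
        sel = scan.selected
        for snp_id, chrom, bp in zip(sel["snp"], sel["chrom"], sel["bp"]):
            for g in genes:
                if g.chrom == chrom and g.start_bp - flank <= bp <= g.end_bp + flank:
                    expect.add((snp_id, g.name))
        assert got == expect

    def test_bed_read_converts_coordinates(self, tmp_path):
        bed = tmp_path / "g.bed"
        bed.write_text("1\t99\t200\tGENE1\n2\t0\t50\tGENE2\n")
        genes = read_bed_genes(bed)
        assert genes[0].start_bp == 100 and genes[0].end_bp == 200
        assert genes[1].start_bp == 1 and genes[1].end_bp == 50


class TestConsensus:
    def test_disjoint_scans_empty(self, rng):
        gm = make_gm(np.zeros((1, 10), dtype=np.int8), spacing=100_000)
        v1 = np.zeros(10); v1[0] = 1
        v2 = np.zeros(10); v2[9] = 1
        genes = [GeneInterval("1", 1, 10, "Ga"), GeneInterval("1", 900_000, 999_999, "Gb")]
        s1 = select_top(gm, v1, 0.1)
        s2 = select_top(gm, v2, 0.1)
        assert consensus_hits(s1, s2, genes) == []

    def test_identical_scans_full_overlap(self, rng):
        gm = make_gm(np.zeros((1, 10), dtype=np.int8), spacing=100_000)
        v = rng.random(10)
        genes = [GeneInterval("1", 1, 2_000_000, "G")]
        s = select_top(gm, v, 0.2)
        assert consensus_hits(s, s, genes) == ["G"]


def test_consensus_gene_found_when_both_signals_present():
    """A trait window with a frequency shift plus a swept homozygous
    haplotype in carriers is recovered as a consensus gene (both the F_ST
    and delta-H top 1%) in >= 18/20 trials."""
    from caprapop.genotypes import GenotypeMatrix
    from caprapop.roh import detect_roh, roh_incidence

    hits = 0
    for trial in range(20):
        rng = np.random.default_rng(3000 + trial)
        cfg = SimConfig(
            n_breeds=1, breed_sizes=(78,), breed_names=("A",), n_snps=2000,
            n_chroms=2, chrom_length=20_000_000, fst_per_breed=(0.05,),
            missing_rate=0.0, n_related_pairs=0, seed=4000 + trial,
        )
        gm, _ = simulate_cohort(cfg)
        gm, truth = assign_trait_groups(gm, [("1", 10_000_000, 3_000_000, 0.6)],
                                        seed=5000 + trial)
        # sweep: most trait-present animals share one homozygous haplotype
        ids = {s.id: j for j, s in enumerate(gm.snps)}
        window = np.array([ids[s] for s in truth["loci"][0]["snp_ids"]])
        a, b = groups(gm)
        carriers = gm.sample_index(a[: int(len(a) * 0.8)])
        hap = rng.binomial(1, 0.5, size=window.size).astype(np.int8)
        calls = gm.calls.copy()
        calls[np.ix_(carriers, window)] = 2 * hap
        gm = GenotypeMatrix(gm.samples, gm.snps, calls)

        fst = snp_fst(gm, a, b)
        segs = detect_roh(gm)
        dh = delta_h(roh_incidence(segs, gm, a), roh_incidence(segs, gm, b))
        scan_fst = select_top(gm, fst, 0.01, "fst")
        scan_dh = select_top(gm, dh, 0.01, "delta_h")
        locus = truth["loci"][0]
        half = locus["window_bp"] // 2
        genes = [GeneInterval(locus["chrom"], locus["center_bp"] - half,
                              locus["center_bp"] + half, "TRAIT_GENE"),
                 GeneInterval("2", 1_000_000, 1_500_000, "DECOY")]
        if consensus_hits(scan_fst, scan_dh, genes) == ["TRAIT_GENE"]:
            hits += 1
    assert hits >= 18


def test_trait_locus_scan_power():
    """A strongly shifted trait window (delta 0.6) lands in the top 1%."""
    cfg = SimConfig(
        n_breeds=1, breed_sizes=(78,), breed_names=("A",), n_snps=2000,
        n_chroms=2, chrom_length=80_000_000, fst_per_breed=(0.05,),
        missing_rate=0.0, n_related_pairs=0, seed=17,
    )
    gm, _ = simulate_cohort(cfg)
    gm2, truth = assign_trait_groups(gm, [("1", 40_000_000, 2_000_000, 0.6)], seed=4)
    a, b = groups(gm2)
    fst = snp_fst(gm2, a, b)
    scan = select_top(gm2, fst, 0.01)
    window_ids = set(truth["loci"][0]["snp_ids"])
    assert window_ids & set(scan.selected["snp"])
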