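"""Genotype I/O, allele frequencies, QC ordering, relatedness, breed capping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from caprapop.genotypes import (
    MISSING,
    DataError,
    FormatError,
    QCParams,
    allele_freq,
    apply_qc,
    cap_breed_size,
    exclude_related,
    read_ped_map,
    relatedness_matrix,
    write_ped_map,
)
from caprapop.simulate import SimConfig, simulate_cohort
from conftest import make_gm


def write_files(tmp_path, ped_text, map_text):
    ped = tmp_path / "a.ped"
    mp = tmp_path / "a.map"
    ped.write_text(ped_text)
    mp.write_text(map_text)
    return ped, mp


class TestReadPedMap:
    def test_single_monomorphic_sample(self, tmp_path):
        ped, mp = write_files(tmp_path, "F1 S1 0 0 2 -9 A A\n", "1 rs1 0 100\n")
        gm = read_ped_map(ped, mp)
        assert gm.n_samples == 1 and gm.n_snps == 1
        assert gm.calls[0, 0] == 0  # only one allele seen -> reference
        assert gm.samples[0].sex == "female"

    def test_half_missing_pair_is_missing(self, tmp_path):
        ped, mp = write_files(tmp_path, "F1 S1 0 0 1 -9 A 0\n", "1 rs1 0 100\n")
        gm = read_ped_map(ped, mp)
        assert gm.calls[0, 0] == MISSING

    def test_minor_allele_is_alternate(self, tmp_path):
        ped, mp = write_files(
            tmp_path,
            "F S1 0 0 0 -9 A A\nF S2 0 0 0 -9 A A\nF S3 0 0 0 -9 A G\n",
            "1 rs1 0 100\n",
        )
        gm = read_ped_map(ped, mp)
        assert gm.snps[0].alt == "G"
        assert list(gm.calls[:, 0]) == [0, 0, 1]

    def test_tie_break_lexicographic(self, tmp_path):
        ped, mp = write_files(
            tmp_path, "F S1 0 0 0 -9 T T\nF S2 0 0 0 -9 A A\n", "1 rs1 0 100\n"
        )
        gm = read_ped_map(ped, mp)
        # equal counts: lexicographically smaller symbol is the reference
        assert gm.snps[0].ref == "A" and gm.snps[0].alt == "T"
        assert list(gm.calls[:, 0]) == [2, 0]

    def test_column_mismatch_names_row(self, tmp_path):
        ped, mp = write_files(tmp_path, "F S1 0 0 0 -9 A A G\n", "1 rs1 0 100\n")
        with pytest.raises(FormatError, match="line 1"):
            read_ped_map(ped, mp)

    def test_triallelic_names_snp(self, tmp_path):
        ped, mp = write_files(
            tmp_path,
            "F S1 0 0 0 -9 A A\nF S2 0 0 0 -9 C C\nF S3 0 0 0 -9 G G\n",
            "1 rs1 0 100\n",
        )
        with pytest.raises(DataError, match="rs1"):
            read_ped_map(ped, mp)

    def test_snps_sorted_by_chrom_bp(self, tmp_path):
        ped, mp = write_files(
            tmp_path,
            "F S1 0 0 0 -9 A A C C\n",
            "2 rs2 0 100\n1 rs1 0 500\n",
        )
        gm = read_ped_map(ped, mp)
        assert [s.id for s in gm.snps] == ["rs1", "rs2"]


class TestWritePedMap:
    def test_empty_matrix(self, tmp_path):
        gm = make_gm(np.zeros((0, 3), dtype=np.int8))
        write_ped_map(gm, tmp_path / "e.ped", tmp_path / "e.map")
        assert (tmp_path / "e.ped").read_text() == ""
        assert len((tmp_path / "e.map").read_text().splitlines()) == 3

    def test_missing_written_as_zero_pair(self, tmp_path):
        calls = np.array([[0, 1, 2], [2, MISSING, 0]], dtype=np.int8)
        gm = make_gm(calls)
        write_ped_map(gm, tmp_path / "m.ped", tmp_path / "m.map")
        genotype_cols = [" ".join(line.split()[6:])
                         for line in (tmp_path / "m.ped").read_text().splitlines()]
        assert sum(g.count("0 0") for g in genotype_cols) == 1

    def test_round_trip_exact(self, tmp_path, rng):
        cfg = SimConfig(
            n_breeds=2, breed_sizes=(5, 5), breed_names=("A", "B"), n_snps=50,
            n_chroms=2, chrom_length=5_000_000, fst_per_breed=(0.1, 0.1),
            missing_rate=0.1, n_related_pairs=0, seed=3,
        )
        gm, _ = simulate_cohort(cfg)
        write_ped_map(gm, tmp_path / "r.ped", tmp_path / "r.map")
        gm2 = read_ped_map(tmp_path / "r.ped", tmp_path / "r.map")
        assert np.array_equal(gm.calls, gm2.calls)
        assert [s.bp for s in gm.snps] == [s.bp for s in gm2.snps]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.data())
    def test_round_trip_property(self, tmp_path_factory, data):
        n = data.draw(st.integers(1, 6))
        m = data.draw(st.integers(1, 12))
        codes = data.draw(
            st.lists(
                st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=m, max_size=m),
                min_size=n, max_size=n,
            )
        )
        gm = make_gm(np.array(codes, dtype=np.int8))
        tmp = tmp_path_factory.mktemp("rt")
        write_ped_map(gm, tmp / "p.ped", tmp / "p.map")
        back = read_ped_map(tmp / "p.ped", tmp / "p.map")
        arr = np.array(codes)
        for j in range(m):
            col = arr[:, j]
            obs = col[col != MISSING]
            alt_n, ref_n = (obs == 2).sum() * 2 + (obs == 1).sum(), (obs == 0).sum() * 2 + (obs == 1).sum()
            expect = col.copy()
            if alt_n > ref_n:  # written alt becomes the major: reader flips
                expect = np.where(col != MISSING, 2 - col, MISSING)
            assert np.array_equal(back.calls[:, j], expect)


class TestAlleleFreq:
    def test_basic_counting(self):
        gm = make_gm(np.array([[0], [1], [2]], dtype=np.int8))
        assert allele_freq(gm)[0] == pytest.approx(0.5)

    def test_missing_excluded_from_denominator(self):
        gm = make_gm(np.array([[0], [0], [MISSING]], dtype=np.int8))
        assert allele_freq(gm)[0] == 0.0

    def test_all_missing_is_nan(self):
        gm = make_gm(np.array([[MISSING], [MISSING]], dtype=np.int8))
        assert np.isnan(allele_freq(gm)[0])

    def test_empty_subset_rejected(self):
        gm = make_gm(np.zeros((2, 2), dtype=np.int8))
        with pytest.raises(ValueError):
            allele_freq(gm, [])

    def test_matches_brute_force(self, rng):
        calls = rng.choice([0, 1, 2, MISSING], size=(20, 100), p=[0.3, 0.3, 0.3, 0.1])
        gm = make_gm(calls.astype(np.int8))
        p = allele_freq(gm)
        for j in range(100):
            col = calls[:, j]
            obs = col[col != MISSING]
            expect = obs.sum() / (2 * len(obs)) if len(obs) else np.nan
            assert p[j] == pytest.approx(expect, nan_ok=True)


class TestApplyQC:
    def test_low_call_sample_removed(self, rng):
        calls = rng.choice([0, 1, 2], size=(5, 100)).astype(np.int8)
        calls[0, :40] = MISSING  # call rate 0.6
        gm = make_gm(calls)
        out, rep = apply_qc(gm)
        assert out.n_samples == 4
        assert rep.removed_samples == ["S001"]

    def test_monomorphic_snp_removed_by_maf(self):
        calls = np.array([[0, 1], [0, 1], [0, 2]], dtype=np.int8)
        gm = make_gm(calls)
        out, rep = apply_qc(gm)
        assert out.n_snps == 1 and rep.n_snps_low_maf == 1

    def test_non_autosome_removed_first(self):
        calls = np.array([[0, 1], [1, 1]], dtype=np.int8)
        gm = make_gm(calls, chroms=["1", "30"])
        out, rep = apply_qc(gm)
        assert rep.n_snps_non_autosomal == 1 and out.n_snps == 1

    def test_clean_input_identity(self, rng):
        calls = rng.choice([0, 1, 2], size=(6, 50)).astype(np.int8)
        # force polymorphism
        calls[0] = 0
        calls[1] = 1
        gm = make_gm(calls)
        out, rep = apply_qc(gm)
        assert out.n_samples == 6 and out.n_snps == 50
        assert rep.n_samples_low_call == rep.n_snps_low_call == rep.n_snps_low_maf == 0

    def test_idempotent(self, small_cohort):
        gm, _ = small_cohort
        once, _ = apply_qc(gm)
        twice, rep = apply_qc(once)
        assert np.array_equal(once.calls, twice.calls)
        assert rep.n_snps_low_call == 0 and rep.n_snps_low_maf == 0

    def test_empty_cohort_error(self):
        calls = np.full((2, 10), MISSING, dtype=np.int8)
        calls[:, 0] = 1
        with pytest.raises(DataError, match="empty cohort"):
            apply_qc(make_gm(calls))


class TestExcludeRelated:
    def test_duplicate_sample_one_removed(self, rng):
        calls = rng.choice([0, 1, 2], size=(6, 300)).astype(np.int8)
        calls[3] = calls[0]
        gm = make_gm(calls)
        out, removed = exclude_related(gm, 0.25)
        assert len(removed) == 1 and removed[0] in ("S001", "S004")
        assert out.n_samples == 5

    def test_unrelated_founders_untouched(self):
        cfg = SimConfig(
            n_breeds=1, breed_sizes=(30,), breed_names=("A",), n_snps=2000,
            n_chroms=2, chrom_length=50_000_000, fst_per_breed=(0.0,),
            missing_rate=0.0, n_related_pairs=0, seed=5,
        )
        gm, _ = simulate_cohort(cfg)
        _, removed = exclude_related(gm, 0.25)
        assert removed == []

    def test_first_degree_pairs_flagged(self):
        cfg = SimConfig(
            n_breeds=1, breed_sizes=(30,), breed_names=("A",), n_snps=2000,
            n_chroms=2, chrom_length=50_000_000, fst_per_breed=(0.0,),
            missing_rate=0.0, n_related_pairs=3, seed=6,
        )
        gm, truth = simulate_cohort(cfg)
        _, removed = exclude_related(gm, 0.25)
        assert len(removed) == 3
        for r in removed:
            assert any(r in pair for pair in truth.related_pairs)

    def test_triangle_removes_two(self, rng):
        calls = rng.choice([0, 1, 2], size=(5, 400)).astype(np.int8)
        calls[1] = calls[0]
        calls[2] = calls[0]
        gm = make_gm(calls)
        out, removed = exclude_related(gm, 0.25)
        # minimal vertex cover of a 3-clique has size 2
        assert len(removed) == 2 and out.n_samples == 3

    def test_threshold_validated(self, small_cohort):
        gm, _ = small_cohort
        with pytest.raises(ValueError):
            exclude_related(gm, 0.0)

    def test_duplicate_phi_is_one(self, rng):
        calls = rng.choice([0, 1, 2], size=(3, 200)).astype(np.int8)
        calls[1] = calls[0]
        phi = relatedness_matrix(make_gm(calls))
        assert phi[0, 1] == pytest.approx(1.0)


class TestCapBreedSize:
    def test_caps_large_breed(self, rng):
        calls = rng.choice([0, 1, 2], size=(72, 20)).astype(np.int8)
        gm = make_gm(calls, breeds=["CCS"] * 72)
        out = cap_breed_size(gm, 35, seed=1)
        assert out.n_samples == 35

    def test_small_breed_kept_whole(self, rng):
        calls = rng.choice([0, 1, 2], size=(24, 20)).astype(np.int8)
        gm = make_gm(calls, breeds=["ASP"] * 24)
        assert cap_breed_size(gm, 35, seed=1).n_samples == 24

    def test_deterministic_and_genotypes_untouched(self, rng):
        calls = rng.choice([0, 1, 2], size=(50, 20)).astype(np.int8)
        gm = make_gm(calls, breeds=["A"] * 30 + ["B"] * 20)
        a = cap_breed_size(gm, 15, seed=9)
        b = cap_breed_size(gm, 15, seed=9)
        assert a.sample_ids == b.sample_ids
        idx = gm.sample_index(a.sample_ids)
        assert np.array_equal(a.calls, gm.calls[idx])


def test_qc_params_validation():
    with pytest.raises(ValueError):
        QCParams(min_maf=1.5)
    with pytest.raises(ValueError):
        QCParams(max_per_breed=0)
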