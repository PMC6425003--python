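"""EIGENSTRAT I/O, pseudo-haploid calling, merging and allele frequencies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fstatkit.eigendata import (
    MISSING,
    EigenstratFormatError,
    GenotypeDataset,
    IndividualRecord,
    PileupSite,
    SNPRecord,
    allele_frequencies,
    merge_datasets,
    pseudohaploid_call,
    read_eigenstrat,
    write_eigenstrat,
)

from conftest import random_dataset
from helpers import site_frequency


def toy_dataset():
    snps = [
        SNPRecord("rs1", "1", 0.0, 1000, "A", "G"),
        SNPRecord("rs2", "1", 0.0, 2000, "C", "T"),
    ]
    individuals = [
        IndividualRecord("i1", "M", "P1"),
        IndividualRecord("i2", "F", "P1"),
        IndividualRecord("i3", "U", "P2"),
    ]
    genotypes = np.array([[0, 1, 2], [2, MISSING, 0]], dtype=np.int8)
    return GenotypeDataset(snps, individuals, genotypes)


class TestRoundTrip:
    def test_toy_round_trip_is_byte_identical(self, tmp_path):
        ds = toy_dataset()
        paths = [tmp_path / f"a.{ext}" for ext in ("geno", "snp", "ind")]
        write_eigenstrat(ds, *paths)
        ds2 = read_eigenstrat(*paths)
        assert ds2 == ds
        paths2 = [tmp_path / f"b.{ext}" for ext in ("geno", "snp", "ind")]
        write_eigenstrat(ds2, *paths2)
        for p1, p2 in zip(paths, paths2):
            assert p1.read_bytes() == p2.read_bytes()

    def test_empty_dataset_round_trip(self, tmp_path):
        ds = GenotypeDataset([], [], np.empty((0, 0), dtype=np.int8))
        paths = [tmp_path / f"e.{ext}" for ext in ("geno", "snp", "ind")]
        write_eigenstrat(ds, *paths)
        assert read_eigenstrat(*paths) == ds

    def test_missing_written_as_nine_and_coding_flipped(self, tmp_path):
        ds = toy_dataset()
        paths = [tmp_path / f"m.{ext}" for ext in ("geno", "snp", "ind")]
        write_eigenstrat(ds, *paths)
        lines = paths[0].read_text().splitlines()
        # alt counts (0,1,2) -> reference counts (2,1,0); missing -> 9
        assert lines == ["210", "092"]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n_snps=st.integers(1, 60))
    def test_round_trip_identity_random_datasets(self, seed, n_snps, tmp_path_factory):
        ds = random_dataset(
            np.random.default_rng(seed), n_snps=n_snps, pseudo_haploid=("B",)
        )
        tmp = tmp_path_factory.mktemp("rt")
        paths = [tmp / f"r.{ext}" for ext in ("geno", "snp", "ind")]
        write_eigenstrat(ds, *paths)
        ds2 = read_eigenstrat(*paths, pseudo_haploid=[
            i.individual_id for i in ds.individuals if i.population_label == "B"
        ])
        assert ds2 == ds


class TestFormatErrors:
    def test_wrong_line_length_raises(self, tmp_path):
        ds = toy_dataset()
        paths = [tmp_path / f"x.{ext}" for ext in ("geno", "snp", "ind")]
        write_eigenstrat(ds, *paths)
        paths[0].write_text("09\n210\n")
        with pytest.raises(EigenstratFormatError, match="characters"):
            read_eigenstrat(*paths)

    def test_illegal_character_raises(self, tmp_path):
        ds = toy_dataset()
        paths = [tmp_path / f"y.{ext}" for ext in ("geno", "snp", "ind")]
        write_eigenstrat(ds, *paths)
        paths[0].write_text("2x0\n092\n")
        with pytest.raises(EigenstratFormatError, match="illegal"):
            read_eigenstrat(*paths)

    def test_line_count_mismatch_raises(self, tmp_path):
        ds = toy_dataset()
        paths = [tmp_path / f"z.{ext}" for ext in ("geno", "snp", "ind")]
        write_eigenstrat(ds, *paths)
        paths[0].write_text("210\n")
        with pytest.raises(EigenstratFormatError, match="genotype lines"):
            read_eigenstrat(*paths)


class TestDatasetInvariants:
    def test_pseudo_haploid_heterozygote_rejected(self):
        ds = toy_dataset()
        with pytest.raises(ValueError, match="pseudo-haploid"):
            GenotypeDataset(
                ds.snps, ds.individuals, ds.genotypes, np.array([False, True, False])
            )

    def test_unsorted_snps_rejected(self):
        snps = [
            SNPRecord("rs1", "1", 0.0, 2000, "A", "G"),
            SNPRecord("rs2", "1", 0.0, 1000, "C", "T"),
        ]
        with pytest.raises(ValueError, match="sorted"):
            GenotypeDataset(
                snps,
                [IndividualRecord("i1", "U", "P")],
                np.zeros((2, 1), dtype=np.int8),
            )


class TestPseudohaploidCall:
    def test_fixed_pileup_is_deterministic(self):
        snp = SNPRecord("rs1", "1", 0.0, 100, "A", "G")
        sites = [
            PileupSite(snp, {"A": 5}),
            PileupSite(snp, {}),
            PileupSite(snp, {"C": 4}),  # matches neither allele
            PileupSite(snp, {"G": 2}),
        ]
        calls = pseudohaploid_call(sites, rng=1)
        assert calls.tolist() == [0, MISSING, MISSING, 2]

    def test_never_heterozygous_and_missing_bounded(self, rng):
        snp = SNPRecord("rs1", "1", 0.0, 100, "A", "G")
        sites = [PileupSite(snp, {"A": 1, "G": 1})] * 50 + [PileupSite(snp, {})] * 10
        calls = pseudohaploid_call(sites, rng)
        assert not (calls == 1).any()
        assert (calls == MISSING).sum() >= 10

    def test_draw_proportions_match_uniform_rule(self):
        """counts {ref:3, alt:1} -> P(genotype 0) = 0.75 (Monte Carlo)."""
        snp = SNPRecord("rs1", "1", 0.0, 100, "A", "G")
        n = 10_000
        sites = [PileupSite(snp, {"A": 3, "G": 1})] * n
        calls = pseudohaploid_call(sites, rng=7)
        frac0 = (calls == 0).mean()
        se = np.sqrt(0.75 * 0.25 / n)
        assert abs(frac0 - 0.75) < 3 * se


class TestMerge:
    def test_consistent_merge_keeps_snps_and_sums_individuals(self, rng):
        a = random_dataset(rng, n_snps=40, pops=("A",), n_per_pop=3)
        b = GenotypeDataset(
            a.snps,
            [IndividualRecord(f"x{k}", "U", "X") for k in range(2)],
            rng.integers(0, 3, size=(40, 2)).astype(np.int8),
        )
        merged, log = merge_datasets(a, b)
        assert merged.n_snps == 40
        assert merged.n_individuals == 5
        assert log.empty

    def test_swapped_alleles_flip_genotypes(self):
        snp = SNPRecord("rs1", "1", 0.0, 500, "A", "G")
        flipped = SNPRecord("rs1", "1", 0.0, 500, "G", "A")
        a = GenotypeDataset(
            [snp], [IndividualRecord("a1", "U", "A")], np.array([[2]], dtype=np.int8)
        )
        b = GenotypeDataset(
            [flipped], [IndividualRecord("b1", "U", "B")], np.array([[2]], dtype=np.int8)
        )
        merged, _ = merge_datasets(a, b)
        ga = merged.genotypes[0, 0]
        gb = merged.genotypes[0, 1]
        # same underlying allele coding after reconciliation: b's 2 becomes 0
        assert (ga, gb) == (2, 0)

    def test_incompatible_alleles_dropped_and_logged(self):
        a = GenotypeDataset(
            [SNPRecord("rs1", "1", 0.0, 500, "A", "G")],
            [IndividualRecord("a1", "U", "A")],
            np.array([[1]], dtype=np.int8),
        )
        b = GenotypeDataset(
            [SNPRecord("rs1", "1", 0.0, 500, "A", "T")],
            [IndividualRecord("b1", "U", "B")],
            np.array([[1]], dtype=np.int8),
        )
        merged, log = merge_datasets(a, b)
        assert merged.n_snps == 0
        assert len(log) == 1 and log.iloc[0]["action"] == "dropped"

    def test_duplicate_individual_ids_rejected(self, rng):
        a = random_dataset(rng, n_snps=10, pops=("A",), n_per_pop=2)
        with pytest.raises(ValueError, match="duplicate"):
            merge_datasets(a, a)

    def test_merge_symmetric_in_snp_content_and_genotypes(self, rng):
        a = random_dataset(rng, n_snps=30, pops=("A",), n_per_pop=2)
        b = random_dataset(rng, n_snps=30, pops=("B",), n_per_pop=2)
        b = GenotypeDataset(
            a.snps[:20] + b.snps[20:],
            [IndividualRecord(f"b{k}", "U", "B") for k in range(2)],
            b.genotypes,
        )
        ab, _ = merge_datasets(a, b)
        ba, _ = merge_datasets(b, a)
        key = lambda ds: {(s.chromosome, s.physical_position) for s in ds.snps}
        assert key(ab) == key(ba)
        for iid in ab.individual_ids:
            ca = ab.genotypes[:, ab.indices_of([iid])[0]]
            cb = ba.genotypes[:, ba.indices_of([iid])[0]]
            assert np.array_equal(ca, cb)


class TestAlleleFrequencies:
    def test_simple_tallies(self):
        snps = [SNPRecord("rs1", "1", 0.0, 100, "A", "G")]
        inds = [IndividualRecord(f"i{k}", "U", "P") for k in range(2)]
        ds = GenotypeDataset(snps, inds, np.array([[2, 2]], dtype=np.int8))
        table = allele_frequencies(ds, ["P"])
        assert table.frequencies[0, 0] == 1.0
        assert table.allele_counts[0, 0] == 4

        ds2 = GenotypeDataset(snps, inds, np.array([[0, MISSING]], dtype=np.int8))
        table2 = allele_frequencies(ds2, ["P"])
        assert table2.frequencies[0, 0] == 0.0
        assert table2.allele_counts[0, 0] == 2

    def test_pseudo_haploid_counts_one_allele(self):
        snps = [SNPRecord("rs1", "1", 0.0, 100, "A", "G")]
        inds = [IndividualRecord("i1", "U", "P"), IndividualRecord("i2", "U", "P")]
        ds = GenotypeDataset(
            snps, inds, np.array([[2, 0]], dtype=np.int8), np.array([True, True])
        )
        table = allele_frequencies(ds, ["P"])
        assert table.frequencies[0, 0] == 0.5
        assert table.allele_counts[0, 0] == 2  # one allele per pseudo-haploid call

    def test_unknown_population_raises(self, small_dataset):
        with pytest.raises(KeyError):
            allele_frequencies(small_dataset, ["nope"])

    def test_matches_brute_force_tally(self, rng):
        ds = random_dataset(
            rng, n_snps=60, pops=("A", "B"), n_per_pop=3, pseudo_haploid=("B",),
            missing_rate=0.25,
        )
        table = allele_frequencies(ds, ["A", "B"])
        for pop in ("A", "B"):
            col = table.column(pop)
            for s in range(ds.n_snps):
                f, c = site_frequency(ds, pop, s)
                assert table.allele_counts[s, col] == c
                if c:
                    assert table.frequencies[s, col] == pytest.approx(f, abs=1e-12)
                    assert 0.0 <= table.frequencies[s, col] <= 1.0
                else:
                    assert np.isnan(table.frequencies[s, col])
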