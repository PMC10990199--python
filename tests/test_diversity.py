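from __future__ import annotations

import itertools

import numpy as np
import pytest

from haploatlas.distances import distance_matrix, p_distance
from haploatlas.diversity import (detect_barcode_sharing, haplotype_diversity,
                                  nearest_neighbor, nucleotide_diversity,
                                  percent_coverage)
from haploatlas.synthetic import preset, simulate

from conftest import make_dataset


class TestNucleotideDiversity:
    def test_two_specimens(self):
        ds = make_dataset([("S1", "Sp", 0, 0, "A" * 100),
                           ("S2", "Sp", 0, 0, "T" + "A" * 99)])
        assert nucleotide_diversity(distance_matrix(ds)) == pytest.approx(0.01)

    def test_identical_specimens_zero(self):
        ds = make_dataset([(f"S{i}", "Sp", 0, 0, "ACGT") for i in range(4)])
        assert nucleotide_diversity(distance_matrix(ds)) == 0.0

    def test_duplicated_haplotype_weights_pairs(self):
        # {A, A, B} with d(A,B)=0.3 -> (0 + 0.3 + 0.3)/3 = 0.2
        a, b = "A" * 10, "T" * 3 + "A" * 7
        ds = make_dataset([("S1", "Sp", 0, 0, a), ("S2", "Sp", 0, 0, a),
                           ("S3", "Sp", 0, 0, b)])
        assert nucleotide_diversity(distance_matrix(ds)) == pytest.approx(0.2)

    def test_matches_bruteforce_pair_loop(self):
        rng = np.random.default_rng(11)
        seqs = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(12)]
        ds = make_dataset([(f"S{i:02d}", "Sp", 0, 0, s)
                           for i, s in enumerate(seqs)])
        pi = nucleotide_diversity(distance_matrix(ds))
        brute = np.mean([p_distance(a, b)[0]
                         for a, b in itertools.combinations(seqs, 2)])
        assert pi == pytest.approx(brute, abs=1e-12)


class TestHaplotypeDiversity:
    def test_single_haplotype_zero(self):
        assert haplotype_diversity([7]) == 0.0

    def test_two_singletons_is_one(self):
        assert haplotype_diversity([1, 1]) == pytest.approx(1.0)

    def test_closed_form(self):
        # counts {5,3,2}, N=10 -> (10/9)(1 - 0.25 - 0.09 - 0.04)
        assert haplotype_diversity([5, 3, 2], N=10) == pytest.approx(
            (10 / 9) * (1 - 0.25 - 0.09 - 0.04))

    def test_bounds_on_random_counts(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            counts = rng.integers(1, 10, size=rng.integers(1, 8))
            if counts.sum() < 2:
                continue
            h = haplotype_diversity(list(counts))
            assert 0.0 <= h <= 1.0


class TestNearestNeighbor:
    def test_single_pair(self):
        focal = make_dataset([("F1", "Sp a", 0, 0, "AAAA")])
        other = make_dataset([("O1", "Sp b", 0, 0, "AAAT")])
        nnd, sp = nearest_neighbor(focal, {"Sp b": other})
        assert nnd == pytest.approx(0.25) and sp == "Sp b"

    def test_shared_haplotype_gives_zero(self):
        focal = make_dataset([("F1", "Sp a", 0, 0, "ACGTACGT")])
        other = make_dataset([("O1", "Sp b", 0, 0, "ACGTACGT")])
        nnd, sp = nearest_neighbor(focal, {"Sp b": other})
        assert nnd == 0.0

    def test_minimum_over_species_bruteforce(self):
        rng = np.random.default_rng(3)
        focal_seqs = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(4)]
        others = {f"Sp {k}": ["".join(rng.choice(list("ACGT"), 50))
                              for _ in range(3)] for k in "bcd"}
        focal = make_dataset([(f"F{i}", "Sp a", 0, 0, s)
                              for i, s in enumerate(focal_seqs)])
        datasets = {sp: make_dataset([(f"{sp}-{i}", sp, 0, 0, s)
                                      for i, s in enumerate(seqs)])
                    for sp, seqs in others.items()}
        nnd, sp = nearest_neighbor(focal, datasets)
        brute = min((p_distance(a, b)[0], name)
                    for name, seqs in others.items()
                    for a in focal_seqs for b in seqs)
        assert nnd == pytest.approx(brute[0])
        assert sp == brute[1]


class TestBarcodeSharing:
    def test_verbatim_sharing_detected(self):
        shared = "ACGT" * 5
        a = make_dataset([("A1", "Sp a", 0, 0, shared),
                          ("A2", "Sp a", 0, 0, "TCGT" + "ACGT" * 4)])
        b = make_dataset([("B1", "Sp b", 0, 0, shared)])
        out = detect_barcode_sharing({"Sp a": a, "Sp b": b})
        assert out == [("Sp a", "Sp b", 1)]

    def test_divergent_species_empty(self):
        a = make_dataset([("A1", "Sp a", 0, 0, "A" * 20)])
        b = make_dataset([("B1", "Sp b", 0, 0, "T" * 20)])
        assert detect_barcode_sharing({"Sp a": a, "Sp b": b}) == []

    def test_sharing_iff_nnd_zero(self):
        ds, _ = simulate(preset("shared_pair", seed=9))
        parts = ds.partition_by_species()
        sharing = detect_barcode_sharing(parts)
        sharing_species = {s for pair in sharing for s in pair[:2]}
        for sp in parts:
            others = {s: d for s, d in parts.items() if s != sp}
            nnd, _ = nearest_neighbor(parts[sp], others)
            assert (nnd == 0.0) == (sp in sharing_species)


def test_percent_coverage_rounds_to_whole_percent():
    assert percent_coverage(9, 10) == 90
    assert percent_coverage(2, 3) == 67
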