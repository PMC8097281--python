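"""Genotypic distances, HAF reconstruction, de novo criteria, rarefaction."""

import numpy as np
import pandas as pd
import pytest

from ploidyscan import datamodel as dm
from ploidyscan import haplotypes as hap


class TestGenotypicDistance:
    @pytest.mark.parametrize("d1,d2,expected", [
        (2, 0, 1), (0, 2, 1), (2, 1, 0), (1, 0, 0), (1, 1, 0), (2, 2, 0),
    ])
    def test_diploid_pairs(self, d1, d2, expected):
        assert hap.genotypic_distance(d1, 2, d2, 2) == expected

    @pytest.mark.parametrize("d1,d2,expected", [
        (4, 0, 1), (3, 0, 1), (4, 1, 1), (0, 3, 1), (0, 4, 1), (1, 4, 1),
        (3, 1, 0), (2, 0, 0), (4, 2, 0), (2, 2, 0),
    ])
    def test_tetraploid_pairs(self, d1, d2, expected):
        assert hap.genotypic_distance(d1, 4, d2, 4) == expected

    @pytest.mark.parametrize("d_dip,d_tet,expected", [
        (2, 0, 1), (2, 1, 1), (0, 4, 1), (0, 3, 1),
        (2, 2, 0), (1, 0, 0), (1, 4, 0), (0, 2, 0),
    ])
    def test_cross_ploidy_pairs(self, d_dip, d_tet, expected):
        assert hap.genotypic_distance(d_dip, 2, d_tet, 4) == expected

    def test_exhaustive_characterizations(self):
        """The printed pair lists equal their dosage characterizations:
        diploid |d1-d2| == 2; tetraploid |d1-d2| >= 3; cross-ploidy diploid
        homozygous with tetraploid sharing <= 1 copy of its allele."""
        for d1 in range(3):
            for d2 in range(3):
                assert hap.genotypic_distance(d1, 2, d2, 2) == int(abs(d1 - d2) == 2)
        for d1 in range(5):
            for d2 in range(5):
                assert hap.genotypic_distance(d1, 4, d2, 4) == int(abs(d1 - d2) >= 3)
        for d in range(3):
            for t in range(5):
                if d == 2:
                    expect = int(t <= 1)        # tetraploid copies of ALT allele
                elif d == 0:
                    expect = int(4 - t <= 1)    # tetraploid copies of REF allele
                else:
                    expect = 0
                assert hap.genotypic_distance(d, 2, t, 4) == expect

    def test_symmetry_and_missing(self):
        for args in [(2, 2, 3, 4), (0, 4, 2, 2), (4, 4, 1, 4)]:
            d1, p1, d2, p2 = args
            assert hap.genotypic_distance(d1, p1, d2, p2) == \
                hap.genotypic_distance(d2, p2, d1, p1)
        assert hap.genotypic_distance(dm.MISSING, 2, 0, 2) == 0

    def test_invalid_dosage_rejected(self):
        with pytest.raises(ValueError):
            hap.genotypic_distance(3, 2, 0, 2)


class TestHamming:
    def test_identical_genotypes(self):
        assert hap.hamming_distance(np.array([1, 2, 0]), 2,
                                    np.array([1, 2, 0]), 2) == 0

    def test_all_opposite_homozygotes(self):
        assert hap.hamming_distance(np.array([2, 2, 2]), 2,
                                    np.array([0, 0, 0]), 2) == 3

    def test_heterozygous_middle_site_ignored(self):
        assert hap.hamming_distance(np.array([2, 1, 0]), 2,
                                    np.array([0, 1, 2]), 2) == 2

    def test_diameter(self):
        group = np.array([[0, 2, 0], [0, 2, 2]]).T  # sites x individuals
        group = np.array([[0, 0], [2, 2], [0, 2]])
        assert hap.hamming_diameter(group, np.array([2, 2])) == 1
        mono = np.zeros((3, 4), dtype=int)
        assert hap.hamming_diameter(mono, np.full(4, 2)) == 0
        two = np.array([[0, 2], [0, 2]])
        assert hap.hamming_diameter(two, np.array([2, 2])) == 2


class TestHaf:
    @pytest.mark.parametrize("m,expected", [
        ((0.9, 0.8), (0.8, 0.1, 0.1)),
        ((1.0, 1.0, 1.0), (1.0, 0.0, 0.0)),
        ((0.7,), (0.7, 0.3, 0.0)),
    ])
    def test_worked_values(self, m, expected):
        got = hap.reconstruct_haf(m)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_identities_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            m = rng.uniform(0, 1, size=rng.integers(1, 12))
            hafd, hafa, hafr = hap.reconstruct_haf(m)
            assert hafd + hafa + hafr == pytest.approx(1.0, abs=1e-12)
            for x in (hafd, hafa, hafr):
                assert -1e-12 <= x <= 1 + 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hap.reconstruct_haf([])


def _panel(dosages_dip, dosages_tet):
    """Matrix from per-individual dosage vectors (sites x individuals)."""
    n_sites = len(dosages_dip[0])
    inds = ([dm.Individual(f"d{i}", f"P{i//2}", "L1", 2)
             for i in range(len(dosages_dip))]
            + [dm.Individual(f"t{i}", "TP", "tetraploid", 4)
               for i in range(len(dosages_tet))])
    variants = [dm.Variant("c", p + 1, "A", "G", "alt") for p in range(n_sites)]
    dosage = np.column_stack(dosages_dip + dosages_tet).astype(np.int16)
    return dm.GenotypeMatrix(variants, inds, dosage,
                             np.full((n_sites, len(inds)), 30, np.int32))


class TestScreenAndVerdict:
    def test_standing_screen(self):
        gm = _panel([[0, 0], [1, 0], [0, 0]], [])
        out = hap.standing_screen(gm, [("c", 1), ("c", 2)])
        assert out["present"].tolist() == [True, False]
        assert out["carrier_count"].tolist() == [1, 0]

    def test_screen_requires_known_sites(self):
        gm = _panel([[0, 0]], [])
        with pytest.raises(KeyError):
            hap.standing_screen(gm, [("c", 99)])

    def test_full_haplotype_presence_counts_cooccurrence(self):
        # one diploid carries the derived allele at both sites, one at a
        # single site only
        gm = _panel([[1, 1], [1, 0], [0, 0]], [])
        dip = gm.take_individuals([0, 1, 2])
        assert hap.haplotype_presence_in_diploids(dip, [("c", 1), ("c", 2)]) == 1

    def test_de_novo_gene_report_and_verdict(self):
        # diploids monomorphic ancestral; tetraploids carry the derived
        # haplotype at high dosage
        gm = _panel(
            [[0, 0, 0]] * 4,
            [[4, 4, 4], [3, 3, 3], [4, 4, 4]],
        )
        report = hap.gene_hamming_report(gm, "g", [("c", 1), ("c", 2), ("c", 3)],
                                         statistic="median")
        assert report.diameter_diploid == 0
        assert report.distance_between == 3
        dip = gm.take_individuals(gm.individual_indices(lambda i: i.ploidy == 2))
        screen = hap.standing_screen(dip, [("c", 1), ("c", 2), ("c", 3)])
        verdict = hap.de_novo_verdict("g", screen, 0, report)
        assert verdict.verdict

    def test_conjunction_fails_when_distance_within_diameter(self):
        # a diploid pair of opposite homozygotes widens the diameter
        gm = _panel(
            [[0, 0, 0], [2, 2, 2], [0, 0, 0]],
            [[2, 2, 2], [2, 2, 2]],
        )
        report = hap.gene_hamming_report(gm, "g", [("c", 1), ("c", 2), ("c", 3)],
                                         statistic="median")
        assert report.diameter_diploid == 3
        dip = gm.take_individuals(gm.individual_indices(lambda i: i.ploidy == 2))
        screen = hap.standing_screen(dip, [("c", 1), ("c", 2), ("c", 3)])
        verdict = hap.de_novo_verdict("g", screen, 0, report)
        assert not verdict.criterion_C_distance_exceeds_diameter
        assert not verdict.verdict

    def test_haf_table_tetraploid_population(self):
        gm = _panel([[0, 0]] * 10, [[4, 4], [4, 3], [3, 4]])
        table = hap.haf_table(gm, "g", [("c", 1), ("c", 2)])
        tet = table[table["population"] == "TP"].iloc[0]
        # derived is minor overall (20 dip vs 12 tet chromosomes), so M_i is
        # the ancestral frequency in the tetraploid population: 1/12 each
        assert tet["HAFd"] == pytest.approx(1 / 12)
        assert tet["HAFa"] == pytest.approx(1 - 1 / 12)
        dip = table[table["population"] == "P0"].iloc[0]
        assert dip["HAFd"] == pytest.approx(1.0)


class TestRarefaction:
    def test_full_panel_recovers_everything(self):
        gm = _panel([[1, 0], [0, 1], [1, 1]], [])
        out = hap.rarefaction_curve(gm, np.ones(2, bool), [3], 5, seed=0)
        assert out["mean_fraction"].iloc[0] == 1.0

    def test_singleton_panel_expectation(self):
        # each of 5 individuals carries exactly one private singleton:
        # a single sampled individual recovers exactly 1/5 of variants
        dosages = [[1 if i == j else 0 for i in range(5)] for j in range(5)]
        gm = _panel(dosages, [])
        out = hap.rarefaction_curve(gm, np.ones(5, bool), [1], 40, seed=1)
        assert out["mean_fraction"].iloc[0] == pytest.approx(0.2)

    def test_monotone_in_sample_size(self):
        rng = np.random.default_rng(2)
        dosages = [list(rng.binomial(2, 0.2, size=30)) for _ in range(20)]
        gm = _panel(dosages, [])
        out = hap.rarefaction_curve(gm, np.ones(30, bool), [2, 5, 10, 20],
                                    30, seed=3)
        fracs = out["mean_fraction"].to_numpy()
        assert (np.diff(fracs) > -0.05).all()

    def test_oversized_subsample_rejected(self):
        gm = _panel([[1, 0]], [])
        with pytest.raises(ValueError):
            hap.rarefaction_curve(gm, np.ones(2, bool), [2], 3, seed=0)
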