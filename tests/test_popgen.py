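"""Frequency machinery, diversity statistics and Hudson F_ST.

The Tajima's D oracle below is an independent re-derivation (its constants
are computed with numpy vector operations rather than the package's scalar
loops) used to cross-check the implementation on random inputs.
"""

import numpy as np
import pytest

from ploidyscan import datamodel as dm
from ploidyscan import popgen
from ploidyscan.simulate import SimConfig, generate_bundle


# --- independent oracles ---------------------------------------------------

def tajima_d_oracle(S, pi_sum, n):
    i = np.arange(1, n)
    a1 = (1.0 / i).sum()
    a2 = (1.0 / i**2).sum()
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    var = (c1 / a1) * S + (c2 / (a1**2 + a2)) * S * (S - 1)
    return (pi_sum - S / a1) / np.sqrt(var)


def hudson_fst_oracle(p1, n1, p2, n2):
    within = p1 * (1 - p1) / (n1 - 1) + p2 * (1 - p2) / (n2 - 1)
    between = p1 * (1 - p2) + p2 * (1 - p1)
    return ((p1 - p2) ** 2 - within) / between


def site_pi_oracle(ac, an):
    # explicit pair enumeration over an allele vector
    alleles = np.array([1] * ac + [0] * (an - ac))
    diff = sum(alleles[i] != alleles[j]
               for i in range(an) for j in range(i + 1, an))
    return diff / (an * (an - 1) / 2)


class TestSitePi:
    @pytest.mark.parametrize("ac,an,expected", [
        (0, 10, 0.0),
        (1, 2, 1.0),
        (2, 4, 2 * 2 * 2 / (4 * 3)),
    ])
    def test_worked_values(self, ac, an, expected):
        assert popgen.site_pi(ac, an) == pytest.approx(expected, abs=1e-12)

    def test_matches_pair_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            an = int(rng.integers(2, 30))
            ac = int(rng.integers(0, an + 1))
            assert popgen.site_pi(ac, an) == pytest.approx(
                site_pi_oracle(ac, an), abs=1e-12)

    def test_maximum_at_half_frequency(self):
        an = 20
        values = [popgen.site_pi(j, an) for j in range(an + 1)]
        assert int(np.argmax(values)) == an // 2

    def test_undefined_below_two_chromosomes(self):
        assert np.isnan(popgen.site_pi(0, 1))


class TestTajimasD:
    def test_zero_when_estimators_agree(self):
        n, S = 10, 16
        a1 = sum(1 / i for i in range(1, n))
        assert popgen.tajimas_d(S, S / a1, n) == pytest.approx(0.0, abs=1e-12)

    def test_worked_value_against_oracle(self):
        d = popgen.tajimas_d(16, 3.888889, 10)
        assert d == pytest.approx(tajima_d_oracle(16, 3.888889, 10), abs=1e-9)

    def test_oracle_agreement_random(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(4, 200))
            S = int(rng.integers(1, 500))
            pi_sum = float(rng.uniform(0, 2 * S))
            assert popgen.tajimas_d(S, pi_sum, n) == pytest.approx(
                tajima_d_oracle(S, pi_sum, n), abs=1e-9)

    def test_neutral_sfs_gives_small_d(self):
        # expected folded-free SFS xi_i proportional to 1/i
        rng = np.random.default_rng(2)
        n, S = 40, 4000
        weights = 1 / np.arange(1, n)
        counts = rng.choice(np.arange(1, n), size=S, p=weights / weights.sum())
        pi_sum = popgen.site_pi(counts, n).sum()
        assert abs(popgen.tajimas_d(S, float(pi_sum), n)) < 0.2

    def test_no_segregating_sites_undefined(self):
        assert popgen.tajimas_d(0, 0.0, 10) is None


class TestHudsonFst:
    def test_fixed_difference_is_one(self):
        assert popgen.hudson_fst(1.0, 20, 0.0, 20) == pytest.approx(1.0)

    def test_monomorphic_is_undefined(self):
        assert np.isnan(popgen.hudson_fst(0.0, 20, 0.0, 20))

    def test_worked_value(self):
        got = popgen.hudson_fst(0.5, 20, 0.9, 20)
        assert got == pytest.approx(0.1421053 / 0.5, abs=1e-6)

    def test_oracle_and_invariants(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            p1, p2 = rng.uniform(0.01, 0.99, 2)
            n1, n2 = rng.integers(2, 300, 2)
            got = popgen.hudson_fst(p1, n1, p2, n2)
            assert got == pytest.approx(
                hudson_fst_oracle(p1, n1, p2, n2), abs=1e-9)
            assert got <= 1.0
            # symmetry under group swap and allele relabeling
            assert got == pytest.approx(popgen.hudson_fst(p2, n2, p1, n1), abs=1e-12)
            assert got == pytest.approx(
                popgen.hudson_fst(1 - p1, n1, 1 - p2, n2), abs=1e-12)

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            popgen.hudson_fst(0.5, 1, 0.5, 10)


class TestAfdAndQuantile:
    def test_afd(self):
        assert popgen.afd(0.9, 0.2) == pytest.approx(0.7)
        assert popgen.afd(0.4, 0.4) == 0.0
        assert popgen.afd(0.0, 1.0) == 1.0

    def test_quantile_interpolates_order_statistics(self):
        values = np.arange(1, 101) / 100.0
        assert popgen.neutral_quantile(values, 0.99) == pytest.approx(
            np.quantile(values, 0.99))
        assert popgen.neutral_quantile(values, 0.99) == pytest.approx(0.9901)

    def test_constant_values(self):
        assert popgen.neutral_quantile(np.full(200, 0.3)) == 0.3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            popgen.neutral_quantile(np.array([np.nan]))


def _toy_matrix():
    inds = ([dm.Individual(f"d{i}", "P1", "L1", 2) for i in range(4)]
            + [dm.Individual(f"e{i}", "P2", "L2", 2) for i in range(4)])
    variants = [dm.Variant("c", p, "A", "G", "alt") for p in (1, 2, 3)]
    dosage = np.array([
        [1, 1, 1, 1, 0, 0, 0, 0],
        [2, 2, 0, 0, 1, 1, 1, 1],
        [0, 0, 0, 0, 0, 0, 0, 0],
    ], dtype=np.int16)
    depth = np.full((3, 8), 30, dtype=np.int32)
    return dm.GenotypeMatrix(variants, inds, dosage, depth)


class TestFiltersAndFrequencies:
    def test_depth_exactly_eight_masked(self):
        gm = _toy_matrix()
        gm.depth[0, 0] = 8
        out = popgen.apply_genotype_filters(gm, min_depth=8, max_missing=0.5)
        assert out.dosage[0, 0] == dm.MISSING
        assert out.dosage[0, 1] == 1

    def test_group_missingness_drops_variant(self):
        gm = _toy_matrix()
        gm.dosage[1, :2] = dm.MISSING  # 2/4 missing in L1 -> 0.5 >= 0.5
        out = popgen.apply_genotype_filters(gm)
        assert len(out.variants) == 2
        assert out.variants[0].pos == 1

    def test_clean_matrix_unchanged(self):
        gm = _toy_matrix()
        out = popgen.apply_genotype_filters(gm)
        np.testing.assert_array_equal(out.dosage, gm.dosage)

    def test_group_frequencies_worked_examples(self):
        gm = _toy_matrix()
        freq = popgen.group_frequencies(gm, {"L1": [0, 1, 2, 3], "L2": [4, 5, 6, 7]})
        assert freq.group_f("L1")[0] == pytest.approx(0.5)   # 4 hets
        assert freq.group_an("L1")[0] == 8
        assert freq.group_f("L2")[2] == 0.0

    def test_all_missing_gives_null_frequency(self):
        gm = _toy_matrix()
        gm.dosage[2, 4:] = dm.MISSING
        freq = popgen.group_frequencies(gm, {"L2": [4, 5, 6, 7]})
        assert np.isnan(freq.group_f("L2")[2])

    def test_tetraploid_counting(self):
        inds = [dm.Individual(f"t{i}", "T", "tet", 4) for i in range(3)]
        variants = [dm.Variant("c", 1, "A", "G", "alt")]
        dosage = np.array([[4, 4, dm.MISSING]], dtype=np.int16)
        gm = dm.GenotypeMatrix(variants, inds, dosage, np.full((1, 3), 30))
        freq = popgen.group_frequencies(gm, {"tet": [0, 1, 2]})
        assert freq.ac[0, 0] == 8 and freq.an[0, 0] == 8
        assert freq.group_f("tet")[0] == 1.0


class TestSubsampling:
    def test_sixteen_deepest_of_twenty(self):
        inds = [dm.Individual(f"d{i}", "P", "L", 2) for i in range(20)]
        variants = [dm.Variant("c", 1, "A", "G", "alt")]
        depth = np.arange(20, dtype=np.int32).reshape(1, 20) + 10
        gm = dm.GenotypeMatrix(variants, inds, np.zeros((1, 20), np.int16), depth)
        chosen = popgen.subsample_chromosomes(gm, list(range(20)), 32)
        assert len(chosen) == 16
        assert set(chosen) == set(range(4, 20))  # the 16 deepest

    def test_exact_fit_keeps_everyone(self):
        inds = [dm.Individual(f"t{i}", "P", "L", 4) for i in range(40)]
        variants = [dm.Variant("c", 1, "A", "G", "alt")]
        gm = dm.GenotypeMatrix(variants, inds, np.zeros((1, 40), np.int16),
                               np.full((1, 40), 30))
        assert len(popgen.subsample_chromosomes(gm, list(range(40)), 160)) == 40

    def test_unrepresentable_target_rejected(self):
        inds = [dm.Individual(f"d{i}", "P", "L", 2) for i in range(20)]
        variants = [dm.Variant("c", 1, "A", "G", "alt")]
        gm = dm.GenotypeMatrix(variants, inds, np.zeros((1, 20), np.int16),
                               np.full((1, 20), 30))
        with pytest.raises(ValueError, match="not representable"):
            popgen.subsample_chromosomes(gm, list(range(20)), 33)

    def test_too_small_group_rejected(self):
        inds = [dm.Individual(f"d{i}", "P", "L", 2) for i in range(5)]
        variants = [dm.Variant("c", 1, "A", "G", "alt")]
        gm = dm.GenotypeMatrix(variants, inds, np.zeros((1, 5), np.int16),
                               np.full((1, 5), 30))
        with pytest.raises(ValueError, match="cannot supply"):
            popgen.subsample_chromosomes(gm, list(range(5)), 32)


class TestPolarize:
    def _gm(self, dosages):
        inds = [dm.Individual(f"d{i}", "P", "L", 2) for i in range(len(dosages))]
        variants = [dm.Variant("c", 1, "A", "G")]
        return dm.GenotypeMatrix(variants, inds,
                                 np.array([dosages], np.int16),
                                 np.full((1, len(dosages)), 30))

    def test_outgroup_fixed_ref_makes_alt_derived(self):
        gm = popgen.polarize(self._gm([1, 1, 0, 0]), {("c", 1): "A"})
        assert gm.variants[0].derived_allele == "alt"

    def test_minor_allele_rule(self):
        # overall ALT frequency 0.7 -> REF is minor, hence derived
        gm = popgen.polarize(self._gm([2, 2, 2, 1, 0]), {})
        assert gm.variants[0].derived_allele == "ref"

    def test_exact_tie_resolves_to_alt(self):
        gm = popgen.polarize(self._gm([2, 0]), {})
        assert gm.variants[0].derived_allele == "alt"


class TestDiversityOnGenerator:
    def test_pi_matches_model_expectation_and_ploidies_agree(self):
        """Lineage pi on neutral sites is within 15% of the drift model's
        expected heterozygosity, and diploid/tetraploid pi agree."""
        cfg = SimConfig(seed=13, sweep_plan=[], mnm_plan=[], generate_msas=False)
        bundle = generate_bundle(cfg)
        gm = bundle.genotypes
        fourfold = np.array([a.fourfold for a in bundle.annotations])
        # E[2 f (1-f)] = 2 (1-F) E[p(1-p)] under Balding-Nichols drift
        lo = 1 / (2 * cfg.n_grid)
        hi = 1 - lo
        c = 1 / np.log(hi / lo)
        e_p1p = c * ((hi - lo) - (hi**2 - lo**2) / 2)
        expected = 2 * (1 - 0.15) * e_p1p
        pis = {}
        for lineage in ("Baltic", "tetraploid"):
            cols = gm.individual_indices(lambda i, lin=lineage: i.lineage == lin)
            res = popgen.diversity(gm, list(cols), fourfold, lineage)
            pis[lineage] = res.pi
            assert abs(res.pi - expected) / expected < 0.15
            assert res.tajima_d is not None and abs(res.tajima_d) < 2.0
        assert abs(pis["Baltic"] - pis["tetraploid"]) / pis["Baltic"] < 0.15
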