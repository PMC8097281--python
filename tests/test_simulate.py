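"""Synthetic-data generator: hierarchical frequencies, planting, determinism."""

import numpy as np
import pytest

from ploidyscan import datamodel as dm
from ploidyscan.conservation import pai_column
from ploidyscan.simulate import (
    MnmPlan, SimConfig, SimulationError, SweepPlan, TruthRecord,
    generate_bundle, plant_mnm, plant_sweep, sample_genotypes,
    simulate_frequencies, simulate_msa,
)

LINEAGES = ["L1", "L2", "L3", "L4", "L5", "tetraploid"]


def small_cfg(**kw):
    base = dict(seed=3, n_genes=10, n_sites_per_gene=20, sweep_plan=[],
                mnm_plan=[], generate_msas=False)
    base.update(kw)
    return SimConfig(**base)


class TestFrequencies:
    def test_low_drift_limit_recovers_ancestral(self):
        cfg = small_cfg(lineage_divergence={l: 1e-4 for l in LINEAGES})
        freqs, p = simulate_frequencies(cfg, np.random.default_rng(0), n_sites=500)
        assert np.max(np.abs(freqs - p[None, :])) < 0.05

    def test_deterministic_under_seed(self):
        cfg = small_cfg()
        f1, p1 = simulate_frequencies(cfg)
        f2, p2 = simulate_frequencies(cfg)
        np.testing.assert_array_equal(f1, f2)
        np.testing.assert_array_equal(p1, p2)

    def test_lineage_mean_matches_ancestral_mean(self):
        # law of total expectation: E[f_lineage] = E[p]
        cfg = small_cfg()
        freqs, p = simulate_frequencies(cfg, np.random.default_rng(1), n_sites=10_000)
        se = freqs.std() / np.sqrt(freqs.shape[1])
        assert abs(freqs.mean() - p.mean()) < 4 * se + 0.01

    def test_invalid_drift_rejected(self):
        with pytest.raises(SimulationError, match="drift"):
            small_cfg(lineage_divergence={"L1": 1.5})


class TestPlanting:
    def _freqs(self, n=30):
        rng = np.random.default_rng(0)
        return rng.uniform(0.05, 0.5, size=(6, n)), rng

    def test_de_novo_zeroes_all_diploid_lineages(self):
        freqs, rng = self._freqs()
        idx = np.array([2, 5, 9])
        hap = plant_sweep(freqs, LINEAGES, idx, "de_novo", 0.9, rng)
        assert (freqs[:5][:, idx] == 0).all()
        assert (freqs[5, idx] == 0.9).all()
        assert hap["tetraploid"] == 0.9

    def test_standing_keeps_positive_diploid_frequency(self):
        freqs, rng = self._freqs()
        idx = np.array([1, 3])
        hap = plant_sweep(freqs, LINEAGES, idx, "standing", 0.9, rng,
                          source_lineage="L2")
        assert 0.02 <= hap["L2"] <= 0.15
        assert (freqs[LINEAGES.index("L2"), idx] > 0).all()

    def test_parallel_sets_two_lineages(self):
        freqs, rng = self._freqs()
        idx = np.array([0])
        plant_sweep(freqs, LINEAGES, idx, "parallel", 0.85, rng,
                    source_lineage="L1")
        assert freqs[0, 0] == 0.85 and freqs[5, 0] == 0.85

    def test_none_is_bitwise_identity(self):
        freqs, rng = self._freqs()
        before = freqs.copy()
        plant_sweep(freqs, LINEAGES, np.array([0, 1]), "none", 0.9, rng)
        np.testing.assert_array_equal(freqs, before)

    @pytest.mark.parametrize("tv_prob,expect", [(1.0, True), (0.0, False)])
    def test_mnm_transversion_control(self, tv_prob, expect):
        rng = np.random.default_rng(0)
        pos, is_tv = plant_mnm(1000, 4000, 5, 19, tv_prob, rng)
        assert (is_tv == expect).all()
        assert (np.diff(pos) <= 19).all() and (np.diff(pos) > 0).all()

    def test_mnm_gene_too_short(self):
        with pytest.raises(SimulationError, match="too short"):
            plant_mnm(100, 110, 8, 19, 0.5, np.random.default_rng(0))


class TestGenotypes:
    def _inds(self):
        return ([dm.Individual(f"d{i}", "P", "L1", 2) for i in range(4)]
                + [dm.Individual(f"t{i}", "T", "tetraploid", 4) for i in range(4)])

    def _variants(self, n):
        return [dm.Variant("c", i + 1, "A", "G", "alt") for i in range(n)]

    def test_fixed_and_absent_alleles(self):
        freqs = np.vstack([np.ones((6, 3)), ]) * 0
        freqs[:, 0] = 1.0
        gm = sample_genotypes(freqs[:6], self._variants(3), self._inds(), LINEAGES,
                              depth_mean=40, missing_rate=0.0,
                              rng=np.random.default_rng(0))
        nonmiss = gm.dosage != dm.MISSING
        assert (gm.dosage[0][nonmiss[0]] == gm.ploidy[nonmiss[0]]).all()
        assert (gm.dosage[1][nonmiss[1]] == 0).all()

    def test_binomial_mean_tetraploid(self):
        n = 10_000
        freqs = np.full((6, n), 0.5)
        inds = [dm.Individual("t", "T", "tetraploid", 4)]
        gm = sample_genotypes(freqs, self._variants(n), inds, LINEAGES,
                              depth_mean=40, missing_rate=0.0,
                              rng=np.random.default_rng(2))
        d = gm.dosage[gm.dosage != dm.MISSING].astype(float)
        se = 1.0 / np.sqrt(d.size)  # binomial(4, .5) sd = 1
        assert abs(d.mean() - 2.0) < 3 * se

    def test_low_depth_forced_missing(self):
        n = 2000
        freqs = np.full((6, n), 0.5)
        gm = sample_genotypes(freqs, self._variants(n), self._inds(), LINEAGES,
                              depth_mean=8, missing_rate=0.0,
                              rng=np.random.default_rng(3))
        assert ((gm.depth <= 8) == (gm.dosage == dm.MISSING)).all()


class TestMsa:
    def test_fully_conserved_columns_have_unit_pai(self):
        aln = simulate_msa(10, ["fixed"] * 50, np.random.default_rng(0),
                           "M" * 50, gap_rate=0.0)
        assert all(pai_column(aln.column(i + 1)) == 1.0 for i in range(50))

    def test_free_columns_match_uniform_identity(self):
        # 20-state uniform draws: expected pairwise identity is 1/20
        aln = simulate_msa(17, ["free"] * 3000, np.random.default_rng(1),
                           "A" * 3000, gap_rate=0.0)
        mean_pai = np.mean([pai_column(aln.column(i + 1)) for i in range(3000)])
        assert abs(mean_pai - 0.05) < 0.005

    def test_species_count(self):
        aln = simulate_msa(17, ["conserved"] * 10, np.random.default_rng(0), "M" * 10)
        assert aln.n_sequences == 17


class TestBundle:
    def test_full_determinism(self):
        cfg = SimConfig(seed=9, n_genes=12, n_sites_per_gene=20,
                        generate_msas=True,
                        sweep_plan=[SweepPlan("gene_000", "de_novo", 3, 0.9)],
                        mnm_plan=[])
        b1, b2 = generate_bundle(cfg), generate_bundle(cfg)
        np.testing.assert_array_equal(b1.genotypes.dosage, b2.genotypes.dosage)
        np.testing.assert_array_equal(b1.genotypes.depth, b2.genotypes.depth)
        assert b1.msas["gene_003"].sequences == b2.msas["gene_003"].sequences
        assert [s.pos for g in b1.truth.genes.values() for s in g.sites] == \
            [s.pos for g in b2.truth.genes.values() for s in g.sites]

    def test_de_novo_absence_guaranteed(self, default_bundle_dir, default_truth):
        """Planted de novo alleles never appear in any diploid genotype."""
        from ploidyscan.simulate import load_bundle
        bundle = load_bundle(default_bundle_dir)
        gm = bundle.genotypes
        index = gm.variant_index()
        dip = np.array([ind.ploidy == 2 for ind in gm.individuals])
        for gene in default_truth.genes.values():
            if gene.mode != "de_novo":
                continue
            for site in gene.sites:
                row = gm.dosage[index[(site.chrom, site.pos)], dip]
                assert set(np.unique(row)) <= {0, dm.MISSING}

    def test_truth_json_roundtrip(self, tmp_path):
        cfg = SimConfig(seed=4, n_genes=8, n_sites_per_gene=20,
                        sweep_plan=[SweepPlan("gene_001", "standing", 3, 0.8,
                                              source_lineage="Dinaric")],
                        mnm_plan=[MnmPlan("gene_002", 4)], generate_msas=False)
        truth = generate_bundle(cfg).truth
        truth.to_json(tmp_path / "t.json")
        back = TruthRecord.from_json(tmp_path / "t.json")
        assert back.genes.keys() == truth.genes.keys()
        assert back.genes["gene_001"].sites[0] == truth.genes["gene_001"].sites[0]
        assert back.genes["gene_002"].mnm_cluster

    def test_mnm_truth_spacings_under_limit(self, default_truth):
        for gene in default_truth.genes.values():
            if gene.mnm_cluster:
                pos = sorted(s.pos for s in gene.sites)
                assert max(np.diff(pos)) <= 19

    def test_plan_site_counts_match_truth(self, default_truth):
        cfg = SimConfig(seed=7)
        planned = {p.gene_id: p.n_candidate_aas for p in cfg.sweep_plan}
        planned.update({p.gene_id: p.cluster_size for p in cfg.mnm_plan})
        for gid, n in planned.items():
            assert len(default_truth.genes[gid].sites) == n

    def test_neutral_fst_quantile_stable_across_seeds(self):
        """99th percentile of neutral-gene per-SNP F_ST varies < 0.05."""
        from ploidyscan import pipeline as pl
        qs = []
        for seed in (21, 22, 23):
            b = generate_bundle(SimConfig(seed=seed, sweep_plan=[], mnm_plan=[],
                                          generate_msas=False))
            cfg = pl.PipelineConfig(bundle_dir=".", output_dir="unused", seed=seed)
            state = pl.prepare_from_bundle(cfg, b)
            scan = pl.stage_scan(state)
            thr = scan.thresholds
            qs.append(float(thr.loc[thr["kind"] == "ploidy", "fst_threshold"].iloc[0]))
        assert max(qs) - min(qs) < 0.05
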