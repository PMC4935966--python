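"""Generators: determinism, distributional expectations and round-trips."""
import numpy as np
import pytest

from syclone import clonality as cl
from syclone import io as sio
from syclone import simulate as sim
from syclone.model import GeneSet, ValidationError


class TestSimulateTumour:
    def test_same_seed_same_sample(self):
        clones = (sim.CloneSpec(1.0, 20), sim.CloneSpec(0.4, 30))
        s1, t1 = sim.simulate_tumour(clones, tc=0.7, depth=100, seed=3)
        s2, t2 = sim.simulate_tumour(clones, tc=0.7, depth=100, seed=3)
        assert s1.variants == s2.variants
        assert t1 == t2

    def test_different_seed_differs(self):
        clones = (sim.CloneSpec(1.0, 20),)
        s1, _ = sim.simulate_tumour(clones, tc=0.7, depth=100, seed=3)
        s2, _ = sim.simulate_tumour(clones, tc=0.7, depth=100, seed=4)
        assert s1.variants != s2.variants

    def test_mean_vaf_matches_half_c_times_tc(self):
        c, tc = 0.6, 0.8
        sample, _ = sim.simulate_tumour(
            (sim.CloneSpec(c, 2000),), tc=tc, depth=200, seed=5
        )
        vafs = [v.allele_frequency for v in sample.variants]
        assert np.mean(vafs) == pytest.approx(c * tc / 2, abs=0.01)

    def test_zero_prevalence_clone_has_no_alt_reads(self):
        sample, _ = sim.simulate_tumour(
            (sim.CloneSpec(0.0, 50),), tc=0.9, depth=100, seed=6
        )
        assert all(v.alt_reads == 0 for v in sample.variants)

    def test_truth_record_aligns_with_variants(self):
        clones = (sim.CloneSpec(1.0, 10), sim.CloneSpec(0.3, 15))
        sample, truth = sim.simulate_tumour(clones, tc=0.7, depth=100, seed=7)
        assert len(truth["variant_prevalence"]) == len(sample.variants) == 25
        assert set(truth["variant_prevalence"]) == {1.0, 0.3}

    def test_invalid_purity_rejected(self):
        with pytest.raises(ValidationError):
            sim.simulate_tumour((sim.CloneSpec(1.0, 5),), tc=0.0, depth=100, seed=0)


class TestSimulateCNV:
    def test_zero_clonality_centres_at_half(self):
        seg, _ = sim.simulate_cnv_segment(
            copy_number=1, clonality=0.0, tc=0.8, n_snps=500, depth=300, seed=8
        )
        assert np.mean(seg.het_snp_afs) == pytest.approx(0.5, abs=0.01)
        assert cl.cnv_clonality(cl.region_median_het_af(seg), 0.8) < 0.1

    def test_diploid_with_positive_clonality_rejected(self):
        with pytest.raises(ValidationError):
            sim.simulate_cnv_segment(
                copy_number=2, clonality=0.5, tc=0.8, n_snps=10, depth=100, seed=0
            )

    def test_pure_clonal_single_copy_loss_recovered(self):
        # CN=1 at tc=1, c=1: folded AF sits at 1 exactly, the one regime
        # where the estimator is unbiased end to end
        seg, _ = sim.simulate_cnv_segment(
            copy_number=1, clonality=1.0, tc=1.0, n_snps=200, depth=500, seed=9
        )
        c_hat = cl.cnv_clonality(cl.region_median_het_af(seg), 1.0)
        assert c_hat == pytest.approx(1.0, abs=0.05)

    def test_amplification_afs_are_bimodal_about_half(self):
        seg, _ = sim.simulate_cnv_segment(
            copy_number=3, clonality=1.0, tc=1.0, n_snps=400, depth=500, seed=10
        )
        afs = np.asarray(seg.het_snp_afs)
        # CN=3, pure and clonal: B-allele frequency is 1/3 or 2/3 per SNP
        assert np.all((np.abs(afs - 1 / 3) < 0.1) | (np.abs(afs - 2 / 3) < 0.1))
        low, high = (afs < 0.5).sum(), (afs > 0.5).sum()
        assert 0.3 < low / (low + high) < 0.7

    def test_determinism(self):
        a = sim.simulate_cnv_segment(3, 0.5, 0.7, 50, 100, seed=11)[0]
        b = sim.simulate_cnv_segment(3, 0.5, 0.7, 50, 100, seed=11)[0]
        assert a == b


class TestSimulateMegaCohorts:
    def _cfg(self, seed=12):
        sets, _ = sim.make_disjoint_gene_sets(3, 20, 1000)
        return sim.CohortSimConfig(
            n_a=40,
            n_b=60,
            n_genes=1000,
            gene_sets=tuple(sets),
            enriched_sets=(sets[0].name,),
            seed=seed,
        )

    def test_mean_burdens_match_study_regime(self):
        sets, _ = sim.make_disjoint_gene_sets(1, 20, 1000)
        cfg = sim.CohortSimConfig(
            n_a=300,
            n_b=300,
            n_genes=1000,
            gene_sets=tuple(sets),
            enriched_sets=(sets[0].name,),
            seed=13,
        )
        a, b, _ = sim.simulate_mega_cohorts(cfg)
        from syclone.mega import geneset_burden

        burden_a = np.mean([geneset_burden(sets[0], p) for p in a])
        burden_b = np.mean([geneset_burden(sets[0], p) for p in b])
        assert burden_a == pytest.approx(sim.MEGA_MEAN_BURDEN_A, abs=0.15)
        assert burden_b == pytest.approx(sim.MEGA_MEAN_BURDEN_B, abs=0.10)

    def test_non_enriched_sets_match_between_cohorts(self):
        cfg = self._cfg()
        a, b, _ = sim.simulate_mega_cohorts(cfg)
        from syclone.mega import geneset_burden

        other = cfg.gene_sets[1]
        ma = np.mean([geneset_burden(other, p) for p in a])
        mb = np.mean([geneset_burden(other, p) for p in b])
        assert ma == pytest.approx(mb, abs=0.25)

    def test_sizes_and_determinism(self):
        cfg = self._cfg()
        a1, b1, t1 = sim.simulate_mega_cohorts(cfg)
        a2, b2, t2 = sim.simulate_mega_cohorts(cfg)
        assert len(a1) == 40 and len(b1) == 60
        assert a1 == a2 and b1 == b2 and t1 == t2

    def test_unknown_enriched_set_rejected(self):
        with pytest.raises(ValidationError):
            sim.CohortSimConfig(enriched_sets=("NOPE",))

    def test_gene_universe_too_small_rejected(self):
        with pytest.raises(ValidationError):
            sim.make_disjoint_gene_sets(10, 20, 100)


class TestSimulateExpression:
    def test_suppressed_genes_below_cutoff_in_cohort_a_only(self):
        sets, genes = sim.make_disjoint_gene_sets(1, 50, 500)
        ma, mb, truth = sim.simulate_expression_cohorts(
            n_a=5, n_b=8, n_genes=500, suppressed_sets=sets, seed=14
        )
        chosen = truth["suppressed_genes"][sets[0].name]
        assert len(chosen) == 5  # 10% of 50
        assert (ma.values.loc[chosen] < 0.1).all().all()
        # cohort B keeps its baseline: suppressed rows are not uniformly low
        assert (mb.values.loc[chosen] >= 0.1).any().any()

    def test_baseline_not_expressed_fraction_near_three_percent(self):
        ma, _, _ = sim.simulate_expression_cohorts(
            n_a=10, n_b=11, n_genes=5000, seed=15
        )
        frac = (ma.values < 0.1).to_numpy().mean()
        assert frac == pytest.approx(0.03, abs=0.015)

    def test_shapes_and_determinism(self):
        m1 = sim.simulate_expression_cohorts(n_a=4, n_b=6, n_genes=100, seed=16)
        m2 = sim.simulate_expression_cohorts(n_a=4, n_b=6, n_genes=100, seed=16)
        assert m1[0].values.shape == (100, 4)
        assert m1[1].values.shape == (100, 6)
        assert m1[0].values.equals(m2[0].values)


class TestGeneratorIORoundTrip:
    def test_simulated_sample_survives_table_round_trip(self, tmp_path):
        sample, _ = sim.simulate_tumour(
            (sim.CloneSpec(0.8, 25),), tc=0.7, depth=150, seed=17
        )
        path = tmp_path / "variants.tsv"
        sio.write_variant_table(sample.variants, path)
        assert sio.read_variant_table(path) == sample.variants

    def test_simulated_segment_survives_round_trip(self, tmp_path):
        seg, _ = sim.simulate_cnv_segment(3, 0.6, 0.8, 30, 120, seed=18)
        path = tmp_path / "segments.tsv"
        sio.write_segments([seg], path)
        assert sio.read_segments(path) == [seg]
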