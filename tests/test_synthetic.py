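import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from enhancerlink.counts import tmm_factors
from enhancerlink.differential import nb_differential
from enhancerlink.synthetic import (
    gen_annotation,
    gen_cohort,
    gen_genotypes,
    gen_interactions,
    gen_peaks_counts,
    gen_phenotypes,
    simulate_study,
)
from enhancerlink.variants import dosage_r2


class TestGenAnnotation:
    def test_counts_positions_and_reproducibility(self):
        tss, sizes = gen_annotation(100, 2, 1_000_000, seed=3)
        assert len(tss) == 100
        assert all(0 <= t.tss < sizes[t.chrom] for t in tss)
        tss2, _ = gen_annotation(100, 2, 1_000_000, seed=3)
        assert tss == tss2

    def test_positions_unique_per_chromosome(self):
        tss, _ = gen_annotation(500, 2, 10_000_000, seed=1)
        seen = {(t.chrom, t.tss) for t in tss}
        assert len(seen) == len(tss)

    def test_overcrowded_chromosome_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            gen_annotation(10_000, 1, 1_000_000, seed=0)

    def test_nonpositive_sizes_rejected(self):
        with pytest.raises(ValueError):
            gen_annotation(0, 1, 1000, seed=0)


class TestGenPeaksCounts:
    def test_planted_enhancers_satisfy_classification_rules(self, study):
        # every planted enhancer id appears in the rule-derived annotation
        ann = study.peaks.annotation
        enh_ids = {eid for eid, _ in ann.enhancers}
        assert set(study.truth.enhancer_truth["enhancer_id"]) <= enh_ids

    def test_null_features_have_uniform_pvalues(self):
        tss, sizes = gen_annotation(2000, 2, 10_000_000, seed=21)
        pk = gen_peaks_counts(tss, sizes, n_enhancers=400, frac_diff_genes=0.0, seed=21)
        res = nb_differential(pk.gene_counts, pk.design, tmm_factors(pk.gene_counts))
        p = res.table.loc[res.table["tested"], "p_value"]
        assert kstest(p, "uniform").pvalue > 0.01

    def test_planted_log2fc_recovered_in_median(self):
        tss, sizes = gen_annotation(1500, 2, 10_000_000, seed=5)
        pk = gen_peaks_counts(tss, sizes, n_enhancers=300, effect_log2fc=1.0,
                              frac_diff_genes=0.3, seed=5)
        res = nb_differential(pk.gene_counts, pk.design, tmm_factors(pk.gene_counts))
        merged = res.table.merge(
            pk.gene_truth.rename(columns={"gene_id": "feature_id"}), on="feature_id"
        )
        planted = merged[merged["true_log2fc"] != 0]
        aligned = planted["logFC"] * np.sign(planted["true_log2fc"])
        assert np.median(aligned) == pytest.approx(1.0, abs=0.15)

    def test_invalid_parameters_rejected(self):
        tss, sizes = gen_annotation(100, 1, 10_000_000, seed=0)
        with pytest.raises(ValueError):
            gen_peaks_counts(tss, sizes, dispersion=0.0, seed=0)
        with pytest.raises(ValueError):
            gen_peaks_counts(tss, sizes, effect_log2fc=np.inf, seed=0)


class TestGenInteractions:
    def test_seed_reproducibility_and_loop_validity(self, study):
        from enhancerlink.synthetic import gen_annotation, gen_peaks_counts

        tss, sizes = gen_annotation(300, 1, 10_000_000, seed=2)
        pk = gen_peaks_counts(tss, sizes, n_enhancers=80, seed=2)
        a, la = gen_interactions(pk.annotation, tss, n_loops=10, seed=9)
        b, lb = gen_interactions(pk.annotation, tss, n_loops=10, seed=9)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(la, lb)
        enh_ids = {eid for eid, _ in pk.annotation.enhancers}
        assert set(la["enhancer_id"]) <= enh_ids
        assert set(la["gene_id"]) <= set(pk.annotation.active_promoters)

    def test_nonnegative_decay_rejected(self, study):
        with pytest.raises(ValueError, match="negative"):
            gen_interactions(study.peaks.annotation, study.tss, decay_exponent=0.5)


class TestGenGenotypes:
    def test_dosages_are_hard_calls_with_target_maf(self):
        gm, panel = gen_genotypes(n_individuals=500, n_blocks=20,
                                  maf_range=(0.3, 0.3001), seed=13)
        assert set(np.unique(gm.dosages)) <= {0.0, 1.0, 2.0}
        maf = gm.dosages.mean(axis=1) / 2
        assert np.all(np.abs(maf - 0.3) < 0.05)

    def test_within_block_ld_exceeds_between_block(self):
        gm, _ = gen_genotypes(n_individuals=400, n_blocks=10, snps_per_block=4,
                              seed=17)
        within, between = [], []
        for i in range(len(gm.snp_ids)):
            for j in range(i + 1, len(gm.snp_ids)):
                r2 = dosage_r2(gm.dosages[i], gm.dosages[j])
                (within if i // 4 == j // 4 else between).append(r2)
        assert np.mean(within) > 0.7 > np.mean(between)
        assert np.mean(within) > np.mean(between) + 0.5

    def test_seed_reproducibility(self):
        a, _ = gen_genotypes(n_individuals=50, n_blocks=3, seed=5)
        b, _ = gen_genotypes(n_individuals=50, n_blocks=3, seed=5)
        assert np.array_equal(a.dosages, b.dosages)


class TestGenCohort:
    def test_seed_reproducibility_and_shapes(self):
        gm, panel = gen_genotypes(n_individuals=200, n_blocks=5, seed=3)
        eqtls = pd.DataFrame({"snp": ["rs000_2"], "gene": ["gA"], "beta": [1.0]})
        e1, c1, _ = gen_cohort(["gA", "gB"], gm, eqtls, n_individuals=140, seed=3)
        e2, c2, _ = gen_cohort(["gA", "gB"], gm, eqtls, n_individuals=140, seed=3)
        pd.testing.assert_frame_equal(e1, e2)
        pd.testing.assert_frame_equal(c1, c2)
        assert e1.shape == (2, 140)

    def test_unknown_planted_snp_rejected(self):
        gm, _ = gen_genotypes(n_individuals=50, n_blocks=2, seed=1)
        with pytest.raises(ValueError, match="absent"):
            gen_cohort(["g"], gm, pd.DataFrame(
                {"snp": ["rs_nope"], "gene": ["g"], "beta": [1.0]}), seed=1)


class TestGenPhenotypes:
    def test_realized_rho_near_target(self):
        rhos = []
        for s in range(30):
            planted = pd.DataFrame({"gene": ["g"], "phenotype": ["pheno_01"],
                                    "rho": [0.6]})
            expr, ph, _ = gen_phenotypes(["g"], n_strains=40, planted=planted,
                                         missing_frac=0.0, seed=s)
            from enhancerlink.phenotypes import spearman

            rhos.append(spearman(expr.loc["g"].to_numpy(),
                                 ph["pheno_01"].to_numpy())["rho"])
        assert np.mean(rhos) == pytest.approx(0.6, abs=0.15)

    def test_panel_shape_and_reproducibility(self):
        e1, p1, _ = gen_phenotypes(["g"], n_strains=25, n_phenotypes=48, seed=8)
        e2, p2, _ = gen_phenotypes(["g"], n_strains=25, n_phenotypes=48, seed=8)
        assert p1.shape == (25, 48)
        pd.testing.assert_frame_equal(p1, p2)

    def test_rho_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gen_phenotypes(["g"], planted=pd.DataFrame(
                {"gene": ["g"], "phenotype": ["pheno_01"], "rho": [1.0]}), seed=0)


class TestRoundTrips:
    def test_generated_files_round_trip_bit_exactly(self, small_study, tmp_path):
        from enhancerlink import io
        from enhancerlink.pipeline import write_study

        write_study(small_study, tmp_path)
        tss = io.read_tss(tmp_path / "tss.bed")
        assert tss == small_study.tss
        k27 = io.read_peaks(tmp_path / "k27ac_peaks.bed", "H3K27ac")
        assert k27.peaks == small_study.peaks.k27ac.peaks
        cm = io.read_counts(tmp_path / "gene_counts.tsv")
        assert np.array_equal(cm.counts, small_study.peaks.gene_counts.counts)
        assert cm.feature_ids == small_study.peaks.gene_counts.feature_ids
        inter = io.read_interactions(tmp_path / "interactions.tsv")
        pd.testing.assert_frame_equal(inter, small_study.interactions)
        gm, panel = io.read_dosage_tsv(tmp_path / "genotypes.tsv")
        assert np.allclose(gm.dosages, small_study.panel_genotypes.dosages)
        pd.testing.assert_frame_equal(panel, small_study.panel)
        truth = io.read_truth(tmp_path / "truth.json")
        pd.testing.assert_frame_equal(
            truth.cascades, small_study.truth.cascades, check_dtype=False
        )

    def test_vcf_round_trip(self, tmp_path):
        from enhancerlink import io

        gm, panel = gen_genotypes(n_individuals=25, n_blocks=4, seed=19)
        gm.dosages[2, 5] = np.nan
        io.write_vcf(gm, panel, tmp_path / "p.vcf")
        gm2, panel2 = io.read_vcf(tmp_path / "p.vcf")
        order = [gm2.snp_ids.index(r) for r in gm.snp_ids]
        assert np.allclose(gm.dosages, gm2.dosages[order], equal_nan=True, atol=1e-3)
        assert np.allclose(gm.imputation_r2, gm2.imputation_r2[order], atol=1e-4)


class TestSimulateStudy:
    def test_same_seed_identical_truth_and_counts(self):
        a = simulate_study(seed=29, n_genes=300, n_enhancers=80, n_cascades=8,
                           n_panel=100, n_cohort=80, n_strains=20)
        b = simulate_study(seed=29, n_genes=300, n_enhancers=80, n_cascades=8,
                           n_panel=100, n_cohort=80, n_strains=20)
        assert np.array_equal(a.peaks.gene_counts.counts, b.peaks.gene_counts.counts)
        pd.testing.assert_frame_equal(a.truth.cascades, b.truth.cascades)
        pd.testing.assert_frame_equal(a.interactions, b.interactions)

    def test_cascade_snps_inside_their_enhancers(self, study):
        enh = dict(study.peaks.annotation.enhancers)
        pos = study.panel.set_index("rsid")["pos"]
        for row in study.truth.cascades.itertuples(index=False):
            iv = enh[row.enhancer_id]
            assert iv.start <= pos[row.rsid] < iv.end

    def test_every_planted_entity_references_generated_records(self, study):
        gene_ids = {t.gene_id for t in study.tss}
        enh_ids = {eid for eid, _ in study.peaks.annotation.enhancers}
        snp_ids = set(study.panel_genotypes.snp_ids)
        t = study.truth
        assert set(t.loops["gene_id"]) <= gene_ids
        assert set(t.loops["enhancer_id"]) <= enh_ids
        assert set(t.cascades["rsid"]) <= snp_ids
        assert set(t.eqtls["gene"]) <= set(study.cohort_expression.index)
        assert set(t.phenotype_truth["gene"]) <= set(study.phenotype_expression.index)
        assert t.seed == 7
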