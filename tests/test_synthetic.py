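"""Generator contracts: annotation geometry, LD structure, planted truth."""
import numpy as np
import pandas as pd
import pytest

from mirnet_gsa.synthetic import (
    SimulationConfig, GenerationError, simulate_annotation, simulate_genotypes,
    simulate_phenotype, simulate_target_networks, simulate_expression_contrasts,
    MIRNA_LENGTH_RANGE,
)


class TestConfig:
    @pytest.mark.parametrize("bad", [
        {"h2": 1.2}, {"h2": -0.1}, {"enrichment_fold": 0.5},
        {"maf_min": 0.0}, {"maf_min": 0.5}, {"target_size_range": (0, 5)},
        {"enrichment_mode": "both"}, {"n_ancestral_haplotypes": 1},
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            SimulationConfig(**bad)

    def test_roundtrip_dict(self):
        cfg = SimulationConfig(seed=3, target_size_range=(4, 9))
        assert SimulationConfig.from_dict(cfg.to_dict()) == cfg


class TestAnnotation:
    def test_no_mirnas_gives_empty_table(self):
        cfg = SimulationConfig(seed=1, n_mirnas=0, n_genes=10,
                               markers_per_chrom=100)
        _, mirnas = simulate_annotation(cfg)
        assert len(mirnas) == 0

    def test_precursor_lengths_within_observed_range(self, small_config):
        _, mirnas = simulate_annotation(small_config)
        lengths = mirnas["end"] - mirnas["start"] + 1
        lo, hi = MIRNA_LENGTH_RANGE
        assert lengths.between(lo, hi).all()

    def test_intervals_inside_chromosomes_and_nonoverlapping(self, small_config):
        genes, _ = simulate_annotation(small_config)
        assert (genes["start"] >= 1).all()
        assert (genes["end"] <= small_config.chrom_length_bp).all()
        for _, grp in genes.groupby("chrom"):
            g = grp.sort_values("start")
            assert (g["start"].to_numpy()[1:] > g["end"].to_numpy()[:-1]).all()

    def test_deterministic_under_seed(self, small_config):
        a = simulate_annotation(small_config)
        b = simulate_annotation(small_config)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_unplaceable_annotation_raises(self):
        cfg = SimulationConfig(seed=1, n_genes=500, markers_per_chrom=50,
                               n_chromosomes=1)
        with pytest.raises(GenerationError):
            simulate_annotation(cfg)


class TestTargetNetworks:
    def test_fixed_size_range_forces_size(self, small_config):
        cfg = SimulationConfig(**{**small_config.to_dict(),
                                  "target_size_range": [5, 5],
                                  "mean_targets_per_mirna": 5.0})
        nets = simulate_target_networks([f"m{i}" for i in range(10)],
                                        [f"g{i}" for i in range(30)], cfg)
        assert all(len(v) == 5 for v in nets.values())

    def test_no_duplicate_targets(self, small_cohort):
        for genes in small_cohort["networks"].values():
            assert len(set(genes)) == len(genes)

    def test_mean_size_matches_config_within_10pct(self):
        cfg = SimulationConfig(seed=11, mean_targets_per_mirna=20.0,
                               target_size_range=(5, 60))
        universe = [f"g{i}" for i in range(100)]
        nets = simulate_target_networks([f"m{i}" for i in range(1000)],
                                        universe, cfg)
        mean = np.mean([len(v) for v in nets.values()])
        assert abs(mean - 20.0) / 20.0 < 0.10

    def test_oversized_range_rejected(self):
        cfg = SimulationConfig(seed=1, target_size_range=(5, 50))
        with pytest.raises(GenerationError):
            simulate_target_networks(["m1"], [f"g{i}" for i in range(20)], cfg)


class TestGenotypes:
    def test_dosages_are_diploid_counts(self, small_cohort):
        d = small_cohort["genotypes"].dosages
        assert set(np.unique(d)) <= {0.0, 1.0, 2.0}

    def test_maf_respects_rejection_bound(self, small_cohort):
        freq = small_cohort["genotypes"].allele_freq()
        maf_min = small_cohort["config"].maf_min
        assert (freq >= maf_min).all() and (freq <= 1 - maf_min).all()

    def test_two_founder_haplotypes_give_complete_ld_within_block(self):
        cfg = SimulationConfig(seed=5, n_individuals=300, n_chromosomes=1,
                               markers_per_chrom=20, ld_block_length=5,
                               n_ancestral_haplotypes=2)
        geno = simulate_genotypes(cfg)
        block = geno.dosages[:, :5]
        r = np.corrcoef(block.T)
        assert np.allclose(np.abs(r), 1.0, atol=1e-12)

    def test_within_block_ld_exceeds_between_block_ld(self):
        cfg = SimulationConfig(seed=9, n_individuals=300, n_chromosomes=1,
                               markers_per_chrom=500, ld_block_length=5)
        geno = simulate_genotypes(cfg)
        X = geno.dosages
        within, between = [], []
        for b in range(99):
            blk = X[:, b * 5:(b + 1) * 5]
            r = np.corrcoef(blk.T)
            within.extend((r[np.triu_indices(5, 1)] ** 2).tolist())
            # adjacent-block pair: last marker of b vs first of b+1
            rb = np.corrcoef(X[:, b * 5 + 4], X[:, (b + 1) * 5])[0, 1]
            between.append(rb ** 2)
        assert np.mean(within) > np.mean(between)

    def test_deterministic_under_seed(self, small_config):
        a = simulate_genotypes(small_config)
        b = simulate_genotypes(small_config)
        assert np.array_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.markers, b.markers)


class TestPhenotype:
    def test_null_heritability_gives_pure_noise(self, small_cohort):
        cfg = SimulationConfig(**{**small_cohort["config"].to_dict(), "h2": 0.0})
        y, truth = simulate_phenotype(small_cohort["genotypes"], {}, cfg)
        assert truth.causal_marker_ids == []
        assert np.isfinite(y).all()

    def test_causal_count_conservation(self, small_cohort):
        cfg = small_cohort["config"]
        y, truth = simulate_phenotype(small_cohort["genotypes"], {}, cfg)
        assert len(truth.causal_marker_ids) == round(
            cfg.prop_causal * small_cohort["genotypes"].n_markers)

    def test_realized_h2_is_exact(self, small_cohort):
        geno = small_cohort["genotypes"]
        cfg = small_cohort["config"]
        y, truth = simulate_phenotype(geno, {}, cfg)
        cols = {m: j for j, m in enumerate(geno.markers["marker_id"])}
        idx = [cols[m] for m in truth.causal_marker_ids]
        beta = np.array([truth.true_effects[m] for m in truth.causal_marker_ids])
        g = geno.dosages[:, idx] @ beta
        realized = g.var() / y.var()
        assert abs(realized - cfg.h2) < 0.01

    def test_stratified_placement_fixes_in_feature_count(self, small_cohort):
        geno = small_cohort["genotypes"]
        feature = {"f": np.arange(0, 200)}
        counts = set()
        for s in range(5):
            cfg = SimulationConfig(**{**small_cohort["config"].to_dict(),
                                      "seed": 100 + s})
            _, truth = simulate_phenotype(geno, feature, cfg)
            cols = {m: j for j, m in enumerate(geno.markers["marker_id"])}
            in_f = sum(cols[m] < 200 for m in truth.causal_marker_ids)
            counts.add(in_f)
        assert len(counts) == 1  # expectation-fixed, not binomial

    def test_shared_truth_reuses_effects_across_cohorts(self, small_cohort):
        cfg = small_cohort["config"]
        geno = small_cohort["genotypes"]
        y1, truth = simulate_phenotype(geno, {}, cfg)
        cfg2 = SimulationConfig(**{**cfg.to_dict(), "seed": cfg.seed + 1})
        geno2 = simulate_genotypes(cfg2)
        y2, truth2 = simulate_phenotype(geno2, {}, cfg2, truth=truth)
        assert truth2.causal_marker_ids == truth.causal_marker_ids
        assert truth2.true_effects == truth.true_effects
        assert not np.allclose(y1, y2)

    def test_h2_without_causal_markers_rejected(self, small_cohort):
        cfg = SimulationConfig(**{**small_cohort["config"].to_dict(),
                                  "prop_causal": 0.0})
        with pytest.raises(ValueError):
            simulate_phenotype(small_cohort["genotypes"], {}, cfg)


class TestExpressionContrasts:
    def _toy_networks(self):
        genes = [f"g{i}" for i in range(200)]
        networks = {"mirA": genes[:20], "mirB": genes[20:40],
                    "mirC": genes[40:60]}
        return genes, networks

    def test_global_null_has_no_excess_discoveries(self, rng):
        genes, networks = self._toy_networks()
        contrasts, _ = simulate_expression_contrasts(genes, networks, 4, [],
                                                     rng=rng)
        assert (contrasts["fdr"] < 0.05).mean() < 0.02

    def test_planted_sign_is_consistent_where_de(self, rng):
        genes, networks = self._toy_networks()
        contrasts, truth = simulate_expression_contrasts(
            genes, networks, 8, ["mirA"], rng=rng)
        for cond, de_genes in truth.de_gene_ids.items():
            sub = contrasts[contrasts["condition"] == cond]
            for g in de_genes:
                lfc = sub.loc[sub["gene_id"] == g, "log2_fc"]
                all_conds = [c for c, gl in truth.de_gene_ids.items() if g in gl]
                signs = [np.sign(contrasts[(contrasts.condition == c)
                                           & (contrasts.gene_id == g)]
                                 ["log2_fc"].iloc[0]) for c in all_conds]
                assert len(set(signs)) == 1

    def test_planted_genes_recovered_at_fdr_in_two_conditions(self, rng):
        genes, networks = self._toy_networks()
        contrasts, truth = simulate_expression_contrasts(
            genes, networks, 8, ["mirA", "mirB"], rng=rng, planted_lfc=2.0)
        planted = {g for gl in truth.de_gene_ids.values() for g in gl}
        de = contrasts[contrasts["fdr"] < 0.05]
        n_cond = de.groupby("gene_id")["condition"].nunique()
        recovered = {g for g in planted if n_cond.get(g, 0) >= 2}
        assert len(recovered) / len(planted) >= 0.8

    def test_single_condition_rejected(self, rng):
        genes, networks = self._toy_networks()
        with pytest.raises(ValueError):
            simulate_expression_contrasts(genes, networks, 1, [], rng=rng)

    def test_unknown_de_network_rejected(self, rng):
        genes, networks = self._toy_networks()
        with pytest.raises(ValueError):
            simulate_expression_contrasts(genes, networks, 4, ["nope"], rng=rng)
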