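"""Canned validation studies for the analysis pipeline.

Each function runs a self-contained simulation study — null calibration
of the marker-set test, power against a planted enriched network, REML
heritability recovery, and end-to-end recovery of infection-responsive
networks across three breeds — at a fixed, documented reduced scale, and
returns summary numbers. They are used by the test suite and by
``scripts/acceptance.py``; every study takes a single integer seed that
controls all of its randomness.

Scale choices (documented in the methods note): studies that only need
null behaviour run on the default 10,000-marker genome; the power and
end-to-end studies run on smaller genomes (1,250 and 2,500 markers),
where a planted network's share of the genetic variance is large enough
for a cohort of a few hundred to one thousand animals to detect — the
same signal-to-marker-count ratio reasoning that applies at full scale.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import (SimulationConfig, simulate_annotation, simulate_genotypes,
                        simulate_phenotype, simulate_target_networks,
                        simulate_expression_contrasts)
from .features import assign_snps_to_genes, build_network_marker_set, TargetNetwork
from .gwas import (compute_grm, reml_variance_components, run_gwas,
                   gls_single_marker, GRM)
from .settest import test_feature_sets, permutation_null, compute_tsum, \
    empirical_pvalue, genome_ordered_t_squared
from .integration import call_significant_networks, compare_partition_enrichment
from .correlation import compare_enrichment_distributions

__all__ = [
    "null_calibration_study",
    "power_study",
    "reml_recovery_study",
    "gls_ols_agreement",
    "rotation_oracle_study",
    "integration_recovery_study",
]


def null_calibration_study(seed: int = 0, n_features: int = 500,
                           feature_size_range: tuple[int, int] = (50, 500),
                           n_perm: int = 1000) -> dict:
    """Type-I error and uniformity of the marker-set test under the null.

    Simulates the default cohort (500 individuals, 10,000 markers in LD
    blocks) with a pure-noise trait (h2 = 0), runs the mixed-model scan,
    and tests ``n_features`` random marker sets of 50-500 markers with
    independent rotation streams. Returns the empirical type-I error at
    nominal 0.05 and the Kolmogorov-Smirnov uniformity p-value.
    """
    cfg = SimulationConfig(seed=seed, h2=0.0)
    geno = simulate_genotypes(cfg)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(101,)))
    y = rng.standard_normal(cfg.n_individuals)
    scan = run_gwas(geno, y)
    m = len(scan)
    lo, hi = feature_size_range
    features = {
        f"f{i}": np.sort(rng.choice(m, size=int(rng.integers(lo, hi + 1)),
                                    replace=False))
        for i in range(n_features)
    }
    res = test_feature_sets(scan, features, n_perm=n_perm, rng=rng,
                            share_offsets=False)
    p = res["p"].to_numpy()
    return {
        "type1_error_at_0.05": float(np.mean(p < 0.05)),
        "ks_uniformity_p": float(stats.kstest(p, "uniform").pvalue),
        "n_features": n_features,
        "p_values": p,
    }


def power_study(seed: int = 0, n_replicates: int = 100, enrichment_fold: float = 5.0,
                h2: float = 0.5, n_individuals: int = 500, alpha: float = 0.05,
                n_perm: int = 1000) -> dict:
    """Detection power for a planted enriched miRNA-target network.

    Study design (frozen): a 1,250-marker genome (5 chromosomes, 2 kb
    marker spacing, 5-marker LD blocks), 60 genes, one planted network of
    45 target genes whose ORF markers cover about a fifth of the genome;
    a highly polygenic trait (12% of markers causal) whose causal effects
    inside the network's ORF markers carry ``enrichment_fold`` times the
    baseline effect variance. Each replicate draws a fresh cohort, runs
    the LOCO mixed-model scan and the marker-set test (1,000 rotations),
    and scores p < alpha.
    """
    hits = 0
    for r in range(n_replicates):
        cfg = SimulationConfig(
            seed=seed * 100_003 + r, n_individuals=n_individuals,
            markers_per_chrom=250, n_genes=60, n_mirnas=1,
            mean_targets_per_mirna=45, target_size_range=(45, 45),
            h2=h2, enrichment_fold=enrichment_fold,
            enrichment_mode="variance", prop_causal=0.12,
        )
        geno = simulate_genotypes(cfg)
        genes, _ = simulate_annotation(cfg)
        g2m = assign_snps_to_genes(geno.markers, genes)
        nets = simulate_target_networks(["planted"], genes["gene_id"], cfg)
        ms = build_network_marker_set(
            TargetNetwork("planted", nets["planted"]), g2m)
        y, _ = simulate_phenotype(geno, {"planted": ms.marker_indices}, cfg)
        scan = run_gwas(geno, y)
        res = test_feature_sets(scan, {"planted": ms}, n_perm=n_perm,
                                rng=np.random.default_rng(seed * 100_003 + r))
        hits += bool(res["p"].iloc[0] < alpha)
    return {"power": hits / n_replicates, "n_replicates": n_replicates}


def reml_recovery_study(seed: int = 0, n_replicates: int = 100,
                        true_h2: float = 0.5, n_individuals: int = 500) -> dict:
    """Bias of REML heritability estimates at a known simulated h2.

    Each replicate simulates genotypes (2,000 markers), a polygenic trait
    whose realized genetic variance fraction equals ``true_h2`` exactly,
    builds the VanRaden GRM, and fits the variance components by REML.
    """
    h2_hats = []
    for r in range(n_replicates):
        cfg = SimulationConfig(seed=seed * 99_991 + r, n_individuals=n_individuals,
                               markers_per_chrom=400, h2=true_h2,
                               prop_causal=0.10, enrichment_fold=1.0)
        geno = simulate_genotypes(cfg)
        y, _ = simulate_phenotype(geno, {}, cfg)
        vc = reml_variance_components(y, compute_grm(geno))
        h2_hats.append(vc.h2)
    h2_hats = np.asarray(h2_hats)
    return {
        "mean_h2_hat": float(h2_hats.mean()),
        "sd_h2_hat": float(h2_hats.std(ddof=1)),
        "n_replicates": n_replicates,
    }


def gls_ols_agreement(seed: int = 0, n_individuals: int = 200,
                      n_markers: int = 50) -> float:
    """Max |GLS - OLS| over (b, se, t) when the covariance is the identity.

    With sigma_a2 = 0 the mixed-model GLS must reproduce ordinary least
    squares exactly; returns the largest absolute discrepancy across
    markers and quantities.
    """
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 3, size=(n_individuals, n_markers)).astype(float)
    y = rng.standard_normal(n_individuals)
    grm = GRM(matrix=np.eye(n_individuals))
    from .gwas import VarianceComponents
    vc = VarianceComponents(sigma_a2=0.0, sigma_e2=1.0, loglik=0.0)
    worst = 0.0
    ones = np.ones(n_individuals)
    for j in range(n_markers):
        b, se, t, p = gls_single_marker(y, X[:, j], grm, vc)
        A = np.column_stack([ones, X[:, j]])
        coef, res_ss, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        s2 = resid @ resid / (n_individuals - 2)
        cov = s2 * np.linalg.inv(A.T @ A)
        b0, se0 = coef[1], np.sqrt(cov[1, 1])
        worst = max(worst, abs(b - b0), abs(se - se0), abs(t - b0 / se0))
    return worst


def rotation_oracle_study(seed: int = 0, m: int = 5000, feature_size: int = 200,
                          n_perm: int = 1000) -> dict:
    """Sampled vs exhaustive rotation null on one genome-scale vector.

    Builds a heavy-tailed t^2 vector of length ``m``, compares the
    sampled empirical p (``n_perm`` offsets) with the exact p over all
    m - 1 rotations, and reports the discrepancy in Monte-Carlo standard
    errors. Also checks the closed 4-marker enumeration: t^2 =
    [1, 4, 9, 16] with the feature on the first two positions gives null
    sums {13, 25, 17}.
    """
    rng = np.random.default_rng(seed)
    t2 = rng.standard_t(df=4, size=m) ** 2
    idx = np.sort(rng.choice(m, size=feature_size, replace=False))
    t_obs = compute_tsum(t2, idx)
    exhaustive = permutation_null(t2, idx, n_perm=m, rng=rng)  # enumerates all m-1
    p_exact = empirical_pvalue(t_obs, exhaustive)
    sampled = permutation_null(t2, idx, n_perm=n_perm, rng=rng)
    p_sampled = empirical_pvalue(t_obs, sampled)
    mc_se = float(np.sqrt(max(p_exact * (1 - p_exact), 1e-12) / n_perm))
    toy = permutation_null(np.array([1.0, 4.0, 9.0, 16.0]), np.array([0, 1]),
                           n_perm=10)
    return {
        "p_exact": float(p_exact),
        "p_sampled": float(p_sampled),
        "discrepancy_in_se": float(abs(p_sampled - p_exact) / mc_se),
        "toy_null_sums": sorted(toy.tolist()),
    }


def _integration_replicate(seed: int, n_individuals: int, n_breeds: int,
                           n_networks: int, n_planted: int, n_perm: int,
                           alpha: float):
    base = SimulationConfig(
        seed=seed, n_individuals=n_individuals, markers_per_chrom=500,
        n_genes=150, n_mirnas=n_networks, mean_targets_per_mirna=14.0,
        target_size_range=(12, 16), h2=0.5, prop_causal=0.12,
        enrichment_mode="density", enrichment_fold=float("inf"),
    )
    genes, mirnas = simulate_annotation(base)
    networks = simulate_target_networks(mirnas["mirna_id"], genes["gene_id"], base)
    rng = np.random.default_rng(seed)
    planted = sorted(rng.choice(sorted(networks), size=n_planted, replace=False))
    contrasts, de_truth = simulate_expression_contrasts(
        genes["gene_id"], networks, 8, planted, rng=rng)
    de_genes = sorted({g for gl in de_truth.de_gene_ids.values() for g in gl})

    pvals, scans = {}, {}
    shared_truth = None
    for b in range(n_breeds):
        bcfg = SimulationConfig(**{**base.to_dict(), "seed": seed + 7919 * (b + 1)})
        geno = simulate_genotypes(bcfg)
        g2m = assign_snps_to_genes(geno.markers, genes)
        de_ms = build_network_marker_set(TargetNetwork("de", de_genes), g2m)
        y, tr = simulate_phenotype(geno, {"de": de_ms.marker_indices}, bcfg,
                                   truth=shared_truth)
        if shared_truth is None:
            shared_truth = tr
        scan = run_gwas(geno, y)
        feats = {mid: build_network_marker_set(TargetNetwork(mid, gl), g2m)
                 for mid, gl in networks.items()}
        res = test_feature_sets(scan, feats, n_perm=n_perm,
                                rng=np.random.default_rng(seed + b))
        pvals[f"breed{b + 1}"] = res.set_index("feature_id")["p"]
        scans[b] = (scan, g2m)

    sig, joint = call_significant_networks(pd.DataFrame(pvals), alpha=alpha)
    recovery = len(set(sig) & set(planted)) / len(planted)

    det_p = None
    if len(sig) >= 2:
        det_vals, non_vals = [], []
        for b, (scan, g2m) in scans.items():
            cmp_res = compare_partition_enrichment(
                scan, {mid: networks[mid] for mid in sig}, contrasts, g2m,
                n_perm=n_perm, rng=np.random.default_rng(seed + 99 + b))
            det_vals.extend(cmp_res["per_network"]["neg_log10_p_det"])
            non_vals.extend(cmp_res["per_network"]["neg_log10_p_non"])
        det_p = compare_enrichment_distributions(det_vals, non_vals, test="t_paired")
    return recovery, det_p


def integration_recovery_study(seed: int = 0, n_replicates: int = 10,
                               n_individuals: int = 1000, n_breeds: int = 3,
                               n_networks: int = 25, n_planted: int = 5,
                               n_perm: int = 1000, alpha: float = 0.05) -> dict:
    """End-to-end recovery of infection-responsive planted networks.

    Study design (frozen): three breed cohorts of 1,000 animals share one
    annotation (2,500 markers, 150 genes, 25 target networks of 12-16
    genes) and one causal architecture. Five networks are planted as
    infection-responsive: 70% of their targets are differentially
    expressed across eight conditions, and every causal variant of the
    (h2 = 0.5) trait lies in a DE gene. Per replicate: per-breed
    mixed-model scans and marker-set tests, significant-network calling
    at p < alpha in every breed, and a paired one-sided t-test of DET vs
    non-DET marker-set enrichment pooled over (network, breed) pairs.

    Returns the mean recovered fraction of planted networks, and the
    geometric-mean and worst-case DET-comparison p-value.
    """
    recoveries, det_ps = [], []
    for r in range(n_replicates):
        rec, det_p = _integration_replicate(
            seed * 101_113 + 17 * r, n_individuals, n_breeds,
            n_networks, n_planted, n_perm, alpha)
        recoveries.append(rec)
        if det_p is not None:
            det_ps.append(det_p)
    det_ps = np.asarray(det_ps if det_ps else [np.nan])
    return {
        "mean_recovery": float(np.mean(recoveries)),
        "det_p_geomean": float(np.exp(np.mean(np.log(np.maximum(det_ps, 1e-300))))),
        "det_p_worst": float(np.max(det_ps)),
        "det_reject_rate": float(np.mean(det_ps < 0.05)),
        "n_replicates": n_replicates,
        "joint_level": alpha ** n_breeds,
    }
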