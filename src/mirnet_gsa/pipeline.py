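"""End-to-end orchestration: simulate -> QC -> GWAS -> marker-set test ->
between-breed correlation -> transcriptome integration.

The pipeline mirrors a multi-breed study design: one shared annotation
(genes, miRNAs, target networks) and several breed cohorts, each with
its own genotypes and phenotype. Every stage writes #-commented TSV
reports tagged with the config hash, and a JSON manifest records the
software version, seeds, input checksums and per-stage timestamps.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import substream
from . import io as mio
from .synthetic import (SimulationConfig, simulate_annotation, simulate_genotypes,
                        simulate_phenotype, simulate_target_networks,
                        simulate_expression_contrasts)
from .features import (assign_snps_to_genes, build_mirna_flank_set,
                       build_network_marker_set, TargetNetwork)
from .gwas import qc_filter, run_gwas, compute_grm, reml_variance_components, \
    bonferroni_threshold, demarcate_qtl
from .settest import test_feature_sets
from .correlation import enrichment_matrix, pairwise_correlation, \
    random_network_null, correlation_significance
from .integration import call_significant_networks, compare_partition_enrichment

log = logging.getLogger("mirnet_gsa")

__all__ = ["RunManifest", "run_pipeline", "default_config", "config_hash"]


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    status: str = "running"

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def config_hash(cfg: dict) -> str:
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def default_config(seed: int = 1) -> dict:
    """Small synthetic multi-breed study configuration."""
    return {
        "seed": seed,
        "n_breeds": 3,
        "trait": "mastitis",
        "simulation": {
            "n_individuals": 300,
            "n_chromosomes": 5,
            "markers_per_chrom": 1000,
            "ld_block_length": 20,
            "n_ancestral_haplotypes": 20,
            "maf_min": 0.05,
            "n_genes": 150,
            "n_mirnas": 40,
            "mean_targets_per_mirna": 15.0,
            "target_size_range": [5, 40],
            "h2": 0.5,
            "enrichment_fold": 5.0,
            "prop_causal": 0.05,
        },
        "n_enriched_networks": 3,
        "n_conditions": 8,
        "qc": {"maf_min": 0.01, "hwe_p_min": 1e-6},
        "gwas": {"loco": True, "vc_refit": "per-chrom"},
        "settest": {"n_perm": 1000, "flank_kb": 5.0},
        "correlate": {"n_null_reps": 100, "n_perm": 200},
        "integrate": {"alpha": 0.05, "fdr_cut": 0.05, "min_conditions": 2},
    }


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: dict, out_dir) -> RunManifest:
    """Execute the full synthetic-study workflow described by ``cfg``.

    Emits, under ``out_dir``: simulated inputs (dosage TSVs, GFF3
    annotation, GMT networks, phenotype and contrast TSVs, truth tables)
    and per-stage reports (GWAS MarkerStats, QTL regions, marker-set
    enrichment per breed, between-breed correlation tests, significant
    networks and the DET comparison). Returns the finalized manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    h = config_hash(cfg)
    meta = {"config_hash": h, "version": __version__, "seed": seed}
    manifest = RunManifest(version=__version__, config_hash=h, seed=seed)
    manifest_path = out / "manifest.json"
    manifest.write(manifest_path)
    mio.write_config(cfg, out / "config.yaml")

    def stage(name):
        t0 = time.time()
        manifest.stages[name] = {"started": t0, "status": "running"}
        manifest.write(manifest_path)
        log.info("stage %s started", name)
        return t0

    def done(name, t0, **info):
        manifest.stages[name].update(status="done", elapsed_s=round(time.time() - t0, 3),
                                     **info)
        manifest.write(manifest_path)
        log.info("stage %s done (%.1fs) %s", name, time.time() - t0, info)

    try:
        # ----- simulate ---------------------------------------------------
        t0 = stage("simulate")
        sim = SimulationConfig(seed=seed, **cfg["simulation"])
        n_breeds = int(cfg.get("n_breeds", 3))
        genes, mirnas = simulate_annotation(sim)
        networks = simulate_target_networks(mirnas["mirna_id"], genes["gene_id"], sim)
        rng_eff = substream(seed, "effects")
        enriched_ids = sorted(
            rng_eff.choice(sorted(networks), size=int(cfg["n_enriched_networks"]),
                           replace=False))

        mio.write_annotation_gff3(genes, mirnas, out / "annotation.gff3")
        mio.write_gene_sets(networks, out / "networks.gmt")

        breeds = [f"breed{i + 1}" for i in range(n_breeds)]
        cohorts = {}
        for bi, breed in enumerate(breeds):
            bseed = seed + 1000 * (bi + 1)
            bsim = SimulationConfig(**{**sim.to_dict(), "seed": bseed})
            geno = simulate_genotypes(bsim)
            gene_to_markers = assign_snps_to_genes(geno.markers, genes)
            enriched_feats = {}
            for mid in enriched_ids:
                net = TargetNetwork(mirna_id=mid, target_gene_ids=networks[mid])
                ms = build_network_marker_set(net, gene_to_markers)
                if ms.m_f:
                    enriched_feats[mid] = ms.marker_indices
            y, truth = simulate_phenotype(geno, enriched_feats, bsim)
            mio.write_genotypes_tsv(geno, out / f"genotypes_{breed}.tsv")
            mio.write_phenotypes(geno.samples, y, cfg.get("trait", "trait"),
                                 out / f"phenotypes_{breed}.tsv", header_meta=meta)
            mio.write_table(pd.DataFrame({"causal_marker_id": truth.causal_marker_ids}),
                            out / f"truth_causal_{breed}.tsv", header_meta=meta)
            cohorts[breed] = (geno, y)

        n_cond = int(cfg.get("n_conditions", 8))
        contrasts, de_truth = simulate_expression_contrasts(
            genes["gene_id"], networks, n_cond, enriched_ids,
            rng=substream(seed, "expression"))
        mio.write_contrasts(contrasts, out / "contrasts.tsv", header_meta=meta)
        mio.write_table(pd.DataFrame({"enriched_network": enriched_ids}),
                        out / "truth_networks.tsv", header_meta=meta)
        done("simulate", t0, n_breeds=n_breeds, n_markers=sim.n_markers,
             n_networks=len(networks))

        # ----- qc + gwas --------------------------------------------------
        scans = {}
        for breed, (geno, y) in cohorts.items():
            t0 = stage(f"gwas:{breed}")
            qcfg = cfg.get("qc", {})
            geno_qc, keep = qc_filter(geno, qcfg.get("maf_min", 0.01),
                                      qcfg.get("hwe_p_min", 1e-6), return_mask=True)
            gcfg = cfg.get("gwas", {})
            stats_df = run_gwas(geno_qc, y, loco=gcfg.get("loco", True),
                                vc_refit=gcfg.get("vc_refit", "per-chrom"))
            grm = compute_grm(geno_qc)
            vc = reml_variance_components(y, grm)
            thr = bonferroni_threshold(len(stats_df))
            qtl = demarcate_qtl(stats_df, thr, sigma_a2=vc.sigma_a2)
            mio.write_table(stats_df, out / f"gwas_{breed}.tsv", header_meta=meta)
            mio.write_table(pd.DataFrame([asdict(q) for q in qtl]),
                            out / f"qtl_{breed}.tsv", header_meta=meta)
            scans[breed] = (geno_qc, stats_df)
            done(f"gwas:{breed}", t0, n_markers_postqc=len(stats_df),
                 n_removed=int((~keep).sum()), h2_hat=round(vc.h2, 4), n_qtl=len(qtl))

        # ----- marker-set test -------------------------------------------
        scfg = cfg.get("settest", {})
        n_perm = int(scfg.get("n_perm", 1000))
        enr_results = {}
        g2m_by_breed = {}
        for bi, (breed, (geno_qc, stats_df)) in enumerate(scans.items()):
            t0 = stage(f"settest:{breed}")
            g2m = assign_snps_to_genes(geno_qc.markers, genes)
            g2m_by_breed[breed] = g2m
            feats = {}
            for mid, gl in networks.items():
                ms = build_network_marker_set(
                    TargetNetwork(mirna_id=mid, target_gene_ids=gl), g2m)
                feats[mid] = ms
            flank = build_mirna_flank_set(geno_qc.markers, mirnas,
                                          scfg.get("flank_kb", 5.0))
            if flank.testable:
                feats[flank.feature_id] = flank
            res = test_feature_sets(stats_df, feats, n_perm=n_perm,
                                    rng=substream(seed + bi, "permutation"))
            mio.write_table(res, out / f"enrichment_{breed}.tsv", header_meta=meta)
            enr_results[breed] = res
            done(f"settest:{breed}", t0, n_features=len(res))

        # ----- correlate --------------------------------------------------
        net_only = {b: r[r["feature_id"].isin(networks)] for b, r in enr_results.items()}
        if len(scans) >= 2:
            t0 = stage("correlate")
            ccfg = cfg.get("correlate", {})
            mat = enrichment_matrix(net_only)
            rows = []
            pairs = [(a, b) for i, a in enumerate(breeds) for b in breeds[i + 1:]]
            universe = sorted(g for g, m in g2m_by_breed[breeds[0]].items() if m.size)
            for a, b in pairs:
                r_obs = pairwise_correlation(mat[a], mat[b])
                mu, sd = random_network_null(
                    networks, universe,
                    (scans[a][1], scans[b][1]), g2m_by_breed[a],
                    n_reps=int(ccfg.get("n_null_reps", 100)),
                    n_perm=int(ccfg.get("n_perm", 200)),
                    rng=substream(seed, "random_networks"))
                p = correlation_significance(r_obs, mu, sd)
                rows.append((f"{a}x{b}", r_obs, mu, sd, p))
            corr = pd.DataFrame(rows, columns=["pair_id", "r_observed", "null_mean",
                                               "null_sd", "p_one_sided"])
            mio.write_table(corr, out / "correlations.tsv", header_meta=meta)
            mio.write_table(mat.reset_index(), out / "enrichment_matrix.tsv",
                            header_meta=meta)
            done("correlate", t0, n_pairs=len(rows))

        # ----- integrate --------------------------------------------------
        t0 = stage("integrate")
        icfg = cfg.get("integrate", {})
        alpha = float(icfg.get("alpha", 0.05))
        pmat = pd.DataFrame({b: r.set_index("feature_id")["p"] for b, r in
                             net_only.items()})
        sig_ids, joint = call_significant_networks(pmat, alpha=alpha)
        mio.write_table(pd.DataFrame({"network": sig_ids}),
                        out / "significant_networks.tsv",
                        header_meta={**meta, "joint_level": joint})
        report = {"significant_networks": sig_ids, "joint_level": joint}
        if sig_ids:
            first = breeds[0]
            cmp_res = compare_partition_enrichment(
                scans[first][1], {m: networks[m] for m in sig_ids}, contrasts,
                g2m_by_breed[first], n_perm=n_perm,
                rng=substream(seed, "permutation"),
                fdr_cut=float(icfg.get("fdr_cut", 0.05)),
                min_conditions=int(icfg.get("min_conditions", 2)))
            mio.write_table(cmp_res["per_network"], out / "det_comparison.tsv",
                            header_meta={**meta,
                                         "p_det_vs_nondet": cmp_res["p_comparison"]})
            report["p_det_vs_nondet"] = cmp_res["p_comparison"]
        done("integrate", t0, **{k: v for k, v in report.items()
                                 if not isinstance(v, list)})

        manifest.status = "done"
    except Exception:
        manifest.status = "failed"
        manifest.write(manifest_path)
        raise
    manifest.write(manifest_path)
    return manifest
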