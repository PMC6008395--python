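"""Integration of infection-induced expression contrasts with network enrichments.

A miRNA-target network is called significant for a trait when its
marker-set p-value falls below alpha in every breed analysed; at three
breeds and alpha = 0.05 the implied joint level is 0.05^3 = 1.25e-4.
Targets of significant networks that are differentially expressed (FDR
below cut) in at least two infection conditions are DETs; these are
partitioned by the sign of their log2 fold-changes (consistently
positive = up-regulated, negative = down, mixed = excluded), and the
GWAS-signal enrichment of DET vs non-DET marker sets is compared across
networks.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .features import MarkerSet, build_network_marker_set, TargetNetwork
from .settest import test_feature_sets
from .correlation import compare_enrichment_distributions

__all__ = [
    "DETPartition",
    "call_significant_networks",
    "hypergeometric_enrichment",
    "benjamini_hochberg",
    "gene_set_enrichment_with_fdr",
    "identify_dets",
    "partition_dets",
    "compare_partition_enrichment",
]


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR control)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


@dataclass
class DETPartition:
    """Per-miRNA split of network targets by infection response."""

    mirna_id: str
    det_genes: set = field(default_factory=set)
    non_det_target_genes: set = field(default_factory=set)
    up_genes: set = field(default_factory=set)
    down_genes: set = field(default_factory=set)
    mixed_genes: set = field(default_factory=set)


def call_significant_networks(pvalues: pd.DataFrame, alpha: float = 0.05):
    """Networks with p < alpha in every breed for one trait.

    ``pvalues``: DataFrame indexed by network id with one column per
    breed. Networks with any missing p-value are not callable and are
    never returned. Returns (significant_ids, joint_level) where
    joint_level = alpha ** n_breeds is the implied genome-wide level of
    the all-breeds rule.
    """
    n_breeds = pvalues.shape[1]
    callable_mask = pvalues.notna().all(axis=1)
    sig = (pvalues < alpha).all(axis=1) & callable_mask
    return list(pvalues.index[sig]), alpha ** n_breeds


def hypergeometric_enrichment(set_a, set_b, universe) -> float:
    """Upper-tail hypergeometric p of the overlap between two gene sets.

    Probability of at least |A ∩ B| successes when drawing |A| genes from
    a universe containing |B| successes. Both sets must lie inside the
    universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    A, B = set(set_a), set(set_b)
    if not A <= universe or not B <= universe:
        raise ValueError("query sets must be subsets of the universe")
    k = len(A & B)
    # P(X >= k), X ~ Hypergeom(N=|U|, K=|B|, n=|A|)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(B), len(A)))


def gene_set_enrichment_with_fdr(query_genes, pathways: dict[str, list[str]],
                                 universe, fdr_cut: float = 0.1) -> pd.DataFrame:
    """Hypergeometric pathway enrichment with Benjamini-Hochberg control.

    Tests the query gene list against each pathway, adjusts the p-values
    by BH, and returns pathways with adjusted p < ``fdr_cut``.
    GeneRatio is (query genes in the pathway) / (query genes annotated in
    any pathway).
    """
    universe = set(universe)
    query = set(query_genes) & universe
    annotated_query = query & {g for genes in pathways.values() for g in genes}
    rows = []
    for name, genes in pathways.items():
        genes = set(genes) & universe
        if not genes:
            continue
        k = len(query & genes)
        p = hypergeometric_enrichment(query, genes, universe)
        rows.append((name, len(genes), k, p))
    if not rows:
        return pd.DataFrame(columns=["pathway", "n_pathway", "n_overlap", "p",
                                     "p_adjust", "gene_ratio"])
    df = pd.DataFrame(rows, columns=["pathway", "n_pathway", "n_overlap", "p"])
    df["p_adjust"] = benjamini_hochberg(df["p"])
    denom = max(len(annotated_query), 1)
    df["gene_ratio"] = df["n_overlap"] / denom
    out = df[df["p_adjust"] < fdr_cut].sort_values("p_adjust").reset_index(drop=True)
    return out


def _de_table(contrasts: pd.DataFrame, fdr_cut: float) -> pd.DataFrame:
    req = {"gene_id", "condition", "log2_fc", "fdr"}
    missing = req - set(contrasts.columns)
    if missing:
        raise ValueError(f"contrast table lacks columns: {sorted(missing)}")
    return contrasts[contrasts["fdr"] < fdr_cut]


def identify_dets(target_genes, contrasts: pd.DataFrame, fdr_cut: float = 0.05,
                  min_conditions: int = 2):
    """Split targets into DETs and non-DETs.

    A target is a differentially expressed target (DET) when its FDR is
    below ``fdr_cut`` in at least ``min_conditions`` distinct conditions.
    Returns (det_set, non_det_set) over the supplied targets.
    """
    targets = {str(g) for g in target_genes}
    de = _de_table(contrasts, fdr_cut)
    counts = de.groupby("gene_id")["condition"].nunique()
    dets = {g for g in targets if counts.get(g, 0) >= min_conditions}
    return dets, targets - dets


def partition_dets(det_genes, contrasts: pd.DataFrame, fdr_cut: float = 0.05):
    """Partition DETs by regulation direction across their DE conditions.

    Signs are read from log2 fold-changes restricted to the conditions
    where the gene is significant (FDR < cut): all positive -> up, all
    negative -> down, mixed signs -> excluded from both and returned as
    the third element. Returns (up_set, down_set, mixed_set).
    """
    dets = {str(g) for g in det_genes}
    de = _de_table(contrasts, fdr_cut)
    de = de[de["gene_id"].isin(dets)]
    up, down, mixed = set(), set(), set()
    for gene, grp in de.groupby("gene_id"):
        signs = np.sign(grp["log2_fc"].to_numpy())
        if np.all(signs > 0):
            up.add(gene)
        elif np.all(signs < 0):
            down.add(gene)
        else:
            mixed.add(gene)
    return up, down, mixed


def compare_partition_enrichment(stats_table, networks: dict[str, list[str]],
                                 contrasts: pd.DataFrame,
                                 gene_to_markers: dict[str, np.ndarray],
                                 n_perm: int = 1000, rng=None,
                                 fdr_cut: float = 0.05, min_conditions: int = 2,
                                 test: str = "t_paired") -> dict:
    """Per-network DET vs non-DET GWAS-enrichment comparison.

    For every network: identify DETs among its targets, build DET and
    non-DET marker sets, run the marker-set test on both, and compare the
    paired -log10 p across networks with a one-sided test (DET side
    greater). Networks with an empty partition side (or a side with no
    markers) are dropped with a warning.

    Returns a dict with the per-network table, the comparison p-value,
    and the partitions.
    """
    partitions: dict[str, DETPartition] = {}
    det_sets, non_det_sets = {}, {}
    dropped = []
    for mid, genes in networks.items():
        dets, non_dets = identify_dets(genes, contrasts, fdr_cut, min_conditions)
        up, down, mixed = partition_dets(dets, contrasts, fdr_cut)
        partitions[mid] = DETPartition(mirna_id=mid, det_genes=dets,
                                       non_det_target_genes=non_dets,
                                       up_genes=up, down_genes=down,
                                       mixed_genes=mixed)
        if not dets or not non_dets:
            dropped.append(mid)
            continue
        ms_det = build_network_marker_set(
            TargetNetwork(mirna_id=f"{mid}:DET", target_gene_ids=sorted(dets)),
            gene_to_markers)
        ms_non = build_network_marker_set(
            TargetNetwork(mirna_id=f"{mid}:nonDET", target_gene_ids=sorted(non_dets)),
            gene_to_markers)
        if ms_det.m_f == 0 or ms_non.m_f == 0:
            dropped.append(mid)
            continue
        det_sets[mid] = ms_det
        non_det_sets[mid] = ms_non
    if dropped:
        warnings.warn(f"networks dropped from the DET comparison: {sorted(dropped)}")
    if len(det_sets) < 2:
        raise ValueError("need at least 2 networks with both partition sides testable")

    res_det = test_feature_sets(stats_table, det_sets, n_perm=n_perm, rng=rng)
    res_non = test_feature_sets(stats_table, non_det_sets, n_perm=n_perm, rng=rng)
    merged = res_det.merge(res_non, on="feature_id", suffixes=("_det", "_non"))
    p_cmp = compare_enrichment_distributions(
        merged["neg_log10_p_det"], merged["neg_log10_p_non"], test=test)
    return {
        "per_network": merged,
        "p_comparison": p_cmp,
        "partitions": partitions,
        "dropped": dropped,
    }
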