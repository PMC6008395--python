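"""Correlation of feature enrichments between traits and breeds.

The per-feature enrichment signal is -log10 p from the marker-set test.
Correlating these across features between two analyses (two traits in a
breed, or one trait in two breeds) measures shared architecture. The
observed correlation is judged against a null built from random
size-matched target networks: the networks are redrawn at random, the
marker-set test is rerun for both analyses, and the correlation is
recomputed — 1000 times — giving a null mean and SD under a normal
approximation, from which a one-sided (upper tail) p follows.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import as_generator
from .features import MarkerSet, TargetNetwork, build_network_marker_set, \
    sample_random_network
from .settest import test_feature_sets

__all__ = [
    "CorrelationTest",
    "pairwise_correlation",
    "enrichment_matrix",
    "random_network_null",
    "correlation_significance",
    "compare_enrichment_distributions",
]


@dataclass
class CorrelationTest:
    pair_id: str
    r_observed: float
    null_mean: float
    null_sd: float
    p_one_sided: float


def pairwise_correlation(col_a, col_b, method: str = "pearson") -> float:
    """Correlation of enrichments over features present in both columns.

    Pairs with a non-finite value in either column are dropped; at least
    3 complete pairs are required. Zero variance in either column is
    undefined and raises.
    """
    a = np.asarray(col_a, dtype=np.float64)
    b = np.asarray(col_b, dtype=np.float64)
    if a.size != b.size:
        raise ValueError("columns differ in length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    raise ValueError("method must be 'pearson' or 'spearman'")


def enrichment_matrix(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Align per-analysis marker-set results into a feature x analysis matrix.

    ``results`` maps a column label (e.g. ``"HOL:MY"``) to a marker-set
    test table. Values are neg_log10_p; features missing from an analysis
    get NaN. Only features present in all columns are retained
    (intersection semantics).
    """
    cols = {}
    for label, df in results.items():
        cols[label] = df.set_index("feature_id")["neg_log10_p"]
    mat = pd.DataFrame(cols)
    return mat.dropna(axis=0, how="any")


def random_network_null(networks: dict[str, list[str]], gene_universe,
                        stats_pair, gene_to_markers: dict[str, np.ndarray],
                        n_reps: int = 1000, n_perm: int = 1000, rng=None,
                        return_null: bool = False):
    """Null (mu, sigma) of the between-column correlation from random networks.

    Each rep redraws every network uniformly at random from the gene
    universe with its observed size (the same draw is used for both
    columns), rebuilds the marker sets, reruns the marker-set test on
    each column's statistics, and correlates the resulting -log10 p
    vectors. Returns (mu, sigma) — and the raw null correlations with
    ``return_null=True``.
    """
    universe = list(gene_universe)
    sizes = {mid: len(genes) for mid, genes in networks.items()}
    if max(sizes.values()) > len(universe):
        raise ValueError("a network is larger than the gene universe")
    rng = as_generator(rng)
    stats_a, stats_b = stats_pair

    r_null = np.empty(n_reps)
    for rep in range(n_reps):
        rand_sets = {}
        for mid, size in sizes.items():
            genes = sample_random_network(size, universe, rng)
            net = TargetNetwork(mirna_id=mid, target_gene_ids=genes)
            rand_sets[mid] = build_network_marker_set(net, gene_to_markers)
        res_a = test_feature_sets(stats_a, rand_sets, n_perm=n_perm, rng=rng)
        res_b = test_feature_sets(stats_b, rand_sets, n_perm=n_perm, rng=rng)
        r_null[rep] = pairwise_correlation(res_a["neg_log10_p"], res_b["neg_log10_p"])
    mu = float(r_null.mean())
    sigma = float(r_null.std(ddof=1))
    if return_null:
        return mu, sigma, r_null
    return mu, sigma


def correlation_significance(r_observed: float, mu: float, sigma: float) -> float:
    """One-sided p for r_observed under r ~ N(mu, sigma^2), upper tail."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(stats.norm.sf((r_observed - mu) / sigma))


def compare_enrichment_distributions(group_a, group_b, test: str = "wilcoxon") -> float:
    """One-sided p that group_a's enrichments stochastically exceed group_b's.

    ``test``: 'wilcoxon' (rank-sum; exact when both groups have at most
    10 values and no ties, else normal approximation with tie
    correction), 't_paired', or 't_welch'. Degenerate inputs (all values
    tied, or identically paired groups) return p = 0.5 with a warning.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")

    if test == "wilcoxon":
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            warnings.warn("all values tied: rank-sum test uninformative, p = 0.5")
            return 0.5
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (a.size <= 10 and b.size <= 10 and not has_ties) \
            else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="greater", method=method)
        return float(res.pvalue)
    if test == "t_paired":
        if a.size != b.size:
            raise ValueError("paired t-test needs equal group sizes")
        d = a - b
        if np.all(d == 0):
            warnings.warn("all paired differences zero: p = 0.5")
            return 0.5
        res = stats.ttest_rel(a, b, alternative="greater")
        return float(res.pvalue)
    if test == "t_welch":
        res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
        if np.isnan(res.pvalue):
            warnings.warn("degenerate t-test input: p = 0.5")
            return 0.5
        return float(res.pvalue)
    raise ValueError("test must be 'wilcoxon', 't_paired' or 't_welch'")
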