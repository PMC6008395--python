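"""Sum-based marker-set test with a cyclical-permutation null.

For a genomic feature f containing m_f markers the statistic is

    T_sum = sum_{i in f} t_i^2

where t_i = b_i / se_i is the single-marker GWAS statistic. Its null
distribution is built by cyclical permutation: the genome-ordered vector
of t^2 values is rotated by a random offset, which detaches markers from
features while preserving the local (LD-induced) correlation structure
of neighbouring test statistics, and T_sum is recomputed at the
feature's original positions. The empirical p-value is the add-one
proportion of rotated statistics at least as large as the observed one,
so p is never exactly zero and -log10 p is always defined.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import as_generator
from .features import MarkerSet

__all__ = [
    "EnrichmentResult",
    "genome_ordered_t_squared",
    "compute_tsum",
    "cyclical_rotation",
    "permutation_null",
    "empirical_pvalue",
    "test_feature_sets",
]


@dataclass
class EnrichmentResult:
    feature_id: str
    m_f: int
    t_sum_observed: float
    n_perm: int
    null_exceed_count: int
    p_empirical: float

    @property
    def neg_log10_p(self) -> float:
        return float(-np.log10(self.p_empirical))


def genome_ordered_t_squared(stats_table: pd.DataFrame) -> np.ndarray:
    """Extract t^2 in genome order from a MarkerStats table.

    The table must already be genome-ordered (chromosomes concatenated in
    the recorded order, positions ascending within each), as produced by
    :func:`mirnet_gsa.gwas.run_gwas`.
    """
    t = stats_table["t"].to_numpy(dtype=np.float64)
    return t * t


def compute_tsum(t_squared: np.ndarray, marker_set: MarkerSet | np.ndarray) -> float:
    """T_sum = sum of t^2 over the feature's member markers."""
    idx = marker_set.marker_indices if isinstance(marker_set, MarkerSet) \
        else np.asarray(marker_set, dtype=np.int64)
    if idx.size == 0:
        raise ValueError("empty marker set is not testable")
    return float(np.asarray(t_squared, dtype=np.float64)[idx].sum())


def cyclical_rotation(t_squared: np.ndarray, offset: int) -> np.ndarray:
    """Rotate the genome-ordered vector: out[i] = in[(i + offset) mod m]."""
    t2 = np.asarray(t_squared)
    m = t2.size
    k = int(offset) % m
    if k == 0:
        return t2.copy()
    return np.concatenate([t2[k:], t2[:k]])


def _draw_offsets(m: int, n_perm: int, rng) -> np.ndarray:
    """Rotation offsets for the null: exhaustive when few, else sampled.

    The identity offset 0 is never drawn — the observed configuration is
    not a null sample. When all m - 1 non-identity rotations number at
    most ``n_perm``, they are enumerated exactly instead of sampled;
    otherwise offsets are drawn uniformly from {1, ..., m-1} with
    replacement.
    """
    if m < 2:
        raise ValueError("need at least 2 markers to rotate")
    if m - 1 <= n_perm:
        return np.arange(1, m, dtype=np.int64)
    return rng.integers(1, m, size=n_perm, dtype=np.int64)


def _null_sums(t2: np.ndarray, idx: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """T_sum at the feature's original positions under each rotation.

    Rotating the statistics by k and reading the feature's original
    positions equals reading positions (idx + k) mod m of the unrotated
    vector, which vectorizes as one fancy-indexed gather.
    """
    m = t2.size
    pos = (idx[None, :] + offsets[:, None]) % m
    return t2[pos].sum(axis=1)


def permutation_null(t_squared: np.ndarray, marker_set: MarkerSet | np.ndarray,
                     n_perm: int = 1000, rng=None) -> np.ndarray:
    """Cyclical-permutation null T_sum values for one feature."""
    t2 = np.asarray(t_squared, dtype=np.float64)
    idx = marker_set.marker_indices if isinstance(marker_set, MarkerSet) \
        else np.asarray(marker_set, dtype=np.int64)
    if idx.size == 0:
        raise ValueError("empty marker set is not testable")
    offsets = _draw_offsets(t2.size, n_perm, as_generator(rng))
    return _null_sums(t2, idx, offsets)


def _count_exceed(null_values: np.ndarray, t_obs: float) -> int:
    """#{null >= obs}, with a relative tolerance so that rotation sums that
    are mathematically tied (e.g. the full-genome feature) are not split
    by floating-point summation order."""
    tol = 1e-9 * max(1.0, abs(t_obs))
    return int(np.count_nonzero(null_values >= t_obs - tol))


def empirical_pvalue(t_obs: float, null_values: np.ndarray) -> float:
    """Add-one empirical upper-tail p: (1 + #{null >= obs}) / (n + 1).

    Ties count against significance (>=), which is conservative for
    discrete statistics.
    """
    null_values = np.asarray(null_values)
    if null_values.size == 0:
        raise ValueError("need at least one null value")
    exceed = _count_exceed(null_values, t_obs)
    return (1 + exceed) / (null_values.size + 1)


def test_feature_sets(stats_table: pd.DataFrame, features, n_perm: int = 1000,
                      rng=None, share_offsets: bool = True) -> pd.DataFrame:
    """Run the marker-set test for every feature against one trait's scan.

    ``features``: mapping feature_id -> MarkerSet (or index array), or an
    iterable of MarkerSet. With ``share_offsets`` (default) one stream of
    rotation offsets is drawn per trait and reused across features, since
    rotations are feature-independent; per-feature independent streams
    give independent Monte-Carlo noise across features.

    Non-testable (empty) features are reported with NaN statistics rather
    than dropped. Returns a DataFrame with columns
    [feature_id, m_f, t_sum, n_perm, null_exceed, p, neg_log10_p].
    """
    if isinstance(features, dict):
        items = [(k, v) for k, v in features.items()]
    else:
        items = [(ms.feature_id, ms) for ms in features]
    if not items:
        raise ValueError("no features supplied")
    t2 = genome_ordered_t_squared(stats_table) if isinstance(stats_table, pd.DataFrame) \
        else np.asarray(stats_table, dtype=np.float64)
    m = t2.size
    rng = as_generator(rng)
    shared = _draw_offsets(m, n_perm, rng) if share_offsets else None

    rows = []
    for fid, ms in items:
        idx = ms.marker_indices if isinstance(ms, MarkerSet) \
            else np.asarray(ms, dtype=np.int64)
        if idx.size == 0:
            rows.append((fid, 0, np.nan, 0, 0, np.nan, np.nan))
            continue
        offsets = shared if shared is not None else _draw_offsets(m, n_perm, rng)
        null = _null_sums(t2, idx, offsets)
        t_obs = float(t2[idx].sum())
        exceed = _count_exceed(null, t_obs)
        p = (1 + exceed) / (null.size + 1)
        rows.append((fid, int(idx.size), t_obs, int(null.size), exceed, p, -np.log10(p)))
    return pd.DataFrame(rows, columns=["feature_id", "m_f", "t_sum", "n_perm",
                                       "null_exceed", "p", "neg_log10_p"])
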