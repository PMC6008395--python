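"""Two-step variance-component single-marker GWAS.

Step 1 fits the polygenic null model

    y = 1 mu + a + e,   a ~ N(0, G sigma_a^2),   e ~ N(0, I sigma_e^2)

by REML, where G is a VanRaden genomic relationship matrix built while
leaving out the chromosome of the candidate SNP (LOCO) so the tested
marker does not also enter the covariance. Step 2 tests each marker by
generalized least squares

    y = 1 mu + x b + eta,   Var(eta) = G sigma_a^2 + I sigma_e^2

with the variance components held fixed (the EMMAX approximation); the
per-marker statistic is t = b / se with n - 2 degrees of freedom.

The one-dimensional REML problem in lambda = sigma_a^2 / sigma_e^2 is
solved on the eigenbasis of G: one symmetric eigendecomposition per GRM,
then each likelihood evaluation is O(n).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats, optimize

from .synthetic import GenotypeMatrix

__all__ = [
    "GRM",
    "VarianceComponents",
    "QTLRegion",
    "qc_filter",
    "hwe_chi2_pvalues",
    "compute_grm",
    "reml_variance_components",
    "gls_single_marker",
    "run_gwas",
    "bonferroni_threshold",
    "demarcate_qtl",
    "variance_explained",
]

_LAMBDA_BOUNDS = (1e-6, 1e6)


@dataclass
class GRM:
    """Genomic relationship matrix with optional LOCO exclusion."""

    matrix: np.ndarray
    excluded_chrom: str | None = None
    _eigen: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def eigen(self):
        """Cached symmetric eigendecomposition (d, U) with G = U diag(d) U'."""
        if self._eigen is None:
            d, U = np.linalg.eigh(self.matrix)
            d = np.clip(d, 0.0, None)  # PSD up to numerical jitter
            self._eigen = (d, U)
        return self._eigen


@dataclass
class VarianceComponents:
    """REML estimates of the polygenic null model."""

    sigma_a2: float
    sigma_e2: float
    loglik: float
    boundary: bool = False

    @property
    def h2(self) -> float:
        tot = self.sigma_a2 + self.sigma_e2
        return self.sigma_a2 / tot if tot > 0 else 0.0

    @property
    def lam(self) -> float:
        return self.sigma_a2 / self.sigma_e2


@dataclass
class QTLRegion:
    chrom: str
    start: int
    end: int
    top_marker_id: str
    top_neg_log10_p: float
    top_freq: float
    top_beta: float
    n_markers: int
    variance_explained: float | None = None


# ---------------------------------------------------------------------------
# QC


def hwe_chi2_pvalues(dosages: np.ndarray) -> np.ndarray:
    """1-df chi-square Hardy-Weinberg test per marker on rounded dosages.

    Imputed dosages carry no hard genotype calls, so dosages are rounded
    to the nearest integer (0.5/1.5 round half-up) before counting.
    """
    calls = np.floor(dosages + 0.5).astype(np.int64)
    n = calls.shape[0]
    n2 = (calls == 2).sum(axis=0)
    n1 = (calls == 1).sum(axis=0)
    n0 = n - n1 - n2
    p = (2 * n2 + n1) / (2.0 * n)
    q = 1.0 - p
    exp = np.stack([n * q * q, 2 * n * p * q, n * p * p])
    obs = np.stack([n0, n1, n2])
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0).sum(axis=0)
    return stats.chi2.sf(chi2, df=1)


def qc_filter(genotypes: GenotypeMatrix, maf_min: float = 0.01,
              hwe_p_min: float = 1e-6, return_mask: bool = False):
    """Remove markers with MAF <= maf_min or HWE test p <= hwe_p_min."""
    freq = genotypes.allele_freq()
    maf = np.minimum(freq, 1.0 - freq)
    hwe_p = hwe_chi2_pvalues(genotypes.dosages)
    keep = (maf > maf_min) & (hwe_p > hwe_p_min)
    if not keep.any():
        raise ValueError("QC removed every marker")
    out = genotypes.subset_markers(keep)
    if return_mask:
        return out, keep
    return out


# ---------------------------------------------------------------------------
# GRM


def compute_grm(genotypes: GenotypeMatrix, excluded_chrom: str | None = None) -> GRM:
    """VanRaden method-1 GRM: G = WW' / sum_j 2 p_j (1 - p_j).

    W centers dosages by twice the observed allele frequency. With
    ``excluded_chrom`` set, only markers outside that chromosome enter
    (leave-one-chromosome-out).
    """
    chroms = genotypes.markers["chrom"].astype(str).to_numpy()
    if excluded_chrom is not None:
        use = chroms != str(excluded_chrom)
        if use.sum() < 2:
            raise ValueError(
                f"fewer than 2 markers outside chromosome {excluded_chrom}"
            )
    else:
        use = np.ones(len(chroms), dtype=bool)
    X = genotypes.dosages[:, use]
    p = X.mean(axis=0) / 2.0
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all GRM markers are monomorphic")
    W = X - 2.0 * p
    G = (W @ W.T) / denom
    return GRM(matrix=G, excluded_chrom=excluded_chrom)


# ---------------------------------------------------------------------------
# REML


def _reml_neg2ll(lam: float, d: np.ndarray, ys: np.ndarray, cs: np.ndarray) -> float:
    """-2 x REML log-likelihood (up to an additive constant) at lambda.

    d: eigenvalues of G; ys = U'y; cs = U'1 (the rotated intercept).
    """
    n = d.size
    w = lam * d + 1.0
    cwc = np.sum(cs * cs / w)
    cwy = np.sum(cs * ys / w)
    mu = cwy / cwc
    r = ys - cs * mu
    rss = np.sum(r * r / w)
    sigma_e2 = rss / (n - 1)
    return ((n - 1) * (np.log(2.0 * np.pi * sigma_e2) + 1.0)
            + np.sum(np.log(w)) + np.log(cwc))


def reml_variance_components(y: np.ndarray, grm: GRM | np.ndarray) -> VarianceComponents:
    """REML variance components via eigendecomposition + bounded 1-D search.

    Searches lambda = sigma_a^2 / sigma_e^2 on a log grid over
    [1e-6, 1e6] and refines with Brent's method; the intercept is
    profiled out. Solutions pinned at the lambda bounds are returned
    with ``boundary=True`` (sigma_a2 effectively 0 at the lower bound).
    """
    if not isinstance(grm, GRM):
        grm = GRM(matrix=np.asarray(grm))
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    if grm.n != n:
        raise ValueError("GRM dimension does not match phenotype length")
    d, U = grm.eigen()
    ys = U.T @ y
    cs = U.T @ np.ones(n)

    grid = np.logspace(np.log10(_LAMBDA_BOUNDS[0]), np.log10(_LAMBDA_BOUNDS[1]), 61)
    vals = np.array([_reml_neg2ll(l, d, ys, cs) for l in grid])
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda loglam: _reml_neg2ll(10.0 ** loglam, d, ys, cs),
        bounds=(np.log10(lo), np.log10(hi)), method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise RuntimeError(f"REML line search failed: {res.message}")
    lam = float(10.0 ** res.x)

    w = lam * d + 1.0
    cwc = np.sum(cs * cs / w)
    mu = np.sum(cs * ys / w) / cwc
    r = ys - cs * mu
    sigma_e2 = float(np.sum(r * r / w) / (n - 1))
    sigma_a2 = lam * sigma_e2
    loglik = -0.5 * _reml_neg2ll(lam, d, ys, cs)
    boundary = bool(lam <= _LAMBDA_BOUNDS[0] * 1.01 or lam >= _LAMBDA_BOUNDS[1] * 0.99)
    if boundary and lam <= _LAMBDA_BOUNDS[0] * 1.01:
        sigma_a2 = 0.0
    return VarianceComponents(sigma_a2=sigma_a2, sigma_e2=sigma_e2,
                              loglik=float(loglik), boundary=boundary)


# ---------------------------------------------------------------------------
# GLS marker tests


def _whiten(grm: GRM, lam: float):
    d, U = grm.eigen()
    sw = 1.0 / np.sqrt(lam * d + 1.0)
    return U, sw


def _gls_scan(ys, cs, Xs):
    """Vectorized per-column GLS-with-intercept on whitened data.

    ys, cs: whitened phenotype and intercept (length n); Xs: whitened
    marker columns (n x m). Returns (b, se, t, p) arrays; columns with no
    residual variance after projecting out the intercept get b = 0, p = 1.
    """
    n = ys.size
    cc = cs @ cs
    cy = cs @ ys
    yy = ys @ ys
    xc = cs @ Xs
    xy = ys @ Xs
    xx = np.einsum("ij,ij->j", Xs, Xs)
    xpx = xx - xc * xc / cc
    xpy = xy - xc * cy / cc
    ypy = yy - cy * cy / cc

    degenerate = xpx <= 1e-12 * np.maximum(xx, 1.0)
    xpx_safe = np.where(degenerate, 1.0, xpx)
    b = np.where(degenerate, 0.0, xpy / xpx_safe)
    rss = np.maximum(ypy - b * xpy, 0.0)
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / xpx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        # a perfect fit (se = 0, b != 0) gets t = +-inf and p -> 0
        t = np.where(se > 0, b / se, np.where(b != 0, np.inf * np.sign(b), 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(degenerate, 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
    t = np.where(degenerate, 0.0, t)
    se = np.where(degenerate, np.nan, se)
    return b, se, t, p


def gls_single_marker(y: np.ndarray, x: np.ndarray, grm: GRM | np.ndarray,
                      vc: VarianceComponents):
    """Test one marker by GLS with the variance components held fixed.

    Returns (b, se, t, p_value); with sigma_a2 = 0 the result equals
    ordinary least squares exactly.
    """
    if not isinstance(grm, GRM):
        grm = GRM(matrix=np.asarray(grm))
    lam = vc.sigma_a2 / vc.sigma_e2 if vc.sigma_e2 > 0 else 0.0
    U, sw = _whiten(grm, lam)
    ys = (U.T @ np.asarray(y, dtype=float)) * sw
    cs = (U.T @ np.ones(len(ys))) * sw
    Xs = ((U.T @ np.asarray(x, dtype=float)) * sw)[:, None]
    b, se, t, p = _gls_scan(ys, cs, Xs)
    return float(b[0]), float(se[0]), float(t[0]), float(p[0])


def _natural_chrom_order(chroms) -> list[str]:
    def key(c):
        return (0, int(c)) if str(c).isdigit() else (1, str(c))
    return sorted({str(c) for c in chroms}, key=key)


def run_gwas(genotypes: GenotypeMatrix, y: np.ndarray, loco: bool = True,
             vc_refit: str = "per-chrom") -> pd.DataFrame:
    """Genome scan: per-chromosome LOCO GRM, REML fit, then GLS of its markers.

    ``vc_refit='per-chrom'`` re-estimates the variance components for each
    LOCO GRM (the GRM changes when a chromosome is dropped);
    ``'once'`` estimates them a single time from the all-marker GRM and
    reuses them for every chromosome, the classic EMMAX shortcut.

    Returns a genome-ordered MarkerStats DataFrame with columns
    [marker_id, chrom, pos, freq, beta, se, t, p].
    """
    if vc_refit not in ("per-chrom", "once"):
        raise ValueError("vc_refit must be 'per-chrom' or 'once'")
    y = np.asarray(y, dtype=np.float64)
    if y.size != genotypes.n_individuals:
        raise ValueError("phenotype length does not match genotypes")
    chroms = genotypes.markers["chrom"].astype(str).to_numpy()
    order = _natural_chrom_order(chroms)
    freq = genotypes.allele_freq()

    if loco and len(order) == 1:
        warnings.warn("single chromosome: LOCO falls back to the full GRM")
        loco = False

    vc_once = None
    if not loco or vc_refit == "once":
        grm_full = compute_grm(genotypes)
        vc_once = reml_variance_components(y, grm_full)

    pieces = []
    for chrom in order:
        mask = chroms == chrom
        if loco:
            grm = compute_grm(genotypes, excluded_chrom=chrom)
            vc = vc_once if vc_refit == "once" else reml_variance_components(y, grm)
        else:
            grm = grm_full
            vc = vc_once
        lam = vc.sigma_a2 / vc.sigma_e2 if vc.sigma_e2 > 0 else 0.0
        U, sw = _whiten(grm, lam)
        ys = (U.T @ y) * sw
        cs = (U.T @ np.ones(y.size)) * sw
        Xs = (U.T @ genotypes.dosages[:, mask]) * sw[:, None]
        b, se, t, p = _gls_scan(ys, cs, Xs)
        sub = genotypes.markers.loc[mask, ["marker_id", "chrom", "pos"]].copy()
        sub["freq"] = freq[mask]
        sub["beta"] = b
        sub["se"] = se
        sub["t"] = t
        sub["p"] = p
        pieces.append(sub)

    out = pd.concat(pieces, ignore_index=True)
    out["chrom"] = out["chrom"].astype(str)
    out = out.sort_values(
        ["chrom", "pos"],
        key=lambda s: s.map({c: i for i, c in enumerate(order)}) if s.name == "chrom" else s,
    ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# thresholds, QTL regions, variance explained


def bonferroni_threshold(n_markers: int, alpha: float = 0.05) -> float:
    """Genome-wide significance threshold alpha / n_markers."""
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    return alpha / n_markers


def demarcate_qtl(stats_table: pd.DataFrame, threshold: float,
                  sigma_a2: float | None = None, drop_window: float = 3.0
                  ) -> list[QTLRegion]:
    """Demarcate QTL regions around genome-wide significant top SNPs.

    Repeatedly takes the most significant remaining SNP below
    ``threshold`` and extends its region contiguously up- and downstream
    to include SNPs whose -log10 p stays within ``drop_window`` (default
    3) of the top SNP's; extension stops at the first SNP falling below
    that bound. The region's SNPs are then removed from candidacy. With
    ``sigma_a2`` given, each region reports the fraction of genetic
    variance explained by its top SNP, 2 p q b^2 / sigma_a2.
    """
    df = stats_table.reset_index(drop=True)
    neglog = -np.log10(df["p"].to_numpy())
    chroms = df["chrom"].astype(str).to_numpy()
    pos = df["pos"].to_numpy()
    sig = df["p"].to_numpy() < threshold
    available = sig.copy()
    consumed = np.zeros(len(df), dtype=bool)

    regions: list[QTLRegion] = []
    while available.any():
        top = int(np.flatnonzero(available)[np.argmax(neglog[available])])
        bound = neglog[top] - drop_window
        chrom = chroms[top]
        lo = top
        while lo - 1 >= 0 and chroms[lo - 1] == chrom and not consumed[lo - 1] \
                and neglog[lo - 1] >= bound:
            lo -= 1
        hi = top
        while hi + 1 < len(df) and chroms[hi + 1] == chrom and not consumed[hi + 1] \
                and neglog[hi + 1] >= bound:
            hi += 1
        ve = None
        if sigma_a2 is not None:
            p_f = float(df.loc[top, "freq"])
            ve = variance_explained(p_f, 1.0 - p_f, float(df.loc[top, "beta"]), sigma_a2)
        regions.append(QTLRegion(
            chrom=chrom, start=int(pos[lo]), end=int(pos[hi]),
            top_marker_id=str(df.loc[top, "marker_id"]),
            top_neg_log10_p=float(neglog[top]),
            top_freq=float(df.loc[top, "freq"]),
            top_beta=float(df.loc[top, "beta"]),
            n_markers=hi - lo + 1,
            variance_explained=ve,
        ))
        consumed[lo:hi + 1] = True
        available[lo:hi + 1] = False
    regions.sort(key=lambda r: (_natural_chrom_order(chroms).index(r.chrom), r.start))
    return regions


def variance_explained(p: float, q: float, b: float, sigma_a2: float) -> float:
    """Fraction of additive genetic variance explained by one SNP: 2pqb^2/sigma_a2."""
    if sigma_a2 <= 0:
        raise ValueError("sigma_a2 must be positive")
    if abs(p + q - 1.0) > 1e-8:
        raise ValueError("allele frequencies must satisfy p + q = 1")
    return 2.0 * p * q * b * b / sigma_a2
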