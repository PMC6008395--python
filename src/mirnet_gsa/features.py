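"""Building marker sets (genomic features) from annotations.

A marker set is the unit tested for GWAS-signal enrichment: the ordered
indices of markers falling in some genomic feature — a gene's open
reading frame (ORF), the flanked union of all miRNA precursors, the ORFs
of one miRNA's predicted target genes, or a curated gene set. SNPs are
assigned to genes purely by position: a SNP belongs to a gene when its
coordinate lies between the gene's start and end (1-based inclusive),
and may belong to several overlapping genes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import as_generator

__all__ = [
    "GeneInterval",
    "MarkerSet",
    "TargetNetwork",
    "assign_snps_to_genes",
    "build_mirna_flank_set",
    "build_per_mirna_flank_sets",
    "build_network_marker_set",
    "filter_gene_sets",
    "sample_random_network",
]


@dataclass(frozen=True)
class GeneInterval:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


@dataclass
class MarkerSet:
    """A named genomic feature as ordered marker indices.

    ``marker_indices`` index into the genome-ordered marker table;
    ``m_f`` is the member count entering the sum statistic. ``member_genes``
    lists the gene ids behind the set (empty for interval-only sets).
    A set with no markers is flagged non-testable rather than rejected.
    """

    feature_id: str
    marker_indices: np.ndarray
    member_genes: list[str] = field(default_factory=list)

    def __post_init__(self):
        idx = np.asarray(self.marker_indices, dtype=np.int64)
        if idx.size and not np.all(np.diff(idx) > 0):
            raise ValueError(f"{self.feature_id}: marker indices must be strictly increasing")
        object.__setattr__(self, "marker_indices", idx)

    @property
    def m_f(self) -> int:
        return int(self.marker_indices.size)

    @property
    def testable(self) -> bool:
        return self.m_f >= 1


@dataclass
class TargetNetwork:
    """One miRNA's predicted target-gene set.

    ``quantile_rank`` in [0, 1] ranks the network by prediction score when
    scores are available (1 = best), so that e.g. only the top quartile of
    predicted targets can be retained.
    """

    mirna_id: str
    target_gene_ids: list[str]
    quantile_rank: float = 1.0

    def __post_init__(self):
        if not self.target_gene_ids:
            raise ValueError(f"{self.mirna_id}: empty target network")
        if len(set(self.target_gene_ids)) != len(self.target_gene_ids):
            raise ValueError(f"{self.mirna_id}: duplicated target genes")


def _as_intervals(genes) -> list[GeneInterval]:
    if isinstance(genes, pd.DataFrame):
        id_col = "gene_id" if "gene_id" in genes.columns else "mirna_id"
        return [GeneInterval(str(r[id_col]), str(r["chrom"]), int(r["start"]), int(r["end"]))
                for _, r in genes.iterrows()]
    return list(genes)


def assign_snps_to_genes(markers: pd.DataFrame, genes) -> dict[str, np.ndarray]:
    """Map gene_id -> sorted marker indices inside the gene body (ORF).

    ``markers`` must carry chrom and pos columns in genome order with
    positions sorted within each chromosome. Membership is 1-based
    inclusive on both bounds; a marker in two overlapping genes appears
    in both. Raises ValueError when annotation chromosomes are absent
    from the marker table.
    """
    genes = _as_intervals(genes)
    chroms = markers["chrom"].astype(str).to_numpy()
    pos = markers["pos"].to_numpy()

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        p = pos[idx]
        if np.any(np.diff(p) < 0):
            raise ValueError(f"marker positions not sorted within chromosome {c}")
        by_chrom[c] = (idx, p)

    missing = sorted({g.chrom for g in genes} - set(by_chrom))
    if missing:
        raise ValueError(
            "annotation chromosomes absent from genotype metadata: " + ", ".join(missing)
        )

    out: dict[str, np.ndarray] = {}
    for g in genes:
        idx, p = by_chrom[g.chrom]
        lo = np.searchsorted(p, g.start, side="left")
        hi = np.searchsorted(p, g.end, side="right")
        out[g.gene_id] = idx[lo:hi]
    return out


def build_mirna_flank_set(markers: pd.DataFrame, mirnas, flank_kb: float,
                          feature_id: str | None = None) -> MarkerSet:
    """Combined marker set of all miRNA precursors extended by ±flank_kb.

    Windows are [start - flank, end + flank] clipped at position 1; the
    result is the deduplicated, genome-ordered union over all miRNAs.
    Precursors are short, so at ±0 kb the set may be empty — it is then
    flagged non-testable, not rejected.
    """
    if flank_kb < 0:
        raise ValueError("flank_kb must be >= 0")
    flank = int(round(flank_kb * 1000))
    intervals = _as_intervals(mirnas)
    widened = [GeneInterval(iv.gene_id, iv.chrom, max(1, iv.start - flank), iv.end + flank)
               for iv in intervals]
    assignment = assign_snps_to_genes(markers, widened)
    union = np.unique(np.concatenate([v for v in assignment.values()])) \
        if assignment else np.empty(0, dtype=np.int64)
    name = feature_id if feature_id is not None else f"miRNA_flank_{flank_kb:g}kb"
    return MarkerSet(feature_id=name, marker_indices=union)


def build_per_mirna_flank_sets(markers: pd.DataFrame, mirnas, flank_kb: float
                               ) -> dict[str, MarkerSet]:
    """Per-locus variant of :func:`build_mirna_flank_set` for diagnostics."""
    out = {}
    for iv in _as_intervals(mirnas):
        ms = build_mirna_flank_set(markers, [iv], flank_kb, feature_id=iv.gene_id)
        out[iv.gene_id] = ms
    return out


def build_network_marker_set(network: TargetNetwork,
                             gene_to_markers: dict[str, np.ndarray]) -> MarkerSet:
    """Marker set of one miRNA-target network: union of its targets' ORF SNPs.

    Target genes without any ORF SNP contribute no markers but remain in
    ``member_genes``; a SNP inside two overlapping targets counts once.
    """
    chunks = [gene_to_markers[g] for g in network.target_gene_ids if g in gene_to_markers]
    union = np.unique(np.concatenate(chunks)) if chunks else np.empty(0, dtype=np.int64)
    return MarkerSet(feature_id=network.mirna_id, marker_indices=union,
                     member_genes=list(network.target_gene_ids))


def filter_gene_sets(sets: dict[str, list[str]], min_genes: int = 10) -> dict[str, list[str]]:
    """Keep only gene sets with at least ``min_genes`` member genes."""
    return {name: genes for name, genes in sets.items() if len(genes) >= min_genes}


def sample_random_network(size: int, gene_universe, rng=None) -> list[str]:
    """Uniform without-replacement sample of ``size`` genes from the universe.

    Size-matched random networks are the comparison baseline for observed
    miRNA-target networks.
    """
    universe = list(gene_universe)
    if size > len(universe):
        raise ValueError(f"requested size {size} exceeds universe {len(universe)}")
    rng = as_generator(rng)
    picked = rng.choice(len(universe), size=size, replace=False)
    return [universe[i] for i in sorted(picked)]
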