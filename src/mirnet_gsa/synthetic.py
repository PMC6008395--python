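"""Synthetic cohort generator.

Emulates, at reduced scale, the data structure of a dairy-cattle
sequence-level association study: LD-block-structured genotype dosages
with background relatedness, gene and miRNA (pre-miRNA) annotations,
size-varying miRNA-target networks, polygenic phenotypes whose causal
variants can be concentrated in designated feature sets, and
multi-condition infection expression contrasts with differentially
expressed genes planted inside chosen networks.

Genotypes are built as a mosaic of ancestral haplotypes: each individual
draws two founder haplotypes per LD block, which gives strong within-block
linkage disequilibrium, weak between-block LD, and a realistic genomic
relationship structure without coalescent machinery.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream, as_generator

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "GenotypeMatrix",
    "GenerationError",
    "simulate_annotation",
    "simulate_target_networks",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_expression_contrasts",
]

#: Infection contrast labels used as defaults: LPS liver time-courses (LL*),
#: E. coli liver (LE*) and E. coli mammary (ME*) contrasts.
DEFAULT_CONDITIONS = ("LL3", "LL6", "LL9", "LL12", "LL48", "LE12", "LE24", "ME24")

#: Simulated pre-miRNA lengths (bp), matching the observed precursor range.
MIRNA_LENGTH_RANGE = (52, 148)


class GenerationError(RuntimeError):
    """Raised when a randomized placement cannot satisfy its constraints."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Defaults describe a reduced-scale cohort: 500 animals, 10,000 markers
    on 5 chromosomes, 200 genes, 30 miRNAs, a highly polygenic trait
    (h2 = 0.5, 10% of markers causal) with a 3-fold causal-variance
    enrichment inside designated feature sets.
    """

    n_individuals: int = 500
    n_chromosomes: int = 5
    markers_per_chrom: int = 2000
    marker_spacing_bp: int = 2000
    ld_block_length: int = 5
    n_ancestral_haplotypes: int = 20
    maf_min: float = 0.05
    n_genes: int = 200
    n_mirnas: int = 30
    mean_targets_per_mirna: float = 20.0
    target_size_range: tuple[int, int] = (5, 60)
    h2: float = 0.5
    enrichment_fold: float = 3.0
    enrichment_mode: str = "variance"  # "variance" | "density"
    prop_causal: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError(f"h2 must be in [0, 1], got {self.h2}")
        if self.enrichment_fold < 1.0:
            raise ValueError("enrichment_fold must be >= 1")
        if self.target_size_range[0] < 1:
            raise ValueError("target_size_range min must be >= 1")
        if not (0.0 < self.maf_min < 0.5):
            raise ValueError("maf_min must be in (0, 0.5)")
        if self.enrichment_mode not in ("variance", "density"):
            raise ValueError("enrichment_mode must be 'variance' or 'density'")
        if self.n_ancestral_haplotypes < 2:
            raise ValueError("need at least 2 ancestral haplotypes")

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.markers_per_chrom

    @property
    def chrom_length_bp(self) -> int:
        return self.markers_per_chrom * self.marker_spacing_bp

    def to_dict(self) -> dict:
        d = asdict(self)
        d["target_size_range"] = list(self.target_size_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "target_size_range" in d:
            d["target_size_range"] = tuple(d["target_size_range"])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a simulated quantity.

    Sufficient to score recovery downstream: which markers are causal and
    with what effect, which feature sets carry enriched causal variance,
    and which genes were planted as differentially expressed per condition.
    """

    causal_marker_ids: list[str] = field(default_factory=list)
    true_effects: dict[str, float] = field(default_factory=dict)
    feature_ids_enriched: list[str] = field(default_factory=list)
    de_gene_ids: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix with per-marker metadata.

    ``dosages`` holds allele dosages in [0, 2]; ``markers`` is a DataFrame
    with columns marker_id, chrom, pos sorted in genome order.
    """

    dosages: np.ndarray
    markers: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError("sample count does not match dosage rows")
        if len(self.markers) != m:
            raise ValueError("marker metadata does not match dosage columns")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Per-marker frequency of the counted allele (column mean / 2)."""
        return self.dosages.mean(axis=0) / 2.0

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to marker columns ``keep`` (bool or index)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            dosages=self.dosages[:, keep],
            markers=self.markers.iloc[keep].reset_index(drop=True),
            samples=list(self.samples),
        )


# ---------------------------------------------------------------------------
# annotation


def _place_intervals(n, lengths, chrom_ids, chrom_len, rng, avoid=None,
                     max_tries_per_interval=200):
    """Place n intervals of given lengths on chromosomes without overlap.

    ``avoid``: optional per-chromosome list of (start, end) to keep clear of.
    Returns a list of (chrom, start, end), 1-based inclusive.
    """
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_ids}
    if avoid:
        for c, iv in avoid.items():
            placed.setdefault(c, []).extend(iv)
    out = []
    for i in range(n):
        length = int(lengths[i])
        for _ in range(max_tries_per_interval):
            chrom = chrom_ids[rng.integers(len(chrom_ids))]
            start = int(rng.integers(1, max(2, chrom_len - length)))
            end = start + length - 1
            if all(end < s or start > e for (s, e) in placed[chrom]):
                placed[chrom].append((start, end))
                out.append((chrom, start, end))
                break
        else:
            raise GenerationError(
                f"could not place interval {i + 1}/{n} without overlap; "
                "reduce n_genes/n_mirnas or lengthen chromosomes"
            )
    return out


def simulate_annotation(config: SimulationConfig, rng=None):
    """Simulate gene and pre-miRNA intervals on the synthetic genome.

    Returns (genes, mirnas): DataFrames with columns
    [gene_id|mirna_id, chrom, start, end], 1-based inclusive coordinates.
    Genes are long enough to contain at least one marker on average;
    pre-miRNA lengths are drawn uniformly from the precursor length range
    (52-148 bp), so most contain no marker and flanking windows matter.
    """
    rng = as_generator(rng if rng is not None else substream(config.seed, "annotation"))
    chrom_ids = [str(c + 1) for c in range(config.n_chromosomes)]
    chrom_len = config.chrom_length_bp

    # Gene extents span a few marker spacings (3-7 markers per gene) and are
    # commensurate with the LD-block scale, as gene bodies are on the real genome.
    sp = config.marker_spacing_bp
    gene_lengths = rng.integers(3 * sp, 7 * sp, size=config.n_genes)
    gene_iv = _place_intervals(config.n_genes, gene_lengths, chrom_ids, chrom_len, rng)
    genes = pd.DataFrame(
        [(f"gene{i + 1}", c, s, e) for i, (c, s, e) in enumerate(gene_iv)],
        columns=["gene_id", "chrom", "start", "end"],
    )

    lo, hi = MIRNA_LENGTH_RANGE
    mir_lengths = rng.integers(lo, hi + 1, size=config.n_mirnas)
    mir_iv = _place_intervals(config.n_mirnas, mir_lengths, chrom_ids, chrom_len, rng)
    mirnas = pd.DataFrame(
        [(f"mir{i + 1}", c, s, e) for i, (c, s, e) in enumerate(mir_iv)],
        columns=["mirna_id", "chrom", "start", "end"],
    )
    return genes, mirnas


# ---------------------------------------------------------------------------
# target networks


def simulate_target_networks(mirna_ids, gene_ids, config: SimulationConfig,
                             rng=None) -> dict[str, list[str]]:
    """Draw one target-gene set per miRNA.

    Network sizes come from a scaled Beta distribution on
    ``target_size_range`` whose mean equals ``mean_targets_per_mirna``;
    members are sampled uniformly without replacement from the gene
    universe. Returns {mirna_id: [gene_id, ...]}.
    """
    rng = as_generator(rng if rng is not None else substream(config.seed, "networks"))
    gene_ids = list(gene_ids)
    if not gene_ids:
        raise GenerationError("gene universe is empty")
    lo, hi = config.target_size_range
    if hi > len(gene_ids):
        raise GenerationError(
            f"target_size_range max {hi} exceeds gene universe size {len(gene_ids)}"
        )
    mean = config.mean_targets_per_mirna
    if lo == hi:
        sizes = np.full(len(mirna_ids), lo)
    else:
        if not (lo <= mean <= hi):
            raise GenerationError("mean_targets_per_mirna outside target_size_range")
        mu = (mean - lo) / (hi - lo)
        conc = 2.0  # moderate spread; right-skewed when mean is near the minimum
        a = max(mu * conc, 1e-3)
        b = max((1.0 - mu) * conc, 1e-3)
        u = rng.beta(a, b, size=len(mirna_ids))
        sizes = np.clip(np.rint(lo + u * (hi - lo)).astype(int), lo, hi)
    networks = {}
    for mid, size in zip(mirna_ids, sizes):
        members = rng.choice(len(gene_ids), size=int(size), replace=False)
        networks[str(mid)] = [gene_ids[j] for j in sorted(members)]
    return networks


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(config: SimulationConfig, rng=None) -> GenotypeMatrix:
    """Simulate a mosaic-of-ancestral-haplotypes dosage matrix.

    Each LD block has ``n_ancestral_haplotypes`` founder haplotypes; every
    individual draws two of them per block (independently across blocks).
    Marker columns are rejection-sampled at the founder-allele level until
    the realized minor allele frequency is at least ``maf_min``.
    """
    rng = as_generator(rng if rng is not None else substream(config.seed, "genotypes"))
    n = config.n_individuals
    K = config.n_ancestral_haplotypes
    L = config.ld_block_length
    max_redraws = 1000

    chrom_col, pos_col, blocks = [], [], []
    for c in range(config.n_chromosomes):
        m = config.markers_per_chrom
        for b0 in range(0, m, L):
            blocks.append((c, b0, min(b0 + L, m)))
        chrom_col.extend([str(c + 1)] * m)
        pos_col.extend((np.arange(m) + 1) * config.marker_spacing_bp)

    dosage_blocks = []
    for (_, b0, b1) in blocks:
        blen = b1 - b0
        h1 = rng.integers(K, size=n)
        h2 = rng.integers(K, size=n)
        founders = (rng.random((K, blen)) < rng.uniform(0.1, 0.9, size=blen)).astype(np.int8)
        X = founders[h1] + founders[h2]
        freq = X.mean(axis=0) / 2.0
        bad = np.flatnonzero(np.minimum(freq, 1 - freq) < config.maf_min)
        tries = 0
        while bad.size:
            tries += 1
            if tries > max_redraws:
                raise GenerationError(
                    "could not satisfy maf_min by rejection sampling; "
                    "lower maf_min or raise n_ancestral_haplotypes"
                )
            fcol = (rng.random((K, bad.size)) <
                    rng.uniform(0.1, 0.9, size=bad.size)).astype(np.int8)
            founders[:, bad] = fcol
            Xb = founders[h1][:, bad] + founders[h2][:, bad]
            X[:, bad] = Xb
            f = Xb.mean(axis=0) / 2.0
            bad = bad[np.minimum(f, 1 - f) < config.maf_min]
        dosage_blocks.append(X.astype(np.float64))

    dosages = np.concatenate(dosage_blocks, axis=1)
    markers = pd.DataFrame({
        "marker_id": [f"snp{i + 1}" for i in range(config.n_markers)],
        "chrom": chrom_col,
        "pos": np.asarray(pos_col, dtype=np.int64),
    })
    samples = [f"ind{i + 1}" for i in range(n)]
    return GenotypeMatrix(dosages=dosages, markers=markers, samples=samples)


# ---------------------------------------------------------------------------
# phenotype


def simulate_phenotype(genotypes: GenotypeMatrix, features: dict,
                       config: SimulationConfig, rng=None,
                       truth: SyntheticTruth | None = None):
    """Simulate a polygenic trait with feature-concentrated causal variance.

    ``features`` maps feature_id -> iterable of marker indices designating
    the enriched sets. Under ``enrichment_mode='variance'`` causal markers
    are drawn uniformly and causal effects inside enriched features get
    ``enrichment_fold`` times the baseline effect variance; under
    ``'density'`` causal markers are drawn with ``enrichment_fold``-times
    the sampling weight inside features and share one effect variance
    (``enrichment_fold=inf`` places every causal marker inside the
    features). Causal placement is stratified: the in-feature causal
    count is fixed at its expectation, so the planted enrichment is
    realized in every replicate rather than only on average. Residual
    noise is scaled so the realized genetic fraction of the phenotypic
    variance equals h2 exactly.

    Passing a ``truth`` from a previous call reuses its causal markers
    and effect sizes (matched by marker id) and draws only fresh noise —
    this is how several breed cohorts share one causal architecture.

    Returns (y, truth): phenotype vector aligned to ``genotypes.samples``
    and the recorded :class:`SyntheticTruth`.
    """
    if config.h2 > 0 and config.prop_causal <= 0:
        raise ValueError("h2 > 0 requires prop_causal > 0")
    if not (config.prop_causal <= 1):
        raise ValueError("prop_causal must be <= 1")
    rng = as_generator(rng if rng is not None else substream(config.seed, "effects"))

    m = genotypes.n_markers
    n = genotypes.n_individuals
    marker_ids = genotypes.markers["marker_id"].to_numpy()
    in_feature = np.zeros(m, dtype=bool)
    for idx in features.values():
        in_feature[np.asarray(list(idx), dtype=int)] = True

    noise = rng.standard_normal(n)
    if config.h2 == 0 or config.prop_causal == 0:
        return noise, SyntheticTruth(feature_ids_enriched=list(features))

    if truth is not None:
        id_to_col = {mid: j for j, mid in enumerate(marker_ids)}
        causal = np.array([id_to_col[mid] for mid in truth.causal_marker_ids],
                          dtype=np.int64)
        beta = np.array([truth.true_effects[mid] for mid in truth.causal_marker_ids])
    else:
        causal, beta = _draw_causal(config, m, in_feature, rng)

    g = genotypes.dosages[:, causal] @ beta
    var_g = g.var()
    if var_g <= 0:
        raise GenerationError("causal markers carry no genotypic variance")
    # exact-h2 noise scaling: orthogonalize the noise against the genetic
    # values so the realized variance fractions add, then scale
    target_var_e = var_g * (1.0 - config.h2) / config.h2
    e = noise - noise.mean()
    gc = g - g.mean()
    e = e - gc * (e @ gc) / (gc @ gc)
    e *= np.sqrt(target_var_e / e.var())
    y = g + e

    out_truth = SyntheticTruth(
        causal_marker_ids=[str(marker_ids[j]) for j in causal],
        true_effects={str(marker_ids[j]): float(b) for j, b in zip(causal, beta)},
        feature_ids_enriched=list(features),
    )
    return y, out_truth


def _draw_causal(config: SimulationConfig, m: int, in_feature: np.ndarray, rng):
    """Stratified draw of causal marker columns and their effect sizes."""
    n_causal = int(round(config.prop_causal * m))
    n_causal = max(n_causal, 1)
    inside = np.flatnonzero(in_feature)
    outside = np.flatnonzero(~in_feature)
    fold = config.enrichment_fold
    # Stratified placement: the in-feature causal count is fixed at its
    # expectation (rounded), so the planted enrichment is realized in every
    # replicate rather than only on average.
    if config.enrichment_mode == "density":
        if np.isinf(fold):
            expect_in = float(min(n_causal, inside.size))
        else:
            expect_in = n_causal * fold * inside.size / (
                fold * inside.size + outside.size)
    else:
        expect_in = n_causal * inside.size / m
    n_in = int(np.clip(round(expect_in), max(0, n_causal - outside.size),
                       min(n_causal, inside.size)))
    causal = np.sort(np.concatenate([
        rng.choice(inside, size=n_in, replace=False) if n_in else
        np.empty(0, dtype=np.int64),
        rng.choice(outside, size=n_causal - n_in, replace=False)
        if n_causal - n_in else np.empty(0, dtype=np.int64),
    ]).astype(np.int64))
    if config.enrichment_mode == "density":
        beta = rng.standard_normal(n_causal)
    else:
        sd = np.where(in_feature[causal], np.sqrt(fold), 1.0)
        beta = rng.standard_normal(n_causal) * sd
    return causal, beta


# ---------------------------------------------------------------------------
# expression contrasts


def simulate_expression_contrasts(gene_ids, networks: dict, n_conditions: int,
                                  de_networks, rng=None, *, planted_lfc: float = 2.0,
                                  lfc_se: float = 0.5, p_condition: float = 0.5,
                                  p_gene: float = 0.7, condition_labels=None):
    """Simulate per-condition differential-expression contrasts.

    A fraction ``p_gene`` of each network in ``de_networks`` is planted as
    differentially expressed (infected networks respond through most but
    not all of their targets, leaving a non-DE remainder in every
    network). Each planted gene picks a regulation sign once (consistent
    across its DE conditions), is nominally DE in each condition with
    probability ``p_condition`` (re-drawn until at least two conditions),
    and in those conditions receives |log2FC| near ``planted_lfc``. All
    other genes get
    null statistics (log2FC ~ N(0, lfc_se^2), uniform p). Benjamini-
    Hochberg FDR is computed within each condition.

    Returns (contrasts, truth): a tidy DataFrame with columns
    [gene_id, condition, log2_fc, p_value, fdr] and the planted truth.
    """
    if n_conditions < 2:
        raise ValueError("need at least 2 conditions to define DETs")
    unknown = set(de_networks) - set(networks)
    if unknown:
        raise ValueError(f"de_networks not in networks: {sorted(unknown)}")
    rng = as_generator(rng)

    gene_ids = [str(g) for g in gene_ids]
    if condition_labels is None:
        if n_conditions <= len(DEFAULT_CONDITIONS):
            condition_labels = list(DEFAULT_CONDITIONS[:n_conditions])
        else:
            condition_labels = [f"C{i + 1}" for i in range(n_conditions)]

    if not (0.0 < p_gene <= 1.0):
        raise ValueError("p_gene must be in (0, 1]")
    planted_set: set[str] = set()
    for net in sorted(de_networks):
        members = sorted(networks[net])
        k = max(1, int(round(p_gene * len(members))))
        picked = rng.choice(len(members), size=k, replace=False)
        planted_set.update(members[i] for i in picked)
    planted = sorted(planted_set)
    signs = {g: (1.0 if rng.random() < 0.5 else -1.0) for g in planted}
    # per-gene DE-condition mask, conditioned on >= 2 conditions
    de_mask = {}
    for g in planted:
        while True:
            mask = rng.random(n_conditions) < p_condition
            if mask.sum() >= 2:
                break
        de_mask[g] = mask

    rows = []
    truth_de: dict[str, list[str]] = {c: [] for c in condition_labels}
    for ci, cond in enumerate(condition_labels):
        for g in gene_ids:
            if g in planted_set and de_mask[g][ci]:
                z = (planted_lfc + rng.normal(0, lfc_se)) / lfc_se
                z = max(z, 0.1)  # keep the planted sign
                lfc = signs[g] * z * lfc_se
                p = 2.0 * stats.norm.sf(abs(z))
                truth_de[cond].append(g)
            else:
                z = rng.standard_normal()
                lfc = z * lfc_se
                p = 2.0 * stats.norm.sf(abs(z))
            rows.append((g, cond, lfc, p))
    contrasts = pd.DataFrame(rows, columns=["gene_id", "condition", "log2_fc", "p_value"])

    from statsmodels.stats.multitest import multipletests
    fdr = np.empty(len(contrasts))
    for cond in condition_labels:
        mask = (contrasts["condition"] == cond).to_numpy()
        fdr[mask] = multipletests(contrasts.loc[mask, "p_value"], method="fdr_bh")[1]
    contrasts["fdr"] = fdr

    truth = SyntheticTruth(de_gene_ids=truth_de,
                           feature_ids_enriched=sorted(de_networks))
    return contrasts, truth
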