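"""Interchange-format readers and writers.

Genotypes travel as VCF (DS dosage field preferred, GT fallback) or as a
TSV dosage matrix (markers x individuals behind four metadata columns);
annotations as GFF3 (feature types ``gene`` and ``pre_miRNA``) or BED;
gene sets and target networks as GMT; phenotypes, expression contrasts
and all reports as #-commented TSV. All writers emit deterministic row
and column order, and report writers prepend ``# key: value`` header
lines so every output records the configuration that produced it.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import GenotypeMatrix

__all__ = [
    "read_genotypes", "write_genotypes_vcf", "write_genotypes_tsv",
    "read_annotation_gff3", "write_annotation_gff3",
    "read_annotation_bed", "write_annotation_bed",
    "read_gene_sets", "write_gene_sets", "read_target_networks",
    "read_phenotypes", "write_phenotypes",
    "read_contrasts", "write_contrasts",
    "write_table", "read_table",
    "read_config", "write_config",
]

_GT_CODES = {0: "0/0", 1: "0/1", 2: "1/1"}


def _natural_key(c: str):
    return (0, int(c)) if str(c).isdigit() else (1, str(c))


# ---------------------------------------------------------------------------
# genotypes


def write_genotypes_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write dosages as a minimal VCF 4.2 with GT (rounded) and DS fields."""
    path = Path(path)
    chroms = sorted(set(genotypes.markers["chrom"].astype(str)), key=_natural_key)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT allele">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.samples) + "\n")
        D = genotypes.dosages
        for j, row in genotypes.markers.iterrows():
            calls = np.clip(np.floor(D[:, j] + 0.5).astype(int), 0, 2)
            cells = [f"{_GT_CODES[c]}:{d:g}" for c, d in zip(calls, D[:, j])]
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['marker_id']}\tA\tC\t.\t.\t.\t"
                     "GT:DS\t" + "\t".join(cells) + "\n")


def _read_genotypes_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, cols = [], [], [], []
    n_skipped = n_total = 0
    for rec in vcf:
        n_total += 1
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=np.float64).ravel()
        else:
            gts = rec.genotypes
            try:
                col = np.array([a + b for (a, b, *_) in gts], dtype=np.float64)
            except TypeError:
                n_skipped += 1
                continue
        if np.any(~np.isfinite(col)) or np.any(col < 0) or np.any(col > 2):
            n_skipped += 1
            continue
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        chroms.append(str(rec.CHROM))
        poss.append(int(rec.POS))
        cols.append(col)
    if n_total and n_skipped / n_total > 0.10:
        raise ValueError(f"{n_skipped}/{n_total} VCF records unusable (>10%)")
    if n_skipped:
        warnings.warn(f"skipped {n_skipped}/{n_total} VCF records")
    markers = pd.DataFrame({"marker_id": ids, "chrom": chroms, "pos": poss})
    return _sorted_genotypes(np.column_stack(cols), markers, samples)


def _sorted_genotypes(dosages, markers, samples) -> GenotypeMatrix:
    order = sorted(range(len(markers)),
                   key=lambda i: (_natural_key(markers["chrom"].iat[i]),
                                  markers["pos"].iat[i]))
    markers = markers.iloc[order].reset_index(drop=True)
    dup = markers.duplicated(["chrom", "pos"])
    if dup.any():
        warnings.warn(f"{int(dup.sum())} duplicate marker positions")
    return GenotypeMatrix(dosages=dosages[:, order], markers=markers,
                          samples=list(samples))


def write_genotypes_tsv(genotypes: GenotypeMatrix, path) -> None:
    """Markers x individuals dosage TSV with 4 metadata columns."""
    freq = genotypes.allele_freq()
    meta = genotypes.markers.copy()
    meta["ref_allele_freq"] = 1.0 - freq
    body = pd.DataFrame(genotypes.dosages.T, columns=genotypes.samples)
    pd.concat([meta.reset_index(drop=True), body], axis=1).to_csv(
        path, sep="\t", index=False)


def _read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["marker_id", "chrom", "pos", "ref_allele_freq"]
    missing = set(meta_cols) - set(df.columns)
    if missing:
        raise ValueError(f"dosage TSV lacks metadata columns {sorted(missing)}")
    samples = [c for c in df.columns if c not in meta_cols]
    dosages = df[samples].to_numpy(dtype=np.float64).T
    markers = df[["marker_id", "chrom", "pos"]].copy()
    return _sorted_genotypes(dosages, markers, samples)


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    """Read genotypes from VCF or dosage TSV (inferred from the suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() in (".vcf", ".gz", ".bcf") else "tsv"
    if fmt == "vcf":
        return _read_genotypes_vcf(path)
    if fmt == "tsv":
        return _read_genotypes_tsv(path)
    raise ValueError("fmt must be 'vcf' or 'tsv'")


# ---------------------------------------------------------------------------
# annotations


def write_annotation_gff3(genes: pd.DataFrame, mirnas: pd.DataFrame, path) -> None:
    """Write gene and pre-miRNA intervals as GFF3 (1-based inclusive)."""
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for df, ftype, idcol in ((genes, "gene", "gene_id"),
                                 (mirnas, "pre_miRNA", "mirna_id")):
            if df is None or df.empty:
                continue
            for _, r in df.iterrows():
                fh.write(f"{r['chrom']}\tmirnet_gsa\t{ftype}\t{r['start']}\t{r['end']}"
                         f"\t.\t+\t.\tID={r[idcol]}\n")


def read_annotation_gff3(path):
    """Read (genes, mirnas) DataFrames back from GFF3.

    Uses pyranges (0-based half-open internally) and converts to 1-based
    inclusive coordinates.
    """
    import pyranges as pr

    df = pr.read_gff3(str(path)).df
    df["start"] = df["Start"] + 1
    df["end"] = df["End"]
    df["chrom"] = df["Chromosome"].astype(str)
    genes = df[df["Feature"] == "gene"][["ID", "chrom", "start", "end"]] \
        .rename(columns={"ID": "gene_id"}).reset_index(drop=True)
    mirnas = df[df["Feature"] == "pre_miRNA"][["ID", "chrom", "start", "end"]] \
        .rename(columns={"ID": "mirna_id"}).reset_index(drop=True)
    return genes, mirnas


def write_annotation_bed(intervals: pd.DataFrame, path, id_col: str = "gene_id") -> None:
    """Write intervals as BED (0-based half-open on disk)."""
    with Path(path).open("w") as fh:
        for _, r in intervals.iterrows():
            fh.write(f"{r['chrom']}\t{r['start'] - 1}\t{r['end']}\t{r[id_col]}\n")


def read_annotation_bed(path, id_col: str = "gene_id") -> pd.DataFrame:
    """Read BED intervals, converting to 1-based inclusive coordinates."""
    import pyranges as pr

    df = pr.read_bed(str(path)).df
    out = pd.DataFrame({
        id_col: df["Name"] if "Name" in df.columns else
        [f"iv{i + 1}" for i in range(len(df))],
        "chrom": df["Chromosome"].astype(str),
        "start": df["Start"] + 1,
        "end": df["End"],
    })
    return out


# ---------------------------------------------------------------------------
# gene sets / networks (GMT)


def read_gene_sets(path) -> dict[str, list[str]]:
    """Read a GMT file into {set_name: [genes...]}.

    Duplicate genes within a set are deduplicated with a warning; empty
    sets are dropped with a warning; duplicate set names are an error.
    """
    out: dict[str, list[str]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 2 tab fields")
            name, _desc, *genes = fields if len(fields) >= 3 else (*fields, )
            if name in out:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = [g for g in genes if g]
            uniq = list(dict.fromkeys(genes))
            if len(uniq) < len(genes):
                warnings.warn(f"set {name!r}: duplicated genes deduplicated")
            if not uniq:
                warnings.warn(f"set {name!r} is empty and was dropped")
                continue
            out[name] = uniq
    return out


def write_gene_sets(sets: dict[str, list[str]], path,
                    descriptions: dict[str, str] | None = None) -> None:
    with Path(path).open("w") as fh:
        for name in sets:
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sets[name]]) + "\n")


def read_target_networks(path, top_quantile: float | None = None):
    """Read miRNA target networks from GMT, optionally keeping top scorers.

    A numeric ``score=<x>`` in the description field ranks networks by
    prediction confidence; with ``top_quantile`` (e.g. 0.25) only
    networks in the top quantile of the score distribution are kept.
    Without scores all networks pass. Returns a list of
    :class:`~mirnet_gsa.features.TargetNetwork`.
    """
    from .features import TargetNetwork

    raw = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            name, desc, *genes = line.split("\t")
            score = None
            if desc.startswith("score="):
                score = float(desc.split("=", 1)[1])
            raw.append((name, score, [g for g in dict.fromkeys(genes) if g]))
    scores = [s for _, s, _ in raw if s is not None]
    nets = []
    if top_quantile is not None and scores:
        cutoff = float(np.quantile(scores, 1.0 - top_quantile))
    else:
        cutoff = None
    for name, score, genes in raw:
        if not genes:
            continue
        rank = 1.0
        if score is not None and len(scores) > 1:
            rank = float(np.mean([score >= s for s in scores]))
        if cutoff is not None and score is not None and score < cutoff:
            continue
        nets.append(TargetNetwork(mirna_id=name, target_gene_ids=genes,
                                  quantile_rank=rank))
    return nets


# ---------------------------------------------------------------------------
# phenotypes, contrasts, generic tables


def write_phenotypes(samples, y, trait: str, path, header_meta=None) -> None:
    df = pd.DataFrame({"individual_id": samples, "trait": trait, "value": y})
    write_table(df, path, header_meta)


def read_phenotypes(path, trait: str | None = None) -> pd.DataFrame:
    df = read_table(path)
    if trait is not None:
        df = df[df["trait"] == trait].reset_index(drop=True)
    if df["individual_id"].duplicated().any():
        raise ValueError("duplicate individual ids in phenotype table")
    return df


def write_contrasts(contrasts: pd.DataFrame, path, header_meta=None) -> None:
    write_table(contrasts, path, header_meta)


def read_contrasts(path) -> pd.DataFrame:
    df = read_table(path)
    need = {"gene_id", "condition", "log2_fc", "fdr"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"contrast table lacks columns {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path, header_meta: dict | None = None) -> None:
    """Write a report TSV with optional ``# key: value`` header lines."""
    path = Path(path)
    with path.open("w") as fh:
        for k, v in (header_meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("chrom", "condition", "gene_id", "feature_id", "individual_id"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    return df


# ---------------------------------------------------------------------------
# config


def read_config(path) -> dict:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
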