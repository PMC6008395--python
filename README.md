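# mirnet-gsa

**miRNA-target-network guided prioritization of GWAS signals.**

Single-marker genome-wide association studies of complex traits in dairy
cattle (milk yield, fat yield, protein yield, mastitis, ...) detect only a
handful of large-effect QTL and leave most of the genomic variance
unexplained. `mirnet-gsa` implements the complementary *marker-set*
strategy: group SNPs into biologically defined genomic features — the
flanked positions of miRNA genes, the open reading frames of one miRNA's
predicted target genes (a *miRNA-target network*), or curated gene sets —
and test whether a feature as a whole is enriched with association
signal, even when no single SNP reaches genome-wide significance. It is
aimed at quantitative geneticists working with livestock (or any
diploid) cohorts with dense genotypes and quantitative phenotypes such
as de-regressed proofs (DRPs).

## The model and the test

**Step 1 — variance components (REML).** The polygenic null model is

```
y = 1μ + a + e,   a ~ N(0, G σ²ₐ),   e ~ N(0, I σ²ₑ)
```

with `G` a VanRaden genomic relationship matrix built *excluding the
chromosome of the candidate SNP* (leave-one-chromosome-out), so the
tested marker does not enter its own covariance.

**Step 2 — single-marker GLS (EMMAX-style).** Each marker is tested by

```
y = 1μ + x b + η,   Var(η) = G σ²ₐ + I σ²ₑ
```

with the variance components held fixed, giving per-SNP `t = b / se`.

**Marker-set test.** For a feature *f* with `m_f` member SNPs,

```
T_sum = Σ_{i∈f} t²ᵢ
```

Its null distribution comes from **cyclical permutation**: the
genome-ordered vector of t² values is rotated by a random offset
(uniform over the m−1 non-identity rotations), which detaches SNPs from
features while preserving the local LD-induced correlation of
neighbouring statistics; the empirical p is the add-one proportion of
rotated `T_sum` values at least as large as the observed one.

Downstream, the package (i) correlates per-feature enrichments
(−log₁₀ p) between traits and breeds and judges each correlation against
a null of 1,000 random size-matched networks under a normal
approximation, (ii) calls a network *significant* when p < 0.05 in every
breed (joint level 0.05³ = 1.25 × 10⁻⁴ at three breeds), and
(iii) integrates infection expression contrasts: targets differentially
expressed in ≥ 2 conditions (DETs) are split from non-DETs and by
up/down regulation, and their GWAS enrichments compared.

A first-class synthetic-data module generates LD-block genotypes with
relatedness, polygenic phenotypes with causal variants concentrated in
designated features, annotations, target networks and expression
contrasts — so the whole pipeline is testable without any external data.

## Worked example

```python
import numpy as np
from mirnet_gsa.synthetic import (SimulationConfig, simulate_genotypes,
                                  simulate_annotation, simulate_target_networks,
                                  simulate_phenotype)
from mirnet_gsa.features import (assign_snps_to_genes, build_network_marker_set,
                                 TargetNetwork)
from mirnet_gsa.gwas import run_gwas, bonferroni_threshold
from mirnet_gsa.settest import test_feature_sets

cfg = SimulationConfig(seed=11, n_individuals=500, markers_per_chrom=250,
                       n_genes=60, n_mirnas=1, mean_targets_per_mirna=45,
                       target_size_range=(45, 45), h2=0.5,
                       enrichment_fold=5.0, prop_causal=0.12)
geno = simulate_genotypes(cfg)                      # 500 x 1250 dosages
genes, mirnas = simulate_annotation(cfg)
g2m = assign_snps_to_genes(geno.markers, genes)
net = simulate_target_networks(["mir-x"], genes["gene_id"], cfg)
ms = build_network_marker_set(TargetNetwork("mir-x", net["mir-x"]), g2m)
y, truth = simulate_phenotype(geno, {"mir-x": ms.marker_indices}, cfg)

scan = run_gwas(geno, y)                            # LOCO mixed-model scan
res = test_feature_sets(scan, {"mir-x": ms}, n_perm=1000,
                        rng=np.random.default_rng(11))
print(res[["feature_id", "m_f", "t_sum", "p", "neg_log10_p"]].to_string(index=False))
print(f"genome-wide threshold: {bonferroni_threshold(len(scan)):.2e}")
```

Output:

```
feature_id  m_f      t_sum        p  neg_log10_p
     mir-x  234 353.953702 0.036963     1.432232
genome-wide threshold: 4.00e-05
```

The planted network holds 234 of the 1,250 markers but carries a 5-fold
enriched share of the causal variance. Its observed `T_sum` = 354 sits
in the upper tail of the 1,000 rotation nulls (whose mean is near the
genome average of t² times `m_f`, ≈ 250): 36 rotations reach it, so the
empirical p is (1+36)/1001 ≈ 0.037 and the feature is called enriched at
the 0.05 level — even though no single SNP in this highly polygenic
trait comes near the genome-wide threshold.

The same stages are exposed on the command line
(`mirnet-gsa simulate|qc|gwas|settest|correlate|integrate|run`); see
`mirnet-gsa --help`.

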