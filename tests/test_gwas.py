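"""Mixed-model association: QC, GRM, REML, GLS, thresholds, QTL regions."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirnet_gsa.synthetic import SimulationConfig, GenotypeMatrix, \
    simulate_genotypes, simulate_phenotype
from mirnet_gsa.gwas import (
    GRM, VarianceComponents, qc_filter, hwe_chi2_pvalues, compute_grm,
    reml_variance_components, gls_single_marker, run_gwas,
    bonferroni_threshold, demarcate_qtl, variance_explained,
)


def _geno_from_columns(cols, chroms=None):
    cols = np.asarray(cols, dtype=float)
    n, m = cols.shape
    markers = pd.DataFrame({
        "marker_id": [f"s{j}" for j in range(m)],
        "chrom": chroms if chroms is not None else ["1"] * m,
        "pos": (np.arange(m) + 1) * 1000,
    })
    return GenotypeMatrix(cols, markers, [f"i{k}" for k in range(n)])


class TestQC:
    def test_rare_marker_removed_at_maf_boundary(self):
        n = 1000
        col_rare = np.zeros(n)
        col_rare[:18] = 1.0  # MAF 0.009
        col_ok = np.tile([0.0, 1.0, 2.0, 1.0], n // 4)
        geno = _geno_from_columns(np.column_stack([col_rare, col_ok]))
        kept = qc_filter(geno, maf_min=0.01)
        assert kept.markers["marker_id"].tolist() == ["s1"]

    def test_perfect_hwp_retained(self):
        col = np.repeat([0.0, 1.0, 2.0], [25, 50, 25])
        p = hwe_chi2_pvalues(col[:, None])
        assert p[0] == pytest.approx(1.0)

    def test_extreme_heterozygote_deficit_removed(self):
        col = np.repeat([0.0, 2.0], [50, 50])  # chi-square = 100
        chi2 = 100.0
        assert hwe_chi2_pvalues(col[:, None])[0] == pytest.approx(
            stats.chi2.sf(chi2, 1))
        geno = _geno_from_columns(
            np.column_stack([col, np.tile([0.0, 1, 2, 1], 25)]))
        kept = qc_filter(geno)
        assert kept.markers["marker_id"].tolist() == ["s1"]

    def test_all_removed_is_an_error(self):
        geno = _geno_from_columns(np.zeros((100, 2)))
        with pytest.raises(ValueError):
            qc_filter(geno)


class TestGRM:
    def test_identical_individuals_have_self_relationship(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 3, size=20).astype(float)
        cols = np.vstack([base, base, rng.integers(0, 3, size=20)])
        grm = compute_grm(_geno_from_columns(cols))
        assert grm.matrix[0, 1] == pytest.approx(grm.matrix[0, 0])

    def test_trace_near_one_for_unrelated(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.1, 0.9, size=2000)
        cols = rng.binomial(2, p, size=(200, 2000)).astype(float)
        grm = compute_grm(_geno_from_columns(cols))
        assert abs(np.trace(grm.matrix) / 200 - 1.0) < 0.1

    def test_loco_matches_brute_force_recomputation(self, small_cohort):
        geno = small_cohort["genotypes"]
        grm = compute_grm(geno, excluded_chrom="2")
        keep = geno.markers["chrom"] != "2"
        sub = geno.subset_markers(keep.to_numpy())
        brute = compute_grm(sub)
        np.testing.assert_allclose(grm.matrix, brute.matrix, atol=1e-12)

    def test_monomorphic_only_is_an_error(self):
        with pytest.raises(ValueError):
            compute_grm(_geno_from_columns(np.full((50, 3), 2.0)))


class TestREML:
    def _related_grm(self, seed=2):
        # deeply related cohort (few founder haplotypes, long shared
        # segments) -> an informative GRM, as in an intensely selected
        # livestock population
        cfg = SimulationConfig(seed=seed, n_individuals=500, n_chromosomes=3,
                               markers_per_chrom=500,
                               n_ancestral_haplotypes=4, ld_block_length=50)
        return compute_grm(simulate_genotypes(cfg))

    def test_null_trait_estimates_near_zero_h2(self):
        grm = self._related_grm()
        rng = np.random.default_rng(3)
        small = sum(reml_variance_components(
            rng.standard_normal(500), grm).h2 < 0.05 for _ in range(100))
        assert small >= 95

    def test_h2_recovery_with_genetic_signal(self):
        grm = self._related_grm()
        d, U = grm.eigen()
        L = U * np.sqrt(d)
        rng = np.random.default_rng(4)
        h2s = []
        for _ in range(50):
            a = L @ rng.standard_normal(500)
            e = rng.standard_normal(500)
            e *= np.sqrt(a.var() / e.var())  # equal parts -> true h2 = 0.5
            h2s.append(reml_variance_components(a + e, grm).h2)
        assert 0.45 < np.mean(h2s) < 0.55

    def test_identity_kinship_matches_dense_oracle_loglik(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal(80)
        vc = reml_variance_components(y, np.eye(80))
        # dense REML log-likelihood at the returned (sigma_a2, sigma_e2)
        n = 80
        H = vc.lam * np.eye(n) + np.eye(n)
        X = np.ones((n, 1))
        Hi = np.linalg.inv(H)
        mu = (X.T @ Hi @ y).item() / (X.T @ Hi @ X).item()
        rss = ((y - mu) @ Hi @ (y - mu)).item()
        se2 = rss / (n - 1)
        ll = -0.5 * ((n - 1) * (np.log(2 * np.pi * se2) + 1)
                     + np.linalg.slogdet(H)[1]
                     + np.log((X.T @ Hi @ X).item()))
        assert vc.loglik == pytest.approx(ll, rel=1e-10)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reml_variance_components(np.zeros(10), np.eye(5))


class TestGLS:
    def test_identity_covariance_equals_ols(self):
        rng = np.random.default_rng(6)
        x = rng.integers(0, 3, size=60).astype(float)
        y = 0.3 * x + rng.standard_normal(60)
        vc = VarianceComponents(sigma_a2=0.0, sigma_e2=1.0, loglik=0.0)
        b, se, t, p = gls_single_marker(y, x, GRM(np.eye(60)), vc)
        lm = stats.linregress(x, y)
        assert b == pytest.approx(lm.slope, abs=1e-10)
        assert se == pytest.approx(lm.stderr, abs=1e-10)

    def test_perfect_fit_recovers_slope_with_vanishing_p(self):
        x = np.array([0.0, 1, 2, 0, 1, 2, 1, 0])
        vc = VarianceComponents(0.0, 1.0, 0.0)
        b, se, t, p = gls_single_marker(2 * x, x, GRM(np.eye(8)), vc)
        assert b == pytest.approx(2.0) and p < 1e-200

    def test_matches_dense_gls_oracle(self):
        rng = np.random.default_rng(7)
        n = 50
        A = rng.standard_normal((n, 5))
        G = A @ A.T / 5 + np.eye(n) * 0.1
        vc = VarianceComponents(sigma_a2=0.7, sigma_e2=1.3, loglik=0.0)
        V = vc.sigma_a2 * G + vc.sigma_e2 * np.eye(n)
        x = rng.integers(0, 3, size=n).astype(float)
        y = 0.5 * x + rng.standard_normal(n)
        b, se, t, p = gls_single_marker(y, x, GRM(G), vc)
        # brute force: whiten by explicit V^{-1/2} scaled to unit residual var
        Vn = V / vc.sigma_e2
        d, U = np.linalg.eigh(Vn)
        W = U @ np.diag(d ** -0.5) @ U.T
        X = W @ np.column_stack([np.ones(n), x])
        yw = W @ y
        coef, *_ = np.linalg.lstsq(X, yw, rcond=None)
        resid = yw - X @ coef
        cov = (resid @ resid / (n - 2)) * np.linalg.inv(X.T @ X)
        assert b == pytest.approx(coef[1], abs=1e-10)
        assert se == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-10)

    def test_monomorphic_marker_flagged(self):
        vc = VarianceComponents(0.0, 1.0, 0.0)
        b, se, t, p = gls_single_marker(np.arange(10.0), np.full(10, 2.0),
                                        GRM(np.eye(10)), vc)
        assert (b, p) == (0.0, 1.0) and np.isnan(se)


class TestRunGwas:
    def test_planted_large_effect_maps_to_causal_block(self):
        cfg = SimulationConfig(seed=21, n_individuals=300, n_chromosomes=2,
                               markers_per_chrom=200)
        geno = simulate_genotypes(cfg)
        rng = np.random.default_rng(21)
        causal = 137
        y = 2.0 * geno.dosages[:, causal] + rng.standard_normal(300)
        res = run_gwas(geno, y)
        top = res["p"].idxmin()
        # top hit inside the causal marker's 5-marker LD block
        assert abs(top - causal) < 5

    def test_single_chromosome_loco_falls_back_to_full_grm(self):
        cfg = SimulationConfig(seed=22, n_individuals=120, n_chromosomes=1,
                               markers_per_chrom=150)
        geno = simulate_genotypes(cfg)
        y = np.random.default_rng(22).standard_normal(120)
        with pytest.warns(UserWarning, match="single chromosome"):
            a = run_gwas(geno, y, loco=True)
        b = run_gwas(geno, y, loco=False)
        pd.testing.assert_frame_equal(a, b)

    def test_null_scan_is_calibrated(self):
        cfg = SimulationConfig(seed=23, n_individuals=300, markers_per_chrom=400)
        geno = simulate_genotypes(cfg)
        y = np.random.default_rng(23).standard_normal(300)
        res = run_gwas(geno, y)
        p = res["p"].to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01
        lam = np.median(stats.chi2.isf(p, 1)) / stats.chi2.isf(0.5, 1)
        assert 0.9 < lam < 1.1


class TestThresholdsAndQtl:
    @pytest.mark.parametrize("n,expected", [
        (13_403_916, 3.7e-9), (15_355_382, 3.3e-9), (1, 0.05),
    ])
    def test_bonferroni_reproduces_printed_thresholds(self, n, expected):
        assert bonferroni_threshold(n) == pytest.approx(expected, rel=0.02)

    def _table(self, neglogp, chroms=None, pos=None):
        m = len(neglogp)
        return pd.DataFrame({
            "marker_id": [f"s{i}" for i in range(m)],
            "chrom": chroms if chroms is not None else ["1"] * m,
            "pos": pos if pos is not None else (np.arange(m) + 1) * 1000,
            "freq": 0.5, "beta": 1.0, "se": 0.5, "t": 2.0,
            "p": 10.0 ** (-np.asarray(neglogp)),
        })

    def test_drop_window_boundary_hand_example(self):
        # top -log10 p = 10 -> boundary 7; upstream 8, 7.5 included;
        # downstream 6.9 stops the extension immediately
        tbl = self._table([1.0, 7.5, 8.0, 10.0, 6.9, 8.0])
        regions = demarcate_qtl(tbl, threshold=5e-8)
        r = regions[0]
        assert (r.start, r.end) == (2000, 4000)
        assert r.n_markers == 3 and r.top_marker_id == "s3"
        # the second significant SNP (s5) seeds its own region downstream
        assert len(regions) == 2 and regions[1].top_marker_id == "s5"

    def test_isolated_snp_gives_zero_width_region(self):
        tbl = self._table([1.0, 9.0, 1.0])
        regions = demarcate_qtl(tbl, threshold=1e-8)
        assert len(regions) == 1
        assert regions[0].start == regions[0].end == 2000

    def test_two_chromosomes_give_two_regions(self):
        tbl = self._table([9.0, 1.0, 1.0, 9.5], chroms=["1", "1", "2", "2"],
                          pos=[1000, 2000, 1000, 2000])
        regions = demarcate_qtl(tbl, threshold=1e-8)
        assert len(regions) == 2
        assert {r.chrom for r in regions} == {"1", "2"}

    def test_no_significant_snps_gives_empty_list(self):
        assert demarcate_qtl(self._table([1.0, 2.0]), threshold=1e-8) == []

    @pytest.mark.parametrize("p,q,b,s2,expected", [
        (0.5, 0.5, 1.0, 1.0, 0.5),
        (0.5, 0.5, 0.0, 1.0, 0.0),
        (0.2, 0.8, 0.5, 0.4, 0.2),
    ])
    def test_variance_explained_formula(self, p, q, b, s2, expected):
        assert variance_explained(p, q, b, s2) == pytest.approx(expected)

    def test_variance_explained_input_validation(self):
        with pytest.raises(ValueError):
            variance_explained(0.5, 0.5, 1.0, 0.0)
        with pytest.raises(ValueError):
            variance_explained(0.5, 0.4, 1.0, 1.0)
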