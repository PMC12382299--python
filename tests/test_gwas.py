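import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _simtools import founder_panel, hybrid_frame, hybrid_means
from testcross_gwas.gwas import (_scan_one_trait, gwas_scan, marker_pca,
                                 naive_gls_scan, vanraden_grm)


class TestGRM:
    def test_two_individual_hand_example(self):
        d = pd.DataFrame({"m1": [0.0, 2.0]}, index=["a", "b"])
        g = vanraden_grm(d)
        # p = 0.5, M = (-1, 1), denominator = 2 * 0.25 = 0.5
        assert np.allclose(g.matrix.to_numpy(), [[2, -2], [-2, 2]])
        assert g.denominator == pytest.approx(0.5)

    def test_rows_sum_to_zero(self, small_bundle):
        g = vanraden_grm(small_bundle["geno"].dosages)
        assert np.allclose(g.matrix.sum(axis=1), 0.0, atol=1e-9)

    def test_duplicated_individual_identical_rows(self):
        rng = np.random.default_rng(3)
        d = pd.DataFrame(rng.choice([0.0, 2.0], size=(5, 30)),
                         index=[f"L{i}" for i in range(5)])
        d.loc["L4"] = d.loc["L0"]
        g = vanraden_grm(d).matrix.to_numpy()
        assert np.allclose(g[0], g[4]) and np.allclose(g[:, 0], g[:, 4])

    def test_monomorphic_markers_excluded(self):
        d = pd.DataFrame({"m1": [0.0, 2.0], "m2": [2.0, 2.0]}, index=["a", "b"])
        g = vanraden_grm(d)
        assert g.excluded_monomorphic == ["m2"]
        assert g.denominator == pytest.approx(0.5)  # m2 contributes nothing

    def test_missing_rejected(self):
        d = pd.DataFrame({"m1": [0.0, np.nan]}, index=["a", "b"])
        with pytest.raises(ValueError, match="impute"):
            vanraden_grm(d)


class TestPCA:
    def test_two_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(1)
        a = rng.choice([0.0, 2.0], size=40)
        b = rng.choice([0.0, 2.0], size=40)
        d = pd.DataFrame([a] * 4 + [b] * 4, index=[f"L{i}" for i in range(8)])
        scores = marker_pca(d, k=2)
        pc1 = scores["PC1"]
        assert pc1[:4].std() < 1e-8 and pc1[4:].std() < 1e-8
        assert abs(pc1.iloc[0] - pc1.iloc[-1]) > 1.0

    def test_scores_orthogonal(self, small_bundle):
        s = marker_pca(small_bundle["geno"].dosages, k=3).to_numpy()
        gram = s.T @ s
        off = gram - np.diag(np.diag(gram))
        assert np.all(np.abs(off) < 1e-6 * np.max(np.diag(gram)))

    def test_k_zero_empty(self, small_bundle):
        assert marker_pca(small_bundle["geno"].dosages, k=0).shape[1] == 0

    def test_k_too_large_errors(self):
        d = pd.DataFrame(np.zeros((3, 5)), index=list("abc"))
        with pytest.raises(ValueError):
            marker_pca(d, k=3)

    def test_sign_convention_stable(self, small_bundle):
        d = small_bundle["geno"].dosages
        s1 = marker_pca(d, k=3)
        s2 = marker_pca(d.iloc[::-1], k=3).loc[s1.index]
        assert np.allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-8)


class TestScanMechanics:
    def setup_method(self):
        self.geno, _ = founder_panel(60, 100, seed=7)
        self.hybrids = hybrid_frame(self.geno.ids)
        rng = np.random.default_rng(42)
        self.means = hybrid_means(self.geno, self.hybrids, rng,
                                  s2_poly=0.5, s2_resid=0.5, mother_effect=0.4)

    def test_eigen_scan_matches_naive_gls(self):
        """The rotation-accelerated scan and an explicit per-marker GLS give
        identical effects, SEs and p-values."""
        y = self.means["trait"].to_numpy()
        n = len(y)
        Xf = np.column_stack([np.ones(n),
                              (self.hybrids["mother"] == "B").to_numpy(float)])
        G = vanraden_grm(self.geno.dosages).matrix
        fidx = G.index.get_indexer(self.hybrids["father"])
        H = G.to_numpy()[np.ix_(fidx, fidx)]
        M = self.geno.dosages.loc[self.hybrids["father"]].to_numpy()
        for lam in (0.0, 0.7, 3.0):
            u1, se1, p1, d1 = _scan_one_trait(y, Xf, M, lam, H)
            u2, se2, p2, d2 = naive_gls_scan(y, Xf, M, lam, H)
            ok = ~(d1 | d2)
            assert np.allclose(u1[ok], u2[ok], atol=1e-8)
            assert np.allclose(se1[ok], se2[ok], atol=1e-8)
            assert np.allclose(p1[ok], p2[ok], atol=1e-8)

    def test_zero_lambda_no_covariates_equals_ols(self):
        """With sigma2_g pinned at zero and no mother/PC covariates the scan
        p-values are exactly simple linear-regression p-values."""
        y = self.means["trait"].to_numpy()
        n = len(y)
        Xf = np.ones((n, 1))
        M = self.geno.dosages.loc[self.hybrids["father"]].to_numpy()
        H = np.eye(n)
        u, se, p, deg = _scan_one_trait(y, Xf, M, 0.0, H)
        for j in [0, 13, 57, 99]:
            res = stats.linregress(M[:, j], y)
            assert u[j] == pytest.approx(res.slope, rel=1e-10)
            assert p[j] == pytest.approx(res.pvalue, rel=1e-8)

    @pytest.mark.parametrize("method", ["exact", "p3d"])
    def test_marker_and_row_order_invariance(self, method):
        G = vanraden_grm(self.geno.dosages)
        pcs = marker_pca(self.geno.dosages, k=3)
        res1 = gwas_scan(self.means, self.hybrids, self.geno.dosages, G, pcs,
                         method=method)
        perm = np.random.default_rng(0).permutation(len(self.means))
        cols = np.random.default_rng(1).permutation(self.geno.dosages.shape[1])
        res2 = gwas_scan(self.means.iloc[perm], self.hybrids,
                         self.geno.dosages.iloc[:, cols], G, pcs, method=method)
        t1 = res1.table.set_index("marker")
        t2 = res2.table.set_index("marker").loc[t1.index]
        assert np.allclose(t1["p"], t2["p"], atol=1e-8)
        assert np.allclose(t1["effect"], t2["effect"], atol=1e-8)

    def test_constant_marker_degenerate(self):
        geno = self.geno.dosages.copy()
        geno.iloc[:, 0] = 2.0
        G = vanraden_grm(geno)
        res = gwas_scan(self.means, self.hybrids, geno, G, None)
        row = res.table.iloc[0]
        assert row["degenerate"] and row["p"] == 1.0 and not row["significant"]

    def test_h2_gate_skips_traits(self):
        G = vanraden_grm(self.geno.dosages)
        h2 = pd.Series({"trait": 0.05})
        res = gwas_scan(self.means, self.hybrids, self.geno.dosages, G, None, h2=h2,
                        gate_h2=0.1)
        assert res.skipped_traits == [("trait", 0.05)]
        assert len(res.table) == 0


class TestScanAgainstPerMarkerRemlOracle:
    def _oracle_p(self, y, G, hybrids, geno, marker):
        """Independent per-marker Wald p: full REML fit of the marker model
        through the generic engine."""
        from testcross_gwas.reml import ModelSpec, RandomTerm, fit_reml

        n = len(y)
        fidx = G.matrix.index.get_indexer(hybrids["father"])
        Z = np.zeros((n, G.matrix.shape[0]))
        Z[np.arange(n), fidx] = 1.0
        m = geno.dosages[marker].to_numpy()[fidx]
        X = np.column_stack([np.ones(n), m])
        fit = fit_reml(ModelSpec(y, X, ["Intercept", "marker"],
                                 [RandomTerm("g", Z, G.matrix.to_numpy())]))
        t = fit.beta[1] / np.sqrt(fit.C_inv[1, 1])
        return 2 * stats.t.sf(abs(t), n - 2)

    def _setup(self):
        geno, _ = founder_panel(100, 200, seed=19)
        hybrids = hybrid_frame(geno.ids)
        rng = np.random.default_rng(7)
        qtl = [(geno.markers[10], 0.1)]  # weak signal; P3D premises hold
        means = hybrid_means(geno, hybrids, rng, s2_poly=0.6, s2_resid=0.6, qtl=qtl)
        return geno, hybrids, means, vanraden_grm(geno.dosages)

    def test_exact_scan_matches_per_marker_reml(self):
        """The grid-profiled exact scan reproduces a continuous per-marker
        REML fit to within 0.05 in -log10 p."""
        geno, hybrids, means, G = self._setup()
        table = gwas_scan(means, hybrids, geno.dosages, G, None,
                          method="exact").table.set_index("marker")
        y = means["trait"].to_numpy()
        for marker in geno.markers[5:16] + geno.markers[100:110]:
            p_oracle = self._oracle_p(y, G, hybrids, geno, marker)
            d = abs(np.log10(table.loc[marker, "p"]) - np.log10(p_oracle))
            assert d < 0.05, marker

    def test_p3d_close_to_per_marker_reml(self):
        """Holding the null variance ratio fixed (P3D) changes -log10 p by
        less than 0.2 compared with re-estimating the components for every
        marker."""
        geno, hybrids, means, G = self._setup()
        table = gwas_scan(means, hybrids, geno.dosages, G, None,
                          method="p3d").table.set_index("marker")
        y = means["trait"].to_numpy()
        for marker in geno.markers[5:16] + geno.markers[100:110]:
            p_oracle = self._oracle_p(y, G, hybrids, geno, marker)
            d = abs(np.log10(table.loc[marker, "p"]) - np.log10(p_oracle))
            assert d < 0.2, marker
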