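"""GWEIS/GWAS scans against independent oracles."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats as sps

import gcim
from gcim.errors import DegenerateInputError
from gcim.gweis import run_gwas, run_gweis


def _ols_oracle(X, y):
    """Textbook normal-equations solution."""
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestRunGweis:
    def test_exact_fit_recovers_coefficient(self):
        # y = 2*g1 exactly, c orthogonal to g1 by construction
        g1 = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        g2 = np.array([1, 0, 1, 2, 1, 0], dtype=float)
        c = np.array([1.0, -1.0, 0.0, -1.0, 1.0, 0.0])
        counts = np.column_stack([g1, g2])
        G = gcim.GenotypeMatrix(counts, ["a", "b"], [0.3, 0.3], list("pqrstu"))
        y = 2.0 * g1
        stats = run_gweis(G, y, c)
        assert stats.beta_add[0] == pytest.approx(2.0, abs=1e-10)
        assert stats.beta_gxe[0] == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, fixed_fixture_20):
        G, y, c = fixed_fixture_20
        stats = run_gweis(G, y, c)
        for j in range(G.m):
            X = np.column_stack([np.ones(G.n), c, G.counts[:, j], G.counts[:, j] * c])
            beta = _ols_oracle(X, y)
            assert stats.beta_add[j] == pytest.approx(beta[2], abs=1e-8)
            assert stats.beta_gxe[j] == pytest.approx(beta[3], abs=1e-8)

    def test_matches_statsmodels_logistic(self):
        cfg = gcim.EffectCovConfig(n_causal=20)
        G, phen, _ = gcim.simulate_dataset(cfg, n=600, m=30, y_type="binary", seed=8)
        stats = run_gweis(G, phen.y, phen.c)
        ok = np.flatnonzero(stats.flags == "ok")[:10]
        for j in ok:
            X = np.column_stack([np.ones(G.n), phen.c, G.counts[:, j],
                                 G.counts[:, j] * phen.c])
            ref = sm.GLM(phen.y, X, family=sm.families.Binomial()).fit()
            assert stats.beta_add[j] == pytest.approx(ref.params[2], abs=1e-6)
            assert stats.beta_gxe[j] == pytest.approx(ref.params[3], abs=1e-6)
            assert stats.se_gxe[j] == pytest.approx(ref.bse[3], rel=1e-4)

    def test_interaction_estimator_tracks_truth(self):
        cfg = gcim.EffectCovConfig(var_add=0.3, var_gxe=0.1, n_causal=500)
        G, phen, eff = gcim.simulate_dataset(cfg, n=10000, m=1000, seed=17)
        stats = run_gweis(G, phen.y, phen.c)
        true = eff.full_vector("beta_gxe")
        keep = np.isfinite(stats.beta_gxe)
        slope, _, _, _, se = sps.linregress(true[keep], stats.beta_gxe[keep])[:5]
        assert slope > 3 * se

    def test_null_pvalues_uniform(self):
        # no genetic effects at all: p_gxe should be U(0,1) across SNPs
        cfg = gcim.EffectCovConfig(var_add=0.0, var_gxe=0.0, var_add_c=0.0,
                                   var_res_y=1.0, var_res_c=1.0, n_causal=10)
        G, phen, _ = gcim.simulate_dataset(cfg, n=2000, m=2000, seed=19)
        stats = run_gweis(G, phen.y, phen.c)
        pv = stats.p_gxe[np.isfinite(stats.p_gxe)]
        assert sps.kstest(pv, "uniform").pvalue > 0.01

    def test_monomorphic_snp_flagged_not_dropped(self):
        counts = np.column_stack([np.zeros(30), np.random.default_rng(1).binomial(2, 0.4, 30)])
        G = gcim.GenotypeMatrix(counts.astype(float), ["mono", "poly"], [0.0, 0.4],
                                [f"i{k}" for k in range(30)])
        rng = np.random.default_rng(2)
        stats = run_gweis(G, rng.standard_normal(30), rng.standard_normal(30))
        assert stats.m == 2
        assert stats.flags[0] == "monomorphic" and np.isnan(stats.beta_add[0])
        assert stats.flags[1] == "ok" and np.isfinite(stats.beta_add[1])

    def test_constant_exposure_rejected(self, fixed_fixture_20):
        G, y, _ = fixed_fixture_20
        with pytest.raises(DegenerateInputError):
            run_gweis(G, y, np.ones(G.n))

    def test_column_permutation_permutes_rows(self, fixed_fixture_20):
        G, y, c = fixed_fixture_20
        perm = np.array([3, 1, 4, 0, 2])
        Gp = gcim.GenotypeMatrix(G.counts[:, perm], G.snp_ids[perm],
                                 G.allele_freqs[perm], G.individual_ids)
        a = run_gweis(G, y, c)
        b = run_gweis(Gp, y, c)
        assert np.allclose(a.beta_add[perm], b.beta_add, equal_nan=True)
        assert np.allclose(a.p_gxe[perm], b.p_gxe, equal_nan=True)

    def test_orthogonal_covariate_leaves_estimates(self, fixed_fixture_20):
        G, y, c = fixed_fixture_20
        base = run_gweis(G, y, c)
        # covariate orthogonal to every genotype column, the intercept and c
        block = np.column_stack([np.ones(G.n), c, G.counts, G.counts * c[:, None]])
        rng = np.random.default_rng(12)
        v = rng.standard_normal(G.n)
        v -= block @ np.linalg.lstsq(block, v, rcond=None)[0]
        adj = run_gweis(G, y, c, covariates=v)
        assert np.allclose(base.beta_add, adj.beta_add, atol=1e-8)
        assert np.allclose(base.beta_gxe, adj.beta_gxe, atol=1e-8)


class TestRunGwas:
    def test_trait_equals_genotype(self):
        rng = np.random.default_rng(3)
        counts = rng.binomial(2, 0.4, size=(50, 3)).astype(float)
        G = gcim.GenotypeMatrix(counts, ["a", "b", "c"], [0.4] * 3,
                                [f"i{k}" for k in range(50)])
        stats = run_gwas(G, counts[:, 1].copy())
        assert stats.beta_add[1] == pytest.approx(1.0, abs=1e-10)
        assert not stats.is_gweis

    def test_matches_normal_equations_oracle(self, fixed_fixture_20):
        G, y, _ = fixed_fixture_20
        stats = run_gwas(G, y)
        for j in range(G.m):
            X = np.column_stack([np.ones(G.n), G.counts[:, j]])
            beta = _ols_oracle(X, y)
            assert stats.beta_add[j] == pytest.approx(beta[1], abs=1e-8)

    def test_logistic_sign_recovery(self):
        # a strong SNP on a 10%-prevalence binary trait: estimated sign
        # matches the simulated sign in nearly all replicates
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 400
            g = rng.binomial(2, 0.3, n).astype(float)
            liability = 0.8 * g + rng.standard_normal(n)
            trait = gcim.dichotomize(liability, 0.1)
            G = gcim.GenotypeMatrix(g[:, None], ["s"], [0.3],
                                    [f"i{k}" for k in range(n)])
            stats = run_gwas(G, trait)
            if np.isfinite(stats.beta_add[0]) and stats.beta_add[0] > 0:
                hits += 1
        assert hits >= 95


def test_summary_stats_tsv_roundtrip(tmp_path, fixed_fixture_20):
    G, y, c = fixed_fixture_20
    stats = run_gweis(G, y, c)
    path = tmp_path / "stats.tsv"
    stats.to_tsv(path)
    back = gcim.SummaryStats.from_tsv(path)
    assert back.is_gweis
    assert np.allclose(back.beta_add, stats.beta_add, equal_nan=True)
    assert np.allclose(back.p_gxe, stats.p_gxe, equal_nan=True)
    assert list(back.snp_ids) == list(stats.snp_ids)
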