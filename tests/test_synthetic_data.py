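"""Unit and property tests for the synthetic-data generator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gcim
from gcim.errors import ConfigurationError, ContractError, DegenerateInputError
from gcim.synthetic_data import standardize_columns


class TestSimulateGenotypes:
    def test_deterministic_and_in_range(self):
        a = gcim.simulate_genotypes(4, 3, 0.5, 0.5, seed=123)
        b = gcim.simulate_genotypes(4, 3, 0.5, 0.5, seed=123)
        assert np.array_equal(a.counts, b.counts)
        assert np.isin(a.counts, (0, 1, 2)).all()
        assert a.counts.shape == (4, 3)

    def test_binomial_moments(self):
        G = gcim.simulate_genotypes(10000, 1, 0.2, 0.2, seed=5)
        # mean allele count 2f = 0.4, SE = sqrt(2 f (1-f) / n)
        se = math.sqrt(2 * 0.2 * 0.8 / 10000)
        assert abs(G.counts.mean() - 0.4) < 3 * se

    @pytest.mark.parametrize("bounds", [(0.6, 0.6), (0.0, 0.2), (0.3, 0.1)])
    def test_invalid_maf_bounds(self, bounds):
        with pytest.raises(ConfigurationError):
            gcim.simulate_genotypes(10, 2, *bounds, seed=0)


class TestEffectCovConfig:
    def test_correlation_grid_arithmetic(self):
        # every covariance used in the scenario grids reproduces its target
        # correlation to within 0.005
        pairs = [
            (0.179, 0.4, 0.5, 0.4), (0.358, 0.4, 0.5, 0.8),
            (0.219, 0.6, 0.5, 0.4), (0.438, 0.6, 0.5, 0.8),
            (0.126, 0.2, 0.5, 0.4), (0.253, 0.2, 0.5, 0.8),
            (0.155, 0.3, 0.5, 0.4), (0.31, 0.3, 0.5, 0.8),
            (0.089, 0.1, 0.5, 0.4), (0.179, 0.1, 0.5, 0.8),
        ]
        for cov, v1, v2, target in pairs:
            assert abs(cov / math.sqrt(v1 * v2) - target) < 0.005
            assert gcim.implied_cov(target, v1, v2) == cov

    def test_non_psd_rejected(self):
        with pytest.raises(ConfigurationError):
            gcim.EffectCovConfig(var_add=0.4, var_add_c=0.5, cov_add_addc=0.5)

    def test_negative_variance_rejected(self):
        with pytest.raises(ConfigurationError):
            gcim.EffectCovConfig(var_gxe=-0.1)


class TestDrawTrueEffects:
    def test_zero_variance_component_exactly_zero(self):
        cfg = gcim.EffectCovConfig(var_gxe=0.0, cov_add_addc=0.0, n_causal=100)
        eff = gcim.draw_true_effects(cfg, m=200, n=50, seed=3)
        assert np.all(eff.beta_gxe == 0.0)
        assert eff.full_vector("beta_add")[np.setdiff1d(np.arange(200), eff.causal_index)].sum() == 0

    def test_genetic_correlation_recovered(self):
        cfg = gcim.EffectCovConfig(var_add=0.4, var_add_c=0.5, cov_add_addc=0.179,
                                   n_causal=10000)
        eff = gcim.draw_true_effects(cfg, m=10000, n=10, seed=4)
        r = np.corrcoef(eff.beta_add, eff.beta_add_c)[0, 1]
        # Fisher-z SE for a correlation at n = 10000
        se = 1 / math.sqrt(10000 - 3)
        assert abs(r - 0.4) < 3 * se

    def test_summed_covariance_converges(self):
        cfg = gcim.EffectCovConfig(var_add=0.4, var_add_c=0.5, cov_add_addc=0.179,
                                   n_causal=5000)
        eff = gcim.draw_true_effects(cfg, m=5000, n=10, seed=9)
        emp = np.cov(np.vstack([eff.beta_add, eff.beta_gxe, eff.beta_add_c])) * cfg.n_causal
        target = cfg.genetic_cov_matrix()
        # variance of a sample variance ~ 2 sigma^4 / n
        for i in range(3):
            se = math.sqrt(2 / cfg.n_causal) * max(target[i, i], 1e-12)
            assert abs(emp[i, i] - target[i, i]) <= 3 * se + 1e-12

    def test_n_causal_exceeds_m(self):
        with pytest.raises(ConfigurationError):
            gcim.draw_true_effects(gcim.EffectCovConfig(n_causal=300), m=200, n=10, seed=0)


class TestSimulatePhenotypes:
    def test_pure_noise_outcome(self):
        cfg = gcim.EffectCovConfig(var_add=0.0, var_gxe=0.0, var_add_c=0.0,
                                   var_res_y=1.0, var_res_c=1.0, n_causal=10)
        G = gcim.simulate_genotypes(10000, 20, 0.1, 0.5, seed=1)
        eff = gcim.draw_true_effects(cfg, m=20, n=10000, seed=2)
        phen = gcim.simulate_phenotypes(G, eff, cfg)
        se = math.sqrt(2 / 10000)  # SE of a unit-variance sample variance
        assert abs(phen.y.var() - 1.0) < 3 * se

    def test_null_config_variance_bookkeeping(self):
        cfg = gcim.EffectCovConfig(n_causal=200)  # 0.4+0.6 and 0.5+0.5
        G, phen, _ = gcim.simulate_dataset(cfg, n=10000, m=500, seed=21)
        se = math.sqrt(2 / 10000)
        assert abs(phen.y.var() - 1.0) < 3 * se * 1.5
        assert abs(phen.c.var() - 1.0) < 3 * se * 1.5

    def test_exposure_main_effect_r2(self):
        # beta_c = 0.447 with var(c)=1 explains ~20% of outcome variance
        # with beta_c: genetic variance drops to 0.2 so the outcome stays at
        # unit total variance (0.2 + 0.447^2*1 + 0.6)
        cfg = gcim.EffectCovConfig(var_add=0.2, var_res_y=0.6, beta_c=0.447,
                                   n_causal=200)
        G, phen, _ = gcim.simulate_dataset(cfg, n=10000, m=500, seed=22)
        r2 = np.corrcoef(phen.y, phen.c)[0, 1] ** 2
        se = 2 * 0.447 * math.sqrt(0.2) / math.sqrt(10000)  # delta-method scale
        assert abs(r2 - 0.20) < 3 * max(se, 0.012)

    def test_heteroscedasticity_signature(self):
        base = dict(var_add=0.4, var_add_c=0.5, n_causal=100)
        het = gcim.EffectCovConfig(var_res_y=0.1, var_res_rxe=0.5, **base)
        hom = gcim.EffectCovConfig(var_res_y=0.6, var_res_rxe=0.0, **base)
        for cfg, expect_ratio_above in ((het, 1.5), (hom, None)):
            G, phen, _ = gcim.simulate_dataset(cfg, n=20000, m=300, seed=33)
            qs = np.quantile(phen.c, [0.45, 0.55, 0.9])
            var_mid = phen.y[(phen.c >= qs[0]) & (phen.c < qs[1])].var()
            var_top = phen.y[phen.c >= qs[2]].var()
            if expect_ratio_above:
                assert var_top / var_mid > expect_ratio_above
            else:
                assert 0.7 < var_top / var_mid < 1.4

    def test_dimension_mismatch(self):
        cfg = gcim.EffectCovConfig(n_causal=10)
        G = gcim.simulate_genotypes(100, 20, 0.1, 0.5, seed=1)
        eff = gcim.draw_true_effects(cfg, m=20, n=50, seed=2)
        with pytest.raises(ContractError):
            gcim.simulate_phenotypes(G, eff, cfg)

    def test_binary_traits_thresholded_post_hoc(self):
        # binary traits transform the already-simulated quantitative data:
        # the outcome is generated from the continuous exposure, and the
        # latent values are retained alongside the 0/1 representation
        cfg = gcim.EffectCovConfig(var_add=0.0, var_gxe=0.0, var_add_c=0.5,
                                   var_res_y=0.1, var_res_c=0.5, beta_c=2.0,
                                   n_causal=50)
        G, phen, _ = gcim.simulate_dataset(cfg, n=20000, m=100, c_type="binary",
                                           prevalence=0.1, seed=44)
        assert set(np.unique(phen.c)) == {0.0, 1.0}
        assert np.array_equal(gcim.dichotomize(phen.c_latent, 0.1), phen.c)
        # y tracks the continuous exposure even within the control group
        ctrl = phen.c == 0
        slope = np.polyfit(phen.c_latent[ctrl], phen.y[ctrl], 1)[0]
        assert abs(slope - 2.0) < 0.1


class TestDichotomize:
    def test_forced_single_case(self):
        out = gcim.dichotomize(np.arange(1, 11, dtype=float), prevalence=0.1)
        assert out.sum() == 1
        assert out[-1] == 1.0

    def test_prevalence_case_count(self):
        rng = np.random.default_rng(0)
        out = gcim.dichotomize(rng.standard_normal(50000), prevalence=0.1)
        assert out.sum() == 5000

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            gcim.dichotomize(np.ones(10), prevalence=0.1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=2, max_value=200),
        prev=st.floats(min_value=0.01, max_value=0.99),
        seed=st.integers(min_value=0, max_value=1000),
    )
    def test_case_count_matches_ceiling(self, n, prev, seed):
        values = np.random.default_rng(seed).standard_normal(n)
        out = gcim.dichotomize(values, prev)
        assert out.sum() == math.ceil(n * prev)
        assert set(np.unique(out)) <= {0.0, 1.0}


class TestSplit:
    def test_sizes_and_disjointness(self):
        idx_d, idx_t = gcim.split_indices(10, 0.8, seed=1)
        assert len(idx_d) == 8 and len(idx_t) == 2
        assert len(np.intersect1d(idx_d, idx_t)) == 0
        assert np.array_equal(np.sort(np.concatenate([idx_d, idx_t])), np.arange(10))

    def test_paper_scale_sizes(self):
        idx_d, idx_t = gcim.split_indices(50000, 0.8, seed=2)
        assert len(idx_d) == 40000 and len(idx_t) == 10000

    @pytest.mark.parametrize("frac", [0.0, 1.0, 1.5])
    def test_invalid_fraction(self, frac):
        with pytest.raises(ContractError):
            gcim.split_indices(100, frac, seed=0)

    def test_too_small(self):
        with pytest.raises(ContractError):
            gcim.split_indices(5, 0.8, seed=0)

    def test_deterministic(self):
        assert np.array_equal(gcim.split_indices(100, 0.8, 7)[0],
                              gcim.split_indices(100, 0.8, 7)[0])


def test_standardize_columns_zero_variance_safe():
    X = np.array([[1.0, 2.0], [1.0, 4.0], [1.0, 6.0]])
    Z = standardize_columns(X)
    assert np.all(Z[:, 0] == 0)
    assert abs(Z[:, 1].mean()) < 1e-12 and abs(Z[:, 1].std() - 1) < 1e-12
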