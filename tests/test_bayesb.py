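"""BayesB spike-and-slab model tests: both inference engines plus tuning."""

import numpy as np
import pytest

from halfsibgs import (
    BayesBPriors,
    GenotypeMatrix,
    PopulationConfig,
    TraitConfig,
    adjust_phenotypes,
    derive_scale,
    fit_bayesb,
    gebv_from_effects,
    simulate_population,
    simulate_trait,
)
from halfsibgs.bayesb import TUNING_GRID, tune_hyperparameters


@pytest.fixture(scope="module")
def qtl_dataset():
    """n=300, m=1000, one QTL explaining 30% of phenotypic variance."""
    g, _ = simulate_population(
        PopulationConfig(n_families=25, progeny_per_family=12, n_snps=1000, seed=31)
    )
    t = adjust_phenotypes(
        simulate_trait(
            g,
            TraitConfig(heritability=0.3, n_qtl=1,
                        large_effect_variance_fraction=1.0, seed=31),
        )
    )
    return g, t


class TestDeriveScale:
    def test_moment_matching_hand_formula(self, small_population):
        g, _ = small_population
        priors = BayesBPriors(nu=4.0, kappa=0.01, mvar=0.5, f=0.10)
        var_y = 2.3
        sum2pq = float((2 * g.snp_meta["freq"] * (1 - g.snp_meta["freq"])).sum())
        expected = 0.5 * var_y / (0.01 * sum2pq * 1.10 * (4.0 / 2.0))
        assert derive_scale(priors, g, var_y) == pytest.approx(expected, rel=1e-12)

    def test_linear_in_phenotypic_variance(self, small_population):
        g, _ = small_population
        priors = BayesBPriors()
        assert derive_scale(priors, g, 2.0) == pytest.approx(
            2 * derive_scale(priors, g, 1.0)
        )

    def test_inbreeding_factor(self, small_population):
        g, _ = small_population
        s0 = derive_scale(BayesBPriors(f=0.0), g, 1.0)
        s1 = derive_scale(BayesBPriors(f=0.10), g, 1.0)
        assert s0 / s1 == pytest.approx(1.1)


class TestVariationalFit:
    def test_large_qtl_lands_in_top_effects(self, qtl_dataset):
        g, t = qtl_dataset
        qtl = t.meta["large_qtl_index"]
        hits = 0
        for seed in range(10):
            eff = fit_bayesb(g, t.y_adj, BayesBPriors(kappa=0.01), seed=seed)
            top = np.argsort(-eff.mu**2)[:1]  # top 0.1% of 1000
            hits += any(abs(int(i) - qtl) <= 1 for i in top)
        assert hits >= 9

    def test_pure_noise_shrinks_to_nothing(self, qtl_dataset):
        g, t = qtl_dataset
        rng = np.random.default_rng(0)
        rs, max_mu = [], []
        for seed in range(6):
            noise = rng.normal(size=g.n_individuals)
            train, val = slice(0, 240), slice(240, None)
            g_train = GenotypeMatrix(
                g.dosage[train], g.snp_meta, g.sample_ids[:240]
            )
            eff = fit_bayesb(g_train, noise[train], BayesBPriors(kappa=0.01))
            g_val = GenotypeMatrix(g.dosage[val], g.snp_meta, g.sample_ids[240:])
            pred = gebv_from_effects(g_val, eff)
            max_mu.append(np.abs(eff.mu).max())
            if pred.std() > 0:
                rs.append(np.corrcoef(pred, noise[val])[0, 1])
        signal = fit_bayesb(g, t.y_adj, BayesBPriors(kappa=0.01))
        assert np.max(max_mu) < 0.5 * np.abs(signal.mu).max()
        if rs:
            assert abs(np.mean(rs)) < 0.25

    def test_kappa_one_diffuse_slab_is_ridge(self, small_population, small_trait):
        """With no spike and a pinned slab variance VB is ridge regression."""
        g, _ = small_population
        sub = GenotypeMatrix(g.dosage[:200, :500], g.snp_meta.iloc[:500],
                             g.sample_ids[:200]).recompute_freq()
        y = small_trait.y_adj[:200]
        nu, scale = 200.0, 0.01  # high df pins the slab variance near `scale`
        eff = fit_bayesb(sub, y, BayesBPriors(kappa=1.0, nu=nu, scale=scale),
                         max_sweeps=5000, tol=1e-9)
        X = (sub.dosage - sub.dosage.mean(0)).astype(float)
        yc = y - y.mean()
        lam = eff.sigma_e2 * (nu + 1.0) / (nu * scale)
        ridge = np.linalg.solve(X.T @ X + lam * np.eye(500), X.T @ yc)
        assert np.corrcoef(eff.mu, ridge)[0, 1] > 0.99

    def test_shrinkage_monotone_in_kappa(self, qtl_dataset):
        g, t = qtl_dataset
        norms = []
        for kappa in (0.1, 0.01, 0.001):
            eff = fit_bayesb(g, t.y_adj, BayesBPriors(kappa=kappa))
            norms.append(np.abs(eff.mu).sum())
        assert norms[0] > norms[1] > norms[2]


class TestGibbsEngine:
    def test_same_seed_identical_chain(self, qtl_dataset):
        g, t = qtl_dataset
        kw = dict(inference="mcmc", seed=5, n_iter=400, burn_in=100)
        e1 = fit_bayesb(g, t.y_adj, BayesBPriors(kappa=0.01), **kw)
        e2 = fit_bayesb(g, t.y_adj, BayesBPriors(kappa=0.01), **kw)
        np.testing.assert_array_equal(e1.mu, e2.mu)

    def test_engines_agree_on_top_snp(self, qtl_dataset):
        g, t = qtl_dataset
        agree = 0
        for seed in range(5):
            vb = fit_bayesb(g, t.y_adj, BayesBPriors(kappa=0.01), seed=seed)
            mc = fit_bayesb(g, t.y_adj, BayesBPriors(kappa=0.01),
                            inference="mcmc", seed=seed, n_iter=600, burn_in=200)
            agree += int(np.argmax(vb.mu**2)) == int(np.argmax(mc.mu**2))
        assert agree >= 4


class TestGebvFromEffects:
    def test_zero_effects_zero_gebvs(self, small_population):
        g, _ = small_population
        from halfsibgs.bayesb import SnpEffects

        eff = SnpEffects(mu=np.zeros(g.n_snps), pip=np.zeros(g.n_snps),
                         intercept=0.0)
        assert np.all(gebv_from_effects(g, eff) == 0)

    def test_single_effect_proportional_to_centered_dosage(self, small_population):
        g, _ = small_population
        from halfsibgs.bayesb import SnpEffects

        mu = np.zeros(g.n_snps)
        mu[7] = 2.0
        eff = SnpEffects(mu=mu, pip=mu * 0, intercept=0.0)
        gebv = gebv_from_effects(g, eff)
        x = g.dosage[:, 7] - g.dosage[:, 7].mean()
        np.testing.assert_allclose(gebv, 2.0 * x, atol=1e-12)

    def test_matches_internal_fitted_values(self, qtl_dataset):
        g, t = qtl_dataset
        eff = fit_bayesb(g, t.y_adj, BayesBPriors(kappa=0.01))
        gebv = gebv_from_effects(g, eff)
        manual = (g.dosage - eff.col_means) @ eff.mu
        assert np.corrcoef(gebv, manual)[0, 1] > 0.999

    def test_dimension_mismatch(self, small_population):
        g, _ = small_population
        from halfsibgs.bayesb import SnpEffects

        eff = SnpEffects(mu=np.zeros(3), pip=np.zeros(3), intercept=0.0)
        with pytest.raises(ValueError):
            gebv_from_effects(g, eff)


class TestTuning:
    def test_grid_evaluates_all_nine_combinations(self, qtl_dataset):
        g, t = qtl_dataset
        assignments = np.arange(g.n_individuals) % 6
        best, table = tune_hyperparameters(g, t.y_adj, assignments)
        assert len(table) == 9
        assert set(zip(table["nu"], table["kappa"])) == {
            (nu, k) for nu in TUNING_GRID["nu"] for k in TUNING_GRID["kappa"]
        }
        assert best.f == 0.10 and best.mvar == 0.50
        assert table.loc[table["mse"].idxmin(), "kappa"] == best.kappa

    def test_degenerate_grid_returned_unchanged(self, qtl_dataset):
        g, t = qtl_dataset
        assignments = np.arange(g.n_individuals) % 3
        best, table = tune_hyperparameters(
            g, t.y_adj, assignments, grid={"nu": (8.0,), "kappa": (0.05,)}
        )
        assert len(table) == 1
        assert (best.nu, best.kappa) == (8.0, 0.05)

    def test_sparse_architecture_prefers_small_kappa(self, qtl_dataset):
        g, t = qtl_dataset
        wins = 0
        for seed in range(4):
            rng = np.random.default_rng(seed)
            assignments = rng.permutation(np.arange(g.n_individuals) % 6)
            best, _ = tune_hyperparameters(g, t.y_adj, assignments, seed=seed)
            wins += best.kappa <= 0.01
        assert wins >= 3

    def test_invalid_priors(self):
        with pytest.raises(ValueError):
            BayesBPriors(kappa=0.0)
        with pytest.raises(ValueError):
            BayesBPriors(nu=2.0)
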