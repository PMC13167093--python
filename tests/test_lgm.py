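"""Engine correctness: PC priors, Laplace vs quadrature/MCMC/closed form, IC."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.special import expit
from scipy.stats import pearsonr

from methylvar import (
    PCPrior,
    LatentModelSpec,
    RandomTerm,
    pc_prior_logdensity,
    fit_laplace,
    information_criteria,
    select_model,
    build_design,
    complete_model_spec,
)
from methylvar.lgm import _laplace_logpost, _Design
from ._mcmc_oracle import batch_means_se, metropolis_latent


class TestPCPrior:
    @pytest.mark.parametrize(
        "u,alpha,lam",
        [(1.0, 0.05, 2.995732), (2.0, 0.01, 2.302585), (1.0, 0.01, 4.605170), (1.5, 0.05, 1.997155)],
    )
    def test_rate_conversion(self, u, alpha, lam):
        assert PCPrior(u, alpha).rate == pytest.approx(lam, abs=1e-6)
        assert PCPrior(u, alpha).rate == pytest.approx(-np.log(alpha) / u)

    @pytest.mark.parametrize("u", [0.5, 1.0, 1.5, 2.0])
    @pytest.mark.parametrize("alpha", [0.01, 0.05])
    def test_tail_probability_by_integration(self, u, alpha):
        prior = PCPrior(u, alpha)
        tail, _ = integrate.quad(lambda s: np.exp(pc_prior_logdensity(s, prior)), u, np.inf)
        assert tail == pytest.approx(alpha, abs=1e-8)

    def test_density_vanishes_at_nonpositive_sigma(self):
        assert pc_prior_logdensity(0.0, PCPrior(1, 0.05)) == -np.inf
        assert pc_prior_logdensity(-1.0, PCPrior(1, 0.05)) == -np.inf

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PCPrior(-1.0, 0.05)
        with pytest.raises(ValueError):
            PCPrior(1.0, 1.5)


def intercept_only_spec(prior_sd=3.0):
    return LatentModelSpec(
        likelihood="binomial-logit",
        X=np.ones((1, 1)),
        fixed_names=["intercept"],
        fixed_prior_sd=np.array([prior_sd]),
    )


class TestLaplaceVsQuadrature:
    def test_intercept_only_binomial_matches_quadrature(self):
        """Posterior of β0 for y=5, n=10 with N(0,3) prior, vs 1-D quadrature."""
        spec = intercept_only_spec(3.0)
        fit = fit_laplace(spec, np.array([5.0]), np.array([10.0]))

        def post(b):
            return expit(b) ** 5 * (1 - expit(b)) ** 5 * np.exp(-0.5 * b**2 / 9.0)

        z, _ = integrate.quad(post, -30, 30)
        mean, _ = integrate.quad(lambda b: b * post(b) / z, -30, 30)
        var, _ = integrate.quad(lambda b: (b - mean) ** 2 * post(b) / z, -30, 30)
        assert fit.latent_mean[0] == pytest.approx(mean, abs=1e-3)
        assert fit.latent_sd[0] == pytest.approx(np.sqrt(var), abs=1e-3)

    def test_skewed_intercept_only_stays_within_tolerance(self):
        spec = intercept_only_spec(3.0)
        fit = fit_laplace(spec, np.array([18.0]), np.array([20.0]))

        def post(b):
            return expit(b) ** 18 * (1 - expit(b)) ** 2 * np.exp(-0.5 * b**2 / 9.0)

        z, _ = integrate.quad(post, -30, 30)
        mean, _ = integrate.quad(lambda b: b * post(b) / z, -30, 30)
        assert fit.latent_mean[0] == pytest.approx(mean, abs=1e-3)


def one_random_effect_model(seed=4, n_groups=10, n_per=5):
    rng = np.random.default_rng(seed)
    idx = np.repeat(np.arange(n_groups), n_per)
    u = rng.normal(0, 0.8, n_groups)
    eta = 0.3 + u[idx]
    trials = np.full(idx.size, 25.0)
    y = rng.binomial(25, expit(eta)).astype(float)
    spec = LatentModelSpec(
        likelihood="binomial-logit",
        X=np.ones((idx.size, 1)),
        fixed_names=["intercept"],
        fixed_prior_sd=np.array([3.0]),
        random_terms=[
            RandomTerm("group", idx, n_groups, [f"g{i}" for i in range(n_groups)], PCPrior(1.0, 0.05))
        ],
    )
    return spec, y, trials


class TestLaplaceVsMCMC:
    def test_latent_posterior_matches_metropolis_oracle(self):
        """EB-conditional latent posterior vs a 200k-iteration RW Metropolis."""
        spec, y, trials = one_random_effect_model()
        fit = fit_laplace(spec, y, trials)
        sigma = np.array([fit.sigma["group"]])
        d = spec.latent_dim
        prop_cov = np.diag(fit.latent_sd**2)
        samples = metropolis_latent(
            spec, y, trials, sigma, n_iter=200_000, burn=20_000, thin=20, seed=0,
            proposal_cov=prop_cov,
        )
        mc_mean = samples.mean(axis=0)
        r = pearsonr(fit.latent_mean, mc_mean)[0]
        assert r >= 0.99
        for k in range(d):
            se = batch_means_se(samples[:, k])
            assert abs(fit.latent_mean[k] - mc_mean[k]) < max(3 * se, 0.02)
        # posterior sds agree within MC noise
        assert np.allclose(fit.latent_sd, samples.std(axis=0, ddof=1), rtol=0.15)


class TestGaussianLimit:
    def test_fixed_effects_match_conjugate_closed_form(self):
        rng = np.random.default_rng(1)
        n, p, s = 40, 3, 0.7
        X = rng.standard_normal((n, p))
        beta = np.array([0.5, -1.0, 2.0])
        y = X @ beta + rng.normal(0, s, n)
        prior_sd = np.array([2.0, 2.0, 2.0])
        spec = LatentModelSpec(
            likelihood="gaussian", X=X, fixed_names=list("abc"),
            fixed_prior_sd=prior_sd, gaussian_noise_sd=s,
        )
        fit = fit_laplace(spec, y)
        H = X.T @ X / s**2 + np.diag(1.0 / prior_sd**2)
        cov = np.linalg.inv(H)
        mean = cov @ X.T @ y / s**2
        assert np.allclose(fit.latent_mean, mean, atol=1e-8)
        assert np.allclose(fit.latent_sd, np.sqrt(np.diag(cov)), atol=1e-8)
        # marginal likelihood equals the exact Gaussian evidence
        from scipy.stats import multivariate_normal

        evidence = multivariate_normal.logpdf(
            y, mean=np.zeros(n), cov=X @ np.diag(prior_sd**2) @ X.T + s**2 * np.eye(n)
        )
        assert fit.log_marginal == pytest.approx(evidence, abs=1e-8)

    def test_random_effect_marginal_exact_at_fixed_sigma(self):
        rng = np.random.default_rng(2)
        n_groups, n_per, s, sig = 6, 4, 0.5, 0.9
        idx = np.repeat(np.arange(n_groups), n_per)
        y = rng.normal(0, 1, idx.size)
        spec = LatentModelSpec(
            likelihood="gaussian", X=np.ones((idx.size, 1)), fixed_names=["mu"],
            fixed_prior_sd=np.array([2.0]), gaussian_noise_sd=s,
            random_terms=[RandomTerm("g", idx, n_groups, list(range(n_groups)), PCPrior(1, 0.05))],
        )
        design = _Design(spec)
        val, x_hat, factor, _it, _gn, log_marg = _laplace_logpost(
            spec, design, y, None, np.log([sig]), np.zeros(spec.latent_dim), 1e-10
        )
        Z = spec.build_Z().toarray()
        prior_cov = np.diag([4.0] + [sig**2] * n_groups)
        from scipy.stats import multivariate_normal

        evidence = multivariate_normal.logpdf(y, mean=np.zeros(idx.size),
                                              cov=Z @ prior_cov @ Z.T + s**2 * np.eye(idx.size))
        assert log_marg == pytest.approx(evidence, abs=1e-8)


class TestPathEquivalence:
    def test_schur_and_generic_paths_agree(self, small_cohort):
        """Singleton-term Schur elimination equals the generic factorization."""
        coh = small_cohort
        sub = coh.table.subset(
            site_ids=set(coh.table.sites["site_id"][:10]),
            subject_ids=set(coh.table.subjects[:12]),
        )
        spec, y, trials = build_design(sub, coh.annotation, template=complete_model_spec(False))
        a = fit_laplace(spec, y, trials)
        b = fit_laplace(spec, y, trials, force_generic=True)
        assert np.allclose(a.latent_mean, b.latent_mean, atol=1e-10)
        assert np.allclose(a.latent_sd, b.latent_sd, atol=1e-10)
        assert a.log_marginal == pytest.approx(b.log_marginal, abs=1e-8)


class TestInformationCriteria:
    def test_determinism_under_fixed_seed(self):
        spec, y, trials = one_random_effect_model()
        fit = fit_laplace(spec, y, trials)
        a = information_criteria(fit, n_samples=400, seed=9)
        dic_a, waic_a, cpo_a = a.dic, a.waic, a.cpo_sum
        b = information_criteria(fit, n_samples=400, seed=9)
        assert (dic_a, waic_a, cpo_a) == (b.dic, b.waic, b.cpo_sum)

    def test_degenerate_posterior_has_no_effective_parameters(self):
        """With the latent field pinned (tiny prior sds), p_D → 0 and DIC → D(x̂)."""
        spec = LatentModelSpec(
            likelihood="binomial-logit",
            X=np.ones((8, 1)),
            fixed_names=["intercept"],
            fixed_prior_sd=np.array([1e-6]),
        )
        y = np.array([3.0, 4, 5, 6, 5, 4, 3, 6])
        trials = np.full(8, 10.0)
        fit = fit_laplace(spec, y, trials)
        fit = information_criteria(fit, n_samples=2000, seed=0)
        from methylvar.lgm import _lik_terms

        ll, _, _ = _lik_terms(spec, fit.design.eta(fit.latent_mean), y, trials)
        assert fit.p_dic == pytest.approx(0.0, abs=0.01)
        assert fit.dic == pytest.approx(-2 * ll.sum(), abs=0.05)

    def test_self_consistency_against_high_sample_run(self):
        """Small-S estimates sit within MC error of a much larger-S run."""
        rng_spec, y, trials = one_random_effect_model(seed=8, n_groups=3, n_per=2)
        fit = fit_laplace(rng_spec, y, trials)
        big = information_criteria(fit, n_samples=50_000, seed=1)
        dic_big, waic_big = big.dic, big.waic
        reps = []
        for s in range(12):
            f = information_criteria(fit, n_samples=1000, seed=100 + s)
            reps.append((f.dic, f.waic))
        reps = np.array(reps)
        for j, target in enumerate([dic_big, waic_big]):
            se = reps[:, j].std(ddof=1)
            assert abs(reps[:, j].mean() - target) < 3 * se / np.sqrt(len(reps)) + 3 * se


class TestSelectModel:
    @staticmethod
    def fake(dic, p_d, waic=None, cpo=None):
        from types import SimpleNamespace

        return SimpleNamespace(dic=dic, waic=waic if waic is not None else dic,
                               cpo_sum=cpo if cpo is not None else dic / 2, p_dic=p_d)

    def test_within_band_prefers_fewer_effective_parameters(self):
        fits = {"big": self.fake(100.0, 50.0), "small": self.fake(103.0, 30.0)}
        _, chosen = select_model(fits)
        assert chosen == "small"

    def test_outside_band_best_dic_wins(self):
        fits = {"big": self.fake(100.0, 50.0), "small": self.fake(110.0, 5.0)}
        _, chosen = select_model(fits)
        assert chosen == "big"

    def test_single_fit_returned_unchanged(self):
        fits = {"only": self.fake(42.0, 3.0)}
        table, chosen = select_model(fits)
        assert chosen == "only" and len(table) == 1

    def test_exhaustive_small_cases(self):
        """Enumerate DIC gaps around the 4-unit band and all p_D orderings."""
        for gap in [0.0, 1.0, 3.99, 4.0, 4.01, 10.0]:
            for pd_a, pd_b in [(10.0, 5.0), (5.0, 10.0), (7.0, 7.0)]:
                fits = {"a": self.fake(100.0, pd_a), "b": self.fake(100.0 + gap, pd_b)}
                _, chosen = select_model(fits)
                if gap <= 4.0:
                    in_band = {"a": pd_a, "b": pd_b}
                    best_pd = min(in_band.values())
                    expected = sorted(k for k, v in in_band.items() if v == best_pd)[0]
                else:
                    expected = "a"
                assert chosen == expected, (gap, pd_a, pd_b)

    def test_missing_criteria_rejected(self):
        from types import SimpleNamespace

        with pytest.raises(ValueError):
            select_model({"x": SimpleNamespace(dic=None)})


class TestBuildDesign:
    def test_interaction_cardinality(self, small_cohort):
        coh = small_cohort
        sub = coh.table.subset(site_ids=set(coh.table.sites["site_id"][:2]),
                               subject_ids=set(coh.table.subjects[:2]))
        spec, _, _ = build_design(sub, coh.annotation, template=complete_model_spec(False))
        inter = next(t for t in spec.random_terms if t.name == "site_subject")
        assert inter.n_levels == 4

    def test_treatment_coding_reference_absorbed(self, small_cohort):
        spec, _, _ = build_design(small_cohort.table, small_cohort.annotation,
                                  template=complete_model_spec(False))
        ann_cols = [n for n in spec.fixed_names if n.startswith("annotation[")]
        assert len(ann_cols) == 3  # 4 categories − intron reference
        assert "annotation[intron]" not in spec.fixed_names

    def test_te_term_dropped_without_te_sites(self, small_cohort):
        coh = small_cohort
        ann = coh.annotation.copy()
        ann["te_present"] = False
        ann["te_taxonomy"] = None
        spec, _, _ = build_design(coh.table, ann, template=complete_model_spec(False))
        assert all(t.name != "te_taxonomy" for t in spec.random_terms)

    def test_complete_model_term_counts(self):
        assert len(complete_model_spec(False).random) == 4
        t = complete_model_spec(True)
        assert len(t.random) + len(t.cell_types) == 6
        from methylvar import candidate_catalogue

        cat = candidate_catalogue()
        assert "with_gene" in cat and "with_cpg_island" in cat
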