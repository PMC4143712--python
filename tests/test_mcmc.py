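"""Sampler correctness: priors, Gibbs full conditionals, determinism, mixing."""

import math

import numpy as np
import pytest
from scipy import stats

from lbltvc import (FrequencyModel, MCMCSettings, ParameterState, PriorSpec,
                    SplineBasis, log_prior, run_chain)
from lbltvc.haplotypes import DiplotypeSupport
from lbltvc.likelihood import ModelData
from lbltvc.mcmc import (Sampler, effective_sample_size,
                         random_walk_metropolis)


def tiny_setup(rng, n_indiv=12, likelihood=True, **settings_kw):
    """Two-haplotype single-SNP instance with a constant (order-1) basis."""
    basis = SplineBasis(interior_knots=(), boundary_knots=(20.0, 100.0),
                        order=1)
    genotypes = [[tuple(sorted(rng.choice(["A", "G"], size=2)))]
                 for _ in range(n_indiv)]
    support = DiplotypeSupport.from_genotypes(genotypes, ["A", "G"])
    freq = FrequencyModel(["A", "G"], [0.6, 0.4], d=0.0)
    data = ModelData(y=rng.integers(0, 2, n_indiv).astype(float),
                     smoke=np.zeros(n_indiv), sex=np.zeros(n_indiv),
                     age=rng.uniform(30, 80, n_indiv),
                     indiv=np.arange(n_indiv), n_indiv=n_indiv, basis=basis)
    kw = dict(update_frequencies=False, update_inbreeding=False,
              update_intensity=False, fixed_intensity=1.0,
              likelihood_enabled=likelihood)
    kw.update(settings_kw)
    settings = MCMCSettings(iterations=kw.pop("iterations", 2000),
                            burn_in=kw.pop("burn_in", 500),
                            thinning=kw.pop("thinning", 1),
                            seed=kw.pop("seed", 0), **kw)
    return data, support, freq, settings


class TestLogPrior:
    def test_laplace_density_at_mode(self):
        fm = FrequencyModel(["A", "G"], [0.5, 0.5], d=0.0)
        prior = PriorSpec()
        p = ParameterState(beta0=0.0, spline_coeffs=np.zeros((1, 1)),
                           beta_smoke=0.0, beta_interaction=np.zeros(1),
                           beta_sex=0.0, freq_model=fm, intensity=3.0)
        q = ParameterState(beta0=0.0, spline_coeffs=np.ones((1, 1)),
                           beta_smoke=0.0, beta_interaction=np.zeros(1),
                           beta_sex=0.0, freq_model=fm, intensity=3.0)
        # moving one coefficient from 0 to 1 changes the log-prior by -lambda
        assert log_prior(prior, p) - log_prior(prior, q) == pytest.approx(3.0)

    def test_symmetry_in_coefficients(self):
        fm = FrequencyModel(["A", "G"], [0.5, 0.5], d=0.0)
        prior = PriorSpec()
        mk = lambda x: ParameterState(
            beta0=0.3, spline_coeffs=np.full((1, 2), x), beta_smoke=-x,
            beta_interaction=np.array([x]), beta_sex=x, freq_model=fm,
            intensity=1.5)
        assert log_prior(prior, mk(0.7)) == pytest.approx(
            log_prior(prior, mk(-0.7)), abs=1e-12)

    def test_matches_term_by_term_density_oracle(self, rng):
        m = 3
        f = rng.dirichlet(np.ones(m))
        fm = FrequencyModel([f"H{i}" for i in range(m)], f, d=0.1)
        prior = PriorSpec(gamma_shape=20, gamma_rate=20, beta0_sd=10)
        lam = 1.7
        p = ParameterState(beta0=rng.normal(), spline_coeffs=rng.normal(size=(2, 6)),
                           beta_smoke=rng.normal(),
                           beta_interaction=rng.normal(size=2),
                           beta_sex=rng.normal(), freq_model=fm, intensity=lam)
        betas = p.penalized_coefficients
        want = (stats.laplace(scale=1 / lam).logpdf(betas).sum()
                + stats.norm(scale=10).logpdf(p.beta0)
                + stats.gamma(a=20, scale=1 / 20).logpdf(lam)
                + stats.dirichlet(np.ones(m)).logpdf(f / f.sum()))
        assert log_prior(prior, p) == pytest.approx(float(want), abs=1e-9)

    def test_invalid_inbreeding_is_minus_infinity(self):
        fm = FrequencyModel(["A", "G"], [0.5, 0.5], d=0.0)
        p = ParameterState(beta0=0.0, spline_coeffs=np.zeros((1, 1)),
                           beta_smoke=0.0, beta_interaction=np.zeros(1),
                           beta_sex=0.0, freq_model=fm)
        p.freq_model.d = -0.999  # below -f/(1-f) = -1/... for f=0.5 -> -1
        p.freq_model.f = np.array([0.9, 0.1])
        assert log_prior(PriorSpec(), p) == -math.inf


class TestGibbsDiplotypes:
    def make_ambiguous_sampler(self, likelihood, seed=0):
        """Individuals with 2 het sites: support of size 2 per individual."""
        rng = np.random.default_rng(5)
        basis = SplineBasis(interior_knots=(), boundary_knots=(20., 100.),
                            order=1)
        genotypes = [[("A", "G"), ("C", "T")] for _ in range(3)]
        universe = ["AC", "AT", "GC", "GT"]
        support = DiplotypeSupport.from_genotypes(genotypes, universe)
        freq = FrequencyModel(universe, [0.4, 0.3, 0.2, 0.1], d=0.1)
        data = ModelData(y=np.array([1.0, 0.0, 1.0]), smoke=np.zeros(3),
                         sex=np.zeros(3), age=np.array([50.0, 60.0, 70.0]),
                         indiv=np.arange(3), n_indiv=3, basis=basis)
        settings = MCMCSettings(iterations=10, burn_in=5, seed=seed,
                                update_frequencies=False,
                                update_inbreeding=False,
                                update_intensity=False,
                                likelihood_enabled=likelihood)
        s = Sampler(data, support, freq, settings, PriorSpec(), reference=0)
        s.d = 0.1
        return s

    def test_flat_likelihood_proportional_to_diplotype_prior(self):
        s = self.make_ambiguous_sampler(likelihood=False)
        probs = s.gibbs_full_conditionals()[0]
        # support of AG/CT genotype: {AC/GT, AT/GC}; weights 2(1-d)f_k f_k'
        w = np.array([0.4 * 0.1, 0.3 * 0.2])
        np.testing.assert_allclose(probs, w / w.sum(), atol=1e-12)

    def test_singleton_support_is_certain(self, rng):
        data, support, freq, settings = tiny_setup(rng)
        s = Sampler(data, support, freq, settings, PriorSpec())
        for probs in s.gibbs_full_conditionals():
            assert probs.size == 1 and probs[0] == pytest.approx(1.0)

    def test_empirical_frequencies_match_exact_conditional(self):
        s = self.make_ambiguous_sampler(likelihood=True, seed=42)
        s.Bh = np.array([[0.8], [0.2], [-0.5]])  # nonflat likelihood
        s._refresh_caches()
        # independent oracle: hand-enumerate the two candidates of indiv 0
        from lbltvc.haplotypes import Diplotype, diplotype_probability
        from lbltvc.likelihood import hap_copy_vector
        cands = [s.support.supports[0][j] for j in range(2)]
        weights = []
        for dip in cands:
            x = hap_copy_vector(dip, 4, s.reference)
            eta = s.beta0 + float(x @ s.Bh[:, 0])
            py = 1 / (1 + math.exp(-eta))  # y[0] == 1
            fm = FrequencyModel(list(s.haplotypes), s.f, s.d)
            weights.append(py * diplotype_probability(fm, dip))
        exact = np.array(weights) / sum(weights)
        n_draw = 4000
        hits = 0
        for _ in range(n_draw):
            s.gibbs_update_diplotypes()
            hits += int(s.assign[0] == 0)
        p_hat = hits / n_draw
        se = math.sqrt(exact[0] * (1 - exact[0]) / n_draw)
        assert abs(p_hat - exact[0]) < 3 * se + 1e-9


class TestChain:
    def test_bitwise_determinism_under_fixed_seed(self, rng):
        data, support, freq, settings = tiny_setup(rng, seed=123,
                                                   update_intensity=True,
                                                   update_frequencies=True,
                                                   update_inbreeding=True)
        out1 = run_chain(data, support, freq, settings, PriorSpec())
        out2 = run_chain(data, support, freq, settings, PriorSpec())
        np.testing.assert_array_equal(out1.beta0, out2.beta0)
        np.testing.assert_array_equal(out1.spline_coeffs, out2.spline_coeffs)
        np.testing.assert_array_equal(out1.f, out2.f)
        np.testing.assert_array_equal(out1.d, out2.d)
        np.testing.assert_array_equal(out1.assignments, out2.assignments)

    def test_different_seeds_differ(self, rng):
        data, support, freq, settings = tiny_setup(rng, seed=1)
        out1 = run_chain(data, support, freq, settings, PriorSpec())
        from dataclasses import replace
        out2 = run_chain(data, support, freq, replace(settings, seed=2),
                         PriorSpec())
        assert not np.array_equal(out1.beta0, out2.beta0)

    def test_frequency_draws_stay_on_simplex(self, rng):
        data, support, freq, settings = tiny_setup(
            rng, seed=7, update_frequencies=True, update_inbreeding=True,
            iterations=1500, burn_in=300)
        out = run_chain(data, support, freq, settings, PriorSpec())
        assert np.all(out.f > 0)
        np.testing.assert_allclose(out.f.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(out.d < 1.0) and np.all(out.d > -1.0)

    def test_acceptance_rates_reasonable_after_adaptation(self, rng):
        data, support, freq, settings = tiny_setup(
            rng, seed=9, iterations=4000, burn_in=2000,
            update_intensity=True)
        out = run_chain(data, support, freq, settings, PriorSpec())
        for name, rate in out.acceptance_rates.items():
            assert 0.1 <= rate <= 0.6, (name, rate)

    def test_chain_output_shape_and_manifest_pieces(self, rng):
        data, support, freq, settings = tiny_setup(rng, iterations=1000,
                                                   burn_in=200, thinning=4)
        out = run_chain(data, support, freq, settings, PriorSpec())
        assert out.n_samples == settings.n_samples == 200
        df = out.to_dataframe()
        assert len(df) == 200 and "beta0" in df.columns
        assert "ess_beta0" in out.diagnostics
        assert "geweke_beta0" in out.diagnostics


class TestRandomWalkMetropolis:
    def test_conjugate_normal_posterior_moments(self):
        """Known normal posterior: chain mean/var within 3 MC standard errors."""
        rng_data = np.random.default_rng(3)
        obs = rng_data.normal(1.5, 1.0, size=25)
        # prior N(0, 10^2), likelihood N(mu, 1): posterior is normal
        tau2 = 1 / (1 / 100 + len(obs))
        mu_post = tau2 * obs.sum()

        def log_target(mu):
            return -0.5 * mu ** 2 / 100 - 0.5 * np.sum((obs - mu) ** 2)

        chain = random_walk_metropolis(log_target, 0.0, 0.5, 40_000,
                                       np.random.default_rng(4))
        chain = chain[5000:]
        ess = effective_sample_size(chain)
        se_mean = math.sqrt(tau2 / ess)
        assert abs(chain.mean() - mu_post) < 3 * se_mean
        se_var = math.sqrt(2 / max(ess - 1, 1)) * tau2
        assert abs(chain.var() - tau2) < 3 * se_var
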