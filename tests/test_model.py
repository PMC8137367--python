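"""Joint Bayesian APC model: likelihood, priors, sampling, summaries."""

import numpy as np
import pytest
from scipy.stats import halfnorm, norm, poisson

from apcmort.data import CountsTable
from apcmort.model import (
    JointPosterior,
    MCMCConfig,
    ModelSpec,
    PosteriorDraws,
    StratumParams,
    effect_summary,
    fit,
    linear_predictor,
    log_likelihood,
    log_prior,
)

AC = ModelSpec.from_code("ac")
QUICK = MCMCConfig(chains=2, warmup=300, steps=1000, thin=1, seed=9)


def single_cell_table(d=(3, 1), n=(1000, 400)):
    deaths = np.array([[[d[0]]], [[d[1]]]])
    births = np.array([[[n[0] - d[0]]], [[n[1] - d[1]]]])
    return CountsTable(deaths=deaths, births=births,
                       age_labels=("15-19",), years=(1995,))


class TestModelSpec:
    def test_seven_admissible_subsets(self):
        from apcmort.model import ALL_SPECS
        assert [s.code for s in ALL_SPECS] == [
            "a", "p", "c", "ap", "ac", "pc", "apc"]

    def test_rejects_empty_and_unknown(self):
        with pytest.raises(ValueError):
            ModelSpec(())
        with pytest.raises(ValueError):
            ModelSpec(("age", "sex"))

    def test_code_round_trip(self):
        assert ModelSpec.from_code("ac").effects == ("age", "cohort")
        assert ModelSpec.from_code("apc").code == "apc"


class TestLinearPredictor:
    def test_intercept_only(self):
        p = StratumParams(mu=-5.0, age=np.zeros(7))
        spec = ModelSpec(("age",))
        assert linear_predictor(p, spec, 3, 2) == pytest.approx(-5.0)

    def test_additivity(self):
        age = np.zeros(7)
        age[0] = 0.3
        age -= age.mean()
        cohort = np.zeros(11)
        cohort[6] = -0.1
        cohort -= cohort.mean()
        p = StratumParams(mu=-5.0, age=age, cohort=cohort)
        got = linear_predictor(p, AC, 0, 0)
        assert got == pytest.approx(-5.0 + age[0] + cohort[6])


class TestLogLikelihood:
    def test_zero_count_cell(self):
        """One cell with D = 0 and n*lambda = 1 contributes exactly -1."""
        t = single_cell_table(d=(0, 0), n=(1, 1))
        p = StratumParams(mu=0.0, age=np.zeros(1))
        assert log_likelihood(t, p, p, ModelSpec(("age",))) == pytest.approx(-2.0)

    def test_closed_form_two_events(self):
        """D = 2, n*lambda = 2 -> 2 log 2 - 2 - log 2!."""
        t = single_cell_table(d=(2, 0), n=(1, 1))
        pw = StratumParams(mu=np.log(2.0), age=np.zeros(1))
        pb = StratumParams(mu=0.0, age=np.zeros(1))
        expected = (2 * np.log(2) - 2 - np.log(2)) + (-1.0)
        got = log_likelihood(t, pw, pb, ModelSpec(("age",)))
        assert got == pytest.approx(expected)

    def test_matches_brute_force_on_fixture(self, bundled):
        rng = np.random.default_rng(0)

        def rand_params():
            age = rng.normal(0, 0.3, 7)
            coh = rng.normal(0, 0.3, 11)
            return StratumParams(mu=rng.normal(-5.4, 0.2),
                                 age=age - age.mean(),
                                 cohort=coh - coh.mean(),
                                 sigma_age=0.4, sigma_cohort=0.3)

        pw, pb = rand_params(), rand_params()
        # independent re-summation with scipy's Poisson pmf
        expected = 0.0
        for s, pr in enumerate((pw, pb)):
            for a in range(7):
                for p in range(5):
                    lam = np.exp(linear_predictor(pr, AC, a, p))
                    n = bundled.exposure[s, a, p]
                    expected += poisson.logpmf(bundled.deaths[s, a, p], n * lam)
        got = log_likelihood(bundled, pw, pb, AC)
        assert got == pytest.approx(expected, rel=1e-10)


class TestLogPrior:
    def test_unit_jump_costs_half(self):
        """An effect with one unit RW1 jump at sigma = 1 is exp(-1/2) less
        likely than the flat vector."""
        flat = StratumParams(mu=0.0, age=np.zeros(7), sigma_age=1.0)
        jump_v = np.zeros(7)
        jump_v[6] = 1.0
        jump = StratumParams(mu=0.0, age=jump_v - jump_v.mean(), sigma_age=1.0)
        spec = ModelSpec(("age",))
        diff = log_prior((7, 5), jump, spec) - log_prior((7, 5), flat, spec)
        assert diff == pytest.approx(-0.5)

    def test_rejects_nonpositive_sigma(self):
        p = StratumParams(mu=0.0, age=np.zeros(7), sigma_age=0.0)
        with pytest.raises(ValueError):
            log_prior((7, 5), p, ModelSpec(("age",)))

    def test_joint_log_prob_matches_independent_recomputation(self, bundled):
        """Sampler target = likelihood + RW1 priors + hyperpriors + the
        log-sigma Jacobian, recomputed from scratch with scipy."""
        rng = np.random.default_rng(1)
        post = JointPosterior(bundled, AC)
        params = []
        for _ in range(2):
            age = rng.normal(0, 0.3, 7)
            coh = rng.normal(0, 0.3, 11)
            params.append(StratumParams(
                mu=rng.normal(-5.4, 0.2), age=age - age.mean(),
                cohort=coh - coh.mean(),
                sigma_age=float(rng.uniform(0.2, 0.8)),
                sigma_cohort=float(rng.uniform(0.2, 0.8))))
        theta = post.layout.pack(tuple(params))

        expected = 0.0
        for s, pr in enumerate(params):
            for a in range(7):
                for p in range(5):
                    lam = np.exp(linear_predictor(pr, AC, a, p))
                    n = bundled.exposure[s, a, p]
                    expected += poisson.logpmf(bundled.deaths[s, a, p], n * lam)
            expected += norm.logpdf(pr.mu, 0, 10)
            for name in ("age", "cohort"):
                sig = pr.sigma(name)
                expected += norm.logpdf(np.diff(pr.effect(name)), 0, sig).sum()
                expected += halfnorm.logpdf(sig) + np.log(sig)
        assert float(post.log_prob(theta)) == pytest.approx(expected, rel=1e-10)


class TestPackUnpack:
    def test_round_trip(self, bundled):
        post = JointPosterior(bundled, AC)
        rng = np.random.default_rng(2)
        age = rng.normal(0, 0.5, 7)
        coh = rng.normal(0, 0.5, 11)
        pw = StratumParams(mu=-5.0, age=age - age.mean(),
                           cohort=coh - coh.mean(),
                           sigma_age=0.4, sigma_cohort=0.25)
        theta = post.layout.pack((pw, pw))
        back = post.layout.unpack(theta, 0)
        assert back.mu == pytest.approx(pw.mu)
        assert np.allclose(back.age, pw.age)
        assert np.allclose(back.cohort, pw.cohort)
        assert back.sigma_age == pytest.approx(0.4)

    def test_pack_rejects_uncentered_effects(self, bundled):
        post = JointPosterior(bundled, AC)
        bad = StratumParams(mu=0.0, age=np.ones(7), cohort=np.zeros(11),
                            sigma_age=1.0, sigma_cohort=1.0)
        with pytest.raises(ValueError, match="sum to zero"):
            post.layout.pack((bad, bad))


class TestSamplerCorrectness:
    def test_single_cell_posterior_matches_quadrature(self, quiet):
        """Intercept-only posterior vs dense 1-D numerical quadrature."""
        t = single_cell_table(d=(7, 2), n=(2000, 500))
        spec = ModelSpec(("age",))      # one age level -> intercept only
        draws = fit(t, spec, MCMCConfig(chains=2, warmup=300, steps=1500,
                                        thin=1, seed=3))
        grid = np.linspace(-12, -1, 40001)
        for s, (d, n) in enumerate(((7, 2000), (2, 500))):
            logp = (norm.logpdf(grid, 0, 10)
                    + d * (grid + np.log(n)) - n * np.exp(grid))
            w = np.exp(logp - logp.max())
            w /= w.sum()
            exact_mean = float((grid * w).sum())
            mu = draws.mu(s)
            mcse = mu.std() / np.sqrt(max(len(mu) / 10, 1.0))
            assert abs(mu.mean() - exact_mean) < 2 * max(mcse, 1e-3)

    def test_toy_grid_posterior_matches_quadrature(self, quiet):
        """2-age x 2-period model with fixed RW scales: MCMC moments match a
        dense 3-D grid quadrature, stratum by stratum."""
        deaths = np.array([[[6, 4], [10, 8]], [[3, 2], [5, 9]]])
        n = np.array([[[1500, 1600], [2400, 2600]], [[700, 650], [900, 1100]]])
        t = CountsTable(deaths=deaths, births=n - deaths,
                        age_labels=("15-19", "20-24"), years=(1995, 2000))
        spec = ModelSpec(("age", "period"))
        fixed = {"age": 0.5, "period": 0.5}
        draws = fit(t, spec, MCMCConfig(chains=2, warmup=300, steps=2000,
                                        thin=1, seed=4),
                    fixed_sigmas=fixed)

        gm = np.linspace(-8.5, -3.5, 161)
        gw = np.linspace(-1.6, 1.6, 161)
        for s in range(2):
            MU, WA, WP = np.meshgrid(gm, gw, gw, indexing="ij")
            logp = (norm.logpdf(MU, 0, 10) + norm.logpdf(WA, 0, 0.5)
                    + norm.logpdf(WP, 0, 0.5))
            for a in range(2):
                for p in range(2):
                    eta = MU + (a - 0.5) * WA + (p - 0.5) * WP
                    lam = n[s, a, p] * np.exp(eta)
                    logp += deaths[s, a, p] * np.log(lam) - lam
            w = np.exp(logp - logp.max())
            w /= w.sum()
            exact = {"mu": float((MU * w).sum()),
                     "wa": float((WA * w).sum()),
                     "wp": float((WP * w).sum())}
            got = {"mu": draws.mu(s),
                   "wa": draws.effect(s, "age")[:, 1] - draws.effect(s, "age")[:, 0],
                   "wp": draws.effect(s, "period")[:, 1] - draws.effect(s, "period")[:, 0]}
            for key, samples in got.items():
                mcse = samples.std() / np.sqrt(max(len(samples) / 10, 1.0))
                assert abs(samples.mean() - exact[key]) < 2 * max(mcse, 2e-3), key

    def test_age_model_recovers_pooled_rates(self, bundled, quiet):
        """In the age-only model the fitted exp(mu + alpha_a) should sit
        near each stratum's crude rate pooled over periods (the flat-prior
        limit), tightly so where exposure is large."""
        draws = fit(bundled, ModelSpec(("age",)), QUICK)
        for s in range(2):
            fitted = np.exp(draws.mu(s)[:, None] + draws.effect(s, "age"))
            med = np.median(fitted, axis=0)
            pooled = (bundled.deaths[s].sum(axis=1)
                      / bundled.exposure[s].sum(axis=1))
            big = bundled.exposure[s].sum(axis=1) > 10000
            assert np.allclose(med[big], pooled[big], rtol=0.05)
            # sparse edge ages are smoothed toward neighbours, but never by
            # more than a factor ~2 on these data
            assert np.all(np.abs(np.log(med / pooled)) < np.log(2.2))

    def test_same_seed_is_bit_reproducible(self, bundled, quiet):
        cfg = MCMCConfig(chains=2, warmup=100, steps=300, thin=1, seed=11)
        d1 = fit(bundled, AC, cfg)
        d2 = fit(bundled, AC, cfg)
        assert np.array_equal(d1.theta, d2.theta)

    def test_flat_table_gives_null_effects(self, quiet):
        """Identical cells in every stratum leave nothing for the effects
        to explain; exp-scale summaries concentrate at 1."""
        deaths = np.full((2, 7, 5), 5)
        births = np.full((2, 7, 5), 995)
        t = CountsTable(deaths=deaths, births=births)
        draws = fit(t, AC, QUICK)
        summ = effect_summary(draws)
        assert np.all(np.abs(summ["median"] - 1.0) < 0.12)

    def test_bigger_exposures_tighten_intervals(self, quiet):
        """100-fold exposures shrink posterior uncertainty on data where
        every cell carries two-sided information.  (A cell with zero
        observed deaths only bounds its rate from above, so its effect
        level keeps a prior-determined lower tail at any exposure; the
        synthetic tables used here have no such cells at the large scale.)"""
        from apcmort.simulate import default_truth, generate
        cfg = default_truth(AC)
        rich_cfg = type(cfg)(params_white=cfg.params_white,
                             params_blue=cfg.params_blue,
                             exposure=cfg.exposure * 100)
        base = fit(generate(cfg, AC, 12), AC, QUICK)
        rich = fit(generate(rich_cfg, AC, 12), AC, QUICK)
        for s in range(2):
            for e in ("age", "cohort"):
                w_base = np.diff(np.quantile(base.effect(s, e),
                                             [0.025, 0.975], axis=0), axis=0)
                w_rich = np.diff(np.quantile(rich.effect(s, e),
                                             [0.025, 0.975], axis=0), axis=0)
                assert np.all(w_rich < w_base)


class TestEffectSummary:
    def test_degenerate_draws_collapse_interval(self, bundled):
        post = JointPosterior(bundled, AC)
        age = np.linspace(-0.3, 0.3, 7)
        age -= age.mean()
        coh = np.zeros(11)
        p = StratumParams(mu=-5.0, age=age, cohort=coh,
                          sigma_age=0.4, sigma_cohort=0.2)
        theta = post.layout.pack((p, p))
        rep = np.tile(theta, (2, 50, 1))
        draws = PosteriorDraws(posterior=post, theta=rep,
                               log_lik_draws=post.log_lik(rep))
        summ = effect_summary(draws)
        age_rows = summ[(summ.worker_type == "white_collar")
                        & (summ.dimension == "age")]
        assert np.allclose(age_rows["median"], np.exp(age))
        assert np.allclose(age_rows["lower"], age_rows["upper"])

    def test_shape_and_labels(self, ac_fit):
        summ = effect_summary(ac_fit)
        assert len(summ) == 2 * (7 + 11)
        assert set(summ.dimension) == {"age", "cohort"}
        assert (summ.lower <= summ["median"]).all()
        assert (summ["median"] <= summ.upper).all()
        assert (summ.lower > 0).all()


class TestConstraints:
    def test_sum_to_zero_every_draw(self, ac_fit):
        for s in range(2):
            for e in ("age", "cohort"):
                sums = ac_fit.effect(s, e).sum(axis=1)
                assert np.max(np.abs(sums)) < 1e-8

    def test_convergence_contract_reported(self, ac_fit):
        d = ac_fit.diagnostics
        assert d["max_rhat"] < 1.01
        assert d["ess"] >= 400
        assert ac_fit.converged
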