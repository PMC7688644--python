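"""Second level: PEB, Bayesian model reduction, GLM search, statistics."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.stats import multivariate_normal as mvn

from lamcsd.group import (GroupDesign, bmr, bonferroni, glm_search,
                          partial_correlation, peb_fit, spearman)
from lamcsd.inversion import Posterior, PriorDensity, default_priors


def _posterior_from(mean, cov, names):
    changes = {n: float(m) for n, m in zip(names, mean)}
    return Posterior(names=tuple(names), mean=np.asarray(mean, float),
                     cov=np.asarray(cov, float), free_energy=0.0,
                     f_trace=np.zeros(1), predictions=[], variance_explained=1.0,
                     connection_changes=changes, converged=True, log_precision=0.0)


def _synthetic_posteriors(rng, n, beta=0.0, sd=0.05, post_sd=0.08):
    """Subject 'posteriors' over the 10 connection latents with a planted slope."""
    prior = default_priors(include_q=False)
    names = prior.names[:10]
    z = rng.normal(0, 1, n)
    z = (z - z.mean()) / z.std()
    posts, X = [], np.column_stack([np.ones(n), z])
    for i in range(n):
        truth = rng.normal(0, sd, 10)
        truth[9] += beta * z[i]  # a22 is the last canonical connection
        mean = truth + rng.normal(0, post_sd, 10)
        posts.append(_posterior_from(mean, post_sd**2 * np.eye(10), names))
    return posts, X, prior


class TestPEB:
    def test_single_subject_identity(self, rng):
        prior = default_priors(include_q=False)
        names = prior.names[:10]
        mean = rng.normal(0, 0.1, 10)
        post = _posterior_from(mean, 0.01 * np.eye(10), names)
        res = peb_fit([post], np.array([[1.0]]), prior=prior,
                      param_names=names, beta_prior_var=1e6, optimize_gamma=False,
                      gamma=-np.log(1e-8))
        # flat second-level prior, negligible between-subject noise: betas = mean
        assert np.allclose(res.beta_mean[0], mean, atol=1e-3)

    def test_recovers_planted_slope(self, rng):
        posts, X, prior = _synthetic_posteriors(rng, 16, beta=0.4)
        res = peb_fit(posts, X, prior=prior, param_names=prior.names[:10])
        i = res.beta_index("x1", "a22")
        b = res.beta_mean.ravel()[i]
        sd = np.sqrt(res.beta_cov[i, i])
        assert abs(b - 0.4) < 2 * sd + 0.1
        assert b > 0.2

    def test_null_slopes_stay_small(self):
        within = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            posts, X, prior = _synthetic_posteriors(rng, 12, beta=0.0)
            res = peb_fit(posts, X, prior=prior, param_names=prior.names[:10])
            bet = res.beta_mean[1]
            sds = np.sqrt(np.diag(res.beta_cov)[10:])
            within.extend(np.abs(bet) <= 2 * sds)
        # recovered covariate betas stay within 2 posterior SDs of zero
        assert np.mean(within) >= 0.9

    def test_rank_deficient_design_rejected(self, rng):
        posts, X, prior = _synthetic_posteriors(rng, 6)
        bad = np.column_stack([X[:, 0], X[:, 0]])
        with pytest.raises(ValueError, match="rank"):
            peb_fit(posts, bad, prior=prior, param_names=prior.names[:10])


class TestBMR:
    def test_identity_reduction(self, rng):
        mu = rng.normal(size=3)
        C = np.diag(rng.uniform(0.5, 1.0, 3))
        m0, S0 = np.zeros(3), np.eye(3)
        dF, mr, Cr = bmr(mu, C, m0, S0, m0, S0)
        assert dF == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(mr, mu) and np.allclose(Cr, C)

    def test_one_dimensional_conjugate_case(self):
        # y = theta + e, e ~ N(0, s2); evidence ratio computable by hand
        y, s2 = 0.7, 0.2
        v0, vr = 1.0, 0.01
        post_var = 1 / (1 / s2 + 1 / v0)
        post_mean = post_var * y / s2
        dF, _, _ = bmr(np.array([post_mean]), np.array([[post_var]]),
                       np.zeros(1), np.array([[v0]]),
                       np.zeros(1), np.array([[vr]]))
        lz0 = stats.norm.logpdf(y, 0, np.sqrt(s2 + v0))
        lzr = stats.norm.logpdf(y, 0, np.sqrt(s2 + vr))
        assert dF == pytest.approx(lzr - lz0, abs=1e-10)

    def test_matches_explicit_refit_on_toys(self, rng):
        worst = 0.0
        for _ in range(25):
            p, nobs = 3, 7
            A = rng.normal(size=(nobs, p))
            m0 = 0.3 * rng.normal(size=p)
            S0 = np.diag(rng.uniform(0.3, 1.0, p))
            R = np.diag(rng.uniform(0.1, 0.6, nobs))
            y = rng.normal(size=nobs)
            P = A.T @ np.linalg.inv(R) @ A + np.linalg.inv(S0)
            C = np.linalg.inv(P)
            mu = C @ (A.T @ np.linalg.inv(R) @ y + np.linalg.inv(S0) @ m0)
            mr = np.zeros(p)
            Sr = S0.copy()
            Sr[0, 0] = 1e-8
            dF, _, _ = bmr(mu, C, m0, S0, mr, Sr)
            oracle = (mvn.logpdf(y, A @ mr, A @ Sr @ A.T + R)
                      - mvn.logpdf(y, A @ m0, A @ S0 @ A.T + R))
            worst = max(worst, abs(dF - oracle))
        assert worst < 1e-3

    def test_non_psd_input_rejected(self):
        with pytest.raises(ValueError):
            bmr(np.zeros(2), -np.eye(2), np.zeros(2), np.eye(2),
                np.zeros(2), np.eye(2))


class TestGLMSearch:
    def test_scores_all_1024_candidates(self, rng):
        posts, X, prior = _synthetic_posteriors(rng, 12)
        res = peb_fit(posts, X, prior=prior, param_names=prior.names[:10])
        gs = glm_search(res)
        assert len(gs.candidates) == 1024

    def test_bayes_factor_to_probability(self):
        from lamcsd.group import GLMCandidate
        c = GLMCandidate(("a22",), 0.0, 20.0, 0.1)
        assert c.prob_vs_null == pytest.approx(20 / 21)

    def test_null_candidate_is_its_own_reference(self, rng):
        posts, X, prior = _synthetic_posteriors(rng, 12)
        res = peb_fit(posts, X, prior=prior, param_names=prior.names[:10])
        gs = glm_search(res)
        null = next(c for c in gs.candidates if not c.connections)
        assert null.bf_vs_null == pytest.approx(1.0)

    def test_detects_planted_a22(self, rng):
        posts, X, prior = _synthetic_posteriors(rng, 16, beta=0.4)
        res = peb_fit(posts, X, prior=prior, param_names=prior.names[:10])
        gs = glm_search(res)
        assert gs.top_connection == "a22"
        assert gs.inclusion_prob["a22"] > 0.95


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1])[0] == pytest.approx(-1.0)
        assert spearman([1, 2, 3, 4], [1, 2, 3, 4])[0] == pytest.approx(1.0)

    def test_exact_p_matches_enumeration(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        rho, p = spearman(x, y, method="exact")
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        obs = abs(stats.spearmanr(x, y).statistic)
        count = sum(abs(stats.spearmanr(rx[list(perm)], ry).statistic) >= obs - 1e-12
                    for perm in itertools.permutations(range(5)))
        assert p == pytest.approx(count / 120)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestPartialCorrelation:
    def test_empty_controls_equal_pearson(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        r, p = partial_correlation(x, y)
        rr, pp = stats.pearsonr(x, y)
        assert r == pytest.approx(rr) and p == pytest.approx(pp, rel=1e-6)

    def test_first_order_identity(self, rng):
        z = rng.normal(size=40)
        x = 0.6 * z + rng.normal(size=40)
        y = -0.4 * z + rng.normal(size=40)
        rxy = stats.pearsonr(x, y)[0]
        rxz = stats.pearsonr(x, z)[0]
        rzy = stats.pearsonr(z, y)[0]
        expect = (rxy - rxz * rzy) / np.sqrt((1 - rxz**2) * (1 - rzy**2))
        r, _ = partial_correlation(x, y, z)
        assert r == pytest.approx(expect, abs=1e-10)

    def test_degenerate_y_in_span_rejected(self, rng):
        z = rng.normal(size=10)
        y = 2.0 * z + 1.0
        x = rng.normal(size=10)
        with pytest.raises(ValueError, match="degenerate"):
            partial_correlation(x, y, z)

    def test_collinear_controls_rejected(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        z = rng.normal(size=10)
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(x, y, np.column_stack([z, 2 * z]))


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expect,significant", [
        (0.004, 10, 0.04, True),
        (0.017, 10, 0.17, False),
        (0.003, 10, 0.03, True),
    ])
    def test_adjustment(self, p, m, expect, significant):
        adj = bonferroni([p], m)[0]
        assert adj == pytest.approx(expect)
        assert (adj < 0.05) == significant

    def test_caps_at_one(self):
        assert bonferroni([0.3], 10)[0] == 1.0

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            bonferroni([1.2], 3)


class TestGroupDesign:
    def test_centred_standardized_covariates(self, rng):
        import pandas as pd
        t = pd.DataFrame({"subject_id": [f"s{i}" for i in range(8)],
                          "v1_size_mm2": rng.lognormal(7.6, 0.3, 8)})
        d = GroupDesign.from_covariates(t, ["v1_size_mm2"])
        assert np.allclose(d.X[:, 0], 1.0)
        assert d.X[:, 1].mean() == pytest.approx(0.0, abs=1e-12)
        assert d.X[:, 1].std() == pytest.approx(1.0)
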