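"""Second-level (between-subject) analysis.

A parametric-empirical-Bayes (PEB) hierarchical model explains the subjects'
connection latents as a group-level GLM, ``theta_i = (x_i (x) I) beta + eps``,
propagating each subject's full posterior covariance rather than point
estimates.  Bayesian model reduction (BMR) then scores, analytically and
without refitting, every reduced prior in which some connections are excluded
as predictors of a covariate — 2^10 = 1024 candidate GLMs over the ten
connections.  Classical Spearman/partial-correlation/Bonferroni statistics on
the posterior connection changes complement the Bayesian scores.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .circuit import CONNECTION_NAMES
from .config import default_config
from .inversion import Posterior, PriorDensity

logger = logging.getLogger(__name__)

__all__ = [
    "GroupDesign",
    "GLMCandidate",
    "PEBResult",
    "PEB",
    "peb_fit",
    "bmr",
    "glm_search",
    "GLMSearchResult",
    "spearman",
    "partial_correlation",
    "bonferroni",
    "connection_correlation_table",
]


@dataclass
class GroupDesign:
    """Second-level design matrix (constant column first, covariates centred)."""

    X: np.ndarray
    regressors: tuple[str, ...]
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.regressors = tuple(self.regressors)
        self.subject_ids = tuple(self.subject_ids)
        n, r = self.X.shape
        if n != len(self.subject_ids) or r != len(self.regressors):
            raise ValueError("design dimensions do not match labels")
        if np.linalg.matrix_rank(self.X) < r:
            raise ValueError("design matrix is rank deficient")

    @classmethod
    def from_covariates(cls, table: pd.DataFrame,
                        columns: Sequence[str],
                        standardize: bool = True) -> "GroupDesign":
        """Constant column plus mean-centred (and unit-scaled) covariates."""
        cols = [np.ones(len(table))]
        for c in columns:
            v = np.asarray(table[c], dtype=float)
            if np.any(~np.isfinite(v)):
                raise ValueError(f"covariate {c!r} contains non-finite values")
            v = v - v.mean()
            if standardize:
                sd = v.std()
                if sd == 0:
                    raise ValueError(f"covariate {c!r} is constant")
                v = v / sd
            cols.append(v)
        return cls(np.column_stack(cols), ("const", *columns),
                   tuple(table["subject_id"].astype(str)))


@dataclass
class PEBResult:
    """Posterior over second-level GLM parameters beta (regressors x connections)."""

    beta_mean: np.ndarray          # (r, p)
    beta_cov: np.ndarray           # (r*p, r*p), row-major over (regressor, connection)
    param_names: tuple[str, ...]
    regressors: tuple[str, ...]
    free_energy: float
    gamma: float                   # between-subject log precision
    prior_mean: np.ndarray
    prior_cov: np.ndarray

    def beta_index(self, regressor: str, param: str) -> int:
        r = self.regressors.index(regressor)
        p = self.param_names.index(param)
        return r * len(self.param_names) + p


def _subject_blocks(posteriors: Sequence[Posterior],
                    prior: PriorDensity,
                    names: Sequence[str]):
    """Marginal (mean, cov) per subject plus the matching first-level prior block."""
    mus, covs = [], []
    for post in posteriors:
        m, c = post.marginal(names)
        mus.append(m)
        covs.append(c)
    idx = [prior.names.index(n) for n in names]
    return np.array(mus), np.array(covs), prior.mean[idx], prior.cov[np.ix_(idx, idx)]


def _peb_free_energy(mus, covs, m0, S0, X, gamma, beta_prior_cov):
    """Closed-form second-level evidence and beta posterior for fixed gamma.

    Summary-statistic hierarchical model: each subject's posterior mean is a
    Gaussian observation of its latent effects with the subject's full
    posterior covariance plus the between-subject covariance e^-gamma I,
    ``mu_i ~ N(X_i beta, Sigma_i + e^-gamma I)``.  With a Gaussian prior on
    beta everything is conjugate; the exact log evidence is returned.
    """
    n, p = mus.shape
    r = X.shape[1]
    Sb = np.exp(-gamma) * np.eye(p)   # between-subject covariance
    A = np.zeros((r * p, r * p))
    h = np.zeros(r * p)
    const = 0.0
    for i in range(n):
        Vi = covs[i] + Sb
        Wi = np.linalg.inv(Vi)
        Xi = np.kron(X[i], np.eye(p))  # theta_i = Xi beta
        A += Xi.T @ Wi @ Xi
        h += Xi.T @ (Wi @ mus[i])
        _, logdet_Vi = np.linalg.slogdet(Vi)
        const += -0.5 * (logdet_Vi + p * np.log(2 * np.pi) + mus[i] @ Wi @ mus[i])
    Pb = np.linalg.inv(beta_prior_cov)
    Apost = A + Pb
    beta = np.linalg.solve(Apost, h)
    _, logdet_Apost = np.linalg.slogdet(Apost)
    _, logdet_Pb = np.linalg.slogdet(Pb)
    F = const + 0.5 * (h @ beta) + 0.5 * (logdet_Pb - logdet_Apost)
    return F, beta, np.linalg.inv(Apost)


class PEB(BaseEstimator):
    """Parametric empirical Bayes over subject posteriors.

    ``fit(posteriors, X)`` estimates a Gaussian posterior over the GLM
    parameters linking the design matrix to the subjects' connection latents,
    optimizing (or fixing) a scalar between-subject log precision ``gamma``.
    """

    def __init__(self,
                 prior: PriorDensity | None = None,
                 param_names: Sequence[str] | None = None,
                 beta_prior_var: float | None = None,
                 optimize_gamma: bool | None = None,
                 gamma: float | None = None,
                 config: Mapping | None = None):
        self.prior = prior
        self.param_names = param_names
        self.beta_prior_var = beta_prior_var
        self.optimize_gamma = optimize_gamma
        self.gamma = gamma
        self.config = config

    def fit(self, posteriors: Sequence[Posterior],
            X: np.ndarray | GroupDesign) -> "PEB":
        cfg = dict(default_config(), **(self.config or {}))
        design = X if isinstance(X, GroupDesign) else GroupDesign(
            np.atleast_2d(np.asarray(X, float)),
            tuple(f"x{j}" for j in range(np.atleast_2d(np.asarray(X, float)).shape[1])),
            tuple(f"sub{i}" for i in range(len(posteriors))))
        if design.X.shape[0] != len(posteriors):
            raise ValueError("one design row per subject posterior required")
        names = tuple(self.param_names or CONNECTION_NAMES)
        prior = self.prior
        if prior is None:
            from .inversion import default_priors
            prior = default_priors(config=self.config)
        mus, covs, m0, S0 = _subject_blocks(posteriors, prior, names)
        p, r = len(names), design.X.shape[1]
        bvar = float(cfg["peb_beta_prior_var"] if self.beta_prior_var is None
                     else self.beta_prior_var)
        beta_prior_cov = bvar * np.eye(r * p)

        def neg_f(g):
            return -_peb_free_energy(mus, covs, m0, S0, design.X, g, beta_prior_cov)[0]

        opt = cfg["peb_optimize_gamma"] if self.optimize_gamma is None else self.optimize_gamma
        if opt:
            res = optimize.minimize_scalar(neg_f, bounds=(-2.0, 12.0), method="bounded",
                                           options={"xatol": 1e-3})
            gamma = float(res.x)
        else:
            gamma = float(cfg["peb_gamma"] if self.gamma is None else self.gamma)
        F, beta, beta_cov = _peb_free_energy(mus, covs, m0, S0, design.X, gamma,
                                             beta_prior_cov)
        self.result_ = PEBResult(
            beta_mean=beta.reshape(r, p), beta_cov=beta_cov,
            param_names=names, regressors=design.regressors,
            free_energy=float(F), gamma=gamma,
            prior_mean=np.zeros(r * p), prior_cov=beta_prior_cov)
        self.free_energy_ = float(F)
        logger.info("PEB: F=%.2f gamma=%.2f (between-subject SD %.3f)",
                    F, gamma, np.exp(-gamma / 2.0))
        return self


def peb_fit(posteriors: Sequence[Posterior],
            X: np.ndarray | GroupDesign,
            prior: PriorDensity | None = None,
            **kwargs) -> PEBResult:
    """Functional wrapper over :class:`PEB`."""
    est = PEB(prior=prior, **kwargs)
    est.fit(posteriors, X)
    return est.result_


def bmr(post_mean: np.ndarray, post_cov: np.ndarray,
        prior_mean: np.ndarray, prior_cov: np.ndarray,
        red_mean: np.ndarray, red_cov: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Bayesian model reduction: evidence change and posterior under a reduced prior.

    Closed-form Gaussian identity: with full prior p0, full posterior q and
    reduced prior pr, the reduced evidence satisfies
    ``dF = log int q(t) pr(t) / p0(t) dt``.  Returns (dF, reduced mean,
    reduced covariance).  Raises on non-positive-definite inputs.
    """
    P = _inv_psd(post_cov, "posterior covariance")
    P0 = _inv_psd(prior_cov, "prior covariance")
    Pr = _inv_psd(red_cov, "reduced prior covariance")
    Pn = P + Pr - P0
    w = np.linalg.eigvalsh(Pn)
    if np.min(w) <= 0:
        raise ValueError("reduced posterior precision is not positive definite")
    mu_n = np.linalg.solve(Pn, P @ post_mean + Pr @ red_mean - P0 @ prior_mean)
    _, ld_P = np.linalg.slogdet(P)
    _, ld_P0 = np.linalg.slogdet(P0)
    _, ld_Pr = np.linalg.slogdet(Pr)
    _, ld_Pn = np.linalg.slogdet(Pn)
    quad = (mu_n @ Pn @ mu_n - post_mean @ P @ post_mean
            - red_mean @ Pr @ red_mean + prior_mean @ P0 @ prior_mean)
    dF = 0.5 * (ld_P + ld_Pr - ld_P0 - ld_Pn) + 0.5 * quad
    return float(dF), mu_n, np.linalg.inv(Pn)


def _inv_psd(C: np.ndarray, what: str) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    w = np.linalg.eigvalsh(0.5 * (C + C.T))
    if np.min(w) <= 0:
        raise ValueError(f"{what} is not positive definite")
    return np.linalg.inv(0.5 * (C + C.T))


@dataclass
class GLMCandidate:
    """One scored GLM: which connections predict the covariate."""

    connections: tuple[str, ...]
    free_energy: float        # dF relative to the full model's prior
    bf_vs_null: float
    posterior_prob: float     # within the searched model space

    @property
    def prob_vs_null(self) -> float:
        return self.bf_vs_null / (1.0 + self.bf_vs_null)


@dataclass
class GLMSearchResult:
    candidates: list[GLMCandidate]
    inclusion_prob: dict[str, float]   # Bayesian-model-averaged per connection
    inclusion_bf: dict[str, float]
    covariate: str

    @property
    def top(self) -> GLMCandidate:
        return self.candidates[0]

    @property
    def top_connection(self) -> str:
        return max(self.inclusion_prob, key=self.inclusion_prob.get)


def glm_search(peb: PEBResult,
               covariate: str | int = 1,
               connections: Sequence[str] | None = None,
               excluded_var: float | None = None,
               config: Mapping | None = None) -> GLMSearchResult:
    """Exhaustively score all subsets of connections as covariate predictors.

    Every reduced model shrinks the prior variance of the covariate betas of
    the *excluded* connections to ~0 (soft exclusion), scored analytically by
    BMR from the full PEB posterior; connection-wise inclusion probabilities
    are Bayesian model averages over all 2^k candidates.
    """
    cfg = dict(default_config(), **(config or {}))
    ev = float(cfg["peb_excluded_var"] if excluded_var is None else excluded_var)
    conns = tuple(connections or peb.param_names)
    k = len(conns)
    cov_name = (peb.regressors[covariate] if isinstance(covariate, int) else covariate)
    beta_idx = np.array([peb.beta_index(cov_name, c) for c in conns])
    mean = peb.beta_mean.ravel()
    base_var = np.diag(peb.prior_cov).copy()

    dFs = np.empty(2 ** k)
    subsets = []
    for m, incl in enumerate(itertools.product([True, False], repeat=k)):
        red_var = base_var.copy()
        off = beta_idx[~np.array(incl)]
        red_var[off] = ev
        dF, _, _ = bmr(mean, peb.beta_cov, peb.prior_mean, peb.prior_cov,
                       np.zeros_like(mean), np.diag(red_var))
        dFs[m] = dF
        subsets.append(tuple(c for c, i in zip(conns, incl) if i))
    null_idx = next(i for i, s in enumerate(subsets) if not s)
    probs = np.exp(dFs - dFs.max())
    probs /= probs.sum()
    incl_prob = {}
    for j, c in enumerate(conns):
        incl_prob[c] = float(sum(p for s, p in zip(subsets, probs) if c in s))
    incl_bf = {c: (p / (1.0 - p) if p < 1.0 else math.inf) for c, p in incl_prob.items()}
    order = np.argsort(-dFs)
    candidates = [GLMCandidate(connections=subsets[i],
                               free_energy=float(dFs[i]),
                               bf_vs_null=float(np.exp(dFs[i] - dFs[null_idx])),
                               posterior_prob=float(probs[i]))
                  for i in order]
    return GLMSearchResult(candidates=candidates, inclusion_prob=incl_prob,
                           inclusion_bf=incl_bf, covariate=cov_name)


# ---------------------------------------------------------------------------
# classical statistics
# ---------------------------------------------------------------------------

def spearman(x: Sequence[float], y: Sequence[float],
             method: str = "auto",
             exact_max_n: int | None = None) -> tuple[float, float]:
    """Spearman rank correlation with exact permutation p at small n.

    ``method``: "exact" enumerates all n! permutations (two-sided p as the
    fraction with |rho| >= |observed|), "asymptotic" uses the t approximation,
    "auto" switches at the configured sample size.  Ties are mid-ranked.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 4:
        raise ValueError("need two equal-length vectors with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has no rank correlation")
    nmax = int(default_config()["spearman_exact_max_n"] if exact_max_n is None
               else exact_max_n)
    n = len(x)
    rho = float(stats.spearmanr(x, y).statistic)
    if method == "asymptotic" or (method == "auto" and n > nmax):
        return rho, float(stats.spearmanr(x, y).pvalue)
    if method not in ("auto", "exact"):
        raise ValueError(f"unknown method {method!r}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    obs = abs(float(rx @ ry) / n)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = abs(float(rx[list(perm)] @ ry) / n)
        count += r >= obs - 1e-12
        total += 1
    return rho, count / total


def partial_correlation(x: Sequence[float], y: Sequence[float],
                        Z: np.ndarray | None = None) -> tuple[float, float]:
    """Correlation of x and y after regressing both on Z (with intercept).

    The p-value uses the t distribution with n - 2 - k degrees of freedom for
    k controlling columns; with empty Z this is the plain Pearson test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if Z is None or (hasattr(Z, "size") and np.asarray(Z).size == 0):
        Zm = np.ones((n, 1))
        k = 0
    else:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[0] != n:
            Z = Z.T
        Zm = np.column_stack([np.ones(n), Z])
        k = Z.shape[1]
        if np.linalg.matrix_rank(Zm) < Zm.shape[1]:
            raise ValueError("collinear control variables")
    if n <= k + 2:
        raise ValueError("need n > number of controls + 2")
    rx = x - Zm @ np.linalg.lstsq(Zm, x, rcond=None)[0]
    ry = y - Zm @ np.linalg.lstsq(Zm, y, rcond=None)[0]
    if np.allclose(ry, 0, atol=1e-12) or np.allclose(rx, 0, atol=1e-12):
        raise ValueError("degenerate residuals: a variable is fully explained by Z")
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    df = n - 2 - k
    r_ = min(max(r, -0.9999999999), 0.9999999999)
    t = r_ * math.sqrt(df / (1.0 - r_ * r_))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def bonferroni(pvals: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, m * p)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = int(m if m is not None else len(p))
    return np.minimum(1.0, m * p)


def connection_correlation_table(posteriors: Sequence[Posterior],
                                 covariates: pd.DataFrame,
                                 covariate: str,
                                 m_tests: int | None = None) -> pd.DataFrame:
    """Spearman + partial correlations of each connection change with a covariate.

    Partial correlations control for the remaining nine connection changes;
    Bonferroni correction defaults to the number of connections tested.
    """
    changes = np.array([[p.connection_changes[c] for c in CONNECTION_NAMES]
                        for p in posteriors])
    v = np.asarray(covariates[covariate], dtype=float)
    rows = []
    for j, c in enumerate(CONNECTION_NAMES):
        rho, pval = spearman(changes[:, j], v)
        Z = np.delete(changes, j, axis=1)
        try:
            pr, pp = partial_correlation(changes[:, j], v, Z)
        except ValueError:
            pr, pp = np.nan, np.nan
        rows.append({"connection": c, "rho": rho, "p": pval,
                     "partial_r": pr, "partial_p": pp})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bonferroni(out["p"].to_numpy(),
                                   m_tests if m_tests is not None else len(CONNECTION_NAMES))
    return out
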