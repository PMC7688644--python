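"""Variational-Laplace inversion of the spectral forward model.

The observed (cross-)spectrum is explained by latent parameters acting on the
canonical model: log-scaling coefficients on the ten connection strengths and
on the four noise densities (so positivity is structural), additive offsets on
the population weights Q, and per-condition log-offsets on connections (the
"B" effects) when several stimulus conditions are fitted simultaneously.
A Gaussian prior over latents is centred at zero, i.e. at the canonical
(tabulated) physical values.

Fitting maximizes a free-energy bound on the log model evidence with a
Gaussian variational density q(theta) = N(mu, Sigma): an E-step performs
Levenberg-regularized Gauss-Newton updates of mu (accepting only steps that
increase the bound), and an M-step updates the scalar log-precision of the
observation noise.  The free energy is the usual Gaussian accuracy term minus
the KL divergence of the posterior from the prior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .circuit import CANONICAL_STRENGTHS, CONNECTION_NAMES, MassParameters, coupling_matrix
from .config import POPULATIONS, default_config
from .spectral import CrossSpectrum, SpectralParameters, _resolvent_gain, noise_spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "PriorDensity",
    "ConditionDesign",
    "Posterior",
    "LatentModel",
    "default_priors",
    "apply_latents",
    "gaussian_kl",
    "free_energy",
    "variance_explained",
    "CrossSpectralDCM",
    "fit_csd",
]

_NOISE_NAMES = ("log_alpha_u", "log_beta_u", "log_alpha_n", "log_beta_n")
_Q_NAMES = tuple(f"q_{p}" for p in POPULATIONS)


@dataclass
class PriorDensity:
    """Gaussian density over the latent parameters.

    Latent zero maps to the canonical physical value of every parameter;
    ``physical`` records those reference values for the connections.
    """

    names: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray
    physical: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        p = len(self.names)
        if self.mean.shape != (p,) or self.cov.shape != (p, p):
            raise ValueError("prior mean/cov shapes do not match names")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("prior covariance must be symmetric")
        if np.min(np.linalg.eigvalsh(self.cov)) < -1e-10:
            raise ValueError("prior covariance must be positive semi-definite")

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class ConditionDesign:
    """Which connections each non-baseline condition may modulate (B effects)."""

    conditions: tuple[str, ...]
    modulated: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.conditions = tuple(self.conditions)
        if not self.conditions:
            raise ValueError("at least one condition required")
        full = {}
        for cond in self.conditions[1:]:
            mods = self.modulated.get(cond, CONNECTION_NAMES)
            bad = set(mods) - set(CONNECTION_NAMES)
            if bad:
                raise ValueError(f"unknown connections in design: {sorted(bad)}")
            full[cond] = tuple(mods)
        if self.conditions[0] in self.modulated:
            raise ValueError("baseline condition must have zero offsets")
        self.modulated = full

    @property
    def baseline(self) -> str:
        return self.conditions[0]


@dataclass
class Posterior:
    """Gaussian posterior over latents plus fit diagnostics."""

    names: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray
    free_energy: float
    f_trace: np.ndarray
    predictions: list[CrossSpectrum]
    variance_explained: float
    connection_changes: dict[str, float]
    converged: bool
    log_precision: float
    diagnostics: dict = field(default_factory=dict)

    def sd(self, name: str) -> float:
        i = self.names.index(name)
        return float(np.sqrt(self.cov[i, i]))

    def marginal(self, names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        idx = [self.names.index(n) for n in names]
        return self.mean[idx], self.cov[np.ix_(idx, idx)]


class LatentModel:
    """Maps latent vectors to physical parameters and spectral predictions."""

    def __init__(self,
                 freqs: np.ndarray,
                 design: ConditionDesign | None = None,
                 include_q: bool = True,
                 layer_resolved: bool = False,
                 fit_complex: bool = False,
                 config: Mapping | None = None):
        self.cfg = dict(default_config(), **(config or {}))
        self.freqs = np.asarray(freqs, dtype=float)
        self.design = design or ConditionDesign(("baseline",))
        self.include_q = include_q
        self.layer_resolved = layer_resolved
        self.fit_complex = fit_complex

        cfg = self.cfg
        self.a0 = np.array([CANONICAL_STRENGTHS[n] for n in CONNECTION_NAMES])
        self.kappa = np.array([cfg["kappa_si"], cfg["kappa_di"], cfg["kappa_dp"], cfg["kappa_sp"]])
        self.h = np.array([cfg["h_si"], cfg["h_di"], cfg["h_dp"], cfg["h_sp"]])
        self.slope = float(cfg["sigmoid_slope"])
        self.threshold = float(cfg["sigmoid_threshold"])
        self.c = np.array([cfg["input_si"], cfg["input_di"], cfg["input_dp"], cfg["input_sp"]])
        self.Q0 = np.array([cfg["q_si"], cfg["q_di"], cfg["q_dp"], cfg["q_sp"]])
        self.noise0 = np.array([cfg["alpha_u"], cfg["beta_u"], cfg["alpha_n"], cfg["beta_n"]])
        self.lead_field = float(cfg["lead_field"])

        names: list[str] = list(CONNECTION_NAMES)
        if include_q and not layer_resolved:
            names += list(_Q_NAMES)
        names += list(_NOISE_NAMES)
        self._b_slices: dict[str, tuple[int, tuple[int, ...]]] = {}
        for cond in self.design.conditions[1:]:
            mods = self.design.modulated[cond]
            start = len(names)
            names += [f"b:{cond}:{m}" for m in mods]
            self._b_slices[cond] = (start, tuple(CONNECTION_NAMES.index(m) for m in mods))
        self.names = tuple(names)
        self.n_latent = len(names)
        self._iq = names.index(_Q_NAMES[0]) if (include_q and not layer_resolved) else None
        self._inoise = names.index(_NOISE_NAMES[0])

        # gain of the centred sigmoid at the origin (the fixed point at zero drive)
        e = np.exp(self.slope * self.threshold)
        self._gain0 = self.slope * e / (1.0 + e) ** 2

    # -- priors -----------------------------------------------------------------
    def default_prior(self) -> PriorDensity:
        cfg = self.cfg
        var = []
        for n in self.names:
            if n.startswith("b:"):
                var.append(cfg["prior_var_b"])
            elif n.startswith("q_"):
                var.append(cfg["prior_var_q"])
            elif n.startswith("log_"):
                var.append(cfg["prior_var_noise"])
            else:
                var.append(cfg["prior_var_conn"])
        physical = dict(CANONICAL_STRENGTHS)
        return PriorDensity(self.names, np.zeros(self.n_latent), np.diag(var), physical)

    def merge_prior(self, prior: PriorDensity | None) -> PriorDensity:
        """Start from the default prior; override entries named in ``prior``."""
        base = self.default_prior()
        if prior is None:
            return base
        mean, cov = base.mean.copy(), base.cov.copy()
        common = [(i, prior.index(n)) for i, n in enumerate(self.names) if n in prior.names]
        for i, j in common:
            mean[i] = prior.mean[j]
        for i, j in common:
            for k, l in common:
                cov[i, k] = prior.cov[j, l]
        return PriorDensity(self.names, mean, cov, dict(base.physical))

    # -- latent -> physical ------------------------------------------------------
    def _connection_latents(self, theta: np.ndarray, condition: str) -> np.ndarray:
        lat = theta[..., :10].copy()
        if condition != self.design.baseline:
            start, conn_idx = self._b_slices[condition]
            for k, ci in enumerate(conn_idx):
                lat[..., ci] += theta[..., start + k]
        return lat

    def physical(self, theta: np.ndarray,
                 condition: str | None = None) -> tuple[MassParameters, SpectralParameters]:
        theta = np.asarray(theta, dtype=float)
        condition = condition or self.design.baseline
        a = self.a0 * np.exp(self._connection_latents(theta, condition))
        noise = self.noise0 * np.exp(theta[self._inoise:self._inoise + 4])
        Q = self.Q0 + (theta[self._iq:self._iq + 4] if self._iq is not None else 0.0)
        mass = MassParameters(a=a, kappa=self.kappa, h=self.h,
                              sigmoid_slope=self.slope, sigmoid_threshold=self.threshold,
                              input_weights=self.c)
        spec = SpectralParameters(alpha_u=noise[0], beta_u=noise[1],
                                  alpha_n=noise[2], beta_n=noise[3],
                                  Q=Q, lead_field=self.lead_field)
        return mass, spec

    # -- data vectorization ------------------------------------------------------
    def data_vector(self, csds: Sequence[CrossSpectrum]) -> np.ndarray:
        return np.concatenate([self._vectorize(c.values) for c in csds])

    def _vectorize(self, vals: np.ndarray) -> np.ndarray:
        if self.layer_resolved:
            parts = [vals[:, 0, 0].real, vals[:, 1, 1].real]
            if self.fit_complex:
                parts += [vals[:, 0, 1].real, vals[:, 0, 1].imag]
            return np.concatenate(parts)
        return vals[:, 0, 0].real

    @property
    def n_data_per_condition(self) -> int:
        F = len(self.freqs)
        if self.layer_resolved:
            return 4 * F if self.fit_complex else 2 * F
        return F

    # -- prediction --------------------------------------------------------------
    def _jacobians(self, a: np.ndarray) -> np.ndarray:
        """Batched linearization Jacobians from connection strengths (m, 10)."""
        m = a.shape[0]
        W = coupling_matrix(a)
        k2 = self.kappa**2
        J = np.zeros((m, 8, 8))
        J[:, :4, 4:] = np.eye(4)
        J[:, 4:, :4] = (k2[:, None] * self.h[:, None]) * W * self._gain0
        J[:, 4:, :4] -= np.diag(k2)
        J[:, 4:, 4:] = -np.diag(2.0 * self.kappa)
        return J

    def predict_many(self, Theta: np.ndarray) -> np.ndarray:
        """Predicted data vectors for a batch of latents; unstable rows are NaN."""
        Theta = np.atleast_2d(np.asarray(Theta, dtype=float))
        m = Theta.shape[0]
        F = len(self.freqs)
        B = np.zeros(8)
        B[4:] = self.kappa**2 * self.h * self.c
        noise = self.noise0 * np.exp(Theta[:, self._inoise:self._inoise + 4])
        g_u = noise[:, 0:1] + noise[:, 1:2] / self.freqs[None, :]
        g_n = noise[:, 2:3] + noise[:, 3:4] / self.freqs[None, :]
        blocks = []
        unstable = np.zeros(m, dtype=bool)
        for cond in self.design.conditions:
            a = self.a0 * np.exp(self._connection_latents(Theta, cond))
            J = self._jacobians(a)
            ev = np.linalg.eigvals(J)
            unstable |= np.any(ev.real >= 0, axis=1)
            T = _resolvent_gain(J, B, self.freqs)  # (m, F, 4)
            if self.layer_resolved:
                idx = [POPULATIONS.index("SP"), POPULATIONS.index("DP")]
                Hf = self.lead_field * T[:, :, idx]
                s11 = np.abs(Hf[:, :, 0]) ** 2 * g_u + g_n
                s22 = np.abs(Hf[:, :, 1]) ** 2 * g_u + g_n
                parts = [s11, s22]
                if self.fit_complex:
                    s12 = Hf[:, :, 0] * np.conj(Hf[:, :, 1]) * g_u
                    parts += [s12.real, s12.imag]
                blocks.append(np.concatenate(parts, axis=1))
            else:
                Q = self.Q0[None, :] + (Theta[:, self._iq:self._iq + 4]
                                        if self._iq is not None else 0.0)
                s = np.einsum("mfj,mj->mf", T, Q.astype(complex) if Q.ndim == 2 else Q)
                blocks.append(np.abs(self.lead_field * s) ** 2 * g_u + g_n)
        out = np.concatenate(blocks, axis=1)
        out[unstable] = np.nan
        return out

    def predict(self, theta: np.ndarray) -> list[CrossSpectrum]:
        """Full CrossSpectrum objects (per condition) at a single latent vector."""
        from .spectral import predict_csd
        out = []
        for cond in self.design.conditions:
            mass, spec = self.physical(np.asarray(theta, dtype=float), cond)
            out.append(predict_csd(mass, spec, self.freqs,
                                   layer_resolved=self.layer_resolved, condition=cond))
        return out


def default_priors(config: Mapping | None = None,
                   conditions: Sequence[str] = ("baseline",),
                   include_q: bool = True) -> PriorDensity:
    """Prior over latents: zero mean (canonical physical values), config variances."""
    model = LatentModel(np.array([40.0]), ConditionDesign(tuple(conditions)),
                        include_q=include_q, config=config)
    return model.default_prior()


def apply_latents(priors: PriorDensity,
                  latents: np.ndarray | Mapping[str, float],
                  design: ConditionDesign | None = None,
                  condition: str | None = None,
                  config: Mapping | None = None) -> tuple[MassParameters, SpectralParameters]:
    """Physical parameters implied by a latent vector (log-scaling; additive Q)."""
    design = design or ConditionDesign(("baseline",))
    model = LatentModel(np.array([40.0]), design,
                        include_q=any(n.startswith("q_") for n in priors.names),
                        config=config)
    theta = np.zeros(model.n_latent)
    if isinstance(latents, Mapping):
        for k, v in latents.items():
            theta[model.names.index(k)] = v
    else:
        latents = np.asarray(latents, dtype=float)
        if latents.shape != (model.n_latent,):
            raise ValueError("latent vector length does not match the model")
        theta = latents
    return model.physical(theta, condition)


# ---------------------------------------------------------------------------
# free energy
# ---------------------------------------------------------------------------

def gaussian_kl(mean_q: np.ndarray, cov_q: np.ndarray,
                mean_p: np.ndarray, cov_p: np.ndarray) -> float:
    """KL( N(mean_q, cov_q) || N(mean_p, cov_p) ), closed form."""
    mean_q, mean_p = np.asarray(mean_q, float), np.asarray(mean_p, float)
    k = len(mean_q)
    Lp = np.linalg.cholesky(cov_p)
    sol = np.linalg.solve(cov_p, cov_q)
    d = mean_q - mean_p
    quad = d @ np.linalg.solve(cov_p, d)
    _, logdet_q = np.linalg.slogdet(cov_q)
    logdet_p = 2.0 * np.sum(np.log(np.diag(Lp)))
    return 0.5 * (np.trace(sol) + quad - k + logdet_p - logdet_q)


def free_energy(y: np.ndarray,
                g: np.ndarray,
                mean: np.ndarray,
                cov: np.ndarray,
                prior: PriorDensity,
                log_precision: float,
                jac: np.ndarray | None = None,
                lam0: float = 0.0,
                lam_var: float = 16.0,
                weights: np.ndarray | None = None) -> float:
    """Free-energy bound: Gaussian accuracy minus KL complexity.

    ``jac`` (the prediction Jacobian w.r.t. latents) supplies the expected
    curvature correction tr(Pi J Sigma J'); omit it for a plain evaluation at
    the mean.  ``weights`` optionally scales the per-element precision.
    """
    y, g = np.asarray(y, float), np.asarray(g, float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)
    r = y - g
    pi = np.exp(log_precision)
    ssq = float(r @ (w * r))
    trace_term = 0.0
    if jac is not None:
        M = jac.T @ (w[:, None] * jac)
        trace_term = float(np.sum(M * cov))
    L = len(y)
    accuracy = (-0.5 * pi * (ssq + trace_term)
                + 0.5 * (L * log_precision + np.sum(np.log(w)))
                - 0.5 * L * np.log(2.0 * np.pi))
    complexity = gaussian_kl(mean, cov, prior.mean, prior.cov)
    hyper = -0.5 * (log_precision - lam0) ** 2 / lam_var
    return accuracy - complexity + hyper


def variance_explained(data: np.ndarray | CrossSpectrum,
                       prediction: np.ndarray | CrossSpectrum) -> float:
    """1 - SS_res / SS_tot over pooled (real) spectral values; can be negative."""
    if isinstance(data, CrossSpectrum):
        data = data.values.real.ravel()
    if isinstance(prediction, CrossSpectrum):
        prediction = prediction.values.real.ravel()
    y = np.asarray(data, float).ravel()
    p = np.asarray(prediction, float).ravel()
    if y.shape != p.shape:
        raise ValueError("data and prediction must share a grid")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("zero-variance data")
    return 1.0 - float(np.sum((y - p) ** 2)) / ss_tot


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class CrossSpectralDCM(BaseEstimator):
    """Fit the laminar mass model to observed (cross-)spectra.

    A scikit-learn style estimator: configure in ``__init__``, call
    :meth:`fit` with one ``CrossSpectrum`` (or a list covering several
    conditions fitted simultaneously with shared subject latents and
    per-condition B offsets), then read the fitted attributes
    ``posterior_``, ``free_energy_``, ``variance_explained_``,
    ``connection_changes_``.

    Parameters
    ----------
    priors : optional PriorDensity overriding (a subset of) the default prior.
    design : optional ConditionDesign naming conditions and modulated connections.
    include_q : fit additive offsets on the population weights Q (single-channel only).
    fit_complex : for two-channel data, fit real and imaginary cross-spectra;
        otherwise auto-spectra (power) only.
    freq_weights : optional per-frequency weights on the observation precision.
    config : mapping overriding configuration defaults.
    """

    def __init__(self,
                 priors: PriorDensity | None = None,
                 design: ConditionDesign | None = None,
                 include_q: bool = True,
                 fit_complex: bool | None = None,
                 freq_weights: np.ndarray | None = None,
                 config: Mapping | None = None):
        self.priors = priors
        self.design = design
        self.include_q = include_q
        self.fit_complex = fit_complex
        self.freq_weights = freq_weights
        self.config = config

    # -- helpers ---------------------------------------------------------------
    def _setup(self, X: CrossSpectrum | Sequence[CrossSpectrum]):
        csds = [X] if isinstance(X, CrossSpectrum) else list(X)
        if not csds:
            raise ValueError("no spectra to fit")
        freqs = csds[0].freqs
        for c in csds[1:]:
            if len(c.freqs) != len(freqs) or not np.allclose(c.freqs, freqs):
                raise ValueError("all conditions must share one frequency grid")
            if c.n_channels != csds[0].n_channels:
                raise ValueError("all conditions must share the channel layout")
        layer = csds[0].n_channels == 2
        cfg = dict(default_config(), **(self.config or {}))
        fit_complex = cfg["fit_complex"] if self.fit_complex is None else self.fit_complex
        design = self.design
        if design is None:
            conds = tuple(c.condition for c in csds)
            if len(set(conds)) != len(conds):
                raise ValueError("duplicate condition labels; provide a ConditionDesign")
            design = ConditionDesign(conds)
        if tuple(c.condition for c in csds) != design.conditions:
            raise ValueError("spectra order must match the condition design")
        model = LatentModel(freqs, design, include_q=self.include_q,
                            layer_resolved=layer, fit_complex=bool(fit_complex and layer),
                            config=self.config)
        return csds, model, cfg

    def _weight_vector(self, model: LatentModel) -> np.ndarray | None:
        if self.freq_weights is None:
            return None
        wf = np.asarray(self.freq_weights, dtype=float)
        if wf.shape != model.freqs.shape:
            raise ValueError("freq_weights must match the frequency grid")
        reps = model.n_data_per_condition // len(model.freqs)
        per_cond = np.tile(wf, reps)
        return np.tile(per_cond, len(model.design.conditions))

    def _fd_jacobian(self, model: LatentModel, mu: np.ndarray,
                     g0: np.ndarray, step: float) -> np.ndarray:
        p = len(mu)
        Theta = np.repeat(mu[None, :], 2 * p, axis=0)
        for k in range(p):
            Theta[2 * k, k] += step
            Theta[2 * k + 1, k] -= step
        G = model.predict_many(Theta)
        Jm = np.empty((len(g0), p))
        for k in range(p):
            gp, gm = G[2 * k], G[2 * k + 1]
            if np.all(np.isfinite(gp)) and np.all(np.isfinite(gm)):
                Jm[:, k] = (gp - gm) / (2.0 * step)
            elif np.all(np.isfinite(gp)):
                Jm[:, k] = (gp - g0) / step
            elif np.all(np.isfinite(gm)):
                Jm[:, k] = (g0 - gm) / step
            else:
                Jm[:, k] = 0.0
        return Jm

    # -- fitting ----------------------------------------------------------------
    def fit(self, X: CrossSpectrum | Sequence[CrossSpectrum], y=None) -> "CrossSpectralDCM":
        csds, model, cfg = self._setup(X)
        prior = model.merge_prior(self.priors)
        ydat = model.data_vector(csds)
        w = self._weight_vector(model)
        wvec = np.ones_like(ydat) if w is None else w
        L = len(ydat)
        P0 = np.linalg.inv(prior.cov + 1e-12 * np.eye(len(prior.mean)))
        fd = float(cfg["fd_step"])
        lam_var = float(cfg["lambda_var"])

        mu = prior.mean.copy()
        g = model.predict_many(mu[None, :])[0]
        if not np.all(np.isfinite(g)):
            raise RuntimeError("model unstable at the prior mean; cannot start inversion")
        r = ydat - g
        # data-informed hyperprior centre: unit-ish standardized residual power,
        # floored so an exact fit at the prior mean stays numerically benign
        ssq0 = max(float(r @ (wvec * r)), 1e-9 * float(ydat @ (wvec * ydat)), 1e-300)
        lam0 = float(np.log(L / ssq0))
        lam = lam0

        Jm = self._fd_jacobian(model, mu, g, fd)

        def posterior_cov(Jm_, lam_):
            H = np.exp(lam_) * (Jm_.T @ (wvec[:, None] * Jm_)) + P0
            return np.linalg.inv(H), H

        Sigma, H = posterior_cov(Jm, lam)
        F = free_energy(ydat, g, mu, Sigma, prior, lam, jac=Jm,
                        lam0=lam0, lam_var=lam_var, weights=w)
        trace = [F]
        tau = float(cfg["tau0"])
        accepted_df: list[float] = []
        n_reject = 0
        converged = False

        for it in range(int(cfg["max_iter"])):
            pi = np.exp(lam)
            grad = pi * (Jm.T @ (wvec * r)) - P0 @ (mu - prior.mean)
            Hreg = H + tau * np.diag(np.diag(H)) + 1e-10 * np.eye(len(mu))
            delta = np.linalg.solve(Hreg, grad)
            if 0.5 * float(grad @ delta) < float(cfg["ftol"]) * 1e-3:
                # expected improvement negligible: already at the optimum
                converged = True
                break
            cand = mu + delta
            gc = model.predict_many(cand[None, :])[0]
            if np.all(np.isfinite(gc)):
                Jc = self._fd_jacobian(model, cand, gc, fd)
                Sc, Hc = posterior_cov(Jc, lam)
                Fc = free_energy(ydat, gc, cand, Sc, prior, lam, jac=Jc,
                                 lam0=lam0, lam_var=lam_var, weights=w)
            else:
                Fc = -np.inf
            if Fc > F:
                accepted_df.append(Fc - F)
                mu, g, Jm, Sigma, H, F = cand, gc, Jc, Sc, Hc, Fc
                r = ydat - g
                tau = max(tau / 2.0, 1e-8)
                # M-step: scalar Newton on the log observation precision
                lam, Sigma, H, F = self._update_lambda(
                    ydat, g, mu, model, prior, Jm, wvec, w, lam, lam0, lam_var,
                    posterior_cov, F)
                trace.append(F)
                if len(accepted_df) >= int(cfg["n_converged"]) and all(
                        d < float(cfg["ftol"]) for d in accepted_df[-int(cfg["n_converged"]):]):
                    converged = True
                    break
            else:
                n_reject += 1
                tau *= 2.0
                if tau > 1e8:
                    break

        # enforce exact symmetry / PSD on the reported covariance
        Sigma = 0.5 * (Sigma + Sigma.T)
        wS, VS = np.linalg.eigh(Sigma)
        Sigma = (VS * np.clip(wS, 1e-12, None)) @ VS.T
        preds = model.predict(mu)
        gfin = model.predict_many(mu[None, :])[0]
        ve = variance_explained(ydat, gfin)
        changes = {n: float(mu[i] - prior.mean[i])
                   for i, n in enumerate(model.names) if n in CONNECTION_NAMES}
        self.model_ = model
        self.prior_ = prior
        self.names_ = model.names
        self.posterior_ = Posterior(
            names=model.names, mean=mu, cov=Sigma, free_energy=float(F),
            f_trace=np.array(trace), predictions=preds, variance_explained=float(ve),
            connection_changes=changes, converged=converged, log_precision=float(lam),
            diagnostics={"n_accepted": len(accepted_df), "n_rejected": n_reject,
                         "lambda0": lam0, "n_data": L})
        self.free_energy_ = float(F)
        self.variance_explained_ = float(ve)
        self.connection_changes_ = changes
        self.converged_ = converged
        self.n_iter_ = len(accepted_df)
        logger.info("fit: F=%.2f, VE=%.3f, %d accepted / %d rejected steps, converged=%s",
                    F, ve, len(accepted_df), n_reject, converged)
        return self

    @staticmethod
    def _update_lambda(ydat, g, mu, model, prior, Jm, wvec, w, lam, lam0, lam_var,
                       posterior_cov, F):
        r = ydat - g
        ssq = float(r @ (wvec * r))
        M = Jm.T @ (wvec[:, None] * Jm)
        L = len(ydat)
        for _ in range(8):
            Sigma, H = posterior_cov(Jm, lam)
            S = ssq + float(np.sum(M * Sigma))
            grad = -0.5 * np.exp(lam) * S + 0.5 * L - (lam - lam0) / lam_var
            hess = -0.5 * np.exp(lam) * S - 1.0 / lam_var
            step = -grad / hess
            if abs(step) < 1e-4:
                break
            cand = lam + np.clip(step, -2.0, 2.0)
            Sc, Hc = posterior_cov(Jm, cand)
            Fc = free_energy(ydat, g, mu, Sc, prior, cand, jac=Jm,
                             lam0=lam0, lam_var=lam_var, weights=w)
            if Fc > F:
                lam, F = float(cand), Fc
            else:
                break
        Sigma, H = posterior_cov(Jm, lam)
        return lam, Sigma, H, F

    def predict(self, condition: str | None = None) -> CrossSpectrum:
        """Posterior-mean predicted spectrum for one condition."""
        post = self.posterior_
        conds = self.model_.design.conditions
        cond = condition or conds[0]
        return post.predictions[conds.index(cond)]


def fit_csd(data: CrossSpectrum | Sequence[CrossSpectrum],
            priors: PriorDensity | None = None,
            design: ConditionDesign | None = None,
            config: Mapping | None = None,
            **kwargs) -> Posterior:
    """Functional wrapper over :class:`CrossSpectralDCM`; returns the Posterior."""
    est = CrossSpectralDCM(priors=priors, design=design, config=config, **kwargs)
    est.fit(data)
    return est.posterior_
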