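"""Synthetic data with the statistical structure the analysis assumes.

Two generators stand in for data that cannot ship with the package:

* a layer-resolved "microscale" surrogate — the mass model simulated in the
  time domain under burst-like exogenous input (groups of spike doublets at a
  10 Hz group rate) plus white+pink noise, with seeded perturbations of the
  synaptic kernel constants so the generating model is *not* exactly the model
  later fitted (model-mismatch realism), Welch-estimated into SP/DP spectra;

* a multi-subject group — each subject's connection latents are a linear
  function of a V1-size-like covariate plus Gaussian random effects, pushed
  through the analytic forward model on the 30-80 Hz grid and degraded by
  Gaussian observation noise at a configurable precision.

Everything is reproducible from (seed, config); ground truth is returned
alongside the data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .circuit import (BurstInputSpec, CONNECTION_NAMES, MassParameters,
                      default_mass_parameters, simulate)
from .config import POPULATIONS, default_config
from .inversion import ConditionDesign, LatentModel
from .spectral import CrossSpectrum, default_spectral_parameters, predict_csd, welch_csd

logger = logging.getLogger(__name__)

__all__ = [
    "GroupTruth",
    "GroupDataset",
    "make_noise_drive",
    "generate_surrogate_microscale",
    "generate_group",
    "observation_noise",
]

_CONDITION_LABELS = ("deg2", "deg4", "deg8")  # three grating sizes


def make_noise_drive(n: int, fs: float, alpha: float, beta: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Sampled drive with one-sided spectral density alpha + beta/f.

    The white part is i.i.d. Gaussian with variance alpha*fs/2; the pink part
    is spectrally shaped Gaussian noise (FFT filter sqrt(beta*fs/(2 f))).
    """
    white = rng.normal(0.0, np.sqrt(alpha * fs / 2.0), n) if alpha > 0 else np.zeros(n)
    if beta <= 0:
        return white
    w = rng.normal(0.0, 1.0, n)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    H = np.zeros_like(f)
    H[1:] = np.sqrt(beta * fs / 2.0 / f[1:])
    pink = np.fft.irfft(np.fft.rfft(w) * H, n)
    return white + pink


def _perturbed_parameters(cfg: Mapping, scale: float,
                          rng: np.random.Generator) -> MassParameters:
    """Canonical parameters with log-normally perturbed kernel constants."""
    p = default_mass_parameters(cfg)
    if scale > 0:
        p.kappa = p.kappa * np.exp(rng.normal(0.0, scale, 4))
        p.h = p.h * np.exp(rng.normal(0.0, scale, 4))
    return p


def generate_surrogate_microscale(seed: int,
                                  config: Mapping | None = None,
                                  mode: str = "simulate",
                                  perturb_scale: float | None = None,
                                  duration: float | None = None) -> CrossSpectrum:
    """Layer-resolved (SP, DP) surrogate spectra on the 1-100 Hz grid.

    ``mode="simulate"`` (default): time-domain run under burst + white/pink
    drive, Welch-estimated — the construct-validity stand-in for a detailed
    compartmental simulation.  ``mode="analytic"``: the forward model's own
    spectrum (zero model-mismatch apart from any kernel perturbation), used
    for self-consistency checks.
    """
    cfg = dict(default_config(), **(config or {}))
    rng = np.random.default_rng(seed)
    scale = cfg["surrogate_perturb_scale"] if perturb_scale is None else perturb_scale
    params = _perturbed_parameters(cfg, float(scale), rng)
    spectral = default_spectral_parameters(cfg)
    freqs = np.arange(cfg["freq_lo_wide"], cfg["freq_hi_wide"] + 0.5 * cfg["freq_step"],
                      cfg["freq_step"])
    if mode == "analytic":
        return predict_csd(params, spectral, freqs, layer_resolved=True)
    if mode != "simulate":
        raise ValueError(f"unknown surrogate mode {mode!r}")

    dt = float(cfg["sim_dt"])
    fs = 1.0 / dt
    dur = float(cfg["sim_duration"] if duration is None else duration)
    trans = float(cfg["sim_transient"])
    n = int(round((dur + trans) / dt))
    burst = BurstInputSpec(
        n_groups=int(cfg["burst_n_groups"]),
        spikes_per_burst=int(cfg["burst_spikes_per_burst"]),
        intra_burst_interval_ms=float(cfg["burst_intra_interval_ms"]),
        inter_group_interval_ms=float(cfg["burst_inter_group_interval_ms"]),
        amplitude=float(cfg["burst_amplitude"]),
        kernel_width_ms=float(cfg["burst_kernel_width_ms"]),
    )
    drive = burst.drive_array(dt, dur + trans)
    drive = drive + make_noise_drive(n, fs, spectral.alpha_u, spectral.beta_u, rng)
    _, v = simulate(params, dt, dur + trans, drive=drive)
    v = v[int(trans / dt):]
    layers = v[:, [POPULATIONS.index("SP"), POPULATIONS.index("DP")]]
    return welch_csd(layers, fs, nperseg=int(fs), channels=("SP", "DP"),
                     fmin=float(freqs[0]), fmax=float(freqs[-1]))


def observation_noise(spectrum: CrossSpectrum,
                      lam: float,
                      seed: int | np.random.Generator) -> CrossSpectrum:
    """Add Gaussian sampling noise of variance exp(-lam) per spectral element.

    Real and imaginary parts of each unique channel pair receive independent
    noise; Hermitian symmetry is preserved and negative auto-spectra are
    clipped at zero (count logged).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = float(np.exp(-lam / 2.0))
    vals = spectrum.values.copy()
    F, C = vals.shape[0], vals.shape[1]
    clipped = 0
    for i in range(C):
        for j in range(i, C):
            re = rng.normal(0.0, sd, F)
            if i == j:
                new = vals[:, i, i].real + re
                clipped += int(np.sum(new < 0))
                vals[:, i, i] = np.clip(new, 0.0, None)
            else:
                im = rng.normal(0.0, sd, F)
                vals[:, i, j] += re + 1j * im
                vals[:, j, i] = np.conj(vals[:, i, j])
    if clipped:
        logger.info("observation_noise: clipped %d negative auto-spectral values", clipped)
    return CrossSpectrum(spectrum.freqs, vals, spectrum.channels, spectrum.condition)


@dataclass
class GroupTruth:
    """Ground truth of a generated group, sufficient to regenerate it."""

    seed: int
    beta: dict[str, float]
    covariate: np.ndarray           # raw V1-size-like values (mm^2)
    covariate_z: np.ndarray         # standardized covariate entering the truth
    subject_latents: np.ndarray     # (n_subjects, 10) connection latents
    condition_offsets: dict[str, dict[str, float]]
    log_precisions: np.ndarray      # per-subject observation log-precision
    n_resampled: int = 0

    def to_json(self) -> str:
        return json.dumps({
            "seed": self.seed,
            "beta": self.beta,
            "covariate": self.covariate.tolist(),
            "covariate_z": self.covariate_z.tolist(),
            "subject_latents": self.subject_latents.tolist(),
            "condition_offsets": self.condition_offsets,
            "log_precisions": self.log_precisions.tolist(),
            "n_resampled": self.n_resampled,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroupTruth":
        d = json.loads(text)
        return cls(seed=d["seed"], beta=d["beta"],
                   covariate=np.array(d["covariate"]),
                   covariate_z=np.array(d["covariate_z"]),
                   subject_latents=np.array(d["subject_latents"]),
                   condition_offsets=d["condition_offsets"],
                   log_precisions=np.array(d["log_precisions"]),
                   n_resampled=d["n_resampled"])


@dataclass
class GroupDataset:
    """Spectra, covariate table and ground truth for one synthetic group."""

    spectra: list[list[CrossSpectrum]]  # [subject][condition]
    covariates: pd.DataFrame
    truth: GroupTruth
    conditions: tuple[str, ...] = ("baseline",)


def generate_group(n_subjects: int | None = None,
                   beta_true: Mapping[str, float] | None = None,
                   seed: int = 0,
                   n_conditions: int = 1,
                   config: Mapping | None = None,
                   noise_frac: float | None = None,
                   subject_sd: float | None = None) -> GroupDataset:
    """Generate a synthetic multi-subject gamma-band dataset.

    Each subject's connection latents are ``z_i * beta + N(0, subject_sd^2)``
    with ``z`` the standardized V1-size-like covariate; spectra come from the
    analytic forward model on the 30-80 Hz grid plus observation noise whose
    SD is ``noise_frac`` times the subject's mean band power.  ``beta_true``
    maps connection names to latent slopes (default: none, the null group).
    """
    cfg = dict(default_config(), **(config or {}))
    n = int(cfg["group_n_subjects"] if n_subjects is None else n_subjects)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if not 1 <= n_conditions <= 3:
        raise ValueError("1 to 3 conditions supported")
    nf = float(cfg["group_noise_frac"] if noise_frac is None else noise_frac)
    ssd = float(cfg["group_subject_sd"] if subject_sd is None else subject_sd)
    rng = np.random.default_rng(seed)

    conditions = _CONDITION_LABELS[:n_conditions] if n_conditions > 1 else ("baseline",)
    design = ConditionDesign(conditions)
    freqs = np.arange(cfg["freq_lo_gamma"], cfg["freq_hi_gamma"] + 0.5 * cfg["freq_step"],
                      cfg["freq_step"])
    model = LatentModel(freqs, design, include_q=True, config=cfg)

    beta_vec = np.zeros(10)
    for k, v in (beta_true or {}).items():
        beta_vec[CONNECTION_NAMES.index(k)] = float(v)

    v1 = rng.lognormal(float(cfg["group_covariate_logmean"]),
                       float(cfg["group_covariate_logsd"]), n)
    z = (v1 - v1.mean()) / v1.std()

    cond_offsets: dict[str, dict[str, float]] = {}
    theta_b = np.zeros(model.n_latent)
    for cond in conditions[1:]:
        offs = rng.normal(0.0, float(cfg["group_condition_offset_sd"]), 10)
        cond_offsets[cond] = dict(zip(CONNECTION_NAMES, offs.tolist()))
        start, conn_idx = model._b_slices[cond]
        theta_b[start:start + len(conn_idx)] = offs

    spectra: list[list[CrossSpectrum]] = []
    latents = np.zeros((n, 10))
    lams = np.zeros(n)
    n_resampled = 0
    for i in range(n):
        for attempt in range(100):
            lat = z[i] * beta_vec + rng.normal(0.0, ssd, 10)
            theta = theta_b.copy()
            theta[:10] = lat
            if np.all(np.isfinite(model.predict_many(theta[None, :])[0])):
                break
            n_resampled += 1
        else:
            raise RuntimeError("could not sample a stable subject in 100 attempts")
        latents[i] = lat
        preds = model.predict(theta)
        sd = nf * float(preds[0].power().mean())
        lam = -2.0 * np.log(sd)
        lams[i] = lam
        spectra.append([observation_noise(c, lam, rng) for c in preds])

    peak_idx = [int(np.argmax(s[0].power())) for s in spectra]
    gamma_peak = freqs[peak_idx]
    gamma_amp = np.array([float(s[0].power().max()) for s in spectra])
    if n_conditions == 3:
        rel = np.array([(s[2].power().max() - s[0].power().max()) / s[0].power().max()
                        for s in spectra])
    else:
        rel = np.full(n, np.nan)
    cov = pd.DataFrame({
        "subject_id": [f"sub{i:02d}" for i in range(n)],
        "v1_size_mm2": v1,
        "gamma_peak_hz": gamma_peak,
        "gamma_amplitude": gamma_amp,
        "rel_amplitude_change": rel,
    })
    if n_resampled:
        logger.info("generate_group: resampled %d unstable subjects", n_resampled)
    truth = GroupTruth(seed=int(seed), beta=dict(zip(CONNECTION_NAMES, beta_vec.tolist())),
                       covariate=v1, covariate_z=z, subject_latents=latents,
                       condition_offsets=cond_offsets, log_precisions=lams,
                       n_resampled=n_resampled)
    return GroupDataset(spectra=spectra, covariates=cov, truth=truth,
                        conditions=conditions)
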