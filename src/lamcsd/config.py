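"""Configuration defaults for the laminar model and analysis pipeline.

Every tunable that the analysis depends on lives here, as a flat key-value
mapping, so a run can be reproduced from (config, seed) alone.  Values can be
overridden from a YAML file of the same flat keys.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

#: Population order used throughout: index 1=SI, 2=DI, 3=DP, 4=SP (a_ij = target i <- source j).
POPULATIONS = ("SI", "DI", "DP", "SP")

DEFAULTS: dict[str, Any] = {
    # --- synaptic kernels (per population, order SI, DI, DP, SP) -------------
    # Rate constants (1/s) and gains (mV): chosen by linear analysis of the two
    # E-I pairs so that, at the canonical connection strengths, the superficial
    # pair resonates in low gamma (~49 Hz) and the deep pair in high beta (~28 Hz),
    # keeping the deep resonance flank inside the 30-80 Hz band so deep-layer
    # connections remain identifiable from gamma-band spectra.
    "kappa_si": 150.0,
    "kappa_di": 125.0,
    "kappa_dp": 125.0,
    "kappa_sp": 150.0,
    "h_si": 1.6,
    "h_di": 0.8,
    "h_dp": 0.8,
    "h_sp": 1.6,
    # firing transform: centred sigmoid, firing(0) = 0
    "sigmoid_slope": 2.0,      # 1/mV
    "sigmoid_threshold": 0.0,  # mV
    # exogenous input weights per population (white+pink drive reaches all layers)
    "input_si": 1.0,
    "input_di": 1.0,
    "input_dp": 1.0,
    "input_sp": 1.0,
    # --- observation / spectral parameters -----------------------------------
    "alpha_u": 4e-4,    # white input-noise density (a.u.)
    "beta_u": 2e-4,     # pink input-noise density (a.u.)
    "alpha_n": 1e-6,    # white channel-noise density (a.u.)
    "beta_n": 1e-6,     # pink channel-noise density (a.u.)
    "q_si": 0.0,        # population contributions to the virtual sensor
    "q_di": 0.0,        # (interneurons produce no appreciable dipole)
    "q_dp": 0.6,
    "q_sp": 1.0,
    "lead_field": 1.0,
    # --- frequency grids ------------------------------------------------------
    "freq_lo_wide": 1.0,     # construct-validity grid (Hz)
    "freq_hi_wide": 100.0,
    "freq_lo_gamma": 30.0,   # subject-fit grid (Hz)
    "freq_hi_gamma": 80.0,
    "freq_step": 1.0,
    # --- inversion (variational Laplace) --------------------------------------
    "prior_var_conn": 1.0 / 16.0,
    "prior_var_q": 1.0 / 64.0,
    "prior_var_noise": 1.0 / 64.0,
    "prior_var_b": 1.0 / 16.0,
    "max_iter": 128,
    "ftol": 1e-2,          # nats; convergence when dF < ftol for n_converged steps
    "n_converged": 3,
    "fd_step": 1e-4,       # central finite-difference step on latents
    "lambda_var": 16.0,    # hyperprior variance on the log observation precision
    "tau0": 0.25,          # initial Levenberg trust parameter
    "fit_complex": False,  # single-channel data: fit power only by default
    # --- construct validity ----------------------------------------------------
    "empirical_cov_inflation": 4.0,
    # --- synthetic data --------------------------------------------------------
    "burst_n_groups": 10,
    "burst_spikes_per_burst": 2,
    "burst_intra_interval_ms": 10.0,
    "burst_inter_group_interval_ms": 100.0,
    "burst_amplitude": 0.15,
    "burst_kernel_width_ms": 2.0,
    "sim_dt": 2.5e-4,          # s
    "sim_duration": 80.0,      # s, surrogate microscale run
    "sim_transient": 1.0,      # s discarded before Welch
    "surrogate_perturb_scale": 0.1,  # lognormal SD on kappa/h (model mismatch)
    "group_n_subjects": 16,
    "group_subject_sd": 0.1,   # between-subject SD of connection latents
    "group_noise_frac": 0.05,  # observation-noise SD / mean band power
    "group_covariate_logmean": 7.6,   # lognormal V1 size, exp(7.6) ~ 2000 mm^2
    "group_covariate_logsd": 0.3,
    "group_condition_offset_sd": 0.05,  # B-effect scale across stimulus conditions
    "group_beta_a22": 0.4,     # default planted covariate -> a22 latent slope
    # --- second level ----------------------------------------------------------
    "peb_beta_prior_var": 1.0 / 16.0,
    "peb_excluded_var": 1e-8,
    "peb_optimize_gamma": True,
    "peb_gamma": 4.6,           # -log between-subject variance if not optimized (~0.1 SD)
    "spearman_exact_max_n": 9,
}


def default_config() -> dict[str, Any]:
    """Return a fresh copy of the default configuration."""
    return dict(DEFAULTS)


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Load defaults, optionally overridden by a flat YAML file and/or a mapping.

    Unknown keys are rejected so typos fail loudly.
    """
    cfg = default_config()
    for source, label in ((_read_yaml(path), str(path)), (overrides, "overrides")):
        if not source:
            continue
        unknown = set(source) - set(cfg)
        if unknown:
            raise KeyError(f"unknown config keys in {label}: {sorted(unknown)}")
        cfg.update(source)
    return cfg


def _read_yaml(path: str | Path | None) -> dict[str, Any] | None:
    if path is None:
        return None
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must be a flat key-value mapping")
    return data


def config_hash(cfg: Mapping[str, Any]) -> str:
    """Short stable hash of a configuration, for logging and provenance."""
    blob = json.dumps({k: cfg[k] for k in sorted(cfg)}, sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
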