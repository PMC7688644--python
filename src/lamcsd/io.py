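"""Plain-text serialization: spectrum CSVs, covariate tables, posterior/prior JSON.

The spectrum dialect is a long-format CSV with columns
``freq_hz, channel_i, channel_j, re, im, condition``; a file may hold several
conditions.  Reading validates the cross-spectrum invariants (positive
increasing frequencies, Hermitian channel pairs) and auto-completes a missing
conjugate pair with a logged notice.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .inversion import Posterior, PriorDensity
from .spectral import CrossSpectrum
from .synth import GroupTruth

logger = logging.getLogger(__name__)

__all__ = [
    "write_timeseries", "read_timeseries",
    "write_spectrum", "read_spectrum", "read_spectra",
    "write_covariates", "read_covariates",
    "write_posterior", "read_posterior",
    "write_prior", "read_prior",
    "write_group_truth", "read_group_truth",
]

_SPECTRUM_COLUMNS = ("freq_hz", "channel_i", "channel_j", "re", "im", "condition")
_COVARIATE_COLUMNS = ("subject_id", "v1_size_mm2", "gamma_peak_hz",
                      "gamma_amplitude", "rel_amplitude_change")


_TS_COLUMNS = ("time_s", "v_SI", "v_DI", "v_DP", "v_SP")


def write_timeseries(t: np.ndarray, v: np.ndarray, path: str | Path) -> None:
    """Write simulated depolarization traces (one condition per file)."""
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    if v.shape != (len(t), 4):
        raise ValueError("expected traces of shape (n_samples, 4)")
    df = pd.DataFrame({"time_s": t, "v_SI": v[:, 0], "v_DI": v[:, 1],
                       "v_DP": v[:, 2], "v_SP": v[:, 3]})
    df.to_csv(path, index=False, float_format="%.17g")


def read_timeseries(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    missing = set(_TS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: time-series file missing columns {sorted(missing)}")
    return df["time_s"].to_numpy(), df[list(_TS_COLUMNS[1:])].to_numpy()


def write_spectrum(csd: CrossSpectrum | Sequence[CrossSpectrum],
                   path: str | Path) -> None:
    """Write one or more conditions to the long-format spectrum CSV."""
    csds = [csd] if isinstance(csd, CrossSpectrum) else list(csd)
    rows = []
    for c in csds:
        for i, chi in enumerate(c.channels):
            for j, chj in enumerate(c.channels):
                for k, f in enumerate(c.freqs):
                    v = c.values[k, i, j]
                    rows.append((f, chi, chj, v.real, v.imag, c.condition))
    df = pd.DataFrame(rows, columns=_SPECTRUM_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_spectra(path: str | Path) -> list[CrossSpectrum]:
    """Read every condition from a spectrum CSV, in file order."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"{path}: cannot parse spectrum CSV: {exc}") from exc
    missing = set(_SPECTRUM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: malformed header, missing columns {sorted(missing)}")
    df["_line"] = df.index + 2  # header is line 1
    out = []
    for cond in df["condition"].drop_duplicates():
        sub = df[df["condition"] == cond]
        out.append(_assemble(sub, str(cond), str(path)))
    if not out:
        raise ValueError(f"{path}: empty spectrum file")
    return out


def read_spectrum(path: str | Path) -> CrossSpectrum | list[CrossSpectrum]:
    """Read a spectrum CSV; a single CrossSpectrum if one condition is present."""
    out = read_spectra(path)
    return out[0] if len(out) == 1 else out


def _assemble(df: pd.DataFrame, condition: str, path: str) -> CrossSpectrum:
    channels = list(dict.fromkeys(list(df["channel_i"]) + list(df["channel_j"])))
    C = len(channels)
    freqs = np.sort(df["freq_hz"].unique())
    bad = df[df["freq_hz"] <= 0]
    if len(bad):
        raise ValueError(f"{path}: line {int(bad['_line'].iloc[0])}: "
                         "non-positive frequency (pink-noise domain requires f > 0)")
    F = len(freqs)
    fidx = {f: k for k, f in enumerate(freqs)}
    cidx = {c: k for k, c in enumerate(channels)}
    vals = np.full((F, C, C), np.nan + 0j)
    for _, row in df.iterrows():
        vals[fidx[row["freq_hz"]], cidx[row["channel_i"]], cidx[row["channel_j"]]] = \
            row["re"] + 1j * row["im"]
    # complete missing conjugate pairs
    completed = 0
    for i in range(C):
        for j in range(C):
            miss = np.isnan(vals[:, i, j].real)
            have = ~np.isnan(vals[:, j, i].real)
            fill = miss & have
            if i != j and fill.any():
                vals[fill, i, j] = np.conj(vals[fill, j, i])
                completed += int(fill.sum())
    if completed:
        logger.info("%s: completed %d missing conjugate entries by Hermitian symmetry",
                    path, completed)
    if np.isnan(vals.real).any():
        k, i, j = np.argwhere(np.isnan(vals.real))[0]
        raise ValueError(f"{path}: missing entry for f={freqs[k]} Hz, "
                         f"pair ({channels[i]},{channels[j]}), condition {condition}")
    try:
        return CrossSpectrum(freqs, vals, tuple(channels), condition)
    except ValueError as exc:
        raise ValueError(f"{path}: condition {condition}: {exc}") from exc


def write_covariates(table: pd.DataFrame, path: str | Path) -> None:
    missing = set(_COVARIATE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"covariate table missing columns {sorted(missing)}")
    table.loc[:, list(_COVARIATE_COLUMNS)].to_csv(path, index=False, float_format="%.17g")


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_COVARIATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: covariate table missing columns {sorted(missing)}")
    return df


def _posterior_dict(post: Posterior) -> dict:
    return {
        "names": list(post.names),
        "mean": post.mean.tolist(),
        "cov": post.cov.tolist(),
        "free_energy": post.free_energy,
        "f_trace": post.f_trace.tolist(),
        "variance_explained": post.variance_explained,
        "connection_changes": post.connection_changes,
        "converged": post.converged,
        "log_precision": post.log_precision,
        "diagnostics": post.diagnostics,
    }


def write_posterior(post: Posterior, path: str | Path) -> None:
    """Posterior JSON; predictions are written separately as spectrum CSVs."""
    with open(path, "w") as fh:
        json.dump(_posterior_dict(post), fh, indent=1)


def read_posterior(path: str | Path) -> Posterior:
    with open(path) as fh:
        d = json.load(fh)
    return Posterior(
        names=tuple(d["names"]), mean=np.array(d["mean"]), cov=np.array(d["cov"]),
        free_energy=d["free_energy"], f_trace=np.array(d["f_trace"]),
        predictions=[], variance_explained=d["variance_explained"],
        connection_changes=d["connection_changes"], converged=d["converged"],
        log_precision=d["log_precision"], diagnostics=d.get("diagnostics", {}))


def write_prior(prior: PriorDensity, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"names": list(prior.names), "mean": prior.mean.tolist(),
                   "cov": prior.cov.tolist(), "physical": prior.physical}, fh, indent=1)


def read_prior(path: str | Path) -> PriorDensity:
    with open(path) as fh:
        d = json.load(fh)
    return PriorDensity(tuple(d["names"]), np.array(d["mean"]), np.array(d["cov"]),
                        d.get("physical", {}))


def write_group_truth(truth: GroupTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json())


def read_group_truth(path: str | Path) -> GroupTruth:
    return GroupTruth.from_json(Path(path).read_text())
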