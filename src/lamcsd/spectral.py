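"""Steady-state spectral predictions from the linearized neural mass.

At a stable fixed point the mass model is a linear stochastic system driven
by white + pink input fluctuations with one-sided density
``g_u(f) = alpha_u + beta_u / f``.  Its transfer function
``T(f) = C (i 2 pi f I - J)^{-1} B`` maps those fluctuations to population
depolarizations; a virtual sensor observes the Q-weighted mixture through a
scalar lead field, with additive channel noise ``g_n(f) = alpha_n + beta_n/f``.
A Welch estimator over simulated time series provides the independent
empirical counterpart of the analytic prediction.

All spectral densities are one-sided, per Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .circuit import MassParameters, coupling_matrix, firing_gain, jacobian_at
from .config import POPULATIONS, default_config

__all__ = [
    "SpectralParameters",
    "CrossSpectrum",
    "default_spectral_parameters",
    "noise_spectrum",
    "transfer_function",
    "predict_csd",
    "welch_csd",
    "compare_predictions",
]


@dataclass
class SpectralParameters:
    """Input/channel noise densities and the observation mixture."""

    alpha_u: float = 4e-4
    beta_u: float = 2e-4
    alpha_n: float = 1e-6
    beta_n: float = 1e-6
    Q: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.6, 1.0]))
    lead_field: float = 1.0

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if self.Q.shape != (4,):
            raise ValueError("Q must have shape (4,)")
        for nm in ("alpha_u", "beta_u", "alpha_n", "beta_n"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be non-negative")
        if not np.all(np.isfinite(self.Q)):
            raise ValueError("Q must be finite")


def default_spectral_parameters(cfg: Mapping | None = None) -> SpectralParameters:
    cfg = dict(default_config(), **(cfg or {}))
    return SpectralParameters(
        alpha_u=float(cfg["alpha_u"]), beta_u=float(cfg["beta_u"]),
        alpha_n=float(cfg["alpha_n"]), beta_n=float(cfg["beta_n"]),
        Q=np.array([cfg["q_si"], cfg["q_di"], cfg["q_dp"], cfg["q_sp"]]),
        lead_field=float(cfg["lead_field"]),
    )


@dataclass
class CrossSpectrum:
    """Cross-spectral density on a strictly positive frequency grid.

    ``values`` has shape (n_freqs, n_channels, n_channels); it is Hermitian in
    the channel indices at every frequency with a real non-negative diagonal.
    """

    freqs: np.ndarray
    values: np.ndarray
    channels: tuple[str, ...] = ("ch0",)
    condition: str = "baseline"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        vals = np.asarray(self.values)
        if vals.ndim == 1:
            vals = vals.reshape(-1, 1, 1)
        self.values = vals.astype(complex)
        self.channels = tuple(self.channels)
        self.validate()

    def validate(self) -> None:
        if self.freqs.ndim != 1 or np.any(self.freqs <= 0):
            raise ValueError("frequencies must be strictly positive (pink noise ~ 1/f)")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        F, C = len(self.freqs), len(self.channels)
        if self.values.shape != (F, C, C):
            raise ValueError(f"values must have shape ({F},{C},{C}), got {self.values.shape}")
        if not np.allclose(self.values, np.conj(np.swapaxes(self.values, 1, 2)),
                           rtol=1e-8, atol=1e-12):
            raise ValueError("cross-spectrum is not Hermitian across channel pairs")
        diag = np.diagonal(self.values, axis1=1, axis2=2)
        if np.any(diag.real < -1e-12):
            raise ValueError("auto-spectra must be non-negative")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def power(self, channel: int | str = 0) -> np.ndarray:
        """Real auto-spectrum of one channel."""
        i = self.channels.index(channel) if isinstance(channel, str) else channel
        return self.values[:, i, i].real

    def band_power(self, lo: float, hi: float, channel: int | str = 0) -> float:
        """Trapezoid-integrated power of one channel in [lo, hi] Hz."""
        m = (self.freqs >= lo) & (self.freqs <= hi)
        return float(np.trapezoid(self.power(channel)[m], self.freqs[m]))


def noise_spectrum(alpha: float, beta: float, freqs: np.ndarray) -> np.ndarray:
    """White + pink density ``alpha + beta / f`` on a positive grid."""
    f = np.asarray(freqs, dtype=float)
    if np.any(f <= 0):
        raise ValueError("noise spectrum requires strictly positive frequencies")
    return alpha + beta / f


def _system_matrices(params: MassParameters) -> tuple[np.ndarray, np.ndarray]:
    """(J, B) of the linearization at the zero-drive fixed point (the origin)."""
    J = jacobian_at(params, np.zeros(8))
    B = np.zeros(8)
    B[4:] = params.kappa**2 * params.h * params.input_weights
    return J, B


def transfer_function(params: MassParameters, freqs: np.ndarray,
                      check_stability: bool = True) -> np.ndarray:
    """Complex gain (n_freqs, 4) of each population's depolarization w.r.t. input.

    Raises ``ValueError`` if the linearized system is unstable (no stationary
    spectrum exists).
    """
    freqs = np.asarray(freqs, dtype=float)
    J, B = _system_matrices(params)
    if check_stability:
        ev = np.linalg.eigvals(J)
        if np.any(ev.real >= 0):
            raise ValueError("no stationary spectrum: linearized system is unstable "
                             f"(max Re eigenvalue {ev.real.max():.3g})")
    return _resolvent_gain(J[None], B[None], freqs)[0]


def _resolvent_gain(J: np.ndarray, B: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Batched T = C (i w I - J)^-1 B; J (m,8,8), B (m,8) -> (m, F, 4)."""
    m = J.shape[0]
    B = np.broadcast_to(np.atleast_2d(B), (m, 8))
    w = 2j * np.pi * freqs
    A = w[None, :, None, None] * np.eye(8) - J[:, None]
    sol = np.linalg.solve(A, np.broadcast_to(B[:, None, :, None], (m, len(freqs), 8, 1)))
    return sol[..., :4, 0]


def predict_csd(params: MassParameters,
                spectral: SpectralParameters,
                freqs: np.ndarray,
                layer_resolved: bool = False,
                condition: str = "baseline") -> CrossSpectrum:
    """Analytic steady-state (cross-)spectrum of the observed signal.

    Default: one virtual-sensor channel carrying
    ``|L * (Q . T(f))|^2 g_u(f) + g_n(f)``.  With ``layer_resolved=True`` the
    output instead has the SP and DP depolarization channels (2x2 complex
    cross-spectra), the variant used for construct validity.
    """
    freqs = np.asarray(freqs, dtype=float)
    T = transfer_function(params, freqs)  # (F, 4)
    g_u = noise_spectrum(spectral.alpha_u, spectral.beta_u, freqs)
    g_n = noise_spectrum(spectral.alpha_n, spectral.beta_n, freqs)
    L = spectral.lead_field
    if layer_resolved:
        idx = [POPULATIONS.index("SP"), POPULATIONS.index("DP")]
        Hf = L * T[:, idx]  # (F, 2)
        vals = Hf[:, :, None] * np.conj(Hf[:, None, :]) * g_u[:, None, None]
        vals[:, np.arange(2), np.arange(2)] += g_n[:, None]
        return CrossSpectrum(freqs, vals, ("SP", "DP"), condition)
    s = L * (T @ spectral.Q)
    vals = (np.abs(s) ** 2 * g_u + g_n).reshape(-1, 1, 1)
    return CrossSpectrum(freqs, vals, ("sensor",), condition)


def welch_csd(x: np.ndarray,
              fs: float,
              nperseg: int | None = None,
              noverlap: int | None = None,
              channels: Sequence[str] | None = None,
              fmin: float | None = None,
              fmax: float | None = None,
              condition: str = "baseline") -> CrossSpectrum:
    """Welch-averaged (cross-)periodogram of one or more time series.

    ``x`` is (n_samples,) or (n_samples, n_channels).  Densities are one-sided
    per Hz (scipy ``scaling='density'``); the f = 0 bin is dropped.  Raises on
    series shorter than two segments.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, C = x.shape
    nperseg = int(nperseg or fs)
    if n < 2 * nperseg:
        raise ValueError(f"series length {n} is shorter than two Welch segments ({2*nperseg})")
    f = None
    vals = None
    for i in range(C):
        for j in range(i, C):
            f, sij = sps.csd(x[:, i], x[:, j], fs=fs, nperseg=nperseg,
                             noverlap=noverlap, scaling="density")
            if vals is None:
                vals = np.zeros((len(f), C, C), dtype=complex)
            vals[:, i, j] = sij
            vals[:, j, i] = np.conj(sij)
    keep = f > 0
    if fmin is not None:
        keep &= f >= fmin - 1e-9
    if fmax is not None:
        keep &= f <= fmax + 1e-9
    vals = vals[keep]
    # numerical asymmetry from scipy averaging is below validation tolerance;
    # force exact Hermitian diagonals
    di = np.arange(C)
    vals[:, di, di] = np.clip(vals[:, di, di].real, 0.0, None)
    channels = tuple(channels) if channels is not None else tuple(f"ch{i}" for i in range(C))
    return CrossSpectrum(f[keep], vals, channels, condition)


def compare_predictions(csd_a: CrossSpectrum, csd_b: CrossSpectrum) -> np.ndarray:
    """Pearson correlation of the real auto-spectra, one value per channel."""
    if csd_a.n_channels != csd_b.n_channels:
        raise ValueError("channel count mismatch")
    if len(csd_a.freqs) != len(csd_b.freqs) or not np.allclose(csd_a.freqs, csd_b.freqs):
        raise ValueError("frequency grids differ")
    out = np.empty(csd_a.n_channels)
    for c in range(csd_a.n_channels):
        pa, pb = csd_a.power(c), csd_b.power(c)
        out[c] = np.corrcoef(pa, pb)[0, 1]
    return out
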