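"""Laminar cortical microcircuit and its neural-mass dynamics.

Four populations occupy two cortical depths: superficial inhibitory
interneurons (SI), deep inhibitory interneurons (DI), deep pyramidal cells
(DP) and superficial pyramidal cells (SP).  They are coupled by exactly ten
directed connections, indexed ``a_ij`` = drive to target ``i`` from source
``j`` with 1=SI, 2=DI, 3=DP, 4=SP.  Connections sourced at interneurons and
all self-connections are inhibitory (recurrent inhibition precludes runaway
excitation); the remaining pyramidal projections are excitatory.

Each population's mean depolarization ``v_i`` obeys a critically damped
second-order synaptic response to the signed, connection-weighted firing of
its afferents plus exogenous drive ``u``::

    dv_i/dt = w_i
    dw_i/dt = kappa_i^2 * (h_i * m_i - v_i) - 2 kappa_i * w_i
    m_i     = sum_j s_ij a_ij f(v_j) + c_i u

where ``f`` is a centred sigmoid (``f(0) = 0``), ``kappa_i`` the synaptic
rate constant (1/s), ``h_i`` the synaptic gain (mV) and ``c_i`` the input
weight.  At zero drive the origin is therefore an exact fixed point, which
makes it the canonical linearization point for the spectral forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize

from .config import POPULATIONS, default_config

__all__ = [
    "POPULATIONS",
    "CONNECTION_NAMES",
    "CANONICAL_STRENGTHS",
    "Connection",
    "Microcircuit",
    "build_canonical_circuit",
    "MassParameters",
    "default_mass_parameters",
    "HiddenState",
    "BurstInputSpec",
    "firing",
    "firing_gain",
    "flow",
    "fixed_point",
    "jacobian_at",
    "simulate",
]

#: Connection names in canonical (tabular) order.
CONNECTION_NAMES = ("a44", "a14", "a34", "a41", "a31",
                    "a11", "a33", "a23", "a32", "a22")

#: Canonical (prior-mean) connection strengths, a.u.
CANONICAL_STRENGTHS: Mapping[str, float] = {
    "a44": 4.4, "a14": 4.8, "a34": 3.3, "a41": 3.8, "a31": 5.9,
    "a11": 4.2, "a33": 2.2, "a23": 4.6, "a32": 6.9, "a22": 4.16,
}

_IDX = {"1": "SI", "2": "DI", "3": "DP", "4": "SP"}


@dataclass(frozen=True)
class Connection:
    """A directed edge target <- source with an excitatory/inhibitory sign."""

    name: str
    target: str
    source: str
    sign: int  # +1 excitatory, -1 inhibitory

    @property
    def target_index(self) -> int:
        return POPULATIONS.index(self.target)

    @property
    def source_index(self) -> int:
        return POPULATIONS.index(self.source)


def _connection_sign(target: str, source: str) -> int:
    # interneuron sources and all self-connections inhibit
    if source in ("SI", "DI") or source == target:
        return -1
    return 1


@dataclass(frozen=True)
class Microcircuit:
    """The fixed 4-population, 10-connection laminar circuit."""

    populations: tuple[str, ...]
    connections: tuple[Connection, ...]

    def __post_init__(self) -> None:
        if len(self.populations) != 4:
            raise ValueError("microcircuit has exactly 4 populations")
        if len(self.connections) != 10:
            raise ValueError("microcircuit has exactly 10 connections")

    def connection(self, name: str) -> Connection:
        for c in self.connections:
            if c.name == name:
                return c
        raise KeyError(name)


def build_canonical_circuit() -> Microcircuit:
    """Construct the canonical laminar microcircuit (deterministic)."""
    conns = []
    for name in CONNECTION_NAMES:
        tgt, src = _IDX[name[1]], _IDX[name[2]]
        conns.append(Connection(name, tgt, src, _connection_sign(tgt, src)))
    return Microcircuit(POPULATIONS, tuple(conns))


# indices (target, source, sign) per connection, in CONNECTION_NAMES order
_TGT = np.array([POPULATIONS.index(_IDX[n[1]]) for n in CONNECTION_NAMES])
_SRC = np.array([POPULATIONS.index(_IDX[n[2]]) for n in CONNECTION_NAMES])
_SIGN = np.array([_connection_sign(_IDX[n[1]], _IDX[n[2]]) for n in CONNECTION_NAMES],
                 dtype=float)


def coupling_matrix(a: np.ndarray) -> np.ndarray:
    """Signed 4x4 coupling matrix W[i, j] from the 10 connection strengths.

    ``a`` may be (10,) or batched (..., 10); returns (..., 4, 4).
    """
    a = np.asarray(a, dtype=float)
    W = np.zeros(a.shape[:-1] + (4, 4))
    W[..., _TGT, _SRC] = _SIGN * a
    return W


@dataclass
class MassParameters:
    """All quantities entering the neural-mass ODEs.

    ``a`` holds the 10 non-negative connection magnitudes in canonical order;
    signs come from the circuit, not the magnitudes.
    """

    a: np.ndarray
    kappa: np.ndarray          # (4,) 1/s
    h: np.ndarray              # (4,) mV
    sigmoid_slope: float       # 1/mV
    sigmoid_threshold: float   # mV
    input_weights: np.ndarray  # (4,)
    delays: np.ndarray | None = None  # optional interlaminar delays (s); unused by default

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        self.input_weights = np.asarray(self.input_weights, dtype=float)
        if self.a.shape != (10,):
            raise ValueError("a must have shape (10,)")
        for arr, nm in ((self.kappa, "kappa"), (self.h, "h"),
                        (self.input_weights, "input_weights")):
            if arr.shape != (4,):
                raise ValueError(f"{nm} must have shape (4,)")
        if np.any(self.a < 0):
            raise ValueError("connection magnitudes must be non-negative")
        if np.any(self.kappa <= 0) or np.any(self.h <= 0):
            raise ValueError("kappa and h must be positive")

    @property
    def coupling(self) -> np.ndarray:
        return coupling_matrix(self.a)

    def a_dict(self) -> dict[str, float]:
        return dict(zip(CONNECTION_NAMES, self.a))


def default_mass_parameters(cfg: Mapping | None = None) -> MassParameters:
    """Canonical parameters: tabulated connection strengths + config kernels."""
    cfg = dict(default_config(), **(cfg or {}))
    return MassParameters(
        a=np.array([CANONICAL_STRENGTHS[n] for n in CONNECTION_NAMES]),
        kappa=np.array([cfg["kappa_si"], cfg["kappa_di"], cfg["kappa_dp"], cfg["kappa_sp"]]),
        h=np.array([cfg["h_si"], cfg["h_di"], cfg["h_dp"], cfg["h_sp"]]),
        sigmoid_slope=float(cfg["sigmoid_slope"]),
        sigmoid_threshold=float(cfg["sigmoid_threshold"]),
        input_weights=np.array([cfg["input_si"], cfg["input_di"], cfg["input_dp"], cfg["input_sp"]]),
    )


@dataclass
class HiddenState:
    """Per-population depolarization v (mV) and its derivative channel w (mV/s)."""

    v: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.v.shape != (4,) or self.w.shape != (4,):
            raise ValueError("v and w must have shape (4,)")

    @classmethod
    def zeros(cls) -> "HiddenState":
        return cls(np.zeros(4), np.zeros(4))

    @property
    def x(self) -> np.ndarray:
        return np.concatenate([self.v, self.w])

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "HiddenState":
        x = np.asarray(x, dtype=float)
        return cls(x[:4], x[4:])


def firing(v: np.ndarray, slope: float, threshold: float = 0.0) -> np.ndarray:
    """Centred sigmoid firing transform with firing(0) = 0."""
    s = 1.0 / (1.0 + np.exp(-slope * (np.asarray(v) - threshold)))
    s0 = 1.0 / (1.0 + np.exp(slope * threshold))
    return s - s0


def firing_gain(v: np.ndarray, slope: float, threshold: float = 0.0) -> np.ndarray:
    """Derivative of the firing transform at v."""
    s = 1.0 / (1.0 + np.exp(-slope * (np.asarray(v) - threshold)))
    return slope * s * (1.0 - s)


def _drive_vector(params: MassParameters, drive) -> np.ndarray:
    """Exogenous drive: scalar u is distributed via the input weights."""
    d = np.asarray(drive, dtype=float)
    if d.ndim == 0:
        return params.input_weights * float(d)
    if d.shape != (4,):
        raise ValueError("drive must be scalar or shape (4,)")
    return d


def flow(state: HiddenState | np.ndarray, params: MassParameters, drive=0.0) -> np.ndarray:
    """Time derivative of the hidden states; returns an 8-vector (dv, dw)."""
    x = state.x if isinstance(state, HiddenState) else np.asarray(state, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite hidden state")
    v, w = x[:4], x[4:]
    m = params.coupling @ firing(v, params.sigmoid_slope, params.sigmoid_threshold)
    m = m + _drive_vector(params, drive)
    dv = w
    dw = params.kappa**2 * (params.h * m - v) - 2.0 * params.kappa * w
    return np.concatenate([dv, dw])


def fixed_point(params: MassParameters, drive=0.0, tol: float = 1e-9) -> HiddenState:
    """Equilibrium state under constant drive (w = 0, v solves v = h * m(v))."""
    d = _drive_vector(params, drive)
    W = params.coupling

    def balance(v: np.ndarray) -> np.ndarray:
        f = firing(v, params.sigmoid_slope, params.sigmoid_threshold)
        return params.h * (W @ f + d) - v

    sol = optimize.root(balance, np.zeros(4), method="hybr", tol=1e-12)
    resid = float(np.max(np.abs(balance(sol.x))))
    if not sol.success or resid > tol:
        raise RuntimeError(f"fixed-point search did not converge (residual {resid:.3e})")
    return HiddenState(sol.x, np.zeros(4))


def jacobian_at(params: MassParameters, state: HiddenState | np.ndarray) -> np.ndarray:
    """Exact 8x8 Jacobian of :func:`flow` at the given state."""
    x = state.x if isinstance(state, HiddenState) else np.asarray(state, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite hidden state")
    v = x[:4]
    gain = firing_gain(v, params.sigmoid_slope, params.sigmoid_threshold)
    k2 = params.kappa**2
    J = np.zeros((8, 8))
    J[:4, 4:] = np.eye(4)
    J[4:, :4] = k2[:, None] * params.h[:, None] * params.coupling * gain[None, :]
    J[4:, :4] -= np.diag(k2)
    J[4:, 4:] = -np.diag(2.0 * params.kappa)
    return J


@dataclass
class BurstInputSpec:
    """Burst-like exogenous drive: groups of spike doublets at a fixed period.

    Defaults reproduce 10 groups of 2 spikes separated by 10 ms, with 100 ms
    between group onsets (a 1 s pattern, tiled for longer simulations); events
    are smoothed by a Gaussian kernel to form a continuous drive.
    """

    n_groups: int = 10
    spikes_per_burst: int = 2
    intra_burst_interval_ms: float = 10.0
    inter_group_interval_ms: float = 100.0
    amplitude: float = 0.15
    kernel_width_ms: float = 2.0

    def __post_init__(self) -> None:
        vals = (self.n_groups, self.spikes_per_burst, self.intra_burst_interval_ms,
                self.inter_group_interval_ms, self.amplitude, self.kernel_width_ms)
        if any(v <= 0 for v in vals):
            raise ValueError("all burst parameters must be positive")

    @property
    def pattern_duration(self) -> float:
        """Duration (s) of one full pattern of n_groups bursts."""
        return self.n_groups * self.inter_group_interval_ms / 1000.0

    def event_times(self, duration: float) -> np.ndarray:
        """Spike event times (s) in [0, duration), tiling the pattern."""
        base = []
        for g in range(self.n_groups):
            t0 = g * self.inter_group_interval_ms / 1000.0
            for s in range(self.spikes_per_burst):
                base.append(t0 + s * self.intra_burst_interval_ms / 1000.0)
        base = np.array(base)
        reps = int(np.ceil(duration / self.pattern_duration))
        times = np.concatenate([base + r * self.pattern_duration for r in range(reps)])
        return times[times < duration]

    def drive_array(self, dt: float, duration: float) -> np.ndarray:
        """Sampled smooth drive on a grid of step dt covering [0, duration)."""
        n = int(round(duration / dt))
        drive = np.zeros(n)
        width = self.kernel_width_ms / 1000.0
        half = int(np.ceil(4 * width / dt))
        kern = self.amplitude * np.exp(-0.5 * (np.arange(-half, half + 1) * dt / width) ** 2)
        for t in self.event_times(duration):
            i = int(round(t / dt))
            lo, hi = max(0, i - half), min(n, i + half + 1)
            drive[lo:hi] += kern[(lo - i + half):(hi - i + half)]
        return drive


def simulate(params: MassParameters,
             dt: float,
             duration: float,
             drive: np.ndarray | Callable[[float], float] | None = None,
             x0: HiddenState | np.ndarray | None = None,
             state_bound: float = 1e6) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step explicit integration (Heun scheme) of the neural-mass ODEs.

    The drive is held constant over each step (zero-order hold), so pre-sampled
    stochastic input integrates reproducibly; the second-order scheme keeps the
    numerical damping of the lightly damped oscillatory modes accurate at the
    default step.

    Parameters
    ----------
    drive : array of per-step scalar drive samples, a callable of time, or None.
    Returns ``(t, v)`` with ``v`` of shape (n_steps, 4): the per-population
    depolarization traces.  Deterministic given the drive samples; stochastic
    input is supplied as a pre-sampled drive array.
    """
    kmax = float(np.max(params.kappa))
    if dt * kmax > 0.5:
        raise ValueError(f"dt={dt} too large for fastest kappa={kmax}: require dt*kappa <= 0.5")
    n = int(round(duration / dt))
    if drive is None:
        u = np.zeros(n)
    elif callable(drive):
        u = np.array([drive(i * dt) for i in range(n)])
    else:
        u = np.asarray(drive, dtype=float)
        if u.shape[0] < n:
            raise ValueError("drive array shorter than the simulation grid")
    x = (x0.x if isinstance(x0, HiddenState) else np.asarray(x0, dtype=float)) \
        if x0 is not None else np.zeros(8)
    x = x.copy()

    W = params.coupling
    k2, k, hh = params.kappa**2, params.kappa, params.h
    c = params.input_weights
    slope, thr = params.sigmoid_slope, params.sigmoid_threshold
    s0 = 1.0 / (1.0 + np.exp(slope * thr))
    out = np.empty((n, 4))
    v, w = x[:4].copy(), x[4:].copy()
    half = 0.5 * dt
    for i in range(n):
        ui = c * u[i]
        m = W @ (1.0 / (1.0 + np.exp(-slope * (v - thr))) - s0) + ui
        dw1 = k2 * (hh * m - v) - 2.0 * k * w
        vp = v + dt * w
        wp = w + dt * dw1
        m = W @ (1.0 / (1.0 + np.exp(-slope * (vp - thr))) - s0) + ui
        dw2 = k2 * (hh * m - vp) - 2.0 * k * wp
        v = v + half * (w + wp)
        w = w + half * (dw1 + dw2)
        if not np.isfinite(v).all() or np.abs(v).max() > state_bound:
            raise RuntimeError(f"simulation unstable at t={i*dt:.4f}s with dt={dt}")
        out[i] = v
    t = np.arange(n) * dt
    return t, out
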