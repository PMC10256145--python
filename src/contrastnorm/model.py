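"""Linear-nonlinear cascade model of transient visual interneurons.

The model chains three stages: a first-order band-pass filter (the transient
membrane response to a luminance step in the receptive-field center), a
divisive nonlinearity implementing contrast normalization, and a first-order
low-pass filter standing in for calcium-indicator (GCaMP6f) dynamics.

Two nonlinearities are provided:

* **static** — the memoryless saturation ``y = x / (x + k)``, where ``k``
  sets the half-saturation point and is controlled by the visual surround
  (small ``k`` for a static surround, large ``k`` for a dynamic one).
* **dynamic** — a conductance-based membrane update in which the
  normalizing signal acts as a shunting inhibitory conductance.  Writing the
  passive-membrane equation as a difference equation (drive ``g_exc = x``,
  leak and inhibition folded into ``k``, reversal potentials
  ``E_inh = E_leak = 0``) gives

      V(t) = (x(t-dt) * E_exc + V(t-dt) * C/dt) / (x(t-dt) + k + C/dt)

  whose fixed point under constant drive is the steady-state voltage
  ``x * E_exc / (x + k)`` — i.e. the static nonlinearity.  Away from steady
  state, ``k`` also sets the effective membrane time constant
  (roughly ``(C/dt) / (x + k)`` time steps), so a dynamic surround both
  divides the amplitude and speeds the response up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from scipy.signal import lfilter

__all__ = [
    "SignalTrace",
    "ModelParams",
    "low_pass",
    "high_pass",
    "band_pass",
    "static_nl",
    "dynamic_nl",
    "run_cascade",
    "make_pulse",
    "steady_state_voltage",
]


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

@dataclass
class SignalTrace:
    """A uniformly sampled real-valued time series.

    Parameters
    ----------
    values
        Sample values.  Must be finite.
    dt
        Sample interval in seconds; must be positive.
    t0
        Time of the first sample, seconds.
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        return self.values.size * self.dt

    def normalized(self) -> "SignalTrace":
        """Divide by the maximum over the trace; a non-positive peak leaves
        the trace unchanged (nothing to normalize)."""
        peak = float(self.values.max(initial=0.0))
        if peak <= 0:
            return replace(self, values=self.values.copy())
        return replace(self, values=self.values / peak)

    def to_csv(self, path: str | Path) -> None:
        """Write a two-column (time, value) CSV."""
        arr = np.column_stack([self.times, self.values])
        np.savetxt(path, arr, delimiter=",", header="time,value", comments="")


_NL_MODES = ("static", "dynamic")


@dataclass
class ModelParams:
    """Cascade constants.

    Attributes
    ----------
    tau_lp, tau_hp
        Time constants (s) of the low- and high-pass stages of the band-pass
        filter; defaults 200 ms and 300 ms.
    tau_ca
        Calcium-indicator low-pass time constant (s), default 200 ms.
    k
        Saturation / inhibitory-plus-leak conductance (dimensionless).
        0.2 emulates a static surround, 1.0 a dynamic (e.g. moving-grating)
        surround.
    e_exc
        Excitatory reversal potential, normalized to 1.0.
    c_over_dt
        Membrane capacitance per time step, dimensionless ratio (100.0).
        Specified as the ratio itself, independent of ``dt``.
    dt
        Simulation step in seconds.
    nl_mode
        Which nonlinearity the cascade uses: ``"static"`` or ``"dynamic"``.
    """

    tau_lp: float = 0.2
    tau_hp: float = 0.3
    tau_ca: float = 0.2
    k: float = 0.2
    e_exc: float = 1.0
    c_over_dt: float = 100.0
    dt: float = 0.001
    nl_mode: Literal["static", "dynamic"] = "static"

    def __post_init__(self) -> None:
        for name in ("tau_lp", "tau_hp", "tau_ca", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.k < 0:
            raise ValueError("k must be non-negative")
        if self.c_over_dt < 0:
            raise ValueError("c_over_dt must be non-negative")
        if self.nl_mode not in _NL_MODES:
            raise ValueError(f"nl_mode must be one of {_NL_MODES}")

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown model parameters: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParams":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls.from_dict(cfg.get("model", cfg))


# --------------------------------------------------------------------------
# Linear stages
# --------------------------------------------------------------------------

def _lp_values(x: np.ndarray, tau: float, dt: float) -> np.ndarray:
    # Exact exponential integrator: y <- y + (1 - exp(-dt/tau)) (x - y),
    # unconditionally stable for any dt/tau.
    a = 1.0 - math.exp(-dt / tau)
    return lfilter([a], [1.0, -(1.0 - a)], x)


def low_pass(x: SignalTrace, tau: float) -> SignalTrace:
    """First-order low-pass filter with unit DC gain, initial state 0."""
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    return replace(x, values=_lp_values(x.values, tau, x.dt))


def high_pass(x: SignalTrace, tau: float) -> SignalTrace:
    """First-order high-pass filter (input minus its low-pass); zero DC gain."""
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    return replace(x, values=x.values - _lp_values(x.values, tau, x.dt))


def band_pass(x: SignalTrace, tau_lp: float = 0.2, tau_hp: float = 0.3) -> SignalTrace:
    """Serial low-pass then high-pass; transient response to steps, zero DC.

    Stage order is immaterial for these linear time-invariant stages and is
    fixed (LP then HP) for reproducibility.
    """
    return high_pass(low_pass(x, tau_lp), tau_hp)


# --------------------------------------------------------------------------
# Nonlinearities
# --------------------------------------------------------------------------

def _rectify(x: np.ndarray) -> np.ndarray:
    # Drive is read as an excitatory conductance, hence non-negative; this
    # also keeps the static form away from its pole at x = -k.
    return np.maximum(x, 0.0)


def static_nl(x: SignalTrace, k: float) -> SignalTrace:
    """Memoryless divisive saturation ``y = x+ / (x+ + k)``.

    ``x+`` is the half-wave-rectified input; the output lies in [0, 1).
    The half-saturation point is at ``x = k``.
    """
    if k <= 0:
        raise ValueError(f"k must be positive for the static nonlinearity, got {k}")
    xp = _rectify(x.values)
    return replace(x, values=xp / (xp + k))


def dynamic_nl(x: SignalTrace, params: ModelParams) -> SignalTrace:
    """Conductance-based membrane update driven by the rectified input.

    Iterates, from rest (``y(0) = 0``),

        y(t) = (x+(t-dt) * E_exc + y(t-dt) * C/dt) / (x+(t-dt) + k + C/dt)

    The output is bounded in [0, E_exc].  Under constant drive the iteration
    converges to the steady-state membrane voltage
    ``x+ * E_exc / (x+ + k)`` (see :func:`steady_state_voltage`); for
    ``C/dt -> 0`` it reduces to the static nonlinearity with a one-step lag.
    """
    xp = _rectify(x.values)
    k, e_exc, c = params.k, params.e_exc, params.c_over_dt
    if k == 0 and c == 0 and np.any(xp == 0):
        raise ValueError("denominator vanishes: x+, k and C/dt are all zero")
    y = np.empty_like(xp)
    if y.size == 0:
        return replace(x, values=y)
    y[0] = 0.0
    num_drive = xp * e_exc
    den = xp + k + c
    prev = 0.0
    for t in range(1, y.size):
        prev = (num_drive[t - 1] + prev * c) / den[t - 1]
        y[t] = prev
    return replace(x, values=y)


def steady_state_voltage(g_exc: float, k: float, e_exc: float = 1.0) -> float:
    """Closed-form steady-state membrane voltage ``g_exc E_exc / (g_exc + k)``.

    ``k`` lumps the inhibitory and leak conductances (shunting inhibition,
    ``E_inh = E_leak = 0``, voltages relative to ``E_leak``).
    """
    if g_exc + k <= 0:
        raise ValueError("g_exc + k must be positive")
    return g_exc * e_exc / (g_exc + k)


# --------------------------------------------------------------------------
# Cascade
# --------------------------------------------------------------------------

def run_cascade(
    x: SignalTrace, params: ModelParams, normalize: bool = False
) -> SignalTrace:
    """Band-pass -> (static | dynamic) nonlinearity -> calcium low-pass.

    With ``normalize=True`` the output is divided by its maximum over the
    simulated window, matching how measured responses are peak-normalized
    before their kinetics are compared.
    """
    bp = band_pass(x, params.tau_lp, params.tau_hp)
    if params.nl_mode == "static":
        nl = static_nl(bp, params.k)
    else:
        nl = dynamic_nl(bp, params)
    out = low_pass(nl, params.tau_ca)
    return out.normalized() if normalize else out


def make_pulse(
    amplitude: float,
    duration: float = 1.0,
    total: float = 3.0,
    dt: float = 0.001,
    rest: float = 1.0,
) -> SignalTrace:
    """Rectangular pulse of the given amplitude after an initial rest period.

    The rest period (default 1 s) lets filter states settle from zero before
    pulse onset.  ``round(total / dt)`` samples are produced.
    """
    if duration <= 0 or total <= 0 or duration > total:
        raise ValueError("need 0 < duration <= total")
    if rest < 0 or rest + duration > total:
        raise ValueError("pulse must fit inside the total window")
    n = round(total / dt)
    t = dt * np.arange(n)
    values = np.where((t >= rest) & (t < rest + duration), amplitude, 0.0)
    return SignalTrace(values=values, dt=dt)
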