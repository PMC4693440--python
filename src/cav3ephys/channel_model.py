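"""Closed-form gating model of the Cav3.1 (CACNA1G) T-type calcium channel.

The channel is described by a Hodgkin–Huxley-style scheme with one activation
gate ``m`` (raised to a configurable integer exponent) and one inactivation
(availability) gate ``h``.  Steady-state voltage dependence of both gates is
Boltzmann (logistic):

    m_inf(V) = 1 / (1 + exp((V_half_act - V) / k_act))      (rising)
    h_inf(V) = 1 / (1 + exp((V - V_half_inact) / k_inact))  (falling)

Whole-cell current under a linear (ohmic) driving force is

    I(V, t) = g_max * m(t)**p * h(t) * (V - E_rev)

with units fixed throughout the package: mV, ms, nS, pA (1 nS * 1 mV = 1 pA).
Within each constant-voltage segment of a clamp protocol the gates relax
exponentially toward their steady state, which gives the step response in
closed form — no ODE solver is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .protocols import VoltageProtocol

__all__ = [
    "TauParams",
    "GatingParams",
    "GateState",
    "steady_state_activation",
    "steady_state_inactivation",
    "tau_m",
    "tau_h",
    "simulate_step_response",
    "window_current_curve",
    "WindowCurrent",
]


@dataclass(frozen=True)
class TauParams:
    """Sigmoid-of-voltage time-constant parameterization (ms).

    tau(V) = floor + amp / (1 + exp((V - v_mid) / slope))

    Monotonically non-increasing in V for amp >= 0, slope > 0: kinetics speed
    up with depolarization, bounded below by ``floor``.
    """

    floor_ms: float
    amp_ms: float
    v_mid_mv: float = -60.0
    slope_mv: float = 8.0

    def __post_init__(self) -> None:
        if not (self.floor_ms > 0):
            raise ValueError(f"tau floor must be > 0 ms, got {self.floor_ms}")
        if self.amp_ms < 0:
            raise ValueError(f"tau amplitude must be >= 0 ms, got {self.amp_ms}")
        if not (self.slope_mv > 0):
            raise ValueError(f"tau slope must be > 0 mV, got {self.slope_mv}")

    def __call__(self, v: float | np.ndarray) -> float | np.ndarray:
        v = _check_voltage(v)
        return self.floor_ms + self.amp_ms / (1.0 + np.exp((v - self.v_mid_mv) / self.slope_mv))


@dataclass(frozen=True)
class GatingParams:
    """Biophysical parameter vector of a single model cell.

    Defaults are the wild-type group means; construct variants with
    :func:`dataclasses.replace` or the group factories in
    :mod:`cav3ephys.synthetic_data`.
    """

    g_max: float = 5.0          # maximum conductance, nS
    e_rev: float = 45.0         # effective reversal potential, mV
    v_half_act: float = -57.5   # half-activation potential, mV
    k_act: float = 6.4          # activation slope factor, mV
    v_half_inact: float = -79.1  # half-inactivation potential, mV
    k_inact: float = 6.3        # inactivation slope factor, mV
    act_exponent: int = 1       # integer exponent on the activation gate
    tau_m_params: TauParams = field(default_factory=lambda: TauParams(floor_ms=1.0, amp_ms=9.0))
    tau_h_params: TauParams = field(default_factory=lambda: TauParams(floor_ms=12.0, amp_ms=50.0))

    def __post_init__(self) -> None:
        if not (self.g_max > 0):
            raise ValueError(f"g_max must be > 0 nS, got {self.g_max}")
        if not (self.k_act > 0):
            raise ValueError(f"k_act must be > 0 mV, got {self.k_act}")
        if not (self.k_inact > 0):
            raise ValueError(f"k_inact must be > 0 mV, got {self.k_inact}")
        if not (isinstance(self.act_exponent, (int, np.integer)) and self.act_exponent >= 1):
            raise ValueError(f"act_exponent must be an integer >= 1, got {self.act_exponent}")

    def with_(self, **kwargs) -> "GatingParams":
        return replace(self, **kwargs)


@dataclass
class GateState:
    """Instantaneous gate fractions carried across protocol segments."""

    m: float
    h: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.m <= 1.0 and 0.0 <= self.h <= 1.0):
            raise ValueError(f"gate fractions must lie in [0, 1], got m={self.m}, h={self.h}")


def _check_voltage(v):
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("membrane potential must be finite")
    return v if v.ndim else float(v)


def steady_state_activation(v, p: GatingParams):
    """Boltzmann steady-state activation m_inf(V); rising, 0.5 at v_half_act."""
    v = _check_voltage(v)
    return 1.0 / (1.0 + np.exp((p.v_half_act - v) / p.k_act))


def steady_state_inactivation(v, p: GatingParams):
    """Boltzmann steady-state availability h_inf(V); falling, 0.5 at v_half_inact."""
    v = _check_voltage(v)
    return 1.0 / (1.0 + np.exp((v - p.v_half_inact) / p.k_inact))


def tau_m(v, p: GatingParams):
    """Activation time constant (ms) at potential ``v``."""
    return p.tau_m_params(v)


def tau_h(v, p: GatingParams):
    """Inactivation time constant (ms) at potential ``v``."""
    return p.tau_h_params(v)


def _segment_gate_trace(x0: float, x_inf: float, tau: float, t: np.ndarray) -> np.ndarray:
    # exact relaxation within a constant-voltage segment
    return x_inf + (x0 - x_inf) * np.exp(-t / tau)


def simulate_step_response(
    p: GatingParams, protocol: VoltageProtocol, include_gates: bool = False
) -> "pd.DataFrame":
    """Simulate whole-cell current for every sweep of a clamp protocol.

    Gates start at steady state for the first segment's level (the holding
    potential) and relax exponentially within each segment; end-of-segment
    state is carried over, so gate values are continuous across boundaries.
    Deterministic and noise-free.

    Returns a tidy table with columns ``sweep_id, time_ms, voltage_mV,
    current_pA`` (plus ``m, h`` when ``include_gates``); ``time_ms`` restarts
    at 0 for each sweep and is left-aligned (first sample of a segment sits
    at the new level).
    """
    import pandas as pd

    if protocol.n_sweeps == 0:
        raise ValueError("protocol has no sweeps")
    frames = []
    for sweep_id in range(protocol.n_sweeps):
        segments = protocol.sweep_segments(sweep_id)
        dt_ms = 1000.0 / protocol.sampling_rate_hz
        m0 = float(steady_state_activation(segments[0].level_mv, p))
        h0 = float(steady_state_inactivation(segments[0].level_mv, p))
        t_offset = 0.0
        times, volts, currents = [], [], []
        m_all, h_all = [], []
        for seg in segments:
            n = protocol.segment_sample_count(seg)
            t_local = np.arange(n) * dt_ms
            v = seg.level_mv
            m_inf = float(steady_state_activation(v, p))
            h_inf = float(steady_state_inactivation(v, p))
            t_m = float(tau_m(v, p))
            t_h = float(tau_h(v, p))
            m = _segment_gate_trace(m0, m_inf, t_m, t_local)
            h = _segment_gate_trace(h0, h_inf, t_h, t_local)
            i = p.g_max * m**p.act_exponent * h * (v - p.e_rev)
            times.append(t_local + t_offset)
            volts.append(np.full(n, v))
            currents.append(i)
            m_all.append(m)
            h_all.append(h)
            # carry-over uses the exact end-of-segment state, not the last sample
            m0 = float(_segment_gate_trace(m0, m_inf, t_m, np.array([seg.duration_ms]))[0])
            h0 = float(_segment_gate_trace(h0, h_inf, t_h, np.array([seg.duration_ms]))[0])
            t_offset += seg.duration_ms
        cols = {
            "sweep_id": sweep_id,
            "time_ms": np.concatenate(times),
            "voltage_mV": np.concatenate(volts),
            "current_pA": np.concatenate(currents),
        }
        if include_gates:
            cols["m"] = np.concatenate(m_all)
            cols["h"] = np.concatenate(h_all)
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class WindowCurrent:
    """Activation x availability overlap curve and its maximum."""

    v_grid: np.ndarray
    curve: np.ndarray
    peak_voltage_mv: float
    peak_fraction: float


def _as_boltzmann(obj, which: str) -> tuple[float, float]:
    """Accept a GatingParams, a fitted object with v_half/k, or a (v_half, k) pair."""
    if isinstance(obj, GatingParams):
        if which == "act":
            return obj.v_half_act, obj.k_act
        return obj.v_half_inact, obj.k_inact
    if hasattr(obj, "v_half") and hasattr(obj, "k"):
        return float(obj.v_half), float(obj.k)
    v_half, k = obj
    return float(v_half), float(k)


def window_current_curve(act, inact, v_grid) -> WindowCurrent:
    """Window current: w(V) = m_inf(V) * h_inf(V) on a voltage grid.

    ``act`` and ``inact`` may each be a :class:`GatingParams`, a Boltzmann fit
    with ``v_half``/``k`` attributes, or a plain ``(v_half, k)`` pair.  Returns
    the product curve with its grid argmax and maximum; a steady fraction of
    channels conducts in this overlap region.
    """
    v_grid = np.asarray(v_grid, dtype=float)
    if v_grid.size == 0:
        raise ValueError("voltage grid is empty")
    if not np.all(np.isfinite(v_grid)):
        raise ValueError("voltage grid must be finite")
    va, ka = _as_boltzmann(act, "act")
    vi, ki = _as_boltzmann(inact, "inact")
    if not (ka > 0 and ki > 0):
        raise ValueError("slope factors must be > 0")
    act_curve = 1.0 / (1.0 + np.exp((va - v_grid) / ka))
    inact_curve = 1.0 / (1.0 + np.exp((v_grid - vi) / ki))
    w = act_curve * inact_curve
    idx = int(np.argmax(w))
    return WindowCurrent(
        v_grid=v_grid, curve=w, peak_voltage_mv=float(v_grid[idx]), peak_fraction=float(w[idx])
    )
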