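"""Analysis chain from raw voltage-clamp sweeps to fitted gating parameters.

Mirrors the standard whole-cell workflow for low-threshold calcium currents:

1. peak current per sweep (signed extremum in the test segment after a
   capacitive blanking window) -> peak I–V curve;
2. reversal potential by ordinary least-squares line fit of the peak I–V over
   the near-linear depolarized range (-10..+30 mV by default);
3. relative conductance G(V) = I_peak / (V - V_rev), normalized to its
   maximum, fitted per cell with a rising Boltzmann;
4. steady-state inactivation: normalized test-pulse peaks vs prepulse
   voltage, fitted with a falling Boltzmann;
5. kinetics: single-exponential decay time constant and 10–90 % rise time
   per test step;
6. group statistics: two-sided Mann–Whitney U (exact for small tie-free
   samples) on every fitted measure, plus the window-current summary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .channel_model import window_current_curve
from .protocols import VoltageProtocol

__all__ = [
    "IVCurve",
    "BoltzmannFit",
    "DecayFit",
    "GroupComparison",
    "PipelineResult",
    "extract_peak_currents",
    "estimate_reversal_potential",
    "relative_conductance",
    "fit_boltzmann",
    "steady_state_inactivation_curve",
    "fit_decay_tau",
    "rise_time_10_90",
    "compare_groups",
    "exact_mannwhitney_p",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

DEFAULT_BLANKING_MS = 2.0
DEFAULT_REVERSAL_RANGE = (-10.0, 30.0)
DEFAULT_EXCLUSION_MARGIN_MV = 10.0
K_BOUNDS_MV = (0.5, 30.0)


@dataclass
class IVCurve:
    """Peak current-voltage relationship (one peak per sweep)."""

    voltages_mv: np.ndarray
    peaks_pa: np.ndarray
    latencies_ms: np.ndarray  # peak time relative to step onset
    blanking_ms: float

    def __post_init__(self) -> None:
        if len(np.unique(self.voltages_mv)) != len(self.voltages_mv):
            raise ValueError("step voltages must be unique")


@dataclass
class BoltzmannFit:
    v_half: float
    k: float
    amplitude: float
    rss: float
    converged: bool
    n_points: int


@dataclass
class DecayFit:
    tau_ms: float
    amplitude_pa: float
    offset_pa: float
    converged: bool


def _sweep_window(sweep_df, protocol: VoltageProtocol, segment_index: int, blanking_ms: float):
    start, end = protocol.segment_bounds_ms()[segment_index]
    t = sweep_df["time_ms"].to_numpy()
    mask = (t >= start + blanking_ms) & (t < end)
    if not mask.any():
        raise ValueError(
            f"blanking window {blanking_ms} ms leaves no samples in segment {segment_index}"
        )
    return t[mask] - start, sweep_df["current_pA"].to_numpy()[mask]


def extract_peak_currents(
    sweeps: pd.DataFrame,
    protocol: VoltageProtocol,
    blanking_ms: float = DEFAULT_BLANKING_MS,
    direction: str = "inward",
    segment_index: int | None = None,
) -> IVCurve:
    """Peak (signed extremum) current per sweep within the test segment.

    The first ``blanking_ms`` after the segment transition are excluded to
    mimic capacitive-artifact blanking.  ``direction='inward'`` takes the
    minimum (negative peaks), ``'outward'`` the maximum.  The returned curve
    is keyed by the protocol's sweep-varying level.
    """
    if direction not in ("inward", "outward"):
        raise ValueError(f"direction must be 'inward' or 'outward', got {direction!r}")
    if segment_index is None:
        segment_index = len(protocol.segments) - 1
    voltages, peaks, latencies = [], [], []
    for sweep_id, sweep_df in sweeps.groupby("sweep_id"):
        t, i = _sweep_window(sweep_df, protocol, segment_index, blanking_ms)
        idx = int(np.argmin(i)) if direction == "inward" else int(np.argmax(i))
        voltages.append(protocol.sweep_levels_mv[sweep_id])
        peaks.append(float(i[idx]))
        latencies.append(float(t[idx]))
    return IVCurve(
        voltages_mv=np.asarray(voltages),
        peaks_pa=np.asarray(peaks),
        latencies_ms=np.asarray(latencies),
        blanking_ms=blanking_ms,
    )


class DegenerateFitError(ValueError):
    """Raised when a fit is not identifiable from the provided points."""


def estimate_reversal_potential(
    iv: IVCurve,
    fit_range=DEFAULT_REVERSAL_RANGE,
    slope_tol: float = 1e-9,
) -> float:
    """Reversal potential from the zero-crossing of an OLS line through the
    peak I–V points inside ``fit_range`` (default -10..+30 mV, where the
    channel is essentially fully activated and the I–V is near-linear)."""
    lo, hi = fit_range
    mask = (iv.voltages_mv >= lo) & (iv.voltages_mv <= hi)
    if mask.sum() < 2:
        raise DegenerateFitError(f"need >= 2 I-V points in [{lo}, {hi}] mV, have {int(mask.sum())}")
    res = stats.linregress(iv.voltages_mv[mask], iv.peaks_pa[mask])
    if abs(res.slope) < slope_tol:
        raise DegenerateFitError("I-V slope indistinguishable from zero; no zero-crossing")
    return float(-res.intercept / res.slope)


def relative_conductance(
    iv: IVCurve,
    v_rev: float,
    exclusion_margin_mv: float = DEFAULT_EXCLUSION_MARGIN_MV,
):
    """Chord conductance G(V) = I_peak / (V - V_rev), normalized to max |G|.

    Voltages within ``exclusion_margin_mv`` of the reversal potential are
    excluded (the quotient is dominated by noise as the driving force
    vanishes).  Returns ``(voltages, g_rel)``.
    """
    mask = np.abs(iv.voltages_mv - v_rev) >= exclusion_margin_mv
    if not mask.any():
        raise ValueError("all I-V points fall inside the reversal exclusion margin")
    v = iv.voltages_mv[mask]
    g = iv.peaks_pa[mask] / (v - v_rev)
    g_max = np.max(np.abs(g))
    if g_max == 0:
        raise DegenerateFitError("all conductances are zero")
    return v, g / g_max


def _boltzmann_rising(v, amp, v_half, k):
    return amp / (1.0 + np.exp((v_half - v) / k))


def _boltzmann_falling(v, amp, v_half, k):
    return amp / (1.0 + np.exp((v - v_half) / k))


def _init_v_half(v, y, amp, orientation):
    """Linear interpolation of the half-maximum crossing for the start value."""
    order = np.argsort(v)
    v, y = np.asarray(v)[order], np.asarray(y)[order]
    half = amp / 2.0
    sign = y - half
    crossings = np.flatnonzero(np.diff(np.sign(sign)) != 0)
    if crossings.size:
        j = crossings[0]
        frac = (half - y[j]) / (y[j + 1] - y[j])
        return float(v[j] + frac * (v[j + 1] - v[j]))
    return float(np.median(v))


def fit_boltzmann(
    v,
    y,
    orientation: str = "rising",
    k_init: float = 6.5,
) -> BoltzmannFit:
    """Nonlinear least-squares Boltzmann fit amp / (1 + exp(±(V_half - V)/k)).

    ``orientation='rising'`` fits an activation-style curve (increasing in V),
    ``'falling'`` an availability-style curve.  Slope factor bounded to
    [0.5, 30] mV; a fit that fails to converge, or lands on the slope bound,
    is returned with ``converged=False`` and must be excluded from group
    statistics.
    """
    if orientation not in ("rising", "falling"):
        raise ValueError(f"orientation must be 'rising' or 'falling', got {orientation!r}")
    v = np.asarray(v, dtype=float)
    y = np.asarray(y, dtype=float)
    if v.size < 4:
        raise ValueError(f"need >= 4 points for a Boltzmann fit, have {v.size}")
    model = _boltzmann_rising if orientation == "rising" else _boltzmann_falling
    amp0 = float(np.max(np.abs(y)))
    if amp0 == 0 or np.ptp(y) == 0:
        return BoltzmannFit(math.nan, math.nan, math.nan, math.nan, False, v.size)
    amp0 = math.copysign(amp0, np.mean(y))
    p0 = [amp0, _init_v_half(v, y, amp0, orientation), k_init]
    lo = [-10.0 * abs(amp0), v.min() - 100.0, K_BOUNDS_MV[0]]
    hi = [10.0 * abs(amp0), v.max() + 100.0, K_BOUNDS_MV[1]]
    try:
        popt, _ = optimize.curve_fit(model, v, y, p0=p0, bounds=(lo, hi), maxfev=10_000)
    except (RuntimeError, ValueError):
        return BoltzmannFit(math.nan, math.nan, math.nan, math.nan, False, v.size)
    amp, v_half, k = (float(x) for x in popt)
    rss = float(np.sum((model(v, *popt) - y) ** 2))
    at_bound = k <= K_BOUNDS_MV[0] + 1e-6 or k >= K_BOUNDS_MV[1] - 1e-6
    return BoltzmannFit(v_half, k, amp, rss, converged=not at_bound, n_points=v.size)


def steady_state_inactivation_curve(
    sweeps: pd.DataFrame,
    protocol: VoltageProtocol,
    blanking_ms: float = DEFAULT_BLANKING_MS,
    direction: str = "inward",
):
    """Availability curve: test-pulse peak per prepulse voltage, normalized to
    the most hyperpolarized prepulse's peak.  Returns ``(prepulse_v, rel)``."""
    iv = extract_peak_currents(
        sweeps,
        protocol,
        blanking_ms=blanking_ms,
        direction=direction,
        segment_index=len(protocol.segments) - 1,
    )
    prepulse_v = iv.voltages_mv  # the sweep-varying level is the prepulse
    order = np.argsort(prepulse_v)
    prepulse_v, peaks = prepulse_v[order], iv.peaks_pa[order]
    ref = peaks[0]  # most hyperpolarized prepulse
    if ref == 0:
        raise DegenerateFitError("reference peak (most hyperpolarized prepulse) is zero")
    return prepulse_v, peaks / ref


def fit_decay_tau(
    time_ms,
    current_pa,
    fit_window_ms: float | None = None,
) -> DecayFit:
    """Single-exponential fit I(t) = A exp(-(t - t_peak)/tau) + C of the decay
    phase from the (signed) peak to the end of the trace.

    A non-decaying trace (no relaxation of at least 5 % of the peak-to-end
    amplitude) is flagged ``converged=False`` with tau = nan.
    """
    t = np.asarray(time_ms, dtype=float)
    i = np.asarray(current_pa, dtype=float)
    i_peak_idx = int(np.argmax(np.abs(i)))
    t_fit = t[i_peak_idx:]
    i_fit = i[i_peak_idx:]
    if fit_window_ms is not None:
        mask = t_fit <= t_fit[0] + fit_window_ms
        t_fit, i_fit = t_fit[mask], i_fit[mask]
    if t_fit.size < 4:
        return DecayFit(math.nan, math.nan, math.nan, False)
    a0 = i_fit[0] - i_fit[-1]
    if abs(a0) < 0.05 * max(abs(i_fit[0]), 1e-12):
        return DecayFit(math.nan, math.nan, math.nan, False)

    def model(t, a, tau, c):
        return a * np.exp(-(t - t_fit[0]) / tau) + c

    span = max(t_fit[-1] - t_fit[0], 1e-6)
    try:
        popt, _ = optimize.curve_fit(
            model,
            t_fit,
            i_fit,
            p0=[a0, span / 3.0, i_fit[-1]],
            bounds=([-np.inf, 1e-6, -np.inf], [np.inf, 100.0 * span, np.inf]),
            maxfev=10_000,
        )
    except (RuntimeError, ValueError):
        return DecayFit(math.nan, math.nan, math.nan, False)
    return DecayFit(tau_ms=float(popt[1]), amplitude_pa=float(popt[0]), offset_pa=float(popt[2]),
                    converged=True)


def rise_time_10_90(time_ms, current_pa) -> float:
    """10–90 % rise time (ms) of the current onset, baseline-subtracted and
    direction-aware, with linear interpolation between samples.

    Returns nan if the peak sits on the first sample (onset not captured);
    returns 0.0 if both threshold crossings fall inside the same inter-sample
    interval (unresolvable at this sampling rate).
    """
    t = np.asarray(time_ms, dtype=float)
    i = np.asarray(current_pa, dtype=float)
    baseline = i[0]
    x = i - baseline
    peak_idx = int(np.argmax(np.abs(x)))
    if peak_idx == 0:
        return math.nan
    amp = x[peak_idx]
    sign = 1.0 if amp >= 0 else -1.0
    mag = sign * x[: peak_idx + 1]  # monotone-ish onset, positive-going
    thresholds = (0.1 * abs(amp), 0.9 * abs(amp))
    crossing_times = []
    crossing_idx = []
    for thr in thresholds:
        above = np.flatnonzero(mag >= thr)
        j = int(above[0])
        crossing_idx.append(j)
        if j == 0:
            crossing_times.append(t[0])
            continue
        frac = (thr - mag[j - 1]) / (mag[j] - mag[j - 1])
        crossing_times.append(t[j - 1] + frac * (t[j] - t[j - 1]))
    if crossing_idx[0] == crossing_idx[1]:
        return 0.0
    return float(crossing_times[1] - crossing_times[0])


# ---------------------------------------------------------------------------
# group statistics


@dataclass
class GroupComparison:
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    u_statistic: float
    p_value: float
    exact: bool
    degenerate: bool = False  # all values identical across both groups


def exact_mannwhitney_p(a, b) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney p by full enumeration of the C(n_a+n_b,
    n_a) group assignments of the pooled ranks (no ties assumed).

    Independent of any library routine; used as the small-sample exact path
    and as a cross-check oracle.  Returns ``(U_a, p)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n, n_a = len(pooled), len(a)
    ranks = stats.rankdata(pooled)
    u_a = float(np.sum(ranks[:n_a]) - n_a * (n_a + 1) / 2.0)
    mean_u = n_a * (n - n_a) / 2.0
    obs_dev = abs(u_a - mean_u)
    count = 0
    total = 0
    all_ranks_sorted = np.sort(ranks)
    for combo in combinations(range(n), n_a):
        u = float(np.sum(all_ranks_sorted[list(combo)]) - n_a * (n_a + 1) / 2.0)
        if abs(u - mean_u) >= obs_dev - 1e-12:
            count += 1
        total += 1
    return u_a, count / total


EXACT_MAX_N = 25


def compare_groups(values_a, values_b, method: str = "auto") -> GroupComparison:
    """Two-sided Mann–Whitney U comparison of two groups.

    Exact null distribution when the pooled sample is tie-free and
    n_a + n_b <= 25; otherwise mid-rank asymptotic with tie correction.
    Identical values across both groups yield p = 1 with a degenerate flag.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    summary = dict(
        n_a=len(a),
        n_b=len(b),
        mean_a=float(np.mean(a)),
        sd_a=float(np.std(a, ddof=1)),
        mean_b=float(np.mean(b)),
        sd_b=float(np.std(b, ddof=1)),
    )
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        u = len(a) * len(b) / 2.0
        return GroupComparison(**summary, u_statistic=u, p_value=1.0, exact=False,
                               degenerate=True)
    has_ties = len(np.unique(pooled)) < len(pooled)
    use_exact = (method == "exact") or (
        method == "auto" and not has_ties and len(pooled) <= EXACT_MAX_N
    )
    scipy_method = "exact" if (use_exact and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=scipy_method)
    return GroupComparison(
        **summary,
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        exact=scipy_method == "exact",
    )


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineResult:
    cells: pd.DataFrame           # per-cell fitted parameters and flags
    kinetics: pd.DataFrame        # per cell x step voltage: decay tau, rise time
    comparisons: dict             # measure -> GroupComparison
    peak_comparisons: pd.DataFrame  # per step voltage: group peak-amplitude stats
    excluded_cells: list


_COMPARED_MEASURES = ("v_half_act", "k_act", "v_half_inact", "k_inact", "window_peak_v")


def analyze_cell(
    rec,
    blanking_ms: float = DEFAULT_BLANKING_MS,
    reversal_range=DEFAULT_REVERSAL_RANGE,
    exclusion_margin_mv: float = DEFAULT_EXCLUSION_MARGIN_MV,
    v_rev: float | None = None,
) -> dict:
    """Run the full single-cell chain; returns a flat result record.

    ``v_rev`` overrides the I–V line-fit reversal estimate (e.g. when the
    true reversal potential is known from the recording solutions); by
    default it is estimated from the peak I–V as in the standard workflow.
    """
    iv = extract_peak_currents(rec.activation_sweeps, rec.act_protocol, blanking_ms=blanking_ms)
    if v_rev is None:
        v_rev = estimate_reversal_potential(iv, fit_range=reversal_range)
    v_g, g_rel = relative_conductance(iv, v_rev, exclusion_margin_mv=exclusion_margin_mv)
    act_fit = fit_boltzmann(v_g, g_rel, orientation="rising")
    v_pre, rel = steady_state_inactivation_curve(
        rec.inactivation_sweeps, rec.inact_protocol, blanking_ms=blanking_ms
    )
    inact_fit = fit_boltzmann(v_pre, rel, orientation="falling")
    out = {
        "cell_id": rec.cell_id,
        "group": rec.group,
        "v_rev": v_rev,
        "v_half_act": act_fit.v_half,
        "k_act": act_fit.k,
        "amp_act": act_fit.amplitude,
        "act_converged": act_fit.converged,
        "v_half_inact": inact_fit.v_half,
        "k_inact": inact_fit.k,
        "amp_inact": inact_fit.amplitude,
        "inact_converged": inact_fit.converged,
    }
    if act_fit.converged and inact_fit.converged:
        grid = np.arange(-100.0, 10.0 + 1e-9, 0.1)
        win = window_current_curve(act_fit, inact_fit, grid)
        out["window_peak_v"] = win.peak_voltage_mv
        out["window_peak_fraction"] = win.peak_fraction
    else:
        out["window_peak_v"] = math.nan
        out["window_peak_fraction"] = math.nan
    out["_iv"] = iv
    return out


def _cell_kinetics(rec, iv: IVCurve, blanking_ms: float) -> list:
    """Decay tau and rise time per test step with measurable current."""
    rows = []
    seg_idx = len(rec.act_protocol.segments) - 1
    max_peak = np.max(np.abs(iv.peaks_pa))
    for sweep_id, sweep_df in rec.activation_sweeps.groupby("sweep_id"):
        v_step = rec.act_protocol.sweep_levels_mv[sweep_id]
        pos = int(np.flatnonzero(iv.voltages_mv == v_step)[0])
        if abs(iv.peaks_pa[pos]) < 0.05 * max_peak:
            continue  # too little current to fit kinetics
        t, i = _sweep_window(sweep_df, rec.act_protocol, seg_idx, blanking_ms)
        decay = fit_decay_tau(t, i)
        rows.append(
            {
                "cell_id": rec.cell_id,
                "group": rec.group,
                "step_mV": v_step,
                "decay_tau_ms": decay.tau_ms if decay.converged else math.nan,
                "rise_10_90_ms": rise_time_10_90(t, i),
            }
        )
    return rows


def run_pipeline(
    cohort,
    blanking_ms: float = DEFAULT_BLANKING_MS,
    reversal_range=DEFAULT_REVERSAL_RANGE,
    exclusion_margin_mv: float = DEFAULT_EXCLUSION_MARGIN_MV,
    kinetics: bool = True,
) -> PipelineResult:
    """Per-cell fits plus group tables for a two-group cohort.

    Cells whose activation or inactivation fit fails to converge are excluded
    from group statistics and logged.  Raises on an empty cohort.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("cohort is empty")
    records, kin_rows, excluded = [], [], []
    for rec in cohort:
        try:
            row = analyze_cell(
                rec,
                blanking_ms=blanking_ms,
                reversal_range=reversal_range,
                exclusion_margin_mv=exclusion_margin_mv,
            )
        except (ValueError, DegenerateFitError) as exc:
            logger.warning("cell %s excluded: %s", rec.cell_id, exc)
            excluded.append(rec.cell_id)
            continue
        iv = row.pop("_iv")
        if not (row["act_converged"] and row["inact_converged"]):
            logger.warning("cell %s excluded: non-converged Boltzmann fit", rec.cell_id)
            excluded.append(rec.cell_id)
            continue
        for v, p in zip(iv.voltages_mv, iv.peaks_pa):
            row[f"peak_{v:+.0f}mV"] = p
        records.append(row)
        if kinetics:
            kin_rows.append((rec, iv))
    if not records:
        raise ValueError("no cell produced converged fits")
    cells = pd.DataFrame(records)
    kin = pd.DataFrame(
        [r for rec, iv in kin_rows for r in _cell_kinetics(rec, iv, blanking_ms)]
        if kinetics
        else []
    )

    groups = cells["group"].unique()
    comparisons: dict = {}
    peak_rows = []
    if len(groups) == 2:
        ga = cells[cells["group"] == groups[0]]
        gb = cells[cells["group"] == groups[1]]
        for measure in _COMPARED_MEASURES:
            a = ga[measure].dropna().to_numpy()
            b = gb[measure].dropna().to_numpy()
            if len(a) >= 2 and len(b) >= 2:
                comparisons[measure] = compare_groups(a, b)
        for col in [c for c in cells.columns if c.startswith("peak_")]:
            a = ga[col].dropna().to_numpy()
            b = gb[col].dropna().to_numpy()
            if len(a) >= 2 and len(b) >= 2:
                cmp = compare_groups(a, b)
                peak_rows.append(
                    {
                        "step_mV": float(col[5:-2]),
                        f"mean_{groups[0]}": cmp.mean_a,
                        f"mean_{groups[1]}": cmp.mean_b,
                        "p_value": cmp.p_value,
                    }
                )
    return PipelineResult(
        cells=cells,
        kinetics=kin,
        comparisons=comparisons,
        peak_comparisons=pd.DataFrame(peak_rows).sort_values("step_mV").reset_index(drop=True)
        if peak_rows
        else pd.DataFrame(),
        excluded_cells=excluded,
    )
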