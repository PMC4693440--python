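"""Sweep analysis: peaks, reversal fit, Boltzmann fits, kinetics, statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cav3ephys.channel_model import (
    TauParams,
    steady_state_activation,
    steady_state_inactivation,
)
from cav3ephys.ephys_analysis import (
    DegenerateFitError,
    IVCurve,
    analyze_cell,
    compare_groups,
    estimate_reversal_potential,
    exact_mannwhitney_p,
    extract_peak_currents,
    fit_boltzmann,
    fit_decay_tau,
    relative_conductance,
    rise_time_10_90,
    run_pipeline,
    steady_state_inactivation_curve,
)
from cav3ephys.protocols import Segment, VoltageProtocol, activation_protocol
from cav3ephys.synthetic_data import generate_cohort, generate_recording


def _iv(voltages, peaks):
    v = np.asarray(voltages, dtype=float)
    return IVCurve(v, np.asarray(peaks, dtype=float), np.zeros_like(v), blanking_ms=2.0)


def _single_sweep_protocol(level=-30.0, step_ms=100.0, rate=1000.0):
    return VoltageProtocol(
        segments=(Segment(-100.0, 10.0), Segment(level, step_ms)),
        sweep_segment_index=1,
        sweep_levels_mv=(level,),
        sampling_rate_hz=rate,
    )


def _sweep_df(protocol, current):
    n0 = protocol.segment_sample_count(protocol.segments[0])
    n1 = protocol.segment_sample_count(protocol.segments[1])
    dt = 1000.0 / protocol.sampling_rate_hz
    t = np.arange(n0 + n1) * dt
    v = np.concatenate([np.full(n0, -100.0), np.full(n1, protocol.sweep_levels_mv[0])])
    return pd.DataFrame(
        {"sweep_id": 0, "time_ms": t, "voltage_mV": v, "current_pA": current}
    )


class TestPeakExtraction:
    def test_brute_force_transient(self):
        proto = _single_sweep_protocol()
        n0 = proto.segment_sample_count(proto.segments[0])
        n1 = proto.segment_sample_count(proto.segments[1])
        t_step = np.arange(n1) * 1.0  # 1 kHz -> 1 ms spacing
        trace = -250.0 * (t_step / 8.0) * np.exp(1 - t_step / 8.0)  # alpha, min -250 at 8 ms
        current = np.concatenate([np.zeros(n0), trace])
        iv = extract_peak_currents(_sweep_df(proto, current), proto, blanking_ms=2.0)
        # oracle: brute-force scan over the blanked step window
        window = trace[2:]
        assert iv.peaks_pa[0] == pytest.approx(window.min())
        assert iv.peaks_pa[0] == pytest.approx(-250.0, rel=1e-9)
        assert iv.latencies_ms[0] == pytest.approx(8.0)

    def test_flat_zero_trace(self):
        proto = _single_sweep_protocol()
        n = proto.samples_per_sweep()
        iv = extract_peak_currents(_sweep_df(proto, np.zeros(n)), proto)
        assert iv.peaks_pa[0] == 0.0

    def test_all_blanked_rejected(self):
        proto = _single_sweep_protocol(step_ms=5.0)
        n = proto.samples_per_sweep()
        with pytest.raises(ValueError):
            extract_peak_currents(_sweep_df(proto, np.zeros(n)), proto, blanking_ms=10.0)

    def test_mutant_smaller_low_threshold_peaks(self, ideal_wt_recording, ideal_mut_recording):
        ivw = extract_peak_currents(
            ideal_wt_recording.activation_sweeps, ideal_wt_recording.act_protocol
        )
        ivm = extract_peak_currents(
            ideal_mut_recording.activation_sweeps, ideal_mut_recording.act_protocol
        )
        for v in (-70.0, -60.0):
            w = ivw.peaks_pa[ivw.voltages_mv == v][0]
            m = ivm.peaks_pa[ivm.voltages_mv == v][0]
            assert abs(m) < abs(w)


class TestReversalPotential:
    def test_exact_line_zero_crossing(self):
        iv = _iv([-10, 0, 10, 20, 30], [-5, -4, -3, -2, -1])  # I = 0.1 V - 4
        assert estimate_reversal_potential(iv) == pytest.approx(40.0, abs=1e-9)

    def test_linear_iv_through_reversal(self):
        v = np.arange(-90.0, 31.0, 10.0)
        iv = _iv(v, 2.0 * (v - 45.0))
        assert estimate_reversal_potential(iv) == pytest.approx(45.0, abs=1e-6)

    def test_model_cell_reversal_recovered(self, ideal_wt_recording, wt_params):
        iv = extract_peak_currents(
            ideal_wt_recording.activation_sweeps, ideal_wt_recording.act_protocol
        )
        v_rev = estimate_reversal_potential(iv)
        assert v_rev == pytest.approx(wt_params.e_rev, abs=1.0)

    def test_too_few_points_rejected(self):
        iv = _iv([-60, -50], [-100, -200])
        with pytest.raises(DegenerateFitError):
            estimate_reversal_potential(iv)

    def test_flat_line_rejected(self):
        iv = _iv([-10, 0, 10, 20, 30], [-3, -3, -3, -3, -3])
        with pytest.raises(DegenerateFitError):
            estimate_reversal_potential(iv)


class TestRelativeConductance:
    def test_constant_conductance_input(self):
        v = np.arange(-90.0, 31.0, 10.0)
        iv = _iv(v, 3.0 * (v - 45.0))
        _, g = relative_conductance(iv, v_rev=45.0)
        assert np.allclose(g, 1.0)

    def test_idealized_cell_matches_gating_product(self, ideal_wt_recording, wt_params):
        p = wt_params
        iv = extract_peak_currents(
            ideal_wt_recording.activation_sweeps, ideal_wt_recording.act_protocol
        )
        v, g = relative_conductance(iv, v_rev=p.e_rev)
        expected = steady_state_activation(v, p) * float(steady_state_inactivation(-100.0, p))
        expected = expected / expected.max()
        assert np.allclose(g, expected, rtol=1e-6)

    def test_margin_exclusion(self):
        v = np.arange(-90.0, 36.0, 5.0)
        iv = _iv(v, 1.0 * (v - 40.0))
        kept_v, _ = relative_conductance(iv, v_rev=40.0, exclusion_margin_mv=10.0)
        assert 30.0 in kept_v
        assert 35.0 not in kept_v

    def test_all_excluded_rejected(self):
        iv = _iv([38.0, 40.0, 42.0], [-1.0, 0.0, 1.0])
        with pytest.raises(ValueError):
            relative_conductance(iv, v_rev=40.0, exclusion_margin_mv=10.0)


def _grid_search_boltzmann(v, y, orientation):
    """Independent coarse-to-fine grid oracle; amplitude solved analytically."""
    best = (np.inf, None, None)
    sign = 1.0 if orientation == "rising" else -1.0
    for v_half in np.arange(-100.0, 10.0, 0.25):
        for k in np.arange(0.5, 20.0, 0.25):
            basis = 1.0 / (1.0 + np.exp(sign * (v_half - v) / k))
            amp = float(basis @ y / (basis @ basis))
            rss = float(np.sum((amp * basis - y) ** 2))
            if rss < best[0]:
                best = (rss, v_half, k)
    return best


class TestBoltzmannFit:
    @pytest.mark.parametrize(
        "orientation,v_half,k",
        [("rising", -44.7, 6.2), ("rising", -57.5, 6.4), ("falling", -79.1, 6.3)],
    )
    def test_exact_recovery(self, orientation, v_half, k):
        v = np.arange(-90.0, 31.0, 10.0)
        sign = 1.0 if orientation == "rising" else -1.0
        y = 1.0 / (1.0 + np.exp(sign * (v_half - v) / k))
        fit = fit_boltzmann(v, y, orientation=orientation)
        assert fit.converged
        assert fit.v_half == pytest.approx(v_half, abs=1e-3)
        assert fit.k == pytest.approx(k, abs=1e-3)
        assert fit.amplitude == pytest.approx(1.0, abs=1e-6)

    def test_grid_oracle_confirms_global_minimum(self):
        v = np.arange(-90.0, 31.0, 10.0)
        y = 1.0 / (1.0 + np.exp((-44.7 - v) / 6.2))
        fit = fit_boltzmann(v, y, orientation="rising")
        _, v_half_g, k_g = _grid_search_boltzmann(v, y, "rising")
        assert fit.v_half == pytest.approx(v_half_g, abs=0.25)
        assert fit.k == pytest.approx(k_g, abs=0.25)

    def test_unidentifiable_flat_points(self):
        v = np.arange(-90.0, 31.0, 10.0)
        fit = fit_boltzmann(v, np.full_like(v, 0.5), orientation="rising")
        assert not fit.converged

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_boltzmann([0, 1, 2], [0.1, 0.5, 0.9])

    def test_invalid_orientation(self):
        with pytest.raises(ValueError):
            fit_boltzmann(np.arange(5.0), np.arange(5.0), orientation="sideways")


class TestInactivationCurve:
    def test_reference_normalization(self, ideal_wt_recording):
        v, rel = steady_state_inactivation_curve(
            ideal_wt_recording.inactivation_sweeps, ideal_wt_recording.inact_protocol
        )
        assert v[0] == -120.0
        assert rel[0] == pytest.approx(1.0)

    def test_half_availability_at_v_half(self, wt_params):
        # a prepulse exactly at V_half reads out half availability
        # (up to the h(-120) ~ 1 normalization reference)
        from cav3ephys.protocols import inactivation_protocol

        proto = inactivation_protocol(
            prepulse_levels_mv=[-120.0, wt_params.v_half_inact], sampling_rate_hz=2000.0
        )
        rec = generate_recording(wt_params, inact_protocol=proto, noise_sd=0.0,
                                 mode="idealized", rng_seed=0)
        v, rel = steady_state_inactivation_curve(rec.inactivation_sweeps, proto)
        h_ref = float(steady_state_inactivation(-120.0, wt_params))
        assert rel[v == wt_params.v_half_inact][0] == pytest.approx(0.5 / h_ref, abs=1e-6)

    def test_non_increasing(self, ideal_wt_recording):
        _, rel = steady_state_inactivation_curve(
            ideal_wt_recording.inactivation_sweeps, ideal_wt_recording.inact_protocol
        )
        assert np.all(np.diff(rel) <= 1e-12)


class TestKinetics:
    def test_pure_exponential_decay(self):
        t = np.arange(0.0, 120.0, 0.05)
        i = -300.0 * np.exp(-t / 20.0)
        fit = fit_decay_tau(t, i)
        assert fit.converged
        assert fit.tau_ms == pytest.approx(20.0, abs=0.01)

    def test_decay_with_offset(self):
        t = np.arange(0.0, 150.0, 0.05)
        i = -200.0 * np.exp(-t / 35.0) - 20.0
        fit = fit_decay_tau(t, i)
        assert fit.tau_ms == pytest.approx(35.0, abs=0.05)

    def test_constant_trace_flagged(self):
        t = np.arange(0.0, 50.0, 0.1)
        fit = fit_decay_tau(t, np.full_like(t, -80.0))
        assert not fit.converged
        assert np.isnan(fit.tau_ms)

    def test_kinetic_sweep_decay_matches_tau_h(self, wt_params):
        # with tau_m << tau_h the decay is governed by h relaxation
        p = wt_params.with_(
            tau_m_params=TauParams(floor_ms=0.05, amp_ms=0.0),
            tau_h_params=TauParams(floor_ms=30.0, amp_ms=0.0),
        )
        proto = activation_protocol(step_levels_mv=[-30.0], sampling_rate_hz=10_000.0)
        rec = generate_recording(p, proto, noise_sd=0.0, mode="kinetic", rng_seed=0)
        sweep = rec.activation_sweeps
        step = sweep[sweep["time_ms"] >= 322.0]
        fit = fit_decay_tau(step["time_ms"].to_numpy(), step["current_pA"].to_numpy())
        assert fit.tau_ms == pytest.approx(30.0, rel=0.05)

    def test_rise_time_closed_form(self):
        t = np.arange(0.0, 60.0, 0.01)
        for tau in (2.0, 4.0):
            i = -100.0 * (1.0 - np.exp(-t / tau))
            rise = rise_time_10_90(t, i)
            assert rise == pytest.approx(tau * np.log(9.0), rel=5e-3)
        # doubling tau doubles the rise time
        r2 = rise_time_10_90(t, -100.0 * (1.0 - np.exp(-t / 2.0)))
        r4 = rise_time_10_90(t, -100.0 * (1.0 - np.exp(-t / 4.0)))
        assert r4 / r2 == pytest.approx(2.0, rel=0.01)

    def test_step_function_trace(self):
        t = np.arange(0.0, 10.0, 0.1)
        i = np.where(t < 5.0, 0.0, -100.0)
        assert rise_time_10_90(t, i) == 0.0

    def test_no_onset_flagged(self):
        # baseline-subtracted amplitude never leaves zero: onset not captured
        t = np.arange(0.0, 10.0, 0.1)
        assert np.isnan(rise_time_10_90(t, np.full_like(t, -100.0)))


class TestMannWhitney:
    def test_separated_triples(self):
        cmp = compare_groups([1, 2, 3], [4, 5, 6])
        assert cmp.exact
        assert cmp.u_statistic == 0.0
        assert cmp.p_value == pytest.approx(0.1)

    def test_enumeration_oracle_separated_triples(self):
        u, p = exact_mannwhitney_p([1, 2, 3], [4, 5, 6])
        assert (u, p) == (0.0, pytest.approx(0.1))

    def test_group_against_itself(self):
        cmp = compare_groups([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert cmp.p_value == pytest.approx(1.0, abs=0.05)

    def test_identical_values_degenerate(self):
        cmp = compare_groups([2.0, 2.0, 2.0], [2.0, 2.0])
        assert cmp.degenerate and cmp.p_value == 1.0

    def test_exact_matches_enumeration_small_samples(self):
        # spot-check the scipy exact path against full enumeration
        rng = np.random.default_rng(0)
        for n_a, n_b in [(2, 3), (3, 3), (4, 4), (5, 4)]:
            for _ in range(5):
                pooled = rng.permutation(np.arange(1.0, n_a + n_b + 1.0))
                a, b = pooled[:n_a], pooled[n_a:]
                cmp = compare_groups(a, b)
                _, p_oracle = exact_mannwhitney_p(a, b)
                assert cmp.exact
                assert cmp.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])

    def test_reports_group_summaries(self):
        cmp = compare_groups([1.0, 2.0, 3.0], [4.0, 6.0])
        assert cmp.n_a == 3 and cmp.n_b == 2
        assert cmp.mean_a == pytest.approx(2.0)
        assert cmp.sd_a == pytest.approx(1.0)
        assert cmp.mean_b == pytest.approx(5.0)


class TestPipeline:
    def test_recovers_printed_group_means(self, ideal_wt_recording, ideal_mut_recording):
        wt = analyze_cell(ideal_wt_recording)
        mut = analyze_cell(ideal_mut_recording)
        assert wt["v_half_act"] == pytest.approx(-57.5, abs=0.5)
        assert mut["v_half_act"] == pytest.approx(-44.7, abs=0.5)
        assert wt["v_half_inact"] == pytest.approx(-79.1, abs=0.5)
        assert mut["v_half_inact"] == pytest.approx(-72.5, abs=0.5)

    def test_idealized_end_to_end_identity(self, fast_protocols):
        # given the true reversal potential, recovered (V_half, k) equal the
        # generating values to fit tolerance for arbitrary cells
        act, inact = fast_protocols
        cohort = generate_cohort(master_seed=3, mode="idealized", noise_sd=0.0,
                                 act_protocol=act, inact_protocol=inact)
        for rec in cohort:
            row = analyze_cell(rec, v_rev=rec.truth.e_rev)
            assert row["v_half_act"] == pytest.approx(rec.truth.v_half_act, abs=0.5)
            assert row["k_act"] == pytest.approx(rec.truth.k_act, abs=0.5)
            assert row["v_half_inact"] == pytest.approx(rec.truth.v_half_inact, abs=0.5)
            assert row["k_inact"] == pytest.approx(rec.truth.k_inact, abs=0.5)

    def test_reversal_estimation_bias_bounded(self, fast_protocols):
        # with the reversal potential estimated from the I-V line fit, cells
        # with shallow, depolarized activation pick up a bounded bias
        act, inact = fast_protocols
        cohort = generate_cohort(master_seed=3, mode="idealized", noise_sd=0.0,
                                 act_protocol=act, inact_protocol=inact)
        result = run_pipeline(cohort, kinetics=False)
        truth = {rec.cell_id: rec.truth for rec in cohort}
        for _, row in result.cells.iterrows():
            p = truth[row["cell_id"]]
            assert row["v_half_act"] == pytest.approx(p.v_half_act, abs=3.0)
            assert row["v_half_inact"] == pytest.approx(p.v_half_inact, abs=0.5)

    def test_kinetic_mode_bias_bounded_and_monotone(self, wt_params):
        # kinetic distortion shifts recovered activation V_half by < 3 mV,
        # decreasing as activation kinetics get faster
        biases = []
        for tau_m_floor in (1.0, 0.3, 0.05):
            p = wt_params.with_(tau_m_params=TauParams(floor_ms=tau_m_floor, amp_ms=0.0))
            rec = generate_recording(p, noise_sd=0.0, mode="kinetic", rng_seed=0)
            row = analyze_cell(rec)
            biases.append(abs(row["v_half_act"] - wt_params.v_half_act))
        assert all(b < 3.0 for b in biases)
        assert biases[0] > biases[1] > biases[2]

    def test_group_tables(self, fast_protocols):
        act, inact = fast_protocols
        cohort = generate_cohort(master_seed=1, mode="idealized", noise_sd=0.0,
                                 act_protocol=act, inact_protocol=inact)
        result = run_pipeline(cohort, kinetics=False)
        assert set(result.cells["group"]) == {"WT", "mutant"}
        assert "v_half_act" in result.comparisons
        cmp = result.comparisons["v_half_act"]
        assert cmp.n_a + cmp.n_b == 21
        assert len(result.peak_comparisons) > 0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            run_pipeline([])
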