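"""Trace measurements: I-V curves, Boltzmann fits, subtraction pharmacology,
M-current amplitude, slow-EPSP metrics, rheobase/F-I, classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import kndysim as ks
from kndysim.analysis import (
    AnalysisError,
    FitQualityWarning,
    IVCurve,
    burst_groups,
    conductance_curve,
    lowpass,
)
from kndysim.calibration import drug_sensitive_iv
from kndysim.protocols import apply_drug
from kndysim.synth import SpikeTrainSpec, generate_spike_train


def boltz(v, vh, k):
    return 1.0 / (1.0 + np.exp((vh - v) / k))


# -------------------------------------------------------------------- peak_iv

class TestPeakIV:
    def test_zero_traces_give_zero_curve(self, leak_only):
        p = leak_only.copy()
        p.channels["leak"].gbar = 0.0
        fam = ks.k_iv_protocol()
        iv = ks.peak_iv(ks.simulate_family(p, fam), mode="peak")
        np.testing.assert_allclose(iv.current, 0.0, atol=1e-6)

    def test_known_waveform_extremum(self, leak_only):
        # a pure leak cell's baseline-subtracted step current is analytic:
        # g * (Vstep - Vhold), constant over the step
        p = leak_only.copy()
        g = p.channels["leak"].gbar
        fam = ks.k_iv_protocol()
        iv = ks.peak_iv(ks.simulate_family(p, fam), mode="peak")
        expected = g * (np.asarray(fam.steps) - fam.hold)
        np.testing.assert_allclose(iv.current, expected, rtol=1e-6, atol=1e-6)
        ivs = ks.peak_iv(ks.simulate_family(p, fam), mode="steady")
        np.testing.assert_allclose(ivs.current, expected, rtol=1e-6, atol=1e-6)

    def test_density_is_current_over_cm(self, ovx):
        fam = ks.k_iv_protocol()
        iv = ks.peak_iv(ks.simulate_family(ovx, fam), mode="steady")
        np.testing.assert_allclose(iv.density, iv.current / ovx.Cm)

    def test_calibrated_ovx_ca_peak_at_minus10(self, ovx):
        # Cd-sensitive peak current of the OVX model is extremal at -10 mV
        fam = ks.ca_iv_protocol()
        ctx = apply_drug(apply_drug(ovx, "ttx"), "cs_internal")
        ctrl = ks.simulate_family(ctx, fam)
        treat = ks.simulate_family(apply_drug(ctx, "cadmium"), fam)
        diff = [ks.drug_subtraction(a, b) for a, b in zip(ctrl, treat)]
        iv = ks.peak_iv(diff, mode="peak")
        assert iv.peak_potential == -10.0
        assert iv.at(-10.0) < 0  # inward


# -------------------------------------------------------------- Boltzmann fits

class TestBoltzmannFit:
    def test_exact_samples_recovered_to_machine_precision(self):
        v = np.arange(-80.0, 1.0, 5.0)
        y = boltz(v, -40.0, 6.0)
        fit = ks.fit_boltzmann(v, y, kind="activation")
        assert fit.V_half == pytest.approx(-40.0, abs=1e-8)
        assert fit.k == pytest.approx(6.0, abs=1e-8)
        assert fit.Imax == pytest.approx(1.0, abs=1e-8)

    def test_inactivation_and_one_minus_conventions_agree(self):
        v = np.arange(-100.0, -19.0, 5.0)
        avail = 1.0 - boltz(v, -48.9, 6.0)   # falling availability curve
        a = ks.fit_boltzmann(v, avail, kind="inactivation")
        b = ks.fit_boltzmann(v, 1.0 - avail, kind="inactivation",
                             convention="one_minus")
        assert a.V_half == pytest.approx(-48.9, abs=1e-6)
        assert b.V_half == pytest.approx(a.V_half, abs=1e-6)
        assert a.k == pytest.approx(b.k, abs=1e-6)

    def test_noisy_recovery_within_1mV(self):
        # 100 replicates, sigma = 0.03: mean recovered V1/2 within 1 mV
        rng = np.random.default_rng(7)
        v = np.arange(-80.0, 1.0, 5.0)
        clean = boltz(v, -40.0, 6.0)
        est = [ks.fit_boltzmann(v, clean + rng.normal(0, 0.03, v.size)).V_half
               for _ in range(100)]
        assert abs(np.mean(est) + 40.0) < 1.0

    def test_scale_invariance(self):
        v = np.arange(-80.0, 1.0, 5.0)
        y = boltz(v, -35.0, 8.0)
        a = ks.fit_boltzmann(v, y)
        b = ks.fit_boltzmann(v, 123.0 * y)
        assert b.V_half == pytest.approx(a.V_half, abs=1e-6)
        assert b.k == pytest.approx(a.k, abs=1e-6)
        assert b.Imax == pytest.approx(123.0 * a.Imax, rel=1e-6)

    def test_model_ca_activation_near_printed_midpoint(self, ovx):
        # activation curve of the HVA Ca current, conductance-transformed
        fam = ks.ca_iv_protocol()
        ctx = apply_drug(apply_drug(ovx, "ttx"), "cs_internal")
        blocked = ctx.copy()
        blocked.channels["Ca"].block_fraction = 1.0
        diff = [ks.drug_subtraction(a, b) for a, b in
                zip(ks.simulate_family(ctx, fam),
                    ks.simulate_family(blocked, fam))]
        iv = ks.peak_iv(diff, mode="peak")
        v, g = conductance_curve(iv, erev=60.0)
        keep = v >= -70.0
        fit = ks.fit_boltzmann(v[keep], g[keep], kind="activation")
        assert fit.V_half == pytest.approx(-32.3, abs=5.0)

    def test_wrong_trend_warns(self):
        v = np.arange(-80.0, 1.0, 10.0)
        y = 1.0 - boltz(v, -40.0, 6.0)
        with pytest.warns(FitQualityWarning):
            ks.fit_boltzmann(v, y, kind="activation")

    def test_too_few_points_rejected(self):
        with pytest.raises(AnalysisError):
            ks.fit_boltzmann([-60, -40, -20], [0.1, 0.5, 0.9])


# -------------------------------------------------------------- drug subtraction

class TestDrugSubtraction:
    def test_self_subtraction_is_zero(self, ovx):
        fam = ks.k_iv_protocol()
        tr = ks.simulate_family(ovx, fam)[3]
        d = ks.drug_subtraction(tr, tr)
        np.testing.assert_allclose(d.net_ionic, 0.0, atol=1e-12)

    def test_equals_stored_decomposition(self, ovx_e2):
        # apamin-sensitive trace == the model's own SK current exactly
        fam = ks.k_iv_protocol()
        ctrl = ks.simulate_family(ovx_e2, fam)[-1]
        blocked = ks.simulate_family(apply_drug(ovx_e2, "apamin"), fam)[-1]
        d = ks.drug_subtraction(ctrl, blocked)
        np.testing.assert_allclose(d.net_ionic, ctrl.current("SK"),
                                   rtol=1e-5, atol=1e-5)

    def test_protocol_mismatch_rejected(self, ovx):
        fam = ks.k_iv_protocol()
        trs = ks.simulate_family(ovx, fam)
        with pytest.raises(AnalysisError):
            ks.drug_subtraction(trs[0], trs[1])

    def test_iv_curve_subtraction(self):
        v = np.arange(-60.0, 41.0, 10.0)
        a = IVCurve(v, np.linspace(0, 100, v.size), 25.0, "steady")
        b = IVCurve(v, np.linspace(0, 60, v.size), 25.0, "steady")
        d = ks.drug_subtraction(a, b)
        np.testing.assert_allclose(d.current, a.current - b.current)


# ---------------------------------------------------------- M-current amplitude

class TestMCurrentAmplitude:
    def test_constant_trace_gives_zero(self, leak_only):
        fam = ks.m_current_protocol()
        tr = ks.simulate_family(leak_only, fam)[0]
        # leak settles within a fraction of a ms: relaxation amplitude ~ 0
        assert ks.m_current_amplitude(tr) == pytest.approx(0.0, abs=1e-3)

    def test_monoexponential_analytic_value(self, ovx):
        # build a synthetic relaxing current A*exp(-t/tau) on a real sweep's
        # time base and compare with the closed-form window means
        fam = ks.m_current_protocol()
        tr = ks.simulate_family(ovx, fam)[0]
        t0, _ = dict(tr.protocol.meta)["step_t0"], None
        A, tau = 40.0, 100.0
        trel = tr.t - t0
        synthetic = np.where(trel >= 0, A * np.exp(-np.clip(trel, 0, None) / tau), 0.0)
        fake = tr.__class__(**{**tr.__dict__,
                               "currents": np.zeros_like(tr.currents)})
        fake.currents[:, 0] = synthetic
        got = ks.m_current_amplitude(fake)

        def window_mean(a, b):
            return (tau * A / (b - a)) * (np.exp(-a / tau) - np.exp(-b / tau))
        dt = tr.dt
        expected = window_mean(dt, 10.0 + dt / 2) - window_mean(475.0, 500.0)
        assert got == pytest.approx(expected, rel=0.02)

    def test_e2_over_ovx_ratio_is_four(self, ovx, ovx_e2):
        fam = ks.m_current_protocol()

        def xe_amp(p):
            base = apply_drug(p, "ttx")
            ctrl = ks.simulate_family(base, fam)[0]          # -30 mV step
            blocked = ks.simulate_family(apply_drug(base, "xe991"), fam)[0]
            return ks.m_current_amplitude(ks.drug_subtraction(ctrl, blocked))
        ratio = xe_amp(ovx_e2) / xe_amp(ovx)
        assert ratio == pytest.approx(4.0, rel=0.01)

    def test_short_step_rejected(self, ovx):
        fam = ks.StepFamilyProtocol(mode="vc", hold=-70.0, steps=(-30.0,),
                                    step_duration=200.0)
        tr = ks.simulate_family(ovx, fam)[0]
        with pytest.raises(AnalysisError):
            ks.m_current_amplitude(tr)


# -------------------------------------------------------------------- slow EPSP

class TestSlowEpsp:
    def test_flat_trace_r1_zero_ratio_undefined(self, ovx):
        silent = ovx.copy()
        silent.channels["TRPC5"].gbar = 0.0
        prot = ks.slow_epsp_pair_protocol(gap_s=20.0, observe_s=15.0,
                                          dyn_co_release=False)
        tr = ks.simulate(silent, prot)
        m = ks.slow_epsp_metrics(tr)
        assert abs(m.R1) < 0.5
        assert m.ratio is None

    def test_two_identical_epochs_ratio_one(self, ovx):
        prot = ks.slow_epsp_pair_protocol(gap_s=90.0, observe_s=30.0)
        tr = ks.simulate(ovx, prot)
        m = ks.slow_epsp_metrics(tr)
        assert m.R1 > 2.0
        assert m.ratio == pytest.approx(1.0, abs=0.1)

    def test_ca_block_reduces_nkb_evoked_trpc5_current(self, ovx):
        # voltage-gated Ca influx potentiates TRPC5: blocking it with Cd
        # shrinks the NKB-evoked TRPC5 current under voltage clamp
        from kndysim.protocols import DriveCommand, Segment, StimulusProtocol

        prot = StimulusProtocol((
            Segment(5000.0, "vc", -60.0),
            Segment(60000.0, "vc", -60.0, nkb=DriveCommand(level=1.0)),
        ))
        base = apply_drug(ovx, "ttx")

        def trpc5_at_steady(p):
            tr = ks.simulate(p, prot)
            return tr.current("TRPC5")[tr.window(60000, 65000)].mean()
        ctrl = trpc5_at_steady(base)
        cd = trpc5_at_steady(apply_drug(base, "cadmium"))
        assert ctrl < 0 and cd < 0            # inward
        assert abs(cd) < abs(ctrl)            # potentiation removed

    def test_trpc5_knockdown_attenuates_epsp(self, ovx):
        prot = ks.nkb_synchronization_protocol(observe_s=40.0)
        kd = ovx.copy()
        kd.channels["TRPC5"].gbar = 0.2 * ovx.channels["TRPC5"].gbar
        a_ctrl = ks.slow_epsp_metrics(ks.simulate(ovx, prot)).R1
        a_kd = ks.slow_epsp_metrics(ks.simulate(kd, prot)).R1
        assert a_kd < a_ctrl


# ---------------------------------------------------------------- rheobase / F-I

class TestRheobaseFI:
    def test_subthreshold_ramp_not_reached(self, ovx):
        tr = ks.simulate(ovx, ks.ramp_protocol(50.0, 2.0))
        assert np.isnan(ks.rheobase_from_ramp(tr))

    def test_trpc5_halving_raises_rheobase(self, ovx):
        ramp = ks.ramp_protocol(50.0, 60.0)
        half = ovx.copy()
        half.channels["TRPC5"].gbar = 0.5 * ovx.channels["TRPC5"].gbar
        r0 = ks.rheobase_from_ramp(ks.simulate(ovx, ramp))
        r1 = ks.rheobase_from_ramp(ks.simulate(half, ramp))
        assert np.isfinite(r0) and np.isfinite(r1)
        assert r1 > r0

    def test_fi_curve_attenuated_by_trpc5_halving(self, ovx):
        fam = ks.current_steps_protocol(np.arange(10.0, 71.0, 10.0), 1000.0)
        half = ovx.copy()
        half.channels["TRPC5"].gbar = 0.5 * ovx.channels["TRPC5"].gbar
        f0 = ks.fi_curve(ks.simulate_family(ovx, fam))
        f1 = ks.fi_curve(ks.simulate_family(half, fam))
        assert np.all(f1.rate_hz <= f0.rate_hz)
        assert f0.rate_hz.max() > 0


# ------------------------------------------------------------- classification

class TestClassifyFiring:
    def test_silent(self):
        tr = generate_spike_train(SpikeTrainSpec("silent"), 15.0, seed=0)
        assert ks.classify_firing(tr).label == "silent"

    def test_tonic_low_cv(self):
        tr = generate_spike_train(SpikeTrainSpec("tonic", rate_hz=5, cv=0.1),
                                  20.0, seed=1)
        assert ks.classify_firing(tr).label == "tonic"

    def test_irregular_high_cv(self):
        tr = generate_spike_train(
            SpikeTrainSpec("irregular", rate_hz=5, cv=1.0), 20.0, seed=2)
        assert ks.classify_firing(tr).label == "irregular"

    def test_burst_with_up_down_states_is_phasic(self):
        tr = generate_spike_train(SpikeTrainSpec("burst", updown=True),
                                  20.0, seed=3)
        c = ks.classify_firing(tr)
        assert c.label == "phasic_burst"
        assert c.features["updown_state"]

    def test_burst_without_up_down_states_is_irregular_burst(self):
        tr = generate_spike_train(SpikeTrainSpec("burst", updown=False),
                                  20.0, seed=4)
        assert ks.classify_firing(tr).label == "irregular_burst"

    def test_e2_preset_fires_phasic_bursts(self, e2_spontaneous):
        c = ks.classify_firing(e2_spontaneous)
        assert c.label == "phasic_burst"
        assert c.features["burst_count"] >= 2

    def test_time_origin_invariance(self):
        tr = generate_spike_train(SpikeTrainSpec("burst"), 20.0, seed=5)
        shifted = tr.__class__(**{**tr.__dict__, "t": tr.t + 12345.0})
        assert ks.classify_firing(shifted).label == ks.classify_firing(tr).label

    def test_resampling_invariance_above_2khz(self):
        tr = generate_spike_train(SpikeTrainSpec("tonic", rate_hz=6, cv=0.2),
                                  20.0, seed=6, dt_ms=0.25)
        dec = tr.__class__(**{**tr.__dict__, "t": tr.t[::2],
                              "states": tr.states[::2],
                              "currents": tr.currents[::2],
                              "segment_index": tr.segment_index[::2],
                              "injected": tr.injected[::2],
                              "is_vc": tr.is_vc[::2]})
        assert ks.classify_firing(dec).label == ks.classify_firing(tr).label

    def test_short_trace_rejected(self):
        tr = generate_spike_train(SpikeTrainSpec("tonic"), 5.0, seed=7)
        with pytest.raises(AnalysisError):
            ks.classify_firing(tr)

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_burst_grouping_spikes_conserved(self, seed):
        rng = np.random.default_rng(seed)
        st_times = np.sort(rng.uniform(0, 20_000, size=rng.integers(2, 60)))
        cfg = ks.FiringConfig()
        groups = burst_groups(st_times, cfg)
        counted = sum(g.size for g in groups)
        assert counted <= st_times.size
        for g in groups:
            assert np.all(np.diff(g) <= cfg.intra_burst_isi_ms)


# ------------------------------------------------------------------ regime map

class TestRegimeMap:
    def test_degenerate_grid_matches_direct_classification(self, ovx_e2):
        prot = ks.spontaneous_protocol(15.0)
        g5 = ovx_e2.channels["TRPC5"].gbar
        gg = ovx_e2.channels["GIRK"].gbar
        rm = ks.regime_map(ovx_e2, ("TRPC5", [g5]), ("GIRK", [gg]), prot)
        direct = ks.classify_firing(ks.simulate(ovx_e2, prot)).label
        assert rm.label_at(0, 0) == direct

    def test_low_trpc5_high_girk_corner_is_silent(self, ovx):
        prot = ks.saturating_drive_protocol(20.0)
        rm = ks.regime_map(ovx, ("TRPC5", [0.3, 2.4]), ("GIRK", [3.0]), prot)
        assert rm.label_at(0, 0) == "silent"       # low TRPC5, high GIRK
        df = rm.to_frame()
        assert set(df.columns) == {"TRPC5", "GIRK", "label"}
        assert len(df) == 2

    def test_firing_boundary_crossed_once_along_trpc5(self, ovx):
        prot = ks.saturating_drive_protocol(15.0)
        vals = np.linspace(0.3, 3.0, 6)
        rm = ks.regime_map(ovx, ("TRPC5", vals), ("GIRK", [1.0]), prot)
        firing = [rm.label_at(i, 0) != "silent" for i in range(len(vals))]
        # once firing starts with increasing TRPC5 it stays on
        flips = sum(a != b for a, b in zip(firing, firing[1:]))
        assert flips <= 1


class TestRegimeBoundary:
    def test_boundary_reports_trpc5_onset(self, ovx):
        prot = ks.saturating_drive_protocol(15.0)
        rm = ks.regime_map(ovx, ("TRPC5", [0.3, 2.8]), ("GIRK", [1.0]), prot)
        b = rm.boundary()
        assert b.loc[0, "TRPC5_onset"] == pytest.approx(2.8)
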