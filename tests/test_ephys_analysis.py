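"""Analysis chain: membrane test, QC, averaging/subtraction, charge, decay,
spontaneous IPSCs, phase planes and waveform classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glomquant.ephys_analysis import (
    aei_charge,
    aei_charge_per_pulse,
    average_sweeps,
    classify_waveform,
    detect_spontaneous_ipscs,
    fit_decay,
    membrane_test,
    phase_plane,
    qc_series_resistance,
    subtract_conditions,
)
from glomquant.errors import (
    EmptyInputError,
    FitFailureError,
    UnclassifiableWaveformError,
    ValidationError,
)
from glomquant.synth_ephys import (
    Pharmacology,
    SweepSet,
    aei_protocol,
    membrane_test_protocol,
    quiet_archetype,
    simulate_aei,
    simulate_membrane_test,
    simulate_spike,
    sipsc_kernel,
)


class TestMembraneTest:
    def test_noise_free_recovery(self):
        arch = quiet_archetype("anaxonic", R_s_true=10.0, R_m_true=490.0, C_m_true=40.0)
        r = membrane_test(simulate_membrane_test(arch, seed=0))
        assert r.R_S == pytest.approx(10.0, rel=0.02)
        assert r.R_I == pytest.approx(500.0, rel=0.02)
        assert r.C_M == pytest.approx(40.0, rel=0.02)

    def test_noisy_recovery_median(self):
        from glomquant.synth_ephys import default_archetype

        arch = default_archetype("anaxonic", R_s_true=10.0, R_m_true=490.0, C_m_true=40.0, noise_sd=5.0)
        errs = []
        for s in range(100):
            r = membrane_test(simulate_membrane_test(arch, seed=s))
            errs.append(max(abs(r.R_S - 10) / 10, abs(r.R_I - 500) / 500, abs(r.C_M - 40) / 40))
        assert np.median(errs) <= 0.10

    def test_linearity_in_step_size(self):
        arch = quiet_archetype("anaxonic", R_s_true=12.0, R_m_true=600.0, C_m_true=45.0)
        r1 = membrane_test(simulate_membrane_test(arch, membrane_test_protocol(step_mV=10.0), seed=0))
        r2 = membrane_test(simulate_membrane_test(arch, membrane_test_protocol(step_mV=20.0), seed=0))
        assert r1.R_S == pytest.approx(r2.R_S, rel=1e-3)
        assert r1.R_I == pytest.approx(r2.R_I, rel=1e-3)
        assert r1.C_M == pytest.approx(r2.C_M, rel=1e-3)

    def test_invariant_to_holding_current(self):
        a1 = quiet_archetype("anaxonic", holding_pA=-20.0)
        a2 = quiet_archetype("anaxonic", holding_pA=-400.0)
        r1 = membrane_test(simulate_membrane_test(a1, seed=0))
        r2 = membrane_test(simulate_membrane_test(a2, seed=0))
        assert r1.R_S == pytest.approx(r2.R_S, rel=1e-6)
        assert r1.C_M == pytest.approx(r2.C_M, rel=1e-6)

    def test_wrong_protocol_kind_rejected(self):
        arch = quiet_archetype("anaxonic")
        sw = simulate_aei(arch, seed=0)
        with pytest.raises(ValidationError):
            membrane_test(sw)


class TestQC:
    @pytest.mark.parametrize(
        "history,passed,reason_part",
        [
            ([15, 18, 19], True, "ok"),
            ([15, 31], False, "exceeded"),
            ([20, 27], False, "changed"),
            ([29.9, 29.9], True, "ok"),
        ],
    )
    def test_rules(self, history, passed, reason_part):
        res = qc_series_resistance(history)
        assert res.passed is passed
        assert reason_part in res.reason

    def test_empty_history_raises(self):
        with pytest.raises(EmptyInputError):
            qc_series_resistance([])


class TestAverageAndSubtract:
    def test_identical_sweeps_average_to_self(self):
        x = np.arange(10.0)
        assert np.array_equal(average_sweeps([x, x, x]), x)

    def test_opposite_sweeps_cancel(self):
        x = np.ones(8)
        assert np.all(average_sweeps([x, -x]) == 0)

    def test_mean_matches_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        sweeps = rng.normal(size=(3, 50))
        avg = average_sweeps(list(sweeps))
        for j in range(50):
            assert avg[j] == pytest.approx(sum(sweeps[i, j] for i in range(3)) / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            average_sweeps([np.zeros(5), np.zeros(6)])

    def test_pre_equals_post_gives_zero(self):
        arch = quiet_archetype("anaxonic")
        sw = simulate_aei(arch, seed=1)
        diff = subtract_conditions(sw, sw)
        assert np.allclose(diff, 0.0)

    def test_constant_offset_removed(self):
        arch = quiet_archetype("anaxonic")
        sw = simulate_aei(arch, seed=1)
        shifted = SweepSet(
            sweeps=sw.sweeps + 37.0,
            sample_interval_us=sw.sample_interval_us,
            units="pA",
            protocol=sw.protocol,
        )
        diff = subtract_conditions(shifted, sw)
        assert np.allclose(diff, 0.0, atol=1e-9)

    def test_difference_is_generated_gaba_component(self):
        arch = quiet_archetype("anaxonic")
        proto = aei_protocol()
        pre = simulate_aei(arch, proto, Pharmacology(), seed=4)
        post = simulate_aei(arch, proto, Pharmacology(gabazine=True), seed=4)
        diff = subtract_conditions(pre, post)
        np.testing.assert_allclose(diff, pre.meta["components"]["gaba"], atol=1e-8)


class TestCharge:
    def test_zero_trace(self):
        proto = aei_protocol()
        assert aei_charge(np.zeros(proto.n_samples), proto) == 0.0

    def test_constant_inward_current_forced_arithmetic(self):
        """-10 pA across the full 500 ms window integrates to 5 pC."""
        proto = aei_protocol()
        trace = np.full(proto.n_samples, -10.0)
        assert aei_charge(trace, proto) == pytest.approx(5.0, rel=1e-6)

    def test_end_to_end_recovery(self):
        arch = quiet_archetype("anaxonic")  # 44.11 pC truth
        proto = aei_protocol()
        pre = simulate_aei(arch, proto, Pharmacology(), seed=2)
        post = simulate_aei(arch, proto, Pharmacology(gabazine=True), seed=2)
        q = aei_charge(subtract_conditions(pre, post), proto)
        assert q == pytest.approx(44.11, rel=0.05)

    def test_window_exceeding_trace_rejected(self):
        proto = aei_protocol()
        with pytest.raises(ValidationError):
            aei_charge(np.zeros(100), proto)

    def test_paired_window_anchors_to_second_pulse(self):
        arch = quiet_archetype("anaxonic")
        proto = aei_protocol("aei_paired")
        pre = simulate_aei(arch, proto, Pharmacology(), seed=3)
        post = simulate_aei(arch, proto, Pharmacology(gabazine=True), seed=3)
        diff = subtract_conditions(pre, post)
        q = aei_charge(diff, proto)
        per_pulse = aei_charge_per_pulse(diff, proto)
        assert len(per_pulse) == 2
        # second-pulse window also contains the first pulse's decaying release
        assert q > 44.11
        assert per_pulse[0] < q

    @settings(deadline=None, max_examples=20)
    @given(a=st.floats(min_value=0.01, max_value=50.0))
    def test_linearity_in_amplitude(self, a):
        proto = aei_protocol()
        rng = np.random.default_rng(0)
        trace = rng.normal(-5.0, 2.0, size=proto.n_samples)
        assert aei_charge(a * trace, proto) == pytest.approx(a * aei_charge(trace, proto), rel=1e-9)


class TestDecay:
    def test_pure_exponential_recovery(self):
        arch = quiet_archetype("anaxonic")  # k = 0.03 / ms
        proto = aei_protocol()
        pre = simulate_aei(arch, proto, Pharmacology(), seed=0)
        post = simulate_aei(arch, proto, Pharmacology(gabazine=True), seed=0)
        fit = fit_decay(subtract_conditions(pre, post), proto)
        assert fit.k == pytest.approx(0.03, rel=0.01)
        assert fit.converged

    def test_constant_trace_fit_failure(self):
        proto = aei_protocol()
        with pytest.raises(FitFailureError):
            fit_decay(np.full(proto.n_samples, -3.0), proto)

    def test_noisy_recovery_median(self):
        from glomquant.synth_ephys import default_archetype

        proto = aei_protocol()
        arch = default_archetype("anaxonic", noise_sd=2.0, sipsc_rate=0.0)
        errs = []
        for s in range(100):
            pre = simulate_aei(arch, proto, Pharmacology(), seed=s)
            post = simulate_aei(arch, proto, Pharmacology(gabazine=True), seed=1000 + s)
            errs.append(abs(fit_decay(subtract_conditions(pre, post), proto).k - 0.03) / 0.03)
        assert np.median(errs) <= 0.10


class TestSpontaneousIPSCs:
    def test_flat_trace_no_events(self):
        ev = detect_spontaneous_ipscs(np.zeros(50_000), 20.0)
        assert ev.n == 0

    def test_injected_events_recovered(self):
        dt_us = 20.0
        t = np.arange(0, 2000.0, dt_us / 1000.0)
        trace = np.zeros_like(t)
        times = [150.0, 400.0, 800.0, 1300.0, 1800.0]
        for t0 in times:
            trace += sipsc_kernel(t - t0, 40.0)
        ev = detect_spontaneous_ipscs(trace, dt_us, threshold_pA=15.0)
        assert ev.n == 5
        for t0 in times:
            assert np.min(np.abs(ev.times_ms - t0)) <= 1.0

    def test_gabazine_suppresses_events(self):
        from glomquant.synth_ephys import simulate_sipsc_recording

        arch = quiet_archetype("anaxonic", sipsc_rate=5.0, noise_sd=3.0)
        pre = simulate_sipsc_recording(arch, duration_ms=10_000.0, seed=0)
        post = simulate_sipsc_recording(
            arch, duration_ms=10_000.0, pharm=Pharmacology(gabazine=True), seed=0
        )
        n_pre = detect_spontaneous_ipscs(pre.sweeps[0], 20.0).n
        n_post = detect_spontaneous_ipscs(post.sweeps[0], 20.0).n
        assert n_pre >= 20
        assert n_post <= 0.1 * n_pre


class TestPhasePlane:
    def test_linear_ramp_constant_derivative(self):
        t = np.arange(4000) * 0.005
        pp = phase_plane(t * 1.0, 5.0)  # 1 mV/ms
        np.testing.assert_allclose(pp.dVdt[50:-50], 1.0, atol=1e-9)

    def test_constant_trace_zero_derivative(self):
        pp = phase_plane(np.full(1000, -60.0), 5.0)
        assert np.all(pp.dVdt == 0)

    def test_sinusoid_attenuation_matches_closed_form(self):
        """Boxcar Dirichlet factor x central-difference sinc factor, to 1%."""
        dt_ms, f = 0.005, 1.0  # 1 kHz test tone at 200 kHz sampling
        w = 2 * np.pi * f
        t = np.arange(8000) * dt_ms
        pp = phase_plane(3.0 * np.sin(w * t), 5.0)
        meas = np.max(np.abs(pp.dVdt[200:-200]))
        L = 20
        diric = abs(np.sin(L * w * dt_ms / 2) / (L * np.sin(w * dt_ms / 2)))
        sinc = np.sin(w * dt_ms) / (w * dt_ms)
        assert meas == pytest.approx(3.0 * w * diric * sinc, rel=0.01)

    def test_short_trace_rejected(self):
        with pytest.raises(ValidationError):
            phase_plane(np.zeros(10), 5.0)


class TestClassifier:
    def test_generator_labels_noise_free(self):
        for sub, want in (("anaxonic", "monophasic"), ("axon_bearing", "biphasic")):
            sw = simulate_spike(quiet_archetype(sub), seed=0)
            lab = classify_waveform(phase_plane(sw.sweeps[0], sw.sample_interval_us))
            assert lab.label == want

    def test_noisy_agreement(self):
        ok = 0
        for i in range(200):
            sub = "anaxonic" if i % 2 == 0 else "axon_bearing"
            sw = simulate_spike(quiet_archetype(sub), seed=500 + i, noise_mV=0.3)
            lab = classify_waveform(phase_plane(sw.sweeps[0], 5.0))
            ok += lab.label == ("monophasic" if sub == "anaxonic" else "biphasic")
        assert ok / 200 >= 0.90

    def test_invariant_to_voltage_offset(self):
        sw = simulate_spike(quiet_archetype("axon_bearing"), seed=0)
        a = classify_waveform(phase_plane(sw.sweeps[0], 5.0))
        b = classify_waveform(phase_plane(sw.sweeps[0] + 25.0, 5.0))
        assert a.label == b.label

    def test_invariant_to_uniform_time_rescaling(self):
        sw = simulate_spike(quiet_archetype("axon_bearing"), seed=0)
        a = classify_waveform(phase_plane(sw.sweeps[0], 5.0))
        b = classify_waveform(phase_plane(sw.sweeps[0], 10.0))  # same samples, slower clock
        assert a.label == b.label

    def test_subthreshold_trace_unclassifiable(self):
        with pytest.raises(UnclassifiableWaveformError):
            classify_waveform(phase_plane(np.full(2000, -60.0), 5.0))
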