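import math

import numpy as np
import pytest

from escrt_kinetics import (
    IntensityTrace,
    add_noise,
    analyze_trace,
    boltzmann_curve,
    compute_rates,
    default_config,
    fit_boltzmann_segment,
    retention_time,
    segment_phases,
    simulate_cohort,
    simulate_trace,
    total_assembly_time,
)
from escrt_kinetics.kinetics import SegmentFit
from escrt_kinetics.synthetic_data import LN81

from conftest import make_event


def trace_of(values, dt=0.2, site_id=0, channel="late"):
    values = np.asarray(values, dtype=float)
    return IntensityTrace(site_id, channel, np.arange(values.size) * dt, values)


def seg(A1, A2, t0, dx, direction):
    return SegmentFit(A1=A1, A2=A2, t0=t0, dx=dx, se=(0,) * 4, r_squared=1.0,
                      direction=direction, window=(0.0, 60.0))


class TestSegmentPhases:
    def test_retention_window_on_noise_free_trace(self, times):
        ev = make_event(tau_late=15.0)
        tr = simulate_trace(ev, "late", times)
        t1, t2, locked = segment_phases(tr)
        assert not locked
        assert t2 - t1 == pytest.approx(15.0, abs=1.0)

    def test_locked_trace(self, times):
        ev = make_event(phenotype="locked", locked=True)
        tr = simulate_trace(ev, "late", times)
        t1, t2, locked = segment_phases(tr)
        assert locked
        assert t2 == pytest.approx(times[-1])

    def test_noise_only_is_no_event(self):
        rng = np.random.default_rng(0)
        tr = trace_of(rng.normal(100.0, 10.0, 300))
        t1, t2, locked = segment_phases(tr)
        assert t1 is None and t2 is None and not locked

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="20"):
            segment_phases(trace_of(np.zeros(10)))


class TestFitBoltzmannSegment:
    def test_exact_sigmoid_recovery(self):
        t = np.arange(0, 30, 0.2)
        y = boltzmann_curve(t, 100.0, 8000.0, 12.0, 2.0)
        fit = fit_boltzmann_segment(trace_of(y), (0.0, 29.9), "rising")
        assert fit.status == "ok"
        assert fit.A1 == pytest.approx(100.0, rel=1e-3, abs=1.0)
        assert fit.A2 == pytest.approx(8000.0, rel=1e-3)
        assert fit.t0 == pytest.approx(12.0, rel=1e-3)
        assert fit.dx == pytest.approx(2.0, rel=1e-3)
        assert fit.r_squared > 0.999

    def test_falling_direction(self):
        t = np.arange(0, 30, 0.2)
        y = boltzmann_curve(t, 500.0, 6000.0, 15.0, -1.5)  # falling
        fit = fit_boltzmann_segment(trace_of(y), (0.0, 29.9), "falling")
        assert fit.status == "ok"
        assert fit.A1 == pytest.approx(500.0, rel=1e-3)
        assert fit.A2 == pytest.approx(6000.0, rel=1e-3)
        assert fit.dx == pytest.approx(1.5, rel=1e-3)

    def test_noisy_dx_recovery_100_seeds(self):
        t = np.arange(0, 30, 0.2)
        clean = boltzmann_curve(t, 0.0, 10000.0, 14.0, 2.0)
        errors = []
        for seed in range(100):
            y = clean + np.random.default_rng(seed).normal(0, 200.0, t.size)
            fit = fit_boltzmann_segment(trace_of(y), (0.0, 29.9), "rising")
            errors.append(abs(fit.dx - 2.0) / 2.0)
        assert np.median(errors) < 0.10

    def test_constant_window_is_poor(self):
        fit = fit_boltzmann_segment(trace_of(np.full(50, 42.0)), (0.0, 9.9), "rising")
        assert fit.status == "poor"

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="10 samples"):
            fit_boltzmann_segment(trace_of(np.zeros(100)), (0.0, 1.0), "rising")

    def test_bad_direction_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            fit_boltzmann_segment(trace_of(np.zeros(100)), (0.0, 10.0), "sideways")


class TestDerivedQuantities:
    def test_rate_closed_form(self):
        fa = seg(0.0, 10000.0, 10.0, 25.0, "rising")
        fd = seg(0.0, 10000.0, 40.0, 25.0, "falling")
        r_a, r_d = compute_rates(fa, fd)
        assert r_a == pytest.approx(100.0)
        assert r_d == pytest.approx(100.0)

    def test_rate_scaling_laws(self):
        base, _ = compute_rates(seg(0.0, 8000.0, 10.0, 2.0, "rising"), None)
        doubled_amp, _ = compute_rates(seg(0.0, 16000.0, 10.0, 2.0, "rising"), None)
        doubled_dx, _ = compute_rates(seg(0.0, 8000.0, 10.0, 4.0, "rising"), None)
        assert doubled_amp == pytest.approx(2 * base)
        assert doubled_dx == pytest.approx(base / 2)

    def test_rate_equals_numerical_max_derivative(self):
        fa = seg(100.0, 9100.0, 12.0, 1.7, "rising")
        t = np.linspace(0, 30, 300001)
        slope = np.max(np.gradient(fa.curve(t), t))
        assert fa.rate == pytest.approx(slope, rel=1e-3)

    def test_poor_fit_gives_absent_rate(self):
        bad = seg(0.0, 1.0, 0.0, 1.0, "rising")
        bad.status = "poor"
        r_a, r_d = compute_rates(bad, None)
        assert r_a is None and r_d is None

    def test_retention_formula(self):
        # 90%-of-range crossings: tau = (t0_d - ln9 dx_d) - (t0_a + ln9 dx_a)
        fa = seg(0.0, 5000.0, 10.0, 1.0, "rising")
        fd = seg(0.0, 5000.0, 30.0, 1.0, "falling")
        expected = (30.0 - math.log(9)) - (10.0 + math.log(9))
        assert retention_time(fa, fd) == pytest.approx(expected)

    def test_retention_coterminal_zero(self):
        fa = seg(0.0, 5000.0, 10.0, 1.0, "rising")
        fd = seg(0.0, 5000.0, 10.0 + 2 * math.log(9), 1.0, "falling")
        assert retention_time(fa, fd) == pytest.approx(0.0, abs=1e-9)

    def test_negative_retention_clipped_with_warning(self):
        fa = seg(0.0, 5000.0, 10.0, 1.0, "rising")
        fd = seg(0.0, 5000.0, 5.0, 1.0, "falling")
        with pytest.warns(UserWarning, match="negative retention"):
            assert retention_time(fa, fd) == 0.0

    def test_total_assembly_time(self):
        assert total_assembly_time(seg(0.0, 1.0, 0.0, 2.276, "rising")) == pytest.approx(
            10.0, abs=0.01
        )
        # invariant to amplitudes and midpoint
        assert total_assembly_time(
            seg(500.0, 99999.0, 42.0, 2.276, "rising")
        ) == pytest.approx(10.0, abs=0.01)
        assert total_assembly_time(seg(0.0, 1.0, 0.0, 1e-9, "rising")) < 1e-7
        assert LN81 * 2.276 == pytest.approx(10.0, abs=0.01)


class TestAnalyzeTrace:
    def test_noise_free_oracle_equivalence(self, times):
        ev = make_event(tau_late=15.0, dx_a=2.0, dx_d=1.0, A2=5000.0)
        ck = ev.channels["late"]
        fit = analyze_trace(simulate_trace(ev, "late", times))
        assert fit.status == "ok"
        assert fit.r_a == pytest.approx(ck.assembly_rate, rel=0.02)
        assert fit.r_d == pytest.approx(ck.disassembly_rate, rel=0.02)
        assert fit.tau_ret == pytest.approx(15.0, abs=0.2)
        assert fit.T_a == pytest.approx(ck.total_assembly_time, rel=0.02)

    def test_steep_sigmoid_retention(self, times):
        ev = make_event(tau_late=15.0, dx_a=0.5, dx_d=0.5)
        fit = analyze_trace(simulate_trace(ev, "late", times))
        assert fit.tau_ret == pytest.approx(15.0, abs=0.5)

    def test_locked_trace_censored(self, times):
        ev = make_event(phenotype="locked", locked=True)
        fit = analyze_trace(simulate_trace(ev, "late", times))
        assert fit.locked and fit.censored
        assert fit.disassembly is None
        assert fit.r_d is None

    def test_no_event_status(self):
        rng = np.random.default_rng(1)
        fit = analyze_trace(trace_of(rng.normal(100.0, 10.0, 300)))
        assert fit.status == "no-event"
        assert fit.assembly is None

    def test_scale_equivariance(self, times):
        ev = make_event()
        tr = simulate_trace(ev, "late", times)
        f1 = analyze_trace(tr)
        tr_scaled = IntensityTrace(0, "late", times, tr.raw * 3.0)
        f2 = analyze_trace(tr_scaled)
        assert f2.r_a == pytest.approx(3.0 * f1.r_a, rel=1e-4)
        assert f2.r_d == pytest.approx(3.0 * f1.r_d, rel=1e-4)
        assert f2.tau_ret == pytest.approx(f1.tau_ret, abs=1e-3)
        assert f2.T_a == pytest.approx(f1.T_a, rel=1e-4)

    def test_time_shift_equivariance(self, times):
        ev = make_event()
        tr = simulate_trace(ev, "late", times)
        f1 = analyze_trace(tr)
        shift = 4.2
        tr_shifted = IntensityTrace(0, "late", times + shift, tr.raw.copy())
        f2 = analyze_trace(tr_shifted)
        assert f2.assembly.t0 == pytest.approx(f1.assembly.t0 + shift, abs=1e-3)
        assert f2.t_I_end == pytest.approx(f1.t_I_end + shift, abs=1e-6)
        assert f2.r_a == pytest.approx(f1.r_a, rel=1e-4)
        assert f2.tau_ret == pytest.approx(f1.tau_ret, abs=1e-3)
        assert f2.T_a == pytest.approx(f1.T_a, rel=1e-4)

    def test_noisy_cohort_recovery_n200(self):
        # cohort means of r_a, r_d, tau_ret within 10% of generating means
        cfg = default_config("WT", 200, seed=31, image_shape=(400, 400))
        events = simulate_cohort(cfg, seed=31)
        t = cfg.frame_times
        est = {"r_a": [], "r_d": [], "tau": [], "T_a": []}
        true = {"r_a": [], "r_d": [], "tau": [], "T_a": []}
        for i, ev in enumerate(events):
            ck = ev.channels["late"]
            tr = add_noise(simulate_trace(ev, "late", t), cfg, seed=5000 + i)
            fit = analyze_trace(tr)
            if fit.status != "ok" or fit.censored:
                continue
            est["r_a"].append(fit.r_a)
            est["r_d"].append(fit.r_d)
            est["tau"].append(fit.tau_ret)
            est["T_a"].append(fit.T_a)
            true["r_a"].append(ck.assembly_rate)
            true["r_d"].append(ck.disassembly_rate)
            true["tau"].append(ck.tau_ret)
            true["T_a"].append(ck.total_assembly_time)
        assert len(est["tau"]) >= 190
        for key, rel_tol in (("r_a", 0.10), ("r_d", 0.10)):
            assert np.mean(est[key]) == pytest.approx(np.mean(true[key]), rel=rel_tol)
        assert abs(np.mean(est["tau"]) - np.mean(true["tau"])) < 1.0
        assert abs(np.mean(est["T_a"]) - np.mean(true["T_a"])) < 1.0
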