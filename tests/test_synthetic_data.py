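import math

import numpy as np
import pytest

from escrt_kinetics import (
    SimulationConfig,
    add_noise,
    boltzmann_curve,
    condition_defaults,
    default_config,
    render_movie,
    simulate_cohort,
    simulate_trace,
)
from escrt_kinetics.synthetic_data import LN9, grid_positions

from conftest import make_event


class TestBoltzmannCurve:
    def test_midpoint(self):
        assert boltzmann_curve(7.0, 0.0, 10000.0, 7.0, 3.0) == pytest.approx(5000.0)

    def test_asymptotes(self):
        assert boltzmann_curve(-1e6, 2.0, 9.0, 0.0, 1.0) == pytest.approx(2.0)
        assert boltzmann_curve(1e6, 2.0, 9.0, 0.0, 1.0) == pytest.approx(9.0)

    def test_max_slope_closed_form_vs_finite_differences(self):
        # closed form (A2-A1)/(4 dx) = 100 for A2=10000, dx=25
        t = np.linspace(-300.0, 300.0, 600001)
        y = boltzmann_curve(t, 0.0, 10000.0, 0.0, 25.0)
        slope = np.max(np.gradient(y, t))
        assert slope == pytest.approx(100.0, rel=1e-6)
        assert t[np.argmax(np.gradient(y, t))] == pytest.approx(0.0, abs=1e-2)

    def test_monotone_increasing(self):
        t = np.linspace(-50, 50, 1000)
        y = boltzmann_curve(t, 1.0, 100.0, 3.0, 2.0)
        assert np.all(np.diff(y) > 0)

    def test_zero_dx_rejected(self):
        with pytest.raises(ValueError, match="dx"):
            boltzmann_curve(np.arange(5.0), 0.0, 1.0, 0.0, 0.0)


class TestSimulateTrace:
    def test_locked_trace_nondecreasing(self, times):
        ev = make_event(phenotype="locked", locked=True)
        tr = simulate_trace(ev, "late", times)
        assert np.all(np.diff(tr.raw) >= 0)

    def test_retention_gap_by_construction(self):
        # 90% assembly completion to 90% disassembly onset equals tau_ret
        ev = make_event(tau_late=15.0, dx_a=0.5, dx_d=0.5)
        t = np.arange(0, 60, 0.001)
        tr = simulate_trace(ev, "late", t)
        plateau = tr.raw.max()
        above = t[tr.raw >= 0.9 * plateau]
        assert above[-1] - above[0] == pytest.approx(15.0, abs=0.05)

    def test_linearity_in_amplitude(self, times):
        tr1 = simulate_trace(make_event(A2=5000.0), "early", times)
        tr2 = simulate_trace(make_event(A2=10000.0), "early", times)
        np.testing.assert_allclose(tr2.raw, 2.0 * tr1.raw, rtol=1e-12)

    def test_continuity(self, times):
        tr = simulate_trace(make_event(), "late", times)
        # no jump anywhere close to a frame-to-frame kink
        assert np.max(np.abs(np.diff(tr.raw))) < 0.3 * tr.raw.max()

    def test_empty_times_error(self):
        with pytest.raises(ValueError):
            simulate_trace(make_event(), "early", np.array([]))

    def test_non_increasing_times_error(self):
        with pytest.raises(ValueError):
            simulate_trace(make_event(), "early", np.array([0.0, 0.2, 0.1]))


class TestAddNoise:
    def test_seed_determinism(self, times):
        cfg = SimulationConfig(n_events=1)
        tr = simulate_trace(make_event(), "early", times)
        a = add_noise(tr, cfg, seed=5)
        b = add_noise(tr, cfg, seed=5)
        np.testing.assert_array_equal(a.raw, b.raw)
        c = add_noise(tr, cfg, seed=6)
        assert not np.array_equal(a.raw, c.raw)

    def test_noiseless_limit(self, times):
        cfg = SimulationConfig(n_events=1, read_sd=0.0, gain=1e7, background=0.0)
        tr = simulate_trace(make_event(), "early", times)
        noisy = add_noise(tr, cfg, seed=1)
        np.testing.assert_allclose(noisy.raw, tr.raw, atol=0.2)

    def test_monte_carlo_mean(self):
        # mean of replicates approx noise-free value within 3 SE
        cfg = SimulationConfig(n_events=1)
        value = 4000.0
        tr_times = np.arange(10000) * 0.2
        tr = simulate_trace(make_event(), "early", tr_times)
        tr.raw[:] = value
        noisy = add_noise(tr, cfg, seed=7)
        se = noisy.raw.std(ddof=1) / math.sqrt(noisy.raw.size)
        assert abs(noisy.raw.mean() - value) < 3 * se

    def test_monte_carlo_variance(self):
        # Var = signal/gain + bkg/gain + read_sd^2 (Poisson + Gaussian)
        cfg = SimulationConfig(n_events=1, background=0.0)
        value = 4000.0
        tr_times = np.arange(20000) * 0.2
        tr = simulate_trace(make_event(), "early", tr_times)
        tr.raw[:] = value
        noisy = add_noise(tr, cfg, seed=8)
        expected_var = value / cfg.gain + cfg.read_sd**2
        assert noisy.raw.var(ddof=1) == pytest.approx(expected_var, rel=0.10)

    def test_negative_expectation_clamped(self, times):
        cfg = SimulationConfig(n_events=1, background=0.0)
        tr = simulate_trace(make_event(), "early", times)
        tr.raw[:5] = -50.0
        with pytest.warns(UserWarning, match="clamped"):
            add_noise(tr, cfg, seed=9)


class TestSimulateCohort:
    def test_degenerate_mixture(self):
        cfg = default_config("WT", 40, mixture=(1.0, 0.0, 0.0), seed=1)
        events = simulate_cohort(cfg)
        assert len(events) == 40
        assert all(e.phenotype == "delayed_late_channel" for e in events)

    def test_law_of_large_numbers_plateau(self):
        cfg = default_config("WT", 10000, mixture=(1.0, 0.0, 0.0), seed=2,
                             image_shape=(4000, 4000))
        events = simulate_cohort(cfg)
        a2 = np.array([e.channels["early"].A2 for e in events])
        assert a2.mean() == pytest.approx(4900.0, rel=0.02)

    def test_depleted_over_wt_plateau_ratio(self):
        wt = condition_defaults("WT").plateau[0]
        dep = condition_defaults("ATP_depleted").plateau[0]
        assert dep / wt == pytest.approx(9900.0 / 4900.0)
        assert dep / wt == pytest.approx(2.02, abs=0.005)

    def test_depleted_condition_locks_everything(self):
        cfg = default_config("ATP_depleted", 20, seed=3)
        events = simulate_cohort(cfg)
        assert all(e.phenotype == "locked" for e in events)
        assert all(
            e.channels[c].locked for e in events for c in ("early", "late")
        )

    def test_phenotype_invariants(self):
        cfg = default_config("WT", 200, seed=4, image_shape=(400, 400))
        for ev in simulate_cohort(cfg):
            gap = ev.onset_gap
            if ev.phenotype == "delayed_late_channel":
                assert gap > 0
            elif ev.phenotype == "co_disassembly":
                assert gap == pytest.approx(0.0, abs=1e-9)

    def test_retention_mean_is_15s(self):
        cfg = default_config("WT", 5000, seed=5, image_shape=(2000, 2400))
        taus = [e.channels["late"].tau_ret for e in simulate_cohort(cfg)]
        assert np.mean(taus) == pytest.approx(15.0, abs=0.25)

    def test_seed_determinism(self, wt_config):
        a = simulate_cohort(wt_config, seed=11)
        b = simulate_cohort(wt_config, seed=11)
        assert a == b

    def test_mixture_validation(self):
        with pytest.raises(ValueError, match="mixture"):
            SimulationConfig(n_events=1, mixture=(0.5, 0.2, 0.1))


class TestRenderMovie:
    def test_channel_frame_counts(self, noisefree_run):
        _, movies, _ = noisefree_run
        assert movies["early"].n_frames == 300
        assert movies["late"].n_frames == 300
        assert movies["gag"].n_frames == 2

    def test_noise_free_flux_conservation(self, noisefree_run, noisefree_config):
        # frame pixel sum minus background equals the summed trace values
        _, movies, truth = noisefree_run
        m = movies["early"]
        bg = noisefree_config.background * m.data[0].size
        for k in (0, 75, 150, 299):
            total = m.data[k].sum() - bg
            expected = truth.true_traces["early"][:, k].sum()
            assert total == pytest.approx(expected, rel=5e-3, abs=1.0)

    def test_single_event_pixel_sum_oracle(self):
        cfg = default_config("WT", 1, noise=False, seed=0)
        ev = make_event(position=(20.0, 20.0))
        movies, truth = render_movie([ev], cfg, seed=0)
        m = movies["late"]
        bg = cfg.background * m.data[0].size
        sums = m.data.reshape(m.n_frames, -1).sum(axis=1) - bg
        expected = truth.true_traces["late"][0]
        scale = max(expected.max(), 1.0)
        assert np.max(np.abs(sums - expected)) < 1e-3 * scale

    def test_seed_determinism_bitwise_tiff(self, wt_config, tmp_path):
        events = simulate_cohort(wt_config, seed=20)
        for tag in ("a", "b"):
            movies, _ = render_movie(events, wt_config, seed=21)
            for ch, m in movies.items():
                m.to_tiff(tmp_path / f"{tag}_{ch}.tif")
        for ch in ("early", "late", "gag"):
            assert (tmp_path / f"a_{ch}.tif").read_bytes() == (
                tmp_path / f"b_{ch}.tif"
            ).read_bytes()

    def test_out_of_bounds_position_rejected(self, wt_config):
        ev = make_event(position=(1.0, 1.0))
        with pytest.raises(ValueError, match="border"):
            render_movie([ev], wt_config)

    def test_close_events_warn(self, wt_config):
        evs = [
            make_event(event_id=0, position=(20.0, 20.0)),
            make_event(event_id=1, position=(20.0, 23.0)),
        ]
        with pytest.warns(UserWarning, match="4 x PSF"):
            render_movie(evs, wt_config, seed=1)

    def test_ground_truth_table_shape(self, noisefree_run):
        events, _, truth = noisefree_run
        assert len(truth.params) == 2 * len(events)
        assert set(truth.params["channel"]) == {"early", "late"}
        for col in ("A1", "A2", "t0_a", "dx_a", "tau_ret", "dx_d", "phenotype",
                    "condition"):
            assert col in truth.params.columns


def test_grid_positions_fit_and_spacing():
    pos, shape = grid_positions(12, spacing=24.0, margin=14.0)
    assert pos.shape == (12, 2)
    assert pos.min() >= 13.0
    d = np.hypot(*(pos[:, None, :] - pos[None, :, :]).transpose(2, 0, 1))
    np.fill_diagonal(d, np.inf)
    assert d.min() > 20.0
    with pytest.raises(ValueError, match="cannot host"):
        grid_positions(100, image_shape=(50, 50), spacing=24.0, margin=14.0)


def test_slow_protocol_defaults():
    cfg = default_config("ATP_depleted", 5)
    assert cfg.dt == 5.0
    assert cfg.n_frames == 120


def test_config_roundtrip_dict():
    cfg = default_config("ATP_depleted", 7, seed=9)
    cfg2 = SimulationConfig.from_dict(cfg.to_dict())
    assert cfg2.to_dict() == cfg.to_dict()
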