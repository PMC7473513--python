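"""Headline-number recomputation used by the acceptance report.

Each function regenerates its inputs from the synthetic-data module's
default condition parameterizations, runs the relevant pipeline stages,
and returns the measured quantity.  Nothing here reads stored results:
every value is computed at call time from the given seed.
"""

from __future__ import annotations

import numpy as np

from . import (
    add_noise,
    analyze_trace,
    classify_event,
    compare_conditions,
    default_config,
    normalize_traces,
    render_movie,
    run_pipeline_on_movies,
    simulate_cohort,
    simulate_trace,
    trace_peak,
)
from .orchestration import PipelineConfig

__all__ = [
    "normalization_target_mean",
    "default_record_frames",
    "atp_fold_change",
    "mean_late_retention_trace_level",
    "delayed_fraction_percent",
]


def normalization_target_mean(seed: int, n_traces: int = 5) -> float:
    """Mean of per-trace maxima after cohort normalization (expected 10000)."""
    rng = np.random.default_rng(seed)
    cfg = default_config("WT", n_traces, seed=seed, mixture=(1.0, 0.0, 0.0))
    events = simulate_cohort(cfg, seed=seed)
    traces = []
    for i, ev in enumerate(events):
        tr = simulate_trace(ev, "late", cfg.frame_times)
        traces.append(add_noise(tr, cfg, seed=int(rng.integers(2**31))))
    normed, _ = normalize_traces(traces)
    return float(np.mean([trace_peak(t) for t in normed]))


def default_record_frames() -> int:
    """Frames in one default ESCRT-channel record (rendered, counted)."""
    cfg = default_config("WT", 1)
    assert cfg.dt == 0.2
    events = simulate_cohort(cfg, seed=0)
    movies, _ = render_movie(events, cfg, seed=1)
    return int(movies["early"].n_frames)


def _pipeline_cfg(sim_cfg) -> PipelineConfig:
    return PipelineConfig(
        dt=sim_cfg.dt, psf_sigma=sim_cfg.psf_sigma, condition=sim_cfg.condition
    )


def atp_fold_change(seed: int, n_per_condition: int = 50) -> dict:
    """Depleted/WT fold change, end-to-end with a shared normalization scale."""
    wt_cfg = default_config("WT", n_per_condition, seed=seed)
    dep_cfg = default_config("ATP_depleted", n_per_condition, seed=seed + 1)

    wt_movies, _ = render_movie(simulate_cohort(wt_cfg, seed=seed), wt_cfg,
                                seed=seed + 2)
    wt = run_pipeline_on_movies(wt_movies, _pipeline_cfg(wt_cfg))

    dep_movies, _ = render_movie(
        simulate_cohort(dep_cfg, seed=seed + 1), dep_cfg, seed=seed + 3
    )
    dep = run_pipeline_on_movies(
        dep_movies, _pipeline_cfg(dep_cfg), shared_scales=wt.scales
    )
    out = compare_conditions(wt.phenotypes, dep.phenotypes, seed=seed)
    return out


def mean_late_retention_trace_level(seed: int, n_events: int = 200) -> dict:
    """Cohort mean late-channel retention from noisy trace-level simulation."""
    cfg = default_config("WT", n_events, seed=seed,
                         image_shape=(2000, 2000) if n_events > 200 else None)
    events = simulate_cohort(cfg, seed=seed)
    rng = np.random.default_rng(seed + 1)
    taus = []
    for ev in events:
        tr = simulate_trace(ev, "late", cfg.frame_times)
        tr = add_noise(tr, cfg, seed=int(rng.integers(2**31)))
        fit = analyze_trace(tr)
        if fit.status == "ok" and not fit.censored and fit.tau_ret is not None:
            taus.append(fit.tau_ret)
    return {"mean_tau_s": float(np.mean(taus)), "n": len(taus)}


def delayed_fraction_percent(seed: int, n_events: int = 1000) -> dict:
    """Percent of events classified delayed-late-channel, default mixture."""
    cfg = default_config("WT", n_events, seed=seed, image_shape=(2000, 2000))
    events = simulate_cohort(cfg, seed=seed)
    rng = np.random.default_rng(seed + 1)
    n_delayed = 0
    for ev in events:
        fits = {}
        for ch in ("early", "late"):
            tr = simulate_trace(ev, ch, cfg.frame_times)
            tr = add_noise(tr, cfg, seed=int(rng.integers(2**31)))
            fits[ch] = analyze_trace(tr)
        p = classify_event(fits["early"], fits["late"])
        n_delayed += p.label == "delayed_late_channel"
    return {"percent_delayed": 100.0 * n_delayed / len(events), "n": len(events)}
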