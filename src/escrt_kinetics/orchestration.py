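"""End-to-end pipeline: detect -> extract -> normalize -> fit -> classify.

The pipeline consumes one :class:`~escrt_kinetics.stacks.MovieStack` per
channel role (``gag`` reference imaged at the record's start and end,
``early`` and ``late`` ESCRT channels imaged continuously), runs every
stage with the parameters in a :class:`PipelineConfig`, and returns a
result bundle.  All randomness is seeded; rerunning a config reproduces
identical outputs, and a manifest records parameters and versions.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import detection, kinetics, phenotyping, photometry
from .photometry import IntensityTrace
from .stacks import MovieStack
from .synthetic_data import (
    ESCRT_CHANNELS,
    GroundTruth,
    SimulationConfig,
    render_movie,
    simulate_cohort,
)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "ValidationError",
    "StageError",
    "run_pipeline",
    "run_pipeline_on_movies",
    "run_synthetic_benchmark",
]


class ValidationError(ValueError):
    """Bad configuration or inputs (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    """All pipeline parameters plus input locations.

    ``channel_paths`` maps the channel roles (``gag``, ``early``,
    ``late``) to multi-page TIFF paths; it may be left empty when the
    pipeline is driven in memory.  Round-trips losslessly through YAML.
    """

    channel_paths: dict = field(default_factory=dict)
    dt: float = 0.2
    pixel_size_um: float = 0.1
    psf_sigma: float = 1.3
    condition: str = "WT"
    seed: int = 0
    # detection
    threshold_snr: float = detection.DEFAULT_THRESHOLD_SNR
    max_displacement: float = detection.DEFAULT_MAX_DISPLACEMENT
    coloc_radius: float = detection.DEFAULT_COLOC_RADIUS
    # photometry
    aperture_radius: float = photometry.DEFAULT_APERTURE_RADIUS
    annulus: tuple[float, float] = photometry.DEFAULT_ANNULUS
    normalization_target: float = photometry.DEFAULT_NORMALIZATION_TARGET
    aperture_correction: bool = True
    # kinetics
    smooth_frames: int = kinetics.DEFAULT_SMOOTH_FRAMES
    plateau_fraction: float = kinetics.DEFAULT_PLATEAU_FRACTION
    decline_frames: int = kinetics.DEFAULT_DECLINE_FRAMES
    overlap_s: float = kinetics.DEFAULT_OVERLAP_S
    # phenotyping
    delay_threshold: float = phenotyping.DEFAULT_DELAY_THRESHOLD
    exclude_minor: bool = True
    bootstrap_n: int = 2000
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValidationError("dt must be positive")
        if self.annulus[0] <= self.aperture_radius:
            raise ValidationError("annulus inner radius must exceed aperture radius")
        roles = list(self.channel_paths)
        if len(set(roles)) != len(roles):
            raise ValidationError("channel roles must be unique")
        self.annulus = tuple(float(a) for a in self.annulus)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["annulus"] = list(self.annulus)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        extra = set(d) - known
        if extra:
            raise ValidationError(f"unknown config keys: {sorted(extra)}")
        if "annulus" in d:
            d["annulus"] = tuple(d["annulus"])
        return cls(**d)


@dataclass
class PipelineResult:
    sites: list
    traces: dict  # channel -> list[IntensityTrace]
    scales: dict  # channel -> float
    fits: dict  # channel -> list[KineticFit]
    phenotypes: list
    summary: phenotyping.CohortSummary
    qc: list = field(default_factory=list)

    def fits_frame(self) -> pd.DataFrame:
        rows = []
        for ch, fits in sorted(self.fits.items()):
            for f in fits:
                rows.append(
                    {
                        "site_id": f.site_id,
                        "channel": ch,
                        "status": f.status,
                        "locked": f.locked,
                        "t_I_end": f.t_I_end,
                        "t_II_end": f.t_II_end,
                        "r_a": f.r_a,
                        "r_d": f.r_d,
                        "tau_ret": f.tau_ret,
                        "censored": f.censored,
                        "T_a": f.T_a,
                        "peak": f.peak,
                    }
                )
        return pd.DataFrame(rows)

    def phenotypes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "site_id": p.site_id,
                    "label": p.label,
                    "delta_tau": p.delta_tau,
                    "peak_early": p.peak_early,
                    "peak_late": p.peak_late,
                    "reason": p.reason,
                }
                for p in self.phenotypes
            ]
        )

    def sites_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "site_id": s.site_id,
                    "row": s.row,
                    "col": s.col,
                    "displacement_px": s.displacement,
                    "status": s.status,
                    "reason": s.reason,
                }
                for s in self.sites
            ]
        )

    def traces_frame(self) -> pd.DataFrame:
        rows = []
        for ch, traces in sorted(self.traces.items()):
            for tr in traces:
                for k in range(tr.times.size):
                    rows.append(
                        {
                            "site_id": tr.site_id,
                            "channel": ch,
                            "frame": k,
                            "time_s": tr.times[k],
                            "raw": tr.raw[k],
                            "background": None
                            if tr.background is None
                            else tr.background[k],
                            "normalized": None
                            if tr.normalized is None
                            else tr.normalized[k],
                        }
                    )
        return pd.DataFrame(rows)


def run_pipeline_on_movies(
    movies: dict[str, MovieStack],
    config: PipelineConfig | None = None,
    shared_scales: dict[str, float] | None = None,
) -> PipelineResult:
    """Run every stage on in-memory stacks.

    ``shared_scales`` (channel -> scale factor) reuses normalization
    factors from another cohort, as required for cross-condition
    intensity comparisons.
    """
    config = config or PipelineConfig()
    missing = [c for c in ("gag", *ESCRT_CHANNELS) if c not in movies]
    if missing:
        raise ValidationError(f"missing channel stacks: {missing}")
    gag = movies["gag"]
    if gag.n_frames < 2:
        raise ValidationError("reference channel needs start and end frames")
    shapes = {c: m.shape for c, m in movies.items()}
    if len(set(shapes.values())) != 1:
        raise ValidationError(f"channel stacks disagree on geometry: {shapes}")

    qc: list[str] = []

    # --- stage 1: reference detection and site building -------------------
    det_start = detection.detect_spots(
        gag.data[0], config.psf_sigma, config.threshold_snr, frame_index=0
    )
    det_end = detection.detect_spots(
        gag.data[-1], config.psf_sigma, config.threshold_snr,
        frame_index=gag.n_frames - 1,
    )
    all_sites = detection.build_event_sites(det_start, det_end, config.max_displacement)
    sites = [s for s in all_sites if s.status == "valid"]
    for s in all_sites:
        if s.status != "valid":
            qc.append(f"site at ({s.row:.1f},{s.col:.1f}) rejected: {s.reason}")

    # --- stage 2: colocalization and photometry ---------------------------
    traces: dict[str, list[IntensityTrace]] = {}
    scales: dict[str, float] = {}
    for ch in ESCRT_CHANNELS:
        movie = movies[ch]
        projection = movie.data.mean(axis=0)
        ch_dets = detection.detect_spots(projection, config.psf_sigma, config.threshold_snr)
        ch_traces = []
        for site in sites:
            found, offset = detection.colocalize(site, ch_dets, config.coloc_radius)
            if not found:
                qc.append(f"site {site.site_id}: no {ch} colocalization within "
                          f"{config.coloc_radius} px")
                offset = (0.0, 0.0)
            site.channel_offsets[ch] = offset
            try:
                tr = photometry.extract_trace(
                    movie,
                    site,
                    aperture_radius=config.aperture_radius,
                    annulus=config.annulus,
                    aperture_correction=config.aperture_correction,
                    offset=offset,
                )
            except ValueError as err:
                raise StageError(f"photometry failed for site {site.site_id}: {err}")
            tr.meta["colocalized"] = found
            ch_traces.append(tr)
        if ch_traces:
            shared = None if shared_scales is None else shared_scales.get(ch)
            try:
                ch_traces, scale = photometry.normalize_traces(
                    ch_traces, config.normalization_target, scale=shared
                )
            except ValueError as err:
                raise StageError(f"normalization failed for channel {ch}: {err}")
            scales[ch] = scale
        traces[ch] = ch_traces

    # --- stage 3: kinetics ------------------------------------------------
    fits: dict[str, list] = {}
    for ch in ESCRT_CHANNELS:
        fits[ch] = []
        for tr in traces[ch]:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fits[ch].append(
                    kinetics.analyze_trace(
                        tr,
                        smooth_frames=config.smooth_frames,
                        plateau_fraction=config.plateau_fraction,
                        decline_frames=config.decline_frames,
                        overlap_s=config.overlap_s,
                    )
                )

    # --- stage 4: phenotyping ---------------------------------------------
    by_site = {
        ch: {f.site_id: f for f in fits[ch]} for ch in ESCRT_CHANNELS
    }
    phenotypes = []
    for site in sites:
        fe = by_site["early"].get(site.site_id)
        fl = by_site["late"].get(site.site_id)
        if fe is None or fl is None:
            continue
        phenotypes.append(
            phenotyping.classify_event(
                fe, fl, config.delay_threshold,
                scale_factor=scales.get("early"),
            )
        )
    summary = phenotyping.summarize_cohort(
        fits["early"] + fits["late"], phenotypes, exclude_minor=config.exclude_minor
    )
    return PipelineResult(
        sites=sites,
        traces=traces,
        scales=scales,
        fits=fits,
        phenotypes=phenotypes,
        summary=summary,
        qc=qc,
    )


def _manifest(config: PipelineConfig) -> dict:
    import scipy

    from . import __version__

    return {
        "escrt_kinetics": __version__,
        "numpy": np.__version__,
        "scipy": scipy.version.version,
        "pandas": pd.__version__,
        "config": {**asdict(config), "annulus": list(config.annulus)},
    }


def load_movies(config: PipelineConfig) -> dict[str, MovieStack]:
    movies = {}
    for role, path in config.channel_paths.items():
        p = Path(path)
        if not p.exists():
            raise ValidationError(f"channel {role!r}: file not found: {p}")
        movies[role] = MovieStack.from_tiff(
            p, channel=role, dt=config.dt, psf_sigma=config.psf_sigma
        )
    if "gag" in movies and movies["gag"].n_frames == 2:
        # reference imaged at start and end of the ESCRT record
        n = max((m.n_frames for r, m in movies.items() if r != "gag"), default=2)
        movies["gag"].frame_times = np.array([0.0, (n - 1) * config.dt])
    return movies


def run_pipeline(config: PipelineConfig, plots: bool = False) -> PipelineResult:
    """File-level pipeline: read TIFFs, run all stages, write outputs."""
    if not config.channel_paths:
        raise ValidationError("config.channel_paths is empty")
    movies = load_movies(config)
    result = run_pipeline_on_movies(movies, config)
    if config.output_dir is not None:
        write_outputs(result, config, plots=plots)
    return result


def write_outputs(
    result: PipelineResult, config: PipelineConfig, plots: bool = False,
    max_trace_plots: int = 12,
) -> Path:
    out = Path(config.output_dir or ".")
    out.mkdir(parents=True, exist_ok=True)
    if plots:
        from . import plots as _plots

        plot_dir = out / "plots"
        plot_dir.mkdir(exist_ok=True)
        _plots.plot_cohort_panels(result, plot_dir / "cohort_panels.png")
        n_done = 0
        for ch in ESCRT_CHANNELS:
            fits_by_site = {f.site_id: f for f in result.fits[ch]}
            for tr in result.traces[ch]:
                if n_done >= max_trace_plots:
                    break
                _plots.plot_trace_fit(
                    tr, fits_by_site[tr.site_id],
                    plot_dir / f"site{tr.site_id:03d}_{ch}.png",
                )
                n_done += 1
    kw = {"index": False, "float_format": "%.8g"}
    result.sites_frame().to_csv(out / "sites.csv", **kw)
    result.traces_frame().to_csv(out / "traces.csv", **kw)
    result.fits_frame().to_csv(out / "fits.csv", **kw)
    result.phenotypes_frame().to_csv(out / "phenotypes.csv", **kw)
    (out / "summary.json").write_text(
        json.dumps(result.summary.to_dict(), indent=2, sort_keys=True)
    )
    (out / "scale_factors.json").write_text(
        json.dumps(result.scales, indent=2, sort_keys=True)
    )
    (out / "manifest.json").write_text(
        json.dumps(_manifest(config), indent=2, sort_keys=True)
    )
    if result.qc:
        (out / "qc.txt").write_text("\n".join(result.qc) + "\n")
    return out


# --------------------------------------------------------------------------
# synthetic benchmark
# --------------------------------------------------------------------------

def _match_sites_to_events(result: PipelineResult, truth: GroundTruth, tol: float = 2.0):
    """site_id -> event_id by nearest position within ``tol`` px."""
    mapping = {}
    for site in result.sites:
        best, best_d = None, tol
        for ev in truth.events:
            d = math.hypot(site.row - ev.position[0], site.col - ev.position[1])
            if d < best_d:
                best, best_d = ev.event_id, d
        if best is not None:
            mapping[site.site_id] = best
    return mapping


def run_synthetic_benchmark(
    sim_config: SimulationConfig,
    pipeline_config: PipelineConfig | None = None,
    seed: int | None = None,
    tolerances: dict | None = None,
) -> dict:
    """Simulate a cohort, run the pipeline, and score parameter recovery.

    Estimates are joined to ground truth by spot position; the report
    carries per-channel bias and RMSE for rates, retention time and
    assembly time, plus recovered phenotype fractions and pass/fail
    against the tolerance thresholds (relative for rates, absolute
    seconds for durations).
    """
    seed = sim_config.seed if seed is None else seed
    tolerances = tolerances or {"rate_rel": 0.10, "tau_abs_s": 1.0, "T_a_abs_s": 1.0}
    pipeline_config = pipeline_config or PipelineConfig(
        dt=sim_config.dt, psf_sigma=sim_config.psf_sigma, condition=sim_config.condition
    )

    events = simulate_cohort(sim_config, seed=seed)
    movies, truth = render_movie(events, sim_config, seed=seed + 1)
    if not events:
        return {"n_events": 0, "rows": pd.DataFrame(), "passed": True, "checks": {}}
    result = run_pipeline_on_movies(movies, pipeline_config)
    mapping = _match_sites_to_events(result, truth, tol=2.0)

    # the normalization scalar rescales intensities; rates in the estimate
    # are on the normalized scale, so compare rates after undoing it
    rows = []
    tp = truth.params.set_index(["event_id", "channel"])
    for ch in ESCRT_CHANNELS:
        scale = result.scales.get(ch, 1.0)
        for f in result.fits[ch]:
            if f.site_id not in mapping:
                continue
            g = tp.loc[(mapping[f.site_id], ch)]
            rows.append(
                {
                    "event_id": mapping[f.site_id],
                    "channel": ch,
                    "status": f.status,
                    "r_a_est": None if f.r_a is None else f.r_a / scale,
                    "r_a_true": g["assembly_rate"],
                    "r_d_est": None if f.r_d is None else f.r_d / scale,
                    "r_d_true": g["disassembly_rate"],
                    "tau_est": None if f.censored else f.tau_ret,
                    "tau_true": g["tau_ret"],
                    "T_a_est": f.T_a,
                    "T_a_true": g["total_assembly_time"],
                    "censored": f.censored,
                }
            )
    df = pd.DataFrame(rows)

    def _score(est_col, true_col):
        sub = df.dropna(subset=[est_col, true_col])
        if sub.empty:
            return {"n": 0, "bias": None, "rmse": None}
        err = sub[est_col].astype(float) - sub[true_col].astype(float)
        return {
            "n": int(len(sub)),
            "bias": float(err.mean()),
            "rmse": float(np.sqrt((err**2).mean())),
            "true_mean": float(sub[true_col].mean()),
        }

    checks = {}
    for name, (e, t) in {
        "r_a": ("r_a_est", "r_a_true"),
        "r_d": ("r_d_est", "r_d_true"),
        "tau_ret": ("tau_est", "tau_true"),
        "T_a": ("T_a_est", "T_a_true"),
    }.items():
        sc = _score(e, t)
        if sc["n"]:
            if name in ("tau_ret", "T_a"):
                key = "tau_abs_s" if name == "tau_ret" else "T_a_abs_s"
                sc["pass"] = abs(sc["bias"]) <= tolerances[key]
            else:
                sc["pass"] = abs(sc["bias"]) <= tolerances["rate_rel"] * abs(sc["true_mean"])
        else:
            sc["pass"] = True
        checks[name] = sc

    truth_fracs = truth.params.drop_duplicates("event_id")["phenotype"].value_counts(
        normalize=True
    ).to_dict()
    est_fracs = result.summary.phenotype_fractions
    return {
        "n_events": len(events),
        "n_recovered": len(mapping),
        "rows": df,
        "checks": checks,
        "passed": all(c["pass"] for c in checks.values()),
        "true_phenotype_fractions": truth_fracs,
        "estimated_phenotype_fractions": est_fracs,
    }
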