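"""Three-phase segmentation and Boltzmann-growth kinetic fitting.

A recruitment trace is segmented into phase I (sigmoidal assembly),
phase II (plateau) and phase III (sigmoidal disassembly).  Each sigmoidal
segment is fit by nonlinear least squares to the Boltzmann growth curve;
the derived quantities are

* assembly / disassembly rate: the fitted sigmoid's maximum slope
  ``(A2 - A1) / (4 dx)``, in a.u./s of the normalized intensities;
* retention time: interval between the assembly sigmoid reaching 90% of
  its range and the disassembly sigmoid falling below 90%, i.e.
  ``(t0_d - ln(9) dx_d) - (t0_a + ln(9) dx_a)``;
* total assembly time: 10% -> 90% rise time, ``ln(81) dx_a``.

Traces with no sustained decline before the record ends are flagged
locked and their retention time is censored at the record end.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from scipy.optimize import curve_fit

from .photometry import IntensityTrace
from .synthetic_data import LN9, LN81, boltzmann_curve

__all__ = [
    "SegmentFit",
    "KineticFit",
    "segment_phases",
    "fit_boltzmann_segment",
    "compute_rates",
    "retention_time",
    "total_assembly_time",
    "analyze_trace",
]

DEFAULT_SMOOTH_FRAMES = 5
DEFAULT_PLATEAU_FRACTION = 0.9
DEFAULT_DECLINE_FRAMES = 5
DEFAULT_OVERLAP_S = 2.0
EVENT_GATE_MADS = 5.0


@dataclass
class SegmentFit:
    """Boltzmann parameters for one rising or falling segment."""

    A1: float
    A2: float
    t0: float
    dx: float
    se: tuple[float, float, float, float]
    r_squared: float
    direction: str  # rising | falling
    window: tuple[float, float]
    status: str = "ok"  # ok | poor

    @property
    def rate(self) -> float:
        """Maximum slope of the fitted sigmoid, a.u./s."""
        return abs(self.A2 - self.A1) / (4.0 * abs(self.dx))

    def onset_90(self) -> float:
        """Time the sigmoid crosses 90% of its range toward the plateau.

        Rising: reaches 90%; falling: drops below 90%.
        """
        if self.direction == "rising":
            return self.t0 + LN9 * abs(self.dx)
        return self.t0 - LN9 * abs(self.dx)

    def curve(self, t: np.ndarray) -> np.ndarray:
        sign = 1.0 if self.direction == "rising" else -1.0
        return boltzmann_curve(t, self.A1, self.A2, self.t0, sign * self.dx)


@dataclass
class KineticFit:
    """Full per-trace kinetic characterization."""

    site_id: int
    channel: str
    status: str  # ok | poor | no-event
    locked: bool = False
    t_I_end: float | None = None
    t_II_end: float | None = None
    assembly: SegmentFit | None = None
    disassembly: SegmentFit | None = None
    r_a: float | None = None
    r_d: float | None = None
    tau_ret: float | None = None
    censored: bool = False
    T_a: float | None = None
    peak: float | None = None


def segment_phases(
    trace: IntensityTrace,
    smooth_frames: int = DEFAULT_SMOOTH_FRAMES,
    plateau_fraction: float = DEFAULT_PLATEAU_FRACTION,
    decline_frames: int = DEFAULT_DECLINE_FRAMES,
) -> tuple[float | None, float | None, bool]:
    """Locate phase boundaries on the median-smoothed trace.

    Returns ``(t_I_end, t_II_end, locked)``: the first time the smoothed
    trace reaches 90% of its plateau level (mean of the top decile), the
    last time it stays at/above that level before a sustained decline
    (``decline_frames`` consecutive frames below), and whether no such
    decline occurs before the record ends.  Returns ``(None, None, False)``
    when no recruitment event is present (max - baseline below
    5 x baseline MAD).
    """
    v = trace.values
    n = v.size
    if n < 20:
        raise ValueError("segmentation requires at least 20 frames")
    sm = median_filter(v, size=smooth_frames, mode="nearest")

    n_base = max(5, n // 10)
    baseline = float(np.median(sm[:n_base]))
    mad = 1.4826 * float(np.median(np.abs(v[:n_base] - baseline)))
    floor = max(mad, 1e-9 * max(abs(float(np.max(sm))), 1.0))

    top_decile = np.sort(sm)[int(math.ceil(0.9 * n)):]
    plateau = float(top_decile.mean()) if top_decile.size else float(sm.max())
    if plateau - baseline <= EVENT_GATE_MADS * floor:
        return None, None, False

    threshold = baseline + plateau_fraction * (plateau - baseline)
    above = sm >= threshold
    idx_above = np.flatnonzero(above)
    if idx_above.size == 0:
        return None, None, False
    i_start = int(idx_above[0])
    t_I_end = float(trace.times[i_start])

    below = ~above
    decline_at = None
    for i in range(i_start + 1, n - decline_frames + 1):
        if below[i : i + decline_frames].all():
            decline_at = i
            break
    if decline_at is None:
        return t_I_end, float(trace.times[-1]), True
    prior = idx_above[idx_above < decline_at]
    t_II_end = float(trace.times[int(prior[-1])]) if prior.size else t_I_end
    return t_I_end, t_II_end, False


def fit_boltzmann_segment(
    trace: IntensityTrace,
    window: tuple[float, float],
    direction: str,
) -> SegmentFit:
    """Least-squares Boltzmann fit over a time window.

    ``direction`` selects the rising (``A1 -> A2``) or falling
    (``A2 -> A1``) branch; ``A1`` is always the low asymptote.  Fits with
    R-squared below 0.5 (or failed convergence) are returned with status
    ``"poor"``, parameters still populated.
    """
    if direction not in ("rising", "falling"):
        raise ValueError("direction must be 'rising' or 'falling'")
    t0_w, t1_w = window
    mask = (trace.times >= t0_w) & (trace.times <= t1_w)
    t = trace.times[mask]
    y = trace.values[mask]
    if t.size < 10:
        raise ValueError(f"fit window {window} contains {t.size} < 10 samples")
    span = float(t[-1] - t[0])
    dt = trace.dt
    lo, hi = float(np.min(y)), float(np.max(y))
    rng_y = hi - lo

    sign = 1.0 if direction == "rising" else -1.0

    def model(tt, A1, A2, t0, dx):
        return boltzmann_curve(tt, A1, A2, t0, sign * dx)

    # half-range crossing for t0 init
    half = lo + 0.5 * rng_y
    if direction == "rising":
        cross = np.flatnonzero(y >= half)
    else:
        cross = np.flatnonzero(y <= half)
    t0_init = float(t[cross[0]]) if cross.size else float(t[t.size // 2])
    p0 = [lo, hi, t0_init, span / 8.0]
    bounds = (
        [lo - rng_y - 1.0, lo, float(t[0]) - span, dt / 2.0],
        [hi, hi + rng_y + 1.0, float(t[-1]) + span, span if span > dt / 2 else dt],
    )
    p0 = np.clip(p0, bounds[0], bounds[1])

    status = "ok"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                model, t, y, p0=p0, bounds=bounds, xtol=1e-10, max_nfev=5000
            )
        se = tuple(float(s) for s in np.sqrt(np.clip(np.diag(pcov), 0, None)))
    except (RuntimeError, ValueError):
        popt, se = p0, (math.nan,) * 4
        status = "poor"

    resid = y - model(t, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    if r2 < 0.5:
        status = "poor"
    return SegmentFit(
        A1=float(popt[0]),
        A2=float(popt[1]),
        t0=float(popt[2]),
        dx=float(popt[3]),
        se=se,
        r_squared=r2,
        direction=direction,
        window=(float(t0_w), float(t1_w)),
        status=status,
    )


def compute_rates(
    fit_assembly: SegmentFit | None, fit_disassembly: SegmentFit | None
) -> tuple[float | None, float | None]:
    """Maximum-slope rates of the fitted sigmoids; None for missing/poor fits."""
    r_a = fit_assembly.rate if fit_assembly and fit_assembly.status == "ok" else None
    r_d = (
        fit_disassembly.rate
        if fit_disassembly and fit_disassembly.status == "ok"
        else None
    )
    return r_a, r_d


def retention_time(
    fit_assembly: SegmentFit, fit_disassembly: SegmentFit
) -> float:
    """Plateau dwell: 90% assembly completion to 90% disassembly onset.

    ``tau = (t0_d - ln(9) dx_d) - (t0_a + ln(9) dx_a)``; negative values
    are clipped to 0 with a warning.
    """
    tau = (fit_disassembly.t0 - LN9 * abs(fit_disassembly.dx)) - (
        fit_assembly.t0 + LN9 * abs(fit_assembly.dx)
    )
    if tau < 0:
        warnings.warn(f"negative retention time {tau:.3f} s clipped to 0", stacklevel=2)
        return 0.0
    return float(tau)


def total_assembly_time(fit_assembly: SegmentFit) -> float | None:
    """10% -> 90% rise time of the fitted assembly sigmoid, ``ln(81) dx``."""
    if fit_assembly is None or fit_assembly.status != "ok":
        return None
    return float(LN81 * abs(fit_assembly.dx))


def analyze_trace(
    trace: IntensityTrace,
    smooth_frames: int = DEFAULT_SMOOTH_FRAMES,
    plateau_fraction: float = DEFAULT_PLATEAU_FRACTION,
    decline_frames: int = DEFAULT_DECLINE_FRAMES,
    overlap_s: float = DEFAULT_OVERLAP_S,
) -> KineticFit:
    """Segment one trace and fit its sigmoidal phases.

    Phase I fit window runs from the record start to ``t_I_end +
    overlap_s``; phase III from ``t_II_end - overlap_s`` to the record
    end (the overlap stabilizes the shared-asymptote estimates).  Locked
    traces get no disassembly fit and a censored retention time.
    """
    t_I_end, t_II_end, locked = segment_phases(
        trace, smooth_frames, plateau_fraction, decline_frames
    )
    peak = float(np.max(median_filter(trace.values, size=3, mode="nearest")))
    if t_I_end is None:
        return KineticFit(
            site_id=trace.site_id, channel=trace.channel, status="no-event", peak=peak
        )

    fit = KineticFit(
        site_id=trace.site_id,
        channel=trace.channel,
        status="ok",
        locked=locked,
        t_I_end=t_I_end,
        t_II_end=t_II_end,
        peak=peak,
    )
    try:
        fit.assembly = fit_boltzmann_segment(
            trace, (float(trace.times[0]), t_I_end + overlap_s), "rising"
        )
    except ValueError:
        fit.status = "poor"
    if not locked:
        try:
            fit.disassembly = fit_boltzmann_segment(
                trace, (t_II_end - overlap_s, float(trace.times[-1])), "falling"
            )
        except ValueError:
            fit.status = "poor"

    fit.r_a, fit.r_d = compute_rates(fit.assembly, fit.disassembly)
    if fit.assembly is not None:
        fit.T_a = total_assembly_time(fit.assembly)
    if locked:
        fit.censored = True
        if fit.assembly is not None and fit.assembly.status == "ok":
            # censored at record end
            fit.tau_ret = float(trace.times[-1]) - (
                fit.assembly.t0 + LN9 * abs(fit.assembly.dx)
            )
    elif (
        fit.assembly is not None
        and fit.disassembly is not None
        and fit.assembly.status == "ok"
        and fit.disassembly.status == "ok"
    ):
        fit.tau_ret = retention_time(fit.assembly, fit.disassembly)
    if (fit.assembly is not None and fit.assembly.status == "poor") or (
        fit.disassembly is not None and fit.disassembly.status == "poor"
    ):
        fit.status = "poor"
    return fit
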