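"""Phenotype classification and cohort-level statistics.

Dual-channel events are classified by the delay between the two channels'
disassembly onsets (the 90% crossing times of the fitted falling
sigmoids): a late-channel delay above the threshold is the major
"delayed late channel" phenotype, a delay within the threshold is
co-disassembly, and events censored in both channels (no disassembly
before the record ends) are locked.  Condition comparisons use per-event
normalized maxima under a shared normalization scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kinetics import KineticFit

__all__ = [
    "EventPhenotype",
    "CohortSummary",
    "classify_event",
    "compare_conditions",
    "summarize_cohort",
    "DEFAULT_DELAY_THRESHOLD",
]

DEFAULT_DELAY_THRESHOLD = 5.0  # s
PHENOTYPE_CLASSES = ("delayed_late_channel", "co_disassembly", "locked", "unclassifiable")


@dataclass
class EventPhenotype:
    site_id: int
    label: str
    delta_tau: float | None = None  # late-minus-early disassembly-onset delay, s
    peak_early: float | None = None  # normalized maxima, a.u.
    peak_late: float | None = None
    scale_factor: float | None = None
    reason: str = ""


def _onset(fit: KineticFit) -> float | None:
    if fit.disassembly is None or fit.disassembly.status != "ok":
        return None
    return fit.disassembly.onset_90()


def classify_event(
    fit_early: KineticFit,
    fit_late: KineticFit,
    delay_threshold: float = DEFAULT_DELAY_THRESHOLD,
    scale_factor: float | None = None,
) -> EventPhenotype:
    """Classify one dual-channel event from its two kinetic fits."""
    if fit_early.site_id != fit_late.site_id:
        raise ValueError("channel fits belong to different sites")
    out = EventPhenotype(
        site_id=fit_early.site_id,
        label="unclassifiable",
        peak_early=fit_early.peak,
        peak_late=fit_late.peak,
        scale_factor=scale_factor,
    )
    if fit_early.status == "no-event" or fit_late.status == "no-event":
        out.reason = "no recruitment event in at least one channel"
        return out
    if fit_early.censored and fit_late.censored:
        out.label = "locked"
        return out
    onset_e, onset_l = _onset(fit_early), _onset(fit_late)
    if onset_e is None or onset_l is None:
        out.reason = "disassembly fit missing or poor in one channel"
        return out
    out.delta_tau = float(onset_l - onset_e)
    if out.delta_tau > delay_threshold:
        out.label = "delayed_late_channel"
    elif abs(out.delta_tau) <= delay_threshold:
        out.label = "co_disassembly"
    return out


def _peaks(phenotypes: list[EventPhenotype]) -> np.ndarray:
    vals = []
    for p in phenotypes:
        for v in (p.peak_early, p.peak_late):
            if v is not None and math.isfinite(v):
                vals.append(v)
    return np.asarray(vals, dtype=float)


def compare_conditions(
    wt: list[EventPhenotype],
    depleted: list[EventPhenotype],
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> dict:
    """Depleted-over-WT fold change in mean normalized maximum intensity.

    Both cohorts must have been normalized with one shared scale factor;
    mixed scales invalidate the comparison and raise.  The 95% interval is
    a seeded percentile bootstrap over events.
    """
    if not wt or not depleted:
        raise ValueError("both cohorts must be non-empty")
    scales = {
        p.scale_factor for p in (*wt, *depleted) if p.scale_factor is not None
    }
    if len(scales) > 1:
        raise ValueError(
            f"mixed normalization scale factors {sorted(scales)}; "
            "re-normalize with a shared scale before comparing conditions"
        )
    wt_peaks, dep_peaks = _peaks(wt), _peaks(depleted)
    if wt_peaks.size == 0 or dep_peaks.size == 0:
        raise ValueError("no usable intensity maxima in at least one cohort")
    fold = float(dep_peaks.mean() / wt_peaks.mean())
    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    for i in range(n_bootstrap):
        bw = wt_peaks[rng.integers(0, wt_peaks.size, wt_peaks.size)]
        bd = dep_peaks[rng.integers(0, dep_peaks.size, dep_peaks.size)]
        boots[i] = bd.mean() / bw.mean()
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {
        "fold_change": fold,
        "ci95": (float(lo), float(hi)),
        "wt_mean": float(wt_peaks.mean()),
        "wt_sd": float(wt_peaks.std(ddof=1)) if wt_peaks.size > 1 else float("nan"),
        "depleted_mean": float(dep_peaks.mean()),
        "depleted_sd": float(dep_peaks.std(ddof=1)) if dep_peaks.size > 1 else float("nan"),
        "n_wt": int(wt_peaks.size),
        "n_depleted": int(dep_peaks.size),
    }


@dataclass
class CohortSummary:
    """Condition-level aggregate statistics."""

    n_events: int
    n_classified: int
    phenotype_counts: dict = field(default_factory=dict)
    phenotype_fractions: dict = field(default_factory=dict)
    channel_stats: dict = field(default_factory=dict)  # channel -> field -> stats
    peak_stats: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_events": self.n_events,
            "n_classified": self.n_classified,
            "phenotype_counts": self.phenotype_counts,
            "phenotype_fractions": self.phenotype_fractions,
            "channel_stats": self.channel_stats,
            "peak_stats": self.peak_stats,
        }


def _stat(values: list[float]) -> dict:
    arr = np.asarray([v for v in values if v is not None and math.isfinite(v)])
    if arr.size == 0:
        return {"mean": None, "sd": None, "n": 0}
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else None,
        "n": int(arr.size),
    }


def summarize_cohort(
    fits: list[KineticFit],
    phenotypes: list[EventPhenotype],
    exclude_minor: bool = True,
) -> CohortSummary:
    """Aggregate per-event fits and classifications.

    Rate/retention/assembly-time summaries are computed per channel over
    events with usable fits; by default only the major (delayed late
    channel) phenotype enters the kinetic summaries, mirroring the
    analysis focus on the major phenotype, while phenotype fractions count
    all classified events.  Locked cohorts are summarized over locked
    events instead.
    """
    counts = {c: 0 for c in PHENOTYPE_CLASSES}
    for p in phenotypes:
        counts[p.label] = counts.get(p.label, 0) + 1
    classified = {c: counts[c] for c in PHENOTYPE_CLASSES if c != "unclassifiable"}
    n_classified = sum(classified.values())
    fractions = (
        {c: v / n_classified for c, v in classified.items()} if n_classified else {}
    )

    if exclude_minor and counts["delayed_late_channel"] > 0:
        kinetic_ids = {
            p.site_id for p in phenotypes if p.label == "delayed_late_channel"
        }
    else:
        kinetic_ids = {p.site_id for p in phenotypes if p.label != "unclassifiable"}

    channel_stats: dict[str, dict] = {}
    for ch in sorted({f.channel for f in fits}):
        ch_fits = [f for f in fits if f.channel == ch and f.site_id in kinetic_ids]
        channel_stats[ch] = {
            "r_a": _stat([f.r_a for f in ch_fits]),
            "r_d": _stat([f.r_d for f in ch_fits]),
            "tau_ret": _stat([f.tau_ret for f in ch_fits if not f.censored]),
            "T_a": _stat([f.T_a for f in ch_fits]),
            "n_censored": sum(f.censored for f in ch_fits),
        }

    peak_stats = _stat(list(_peaks(phenotypes)))
    return CohortSummary(
        n_events=len(phenotypes),
        n_classified=n_classified,
        phenotype_counts=counts,
        phenotype_fractions=fractions,
        channel_stats=channel_stats,
        peak_stats=peak_stats,
    )
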