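"""Diagnostic and summary figures (matplotlib, Agg backend)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_trace_fit", "plot_cohort_panels"]

_CHANNEL_COLORS = {"early": "tab:blue", "late": "tab:red", "gag": "k"}


def plot_trace_fit(trace, fit, path=None):
    """One event's trace with fitted sigmoids and phase boundaries."""
    figure, ax = plt.subplots(figsize=(5, 3))
    ax.plot(trace.times, trace.values, ".", ms=2, color="0.6", label="data")
    for seg in (fit.assembly, fit.disassembly):
        if seg is None:
            continue
        tt = np.linspace(*seg.window, 200)
        ax.plot(tt, seg.curve(tt), "-", lw=1.5,
                color=_CHANNEL_COLORS.get(trace.channel, "tab:green"))
    for t, ls in ((fit.t_I_end, "--"), (fit.t_II_end, ":")):
        if t is not None:
            ax.axvline(t, color="k", ls=ls, lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("intensity (a.u.)")
    ax.set_title(f"site {fit.site_id} / {trace.channel} ({fit.status})", fontsize=9)
    figure.tight_layout()
    if path is not None:
        figure.savefig(path, dpi=120)
        plt.close(figure)
    return figure


def plot_cohort_panels(result, path=None):
    """Rate scatter, retention histogram, and phenotype fractions."""
    figure, axes = plt.subplots(1, 3, figsize=(11, 3.2))

    ax = axes[0]
    for ch, fits in sorted(result.fits.items()):
        ra = [f.r_a for f in fits if f.r_a is not None and f.r_d is not None]
        rd = [f.r_d for f in fits if f.r_a is not None and f.r_d is not None]
        ax.scatter(ra, rd, s=12, alpha=0.6, label=ch,
                   color=_CHANNEL_COLORS.get(ch))
    ax.set_xlabel("assembly rate (a.u./s)")
    ax.set_ylabel("disassembly rate (a.u./s)")
    ax.legend(fontsize=8)

    ax = axes[1]
    taus = [
        f.tau_ret
        for f in result.fits.get("late", [])
        if f.tau_ret is not None and not f.censored
    ]
    if taus:
        ax.hist(taus, bins=15, color="tab:red", alpha=0.8)
    ax.set_xlabel("late-channel retention time (s)")
    ax.set_ylabel("events")

    ax = axes[2]
    fracs = result.summary.phenotype_fractions
    if fracs:
        ax.bar(range(len(fracs)), list(fracs.values()), color="0.4")
        ax.set_xticks(range(len(fracs)))
        ax.set_xticklabels(list(fracs.keys()), rotation=30, ha="right", fontsize=7)
    ax.set_ylabel("fraction")

    figure.tight_layout()
    if path is not None:
        figure.savefig(path, dpi=120)
        plt.close(figure)
    return figure
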