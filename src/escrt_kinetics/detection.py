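"""Spot detection on reference frames and cross-channel event sites.

Budding sites are anchored on the Gag reference channel, which is imaged
only at the start and end of the record; a site is valid when its start
and end detections match within a displacement tolerance (stationarity).
Detection is difference-of-Gaussians filtering with a robust
(MAD-scaled) threshold and centre-of-mass subpixel refinement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "SpotDetection",
    "EventSite",
    "detect_spots",
    "build_event_sites",
    "colocalize",
    "DEFAULT_THRESHOLD_SNR",
    "DEFAULT_MAX_DISPLACEMENT",
    "DEFAULT_COLOC_RADIUS",
]

DEFAULT_THRESHOLD_SNR = 5.0
DEFAULT_MAX_DISPLACEMENT = 2.0
DEFAULT_COLOC_RADIUS = 2.0


@dataclass(frozen=True)
class SpotDetection:
    frame_index: int
    row: float
    col: float
    peak: float  # DoG response at the local maximum
    quality: bool = True


@dataclass
class EventSite:
    """A colocalized budding-site location shared across channels."""

    site_id: int
    row: float
    col: float
    displacement: float  # px between start and end reference detections
    status: str = "valid"  # valid | rejected
    reason: str = ""
    channel_offsets: dict = field(default_factory=dict)


def _robust_sd(x: np.ndarray) -> float:
    """SD estimate via the median absolute deviation (normal-consistent)."""
    med = np.median(x)
    return 1.4826 * float(np.median(np.abs(x - med)))


def detect_spots(
    frame: np.ndarray,
    psf_sigma: float,
    threshold_snr: float = DEFAULT_THRESHOLD_SNR,
    frame_index: int = 0,
) -> list[SpotDetection]:
    """Detect diffraction-limited spots in a single frame.

    Difference-of-Gaussians response (sigmas ``psf_sigma`` and
    ``1.6 * psf_sigma``), local maxima above
    ``threshold_snr * robust noise SD``, subpixel centroids by
    intensity-weighted centre of mass in a window of half-width
    ``ceil(3 * psf_sigma)``.  Results sorted by descending peak response.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0 or not np.all(np.isfinite(frame)):
        raise ValueError("frame must be non-empty and finite-valued")
    if np.ptp(frame) == 0:
        return []

    dog = ndimage.gaussian_filter(frame, psf_sigma) - ndimage.gaussian_filter(
        frame, 1.6 * psf_sigma
    )
    noise_sd = _robust_sd(dog)
    if noise_sd == 0:
        # noise-free image: any positive response is signal
        noise_sd = np.finfo(float).tiny
    threshold = threshold_snr * noise_sd

    is_max = dog == ndimage.maximum_filter(dog, size=3, mode="nearest")
    cand = np.argwhere(is_max & (dog > threshold))

    w = int(math.ceil(3.0 * psf_sigma))
    h, wd = frame.shape
    detections = []
    for r, c in cand:
        r0, r1 = max(r - w, 0), min(r + w + 1, h)
        c0, c1 = max(c - w, 0), min(c + w + 1, wd)
        window = frame[r0:r1, c0:c1]
        weights = np.clip(window - np.median(window), 0, None)
        total = weights.sum()
        if total <= 0:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        detections.append(
            SpotDetection(
                frame_index=frame_index,
                row=float((weights * rr).sum() / total),
                col=float((weights * cc).sum() / total),
                peak=float(dog[r, c]),
            )
        )
    detections.sort(key=lambda d: (-d.peak, d.row, d.col))
    return detections


def build_event_sites(
    gag_start: list[SpotDetection],
    gag_end: list[SpotDetection],
    max_displacement: float = DEFAULT_MAX_DISPLACEMENT,
) -> list[EventSite]:
    """Match start/end reference detections into stationary event sites.

    Greedy nearest-neighbour matching by ascending pair distance (ties
    broken by (row, col) order); each detection used at most once.  Pairs
    within ``max_displacement`` become valid sites at the start centroid;
    everything else is reported rejected with a reason.
    """
    pairs = sorted(
        (
            (math.hypot(s.row - e.row, s.col - e.col), si, ei)
            for si, s in enumerate(gag_start)
            for ei, e in enumerate(gag_end)
        ),
        key=lambda p: (p[0], gag_start[p[1]].row, gag_start[p[1]].col),
    )
    used_s: set[int] = set()
    used_e: set[int] = set()
    sites = []
    for dist, si, ei in pairs:
        if si in used_s or ei in used_e:
            continue
        used_s.add(si)
        used_e.add(ei)
        s = gag_start[si]
        if dist <= max_displacement:
            sites.append(
                EventSite(site_id=0, row=s.row, col=s.col, displacement=dist)
            )
        else:
            sites.append(
                EventSite(
                    site_id=0,
                    row=s.row,
                    col=s.col,
                    displacement=dist,
                    status="rejected",
                    reason=f"displacement {dist:.2f} px > {max_displacement} px",
                )
            )
    for si, s in enumerate(gag_start):
        if si not in used_s:
            sites.append(
                EventSite(
                    site_id=0,
                    row=s.row,
                    col=s.col,
                    displacement=math.nan,
                    status="rejected",
                    reason="no matching end-frame detection",
                )
            )
    sites.sort(key=lambda st: (st.status != "valid", st.row, st.col))
    for i, st in enumerate(sites):
        st.site_id = i
    return sites


def colocalize(
    site: EventSite,
    channel_detections: list[SpotDetection],
    radius: float = DEFAULT_COLOC_RADIUS,
) -> tuple[bool, tuple[float, float]]:
    """Whether any channel detection lies within ``radius`` of the site.

    Returns (found, (row offset, col offset)); the offset of the nearest
    detection is recorded for photometry centring (zero when not found).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    best, best_d = None, math.inf
    for det in channel_detections:
        d = math.hypot(det.row - site.row, det.col - site.col)
        if d < best_d:
            best, best_d = det, d
    if best is None or best_d > radius:
        return False, (0.0, 0.0)
    return True, (best.row - site.row, best.col - site.col)
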