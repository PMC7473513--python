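"""Image-stack container and TIFF I/O.

A :class:`MovieStack` holds one channel's time series as a float array of
shape ``(n_frames, height, width)`` together with the acquisition metadata
the downstream stages need (frame times, PSF width, background level).
Export rounds to 16-bit unsigned TIFF, one page per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["MovieStack"]


@dataclass
class MovieStack:
    """One channel's image time series plus acquisition metadata.

    Parameters
    ----------
    channel
        Channel label (e.g. ``"gag"``, ``"early"``, ``"late"``).
    data
        Float array, shape ``(n_frames, height, width)``, arbitrary units.
    frame_times
        Acquisition time of each frame in seconds (length ``n_frames``).
        Not necessarily uniformly spaced: the reference channel is imaged
        only at the start and end of the record.
    psf_sigma
        Gaussian PSF standard deviation in pixels.
    background
        Nominal background level in a.u. per pixel (camera offset +
        cellular background), used by photometry sanity checks only.
    """

    channel: str
    data: np.ndarray
    frame_times: np.ndarray
    psf_sigma: float = 1.3
    background: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("MovieStack.data must be (n_frames, H, W)")
        if len(self.frame_times) != self.data.shape[0]:
            raise ValueError(
                f"frame_times length {len(self.frame_times)} != "
                f"n_frames {self.data.shape[0]}"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def dt(self) -> float:
        """Median frame spacing in seconds (exact for uniform records)."""
        if len(self.frame_times) < 2:
            return float("nan")
        return float(np.median(np.diff(self.frame_times)))

    def to_tiff(self, path) -> None:
        """Write as multi-page uint16 TIFF (values rounded and clipped)."""
        arr = np.clip(np.round(self.data), 0, np.iinfo(np.uint16).max)
        tifffile.imwrite(path, arr.astype(np.uint16))

    @classmethod
    def from_tiff(
        cls,
        path,
        channel: str,
        frame_times: np.ndarray | None = None,
        dt: float | None = None,
        psf_sigma: float = 1.3,
        background: float = 0.0,
    ) -> "MovieStack":
        """Read a multi-page TIFF; frame times from ``frame_times`` or ``dt``."""
        data = tifffile.imread(path).astype(float)
        if data.ndim == 2:
            data = data[None]
        if frame_times is None:
            if dt is None:
                raise ValueError("provide frame_times or dt")
            frame_times = np.arange(data.shape[0]) * dt
        return cls(
            channel=channel,
            data=data,
            frame_times=np.asarray(frame_times, dtype=float),
            psf_sigma=psf_sigma,
            background=background,
        )
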