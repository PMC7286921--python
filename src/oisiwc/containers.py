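"""In-memory carriers for image stacks and block-averaged time series."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .schedule import TrialSchedule

__all__ = ["ImageStack", "BlockSeries", "PSDEstimate", "ORIGIN_ORDER"]

# Processing stages in pipeline order; each preprocessing operation tags its
# output and refuses input that is already past it in the chain.
ORIGIN_ORDER = ("raw", "registered", "fractional", "filtered", "downsampled")


@dataclass
class ImageStack:
    """A reflectance image stack (frames x height x width).

    ``origin`` records the last preprocessing stage applied; raw stacks hold
    camera counts, ``fractional`` and later stacks hold dR/R.
    """

    data: np.ndarray
    frame_rate: float
    origin: str = "raw"
    schedule: Optional[TrialSchedule] = None
    transforms: Optional[np.ndarray] = None  # per-frame (dy, dx, theta_rad)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("ImageStack.data must be frames x H x W")
        if self.data.shape[1] <= 0 or self.data.shape[2] <= 0:
            raise ValueError("image dimensions must be positive")
        if self.origin not in ORIGIN_ORDER:
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.schedule is not None:
            expected = self.schedule.duration_s * self.frame_rate
            if abs(self.n_frames - expected) > 1.5:
                raise ValueError(
                    f"stack has {self.n_frames} frames but the schedule implies "
                    f"{expected:.1f} at {self.frame_rate} Hz"
                )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def origin_rank(self) -> int:
        return ORIGIN_ORDER.index(self.origin)

    def with_data(self, data: np.ndarray, origin: str | None = None,
                  frame_rate: float | None = None, **meta) -> "ImageStack":
        return replace(
            self,
            data=data,
            origin=self.origin if origin is None else origin,
            frame_rate=self.frame_rate if frame_rate is None else frame_rate,
            meta={**self.meta, **meta},
        )


@dataclass
class BlockSeries:
    """Per-block mean time series (blocks x timepoints).

    ``block_map`` keeps the pixel rectangle (r0, r1, c0, c1) of every block
    (half-open bounds); it is None for series generated directly at block
    level by the synthetic generator.
    """

    values: np.ndarray
    sampling_rate: float
    block_map: Optional[tuple[tuple[int, int, int, int], ...]] = None
    schedule: Optional[TrialSchedule] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("BlockSeries.values must be blocks x timepoints")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.block_map is not None:
            if len(self.block_map) != self.n_blocks:
                raise ValueError("block_map length must match number of blocks")
            rects = list(self.block_map)
            sizes = {(r1 - r0, c1 - c0) for r0, r1, c0, c1 in rects}
            if len(sizes) > 1:
                raise ValueError("all block rectangles must have equal size")
            for i, a in enumerate(rects):
                for b in rects[i + 1:]:
                    if a[0] < b[1] and b[0] < a[1] and a[2] < b[3] and b[2] < a[3]:
                        raise ValueError("block rectangles must be disjoint")

    @property
    def n_blocks(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_timepoints) / self.sampling_rate

    def copy_with(self, values: np.ndarray, sampling_rate: float | None = None) -> "BlockSeries":
        return BlockSeries(
            values=values,
            sampling_rate=self.sampling_rate if sampling_rate is None else sampling_rate,
            block_map=self.block_map,
            schedule=self.schedule,
            label=self.label,
        )


@dataclass
class PSDEstimate:
    """Welch power spectral density estimate for one or more series."""

    frequencies: np.ndarray          # Hz, ascending
    power: np.ndarray                # (dR/R)^2 / Hz; (..., n_freqs)
    segment_s: float
    overlap_frac: float
    sampling_rate: float

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly ascending")
        if self.frequencies[-1] > self.sampling_rate / 2 + 1e-9:
            raise ValueError("frequencies exceed the Nyquist frequency")
        if np.any(self.power < -1e-15):
            raise ValueError("power must be non-negative")

    def peak_frequency(self, fmin: float | None = None, fmax: float | None = None) -> float:
        """Frequency of maximum power, optionally restricted to [fmin, fmax]."""
        p = self.power if self.power.ndim == 1 else self.power.mean(axis=0)
        sel = np.ones_like(self.frequencies, dtype=bool)
        if fmin is not None:
            sel &= self.frequencies >= fmin
        if fmax is not None:
            sel &= self.frequencies <= fmax
        if not sel.any():
            raise ValueError("empty frequency selection")
        idx = np.flatnonzero(sel)
        return float(self.frequencies[idx[np.argmax(p[idx])]])
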