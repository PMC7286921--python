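"""Preprocessing chain: registration, fractional reflectance, spatial
Gaussian smoothing, temporal averaging, repetition averaging, block
segmentation, and Welch PSD estimation.

The stages must be applied in pipeline order (register -> fractional ->
Gaussian -> temporal average -> repetition average -> blocks); every stage
tags the stack ``origin`` and refuses input that is already past it.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage, signal

from .containers import BlockSeries, ImageStack, PSDEstimate

__all__ = [
    "register_frames",
    "fractional_value",
    "spatial_gaussian",
    "temporal_average",
    "average_repetitions",
    "segment_blocks",
    "welch_psd",
]


# ---------------------------------------------------------------------------
# rigid registration (SimpleITK: mean-squares metric, Euler2D transform,
# multi-resolution regular-step gradient descent)


def _register_one(R, fixed, moving, initial):
    import SimpleITK as sitk

    R.SetInitialTransform(initial, inPlace=False)
    tx = R.Execute(fixed, moving)
    return tx


def register_frames(
    stack: ImageStack,
    reference_frame: int = 0,
    max_iterations: int = 150,
) -> ImageStack:
    """Rigidly align every frame to ``reference_frame``.

    Uses an iterative intensity-based optimizer (mean-squared intensity
    similarity metric, rigid translation+rotation transform, two-level
    multi-resolution regular-step gradient descent).  Frames on which the
    optimizer fails keep the identity transform and are reported in
    ``meta['registration_warnings']``.

    The returned stack carries ``transforms`` of shape (n_frames, 3) holding
    the estimated (dy, dx, theta) motion of each frame's content relative to
    the reference, i.e. the negated resampling transform; for a frame whose
    content was shifted by (dy, dx) the estimate recovers (dy, dx).
    """
    import SimpleITK as sitk

    if stack.origin != "raw":
        raise ValueError("register_frames expects a raw stack")
    if not 0 <= reference_frame < stack.n_frames:
        raise IndexError(f"reference_frame {reference_frame} out of range")

    data = np.asarray(stack.data, dtype=np.float32)
    fixed = sitk.GetImageFromArray(data[reference_frame])

    R = sitk.ImageRegistrationMethod()
    R.SetMetricAsMeanSquares()
    R.SetInterpolator(sitk.sitkLinear)
    R.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-5,
        numberOfIterations=max_iterations,
        relaxationFactor=0.6,
    )
    R.SetOptimizerScalesFromPhysicalShift()
    shrink = [2, 1] if min(stack.shape[1:]) >= 16 else [1]
    R.SetShrinkFactorsPerLevel(shrink)
    R.SetSmoothingSigmasPerLevel([1.0, 0.0] if len(shrink) == 2 else [0.0])

    center = [(s - 1) / 2.0 for s in reversed(data.shape[1:])]
    out = np.empty_like(data)
    transforms = np.zeros((stack.n_frames, 3))
    failed: list[int] = []
    for i in range(stack.n_frames):
        if i == reference_frame:
            out[i] = data[i]
            continue
        moving = sitk.GetImageFromArray(data[i])
        initial = sitk.Euler2DTransform()
        initial.SetCenter(center)
        try:
            tx = _register_one(R, fixed, moving, initial)
            out[i] = sitk.GetArrayFromImage(
                sitk.Resample(moving, fixed, tx, sitk.sitkLinear, 0.0)
            )
            pars = tx.GetParameters()  # (theta, tx_x, tx_y) in physical units
            transforms[i] = (pars[2], pars[1], pars[0])
        except RuntimeError as exc:  # pragma: no cover - optimizer failure path
            warnings.warn(f"registration failed on frame {i}: {exc}", stacklevel=2)
            failed.append(i)
            out[i] = data[i]
    meta = {"registration_reference": reference_frame}
    if failed:
        meta["registration_warnings"] = failed
    registered = stack.with_data(out, origin="registered", **meta)
    registered.transforms = transforms
    return registered


# ---------------------------------------------------------------------------


def fractional_value(stack: ImageStack, baseline: tuple[int, int]) -> ImageStack:
    """Per-pixel fractional reflectance dR/R = (R_i - R_B) / R_B.

    ``baseline`` is a half-open frame range (start, stop) preceding the
    stimulus onset; R_B is the per-pixel mean over those frames.
    """
    if stack.origin not in ("raw", "registered"):
        raise ValueError("fractional_value expects a raw or registered stack")
    b0, b1 = baseline
    if not (0 <= b0 < b1 <= stack.n_frames):
        raise ValueError(f"invalid baseline frame range {baseline}")
    if stack.schedule is not None and stack.schedule.mode == "stimulation":
        onset = stack.schedule.stim_onsets_s[0] * stack.frame_rate
        if b1 > onset + 0.5:
            raise ValueError("baseline frames must precede the first stimulus onset")
    data = np.asarray(stack.data, dtype=np.float64)
    rb = data[b0:b1].mean(axis=0)
    bad = int(np.count_nonzero(rb <= 0))
    if bad:
        raise ValueError(f"baseline mean non-positive at {bad} pixel(s)")
    out = (data - rb) / rb
    return stack.with_data(out, origin="fractional", baseline_frames=(b0, b1))


def spatial_gaussian(stack: ImageStack, kernel_px: int = 5,
                     sigma: float | None = None) -> ImageStack:
    """Per-frame 2-D Gaussian smoothing with a truncated kernel of width
    ``kernel_px`` (sigma defaults to kernel_px / 4), reflective boundaries.

    Reflective boundaries with a symmetric normalized kernel preserve each
    frame's mean exactly.
    """
    if kernel_px < 1 or kernel_px % 2 == 0:
        raise ValueError("kernel_px must be odd and >= 1")
    if stack.origin != "fractional":
        raise ValueError("spatial_gaussian expects a fractional (dR/R) stack")
    if kernel_px == 1:
        return stack.with_data(stack.data.copy(), origin="filtered",
                               gaussian_kernel_px=1)
    if sigma is None:
        sigma = kernel_px / 4.0
    radius = kernel_px // 2
    out = ndimage.gaussian_filter(
        np.asarray(stack.data, dtype=float),
        sigma=(0.0, sigma, sigma),
        truncate=radius / sigma,
        mode="reflect",
    )
    return stack.with_data(out, origin="filtered",
                           gaussian_kernel_px=kernel_px, gaussian_sigma=sigma)


def temporal_average(stack_or_series, window: int = 10):
    """Non-overlapping consecutive-sample means along time.

    The sampling rate drops by ``window``; a trailing partial window is
    dropped.  Accepts an ImageStack, a BlockSeries or a plain array (time on
    the last axis).
    """
    if window < 1:
        raise ValueError("window must be >= 1")

    def _avg(arr: np.ndarray, axis0: bool) -> np.ndarray:
        n = arr.shape[0] if axis0 else arr.shape[-1]
        if window > n:
            raise ValueError("window longer than the series")
        m = n // window
        if axis0:
            return arr[: m * window].reshape(m, window, *arr.shape[1:]).mean(axis=1)
        out = arr[..., : m * window].reshape(*arr.shape[:-1], m, window)
        return out.mean(axis=-1)

    if isinstance(stack_or_series, ImageStack):
        st = stack_or_series
        if st.origin not in ("fractional", "filtered"):
            raise ValueError("temporal_average expects a fractional or filtered stack")
        return st.with_data(_avg(np.asarray(st.data, dtype=float), True),
                            origin="downsampled", temporal_window=window,
                            frame_rate=st.frame_rate / window)
    if isinstance(stack_or_series, BlockSeries):
        bs = stack_or_series
        return bs.copy_with(_avg(bs.values, False),
                            sampling_rate=bs.sampling_rate / window)
    arr = np.asarray(stack_or_series, dtype=float)
    return _avg(arr, axis0=False)


def average_repetitions(stacks: Sequence[ImageStack] | Sequence[BlockSeries]):
    """Pointwise mean over repeated trials (identical shapes and schedules)."""
    items = list(stacks)
    if not items:
        raise ValueError("no repetitions given")
    first = items[0]
    if isinstance(first, ImageStack):
        for st in items[1:]:
            if st.shape != first.shape:
                raise ValueError("repetition shape mismatch")
            if st.origin != first.origin:
                raise ValueError("repetitions must share a processing stage")
        mean = np.mean([np.asarray(s.data, dtype=float) for s in items], axis=0)
        return first.with_data(mean, n_repetitions=len(items))
    for bs in items[1:]:
        if bs.values.shape != first.values.shape:
            raise ValueError("repetition shape mismatch")
    return first.copy_with(np.mean([s.values for s in items], axis=0))


def segment_blocks(
    stack: ImageStack,
    block_px: int = 10,
    layout: str = "grid",
    region: tuple[int, int] | None = None,
) -> BlockSeries:
    """Average pixels into block time series.

    ``grid`` tiles the whole image with ``block_px`` squares (dimensions must
    divide evenly; the error lists valid crops otherwise).  ``twelve_regions``
    is the 12-block cortex division: a 3 x 4 arrangement of ``block_px``
    squares anchored at ``region`` (default image origin).
    """
    if stack.origin == "raw":
        raise ValueError("segment_blocks expects a preprocessed (dR/R) stack")
    nf, h, w = stack.shape
    data = np.asarray(stack.data, dtype=float)

    if layout == "grid":
        if h % block_px or w % block_px:
            raise ValueError(
                f"image {h}x{w} not divisible by block_px={block_px}; "
                f"valid crops: {h - h % block_px}x{w - w % block_px}"
            )
        nr, nc = h // block_px, w // block_px
    elif layout == "twelve_regions":
        nr, nc = 3, 4
        r0, c0 = region if region is not None else (0, 0)
        if r0 + nr * block_px > h or c0 + nc * block_px > w:
            raise ValueError("twelve_regions layout does not fit the image")
    else:
        raise ValueError(f"unknown layout {layout!r}")

    if layout == "grid":
        r0 = c0 = 0
    rects = []
    series = np.empty((nr * nc, nf))
    for i in range(nr):
        for j in range(nc):
            rr0, cc0 = r0 + i * block_px, c0 + j * block_px
            rect = (rr0, rr0 + block_px, cc0, cc0 + block_px)
            rects.append(rect)
            series[i * nc + j] = data[:, rect[0]:rect[1], rect[2]:rect[3]].mean(axis=(1, 2))
    return BlockSeries(
        values=series,
        sampling_rate=stack.frame_rate,
        block_map=tuple(rects),
        schedule=stack.schedule,
    )


def welch_psd(
    series,
    sampling_rate: float | None = None,
    segment_s: float = 40.0,
    overlap_frac: float = 0.5,
    detrend: str = "constant",
) -> PSDEstimate:
    """Welch-averaged periodogram (Hann window).

    ``series`` may be a BlockSeries (sampling rate taken from it) or an array
    with time on the last axis.
    """
    if isinstance(series, BlockSeries):
        values = series.values
        sampling_rate = series.sampling_rate
    else:
        values = np.asarray(series, dtype=float)
        if sampling_rate is None:
            raise ValueError("sampling_rate required for plain arrays")
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must lie in [0, 1)")
    nperseg = int(round(segment_s * sampling_rate))
    n = values.shape[-1]
    if nperseg > n:
        raise ValueError("segment longer than the series")
    noverlap = int(nperseg * overlap_frac)
    freqs, power = signal.welch(
        values, fs=sampling_rate, nperseg=nperseg, noverlap=noverlap,
        detrend=detrend, axis=-1,
    )
    # drop the DC bin: ascending positive frequencies only
    return PSDEstimate(
        frequencies=freqs[1:],
        power=np.maximum(power[..., 1:], 0.0),
        segment_s=segment_s,
        overlap_frac=overlap_frac,
        sampling_rate=sampling_rate,
    )
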