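"""Correlation-based functional connectivity in the 0.009-0.08 Hz band.

Pipeline: temporal-component nuisance regression (tCompCor-style: principal
components of the highest-variance block series regressed out of every
block), zero-phase Butterworth band-pass, Pearson correlation between all
block pairs, Fisher z-transform and min-max normalization, and the scalar
FC strength (mean off-diagonal correlation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .containers import BlockSeries

__all__ = [
    "FCMatrix",
    "nuisance_regression",
    "bandpass",
    "pearson_fc",
    "seed_fc_map",
    "fc_pipeline",
]

BAND_LOW_HZ = 0.009
BAND_HIGH_HZ = 0.08


def nuisance_regression(
    block_series: BlockSeries,
    n_components: int = 5,
    variance_quantile: float = 0.98,
) -> BlockSeries:
    """Regress principal components of the highest-temporal-variance blocks
    out of every block series.

    Blocks with temporal variance at or above ``variance_quantile`` of the
    block-variance distribution (at least one) define the noise set; its top
    ``n_components`` principal components plus an intercept are removed by
    least squares, leaving residuals orthogonal to the regressors.
    """
    if n_components == 0:
        return block_series.copy_with(block_series.values.copy())
    if n_components < 0:
        raise ValueError("n_components must be >= 0")
    X = block_series.values
    n_t = X.shape[1]
    if n_components >= n_t:
        raise ValueError("n_components must be smaller than the series length")
    var = X.var(axis=1)
    cutoff = np.quantile(var, variance_quantile)
    noise = X[var >= cutoff]
    centered = (noise - noise.mean(axis=1, keepdims=True)).T  # time x k
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    k = min(n_components, int(np.sum(s > 1e-12 * s.max()))) if s.size else 0
    design = np.column_stack([np.ones(n_t), u[:, :k]])
    beta, *_ = np.linalg.lstsq(design, X.T, rcond=None)
    resid = X.T - design @ beta
    return block_series.copy_with(resid.T)


def bandpass(
    series,
    sampling_rate: float | None = None,
    low: float = BAND_LOW_HZ,
    high: float = BAND_HIGH_HZ,
    order: int = 3,
):
    """Zero-phase Butterworth band-pass (applied forward and backward).

    Accepts a BlockSeries or an array with time on the last axis.
    """
    if isinstance(series, BlockSeries):
        out = bandpass(series.values, series.sampling_rate, low, high, order)
        return series.copy_with(out)
    x = np.asarray(series, dtype=float)
    if sampling_rate is None:
        raise ValueError("sampling_rate required for plain arrays")
    nyq = sampling_rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError("need 0 < low < high < Nyquist")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=sampling_rate,
                        output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.shape[-1] <= padlen:
        raise ValueError(
            f"series too short ({x.shape[-1]} samples) for the requested band"
        )
    return signal.sosfiltfilt(sos, x, axis=-1)


@dataclass
class FCMatrix:
    """Pairwise Pearson functional connectivity between blocks."""

    raw_r: np.ndarray
    fisher_z: np.ndarray
    normalized: np.ndarray
    strength: float                    # mean off-diagonal raw r
    strength_fisher: float
    strength_normalized: float
    undefined_blocks: tuple[int, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        n = self.raw_r.shape[0]
        cols = [f"b{i:02d}" for i in range(n)]
        return pd.DataFrame(self.raw_r, index=cols, columns=cols)


def pearson_fc(block_series: BlockSeries) -> FCMatrix:
    """Pearson correlation FC with Fisher z and [0, 1] min-max rescaling.

    Constant blocks get NaN rows/columns and are reported in
    ``undefined_blocks``; |r| is clipped to 1 - 1e-12 before atanh.
    """
    X = block_series.values
    if X.shape[0] < 2:
        raise ValueError("at least 2 blocks required")
    sd = X.std(axis=1)
    undefined = tuple(int(i) for i in np.flatnonzero(sd == 0))
    if undefined:
        warnings.warn(f"constant blocks {undefined}: correlations undefined",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    r = (r + r.T) / 2.0          # exact symmetry despite float rounding
    for i in undefined:
        r[i, :] = np.nan
        r[:, i] = np.nan
    np.fill_diagonal(r, np.where(sd == 0, np.nan, 1.0))

    off = ~np.eye(r.shape[0], dtype=bool)
    z = np.zeros_like(r)
    clipped = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    z[off] = np.arctanh(clipped[off])
    np.fill_diagonal(z, np.nan)

    finite = np.isfinite(z) & off
    if finite.any():
        zmin, zmax = z[finite].min(), z[finite].max()
        span = zmax - zmin
        norm = (z - zmin) / span if span > 0 else np.where(np.isfinite(z), 0.5, np.nan)
    else:
        norm = np.full_like(z, np.nan)

    valid_off = np.isfinite(r) & off
    strength = float(np.mean(r[valid_off])) if valid_off.any() else np.nan
    return FCMatrix(
        raw_r=r,
        fisher_z=z,
        normalized=norm,
        strength=strength,
        strength_fisher=float(np.nanmean(z[off])) if finite.any() else np.nan,
        strength_normalized=float(np.nanmean(norm[off])) if finite.any() else np.nan,
        undefined_blocks=undefined,
    )


def seed_fc_map(block_series: BlockSeries, seed_block: int) -> np.ndarray:
    """Correlation of every block with the seed block (row of raw_r)."""
    if not 0 <= seed_block < block_series.n_blocks:
        raise IndexError(f"seed block {seed_block} out of range")
    return pearson_fc(block_series).raw_r[seed_block]


def fc_pipeline(
    block_series: BlockSeries,
    n_components: int = 5,
    variance_quantile: float = 0.98,
    low: float = BAND_LOW_HZ,
    high: float = BAND_HIGH_HZ,
) -> FCMatrix:
    """Nuisance regression -> band-pass -> Pearson FC."""
    cleaned = nuisance_regression(block_series, n_components, variance_quantile)
    filtered = bandpass(cleaned)
    return pearson_fc(filtered)
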