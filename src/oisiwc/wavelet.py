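"""Morlet continuous wavelet transform, cross-wavelet transform, smoothed
wavelet coherence, cone of influence and Monte-Carlo significance.

Conventions
-----------
The mother wavelet is the analytic Morlet wavelet with dimensionless central
frequency ``omega0`` (default 6), whose Fourier transform is
``pi**-0.25 * H(w) * exp(-(s*w - omega0)**2 / 2)``.  The Fourier frequency of
scale ``s`` is ``(omega0 + sqrt(2 + omega0**2)) / (4 * pi * s)``; for
omega0 = 6 one scale unit corresponds to a Fourier period of ~1.033 s.  The
CWT is evaluated in the Fourier domain (series zero-padded to the next power
of two), which equals direct time-domain convolution with the sampled
wavelet to numerical precision.  The cone of influence is the ``sqrt(2)*s``
e-folding distance from either edge.

Coherence smoothing is a Gaussian in time of width equal to the scale,
applied in the frequency domain, followed by a boxcar over 0.6/dj scale
bins (the Morlet scale-decorrelation length).  The time smoothing is
edge-normalized (divided by the smoothed indicator), which preserves
constant fields exactly and cancels identically in the coherence ratio.

Significance of coherence is assessed against Monte-Carlo surrogate pairs
of AR(1) processes with lag-1 autocorrelation matched to the data, using a
pointwise per-scale null quantile.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ScaleGrid",
    "WaveletSpectrum",
    "CrossSpectrum",
    "CoherenceMap",
    "SignificanceResult",
    "build_scale_grid",
    "morlet_fourier_normalized",
    "cwt",
    "xwt",
    "smooth",
    "wavelet_coherence",
    "mc_significance",
    "phase_summary",
    "arrow_components",
    "fit_ar1",
]


def fourier_factor(omega0: float) -> float:
    """Fourier period per unit scale for the Morlet wavelet."""
    return 4.0 * math.pi / (omega0 + math.sqrt(2.0 + omega0 * omega0))


@dataclass(frozen=True)
class ScaleGrid:
    """Dyadic wavelet-scale grid s_j = s0 * 2**(j*dj)."""

    scales: np.ndarray            # seconds, strictly increasing
    fourier_freqs: np.ndarray     # Hz, strictly decreasing
    dj: float
    s0: float
    omega0: float
    sampling_rate: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be strictly increasing")
        if np.any(np.diff(self.fourier_freqs) >= 0):
            raise ValueError("fourier_freqs must be strictly decreasing")

    @property
    def n_scales(self) -> int:
        return len(self.scales)

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def cache_key(self) -> tuple:
        return (round(self.s0, 12), round(self.dj, 12), self.n_scales,
                round(self.omega0, 12), round(self.sampling_rate, 9))


def build_scale_grid(
    sampling_rate: float,
    fmin: float = 0.05,
    fmax: float = 4.5,
    dj: float = 1.0 / 12.0,
    omega0: float = 6.0,
) -> ScaleGrid:
    """Dyadic scale grid whose Fourier frequencies span [fmin, fmax]."""
    nyquist = sampling_rate / 2.0
    if fmax > nyquist + 1e-12:
        raise ValueError(f"fmax={fmax} exceeds the Nyquist frequency {nyquist}")
    if not 0 < fmin <= fmax:
        raise ValueError("need 0 < fmin <= fmax")
    ff = fourier_factor(omega0)
    s0 = 1.0 / (ff * fmax)
    n_octaves = math.log2(fmax / fmin)
    J = int(math.ceil(n_octaves / dj - 1e-9))
    scales = s0 * 2.0 ** (dj * np.arange(J + 1))
    freqs = 1.0 / (ff * scales)
    return ScaleGrid(scales=scales, fourier_freqs=freqs, dj=dj, s0=s0,
                     omega0=omega0, sampling_rate=sampling_rate)


def morlet_fourier_normalized(
    s: float, omega: np.ndarray, dt: float, omega0: float = 6.0
) -> np.ndarray:
    """Energy-normalized Fourier transform of the Morlet wavelet at scale s.

    Zero for omega <= 0 (analytic wavelet); the peak of the un-normalized
    shape is pi**-0.25 at s*omega = omega0, and the normalization makes
    sum_k |psi_hat(s w_k)|**2 ~= N for scales inside the resolvable band.
    """
    if s <= 0:
        raise ValueError("scale must be positive")
    omega = np.asarray(omega, dtype=float)
    norm = math.sqrt(2.0 * math.pi * s / dt) * math.pi ** -0.25
    out = np.zeros_like(omega)
    pos = omega > 0
    out[pos] = norm * np.exp(-0.5 * (s * omega[pos] - omega0) ** 2)
    return out


# ---------------------------------------------------------------------------
# cached per-(grid, N) FFT plan


def _next_pow2(n: int) -> int:
    return 1 << (int(n - 1).bit_length())


class _Plan:
    """Precomputed wavelet filters and smoothing multipliers for (grid, N)."""

    def __init__(self, grid: ScaleGrid, n: int):
        dt = grid.dt
        smax = grid.scales[-1]
        # margin of >= 5 e-foldings of the largest scale keeps circular
        # wrap-around below ~4e-6 relative at the outermost scale
        npad = _next_pow2(n)
        while npad < n + 5.0 * smax / dt:
            npad *= 2
        self.n = n
        self.npad = npad
        omega = 2.0 * math.pi * np.fft.fftfreq(npad, d=dt)
        self.psi = np.empty((grid.n_scales, npad))
        for j, s in enumerate(grid.scales):
            self.psi[j] = morlet_fourier_normalized(s, omega, dt, grid.omega0)
        # time-smoothing Gaussian multipliers exp(-(s w)^2 / 2), unit DC gain
        self.gauss = np.exp(-0.5 * (grid.scales[:, None] * omega[None, :]) ** 2)
        # smoothed indicator for edge normalization of the time smoothing
        ones = np.zeros(npad)
        ones[:n] = 1.0
        sm = np.fft.ifft(np.fft.fft(ones)[None, :] * self.gauss, axis=1).real[:, :n]
        self.norm = np.maximum(sm, 1e-12)
        # cone of influence: largest valid scale per timepoint (seconds)
        edge = np.minimum(np.arange(n), np.arange(n)[::-1]) * dt
        self.coi_scale = edge / math.sqrt(2.0)
        # fractional boxcar over scales, half-width 0.3/dj bins
        half = 0.6 / grid.dj / 2.0
        m = int(math.ceil(half - 0.5))
        offs = np.arange(-m, m + 1)
        w = np.clip(half - (np.abs(offs) - 0.5), 0.0, 1.0)
        self.box = w / w.sum()


_PLANS: dict[tuple, _Plan] = {}


def _get_plan(grid: ScaleGrid, n: int) -> _Plan:
    key = (grid.cache_key(), n)
    plan = _PLANS.get(key)
    if plan is None:
        if len(_PLANS) > 32:
            _PLANS.clear()
        plan = _PLANS[key] = _Plan(grid, n)
    return plan


# ---------------------------------------------------------------------------
# transforms


@dataclass
class WaveletSpectrum:
    """Complex CWT coefficients over scales x timepoints."""

    W: np.ndarray
    grid: ScaleGrid
    dt: float
    n: int
    coi_scale: np.ndarray         # per-timepoint largest valid scale (s)

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.W) ** 2

    def coi_mask(self) -> np.ndarray:
        """Boolean (scales x time), True where the estimate is inside the COI
        (i.e. unaffected by edges)."""
        return self.grid.scales[:, None] <= self.coi_scale[None, :]


def _cwt_array(x: np.ndarray, grid: ScaleGrid, plan: _Plan) -> np.ndarray:
    xpad = np.zeros(plan.npad)
    xpad[: plan.n] = x
    xhat = np.fft.fft(xpad)
    return np.fft.ifft(xhat[None, :] * np.conj(plan.psi), axis=1)[:, : plan.n]


def _standardize(x: np.ndarray, detrend: bool, standardize: bool) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if detrend:
        t = np.arange(len(x))
        x = x - np.polyval(np.polyfit(t, x, 1), t)
    else:
        x = x - x.mean()
    if standardize:
        sd = x.std()
        if sd > 0:
            x = x / sd
    return x


def cwt(
    series: np.ndarray,
    grid: ScaleGrid,
    detrend: bool = True,
    standardize: bool = True,
) -> WaveletSpectrum:
    """Continuous Morlet wavelet transform via the Fourier domain."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 8:
        raise ValueError("series must be 1-D with at least 8 samples")
    if x.std() == 0:
        warnings.warn("constant series: returning an all-zero spectrum", stacklevel=2)
        plan = _get_plan(grid, len(x))
        return WaveletSpectrum(
            W=np.zeros((grid.n_scales, len(x)), dtype=complex),
            grid=grid, dt=grid.dt, n=len(x), coi_scale=plan.coi_scale,
        )
    x = _standardize(x, detrend, standardize)
    plan = _get_plan(grid, len(x))
    W = _cwt_array(x, grid, plan)
    return WaveletSpectrum(W=W, grid=grid, dt=grid.dt, n=len(x),
                           coi_scale=plan.coi_scale)


@dataclass
class CrossSpectrum:
    """Cross-wavelet transform W^M * conj(W^N)."""

    W: np.ndarray
    grid: ScaleGrid
    coi_scale: np.ndarray

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.W)

    @property
    def phase(self) -> np.ndarray:
        """Relative phase in (-pi, pi]; positive when the first series leads."""
        return np.angle(self.W)


def xwt(wm: WaveletSpectrum, wn: WaveletSpectrum) -> CrossSpectrum:
    """Cross-wavelet transform of two spectra on the same grid."""
    if wm.grid.cache_key() != wn.grid.cache_key() or wm.n != wn.n:
        raise ValueError("wavelet spectra must share scale grid and length")
    return CrossSpectrum(W=wm.W * np.conj(wn.W), grid=wm.grid,
                         coi_scale=wm.coi_scale)


# ---------------------------------------------------------------------------
# smoothing and coherence


def _smooth_time(field: np.ndarray, plan: _Plan) -> np.ndarray:
    npad, n = plan.npad, plan.n
    pad = np.zeros((field.shape[0], npad), dtype=complex)
    pad[:, :n] = field
    st = np.fft.ifft(np.fft.fft(pad, axis=1) * plan.gauss, axis=1)[:, :n]
    st /= plan.norm
    return st


def _smooth_scale(st: np.ndarray, box: np.ndarray,
                  cols: np.ndarray | None = None) -> np.ndarray:
    if cols is not None:
        st = st[:, cols]
    m = (len(box) - 1) // 2
    out = np.zeros_like(st)
    wsum = np.zeros(st.shape[0])
    for k, w in zip(range(-m, m + 1), box):
        lo, hi = max(0, -k), min(st.shape[0], st.shape[0] - k)
        out[lo:hi] += w * st[lo + k:hi + k]
        wsum[lo:hi] += w
    out /= wsum[:, None]
    return out


def _smooth_field(field: np.ndarray, grid: ScaleGrid, plan: _Plan) -> np.ndarray:
    return _smooth_scale(_smooth_time(field, plan), plan.box)


def smooth(field: np.ndarray, grid: ScaleGrid, n: int | None = None) -> np.ndarray:
    """Smoothing operator: Gaussian in time (width = scale) then a 0.6/dj
    boxcar along scales.  Preserves constant fields exactly; linear."""
    field = np.asarray(field)
    if field.ndim != 2 or field.shape[0] != grid.n_scales:
        raise ValueError("field must be scales x timepoints")
    if not np.all(np.isfinite(field)):
        raise ValueError("field must be finite")
    plan = _get_plan(grid, field.shape[1] if n is None else n)
    out = _smooth_field(field.astype(complex), grid, plan)
    return out.real if np.isrealobj(field) else out


@dataclass
class CoherenceMap:
    """Smoothed wavelet coherence R^2 over scales x timepoints."""

    r2: np.ndarray
    phase: np.ndarray
    grid: ScaleGrid
    sampling_rate: float
    coi_scale: np.ndarray
    sig_mask: Optional[np.ndarray] = None
    sig_threshold: Optional[np.ndarray] = None     # per scale
    params: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.r2.shape[1]) / self.sampling_rate

    def coi_mask(self) -> np.ndarray:
        return self.grid.scales[:, None] <= self.coi_scale[None, :]


def _coherence_arrays(
    xm: np.ndarray,
    xn: np.ndarray,
    grid: ScaleGrid,
    plan: _Plan,
    cols: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Coherence R^2 and phase; with ``cols`` only those time columns are
    scale-smoothed and returned (used by the Monte-Carlo surrogate loop).

    The two real auto-power fields are packed into one complex field: the
    smoothing kernels are real, so smoothing commutes with the packing.
    """
    wm = _cwt_array(xm, grid, plan)
    wn = _cwt_array(xn, grid, plan)
    sinv = 1.0 / grid.scales[:, None]
    cross = wm * np.conj(wn) * sinv
    autos = (np.abs(wm) ** 2 + 1j * np.abs(wn) ** 2) * sinv
    num = _smooth_scale(_smooth_time(cross, plan), plan.box, cols)
    sm_autos = _smooth_scale(_smooth_time(autos, plan), plan.box, cols)
    denom = sm_autos.real * sm_autos.imag
    tiny = denom <= 1e-300
    denom[tiny] = 1.0
    r2 = np.abs(num) ** 2 / denom
    r2[tiny] = 0.0
    phase = np.angle(num)
    return r2, phase


def wavelet_coherence(
    m: np.ndarray,
    n: np.ndarray,
    grid: ScaleGrid,
    detrend: bool = True,
) -> CoherenceMap:
    """Smoothed Morlet wavelet coherence of two equal-length series.

    R^2 lies in [0, 1] (Cauchy-Schwarz, positive smoothing weights); the
    phase field is the argument of the smoothed cross term, positive when
    the first series leads.
    """
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    if m.shape != n.shape or m.ndim != 1:
        raise ValueError("series must be 1-D and equal length")
    xm = _standardize(m, detrend, True)
    xn = _standardize(n, detrend, True)
    plan = _get_plan(grid, len(m))
    r2, phase = _coherence_arrays(xm, xn, grid, plan)
    return CoherenceMap(
        r2=r2, phase=phase, grid=grid, sampling_rate=grid.sampling_rate,
        coi_scale=plan.coi_scale,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo significance


def fit_ar1(x: np.ndarray) -> float:
    """Lag-1 autocorrelation of a demeaned series, clipped to |phi| <= 0.99."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    denom = float(np.dot(x, x))
    phi = float(np.dot(x[:-1], x[1:]) / denom) if denom > 0 else 0.0
    if abs(phi) >= 1.0:
        warnings.warn("|phi| >= 1 estimated; clipping to 0.99", stacklevel=2)
        phi = math.copysign(0.99, phi)
    return phi


@dataclass
class SignificanceResult:
    mask: np.ndarray              # scales x time, True = significant
    threshold: np.ndarray         # per-scale R^2 threshold
    level: float
    n_surrogates: int
    phi: tuple[float, float]


def mc_significance(
    m: np.ndarray,
    n: np.ndarray,
    grid: ScaleGrid,
    n_surrogates: int = 300,
    level: float = 0.05,
    seed: int | None = None,
    coi_filter: bool = True,
    r2: np.ndarray | None = None,
) -> SignificanceResult:
    """Monte-Carlo significance of wavelet coherence against AR(1) noise.

    Fits phi to each input by lag-1 autocorrelation, simulates
    ``n_surrogates`` independent AR(1) pairs of the same length, and takes
    the per-scale (1 - level) quantile of their coherence inside the COI as
    the pointwise threshold.
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    m = np.asarray(m, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    if m.shape != n_arr.shape:
        raise ValueError("series must have equal length")
    npts = len(m)
    phi_m, phi_n = fit_ar1(m), fit_ar1(n_arr)
    plan = _get_plan(grid, npts)
    inside = grid.scales[:, None] <= plan.coi_scale[None, :]

    rng = np.random.default_rng(seed)
    from scipy.signal import lfilter

    # subsample times (coherence is heavily autocorrelated in time)
    stride = max(1, npts // 64)
    cols = np.arange(0, npts, stride)
    inside_cols = inside[:, cols]
    samples: list[np.ndarray] = []
    for _ in range(n_surrogates):
        a = lfilter([1.0], [1.0, -phi_m], rng.standard_normal(npts + 50))[50:]
        b = lfilter([1.0], [1.0, -phi_n], rng.standard_normal(npts + 50))[50:]
        r2s, _ = _coherence_arrays(_standardize(a, True, True),
                                   _standardize(b, True, True), grid, plan,
                                   cols=cols)
        sub = r2s.copy()
        sub[~inside_cols] = np.nan
        samples.append(sub)
    pool = np.concatenate(samples, axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        threshold = np.nanquantile(pool, 1.0 - level, axis=1)
    # scales with no in-COI samples (longest scales of short series)
    threshold = np.where(np.isfinite(threshold), threshold, np.inf)

    if r2 is None:
        r2, _ = _coherence_arrays(_standardize(m, True, True),
                                  _standardize(n_arr, True, True), grid, plan)
    mask = r2 > threshold[:, None]
    if coi_filter:
        mask &= inside
    return SignificanceResult(mask=mask, threshold=threshold, level=level,
                              n_surrogates=n_surrogates, phi=(phi_m, phi_n))


# ---------------------------------------------------------------------------
# phase conventions


def arrow_components(phase: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(u, v) phase-arrow components for plotting.

    Right (u=1) is in-phase, left anti-phase; a downward arrow (v=-1) means
    the first series leads by 90 degrees, upward that it lags by 90 degrees.
    The cross-spectrum phase is +pi/2 when the first series leads, so the
    arrow angle is the negated phase.
    """
    phase = np.asarray(phase)
    return np.cos(phase), -np.sin(phase)


def phase_summary(
    cmap: CoherenceMap,
    time_range: tuple[float, float],
    freq_range: tuple[float, float],
) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Circular-mean phase over a time-frequency rectangle plus the arrow
    field (u, v) of that region."""
    t = cmap.times
    f = cmap.grid.fourier_freqs
    tsel = (t >= time_range[0]) & (t <= time_range[1])
    fsel = (f >= freq_range[0]) & (f <= freq_range[1])
    if not tsel.any() or not fsel.any():
        raise ValueError("empty time-frequency region")
    region = cmap.phase[np.ix_(fsel, tsel)]
    mean_angle = float(np.angle(np.exp(1j * region).mean()))
    return mean_angle, arrow_components(region)
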