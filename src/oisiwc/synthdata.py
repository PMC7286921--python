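"""Ground-truthed synthetic two-hemisphere OISi data.

The generator emulates the statistical structure the analysis pipeline
assumes: a tri-phasic stimulus-evoked dR/R response on a configurable set of
active blocks, narrowband physiological oscillators near 0.12, 0.34, 1.67 and
4.35 Hz with a tunable inter-block coupling per frequency band, a partially
shared AR(1) physiological background, shot noise at the camera, optional
rigid motion, and a "stroke" hemisphere degraded in amplitude, latency,
responsive area and coupling relative to the "healthy" one.

Oscillators are AR(2) stochastic resonators (unit variance, fractional
linewidth ``component_bandwidth``) rather than pure tones: a Morlet wavelet
at 4.35 Hz only resolves a bandwidth of roughly f/6, so independent pure
tones would be indistinguishable from perfectly coupled ones and the
injected coupling could never be recovered.  Narrow linewidths
(bandwidth ~0.02) turn the components into sharp spectral lines for PSD
recovery studies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import ndimage, signal

from .containers import BlockSeries, ImageStack
from .schedule import TrialSchedule, make_trial_schedule

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "make_trial_schedule",
    "evoked_waveform",
    "physiological_background",
    "generate_block_dataset",
    "generate_dataset",
    "COMPONENT_FREQS",
]

#: Physiological component frequencies (Hz): band IV (neurogenic), band III
#: (myogenic), band II (respiratory), band I (cardiac).
COMPONENT_FREQS = (0.12, 0.34, 1.67, 4.35)

HEMISPHERES = ("healthy", "stroke")


def _per_hemisphere(value) -> dict:
    if isinstance(value, Mapping):
        d = dict(value)
        missing = set(HEMISPHERES) - set(d)
        if missing:
            raise ValueError(f"missing hemisphere entries: {sorted(missing)}")
        return d
    return {h: value for h in HEMISPHERES}


@dataclass
class SynthConfig:
    """Parameters of the synthetic two-hemisphere experiment.

    Amplitudes are dR/R.  Defaults follow the acquisition described for the
    experiment this package analyses: 100 fps imaging, 9 stimulation epochs,
    oscillators at 0.12/0.34/1.67/4.35 Hz.  Response amplitudes (~0.4% initial
    dip) and oscillator amplitudes (~0.05%) are typical intrinsic-signal
    magnitudes; the stroke hemisphere halves the amplitude, delays the dip by
    0.5 s, halves the responsive area and weakens coupling from 0.8 to 0.3.
    """

    frame_rate: float = 100.0
    image_size: tuple[int, int] = (30, 40)          # per hemisphere (H, W)
    n_stim_epochs: int = 9
    component_freqs: tuple[float, ...] = COMPONENT_FREQS
    component_amps: tuple[float, ...] = (5e-4, 5e-4, 5e-4, 5e-4)
    component_bandwidth: float = 0.15               # fractional FWHM of each line
    coupling: dict = field(default_factory=lambda: {
        "healthy": (0.8, 0.8, 0.8, 0.8),
        "stroke": (0.3, 0.3, 0.3, 0.3),
    })
    noise_coupling: dict = field(default_factory=lambda: {"healthy": 0.8, "stroke": 0.3})
    response_amp: dict = field(default_factory=lambda: {"healthy": 4e-3, "stroke": 2e-3})
    response_latency: dict = field(default_factory=lambda: {"healthy": 1.5, "stroke": 2.0})
    active_blocks: dict = field(default_factory=lambda: {
        "healthy": tuple(range(12)),
        "stroke": tuple(range(6)),
    })
    n_blocks: int = 12
    block_px: int = 10
    ar1_phi: float = 0.7
    noise_sd: float = 2e-4
    shot_noise_scale: float = 1.0                    # 0 disables shot noise
    baseline_counts: float = 10000.0                 # camera counts at rest
    motion_amplitude: float = 0.0                    # pixels (0 disables motion)
    emulate_binning: bool = False                    # generate at 2x and 2x2 block-sum
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.coupling = {h: tuple(v) for h, v in _per_hemisphere(self.coupling).items()}
        self.noise_coupling = _per_hemisphere(self.noise_coupling)
        self.response_amp = _per_hemisphere(self.response_amp)
        self.response_latency = _per_hemisphere(self.response_latency)
        self.active_blocks = {h: tuple(v) for h, v in _per_hemisphere(self.active_blocks).items()}
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_stim_epochs < 1:
            raise ValueError("n_stim_epochs must be >= 1")
        if len(self.component_amps) != len(self.component_freqs):
            raise ValueError("component_amps must match component_freqs")
        for f in self.component_freqs:
            if not 0 < f < self.frame_rate / 2:
                raise ValueError("component frequencies must lie below Nyquist")
        for h in HEMISPHERES:
            cs = self.coupling[h]
            if len(cs) != len(self.component_freqs):
                raise ValueError("one coupling per component frequency required")
            if any(not 0 <= c <= 1 for c in cs):
                raise ValueError("coupling must lie in [0, 1]")
            if not 0 <= self.noise_coupling[h] <= 1:
                raise ValueError("noise_coupling must lie in [0, 1]")
            if any(not 0 <= b < self.n_blocks for b in self.active_blocks[h]):
                raise ValueError("active block index out of range")
        if not -1 < self.ar1_phi < 1:
            raise ValueError("ar1_phi must lie in (-1, 1)")
        h, w = self.image_size
        if h % self.block_px or w % self.block_px:
            raise ValueError("image_size must be divisible by block_px")
        if (h // self.block_px) * (w // self.block_px) != self.n_blocks:
            raise ValueError("image_size / block_px must yield n_blocks blocks")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Injected parameters, kept for parameter-recovery oracles."""

    response_amp: dict
    response_latency: dict
    active_blocks: dict
    coupling: dict
    noise_coupling: dict
    schedule: TrialSchedule
    motion: dict = field(default_factory=dict)       # hemi -> (n_frames, 3) dy,dx,theta
    config: SynthConfig | None = None

    def to_dict(self) -> dict:
        return {
            "response_amp": self.response_amp,
            "response_latency": self.response_latency,
            "active_blocks": {h: list(v) for h, v in self.active_blocks.items()},
            "coupling": {h: list(v) for h, v in self.coupling.items()},
            "noise_coupling": self.noise_coupling,
            "schedule": self.schedule.to_dict(),
            "motion": {h: np.asarray(m).tolist() for h, m in self.motion.items()},
            "config": self.config.to_dict() if self.config is not None else None,
        }


# ---------------------------------------------------------------------------
# evoked response


def _gamma_kernel(tau: np.ndarray, peak: float, shape: float) -> np.ndarray:
    """Gamma-density bump, peak value 1 at ``tau = peak``; zero for tau <= 0."""
    theta = peak / (shape - 1.0)
    out = np.zeros_like(tau, dtype=float)
    pos = tau > 0
    tp = tau[pos] / theta
    logk = (shape - 1.0) * np.log(tp) - tp
    logk -= (shape - 1.0) * math.log(shape - 1.0) - (shape - 1.0)
    out[pos] = np.exp(logk)
    return out


def evoked_waveform(
    t: np.ndarray,
    amp: float,
    latency: float,
    onset: float = 0.0,
    overshoot_frac: float = 0.35,
    overshoot_delay: float = 3.5,
    undershoot_frac: float = 0.15,
    undershoot_delay: float = 8.0,
    shape: float = 4.0,
) -> np.ndarray:
    """Tri-phasic stimulus-evoked dR/R waveform on the time grid ``t``.

    The initial dip is a gamma-density bump with extremum exactly ``-amp``
    at ``onset + latency``; the later two phases (positive rebound, smaller
    late undershoot) are gamma bumps shifted to start at the dip extremum so
    they cannot displace it.  Zero before ``onset``.  Linear in ``amp``.
    """
    t = np.asarray(t, dtype=float)
    if not np.isfinite(amp) or not np.isfinite(latency):
        raise ValueError("amp and latency must be finite")
    if amp == 0:
        return np.zeros_like(t)
    if latency <= 0:
        raise ValueError("latency must be positive")
    span = t.max() - onset if t.size else 0.0
    if latency > span:
        raise ValueError("latency lies outside the covered epoch window")

    tau = t - onset
    w = -amp * _gamma_kernel(tau, latency, shape)
    w += amp * overshoot_frac * _gamma_kernel(tau - latency, overshoot_delay, shape)
    w -= amp * undershoot_frac * _gamma_kernel(tau - latency - overshoot_delay,
                                               undershoot_delay, shape)
    return w


# ---------------------------------------------------------------------------
# stochastic background


def _resonator(rng: np.random.Generator, n: int, fs: float,
               freq: float, rel_bw: float) -> np.ndarray:
    """Unit-variance AR(2) resonator: spectral line at ``freq`` with
    fractional FWHM ``rel_bw``."""
    hwhm = max(rel_bw * freq / 2.0, 1e-6)
    r = math.exp(-math.pi * hwhm / fs)
    a1, a2 = 2.0 * r * math.cos(2.0 * math.pi * freq / fs), -r * r
    burn = min(int(5.0 / (1.0 - r)) + 1, 30000)
    e = rng.standard_normal(n + burn)
    x = signal.lfilter([1.0], [1.0, -a1, -a2], e)[burn:]
    sd = x.std()
    return x / sd if sd > 0 else x


def _ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Unit-variance AR(1) series."""
    burn = 200
    e = rng.standard_normal(n + burn)
    x = signal.lfilter([1.0], [1.0, -phi], e)[burn:]
    x *= math.sqrt(1.0 - phi * phi)
    return x


def make_shared_drivers(
    rng: np.random.Generator, n: int, config: SynthConfig
) -> dict:
    """Draw one shared unit-variance driver per component band plus a shared
    AR(1) background for one hemisphere."""
    fs = config.frame_rate
    return {
        "components": [
            _resonator(rng, n, fs, f, config.component_bandwidth)
            for f in config.component_freqs
        ],
        "ar1": _ar1(rng, n, config.ar1_phi),
    }


def physiological_background(
    n: int,
    config: SynthConfig,
    shared_drivers: dict,
    rng: np.random.Generator,
    hemisphere: str = "healthy",
) -> BlockSeries:
    """Per-block physiological background at the native frame rate.

    Each block receives, per component band ``b`` with coupling ``c_b``,
    ``amp_b * (sqrt(c_b) * shared_b + sqrt(1 - c_b) * private_b)`` plus a
    partially shared AR(1) noise floor scaled by ``noise_sd``.
    """
    comps = shared_drivers["components"]
    if len(comps) != len(config.component_freqs):
        raise ValueError("need one shared driver per component frequency")
    fs = config.frame_rate
    couplings = config.coupling[hemisphere]
    cn = config.noise_coupling[hemisphere]
    out = np.zeros((config.n_blocks, n))
    for b, (f, amp, c) in enumerate(
        zip(config.component_freqs, config.component_amps, couplings)
    ):
        shared = comps[b][:n]
        for blk in range(config.n_blocks):
            private = _resonator(rng, n, fs, f, config.component_bandwidth)
            out[blk] += amp * (math.sqrt(c) * shared + math.sqrt(1.0 - c) * private)
    if config.noise_sd > 0:
        shared_ar = shared_drivers["ar1"][:n]
        for blk in range(config.n_blocks):
            private = _ar1(rng, n, config.ar1_phi)
            out[blk] += config.noise_sd * (
                math.sqrt(cn) * shared_ar + math.sqrt(1.0 - cn) * private
            )
    return BlockSeries(values=out, sampling_rate=fs, label=f"{hemisphere}-background")


# ---------------------------------------------------------------------------
# dataset assembly


def _block_signals(
    config: SynthConfig,
    schedule: TrialSchedule,
    rng: np.random.Generator,
    hemisphere: str,
) -> np.ndarray:
    n = schedule.n_frames
    t = np.arange(n) / config.frame_rate
    drivers = make_shared_drivers(rng, n, config)
    bg = physiological_background(n, config, drivers, rng, hemisphere)
    sig = bg.values.copy()
    if schedule.mode == "stimulation":
        amp = config.response_amp[hemisphere]
        lat = config.response_latency[hemisphere]
        evoked = np.zeros(n)
        for onset in schedule.stim_onsets_s:
            evoked += evoked_waveform(t, amp, lat, onset=onset)
        for blk in config.active_blocks[hemisphere]:
            sig[blk] += evoked
    return sig


def generate_block_dataset(
    config: SynthConfig,
    mode: Literal["stimulation", "resting"] = "stimulation",
) -> tuple[BlockSeries, BlockSeries, TrialSchedule, GroundTruth]:
    """Fast path: block-level dR/R series for both hemispheres at the native
    frame rate, without pixel painting, motion or shot noise."""
    rng = np.random.default_rng(config.rng_seed)
    schedule = make_trial_schedule(config.n_stim_epochs, config.frame_rate, mode)
    series = {}
    for hemi in HEMISPHERES:
        vals = _block_signals(config, schedule, rng, hemi)
        series[hemi] = BlockSeries(
            values=vals,
            sampling_rate=config.frame_rate,
            schedule=schedule,
            label=hemi,
        )
    truth = GroundTruth(
        response_amp=dict(config.response_amp),
        response_latency=dict(config.response_latency),
        active_blocks=dict(config.active_blocks),
        coupling=dict(config.coupling),
        noise_coupling=dict(config.noise_coupling),
        schedule=schedule,
        config=config,
    )
    return series["healthy"], series["stroke"], schedule, truth


def _smooth_random_walk(rng: np.random.Generator, n: int, amplitude: float,
                        smooth_frames: float = 50.0) -> np.ndarray:
    x = ndimage.gaussian_filter1d(rng.standard_normal(n), smooth_frames, mode="reflect")
    peak = np.abs(x).max()
    return x * (amplitude / peak) if peak > 0 else x


def _paint_hemisphere(
    config: SynthConfig,
    block_vals: np.ndarray,
    rng: np.random.Generator,
    quantize: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel stack from block series; returns (stack, motion (n,3))."""
    h, w = config.image_size
    bp = config.block_px
    n = block_vals.shape[1]
    upscale = 2 if config.emulate_binning else 1
    hh, ww, bb = h * upscale, w * upscale, bp * upscale

    # static smooth reflectance texture so registration has intensity gradients
    texture = 1.0 + 0.05 * ndimage.gaussian_filter(
        rng.standard_normal((hh, ww)), 2.0 * upscale, mode="reflect"
    )
    base = config.baseline_counts / (upscale * upscale) * texture

    nbc = w // bp
    block_img = np.zeros((n, hh, ww), dtype=np.float32)
    for blk in range(config.n_blocks):
        r, c = divmod(blk, nbc)
        block_img[:, r * bb:(r + 1) * bb, c * bb:(c + 1) * bb] = (
            block_vals[blk][:, None, None]
        )

    motion = np.zeros((n, 3))
    if config.motion_amplitude > 0:
        motion[:, 0] = _smooth_random_walk(rng, n, config.motion_amplitude)
        motion[:, 1] = _smooth_random_walk(rng, n, config.motion_amplitude)
        motion[:, 2] = _smooth_random_walk(
            rng, n, config.motion_amplitude * math.pi / 360.0
        )  # radians; ~0.5 deg per pixel of translation amplitude

    frames = np.empty((n, h, w), dtype=np.float32)
    center = np.array([(hh - 1) / 2.0, (ww - 1) / 2.0])
    for i in range(n):
        img = base * (1.0 + block_img[i])
        dy, dx, th = motion[i]
        if dy or dx or th:
            cos, sin = math.cos(th), math.sin(th)
            mat = np.array([[cos, -sin], [sin, cos]])
            offset = center - mat @ center - np.array([dy, dx])
            img = ndimage.affine_transform(img, mat, offset=offset, order=1,
                                           mode="nearest")
        if config.shot_noise_scale > 0:
            img = img + rng.standard_normal(img.shape) * (
                config.shot_noise_scale * np.sqrt(np.maximum(img, 0.0))
            )
        if config.emulate_binning:
            img = img.reshape(h, 2, w, 2).sum(axis=(1, 3))
        frames[i] = img
    if quantize:
        return np.clip(np.round(frames), 0, 65535).astype(np.uint16), motion
    return frames, motion


def generate_dataset(
    config: SynthConfig,
    mode: Literal["stimulation", "resting"] = "stimulation",
    quantize: bool = True,
) -> tuple[ImageStack, ImageStack, TrialSchedule, GroundTruth]:
    """Full pixel-level dataset: one 16-bit reflectance stack per hemisphere
    plus the schedule and the injected ground truth.

    Deterministic for a fixed ``config.rng_seed``.  ``quantize=False`` keeps
    float32 counts (useful for exact-reconstruction oracles).
    """
    rng = np.random.default_rng(config.rng_seed)
    schedule = make_trial_schedule(config.n_stim_epochs, config.frame_rate, mode)
    if schedule.n_frames * config.image_size[0] * config.image_size[1] > 2e8:
        warnings.warn("very large synthetic stack requested", stacklevel=2)

    stacks = {}
    motions = {}
    for hemi in HEMISPHERES:
        vals = _block_signals(config, schedule, rng, hemi)
        data, motion = _paint_hemisphere(config, vals, rng, quantize)
        motions[hemi] = motion
        stacks[hemi] = ImageStack(
            data=data,
            frame_rate=config.frame_rate,
            origin="raw",
            schedule=schedule,
            meta={"hemisphere": hemi, "synthetic": True},
        )
    truth = GroundTruth(
        response_amp=dict(config.response_amp),
        response_latency=dict(config.response_latency),
        active_blocks=dict(config.active_blocks),
        coupling=dict(config.coupling),
        noise_coupling=dict(config.noise_coupling),
        schedule=schedule,
        motion=motions,
        config=config,
    )
    return stacks["healthy"], stacks["stroke"], schedule, truth
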