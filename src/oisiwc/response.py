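"""Evoked-response characterization: amplitude/latency metrics, the
expected-response template selection, the pattern-detection (similarity)
algorithm for activated area, and activation-threshold calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import BlockSeries
from .schedule import BASELINE_S, POST_S, STIM_S, TrialSchedule

__all__ = [
    "ResponseMetrics",
    "ExpectedResponse",
    "SimilarityMap",
    "epoch_average",
    "default_reference_scale",
    "reference_specs_from_waveform",
    "signal_metrics",
    "select_expected_response",
    "pattern_detection",
    "calibrate_threshold",
    "BLOCK_AREA_UM2",
]

#: Cortical area covered by one 10x10-pixel block.
BLOCK_AREA_UM2 = 100.0 * 100.0


def epoch_average(
    block_series: BlockSeries, schedule: TrialSchedule
) -> tuple[np.ndarray, np.ndarray]:
    """Average the per-block series over stimulation epochs.

    Returns ``(avg, t_rel)`` where ``avg`` is blocks x samples and ``t_rel``
    is time relative to stimulus onset, covering the 1 s pre-stimulus
    baseline through the 13 s post window.
    """
    if schedule.mode != "stimulation" or not schedule.stim_onsets_s:
        raise ValueError("a stimulation-mode schedule is required")
    fs = block_series.sampling_rate
    pre = int(round(BASELINE_S * fs))
    post = int(round((STIM_S + POST_S) * fs))
    segs = []
    for onset in schedule.stim_onsets_s:
        i0 = int(round(onset * fs)) - pre
        i1 = i0 + pre + post
        if i0 < 0 or i1 > block_series.n_timepoints:
            raise ValueError("epoch window exceeds the series")
        segs.append(block_series.values[:, i0:i1])
    avg = np.mean(segs, axis=0)
    t_rel = (np.arange(pre + post) - pre) / fs
    return avg, t_rel


@dataclass
class ResponseMetrics:
    """Per-block evoked-response metrics from the epoch-averaged series.

    ``amplitude`` is |min| of the initial dip relative to the pre-stimulus
    baseline mean; ``latency`` the time from stimulus onset to that
    extremum (NaN for flat blocks).
    """

    amplitude: np.ndarray
    latency: np.ndarray
    epoch_avg: np.ndarray
    t_rel: np.ndarray
    dip_window_s: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "block": np.arange(len(self.amplitude)),
            "amplitude": self.amplitude,
            "latency_s": self.latency,
        })


def signal_metrics(
    block_series: BlockSeries,
    schedule: TrialSchedule,
    dip_window_s: float = 6.0,
    smooth_s: float = 0.5,
) -> ResponseMetrics:
    """Amplitude and latency of the stimulus-evoked initial dip per block.

    The initial dip is searched in the first ``dip_window_s`` seconds after
    stimulus onset of the epoch-averaged, baseline-subtracted response.  A
    moving average of length ``smooth_s`` is applied before locating the
    extremum so that residual physiological oscillations do not displace it
    (0 disables the smoothing).
    """
    avg, t_rel = epoch_average(block_series, schedule)
    fs = block_series.sampling_rate
    pre = int(round(BASELINE_S * fs))
    baseline = avg[:, :pre].mean(axis=1, keepdims=True)
    resp = avg - baseline
    k = int(round(smooth_s * fs))
    if k > 1:
        kernel = np.ones(k) / k
        resp = np.apply_along_axis(
            lambda r: np.convolve(np.pad(r, (k // 2, k - 1 - k // 2), mode="edge"),
                                  kernel, mode="valid"),
            1, resp)
    post = resp[:, pre:]
    t_post = t_rel[pre:]
    win = t_post <= dip_window_s
    seg = post[:, win]
    amp = np.maximum(0.0, -seg.min(axis=1))
    lat = t_post[win][np.argmin(seg, axis=1)]
    flat = seg.std(axis=1) == 0
    amp[flat] = 0.0
    lat = lat.astype(float)
    lat[flat] = np.nan
    return ResponseMetrics(amplitude=amp, latency=lat, epoch_avg=avg,
                           t_rel=t_rel, dip_window_s=dip_window_s)


# ---------------------------------------------------------------------------
# expected-response selection


FEATURE_NAMES = (
    "dip_latency_s",
    "dip_amplitude",
    "rebound_time_s",
    "rebound_amplitude",
    "undershoot_time_s",
    "undershoot_amplitude",
)


def temporal_features(resp: np.ndarray, t_post: np.ndarray,
                      dip_window_s: float = 6.0) -> np.ndarray:
    """Feature vector of one baseline-subtracted post-onset response:
    initial-dip latency/amplitude, later positive rebound peak time/
    amplitude, late undershoot time/amplitude."""
    win = t_post <= dip_window_s
    i_dip = int(np.argmin(resp[win]))
    dip_t, dip_a = t_post[win][i_dip], -resp[win][i_dip]
    after = t_post > dip_t
    if after.any():
        ra = resp[after]
        i_reb = int(np.argmax(ra))
        reb_t, reb_a = t_post[after][i_reb], ra[i_reb]
        late = t_post > reb_t
        if late.any():
            la = resp[late]
            i_un = int(np.argmin(la))
            un_t, un_a = t_post[late][i_un], -la[i_un]
        else:
            un_t, un_a = reb_t, 0.0
    else:
        reb_t = un_t = dip_t
        reb_a = un_a = 0.0
    return np.array([dip_t, dip_a, reb_t, reb_a, un_t, un_a])


def default_reference_scale(specs: Mapping[str, float]) -> dict:
    """Feature scales for the convergence distance: amplitude features are
    scaled by the dip amplitude (so sub-dip phases are not hyper-sensitive
    to noise), time features by their reference value (at least 1 s)."""
    dip = abs(specs["dip_amplitude"]) or 1.0
    scale = {}
    for k in FEATURE_NAMES:
        scale[k] = dip if k.endswith("amplitude") else max(1.0, abs(specs[k]))
    return scale


def reference_specs_from_waveform(
    amp: float,
    latency: float,
    overshoot_frac: float = 0.35,
    overshoot_delay: float = 3.5,
    undershoot_frac: float = 0.15,
    undershoot_delay: float = 8.0,
) -> dict:
    """Reference temporal specifications for a tri-phasic response with the
    given dip amplitude and latency (matches the synthetic waveform's
    parametrization)."""
    return {
        "dip_latency_s": latency,
        "dip_amplitude": amp,
        "rebound_time_s": latency + overshoot_delay,
        "rebound_amplitude": overshoot_frac * amp,
        "undershoot_time_s": latency + overshoot_delay + undershoot_delay,
        "undershoot_amplitude": undershoot_frac * amp,
    }


@dataclass
class ExpectedResponse:
    """The epoch-averaged waveform of the block whose temporal features best
    match the reference specifications (standardized to unit variance)."""

    template: np.ndarray
    source_block: int
    convergence: float
    scores: np.ndarray = field(repr=False, default=None)


def select_expected_response(
    block_series: BlockSeries,
    reference_specs: Mapping[str, float] | Sequence[float],
    schedule: TrialSchedule,
    scale: Mapping[str, float] | Sequence[float] | None = None,
    method: str = "distance",
    dip_window_s: float = 6.0,
) -> ExpectedResponse:
    """Select the block whose response converges best to the reference
    temporal specifications.

    ``reference_specs`` gives target values for the features in
    ``FEATURE_NAMES``; convergence is ``1 / (1 + d)`` with ``d`` the
    Euclidean distance between feature vectors z-scored by the reference
    scale (``method="pearson"`` uses the feature-vector Pearson correlation
    instead).  Ties break to the lowest block index.
    """
    if isinstance(reference_specs, Mapping):
        ref = np.array([reference_specs[k] for k in FEATURE_NAMES], dtype=float)
    else:
        ref = np.asarray(reference_specs, dtype=float)
    if ref.shape != (len(FEATURE_NAMES),):
        raise ValueError(f"reference_specs must supply {len(FEATURE_NAMES)} features")
    if scale is None:
        sc = np.array([default_reference_scale(dict(zip(FEATURE_NAMES, ref)))[k]
                       for k in FEATURE_NAMES])
    elif isinstance(scale, Mapping):
        sc = np.array([scale[k] for k in FEATURE_NAMES], dtype=float)
    else:
        sc = np.asarray(scale, dtype=float)

    avg, t_rel = epoch_average(block_series, schedule)
    fs = block_series.sampling_rate
    pre = int(round(BASELINE_S * fs))
    baseline = avg[:, :pre].mean(axis=1, keepdims=True)
    resp = avg - baseline
    t_post = t_rel[pre:]
    if np.all(resp[:, pre:].std(axis=1) == 0):
        raise ValueError("all blocks are flat; no expected response can be selected")

    scores = np.empty(block_series.n_blocks)
    for b in range(block_series.n_blocks):
        feats = temporal_features(resp[b, pre:], t_post, dip_window_s)
        if method == "distance":
            d = np.linalg.norm((feats - ref) / sc)
            scores[b] = 1.0 / (1.0 + d)
        elif method == "pearson":
            fz, rz = feats / sc, ref / sc
            num = np.corrcoef(fz, rz)[0, 1]
            scores[b] = num if np.isfinite(num) else -np.inf
        else:
            raise ValueError(f"unknown method {method!r}")
    best = int(np.argmax(scores))  # argmax takes the first (lowest) index on ties
    template = avg[best].copy()
    sd = template.std()
    template = (template - template.mean()) / sd if sd > 0 else template - template.mean()
    return ExpectedResponse(template=template, source_block=best,
                            convergence=float(scores[best]), scores=scores)


# ---------------------------------------------------------------------------
# pattern detection


@dataclass
class SimilarityMap:
    """Per-block Pearson similarity to the expected response."""

    similarity: np.ndarray
    threshold: float
    mask: np.ndarray
    activated_area_um2: float
    block_area_um2: float = BLOCK_AREA_UM2

    @property
    def n_activated(self) -> int:
        return int(self.mask.sum())


def pattern_detection(
    block_series: BlockSeries,
    expected: ExpectedResponse,
    schedule: TrialSchedule,
    threshold: float = 0.7,
    block_area_um2: float = BLOCK_AREA_UM2,
) -> SimilarityMap:
    """Pearson-correlate every block's epoch-averaged response with the
    expected-response template; blocks with similarity >= threshold form the
    activated area (block count x per-block cortical area)."""
    avg, _ = epoch_average(block_series, schedule)
    if avg.shape[1] != len(expected.template):
        raise ValueError("template and epoch averages differ in length")
    tpl = expected.template - expected.template.mean()
    tn = np.linalg.norm(tpl)
    sim = np.zeros(block_series.n_blocks)
    for b in range(block_series.n_blocks):
        y = avg[b] - avg[b].mean()
        yn = np.linalg.norm(y)
        if yn == 0 or tn == 0:
            warnings.warn(f"zero-variance block {b}: similarity set to 0",
                          stacklevel=2)
            sim[b] = 0.0
        else:
            sim[b] = float(np.dot(tpl, y) / (tn * yn))
    mask = sim >= threshold
    return SimilarityMap(
        similarity=sim,
        threshold=threshold,
        mask=mask,
        activated_area_um2=float(mask.sum() * block_area_um2),
        block_area_um2=block_area_um2,
    )


def calibrate_threshold(
    block_series: BlockSeries,
    expected: ExpectedResponse,
    fc_matrix_seeded: np.ndarray,
    schedule: TrialSchedule,
    candidates: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9),
) -> tuple[float, pd.DataFrame]:
    """Pick the activation threshold whose binarized similarity map agrees
    best with a seed-based functional-connectivity map.

    ``fc_matrix_seeded`` is either a per-block seed-correlation vector or a
    full block x block correlation matrix; for a matrix the component-wise
    Pearson correlation with the binarized map is averaged over rows.
    Returns the arg-max threshold (ties to the smaller value) and the full
    score table; degenerate (constant) maps get a NaN score.
    """
    fc = np.asarray(fc_matrix_seeded, dtype=float)
    rows = fc[None, :] if fc.ndim == 1 else fc
    if rows.shape[-1] != block_series.n_blocks:
        raise ValueError("FC matrix size must match the number of blocks")
    sim = pattern_detection(block_series, expected, schedule, threshold=0.0).similarity

    def _corr(a: np.ndarray, b: np.ndarray) -> float:
        if a.std() == 0 or b.std() == 0:
            return np.nan
        return float(np.corrcoef(a, b)[0, 1])

    records = []
    for th in candidates:
        binarized = (sim >= th).astype(float)
        scores = [_corr(binarized, row) for row in rows]
        scores = [s for s in scores if np.isfinite(s)]
        records.append({
            "threshold": th,
            "score": float(np.mean(scores)) if scores else np.nan,
            "n_activated": int((sim >= th).sum()),
        })
    table = pd.DataFrame(records)
    if table["score"].notna().any():
        best = float(table.loc[table["score"].idxmax(), "threshold"])
    else:
        best = float(candidates[0])
    return best, table
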