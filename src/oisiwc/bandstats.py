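"""Band x interval averaging of wavelet coherence and the group-comparison
statistics.

The frequency axis is split into four physiological bands — I (2-4.5 Hz,
cardiac), II (0.4-2 Hz, respiratory), III (0.15-0.4 Hz, myogenic), IV
(0.05-0.15 Hz, neurogenic) — and the peri-stimulus time axis into four
intervals: 1 s before stimulation (dt1), the 1 s stimulation (dt2), and the
first and second 6.5 s after it (dt3, dt4).  Bands are half-open on the
upper edge except band I, which is closed at 4.5 Hz.

Comparisons between hemispheres follow the study design: per block pair and
domain a balanced two-way ANOVA (factors group and replicate, no
interaction) collected into 12 x 12 statistical matrices with P-value color
classes; per domain a one-way ANOVA on the pair-averaged coherence; per
band and overall an independent-sample t-test; plus normality (corrected
Kolmogorov-Smirnov), variance-homogeneity (Levene) and Bonferroni post-hoc
checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BlockSeries
from .schedule import BASELINE_S, TrialSchedule
from .wavelet import CoherenceMap, ScaleGrid, wavelet_coherence

__all__ = [
    "BANDS",
    "INTERVALS",
    "DomainGrid",
    "StatMatrix",
    "band_interval_average",
    "compute_pairwise_domains",
    "pairwise_domain_stats",
    "domain_mean_comparison",
    "band_and_overall_comparison",
    "assumption_checks",
    "p_color_class",
]

#: Frequency bands (Hz), high to low frequency.
BANDS: dict[str, tuple[float, float]] = {
    "I": (2.0, 4.5),
    "II": (0.4, 2.0),
    "III": (0.15, 0.4),
    "IV": (0.05, 0.15),
}

#: Peri-stimulus intervals in seconds relative to stimulus onset.
INTERVALS: dict[str, tuple[float, float]] = {
    "dt1": (-1.0, 0.0),
    "dt2": (0.0, 1.0),
    "dt3": (1.0, 7.5),
    "dt4": (7.5, 14.0),
}

BAND_NAMES = tuple(BANDS)
INTERVAL_NAMES = tuple(INTERVALS)


def p_color_class(p: float, diagonal: bool = False) -> str:
    """Color class of a P value: red < 0.001, orange < 0.01, yellow < 0.05,
    blue >= 0.05, white on the diagonal."""
    if diagonal:
        return "white"
    if p < 0.001:
        return "red"
    if p < 0.01:
        return "orange"
    if p < 0.05:
        return "yellow"
    return "blue"


@dataclass
class DomainGrid:
    """Mean wavelet coherence over 4 bands x 4 peri-stimulus intervals."""

    values: np.ndarray                      # (4 bands, 4 intervals)
    bands: tuple[str, ...] = BAND_NAMES
    intervals: tuple[str, ...] = INTERVAL_NAMES
    n_cells: np.ndarray | None = None       # cells averaged per domain

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.bands), len(self.intervals)):
            raise ValueError("DomainGrid values must be bands x intervals")
        finite = np.isfinite(self.values)
        if np.any((self.values[finite] < -1e-9) | (self.values[finite] > 1 + 1e-9)):
            raise ValueError("coherence domain means must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.bands),
                            columns=list(self.intervals))


def _band_membership(freqs: np.ndarray, band: tuple[float, float],
                     closed_top: bool) -> np.ndarray:
    lo, hi = band
    top = freqs <= hi if closed_top else freqs < hi
    return (freqs >= lo) & top


def band_interval_average(
    cmap: CoherenceMap,
    schedule: TrialSchedule,
    bands: Mapping[str, tuple[float, float]] = BANDS,
    intervals: Mapping[str, tuple[float, float]] = INTERVALS,
    coi_filter: bool = True,
) -> DomainGrid:
    """Average R^2 over each band x epoch-relative interval.

    Cells are pooled across all stimulation epochs; with ``coi_filter`` cells
    outside the cone of influence are excluded.  Domains with no valid cell
    are NaN.
    """
    if schedule.mode != "stimulation":
        raise ValueError("a stimulation-mode schedule is required")
    t = cmap.times
    freqs = cmap.grid.fourier_freqs
    fmax_band = max(hi for _, hi in bands.values())
    for name, (a, b) in intervals.items():
        if a < -BASELINE_S - 1e-9 or b > 14.0 + 1e-9 or a >= b:
            raise ValueError(f"interval {name} lies outside the epoch window")

    valid = cmap.coi_mask() if coi_filter else np.ones_like(cmap.r2, dtype=bool)
    out = np.full((len(bands), len(intervals)), np.nan)
    counts = np.zeros_like(out, dtype=int)
    band_rows = {
        name: _band_membership(freqs, edges, closed_top=np.isclose(edges[1], fmax_band))
        for name, edges in bands.items()
    }
    for j, (iname, (a, b)) in enumerate(intervals.items()):
        tsel = np.zeros_like(t, dtype=bool)
        for onset in schedule.stim_onsets_s:
            tsel |= (t >= onset + a) & (t < onset + b)
        for i, bname in enumerate(bands):
            cells = valid[np.ix_(band_rows[bname], tsel)]
            vals = cmap.r2[np.ix_(band_rows[bname], tsel)][cells]
            counts[i, j] = vals.size
            if vals.size:
                out[i, j] = float(vals.mean())
    return DomainGrid(values=out, bands=tuple(bands), intervals=tuple(intervals),
                      n_cells=counts)


def compute_pairwise_domains(
    block_series: BlockSeries,
    schedule: TrialSchedule,
    grid: ScaleGrid,
    coi_filter: bool = True,
) -> np.ndarray:
    """Domain grids for every block pair of one cortex.

    Returns an array (n_blocks, n_blocks, 4, 4), symmetric in the first two
    axes, NaN on the diagonal.
    """
    nb = block_series.n_blocks
    out = np.full((nb, nb, len(BANDS), len(INTERVALS)), np.nan)
    for i in range(nb):
        for j in range(i + 1, nb):
            cmap = wavelet_coherence(block_series.values[i],
                                     block_series.values[j], grid)
            dg = band_interval_average(cmap, schedule, coi_filter=coi_filter)
            out[i, j] = out[j, i] = dg.values
    return out


@dataclass
class StatMatrix:
    """12 x 12 group-difference P values for one time-frequency domain."""

    p: np.ndarray
    band: str
    interval: str
    classes: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        n = self.p.shape[0]
        if self.p.shape != (n, n):
            raise ValueError("StatMatrix must be square")
        if not np.allclose(self.p, self.p.T, equal_nan=True):
            raise ValueError("StatMatrix must be symmetric")
        if self.classes is None:
            self.classes = np.empty((n, n), dtype=object)
            for i in range(n):
                for j in range(n):
                    self.classes[i, j] = p_color_class(self.p[i, j], diagonal=i == j)

    def to_frame(self) -> pd.DataFrame:
        n = self.p.shape[0]
        cols = [f"b{i:02d}" for i in range(n)]
        return pd.DataFrame(self.p, index=cols, columns=cols)


def _twoway_anova_group_p(y: np.ndarray) -> np.ndarray:
    """Vectorized balanced two-way ANOVA (group x replicate, no interaction,
    one observation per cell); returns the group-effect P value.

    ``y`` has shape (2, r, ...); the test statistic is
    F = MS_group / MS_error with df (1, r - 1).
    """
    n_groups, r = y.shape[0], y.shape[1]
    if n_groups != 2 or r < 2:
        raise ValueError("need 2 groups with >= 2 replicates")
    grand = y.mean(axis=(0, 1))
    gm = y.mean(axis=1)                       # (2, ...)
    rm = y.mean(axis=0)                       # (r, ...)
    ss_tot = ((y - grand) ** 2).sum(axis=(0, 1))
    ss_g = r * ((gm - grand) ** 2).sum(axis=0)
    ss_r = n_groups * ((rm - grand) ** 2).sum(axis=0)
    ss_e = np.maximum(ss_tot - ss_g - ss_r, 0.0)
    dfe = (n_groups - 1) * (r - 1)
    ms_e = ss_e / dfe
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(ms_e > 0, ss_g / ms_e, np.inf)
        f = np.where((ss_g <= 1e-30) & (ms_e <= 0), 0.0, f)
    return stats.f.sf(f, 1, dfe)


def _check_groups(healthy: np.ndarray, stroke: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    healthy = np.asarray(healthy, dtype=float)
    stroke = np.asarray(stroke, dtype=float)
    if healthy.shape != stroke.shape:
        raise ValueError("groups must have identical shapes")
    if healthy.shape[0] < 2:
        raise ValueError("at least 2 replicates per group are required")
    return healthy, stroke


def pairwise_domain_stats(
    healthy: np.ndarray,
    stroke: np.ndarray,
) -> list[StatMatrix]:
    """Per-domain 12 x 12 statistical matrices of group-effect P values.

    Inputs are stacked pairwise domain grids of shape
    (n_replicates, n_blocks, n_blocks, 4, 4) per group (replicates =
    animals or seeds).  Each off-diagonal cell holds the two-way ANOVA
    (group x replicate) P value for that block pair; the diagonal is 0.
    """
    healthy, stroke = _check_groups(healthy, stroke)
    y = np.stack([healthy, stroke])           # (2, r, nb, nb, 4, 4)
    p = _twoway_anova_group_p(y)              # (nb, nb, 4, 4)
    nb = p.shape[0]
    mats = []
    for bi, bname in enumerate(BAND_NAMES):
        for ii, iname in enumerate(INTERVAL_NAMES):
            m = p[:, :, bi, ii].copy()
            m = (m + m.T) / 2.0               # enforce exact symmetry
            np.fill_diagonal(m, 0.0)
            mats.append(StatMatrix(p=m, band=bname, interval=iname))
    return mats


def _pair_average(grids: np.ndarray) -> np.ndarray:
    """Average over off-diagonal block pairs -> (n_replicates, 4, 4)."""
    nb = grids.shape[1]
    iu = np.triu_indices(nb, k=1)
    return grids[:, iu[0], iu[1], :, :].mean(axis=1)


def domain_mean_comparison(healthy: np.ndarray, stroke: np.ndarray) -> pd.DataFrame:
    """Per-domain one-way ANOVA on the pair-averaged coherence.

    Returns 16 rows with group means +/- SEM and the P value.
    """
    healthy, stroke = _check_groups(healthy, stroke)
    h = _pair_average(healthy)
    s = _pair_average(stroke)
    rows = []
    for bi, bname in enumerate(BAND_NAMES):
        for ii, iname in enumerate(INTERVAL_NAMES):
            a, b = h[:, bi, ii], s[:, bi, ii]
            f, p = stats.f_oneway(a, b)
            rows.append({
                "band": bname, "interval": iname,
                "mean_healthy": a.mean(), "sem_healthy": stats.sem(a),
                "mean_stroke": b.mean(), "sem_stroke": stats.sem(b),
                "F": f, "p": p,
            })
    return pd.DataFrame(rows)


def band_and_overall_comparison(
    healthy: np.ndarray,
    stroke: np.ndarray,
    equal_var: bool = True,
) -> dict:
    """Per-band means (averaged across the four intervals) and the overall
    independent-sample t-test on the grand means.

    ``equal_var=False`` switches to the Welch t-test; the choice is recorded
    in the result.
    """
    healthy, stroke = _check_groups(healthy, stroke)
    h = _pair_average(healthy)                # (r, 4, 4)
    s = _pair_average(stroke)
    band_rows = []
    for bi, bname in enumerate(BAND_NAMES):
        a, b = h[:, bi, :].mean(axis=1), s[:, bi, :].mean(axis=1)
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        band_rows.append({
            "band": bname,
            "mean_healthy": a.mean(), "sem_healthy": stats.sem(a),
            "mean_stroke": b.mean(), "sem_stroke": stats.sem(b),
            "t": t, "p": p,
        })
    gh, gs = h.mean(axis=(1, 2)), s.mean(axis=(1, 2))
    t, p = stats.ttest_ind(gh, gs, equal_var=equal_var)
    return {
        "bands": pd.DataFrame(band_rows),
        "overall": {
            "mean_healthy": float(gh.mean()), "mean_stroke": float(gs.mean()),
            "t": float(t), "p": float(p),
            "test": "student-t" if equal_var else "welch-t",
        },
    }


def assumption_checks(groups: Mapping[str, Sequence[float]]) -> dict:
    """Normality (Lilliefors-corrected Kolmogorov-Smirnov), variance
    homogeneity (Levene) and Bonferroni-adjusted pairwise t-tests."""
    from statsmodels.stats.diagnostic import lilliefors

    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 3:
            raise ValueError(f"group {k!r} needs at least 3 samples")
    ks = {}
    for k, v in arrays.items():
        stat, p = lilliefors(v, dist="norm")
        ks[k] = {"statistic": float(stat), "p": float(p)}
    lev_stat, lev_p = stats.levene(*arrays.values())
    names = list(arrays)
    m = len(names) * (len(names) - 1) // 2
    posthoc = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            t, p = stats.ttest_ind(arrays[names[i]], arrays[names[j]])
            posthoc.append({
                "pair": (names[i], names[j]),
                "t": float(t),
                "p": float(p),
                "p_bonferroni": min(1.0, m * float(p)),
            })
    return {
        "ks_normality": ks,
        "levene": {"statistic": float(lev_stat), "p": float(lev_p)},
        "posthoc_bonferroni": posthoc,
        "n_comparisons": m,
    }
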