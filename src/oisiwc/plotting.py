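"""Rendering of coherence maps and statistical matrices (optional)."""

from __future__ import annotations

import numpy as np

from .bandstats import StatMatrix
from .wavelet import CoherenceMap, arrow_components

CLASS_COLORS = {
    "red": (0.85, 0.1, 0.1),
    "orange": (1.0, 0.6, 0.1),
    "yellow": (1.0, 0.95, 0.3),
    "blue": (0.25, 0.4, 0.85),
    "white": (1.0, 1.0, 1.0),
}


def plot_coherence_map(cmap: CoherenceMap, path=None, arrow_stride=(6, 24),
                       title: str = "wavelet coherence"):
    """R^2 heat map on a log-frequency axis with COI curve, significance
    contour and phase arrows; saves to ``path`` if given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = cmap.times
    f = cmap.grid.fourier_freqs
    fig, ax = plt.subplots(figsize=(9, 4))
    mesh = ax.pcolormesh(t, f, cmap.r2, shading="auto", cmap="viridis",
                         vmin=0, vmax=1)
    fig.colorbar(mesh, ax=ax, label=r"$R^2$")
    # cone of influence: frequency below which edges dominate
    with np.errstate(divide="ignore"):
        coi_f = 1.0 / (cmap.coi_scale * 4 * np.pi
                       / (cmap.grid.omega0 + np.sqrt(2 + cmap.grid.omega0 ** 2)))
    ax.plot(t, np.clip(coi_f, f.min(), f.max()), "k-", lw=0.8)
    if cmap.sig_mask is not None and cmap.sig_mask.any():
        ax.contour(t, f, cmap.sig_mask.astype(float), levels=[0.5],
                   colors="k", linewidths=1.5)
    u, v = arrow_components(cmap.phase)
    si, sj = arrow_stride
    ax.quiver(t[::sj], f[::si], u[::si, ::sj], v[::si, ::sj],
              scale=40, width=0.002, color="w", alpha=0.7)
    ax.set_yscale("log")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_stat_matrix(sm: StatMatrix, path=None):
    """Color-class rendering of one 12 x 12 statistical matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = sm.p.shape[0]
    img = np.ones((n, n, 3))
    for i in range(n):
        for j in range(n):
            img[i, j] = CLASS_COLORS[sm.classes[i, j]]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(img, origin="upper")
    ax.set_title(f"band {sm.band}, interval {sm.interval}")
    ax.set_xlabel("block")
    ax.set_ylabel("block")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
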