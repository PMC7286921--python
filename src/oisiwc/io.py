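"""File I/O: TIFF stacks with JSON sidecars, CSV tables, coherence archives.

All writers have matching readers with write-then-read equality (exact for
integers and strings, ~1e-12 for floats); serialized artifacts carry a
format version and readers refuse unknown versions.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .bandstats import DomainGrid, StatMatrix
from .containers import BlockSeries, ImageStack, PSDEstimate
from .corrfc import FCMatrix
from .schedule import TrialSchedule
from .wavelet import CoherenceMap, ScaleGrid

__all__ = [
    "write_stack", "read_stack",
    "write_schedule", "read_schedule",
    "write_block_series", "read_block_series",
    "write_psd", "read_psd",
    "write_fc_matrix", "read_fc_matrix",
    "write_coherence_map", "read_coherence_map",
    "write_domain_grid", "read_domain_grid",
    "write_stat_matrix", "read_stat_matrix",
    "write_json", "read_json",
]

FORMAT_VERSION = 1
_FLOAT_FMT = "%.17g"


def _check_version(meta: dict, what: str) -> None:
    v = meta.get("format_version")
    if v != FORMAT_VERSION:
        raise ValueError(f"{what}: unsupported format version {v!r}")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# --- stacks ----------------------------------------------------------------


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Multi-page TIFF plus a JSON sidecar (<path>.json) with frame rate,
    origin, schedule and metadata."""
    path = Path(path)
    data = stack.data
    if data.dtype.kind == "f":
        data = data.astype(np.float32)
    tifffile.imwrite(path, data)
    sidecar = {
        "format_version": FORMAT_VERSION,
        "frame_rate": stack.frame_rate,
        "origin": stack.origin,
        "schedule": stack.schedule.to_dict() if stack.schedule else None,
        "meta": stack.meta,
    }
    write_json(sidecar, path.with_suffix(path.suffix + ".json"))


def read_stack(path: str | Path) -> ImageStack:
    path = Path(path)
    data = tifffile.imread(path)
    side = read_json(path.with_suffix(path.suffix + ".json"))
    _check_version(side, "stack sidecar")
    sched = TrialSchedule.from_dict(side["schedule"]) if side["schedule"] else None
    return ImageStack(data=data, frame_rate=side["frame_rate"],
                      origin=side["origin"], schedule=sched,
                      meta=side.get("meta", {}))


def write_schedule(schedule: TrialSchedule, path: str | Path) -> None:
    write_json({"format_version": FORMAT_VERSION, **schedule.to_dict()}, path)


def read_schedule(path: str | Path) -> TrialSchedule:
    d = read_json(path)
    _check_version(d, "schedule")
    return TrialSchedule.from_dict(d)


# --- block series and PSD --------------------------------------------------


def write_block_series(bs: BlockSeries, path: str | Path) -> None:
    """CSV with a time column and one column per block; block rectangles and
    sampling metadata go to a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(bs.values.T, columns=[f"b{i:02d}" for i in range(bs.n_blocks)])
    df.insert(0, "time_s", bs.times)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    side = {
        "format_version": FORMAT_VERSION,
        "sampling_rate": bs.sampling_rate,
        "block_map": bs.block_map,
        "schedule": bs.schedule.to_dict() if bs.schedule else None,
        "label": bs.label,
    }
    write_json(side, path.with_suffix(path.suffix + ".json"))


def read_block_series(path: str | Path) -> BlockSeries:
    path = Path(path)
    df = pd.read_csv(path)
    side = read_json(path.with_suffix(path.suffix + ".json"))
    _check_version(side, "block series sidecar")
    bm = side.get("block_map")
    return BlockSeries(
        values=df.drop(columns=["time_s"]).to_numpy().T,
        sampling_rate=side["sampling_rate"],
        block_map=tuple(tuple(r) for r in bm) if bm else None,
        schedule=TrialSchedule.from_dict(side["schedule"]) if side["schedule"] else None,
        label=side.get("label", ""),
    )


def write_psd(psd: PSDEstimate, path: str | Path) -> None:
    power = np.atleast_2d(psd.power)
    df = pd.DataFrame(power.T, columns=[f"b{i:02d}" for i in range(power.shape[0])])
    df.insert(0, "frequency_hz", psd.frequencies)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    write_json({
        "format_version": FORMAT_VERSION,
        "segment_s": psd.segment_s,
        "overlap_frac": psd.overlap_frac,
        "sampling_rate": psd.sampling_rate,
        "ndim": int(np.ndim(psd.power)),
    }, Path(path).with_suffix(Path(path).suffix + ".json"))


def read_psd(path: str | Path) -> PSDEstimate:
    path = Path(path)
    df = pd.read_csv(path)
    side = read_json(path.with_suffix(path.suffix + ".json"))
    _check_version(side, "psd sidecar")
    power = df.drop(columns=["frequency_hz"]).to_numpy().T
    if side.get("ndim") == 1:
        power = power[0]
    return PSDEstimate(frequencies=df["frequency_hz"].to_numpy(), power=power,
                       segment_s=side["segment_s"],
                       overlap_frac=side["overlap_frac"],
                       sampling_rate=side["sampling_rate"])


# --- FC matrix -------------------------------------------------------------


def write_fc_matrix(fc: FCMatrix, path: str | Path) -> None:
    path = Path(path)
    fc.to_frame().to_csv(path, float_format=_FLOAT_FMT)
    write_json({
        "format_version": FORMAT_VERSION,
        "fisher_z": fc.fisher_z,
        "normalized": fc.normalized,
        "strength": fc.strength,
        "strength_fisher": fc.strength_fisher,
        "strength_normalized": fc.strength_normalized,
        "undefined_blocks": list(fc.undefined_blocks),
    }, path.with_suffix(path.suffix + ".json"))


def read_fc_matrix(path: str | Path) -> FCMatrix:
    path = Path(path)
    raw = pd.read_csv(path, index_col=0).to_numpy()
    side = read_json(path.with_suffix(path.suffix + ".json"))
    _check_version(side, "fc sidecar")
    return FCMatrix(
        raw_r=raw,
        fisher_z=np.asarray(side["fisher_z"], dtype=float),
        normalized=np.asarray(side["normalized"], dtype=float),
        strength=side["strength"],
        strength_fisher=side["strength_fisher"],
        strength_normalized=side["strength_normalized"],
        undefined_blocks=tuple(side["undefined_blocks"]),
    )


# --- coherence map ---------------------------------------------------------


def write_coherence_map(cmap: CoherenceMap, path: str | Path,
                        csv_path: str | Path | None = None) -> None:
    """Compressed array archive (.npz); optionally also a long-format CSV of
    (time, scale, R2, phase, significant)."""
    np.savez_compressed(
        path,
        r2=cmap.r2, phase=cmap.phase,
        scales=cmap.grid.scales, fourier_freqs=cmap.grid.fourier_freqs,
        coi_scale=cmap.coi_scale,
        grid_params=np.array([cmap.grid.dj, cmap.grid.s0, cmap.grid.omega0,
                              cmap.grid.sampling_rate]),
        sig_mask=(cmap.sig_mask if cmap.sig_mask is not None
                  else np.zeros((0, 0), dtype=bool)),
        sig_threshold=(cmap.sig_threshold if cmap.sig_threshold is not None
                       else np.zeros(0)),
        format_version=np.array([FORMAT_VERSION]),
    )
    if csv_path is not None:
        t = cmap.times
        sig = (cmap.sig_mask if cmap.sig_mask is not None
               else np.zeros_like(cmap.r2, dtype=bool))
        rows = {
            "time_s": np.repeat(t, cmap.grid.n_scales),
            "scale_s": np.tile(cmap.grid.scales, len(t)),
            "r2": cmap.r2.T.ravel(),
            "phase": cmap.phase.T.ravel(),
            "significant": sig.T.ravel().astype(int),
        }
        pd.DataFrame(rows).to_csv(csv_path, index=False, float_format="%.8g")


def read_coherence_map(path: str | Path) -> CoherenceMap:
    with np.load(path) as z:
        if int(z["format_version"][0]) != FORMAT_VERSION:
            raise ValueError("coherence archive: unsupported format version")
        dj, s0, omega0, fs = z["grid_params"]
        grid = ScaleGrid(scales=z["scales"], fourier_freqs=z["fourier_freqs"],
                         dj=float(dj), s0=float(s0), omega0=float(omega0),
                         sampling_rate=float(fs))
        sig_mask = z["sig_mask"] if z["sig_mask"].size else None
        sig_thr = z["sig_threshold"] if z["sig_threshold"].size else None
        return CoherenceMap(r2=z["r2"], phase=z["phase"], grid=grid,
                            sampling_rate=float(fs), coi_scale=z["coi_scale"],
                            sig_mask=sig_mask, sig_threshold=sig_thr)


# --- domain grids and stat matrices ---------------------------------------


def write_domain_grid(dg: DomainGrid, path: str | Path) -> None:
    dg.to_frame().to_csv(path, float_format=_FLOAT_FMT)


def read_domain_grid(path: str | Path) -> DomainGrid:
    df = pd.read_csv(path, index_col=0)
    return DomainGrid(values=df.to_numpy(), bands=tuple(df.index),
                      intervals=tuple(df.columns))


def write_stat_matrix(sm: StatMatrix, path: str | Path,
                      classes_path: str | Path | None = None) -> None:
    sm.to_frame().to_csv(path, float_format=_FLOAT_FMT)
    if classes_path is not None:
        n = sm.p.shape[0]
        cols = [f"b{i:02d}" for i in range(n)]
        pd.DataFrame(sm.classes, index=cols, columns=cols).to_csv(classes_path)


def read_stat_matrix(path: str | Path, band: str = "", interval: str = "") -> StatMatrix:
    df = pd.read_csv(path, index_col=0)
    return StatMatrix(p=df.to_numpy(), band=band, interval=interval)
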