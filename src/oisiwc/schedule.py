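"""Trial schedules for stimulation and resting-state imaging runs.

A stimulation trial is a sequence of stimulation epochs (1 s pre-stimulus
baseline, 1 s whisker stimulation, 13 s post-stimulus rest) with a 21 s
control epoch inserted between every two consecutive stimulation epochs.
A resting trial is a single continuous resting segment (300 s by default).
Segment boundaries are carried both in seconds and in frame indices at the
acquisition frame rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

__all__ = [
    "Segment",
    "TrialSchedule",
    "make_trial_schedule",
    "BASELINE_S",
    "STIM_S",
    "POST_S",
    "CONTROL_S",
    "RESTING_S",
]

BASELINE_S = 1.0
STIM_S = 1.0
POST_S = 13.0
CONTROL_S = 21.0
RESTING_S = 300.0

EPOCH_S = BASELINE_S + STIM_S + POST_S  # 15 s


@dataclass(frozen=True)
class Segment:
    """One contiguous labelled interval of a trial."""

    label: str          # baseline | stimulation | post | control | resting
    epoch: int          # stimulation-epoch index, -1 for control/resting
    t_start: float      # seconds from trial start (inclusive)
    t_stop: float       # seconds (exclusive)
    f_start: int        # frame index at the schedule frame rate (inclusive)
    f_stop: int         # frame index (exclusive)

    @property
    def duration_s(self) -> float:
        return self.t_stop - self.t_start


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered, gap-free segmentation of one imaging trial."""

    mode: str                       # "stimulation" | "resting"
    frame_rate: float               # Hz of the acquisition this refers to
    n_stim_epochs: int
    segments: tuple[Segment, ...] = field(repr=False)

    def __post_init__(self) -> None:
        t = 0.0
        f = 0
        for seg in self.segments:
            if abs(seg.t_start - t) > 1e-9 or seg.f_start != f:
                raise ValueError("schedule segments must tile the trial without gaps")
            t, f = seg.t_stop, seg.f_stop

    @property
    def duration_s(self) -> float:
        return self.segments[-1].t_stop

    @property
    def n_frames(self) -> int:
        return self.segments[-1].f_stop

    @property
    def stim_onsets_s(self) -> tuple[float, ...]:
        """Stimulus onset times (start of the 1 s stimulation segment)."""
        return tuple(s.t_start for s in self.segments if s.label == "stimulation")

    @property
    def epoch_starts_s(self) -> tuple[float, ...]:
        """Start of each stimulation epoch (beginning of its 1 s baseline)."""
        return tuple(s.t_start for s in self.segments if s.label == "baseline")

    def segment_of_frame(self, frame: int) -> Segment:
        for seg in self.segments:
            if seg.f_start <= frame < seg.f_stop:
                return seg
        raise IndexError(f"frame {frame} outside schedule (0..{self.n_frames - 1})")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "frame_rate": self.frame_rate,
            "n_stim_epochs": self.n_stim_epochs,
            "segments": [
                {
                    "label": s.label,
                    "epoch": s.epoch,
                    "t_start": s.t_start,
                    "t_stop": s.t_stop,
                    "f_start": s.f_start,
                    "f_stop": s.f_stop,
                }
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrialSchedule":
        segs = tuple(Segment(**s) for s in d["segments"])
        return cls(
            mode=d["mode"],
            frame_rate=float(d["frame_rate"]),
            n_stim_epochs=int(d["n_stim_epochs"]),
            segments=segs,
        )


def make_trial_schedule(
    n_stim_epochs: int,
    frame_rate: float = 100.0,
    mode: Literal["stimulation", "resting"] = "stimulation",
    resting_s: float = RESTING_S,
) -> TrialSchedule:
    """Build the trial schedule used throughout the pipeline.

    In ``stimulation`` mode the trial alternates 15 s stimulation epochs
    (1 s baseline + 1 s stimulation + 13 s post) with 21 s control epochs,
    one control between every two consecutive stimulation epochs, so the
    total length is ``15*n + 21*(n-1)`` seconds.  In ``resting`` mode a
    single resting segment of ``resting_s`` seconds is returned.
    """
    if n_stim_epochs < 1:
        raise ValueError("n_stim_epochs must be >= 1")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if mode not in ("stimulation", "resting"):
        raise ValueError(f"unknown mode {mode!r}")

    def frames(t: float) -> int:
        return int(round(t * frame_rate))

    segments: list[Segment] = []
    t = 0.0

    def add(label: str, epoch: int, dur: float) -> None:
        nonlocal t
        segments.append(
            Segment(label, epoch, t, t + dur, frames(t), frames(t + dur))
        )
        t += dur

    if mode == "resting":
        add("resting", -1, resting_s)
    else:
        for e in range(n_stim_epochs):
            add("baseline", e, BASELINE_S)
            add("stimulation", e, STIM_S)
            add("post", e, POST_S)
            if e < n_stim_epochs - 1:
                add("control", -1, CONTROL_S)

    return TrialSchedule(
        mode=mode,
        frame_rate=float(frame_rate),
        n_stim_epochs=n_stim_epochs if mode == "stimulation" else 0,
        segments=tuple(segments),
    )
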