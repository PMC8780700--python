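"""Movement segmentation by zero-velocity crossings of the speed magnitude.

The speed magnitude epsilon = sqrt(vx**2 + vy**2) combines both trajectory
axes.  Candidate movements are extracted as one speed peak between two
valleys by a finite-state machine; because the filtered speed never reaches
exactly zero, "zero crossing" is implemented as hysteresis between a small
valley threshold and a higher peak threshold.

An out-and-back reach produces two speed bumps (go and return) separated by
a momentary near-zero dip at peak displacement; with ``merge_return`` on
(the default), consecutive segments separated by less than ``merge_gap``
seconds are merged so the unit of classification is the full reach.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .tracking import Trajectory

__all__ = [
    "Segment",
    "speed_magnitude",
    "segment_motion",
    "segment_trajectory",
    "segments_to_frame",
    "write_segments_csv",
    "read_segments_csv",
]

VALLEY_THRESHOLD = 2.0  # px/s: "zero" speed for valley detection
PEAK_THRESHOLD = 8.0    # px/s: a segment must exceed this to count as movement
MIN_SAMPLES = 5
MERGE_GAP = 0.3         # s: go/return bumps closer than this are one reach


@dataclass
class Segment:
    """A contiguous trajectory slice between two speed valleys, one peak inside."""

    start: int
    peak: int
    end: int  # inclusive
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray

    def __post_init__(self) -> None:
        if not (self.start < self.peak < self.end):
            raise ValueError("segment indices must satisfy start < peak < end")
        if self.n_s < 3:
            raise ValueError("segment must contain at least 3 samples")

    @property
    def n_s(self) -> int:
        return self.end - self.start + 1

    @property
    def start_t(self) -> float:
        return float(self.t[0])

    @property
    def end_t(self) -> float:
        return float(self.t[-1])

    @property
    def peak_t(self) -> float:
        return float(self.t[self.peak - self.start])


def speed_magnitude(trajectory: Trajectory) -> np.ndarray:
    """Pointwise speed epsilon = sqrt(vx**2 + vy**2), in px/s."""
    vx, vy = trajectory.vx, trajectory.vy
    if vx is None or vy is None:
        raise ValueError("trajectory has no velocity estimates")
    return np.hypot(np.asarray(vx, float), np.asarray(vy, float))


def segment_motion(
    speed: np.ndarray,
    t: np.ndarray | None = None,
    valley_threshold: float = VALLEY_THRESHOLD,
    peak_threshold: float = PEAK_THRESHOLD,
    min_samples: int = MIN_SAMPLES,
    merge_return: bool = True,
    merge_gap: float = MERGE_GAP,
) -> list[tuple[int, int, int]]:
    """Extract (start, peak, end) index triples of one-peak movement episodes.

    The finite-state machine opens a segment at the last sample with
    ``speed <= valley_threshold`` before the speed exceeds
    ``peak_threshold``, takes the argmax of speed as the peak, and closes at
    the first later sample back at or below the valley threshold.  Episodes
    that never exceed the peak threshold are ignored; segments shorter than
    ``min_samples`` are discarded; an episode still open at the end of the
    series is dropped.  With ``merge_return``, consecutive segments whose
    time gap is below ``merge_gap`` are merged into one.
    """
    if not 0 <= valley_threshold < peak_threshold:
        raise ValueError("thresholds must satisfy 0 <= valley < peak")
    speed = np.asarray(speed, float)
    n = len(speed)
    if t is None:
        t = np.arange(n, dtype=float)
    t = np.asarray(t, float)

    raw: list[tuple[int, int]] = []
    last_valley: int | None = None
    active_start: int | None = None
    for i in range(n):
        if active_start is None:
            if speed[i] <= valley_threshold:
                last_valley = i
            elif speed[i] > peak_threshold and last_valley is not None:
                active_start = last_valley
        else:
            if speed[i] <= valley_threshold:
                raw.append((active_start, i))
                active_start = None
                # this valley may also open the next segment: adjacent
                # segments share at most the boundary valley sample
                last_valley = i
    segs = [(s, e) for s, e in raw if e - s + 1 >= min_samples]

    if merge_return and segs:
        merged = [segs[0]]
        for s, e in segs[1:]:
            ps, pe = merged[-1]
            if t[s] - t[pe] <= merge_gap:
                merged[-1] = (ps, e)
            else:
                merged.append((s, e))
        segs = merged

    out = []
    for s, e in segs:
        peak = s + int(np.argmax(speed[s : e + 1]))
        if s < peak < e:
            out.append((s, peak, e))
        elif e - s >= 2:
            # argmax fell on an endpoint (plateau); keep the interior maximum
            interior = s + 1 + int(np.argmax(speed[s + 1 : e]))
            out.append((s, interior, e))
    return out


def segment_trajectory(trajectory: Trajectory, **kwargs) -> list[Segment]:
    """Segment a trajectory into movement episodes (see :func:`segment_motion`)."""
    eps = speed_magnitude(trajectory)
    triples = segment_motion(eps, t=trajectory.t, **kwargs)
    segs = []
    for s, p, e in triples:
        sl = slice(s, e + 1)
        segs.append(
            Segment(
                start=s,
                peak=p,
                end=e,
                t=trajectory.t[sl],
                x=trajectory.x[sl],
                y=trajectory.y[sl],
                vx=trajectory.vx[sl],
                vy=trajectory.vy[sl],
            )
        )
    return segs


def segments_to_frame(segments: list[Segment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "seg_id": np.arange(len(segments)),
            "start_idx": [s.start for s in segments],
            "peak_idx": [s.peak for s in segments],
            "end_idx": [s.end for s in segments],
            "start_t": [s.start_t for s in segments],
            "peak_t": [s.peak_t for s in segments],
            "end_t": [s.end_t for s in segments],
            "n_s": [s.n_s for s in segments],
        }
    )


def write_segments_csv(segments: list[Segment], path: str | Path) -> None:
    segments_to_frame(segments).to_csv(path, index=False, float_format="%.6f")


def read_segments_csv(path: str | Path, trajectory: Trajectory) -> list[Segment]:
    """Rebuild Segment objects from a segments CSV plus its source trajectory."""
    df = pd.read_csv(path)
    segs = []
    for row in df.itertuples(index=False):
        s, p, e = int(row.start_idx), int(row.peak_idx), int(row.end_idx)
        sl = slice(s, e + 1)
        segs.append(
            Segment(
                start=s,
                peak=p,
                end=e,
                t=trajectory.t[sl],
                x=trajectory.x[sl],
                y=trajectory.y[sl],
                vx=trajectory.vx[sl],
                vy=trajectory.vy[sl],
            )
        )
    return segs
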