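"""Position-threshold movement classifier.

The simplest intent detector mimics a mechanical head switch: during
calibration the user performs a set of reaching movements, and the decision
threshold ``x_t`` is placed 20 px closer to the rest position than the mean
maximum horizontal displacement ``max(x_h)``.  Reaches toward either side
are supported (positive or negative ``x_t`` relative to the reference).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .segmentation import Segment
from .tracking import Trajectory

__all__ = [
    "ThresholdModel",
    "CalibrationError",
    "calibrate_threshold",
    "threshold_score",
    "threshold_decision",
    "classify_threshold_stream",
]

MARGIN_PX = 20.0


class CalibrationError(ValueError):
    """Calibration movements are empty or disagree in direction."""


@dataclass(frozen=True)
class ThresholdModel:
    """Calibrated horizontal threshold relative to the rest position ``x_h0``."""

    x_h0: float
    direction: int  # +1 or -1: sign of the calibrated reach
    x_t: float
    margin_px: float = MARGIN_PX

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        if (self.x_t - self.x_h0) * self.direction <= 0:
            raise ValueError("threshold must lie on the calibrated side of x_h0")

    @property
    def decision_level(self) -> float:
        """Score value at the calibrated operating point."""
        return self.direction * (self.x_t - self.x_h0)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdModel":
        raw = json.loads(Path(path).read_text())
        return cls(
            x_h0=float(raw["x_h0"]),
            direction=int(raw["direction"]),
            x_t=float(raw["x_t"]),
            margin_px=float(raw.get("margin_px", MARGIN_PX)),
        )


def _movement_extremum(x: np.ndarray, x_h0: float) -> float:
    """The x value of largest absolute excursion from the reference."""
    x = np.asarray(x, float)
    if x.size == 0:
        raise CalibrationError("empty calibration movement")
    return float(x[np.argmax(np.abs(x - x_h0))])


def calibrate_threshold(
    movements: Iterable[Segment | Sequence[float] | np.ndarray],
    x_h0: float,
    margin_px: float = MARGIN_PX,
) -> ThresholdModel:
    """Calibrate ``x_t`` from the extrema of reaching movements.

    Each movement may be a :class:`Segment` or a bare array of x positions.
    The threshold is the mean extremal ``x_h`` pulled ``margin_px`` pixels
    back toward the reference; all calibration movements must reach to the
    same side of ``x_h0``.
    """
    extrema = []
    for mv in movements:
        x = mv.x if isinstance(mv, Segment) else np.asarray(mv, float)
        extrema.append(_movement_extremum(x, x_h0))
    if not extrema:
        raise CalibrationError("no calibration movements supplied")
    extrema = np.array(extrema)
    signs = np.sign(extrema - x_h0)
    if np.any(signs == 0) or len(set(signs.tolist())) > 1:
        raise CalibrationError("calibration movements disagree in direction")
    direction = int(signs[0])
    x_t = float(extrema.mean() - direction * margin_px)
    return ThresholdModel(x_h0=x_h0, direction=direction, x_t=x_t, margin_px=margin_px)


def threshold_score(segment: Segment | np.ndarray, model: ThresholdModel) -> float:
    """Signed excursion of the segment toward the calibrated direction (px).

    This is the quantity swept when building a ROC curve for the threshold
    method; the calibrated operating point accepts a segment when the score
    reaches ``direction * (x_t - x_h0)``.
    """
    x = segment.x if isinstance(segment, Segment) else np.asarray(segment, float)
    return float(np.max(model.direction * (x - model.x_h0)))


def threshold_decision(segment: Segment | np.ndarray, model: ThresholdModel) -> bool:
    return threshold_score(segment, model) >= model.decision_level


def classify_threshold_stream(trajectory: Trajectory, model: ThresholdModel) -> np.ndarray:
    """Detect switch activations directly on the trajectory (no segmentation).

    Emits one event per excursion episode: the detector fires at the first
    sample crossing ``x_t`` in the calibrated direction and re-arms only
    after the head returns within the threshold, so boundary jitter cannot
    produce duplicate activations.  Returns event timestamps in seconds.
    """
    rel = model.direction * (np.asarray(trajectory.x, float) - model.x_h0)
    level = model.decision_level
    events = []
    armed = True
    for ti, ri in zip(trajectory.t, rel):
        if armed and ri >= level:
            events.append(float(ti))
            armed = False
        elif not armed and ri < level:
            armed = True
    return np.asarray(events)
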