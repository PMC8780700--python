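"""Synthetic head-movement sessions for end-to-end testing of the pipeline.

Sessions emulate a seated user operating a head switch: functional
out-and-back reaching movements with bell-shaped (minimum-jerk) speed
profiles toward a preferred direction, separated by rest, with a
ground-truth switch event at the peak displacement of every valid reach.
Distractor ("invalid") movements reproduce the confusion modes a classifier
faces in practice — equal-amplitude reaches in a different direction,
same-direction reaches at half amplitude, or amplitude-matched reaches with
a different velocity profile.  Two involuntary-movement models (sinusoidal
tremor and choreiform jerks: low-pass-filtered heavy-tailed displacement
pulses) approximate the movement disorders that degrade real sessions; no
clinical fidelity is claimed.

All generators are pure functions of (config, seed): identical inputs give
identical outputs, byte-for-byte through the CSV writers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .tracking import Trajectory, kalman_track

__all__ = [
    "MovementSpec",
    "InvoluntaryConfig",
    "SessionConfig",
    "SyntheticSession",
    "SchedulingError",
    "gen_reach",
    "gen_involuntary",
    "gen_session",
    "render_frames",
    "render_to_dir",
]

# Study-condition defaults: a comfortable lateral head reach on a 300 px
# canonical ROI at webcam rate.  See docs/methods.md for the rationale.
FRAME_RATE = 30.0
REACH_AMPLITUDE = 120.0   # px
REACH_DURATION = 0.8      # s, full out-and-back
NOISE_SIGMA = 0.5         # px, tracking measurement jitter
SESSION_SIGMA_A = 30.0    # px/s^2, Kalman process noise for session smoothing
WARMUP = 1.5              # s of rest before the first movement
REST_RANGE = (1.5, 2.5)   # s of rest between movements (scanning-keyboard pacing)


class SchedulingError(ValueError):
    """The configured movements do not fit inside the session duration."""


@dataclass(frozen=True)
class MovementSpec:
    """One scheduled movement: amplitude (px), unit direction, duration (s)."""

    amplitude: float
    direction: tuple[float, float]
    duration: float
    profile: str = "minjerk"  # or "ramp"
    valid: bool = False
    kind: str = "reach"


@dataclass(frozen=True)
class InvoluntaryConfig:
    """Involuntary-movement model: sinusoidal tremor or choreiform jerks."""

    kind: str                 # "tremor" | "choreiform"
    amplitude: float          # px, peak displacement scale
    frequency: float = 4.0    # Hz (tremor)
    rate: float = 0.5         # impulses/s (choreiform)
    pulse_duration: float = 0.3   # s, width of each choreiform pulse
    cutoff: float = 3.0       # Hz, low-pass cutoff smoothing the pulses

    def __post_init__(self) -> None:
        if self.kind not in ("tremor", "choreiform"):
            raise ValueError(f"unknown involuntary model {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass
class SessionConfig:
    """Parameters of one synthetic session (the emulated study conditions)."""

    frame_rate: float = FRAME_RATE
    duration: float | None = None  # s; None = fit to the scheduled content
    n_valid_reaches: int = 8
    reach_amplitude: float = REACH_AMPLITUDE
    reach_direction: tuple[float, float] = (1.0, 0.0)
    reach_duration: float = REACH_DURATION
    n_invalid_movements: int = 0
    invalid_kind: str = "mixed"  # orthogonal|opposite|half_amplitude|slow_matched|mixed
    amplitude_jitter: float = 0.08  # relative sd of per-movement amplitude
    duration_jitter: float = 0.08   # relative sd of per-movement duration
    involuntary: InvoluntaryConfig | None = None
    noise_sigma: float = NOISE_SIGMA
    kalman_sigma_a: float = SESSION_SIGMA_A
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SessionConfig":
        d = json.loads(Path(path).read_text())
        if d.get("involuntary"):
            d["involuntary"] = InvoluntaryConfig(**d["involuntary"])
        if "reach_direction" in d:
            d["reach_direction"] = tuple(d["reach_direction"])
        return cls(**d)


@dataclass
class SyntheticSession:
    """Generated session: true and observed kinematics plus ground truth."""

    config: SessionConfig
    true: Trajectory
    observed: Trajectory
    truth_times: np.ndarray          # one switch event per valid reach
    annotations: pd.DataFrame        # per-movement onset/offset/kind/valid

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.observed.to_csv(out / "trajectory.csv")
        self.true.to_csv(out / "trajectory_true.csv")
        pd.DataFrame({"t_switch": self.truth_times}).to_csv(
            out / "truth.csv", index=False, float_format="%.6f"
        )
        self.annotations.to_csv(out / "annotations.csv", index=False, float_format="%.6f")
        self.config.to_json(out / "config.json")


# ---------------------------------------------------------------------------
# Movement primitives


def _minjerk(tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-jerk position profile and its derivative w.r.t. tau on [0, 1]."""
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    ds = 30 * tau**2 - 60 * tau**3 + 30 * tau**4
    return s, ds


def gen_reach(
    amplitude: float,
    direction: tuple[float, float],
    duration: float,
    frame_rate: float,
    profile: str = "minjerk",
) -> tuple[np.ndarray, np.ndarray]:
    """Out-and-back reach fragment: positions (T, 2) and analytic velocities.

    The go phase follows a minimum-jerk profile over the first half of
    ``duration`` (peak speed ``1.875 * amplitude / (duration / 2)``), the
    return phase mirrors it; the movement starts and ends at rest at the
    origin.  A "ramp" profile (constant speed out and back) is available
    for velocity-structure mismatch experiments.
    """
    if amplitude <= 0 or duration <= 0 or frame_rate <= 0:
        raise ValueError("amplitude, duration and frame_rate must be positive")
    u = np.asarray(direction, float)
    u = u / np.linalg.norm(u)
    n = int(round(duration * frame_rate)) + 1
    t = np.arange(n) / frame_rate
    half = duration / 2.0
    going = t <= half
    tau = np.where(going, t / half, np.clip((duration - t) / half, 0.0, 1.0))
    if profile == "minjerk":
        s, ds = _minjerk(tau)
    elif profile == "ramp":
        s, ds = tau, np.ones_like(tau)
    else:
        raise ValueError(f"unknown profile {profile!r}")
    disp = amplitude * s
    speed = amplitude * ds / half * np.where(going, 1.0, -1.0)
    return disp[:, None] * u, speed[:, None] * u


def gen_involuntary(
    config: InvoluntaryConfig,
    duration: float,
    frame_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Additive involuntary displacement (T, 2) and its impulse times.

    Tremor: a zero-mean sinusoid of the configured amplitude and frequency
    along a random fixed direction with random phase.  Choreiform:
    Poisson-timed displacement pulses with heavy-tailed (Student-t, 3 df)
    magnitudes, smoothed by a zero-phase low-pass Butterworth filter.
    Returns impulse times only for the choreiform model (empty otherwise).
    """
    n = int(round(duration * frame_rate)) + 1
    t = np.arange(n) / frame_rate
    if config.amplitude == 0:
        return np.zeros((n, 2)), np.array([])
    if config.kind == "tremor":
        theta = rng.uniform(0, 2 * np.pi)
        u = np.array([np.cos(theta), np.sin(theta)])
        phase = rng.uniform(0, 2 * np.pi)
        sig = config.amplitude * np.sin(2 * np.pi * config.frequency * t + phase)
        return sig[:, None] * u, np.array([])
    # choreiform
    count = rng.poisson(config.rate * duration)
    times = np.sort(rng.uniform(0.0, duration, size=count))
    mags = config.amplitude * np.clip(np.abs(rng.standard_t(df=3, size=count)), 0.3, 3.0)
    thetas = rng.uniform(0, 2 * np.pi, size=count)
    sig = np.zeros((n, 2))
    half_w = config.pulse_duration / 2.0
    for ti, mag, th in zip(times, mags, thetas):
        mask = np.abs(t - ti) <= half_w
        sig[mask] += mag * np.array([np.cos(th), np.sin(th)])
    if count and n > 18:
        nyq = frame_rate / 2.0
        b, a = butter(2, min(config.cutoff / nyq, 0.99))
        sig = filtfilt(b, a, sig, axis=0)
    return sig, times


def _rotate90(v: tuple[float, float]) -> tuple[float, float]:
    return (-v[1], v[0])


def _invalid_specs(config: SessionConfig) -> list[MovementSpec]:
    """Distractor movements for the configured confusion mode."""
    base = dict(
        amplitude=config.reach_amplitude,
        direction=tuple(config.reach_direction),
        duration=config.reach_duration,
        valid=False,
    )
    def make(kind: str) -> MovementSpec:
        if kind == "orthogonal":
            return MovementSpec(**{**base, "direction": _rotate90(config.reach_direction), "kind": kind})
        if kind == "opposite":
            d = config.reach_direction
            return MovementSpec(**{**base, "direction": (-d[0], -d[1]), "kind": kind})
        if kind == "half_amplitude":
            return MovementSpec(**{**base, "amplitude": config.reach_amplitude * 0.5, "kind": kind})
        if kind == "slow_matched":
            # same endpoint amplitude, 3x slower: distinct velocity structure
            return MovementSpec(**{**base, "duration": config.reach_duration * 3.0, "kind": kind})
        raise ValueError(f"unknown invalid movement kind {kind!r}")

    kinds = (
        ["orthogonal", "half_amplitude", "opposite"]
        if config.invalid_kind == "mixed"
        else [config.invalid_kind]
    )
    return [make(kinds[i % len(kinds)]) for i in range(config.n_invalid_movements)]


def gen_session(config: SessionConfig) -> SyntheticSession:
    """Generate one full session: schedule, kinematics, noise, ground truth.

    Valid reaches and distractors are interleaved in random order with rest
    gaps between them; each valid reach contributes one switch event at its
    peak displacement.  The observed trajectory adds measurement jitter to
    the true positions; its velocities come from the same constant-velocity
    Kalman filter the tracking front-end uses (so downstream modules see
    filter-grade velocity estimates), except in the fully noise-free case
    where the analytic velocities are passed through.
    """
    rng = np.random.default_rng(config.seed)
    fr = config.frame_rate

    specs = [
        MovementSpec(
            amplitude=config.reach_amplitude,
            direction=tuple(config.reach_direction),
            duration=config.reach_duration,
            valid=True,
        )
        for _ in range(config.n_valid_reaches)
    ] + _invalid_specs(config)
    specs = [specs[i] for i in rng.permutation(len(specs))]

    # jitter per-movement amplitude/duration (human variability)
    jittered = []
    for sp in specs:
        amp = sp.amplitude * max(0.2, 1.0 + config.amplitude_jitter * rng.standard_normal())
        dur = sp.duration * max(0.2, 1.0 + config.duration_jitter * rng.standard_normal())
        jittered.append(MovementSpec(amp, sp.direction, dur, sp.profile, sp.valid, sp.kind))

    onsets = []
    cursor = WARMUP
    for sp in jittered:
        onsets.append(cursor)
        cursor += sp.duration + rng.uniform(*REST_RANGE)
    total = cursor + WARMUP
    if config.duration is not None:
        if total > config.duration + 1e-9:
            raise SchedulingError(
                f"movements need {total:.1f}s but session duration is {config.duration}s"
            )
        total = config.duration

    n = int(round(total * fr)) + 1
    t = np.arange(n) / fr
    pos = np.zeros((n, 2))
    vel = np.zeros((n, 2))
    truth = []
    ann = []
    for sp, onset in zip(jittered, onsets):
        p, v = gen_reach(sp.amplitude, sp.direction, sp.duration, fr, sp.profile)
        i0 = int(round(onset * fr))
        i1 = min(i0 + len(p), n)
        pos[i0:i1] += p[: i1 - i0]
        vel[i0:i1] += v[: i1 - i0]
        if sp.valid:
            truth.append(t[i0] + sp.duration / 2.0)
        ann.append(
            {
                "kind": sp.kind if not sp.valid else "valid_reach",
                "valid": sp.valid,
                "t_on": t[i0],
                "t_off": t[i0] + sp.duration,
                "amplitude": sp.amplitude,
                "duration": sp.duration,
            }
        )

    if config.involuntary is not None:
        inv_pos, _ = gen_involuntary(config.involuntary, total, fr, rng)
        inv_pos = inv_pos[:n]
        pos = pos + inv_pos
        vel = vel + np.gradient(inv_pos, t, axis=0)

    true_traj = Trajectory(
        t=t, x_m=pos[:, 0], y_m=pos[:, 1],
        x=pos[:, 0], y=pos[:, 1], vx=vel[:, 0], vy=vel[:, 1],
        frame_rate=fr, reference_xy=(0.0, 0.0),
    )

    if config.noise_sigma > 0:
        zx = pos[:, 0] + rng.normal(0.0, config.noise_sigma, n)
        zy = pos[:, 1] + rng.normal(0.0, config.noise_sigma, n)
        fx, fy, fvx, fvy = kalman_track(
            t, zx, zy, sigma_a=config.kalman_sigma_a, sigma_m=max(config.noise_sigma, 0.25)
        )
        observed = Trajectory(
            t=t, x_m=zx, y_m=zy, x=fx, y=fy, vx=fvx, vy=fvy,
            frame_rate=fr, reference_xy=(0.0, 0.0),
        )
    else:
        observed = Trajectory(
            t=t, x_m=pos[:, 0], y_m=pos[:, 1],
            x=pos[:, 0], y=pos[:, 1], vx=vel[:, 0], vy=vel[:, 1],
            frame_rate=fr, reference_xy=(0.0, 0.0),
        )

    return SyntheticSession(
        config=config,
        true=true_traj,
        observed=observed,
        truth_times=np.asarray(truth),
        annotations=pd.DataFrame(ann),
    )


# ---------------------------------------------------------------------------
# Rendering


BACKGROUND_RGB = (70, 90, 120)
SKIN_RGB = (214, 166, 122)
HAIR_RGB = (60, 42, 28)
FEATURE_RGB = (150, 100, 70)  # distinct-hue interior band (informative histogram)


def _draw_head(frame: np.ndarray, cx: float, cy: float, rx: float, ry: float) -> None:
    """Paint an ellipse head with hair cap and an interior feature band."""
    h, w = frame.shape[:2]
    x0, x1 = max(0, int(cx - rx - 2)), min(w, int(cx + rx + 3))
    y0, y1 = max(0, int(cy - ry - 2)), min(h, int(cy + ry + 3))
    ys, xs = np.mgrid[y0:y1, x0:x1]
    d2 = ((xs - cx) / rx) ** 2 + ((ys - cy) / ry) ** 2
    inside = d2 <= 1.0
    region = frame[y0:y1, x0:x1]
    region[inside] = SKIN_RGB
    hair = inside & (ys < cy - 0.55 * ry)
    region[hair] = HAIR_RGB
    feat = inside & (np.abs(ys - (cy + 0.15 * ry)) < 0.18 * ry) & (np.abs(xs - cx) < 0.55 * rx)
    region[feat] = FEATURE_RGB


def render_frames(
    session: SyntheticSession,
    frame_size: tuple[int, int] = (640, 480),
    head_radii: tuple[float, float] = (50.0, 62.0),
) -> Iterator[np.ndarray]:
    """Yield uint8 RGB frames of the session's true head motion.

    The head is a skin-tone ellipse (with hair cap and a distinct-hue
    interior band so HSV histograms are informative) on a static
    contrasting background; its centre follows the true trajectory offset
    from the frame centre.  Raises if any position leaves the frame.
    """
    w, h = frame_size
    rx, ry = head_radii
    cx0, cy0 = w / 2.0, h / 2.0
    xs = session.true.x + cx0
    ys = session.true.y + cy0
    if (
        (xs - rx).min() < 0 or (xs + rx).max() > w
        or (ys - ry).min() < 0 or (ys + ry).max() > h
    ):
        raise ValueError("trajectory leaves the frame after offsetting; shrink the amplitude")
    base = np.empty((h, w, 3), np.uint8)
    base[:] = BACKGROUND_RGB
    for cx, cy in zip(xs, ys):
        frame = base.copy()
        _draw_head(frame, cx, cy, rx, ry)
        yield frame


def render_to_dir(
    session: SyntheticSession,
    out_dir: str | Path,
    frame_size: tuple[int, int] = (640, 480),
    head_radii: tuple[float, float] = (50.0, 62.0),
) -> Path:
    """Write the rendered session as a numbered PNG sequence plus ground truth."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(render_frames(session, frame_size, head_radii)):
        iio.imwrite(out / f"frame_{i:05d}.png", frame)
    w, h = frame_size
    pd.DataFrame(
        {
            "t": session.true.t,
            "cx": session.true.x + w / 2.0,
            "cy": session.true.y + h / 2.0,
        }
    ).to_csv(out / "ground_truth.csv", index=False, float_format="%.6f")
    return out
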