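"""Head detection, ROI normalization, mean-shift tracking and Kalman smoothing.

The tracking front-end turns a webcam video of a seated user into a per-frame
head trajectory expressed in a canonical region-of-interest (ROI) frame:

1. detect the face once in the first frame (pluggable detector; the largest
   candidate rectangle wins, assuming the user is closest to the camera);
2. fix a normalization transform so the ROI is ``3 * w_h0`` wide and the face
   starts centred — the same transform is applied to every later frame, which
   makes trajectories comparable across sessions and camera distances;
3. track the head with mean shift over an HSV color histogram, weighting
   pixels by a posterior-probability-measure style ratio;
4. smooth positions and estimate velocities with a constant-velocity Kalman
   filter.  The filtered velocity feeds the downstream speed magnitude
   epsilon = sqrt(vx**2 + vy**2).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from skimage import measure
from skimage.color import rgb2hsv
from skimage.transform import resize
from skimage.util import img_as_float

__all__ = [
    "TrackingError",
    "NoFaceDetectedError",
    "LostTargetError",
    "ReferencePose",
    "TargetModel",
    "Trajectory",
    "NormalizationTransform",
    "TrackerConfig",
    "detect_reference",
    "skin_blob_detector",
    "normalize_reference",
    "build_target_model",
    "meanshift_step",
    "kalman_track",
    "track_video",
    "iter_frames",
]

# Defaults selected empirically on rendered sessions (see docs/methods.md):
# sigma_a must cover reach accelerations (~3000 px/s^2 in ROI units) or the
# filter lags the head during fast movements.
KALMAN_SIGMA_A = 3000.0  # px/s^2, process (white-acceleration) noise
KALMAN_SIGMA_M = 2.0     # px, measurement noise
ROI_WIDTH = 300          # canonical ROI width in px; ROI is square
HUE_BINS = 16
SAT_BINS = 8


class TrackingError(RuntimeError):
    """Base class for tracking failures."""


class NoFaceDetectedError(TrackingError):
    """The configured face detector returned no candidate rectangles."""


class LostTargetError(TrackingError):
    """Mean-shift similarity fell below the lost-target floor."""


@dataclass(frozen=True)
class ReferencePose:
    """Initial face rectangle ``(p_h0, s_h0)`` defining the user's rest frame.

    Rectangles are ``(x, y, w, h)`` with origin top-left, x rightward,
    y downward, half-open extent.
    """

    x: float
    y: float
    w: float
    h: float
    frame_size: tuple[int, int]  # (width, height)
    roi_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("reference rectangle must have positive size")
        fw, fh = self.frame_size
        if self.x < 0 or self.y < 0 or self.x + self.w > fw or self.y + self.h > fh:
            raise ValueError("reference rectangle lies outside frame bounds")
        if self.roi_scale <= 0:
            raise ValueError("roi_scale must be positive")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def area(self) -> float:
        return self.w * self.h


@dataclass
class TargetModel:
    """Color-histogram target for mean-shift tracking.

    ``hist`` is the target histogram over quantized (hue, saturation);
    ``bg_hist`` the background histogram used by the PPM-style ratio
    weighting.  The target rectangle is the reference rectangle with both
    dimensions reduced by 20% (to drop hair pixels); the search rectangle is
    50% larger than the target.
    """

    hist: np.ndarray
    bg_hist: np.ndarray
    target_size: tuple[float, float]
    search_size: tuple[float, float]
    hue_bins: int = HUE_BINS
    sat_bins: int = SAT_BINS
    weight_strategy: str = "ppm"

    def __post_init__(self) -> None:
        tw, th = self.target_size
        sw, sh = self.search_size
        if tw <= 0 or th <= 0:
            raise ValueError("degenerate target rectangle")
        if not (sw > tw and sh > th):
            raise ValueError("search rectangle must strictly contain the target")

    def pixel_weights(self, bin_idx: np.ndarray) -> np.ndarray:
        """Per-pixel weights for the given flattened histogram-bin indices."""
        t = self.hist.ravel()[bin_idx]
        if self.weight_strategy == "ppm":
            b = self.bg_hist.ravel()[bin_idx]
            with np.errstate(invalid="ignore"):
                w = t / (t + b)
            return np.nan_to_num(w)
        if self.weight_strategy == "backproject":
            return t / (t.max() if t.max() > 0 else 1.0)
        raise ValueError(f"unknown weight strategy {self.weight_strategy!r}")


@dataclass
class Trajectory:
    """Per-frame head kinematics at (approximately) fixed frame interval.

    ``x_m, y_m`` are raw measured positions; ``x, y, vx, vy`` are the Kalman
    filtered position and velocity.  ``reference_xy`` is the rest position of
    the head in the same coordinates (the ROI centre for tracked video, the
    origin for synthetic sessions).
    """

    t: np.ndarray
    x_m: np.ndarray
    y_m: np.ndarray
    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    frame_rate: float = 30.0
    reference: ReferencePose | None = None
    reference_xy: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        arrays = [self.t, self.x_m, self.y_m, self.x, self.y, self.vx, self.vy]
        n = len(self.t)
        if n == 0:
            raise ValueError("trajectory must be non-empty")
        if any(len(a) != n for a in arrays):
            raise ValueError("trajectory columns must have equal length")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "x_m": self.x_m,
                "y_m": self.y_m,
                "x": self.x,
                "y": self.y,
                "vx": self.vx,
                "vy": self.vy,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        frame_rate: float | None = None,
        reference_xy: tuple[float, float] = (0.0, 0.0),
    ) -> "Trajectory":
        t = df["t"].to_numpy(float)
        if frame_rate is None:
            frame_rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 30.0
        return cls(
            t=t,
            x_m=df["x_m"].to_numpy(float),
            y_m=df["y_m"].to_numpy(float),
            x=df["x"].to_numpy(float),
            y=df["y"].to_numpy(float),
            vx=df["vx"].to_numpy(float),
            vy=df["vy"].to_numpy(float),
            frame_rate=frame_rate,
            reference_xy=reference_xy,
        )

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "Trajectory":
        return cls.from_frame(pd.read_csv(path), **kwargs)


# ---------------------------------------------------------------------------
# Detection


def skin_blob_detector(
    image: np.ndarray,
    hue_range: tuple[float, float] = (0.02, 0.16),
    min_saturation: float = 0.15,
    min_value: float = 0.25,
    min_area: int = 64,
) -> list[tuple[float, float, float, float]]:
    """Detect face-like regions as connected skin-tone blobs.

    A lightweight stand-in for a pretrained frontal-face cascade: thresholds
    the image in HSV around skin hues, labels connected components and
    returns their bounding boxes as ``(x, y, w, h)``.  Works reliably on the
    synthetic renderer's faces and on roughly uniform skin regions.
    """
    hsv = rgb2hsv(img_as_float(image))
    mask = (
        (hsv[..., 0] >= hue_range[0])
        & (hsv[..., 0] <= hue_range[1])
        & (hsv[..., 1] >= min_saturation)
        & (hsv[..., 2] >= min_value)
    )
    labels = measure.label(mask)
    boxes = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        r0, c0, r1, c1 = region.bbox
        boxes.append((float(c0), float(r0), float(c1 - c0), float(r1 - r0)))
    return boxes


Detector = Callable[[np.ndarray], Sequence[tuple[float, float, float, float]]]


def detect_reference(image: np.ndarray, detector: Detector | None = None) -> ReferencePose:
    """Detect the user's head in ``image`` and return the reference pose.

    Among all candidate rectangles only the largest is analyzed (the user is
    assumed closest to the camera, so other faces in view are ignored).
    """
    if image is None or np.ndim(image) < 2 or image.size == 0:
        raise ValueError("invalid or empty image")
    if detector is None:
        detector = skin_blob_detector
    candidates = list(detector(image))
    if not candidates:
        raise NoFaceDetectedError("no face candidate detected in the first frame")
    x, y, w, h = max(candidates, key=lambda r: r[2] * r[3])
    fh, fw = image.shape[:2]
    return ReferencePose(x=x, y=y, w=w, h=h, frame_size=(fw, fh))


# ---------------------------------------------------------------------------
# Normalization


@dataclass(frozen=True)
class NormalizationTransform:
    """Fixed crop-and-scale transform from source frames to the canonical ROI.

    The crop window is centred on the initially detected face centre with
    side ``3 * w_h0`` (so the ROI width is three face widths), then resized
    to ``roi_width`` square.  The transform is computed once from the first
    frame and applied unchanged to every subsequent frame.
    """

    center: tuple[float, float]
    crop_half: float
    roi_width: int

    @property
    def scale(self) -> float:
        return self.roi_width / (2.0 * self.crop_half)

    def apply(self, image: np.ndarray) -> np.ndarray:
        img = img_as_float(image)
        fh, fw = img.shape[:2]
        cx, cy = self.center
        x0 = int(round(cx - self.crop_half))
        y0 = int(round(cy - self.crop_half))
        side = int(round(2.0 * self.crop_half))
        pad_l = max(0, -x0)
        pad_t = max(0, -y0)
        pad_r = max(0, x0 + side - fw)
        pad_b = max(0, y0 + side - fh)
        if pad_l or pad_t or pad_r or pad_b:
            widths = ((pad_t, pad_b), (pad_l, pad_r)) + ((0, 0),) * (img.ndim - 2)
            img = np.pad(img, widths, mode="edge")
            x0 += pad_l
            y0 += pad_t
        crop = img[y0 : y0 + side, x0 : x0 + side]
        out_shape = (self.roi_width, self.roi_width) + crop.shape[2:]
        return resize(crop, out_shape, order=1, anti_aliasing=False, preserve_range=True)

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        """Map (N, 2) frame coordinates into ROI coordinates."""
        pts = np.asarray(pts, float)
        cx, cy = self.center
        origin = np.array(
            [round(cx - self.crop_half), round(cy - self.crop_half)], float
        )
        return (pts - origin) * self.scale


def normalize_reference(
    reference: ReferencePose, image: np.ndarray, roi_width: int = ROI_WIDTH
) -> tuple[np.ndarray, ReferencePose, NormalizationTransform]:
    """Scale and centre the reference frame so the ROI width is ``3 * w_h0``.

    Returns the normalized image, the reference pose re-expressed in ROI
    coordinates (face centred), and the reusable transform.
    """
    fh, fw = image.shape[:2]
    if (fw, fh) != reference.frame_size:
        raise ValueError("image size does not match reference frame_size")
    transform = NormalizationTransform(
        center=reference.center, crop_half=1.5 * reference.w, roi_width=roi_width
    )
    roi = transform.apply(image)
    s = transform.scale
    w, h = reference.w * s, reference.h * s
    ref_roi = ReferencePose(
        x=roi_width / 2.0 - w / 2.0,
        y=roi_width / 2.0 - h / 2.0,
        w=w,
        h=h,
        frame_size=(roi_width, roi_width),
        roi_scale=s,
    )
    return roi, ref_roi, transform


# ---------------------------------------------------------------------------
# Mean-shift target model


def _hs_bin_indices(patch: np.ndarray, hue_bins: int, sat_bins: int) -> np.ndarray:
    """Flattened (hue, saturation) histogram-bin index per pixel."""
    hsv = rgb2hsv(patch) if patch.ndim == 3 else np.stack([patch] * 3, -1)
    hi = np.minimum((hsv[..., 0] * hue_bins).astype(int), hue_bins - 1)
    si = np.minimum((hsv[..., 1] * sat_bins).astype(int), sat_bins - 1)
    return hi * sat_bins + si


def _rect_slice(center: tuple[float, float], size: tuple[float, float], bounds: tuple[int, int]):
    cx, cy = center
    w, h = size
    bw, bh = bounds
    x0 = max(0, int(round(cx - w / 2.0)))
    y0 = max(0, int(round(cy - h / 2.0)))
    x1 = min(bw, int(round(cx + w / 2.0)))
    y1 = min(bh, int(round(cy + h / 2.0)))
    return x0, y0, x1, y1


def build_target_model(
    roi_image: np.ndarray,
    reference: ReferencePose,
    hue_bins: int = HUE_BINS,
    sat_bins: int = SAT_BINS,
    shrink: float = 0.20,
    search_factor: float = 1.5,
    weight_strategy: str = "ppm",
) -> TargetModel:
    """Build the HSV histogram target from the 20%-shrunk face rectangle.

    The shrink partially removes hair pixels; the background histogram is
    estimated from all ROI pixels outside the target rectangle, which the
    PPM-style ratio uses to down-weight colors shared with the background.
    """
    tw, th = reference.w * (1.0 - shrink), reference.h * (1.0 - shrink)
    if tw <= 0 or th <= 0:
        raise ValueError("degenerate (zero-area) target rectangle")
    # search region: 50% larger than the original (unshrunk) scaled rectangle,
    # so the full head blob plus inter-frame motion stays inside it
    sw, sh = reference.w * search_factor, reference.h * search_factor
    img = img_as_float(roi_image)
    fh, fw = img.shape[:2]
    bins = _hs_bin_indices(img, hue_bins, sat_bins)
    x0, y0, x1, y1 = _rect_slice(reference.center, (tw, th), (fw, fh))
    if x1 <= x0 or y1 <= y0:
        raise ValueError("degenerate (zero-area) target rectangle")
    n_bins = hue_bins * sat_bins
    inside = np.zeros((fh, fw), bool)
    inside[y0:y1, x0:x1] = True
    hist = np.bincount(bins[inside].ravel(), minlength=n_bins).astype(float)
    bg = np.bincount(bins[~inside].ravel(), minlength=n_bins).astype(float)
    hist /= max(hist.sum(), 1.0)
    bg /= max(bg.sum(), 1.0)
    return TargetModel(
        hist=hist.reshape(hue_bins, sat_bins),
        bg_hist=bg.reshape(hue_bins, sat_bins),
        target_size=(tw, th),
        search_size=(sw, sh),
        hue_bins=hue_bins,
        sat_bins=sat_bins,
        weight_strategy=weight_strategy,
    )


def meanshift_step(
    frame: np.ndarray,
    model: TargetModel,
    previous: tuple[float, float],
    max_iter: int = 20,
    tol: float = 1.0,
    similarity_floor: float = 0.05,
) -> tuple[float, float]:
    """One tracking update: mean-shift the target window to the local mode.

    Pixel weights come from the model's similarity strategy (default: the
    PPM-style ratio of target to target-plus-background histogram mass); the
    new position is the weight centroid, iterated until the shift is below
    ``tol`` px or ``max_iter`` is reached.  The result never leaves the
    search region centred on ``previous``.
    """
    img = img_as_float(frame)
    fh, fw = img.shape[:2]
    sx0, sy0, sx1, sy1 = _rect_slice(previous, model.search_size, (fw, fh))
    if sx1 <= sx0 or sy1 <= sy0:
        raise LostTargetError("search region outside frame")
    window = img[sy0:sy1, sx0:sx1]
    bins = _hs_bin_indices(window, model.hue_bins, model.sat_bins)
    weights = model.pixel_weights(bins)
    ys, xs = np.mgrid[sy0:sy1, sx0:sx1]
    cx, cy = previous
    # the centroid window matches the search rectangle: the target blob fits
    # inside it, so the weight centroid seeks the blob mode without the
    # plateau stall a target-sized window exhibits on flat weight regions
    for _ in range(max_iter):
        tx0, ty0, tx1, ty1 = _rect_slice((cx, cy), model.search_size, (fw, fh))
        tx0, ty0 = max(tx0, sx0), max(ty0, sy0)
        tx1, ty1 = min(tx1, sx1), min(ty1, sy1)
        sub = np.s_[ty0 - sy0 : ty1 - sy0, tx0 - sx0 : tx1 - sx0]
        w = weights[sub]
        mass = w.sum()
        if mass <= 0:
            raise LostTargetError("target similarity vanished in search window")
        nx = float((w * xs[sub]).sum() / mass)
        ny = float((w * ys[sub]).sum() / mass)
        shift = math.hypot(nx - cx, ny - cy)
        cx, cy = nx, ny
        if shift < tol:
            break
    # clamp to the search region
    cx = min(max(cx, sx0), sx1 - 1)
    cy = min(max(cy, sy0), sy1 - 1)
    tx0, ty0, tx1, ty1 = _rect_slice((cx, cy), model.target_size, (fw, fh))
    sub = np.s_[max(ty0, sy0) - sy0 : min(ty1, sy1) - sy0, max(tx0, sx0) - sx0 : min(tx1, sx1) - sx0]
    similarity = float(weights[sub].mean()) if weights[sub].size else 0.0
    if similarity < similarity_floor:
        raise LostTargetError(f"similarity {similarity:.3f} below floor {similarity_floor}")
    return cx, cy


# ---------------------------------------------------------------------------
# Kalman filtering


def kalman_track(
    t: np.ndarray,
    zx: np.ndarray,
    zy: np.ndarray,
    sigma_a: float = KALMAN_SIGMA_A,
    sigma_m: float = KALMAN_SIGMA_M,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Constant-velocity Kalman filter over 2-D position measurements.

    State is (x, y, vx, vy) with white-acceleration process noise of
    standard deviation ``sigma_a`` (px/s^2) and isotropic measurement noise
    ``sigma_m`` (px).  Returns filtered ``x, y, vx, vy`` per sample; the
    velocity is the filter's velocity state.
    """
    t = np.asarray(t, float)
    zx = np.asarray(zx, float)
    zy = np.asarray(zy, float)
    n = len(t)
    if n == 0:
        raise ValueError("no measurements")
    if n > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")

    m = np.array([zx[0], zy[0], 0.0, 0.0])
    # tracking starts from the detected rest posture: a tight velocity prior
    # (std 3 px/s) suppresses the startup transient that otherwise lets
    # measurement noise masquerade as movement
    P = np.diag([sigma_m**2, sigma_m**2, 9.0, 9.0])
    H = np.zeros((2, 4))
    H[0, 0] = H[1, 1] = 1.0
    R = np.eye(2) * sigma_m**2
    out = np.empty((n, 4))
    out[0] = m
    for i in range(1, n):
        dt = t[i] - t[i - 1]
        F = np.eye(4)
        F[0, 2] = F[1, 3] = dt
        q = sigma_a**2
        q11 = q * dt**4 / 4.0
        q12 = q * dt**3 / 2.0
        q22 = q * dt**2
        Q = np.zeros((4, 4))
        Q[0, 0] = Q[1, 1] = q11
        Q[0, 2] = Q[2, 0] = Q[1, 3] = Q[3, 1] = q12
        Q[2, 2] = Q[3, 3] = q22
        m = F @ m
        P = F @ P @ F.T + Q
        z = np.array([zx[i], zy[i]])
        S = H @ P @ H.T + R
        K = P @ H.T @ np.linalg.inv(S)
        m = m + K @ (z - H @ m)
        P = (np.eye(4) - K @ H) @ P
        out[i] = m
    return out[:, 0], out[:, 1], out[:, 2], out[:, 3]


# ---------------------------------------------------------------------------
# Full pipeline


@dataclass
class TrackerConfig:
    """Configuration for :func:`track_video` (JSON-serializable)."""

    reference_rect: tuple[float, float, float, float] | None = None
    hsv_bins: tuple[int, int] = (HUE_BINS, SAT_BINS)
    sigma_a: float = KALMAN_SIGMA_A
    sigma_m: float = KALMAN_SIGMA_M
    roi_width: int = ROI_WIDTH
    frame_rate: float | None = None
    weight_strategy: str = "ppm"
    detector: Detector | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "TrackerConfig":
        raw = json.loads(Path(path).read_text())
        kalman = raw.pop("kalman", {})
        cfg = cls(
            reference_rect=tuple(raw["reference_rect"]) if raw.get("reference_rect") else None,
            hsv_bins=tuple(raw.get("hsv_bins", (HUE_BINS, SAT_BINS))),
            sigma_a=float(kalman.get("sigma_a", KALMAN_SIGMA_A)),
            sigma_m=float(kalman.get("sigma_m", KALMAN_SIGMA_M)),
            roi_width=int(raw.get("roi_width", ROI_WIDTH)),
            frame_rate=raw.get("frame_rate"),
        )
        return cfg


def iter_frames(source) -> tuple[Iterator[np.ndarray], float | None]:
    """Yield RGB frames from a video file, a directory of images, or an iterable."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.is_dir():
            files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".png", ".jpg", ".jpeg", ".tif"})
            if not files:
                raise TrackingError(f"no image frames found in {path}")
            import imageio.v3 as iio

            return (iio.imread(f) for f in files), None
        if not path.exists():
            raise TrackingError(f"unreadable video source: {path}")
        import imageio.v3 as iio

        meta = iio.immeta(path)
        fps = meta.get("fps")
        return iio.imiter(path), fps
    return iter(source), None


def track_video(source, config: TrackerConfig | None = None) -> tuple[Trajectory, ReferencePose]:
    """Track the head through a video: detect, normalize, mean shift, Kalman.

    ``source`` may be a video path, a directory of numbered image frames, or
    any iterable of RGB frames.  Returns the trajectory in canonical ROI
    coordinates together with the detected reference pose (original frame
    coordinates).
    """
    config = config or TrackerConfig()
    frames, fps = iter_frames(source)
    frame_rate = config.frame_rate or fps or 30.0
    it = iter(frames)
    try:
        first = next(it)
    except StopIteration:
        raise TrackingError("video source contains no frames") from None
    fh, fw = first.shape[:2]
    if config.reference_rect is not None:
        x, y, w, h = config.reference_rect
        reference = ReferencePose(x=x, y=y, w=w, h=h, frame_size=(fw, fh))
    else:
        reference = detect_reference(first, config.detector)
    roi, ref_roi, transform = normalize_reference(reference, first, config.roi_width)
    model = build_target_model(
        roi,
        ref_roi,
        hue_bins=config.hsv_bins[0],
        sat_bins=config.hsv_bins[1],
        weight_strategy=config.weight_strategy,
    )
    # the weight centroid sits at a fixed offset from the geometric face
    # centre (hair exclusion, interior features); calibrate it once on the
    # reference frame so reported positions follow the face-centre convention
    c0 = ref_roi.center
    for _ in range(20):  # fixed point of the tracker on a static face
        nxt = meanshift_step(roi, model, c0)
        moved = math.hypot(nxt[0] - c0[0], nxt[1] - c0[1])
        c0 = nxt
        if moved < 0.1:
            break
    offset = (c0[0] - ref_roi.center[0], c0[1] - ref_roi.center[1])
    positions = [ref_roi.center]
    pos = c0
    for frame in it:
        roi = transform.apply(frame)
        pos = meanshift_step(roi, model, pos)
        positions.append((pos[0] - offset[0], pos[1] - offset[1]))
    pts = np.asarray(positions, float)
    t = np.arange(len(pts)) / frame_rate
    if len(pts) == 1:
        x, y = pts[:, 0], pts[:, 1]
        vx = vy = np.zeros(1)
    else:
        x, y, vx, vy = kalman_track(t, pts[:, 0], pts[:, 1], config.sigma_a, config.sigma_m)
    traj = Trajectory(
        t=t,
        x_m=pts[:, 0],
        y_m=pts[:, 1],
        x=x,
        y=y,
        vx=vx,
        vy=vy,
        frame_rate=frame_rate,
        reference=reference,
        reference_xy=(config.roi_width / 2.0, config.roi_width / 2.0),
    )
    return traj, reference
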