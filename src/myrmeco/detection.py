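"""Seed and ant detection in time-lapse arena frames.

The pipeline mirrors how a static, millimetre-scale seed can be told apart
from a moving ant of similar darkness:

1. a *modal background* — for every pixel, the most frequent RGB triplet over
   a set of frames — captures the empty arena floor;
2. pixels whose RGB Euclidean distance to the background exceeds a threshold
   are candidate foreground; a second, colour-based pass keeps only the
   darkest of them (seeds and ants are both dark on a light floor);
3. a temporal *persistence filter* retains pixels present in at least two of
   three consecutive frames: seeds persist, walking ants do not;
4. connected components ("blobs") of the persistent mask whose size falls in
   the seed gate (5–19 px at 0.677 mm/px) are classified as seeds; persistent
   blobs outside the gate are discarded as static ants; blobs of the
   non-persistent (moving) mask are ants, with no size threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .stitching import RawImage

_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT_8 = np.ones((3, 3), dtype=bool)


@dataclass
class SegmentationParams:
    """Thresholds for foreground segmentation and the seed size gate.

    diff_threshold : Euclidean RGB distance to background (grey levels,
        strict inequality) above which a pixel is foreground.
    dark_threshold : maximum luminance (grey levels) of a "dark" pixel.
    seed_min_px, seed_max_px : inclusive blob-size gate for seeds; the
        published gate is 5–19 px for 1–2.5 mm seeds at 0.677 mm/px.
    connectivity : 4 or 8 (default 8; seeds are compact).
    """

    diff_threshold: float = 40.0
    dark_threshold: float = 90.0
    seed_min_px: int = 5
    seed_max_px: int = 19
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.diff_threshold < np.sqrt(3 * 255**2):
            raise ValueError("diff_threshold out of range")
        if not 0 <= self.dark_threshold <= 255:
            raise ValueError("dark_threshold out of range")
        if not 0 < self.seed_min_px <= self.seed_max_px:
            raise ValueError("invalid seed size gate")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def structure(self) -> np.ndarray:
        return _STRUCT_8 if self.connectivity == 8 else _STRUCT_4


@dataclass
class BackgroundModel:
    """Static arena image: per-pixel modal RGB triplet over frames."""

    pixels: np.ndarray
    n_frames_used: int

    def __post_init__(self) -> None:
        if self.n_frames_used < 2:
            raise ValueError("background needs >= 2 frames")


@dataclass
class Blob:
    """A maximal connected component of a binary mask."""

    pixel_set: np.ndarray  # (n, 2) array of (x, y) integer pixels
    size_px: int
    centroid_px: tuple[float, float]
    centroid_cm: tuple[float, float] | None = None
    label: str = "unlabelled"  # seed | ant | discarded | unlabelled


@dataclass
class FrameDetections:
    """Classified blobs for one frame."""

    timestamp: float
    seeds: list[Blob] = field(default_factory=list)
    ants: list[Blob] = field(default_factory=list)
    discarded: list[Blob] = field(default_factory=list)


def build_background(
    frames: list[RawImage],
    manual_patches: list[tuple[tuple[int, int, int, int], tuple[int, int, int]]]
    | None = None,
) -> BackgroundModel:
    """Per-pixel modal RGB triplet over >= 2 same-sized frames.

    Ties are broken toward the lexicographically smallest (R, G, B) triplet,
    which is deterministic.  ``manual_patches`` — (y0, y1, x0, x1) regions
    with a replacement RGB — emulate the manual removal of artefacts (seed or
    ant traces) from the background.
    """
    if len(frames) < 2:
        raise ValueError("background needs >= 2 frames")
    shape = frames[0].shape
    for f in frames:
        if f.shape != shape:
            raise ValueError("frames have mismatched dimensions")
    stack = np.stack([f.pixels for f in frames]).astype(np.uint32)  # (N,H,W,3)
    codes = (stack[..., 0] << 16) | (stack[..., 1] << 8) | stack[..., 2]
    codes.sort(axis=0)  # ascending code == lexicographic RGB order
    n = codes.shape[0]
    counts = np.zeros_like(codes, dtype=np.int32)
    for i in range(n):
        for j in range(n):
            counts[i] += codes[i] == codes[j]
    # first argmax in ascending order -> smallest triplet among the modes
    best = counts.argmax(axis=0)
    mode = np.take_along_axis(codes, best[None], axis=0)[0]
    bg = np.stack(
        [(mode >> 16) & 0xFF, (mode >> 8) & 0xFF, mode & 0xFF], axis=-1
    ).astype(np.uint8)
    if manual_patches:
        for (y0, y1, x0, x1), rgb in manual_patches:
            bg[y0:y1, x0:x1] = np.asarray(rgb, dtype=np.uint8)
    return BackgroundModel(bg, n_frames_used=len(frames))


def segment_difference(
    frame: RawImage, bg: BackgroundModel, params: SegmentationParams
) -> np.ndarray:
    """Mask of pixels whose RGB distance to the background exceeds threshold."""
    if frame.shape != bg.pixels.shape[:2]:
        raise ValueError("frame and background dimensions differ")
    diff = frame.pixels.astype(np.float64) - bg.pixels.astype(np.float64)
    dist = np.sqrt((diff**2).sum(axis=2))
    return dist > params.diff_threshold


def segment_dark(
    frame: RawImage, mask: np.ndarray, params: SegmentationParams
) -> np.ndarray:
    """Restrict a foreground mask to its dark pixels (luminance <= threshold)."""
    if mask.shape != frame.shape:
        raise ValueError("mask and frame dimensions differ")
    return mask & (frame.luminance() <= params.dark_threshold)


def persistence_filter(masks: list[np.ndarray]) -> np.ndarray:
    """Pixels present in at least 2 of 3 consecutive masks (middle-aligned)."""
    if len(masks) != 3:
        raise ValueError("persistence filter needs exactly 3 consecutive masks")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("masks have mismatched dimensions")
    return (masks[0].astype(np.int8) + masks[1] + masks[2]) >= 2


def detect_blobs(mask: np.ndarray, params: SegmentationParams) -> list[Blob]:
    """Maximal connected components with size and centroid."""
    labels, n = ndimage.label(mask, structure=params.structure)
    if n == 0:
        return []
    ys, xs = np.nonzero(labels)
    lab = labels[ys, xs]
    order = np.argsort(lab, kind="stable")
    ys, xs, lab = ys[order], xs[order], lab[order]
    starts = np.searchsorted(lab, np.arange(1, n + 1), side="left")
    ends = np.searchsorted(lab, np.arange(1, n + 1), side="right")
    blobs = []
    for k in range(n):
        bx, by = xs[starts[k] : ends[k]], ys[starts[k] : ends[k]]
        blobs.append(
            Blob(
                pixel_set=np.column_stack([bx, by]),
                size_px=len(bx),
                centroid_px=(float(bx.mean()), float(by.mean())),
            )
        )
    return blobs


def px_to_cm(
    point_px: tuple[float, float],
    resolution: float,
    nest_centre_px: tuple[float, float],
) -> tuple[float, float]:
    """Pixel coordinates to arena centimetres relative to the nest centre.

    The image y axis points down; arena y points up, hence the negation.
    """
    if not resolution > 0:
        raise ValueError("resolution must be positive")
    x = (point_px[0] - nest_centre_px[0]) * resolution / 10.0
    y = -(point_px[1] - nest_centre_px[1]) * resolution / 10.0
    return (x, y)


def cm_to_px(
    point_cm: tuple[float, float],
    resolution: float,
    nest_centre_px: tuple[float, float],
) -> tuple[float, float]:
    """Inverse of :func:`px_to_cm`."""
    x = nest_centre_px[0] + point_cm[0] * 10.0 / resolution
    y = nest_centre_px[1] - point_cm[1] * 10.0 / resolution
    return (x, y)


def classify_frame(
    persistent: np.ndarray,
    moving: np.ndarray,
    params: SegmentationParams,
    resolution: float,
    nest_centre_px: tuple[float, float],
    timestamp: float = 0.0,
) -> FrameDetections:
    """Size-gate persistent blobs into seeds; moving blobs are ants.

    Persistent blobs outside [seed_min_px, seed_max_px] are discarded —
    these are static ants, too large for the seed gate.  Ant blobs carry no
    size threshold.
    """
    det = FrameDetections(timestamp=timestamp)
    for blob in detect_blobs(persistent, params):
        blob.centroid_cm = px_to_cm(blob.centroid_px, resolution, nest_centre_px)
        if params.seed_min_px <= blob.size_px <= params.seed_max_px:
            blob.label = "seed"
            det.seeds.append(blob)
        else:
            blob.label = "discarded"
            det.discarded.append(blob)
    for blob in detect_blobs(moving, params):
        blob.centroid_cm = px_to_cm(blob.centroid_px, resolution, nest_centre_px)
        blob.label = "ant"
        det.ants.append(blob)
    return det


def segment_frame(
    frame: RawImage, bg: BackgroundModel, params: SegmentationParams
) -> np.ndarray:
    """Difference segmentation followed by the darkness pass."""
    return segment_dark(frame, segment_difference(frame, bg, params), params)


def detect_sequence(
    frames: list[RawImage],
    bg: BackgroundModel,
    params: SegmentationParams,
    nest_centre_px: tuple[float, float],
) -> list[FrameDetections]:
    """Run the full pipeline over an ordered frame sequence.

    Frame t's persistence mask uses the segmented masks of (t-1, t, t+1), so
    the first and last frame of the sequence yield no detections; the
    returned list covers frames 1 .. n-2.
    """
    if len(frames) < 3:
        raise ValueError("need >= 3 frames for the persistence filter")
    masks = [segment_frame(f, bg, params) for f in frames]
    out = []
    for t in range(1, len(frames) - 1):
        persistent = persistence_filter(masks[t - 1 : t + 2])
        moving = masks[t] & ~persistent
        out.append(
            classify_frame(
                persistent,
                moving,
                params,
                frames[t].resolution,
                nest_centre_px,
                timestamp=frames[t].timestamp,
            )
        )
    return out
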