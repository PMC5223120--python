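"""Foraging-platform monitoring: remaining diaspores and ant in/out flow.

During the foraging stage a 10 cm x 10 cm platform holding the diaspores is
reached via a narrow bridge.  Two quantities are extracted per frame:

* ``D_track`` — the number of diaspores still on the platform, obtained by
  segmenting dark blobs inside the platform polygon and subtracting blobs
  large enough to be ants;
* the cumulative in/out flow of ants, counted as directed crossings of a
  gate segment spanning the bridge by tracked ant trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon2mask

from .detection import SegmentationParams, detect_blobs
from .stitching import RawImage


@dataclass
class PlatformROI:
    """Platform polygon and bridge gate, both in pixel coordinates.

    ``polygon`` is an (N, 3+) -> (N, 2) array of (x, y) vertices of a simple
    polygon.  ``gate`` is a directed segment ((x1, y1), (x2, y2)); a
    trajectory crossing from the gate's right-hand side to its left-hand side
    (positive orientation) counts as *entering* the platform.
    """

    polygon: np.ndarray
    gate: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        poly = np.asarray(self.polygon, dtype=np.float64)
        if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
            raise ValueError("polygon needs >= 3 (x, y) vertices")
        self.polygon = poly
        g0, g1 = np.asarray(self.gate[0]), np.asarray(self.gate[1])
        if np.allclose(g0, g1):
            raise ValueError("gate must have nonzero length")


@dataclass
class Trajectory:
    """One tracked object: ordered (timestamp, x_px, y_px) samples."""

    track_id: int
    timestamps: np.ndarray
    points: np.ndarray  # (n, 2) of (x, y)

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=np.float64)
        if len(ts) > 1 and not np.all(np.diff(ts) > 0):
            raise ValueError("timestamps must be strictly increasing")
        self.timestamps = ts
        self.points = np.asarray(self.points, dtype=np.float64)


def count_platform_diaspores(
    frame: RawImage, roi: PlatformROI, params: SegmentationParams
) -> int:
    """Diaspores remaining on the platform (dark blobs minus ant-sized blobs).

    Dark pixels (luminance <= ``dark_threshold``) inside the platform polygon
    are pooled into blobs; blobs larger than ``seed_max_px`` are taken to be
    ants standing on the platform and subtracted from the count.
    """
    h, w = frame.shape
    poly = roi.polygon
    if (
        poly[:, 0].min() < 0
        or poly[:, 1].min() < 0
        or poly[:, 0].max() > w
        or poly[:, 1].max() > h
    ):
        raise ValueError("platform ROI lies outside the frame")
    # polygon2mask expects (row, col) vertex order
    mask = polygon2mask((h, w), poly[:, ::-1])
    dark = mask & (frame.luminance() <= params.dark_threshold)
    blobs = detect_blobs(dark, params)
    n_ants = sum(1 for b in blobs if b.size_px > params.seed_max_px)
    return len(blobs) - n_ants


def _gate_crossings_for_track(
    traj: Trajectory, gate: tuple[tuple[float, float], tuple[float, float]]
) -> tuple[int, int]:
    g0 = np.asarray(gate[0], dtype=np.float64)
    g1 = np.asarray(gate[1], dtype=np.float64)
    d = g1 - g0
    pts = traj.points
    if len(pts) < 2:
        return (0, 0)
    rel = pts - g0
    side = d[0] * rel[:, 1] - d[1] * rel[:, 0]
    # points exactly on the gate line are ignored until the object moves off it
    keep = side != 0
    pts = pts[keep]
    side = side[keep]
    if len(pts) < 2:
        return (0, 0)
    inflow = outflow = 0
    for i in range(len(pts) - 1):
        s0, s1 = side[i], side[i + 1]
        if s0 * s1 >= 0:
            continue
        p, q = pts[i], pts[i + 1]
        seg = q - p
        denom = d[0] * seg[1] - d[1] * seg[0]
        if denom == 0:
            continue
        # parameter of the intersection along the gate segment:
        # u = cross(p - g0, seg) / cross(d, seg)
        u = ((p[0] - g0[0]) * seg[1] - (p[1] - g0[1]) * seg[0]) / denom
        if 0.0 <= u <= 1.0:
            if s1 > 0:
                inflow += 1
            else:
                outflow += 1
    return (inflow, outflow)


def count_gate_crossings(
    trajectories: list[Trajectory], roi: PlatformROI
) -> tuple[int, int]:
    """Total (inflow, outflow) of directed gate crossings over all tracks."""
    inflow = outflow = 0
    for traj in trajectories:
        i, o = _gate_crossings_for_track(traj, roi.gate)
        inflow += i
        outflow += o
    return (inflow, outflow)
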