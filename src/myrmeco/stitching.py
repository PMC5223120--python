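"""Two-camera image stitching with luminosity compensation.

The arena is photographed by two fixed cameras whose fields of view overlap.
The overlap is registered with a plane-projective transformation (homography)
estimated from checkerboard correspondence points, and the two exposures are
equalised by shifting each image's mean luminance to the global mean.  The
composite is assembled without blending: a *stitch line* partitions the
overlap so that every composite pixel originates from exactly one camera,
which avoids ghosting/doubling artefacts that would confound millimetre-scale
seed detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage.transform import ProjectiveTransform, warp


@dataclass
class RawImage:
    """An 8-bit RGB frame with physical resolution and acquisition time.

    Parameters
    ----------
    pixels : ndarray of shape (H, W, 3), uint8
    resolution : float
        Millimetres per pixel (> 0).
    timestamp : float
        Minutes since the start of the experiment.
    camera_id : str
    """

    pixels: np.ndarray
    resolution: float = 0.677
    timestamp: float = 0.0
    camera_id: str = "cam0"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must have shape (H, W, 3)")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be nonempty")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if not self.resolution > 0:
            raise ValueError("resolution must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def luminance(self) -> np.ndarray:
        """Per-pixel luminance L = mean(R, G, B) as float."""
        return self.pixels.astype(np.float64).mean(axis=2)


@dataclass
class Homography:
    """3x3 invertible projective transform, normalised so matrix[2, 2] == 1."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (3, 3):
            raise ValueError("homography matrix must be 3x3")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("homography matrix must be invertible")
        if m[2, 2] == 0:
            raise ValueError("cannot normalise: matrix[2, 2] is zero")
        self.matrix = m / m[2, 2]

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix))

    @classmethod
    def identity(cls) -> "Homography":
        return cls(np.eye(3))

    @classmethod
    def translation(cls, dx: float, dy: float) -> "Homography":
        m = np.eye(3)
        m[0, 2], m[1, 2] = dx, dy
        return cls(m)


@dataclass
class StitchLine:
    """Polyline (in composite pixel coordinates) separating the two sources.

    ``vertices`` is an (N, 2) array of (x, y) points, N >= 2.  Pixels are
    assigned to a side by the sign of the cross product with the nearest
    polyline segment.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError("stitch line needs >= 2 (x, y) vertices")
        self.vertices = v

    def side(self, points: np.ndarray) -> np.ndarray:
        """Signed side (+1/-1/0) of each (x, y) point w.r.t. the polyline."""
        pts = np.asarray(points, dtype=np.float64)
        segs_a = self.vertices[:-1]
        segs_b = self.vertices[1:]
        d = segs_b - segs_a  # (S, 2)
        # distance of each point to each segment
        ap = pts[:, None, :] - segs_a[None, :, :]  # (P, S, 2)
        seg_len2 = np.maximum((d**2).sum(axis=1), 1e-300)
        t = np.clip((ap * d[None]).sum(axis=2) / seg_len2, 0.0, 1.0)
        proj = segs_a[None] + t[..., None] * d[None]
        dist2 = ((pts[:, None, :] - proj) ** 2).sum(axis=2)
        nearest = dist2.argmin(axis=1)
        dn = d[nearest]
        apn = pts - segs_a[nearest]
        cross = dn[:, 0] * apn[:, 1] - dn[:, 1] * apn[:, 0]
        return np.sign(cross)


@dataclass
class DistortionModel:
    """Radial lens distortion r_corrected = r (1 + k1 r^2 + k2 r^4).

    Radii are measured in focal-length units around the principal point
    (cx, cy); ``f`` is the focal length in pixels.
    """

    k1: float = 0.0
    k2: float = 0.0
    cx: float = 0.0
    cy: float = 0.0
    f: float = 1.0

    def __post_init__(self) -> None:
        if not self.f > 0:
            raise ValueError("focal length must be positive")


def compensate_luminosity(images: list[RawImage]) -> list[RawImage]:
    """Shift every image's mean luminance to the global mean.

    The compensation is a pure additive offset applied equally to all three
    channels (exposure-like), clipped to [0, 255].  Within-image contrast
    ordering is therefore preserved away from clipping.
    """
    if not images:
        raise ValueError("no images")
    means = np.array([img.luminance().mean() for img in images])
    global_mean = means.mean()
    out = []
    for img, m in zip(images, means):
        offset = global_mean - m
        shifted = np.clip(np.rint(img.pixels.astype(np.float64) + offset), 0, 255)
        out.append(
            RawImage(
                shifted.astype(np.uint8),
                resolution=img.resolution,
                timestamp=img.timestamp,
                camera_id=img.camera_id,
            )
        )
    return out


def _normalise_points(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hartley normalisation: centroid at origin, mean distance sqrt(2)."""
    centroid = pts.mean(axis=0)
    d = np.sqrt(((pts - centroid) ** 2).sum(axis=1)).mean()
    s = np.sqrt(2) / d if d > 0 else 1.0
    T = np.array([[s, 0, -s * centroid[0]], [0, s, -s * centroid[1]], [0, 0, 1.0]])
    ones = np.ones((len(pts), 1))
    normed = (T @ np.hstack([pts, ones]).T).T[:, :2]
    return normed, T


def estimate_homography(
    correspondences: list[tuple[tuple[float, float], tuple[float, float]]],
    refine: bool = True,
) -> Homography:
    """Estimate the homography mapping source points onto target points.

    Uses the normalised direct linear transform; when ``refine`` is true the
    DLT solution is polished by Levenberg-Marquardt minimisation of the summed
    squared reprojection error.

    Raises
    ------
    ValueError
        With fewer than 4 pairs or a degenerate (collinear) configuration.
    """
    pairs = list(correspondences)
    if len(pairs) < 4:
        raise ValueError("insufficient correspondences")
    src = np.asarray([p[0] for p in pairs], dtype=np.float64)
    dst = np.asarray([p[1] for p in pairs], dtype=np.float64)

    src_n, Ts = _normalise_points(src)
    dst_n, Td = _normalise_points(dst)
    n = len(pairs)
    A = np.zeros((2 * n, 9))
    x, y = src_n[:, 0], src_n[:, 1]
    u, v = dst_n[:, 0], dst_n[:, 1]
    A[0::2, 0] = -x
    A[0::2, 1] = -y
    A[0::2, 2] = -1
    A[0::2, 6] = u * x
    A[0::2, 7] = u * y
    A[0::2, 8] = u
    A[1::2, 3] = -x
    A[1::2, 4] = -y
    A[1::2, 5] = -1
    A[1::2, 6] = v * x
    A[1::2, 7] = v * y
    A[1::2, 8] = v
    _, s, vt = np.linalg.svd(A)
    # rank must be 8 for a unique solution: 3+ collinear source points drop it
    if s[7] < 1e-9 * s[0]:
        raise ValueError("insufficient correspondences")
    Hn = vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ Hn @ Ts
    if abs(H[2, 2]) < 1e-12:
        raise ValueError("insufficient correspondences")
    H = H / H[2, 2]

    if refine and n > 4:

        def residuals(params: np.ndarray) -> np.ndarray:
            M = np.append(params, 1.0).reshape(3, 3)
            ph = np.hstack([src, np.ones((n, 1))]) @ M.T
            proj = ph[:, :2] / ph[:, 2:3]
            return (proj - dst).ravel()

        sol = optimize.least_squares(residuals, H.ravel()[:8], method="lm")
        H = np.append(sol.x, 1.0).reshape(3, 3)
    return Homography(H)


def apply_homography(
    point: tuple[float, float], h: Homography
) -> tuple[float, float]:
    """Map one (x, y) pixel coordinate through ``h``."""
    x, y = point
    xp, yp, w = h.matrix @ np.array([x, y, 1.0])
    if abs(w) < 1e-15:
        raise ValueError("point at infinity")
    return (xp / w, yp / w)


def _distort_radii(r: np.ndarray, model: DistortionModel) -> np.ndarray:
    return r * (1.0 + model.k1 * r**2 + model.k2 * r**4)


def _undistort_radii(
    rc: np.ndarray, model: DistortionModel, iters: int = 8
) -> np.ndarray:
    """Invert the radial polynomial by Newton iteration (rd from rc)."""
    rd = rc.copy()
    for _ in range(iters):
        f = rd * (1 + model.k1 * rd**2 + model.k2 * rd**4) - rc
        fp = 1 + 3 * model.k1 * rd**2 + 5 * model.k2 * rd**4
        rd = rd - f / np.maximum(fp, 1e-12)
    return rd


def distort_points(points: np.ndarray, model: DistortionModel) -> np.ndarray:
    """Apply the radial model to (N, 2) pixel points (corrected -> distorted)."""
    pts = np.asarray(points, dtype=np.float64)
    xn = (pts[:, 0] - model.cx) / model.f
    yn = (pts[:, 1] - model.cy) / model.f
    rc = np.hypot(xn, yn)
    rd = _undistort_radii(rc, model)
    scale = np.where(rc > 0, rd / np.maximum(rc, 1e-300), 1.0)
    return np.column_stack(
        [model.cx + model.f * xn * scale, model.cy + model.f * yn * scale]
    )


def undistort_points(points: np.ndarray, model: DistortionModel) -> np.ndarray:
    """Map (N, 2) distorted pixel points to corrected positions."""
    pts = np.asarray(points, dtype=np.float64)
    xn = (pts[:, 0] - model.cx) / model.f
    yn = (pts[:, 1] - model.cy) / model.f
    rd = np.hypot(xn, yn)
    rc = _distort_radii(rd, model)
    scale = np.where(rd > 0, rc / np.maximum(rd, 1e-300), 1.0)
    return np.column_stack(
        [model.cx + model.f * xn * scale, model.cy + model.f * yn * scale]
    )


def undistort(image: RawImage, model: DistortionModel, order: int = 1) -> RawImage:
    """Resample an image through the inverse radial model.

    Output dimensions equal input dimensions; bilinear interpolation by
    default (``order=0`` for nearest-neighbour).
    """
    h, w = image.shape
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    # output pixel lives at corrected coordinates; sample the distorted source
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    src = distort_points(pts, model)
    coords = np.stack([src[:, 1].reshape(h, w), src[:, 0].reshape(h, w)])
    out = np.empty_like(image.pixels)
    for c in range(3):
        out[..., c] = np.clip(
            np.rint(
                ndimage.map_coordinates(
                    image.pixels[..., c].astype(np.float64),
                    coords,
                    order=order,
                    mode="nearest",
                )
            ),
            0,
            255,
        ).astype(np.uint8)
    return RawImage(
        out,
        resolution=image.resolution,
        timestamp=image.timestamp,
        camera_id=image.camera_id,
    )


def distort(image: RawImage, model: DistortionModel, order: int = 1) -> RawImage:
    """Apply radial distortion to an image (the camera's forward model)."""
    h, w = image.shape
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    src = undistort_points(pts, model)
    coords = np.stack([src[:, 1].reshape(h, w), src[:, 0].reshape(h, w)])
    out = np.empty_like(image.pixels)
    for c in range(3):
        out[..., c] = np.clip(
            np.rint(
                ndimage.map_coordinates(
                    image.pixels[..., c].astype(np.float64),
                    coords,
                    order=order,
                    mode="nearest",
                )
            ),
            0,
            255,
        ).astype(np.uint8)
    return RawImage(
        out,
        resolution=image.resolution,
        timestamp=image.timestamp,
        camera_id=image.camera_id,
    )


def default_stitch_line(
    centre_a: np.ndarray, centre_b: np.ndarray, extent: float
) -> StitchLine:
    """Perpendicular bisector of the segment joining the two image centres."""
    mid = (centre_a + centre_b) / 2.0
    d = centre_b - centre_a
    norm = np.hypot(*d)
    if norm == 0:
        raise ValueError("image centres coincide; no default stitch line")
    perp = np.array([-d[1], d[0]]) / norm
    return StitchLine(np.array([mid - extent * perp, mid + extent * perp]))


def stitch(
    image_a: RawImage,
    image_b: RawImage,
    h: Homography,
    line: StitchLine | None = None,
    order: int = 1,
) -> RawImage:
    """Composite two luminosity-compensated views into one large image.

    ``h`` maps image_b pixel coordinates into image_a's frame.  The composite
    covers the joint bounding box of image_a's corners and image_b's warped
    corners, with its origin at the box's top-left.  Within the overlap each
    pixel is copied verbatim from the single source dictated by the stitch
    line (default: perpendicular bisector of the two image centres) — no
    pixel is a blend of the two cameras.
    """
    ha, wa = image_a.shape
    hb, wb = image_b.shape
    corners_b = np.array([[0, 0], [wb, 0], [wb, hb], [0, hb]], dtype=np.float64)
    warped_b = np.array([apply_homography((x, y), h) for x, y in corners_b])
    corners_a = np.array([[0, 0], [wa, 0], [wa, ha], [0, ha]], dtype=np.float64)
    all_pts = np.vstack([corners_a, warped_b])
    # tolerate numerical fuzz in warped corners before snapping to the grid
    min_xy = np.floor(all_pts.min(axis=0) + 1e-6)
    max_xy = np.ceil(all_pts.max(axis=0) - 1e-6)
    out_w = int(max_xy[0] - min_xy[0])
    out_h = int(max_xy[1] - min_xy[1])
    offset = Homography.translation(-min_xy[0], -min_xy[1])

    # place A by pure translation, warp B by offset ∘ h
    tf_a = ProjectiveTransform(matrix=offset.matrix)
    tf_b = ProjectiveTransform(matrix=offset.matrix @ h.matrix)
    shape = (out_h, out_w)
    warp_kw = dict(output_shape=shape, order=order, preserve_range=True, cval=-1.0)
    a_img = warp(image_a.pixels.astype(np.float64), tf_a.inverse, **warp_kw)
    b_img = warp(image_b.pixels.astype(np.float64), tf_b.inverse, **warp_kw)
    cov_a = (
        warp(np.ones((ha, wa)), tf_a.inverse, output_shape=shape, order=0, cval=0.0)
        > 0.5
    )
    cov_b = (
        warp(np.ones((hb, wb)), tf_b.inverse, output_shape=shape, order=0, cval=0.0)
        > 0.5
    )
    overlap = cov_a & cov_b
    if not overlap.any():
        raise ValueError("no overlap")

    centre_a = np.array([wa / 2.0, ha / 2.0]) + np.array([-min_xy[0], -min_xy[1]])
    cb = apply_homography((wb / 2.0, hb / 2.0), h)
    centre_b = np.array(cb) + np.array([-min_xy[0], -min_xy[1]])
    if line is None:
        extent = float(np.hypot(out_w, out_h))
        line = default_stitch_line(centre_a, centre_b, extent)

    ys, xs = np.nonzero(overlap)
    pts = np.column_stack([xs, ys]).astype(np.float64)
    sides = line.side(pts)
    side_a = line.side(centre_a[None, :])[0]
    from_a_overlap = sides == side_a if side_a != 0 else sides >= 0

    composite = np.zeros((out_h, out_w, 3), dtype=np.float64)
    composite[cov_a & ~overlap] = a_img[cov_a & ~overlap]
    composite[cov_b & ~overlap] = b_img[cov_b & ~overlap]
    take_a = np.zeros(shape, dtype=bool)
    take_a[ys[from_a_overlap], xs[from_a_overlap]] = True
    composite[overlap & take_a] = a_img[overlap & take_a]
    composite[overlap & ~take_a] = b_img[overlap & ~take_a]

    return RawImage(
        np.clip(np.rint(composite), 0, 255).astype(np.uint8),
        resolution=image_a.resolution,
        timestamp=image_a.timestamp,
        camera_id=f"{image_a.camera_id}+{image_b.camera_id}",
    )
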