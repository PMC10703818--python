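"""Image/landmark preprocessing: face alignment, edge filters, augmentation.

Alignment rotates the image so the line through the two eye-group centroids
(landmarks 13/14 and 17/18) is horizontal, crops to the bounding box of the
eight peripheral crop landmarks (3, 10, 29-32, 36, 37) plus a margin —
expanded if necessary so that every one of the 37 landmarks stays inside,
since keeping all landmarks was judged more important than the exact face
size or position — and resizes to a fixed output size.

Augmentation applies the study's geometric transforms (rotation in
[3, 19] or [341, 357] degrees, shear in (-0.16, 0.18), left-right flip /
rotate -90 / rotate -270) identically to raster and landmarks, plus
image-only colour-space transforms (contrast 0.6-2, sharpness 0.4-8,
brightness 0.7-1.6, colour balance 0.2-3.5) and Gaussian blur (1.05-2.9),
each parameter drawn uniformly from its range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from PIL import Image, ImageEnhance, ImageFilter
from skimage.restoration import denoise_bilateral

from .descriptors import DegenerateGeometryError
from .schema import FaceAnnotation, LandmarkSchema, build_default_schema

__all__ = [
    "AffineTransform",
    "AugmentConfig",
    "CropResult",
    "compute_rotation_angle",
    "align_face",
    "apply_edge_filter",
    "augment_sample",
    "geometric_transform",
    "crop_face",
    "whole_image_box",
    "landmark_box",
]


@dataclass(frozen=True)
class AffineTransform:
    """2x3 affine map from input pixel coordinates to output coordinates."""

    matrix: np.ndarray  # shape (2, 3)

    def __post_init__(self):
        m = np.asarray(self.matrix, float)
        if m.shape != (2, 3):
            raise ValueError("affine matrix must be 2x3")
        if abs(np.linalg.det(m[:, :2])) < 1e-12:
            raise ValueError("affine transform is not invertible")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls):
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @classmethod
    def rotation(cls, angle_deg: float, center=(0.0, 0.0)):
        """Rotation by *angle_deg* about *center* (y-down pixel coordinates)."""
        t = math.radians(angle_deg)
        c, s = math.cos(t), math.sin(t)
        cx, cy = center
        return cls(np.array([
            [c, -s, cx - c * cx + s * cy],
            [s, c, cy - s * cx - c * cy],
        ]))

    @classmethod
    def scale_translate(cls, sx, sy, tx=0.0, ty=0.0):
        return cls(np.array([[sx, 0.0, tx], [0.0, sy, ty]]))

    @classmethod
    def shear(cls, k: float, center=(0.0, 0.0)):
        """Horizontal shear x' = x + k*(y - cy)."""
        cx, cy = center
        return cls(np.array([[1.0, k, -k * cy], [0.0, 1.0, 0.0]]))

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self o other: apply *other* first, then self."""
        a, b = self.matrix, other.matrix
        m = np.empty((2, 3))
        m[:, :2] = a[:, :2] @ b[:, :2]
        m[:, 2] = a[:, :2] @ b[:, 2] + a[:, 2]
        return AffineTransform(m)

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix[:, :2])
        m = np.empty((2, 3))
        m[:, :2] = inv
        m[:, 2] = -inv @ self.matrix[:, 2]
        return AffineTransform(m)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    def warp_image(self, image, out_size) -> np.ndarray:
        """Resample *image* (H, W[, C] array) onto an out_size=(W, H) canvas."""
        pil = _to_pil(image)
        inv = self.inverse().matrix
        coeffs = (inv[0, 0], inv[0, 1], inv[0, 2], inv[1, 0], inv[1, 1], inv[1, 2])
        out = pil.transform(tuple(int(v) for v in out_size), Image.AFFINE,
                            coeffs, resample=Image.BILINEAR)
        return np.asarray(out)


def _to_pil(image) -> Image.Image:
    if isinstance(image, Image.Image):
        return image
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return Image.fromarray(arr)


def compute_rotation_angle(ann: FaceAnnotation,
                           schema: LandmarkSchema | None = None) -> float:
    """Signed angle (degrees, in (-180, 180]) of the eye line vs horizontal.

    The eye line joins the centroid of landmarks 13/14 (left eye corners) and
    the centroid of 17/18 (right eye corners).  Positive when the right eye
    group sits lower than the left in image coordinates (y down).
    """
    schema = schema or build_default_schema()
    del schema  # rotation landmarks are fixed by the published role set
    c1 = (ann.point(13) + ann.point(14)) / 2.0
    c2 = (ann.point(17) + ann.point(18)) / 2.0
    d = c2 - c1
    if np.hypot(*d) < 1e-12:
        raise DegenerateGeometryError("eye-group centroids coincide")
    ang = math.degrees(math.atan2(d[1], d[0]))
    return 180.0 if ang <= -180.0 else ang


def align_face(image, ann: FaceAnnotation, schema: LandmarkSchema | None = None,
               out_size=(224, 224), margin_fraction: float = 0.10):
    """Rotate, crop and resize so faces share orientation and size.

    Returns ``(aligned image or None, transformed annotation, transform)``.
    *image* may be None for a coordinates-only pathway (e.g. when descriptors
    are computed from annotations without rasters).
    """
    schema = schema or build_default_schema()
    angle = compute_rotation_angle(ann, schema)
    if image is not None:
        h, w = np.asarray(image).shape[:2]
        center = (w / 2.0, h / 2.0)
    else:
        center = tuple(ann.points.mean(axis=0))
    rot = AffineTransform.rotation(-angle, center)
    rpts = rot.apply(ann.points)

    crop_idx = [i - 1 for i in sorted(schema.crop_set)]
    box = rpts[crop_idx]
    lo, hi = box.min(axis=0), box.max(axis=0)
    span = hi - lo
    if span[0] <= 0 or span[1] <= 0:
        raise DegenerateGeometryError("crop box has zero area")
    lo = lo - margin_fraction * span
    hi = hi + margin_fraction * span
    # landmarks outrank crop-box tightness: grow the box to hold all 37
    lo = np.minimum(lo, rpts.min(axis=0))
    hi = np.maximum(hi, rpts.max(axis=0))

    ow, oh = out_size
    scale = AffineTransform.scale_translate(
        ow / (hi[0] - lo[0]), oh / (hi[1] - lo[1]))
    shift = AffineTransform.scale_translate(1.0, 1.0, -lo[0], -lo[1])
    tf = scale.compose(shift).compose(rot)
    out_ann = ann.replace(tf.apply(ann.points), image_size=(ow, oh))
    out_img = tf.warp_image(image, out_size) if image is not None else None
    return out_img, out_ann, tf


# ---------------------------------------------------------------------------
# Edge-detection filters (3x3 kernels, reflect padding)
# ---------------------------------------------------------------------------

_LAPLACIAN = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], float)
_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], float)
_PREWITT_X = np.array([[-1, 0, 1], [-1, 0, 1], [-1, 0, 1]], float)

EDGE_FILTER_KINDS = ("laplacian", "laplacian_bilateral", "prewitt", "sobel")


def _to_gray(image) -> np.ndarray:
    arr = np.asarray(image, float)
    if arr.ndim == 3:
        arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
    return arr


def apply_edge_filter(image, kind: str, rescale: bool = True) -> np.ndarray:
    """3x3 edge filter response, optionally rescaled to [0, 255].

    ``laplacian``: 4-neighbour Laplacian convolution.
    ``laplacian_bilateral``: bilateral smoothing (3 px neighbourhood,
    sigma_color 100 on the 0-255 scale, sigma_spatial 100) then Laplacian.
    ``prewitt`` / ``sobel``: 0.5*|vertical response| + 0.5*|horizontal
    response| of the 3x3 masks.  RGB input is converted to grayscale first.
    """
    if kind not in EDGE_FILTER_KINDS:
        raise ValueError(f"unknown edge filter {kind!r}; "
                         f"choose from {EDGE_FILTER_KINDS}")
    gray = _to_gray(image)
    if kind == "laplacian_bilateral":
        smooth = denoise_bilateral(gray / 255.0, win_size=3,
                                   sigma_color=100.0 / 255.0,
                                   sigma_spatial=100.0)
        gray = smooth * 255.0
    if kind in ("laplacian", "laplacian_bilateral"):
        resp = ndi.convolve(gray, _LAPLACIAN, mode="reflect")
        resp = np.abs(resp)
    else:
        kx = _SOBEL_X if kind == "sobel" else _PREWITT_X
        gx = ndi.convolve(gray, kx, mode="reflect")
        gy = ndi.convolve(gray, kx.T, mode="reflect")
        resp = 0.5 * np.abs(gx) + 0.5 * np.abs(gy)
    if rescale:
        lo, hi = resp.min(), resp.max()
        resp = np.zeros_like(resp) if hi == lo else (resp - lo) / (hi - lo) * 255.0
    return resp


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

FLIPS = ("left_right", "rotate_minus_90", "rotate_minus_270")


@dataclass
class AugmentConfig:
    """Augmentation parameter ranges (study values as defaults)."""

    rotation_ranges: tuple = ((3.0, 19.0), (341.0, 357.0))
    shear_range: tuple = (-0.16, 0.18)
    flips: tuple = FLIPS
    flip_prob: float = 0.5
    contrast: tuple = (0.6, 2.0)
    sharpness: tuple = (0.4, 8.0)
    brightness: tuple = (0.7, 1.6)
    color_balance: tuple = (0.2, 3.5)
    gaussian_blur: tuple = (1.05, 2.9)
    crop_scale_factor: float = 1.01
    crop_min_neighbors: int = 5
    crop_area_fraction: float = 0.4

    def __post_init__(self):
        for lo, hi in (*self.rotation_ranges, self.shear_range, self.contrast,
                       self.sharpness, self.brightness, self.color_balance,
                       self.gaussian_blur):
            if lo > hi:
                raise ValueError("interval lower bound must not exceed upper")
        if not 0.0 < self.crop_area_fraction < 1.0:
            raise ValueError("crop_area_fraction must lie in (0, 1)")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must lie in [0, 1]")

    @classmethod
    def identity(cls):
        """All ranges collapsed so augmentation is a no-op (testing aid)."""
        return cls(rotation_ranges=((0.0, 0.0), (0.0, 0.0)),
                   shear_range=(0.0, 0.0), flip_prob=0.0,
                   contrast=(1.0, 1.0), sharpness=(1.0, 1.0),
                   brightness=(1.0, 1.0), color_balance=(1.0, 1.0),
                   gaussian_blur=(0.0, 0.0))


def geometric_transform(angle_deg: float, shear: float, flip: str | None,
                        size) -> AffineTransform:
    """Composite rotation-about-centre, shear and flip for a (W, H) canvas."""
    w, h = size
    center = (w / 2.0, h / 2.0)
    tf = AffineTransform.shear(shear, center).compose(
        AffineTransform.rotation(angle_deg, center))
    if flip is None:
        return tf
    if flip == "left_right":
        f = AffineTransform(np.array([[-1.0, 0.0, w], [0.0, 1.0, 0.0]]))
    elif flip == "rotate_minus_90":
        f = AffineTransform.rotation(-90, center)
    elif flip == "rotate_minus_270":
        f = AffineTransform.rotation(-270, center)
    else:
        raise ValueError(f"unknown flip {flip!r}")
    return f.compose(tf)


def augment_sample(image, ann: FaceAnnotation, cfg: AugmentConfig,
                   rng: np.random.Generator):
    """One random augmentation applied consistently to image and landmarks.

    Geometric parameters (rotation range chosen with probability 1/2 each,
    shear, optional flip) act on raster and landmarks alike; colour-space
    enhancements and Gaussian blur act on the raster only.  *image* may be
    None for a coordinates-only check.  Returns (image or None, annotation).
    """
    if image is not None:
        h, w = np.asarray(image).shape[:2]
        size = (w, h)
    elif ann.image_size is not None:
        size = ann.image_size
    else:
        raise ValueError("need an image or an annotation with image_size")

    rr = cfg.rotation_ranges[int(rng.random() < 0.5)]
    angle = float(rng.uniform(*rr))
    shear = float(rng.uniform(*cfg.shear_range))
    flip = None
    if cfg.flips and rng.random() < cfg.flip_prob:
        flip = cfg.flips[int(rng.integers(len(cfg.flips)))]
    tf = geometric_transform(angle, shear, flip, size)
    out_ann = ann.replace(tf.apply(ann.points), image_size=size)

    out_img = None
    if image is not None:
        pil = _to_pil(tf.warp_image(image, size))
        if pil.mode not in ("RGB", "L"):
            pil = pil.convert("RGB")
        for enhancer, rng_range in ((ImageEnhance.Contrast, cfg.contrast),
                                    (ImageEnhance.Sharpness, cfg.sharpness),
                                    (ImageEnhance.Brightness, cfg.brightness)):
            factor = float(rng.uniform(*rng_range))
            pil = enhancer(pil).enhance(factor)
        color_factor = float(rng.uniform(*cfg.color_balance))
        if pil.mode == "RGB":
            pil = ImageEnhance.Color(pil).enhance(color_factor)
        radius = float(rng.uniform(*cfg.gaussian_blur))
        if radius > 0:
            pil = pil.filter(ImageFilter.GaussianBlur(radius))
        out_img = np.asarray(pil)
    return out_img, out_ann


# ---------------------------------------------------------------------------
# Face-crop acceptance rule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CropResult:
    accepted: bool
    image: np.ndarray | None
    area_ratio: float


def crop_face(image, face_box, min_area_fraction: float = 0.4) -> CropResult:
    """Crop to *face_box* = (x, y, w, h) if its area exceeds the threshold.

    The box is clipped to the image first.  Accepted iff clipped area is
    strictly greater than ``min_area_fraction`` times the original image
    area; accepted crops are resized back to the original image size.
    """
    arr = np.asarray(image)
    h, w = arr.shape[:2]
    x, y, bw, bh = face_box
    x0, y0 = max(0, int(round(x))), max(0, int(round(y)))
    x1, y1 = min(w, int(round(x + bw))), min(h, int(round(y + bh)))
    area = max(0, x1 - x0) * max(0, y1 - y0)
    ratio = area / float(w * h)
    if ratio <= min_area_fraction:
        return CropResult(False, None, ratio)
    crop = _to_pil(arr[y0:y1, x0:x1]).resize((w, h), Image.BILINEAR)
    return CropResult(True, np.asarray(crop), ratio)


def whole_image_box(image):
    """Trivial face-box provider: the full image."""
    h, w = np.asarray(image).shape[:2]
    return (0, 0, w, h)


def landmark_box(ann: FaceAnnotation, margin: float = 0.0):
    """Face-box provider from the annotation's landmark bounding box."""
    lo = ann.points.min(axis=0)
    hi = ann.points.max(axis=0)
    span = hi - lo
    lo = lo - margin * span
    span = span * (1 + 2 * margin)
    return (float(lo[0]), float(lo[1]), float(span[0]), float(span[1]))
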