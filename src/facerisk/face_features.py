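"""Facial region geometry and the canonical 124-feature color/texture schema.

The facial complexion analysis operates on nine anatomically named skin
regions (forehead, glabella, nasal tip, mandible, left/right zygomatic,
left/right cheek, lip).  For every region the mean of twelve color-space
channels is recorded (RGB, HSV, CIELAB, YCrCb), giving 9 x 12 = 108 color
features; whole-face texture is summarized by gray-level co-occurrence
matrix (GLCM) statistics -- angular second moment, contrast, entropy and
inverse difference moment -- at four orientations, giving 16 texture
features, for 124 features in total.

Channel scale conventions (config-pinned, internally consistent):

* R, G, B: raw 8-bit values, 0-255.
* H, S, V: hue/saturation/value fractions scaled to 0-255.
* L, a, b: CIELAB under D65; L in 0-100, a/b signed and offset-free.
* Y, Cr, Cb: BT.601 digital YCrCb (Y 16-235, chroma centered at 128).

Face detection/landmarking itself is out of scope: callers supply either a
68-point landmark set (standard iBUG ordering) or precomputed region masks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.spatial import ConvexHull
from skimage.color import rgb2hsv, rgb2lab, rgb2ycbcr
from skimage.draw import ellipse as _draw_ellipse
from skimage.draw import polygon as _draw_polygon
from skimage.feature import graycomatrix

__all__ = [
    "COLOR_CHANNELS",
    "REGION_NAMES",
    "GLCM_STATS",
    "FEATURE_NAMES",
    "MIRROR_PERMUTATION_68",
    "GLCMConfig",
    "LandmarkSet",
    "RegionSet",
    "canonical_landmarks",
    "regions_from_landmarks",
    "regions_from_labelmap",
    "color_features",
    "glcm_features",
    "extract_features",
    "extract_table",
    "read_image",
    "read_landmarks",
]

# ---------------------------------------------------------------------------
# Schema constants
# ---------------------------------------------------------------------------

COLOR_CHANNELS: tuple[str, ...] = ("R", "G", "B", "H", "S", "V", "L", "a", "b", "Y", "Cr", "Cb")

#: Region order fixes the numeric feature suffixes 0-7; the lip region is
#: reported under the dedicated ``lipcolor-<channel>`` names.
REGION_NAMES: tuple[str, ...] = (
    "forehead",
    "glabella",
    "nasal_tip",
    "mandible",
    "left_zygomatic",
    "right_zygomatic",
    "left_cheek",
    "right_cheek",
    "lip",
)

GLCM_STATS: tuple[str, ...] = ("asm", "con", "ent", "idm")

REGION_SUFFIX: dict[str, str] = {name: str(i) for i, name in enumerate(REGION_NAMES[:8])}
REGION_SUFFIX["lip"] = "lip"


def _color_feature_name(region: str, channel: str) -> str:
    if region == "lip":
        return f"lipcolor-{channel}"
    return f"color-{channel}-{REGION_SUFFIX[region]}"


def _build_feature_names() -> tuple[str, ...]:
    names = [
        _color_feature_name(region, ch) for region in REGION_NAMES for ch in COLOR_CHANNELS
    ]
    names += [f"GLCM-{stat}_{k}" for stat in GLCM_STATS for k in range(4)]
    return tuple(names)


#: Canonical ordering of the 124 features: color features region 0..7, then
#: lip color, then the 16 GLCM indicators.
FEATURE_NAMES: tuple[str, ...] = _build_feature_names()
COLOR_FEATURE_NAMES: tuple[str, ...] = FEATURE_NAMES[:108]
GLCM_FEATURE_NAMES: tuple[str, ...] = FEATURE_NAMES[108:]
assert len(FEATURE_NAMES) == 124

# Index permutation mapping each of the 68 iBUG landmarks to its horizontal
# mirror counterpart (jaw reverses, eyes/brows/mouth corners swap sides).
_MIRROR_PAIRS = (
    [(i, 16 - i) for i in range(8)]
    + [(17 + i, 26 - i) for i in range(5)]
    + [(31, 35), (32, 34)]
    + [(36, 45), (37, 44), (38, 43), (39, 42), (40, 47), (41, 46)]
    + [(48, 54), (49, 53), (50, 52), (55, 59), (56, 58)]
    + [(60, 64), (61, 63), (65, 67)]
)
MIRROR_PERMUTATION_68: np.ndarray = np.arange(68)
for _a, _b in _MIRROR_PAIRS:
    MIRROR_PERMUTATION_68[_a], MIRROR_PERMUTATION_68[_b] = _b, _a


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class GeometryError(ValueError):
    """Raised when landmarks or masks cannot yield a valid region set."""


@dataclass(frozen=True)
class GLCMConfig:
    """Settings for the co-occurrence texture extraction.

    ``levels`` gray bins, offset ``distance`` in pixels, and the four
    canonical orientations.  Entropy uses ``log_base`` (natural log by
    default).
    """

    levels: int = 64
    distance: int = 1
    angles: tuple[float, float, float, float] = (0.0, 45.0, 90.0, 135.0)
    symmetric: bool = True
    log_base: float = math.e

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if len(self.angles) != 4:
            raise ValueError("exactly 4 angles required")


@dataclass(frozen=True)
class LandmarkSet:
    """68 (x, y) facial landmarks in pixel coordinates, iBUG ordering."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (68, 2):
            raise ValueError(f"expected 68 (x, y) points, got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("landmarks contain non-finite coordinates")
        object.__setattr__(self, "points", pts)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def translated(self, dx: float, dy: float) -> "LandmarkSet":
        return LandmarkSet(self.points + np.array([dx, dy]))

    def mirrored(self, image_width: int) -> "LandmarkSet":
        """Horizontal mirror with the standard 68-point index permutation."""
        pts = self.points.copy()
        pts[:, 0] = image_width - 1 - pts[:, 0]
        return LandmarkSet(pts[MIRROR_PERMUTATION_68])


@dataclass
class RegionSet:
    """Nine boolean pixel masks keyed by region name for one image geometry."""

    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.masks) != set(REGION_NAMES):
            missing = set(REGION_NAMES) - set(self.masks)
            extra = set(self.masks) - set(REGION_NAMES)
            raise ValueError(f"bad region names: missing={sorted(missing)} extra={sorted(extra)}")
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) != 1:
            raise ValueError("all masks must share one image geometry")
        total = np.zeros(next(iter(shapes)), dtype=int)
        for name in REGION_NAMES:
            mask = np.asarray(self.masks[name], dtype=bool)
            if not mask.any():
                raise GeometryError(f"region '{name}' is empty")
            self.masks[name] = mask
            total += mask
        if int(total.max()) > 1:
            raise GeometryError("region masks overlap")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.masks.values())).shape

    def suffix(self, name: str) -> str:
        return REGION_SUFFIX[name]

    def bounding_box(self) -> tuple[int, int, int, int]:
        """(row0, row1, col0, col1) half-open bounds of the union of masks."""
        union = np.zeros(self.shape, dtype=bool)
        for m in self.masks.values():
            union |= m
        rows = np.flatnonzero(union.any(axis=1))
        cols = np.flatnonzero(union.any(axis=0))
        return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1

    def to_labelmap(self) -> np.ndarray:
        """Single-channel label map: region index + 1, background 0."""
        lab = np.zeros(self.shape, dtype=np.uint8)
        for i, name in enumerate(REGION_NAMES):
            lab[self.masks[name]] = i + 1
        return lab


def regions_from_labelmap(labelmap: np.ndarray) -> RegionSet:
    lab = np.asarray(labelmap)
    return RegionSet({name: lab == i + 1 for i, name in enumerate(REGION_NAMES)})


# ---------------------------------------------------------------------------
# Region construction from landmarks
# ---------------------------------------------------------------------------


def canonical_landmarks(image_dims: tuple[int, int]) -> LandmarkSet:
    """A fixed frontal 68-point template scaled into ``(height, width)``.

    Useful as a deterministic stand-in for a landmark detector in tests and
    synthetic cohorts.
    """
    h, w = image_dims
    pts = np.empty((68, 2), dtype=float)
    # jaw 0-16: elliptic arc, chin at the bottom
    t = np.linspace(0.0, 1.0, 17)
    pts[0:17, 0] = 0.08 + 0.84 * t
    pts[0:17, 1] = 0.40 + 0.58 * np.sqrt(np.clip(1.0 - (2 * t - 1) ** 2, 0.0, 1.0))
    # brows 17-21 (image-left) and 22-26 (image-right)
    bx = np.linspace(0.18, 0.40, 5)
    pts[17:22, 0] = bx
    pts[17:22, 1] = [0.31, 0.295, 0.29, 0.295, 0.31]
    pts[22:27, 0] = 1.0 - bx[::-1]
    pts[22:27, 1] = [0.31, 0.295, 0.29, 0.295, 0.31]
    # nose bridge 27-30, nostril line 31-35
    pts[27:31, 0] = 0.5
    pts[27:31, 1] = [0.33, 0.40, 0.47, 0.55]
    pts[31:36, 0] = np.linspace(0.42, 0.58, 5)
    pts[31:36, 1] = [0.60, 0.605, 0.61, 0.605, 0.60]
    # eyes 36-41 (left), 42-47 (right)
    pts[36:42] = [(0.22, 0.38), (0.26, 0.36), (0.32, 0.36), (0.36, 0.38), (0.32, 0.40), (0.26, 0.40)]
    pts[42:48] = [(0.64, 0.38), (0.68, 0.36), (0.74, 0.36), (0.78, 0.38), (0.74, 0.40), (0.68, 0.40)]
    # mouth outer 48-59, inner 60-67
    pts[48:60] = [
        (0.34, 0.78), (0.40, 0.75), (0.46, 0.74), (0.50, 0.735), (0.54, 0.74), (0.60, 0.75),
        (0.66, 0.78), (0.60, 0.81), (0.54, 0.82), (0.50, 0.825), (0.46, 0.82), (0.40, 0.81),
    ]
    pts[60:68] = [
        (0.38, 0.78), (0.46, 0.77), (0.50, 0.765), (0.54, 0.77), (0.62, 0.78),
        (0.54, 0.79), (0.50, 0.795), (0.46, 0.79),
    ]
    scale = np.array([w, h], dtype=float)
    return LandmarkSet(pts * 0.9 * scale + 0.05 * scale)


def _rect_mask(shape, x0, x1, y0, y1) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    r0 = max(0, int(round(y0)))
    r1 = min(shape[0], int(round(y1)))
    c0 = max(0, int(round(x0)))
    c1 = min(shape[1], int(round(x1)))
    mask[r0:r1, c0:c1] = True
    return mask


def _ellipse_mask(shape, cx, cy, rx, ry) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = _draw_ellipse(cy, cx, ry, rx, shape=shape)
    mask[rr, cc] = True
    return mask


def _hull_mask(shape, points_xy: np.ndarray) -> np.ndarray:
    hull = ConvexHull(points_xy)
    poly = points_xy[hull.vertices]
    mask = np.zeros(shape, dtype=bool)
    rr, cc = _draw_polygon(poly[:, 1], poly[:, 0], shape=shape)
    mask[rr, cc] = True
    return mask


def regions_from_landmarks(landmarks: LandmarkSet, image_dims: tuple[int, int]) -> RegionSet:
    """Build the 9 disjoint skin-region masks from 68 landmarks.

    The anatomical regions are only named, not bit-specified, by the facial
    complexion tradition; this module fixes one landmark-anchored polygon
    construction (documented below) so extraction is deterministic.  The
    margins between neighboring constructions make the masks disjoint by
    design; a final priority pass guards against rasterization contact.
    """
    shape = tuple(int(v) for v in image_dims)
    xs, ys = landmarks.x, landmarks.y
    brow_top = float(ys[17:27].min())
    chin = float(ys[8])
    face_h = chin - brow_top
    face_w = float(xs[16] - xs[0])
    if face_h <= 0 or face_w <= 0:
        raise GeometryError("degenerate landmarks: zero-area face")

    eye_l_bot = float(ys[36:42].max())
    eye_r_bot = float(ys[42:48].max())
    mouth = landmarks.points[48:68]
    mouth_l, mouth_r = float(mouth[:, 0].min()), float(mouth[:, 0].max())
    mouth_bot = float(mouth[:, 1].max())
    nose_l, nose_r = float(xs[31]), float(xs[35])

    masks: dict[str, np.ndarray] = {}
    # forehead: band above the brow line
    masks["forehead"] = _rect_mask(
        shape, xs[17], xs[26], brow_top - 0.30 * face_h, brow_top - 0.06 * face_h
    )
    # glabella: inter-brow column down to the upper nose bridge
    masks["glabella"] = _rect_mask(
        shape, xs[21] + 0.01 * face_w, xs[22] - 0.01 * face_w, brow_top - 0.04 * face_h, ys[28]
    )
    # nasal tip: ellipse around landmark 30
    rx = 0.35 * (nose_r - nose_l)
    masks["nasal_tip"] = _ellipse_mask(shape, xs[30], ys[30], max(rx, 1.5), max(0.7 * rx, 1.5))
    # mandible: chin band between the lower lip and the jaw line
    masks["mandible"] = _rect_mask(
        shape, xs[6], xs[10], mouth_bot + 0.18 * (chin - mouth_bot), chin
    )
    # zygomatic: lateral bands just under each eye
    masks["left_zygomatic"] = _rect_mask(
        shape, xs[36] - 0.04 * face_w, xs[39], eye_l_bot + 0.04 * face_h, eye_l_bot + 0.14 * face_h
    )
    masks["right_zygomatic"] = _rect_mask(
        shape, xs[42], xs[45] + 0.04 * face_w, eye_r_bot + 0.04 * face_h, eye_r_bot + 0.14 * face_h
    )
    # cheeks: mid-face panels between nose/mouth and the jaw
    cheek_top_l = eye_l_bot + 0.16 * face_h
    cheek_top_r = eye_r_bot + 0.16 * face_h
    masks["left_cheek"] = _rect_mask(
        shape, xs[36] - 0.02 * face_w, min(nose_l, mouth_l) - 0.02 * face_w, cheek_top_l, mouth_bot
    )
    masks["right_cheek"] = _rect_mask(
        shape, max(nose_r, mouth_r) + 0.02 * face_w, xs[45] + 0.02 * face_w, cheek_top_r, mouth_bot
    )
    # lip: convex hull of the mouth landmarks
    masks["lip"] = _hull_mask(shape, mouth)

    # priority pass: earlier regions keep contested pixels
    claimed = np.zeros(shape, dtype=bool)
    for name in REGION_NAMES:
        masks[name] = masks[name] & ~claimed
        claimed |= masks[name]
        if not masks[name].any():
            raise GeometryError(f"region '{name}' rasterized empty for these landmarks")
    return RegionSet(masks)


# ---------------------------------------------------------------------------
# Color features
# ---------------------------------------------------------------------------


def _channel_stack(image: np.ndarray) -> np.ndarray:
    """(H, W, 12) stack of channels in COLOR_CHANNELS order and scales."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if img.dtype != np.uint8:
        img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    rgb = img.astype(float)
    hsv = rgb2hsv(img) * 255.0
    lab = rgb2lab(img)
    ycc = rgb2ycbcr(img)  # order Y, Cb, Cr
    return np.dstack([rgb, hsv, lab, ycc[..., 0], ycc[..., 2], ycc[..., 1]])


def color_features(image: np.ndarray, regions: RegionSet) -> pd.Series:
    """Mean of each of 12 color channels over each of the 9 region masks."""
    stack = _channel_stack(image)
    if stack.shape[:2] != regions.shape:
        raise ValueError("regions were built for a different image geometry")
    values: dict[str, float] = {}
    for region in REGION_NAMES:
        mask = regions.masks[region]
        if not mask.any():
            raise GeometryError(f"region '{region}' has no pixels")
        means = stack[mask].mean(axis=0)
        for ch, val in zip(COLOR_CHANNELS, means):
            values[_color_feature_name(region, ch)] = float(val)
    return pd.Series(values, index=list(COLOR_FEATURE_NAMES), dtype=float)


# ---------------------------------------------------------------------------
# GLCM texture features
# ---------------------------------------------------------------------------


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """BT.601 luma in [0, 255] (consistent with the YCrCb channel choice)."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        return img
    return 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]


def glcm_matrix(image: np.ndarray, config: GLCMConfig = GLCMConfig()) -> np.ndarray:
    """Normalized (symmetric) co-occurrence matrices, shape (levels, levels, 4)."""
    gray = to_grayscale(image)
    q = np.clip((gray * config.levels / 256.0).astype(int), 0, config.levels - 1)
    mats = graycomatrix(
        q.astype(np.uint8),
        distances=[config.distance],
        angles=[math.radians(a) for a in config.angles],
        levels=config.levels,
        symmetric=config.symmetric,
        normed=True,
    )
    return mats[:, :, 0, :]


def glcm_features(image: np.ndarray, config: GLCMConfig = GLCMConfig()) -> pd.Series:
    """The 16 texture indicators: ASM, contrast, entropy, IDM at 4 angles.

    With P the normalized co-occurrence matrix at one angle:
    ASM = sum P^2, Contrast = sum (i-j)^2 P, IDM = sum P / (1 + (i-j)^2),
    Entropy = -sum P log P over nonzero cells.
    """
    mats = glcm_matrix(image, config)
    i, j = np.indices(mats.shape[:2])
    d2 = (i - j) ** 2
    values: dict[str, float] = {}
    for k in range(4):
        p = mats[:, :, k]
        nz = p[p > 0]
        values[f"GLCM-asm_{k}"] = float((p ** 2).sum())
        values[f"GLCM-con_{k}"] = float((d2 * p).sum())
        values[f"GLCM-ent_{k}"] = float(-(nz * (np.log(nz) / math.log(config.log_base))).sum())
        values[f"GLCM-idm_{k}"] = float((p / (1.0 + d2)).sum())
    return pd.Series(values, index=list(GLCM_FEATURE_NAMES), dtype=float)


# ---------------------------------------------------------------------------
# Assembly and I/O
# ---------------------------------------------------------------------------


def extract_features(
    image: np.ndarray,
    regions: RegionSet,
    glcm_config: GLCMConfig = GLCMConfig(),
) -> pd.Series:
    """The full 124-value feature vector for one image.

    Color features are per-region means; GLCM statistics are computed on the
    grayscale crop of the face bounding box (the union of the region masks),
    since the texture indicators are whole-face quantities.
    """
    color = color_features(image, regions)
    r0, r1, c0, c1 = regions.bounding_box()
    texture = glcm_features(np.asarray(image)[r0:r1, c0:c1], glcm_config)
    return pd.concat([color, texture]).reindex(list(FEATURE_NAMES))


def extract_table(
    images,
    regions,
    labels=None,
    glcm_config: GLCMConfig = GLCMConfig(),
) -> pd.DataFrame:
    """Feature table for a cohort: one row per image, canonical columns.

    ``regions`` may be a single RegionSet (shared geometry) or one per image.
    """
    if isinstance(regions, RegionSet):
        regions = [regions] * len(images)
    rows = [extract_features(img, reg, glcm_config) for img, reg in zip(images, regions)]
    table = pd.DataFrame(rows).reset_index(drop=True)
    if labels is not None:
        table["label"] = np.asarray(labels, dtype=int)
    return table


def read_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def read_landmarks(path) -> LandmarkSet:
    """Landmarks from CSV (68 rows of x,y) or JSON (list of [x, y])."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        pts = np.asarray(json.loads(path.read_text()), dtype=float)
    else:
        frame = pd.read_csv(path)
        cols = ["x", "y"] if {"x", "y"} <= set(frame.columns) else list(frame.columns[:2])
        pts = frame[cols].to_numpy(dtype=float)
    return LandmarkSet(pts)
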