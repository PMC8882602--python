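"""Forward cut-and-mirror augmentation.

Two cutting geometries are implemented for a single-lesion 2-D image:

* **HV** — cut horizontally and vertically through a center point ``O``
  (normally the lesion centroid) into four rectangular quadrants; each
  quadrant is zero-padded to a square anchored at the corner containing
  ``O`` and expanded by its horizontal, vertical and point mirrors into
  one square image of twice the side, with ``O`` at the exact center.

* **DIAG** — zero-pad the image to a square centered on ``O``, cut it
  into four triangular cones along the two diagonals, and expand each
  triangle by its reflections across the main and anti-diagonal into a
  full square of the same side.

Each original image therefore yields four synthetic images per mode, all
mirror-symmetric about their center, and every augmented pixel can be
mapped back to an original pixel (see :mod:`cutmirror.reconstruction`).

Also provided are the three traditional reference augmentations used as
comparison baselines: seeded random crops containing the lesion,
rotations by 90/180/270 degrees, and vertical/horizontal/diagonal
mirrors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Literal

import numpy as np

logger = logging.getLogger(__name__)

QuadrantLabel = Literal["tl", "tr", "bl", "br"]
TriangleLabel = Literal["top", "right", "bottom", "left"]

HV_LABELS: tuple[QuadrantLabel, ...] = ("tl", "tr", "bl", "br")
DIAG_LABELS: tuple[TriangleLabel, ...] = ("top", "right", "bottom", "left")


class CutMode(str, Enum):
    HV = "hv"
    DIAG = "diag"


@dataclass(frozen=True)
class CutSpec:
    """Cut center ``O`` and its snapped integer grid position.

    ``snapped_row``/``snapped_col`` are the first row/column of the
    lower/right quadrants; both are clamped so every quadrant is
    non-empty for the image shape they are validated against.
    """

    center_row: float
    center_col: float
    snapped_row: int
    snapped_col: int
    mode: CutMode | None = None

    def with_mode(self, mode: CutMode | str) -> "CutSpec":
        return CutSpec(
            self.center_row, self.center_col,
            self.snapped_row, self.snapped_col, CutMode(mode),
        )

    def validate_for(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if not (1 <= self.snapped_row <= h - 1):
            raise ValueError(f"snapped_row {self.snapped_row} outside [1, {h - 1}]")
        if not (1 <= self.snapped_col <= w - 1):
            raise ValueError(f"snapped_col {self.snapped_col} outside [1, {w - 1}]")

    def to_dict(self) -> dict:
        return {
            "center_row": float(self.center_row),
            "center_col": float(self.center_col),
            "snapped_row": int(self.snapped_row),
            "snapped_col": int(self.snapped_col),
            "mode": self.mode.value if self.mode is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CutSpec":
        mode = CutMode(d["mode"]) if d.get("mode") else None
        return cls(d["center_row"], d["center_col"],
                   d["snapped_row"], d["snapped_col"], mode)


@dataclass
class QuadrantSet:
    """The four parts of a cut image plus placement metadata.

    HV mode: rectangular sub-rasters keyed ``tl/tr/bl/br``, offsets in
    original-image coordinates; the parts tile the original exactly.
    DIAG mode: full padded-square rasters zeroed outside the triangle,
    keyed ``top/right/bottom/left``, offsets all relative to the padded
    square.
    """

    mode: CutMode
    parts: dict[str, np.ndarray]
    offsets: dict[str, tuple[int, int]]
    side: int  # padded-square side (DIAG) / 0 for HV (per-part sides vary)


@dataclass
class InversionMeta:
    """Everything needed to map a generated image's pixels back.

    ``pad_offset`` is the (row, col) of the part's local origin inside
    its padded square; ``part_shape`` the unpadded part shape;
    ``offset`` the part origin in original-image coordinates (HV) or
    the padded-square origin in original coordinates (DIAG, negative or
    zero components).
    """

    mode: CutMode
    label: str
    side: int
    pad_offset: tuple[int, int]
    part_shape: tuple[int, int]
    offset: tuple[int, int]
    image_shape: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "mode": self.mode.value,
            "label": self.label,
            "side": int(self.side),
            "pad_offset": list(map(int, self.pad_offset)),
            "part_shape": list(map(int, self.part_shape)),
            "offset": list(map(int, self.offset)),
            "image_shape": list(map(int, self.image_shape)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InversionMeta":
        return cls(
            CutMode(d["mode"]), d["label"], d["side"],
            tuple(d["pad_offset"]), tuple(d["part_shape"]),
            tuple(d["offset"]), tuple(d["image_shape"]),
        )


@dataclass
class AugmentedSet:
    """Four generated square images for one (image, cut) pair."""

    mode: CutMode
    cut: CutSpec
    images: dict[str, np.ndarray]
    meta: dict[str, InversionMeta] = field(default_factory=dict)

    @property
    def labels(self) -> tuple[str, ...]:
        return HV_LABELS if self.mode is CutMode.HV else DIAG_LABELS


def as_gray(image: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) raster to a single channel; pass 2-D through."""
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] in (3, 4):
        from skimage.color import rgb2gray

        return rgb2gray(image[..., :3])
    raise ValueError(f"expected 2-D or RGB image, got shape {image.shape}")


def as_binary(mask: np.ndarray) -> np.ndarray:
    """Coerce a raster to boolean: any value > 0 is foreground."""
    if mask.ndim == 3:
        mask = mask[..., 0]
    return np.asarray(mask) > 0


def snap_center(mask: np.ndarray) -> CutSpec:
    """Cut center from a mask: foreground centroid, rounded half-up,
    clamped so all four quadrants are non-empty.

    Raises
    ------
    ValueError
        If the mask has no foreground pixel.
    """
    mask = as_binary(mask)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("no foreground")
    h, w = mask.shape
    cr = float(rows.mean())
    cc = float(cols.mean())
    # round half up, then clamp into [1, dim-1]
    sr = int(min(max(int(np.floor(cr + 0.5)), 1), h - 1))
    sc = int(min(max(int(np.floor(cc + 0.5)), 1), w - 1))
    return CutSpec(cr, cc, sr, sc)


def cut_hv(image: np.ndarray, cut: CutSpec) -> QuadrantSet:
    """Cut an image into four rectangular quadrants at the snapped center.

    Rows ``>= snapped_row`` belong to the bottom parts and columns
    ``>= snapped_col`` to the right parts, so the quadrants tile the
    image exactly.
    """
    image = np.asarray(image)
    cut.validate_for(image.shape[:2])
    r0, c0 = cut.snapped_row, cut.snapped_col
    parts = {
        "tl": image[:r0, :c0],
        "tr": image[:r0, c0:],
        "bl": image[r0:, :c0],
        "br": image[r0:, c0:],
    }
    offsets = {"tl": (0, 0), "tr": (0, c0), "bl": (r0, 0), "br": (r0, c0)}
    return QuadrantSet(CutMode.HV, parts, offsets, side=0)


# For each HV quadrant, the corner of the part containing O, as a
# (row_at_bottom, col_at_right) flag pair.
_O_CORNER = {"tl": (1, 1), "tr": (1, 0), "bl": (0, 1), "br": (0, 0)}


def pad_quadrant(part: np.ndarray, label: QuadrantLabel) -> tuple[np.ndarray, tuple[int, int]]:
    """Zero-pad a quadrant to a square of side ``max(h, w)``.

    The content is anchored at the corner of the square containing the
    cut point ``O`` (the bottom-right corner for the top-left quadrant,
    the top-left corner for the bottom-right quadrant, ...), so that
    after mirror expansion ``O`` sits at the generated image's center.
    Returns the square and the (row, col) of the part origin inside it.
    """
    part = np.asarray(part)
    if part.size == 0:
        raise ValueError("empty quadrant")
    h, w = part.shape[:2]
    s = max(h, w)
    out = np.zeros((s, s), dtype=part.dtype)
    at_bottom, at_right = _O_CORNER[label]
    r = s - h if at_bottom else 0
    c = s - w if at_right else 0
    out[r:r + h, c:c + w] = part
    return out, (r, c)


def mirror_expand_hv(square_part: np.ndarray, label: QuadrantLabel) -> np.ndarray:
    """Expand a padded square quadrant into a 2s-by-2s mirrored image.

    The input occupies the block matching its quadrant position (so the
    corner containing ``O`` touches the output center); the other three
    blocks are its left-right mirror, its up-down mirror and its point
    mirror.  The result equals its own left-right and up-down flip.
    """
    sq = np.asarray(square_part)
    if sq.ndim != 2 or sq.shape[0] != sq.shape[1]:
        raise ValueError(f"expected a square 2-D raster, got {sq.shape}")
    s = sq.shape[0]
    bi = 1 if label in ("bl", "br") else 0
    bj = 1 if label in ("tr", "br") else 0
    out = np.empty((2 * s, 2 * s), dtype=sq.dtype)
    for pi in (0, 1):
        for pj in (0, 1):
            blk = sq
            if pi != bi:
                blk = blk[::-1, :]
            if pj != bj:
                blk = blk[:, ::-1]
            out[pi * s:(pi + 1) * s, pj * s:(pj + 1) * s] = blk
    return out


def hvcma(image: np.ndarray, cut: CutSpec) -> AugmentedSet:
    """HV cut-and-mirror augmentation: four square images, one per quadrant.

    Applying the same :class:`CutSpec` to a paired mask yields
    pixel-aligned augmented masks.
    """
    image = np.asarray(image)
    qs = cut_hv(image, cut)
    images: dict[str, np.ndarray] = {}
    meta: dict[str, InversionMeta] = {}
    for label in HV_LABELS:
        part = qs.parts[label]
        sq, pad_off = pad_quadrant(part, label)
        images[label] = mirror_expand_hv(sq, label)
        meta[label] = InversionMeta(
            mode=CutMode.HV,
            label=label,
            side=sq.shape[0],
            pad_offset=pad_off,
            part_shape=part.shape[:2],
            offset=qs.offsets[label],
            image_shape=image.shape[:2],
        )
    return AugmentedSet(CutMode.HV, cut.with_mode(CutMode.HV), images, meta)


def pad_to_centered_square(image: np.ndarray, cut: CutSpec) -> tuple[np.ndarray, tuple[int, int]]:
    """Zero-pad an image to a square centered on the snapped cut point.

    The side is ``2 * max(r0, H - r0, c0, W - c0)`` so that ``O`` lands
    exactly at index ``side/2`` on both axes.  Returns the square and
    the (row, col) of the original image's origin inside it.
    """
    image = np.asarray(image)
    cut.validate_for(image.shape[:2])
    h, w = image.shape[:2]
    r0, c0 = cut.snapped_row, cut.snapped_col
    half = max(r0, h - r0, c0, w - c0)
    side = 2 * half
    out = np.zeros((side, side), dtype=image.dtype)
    dr, dc = half - r0, half - c0
    out[dr:dr + h, dc:dc + w] = image
    return out, (dr, dc)


def _cone_masks(side: int) -> dict[str, np.ndarray]:
    """Triangle membership masks over an even-sided square.

    Pixel centers are used (offset 0.5), so the diagonals pass through
    the square's exact center and reflections are exact array
    transposes.  Ties on the diagonals go to top/bottom.
    """
    c = side / 2.0
    dy = np.arange(side)[:, None] + 0.5 - c
    dx = np.arange(side)[None, :] + 0.5 - c
    ady, adx = np.abs(dy), np.abs(dx)
    return {
        "top": -dy >= adx,
        "bottom": dy >= adx,
        "right": dx > ady,
        "left": -dx > ady,
    }


def cut_diag(square: np.ndarray) -> QuadrantSet:
    """Cut a centered square into four triangular cones along its diagonals.

    Returns full-sized rasters zeroed outside each triangle.  The side
    must be even (guaranteed by :func:`pad_to_centered_square`); pixels
    exactly on a diagonal belong to the top/bottom cones.
    """
    square = np.asarray(square)
    if square.ndim != 2 or square.shape[0] != square.shape[1]:
        raise ValueError(f"expected a square raster, got {square.shape}")
    s = square.shape[0]
    if s % 2:
        raise ValueError("diagonal cut requires an even side")
    cones = _cone_masks(s)
    parts = {lab: np.where(m, square, np.zeros((), dtype=square.dtype)) for lab, m in cones.items()}
    offsets = {lab: (0, 0) for lab in DIAG_LABELS}
    return QuadrantSet(CutMode.DIAG, parts, offsets, side=s)


def _anti_transpose(a: np.ndarray) -> np.ndarray:
    return a[::-1, ::-1].T


# Reflection carrying each target cone onto each source cone.  The main
# diagonal swaps right<->bottom and left<->top; the anti-diagonal swaps
# right<->top and left<->bottom; opposite cones are point reflections.
_DIAG_REFLECT = {
    frozenset(("right", "bottom")): np.transpose,
    frozenset(("left", "top")): np.transpose,
    frozenset(("right", "top")): _anti_transpose,
    frozenset(("left", "bottom")): _anti_transpose,
    frozenset(("top", "bottom")): lambda a: a[::-1, ::-1],
    frozenset(("left", "right")): lambda a: a[::-1, ::-1],
}


def mirror_expand_diag(triangle: np.ndarray, label: TriangleLabel) -> np.ndarray:
    """Expand one triangular cone into a full square by diagonal mirrors.

    Each output pixel takes its value from exactly one reflected copy of
    the source triangle: itself inside the source cone, the transposed /
    anti-transposed / point-reflected copy elsewhere.  The output equals
    its own reflection across both diagonals.  Diagonal pixels have no
    pre-image in the (open) left/right cones and stay zero for those
    sources.
    """
    tri = np.asarray(triangle)
    if tri.ndim != 2 or tri.shape[0] != tri.shape[1]:
        raise ValueError(f"expected a square raster, got {tri.shape}")
    if label not in DIAG_LABELS:
        raise ValueError(f"unknown triangle label {label!r}")
    s = tri.shape[0]
    cones = _cone_masks(s)
    out = np.zeros_like(tri)
    for target, m in cones.items():
        if target == label:
            src = tri
        else:
            src = _DIAG_REFLECT[frozenset((label, target))](tri)
        out[m] = src[m]
    return out


def dcma(image: np.ndarray, cut: CutSpec) -> AugmentedSet:
    """Diagonal cut-and-mirror augmentation: four square images, one per cone."""
    image = np.asarray(image)
    square, (dr, dc) = pad_to_centered_square(image, cut)
    qs = cut_diag(square)
    images: dict[str, np.ndarray] = {}
    meta: dict[str, InversionMeta] = {}
    for label in DIAG_LABELS:
        images[label] = mirror_expand_diag(qs.parts[label], label)
        meta[label] = InversionMeta(
            mode=CutMode.DIAG,
            label=label,
            side=qs.side,
            pad_offset=(dr, dc),
            part_shape=image.shape[:2],
            offset=(-dr, -dc),
            image_shape=image.shape[:2],
        )
    return AugmentedSet(CutMode.DIAG, cut.with_mode(CutMode.DIAG), images, meta)


def _mask_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows, cols = np.nonzero(mask)
    return rows.min(), rows.max(), cols.min(), cols.max()


def ref_augment(
    image: np.ndarray,
    mask: np.ndarray,
    method: str,
    rng: np.random.Generator | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Traditional reference augmentations: crop, rotate or mirror.

    ``rotate`` yields the 90/180/270-degree rotations; ``mirror`` the
    vertical, horizontal and double (diagonal) mirrors; ``crop`` three
    seeded random crops, each fully containing the lesion's bounding
    box.  Each returns three (image, mask) pairs.
    """
    image = np.asarray(image)
    mask = as_binary(mask)
    method = method.lower()
    if method == "rotate":
        return [(np.rot90(image, k), np.rot90(mask, k)) for k in (1, 2, 3)]
    if method == "mirror":
        return [
            (image[::-1, :].copy(), mask[::-1, :].copy()),
            (image[:, ::-1].copy(), mask[:, ::-1].copy()),
            (image[::-1, ::-1].copy(), mask[::-1, ::-1].copy()),
        ]
    if method == "crop":
        rng = np.random.default_rng(0) if rng is None else rng
        h, w = mask.shape
        r0, r1, c0, c1 = _mask_bbox(mask)
        if (r0, r1, c0, c1) == (0, h - 1, 0, w - 1):
            logger.warning("crop impossible: lesion bounding box fills the image; returning uncropped copies")
            return [(image.copy(), mask.copy()) for _ in range(3)]
        out = []
        for _ in range(3):
            top = int(rng.integers(0, r0 + 1))
            left = int(rng.integers(0, c0 + 1))
            bottom = int(rng.integers(r1 + 1, h + 1))
            right = int(rng.integers(c1 + 1, w + 1))
            out.append((image[top:bottom, left:right].copy(),
                        mask[top:bottom, left:right].copy()))
        return out
    raise ValueError(f"unknown reference method {method!r}; use crop|rotate|mirror")
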