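"""Boundary reconstruction: the inverse of cut-and-mirror augmentation.

A segmentation of one augmented image contains four mirrored copies of
the same source quadrant, so it yields four independent estimates of
that quadrant's mask.  Reconstruction proceeds:

1. inverse-mirror each augmented segmentation back into quadrant-local
   estimates (:func:`invert_quadrant`);
2. majority-vote the four estimates per quadrant, assemble the voted
   quadrants into a full-frame mask and extract its outer contour
   (:func:`extract_boundary`);
3. convert the contour to polar coordinates (theta, r) about the cut
   center ``O`` (:func:`to_polar`), replicate the samples at theta +/-
   2*pi (:func:`triple_expand`) so the fit is well behaved at the +/-pi
   seam, and fit a cubic smoothing spline r(theta)
   (:func:`fit_and_intercept`);
4. discretize the middle period, map back to image coordinates and
   rasterize the closed polygon.

Complex mode combines the two augmentation geometries: near the HV cut
angles {-pi, -pi/2, 0, pi/2, pi} — where HV cutting loses edge
information — boundary samples are taken from the DIAG reconstruction
(the angular union ``U`` of half-width ``h``, default pi/9), and from
the HV reconstruction elsewhere (:func:`combine_complex`).

The polar representation assumes the lesion is star-shaped about ``O``:
every ray from the center crosses the boundary once.  Boundaries
violating this are smoothed toward their star-shaped hull; this is an
inherent limit of the r(theta) model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline
from skimage import draw as skdraw
from skimage import measure as skmeasure

from .augmentation import (
    DIAG_LABELS,
    CutMode,
    CutSpec,
    InversionMeta,
    _cone_masks,
    _DIAG_REFLECT,
    as_binary,
)

logger = logging.getLogger(__name__)


@dataclass
class PolarBoundary:
    """Ordered polar boundary samples about a fixed center.

    ``thetas`` are radians in [-pi, pi], sorted ascending; ``radii`` are
    non-negative pixel distances.  ``source`` records which augmentation
    geometry produced the samples ("hv", "diag" or "combined").
    """

    center: tuple[float, float]
    thetas: np.ndarray
    radii: np.ndarray
    source: str = "hv"
    n_center_points: int = 0

    def __post_init__(self) -> None:
        self.thetas = np.asarray(self.thetas, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.thetas.shape != self.radii.shape:
            raise ValueError("thetas and radii must have matching shapes")

    def __len__(self) -> int:
        return self.thetas.size

    def to_xy(self) -> np.ndarray:
        """Return (n, 2) array of (row, col) image coordinates."""
        cr, cc = self.center
        rows = cr - self.radii * np.sin(self.thetas)
        cols = cc + self.radii * np.cos(self.thetas)
        return np.column_stack([rows, cols])


@dataclass(frozen=True)
class CompensationSpec:
    """Angular compensation region for complex-mode reconstruction.

    ``U`` is the union of five intervals of half-width ``h`` around the
    HV cut angles {-pi, -pi/2, 0, pi/2, pi}, clipped to [-pi, pi]; its
    total measure is ``8 h``.  ``u_source`` selects which geometry fills
    ``U`` ("diag" by default — the DIAG boundary is most reliable where
    the HV cuts lose information).
    """

    h: float = math.pi / 9
    u_source: str = "diag"

    def __post_init__(self) -> None:
        if not 0 <= self.h < math.pi / 4:
            raise ValueError("h must lie in [0, pi/4) so the intervals do not overlap")
        if self.u_source not in ("diag", "hv"):
            raise ValueError("u_source must be 'diag' or 'hv'")

    @property
    def intervals(self) -> list[tuple[float, float]]:
        h = self.h
        p = math.pi
        return [
            (-p, -p + h),
            (-p / 2 - h, -p / 2 + h),
            (-h, h),
            (p / 2 - h, p / 2 + h),
            (p - h, p),
        ]

    @property
    def measure(self) -> float:
        return sum(b - a for a, b in self.intervals)

    def contains(self, theta: np.ndarray | float) -> np.ndarray:
        """Vectorized membership of theta in U."""
        theta = np.asarray(theta, dtype=float)
        out = np.zeros(theta.shape, dtype=bool)
        for a, b in self.intervals:
            out |= (theta >= a) & (theta <= b)
        return out


@dataclass(frozen=True)
class SplineConfig:
    """Smoothing-spline controls for the polar boundary fit.

    ``smoothing_p`` follows the MATLAB convention: 0 gives the least-
    squares line, 1 the interpolating cubic spline.  ``None`` selects
    the smoothing automatically by generalized cross-validation.
    ``n_samples`` is the number of evaluation angles over [-pi, pi).
    """

    smoothing_p: float | None = 0.99
    n_samples: int = 360

    def __post_init__(self) -> None:
        if self.smoothing_p is not None and not 0 <= self.smoothing_p <= 1:
            raise ValueError("smoothing_p must lie in [0, 1]")
        if self.n_samples < 8:
            raise ValueError("n_samples must be at least 8")


@dataclass
class ReconstructedBoundary:
    """Closed boundary polygon plus its rasterized mask."""

    polygon: np.ndarray  # (n, 2) of (row, col), closed implicitly by wrap
    mask: np.ndarray  # boolean, original-image shape
    polar: PolarBoundary
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# inverse mirroring


def invert_quadrant(
    seg_mask: np.ndarray, meta: InversionMeta
) -> list[np.ndarray]:
    """Split an augmented segmentation into its four mirrored copies and
    inverse-reflect each, yielding four quadrant-local estimates.

    HV mode: estimates have the source quadrant's (unpadded) shape.
    DIAG mode: estimates are padded-square rasters zeroed outside the
    source triangle.
    """
    seg = as_binary(seg_mask)
    if meta.mode is CutMode.HV:
        s = meta.side
        if seg.shape != (2 * s, 2 * s):
            raise ValueError(f"segmentation shape {seg.shape} does not match meta (expected {(2 * s, 2 * s)})")
        bi = 1 if meta.label in ("bl", "br") else 0
        bj = 1 if meta.label in ("tr", "br") else 0
        pr, pc = meta.pad_offset
        ph, pw = meta.part_shape
        estimates = []
        for pi in (0, 1):
            for pj in (0, 1):
                blk = seg[pi * s:(pi + 1) * s, pj * s:(pj + 1) * s]
                if pi != bi:
                    blk = blk[::-1, :]
                if pj != bj:
                    blk = blk[:, ::-1]
                estimates.append(blk[pr:pr + ph, pc:pc + pw].copy())
        return estimates
    # DIAG
    s = meta.side
    if seg.shape != (s, s):
        raise ValueError(f"segmentation shape {seg.shape} does not match meta (expected {(s, s)})")
    cones = _cone_masks(s)
    src_cone = cones[meta.label]
    estimates = []
    for target in DIAG_LABELS:
        if target == meta.label:
            back = seg.copy()
        else:
            # the reflections are involutions: mapping the target cone's
            # content back into the source cone uses the same transform
            back = _DIAG_REFLECT[frozenset((meta.label, target))](seg)
        est = np.zeros_like(seg)
        est[src_cone] = back[src_cone]
        estimates.append(est)
    return estimates


def _majority(estimates: list[np.ndarray], k: int = 2) -> np.ndarray:
    """Pixel-wise vote: foreground where at least ``k`` estimates agree."""
    stack = np.stack([e.astype(np.uint8) for e in estimates])
    return stack.sum(axis=0) >= k


def assemble_quadrants(
    segmentations: dict[str, np.ndarray],
    meta: dict[str, InversionMeta],
) -> np.ndarray:
    """Invert all four augmented segmentations, majority-vote the four
    estimates per quadrant and assemble a full-frame mask in
    original-image coordinates.
    """
    labels = list(segmentations)
    any_meta = meta[labels[0]]
    h, w = any_meta.image_shape
    full = np.zeros((h, w), dtype=bool)
    if any_meta.mode is CutMode.HV:
        for label in labels:
            m = meta[label]
            voted = _majority(invert_quadrant(segmentations[label], m))
            r, c = m.offset
            ph, pw = m.part_shape
            full[r:r + ph, c:c + pw] = voted
        return full
    # DIAG: quadrant estimates live on the padded square; vote per cone,
    # sum the (disjoint) cones, then crop to the original frame.
    s = any_meta.side
    padded = np.zeros((s, s), dtype=bool)
    for label in labels:
        m = meta[label]
        voted = _majority(invert_quadrant(segmentations[label], m))
        padded |= voted
    dr, dc = any_meta.pad_offset
    full = padded[dr:dr + h, dc:dc + w]
    return full.copy()


# ---------------------------------------------------------------------------
# contour -> polar


def extract_boundary(mask: np.ndarray) -> np.ndarray:
    """Outer contour of the largest 8-connected component, as (n, 2)
    sub-pixel (row, col) vertices in order.  Empty mask -> empty array.
    """
    mask = as_binary(mask)
    if not mask.any():
        return np.empty((0, 2), dtype=float)
    from scipy import ndimage

    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        mask = labels == keep
    padded = np.pad(mask.astype(float), 1)
    contours = skmeasure.find_contours(padded, 0.5)
    if not contours:  # pragma: no cover - any nonempty mask has a contour
        return np.empty((0, 2), dtype=float)
    contour = max(contours, key=len) - 1.0  # undo the pad shift
    return contour


def to_polar(points: np.ndarray, center: tuple[float, float], source: str = "hv") -> PolarBoundary:
    """Convert (row, col) contour points to (theta, r) about ``center``.

    Angles follow the mathematical convention (counter-clockwise
    positive): image rows grow downward, so theta = atan2(-(row - cr),
    col - cc).  A point coincident with the center keeps r = 0 and
    theta = 0 and is counted in ``n_center_points``; such points carry
    no angular information and are dropped before spline fitting.
    Samples are sorted by theta.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    cr, cc = center
    dy = -(points[:, 0] - cr)
    dx = points[:, 1] - cc
    r = np.hypot(dy, dx)
    theta = np.where(r > 0, np.arctan2(dy, dx), 0.0)
    n_center = int(np.count_nonzero(r == 0))
    order = np.argsort(theta, kind="stable")
    return PolarBoundary(
        center=(float(cr), float(cc)),
        thetas=theta[order],
        radii=r[order],
        source=source,
        n_center_points=n_center,
    )


def triple_expand(pb: PolarBoundary) -> tuple[np.ndarray, np.ndarray]:
    """Replicate polar samples at theta - 2*pi and theta + 2*pi.

    The spline is then fitted over three periods and only the middle
    period retained, so the fit is periodic-consistent at the +/-pi
    seam.  Returns sorted (thetas, radii) with 3x the samples.
    """
    if len(pb) == 0:
        raise ValueError("no boundary points")
    t, r = pb.thetas, pb.radii
    tt = np.concatenate([t - 2 * np.pi, t, t + 2 * np.pi])
    rr = np.concatenate([r, r, r])
    order = np.argsort(tt, kind="stable")
    return tt[order], rr[order]


def fit_and_intercept(
    thetas: np.ndarray,
    radii: np.ndarray,
    cfg: SplineConfig,
    center: tuple[float, float] = (0.0, 0.0),
    source: str = "hv",
) -> PolarBoundary:
    """Fit a cubic smoothing spline r(theta) to triple-expanded samples
    and evaluate it on the middle period.

    Duplicate angles are averaged before fitting (the solver needs
    strictly increasing abscissae).  ``smoothing_p`` maps onto the
    spline roughness penalty as lam = (1 - p) / p, so p = 1 reproduces
    the interpolating spline; ``None`` uses generalized cross-
    validation.  Fitted radii are clipped at zero.
    """
    thetas = np.asarray(thetas, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if thetas.size < 8:
        raise ValueError(f"need at least 8 samples to fit, got {thetas.size}")
    if thetas.max() - thetas.min() <= 2 * np.pi:
        raise ValueError("samples must span more than one period; apply triple_expand first")
    # collapse duplicate abscissae by averaging
    uniq, inverse = np.unique(thetas, return_inverse=True)
    if uniq.size < thetas.size:
        sums = np.bincount(inverse, weights=radii)
        counts = np.bincount(inverse)
        radii = sums / counts
        thetas = uniq
    if cfg.smoothing_p is None:
        lam = None
    elif cfg.smoothing_p >= 1.0:
        lam = 0.0
    else:
        lam = (1.0 - cfg.smoothing_p) / max(cfg.smoothing_p, 1e-12)
    try:
        spline = make_smoothing_spline(thetas, radii, lam=lam)
    except Exception as exc:  # pragma: no cover - solver failure diagnostics
        raise RuntimeError(
            f"smoothing-spline fit failed on {thetas.size} samples "
            f"(span [{thetas.min():.3f}, {thetas.max():.3f}], lam={lam}): {exc}"
        ) from exc
    eval_t = np.linspace(-np.pi, np.pi, cfg.n_samples, endpoint=False)
    eval_r = np.clip(spline(eval_t), 0.0, None)
    return PolarBoundary(center=center, thetas=eval_t, radii=eval_r, source=source)


# ---------------------------------------------------------------------------
# full reconstructions


def _polar_cloud(
    segmentations: dict[str, np.ndarray],
    meta: dict[str, InversionMeta],
    cut: CutSpec,
    source: str,
) -> PolarBoundary:
    """Inverse-mirror, vote, assemble and extract one polar point cloud."""
    full = assemble_quadrants(segmentations, meta)
    contour = extract_boundary(full)
    pb = to_polar(contour, (cut.center_row, cut.center_col), source=source)
    if pb.n_center_points:
        logger.warning("dropped %d boundary points coincident with the center", pb.n_center_points)
    keep = pb.radii > 0
    return PolarBoundary(pb.center, pb.thetas[keep], pb.radii[keep],
                         source=source, n_center_points=pb.n_center_points)


def _finalize(
    pb: PolarBoundary, cut: CutSpec, cfg: SplineConfig, shape: tuple[int, int], source: str
) -> ReconstructedBoundary:
    """Triple-expand, fit, discretize and rasterize a polar cloud."""
    if len(pb) == 0:
        raise ValueError("no tumor detected")
    tt, rr = triple_expand(pb)
    fitted = fit_and_intercept(tt, rr, cfg, center=pb.center, source=source)
    poly = fitted.to_xy()
    rows, cols = skdraw.polygon(poly[:, 0], poly[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rows, cols] = True
    return ReconstructedBoundary(polygon=poly, mask=mask, polar=fitted)


def reconstruct_single(
    segmentations: dict[str, np.ndarray],
    meta: dict[str, InversionMeta],
    cut: CutSpec,
    cfg: SplineConfig | None = None,
) -> ReconstructedBoundary:
    """Reconstruct the lesion boundary from one augmentation mode's four
    segmented images.

    ``segmentations`` maps quadrant label -> segmented augmented image;
    ``meta`` carries the matching inversion records from the forward
    :class:`~cutmirror.augmentation.AugmentedSet`.
    """
    cfg = cfg or SplineConfig()
    any_meta = next(iter(meta.values()))
    source = "hv" if any_meta.mode is CutMode.HV else "diag"
    pb = _polar_cloud(segmentations, meta, cut, source)
    return _finalize(pb, cut, cfg, any_meta.image_shape, source)


def combine_complex(
    hv: PolarBoundary, diag: PolarBoundary, comp: CompensationSpec | None = None
) -> PolarBoundary:
    """Merge HV- and DIAG-derived polar samples: inside the angular
    region ``U`` (neighborhoods of the HV cut angles) take the DIAG
    samples, elsewhere the HV samples.

    If one source has no samples in its assigned region, the other
    source fills in with a logged warning.  Setting ``u_source='hv'``
    swaps the roles.
    """
    comp = comp or CompensationSpec()
    if len(hv) == 0 or len(diag) == 0:
        raise ValueError("both polar boundaries must be non-empty")
    if not np.allclose(hv.center, diag.center):
        raise ValueError("polar boundaries must share a center")
    in_u, out_u = (diag, hv) if comp.u_source == "diag" else (hv, diag)
    sel_u = comp.contains(in_u.thetas)
    sel_out = ~comp.contains(out_u.thetas)
    if not sel_u.any() and comp.h > 0:
        logger.warning("no %s samples inside U; falling back to %s there", in_u.source, out_u.source)
        sel_alt = comp.contains(out_u.thetas)
        thetas = np.concatenate([out_u.thetas[sel_alt], out_u.thetas[sel_out]])
        radii = np.concatenate([out_u.radii[sel_alt], out_u.radii[sel_out]])
    elif not sel_out.any():
        logger.warning("no %s samples outside U; falling back to %s there", out_u.source, in_u.source)
        sel_alt = ~comp.contains(in_u.thetas)
        thetas = np.concatenate([in_u.thetas[sel_u], in_u.thetas[sel_alt]])
        radii = np.concatenate([in_u.radii[sel_u], in_u.radii[sel_alt]])
    else:
        thetas = np.concatenate([in_u.thetas[sel_u], out_u.thetas[sel_out]])
        radii = np.concatenate([in_u.radii[sel_u], out_u.radii[sel_out]])
    order = np.argsort(thetas, kind="stable")
    return PolarBoundary(tuple(hv.center), thetas[order], radii[order], source="combined")


def reconstruct_complex(
    hv_segmentations: dict[str, np.ndarray],
    hv_meta: dict[str, InversionMeta],
    diag_segmentations: dict[str, np.ndarray],
    diag_meta: dict[str, InversionMeta],
    cut: CutSpec,
    cfg: SplineConfig | None = None,
    comp: CompensationSpec | None = None,
) -> ReconstructedBoundary:
    """Complex-mode reconstruction: build both polar clouds, compensate
    the HV cloud with DIAG samples inside ``U``, then fit and rasterize.
    """
    cfg = cfg or SplineConfig()
    comp = comp or CompensationSpec()
    hv_pb = _polar_cloud(hv_segmentations, hv_meta, cut, "hv")
    diag_pb = _polar_cloud(diag_segmentations, diag_meta, cut, "diag")
    combined = combine_complex(hv_pb, diag_pb, comp)
    shape = next(iter(hv_meta.values())).image_shape
    return _finalize(combined, cut, cfg, shape, "combined")
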