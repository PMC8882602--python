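"""Ultrasound-like single-lesion phantoms with exact ground truth, and
plug-in segmenters standing in for a trained network.

A phantom is a dark, roughly elliptical lesion on a brighter speckled
background.  The lesion outline is a rotated ellipse whose radius is
modulated by a few low-order harmonics, so the region is star-shaped
about its center by construction (required for the polar boundary model
to be exact) as long as the roughness amplitude stays below ~0.3.
Speckle is multiplicative log-normal noise, the standard first-order
approximation to ultrasound texture; the augmentation/reconstruction
method under test is agnostic to the intensity model.

Segmenters:

* ``oracle`` returns the ground truth — isolates the loss of the
  augmentation/reconstruction machinery itself;
* ``perturbed_oracle`` degrades the truth by a seeded boundary-band
  erosion/dilation plus salt-and-pepper flips, optionally confined to
  an angular band about stated polar angles (used to corrupt the
  neighborhoods of the HV cut directions);
* ``threshold`` smooths and Otsu-thresholds the image, keeping the
  darkest blob — a weak but honest image-driven baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import disk

from .augmentation import as_binary

# Background mean gray level of the phantoms (arbitrary intensity units
# on [0, 1]); the lesion sits ``contrast`` below it.
BACKGROUND_MEAN = 0.55


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and texture of one synthetic lesion image."""

    height: int = 128
    width: int = 128
    center: tuple[float, float] = (64.0, 64.0)
    axes: tuple[float, float] = (24.0, 16.0)
    rotation: float = 0.0
    boundary_roughness: float = 0.05
    contrast: float = 0.35
    speckle_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.axes
        if min(a, b) < 3:
            raise ValueError("lesion semi-axes must be at least 3 px")
        if self.boundary_roughness < 0 or self.speckle_sigma < 0:
            raise ValueError("roughness and speckle sigma must be non-negative")


@dataclass(frozen=True)
class SegmenterSpec:
    """Configuration of a plug-in segmenter.

    ``band_angles``/``band_halfwidth`` restrict the perturbation of a
    ``perturbed_oracle`` to pixels whose polar angle about the lesion
    centroid lies within ``band_halfwidth`` of one of the given angles
    (radians, counter-clockwise, 0 = to the right).  With
    ``perturb_radius = 0`` and ``flip_rate = 0`` the perturbed oracle
    reduces to the oracle.
    """

    kind: str = "oracle"  # oracle | perturbed_oracle | threshold
    perturb_radius: int = 0
    flip_rate: float = 0.0
    band_angles: tuple[float, ...] | None = None
    band_halfwidth: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("oracle", "perturbed_oracle", "threshold"):
            raise ValueError(f"unknown segmenter kind {self.kind!r}")
        if not 0.0 <= self.flip_rate <= 1.0:
            raise ValueError("flip_rate must lie in [0, 1]")


def _radius_profile(spec: PhantomSpec, phi: np.ndarray) -> np.ndarray:
    """Lesion radius at polar angle phi about the lesion center."""
    a, b = spec.axes
    rel = phi - spec.rotation
    base = a * b / np.sqrt((b * np.cos(rel)) ** 2 + (a * np.sin(rel)) ** 2)
    if spec.boundary_roughness > 0:
        rng = np.random.default_rng(spec.seed)
        mod = np.zeros_like(phi)
        for k in (2, 3, 4, 5):
            amp = spec.boundary_roughness * float(rng.uniform(0.3, 1.0)) / 2.0
            phase = float(rng.uniform(0, 2 * math.pi))
            mod += amp * np.cos(k * phi + phase)
        base = base * (1.0 + mod)
    return base


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one phantom: (image float in ~[0, 1], boolean mask).

    Deterministic given ``spec.seed``.  Raises if the lesion would
    touch the image border.
    """
    h, w = spec.height, spec.width
    cr, cc = spec.center
    rows = np.arange(h)[:, None] - cr
    cols = np.arange(w)[None, :] - cc
    dist = np.hypot(rows, cols)
    phi = np.arctan2(-rows, cols)  # counter-clockwise, rows point down
    radius = _radius_profile(spec, phi)
    mask = dist <= radius
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        raise ValueError("lesion overflows the image; shrink axes or recenter")
    image = np.full((h, w), BACKGROUND_MEAN)
    image[mask] -= spec.contrast
    if spec.speckle_sigma > 0:
        rng = np.random.default_rng(spec.seed + 1)
        speckle = np.exp(rng.normal(0.0, spec.speckle_sigma, size=(h, w))
                         - spec.speckle_sigma**2 / 2)
        image = image * speckle
    return np.clip(image, 0.0, 1.0), mask


def _angular_band(shape: tuple[int, int], center: tuple[float, float],
                  angles: tuple[float, ...], halfwidth: float) -> np.ndarray:
    """Pixels whose polar angle about ``center`` is within ``halfwidth``
    of any of ``angles`` (circular distance)."""
    h, w = shape
    rows = np.arange(h)[:, None] - center[0]
    cols = np.arange(w)[None, :] - center[1]
    phi = np.arctan2(-rows, cols)
    band = np.zeros(shape, dtype=bool)
    for a in angles:
        d = np.abs(np.angle(np.exp(1j * (phi - a))))
        band |= d <= halfwidth
    return band


def segment(image: np.ndarray, gt: np.ndarray | None, spec: SegmenterSpec) -> np.ndarray:
    """Produce a segmentation of ``image`` according to ``spec``.

    The oracle kinds require ``gt``; ``threshold`` ignores it.
    """
    if spec.kind == "threshold":
        smoothed = gaussian(np.asarray(image, dtype=float), sigma=2.0)
        t = threshold_otsu(smoothed)
        dark = smoothed < t
        labels, n = ndimage.label(dark, structure=np.ones((3, 3), dtype=int))
        if n == 0:
            return dark
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        return labels == (int(np.argmax(sizes)) + 1)
    if gt is None:
        raise ValueError("oracle segmenters require a ground-truth mask")
    gt = as_binary(gt)
    if spec.kind == "oracle":
        return gt.copy()
    # perturbed oracle
    out = gt.copy()
    rng = np.random.default_rng(spec.seed)
    if spec.band_angles is not None and gt.any():
        cr, cc = np.argwhere(gt).mean(axis=0)
        region = _angular_band(gt.shape, (cr, cc), spec.band_angles, spec.band_halfwidth)
    else:
        region = np.ones(gt.shape, dtype=bool)
    if spec.perturb_radius > 0:
        selem = disk(spec.perturb_radius)
        altered = (ndimage.binary_dilation(gt, structure=selem)
                   if rng.random() < 0.5
                   else ndimage.binary_erosion(gt, structure=selem))
        out = np.where(region, altered, out)
    if spec.flip_rate > 0:
        flips = (rng.random(gt.shape) < spec.flip_rate) & region
        out = out ^ flips
    return out


@dataclass(frozen=True)
class CohortRanges:
    """Uniform sampling ranges for cohort phantom parameters."""

    height: int = 128
    width: int = 128
    axis_range: tuple[float, float] = (14.0, 30.0)
    axis_ratio_range: tuple[float, float] = (1.0, 2.0)
    center_jitter: float = 12.0
    roughness_range: tuple[float, float] = (0.0, 0.10)
    contrast_range: tuple[float, float] = (0.25, 0.45)
    speckle_range: tuple[float, float] = (0.15, 0.35)


def make_cohort(
    n: int, seed: int, ranges: CohortRanges | None = None
) -> list[tuple[np.ndarray, np.ndarray, PhantomSpec]]:
    """Generate ``n`` phantoms with parameters drawn uniformly from
    ``ranges`` under one master seed; per-case seeds are derived
    deterministically, so regeneration is byte-identical.
    Returns [(image, mask, spec), ...].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = ranges or CohortRanges()
    master = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        case_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(case_seed)
        a = float(rng.uniform(*ranges.axis_range))
        ratio = float(rng.uniform(*ranges.axis_ratio_range))
        b = max(a / ratio, 3.0)
        jr = float(rng.uniform(-ranges.center_jitter, ranges.center_jitter))
        jc = float(rng.uniform(-ranges.center_jitter, ranges.center_jitter))
        spec = PhantomSpec(
            height=ranges.height,
            width=ranges.width,
            center=(ranges.height / 2 + jr, ranges.width / 2 + jc),
            axes=(a, b),
            rotation=float(rng.uniform(0, math.pi)),
            boundary_roughness=float(rng.uniform(*ranges.roughness_range)),
            contrast=float(rng.uniform(*ranges.contrast_range)),
            speckle_sigma=float(rng.uniform(*ranges.speckle_range)),
            seed=case_seed,
        )
        image, mask = make_phantom(spec)
        cohort.append((image, mask, spec))
    return cohort
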