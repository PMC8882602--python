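"""Reading and writing images, masks and augmentation sidecars.

Images are PNG/TIFF, 8- or 16-bit, loaded as float arrays; RGB inputs
are collapsed to grayscale.  Masks are PNG with 0 = background and any
positive value (conventionally 255) = foreground.  Each augmented set
is written as four PNGs plus one JSON sidecar carrying the cut spec and
the per-image inversion metadata needed for reconstruction.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .augmentation import AugmentedSet, CutMode, CutSpec, InversionMeta, as_binary, as_gray

THETA_CONVENTION = "counter-clockwise positive, image rows negated (theta = atan2(-(row-cr), col-cc))"


def read_image(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF image as a 2-D float array scaled to [0, 1]."""
    arr = iio.imread(path)
    gray = as_gray(arr)
    if np.issubdtype(gray.dtype, np.integer):
        info = np.iinfo(gray.dtype)
        return gray.astype(float) / info.max
    return gray.astype(float)


def read_mask(path: str | Path) -> np.ndarray:
    """Load a mask PNG as a boolean array (any value > 0 is foreground)."""
    return as_binary(iio.imread(path))


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a float (assumed [0, 1]) or integer image as 8-bit PNG/TIFF."""
    image = np.asarray(image)
    if np.issubdtype(image.dtype, np.floating):
        image = (np.clip(image, 0, 1) * 255).round().astype(np.uint8)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, image.astype(np.uint8))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit PNG (0 / 255)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (as_binary(mask) * np.uint8(255)))


def write_augmented_set(out_dir: str | Path, stem: str, aug: AugmentedSet,
                        mask_aug: AugmentedSet | None = None) -> Path:
    """Write the four generated images (and optionally masks) plus the
    JSON sidecar.  Returns the sidecar path.

    Files follow ``<stem>_<mode>_<label>.png`` and
    ``<stem>_<mode>_<label>_mask.png``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mode = aug.mode.value
    for label in aug.labels:
        write_image(out_dir / f"{stem}_{mode}_{label}.png", aug.images[label])
        if mask_aug is not None:
            write_mask(out_dir / f"{stem}_{mode}_{label}_mask.png", mask_aug.images[label])
    sidecar = {
        "stem": stem,
        "mode": mode,
        "cut": aug.cut.to_dict(),
        "theta_convention": THETA_CONVENTION,
        "meta": {label: aug.meta[label].to_dict() for label in aug.labels},
    }
    sidecar_path = out_dir / f"{stem}_{mode}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return sidecar_path


def read_sidecar(path: str | Path) -> tuple[CutSpec, dict[str, InversionMeta], str]:
    """Load a sidecar; returns (cut, meta-by-label, mode)."""
    d = json.loads(Path(path).read_text())
    cut = CutSpec.from_dict(d["cut"])
    meta = {label: InversionMeta.from_dict(m) for label, m in d["meta"].items()}
    return cut, meta, d["mode"]
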