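"""Independent brute-force oracles used by the test suite.

Everything here is written per-pixel / per-pair from first principles,
deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def hv_expand_oracle(square: np.ndarray, label: str) -> np.ndarray:
    """Per-pixel mirrored expansion of a square quadrant.

    The quadrant occupies the output block matching its position
    (tl/tr/bl/br); every other pixel reflects across the central axes.
    """
    s = square.shape[0]
    bi = 1 if label in ("bl", "br") else 0
    bj = 1 if label in ("tr", "br") else 0
    out = np.empty((2 * s, 2 * s), dtype=square.dtype)
    for i in range(2 * s):
        for j in range(2 * s):
            li, lj = i % s, j % s
            fi = li if (i // s) == bi else s - 1 - li
            fj = lj if (j // s) == bj else s - 1 - lj
            out[i, j] = square[fi, fj]
    return out


def cone_of(i: int, j: int, s: int) -> str:
    """Cone membership from the defining inequalities on pixel centers."""
    dy = i + 0.5 - s / 2
    dx = j + 0.5 - s / 2
    if -dy >= abs(dx):
        return "top"
    if dy >= abs(dx):
        return "bottom"
    if dx > abs(dy):
        return "right"
    return "left"


def in_cone(i: int, j: int, s: int, label: str) -> bool:
    return cone_of(i, j, s) == label


def diag_expand_oracle(triangle: np.ndarray, label: str) -> np.ndarray:
    """Per-pixel diagonal expansion: for each output pixel, find the
    reflection (identity, transpose, anti-transpose, point) whose image
    lies in the source cone and copy that value; pixels with no
    pre-image in the cone stay zero.  When several reflections land in
    the source cone they must agree (asserted)."""
    s = triangle.shape[0]
    reflections = [
        lambda i, j: (i, j),
        lambda i, j: (j, i),
        lambda i, j: (s - 1 - j, s - 1 - i),
        lambda i, j: (s - 1 - i, s - 1 - j),
    ]
    out = np.zeros_like(triangle)
    for i in range(s):
        for j in range(s):
            values = []
            for refl in reflections:
                fi, fj = refl(i, j)
                if in_cone(fi, fj, s, label):
                    values.append(triangle[fi, fj])
            if values:
                assert all(v == values[0] for v in values)
                out[i, j] = values[0]
    return out


def dice_oracle(gt: np.ndarray, pred: np.ndarray) -> float:
    """Dice from explicit per-pixel loops."""
    tp = fp = fn = 0
    for a, b in zip(gt.ravel(), pred.ravel()):
        if a and b:
            tp += 1
        elif b:
            fp += 1
        elif a:
            fn += 1
    if 2 * tp + fp + fn == 0:
        return 1.0
    return 2 * tp / (2 * tp + fp + fn)


def hausdorff_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Hausdorff distance by exhaustive pairwise distances."""

    def directed(p, q):
        worst = 0.0
        for a in p:
            best = min(float(np.hypot(a[0] - b[0], a[1] - b[1])) for b in q)
            worst = max(worst, best)
        return worst

    return max(directed(x, y), directed(y, x))
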