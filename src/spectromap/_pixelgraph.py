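"""Low-level helpers for 8-connected skeleton pixel graphs."""
from __future__ import annotations

import numpy as np
from scipy import ndimage

# 8-neighbourhood offsets, axial first (used for traversal preference).
AXIAL = ((-1, 0), (1, 0), (0, -1), (0, 1))
DIAGONAL = ((-1, -1), (-1, 1), (1, -1), (1, 1))
OFFSETS = AXIAL + DIAGONAL

EIGHT = np.ones((3, 3), dtype=bool)

_DEG_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)


def degree_image(skel: np.ndarray) -> np.ndarray:
    """Number of 8-neighbours for every pixel (meaningful on skeleton pixels)."""
    return ndimage.convolve(skel.astype(np.uint8), _DEG_KERNEL, mode="constant")


def neighbors_in(p: tuple[int, int], pixel_set: set[tuple[int, int]]) -> list[tuple[int, int]]:
    y, x = p
    return [(y + dy, x + dx) for dy, dx in OFFSETS if (y + dy, x + dx) in pixel_set]


def remove_triangle_corners(skel: np.ndarray) -> np.ndarray:
    """Canonicalize a thin skeleton: drop pixels whose two neighbours are
    themselves adjacent (staircase chords), replacing an L-step by the
    diagonal.  Applied iteratively until stable; topology is preserved
    because the removed pixel's neighbours stay connected through each other.
    """
    out = skel.astype(bool).copy()
    pixels = set(map(tuple, np.argwhere(out)))
    changed = True
    while changed:
        changed = False
        for p in sorted(pixels):
            nbrs = neighbors_in(p, pixels)
            if len(nbrs) == 2:
                (y1, x1), (y2, x2) = nbrs
                if max(abs(y1 - y2), abs(x1 - x2)) == 1:
                    pixels.discard(p)
                    out[p] = False
                    changed = True
    return out


def components(skel: np.ndarray) -> tuple[np.ndarray, int]:
    """8-connected component labelling (raster founder order)."""
    return ndimage.label(skel, structure=EIGHT)
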