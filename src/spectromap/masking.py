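"""Mask construction: from raw channels to optimized binary masks.

Background pixels dominate fluorescence images and propagate noise into any
ratio-type quantity computed from them, so the pipeline rejects them before
thresholding: saturated-pixel removal -> SNR background rejection ->
smoothing -> pixel-value compression -> channel selection -> Otsu threshold
-> morphological cleanup.  Membrane and cytosol masks are built
independently (or the cytosol derived as the filled membrane interior).

The pixel-value compression step exists so that regions of very different
brightness (e.g. ordered vs disordered membrane phases) land in a single
Otsu-separable intensity regime: intensities are clipped to a percentile
window, normalized, raised to a power gamma in (0, 1], and rescaled.  The
map is monotone, so it never reorders pixels, and with gamma=1 and the full
percentile window it is the identity.
"""
from __future__ import annotations

import logging
import warnings
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import ConfigError, DegenerateInputError
from .model import ImageStack, MaskSet, MaskingParams

logger = logging.getLogger(__name__)

__all__ = [
    "remove_saturated",
    "snr_filter",
    "compress_pixels",
    "select_threshold_plane",
    "otsu_threshold",
    "morphological_cleanup",
    "build_masks",
]


def remove_saturated(
    stack: ImageStack,
    t: int = 0,
    z: int = 0,
    channels: Optional[list[int]] = None,
) -> np.ndarray:
    """Validity mask: True where no used channel hits the saturation ceiling.

    A pixel saturated in *any* of ``channels`` (default: all) is excluded
    from thresholding and beta computation, because its true intensity is
    unknown.  Float sources without a ceiling are fully valid.
    """
    if stack.dtype_max is None:
        return np.ones(stack.shape_yx, dtype=bool)
    planes = stack.slice_channels(t, z)
    if channels is not None:
        planes = planes[list(channels)]
    saturated = (planes >= stack.dtype_max).any(axis=0)
    return ~saturated


def otsu_threshold(image: np.ndarray) -> tuple[np.ndarray, float]:
    """Otsu threshold over the exact value histogram.

    Returns ``(mask, threshold)`` where the mask is pixels *strictly above*
    the threshold and the threshold is the pixel value maximizing the
    between-class variance w0*w1*(mu0-mu1)^2 over all candidate cuts (ties
    resolved to the lowest value, sending tied pixels to background).

    Working on distinct sample values rather than fixed-width bins keeps the
    result exact for integer data of any bit depth.
    """
    data = np.asarray(image, dtype=np.float64).ravel()
    data = data[np.isfinite(data)]
    if data.size == 0:
        raise DegenerateInputError("otsu_threshold: no finite pixels")
    values, counts = np.unique(data, return_counts=True)
    if values.size < 2:
        raise DegenerateInputError(
            "otsu_threshold: constant image has no between-class variance"
        )
    w = np.cumsum(counts)[:-1]  # class 0 = values <= t, for t = values[:-1]
    total = data.size
    csum = np.cumsum(values * counts)[:-1]
    gsum = float((values * counts).sum())
    mu0 = csum / w
    mu1 = (gsum - csum) / (total - w)
    between = w * (total - w) * (mu0 - mu1) ** 2
    thr = float(values[int(np.argmax(between))])
    return np.asarray(image) > thr, thr


def snr_filter(image: np.ndarray, snr_k: float) -> np.ndarray:
    """Reject background pixels below ``mu_b + snr_k * sigma_b``.

    Background statistics are estimated from the pixels at or below a
    provisional Otsu cut on the raw image.  A constant image is treated as
    all-background: the result is empty and a warning is issued.
    """
    if snr_k < 0:
        raise ConfigError("snr_k must be >= 0")
    image = np.asarray(image, dtype=np.float64)
    try:
        _, thr = otsu_threshold(image)
    except DegenerateInputError:
        warnings.warn(
            "snr_filter: constant image treated as background; empty mask",
            stacklevel=2,
        )
        return np.zeros(image.shape, dtype=bool)
    background = image[image <= thr]
    mu_b = float(background.mean())
    sigma_b = float(background.std())
    return image > mu_b + snr_k * sigma_b


def compress_pixels(
    image: np.ndarray, gamma: float, p_lo: float = 0.0, p_hi: float = 100.0
) -> np.ndarray:
    """Percentile-clip then gamma-compress intensities (monotone map).

    Values are clipped to the [p_lo, p_hi] percentile window, normalized by
    the window ceiling, raised to ``gamma`` and rescaled: ``out = hi *
    (clip(v) / hi) ** gamma``.  With gamma < 1 bright regions are pulled
    toward dim ones — two regions with a 10:1 intensity ratio end up at
    sqrt(10):1 for gamma = 1/2 — so a foreground of heterogeneous
    brightness becomes separable by a single Otsu cut.  gamma = 1 with the
    full window is the identity, and the map never reorders pixel values.
    """
    if not (0 < gamma <= 1):
        raise ConfigError(f"gamma must be in (0, 1], got {gamma}")
    if not (0 <= p_lo < p_hi <= 100):
        raise ConfigError(f"need 0 <= p_lo < p_hi <= 100, got ({p_lo}, {p_hi})")
    image = np.asarray(image, dtype=np.float64)
    lo, hi = np.percentile(image, [p_lo, p_hi])
    if hi <= lo or hi <= 0:  # constant (or constant window): nothing to do
        return image.copy()
    clipped = np.clip(image, lo, hi)
    return hi * (clipped / hi) ** gamma


def select_threshold_plane(
    stack: ImageStack, params: MaskingParams, t: int = 0, z: int = 0
) -> np.ndarray:
    """Extract the 2-D plane to threshold: one channel or a weighted sum."""
    pairs = params.channel_weights(stack.n_channels)
    out = np.zeros(stack.shape_yx, dtype=np.float64)
    for idx, w in pairs:
        out += w * stack.plane(t, z, idx).astype(np.float64)
    return out


def _smooth(image: np.ndarray, kind: str, size: float) -> np.ndarray:
    if kind == "none":
        return image
    if kind == "median":
        return ndimage.median_filter(image, size=int(size))
    if kind == "mean":
        return ndimage.uniform_filter(image, size=int(size))
    if kind == "gaussian":
        return ndimage.gaussian_filter(image, sigma=float(size))
    raise ConfigError(f"unknown smoothing filter {kind!r}")


_EIGHT = np.ones((3, 3), dtype=bool)


def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= r**2


def morphological_cleanup(mask: np.ndarray, morphology_ops: list) -> np.ndarray:
    """Apply an ordered list of ``[op, value]`` morphology operations.

    Supported ops: ``remove_small`` (drop 8-connected components with area
    < value), ``dilation``/``erosion``/``closing`` with a disk of radius
    value, and ``fill_holes``.  An empty list is the identity.
    """
    out = np.asarray(mask, dtype=bool).copy()
    for op, value in morphology_ops:
        if op == "remove_small":
            labels, n = ndimage.label(out, structure=_EIGHT)
            if n:
                areas = np.bincount(labels.ravel())
                keep = areas >= int(value)
                keep[0] = False
                out = keep[labels]
        elif op == "dilation":
            out = ndimage.binary_dilation(out, structure=_disk(value))
        elif op == "erosion":
            out = ndimage.binary_erosion(out, structure=_disk(value))
        elif op == "closing":
            out = ndimage.binary_closing(out, structure=_disk(value))
        elif op == "fill_holes":
            out = ndimage.binary_fill_holes(out)
        else:
            raise ConfigError(f"unknown morphology op {op!r}")
    return out


def _single_mask(
    stack: ImageStack, params: MaskingParams, t: int, z: int
) -> tuple[np.ndarray, Optional[float]]:
    """Run the full pipeline for one target; returns (mask, otsu threshold)."""
    valid = remove_saturated(
        stack, t, z, channels=[int(k) for k in params.threshold_channels]
    )
    plane = select_threshold_plane(stack, params, t, z)
    candidates = snr_filter(plane, params.snr_k) & valid
    plane = _smooth(plane, params.smooth_kind, params.smooth_size)
    if params.compress_enabled:
        plane = compress_pixels(plane, params.gamma, params.p_lo, params.p_hi)
    if not candidates.any():
        warnings.warn("masking produced no foreground candidates", stacklevel=2)
        return np.zeros(stack.shape_yx, dtype=bool), None
    try:
        _, thr = otsu_threshold(plane[candidates])
    except DegenerateInputError:
        # one surviving intensity level: keep every candidate
        thr = float(plane[candidates].min()) - 1.0
    mask = (plane > thr) & candidates
    mask = morphological_cleanup(mask, params.morphology_ops)
    return mask & valid, thr


def build_masks(
    stack: ImageStack,
    params_membrane: MaskingParams,
    params_cytosol: Optional[MaskingParams] = None,
    t: int = 0,
    z: int = 0,
    cytosol_mode: str = "derived",
) -> MaskSet:
    """Build the membrane mask and (optionally) the cytosol mask.

    ``cytosol_mode``:

    * ``"derived"`` — cytosol = filled membrane interior minus the membrane
      band (no separate parameter set needed);
    * ``"independent"`` — run the full pipeline with ``params_cytosol`` and
      subtract the membrane band to keep the two disjoint;
    * ``"none"`` — cytosol mask left empty.
    """
    membrane, thr_m = _single_mask(stack, params_membrane, t, z)
    thr_c: Optional[float] = None
    if cytosol_mode == "none":
        cytosol = np.zeros_like(membrane)
    elif cytosol_mode == "derived":
        cytosol = ndimage.binary_fill_holes(membrane) & ~membrane
    elif cytosol_mode == "independent":
        if params_cytosol is None:
            raise ConfigError("independent cytosol masking needs params_cytosol")
        cytosol, thr_c = _single_mask(stack, params_cytosol, t, z)
        cytosol &= ~membrane
    else:
        raise ConfigError(f"unknown cytosol_mode {cytosol_mode!r}")
    if not membrane.any() and not cytosol.any():
        warnings.warn("both masks empty", stacklevel=2)
    return MaskSet(
        membrane_mask=membrane,
        cytosol_mask=cytosol,
        threshold_membrane=thr_m,
        threshold_cytosol=thr_c,
        provenance={
            "membrane": params_membrane.to_dict(),
            "cytosol": params_cytosol.to_dict() if params_cytosol else None,
            "cytosol_mode": cytosol_mode,
            "t": t,
            "z": z,
        },
    )
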