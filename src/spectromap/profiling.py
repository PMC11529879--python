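"""Ordered membrane profiling: trajectories of beta and intensity vs arc length.

A 1-px guiding line is extracted down the middle of the membrane band, its
pixel coordinates are re-ordered into a unidirectional walk, and a
constant-area integrating element (a k x k square or a k x 1 line along the
local tangent) slides along the walk, averaging the valid pixels under it at
every position.  The abscissa DeltaX is the cumulative Euclidean arc length
in micrometres (steps of 1 or sqrt(2) px times the pixel size), so the
integration area is independent of local curvature — unlike equal-angle
slicing, which distorts on irregular shapes.

In clustered objects the guiding line branches; intersection nodes (pixels
with >= 3 neighbours, adjacent ones merged) split the line into segments
that are profiled individually.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .errors import ConfigError, SpectromapError
from ._pixelgraph import components, degree_image, neighbors_in
from .model import ProfileParams
from .segmentation import skeletonize_mask

__all__ = [
    "OrderedPath",
    "SegmentGraph",
    "ProfileTrajectory",
    "extract_guideline",
    "detect_nodes_and_segments",
    "order_path",
    "profile_along",
    "recenter_guideline",
    "colocalize",
    "split_by_threshold",
]


@dataclass
class OrderedPath:
    """An ordered 1-px pixel path (open) or loop (closed).

    ``coords`` holds each pixel exactly once; for closed paths the implicit
    closing step back to ``coords[0]`` is included in ``step_lengths``, so
    ``len(step_lengths)`` is ``len(coords) - 1`` for open paths and
    ``len(coords)`` for loops.  Steps are 1 (axial) or sqrt(2) (diagonal).
    """

    coords: np.ndarray
    closed: bool
    step_lengths: np.ndarray
    label: int = 0
    segment_id: int = 0

    @property
    def total_length_px(self) -> float:
        return float(self.step_lengths.sum())

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class SegmentGraph:
    """Intersection nodes and the membrane segments between them."""

    nodes: list  # list of (n_i, 2) coordinate arrays, one per merged node
    segments: list  # list of OrderedPath

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def segment_lengths_um(self, pixel_size_um: float) -> list[float]:
        return [s.total_length_px * pixel_size_um for s in self.segments]


@dataclass
class ProfileTrajectory:
    """Values sampled along a membrane path, indexed by arc length DeltaX."""

    delta_x_um: np.ndarray
    beta: Optional[np.ndarray]
    channel_intensities: dict = field(default_factory=dict)
    coloc: Optional[np.ndarray] = None
    element_shape: str = "square"
    element_size: int = 3
    label: int = 0
    segment_id: int = 0


def extract_guideline(membrane_mask: np.ndarray) -> np.ndarray:
    """1-px medial guiding line of the membrane band.

    The mask must be a continuous band (the masking stage is responsible for
    closing gaps); a discontinuous band still returns all components but
    warns with their count.
    """
    skel = skeletonize_mask(membrane_mask)
    if not skel.any():
        warnings.warn("extract_guideline: empty mask", stacklevel=2)
        return skel
    _, n = components(skel)
    if n > 1:
        warnings.warn(
            f"membrane band is discontinuous: {n} separate guiding lines",
            stacklevel=2,
        )
    return skel


def order_path(
    pixels: Union[np.ndarray, Sequence[tuple[int, int]]],
    label: int = 0,
    segment_id: int = 0,
) -> OrderedPath:
    """Re-order an unordered 1-px path/loop into a unidirectional walk.

    Open paths start at the topmost-then-leftmost endpoint; loops start at
    the topmost-then-leftmost pixel and proceed clockwise in image display
    coordinates (y down: rightward along the top first).  Every pixel is
    visited exactly once.  Branching input (a pixel with more than two
    neighbours) is a precondition violation and raises :class:`ConfigError`.
    """
    coords = [tuple(int(v) for v in p) for p in np.asarray(pixels).reshape(-1, 2)]
    pixel_set = set(coords)
    if len(pixel_set) != len(coords):
        raise ConfigError("order_path: duplicate pixels in input")
    if len(pixel_set) == 1:
        only = np.array(coords)
        return OrderedPath(only, False, np.zeros(0), label, segment_id)

    degrees = {p: len(neighbors_in(p, pixel_set)) for p in pixel_set}
    if any(d > 2 for d in degrees.values()):
        raise ConfigError(
            "order_path: branching input (a node pixel was not removed)"
        )
    endpoints = sorted(p for p, d in degrees.items() if d <= 1)
    if endpoints:
        start = endpoints[0]
        closed = False
    else:
        start = min(pixel_set)
        closed = True

    order = [start]
    visited = {start}
    if closed:
        # clockwise: from the topmost-leftmost pixel head toward larger x
        nbrs = neighbors_in(start, pixel_set)
        cur = max(nbrs, key=lambda p: (p[1], p[0]))
    else:
        cur = neighbors_in(start, pixel_set)[0]
    while True:
        order.append(cur)
        visited.add(cur)
        nxt = [q for q in neighbors_in(cur, pixel_set) if q not in visited]
        if not nxt:
            break
        # prefer the axial neighbour so staircase corners are not skipped
        nxt.sort(key=lambda q: (abs(q[0] - cur[0]) + abs(q[1] - cur[1]), q))
        cur = nxt[0]
    if len(order) != len(pixel_set):
        raise ConfigError("order_path: path is not a single connected chain")
    arr = np.array(order)
    diffs = np.diff(arr, axis=0)
    steps = np.hypot(diffs[:, 0], diffs[:, 1])
    if closed:
        back = np.hypot(*(arr[0] - arr[-1]))
        if back > np.sqrt(2) + 1e-9:
            raise ConfigError("order_path: loop does not close")
        steps = np.append(steps, back)
    if steps.size and (steps.max() > np.sqrt(2) + 1e-9):
        raise ConfigError("order_path: non-adjacent consecutive pixels")
    return OrderedPath(arr, closed, steps, label, segment_id)


def detect_nodes_and_segments(skeleton: np.ndarray) -> SegmentGraph:
    """Find intersection nodes and the ordered segments between them.

    Node pixels have >= 3 eight-neighbours; adjacent node pixels merge into
    one node.  Segments are the connected components of the skeleton minus
    the node pixels, each returned as an :class:`OrderedPath`; an isolated
    loop is a single closed segment.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    graph = SegmentGraph(nodes=[], segments=[])
    if not skeleton.any():
        return graph
    deg = degree_image(skeleton)
    node_mask = skeleton & (deg >= 3)
    node_labels, n_nodes = components(node_mask)
    for i in range(1, n_nodes + 1):
        graph.nodes.append(np.argwhere(node_labels == i))
    seg_mask = skeleton & ~node_mask
    seg_labels, n_segs = components(seg_mask)
    for i in range(1, n_segs + 1):
        pix = np.argwhere(seg_labels == i)
        graph.segments.append(order_path(pix, segment_id=i))
    return graph


def _tangent(coords: np.ndarray, i: int, closed: bool) -> np.ndarray:
    """Local tangent from the path +-2 neighbours (unit vector, (dy, dx))."""
    n = len(coords)
    if closed:
        a, b = coords[(i - 2) % n], coords[(i + 2) % n]
    else:
        a, b = coords[max(i - 2, 0)], coords[min(i + 2, n - 1)]
    d = (b - a).astype(np.float64)
    norm = np.hypot(*d)
    if norm == 0:
        return np.array([0.0, 1.0])
    return d / norm


def _element_offsets(
    shape: str, size: int, tangent: Optional[np.ndarray]
) -> np.ndarray:
    h = size // 2
    if shape == "square":
        dy, dx = np.mgrid[-h : h + 1, -h : h + 1]
        return np.column_stack([dy.ravel(), dx.ravel()])
    # line element along the local tangent
    ts = np.arange(-h, h + 1)
    pts = np.rint(ts[:, None] * tangent[None, :]).astype(int)
    return np.unique(pts, axis=0)


def profile_along(
    path: OrderedPath,
    value_image: np.ndarray,
    element: Union[ProfileParams, tuple[str, int]] = ("square", 3),
    pixel_size_um: float = 1.0,
) -> ProfileTrajectory:
    """Slide the integrating element along the path and average under it.

    At every path pixel the mean of the valid (finite) pixels under the
    element becomes one trajectory value; a position where the whole element
    is NaN (or off-image) yields NaN.  Passing the beta map (NaN outside the
    mask) automatically restricts integration to in-mask pixels, keeping
    cytosol signal out of membrane profiles.
    """
    if isinstance(element, ProfileParams):
        shape, size = element.element_shape, element.element_size
    else:
        shape, size = element
    if size < 3 or size % 2 == 0:
        raise ConfigError("element size must be odd and >= 3")
    if shape not in ("square", "line"):
        raise ConfigError(f"unknown element shape {shape!r}")
    img = np.asarray(value_image, dtype=np.float64)
    h, w = img.shape
    coords = path.coords
    values = np.empty(len(coords))
    for i, (y, x) in enumerate(coords):
        tang = _tangent(coords, i, path.closed) if shape == "line" else None
        offs = _element_offsets(shape, size, tang)
        ys = y + offs[:, 0]
        xs = x + offs[:, 1]
        ok = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
        samples = img[ys[ok], xs[ok]]
        samples = samples[np.isfinite(samples)]
        values[i] = samples.mean() if samples.size else np.nan
    if path.closed:
        delta = np.concatenate([[0.0], np.cumsum(path.step_lengths[:-1])])
    else:
        delta = np.concatenate([[0.0], np.cumsum(path.step_lengths)])
    return ProfileTrajectory(
        delta_x_um=delta * pixel_size_um,
        beta=values,
        element_shape=shape,
        element_size=size,
        label=path.label,
        segment_id=path.segment_id,
    )


def recenter_guideline(
    path: OrderedPath, intensity_image: np.ndarray, search_radius: int
) -> OrderedPath:
    """Shift each path pixel to the intensity-weighted centroid along the
    local normal within ``search_radius``, re-snapped to the pixel grid.

    Useful when the skeleton of a clustered/aggregated membrane falls off
    the true intensity ridge.  A move that would break 8-connectivity with
    the already-recentred predecessor, or collide with another path pixel,
    leaves that pixel in place.  ``search_radius=0`` is the identity.
    """
    if search_radius < 0:
        raise ConfigError("search_radius must be >= 0")
    if search_radius == 0:
        return path
    from skimage.draw import line as draw_line

    img = np.asarray(intensity_image, dtype=np.float64)
    h, w = img.shape
    coords = path.coords
    n = len(coords)
    targets = coords.copy()
    for i in range(n):
        y, x = coords[i]
        tang = _tangent(coords, i, path.closed)
        normal = np.array([-tang[1], tang[0]])
        ss = np.arange(-search_radius, search_radius + 1)
        pts = np.rint(
            np.array([y, x])[None, :] + ss[:, None] * normal[None, :]
        ).astype(int)
        ok = (pts[:, 0] >= 0) & (pts[:, 0] < h) & (pts[:, 1] >= 0) & (pts[:, 1] < w)
        weights = np.where(ok, img[pts[:, 0].clip(0, h - 1), pts[:, 1].clip(0, w - 1)], 0.0)
        total = weights.sum()
        if total <= 0:
            continue  # no signal in reach: leave in place
        s_star = float((ss * weights).sum() / total)
        targets[i] = np.rint(np.array([y, x]) + s_star * normal).astype(int)
        targets[i, 0] = np.clip(targets[i, 0], 0, h - 1)
        targets[i, 1] = np.clip(targets[i, 1], 0, w - 1)
    # redraw the moved line (moves may stretch or shorten it, so the pixel
    # count changes), then re-extract a canonical ordered 1-px path
    canvas = np.zeros((h, w), dtype=bool)
    pairs = zip(targets, np.roll(targets, -1, axis=0)) if path.closed else zip(
        targets[:-1], targets[1:]
    )
    for a, b in pairs:
        rr, cc = draw_line(int(a[0]), int(a[1]), int(b[0]), int(b[1]))
        canvas[rr, cc] = True
    from .segmentation import skeletonize_mask

    thin = skeletonize_mask(canvas)
    try:
        out = order_path(np.argwhere(thin), path.label, path.segment_id)
    except ConfigError:
        warnings.warn(
            "recentring would break the guiding line; leaving path in place",
            stacklevel=2,
        )
        return path
    if out.closed != path.closed:
        warnings.warn(
            "recentring changed the path topology; leaving path in place",
            stacklevel=2,
        )
        return path
    return out


def colocalize(
    trajectory: ProfileTrajectory,
    path: OrderedPath,
    third_channel_image: np.ndarray,
    pixel_size_um: float = 1.0,
) -> ProfileTrajectory:
    """Sample a third channel with the identical element and positions.

    The colocalization values are aligned 1:1 with the existing trajectory
    by DeltaX, enabling paired analysis (e.g. receptor enrichment where a
    phosphatase is excluded).
    """
    if len(path) != len(trajectory.delta_x_um):
        raise SpectromapError("colocalize: path and trajectory lengths differ")
    extra = profile_along(
        path,
        third_channel_image,
        (trajectory.element_shape, trajectory.element_size),
        pixel_size_um,
    )
    trajectory.coloc = extra.beta
    return trajectory


def split_by_threshold(
    trajectory: Union[ProfileTrajectory, np.ndarray],
    threshold: Optional[float] = None,
) -> dict:
    """Split trajectory values into high/low sets around a threshold.

    The default threshold is the median of the trajectory's own valid
    values, which splits a two-phase membrane into its ordered and
    disordered point sets.  Returns per-set medians, counts and
    ``fraction_high`` (share of valid points strictly above the threshold).
    """
    values = trajectory.beta if isinstance(trajectory, ProfileTrajectory) else np.asarray(trajectory)
    valid = values[np.isfinite(values)]
    if valid.size < 2:
        raise SpectromapError("split_by_threshold: need >= 2 valid points")
    if threshold is None:
        threshold = float(np.median(valid))
    high = valid[valid > threshold]
    low = valid[valid <= threshold]
    return {
        "threshold": threshold,
        "n_high": int(high.size),
        "n_low": int(low.size),
        "fraction_high": float(high.size / valid.size),
        "median_high": float(np.median(high)) if high.size else float("nan"),
        "median_low": float(np.median(low)) if low.size else float("nan"),
    }
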