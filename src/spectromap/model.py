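"""Core data model: the image hypercube and the run configuration.

The canonical in-memory image is a 5-axis array in ``(t, z, c, y, x)`` order.
Axes absent from the source file are padded to length 1 and recorded in
``axes_present`` so exporters can squeeze them back out.  Pixel coordinates
are 0-based ``(row=y, col=x)``; physical positions are ``index *
pixel_size_um``.

All configuration objects are plain dataclasses that round-trip through JSON
bit-exactly (same key order, same float repr), which makes saved parameter
files diffable and re-runnable.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np

from .errors import ConfigError

CANONICAL_AXES = "tzcyx"

__all__ = [
    "ImageStack",
    "MaskingParams",
    "SegmentationParams",
    "BetaConfig",
    "ProfileParams",
    "ExportOptions",
    "RunConfig",
    "MaskSet",
]


@dataclass
class ImageStack:
    """A multi-dimensional microscopy image in canonical (t,z,c,y,x) order.

    Parameters
    ----------
    data
        5-D array of non-negative intensities.
    pixel_size_um
        Isotropic x/y pixel size in micrometres; must be > 0.
    channel_centers_nm
        Optional per-channel emission-window centers, strictly increasing.
    dtype_max
        Saturation ceiling of the source encoding (e.g. 255 for 8-bit);
        ``None`` when the source has no meaningful ceiling (float data).
    axes_present
        Subset of ``"tzc"`` that was actually present in the source file.
    """

    data: np.ndarray
    pixel_size_um: float = 1.0
    channel_centers_nm: Optional[tuple[float, ...]] = None
    dtype_max: Optional[float] = None
    axes_present: str = "tzc"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ConfigError(
                f"ImageStack.data must be 5-D (t,z,c,y,x); got {self.data.ndim}-D"
            )
        if any(s < 1 for s in self.data.shape):
            raise ConfigError("all axis lengths must be >= 1")
        if not (self.pixel_size_um > 0):
            raise ConfigError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.channel_centers_nm is not None:
            self.channel_centers_nm = tuple(float(v) for v in self.channel_centers_nm)
            if len(self.channel_centers_nm) != self.n_channels:
                raise ConfigError(
                    "channel_centers_nm length "
                    f"{len(self.channel_centers_nm)} != channel count {self.n_channels}"
                )
            if any(
                b <= a
                for a, b in zip(self.channel_centers_nm, self.channel_centers_nm[1:])
            ):
                raise ConfigError("channel_centers_nm must be strictly increasing")
        bad = set(self.axes_present) - set("tzc")
        if bad:
            raise ConfigError(f"axes_present may only contain 'tzc', got {bad!r}")

    # -- convenience accessors -------------------------------------------------
    @property
    def n_t(self) -> int:
        return self.data.shape[0]

    @property
    def n_z(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[3], self.data.shape[4]

    def plane(self, t: int, z: int, c: int) -> np.ndarray:
        """One 2-D (y,x) channel plane."""
        return self.data[t, z, c]

    def slice_channels(self, t: int, z: int) -> np.ndarray:
        """All channels of one (t,z) slice, shape (c, y, x)."""
        return self.data[t, z]


@dataclass
class MaskSet:
    """Paired membrane/cytosol masks for one (t,z) slice with provenance."""

    membrane_mask: np.ndarray
    cytosol_mask: np.ndarray
    threshold_membrane: Optional[float] = None
    threshold_cytosol: Optional[float] = None
    provenance: Optional[dict] = None


def _check_finite(obj: Any, path: str) -> None:
    if isinstance(obj, float) and not math.isfinite(obj):
        raise ConfigError(f"non-finite value at config key {path!r}")
    if isinstance(obj, dict):
        for k, v in obj.items():
            _check_finite(v, f"{path}.{k}")
    if isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            _check_finite(v, f"{path}[{i}]")


class _JsonDataclass:
    """Mixin: dataclass <-> plain-dict conversion for JSON round-tripping."""

    def to_dict(self) -> dict:
        out: dict[str, Any] = {}
        for f in dataclasses.fields(self):  # type: ignore[arg-type]
            v = getattr(self, f.name)
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                v = v.to_dict()  # type: ignore[union-attr]
            elif isinstance(v, dict):
                v = {
                    k: (vv.to_dict() if isinstance(vv, _JsonDataclass) else vv)
                    for k, vv in v.items()
                }
            elif isinstance(v, tuple):
                v = list(v)
            out[f.name] = v
        return out

    @classmethod
    def from_dict(cls, d: dict):
        kwargs = {}
        hints = {f.name: f for f in dataclasses.fields(cls)}  # type: ignore[arg-type]
        for name, f in hints.items():
            if name not in d:
                continue
            kwargs[name] = d[name]
        return cls(**kwargs)  # type: ignore[call-arg]


@dataclass
class MaskingParams(_JsonDataclass):
    """Parameters of the mask-optimization pipeline for one target region.

    The pipeline runs in the fixed order: saturated-pixel removal ->
    SNR background rejection -> smoothing -> pixel-value compression ->
    channel selection -> Otsu threshold -> morphological cleanup.

    ``threshold_channels`` maps channel index -> non-negative weight; a single
    entry with weight 1 selects that channel, several entries form a weighted
    sum. ``morphology_ops`` is an ordered list of ``[op, value]`` pairs with
    op in {"remove_small", "dilation", "erosion", "closing", "fill_holes"}.
    """

    target: str = "membrane"
    snr_k: float = 0.0
    smooth_kind: str = "none"  # none | median | mean | gaussian
    smooth_size: float = 3.0  # window size (median/mean) or sigma (gaussian)
    compress_enabled: bool = False
    gamma: float = 1.0
    p_lo: float = 0.0
    p_hi: float = 100.0
    threshold_channels: dict[str, float] = field(default_factory=lambda: {"0": 1.0})
    morphology_ops: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.target not in ("membrane", "cytosol"):
            raise ConfigError(f"target must be membrane|cytosol, got {self.target!r}")
        if self.snr_k < 0:
            raise ConfigError("snr_k must be >= 0")
        if not (0 < self.gamma <= 1):
            raise ConfigError(f"gamma must be in (0, 1], got {self.gamma}")
        if not (0 <= self.p_lo < self.p_hi <= 100):
            raise ConfigError(
                f"percentiles must satisfy 0 <= p_lo < p_hi <= 100, got "
                f"({self.p_lo}, {self.p_hi})"
            )
        if self.smooth_kind not in ("none", "median", "mean", "gaussian"):
            raise ConfigError(f"unknown smoothing filter {self.smooth_kind!r}")
        self.threshold_channels = {
            str(k): float(v) for k, v in self.threshold_channels.items()
        }
        if not self.threshold_channels:
            raise ConfigError("threshold_channels must name at least one channel")
        if any(w < 0 for w in self.threshold_channels.values()):
            raise ConfigError("threshold channel weights must be >= 0")
        self.morphology_ops = [list(op) for op in self.morphology_ops]
        known = {"remove_small", "dilation", "erosion", "closing", "fill_holes"}
        for op in self.morphology_ops:
            if len(op) != 2 or op[0] not in known:
                raise ConfigError(f"bad morphology op {op!r}; known: {sorted(known)}")

    def channel_weights(self, n_channels: int) -> list[tuple[int, float]]:
        """Validated (index, weight) pairs against an actual channel count."""
        pairs = []
        for k, w in self.threshold_channels.items():
            idx = int(k)
            if not (0 <= idx < n_channels):
                raise ConfigError(
                    f"threshold channel {idx} out of range for {n_channels} channels"
                )
            pairs.append((idx, w))
        return sorted(pairs)


@dataclass
class SegmentationParams(_JsonDataclass):
    """Knobs of the skeleton / distance-transform / DBSCAN object detector.

    ``tol_0`` (pixels, > 0) is how far each filled object retracts from its
    boundary before clustering — larger values split more tightly fused
    objects at the price of losing thin ones.  ``tol`` (pixels, >= 0) pads
    the per-object crop window.  The DBSCAN defaults reduce to plain
    8-connected labelling on dense masks while tolerating 1-px raggedness.
    """

    tol_0: float = 4.0
    tol: float = 2.0
    dbscan_radius: float = 1.5
    dbscan_min_points: int = 4
    prune_len: int = 10

    def __post_init__(self) -> None:
        if not (self.tol_0 > 0):
            raise ConfigError(f"tol_0 must be > 0, got {self.tol_0}")
        if self.tol < 0:
            raise ConfigError("tol must be >= 0")
        if self.dbscan_radius < 1:
            raise ConfigError("dbscan_radius must be >= 1")
        if self.dbscan_min_points < 1:
            raise ConfigError("dbscan_min_points must be >= 1")
        if self.prune_len < 0:
            raise ConfigError("prune_len must be >= 0")


@dataclass
class BetaConfig(_JsonDataclass):
    """A user equation over up to four channels defining the beta-value.

    ``expression`` is an arithmetic formula over identifiers C1..C4 (e.g. the
    generalized-polarization form ``"(C1-C2)/(C1+C2)"``); ``channel_binding``
    maps each identifier to a channel index.  Pixels whose value is
    non-finite or falls outside ``valid_range`` are removed (NaN).
    """

    expression: str = "(C1-C2)/(C1+C2)"
    channel_binding: dict[str, int] = field(
        default_factory=lambda: {"C1": 0, "C2": 1}
    )
    valid_range: Optional[list] = None
    target: str = "membrane"

    def __post_init__(self) -> None:
        if len(self.channel_binding) > 4:
            raise ConfigError("at most four channels may be bound (C1..C4)")
        for k in self.channel_binding:
            if k not in ("C1", "C2", "C3", "C4"):
                raise ConfigError(f"bad identifier {k!r}; use C1..C4")
        self.channel_binding = {k: int(v) for k, v in self.channel_binding.items()}
        if self.valid_range is not None:
            if len(self.valid_range) != 2 or not self.valid_range[0] < self.valid_range[1]:
                raise ConfigError(
                    f"valid_range must be [lo, hi] with lo < hi, got {self.valid_range}"
                )
            self.valid_range = [float(v) for v in self.valid_range]


@dataclass
class ProfileParams(_JsonDataclass):
    """Membrane-profiling options.

    The integrating element is either a ``size x size`` square or a
    ``size x 1`` line oriented along the local tangent; ``size`` must be odd
    and >= 3 so the element is centred on the guiding line.
    """

    element_shape: str = "square"  # square | line
    element_size: int = 3
    recenter_radius: int = 0
    coloc_channel: Optional[int] = None

    def __post_init__(self) -> None:
        if self.element_shape not in ("square", "line"):
            raise ConfigError("element_shape must be 'square' or 'line'")
        if self.element_size < 3 or self.element_size % 2 == 0:
            raise ConfigError("element_size must be odd and >= 3")
        if self.recenter_radius < 0:
            raise ConfigError("recenter_radius must be >= 0")


@dataclass
class ExportOptions(_JsonDataclass):
    csv: bool = True
    xlsx: bool = True
    beta_tiff: bool = True
    mask_tiff: bool = False
    labels_tiff: bool = False
    params_json: bool = True


def _slice_key(t: int, z: int) -> str:
    return f"{t},{z}"


@dataclass
class RunConfig(_JsonDataclass):
    """Everything needed to reproduce one analysis run.

    Per-slice masking overrides are keyed ``"t,z"`` and fall back to the
    global parameter set for slices without an entry.
    """

    masking_membrane: MaskingParams = field(default_factory=MaskingParams)
    masking_cytosol: Optional[MaskingParams] = None
    cytosol_mode: str = "derived"  # derived | independent | none
    membrane_overrides: dict[str, MaskingParams] = field(default_factory=dict)
    cytosol_overrides: dict[str, MaskingParams] = field(default_factory=dict)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    beta_membrane: Optional[BetaConfig] = None
    beta_cytosol: Optional[BetaConfig] = None
    profiling: ProfileParams = field(default_factory=ProfileParams)
    export: ExportOptions = field(default_factory=ExportOptions)
    pixel_size_um: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cytosol_mode not in ("derived", "independent", "none"):
            raise ConfigError(
                f"cytosol_mode must be derived|independent|none, got {self.cytosol_mode!r}"
            )
        if isinstance(self.masking_membrane, dict):
            self.masking_membrane = MaskingParams.from_dict(self.masking_membrane)
        if isinstance(self.masking_cytosol, dict):
            self.masking_cytosol = MaskingParams.from_dict(self.masking_cytosol)
        if isinstance(self.segmentation, dict):
            self.segmentation = SegmentationParams.from_dict(self.segmentation)
        if isinstance(self.beta_membrane, dict):
            self.beta_membrane = BetaConfig.from_dict(self.beta_membrane)
        if isinstance(self.beta_cytosol, dict):
            self.beta_cytosol = BetaConfig.from_dict(self.beta_cytosol)
        if isinstance(self.profiling, dict):
            self.profiling = ProfileParams.from_dict(self.profiling)
        if isinstance(self.export, dict):
            self.export = ExportOptions.from_dict(self.export)
        self.membrane_overrides = {
            k: (MaskingParams.from_dict(v) if isinstance(v, dict) else v)
            for k, v in self.membrane_overrides.items()
        }
        self.cytosol_overrides = {
            k: (MaskingParams.from_dict(v) if isinstance(v, dict) else v)
            for k, v in self.cytosol_overrides.items()
        }
        if self.cytosol_mode == "independent" and self.masking_cytosol is None:
            raise ConfigError(
                "cytosol_mode='independent' requires masking_cytosol parameters"
            )

    # -- per-slice lookup ------------------------------------------------------
    def membrane_params_for(self, t: int, z: int) -> MaskingParams:
        return self.membrane_overrides.get(_slice_key(t, z), self.masking_membrane)

    def cytosol_params_for(self, t: int, z: int) -> Optional[MaskingParams]:
        return self.cytosol_overrides.get(_slice_key(t, z), self.masking_cytosol)

    # -- JSON ------------------------------------------------------------------
    def to_json(self) -> str:
        d = self.to_dict()
        _check_finite(d, "config")
        return json.dumps(d, indent=2, sort_keys=True, allow_nan=False)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.from_dict(json.loads(text))
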