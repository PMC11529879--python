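"""Reading image stacks and writing every output artifact.

Input is TIFF / OME-TIFF (the reference dialect; vendor formats can be
adapted by converting to OME-TIFF first).  Outputs are UTF-8 CSV, XLSX,
32-bit float TIFF for beta maps (removed pixels stored as NaN), 8/16-bit
TIFF for masks and label images, and JSON for parameters and metadata.

CSV and XLSX exports of the same run are numerically identical field by
field; missing beta values become empty cells, never zeros.
"""
from __future__ import annotations

import datetime
import json
import logging
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import AxisAmbiguityError, ConfigError, ImageIOError
from .model import CANONICAL_AXES, ImageStack, RunConfig

logger = logging.getLogger(__name__)

# Fixed workbook timestamp so repeated exports of identical results compare
# equal; the run date belongs in the log, not the artifact.
_EPOCH = datetime.datetime(2000, 1, 1)

_AXIS_ALIASES = {"s": "c", "q": None, "i": None}


def canonicalize(data: np.ndarray, axes: str) -> tuple[np.ndarray, str]:
    """Reorder ``data`` with per-dimension ``axes`` labels into (t,z,c,y,x).

    Returns the 5-D array and the subset of "tzc" that was present.
    Idempotent: canonical input comes back unchanged.
    """
    axes = axes.lower()
    if len(axes) != data.ndim:
        raise ConfigError(f"axes {axes!r} does not match {data.ndim}-D data")
    labels = []
    for a in axes:
        a = _AXIS_ALIASES.get(a, a)
        if a is None or a not in CANONICAL_AXES:
            raise AxisAmbiguityError(
                f"cannot interpret axis label {a!r} in {axes!r}",
                candidates=tuple(CANONICAL_AXES),
            )
        labels.append(a)
    if len(set(labels)) != len(labels):
        raise ConfigError(f"duplicate axis label in {axes!r}")
    if "y" not in labels or "x" not in labels:
        raise ConfigError(f"axes {axes!r} must include y and x")
    present = "".join(a for a in "tzc" if a in labels)
    order = [labels.index(a) for a in CANONICAL_AXES if a in labels]
    out = np.transpose(data, order)
    for i, a in enumerate(CANONICAL_AXES):
        if a not in labels:
            out = np.expand_dims(out, i)
    return out, present


def _dtype_ceiling(dtype: np.dtype) -> Optional[float]:
    if np.issubdtype(dtype, np.integer):
        return float(np.iinfo(dtype).max)
    return None


def load_image(
    path: str | Path,
    axis_hint: Optional[str] = None,
    pixel_size_um: Optional[float] = None,
    channel_centers_nm: Optional[Sequence[float]] = None,
) -> ImageStack:
    """Load a TIFF/OME-TIFF into a canonical :class:`ImageStack`.

    Axis order is taken from file metadata when present; ``axis_hint`` (e.g.
    ``"tcyx"``) overrides or supplies it when metadata is absent or ambiguous.
    Pixel size comes from OME ``PhysicalSizeX`` when available, else from the
    ``pixel_size_um`` argument, else defaults to 1 µm.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            data = series.asarray()
            file_axes = series.axes
            ome_px = None
            if tf.is_ome and tf.ome_metadata:
                m = re.search(r'PhysicalSizeX="([0-9.eE+-]+)"', tf.ome_metadata)
                if m:
                    ome_px = float(m.group(1))
    except (OSError, ValueError, tifffile.TiffFileError, IndexError) as exc:
        raise ImageIOError(f"cannot read image file {path}: {exc}") from exc

    axes = axis_hint if axis_hint is not None else file_axes
    try:
        canon, present = canonicalize(data, axes)
    except AxisAmbiguityError:
        if axis_hint is None:
            raise AxisAmbiguityError(
                f"axis order of {path} is ambiguous (file reports {file_axes!r}); "
                "pass axis_hint",
                candidates=tuple(CANONICAL_AXES),
            )
        raise
    return ImageStack(
        data=canon,
        pixel_size_um=ome_px or pixel_size_um or 1.0,
        channel_centers_nm=tuple(channel_centers_nm) if channel_centers_nm else None,
        dtype_max=_dtype_ceiling(canon.dtype),
        axes_present=present,
    )


def write_stack(
    path: str | Path,
    stack: ImageStack,
    channel_centers_nm: Optional[Sequence[float]] = None,
) -> None:
    """Write an :class:`ImageStack` as OME-TIFF, preserving pixel size."""
    meta = {
        "axes": "TZCYX",
        "PhysicalSizeX": stack.pixel_size_um,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": stack.pixel_size_um,
        "PhysicalSizeYUnit": "µm",
    }
    tifffile.imwrite(str(path), stack.data, ome=True, metadata=meta)


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def _normalize_zip_times(path: Path) -> None:
    """Rewrite a zip container with fixed member timestamps.

    XLSX is a zip archive whose member headers carry the wall-clock time of
    writing; pinning them makes repeated exports of identical results
    byte-identical.
    """
    import zipfile

    with zipfile.ZipFile(path) as zin:
        items = [(info, zin.read(info.filename)) for info in zin.infolist()]
    stamp = _EPOCH.strftime("%Y-%m-%dT%H:%M:%SZ").encode()
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zout:
        for info, data in items:
            info.date_time = (1980, 1, 1, 0, 0, 0)
            if info.filename == "docProps/core.xml":
                # openpyxl stamps the save wall-clock time here regardless
                # of the workbook properties set before saving
                data = re.sub(
                    rb"(<dcterms:(created|modified)[^>]*>)[^<]*(</dcterms:\2>)",
                    rb"\g<1>" + stamp + rb"\g<3>",
                    data,
                )
            zout.writestr(info, data)


def _objects_frame(records: Iterable) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "source": getattr(r, "source", ""),
            "t": getattr(r, "t", 0),
            "z": getattr(r, "z", 0),
            "label": r.label,
            "area_px": getattr(r, "area_px", np.nan),
            "area_um2": getattr(r, "area_um2", np.nan),
            "perimeter_um": getattr(r, "perimeter_um", np.nan),
            "eccentricity": getattr(r, "eccentricity", np.nan),
            "centroid_y": (r.centroid[0] if getattr(r, "centroid", None) else np.nan),
            "centroid_x": (r.centroid[1] if getattr(r, "centroid", None) else np.nan),
            "unreliable": getattr(r, "unreliable", False),
            "beta_median": getattr(r, "beta_median", np.nan),
            "beta_std": getattr(r, "beta_std", np.nan),
            "beta_count": getattr(r, "beta_count", 0),
            "n_segments": getattr(r, "n_segments", 0),
            "segment_lengths_um": ";".join(
                f"{v:.6g}" for v in getattr(r, "segment_lengths_um", []) or []
            ),
        }
        spectrum = getattr(r, "spectrum", None)
        if spectrum is not None:
            for i, v in enumerate(spectrum):
                row[f"spectrum_ch{i}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def _trajectories_frame(trajectories: Iterable) -> pd.DataFrame:
    rows = []
    for tr in trajectories:
        n = len(tr.delta_x_um)
        for i in range(n):
            row = {
                "label": tr.label,
                "segment_id": tr.segment_id,
                "delta_x_um": tr.delta_x_um[i],
                "beta": tr.beta[i] if tr.beta is not None else np.nan,
            }
            for name, arr in (tr.channel_intensities or {}).items():
                row[f"intensity_ch{name}"] = arr[i]
            if tr.coloc is not None:
                row["coloc"] = tr.coloc[i]
            rows.append(row)
    return pd.DataFrame(rows)


def export_tables(
    records: Sequence,
    whole_image_stats: Optional[dict],
    out_dir: str | Path,
    base_name: str = "results",
    trajectories: Sequence = (),
    write_csv: bool = True,
    write_xlsx: bool = True,
) -> dict[str, Path]:
    """Write per-object, whole-image and trajectory tables as CSV and XLSX.

    The XLSX workbook mirrors each CSV as one sheet with identical values.
    Returns the mapping of table name to the CSV path (or XLSX when CSV is
    disabled).  An empty result set produces header-only files and a warning.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ImageIOError(f"cannot create output directory {out_dir}: {exc}") from exc
    if not records and not whole_image_stats and not trajectories:
        logger.warning("export_tables called with no results; writing headers only")

    frames: dict[str, pd.DataFrame] = {}
    frames["objects"] = _objects_frame(records)
    if frames["objects"].empty:
        frames["objects"] = pd.DataFrame(
            columns=["source", "t", "z", "label", "area_px", "beta_median"]
        )
    if whole_image_stats is not None:
        frames["image_stats"] = pd.DataFrame([whole_image_stats])
    if trajectories:
        frames["trajectories"] = _trajectories_frame(trajectories)

    written: dict[str, Path] = {}
    if write_csv:
        for name, df in frames.items():
            p = out_dir / f"{base_name}_{name}.csv"
            df.to_csv(p, index=False)
            written[name] = p
    if write_xlsx:
        xp = out_dir / f"{base_name}.xlsx"
        with pd.ExcelWriter(xp, engine="openpyxl") as writer:
            for name, df in frames.items():
                df.to_excel(writer, sheet_name=name, index=False)
            writer.book.properties.created = _EPOCH
            writer.book.properties.modified = _EPOCH
        _normalize_zip_times(xp)
        for name in frames:
            written.setdefault(name, xp)
        written["xlsx"] = xp
    return written


# ---------------------------------------------------------------------------
# image export
# ---------------------------------------------------------------------------

def export_beta_tiff(beta_values: np.ndarray, path: str | Path, overwrite: bool = False) -> None:
    """Write a beta map as single-plane 32-bit float TIFF (removed = NaN)."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise ImageIOError(f"{path} exists; pass overwrite=True to replace it")
    tifffile.imwrite(str(path), np.asarray(beta_values, dtype=np.float32))


def export_mask_tiff(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as 8-bit TIFF (0/255)."""
    tifffile.imwrite(str(path), (np.asarray(mask, bool) * np.uint8(255)))


def export_labels_tiff(labels: np.ndarray, path: str | Path) -> None:
    """Write a label image as 16-bit TIFF."""
    tifffile.imwrite(str(path), np.asarray(labels, dtype=np.uint16))


# ---------------------------------------------------------------------------
# JSON export
# ---------------------------------------------------------------------------

def export_params_json(
    config: RunConfig,
    metadata: Optional[dict],
    params_path: str | Path,
    metadata_path: Optional[str | Path] = None,
) -> None:
    """Write the run configuration (and optional image metadata) as JSON.

    The configuration is validated (no NaN/Inf entries) before anything is
    written, so a failed export never leaves a half-written file behind.
    """
    text = config.to_json()  # raises ConfigError naming the offending key
    meta_text = None
    if metadata is not None:
        try:
            meta_text = json.dumps(metadata, indent=2, sort_keys=True, allow_nan=False)
        except ValueError as exc:
            raise ConfigError(f"metadata is not JSON-serializable: {exc}") from exc
    Path(params_path).write_text(text, encoding="utf-8")
    if meta_text is not None:
        if metadata_path is None:
            raise ConfigError("metadata given but metadata_path is None")
        Path(metadata_path).write_text(meta_text, encoding="utf-8")


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a JSON file."""
    try:
        text = Path(path).read_text(encoding="utf-8")
    except OSError as exc:
        raise ImageIOError(f"cannot read config {path}: {exc}") from exc
    return RunConfig.from_json(text)
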