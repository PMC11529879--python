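"""High-level drivers: one image or a batch, masking through export.

``run_single`` executes masking -> beta computation -> (optional)
segmentation -> (optional) profiling for every (t, z) slice of one image
and writes the export artifacts; ``run_batch`` maps it over a sorted list
of files, never letting one failure abort the rest, and concatenates all
per-object rows into one aggregate table with a source-file column.

Results are deterministic: files are processed in sorted-path order and no
artifact embeds a timestamp.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import beta as beta_mod
from . import masking, profiling, readwrite, segmentation
from .errors import SpectromapError
from .model import ImageStack, RunConfig

logger = logging.getLogger(__name__)

__all__ = ["RunSummary", "run_single", "run_batch"]


@dataclass
class RunSummary:
    """Counts and outcomes of one image run."""

    source: str
    object_count: int = 0
    removed_pixels: int = 0
    segment_count: int = 0
    slices_processed: int = 0
    slice_errors: list = field(default_factory=list)
    ok: bool = True


def _whole_image_stats(
    stack: ImageStack, mask: np.ndarray, config, t: int, z: int, prefix: str
) -> tuple[dict, int]:
    """Beta stats + spectrum + phasor for one region of one slice."""
    out: dict = {}
    removed = 0
    if config is None or not mask.any():
        return out, removed
    bmap = beta_mod.compute_beta_map(stack, mask, config, t=t, z=z)
    removed = bmap.removed_count
    try:
        stats = beta_mod.beta_stats(bmap)
    except SpectromapError:
        stats = {"median": np.nan, "std": np.nan, "count": 0}
    out[f"{prefix}_beta_median"] = stats["median"]
    out[f"{prefix}_beta_std"] = stats["std"]
    out[f"{prefix}_beta_count"] = stats["count"]
    out[f"{prefix}_removed"] = removed
    spectrum = beta_mod.reconstruct_spectrum(stack, mask, t=t, z=z)
    for i, v in enumerate(spectrum.intensities):
        out[f"{prefix}_spectrum_ch{i}"] = float(v)
    point = beta_mod.phasor_transform(spectrum)
    out[f"{prefix}_phasor_G"] = point.G
    out[f"{prefix}_phasor_S"] = point.S
    return out, removed


def _profile_object(
    rec: segmentation.ObjectRecord,
    beta_values: np.ndarray,
    stack: ImageStack,
    config: RunConfig,
    t: int,
    z: int,
) -> list[profiling.ProfileTrajectory]:
    """Profile one object's skeleton share, segment by segment."""
    skel_img = np.zeros(stack.shape_yx, dtype=bool)
    skel_img[rec.skeleton_pixels[:, 0], rec.skeleton_pixels[:, 1]] = True
    graph = profiling.detect_nodes_and_segments(skel_img)
    params = config.profiling
    trajectories = []
    for seg in graph.segments:
        seg.label = rec.label
        if params.recenter_radius and config.beta_membrane is not None:
            chan = config.beta_membrane.channel_binding.get("C1", 0)
            seg = profiling.recenter_guideline(
                seg, stack.plane(t, z, chan), params.recenter_radius
            )
        traj = profiling.profile_along(
            seg, beta_values, params, stack.pixel_size_um
        )
        for ident, ch in (config.beta_membrane.channel_binding.items()
                          if config.beta_membrane else []):
            ch_traj = profiling.profile_along(
                seg, stack.plane(t, z, ch).astype(float), params, stack.pixel_size_um
            )
            traj.channel_intensities[str(ch)] = ch_traj.beta
        if params.coloc_channel is not None:
            profiling.colocalize(
                traj, seg, stack.plane(t, z, params.coloc_channel).astype(float),
                stack.pixel_size_um,
            )
        trajectories.append(traj)
    rec.n_segments = graph.n_segments
    rec.segment_lengths_um = graph.segment_lengths_um(stack.pixel_size_um)
    return trajectories


def run_single(
    image_path: str | Path,
    config: RunConfig,
    out_dir: str | Path,
    mode: str = "objects",
    profile: bool = False,
    axis_hint: Optional[str] = None,
    stack: Optional[ImageStack] = None,
) -> RunSummary:
    """Analyse one image and write every requested artifact.

    ``mode="whole"`` produces whole-image statistics only; ``mode="objects"``
    adds segmentation (and profiling when ``profile`` is set).  A stage
    failure on one slice is logged and the run continues with the next.
    """
    image_path = Path(image_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = RunSummary(source=image_path.name)
    if stack is None:
        stack = readwrite.load_image(
            image_path, axis_hint=axis_hint, pixel_size_um=config.pixel_size_um
        )
    records: list[segmentation.ObjectRecord] = []
    trajectories: list[profiling.ProfileTrajectory] = []
    image_stats: dict = {"source": image_path.name}

    for t in range(stack.n_t):
        for z in range(stack.n_z):
            try:
                mask_set = masking.build_masks(
                    stack,
                    config.membrane_params_for(t, z),
                    config.cytosol_params_for(t, z),
                    t=t,
                    z=z,
                    cytosol_mode=config.cytosol_mode,
                )
                stats_m, removed_m = _whole_image_stats(
                    stack, mask_set.membrane_mask, config.beta_membrane, t, z,
                    f"t{t}z{z}_membrane",
                )
                stats_c, removed_c = _whole_image_stats(
                    stack, mask_set.cytosol_mask, config.beta_cytosol, t, z,
                    f"t{t}z{z}_cytosol",
                )
                image_stats.update(stats_m)
                image_stats.update(stats_c)
                summary.removed_pixels += removed_m + removed_c

                beta_map = None
                if config.beta_membrane is not None and mask_set.membrane_mask.any():
                    beta_map = beta_mod.compute_beta_map(
                        stack, mask_set.membrane_mask, config.beta_membrane, t=t, z=z
                    )
                    if config.export.beta_tiff:
                        readwrite.export_beta_tiff(
                            beta_map.values,
                            out_dir / f"{image_path.stem}_t{t}z{z}_membrane_beta.tif",
                            overwrite=True,
                        )

                if mode == "objects":
                    recs, labeled = segmentation.segment_objects(
                        mask_set.membrane_mask,
                        config.segmentation,
                        stack.pixel_size_um,
                    )
                    if config.export.labels_tiff:
                        readwrite.export_labels_tiff(
                            labeled, out_dir / f"{image_path.stem}_t{t}z{z}_labels.tif"
                        )
                    for rec in recs:
                        rec.t, rec.z, rec.source = t, z, image_path.name
                        if beta_map is not None:
                            vals = rec.crop(beta_map.values)
                            valid = vals[np.isfinite(vals)]
                            if valid.size:
                                rec.beta_median = float(np.median(valid))
                                rec.beta_std = float(np.std(valid))
                                rec.beta_count = int(valid.size)
                        region = rec.crop(mask_set.membrane_mask)
                        if region.any():
                            full = np.zeros(stack.shape_yx, dtype=bool)
                            y0, x0, y1, x1 = rec.bbox
                            full[y0:y1, x0:x1] = region
                            rec.spectrum = beta_mod.reconstruct_spectrum(
                                stack, full, t=t, z=z
                            ).intensities
                        if profile and beta_map is not None:
                            trajectories.extend(
                                _profile_object(rec, beta_map.values, stack, config, t, z)
                            )
                    records.extend(recs)
                summary.slices_processed += 1
            except SpectromapError as exc:
                logger.error("slice (t=%d, z=%d) of %s failed: %s", t, z, image_path, exc)
                summary.slice_errors.append((t, z, str(exc)))

    summary.object_count = len(records)
    summary.segment_count = sum(r.n_segments for r in records)
    readwrite.export_tables(
        records,
        image_stats,
        out_dir,
        base_name=image_path.stem,
        trajectories=trajectories,
        write_csv=config.export.csv,
        write_xlsx=config.export.xlsx,
    )
    if config.export.params_json:
        readwrite.export_params_json(
            config,
            {
                "source": image_path.name,
                "shape_tzcyx": list(stack.data.shape),
                "pixel_size_um": stack.pixel_size_um,
                "axes_present": stack.axes_present,
            },
            out_dir / f"{image_path.stem}_params.json",
            out_dir / f"{image_path.stem}_metadata.json",
        )
    summary.ok = not summary.slice_errors or summary.slices_processed > 0
    return summary


def run_batch(
    inputs: Sequence[str | Path],
    config: RunConfig,
    out_dir: str | Path,
    mode: str = "objects",
    profile: bool = False,
    axis_hint: Optional[str] = None,
) -> list[RunSummary]:
    """Process files in sorted order; aggregate per-object rows at the end.

    One failing file is recorded (``ok=False``) and the batch continues.
    The aggregate CSV carries a ``source`` column, so outputs are
    independent of file discovery order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = sorted(Path(p) for p in inputs)
    if not paths:
        raise SpectromapError("no inputs")
    summaries: list[RunSummary] = []
    frames = []
    for path in paths:
        sub = out_dir / path.stem
        try:
            summary = run_single(
                path, config, sub, mode=mode, profile=profile, axis_hint=axis_hint
            )
        except SpectromapError as exc:
            logger.error("file %s failed: %s", path, exc)
            summary = RunSummary(source=path.name, ok=False)
            summary.slice_errors.append((-1, -1, str(exc)))
        summaries.append(summary)
        obj_csv = sub / f"{path.stem}_objects.csv"
        if obj_csv.exists():
            df = pd.read_csv(obj_csv)
            if not df.empty:
                frames.append(df)
    agg = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["source", "t", "z", "label"]
    )
    agg.to_csv(out_dir / "aggregate_objects.csv", index=False)
    return summaries
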