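# spectromap

Headless analysis of multi-dimensional fluorescence microscopy images:
mask optimization, single-object segmentation, pixel-wise biophysical
parameter maps, and sub-pixel-ordered membrane profiling, with batch
processing and tabular/image export.

## What problem it solves

Environment-sensitive membrane probes (LAURDAN, NR12S/A, Pro12A) shift
their emission with lipid order, and ratiometric dyes such as JC-1 report
mitochondrial membrane potential through an aggregate/monomer intensity
ratio. Turning such multi-channel or spectral images into numbers requires
pixel-wise arithmetic over channels, careful masking (background and
saturated pixels corrupt any ratio), per-cell segmentation, and — for
membranes — a way to read the signal *along* the bilayer rather than over
an area. `spectromap` provides that chain as a library plus a CLI, for
researchers quantifying membrane fluidity, phase separation, organelle
potential, or protein redistribution at cell–cell contacts.

The central quantity is a generic **β-value**: any arithmetic expression
over up to four channel intensities, evaluated per pixel inside a mask.
The canonical example is the generalized polarization,

```
GP = (I_ordered − I_disordered) / (I_ordered + I_disordered) ∈ [−1, 1],
```

where higher GP means a more ordered (less fluid) membrane; another preset
is the mitochondrial potential ratio `I_red / I_green`. Pixels whose
expression produces a non-finite value (0/0, division by zero) or falls
outside a user range are *removed* — stored as NaN, exported as empty
cells, never as zeros.

Key components:

* **Masking** — saturated-pixel removal, SNR background rejection
  (`µ_b + k·σ_b`), smoothing, monotone pixel-value compression
  (`hi·(I/hi)^γ`, which makes regions of different brightness separable by
  one Otsu cut), thresholding on any channel or weighted channel
  combination, exact-histogram Otsu, and ordered morphological cleanup.
  Membrane and cytosol masks are built independently.
* **Segmentation** — skeletonize the mask, prune side branches, fill
  closed membrane loops (discarding anything touching the image border),
  retract each body by `tol₀` via the Euclidean distance transform so
  fused objects split at their neck, label the cores with DBSCAN, then
  expand back out and crop per object. Morphology (area, Crofton
  perimeter, eccentricity) is reported per object.
* **Profiling** — a 1-px guiding line centred on the membrane is ordered
  into a unidirectional walk; a constant-area element (k×k square or k×1
  tangent line) slides along it producing β/intensity trajectories versus
  arc length ΔX (µm), with node/segment decomposition for clustered
  objects, optional line recentring, third-channel colocalization, and
  threshold splitting of trajectory points.
* **Synthetic scenes** (`spectromap.synth`) — ground-truthed phase-
  separated vesicles, four-channel cells with ratiometric puncta, and
  contact-site rings, rendered with 4× supersampling so every measurement
  can be validated against construction.

## Worked example

A 70/30 phase-separated vesicle with channel intensities (200, 100) in the
ordered phase and (100, 200) in the disordered phase — so GP is exactly
+1/3 and −1/3:

```python
import numpy as np
from spectromap import synth, masking, beta, profiling
from spectromap.model import MaskingParams, BetaConfig

spec = synth.two_phase_ring_spec(fraction_a=0.7)        # 70% ordered phase
stack, truth = synth.make_vesicle_scene(spec)

params = MaskingParams(snr_k=3.0, threshold_channels={"0": 1.0, "1": 1.0},
                       compress_enabled=True, gamma=0.5)
masks = masking.build_masks(stack, params)

gp = beta.compute_beta_map(stack, masks.membrane_mask, BetaConfig())
stats = beta.beta_stats(gp)
print(f"membrane pixels: {int(masks.membrane_mask.sum())}, "
      f"GP median: {stats['median']:+.4f}, std: {stats['std']:.4f}")

line = profiling.extract_guideline(masks.membrane_mask)
path = profiling.order_path(np.argwhere(line))
traj = profiling.profile_along(path, gp.values, ("square", 3), stack.pixel_size_um)
split = profiling.split_by_threshold(traj, threshold=0.0)
print(f"profiled {len(traj.delta_x_um)} points over "
      f"{traj.delta_x_um[-1]:.2f} um of membrane")
print(f"high-GP fraction: {split['fraction_high']:.3f}, "
      f"set medians: {split['median_high']:+.4f} / {split['median_low']:+.4f}")
```

Output:

```
membrane pixels: 320, GP median: +0.3333, std: 0.3055
profiled 89 points over 10.21 um of membrane
high-GP fraction: 0.697, set medians: +0.3333 / -0.3333
```

The mask threshold is taken on the channel *sum* (uniform across both
phases) after γ-compression, so the whole ring is masked; the per-phase GP
medians recover the constructed ±1/3 exactly, and 69.7% of profiled points
lie in the high-GP set, matching the 70% angular fraction up to
element-edge effects at the two phase boundaries.

Batch runs from the shell:

```
spectromap 'data/*.ome.tif' --config run.json --out results/ --mode objects --profile
```

where `run.json` is a serialized `RunConfig` (masking, segmentation, β
expressions, profiling element, per-slice overrides). Each image yields
CSV + XLSX tables (objects, whole-image statistics, trajectories), a
float-32 β TIFF with NaN for removed pixels, and the parameters/metadata
as JSON; the batch adds an aggregate object table with a source column.

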