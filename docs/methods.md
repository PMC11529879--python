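# Methods

This note documents the models, algorithms and numerical choices behind
`spectromap`, the assumptions they rest on, and what the synthetic-scene
validation does and does not establish about real microscopy data.

## Image model

Images live in a canonical 5-axis hypercube `(t, z, c, y, x)`; axes absent
from the source file are padded to length 1 and recorded so exports can
squeeze them back. Pixel coordinates are 0-based `(row=y, col=x)` and
physical positions are `index × pixel_size_um` with isotropic x/y pixels.
The saturation ceiling is taken from the source bit depth (e.g. 255,
65535); float sources have none. Channel wavelength centers, when known,
are carried for spectra and export only — no algorithm depends on them.

## Masking

Ratio-type quantities amplify noise: a background pixel entering
`(C1−C2)/(C1+C2)` can produce any value in [−1, 1]. The pipeline therefore
rejects unusable pixels *before* thresholding, in a fixed order:

1. **Saturated-pixel removal.** A pixel at the encoding ceiling in any
   used channel has an unknown true intensity and is excluded from both
   thresholding and β computation.
2. **SNR filter.** Background statistics (µ_b, σ_b) are estimated from
   the pixels at or below a provisional Otsu cut on the raw plane; pixels
   above `µ_b + k·σ_b` survive. `k` (default 3) trades background leakage
   against dim-signal loss; `k = 0` reduces to "above background mean".
   The below-provisional-Otsu background estimator was chosen because it
   needs no separate background ROI and is stable whenever background
   occupies a nontrivial image fraction.
3. **Smoothing.** Optional median / mean / Gaussian filter (window or σ
   in pixels).
4. **Pixel-value compression.** `out = hi · (clip(v, lo, hi)/hi)^γ` with
   `(lo, hi)` the (p_lo, p_hi) percentile values and γ ∈ (0, 1]. The map
   is monotone (never reorders pixels), is the identity at γ = 1 over the
   full window, and contracts brightness ratios to their γ-th power — two
   regions 10× apart end up √10 apart at γ = 0.5 — which is what lets a
   single Otsu cut capture a membrane whose phases differ several-fold in
   brightness. Normalizing by the window ceiling (rather than affinely
   pinning both window endpoints) is essential for that contraction
   property: an endpoint-pinned map leaves the extremes untouched.
5. **Channel selection.** Thresholding runs on one channel or a
   non-negative weighted channel sum. For two-phase membranes the sum of
   the two GP channels is the natural choice: total brightness is
   approximately phase-independent.
6. **Otsu threshold.** Computed over the *exact* distinct-value histogram
   of the surviving pixels, maximizing the between-class variance
   `w₀w₁(µ₀−µ₁)²`; ties resolve to the lowest threshold and the mask is
   strictly-above, so tied pixels fall to background. The in-package
   implementation (cumulative sums over unique values) is exact for
   integer data of any bit depth, where bin-center-based implementations
   can return values that are not attainable thresholds; the scikit-image
   implementation serves as an independent cross-check in the tests.
   Restricting Otsu to the SNR survivors is deliberate: on a
   background-dominated image a global cut separates background from
   foreground, whereas the survivors' cut separates the structures of
   interest (e.g. membrane from cytosol).
7. **Morphological cleanup.** An ordered op list: remove small components
   (8-connected), dilation/erosion/closing with a disk, fill holes.
   Dilation is the tool for restoring membrane continuity when the band
   has 1-px gaps — segmentation and profiling both require a closed band.

The cytosol mask is either derived (filled membrane interior minus the
band — guaranteed disjoint) or built independently from its own parameter
set and then made disjoint from the membrane. Parameters can be global or
overridden per `(t, z)` slice.

## β-value engine

Expressions over `C1..C4` support `+ − * / ^` (also `×`, `÷`), unary
minus, parentheses and numeric constants; `^` is right-associative and
binds tighter than unary minus. The recursive-descent parser exposes
nothing beyond those operators, so evaluating configuration files is safe
by construction. Evaluation is vectorized over the masked pixels only —
out-of-mask pixels are never read (verified by NaN-poisoning tests).
"Erroneous" is defined as non-finite after evaluation, or outside the
optional `[β_min, β_max]` validity window; such pixels become NaN and are
counted. Statistics (median, std, count), histograms (NaN-excluded,
counts conserve the valid-pixel total), per-channel mean spectra, and the
spectral phasor
`G = Σ I_k cos(2πnk/N) / Σ I_k`, `S = Σ I_k sin(2πnk/N) / Σ I_k`
(first harmonic by default; any non-negative spectrum lands inside the
unit circle) are computed per region. The phasor is the standard spectral
phasor over the channel axis; a phasor of the β histogram would be the
alternative reading, and is intentionally not what this implements.

## Segmentation

Six deterministic steps from optimized mask to labelled objects:

1. **Skeletonize** (scikit-image) and canonicalize: staircase-corner
   pixels whose two neighbours are mutually adjacent are removed, giving
   loops in which every pixel has exactly two 8-neighbours.
2. **Prune side branches**: from each 1-neighbour endpoint, walk to the
   first junction (≥ 3 neighbours); delete the walked pixels if the branch
   is at most `prune_len` (default 10 px). Loops are never broken;
   isolated open arcs are kept (they are input for profiling, not object
   bodies). Each pass ends with corner canonicalization because removing
   a branch can expose a 1-px stub at the attachment point.
3. **Fill and de-border**: closed loops are filled (the body includes the
   1-px line, so a loop of mid-radius r encloses ≈ π(r+½)² pixels); any
   component whose skeleton touches the image border — a cropped membrane
   — is discarded entirely; open arcs enclose nothing.
4. **Distance shrink**: keep pixels whose Euclidean distance transform
   exceeds `tol₀`. Fused objects separate where the neck half-width is
   below `tol₀`; an object vanishes (with a warning giving its location)
   if `tol₀` exceeds its inradius. Note that skeletonizing two crossing
   membrane bands rounds off the concave fusion notch, so the effective
   waist is wider than the ideal circle-intersection geometry — `tol₀`
   should be chosen against the *observed* neck, and the default suite
   geometry (radius-13 rings, centres 26 px apart, `tol₀ = 7`) reflects
   that.
5. **DBSCAN labelling** of core pixels (defaults: radius 1.5 px,
   min_points 4). With radius 1.5 and min_points 1 this provably reduces
   to 8-connected component labelling; min_points 4 additionally discards
   stray pixels. Labels are renumbered by the row-major position of each
   cluster's first pixel, making the labelling order deterministic.
6. **Expansion and cropping**: every body/skeleton pixel is assigned to
   the nearest core (per-label distance transforms; equidistant pixels go
   to the lower label), partitioning the global skeleton among objects.
   The crop window is the bounding box of body ∪ skeleton share padded by
   `tol` pixels.

Morphology per object: area = pixel count × pixel area; perimeter via the
4-direction Crofton estimator (naive pixel-edge counting overestimates a
circle's perimeter by ~27%, Crofton is within ~2%); eccentricity from
second-order central moments. Bodies under 5 px are flagged unreliable.

## Membrane profiling

The guiding line is the 1-px skeleton of the membrane band. In clustered
objects, node pixels (≥ 3 neighbours, adjacent node pixels merged) split
the line into segments; each segment is ordered into a unidirectional
walk: open paths start at the topmost-then-leftmost endpoint; loops start
at the topmost-then-leftmost pixel and proceed clockwise in display
coordinates (y down — i.e. rightward along the top first). Both rules are
arbitrary but fixed: determinism beats convention here. ΔX is the
cumulative Euclidean step length (1 or √2 px) times the pixel size — true
arc length, not projected displacement.

The integrating element is a k×k square or a k×1 line along the local
tangent (estimated from the path ±2 neighbours), k odd ≥ 3, centred on
each path pixel in turn; the trajectory value is the mean of the valid
(finite) pixels under it. Because the β map is NaN outside the mask, the
element automatically excludes cytosol and background; a fully-NaN
element yields a NaN trajectory point. The element has constant area
regardless of local curvature — unlike equal-angle sector integration,
which distorts on non-spherical shapes. Larger elements trade spatial
resolution for smoothness; the transition zone across a phase boundary is
bounded by the element extent plus the ~2 px of anti-aliased boundary.

Recentring (for membranes with clusters or aggregates that pull the
skeleton off the intensity ridge) moves each path pixel to the
intensity-weighted centroid along the local normal within a search
radius, then redraws the moved polyline, re-skeletonizes and re-orders
it. The redraw step is what allows the line to stretch: a fixed set of
snapped pixels cannot migrate to a longer contour without tearing
(per-pixel moves with connectivity checks deadlock). If re-extraction
would change the topology, the original path is kept and a warning
issued. Colocalization samples a third channel with the identical element
at the identical positions; `split_by_threshold` divides trajectory
points into sets above/below a threshold (defaulting to the trajectory's
own median β) and reports per-set medians and the high fraction.

## Synthetic scenes and what the tests show

The generator renders anti-aliased (4× supersampled, box-averaged) rings
with per-phase channel intensities and angular fractions, optional radial
lobes (starfish shapes), fused pairs, border-clipped rings, cytosolic
ratiometric puncta and contact-site enrichment/exclusion arcs. Noise
(Gaussian and/or Poisson, seeded) is applied after downsampling, so the
expected interior intensity equals the specification exactly and
noise-free scenes give bit-exact β values; ground truth (labels, bands,
pure-phase pixels with a 1-px radial and ~2-px angular margin, per-phase
β including the background offset) is computed at the same resolution.
Default conditions: 0.1 µm pixels, radii 12–20 px (GUV/GPMV equatorial
sections at confocal sampling), 3-px membrane bands, phase intensities
200/100 (GP = ±1/3), background 2, σ = 1 counting noise where noise is
wanted; exactness fixtures use zero background so the constructed values
are the stated closed forms.

What passing does **not** show: real images have structured background,
shading, spectral bleed-through, out-of-focus light and PSF correlations
none of which the generator emulates; the validation establishes
correctness of the computations, not robustness to acquisition
pathologies. Parameter guidance (snr_k, γ, tol₀) transfers qualitatively,
not numerically.

## Problem sizes and numerical choices

Validation scenes are 96–160 px squares with up to six objects — large
enough that digitization error is below the stated tolerances (e.g. disk
perimeter error 1.6% at r = 20) and small enough that the whole suite and
the acceptance script run in seconds. Ties: Otsu ties → background;
expansion ties → lower label; DBSCAN founder order → row-major. Degenerate
inputs: constant images are an error for Otsu, an all-background warning
for the SNR filter; empty masks yield empty maps with warnings; zero-total
spectra yield NaN phasor points. All exports avoid wall-clock state (XLSX
member timestamps are pinned), so identical runs are byte-identical.

## Known limitations

* Vesicles fused more deeply than the `tol₀` geometry allows (waist wider
  than every object's inradius) cannot be split; adaptive or
  learning-based segmentation is out of scope.
* Profiling assumes a closed or simply-branched 1-px line; membranes
  whose mask cannot be made continuous profile as multiple segments.
* The spectral phasor is computed from channel indices, not calibrated
  wavelengths; harmonics beyond the first are supported but untested
  against instrument conventions.
* No background subtraction is applied before β computation; offsets bias
  ratio-type β values (the generator's ground truth accounts for this,
  real data may need pre-processing).
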